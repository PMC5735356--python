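"""Novel-miRNA candidate filtering.

A candidate precursor hairpin is accepted when all of

* discovery score > 1 (produced externally by a miRDeep-like tool),
* randfold-style permutation P-value < 0.05,
* minimum folding energy (MFE) < -19 kcal/mol

hold.  The permutation test asks whether the candidate folds more stably
than dinucleotide-preserving shuffles of itself (Euler-path shuffle, so
the 16-dimensional dinucleotide count vector and the terminal bases are
invariant).

The default energy scorer is a deliberately simple nested-structure
model: each base pair contributes a fixed energy (GC -3, AU -2, GU -1
kcal/mol) plus a -1 kcal/mol bonus when stacked directly on an adjacent
pair; the optimum over all pseudoknot-free structures with hairpin loops
of at least 3 nt is found by dynamic programming.  The scorer is
pluggable — an installed ViennaRNA `RNAfold` binary can be used instead —
and the -19 kcal/mol threshold is meaningful only relative to the
configured model.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PrecursorCandidate",
    "normalize_rna",
    "dinucleotide_shuffle",
    "fold_energy",
    "randfold_pvalue",
    "apply_criteria",
]

RNA_ALPHABET = set("ACGU")

PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}
STACK_BONUS = -1.0
MIN_HAIRPIN_LOOP = 3

SCORE_THRESHOLD = 1.0
RANDFOLD_ALPHA = 0.05
MFE_THRESHOLD = -19.0


@dataclass
class PrecursorCandidate:
    """A candidate hairpin with its discovery score and folding statistics."""

    id: str
    sequence: str
    discovery_score: float
    mfe: float | None = None
    randfold_p: float | None = None

    def __post_init__(self) -> None:
        self.sequence = normalize_rna(self.sequence)


def normalize_rna(sequence: str) -> str:
    """Uppercase and T->U; reject non-ACGU characters."""
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"invalid RNA alphabet characters: {sorted(bad)}")
    return seq


def dinucleotide_shuffle(sequence: str, seed: int | np.random.Generator) -> str:
    """Dinucleotide-preserving shuffle (Altschul-Erickson Euler walk).

    The shuffled sequence has exactly the same multiset of overlapping
    dinucleotides as the input, and the same first and last base.
    """
    seq = normalize_rna(sequence)
    if len(seq) < 3:
        raise ValueError("sequence must be at least 3 nt for a dinucleotide shuffle")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # edge multigraph of the Eulerian walk spelled by the sequence
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    vertices = set(seq)
    last = seq[-1]

    # pick a random last-exit edge per non-terminal vertex; the chosen edges
    # must form an arborescence into the terminal vertex for the walk to be
    # completable (Altschul-Erickson condition); retry until they do
    non_terminal = [v for v in vertices if v != last and edges.get(v)]
    while True:
        last_exit = {v: edges[v][rng.integers(len(edges[v]))] for v in non_terminal}
        ok = True
        for v in non_terminal:
            seen, cur = {v}, v
            while cur != last:
                cur = last_exit.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break

    pools: dict[str, list[str]] = {}
    for v, targets in edges.items():
        pool = list(targets)
        if v in last_exit:
            pool.remove(last_exit[v])
        rng.shuffle(pool)
        if v in last_exit:
            pool.append(last_exit[v])
        pools[v] = pool

    out = [seq[0]]
    cursor = {v: 0 for v in pools}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = pools[cur][cursor[cur]]
        cursor[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


_BASE_INDEX = {b: i for i, b in enumerate("ACGU")}
_PAIR_E_MATRIX = np.full((4, 4), np.inf)
for (_a, _b), _e in PAIR_ENERGY.items():
    _PAIR_E_MATRIX[_BASE_INDEX[_a], _BASE_INDEX[_b]] = _e


def _fold_energy_stacking(seq: str) -> float:
    """Minimum energy over nested structures, O(n^3) dynamic program.

    V[i, j]: best energy of [i, j] given (i, j) paired (inf if unpairable);
    W[i, j]: best energy of [i, j] unconstrained.  The stacking bonus is
    granted when (i+1, j-1) is paired inside (i, j).  Arrays are padded by
    one row/column so W[j+1, j] reads as the empty-interval 0.
    """
    n = len(seq)
    min_span = MIN_HAIRPIN_LOOP + 1
    if n < min_span + 1:
        return 0.0
    idx = np.fromiter((_BASE_INDEX[c] for c in seq), dtype=np.intp, count=n)
    E = _PAIR_E_MATRIX[idx[:, None], idx[None, :]]
    V = np.full((n + 1, n + 1), np.inf)
    W = np.zeros((n + 1, n + 1))
    for span in range(min_span, n):
        i = np.arange(n - span)
        j = i + span
        interior = np.minimum(W[i + 1, j - 1], V[i + 1, j - 1] + STACK_BONUS)
        V[i, j] = E[i, j] + interior
        for ii in range(n - span):
            jj = ii + span
            ks = np.arange(ii + min_span, jj + 1)
            W[ii, jj] = min(W[ii + 1, jj], np.min(V[ii, ks] + W[ks + 1, jj]))
    return float(min(W[0, n - 1], 0.0))


def _fold_energy_rnafold(seq: str) -> float:
    """MFE from an installed ViennaRNA RNAfold binary (optional backend)."""
    proc = subprocess.run(
        ["RNAfold", "--noPS"], input=seq + "\n", text=True,
        capture_output=True, check=True,
    )
    line = proc.stdout.strip().splitlines()[-1]
    return float(line[line.rindex("(") + 1 : line.rindex(")")])


FOLD_BACKENDS = {"stacking": _fold_energy_stacking, "rnafold": _fold_energy_rnafold}


def fold_energy(sequence: str, backend: str = "stacking") -> float:
    """Minimum folding energy in kcal/mol (<= 0) under the chosen backend."""
    seq = normalize_rna(sequence)
    try:
        scorer = FOLD_BACKENDS[backend]
    except KeyError:
        raise ValueError(f"unknown fold backend {backend!r}") from None
    return scorer(seq)


def randfold_pvalue(
    sequence: str, n_shuffles: int = 99, seed: int = 0, backend: str = "stacking"
) -> float:
    """Empirical P that a dinucleotide shuffle folds at least as stably.

    p = (1 + #{shuffles with MFE <= MFE(sequence)}) / (1 + n_shuffles);
    the +1 terms are the standard permutation-test estimator, so p is
    never 0.  n_shuffles must be >= 19, the minimum at which p < 0.05 is
    attainable.
    """
    if n_shuffles < 19:
        raise ValueError("n_shuffles must be >= 19 to resolve p < 0.05")
    seq = normalize_rna(sequence)
    observed = fold_energy(seq, backend)
    rng = np.random.default_rng(seed)
    hits = sum(
        fold_energy(dinucleotide_shuffle(seq, rng), backend) <= observed
        for _ in range(n_shuffles)
    )
    return (1 + hits) / (1 + n_shuffles)


def apply_criteria(candidate: PrecursorCandidate) -> tuple[bool, str | None]:
    """Accept/reject one candidate; the reason names the first failed rule.

    Criteria: discovery score > 1, randfold P < 0.05, MFE < -19 kcal/mol.
    """
    for name, value in (
        ("discovery_score", candidate.discovery_score),
        ("mfe", candidate.mfe),
        ("randfold_p", candidate.randfold_p),
    ):
        if value is None:
            raise ValueError(f"candidate {candidate.id}: missing {name}")
    if not candidate.discovery_score > SCORE_THRESHOLD:
        return False, "score"
    if not candidate.randfold_p < RANDFOLD_ALPHA:
        return False, "randfold"
    if not candidate.mfe < MFE_THRESHOLD:
        return False, "mfe"
    return True, None
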