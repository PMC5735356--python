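"""miRNA target-set intersection across prediction programs.

Published target analyses typically run several predictors (RNAhybrid,
miRanda, TargetScan, ...) and keep only the pairs called by all of them.
This module provides the three-way intersection bookkeeping over
(miRNA, transcript) pairs, plus a minimal canonical seed-match predictor
usable as a runnable stand-in for an external program: a pair is emitted
when the reverse complement of the miRNA seed (positions 2-8) occurs in
the transcript 3'UTR.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["TargetPair", "seed_match_predict", "venn_intersections"]

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


@dataclass(frozen=True)
class TargetPair:
    mirna_id: str
    transcript_id: str
    site_position: int | None = None

    @property
    def key(self) -> tuple[str, str]:
        # site position is ignored for set identity
        return (self.mirna_id, self.transcript_id)


def _seed_site(mirna_seq: str) -> str:
    """DNA-space reverse complement of the 7-nt seed (positions 2-8)."""
    seed = mirna_seq.upper().replace("T", "U")[1:8]
    if len(seed) < 7:
        raise ValueError("miRNA shorter than 8 nt has no full seed")
    return seed.translate(_COMPLEMENT)[::-1].replace("U", "T")


def seed_match_predict(mirnas: dict, utrs: dict) -> set[tuple[str, str]]:
    """Seed-complement target prediction.

    mirnas: id -> mature sequence (DNA or RNA alphabet);
    utrs: transcript id -> 3'UTR sequence (DNA alphabet).
    Returns the set of (mirna_id, transcript_id) pairs whose UTR contains
    the exact reverse complement of miRNA positions 2-8.
    """
    pairs = set()
    for mid, mseq in mirnas.items():
        site = _seed_site(mseq)
        for tid, utr in utrs.items():
            if site in utr.upper().replace("U", "T"):
                pairs.add((mid, tid))
    return pairs


def _keys(pairs) -> set:
    return {p.key if isinstance(p, TargetPair) else tuple(p) for p in pairs}


def venn_intersections(set_a, set_b, set_c) -> dict:
    """Counts of the 7 Venn regions plus the common-to-all pair set.

    Region keys: 'a_only', 'b_only', 'c_only', 'ab_only', 'ac_only',
    'bc_only', 'abc'; pairwise totals 'ab', 'ac', 'bc' (each including the
    triple overlap, as printed beside published Venn diagrams) and the
    'common' set of pairs found by all three predictors.
    """
    a, b, c = _keys(set_a), _keys(set_b), _keys(set_c)
    abc = a & b & c
    regions = {
        "a_only": len(a - b - c),
        "b_only": len(b - a - c),
        "c_only": len(c - a - b),
        "ab_only": len((a & b) - c),
        "ac_only": len((a & c) - b),
        "bc_only": len((b & c) - a),
        "abc": len(abc),
        "ab": len(a & b),
        "ac": len(a & c),
        "bc": len(b & c),
        "union": len(a | b | c),
        "common": abc,
    }
    return regions


def venn_frame(regions: dict) -> pd.DataFrame:
    rows = [
        (k, regions[k])
        for k in ("a_only", "b_only", "c_only", "ab_only", "ac_only",
                  "bc_only", "abc", "ab", "ac", "bc", "union")
    ]
    return pd.DataFrame(rows, columns=["region", "count"])
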