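"""Hierarchical annotation of clean small-RNA tags.

Each tag is assigned the highest-priority class with a sequence match,
following the conventional small-RNA annotation hierarchy:

    rRNA-like (rRNA, scRNA, snoRNA, snRNA, tRNA) > known miRNA > repeat
    > exon > intron > unannotated

Genome mapping is an exact-substring contract (both strands); full
aligner heuristics are out of scope.  Mature-miRNA matching treats a tag
as a hit when it is a substring of the mature reference, optionally with
a +/- 2 nt isomiR offset window at the mature ends (off by default).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
from Bio import SeqIO

__all__ = [
    "PRIORITY",
    "ReferenceSets",
    "load_fasta",
    "load_bed_sequences",
    "map_exact",
    "classify_tag",
    "classify_tags",
    "class_composition",
    "pairwise_common",
]

RRNA_LIKE = ("rRNA", "scRNA", "snoRNA", "snRNA", "tRNA")
# annotation classes from highest to lowest priority
PRIORITY = ("rRNA_like", "known_miRNA", "repeat", "exon", "intron")
UNANNOTATED = "unannotated"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _round2(value) -> float:
    return float(Decimal(value).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def load_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def load_bed_sequences(bed_path: str | Path, genome: dict) -> list[tuple[str, str]]:
    """Materialise 0-based half-open BED intervals as sequences.

    `genome` maps chromosome name -> sequence string.
    """
    out = []
    for i, line in enumerate(Path(bed_path).read_text().splitlines()):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
        if chrom not in genome:
            raise KeyError(f"BED line {i}: chromosome {chrom!r} not in genome")
        out.append((name, genome[chrom][start:end].upper()))
    return out


class ReferenceSets:
    """Per-class reference sequences with priority-ordered matching.

    `sets` maps class names to lists of (id, sequence).  Classes in the
    rRNA-like group may be supplied individually (rRNA, tRNA, ...) or as
    a single 'rRNA_like' set.
    """

    def __init__(self, sets: dict, isomir_offset: int = 0):
        self.isomir_offset = isomir_offset
        grouped: dict[str, list] = {cls: [] for cls in PRIORITY}
        for name, records in sets.items():
            if name in RRNA_LIKE or name == "rRNA_like":
                grouped["rRNA_like"].extend(records)
            elif name in ("known_miRNA", "miRNA"):
                grouped["known_miRNA"].extend(records)
            elif name in ("repeat", "exon", "intron"):
                grouped[name].extend(records)
            elif name == UNANNOTATED:
                continue  # unannotated is the fall-through, never a reference
            else:
                raise ValueError(f"unknown annotation class {name!r}")
        self.grouped = grouped

    def _matches_mirna(self, tag: str, mature: str) -> bool:
        if tag in mature:
            return True
        off = self.isomir_offset
        if off > 0:
            # allow the tag to overhang the mature ends by up to `off` nt
            for shift in range(1, off + 1):
                if tag[shift:] and tag[shift:] in mature:
                    return True
                if tag[:-shift] and tag[:-shift] in mature:
                    return True
        return False

    def match(self, tag: str, cls: str) -> bool:
        records = self.grouped[cls]
        if cls == "known_miRNA":
            return any(self._matches_mirna(tag, seq) for _, seq in records)
        return any(tag in seq for _, seq in records)


def classify_tag(tag: str, refs: ReferenceSets) -> str:
    """Highest-priority class with a match; 'unannotated' when none."""
    for cls in PRIORITY:
        if refs.grouped[cls] and refs.match(tag, cls):
            return cls
    return UNANNOTATED


def classify_tags(tags: dict, refs: ReferenceSets) -> pd.DataFrame:
    """Classify a tag->count mapping; returns sequence, count, class rows."""
    rows = [
        (seq, count, classify_tag(seq, refs)) for seq, count in sorted(tags.items())
    ]
    return pd.DataFrame(rows, columns=["sequence", "count", "class"])


def class_composition(classified: pd.DataFrame) -> pd.DataFrame:
    """Read-mass composition per class, percentages to 2 decimals."""
    mass = classified.groupby("class")["count"].sum()
    total = mass.sum()
    out = mass.to_frame("count")
    out["percent"] = [_round2(Decimal(100 * int(c)) / Decimal(int(total))) for c in mass]
    return out.reset_index()


def mapped_percentage(mapped_mass: int, total_mass: int) -> float:
    """Mapped share of clean read mass, as a percentage to 2 decimals."""
    if total_mass <= 0:
        raise ValueError("total mass must be positive")
    return float(
        (Decimal(100 * mapped_mass) / Decimal(total_mass)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def map_exact(tags: dict, genome: dict) -> tuple[dict, float]:
    """Exact-substring genome mapping on either strand.

    Returns (per-tag mapped flag, mapped percentage of clean read mass,
    half-up to 2 decimals).
    """
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("genome is empty")
    chroms = [s.upper() for s in genome.values()]
    flags = {}
    for seq in tags:
        rc = _revcomp(seq)
        flags[seq] = any(seq in c or rc in c for c in chroms)
    total = sum(tags.values())
    mapped = sum(count for seq, count in tags.items() if flags[seq])
    return flags, mapped_percentage(mapped, total)


def pairwise_common(tags_a: dict, tags_b: dict) -> dict:
    """Shared sequence mass between two libraries.

    The headline `percent` is the symmetric pooled-mass convention:
    100 * (mass of shared tags in A + mass of shared tags in B)
    / (total mass of A + total mass of B).  Per-side fractions are also
    returned.  Symmetric in A and B; 100 for identical tag sets, 0 for
    disjoint ones.
    """
    if not tags_a or not tags_b:
        raise ValueError("pairwise_common requires non-empty tag sets")
    shared = set(tags_a) & set(tags_b)
    mass_a = sum(tags_a.values())
    mass_b = sum(tags_b.values())
    shared_a = sum(tags_a[s] for s in shared)
    shared_b = sum(tags_b[s] for s in shared)
    return {
        "percent": 100.0 * (shared_a + shared_b) / (mass_a + mass_b),
        "percent_a": 100.0 * shared_a / mass_a,
        "percent_b": 100.0 * shared_b / mass_b,
        "shared_tags": len(shared),
    }
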