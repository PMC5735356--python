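"""Raw small-RNA read filtering, category accounting and tag collapsing.

Reads are assigned to exactly one removal category, checked in a fixed
order that mirrors published per-library accounting tables:

    low-quality -> 3' adapter-null -> insert-null -> 5' adapter
    contaminant -> shorter than 18 nt -> polyA -> clean

Definitions (the published categories are named, not defined, so the
contract is fixed here and shared with the synthetic generator):

* low-quality: mean Phred quality < 20, or any N base;
* 3' adapter-null: no prefix of the 3' adapter (>= 6 nt, exact match)
  occurs in the read;
* insert-null: the 3' adapter starts at position 0 (empty insert);
* 5' adapter contaminant: the insert begins with >= 8 nt of the 5' adapter;
* shorter than 18 nt: trimmed insert below 18 nt;
* polyA: >= 80% A in the trimmed insert;
* clean: everything else; the trimmed insert is kept and collapsed into
  unique tags with counts.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, fields
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

__all__ = [
    "RawRead",
    "FilterAccounting",
    "read_fastq",
    "find_adapter",
    "filter_and_trim",
    "collapse",
    "length_distribution",
]

MIN_INSERT_LEN = 18
MIN_ADAPTER_OVERLAP = 6
MIN_5P_CONTAMINANT_OVERLAP = 8
POLYA_FRACTION = 0.80
LOW_QUALITY_MEAN_PHRED = 20.0

# accounting rows in output order; low_quality is tracked separately because
# published accounting tables use the post-quality ("high-quality") total as
# the 100% denominator
REMOVAL_CATEGORIES = (
    "three_prime_adapter_null",
    "insert_null",
    "five_prime_contaminant",
    "shorter_than_18",
    "polyA",
)


@dataclass
class RawRead:
    id: str
    bases: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(f"read {self.id}: bases/qualities length mismatch")


@dataclass
class FilterAccounting:
    """Per-category read counts for one library (accounting-table shape)."""

    high_quality_total: int = 0
    three_prime_adapter_null: int = 0
    insert_null: int = 0
    five_prime_contaminant: int = 0
    shorter_than_18: int = 0
    polyA: int = 0
    clean: int = 0
    low_quality: int = 0  # removed before the high-quality total

    def __post_init__(self) -> None:
        if any(getattr(self, f.name) < 0 for f in fields(self)):
            raise ValueError("accounting counts must be non-negative")

    def percentage(self, category: str) -> float:
        """Category share of the high-quality total, half-up to 2 decimals."""
        count = getattr(self, category)
        if self.high_quality_total == 0:
            return 0.0
        pct = Decimal(100 * count) / Decimal(self.high_quality_total)
        return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))

    def to_frame(self) -> pd.DataFrame:
        rows = ["high_quality_total", *REMOVAL_CATEGORIES, "clean"]
        return pd.DataFrame(
            {
                "category": rows,
                "count": [getattr(self, r) for r in rows],
                "percent": [self.percentage(r) for r in rows],
            }
        )

    def check_conservation(self) -> None:
        removed = sum(getattr(self, c) for c in REMOVAL_CATEGORIES)
        if self.clean != self.high_quality_total - removed:
            raise ValueError("category counts do not partition the high-quality total")


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    """Stream RawReads from a (optionally gzipped) Sanger FASTQ file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for i, rec in enumerate(SeqIO.parse(handle, "fastq")):
            try:
                yield RawRead(
                    rec.id, str(rec.seq).upper(),
                    rec.letter_annotations["phred_quality"],
                )
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record {i}: {exc}") from exc


def find_adapter(bases: str, adapter: str, min_overlap: int = MIN_ADAPTER_OVERLAP) -> int:
    """Leftmost start of the 3' adapter in the read, or -1.

    The full adapter is searched first; failing that, progressively shorter
    adapter prefixes (down to `min_overlap`) are matched against the read
    end, covering adapters truncated by the read length. Exact match only.
    """
    pos = bases.find(adapter)
    if pos != -1:
        return pos
    max_k = min(len(adapter) - 1, len(bases))
    for k in range(max_k, min_overlap - 1, -1):
        if bases.endswith(adapter[:k]):
            return len(bases) - k
    return -1


def _categorize(read: RawRead, adapter_3p: str, adapter_5p: str) -> tuple[str, str | None]:
    """Assign one category; returns (category, trimmed insert or None)."""
    if "N" in read.bases or (
        read.qualities and sum(read.qualities) / len(read.qualities) < LOW_QUALITY_MEAN_PHRED
    ):
        return "low_quality", None
    pos = find_adapter(read.bases, adapter_3p)
    if pos == -1:
        return "three_prime_adapter_null", None
    if pos == 0:
        return "insert_null", None
    insert = read.bases[:pos]
    # a residual 5' adapter at the read start is a suffix of the adapter
    for k in range(min(len(adapter_5p), len(insert)), MIN_5P_CONTAMINANT_OVERLAP - 1, -1):
        if insert.startswith(adapter_5p[-k:]):
            return "five_prime_contaminant", None
    if len(insert) < MIN_INSERT_LEN:
        return "shorter_than_18", None
    if insert.count("A") / len(insert) >= POLYA_FRACTION:
        return "polyA", None
    return "clean", insert


def filter_and_trim(
    reads: Iterable[RawRead], adapter_3p: str, adapter_5p: str
) -> tuple[Counter, FilterAccounting]:
    """Filter a read stream into clean tag counts plus category accounting.

    Returns (tags, accounting) where tags maps each unique trimmed insert
    to its read count. An empty stream yields empty tags and zero totals.
    """
    for name, adapter in (("adapter_3p", adapter_3p), ("adapter_5p", adapter_5p)):
        if not adapter or set(adapter) - set("ACGT"):
            raise ValueError(f"{name} must be a non-empty ACGT string, got {adapter!r}")
    acct = FilterAccounting()
    tags: Counter = Counter()
    for read in reads:
        if not isinstance(read, RawRead):
            read = RawRead(*read)  # accept (id, bases, qualities) triples
        category, insert = _categorize(read, adapter_3p, adapter_5p)
        setattr(acct, category, getattr(acct, category) + 1)
        if category != "low_quality":
            acct.high_quality_total += 1
        if insert is not None:
            tags[insert] += 1
    acct.check_conservation()
    return tags, acct


def collapse(inserts: Iterable[str]) -> list[tuple[str, int]]:
    """Collapse clean inserts to unique tags, count-descending.

    Ties are broken lexicographically; total tag mass equals the number of
    input inserts.
    """
    counts = Counter(inserts)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def length_distribution(tags: Counter | dict) -> dict[int, float]:
    """Read-mass-weighted length histogram as frequency percentages.

    Weighted by tag count (reads), not unique tags; percentages sum to 100.
    """
    if not tags:
        raise ValueError("no clean tags")
    mass: Counter = Counter()
    for seq, count in tags.items():
        mass[len(seq)] += count
    total = sum(mass.values())
    return {length: 100.0 * m / total for length, m in sorted(mass.items())}
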