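"""Packaged worked-example tables from the published five-library
*Plutella xylostella* / *Isaria fumosorosea* small-RNA study.

These small TSVs carry the study's printed numbers — per-library read
filtering accounting, genome-mapping totals, the five common
differentially expressed miRNAs (TPM pairs, fold-changes, P-values) and
the ten most abundant miRNAs — so the pipeline's arithmetic can be
exercised against published values without any external download.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "filter_accounting_published",
    "genome_mapping_published",
    "de_published",
    "top_abundant_published",
]

LIBRARIES = ("TW", "12h", "18h", "24h", "36h")


def _load(name: str) -> pd.DataFrame:
    with resources.files("smrnade.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def filter_accounting_published() -> pd.DataFrame:
    """Per-library filter-category counts and printed percentages.

    Columns `<lib>_count` / `<lib>_percent` for libraries TW, 12h, 18h,
    24h, 36h (12h etc. prefixed `h12` to stay valid identifiers).
    """
    return _load("filter_accounting_published.tsv").set_index("category")


def genome_mapping_published() -> pd.DataFrame:
    """Genome-mapped read totals and printed percentages per library."""
    return _load("genome_mapping_published.tsv").set_index("library")


def de_published() -> pd.DataFrame:
    """Five common DE miRNAs: TPMs, fold-changes, P-values, adjusted P."""
    return _load("de_published.tsv").set_index("mirna_id")


def top_abundant_published() -> pd.DataFrame:
    """Ten most abundant miRNAs with mature sequences and library counts."""
    return _load("top_abundant_published.tsv").set_index("mirna_id")
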