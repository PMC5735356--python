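"""Synthetic small-RNA libraries with known ground truth.

Emulates the structure of an insect small-RNA sequencing experiment: one
control library plus several treatment libraries, a bimodal insert-length
distribution (miRNA peak near 22 nt, piRNA-like peak near 28 nt), reads
composed of insert + 3' adapter + random fill, a configurable share of
removal-category contaminants (low quality, adapter-null, insert-null,
5' adapter contaminants, short inserts, polyA), a class mixture over
miRNA / rRNA / tRNA / snRNA / snoRNA / repeat / exon / intron /
unannotated sources, and differential expression planted as per-library
log2 fold-changes on chosen miRNAs.

Per-source read counts are Poisson with mean proportional to a fixed
relative abundance times library depth, matching the sampling assumptions
of the downstream exact test. Every read carries a truth label so
filtering, annotation and DE calls can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimConfig",
    "References",
    "TruthTable",
    "generate_references",
    "build_precursor",
    "generate_library",
    "simulate_mirna_counts",
    "write_fasta",
    "write_fastq",
]

BASES = np.array(list("ACGT"))
COMPLEMENT = str.maketrans("ACGT", "TGCA")

ANNOTATION_CLASSES = (
    "miRNA", "rRNA", "tRNA", "snRNA", "snoRNA",
    "repeat", "exon", "intron", "unannotated",
)
FILTER_CATEGORIES = (
    "low_quality", "three_prime_adapter_null", "insert_null",
    "five_prime_contaminant", "shorter_than_18", "polyA",
)

# default class mixture of clean reads: unannotated (piRNA-like) and miRNA
# fractions dominate, as in insect small-RNA libraries
DEFAULT_CLASS_FRACTIONS = {
    "miRNA": 0.30, "rRNA": 0.10, "tRNA": 0.06, "snRNA": 0.02, "snoRNA": 0.02,
    "repeat": 0.05, "exon": 0.05, "intron": 0.05, "unannotated": 0.35,
}
# default contaminant shares follow the control-library accounting of the
# five-library P. xylostella dataset (0.23% adapter-null, 0.08% insert-null,
# 1.73% 5' contaminants, 5.02% short, 0.01% polyA)
DEFAULT_CONTAMINATION = {
    "low_quality": 0.01,
    "three_prime_adapter_null": 0.0023,
    "insert_null": 0.0008,
    "five_prime_contaminant": 0.0173,
    "shorter_than_18": 0.0502,
    "polyA": 0.0001,
}
# Illumina TruSeq small-RNA adapters
DEFAULT_ADAPTER_3P = "TGGAATTCTCGGGTGCCAAGG"
DEFAULT_ADAPTER_5P = "GTTCAGAGTTCTACAGTCCGACGATC"

MATURE_LEN_RANGE = (18, 24)
# weights for mature miRNA lengths 18..24; mode at the 22-nt peak
MATURE_LEN_WEIGHTS = np.array([1, 2, 4, 10, 4, 2, 1], dtype=float)
HIGH_QUALITY_PHRED = 40
LOW_QUALITY_PHRED = 15


@dataclass
class SimConfig:
    """Study design for one synthetic experiment.

    library_ids[0] is the control; planted_effects entries are
    (mirna_id, library_id, log2_fold_change) applied multiplicatively to
    that miRNA's expected count in that library.
    """

    n_libraries: int = 5
    library_ids: tuple = ("TW", "12h", "18h", "24h", "36h")
    reads_per_library: int = 20_000
    n_mirnas: int = 30
    n_refs_per_class: int = 4
    class_fractions: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS))
    planted_effects: list = field(default_factory=list)
    length_peaks: tuple = (22, 28)
    contamination_fractions: dict = field(default_factory=lambda: dict(DEFAULT_CONTAMINATION))
    adapter_3p: str = DEFAULT_ADAPTER_3P
    adapter_5p: str = DEFAULT_ADAPTER_5P
    read_length: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reads_per_library <= 0:
            raise ValueError("reads_per_library must be positive")
        if len(self.library_ids) != self.n_libraries:
            raise ValueError("library_ids length must equal n_libraries")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1, got {total}")
        for cat, frac in self.contamination_fractions.items():
            if not 0.0 <= frac < 1.0:
                raise ValueError(f"contamination fraction {cat}={frac} outside [0, 1)")
            if cat not in FILTER_CATEGORIES:
                raise ValueError(f"unknown contamination category {cat!r}")
        for name in ("adapter_3p", "adapter_5p"):
            adapter = getattr(self, name)
            if not adapter or set(adapter) - set("ACGT"):
                raise ValueError(f"{name} must be a non-empty ACGT string, got {adapter!r}")

    @property
    def control(self) -> str:
        return self.library_ids[0]

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["library_ids"] = list(self.library_ids)
        data["length_peaks"] = list(self.length_peaks)
        data["planted_effects"] = [list(e) for e in self.planted_effects]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["library_ids"] = tuple(data["library_ids"])
        data["length_peaks"] = tuple(data["length_peaks"])
        data["planted_effects"] = [tuple(e) for e in data["planted_effects"]]
        return cls(**data)


@dataclass
class References:
    """Generated reference sequences plus fixed relative abundances."""

    by_class: dict  # class -> list of (seq_id, sequence); incl. unannotated sources
    mature: list    # (mirna_id, mature sequence)
    precursors: list  # (precursor_id, sequence)
    abundance: dict  # class -> np.ndarray of within-class relative abundances

    def mature_ids(self) -> list:
        return [mid for mid, _ in self.mature]


@dataclass
class TruthTable:
    """Ground truth for one generated library."""

    reads: pd.DataFrame          # read_id, category, source_id
    expected_counts: pd.DataFrame  # per-source expected clean read count

    def to_tsv(self, path: str | Path) -> None:
        self.reads.to_csv(path, sep="\t", index=False)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _looks_5p_contaminated(insert: str, adapter_5p: str) -> bool:
    """True when the insert starts with a >= 8 nt suffix of the 5' adapter."""
    for k in range(min(len(adapter_5p), len(insert)), 7, -1):
        if insert.startswith(adapter_5p[-k:]):
            return True
    return False


def _contains_5p_suffix(seq: str, adapter_5p: str) -> bool:
    return any(
        adapter_5p[-k:] in seq for k in range(8, len(adapter_5p) + 1)
    )


def _reference_seq(rng: np.random.Generator, length: int, adapter_5p: str) -> str:
    """Random reference free of filter-rule artifacts.

    Rejects draws containing a >= 8 nt suffix of the 5' adapter (whose
    substrings would be misfiled as 5' contaminants) or any 18-nt window
    that is >= 80% A (which would trip the polyA rule).
    """
    while True:
        seq = _random_seq(rng, length)
        if _contains_5p_suffix(seq, adapter_5p):
            continue
        a = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("A")
        if len(a) >= 18 and np.convolve(a, np.ones(18), "valid").max() >= 0.8 * 18:
            continue
        return seq


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def build_precursor(
    mature: str, rng: np.random.Generator | None = None,
    loop_len: int = 10, n_mismatches: int = 2,
) -> str:
    """Stem-loop precursor: mature + loop + mismatched reverse complement.

    The mature sequence is always an exact prefix (hence substring) of the
    precursor; the returned hairpin folds into a stem of ~len(mature) pairs.
    """
    rng = rng or np.random.default_rng(0)
    loop = _random_seq(rng, loop_len)
    arm = list(reverse_complement(mature))
    positions = rng.choice(len(arm), size=min(n_mismatches, len(arm)), replace=False)
    for pos in positions:
        choices = [b for b in "ACGT" if b != arm[pos]]
        arm[pos] = choices[rng.integers(len(choices))]
    return mature + loop + "".join(arm)


def _mature_lengths(rng: np.random.Generator, n: int, peak: int) -> np.ndarray:
    lo, hi = MATURE_LEN_RANGE
    lengths = np.arange(lo, hi + 1)
    # re-center the weight profile so its mode sits on the configured peak
    shift = peak - 22
    weights = np.roll(MATURE_LEN_WEIGHTS, shift)
    return rng.choice(lengths, size=n, p=weights / weights.sum())


def generate_references(config: SimConfig) -> References:
    """Build per-class reference FASTA sets and miRNA mature/precursor sets.

    Deterministic in config.seed. Within-class relative abundances are
    drawn once here (log-normal, so a few sources dominate, as observed in
    real libraries) and shared by every library.
    """
    rng = np.random.default_rng([config.seed, 101])
    by_class: dict = {}
    mature = []
    lengths = _mature_lengths(rng, config.n_mirnas, config.length_peaks[0])
    for i, length in enumerate(lengths):
        mid = f"syn-mir-{i + 1}"
        mature.append((mid, _reference_seq(rng, int(length), config.adapter_5p)))
    by_class["miRNA"] = list(mature)
    precursors = [
        (f"{mid}-precursor", build_precursor(seq, rng)) for mid, seq in mature
    ]
    ref_len = {
        "rRNA": 400, "tRNA": 80, "snRNA": 150, "snoRNA": 120,
        "repeat": 300, "exon": 250, "intron": 350, "unannotated": 300,
    }
    for cls in ANNOTATION_CLASSES:
        if cls == "miRNA":
            continue
        by_class[cls] = [
            (f"{cls}-{j + 1}", _reference_seq(rng, ref_len[cls], config.adapter_5p))
            for j in range(config.n_refs_per_class)
        ]
    abundance = {}
    for cls, records in by_class.items():
        raw = rng.lognormal(mean=0.0, sigma=1.0, size=len(records))
        abundance[cls] = raw / raw.sum()
    return References(by_class, mature, precursors, abundance)


def _insert_length_weights(peaks: tuple) -> tuple[np.ndarray, np.ndarray]:
    """Bimodal length law for non-miRNA inserts over 18..30 nt."""
    lengths = np.arange(18, 31)
    weights = np.full(lengths.shape, 2.0)
    for peak, height in zip(peaks, (8.0, 14.0)):
        weights[lengths == peak] += height
        weights[np.abs(lengths - peak) == 1] += height * 0.15
    return lengths, weights / weights.sum()


def _planted_factor(config: SimConfig, mirna_id: str, library_id: str) -> float:
    factor = 1.0
    for mid, lib, lfc in config.planted_effects:
        if mid == mirna_id and lib == library_id:
            factor *= 2.0 ** lfc
    return factor


def expected_clean_fraction(config: SimConfig) -> float:
    return 1.0 - sum(config.contamination_fractions.values())


def _validate_planted(config: SimConfig, refs: References) -> None:
    known = set(refs.mature_ids())
    for mid, lib, _ in config.planted_effects:
        if mid not in known:
            raise ValueError(f"planted miRNA {mid!r} not present in the references")
        if lib not in config.library_ids:
            raise ValueError(f"planted library {lib!r} not in config.library_ids")


def expected_mirna_counts(config: SimConfig, refs: References) -> pd.DataFrame:
    """Expected clean-read count per miRNA per library (the DE ground truth)."""
    _validate_planted(config, refs)
    clean = config.reads_per_library * expected_clean_fraction(config)
    mirna_mass = clean * config.class_fractions["miRNA"]
    rows = {}
    for (mid, _), rel in zip(refs.mature, refs.abundance["miRNA"]):
        rows[mid] = [
            mirna_mass * rel * _planted_factor(config, mid, lib)
            for lib in config.library_ids
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(config.library_ids))


def simulate_mirna_counts(
    config: SimConfig, refs: References, seed: int | None = None
) -> pd.DataFrame:
    """Poisson miRNA count table (miRNA x library) without building reads.

    Uses the same count model as generate_library; intended for fast
    power / error-rate studies at many replicates.
    """
    rng = np.random.default_rng([config.seed if seed is None else seed, 211])
    mean = expected_mirna_counts(config, refs)
    return pd.DataFrame(
        rng.poisson(mean.to_numpy()), index=mean.index, columns=mean.columns
    )


def _pad_read(rng: np.random.Generator, core: str, read_length: int) -> str:
    if len(core) >= read_length:
        return core[:read_length]
    return core + _random_seq(rng, read_length - len(core))


def generate_library(
    config: SimConfig, library_id: str, refs: References
) -> tuple[list, TruthTable]:
    """One FASTQ library: [(read_id, bases, phred list)] plus its truth table.

    Clean reads are insert + 3' adapter + random fill at constant high
    quality; each contaminant category is constructed to violate exactly
    its own filter rule. Per-source counts are Poisson; the realised
    library size therefore fluctuates around reads_per_library.
    """
    if library_id not in config.library_ids:
        raise ValueError(f"unknown library_id {library_id!r}")
    _validate_planted(config, refs)
    lib_index = config.library_ids.index(library_id)
    rng = np.random.default_rng([config.seed, 307, lib_index])
    n = config.reads_per_library
    adapter = config.adapter_3p
    reads: list = []
    truth_rows: list = []
    serial = 0

    def emit(bases: str, phred: int, category: str, source: str) -> None:
        nonlocal serial
        serial += 1
        rid = f"{library_id}_{serial:07d}"
        reads.append((rid, bases, [phred] * len(bases)))
        truth_rows.append((rid, category, source))

    ins_lengths, ins_weights = _insert_length_weights(config.length_peaks)

    def random_insert() -> str:
        return _random_seq(rng, int(rng.choice(ins_lengths, p=ins_weights)))

    # contaminant categories
    for category in FILTER_CATEGORIES:
        frac = config.contamination_fractions.get(category, 0.0)
        for _ in range(rng.poisson(n * frac)):
            if category == "low_quality":
                core = random_insert() + adapter
                emit(_pad_read(rng, core, config.read_length), LOW_QUALITY_PHRED,
                     category, "contaminant")
                continue
            if category == "three_prime_adapter_null":
                while True:
                    bases = _pad_read(rng, random_insert(), config.read_length)
                    from .preprocess import find_adapter  # local to avoid cycle
                    if find_adapter(bases, adapter) == -1:
                        break
                emit(bases, HIGH_QUALITY_PHRED, category, "contaminant")
                continue
            if category == "insert_null":
                core = adapter
            elif category == "five_prime_contaminant":
                # keep total insert short enough that >= 6 nt of the 3'
                # adapter survive within the read length
                budget = config.read_length - len(adapter)
                k = int(rng.integers(8, min(len(config.adapter_5p), budget - 10) + 1))
                core = (
                    config.adapter_5p[-k:]
                    + _random_seq(rng, int(rng.integers(8, budget - k + 1)))
                    + adapter
                )
            elif category == "shorter_than_18":
                while True:
                    stub = _random_seq(rng, int(rng.integers(10, 18)))
                    if not _looks_5p_contaminated(stub, config.adapter_5p):
                        break
                core = stub + adapter
            else:  # polyA
                length = int(rng.integers(20, 26))
                ins = "".join(
                    "A" if rng.random() < 0.92 else rng.choice(list("CGT"))
                    for _ in range(length)
                )
                if ins.count("A") / len(ins) < 0.80:
                    ins = "A" * length
                core = ins + adapter
            emit(_pad_read(rng, core, config.read_length), HIGH_QUALITY_PHRED,
                 category, "contaminant")

    # clean reads, class by class, Poisson per source
    clean_mass = n * expected_clean_fraction(config)
    expected = expected_mirna_counts(config, refs)
    for cls in ANNOTATION_CLASSES:
        frac = config.class_fractions.get(cls, 0.0)
        if frac == 0.0:
            continue
        records = refs.by_class[cls]
        for (sid, seq), rel in zip(records, refs.abundance[cls]):
            if cls == "miRNA":
                mean = expected.loc[sid, library_id]
            else:
                mean = clean_mass * frac * rel
            for _ in range(rng.poisson(mean)):
                if cls == "miRNA":
                    insert = seq
                else:
                    length = int(rng.choice(ins_lengths, p=ins_weights))
                    start = int(rng.integers(0, len(seq) - length + 1))
                    insert = seq[start : start + length]
                core = insert + adapter
                emit(_pad_read(rng, core, config.read_length), HIGH_QUALITY_PHRED,
                     cls, sid)

    truth = TruthTable(
        reads=pd.DataFrame(truth_rows, columns=["read_id", "category", "source_id"]),
        expected_counts=expected,
    )
    return reads, truth


def write_fasta(records, path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTA."""
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n{seq}\n")


def write_fastq(reads, path: str | Path) -> None:
    """Write (id, bases, phred list) triples as Sanger FASTQ."""
    with open(path, "w") as fh:
        for rid, bases, quals in reads:
            qual = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{rid}\n{bases}\n+\n{qual}\n")
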