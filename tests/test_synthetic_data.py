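"""Synthetic library generator: structure, determinism, ground truth."""

import numpy as np
import pytest

from smrnade.preprocess import filter_and_trim, find_adapter, length_distribution
from smrnade.synthetic_data import (
    SimConfig,
    build_precursor,
    expected_mirna_counts,
    generate_library,
    generate_references,
    simulate_mirna_counts,
    write_fasta,
    write_fastq,
)


class TestConfig:
    def test_class_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(class_fractions={"miRNA": 0.5, "rRNA": 0.2})

    def test_invalid_adapter_alphabet_rejected(self):
        with pytest.raises(ValueError, match="adapter_3p"):
            SimConfig(adapter_3p="ACGX")

    def test_contamination_fraction_bounds(self):
        with pytest.raises(ValueError):
            SimConfig(contamination_fractions={"polyA": 1.5})

    def test_yaml_round_trip(self, tmp_path, small_config):
        path = tmp_path / "cfg.yaml"
        small_config.to_yaml(path)
        assert SimConfig.from_yaml(path) == small_config


class TestReferences:
    def test_mature_count_and_lengths(self):
        refs = generate_references(SimConfig(n_mirnas=10, seed=1))
        assert len(refs.mature) == 10
        assert all(18 <= len(seq) <= 24 for _, seq in refs.mature)

    def test_each_class_nonempty(self, small_refs):
        assert all(len(records) >= 1 for records in small_refs.by_class.values())

    def test_seeded_regeneration_byte_identical(self, tmp_path, small_config):
        paths = []
        for run in range(2):
            refs = generate_references(small_config)
            p = tmp_path / f"mature_{run}.fasta"
            write_fasta(refs.mature, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_precursor_contains_mature(self):
        mature = "TGGAATGTAAAGAAGTATGGAG"  # a published mature miRNA sequence
        precursor = build_precursor(mature, np.random.default_rng(5))
        assert mature in precursor
        assert len(precursor) == 2 * len(mature) + 10


class TestLibrary:
    def test_regeneration_byte_identical(self, tmp_path, small_config, small_refs):
        blobs = []
        for run in range(2):
            reads, _ = generate_library(small_config, "12h", small_refs)
            p = tmp_path / f"lib_{run}.fastq"
            write_fastq(reads, p)
            blobs.append(p.read_bytes())
        assert blobs[0] == blobs[1]

    def test_no_contamination_means_adapter_everywhere(self):
        cfg = SimConfig(
            n_libraries=1, library_ids=("TW",), reads_per_library=400,
            n_mirnas=5, n_refs_per_class=2,
            contamination_fractions={}, seed=3,
        )
        refs = generate_references(cfg)
        reads, truth = generate_library(cfg, "TW", refs)
        assert (truth.reads["category"].isin(
            list(cfg.class_fractions))).all()
        assert all(find_adapter(bases, cfg.adapter_3p) > 0 for _, bases, _ in reads)

    def test_unknown_planted_mirna_named_in_error(self, small_refs):
        cfg = SimConfig(
            n_libraries=2, library_ids=("TW", "12h"), n_mirnas=12,
            planted_effects=[("no-such-mir", "12h", 1.0)], seed=11,
        )
        with pytest.raises(ValueError, match="no-such-mir"):
            generate_library(cfg, "12h", small_refs)

    def test_truth_labels_match_filter_categories(self, small_config, small_refs):
        reads, truth = generate_library(small_config, "TW", small_refs)
        filter_cats = {
            "low_quality", "three_prime_adapter_null", "insert_null",
            "five_prime_contaminant", "shorter_than_18", "polyA",
        }
        by_id = dict(zip(truth.reads["read_id"], truth.reads["category"]))
        from smrnade.preprocess import _categorize, RawRead

        for rid, bases, quals in reads:
            category, _ = _categorize(
                RawRead(rid, bases, quals),
                small_config.adapter_3p, small_config.adapter_5p,
            )
            expected = by_id[rid]
            if expected not in filter_cats:
                expected = "clean"
            assert category == expected, rid


class TestPlantedEffects:
    def test_zero_lfc_gives_unit_expected_ratio(self, small_refs):
        cfg = SimConfig(
            n_libraries=2, library_ids=("TW", "12h"), n_mirnas=12, seed=11,
            planted_effects=[("syn-mir-1", "12h", 0.0)],
        )
        expected = expected_mirna_counts(cfg, small_refs)
        assert np.allclose(expected["12h"], expected["TW"])

    def test_published_fold_change_moves_expected_tpm(self, small_refs):
        # a planted log2FC of -2.169925 turns 17.64 TPM into 3.92 TPM
        cfg = SimConfig(
            n_libraries=2, library_ids=("TW", "12h"), n_mirnas=12, seed=11,
            planted_effects=[("syn-mir-1", "12h", -2.169925)],
        )
        expected = expected_mirna_counts(cfg, small_refs)
        ratio = expected.loc["syn-mir-1", "12h"] / expected.loc["syn-mir-1", "TW"]
        assert 17.64 * ratio == pytest.approx(3.92, abs=5e-4)

    def test_count_simulation_recovers_planted_lfc(self, small_config, small_refs):
        deep = SimConfig(
            n_libraries=2, library_ids=("TW", "12h"), reads_per_library=2_000_000,
            n_mirnas=12, n_refs_per_class=2, seed=11,
            planted_effects=[("syn-mir-1", "12h", -2.0)],
        )
        counts = simulate_mirna_counts(deep, small_refs, seed=99)
        est = np.log2(counts.loc["syn-mir-1", "12h"] / counts.loc["syn-mir-1", "TW"])
        assert est == pytest.approx(-2.0, abs=0.15)


@pytest.fixture(scope="module")
def big_library():
    cfg = SimConfig(
        n_libraries=1, library_ids=("TW",), reads_per_library=40_000,
        n_mirnas=25, seed=7,
    )
    refs = generate_references(cfg)
    reads, truth = generate_library(cfg, "TW", refs)
    return cfg, reads, truth


class TestDistributions:
    def test_class_fractions_converge(self, big_library):
        cfg, _, truth = big_library
        clean = truth.reads[~truth.reads["category"].isin(
            ["low_quality", "three_prime_adapter_null", "insert_null",
             "five_prime_contaminant", "shorter_than_18", "polyA"])]
        n = len(clean)
        observed = clean["category"].value_counts(normalize=True)
        for cls, frac in cfg.class_fractions.items():
            sigma = np.sqrt(frac * (1 - frac) / n)
            assert abs(observed.get(cls, 0.0) - frac) < 3 * sigma + 1e-12, cls

    def test_length_modes_at_configured_peaks(self, big_library):
        cfg, reads, _ = big_library
        tags, _ = filter_and_trim(reads, cfg.adapter_3p, cfg.adapter_5p)
        hist = length_distribution(tags)
        top_two = sorted(hist, key=hist.get, reverse=True)[:2]
        assert set(top_two) == set(cfg.length_peaks)
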