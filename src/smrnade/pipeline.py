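"""End-to-end pipeline: simulate -> preprocess -> annotate -> DE ->
novel-candidate filter -> target intersection -> qPCR concordance.

Every stage writes plain TSV outputs into one run directory and can be
skipped; a fixed seed makes the whole run byte-reproducible.  In demo
mode the synthetic generator supplies the inputs and ground truth.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import de_stats, novel_filter, qpcr, synthetic_data, targets_report
from . import preprocess as pp

__all__ = ["PipelineConfig", "run_pipeline", "aggregate_mirna_counts"]

log = logging.getLogger("smrnade")

ALL_STAGES = ("simulate", "preprocess", "annotate", "de", "novel", "targets", "qpcr")


@dataclass
class PipelineConfig:
    out_dir: str = "smrnade_run"
    sim: synthetic_data.SimConfig = field(default_factory=synthetic_data.SimConfig)
    alpha: float = 0.05
    min_abs_log2fc: float = 1.0
    novel_shuffles: int = 49
    stages: tuple = ALL_STAGES
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["sim"]["library_ids"] = list(self.sim.library_ids)
        data["sim"]["length_peaks"] = list(self.sim.length_peaks)
        data["sim"]["planted_effects"] = [list(e) for e in self.sim.planted_effects]
        data["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        sim = data.pop("sim")
        sim["library_ids"] = tuple(sim["library_ids"])
        sim["length_peaks"] = tuple(sim["length_peaks"])
        sim["planted_effects"] = [tuple(e) for e in sim["planted_effects"]]
        data["stages"] = tuple(data["stages"])
        return cls(sim=synthetic_data.SimConfig(**sim), **data)


def aggregate_mirna_counts(tags: dict, mature: list) -> dict:
    """Sum tag counts per mature miRNA (tag must be a substring; isomiR
    aggregation).  A tag matching several matures is credited to the first
    in list order."""
    counts = {mid: 0 for mid, _ in mature}
    for seq, count in tags.items():
        for mid, mseq in mature:
            if seq in mseq:
                counts[mid] += count
                break
    return counts


def _save(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns a summary dict of key outputs."""
    logging.basicConfig(
        stream=sys.stderr, level=config.log_level,
        format="%(levelname)s %(name)s: %(message)s",
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.sim
    config.to_yaml(out / "config.yaml")
    log.info("resolved config written to %s", out / "config.yaml")
    summary: dict = {}

    refs = synthetic_data.generate_references(cfg)

    if "simulate" in config.stages:
        synthetic_data.write_fasta(refs.mature, out / "mature_mirnas.fasta")
        synthetic_data.write_fasta(refs.precursors, out / "precursors.fasta")
        for cls, records in refs.by_class.items():
            if cls != "miRNA":
                synthetic_data.write_fasta(records, out / f"ref_{cls}.fasta")
        for lib in cfg.library_ids:
            reads, truth = synthetic_data.generate_library(cfg, lib, refs)
            synthetic_data.write_fastq(reads, out / f"{lib}.fastq")
            truth.to_tsv(out / f"{lib}.truth.tsv")
        _save(
            synthetic_data.expected_mirna_counts(cfg, refs).rename_axis("mirna_id"),
            out / "expected_mirna_counts.tsv", index=True,
        )
        log.info("simulate: %d libraries written", cfg.n_libraries)

    tags_by_lib: dict = {}
    totals: dict = {}
    if "preprocess" in config.stages:
        for lib in cfg.library_ids:
            reads = pp.read_fastq(out / f"{lib}.fastq")
            tags, acct = pp.filter_and_trim(reads, cfg.adapter_3p, cfg.adapter_5p)
            tags_by_lib[lib] = tags
            totals[lib] = acct.clean
            _save(acct.to_frame(), out / f"{lib}.accounting.tsv")
            _save(
                pd.DataFrame(pp.collapse(tags.elements()),
                             columns=["sequence", "count"]),
                out / f"{lib}.tags.tsv",
            )
            hist = pp.length_distribution(tags)
            _save(
                pd.DataFrame(hist.items(), columns=["length", "percent"]),
                out / f"{lib}.length_hist.tsv",
            )
            log.info("preprocess %s: %d clean reads, %d tags",
                     lib, acct.clean, len(tags))

    if "annotate" in config.stages and tags_by_lib:
        refsets = ann.ReferenceSets(
            {cls: recs for cls, recs in refs.by_class.items() if cls != "unannotated"}
        )
        for lib in cfg.library_ids:
            classified = ann.classify_tags(tags_by_lib[lib], refsets)
            _save(classified, out / f"{lib}.classes.tsv")
            _save(ann.class_composition(classified), out / f"{lib}.composition.tsv")
        # pseudo-genome: every reference except the last unannotated source,
        # so the mapped fraction is informative rather than trivially 100%
        genome_parts = [
            seq for cls, recs in refs.by_class.items()
            for _, seq in (recs[:-1] if cls == "unannotated" else recs)
        ]
        genome = {"chr1": "NN".join(genome_parts)}
        mapped_rows = []
        for lib in cfg.library_ids:
            _, pct = ann.map_exact(tags_by_lib[lib], genome)
            mapped_rows.append((lib, pct))
        _save(pd.DataFrame(mapped_rows, columns=["library", "mapped_percent"]),
              out / "genome_mapping.tsv")
        common_rows = [
            (a, b, ann.pairwise_common(tags_by_lib[a], tags_by_lib[b])["percent"])
            for i, a in enumerate(cfg.library_ids)
            for b in cfg.library_ids[i + 1:]
        ]
        _save(pd.DataFrame(common_rows, columns=["library_a", "library_b", "percent"]),
              out / "pairwise_common.tsv")
        log.info("annotate: composition and commonality written")

    if "de" in config.stages and tags_by_lib:
        counts = pd.DataFrame({
            lib: aggregate_mirna_counts(tags_by_lib[lib], refs.mature)
            for lib in cfg.library_ids
        })
        _save(counts.rename_axis("mirna_id"), out / "mirna_counts.tsv", index=True)
        params = de_stats.DeCallParams(config.alpha, config.min_abs_log2fc)
        n_sig = {}
        for treatment in cfg.library_ids[1:]:
            table = de_stats.de_table(counts, totals, cfg.control, treatment, params)
            _save(table.rename_axis("mirna_id"),
                  out / f"de_{treatment}_vs_{cfg.control}.tsv", index=True)
            _save(de_stats.volcano_table(table).rename_axis("mirna_id"),
                  out / f"volcano_{treatment}_vs_{cfg.control}.tsv", index=True)
            n_sig[treatment] = int(table["significant"].sum())
        summary["n_significant"] = n_sig
        log.info("de: significant calls per treatment %s", n_sig)

    if "novel" in config.stages:
        rng = np.random.default_rng([cfg.seed, 401])
        rows = []
        for pid, seq in refs.precursors:
            score = float(rng.uniform(1.5, 6.0))
            decoy = novel_filter.dinucleotide_shuffle(seq, rng)
            for cid, cseq, cscore in (
                (pid, seq, score),
                (pid + "-decoy", decoy, float(rng.uniform(1.5, 6.0))),
            ):
                cand = novel_filter.PrecursorCandidate(cid, cseq, cscore)
                cand.mfe = novel_filter.fold_energy(cand.sequence)
                cand.randfold_p = novel_filter.randfold_pvalue(
                    cand.sequence, config.novel_shuffles,
                    seed=int(rng.integers(2**31)),
                )
                accept, reason = novel_filter.apply_criteria(cand)
                rows.append((cid, cscore, cand.mfe, cand.randfold_p,
                             "accept" if accept else "reject", reason or ""))
        novel_tab = pd.DataFrame(
            rows, columns=["id", "score", "mfe", "randfold_p", "decision", "reason"])
        _save(novel_tab, out / "novel_candidates.tsv")
        summary["n_novel_accepted"] = int((novel_tab["decision"] == "accept").sum())
        log.info("novel: %d/%d candidates accepted",
                 summary["n_novel_accepted"], len(novel_tab))

    if "targets" in config.stages:
        rng = np.random.default_rng([cfg.seed, 503])
        mirnas = dict(refs.mature)
        # synthetic transcript 3'UTRs with planted seed sites
        utrs = {}
        mids = list(mirnas)
        for t in range(40):
            utr = synthetic_data._random_seq(rng, 200)
            for mid in rng.choice(mids, size=2, replace=False):
                site = targets_report._seed_site(mirnas[mid])
                pos = int(rng.integers(0, len(utr) - len(site)))
                utr = utr[:pos] + site + utr[pos + len(site):]
            utrs[f"transcript-{t + 1}"] = utr
        base = targets_report.seed_match_predict(mirnas, utrs)
        def jitter(pairs):
            pairs = sorted(pairs)
            keep = [p for p in pairs if rng.random() > 0.05]
            extra = {(mids[rng.integers(len(mids))],
                      f"transcript-{rng.integers(40) + 1}") for _ in range(5)}
            return set(keep) | extra
        sets = {"A": base, "B": jitter(base), "C": jitter(base)}
        regions = targets_report.venn_intersections(sets["A"], sets["B"], sets["C"])
        _save(targets_report.venn_frame(regions), out / "target_venn.tsv")
        _save(pd.DataFrame(sorted(regions["common"]),
                           columns=["mirna_id", "transcript_id"]),
              out / "target_common.tsv")
        summary["n_common_targets"] = regions["abc"]
        log.info("targets: %d pairs common to all three predictors", regions["abc"])

    if "qpcr" in config.stages and "n_significant" in summary:
        rng = np.random.default_rng([cfg.seed, 601])
        treatment = cfg.library_ids[1]
        de_file = out / f"de_{treatment}_vs_{cfg.control}.tsv"
        de = pd.read_csv(de_file, sep="\t", index_col=0)
        picked = de.reindex(de["log2fc"].abs().sort_values(ascending=False).index)
        picked = picked.head(10)
        ct_rows = []
        for mid, row in picked.iterrows():
            # Ct values consistent with the sequencing fold-change plus
            # replicate noise; reference gene near 20 cycles
            base_ct = float(rng.uniform(22, 30))
            for cond, shift in (("control", 0.0), ("treatment", -row["log2fc"])):
                for rep in range(3):
                    ct_rows.append({
                        "target_id": mid, "condition": cond, "replicate": rep + 1,
                        "ct_target": base_ct + shift + rng.normal(0, 0.15),
                        "ct_reference": 20.0 + rng.normal(0, 0.1),
                    })
        ct = pd.DataFrame(ct_rows)
        _save(ct, out / "qpcr_ct.tsv")
        folds = qpcr.ddct_fold(ct)
        _save(folds, out / "qpcr_folds.tsv", index=True)
        conc = qpcr.concordance(
            folds["log2_fold"].to_dict(), picked["log2fc"].to_dict())
        _save(pd.DataFrame(
            [(t, agree) for t, agree in conc["per_target"].items()],
            columns=["target_id", "sign_agrees"]), out / "qpcr_concordance.tsv")
        summary["qpcr_concordance"] = conc["fraction_agreeing"]
        log.info("qpcr: sign concordance %.2f", conc["fraction_agreeing"])

    return summary
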