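"""Relative quantification of miRNA qPCR data by the 2^-ddCt method.

Per condition, replicate Ct values are averaged on the Ct scale; the
reference gene (U6 snRNA in small-RNA work) is subtracted to give dCt;
ddCt = dCt(treatment) - dCt(control); relative expression is 2^-ddCt.
Concordance with sequencing compares the sign of log2(2^-ddCt) = -ddCt
against the sign of the sequencing log2 fold-change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ddct_fold", "concordance"]

CONDITIONS = ("control", "treatment")


def _validate(ct: pd.DataFrame) -> None:
    required = {"target_id", "condition", "ct_target", "ct_reference"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    bad = ct[(ct["ct_target"] <= 0) | (ct["ct_target"] >= 45)
             | (ct["ct_reference"] <= 0) | (ct["ct_reference"] >= 45)]
    if len(bad):
        raise ValueError("Ct values must lie in (0, 45) cycles")


def ddct_fold(ct: pd.DataFrame) -> pd.DataFrame:
    """2^-ddCt relative expression per target.

    Expects columns target_id, condition (control/treatment), replicate,
    ct_target, ct_reference. Returns per-target dCt means, ddCt, the fold
    2^-ddCt, its log2 (= -ddCt), and an SD-propagated error
    (sd_ddct = sqrt(sd_dct_treatment^2 + sd_dct_control^2) cycles).
    """
    _validate(ct)
    ct = ct.copy()
    ct["dct"] = ct["ct_target"] - ct["ct_reference"]
    rows = []
    for target, grp in ct.groupby("target_id", sort=True):
        stats = {}
        for cond in CONDITIONS:
            sub = grp[grp["condition"] == cond]
            if sub.empty:
                raise ValueError(f"target {target!r}: missing {cond} condition")
            stats[cond] = (sub["dct"].mean(), sub["dct"].std(ddof=1))
        ddct = stats["treatment"][0] - stats["control"][0]
        sds = [s for _, s in stats.values() if np.isfinite(s)]
        rows.append({
            "target_id": target,
            "dct_control": stats["control"][0],
            "dct_treatment": stats["treatment"][0],
            "ddct": ddct,
            "fold": 2.0 ** -ddct,
            "log2_fold": -ddct,
            "sd_ddct": float(np.sqrt(np.sum(np.square(sds)))) if sds else np.nan,
        })
    return pd.DataFrame(rows).set_index("target_id")


def concordance(qpcr_log2_folds: dict, sequencing_log2fc: dict) -> dict:
    """Sign agreement between qPCR and sequencing fold-changes.

    Returns per-target agreement flags and the overall agreeing fraction
    over the shared target ids.
    """
    shared = sorted(set(qpcr_log2_folds) & set(sequencing_log2fc))
    if not shared:
        raise ValueError("no shared target ids between qPCR and sequencing")
    per_target = {
        t: bool(np.sign(qpcr_log2_folds[t]) == np.sign(sequencing_log2fc[t]))
        for t in shared
    }
    return {
        "per_target": per_target,
        "fraction_agreeing": sum(per_target.values()) / len(shared),
        "n_shared": len(shared),
    }
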