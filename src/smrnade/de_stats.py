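"""Differential expression of miRNAs between two sequencing libraries.

Counts are compared with the Audic-Claverie exact test: given a miRNA seen
``x`` times among ``N1`` clean reads in the control library, the probability
of seeing it ``y`` times among ``N2`` clean reads in the treatment is

    p(y | x) = r**y * (x+y)! / (x! y!) / (1 + r)**(x+y+1),    r = N2/N1

which is the negative-binomial pmf NB(x+1, N1/(N1+N2)) evaluated at y.
Expression is normalised to tags per million (TPM), zeros are floored at
0.01, miRNAs below 1 TPM in every library are dropped, fold-change is
log2(treatment/control), and P-values are Bonferroni-adjusted per
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import nbinom

__all__ = [
    "DeCallParams",
    "tpm",
    "apply_zero_and_low_rules",
    "log2_fold_change",
    "ac_pmf",
    "ac_pvalue",
    "bonferroni",
    "de_table",
    "top_n",
]

ZERO_TPM = 0.01  # floor applied to zero TPM so ratios stay finite
LOW_EXPRESSION_TPM = 1.0  # miRNAs below this in *all* libraries are dropped


@dataclass
class DeCallParams:
    """Thresholds for calling a miRNA differentially expressed.

    alpha is compared against the Bonferroni-adjusted P-value;
    min_abs_log2fc against |log2(treatment/control)|.
    """

    alpha: float = 0.05
    min_abs_log2fc: float = 1.0
    low_expression_threshold: float = field(default=LOW_EXPRESSION_TPM)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


def tpm(count: float, total_clean: float) -> float:
    """Tags-per-million normalisation: 1e6 * count / total clean reads."""
    if total_clean <= 0:
        raise ValueError(f"total_clean must be positive, got {total_clean}")
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    return 1e6 * count / total_clean


def apply_zero_and_low_rules(
    matrix: pd.DataFrame, low_threshold: float = LOW_EXPRESSION_TPM
) -> pd.DataFrame:
    """Floor zero TPM entries at 0.01 and drop all-low rows.

    Rows are miRNAs, columns libraries.  A row is dropped when every entry
    is below ``low_threshold`` (checked before the zero floor); remaining
    zero entries become 0.01 so log fold-changes and the exact test stay
    defined.
    """
    keep = (matrix >= low_threshold).any(axis=1)
    out = matrix.loc[keep].copy()
    out[out == 0.0] = ZERO_TPM
    return out


def log2_fold_change(tpm_treatment: float, tpm_control: float) -> float:
    """log2(treatment / control); both inputs must be positive."""
    if tpm_treatment <= 0 or tpm_control <= 0:
        raise ValueError(
            "log2_fold_change requires positive TPMs (apply the zero rule first); "
            f"got treatment={tpm_treatment}, control={tpm_control}"
        )
    return float(np.log2(tpm_treatment / tpm_control))


def ac_pmf(y, x, ratio: float):
    """Audic-Claverie pmf p(y | x) at library-size ratio r = N2/N1.

    Evaluated in log space via log-gamma:
        log p = y log r + lgamma(x+y+1) - lgamma(x+1) - lgamma(y+1)
                - (x+y+1) log(1+r)
    Accepts scalars or arrays of non-negative integers.
    """
    y = np.asarray(y)
    x = np.asarray(x)
    if np.any(y < 0) or np.any(x < 0):
        raise ValueError("counts must be non-negative")
    if ratio <= 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    logp = (
        y * np.log(ratio)
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * np.log1p(ratio)
    )
    out = np.exp(logp)
    return float(out) if out.ndim == 0 else out


def ac_pvalue(x, y, n1: float, n2: float):
    """Two-tailed exact P for treatment count y given control count x.

    p = 2 * min( C(y' <= y | x), D(y' >= y | x) ), capped at 1.  The
    conditional law of y given x is NB(x+1, N1/(N1+N2)), so both tails are
    negative-binomial cdf/sf evaluations.  Vectorised over x, y.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    p_succ = n1 / (n1 + n2)
    lower = nbinom.cdf(y, x + 1, p_succ)
    upper = nbinom.sf(y - 1, x + 1, p_succ)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return float(p) if p.ndim == 0 else p


def bonferroni(pvalues) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p) with m = number of tests."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


def de_table(
    counts: pd.DataFrame,
    totals: dict,
    control: str,
    treatment: str,
    params: DeCallParams | None = None,
) -> pd.DataFrame:
    """Full two-library differential expression table.

    Parameters
    ----------
    counts
        miRNA x library integer count table (index = miRNA ids, columns
        include `control` and `treatment`).
    totals
        library -> total clean reads (TPM denominators).
    control, treatment
        column names of the two libraries to compare.

    Returns a table with columns control_tpm, treatment_tpm, log2fc,
    pvalue, fdr (Bonferroni-adjusted; the column keeps the conventional
    FDR label used in published DE tables), significant.  Low-expression
    filtering considers every library in `counts`, not just the pair, so
    the retained miRNA set is shared across pairwise comparisons.
    """
    params = params or DeCallParams()
    for lib in (control, treatment):
        if lib not in counts.columns:
            raise KeyError(f"library {lib!r} not in count table")
        if totals.get(lib, 0) <= 0:
            raise ValueError(f"total clean reads for {lib!r} must be positive")

    tpm_all = counts.astype(float).div(
        pd.Series({k: float(v) for k, v in totals.items()})[counts.columns], axis=1
    ) * 1e6
    tpm_all = apply_zero_and_low_rules(tpm_all, params.low_expression_threshold)
    kept = tpm_all.index

    x = counts.loc[kept, control].to_numpy()
    y = counts.loc[kept, treatment].to_numpy()
    n1, n2 = float(totals[control]), float(totals[treatment])

    tab = pd.DataFrame(index=kept)
    tab["control_tpm"] = tpm_all[control]
    tab["treatment_tpm"] = tpm_all[treatment]
    tab["log2fc"] = np.log2(tab["treatment_tpm"] / tab["control_tpm"])
    tab["pvalue"] = ac_pvalue(x, y, n1, n2)
    tab["fdr"] = bonferroni(tab["pvalue"].to_numpy())
    tab["significant"] = (tab["fdr"] < params.alpha) & (
        tab["log2fc"].abs() >= params.min_abs_log2fc
    )
    return tab.sort_values("pvalue", kind="mergesort")


def volcano_table(de: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot coordinates: log2fc vs -log10 adjusted P plus the call."""
    out = pd.DataFrame(index=de.index)
    out["log2fc"] = de["log2fc"]
    out["neg_log10_fdr"] = -np.log10(de["fdr"].clip(lower=np.finfo(float).tiny))
    out["call"] = np.where(de["significant"], "DE", "ns")
    return out


def top_n(counts: pd.DataFrame, n: int, rank_by: str | None = None) -> pd.DataFrame:
    """Top-n most abundant miRNAs expressed in every library.

    Restricted to miRNAs with a nonzero count in all libraries, ranked by
    the `rank_by` column (default: first column, the control library)
    descending; ties broken lexicographically by miRNA id.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rank_by = rank_by or counts.columns[0]
    common = counts[(counts > 0).all(axis=1)]
    common = common.sort_index(kind="mergesort").sort_values(
        rank_by, ascending=False, kind="mergesort"
    )
    return common.head(n)
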