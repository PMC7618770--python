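"""Group-level inference for the uptake readouts.

Three pieces:

* a positivity threshold derived from sham (EV-free) control cells — the
  highest sham value retained after iterative removal of Gaussian outliers
  (Grubbs' test by default), with a full audit trail;
* hierarchical group comparison that respects the nesting of myocytes within
  hearts: cells are first averaged per heart (removing pseudo-replication),
  then a Welch one-way ANOVA is run on heart means with Dunnett's T3
  pairwise comparisons versus the control group (unequal-variance
  studentized-maximum-modulus adjustment with Welch degrees of freedom);
* biodistribution normalization: organ luminescence divided by administered
  dose and tissue mass, expressed as per-organ fold-change versus control.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import stats as sps
from statsmodels.stats.oneway import anova_oneway

__all__ = [
    "PositivityThreshold",
    "GroupComparison",
    "grubbs_critical",
    "sham_threshold",
    "fraction_positive",
    "smm_cdf",
    "dunnett_t3",
    "hierarchical_anova",
    "normalize_biodistribution",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# sham-derived positivity threshold
# ---------------------------------------------------------------------------


@dataclass
class PositivityThreshold:
    """Sham-derived positivity cutoff with its outlier-removal audit trail.

    The threshold is the maximum of the sham values retained after outlier
    removal, so sham positivity is exactly zero under the strict ">" rule.
    """

    value: float
    readout: str  # "cell" or "nucleus"
    n_used: int
    removed_indices: list[int]
    rule: str
    params: dict = dc_field(default_factory=dict)


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value for a sample of size n."""
    if n < 3:
        raise ValueError("Grubbs' test needs n >= 3")
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))


def sham_threshold(
    values: Sequence[float],
    readout: str = "cell",
    rule: str = "grubbs",
    alpha: float = 0.05,
    sd_factor: float = 3.0,
) -> PositivityThreshold:
    """Positivity threshold = max sham value after iterative Gaussian-outlier removal.

    ``rule`` is ``"grubbs"`` (iterative Grubbs' test at ``alpha``, repeated
    until no value is flagged) or ``"sd"`` (iterative mean +/- sd_factor x SD).
    Identical values yield that value with nothing removed.  Fewer than 3
    values is an error.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 3:
        raise ValueError("need at least 3 sham values")
    if not np.all(np.isfinite(vals)):
        raise ValueError("sham values must be finite")
    if rule not in ("grubbs", "sd"):
        raise ValueError(f"unknown outlier rule {rule!r}")

    keep = np.arange(vals.size)
    removed: list[int] = []
    while keep.size >= 3:
        x = vals[keep]
        sd = x.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(x - x.mean())
        worst = int(np.argmax(dev))
        if rule == "grubbs":
            flagged = dev[worst] / sd > grubbs_critical(keep.size, alpha)
        else:
            flagged = dev[worst] / sd > sd_factor
        if not flagged:
            break
        removed.append(int(keep[worst]))
        keep = np.delete(keep, worst)

    return PositivityThreshold(
        value=float(vals[keep].max()),
        readout=readout,
        n_used=int(keep.size),
        removed_indices=sorted(removed),
        rule=rule,
        params={"alpha": alpha} if rule == "grubbs" else {"sd_factor": sd_factor},
    )


def fraction_positive(
    measurements: pd.DataFrame,
    threshold: PositivityThreshold | float,
    value_col: str,
    treatment_col: str = "treatment",
    heart_col: str = "heart_id",
) -> tuple[pd.Series, pd.Series]:
    """Proportion of cells strictly above threshold, per treatment and per heart.

    Returns ``(by_treatment, by_heart)``; NaN-valued cells are excluded from
    both numerator and denominator.  Empty groups are absent (missing), not 0.
    """
    thr = threshold.value if isinstance(threshold, PositivityThreshold) else float(threshold)
    df = measurements.dropna(subset=[value_col])
    positive = df[value_col] > thr
    by_treatment = positive.groupby(df[treatment_col]).mean()
    by_heart = positive.groupby([df[treatment_col], df[heart_col]]).mean()
    return by_treatment, by_heart


# ---------------------------------------------------------------------------
# Dunnett's T3 via the studentized maximum modulus
# ---------------------------------------------------------------------------


def smm_cdf(q: float, k: int, df: float) -> float:
    """CDF of the studentized maximum modulus: max of k |N(0,1)| over a shared chi/sqrt(df).

    Computed by numerical integration over the chi distribution (absolute
    tolerance 1e-9); the limiting normal form is used for very large df.
    """
    if q <= 0:
        return 0.0
    if k < 1:
        raise ValueError("k must be >= 1")
    if not np.isfinite(df) or df > 1e6:
        return float((2.0 * sps.norm.cdf(q) - 1.0) ** k)
    root_df = math.sqrt(df)

    def integrand(u: float) -> float:
        return (2.0 * sps.norm.cdf(q * u) - 1.0) ** k * root_df * sps.chi.pdf(u * root_df, df)

    val, _ = integrate.quad(integrand, 0.0, np.inf, epsabs=1e-9, epsrel=1e-9, limit=200)
    return float(min(max(val, 0.0), 1.0))


def _welch_df(v1: float, n1: int, v2: float, n2: int) -> float:
    a, b = v1 / n1, v2 / n2
    denom = a**2 / (n1 - 1) + b**2 / (n2 - 1)
    if denom == 0:
        return float(n1 + n2 - 2)
    return (a + b) ** 2 / denom


def dunnett_t3(
    samples: Mapping[str, Sequence[float]],
    control_label: str,
) -> pd.DataFrame:
    """Dunnett's T3 comparisons of every group versus the control.

    Each comparison uses the Welch t statistic with its own degrees of
    freedom; the adjusted p-value is 1 - F_SMM(|t|; k, df) with k the number
    of comparisons.  Zero-variance ties report p = 1 by convention (logged);
    groups with fewer than 2 observations are excluded with a warning.
    """
    if control_label not in samples:
        raise ValueError(f"control group {control_label!r} missing")
    control = np.asarray(list(samples[control_label]), dtype=float)
    if control.size < 2:
        raise ValueError("control group needs at least 2 observations")

    usable = {}
    for label, data in samples.items():
        if label == control_label:
            continue
        arr = np.asarray(list(data), dtype=float)
        if arr.size < 2:
            warnings.warn(f"group {label!r} has fewer than 2 units; excluded from testing")
            continue
        usable[label] = arr
    k = len(usable)

    rows = []
    vc = control.var(ddof=1)
    for label, arr in usable.items():
        vg = arr.var(ddof=1)
        diff = float(arr.mean() - control.mean())
        se = math.sqrt(vg / arr.size + vc / control.size)
        df = _welch_df(vg, arr.size, vc, control.size)
        if se == 0:
            if diff == 0:
                logger.info("zero-variance tie for group %r: p set to 1 by convention", label)
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = math.copysign(float("inf"), diff), 0.0
        else:
            t_stat = diff / se
            p = 1.0 - smm_cdf(abs(t_stat), k, df)
        rows.append(
            {
                "group": label,
                "control": control_label,
                "n": int(arr.size),
                "n_control": int(control.size),
                "estimate": diff,
                "se": se,
                "t": t_stat,
                "df": df,
                "p_adj": float(min(max(p, 0.0), 1.0)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hierarchical one-way ANOVA
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    """Hierarchical comparison result: heart summaries, omnibus test, T3 contrasts."""

    comparisons: pd.DataFrame
    heart_summaries: pd.DataFrame
    anova_statistic: float
    anova_p: float
    method: dict


def hierarchical_anova(
    measurements: pd.DataFrame,
    value_col: str,
    control_label: str,
    aggregation: str = "heart_mean",
    treatment_col: str = "treatment",
    heart_col: str = "heart_id",
) -> GroupComparison:
    """Two-stage hierarchical test of treatment groups versus control.

    Default (``aggregation="heart_mean"``): average cells within each heart,
    then run a Welch one-way ANOVA across groups of heart means and Dunnett's
    T3 versus the control.  Using the heart — the biological replicate — as
    the unit of analysis removes pseudo-replication: duplicating every cell
    within a heart leaves the result unchanged.  ``aggregation="none"``
    deliberately tests at the cell level (the naive, anti-conservative
    analysis) for methodological comparison.
    """
    if aggregation not in ("heart_mean", "none"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    df = measurements.dropna(subset=[value_col])
    if control_label not in set(df[treatment_col]):
        raise ValueError(f"control group {control_label!r} not present")

    heart_means = (
        df.groupby([treatment_col, heart_col])[value_col]
        .agg(["mean", "count"])
        .rename(columns={"mean": "heart_mean", "count": "n_cells"})
        .reset_index()
    )

    if aggregation == "heart_mean":
        unit = heart_means.rename(columns={"heart_mean": "_v"})[[treatment_col, "_v"]]
    else:
        unit = df.rename(columns={value_col: "_v"})[[treatment_col, "_v"]]

    samples = {lab: grp["_v"].to_numpy() for lab, grp in unit.groupby(treatment_col)}
    testable = {lab: v for lab, v in samples.items() if v.size >= 2}
    for lab in set(samples) - set(testable):
        warnings.warn(f"group {lab!r} has a single unit; excluded from testing")
    if control_label not in testable:
        raise ValueError("control group has fewer than 2 units; cannot test")

    arrays = [testable[lab] for lab in sorted(testable)]
    if all(a.var(ddof=1) == 0 for a in arrays) and len({a.mean() for a in arrays}) == 1:
        stat, pval = 0.0, 1.0  # degenerate tie: no evidence of any difference
    else:
        res = anova_oneway(arrays, use_var="unequal", welch_correction=True)
        stat, pval = float(res.statistic), float(res.pvalue)

    comparisons = dunnett_t3(testable, control_label)
    return GroupComparison(
        comparisons=comparisons,
        heart_summaries=heart_means,
        anova_statistic=stat,
        anova_p=pval,
        method={
            "aggregation": aggregation,
            "omnibus": "Welch one-way ANOVA",
            "posthoc": "Dunnett T3 (studentized maximum modulus, Welch df)",
            "unit": "heart" if aggregation == "heart_mean" else "cell",
        },
    )


# ---------------------------------------------------------------------------
# biodistribution normalization
# ---------------------------------------------------------------------------


def normalize_biodistribution(
    table: pd.DataFrame,
    control_label: str = "control",
    value_col: str = "luminescence",
    dose_col: str = "dose",
    mass_col: str = "tissue_mass",
    group_col: str = "group",
    organ_col: str = "organ",
    compare: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None]:
    """Dose- and mass-normalized luminescence with per-organ fold-change versus control.

    normalized = raw / (dose x tissue mass); fold = group mean normalized /
    control mean normalized, per organ (control fold is 1 by definition).
    When ``compare`` is true, per-organ Dunnett T3 comparisons of normalized
    values versus control are returned as a third table.
    """
    required = {value_col, dose_col, mass_col, group_col, organ_col}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if table[[dose_col, mass_col]].isna().any().any():
        raise ValueError("dose and tissue mass must be present for every row")
    if (table[dose_col] <= 0).any() or (table[mass_col] <= 0).any():
        raise ValueError("dose and tissue mass must be positive")

    out = table.copy()
    out["normalized"] = out[value_col] / (out[dose_col] * out[mass_col])

    organs = sorted(out[organ_col].unique())
    control = out[out[group_col] == control_label]
    if set(control[organ_col]) != set(organs):
        raise ValueError("control group is missing rows for some organs")

    group_means = out.groupby([group_col, organ_col])["normalized"].mean()
    fold_rows = []
    for (grp, organ), mean in group_means.items():
        fold_rows.append(
            {
                group_col: grp,
                organ_col: organ,
                "mean_normalized": float(mean),
                "fold_vs_control": float(mean / group_means[(control_label, organ)]),
            }
        )
    folds = pd.DataFrame(fold_rows)

    comparisons = None
    if compare:
        comp_rows = []
        for organ in organs:
            sub = out[out[organ_col] == organ]
            samples = {g: grp["normalized"].to_numpy() for g, grp in sub.groupby(group_col)}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = dunnett_t3(samples, control_label)
            res.insert(0, organ_col, organ)
            comp_rows.append(res)
        comparisons = pd.concat(comp_rows, ignore_index=True) if comp_rows else None
    return out, folds, comparisons
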