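"""Intra- and inter-scanner variability analysis of volume estimates.

Given repeat scans of one subject across many scanners (a traveling-phantom
study), intra-scanner residuals are deviations of each scan from the mean of
its own scanner's repeats, pooled over all scans; inter-scanner residuals
are per-scanner mean volumes minus the grand mean of scanner means. Both
vectors have zero mean by construction. Spreads are summarized as stds and
percentiles of absolute residuals, and dispersions of two methods are
compared with Levene's test (mean-centered) at a Bonferroni-adjusted level.

Because subtracting each group's own mean shrinks residuals, the raw pooled
intra-scanner std underestimates the true test-retest sigma by a factor
sqrt(1 - 1/m) for m repeats; likewise the spread of scanner means contains a
sigma_intra^2/m leakage term. The report carries both the raw construction
and bias-corrected estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

_GROUP_COLS = ["subject_id", "scanner_id", "session_id"]


@dataclass
class StabilityReport:
    intra_residuals: np.ndarray  # mL, length = total scans
    inter_residuals: np.ndarray  # mL, length = number of scanners
    intra_std: float  # mL, std of the pooled intra residual vector
    inter_std: float  # mL, std of the inter residual vector
    intra_std_corrected: float  # mL, pooled unbiased test-retest sigma
    inter_std_corrected: float  # mL, spread of scanner means minus intra leakage
    intra_p50: float
    intra_p95: float
    inter_p50: float
    inter_p95: float
    variance_tests: dict = field(default_factory=dict)  # name -> (W, p)
    alpha: float = 0.05
    n_comparisons: int = 1
    significance_threshold: float = 0.05
    percentile_method: str = "linear"


def intra_residuals(records: pd.DataFrame) -> np.ndarray:
    """Residual of each scan from the mean of its own repeat group, pooled.

    Groups are (subject, scanner, session); a group with a single scan
    contributes a zero residual (its mean is itself), keeping the pooled
    vector length equal to the total number of scans.
    """
    g = records.groupby(_GROUP_COLS)["thalv_ml"]
    return (records["thalv_ml"] - g.transform("mean")).to_numpy()


def inter_residuals(records: pd.DataFrame) -> np.ndarray:
    """Per-scanner mean volume minus the grand mean of scanner means."""
    means = records.groupby("scanner_id")["thalv_ml"].mean()
    if len(means) < 2:
        raise ValueError("inter-scanner residuals need at least 2 scanners")
    return (means - means.mean()).to_numpy()


def levene_variance_test(x, y):
    """Classic mean-centered Levene test for equality of variances.

    Returns (W statistic, p value); degenerate input (no dispersion in
    either group) yields (0, 1) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        warnings.warn("both groups are constant; dispersions equal, p set to 1",
                      stacklevel=2)
        return 0.0, 1.0
    zx = np.abs(x - x.mean())
    zy = np.abs(y - y.mean())
    if zx.std() == 0 and zy.std() == 0:
        # deviations constant within each group: W degenerates
        if np.isclose(zx.mean(), zy.mean()):
            return 0.0, 1.0
        return float("inf"), 0.0
    w, p = stats.levene(x, y, center="mean")
    return float(w), float(p)


def _corrected_stds(records: pd.DataFrame):
    """Unbiased pooled intra sigma and leakage-corrected inter sigma."""
    groups = records.groupby(_GROUP_COLS)["thalv_ml"]
    n_total = len(records)
    n_groups = groups.ngroups
    ss_within = float(((records["thalv_ml"] - groups.transform("mean")) ** 2).sum())
    dof = n_total - n_groups
    intra_var = ss_within / dof if dof > 0 else 0.0

    means = records.groupby("scanner_id")["thalv_ml"].agg(["mean", "size"])
    inter_raw_var = float(means["mean"].var(ddof=1)) if len(means) > 1 else 0.0
    mean_inv_m = float((1.0 / means["size"]).mean())
    inter_var = max(inter_raw_var - intra_var * mean_inv_m, 0.0)
    return float(np.sqrt(intra_var)), float(np.sqrt(inter_var))


def stability_report(
    records: pd.DataFrame,
    comparisons: dict | None = None,
    alpha: float = 0.05,
    n_comparisons: int | None = None,
) -> StabilityReport:
    """Assemble the full intra/inter-scanner variability report.

    Parameters
    ----------
    records
        Scans of a single traveling subject (columns ``subject_id``,
        ``scanner_id``, ``session_id``, ``repeat``, ``thalv_ml``).
    comparisons
        Optional named pairs of residual vectors, e.g.
        ``{"intra_vs_other": (x, y)}``; each is tested with Levene's test.
    alpha, n_comparisons
        Family-wise level and number of pairwise tests for the Bonferroni
        threshold recorded in the report (defaults to the number of
        supplied comparisons).
    """
    intra = intra_residuals(records)
    inter = inter_residuals(records)
    intra_c, inter_c = _corrected_stds(records)
    abs_intra = np.abs(intra)
    abs_inter = np.abs(inter)

    comparisons = comparisons or {}
    ncmp = n_comparisons if n_comparisons is not None else max(1, len(comparisons))
    tests = {name: levene_variance_test(x, y) for name, (x, y) in comparisons.items()}

    return StabilityReport(
        intra_residuals=intra,
        inter_residuals=inter,
        intra_std=float(intra.std(ddof=1)) if intra.size > 1 else 0.0,
        inter_std=float(inter.std(ddof=1)) if inter.size > 1 else 0.0,
        intra_std_corrected=intra_c,
        inter_std_corrected=inter_c,
        intra_p50=float(np.percentile(abs_intra, 50)),
        intra_p95=float(np.percentile(abs_intra, 95)),
        inter_p50=float(np.percentile(abs_inter, 50)),
        inter_p95=float(np.percentile(abs_inter, 95)),
        variance_tests=tests,
        alpha=alpha,
        n_comparisons=ncmp,
        significance_threshold=alpha / ncmp,
    )


def variability_ratio(inter_std: float, between_std: float) -> float:
    """Inter-scanner to between-subject variability ratio.

    The fraction of the normal between-subject spread taken up by scanner
    effects; lower means more of a normative band is usable for detecting
    true atrophy.
    """
    if between_std <= 0:
        raise ValueError("between-subject std must be positive")
    return inter_std / between_std
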