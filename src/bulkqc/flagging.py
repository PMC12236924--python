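"""Warn/fail outlier flagging against a reference distribution.

Each metric is compared to the reference cohort (the query itself when
no reference is given).  Because many QC metrics are far from normal,
the null distribution is stabilized by bootstrap: B resamples of the
reference give a distribution of means whose average centers a normal
null; the reference sample standard deviation provides the spread.
Warn and fail cutoffs are the 0.1 / 0.05 tail quantiles of that null in
the flagged direction.  Gene-body-coverage curves are flagged by a
two-sample Kolmogorov–Smirnov comparison of each sample's binned
coverage distribution against the per-bin median curve of the cohort.

Flags are encoded 0 (pass), 0.5 (warn), 1 (fail); the flag matrix is
hierarchically clustered (complete linkage, Euclidean distance) for
heatmap display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster import hierarchy

from .io import FLAG_ENCODING, _check_cutoff_row
from .metrics import DegenerateCurveError, derive_metrics_frame

__all__ = [
    "FlagConfig",
    "KSFlagResult",
    "DEFAULT_DIRECTIONS",
    "estimate_metric_cutoffs",
    "flag_value",
    "flag_gbc",
    "flag_dataset",
    "cluster_flag_matrix",
]

# One-sided flag direction per metric: low values are bad for yield /
# alignment / complexity metrics, high values for contamination metrics.
DEFAULT_DIRECTIONS = {
    "n_sequenced_reads": "low_is_bad",
    "pct_post_trim": "low_is_bad",
    "pct_uniquely_aligned": "low_is_bad",
    "pct_mapped_exons": "low_is_bad",
    "n_detected_genes": "low_is_bad",
    "auc_gbc": "low_is_bad",
    "pct_rrna": "high_is_bad",
    "pct_adapter": "high_is_bad",
    "pct_overrepresented": "high_is_bad",
}


@dataclass
class FlagConfig:
    """Thresholding configuration.

    warn_quantile / fail_quantile are the statistical thresholds (default
    0.1 and 0.05) applied in the flagged tail; n_bootstrap resamples
    stabilize the null center.
    """

    warn_quantile: float = 0.1
    fail_quantile: float = 0.05
    n_bootstrap: int = 1000
    seed: int = 0
    directions: dict = field(default_factory=lambda: dict(DEFAULT_DIRECTIONS))

    def __post_init__(self):
        if not 0 < self.fail_quantile < self.warn_quantile < 0.5:
            raise ValueError("require 0 < fail_quantile < warn_quantile < 0.5")
        if self.n_bootstrap < 100:
            raise ValueError("n_bootstrap must be >= 100")


@dataclass
class KSFlagResult:
    sample_id: str
    ks_statistic: float
    p_value: float
    flag: str  # "pass" | "warn" | "fail" | "unscoreable"


def estimate_metric_cutoffs(
    reference_values, direction: str, config: FlagConfig
) -> tuple[float, float]:
    """Bootstrap-calibrated (warn_cutoff, fail_cutoff) for one metric.

    Draws ``n_bootstrap`` resamples with replacement; the normal null is
    centered at the mean of the bootstrap means with the reference's
    sample standard deviation as spread.  Cutoffs are the warn/fail
    quantiles of that normal in the flagged direction.  Deterministic
    given ``config.seed``.
    """
    vals = np.asarray(reference_values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) < 5:
        raise ValueError(f"need >= 5 reference values, got {len(vals)}")
    sd = vals.std(ddof=1)
    rng = np.random.default_rng(config.seed)
    boot_means = rng.choice(vals, size=(config.n_bootstrap, len(vals)), replace=True).mean(axis=1)
    center = boot_means.mean()
    if sd == 0:
        warnings.warn("zero-variance reference: warn and fail cutoffs collapse to the mean",
                      stacklevel=2)
        # all reference values are identical; use the common value verbatim so
        # non-deviating samples compare equal (strict inequality -> pass)
        return float(vals[0]), float(vals[0])
    if direction == "low_is_bad":
        warn = stats.norm.ppf(config.warn_quantile, loc=center, scale=sd)
        fail = stats.norm.ppf(config.fail_quantile, loc=center, scale=sd)
    elif direction == "high_is_bad":
        warn = stats.norm.ppf(1 - config.warn_quantile, loc=center, scale=sd)
        fail = stats.norm.ppf(1 - config.fail_quantile, loc=center, scale=sd)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return float(warn), float(fail)


def flag_value(value: float, cutoffs: tuple[float, float], direction: str) -> str | None:
    """Three-way pass/warn/fail call for one value (strict inequality).

    A value exactly at a cutoff passes that cutoff (ties are passes).
    Absent values yield ``None`` (no flag emitted).
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    warn, fail = cutoffs
    if direction == "low_is_bad":
        if value < fail:
            return "fail"
        if value < warn:
            return "warn"
        return "pass"
    if direction == "high_is_bad":
        if value > fail:
            return "fail"
        if value > warn:
            return "warn"
        return "pass"
    raise ValueError(f"unknown direction {direction!r}")


def _curve_to_cdf(curve: np.ndarray) -> np.ndarray:
    total = curve.sum()
    if total <= 0:
        raise DegenerateCurveError("coverage curve sums to zero")
    return np.cumsum(curve / total)


def ks_curve_statistic(sample_curve, reference_curve) -> float:
    """Two-sample KS statistic between two binned coverage profiles.

    Both curves are normalized to unit mass over the 100 bins and their
    cumulative distributions compared; the statistic is the maximal
    absolute CDF gap (symmetric in its arguments).
    """
    a = _curve_to_cdf(np.asarray(sample_curve, dtype=float))
    b = _curve_to_cdf(np.asarray(reference_curve, dtype=float))
    return float(np.abs(a - b).max())


def flag_gbc(sample_id: str, sample_curve, reference_curves, config: FlagConfig) -> KSFlagResult:
    """KS flag for one coverage curve against the cohort median curve.

    The p-value uses the asymptotic two-sample KS formula with an
    effective sample size of 100 bins per side.
    """
    ref = np.asarray(reference_curves, dtype=float)
    if ref.ndim != 2 or ref.shape[0] < 3:
        raise ValueError("need >= 3 reference curves")
    median_curve = np.median(ref, axis=0)
    try:
        d = ks_curve_statistic(sample_curve, median_curve)
    except DegenerateCurveError:
        return KSFlagResult(sample_id, np.nan, np.nan, "unscoreable")
    n = m = 100.0
    en = np.sqrt(n * m / (n + m))
    p = float(np.clip(special.kolmogorov(d * (en + 0.12 + 0.11 / en)), 0.0, 1.0))
    if p < config.fail_quantile:
        flag = "fail"
    elif p < config.warn_quantile:
        flag = "warn"
    else:
        flag = "pass"
    return KSFlagResult(sample_id, d, p, flag)


#: metrics flagged by default, in report order (GBC handled via KS)
FLAGGED_METRICS = [
    "n_sequenced_reads",
    "pct_post_trim",
    "pct_uniquely_aligned",
    "pct_mapped_exons",
    "pct_rrna",
    "pct_adapter",
    "pct_overrepresented",
    "n_detected_genes",
]


def flag_dataset(
    query: pd.DataFrame,
    reference: pd.DataFrame | None = None,
    config: FlagConfig | None = None,
    counts: pd.DataFrame | None = None,
    gbc: pd.DataFrame | None = None,
    custom_cutoffs: pd.DataFrame | None = None,
    adapter_stage: str = "posttrim",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag every metric with data for every query sample.

    Cutoffs come from ``custom_cutoffs`` where provided, otherwise they
    are estimated from the reference table (the query itself when no
    reference is supplied).  Returns ``(flag_table, cutoff_table)``:
    the flag table is samples x metrics with entries 0/0.5/1 (NaN where
    a sample lacks the metric), the cutoff table lists the absolute
    warn/fail cutoffs actually used.
    """
    if config is None:
        config = FlagConfig()
    if len(query) == 0:
        raise ValueError("empty query table")
    qm = derive_metrics_frame(query, counts, gbc, adapter_stage=adapter_stage)
    if reference is not None:
        rm = derive_metrics_frame(reference, counts, gbc, adapter_stage=adapter_stage)
    else:
        rm = qm

    flag_cols, cut_rows = {}, []
    for metric in FLAGGED_METRICS + (["auc_gbc"] if gbc is not None else []):
        direction = config.directions.get(metric, "low_is_bad")
        if custom_cutoffs is not None and metric in custom_cutoffs.index:
            row = custom_cutoffs.loc[metric]
            direction = row["direction"]
            cuts = (float(row["warn_cutoff"]), float(row["fail_cutoff"]))
        else:
            ref_vals = rm[metric].dropna()
            if len(ref_vals) < 5:
                if ref_vals.size or qm[metric].notna().any():
                    warnings.warn(f"metric {metric!r}: insufficient reference values, dropped",
                                  stacklevel=2)
                continue
            try:
                cuts = estimate_metric_cutoffs(ref_vals, direction, config)
            except ValueError as exc:  # pragma: no cover - defensive
                warnings.warn(f"metric {metric!r} dropped: {exc}", stacklevel=2)
                continue
        _check_cutoff_row(metric, direction, *cuts)
        flags = qm[metric].map(lambda v: flag_value(v, cuts, direction))
        flag_cols[metric] = flags.map(lambda f: FLAG_ENCODING.get(f, np.nan) if f else np.nan)
        cut_rows.append((metric, direction, cuts[0], cuts[1]))

    if gbc is not None:
        ref_curves = (
            gbc.loc[gbc.index.intersection(reference["sample_id"] if reference is not None
                                           else query["sample_id"])]
        )
        ks_flags = {}
        if len(ref_curves) >= 3:
            for sid in qm.index:
                if sid in gbc.index:
                    res = flag_gbc(sid, gbc.loc[sid].to_numpy(), ref_curves.to_numpy(), config)
                    ks_flags[sid] = FLAG_ENCODING.get(res.flag, np.nan)
            flag_cols["gbc_ks"] = pd.Series(ks_flags)

    flag_table = pd.DataFrame(flag_cols, index=qm.index)
    flag_table.index.name = "sample_id"
    cutoff_table = pd.DataFrame(
        cut_rows, columns=["metric", "direction", "warn_cutoff", "fail_cutoff"]
    ).set_index("metric")
    return flag_table, cutoff_table


def cluster_flag_matrix(flags: pd.DataFrame):
    """Order samples by complete-linkage Euclidean clustering of flag vectors.

    Returns ``(leaf_order, linkage_matrix)``; a single sample returns the
    identity ordering with no linkage.  NaN entries (metric absent for a
    sample) are treated as passes for distance purposes.
    """
    mat = flags.fillna(0.0).to_numpy(dtype=float)
    if len(mat) < 2:
        return list(flags.index), None
    link = hierarchy.linkage(mat, method="complete", metric="euclidean")
    order = hierarchy.leaves_list(link)
    return [flags.index[i] for i in order], link
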