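"""Per-sample pipeline QC metrics derived from raw pipeline outputs.

Eighteen metrics summarize the pipeline stages (sequencing, trimming,
alignment, quantification).  Most are direct ratios of the read-count
funnel; two are less conventional:

``n_detected_genes``
    The number of genes with non-zero raw counts — a cheap proxy for
    library complexity and transcriptome coverage.

``auc_gbc``
    The area under the 0-1 normalized gene-body-coverage curve (100
    bins along the gene body).  Flat, high coverage across the body
    gives values near 100; 3'-biased (degraded) libraries score low.
    Reported on a 0-100 scale by default so that the metric reads like
    a percentage of the maximal (flat) coverage profile.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "METRICS_18",
    "DegenerateCurveError",
    "derive_pipeline_metrics",
    "derive_metrics_frame",
    "count_detected_genes",
    "log2_cpm",
    "build_expression_histogram",
    "normalize_gbc_curve",
    "compute_auc_gbc",
]

# The 18 pipeline metrics used as classifier features, in pipeline order.
METRICS_18 = [
    "n_sequenced_reads",
    "per_base_quality",
    "pct_gc",
    "pct_duplicate_reads",
    "pct_adapter",
    "pct_overrepresented",
    "n_post_trim_reads",
    "pct_post_trim",
    "n_uniquely_aligned",
    "pct_uniquely_aligned",
    "n_rrna",
    "pct_rrna",
    "auc_gbc",
    "n_mapped_exons",
    "pct_mapped_exons",
    "pct_rpl_genes",
    "pct_mt_genes",
    "n_detected_genes",
]


class DegenerateCurveError(ValueError):
    """Raised for a constant coverage curve that cannot be 0-1 normalized."""


def _ratio_pct(num, den, what: str):
    """100 * num/den with absent propagation and 0/0 -> absent + warning."""
    if num is None or den is None or pd.isna(num) or pd.isna(den):
        return np.nan
    if den == 0:
        if num == 0:
            warnings.warn(f"{what}: 0/0, recorded as absent", stacklevel=3)
            return np.nan
        raise ZeroDivisionError(f"{what}: nonzero numerator over zero denominator")
    return 100.0 * num / den


def derive_pipeline_metrics(
    record: dict | pd.Series,
    counts_column: np.ndarray | pd.Series | None = None,
    curve: np.ndarray | None = None,
    adapter_stage: str = "posttrim",
) -> dict:
    """Compute the 18 pipeline metrics for one sample.

    ``record`` holds the raw query-table fields (canonical keys);
    ``counts_column`` the sample's raw gene counts; ``curve`` its
    normalized 100-bin coverage curve.  ``adapter_stage`` picks which
    trimming stage feeds ``pct_adapter`` / ``pct_overrepresented``
    ("posttrim" for in-house data, "pretrim" for externally trimmed
    libraries).  Fields whose inputs are absent come back as NaN.
    """
    r = dict(record)

    def g(key):
        v = r.get(key)
        return np.nan if v is None else v

    out = {
        "n_sequenced_reads": g("n_sequenced_reads"),
        "per_base_quality": g("per_base_quality"),
        "pct_gc": g("pct_gc"),
        "pct_duplicate_reads": g("pct_duplicate_reads"),
        "pct_adapter": g(f"pct_adapter_{adapter_stage}"),
        "pct_overrepresented": g(f"pct_overrepresented_{adapter_stage}"),
        "n_post_trim_reads": g("n_post_trim_reads"),
        "n_uniquely_aligned": g("n_uniquely_aligned_reads"),
        "n_rrna": g("n_rrna_reads"),
        "n_mapped_exons": g("n_mapped_to_exons"),
        "pct_rpl_genes": g("pct_rpl_genes"),
        "pct_mt_genes": g("pct_mt_genes"),
    }
    out["pct_post_trim"] = _ratio_pct(
        out["n_post_trim_reads"], out["n_sequenced_reads"], "pct_post_trim"
    )
    out["pct_uniquely_aligned"] = _ratio_pct(
        out["n_uniquely_aligned"], out["n_post_trim_reads"], "pct_uniquely_aligned"
    )
    out["pct_rrna"] = _ratio_pct(out["n_rrna"], out["n_uniquely_aligned"], "pct_rrna")
    out["pct_mapped_exons"] = _ratio_pct(
        out["n_mapped_exons"], out["n_uniquely_aligned"], "pct_mapped_exons"
    )
    out["n_detected_genes"] = (
        count_detected_genes(counts_column) if counts_column is not None else np.nan
    )
    out["auc_gbc"] = compute_auc_gbc(np.asarray(curve)) if curve is not None else np.nan
    return {k: out[k] for k in METRICS_18}


def derive_metrics_frame(
    qc: pd.DataFrame,
    counts: pd.DataFrame | None = None,
    gbc: pd.DataFrame | None = None,
    adapter_stage: str = "posttrim",
) -> pd.DataFrame:
    """Vectorized :func:`derive_pipeline_metrics` over a whole query table.

    Returns a samples x 18 DataFrame indexed by sample id.
    """
    rows = {}
    for _, rec in qc.iterrows():
        sid = rec["sample_id"]
        col = counts[sid] if counts is not None and sid in counts.columns else None
        crv = gbc.loc[sid].to_numpy() if gbc is not None and sid in gbc.index else None
        rows[sid] = derive_pipeline_metrics(rec, col, crv, adapter_stage=adapter_stage)
    out = pd.DataFrame.from_dict(rows, orient="index")[METRICS_18]
    out.index.name = "sample_id"
    return out


def count_detected_genes(counts_column) -> int:
    """Number of genes with non-zero counts in one sample."""
    arr = np.asarray(counts_column)
    if (arr < 0).any():
        raise ValueError("negative counts")
    return int(np.count_nonzero(arr))


def log2_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(CPM + 1) per sample (columns).  Errors on zero-total samples."""
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero)}")
    return np.log2(counts.div(totals, axis=1) * 1e6 + 1.0)


def build_expression_histogram(counts: pd.DataFrame, bin_width: float = 0.25) -> pd.DataFrame:
    """Per-sample histogram of log2(CPM+1) expression, binned by 0.25.

    Returns a long-form frame (sample_id, bin_start, bin_end, gene_count)
    covering every bin from 0 up to the cohort maximum; the bin counts of
    one sample sum to the number of genes.  Genes with zero counts land
    in the first bin, so the number of detected genes is recoverable as
    total genes minus the count of genes at transformed value exactly 0.
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("empty count matrix")
    expr = log2_cpm(counts)
    top = float(expr.to_numpy().max())
    n_bins = max(1, int(np.ceil((top + 1e-9) / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    recs = []
    for sid in expr.columns:
        hist, _ = np.histogram(expr[sid].to_numpy(), bins=edges)
        # np.histogram's last bin is closed; values exactly at the top edge
        # belong there, consistent with [start, end) elsewhere
        for b in range(n_bins):
            recs.append((sid, edges[b], edges[b + 1], int(hist[b])))
    return pd.DataFrame(recs, columns=["sample_id", "bin_start", "bin_end", "gene_count"])


def normalize_gbc_curve(raw_curve) -> np.ndarray:
    """Min-max normalize a 100-bin coverage curve to [0, 1].

    The minimum maps to exactly 0 and the maximum to exactly 1.  A
    constant curve carries no shape information and raises
    :class:`DegenerateCurveError` (the sample is unscoreable).
    """
    arr = np.asarray(raw_curve, dtype=float)
    if arr.shape != (100,):
        raise ValueError(f"expected 100 bins, got {arr.shape}")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        raise DegenerateCurveError("constant coverage curve cannot be normalized")
    return (arr - lo) / (hi - lo)


def compute_auc_gbc(curve, scale_100: bool = True) -> float:
    """Area under a normalized gene-body-coverage curve.

    Sum of the 100 normalized bin values divided by the bin count, i.e.
    the mean bin height; multiplied by 100 by default so the flat
    maximal profile scores 100.
    """
    arr = np.asarray(curve, dtype=float)
    if arr.shape != (100,):
        raise ValueError(f"expected 100 bins, got {arr.shape}")
    if arr.min() < 0 or arr.max() > 1 + 1e-12:
        raise ValueError("curve must be 0-1 normalized")
    auc = arr.sum() / 100.0
    return float(100.0 * auc if scale_100 else auc)
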