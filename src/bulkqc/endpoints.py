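"""Endpoint quality scores: MSC, UGP and CTS, plus stringency labels.

Three scores capture distinct, intuitively important aspects of sample
quality for a cohort of one expected cell type:

MSC (Mean Sample Correlation)
    Pearson correlation of a sample's log2(CPM+1) expression vector with
    the cohort centroid (per-gene mean across all samples).  Aberrant
    samples correlate poorly with the centroid.  MSC = corr(x, x_bar).

UGP (Unique Genomic Positions)
    log10(min(U, Lim)) / log10(Lim) where U is the number of distinct
    genomic positions covered by reads and Lim the saturation expected
    of a well-sequenced library.  Measures library complexity on a
    0-1 scale.

CTS (Cell Type Score)
    mean(M) / (mean(M) + sum(C)) over marker-gene expressions M and
    contaminant-gene expressions C: 1 means no contaminating signal,
    0 means no marker signal.

A sample is labeled low quality at a given cutoff when it falls below
the cutoff in at least two of the three scores.  Three stringencies are
conventional: 0.88 (base), 0.90 (stricter), 0.91 (strictest).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .metrics import log2_cpm

__all__ = [
    "STRINGENCY_CUTOFFS",
    "compute_msc",
    "compute_ugp",
    "compute_cts",
    "compute_cts_frame",
    "label_quality",
    "compute_endpoint_scores",
]

STRINGENCY_CUTOFFS = {"base": 0.88, "stricter": 0.90, "strictest": 0.91}

# Small default gene lists for an alveolar-macrophage cohort; real runs
# should supply curated lists as configuration.
DEFAULT_MARKER_GENES = ["MARCO", "MRC1"]
DEFAULT_CONTAMINANT_GENES = ["CD3D", "CD19"]


def compute_msc(counts: pd.DataFrame, leave_one_out: bool = False) -> pd.Series:
    """Per-sample Pearson correlation with the cohort centroid.

    Expression is log2(CPM+1); the centroid is the per-gene mean over
    all samples (including the sample itself, unless ``leave_one_out``).
    """
    if counts.shape[1] < 3:
        raise ValueError("need >= 3 samples for a meaningful centroid")
    expr = log2_cpm(counts)
    mat = expr.to_numpy(dtype=float)
    n = mat.shape[1]
    total = mat.sum(axis=1)
    out = {}
    for j, sid in enumerate(expr.columns):
        x = mat[:, j]
        centroid = (total - x) / (n - 1) if leave_one_out else total / n
        if np.std(x) == 0 or np.std(centroid) == 0:
            raise ValueError(f"zero-variance expression vector for sample {sid!r}")
        out[sid] = float(np.corrcoef(x, centroid)[0, 1])
    return pd.Series(out, name="msc")


def compute_ugp(U: float, Lim: float = 2e6) -> float:
    """Library-complexity score log10(min(U, Lim)) / log10(Lim) in [0, 1].

    U = 0 maps to 0 via a floor of 1 inside the logarithm (a sample with
    no aligned reads has no complexity).  Lim defaults to 2e6, the
    saturation of a deeply sequenced bulk library; protocols with higher
    expected coverage should raise it (e.g. 5e6).
    """
    if Lim <= 1:
        raise ValueError("Lim must exceed 1")
    if U < 0:
        raise ValueError("U must be non-negative")
    u = min(max(U, 1.0), float(Lim))
    return float(np.clip(np.log10(u) / np.log10(Lim), 0.0, 1.0))


def compute_cts(marker_expr, contaminant_expr, contaminant_agg: str = "sum") -> float:
    """Cell Type Score from marker and contaminant expression levels.

    Literal form (default): mean(M) / (mean(M) + sum(C)).  With
    ``contaminant_agg="mean"`` the denominator uses mean(C) instead,
    which weighs the two lists symmetrically.
    """
    m = np.asarray(marker_expr, dtype=float)
    c = np.asarray(contaminant_expr, dtype=float)
    if m.size < 1 or c.size < 1:
        raise ValueError("need at least one marker and one contaminant gene")
    if (m < 0).any() or (c < 0).any():
        raise ValueError("expression levels must be non-negative")
    mm = m.mean()
    cc = c.sum() if contaminant_agg == "sum" else c.mean()
    denom = mm + cc
    if denom == 0:
        raise ValueError("all marker and contaminant expressions are zero")
    return float(mm / denom)


def compute_cts_frame(
    counts: pd.DataFrame,
    marker_genes: list[str],
    contaminant_genes: list[str],
    units: str = "cpm",
    contaminant_agg: str = "sum",
) -> pd.Series:
    """CTS per sample from a count matrix and gene lists.

    ``units`` selects the expression scale fed into the score: "cpm"
    (default), "counts", or "log2cpm".
    """
    markers = [g for g in marker_genes if g in counts.index]
    contams = [g for g in contaminant_genes if g in counts.index]
    if not markers or not contams:
        raise ValueError("marker or contaminant genes absent from the count matrix")
    if units == "counts":
        expr = counts.astype(float)
    elif units == "cpm":
        expr = counts.div(counts.sum(axis=0), axis=1) * 1e6
    elif units == "log2cpm":
        expr = log2_cpm(counts)
    else:
        raise ValueError(f"unknown units {units!r}")
    out = {
        sid: compute_cts(expr.loc[markers, sid], expr.loc[contams, sid],
                         contaminant_agg=contaminant_agg)
        for sid in expr.columns
    }
    return pd.Series(out, name="cts")


def label_quality(scores: pd.DataFrame, cutoff: float) -> pd.Series:
    """Low/high label per sample by the at-least-two-of-three rule.

    ``scores`` must hold msc, ugp and cts columns; a sample is "low"
    when at least two of the three fall strictly below ``cutoff``.
    Samples missing any score are excluded with a warning.
    """
    need = ["msc", "ugp", "cts"]
    missing = [c for c in need if c not in scores.columns]
    if missing:
        raise ValueError(f"scores frame missing columns {missing}")
    complete = scores[need].notna().all(axis=1)
    if (~complete).any():
        warnings.warn(
            f"{(~complete).sum()} sample(s) missing endpoint scores, excluded",
            stacklevel=2,
        )
    below = (scores.loc[complete, need] < cutoff).sum(axis=1)
    return below.map(lambda k: "low" if k >= 2 else "high").rename("label")


def compute_endpoint_scores(
    counts: pd.DataFrame,
    unique_positions: pd.Series,
    marker_genes: list[str] | None = None,
    contaminant_genes: list[str] | None = None,
    lim: float = 2e6,
    cutoffs: dict[str, float] | None = None,
    cts_units: str = "cpm",
    cts_contaminant_agg: str = "sum",
) -> pd.DataFrame:
    """All three endpoint scores plus labels at each stringency.

    Returns a frame indexed by sample id with columns msc, ugp, cts and
    ``label_<stringency>`` for every cutoff.
    """
    marker_genes = marker_genes or DEFAULT_MARKER_GENES
    contaminant_genes = contaminant_genes or DEFAULT_CONTAMINANT_GENES
    cutoffs = cutoffs or STRINGENCY_CUTOFFS
    msc = compute_msc(counts)
    cts = compute_cts_frame(counts, marker_genes, contaminant_genes,
                            units=cts_units, contaminant_agg=cts_contaminant_agg)
    ugp = pd.Series(
        {sid: compute_ugp(unique_positions.get(sid, np.nan), lim)
         for sid in counts.columns if pd.notna(unique_positions.get(sid, np.nan))},
        name="ugp",
    )
    out = pd.concat([msc, ugp, cts], axis=1)
    out.index.name = "sample_id"
    for name, cut in cutoffs.items():
        lab = label_quality(out, cut)
        out[f"label_{name}"] = lab.reindex(out.index)
    return out
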