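"""Per-sample diagnostic reports and the cohort summary heatmap.

Each sample gets a page of up to eight panels: sequencing depth,
trimming, alignment and gene-quantification histograms (cohort
distribution with smoothed density, the current sample in teal, the
batch mean dashed purple, warn/fail cutoffs in yellow/red); a ribosomal
RNA scatter of uniquely aligned vs rRNA reads with a least-squares
line; pre/post-trim sequence-contamination violins; the per-sample
gene-expression-distribution curves; and gene-body-coverage curves with
the cohort 95% band.  Panels whose inputs are absent are omitted.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .flagging import cluster_flag_matrix
from .metrics import derive_metrics_frame

__all__ = ["render_sample_report", "render_summary_heatmap", "panel_inventory"]

TEAL = "#009688"
PURPLE = "#7E57C2"
WARN = "#F9A825"
FAIL = "#C62828"

# metric panels: (title, derived-metric key)
_METRIC_PANELS = [
    ("Sequencing Depth", "n_sequenced_reads"),
    ("Trimming", "pct_post_trim"),
    ("Alignment", "pct_uniquely_aligned"),
    ("Gene Quantification", "pct_mapped_exons"),
]


def panel_inventory(qc: pd.DataFrame, histogram=None, gbc=None) -> list[str]:
    """Names of the panels renderable from the supplied tables."""
    metrics = derive_metrics_frame(qc)
    panels = [t for t, key in _METRIC_PANELS if metrics[key].notna().any()]
    if (metrics["n_uniquely_aligned"].notna() & metrics["n_rrna"].notna()).any():
        panels.append("Ribosomal RNA")
    contam = ["pct_overrepresented_pretrim", "pct_adapter_pretrim",
              "pct_overrepresented_posttrim", "pct_adapter_posttrim"]
    if any(c in qc.columns and qc[c].notna().any() for c in contam):
        panels.append("Sequence Contamination")
    if histogram is not None:
        panels.append("Gene Expression Distribution")
    if gbc is not None:
        panels.append("Gene Body Coverage")
    return panels


def _hist_panel(ax, title, values, current, batch_mean, cutoffs):
    vals = values.dropna().to_numpy()
    ax.hist(vals, bins=20, color="0.8", edgecolor="0.6", density=True)
    if len(vals) > 1 and np.std(vals) > 0:
        from scipy.stats import gaussian_kde

        grid = np.linspace(vals.min(), vals.max(), 200)
        ax.plot(grid, gaussian_kde(vals)(grid), color="black", lw=1)
    if pd.notna(current):
        ax.axvline(current, color=TEAL, lw=2, label="sample")
    if pd.notna(batch_mean):
        ax.axvline(batch_mean, color=PURPLE, ls="--", lw=1.5, label="batch mean")
    if cutoffs is not None:
        ax.axvline(cutoffs[0], color=WARN, ls=":", lw=1.5)
        ax.axvline(cutoffs[1], color=FAIL, ls=":", lw=1.5)
    ax.set_title(title, fontsize=9)
    ax.tick_params(labelsize=7)


def render_sample_report(
    sample_id: str,
    qc: pd.DataFrame,
    flags: pd.DataFrame,
    cutoffs: pd.DataFrame,
    out_path: str | Path,
    histogram: pd.DataFrame | None = None,
    gbc: pd.DataFrame | None = None,
) -> Path:
    """Render one sample's multi-panel report to ``out_path``."""
    if sample_id not in set(qc["sample_id"]):
        raise KeyError(f"unknown sample id {sample_id!r}")
    metrics = derive_metrics_frame(qc)
    row = qc.set_index("sample_id").loc[sample_id]
    batch = row["batch_id"]
    in_batch = metrics.loc[qc.loc[qc["batch_id"] == batch, "sample_id"]]

    panels = []  # list of (title, draw_fn)

    for title, key in _METRIC_PANELS:
        if metrics[key].notna().any():
            cuts = (tuple(cutoffs.loc[key, ["warn_cutoff", "fail_cutoff"]])
                    if key in cutoffs.index else None)
            panels.append((title, lambda ax, k=key, t=title, c=cuts: _hist_panel(
                ax, t, metrics[k], metrics.loc[sample_id, k], in_batch[k].mean(), c)))

    if metrics["n_uniquely_aligned"].notna().any() and metrics["n_rrna"].notna().any():
        def rrna_panel(ax):
            x = metrics["n_uniquely_aligned"]
            y = metrics["n_rrna"]
            ok = x.notna() & y.notna()
            ax.scatter(x[ok], y[ok], s=8, color="0.7")
            bmask = ok & metrics.index.isin(in_batch.index)
            ax.scatter(x[bmask], y[bmask], s=10, color=PURPLE)
            if ok.sum() > 1:
                coef = np.polyfit(x[ok], y[ok], 1)
                grid = np.linspace(x[ok].min(), x[ok].max(), 50)
                ax.plot(grid, np.polyval(coef, grid), color="black", lw=1)
            ax.scatter([x[sample_id]], [y[sample_id]], marker="*", s=120, color=TEAL)
            ax.set_title("Ribosomal RNA", fontsize=9)
            ax.tick_params(labelsize=7)

        panels.append(("Ribosomal RNA", rrna_panel))

    contam_cols = [
        ("overrep pre", "pct_overrepresented_pretrim"),
        ("adapter pre", "pct_adapter_pretrim"),
        ("overrep post", "pct_overrepresented_posttrim"),
        ("adapter post", "pct_adapter_posttrim"),
    ]
    avail = [(lab, c) for lab, c in contam_cols if c in qc.columns and qc[c].notna().any()]
    if avail:
        def contam_panel(ax):
            data = [qc[c].dropna().to_numpy() for _, c in avail]
            ax.violinplot(data, showmedians=True)
            for k, (_, c) in enumerate(avail):
                v = row.get(c)
                if pd.notna(v):
                    ax.plot([k + 1], [v], marker="o", color=TEAL)
            ax.set_xticks(range(1, len(avail) + 1))
            ax.set_xticklabels([lab for lab, _ in avail], fontsize=6, rotation=20)
            ax.set_title("Sequence Contamination", fontsize=9)
            ax.tick_params(labelsize=7)

        panels.append(("Sequence Contamination", contam_panel))

    if histogram is not None and (histogram["sample_id"] == sample_id).any():
        def hist_panel(ax):
            for sid, grp in histogram.groupby("sample_id"):
                mid = (grp["bin_start"] + grp["bin_end"]) / 2
                color, lw, z = ("0.8", 0.5, 1)
                if sid == sample_id:
                    color, lw, z = (TEAL, 2.0, 3)
                ax.plot(mid, grp["gene_count"], color=color, lw=lw, zorder=z)
            ax.set_title("Gene Expression Distribution", fontsize=9)
            ax.set_xlabel("log2(CPM+1)", fontsize=7)
            ax.tick_params(labelsize=7)

        panels.append(("Gene Expression Distribution", hist_panel))

    if gbc is not None and sample_id in gbc.index:
        def gbc_panel(ax):
            bins = np.arange(1, 101)
            lo = gbc.quantile(0.025, axis=0)
            hi = gbc.quantile(0.975, axis=0)
            ax.fill_between(bins, lo, hi, color="0.85", label="95% band")
            ax.plot(bins, gbc.mean(axis=0), color="0.4", lw=1)
            ax.plot(bins, gbc.loc[sample_id], color=TEAL, lw=2)
            ax.set_title("Gene Body Coverage", fontsize=9)
            ax.set_xlabel("gene body percentile (5'->3')", fontsize=7)
            ax.tick_params(labelsize=7)

        panels.append(("Gene Body Coverage", gbc_panel))

    n = len(panels)
    ncols = 4
    nrows = int(np.ceil(n / ncols)) or 1
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows))
    axes = np.atleast_1d(axes).ravel()
    for ax, (_, draw) in zip(axes, panels):
        draw(ax)
    for ax in axes[n:]:
        ax.axis("off")
    sample_flags = flags.loc[sample_id] if sample_id in flags.index else pd.Series(dtype=float)
    n_fail = int((sample_flags == 1.0).sum())
    n_warn = int((sample_flags == 0.5).sum())
    fig.suptitle(f"{sample_id}  (batch {batch}) — {n_warn} warn, {n_fail} fail", fontsize=11)
    fig.tight_layout(rect=(0, 0, 1, 0.95))
    out_path = Path(out_path)
    fig.savefig(out_path)
    plt.close(fig)
    return out_path


def render_summary_heatmap(flags: pd.DataFrame, out_path: str | Path) -> Path | None:
    """Samples x metrics grid colored pass (gray) / warn (yellow) / fail (red).

    Rows are ordered by complete-linkage clustering of the flag vectors
    when at least two samples are flagged.
    """
    if flags.shape[0] == 0 or flags.shape[1] == 0:
        warnings.warn("empty flag table: no heatmap rendered", stacklevel=2)
        return None
    order, _ = cluster_flag_matrix(flags)
    mat = flags.loc[order].fillna(0.0).to_numpy()
    cmap = matplotlib.colors.ListedColormap(["0.85", WARN, FAIL])
    bounds = matplotlib.colors.BoundaryNorm([-0.25, 0.25, 0.75, 1.25], cmap.N)
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.4 * flags.shape[1], 1.0 + 0.18 * max(len(flags), 5))
    )
    ax.imshow(mat, aspect="auto", cmap=cmap, norm=bounds, interpolation="nearest")
    ax.set_xticks(range(flags.shape[1]))
    ax.set_xticklabels(flags.columns, rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels(order, fontsize=6)
    ax.set_title("QC flags (gray=pass, yellow=warn, red=fail)", fontsize=10)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path)
    plt.close(fig)
    return out_path
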