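"""Seeded synthetic bulk RNA-seq cohorts with injected low-quality archetypes.

The generator emulates the observable structure of a clinical bulk
RNA-seq cohort of one expected cell type: a read-count funnel
(sequenced >= post-trim >= uniquely aligned >= {rRNA, mapped-to-exons}),
batch structure, a heavy-tailed negative-binomial gene-count matrix
with elevated marker genes and near-silent contaminant genes, unimodal
100-bin gene-body-coverage curves, and library-complexity (unique
genomic position) counts that saturate with depth.

Five defect archetypes perturb the relevant generative parameters:

* ``low_depth`` — sequenced reads divided by 10;
* ``rrna_contaminated`` — rRNA fraction raised to 30-60%;
* ``degraded_3prime`` — coverage mass shifted toward the 3' end,
  lowering the coverage AUC;
* ``cell_contaminated`` — contaminant-gene expression up, marker genes
  down, with the mapping-rate and mitochondrial/ribosomal-protein
  signatures of a mixed cell population;
* ``low_complexity`` — counts concentrated on few genes, fewer unique
  positions, more duplicates.

Every defect also adds gene-wise expression noise, so all archetypes
depress the sample-to-centroid correlation.  Outputs are deterministic
per seed and always satisfy the funnel invariants by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import normalize_gbc_curve

__all__ = ["ARCHETYPES", "CohortSpec", "Cohort", "generate_cohort",
           "default_cohort_spec", "study_like_spec", "write_fixture_bundle",
           "save_spec", "load_spec"]

ARCHETYPES = [
    "low_depth",
    "rrna_contaminated",
    "degraded_3prime",
    "cell_contaminated",
    "low_complexity",
]

#: conventional pipeline headers used when writing the query table
_QUERY_HEADERS = {
    "sample_id": "Sample",
    "batch_id": "Batch",
    "n_sequenced_reads": "# Sequenced Reads",
    "n_post_trim_reads": "# Post-Trim Reads",
    "pct_overrepresented_pretrim": "% Overrepresented Sequences (Pre-trim)",
    "pct_adapter_pretrim": "% Adapter Content (Pre-trim)",
    "pct_overrepresented_posttrim": "% Overrepresented Sequences (Post-trim)",
    "pct_adapter_posttrim": "% Adapter Content (Post-trim)",
    "n_uniquely_aligned_reads": "# Uniquely Aligned Reads",
    "n_rrna_reads": "# rRNA Reads",
    "n_mapped_to_exons": "# Mapped to Exons",
    "pct_duplicate_reads": "% Duplicate Reads",
    "pct_gc": "% GC Content",
    "per_base_quality": "Per Base Sequence Quality",
    "pct_mt_genes": "% MT Genes",
    "pct_rpl_genes": "% RPL Genes",
    "unique_genomic_positions": "Unique Genomic Positions",
}


@dataclass
class CohortSpec:
    """Conditions a synthetic cohort is generated under."""

    n_samples: int = 300
    n_genes: int = 8000
    n_batches: int = 4
    defects: dict = field(default_factory=dict)  # sample index -> archetype(s)
    n_marker_genes: int = 5
    n_contaminant_genes: int = 5
    nb_dispersion: float = 0.3
    mean_sequenced_reads: float = 3e7
    lim: float = 2e6
    seed: int = 0
    # per-archetype effect sizes
    low_depth_factor: float = 10.0
    rrna_range: tuple = (0.30, 0.60)
    degraded_gamma: float = 3.0
    contamination_fraction: tuple = (0.4, 0.6)  # foreign-profile mixing range
    low_complexity_alpha: float = 3.0
    defect_noise_sigma: float = 1.0
    clean_noise_sigma: float = 0.15

    def __post_init__(self):
        if self.n_samples < 0 or self.n_genes < 20 or self.n_batches < 1:
            raise ValueError("infeasible cohort spec")
        for idx, arcs in self.defects.items():
            if not 0 <= idx < self.n_samples:
                raise ValueError(f"defect index {idx} out of range")
            arcs = [arcs] if isinstance(arcs, str) else list(arcs)
            for a in arcs:
                if a not in ARCHETYPES:
                    raise ValueError(f"unknown archetype {a!r}")


@dataclass
class Cohort:
    """Generated cohort: tables ready for the QC pipeline plus truth."""

    qc: pd.DataFrame  # query-table schema (canonical columns)
    counts: pd.DataFrame  # genes x samples
    gbc: pd.DataFrame  # samples x 100 normalized bins
    unique_positions: pd.Series
    truth: pd.DataFrame  # sample_id, archetype ("none" for clean), is_defect
    marker_genes: list
    contaminant_genes: list
    spec: CohortSpec


def default_cohort_spec(n_samples: int = 300, defect_fraction: float = 0.10,
                        seed: int = 0, **kwargs) -> CohortSpec:
    """Default study conditions: archetypes assigned round-robin to the
    first ``defect_fraction`` of samples (positions are shuffled by seed)."""
    n_def = int(round(n_samples * defect_fraction))
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_samples, size=n_def, replace=False)
    defects = {int(i): ARCHETYPES[k % len(ARCHETYPES)] for k, i in enumerate(sorted(idx))}
    return CohortSpec(n_samples=n_samples, defects=defects, seed=seed, **kwargs)


def study_like_spec(seed: int = 0, **kwargs) -> CohortSpec:
    """A cohort at large clinical scale: 252 samples sequenced across
    11 batches, ~10% defective."""
    spec = default_cohort_spec(n_samples=252, defect_fraction=0.10, seed=seed, **kwargs)
    spec.n_batches = 11
    return spec


def save_spec(spec: CohortSpec, path: str | Path) -> None:
    """Write a cohort spec as a YAML key-value file."""
    import dataclasses

    import yaml

    blob = dataclasses.asdict(spec)
    blob["rrna_range"] = list(blob["rrna_range"])
    blob["contamination_fraction"] = list(blob["contamination_fraction"])
    with open(path, "w") as fh:
        yaml.safe_dump(blob, fh, sort_keys=False)


def load_spec(path: str | Path) -> CohortSpec:
    """Read a cohort spec written by :func:`save_spec`."""
    import yaml

    with open(path) as fh:
        blob = yaml.safe_load(fh)
    for key in ("rrna_range", "contamination_fraction"):
        if key in blob:
            blob[key] = tuple(blob[key])
    if "defects" in blob and blob["defects"]:
        blob["defects"] = {int(k): v for k, v in blob["defects"].items()}
    return CohortSpec(**blob)


def _sample_archetypes(spec: CohortSpec, i: int) -> list[str]:
    a = spec.defects.get(i, [])
    return [a] if isinstance(a, str) else list(a)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw one cohort under ``spec``.  Deterministic per ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    G, N = spec.n_genes, spec.n_samples

    # gene-level relative expression: 60% common genes (lognormal), 40%
    # rare genes that are depth-sensitively detected
    n_common = int(G * 0.6)
    rel = np.empty(G)
    rel[:n_common] = rng.lognormal(0.0, 1.2, n_common)
    rel[n_common:] = rng.lognormal(-7.0, 1.5, G - n_common)
    gene_ids = [f"G{i:05d}" for i in range(G)]
    marker_idx = np.arange(spec.n_marker_genes)
    contam_idx = np.arange(spec.n_marker_genes,
                           spec.n_marker_genes + spec.n_contaminant_genes)
    rel[marker_idx] = 30.0 * rng.uniform(0.8, 1.2, len(marker_idx))
    rel[contam_idx] = 0.03 * rng.uniform(0.8, 1.2, len(contam_idx))
    marker_genes = [gene_ids[i] for i in marker_idx]
    contaminant_genes = [gene_ids[i] for i in contam_idx]

    # the expression profile of a contaminating cell population: an
    # independent transcriptome that expresses the contaminant genes and
    # is silent for the cohort's marker genes
    foreign = rng.lognormal(-7.0, 1.5, G)
    foreign_common = rng.choice(G, n_common, replace=False)  # its own expressed set
    foreign[foreign_common] = rng.lognormal(0.0, 1.2, n_common)
    foreign[marker_idx] = 0.03 * rng.uniform(0.8, 1.2, len(marker_idx))
    foreign[contam_idx] = 30.0 * rng.uniform(0.8, 1.2, len(contam_idx))

    t = (np.arange(100) + 0.5) / 100.0  # bin centers, 5'->3'
    base_curve = 1.0 - 0.8 * ((t - 0.5) * 2.0) ** 4

    qc_rows, counts_cols, gbc_rows, upos, truth_rows = [], {}, {}, {}, []
    for i in range(N):
        arcs = _sample_archetypes(spec, i)
        sid = f"S{i:04d}"
        batch = f"B{(i % spec.n_batches) + 1:02d}"

        n_seq = rng.lognormal(np.log(spec.mean_sequenced_reads), 0.3)
        if "low_depth" in arcs:
            n_seq /= spec.low_depth_factor
        post_frac = rng.uniform(0.95, 0.99)
        uniq_frac = rng.uniform(0.70, 0.90)
        mapped_frac = (rng.uniform(0.30, 0.42) if "cell_contaminated" in arcs
                       else rng.uniform(0.50, 0.80))
        rrna_frac = (rng.uniform(*spec.rrna_range) if "rrna_contaminated" in arcs
                     else rng.uniform(0.01, 0.05))
        n_seq = int(round(n_seq))
        n_post = int(round(n_seq * post_frac))
        n_uniq = int(round(n_post * uniq_frac))
        n_rrna = int(round(n_uniq * rrna_frac))
        n_mapped = int(round(n_uniq * mapped_frac))

        # expression profile for this sample
        sigma = spec.defect_noise_sigma if arcs else spec.clean_noise_sigma
        r = rel * rng.lognormal(0.0, sigma, G)
        if "cell_contaminated" in arcs:
            # mix in the foreign population's transcriptome
            frac = rng.uniform(*spec.contamination_fraction)
            r = ((1 - frac) * r / r.sum()
                 + frac * (foreign * rng.lognormal(0.0, 0.3, G)) / foreign.sum())
        if "low_complexity" in arcs:
            r = r ** spec.low_complexity_alpha
        p = r / r.sum()
        lib = n_mapped / 20.0  # count-table depth scales with exonic reads
        mu = p * lib
        lam = rng.gamma(1.0 / spec.nb_dispersion, spec.nb_dispersion * mu)
        counts_cols[sid] = rng.poisson(lam)

        # coverage curve
        curve = base_curve * rng.lognormal(0.0, 0.05, 100)
        if "degraded_3prime" in arcs:
            curve = curve * np.exp(spec.degraded_gamma * t)
        gbc_rows[sid] = normalize_gbc_curve(curve)

        # unique genomic positions saturate with aligned depth
        u_factor = 0.05 if "low_complexity" in arcs else 1.0
        upos[sid] = int(min(n_uniq * 0.1 * u_factor, spec.lim))

        qc_rows.append({
            "sample_id": sid,
            "batch_id": batch,
            "n_sequenced_reads": n_seq,
            "n_post_trim_reads": n_post,
            "pct_overrepresented_pretrim": rng.uniform(1.0, 5.0),
            "pct_adapter_pretrim": rng.uniform(2.0, 8.0),
            "pct_overrepresented_posttrim": rng.uniform(0.05, 0.5),
            "pct_adapter_posttrim": rng.uniform(0.1, 1.0),
            "n_uniquely_aligned_reads": n_uniq,
            "n_rrna_reads": n_rrna,
            "n_mapped_to_exons": n_mapped,
            "pct_duplicate_reads": (rng.uniform(60, 85) if "low_complexity" in arcs
                                    else rng.uniform(20, 40)),
            "pct_gc": rng.normal(47.0, 2.0),
            "per_base_quality": (rng.uniform(28, 33) if "degraded_3prime" in arcs
                                 else rng.normal(36.0, 1.0)),
            "pct_mt_genes": (rng.uniform(10, 16) if "cell_contaminated" in arcs
                             else rng.uniform(3, 8)),
            "pct_rpl_genes": (rng.uniform(16, 22) if "cell_contaminated" in arcs
                              else rng.uniform(8, 12)),
            "unique_genomic_positions": upos[sid],
        })
        truth_rows.append({
            "sample_id": sid,
            "archetype": "+".join(arcs) if arcs else "none",
            "is_defect": bool(arcs),
        })

    qc = pd.DataFrame(qc_rows, columns=list(_QUERY_HEADERS))
    counts = pd.DataFrame(counts_cols, index=pd.Index(gene_ids, name="gene_id"))
    gbc = pd.DataFrame.from_dict(gbc_rows, orient="index",
                                 columns=[f"bin_{b + 1}" for b in range(100)])
    gbc.index.name = "sample_id"
    truth = pd.DataFrame(truth_rows, columns=["sample_id", "archetype", "is_defect"]
                         ).set_index("sample_id")
    return Cohort(qc, counts, gbc, pd.Series(upos, name="unique_genomic_positions"),
                  truth, marker_genes, contaminant_genes, spec)


def write_fixture_bundle(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort in the standard on-disk dialects.

    Emits query CSV (conventional pipeline headers), counts CSV, gene
    body coverage CSV, unique position CSV and truth-label CSV, all
    loadable by the readers in :mod:`bulkqc.io` without warnings.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    q = cohort.qc.rename(columns=_QUERY_HEADERS)
    paths["query"] = out / "query_qc.csv"
    q.to_csv(paths["query"], index=False)

    paths["counts"] = out / "gene_counts.csv"
    cohort.counts.to_csv(paths["counts"], index_label="gene_id")

    paths["gbc"] = out / "gene_body_coverage.csv"
    cohort.gbc.to_csv(paths["gbc"], index_label="sample_id")

    paths["unique_positions"] = out / "unique_positions.csv"
    cohort.unique_positions.rename("unique_genomic_positions").to_csv(
        paths["unique_positions"], index_label="sample_id")

    paths["truth"] = out / "truth_labels.csv"
    cohort.truth.to_csv(paths["truth"], index_label="sample_id")

    genes = pd.DataFrame({
        "gene_id": cohort.marker_genes + cohort.contaminant_genes,
        "role": (["marker"] * len(cohort.marker_genes)
                 + ["contaminant"] * len(cohort.contaminant_genes)),
    })
    paths["gene_lists"] = out / "gene_lists.csv"
    genes.to_csv(paths["gene_lists"], index=False)
    return paths
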