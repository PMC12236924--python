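"""Reading, validating and writing the tabular inputs and outputs.

The central input is a *query table* of per-sample pipeline QC metrics
(one row per sequencing library) with the columns produced by a standard
bulk RNA-seq pipeline: read counts at each stage of the trimming /
alignment / quantification funnel plus contamination percentages.
Optional side tables carry per-sample gene-expression histograms,
gene-body-coverage curves (100 bins per sample) and the raw gene count
matrix.  Everything is plain CSV/TSV; the flag matrix is additionally
exported as XLSX for spreadsheet users.

Header spellings vary across pipelines ("# Sequenced Reads",
"n_sequenced_reads", "Sequenced.Reads" ...), so headers are normalized
by lowercasing and stripping punctuation before matching against
canonical keys.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "QCSchemaError",
    "QCValidationError",
    "RAW_COLUMNS",
    "EXTRA_COLUMNS",
    "FLAG_ENCODING",
    "read_qc_table",
    "read_counts_matrix",
    "read_gbc_table",
    "read_histogram_table",
    "read_aux_tables",
    "read_cutoff_table",
    "write_cutoff_table",
    "write_flag_outputs",
    "read_flag_table",
    "validate_qc_frame",
]


class QCSchemaError(ValueError):
    """A required column is missing or a table has the wrong shape."""


class QCValidationError(ValueError):
    """Values present but inconsistent (duplicates, negative counts, ...)."""


# canonical raw query-table columns, in the conventional order
RAW_COLUMNS = [
    "n_sequenced_reads",
    "n_post_trim_reads",
    "pct_overrepresented_pretrim",
    "pct_adapter_pretrim",
    "pct_overrepresented_posttrim",
    "pct_adapter_posttrim",
    "n_uniquely_aligned_reads",
    "n_rrna_reads",
    "n_mapped_to_exons",
]

# optional extras that some pipelines provide directly
EXTRA_COLUMNS = [
    "pct_duplicate_reads",
    "pct_gc",
    "per_base_quality",
    "pct_mt_genes",
    "pct_rpl_genes",
    "unique_genomic_positions",
]

COUNT_COLUMNS = {
    "n_sequenced_reads",
    "n_post_trim_reads",
    "n_uniquely_aligned_reads",
    "n_rrna_reads",
    "n_mapped_to_exons",
    "unique_genomic_positions",
}

PCT_COLUMNS = {
    "pct_overrepresented_pretrim",
    "pct_adapter_pretrim",
    "pct_overrepresented_posttrim",
    "pct_adapter_posttrim",
    "pct_duplicate_reads",
    "pct_gc",
    "pct_mt_genes",
    "pct_rpl_genes",
}

# the read-count funnel: (larger, smaller) pairs that must satisfy >=
FUNNEL = [
    ("n_sequenced_reads", "n_post_trim_reads"),
    ("n_post_trim_reads", "n_uniquely_aligned_reads"),
    ("n_uniquely_aligned_reads", "n_rrna_reads"),
    ("n_uniquely_aligned_reads", "n_mapped_to_exons"),
]

FLAG_ENCODING = {"pass": 0.0, "warn": 0.5, "fail": 1.0}
FLAG_DECODING = {v: k for k, v in FLAG_ENCODING.items()}


def _norm_header(name: str) -> str:
    """Lowercase and strip whitespace/#/%/punctuation from a header."""
    return re.sub(r"[^a-z0-9]", "", str(name).lower())


# accepted spellings (normalized) -> canonical key.  The verbatim pipeline
# headers normalize onto the left-hand keys below.
_HEADER_ALIASES = {
    "sample": "sample_id",
    "sampleid": "sample_id",
    "batch": "batch_id",
    "batchid": "batch_id",
    "sequencedreads": "n_sequenced_reads",
    "nsequencedreads": "n_sequenced_reads",
    "posttrimreads": "n_post_trim_reads",
    "nposttrimreads": "n_post_trim_reads",
    "overrepresentedsequencespretrim": "pct_overrepresented_pretrim",
    "pctoverrepresentedpretrim": "pct_overrepresented_pretrim",
    "adaptercontentpretrim": "pct_adapter_pretrim",
    "pctadapterpretrim": "pct_adapter_pretrim",
    "overrepresentedsequencesposttrim": "pct_overrepresented_posttrim",
    "pctoverrepresentedposttrim": "pct_overrepresented_posttrim",
    "adaptercontentposttrim": "pct_adapter_posttrim",
    "pctadapterposttrim": "pct_adapter_posttrim",
    "uniquelyalignedreads": "n_uniquely_aligned_reads",
    "nuniquelyalignedreads": "n_uniquely_aligned_reads",
    "rrnareads": "n_rrna_reads",
    "nrrnareads": "n_rrna_reads",
    "mappedtoexons": "n_mapped_to_exons",
    "nmappedtoexons": "n_mapped_to_exons",
    "duplicatereads": "pct_duplicate_reads",
    "pctduplicatereads": "pct_duplicate_reads",
    "gccontent": "pct_gc",
    "pctgc": "pct_gc",
    "perbasesequencequality": "per_base_quality",
    "perbasequality": "per_base_quality",
    "mtgenes": "pct_mt_genes",
    "pctmtgenes": "pct_mt_genes",
    "rplgenes": "pct_rpl_genes",
    "pctrplgenes": "pct_rpl_genes",
    "uniquegenomicpositions": "unique_genomic_positions",
    "uniquegenetic positions".replace(" ", ""): "unique_genomic_positions",
}


def _canonicalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    mapping = {}
    for col in df.columns:
        key = _norm_header(col)
        mapping[col] = _HEADER_ALIASES.get(key, key)
    return df.rename(columns=mapping)


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a CSV/TSV, sniffing the delimiter between comma and tab."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") > first.count(",") else ","
    return pd.read_csv(path, sep=sep)


def validate_qc_frame(df: pd.DataFrame) -> None:
    """Check uniqueness, non-negativity, percentage bounds and the funnel.

    Raises :class:`QCValidationError` naming the offending sample/column.
    Missing values are allowed everywhere except ``sample_id``.
    """
    if df["sample_id"].isna().any() or (df["sample_id"].astype(str).str.strip() == "").any():
        raise QCValidationError("empty sample_id encountered")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise QCValidationError(f"duplicate sample ids: {sorted(set(dup))}")
    for col in sorted(COUNT_COLUMNS & set(df.columns)):
        bad = df.loc[df[col].notna() & (df[col] < 0), "sample_id"]
        if len(bad):
            raise QCValidationError(
                f"negative count in column {col!r} for sample(s) {list(bad)}"
            )
    for col in sorted(PCT_COLUMNS & set(df.columns)):
        vals = df[col]
        bad = df.loc[vals.notna() & ((vals < 0) | (vals > 100)), "sample_id"]
        if len(bad):
            raise QCValidationError(
                f"percentage outside [0,100] in column {col!r} for sample(s) {list(bad)}"
            )
    for big, small in FUNNEL:
        if big in df.columns and small in df.columns:
            both = df[big].notna() & df[small].notna()
            bad = df.loc[both & (df[small] > df[big]), "sample_id"]
            if len(bad):
                raise QCValidationError(
                    f"read-count funnel violated ({small} > {big}) "
                    f"for sample(s) {list(bad)}"
                )


def read_qc_table(path: str | Path, role: str = "query") -> pd.DataFrame:
    """Read and validate a query or reference QC table.

    Returns a DataFrame with canonical column names, one row per sample.
    A missing ``Batch`` column assigns every sample to batch ``"all"``.
    Metric columns that are absent from the file stay absent from the
    frame; downstream steps that need them are skipped.
    """
    if role not in ("query", "reference"):
        raise ValueError(f"role must be 'query' or 'reference', got {role!r}")
    df = _canonicalize_columns(_read_delimited(path))
    if "sample_id" not in df.columns:
        raise QCSchemaError(f"{path}: no Sample column found")
    df["sample_id"] = df["sample_id"].astype(str)
    if "batch_id" not in df.columns:
        df["batch_id"] = "all"
    df["batch_id"] = df["batch_id"].fillna("all").astype(str)
    known = ["sample_id", "batch_id"] + RAW_COLUMNS + EXTRA_COLUMNS
    keep = [c for c in known if c in df.columns]
    extra = [c for c in df.columns if c not in known]
    df = df[keep + extra]
    validate_qc_frame(df)
    return df.reset_index(drop=True)


def read_counts_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples raw count matrix (first column = gene id)."""
    df = _read_delimited(path)
    df = df.set_index(df.columns[0])
    df.index.name = "gene_id"
    df.columns = [str(c) for c in df.columns]
    if df.index.duplicated().any():
        raise QCValidationError("duplicate gene ids in count matrix")
    if pd.Index(df.columns).duplicated().any():
        raise QCValidationError("duplicate sample ids in count matrix")
    mat = df.apply(pd.to_numeric)
    if (mat.to_numpy() < 0).any():
        raise QCValidationError("negative entries in count matrix")
    return mat


def read_gbc_table(path: str | Path, normalize: bool = True) -> pd.DataFrame:
    """Read a gene-body-coverage table: one sample per row, 100 bins.

    The dialect matches the combined output of the standard coverage
    utility after 0-1 normalization: first column sample id, then 100
    numeric bins running 5'->3'.  Raw (un-normalized) curves are min-max
    rescaled on read when ``normalize`` is set.
    """
    df = _read_delimited(path)
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    if df.shape[1] != 100:
        # find first offending row for a useful message
        raise QCSchemaError(
            f"{path}: gene body coverage rows must have exactly 100 bins, "
            f"got {df.shape[1]}"
        )
    try:
        mat = df.apply(pd.to_numeric).astype(float)
    except (ValueError, TypeError) as exc:
        raise QCSchemaError(f"{path}: non-numeric coverage value ({exc})") from exc
    if normalize:
        from .metrics import normalize_gbc_curve

        out = {}
        for sid, row in mat.iterrows():
            vals = row.to_numpy(dtype=float)
            if np.isclose(vals.min(), 0.0) and np.isclose(vals.max(), 1.0):
                out[sid] = vals
            else:
                out[sid] = normalize_gbc_curve(vals)
        mat = pd.DataFrame.from_dict(out, orient="index", columns=mat.columns)
        mat.index.name = "sample_id"
    return mat


def read_histogram_table(path: str | Path) -> pd.DataFrame:
    """Read a long-form expression histogram: sample, bin_start, bin_end, gene_count."""
    df = _canonicalize_columns(_read_delimited(path))
    required = {"sample_id", "bin_start", "bin_end", "gene_count"}
    missing = required - set(df.columns)
    if missing:
        raise QCSchemaError(f"{path}: histogram table missing columns {sorted(missing)}")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def read_aux_tables(
    histogram_path: str | Path | None = None,
    gbc_path: str | Path | None = None,
    counts_path: str | Path | None = None,
    query_samples: list[str] | None = None,
):
    """Read whichever optional side tables are supplied.

    Returns ``(histogram, gbc, counts)`` with ``None`` for absent paths.
    Sample ids are cross-checked against the query table (warning only).
    """
    hist = read_histogram_table(histogram_path) if histogram_path else None
    gbc = read_gbc_table(gbc_path) if gbc_path else None
    counts = read_counts_matrix(counts_path) if counts_path else None
    if query_samples is not None:
        qset = set(map(str, query_samples))
        checks = [
            ("histogram", set(hist["sample_id"]) if hist is not None else None),
            ("gene body coverage", set(gbc.index) if gbc is not None else None),
            ("counts", set(counts.columns) if counts is not None else None),
        ]
        for name, ids in checks:
            if ids is not None and not ids & qset:
                warnings.warn(
                    f"{name} table shares no sample ids with the query table",
                    stacklevel=2,
                )
            elif ids is not None and ids - qset:
                warnings.warn(
                    f"{name} table has {len(ids - qset)} sample id(s) absent "
                    "from the query table",
                    stacklevel=2,
                )
    return hist, gbc, counts


def read_cutoff_table(path: str | Path) -> pd.DataFrame:
    """Read a cutoff table: metric, direction, warn_cutoff, fail_cutoff."""
    df = _canonicalize_columns(_read_delimited(path))
    required = {"metric", "direction", "warncutoff", "failcutoff"} - set(df.columns)
    # _canonicalize leaves warn_cutoff -> warncutoff; accept both spellings
    rename = {"warncutoff": "warn_cutoff", "failcutoff": "fail_cutoff"}
    df = df.rename(columns=rename)
    missing = {"metric", "direction", "warn_cutoff", "fail_cutoff"} - set(df.columns)
    if missing:
        raise QCSchemaError(f"{path}: cutoff table missing columns {sorted(missing)}")
    df = df.set_index("metric")
    for metric, row in df.iterrows():
        _check_cutoff_row(metric, row["direction"], row["warn_cutoff"], row["fail_cutoff"])
    return df[["direction", "warn_cutoff", "fail_cutoff"]]


def _check_cutoff_row(metric, direction, warn, fail):
    if direction not in ("low_is_bad", "high_is_bad"):
        raise QCValidationError(f"{metric}: unknown direction {direction!r}")
    if direction == "low_is_bad" and fail > warn:
        raise QCValidationError(f"{metric}: fail cutoff must be <= warn cutoff (low_is_bad)")
    if direction == "high_is_bad" and fail < warn:
        raise QCValidationError(f"{metric}: fail cutoff must be >= warn cutoff (high_is_bad)")


def write_cutoff_table(cutoffs: pd.DataFrame, path: str | Path) -> None:
    cutoffs.to_csv(path, index_label="metric")


def write_flag_outputs(flags: pd.DataFrame, cutoffs: pd.DataFrame, out_dir: str | Path):
    """Write flag matrix (CSV + XLSX, labels and 0/0.5/1 encoding) and cutoffs.

    Returns the list of files written.  ``flags`` is samples x metrics with
    entries in {0, 0.5, 1} (NaN allowed for metrics without data for a
    sample; written as empty cells).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = flags.map(lambda v: FLAG_DECODING.get(v, "") if pd.notna(v) else "")
    files = []

    enc_path = out_dir / "qc_flags_encoded.csv"
    flags.to_csv(enc_path, index_label="sample_id")
    files.append(enc_path)

    lab_path = out_dir / "qc_flags.csv"
    labels.to_csv(lab_path, index_label="sample_id")
    files.append(lab_path)

    xlsx_path = out_dir / "qc_flags.xlsx"
    with pd.ExcelWriter(xlsx_path, engine="openpyxl") as xl:
        labels.to_excel(xl, sheet_name="flags", index_label="sample_id")
        flags.to_excel(xl, sheet_name="flags_encoded", index_label="sample_id")
    files.append(xlsx_path)

    cut_path = out_dir / "qc_cutoffs.csv"
    write_cutoff_table(cutoffs, cut_path)
    files.append(cut_path)
    return files


def read_flag_table(path: str | Path) -> pd.DataFrame:
    """Read back an encoded flag CSV written by :func:`write_flag_outputs`."""
    df = pd.read_csv(path, index_col="sample_id")
    df.index = df.index.astype(str)
    vals = df.to_numpy(dtype=float)
    ok = np.isnan(vals) | np.isin(vals, [0.0, 0.5, 1.0])
    if not ok.all():
        raise QCValidationError("flag table entries must be in {0, 0.5, 1}")
    return df.astype(float)
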