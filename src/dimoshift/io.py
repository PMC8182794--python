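"""Reading and writing the pipeline's plain-text formats.

Canonical formats are diff-able TSV/CSV: counts (first column gene id,
remaining columns library ids), a design table (library_id, sex,
temperature, replicate), a CTmin phenotype CSV, two-column term/gene
annotation (or GMT), and per-stage result tables.  Output tables begin with
commented metadata lines (``# key: value``) which readers skip.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix

__all__ = [
    "read_counts",
    "read_design",
    "read_count_matrix",
    "read_ctmin",
    "read_annotation",
    "read_external_bias",
    "write_table",
    "read_table",
]


def _fail(path, line, column, message) -> None:
    raise ValueError(f"{path}:{line}:{column}: {message}")


def read_design(path) -> pd.DataFrame:
    path = Path(path)
    design = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"library_id", "sex", "temperature"}
    missing = required - set(design.columns)
    if missing:
        _fail(path, 1, 1, f"design lacks columns {sorted(missing)}")
    dup = design["library_id"].duplicated()
    if dup.any():
        line = int(np.flatnonzero(dup)[0]) + 2
        _fail(path, line, 1, f"duplicate library id {design['library_id'][dup].iloc[0]!r}")
    return design.set_index("library_id")


def read_counts(path) -> pd.DataFrame:
    """Raw counts TSV -> integer DataFrame (validation happens here)."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if raw.index.duplicated().any():
        gene = raw.index[raw.index.duplicated()][0]
        line = int(np.flatnonzero(raw.index == gene)[-1]) + 2
        _fail(path, line, 1, f"duplicate gene id {gene!r}")
    values = raw.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for j, col in enumerate(raw.columns):
            coerced = pd.to_numeric(raw[col], errors="coerce")
            if coerced.isna().any():
                line = int(np.flatnonzero(coerced.isna())[0]) + 2
                _fail(path, line, j + 2, f"non-numeric count {raw[col].iloc[line - 2]!r}")
        values = raw.to_numpy(float)
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        _fail(path, int(i) + 2, int(j) + 2, f"negative count {values[i, j]}")
    frac = values != np.floor(values)
    if frac.any():
        i, j = np.argwhere(frac)[0]
        _fail(path, int(i) + 2, int(j) + 2, f"non-integer count {values[i, j]}")
    return raw.astype(np.int64)


def read_count_matrix(counts_path, design_path) -> CountMatrix:
    return CountMatrix(read_counts(counts_path), read_design(design_path))


def read_ctmin(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    required = {"fly_id", "sex", "treatment", "weight_mg", "batch", "ctmin_c"}
    missing = required - set(df.columns)
    if missing:
        _fail(path, 1, 1, f"CTmin table lacks columns {sorted(missing)}")
    return df


def read_external_bias(path) -> pd.Series:
    """Gene -> external bias label (female_biased / male_biased / unbiased)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        _fail(path, 1, 1, "expected columns gene_id, label")
    s = df.set_index(df.columns[0])[df.columns[1]]
    bad = ~s.isin(["female_biased", "male_biased", "unbiased"])
    if bad.any():
        _fail(path, int(np.flatnonzero(bad)[0]) + 2, 2, f"unknown label {s[bad].iloc[0]!r}")
    return s


def read_annotation(path, seed: int | None = None) -> dict[str, set[str]]:
    """Two-column TSV (term_id, gene_id) or GMT -> term -> gene set map.

    When ``seed`` is given and the table carries a third column of
    alternative ortholog ids per gene, one is chosen at random (seeded) —
    mirroring pipelines that must pick a single ortholog before enrichment.
    """
    path = Path(path)
    annotation: dict[str, set[str]] = {}
    if path.suffix.lower() == ".gmt":
        for line in path.read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            annotation[parts[0]] = set(parts[2:])
        return annotation
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        _fail(path, 1, 1, "expected columns term_id, gene_id")
    term_col, gene_col = df.columns[:2]
    if df.shape[1] >= 3 and seed is not None:
        rng = np.random.default_rng(seed)
        genes = []
        for _, row in df.iterrows():
            options = [g for g in str(row.iloc[2]).split(",") if g] or [row[gene_col]]
            genes.append(options[rng.integers(len(options))])
        df = df.assign(**{gene_col: genes})
    for term, group in df.groupby(term_col):
        annotation[str(term)] = set(group[gene_col])
    return annotation


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_table(
    frame: pd.DataFrame,
    path,
    metadata: dict | None = None,
    index: bool = True,
    sep: str = "\t",
    float_format: str = "%.10g",
) -> Path:
    """Write a TSV with a commented metadata header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, sep=sep, index=index, float_format=float_format)
    return path


def read_table(path, sep: str = "\t", index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", index_col=index_col)
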