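"""Core in-memory containers for the expression pipeline.

The canonical experimental unit is a gene x library matrix of integer read
counts together with a per-library design (sex, temperature, replicate).
All downstream stages consume these validated containers rather than raw
frames, so schema errors surface once, at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEXES = ("F", "M")
TEMPERATURES = ("control", "cold")

#: canonical ordering of the four sex x temperature groups
GROUPS = tuple((s, t) for s in SEXES for t in TEMPERATURES)

_SEX_ALIASES = {
    "f": "F", "female": "F", "m": "M", "male": "M",
}
_TEMP_ALIASES = {
    "control": "control", "ctrl": "control", "19c": "control",
    "19c-control": "control", "cold": "cold", "6c": "cold", "6c-cold": "cold",
}


def canonical_sex(value: str) -> str:
    try:
        return _SEX_ALIASES[str(value).strip().lower()]
    except KeyError:
        raise ValueError(f"unrecognized sex label: {value!r} (expected F/M/female/male)")


def canonical_temperature(value: str) -> str:
    try:
        return _TEMP_ALIASES[str(value).strip().lower()]
    except KeyError:
        raise ValueError(
            f"unrecognized temperature label: {value!r} (expected control/cold/19C/6C)"
        )


@dataclass
class CountMatrix:
    """Integer read counts (genes x libraries) with the 2x2 factorial design.

    Parameters
    ----------
    counts : DataFrame
        Rows indexed by gene id, columns by library id; non-negative integers.
    design : DataFrame
        Indexed by library id with columns ``sex`` in {F, M}, ``temperature``
        in {control, cold} and ``replicate``.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        counts, design = self.counts, self.design
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        if counts.columns.duplicated().any():
            dup = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate library ids: {dup[:5]}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if not np.isfinite(values).all():
            raise ValueError("counts contain non-finite values")
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        if np.any(values != np.floor(values)):
            bad = counts.index[np.nonzero((values != np.floor(values)).any(axis=1))[0][0]]
            raise ValueError(f"counts must be integers (gene {bad!r} has fractional counts)")
        self.counts = counts.astype(np.int64)

        missing = counts.columns.difference(design.index)
        if len(missing):
            raise ValueError(f"libraries missing from design: {missing.tolist()}")
        design = design.loc[counts.columns].copy()
        for col in ("sex", "temperature"):
            if col not in design.columns:
                raise ValueError(f"design lacks required column {col!r}")
        design["sex"] = [canonical_sex(v) for v in design["sex"]]
        design["temperature"] = [canonical_temperature(v) for v in design["temperature"]]
        if "replicate" not in design.columns:
            design["replicate"] = np.arange(1, len(design) + 1)
        present = set(zip(design["sex"], design["temperature"]))
        absent = [g for g in GROUPS if g not in present]
        if absent:
            raise ValueError(f"design is missing sex x temperature groups: {absent}")
        design.index.name = "library_id"
        self.counts.index.name = "gene_id"
        self.design = design

    # -- convenience views -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def library_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_libraries(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> pd.Series:
        """Raw per-library total counts."""
        return self.counts.sum(axis=0)

    def group_columns(self, sex: str, temperature: str) -> pd.Index:
        mask = (self.design["sex"] == sex) & (self.design["temperature"] == temperature)
        return self.design.index[mask]

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[gene_ids], self.design.copy())


@dataclass
class NormalizedExpression:
    """TMM-normalized expression: factors, effective sizes, CPM and log2 CPM."""

    tmm_factors: pd.Series
    effective_lib_sizes: pd.Series
    cpm: pd.DataFrame
    log_cpm: pd.DataFrame
    prior_count: float
    design: pd.DataFrame | None = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if (self.tmm_factors <= 0).any():
            raise ValueError("TMM factors must be positive")
        if (self.effective_lib_sizes <= 0).any():
            raise ValueError("effective library sizes must be positive")
        log_gm = np.log(self.tmm_factors.to_numpy()).mean()
        if abs(log_gm) > 1e-8:
            raise ValueError("TMM factors must have geometric mean 1")
        if not np.isfinite(self.log_cpm.to_numpy()).all():
            raise ValueError("log_cpm contains non-finite values")

    def group_mean_log_cpm(self, sex: str, temperature: str) -> pd.Series:
        if self.design is None:
            raise ValueError("no design attached to this NormalizedExpression")
        mask = (self.design["sex"] == sex) & (self.design["temperature"] == temperature)
        cols = self.design.index[mask]
        return self.log_cpm[cols].mean(axis=1)
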