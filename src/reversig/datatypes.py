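"""Core containers for count matrices, sample designs and contrast results.

The containers are thin, validated wrappers around :class:`pandas.DataFrame`
so that every downstream operation can rely on a small set of invariants:
unique identifiers, non-negative finite counts, and known factor levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AGE_LEVELS = ("adult", "aged")
TREATMENT_LEVELS = ("control", "repopulation")
STIMULUS_LEVELS = ("saline", "lps")

FACTOR_LEVELS = {
    "age": AGE_LEVELS,
    "treatment": TREATMENT_LEVELS,
    "stimulus": STIMULUS_LEVELS,
}

#: column order of a contrast result table
CONTRAST_COLUMNS = ("base_mean", "log2fc", "lfc_se", "stat", "pvalue", "padj", "tested")


class ValidationError(ValueError):
    """An input table violates a structural invariant."""


@dataclass
class CountMatrix:
    """Gene x sample expression matrix.

    Parameters
    ----------
    data
        DataFrame indexed by gene identifier with one column per sample.
    scale
        ``"raw"`` for integer sequencing counts, ``"normalized"`` for
        size-factor-scaled values.
    """

    data: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "normalized"):
            raise ValidationError(f"scale must be 'raw' or 'normalized', got {self.scale!r}")
        idx = self.data.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate gene identifier: {dup!r}")
        cols = self.data.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValidationError(f"duplicate sample identifier: {dup!r}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = np.argwhere(~self.data.map(lambda v: isinstance(v, (int, float, np.number))).to_numpy())
            r, c = bad[0] if len(bad) else (0, 0)
            raise ValidationError(
                f"non-numeric cell at gene {idx[r]!r}, sample {cols[c]!r}"
            )
        if not np.all(np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(f"non-finite cell at gene {idx[r]!r}, sample {cols[c]!r}")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative cell at gene {idx[r]!r}, sample {cols[c]!r}: {values[r, c]}"
            )
        if self.scale == "raw" and not np.allclose(values, np.round(values), atol=0):
            r, c = np.argwhere(values != np.round(values))[0]
            raise ValidationError(
                f"raw counts must be integers; gene {idx[r]!r}, sample {cols[c]!r} "
                f"has value {values[r, c]}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class SampleDesign:
    """Sample-to-factor-level map for a factorial design.

    ``table`` is indexed by sample identifier with a column per factor
    (``age``, ``treatment`` and optionally ``stimulus``); ``covariates``
    holds optional numeric per-sample covariates (e.g. externally supplied
    unwanted-variation factors) aligned to the same index.
    """

    table: pd.DataFrame
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        idx = self.table.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate sample identifier in design: {dup!r}")
        for col in ("age", "treatment"):
            if col not in self.table.columns:
                raise ValidationError(f"sample design is missing required column {col!r}")
        for col, levels in FACTOR_LEVELS.items():
            if col in self.table.columns:
                bad = set(self.table[col].dropna()) - set(levels)
                if bad:
                    raise ValidationError(
                        f"unknown {col} level(s) {sorted(bad)}; allowed: {list(levels)}"
                    )
        if self.covariates is not None:
            if not self.covariates.index.equals(idx):
                raise ValidationError("covariates must be indexed like the design table")
            if not all(np.issubdtype(d, np.number) for d in self.covariates.dtypes):
                raise ValidationError("covariates must be numeric")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def factors(self) -> list[str]:
        return [c for c in ("age", "treatment", "stimulus") if c in self.table.columns]

    def group_labels(self) -> pd.Series:
        """Combined factor label per sample, e.g. ``aged_repopulation``."""
        parts = [self.table[f].astype(str) for f in self.factors]
        out = parts[0]
        for p in parts[1:]:
            out = out + "_" + p
        return out.rename("group")

    def with_group_column(self) -> pd.DataFrame:
        t = self.table.copy()
        t["group"] = self.group_labels()
        return t

    def subset(self, sample_ids) -> "SampleDesign":
        cov = None if self.covariates is None else self.covariates.loc[sample_ids]
        return SampleDesign(self.table.loc[sample_ids], cov)


@dataclass
class DdctTable:
    """Per-sample qPCR cycle-threshold values for target and reference genes."""

    table: pd.DataFrame  # columns: sample_id, group, ct_target, ct_reference

    def __post_init__(self) -> None:
        for col in ("sample_id", "group", "ct_target", "ct_reference"):
            if col not in self.table.columns:
                raise ValidationError(f"ddCT table is missing column {col!r}")
        for col in ("ct_target", "ct_reference"):
            vals = pd.to_numeric(self.table[col], errors="coerce")
            if not np.all(np.isfinite(vals.to_numpy(dtype=float))):
                raise ValidationError(f"non-finite value in column {col!r}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table["sample_id"][self.table["sample_id"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate sample identifier in ddCT table: {dup!r}")


@dataclass
class ContrastSpec:
    """One two-level comparison, optionally within fixed levels of other factors.

    ``factor`` may be any design column, including the derived ``group``
    column, so cross-factor comparisons such as aged-repopulation vs
    adult-control are expressible.
    """

    factor: str
    numerator: str
    denominator: str
    stratum: dict = field(default_factory=dict)
    covariates: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ValidationError("contrast numerator and denominator must differ")

    @property
    def name(self) -> str:
        strat = ",".join(f"{k}={v}" for k, v in sorted(self.stratum.items()))
        base = f"{self.factor}:{self.numerator}_vs_{self.denominator}"
        return f"{base}[{strat}]" if strat else base


def empty_contrast_result(gene_ids) -> pd.DataFrame:
    """All-untested contrast result skeleton."""
    df = pd.DataFrame(
        {
            "base_mean": 0.0,
            "log2fc": np.nan,
            "lfc_se": np.nan,
            "stat": np.nan,
            "pvalue": np.nan,
            "padj": np.nan,
            "tested": False,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return df
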