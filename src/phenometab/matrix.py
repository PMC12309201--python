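"""Core in-memory containers shared across the metabolomics modules.

The interchange representation is a wide samples x features intensity table
(:class:`IntensityMatrix`) carrying its sample metadata, plus a
:class:`PreprocessReport` that records, step by step, which features each
filtering stage removed and why. Phenotype time series travel as plain tidy
:class:`pandas.DataFrame` objects (plant, genotype, treatment, day, trait,
value) and need no wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: metadata columns every sample must carry
REQUIRED_META = ("genotype", "treatment", "timepoint", "replicate", "is_blank")


class SchemaError(ValueError):
    """Raised when an input table violates the expected schema."""


@dataclass
class IntensityMatrix:
    """Samples x metabolite-features intensity matrix with sample metadata.

    Parameters
    ----------
    values
        Wide table, index = sample IDs, columns = feature IDs. Entries are
        non-negative peak intensities; ``NaN`` marks a missing (unquantified)
        feature. Zeros are treated as missing by the preprocessing chain.
    meta
        Sample metadata indexed identically to ``values``. Must contain
        ``genotype, treatment, timepoint, replicate, is_blank``; may carry
        ``fresh_weight``, ``is_response`` (internal-standard response) and
        ``batch`` for raw normalization.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.meta.index):
            # allow meta given in any order as long as the sets match
            if set(self.values.index) != set(self.meta.index):
                raise SchemaError("values and meta must cover the same samples")
            self.meta = self.meta.loc[self.values.index]
        missing = [c for c in REQUIRED_META if c not in self.meta.columns]
        if missing:
            raise SchemaError(f"sample metadata lacks required columns: {missing}")
        if self.values.columns.duplicated().any():
            raise SchemaError("feature IDs must be unique")

    def check_nonnegative(self) -> "IntensityMatrix":
        """Raw intensities must be non-negative (call at ingestion; the
        container is reused for log/Pareto matrices, which may be negative)."""
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy(dtype=float) < 0).any():
                raise SchemaError("negative intensities are not allowed")
        return self

    # -- convenient views -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def blanks(self) -> "IntensityMatrix":
        mask = self.meta["is_blank"].astype(bool)
        return IntensityMatrix(self.values.loc[mask], self.meta.loc[mask])

    def biological(self) -> "IntensityMatrix":
        """Non-blank (leaf) samples."""
        mask = ~self.meta["is_blank"].astype(bool)
        return IntensityMatrix(self.values.loc[mask], self.meta.loc[mask])

    def at_timepoint(self, timepoint) -> "IntensityMatrix":
        mask = self.meta["timepoint"] == timepoint
        return IntensityMatrix(self.values.loc[mask], self.meta.loc[mask])

    def subset_features(self, keep) -> "IntensityMatrix":
        return IntensityMatrix(self.values[list(keep)], self.meta)

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.values.copy(), self.meta.copy())

    # -- IO ----------------------------------------------------------------
    def to_long(self) -> pd.DataFrame:
        """Tidy long representation (sample, feature, intensity + metadata)."""
        long = (
            self.values.rename_axis("sample")
            .reset_index()
            .melt(id_vars="sample", var_name="feature", value_name="intensity")
        )
        return long.merge(
            self.meta.rename_axis("sample").reset_index(), on="sample", how="left"
        )

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "IntensityMatrix":
        need = {"sample", "feature", "intensity"}
        missing = need - set(long.columns)
        if missing:
            raise SchemaError(f"long table lacks columns: {sorted(missing)}")
        values = long.pivot_table(
            index="sample", columns="feature", values="intensity", aggfunc="first",
            dropna=False,
        )
        meta_cols = [c for c in long.columns if c not in ("feature", "intensity")]
        meta = long[meta_cols].drop_duplicates("sample").set_index("sample")
        return cls(values, meta.loc[values.index])


@dataclass
class ReportStep:
    step: str
    n_in: int
    n_removed: int
    n_out: int
    removed: list = field(default_factory=list)
    params: dict = field(default_factory=dict)


@dataclass
class PreprocessReport:
    """Step-by-step record of feature removals; counts must telescope."""

    steps: list[ReportStep] = field(default_factory=list)

    def add(self, step: str, n_in: int, removed, params: dict | None = None) -> None:
        removed = list(removed)
        entry = ReportStep(
            step=step,
            n_in=n_in,
            n_removed=len(removed),
            n_out=n_in - len(removed),
            removed=removed,
            params=dict(params or {}),
        )
        if self.steps and self.steps[-1].n_out != n_in:
            raise ValueError(
                f"report does not telescope: previous n_out={self.steps[-1].n_out}, "
                f"step '{step}' n_in={n_in}"
            )
        self.steps.append(entry)

    def validate(self) -> None:
        for prev, cur in zip(self.steps, self.steps[1:]):
            if prev.n_out != cur.n_in:
                raise ValueError(f"telescoping violated between {prev.step} and {cur.step}")
        for s in self.steps:
            if s.n_in - s.n_removed != s.n_out:
                raise ValueError(f"step {s.step}: n_in - n_removed != n_out")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": s.step,
                    "n_in": s.n_in,
                    "n_removed": s.n_removed,
                    "n_out": s.n_out,
                    "removed": ";".join(map(str, s.removed)),
                }
                for s in self.steps
            ]
        )
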