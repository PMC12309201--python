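"""Table reading/writing with schema validation, and run configuration."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .matrix import SchemaError

PHENO_SCHEMA = ("plant", "genotype", "treatment", "day", "trait", "value")
METAB_LONG_SCHEMA = ("sample", "feature", "intensity", "genotype",
                     "treatment", "timepoint", "replicate", "is_blank")
POST_HARVEST_SCHEMA = ("plant", "genotype", "treatment")


def read_long_table(path, schema: tuple[str, ...]) -> pd.DataFrame:
    """Read a CSV/TSV with header and validate required columns.

    The delimiter is inferred from the extension (.tsv/.txt -> tab). Raises
    :class:`SchemaError` naming missing columns or an empty file.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    try:
        df = pd.read_csv(path, sep=sep, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    if df.empty:
        raise SchemaError(f"{path}: table has no rows")
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df.to_csv(path, sep=sep, index=index)


@dataclass
class PipelineConfig:
    """Every stage's parameters, with study defaults; unknown keys rejected."""

    # inputs (optional: the pipeline simulates when absent)
    metabolite_table: str | None = None
    phenotype_table: str | None = None
    post_harvest_table: str | None = None
    pathway_map: str | None = None
    # synthetic generator
    simulate: dict = field(default_factory=dict)
    # QC
    conf_int_size: float = 5.0
    nn_span: float = 0.5
    qc_rounds: int = 2
    sd_k: float = 2.0
    drop_fraction: float = 0.20
    last_qc_day: int = 22
    # preprocessing
    presence_min_frac: float = 0.8
    impute_frac: float = 0.2
    rsd_top_frac: float = 0.25
    blank_fold: float = 2.0
    # DAM
    alpha: float = 0.05
    fc_cut: float = 1.0
    # biomarker
    p_cut: float = 0.001
    fold_size: int = 3
    ncomp_max: int = 5
    inner_folds: int = 4
    target_trait: str = "GrainWeight"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "p_cut"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if not (0 <= self.presence_min_frac <= 1):
            raise ValueError("presence_min_frac must lie in [0, 1]")
        if self.qc_rounds < 1:
            raise ValueError("qc_rounds must be >= 1")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") \
                else json.load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
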