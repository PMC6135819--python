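"""Nucleus-level feature vectors: the nuclear signature augmented with
aggregated nucleolar statistics.

Each nucleus contributes a fixed-length 31-feature vector regardless of how
many nucleoli it contains: its own 6 morphometry measures, the nucleolus
count, and Avg/Min/Max/Var sample statistics of each of the 6 measures over
its nucleoli (nuclei without internal nucleoli are excluded upstream, so
the nucleolar list is never empty).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .morphometry import MorphometrySignature

MEASURE_NAMES = (
    "Volume", "SurfaceArea", "MeanCurvature", "ShapeIndex", "Curvedness",
    "FractalDimension",
)
AGGREGATE_PREFIXES = ("Avg", "Min", "Max", "Var")

#: stable feature column order: 6 nuclear + count + 24 nucleolar aggregates
FEATURE_COLUMNS = (
    list(MEASURE_NAMES)
    + ["NucleolusCount"]
    + [f"{p}{m}" for m in MEASURE_NAMES for p in AGGREGATE_PREFIXES]
)
PROVENANCE_COLUMNS = ["image_id", "condition"]
N_FEATURES = len(FEATURE_COLUMNS)  # 31


@dataclass(frozen=True)
class NucleusRecord:
    """One nucleus' classification feature vector plus provenance."""

    nucleus: MorphometrySignature
    nucleolus_count: int
    aggregates: dict[str, float]  # {"AvgVolume": ..., ...}, 24 entries

    def __post_init__(self) -> None:
        if self.nucleolus_count < 1:
            raise ValueError("nucleolus_count must be >= 1")
        expected = {f"{p}{m}" for m in MEASURE_NAMES for p in AGGREGATE_PREFIXES}
        if set(self.aggregates) != expected:
            raise ValueError("aggregates must contain exactly the 24 Avg/Min/Max/Var keys")

    @property
    def image_id(self) -> str:
        return self.nucleus.image_id

    @property
    def condition(self) -> str:
        return self.nucleus.condition

    def as_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = dict(zip(MEASURE_NAMES, self.nucleus.as_array()))
        row["NucleolusCount"] = float(self.nucleolus_count)
        row.update(self.aggregates)
        row["image_id"] = self.image_id
        row["condition"] = self.condition
        return row


def aggregate_features(
    nucleus_sig: MorphometrySignature,
    nucleolar_sigs: Sequence[MorphometrySignature],
) -> NucleusRecord:
    """Merge nucleolar signatures into the parent nucleus' feature vector.

    Avg/Min/Max are the obvious sample statistics; Var is the unbiased
    sample variance (ddof=1), defined as 0 for a single nucleolus.  The
    result is permutation-invariant in the nucleolar list.
    """
    if len(nucleolar_sigs) < 1:
        raise ValueError("aggregate_features requires at least one nucleolus "
                         "(nuclei without nucleoli must be excluded upstream)")
    values = np.stack([s.as_array() for s in nucleolar_sigs])  # (n, 6)
    n = len(nucleolar_sigs)
    aggs: dict[str, float] = {}
    for j, name in enumerate(MEASURE_NAMES):
        col = np.sort(values[:, j])  # exact permutation invariance of the sums
        # clip the mean into [min, max] so the ordering invariant holds exactly
        # even under float round-off
        aggs[f"Avg{name}"] = float(np.clip(col.mean(), col[0], col[-1]))
        aggs[f"Min{name}"] = float(col.min())
        aggs[f"Max{name}"] = float(col.max())
        aggs[f"Var{name}"] = float(col.var(ddof=1)) if n > 1 else 0.0
    return NucleusRecord(nucleus=nucleus_sig, nucleolus_count=n, aggregates=aggs)


def build_feature_table(records: Sequence[NucleusRecord]) -> pd.DataFrame:
    """One row per nucleus with the 31 feature columns in stable order plus
    image_id / condition provenance; no missing values."""
    columns = FEATURE_COLUMNS + PROVENANCE_COLUMNS
    if not records:
        return pd.DataFrame(columns=columns)
    ids = [(r.image_id, r.nucleus.object_id) for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated (image_id, object_id) among nucleus records")
    df = pd.DataFrame([r.as_row() for r in records], columns=columns)
    if df[FEATURE_COLUMNS].isna().any().any():
        raise ValueError("feature table contains missing values")
    return df


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"image_id": str, "condition": str})
    missing = set(FEATURE_COLUMNS + PROVENANCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature table {path} missing columns: {sorted(missing)}")
    return df
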