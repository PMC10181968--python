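"""Cohort tables: per-subject clinical covariates, QCT metrics and outcome.

The on-disk form is a plain CSV with a documented header. Unknown smoking
status / family history are explicit ``"unknown"`` categories, never
silently imputed; model-fitting code decides how to handle them.
"""

from __future__ import annotations

import dataclasses
import os

import numpy as np
import pandas as pd

__all__ = [
    "CohortTable",
    "REQUIRED_COLUMNS",
    "QCT_COLUMNS",
    "read_cohort_table",
    "write_cohort_table",
]

QCT_COLUMNS = (
    "mld_hu",
    "ei_pct",
    "pei_pct",
    "ei_cc120_pct",
    "perc15_hu",
    "bi_pct",
    "ggoi_pct",
    "fibi_pct",
    "lung_volume_ml",
    "wp_pct",
    "awt_pi10_cm",
)

REQUIRED_COLUMNS = (
    "subject_id",
    "age_years",
    "sex",
    "smoking_status",
    "family_lung_cancer",
    "prior_extrathoracic_cancer",
    "diameter_mm",
    "spiculation",
    "upper_lobe",
    "nodule_type",
    "nodule_count",
    "emphysema_on_ct",
    *QCT_COLUMNS,
    "malignant",
)

_CATEGORICAL_LEVELS = {
    "sex": {"female", "male"},
    "smoking_status": {"current", "former", "never", "unknown"},
    "family_lung_cancer": {"yes", "no", "unknown"},
    "nodule_type": {"solid", "part_solid", "ggo"},
}


@dataclasses.dataclass
class CohortTable:
    """Validated cohort DataFrame plus provenance."""

    data: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table missing required columns: {missing}")
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise ValueError(f"duplicate subject_id: {dup!r}")
        out = df["malignant"]
        if not np.isin(out.to_numpy(), [0, 1]).all():
            raise ValueError("outcome 'malignant' must be coded 0 (benign) / 1 (malignant)")
        for col, levels in _CATEGORICAL_LEVELS.items():
            bad = set(df[col].astype(str)) - levels
            if bad:
                raise ValueError(f"column {col!r} has undeclared levels {sorted(bad)}")
        if (df["age_years"] <= 0).any():
            raise ValueError("age_years must be positive")
        if (df["diameter_mm"] <= 0).any():
            raise ValueError("diameter_mm must be positive")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_malignant(self) -> int:
        return int(self.data["malignant"].sum())

    @property
    def n_benign(self) -> int:
        return len(self) - self.n_malignant

    def with_derived(self) -> pd.DataFrame:
        """Copy of the table with derived model covariates.

        ``ever_smoker`` is 1 for current/former, 0 for never, missing (NA)
        for unknown; ``sex_female`` is the 0/1 indicator used by the risk
        models.
        """
        df = self.data.copy()
        status = df["smoking_status"].astype(str)
        df["ever_smoker"] = np.select(
            [status.isin(["current", "former"]), status == "never"],
            [1.0, 0.0],
            default=np.nan,
        )
        df["sex_female"] = (df["sex"].astype(str) == "female").astype(int)
        return df


def read_cohort_table(path: str | os.PathLike) -> CohortTable:
    if not os.path.exists(path):
        raise FileNotFoundError(f"cohort file not found: {path}")
    df = pd.read_csv(path)
    return CohortTable(data=df, provenance=str(path))


def write_cohort_table(table: CohortTable, path: str | os.PathLike) -> None:
    table.data.to_csv(path, index=False)
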