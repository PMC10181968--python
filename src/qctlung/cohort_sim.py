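"""Simulated benign/malignant nodule cohorts with known ground truth.

The simulator emulates the summary structure of a chest-hospital nodule
cohort: two outcome groups whose whole-lung QCT metric distributions are
parameterized by (median, IQR) per metric — normal families for MLD,
Perc15, lung volume, WP and AWT-Pi10; log-normal for the non-negative,
right-skewed emphysema/GGO/fibrosis indices; logit-normal for pEI (a
percentage of emphysema, bounded at 100). Default parameters are calibrated
to the published group medians/IQRs of a 251-subject cohort (200 benign /
51 malignant).

Two outcome mechanisms:

* group-conditional (default): group sizes fixed, covariates drawn from the
  group-specific distributions — reproduces the descriptive-table structure;
* logistic: covariates drawn from the benign (base) distributions for all
  subjects and the malignancy outcome drawn from a user-specified logistic
  model — gives known true coefficients for estimator calibration studies.

All draws come from a single seeded generator in fixed column order, so a
given ``(spec, seed)`` pair is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import CohortTable, QCT_COLUMNS

__all__ = [
    "MetricModel",
    "CohortSpec",
    "simulate_cohort",
    "TABLE_LIKE_BENIGN",
    "TABLE_LIKE_MALIGNANT",
]

_IQR_Z = 1.3489795003921634  # Phi^-1(0.75) - Phi^-1(0.25)


@dataclasses.dataclass(frozen=True)
class MetricModel:
    """One metric's sampling family parameterized by median and IQR."""

    family: str  # "normal" | "lognormal" | "logitnormal"
    median: float
    iqr: tuple[float, float]

    def __post_init__(self) -> None:
        if self.family not in ("normal", "lognormal", "logitnormal"):
            raise ValueError(f"unknown family {self.family!r}")
        lo, hi = self.iqr
        if hi <= lo:
            raise ValueError("IQR upper bound must exceed lower bound")

    def _mu_sigma(self) -> tuple[float, float]:
        lo, hi = self.iqr
        if self.family == "normal":
            return self.median, (hi - lo) / _IQR_Z
        if self.family == "lognormal":
            if self.median <= 0 or hi <= 0:
                raise ValueError("lognormal needs positive median and upper quartile")
            mu = math.log(self.median)
            if lo > 0:
                sigma = (math.log(hi) - math.log(lo)) / _IQR_Z
            else:
                # lower quartile printed as 0: scale from the upper half only
                sigma = (math.log(hi) - mu) / (_IQR_Z / 2)
            return mu, sigma
        # logitnormal on percent scale
        mu = logit(self.median / 100.0)
        sigma = (logit(hi / 100.0) - logit(lo / 100.0)) / _IQR_Z
        return mu, sigma

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        mu, sigma = self._mu_sigma()
        if sigma <= 0:
            raise ValueError("non-positive scale parameter")
        z = rng.normal(mu, sigma, size=n)
        if self.family == "normal":
            return z
        if self.family == "lognormal":
            return np.exp(z)
        return 100.0 * expit(z)


# Calibration: group medians [IQR] of the whole-lung QCT panel in a
# 200-benign / 51-malignant incidental-nodule cohort.
TABLE_LIKE_BENIGN: dict[str, MetricModel] = {
    "mld_hu": MetricModel("normal", -766, (-796, -729)),
    "ei_pct": MetricModel("lognormal", 0.7, (0.2, 2.9)),
    "pei_pct": MetricModel("logitnormal", 40.1, (32.6, 51.8)),
    "ei_cc120_pct": MetricModel("lognormal", 0.03, (0.0, 0.36)),
    "perc15_hu": MetricModel("normal", -907, (-923, -885)),
    "bi_pct": MetricModel("lognormal", 0.20, (0.05, 1.15)),
    "ggoi_pct": MetricModel("lognormal", 12.5, (7.4, 19.6)),
    "fibi_pct": MetricModel("lognormal", 15.9, (13.4, 23.0)),
    "lung_volume_ml": MetricModel("normal", 5443, (4678, 6654)),
    "wp_pct": MetricModel("normal", 46.4, (42.9, 51.6)),
    "awt_pi10_cm": MetricModel("normal", 0.22, (0.17, 0.26)),
}

TABLE_LIKE_MALIGNANT: dict[str, MetricModel] = {
    "mld_hu": MetricModel("normal", -789, (-802, -755)),
    "ei_pct": MetricModel("lognormal", 1.5, (0.4, 4.5)),
    "pei_pct": MetricModel("logitnormal", 44.6, (38.5, 53.9)),
    "ei_cc120_pct": MetricModel("lognormal", 0.19, (0.01, 1.33)),
    "perc15_hu": MetricModel("normal", -915, (-930, -898)),
    "bi_pct": MetricModel("lognormal", 0.63, (0.09, 2.38)),
    "ggoi_pct": MetricModel("lognormal", 8.8, (6.2, 17.6)),
    "fibi_pct": MetricModel("lognormal", 13.9, (12.7, 17.3)),
    "lung_volume_ml": MetricModel("normal", 6233, (4962, 7460)),
    "wp_pct": MetricModel("normal", 46.2, (42.0, 49.4)),
    "awt_pi10_cm": MetricModel("normal", 0.21, (0.16, 0.25)),
}

# Clinical covariate frequencies per group (benign, malignant)
_CLINICAL = {
    "age": {"benign": (64.0, 13.3), "malignant": (67.0, 11.1)},  # (median, sd)
    "female": {"benign": 0.355, "malignant": 0.412},
    "smoking": {
        "levels": ("current", "former", "never", "unknown"),
        "benign": (0.110, 0.495, 0.150, 0.245),
        "malignant": (0.137, 0.569, 0.176, 0.118),
    },
    "family": {
        "levels": ("yes", "no", "unknown"),
        "benign": (0.120, 0.755, 0.125),
        "malignant": (0.039, 0.863, 0.098),
    },
    # prior extrathoracic malignancy is not tabulated in the source cohort;
    # plausible rates chosen once (methods note)
    "prior_cancer": {"benign": 0.10, "malignant": 0.30},
    "diameter": {"benign": (7.3, 0.40), "malignant": (13.0, 0.65)},  # (median, log-sd)
    "spiculation": {"benign": 0.225, "malignant": 0.667},
    "upper_lobe": {"benign": 0.375, "malignant": 0.392},
    "nodule_type": {
        "levels": ("solid", "part_solid", "ggo"),
        "benign": (0.895, 0.075, 0.030),
        "malignant": (0.843, 0.137, 0.020),
    },
    "emphysema_on_ct": {"benign": 0.22, "malignant": 0.353},
}


@dataclasses.dataclass
class CohortSpec:
    """Simulation recipe for a two-group nodule cohort.

    ``true_coefficients`` switches the outcome mechanism: when given (map of
    covariate column -> coefficient, plus ``intercept``), covariates are
    drawn from the benign/base distributions for ``n_benign + n_malignant``
    subjects and malignancy follows the logistic model; otherwise group
    sizes are fixed and covariates drawn per group.
    """

    n_benign: int = 200
    n_malignant: int = 51
    metrics_benign: Mapping[str, MetricModel] = dataclasses.field(
        default_factory=lambda: dict(TABLE_LIKE_BENIGN)
    )
    metrics_malignant: Mapping[str, MetricModel] = dataclasses.field(
        default_factory=lambda: dict(TABLE_LIKE_MALIGNANT)
    )
    true_coefficients: Mapping[str, float] | None = None
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.n_benign < 1 or self.n_malignant < 1:
            raise ValueError("group sizes must be >= 1")
        for grp in (self.metrics_benign, self.metrics_malignant):
            for name, model in grp.items():
                if name not in QCT_COLUMNS:
                    raise ValueError(f"unknown QCT metric {name!r}")
                model._mu_sigma()  # validates scale


def _draw_group(
    rng: np.random.Generator,
    n: int,
    group: str,
    metrics: Mapping[str, MetricModel],
) -> pd.DataFrame:
    c = _CLINICAL
    med, sd = c["age"][group]
    cols: dict[str, np.ndarray] = {}
    cols["age_years"] = np.clip(np.rint(rng.normal(med, sd, n)), 30, 95).astype(int)
    cols["sex"] = np.where(rng.random(n) < c["female"][group], "female", "male")
    cols["smoking_status"] = rng.choice(
        c["smoking"]["levels"], size=n, p=c["smoking"][group]
    )
    cols["family_lung_cancer"] = rng.choice(
        c["family"]["levels"], size=n, p=c["family"][group]
    )
    cols["prior_extrathoracic_cancer"] = (
        rng.random(n) < c["prior_cancer"][group]
    ).astype(int)
    dmed, dsig = c["diameter"][group]
    cols["diameter_mm"] = np.maximum(
        np.round(np.exp(rng.normal(math.log(dmed), dsig, n)), 1), 3.0
    )
    cols["spiculation"] = (rng.random(n) < c["spiculation"][group]).astype(int)
    cols["upper_lobe"] = (rng.random(n) < c["upper_lobe"][group]).astype(int)
    cols["nodule_type"] = rng.choice(
        c["nodule_type"]["levels"], size=n, p=c["nodule_type"][group]
    )
    cols["nodule_count"] = 1 + rng.poisson(0.3, n)
    cols["emphysema_on_ct"] = (rng.random(n) < c["emphysema_on_ct"][group]).astype(int)
    for name in QCT_COLUMNS:
        if name in metrics:
            cols[name] = metrics[name].sample(rng, n)
        else:
            cols[name] = np.full(n, np.nan)
    return pd.DataFrame(cols)


def simulate_cohort(
    spec: CohortSpec, seed: int | None = None
) -> tuple[CohortTable, dict]:
    """Simulate a cohort; returns the table and the generating truth record."""
    rng = np.random.default_rng(seed)
    if spec.true_coefficients is None:
        ben = _draw_group(rng, spec.n_benign, "benign", spec.metrics_benign)
        mal = _draw_group(rng, spec.n_malignant, "malignant", spec.metrics_malignant)
        ben["malignant"] = 0
        mal["malignant"] = 1
        df = pd.concat([ben, mal], ignore_index=True)
        truth = {"mechanism": "group-conditional", "seed": seed}
    else:
        n = spec.n_benign + spec.n_malignant
        df = _draw_group(rng, n, "benign", spec.metrics_benign)
        lp = np.full(n, float(spec.intercept))
        for name, beta in spec.true_coefficients.items():
            if name not in df.columns:
                raise ValueError(f"unknown covariate {name!r} in true_coefficients")
            x = pd.to_numeric(df[name], errors="raise").to_numpy(dtype=float)
            lp += beta * x
        p = expit(lp)
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("event probability outside (0,1)")
        df["malignant"] = (rng.random(n) < p).astype(int)
        truth = {
            "mechanism": "logistic",
            "intercept": float(spec.intercept),
            "coefficients": dict(spec.true_coefficients),
            "seed": seed,
        }
    df.insert(0, "subject_id", [f"S{i:05d}" for i in range(len(df))])
    return CohortTable(data=df, provenance=f"simulated(seed={seed})"), truth
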