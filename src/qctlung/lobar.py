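"""Lobe-specific analysis: nodule-bearing lobe vs the rest of the lung.

The "rest of the lung" is the pool of the non-bearing lobes, with every
intensive metric weighted by the lobes' voxel counts (equivalently, their
relative share of total lung volume); volumes are summed. Percentiles are
not linear, so Perc15 is recomputed from pooled voxel values when they are
supplied and otherwise approximated by the volume-weighted mean of lobe
values and flagged as such.

Cohort-level comparisons of bearing lobe vs rest use the Wilcoxon
signed-rank test on per-subject differences (zero differences dropped;
exact distribution for small samples, normal approximation with tie
correction otherwise).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .parenchyma import QCTProfile

__all__ = [
    "LobarComparison",
    "LobarTestResult",
    "combine_profiles",
    "rest_of_lung_profile",
    "lobar_comparison",
    "paired_lobar_test",
]

# metrics pooled by voxel-count weighting; pEI is weighted by each lobe's
# emphysema voxel count instead (it is a percentage *of emphysema*)
_VOXEL_WEIGHTED = (
    "mld_hu",
    "ei_pct",
    "ei_cc120_pct",
    "bi_pct",
    "ggoi_pct",
    "fibi_pct",
)


@dataclasses.dataclass
class LobarComparison:
    subject_id: str
    bearing_lobe: int
    bearing: QCTProfile
    rest: QCTProfile
    volume_shares: dict[int, float]

    def __post_init__(self) -> None:
        if self.bearing_lobe not in (1, 2, 3, 4, 5):
            raise ValueError("bearing lobe must be one of 1..5")
        total = sum(self.volume_shares.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"lobe volume shares sum to {total}, expected 1")


@dataclasses.dataclass
class LobarTestResult:
    metric: str
    median_bearing: float
    median_rest: float
    statistic: float
    p_value: float
    n_pairs: int
    n_nonzero: int
    all_zero: bool = False


def combine_profiles(
    profiles: Sequence[QCTProfile],
    *,
    region_id: str,
    hu_values: Sequence[np.ndarray] | None = None,
) -> QCTProfile:
    """Pool several disjoint regions into one profile by voxel weighting."""
    if not profiles:
        raise ValueError("no profiles to combine")
    w = np.array([p.voxel_count for p in profiles], dtype=float)
    pooled: dict[str, float | None] = {}
    for name in _VOXEL_WEIGHTED:
        vals = np.array([getattr(p, name) for p in profiles], dtype=float)
        pooled[name] = float(np.average(vals, weights=w))
    # pEI: weight by emphysema voxel count; missing when no lobe has emphysema
    emph_w = np.array([p.ei_pct * p.voxel_count / 100.0 for p in profiles])
    pei_vals = [p.pei_pct for p in profiles]
    if emph_w.sum() > 0 and any(v is not None for v in pei_vals):
        num = sum(v * ew for v, ew in zip(pei_vals, emph_w) if v is not None)
        pooled["pei_pct"] = float(num / emph_w.sum())
    else:
        pooled["pei_pct"] = None
    # WP: volume-weighted over lobes that carry it
    wp = [(p.wp_pct, wi) for p, wi in zip(profiles, w) if p.wp_pct is not None]
    pooled["wp_pct"] = (
        float(sum(v * wi for v, wi in wp) / sum(wi for _, wi in wp)) if wp else None
    )
    flags: list[str] = []
    if hu_values is not None:
        allv = np.concatenate([np.asarray(v, dtype=float).ravel() for v in hu_values])
        if allv.size != int(w.sum()):
            raise ValueError("pooled HU values do not match pooled voxel count")
        perc15 = float(np.percentile(allv, 15, method="linear"))
    else:
        perc15 = float(
            np.average(np.array([p.perc15_hu for p in profiles]), weights=w)
        )
        flags.append("perc15_volume_weighted_approximation")
    return QCTProfile(
        region_id=region_id,
        voxel_count=int(w.sum()),
        volume_ml=float(sum(p.volume_ml for p in profiles)),
        mld_hu=pooled["mld_hu"],
        ei_pct=pooled["ei_pct"],
        pei_pct=pooled["pei_pct"],
        ei_cc120_pct=pooled["ei_cc120_pct"],
        perc15_hu=perc15,
        bi_pct=pooled["bi_pct"],
        ggoi_pct=pooled["ggoi_pct"],
        fibi_pct=pooled["fibi_pct"],
        wp_pct=pooled["wp_pct"],
        flags=tuple(flags),
    )


def rest_of_lung_profile(
    lobe_profiles: Mapping[int, QCTProfile],
    bearing_lobe: int,
    *,
    hu_values: Mapping[int, np.ndarray] | None = None,
) -> QCTProfile:
    """Pool all non-bearing lobes into a single rest-of-lung profile."""
    if bearing_lobe not in lobe_profiles:
        raise ValueError(f"bearing lobe {bearing_lobe} not among profiles")
    rest_ids = [k for k in sorted(lobe_profiles) if k != bearing_lobe]
    if not rest_ids:
        raise ValueError("single-lobe subject: rest of lung undefined")
    vals = [hu_values[k] for k in rest_ids] if hu_values is not None else None
    return combine_profiles(
        [lobe_profiles[k] for k in rest_ids],
        region_id="rest_of_lung",
        hu_values=vals,
    )


def lobar_comparison(
    subject_id: str,
    lobe_profiles: Mapping[int, QCTProfile],
    bearing_lobe: int,
    *,
    hu_values: Mapping[int, np.ndarray] | None = None,
) -> LobarComparison:
    total = sum(p.volume_ml for p in lobe_profiles.values())
    shares = {k: p.volume_ml / total for k, p in lobe_profiles.items()}
    return LobarComparison(
        subject_id=subject_id,
        bearing_lobe=bearing_lobe,
        bearing=lobe_profiles[bearing_lobe],
        rest=rest_of_lung_profile(lobe_profiles, bearing_lobe, hu_values=hu_values),
        volume_shares=shares,
    )


def paired_lobar_test(
    comparisons: Sequence[LobarComparison] | None = None,
    metric: str = "ei_pct",
    *,
    bearing_values: Sequence[float] | None = None,
    rest_values: Sequence[float] | None = None,
    exact_max_n: int = 25,
) -> LobarTestResult:
    """Two-sided Wilcoxon signed-rank test of bearing lobe vs rest of lung.

    Accepts either a cohort of :class:`LobarComparison` (values read off the
    requested ``metric``) or raw paired value arrays. Pairs where either
    value is missing are excluded; zero differences are dropped (classical
    Wilcoxon); with every difference zero the p-value is reported as 1 with
    a flag.
    """
    if comparisons is not None:
        pairs = [
            (getattr(c.bearing, metric), getattr(c.rest, metric)) for c in comparisons
        ]
        pairs = [(b, r) for b, r in pairs if b is not None and r is not None]
        b = np.array([p[0] for p in pairs], dtype=float)
        r = np.array([p[1] for p in pairs], dtype=float)
    else:
        if bearing_values is None or rest_values is None:
            raise ValueError("provide comparisons or both value arrays")
        b = np.asarray(bearing_values, dtype=float)
        r = np.asarray(rest_values, dtype=float)
        keep = ~(np.isnan(b) | np.isnan(r))
        b, r = b[keep], r[keep]
    if b.size == 0:
        raise ValueError("no usable pairs")
    d = b - r
    nz = d[d != 0]
    if nz.size == 0:
        return LobarTestResult(
            metric=metric,
            median_bearing=float(np.median(b)),
            median_rest=float(np.median(r)),
            statistic=0.0,
            p_value=1.0,
            n_pairs=int(b.size),
            n_nonzero=0,
            all_zero=True,
        )
    ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= exact_max_n and not ties) else "approx"
    res = stats.wilcoxon(
        nz, alternative="two-sided", zero_method="wilcox", method=method
    )
    ranks = stats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    return LobarTestResult(
        metric=metric,
        median_bearing=float(np.median(b)),
        median_rest=float(np.median(r)),
        statistic=w_plus,
        p_value=float(res.pvalue),
        n_pairs=int(b.size),
        n_nonzero=int(nz.size),
    )
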