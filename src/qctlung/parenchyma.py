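"""Parenchymal densitometry of the segmented lung.

Implements the standard whole-lung / per-lobe density panel used in
quantitative CT of COPD and interstitial lung disease:

* MLD — mean lung density (HU)
* EI (LAA-950) — percent of lung voxels below -950 HU
* pEI — percent of all emphysema voxels lying in the peripheral 50% zone
* EI_CC120 — percent of lung volume in emphysema clusters > 120 mm^3
* Perc15 — 15th percentile of the lung HU histogram
* BI — bulla index: emphysema in very large (> 1000 mm^3) clusters after a
  one-voxel morphological closing, as percent of lung volume
* GGOI — ground-glass opacity index, voxels in [-800, -700) HU
* FIBI — fibrosis index, voxels >= -700 HU
* lung volume (mL)

plus the 50/50 central–peripheral partition of the lung by Euclidean
distance to the lung boundary, and region profiles for the whole lung or
single lobes.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .volumes import CTVolume, LabelVolume, LOBE_LABELS

__all__ = [
    "QCTThresholds",
    "DEFAULT_THRESHOLDS",
    "ZonePartition",
    "QCTProfile",
    "ClusterTable",
    "segment_lungs",
    "partition_zones",
    "density_metrics",
    "cluster_metrics",
    "peripheral_emphysema_index",
    "region_profile",
    "EmptyRegionError",
]

# 26-connectivity in 3-D
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


class EmptyRegionError(ValueError):
    """Raised when a metric is requested on an empty voxel set."""


@dataclasses.dataclass(frozen=True)
class QCTThresholds:
    """HU and cluster-size thresholds of the density panel.

    Defaults follow the conventional LAA-950 densitometry cut-offs:
    emphysema below -950 HU, ground-glass in [-800, -700) HU, fibrosis at
    and above -700 HU, a 120 mm^3 cluster class boundary and a 1000 mm^3
    bulla surrogate threshold.
    """

    emphysema_hu: float = -950.0
    ggo_low_hu: float = -800.0
    ggo_high_hu: float = -700.0
    cluster_mm3: float = 120.0
    bulla_mm3: float = 1000.0
    lung_air_hu: float = -400.0


DEFAULT_THRESHOLDS = QCTThresholds()


@dataclasses.dataclass
class ZonePartition:
    """Central/peripheral split of the lung mask.

    ``zones`` holds 0 outside the lung, 1 central, 2 peripheral. Within each
    connected lung component the cut-off is the median Euclidean
    distance-to-boundary (mm); voxels at or below the cut-off are peripheral,
    so the peripheral share is at least 50% (ties go peripheral).
    """

    zones: np.ndarray
    cutoff_mm: dict[int, float]
    n_central: int
    n_peripheral: int
    n_tied: int = 0  # voxels exactly at their component's cut-off

    @property
    def peripheral_fraction(self) -> float:
        total = self.n_central + self.n_peripheral
        return self.n_peripheral / total if total else float("nan")

    @property
    def tie_fraction(self) -> float:
        """Share of lung voxels lying exactly on the cut-off distance.

        The peripheral fraction always satisfies
        ``peripheral_fraction - tie_fraction <= 0.5 <= peripheral_fraction``:
        the excess over the nominal 50% is entirely tie mass at the cut-off.
        """
        total = self.n_central + self.n_peripheral
        return self.n_tied / total if total else float("nan")

    def peripheral_mask(self) -> np.ndarray:
        return self.zones == 2


@dataclasses.dataclass
class ClusterTable:
    """Connected emphysema clusters (26-connectivity)."""

    cluster_ids: np.ndarray
    voxel_counts: np.ndarray
    volumes_mm3: np.ndarray
    centroids: np.ndarray  # (n, 3) in voxel index space (z, y, x)
    connectivity: int = 26

    def __len__(self) -> int:
        return len(self.cluster_ids)


@dataclasses.dataclass
class QCTProfile:
    """Full QCT metric vector for one region (whole lung or a lobe)."""

    region_id: str
    voxel_count: int
    volume_ml: float
    mld_hu: float
    ei_pct: float
    pei_pct: float | None
    ei_cc120_pct: float
    perc15_hu: float
    bi_pct: float
    ggoi_pct: float
    fibi_pct: float
    wp_pct: float | None = None
    awt_pi10_cm: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        tol = 1e-9
        for name in ("ei_pct", "ei_cc120_pct", "bi_pct", "ggoi_pct", "fibi_pct"):
            v = getattr(self, name)
            if not (-tol <= v <= 100 + tol):
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.pei_pct is not None and not (-tol <= self.pei_pct <= 100 + tol):
            raise ValueError(f"pei_pct={self.pei_pct} outside [0, 100]")
        if self.ei_cc120_pct > self.ei_pct + tol:
            raise ValueError("EI_CC120 cannot exceed EI")
        if self.voxel_count <= 0:
            raise EmptyRegionError(f"region {self.region_id!r} is empty")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["flags"] = list(self.flags)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "QCTProfile":
        d = dict(d)
        d["flags"] = tuple(d.get("flags", ()))
        return cls(**d)


def segment_lungs(
    ct: CTVolume,
    *,
    threshold_hu: float = DEFAULT_THRESHOLDS.lung_air_hu,
    min_volume_ml: float = 20.0,
    fill_holes: bool = True,
    max_hole_voxels: int | None = None,
) -> np.ndarray:
    """Threshold-based lung segmentation for phantom-grade images.

    Voxels below ``threshold_hu`` are candidate air; connected components
    touching the volume border (ambient air) are discarded; remaining
    components smaller than ``min_volume_ml`` are dropped; interior holes
    (vessel-like inclusions) up to ``max_hole_voxels`` are filled
    (``None`` = fill all holes).

    This is a deliberately simple surrogate for clinical lung-segmentation
    software and is only expected to work on images with a clear body/lung
    attenuation contrast.
    """
    air = ct.values < threshold_hu
    comp, ncomp = ndimage.label(air, structure=_STRUCT26)
    if ncomp == 0:
        raise EmptyRegionError("no lung found")
    border = np.zeros(ct.shape, dtype=bool)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    border_ids = np.unique(comp[border & air])
    counts = np.bincount(comp.ravel())
    min_vox = int(np.ceil(min_volume_ml * 1000.0 / ct.voxel_volume_mm3))
    keep = np.zeros(ncomp + 1, dtype=bool)
    for cid in range(1, ncomp + 1):
        keep[cid] = cid not in border_ids and counts[cid] >= min_vox
    mask = keep[comp]
    if not mask.any():
        raise EmptyRegionError("no lung found")
    if fill_holes:
        filled = ndimage.binary_fill_holes(mask)
        if max_hole_voxels is not None:
            holes = filled & ~mask
            hcomp, hn = ndimage.label(holes, structure=_STRUCT26)
            hcounts = np.bincount(hcomp.ravel())
            small = np.zeros(hn + 1, dtype=bool)
            small[1:] = hcounts[1:] <= max_hole_voxels
            mask = mask | (small[hcomp] & holes)
        else:
            mask = filled
    return mask


def partition_zones(mask: np.ndarray, spacing_mm: Sequence[float]) -> ZonePartition:
    """Split a lung mask into 50% central and 50% peripheral zones.

    Per connected component, the Euclidean distance of every lung voxel to
    the nearest non-lung voxel is computed in millimetres; the component's
    cut-off is the median distance and voxels with distance <= cut-off are
    labelled peripheral (ties peripheral, so the peripheral share is >= 50%).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRegionError("empty lung mask")
    dist = ndimage.distance_transform_edt(mask, sampling=spacing_mm)
    comp, ncomp = ndimage.label(mask, structure=_STRUCT26)
    zones = np.zeros(mask.shape, dtype=np.int8)
    cutoffs: dict[int, float] = {}
    n_tied = 0
    for cid in range(1, ncomp + 1):
        sel = comp == cid
        d = dist[sel]
        cut = float(np.median(d))
        zones[sel] = np.where(d <= cut, 2, 1)
        cutoffs[cid] = cut
        n_tied += int(np.count_nonzero(d == cut))
    n_per = int((zones == 2).sum())
    n_cen = int((zones == 1).sum())
    return ZonePartition(
        zones=zones,
        cutoff_mm=cutoffs,
        n_central=n_cen,
        n_peripheral=n_per,
        n_tied=n_tied,
    )


def density_metrics(
    ct: CTVolume,
    mask: np.ndarray,
    *,
    thresholds: QCTThresholds = DEFAULT_THRESHOLDS,
) -> dict[str, float]:
    """Histogram metrics over ``mask``: MLD, EI, GGOI, FIBI, Perc15, volume.

    EI counts voxels strictly below the emphysema threshold; GGOI counts
    voxels in ``[ggo_low, ggo_high)``; FIBI counts voxels at or above
    ``ggo_high`` (no upper cap — the mask is responsible for excluding soft
    tissue). Perc15 uses linear interpolation between order statistics.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRegionError("empty region mask")
    vals = np.asarray(ct.values, dtype=np.float64)[mask]
    n = vals.size
    t = thresholds
    return {
        "voxel_count": n,
        "volume_ml": n * ct.voxel_volume_mm3 / 1000.0,
        "mld_hu": float(vals.mean()),
        "ei_pct": 100.0 * np.count_nonzero(vals < t.emphysema_hu) / n,
        "ggoi_pct": 100.0
        * np.count_nonzero((vals >= t.ggo_low_hu) & (vals < t.ggo_high_hu))
        / n,
        "fibi_pct": 100.0 * np.count_nonzero(vals >= t.ggo_high_hu) / n,
        "perc15_hu": float(np.percentile(vals, 15, method="linear")),
    }


def cluster_metrics(
    ct: CTVolume,
    mask: np.ndarray,
    *,
    thresholds: QCTThresholds = DEFAULT_THRESHOLDS,
) -> tuple[ClusterTable, float, float]:
    """Emphysema cluster analysis: table, EI_CC120 and bulla index.

    Emphysema voxels (HU below the threshold, within ``mask``) are grouped
    by 26-connectivity. ``EI_CC120`` is the percent of lung voxels lying in
    clusters whose volume exceeds ``cluster_mm3``. The bulla index applies a
    one-voxel morphological closing to the emphysema mask first (merging
    voxel-scale gaps inside large bullae), then reports the percent of lung
    voxels that are *original* emphysema voxels inside closed clusters
    larger than ``bulla_mm3``; counting only original voxels keeps
    BI <= EI.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRegionError("empty region mask")
    n_lung = int(mask.sum())
    voxvol = ct.voxel_volume_mm3
    emph = mask & (np.asarray(ct.values) < thresholds.emphysema_hu)

    lab, nclust = ndimage.label(emph, structure=_STRUCT26)
    if nclust:
        counts = np.bincount(lab.ravel())[1:]
        centroids = np.asarray(
            ndimage.center_of_mass(emph, lab, index=np.arange(1, nclust + 1))
        ).reshape(nclust, 3)
    else:
        counts = np.zeros(0, dtype=int)
        centroids = np.zeros((0, 3))
    vols = counts * voxvol
    table = ClusterTable(
        cluster_ids=np.arange(1, nclust + 1),
        voxel_counts=counts.astype(int),
        volumes_mm3=vols,
        centroids=centroids,
    )
    big = vols > thresholds.cluster_mm3
    ei_cc120 = 100.0 * counts[big].sum() / n_lung

    closed = ndimage.binary_closing(emph, structure=_STRUCT26) & mask
    clab, cn = ndimage.label(closed, structure=_STRUCT26)
    bi_vox = 0
    if cn:
        ccounts = np.bincount(clab.ravel())
        qualifying = np.zeros(cn + 1, dtype=bool)
        qualifying[1:] = ccounts[1:] * voxvol > thresholds.bulla_mm3
        bi_vox = int(np.count_nonzero(qualifying[clab] & emph))
    bi = 100.0 * bi_vox / n_lung
    return table, float(ei_cc120), float(bi)


def peripheral_emphysema_index(
    ct: CTVolume,
    mask: np.ndarray,
    zones: ZonePartition,
    *,
    thresholds: QCTThresholds = DEFAULT_THRESHOLDS,
) -> float | None:
    """Share of total emphysema located in the peripheral zone, in percent.

    Returns ``None`` (missing, not zero) when the region has no emphysema.
    """
    mask = np.asarray(mask, dtype=bool)
    if zones.zones.shape != mask.shape:
        raise ValueError("zone partition shape does not match mask shape")
    emph = mask & (np.asarray(ct.values) < thresholds.emphysema_hu)
    total = int(emph.sum())
    if total == 0:
        return None
    periph = int((emph & (zones.zones == 2)).sum())
    return 100.0 * periph / total


def region_profile(
    ct: CTVolume,
    labels: LabelVolume,
    region: int | Sequence[int] | str = "lung",
    *,
    zones: ZonePartition | None = None,
    thresholds: QCTThresholds = DEFAULT_THRESHOLDS,
    exclude_nodule: bool = False,
    wp_pct: float | None = None,
    awt_pi10_cm: float | None = None,
) -> QCTProfile:
    """Assemble the full parenchymal metric vector for a labelled region.

    ``region`` is ``"lung"`` (all five lobes), a lobe label, or a sequence
    of lobe labels. ``zones`` should be the partition of the *whole* lung;
    it is computed on demand when omitted. Nodule voxels are included by
    default, mirroring densitometry pipelines that cannot segment the
    nodule out; pass ``exclude_nodule=True`` to remove them.
    Airway metrics are pass-through fields filled only when supplied.
    """
    if ct.shape != labels.shape:
        raise ValueError("CT and label volume shapes differ")
    if isinstance(region, str):
        if region != "lung":
            raise ValueError(f"unknown region selector {region!r}")
        ids: tuple[int, ...] = LOBE_LABELS
        region_id = "lung"
    elif np.isscalar(region):
        ids = (int(region),)
        region_id = f"lobe_{int(region)}"
    else:
        ids = tuple(int(r) for r in region)
        region_id = "+".join(f"lobe_{r}" for r in ids)
    mask = labels.mask(*ids)
    # nodule voxels carry label 8, not a lobe label; re-attach them to the
    # region they sit in unless excluded
    if not exclude_nodule:
        nodule = labels.mask(8)
        if nodule.any():
            host = _nodule_host_lobe(labels)
            if host in ids:
                mask = mask | nodule
    if not mask.any():
        raise EmptyRegionError(f"region {region_id!r} resolves to no voxels")
    if zones is None:
        lung = labels.lung_mask()
        if not exclude_nodule:
            lung = lung | labels.mask(8)
        zones = partition_zones(lung, ct.spacing_mm)
    dens = density_metrics(ct, mask, thresholds=thresholds)
    _, ei_cc120, bi = cluster_metrics(ct, mask, thresholds=thresholds)
    pei = peripheral_emphysema_index(ct, mask, zones, thresholds=thresholds)
    return QCTProfile(
        region_id=region_id,
        voxel_count=int(dens["voxel_count"]),
        volume_ml=dens["volume_ml"],
        mld_hu=dens["mld_hu"],
        ei_pct=dens["ei_pct"],
        pei_pct=pei,
        ei_cc120_pct=ei_cc120,
        perc15_hu=dens["perc15_hu"],
        bi_pct=bi,
        ggoi_pct=dens["ggoi_pct"],
        fibi_pct=dens["fibi_pct"],
        wp_pct=wp_pct,
        awt_pi10_cm=awt_pi10_cm,
    )


def _nodule_host_lobe(labels: LabelVolume) -> int | None:
    """Lobe label whose voxels are nearest to the nodule centroid."""
    nod = labels.mask(8)
    if not nod.any():
        return None
    # dilate the nodule until it touches a lobe label
    lob = labels.labels * labels.lung_mask()
    grow = nod
    for _ in range(max(labels.shape)):
        touched = lob[ndimage.binary_dilation(grow, structure=_STRUCT26)]
        touched = touched[touched > 0]
        if touched.size:
            vals, cnts = np.unique(touched, return_counts=True)
            return int(vals[np.argmax(cnts)])
        grow = ndimage.binary_dilation(grow, structure=_STRUCT26)
    return None
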