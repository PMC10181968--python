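"""Digital CT phantoms with analytic ground truth.

A phantom is a box-world chest: ambient air at the volume border, a soft
tissue body, five non-overlapping rectangular "lobes" of parenchyma, and
optional embedded compartments — emphysema cubes (below -950 HU),
ground-glass boxes ([-800, -700) HU), fibrotic boxes (>= -700 HU) and a
spherical nodule. Because every compartment is placed analytically, every
density metric of the parenchymal panel has an exact expected value
computed from the placed geometry (integer voxel arithmetic), which is what
makes the downstream pipeline testable without patient data.

Emphysema compartments are axis-aligned cubes separated by at least three
voxels, so 26-connected labelling sees each cube as one cluster and a
one-voxel morphological closing is exactly the identity — the cluster-class
metrics (EI_CC120, BI) therefore also have exact ground truth.

Optional noise is truncated per tissue class so that no voxel crosses an HU
class threshold: count-based metrics stay exact under noise while MLD
shifts within the stated bound.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np

from .parenchyma import (
    DEFAULT_THRESHOLDS,
    QCTThresholds,
    partition_zones,
)
from .volumes import CTVolume, LabelVolume, LOBE_LABELS

__all__ = [
    "BoxRegion",
    "NoduleSpec",
    "TubeSpec",
    "PhantomSpec",
    "PhantomGroundTruth",
    "generate_phantom",
    "generate_airway_phantom",
    "random_phantom_spec",
    "RegionCollisionError",
]


class RegionCollisionError(ValueError):
    """Two compartments of different tissue classes overlap."""


@dataclasses.dataclass
class BoxRegion:
    """Axis-aligned box in voxel index space: ``lo`` corner and ``size``."""

    lo: tuple[int, int, int]
    size: tuple[int, int, int]
    hu: float

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, l + s) for l, s in zip(self.lo, self.size))  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.size))


@dataclasses.dataclass
class NoduleSpec:
    center: tuple[float, float, float]  # voxel index space (z, y, x)
    radius_mm: float
    hu: float = 20.0


@dataclasses.dataclass
class TubeSpec:
    """Straight airway tube along the z axis."""

    center_yx_mm: tuple[float, float]
    lumen_radius_mm: float
    wall_thickness_mm: float
    lumen_hu: float = -1000.0
    wall_hu: float = 0.0

    def __post_init__(self) -> None:
        if self.lumen_radius_mm <= 0 or self.wall_thickness_mm <= 0:
            raise ValueError("lumen radius and wall thickness must be positive")


@dataclasses.dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (36, 44, 44)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    outside_hu: float = -1000.0
    body_hu: float = 20.0
    lobes: dict[int, BoxRegion] = dataclasses.field(default_factory=dict)
    emphysema: list[BoxRegion] = dataclasses.field(default_factory=list)
    ggo: list[BoxRegion] = dataclasses.field(default_factory=list)
    fibrosis: list[BoxRegion] = dataclasses.field(default_factory=list)
    nodule: NoduleSpec | None = None
    noise_sd: float = 0.0
    thresholds: QCTThresholds = dataclasses.field(default_factory=QCTThresholds)

    def __post_init__(self) -> None:
        t = self.thresholds
        for b in self.emphysema:
            if not b.hu < t.emphysema_hu:
                raise ValueError(f"emphysema HU {b.hu} not below {t.emphysema_hu}")
        for b in self.ggo:
            if not (t.ggo_low_hu <= b.hu < t.ggo_high_hu):
                raise ValueError(f"GGO HU {b.hu} outside [{t.ggo_low_hu}, {t.ggo_high_hu})")
        for b in self.fibrosis:
            if not b.hu >= t.ggo_high_hu:
                raise ValueError(f"fibrosis HU {b.hu} below {t.ggo_high_hu}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")


@dataclasses.dataclass
class PhantomGroundTruth:
    """Exact expected metrics per region, computed from the placed geometry."""

    regions: dict[str, dict]
    class_counts: dict[str, dict[str, int]]
    cluster_volumes_mm3: dict[str, list[float]]
    noise_sd: float
    seed: int | None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=float)


# HU class bands used for threshold-safe noise truncation
def _band(hu: float, t: QCTThresholds) -> tuple[float, float]:
    if hu < t.emphysema_hu:
        return (-1090.0, t.emphysema_hu - 0.5)
    if hu < t.ggo_low_hu:
        return (t.emphysema_hu + 0.5, t.ggo_low_hu - 0.5)
    if hu < t.ggo_high_hu:
        return (t.ggo_low_hu + 0.5, t.ggo_high_hu - 0.5)
    return (t.ggo_high_hu + 0.5, 3090.0)


def _expected_metrics(
    base_hu: np.ndarray,
    cluster_vols_and_counts: list[tuple[float, int]],
    periph_emph: int,
    voxvol: float,
    t: QCTThresholds,
) -> dict:
    n = base_hu.size
    emph = int(np.count_nonzero(base_hu < t.emphysema_hu))
    ggo = int(np.count_nonzero((base_hu >= t.ggo_low_hu) & (base_hu < t.ggo_high_hu)))
    fib = int(np.count_nonzero(base_hu >= t.ggo_high_hu))
    cc = sum(c for v, c in cluster_vols_and_counts if v > t.cluster_mm3)
    bi = sum(c for v, c in cluster_vols_and_counts if v > t.bulla_mm3)
    return {
        "voxel_count": n,
        "volume_ml": n * voxvol / 1000.0,
        "mld_hu": float(base_hu.mean()),
        "ei_pct": 100.0 * emph / n,
        "pei_pct": (100.0 * periph_emph / emph) if emph else None,
        "ei_cc120_pct": 100.0 * cc / n,
        "perc15_hu": float(np.percentile(base_hu.astype(np.float64), 15, method="linear")),
        "bi_pct": 100.0 * bi / n,
        "ggoi_pct": 100.0 * ggo / n,
        "fibi_pct": 100.0 * fib / n,
    }


def generate_phantom(
    spec: PhantomSpec, seed: int | None = None
) -> tuple[CTVolume, LabelVolume, PhantomGroundTruth]:
    """Rasterize a phantom spec into CT + labels and derive exact ground truth.

    Deterministic given ``seed`` (used only for the optional class-truncated
    noise). Raises :class:`RegionCollisionError` when compartments of
    different classes overlap.
    """
    t = spec.thresholds
    shape = tuple(spec.shape)
    base = np.full(shape, spec.outside_hu, dtype=np.float64)
    labels = np.zeros(shape, dtype=np.int16)

    # body occupies the interior, leaving a one-voxel ambient-air border
    body = tuple(slice(1, s - 1) for s in shape)
    base[body] = spec.body_hu

    for lab, box in spec.lobes.items():
        if lab not in LOBE_LABELS:
            raise ValueError(f"lobe label {lab} outside 1..5")
        base[box.slices()] = box.hu
        labels[box.slices()] = lab

    lung = np.isin(labels, LOBE_LABELS)
    occupancy = np.zeros(shape, dtype=np.int8)  # compartment class per voxel

    def _place_box(box: BoxRegion, cls: int, cls_name: str) -> None:
        sl = box.slices()
        if not lung[sl].all():
            raise ValueError(f"{cls_name} box at {box.lo} extends outside the lung")
        clash = occupancy[sl] != 0
        if clash.any():
            other = int(occupancy[sl][clash][0])
            raise RegionCollisionError(
                f"{cls_name} box at {box.lo} overlaps a class-{other} compartment"
            )
        occupancy[sl] = cls
        base[sl] = box.hu

    for box in spec.emphysema:
        _place_box(box, 1, "emphysema")
    for box in spec.ggo:
        _place_box(box, 2, "GGO")
    for box in spec.fibrosis:
        _place_box(box, 3, "fibrosis")

    nodule_mask = None
    if spec.nodule is not None:
        nd = spec.nodule
        zz, yy, xx = np.indices(shape).astype(np.float64)
        sz, sy, sx = spec.spacing_mm
        r2 = (
            ((zz - nd.center[0]) * sz) ** 2
            + ((yy - nd.center[1]) * sy) ** 2
            + ((xx - nd.center[2]) * sx) ** 2
        )
        nodule_mask = r2 <= nd.radius_mm**2
        if not nodule_mask.any():
            raise ValueError("nodule radius too small to cover any voxel")
        if not lung[nodule_mask].all():
            raise ValueError("nodule extends outside the lung")
        if (occupancy[nodule_mask] != 0).any():
            raise RegionCollisionError("nodule overlaps another compartment")
        occupancy[nodule_mask] = 4
        base[nodule_mask] = nd.hu
        labels[nodule_mask] = 8

    values = base.copy()
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, spec.noise_sd, size=shape)
        noisy = base + noise
        lo = np.empty(shape)
        hi = np.empty(shape)
        # vectorized per-band clipping
        for band_sel, (blo, bhi) in (
            (base < t.emphysema_hu, (-1090.0, t.emphysema_hu - 0.5)),
            (
                (base >= t.emphysema_hu) & (base < t.ggo_low_hu),
                (t.emphysema_hu + 0.5, t.ggo_low_hu - 0.5),
            ),
            (
                (base >= t.ggo_low_hu) & (base < t.ggo_high_hu),
                (t.ggo_low_hu + 0.5, t.ggo_high_hu - 0.5),
            ),
            (base >= t.ggo_high_hu, (t.ggo_high_hu + 0.5, 3090.0)),
        ):
            lo[band_sel], hi[band_sel] = blo, bhi
        values = np.clip(noisy, np.maximum(lo, base - 3 * spec.noise_sd), np.minimum(hi, base + 3 * spec.noise_sd))

    ct = CTVolume(values=values, spacing_mm=spec.spacing_mm)
    label_vol = LabelVolume(labels=labels, spacing_mm=spec.spacing_mm)

    # ---- ground truth from placed geometry (noise-free base values) ----
    voxvol = float(np.prod(spec.spacing_mm))
    lung_or_nodule = lung | (labels == 8)
    zones = partition_zones(lung_or_nodule, spec.spacing_mm)
    periph = zones.zones == 2
    emph_mask = occupancy == 1

    regions: dict[str, dict] = {}
    class_counts: dict[str, dict[str, int]] = {}
    cluster_vols: dict[str, list[float]] = {}
    region_masks: dict[str, np.ndarray] = {"lung": lung_or_nodule}
    for lab in sorted(spec.lobes):
        m = labels == lab
        if nodule_mask is not None:
            # the nodule displaced lobe voxels; reattach to its host lobe
            host = _host_lobe(spec, nodule_mask)
            if host == lab:
                m = m | nodule_mask
        region_masks[f"lobe_{lab}"] = m

    for rid, m in region_masks.items():
        vals = base[m]
        clusters = []
        for box in spec.emphysema:
            sl = box.slices()
            inside = int(m[sl].sum())
            if inside:
                clusters.append((box.n_voxels * voxvol, inside))
                if inside != box.n_voxels and rid != "lung":
                    raise ValueError(
                        f"emphysema box at {box.lo} straddles region {rid}"
                    )
        pe = int((emph_mask & periph & m).sum())
        regions[rid] = _expected_metrics(vals, clusters, pe, voxvol, t)
        class_counts[rid] = {
            "parenchyma": int(np.count_nonzero(m & (occupancy == 0))),
            "emphysema": int(np.count_nonzero(m & (occupancy == 1))),
            "ggo": int(np.count_nonzero(m & (occupancy == 2))),
            "fibrosis": int(np.count_nonzero(m & (occupancy == 3))),
            "nodule": int(np.count_nonzero(m & (occupancy == 4))),
        }
        cluster_vols[rid] = [v for v, _ in clusters]

    truth = PhantomGroundTruth(
        regions=regions,
        class_counts=class_counts,
        cluster_volumes_mm3=cluster_vols,
        noise_sd=spec.noise_sd,
        seed=seed,
    )
    return ct, label_vol, truth


def _host_lobe(spec: PhantomSpec, nodule_mask: np.ndarray) -> int:
    zc, yc, xc = (float(c.mean()) for c in np.nonzero(nodule_mask))
    best, best_d = 0, np.inf
    for lab, box in spec.lobes.items():
        c = [l + s / 2 for l, s in zip(box.lo, box.size)]
        d = (c[0] - zc) ** 2 + (c[1] - yc) ** 2 + (c[2] - xc) ** 2
        if d < best_d:
            best, best_d = lab, d
    return best


def generate_airway_phantom(
    tubes: Sequence[TubeSpec],
    *,
    shape: tuple[int, int, int] = (20, 80, 80),
    spacing_mm: tuple[float, float, float] = (1.0, 0.25, 0.25),
    background_hu: float = -780.0,
) -> tuple[CTVolume, LabelVolume, list[dict]]:
    """Voxelize straight airway tubes and record their analytic geometry.

    Tubes run along z. A voxel belongs to the lumen when its centre lies
    within the lumen radius of the tube axis, to the wall when within
    ``lumen_radius + wall_thickness``. Returns the CT volume, label volume
    (lumen 6, wall 7) and, per tube, the analytic lumen area, wall area,
    internal perimeter and wall thickness of the ideal annulus.
    """
    values = np.full(shape, background_hu, dtype=np.float64)
    labels = np.zeros(shape, dtype=np.int16)
    _, sy, sx = spacing_mm
    yy, xx = np.meshgrid(
        np.arange(shape[1]) * sy, np.arange(shape[2]) * sx, indexing="ij"
    )
    geom: list[dict] = []
    extent_y, extent_x = (shape[1] - 1) * sy, (shape[2] - 1) * sx
    for tube in tubes:
        cy, cx = tube.center_yx_mm
        outer = tube.lumen_radius_mm + tube.wall_thickness_mm
        if cy - outer < 0 or cx - outer < 0 or cy + outer > extent_y or cx + outer > extent_x:
            raise ValueError(f"tube at {tube.center_yx_mm} does not fit the grid")
        r = np.hypot(yy - cy, xx - cx)
        lumen2d = r < tube.lumen_radius_mm
        wall2d = (r >= tube.lumen_radius_mm) & (r < outer)
        if (labels[0][lumen2d | wall2d] != 0).any():
            raise RegionCollisionError("tubes overlap")
        for z in range(shape[0]):
            values[z][lumen2d] = tube.lumen_hu
            values[z][wall2d] = tube.wall_hu
            labels[z][lumen2d] = 6
            labels[z][wall2d] = 7
        rl, t = tube.lumen_radius_mm, tube.wall_thickness_mm
        geom.append(
            {
                "lumen_area_mm2": np.pi * rl**2,
                "wall_area_mm2": np.pi * ((rl + t) ** 2 - rl**2),
                "internal_perimeter_mm": 2 * np.pi * rl,
                "wall_thickness_mm": t,
                "wall_percentage": 100.0 * ((rl + t) ** 2 - rl**2) / (rl + t) ** 2,
            }
        )
    return (
        CTVolume(values=values, spacing_mm=spacing_mm),
        LabelVolume(labels=labels, spacing_mm=spacing_mm),
        geom,
    )


def random_phantom_spec(
    seed: int,
    *,
    shape: tuple[int, int, int] = (36, 44, 44),
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    noise_sd: float = 0.0,
    max_emphysema_per_lobe: int = 2,
) -> PhantomSpec:
    """Randomized five-lobe phantom geometry with analytic ground truth.

    Lobes are five rectangular slabs (three right, two left). Each lobe
    receives up to ``max_emphysema_per_lobe`` emphysema cubes with edge
    lengths 2–6 voxels (spanning the 120 mm^3 cluster-class boundary at
    1 mm spacing), and optionally one ground-glass and one fibrosis box; one
    lobe hosts a spherical nodule. Compartments keep a 3-voxel clearance so
    clusters stay 26-disconnected and closing-invariant.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    margin = 3
    xmid = nx // 2
    right_x = (margin, xmid - 2)
    left_x = (xmid + 2, nx - margin)

    def _stack(labs: list[int], xr: tuple[int, int]) -> dict[int, BoxRegion]:
        out = {}
        z0, z1 = margin, nz - margin
        edges = np.linspace(z0, z1, len(labs) + 1).astype(int)
        for lab, (a, b) in zip(labs, zip(edges[:-1], edges[1:])):
            hu = _safe_parenchyma_hu(rng)
            out[lab] = BoxRegion(
                lo=(int(a), margin, xr[0]),
                size=(int(b - a), ny - 2 * margin, xr[1] - xr[0]),
                hu=hu,
            )
        return out

    lobes = {**_stack([1, 2, 3], right_x), **_stack([4, 5], left_x)}

    taken = np.zeros(shape, dtype=bool)  # compartments plus clearance halo
    emphysema: list[BoxRegion] = []
    ggo: list[BoxRegion] = []
    fibrosis: list[BoxRegion] = []

    def _try_place(lab: int, size: tuple[int, int, int], hu: float, halo: int) -> BoxRegion | None:
        box = lobes[lab]
        for _ in range(30):
            lo = tuple(
                int(rng.integers(box.lo[i] + 1, box.lo[i] + box.size[i] - size[i]))
                if box.size[i] - size[i] > 1
                else -1
                for i in range(3)
            )
            if -1 in lo:
                return None
            sl_h = tuple(
                slice(max(l - halo, 0), l + s + halo) for l, s in zip(lo, size)
            )
            if taken[sl_h].any():
                continue
            taken[tuple(slice(l, l + s) for l, s in zip(lo, size))] = True
            # reserve the halo too so later boxes keep their distance
            taken[sl_h] = True
            return BoxRegion(lo=lo, size=size, hu=hu)
        return None

    for lab in lobes:
        for _ in range(int(rng.integers(0, max_emphysema_per_lobe + 1))):
            e = int(rng.integers(2, 7))
            b = _try_place(lab, (e, e, e), float(rng.uniform(-1020, -970)), halo=3)
            if b is not None:
                emphysema.append(b)
        if rng.random() < 0.7:
            s = tuple(int(rng.integers(2, 5)) for _ in range(3))
            b = _try_place(lab, s, float(rng.uniform(-795, -705)), halo=1)
            if b is not None:
                ggo.append(b)
        if rng.random() < 0.7:
            s = tuple(int(rng.integers(2, 5)) for _ in range(3))
            b = _try_place(lab, s, float(rng.uniform(-650, -100)), halo=1)
            if b is not None:
                fibrosis.append(b)

    # guarantee at least one emphysema cube somewhere
    if not emphysema:
        b = _try_place(1, (5, 5, 5), -985.0, halo=3)
        if b is None:
            raise RuntimeError("could not place mandatory emphysema cube")
        emphysema.append(b)

    nodule = None
    for lab in rng.permutation(list(lobes)):
        box = lobes[int(lab)]
        center = tuple(box.lo[i] + box.size[i] / 2 for i in range(3))
        radius = float(rng.uniform(1.5, 3.0))
        # accept only if the sphere stays clear of placed compartments
        zz, yy, xx = np.indices(shape).astype(float)
        m = (
            ((zz - center[0]) * spacing_mm[0]) ** 2
            + ((yy - center[1]) * spacing_mm[1]) ** 2
            + ((xx - center[2]) * spacing_mm[2]) ** 2
        ) <= radius**2
        if m.any() and not taken[m].any():
            nodule = NoduleSpec(center=center, radius_mm=radius, hu=float(rng.uniform(-100, 100)))
            break

    return PhantomSpec(
        shape=shape,
        spacing_mm=spacing_mm,
        lobes=lobes,
        emphysema=emphysema,
        ggo=ggo,
        fibrosis=fibrosis,
        nodule=nodule,
        noise_sd=noise_sd,
    )


def _safe_parenchyma_hu(rng: np.random.Generator) -> float:
    """Parenchyma HU away from class boundaries (for threshold-safe noise)."""
    while True:
        hu = float(rng.uniform(-930.0, -720.0))
        if all(abs(hu - b) > 6.0 for b in (-950.0, -800.0, -700.0)):
            return hu
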