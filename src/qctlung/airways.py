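"""Airway cross-sectional measurement: wall percentage and AWT-Pi10.

Cross-sections are taken perpendicular to each tube's principal axis
(phantom tubes are axis-aligned straight cylinders). Per cross-section,
lumen and wall areas come from voxel counts, the internal perimeter from a
marching-squares contour of the lumen, and the local wall thickness from
wall area / internal perimeter. Segment values are means over the tube's
cross-sections.

AWT-Pi10 regresses wall thickness (mm) on internal perimeter (mm) across
segments by ordinary least squares and reports the predicted thickness of a
theoretical airway with a 10 mm internal perimeter, in cm. The regression
target is the thickness itself, matching the centimetre unit and ~0.2 cm
magnitude this quantity is reported with.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure

from .volumes import CTVolume, LabelVolume, LABEL_SCHEME

__all__ = [
    "AirwaySegmentMeasurement",
    "measure_airways",
    "wall_percentage",
    "awt_pi10",
    "read_measurements_csv",
    "write_measurements_csv",
    "NoEligibleSegmentsError",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


class NoEligibleSegmentsError(ValueError):
    pass


@dataclasses.dataclass
class AirwaySegmentMeasurement:
    segment_id: int
    generation: int
    lumen_area_mm2: float
    wall_area_mm2: float
    internal_perimeter_mm: float
    wall_thickness_mm: float

    def __post_init__(self) -> None:
        for name in (
            "lumen_area_mm2",
            "wall_area_mm2",
            "internal_perimeter_mm",
            "wall_thickness_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def wall_percentage(self) -> float:
        return 100.0 * self.wall_area_mm2 / (self.wall_area_mm2 + self.lumen_area_mm2)


def _contour_length(binary2d: np.ndarray, spacing2d: Sequence[float]) -> float:
    """Total marching-squares contour length of a binary 2-D region, in mm."""
    padded = np.pad(binary2d.astype(float), 1)
    total = 0.0
    for contour in skmeasure.find_contours(padded, 0.5):
        diffs = np.diff(contour, axis=0) * np.asarray(spacing2d)[None, :]
        total += float(np.sqrt((diffs**2).sum(axis=1)).sum())
    return total


def measure_airways(
    ct: CTVolume,
    labels: LabelVolume,
    *,
    generations: Sequence[int] | None = None,
    default_generation: int = 3,
) -> list[AirwaySegmentMeasurement]:
    """Measure every labelled airway tube in a volume.

    Tubes are the 26-connected components of the combined lumen+wall label
    mask; the principal axis of each tube is the coordinate axis of largest
    lumen extent. ``generations`` assigns an airway generation per tube (in
    component order); phantom labels carry no generation, so the default
    marks every tube as generation ``default_generation`` (eligible for
    wall statistics).
    """
    lumen_all = labels.mask(LABEL_SCHEME["airway_lumen"])
    wall_all = labels.mask(LABEL_SCHEME["airway_wall"])
    if not lumen_all.any():
        warnings.warn("no airway labels present; returning empty measurement list")
        return []
    comp, ncomp = ndimage.label(lumen_all | wall_all, structure=_STRUCT26)
    out: list[AirwaySegmentMeasurement] = []
    for cid in range(1, ncomp + 1):
        tube = comp == cid
        lumen = tube & lumen_all
        wall = tube & wall_all
        if not lumen.any():
            continue
        if not wall.any():
            warnings.warn(f"tube {cid} has no wall label; skipped")
            continue
        coords = np.argwhere(lumen)
        extents_mm = (coords.max(axis=0) - coords.min(axis=0)) * np.asarray(
            ct.spacing_mm
        )
        axis = int(np.argmax(extents_mm))
        inplane = [a for a in range(3) if a != axis]
        pix_area = ct.spacing_mm[inplane[0]] * ct.spacing_mm[inplane[1]]
        spacing2d = (ct.spacing_mm[inplane[0]], ct.spacing_mm[inplane[1]])
        la, wa, per, wt = [], [], [], []
        for idx in range(coords[:, axis].min(), coords[:, axis].max() + 1):
            lum2d = np.take(lumen, idx, axis=axis)
            wal2d = np.take(wall, idx, axis=axis)
            nl, nw = int(lum2d.sum()), int(wal2d.sum())
            if nl == 0 or nw == 0:
                continue
            p = _contour_length(lum2d, spacing2d)
            if p <= 0:
                continue
            la.append(nl * pix_area)
            wa.append(nw * pix_area)
            per.append(p)
            wt.append(nw * pix_area / p)
        if not la:
            warnings.warn(f"tube {cid} yielded no usable cross-sections; skipped")
            continue
        gen = default_generation
        if generations is not None and len(out) < len(generations):
            gen = int(generations[len(out)])
        out.append(
            AirwaySegmentMeasurement(
                segment_id=cid,
                generation=gen,
                lumen_area_mm2=float(np.mean(la)),
                wall_area_mm2=float(np.mean(wa)),
                internal_perimeter_mm=float(np.mean(per)),
                wall_thickness_mm=float(np.mean(wt)),
            )
        )
    return out


def wall_percentage(
    measurements: Sequence[AirwaySegmentMeasurement],
    *,
    min_generation: int = 3,
) -> float:
    """Mean airway wall percentage over eligible segments.

    WP per segment is ``100 * wall / (wall + lumen)`` by area; trachea and
    main bronchi (generation below ``min_generation``) are excluded.
    """
    eligible = [m for m in measurements if m.generation >= min_generation]
    if not eligible:
        raise NoEligibleSegmentsError("no eligible segments after generation filter")
    return float(np.mean([m.wall_percentage for m in eligible]))


def awt_pi10(
    measurements: Sequence[AirwaySegmentMeasurement],
    *,
    min_generation: int = 0,
) -> float:
    """Airway wall thickness of a theoretical 10 mm-perimeter airway, in cm.

    Fits wall thickness (mm) on internal perimeter (mm) by OLS across
    segments and evaluates the line at Pi = 10 mm.
    """
    eligible = [m for m in measurements if m.generation >= min_generation]
    if len(eligible) < 2:
        raise NoEligibleSegmentsError("AWT-Pi10 needs at least two segments")
    x = np.array([m.internal_perimeter_mm for m in eligible])
    y = np.array([m.wall_thickness_mm for m in eligible])
    if np.ptp(x) == 0:
        raise ValueError("AWT-Pi10 undefined: zero variance in internal perimeter")
    # closed-form simple OLS
    xbar, ybar = x.mean(), y.mean()
    slope = float(((x - xbar) * (y - ybar)).sum() / ((x - xbar) ** 2).sum())
    intercept = float(ybar - slope * xbar)
    return (intercept + slope * 10.0) / 10.0


def write_measurements_csv(
    measurements: Sequence[AirwaySegmentMeasurement], path
) -> None:
    import pandas as pd

    pd.DataFrame([dataclasses.asdict(m) for m in measurements]).to_csv(
        path, index=False
    )


def read_measurements_csv(path) -> list[AirwaySegmentMeasurement]:
    import pandas as pd

    df = pd.read_csv(path)
    required = {
        "segment_id",
        "generation",
        "lumen_area_mm2",
        "wall_area_mm2",
        "internal_perimeter_mm",
        "wall_thickness_mm",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurements CSV missing columns: {sorted(missing)}")
    return [
        AirwaySegmentMeasurement(
            segment_id=int(r.segment_id),
            generation=int(r.generation),
            lumen_area_mm2=float(r.lumen_area_mm2),
            wall_area_mm2=float(r.wall_area_mm2),
            internal_perimeter_mm=float(r.internal_perimeter_mm),
            wall_thickness_mm=float(r.wall_thickness_mm),
        )
        for r in df.itertuples()
    ]
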