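"""Osteocyte counting on stained sections.

Viability readout: LDH-stained viable osteocytes versus the total number of
osteocyte lacunae (stained plus empty) on a section, expressed as a
percentage. Sclerostin readout: positive-cell fraction counted in three
equal areas of interest — one flush with each end of the section and one in
the center (2.94 or 2.16 mm2 in the characterised sections) — pooled by
summed counts.

Counting here is automated: connected components above a minimum object
size, classified positive versus empty by mean stain intensity. It is
validated against the synthetic section generator, not against human
counting on real histology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .synthetic_data import CellCounts, SectionImage

__all__ = [
    "AreaOfInterest",
    "LacunaThresholds",
    "detect_lacunae",
    "viability_fraction",
    "place_areas_of_interest",
    "positive_fraction_in_aois",
]


@dataclass(frozen=True)
class LacunaThresholds:
    """Intensity thresholds separating background / empty / positive classes.

    ``object_intensity``: pixels above it belong to a lacuna;
    ``positive_intensity``: components whose mean stain intensity exceeds it
    are positive; ``min_size_px``: object-size floor rejecting single-pixel
    noise.
    """

    object_intensity: float = 60.0
    positive_intensity: float = 160.0
    min_size_px: int = 5

    def __post_init__(self) -> None:
        if self.positive_intensity <= self.object_intensity:
            raise ValueError("positive_intensity must exceed object_intensity")
        if self.min_size_px < 1:
            raise ValueError("min_size_px must be >= 1")

    def scaled(self, factor: float) -> "LacunaThresholds":
        return LacunaThresholds(
            self.object_intensity * factor, self.positive_intensity * factor,
            self.min_size_px,
        )


@dataclass(frozen=True)
class AreaOfInterest:
    """A rectangular counting window on a section."""

    origin: tuple[int, int]  # (row, col), px
    width: int  # px
    height: int  # px
    pixel_size_um: float

    @property
    def area_mm2(self) -> float:
        return self.width * self.height * (self.pixel_size_um / 1000.0) ** 2

    def slice(self) -> tuple[slice, slice]:
        r, c = self.origin
        return slice(r, r + self.height), slice(c, c + self.width)


def detect_lacunae(
    image: SectionImage, thresholds: LacunaThresholds = LacunaThresholds()
) -> pd.DataFrame:
    """Segment and classify lacunae on a section.

    Returns one row per detected lacuna with columns
    ``label, centroid_row, centroid_col, area_px, mean_intensity, positive``.
    """
    plane = image.stain_plane
    fg = plane > thresholds.object_intensity
    labels = measure.label(fg, connectivity=2)
    rows = []
    for region in measure.regionprops(labels, intensity_image=plane):
        if region.area < thresholds.min_size_px:
            continue
        mean_int = float(region.intensity_mean)
        rows.append(
            (
                region.label,
                float(region.centroid[0]),
                float(region.centroid[1]),
                int(region.area),
                mean_int,
                mean_int > thresholds.positive_intensity,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label",
            "centroid_row",
            "centroid_col",
            "area_px",
            "mean_intensity",
            "positive",
        ],
    )


def counts_from_detections(detections: pd.DataFrame) -> CellCounts:
    return CellCounts(
        positive=int(detections["positive"].sum()), total=int(len(detections))
    )


def viability_fraction(counts: CellCounts) -> float:
    """Percentage of positive (viable) osteocytes over all lacunae."""
    if counts.total == 0:
        raise ValueError("viability fraction undefined: no lacunae counted")
    return counts.fraction_percent


def place_areas_of_interest(
    image: SectionImage, target_area_mm2: float
) -> list[AreaOfInterest]:
    """Three equal square AOIs: two flush with the section ends, one centered.

    All three realise ``target_area_mm2`` (within pixel rounding); raises if
    three disjoint AOIs of that size do not fit on the section.
    """
    if target_area_mm2 <= 0:
        raise ValueError("target_area_mm2 must be > 0")
    h_px, w_px = image.stain_plane.shape
    side = int(round(np.sqrt(target_area_mm2) / (image.pixel_size_um / 1000.0)))
    if side > h_px or 3 * side > w_px:
        raise ValueError(
            f"section {w_px}x{h_px} px too small for three disjoint "
            f"{side}x{side} px areas of interest"
        )
    top = (h_px - side) // 2
    return [
        AreaOfInterest((top, 0), side, side, image.pixel_size_um),
        AreaOfInterest((top, (w_px - side) // 2), side, side, image.pixel_size_um),
        AreaOfInterest((top, w_px - side), side, side, image.pixel_size_um),
    ]


def positive_fraction_in_aois(
    image: SectionImage,
    aois: list[AreaOfInterest],
    thresholds: LacunaThresholds = LacunaThresholds(),
) -> tuple[list[CellCounts], float]:
    """Per-AOI counts plus the pooled positive percentage.

    Counting is restricted to each AOI crop; the pooled fraction is
    100 x (sum of positives) / (sum of totals) across the three AOIs, i.e.
    counts are summed, not fractions averaged.
    """
    h_px, w_px = image.stain_plane.shape
    per_aoi = []
    for aoi in aois:
        r, c = aoi.origin
        if r < 0 or c < 0 or r + aoi.height > h_px or c + aoi.width > w_px:
            raise ValueError("area of interest extends beyond the section")
        crop = SectionImage(
            image.stain_plane[aoi.slice()], image.pixel_size_um
        )
        per_aoi.append(counts_from_detections(detect_lacunae(crop, thresholds)))
    total = sum(c.total for c in per_aoi)
    if total == 0:
        raise ValueError("no lacunae detected in any area of interest")
    pooled = 100.0 * sum(c.positive for c in per_aoi) / total
    return per_aoi, pooled
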