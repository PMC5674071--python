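"""Sum-intensity viability quantification.

The assay statistic is the *sum intensity*: the sum of grey levels
(0-255) over all pixels selected by a low/high threshold window in one
channel.  Under a matched calibration (equal live and dead cells give
equal sum intensity) the viability of a field is

    % viability = S_FDA / (S_FDA + S_PI) x 100

Per-bead viability applies the same formula to the pixels of one
segmented bead region; multi-field aggregates pool sum intensities
across fields before applying the formula (weighted by signal), which is
robust to sparse fields — per-field percentages are reported alongside.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .calibrate import CalibrationConfig, robust_background
from .errors import ParameterError
from .imgen import BeadField, Channel, ChannelImage

__all__ = [
    "SumIntensity",
    "BeadRegion",
    "ViabilityResult",
    "sum_intensity",
    "compute_viability",
    "segment_beads",
    "quantify",
]

#: Minimum numbers of fields and beads recommended for a batch estimate.
MIN_FIELDS = 5
MIN_BEADS = 100


@dataclass(frozen=True)
class SumIntensity:
    """Sum of grey levels over threshold-selected pixels of one channel."""

    channel: Channel
    value: int
    n_selected_pixels: int

    def __post_init__(self) -> None:
        if self.value < 0 or self.n_selected_pixels < 0:
            raise ParameterError("sum intensity fields must be non-negative")
        if self.value > 255 * self.n_selected_pixels:
            raise ParameterError(
                "sum intensity cannot exceed 255 x selected pixel count")


@dataclass(frozen=True)
class BeadRegion:
    """One segmented bead: centre, radius and its pixel mask.

    ``mask`` is local to ``bbox`` (top, left, bottom, right) to keep
    per-bead storage small."""

    label: int
    center_xy: tuple[float, float]
    radius_px: float
    bbox: tuple[int, int, int, int]
    mask: np.ndarray

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        t, l, b, r = self.bbox
        out[t:b, l:r] = self.mask
        return out


@dataclass
class ViabilityResult:
    """Field- and bead-level viability of a batch of fields.

    ``percent`` is the pooled estimate (formula applied to sum
    intensities summed across all fields); it is NaN — with
    ``undefined`` set — when neither channel carries signal.
    """

    percent: float
    s_fda: SumIntensity
    s_pi: SumIntensity
    n_fields: int
    n_beads: int | None = None
    per_field: list[float] = field(default_factory=list)
    per_bead: list[dict] = field(default_factory=list)
    warnings: list[dict] = field(default_factory=list)

    @property
    def undefined(self) -> bool:
        return math.isnan(self.percent)

    def to_dict(self) -> dict:
        return {
            "percent": None if self.undefined else self.percent,
            "undefined": self.undefined,
            "s_fda": {"value": self.s_fda.value,
                      "n_selected_pixels": self.s_fda.n_selected_pixels},
            "s_pi": {"value": self.s_pi.value,
                     "n_selected_pixels": self.s_pi.n_selected_pixels},
            "n_fields": self.n_fields,
            "n_beads": self.n_beads,
            "per_field": [None if math.isnan(p) else p for p in self.per_field],
            "per_bead": self.per_bead,
            "warnings": self.warnings,
        }


# ---------------------------------------------------------------------------
# Core statistics
# ---------------------------------------------------------------------------

def sum_intensity(image: ChannelImage, low: int, high: int = 255) -> SumIntensity:
    """Sum grey levels of pixels ``p`` with ``low <= p <= high``.

    Both bounds are inclusive, matching the thresholding convention of
    the acquisition software (high fixed at the 8-bit maximum in normal
    use)."""
    if not (isinstance(low, (int, np.integer)) and isinstance(high, (int, np.integer))):
        raise ParameterError("thresholds must be integers")
    if not 0 <= low <= high <= 255:
        raise ParameterError("thresholds must satisfy 0 <= low <= high <= 255")
    px = image.pixels
    sel = (px >= low) & (px <= high)
    return SumIntensity(
        channel=image.channel,
        value=int(px[sel].astype(np.int64).sum()),
        n_selected_pixels=int(sel.sum()),
    )


def compute_viability(s_fda: SumIntensity | float,
                      s_pi: SumIntensity | float) -> float:
    """``100 x S_FDA / (S_FDA + S_PI)``.

    Returns NaN (the machine-readable undefined flag, not an exception)
    when the denominator is zero."""
    a = s_fda.value if isinstance(s_fda, SumIntensity) else float(s_fda)
    b = s_pi.value if isinstance(s_pi, SumIntensity) else float(s_pi)
    if a < 0 or b < 0:
        raise ParameterError("sum intensities must be non-negative")
    denom = a + b
    if denom == 0:
        return float("nan")
    return 100.0 * a / denom


# ---------------------------------------------------------------------------
# Bead segmentation
# ---------------------------------------------------------------------------

def segment_beads(bead_field: BeadField,
                  config: CalibrationConfig | None = None,
                  min_bead_diameter_um: float = 150.0,
                  k: float = 3.0) -> list[BeadRegion]:
    """Detect circular bead regions from the dual-channel signal.

    The union of above-threshold pixels from both channels is closed and
    hole-filled, then split into beads by a distance-transform watershed
    (robust to touching beads); each pixel belongs to at most one bead.
    Regions smaller than ``min_bead_diameter_um`` are treated as debris
    and dropped.  Returns an empty list — with a warning — when nothing
    is found.
    """
    from skimage.feature import peak_local_max
    from skimage.morphology import binary_closing, disk, remove_small_objects
    from skimage.segmentation import watershed

    fda, pi = bead_field.fda, bead_field.pi
    if config is not None:
        low_fda, low_pi = config.low_fda, config.low_pi
    else:
        low_fda = min(int(np.floor(robust_background(fda.pixels, k=k))) + 1, 255)
        low_pi = min(int(np.floor(robust_background(pi.pixels, k=k))) + 1, 255)
    mask = (fda.pixels >= low_fda) | (pi.pixels >= low_pi)
    mask = binary_closing(mask, disk(3))
    mask = ndi.binary_fill_holes(mask)
    min_r_px = min_bead_diameter_um / 2.0 / bead_field.pixel_size_um
    min_area = math.pi * (min_r_px * 0.5) ** 2  # generous: half the minimum radius
    mask = remove_small_objects(mask, min_size=int(min_area))
    if not mask.any():
        warnings.warn("no beads found in field", stacklevel=2)
        return []

    distance = ndi.distance_transform_edt(mask)
    # watershed seeds: distance maxima at least one minimum-radius apart
    coords = peak_local_max(distance, min_distance=max(3, int(min_r_px)),
                            threshold_abs=min_r_px * 0.5, labels=mask)
    if len(coords) == 0:
        warnings.warn("no beads found in field", stacklevel=2)
        return []
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    labels = watershed(-distance, markers, mask=mask)

    regions: list[BeadRegion] = []
    for lab in range(1, len(coords) + 1):
        obj = labels == lab
        area = int(obj.sum())
        if area < min_area:
            continue
        ys, xs = np.nonzero(obj)
        t, b = int(ys.min()), int(ys.max()) + 1
        l, r = int(xs.min()), int(xs.max()) + 1
        regions.append(BeadRegion(
            label=lab,
            center_xy=(float(xs.mean()), float(ys.mean())),
            radius_px=float(math.sqrt(area / math.pi)),
            bbox=(t, l, b, r),
            mask=obj[t:b, l:r],
        ))
    if not regions:
        warnings.warn("no beads found in field", stacklevel=2)
    return regions


# ---------------------------------------------------------------------------
# Batch quantification
# ---------------------------------------------------------------------------

def _masked_sum(img: np.ndarray, region: BeadRegion, low: int, high: int) -> int:
    t, l, b, r = region.bbox
    sub = img[t:b, l:r][region.mask]
    sel = (sub >= low) & (sub <= high)
    return int(sub[sel].astype(np.int64).sum())


def quantify(fields: Sequence[BeadField], config: CalibrationConfig,
             per_bead: bool = False) -> ViabilityResult:
    """Viability of a batch of fields under a matched calibration.

    Field-level viability uses whole-image sum intensities.  The
    aggregate ``percent`` applies the formula to intensities pooled
    across all fields (signal-weighted), not to the mean of per-field
    percentages; per-field values are reported for inspection.  With
    ``per_bead`` the fields are segmented and the formula applied per
    bead region.
    """
    if len(fields) == 0:
        raise ParameterError("at least one field is required")
    shapes = {f.fda.shape for f in fields}
    if len(shapes) > 1:
        from .errors import InputError
        raise InputError(f"fields have mismatched image dimensions: {shapes}")

    warns: list[dict] = []
    if len(fields) < MIN_FIELDS:
        msg = (f"{len(fields)} field(s) quantified; at least {MIN_FIELDS} "
               "fields are recommended per batch")
        warnings.warn(msg, stacklevel=2)
        warns.append({"rule": "min_fields", "message": msg})

    tot_fda = tot_pi = 0
    n_fda = n_pi = 0
    per_field: list[float] = []
    per_bead_rows: list[dict] = []
    n_beads_total: int | None = 0 if (per_bead or all(
        f.truth is not None for f in fields)) else None

    for i, f in enumerate(fields):
        s_fda = sum_intensity(f.fda, config.low_fda, config.high)
        s_pi = sum_intensity(f.pi, config.low_pi, config.high)
        tot_fda += s_fda.value
        tot_pi += s_pi.value
        n_fda += s_fda.n_selected_pixels
        n_pi += s_pi.n_selected_pixels
        per_field.append(compute_viability(s_fda, s_pi))
        if per_bead:
            regions = segment_beads(f, config=config)
            if n_beads_total is not None:
                n_beads_total += len(regions)
            for reg in regions:
                bf = _masked_sum(f.fda.pixels, reg, config.low_fda, config.high)
                bp = _masked_sum(f.pi.pixels, reg, config.low_pi, config.high)
                per_bead_rows.append({
                    "field": i,
                    "bead": reg.label,
                    "center_xy": list(reg.center_xy),
                    "radius_px": reg.radius_px,
                    "percent": compute_viability(bf, bp),
                })
        elif n_beads_total is not None:
            n_beads_total += len(f.truth.beads)

    if n_beads_total is not None and n_beads_total < MIN_BEADS:
        msg = (f"{n_beads_total} beads in batch; at least {MIN_BEADS} "
               "are recommended")
        warnings.warn(msg, stacklevel=2)
        warns.append({"rule": "min_beads", "message": msg})

    return ViabilityResult(
        percent=compute_viability(float(tot_fda), float(tot_pi)),
        s_fda=SumIntensity("FDA", tot_fda, n_fda),
        s_pi=SumIntensity("PI", tot_pi, n_pi),
        n_fields=len(fields),
        n_beads=n_beads_total,
        per_field=per_field,
        per_bead=per_bead_rows,
        warnings=warns,
    )
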