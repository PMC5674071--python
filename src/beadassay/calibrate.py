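"""Exposure-time and low-threshold calibration for the FDA/PI assay.

The assay's viability formula is valid only when an equal number of live
and dead cells produce the same sum intensity in their respective
channels.  Calibration therefore (1) picks, per channel, the exposure
time maximising the signal-to-noise ratio without saturating,
(2) derives the low threshold that separates background from cell
pixels, and (3) matches the PI set-up (exposure and low threshold) on
fully killed control fields so its per-cell sum intensity equals the FDA
per-cell sum intensity measured on fully live fields.

The high threshold is always the 8-bit maximum, 255.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .errors import CalibrationError, ParameterError
from .imgen import BeadField, Channel, ChannelImage

__all__ = [
    "DEFAULT_LOW_THRESHOLD",
    "FDA_EXPOSURE_CANDIDATES_MS",
    "PI_EXPOSURE_CANDIDATES_MS",
    "CalibrationConfig",
    "SNRReport",
    "select_exposure",
    "fit_low_threshold",
    "match_pi_setup",
    "check_overspill",
    "robust_background",
]

#: Published operating low threshold (both channels) for the original
#: Nikon TE200 / DS-Fi1c set-up; used as the documented default when no
#: calibration images are supplied.
DEFAULT_LOW_THRESHOLD = 41

#: Camera exposure times available on the acquisition software for each
#: channel (milliseconds).
FDA_EXPOSURE_CANDIDATES_MS = (100.0, 150.0, 200.0, 300.0, 400.0)
PI_EXPOSURE_CANDIDATES_MS = (600.0, 800.0, 1000.0, 2000.0)

#: Relative tolerance within which two SNR values count as tied
#: (ties are resolved toward the shorter exposure).
_SNR_TIE_RTOL = 1e-6


@dataclass(frozen=True)
class CalibrationConfig:
    """Thresholds and exposure times for both channels.

    ``high`` is fixed at 255 (the 8-bit maximum)."""

    low_fda: int
    low_pi: int
    exposure_fda_ms: float
    exposure_pi_ms: float
    high: int = 255

    def __post_init__(self) -> None:
        for name in ("low_fda", "low_pi"):
            v = getattr(self, name)
            if not 0 <= v <= self.high:
                raise ParameterError(f"{name} must be in [0, {self.high}]")
        if self.high != 255:
            raise ParameterError("high threshold is fixed at 255")
        if self.exposure_fda_ms <= 0 or self.exposure_pi_ms <= 0:
            raise ParameterError("exposures must be positive")

    def low(self, channel: Channel) -> int:
        return self.low_fda if channel == "FDA" else self.low_pi

    def to_dict(self) -> dict:
        return {
            "low_fda": self.low_fda,
            "low_pi": self.low_pi,
            "high": self.high,
            "exposure_fda_ms": self.exposure_fda_ms,
            "exposure_pi_ms": self.exposure_pi_ms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationConfig":
        return cls(
            low_fda=int(d["low_fda"]), low_pi=int(d["low_pi"]),
            exposure_fda_ms=float(d["exposure_fda_ms"]),
            exposure_pi_ms=float(d["exposure_pi_ms"]),
            high=int(d.get("high", 255)),
        )


@dataclass(frozen=True)
class SNRReport:
    """Signal-to-noise summary for one candidate exposure."""

    exposure_ms: float
    snr: float
    saturated_fraction: float

    def __post_init__(self) -> None:
        if self.snr < 0:
            raise ParameterError("snr must be non-negative")
        if not 0.0 <= self.saturated_fraction <= 1.0:
            raise ParameterError("saturated_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# Masks and background
# ---------------------------------------------------------------------------

def robust_background(pixels: np.ndarray, k: float = 3.0) -> float:
    """Robust background level: histogram mode + ``k`` x MAD.

    The mode tracks the background plateau (background pixels dominate a
    bead field) and the median absolute deviation its spread, so the
    estimate is insensitive to the bright minority of cell pixels.
    """
    counts = np.bincount(pixels.ravel(), minlength=256)
    mode = int(np.argmax(counts))
    med = float(np.median(pixels))
    mad = float(np.median(np.abs(pixels.astype(np.int16) - med)))
    return mode + k * mad


def _bead_disk_mask(field: BeadField, beads) -> np.ndarray:
    """Boolean mask of the interiors of the given beads."""
    rows, cols = field.fda.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    mask = np.zeros((rows, cols), dtype=bool)
    for b in beads:
        r = b.diameter_um / 2.0 / field.pixel_size_um
        cx, cy = b.center_xy
        mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    return mask


def cell_pixel_mask(field: BeadField, channel: Channel) -> np.ndarray:
    """Pixels "representing cells" for SNR and threshold fitting.

    Synthetic fields use the ground-truth interiors of the beads that
    contain cells for this channel (live beads for FDA, dead for PI);
    real fields fall back to a provisional Otsu split of the channel
    image.
    """
    if field.truth is not None:
        attr = "n_live" if channel == "FDA" else "n_dead"
        beads = [b for b in field.truth.beads if getattr(b, attr) > 0]
        return _bead_disk_mask(field, beads)
    from skimage.filters import threshold_otsu

    img = field.channel(channel).pixels
    return img > threshold_otsu(img)


# ---------------------------------------------------------------------------
# Exposure selection
# ---------------------------------------------------------------------------

def _group_by_exposure(fields: Iterable[BeadField], channel: Channel,
                       ) -> dict[float, list[BeadField]]:
    groups: dict[float, list[BeadField]] = {}
    for f in fields:
        groups.setdefault(f.channel(channel).exposure_ms, []).append(f)
    return groups


def select_exposure(fields: Sequence[BeadField], channel: Channel,
                    candidates: Sequence[float],
                    max_saturated_fraction: float = 0.01,
                    ) -> tuple[float, list[SNRReport]]:
    """Choose the candidate exposure maximising SNR without saturation.

    SNR is the sum intensity over cell pixels divided by the sum
    intensity over non-cell pixels, pooled across the fields acquired at
    each candidate.  Candidates whose fraction of saturated (255) pixels
    exceeds ``max_saturated_fraction`` are excluded; SNR ties within
    1e-6 relative resolve toward the shorter exposure.

    Returns the chosen exposure and one :class:`SNRReport` per candidate
    (in candidate order, including excluded ones).
    """
    if len(candidates) == 0:
        raise ParameterError("candidate exposure list is empty")
    groups = _group_by_exposure(fields, channel)
    missing = [c for c in candidates if c not in groups]
    if missing:
        raise ParameterError(
            f"no field acquired at candidate exposure(s) {missing} for {channel}")

    reports: list[SNRReport] = []
    for cand in candidates:
        cell_sum = 0.0
        bg_sum = 0.0
        n_sat = 0
        n_px = 0
        for f in groups[cand]:
            img = f.channel(channel).pixels
            mask = cell_pixel_mask(f, channel)
            img64 = img.astype(np.int64)
            cell_sum += float(img64[mask].sum())
            bg_sum += float(img64[~mask].sum())
            n_sat += int((img == 255).sum())
            n_px += img.size
        snr = cell_sum / bg_sum if bg_sum > 0 else np.inf
        reports.append(SNRReport(cand, snr, n_sat / n_px))

    eligible = [r for r in reports
                if r.saturated_fraction <= max_saturated_fraction]
    if not eligible:
        raise CalibrationError(
            "all candidate exposures exceed the saturation limit "
            f"({max_saturated_fraction:.3g})")
    best = max(r.snr for r in eligible)
    tied = [r for r in eligible if r.snr >= best * (1.0 - _SNR_TIE_RTOL)]
    chosen = min(tied, key=lambda r: r.exposure_ms)
    return chosen.exposure_ms, reports


# ---------------------------------------------------------------------------
# Low-threshold fitting
# ---------------------------------------------------------------------------

def _per_field_threshold(field: BeadField, channel: Channel, k: float,
                         ) -> int | None:
    """Per-field low threshold, or ``None`` when no cells are detectable.

    Operationalises "capturing all pixels with visible cells" as the
    minimum integer level above the robust background estimate that
    still retains every connected cell region; raising the level can
    only lose regions, so this is the first level above background,
    provided every populated region reaches it.
    """
    img = field.channel(channel).pixels
    t0 = int(np.floor(robust_background(img, k=k))) + 1
    if t0 > 255:
        return None
    mask = cell_pixel_mask(field, channel)
    labels, n_regions = ndimage.label(mask)
    if n_regions == 0:
        return None
    maxima = ndimage.labeled_comprehension(
        img, labels, np.arange(1, n_regions + 1), np.max, int, 0)
    if np.min(maxima) < t0:
        if np.max(maxima) < t0:
            return None  # nothing above background anywhere
        warnings.warn(
            f"{int((maxima < t0).sum())} cell region(s) never rise above the "
            "background estimate and cannot be captured by any threshold",
            stacklevel=3)
    return t0


def fit_low_threshold(fields: Sequence[BeadField], channel: Channel,
                      k: float = 3.0) -> int:
    """Low threshold for one channel: rounded mean of per-field values.

    Each field contributes the smallest integer level that separates its
    background from its cell pixels (see :func:`_per_field_threshold`);
    fields without detectable cells are excluded with a warning.  The
    recommended input is 10 fields of 40-60 beads each, including
    high-density samples; fewer trigger a warning, not an error.
    """
    if len(fields) == 0:
        raise ParameterError("at least one field is required")
    if len(fields) < 10:
        warnings.warn(
            f"low-threshold fit uses {len(fields)} field(s); 10 images of "
            "40-60 beads are recommended", stacklevel=2)
    per_field: list[int] = []
    for i, f in enumerate(fields):
        if f.truth is not None:
            nb = len(f.truth.beads)
            if not 40 <= nb <= 60:
                warnings.warn(
                    f"field {i} has {nb} beads; 40-60 per image recommended",
                    stacklevel=2)
        t = _per_field_threshold(f, channel, k)
        if t is None:
            warnings.warn(f"field {i} has no detectable cells; excluded",
                          stacklevel=2)
            continue
        per_field.append(t)
    if not per_field:
        raise CalibrationError(
            f"no field contained detectable {channel} cells")
    mean = float(np.mean(per_field))
    return int(np.floor(mean + 0.5))  # round half-up, documented convention


# ---------------------------------------------------------------------------
# PI set-up matching
# ---------------------------------------------------------------------------

def _sum_intensity_by_threshold(images: Sequence[ChannelImage]) -> np.ndarray:
    """``s[t]`` = pooled sum of grey levels of pixels in ``[t, 255]``."""
    counts = np.zeros(256, dtype=np.int64)
    for im in images:
        counts += np.bincount(im.pixels.ravel(), minlength=256)
    weighted = counts * np.arange(256, dtype=np.int64)
    return weighted[::-1].cumsum()[::-1]


def _cells_in(fields: Iterable[BeadField], which: str) -> int:
    total = 0
    for f in fields:
        if f.truth is None:
            raise ParameterError(
                "signal-equivalence matching needs known cell counts "
                "(ground truth or matched aliquots)")
        total += getattr(f.truth, which)
    return total


def match_pi_setup(dead_fields: Sequence[BeadField],
                   live_fields: Sequence[BeadField],
                   pi_candidates: Sequence[float],
                   tolerance: float = 0.05,
                   k: float = 3.0) -> CalibrationConfig:
    """Match the PI set-up to the FDA set-up on control fields.

    ``live_fields`` are ~100%-viability controls defining the FDA
    reference (fitted low threshold, mean FDA sum intensity per live
    cell); ``dead_fields`` are 0%-viability controls acquired at each
    candidate PI exposure.  The (exposure, low threshold) pair whose
    mean PI sum intensity per dead cell best matches the FDA reference
    is returned, provided the relative mismatch is within ``tolerance``;
    thresholds are scanned only above the robust background so the match
    can never be bought with background pixels.  Ties prefer the shorter
    exposure, then the lower threshold.
    """
    if not dead_fields or not live_fields:
        raise ParameterError("both live and dead control fields are required")
    if len(pi_candidates) == 0:
        raise ParameterError("candidate exposure list is empty")

    fda_exposures = {f.fda.exposure_ms for f in live_fields}
    if len(fda_exposures) != 1:
        raise ParameterError("live fields must share one FDA exposure")
    exposure_fda = fda_exposures.pop()

    low_fda = fit_low_threshold(live_fields, "FDA", k=k)
    s_fda = _sum_intensity_by_threshold([f.fda for f in live_fields])
    n_live = _cells_in(live_fields, "n_live")
    if n_live == 0:
        raise ParameterError("live control fields contain no live cells")
    ref = s_fda[low_fda] / n_live

    groups = _group_by_exposure(dead_fields, "PI")
    present = [c for c in pi_candidates if c in groups]
    if not present:
        raise ParameterError(
            "no dead control field acquired at any candidate PI exposure "
            f"{list(pi_candidates)}")
    missing = [c for c in pi_candidates if c not in groups]
    if missing:
        warnings.warn(f"no dead control field at PI exposure(s) {missing}; "
                      "matching over the remaining candidates", stacklevel=2)

    best: tuple[float, float, int] | None = None  # (mismatch, exposure, t)
    for cand in present:
        flds = groups[cand]
        n_dead = _cells_in(flds, "n_dead")
        if n_dead == 0:
            warnings.warn(f"dead fields at {cand} ms contain no dead cells; "
                          "candidate skipped", stacklevel=2)
            continue
        t0 = max(int(np.floor(robust_background(f.pi.pixels, k=k))) + 1
                 for f in flds)
        t0 = min(t0, 255)
        s_pi = _sum_intensity_by_threshold([f.pi for f in flds])
        for t in range(t0, 256):
            mism = abs(s_pi[t] / n_dead - ref) / ref
            cand_key = (mism, cand, t)
            if best is None or cand_key < best:
                best = cand_key
    if best is None:
        raise CalibrationError("no usable dead control fields")
    mismatch, exposure_pi, low_pi = best
    if mismatch > tolerance:
        raise CalibrationError(
            f"signal-equivalence matching failed: best achievable mismatch "
            f"{mismatch:.3f} exceeds tolerance {tolerance:.3f} "
            f"(PI exposure {exposure_pi:g} ms, low threshold {low_pi})",
            best_mismatch=mismatch)
    return CalibrationConfig(
        low_fda=low_fda, low_pi=low_pi,
        exposure_fda_ms=exposure_fda, exposure_pi_ms=exposure_pi)


# ---------------------------------------------------------------------------
# Filter overspill check
# ---------------------------------------------------------------------------

def check_overspill(fields: Sequence[BeadField],
                    config: CalibrationConfig | None = None,
                    limit: float = 0.01,
                    k: float = 3.0) -> dict:
    """Quantify optical crosstalk between the green and red filters.

    Fields must carry single-channel-only content (all-live or all-dead
    controls; background-only fields contribute nothing).  For each
    direction the report gives the above-threshold sum intensity in the
    *wrong* channel as a fraction of the above-threshold sum intensity
    in the source channel, pooled across fields.  ``pass`` requires both
    fractions below ``limit``.
    """
    if not fields:
        raise ParameterError("at least one field is required")
    sums = {"FDA": 0.0, "PI": 0.0}        # source-channel signal
    leaks = {"fda_into_pi": 0.0, "pi_into_fda": 0.0}
    for f in fields:
        if f.truth is None:
            raise ParameterError("overspill check requires ground truth")
        if f.truth.n_live > 0 and f.truth.n_dead > 0:
            raise ParameterError(
                "overspill check requires single-channel-only fields "
                "(all-live or all-dead)")
        if f.truth.n_cells == 0:
            continue
        source: Channel = "FDA" if f.truth.n_live > 0 else "PI"
        other: Channel = "PI" if source == "FDA" else "FDA"
        for ch_name in (source, other):
            img = f.channel(ch_name).pixels
            if config is not None:
                low = config.low(ch_name)
            else:
                low = min(int(np.floor(robust_background(img, k=k))) + 1, 255)
            s = float(img[img >= low].astype(np.int64).sum())
            if ch_name == source:
                sums[source] += s
            elif source == "FDA":
                leaks["fda_into_pi"] += s
            else:
                leaks["pi_into_fda"] += s
    fda_into_pi = leaks["fda_into_pi"] / sums["FDA"] if sums["FDA"] > 0 else 0.0
    pi_into_fda = leaks["pi_into_fda"] / sums["PI"] if sums["PI"] > 0 else 0.0
    return {
        "fda_into_pi": fda_into_pi,
        "pi_into_fda": pi_into_fda,
        "pass": fda_into_pi < limit and pi_into_fda < limit,
    }
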