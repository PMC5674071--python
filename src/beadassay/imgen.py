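"""Synthetic dual-channel bead-field generator.

Renders fields of ~500 µm alginate beads containing 3-D cell spheroids as
a registered pair of 8-bit grayscale fluorescence channels: FDA (green,
esterase product of viable cells) and PI (red, nuclei of dead cells).
Every generated field carries its ground truth (per-bead live/dead
counts), so calibration and quantification can be validated against known
compositions without real micrographs.

Rendering model
---------------
Each cell is a Gaussian blob of configurable width placed uniformly inside
its bead's circle.  A cell contributes a fixed *integrated* grey-level sum
(``per_cell_intensity`` at the channel's reference exposure), scaled
linearly with exposure time.  Blobs are accumulated as point masses on the
pixel grid and convolved once per channel with a normalised Gaussian
kernel, so the total pre-clipping signal is exactly
``n_cells x per_cell_intensity x exposure / reference_exposure`` whenever
beads keep the configured margin from the image border.  Background is a
constant camera dark offset plus a light-dependent component that scales
with exposure; optional Gaussian read noise is added before quantisation
to 8-bit with clipping at 255.

Geometry (bead diameters, centres, cell positions) and pixel noise are
drawn from separate child streams of the field seed, so geometry is stable
when only the noise level changes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ParameterError

__all__ = [
    "BeadSpec",
    "FieldGroundTruth",
    "ChannelImage",
    "BeadField",
    "GeneratorParams",
    "KILL_PRESET_MINUTES",
    "DEFAULT_KILL_RATE_PER_MIN",
    "generate_bead_field",
    "apply_lethal_insult",
    "write_bead_field",
]

Channel = Literal["FDA", "PI"]

#: Me2SO exposure durations (minutes) used for the graded killed controls
#: (samples 1-3 of the validation series).
KILL_PRESET_MINUTES = (5.0, 10.0, 15.0)

#: Default first-order kill rate for the Me2SO insult.  Chosen so the
#: 15-minute preset leaves < 1% of cells alive (exp(-0.35*15) ~ 0.5%).
DEFAULT_KILL_RATE_PER_MIN = 0.35


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeadSpec:
    """One alginate bead: position, size and live/dead cell content."""

    center_xy: tuple[float, float]  # pixel coordinates (x, y)
    diameter_um: float
    n_live: int
    n_dead: int

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ParameterError("bead diameter must be positive")
        if self.n_live < 0 or self.n_dead < 0:
            raise ParameterError("cell counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.n_live + self.n_dead

    @property
    def viability_fraction(self) -> float | None:
        """Live fraction; ``None`` for a cell-free bead."""
        if self.n_cells == 0:
            return None
        return self.n_live / self.n_cells

    @property
    def volume_mL(self) -> float:
        return math.pi / 6.0 * self.diameter_um**3 * 1e-12

    def to_dict(self) -> dict:
        return {
            "center_xy": list(self.center_xy),
            "diameter_um": self.diameter_um,
            "n_live": self.n_live,
            "n_dead": self.n_dead,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BeadSpec":
        return cls(tuple(d["center_xy"]), d["diameter_um"], d["n_live"], d["n_dead"])


@dataclass(frozen=True)
class FieldGroundTruth:
    """Known composition of one generated field.

    ``cells_per_ml_beads`` is the cell density the field was generated at
    (cells per mL of bead volume); the achieved density derived from the
    bead list agrees with it to within rounding (< 1%).
    """

    beads: tuple[BeadSpec, ...]
    cells_per_ml_beads: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "beads", tuple(self.beads))

    @property
    def n_live(self) -> int:
        return sum(b.n_live for b in self.beads)

    @property
    def n_dead(self) -> int:
        return sum(b.n_dead for b in self.beads)

    @property
    def n_cells(self) -> int:
        return self.n_live + self.n_dead

    @property
    def viability_fraction(self) -> float | None:
        if self.n_cells == 0:
            return None
        return self.n_live / self.n_cells

    @property
    def total_bead_volume_mL(self) -> float:
        return sum(b.volume_mL for b in self.beads)

    @property
    def achieved_cells_per_ml_beads(self) -> float:
        v = self.total_bead_volume_mL
        return self.n_cells / v if v > 0 else 0.0

    def to_dict(self) -> dict:
        return {
            "beads": [b.to_dict() for b in self.beads],
            "cells_per_ml_beads": self.cells_per_ml_beads,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FieldGroundTruth":
        return cls(
            tuple(BeadSpec.from_dict(b) for b in d["beads"]),
            d["cells_per_ml_beads"],
        )


@dataclass
class ChannelImage:
    """One fluorescence channel of a field.

    ``pixels`` is the quantised 8-bit image; ``analog`` (kept for synthetic
    images only) is the pre-quantisation, pre-clipping float image used by
    linearity checks.
    """

    pixels: np.ndarray  # uint8, 2-D
    channel: Channel
    exposure_ms: float
    pixel_size_um: float
    analog: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.exposure_ms <= 0:
            raise ParameterError("exposure_ms must be positive")
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be positive")
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ParameterError("pixels must be a 2-D grid")
        if self.pixels.dtype != np.uint8:
            raise ParameterError("pixels must be 8-bit (uint8)")
        if self.channel not in ("FDA", "PI"):
            raise ParameterError(f"unknown channel {self.channel!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BeadField:
    """Registered FDA + PI image pair of one microscope field."""

    fda: ChannelImage
    pi: ChannelImage
    truth: FieldGroundTruth | None = None

    def __post_init__(self) -> None:
        if self.fda.shape != self.pi.shape:
            raise ParameterError("FDA and PI images must have equal dimensions")
        if self.fda.pixel_size_um != self.pi.pixel_size_um:
            raise ParameterError("FDA and PI images must share pixel_size_um")

    def channel(self, name: Channel) -> ChannelImage:
        if name == "FDA":
            return self.fda
        if name == "PI":
            return self.pi
        raise ParameterError(f"unknown channel {name!r}")

    @property
    def pixel_size_um(self) -> float:
        return self.fda.pixel_size_um


# ---------------------------------------------------------------------------
# Generator settings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorParams:
    """Settings for :func:`generate_bead_field`.

    Defaults emulate the validated production conditions: beads of
    525.8 +/- 95 um, 40-60 beads per calibration image, harvest-relevant
    densities around 22e6 cells/mL of beads, and acquisition at 150 ms
    (FDA) / 1000 ms (PI).  ``per_cell_intensity`` is the integrated
    grey-level sum one cell contributes at the channel's reference
    exposure; with equal reference-anchored responses in both channels the
    signal-equivalence requirement of the assay holds by construction at
    (150 ms, 1000 ms).
    """

    n_beads: int = 45
    bead_diameter_mean_um: float = 525.8
    bead_diameter_sd_um: float = 95.0
    cells_per_ml_beads: float = 22e6
    viability_fraction: float = 1.0
    per_cell_intensity: float = 1200.0  # grey-level sum / cell at reference exposure
    background_level: float = 2.0       # light-dependent background at reference exposure
    dark_offset: float = 1.0            # exposure-independent camera offset
    noise_sd: float = 1.0               # Gaussian read noise (grey levels)
    exposure_fda_ms: float = 150.0
    exposure_pi_ms: float = 1000.0
    reference_exposure_fda_ms: float = 150.0
    reference_exposure_pi_ms: float = 1000.0
    pixel_size_um: float = 4.0          # a 525 um bead spans ~131 px (x4 objective)
    shape: tuple[int, int] = (1280, 1280)  # rows, cols
    cell_sigma_um: float = 15.0         # blob width ~ one cell diameter
    crosstalk_fda_to_pi: float = 0.0    # fraction of FDA-channel signal leaking into PI
    crosstalk_pi_to_fda: float = 0.0
    fda_density_halfsat_per_ml: float = 0.0  # >0 dims FDA at low density (off by default)
    touching_pair_overlap: float = 0.0  # >0 places beads 0,1 overlapping by this radius fraction
    min_bead_diameter_um: float = 50.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.viability_fraction <= 1.0:
            raise ParameterError("viability_fraction must be in [0, 1]")
        if self.n_beads < 1:
            raise ParameterError("n_beads must be >= 1")
        for name in ("bead_diameter_mean_um", "pixel_size_um", "cell_sigma_um",
                     "exposure_fda_ms", "exposure_pi_ms",
                     "reference_exposure_fda_ms", "reference_exposure_pi_ms"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("bead_diameter_sd_um", "cells_per_ml_beads", "per_cell_intensity",
                     "background_level", "dark_offset", "noise_sd",
                     "crosstalk_fda_to_pi", "crosstalk_pi_to_fda",
                     "fda_density_halfsat_per_ml", "touching_pair_overlap"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if len(self.shape) != 2 or min(self.shape) < 16:
            raise ParameterError("shape must be a (rows, cols) pair of at least 16 px")

    def exposure_ms(self, channel: Channel) -> float:
        return self.exposure_fda_ms if channel == "FDA" else self.exposure_pi_ms

    def reference_exposure_ms(self, channel: Channel) -> float:
        return (self.reference_exposure_fda_ms if channel == "FDA"
                else self.reference_exposure_pi_ms)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``targets``.

    Floors each target and hands out the remaining units in order of
    decreasing fractional part (ties broken by index), so the allocation
    sums exactly to ``total``.
    """
    base = np.floor(targets).astype(int)
    short = total - int(base.sum())
    if short > 0:
        frac = targets - np.floor(targets)
        order = np.argsort(-frac, kind="stable")
        base[order[:short]] += 1
    elif short < 0:  # degenerate: rounding overshoot, trim largest bases
        order = np.argsort(-base, kind="stable")
        for i in order[: -short]:
            base[i] -= 1
    return base


def _sample_diameters(rng: np.random.Generator, n: int, mean_um: float,
                      sd_um: float, min_um: float) -> np.ndarray:
    """Normal bead diameters, resampled below ``min_um`` (negligible mass
    for the default 525.8 +/- 95 um population)."""
    d = rng.normal(mean_um, sd_um, size=n)
    bad = d < min_um
    while bad.any():
        d[bad] = rng.normal(mean_um, sd_um, size=int(bad.sum()))
        bad = d < min_um
    return d


def _place_beads(rng: np.random.Generator, radii_px: np.ndarray,
                 shape: tuple[int, int], margin_px: float,
                 touching_pair_overlap: float) -> np.ndarray:
    """Rejection-sample non-overlapping centres (x, y); beads keep
    ``margin_px`` beyond their radius from the border.

    Sequential placement can jam at high packing fractions, so the
    whole layout is restarted (fresh draws from the same stream) when a
    bead exhausts its attempt budget; only a repeatedly jammed layout is
    a parameter error."""
    n = len(radii_px)
    rows, cols = shape
    centers = np.empty((n, 2))
    placed = 0
    attempts = 0
    restarts = 0
    max_attempts = 500 * n
    pair_pending = touching_pair_overlap > 0 and n >= 2
    while placed < n:
        if attempts > max_attempts:
            restarts += 1
            if restarts > 50:
                raise ParameterError(
                    "could not place beads without overlap; reduce n_beads "
                    "or bead diameter, or enlarge the image"
                )
            placed = 0
            attempts = 0
        attempts += 1
        r = radii_px[placed]
        lo_x, hi_x = r + margin_px, cols - 1 - r - margin_px
        lo_y, hi_y = r + margin_px, rows - 1 - r - margin_px
        if hi_x <= lo_x or hi_y <= lo_y:
            raise ParameterError("image too small for the requested bead size")
        c = np.array([rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y)])
        ok = True
        for j in range(placed):
            gap = 2.0
            if pair_pending and placed == 1 and j == 0:
                continue  # bead 1 is positioned relative to bead 0 below
            if np.hypot(*(c - centers[j])) < r + radii_px[j] + gap:
                ok = False
                break
        if not ok:
            continue
        if pair_pending and placed == 1:
            # controlled touching pair: centre distance r0 + r1 minus the
            # requested fraction of the smaller radius
            r0, r1 = radii_px[0], radii_px[1]
            dist = r0 + r1 - touching_pair_overlap * min(r0, r1)
            theta = rng.uniform(0, 2 * math.pi)
            c = centers[0] + dist * np.array([math.cos(theta), math.sin(theta)])
            if not (lo_x <= c[0] <= hi_x and lo_y <= c[1] <= hi_y):
                continue
            clash = False
            for j in range(1, placed):
                if np.hypot(*(c - centers[j])) < r + radii_px[j] + 2.0:
                    clash = True
                    break
            if clash:
                continue
        centers[placed] = c
        placed += 1
    return centers


def _render_channel(delta: np.ndarray, sigma_px: float) -> np.ndarray:
    """Convolve accumulated point masses with a normalised Gaussian.

    scipy's truncated kernel is normalised to unit sum, so the total
    signal of interior sources is conserved exactly."""
    return gaussian_filter(delta, sigma_px, mode="constant", truncate=4.0)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def generate_bead_field(params: GeneratorParams, seed: int) -> BeadField:
    """Generate one synthetic dual-channel bead field.

    Live cells contribute signal only to the FDA channel and dead cells
    only to the PI channel (plus any configured crosstalk).  Identical
    ``(params, seed)`` give bit-identical output.

    Parameters
    ----------
    params
        Generator settings; see :class:`GeneratorParams`.
    seed
        Integer seed for the field.  Geometry and noise use separate
        child streams, so geometry is unchanged when only ``noise_sd``
        differs.
    """
    ss = np.random.SeedSequence(seed)
    geom_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    px = params.pixel_size_um
    diameters = _sample_diameters(
        geom_rng, params.n_beads, params.bead_diameter_mean_um,
        params.bead_diameter_sd_um, params.min_bead_diameter_um)
    radii_px = diameters / 2.0 / px
    sigma_px = params.cell_sigma_um / px  # blob sigma ~ one cell diameter
    margin_px = 4.0 * sigma_px + 2.0
    centers = _place_beads(geom_rng, radii_px, params.shape, margin_px,
                           params.touching_pair_overlap)

    # integer cell allocation: total = density x total bead volume,
    # distributed by largest remainder, then split into live/dead
    volumes = math.pi / 6.0 * diameters**3 * 1e-12  # mL
    cell_targets = params.cells_per_ml_beads * volumes
    n_cells = _largest_remainder(cell_targets, int(round(cell_targets.sum())))
    live_total = int(round(params.viability_fraction * n_cells.sum()))
    n_live = _largest_remainder(params.viability_fraction * n_cells, live_total)
    n_live = np.minimum(n_live, n_cells)
    n_dead = n_cells - n_live

    rows, cols = params.shape
    delta_fda = np.zeros((rows, cols), dtype=np.float64)
    delta_pi = np.zeros((rows, cols), dtype=np.float64)

    fda_scale = params.per_cell_intensity * (
        params.exposure_fda_ms / params.reference_exposure_fda_ms)
    if params.fda_density_halfsat_per_ml > 0:
        # optional low-density dimming of the esterase product signal
        d = params.cells_per_ml_beads
        fda_scale *= d / (d + params.fda_density_halfsat_per_ml)
    pi_scale = params.per_cell_intensity * (
        params.exposure_pi_ms / params.reference_exposure_pi_ms)

    beads = []
    for i in range(params.n_beads):
        k = int(n_cells[i])
        beads.append(BeadSpec(
            center_xy=(float(centers[i, 0]), float(centers[i, 1])),
            diameter_um=float(diameters[i]),
            n_live=int(n_live[i]),
            n_dead=int(n_dead[i]),
        ))
        if k == 0:
            continue
        # uniform positions inside the bead circle; first n_live are live,
        # so the same geometry stream yields identical positions whatever
        # the live/dead split
        rr = radii_px[i] * np.sqrt(geom_rng.uniform(size=k))
        th = geom_rng.uniform(0.0, 2.0 * math.pi, size=k)
        x = centers[i, 0] + rr * np.cos(th)
        y = centers[i, 1] + rr * np.sin(th)
        ix = np.clip(np.rint(x).astype(int), 0, cols - 1)
        iy = np.clip(np.rint(y).astype(int), 0, rows - 1)
        nl = int(n_live[i])
        np.add.at(delta_fda, (iy[:nl], ix[:nl]), fda_scale)
        np.add.at(delta_pi, (iy[nl:], ix[nl:]), pi_scale)

    sig_fda = _render_channel(delta_fda, sigma_px)
    sig_pi = _render_channel(delta_pi, sigma_px)
    if params.crosstalk_fda_to_pi > 0:
        sig_pi = sig_pi + params.crosstalk_fda_to_pi * sig_fda
    if params.crosstalk_pi_to_fda > 0:
        sig_fda = sig_fda + params.crosstalk_pi_to_fda * sig_pi

    truth = FieldGroundTruth(tuple(beads), params.cells_per_ml_beads)
    channels = {}
    for name, sig in (("FDA", sig_fda), ("PI", sig_pi)):
        exp = params.exposure_ms(name)
        bg = params.dark_offset + params.background_level * (
            exp / params.reference_exposure_ms(name))
        analog = sig + bg
        if params.noise_sd > 0:
            analog = analog + noise_rng.normal(0.0, params.noise_sd, size=analog.shape)
        pixels = np.clip(np.rint(analog), 0, 255).astype(np.uint8)
        channels[name] = ChannelImage(
            pixels=pixels, channel=name, exposure_ms=exp,
            pixel_size_um=px, analog=analog)
    return BeadField(fda=channels["FDA"], pi=channels["PI"], truth=truth)


def apply_lethal_insult(truth: FieldGroundTruth, minutes: float,
                        rate_per_min: float = DEFAULT_KILL_RATE_PER_MIN,
                        ) -> FieldGroundTruth:
    """Convert live cells to dead after a timed Me2SO insult.

    Survival follows first-order decay ``exp(-rate_per_min * minutes)``;
    the default rate leaves < 1% viability after the 15-minute preset.
    Total cell count is conserved per bead.
    """
    if minutes < 0:
        raise ParameterError("insult duration must be non-negative")
    if rate_per_min < 0:
        raise ParameterError("kill rate must be non-negative")
    surv = math.exp(-rate_per_min * minutes)
    beads = []
    for b in truth.beads:
        nl = int(round(b.n_live * surv))
        beads.append(replace(b, n_live=nl, n_dead=b.n_dead + (b.n_live - nl)))
    return FieldGroundTruth(tuple(beads), truth.cells_per_ml_beads)


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def _format_ms(exposure_ms: float) -> str:
    return f"{exposure_ms:g}"


def write_bead_field(field: BeadField, outdir: str | Path, stem: str,
                     seed: int | None = None) -> dict[str, Path]:
    """Write a field as two 8-bit grayscale TIFFs plus a JSON sidecar.

    Files follow ``<stem>_<channel>_<exposure_ms>ms.tif``; the sidecar
    ``<stem>_meta.json`` records channel metadata, the seed and (for
    synthetic fields) the ground truth.
    """
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    meta: dict = {"pixel_size_um": field.pixel_size_um, "channels": {}}
    if seed is not None:
        meta["seed"] = int(seed)
    for ch in (field.fda, field.pi):
        name = f"{stem}_{ch.channel}_{_format_ms(ch.exposure_ms)}ms.tif"
        path = outdir / name
        tifffile.imwrite(path, ch.pixels, photometric="minisblack")
        meta["channels"][ch.channel] = {
            "file": name,
            "exposure_ms": ch.exposure_ms,
            "pixel_size_um": ch.pixel_size_um,
        }
        paths[ch.channel] = path
    if field.truth is not None:
        meta["truth"] = field.truth.to_dict()
    sidecar = outdir / f"{stem}_meta.json"
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))
    paths["sidecar"] = sidecar
    return paths
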