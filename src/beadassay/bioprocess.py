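"""Bioreactor-side quantifications for the fluidised-bed bioprocess.

Mass-balance and normalisation metrics for a perfused fluidised-bed
bioreactor (FBB) fed from a single-use stirred-tank bioreactor (SUB):
nutrient-bound monitoring against the process safety levels, per-cell
oxygen consumption from the pre/post-chamber dissolved-oxygen (DO)
difference, production-efficiency comparison of media regimes,
viability-drop summaries, per-cell functional-value and secretion-rate
normalisations, protein AUC, the biomass:media ratio and the DO
setpoint escalation rule.

Time series arrive as CSV with documented headers (see
:meth:`ProcessLog.from_csv` and :meth:`ConcentrationSeries.from_csv`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError

__all__ = [
    "ProcessLog",
    "MediaRegime",
    "ConcentrationSeries",
    "DOEscalationConfig",
    "DEFAULT_MEDIA_REGIME",
    "ALTERNATE_MEDIA_REGIME",
    "GLUCOSE_MIN_MM",
    "LACTATE_MAX_MM",
    "DEFAULT_O2_SATURATION_UM",
    "BILIRUBIN_MW_G_PER_MOL",
    "ADULT_BILIRUBIN_REFERENCE_MG_PER_DAY",
    "VALIDATED_BILIRUBIN_FUNCTIONAL_VALUE",
    "check_nutrient_bounds",
    "oxygen_consumption_per_cell",
    "production_efficiency",
    "viability_drop_summary",
    "functional_value_bilirubin",
    "secretion_rate",
    "protein_auc_mg",
    "do_setpoint_recipe",
    "media_biomass_ratio",
]

#: Process safety bounds: glucose must stay strictly above, lactate
#: strictly below, these levels (mM).  High lactate destabilises the
#: alginate hydrogel as well as inhibiting growth.
GLUCOSE_MIN_MM = 15.0
LACTATE_MAX_MM = 10.0

#: Dissolved O2 concentration at 100% air saturation, 37 C culture
#: medium (µmol/L).  DO probes report percent of this; the conversion is
#: an explicit argument of :func:`oxygen_consumption_per_cell` because
#: it depends on medium and temperature.
DEFAULT_O2_SATURATION_UM = 200.0

#: Molar mass of bilirubin (g/mol).
BILIRUBIN_MW_G_PER_MOL = 584.66

#: Physiological reference: ~5 mg conjugated bilirubin excreted in urine
#: per adult per day, attributed to ~1e11 liver cells.  Contextual
#: constant for interpreting functional values; not recomputed here.
ADULT_BILIRUBIN_REFERENCE_MG_PER_DAY = 5.0

#: Functional value measured for the day-12 biomass in liver-failure
#: plasma (mg conjugated bilirubin per 1e11 cells per day).  Contextual
#: constant; the underlying raw series is not deposited.
VALIDATED_BILIRUBIN_FUNCTIONAL_VALUE = 88.2


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

def _as_array(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ParameterError(f"{name} must be one-dimensional")
    return a


@dataclass
class ProcessLog:
    """Time series of bioreactor state.

    All arrays share one length; ``time_h`` must be strictly increasing
    and concentrations, flows and counts non-negative.
    """

    time_h: np.ndarray
    glucose_mM: np.ndarray
    lactate_mM: np.ndarray
    do_sub_pct: np.ndarray        # DO1, pre-chamber (SUB)
    do_post_pct: np.ndarray      # DO2, post-chamber
    flow_mL_min: np.ndarray
    cell_count: np.ndarray
    biomass_volume_L: np.ndarray
    media_volume_L: np.ndarray

    COLUMNS = ("time_h", "glucose_mM", "lactate_mM", "do_sub_pct",
               "do_post_pct", "flow_mL_min", "cell_count",
               "biomass_volume_L", "media_volume_L")

    def __post_init__(self) -> None:
        n = None
        for name in self.COLUMNS:
            a = _as_array(getattr(self, name), name)
            setattr(self, name, a)
            if n is None:
                n = len(a)
            elif len(a) != n:
                raise ParameterError("all log columns must share one length")
        if n == 0:
            raise ParameterError("process log is empty")
        if np.any(np.diff(self.time_h) <= 0):
            raise ParameterError("time_h must be strictly increasing")
        for name in ("glucose_mM", "lactate_mM", "flow_mL_min", "cell_count"):
            if np.any(getattr(self, name) < 0):
                raise ParameterError(f"{name} must be non-negative")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ProcessLog":
        """Read a log from CSV with the documented column headers."""
        df = pd.read_csv(path)
        missing = [c for c in cls.COLUMNS if c not in df.columns]
        if missing:
            raise InputError(f"process log {path} lacks column(s) {missing}")
        return cls(**{c: df[c].to_numpy(dtype=float) for c in cls.COLUMNS})

    def __len__(self) -> int:
        return len(self.time_h)


@dataclass(frozen=True)
class MediaRegime:
    """Batch media-change schedule: (culture day, percent replaced)."""

    schedule: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "schedule", tuple(
            (float(d), float(p)) for d, p in self.schedule))
        days = [d for d, _ in self.schedule]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ParameterError("media-change days must increase")
        if any(not 0 < p <= 100 for _, p in self.schedule):
            raise ParameterError("replacement percent must be in (0, 100]")


#: Shipped default schedule (regime 2): 50% on day 4, 50-60% on day 7
#: (represented as 60), 70% on day 9, 80% on day 11.
DEFAULT_MEDIA_REGIME = MediaRegime(((4, 50), (7, 60), (9, 70), (11, 80)))

#: Earlier regime (regime 1): a 25% change on day 5 instead of 50% on
#: day 4, with further changes on days 7 and 11; later-day proportions
#: follow the default escalation.
ALTERNATE_MEDIA_REGIME = MediaRegime(((5, 25), (7, 50), (11, 80)))


@dataclass
class ConcentrationSeries:
    """Concentration time series in a perfused compartment.

    ``conc`` units are declared via ``unit`` (``"ng/mL"`` for proteins,
    ``"umol/L"`` for bilirubin).  ``volume_L`` may be a scalar or a
    per-sample array.
    """

    time_h: np.ndarray
    conc: np.ndarray
    volume_L: np.ndarray
    unit: str = "ng/mL"

    def __post_init__(self) -> None:
        self.time_h = _as_array(self.time_h, "time_h")
        self.conc = _as_array(self.conc, "conc")
        vol = np.asarray(self.volume_L, dtype=float)
        if vol.ndim == 0:
            vol = np.full_like(self.time_h, float(vol))
        self.volume_L = _as_array(vol, "volume_L")
        if not (len(self.time_h) == len(self.conc) == len(self.volume_L)):
            raise ParameterError("series columns must share one length")
        if np.any(np.diff(self.time_h) <= 0):
            raise ParameterError("time_h must be strictly increasing")
        if np.any(self.volume_L <= 0):
            raise ParameterError("volume_L must be positive")

    @classmethod
    def from_csv(cls, path: str | Path, unit: str = "ng/mL",
                 ) -> "ConcentrationSeries":
        """Read from CSV with columns ``time_h, conc, volume_L``."""
        df = pd.read_csv(path)
        missing = [c for c in ("time_h", "conc", "volume_L")
                   if c not in df.columns]
        if missing:
            raise InputError(f"series {path} lacks column(s) {missing}")
        return cls(df["time_h"].to_numpy(float), df["conc"].to_numpy(float),
                   df["volume_L"].to_numpy(float), unit=unit)

    def __len__(self) -> int:
        return len(self.time_h)


@dataclass(frozen=True)
class DOEscalationConfig:
    """DO setpoint escalation rule configuration.

    ``low_trigger_pct`` (the post-chamber DO level below which the SUB
    setpoint escalates) has no shipped default: it is a site-specific
    control parameter and must be chosen for the installation.
    """

    low_trigger_pct: float
    setpoints: tuple[float, ...] = (21.0, 35.0)

    def __post_init__(self) -> None:
        if len(self.setpoints) < 1:
            raise ParameterError("at least one setpoint is required")
        if any(b <= a for a, b in zip(self.setpoints, self.setpoints[1:])):
            raise ParameterError("setpoints must be strictly increasing")


# ---------------------------------------------------------------------------
# Monitoring
# ---------------------------------------------------------------------------

def check_nutrient_bounds(log: ProcessLog,
                          glucose_min_mM: float = GLUCOSE_MIN_MM,
                          lactate_max_mM: float = LACTATE_MAX_MM,
                          ) -> list[dict]:
    """Flag samples violating the nutrient safety bounds.

    Bounds are strict as specified for the process — glucose must stay
    *above* 15 mM and lactate *below* 10 mM — so a sample exactly on a
    bound is a violation.
    """
    violations: list[dict] = []
    for t, g, l in zip(log.time_h, log.glucose_mM, log.lactate_mM):
        if g <= glucose_min_mM:
            violations.append({"time_h": float(t), "variable": "glucose_mM",
                               "value": float(g), "bound": glucose_min_mM})
        if l >= lactate_max_mM:
            violations.append({"time_h": float(t), "variable": "lactate_mM",
                               "value": float(l), "bound": lactate_max_mM})
    return violations


def oxygen_consumption_per_cell(do_in_pct: float, do_out_pct: float,
                                flow_mL_min: float, cell_count: float,
                                sat_uM: float = DEFAULT_O2_SATURATION_UM,
                                ) -> float:
    """Per-cell oxygen uptake from the chamber DO mass balance.

    The DO drop across the chamber, converted to a concentration via
    ``sat_uM`` (µmol/L at 100% saturation), times the volumetric media
    flow gives the molar uptake rate, divided by the cell number:

        OUR = (ΔDO/100 · sat_uM) [µmol/L] · flow [L/s] / cells · 1e9

    in fmol/cell/s.  A negative result (post-chamber DO above
    pre-chamber) is returned as-is with a warning.
    """
    if cell_count <= 0:
        raise ParameterError("cell_count must be positive")
    if flow_mL_min < 0:
        raise ParameterError("flow must be non-negative")
    if sat_uM <= 0:
        raise ParameterError("sat_uM must be positive")
    delta_uM = (do_in_pct - do_out_pct) / 100.0 * sat_uM
    flow_L_s = flow_mL_min / 1000.0 / 60.0
    fmol = delta_uM * flow_L_s / cell_count * 1e9
    if fmol < 0:
        warnings.warn("post-chamber DO exceeds pre-chamber DO; "
                      "negative consumption reported", stacklevel=2)
    return fmol


def production_efficiency(density_old: float, density_new: float,
                          ) -> tuple[int, float]:
    """Percent improvement in harvest cell density between regimes.

    Returns ``(rounded, unrounded)`` percent change
    ``100 (new - old) / old``; rounding is to the nearest integer for
    reporting."""
    if density_old <= 0:
        raise ParameterError("density_old must be positive")
    pct = 100.0 * (density_new - density_old) / density_old
    return int(np.rint(pct)), pct


def viability_drop_summary(pairs: Sequence[tuple[float, float]]) -> dict:
    """Mean and SEM of viability drops over (start%, end%) pairs.

    The SEM is the sample standard deviation (ddof=1) over sqrt(n); it
    is NaN for a single pair."""
    if len(pairs) == 0:
        raise ParameterError("at least one (start, end) pair is required")
    for s, e in pairs:
        if not (0 <= s <= 100 and 0 <= e <= 100):
            raise ParameterError("viability percentages must be in [0, 100]")
    drops = np.array([s - e for s, e in pairs], dtype=float)
    n = len(drops)
    sem = float(drops.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return {"mean_drop": float(drops.mean()), "sem": sem, "n": n}


# ---------------------------------------------------------------------------
# Rates and normalisations
# ---------------------------------------------------------------------------

def _windowed(series: ConcentrationSeries, window_start_h: float,
              window_end_h: float | None):
    sel = series.time_h >= window_start_h
    if window_end_h is not None:
        sel &= series.time_h <= window_end_h
    t = series.time_h[sel]
    c = series.conc[sel]
    v = series.volume_L[sel]
    if len(t) < 2:
        raise ParameterError(
            "at least two samples are required inside the rate window "
            f"[{window_start_h}, {window_end_h if window_end_h is not None else 'end'}] h")
    return t, c, v


def _slope(t: np.ndarray, c: np.ndarray) -> float:
    """Ordinary least-squares slope of concentration vs time."""
    return float(np.polyfit(t, c, 1)[0])


def functional_value_bilirubin(series: ConcentrationSeries, cell_count: float,
                               mw_g_per_mol: float = BILIRUBIN_MW_G_PER_MOL,
                               window_start_h: float = 1.0,
                               window_end_h: float | None = None) -> float:
    """Conjugated-bilirubin functional value: mg per 1e11 cells per day.

    The conjugation rate is the OLS slope of the series (µmol/L/h) over
    the analysis window — the default starts at hour 1 to exclude the
    initial dilution of plasma into the hydrogel — times the treated
    volume, converted to mg/day via the molar mass and normalised to
    1e11 cells (the conventional whole-liver cell number).
    """
    if cell_count <= 0:
        raise ParameterError("cell_count must be positive")
    if series.unit not in ("umol/L", "µmol/L", "uM"):
        raise ParameterError("bilirubin series must be in umol/L")
    if len(series) < 2:
        raise ParameterError("at least two time points are required")
    t, c, v = _windowed(series, window_start_h, window_end_h)
    rate_umol_h = _slope(t, c) * float(v.mean())        # µmol/h in compartment
    mg_day = rate_umol_h * mw_g_per_mol * 1e-3 * 24.0    # µg/µmol -> mg/day
    return mg_day * (1e11 / cell_count)


def secretion_rate(series: ConcentrationSeries, cell_count: float,
                   window_start_h: float = 1.0,
                   window_end_h: float | None = None) -> dict:
    """Protein secretion rate normalised per 1e6 cells.

    The slope (ng/mL/h) times the compartment volume gives the total
    secretion rate in ng/h; reported per 1e6 cells per hour and per day.
    """
    if cell_count <= 0:
        raise ParameterError("cell_count must be positive")
    if series.unit != "ng/mL":
        raise ParameterError("secretion series must be in ng/mL")
    if len(series) < 2:
        raise ParameterError("at least two time points are required")
    t, c, v = _windowed(series, window_start_h, window_end_h)
    ng_per_h = _slope(t, c) * float(v.mean()) * 1000.0   # mL per compartment
    per_million_h = ng_per_h / (cell_count / 1e6)
    return {"ng_per_1e6_cells_per_h": per_million_h,
            "ng_per_1e6_cells_per_day": per_million_h * 24.0,
            "ng_per_h_total": ng_per_h}


def protein_auc_mg(series: ConcentrationSeries) -> float:
    """Trapezoidal AUC of the compartment protein mass over time.

    The per-sample mass is concentration x volume (ng/mL x L x 1000
    -> ng -> mg); the reported number is the trapezoidal area of that
    mass curve over time in hours, the "total mg produced" convention
    used for treatment summaries.  Additive over concatenated windows.
    """
    if series.unit != "ng/mL":
        raise ParameterError("protein series must be in ng/mL")
    if len(series) < 2:
        raise ParameterError("at least two time points are required")
    mass_mg = series.conc * series.volume_L * 1e-3
    return float(np.trapezoid(mass_mg, series.time_h))


# ---------------------------------------------------------------------------
# Control and ratios
# ---------------------------------------------------------------------------

def do_setpoint_recipe(do_post_pct: float, current_setpoint: float,
                       config: DOEscalationConfig) -> float:
    """One step of the SUB DO setpoint escalation recipe.

    The setpoint escalates to the next configured level when the
    post-chamber DO falls below ``config.low_trigger_pct``; it never
    de-escalates within a run and is idempotent at the top level.
    """
    sp = list(config.setpoints)
    if current_setpoint not in sp:
        raise ParameterError(
            f"current setpoint {current_setpoint} not in allowed list {sp}")
    i = sp.index(current_setpoint)
    if i == len(sp) - 1:
        return current_setpoint          # absorbing top state
    if do_post_pct < config.low_trigger_pct:
        return sp[i + 1]
    return current_setpoint


def media_biomass_ratio(biomass_L: float, media_L: float) -> tuple[str, float]:
    """Biomass:media ratio, e.g. 2.5 L beads in 116 L media -> "1:46".

    Returns the rounded ``"1:N"`` string and the unrounded N."""
    if biomass_L <= 0:
        raise ParameterError("biomass volume must be positive")
    if media_L < 0:
        raise ParameterError("media volume must be non-negative")
    n = media_L / biomass_L
    return f"1:{int(np.rint(n))}", n
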