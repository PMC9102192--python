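"""Cell-mechanics processing: Hertz–Sneddon AFM force-curve fitting and
real-time deformability cytometry (RT-DC) event filtering.

AFM side
--------
An approach force–distance curve records cantilever force F (nN) versus
piezo height z (µm). Below the contact point z0 the tip indents the cell
by δ and, for a conical or four-sided pyramidal indenter on an elastic
half-space, the force follows the Hertz–Sneddon law

    F = c(θ) · E / (1 − ν²) · δ²,     c_cone = (2/π)·tanθ,
                                      c_pyramid = 0.7453·tanθ,

with E the Young's modulus (Pa), θ the tip half-angle and ν the Poisson
ratio (0.5 for an incompressible cell). Fitting estimates (E, z0) with
the force baseline F0 taken as the median of the first 20% of the
approach. Indentation is computed from piezo height without cantilever
deflection correction — a known approximation when only force-vs-height
exports are available.

RT-DC side
----------
Events are kept when cell area lies in [70, 2000] µm² (removes debris
and multicellular clusters) and porosity in [1.00, 1.05] (removes
damaged cells); measurements with fewer than 1000 retained events are
flagged. Per-measurement summaries are medians; duplicate measurements
of a treatment are averaged. The deformation→modulus conversion is not
performed here: a precomputed modulus column is consumed as input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar

_PA_UM2_TO_NN = 1e-3  # Pa·µm² = 1e-12 N = 1e-3 nN

E_BOUNDS_PA = (1.0, 1e6)
_MIN_POST_CONTACT = 10
_GRID_STEP_FRACTION = 0.02  # coarse contact-point grid: every 2% of span
_BASELINE_FRACTION = 0.2
_MIN_IMPROVEMENT = 0.01  # relative SSE improvement required to converge


class BiomechError(ValueError):
    """Invalid input to a biomechanics routine."""


# ---------------------------------------------------------------------------
# Indentation model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndenterModel:
    """Tip geometry for the Hertz–Sneddon force law.

    ``half_angle_deg`` is the tip half-opening angle (probe datasheet
    value); ``poisson`` defaults to 0.5, the incompressible-cell
    convention.
    """

    geometry: str = "four_sided_pyramid"
    half_angle_deg: float = 35.0
    poisson: float = 0.5

    def __post_init__(self) -> None:
        if self.geometry not in ("four_sided_pyramid", "cone"):
            raise BiomechError(f"unknown indenter geometry {self.geometry!r}")
        if not 0.0 < self.half_angle_deg < 90.0:
            raise BiomechError("half angle must be in (0, 90) degrees")
        if not 0.0 <= self.poisson < 0.5 + 1e-9:
            raise BiomechError("Poisson ratio must be in [0, 0.5]")

    @property
    def prefactor(self) -> float:
        """Geometry factor c(θ)/(1−ν²) so that F = prefactor·E·δ²."""
        tan = math.tan(math.radians(self.half_angle_deg))
        c = (2.0 / math.pi) * tan if self.geometry == "cone" else 0.7453 * tan
        return c / (1.0 - self.poisson**2)


def model_force(delta_um, E_pa: float, model: IndenterModel) -> np.ndarray:
    """Hertz–Sneddon force (nN) at indentation δ (µm) for modulus E (Pa)."""
    d = np.asarray(delta_um, dtype=float)
    if np.any(d < 0):
        raise BiomechError("indentation must be non-negative")
    return model.prefactor * E_pa * d**2 * _PA_UM2_TO_NN


# ---------------------------------------------------------------------------
# Force curves and fitting
# ---------------------------------------------------------------------------

@dataclass
class ForceCurve:
    """Approach segment of an AFM force–distance record.

    ``height_um`` must be monotone (stored in acquisition order, far
    side first, so the first samples are the force baseline);
    ``force_nN`` has the same length. ``meta`` carries acquisition
    metadata (speed, setpoint, probe id).
    """

    height_um: np.ndarray
    force_nN: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.height_um = np.asarray(self.height_um, dtype=float)
        self.force_nN = np.asarray(self.force_nN, dtype=float)
        if self.height_um.shape != self.force_nN.shape:
            raise BiomechError("height and force arrays differ in length")
        if self.height_um.size < 50:
            raise BiomechError("force curve needs at least 50 samples")
        if not (
            np.all(np.isfinite(self.height_um))
            and np.all(np.isfinite(self.force_nN))
        ):
            raise BiomechError("force curve contains non-finite values")
        d = np.diff(self.height_um)
        if not (np.all(d <= 0) or np.all(d >= 0)):
            raise BiomechError("height must be monotone over the approach")

    @property
    def approach_sign(self) -> int:
        """+1 when height decreases toward contact, -1 when it increases."""
        return 1 if self.height_um[0] >= self.height_um[-1] else -1

    def indentation(self, z0: float) -> np.ndarray:
        """δ(z) = contact-side displacement past z0, clipped at zero."""
        return np.maximum(0.0, self.approach_sign * (z0 - self.height_um))


@dataclass
class FitResult:
    """Hertz–Sneddon fit of one force curve."""

    E_pa: float
    z0_um: float
    F0_nN: float
    rms_residual_nN: float
    converged: bool


def _ls_modulus(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares E for the linear-in-E model y = E·x (x = c·δ²·10⁻³)."""
    denom = float(np.dot(x, x))
    if denom == 0.0:
        return 0.0
    return float(np.dot(x, y) / denom)


def fit_curve(curve: ForceCurve, model: IndenterModel) -> FitResult:
    """Fit (E, z0) to an approach curve with fixed baseline F0.

    F0 is the median force over the first 20% of the approach. Candidate
    contact points are scanned on a coarse grid (every 2% of the height
    span); at each, E follows in closed form by least squares on the
    post-contact region and the total squared residual is evaluated over
    the whole curve. The best grid point is refined by bounded 1-D
    minimisation. The fit is declared non-converged when the best model
    improves on the baseline-only fit by less than 1%, when E lies at
    the search bounds [1 Pa, 1 MPa], or when fewer than 10 samples fall
    past the contact point.
    """
    h = curve.height_um
    f = curve.force_nN
    n = h.size
    n_base = max(1, int(_BASELINE_FRACTION * n))
    F0 = float(np.median(f[:n_base]))
    y = f - F0
    sse0 = float(np.dot(y, y))
    pref = model.prefactor

    def sse_at(z0: float) -> tuple[float, float, int]:
        delta = curve.indentation(z0)
        post = delta > 0
        x = pref * delta**2 * _PA_UM2_TO_NN
        E = _ls_modulus(x[post], y[post])
        resid = y - E * x
        return float(np.dot(resid, resid)), E, int(post.sum())

    lo, hi = float(h.min()), float(h.max())
    step = max((hi - lo) * _GRID_STEP_FRACTION, 1e-12)
    grid = np.arange(lo, hi + step / 2, step)
    results = [(z0,) + sse_at(z0) for z0 in grid]
    valid = [r for r in results if r[3] >= _MIN_POST_CONTACT and r[2] > 0]
    if not valid:
        return FitResult(0.0, float("nan"), F0, math.sqrt(sse0 / n), False)
    z0_best, sse_best, E_best, _ = min(valid, key=lambda r: r[1])

    # local refinement between neighbouring grid points
    lo_ref = max(lo, z0_best - step)
    hi_ref = min(hi, z0_best + step)
    if hi_ref > lo_ref:
        res = minimize_scalar(
            lambda z: sse_at(z)[0], bounds=(lo_ref, hi_ref), method="bounded",
            options={"xatol": step * 1e-6},
        )
        sse_ref, E_ref, npost_ref = sse_at(float(res.x))
        if sse_ref <= sse_best and npost_ref >= _MIN_POST_CONTACT and E_ref > 0:
            z0_best, sse_best, E_best = float(res.x), sse_ref, E_ref

    converged = True
    if sse0 <= 0 or (sse0 - sse_best) / sse0 < _MIN_IMPROVEMENT:
        converged = False
    if not (E_BOUNDS_PA[0] < E_best < E_BOUNDS_PA[1]):
        converged = False
    return FitResult(
        E_pa=float(E_best),
        z0_um=float(z0_best),
        F0_nN=F0,
        rms_residual_nN=math.sqrt(sse_best / n),
        converged=converged,
    )


@dataclass
class ForceMap:
    """n×n grid of force curves with a boolean cell mask."""

    curves: list[list[ForceCurve]]
    cell_mask: np.ndarray

    def __post_init__(self) -> None:
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
        shape = (len(self.curves), len(self.curves[0]) if self.curves else 0)
        if any(len(row) != shape[1] for row in self.curves):
            raise BiomechError("force-map grid is ragged")
        if self.cell_mask.shape != shape:
            raise BiomechError("cell mask shape differs from the curve grid")


@dataclass
class MapSummary:
    E_pa: float  # median over converged masked fits
    converged_fraction: float
    n_masked: int


def summarize_map(force_map: ForceMap, model: IndenterModel) -> MapSummary:
    """Per-cell stiffness: median E over converged fits inside the mask."""
    fits = []
    n_masked = 0
    for i, row in enumerate(force_map.curves):
        for j, curve in enumerate(row):
            if not force_map.cell_mask[i, j]:
                continue
            n_masked += 1
            fits.append(fit_curve(curve, model))
    if n_masked == 0:
        raise BiomechError("cell mask selects no curves")
    converged = [r.E_pa for r in fits if r.converged]
    if not converged:
        raise BiomechError("no converged fits inside the cell mask")
    return MapSummary(
        E_pa=float(np.median(converged)),
        converged_fraction=len(converged) / n_masked,
        n_masked=n_masked,
    )


# ---------------------------------------------------------------------------
# RT-DC filtering and summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RtdcFilterConfig:
    """Closed-interval gates on event area and porosity."""

    area_range_um2: tuple[float, float] = (70.0, 2000.0)
    porosity_range: tuple[float, float] = (1.00, 1.05)
    min_events: int = 1000

    def __post_init__(self) -> None:
        if self.area_range_um2[0] >= self.area_range_um2[1]:
            raise BiomechError("area range lower bound must be below upper")
        if self.porosity_range[0] >= self.porosity_range[1]:
            raise BiomechError("porosity range lower bound must be below upper")


@dataclass
class QcReport:
    n_input: int
    n_retained: int
    n_excluded_area: int
    n_excluded_porosity: int  # area-passing events failing the porosity gate
    low_count: bool  # fewer retained events than the per-measurement minimum


def filter_events(
    events: pd.DataFrame, config: RtdcFilterConfig | None = None
) -> tuple[pd.DataFrame, QcReport]:
    """Gate RT-DC events on area and porosity (closed intervals).

    Events failing the area gate are counted against the area rule;
    area-passing events failing the porosity gate against the porosity
    rule, so exclusion counts and the retained count sum to the input
    count. ``low_count`` flags measurements with fewer retained events
    than ``config.min_events``.
    """
    config = config or RtdcFilterConfig()
    a_lo, a_hi = config.area_range_um2
    p_lo, p_hi = config.porosity_range
    area_ok = (events["area_um2"] >= a_lo) & (events["area_um2"] <= a_hi)
    poro_ok = (events["porosity"] >= p_lo) & (events["porosity"] <= p_hi)
    retained = events[area_ok & poro_ok]
    report = QcReport(
        n_input=len(events),
        n_retained=len(retained),
        n_excluded_area=int((~area_ok).sum()),
        n_excluded_porosity=int((area_ok & ~poro_ok).sum()),
        low_count=len(retained) < config.min_events,
    )
    return retained, report


def summarize_measurement(events: pd.DataFrame) -> dict[str, float]:
    """Medians of modulus, deformation and area over one measurement."""
    if len(events) == 0:
        raise BiomechError("cannot summarise an empty measurement")
    out = {
        "deformation": float(events["deformation"].median()),
        "area_um2": float(events["area_um2"].median()),
    }
    if "emod_kpa" in events.columns:
        out["emod_kpa"] = float(events["emod_kpa"].median())
    return out


def summarize_treatments(
    events: pd.DataFrame,
    measurement_col: str = "measurement",
    treatment_col: str = "treatment",
) -> pd.DataFrame:
    """Average per-measurement medians over duplicate measurements.

    Returns one row per treatment with the mean of its measurements'
    medians for each summarised quantity.
    """
    if len(events) == 0:
        raise BiomechError("no events to summarise")
    rows = []
    for (treat, meas), grp in events.groupby([treatment_col, measurement_col]):
        row = {"treatment": treat, "measurement": meas}
        row.update(summarize_measurement(grp))
        rows.append(row)
    per_meas = pd.DataFrame(rows)
    value_cols = [c for c in per_meas.columns if c not in ("treatment", "measurement")]
    return per_meas.groupby("treatment")[value_cols].mean()


def correlate_moduli(
    afm_kpa: Sequence[float], rtdc_kpa: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation of paired AFM and RT-DC stiffness values."""
    a = np.asarray(afm_kpa, dtype=float)
    b = np.asarray(rtdc_kpa, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise BiomechError("paired modulus vectors of length >= 3 required")
    if np.std(a) == 0 or np.std(b) == 0:
        raise BiomechError("modulus correlation undefined for constant input")
    res = sps.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)
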