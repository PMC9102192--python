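"""Synthetic study data with planted ground truth.

Every input the pipeline consumes can be generated here under one global
seed: a patient cohort with planted mRNA subtypes and lactate-gene
clusters driving survival, colony-plate images with known covered-area
fractions and registration shifts, AFM approach curves with known
Young's moduli, RT-DC event tables with known in-gate flags, and qPCR Ct
tables with known fold changes. Per-generator substreams are derived
deterministically from the global seed, so regeneration with the same
configuration is byte-identical.

The generators emulate the *structure* of the real assays (marker-shift
geometry, stain contrast, contact mechanics, gating bounds, ΔΔCt
arithmetic), not their full biological variability; distributions are
the simplest forms consistent with the downstream analyses (Gaussian on
the standardised expression scale, exponential survival with uniform
censoring).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .biomech import ForceCurve, ForceMap, IndenterModel, model_force
from .subtype import (
    DEFAULT_MARKERS,
    MARKER_GENES,
    SUBTYPES,
    PatientRecord,
)
from .stats import LACTATE_PANEL


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ColonySpec:
    n_images: int = 6
    image_size: tuple[int, int] = (192, 192)
    n_colonies_range: tuple[int, int] = (5, 15)
    radius_range_px: tuple[float, float] = (6.0, 18.0)
    shift_jitter_px: int = 8
    pixel_noise_sd: float = 5.0
    background_blue: int = 100
    contrast_margin: int = 60  # colony blue = background + margin


@dataclass
class AfmSpec:
    E_true_pa: float = 1000.0
    E_substrate_pa: float = 100_000.0
    n_samples: int = 400
    z_span_um: float = 3.0
    force_noise_nN: float = 0.02
    half_angle_deg: float = 35.0
    geometry: str = "four_sided_pyramid"
    map_size: int = 64


@dataclass
class RtdcSpec:
    n_events: int = 2000
    fraction_in_gate: float = 0.6
    area_mean_um2: float = 150.0
    area_sd_um2: float = 30.0
    emod_median_kpa: float = 1.0
    emod_log_sd: float = 0.3


@dataclass
class QpcrSpec:
    #: gene → condition → planted log2 fold change vs control
    true_log2fc: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "MCT1": {"coculture": -1.5},
            "MCT4": {"coculture": -1.0},
            "CD147": {"coculture": -0.5},
        }
    )
    control_condition: str = "control"
    n_replicates: int = 6
    ct_noise_sd: float = 0.2
    baseline_dct: float = 2.0
    ref_ct_mean: float = 20.0


@dataclass
class SurvivalSpec:
    baseline_hazard_per_day: float = 1.0 / 1000.0
    cluster_hr: float = 3.0
    censor_rate: float = 0.3
    cluster2_probability: float = 0.3
    lactate_effect: float = 4.0  # z-shift of panel genes in cluster 2
    lactate_noise_sd: float = 1.0


@dataclass
class SimConfig:
    """Study conditions for the synthetic-data generators."""

    seed: int = 0
    n_patients: int = 55
    subtype_proportions: tuple[float, float, float, float] = (
        18 / 55, 11 / 55, 14 / 55, 12 / 55,  # AT, BA, CL, ME cohort mix
    )
    marker_effect: float = 3.0  # signed z-shift Δ of signature markers
    noise_sd: float = 0.5
    covariate_flip_probability: float = 0.05
    colony_spec: ColonySpec = field(default_factory=ColonySpec)
    afm_spec: AfmSpec = field(default_factory=AfmSpec)
    rtdc_spec: RtdcSpec = field(default_factory=RtdcSpec)
    qpcr_spec: QpcrSpec = field(default_factory=QpcrSpec)
    survival_spec: SurvivalSpec = field(default_factory=SurvivalSpec)

    def __post_init__(self) -> None:
        p = np.asarray(self.subtype_proportions, dtype=float)
        if p.shape != (4,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigError(
                "subtype_proportions must be 4 non-negative reals summing to 1"
            )
        if self.noise_sd < 0 or self.colony_spec.pixel_noise_sd < 0 \
                or self.afm_spec.force_noise_nN < 0 \
                or self.qpcr_spec.ct_noise_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        if self.n_patients < 8:
            raise ConfigError("n_patients must be >= 8")
        h, w = self.colony_spec.image_size
        if h < 128 or w < 128:
            raise ConfigError("colony images must be at least 128×128")
        if self.colony_spec.radius_range_px[1] * 2 > min(h, w):
            raise ConfigError("colony radius too large for the image")
        if self.afm_spec.E_true_pa <= 0:
            raise ConfigError("E_true must be positive")
        if self.rtdc_spec.n_events < 1:
            raise ConfigError("n_events must be >= 1")


# stream ids for per-generator substreams
_STREAMS = {"cohort": 0, "colony": 1, "afm": 2, "rtdc": 3, "qpcr": 4}


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass
class TruthBundle:
    """Planted ground truth for every generated object."""

    subtypes: dict[str, str] = field(default_factory=dict)
    clusters: dict[str, int] = field(default_factory=dict)
    colony_fractions: dict[str, float] = field(default_factory=dict)
    colony_shifts: dict[str, tuple[int, int]] = field(default_factory=dict)
    afm_moduli: dict[str, float] = field(default_factory=dict)
    rtdc_in_gate: list[bool] = field(default_factory=list)
    qpcr_log2fc: dict[str, dict[str, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

_GENE_BASELINES = {
    "TP63": 6.0, "EGFR": 7.0, "SOX2": 5.0,
    "VIM": 8.0, "DES": 4.0, "NFE2L2": 6.5,
    "MCT1": 5.5, "MCT4": 6.0, "CD147": 9.0, "CAV1": 7.5, "ACTA2": 8.5,
}

_SITES = ("oropharynx", "larynx", "hypopharynx", "tongue",
          "floor of the mouth", "oral cavity")
_SITE_P = (24 / 55, 16 / 55, 6 / 55, 5 / 55, 3 / 55, 1 / 55)


def _censor_horizon(rate_: float, censor_rate: float) -> float:
    """Uniform(0, c) censoring horizon giving the requested censor share."""
    if censor_rate <= 0:
        return np.inf
    # P(C < T) for T ~ Exp(rate), C ~ U(0, c): (1 - (1 - e^{-rate c})/(rate c))
    def frac(c: float) -> float:
        x = rate_ * c
        return 1.0 - (1.0 - np.exp(-x)) / x

    return brentq(lambda c: frac(c) - censor_rate, 1e-6 / rate_, 1e3 / rate_)


def gen_cohort(config: SimConfig) -> tuple[list[PatientRecord], TruthBundle]:
    """Cohort with planted subtypes, lactate clusters and survival.

    Each patient's signature markers are shifted by ±Δ on the
    standardised scale according to their planted subtype's signed
    signature; non-signature markers are pure noise. Smoking is forced
    to 1 for classical-planted and p16 to 1 for atypical-planted
    patients, each flipped with ``covariate_flip_probability``. Lactate
    panel genes are shifted for cluster-2 patients, whose hazard is
    scaled by the planted hazard ratio.
    """
    rng = _rng(config, "cohort")
    sspec = config.survival_spec
    truth = TruthBundle()
    labels = rng.choice(
        SUBTYPES, size=config.n_patients, p=config.subtype_proportions
    )
    clusters = 1 + (rng.random(config.n_patients) < sspec.cluster2_probability)
    rate2 = sspec.baseline_hazard_per_day * sspec.cluster_hr
    horizon1 = _censor_horizon(sspec.baseline_hazard_per_day, sspec.censor_rate)
    # mean horizon so censoring is outcome-independent
    horizon = horizon1 if np.isfinite(horizon1) else np.inf

    cohort: list[PatientRecord] = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        sub = str(labels[i])
        signature = dict(DEFAULT_MARKERS[sub])
        expr = {}
        for gene in MARKER_GENES:
            shift = config.marker_effect * signature.get(gene, 0)
            expr[gene] = _GENE_BASELINES[gene] + shift \
                + rng.normal(0.0, config.noise_sd)
        cl = int(clusters[i])
        for gene in LACTATE_PANEL:
            shift = sspec.lactate_effect if cl == 2 else 0.0
            expr[gene] = _GENE_BASELINES[gene] + shift \
                + rng.normal(0.0, sspec.lactate_noise_sd)

        # covariate forcing is part of the planted signal: with a zero
        # marker effect the cohort must be uninformative, so forcing is
        # disabled and everyone draws from the background rates
        flip = rng.random(2) < config.covariate_flip_probability
        forced = config.marker_effect != 0
        if sub == "CL" and forced:
            smoking = 0 if flip[0] else 1
        else:
            smoking = int(rng.random() < 0.4)
        if sub == "AT" and forced:
            p16 = 0 if flip[1] else 1
        else:
            p16 = int(rng.random() < 0.15)

        rate = rate2 if cl == 2 else sspec.baseline_hazard_per_day
        t_event = rng.exponential(1.0 / rate)
        if np.isfinite(horizon):
            c = rng.uniform(0.0, horizon)
        else:
            c = np.inf
        time = float(min(t_event, c))
        event = int(t_event <= c)

        clinical = {
            "gender": "M" if rng.random() < 41 / 55 else "F",
            "site": str(rng.choice(_SITES, p=_SITE_P)),
            "pN": "<2" if rng.random() < 37 / 55 else ">2",
            "stage": "I-II" if rng.random() < 28 / 55 else "III-IV",
        }
        cohort.append(
            PatientRecord(
                id=pid, expr=expr, smoking=smoking, p16=p16,
                clinical=clinical, survival_time=max(time, 1e-3), event=event,
            )
        )
        truth.subtypes[pid] = sub
        truth.clusters[pid] = cl
    return cohort, truth


def cohort_frame(cohort: list[PatientRecord]) -> pd.DataFrame:
    """Cohort as a flat table (one row per patient)."""
    rows = []
    for p in cohort:
        row = {"id": p.id, **{g: p.expr[g] for g in sorted(p.expr)},
               "smoking": p.smoking, "p16": p.p16, **p.clinical,
               "time": p.survival_time, "event": p.event}
        rows.append(row)
    return pd.DataFrame(rows).set_index("id")


# ---------------------------------------------------------------------------
# Colony images
# ---------------------------------------------------------------------------

@dataclass
class ColonySim:
    reference: np.ndarray  # H×W×3 uint8
    roi: np.ndarray  # boolean
    images: dict[str, np.ndarray]
    truth: TruthBundle


def _render_plate(
    spec: ColonySpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(clean float RGB plate, boolean colony mask) for one layout."""
    h, w = spec.image_size
    n = int(rng.integers(spec.n_colonies_range[0], spec.n_colonies_range[1] + 1))
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(n):
        r = rng.uniform(*spec.radius_range_px)
        cy = rng.uniform(r, h - r)
        cx = rng.uniform(r, w - r)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    plate = np.empty((h, w, 3), dtype=float)
    bg_blue = float(spec.background_blue)
    plate[:, :, 0] = 150.0
    plate[:, :, 1] = 150.0
    plate[:, :, 2] = bg_blue
    colony_blue = bg_blue + spec.contrast_margin
    plate[mask] = (80.0, 80.0, colony_blue)
    return plate, mask


def _shift_content(plate: np.ndarray, dy: int, dx: int, fill) -> np.ndarray:
    """Translate image content by (dy, dx), filling exposed pixels."""
    out = np.empty_like(plate)
    out[..., 0], out[..., 1], out[..., 2] = fill
    h, w = plate.shape[:2]
    ys_o = slice(max(0, dy), h + min(0, dy))
    xs_o = slice(max(0, dx), w + min(0, dx))
    ys_i = slice(max(0, -dy), h + min(0, -dy))
    xs_i = slice(max(0, -dx), w + min(0, -dx))
    out[ys_o, xs_o] = plate[ys_i, xs_i]
    return out


def gen_colony_images(config: SimConfig) -> ColonySim:
    """Reference plate + ROI and translated noisy copies with truth.

    The ROI is a centred rectangle covering half of each dimension. The
    truth area fraction is counted on the rendered colony mask inside
    the ROI (not analytically); each non-reference image is the
    reference content translated by a known integer shift plus pixel
    noise.
    """
    spec = config.colony_spec
    rng = _rng(config, "colony")
    h, w = spec.image_size
    roi = np.zeros((h, w), dtype=bool)
    roi[h // 4: h // 4 + h // 2, w // 4: w // 4 + w // 2] = True

    truth = TruthBundle()
    plate, mask = _render_plate(spec, rng)

    def finalize(img: np.ndarray, rng_: np.random.Generator) -> np.ndarray:
        noisy = img + rng_.normal(0.0, spec.pixel_noise_sd, img.shape)
        return np.clip(np.rint(noisy), 0, 255).astype(np.uint8)

    reference = finalize(plate, rng)
    frac = float(mask[roi].sum() / roi.sum())
    truth.colony_fractions["reference"] = frac
    truth.colony_shifts["reference"] = (0, 0)

    bg = (150.0, 150.0, float(spec.background_blue))
    images: dict[str, np.ndarray] = {}
    j = spec.shift_jitter_px
    for k in range(spec.n_images):
        name = f"well_{k + 1:02d}"
        dy = int(rng.integers(-j, j + 1))
        dx = int(rng.integers(-j, j + 1))
        images[name] = finalize(_shift_content(plate, dy, dx, bg), rng)
        truth.colony_shifts[name] = (dy, dx)
        truth.colony_fractions[name] = frac
    return ColonySim(reference=reference, roi=roi, images=images, truth=truth)


# ---------------------------------------------------------------------------
# AFM force curves and maps
# ---------------------------------------------------------------------------

def _make_curve(
    E_pa: float, spec: AfmSpec, rng: np.random.Generator,
    model: IndenterModel,
) -> ForceCurve:
    z = np.linspace(spec.z_span_um, 0.0, spec.n_samples)  # descending approach
    z0 = rng.uniform(0.35 * spec.z_span_um, 0.6 * spec.z_span_um)
    delta = np.maximum(0.0, z0 - z)
    f = model_force(delta, E_pa, model)
    if spec.force_noise_nN > 0:
        f = f + rng.normal(0.0, spec.force_noise_nN, f.shape)
    return ForceCurve(
        height_um=z, force_nN=f,
        meta={"speed_um_s": 30.0, "setpoint_nN": 1.0,
              "probe": "HYDRA-2R-100N", "z0_true_um": z0},
    )


def gen_force_curves(
    config: SimConfig, n_curves: int = 200
) -> tuple[list[ForceCurve], TruthBundle]:
    """Approach curves built from the indenter forward model."""
    spec = config.afm_spec
    rng = _rng(config, "afm")
    model = IndenterModel(spec.geometry, spec.half_angle_deg)
    truth = TruthBundle()
    curves = []
    for k in range(n_curves):
        curves.append(_make_curve(spec.E_true_pa, spec, rng, model))
        truth.afm_moduli[f"curve_{k:04d}"] = spec.E_true_pa
    return curves, truth


def gen_force_map(
    config: SimConfig, map_size: int | None = None
) -> tuple[ForceMap, TruthBundle]:
    """n×n force map: a central circular cell on a stiff substrate."""
    spec = config.afm_spec
    rng = _rng(config, "afm")
    model = IndenterModel(spec.geometry, spec.half_angle_deg)
    n = map_size or spec.map_size
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    cell = (yy - c) ** 2 + (xx - c) ** 2 <= (0.35 * n) ** 2
    truth = TruthBundle()
    grid: list[list[ForceCurve]] = []
    for i in range(n):
        row = []
        for j in range(n):
            E = spec.E_true_pa if cell[i, j] else spec.E_substrate_pa
            row.append(_make_curve(E, spec, rng, model))
            truth.afm_moduli[f"px_{i}_{j}"] = E
        grid.append(row)
    return ForceMap(curves=grid, cell_mask=cell), truth


# ---------------------------------------------------------------------------
# RT-DC events
# ---------------------------------------------------------------------------

def gen_rtdc_events(config: SimConfig) -> tuple[pd.DataFrame, TruthBundle]:
    """Event table with a planted fraction of in-gate events.

    In-gate events satisfy area ∈ [70, 2000] µm² and porosity ∈
    [1.00, 1.05]; contaminants violate at least one bound (small
    debris, multicellular clusters, or damaged high-porosity cells).
    """
    spec = config.rtdc_spec
    rng = _rng(config, "rtdc")
    n = spec.n_events
    in_gate = rng.random(n) < spec.fraction_in_gate
    area = np.empty(n)
    porosity = np.empty(n)

    n_in = int(in_gate.sum())
    area[in_gate] = np.clip(
        rng.normal(spec.area_mean_um2, spec.area_sd_um2, n_in), 70.0, 2000.0
    )
    porosity[in_gate] = rng.uniform(1.0, 1.05, n_in)

    n_out = n - n_in
    kind = rng.integers(0, 3, n_out)  # 0 debris, 1 cluster, 2 damaged
    a_out = np.empty(n_out)
    p_out = np.empty(n_out)
    a_out[kind == 0] = rng.uniform(5.0, 69.5, int((kind == 0).sum()))
    p_out[kind == 0] = rng.uniform(1.0, 1.05, int((kind == 0).sum()))
    a_out[kind == 1] = rng.uniform(2000.5, 4000.0, int((kind == 1).sum()))
    p_out[kind == 1] = rng.uniform(1.0, 1.05, int((kind == 1).sum()))
    a_out[kind == 2] = np.clip(
        rng.normal(spec.area_mean_um2, spec.area_sd_um2, int((kind == 2).sum())),
        70.0, 2000.0,
    )
    p_out[kind == 2] = rng.uniform(1.0505, 1.3, int((kind == 2).sum()))
    area[~in_gate] = a_out
    porosity[~in_gate] = p_out

    emod = spec.emod_median_kpa * np.exp(rng.normal(0.0, spec.emod_log_sd, n))
    deformation = rng.beta(2.0, 20.0, n)
    events = pd.DataFrame(
        {"area_um2": area, "deformation": deformation,
         "porosity": porosity, "emod_kpa": emod}
    )
    truth = TruthBundle(rtdc_in_gate=in_gate.tolist())
    return events, truth


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------

def gen_qpcr(config: SimConfig) -> tuple[pd.DataFrame, TruthBundle]:
    """Ct table constructed so ΔΔCt recovers the planted fold changes.

    Ct_target = Ct_ref + baseline ΔCt − log2FC + noise, with log2FC = 0
    for the control condition; the reference gene (PSMB2) is present
    for every sample.
    """
    spec = config.qpcr_spec
    rng = _rng(config, "qpcr")
    rows = []
    truth = TruthBundle()
    for gene, cond_fc in spec.true_log2fc.items():
        truth.qpcr_log2fc[gene] = {spec.control_condition: 0.0, **dict(cond_fc)}
        for condition, fc in truth.qpcr_log2fc[gene].items():
            for rep in range(spec.n_replicates):
                ct_ref = rng.normal(spec.ref_ct_mean, 0.1)
                ct_t = ct_ref + spec.baseline_dct - fc \
                    + rng.normal(0.0, spec.ct_noise_sd)
                rows.append(
                    {"sample": f"{condition}_{rep + 1}", "condition": condition,
                     "gene": gene, "ct_target": ct_t, "ct_ref": ct_ref}
                )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Everything at once
# ---------------------------------------------------------------------------

@dataclass
class SimOutput:
    cohort: list[PatientRecord]
    colony: ColonySim
    force_curves: list[ForceCurve]
    rtdc_events: pd.DataFrame
    qpcr: pd.DataFrame
    truth: TruthBundle


def simulate_all(config: SimConfig, n_curves: int = 50) -> SimOutput:
    """Generate every pipeline input under one seed, with merged truth."""
    cohort, t_cohort = gen_cohort(config)
    colony = gen_colony_images(config)
    curves, t_afm = gen_force_curves(config, n_curves)
    rtdc, t_rtdc = gen_rtdc_events(config)
    qpcr, t_qpcr = gen_qpcr(config)
    truth = TruthBundle(
        subtypes=t_cohort.subtypes,
        clusters=t_cohort.clusters,
        colony_fractions=colony.truth.colony_fractions,
        colony_shifts=colony.truth.colony_shifts,
        afm_moduli=t_afm.afm_moduli,
        rtdc_in_gate=t_rtdc.rtdc_in_gate,
        qpcr_log2fc=t_qpcr.qpcr_log2fc,
    )
    return SimOutput(cohort, colony, curves, rtdc, qpcr, truth)
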