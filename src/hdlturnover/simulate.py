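"""Synthetic cohorts for the nephrectomized-vs-sham turnover study design.

Generates every input the pipeline consumes — per-animal kinetic rate sets,
lipid panels, noisy time-activity curves, and stained-gel densitograms —
with the statistical structure the analysis assumes: two groups of rabbits
(sham-operated controls and three-quarter renal-mass-reduced, "ntx"),
median/IQR-matched log-normal between-animal variation, proportional
counting noise on the tracer curves, and five-component Gaussian
densitograms over the HDL size span.

Group-level targets default to the published biochemistry of the study
design being emulated (median and interquartile range per analyte); each
animal's kinetic rate set is the group's base rate set scaled by a common
log-normal factor matched to the group's FCR median/IQR, so turnover speed
varies between animals while the exchange topology stays fixed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
from scipy.stats import norm

#: z-score of the 75th percentile, the quartile constant of the
#: median/IQR -> log-normal-sigma conversion.
_Z75 = float(norm.ppf(0.75))

from .densitometry import (Densitogram, LipidPanel, SUBCLASS_INTERVALS_NM,
                           SUBCLASS_NAMES, SizeCalibration, calibrate_sizes)
from .errors import ValidationError
from .kinetics import (KineticRateSet, PoolConcentrations, SAMPLING_TIMES_MIN,
                       TimeActivityCurve, fcr_closed_form, solve_model)

logger = logging.getLogger(__name__)

GROUPS = ("sham", "ntx")

#: Tracer dose injected per animal, counts per minute.
DOSE_CPM = 1.0e6

#: Fraction of non-HDL total cholesterol assumed esterified when deriving
#: the VLDL/LDL cholesteryl-ester pool from a lipid panel.
NONHDL_ESTERIFIED_FRACTION = 0.75

#: Gel calibration used for synthetic densitograms: two marker proteins at
#: migration positions 10 and 90 with hydrodynamic diameters 17.0 and
#: 7.1 nm (log-diameter linear in position).
GEL_MARKER_POSITIONS = (10.0, 90.0)
GEL_MARKER_DIAMETERS_NM = (17.0, 7.1)


def gel_calibration() -> SizeCalibration:
    return calibrate_sizes(GEL_MARKER_POSITIONS, GEL_MARKER_DIAMETERS_NM)


#: Base (median) rate sets per group, min^-1.  Their closed-form FCRs are
#: 0.24 h^-1 (sham) and 0.14 h^-1 (ntx), the group medians being emulated.
BASE_RATES = {
    "sham": KineticRateSet(k_hdl_to_vldl=0.002, k_vldl_to_hdl=0.002,
                           k_hdl_out=0.003, k_vldl_out=0.002),
    "ntx": KineticRateSet(k_hdl_to_vldl=0.001, k_vldl_to_hdl=0.001,
                          k_hdl_out=0.002, k_vldl_out=0.0005),
}

#: FCR median (h^-1) and quartiles per group; the quartile ratio sets the
#: log-normal spread of the per-animal rate-set scale factor.
FCR_TARGETS = {
    "sham": (0.24, 0.17, 0.36),
    "ntx": (0.14, 0.10, 0.19),
}

#: Lipid-panel targets, mmol/L, as (median, q1, q3) per analyte per group.
#: HDL total cholesterol is fc + ce by construction, so it is not drawn.
LIPID_TARGETS = {
    "sham": {
        "plasma_tc": (1.18, 0.86, 1.39),
        "plasma_tg": (1.19, 1.00, 1.32),
        "hdl_fc": (0.15, 0.13, 0.17),
        "hdl_ce": (0.59, 0.50, 0.63),
        "hdl_tg": (0.18, 0.16, 0.19),
        "hdl_ph": (0.84, 0.63, 1.08),
        "nonhdl_tc": (0.45, 0.12, 0.73),
    },
    "ntx": {
        "plasma_tc": (1.89, 1.42, 2.04),
        "plasma_tg": (0.99, 0.80, 1.18),
        "hdl_fc": (0.17, 0.16, 0.22),
        "hdl_ce": (0.80, 0.62, 1.04),
        "hdl_tg": (0.23, 0.19, 0.26),
        "hdl_ph": (0.89, 0.85, 1.50),
        "nonhdl_tc": (0.92, 0.70, 1.64),
    },
}

#: Base subclass AUC fractions per group, (2b, 2a, 3a, 3b, 3c): the ntx
#: profile shifts mass toward the small (3b, 3c) subclasses.
BASE_FRACTIONS = {
    "sham": (0.32, 0.18, 0.27, 0.13, 0.10),
    "ntx": (0.29, 0.17, 0.26, 0.15, 0.13),
}

#: Body-weight range of the animals, kg (uniform draw).
BODY_WEIGHT_RANGE_KG = (3.0, 3.5)

#: Log-normal sigma of the per-animal, per-stain jitter applied to the
#: base subclass fractions before renormalization.
_FRACTION_JITTER_SIGMA = 0.08

_STAIN_BY_LIPID = {"tc": "total cholesterol", "fc": "free cholesterol",
                   "tg": "triglycerides", "ph": "phospholipids"}


def lognormal_sigma(q1: float, q3: float) -> float:
    """Log-normal sigma whose quartile ratio matches the target IQR.

    sigma = ln(q3/q1) / (2 * z_0.75) with z_0.75 = norm.ppf(0.75); a point
    mass (sigma = 0) when q3 == q1.
    """
    if q3 < q1:
        raise ValidationError(f"q3 must be >= q1, got ({q1}, {q3})")
    if q1 <= 0:
        raise ValidationError("quartiles must be > 0 for a log-normal draw")
    return math.log(q3 / q1) / (2.0 * _Z75)


def _draw_lognormal(rng: np.random.Generator, median: float, q1: float,
                    q3: float) -> float:
    if median <= 0:
        raise ValidationError("median must be > 0 for a log-normal draw")
    sigma = lognormal_sigma(q1, q3)
    if sigma == 0.0:
        return median
    return median * math.exp(sigma * rng.standard_normal())


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults emulate the two-group rabbit design: n = 6 per group, 3%
    proportional counting noise, the published lipid-panel and FCR targets,
    and the 11-sample tracer schedule.
    """

    seed: int
    n_per_group: int = 6
    noise_cv: float = 0.03
    noise_model: str = "proportional"   # or "poisson"
    times_min: tuple = SAMPLING_TIMES_MIN
    fcr_targets: Mapping[str, tuple] = field(
        default_factory=lambda: dict(FCR_TARGETS))
    lipid_targets: Mapping[str, Mapping[str, tuple]] = field(
        default_factory=lambda: {g: dict(t) for g, t in LIPID_TARGETS.items()})
    base_rates: Mapping[str, KineticRateSet] = field(
        default_factory=lambda: dict(BASE_RATES))
    base_fractions: Mapping[str, tuple] = field(
        default_factory=lambda: dict(BASE_FRACTIONS))
    densitogram_resolution: int = 400

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ValidationError("n_per_group must be >= 1")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.noise_model not in ("proportional", "poisson"):
            raise ValidationError(
                f"unknown noise_model {self.noise_model!r}")
        for group, (median, q1, q3) in self.fcr_targets.items():
            lognormal_sigma(q1, q3)  # validates quartile ordering
            if median <= 0:
                raise ValidationError(f"{group} FCR median must be > 0")
        for group, targets in self.lipid_targets.items():
            for name, (median, q1, q3) in targets.items():
                lognormal_sigma(q1, q3)
                if median <= 0 and q1 > 0:
                    raise ValidationError(
                        f"{group}:{name} median must be > 0")


@dataclass(frozen=True)
class SyntheticAnimal:
    """One simulated rabbit with its generating truth retained."""

    animal_id: str
    group: str
    body_weight_kg: float
    true_rates: KineticRateSet
    true_pools: PoolConcentrations
    true_fcr_per_hour: float
    hdl_panel: LipidPanel
    chemistry: Mapping[str, float]
    true_fractions: Mapping[str, np.ndarray]
    curve: TimeActivityCurve
    densitograms: Mapping[str, Densitogram]


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def sample_cohort(spec: CohortSpec) -> list[SyntheticAnimal]:
    """Draw a full two-group cohort under the given study conditions.

    Per-animal parameters are log-normal with mu = ln(median) and sigma
    matched to the target quartile ratio, so group medians of generated
    values converge to the spec's medians as n grows.  Deterministic for a
    fixed seed.
    """
    root = np.random.default_rng(spec.seed)
    animals = []
    for group in GROUPS:
        fcr_median, fcr_q1, fcr_q3 = spec.fcr_targets[group]
        base = spec.base_rates[group]
        base_fcr = fcr_closed_form(base)
        for i in range(spec.n_per_group):
            rng = np.random.default_rng(root.integers(2 ** 31))
            animals.append(_sample_animal(
                spec, rng, group, f"{group}-{i + 1:02d}",
                base, base_fcr, (fcr_median, fcr_q1, fcr_q3)))
    return animals


def _sample_animal(spec, rng, group, animal_id, base, base_fcr, fcr_target):
    fcr_median, fcr_q1, fcr_q3 = fcr_target
    # Common scale factor for the whole rate set: median matched to the
    # group FCR median, spread to the FCR quartile ratio.
    scale = _draw_lognormal(rng, fcr_median / base_fcr, fcr_q1 / base_fcr,
                            fcr_q3 / base_fcr)
    rates = KineticRateSet(*(k * scale for k in base.as_tuple()))

    targets = spec.lipid_targets[group]
    lipids = {name: _draw_lognormal(rng, *t) for name, t in targets.items()}
    hdl_panel = LipidPanel(tc=lipids["hdl_fc"] + lipids["hdl_ce"],
                           fc=lipids["hdl_fc"], tg=lipids["hdl_tg"],
                           ph=lipids["hdl_ph"])
    chemistry = {"plasma_tc": lipids["plasma_tc"],
                 "plasma_tg": lipids["plasma_tg"],
                 "nonhdl_tc": lipids["nonhdl_tc"]}
    pools = PoolConcentrations(
        hdl_ce=hdl_panel.ce * 1000.0,
        vldl_ce=NONHDL_ESTERIFIED_FRACTION * lipids["nonhdl_tc"] * 1000.0)

    weight = rng.uniform(*BODY_WEIGHT_RANGE_KG)

    base_frac = np.asarray(spec.base_fractions[group], dtype=float)
    fractions = {}
    densitograms = {}
    for lipid, stain in _STAIN_BY_LIPID.items():
        jitter = np.exp(_FRACTION_JITTER_SIGMA * rng.standard_normal(5))
        frac = base_frac * jitter
        frac = frac / frac.sum()
        fractions[lipid] = frac
        densitograms[lipid] = synth_densitogram(
            frac, stain, resolution=spec.densitogram_resolution)

    animal = SyntheticAnimal(
        animal_id=animal_id, group=group, body_weight_kg=weight,
        true_rates=rates, true_pools=pools,
        true_fcr_per_hour=fcr_closed_form(rates),
        hdl_panel=hdl_panel, chemistry=chemistry,
        true_fractions=fractions,
        curve=None, densitograms=densitograms)  # type: ignore[arg-type]
    curve = simulate_decay(animal, times_min=spec.times_min,
                           cv=spec.noise_cv, noise_model=spec.noise_model,
                           rng=rng)
    object.__setattr__(animal, "curve", curve)
    return animal


def simulate_decay(animal_or_rates, times_min=SAMPLING_TIMES_MIN, *,
                   cv: float = 0.03, noise_model: str = "proportional",
                   dose_cpm: float = DOSE_CPM,
                   rng: Optional[Union[np.random.Generator, int]] = None,
                   ) -> TimeActivityCurve:
    """Simulate one noisy tracer study.

    The analytic model solution is scaled to counts (dose-proportional),
    perturbed with seeded counting noise — proportional Gaussian at the
    given CV by default, or Poisson on the raw counts — and renormalized
    so the first sample reads exactly 100% (HDL) and 0% (VLDL/LDL), the
    same convention the in-vivo protocol applies to its 5-minute draw.

    ``times_min`` is the absolute sampling schedule; its first entry is the
    normalization sample and is shifted to t = 0.
    """
    rates = getattr(animal_or_rates, "true_rates", animal_or_rates)
    t = np.asarray(times_min, dtype=float)
    shifted = t - t[0]
    sol = solve_model(rates, shifted)
    cpm1 = sol.hdl_activity * (dose_cpm / 100.0)
    cpm2 = sol.vldl_activity * (dose_cpm / 100.0)

    if cv > 0 or noise_model == "poisson":
        rng = np.random.default_rng(rng) if not isinstance(
            rng, np.random.Generator) else rng
        if noise_model == "proportional":
            cpm1 = cpm1 * (1.0 + cv * rng.standard_normal(cpm1.size))
            cpm2 = cpm2 * (1.0 + cv * rng.standard_normal(cpm2.size))
        else:
            cpm1 = rng.poisson(cpm1).astype(float)
            cpm2 = rng.poisson(cpm2).astype(float)

    n_clipped = int(np.sum(cpm1 < 0) + np.sum(cpm2 < 0))
    if n_clipped:
        logger.warning("clipped %d negative noisy counts to 0", n_clipped)
    cpm1 = np.maximum(cpm1, 0.0)
    cpm2 = np.maximum(cpm2, 0.0)

    hdl = 100.0 * cpm1 / cpm1[0]
    vldl = 100.0 * cpm2 / cpm1[0]
    hdl[0], vldl[0] = 100.0, 0.0
    return TimeActivityCurve(times=shifted, hdl_activity=hdl,
                             vldl_activity=vldl)


#: Gaussian component centers, the midpoints of the five size windows (nm).
COMPONENT_CENTERS_NM = tuple(
    0.5 * (lo + hi) for lo, hi in
    (SUBCLASS_INTERVALS_NM[name] for name in SUBCLASS_NAMES))

#: Rendered nm span of synthetic densitograms.
RENDER_SPAN_NM = (7.6, 13.9)


def synth_densitogram(fractions, stain: str, resolution: int = 400,
                      sigma_scale: float = 1.0 / 8.0,
                      in_gel_coordinates: bool = True) -> Densitogram:
    """Render a five-Gaussian synthetic densitogram.

    One Gaussian per subclass, centered at its window midpoint with
    sigma = ``sigma_scale`` x window width (1/8 by default, keeping
    > 99.99% of each component inside its window), masses equal to the
    target fractions, evaluated on a uniform nm grid over 7.6-13.9 nm.
    With ``in_gel_coordinates`` the profile is mapped through the inverse
    of :func:`gel_calibration` so positions are migration coordinates, as
    a scanned gel would supply; pass ``False`` to keep nm positions
    (pair with ``calibration=None`` downstream).  Deterministic.
    """
    frac = np.asarray(getattr(fractions, "fractions", fractions), dtype=float)
    if frac.shape != (5,) or np.any(frac < 0):
        raise ValidationError("fractions must be 5 non-negative values")
    if frac.sum() <= 0:
        raise ValidationError("fractions must not be all zero")
    if resolution < 50:
        raise ValidationError("resolution must be >= 50 grid points")
    frac = frac / frac.sum()

    nm = np.linspace(*RENDER_SPAN_NM, resolution)
    signal = np.zeros_like(nm)
    for mass, name, center in zip(frac, SUBCLASS_NAMES, COMPONENT_CENTERS_NM):
        lo, hi = SUBCLASS_INTERVALS_NM[name]
        sigma = sigma_scale * (hi - lo)
        signal += (mass / (sigma * math.sqrt(2.0 * math.pi))
                   * np.exp(-0.5 * ((nm - center) / sigma) ** 2))

    if not in_gel_coordinates:
        return Densitogram(positions=nm, signal=signal, stain=stain)
    pos = gel_calibration().diameter_to_position(nm)
    order = np.argsort(pos)  # larger diameters migrate less far
    return Densitogram(positions=pos[order], signal=signal[order],
                       stain=stain)


def truth_record(animal: SyntheticAnimal) -> dict:
    """JSON-serializable sidecar of one animal's generating parameters."""
    return {
        "animal_id": animal.animal_id,
        "group": animal.group,
        "body_weight_kg": animal.body_weight_kg,
        "rates_per_min": {
            "k_hdl_to_vldl": animal.true_rates.k_hdl_to_vldl,
            "k_vldl_to_hdl": animal.true_rates.k_vldl_to_hdl,
            "k_hdl_out": animal.true_rates.k_hdl_out,
            "k_vldl_out": animal.true_rates.k_vldl_out,
        },
        "fcr_per_hour": animal.true_fcr_per_hour,
        "pools_umol_per_l": {"hdl_ce": animal.true_pools.hdl_ce,
                             "vldl_ce": animal.true_pools.vldl_ce},
        "hdl_panel_mmol_per_l": {"tc": animal.hdl_panel.tc,
                                 "fc": animal.hdl_panel.fc,
                                 "tg": animal.hdl_panel.tg,
                                 "ph": animal.hdl_panel.ph},
        "chemistry_mmol_per_l": dict(animal.chemistry),
        "subclass_fractions": {lipid: list(map(float, frac))
                               for lipid, frac in
                               animal.true_fractions.items()},
    }
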