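"""Two-compartment plasma cholesteryl-ester kinetics.

The model tracks tracer mass in two plasma pools: compartment 1 is the HDL
cholesteryl-ester pool (where the labeled bolus enters), compartment 2 the
combined VLDL/LDL pool.  Four first-order transfer coefficients connect them:

    dq1/dt = -(k_hdl_out + k_hdl_to_vldl) * q1 + k_vldl_to_hdl * q2
    dq2/dt =  k_hdl_to_vldl * q1 - (k_vldl_to_hdl + k_vldl_out) * q2

with q1(0) = 100 (percent of dose), q2(0) = 0.  All rate constants are in
min^-1; the fractional catabolic rate (FCR) and production rate (PR) are
reported in h^-1 and mg.kg^-1.h^-1 respectively, matching how turnover
studies print them.

Naming note: in the compartmental-modeling literature these coefficients are
often labeled K(1,2), K(2,1), K(1,0), K(2,0).  Field names here spell out
the direction of transfer (``k_hdl_to_vldl`` is HDL -> VLDL/LDL, the
coefficient usually printed K(1,2)); the K(i,j) labels are presentation
only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, ValidationError

#: Plasma volume per kg body weight assumed for rabbits (L/kg).
PLASMA_VOLUME_L_PER_KG = 0.0328

#: Molar mass used to convert cholesteryl ester mmol/L to mg/L (g/mol).
#: Typical cholesteryl esters (oleate/linoleate) are ~650 g/mol.
CE_MOLAR_MASS_G_PER_MOL = 650.0

#: Blood-sampling schedule of the turnover protocol, minutes post bolus.
SAMPLING_TIMES_MIN = (5.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0, 150.0,
                      180.0, 240.0, 300.0)

#: Same schedule with the normalization sample (5 min) shifted to t = 0.
SHIFTED_TIMES_MIN = tuple(t - SAMPLING_TIMES_MIN[0] for t in SAMPLING_TIMES_MIN)

# Relative eigenvalue gap below which the rate matrix is treated as having a
# repeated eigenvalue and the (A + B t) e^(lambda t) branch is used.
_EIGENVALUE_GAP_RTOL = 1e-12


def per_minute_to_per_hour(rate_per_min: float) -> float:
    """Convert a first-order rate from min^-1 to h^-1.

    The single place where the minutes -> hours conversion lives.
    """
    return 60.0 * rate_per_min


def _require_finite_nonneg(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    if value < 0:
        raise ValidationError(f"{name} must be >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class KineticRateSet:
    """The four transfer coefficients of the two-pool model, in min^-1.

    Attributes
    ----------
    k_hdl_to_vldl : float
        Transfer of CE from HDL to VLDL/LDL (the coefficient K(1,2)).
    k_vldl_to_hdl : float
        Transfer of CE from VLDL/LDL back to HDL (K(2,1)).
    k_hdl_out : float
        Irreversible removal of CE from the HDL pool (K(1,0)).
    k_vldl_out : float
        Irreversible removal of CE from the VLDL/LDL pool (K(2,0)).
    """

    k_hdl_to_vldl: float
    k_vldl_to_hdl: float
    k_hdl_out: float
    k_vldl_out: float

    def __post_init__(self):
        for name in ("k_hdl_to_vldl", "k_vldl_to_hdl", "k_hdl_out",
                     "k_vldl_out"):
            object.__setattr__(
                self, name, _require_finite_nonneg(name, getattr(self, name))
            )

    def rate_matrix(self) -> np.ndarray:
        """The 2x2 system matrix M such that dq/dt = M q."""
        return np.array(
            [
                [-(self.k_hdl_out + self.k_hdl_to_vldl), self.k_vldl_to_hdl],
                [self.k_hdl_to_vldl, -(self.k_vldl_to_hdl + self.k_vldl_out)],
            ]
        )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.k_hdl_to_vldl, self.k_vldl_to_hdl, self.k_hdl_out,
                self.k_vldl_out)


@dataclass(frozen=True)
class TimeActivityCurve:
    """Normalized tracer percentages in both pools over time.

    ``times`` are minutes since the normalization sample (the 5-min draw in
    the in-vivo protocol), so ``times[0] == 0`` and the activities start at
    100% (HDL) and 0% (VLDL/LDL) by construction.
    """

    times: np.ndarray
    hdl_activity: np.ndarray
    vldl_activity: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        hdl = np.asarray(self.hdl_activity, dtype=float)
        vldl = np.asarray(self.vldl_activity, dtype=float)
        if times.ndim != 1 or times.size == 0:
            raise ValidationError("times must be a non-empty 1-D sequence")
        if hdl.shape != times.shape or vldl.shape != times.shape:
            raise ValidationError("times and activity series must have equal "
                                  "lengths")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(hdl)) \
                or not np.all(np.isfinite(vldl)):
            raise ValidationError("curve contains non-finite values")
        if np.any(np.diff(times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if times[0] != 0.0:
            raise ValidationError(
                f"times[0] must be 0 (normalization sample), got {times[0]}")
        if not math.isclose(hdl[0], 100.0, rel_tol=0, abs_tol=1e-9):
            raise ValidationError(
                f"hdl_activity[0] must be 100, got {hdl[0]!r}")
        if not math.isclose(vldl[0], 0.0, rel_tol=0, abs_tol=1e-9):
            raise ValidationError(
                f"vldl_activity[0] must be 0, got {vldl[0]!r}")
        if np.any(hdl < 0) or np.any(vldl < 0):
            raise ValidationError("activities must be >= 0")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "hdl_activity", hdl)
        object.__setattr__(self, "vldl_activity", vldl)

    @property
    def n_points(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class PoolConcentrations:
    """Cholesteryl-ester concentrations of the two pools, umol/L."""

    hdl_ce: float
    vldl_ce: float

    def __post_init__(self):
        object.__setattr__(self, "hdl_ce",
                           _require_finite_nonneg("hdl_ce", self.hdl_ce))
        object.__setattr__(self, "vldl_ce",
                           _require_finite_nonneg("vldl_ce", self.vldl_ce))


@dataclass(frozen=True)
class FluxSet:
    """Specific mass-transfer rates, umol.L^-1.min^-1.

    ``total_outflow`` is the sum of both irreversible removal fluxes — the
    total mass of cholesteryl ester leaving the plasma compartment.
    """

    flux_hdl_to_vldl: float
    flux_vldl_to_hdl: float
    flux_hdl_out: float
    flux_vldl_out: float
    total_outflow: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        for name in ("flux_hdl_to_vldl", "flux_vldl_to_hdl", "flux_hdl_out",
                     "flux_vldl_out"):
            object.__setattr__(
                self, name, _require_finite_nonneg(name, getattr(self, name)))
        expected = self.flux_hdl_out + self.flux_vldl_out
        if self.total_outflow is None:
            object.__setattr__(self, "total_outflow", expected)
        elif float(self.total_outflow) != expected:
            raise ValidationError(
                "total_outflow must equal flux_hdl_out + flux_vldl_out "
                f"exactly ({self.total_outflow!r} != {expected!r})")


@dataclass(frozen=True)
class TurnoverSummary:
    """FCR, production rate and the inputs the PR formula consumed."""

    fcr_per_hour: float
    ce_conc_mg_per_l: float
    body_weight_kg: float
    pr_mg_per_kg_per_hour: float
    plasma_volume_per_kg: float = PLASMA_VOLUME_L_PER_KG

    def __post_init__(self):
        _require_finite_nonneg("fcr_per_hour", self.fcr_per_hour)
        _require_finite_nonneg("ce_conc_mg_per_l", self.ce_conc_mg_per_l)
        if self.body_weight_kg <= 0:
            raise ValidationError("body_weight_kg must be > 0")
        expected = production_rate(
            self.fcr_per_hour, self.ce_conc_mg_per_l, self.body_weight_kg,
            self.plasma_volume_per_kg)
        if not math.isclose(self.pr_mg_per_kg_per_hour, expected,
                            rel_tol=1e-9, abs_tol=1e-12):
            raise ValidationError(
                "pr_mg_per_kg_per_hour inconsistent with the PR formula: "
                f"got {self.pr_mg_per_kg_per_hour!r}, expected {expected!r}")


# ---------------------------------------------------------------------------
# Analytic solution
# ---------------------------------------------------------------------------

def solve_model(rates: KineticRateSet, times) -> TimeActivityCurve:
    """Evaluate the analytic tracer solution at the given times.

    Solves the two-pool linear system with the unit-bolus initial condition
    q1(0) = 100, q2(0) = 0 by eigen-decomposition of the 2x2 rate matrix.
    Both the distinct-eigenvalue and the repeated-eigenvalue (defective or
    proportional) branches are handled; eigenvalues closer than a relative
    gap of 1e-12 take the (A + B t) e^(lambda t) form.

    Parameters
    ----------
    rates : KineticRateSet
        The four transfer coefficients, min^-1.
    times : sequence of float
        Sampling times in minutes, strictly increasing, starting at 0.
    """
    if not isinstance(rates, KineticRateSet):
        rates = KineticRateSet(*rates)
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValidationError("times must be a non-empty 1-D sequence")
    if t[0] != 0.0:
        raise ValidationError(f"times[0] must be 0, got {t[0]}")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")

    a = -(rates.k_hdl_out + rates.k_hdl_to_vldl)   # M[0, 0]
    b = rates.k_vldl_to_hdl                        # M[0, 1]
    c = rates.k_hdl_to_vldl                        # M[1, 0]
    d = -(rates.k_vldl_to_hdl + rates.k_vldl_out)  # M[1, 1]

    # Eigenvalues of [[a, b], [c, d]]; discriminant (a-d)^2 + 4bc >= 0 here
    # because b, c >= 0, so both eigenvalues are real (and <= 0).
    half_tr = 0.5 * (a + d)
    disc = math.sqrt(max((a - d) ** 2 + 4.0 * b * c, 0.0))
    lam1 = half_tr + 0.5 * disc
    lam2 = half_tr - 0.5 * disc

    q10 = 100.0
    scale = max(abs(lam1), abs(lam2), 1e-300)
    if abs(lam1 - lam2) <= _EIGENVALUE_GAP_RTOL * scale:
        # Repeated eigenvalue: e^{Mt} = e^{lam t} (I + (M - lam I) t)
        lam = half_tr
        e = np.exp(lam * t)
        q1 = q10 * e * (1.0 + (a - lam) * t)
        q2 = q10 * c * t * e
    else:
        e1 = np.exp(lam1 * t)
        e2 = np.exp(lam2 * t)
        inv_gap = 1.0 / (lam1 - lam2)
        q1 = q10 * ((a - lam2) * e1 - (a - lam1) * e2) * inv_gap
        q2 = q10 * c * (e1 - e2) * inv_gap

    # Guard against -1e-18 style round-off; the exact solution is >= 0.
    q1 = np.maximum(q1, 0.0)
    q2 = np.maximum(q2, 0.0)
    q1[0], q2[0] = 100.0, 0.0
    return TimeActivityCurve(times=t, hdl_activity=q1, vldl_activity=q2)


def fcr_closed_form(rates: KineticRateSet) -> float:
    """Closed-form fractional catabolic rate of the HDL pool, h^-1.

    The FCR is the reciprocal of the area under the normalized
    fraction-remaining curve q1(t)/100.  For this model that area has the
    closed form 1 / [k_hdl_out + k_hdl_to_vldl * k_vldl_out /
    (k_vldl_to_hdl + k_vldl_out)]: tracer leaves either directly from HDL
    or via the VLDL/LDL pool, where a fraction k_vldl_out /
    (k_vldl_to_hdl + k_vldl_out) of each transfer is eventually removed.

    Raises
    ------
    DomainError
        If tracer can reach the VLDL/LDL pool but never leave it
        (trapped-tracer configuration), or if no removal path exists at
        all — in both cases the residence time is infinite.
    """
    if not isinstance(rates, KineticRateSet):
        rates = KineticRateSet(*rates)
    k12, k21, k10, k20 = (rates.k_hdl_to_vldl, rates.k_vldl_to_hdl,
                          rates.k_hdl_out, rates.k_vldl_out)
    if k12 > 0 and (k21 + k20) == 0:
        raise DomainError(
            "trapped tracer: transfer into the VLDL/LDL pool with no exit "
            "from it makes the residence time infinite")
    recycled_loss = k12 * k20 / (k21 + k20) if k12 > 0 else 0.0
    fcr_per_min = k10 + recycled_loss
    if fcr_per_min <= 0:
        raise DomainError(
            "no removal path: FCR undefined for a closed system")
    return per_minute_to_per_hour(fcr_per_min)


def mass_fluxes(rates: KineticRateSet, pools: PoolConcentrations) -> FluxSet:
    """First-order mass fluxes, umol.L^-1.min^-1.

    Each flux is the rate constant times the cholesteryl-ester
    concentration of its *source* compartment: transfers out of HDL
    (k_hdl_to_vldl, k_hdl_out) multiply the HDL pool, transfers out of
    VLDL/LDL (k_vldl_to_hdl, k_vldl_out) multiply the VLDL/LDL pool.
    Total outflow is the sum of the two removal fluxes.
    """
    if not isinstance(rates, KineticRateSet):
        rates = KineticRateSet(*rates)
    if not isinstance(pools, PoolConcentrations):
        pools = PoolConcentrations(*pools)
    return FluxSet(
        flux_hdl_to_vldl=rates.k_hdl_to_vldl * pools.hdl_ce,
        flux_vldl_to_hdl=rates.k_vldl_to_hdl * pools.vldl_ce,
        flux_hdl_out=rates.k_hdl_out * pools.hdl_ce,
        flux_vldl_out=rates.k_vldl_out * pools.vldl_ce,
    )


def production_rate(fcr_per_hour: float, ce_conc_mg_per_l: float,
                    body_weight_kg: float = 1.0,
                    plasma_volume_per_kg: float = PLASMA_VOLUME_L_PER_KG,
                    ) -> float:
    """Steady-state cholesteryl-ester production rate, mg.kg^-1.h^-1.

    PR = FCR x CE plasma concentration (mg/L) x total plasma volume (L)
    / body weight (kg).  With plasma volume proportional to body weight
    (0.0328 L/kg by default) the weight cancels algebraically; it is kept
    as a parameter so per-animal records stay traceable.
    """
    fcr_per_hour = _require_finite_nonneg("fcr_per_hour", fcr_per_hour)
    ce_conc_mg_per_l = _require_finite_nonneg("ce_conc_mg_per_l",
                                              ce_conc_mg_per_l)
    plasma_volume_per_kg = _require_finite_nonneg("plasma_volume_per_kg",
                                                  plasma_volume_per_kg)
    body_weight_kg = float(body_weight_kg)
    if body_weight_kg <= 0:
        raise ValidationError(
            f"body_weight_kg must be > 0, got {body_weight_kg!r}")
    plasma_volume_l = plasma_volume_per_kg * body_weight_kg
    return fcr_per_hour * ce_conc_mg_per_l * plasma_volume_l / body_weight_kg


def ce_mmol_to_mg_per_l(ce_mmol_per_l: float,
                        molar_mass: float = CE_MOLAR_MASS_G_PER_MOL) -> float:
    """Convert a cholesteryl-ester concentration from mmol/L to mg/L."""
    return float(ce_mmol_per_l) * float(molar_mass)
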