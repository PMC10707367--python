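"""HDL-subclass quantification from gradient-gel densitograms.

A densitogram is a one-dimensional stain-signal profile along the gel
migration axis.  Marker proteins of known hydrodynamic diameter calibrate
the axis (log-diameter linear in migration distance, the usual convention
for native gradient gels); the stained-lipid signal is then integrated over
five fixed particle-diameter windows:

    HDL 2b  10.58-13.59 nm
    HDL 2a   9.94-10.58 nm
    HDL 3a   8.98-9.94 nm
    HDL 3b   8.45-8.98 nm
    HDL 3c   7.94-8.45 nm

Each subclass fraction is the trapezoidal area under the curve inside its
window divided by the area over the whole 7.94-13.59 nm span; multiplying
by the total HDL concentration of the stained lipid apportions plasma
concentrations across subclasses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError

#: Subclass order used throughout: largest to smallest particles.
SUBCLASS_NAMES = ("HDL2b", "HDL2a", "HDL3a", "HDL3b", "HDL3c")

#: Particle-diameter windows (nm), half-open [low, high) except HDL 2b,
#: whose upper edge closes the analyzed span.
SUBCLASS_INTERVALS_NM: dict[str, tuple[float, float]] = {
    "HDL2b": (10.58, 13.59),
    "HDL2a": (9.94, 10.58),
    "HDL3a": (8.98, 9.94),
    "HDL3b": (8.45, 8.98),
    "HDL3c": (7.94, 8.45),
}

SPAN_NM = (7.94, 13.59)

VALID_STAINS = ("total cholesterol", "free cholesterol", "triglycerides",
                "phospholipids", "protein")

#: Fraction of the marker position range by which queries may extrapolate.
_EXTRAPOLATION_LIMIT = 0.05


@dataclass(frozen=True)
class SizeCalibration:
    """Monotone migration-position -> particle-diameter mapping.

    Linear interpolation of log-diameter against migration position through
    the marker knots; markers are sorted canonically by position on
    construction, so input order does not matter.  Queries may extrapolate
    at most 5% of the marker position range beyond either end.
    """

    marker_positions: np.ndarray
    marker_diameters: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.marker_positions, dtype=float)
        dia = np.asarray(self.marker_diameters, dtype=float)
        if pos.ndim != 1 or pos.size < 2 or dia.shape != pos.shape:
            raise ValidationError("need >= 2 markers with matching "
                                  "positions and diameters")
        order = np.argsort(pos)
        pos, dia = pos[order], dia[order]
        if np.any(np.diff(pos) <= 0):
            raise ValidationError("marker positions must be distinct")
        if np.any(dia <= 0):
            raise ValidationError("marker diameters must be > 0")
        d = np.diff(dia)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError(
                "markers must map positions to strictly monotone diameters")
        object.__setattr__(self, "marker_positions", pos)
        object.__setattr__(self, "marker_diameters", dia)

    def position_to_diameter(self, positions) -> np.ndarray:
        """Map migration positions to particle diameters (nm)."""
        q = np.atleast_1d(np.asarray(positions, dtype=float))
        pos = self.marker_positions
        logd = np.log(self.marker_diameters)
        span = pos[-1] - pos[0]
        slack = _EXTRAPOLATION_LIMIT * span
        if np.any(q < pos[0] - slack) or np.any(q > pos[-1] + slack):
            raise DomainError(
                f"query positions outside the calibrated range "
                f"[{pos[0] - slack:g}, {pos[-1] + slack:g}]")
        # np.interp clamps; extend the end segments linearly for the
        # permitted 5% slack instead.
        out = np.interp(q, pos, logd)
        below = q < pos[0]
        above = q > pos[-1]
        if np.any(below):
            slope = (logd[1] - logd[0]) / (pos[1] - pos[0])
            out[below] = logd[0] + slope * (q[below] - pos[0])
        if np.any(above):
            slope = (logd[-1] - logd[-2]) / (pos[-1] - pos[-2])
            out[above] = logd[-1] + slope * (q[above] - pos[-1])
        return np.exp(out)

    def diameter_to_position(self, diameters) -> np.ndarray:
        """Inverse mapping, used when synthesizing gel-space profiles."""
        d = np.atleast_1d(np.asarray(diameters, dtype=float))
        logd = np.log(self.marker_diameters)
        pos = self.marker_positions
        if logd[0] > logd[-1]:  # np.interp needs ascending x
            logd, pos = logd[::-1], pos[::-1]
        slope0 = (pos[1] - pos[0]) / (logd[1] - logd[0])
        slope1 = (pos[-1] - pos[-2]) / (logd[-1] - logd[-2])
        ld = np.log(d)
        out = np.interp(ld, logd, pos)
        out[ld < logd[0]] = pos[0] + slope0 * (ld[ld < logd[0]] - logd[0])
        out[ld > logd[-1]] = pos[-1] + slope1 * (ld[ld > logd[-1]] - logd[-1])
        return out


def calibrate_sizes(marker_positions, marker_diameters) -> SizeCalibration:
    """Build a size calibration from marker positions and diameters (nm)."""
    return SizeCalibration(np.asarray(marker_positions, dtype=float),
                           np.asarray(marker_diameters, dtype=float))


@dataclass(frozen=True)
class Densitogram:
    """Stain signal versus migration position (strictly increasing)."""

    positions: np.ndarray
    signal: np.ndarray
    stain: str

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        sig = np.asarray(self.signal, dtype=float)
        if pos.ndim != 1 or pos.size < 2 or sig.shape != pos.shape:
            raise ValidationError("positions and signal must be equal-length "
                                  "1-D arrays with >= 2 points")
        if np.any(np.diff(pos) <= 0):
            raise ValidationError("positions must be strictly increasing")
        if np.any(sig < 0) or not np.all(np.isfinite(sig)):
            raise ValidationError("signal must be finite and >= 0")
        if self.stain not in VALID_STAINS:
            raise ValidationError(
                f"stain must be one of {VALID_STAINS}, got {self.stain!r}")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "signal", sig)


@dataclass(frozen=True)
class SubclassProfile:
    """Five size-window AUC fractions and optional derived concentrations.

    ``fractions`` follows :data:`SUBCLASS_NAMES` order (2b, 2a, 3a, 3b, 3c)
    and sums to 1 over the analyzed span.  ``concentrations`` maps lipid
    name -> per-subclass mmol/L (same order), each summing to the total HDL
    concentration of that lipid.
    """

    fractions: np.ndarray
    concentrations: Mapping[str, np.ndarray] = field(default_factory=dict)
    intervals: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(SUBCLASS_INTERVALS_NM))

    def __post_init__(self):
        frac = np.asarray(self.fractions, dtype=float)
        if frac.shape != (5,):
            raise ValidationError("fractions must have exactly 5 entries")
        if np.any(frac < 0):
            raise ValidationError("fractions must be >= 0")
        if not math.isclose(frac.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValidationError(
                f"fractions must sum to 1, got {frac.sum()!r}")
        object.__setattr__(self, "fractions", frac)

    def as_series(self) -> pd.Series:
        return pd.Series(self.fractions, index=list(SUBCLASS_NAMES),
                         name="fraction")


@dataclass(frozen=True)
class LipidPanel:
    """Lipid concentrations (mmol/L) of one lipoprotein fraction.

    Cholesteryl ester is the difference between total and free cholesterol;
    it is computed here rather than stored, so the identity ce = tc - fc
    holds by construction.
    """

    tc: float
    fc: float
    tg: float
    ph: float

    def __post_init__(self):
        for name in ("tc", "fc", "tg", "ph"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0")
            object.__setattr__(self, name, v)
        if self.fc > self.tc + 1e-12:
            raise ValidationError(
                "free cholesterol cannot exceed total cholesterol "
                f"(tc={self.tc}, fc={self.fc})")

    @property
    def ce(self) -> float:
        """Cholesteryl ester, mmol/L (total minus free cholesterol)."""
        return self.tc - self.fc

    @property
    def ratios(self) -> dict[str, float]:
        """Lipid-to-phospholipid ratios; requires ph > 0."""
        if self.ph <= 0:
            raise DomainError("ratios undefined: phospholipids are 0")
        return {"tc_ph": self.tc / self.ph, "fc_ph": self.fc / self.ph,
                "ce_ph": self.ce / self.ph, "tg_ph": self.tg / self.ph}


# ---------------------------------------------------------------------------
# Area-under-curve apportionment
# ---------------------------------------------------------------------------

def _trapz_window(x: np.ndarray, y: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of the piecewise-linear (x, y) over [lo, hi]."""
    y_lo = float(np.interp(lo, x, y))
    y_hi = float(np.interp(hi, x, y))
    inside = (x > lo) & (x < hi)
    xs = np.concatenate(([lo], x[inside], [hi]))
    ys = np.concatenate(([y_lo], y[inside], [y_hi]))
    return float(np.trapezoid(ys, xs))


def subclass_fractions(densitogram: Densitogram,
                       calibration: Optional[SizeCalibration] = None,
                       *, baseline_subtract: bool = False) -> SubclassProfile:
    """Percent-of-total AUC of each diameter window.

    The signal is integrated on the calibrated nanometer axis (so a
    nonuniform calibration does not bias window masses), each window's
    trapezoidal AUC is divided by the AUC over the full 7.94-13.59 nm
    span, and windows partition the span half-open [low, high) with the
    last (largest-diameter) window closed.

    Parameters
    ----------
    densitogram : Densitogram
        Signal versus migration position.
    calibration : SizeCalibration, optional
        Position -> diameter mapping.  ``None`` declares that the
        densitogram positions are already particle diameters in nm.
    baseline_subtract : bool
        Subtract the minimum signal over the analyzed span first
        (constant-baseline correction, off by default).
    """
    if calibration is None:
        diameters = densitogram.positions.copy()
    else:
        diameters = calibration.position_to_diameter(densitogram.positions)
    signal = densitogram.signal.copy()
    order = np.argsort(diameters)
    diameters, signal = diameters[order], signal[order]

    lo_span, hi_span = SPAN_NM
    missing = []
    if diameters[0] > lo_span:
        missing.append(f"{lo_span}-{min(diameters[0], hi_span):.3g} nm")
    if diameters[-1] < hi_span:
        missing.append(f"{max(diameters[-1], lo_span):.3g}-{hi_span} nm")
    if missing:
        raise ValidationError(
            "densitogram does not cover the analyzed span; missing "
            + " and ".join(missing))

    if baseline_subtract:
        in_span = (diameters >= lo_span) & (diameters <= hi_span)
        signal = np.maximum(signal - signal[in_span].min(), 0.0)

    areas = np.array([
        _trapz_window(diameters, signal, *SUBCLASS_INTERVALS_NM[name])
        for name in SUBCLASS_NAMES
    ])
    total = areas.sum()
    if total <= 0:
        raise DomainError("zero total AUC over the analyzed span")
    return SubclassProfile(fractions=areas / total)


def subclass_concentrations(fractions, total_mmol_per_l: float) -> np.ndarray:
    """Apportion a total HDL lipid concentration across subclasses.

    concentration_i = fraction_i x total; per-subclass cholesteryl ester
    then follows as per-subclass TC minus per-subclass FC.
    """
    frac = np.asarray(getattr(fractions, "fractions", fractions), dtype=float)
    total = float(total_mmol_per_l)
    if total < 0:
        raise ValidationError("total concentration must be >= 0")
    if frac.shape != (5,):
        raise ValidationError("fractions must have exactly 5 entries")
    return frac * total


def lipid_ratios(panels: Mapping[str, LipidPanel]) -> pd.DataFrame:
    """Lipid-to-phospholipid ratio table, one row per subclass.

    Subclasses with zero phospholipids get NaN ratios (flagged in the
    ``defined`` column); the rest of the table is still computed.
    """
    rows = []
    for subclass, panel in panels.items():
        try:
            r = panel.ratios
            rows.append({"subclass": subclass, **r, "defined": True})
        except DomainError:
            rows.append({"subclass": subclass, "tc_ph": np.nan,
                         "fc_ph": np.nan, "ce_ph": np.nan, "tg_ph": np.nan,
                         "defined": False})
    return pd.DataFrame(rows).set_index("subclass")


def profile_with_concentrations(
        fraction_by_stain: Mapping[str, SubclassProfile],
        totals_mmol_per_l: Mapping[str, float]) -> pd.DataFrame:
    """Tidy per-subclass table of fractions and plasma concentrations.

    ``fraction_by_stain`` maps lipid name (tc/fc/tg/ph) to the profile
    measured with that stain; ``totals_mmol_per_l`` gives the total HDL
    concentration of each lipid.  Per-subclass CE is TC - FC.
    """
    records = []
    conc = {}
    for lipid, profile in fraction_by_stain.items():
        values = subclass_concentrations(profile, totals_mmol_per_l[lipid])
        conc[lipid] = values
        for name, frac, c in zip(SUBCLASS_NAMES, profile.fractions, values):
            records.append({"subclass": name, "lipid": lipid,
                            "fraction": frac,
                            "concentration_mmol_per_l": c})
    if "tc" in conc and "fc" in conc:
        ce = conc["tc"] - conc["fc"]
        for name, c in zip(SUBCLASS_NAMES, ce):
            records.append({"subclass": name, "lipid": "ce",
                            "fraction": np.nan,
                            "concentration_mmol_per_l": c})
    return pd.DataFrame.from_records(records)
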