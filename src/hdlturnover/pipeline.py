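"""Configuration, CSV readers/writers, and the end-to-end pipeline.

File conventions: comma-separated UTF-8 CSV with a header row and "."
decimals; times in minutes in files, fitted FCR/PR reported in h^-1 and
mg.kg^-1.h^-1.  Every writer here has a paired reader and round-trips
losslessly to double precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import densitometry as dens
from . import fitting, simulate, stats
from .errors import FittingError, ValidationError
from .kinetics import (CE_MOLAR_MASS_G_PER_MOL, PLASMA_VOLUME_L_PER_KG,
                       KineticRateSet, PoolConcentrations, TimeActivityCurve,
                       fcr_closed_form, mass_fluxes, production_rate)

logger = logging.getLogger(__name__)

#: Tolerance (percentage points) within which a first sample is silently
#: renormalized to the 100%/0% convention instead of rejected.
RENORMALIZE_TOL_PCT = 2.0


def configure_logging(level: int = logging.INFO) -> None:
    """Opinionated default logging setup for scripts and the CLI."""
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s: %(message)s")


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs.

    Exactly one input source must be given: either the real-input CSV
    paths (``time_activity_csv`` plus optional panels/densitograms) or a
    synthetic-cohort request (``synthetic=True``).
    """

    seed: int = 0
    synthetic: bool = False
    n_per_group: int = 6
    noise_cv: float = 0.03
    noise_model: str = "proportional"
    time_activity_csv: Optional[str] = None
    animals_csv: Optional[str] = None
    panels_csv: Optional[str] = None
    densitograms_csv: Optional[str] = None
    markers_csv: Optional[str] = None
    weighting: str = "uniform"
    n_random_starts: int = 4
    ce_molar_mass_g_per_mol: float = CE_MOLAR_MASS_G_PER_MOL
    plasma_volume_l_per_kg: float = PLASMA_VOLUME_L_PER_KG
    nonhdl_esterified_fraction: float = simulate.NONHDL_ESTERIFIED_FRACTION
    output_dir: Optional[str] = None

    def __post_init__(self):
        if self.synthetic == (self.time_activity_csv is not None):
            raise ValidationError(
                "exactly one of synthetic=True or time_activity_csv must "
                "be provided")
        for name in ("ce_molar_mass_g_per_mol", "plasma_volume_l_per_kg",
                     "nonhdl_esterified_fraction"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} must be a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        payload = {k: getattr(self, k) for k in self.__dataclass_fields__}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_csv(path, required: set[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(
            f"{path}: missing required columns {sorted(missing)}")
    return df


def _numeric(df: pd.DataFrame, path, columns) -> pd.DataFrame:
    for col in columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            raise ValidationError(
                f"{path}: non-numeric value in column {col!r} at data "
                f"row(s) {[int(i) + 2 for i in bad[:5]]}")
        if converted.isna().any():
            raise ValidationError(
                f"{path}: empty cells in column {col!r}")
        df[col] = converted
    return df


def read_time_activity(path) -> dict[str, tuple[str, TimeActivityCurve]]:
    """Per-animal tracer curves from a tidy CSV.

    Columns: ``animal_id, group, time_min, hdl_pct, vldl_pct``.  The first
    sample of each animal is shifted to t = 0 and renormalized to 100%/0%
    when it lies within 2 percentage points of that convention (with a
    logged warning); larger deviations are rejected.
    """
    df = _read_csv(path, {"animal_id", "group", "time_min", "hdl_pct",
                          "vldl_pct"})
    df = _numeric(df, path, ["time_min", "hdl_pct", "vldl_pct"])
    out = {}
    for animal_id, sub in df.groupby("animal_id", sort=False):
        sub = sub.sort_values("time_min")
        times = sub["time_min"].to_numpy(float)
        dup = times[:-1][np.diff(times) == 0]
        if dup.size:
            raise ValidationError(
                f"{path}: duplicated time {dup[0]:g} min for animal "
                f"{animal_id!r}")
        hdl = sub["hdl_pct"].to_numpy(float)
        vldl = sub["vldl_pct"].to_numpy(float)
        if abs(hdl[0] - 100.0) > RENORMALIZE_TOL_PCT \
                or abs(vldl[0]) > RENORMALIZE_TOL_PCT:
            raise ValidationError(
                f"{path}: animal {animal_id!r} first sample "
                f"({hdl[0]:g}%, {vldl[0]:g}%) violates the 100%/0% "
                "normalization beyond the 2% tolerance")
        if hdl[0] != 100.0 or vldl[0] != 0.0:
            logger.warning("animal %s: first sample (%g%%, %g%%) "
                           "renormalized to 100%%/0%%",
                           animal_id, hdl[0], vldl[0])
            # both series are percentages of the same reference counts, so
            # one common factor rescales them after baseline subtraction
            factor = 100.0 / hdl[0]
            vldl = np.maximum(vldl - vldl[0], 0.0) * factor
            hdl = hdl * factor
            hdl[0] = 100.0
        group = str(sub["group"].iloc[0])
        curve = TimeActivityCurve(times=times - times[0],
                                  hdl_activity=np.maximum(hdl, 0.0),
                                  vldl_activity=np.maximum(vldl, 0.0))
        out[str(animal_id)] = (group, curve)
    return out


def write_time_activity(curves: Mapping[str, tuple[str, TimeActivityCurve]],
                        path) -> None:
    rows = []
    for animal_id, (group, curve) in curves.items():
        for t, h, v in zip(curve.times, curve.hdl_activity,
                           curve.vldl_activity):
            rows.append({"animal_id": animal_id, "group": group,
                         "time_min": t, "hdl_pct": h, "vldl_pct": v})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_animals(path) -> pd.DataFrame:
    """Animal roster: ``animal_id, group, body_weight_kg``."""
    df = _read_csv(path, {"animal_id", "group", "body_weight_kg"})
    df = _numeric(df, path, ["body_weight_kg"])
    if (df["body_weight_kg"] <= 0).any():
        raise ValidationError(f"{path}: body weights must be > 0")
    return df


def read_lipid_panels(path) -> pd.DataFrame:
    """Tidy lipid panel: ``animal_id, group, analyte, value_mmol_per_l``."""
    df = _read_csv(path, {"animal_id", "group", "analyte",
                          "value_mmol_per_l"})
    df = _numeric(df, path, ["value_mmol_per_l"])
    if (df["value_mmol_per_l"] < 0).any():
        raise ValidationError(f"{path}: concentrations must be >= 0")
    return df


def read_densitograms(path) -> dict[tuple[str, str], dens.Densitogram]:
    """All densitograms from one tidy CSV keyed by (animal_id, stain).

    Columns: ``animal_id, stain, position, signal``.
    """
    df = _read_csv(path, {"animal_id", "stain", "position", "signal"})
    df = _numeric(df, path, ["position", "signal"])
    out = {}
    for (animal_id, stain), sub in df.groupby(["animal_id", "stain"],
                                              sort=False):
        sub = sub.sort_values("position")
        out[(str(animal_id), str(stain))] = dens.Densitogram(
            positions=sub["position"].to_numpy(float),
            signal=sub["signal"].to_numpy(float), stain=str(stain))
    return out


def read_markers(path) -> dens.SizeCalibration:
    """Marker calibration points: ``position, diameter_nm``."""
    df = _read_csv(path, {"position", "diameter_nm"})
    df = _numeric(df, path, ["position", "diameter_nm"])
    return dens.calibrate_sizes(df["position"].to_numpy(float),
                                df["diameter_nm"].to_numpy(float))


def write_cohort(cohort: list[simulate.SyntheticAnimal], outdir) -> dict:
    """Write a synthetic cohort in the same CSV dialects the readers
    consume, plus a ``truth.json`` sidecar of generating parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "time_activity": outdir / "time_activity.csv",
        "animals": outdir / "animals.csv",
        "panels": outdir / "panels.csv",
        "densitograms": outdir / "densitograms.csv",
        "markers": outdir / "markers.csv",
        "truth": outdir / "truth.json",
    }
    write_time_activity(
        {a.animal_id: (a.group, a.curve) for a in cohort},
        paths["time_activity"])
    pd.DataFrame([{"animal_id": a.animal_id, "group": a.group,
                   "body_weight_kg": a.body_weight_kg} for a in cohort]
                 ).to_csv(paths["animals"], index=False)
    panel_rows = []
    for a in cohort:
        analytes = {"hdl_tc": a.hdl_panel.tc, "hdl_fc": a.hdl_panel.fc,
                    "hdl_tg": a.hdl_panel.tg, "hdl_ph": a.hdl_panel.ph,
                    **a.chemistry}
        for analyte, value in analytes.items():
            panel_rows.append({"animal_id": a.animal_id, "group": a.group,
                               "analyte": analyte,
                               "value_mmol_per_l": value})
    pd.DataFrame(panel_rows).to_csv(paths["panels"], index=False)
    dgram_rows = []
    for a in cohort:
        for lipid, d in a.densitograms.items():
            for p, s in zip(d.positions, d.signal):
                dgram_rows.append({"animal_id": a.animal_id,
                                   "stain": d.stain,
                                   "position": p, "signal": s})
    pd.DataFrame(dgram_rows).to_csv(paths["densitograms"], index=False)
    cal = simulate.gel_calibration()
    pd.DataFrame({"position": cal.marker_positions,
                  "diameter_nm": cal.marker_diameters}
                 ).to_csv(paths["markers"], index=False)
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump([simulate.truth_record(a) for a in cohort], fh, indent=1)
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

_STAIN_TO_LIPID = {stain: lipid
                   for lipid, stain in simulate._STAIN_BY_LIPID.items()}

#: Variables compared between groups in the standard report.
REPORT_VARIABLES = (
    "fcr_biexp_per_h", "fcr_compartmental_per_h", "pr_mg_per_kg_per_h",
    "flux_hdl_to_vldl", "flux_vldl_to_hdl", "flux_hdl_out", "flux_vldl_out",
    "total_outflow", "hdl_ce_mmol_per_l",
)


@dataclass(frozen=True)
class ReportBundle:
    """Everything one pipeline run produced."""

    per_animal: pd.DataFrame
    comparisons: pd.DataFrame
    markdown: str
    recovery: Optional[pd.DataFrame] = None
    errors: Mapping[str, str] = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the full analysis under one configuration.

    Simulates or reads the cohort, fits each animal's curve both ways
    (biexponential and compartmental), computes FCR, PR and mass fluxes,
    apportions HDL subclass concentrations when densitograms are present,
    and assembles the group-comparison report.  Per-animal failures are
    collected; the run aborts only if an entire group yields no usable
    fit.  Deterministic for a fixed config.
    """
    truth = None
    if config.synthetic:
        spec = simulate.CohortSpec(seed=config.seed,
                                   n_per_group=config.n_per_group,
                                   noise_cv=config.noise_cv,
                                   noise_model=config.noise_model)
        cohort = simulate.sample_cohort(spec)
        curves = {a.animal_id: (a.group, a.curve) for a in cohort}
        weights = {a.animal_id: a.body_weight_kg for a in cohort}
        panels = {a.animal_id: {"hdl_tc": a.hdl_panel.tc,
                                "hdl_fc": a.hdl_panel.fc,
                                "hdl_tg": a.hdl_panel.tg,
                                "hdl_ph": a.hdl_panel.ph,
                                **a.chemistry} for a in cohort}
        densitograms = {(a.animal_id, d.stain): d
                        for a in cohort for d in a.densitograms.values()}
        calibration = simulate.gel_calibration()
        truth = {a.animal_id: simulate.truth_record(a) for a in cohort}
    else:
        curves = read_time_activity(config.time_activity_csv)
        weights = {}
        if config.animals_csv:
            roster = read_animals(config.animals_csv)
            weights = dict(zip(roster["animal_id"].astype(str),
                               roster["body_weight_kg"]))
        panels = {}
        if config.panels_csv:
            tidy = read_lipid_panels(config.panels_csv)
            for animal_id, sub in tidy.groupby("animal_id", sort=False):
                panels[str(animal_id)] = dict(
                    zip(sub["analyte"], sub["value_mmol_per_l"]))
        densitograms = {}
        calibration = None
        if config.densitograms_csv:
            densitograms = read_densitograms(config.densitograms_csv)
            if config.markers_csv:
                calibration = read_markers(config.markers_csv)

    rows, errors = [], {}
    for animal_id, (group, curve) in curves.items():
        try:
            rows.extend(_analyze_animal(
                config, animal_id, group, curve,
                panels.get(animal_id), weights.get(animal_id),
                densitograms, calibration))
        except (FittingError, ValidationError) as exc:
            logger.error("animal %s failed: %s", animal_id, exc)
            errors[animal_id] = str(exc)

    per_animal = pd.DataFrame(
        rows, columns=["animal_id", "group", "variable", "value"])
    for group in ("sham", "ntx"):
        group_ids = {aid for aid, (g, _) in curves.items() if g == group}
        if group_ids and group_ids <= set(errors):
            raise FittingError(
                f"no usable fits in the {group} group", diagnostics=errors)

    comparisons, markdown = stats.build_report(
        per_animal,
        variables=[v for v in REPORT_VARIABLES
                   if v in set(per_animal["variable"])])
    recovery = _recovery_table(per_animal, truth) if truth else None
    bundle = ReportBundle(per_animal=per_animal, comparisons=comparisons,
                          markdown=markdown, recovery=recovery,
                          errors=errors)
    if config.output_dir:
        write_bundle(bundle, config.output_dir)
    return bundle


def _analyze_animal(config, animal_id, group, curve, panel, weight,
                    densitograms, calibration):
    """Per-animal stage: both fits, FCR, PR, fluxes, subclasses."""
    seed = _animal_seed(config.seed, animal_id)
    biexp, biexp_report = fitting.fit_biexponential(
        curve, weighting=config.weighting,
        n_random_starts=config.n_random_starts, seed=seed)
    fcr_biexp = fitting.fcr_from_biexponential(biexp)
    rates, comp_report = fitting.fit_compartmental(
        curve, weighting=config.weighting,
        n_random_starts=config.n_random_starts, seed=seed)
    logger.info("animal %s: biexp FCR %.4g h^-1 (start %d), compartmental "
                "winner start %d RSS %.3g", animal_id, fcr_biexp,
                biexp_report.winning_start, comp_report.winning_start,
                comp_report.residual_sum_of_squares)
    try:
        fcr_comp = fcr_closed_form(rates)
    except Exception:
        fcr_comp = np.nan

    rows = [
        {"variable": "fcr_biexp_per_h", "value": fcr_biexp},
        {"variable": "fcr_compartmental_per_h", "value": fcr_comp},
        {"variable": "rss_biexp",
         "value": biexp_report.residual_sum_of_squares},
        {"variable": "k_hdl_to_vldl", "value": rates.k_hdl_to_vldl},
        {"variable": "k_vldl_to_hdl", "value": rates.k_vldl_to_hdl},
        {"variable": "k_hdl_out", "value": rates.k_hdl_out},
        {"variable": "k_vldl_out", "value": rates.k_vldl_out},
    ]

    if panel and "hdl_tc" in panel and "hdl_fc" in panel:
        hdl_ce = panel["hdl_tc"] - panel["hdl_fc"]
        rows.append({"variable": "hdl_ce_mmol_per_l", "value": hdl_ce})
        nonhdl_ce = config.nonhdl_esterified_fraction \
            * panel.get("nonhdl_tc", 0.0)
        pools = PoolConcentrations(hdl_ce=hdl_ce * 1000.0,
                                   vldl_ce=nonhdl_ce * 1000.0)
        fluxes = mass_fluxes(rates, pools)
        rows.extend([
            {"variable": "flux_hdl_to_vldl",
             "value": fluxes.flux_hdl_to_vldl},
            {"variable": "flux_vldl_to_hdl",
             "value": fluxes.flux_vldl_to_hdl},
            {"variable": "flux_hdl_out", "value": fluxes.flux_hdl_out},
            {"variable": "flux_vldl_out", "value": fluxes.flux_vldl_out},
            {"variable": "total_outflow", "value": fluxes.total_outflow},
        ])
        if weight:
            ce_mg_per_l = (hdl_ce + nonhdl_ce) \
                * config.ce_molar_mass_g_per_mol
            pr = production_rate(fcr_biexp, ce_mg_per_l, weight,
                                 config.plasma_volume_l_per_kg)
            rows.append({"variable": "pr_mg_per_kg_per_h", "value": pr})

    animal_dgrams = {stain: d for (aid, stain), d in densitograms.items()
                     if aid == animal_id}
    totals = {"tc": panel.get("hdl_tc"), "fc": panel.get("hdl_fc"),
              "tg": panel.get("hdl_tg"), "ph": panel.get("hdl_ph")} \
        if panel else {}
    for stain, dgram in animal_dgrams.items():
        lipid = _STAIN_TO_LIPID.get(stain, stain)
        profile = dens.subclass_fractions(dgram, calibration)
        for name, frac in zip(dens.SUBCLASS_NAMES, profile.fractions):
            rows.append({"variable": f"frac_{lipid}_{name}", "value": frac})
        total = totals.get(lipid)
        if total is not None:
            conc = dens.subclass_concentrations(profile, total)
            for name, c in zip(dens.SUBCLASS_NAMES, conc):
                rows.append({"variable": f"conc_{lipid}_{name}", "value": c})
    return [{"animal_id": animal_id, "group": group, **row} for row in rows]


def _animal_seed(base_seed: int, animal_id: str) -> int:
    """Stable per-animal sub-seed (< 2^31), independent of cohort order."""
    h = 0
    for ch in str(animal_id):
        h = (h * 31 + ord(ch)) % (2 ** 31 - 1)
    return (int(base_seed) * 2654435761 + h) % (2 ** 31 - 1)


def _recovery_table(per_animal: pd.DataFrame, truth: Mapping[str, dict],
                    ) -> pd.DataFrame:
    """Truth-versus-estimate summary for synthetic runs."""
    est = per_animal[per_animal["variable"] == "fcr_biexp_per_h"]
    rows = []
    for _, r in est.iterrows():
        t = truth.get(r["animal_id"])
        if t is None:
            continue
        rows.append({"animal_id": r["animal_id"], "group": r["group"],
                     "fcr_true_per_h": t["fcr_per_hour"],
                     "fcr_estimated_per_h": r["value"],
                     "relative_error":
                         (r["value"] - t["fcr_per_hour"])
                         / t["fcr_per_hour"]})
    return pd.DataFrame(rows)


def write_bundle(bundle: ReportBundle, outdir) -> dict:
    """Persist a report bundle (CSV tables plus the markdown report)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"per_animal": outdir / "per_animal.csv",
             "comparisons": outdir / "comparisons.csv",
             "report": outdir / "report.md"}
    bundle.per_animal.to_csv(paths["per_animal"], index=False)
    bundle.comparisons.to_csv(paths["comparisons"], index=False)
    paths["report"].write_text(bundle.markdown, encoding="utf-8")
    if bundle.recovery is not None:
        paths["recovery"] = outdir / "recovery.csv"
        bundle.recovery.to_csv(paths["recovery"], index=False)
    if bundle.errors:
        paths["errors"] = outdir / "errors.json"
        with open(paths["errors"], "w", encoding="utf-8") as fh:
            json.dump(dict(bundle.errors), fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
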