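"""Median (IQR) summaries, exact Mann-Whitney tests, and result tables.

The study design compares two small groups (n = 6 per group) variable by
variable, reporting each as "median (q1-q3)" and testing with the
two-sided Mann-Whitney U test at alpha = 0.05, no multiple-testing
correction.  At these sample sizes the exact permutation null of U is
both feasible and necessary — the normal approximation is unreliable —
so the exact distribution is enumerated whenever both groups have at
most 10 observations and the data are tie-free; otherwise the mid-rank
normal approximation with tie correction takes over (flagged in the
result).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

logger = logging.getLogger(__name__)

ALPHA = 0.05

#: Largest per-group n for which the exact U null is enumerated.
EXACT_N_MAX = 10


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, q1, q3) by the linear-interpolation quartile convention."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("median_iqr needs at least one value")
    if not np.all(np.isfinite(v)):
        raise ValidationError("values must be finite")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


@lru_cache(maxsize=None)
def _u_null_counts(n: int, m: int) -> tuple:
    """Number of rank assignments giving each value of U, for sizes (n, m).

    Standard recursion on the count-generating function:
    c(u; n, m) = c(u - m; n - 1, m) + c(u; n, m - 1).
    """
    if n == 0 or m == 0:
        return (1,)
    a = _u_null_counts(n - 1, m)   # largest observation in the x sample
    b = _u_null_counts(n, m - 1)   # largest observation in the y sample
    out = [0] * (n * m + 1)
    for u, c in enumerate(a):
        out[u + m] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_two_sided: float
    method: str   # "exact" or "asymptotic"


def mann_whitney_exact(x: Sequence[float], y: Sequence[float],
                       ) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test, exact at small tie-free n.

    Returns U = min(U_x, U_y).  The exact two-sided p is twice the lower
    tail P(U <= u_obs) under full enumeration of the C(n+m, n) rank
    assignments, capped at 1 (the classical-table convention).  With ties
    or groups larger than 10 the mid-rank normal approximation with tie
    and continuity correction is used instead and flagged ``asymptotic``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    n, m = x.size, y.size

    ranks = sps.rankdata(np.concatenate([x, y]))
    u_x = float(np.sum(ranks[:n]) - n * (n + 1) / 2.0)
    u_y = n * m - u_x
    u = min(u_x, u_y)

    has_ties = np.unique(np.concatenate([x, y])).size < n + m
    if not has_ties and max(n, m) <= EXACT_N_MAX:
        counts = _u_null_counts(n, m)
        total = math.comb(n + m, n)
        lower = sum(counts[: int(u) + 1])
        p = min(1.0, 2.0 * lower / total)
        return MannWhitneyResult(u=u, p_two_sided=p, method="exact")

    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    logger.debug("Mann-Whitney fell back to the normal approximation "
                 "(n=%d, m=%d, ties=%s)", n, m, has_ties)
    return MannWhitneyResult(u=u, p_two_sided=float(res.pvalue),
                             method="asymptotic")


@dataclass(frozen=True)
class GroupComparison:
    """One variable's two-group comparison, formatted the way the study
    tables report it."""

    variable: str
    sham_values: np.ndarray
    ntx_values: np.ndarray
    sham_median: float
    sham_q1: float
    sham_q3: float
    ntx_median: float
    ntx_q1: float
    ntx_q3: float
    u_statistic: float
    p_two_sided: float
    method: str

    @property
    def significant(self) -> bool:
        return self.p_two_sided < ALPHA


def compare_groups(variable: str, sham_values, ntx_values) -> GroupComparison:
    """Median/IQR summary plus Mann-Whitney comparison for one variable."""
    sham = np.asarray(sham_values, dtype=float)
    ntx = np.asarray(ntx_values, dtype=float)
    s_med, s_q1, s_q3 = median_iqr(sham)
    n_med, n_q1, n_q3 = median_iqr(ntx)
    mw = mann_whitney_exact(sham, ntx)
    return GroupComparison(
        variable=variable, sham_values=sham, ntx_values=ntx,
        sham_median=s_med, sham_q1=s_q1, sham_q3=s_q3,
        ntx_median=n_med, ntx_q1=n_q1, ntx_q3=n_q3,
        u_statistic=mw.u, p_two_sided=mw.p_two_sided, method=mw.method)


def format_cell(median: float, q1: float, q3: float, digits: int = 2) -> str:
    """Render one table cell as ``median (q1-q3)``."""
    fmt = f"{{:.{digits}f}}"
    return f"{fmt.format(median)} ({fmt.format(q1)}-{fmt.format(q3)})"


def build_report(per_animal: pd.DataFrame, *,
                 variables: Optional[Sequence[str]] = None,
                 digits: int = 2) -> tuple[pd.DataFrame, str]:
    """Assemble the group-comparison table and its markdown rendering.

    ``per_animal`` is tidy with columns ``animal_id``, ``group``
    ("sham"/"ntx"), ``variable``, ``value``.  Every requested variable
    becomes one row "median (q1-q3)" per group with a significance star
    at p < 0.05; a variable missing for one group renders as absent with
    a warning instead of aborting the run.  Output is deterministic for
    identical input.
    """
    required = {"animal_id", "group", "variable", "value"}
    if not required.issubset(per_animal.columns):
        raise ValidationError(
            f"per-animal table must have columns {sorted(required)}")
    if variables is None:
        variables = list(dict.fromkeys(per_animal["variable"]))

    rows = []
    for var in variables:
        sub = per_animal[per_animal["variable"] == var]
        sham = sub.loc[sub["group"] == "sham", "value"].to_numpy(float)
        ntx = sub.loc[sub["group"] == "ntx", "value"].to_numpy(float)
        sham = sham[np.isfinite(sham)]
        ntx = ntx[np.isfinite(ntx)]
        if sham.size == 0 or ntx.size == 0:
            logger.warning("variable %r missing for %s group; cell left "
                           "absent", var,
                           "sham" if sham.size == 0 else "ntx")
            rows.append({
                "variable": var,
                "sham": format_cell(*median_iqr(sham), digits)
                        if sham.size else "-",
                "ntx": format_cell(*median_iqr(ntx), digits)
                       if ntx.size else "-",
                "u_statistic": np.nan, "p_two_sided": np.nan,
                "method": "-", "significant": False})
            continue
        cmp = compare_groups(var, sham, ntx)
        rows.append({
            "variable": var,
            "sham": format_cell(cmp.sham_median, cmp.sham_q1, cmp.sham_q3,
                                digits),
            "ntx": format_cell(cmp.ntx_median, cmp.ntx_q1, cmp.ntx_q3,
                               digits)
                   + (" *" if cmp.significant else ""),
            "u_statistic": cmp.u_statistic,
            "p_two_sided": cmp.p_two_sided,
            "method": cmp.method,
            "significant": cmp.significant})
    table = pd.DataFrame(rows)
    return table, render_markdown(table)


def render_markdown(table: pd.DataFrame) -> str:
    """Human-readable report.  Stars mark p < 0.05 (two-sided
    Mann-Whitney); no multiple-testing correction is applied, matching
    the per-variable reporting convention of the study design."""
    lines = [
        "| Variable | Sham | Ntx | U | p |",
        "| --- | --- | --- | --- | --- |",
    ]
    for _, row in table.iterrows():
        u = "-" if pd.isna(row["u_statistic"]) else f"{row['u_statistic']:g}"
        p = "-" if pd.isna(row["p_two_sided"]) else f"{row['p_two_sided']:.4f}"
        lines.append(
            f"| {row['variable']} | {row['sham']} | {row['ntx']} | {u} | {p} |")
    lines.append("")
    lines.append("Data are median (interquartile range); "
                 "`*` p < 0.05, two-sided Mann-Whitney U, "
                 "no multiple-testing correction.")
    return "\n".join(lines) + "\n"
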