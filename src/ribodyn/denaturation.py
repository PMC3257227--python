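"""Per-residue two-state urea unfolding of native-peak intensities.

In slow exchange the native cross-peak intensity tracks the folded
fraction, so each residue is fit independently with

    I(c) = 1 / (1 + exp(-(dG_H2O - m c) / RT))

after normalization to the 0 M point. The per-residue midpoints
C_1/2 = dG_H2O/m are aggregated into a cohort mean with a dispersion flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .constants import R_KCAL
from .peakio import PeakSeries, ResidueID

logger = logging.getLogger(__name__)


class UnbracketedTransitionError(ValueError):
    """The titration never crosses the midpoint within the measured range."""


@dataclass
class TwoStateFit:
    residue: ResidueID
    dG_H2O: float          # kcal/mol
    m_value: float         # kcal/(mol M)
    C_half: float          # M
    dG_err: float = math.nan
    m_err: float = math.nan
    C_half_err: float = math.nan
    converged: bool = True
    rms_residual: float = math.nan


def native_fraction(conc, dG_H2O, m_value, temperature_K=300.0):
    """Two-state folded fraction at denaturant concentration ``conc``."""
    rt = R_KCAL * temperature_K
    return 1.0 / (1.0 + np.exp(-(dG_H2O - m_value * np.asarray(conc)) / rt))


def fit_two_state(series: PeakSeries, temperature_K: float = 300.0,
                  normalize: bool = True) -> TwoStateFit:
    """Fit one residue's native-peak titration with the two-state model.

    Intensities are normalized to the 0 M point (scale invariance); the
    transition must be bracketed (the normalized curve has to fall below
    0.5 by the last concentration). A negative fitted m-value marks the fit
    as rejected (``converged=False``).
    """
    if series.axis_name != "urea_M":
        raise ValueError("two-state fits require axis_name == 'urea_M'")
    if len(series) < 6:
        raise ValueError("need at least 6 concentrations")
    c = series.axis_values
    y = series.values.astype(float)
    if normalize:
        if c[0] != 0.0:
            raise ValueError("normalization requires a 0 M point first")
        if y[0] <= 0:
            raise ValueError("non-positive 0 M intensity")
        y = y / y[0]
    if float(np.min(y)) > 0.5:
        raise UnbracketedTransitionError(
            f"{series.residue.label}: intensities never fall below 0.5 "
            f"within 0-{c[-1]:g} M")

    # midpoint start value: first crossing of 0.5
    cross = np.argmax(y < 0.5)
    c_half0 = float(c[cross]) if cross > 0 else float(np.median(c))
    m0 = 1.0
    try:
        popt, pcov = curve_fit(
            lambda cc, dg, m: native_fraction(cc, dg, m, temperature_K),
            c, y, p0=[m0 * c_half0, m0], maxfev=20000)
    except RuntimeError:
        return TwoStateFit(series.residue, math.nan, math.nan, math.nan,
                           converged=False)
    dg, m = (float(v) for v in popt)
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    if m <= 0:
        return TwoStateFit(series.residue, dg, m, math.nan,
                           float(perr[0]), float(perr[1]), converged=False)
    c_half = dg / m
    # first-order propagation ignoring the dG/m covariance sign would
    # overestimate; use the full covariance
    var = (pcov[0, 0] / m**2 + dg**2 * pcov[1, 1] / m**4
           - 2.0 * dg * pcov[0, 1] / m**3)
    resid = y - native_fraction(c, dg, m, temperature_K)
    return TwoStateFit(series.residue, dg, m, c_half,
                       float(perr[0]), float(perr[1]),
                       float(math.sqrt(max(var, 0.0))),
                       converged=True,
                       rms_residual=float(np.sqrt(np.mean(resid**2))))


def aggregate_midpoints(fits: Sequence[TwoStateFit],
                        dispersion_fraction: float = 0.10) -> dict:
    """Unweighted mean and SD of C_1/2 over converged fits.

    Returns a dict with ``mean``, ``sd``, ``n``, a ``heterogeneous`` flag
    (SD/mean above ``dispersion_fraction``) and the list of outliers
    (beyond 3 SD, or beyond the dispersion band when SD is degenerate).
    """
    ok = [f for f in fits if f.converged and np.isfinite(f.C_half)]
    if len(ok) < 2:
        raise ValueError("need at least 2 converged fits")
    vals = np.array([f.C_half for f in ok])
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    # robust outlier screen: the SD itself is inflated by a gross outlier,
    # so deviations are judged against the median with a MAD-based scale
    # (floored at 25% of the median for degenerate cohorts)
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    cut = max(3.0 * 1.4826 * mad, 0.25 * med)
    out_mask = np.abs(vals - med) > cut
    outliers = [ok[i].residue for i in np.nonzero(out_mask)[0]]
    heterogeneous = (sd / mean > dispersion_fraction) or bool(outliers)
    table = {f.residue: f.C_half for f in ok}
    return {"mean": mean, "sd": sd, "n": len(ok),
            "heterogeneous": heterogeneous, "outliers": outliers,
            "per_residue": table}


def chemical_shift_perturbation(shifts_0M: dict, shifts_cM: dict,
                                alpha: float = 0.154,
                                threshold: float = 0.1) -> dict:
    """Combined 1H/15N chemical-shift perturbation per residue.

    ``shifts_*`` map ResidueID -> (delta_H ppm, delta_N ppm). Residues
    present in only one list are skipped with a warning. Returns ``csp``
    (per-residue values) and ``above_threshold`` (listed at >= threshold).
    """
    csp = {}
    for rid, (h0, n0) in shifts_0M.items():
        if rid not in shifts_cM:
            logger.warning("%s missing from perturbed list — skipped", rid.label)
            continue
        h1, n1 = shifts_cM[rid]
        csp[rid] = math.sqrt((h1 - h0) ** 2 + (alpha * (n1 - n0)) ** 2)
    for rid in shifts_cM:
        if rid not in shifts_0M:
            logger.warning("%s missing from reference list — skipped", rid.label)
    above = sorted((r for r, v in csp.items() if v >= threshold - 1e-12),
                   key=lambda r: r.seq_number)
    return {"csp": csp, "above_threshold": above}
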