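"""Hydrogen/deuterium exchange kinetics and opening energetics.

Pipeline: first-order decay fits of peak height versus time, intrinsic
(random-coil) rate prediction from a shipped nearest-neighbour parameter
set, protection factors P = k_rc/k_obs, opening free energies
dG_op = R T ln(P), and EX1/EX2 regime discrimination from the pH dependence
of the observed rates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import curve_fit

from .constants import R_KCAL
from .peakio import PeakSeries, ResidueID

logger = logging.getLogger(__name__)

__all__ = [
    "ExchangeResult", "DecayFit", "fit_exchange_decay", "intrinsic_rate",
    "protection_and_energy", "classify_regime", "analyze_series",
    "load_reference_table",
]


@dataclass
class DecayFit:
    """Result of a first-order decay fit I(t) = I0 exp(-k t)."""

    k_obs: float            # 1/hr (nan when not quantifiable)
    k_obs_err: float
    I0: float
    I0_err: float
    flag: str               # "ok" | "too_slow" | "non_exchanging" | "fit_failure"
    k_upper_bound: Optional[float] = None
    qualitative_only: bool = False


@dataclass
class ExchangeResult:
    residue: ResidueID
    k_obs: float
    k_obs_err: float
    k_rc: float
    P: float
    dG_op: float
    dG_op_err: float
    regime: str = "undetermined"
    flag: str = "ok"


# ---------------------------------------------------------------------------
# decay fitting
# ---------------------------------------------------------------------------

def _noise_level(series: PeakSeries) -> float:
    if series.errors is not None and np.any(series.errors > 0):
        return float(np.median(series.errors[series.errors > 0]))
    # fall back to the rms of second differences (detrended noise estimate)
    if len(series) >= 3:
        d2 = np.diff(series.values, n=2)
        return float(np.sqrt(np.mean(d2**2) / 6.0)) if len(d2) else 0.0
    return 0.0


def fit_exchange_decay(series: PeakSeries,
                       quantifiable_halflife_factor: float = 5.0) -> DecayFit:
    """Weighted least-squares fit of I(t) = I(0) exp(-k t).

    Series whose total decay is below twice the noise level are flagged
    ``too_slow`` and only an upper bound on k is reported. Fits whose
    half-life exceeds ``quantifiable_halflife_factor`` times the last time
    point are marked qualitative-only. A negative fitted rate flags the
    residue as non-exchanging rather than raising.
    """
    if series.axis_name != "time_hr":
        raise ValueError("exchange fits require axis_name == 'time_hr'")
    if len(series) < 4:
        raise ValueError("need at least 4 time points for a decay fit")
    t = series.axis_values
    y = series.values
    noise = _noise_level(series)
    decay = float(y[0] - y[-1])
    t_last = float(t[-1])

    if noise > 0 and 0.0 <= decay < 2.0 * noise:
        # an unobservable decay bounds the rate from above
        frac = max(2.0 * noise / max(abs(y[0]), 1e-300), 1e-12)
        k_ub = -math.log(max(1.0 - frac, 1e-12)) / t_last
        return DecayFit(math.nan, math.nan, float(y[0]), noise,
                        "too_slow", k_upper_bound=k_ub, qualitative_only=True)

    sigma = series.errors if (series.errors is not None
                              and np.all(series.errors > 0)) else None
    k0 = max(1.0 / t_last, 1e-6)
    if decay > 0 and y[-1] > 0 and y[0] > 0:
        k0 = max(math.log(y[0] / y[-1]) / t_last, 1e-6)
    try:
        popt, pcov = curve_fit(
            lambda tt, i0, k: i0 * np.exp(-k * tt), t, y,
            p0=[float(y[0]), k0], sigma=sigma, absolute_sigma=sigma is not None,
            maxfev=10000)
    except RuntimeError:
        return DecayFit(math.nan, math.nan, math.nan, math.nan, "fit_failure")
    i0, k = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    if k <= 0:
        return DecayFit(math.nan, math.nan, i0, float(perr[0]), "non_exchanging")
    qualitative = (math.log(2.0) / k) > quantifiable_halflife_factor * t_last
    return DecayFit(k, float(perr[1]), i0, float(perr[0]), "ok",
                    qualitative_only=qualitative)


# ---------------------------------------------------------------------------
# intrinsic rates
# ---------------------------------------------------------------------------

_PARAMS = None


def _load_params() -> dict:
    global _PARAMS
    if _PARAMS is None:
        text = resources.files("ribodyn.data").joinpath(
            "intrinsic_exchange_params.yaml").read_text()
        _PARAMS = yaml.safe_load(text)
    return _PARAMS


def _factors(code: str, pD: float, params: dict) -> np.ndarray:
    """[AL, AR, BL, BR] for one residue, titration-averaged where needed."""
    table = params["factors"]
    if code in table:
        return np.array(table[code], dtype=float)
    if code in params["pka_D2O"]:
        pka = params["pka_D2O"][code]
        f_prot = 1.0 / (1.0 + 10.0 ** (pD - pka))
        prot = np.array(table[f"{code}_prot"], dtype=float)
        deprot = np.array(table[f"{code}_deprot"], dtype=float)
        # population-average the factor multipliers (not the exponents)
        return np.log10(f_prot * 10.0**prot + (1.0 - f_prot) * 10.0**deprot)
    raise KeyError(f"no intrinsic-rate parameters for residue {code!r}")


def intrinsic_rate(residue_code: str, left_neighbor_code: str,
                   pH_read: float, temperature_K: float = 300.0,
                   medium: str = "H2O->D2O") -> float:
    """Random-coil amide exchange rate k_rc in 1/hr.

    Poly-DL-alanine reference rates with acid-, base- and water-catalysed
    terms, nearest-neighbour side-chain factors, Arrhenius temperature
    correction and the glass-electrode pD correction (pD = pH_read + 0.4).
    """
    if not (0.0 < pH_read < 14.0):
        raise ValueError("pH_read must be in (0, 14)")
    if medium != "H2O->D2O":
        raise ValueError(f"unsupported medium {medium!r}")
    p = _load_params()
    pD = pH_read + 0.4
    own = _factors(residue_code.upper(), pD, p)
    left = _factors(left_neighbor_code.upper(), pD, p)
    al, bl = own[0], own[2]
    ar, br = left[1], left[3]

    t_ref = p["reference_temperature_K"]
    r_cal = 1.987e-3  # kcal/(mol K)
    arr = {k: math.exp(-ea / r_cal * (1.0 / temperature_K - 1.0 / t_ref))
           for k, ea in p["activation_energy_kcal"].items()}

    k_acid = 10.0 ** (p["log_kA_ref"] + al + ar - pD) * arr["acid"]
    k_base = 10.0 ** (p["log_kB_ref"] + bl + br + pD - p["pKD"]) * arr["base"]
    k_water = 10.0 ** (p["log_kW_ref"] + bl + br) * arr["water"]
    return (k_acid + k_base + k_water) * 60.0  # per min -> per hr


# ---------------------------------------------------------------------------
# protection and opening free energy
# ---------------------------------------------------------------------------

def protection_and_energy(k_obs: float, k_rc: float,
                          temperature_K: float = 300.0,
                          k_obs_err: float = 0.0) -> tuple:
    """(P, dG_op, dG_op_err) from observed and intrinsic rates.

    P = k_rc/k_obs and dG_op = -R T ln(k_obs/k_rc) = R T ln(P). A protection
    factor below 1 (exchange faster than the random-coil reference) warns
    but is still returned.
    """
    if k_obs <= 0 or k_rc <= 0:
        raise ValueError("k_obs and k_rc must be positive")
    P = k_rc / k_obs
    if P < 1.0:
        logger.warning("protection factor %.3g < 1: exchange faster than "
                       "intrinsic reference", P)
    dG = R_KCAL * temperature_K * math.log(P)
    dG_err = R_KCAL * temperature_K * (k_obs_err / k_obs) if k_obs_err else 0.0
    return P, dG, dG_err


def dG_from_protection(P: float, temperature_K: float = 300.0) -> float:
    """R T ln(P) in kcal/mol."""
    if P <= 0:
        raise ValueError("P must be positive")
    return R_KCAL * temperature_K * math.log(P)


def classify_regime(k_ex_low_pH: float, k_ex_high_pH: float,
                    delta_pH: float, band_factor: float = 3.0) -> str:
    """EX1/EX2 discrimination from a pH pair of observed rates.

    EX2 predicts the rate ratio 10**delta_pH (base catalysis tracks [OD-]);
    EX1 predicts a ratio of 1. A rate ratio within ``band_factor`` of either
    limiting prediction selects the regime; anything else (or an ambiguous
    overlap) is ``undetermined``.
    """
    if k_ex_low_pH <= 0 or k_ex_high_pH <= 0:
        raise ValueError("rates must be positive")
    if delta_pH <= 0:
        raise ValueError("delta_pH must be positive")
    r = k_ex_high_pH / k_ex_low_pH
    ex2_pred = 10.0 ** delta_pH
    in_ex1 = 1.0 / band_factor <= r <= band_factor
    in_ex2 = ex2_pred / band_factor <= r <= ex2_pred * band_factor
    if in_ex1 and not in_ex2:
        return "EX1"
    if in_ex2 and not in_ex1:
        return "EX2"
    return "undetermined"


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def analyze_series(series_list: Sequence[PeakSeries], sequence: str,
                   pH_read: float, temperature_K: float = 300.0) -> list:
    """Fit all series and assemble :class:`ExchangeResult` records.

    ``sequence`` is the one-letter protein sequence with 1-based numbering;
    it supplies the left-neighbour context for the intrinsic rates.
    Prolines and residue 1 carry no exchangeable backbone amide information
    and are skipped.
    """
    out = []
    for series in series_list:
        n = series.residue.seq_number
        if n < 2 or n > len(sequence):
            logger.warning("%s outside sequence — skipped", series.residue.label)
            continue
        if sequence[n - 1].upper() == "P":
            logger.warning("%s is proline — skipped", series.residue.label)
            continue
        fit = fit_exchange_decay(series)
        if fit.flag != "ok":
            out.append(ExchangeResult(series.residue, math.nan, math.nan,
                                      math.nan, math.nan, math.nan, math.nan,
                                      flag=fit.flag))
            continue
        from .peakio import AA_1TO3
        code = AA_1TO3.get(sequence[n - 1].upper(), "UNK")
        left = AA_1TO3.get(sequence[n - 2].upper(), "UNK")
        k_rc = intrinsic_rate(code, left, pH_read, temperature_K)
        P, dG, dG_err = protection_and_energy(fit.k_obs, k_rc, temperature_K,
                                              fit.k_obs_err)
        flag = "qualitative" if fit.qualitative_only else "ok"
        out.append(ExchangeResult(series.residue, fit.k_obs, fit.k_obs_err,
                                  k_rc, P, dG, dG_err, flag=flag))
    return out


def results_to_frame(results: Sequence[ExchangeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {"residue": [r.residue.label for r in results],
         "k_obs": [r.k_obs for r in results],
         "k_obs_err": [r.k_obs_err for r in results],
         "k_rc": [r.k_rc for r in results],
         "P": [r.P for r in results],
         "dG_op": [r.dG_op for r in results],
         "dG_op_err": [r.dG_op_err for r in results],
         "regime": [r.regime for r in results],
         "flag": [r.flag for r in results]})


def load_reference_table() -> pd.DataFrame:
    """Published per-residue exchange summary shipped with the package."""
    with resources.files("ribodyn.data").joinpath(
            "hx_reference_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")
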