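"""Amide 15N relaxation: forward model and model-free inversion.

Implements the two-parameter (S2, tau_e) spectral density with a single
global rotational correlation time, the standard dipolar + axially
symmetric CSA expressions for R1, R2, NOE and the transverse/longitudinal
CSA-dipole cross-correlated rates, reduced spectral-density mapping,
detection of exchange contributions from the R2/eta_xy combination, and an
empirical size/temperature estimate of the correlation time.

Times are seconds and frequencies rad/s at this module's boundary; the
result container reports ns/ps for readability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares, minimize_scalar

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .peakio import RelaxationRecord, ResidueID

logger = logging.getLogger(__name__)

__all__ = [
    "Rates", "ModelFreeResult", "SpectralDensityTriple",
    "spectral_density", "forward_rates", "fit_model_free",
    "reduced_spectral_density", "rigid_body_curve", "detect_exchange",
    "empirical_tauc",
]


def spectral_density(S2, tau_e, tau_c, omega):
    """Model-free spectral density J(omega), s/rad.

    J(w) = (2/5) [ S2 tau_c / (1 + (w tau_c)^2)
                 + (1 - S2) tau / (1 + (w tau)^2) ],   1/tau = 1/tau_c + 1/tau_e

    Arguments may be scalars or broadcastable arrays; ``omega`` is used in
    magnitude. ``tau_e == 0`` cleanly removes the internal-motion term.
    """
    S2 = np.asarray(S2, dtype=float)
    tau_e = np.asarray(tau_e, dtype=float)
    omega = np.abs(np.asarray(omega, dtype=float))
    tau = np.where(tau_e > 0, tau_c * tau_e / (tau_c + tau_e), 0.0)
    j_global = S2 * tau_c / (1.0 + (omega * tau_c) ** 2)
    j_internal = np.where(
        tau > 0, (1.0 - S2) * tau / (1.0 + (omega * tau) ** 2), 0.0)
    return 0.4 * (j_global + j_internal)


@dataclass(frozen=True)
class Rates:
    R1: float
    R2: float
    NOE: float
    eta_xy: float
    eta_zz: float


def _frequencies(field_MHz: float, constants: PhysicalConstants):
    wh = constants.omega_h(field_MHz)
    wn = constants.omega_n(field_MHz)  # negative
    return wh, wn


def forward_rates(S2, tau_e, tau_c, Rex=0.0, field_MHz: float = 500.13,
                  constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Forward-calculate (R1, R2, NOE, eta_xy, eta_zz).

    Isotropic overall tumbling, axially symmetric 15N CSA; ``Rex`` adds to
    R2 only. The sign of gamma_N is honoured, so NOE < 1 emerges naturally
    in the slow-tumbling regime. All rate arguments broadcast.
    """
    wh, wn = _frequencies(field_MHz, constants)
    d = constants.d_dipolar
    c = constants.c_csa(field_MHz)
    J = lambda w: spectral_density(S2, tau_e, tau_c, w)  # noqa: E731

    j0 = J(0.0)
    jn = J(wn)
    jhmn = J(wh - wn)   # |wh| + |wn|
    jh = J(wh)
    jhpn = J(wh + wn)   # |wh| - |wn|

    d2_4 = d * d / 4.0
    R1 = d2_4 * (jhmn + 3.0 * jn + 6.0 * jhpn) + c * c * jn
    R2 = (d * d / 8.0) * (4.0 * j0 + jhmn + 3.0 * jn + 6.0 * jh + 6.0 * jhpn) \
        + (c * c / 6.0) * (4.0 * j0 + 3.0 * jn) + Rex
    sigma = d2_4 * (6.0 * jhpn - jhmn)
    NOE = 1.0 + (constants.gamma_H / constants.gamma_N) * sigma / R1
    p2 = constants.p2_theta
    eta_xy = (math.sqrt(3.0) / 6.0) * d * c * p2 * (4.0 * j0 + 3.0 * jn)
    eta_zz = math.sqrt(3.0) * d * c * p2 * jn
    return Rates(R1, R2, NOE, eta_xy, eta_zz)


# ---------------------------------------------------------------------------
# model-free fitting
# ---------------------------------------------------------------------------

@dataclass
class ModelFreeResult:
    tau_c_ns: float
    residues: list
    S2: np.ndarray
    tau_e_ps: np.ndarray
    Rex: Optional[np.ndarray]
    S2_ci90: Optional[np.ndarray]        # (n, 2): 5th/95th percentiles
    tau_e_ci90_ps: Optional[np.ndarray]
    excluded: list = field(default_factory=list)   # (label, reason)
    chi2: float = math.nan
    back_calc: dict = field(default_factory=dict)  # mean |dev|/value per obs

    @property
    def mean_S2(self) -> float:
        return float(np.mean(self.S2))


def _rate_arrays(S2, tau_e, tau_c, field_MHz, constants):
    r = forward_rates(S2, tau_e, tau_c, 0.0, field_MHz, constants)
    return np.stack([np.broadcast_to(r.R1, np.shape(S2)),
                     np.broadcast_to(r.R2, np.shape(S2)),
                     np.broadcast_to(r.NOE, np.shape(S2))], axis=-1)


def _default_grids():
    s2 = np.linspace(0.05, 1.0, 96)
    te = np.concatenate([[0.0], np.geomspace(1e-12, 2e-9, 48)])
    g = np.stack(np.meshgrid(s2, te, indexing="ij"), axis=-1).reshape(-1, 2)
    return g[:, 0], g[:, 1]


def _profile_chi2(tau_c, data, err, field_MHz, constants, s2g, teg):
    """Grid-profiled objective: per residue, min over the (S2, tau_e) grid."""
    grid_rates = _rate_arrays(s2g, teg, tau_c, field_MHz, constants)  # (G, 3)
    resid = (grid_rates[None, :, :] - data[:, None, :]) / err[:, None, :]
    chi2 = np.einsum("rgo,rgo->rg", resid, resid)
    idx = np.argmin(chi2, axis=1)
    return float(chi2[np.arange(len(data)), idx].sum()), idx


def _polish_residue(obs, err, tau_c, field_MHz, constants, x0):
    """Refine (S2, tau_e) for one residue at fixed tau_c."""
    def fun(x):
        r = forward_rates(x[0], x[1] * 1e-12, tau_c, 0.0, field_MHz, constants)
        model = np.array([r.R1, r.R2, r.NOE])
        return (model - obs) / err

    sol = least_squares(fun, x0=[min(max(x0[0], 0.051), 0.999),
                                 min(max(x0[1], 0.0), 4999.0)],
                        bounds=([0.05, 0.0], [1.0, 5000.0]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    return sol.x, float(np.sum(sol.fun**2))


def fit_model_free(records: Sequence[RelaxationRecord],
                   exclusions: Sequence[str] = (),
                   tau_c_bounds_ns=(2.0, 15.0), tau_c_step_ns: float = 0.05,
                   n_mc: int = 0, seed: Optional[int] = None,
                   constants: PhysicalConstants = DEFAULT_CONSTANTS) -> ModelFreeResult:
    """Two-stage global model-free fit at a single field.

    Stage 1 scans a tau_c grid, profiling per-residue (S2, tau_e) out on a
    vectorized parameter grid; stage 2 polishes tau_c by bounded scalar
    minimization with exact per-residue refits. Per-parameter 90% confidence
    bounds come from ``n_mc`` Monte-Carlo noise replicates refit at the
    fitted tau_c. Residues named in ``exclusions`` or with negative NOE are
    left out with a recorded reason.
    """
    excluded = []
    usable = []
    for rec in records:
        if rec.residue.label in exclusions:
            excluded.append((rec.residue.label, "excluded by caller"))
        elif rec.NOE < 0:
            excluded.append((rec.residue.label, "negative NOE"))
        else:
            usable.append(rec.with_default_errors())
    if len(usable) < 10:
        raise ValueError(f"need >= 10 usable residues, have {len(usable)}")
    fields = {r.field_MHz for r in usable}
    if len(fields) != 1:
        raise ValueError("all records must share one spectrometer field")
    field_MHz = usable[0].field_MHz

    data = np.array([[r.R1, r.R2, r.NOE] for r in usable])
    err = np.array([[r.R1_err, r.R2_err, r.NOE_err] for r in usable])

    s2g, teg = _default_grids()
    lo, hi = (b * 1e-9 for b in tau_c_bounds_ns)
    taus = np.arange(lo, hi + 1e-15, tau_c_step_ns * 1e-9)
    chi_grid = np.array([_profile_chi2(t, data, err, field_MHz, constants,
                                       s2g, teg)[0] for t in taus])
    # smallest tau_c wins ties
    i_best = int(np.argmin(chi_grid))
    tau0 = taus[i_best]
    _, idx0 = _profile_chi2(tau0, data, err, field_MHz, constants, s2g, teg)
    starts = {i: (s2g[idx0[i]], teg[idx0[i]] * 1e12) for i in range(len(data))}

    def objective(tau_c):
        total = 0.0
        for i in range(len(data)):
            x, chi = _polish_residue(data[i], err[i], tau_c, field_MHz,
                                     constants, starts[i])
            starts[i] = tuple(x)
            total += chi
        return total

    span = 2.0 * tau_c_step_ns * 1e-9
    res = minimize_scalar(objective, bounds=(max(lo, tau0 - span),
                                             min(hi, tau0 + span)),
                          method="bounded",
                          options={"xatol": 1e-13})
    tau_c = float(res.x)

    S2 = np.empty(len(data))
    te_ps = np.empty(len(data))
    chi_total = 0.0
    for i in range(len(data)):
        x, chi = _polish_residue(data[i], err[i], tau_c, field_MHz,
                                 constants, starts[i])
        S2[i], te_ps[i] = x
        chi_total += chi

    back = _back_calculation_report(data, S2, te_ps * 1e-12, tau_c,
                                    field_MHz, constants)

    S2_ci = te_ci = None
    if n_mc > 0:
        S2_ci, te_ci = _monte_carlo_ci(data, err, tau_c, field_MHz, constants,
                                       n_mc, seed)

    return ModelFreeResult(
        tau_c_ns=tau_c * 1e9,
        residues=[r.residue for r in usable],
        S2=S2, tau_e_ps=te_ps, Rex=None,
        S2_ci90=S2_ci, tau_e_ci90_ps=te_ci,
        excluded=excluded, chi2=chi_total, back_calc=back)


def _back_calculation_report(data, S2, tau_e, tau_c, field_MHz, constants):
    """Mean fractional |deviation| for T1, T2 and NOE."""
    r = forward_rates(S2, tau_e, tau_c, 0.0, field_MHz, constants)
    t1_dev = np.abs(1.0 / r.R1 - 1.0 / data[:, 0]) * data[:, 0]
    t2_dev = np.abs(1.0 / r.R2 - 1.0 / data[:, 1]) * data[:, 1]
    noe_dev = np.abs((r.NOE - data[:, 2]) / data[:, 2])
    return {"T1": float(np.mean(t1_dev)), "T2": float(np.mean(t2_dev)),
            "NOE": float(np.mean(noe_dev))}


def _monte_carlo_ci(data, err, tau_c, field_MHz, constants, n_mc, seed):
    """90% intervals (5th/95th percentiles) from noise replicates.

    Per-residue parameters are refit at fixed tau_c on a fine grid; this is
    vectorized over replicates.
    """
    rng = np.random.default_rng(seed)
    s2_fine = np.linspace(0.05, 1.0, 381)
    te_fine = np.concatenate([[0.0], np.geomspace(1e-12, 2e-9, 41)])
    g = np.stack(np.meshgrid(s2_fine, te_fine, indexing="ij"),
                 axis=-1).reshape(-1, 2)
    grid_rates = _rate_arrays(g[:, 0], g[:, 1], tau_c, field_MHz, constants)
    n = len(data)
    S2_ci = np.empty((n, 2))
    te_ci = np.empty((n, 2))
    for i in range(n):
        reps = data[i][None, :] + rng.normal(size=(n_mc, 3)) * err[i][None, :]
        chi2 = np.zeros((n_mc, len(g)))
        for o in range(3):
            chi2 += ((grid_rates[None, :, o] - reps[:, o, None])
                     / err[i][o]) ** 2
        best = np.argmin(chi2, axis=1)
        S2_ci[i] = np.percentile(g[best, 0], [5.0, 95.0])
        te_ci[i] = np.percentile(g[best, 1] * 1e12, [5.0, 95.0])
    return S2_ci, te_ci


# ---------------------------------------------------------------------------
# reduced spectral density mapping
# ---------------------------------------------------------------------------

@dataclass
class SpectralDensityTriple:
    residue: ResidueID
    J0: float
    J_wN: float
    J_087wH: float
    flagged: bool = False

    def __post_init__(self) -> None:
        if not self.flagged and not (
                self.J0 >= self.J_wN >= self.J_087wH >= 0.0):
            logger.warning("%s: J ordering violated (J0=%.3g, JwN=%.3g, "
                           "Jh=%.3g)", self.residue.label, self.J0, self.J_wN,
                           self.J_087wH)


def reduced_spectral_density(
        record: RelaxationRecord,
        constants: PhysicalConstants = DEFAULT_CONSTANTS) -> SpectralDensityTriple:
    """Map (R1, R2, NOE) onto J(0), J(wN), J(0.87 wH).

    Uses the standard high-frequency lumping: the three proton-frequency
    densities entering R1/R2 are replaced by a single J(0.87 wH) obtained
    from the cross-relaxation rate sigma_NH = (NOE - 1) R1 gammaN/gammaH.
    A NOE at or above 1 (no measurable sigma) flags the residue and leaves
    J(0.87 wH) undefined.
    """
    d = constants.d_dipolar
    c = constants.c_csa(record.field_MHz)
    flagged = record.NOE >= 1.0
    if flagged:
        jh = math.nan
        jh_eff = 0.0
    else:
        sigma = (record.NOE - 1.0) * record.R1 * (
            constants.gamma_N / constants.gamma_H)
        jh = 4.0 * sigma / (5.0 * d * d)
        jh_eff = jh
    jn = (record.R1 - 1.75 * d * d * jh_eff) / (0.75 * d * d + c * c)
    j0 = (record.R2 - (d * d / 8.0) * (3.0 * jn + 13.0 * jh_eff)
          - 0.5 * c * c * jn) / (0.5 * d * d + (2.0 / 3.0) * c * c)
    return SpectralDensityTriple(record.residue, float(j0), float(jn),
                                 float(jh), flagged)


def rigid_body_curve(field_MHz: float, tau_range_s=(0.5e-9, 20e-9),
                     n: int = 200,
                     constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """(J0, JwN) limiting curve for a rigid isotropic tumbler.

    Parametrized by correlation time; for plotting measured (J0, JwN)
    points against the rigid-body expectation.
    """
    wn = constants.omega_n(field_MHz)
    taus = np.geomspace(tau_range_s[0], tau_range_s[1], n)
    j0 = 0.4 * taus
    jn = 0.4 * taus / (1.0 + (wn * taus) ** 2)
    return j0, jn


# ---------------------------------------------------------------------------
# exchange detection from cross-correlated rates
# ---------------------------------------------------------------------------

def _trimmed_mean(x: np.ndarray, trim: float = 0.2) -> float:
    xs = np.sort(x)
    k = int(len(xs) * trim / 2.0)
    core = xs[k: len(xs) - k] if len(xs) - 2 * k >= 1 else xs
    return float(np.mean(core))


def _tau_c_from_eta(eta_med: float, field_MHz: float, s2_assumed: float,
                    constants: PhysicalConstants):
    wn = constants.omega_n(field_MHz)
    d = constants.d_dipolar
    c = constants.c_csa(field_MHz)
    pref = (math.sqrt(3.0) / 6.0) * d * c * constants.p2_theta * s2_assumed

    def f(tau):
        j0 = 0.4 * tau
        jn = 0.4 * tau / (1.0 + (wn * tau) ** 2)
        return pref * (4.0 * j0 + 3.0 * jn) - eta_med

    return brentq(f, 1e-10, 1e-7)


def detect_exchange(records: Sequence[RelaxationRecord],
                    threshold_sd: float = 2.0, s2_assumed: float = 0.9,
                    constants: PhysicalConstants = DEFAULT_CONSTANTS) -> dict:
    """Flag residues with an exchange contribution to R2.

    Exchange-free R2 is proportional to eta_xy; the proportionality kappa
    is estimated as the trimmed mean of R2/eta_xy over the consensus, so
    residues whose R2 - kappa*eta_xy exceeds the trimmed-mean baseline by
    more than ``threshold_sd`` standard deviations stand out. A uniform
    offset over the whole sequence is absorbed into kappa; it is reported
    through ``global_offset_warning`` instead (kappa well above the value
    expected for a rigid tumbler of the eta-implied size).
    """
    usable = [r for r in records if r.eta_xy is not None and r.eta_xy > 0]
    if len(usable) < 5:
        raise ValueError("need at least 5 residues with eta_xy")
    r2 = np.array([r.R2 for r in usable])
    eta = np.array([r.eta_xy for r in usable])
    kappa = _trimmed_mean(r2 / eta)
    base = r2 - kappa * eta
    mu = _trimmed_mean(base)
    sd = float(np.std(base))
    floor = 1e-3 * float(np.median(r2))
    cut = mu + max(threshold_sd * sd, floor)
    flags = {u.residue: bool(b > cut) for u, b in zip(usable, base)}

    warning = False
    try:
        tau_est = _tau_c_from_eta(float(np.median(eta)), usable[0].field_MHz,
                                  s2_assumed, constants)
        rigid = forward_rates(s2_assumed, 0.0, tau_est,
                              field_MHz=usable[0].field_MHz,
                              constants=constants)
        kappa_theory = rigid.R2 / rigid.eta_xy
        if kappa > 1.15 * kappa_theory:
            warning = True
            logger.warning(
                "R2/eta_xy consensus (%.2f) well above the exchange-free "
                "expectation (%.2f): a uniform exchange contribution over "
                "the whole sequence cannot be ruled out", kappa, kappa_theory)
    except ValueError:
        logger.warning("could not invert eta_xy for a size estimate")
    return {"flags": flags, "kappa": kappa,
            "global_offset_warning": warning}


# ---------------------------------------------------------------------------
# empirical size -> correlation time
# ---------------------------------------------------------------------------

def empirical_tauc(n_residues: int, temperature_K: float = 300.0) -> float:
    """Empirical correlation time (ns) of a globular protein in water.

    tau_c = (9.18e-3 / T) * exp(2416 / T) * N**0.93  [ns]
    """
    if n_residues < 10:
        raise ValueError("formula calibrated for n_residues >= 10")
    return (9.18e-3 / temperature_K) * math.exp(2416.0 / temperature_K) \
        * n_residues ** 0.93
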