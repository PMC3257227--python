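"""Ground-truthed synthetic inputs for every analysis pipeline.

Each generator returns ``(data, truth)`` where ``truth`` is a
machine-readable table (DataFrame or dict) consumed directly by the test
suite. All randomness flows from the seed in :class:`GeneratorSpec`;
identical specs give identical outputs.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import relaxation
from .constants import R_KCAL
from .peakio import (AA_1TO3, Atom, PeakSeries, RelaxationRecord, ResidueID,
                     StructureModel, Trajectory, VolumePair)

# sequence alphabet without proline (prolines carry no backbone amide)
_ALPHABET = "ACDEFGHIKLMNQRSTVWY"


@dataclass(frozen=True)
class GeneratorSpec:
    seed: int = 0
    n_residues: int = 50
    noise_model: str = "gaussian_fractional"
    noise_level: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_model not in ("gaussian_fractional", "gaussian_absolute"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_level < 0:
            raise ValueError("noise_level must be non-negative")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream so generators stay reproducible under reordering."""
        key = zlib.crc32(stream.encode())  # stable across processes
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


def _add_noise(rng, values: np.ndarray, spec: GeneratorSpec) -> np.ndarray:
    if spec.noise_level == 0:
        return values.copy()
    eps = rng.normal(size=values.shape)
    if spec.noise_model == "gaussian_fractional":
        return values * (1.0 + spec.noise_level * eps)
    return values + spec.noise_level * eps


def random_sequence(spec: GeneratorSpec) -> str:
    rng = spec.rng("sequence")
    return "".join(rng.choice(list(_ALPHABET), size=spec.n_residues))


def _residue_ids(spec: GeneratorSpec, sequence: str) -> list:
    # numbering starts at 2: position 1 has no observable amide decay
    return [ResidueID(i + 1, AA_1TO3[sequence[i]])
            for i in range(1, spec.n_residues)]


# ---------------------------------------------------------------------------
# hydrogen exchange
# ---------------------------------------------------------------------------

def gen_hx(spec: GeneratorSpec, k_range=(0.003, 2.2),
           timepoints: Optional[np.ndarray] = None,
           temperature_K: float = 300.0):
    """Exponential H/D decays with log-uniform rates over ``k_range`` (1/hr).

    Returns (series, truth) with truth columns residue, k_true, plus the
    sequence string in ``truth.attrs['sequence']``.
    """
    rng = spec.rng("hx")
    sequence = random_sequence(spec)
    residues = _residue_ids(spec, sequence)
    if timepoints is None:
        timepoints = np.array([0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0,
                               64.0, 128.0])
    k_true = np.exp(rng.uniform(math.log(k_range[0]), math.log(k_range[1]),
                                size=len(residues)))
    series = []
    for rid, k in zip(residues, k_true):
        clean = 100.0 * np.exp(-k * timepoints)
        noisy = _add_noise(rng, clean, spec)
        err = (spec.noise_level * clean if spec.noise_level > 0 else None)
        series.append(PeakSeries(rid, "time_hr", timepoints.copy(), noisy,
                                 errors=err))
    truth = pd.DataFrame({"residue": [r.label for r in residues],
                          "k_true": k_true})
    truth.attrs["sequence"] = sequence
    truth.attrs["temperature_K"] = temperature_K
    return series, truth


# ---------------------------------------------------------------------------
# relaxation
# ---------------------------------------------------------------------------

def gen_relaxation(spec: GeneratorSpec, tau_c_ns: float = 7.9,
                   S2_mean: float = 0.90, S2_sd: float = 0.07,
                   tau_e_ps: float = 30.0,
                   flexible_residues: Sequence[int] = (),
                   flexible_S2: float = 0.6,
                   rex: Optional[dict] = None,
                   field_MHz: float = 500.13,
                   with_eta: bool = True):
    """Relaxation records from an isotropic tumbler with per-residue S2.

    S2 values are drawn from N(S2_mean, S2_sd) truncated to (0, 1] by
    rejection; residues listed in ``flexible_residues`` (sequence numbers)
    are planted at ``flexible_S2``. ``rex`` maps sequence number -> Rex
    (1/s) added to R2. Reported errors equal the noise level (2% default
    when noiseless, so weighting stays sane).
    """
    rng = spec.rng("relaxation")
    sequence = random_sequence(spec)
    residues = _residue_ids(spec, sequence)
    n = len(residues)
    S2 = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(S2_mean, S2_sd, size=n - filled)
        ok = draw[(draw > 0.0) & (draw <= 1.0)]
        S2[filled: filled + len(ok)] = ok
        filled += len(ok)
    flex = set(flexible_residues)
    for i, rid in enumerate(residues):
        if rid.seq_number in flex:
            S2[i] = flexible_S2
    rex = rex or {}
    tau_c = tau_c_ns * 1e-9
    tau_e = tau_e_ps * 1e-12

    err_frac = spec.noise_level if spec.noise_level > 0 else 0.02
    records = []
    rows = []
    for i, rid in enumerate(residues):
        rx = float(rex.get(rid.seq_number, 0.0))
        r = relaxation.forward_rates(S2[i], tau_e, tau_c, rx, field_MHz)
        vals = np.array([r.R1, r.R2, r.NOE, r.eta_xy, r.eta_zz])
        noisy = _add_noise(rng, vals, spec)
        errs = err_frac * np.abs(vals)
        records.append(RelaxationRecord(
            residue=rid, R1=float(noisy[0]), R2=float(noisy[1]),
            NOE=float(noisy[2]),
            R1_err=float(errs[0]), R2_err=float(errs[1]),
            NOE_err=float(errs[2]),
            eta_xy=float(noisy[3]) if with_eta else None,
            eta_xy_err=float(errs[3]) if with_eta else None,
            eta_zz=float(noisy[4]) if with_eta else None,
            eta_zz_err=float(errs[4]) if with_eta else None,
            field_MHz=field_MHz))
        rows.append({"residue": rid.label, "S2_true": S2[i],
                     "tau_e_ps_true": tau_e_ps, "Rex_true": rx})
    truth = pd.DataFrame(rows)
    truth.attrs.update({"tau_c_ns": tau_c_ns, "field_MHz": field_MHz,
                        "sequence": sequence})
    return records, truth


# ---------------------------------------------------------------------------
# urea denaturation
# ---------------------------------------------------------------------------

def gen_urea(spec: GeneratorSpec, C_half: float = 4.2, m_value: float = 1.2,
             conc: Optional[np.ndarray] = None,
             midpoint_jitter_M: float = 0.0,
             temperature_K: float = 300.0):
    """Two-state native-fraction titrations with optional midpoint jitter."""
    rng = spec.rng("urea")
    sequence = random_sequence(spec)
    residues = _residue_ids(spec, sequence)
    if conc is None:
        conc = np.arange(0.0, 7.0 + 1e-9, 1.0)
    rt = R_KCAL * temperature_K
    series, rows = [], []
    for rid in residues:
        c_half_i = C_half + (rng.normal(0.0, midpoint_jitter_M)
                             if midpoint_jitter_M > 0 else 0.0)
        dg = m_value * c_half_i
        clean = 1.0 / (1.0 + np.exp(-(dg - m_value * conc) / rt))
        noisy = _add_noise(rng, clean, spec)
        noisy[0] = clean[0]  # the 0 M anchor is the normalization reference
        series.append(PeakSeries(rid, "urea_M", conc.copy(), noisy))
        rows.append({"residue": rid.label, "C_half_true": c_half_i,
                     "m_true": m_value, "dG_true": dg})
    truth = pd.DataFrame(rows)
    truth.attrs["temperature_K"] = temperature_K
    return series, truth


# ---------------------------------------------------------------------------
# paramagnetic volume pairs
# ---------------------------------------------------------------------------

def gen_para(spec: GeneratorSpec, hotspot_set: Sequence[int] = (),
             hotspot_factor: float = 2.0,
             background_range=(0.4, 1.45)):
    """Volume pairs with planted hot spots and independent spectrum gains.

    Background attenuations are lognormal, clipped into
    ``background_range``; hot spots get ``hotspot_factor``. The two spectra
    receive independent global gains, which autoscaling must remove.
    """
    rng = spec.rng("para")
    sequence = random_sequence(spec)
    residues = _residue_ids(spec, sequence)
    n = len(residues)
    base = rng.lognormal(mean=2.0, sigma=0.4, size=n)
    atten = np.clip(rng.lognormal(mean=0.0, sigma=0.28, size=n),
                    *background_range)
    hot = set(hotspot_set)
    for i, rid in enumerate(residues):
        if rid.seq_number in hot:
            atten[i] = hotspot_factor
    gain_d = rng.uniform(0.5, 2.0)
    gain_p = rng.uniform(0.5, 2.0)
    vd = _add_noise(rng, gain_d * base, spec)
    vp = _add_noise(rng, gain_p * base / atten, spec)
    pairs = [VolumePair(rid, float(d), float(p))
             for rid, d, p in zip(residues, vd, vp)]
    truth = pd.DataFrame({"residue": [r.label for r in residues],
                          "attenuation_true": atten,
                          "hotspot": [r.seq_number in hot for r in residues]})
    return pairs, truth


# ---------------------------------------------------------------------------
# toy structures and trajectories
# ---------------------------------------------------------------------------

def make_helix(n_residues: int = 10, sequence: Optional[str] = None
               ) -> StructureModel:
    """Ideal alpha-helical backbone (N, H, CA, C, O per residue)."""
    atoms = []
    rise, twist, radius = 1.5, math.radians(100.0), 2.3
    for i in range(n_residues):
        code = (AA_1TO3[sequence[i]] if sequence else "ALA")
        rid = ResidueID(i + 1, code)
        th = i * twist
        ca = np.array([radius * math.cos(th), radius * math.sin(th),
                       rise * i])
        nd = np.array([math.cos(th - 0.45), math.sin(th - 0.45), 0.0])
        n_at = ca + 1.46 * np.array([nd[0], nd[1], -0.35])
        h_at = n_at + 1.0 * np.array([math.cos(th - 0.45),
                                      math.sin(th - 0.45), -0.6])
        cd = np.array([math.cos(th + 0.45), math.sin(th + 0.45), 0.0])
        c_at = ca + 1.52 * np.array([cd[0], cd[1], 0.35])
        o_at = c_at + 1.23 * np.array([cd[0], cd[1], 0.1])
        for name, el, xyz in (("N", "N", n_at), ("H", "H", h_at),
                              ("CA", "C", ca), ("C", "C", c_at),
                              ("O", "O", o_at)):
            atoms.append(Atom(name, rid, el, tuple(float(v) for v in xyz)))
    return StructureModel(atoms=atoms)


def gen_trajectory(spec: GeneratorSpec,
                   protein_template: Optional[StructureModel] = None,
                   n_waters: int = 50, n_frames: int = 100,
                   jitter_A=0.0,
                   planted_hbonds: Sequence[tuple] = (),
                   planted_site: Optional[tuple] = None,
                   water_pad: float = 8.0,
                   frame_interval_ps: float = 0.2):
    """Toy solvated trajectory with known ground truth.

    * ``jitter_A``: per-atom Gaussian positional noise (scalar or per-atom
      array over the protein atoms); the expected RMSF of an atom with
      per-coordinate sigma is sqrt(3) * sigma * sqrt(1 - 1/F).
    * ``planted_hbonds``: sequence of occupancies in (0, 1]; for each one
      a donor/hydrogen/acceptor triplet of dedicated atoms is appended and
      held at ideal geometry (2.9 A, linear) for exactly
      round(occupancy * n_frames) frames and far apart otherwise.
    * ``planted_site``: xyz where one water oxygen sits in every frame.

    Returns (trajectory, truth) with atom-index bookkeeping in ``truth``.
    """
    rng = spec.rng("trajectory")
    protein = protein_template or make_helix(8)
    p_atoms = list(protein.atoms)
    n_prot = len(p_atoms)
    next_seq = max(a.residue.seq_number for a in p_atoms) + 1

    hb_truth = []
    hb_atoms = []
    far_vec = np.array([0.0, 0.0, 6.0])
    base = np.array(p_atoms[0].xyz) + np.array([12.0, 0.0, 0.0])
    for b, occ in enumerate(planted_hbonds):
        rid = ResidueID(next_seq + b, "UNK")
        d = base + np.array([0.0, 4.0 * b, 0.0])
        h = d + np.array([1.0, 0.0, 0.0])
        a = d + np.array([2.9, 0.0, 0.0])
        hb_atoms += [Atom("ND", rid, "N", tuple(d)),
                     Atom("HD", rid, "H", tuple(h)),
                     Atom("OA", rid, "O", tuple(a))]
        n_on = int(round(occ * n_frames))
        hb_truth.append({"donor": n_prot + 3 * b,
                         "hydrogen": n_prot + 3 * b + 1,
                         "acceptor": n_prot + 3 * b + 2,
                         "occupancy_pct": 100.0 * n_on / n_frames,
                         "n_on": n_on})
    n_hb = len(hb_atoms)
    next_seq += len(planted_hbonds)

    prot_coords = np.array([a.xyz for a in p_atoms])
    lo = prot_coords.min(axis=0) - water_pad
    hi = prot_coords.max(axis=0) + water_pad
    w_atoms = []
    site_index = None
    if planted_site is not None:
        w_atoms.append(Atom("OW", ResidueID(next_seq, "UNK"), "O",
                            tuple(float(v) for v in planted_site)))
        site_index = n_prot + n_hb
        next_seq += 1
    for w in range(n_waters):
        xyz = rng.uniform(lo, hi)
        w_atoms.append(Atom("OW", ResidueID(next_seq + w, "UNK"), "O",
                            tuple(float(v) for v in xyz)))

    topo = StructureModel(atoms=p_atoms + hb_atoms + w_atoms)
    n_atoms = len(topo.atoms)
    frames = np.repeat(topo.coords[None, :, :], n_frames, axis=0)

    jit = np.broadcast_to(np.asarray(jitter_A, dtype=float),
                          (n_prot,)).copy()
    if np.any(jit > 0):
        noise = rng.normal(size=(n_frames, n_prot, 3)) * jit[None, :, None]
        frames[:, :n_prot, :] += noise

    for b, info in enumerate(hb_truth):
        off_frames = np.arange(info["n_on"], n_frames)
        frames[off_frames, info["acceptor"], :] += far_vec

    # waters rewander every frame (uniform), except the planted site
    w0 = n_prot + n_hb + (1 if site_index is not None else 0)
    if n_waters > 0:
        frames[:, w0:, :] = rng.uniform(lo, hi, size=(n_frames,
                                                      n_atoms - w0, 3))

    truth = {"n_protein_atoms": n_prot,
             "protein_indices": list(range(n_prot)),
             "hbonds": hb_truth,
             "water_indices": list(range(n_prot + n_hb, n_atoms)),
             "site_index": site_index,
             "planted_site": (tuple(float(v) for v in planted_site)
                              if planted_site is not None else None),
             "jitter_A": jit}
    traj = Trajectory(topology=topo, frames=frames,
                      frame_interval_ps=frame_interval_ps)
    return traj, truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def preset_mbs_like(seed: int = 17) -> dict:
    """Scenario parameters reproducing the headline regime in one call."""
    return {
        "hx": dict(spec=GeneratorSpec(seed=seed, n_residues=124,
                                      noise_level=0.05),
                   k_range=(0.003, 2.2)),
        "relax": dict(spec=GeneratorSpec(seed=seed, n_residues=124,
                                         noise_level=0.02),
                      tau_c_ns=7.9, S2_mean=0.90, S2_sd=0.07,
                      flexible_residues=(18, 19, 20, 21, 22),
                      field_MHz=500.13),
        "urea": dict(spec=GeneratorSpec(seed=seed, n_residues=31,
                                        noise_level=0.05),
                     C_half=4.2, m_value=1.2),
        "para": dict(spec=GeneratorSpec(seed=seed, n_residues=88,
                                        noise_level=0.03),
                     hotspot_set=(13, 15, 45, 65, 87),
                     hotspot_factor=2.0),
        "traj": dict(spec=GeneratorSpec(seed=seed),
                     n_waters=150, n_frames=200, jitter_A=0.3,
                     planted_hbonds=(0.9, 0.6, 0.25)),
    }
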