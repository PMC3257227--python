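"""Paramagnetic-probe surface-accessibility profiling.

Peak volumes measured with and without the soluble nitroxide probe are made
comparable by autoscaling each spectrum to unit mean; the per-residue
attenuation A_i is the ratio of autoscaled diamagnetic to paramagnetic
volume. A_i > 1 marks probe-accessible (attenuated) amides, A_i < 1
protected ones. Hot spots are residues above a threshold (default 1.7),
and the profile can be regressed against the fractional freedom from
intramolecular hydrogen bonding derived from a trajectory.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .peakio import ResidueID, VolumePair

logger = logging.getLogger(__name__)

#: relative volume-measurement error propagated into A_i
VOLUME_ERROR_FRACTION = 0.10


def autoscale(volumes, method: str = "mean"):
    """Scale positive volumes so the output mean (or median) is exactly 1.

    Non-positive entries are excluded with a warning before scaling and
    returned as NaN in place.
    """
    v = np.asarray(volumes, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 volumes to autoscale")
    good = v > 0
    if not np.all(good):
        logger.warning("%d non-positive volume(s) excluded from autoscaling",
                       int(np.sum(~good)))
    if not np.any(good):
        raise ValueError("no positive volumes")
    if method == "mean":
        ref = float(np.mean(v[good]))
    elif method == "median":
        ref = float(np.median(v[good]))
    else:
        raise ValueError(f"unknown autoscale method {method!r}")
    out = np.where(good, v / ref, np.nan)
    return out


@dataclass
class AttenuationProfile:
    residues: list
    A: np.ndarray
    A_err: np.ndarray
    v_dia: np.ndarray
    v_para: np.ndarray
    n_usable: int
    censored_high: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {r: float(a) for r, a in zip(self.residues, self.A)}


def attenuation(pairs: Sequence[VolumePair],
                method: str = "mean") -> AttenuationProfile:
    """Per-residue attenuations A_i = v_i^dia / v_i^para from volume pairs.

    The two spectra are autoscaled independently, which removes any global
    acquisition-gain difference between them. Pairs with a zero
    paramagnetic volume are reported as censored-high (infinite A) and
    excluded from profile statistics.
    """
    if len(pairs) < 5:
        raise ValueError("need at least 5 usable volume pairs")
    residues = [p.residue for p in pairs]
    vd = autoscale([p.V_dia for p in pairs], method)
    zero_para = [p.V_para == 0.0 for p in pairs]
    vp_raw = [p.V_para if p.V_para > 0 else np.nan for p in pairs]
    if all(np.isnan(v) for v in vp_raw):
        raise ValueError("no positive paramagnetic volumes")
    vp = autoscale(np.nan_to_num(vp_raw, nan=-1.0), method)
    A = vd / vp
    censored = [r for r, z in zip(residues, zero_para) if z]
    for i, z in enumerate(zero_para):
        if z:
            A[i] = math.inf
    # 10% per volume, independent -> sqrt(2)*10% on the ratio
    A_err = np.where(np.isfinite(A),
                     np.abs(A) * VOLUME_ERROR_FRACTION * math.sqrt(2.0),
                     np.nan)
    n_usable = int(np.sum(np.isfinite(A)))
    return AttenuationProfile(residues, A, A_err, vd, vp, n_usable, censored)


def classify_hotspots(profile: AttenuationProfile,
                      threshold: float = 1.7) -> list:
    """Residues with A_i above ``threshold``, sorted by descending A_i."""
    pairs = [(r, a) for r, a in zip(profile.residues, profile.A)
             if np.isfinite(a) and a > threshold]
    return [r for r, _ in sorted(pairs, key=lambda t: -t[1])]


def correlate_with_hbond_freedom(profile: AttenuationProfile,
                                 hb_freedom: dict) -> dict:
    """OLS regression of A_i on hydrogen-bond fractional freedom.

    ``hb_freedom`` maps ResidueID -> fraction in [0, 1]. Only residues
    present in both inputs enter the fit. Returns slope, intercept and the
    Pearson correlation coefficient.
    """
    xs, ys = [], []
    for r, a in zip(profile.residues, profile.A):
        if r in hb_freedom and np.isfinite(a):
            xs.append(hb_freedom[r])
            ys.append(a)
    if len(xs) < 5:
        raise ValueError("need at least 5 residues common to both inputs")
    x = np.array(xs)
    if np.allclose(x, x[0]):
        raise ValueError("zero-variance predictor: regression undefined")
    fit = stats.linregress(x, np.array(ys))
    return {"slope": float(fit.slope), "intercept": float(fit.intercept),
            "r": float(fit.rvalue), "n": len(xs)}
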