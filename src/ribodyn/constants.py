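"""Physical constants shared across the package.

All NMR interaction constants are derived from the fixed values below
(axially symmetric 15N shielding tensor, rigid N-H bond length); they are
deliberately not configurable per call so that forward and inverse
calculations always agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Gas constant in kcal/(mol K) — used for all free-energy conversions.
R_KCAL = 1.987e-3

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_H = 2.6752218744e8

#: 15N gyromagnetic ratio, rad s^-1 T^-1 (negative).
GAMMA_N = -2.7126e7

#: Vacuum permeability, T^2 m^3 J^-1.
MU_0 = 4.0e-7 * math.pi

#: Planck constant, J s.
H_PLANCK = 6.62607015e-34

HBAR = H_PLANCK / (2.0 * math.pi)


@dataclass(frozen=True)
class PhysicalConstants:
    """Interaction constants for amide 15N relaxation.

    Attributes
    ----------
    gamma_H, gamma_N:
        Gyromagnetic ratios in rad s^-1 T^-1; ``gamma_N`` is negative and
        the sign is kept so heteronuclear NOE < 1 is representable.
    r_NH:
        N-H bond length in metres (1.02 Angstrom).
    delta_sigma:
        15N chemical-shift anisotropy (dimensionless, -160 ppm).
    theta_deg:
        Angle between the dipolar N-H vector and the unique CSA axis,
        used only for the cross-correlated rates.
    """

    gamma_H: float = GAMMA_H
    gamma_N: float = GAMMA_N
    r_NH: float = 1.02e-10
    delta_sigma: float = -160e-6
    theta_deg: float = 17.0

    @property
    def d_dipolar(self) -> float:
        """Dipolar interaction constant (mu0/4pi) hbar gH gN / r^3, rad/s.

        Magnitude only; signs are handled explicitly where they matter.
        """
        return abs(
            (MU_0 / (4.0 * math.pi))
            * HBAR
            * self.gamma_H
            * self.gamma_N
            / self.r_NH**3
        )

    def omega_h(self, field_MHz: float) -> float:
        """Proton Larmor angular frequency (rad/s, positive)."""
        return 2.0 * math.pi * field_MHz * 1.0e6

    def omega_n(self, field_MHz: float) -> float:
        """15N Larmor angular frequency (rad/s, negative for 15N)."""
        b0 = self.omega_h(field_MHz) / self.gamma_H
        return self.gamma_N * b0

    def c_csa(self, field_MHz: float) -> float:
        """CSA interaction constant |omega_N * delta_sigma| / sqrt(3), rad/s."""
        return abs(self.omega_n(field_MHz) * self.delta_sigma) / math.sqrt(3.0)

    @property
    def p2_theta(self) -> float:
        """P2(cos theta) geometric factor for the cross-correlated rates."""
        c = math.cos(math.radians(self.theta_deg))
        return 0.5 * (3.0 * c * c - 1.0)


DEFAULT_CONSTANTS = PhysicalConstants()
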