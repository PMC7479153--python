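"""3D-Gaussian confocal observation volume.

The detection profile is modelled as

    f(x, y, z) = exp(-2 (x^2 + y^2) / omega_r^2 - 2 z^2 / omega_z^2)

with radial waist ``omega_r`` and axial waist ``omega_z``; the structural
factor S = omega_r / omega_z couples the two.  The geometric factor for
one-photon excitation, gamma = 2^(-3/2) = 0.3536, is the ratio
integral(f^2) / integral(f) of this profile and fixes the relation between
the correlation amplitude G(0) and the particle number N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Geometric ("gamma") factor of the one-photon 3D-Gaussian volume, 2^(-3/2).
GAMMA_1P: float = 2.0 ** -1.5

#: Boltzmann constant, J/K.
BOLTZMANN: float = 1.380649e-23

#: Avogadro constant, 1/mol.
AVOGADRO: float = 6.02214076e23


@dataclass(frozen=True)
class PSFModel:
    """3D-Gaussian observation volume.

    Parameters
    ----------
    omega_r
        Radial (lateral) 1/e^2 waist in micrometres.
    structural_factor
        S = omega_r / omega_z, dimensionless.  Confocal volumes are
        elongated axially, so S <= 1.
    """

    omega_r: float
    structural_factor: float = 0.2

    def __post_init__(self) -> None:
        if not self.omega_r > 0:
            raise ValueError("omega_r must be positive")
        if not 0 < self.structural_factor <= 1:
            raise ValueError("structural factor must be in (0, 1]")

    @property
    def omega_z(self) -> float:
        """Axial 1/e^2 waist in micrometres."""
        return self.omega_r / self.structural_factor

    @property
    def gamma(self) -> float:
        """One-photon geometric factor, 2^(-3/2)."""
        return GAMMA_1P

    @property
    def volume_3dg(self) -> float:
        """V_3DG = omega_r^2 * omega_z * (pi/2)^(3/2), in um^3."""
        return self.omega_r**2 * self.omega_z * (np.pi / 2.0) ** 1.5

    @property
    def volume_eff(self) -> float:
        """Effective volume V_eff = 2^(3/2) * V_3DG, in um^3."""
        return 2.0**1.5 * self.volume_3dg

    def intensity_profile(self, x, y, z):
        """Normalized detection profile f(r) evaluated at (x, y, z) in um."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = np.asarray(z, dtype=float)
        return np.exp(
            -2.0 * (x * x + y * y) / self.omega_r**2
            - 2.0 * z * z / self.omega_z**2
        )
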