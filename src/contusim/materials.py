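"""Quasi-linear viscoelastic (QLV) material constants and the Prony reduced
relaxation function.

The brain and the dura-arachnoid mater (DAM) are described by neo-Hookean
based QLV models whose time dependence is a two-term Prony series

    Gamma(t) = 1 - g1 (1 - exp(-t / tau1)) - g2 (1 - exp(-t / tau2)),

so Gamma(0) = 1 and Gamma(inf) = 1 - g1 - g2 (the long-time modulus
fraction). The constants shipped here are the porcine indentation-derived
values used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MaterialQLV", "BRAIN", "DAM", "CSF_BULK_MODULUS_GPA", "reduced_relaxation"]


@dataclass(frozen=True)
class MaterialQLV:
    """Neo-Hookean QLV material constants.

    Parameters
    ----------
    mu : float
        Shear modulus in kPa.
    nu : float
        Poisson ratio (dimensionless, < 0.5; nearly incompressible tissue
        uses 0.49995).
    g1, g2 : float
        Prony relaxation fractions (dimensionless, g1 + g2 < 1).
    tau1, tau2 : float
        Prony time constants in seconds.
    K : float or None
        Bulk modulus in GPa; only meaningful for the CSF cavity and carried
        for completeness.
    """

    mu: float
    nu: float
    g1: float
    g2: float
    tau1: float
    tau2: float
    K: float | None = None

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError(f"shear modulus must be positive, got mu={self.mu}")
        if not (0.0 < self.nu <= 0.49995):
            raise ValueError(f"Poisson ratio out of (0, 0.49995], got nu={self.nu}")
        if self.g1 < 0 or self.g2 < 0:
            raise ValueError("Prony fractions g1, g2 must be non-negative")
        if self.g1 + self.g2 >= 1.0:
            raise ValueError(
                f"g1 + g2 must be < 1 (long-time modulus positive), got {self.g1 + self.g2}"
            )
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("Prony time constants must be positive")


#: Porcine brain (pia integrated), dynamic-indentation calibration.
BRAIN = MaterialQLV(mu=6.97, nu=0.49995, g1=0.451, g2=0.301, tau1=0.021, tau2=0.199)

#: Dura-arachnoid mater modelled as a single membrane.
DAM = MaterialQLV(mu=19.10, nu=0.4, g1=0.568, g2=0.240, tau1=0.034, tau2=0.336)

#: CSF approximated as water; bulk modulus in GPa.
CSF_BULK_MODULUS_GPA = 2.1


def reduced_relaxation(t, mat: MaterialQLV = BRAIN):
    """Prony reduced relaxation function Gamma(t).

    Parameters
    ----------
    t : float or array_like
        Time(s) in seconds, all >= 0.
    mat : MaterialQLV
        Material constants; defaults to the brain.

    Returns
    -------
    float or ndarray
        Gamma(t) in (1 - g1 - g2, 1]; monotone non-increasing in t.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("reduced_relaxation requires t >= 0")
    gamma = (
        1.0
        - mat.g1 * (1.0 - np.exp(-t_arr / mat.tau1))
        - mat.g2 * (1.0 - np.exp(-t_arr / mat.tau2))
    )
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(gamma)
    return gamma
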