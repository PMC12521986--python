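"""Hemoglobin extinction coefficients for continuous-wave NIRS.

Molar extinction coefficients of oxygenated (HbO) and deoxygenated (HbR)
hemoglobin at common NIRS wavelengths, in cm^-1 per mol/L.  Values follow the
widely used compiled in-vitro spectra (Prahl compilation).  The forward model
and the modified Beer-Lambert inversion both draw on this table, so the
absolute scale cancels in round trips; what matters for concentration
estimates is the relative shape of the two spectra.
"""

from __future__ import annotations

import numpy as np

__all__ = ["extinction_coefficients", "extinction_matrix", "MissingCoefficientError"]


class MissingCoefficientError(KeyError):
    """Raised when no extinction coefficients are tabulated for a wavelength."""


#: wavelength (nm) -> (epsilon_HbO, epsilon_HbR) in cm^-1 M^-1
_TABLE: dict[float, tuple[float, float]] = {
    690.0: (276.0, 2051.96),
    730.0: (390.0, 1102.2),
    760.0: (586.0, 1548.52),
    780.0: (710.0, 1075.44),
    808.0: (844.0, 747.24),
    830.0: (974.0, 693.04),
    850.0: (1058.0, 691.32),
}


def extinction_coefficients(wavelength_nm: float) -> tuple[float, float]:
    """Return ``(eps_hbo, eps_hbr)`` in cm^-1 M^-1 for one wavelength.

    Raises
    ------
    MissingCoefficientError
        If the wavelength is not in the bundled table (no interpolation is
        attempted; coefficients vary too steeply near 760 nm to extrapolate
        silently).
    """
    key = float(wavelength_nm)
    if key not in _TABLE:
        raise MissingCoefficientError(
            f"no extinction coefficients tabulated for {wavelength_nm} nm; "
            f"available: {sorted(_TABLE)}"
        )
    return _TABLE[key]


def extinction_matrix(wavelengths_nm: tuple[float, float]) -> np.ndarray:
    """2x2 matrix ``E[i, :] = (eps_hbo, eps_hbr)`` at ``wavelengths_nm[i]``.

    This is the system matrix of the modified Beer-Lambert law: for one
    channel, ``delta_OD(lambda_i) = E[i] @ (dHbO, dHbR) * distance * ppf``.
    """
    lo, hi = wavelengths_nm
    if float(lo) == float(hi):
        raise ValueError("the two wavelengths must be distinct")
    return np.array([extinction_coefficients(lo), extinction_coefficients(hi)])
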