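"""Physical-chemistry and optics utilities for the recording conditions.

Nernst reversal potentials from pipette/bath compositions (the high-Cl
internal solution puts E_Cl near −14 mV, giving voltage-clamped IPSCs a
large inward driving force), Gaussian laser-spot sizing at the 1/e²
intensity points, and power-density (irradiance) conversions under
several explicit conventions, since "average intensity over a spot" is
not uniquely defined for a Gaussian beam.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import constants, optimize

__all__ = [
    "SolutionPair",
    "FitFailureError",
    "nernst_reversal",
    "spot_diameter_1e2",
    "spot_irradiance",
]


class FitFailureError(RuntimeError):
    """Raised when a beam-profile fit cannot be performed."""


@dataclass
class SolutionPair:
    """Inside/outside concentrations of one permeant ion.

    valence: signed ionic charge (−1 for Cl⁻); concentrations in mM;
    temperature in K (default: room temperature used for mapping).
    """

    ion: str
    valence: int
    inside: float
    outside: float
    temperature: float = 295.0

    def __post_init__(self):
        if self.inside <= 0 or self.outside <= 0:
            raise ValueError("concentrations must be strictly positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")
        if self.valence == 0:
            raise ValueError("valence must be nonzero")

    def reversal_mv(self) -> float:
        return nernst_reversal(self.inside, self.outside,
                               valence=self.valence,
                               temperature=self.temperature)


def nernst_reversal(inside: float, outside: float, valence: int = -1,
                    temperature: float = 295.0) -> float:
    """Nernst equilibrium potential (mV): (RT/zF)·ln([out]/[in]).

    Concentrations are totals in mM; activity coefficients are ignored,
    which reproduces the usual experimental bookkeeping (e.g. 72 CsCl +
    3 QX-314·Cl pipette vs 125 NaCl + 2.5 KCl + 2 CaCl₂ bath gives
    E_Cl ≈ −14 mV at room temperature).
    """
    if inside <= 0 or outside <= 0:
        raise ValueError("concentrations must be strictly positive")
    if valence == 0:
        raise ValueError("valence must be nonzero")
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    rt_zf = constants.R * temperature / (valence * constants.value("Faraday constant"))
    return float(rt_zf * np.log(outside / inside) * 1e3)


def spot_diameter_1e2(positions, intensities) -> float:
    """Gaussian-beam diameter at the 1/e² intensity points (same units as x).

    Fits I(x) = I0·exp(−2(x − x0)²/w²) to a measured profile (radial or
    full cross-section) and returns 2w.  The profile must be unimodal.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if x.size < 4:
        raise FitFailureError("need at least 4 profile points")
    i_max = int(np.argmax(y))
    smooth = np.convolve(y, np.ones(3) / 3, mode="same")
    resid = float(np.std(y - smooth))
    wiggle = max(3.0 * resid, 0.02 * float(y.max()))
    rising = np.diff(smooth[: i_max + 1])
    falling = np.diff(smooth[i_max:])
    if (rising < -wiggle).sum() > 3 or (falling > wiggle).sum() > 3:
        raise FitFailureError("intensity profile is not unimodal")

    def model(x, i0, x0, w):
        return i0 * np.exp(-2.0 * (x - x0) ** 2 / w ** 2)

    span = x.max() - x.min()
    p0 = (float(y.max()), float(x[i_max]), max(span / 4, 1e-6))
    try:
        popt, _ = optimize.curve_fit(model, x, y, p0=p0, maxfev=5000)
    except RuntimeError as err:
        raise FitFailureError(f"beam-profile fit failed: {err}") from err
    return float(2.0 * abs(popt[2]))


def spot_irradiance(total_power: float, spot_diameter: float,
                    convention: str = "uniform-disc") -> float:
    """Average laser power density in mW/mm² for a Gaussian spot.

    ``total_power`` in µW, ``spot_diameter`` the 1/e² diameter in µm.
    Conventions:

    - "uniform-disc": total power spread evenly over the 1/e² disc,
      P / (π r²).
    - "peak": peak irradiance of the Gaussian beam, 2P / (π w²) with
      w = diameter/2.
    - "gaussian-disc95": Gaussian power enclosed within the disc whose
      area is 95% of the 1/e² disc, averaged over that disc.
    """
    if total_power <= 0 or spot_diameter <= 0:
        raise ValueError("power and diameter must be positive")
    p_mw = total_power * 1e-3
    r_mm = spot_diameter * 1e-3 / 2.0
    if convention == "uniform-disc":
        return p_mw / (np.pi * r_mm ** 2)
    if convention == "peak":
        return 2.0 * p_mw / (np.pi * r_mm ** 2)
    if convention == "gaussian-disc95":
        r95 = np.sqrt(0.95) * r_mm
        enclosed = 1.0 - np.exp(-2.0 * (r95 / r_mm) ** 2)
        return enclosed * p_mw / (np.pi * r95 ** 2)
    raise ValueError(f"unknown irradiance convention {convention!r}")
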