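"""Forward model of the differential-pulse voltammetry (DPV) response.

DPV superimposes potential pulses of amplitude ``dE`` on a staircase sweep and
reports the current difference across each pulse.  For a reversible couple the
difference of the Nernstian reduced fractions evaluated at ``E`` and
``E + dE`` gives a symmetric, single-peaked response whose position and width
carry the thermodynamic information used throughout this package:

* peak potential ``E_p = E0 - s*dE/2`` (``s = +1`` for an anodic sweep),
* full width at half maximum ``dE_p/2`` that shrinks with the number of
  electrons ``n`` and grows with the pulse amplitude, converging to
  ``2*(RT/nF)*ln(3 + 2*sqrt(2)) ~ 90.6/n mV`` (25 degC) as the amplitude
  vanishes.

The same sigmoid-difference family is used for surface-confined and solution
couples: it is exact for a reversible adsorbed couple with full inter-pulse
relaxation and reproduces the peak position/width phenomenology that the
analyses here rest on (peak shape, not mass transport, is the subject).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "DEFAULT_TEMPERATURE_K",
    "AG_AGCL_SAT_KCL_OFFSET_V",
    "PulseParams",
    "RedoxCouple",
    "PeakShape",
    "thermal_voltage",
    "nernst_reduced_fraction",
    "nernstian_peak",
    "gaussian_peak",
    "dpv_response",
    "theoretical_half_width",
    "half_width_from_k",
    "k_from_half_width",
    "apparent_n_from_width",
    "convert_reference",
]

FARADAY = 96485.33212  # C mol^-1
GAS_CONSTANT = 8.314462618  # J mol^-1 K^-1

#: Reactor temperature (30 degC) used throughout unless stated otherwise.
DEFAULT_TEMPERATURE_K = 303.15

#: Ag/AgCl (saturated KCl) reference electrode potential vs SHE, volts.
AG_AGCL_SAT_KCL_OFFSET_V = 0.199

_LN_3_2SQRT2 = math.log(3.0 + 2.0 * math.sqrt(2.0))


@dataclass(frozen=True)
class PulseParams:
    """DPV waveform description.  All fields in instrument units (mV, ms)."""

    increment_mV: float = 5.0
    amplitude_mV: float = 50.0
    pulse_width_ms: float = 300.0
    pulse_period_ms: float = 5000.0
    sampling_delay_ms: float = 290.0
    scan_direction: str = "anodic"

    def __post_init__(self):
        if self.increment_mV <= 0:
            raise InvalidParameterError("pulse increment must be positive")
        if self.amplitude_mV <= 0:
            raise InvalidParameterError("pulse amplitude must be positive")
        if not 0 < self.pulse_width_ms < self.pulse_period_ms:
            raise InvalidParameterError(
                "pulse width must lie in (0, pulse period)"
            )
        if self.sampling_delay_ms > self.pulse_width_ms:
            raise InvalidParameterError(
                "sampling delay cannot exceed the pulse width"
            )
        if self.scan_direction not in ("anodic", "cathodic"):
            raise InvalidParameterError(
                f"unknown scan direction {self.scan_direction!r}"
            )

    @property
    def amplitude_V(self) -> float:
        return self.amplitude_mV / 1000.0

    @property
    def increment_V(self) -> float:
        return self.increment_mV / 1000.0

    @property
    def sign(self) -> int:
        """Scan-direction sign ``s``: +1 anodic, -1 cathodic."""
        return 1 if self.scan_direction == "anodic" else -1

    @property
    def scan_rate_V_s(self) -> float:
        """Staircase scan rate: one increment per pulse period."""
        return self.increment_V / (self.pulse_period_ms / 1000.0)


@dataclass(frozen=True)
class RedoxCouple:
    """A reversible redox couple.

    ``n`` is the (possibly apparent, non-integer) number of electrons;
    ``magnitude`` is the DPV peak current the couple contributes, uA cm^-2.
    """

    E0_V: float
    n: float = 1.0
    magnitude: float = 1.0
    label: str = ""

    def __post_init__(self):
        if self.n <= 0:
            raise InvalidParameterError("electron count n must be positive")
        if self.magnitude < 0:
            raise InvalidParameterError("magnitude must be non-negative")


@dataclass(frozen=True)
class PeakShape:
    """Observed/fitted DPV peak: position (V), half-width (mV), height."""

    Ep_V: float
    W_mV: float
    height: float
    kind: str = "nernstian"  # or "gaussian" (broad heme envelope)

    def __post_init__(self):
        if self.W_mV <= 0:
            raise InvalidParameterError("half-width must be positive")
        if self.height < 0:
            raise InvalidParameterError("peak height must be non-negative")


def thermal_voltage(n: float, T: float = DEFAULT_TEMPERATURE_K) -> float:
    """Logistic scale RT/nF in volts (26.12 mV for n=1 at 303.15 K)."""
    if T <= 0:
        raise InvalidParameterError("temperature must be positive")
    if n <= 0:
        raise InvalidParameterError("electron count n must be positive")
    return GAS_CONSTANT * T / (n * FARADAY)


def nernst_reduced_fraction(E, couple: RedoxCouple, T: float = DEFAULT_TEMPERATURE_K):
    """Equilibrium reduced fraction 1/(1 + exp(nF(E - E0)/RT)).

    Strictly decreasing in ``E``; equals 1/2 at the formal potential.
    """
    k = thermal_voltage(couple.n, T)
    return expit(-(np.asarray(E, dtype=float) - couple.E0_V) / k)


def nernstian_peak(E, Ep_V: float, k_V: float, height: float, amplitude_V: float):
    """Sigmoid-difference DPV peak, unit-normalized to ``height`` at ``Ep_V``.

    ``k_V`` is the logistic scale RT/nF.  The shape is symmetric about the
    peak; in the small-amplitude limit it reduces to the logistic derivative.
    """
    k = abs(k_V)
    d = abs(amplitude_V) / 2.0
    x = np.asarray(E, dtype=float) - Ep_V
    if d / k < 1e-7:
        s = expit(x / k)
        return height * 4.0 * s * (1.0 - s)
    norm = math.tanh(d / (2.0 * k))
    return height * (expit((x + d) / k) - expit((x - d) / k)) / norm


def gaussian_peak(E, center_V: float, sigma_V: float, height: float):
    """Gaussian envelope (used for the broad multi-heme background)."""
    x = np.asarray(E, dtype=float) - center_V
    return height * np.exp(-0.5 * (x / sigma_V) ** 2)


def dpv_response(
    E_grid,
    couple: RedoxCouple,
    pulse: PulseParams,
    T: float = DEFAULT_TEMPERATURE_K,
):
    """DPV current of a reversible couple on a potential grid (V vs SHE).

    Returns ``magnitude * |f_red(E) - f_red(E + s*dE)|`` where ``f_red`` is the
    Nernstian reduced fraction and ``s`` the scan-direction sign.  The result
    is non-negative, single-peaked, symmetric, and peaks at ``E0 - s*dE/2``.
    """
    E = np.asarray(E_grid, dtype=float)
    if E.size == 0:
        raise InvalidInputError("empty potential grid")
    k = thermal_voltage(couple.n, T)
    Ep = couple.E0_V - pulse.sign * pulse.amplitude_V / 2.0
    return nernstian_peak(E, Ep, k, couple.magnitude, pulse.amplitude_V)


def half_width_from_k(k_V: float, amplitude_mV: float) -> float:
    """FWHM (mV) of the sigmoid-difference peak with logistic scale ``k_V``."""
    if k_V <= 0:
        raise InvalidParameterError("logistic scale must be positive")
    if amplitude_mV < 0:
        raise InvalidParameterError("pulse amplitude must be non-negative")
    k = k_V
    d = amplitude_mV / 2000.0
    if d / k < 1e-7:
        return 2.0 * k * _LN_3_2SQRT2 * 1000.0

    def g(x):
        num = expit((x + d) / k) - expit((x - d) / k)
        return num / math.tanh(d / (2.0 * k)) - 0.5

    hi = 2.0 * (2.0 * k * _LN_3_2SQRT2 + d)
    while g(hi) > 0:
        hi *= 2.0
    x_half = brentq(g, 0.0, hi, xtol=1e-12)
    return 2.0 * x_half * 1000.0


def theoretical_half_width(
    n: float, amplitude_mV: float, T: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Theoretical DPV half-width dE_p/2 in mV for a reversible n-electron couple.

    Decreasing in ``n``, increasing in the pulse amplitude; the zero-amplitude
    limit is ``2*(RT/nF)*ln(3+2*sqrt(2))`` (~90.6/n mV at 298.15 K).
    """
    return half_width_from_k(thermal_voltage(n, T), amplitude_mV)


def k_from_half_width(W_mV: float, amplitude_mV: float) -> float:
    """Invert :func:`half_width_from_k`: logistic scale (V) giving FWHM ``W_mV``."""
    if W_mV <= 0:
        raise InvalidParameterError("half-width must be positive")
    # FWHM is strictly increasing in k and bounded below by ~amplitude as k->0
    lo, hi = 1e-5, 1.0
    if half_width_from_k(lo, amplitude_mV) > W_mV:
        raise InvalidParameterError(
            f"half-width {W_mV} mV is below the sharp-peak limit for a "
            f"{amplitude_mV} mV pulse amplitude"
        )
    return brentq(
        lambda k: half_width_from_k(k, amplitude_mV) - W_mV, lo, hi, xtol=1e-12
    )


def apparent_n_from_width(
    W_mV: float, amplitude_mV: float, T: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Apparent electron count whose theoretical half-width equals ``W_mV``.

    Peak broadening (site dispersion) makes this smaller than the true n; the
    integer call is made by :mod:`flavodpv.electrons`.
    """
    k = k_from_half_width(W_mV, amplitude_mV)
    return GAS_CONSTANT * T / (FARADAY * k)


_SCALE_OFFSETS_DEFAULT = {"SHE": 0.0, "Ag/AgCl_satKCl": AG_AGCL_SAT_KCL_OFFSET_V}
_SCALE_ALIASES = {
    "she": "SHE",
    "ag/agcl_satkcl": "Ag/AgCl_satKCl",
    "ag/agcl": "Ag/AgCl_satKCl",
    "agagcl": "Ag/AgCl_satKCl",
}


def convert_reference(
    E,
    from_scale: str,
    to_scale: str,
    offset_V: float = AG_AGCL_SAT_KCL_OFFSET_V,
):
    """Convert potentials between reference scales.

    ``E(SHE) = E(Ag/AgCl sat. KCl) + offset`` with a configurable offset
    (default +0.199 V).  Round trips are exact.
    """

    def canon(scale):
        key = _SCALE_ALIASES.get(scale.lower())
        if key is None:
            raise InvalidParameterError(f"unknown reference scale {scale!r}")
        return key

    offsets = {"SHE": 0.0, "Ag/AgCl_satKCl": offset_V}
    E = np.asarray(E, dtype=float)
    out = E + offsets[canon(from_scale)] - offsets[canon(to_scale)]
    return float(out) if out.ndim == 0 else out
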