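"""Electron-count inference from DPV peak half-widths.

A reversible n-electron couple has a theoretical half-width that shrinks as
1/n (~100 mV for n=1 and ~62 mV for n=2 with a 50 mV pulse at 303 K).  An
observed width is assigned the candidate n whose theoretical width it is
closest to.  Real adsorbed couples broaden beyond the ideal width through
site dispersion, so widths above the smallest-n theoretical value still call
that smallest n — broadening never argues for more electrons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import InvalidInputError, InvalidParameterError
from .model import DEFAULT_TEMPERATURE_K, theoretical_half_width

__all__ = ["ElectronCall", "classify_n"]

#: Calls whose two nearest theoretical widths differ by less than this are
#: flagged ambiguous.
AMBIGUITY_MARGIN_MV = 5.0


@dataclass(frozen=True)
class ElectronCall:
    """Result of an electron-count classification."""

    n_best: int
    margin_mV: float  # |distance gap| between the two nearest theoretical widths
    widths_table: dict  # candidate n -> theoretical half-width (mV)
    W_obs_mV: float
    ambiguous: bool = False


def classify_n(
    W_obs_mV: float,
    amplitude_mV: float = 50.0,
    T: float = DEFAULT_TEMPERATURE_K,
    candidates=(1, 2),
) -> ElectronCall:
    """Assign an electron count to an observed DPV half-width.

    Nearest-theoretical-width rule over ``candidates``, with super-theoretical
    broadening mapped to the smallest candidate n (whose theoretical width is
    the largest).  The ``ambiguous`` flag is set when the two best distances
    differ by less than 5 mV.
    """
    if W_obs_mV <= 0:
        raise InvalidParameterError("observed half-width must be positive")
    candidates = sorted(set(int(n) for n in candidates))
    if not candidates:
        raise InvalidInputError("empty candidate set")
    widths = {n: theoretical_half_width(n, amplitude_mV, T) for n in candidates}

    n_min = candidates[0]
    if W_obs_mV >= widths[n_min]:
        # broader than the widest ideal width: dispersion, not extra electrons
        others = [n for n in candidates if n != n_min]
        if others:
            runner = min(others, key=lambda n: abs(W_obs_mV - widths[n]))
            margin = abs(
                abs(W_obs_mV - widths[runner]) - abs(W_obs_mV - widths[n_min])
            )
        else:
            margin = float("inf")
        return ElectronCall(n_min, margin, widths, W_obs_mV, margin < AMBIGUITY_MARGIN_MV)

    dist = sorted(candidates, key=lambda n: (abs(W_obs_mV - widths[n]), n))
    n_best = dist[0]
    if len(dist) > 1:
        margin = abs(
            abs(W_obs_mV - widths[dist[1]]) - abs(W_obs_mV - widths[n_best])
        )
    else:
        margin = float("inf")
    return ElectronCall(n_best, margin, widths, W_obs_mV, margin < AMBIGUITY_MARGIN_MV)
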