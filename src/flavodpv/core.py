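"""Domain containers: voltammograms, chronoamperometry traces, events.

Potentials are volts vs SHE internally; currents uA cm^-2; times seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import InvalidInputError
from .model import PulseParams, DEFAULT_TEMPERATURE_K

__all__ = ["Voltammogram", "AdditionEvent", "CurrentTrace"]


@dataclass
class Voltammogram:
    """A potential-current series with acquisition metadata."""

    potentials_V: np.ndarray
    currents: np.ndarray
    pulse: PulseParams = field(default_factory=PulseParams)
    temperature_K: float = DEFAULT_TEMPERATURE_K
    electrode_area_cm2: float = 3.1
    reference_scale: str = "SHE"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.potentials_V = np.asarray(self.potentials_V, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.potentials_V.shape != self.currents.shape:
            raise InvalidInputError("potential and current arrays differ in length")
        if self.potentials_V.size == 0:
            raise InvalidInputError("empty voltammogram")
        dE = np.diff(self.potentials_V)
        if self.potentials_V.size > 1 and not (np.all(dE > 0) or np.all(dE < 0)):
            raise InvalidInputError("potentials must be strictly monotone")
        if self.electrode_area_cm2 <= 0:
            raise InvalidInputError("electrode area must be positive")

    @property
    def increment_V(self) -> float:
        """Median grid step (signed)."""
        return float(np.median(np.diff(self.potentials_V)))

    def with_currents(self, currents, **meta) -> "Voltammogram":
        """Copy with replaced currents and updated metadata."""
        new = replace(self, currents=np.asarray(currents, dtype=float))
        new.metadata = {**self.metadata, **meta}
        return new


@dataclass(frozen=True)
class AdditionEvent:
    """A timestamped perturbation of a chronoamperometry experiment."""

    time_s: float
    kind: str = "flavin_addition"  # or potential_step, pH_change
    payload: dict = field(default_factory=dict)

    _KINDS = ("flavin_addition", "potential_step", "pH_change")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise InvalidInputError(f"unknown event kind {self.kind!r}")


@dataclass
class CurrentTrace:
    """A chronoamperometry time-current series with experiment annotations."""

    times_s: np.ndarray
    currents: np.ndarray
    events: list = field(default_factory=list)
    potential_V: float = 0.4
    pH: float = 7.8
    strain: str = "WT"
    flavin: str = "none"
    flavin_conc_uM: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.times_s.shape != self.currents.shape:
            raise InvalidInputError("time and current arrays differ in length")
        if self.times_s.size == 0:
            raise InvalidInputError("empty trace")
        if np.any(np.diff(self.times_s) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        for ev in self.events:
            if not self.times_s[0] <= ev.time_s <= self.times_s[-1]:
                raise InvalidInputError(
                    f"event at t={ev.time_s} s lies outside the trace span"
                )

    def interp(self, t):
        """Current at time(s) ``t`` by linear interpolation."""
        return np.interp(t, self.times_s, self.currents)
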