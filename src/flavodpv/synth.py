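"""Synthetic voltammograms, titrations and chronoamperometry traces.

The generators emulate whole-cell electrochemistry of *Shewanella oneidensis*
MR-1 on an ITO electrode: DP voltammograms of free and cytochrome-bound
flavins over a smooth charging baseline, flavin titration series following a
Langmuir isotherm, and microbial lactate-oxidation current traces for the
wild type and the OmcA/MtrC deletion mutants with or without added flavin.

Fixture peak parameters come from measured values where such values exist
(peak potentials -260/-145/-110/-102 mV vs SHE, half-widths 60/130/150 mV,
plateau currents ~15 uA cm^-2, flavin enhancement factors 15x/3x at -0.2 V);
everything else — heme envelope, baseline coefficients, pH/potential panel
entries not printed anywhere — is an invented default flagged
``figure_derived_invented`` in the metadata so downstream tests never treat
it as ground truth.

All randomness flows through explicit integer seeds; ``noise == 0``
reproduces bit-identical arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AdditionEvent, CurrentTrace, Voltammogram
from .exceptions import InvalidInputError, InvalidParameterError
from .model import (
    DEFAULT_TEMPERATURE_K,
    PulseParams,
    gaussian_peak,
    k_from_half_width,
    nernstian_peak,
    thermal_voltage,
)

__all__ = [
    "FixtureSpec",
    "FIXTURES",
    "DEFAULT_CONCENTRATIONS_UM",
    "DEFAULT_KD_UM",
    "DEFAULT_IMAX_UA_CM2",
    "fixture_names",
    "fixture_baseline",
    "fixture_components",
    "make_dpv_fixture",
    "make_titration",
    "make_titration_series",
    "make_current_trace",
    "enhancement_factor_table",
]

# --------------------------------------------------------------------------
# DPV fixtures
# --------------------------------------------------------------------------

E_MIN_V = -0.45
E_MAX_V = 0.25

#: Charging-current baseline: cubic polynomial plus an exponential tail at the
#: negative end (solvent/oxide onset).  Coefficients are invented but fixed.
_BASELINE = {
    "poly": (5.0, 4.0, 6.0, 4.0),  # c0 + c1*E + c2*E^2 + c3*E^3, uA cm^-2
    "exp_amplitude": 1.5,  # uA cm^-2 at E_MIN_V
    "exp_decay_V": 0.06,
}

# Heme envelope: the broad multi-heme cytochrome background seen in whole-cell
# voltammograms.  Invented default (the measurements never quantify it).
_HEME = {"kind": "gaussian", "center_V": -0.05, "fwhm_mV": 250.0, "height": 1.5}

_GAUSS_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # FWHM = 2.3548 sigma


@dataclass(frozen=True)
class FixtureSpec:
    """A named voltammogram fixture: peak components over the fixed baseline."""

    name: str
    components: tuple  # of dicts (kind, position, width, height)
    description: str = ""


def _nern(Ep_mV, W_mV, height, label):
    return {
        "kind": "nernstian",
        "Ep_V": Ep_mV / 1000.0,
        "W_mV": W_mV,
        "height": height,
        "label": label,
    }


def _heme(height=_HEME["height"]):
    return {
        "kind": "gaussian",
        "center_V": _HEME["center_V"],
        "W_mV": _HEME["fwhm_mV"],
        "height": height,
        "label": "heme envelope",
        "figure_derived_invented": True,
    }


def _free_width_mV(T=DEFAULT_TEMPERATURE_K, amplitude_mV=50.0):
    # free flavins are ideal two-electron couples; width from theory
    from .model import theoretical_half_width

    return theoretical_half_width(2.0, amplitude_mV, T)


_W_FREE = _free_width_mV()

FIXTURES: dict[str, FixtureSpec] = {
    "free_FMN": FixtureSpec(
        "free_FMN",
        (_nern(-260.0, _W_FREE, 5.0, "free FMN Ox/Rd (2e-)"),),
        "free FMN in solution, no cells",
    ),
    "free_RF": FixtureSpec(
        "free_RF",
        (_nern(-260.0, _W_FREE, 4.5, "free RF Ox/Rd (2e-)"),),
        "free riboflavin in solution, no cells",
    ),
    "bound_FMN_WT": FixtureSpec(
        "bound_FMN_WT",
        (_nern(-145.0, 130.0, 3.5, "MtrC-bound FMN Ox/Sq (1e-)"), _heme()),
        "wild type + FMN: cofactor peak plus heme envelope",
    ),
    "bound_RF_WT": FixtureSpec(
        "bound_RF_WT",
        (_nern(-110.0, 130.0, 3.5, "OmcA-bound RF Ox/Sq (1e-)"), _heme()),
        "wild type + RF",
    ),
    "bound_RF_dmtrC": FixtureSpec(
        "bound_RF_dmtrC",
        (_nern(-102.0, 150.0, 3.0, "OmcA-bound RF Ox/Sq (1e-)"), _heme()),
        "mtrC deletion mutant + RF",
    ),
    "heme_envelope": FixtureSpec(
        "heme_envelope", (_heme(2.0),), "heme background only"
    ),
}


def fixture_names() -> list[str]:
    return list(FIXTURES)


def _potential_grid(pulse: PulseParams) -> np.ndarray:
    n = int(round((E_MAX_V - E_MIN_V) / pulse.increment_V))
    return E_MIN_V + pulse.increment_V * np.arange(n + 1)


def fixture_baseline(E) -> np.ndarray:
    """Evaluate the generating charging-current baseline on a grid (V)."""
    E = np.asarray(E, dtype=float)
    c0, c1, c2, c3 = _BASELINE["poly"]
    base = c0 + c1 * E + c2 * E**2 + c3 * E**3
    base += _BASELINE["exp_amplitude"] * np.exp(
        -(E - E_MIN_V) / _BASELINE["exp_decay_V"]
    )
    return base


def _component_currents(E, components, pulse, T):
    total = np.zeros_like(np.asarray(E, dtype=float))
    for c in components:
        if c["kind"] == "nernstian":
            k = k_from_half_width(c["W_mV"], pulse.amplitude_mV)
            total += nernstian_peak(E, c["Ep_V"], k, c["height"], pulse.amplitude_V)
        elif c["kind"] == "gaussian":
            sigma = c["W_mV"] / 1000.0 / _GAUSS_FWHM
            total += gaussian_peak(E, c["center_V"], sigma, c["height"])
        else:  # pragma: no cover - registry is static
            raise InvalidParameterError(f"unknown component kind {c['kind']!r}")
    return total


def fixture_components(name: str) -> list[dict]:
    """Generating components of a registry fixture (deep copies)."""
    if name not in FIXTURES:
        raise InvalidInputError(
            f"unknown fixture {name!r}; known: {', '.join(FIXTURES)}"
        )
    return [dict(c) for c in FIXTURES[name].components]


def make_dpv_fixture(
    name: str,
    noise_sd: float = 0.0,
    seed: int = 0,
    pulse: PulseParams | None = None,
    T: float = DEFAULT_TEMPERATURE_K,
) -> Voltammogram:
    """Generate a registry voltammogram: baseline + peaks + Gaussian noise.

    ``noise_sd`` is in uA cm^-2; zero gives a bit-reproducible array.
    """
    components = fixture_components(name)
    pulse = pulse or PulseParams()
    E = _potential_grid(pulse)
    currents = fixture_baseline(E) + _component_currents(E, components, pulse, T)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        currents = currents + rng.normal(0.0, noise_sd, size=E.shape)
    meta = {
        "fixture": name,
        "seed": int(seed),
        "noise_sd": float(noise_sd),
        "components": components,
        "baseline": {
            "poly": list(_BASELINE["poly"]),
            "exp_amplitude": _BASELINE["exp_amplitude"],
            "exp_decay_V": _BASELINE["exp_decay_V"],
            "E_min_V": E_MIN_V,
        },
    }
    return Voltammogram(
        E, currents, pulse=pulse, temperature_K=T, metadata=meta
    )


# --------------------------------------------------------------------------
# Flavin titration
# --------------------------------------------------------------------------

DEFAULT_CONCENTRATIONS_UM = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 35.0, 52.0)
DEFAULT_KD_UM = 10.0
#: Saturated bound-flavin peak current.  Chosen so the 52 uM point of the
#: default titration reproduces the measured 7 uA cm^-2 peak at -145 mV
#: (52/(52+Kd) of saturation with Kd = 10 uM).
DEFAULT_IMAX_UA_CM2 = 7.0 * 62.0 / 52.0

#: Free-flavin peak grows linearly (unsaturated solution couple), uA/uM.
_FREE_SLOPE_UA_PER_UM = 0.05


def _langmuir(C, Kd, i_max):
    return i_max * np.asarray(C, dtype=float) / (np.asarray(C, dtype=float) + Kd)


def make_titration(
    fixture: str = "bound_FMN_WT",
    concentrations_uM=DEFAULT_CONCENTRATIONS_UM,
    Kd_uM: float = DEFAULT_KD_UM,
    i_max: float = DEFAULT_IMAX_UA_CM2,
    noise_frac: float = 0.0,
    seed: int = 0,
    pulse: PulseParams | None = None,
    T: float = DEFAULT_TEMPERATURE_K,
) -> list[tuple[float, Voltammogram]]:
    """Voltammograms of a flavin titration of a cell monolayer.

    The bound-flavin peak follows a Langmuir isotherm ``i_max*C/(C+Kd)``; the
    free-flavin peak at -260 mV grows linearly with concentration; the heme
    envelope and baseline are concentration-independent.
    """
    concentrations = [float(c) for c in concentrations_uM]
    if not concentrations:
        raise InvalidInputError("empty concentration list")
    if any(c <= 0 for c in concentrations):
        raise InvalidParameterError("concentrations must be positive")
    if Kd_uM <= 0:
        raise InvalidParameterError("Kd must be positive")
    bound_tpl = fixture_components(fixture)[0]
    if bound_tpl["kind"] != "nernstian":
        raise InvalidInputError(f"fixture {fixture!r} has no flavin peak")
    pulse = pulse or PulseParams()
    E = _potential_grid(pulse)
    out = []
    for i, C in enumerate(concentrations):
        bound = dict(bound_tpl, height=float(_langmuir(C, Kd_uM, i_max)))
        free = _nern(-260.0, _W_FREE, _FREE_SLOPE_UA_PER_UM * C, "free flavin (2e-)")
        components = [free, bound, _heme()]
        currents = fixture_baseline(E) + _component_currents(E, components, pulse, T)
        noise_sd = noise_frac * bound["height"]
        if noise_sd > 0:
            rng = np.random.default_rng(seed + 1000 * i)
            currents = currents + rng.normal(0.0, noise_sd, size=E.shape)
        meta = {
            "fixture": fixture,
            "titration_concentration_uM": C,
            "Kd_uM": Kd_uM,
            "i_max": i_max,
            "seed": int(seed),
            "noise_frac": float(noise_frac),
            "components": components,
            "baseline": {
                "poly": list(_BASELINE["poly"]),
                "exp_amplitude": _BASELINE["exp_amplitude"],
                "exp_decay_V": _BASELINE["exp_decay_V"],
                "E_min_V": E_MIN_V,
            },
        }
        out.append(
            (C, Voltammogram(E, currents, pulse=pulse, temperature_K=T, metadata=meta))
        )
    return out


def make_titration_series(
    concentrations_uM=DEFAULT_CONCENTRATIONS_UM,
    Kd_uM: float = DEFAULT_KD_UM,
    i_max: float = DEFAULT_IMAX_UA_CM2,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Bound-peak current vs concentration as a two-column DataFrame.

    Multiplicative Gaussian noise of relative sd ``noise_frac`` on the peak
    currents.  This is the series the binding estimators consume.
    """
    C = np.asarray(list(concentrations_uM), dtype=float)
    if C.size == 0:
        raise InvalidInputError("empty concentration list")
    i = _langmuir(C, Kd_uM, i_max)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        i = i * (1.0 + rng.normal(0.0, noise_frac, size=C.shape))
    return pd.DataFrame(
        {"concentration_uM": C, "peak_current_uA_cm2": i}
    )


# --------------------------------------------------------------------------
# Chronoamperometry traces
# --------------------------------------------------------------------------

#: No-lactate background current, uA cm^-2 (invented; "less-than hundred
#: nA/cm^2" initial currents bound it from above).
_BACKGROUND_UA_CM2 = 0.02

#: Steady-state plateau currents at +0.4 V vs SHE, pH 7.8, uA cm^-2.
#: WT+flavin = 15 (measured); mutant ratios reproduce the reported 10-fold
#: FMN enhancement of dOmcA and RF enhancement of dMtrC; the rest invented.
_PLATEAU = {
    ("WT", "none"): 5.0,
    ("WT", "RF"): 15.0,
    ("WT", "FMN"): 15.0,
    ("dOmcA", "none"): 0.5,
    ("dOmcA", "RF"): 0.5,
    ("dOmcA", "FMN"): 5.0,
    ("dMtrC", "none"): 0.5,
    ("dMtrC", "RF"): 5.0,
    ("dMtrC", "FMN"): 0.75,
}
_MEASURED_PLATEAUS = {("WT", "RF"), ("WT", "FMN"), ("dOmcA", "FMN"),
                      ("dOmcA", "RF"), ("dOmcA", "none"), ("dMtrC", "RF")}

_GROWTH_MID_H = 15.0
_GROWTH_TAU_H = 2.5

#: Potential scaling of catalytic current (invented, monotone in driving force).
_POT_FACTOR = {-0.2: 0.6, 0.4: 1.0, 0.8: 1.1}

#: Enhancement factors vs electrode potential at pH 7.8.  The -0.2 V entries
#: (FMN 15x, RF 3x) are measured; +0.4/+0.8 V are invented with the measured
#: qualitative ordering (EF grows toward negative potentials, flavin contrast
#: shrinks at positive ones).
_EF_POTENTIAL = {
    "FMN": {-0.2: 15.0, 0.4: 3.5, 0.8: 1.5},
    "RF": {-0.2: 3.0, 0.4: 2.5, 0.8: 1.3},
}

#: pH modifiers at +0.4 V (invented magnitudes, measured shape: FMN EF
#: non-decreasing with pH; RF EF minimum at pH 7, maximum at pH 6).
_EF_PH = {
    "FMN": {6.0: 2.8, 7.0: 3.2, 8.0: 3.8, 9.0: 4.5},
    "RF": {6.0: 3.4, 7.0: 2.2, 8.0: 2.6, 9.0: 3.0},
}

_EF_RISE_TAU_S = 200.0

_STRAINS = ("WT", "dOmcA", "dMtrC")
_FLAVINS = ("none", "RF", "FMN")


def _interp_table(table: dict, x: float) -> float:
    xs = np.array(sorted(table))
    ys = np.array([table[v] for v in xs])
    return float(np.interp(x, xs, ys))


def enhancement_factor_table(flavin: str, potential_V: float, pH: float) -> dict:
    """Target enhancement factor for a condition, with provenance flag.

    EF(P, pH) = EF_P(P) * EF_pH(pH) / EF_pH(7.8); only the (-0.2 V, pH 7.8)
    values are measured, all other entries are invented panel defaults.
    """
    if flavin not in ("RF", "FMN"):
        raise InvalidParameterError(f"no enhancement table for flavin {flavin!r}")
    ef_pot = _interp_table(_EF_POTENTIAL[flavin], potential_V)
    ph_mod = _interp_table(_EF_PH[flavin], pH) / _interp_table(_EF_PH[flavin], 7.8)
    measured = abs(potential_V - (-0.2)) < 1e-9 and abs(pH - 7.8) < 1e-9
    return {
        "EF": ef_pot * ph_mod,
        "figure_derived_invented": not measured,
    }


def make_current_trace(
    strain: str = "WT",
    flavin: str = "none",
    flavin_conc_uM: float = 2.0,
    potential_V: float = 0.4,
    pH: float = 7.8,
    events=(),
    seed: int = 0,
    noise_sd: float | None = None,
    duration_h: float = 40.0,
    dt_s: float = 20.0,
    lactate: bool = True,
) -> CurrentTrace:
    """Microbial current-production trace for a strain/flavin condition.

    Lactate-oxidation current follows logistic growth to a plateau set by the
    strain/flavin table, scaled by electrode potential.  A ``flavin_addition``
    event switches the trace from the flavin-free plateau to ``EF`` times the
    background-subtracted pre-addition current through a first-order rise
    (tau = 200 s).  ``lactate=False`` generates the matching background trace
    (no catalytic current) for the same condition.  ``noise_sd=None`` uses
    1% of the plateau; 0 disables noise.
    """
    if strain not in _STRAINS:
        raise InvalidParameterError(f"unknown strain {strain!r}")
    if flavin not in _FLAVINS:
        raise InvalidParameterError(f"unknown flavin {flavin!r}")
    events = list(events)
    t = np.arange(0.0, duration_h * 3600.0 + dt_s / 2, dt_s)
    addition = next((e for e in events if e.kind == "flavin_addition"), None)
    if addition is not None and flavin == "none":
        raise InvalidParameterError("flavin_addition event requires a flavin species")

    pot_factor = _interp_table(_POT_FACTOR, potential_V)
    # flavin present from t=0 unless it arrives via an addition event
    flavin_at_start = flavin if addition is None else "none"
    plateau = _PLATEAU[(strain, flavin_at_start)] * pot_factor
    meta = {
        "strain": strain,
        "flavin": flavin,
        "plateau_uA_cm2": plateau,
        "plateau_measured": (strain, flavin_at_start) in _MEASURED_PLATEAUS,
        "background_uA_cm2": _BACKGROUND_UA_CM2,
        "seed": int(seed),
        "lactate": bool(lactate),
    }

    if not lactate:
        currents = np.full_like(t, _BACKGROUND_UA_CM2)
        noise_scale = noise_sd if noise_sd is not None else 0.01 * _BACKGROUND_UA_CM2
    else:
        th = t / 3600.0
        growth = 1.0 / (1.0 + np.exp(-(th - _GROWTH_MID_H) / _GROWTH_TAU_H))
        net = plateau * growth
        if addition is not None:
            t0 = addition.time_s
            ef_entry = enhancement_factor_table(flavin, potential_V, pH)
            ef = ef_entry["EF"]
            meta["EF_target"] = ef
            meta["figure_derived_invented"] = ef_entry["figure_derived_invented"]
            net0 = plateau / (1.0 + np.exp(-(t0 / 3600.0 - _GROWTH_MID_H) / _GROWTH_TAU_H))
            post = t >= t0
            rise = 1.0 - np.exp(-(t[post] - t0) / _EF_RISE_TAU_S)
            net = np.where(post, net0, net)
            net[post] = net0 * (1.0 + (ef - 1.0) * rise)
        currents = _BACKGROUND_UA_CM2 + net
        noise_scale = noise_sd if noise_sd is not None else 0.01 * plateau

    if noise_scale > 0:
        rng = np.random.default_rng(seed)
        currents = currents + rng.normal(0.0, noise_scale, size=t.shape)

    return CurrentTrace(
        t,
        currents,
        events=events,
        potential_V=potential_V,
        pH=pH,
        strain=strain,
        flavin=flavin,
        flavin_conc_uM=flavin_conc_uM if flavin != "none" else 0.0,
        metadata=meta,
    )
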