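"""Baseline subtraction and multi-peak deconvolution of DP voltammograms.

The analysis chain mirrors standard protein-film voltammetry practice:

1. :func:`detect_peaks` — candidate peaks from smoothed local maxima of the
   detrended signal.
2. :func:`fit_baseline` / :func:`subtract_baseline` — the charging current is
   fitted over potential windows far from the peaks, assuming it continues
   smoothly through the peak region, and subtracted.
3. :func:`deconvolve` — the residual faradaic signal is decomposed into
   sigmoid-difference (Nernstian) flavin peaks and/or a Gaussian heme
   envelope by weighted orthogonal-distance regression (ODRPACK via
   :mod:`scipy.odr`), with per-axis weights 1/x_sd^2 and 1/y_sd^2.  In the
   vanishing-x-uncertainty limit the fit coincides with ordinary least
   squares, which is also available directly.
4. :func:`summarize_peaks` — peak potential, half-width (FWHM), height,
   charge proxy and apparent electron count per fitted component.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.odr
from scipy.optimize import least_squares, minimize_scalar
from scipy.signal import find_peaks, peak_widths

from .core import Voltammogram
from .exceptions import (
    ConvergenceError,
    InvalidInputError,
    UnderdeterminedError,
)
from .model import (
    DEFAULT_TEMPERATURE_K,
    PulseParams,
    apparent_n_from_width,
    gaussian_peak,
    half_width_from_k,
    k_from_half_width,
    nernstian_peak,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BaselineFit",
    "FittedPeak",
    "DeconvolutionResult",
    "detect_peaks",
    "fit_baseline",
    "subtract_baseline",
    "deconvolve",
    "refine_baseline",
    "summarize_peaks",
    "analyze",
]

_GAUSS_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


# --------------------------------------------------------------------------
# Peak detection
# --------------------------------------------------------------------------

def _edge_mask(n: int, frac: float = 0.12) -> np.ndarray:
    k = max(4, int(round(n * frac)))
    mask = np.zeros(n, dtype=bool)
    mask[:k] = True
    mask[-k:] = True
    return mask


def _edge_poly_detrend(E, y, degree=3):
    """Provisional baseline: polynomial fitted through the scan edges."""
    mask = _edge_mask(E.size)
    coeffs = np.polynomial.polynomial.polyfit(E[mask], y[mask], degree)
    return y - np.polynomial.polynomial.polyval(E, coeffs)


def _smooth(y, window: int):
    window = max(1, int(window))
    if window % 2 == 0:
        window += 1
    if window == 1:
        return y
    kernel = np.ones(window) / window
    return np.convolve(np.pad(y, window // 2, mode="edge"), kernel, mode="valid")


def detect_peaks(
    v: Voltammogram,
    min_prominence: float | None = None,
    smooth_window: int = 5,
) -> list[dict]:
    """Initial peak candidates ordered by prominence.

    Positions come from smoothed local maxima of the edge-detrended signal;
    ties in prominence break toward more negative potential.  Returns a list
    of dicts with keys ``Ep_V``, ``W_mV`` (crude FWHM estimate), ``height``
    and ``prominence``; may be empty.
    """
    if v.potentials_V.size < 20:
        raise InvalidInputError("need at least 20 samples for peak detection")
    E = v.potentials_V
    y = _edge_poly_detrend(E, v.currents)
    ys = _smooth(y, smooth_window)
    if min_prominence is None:
        ptp = float(np.ptp(ys))
        if ptp <= 0:
            return []
        min_prominence = 0.05 * ptp
    idx, props = find_peaks(ys, prominence=min_prominence)
    if idx.size == 0:
        return []
    widths_samples = peak_widths(ys, idx, rel_height=0.5)[0]
    step_mV = abs(v.increment_V) * 1000.0
    cands = []
    for i, j in enumerate(idx):
        cands.append(
            {
                "Ep_V": float(E[j]),
                "W_mV": float(max(widths_samples[i] * step_mV, step_mV)),
                "height": float(ys[j]),
                "prominence": float(props["prominences"][i]),
            }
        )
    cands.sort(key=lambda c: (-c["prominence"], c["Ep_V"]))
    return cands


# --------------------------------------------------------------------------
# Baseline
# --------------------------------------------------------------------------

@dataclass
class BaselineFit:
    """A fitted charging-current baseline.

    ``model`` is ``"poly"`` (degree-d polynomial) or ``"poly+exp"`` (the same
    plus an exponential tail anchored at the negative end of the scan).
    """

    model: str
    degree: int
    coefficients: dict
    windows: list  # list of (lo_V, hi_V) fit intervals
    rmse: float
    grid_V: np.ndarray = field(repr=False)
    prediction: np.ndarray = field(repr=False)

    def predict(self, E) -> np.ndarray:
        E = np.asarray(E, dtype=float)
        c = self.coefficients
        out = np.polynomial.polynomial.polyval(E, c["poly"])
        if self.model == "poly+exp":
            out = out + c["exp_amplitude"] * np.exp(
                -(E - c["exp_anchor_V"]) / c["exp_decay_V"]
            )
        return out


def _design(E, degree, model, decay, anchor):
    cols = [E**i for i in range(degree + 1)]
    if model == "poly+exp":
        cols.append(np.exp(-(E - anchor) / decay))
    return np.column_stack(cols)


def _dilate(mask: np.ndarray, k: int) -> np.ndarray:
    out = mask.copy()
    for s in range(1, k + 1):
        out[s:] |= mask[:-s]
        out[:-s] |= mask[s:]
    return out


def _fit_coeffs(Ew, yw, degree, model, anchor):
    """Least-squares baseline coefficients over window samples."""
    if model == "poly":
        A = _design(Ew, degree, model, None, anchor)
        coef, *_ = np.linalg.lstsq(A, yw, rcond=None)
        return {"poly": coef}

    def sse(log_decay):
        A = _design(Ew, degree, model, math.exp(log_decay), anchor)
        c, *_ = np.linalg.lstsq(A, yw, rcond=None)
        r = yw - A @ c
        return float(r @ r)

    # the exponential term models a short-range onset at the negative edge;
    # its reach is capped so it cannot turn into a global trend collinear
    # with the polynomial
    res = minimize_scalar(
        sse, bounds=(math.log(0.02), math.log(0.10)), method="bounded",
        options={"xatol": 1e-10},
    )
    decay = math.exp(res.x)
    A = _design(Ew, degree, model, decay, anchor)
    coef, *_ = np.linalg.lstsq(A, yw, rcond=None)
    return {
        "poly": coef[: degree + 1],
        "exp_amplitude": float(coef[degree + 1]),
        "exp_decay_V": decay,
        "exp_anchor_V": anchor,
    }


def _predict_coeffs(E, coeffs, model):
    out = np.polynomial.polynomial.polyval(E, coeffs["poly"])
    if model == "poly+exp":
        out = out + coeffs["exp_amplitude"] * np.exp(
            -(E - coeffs["exp_anchor_V"]) / coeffs["exp_decay_V"]
        )
    return out


def _auto_windows(v: Voltammogram, degree: int, model: str, n_params: int):
    """Window samples: complement of the peak regions.

    A provisional polynomial through the scan edges is subtracted; samples
    whose residual exceeds a threshold (dilated by a few points) are treated
    as peak cores and excluded.  The outermost samples at both ends are
    always retained — they anchor the exponential-tail term and are by
    construction the regions farthest from any faradaic peak.  If the
    exclusion swallows nearly the whole scan, the threshold is relaxed with
    a warning.
    """
    E, y = v.potentials_V, v.currents
    mask = _edge_mask(E.size)
    coeffs = np.polynomial.polynomial.polyfit(E[mask], y[mask], min(degree, 3))
    resid = y - np.polynomial.polynomial.polyval(E, coeffs)
    noise = 1.4826 * float(
        np.median(np.abs(resid[mask] - np.median(resid[mask])))
    )
    thr = max(4.0 * noise, 0.04 * float(np.max(resid)), 1e-12)
    min_keep = max(2 * n_params, 12)
    for _ in range(6):
        keep = ~_dilate(resid > thr, 3)
        keep[:8] = True
        keep[-8:] = True
        if keep.sum() >= min_keep:
            return keep
        thr *= 2.0
    logger.warning("auto baseline windows overlap all detected peak cores")
    return keep


def _mask_from_windows(E, windows):
    mask = np.zeros(E.size, dtype=bool)
    for lo, hi in windows:
        lo, hi = min(lo, hi), max(lo, hi)
        mask |= (E >= lo) & (E <= hi)
    return mask


def _windows_from_mask(E, mask):
    out = []
    i = 0
    while i < mask.size:
        if mask[i]:
            j = i
            while j + 1 < mask.size and mask[j + 1]:
                j += 1
            out.append((float(E[i]), float(E[j])))
            i = j + 1
        else:
            i += 1
    return out


def fit_baseline(
    v: Voltammogram,
    windows="auto",
    degree: int = 3,
    model: str = "poly+exp",
) -> BaselineFit:
    """Fit the charging-current baseline over peak-free potential windows.

    ``windows`` is a list of ``(lo_V, hi_V)`` intervals or ``"auto"``
    (complement of the detected peak regions).  The fit is ordinary least
    squares over the window samples only; the returned object predicts the
    baseline over the full scan range.
    """
    if model not in ("poly", "poly+exp"):
        raise InvalidInputError(f"unknown baseline model {model!r}")
    E, y = v.potentials_V, v.currents
    n_params = degree + 1 + (2 if model == "poly+exp" else 0)
    if isinstance(windows, str) and windows == "auto":
        mask = _auto_windows(v, degree, model, n_params)
        window_list = _windows_from_mask(E, mask)
    else:
        window_list = list(windows)
        mask = _mask_from_windows(E, window_list)
    n_win = int(mask.sum())
    if n_win < degree + 1 or (model == "poly+exp" and n_win < n_params):
        raise UnderdeterminedError(
            f"baseline windows contain {n_win} samples, fewer than the "
            f"{max(degree + 1, n_params)} parameters of the {model} model"
        )
    coeffs = _fit_coeffs(E[mask], y[mask], degree, model, float(E.min()))

    fit = BaselineFit(
        model=model,
        degree=degree,
        coefficients=coeffs,
        windows=window_list,
        rmse=0.0,
        grid_V=E.copy(),
        prediction=np.empty(0),
    )
    pred_w = fit.predict(E[mask])
    fit.rmse = float(np.sqrt(np.mean((y[mask] - pred_w) ** 2)))
    fit.prediction = fit.predict(E)
    return fit


def subtract_baseline(v: Voltammogram, b: BaselineFit) -> Voltammogram:
    """Replace currents by the baseline residual; record the model used."""
    if v.potentials_V.shape != b.grid_V.shape or not np.allclose(
        v.potentials_V, b.grid_V
    ):
        raise InvalidInputError("baseline was fitted on a different potential grid")
    return v.with_currents(
        v.currents - b.prediction,
        baseline_model=b.model,
        baseline_degree=b.degree,
        baseline_windows=b.windows,
        baseline_subtracted=True,
    )


# --------------------------------------------------------------------------
# Deconvolution
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FittedPeak:
    """One fitted component of a deconvolution."""

    kind: str  # nernstian | gaussian
    Ep_V: float
    W_mV: float
    height: float
    label: str = ""


@dataclass
class DeconvolutionResult:
    """Converged multi-peak fit: components, covariance, residuals."""

    peaks: list
    beta: np.ndarray
    covariance: np.ndarray | None
    residual_norm: float
    objective: str  # "ODR" | "OLS"
    objective_value: float
    initial_objective: float
    amplitude_mV: float
    n_iterations: int = 0
    ill_conditioned: bool = False
    baseline: BaselineFit | None = None

    def model_currents(self, E) -> np.ndarray:
        return _compose(self.beta, [p.kind for p in self.peaks], E,
                        self.amplitude_mV / 1000.0)


def _compose(beta, kinds, E, amplitude_V):
    E = np.asarray(E, dtype=float)
    out = np.zeros_like(E)
    for i, kind in enumerate(kinds):
        pos, scale, height = beta[3 * i: 3 * i + 3]
        if kind == "nernstian":
            out += nernstian_peak(E, pos, abs(scale), height, amplitude_V)
        else:
            out += gaussian_peak(E, pos, abs(scale), height)
    return out


def _init_beta(init, amplitude_mV):
    beta, kinds = [], []
    for c in init:
        kind = c.get("kind", "nernstian")
        kinds.append(kind)
        if kind == "nernstian":
            scale = k_from_half_width(c["W_mV"], amplitude_mV)
            pos = c["Ep_V"]
        elif kind == "gaussian":
            scale = c["W_mV"] / 1000.0 / _GAUSS_FWHM
            pos = c.get("center_V", c.get("Ep_V"))
        else:
            raise InvalidInputError(f"unknown peak kind {kind!r}")
        beta.extend([pos, scale, c["height"]])
    return np.asarray(beta, dtype=float), kinds


def _peaks_from_beta(beta, kinds, amplitude_mV, labels=None):
    peaks = []
    for i, kind in enumerate(kinds):
        pos, scale, height = beta[3 * i: 3 * i + 3]
        if kind == "nernstian":
            W = half_width_from_k(abs(scale), amplitude_mV)
        else:
            W = abs(scale) * _GAUSS_FWHM * 1000.0
        label = labels[i] if labels else ""
        peaks.append(FittedPeak(kind, float(pos), float(W), float(height), label))
    return peaks


def _robust_noise_sd(y):
    n = max(3, y.size // 10)
    tails = np.concatenate([y[:n], y[-n:]])
    return 1.4826 * float(np.median(np.abs(tails - np.median(tails))))


def deconvolve(
    v: Voltammogram,
    init: list[dict],
    x_sd_mV: float | None = None,
    y_sd: float | None = None,
    method: str = "odr",
    max_iter: int = 200,
) -> DeconvolutionResult:
    """Weighted orthogonal-distance fit of a sum of peaks.

    Parameters
    ----------
    v : baseline-subtracted voltammogram.
    init : list of component dicts ``{kind, Ep_V, W_mV, height}``; its length
        fixes the number of fitted peaks.
    x_sd_mV : potential uncertainty.  Default ``increment/sqrt(12)``, the
        quantization noise of the staircase grid.
    y_sd : current uncertainty.  Default: robust MAD of the outer 10% of the
        (baseline-subtracted) samples, floored to stay finite on noise-free
        input.
    method : ``"odr"`` (weighted orthogonal distances, the default) or
        ``"ols"`` (ordinary least squares on the current axis only).

    Raises :class:`ConvergenceError` (carrying the last iterate) when the
    optimizer stops without convergence.
    """
    if not init:
        raise InvalidInputError("need at least one initial peak")
    E, y = v.potentials_V, v.currents
    amplitude_mV = v.pulse.amplitude_mV
    beta0, kinds = _init_beta(init, amplitude_mV)
    labels = [c.get("label", "") for c in init]
    if x_sd_mV is None:
        x_sd_mV = abs(v.increment_V) * 1000.0 / math.sqrt(12.0)
    if y_sd is None:
        y_sd = max(_robust_noise_sd(y), 1e-4 * float(np.max(np.abs(y))), 1e-9)
    x_sd_V = max(x_sd_mV / 1000.0, 1e-15)
    amp_V = amplitude_mV / 1000.0

    def f(beta, x):
        return _compose(beta, kinds, x, amp_V)

    init_obj = float(np.sum(((y - f(beta0, E)) / y_sd) ** 2))

    if method == "ols":
        sol = least_squares(
            lambda b: (f(b, E) - y) / y_sd, beta0, xtol=1e-12, ftol=1e-12,
            max_nfev=200 * beta0.size,
        )
        if not sol.success:
            raise ConvergenceError(
                f"least-squares fit did not converge: {sol.message}",
                last_iterate=sol.x,
            )
        beta = sol.x
        obj = float(2.0 * sol.cost)
        resid = f(beta, E) - y
        J = sol.jac
        try:
            cov = np.linalg.inv(J.T @ J) * obj / max(E.size - beta.size, 1)
        except np.linalg.LinAlgError:
            cov = None
        n_iter = sol.nfev
    elif method == "odr":
        data = scipy.odr.RealData(E, y, sx=x_sd_V, sy=y_sd)
        odr = scipy.odr.ODR(
            data, scipy.odr.Model(f), beta0=beta0, maxit=max_iter,
        )
        out = odr.run()
        # ODRPACK info < 4: converged (1 sum-of-squares, 2 parameter, 3 both)
        if out.info >= 4:
            raise ConvergenceError(
                f"ODR did not converge: {'; '.join(out.stopreason)}",
                last_iterate=out.beta,
            )
        beta = out.beta
        obj = float(out.sum_square)
        cov = out.cov_beta * out.res_var if out.cov_beta is not None else None
        resid = f(beta, E) - y
        n_iter = getattr(out, "iwork", [0])[0] if out.iwork is not None else 0
    else:
        raise InvalidInputError(f"unknown deconvolution method {method!r}")

    ill = False
    if cov is not None:
        diag = np.diag(cov)
        ill = bool(np.any(~np.isfinite(diag)) or np.any(diag < 0))
    # overlapping/duplicate components also flag ill-conditioning
    positions = sorted(beta[0::3])
    for a, b_ in zip(positions, positions[1:]):
        if abs(b_ - a) < 1e-4:
            ill = True
    if ill:
        logger.warning("deconvolution appears ill-conditioned "
                       "(requested peaks may exceed resolvable peaks)")

    peaks = _peaks_from_beta(beta, kinds, amplitude_mV, labels)
    return DeconvolutionResult(
        peaks=peaks,
        beta=np.asarray(beta, dtype=float),
        covariance=cov,
        residual_norm=float(np.linalg.norm(resid)),
        objective="ODR" if method == "odr" else "OLS",
        objective_value=obj,
        initial_objective=init_obj,
        amplitude_mV=amplitude_mV,
        n_iterations=int(n_iter),
        ill_conditioned=ill,
    )


def summarize_peaks(
    r: DeconvolutionResult,
    pulse: PulseParams | None = None,
    T: float = DEFAULT_TEMPERATURE_K,
) -> pd.DataFrame:
    """Report table: E_p (mV), half-width (mV), height, charge, apparent n.

    The charge proxy integrates each fitted component over potential and
    divides by the staircase scan rate (increment/period); apparent n inverts
    the theoretical half-width (Nernstian components only).
    """
    pulse = pulse or PulseParams(amplitude_mV=r.amplitude_mV)
    rows = []
    # integrate each component on a wide fine grid
    for i, p in enumerate(r.peaks):
        span = 6.0 * p.W_mV / 1000.0
        grid = np.linspace(p.Ep_V - span, p.Ep_V + span, 2001)
        comp = _compose(
            r.beta[3 * i: 3 * i + 3], [p.kind], grid, r.amplitude_mV / 1000.0
        )
        area_uA_V = float(np.trapezoid(comp, grid))
        charge_uC = area_uA_V / pulse.scan_rate_V_s
        if p.kind == "nernstian":
            n_app = apparent_n_from_width(p.W_mV, r.amplitude_mV, T)
        else:
            n_app = float("nan")
        rows.append(
            {
                "component": i,
                "kind": p.kind,
                "label": p.label,
                "Ep_mV": p.Ep_V * 1000.0,
                "half_width_mV": p.W_mV,
                "height_uA_cm2": p.height,
                "charge_uC_cm2": charge_uC,
                "apparent_n": n_app,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# End-to-end convenience
# --------------------------------------------------------------------------

def _build_init(v: Voltammogram, n_flavin: int, include_heme: bool):
    """Initial components by greedy peak stripping.

    The strongest candidate seeds a Nernstian component whose crude guess is
    subtracted before re-detecting, so shoulder peaks riding on a dominant
    neighbour (e.g. residual free flavin next to the bound-cofactor peak)
    are still found.  The heme envelope starts at the maximum of whatever
    smooth structure remains.
    """
    E = v.potentials_V
    remaining = v.currents.astype(float).copy()
    init = []
    for _ in range(n_flavin):
        work = v.with_currents(remaining)
        cands = detect_peaks(work)
        narrow = [c for c in cands if c["W_mV"] < 200.0]
        if not (narrow or cands):
            break
        c = (narrow or cands)[0]
        guess = {
            "kind": "nernstian",
            "Ep_V": c["Ep_V"],
            "W_mV": min(max(c["W_mV"], 40.0), 180.0),
            "height": max(c["height"], 1e-3),
            "label": "flavin",
        }
        init.append(guess)
        remaining = remaining - nernstian_peak(
            E, guess["Ep_V"],
            k_from_half_width(guess["W_mV"], v.pulse.amplitude_mV),
            guess["height"], v.pulse.amplitude_V,
        )
    init.sort(key=lambda c: c["Ep_V"])
    if include_heme:
        smoothed = _smooth(remaining, 9)
        j = int(np.argmax(smoothed))
        init.append(
            {
                "kind": "gaussian",
                "Ep_V": float(E[j]),
                "W_mV": 250.0,
                "height": max(float(smoothed[j]), 1e-3),
                "label": "heme envelope",
            }
        )
    if not init:
        raise InvalidInputError("no peak candidates detected")
    return init


def refine_baseline(
    v: Voltammogram,
    baseline: BaselineFit,
    init: list[dict],
) -> tuple[BaselineFit, list[dict]]:
    """Peak-aware baseline refinement by a joint least-squares fit.

    A broad envelope (e.g. the heme background) is nearly collinear with a
    smooth baseline when the baseline is constrained only by the scan edges.
    Fitting baseline and peak parameters together over the full scan removes
    the window-extrapolation error; the refined baseline and peak parameters
    are returned (peaks as init dicts for a final deconvolution).
    """
    E, y = v.potentials_V, v.currents
    amp_V = v.pulse.amplitude_V
    degree, model = baseline.degree, baseline.model
    c = baseline.coefficients
    anchor = float(c.get("exp_anchor_V", E.min()))
    beta0, kinds = _init_beta(init, v.pulse.amplitude_mV)
    labels = [c_.get("label", "") for c_ in init]
    nb = degree + 1
    if model == "poly+exp":
        p0 = np.concatenate(
            [c["poly"], [c["exp_amplitude"], math.log(c["exp_decay_V"])], beta0]
        )
        npar = nb + 2
    else:
        p0 = np.concatenate([c["poly"], beta0])
        npar = nb

    def base_of(p):
        out = np.polynomial.polynomial.polyval(E, p[:nb])
        if model == "poly+exp":
            out = out + p[nb] * np.exp(-(E - anchor) / math.exp(p[nb + 1]))
        return out

    def resid(p):
        return base_of(p) + _compose(p[npar:], kinds, E, amp_V) - y

    sol = least_squares(
        resid, p0, xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000
    )
    if model == "poly+exp":
        coeffs = {
            "poly": sol.x[:nb],
            "exp_amplitude": float(sol.x[nb]),
            "exp_decay_V": float(math.exp(sol.x[nb + 1])),
            "exp_anchor_V": anchor,
        }
    else:
        coeffs = {"poly": sol.x[:nb]}
    refined = BaselineFit(
        model=model,
        degree=degree,
        coefficients=coeffs,
        windows=[(float(E.min()), float(E.max()))],
        rmse=float(np.sqrt(np.mean(resid(sol.x) ** 2))),
        grid_V=E.copy(),
        prediction=np.empty(0),
    )
    refined.prediction = refined.predict(E)
    peaks = _peaks_from_beta(sol.x[npar:], kinds, v.pulse.amplitude_mV, labels)
    new_init = [
        {"kind": p.kind, "Ep_V": p.Ep_V, "W_mV": p.W_mV, "height": p.height,
         "label": p.label}
        for p in peaks
    ]
    return refined, new_init


def analyze(
    v: Voltammogram,
    n_flavin: int | None = None,
    include_heme: bool | None = None,
    baseline_degree: int = 3,
    baseline_model: str = "poly+exp",
    method: str = "odr",
    T: float | None = None,
) -> tuple[DeconvolutionResult, pd.DataFrame]:
    """Full chain: baseline fit/subtraction, deconvolution, peak report.

    Stages: auto-window baseline fit; peak detection for initial values;
    peak-aware joint baseline refinement; final weighted-ODR deconvolution
    of the baseline-subtracted signal; report table.  The refined baseline
    is attached to the returned result as ``result.baseline``.

    Component structure (how many flavin peaks, whether a heme envelope is
    present) defaults to the ``components`` metadata hint when the
    voltammogram carries one, else to one Nernstian peak per detected narrow
    candidate with no heme envelope.  Initial parameter values always come
    from peak detection, never from metadata.
    """
    T = T if T is not None else v.temperature_K
    hinted = v.metadata.get("components")
    if n_flavin is None:
        if hinted is not None:
            n_flavin = sum(1 for c in hinted if c.get("kind") == "nernstian")
        else:
            n_flavin = max(
                1, len([c for c in detect_peaks(v) if c["W_mV"] < 200.0])
            )
    if include_heme is None:
        include_heme = (
            any(c.get("kind") == "gaussian" for c in hinted)
            if hinted is not None
            else False
        )
    if v.metadata.get("baseline_subtracted"):
        init = _build_init(v, n_flavin, include_heme)
        result = deconvolve(v, init, method=method)
        result.baseline = None
    else:
        b = fit_baseline(v, "auto", degree=baseline_degree, model=baseline_model)
        vs = subtract_baseline(v, b)
        init = _build_init(vs, n_flavin, include_heme)
        b, init = refine_baseline(v, b, init)
        vs = subtract_baseline(v, b)
        result = deconvolve(vs, init, method=method)
        result.baseline = b
    report = summarize_peaks(result, v.pulse, T)
    return result, report
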