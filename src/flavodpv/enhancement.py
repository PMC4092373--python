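"""Flavin enhancement factors from chronoamperometry traces.

The enhancement factor (EF) quantifies how much a flavin addition speeds up
microbial current production:

    EF = (i(t0 + 1000 s) - i_bg) / (mean_{[t0-60 s, t0)} i - i_bg)

with the background current i_bg measured on the same biofilm without
lactate at the same electrode potential.  EF is a ratio of
background-subtracted currents, so it is invariant to current-unit rescaling
and to any constant offset applied to both trace and background.

:func:`build_panel` aggregates EF results over electrode potential or pH
into mean +/- standard error rows (the structure of a potential/pH
dependency figure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AdditionEvent, CurrentTrace
from .exceptions import (
    InvalidInputError,
    TraceTooShortError,
    UndefinedEnhancementError,
)

logger = logging.getLogger(__name__)

__all__ = ["EnhancementResult", "enhancement_factor", "build_panel"]

PRE_WINDOW_S = 60.0
POST_DELAY_S = 1000.0


@dataclass(frozen=True)
class EnhancementResult:
    """An enhancement factor with its experimental coordinates."""

    EF: float
    potential_V: float
    pH: float
    flavin: str
    pre_current: float
    post_current: float
    background_current: float


def _background_at(background, times):
    if background is None:
        logger.warning("no background trace supplied; assuming zero background")
        return np.zeros_like(np.asarray(times, dtype=float))
    if isinstance(background, CurrentTrace):
        return background.interp(times)
    return np.full_like(np.asarray(times, dtype=float), float(background))


def enhancement_factor(
    trace: CurrentTrace,
    event: AdditionEvent | None = None,
    background=None,
) -> EnhancementResult:
    """EF of a flavin addition: pre-addition mean vs 1000 s post-addition.

    ``event`` defaults to the trace's first ``flavin_addition`` event;
    ``background`` may be a matched no-lactate :class:`CurrentTrace`, a
    scalar, or ``None`` (zero, with a logged warning).  The pre-addition
    current is the mean over the 60 s before the event; the post-addition
    current is the linear interpolant at exactly +1000 s.
    """
    if event is None:
        event = next(
            (e for e in trace.events if e.kind == "flavin_addition"), None
        )
        if event is None:
            raise InvalidInputError("trace has no flavin_addition event")
    t0 = event.time_s
    if not trace.times_s[0] <= t0 <= trace.times_s[-1]:
        raise InvalidInputError("event lies outside the trace span")
    if trace.times_s[-1] < t0 + POST_DELAY_S:
        raise TraceTooShortError(
            f"trace ends {trace.times_s[-1] - t0:.0f} s after the event; "
            f"{POST_DELAY_S:.0f} s required"
        )
    pre_mask = (trace.times_s >= t0 - PRE_WINDOW_S) & (trace.times_s < t0)
    if not pre_mask.any():
        raise TraceTooShortError("no samples in the 60 s pre-addition window")
    pre_times = trace.times_s[pre_mask]
    i_pre = float(np.mean(trace.currents[pre_mask]))
    bg_pre = float(np.mean(_background_at(background, pre_times)))
    t_post = t0 + POST_DELAY_S
    i_post = float(trace.interp(t_post))
    bg_post = float(_background_at(background, [t_post])[0])

    denom = i_pre - bg_pre
    if denom <= 0:
        raise UndefinedEnhancementError(
            "pre-addition current does not exceed background; EF undefined"
        )
    ef = (i_post - bg_post) / denom
    return EnhancementResult(
        EF=float(ef),
        potential_V=trace.potential_V,
        pH=trace.pH,
        flavin=trace.flavin,
        pre_current=i_pre,
        post_current=i_post,
        background_current=bg_pre,
    )


def build_panel(results, axis: str = "potential") -> pd.DataFrame:
    """Group EF results into (axis value, flavin) -> mean, sem, n rows.

    ``axis`` is ``"potential"`` or ``"pH"``; rows are sorted by axis value.
    A warning is logged when the grouping mixes inconsistent settings on the
    other axis (e.g. a potential panel spanning several pH values).
    """
    if axis not in ("potential", "pH"):
        raise InvalidInputError(f"unknown panel axis {axis!r}")
    results = list(results)
    if not results:
        raise InvalidInputError("no enhancement results to aggregate")
    df = pd.DataFrame(
        {
            "potential": [r.potential_V for r in results],
            "pH": [r.pH for r in results],
            "flavin": [r.flavin for r in results],
            "EF": [r.EF for r in results],
        }
    )
    other = "pH" if axis == "potential" else "potential"
    if df[other].nunique() > 1:
        logger.warning(
            "panel over %s mixes %d distinct %s values", axis,
            df[other].nunique(), other,
        )
    grouped = (
        df.groupby([axis, "flavin"], sort=True)["EF"]
        .agg(mean_EF="mean", sem="sem", n="count")
        .reset_index()
    )
    grouped["sem"] = grouped["sem"].fillna(0.0)
    return grouped.sort_values([axis, "flavin"]).reset_index(drop=True)
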