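"""Figure-of-merit definitions for nonlinear-optical molecular switches.

A molecular switch interconverts between an ON state (large β_HRS) and an OFF
state (small β_HRS).  Two figures of merit are used:

* ratio contrast:       β_HRS(ON) / β_HRS(OFF)
* difference contrast:  β_HRS(ON) − β_HRS(OFF)

A centrosymmetric OFF state has β_HRS = 0 and would send the ratio to
infinity; whenever β_HRS(OFF) falls below a clamp threshold (default 10 a.u.)
the denominator is replaced by a small fixed value (default 0.001 a.u.) so
that clamped ratios stay finite and comparable.  The OFF state is assigned by
chemical role (the rectangular Hückel 28R form by convention), not by
magnitude; an ON/OFF reversal (larger OFF response) is reported via a flag
rather than silently relabelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SwitchPair",
    "ContrastResult",
    "ratio_contrast",
    "difference_contrast",
    "evaluate_switch",
    "contrast_correlation",
    "DEFAULT_CLAMP_THRESHOLD",
    "DEFAULT_CLAMP_VALUE",
    "ContrastError",
    "UndefinedStatisticError",
]

DEFAULT_CLAMP_THRESHOLD = 10.0  # a.u.; OFF responses below this are clamped
DEFAULT_CLAMP_VALUE = 0.001  # a.u.; replacement denominator

OBJECTIVES = ("ratio", "difference")


class ContrastError(ValueError):
    """Invalid switch pair or objective configuration."""


class UndefinedStatisticError(ValueError):
    """Raised when a correlation statistic is undefined (< 2 points, 0 variance)."""


@dataclass(frozen=True)
class SwitchPair:
    """β_HRS values of the two states of one switch at one frequency."""

    beta_on: float
    beta_off: float
    on_label: str = "26R"
    off_label: str = "28R"
    frequency: float = 0.0

    def __post_init__(self):
        for name, v in (("beta_on", self.beta_on), ("beta_off", self.beta_off)):
            if not math.isfinite(v):
                raise ContrastError(f"{name} must be finite, got {v!r}")
            if v < 0:
                raise ContrastError(f"{name} must be >= 0 (beta_hrs is a norm), got {v}")


@dataclass(frozen=True)
class ContrastResult:
    """Both contrasts for a pair, plus the designated objective value."""

    ratio: float
    difference: float
    clamped: bool
    reversed: bool
    objective: str = "ratio"

    @property
    def objective_value(self) -> float:
        return self.ratio if self.objective == "ratio" else self.difference


def ratio_contrast(
    pair: SwitchPair,
    clamp_threshold: float = DEFAULT_CLAMP_THRESHOLD,
    clamp_value: float = DEFAULT_CLAMP_VALUE,
) -> tuple[float, bool]:
    """Ratio figure of merit with the OFF-state clamping rule.

    Returns ``(ratio, clamped)``.  When ``beta_off < clamp_threshold`` the
    denominator is replaced by ``clamp_value``, which reproduces the 10⁶–10⁷
    contrast regime of switches with a centrosymmetric OFF state.
    """
    if pair.beta_off < clamp_threshold:
        return pair.beta_on / clamp_value, True
    return pair.beta_on / pair.beta_off, False


def difference_contrast(pair: SwitchPair) -> float:
    """Difference figure of merit; negative values signal ON/OFF reversal."""
    return pair.beta_on - pair.beta_off


def evaluate_switch(
    pair: SwitchPair,
    objective: str = "ratio",
    clamp_threshold: float = DEFAULT_CLAMP_THRESHOLD,
    clamp_value: float = DEFAULT_CLAMP_VALUE,
) -> ContrastResult:
    """Compute both contrasts and designate one as the optimization objective."""
    if objective not in OBJECTIVES:
        raise ContrastError(
            f"unknown objective {objective!r}; expected one of {OBJECTIVES}"
        )
    ratio, clamped = ratio_contrast(pair, clamp_threshold, clamp_value)
    diff = difference_contrast(pair)
    return ContrastResult(
        ratio=ratio,
        difference=diff,
        clamped=clamped,
        reversed=diff < 0,
        objective=objective,
    )


def contrast_correlation(points, subset=None) -> float:
    """Ordinary-least-squares R² of difference contrast regressed on ratio.

    ``points`` is an iterable of ``(ratio, difference)`` pairs (or objects
    with ``.ratio``/``.difference``); ``subset`` is an optional predicate
    filtering the points first.  For switches whose OFF state is
    centrosymmetric (stored β_HRS = 0, clamp at 0.001 a.u.) the ratio is
    exactly 1000 × the difference, so R² = 1 by construction.
    """
    xy = []
    for p in points:
        if subset is not None and not subset(p):
            continue
        if hasattr(p, "ratio"):
            xy.append((p.ratio, p.difference))
        else:
            xy.append((float(p[0]), float(p[1])))
    if len(xy) < 2:
        raise UndefinedStatisticError("need at least 2 points for a correlation")
    x, y = np.array(xy).T
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    res = stats.linregress(x, y)
    return float(res.rvalue**2)
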