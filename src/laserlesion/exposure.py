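"""Radiant-exposure arithmetic, reciprocity testing, damage frequency and
concurrent-exposure interaction classification."""

from __future__ import annotations

from dataclasses import dataclass, field
from math import copysign, floor

import numpy as np
from scipy import stats

from .errors import InvalidComparisonError, InvalidParameterError
from .probit import ProbitFit, fiducial_limits

__all__ = [
    "FrequencyResult",
    "InteractionResult",
    "ReciprocityReport",
    "radiant_exposure",
    "test_reciprocity",
    "damage_frequency",
    "classify_interaction",
    "delta_threshold_dT",
]


def radiant_exposure(irradiance: float, duration: float) -> float:
    """H = E·τ, J cm^-2 (irradiance in W cm^-2, duration in s)."""
    if irradiance < 0 or duration < 0:
        raise InvalidParameterError("irradiance and duration must be >= 0")
    return irradiance * duration


# ---------------------------------------------------------------------------
# reciprocity
# ---------------------------------------------------------------------------

@dataclass
class ReciprocityReport:
    is_reciprocal: bool
    radiant_exposures: tuple[float, float]  # J cm^-2, same order as inputs
    relative_difference: float              # |ΔH| / mean(H)
    tolerance: float
    fiducial_intervals_disjoint: bool | None = None
    details: dict = field(default_factory=dict)


def test_reciprocity(
    fit_a: ProbitFit,
    duration_a: float,
    fit_b: ProbitFit,
    duration_b: float,
    tolerance: float = 0.10,
    p: float = 0.5,
) -> ReciprocityReport:
    """Bunsen–Roscoe check: do the two ED_p radiant exposures agree?

    Reciprocal iff |H_a − H_b| / mean(H) <= tolerance. The irradiance
    fiducial intervals' disjointness (the published significance check for
    the ED50 irradiances differing) is reported separately when limits are
    computable.
    """
    if duration_a == duration_b:
        raise InvalidComparisonError(
            "reciprocity needs two different exposure durations"
        )
    ed_a = fit_a.ed(p)
    ed_b = fit_b.ed(p)
    h_a = radiant_exposure(ed_a, duration_a)
    h_b = radiant_exposure(ed_b, duration_b)
    rel = abs(h_a - h_b) / ((h_a + h_b) / 2.0)

    disjoint = None
    details = {"ed_a": ed_a, "ed_b": ed_b, "p": p}
    try:
        fl_a = fiducial_limits(fit_a, p)
        fl_b = fiducial_limits(fit_b, p)
        details["fl_a"] = fl_a
        details["fl_b"] = fl_b
        disjoint = fl_a[1] < fl_b[0] or fl_b[1] < fl_a[0]
    except Exception as exc:  # limits unbounded or fit degenerate
        details["fl_error"] = str(exc)

    return ReciprocityReport(
        is_reciprocal=rel <= tolerance,
        radiant_exposures=(h_a, h_b),
        relative_difference=rel,
        tolerance=tolerance,
        fiducial_intervals_disjoint=disjoint,
        details=details,
    )


# ---------------------------------------------------------------------------
# damage frequency
# ---------------------------------------------------------------------------

def _round_half_away(x: float) -> int:
    return int(floor(abs(x) + 0.5) * copysign(1, x))


@dataclass
class FrequencyResult:
    positives: int
    total: int
    frequency: int                      # percent, nearest integer
    raw_fraction: float
    ci95: tuple[float, float]           # percent, Clopper–Pearson


def damage_frequency(positives: int, total: int) -> FrequencyResult:
    """Observed damage frequency with an exact Clopper–Pearson 95% CI.

    The headline frequency is rounded to the nearest integer percent
    (half away from zero); the raw fraction is retained.
    """
    if total <= 0:
        raise InvalidParameterError("total must be > 0")
    if not (0 <= positives <= total):
        raise InvalidParameterError("positives must be in [0, total]")
    frac = positives / total
    alpha = 0.05
    lo = 0.0 if positives == 0 else stats.beta.ppf(
        alpha / 2, positives, total - positives + 1)
    hi = 1.0 if positives == total else stats.beta.ppf(
        1 - alpha / 2, positives + 1, total - positives)
    return FrequencyResult(
        positives=positives, total=total,
        frequency=_round_half_away(100.0 * frac),
        raw_fraction=frac,
        ci95=(100.0 * lo, 100.0 * hi),
    )


# ---------------------------------------------------------------------------
# interaction classification
# ---------------------------------------------------------------------------

_LABEL_ORDER = ["inhibitory", "independent", "additive", "synergistic"]


@dataclass
class InteractionResult:
    expected_independent: float   # percent
    expected_additive: float      # percent
    observed: FrequencyResult
    label: str
    p_value_vs_independent: float
    details: dict = field(default_factory=dict)


def classify_interaction(
    p_a: float, p_b: float, positives: int, total: int
) -> InteractionResult:
    """Classify a concurrent-exposure outcome against two single-agent rates.

    The independent expectation is 1 − (1−pA)(1−pB) and the additive one
    min(1, pA + pB). Exact central binomial 95% bands at each expectation
    partition the observed count into inhibitory / independent / additive /
    synergistic, in that (monotone) order.
    """
    for name, p in (("p_a", p_a), ("p_b", p_b)):
        if not (0 <= p <= 1):
            raise InvalidParameterError(f"{name} must be in [0, 1]")
    obs = damage_frequency(positives, total)

    p_ind = 1.0 - (1.0 - p_a) * (1.0 - p_b)
    p_add = min(1.0, p_a + p_b)

    lo_ind = int(stats.binom.ppf(0.025, total, p_ind))
    hi_ind = int(stats.binom.ppf(0.975, total, p_ind))
    hi_add = int(stats.binom.ppf(0.975, total, p_add))
    hi_add = max(hi_add, hi_ind)  # additive band never narrower downward

    if positives < lo_ind:
        label = "inhibitory"
    elif positives <= hi_ind:
        label = "independent"
    elif positives <= hi_add:
        label = "additive"
    else:
        label = "synergistic"

    p_value = float(stats.binomtest(positives, total, p_ind).pvalue)
    return InteractionResult(
        expected_independent=100.0 * p_ind,
        expected_additive=100.0 * p_add,
        observed=obs,
        label=label,
        p_value_vs_independent=p_value,
        details={
            "band_independent": (lo_ind, hi_ind),
            "band_additive_upper": hi_add,
        },
    )


# ---------------------------------------------------------------------------
# threshold ΔT differences
# ---------------------------------------------------------------------------

def delta_threshold_dT(
    dT_control: float,
    dT_test: float,
    samples_control=None,
    samples_test=None,
):
    """Control-minus-test threshold peak ΔT (°C).

    When per-exposure boundary samples are supplied, a Welch two-sample
    t-test is run and (difference, p_value) is returned; otherwise just
    the difference.
    """
    diff = dT_control - dT_test
    if samples_control is not None and samples_test is not None:
        res = stats.ttest_ind(
            np.asarray(samples_control, dtype=float),
            np.asarray(samples_test, dtype=float),
            equal_var=False,
        )
        return diff, float(res.pvalue)
    return diff
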