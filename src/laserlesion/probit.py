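"""Probit dose-response fitting with fiducial limits and quality gates.

The dose metameter is log10(irradiance): P(damage) = Φ(β0 + β1·x), so β1
is the probit slope in probits per decade and ED_p = 10^((Φ⁻¹(p) − β0)/β1).
Fiducial limits follow Fieller's theorem on the dose ratio, with Finney's
heterogeneity inflation (χ²-scaled variances and a t multiplier) when the
grouped Pearson χ²/df exceeds 1.

Completely separated data (every negative below every positive, with a
gap) has no finite ML estimate; :func:`fit_probit` raises
:class:`SeparationError` and :func:`detect_deterministic` takes over.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    InvalidParameterError,
    SeparationError,
    UnboundedLimitsError,
)
from .fileio import ExposureRecord

__all__ = [
    "ProbitFit",
    "DeterminismReport",
    "CriteriaResult",
    "fit_probit",
    "fiducial_limits",
    "check_criteria",
    "detect_deterministic",
]

#: default relative dose uncertainty for the deterministic rule; the
#: instrument's irradiance uncertainty band is 2.8–3.2%
DEFAULT_DOSE_UNCERTAINTY = 0.032


@dataclass
class ProbitFit:
    """Maximum-likelihood probit fit on x = log10(dose)."""

    intercept: float                 # β0
    slope: float                     # β1, probits per log10 decade
    cov: np.ndarray                  # 2×2 covariance of (β0, β1)
    heterogeneity: float             # Pearson χ²/df over dose groups
    het_df: int
    n_used: int
    n_excluded: int
    converged: bool
    slope_at_ed50: float             # dP/dx at P=0.5, probability per decade

    def ed(self, p: float) -> float:
        """Dose with damage probability p (W cm^-2)."""
        if not (0 < p < 1):
            raise InvalidParameterError("p must be in (0, 1)")
        return float(10 ** ((stats.norm.ppf(p) - self.intercept) / self.slope))

    def predict(self, dose) -> np.ndarray:
        x = np.log10(np.asarray(dose, dtype=float))
        return stats.norm.cdf(self.intercept + self.slope * x)


@dataclass
class DeterminismReport:
    is_deterministic: bool
    crossover_range: tuple[float, float]
    deterministic_threshold: float
    n_crossovers: int
    reason: str = ""


@dataclass
class CriteriaResult:
    passed: bool
    reasons: list[str] = field(default_factory=list)
    details: dict = field(default_factory=dict)


def _usable(records: list[ExposureRecord]):
    used = [r for r in records if r.outcome in (0, 1)]
    excluded = len(records) - len(used)
    return used, excluded


def fit_probit(records: list[ExposureRecord]) -> ProbitFit:
    """Fit the probit model by maximum likelihood.

    Requires at least two positives and two negatives among non-excluded
    records and strictly positive doses. Raises :class:`SeparationError`
    when the outcomes are completely separated in dose.
    """
    used, n_excluded = _usable(records)
    doses = np.array([r.irradiance for r in used], dtype=float)
    y = np.array([r.outcome for r in used], dtype=float)
    if np.any(doses <= 0):
        raise InvalidParameterError("all doses must be > 0 for a log fit")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos < 2 or n_neg < 2:
        raise InvalidParameterError(
            f"need >= 2 positives and >= 2 negatives, got {n_pos}/{n_neg}"
        )
    max_neg = doses[y == 0].max()
    min_pos = doses[y == 1].min()
    if max_neg < min_pos:
        raise SeparationError(
            "complete separation: all negatives below all positives; "
            "use detect_deterministic",
            max_negative=float(max_neg), min_positive=float(min_pos),
        )

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    x = np.log10(doses)
    exog = np.column_stack([np.ones_like(x), x])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Probit(y, exog).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"probit fit failed to converge: {exc}")
    if not res.mle_retvals.get("converged", False):
        raise SeparationError("probit fit did not converge")

    beta0, beta1 = res.params
    cov = np.asarray(res.cov_params())

    # grouped Pearson heterogeneity over unique doses
    chi2 = 0.0
    groups = 0
    for d in np.unique(doses):
        sel = doses == d
        n = int(sel.sum())
        k = float(y[sel].sum())
        p = float(stats.norm.cdf(beta0 + beta1 * np.log10(d)))
        p = min(max(p, 1e-12), 1 - 1e-12)
        chi2 += (k - n * p) ** 2 / (n * p * (1 - p))
        groups += 1
    het_df = max(groups - 2, 1)
    heterogeneity = chi2 / het_df

    # dP/dx at the ED50: φ(0)·β1 — reported alongside β1 because "slope"
    # is ambiguous in parts of the literature; the >5 gate uses β1
    slope_at_ed50 = float(stats.norm.pdf(0.0) * beta1)

    return ProbitFit(
        intercept=float(beta0), slope=float(beta1), cov=cov,
        heterogeneity=float(heterogeneity), het_df=het_df,
        n_used=len(used), n_excluded=n_excluded,
        converged=True, slope_at_ed50=slope_at_ed50,
    )


def fiducial_limits(
    fit: ProbitFit, p: float, level: float = 0.95
) -> tuple[float, float]:
    """Fieller fiducial limits for ED_p on the dose scale.

    When the grouped heterogeneity factor exceeds 1 the covariance is
    scaled by it and the normal quantile is replaced by Student's t on the
    heterogeneity df (Finney's correction).
    """
    if not fit.converged:
        raise InvalidParameterError("fit did not converge")
    z_p = stats.norm.ppf(p)
    h = max(fit.heterogeneity, 1.0)
    if fit.heterogeneity > 1.0:
        tq = stats.t.ppf(1 - (1 - level) / 2, fit.het_df)
    else:
        tq = stats.norm.ppf(1 - (1 - level) / 2)
    cov = fit.cov * h

    # ratio m = (z_p − β0)/β1 = a/b with a = z_p − β0, b = β1
    a = z_p - fit.intercept
    b = fit.slope
    v_aa = cov[0, 0]            # Var(z_p − β0) = Var(β0)
    v_bb = cov[1, 1]
    v_ab = -cov[0, 1]           # Cov(z_p − β0, β1)
    m = a / b
    g = tq ** 2 * v_bb / b ** 2
    if g >= 1:
        raise UnboundedLimitsError(
            f"g = {g:.3f} >= 1: fiducial limits unbounded at level {level}"
        )
    if v_bb > 0:
        disc = (v_aa - 2 * m * v_ab + m ** 2 * v_bb
                - g * (v_aa - v_ab ** 2 / v_bb))
        center = m - g * v_ab / v_bb
    else:  # no slope uncertainty: Fieller degenerates to Wald
        disc = v_aa
        center = m
    if disc < 0:
        disc = 0.0
    half = (tq / abs(b)) * np.sqrt(disc)
    lo = (center - half) / (1 - g)
    hi = (center + half) / (1 - g)
    return float(10 ** lo), float(10 ** hi)


def check_criteria(
    fit: ProbitFit,
    p_list=(0.5,),
    slope_min: float = 5.0,
    rel_limit: float = 0.30,
    level: float = 0.95,
) -> CriteriaResult:
    """Quality gates: slope > 5 probits/decade and relative fiducial
    limits within ±30% of each ED_p of interest."""
    reasons = []
    details: dict = {"slope": fit.slope}
    if not fit.slope > slope_min:
        reasons.append("slope")
    for p in p_list:
        ed = fit.ed(p)
        try:
            lo, hi = fiducial_limits(fit, p, level=level)
        except UnboundedLimitsError:
            reasons.append("fiducial width")
            details[f"ed{int(round(p * 100))}"] = {
                "ed": ed, "limits": None, "rel_width": None,
            }
            continue
        rel = max(abs(hi - ed), abs(ed - lo)) / ed
        details[f"ed{int(round(p * 100))}"] = {
            "ed": ed, "limits": (lo, hi), "rel_width": rel,
        }
        if rel > rel_limit:
            reasons.append("fiducial width")
    # deduplicate, preserving order
    reasons = list(dict.fromkeys(reasons))
    return CriteriaResult(passed=not reasons, reasons=reasons, details=details)


def detect_deterministic(
    records: list[ExposureRecord],
    dose_uncertainty: float = DEFAULT_DOSE_UNCERTAINTY,
) -> DeterminismReport:
    """Classify a dose-response dataset as deterministic or probabilistic.

    The crossover range is [min positive dose, max negative dose] (ordered).
    The response is deterministic when that range is no wider than the
    relative dose uncertainty, or when the probit fit cannot converge at
    all; the deterministic threshold is the midpoint of the mixed-outcome
    range.
    """
    used, _ = _usable(records)
    doses = np.array([r.irradiance for r in used], dtype=float)
    y = np.array([r.outcome for r in used], dtype=int)
    if not (y == 1).any() or not (y == 0).any():
        raise InvalidParameterError("need at least one positive and one negative")

    min_pos = float(doses[y == 1].min())
    max_neg = float(doses[y == 0].max())
    lo, hi = sorted((min_pos, max_neg))
    midpoint = 0.5 * (lo + hi)
    width = hi - lo

    if max_neg < min_pos:
        # no crossovers at all: the mixed range is the empty gap
        return DeterminismReport(
            is_deterministic=True,
            crossover_range=(lo, hi),
            deterministic_threshold=midpoint,
            n_crossovers=0,
            reason="no crossovers (complete separation)",
        )

    n_crossovers = int(((doses >= lo) & (doses <= hi)).sum())
    if width <= dose_uncertainty * midpoint:
        return DeterminismReport(
            is_deterministic=True,
            crossover_range=(lo, hi),
            deterministic_threshold=midpoint,
            n_crossovers=n_crossovers,
            reason=(f"crossover span {width:.4g} within dose uncertainty "
                    f"{dose_uncertainty:.1%} of midpoint"),
        )

    try:
        fit_probit(records)
    except (SeparationError, InvalidParameterError) as exc:
        return DeterminismReport(
            is_deterministic=True,
            crossover_range=(lo, hi),
            deterministic_threshold=midpoint,
            n_crossovers=n_crossovers,
            reason=f"probit non-convergence: {exc}",
        )
    return DeterminismReport(
        is_deterministic=False,
        crossover_range=(lo, hi),
        deterministic_threshold=midpoint,
        n_crossovers=n_crossovers,
        reason="probabilistic: wide crossover span and convergent probit",
    )
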