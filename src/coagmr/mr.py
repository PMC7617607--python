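"""Two-sample Mendelian randomization estimators.

Implements the Wald ratio (single instrument, first-order delta-method SE),
the random-effects inverse-variance weighted estimator (origin-constrained
weighted regression of outcome betas on exposure betas, multiplicative
over-dispersion floored at 1), multivariable MR (the K-exposure analogue),
per-doubling-of-liability rescaling for disease-derived instruments, and the
Bonferroni multiplicity plan.

All causal estimates are on the outcome's log-odds scale; ``exposure_scale``
records whether the unit of exposure is 1 SD of protein level or a doubling
of liability (VTE) odds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .harmonize import HarmonizedPair

Z95 = 1.96


class MRError(ValueError):
    pass


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the log-odds scale."""

    theta: float
    se: float
    pval: float
    method: str  # wald | ivw | mvmr
    n_variants: int
    Q: float = 0.0
    phi: float = 1.0
    exposure_scale: str = "per_sd"  # per_sd | per_doubling_liability
    exposure_id: str = ""
    outcome_id: str = ""

    @property
    def ci_low(self) -> float:
        return self.theta - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.theta + Z95 * self.se

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.theta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)

    def summary_row(self) -> dict:
        lo, hi = self.or_ci
        return {
            "exposure": self.exposure_id,
            "outcome": self.outcome_id,
            "method": self.method,
            "n_variants": self.n_variants,
            "theta": self.theta,
            "se": self.se,
            "or": round(self.odds_ratio, 2),
            "or_ci_low": round(lo, 2),
            "or_ci_high": round(hi, 2),
            "pval": float(f"{self.pval:.3g}"),
            "Q": self.Q,
            "phi": self.phi,
            "scale": self.exposure_scale,
        }


@dataclass(frozen=True)
class ThresholdPlan:
    """Family-wise Bonferroni plan: alpha_per_test = alpha_family / n_tests."""

    n_tests: int
    alpha_family: float = 0.05

    @property
    def alpha_per_test(self) -> float:
        return self.alpha_family / self.n_tests

    @property
    def z_cutoff(self) -> float:
        return float(stats.norm.isf(self.alpha_per_test / 2.0))

    def significant(self, pval: float) -> bool:
        return pval < self.alpha_per_test


def bonferroni(n_tests: int, alpha_family: float = 0.05) -> ThresholdPlan:
    if n_tests < 1:
        raise MRError("n_tests must be >= 1")
    return ThresholdPlan(n_tests=n_tests, alpha_family=alpha_family)


def _pval(theta: float, se: float) -> float:
    if se == 0:
        return 0.0 if theta != 0 else 1.0
    return float(2.0 * stats.norm.sf(abs(theta) / se))


def wald_ratio(pair: HarmonizedPair, **ids) -> MREstimate:
    """Single-instrument ratio estimate with first-order delta-method SE."""
    if pair.excluded:
        raise MRError(f"pair {pair.variant_id} was excluded: {pair.action}")
    if pair.beta_exposure == 0:
        raise MRError(f"{pair.variant_id}: Wald ratio undefined for beta_exposure = 0")
    theta = pair.beta_outcome / pair.beta_exposure
    se = pair.se_outcome / abs(pair.beta_exposure)
    return MREstimate(
        theta=theta, se=se, pval=_pval(theta, se),
        method="wald", n_variants=1, Q=0.0, phi=1.0, **ids,
    )


def ivw(pairs: list[HarmonizedPair], **ids) -> MREstimate:
    """Random-effects inverse-variance weighted estimate.

    Equivalent to no-intercept weighted least squares of beta_outcome on
    beta_exposure with weights 1/se_outcome^2. The SE is inflated by
    sqrt(phi) with phi = max(1, Q / (J - 1)) (multiplicative random effects,
    never shrinking below the fixed-effect SE). A single pair reduces exactly
    to the Wald ratio.
    """
    pairs = [p for p in pairs if not p.excluded]
    if not pairs:
        raise MRError("ivw requires at least one non-excluded pair")
    if len(pairs) == 1:
        est = wald_ratio(pairs[0], **ids)
        return replace(est, method="ivw")
    bx = np.array([p.beta_exposure for p in pairs])
    by = np.array([p.beta_outcome for p in pairs])
    sy = np.array([p.se_outcome for p in pairs])
    if np.all(bx == 0):
        raise MRError("all exposure betas are zero")
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    theta = float(np.sum(w * bx * by)) / denom
    base_se = math.sqrt(1.0 / denom)
    q = float(np.sum(w * (by - theta * bx) ** 2))
    phi = max(1.0, q / (len(pairs) - 1))
    se = base_se * math.sqrt(phi)
    return MREstimate(
        theta=theta, se=se, pval=_pval(theta, se),
        method="ivw", n_variants=len(pairs), Q=q, phi=phi, **ids,
    )


def mvmr(
    exposure_betas: np.ndarray,
    beta_outcome: np.ndarray,
    se_outcome: np.ndarray,
    exposure_ids: list[str] | None = None,
    outcome_id: str = "",
) -> list[MREstimate]:
    """Multivariable MR: joint no-intercept WLS of outcome on K exposures.

    ``exposure_betas`` is (J variants, K exposures). Each exposure's direct
    effect is estimated conditional on the others; SEs come from the weighted
    information matrix, inflated by phi = max(1, Q / (J - K)).
    """
    X = np.asarray(exposure_betas, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(beta_outcome, dtype=float)
    s = np.asarray(se_outcome, dtype=float)
    J, K = X.shape
    if J < K:
        raise MRError(f"need at least K={K} variants, got J={J}")
    if np.linalg.matrix_rank(X) < K:
        corr = np.corrcoef(X, rowvar=False)
        pairs = [
            (i, j)
            for i in range(K)
            for j in range(i + 1, K)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        names = exposure_ids or [f"exposure_{k}" for k in range(K)]
        detail = ", ".join(f"{names[i]}~{names[j]}" for i, j in pairs) or "unknown pair"
        raise MRError(f"exposure matrix is rank deficient (collinear: {detail})")
    w = 1.0 / s**2
    XtW = X.T * w
    info = XtW @ X
    theta = np.linalg.solve(info, XtW @ y)
    cov = np.linalg.inv(info)
    resid = y - X @ theta
    q = float(np.sum(w * resid**2))
    phi = max(1.0, q / (J - K)) if J > K else 1.0
    ses = np.sqrt(np.diag(cov) * phi)
    names = exposure_ids or [f"exposure_{k}" for k in range(K)]
    return [
        MREstimate(
            theta=float(theta[k]), se=float(ses[k]),
            pval=_pval(float(theta[k]), float(ses[k])),
            method="mvmr", n_variants=J, Q=q, phi=phi,
            exposure_id=names[k], outcome_id=outcome_id,
        )
        for k in range(K)
    ]


def rescale_per_doubling(estimate: MREstimate, liability_beta: float) -> MREstimate:
    """Re-express a liability-instrumented estimate per doubling of liability odds.

    The Wald ratio with the liability log-odds as denominator gives the outcome
    effect per unit log-odds of liability; multiplying by ln 2 converts the
    unit to one doubling of liability odds:
    theta_per_doubling = (beta_outcome / beta_liability) * ln 2. Applied to an
    existing per-allele-denominated estimate this is a scale change by
    ln 2 / |beta_liability| on both theta and se.
    """
    if liability_beta == 0:
        raise MRError("liability beta of zero cannot define a doubling scale")
    factor = math.log(2.0) / abs(liability_beta)
    # the sign of the liability effect carries into the ratio's denominator
    sign = 1.0 if liability_beta > 0 else -1.0
    theta = estimate.theta * factor * sign
    se = estimate.se * factor
    return replace(
        estimate,
        theta=theta,
        se=se,
        pval=_pval(theta, se),
        exposure_scale="per_doubling_liability",
    )
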