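"""Regional statistical inference: colocalization, conditional analysis, and
single-signal fine-mapping.

These are the tools used to disambiguate causal genes when two neighbouring
genes (the F11/KLKB1 situation) produce overlapping regional associations:

* pairwise Bayesian colocalization by enumeration over single-causal-variant
  configurations, scored with Wakefield approximate Bayes factors (hypotheses
  H0 no association, H1/H2 one trait only, H3 two distinct causal variants,
  H4 one shared causal variant);
* approximate conditional analysis on z-scores under LD (condition the
  regional associations on an index variant and test for residual signal);
* fine-mapping under the single-causal-variant assumption, yielding posterior
  inclusion probabilities and a minimal credible set, plus a stepwise
  conditional signal counter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .sumstats import GeneRegion, LDMatrix, SummaryStatSet

DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)  # p1, p2, p12
PRIOR_SD_QUANTITATIVE = 0.15
PRIOR_SD_BINARY = 0.20


class RegionalError(ValueError):
    pass


@dataclass
class RegionalDataset:
    """>=2 traits restricted to one region on a shared, ordered variant list."""

    region: GeneRegion
    traits: list[SummaryStatSet]
    ld: LDMatrix

    def __post_init__(self) -> None:
        if len(self.traits) < 2:
            raise RegionalError("RegionalDataset needs at least 2 traits")
        ref = self.ld.variant_ids
        for t in self.traits:
            if t.variant_ids() != ref:
                raise RegionalError(
                    f"trait {t.trait_id} variant order does not match LD matrix"
                )
            for r in t.records:
                if not np.isfinite(r.beta):
                    raise RegionalError(f"missing beta for {r.variant_id}")

    @property
    def variant_ids(self) -> list[str]:
        return self.ld.variant_ids

    def trait(self, trait_id: str) -> SummaryStatSet:
        for t in self.traits:
            if t.trait_id == trait_id:
                return t
        raise KeyError(f"trait {trait_id!r} not in regional dataset")

    def z(self, trait_id: str) -> np.ndarray:
        return np.array([r.z for r in self.trait(trait_id).records])

    def se(self, trait_id: str) -> np.ndarray:
        return np.array([r.se for r in self.trait(trait_id).records])


def build_regional_dataset(
    region: GeneRegion, traits: list[SummaryStatSet], ld: LDMatrix
) -> RegionalDataset:
    """Align traits and LD onto their shared variant list (order from the LD)."""
    shared = [v for v in ld.variant_ids if all(t.get(v) is not None for t in traits)]
    if not shared:
        raise RegionalError("no variants shared across all traits and LD matrix")
    aligned = [
        t.with_records([t.get(v) for v in shared]) for t in traits
    ]
    return RegionalDataset(region=region, traits=aligned, ld=ld.subset(shared))


@dataclass(frozen=True)
class ColocResult:
    """Posterior over the five colocalization hypotheses."""

    pp: dict[str, float]  # keys H0..H4
    priors: tuple[float, float, float]
    prior_sd: tuple[float, float]
    trait_ids: tuple[str, str]
    n_variants: int = 0

    @property
    def pp_h4(self) -> float:
        return self.pp["H4"]


@dataclass(frozen=True)
class CredibleSet:
    """Minimal credible set under descending-PIP greedy ordering."""

    variant_ids: tuple[str, ...]
    pip: dict[str, float]
    cumulative_mass: float
    coverage: float = 0.95


def log_abf(z: float | np.ndarray, se: float | np.ndarray, prior_sd: float) -> np.ndarray:
    """Wakefield log approximate Bayes factor for association vs the null.

    With V = se^2 (sampling variance of the estimate), W = prior_sd^2 (prior
    effect variance) and shrinkage r = W / (V + W):
    log ABF = 0.5 log(1 - r) + r z^2 / 2.
    """
    z = np.asarray(z, dtype=float)
    V = np.asarray(se, dtype=float) ** 2
    if np.any(V <= 0) or prior_sd <= 0:
        raise RegionalError("se and prior_sd must be positive")
    W = prior_sd**2
    r = W / (V + W)
    return 0.5 * np.log1p(-r) + r * z**2 / 2.0


def coloc_pair(
    data: RegionalDataset,
    trait1: str | None = None,
    trait2: str | None = None,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
    prior_sd: tuple[float, float] | None = None,
) -> ColocResult:
    """Pairwise enumeration colocalization over single-causal configurations.

    Per-variant Wakefield log ABFs are combined into hypothesis sums
    (log-sum-exp throughout):
    H1 = p1 sum_j BF1_j; H2 = p2 sum_j BF2_j;
    H3 = p1 p2 sum_{j != k} BF1_j BF2_k; H4 = p12 sum_j BF1_j BF2_j; H0 = 1.
    More than two traits must be handled by repeated pairwise calls.
    """
    ids = [t.trait_id for t in data.traits]
    if trait1 is None and trait2 is None and len(ids) == 2:
        trait1, trait2 = ids
    if trait1 is None or trait2 is None:
        raise RegionalError(
            "more than 2 traits present: name the pair explicitly "
            "(repeat pairwise calls for multi-trait questions)"
        )
    t1, t2 = data.trait(trait1), data.trait(trait2)
    if prior_sd is None:
        prior_sd = (
            PRIOR_SD_BINARY if t1.trait_type == "binary" else PRIOR_SD_QUANTITATIVE,
            PRIOR_SD_BINARY if t2.trait_type == "binary" else PRIOR_SD_QUANTITATIVE,
        )
    p1, p2, p12 = priors
    lbf1 = log_abf(data.z(trait1), data.se(trait1), prior_sd[0])
    lbf2 = log_abf(data.z(trait2), data.se(trait2), prior_sd[1])

    l1 = logsumexp(lbf1)
    l2 = logsumexp(lbf2)
    l12 = logsumexp(lbf1 + lbf2)
    # sum_{j != k} BF1_j BF2_k = (sum_j BF1_j)(sum_k BF2_k) - sum_j BF1_j BF2_j
    # computed stably on the log scale
    lsum_cross = l1 + l2
    if lsum_cross > l12:
        l3_sum = lsum_cross + np.log1p(-np.exp(l12 - lsum_cross))
    else:  # m = 1: no off-diagonal terms
        l3_sum = -np.inf
    log_h = np.array(
        [
            0.0,
            np.log(p1) + l1,
            np.log(p2) + l2,
            np.log(p1) + np.log(p2) + l3_sum,
            np.log(p12) + l12,
        ]
    )
    pp = np.exp(log_h - logsumexp(log_h))
    pp /= pp.sum()
    return ColocResult(
        pp={f"H{i}": float(v) for i, v in enumerate(pp)},
        priors=priors,
        prior_sd=tuple(prior_sd),
        trait_ids=(trait1, trait2),
        n_variants=len(data.variant_ids),
    )


def conditional_z_scores(
    z: np.ndarray, r_index: np.ndarray, index: int
) -> np.ndarray:
    """Condition marginal z-scores on one index variant under standardized LD.

    z_cond_j = (z_j - r_j,index z_index) / sqrt(1 - r_j,index^2); the index
    variant's own conditional z is 0. Variants in perfect LD with the index
    (|r| = 1) are inestimable and returned as NaN.
    """
    z = np.asarray(z, dtype=float)
    r = np.asarray(r_index, dtype=float)
    out = np.full_like(z, np.nan)
    ok = np.abs(r) < 1.0 - 1e-12
    out[ok] = (z[ok] - r[ok] * z[index]) / np.sqrt(1.0 - r[ok] ** 2)
    out[index] = 0.0
    return out


def conditional_z(
    data: RegionalDataset, trait: str, index_variant: str
) -> pd.DataFrame:
    """Per-variant conditional z-scores and p-values after conditioning.

    Returns a frame (variant_id, z_marginal, z_conditional, pval_conditional,
    estimable); inestimable variants (r^2 = 1 with the index) are flagged and
    excluded from any residual-significance test.
    """
    idx = data.ld.index_of(index_variant)
    z = data.z(trait)
    zc = conditional_z_scores(z, data.ld.r[:, idx], idx)
    estimable = np.isfinite(zc)
    pc = np.where(estimable, 2.0 * stats.norm.sf(np.abs(zc)), np.nan)
    return pd.DataFrame(
        {
            "variant_id": data.variant_ids,
            "z_marginal": z,
            "z_conditional": zc,
            "pval_conditional": pc,
            "estimable": estimable,
        }
    )


def finemap_single(
    data: RegionalDataset,
    trait: str,
    prior_sd: float | None = None,
    coverage: float = 0.95,
) -> CredibleSet:
    """Single-causal-variant fine-mapping with a uniform prior over variants.

    PIP_j = BF_j / sum_k BF_k; the credible set is the smallest prefix of the
    descending-PIP ordering (ties broken by position) reaching the coverage.
    """
    t = data.trait(trait)
    if prior_sd is None:
        prior_sd = PRIOR_SD_BINARY if t.trait_type == "binary" else PRIOR_SD_QUANTITATIVE
    lbf = log_abf(data.z(trait), data.se(trait), prior_sd)
    pip = np.exp(lbf - logsumexp(lbf))
    pip /= pip.sum()
    pos = np.array([r.pos for r in t.records])
    order = np.lexsort((pos, -pip))
    mass = 0.0
    chosen: list[int] = []
    for j in order:
        chosen.append(int(j))
        mass += float(pip[j])
        if mass >= coverage:
            break
    return CredibleSet(
        variant_ids=tuple(data.variant_ids[j] for j in chosen),
        pip={v: float(p) for v, p in zip(data.variant_ids, pip)},
        cumulative_mass=mass,
        coverage=coverage,
    )


@dataclass(frozen=True)
class SignalCount:
    n_signals: int
    index_variants: tuple[str, ...]
    stop_p: float


def count_signals(
    data: RegionalDataset,
    trait: str,
    stop_p: float | None = None,
) -> SignalCount:
    """Stepwise conditional signal counting.

    Repeatedly take the minimum-p variant; stop when it is no longer below
    ``stop_p`` (default: the regional Bonferroni 0.05/m), otherwise record it
    as a signal and replace the z vector by its conditional counterpart.
    """
    m = len(data.variant_ids)
    if stop_p is None:
        stop_p = 0.05 / m
    if not 0.0 < stop_p < 1.0:
        raise RegionalError("stop_p must be in (0, 1)")
    z = data.z(trait)
    R = data.ld.r
    active = np.ones(m, dtype=bool)
    signals: list[str] = []
    for _ in range(m):
        absz = np.where(active & np.isfinite(z), np.abs(z), -np.inf)
        j = int(np.argmax(absz))
        if not np.isfinite(absz[j]):
            break
        p = 2.0 * stats.norm.sf(absz[j])
        if p >= stop_p:
            break
        signals.append(data.variant_ids[j])
        z = conditional_z_scores(z, R[:, j], j)
        active[j] = False
        active &= np.isfinite(z)
    return SignalCount(
        n_signals=len(signals), index_variants=tuple(signals), stop_p=stop_p
    )


def regional_plot_table(
    data: RegionalDataset, trait: str, lead_variant: str | None = None
) -> pd.DataFrame:
    """(pos, -log10 p, r^2 to lead) table for external regional plotting."""
    t = data.trait(trait)
    z = data.z(trait)
    if lead_variant is None:
        lead_variant = data.variant_ids[int(np.argmax(np.abs(z)))]
    i = data.ld.index_of(lead_variant)
    logp = -stats.norm.logsf(np.abs(z)) / np.log(10) - np.log10(2.0)
    return pd.DataFrame(
        {
            "variant_id": data.variant_ids,
            "pos": [r.pos for r in t.records],
            "neg_log10_p": logp,
            "r2_to_lead": data.ld.r[:, i] ** 2,
            "is_lead": [v == lead_variant for v in data.variant_ids],
        }
    )
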