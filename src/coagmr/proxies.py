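"""Instrument (genetic proxy) selection for each protein.

The cascade mirrors standard cis-MR practice for plasma proteins: restrict to
variants inside the gene body (cis), keep genome-wide significant associations
(p < 5e-8), apply a minor-allele-frequency floor (0.01), intersect with the
outcome GWAS variant list, optionally require nominal support from the
disease-liability (VTE) GWAS (p < 0.05, with a disable switch for the
sensitivity analysis), and finally clump to approximate LD independence
(r^2 < 0.001) by greedy p-value ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sumstats import GeneRegion, LDMatrix, SummaryStatSet, subset_region


class ProxySelectionError(ValueError):
    pass


@dataclass
class SelectionParams:
    p_threshold: float = 5e-8
    maf_floor: float = 0.01
    liability_alpha: float = 0.05
    use_liability_filter: bool = True
    clump_r2: float = 0.001


@dataclass
class ProxySet:
    """Clumped instruments for one protein from one source data set."""

    protein_id: str
    source: str  # pqtl_cohortA | pqtl_cohortB | liability
    exposure: SummaryStatSet
    liability: SummaryStatSet | None = None
    clump_r2: float = 0.001
    filters_applied: list[dict] = field(default_factory=list)

    @property
    def variant_ids(self) -> list[str]:
        return self.exposure.variant_ids()

    @property
    def n_variants(self) -> int:
        return len(self.exposure)

    @property
    def no_proxy(self) -> bool:
        return self.n_variants == 0

    def audit_trail(self) -> list[dict]:
        return list(self.filters_applied)


def _log_filter(
    trail: list[dict] | None, name: str, n_in: int, n_out: int, **extra
) -> None:
    if trail is not None:
        trail.append({"filter": name, "n_in": n_in, "n_out": n_out, **extra})


def filter_significance(
    ss: SummaryStatSet, threshold: float = 5e-8, trail: list[dict] | None = None
) -> SummaryStatSet:
    """Retain records with pval < threshold (genome-wide significance)."""
    if not 0.0 < threshold <= 1.0:
        raise ProxySelectionError(f"threshold must be in (0, 1], got {threshold}")
    out = ss.with_records(r for r in ss.records if r.pval < threshold)
    _log_filter(trail, "significance", len(ss), len(out), threshold=threshold)
    return out


def filter_maf(
    ss: SummaryStatSet, floor: float = 0.01, trail: list[dict] | None = None
) -> SummaryStatSet:
    """Retain records with min(eaf, 1-eaf) >= floor; missing eaf is excluded."""
    if not 0.0 <= floor <= 0.5:
        raise ProxySelectionError(f"MAF floor must be in [0, 0.5], got {floor}")
    kept = []
    n_missing = 0
    for r in ss.records:
        maf = r.maf
        if maf is None:
            n_missing += 1
            continue
        if maf >= floor:
            kept.append(r)
    out = ss.with_records(kept)
    _log_filter(
        trail, "maf_floor", len(ss), len(out), floor=floor, missing_eaf=n_missing
    )
    return out


def intersect_variants(
    ss: SummaryStatSet, other: SummaryStatSet, trail: list[dict] | None = None
) -> SummaryStatSet:
    """Keep exposure records whose variant is measured in the other data set."""
    present = set(other.variant_ids())
    out = ss.with_records(r for r in ss.records if r.variant_id in present)
    _log_filter(trail, "outcome_intersection", len(ss), len(out))
    return out


def filter_liability_support(
    exposure_ss: SummaryStatSet,
    liability_ss: SummaryStatSet,
    alpha: float = 0.05,
    enabled: bool = True,
    trail: list[dict] | None = None,
) -> SummaryStatSet:
    """Require nominal liability (VTE) association, p < alpha.

    Only a p-value condition is imposed; directional concordance between the
    exposure and liability effects is not required. ``enabled=False``
    reproduces the sensitivity analysis that omits this step.
    """
    if enabled and not 0.0 < alpha < 1.0:
        raise ProxySelectionError(f"alpha must be in (0, 1), got {alpha}")
    if not enabled:
        _log_filter(
            trail, "liability_support", len(exposure_ss), len(exposure_ss),
            enabled=False,
        )
        return exposure_ss.with_records(exposure_ss.records)
    idx = {r.variant_id: r for r in liability_ss.records}
    kept, n_absent = [], 0
    for r in exposure_ss.records:
        lia = idx.get(r.variant_id)
        if lia is None:
            n_absent += 1
            continue
        if lia.pval < alpha:
            kept.append(r)
    out = exposure_ss.with_records(kept)
    _log_filter(
        trail, "liability_support", len(exposure_ss), len(out),
        alpha=alpha, absent_from_liability=n_absent,
    )
    return out


def clump(
    ss: SummaryStatSet,
    ld: LDMatrix,
    r2_max: float = 0.001,
    protein_id: str = "",
    source: str = "",
    trail: list[dict] | None = None,
) -> ProxySet:
    """Greedy p-value clumping to approximate LD independence.

    Candidates are ordered by ascending p-value (ties by ascending position,
    then variant id); the best remaining becomes an index variant, and every
    remaining candidate with r^2 >= r2_max against it is discarded. r^2 is the
    square of the signed allelic correlation in the LD matrix.
    """
    missing = [v for v in ss.variant_ids() if v not in ld.variant_ids]
    if missing:
        raise ProxySelectionError(
            f"variant(s) missing from LD matrix: {missing}"
        )
    remaining = sorted(
        ss.records, key=lambda r: (r.pval, r.pos, r.variant_id)
    )
    kept = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        i = ld.index_of(index.variant_id)
        remaining = [
            r
            for r in remaining
            if ld.r[i, ld.index_of(r.variant_id)] ** 2 < r2_max
        ]
    # restore input record order for determinism independent of p ranking
    order = {v: k for k, v in enumerate(ss.variant_ids())}
    kept.sort(key=lambda r: order[r.variant_id])
    out = ss.with_records(kept)
    _log_filter(trail, "clump", len(ss), len(out), r2_max=r2_max)
    return ProxySet(
        protein_id=protein_id,
        source=source,
        exposure=out,
        clump_r2=r2_max,
        filters_applied=list(trail) if trail is not None else [],
    )


def select_proxies(
    protein_id: str,
    sources: dict[str, SummaryStatSet],
    liability_ss: SummaryStatSet,
    outcome_ss: SummaryStatSet,
    region: GeneRegion,
    ld: LDMatrix,
    params: SelectionParams | None = None,
) -> list[ProxySet]:
    """Run the full selection cascade for one protein, once per source.

    Order: cis subset -> genome-wide significance -> MAF floor -> intersection
    with the outcome variant list -> liability support -> clumping. Each
    ProxySet carries an audit trail of per-stage counts; an empty final set is
    returned flagged rather than raised (gene regions without a usable proxy
    are an expected outcome).

    For the liability source itself the liability-support filter is redundant
    (significance at 5e-8 implies nominal support) but harmless, and clumping
    ranks by the p-value of the defining data set.
    """
    params = params or SelectionParams()
    out: list[ProxySet] = []
    for source, ss in sources.items():
        trail: list[dict] = []
        stage = subset_region(ss, region)
        _log_filter(trail, "cis_subset", len(ss), len(stage), region=region.gene_symbol)
        stage = filter_significance(stage, params.p_threshold, trail)
        stage = filter_maf(stage, params.maf_floor, trail)
        stage = intersect_variants(stage, outcome_ss, trail)
        stage = filter_liability_support(
            stage, liability_ss, params.liability_alpha,
            enabled=params.use_liability_filter, trail=trail,
        )
        ps = clump(
            stage, ld, params.clump_r2,
            protein_id=protein_id, source=source, trail=trail,
        )
        if params.use_liability_filter:
            lia_idx = {r.variant_id: r for r in liability_ss.records}
            ps.liability = liability_ss.with_records(
                lia_idx[v] for v in ps.variant_ids if v in lia_idx
            )
        out.append(ps)
    return out
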