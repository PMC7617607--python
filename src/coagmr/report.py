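"""Cross-trait contextualization and final target prioritization.

Builds the proxy-by-protein association library (with a family-wide
Bonferroni mask over every cell actually tested), the venous-vs-arterial
z-score comparison, and the final verdict combining MR significance with
colocalization support. ``run_pipeline`` orchestrates the full analysis over
a fixture bundle or an in-memory simulation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .harmonize import harmonize_sets, retained
from . import mr as mr_mod
from .mr import MREstimate, ThresholdPlan, bonferroni
from .proxies import ProxySet, SelectionParams, select_proxies
from .regional import (
    ColocResult,
    build_regional_dataset,
    coloc_pair,
)
from .simulate import SimulationConfig, simulate_sumstats
from .sumstats import (
    GeneRegion,
    LDMatrix,
    SummaryStatSet,
    read_gene_bed,
    read_ld,
    read_sumstats,
    subset_region,
)


class ReportError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Cross-trait association library


@dataclass
class CrossTraitMatrix:
    """Proxy-variant x protein-trait association look-up table.

    ``beta``/``se``/``pval`` are aligned DataFrames (rows: variants, columns:
    protein traits); missing measurements are NaN and excluded from the
    Bonferroni family size ``n_tests``.
    """

    beta: pd.DataFrame
    se: pd.DataFrame
    pval: pd.DataFrame
    plan: ThresholdPlan

    @property
    def n_tests(self) -> int:
        return self.plan.n_tests

    @property
    def mask(self) -> pd.DataFrame:
        return self.pval < self.plan.alpha_per_test


def build_cross_trait(
    proxies: list[ProxySet], protein_sets: list[SummaryStatSet]
) -> CrossTraitMatrix:
    """Look up every selected proxy in every protein GWAS.

    ``n_tests`` counts the cells with an available measurement (unique
    variants x protein traits, minus gaps), and the significance mask applies
    0.05 / n_tests.
    """
    variant_ids: list[str] = []
    for ps in proxies:
        for v in ps.variant_ids:
            if v not in variant_ids:
                variant_ids.append(v)
    cols = [ss.trait_id for ss in protein_sets]
    beta = pd.DataFrame(np.nan, index=variant_ids, columns=cols)
    se = pd.DataFrame(np.nan, index=variant_ids, columns=cols)
    pval = pd.DataFrame(np.nan, index=variant_ids, columns=cols)
    for ss in protein_sets:
        idx = {r.variant_id: r for r in ss.records}
        for v in variant_ids:
            rec = idx.get(v)
            if rec is not None:
                beta.loc[v, ss.trait_id] = rec.beta
                se.loc[v, ss.trait_id] = rec.se
                pval.loc[v, ss.trait_id] = rec.pval
    n_tests = int(pval.notna().to_numpy().sum())
    plan = bonferroni(max(n_tests, 1))
    return CrossTraitMatrix(beta=beta, se=se, pval=pval, plan=plan)


# ---------------------------------------------------------------------------
# VTE-vs-outcome z-score comparison


@dataclass
class ZComparison:
    """Per-proxy z-scores for the liability (VTE) and outcome traits."""

    table: pd.DataFrame  # variant_id, protein, z_vte, z_outcome, category
    cutoff: float
    alpha: float


def compare_z(
    proxies: list[ProxySet],
    vte_ss: SummaryStatSet,
    outcome_ss: SummaryStatSet,
    alpha: float = 0.0017,
) -> ZComparison:
    """z_outcome against z_vte per proxy, classified against the MR cutoff.

    The cutoff is the two-sided normal quantile at alpha (3.15 for 0.0017);
    each proxy falls into both / vte_only / outcome_only / neither by |z|.
    Variants missing from either GWAS are dropped.
    """
    from scipy import stats

    cutoff = float(stats.norm.isf(alpha / 2.0))
    rows = []
    for ps in proxies:
        for v in ps.variant_ids:
            a, b = vte_ss.get(v), outcome_ss.get(v)
            if a is None or b is None:
                continue
            zv, zo = a.z, b.z
            sig_v, sig_o = abs(zv) >= cutoff, abs(zo) >= cutoff
            category = (
                "both" if sig_v and sig_o
                else "vte_only" if sig_v
                else "outcome_only" if sig_o
                else "neither"
            )
            rows.append(
                {
                    "variant_id": v,
                    "protein": ps.protein_id,
                    "source": ps.source,
                    "z_vte": zv,
                    "z_outcome": zo,
                    "category": category,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["variant_id", "protein", "source", "z_vte", "z_outcome", "category"],
    )
    return ZComparison(table=table, cutoff=cutoff, alpha=alpha)


# ---------------------------------------------------------------------------
# Prioritization


@dataclass
class PrioritizationRecord:
    protein: str
    source: str
    outcome: str
    mr: MREstimate
    coloc: ColocResult | None
    verdict: str  # prioritized | not_prioritized | incomplete
    pp_min: float
    alpha: float

    def row(self) -> dict:
        d = self.mr.summary_row()
        d.update(
            protein=self.protein,
            source=self.source,
            outcome=self.outcome,
            pp_h4=self.coloc.pp_h4 if self.coloc else np.nan,
            verdict=self.verdict,
        )
        return d


def prioritize(
    mr_results: list[tuple[str, str, str, MREstimate]],
    coloc_results: dict[tuple[str, str], ColocResult],
    plan: ThresholdPlan,
    pp_min: float = 0.7,
) -> list[PrioritizationRecord]:
    """Conjunction verdict: MR p below the family threshold AND PP(H4) >= pp_min.

    ``mr_results`` rows are (protein, source, outcome, estimate); coloc keys
    are (protein, outcome). Proteins lacking a coloc result are 'incomplete',
    never 'prioritized'. Output is sorted by verdict class then MR p-value.
    """
    records = []
    for protein, source, outcome, est in mr_results:
        coloc = coloc_results.get((protein, outcome))
        if coloc is None:
            verdict = "incomplete"
        elif plan.significant(est.pval) and coloc.pp_h4 >= pp_min:
            verdict = "prioritized"
        else:
            verdict = "not_prioritized"
        records.append(
            PrioritizationRecord(
                protein=protein, source=source, outcome=outcome,
                mr=est, coloc=coloc, verdict=verdict,
                pp_min=pp_min, alpha=plan.alpha_per_test,
            )
        )
    order = {"prioritized": 0, "not_prioritized": 1, "incomplete": 2}
    records.sort(key=lambda r: (order[r.verdict], r.mr.pval))
    return records


# ---------------------------------------------------------------------------
# Pipeline orchestration


@dataclass
class PipelineConfig:
    """Thresholds for the end-to-end run (defaults follow the analysis plan)."""

    p_threshold: float = 5e-8
    maf_floor: float = 0.01
    liability_alpha: float = 0.05
    use_liability_filter: bool = True
    clump_r2: float = 0.001
    maf_ambiguity: float = 0.42
    pp_min: float = 0.7
    coloc_priors: tuple[float, float, float] = (1e-4, 1e-4, 1e-5)
    liability_trait: str = "vte"
    primary_outcome: str = "stroke"


@dataclass
class DataBundle:
    """In-memory analysis inputs: trait sets, LD per region, gene annotation."""

    trait_sets: dict[str, SummaryStatSet]
    ld: dict[str, LDMatrix]
    regions: dict[str, GeneRegion]
    proteins: dict[str, dict]  # protein_id -> {region, cohorts: [labels]}

    @classmethod
    def from_simulation(cls, config: SimulationConfig) -> tuple["DataBundle", dict]:
        sets, truth, ld, gene_regions = simulate_sumstats(config)
        proteins = {
            p.protein_id: {"region": p.region, "cohorts": list(p.cohorts)}
            for p in config.proteins
        }
        return (
            cls(
                trait_sets={s.trait_id: s for s in sets},
                ld=ld,
                regions={g.gene_symbol: g for g in gene_regions},
                proteins=proteins,
            ),
            truth.to_dict(),
        )

    @classmethod
    def from_fixture(cls, bundle_dir: str | Path) -> "DataBundle":
        bundle_dir = Path(bundle_dir)
        with open(bundle_dir / "config.yaml") as fh:
            config = SimulationConfig.from_dict(yaml.safe_load(fh))
        regions = {g.gene_symbol: g for g in read_gene_bed(bundle_dir / "genes.bed")}
        ld = {
            p.stem.replace(".ld", ""): read_ld(p)
            for p in sorted((bundle_dir / "ld").glob("*.ld.txt"))
        }
        trait_sets = {}
        binary_ids = {o.trait_id for o in config.outcomes}
        for p in sorted((bundle_dir / "sumstats").glob("*.tsv")):
            tid = p.stem
            ttype = "binary" if tid in binary_ids else "quantitative"
            cohort = tid.rsplit("_", 1)[-1] if ttype == "quantitative" else tid
            ss, rejected = read_sumstats(p, tid, ttype, cohort)
            if len(rejected):
                raise ReportError(
                    f"{p}: {len(rejected)} record(s) failed validation"
                )
            trait_sets[tid] = ss
        proteins = {
            sp.protein_id: {"region": sp.region, "cohorts": list(sp.cohorts)}
            for sp in config.proteins
        }
        return cls(trait_sets=trait_sets, ld=ld, regions=regions, proteins=proteins)


@dataclass
class PipelineResult:
    proxies: list[ProxySet]
    mr_table: pd.DataFrame
    records: list[PrioritizationRecord]
    coloc: dict[tuple[str, str], ColocResult]
    plan: ThresholdPlan
    zcomp: ZComparison
    cross_trait: CrossTraitMatrix
    log: dict = field(default_factory=dict)

    def prioritized_proteins(self) -> list[str]:
        return sorted(
            {r.protein for r in self.records if r.verdict == "prioritized"}
        )


def _source_label(cohort: str) -> str:
    return f"pqtl_{cohort}"


def run_pipeline(
    bundle: DataBundle,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Execute the full analysis: proxy selection -> harmonization -> MR ->
    colocalization -> cross-trait library -> prioritization.

    One MR estimate is produced per protein x source x outcome (sources with
    no surviving proxy are recorded as such); colocalization runs per protein
    region against each binary outcome using the first available pQTL cohort;
    the final verdict combines the best-powered pQTL source per protein with
    the regional colocalization posterior for the primary outcome.
    """
    cfg = config or PipelineConfig()
    liability = bundle.trait_sets[cfg.liability_trait]
    # sorted so the output ordering does not depend on input enumeration order
    outcomes = {
        tid: bundle.trait_sets[tid]
        for tid in sorted(bundle.trait_sets)
        if bundle.trait_sets[tid].trait_type == "binary"
    }
    primary = outcomes[cfg.primary_outcome]
    params = SelectionParams(
        p_threshold=cfg.p_threshold,
        maf_floor=cfg.maf_floor,
        liability_alpha=cfg.liability_alpha,
        use_liability_filter=cfg.use_liability_filter,
        clump_r2=cfg.clump_r2,
    )

    all_proxies: list[ProxySet] = []
    mr_rows: list[dict] = []
    mr_results: list[tuple[str, str, str, MREstimate]] = []
    for protein_id, meta in bundle.proteins.items():
        region = bundle.regions[meta["region"]]
        ld = bundle.ld[meta["region"]]
        sources = {
            _source_label(c): bundle.trait_sets[f"{protein_id}_{c}"]
            for c in meta["cohorts"]
        }
        sources["liability"] = liability
        proxy_sets = select_proxies(
            protein_id, sources, liability, primary, region, ld, params
        )
        all_proxies.extend(proxy_sets)
        for ps in proxy_sets:
            if ps.no_proxy:
                mr_rows.append(
                    {
                        "protein": protein_id,
                        "source": ps.source,
                        "outcome": "",
                        "n_variants": 0,
                        "note": "no proxy",
                    }
                )
                continue
            for out_id, out_ss in outcomes.items():
                if ps.source == "liability" and out_id == cfg.liability_trait:
                    continue  # the defining data set is not an outcome for itself
                pairs = retained(
                    harmonize_sets(
                        ps.exposure.records,
                        {r.variant_id: r for r in out_ss.records},
                        cfg.maf_ambiguity,
                    )
                )
                if not pairs:
                    continue
                est = mr_mod.ivw(
                    pairs, exposure_id=protein_id, outcome_id=out_id
                )
                if ps.source == "liability":
                    # the IVW exposure here is the liability log-odds, so
                    # theta is already a ratio over beta_VTE; multiplying by
                    # ln 2 expresses it per doubling of liability odds
                    ln2 = float(np.log(2.0))
                    est = dataclasses.replace(
                        est,
                        theta=est.theta * ln2,
                        se=est.se * ln2,
                        exposure_scale="per_doubling_liability",
                    )
                mr_results.append((protein_id, ps.source, out_id, est))
                row = est.summary_row()
                row.update(protein=protein_id, source=ps.source)
                mr_rows.append(row)

    # colocalization: protein pQTL (first cohort) vs each outcome, per region
    coloc_results: dict[tuple[str, str], ColocResult] = {}
    for protein_id, meta in bundle.proteins.items():
        region = bundle.regions[meta["region"]]
        ld = bundle.ld[meta["region"]]
        pqtl = bundle.trait_sets[f"{protein_id}_{meta['cohorts'][0]}"]
        pqtl_region = subset_region(pqtl, region)
        for out_id, out_ss in outcomes.items():
            out_region = subset_region(out_ss, region)
            try:
                data = build_regional_dataset(region, [pqtl_region, out_region], ld)
            except Exception:
                continue
            coloc_results[(protein_id, out_id)] = coloc_pair(
                data, pqtl.trait_id, out_id, priors=cfg.coloc_priors
            )

    n_proteins = len(bundle.proteins)
    plan = bonferroni(max(n_proteins, 1))
    records = prioritize(
        [r for r in mr_results if r[2] == cfg.primary_outcome],
        coloc_results,
        plan,
        cfg.pp_min,
    )
    protein_sets = [
        bundle.trait_sets[f"{pid}_{c}"]
        for pid, meta in bundle.proteins.items()
        for c in meta["cohorts"]
    ]
    cross = build_cross_trait(
        [ps for ps in all_proxies if not ps.no_proxy], protein_sets
    )
    zcomp = compare_z(
        [ps for ps in all_proxies if not ps.no_proxy and ps.source != "liability"],
        liability,
        primary,
        plan.alpha_per_test,
    )
    mr_table = pd.DataFrame(mr_rows)
    return PipelineResult(
        proxies=all_proxies,
        mr_table=mr_table,
        records=records,
        coloc=coloc_results,
        plan=plan,
        zcomp=zcomp,
        cross_trait=cross,
        log={
            "n_proteins": n_proteins,
            "alpha_per_test": plan.alpha_per_test,
            "pp_min": cfg.pp_min,
            "thresholds": {
                "p_threshold": cfg.p_threshold,
                "maf_floor": cfg.maf_floor,
                "liability_alpha": cfg.liability_alpha,
                "clump_r2": cfg.clump_r2,
                "maf_ambiguity": cfg.maf_ambiguity,
            },
        },
    )


def write_report(result: PipelineResult, out_dir: str | Path) -> Path:
    """Write the TSV/JSON report bundle for a pipeline run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.mr_table.to_csv(out / "mr_estimates.tsv", sep="\t", index=False)
    pd.DataFrame([r.row() for r in result.records]).to_csv(
        out / "prioritization.tsv", sep="\t", index=False
    )
    result.zcomp.table.to_csv(out / "z_comparison.tsv", sep="\t", index=False)
    result.cross_trait.pval.to_csv(out / "cross_trait_pval.tsv", sep="\t")
    result.cross_trait.beta.to_csv(out / "cross_trait_beta.tsv", sep="\t")
    coloc = {
        f"{protein}|{outcome}": res.pp
        for (protein, outcome), res in result.coloc.items()
    }
    audit = [
        {
            "protein": ps.protein_id,
            "source": ps.source,
            "n_variants": ps.n_variants,
            "filters": ps.audit_trail(),
        }
        for ps in result.proxies
    ]
    with open(out / "report.json", "w") as fh:
        json.dump(
            {
                "log": result.log,
                "coloc": coloc,
                "proxy_audit": audit,
                "prioritized": result.prioritized_proteins(),
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return out
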