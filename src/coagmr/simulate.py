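"""Synthetic GWAS summary statistics with known causal structure.

Summary statistics are drawn directly from the standard multivariate-normal
model for z-scores under LD (the RSS likelihood): for a region with allelic
correlation matrix ``R`` and joint (multiple-regression) effects ``b``, the
vector of marginal z-scores is

    z ~ MVN(R @ eta, R),        eta_j = b_j / SE_j,

with the per-variant standard errors of marginal effect estimates

    SE_j = 1 / sqrt(2 n f_j (1 - f_j))                    (quantitative, per SD)
    SE_j = 1 / sqrt(2 n phi (1 - phi) f_j (1 - f_j))      (binary, log odds)

where ``f_j`` is the effect-allele frequency and ``phi`` the case fraction.
Marginal betas are ``z * SE`` and p-values are two-sided normal.

The generator emulates the statistical structure of the study inputs it stands
in for: a cis-pQTL architecture inside each gene body, two proteomics cohorts
(optionally with a sign-flip assay artifact for selected proteins), binary
outcomes whose genetic effects are mediated through protein levels
(``theta`` log-odds per SD of protein) plus optional direct-pleiotropy
effects, block-AR(1) LD, and optional sample overlap between cohorts.

A small individual-level generator (Gaussian-copula haplotypes, linear or
logistic trait model) is also provided; it serves as an independent oracle for
the summary-statistic conditional analysis.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import stats

from .sumstats import (
    GeneRegion,
    LDMatrix,
    SummaryStatSet,
    VariantAssociation,
    write_gene_bed,
    write_ld,
    write_sumstats,
)

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# LD


def make_ld(
    m: int,
    blocks: Sequence[int] | None = None,
    rho: float = 0.0,
    variant_ids: Sequence[str] | None = None,
) -> LDMatrix:
    """Block-diagonal AR(1) LD: within a block r_ij = rho^|i-j|, zero across.

    Positive definite for any |rho| < 1, so it doubles as a valid correlation
    matrix for drawing z-scores.
    """
    if m < 1:
        raise SimulationError("m must be >= 1")
    if not -1.0 < rho < 1.0:
        raise SimulationError(f"AR(1) decay rho must satisfy |rho| < 1, got {rho}")
    if blocks is None:
        blocks = [m]
    if sum(blocks) != m:
        raise SimulationError(f"block sizes {list(blocks)} do not sum to m={m}")
    mat = np.zeros((m, m))
    off = 0
    for b in blocks:
        idx = np.arange(b)
        mat[off : off + b, off : off + b] = rho ** np.abs(idx[:, None] - idx[None, :])
        off += b
    if variant_ids is None:
        variant_ids = [f"rs{j + 1}" for j in range(m)]
    return LDMatrix(list(variant_ids), mat)


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class RegionSpec:
    """One simulated gene region: variant grid, frequencies, and LD."""

    name: str
    m: int
    rho: float = 0.8
    blocks: list[int] | None = None
    chrom: str = "4"
    start: int = 0
    end: int = 0
    eaf_range: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self) -> None:
        if self.m < 1:
            raise SimulationError(f"{self.name}: m must be >= 1")
        if not 0.0 <= self.rho < 1.0:
            raise SimulationError(f"{self.name}: rho must be in [0, 1)")
        lo, hi = self.eaf_range
        if lo < 0.01 or hi > 0.99 or lo > hi:
            raise SimulationError(
                f"{self.name}: eaf_range must lie within [0.01, 0.99]"
            )
        if self.end <= self.start:
            # default gene body: 1 kb per variant
            self.end = self.start + max(1000 * self.m, 1000)

    def gene_region(self) -> GeneRegion:
        return GeneRegion(self.name, self.chrom, self.start, self.end)


@dataclass
class ProteinSpec:
    """A protein trait measured in one or more cohorts.

    ``causal_indices``/``causal_betas`` give the joint per-allele effects
    (lambda, in SD units of protein level) of the cis causal variants inside
    the protein's gene region.
    """

    protein_id: str
    region: str
    causal_indices: list[int] = field(default_factory=list)
    causal_betas: list[float] = field(default_factory=list)
    cohorts: list[str] = field(default_factory=lambda: ["cohortA"])
    sign_flip_cohorts: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.causal_indices) != len(self.causal_betas):
            raise SimulationError(
                f"{self.protein_id}: causal_indices and causal_betas differ in length"
            )


@dataclass
class OutcomeSpec:
    """A binary outcome (case-control GWAS on the log-odds scale).

    ``theta`` maps protein_id -> causal log-odds effect per SD of protein.
    ``pleiotropy`` maps region name -> {variant index: direct log-odds effect},
    modelling horizontal pleiotropy that bypasses the protein.
    """

    trait_id: str
    n_case: int
    n_control: int
    theta: dict[str, float] = field(default_factory=dict)
    pleiotropy: dict[str, dict[int, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_case + self.n_control <= 0:
            raise SimulationError(f"{self.trait_id}: n_case + n_control must be > 0")

    @property
    def n(self) -> int:
        return self.n_case + self.n_control

    @property
    def case_fraction(self) -> float:
        return self.n_case / self.n


@dataclass
class SimulationConfig:
    seed: int
    regions: list[RegionSpec]
    proteins: list[ProteinSpec]
    outcomes: list[OutcomeSpec]
    cohort_n: dict[str, int] = field(
        default_factory=lambda: {"cohortA": 35_000, "cohortB": 46_000}
    )
    overlap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise SimulationError("overlap_fraction must be in [0, 1]")
        names = {r.name for r in self.regions}
        for p in self.proteins:
            if p.region not in names:
                raise SimulationError(
                    f"protein {p.protein_id} references unknown region {p.region}"
                )
            for c in p.cohorts:
                if c not in self.cohort_n:
                    raise SimulationError(
                        f"protein {p.protein_id}: unknown cohort {c}"
                    )

    def to_dict(self) -> dict:
        d = asdict(self)
        for r in d["regions"]:
            r["eaf_range"] = list(r["eaf_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        regions = [
            RegionSpec(**{**r, "eaf_range": tuple(r["eaf_range"])})
            for r in d["regions"]
        ]
        proteins = [ProteinSpec(**p) for p in d["proteins"]]
        outcomes = []
        for o in d["outcomes"]:
            o = dict(o)
            o["pleiotropy"] = {
                reg: {int(k): v for k, v in eff.items()}
                for reg, eff in o.get("pleiotropy", {}).items()
            }
            outcomes.append(OutcomeSpec(**o))
        return cls(
            seed=d["seed"],
            regions=regions,
            proteins=proteins,
            outcomes=outcomes,
            cohort_n=dict(d.get("cohort_n", {"cohortA": 35_000, "cohortB": 46_000})),
            overlap_fraction=d.get("overlap_fraction", 0.0),
        )


@dataclass
class SimTruth:
    """Generative ground truth for recovery scoring; reproducible from config."""

    causal_variants: dict[str, list[str]]  # protein_id -> variant ids
    theta: dict[str, dict[str, float]]  # outcome -> protein -> theta
    marginal_noncentrality: dict[str, dict[str, list[float]]]  # region -> trait -> E[z]
    variant_ids: dict[str, list[str]]  # region -> ids
    sign_flips: dict[str, list[str]]  # protein -> cohorts with flipped assay
    pleiotropy: dict[str, dict[str, dict[str, float]]]  # outcome -> region -> vid -> b

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Core draws


def se_quantitative(n: float, f: np.ndarray) -> np.ndarray:
    """SE of a per-SD marginal effect estimate at frequency f, sample size n."""
    return 1.0 / np.sqrt(2.0 * n * f * (1.0 - f))


def se_binary(n: float, case_fraction: float, f: np.ndarray) -> np.ndarray:
    """SE of a marginal log-odds estimate (standard logistic approximation)."""
    phi = case_fraction
    return 1.0 / np.sqrt(2.0 * n * phi * (1.0 - phi) * f * (1.0 - f))


def _joint_effects(m: int, indices: Sequence[int], betas: Sequence[float]) -> np.ndarray:
    b = np.zeros(m)
    for i, v in zip(indices, betas):
        if not 0 <= i < m:
            raise SimulationError(f"causal index {i} outside region of {m} variants")
        b[i] = v
    return b


def _region_rng(seed: int, region_idx: int, stream: int) -> np.random.Generator:
    # Documented counter scheme: one child stream per (region, trait slot), so
    # adding a trait never perturbs the draws of existing traits.
    return np.random.default_rng(np.random.SeedSequence([seed, region_idx, stream]))


def simulate_sumstats(
    config: SimulationConfig,
) -> tuple[list[SummaryStatSet], SimTruth, dict[str, LDMatrix], list[GeneRegion]]:
    """Draw one complete multi-trait, multi-cohort summary-statistic bundle.

    Returns the trait sets (one per protein x cohort, plus one per outcome),
    the ground truth, per-region LD matrices, and the gene annotation.
    """
    rng_master = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    regions = {r.name: r for r in config.regions}
    gene_regions: list[GeneRegion] = []
    ld_by_region: dict[str, LDMatrix] = {}
    pos_by_region: dict[str, np.ndarray] = {}
    eaf_by_region: dict[str, np.ndarray] = {}
    alleles_by_region: dict[str, list[tuple[str, str]]] = {}

    # region scaffolding (positions, frequencies, alleles) from the master stream
    for ridx, spec in enumerate(config.regions):
        gr = spec.gene_region()
        gene_regions.append(gr)
        vids = [f"rs{spec.name}_{j + 1}" for j in range(spec.m)]
        ld_by_region[spec.name] = make_ld(spec.m, spec.blocks, spec.rho, vids)
        scaffold_rng = _region_rng(config.seed, ridx, 0)
        lo, hi = spec.eaf_range
        eaf_by_region[spec.name] = np.round(scaffold_rng.uniform(lo, hi, spec.m), 4)
        pos_by_region[spec.name] = np.sort(
            scaffold_rng.choice(
                np.arange(gr.start + 1, gr.end + 1), size=spec.m, replace=False
            )
        )
        alleles_by_region[spec.name] = [
            _ALLELE_PAIRS[int(k)]
            for k in scaffold_rng.integers(0, len(_ALLELE_PAIRS), spec.m)
        ]
    del rng_master

    # enumerate traits per region: (trait key, kind, params)
    region_traits: dict[str, list[dict]] = {r.name: [] for r in config.regions}
    for p in config.proteins:
        m = regions[p.region].m
        b_joint = _joint_effects(m, p.causal_indices, p.causal_betas)
        for c in p.cohorts:
            region_traits[p.region].append(
                {
                    "trait_id": f"{p.protein_id}_{c}",
                    "kind": "quantitative",
                    "n": config.cohort_n[c],
                    "b_joint": b_joint,
                    "flip": c in p.sign_flip_cohorts,
                    "cohort": c,
                }
            )
    for o in config.outcomes:
        for rname, spec in regions.items():
            m = spec.m
            b = np.zeros(m)
            for p in config.proteins:
                if p.region == rname and p.protein_id in o.theta:
                    b += o.theta[p.protein_id] * _joint_effects(
                        m, p.causal_indices, p.causal_betas
                    )
            for i, eff in o.pleiotropy.get(rname, {}).items():
                if not 0 <= i < m:
                    raise SimulationError(
                        f"{o.trait_id}: pleiotropy index {i} outside region {rname}"
                    )
                b[i] += eff
            region_traits[rname].append(
                {
                    "trait_id": o.trait_id,
                    "kind": "binary",
                    "n": o.n,
                    "case_fraction": o.case_fraction,
                    "b_joint": b,
                    "flip": False,
                    "cohort": o.trait_id,
                }
            )

    # draw z-scores region by region
    records_by_trait: dict[str, list[VariantAssociation]] = {}
    trait_meta: dict[str, dict] = {}
    noncentrality: dict[str, dict[str, list[float]]] = {}
    for ridx, spec in enumerate(config.regions):
        rname = spec.name
        gr = regions[rname].gene_region()
        ld = ld_by_region[rname]
        R = ld.r
        L = np.linalg.cholesky(R + 1e-12 * np.eye(spec.m))
        f = eaf_by_region[rname]
        pos = pos_by_region[rname]
        alleles = alleles_by_region[rname]
        noncentrality[rname] = {}
        shared_rng = _region_rng(config.seed, ridx, 1)
        shared_eps = shared_rng.standard_normal(spec.m)
        ov = config.overlap_fraction
        for tidx, t in enumerate(region_traits[rname]):
            if t["kind"] == "quantitative":
                se = se_quantitative(t["n"], f)
            else:
                se = se_binary(t["n"], t["case_fraction"], f)
            eta = t["b_joint"] / se
            mean_z = R @ eta
            own = _region_rng(config.seed, ridx, 2 + tidx).standard_normal(spec.m)
            eps = np.sqrt(ov) * shared_eps + np.sqrt(1.0 - ov) * own
            z = mean_z + L @ eps
            if t["flip"]:
                z = -z
                mean_z = -mean_z
            beta = z * se
            pval = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-320, 1.0)
            noncentrality[rname][t["trait_id"]] = [float(x) for x in mean_z]
            recs = records_by_trait.setdefault(t["trait_id"], [])
            trait_meta[t["trait_id"]] = {
                "trait_type": t["kind"],
                "cohort_label": t["cohort"],
            }
            for j, vid in enumerate(ld.variant_ids):
                ea, oa = alleles[j]
                recs.append(
                    VariantAssociation(
                        variant_id=vid,
                        chrom=gr.chrom,
                        pos=int(pos[j]),
                        effect_allele=ea,
                        other_allele=oa,
                        eaf=float(f[j]),
                        beta=float(beta[j]),
                        se=float(se[j]),
                        pval=float(pval[j]),
                        n=float(t["n"]),
                        trait_id=t["trait_id"],
                        trait_type=t["kind"],
                    )
                )

    sets = [
        SummaryStatSet(
            trait_id=tid,
            trait_type=trait_meta[tid]["trait_type"],
            cohort_label=trait_meta[tid]["cohort_label"],
            records=recs,
        )
        for tid, recs in records_by_trait.items()
    ]
    truth = SimTruth(
        causal_variants={
            p.protein_id: [
                ld_by_region[p.region].variant_ids[i] for i in p.causal_indices
            ]
            for p in config.proteins
        },
        theta={o.trait_id: dict(o.theta) for o in config.outcomes},
        marginal_noncentrality=noncentrality,
        variant_ids={r.name: list(ld_by_region[r.name].variant_ids) for r in config.regions},
        sign_flips={
            p.protein_id: list(p.sign_flip_cohorts)
            for p in config.proteins
            if p.sign_flip_cohorts
        },
        pleiotropy={
            o.trait_id: {
                reg: {
                    ld_by_region[reg].variant_ids[i]: eff
                    for i, eff in effs.items()
                }
                for reg, effs in o.pleiotropy.items()
            }
            for o in config.outcomes
            if o.pleiotropy
        },
    )
    return sets, truth, ld_by_region, gene_regions


def write_fixture(config: SimulationConfig, out_dir: str | Path, force: bool = False) -> Path:
    """Write the full fixture bundle: sumstats/, ld/, genes.bed, truth.json, config.yaml."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        if not force:
            raise SimulationError(
                f"output directory {out} is not empty (use force=True to overwrite)"
            )
        shutil.rmtree(out)
    (out / "sumstats").mkdir(parents=True, exist_ok=True)
    (out / "ld").mkdir(exist_ok=True)
    sets, truth, ld_by_region, gene_regions = simulate_sumstats(config)
    for ss in sets:
        write_sumstats(ss, out / "sumstats" / f"{ss.trait_id}.tsv")
    for rname, ld in ld_by_region.items():
        write_ld(ld, out / "ld" / f"{rname}.ld.txt")
    write_gene_bed(gene_regions, out / "genes.bed")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return out


# ---------------------------------------------------------------------------
# Fast instrument-level draws (post-clumping world: independent variants)


def simulate_instruments(
    rng: np.random.Generator,
    n_variants: int,
    lam: float | np.ndarray,
    eaf: float | np.ndarray,
    n_exposure: float,
    n_case: float,
    n_control: float,
    theta: float,
    n_replicates: int = 1,
) -> dict[str, np.ndarray]:
    """Vectorised draws of J independent (clumped) instruments.

    Exposure betas ~ N(lambda, se_x^2); outcome betas ~ N(theta*lambda, se_y^2).
    Returns arrays of shape (n_replicates, J). This is the zero-LD special
    case of :func:`simulate_sumstats`, drawn directly for Monte-Carlo studies
    of the estimators.
    """
    lam = np.broadcast_to(np.asarray(lam, float), (n_variants,))
    f = np.broadcast_to(np.asarray(eaf, float), (n_variants,))
    se_x = se_quantitative(n_exposure, f)
    n_out = n_case + n_control
    se_y = se_binary(n_out, n_case / n_out, f)
    shape = (n_replicates, n_variants)
    beta_x = lam + se_x * rng.standard_normal(shape)
    beta_y = theta * lam + se_y * rng.standard_normal(shape)
    return {
        "beta_x": beta_x,
        "se_x": np.broadcast_to(se_x, shape),
        "beta_y": beta_y,
        "se_y": np.broadcast_to(se_y, shape),
    }


# ---------------------------------------------------------------------------
# Individual-level oracle generator


def simulate_individuals(
    rng: np.random.Generator,
    n: int,
    ld: LDMatrix | np.ndarray,
    eaf: np.ndarray,
    joint_beta: np.ndarray,
    noise_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Small-scale individual-level generator (oracle for conditional analysis).

    Haplotypes are drawn from a Gaussian copula with target correlation, so
    realised genotype LD approximates the requested matrix; the quantitative
    trait is y = G_c @ joint_beta + e with centred genotypes. Returns (G, y).
    """
    R = ld.r if isinstance(ld, LDMatrix) else np.asarray(ld)
    m = R.shape[0]
    L = np.linalg.cholesky(R + 1e-10 * np.eye(m))
    thresh = stats.norm.ppf(np.asarray(eaf))

    def haplotypes() -> np.ndarray:
        latent = rng.standard_normal((n, m)) @ L.T
        return (latent < thresh).astype(float)

    G = haplotypes() + haplotypes()
    Gc = G - G.mean(axis=0)
    y = Gc @ np.asarray(joint_beta) + noise_sd * rng.standard_normal(n)
    return G, y


def marginal_z_from_individuals(G: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-variant marginal association z-scores by simple linear regression."""
    n = G.shape[0]
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = (Gc**2).sum(axis=0)
    beta = (Gc * yc[:, None]).sum(axis=0) / sxx
    resid_var = ((yc[:, None] - Gc * beta) ** 2).sum(axis=0) / (n - 2)
    se = np.sqrt(resid_var / sxx)
    return beta / se
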