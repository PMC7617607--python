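import numpy as np
import pytest

from coagmr.simulate import (
    OutcomeSpec,
    ProteinSpec,
    RegionSpec,
    SimulationConfig,
)
from coagmr.sumstats import SummaryStatSet, VariantAssociation

from scipy import stats


def va(
    variant_id="rs1",
    chrom="4",
    pos=100,
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.1,
    se=0.02,
    pval=None,
    n=35000,
    trait_id="prot",
    trait_type="quantitative",
):
    """Record factory with a p-value consistent with beta/se by default."""
    if pval is None:
        pval = float(2 * stats.norm.sf(abs(beta / se)))
        pval = max(pval, 1e-300)
    return VariantAssociation(
        variant_id=variant_id,
        chrom=chrom,
        pos=pos,
        effect_allele=effect_allele,
        other_allele=other_allele,
        eaf=eaf,
        beta=beta,
        se=se,
        pval=pval,
        n=n,
        trait_id=trait_id,
        trait_type=trait_type,
    )


def make_set(records, trait_id="prot", trait_type="quantitative", cohort="cohortA"):
    import dataclasses

    records = [
        dataclasses.replace(r, trait_id=trait_id, trait_type=trait_type)
        if (r.trait_id != trait_id or r.trait_type != trait_type)
        else r
        for r in records
    ]
    return SummaryStatSet(
        trait_id=trait_id,
        trait_type=trait_type,
        cohort_label=cohort,
        records=records,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1)


@pytest.fixture
def small_config():
    """Two gene regions, two proteins (one stroke-causal), three outcomes' worth
    of structure in a few hundred variants — small enough for per-test use."""
    return SimulationConfig(
        seed=11,
        regions=[
            RegionSpec(name="F11", m=30, rho=0.7, chrom="4"),
            RegionSpec(name="PROC", m=25, rho=0.7, chrom="2", start=2_000_000),
        ],
        proteins=[
            ProteinSpec("F11", "F11", [10], [0.5], cohorts=["cohortA", "cohortB"]),
            ProteinSpec("PROC", "PROC", [5], [0.5], cohorts=["cohortA"]),
        ],
        outcomes=[
            OutcomeSpec("vte", 8_000, 140_000, theta={"F11": 0.4, "PROC": 0.4}),
            OutcomeSpec("stroke", 6_000, 120_000, theta={"F11": 0.26, "PROC": 0.0}),
        ],
    )
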