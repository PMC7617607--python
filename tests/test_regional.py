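"""Regional inference: Wakefield ABFs, colocalization, conditional analysis,
single-causal fine-mapping, and stepwise signal counting."""

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import logsumexp

from coagmr.regional import (
    DEFAULT_PRIORS,
    RegionalError,
    build_regional_dataset,
    coloc_pair,
    conditional_z,
    conditional_z_scores,
    count_signals,
    finemap_single,
    log_abf,
    regional_plot_table,
)
from coagmr.simulate import make_ld
from coagmr.sumstats import GeneRegion

from conftest import make_set, va

REGION = GeneRegion("F11", "4", 0, 100_000)
SE = 0.03


def _trait(zs, trait_id, trait_type="quantitative", ids=None):
    zs = np.asarray(zs, dtype=float)
    ids = ids or [f"rs{j}" for j in range(len(zs))]
    recs = [
        va(
            ids[j], pos=100 + j, beta=float(zs[j] * SE), se=SE,
            pval=float(max(2 * stats.norm.sf(abs(zs[j])), 1e-300)),
            trait_id=trait_id, trait_type=trait_type,
        )
        for j in range(len(zs))
    ]
    return make_set(recs, trait_id=trait_id, trait_type=trait_type)


def _dataset(z1, z2, ld, t1="prot", t2="stroke", type2="binary"):
    return build_regional_dataset(
        REGION,
        [_trait(z1, t1, ids=ld.variant_ids), _trait(z2, t2, type2, ids=ld.variant_ids)],
        ld,
    )


class TestLogABF:
    def test_zero_z_favors_the_null(self):
        # with no signal the ABF is the shrinkage factor sqrt(1-r) < 1
        lbf = log_abf(0.0, SE, 0.15)
        assert lbf < 0

    def test_vanishing_prior_sd_rejected(self):
        with pytest.raises(RegionalError):
            log_abf(2.0, SE, 0.0)

    def test_matches_numerical_quadrature(self, rng):
        """Closed form equals the defining integral
        ABF = ∫ N(b; beta, V) N(beta; 0, W) dbeta / N(b; 0, V)
        on 50 random (z, se, prior_sd) draws to 1e-6 relative accuracy."""
        for _ in range(50):
            z = float(rng.uniform(-6, 6))
            se = float(rng.uniform(0.01, 0.5))
            w = float(rng.uniform(0.05, 0.5))
            b = z * se

            def integrand(beta):
                return stats.norm.pdf(b, beta, se) * stats.norm.pdf(beta, 0, w)

            num, _ = integrate.quad(integrand, -10 * w, 10 * w)
            abf = num / stats.norm.pdf(b, 0, se)
            assert np.exp(log_abf(z, se, w)) == pytest.approx(abf, rel=1e-6)

    def test_increasing_in_absolute_z(self):
        zs = np.array([0.0, 1.0, 2.0, 4.0, 8.0])
        lbf = log_abf(zs, SE, 0.15)
        assert np.all(np.diff(lbf) > 0)


class TestColoc:
    def test_posteriors_sum_to_one(self, rng):
        ld = make_ld(20, rho=0.5)
        ds = _dataset(rng.normal(0, 1, 20), rng.normal(0, 1, 20), ld)
        res = coloc_pair(ds)
        assert sum(res.pp.values()) == pytest.approx(1.0, abs=1e-9)

    def test_flat_region_prefers_h0(self, rng):
        ld = make_ld(100, rho=0.5)
        ds = _dataset(rng.normal(0, 1, 100), rng.normal(0, 1, 100), ld)
        res = coloc_pair(ds)
        assert res.pp["H0"] > 0.9

    def test_shared_causal_variant_gives_h4(self):
        ld = make_ld(50, rho=0.7)
        z = np.array([8.0 * ld.r[j, 25] for j in range(50)])
        ds = _dataset(z, z * 0.8, ld)
        assert coloc_pair(ds).pp_h4 > 0.9

    def test_distinct_causal_variants_give_h3(self):
        # two uncorrelated blocks, each trait causal in a different block
        ld = make_ld(40, blocks=[20, 20], rho=0.7)
        z1 = np.array([8.0 * ld.r[j, 10] for j in range(40)])
        z2 = np.array([8.0 * ld.r[j, 30] for j in range(40)])
        ds = _dataset(z1, z2, ld)
        res = coloc_pair(ds)
        assert res.pp["H3"] > 0.9

    def test_one_sided_signal_gives_h1(self):
        ld = make_ld(40, rho=0.6)
        z1 = np.array([8.0 * ld.r[j, 20] for j in range(40)])
        ds = _dataset(z1, np.zeros(40), ld)
        assert coloc_pair(ds).pp["H1"] > 0.9

    def test_invariant_to_variant_permutation(self, rng):
        ld = make_ld(30, rho=0.6)
        z1 = np.array([7.0 * ld.r[j, 15] for j in range(30)])
        z2 = 0.9 * z1 + rng.normal(0, 0.3, 30)
        a = coloc_pair(_dataset(z1, z2, ld))
        perm = rng.permutation(30)
        ids = [ld.variant_ids[j] for j in perm]
        from coagmr.sumstats import LDMatrix

        ld_p = LDMatrix(ids, ld.r[np.ix_(perm, perm)])
        b = coloc_pair(_dataset(z1[perm], z2[perm], ld_p))
        for h in a.pp:
            assert b.pp[h] == pytest.approx(a.pp[h], abs=1e-12)

    def test_h4_monotone_in_p12(self):
        ld = make_ld(30, rho=0.6)
        z = np.array([6.0 * ld.r[j, 15] for j in range(30)])
        ds = _dataset(z, z, ld)
        pps = [
            coloc_pair(ds, priors=(1e-4, 1e-4, p12)).pp_h4
            for p12 in [1e-8, 1e-6, 1e-5, 1e-4]
        ]
        assert all(a < b for a, b in zip(pps, pps[1:]))

    def test_three_traits_require_named_pair(self, rng):
        ld = make_ld(10, rho=0.5)
        traits = [
            _trait(rng.normal(0, 1, 10), t, ids=ld.variant_ids)
            for t in ("a", "b", "c")
        ]
        ds = build_regional_dataset(REGION, traits, ld)
        with pytest.raises(RegionalError, match="name the pair"):
            coloc_pair(ds)
        res = coloc_pair(ds, "a", "c")
        assert res.trait_ids == ("a", "c")


class TestConditional:
    def test_uncorrelated_variants_unchanged(self):
        z = np.array([3.0, 1.0, -2.0])
        out = conditional_z_scores(z, np.array([0.0, 0.0, 1.0]), 2)
        assert out[0] == 3.0 and out[1] == 1.0 and out[2] == 0.0

    def test_index_variant_conditional_is_zero(self):
        z = np.array([5.0, 4.0])
        out = conditional_z_scores(z, np.array([1.0, 0.8]), 0)
        assert out[0] == 0.0

    def test_perfect_ld_partner_is_nan(self):
        z = np.array([5.0, 5.0, 2.0])
        out = conditional_z_scores(z, np.array([1.0, 1.0, 0.5]), 0)
        assert np.isnan(out[1])

    def test_pure_ld_echo_fully_removed(self):
        """A variant whose signal is exactly r * z_index conditions to 0."""
        r = np.array([1.0, 0.7, 0.4, -0.3])
        z = 6.0 * r
        out = conditional_z_scores(z, r, 0)
        assert out[1:] == pytest.approx(np.zeros(3), abs=1e-12)

    def test_null_conditional_z_is_standard_normal(self, rng):
        """Conditioning preserves calibration: for MVN(0, R) draws the
        conditional z of a correlated partner remains standard normal."""
        R = np.array([[1.0, 0.8], [0.8, 1.0]])
        L = np.linalg.cholesky(R)
        zc = []
        for _ in range(4_000):
            z = L @ rng.standard_normal(2)
            zc.append(conditional_z_scores(z, R[:, 0], 0)[1])
        zc = np.array(zc)
        assert abs(zc.mean()) < 3 / np.sqrt(len(zc))
        assert 0.9 < zc.var() < 1.1

    def test_dataframe_flags_inestimable(self):
        from coagmr.sumstats import LDMatrix

        ids = ["rs0", "rs1", "rs2"]
        R = np.array([[1.0, 1.0, 0.5], [1.0, 1.0, 0.5], [0.5, 0.5, 1.0]])
        ld = LDMatrix(ids, R)
        ds = _dataset([6.0, 6.0, 3.0], [0.0, 0.0, 0.0], ld)
        df = conditional_z(ds, "prot", "rs0")
        assert not df.loc[df.variant_id == "rs1", "estimable"].item()
        assert df.loc[df.variant_id == "rs2", "estimable"].item()


class TestFinemap:
    def test_pips_sum_to_one(self, rng):
        ld = make_ld(25, rho=0.6)
        ds = _dataset(rng.normal(0, 1, 25), np.zeros(25), ld)
        cs = finemap_single(ds, "prot")
        assert sum(cs.pip.values()) == pytest.approx(1.0, abs=1e-9)

    def test_dominant_variant_yields_singleton_set(self):
        ld = make_ld(20, rho=0.3)
        z = np.zeros(20)
        z[7] = 12.0
        ds = _dataset(z, np.zeros(20), ld)
        cs = finemap_single(ds, "prot")
        assert cs.variant_ids == (ld.variant_ids[7],)
        assert cs.pip[ld.variant_ids[7]] > 0.99

    def test_exchangeable_variants_get_equal_pips(self):
        ld = make_ld(4, rho=0.0)
        ds = _dataset([3.0, 3.0, 3.0, 3.0], np.zeros(4), ld)
        cs = finemap_single(ds, "prot")
        pips = list(cs.pip.values())
        assert pips == pytest.approx([0.25] * 4)

    def test_credible_set_is_minimal_prefix(self, rng):
        ld = make_ld(30, rho=0.7)
        z = np.array([7.0 * ld.r[j, 15] for j in range(30)]) + rng.normal(0, 0.5, 30)
        ds = _dataset(z, np.zeros(30), ld)
        cs = finemap_single(ds, "prot", coverage=0.95)
        masses = sorted(cs.pip.values(), reverse=True)
        k = len(cs.variant_ids)
        assert sum(masses[:k]) >= 0.95
        assert k == 1 or sum(masses[: k - 1]) < 0.95

    def test_sharper_signal_concentrates_pip(self):
        ld = make_ld(20, rho=0.5)
        base = np.array([3.0 * ld.r[j, 10] for j in range(20)])
        lead_pips = []
        for scale in [1.0, 1.5, 2.0, 3.0]:
            ds = _dataset(base * scale, np.zeros(20), ld)
            lead_pips.append(finemap_single(ds, "prot").pip[ld.variant_ids[10]])
        assert all(a < b for a, b in zip(lead_pips, lead_pips[1:]))


class TestCountSignals:
    def test_null_region_counts_zero(self, rng):
        ld = make_ld(50, rho=0.5)
        L = np.linalg.cholesky(ld.r)
        z = L @ rng.standard_normal(50)
        ds = _dataset(z, np.zeros(50), ld)
        assert count_signals(ds, "prot").n_signals == 0

    def test_single_strong_signal_counts_one(self):
        ld = make_ld(40, rho=0.7)
        z = np.array([9.0 * ld.r[j, 20] for j in range(40)])
        ds = _dataset(z, np.zeros(40), ld)
        sc = count_signals(ds, "prot")
        assert sc.n_signals == 1
        assert sc.index_variants == (ld.variant_ids[20],)

    def test_two_independent_signals_count_two(self):
        ld = make_ld(40, blocks=[20, 20], rho=0.7)
        z = np.array(
            [9.0 * ld.r[j, 10] + 7.0 * ld.r[j, 30] for j in range(40)]
        )
        ds = _dataset(z, np.zeros(40), ld)
        sc = count_signals(ds, "prot")
        assert sc.n_signals == 2
        assert set(sc.index_variants) == {ld.variant_ids[10], ld.variant_ids[30]}

    def test_default_stop_p_is_regional_bonferroni(self):
        ld = make_ld(40, rho=0.3)
        ds = _dataset(np.zeros(40), np.zeros(40), ld)
        assert count_signals(ds, "prot").stop_p == pytest.approx(0.05 / 40)

    def test_invalid_stop_p_rejected(self):
        ld = make_ld(5, rho=0.3)
        ds = _dataset(np.zeros(5), np.zeros(5), ld)
        with pytest.raises(RegionalError):
            count_signals(ds, "prot", stop_p=1.5)


class TestBuildDataset:
    def test_aligns_on_shared_variants_in_ld_order(self):
        ld = make_ld(3, rho=0.4, variant_ids=["rs0", "rs1", "rs2"])
        t1 = _trait([1.0, 2.0, 3.0], "a", ids=["rs0", "rs1", "rs2"])
        t2 = _trait([1.0, 2.0], "b", ids=["rs2", "rs0"])
        ds = build_regional_dataset(REGION, [t1, t2], ld)
        assert ds.variant_ids == ["rs0", "rs2"]
        assert ds.z("a") == pytest.approx([1.0, 3.0])
        assert ds.z("b") == pytest.approx([2.0, 1.0])

    def test_disjoint_traits_rejected(self):
        ld = make_ld(2, rho=0.4, variant_ids=["rs0", "rs1"])
        t1 = _trait([1.0], "a", ids=["rs0"])
        t2 = _trait([1.0], "b", ids=["rs1"])
        with pytest.raises(RegionalError, match="no variants shared"):
            build_regional_dataset(REGION, [t1, t2], ld)

    def test_single_trait_rejected(self):
        ld = make_ld(2, rho=0.4)
        with pytest.raises(RegionalError, match="at least 2"):
            build_regional_dataset(
                REGION, [_trait([1.0, 2.0], "a", ids=ld.variant_ids)], ld
            )


class TestPlotTable:
    def test_lead_and_r2_columns(self):
        ld = make_ld(10, rho=0.6)
        z = np.array([6.0 * ld.r[j, 5] for j in range(10)])
        ds = _dataset(z, np.zeros(10), ld)
        df = regional_plot_table(ds, "prot")
        assert df.loc[df.is_lead, "variant_id"].item() == ld.variant_ids[5]
        assert df["r2_to_lead"].max() == pytest.approx(1.0)
        assert df["neg_log10_p"].idxmax() == 5
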