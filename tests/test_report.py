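"""Cross-trait library, z-comparison, prioritization, and the full pipeline."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coagmr.mr import MREstimate, bonferroni
from coagmr.proxies import ProxySet
from coagmr.regional import ColocResult
from coagmr.report import (
    DataBundle,
    PipelineConfig,
    build_cross_trait,
    compare_z,
    prioritize,
    run_pipeline,
    write_report,
)

from conftest import make_set, va


def _proxy(protein, variant_ids, source="pqtl_cohortA", zv=None):
    recs = [
        va(v, pos=100 + i, trait_id=f"{protein}_cohortA")
        for i, v in enumerate(variant_ids)
    ]
    return ProxySet(
        protein_id=protein,
        source=source,
        exposure=make_set(recs, trait_id=f"{protein}_cohortA"),
    )


def _protein_set(trait_id, variant_ids, pvals=None, rng=None):
    pvals = pvals if pvals is not None else [0.5] * len(variant_ids)
    recs = [
        va(
            v, pos=100 + i, trait_id=trait_id,
            beta=0.01, se=0.02, pval=float(p),
        )
        for i, (v, p) in enumerate(zip(variant_ids, pvals))
    ]
    return make_set(recs, trait_id=trait_id)


def _estimate(pval, theta=0.3, exposure="F11", outcome="stroke"):
    se = abs(theta) / stats.norm.isf(pval / 2)
    return MREstimate(
        theta=theta, se=se, pval=pval, method="ivw", n_variants=3,
        Q=0.0, phi=1.0, exposure_id=exposure, outcome_id=outcome,
    )


def _coloc(pp_h4, trait_ids=("F11_cohortA", "stroke")):
    rest = (1 - pp_h4) / 4
    return ColocResult(
        pp={"H0": rest, "H1": rest, "H2": rest, "H3": rest, "H4": pp_h4},
        priors=(1e-4, 1e-4, 1e-5),
        prior_sd=(0.15, 0.2),
        trait_ids=trait_ids,
        n_variants=30,
    )


class TestCrossTraitMatrix:
    def test_full_46_by_30_grid_family_size(self):
        """The library-wide Bonferroni family: 46 proxies x 30 protein traits
        with no gaps gives 1380 tests and alpha 3.6e-5."""
        variants = [f"rs{i}" for i in range(46)]
        proxies = [_proxy("P", variants)]
        protein_sets = [
            _protein_set(f"prot{k}_cohortA", variants) for k in range(30)
        ]
        mat = build_cross_trait(proxies, protein_sets)
        assert mat.n_tests == 1380
        assert mat.plan.alpha_per_test == pytest.approx(3.623e-5, rel=1e-3)

    def test_single_cell_family_is_nominal(self):
        mat = build_cross_trait(
            [_proxy("P", ["rs1"])], [_protein_set("prot0_cohortA", ["rs1"])]
        )
        assert mat.n_tests == 1
        assert mat.plan.alpha_per_test == 0.05

    def test_gaps_shrink_the_family(self):
        variants = ["rs1", "rs2", "rs3"]
        proxies = [_proxy("P", variants)]
        sets = [
            _protein_set("a_cohortA", ["rs1", "rs2", "rs3"]),
            _protein_set("b_cohortA", ["rs1"]),  # 2 gaps
        ]
        mat = build_cross_trait(proxies, sets)
        assert mat.n_tests == 4
        assert mat.pval.isna().to_numpy().sum() == 2

    def test_mask_equals_brute_force(self, rng):
        variants = [f"rs{i}" for i in range(12)]
        pvals = {
            f"t{k}_cohortA": rng.uniform(1e-8, 1, 12) for k in range(5)
        }
        proxies = [_proxy("P", variants)]
        sets = [_protein_set(t, variants, pv) for t, pv in pvals.items()]
        mat = build_cross_trait(proxies, sets)
        alpha = 0.05 / (12 * 5)
        for t, pv in pvals.items():
            for v, p in zip(variants, pv):
                assert bool(mat.mask.loc[v, t]) == (p < alpha)

    def test_duplicate_proxies_counted_once(self):
        proxies = [
            _proxy("P1", ["rs1", "rs2"]),
            _proxy("P2", ["rs2", "rs3"]),
        ]
        mat = build_cross_trait(
            proxies, [_protein_set("a_cohortA", ["rs1", "rs2", "rs3"])]
        )
        assert list(mat.pval.index) == ["rs1", "rs2", "rs3"]
        assert mat.n_tests == 3


class TestCompareZ:
    def _sets(self, z_vte, z_out):
        se = 0.02
        vte = make_set(
            [
                va(f"rs{i}", pos=100 + i, beta=float(z * se), se=se,
                   pval=float(max(2 * stats.norm.sf(abs(z)), 1e-300)),
                   trait_id="vte", trait_type="binary")
                for i, z in enumerate(z_vte)
            ],
            trait_id="vte", trait_type="binary",
        )
        out = make_set(
            [
                va(f"rs{i}", pos=100 + i, beta=float(z * se), se=se,
                   pval=float(max(2 * stats.norm.sf(abs(z)), 1e-300)),
                   trait_id="stroke", trait_type="binary")
                for i, z in enumerate(z_out)
            ],
            trait_id="stroke", trait_type="binary",
        )
        return vte, out

    def test_four_quadrant_classification(self):
        # cutoff at the 30-protein family alpha (0.05/30) is ~3.14
        vte, out = self._sets([5.0, 5.0, 1.0, 1.0], [5.0, 1.0, 5.0, 1.0])
        zc = compare_z(
            [_proxy("P", [f"rs{i}" for i in range(4)])], vte, out, alpha=0.05 / 30
        )
        assert zc.cutoff == pytest.approx(3.1440, abs=1e-3)
        assert list(zc.table["category"]) == [
            "both", "vte_only", "outcome_only", "neither"
        ]

    def test_classification_uses_absolute_z(self):
        vte, out = self._sets([-5.0, 4.0], [4.0, -4.0])
        zc = compare_z([_proxy("P", ["rs0", "rs1"])], vte, out, alpha=0.0017)
        assert list(zc.table["category"]) == ["both", "both"]

    def test_variant_missing_from_either_side_dropped(self):
        vte, out = self._sets([5.0], [5.0])
        zc = compare_z([_proxy("P", ["rs0", "rs_absent"])], vte, out)
        assert list(zc.table["variant_id"]) == ["rs0"]


class TestPrioritize:
    PLAN = bonferroni(30)  # alpha 0.0017

    def test_significant_mr_with_strong_coloc_prioritized(self):
        recs = prioritize(
            [("F11", "pqtl_cohortA", "stroke", _estimate(1e-5))],
            {("F11", "stroke"): _coloc(0.86)},
            self.PLAN,
        )
        assert recs[0].verdict == "prioritized"

    def test_weak_coloc_blocks_prioritization(self):
        """MR significance alone is not enough: PP(H4)=0.22 < 0.7 fails."""
        recs = prioritize(
            [("F2", "pqtl_cohortA", "stroke", _estimate(1e-6))],
            {("F2", "stroke"): _coloc(0.22)},
            self.PLAN,
        )
        assert recs[0].verdict == "not_prioritized"

    def test_nonsignificant_mr_blocks_prioritization(self):
        recs = prioritize(
            [("PROC", "pqtl_cohortA", "stroke", _estimate(0.01))],
            {("PROC", "stroke"): _coloc(0.99)},
            self.PLAN,
        )
        assert recs[0].verdict == "not_prioritized"

    def test_missing_coloc_is_incomplete_never_prioritized(self):
        recs = prioritize(
            [("KLKB1", "pqtl_cohortA", "stroke", _estimate(1e-10))],
            {},
            self.PLAN,
        )
        assert recs[0].verdict == "incomplete"

    def test_boundary_pp_h4_exactly_pp_min_is_prioritized(self):
        recs = prioritize(
            [("F11", "pqtl_cohortA", "stroke", _estimate(1e-5))],
            {("F11", "stroke"): _coloc(0.7)},
            self.PLAN,
            pp_min=0.7,
        )
        assert recs[0].verdict == "prioritized"

    def test_raising_pp_min_only_shrinks_the_prioritized_set(self):
        mr = [
            (f"P{k}", "pqtl_cohortA", "stroke", _estimate(1e-5, exposure=f"P{k}"))
            for k in range(6)
        ]
        coloc = {(f"P{k}", "stroke"): _coloc(0.5 + 0.09 * k) for k in range(6)}
        prev = None
        for pp_min in [0.5, 0.6, 0.7, 0.8, 0.9]:
            cur = {
                r.protein
                for r in prioritize(mr, coloc, self.PLAN, pp_min)
                if r.verdict == "prioritized"
            }
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_sorted_by_verdict_then_pvalue(self):
        mr = [
            ("A", "pqtl_cohortA", "stroke", _estimate(1e-4, exposure="A")),
            ("B", "pqtl_cohortA", "stroke", _estimate(1e-8, exposure="B")),
            ("C", "pqtl_cohortA", "stroke", _estimate(0.5, exposure="C")),
        ]
        coloc = {("A", "stroke"): _coloc(0.9), ("B", "stroke"): _coloc(0.9)}
        recs = prioritize(mr, coloc, self.PLAN)
        assert [r.protein for r in recs] == ["B", "A", "C"]
        assert [r.verdict for r in recs] == [
            "prioritized", "prioritized", "incomplete"
        ]


class TestRunPipeline:
    def test_recovers_the_causal_protein_and_not_the_null(self, small_config):
        bundle, _ = DataBundle.from_simulation(small_config)
        result = run_pipeline(bundle)
        assert result.prioritized_proteins() == ["F11"]
        proc = [r for r in result.records if r.protein == "PROC"]
        assert proc and all(r.verdict != "prioritized" for r in proc)

    def test_estimate_close_to_simulated_theta(self, small_config):
        bundle, truth = DataBundle.from_simulation(small_config)
        result = run_pipeline(bundle)
        rows = [
            r for r in result.records
            if r.protein == "F11" and r.source == "pqtl_cohortA"
        ]
        est = rows[0].mr
        true_theta = truth["theta"]["stroke"]["F11"]
        assert abs(est.theta - true_theta) < 4 * est.se

    def test_liability_source_reported_per_doubling(self, small_config):
        bundle, _ = DataBundle.from_simulation(small_config)
        result = run_pipeline(bundle)
        liab = [
            r for r in result.records if r.source == "liability"
        ]
        assert liab
        assert all(r.mr.exposure_scale == "per_doubling_liability" for r in liab)

    def test_family_plan_counts_proteins(self, small_config):
        bundle, _ = DataBundle.from_simulation(small_config)
        result = run_pipeline(bundle)
        assert result.plan.n_tests == 2
        assert result.log["n_proteins"] == 2

    def test_report_is_deterministic_and_byte_identical(self, small_config, tmp_path):
        bundle, _ = DataBundle.from_simulation(small_config)
        a = write_report(run_pipeline(bundle), tmp_path / "a")
        bundle2, _ = DataBundle.from_simulation(small_config)
        b = write_report(run_pipeline(bundle2), tmp_path / "b")
        files = sorted(p.name for p in a.iterdir())
        assert files == sorted(p.name for p in b.iterdir())
        for name in files:
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_report_json_structure(self, small_config, tmp_path):
        bundle, _ = DataBundle.from_simulation(small_config)
        out = write_report(run_pipeline(bundle), tmp_path / "r")
        payload = json.loads((out / "report.json").read_text())
        assert payload["prioritized"] == ["F11"]
        assert any(k.startswith("F11|") for k in payload["coloc"])
        for audit in payload["proxy_audit"]:
            assert {"protein", "source", "n_variants", "filters"} <= set(audit)

    def test_fixture_and_in_memory_runs_agree(self, small_config, tmp_path):
        from coagmr.simulate import write_fixture

        write_fixture(small_config, tmp_path / "fx")
        res_fx = run_pipeline(DataBundle.from_fixture(tmp_path / "fx"))
        res_mem = run_pipeline(DataBundle.from_simulation(small_config)[0])
        assert res_fx.prioritized_proteins() == res_mem.prioritized_proteins()
        pd.testing.assert_frame_equal(res_fx.mr_table, res_mem.mr_table)


class TestCLI:
    def test_simulate_then_run_end_to_end(self, small_config, tmp_path):
        import yaml
        from click.testing import CliRunner

        from coagmr.cli import main

        cfg_path = tmp_path / "config.yaml"
        with open(cfg_path, "w") as fh:
            yaml.safe_dump(small_config.to_dict(), fh)
        runner = CliRunner()
        fx = tmp_path / "fx"
        r1 = runner.invoke(
            main, ["simulate", "--config", str(cfg_path), "--out", str(fx)]
        )
        assert r1.exit_code == 0, r1.output
        out = tmp_path / "report"
        r2 = runner.invoke(main, ["run", "--bundle", str(fx), "--out", str(out)])
        assert r2.exit_code == 0, r2.output
        payload = json.loads((out / "report.json").read_text())
        assert payload["prioritized"] == ["F11"]
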