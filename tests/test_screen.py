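"""Candidate selection rules, ranking, and the end-to-end design round."""

import hashlib
import itertools
import json
from pathlib import Path

import numpy as np
import pytest

from taqdesign.dataset import TransformParams
from taqdesign.regression import PredictiveDistribution, _summaries
from taqdesign.screen import (CandidateReport, Rule, apply_criteria,
                              default_criteria, fit_property_models,
                              predict_scan, rank_candidates, run_design_round)
from taqdesign.variants import ScanSpec, Variant, enumerate_scan, parse_variant

IDENTITY = TransformParams("identity", 0.0, 1.0)


def point(v: float) -> PredictiveDistribution:
    return _summaries(v, 0.0, IDENTITY, 0.9)


def wrap(variant_name, preds):
    from taqdesign.variants import Mutation, ProteinSequence
    ref = ProteinSequence("r", "A" * 10)
    v = Variant(()) if variant_name == "WT" else parse_variant(variant_name, ref)
    return v, preds


class TestApplyCriteria:
    def test_means_exactly_on_thresholds_pass(self):
        criteria = {"kcat_dT": Rule(20.0, ">="), "dTdU_rate": Rule(1.5, "<=")}
        preds = [wrap("WT", {"kcat_dT": point(20.0), "dTdU_rate": point(1.5)})]
        params = {p: IDENTITY for p in criteria}
        report = next(apply_criteria(iter(preds), criteria, params))
        assert report.passes

    def test_wt_measured_values_pass_default_continuous_rules(self, table1):
        # the wild type's own measurements, treated as point predictions,
        # clear every continuous threshold of the default filter
        criteria = {k: v for k, v in default_criteria().items()
                    if k in table1.values.columns}
        assert set(criteria) == {"kcat_dT", "kcat_dU", "dTdU_rate",
                                 "fidelity", "k_rel"}
        preds = [wrap("WT", {p: point(float(table1.values.at["WT", p]))
                             for p in criteria})]
        params = {p: IDENTITY for p in criteria}
        report = next(apply_criteria(iter(preds), criteria, params))
        assert report.passes
        assert report.rule_pass == {p: True for p in criteria}

    def test_relaxing_a_threshold_never_shrinks_pass_set(self):
        rng = np.random.default_rng(0)
        values = rng.normal(10, 5, 30)
        preds = [wrap("WT", {"kcat_dT": point(v)}) for v in values]
        params = {"kcat_dT": IDENTITY}
        strict = {r.variant for r in apply_criteria(
            iter(preds), {"kcat_dT": Rule(12.0, ">=")}, params) if r.passes}
        relaxed = {r.variant for r in apply_criteria(
            iter(preds), {"kcat_dT": Rule(8.0, ">=")}, params) if r.passes}
        assert strict <= relaxed

    def test_chance_mode_converges_to_mean_mode_at_half(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            mu, sigma = rng.normal(), rng.uniform(0.1, 2.0)
            d = _summaries(mu, sigma, IDENTITY, 0.9)
            preds = [wrap("WT", {"kcat_dT": d})]
            mean_rule = {"kcat_dT": Rule(0.0, ">=", "mean")}
            chance_rule = {"kcat_dT": Rule(0.0, ">=", "chance", p_level=0.5)}
            params = {"kcat_dT": IDENTITY}
            a = next(apply_criteria(iter(preds), mean_rule, params)).passes
            b = next(apply_criteria(iter(preds), chance_rule, params)).passes
            assert a == b  # symmetric posterior: P(X >= t) >= 1/2 iff mean >= t

    def test_union_criteria_is_intersection_of_pass_sets(self):
        rng = np.random.default_rng(2)
        preds_data = [(f"A{i+1}C", {"kcat_dT": point(rng.normal(20, 5)),
                                    "dTdU_rate": point(rng.normal(1.5, 0.5))})
                      for i in range(9)]
        A = {"kcat_dT": Rule(20.0, ">=")}
        B = {"dTdU_rate": Rule(1.5, "<=")}
        params = {"kcat_dT": IDENTITY, "dTdU_rate": IDENTITY}

        def pass_set(criteria):
            preds = [wrap(n, p) for n, p in preds_data]
            return {r.variant for r in apply_criteria(iter(preds), criteria, params)
                    if r.passes}

        assert pass_set({**A, **B}) == pass_set(A) & pass_set(B)

    def test_unmodeled_property_rejected(self):
        preds = [wrap("WT", {"kcat_dT": point(30.0)})]
        with pytest.raises(KeyError, match="unmodeled"):
            list(apply_criteria(iter(preds), {"kd": Rule(5.0, "<=")},
                                {"kd": IDENTITY}))

    def test_error_rate_rule_is_fidelity_bound(self):
        # "error rate <= 1/3000" is the fidelity >= 3000 nt/error rule
        rule = default_criteria()["fidelity"]
        assert rule.threshold == 3000.0 and rule.direction == ">="


class TestRank:
    @staticmethod
    def _report(name, mean, sd):
        return CandidateReport(name, {"rt90": _summaries(mean, sd, IDENTITY, 0.9)},
                               {}, {}, True)

    def test_lambda_zero_orders_by_mean(self):
        reports = [self._report("b", 2.0, 0.1), self._report("a", 1.0, 0.1)]
        ranked = rank_candidates(reports, "rt90", "lower")
        assert [r.variant for r in ranked] == ["a", "b"]

    def test_large_lambda_prefers_low_uncertainty(self):
        better_mean = self._report("risky", 1.0, 2.0)
        safer = self._report("safe", 1.5, 0.01)
        ranked = rank_candidates([better_mean, safer], "rt90", "lower",
                                 uncertainty_penalty=5.0)
        assert ranked[0].variant == "safe"

    def test_top_n_equals_full_sort_prefix(self):
        rng = np.random.default_rng(3)
        reports = [self._report(f"v{i:02d}", rng.normal(), rng.uniform(0, 1))
                   for i in range(25)]
        full = rank_candidates(reports, "rt90", "lower")
        top = rank_candidates(reports, "rt90", "lower", top_n=7)
        # independent sort oracle
        oracle = sorted(reports, key=lambda r: (r.predictions["rt90"].mean,
                                                r.variant))
        assert [r.variant for r in top] == [r.variant for r in oracle[:7]]
        assert [r.variant for r in full] == [r.variant for r in oracle]

    def test_empty_pass_set_yields_empty_list(self):
        assert rank_candidates([], "rt90", "lower") == []


class TestPredictScan:
    @pytest.fixture
    def fitted(self, toy_round_config):
        from taqdesign.dataset import default_schemas, load_property_table
        from taqdesign.embedding import EmbedderSpec
        from taqdesign.variants import read_fasta
        land, config = toy_round_config
        table = load_property_table(config["property_tables"][0])
        reference = read_fasta(config["reference_fasta"])
        embedder = EmbedderSpec(dim=32, seed=7)
        models = fit_property_models(table, default_schemas(), reference, embedder)
        return land, reference, embedder, models

    def test_wt_predictions_finite(self, fitted):
        land, reference, embedder, models = fitted
        rows = list(predict_scan(models, [Variant(())], reference, embedder))
        assert len(rows) == 1
        for dist in rows[0][1].values():
            assert np.isfinite([dist.mean, dist.sigma, dist.mu]).all()

    def test_batched_equals_single_calls(self, fitted):
        land, reference, embedder, models = fitted
        spec = ScanSpec(frozenset(), 1)
        variants = list(itertools.islice(enumerate_scan(reference, spec), 30))
        batched = list(predict_scan(models, variants, reference, embedder,
                                    batch_size=7))
        singles = [next(predict_scan(models, [v], reference, embedder))
                   for v in variants]
        for (v1, d1), (v2, d2) in zip(batched, singles):
            assert v1.name == v2.name
            for p in d1:
                assert d1[p].mean == pytest.approx(d2[p].mean, rel=1e-12)

    def test_cursor_restart_reproduces_remaining_rows(self, fitted):
        land, reference, embedder, models = fitted
        spec = ScanSpec(frozenset(), 1)
        full = [(v.name, d["rt90"].mean) for v, d in predict_scan(
            models, enumerate_scan(reference, spec), reference, embedder)]
        resumed = [(v.name, d["rt90"].mean) for v, d in predict_scan(
            models, enumerate_scan(reference, spec, start=100), reference,
            embedder)]
        assert resumed == full[100:]


class TestDesignRound:
    def test_toy_round_emits_all_artifacts(self, toy_round_config):
        land, config = toy_round_config
        manifest = run_design_round(config)
        out = Path(config["output_dir"])
        for name in ("predictions.tsv", "candidates.tsv", "selected.fasta",
                     "manifest.json"):
            assert (out / name).exists()
        assert manifest["n_selected"] <= config["top_n"]
        n_rows = len((out / "predictions.tsv").read_text().splitlines()) - 1
        assert n_rows == config["scan"]["limit"]

    def test_rerun_is_byte_identical(self, toy_round_config, tmp_path):
        land, config = toy_round_config
        run_design_round(config)
        config2 = dict(config, output_dir=str(tmp_path / "run-b"))
        run_design_round(config2)
        for name in ("predictions.tsv", "candidates.tsv", "selected.fasta"):
            a = (Path(config["output_dir"]) / name).read_bytes()
            b = (Path(config2["output_dir"]) / name).read_bytes()
            assert a == b

    def test_manifest_digests_match_recomputed_hashes(self, toy_round_config):
        land, config = toy_round_config
        manifest = run_design_round(config)
        out = Path(config["output_dir"])
        for name, digest in manifest["digests"].items():
            assert hashlib.sha256((out / name).read_bytes()).hexdigest() == digest

    def test_stage_failure_names_the_stage(self, toy_round_config, tmp_path):
        land, config = toy_round_config
        config = dict(config, reference_fasta=str(tmp_path / "missing.fasta"))
        with pytest.raises(RuntimeError, match="stage 'load'"):
            run_design_round(config)
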