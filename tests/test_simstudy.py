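"""Monte-Carlo engine: determinism, aggregation, table/report formats, CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from gelrct import (
    MethodResult,
    Part3Scenario,
    Scenario,
    aggregate,
    analyze_dataset,
    reproduce_table,
    run_replicate,
    run_study,
    sample_part3,
)
from gelrct.cli import main
from gelrct.simstudy import _ols_batch, _run_arrays, sample_batch

from conftest import SEED


class TestReplicates:
    def test_same_seed_bit_identical(self):
        sc = Scenario(dist="normal", rho=0.5, k=1)
        a = run_replicate(sc, ["cue", "ancova"], 42)
        b = run_replicate(sc, ["cue", "ancova"], 42)
        for ra, rb in zip(a, b):
            assert (ra.estimate, ra.ci_lower, ra.ci_upper) == \
                   (rb.estimate, rb.ci_lower, rb.ci_upper)

    def test_null_estimates_are_small(self):
        sc = Scenario(dist="normal", rho=0.5, k=0)
        (res,) = run_replicate(sc, ["ancova"], 7)
        assert abs(res.estimate) < 1.0

    def test_anova_ci_is_pooled_t_interval(self):
        from gelrct import fit_ancova
        sc = Scenario(dist="normal", rho=0.5, k=0)
        (res,) = run_replicate(sc, ["ancova"], 9)
        ref = fit_ancova(sc.sample(np.random.default_rng(9)), 0)
        assert res.estimate == ref.delta_hat
        assert (res.ci_lower, res.ci_upper) == ref.ci_classical


class TestAggregate:
    def test_hand_arithmetic(self):
        rs = [MethodResult("cue", 0.5 + s, -1.0, 1.0, True, i)
              for i, s in enumerate((1.0, -1.0))]
        s = aggregate(rs, delta_true=0.5)
        assert s.rmse == 1.0
        assert s.coverage == 1.0
        assert s.n_converged == 2

    def test_rejection_rate(self):
        rs = [MethodResult("cue", 0.0, 0.2, 1.0, True, 0),
              MethodResult("cue", 0.0, -0.2, 1.0, True, 1)]
        s = aggregate(rs, 0.5)
        assert s.rejection_rate == 0.5

    def test_nonconverged_excluded(self):
        rs = [MethodResult("cue", 0.0, -1.0, 1.0, True, 0),
              MethodResult("cue", np.nan, np.nan, np.nan, False, 1)]
        s = aggregate(rs, 0.0)
        assert s.n_converged == 1 and s.coverage == 1.0

    def test_errors(self):
        with pytest.raises(ValueError):
            aggregate([], 0.0)
        with pytest.raises(ValueError):
            aggregate([MethodResult("cue", np.nan, np.nan, np.nan, False, 0)],
                      0.0)
        with pytest.raises(ValueError):
            aggregate([MethodResult("cue", 0, 0, 0, True, 0),
                       MethodResult("el", 0, 0, 0, True, 1)], 0.0)


class TestBatchedOLS:
    @pytest.mark.parametrize("method", ["ancova", "ancova_hc3"])
    def test_matches_per_replicate_path(self, method):
        sc = Scenario(dist="normal", rho=0.5, k=1)
        est, lo, hi, conv = _run_arrays(sc, method, 5, SEED)
        seeds = np.random.SeedSequence(SEED).spawn(5)
        for r in range(5):
            (ref,) = run_replicate(sc, [method], seeds[r])
            assert abs(est[r] - ref.estimate) < 1e-8
            assert abs(lo[r] - ref.ci_lower) < 1e-8
            assert abs(hi[r] - ref.ci_upper) < 1e-8

    def test_part3_batch_runs(self):
        sc = Part3Scenario(effect_size=0.3)
        Y, z, X = sample_batch(sc, 8, SEED)
        est, lo, hi = _ols_batch(Y, z, X, 1)
        assert est.shape == (8,) and (lo < hi).all()


class TestRunStudy:
    def test_summaries_and_determinism(self):
        sc = Scenario(dist="normal", rho=0.5, k=1)
        a = run_study(sc, ["ancova", "cue"], 4, SEED)
        b = run_study(sc, ["ancova", "cue"], 4, SEED)
        for m in ("ancova", "cue"):
            assert a[m].rmse == b[m].rmse
            assert a[m].coverage == b[m].coverage
            assert a[m].n_converged <= a[m].n_reps_requested


class TestReproduceTable:
    def test_table1_layout(self, tmp_path):
        out = tmp_path / "t1.csv"
        df = reproduce_table(1, reps=20, gel_reps=3, seed=SEED,
                             methods_subset=["cue", "ancova"], out=out)
        assert out.exists()
        assert set(df["method"]) == {"CUE", "ANOVA"}
        assert set(df["dist"]) == {"normal", "t3", "lognormal"}
        assert {"rmse", "coverage", "n_converged"} <= set(df.columns)
        assert len(df) == 6

    def test_table8_delta_grid(self):
        df = reproduce_table(8, reps=10, seed=SEED,
                             methods_subset=["ancova"])
        assert list(df["delta"]) == [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6,
                                     0.7, 0.8]

    def test_unknown_table_rejected(self):
        with pytest.raises(ValueError):
            reproduce_table(9)


class TestAnalyzeDataset:
    @pytest.fixture
    def lookalike_csv(self, tmp_path):
        # synthetic stand-in for the lead-trial data (Delta = 0)
        d = sample_part3(0.0, 100, np.random.default_rng(SEED))
        p = tmp_path / "lookalike.csv"
        d.to_csv(p)
        return p

    def test_gel_report_shape(self, lookalike_csv):
        rep = analyze_dataset(lookalike_csv, method="cue", k=1)
        est = rep["estimates"]
        assert set(est) == {"mu1", "delta", "mux"}
        lo, hi = est["delta"]["ci"]
        assert lo < est["delta"]["estimate"] < hi
        assert abs(est["delta"]["estimate"]) < 0.25
        assert lo < 0.0 < hi  # null effect: CI spans zero
        assert abs(est["mu1"]["estimate"] - 1.82) < 0.2
        json.dumps(rep)  # JSON-serialisable

    def test_ancova_without_covariates_has_no_slope(self, lookalike_csv):
        rep = analyze_dataset(lookalike_csv, method="ancova", k=0)
        assert "beta_x" not in rep["estimates"]
        assert "mux" not in rep["estimates"]

    def test_ancova_reports_slope(self, lookalike_csv):
        rep = analyze_dataset(lookalike_csv, method="ancova", k=1)
        b = rep["estimates"]["beta_x"][0]
        assert b["ci"][0] < b["estimate"] < b["ci"][1]

    def test_invalid_group_code_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("y,z,x1\n1.0,0,0.1\n2.0,2,0.2\n3.0,1,0.3\n")
        with pytest.raises(ValueError):
            analyze_dataset(p, method="cue", k=1)


class TestCLI:
    def test_simulate_and_analyze(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "sim.csv"
        r = runner.invoke(main, ["simulate", "--part", "1", "--reps", "3",
                                 "--methods", "ancova", "--seed", "1",
                                 "--out", str(out)])
        assert r.exit_code == 0, r.output
        assert out.exists()

        d = sample_part3(0.0, 30, np.random.default_rng(SEED))
        csv = tmp_path / "d.csv"
        d.to_csv(csv)
        rep = tmp_path / "rep.json"
        r = runner.invoke(main, ["analyze", str(csv), "--method", "ancova",
                                 "-k", "1", "--out", str(rep)])
        assert r.exit_code == 0, r.output
        assert "delta" in json.loads(rep.read_text())["estimates"]
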