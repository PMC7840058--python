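"""Control allocation, the random-intercept logistic fit, draw pooling,
empirical-CDF significance, and classification accuracy."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit

from rsfperm.inference import (
    allocate_controls,
    allocation_sizes,
    classification_accuracy,
    draw_parameters,
    ecdf_two_tailed_p,
    fit_behavior_model,
    largest_remainder,
    run_permutation_analysis,
    run_study_analysis,
)
from rsfperm.preprocess import standardize
from rsfperm.simulate import SyntheticTruth, generate_study


class TestAllocationArithmetic:
    """The region-by-region proportional split of control sites."""

    @pytest.mark.parametrize(
        "n_controls, counts, expected",
        [
            # the study's printed allocations, region by region
            (81, {"caching": 32, "foraging": 19}, {"caching": 51, "foraging": 30}),
            (53, {"caching": 26, "foraging": 22, "nesting": 28},
             {"caching": 18, "foraging": 15, "nesting": 20}),
            (212, {"caching": 12, "nesting": 12}, {"caching": 106, "nesting": 106}),
        ],
    )
    def test_study_allocations(self, n_controls, counts, expected):
        assert allocation_sizes(n_controls, counts) == expected

    def test_single_behavior_takes_all(self):
        assert allocation_sizes(40, {"caching": 9}) == {"caching": 40}

    @settings(max_examples=100, deadline=None)
    @given(
        total=st.integers(0, 500),
        weights=st.lists(st.integers(0, 60), min_size=1, max_size=5),
    )
    def test_apportionment_properties(self, total, weights):
        w = {f"b{i}": v for i, v in enumerate(weights)}
        if sum(weights) == 0:
            if total > 0:
                with pytest.raises(ValueError):
                    largest_remainder(total, w)
            return
        sizes = largest_remainder(total, w)
        assert sum(sizes.values()) == total
        for k, v in w.items():
            quota = total * v / sum(weights)
            assert np.floor(quota) <= sizes[k] <= np.ceil(quota)


class TestAllocateControls:
    CONTROL_IDS = {"en": [f"en{i}" for i in range(212)], "si": [f"si{i}" for i in range(81)]}
    USED = {"en": {"caching": 12, "nesting": 12}, "si": {"caching": 32, "foraging": 19}}

    def test_partition_invariants(self):
        rng = np.random.default_rng(0)
        plan = allocate_controls(self.CONTROL_IDS, self.USED, rng)
        for region, ids in self.CONTROL_IDS.items():
            sets = [set(s) for s in plan.assignment[region].values()]
            union = set().union(*sets)
            assert union == set(ids)
            assert sum(len(s) for s in sets) == len(ids)  # pairwise disjoint

    def test_sizes_fixed_membership_varies(self):
        rng = np.random.default_rng(1)
        plans = [allocate_controls(self.CONTROL_IDS, self.USED, rng, k) for k in range(5)]
        sizes = {tuple(sorted((r, b, n) for r, bs in p.sizes().items() for b, n in bs.items()))
                 for p in plans}
        assert len(sizes) == 1
        memberships = {tuple(sorted(p.assignment["si"]["caching"])) for p in plans}
        assert len(memberships) > 1

    def test_region_without_used_leaves_controls_unassigned(self):
        rng = np.random.default_rng(2)
        with pytest.warns(UserWarning, match="unassigned"):
            plan = allocate_controls({"cn": ["a", "b"]}, {"cn": {}}, rng)
        assert plan.assignment["cn"] == {}


def simulate_glmm(seed, n=900, beta=(-0.5, 1.0, -0.7), sigma=0.0, n_groups=3):
    rng = np.random.default_rng(seed)
    g = rng.integers(0, n_groups, n)
    u = rng.normal(0, sigma, n_groups) if sigma > 0 else np.zeros(n_groups)
    X = rng.normal(size=(n, len(beta) - 1))
    eta = beta[0] + X @ np.array(beta[1:]) + u[g]
    y = rng.random(n) < expit(eta)
    df = pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])
    df["region"] = [f"r{i}" for i in g]
    return df[y].copy(), df[~y].copy(), y


class TestFitBehaviorModel:
    def test_sigma_zero_matches_irls_oracle(self):
        """Constrained at sigma^2 = 0 the mixed fit must reproduce plain
        logistic regression (independent IRLS fit) to 1e-4."""
        used, ctrl, y = simulate_glmm(0)
        attrs = ["x0", "x1"]
        fit = fit_behavior_model(used, ctrl, attrs, max_sigma2=0.0)
        assert fit.converged and fit.boundary
        df = pd.concat([used, ctrl])
        resp = np.concatenate([np.ones(len(used)), np.zeros(len(ctrl))])
        glm = sm.GLM(resp, sm.add_constant(df[attrs]), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.fixed_effects, glm.params.values, atol=1e-4)
        np.testing.assert_allclose(fit.fixed_cov, glm.cov_params().values, atol=1e-4)

    def test_null_data_recovers_prevalence(self):
        used, ctrl, y = simulate_glmm(1, n=4000, beta=(-1.0, 0.0, 0.0))
        fit = fit_behavior_model(used, ctrl, ["x0", "x1"])
        assert fit.converged
        q = y.mean()
        assert fit.fixed_effects[0] == pytest.approx(logit(q), abs=0.15)
        np.testing.assert_allclose(fit.fixed_effects[1:], 0.0, atol=0.15)

    def test_matches_lme4_glmer(self, tmp_path):
        """Independent oracle: lme4's Laplace glmer on the same data."""
        used, ctrl, _ = simulate_glmm(7, n=900, beta=(-0.5, 1.0, -0.7), sigma=0.8)
        fit = fit_behavior_model(used, ctrl, ["x0", "x1"])
        assert fit.converged
        df = pd.concat([used, ctrl])
        df["y"] = np.concatenate([np.ones(len(used)), np.zeros(len(ctrl))])
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(y ~ x0 + x1 + (1|region), data=d, family=binomial)
            cat(fixef(m), as.numeric(VarCorr(m)$region), sep="\\n")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, check=True)
        vals = [float(v) for v in out.stdout.split()]
        np.testing.assert_allclose(fit.fixed_effects, vals[:3], atol=2e-3)
        assert fit.random_variance == pytest.approx(vals[3], abs=5e-3)

    def test_parameter_recovery_coverage(self):
        """True slope lies in its 95% Wald interval in >= 90% of replicates."""
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            used, ctrl, _ = simulate_glmm(100 + rep, n=2000, beta=(-1.0, 1.0), sigma=0.5)
            fit = fit_behavior_model(used, ctrl, ["x0"])
            if not fit.converged:
                continue
            se = np.sqrt(fit.fixed_cov[1, 1])
            hits += abs(fit.fixed_effects[1] - 1.0) <= 1.96 * se
        assert hits / n_rep >= 0.90

    def test_unreasonable_split_flagged(self):
        used, ctrl, _ = simulate_glmm(3, n=200)
        fit = fit_behavior_model(used, ctrl.iloc[:2], ["x0", "x1"])
        assert not fit.converged
        assert "unreasonable split" in fit.message


class TestDrawParameters:
    def _fit(self):
        used, ctrl, _ = simulate_glmm(4)
        return fit_behavior_model(used, ctrl, ["x0", "x1"])

    def test_zero_covariance_returns_estimate(self):
        fit = self._fit()
        fit.fixed_cov = np.zeros_like(fit.fixed_cov)
        draw = draw_parameters(fit, np.random.default_rng(0))
        np.testing.assert_allclose(draw, fit.fixed_effects)

    def test_fixed_seed_reproducible(self):
        fit = self._fit()
        d1 = draw_parameters(fit, np.random.default_rng(5))
        d2 = draw_parameters(fit, np.random.default_rng(5))
        np.testing.assert_array_equal(d1, d2)

    def test_law_of_large_numbers(self):
        fit = self._fit()
        fit.fixed_effects = np.zeros(3)
        fit.fixed_cov = np.eye(3)
        rng = np.random.default_rng(6)
        draws = np.array([draw_parameters(fit, rng) for _ in range(20_000)])
        np.testing.assert_allclose(draws.mean(axis=0), 0.0, atol=0.025)

    def test_non_psd_projected_with_warning(self):
        fit = self._fit()
        fit.fixed_cov = np.diag([1.0, 1.0, -0.5])
        with pytest.warns(UserWarning, match="PSD"):
            draw = draw_parameters(fit, np.random.default_rng(7))
        assert np.isfinite(draw).all()


class TestEcdfTwoTailedP:
    @pytest.mark.parametrize(
        "draws, expected",
        [
            ([-1, 1, 2, 3], 0.5),       # lower tail 1/4, doubled
            ([-2, -1, 1, 2], 1.0),      # symmetric about 0
            ([1, 2, 3], 0.0),           # empty focal tail
            ([-5], 0.0),                # single negative draw: upper tail empty
        ],
    )
    def test_enumerated_examples(self, draws, expected):
        assert ecdf_two_tailed_p(np.array(draws, float)) == pytest.approx(expected)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=40))
    def test_matches_counting_oracle(self, values):
        draws = np.array(values)
        n = len(draws)
        oracle = min(1.0, 2 * min((draws <= 0).sum() / n, (draws >= 0).sum() / n))
        assert ecdf_two_tailed_p(draws) == pytest.approx(oracle)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ecdf_two_tailed_p(np.array([]))


class TestClassificationAccuracy:
    def test_perfectly_separated_toy_data(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.uniform(2, 3, 30), rng.uniform(-3, -2, 70)])
        df = pd.DataFrame({"x0": x, "region": "r0"})
        fit = fit_behavior_model(df.iloc[:30], df.iloc[30:], ["x0"])
        # separation may trip the convergence guard; force a clean fit
        if fit.converged:
            assert classification_accuracy(fit) == 1.0

    def test_uninformative_predictor_majority_class(self):
        # prevalence q < 0.5 with no signal: everything classified control
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x0": rng.normal(size=1000), "region": "r0"})
        fit = fit_behavior_model(df.iloc[:300], df.iloc[300:], ["x0"])
        assert fit.converged
        assert classification_accuracy(fit) == pytest.approx(0.7, abs=0.02)

    def test_tie_counts_as_incorrect(self):
        from rsfperm.inference import PermutationFit

        fit = PermutationFit(
            behavior="caching", permutation_id=0, converged=True,
            coef_names=["intercept"], fixed_effects=np.array([0.0]),
            fixed_cov=np.eye(1),
        )
        y = np.array([1.0, 0.0])
        fit._design = (y, np.ones((2, 1)), np.zeros(2, int), np.zeros(1))
        # predicted probability is exactly 0.5 for both records
        assert classification_accuracy(fit) == 0.0


@pytest.fixture(scope="module")
def recovery_study():
    truth = SyntheticTruth.recovery_default(
        n_controls_per_region=220, n_used_per_region=60, seed=5
    )
    study = generate_study(truth)
    ds = standardize(study.dataset, list(truth.behaviors["caching"].beta), reference="controls")
    return ds, truth


class TestRunPermutationAnalysis:
    def test_single_permutation_single_draw(self, recovery_study):
        ds, truth = recovery_study
        attrs = list(truth.behaviors["caching"].beta)
        pooled = run_permutation_analysis(ds, "caching", attrs, n_perm=1, seed=0)
        assert pooled.n_permutations_run == 1
        assert pooled.n_retained == 1
        assert pooled.pooled_draws.shape == (1, len(attrs) + 1)
        assert 0 <= pooled.mean_accuracy <= 1

    def test_seed_determinism_bit_identical(self, recovery_study):
        ds, truth = recovery_study
        attrs = list(truth.behaviors["caching"].beta)
        a = run_permutation_analysis(ds, "caching", attrs, n_perm=8, seed=3)
        b = run_permutation_analysis(ds, "caching", attrs, n_perm=8, seed=3)
        pd.testing.assert_frame_equal(a.pooled_draws, b.pooled_draws)
        pd.testing.assert_frame_equal(a.fixed_summary, b.fixed_summary)
        pd.testing.assert_frame_equal(a.random_summary, b.random_summary)
        assert a.mean_accuracy == b.mean_accuracy

    def test_focal_only_matches_full_run(self, small_study):
        ds = standardize(small_study.dataset, ["elevation", "slope", "distance_to_road"],
                         reference="controls")
        attrs = ["elevation", "slope", "distance_to_road"]
        full = run_study_analysis(ds, attrs, n_perm=6, seed=9)
        focal = run_permutation_analysis(ds, "caching", attrs, n_perm=6, seed=9, focal_only=True)
        pd.testing.assert_frame_equal(full["caching"].pooled_draws, focal.pooled_draws)

    def test_pooled_mean_converges_to_single_fit_glm(self):
        """One behavior and sigma^2 pinned at 0: every permutation assigns all
        controls, so pooled means approach the single GLM estimate."""
        used, ctrl, _ = simulate_glmm(11, n=700)
        used, ctrl = used.copy(), ctrl.copy()
        frame = pd.concat([used.assign(role="used", behavior="caching"),
                           ctrl.assign(role="control", behavior="none")], ignore_index=True)
        frame["record_id"] = [f"r{i}" for i in range(len(frame))]
        from rsfperm.dataset_io import AnalysisDataset
        ds = AnalysisDataset(frame=frame)
        pooled = run_study_analysis(ds, ["x0", "x1"], n_perm=150, seed=2)["caching"]
        resp = np.concatenate([np.ones(len(used)), np.zeros(len(ctrl))])
        df = pd.concat([used, ctrl])
        glm = sm.GLM(resp, sm.add_constant(df[["x0", "x1"]]), family=sm.families.Binomial()).fit()
        mc = 4 * pooled.fixed_summary["se"] / np.sqrt(pooled.n_retained)
        # mixed fit may estimate a small sigma^2 > 0; allow that wobble too
        assert np.all(np.abs(pooled.fixed_summary["mean"] - glm.params.values) <= mc + 0.05)

    def test_recovers_generating_coefficients(self, recovery_study):
        ds, truth = recovery_study
        beta = truth.behaviors["caching"].beta
        attrs = list(beta)
        pooled = run_permutation_analysis(ds, "caching", attrs, n_perm=40, seed=1)
        assert pooled.n_retained >= 35
        for attr, true_val in beta.items():
            got = pooled.fixed_summary.loc[attr]
            assert abs(got["mean"] - true_val) <= 2 * max(got["se"], 0.05), attr
            if abs(true_val) >= 0.5:
                assert np.sign(got["mean"]) == np.sign(true_val)
                assert got["p"] < 0.05

    def test_zero_retained_is_an_error(self, recovery_study):
        ds, truth = recovery_study
        # 30 fixed-effect columns of noise force unreasonable-split rejection
        ds2 = ds.copy()
        rng = np.random.default_rng(0)
        fake = [f"noise_{j}" for j in range(30)]
        controls_mask = ds2.frame["role"] == "control"
        keep = ds2.frame[controls_mask].sample(n=20, random_state=0).index
        ds2.frame = pd.concat([ds2.frame[~controls_mask], ds2.frame.loc[keep]])
        for name in fake:
            ds2.frame[name] = rng.normal(size=len(ds2.frame))
        with pytest.raises(RuntimeError, match="no retained permutations"):
            run_permutation_analysis(ds2, "caching", fake, n_perm=2, seed=0)
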