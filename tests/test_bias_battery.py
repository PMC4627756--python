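import math

import numpy as np
import pytest
from scipy import stats

from metasense import (
    MetaDataset,
    Study,
    cumulative_by_precision,
    funnel_contours,
    p_uniform,
    pet_peese,
    pool,
    run_battery,
    selection_model,
    tes,
    to_fisher_z,
    trim_and_fill,
)
from metasense.bias_battery import (
    VEVEA_WOODS_CUTPOINTS,
    VEVEA_WOODS_MODERATE_ONE_TAILED,
    VEVEA_WOODS_SEVERE_ONE_TAILED,
    _neg_log_q_sum,
)


def _suppressed_fixture() -> MetaDataset:
    """25 studies drawn from a one-tailed suppressed literature (true
    z = 0.08), regenerated deterministically; frozen external-oracle
    values below refer to exactly this corpus."""
    rng = np.random.default_rng(42)
    rows = []
    while len(rows) < 25:
        n = int(np.exp(rng.normal(np.log(120), 0.6)))
        n = max(n, 20)
        se = 1 / np.sqrt(n - 3)
        z = rng.normal(0.08, se)
        p = stats.norm.sf(z / se)
        if p < 0.05 or rng.uniform() < 0.2:
            rows.append((z, n))
    return MetaDataset(
        tuple(
            Study(f"s{i}", float(np.tanh(z)), n) for i, (z, n) in enumerate(rows)
        )
    )


class TestTrimAndFill:
    def test_symmetric_set_imputes_nothing(self):
        zs = [-0.2, -0.1, 0.0, 0.1, 0.2]
        ds = MetaDataset(
            tuple(Study(f"s{i}", float(np.tanh(z)), 103) for i, z in enumerate(zs))
        )
        tf = trim_and_fill(ds, side="left")
        assert tf.k0 == 0
        assert tf.adjusted_mean == pytest.approx(pool(ds).mean, abs=1e-12)

    def test_mirrored_twins_force_k0_zero(self, mixed_dataset):
        y, _ = mixed_dataset.effects("fisher_z")
        twins = [
            Study(f"m{i}", float(np.tanh(-z)), s.n)
            for i, (z, s) in enumerate(zip(y, mixed_dataset.studies))
        ]
        ds = MetaDataset(mixed_dataset.studies + tuple(twins))
        assert trim_and_fill(ds, side="left").k0 == 0
        assert trim_and_fill(ds, side="right").k0 == 0

    def test_hand_trace_of_rank_iteration(self):
        """Six-study toy (three precise at z~0.20, three noisy at
        0.5-0.7): the L0 iteration trims two, recenters at the FE mean of
        the remainder, and mirror-imputes; every quantity below is an
        independent step-by-step evaluation of the rank formulas."""
        z = [0.19, 0.20, 0.21, 0.5, 0.6, 0.7]
        n = [1003, 1003, 1003, 28, 28, 28]
        ds = MetaDataset(
            tuple(Study(f"t{i}", float(np.tanh(z[i])), n[i]) for i in range(6))
        )
        tf = trim_and_fill(ds, side="left")
        assert tf.k0 == 2
        # hand trace: FE center of all six is 0.20976 -> L0 = 2; after
        # trimming the two largest, center = (0.19+0.20+0.21)/3.025-weighted
        center = (1000 * (0.19 + 0.20 + 0.21) + 25 * 0.5) / (3 * 1000 + 25)
        assert tf.imputed_effects[0][0] == pytest.approx(2 * center - 0.6, abs=1e-9)
        assert tf.imputed_effects[1][0] == pytest.approx(2 * center - 0.7, abs=1e-9)
        # DL pooling of the eight effects, done longhand
        ya = np.array(z + [2 * center - 0.6, 2 * center - 0.7])
        va = np.array([1 / (x - 3) for x in n] + [0.04, 0.04])
        w = 1 / va
        mu_fe = np.sum(w * ya) / np.sum(w)
        Q = float(np.sum(w * (ya - mu_fe) ** 2))
        c = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (Q - 7) / c)
        w_re = 1 / (va + tau2)
        mu_re = float(np.sum(w_re * ya) / np.sum(w_re))
        assert to_fisher_z(tf.adjusted_mean) == pytest.approx(mu_re, abs=1e-10)

    def test_matches_external_oracle_on_suppressed_corpus(self):
        """k0 and DL-refit adjusted means frozen from an independent
        rank-based implementation run on the same 25-study corpus."""
        ds = _suppressed_fixture()
        left = trim_and_fill(ds, side="left")
        assert left.k0 == 0
        assert to_fisher_z(left.adjusted_mean) == pytest.approx(0.15142605, abs=1e-6)
        right = trim_and_fill(ds, side="right")
        assert right.k0 == 2
        assert to_fisher_z(right.adjusted_mean) == pytest.approx(0.16253114, abs=1e-6)

    def test_small_k_rejected(self):
        ds = MetaDataset((Study("a", 0.1, 50), Study("b", 0.2, 60)))
        with pytest.raises(ValueError):
            trim_and_fill(ds)


class TestSelectionModel:
    def test_unit_weights_recover_ml_pooled_mean(self, mixed_dataset):
        """With all weights 1 the weighted likelihood reduces to the
        ordinary RE likelihood, so mu-hat equals the ML pooled mean
        (frozen from an independent ML fit of this fixture)."""
        res = selection_model(
            mixed_dataset,
            cutpoints=VEVEA_WOODS_CUTPOINTS,
            weights=(1.0,) * len(VEVEA_WOODS_CUTPOINTS),
        )
        # independent grid-free oracle: maximise the plain RE log-likelihood
        y, v = mixed_dataset.effects("fisher_z")
        from scipy.optimize import minimize

        def nll(params):
            mu, log_t2 = params
            s2 = v + math.exp(log_t2)
            return 0.5 * float(np.sum(np.log(s2) + (y - mu) ** 2 / s2))

        ml = minimize(nll, x0=[0.15, math.log(0.005)], method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12})
        assert to_fisher_z(res.adjusted_mean) == pytest.approx(ml.x[0], abs=1e-5)

    def test_matches_external_oracle_fit(self):
        """Moderate and severe one-tailed fits on a 60-study unsuppressed
        corpus, frozen from an independent step-function selection-model
        implementation (mu on z scale, tau2, log-likelihood)."""
        from metasense import GeneratorConfig, generate_dataset

        ds = generate_dataset(GeneratorConfig(k_target=60, mu_z=0.15, tau=0.08, seed=7))
        mod = selection_model(ds, "moderate")
        assert to_fisher_z(mod.adjusted_mean) == pytest.approx(0.113306, abs=2e-4)
        assert mod.variance_component == pytest.approx(0.006749, abs=2e-4)
        assert mod.loglik == pytest.approx(40.3272, abs=2e-3)
        sev = selection_model(ds, "severe")
        assert to_fisher_z(sev.adjusted_mean) == pytest.approx(0.073961, abs=2e-4)
        assert sev.variance_component == pytest.approx(0.010153, abs=2e-4)

    def test_recovers_truth_under_matched_suppression(self):
        """Severe-suppressed corpus (true z mean 0.10, k=200): the severe
        model lands within 0.02 of the truth while the naive RE mean is
        biased upward by more than 0.03."""
        from metasense import generate_dataset
        from metasense.synthetic_data import suppression_experiment_config

        errs, naive = [], []
        for seed in (1, 2, 3):
            ds = generate_dataset(suppression_experiment_config(seed))
            errs.append(
                to_fisher_z(selection_model(ds, "severe").adjusted_mean) - 0.10034
            )
            naive.append(pool(ds).mean_on_scale - 0.10034)
        assert abs(np.mean(errs)) < 0.02
        assert np.mean(naive) > 0.03

    def test_single_interval_not_identified(self):
        # all extremely significant: every study lands in the first bin
        ds = MetaDataset(tuple(Study(f"s{i}", 0.6, 500) for i in range(5)))
        with pytest.raises(ValueError, match="single p-value interval"):
            selection_model(ds, "moderate")

    def test_weight_vectors_well_formed(self):
        for w in (VEVEA_WOODS_MODERATE_ONE_TAILED, VEVEA_WOODS_SEVERE_ONE_TAILED):
            assert len(w) == len(VEVEA_WOODS_CUTPOINTS)
            assert w[0] == 1.0
            assert all(b <= a for a, b in zip(w, w[1:]))  # non-increasing


class TestPetPeese:
    def test_three_point_wls_closed_form(self):
        """(r, SE) = (.10, .05), (.14, .10), (.20, .15): intercepts from
        the closed-form weighted normal equations."""
        r = np.array([0.10, 0.14, 0.20])
        se = np.array([0.05, 0.10, 0.15])
        studies = tuple(
            Study(f"s{i}", float(r[i]), 50, se_override=float(se[i]))
            for i in range(3)
        )
        ds = MetaDataset(studies)
        res = pet_peese(ds)

        def wls_intercept(x):
            w = 1 / se**2
            X = np.column_stack([np.ones(3), x])
            beta = np.linalg.solve(X.T @ (X * w[:, None]), (X * w[:, None]).T @ r)
            return beta

        b_pet = wls_intercept(se)
        b_peese = wls_intercept(se**2)
        assert res.pet_estimate == pytest.approx(b_pet[0], abs=1e-10)
        assert res.slope_pet == pytest.approx(b_pet[1], abs=1e-10)
        assert res.peese_estimate == pytest.approx(b_peese[0], abs=1e-10)
        assert res.slope_peese == pytest.approx(b_peese[1], abs=1e-10)

    def test_zero_slope_for_constant_effects(self):
        ds = MetaDataset(
            tuple(Study(f"s{i}", 0.2, n) for i, n in enumerate([40, 80, 160, 320]))
        )
        res = pet_peese(ds)
        assert res.slope_pet == pytest.approx(0.0, abs=1e-10)
        assert res.pet_estimate == pytest.approx(0.2, abs=1e-10)

    def test_selection_rule(self):
        """PEESE is selected iff PET's one-tailed p falls below alpha."""
        rng = np.random.default_rng(3)
        n = rng.integers(20, 400, size=40)
        z = rng.normal(0.3, np.sqrt(1 / (n - 3)))
        ds = MetaDataset(
            tuple(
                Study(f"s{i}", float(np.tanh(z[i])), int(n[i])) for i in range(40)
            )
        )
        res = pet_peese(ds, alpha=0.05)
        expected = res.peese_estimate if res.pet_p_one_tailed < 0.05 else res.pet_estimate
        assert res.selected == expected
        forced = pet_peese(ds, alpha=1.0)  # always "significant"
        assert forced.selected == forced.peese_estimate

    def test_constant_se_rejected(self):
        ds = MetaDataset(tuple(Study(f"s{i}", 0.1 + 0.05 * i, 100) for i in range(4)))
        with pytest.raises(ValueError, match="collinear"):
            pet_peese(ds)


class TestPUniform:
    def test_conditional_probabilities_uniform_at_truth(self):
        """At the generating mu the conditional exceedance probabilities
        are Uniform(0,1): their mean over 2000 simulated significant
        studies is 1/2 up to Monte-Carlo error."""
        rng = np.random.default_rng(5)
        mu, n = 0.2, 100
        sd = 1 / math.sqrt(n - 3)
        zcrit = stats.norm.isf(0.05) * sd
        zs = []
        while len(zs) < 2000:
            z = rng.normal(mu, sd, size=4000)
            zs.extend(z[z > zcrit].tolist())
        zs = np.array(zs[:2000])
        q = stats.norm.sf((zs - mu) / sd) / stats.norm.sf((zcrit - mu) / sd)
        assert np.mean(q) == pytest.approx(0.5, abs=3 * 0.29 / math.sqrt(2000))

    def test_objective_monotone_decreasing_in_mu(self, mixed_dataset):
        y, v = mixed_dataset.effects("fisher_z")
        sd = np.sqrt(v)
        zcrit = stats.norm.isf(0.05) * sd
        sig = y > zcrit
        grid = np.linspace(-0.5, 1.0, 61)
        vals = [_neg_log_q_sum(m, y[sig], sd[sig], zcrit[sig]) for m in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_root_matches_grid_scan(self):
        """Single significant study far above its threshold: the solver's
        root agrees with a brute-force scan of the moment condition, and
        the estimate sits near the observed effect."""
        ds = MetaDataset((Study("big", float(np.tanh(0.5)), 103),
                          Study("null", 0.01, 103)))
        res = p_uniform(ds)
        assert res.k_sig == 1
        sd = math.sqrt(0.01)
        zcrit = stats.norm.isf(0.05) * sd
        grid = np.linspace(-0.5, 1.2, 20001)
        vals = np.array([_neg_log_q_sum(m, np.array([0.5]), np.array([sd]),
                                        np.array([zcrit])) for m in grid])
        root_grid = grid[np.argmin(np.abs(vals - 1.0))]
        assert to_fisher_z(res.estimate) == pytest.approx(root_grid, abs=2e-4)
        assert abs(to_fisher_z(res.estimate) - 0.5) < 3 * sd

    def test_ci_brackets_estimate(self, mixed_dataset):
        res = p_uniform(mixed_dataset)
        assert res.ci95[0] < res.estimate < res.ci95[1]

    def test_no_significant_studies_rejected(self):
        ds = MetaDataset(tuple(Study(f"s{i}", 0.01, 30) for i in range(5)))
        with pytest.raises(ValueError, match="significant"):
            p_uniform(ds)


class TestTes:
    def test_all_powers_one_and_all_significant_gives_p_one(self):
        ds = MetaDataset(tuple(Study(f"s{i}", 0.5, 400) for i in range(6)))
        res = tes(ds, rho_hat=0.5)
        assert res.observed_sig == 6
        assert res.expected_sig == pytest.approx(6.0, abs=1e-6)
        assert res.p_tes == pytest.approx(1.0, abs=1e-6)

    def test_statistic_matches_direct_formula(self):
        """Five studies engineered so three are significant and per-study
        power is ~0.3: A = (O-E)^2/E + (O-E)^2/(k-E), p from the
        chi-square(1) tail, both evaluated independently here."""
        sd = 0.1
        theta = 1.4356283 * sd  # power ~ 0.30 at two-sided alpha = .05
        rho = math.tanh(theta)
        zs = [0.3, 0.3, 0.3, 0.05, 0.05]
        ds = MetaDataset(
            tuple(Study(f"s{i}", float(math.tanh(z)), 103) for i, z in enumerate(zs))
        )
        res = tes(ds, rho_hat=rho)
        zc = stats.norm.isf(0.025)
        power = stats.norm.sf(zc - theta / sd) + stats.norm.cdf(-zc - theta / sd)
        E = 5 * power
        O = 3
        A = (O - E) ** 2 / E + (O - E) ** 2 / (5 - E)
        assert res.observed_sig == O
        assert res.expected_sig == pytest.approx(E, abs=1e-9)
        assert res.statistic == pytest.approx(A, abs=1e-9)
        assert res.p_tes == pytest.approx(float(stats.chi2.sf(A, 1)), abs=1e-12)

    def test_default_rho_is_pooled_mean(self, mixed_dataset):
        assert (
            tes(mixed_dataset).expected_sig
            == tes(mixed_dataset, rho_hat=pool(mixed_dataset).mean).expected_sig
        )

    def test_saturated_boundary(self):
        ds = MetaDataset(tuple(Study(f"s{i}", 0.8, 400) for i in range(5)))
        res = tes(ds, rho_hat=0.8)
        assert res.p_tes == pytest.approx(1.0)


class TestCumulative:
    def test_identical_studies_flat(self, homogeneous_dataset):
        steps = cumulative_by_precision(homogeneous_dataset)
        assert all(s.mean == pytest.approx(0.25, abs=1e-12) for s in steps)

    def test_structure_and_final_step(self, mixed_dataset):
        steps = cumulative_by_precision(mixed_dataset)
        assert len(steps) == mixed_dataset.k
        ns = [s.n_cum for s in steps]
        assert ns == sorted(ns) and len(set(ns)) == len(ns)
        assert steps[0].k_cum == 1 and steps[0].n_cum == 300  # largest study first
        assert steps[-1].mean == pytest.approx(pool(mixed_dataset).mean, abs=1e-12)

    def test_two_studies(self):
        ds = MetaDataset((Study("a", 0.1, 200), Study("b", 0.3, 50)))
        steps = cumulative_by_precision(ds)
        assert len(steps) == 2
        assert steps[0].mean == pytest.approx(0.1)
        assert steps[1].mean == pytest.approx(pool(ds).mean, abs=1e-12)

    def test_drift_under_suppression(self):
        """Suppressed corpora drift toward larger means as small studies
        enter (final mean above the first-quartile step, on average)."""
        from metasense import generate_dataset
        from metasense.synthetic_data import suppression_experiment_config

        drifts = []
        for seed in range(8):
            ds = generate_dataset(suppression_experiment_config(seed, k=100))
            steps = cumulative_by_precision(ds)
            drifts.append(steps[-1].mean - steps[len(steps) // 4].mean)
        assert np.mean(drifts) > 0


class TestFunnelContours:
    def test_boundary_at_known_se(self, mixed_dataset):
        contour, _ = funnel_contours(mixed_dataset)
        lo, hi = contour.boundary(0.05, 0.10)
        assert hi == pytest.approx(1.959964 * 0.10, abs=1e-6)
        assert lo == pytest.approx(-hi)

    def test_marginal_classification(self, mixed_dataset):
        contour, _ = funnel_contours(mixed_dataset)
        # |effect|/SE = 1.7: two-sided p ~ .089, between .05 and .10
        assert contour.classify(0.17, 0.10) == "marginal"
        assert contour.classify(0.30, 0.10) == "significant"
        assert contour.classify(0.05, 0.10) == "clear"

    def test_boundary_widens_with_se(self, mixed_dataset):
        contour, _ = funnel_contours(mixed_dataset)
        widths = [contour.boundary(0.05, se)[1] for se in (0.05, 0.10, 0.20)]
        assert widths[0] < widths[1] < widths[2]

    def test_frame_has_one_row_per_study(self, mixed_dataset):
        _, frame = funnel_contours(mixed_dataset)
        assert len(frame) == mixed_dataset.k
        assert set(frame["region"]) <= {"clear", "marginal", "significant"}


class TestBatteryGate:
    def test_small_distribution_reports_pooling_only(self):
        ds = MetaDataset(tuple(Study(f"s{i}", 0.1 + 0.02 * i, 60) for i in range(7)))
        row = run_battery(ds)
        assert row.skipped_reason is not None
        assert row.pooled is not None and row.osr is not None
        assert row.trim_fill is None and row.petpeese is None

    def test_full_battery_above_gate(self, mixed_dataset):
        row = run_battery(mixed_dataset)
        assert row.skipped_reason is None
        assert row.trim_fill is not None
        assert row.sm_moderate is not None and row.sm_severe is not None
        assert row.petpeese is not None and row.tes_result is not None
        assert row.cumulative is not None and len(row.cumulative) == mixed_dataset.k
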