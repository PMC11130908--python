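"""Tests for design assembly, NNLS fitting and cross-validated selection."""

import itertools

import numpy as np
import pytest
from scipy.optimize import nnls as scipy_nnls

import tetflux as tf
from tetflux.errors import ConditioningWarning, DegenerateSystemError, ValidationError
from tetflux.selection import DesignSystem, assemble_design, fit_nnls


def brute_force_nnls(A, b):
    """Global NNLS optimum by exhaustive active-set enumeration.

    For every support subset solve the unconstrained least squares on
    those columns; any solution with non-negative entries is feasible for
    the original problem, and the optimum's own support appears among the
    subsets, so the feasible minimum is the global one.
    """
    n = A.shape[1]
    best_x, best_r = np.zeros(n), float(np.linalg.norm(b))
    for size in range(1, n + 1):
        for support in itertools.combinations(range(n), size):
            sol, *_ = np.linalg.lstsq(A[:, support], b, rcond=None)
            if np.any(sol < -1e-12):
                continue
            x = np.zeros(n)
            x[list(support)] = np.clip(sol, 0, None)
            r = float(np.linalg.norm(A @ x - b))
            if r < best_r - 1e-12:
                best_x, best_r = x, r
    return best_x, best_r


def make_system(A, b):
    A = np.asarray(A, dtype=float)
    return DesignSystem(
        A=A,
        b=np.asarray(b, dtype=float),
        columns=[f"c{i}" for i in range(A.shape[1])],
        row_labels=[f"r{i}" for i in range(A.shape[0])],
        structure=tf.ModelStructure.full(),
        tie_aid=True,
    )


class TestAssembleDesign:
    def test_single_line_full_structure_shape(self, noiseless_dataset):
        dataset, _ = noiseless_dataset
        one = dataset.subset([0])
        with pytest.warns(ConditioningWarning):
            system = tf.assemble_design(one, tf.ModelStructure.full())
        assert system.A.shape == (6, 14)
        assert system.columns == [
            "k1_TET1", "k1_TET2", "k1_TET3", "k2_TET1", "k2_TET2", "k2_TET3",
            "k3_TET1", "k3_TET2", "k3_TET3", "k4", "k5", "kAID", "kSMUG", "kTDG",
        ]
        # only the methylation-influx row has a right-hand side
        b = system.b
        assert b[0] == pytest.approx(dataset.enzymes[0].dnmt1)
        assert np.all(b[1:] == 0.0)

    def test_untied_aid_adds_one_column(self, noiseless_dataset):
        dataset, _ = noiseless_dataset
        # splitting the AID affinity leaves the dU-loop pair (kAID_C, kTDG)
        # identified only up to scale, so the design is rank-deficient
        with pytest.warns(ConditioningWarning):
            system = tf.assemble_design(dataset, tf.ModelStructure.full(), tie_aid=False)
        assert system.A.shape == (30, 15)
        assert "kAID_hmdC" in system.columns and "kAID_C" in system.columns

    def test_second_balance_row_coefficients(self):
        enz = tf.EnzymeProfile(dnmt1=1, tet1=1, tet2=1, tet3=1, aid=2.5, smug1=1, tdg=1)
        obs = tf.ModificationState(2, 3, 0, 0, 0, 0)
        dataset = tf.CellLineDataset(cell_lines=["A"], enzymes=[enz], observations=[obs])
        with pytest.warns(ConditioningWarning):
            system = tf.assemble_design(dataset, tf.ModelStructure.full())
        row = dict(zip(system.columns, system.A[1]))
        for t in tf.TETS:
            assert row[f"k1_{t}"] == pytest.approx(2.0)
            assert row[f"k2_{t}"] == pytest.approx(-3.0)
        assert row["kAID"] == pytest.approx(-3.0 * 2.5)
        assert row["k4"] == row["k5"] == row["kSMUG"] == row["kTDG"] == 0.0
        assert system.b[1] == 0.0

    def test_noiseless_truth_is_exact_solution(self, noiseless_dataset):
        dataset, truth = noiseless_dataset
        system = tf.assemble_design(dataset, truth.structure)
        k_true = {
            "k1_TET1": truth.params.k1_tet1, "k1_TET2": truth.params.k1_tet2,
            "k2_TET1": truth.params.k2_tet1, "k2_TET3": truth.params.k2_tet3,
            "k3_TET2": truth.params.k3_tet2, "k3_TET3": truth.params.k3_tet3,
            "k4": truth.params.k4, "k5": truth.params.k5,
            "kAID": truth.params.k_aid_hmdc,
            "kSMUG": truth.params.k_smug, "kTDG": truth.params.k_tdg,
        }
        x = np.array([k_true[c] for c in system.columns])
        residual = system.A @ x - system.b
        assert np.max(np.abs(residual)) < 1e-10

    def test_structure_design_is_column_subset_of_full(self, noiseless_dataset):
        dataset, truth = noiseless_dataset
        full_sys = tf.assemble_design(dataset, tf.ModelStructure.full())
        sub_sys = tf.assemble_design(dataset, truth.structure)
        idx = [full_sys.columns.index(c) for c in sub_sys.columns]
        np.testing.assert_array_equal(full_sys.A[:, idx], sub_sys.A)
        np.testing.assert_array_equal(full_sys.b, sub_sys.b)

    def test_missing_required_observation_rejected(self, noiseless_dataset):
        dataset, _ = noiseless_dataset
        mask = dataset.observed_mask.copy()
        mask[tf.SPECIES.index("fdC")] = False
        broken = tf.CellLineDataset(
            cell_lines=dataset.cell_lines, enzymes=dataset.enzymes,
            observations=dataset.observations, observed_mask=mask,
        )
        with pytest.raises(ValidationError, match="fdC"):
            tf.assemble_design(broken, tf.ModelStructure.full())

    def test_unobserved_u_drops_balance_row(self, noiseless_dataset):
        dataset, _ = noiseless_dataset
        mask = dataset.observed_mask.copy()
        mask[tf.SPECIES.index("U")] = False
        no_u = tf.CellLineDataset(
            cell_lines=dataset.cell_lines, enzymes=dataset.enzymes,
            observations=dataset.observations, observed_mask=mask,
        )
        with pytest.warns(ConditioningWarning):
            # without the dU balance, kTDG is unconstrained -> rank deficient
            system = tf.assemble_design(no_u, tf.ModelStructure.full())
        assert system.A.shape[0] == 5 * dataset.n_lines

    def test_proportional_profiles_warn_rank_deficient(self):
        enz = tf.EnzymeProfile(dnmt1=0.1, tet1=0.1, tet2=0.5, tet3=0.01,
                               aid=0.01, smug1=1.0, tdg=0.2, cell_line_id="A")
        scaled = tf.EnzymeProfile(dnmt1=0.2, tet1=0.2, tet2=1.0, tet3=0.02,
                                  aid=0.02, smug1=2.0, tdg=0.4, cell_line_id="B")
        params = tf.DEFAULT_TRUE_PARAMS.masked(tf.DEFAULT_STRUCTURE)
        obs = [tf.steady_state(e, params, tf.DEFAULT_STRUCTURE) for e in (enz, scaled)]
        dataset = tf.CellLineDataset(cell_lines=["A", "B"], enzymes=[enz, scaled],
                                     observations=obs)
        with pytest.warns(ConditioningWarning):
            tf.assemble_design(dataset, tf.ModelStructure.full())


class TestFitNNLS:
    def test_nonnegativity_clipping(self):
        result = fit_nnls(make_system(np.eye(2), [1.0, -1.0]))
        assert result.coefficients["c0"] == pytest.approx(1.0)
        assert result.coefficients["c1"] == 0.0
        assert result.residual_norm == pytest.approx(1.0)

    def test_interior_solution_equals_ols(self):
        result = fit_nnls(make_system([[1, 0], [0, 1], [1, 1]], [1, 1, 3]))
        assert result.coefficients["c0"] == pytest.approx(4 / 3)
        assert result.coefficients["c1"] == pytest.approx(4 / 3)

    def test_all_zero_design_rejected(self):
        with pytest.raises(DegenerateSystemError):
            fit_nnls(make_system(np.zeros((3, 2)), [1, 2, 3]))

    def test_matches_bruteforce_active_set(self):
        rng = np.random.default_rng(61)
        for _ in range(60):
            m = int(rng.integers(2, 7))
            n = int(rng.integers(1, 5))
            A = rng.normal(size=(m, n))
            b = rng.normal(size=m)
            x, r = scipy_nnls(A, b)
            bx, br = brute_force_nnls(A, b)
            assert r == pytest.approx(br, abs=1e-8)
            np.testing.assert_allclose(A @ x, A @ bx, atol=1e-7)


class TestPerformanceIndex:
    def test_perfect_predictions_score_zero(self):
        obs = [tf.ModificationState(1, 2, 3, 4, 5, 6)] * 3
        assert tf.performance_index(obs, obs) == 0.0

    def test_half_square_of_single_residual(self):
        a = [tf.ModificationState(2, 0, 0, 0, 0, 0)]
        b = [tf.ModificationState(4, 0, 0, 0, 0, 0)]
        assert tf.performance_index(a, b) == pytest.approx(2.0)

    def test_uniform_residual_closed_form(self):
        r = 0.3
        pred = [tf.ModificationState(*([1 + r] * 6)) for _ in range(5)]
        obs = [tf.ModificationState(*([1.0] * 6)) for _ in range(5)]
        assert tf.performance_index(pred, obs) == pytest.approx(15 * r**2)

    def test_length_mismatch_rejected(self):
        a = [tf.ModificationState(1, 1, 1, 1, 1, 1)]
        with pytest.raises(ValidationError):
            tf.performance_index(a, a * 2)


class TestCrossValidation:
    def test_noiseless_true_structure_scores_zero(self, noiseless_dataset):
        dataset, truth = noiseless_dataset
        score = tf.cross_validate_structure(dataset, truth.structure)
        assert score.n_folds == 5
        assert score.j_cv < 1e-12

    def test_invariant_to_cell_line_order(self, noiseless_dataset):
        dataset, truth = noiseless_dataset
        perm = [3, 1, 4, 0, 2]
        shuffled = dataset.subset(perm)
        a = tf.cross_validate_structure(dataset, truth.structure).j_cv
        b = tf.cross_validate_structure(shuffled, truth.structure).j_cv
        assert a == pytest.approx(b, abs=1e-18)

    def test_two_lines_minimum(self, noiseless_dataset):
        dataset, truth = noiseless_dataset
        with pytest.raises(ValidationError):
            tf.cross_validate_structure(dataset.subset([0]), truth.structure)

    def test_parameter_recovery_from_noiseless_data(self, noiseless_dataset):
        dataset, truth = noiseless_dataset
        system = tf.assemble_design(dataset, truth.structure)
        result = tf.fit_nnls(system)
        fitted = result.params
        for name, true_value in truth.params.to_dict().items():
            if true_value > 0:
                rel = abs(getattr(fitted, name) - true_value) / true_value
                assert rel < 1e-6, name
            else:
                assert getattr(fitted, name) == 0.0


class TestRanking:
    def test_noiseless_generating_structure_ranks_first(self, noiseless_dataset):
        dataset, truth = noiseless_dataset
        scores = tf.rank_structures(dataset)
        assert len(scores) == 343
        js = [s.j_cv if s.j_cv >= 1e-12 else 0.0 for s in scores]
        assert js == sorted(js)
        assert scores[0].code == tf.encode(truth.structure)

    def test_ranking_ties_broken_by_code(self, noiseless_dataset):
        dataset, _ = noiseless_dataset
        scores = tf.rank_structures(dataset)
        tied = [s.code for s in scores if s.j_cv < 1e-12]
        assert tied == sorted(tied)

    def test_single_structure_cv_agrees_with_ranking(self, noiseless_dataset):
        dataset, _ = noiseless_dataset
        scores = tf.rank_structures(dataset)
        probe = scores[40]
        solo = tf.cross_validate_structure(dataset, probe.structure)
        assert solo.j_cv == pytest.approx(probe.j_cv, rel=1e-12, abs=1e-18)


class TestResubstitution:
    def test_zero_on_noiseless_truth(self, noiseless_dataset):
        dataset, truth = noiseless_dataset
        result = tf.resubstitution_fit(dataset, truth.structure)
        assert result.resubstitution_mse < 1e-20

    def test_full_structure_residual_never_worse_than_substructure(self):
        # the sub-structure's feasible set is contained in the full one's,
        # so the full-structure NNLS residual cannot exceed it
        config = tf.GeneratorConfig(noise_cv=0.08, seed=19)
        dataset, _ = tf.generate_dataset(config)
        full_res = tf.fit_nnls(tf.assemble_design(dataset, tf.ModelStructure.full()))
        rng = np.random.default_rng(7)
        for code in rng.choice(343, size=12, replace=False):
            sub = tf.decode(int(code))
            sub_res = tf.fit_nnls(tf.assemble_design(dataset, sub, warn_conditioning=False))
            assert full_res.residual_norm <= sub_res.residual_norm + 1e-10

    def test_resubstitution_optimism_vs_cross_validation(self):
        # training MSE should not exceed the CV analogue on the same data
        config = tf.GeneratorConfig(noise_cv=0.05, seed=29)
        dataset, truth = tf.generate_dataset(config)
        res = tf.resubstitution_fit(dataset, truth.structure)
        cv = tf.cross_validate_structure(dataset, truth.structure)
        cv_mse = 2 * cv.j_cv / (cv.n_folds * cv.n_states)
        assert res.resubstitution_mse <= cv_mse


class TestPredictHoldout:
    def test_ground_truth_params_reproduce_heldout_state(self, noiseless_dataset):
        dataset, truth = noiseless_dataset
        for enz, obs in zip(dataset.enzymes, dataset.observations):
            pred = tf.predict_holdout(truth.params, enz, truth.structure)
            np.testing.assert_allclose(pred.as_array(), obs.as_array(), rtol=1e-12)

    def test_agrees_with_long_integration(self, noiseless_dataset):
        dataset, truth = noiseless_dataset
        enz = dataset.enzymes[2]
        pred = tf.predict_holdout(truth.params, enz, truth.structure)
        traj = tf.simulate(tf.ModificationState(0, 0, 0, 0, 0, 0), enz, truth.params,
                           truth.structure, horizon=5000.0, n_points=5)
        np.testing.assert_allclose(traj.states[-1], pred.as_array(), rtol=1e-6)

    def test_zero_removal_policy(self):
        enz = tf.EnzymeProfile(dnmt1=1, tet1=1, tet2=1, tet3=1, aid=1, smug1=1, tdg=1)
        params = tf.RateParameters(k_dnmt1=1, k1_tet1=1, k2_tet1=1, k3_tet1=1,
                                   k4=1, k5=1, k_aid_hmdc=1, k_aid_c=1,
                                   k_smug=0.0, k_tdg=1)
        structure = tf.ModelStructure(s1={"TET1"}, s2={"TET1"}, s3={"TET1"})
        pred = tf.predict_holdout(params, enz, structure, policy="zero")
        assert pred.hmdU == 0.0
        with pytest.raises(tf.NoFiniteSteadyStateError):
            tf.predict_holdout(params, enz, structure, policy="raise")
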