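"""The five classifiers and the alternating split, checked against
independent brute-force oracles on hand-sized instances."""

import numpy as np
import pytest

from mirclass import (
    fit_discriminant,
    fit_margin,
    fit_model,
    generate_cohort,
    flatten_cohort,
    make_grid,
    predict_discriminant,
    predict_margin,
    predict_model,
    predict_table,
    split_alternating,
)
from mirclass.classify import nu_feasibility_bound

from conftest import table_from_arrays


def _labeled_table(X, y, grid, roles=None):
    X = np.asarray(X, dtype=float)
    return table_from_arrays(
        X,
        grid,
        patient_ids=[f"{lab}-p" for lab in y],
        subtypes=list(y),
        roles=roles or ["train"] * len(X),
    )


def _grid_for(p):
    """A p-channel axis for toy feature spaces (p = 1 is a degenerate
    single-channel grid)."""
    return make_grid(1000 + 8 * (p - 1), 1000, 8)


class TestSplit:
    def test_even_positions_train(self, grid10, rng):
        table = table_from_arrays(rng.normal(size=(6, 10)), grid10)
        split = split_alternating(table)
        assert list(split.meta["role"]) == ["train", "test"] * 3

    def test_split_balanced_per_patient(self, tiny_config):
        split = split_alternating(flatten_cohort(generate_cohort(tiny_config)))
        for _, grp in split.meta.groupby("patient_id"):
            n_train = (grp["role"] == "train").sum()
            n_test = (grp["role"] == "test").sum()
            assert abs(n_train - n_test) <= 1
            assert n_train + n_test == len(grp)

    def test_half_of_3840_each(self):
        """A full-size 40x96 image splits into 1,920 train + 1,920 test."""
        import pandas as pd
        from mirclass import SpectrumTable

        grid = _grid_for(2)
        n = 3840
        meta = pd.DataFrame(
            {
                "patient_id": "P1",
                "subtype": "SQ",
                "row": np.repeat(np.arange(40), 96),
                "col": np.tile(np.arange(96), 40),
                "role": "unassigned",
            }
        )
        table = SpectrumTable(np.zeros((n, 2)), grid, meta)
        split = split_alternating(table)
        assert (split.meta["role"] == "train").sum() == 1920
        assert (split.meta["role"] == "test").sum() == 1920

    def test_empty_table_passes_through(self, grid10):
        table = table_from_arrays(np.empty((0, 10)), grid10)
        assert split_alternating(table).n_spectra == 0


class TestDiscriminantFit:
    def test_pooled_variance_hand_example(self):
        """Two 1-D classes {0,0,2,2} and {8,8,10,10}: means 1 and 9,
        pooled unbiased variance (4 + 4) / (8 - 2) = 4/3."""
        grid = _grid_for(1)
        X = np.array([[0.0], [0.0], [2.0], [2.0], [8.0], [8.0], [10.0], [10.0]])
        y = ["LUAD"] * 4 + ["SQ"] * 4
        model = fit_discriminant(_labeled_table(X, y, grid), "linear", ridge_eps=0.0)
        assert model.labels == ["LUAD", "SQ"]
        np.testing.assert_allclose(model.means[:, 0], [1.0, 9.0])
        assert model.covariances[0][0, 0] == pytest.approx(4.0 / 3.0)

    def test_identical_classes_score_equally(self, rng):
        grid = _grid_for(3)
        Xc = rng.normal(size=(10, 3))
        X = np.vstack([Xc, Xc])
        y = ["LUAD"] * 10 + ["SQ"] * 10
        model = fit_discriminant(_labeled_table(X, y, grid), "linear")
        from mirclass.classify import discriminant_scores

        q = rng.normal(size=(5, 3))
        s = discriminant_scores(model, q)
        np.testing.assert_allclose(s[:, 0], s[:, 1], atol=1e-10)
        # ties resolve to the lexicographically smaller label
        assert set(predict_discriminant(model, q)) == {"LUAD"}

    def test_singular_covariance_requires_ridge(self):
        grid = _grid_for(2)
        # duplicated feature -> rank-1 covariance
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0],
                      [5.0, 5.0], [6.0, 6.0], [7.0, 7.0]])
        y = ["LUAD"] * 3 + ["SQ"] * 3
        with pytest.raises(ValueError, match="singular"):
            fit_discriminant(_labeled_table(X, y, grid), "quadratic", ridge_eps=0.0)
        model = fit_discriminant(_labeled_table(X, y, grid), "quadratic", ridge_eps=1e-6)
        assert model.ridge_eps == 1e-6

    def test_absent_class_named_in_error(self, rng):
        grid = _grid_for(2)
        X = rng.normal(size=(4, 2))
        roles = ["train", "train", "test", "test"]
        # SQ only appears in test rows
        table = _labeled_table(X, ["LUAD", "LUAD", "SQ", "SQ"], grid, roles=roles)
        # need >= 2 training classes: add SCLC train rows
        import pandas as pd

        X2 = np.vstack([X, rng.normal(size=(2, 2))])
        table = _labeled_table(
            X2, ["LUAD", "LUAD", "SQ", "SQ", "SCLC", "SCLC"], grid,
            roles=roles + ["train", "train"],
        )
        with pytest.raises(ValueError, match="'SQ'"):
            fit_discriminant(table, "linear")


class TestDiscriminantPredict:
    @pytest.mark.parametrize("variant", ["linear", "quadratic", "mahalanobis"])
    def test_class_mean_classified_to_its_class(self, variant, rng):
        grid = _grid_for(4)
        X = np.vstack([
            rng.normal(loc=m, scale=0.3, size=(12, 4))
            for m in (0.0, 3.0, 6.0)
        ])
        y = ["LUAD"] * 12 + ["SCLC"] * 12 + ["SQ"] * 12
        model = fit_discriminant(_labeled_table(X, y, grid), variant)
        preds = predict_discriminant(model, model.means)
        assert list(preds) == model.labels

    def test_midpoint_tie_goes_to_lexicographically_smaller(self):
        grid = _grid_for(1)
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = ["SQ", "SQ", "LUAD", "LUAD"]
        model = fit_discriminant(_labeled_table(X, y, grid), "linear")
        assert predict_discriminant(model, np.array([[0.0]]))[0] == "LUAD"

    @pytest.mark.parametrize("variant", ["linear", "quadratic", "mahalanobis"])
    def test_matches_direct_formula_oracle(self, variant, rng):
        """Oracle: evaluate each variant's discriminant formula per class per
        query with plain inv/det calls, no shared code path."""
        grid = _grid_for(5)
        X = rng.normal(size=(40, 5)) + np.repeat(
            np.array([[0.0], [1.5], [3.0]]), [14, 13, 13], axis=0
        )
        y = ["LUAD"] * 14 + ["SCLC"] * 13 + ["SQ"] * 13
        model = fit_discriminant(_labeled_table(X, y, grid), variant, ridge_eps=1e-6)
        queries = rng.normal(size=(10, 5)) + 1.5

        def oracle_label(x):
            best, best_score = None, None
            for k, lab in enumerate(model.labels):
                mu, cov, pi = model.means[k], model.covariances[k], model.priors[k]
                inv = np.linalg.inv(cov)
                if variant == "linear":
                    score = x @ inv @ mu - 0.5 * mu @ inv @ mu + np.log(pi)
                elif variant == "quadratic":
                    _, logdet = np.linalg.slogdet(cov)
                    score = (
                        -0.5 * logdet
                        - 0.5 * (x - mu) @ inv @ (x - mu)
                        + np.log(pi)
                    )
                else:
                    score = -((x - mu) @ inv @ (x - mu))
                if best_score is None or score > best_score + 1e-12:
                    best, best_score = lab, score
            return best

        preds = predict_discriminant(model, queries)
        assert list(preds) == [oracle_label(x) for x in queries]

    def test_channel_mismatch_rejected(self, rng):
        grid = _grid_for(3)
        X = rng.normal(size=(12, 3))
        y = ["LUAD"] * 6 + ["SQ"] * 6
        model = fit_discriminant(_labeled_table(X, y, grid), "linear")
        with pytest.raises(ValueError, match="channels"):
            predict_discriminant(model, rng.normal(size=(2, 4)))


class TestMarginFit:
    def test_two_point_maximum_margin(self):
        """Points -1 / +1 with C=1: boundary at 0, margin 2, both support
        vectors with dual coefficients +-1/2."""
        grid = _grid_for(1)
        X = np.array([[-1.0], [1.0]])
        y = ["LUAD", "SQ"]
        model = fit_margin(_labeled_table(X, y, grid), "c_svc", 1.0)
        (m,) = model.machines
        assert m.decision(np.array([[0.0]]))[0] == pytest.approx(0.0, abs=1e-6)
        assert abs(m.w[0]) == pytest.approx(1.0, abs=1e-6)  # margin 2/|w| = 2
        assert len(m.support_indices) == 2
        np.testing.assert_allclose(sorted(m.dual_coef), [-0.5, 0.5], atol=1e-6)

    def test_separable_toy_zero_training_errors(self, rng):
        grid = _grid_for(2)
        left = rng.normal(size=(4, 2)) * 0.2 + [-2, 0]
        right = rng.normal(size=(4, 2)) * 0.2 + [2, 0]
        X = np.vstack([left, right])
        y = ["LUAD"] * 4 + ["SQ"] * 4
        table = _labeled_table(X, y, grid)
        model = fit_margin(table, "c_svc", 1000.0)
        assert list(predict_margin(model, X)) == y

    def test_dual_qp_oracle(self):
        """8-point binary toy: alphas and the dual objective match an
        independent SLSQP solve of the soft-margin dual."""
        from scipy.optimize import minimize

        grid = _grid_for(2)
        X = np.array([
            [-1.5, 0.2], [-1.0, -0.4], [-2.0, 0.6], [-0.3, 0.1],
            [1.2, -0.1], [0.8, 0.5], [1.9, -0.6], [0.2, -0.2],
        ])
        y_lab = ["LUAD"] * 4 + ["SQ"] * 4
        C = 1.0
        model = fit_margin(_labeled_table(X, y_lab, grid), "c_svc", C)
        (machine,) = model.machines

        y = np.array([-1.0] * 4 + [1.0] * 4)  # SQ (lex larger) is +1
        K = (X @ X.T) * np.outer(y, y)

        def neg_dual(a):
            return 0.5 * a @ K @ a - a.sum()

        res = minimize(
            neg_dual,
            np.full(8, 0.1),
            bounds=[(0, C)] * 8,
            constraints={"type": "eq", "fun": lambda a: a @ y},
            method="SLSQP",
            options={"ftol": 1e-12, "maxiter": 1000},
        )
        assert res.success
        alpha = res.x

        impl_alpha = np.zeros(8)
        impl_alpha[machine.support_indices] = np.abs(machine.dual_coef)
        np.testing.assert_allclose(impl_alpha, alpha, atol=1e-4)
        np.testing.assert_allclose(-neg_dual(impl_alpha), -res.fun, atol=1e-4)
        # and the primal weight vector agrees with w = sum alpha_i y_i x_i
        np.testing.assert_allclose(machine.w, (alpha * y) @ X, atol=1e-4)

    def test_nu_svc_feasibility_bound_cited(self, rng):
        grid = _grid_for(2)
        X = rng.normal(size=(10, 2))
        y = ["LUAD"] * 8 + ["SQ"] * 2  # bound = 2*2/10 = 0.4
        assert nu_feasibility_bound(8, 2) == pytest.approx(0.4)
        with pytest.raises(ValueError, match="0.4"):
            fit_margin(_labeled_table(X, y, grid), "nu_svc", 0.6)

    def test_nu_svc_fits_separable_toy(self, rng):
        grid = _grid_for(2)
        X = np.vstack([
            rng.normal(size=(6, 2)) * 0.2 + [-2, 0],
            rng.normal(size=(6, 2)) * 0.2 + [2, 0],
        ])
        y = ["LUAD"] * 6 + ["SQ"] * 6
        model = fit_margin(_labeled_table(X, y, grid), "nu_svc", 0.5)
        assert list(predict_margin(model, X)) == y

    def test_invalid_hyperparameters_rejected(self, rng):
        grid = _grid_for(2)
        X = rng.normal(size=(8, 2))
        y = ["LUAD"] * 4 + ["SQ"] * 4
        table = _labeled_table(X, y, grid)
        with pytest.raises(ValueError):
            fit_margin(table, "c_svc", -1.0)
        with pytest.raises(ValueError):
            fit_margin(table, "nu_svc", 1.5)
        with pytest.raises(ValueError):
            fit_margin(table, "rbf_svc", 1.0)

    def test_training_error_monotone_in_C(self, rng):
        """On an (almost) separable toy the training-error count never
        increases as C grows."""
        grid = _grid_for(2)
        X = np.vstack([
            rng.normal(size=(15, 2)) * 0.8 + [-1.5, 0],
            rng.normal(size=(15, 2)) * 0.8 + [1.5, 0],
        ])
        y = ["LUAD"] * 15 + ["SQ"] * 15
        table = _labeled_table(X, y, grid)
        errors = []
        for C in (0.001, 0.01, 0.1, 1.0, 10.0, 100.0):
            model = fit_margin(table, "c_svc", C)
            errors.append(int(np.sum(predict_margin(model, X) != np.array(y))))
        assert all(a >= b for a, b in zip(errors, errors[1:]))


class TestMarginPredict:
    def test_two_class_voting_is_decision_sign(self, rng):
        grid = _grid_for(2)
        X = np.vstack([
            rng.normal(size=(5, 2)) + [-2, 0],
            rng.normal(size=(5, 2)) + [2, 0],
        ])
        y = ["LUAD"] * 5 + ["SQ"] * 5
        model = fit_margin(_labeled_table(X, y, grid), "c_svc", 1.0)
        (m,) = model.machines
        q = rng.normal(size=(20, 2)) * 3
        preds = predict_margin(model, q)
        d = m.decision(q)
        expected = np.where(d > 0, m.label_pos, m.label_neg)
        np.testing.assert_array_equal(preds, expected)

    def test_three_class_vote_enumeration_oracle(self, rng):
        """Oracle: refit each pairwise machine with sklearn directly and
        tally one-vs-one votes by hand."""
        from sklearn.svm import SVC

        grid = _grid_for(2)
        centers = {"LUAD": [-2, 0], "SCLC": [2, 0], "SQ": [0, 2.5]}
        X, y = [], []
        for lab, c in centers.items():
            X.append(rng.normal(size=(4, 2)) * 0.3 + c)
            y += [lab] * 4
        X = np.vstack(X)
        model = fit_margin(_labeled_table(X, y, grid), "c_svc", 10.0)
        queries = np.vstack([rng.normal(size=(2, 2)) * 0.3 + c
                             for c in centers.values()])

        y_arr = np.array(y)
        labels = sorted(centers)
        votes = {q: {lab: 0.0 for lab in labels} for q in range(len(queries))}
        for i in range(3):
            for j in range(i + 1, 3):
                a, b = labels[i], labels[j]
                mask = (y_arr == a) | (y_arr == b)
                clf = SVC(C=10.0, kernel="linear", tol=1e-6).fit(X[mask], y_arr[mask])
                for q, lab in enumerate(clf.predict(queries)):
                    votes[q][lab] += 1
        oracle = [max(labels, key=lambda lab: (votes[q][lab], lab == min(labels)))
                  for q in range(len(queries))]
        # no ties occur in this well-separated toy; plain max vote suffices
        assert all(
            sorted(votes[q].values())[-1] > sorted(votes[q].values())[-2]
            for q in range(len(queries))
        )
        np.testing.assert_array_equal(predict_margin(model, queries), oracle)

    def test_channel_mismatch_rejected(self, rng):
        grid = _grid_for(2)
        X = rng.normal(size=(8, 2))
        y = ["LUAD"] * 4 + ["SQ"] * 4
        model = fit_margin(_labeled_table(X, y, grid), "c_svc", 1.0)
        with pytest.raises(ValueError, match="channels"):
            predict_margin(model, rng.normal(size=(2, 3)))


class TestCrossModelInvariants:
    def test_linear_equals_pooled_mahalanobis(self, rng):
        """With equal priors, the pooled-covariance Bayes rule is the
        Mahalanobis rule computed with the pooled covariance."""
        from mirclass.classify import DiscriminantModel, predict_discriminant

        grid = _grid_for(4)
        X = rng.normal(size=(36, 4)) + np.repeat(
            np.array([[0.0], [1.0], [2.0]]), 12, axis=0
        )
        y = ["LUAD"] * 12 + ["SCLC"] * 12 + ["SQ"] * 12
        table = _labeled_table(X, y, grid)
        linear = fit_discriminant(table, "linear")
        pooled_maha = DiscriminantModel(
            variant="mahalanobis",
            labels=linear.labels,
            means=linear.means,
            covariances=linear.covariances,  # pooled, broadcast per class
            priors=linear.priors,
            ridge_eps=linear.ridge_eps,
            grid_channels=linear.grid_channels,
        )
        q = rng.normal(size=(50, 4)) + 1.0
        np.testing.assert_array_equal(
            predict_discriminant(linear, q), predict_discriminant(pooled_maha, q)
        )

    @pytest.mark.parametrize(
        "name", ["lda-linear", "lda-quadratic", "lda-mahalanobis", "svm-c", "svm-nu"]
    )
    def test_translation_invariance(self, name, rng):
        grid = _grid_for(3)
        X = rng.normal(size=(24, 3)) + np.repeat(
            np.array([[0.0], [2.0], [4.0]]), 8, axis=0
        )
        y = ["LUAD"] * 8 + ["SCLC"] * 8 + ["SQ"] * 8
        shift = np.array([5.0, -3.0, 2.0])
        q = rng.normal(size=(10, 3)) + 2.0
        m0 = fit_model(_labeled_table(X, y, grid), name)
        m1 = fit_model(_labeled_table(X + shift, y, grid), name)
        np.testing.assert_array_equal(
            predict_model(m0, q), predict_model(m1, q + shift)
        )

    @pytest.mark.parametrize(
        "name", ["lda-linear", "lda-quadratic", "lda-mahalanobis", "svm-c", "svm-nu"]
    )
    def test_refit_determinism(self, name, rng):
        grid = _grid_for(3)
        X = rng.normal(size=(30, 3)) + np.repeat(
            np.array([[0.0], [1.0], [2.0]]), 10, axis=0
        )
        y = ["LUAD"] * 10 + ["SCLC"] * 10 + ["SQ"] * 10
        q = rng.normal(size=(20, 3)) + 1.0
        t1 = _labeled_table(X, y, grid)
        t2 = _labeled_table(X.copy(), y, grid)
        np.testing.assert_array_equal(
            predict_model(fit_model(t1, name), q),
            predict_model(fit_model(t2, name), q),
        )


class TestStandardization:
    @pytest.mark.parametrize("name", ["lda-linear", "svm-c"])
    def test_scaler_recorded_and_scale_invariant(self, name, rng):
        """With standardization on, rescaling one channel of both training
        and query data leaves predictions unchanged."""
        grid = _grid_for(3)
        X = rng.normal(size=(24, 3)) + np.repeat(
            np.array([[0.0], [2.0], [4.0]]), 8, axis=0
        )
        y = ["LUAD"] * 8 + ["SCLC"] * 8 + ["SQ"] * 8
        q = rng.normal(size=(10, 3)) + 2.0
        scale = np.array([100.0, 1.0, 0.01])
        m_plain = fit_model(_labeled_table(X, y, grid), name, standardize=True)
        m_scaled = fit_model(_labeled_table(X * scale, y, grid), name, standardize=True)
        assert m_plain.scaler_mean is not None and m_plain.scaler_sd is not None
        np.testing.assert_array_equal(
            predict_model(m_plain, q), predict_model(m_scaled, q * scale)
        )

    def test_off_by_default(self, rng):
        grid = _grid_for(2)
        X = rng.normal(size=(8, 2))
        y = ["LUAD"] * 4 + ["SQ"] * 4
        model = fit_model(_labeled_table(X, y, grid), "lda-linear")
        assert model.scaler_mean is None and model.scaler_sd is None


class TestPredictTable:
    def test_one_prediction_per_test_row(self, tiny_config):
        split = split_alternating(flatten_cohort(generate_cohort(tiny_config)))
        model = fit_model(split, "lda-linear")
        pred = predict_table(model, split)
        assert len(pred) == (split.meta["role"] == "test").sum()
        assert (pred["model"] == "lda-linear").all()
        assert set(pred["predicted"]) <= set(tiny_config.subtypes)
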