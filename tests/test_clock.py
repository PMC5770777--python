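"""Pedigree split, elastic-net solver oracles, KKT conditions, prediction
and delta-age contracts."""

import numpy as np
import pandas as pd
import pytest

from mirclock.clock import (
    ClockModel,
    delta_age,
    enet_path,
    predict_age,
    split_by_pedigree,
    train_clock,
)
from mirclock.exceptions import AlignmentError, ConfigurationError


def _ped_of_sizes(sizes):
    rows = []
    for i, s in enumerate(sizes):
        fam = f"P{i}"
        rows.append((fam, f"{fam}_d", "0", "0", "male"))
        if s >= 2:
            rows.append((fam, f"{fam}_m", "0", "0", "female"))
        for c in range(s - 2):
            rows.append((fam, f"{fam}_k{c}", f"{fam}_d", f"{fam}_m", "male"))
    return pd.DataFrame(
        rows, columns=["pedigree_id", "individual_id", "father_id", "mother_id", "sex"]
    )


def _standardize(X):
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)


def _random_problem(rng, n=120, p=15, k=5, noise=1.0):
    X = _standardize(rng.normal(0, 1, (n, p)))
    beta = np.zeros(p)
    beta[:k] = rng.normal(0, 2, k)
    y = 50 + X @ beta + rng.normal(0, noise, n)
    return X, y


class TestSplit:
    def test_singleton_pedigrees_balance(self):
        ped = _ped_of_sizes([1] * 11)
        split = split_by_pedigree(ped, ratio=0.5, seed=0)
        counts = split.value_counts()
        assert abs(counts.get("A", 0) - counts.get("B", 0)) <= 1

    def test_no_pedigree_spans_sets(self, small_cohort):
        split = split_by_pedigree(small_cohort.pedigree, seed=1)
        fam = small_cohort.pedigree.set_index("individual_id")["pedigree_id"]
        spans = pd.DataFrame({"fam": fam, "split": split}).groupby("fam")["split"].nunique()
        assert (spans == 1).all()
        assert not split.index.duplicated().any()

    def test_greedy_exact_split_4321(self):
        split = split_by_pedigree(_ped_of_sizes([4, 3, 2, 1]), ratio=0.5, seed=0)
        assert sorted(split.value_counts().tolist()) == [5, 5]

    def test_single_pedigree_unsplittable(self):
        with pytest.raises(ConfigurationError):
            split_by_pedigree(_ped_of_sizes([5]))

    def test_deterministic_given_seed(self, small_cohort):
        a = split_by_pedigree(small_cohort.pedigree, seed=7)
        b = split_by_pedigree(small_cohort.pedigree, seed=7)
        pd.testing.assert_series_equal(a, b)


class TestElasticNetSolver:
    def test_lambda_max_zeroes_everything(self, rng):
        X, y = _random_problem(rng)
        n = X.shape[0]
        alpha = 0.5
        lam_max = np.abs(X.T @ (y - y.mean()) / n).max() / alpha
        lams, betas, icpt = enet_path(X, y, alpha=alpha, lambdas=np.array([lam_max * 1.001]))
        assert np.all(betas == 0.0)
        assert icpt == pytest.approx(y.mean())

    def test_lambda_zero_matches_ols(self, rng):
        X, y = _random_problem(rng, n=100, p=10)
        lams, betas, icpt = enet_path(
            X, y, alpha=0.5, lambdas=np.array([1e-10])
        )
        Xi = np.column_stack([np.ones(len(y)), X])
        ols = np.linalg.lstsq(Xi, y, rcond=None)[0]
        assert np.abs(betas[-1] - ols[1:]).max() < 1e-6

    def test_single_predictor_soft_threshold_closed_form(self, rng):
        n = 200
        x = _standardize(rng.normal(0, 1, (n, 1)))
        y = 30 + 2.0 * x[:, 0] + rng.normal(0, 1, n)
        rho = float(x[:, 0] @ (y - y.mean())) / n
        for lam in (0.1, 0.5, 1.0, 3.0):
            _, betas, _ = enet_path(x, y, alpha=1.0, lambdas=np.array([lam]))
            expected = np.sign(rho) * max(abs(rho) - lam, 0.0)
            assert betas[0, 0] == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_kkt_conditions_along_path(self, seed):
        rng = np.random.default_rng(seed)
        X, y = _random_problem(rng)
        n = X.shape[0]
        alpha = 0.5
        lams, betas, icpt = enet_path(X, y, alpha=alpha, n_lambda=20)
        yc = y - y.mean()
        for lam, b in zip(lams, betas):
            g = X.T @ (yc - X @ b) / n  # gradient of the smooth part
            nz = b != 0
            stat = g[nz] - lam * (1 - alpha) * b[nz] - lam * alpha * np.sign(b[nz])
            assert np.abs(stat).max() < 1e-6 if nz.any() else True
            assert (np.abs(g[~nz]) <= lam * alpha + 1e-6).all()

    def test_warm_start_matches_cold_start(self, rng):
        X, y = _random_problem(rng)
        lams, betas, _ = enet_path(X, y, alpha=0.5, n_lambda=15)
        for lam, warm in zip(lams, betas):
            _, cold, _ = enet_path(X, y, alpha=0.5, lambdas=np.array([lam]))
            assert np.abs(warm - cold[0]).max() < 1e-6

    def test_matches_sklearn_elastic_net(self, rng):
        from sklearn.linear_model import ElasticNet

        X, y = _random_problem(rng, n=150, p=12)
        for lam in (0.05, 0.3, 1.0):
            _, betas, icpt = enet_path(X, y, alpha=0.5, lambdas=np.array([lam]))
            sk = ElasticNet(alpha=lam, l1_ratio=0.5, fit_intercept=True, tol=1e-10)
            sk.fit(X, y)
            assert np.abs(betas[0] - sk.coef_).max() < 1e-5

    def test_empty_lambda_grid_rejected(self, rng):
        X, y = _random_problem(rng)
        with pytest.raises(ConfigurationError):
            enet_path(X, y, lambdas=np.array([]))


class TestTrainPredict:
    def _resid_frame(self, X, ids):
        return pd.DataFrame(X, index=ids, columns=[f"m{j}" for j in range(X.shape[1])])

    def test_requires_standardized_input(self, rng):
        X, y = _random_problem(rng)
        ids = [f"s{i}" for i in range(len(y))]
        ages = pd.Series(y, index=ids)
        with pytest.raises(ConfigurationError, match="standardized"):
            train_clock(self._resid_frame(X * 3.0, ids), ages, lam=0.2)

    def test_fixed_lambda_and_serialization_roundtrip(self, rng, tmp_path):
        X, y = _random_problem(rng)
        ids = [f"s{i}" for i in range(len(y))]
        ages = pd.Series(y, index=ids)
        resid = self._resid_frame(X, ids)
        model = train_clock(resid, ages, lam=0.2)
        assert model.lambda_penalty == pytest.approx(0.2)
        path = tmp_path / "model.tsv"
        model.save(path)
        loaded = ClockModel.load(path)
        pred1, _ = predict_age(model, resid)
        pred2, _ = predict_age(loaded, resid)
        assert np.abs(pred1 - pred2).max() < 1e-12

    def test_cv_selects_lambda_and_predicts(self, rng):
        X, y = _random_problem(rng, n=200, p=20, k=6)
        ids = [f"s{i}" for i in range(len(y))]
        ages = pd.Series(y, index=ids)
        model = train_clock(self._resid_frame(X, ids), ages, folds=5, seed=0)
        assert model.cv_curve is not None
        assert len(model.selected) > 0
        _, r = predict_age(model, self._resid_frame(X, ids), ages)
        assert r > 0.8

    def test_in_sample_r_at_least_held_out(self, rng):
        Xtr, ytr = _random_problem(rng, n=150, p=30, k=8, noise=3.0)
        Xte = _standardize(rng.normal(0, 1, (150, 30)))
        beta_true = np.zeros(30)
        ids_tr = [f"a{i}" for i in range(150)]
        ids_te = [f"b{i}" for i in range(150)]
        ages_tr = pd.Series(ytr, index=ids_tr)
        model = train_clock(self._resid_frame(Xtr, ids_tr), ages_tr, lam=0.1)
        _, r_in = predict_age(model, self._resid_frame(Xtr, ids_tr), ages_tr)
        # held-out targets generated from the same sparse signal
        yte = 50 + Xte @ beta_true + rng.normal(0, 3.0, 150)
        _, r_out = predict_age(
            model, self._resid_frame(Xte, ids_te), pd.Series(yte, index=ids_te)
        )
        assert r_in >= r_out

    def test_all_zero_model_predicts_intercept(self):
        model = ClockModel(
            mirna_ids=["m0", "m1"],
            coefficients=np.zeros(2),
            intercept=54.2,
            alpha_mix=0.5,
            lambda_penalty=1.0,
            n_train=10,
        )
        resid = pd.DataFrame(
            np.random.default_rng(0).normal(0, 1, (5, 2)),
            index=list("abcde"),
            columns=["m0", "m1"],
        )
        pred, _ = predict_age(model, resid)
        assert (pred == 54.2).all()

    def test_missing_model_mirna_raises(self):
        model = ClockModel(
            mirna_ids=["m0", "mX"],
            coefficients=np.array([1.0, 2.0]),
            intercept=0.0,
            alpha_mix=0.5,
            lambda_penalty=0.1,
            n_train=10,
        )
        resid = pd.DataFrame(np.zeros((3, 1)), index=list("abc"), columns=["m0"])
        with pytest.raises(ConfigurationError, match="mX"):
            predict_age(model, resid)

    def test_no_leakage_from_test_ages(self, rng):
        X, y = _random_problem(rng)
        ids = [f"s{i}" for i in range(len(y))]
        model = train_clock(self._resid_frame(X, ids), pd.Series(y, index=ids), lam=0.2)
        Xte = _standardize(rng.normal(0, 1, (40, X.shape[1])))
        te_ids = [f"t{i}" for i in range(40)]
        resid_te = self._resid_frame(Xte, te_ids)
        ages1 = pd.Series(rng.normal(50, 9, 40), index=te_ids)
        ages2 = pd.Series(rng.permutation(ages1.to_numpy()), index=te_ids)
        p1, _ = predict_age(model, resid_te, ages1)
        p2, _ = predict_age(model, resid_te, ages2)
        assert np.abs(p1 - p2).max() == 0.0


class TestDeltaAge:
    def test_definition_examples(self):
        pred = pd.Series([60.0, 55.0], index=["a", "b"])
        chron = pd.Series([55.0, 55.0], index=["a", "b"])
        out = delta_age(pred, chron)
        assert out.loc["a", "delta_age"] == 5.0
        assert out.loc["b", "delta_age"] == 0.0
        assert (out["delta_age"] == out["mirna_age"] - out["chronological_age"]).all()

    def test_misalignment_raises(self):
        with pytest.raises(AlignmentError):
            delta_age(
                pd.Series([1.0], index=["a"]), pd.Series([1.0], index=["b"])
            )

    def test_mean_delta_near_zero_held_out(self, rng):
        """An unbiased generator plus an unbiased clock give held-out mean
        delta-age within 3 SE of zero."""
        X, y = _random_problem(rng, n=400, p=20, k=6, noise=4.0)
        ids = [f"s{i}" for i in range(400)]
        ages = pd.Series(y, index=ids)
        tr, te = ids[:200], ids[200:]
        frame = pd.DataFrame(X, index=ids, columns=[f"m{j}" for j in range(20)])
        tr_frame = (frame.loc[tr] - frame.loc[tr].mean()) / frame.loc[tr].std(ddof=0)
        model = train_clock(tr_frame, ages.loc[tr], lam=0.1)
        te_frame = (frame.loc[te] - frame.loc[tr].mean()) / frame.loc[tr].std(ddof=0)
        pred, _ = predict_age(model, te_frame)
        out = delta_age(pred, ages)
        se = out["delta_age"].std() / np.sqrt(len(te))
        assert abs(out["delta_age"].mean()) < 3 * se + 0.5
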