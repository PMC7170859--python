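import numpy as np
import pytest

from cfopt.ensemble import (
    Ensemble,
    EnsembleConfig,
    cross_validate,
    data_fingerprint,
    regression_metrics,
    train_ensemble,
    train_member,
)
from cfopt.exceptions import (
    FingerprintMismatchError,
    NotFittedError,
    UnderdeterminedError,
    UnnormalizedInputError,
)

LEVELS = np.array([0.1, 0.3, 0.5, 1.0])


@pytest.fixture(scope="module")
def linear_data():
    rng = np.random.default_rng(0)
    X = LEVELS[rng.integers(0, 4, size=(102, 11))]
    w = rng.uniform(-2, 2, size=11)
    return X, X @ w


@pytest.fixture(scope="module")
def small_ensemble(linear_data, ):
    X, y = linear_data
    cfg = EnsembleConfig(n_members=3, restarts_per_member=2, max_iterations=2000, base_seed=5)
    return train_ensemble(X, y, cfg), X, y


def test_member_fits_noiseless_linear_map(linear_data):
    X, y = linear_data
    cfg = EnsembleConfig(max_iterations=5000)
    model = train_member(X, y, restarts=10, seed=0, config=cfg)
    assert model.score(X, y) >= 0.95


def test_single_restart_equals_plain_fit(linear_data):
    X, y = linear_data
    cfg = EnsembleConfig(max_iterations=500)
    a = train_member(X, y, restarts=1, seed=9, config=cfg)
    b = train_member(X, y, restarts=1, seed=9, config=cfg)
    assert np.array_equal(a.predict(X[:10]), b.predict(X[:10]))


def test_ensemble_mean_is_member_mean_and_std_symmetric(small_ensemble):
    ens, X, y = small_ensemble
    pred = ens.predict(X[:20])
    members = pred.member_predictions
    assert np.allclose(pred.mean, members.mean(axis=0))
    assert np.allclose(pred.std, members.std(axis=0, ddof=1))
    # reordering members cannot change the dispersion
    rev = Ensemble(members=list(reversed(ens.members)), config=ens.config)
    assert np.allclose(rev.predict(X[:20]).std, pred.std)


def test_same_base_seed_reproduces_predictions(linear_data):
    X, y = linear_data
    cfg = EnsembleConfig(n_members=2, restarts_per_member=2, max_iterations=500, base_seed=3)
    p1 = train_ensemble(X, y, cfg).predict(X[:10]).mean
    p2 = train_ensemble(X, y, cfg).predict(X[:10]).mean
    assert np.array_equal(p1, p2)


def test_sem_uncertainty_shrinks_dispersion(small_ensemble):
    ens, X, y = small_ensemble
    sem_ens = Ensemble(
        members=ens.members,
        config=EnsembleConfig(n_members=3, restarts_per_member=2, uncertainty="sem"),
    )
    n = len(ens.members)
    assert np.allclose(sem_ens.predict(X[:5]).std, ens.predict(X[:5]).std / np.sqrt(n))


def test_raw_concentrations_rejected(linear_data):
    X, y = linear_data
    with pytest.raises(UnnormalizedInputError):
        train_ensemble(X * 100.0, y, EnsembleConfig(n_members=1, restarts_per_member=1))


def test_too_few_rows_rejected():
    with pytest.raises(UnderdeterminedError):
        train_ensemble(np.array([[0.5]]), np.array([1.0]))


def test_unfitted_ensemble_raises():
    with pytest.raises(NotFittedError):
        Ensemble(members=[], config=EnsembleConfig()).predict(np.array([[0.5]]))


class TestCrossValidation:
    def test_five_scores_and_partition(self, linear_data):
        X, y = linear_data
        cfg = EnsembleConfig(n_members=1, restarts_per_member=1, max_iterations=300)
        report = cross_validate(X, y, cfg, k=5, seed=0)
        assert len(report.scores) == 5
        assert report.mean == pytest.approx(np.mean(report.scores))

    def test_fold_assignment_partitions_data(self, linear_data):
        from sklearn.model_selection import KFold

        X, _ = linear_data
        seen = np.zeros(len(X), dtype=int)
        for _, test_idx in KFold(n_splits=5, shuffle=True, random_state=0).split(X):
            seen[test_idx] += 1
        assert (seen == 1).all()

    def test_constant_target_explains_no_variance(self):
        rng = np.random.default_rng(1)
        X = LEVELS[rng.integers(0, 4, size=(30, 4))]
        y = np.full(30, 2.0)
        cfg = EnsembleConfig(n_members=1, restarts_per_member=1, max_iterations=200)
        report = cross_validate(X, y, cfg, k=5, seed=0)
        assert all(s <= 0 for s in report.scores)

    def test_too_few_rows_for_folds(self):
        with pytest.raises(UnderdeterminedError):
            cross_validate(np.full((3, 2), 0.5), np.arange(3.0), k=5)


def test_cv_plateau_on_noiseless_campaign_history(space11, benchmark):
    """With 500 noiseless training points distributed like a campaign
    history, 5-fold CV of the ensemble plateaus at a high score."""
    from cfopt.synthetic import sample_history

    profile = benchmark["ori"]
    comps = sample_history(profile, 500, seed=0)
    X = space11.normalize_many(comps)
    y = profile.ground_truth_yields(comps)
    cfg = EnsembleConfig(n_members=5, restarts_per_member=3, max_iterations=3000, base_seed=0)
    report = cross_validate(X, y, cfg, k=5, seed=0)
    assert report.mean >= 0.8


def test_prediction_dispersion_shrinks_with_training_data(space11, benchmark):
    """Median ensemble dispersion over 1000 random compositions is
    non-increasing (within Monte-Carlo slack) as the training set grows
    102 -> 510 -> 1020."""
    profile = benchmark["ori"]
    probe = space11.normalize_many(space11.sample_unseen(1000, seed=99))
    medians = []
    for n in (102, 510, 1020):
        comps = space11.sample_unseen(n, seed=7)
        X = space11.normalize_many(comps)
        y = profile.ground_truth_yields(comps)
        ens = train_ensemble(X, y, EnsembleConfig.reduced(base_seed=1))
        medians.append(float(np.median(ens.predict(probe).std)))
    assert medians[1] <= medians[0] * 1.1
    assert medians[2] <= medians[1] * 1.1


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        m = regression_metrics(y, y, train_mask=[True, True, False, False, False])
        assert m.r2 == pytest.approx(1.0)
        assert m.q2 == pytest.approx(1.0)
        assert m.slope == pytest.approx(1.0)
        assert m.intercept == pytest.approx(0.0)

    def test_mean_prediction_has_nonpositive_q2(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.full(4, y.mean())
        # constant prediction on the test half cannot beat the test mean
        m = regression_metrics(pred + [0, 0, 1e-9, -1e-9], y, [True, True, False, False])
        assert m.q2 <= 0

    def test_fit_matches_closed_form_least_squares(self):
        pred = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        obs = np.array([1.2, 1.9, 3.4, 3.9, 5.3])
        mask = np.zeros(5, dtype=bool)
        # closed-form simple regression of obs on pred
        sxy = np.sum((pred - pred.mean()) * (obs - obs.mean()))
        sxx = np.sum((pred - pred.mean()) ** 2)
        slope = sxy / sxx
        intercept = obs.mean() - slope * pred.mean()
        m = regression_metrics(pred, obs, mask)
        assert m.slope == pytest.approx(slope)
        assert m.intercept == pytest.approx(intercept)

    def test_zero_variance_observed_rejected(self):
        with pytest.raises(ValueError):
            regression_metrics([1.0, 2.0], [3.0, 3.0], [True, False])

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            regression_metrics([1.0, 2.0], [1.0, 2.0], [True, True])


def test_model_bundle_roundtrip(tmp_path, small_ensemble):
    ens, X, y = small_ensemble
    ens.save(tmp_path / "bundle")
    loaded = Ensemble.load(tmp_path / "bundle", expected_fingerprint=data_fingerprint(X, y))
    assert np.array_equal(loaded.predict(X[:5]).mean, ens.predict(X[:5]).mean)
    assert loaded.config == ens.config
    with pytest.raises(FingerprintMismatchError):
        Ensemble.load(tmp_path / "bundle", expected_fingerprint="bogus")
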