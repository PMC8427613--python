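import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, poisson

from cnsig.features import FEATURE_NAMES, FeatureEvents
from cnsig.mixtures import (
    ComponentModel,
    Mixture,
    fit_mixture,
    posterior_encode,
)


class TestFitMixture:
    def test_poisson_two_component_recovery(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.poisson(1, 1000), rng.poisson(10, 1000)])
        m = fit_mixture(x, "poisson", k_range=range(1, 6), n_init=5, seed=0)
        assert m.k == 2
        assert 0.8 <= m.params[0, 0] <= 1.2
        assert 9.0 <= m.params[1, 0] <= 11.0

    def test_gaussian_two_component_recovery(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0.5, 0.2, 1000), rng.normal(3.0, 0.2, 1000)])
        m = fit_mixture(x, "gaussian", k_range=range(1, 6), n_init=5, seed=0)
        assert m.k == 2
        assert m.params[0, 0] == pytest.approx(0.5, abs=0.1)
        assert m.params[1, 0] == pytest.approx(3.0, abs=0.1)

    def test_identical_values_single_component(self):
        x = np.full(50, 4.0)
        for family in ("gaussian", "poisson"):
            m = fit_mixture(x, family, k_range=range(1, 5), seed=0)
            assert m.k == 1
            assert m.params[0, 0] == pytest.approx(4.0, abs=1e-6)

    def test_too_few_values_raises(self):
        with pytest.raises(ValueError, match="10"):
            fit_mixture([1.0] * 5, "gaussian", seed=0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="Poisson"):
            fit_mixture([-1.0] * 20, "poisson", seed=0)

    def test_weights_sum_to_one_and_sorted(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.poisson(2, 500), rng.poisson(8, 500)])
        m = fit_mixture(x, "poisson", k_range=range(1, 5), seed=0)
        assert m.weights.sum() == pytest.approx(1.0)
        assert (np.diff(m.params[:, 0]) >= 0).all()

    @pytest.mark.parametrize("true_k", [2, 3])
    def test_bic_recovers_k_on_separated_mixtures(self, true_k):
        """Components separated by >= 3 sd recovered in >= 90% of seeds."""
        hits = 0
        n_seeds = 20
        means = [0.0, 3.0, 6.0][:true_k]
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            x = np.concatenate([
                rng.normal(mu, 0.5, 2000 // true_k) for mu in means
            ])
            m = fit_mixture(x, "gaussian", k_range=range(1, 6), n_init=4, seed=seed)
            hits += m.k == true_k
        assert hits / n_seeds >= 0.9

    def test_cross_check_against_sklearn_gmm(self):
        """Independent EM route (sklearn GaussianMixture) agrees on a 1-D fit."""
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(1.0, 0.3, 800), rng.normal(4.0, 0.5, 1200)])
        ours = fit_mixture(x, "gaussian", k_range=[2], n_init=5, seed=0)
        gmm = GaussianMixture(2, n_init=5, random_state=0).fit(x[:, None])
        order = np.argsort(gmm.means_.ravel())
        assert ours.params[:, 0] == pytest.approx(gmm.means_.ravel()[order], abs=0.05)
        assert ours.weights == pytest.approx(gmm.weights_[order], abs=0.02)


def _toy_model():
    return ComponentModel(mixtures={
        "segsize": Mixture("gaussian", np.array([0.5, 0.5]),
                           np.array([[1e6, 2e5], [5e6, 1e6]])),
        "copynumber": Mixture("gaussian", np.array([0.3, 0.7]),
                              np.array([[1.0, 0.2], [3.0, 0.4]])),
        "changepoint": Mixture("gaussian", np.array([1.0]), np.array([[1.0, 0.5]])),
        "bp10MB": Mixture("poisson", np.array([0.6, 0.4]), np.array([[0.2], [3.0]])),
        "bpchrarm": Mixture("poisson", np.array([1.0]), np.array([[1.0]])),
        "osCN": Mixture("poisson", np.array([1.0]), np.array([[0.5]])),
    })


def _events(sample_id, **kwargs):
    ev = {f: [] for f in FEATURE_NAMES}
    ev.update(kwargs)
    return FeatureEvents(sample_id=sample_id, events=ev)


class TestPosteriorEncode:
    def test_zero_event_sample_gives_zero_row(self):
        M = posterior_encode([_events("S0")], _toy_model())
        assert (M.loc["S0"] == 0).all()

    def test_event_at_mean_of_separated_component_dominates(self):
        model = _toy_model()
        M = posterior_encode([_events("S", copynumber=[3.0])], model)
        assert M.loc["S", "copynumber:2"] >= 0.99
        assert M.loc["S", "copynumber:1"] <= 0.01

    def test_hand_computed_bayes_posteriors(self):
        model = _toy_model()
        events = _events("S", copynumber=[2.0], bp10MB=[1.0, 0.0])
        M = posterior_encode([events], model)
        # gaussian posterior for value 2.0 under components N(1,0.2)/N(3,0.4)
        lik1 = 0.3 * norm.pdf(2.0, 1.0, 0.2)
        lik2 = 0.7 * norm.pdf(2.0, 3.0, 0.4)
        assert M.loc["S", "copynumber:1"] == pytest.approx(lik1 / (lik1 + lik2), abs=1e-9)
        assert M.loc["S", "copynumber:2"] == pytest.approx(lik2 / (lik1 + lik2), abs=1e-9)
        # poisson posteriors for counts 1 and 0 under Pois(0.2)/Pois(3.0)
        expected = np.zeros(2)
        for x in (1.0, 0.0):
            a = 0.6 * poisson.pmf(x, 0.2)
            b = 0.4 * poisson.pmf(x, 3.0)
            expected += np.array([a, b]) / (a + b)
        assert M.loc["S", "bp10MB:1"] == pytest.approx(expected[0], abs=1e-9)
        assert M.loc["S", "bp10MB:2"] == pytest.approx(expected[1], abs=1e-9)

    def test_row_sum_conservation_per_feature(self):
        model = _toy_model()
        rng = np.random.default_rng(0)
        events = _events(
            "S",
            segsize=list(rng.uniform(5e5, 8e6, 7)),
            copynumber=list(rng.uniform(0.5, 4, 7)),
            changepoint=list(rng.uniform(0, 2, 6)),
            bp10MB=list(rng.poisson(1, 9).astype(float)),
            bpchrarm=list(rng.poisson(1, 4).astype(float)),
            osCN=[0.0, 3.0],
        )
        M = posterior_encode([events], model)
        for feat, count in [("segsize", 7), ("copynumber", 7), ("changepoint", 6),
                            ("bp10MB", 9), ("bpchrarm", 4), ("osCN", 2)]:
            cols = [c for c in M.columns if c.startswith(feat + ":")]
            assert M.loc["S", cols].sum() == pytest.approx(count, abs=1e-6)

    def test_duplicating_events_doubles_row(self):
        model = _toy_model()
        ev1 = _events("S", copynumber=[1.2, 2.8], bp10MB=[2.0])
        ev2 = _events("S", copynumber=[1.2, 2.8] * 2, bp10MB=[2.0] * 2)
        M1 = posterior_encode([ev1], model)
        M2 = posterior_encode([ev2], model)
        assert np.allclose(2 * M1.values, M2.values)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="support"):
            posterior_encode([_events("S", bp10MB=[-1.0])], _toy_model())


class TestComponentModelIO:
    @pytest.mark.parametrize("ext", ["json", "yaml"])
    def test_bit_exact_round_trip(self, tmp_path, ext):
        model = _toy_model()
        rng = np.random.default_rng(0)
        for m in model.mixtures.values():  # perturb to non-round floats
            m.params = m.params * (1 + rng.uniform(0, 1e-3, m.params.shape))
            m.log_likelihood = -1234.56789
        path = tmp_path / f"model.{ext}"
        model.save(path)
        back = ComponentModel.load(path)
        for feat, m in model.mixtures.items():
            b = back.mixtures[feat]
            assert b.family == m.family
            np.testing.assert_array_equal(b.weights, m.weights)
            np.testing.assert_array_equal(b.params, m.params)

    def test_component_labels_and_count(self):
        model = _toy_model()
        assert model.n_components == 9
        assert model.component_labels[0] == "segsize:1"
        assert len(model.component_labels) == 9
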