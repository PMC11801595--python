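import numpy as np
import pandas as pd
import pytest

from cervitex.classifier import (DegenerateWeightsError, average_weight,
                                 class_scores, classify, fit_model, hd, jsd,
                                 load_classifier, normalize_weights,
                                 save_classifier, td, train_classifier)
from cervitex.image_io import LABELS


def _random_dist(rng, k):
    p = rng.uniform(0.01, 1.0, k)
    return p / p.sum()


def _direct_printed_jsd(p, q):
    """Independent direct evaluation of the symmetrized per-bin Bernoulli-KL sum."""
    def one_way(a, b):
        total = 0.0
        for pa, pb in zip(a, b):
            pb = min(max(pb, 1e-12), 1 - 1e-12)
            if pa > 0:
                total += pa * np.log(pa / pb)
            if pa < 1:
                total += (1 - pa) * np.log((1 - pa) / (1 - pb))
        return total
    return 0.5 * (one_way(p, q) + one_way(q, p))


class TestDivergences:
    def test_identity_gives_zero(self, rng):
        p = _random_dist(rng, 10)
        assert jsd(p, p) == pytest.approx(0.0, abs=1e-12)
        assert hd(p, p) == 0.0
        assert td(p, p) == 0.0

    def test_symmetry(self, rng):
        for _ in range(10):
            p, q = _random_dist(rng, 8), _random_dist(rng, 8)
            assert jsd(p, q) == pytest.approx(jsd(q, p), rel=1e-12)
            assert hd(p, q) == hd(q, p)
            assert td(p, q) == pytest.approx(td(q, p), rel=1e-12)

    def test_jsd_matches_direct_formula(self, rng):
        p, q = np.array([0.5, 0.5]), np.array([0.9, 0.1])
        assert jsd(p, q) == pytest.approx(_direct_printed_jsd(p, q), abs=1e-12)
        for _ in range(50):
            p, q = _random_dist(rng, 10), _random_dist(rng, 10)
            assert jsd(p, q) == pytest.approx(_direct_printed_jsd(p, q),
                                              abs=1e-12)

    def test_disjoint_support_extremes(self):
        p, q = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert hd(p, q) == 2.0           # (1-0)^2 + (0-1)^2
        assert td(p, q) == 2.0           # 1/1 + 1/1

    def test_bounds(self, rng):
        for _ in range(200):
            p, q = _random_dist(rng, 12), _random_dist(rng, 12)
            assert 0.0 <= hd(p, q) <= 2.0
            assert 0.0 <= td(p, q) <= 2.0

    def test_standard_forms(self, rng):
        p, q = _random_dist(rng, 6), _random_dist(rng, 6)
        # textbook JSD is bounded by ln 2; Hellinger^2 form by 2
        assert 0.0 <= jsd(p, q, form="standard") <= np.log(2) + 1e-12
        expected = float(np.sum((np.sqrt(p) - np.sqrt(q)) ** 2))
        assert hd(p, q, form="standard") == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            jsd(np.array([1.0]), np.array([0.5, 0.5]))


def _training_table(rng, n_per_class=90, informative=True):
    rows = []
    centers = {"normal": 0.0, "benign": 3.0, "malign": 6.0}
    for label in LABELS:
        mu = centers[label] if informative else 0.0
        for _ in range(n_per_class):
            rows.append({"label": label,
                         "f_sep": rng.normal(mu, 0.5),
                         "f_noise": rng.normal(0.0, 1.0)})
    return pd.DataFrame(rows)


class TestFitModel:
    def test_balanced_priors_and_smoothed_histograms(self, rng):
        model = fit_model(_training_table(rng), R=10)
        assert np.allclose(model.priors, 1 / 3)
        for ci in range(3):
            for j in range(model.n_features):
                pj = model.cond_probs[ci, j, :model.n_bins[j]]
                assert pj.sum() == pytest.approx(1.0, abs=1e-12)
                assert np.all(pj > 0)  # Laplace smoothing

    def test_equal_frequency_bins(self, rng):
        model = fit_model(_training_table(rng), R=10)
        df = _training_table(rng)  # counts checked on the fitted table below
        model = fit_model(df, R=10)
        x = df["f_sep"].to_numpy()
        b = np.searchsorted(model.edges[model.feature_names.index("f_sep")],
                            x, side="right")
        counts = np.bincount(b)
        assert np.all(np.abs(counts - 27) <= 1)  # 270 / 10 bins

    def test_missing_class_rejected(self, rng):
        df = _training_table(rng)
        with pytest.raises(ValueError):
            fit_model(df[df["label"] != "benign"])

    def test_constant_feature_degenerates_to_single_bin(self, rng):
        df = _training_table(rng)
        df["f_const"] = 1.0
        model = fit_model(df)
        j = model.feature_names.index("f_const")
        assert model.n_bins[j] == 1


class TestWeights:
    def test_identical_distributions_give_zero_weight(self, rng):
        df = _training_table(rng, informative=False)
        model = fit_model(df)
        # uninformative features: small but not exactly zero; constant is zero
        df["f_const"] = 2.5
        model = fit_model(df)
        j = model.feature_names.index("f_const")
        for div in ("jsd", "hd", "td"):
            assert average_weight(model, j, div) == pytest.approx(0.0, abs=1e-9)

    def test_average_over_three_class_pairs(self, rng):
        model = fit_model(_training_table(rng))
        j = model.feature_names.index("f_sep")
        for div, f in (("jsd", jsd), ("hd", hd), ("td", td)):
            dists = [model.cond_probs[ci, j, :model.n_bins[j]]
                     for ci in range(3)]
            expected = (f(dists[0], dists[1]) + f(dists[0], dists[2])
                        + f(dists[1], dists[2])) / 3
            assert average_weight(model, j, div) == pytest.approx(expected)

    def test_weight_grows_with_separation(self, rng):
        prev = -1.0
        for shift in (0.0, 1.0, 2.0, 4.0):
            rows = []
            for label, mu in zip(LABELS, (0.0, shift, 2 * shift)):
                rows.extend({"label": label, "f": rng.normal(mu, 0.5)}
                            for _ in range(60))
            model = fit_model(pd.DataFrame(rows))
            w = average_weight(model, 0, "td")
            assert w >= prev - 1e-9
            prev = w

    def test_entropy_normalization_example(self, rng):
        df = _training_table(rng)
        model = fit_model(df[["label", "f_sep", "f_noise"]])
        # impose the example: equal raw weights, entropies ln2 and ln4
        model.n_bins = np.array([2, 4])
        model.pooled = np.zeros((2, 4))
        model.pooled[0, :2] = 0.5
        model.pooled[1, :4] = 0.25
        fw = normalize_weights(np.array([1.0, 1.0]), model, "jsd")
        expected = np.array([1 / np.log(2), 1 / np.log(4)])
        expected /= expected.sum()
        assert np.allclose(fw.normalized, expected)
        assert fw.normalized.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_raw_weight_stays_zero(self, rng):
        df = _training_table(rng)
        df["f_const"] = 1.0
        model = fit_model(df)
        raw = np.array([average_weight(model, p, "hd")
                        for p in range(model.n_features)])
        fw = normalize_weights(raw, model, "hd")
        j = model.feature_names.index("f_const")
        assert fw.normalized[j] == 0.0
        assert fw.normalized.sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_raw_weights_raise(self, rng):
        model = fit_model(_training_table(rng))
        with pytest.raises(DegenerateWeightsError):
            normalize_weights(np.zeros(model.n_features), model, "jsd")

    def test_label_permutation_shrinks_weights(self, rng):
        df = _training_table(rng, n_per_class=60)
        model = fit_model(df)
        j = model.feature_names.index("f_sep")
        w_true = average_weight(model, j, "td")
        permuted = []
        for _ in range(20):
            shuf = df.copy()
            shuf["label"] = rng.permutation(shuf["label"].to_numpy())
            m = fit_model(shuf)
            permuted.append(average_weight(m, j, "td"))
        assert np.mean(permuted) < 0.25 * w_true


class TestClassify:
    def test_weighted_ties_break_to_first_label(self, rng):
        clf = train_classifier(_training_table(rng, informative=False), "td")
        # force identical scores by making all class-conditionals equal
        clf.model.cond_probs[:] = clf.model.cond_probs[0]
        clf.model.priors[:] = 1 / 3
        label, scores = classify(clf, np.zeros(clf.model.n_features))
        assert np.allclose(scores, scores[0])
        assert label == "normal"

    def test_uniform_weights_match_unweighted_naive_bayes(self, rng):
        df = _training_table(rng)
        clf = train_classifier(df, "jsd")
        n = clf.model.n_features
        clf.weights.normalized = np.full(n, 1.0 / n)
        clf.model.priors[:] = 1 / 3
        for _ in range(25):
            x = rng.normal(3.0, 2.0, n)
            scores = class_scores(clf, x)
            # unweighted argmax computed independently
            logp = np.zeros(3)
            for j in range(n):
                b = int(np.searchsorted(clf.model.edges[j], x[j], side="right"))
                logp += np.log(clf.model.cond_probs[:, j, b])
            assert int(np.argmax(scores)) == int(np.argmax(logp))

    @staticmethod
    def _disjoint_table(rng, n_per_class=90):
        """One informative feature with disjoint class supports, one noise."""
        rows = []
        lo = {"normal": 0.0, "benign": 2.0, "malign": 4.0}
        for label in LABELS:
            for _ in range(n_per_class):
                rows.append({"label": label,
                             "f_sep": rng.uniform(lo[label], lo[label] + 1),
                             "f_noise": rng.normal(0.0, 1.0)})
        return pd.DataFrame(rows)

    @pytest.mark.parametrize("div", ["jsd", "hd", "td"])
    def test_disjoint_support_problem_is_perfect(self, div, rng):
        # R a multiple of the class count puts a bin edge inside each gap
        clf = train_classifier(self._disjoint_table(rng), div, R=9)
        test = self._disjoint_table(rng)
        X = test[clf.model.feature_names].to_numpy()
        pred = np.array([classify(clf, x)[0] for x in X])
        assert np.mean(pred == test["label"].to_numpy()) == 1.0

    def test_serialization_roundtrip(self, rng, tmp_path):
        clf = train_classifier(_training_table(rng), "hd", family="db2")
        p = tmp_path / "model.json"
        save_classifier(clf, p)
        back = load_classifier(p)
        x = rng.normal(3.0, 2.0, clf.model.n_features)
        lab1, s1 = classify(clf, x)
        lab2, s2 = classify(back, x)
        assert lab1 == lab2
        assert np.allclose(s1, s2)
        assert np.allclose(back.weights.normalized, clf.weights.normalized)
        assert back.family == "db2"
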