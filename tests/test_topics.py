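"""Seeded topic model: vocabulary, initialization, sampler, theme assignment."""

import numpy as np
import pytest

from gadprofiler import _sampler
from gadprofiler.topics import (
    GuidedTopicSpec, LdaConfig, ThemeAssignmentConfig, assign_tweet_themes,
    build_vocabulary, fit_model, gibbs_sweep, initialize_assignments,
    load_seed_specs, log_joint, theme_profile,
)

SPECS = [
    GuidedTopicSpec("alpha_theme", frozenset({"apple", "apricot"})),
    GuidedTopicSpec("beta_theme", frozenset({"banana", "berry"})),
]


def planted_docs(rng, n_docs=120, doc_len=12):
    """Two planted word pools plus shared filler."""
    pools = {
        0: ["apple", "apricot", "acorn", "almond", "anise"],
        1: ["banana", "berry", "bean", "beet", "basil"],
    }
    filler = ["table", "chair", "spoon", "plate"]
    docs = []
    for d in range(n_docs):
        k = d % 2
        words = list(rng.choice(pools[k], size=doc_len - 3)) + \
            list(rng.choice(filler, size=3))
        docs.append(words)
    return docs


class TestVocabulary:
    def test_min_df_prunes(self):
        docs = [["rare"] if i < 2 else ["common"] for i in range(10)]
        vocab = build_vocabulary(docs, min_df=5, max_df_fraction=1.0)
        assert vocab == ["common"]

    def test_seed_always_retained(self):
        docs = [["seedy"] if i == 0 else ["common"] for i in range(10)]
        vocab = build_vocabulary(docs, min_df=5, max_df_fraction=1.0,
                                 seed_words=frozenset({"seedy"}))
        assert "seedy" in vocab

    def test_high_df_pruned_and_tie_order_lexicographic(self):
        docs = [["everywhere", "aa", "bb"] if i < 5 else ["everywhere"]
                for i in range(10)]
        vocab = build_vocabulary(docs, min_df=5, max_df_fraction=0.5)
        assert vocab == ["aa", "bb"]  # df tie broken lexicographically
        vocab = build_vocabulary(docs, min_df=5, max_df_fraction=1.0)
        assert vocab == ["everywhere", "aa", "bb"]  # df desc, then lexicographic

    def test_empty_vocabulary_fatal(self):
        with pytest.raises(ValueError):
            build_vocabulary([["one"], ["two"]], min_df=5)


class TestInitialization:
    def test_pi_one_pins_every_seed_token(self):
        rng = np.random.default_rng(0)
        docs = planted_docs(rng)
        cfg = LdaConfig(seed_confidence=1.0, n_iterations=2, burn_in=1)
        model = initialize_assignments(docs, SPECS, cfg)
        windex = model.word_index
        for w, k in [("apple", 0), ("apricot", 0), ("banana", 1), ("berry", 1)]:
            mask = model.word_idx == windex[w]
            assert (model.z[mask] == k).all()

    def test_pi_zero_is_plain_uniform(self):
        rng = np.random.default_rng(0)
        docs = planted_docs(rng)
        cfg = LdaConfig(seed_confidence=0.0, n_iterations=2, burn_in=1,
                        rng_seed=7)
        model = initialize_assignments(docs, SPECS, cfg)
        seed_ids = [model.word_index[w] for w in
                    ("apple", "apricot", "banana", "berry")]
        mask = np.isin(model.word_idx, seed_ids)
        counts = np.bincount(model.z[mask], minlength=model.n_topics)
        assert (counts > 0).all()  # spread across all topics, not pinned

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(0)
        docs = planted_docs(rng)
        cfg = LdaConfig(n_iterations=2, burn_in=1, rng_seed=3)
        a = initialize_assignments(docs, SPECS, cfg)
        b = initialize_assignments(docs, SPECS, cfg)
        assert np.array_equal(a.z, b.z)

    def test_counts_match_assignments(self):
        rng = np.random.default_rng(0)
        docs = planted_docs(rng)
        model = initialize_assignments(
            docs, SPECS, LdaConfig(n_iterations=2, burn_in=1))
        model.check_counts()

    def test_duplicate_seed_across_themes_fatal(self):
        bad = [GuidedTopicSpec("a", frozenset({"x"})),
               GuidedTopicSpec("b", frozenset({"x"}))]
        with pytest.raises(ValueError, match="two themes"):
            initialize_assignments([["x", "x"]], bad,
                                   LdaConfig(n_iterations=2, burn_in=1))


class TestSweep:
    def _model(self, seed=0, **cfg_kwargs):
        rng = np.random.default_rng(1)
        docs = planted_docs(rng)
        cfg = LdaConfig(n_iterations=5, burn_in=1, rng_seed=seed, **cfg_kwargs)
        return docs, cfg, initialize_assignments(docs, SPECS, cfg)

    def test_exact_conservation_after_every_sweep(self):
        docs, cfg, model = self._model()
        for _ in range(5):
            gibbs_sweep(model, cfg)
            assert np.array_equal(
                model.n_dk.sum(axis=1),
                model.doc_lengths)
            model.check_counts()

    def test_single_topic_degenerate(self):
        docs = [["apple", "acorn"], ["apple", "apple"]]
        spec = [GuidedTopicSpec("only", frozenset({"apple"}))]
        cfg = LdaConfig(k_free=0, n_iterations=3, burn_in=1)
        model = initialize_assignments(docs, spec, cfg)
        for _ in range(3):
            gibbs_sweep(model, cfg)
        assert (model.z == 0).all()

    def test_identical_runs_identical_assignments(self):
        docs, cfg, m1 = self._model(seed=5)
        _, _, m2 = self._model(seed=5)
        for _ in range(4):
            gibbs_sweep(m1, cfg)
            gibbs_sweep(m2, cfg)
        assert np.array_equal(m1.z, m2.z)

    def test_python_and_jit_kernels_agree_bitwise(self):
        docs, cfg, m1 = self._model(seed=2)
        _, _, m2 = self._model(seed=2)
        rng1 = np.random.default_rng(99)
        rng2 = np.random.default_rng(99)
        for _ in range(3):
            u = rng1.random(m1.doc_idx.shape[0])
            _sampler.sweep(m1.doc_idx, m1.word_idx, m1.z, m1.n_dk, m1.n_kw,
                           m1.n_k, cfg.alpha, cfg.beta, u)
            u = rng2.random(m2.doc_idx.shape[0])
            _sampler.sweep_py(m2.doc_idx, m2.word_idx, m2.z, m2.n_dk, m2.n_kw,
                              m2.n_k, cfg.alpha, cfg.beta, u)
        assert np.array_equal(m1.z, m2.z)
        assert np.array_equal(m1.n_kw, m2.n_kw)


class TestFit:
    def test_rows_stochastic_and_guidance_recovers_pools(self):
        rng = np.random.default_rng(0)
        docs = planted_docs(rng, n_docs=200)
        cfg = LdaConfig(k_free=1, n_iterations=60, burn_in=20, thin=5,
                        rng_seed=0)
        model = fit_model(docs, SPECS, cfg)
        np.testing.assert_allclose(model.phi.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(model.theta.sum(axis=1), 1.0, atol=1e-9)
        pools = {
            "alpha_theme": {"apple", "apricot", "acorn", "almond", "anise"},
            "beta_theme": {"banana", "berry", "bean", "beet", "basil"},
        }
        for ki, name in enumerate(model.guided_names):
            top = model.top_words(ki, 5)
            assert sum(w in pools[name] for w in top) >= 4

    def test_loglik_trend_not_decreasing(self):
        rng = np.random.default_rng(0)
        docs = planted_docs(rng, n_docs=200)
        cfg = LdaConfig(k_free=1, n_iterations=60, burn_in=20,
                        loglik_every=1, rng_seed=0)
        model = fit_model(docs, SPECS, cfg)
        lls = [v for _, v in model.loglik_trace]
        first = np.mean(lls[:10])
        last = np.mean(lls[-10:])
        assert last > first

    def test_seed_confidence_beats_uniform_on_seed_mass(self):
        rng = np.random.default_rng(0)
        docs = planted_docs(rng, n_docs=200)
        masses = {}
        for pi in (0.7, 0.0):
            cfg = LdaConfig(k_free=1, n_iterations=60, burn_in=20, thin=5,
                            seed_confidence=pi, rng_seed=0)
            model = fit_model(docs, SPECS, cfg)
            windex = model.word_index
            mass = np.mean([
                model.phi[ki, windex[w]]
                for ki, spec in enumerate(SPECS) for w in spec.seed_words
            ])
            masses[pi] = mass
        assert masses[0.7] > masses[0.0]


class TestThemeAssignment:
    def _fitted_toy(self):
        docs = [["apple"] * 3 + ["table"],        # 0.75 on guided topic 0
                ["apple", "table"],               # too short for min_tokens=3
                ["table", "spoon", "plate"]]      # background only
        spec = [GuidedTopicSpec("alpha_theme", frozenset({"apple"}))]
        cfg = LdaConfig(k_free=1, n_iterations=30, burn_in=10, thin=2,
                        seed_confidence=1.0, rng_seed=0)
        return fit_model(docs, spec, cfg,
                         vocabulary=["apple", "table", "spoon", "plate"])

    def test_share_threshold_and_min_tokens(self):
        model = self._fitted_toy()
        themes = assign_tweet_themes(model, ThemeAssignmentConfig())
        assert themes[0] == {"alpha_theme"}
        assert themes[1] == frozenset()      # below min_tokens
        assert themes[2] == frozenset()      # background document

    def test_tau_one_requires_unanimous_assignment(self):
        import numpy as np
        model = self._fitted_toy()
        # Pin the posterior-mean counts: 3 of doc 0's four tokens guided.
        model.mean_n_dk = model.mean_n_dk.copy()
        model.mean_n_dk[0] = [3.0, 1.0]
        themes = assign_tweet_themes(
            model, ThemeAssignmentConfig(tau=1.0, min_tokens=3))
        assert themes[0] == frozenset()      # mixed assignments: share 0.75 < 1
        themes = assign_tweet_themes(
            model, ThemeAssignmentConfig(tau=0.75, min_tokens=3))
        assert themes[0] == {"alpha_theme"}

    def test_profile_arithmetic(self):
        sets = [frozenset({"symptoms"})] * 2 + [frozenset()] * 8
        prof = theme_profile("u", sets, ["symptoms", "feelings"])
        assert prof.theme_pct["symptoms"] == 20.0
        assert prof.theme_pct["feelings"] == 0.0
        assert prof.per_tweet_freq == pytest.approx(0.2)

    def test_zero_tweets_flagged(self):
        with pytest.raises(ValueError):
            theme_profile("u", [], ["symptoms"])


class TestDefaults:
    def test_shipped_seed_specs(self):
        specs = load_seed_specs()
        names = [s.name for s in specs]
        assert names == ["symptoms", "life_problems", "relationships", "feelings"]
        sym = dict((s.name, s.seed_words) for s in specs)["symptoms"]
        assert {"worry", "concern", "anxiety", "health"} <= sym

    def test_config_validation(self):
        with pytest.raises(ValueError):
            LdaConfig(alpha=0.0)
        with pytest.raises(ValueError):
            LdaConfig(burn_in=500, n_iterations=500)
        with pytest.raises(ValueError):
            ThemeAssignmentConfig(tau=0.0)
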