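"""Seed-guided latent Dirichlet allocation with collapsed Gibbs sampling.

Semisupervised LDA: each guided topic carries a set of seed words.  Guidance
acts at initialization only — a seed-word token starts in its guided topic
with probability ``seed_confidence`` (π) and uniformly at random otherwise;
the sampler conditional itself is the standard unbiased collapsed form.
Documents are individual tweets; theme prevalence is therefore denominated in
tweets per user.  A tweet "expresses" a theme when at least a τ share of its
modeled tokens sit in that guided topic (posterior-averaged assignments).
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import gammaln

from . import _sampler
from .preprocess import lemmatize, pos_tag


@dataclasses.dataclass
class GuidedTopicSpec:
    name: str
    seed_words: frozenset[str]

    def __post_init__(self) -> None:
        if not self.seed_words:
            raise ValueError(f"theme {self.name!r} has an empty seed set")
        for w in self.seed_words:
            if w != w.lower():
                raise ValueError(f"seed {w!r} is not lower-case")


def load_seed_specs(path: Optional[str | Path] = None,
                    normalize: bool = True) -> list[GuidedTopicSpec]:
    """Load theme → seed-word lists from YAML (shipped defaults if no path).

    With ``normalize=True`` seeds pass through the same tagger/lemmatizer as
    the documents, so surface forms like "kids" meet their document lemma
    "kid" in the model vocabulary.
    """
    if path is None:
        raw = yaml.safe_load(
            resources.files("gadprofiler.data")
            .joinpath("theme_seeds.yaml").read_text(encoding="utf-8")
        )
    else:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    specs = []
    for name, words in raw.items():
        words = [str(w).lower() for w in words]
        if normalize:
            words = lemmatize(words, pos_tag(words))
        specs.append(GuidedTopicSpec(name, frozenset(words)))
    seen: dict[str, str] = {}
    for spec in specs:
        for w in spec.seed_words:
            if w in seen:
                raise ValueError(
                    f"seed word {w!r} appears in both {seen[w]!r} and {spec.name!r}"
                )
            seen[w] = spec.name
    return specs


@dataclasses.dataclass
class LdaConfig:
    k_free: int = 2               # unguided background topics
    alpha: float = 0.1            # symmetric document-topic prior
    beta: float = 0.01            # symmetric topic-word prior
    seed_confidence: float = 0.7  # π
    n_iterations: int = 500
    burn_in: int = 100
    thin: int = 10                # average counts every thin-th post-burn-in sweep
    loglik_every: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if not 0.0 <= self.seed_confidence <= 1.0:
            raise ValueError("seed_confidence must lie in [0, 1]")
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.k_free < 0:
            raise ValueError("k_free must be nonnegative")


@dataclasses.dataclass
class ThemeAssignmentConfig:
    tau: float = 0.5       # token-share threshold
    min_tokens: int = 3    # minimum modeled tokens per tweet

    def __post_init__(self) -> None:
        if not 0.0 < self.tau <= 1.0:
            raise ValueError("tau must lie in (0, 1]")


def build_vocabulary(
    docs: Sequence[Sequence[str]],
    min_df: int = 5,
    max_df_fraction: float = 0.5,
    seed_words: frozenset[str] = frozenset(),
) -> list[str]:
    """Document-frequency pruned vocabulary with a deterministic order.

    Words with df < ``min_df`` or df > ``max_df_fraction``·D are removed;
    seed words are always retained.  Order: df descending, then lexicographic.
    """
    if not any(len(d) for d in docs):
        raise ValueError("no nonempty documents")
    df: dict[str, int] = {}
    for doc in docs:
        for w in set(doc):
            df[w] = df.get(w, 0) + 1
    d_total = len(docs)
    kept = {
        w: n for w, n in df.items()
        if (min_df <= n <= max_df_fraction * d_total) or w in seed_words
    }
    for w in seed_words:
        kept.setdefault(w, df.get(w, 0))
    if not kept:
        raise ValueError("vocabulary empty after document-frequency pruning")
    return sorted(kept, key=lambda w: (-kept[w], w))


@dataclasses.dataclass
class TopicModel:
    vocabulary: list[str]
    guided_names: list[str]
    k_free: int
    config: LdaConfig
    doc_idx: np.ndarray      # token → document
    word_idx: np.ndarray     # token → vocabulary index
    z: np.ndarray            # token → topic assignment
    n_dk: np.ndarray
    n_kw: np.ndarray
    n_k: np.ndarray
    doc_lengths: np.ndarray  # modeled (in-vocabulary) tokens per document
    rng: np.random.Generator
    phi: Optional[np.ndarray] = None
    theta: Optional[np.ndarray] = None
    mean_n_dk: Optional[np.ndarray] = None
    loglik_trace: list[tuple[int, float]] = dataclasses.field(default_factory=list)

    @property
    def n_topics(self) -> int:
        return len(self.guided_names) + self.k_free

    @property
    def n_docs(self) -> int:
        return self.n_dk.shape[0]

    @property
    def word_index(self) -> dict[str, int]:
        return {w: i for i, w in enumerate(self.vocabulary)}

    def check_counts(self) -> None:
        """Assert exact integer consistency of count tables with assignments."""
        K, D, V = self.n_topics, self.n_docs, len(self.vocabulary)
        n_dk = np.zeros((D, K), dtype=np.int32)
        np.add.at(n_dk, (self.doc_idx, self.z), 1)
        n_kw = np.zeros((K, V), dtype=np.int32)
        np.add.at(n_kw, (self.z, self.word_idx), 1)
        if not (np.array_equal(n_dk, self.n_dk)
                and np.array_equal(n_kw, self.n_kw)
                and np.array_equal(n_kw.sum(axis=1), self.n_k)):
            raise AssertionError("count tables inconsistent with assignments")

    def top_words(self, topic: int, n: int = 10) -> list[str]:
        phi = self.phi if self.phi is not None else self.n_kw + self.config.beta
        order = np.argsort(-phi[topic])
        return [self.vocabulary[i] for i in order[:n]]


def initialize_assignments(
    docs: Sequence[Sequence[str]],
    specs: Sequence[GuidedTopicSpec],
    config: LdaConfig,
    vocabulary: Optional[list[str]] = None,
) -> TopicModel:
    """Build the initial model state with seed-confidence initialization.

    A token of a seed word of guided topic k starts in k with probability π,
    otherwise uniformly at random over all topics; non-seed tokens start
    uniformly at random.  Out-of-vocabulary tokens are dropped from the model.
    """
    seen: dict[str, int] = {}
    for ki, spec in enumerate(specs):
        for w in spec.seed_words:
            if w in seen:
                raise ValueError(f"seed word {w!r} belongs to two themes")
            seen[w] = ki
    all_seeds = frozenset(seen)
    if vocabulary is None:
        vocabulary = build_vocabulary(docs, seed_words=all_seeds)
    windex = {w: i for i, w in enumerate(vocabulary)}
    K = len(specs) + config.k_free
    if K < 1:
        raise ValueError("model needs at least one topic")

    doc_idx, word_idx, doc_lengths = [], [], []
    for d, doc in enumerate(docs):
        n = 0
        for w in doc:
            wi = windex.get(w)
            if wi is not None:
                doc_idx.append(d)
                word_idx.append(wi)
                n += 1
        doc_lengths.append(n)
    doc_idx = np.asarray(doc_idx, dtype=np.int64)
    word_idx = np.asarray(word_idx, dtype=np.int64)
    T = doc_idx.shape[0]

    rng = np.random.default_rng(config.rng_seed)
    z = rng.integers(0, K, size=T)
    seed_topic_of_word = np.full(len(vocabulary), -1, dtype=np.int64)
    for w, ki in seen.items():
        if w in windex:
            seed_topic_of_word[windex[w]] = ki
    guided = seed_topic_of_word[word_idx]
    take_seed = rng.random(T) < config.seed_confidence
    mask = (guided >= 0) & take_seed
    z[mask] = guided[mask]

    n_dk = np.zeros((len(docs), K), dtype=np.int32)
    np.add.at(n_dk, (doc_idx, z), 1)
    n_kw = np.zeros((K, len(vocabulary)), dtype=np.int32)
    np.add.at(n_kw, (z, word_idx), 1)
    model = TopicModel(
        vocabulary=vocabulary,
        guided_names=[s.name for s in specs],
        k_free=config.k_free,
        config=config,
        doc_idx=doc_idx,
        word_idx=word_idx,
        z=z,
        n_dk=n_dk,
        n_kw=n_kw,
        n_k=n_kw.sum(axis=1).astype(np.int64),
        doc_lengths=np.asarray(doc_lengths, dtype=np.int64),
        rng=rng,
    )
    return model


def gibbs_sweep(model: TopicModel, config: Optional[LdaConfig] = None) -> TopicModel:
    """Resample every token once, in deterministic document/token order."""
    cfg = config or model.config
    u = model.rng.random(model.doc_idx.shape[0])
    _sampler.sweep(
        model.doc_idx, model.word_idx, model.z,
        model.n_dk, model.n_kw, model.n_k,
        cfg.alpha, cfg.beta, u,
    )
    if int(model.n_k.sum()) != model.doc_idx.shape[0]:
        raise AssertionError("token count not conserved by sweep")
    return model


def log_joint(model: TopicModel) -> float:
    """Collapsed log p(w, z): two Dirichlet-multinomial terms."""
    a, b = model.config.alpha, model.config.beta
    K, V = model.n_topics, len(model.vocabulary)
    nd = model.doc_lengths
    doc_term = (
        model.n_docs * (gammaln(K * a) - K * gammaln(a))
        + gammaln(model.n_dk + a).sum()
        - gammaln(nd + K * a).sum()
    )
    word_term = (
        K * (gammaln(V * b) - V * gammaln(b))
        + gammaln(model.n_kw + b).sum()
        - gammaln(model.n_k + V * b).sum()
    )
    return float(doc_term + word_term)


def fit_model(
    docs: Sequence[Sequence[str]],
    specs: Sequence[GuidedTopicSpec],
    config: Optional[LdaConfig] = None,
    vocabulary: Optional[list[str]] = None,
) -> TopicModel:
    """Initialization plus ``n_iterations`` sweeps with posterior averaging.

    φ and θ are estimated from count tables averaged over every ``thin``-th
    post-burn-in sweep; the log-joint trace is recorded every
    ``loglik_every`` sweeps.
    """
    if config is None:
        config = LdaConfig()
    model = initialize_assignments(docs, specs, config, vocabulary)
    acc_dk = np.zeros_like(model.n_dk, dtype=np.float64)
    acc_kw = np.zeros_like(model.n_kw, dtype=np.float64)
    n_samples = 0
    for it in range(config.n_iterations):
        gibbs_sweep(model, config)
        if config.loglik_every and (it % config.loglik_every == 0):
            model.loglik_trace.append((it, log_joint(model)))
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            acc_dk += model.n_dk
            acc_kw += model.n_kw
            n_samples += 1
    if n_samples == 0:  # degenerate config: fall back to final state
        acc_dk, acc_kw, n_samples = model.n_dk.astype(float), model.n_kw.astype(float), 1
    mean_kw = acc_kw / n_samples
    mean_dk = acc_dk / n_samples
    V = len(model.vocabulary)
    K = model.n_topics
    model.phi = (mean_kw + config.beta) / (
        mean_kw.sum(axis=1, keepdims=True) + V * config.beta)
    model.theta = (mean_dk + config.alpha) / (
        mean_dk.sum(axis=1, keepdims=True) + K * config.alpha)
    model.mean_n_dk = mean_dk
    return model


def assign_tweet_themes(
    model: TopicModel,
    assign_cfg: Optional[ThemeAssignmentConfig] = None,
) -> list[frozenset[str]]:
    """Per-document theme sets under the token-share rule.

    A document expresses guided theme k iff its posterior-mean share of
    tokens in topic k is at least τ and it has at least ``min_tokens``
    modeled tokens.  Multi-label is allowed; background topics never yield
    themes.
    """
    cfg = assign_cfg or ThemeAssignmentConfig()
    counts = model.mean_n_dk if model.mean_n_dk is not None else model.n_dk
    lengths = np.maximum(model.doc_lengths, 1)
    shares = counts[:, :len(model.guided_names)] / lengths[:, None]
    out = []
    for d in range(model.n_docs):
        if model.doc_lengths[d] < cfg.min_tokens:
            out.append(frozenset())
            continue
        out.append(frozenset(
            name for ki, name in enumerate(model.guided_names)
            if shares[d, ki] >= cfg.tau
        ))
    return out


@dataclasses.dataclass
class ThemeProfile:
    user_id: str
    theme_pct: dict[str, float]   # % of the user's tweets expressing each theme
    per_tweet_freq: float         # mean number of themes per tweet


def theme_profile(
    user_id: str,
    tweet_themes: Sequence[frozenset[str]],
    theme_names: Sequence[str],
) -> ThemeProfile:
    """Aggregate per-tweet theme sets into a user profile."""
    n = len(tweet_themes)
    if n == 0:
        raise ValueError(f"user {user_id!r} has zero tweets")
    pct = {
        name: 100.0 * sum(1 for s in tweet_themes if name in s) / n
        for name in theme_names
    }
    freq = sum(len(s) for s in tweet_themes) / n
    return ThemeProfile(user_id, pct, freq)


def theme_profiles_frame(profiles: Iterable[ThemeProfile]) -> pd.DataFrame:
    rows = {}
    for p in profiles:
        row = dict(p.theme_pct)
        row["per_tweet_freq"] = p.per_tweet_freq
        rows[p.user_id] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def save_model(model: TopicModel, outdir: str | Path) -> None:
    """Dump φ (topic×word TSV), θ (doc×topic TSV) and a run-metadata JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    topics = model.guided_names + [
        f"background_{i}" for i in range(model.k_free)]
    if model.phi is not None:
        pd.DataFrame(model.phi, index=topics, columns=model.vocabulary).to_csv(
            outdir / "phi.tsv", sep="\t")
    if model.theta is not None:
        pd.DataFrame(model.theta, columns=topics).to_csv(
            outdir / "theta.tsv", sep="\t", index_label="doc")
    meta = {
        "config": dataclasses.asdict(model.config),
        "n_docs": int(model.n_docs),
        "n_tokens": int(model.doc_idx.shape[0]),
        "vocabulary_size": len(model.vocabulary),
        "guided_topics": model.guided_names,
        "k_free": model.k_free,
        "loglik_trace": model.loglik_trace,
    }
    (outdir / "model_metadata.json").write_text(
        json.dumps(meta, indent=2), encoding="utf-8")
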