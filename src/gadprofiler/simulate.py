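"""Synthetic two-group corpus generator with planted effects and ground truth.

The generator emulates the study conditions of a diagnosed-vs-control
microblog cohort: per-user tweet volumes at the observed scale, per-user
category word-usage rates at linguistic-table scale (three designated
categories carry exact planted effect sizes d ∈ {0.4, 0.8, 1.2}), mutually
exclusive per-tweet theme labels at thematic-table scale, and behavioral
flag probabilities (reply / retweet / hashtag / mention) at behavior-table
scale.  A latent per-user severity factor in the diagnosed group tilts both
theme probabilities and behavior flags through a logistic link, which is the
mechanism that produces group-specific theme × behavior correlations.

Tokens are draws from structured, mutually disjoint vocabularies — no
natural-language realism is attempted.  Group moments are planted by
stratified (quantile-randomized) draws so that realized means and SDs match
their targets essentially exactly, and every planted quantity is recoverable
from :class:`GroundTruth` by closed-form bookkeeping.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from .corpus import Cohort, Group, TweetRecord, UserCorpus, UserRecord
from .lexicon import Lexicon, open_fixture_lexicon

_EPOCH = datetime(2023, 1, 1, tzinfo=timezone.utc)

THEMES = ("symptoms", "life_problems", "relationships", "feelings")
FLAGS = ("reply", "retweet", "hashtag", "mention")

#: Designated categories carrying exact planted effect sizes, as
#: (category, d, control_mean_pct, common_sd_pct).  The three highest-rate
#: categories are used so multinomial token noise leaves the realized d
#: essentially unattenuated.
PLANTED_CATEGORY_EFFECTS = (
    ("curiosity", 1.2, 3.82, 1.2),
    ("communication", 0.8, 4.80, 1.25),
    ("negative_tone", 0.4, 4.24, 1.5),
)

#: Non-designated category usage rates, category → group → (mean%, sd%),
#: at linguistic-table scale.
_TABLE_CATEGORY_RATES: dict[str, dict[str, tuple[float, float]]] = {
    "insight": {"GAD": (1.59, 0.57), "CONTROL": (0.90, 0.65)},
    "causation": {"GAD": (1.028, 0.39), "CONTROL": (0.60, 0.44)},
    "discrepancy": {"GAD": (1.39, 0.47), "CONTROL": (0.78, 0.58)},
    "tentativeness": {"GAD": (1.40, 0.48), "CONTROL": (0.74, 0.56)},
    "certitude": {"GAD": (0.57, 0.29), "CONTROL": (0.30, 0.31)},
    "differentiation": {"GAD": (2.15, 0.71), "CONTROL": (1.17, 0.88)},
    "memory": {"GAD": (0.10, 0.07), "CONTROL": (0.07, 0.09)},
    "need": {"GAD": (0.35, 0.18), "CONTROL": (0.20, 0.18)},
    "want": {"GAD": (0.38, 0.25), "CONTROL": (0.23, 0.21)},
    "lack": {"GAD": (0.11, 0.20), "CONTROL": (0.06, 0.07)},
    "reward": {"GAD": (0.11, 0.22), "CONTROL": (0.15, 0.46)},
    "risk": {"GAD": (0.19, 0.12), "CONTROL": (0.11, 0.12)},
    "substances": {"GAD": (0.05, 0.17), "CONTROL": (0.03, 0.06)},
    "food": {"GAD": (0.48, 0.33), "CONTROL": (0.32, 0.44)},
    "death": {"GAD": (0.19, 0.19), "CONTROL": (0.11, 0.13)},
    "interpersonal_conflict": {"GAD": (0.27, 0.17), "CONTROL": (0.18, 0.19)},
    "anxiety": {"GAD": (0.18, 0.26), "CONTROL": (0.06, 0.08)},
    "anger": {"GAD": (0.17, 0.12), "CONTROL": (0.09, 0.10)},
    "sadness": {"GAD": (0.22, 0.22), "CONTROL": (0.13, 0.15)},
    "swear_words": {"GAD": (0.77, 0.74), "CONTROL": (0.47, 0.72)},
}

_THEME_EXTRAS: dict[str, list[str]] = {
    "symptoms": [
        "insomnia", "headache", "fatigue", "tremor", "nausea", "dizziness",
        "heartbeat", "breathing", "sleepless", "therapy", "doctor",
        "symptom", "diagnosis", "medication", "tension",
    ],
    "life_problems": [
        "deadline", "bills", "debt", "rent", "boss", "interview", "exam",
        "grades", "homework", "unemployment", "paycheck", "overtime",
        "career", "budget", "taxes",
    ],
    "relationships": [
        "marriage", "divorce", "family", "brother", "sister", "mother",
        "daughter", "son", "roommate", "neighbor", "girlfriend",
        "boyfriend", "cousin", "grandma", "uncle",
    ],
    "feelings": [
        "emotions", "empathy", "comfort", "gratitude", "warmth", "kindness",
        "sharing", "openness", "trust", "affection", "compassion",
        "listening", "caring", "hug", "gentle",
    ],
}

_DEFAULT_SEEDS: dict[str, list[str]] = {
    "symptoms": ["worry", "concern", "anxiety", "twitch", "treatment",
                 "restlessness", "concentration", "muscle", "mental", "health"],
    "life_problems": ["business", "money", "work", "school", "job", "salary",
                      "promotion", "college", "office", "experience"],
    "relationships": ["wife", "husband", "parents", "kids", "friends",
                      "partners", "spouse", "fiancee", "fiance", "father"],
    "feelings": ["feel", "cry", "respect", "release", "support", "emotion",
                 "disclosure", "care", "sadness", "sense", "sorry"],
}

_FILLER = [
    "morning", "coffee", "window", "street", "garden", "weather", "guitar",
    "picture", "camera", "kitchen", "table", "chair", "mountain", "river",
    "ocean", "train", "airport", "ticket", "jacket", "pocket", "umbrella",
    "bicycle", "library", "museum", "market", "concert", "painting", "poem",
    "novel", "chapter", "puzzle", "garden", "bridge", "castle", "village",
    "island", "forest", "meadow", "sunset", "sunrise", "cloud", "thunder",
    "raincoat", "sweater", "blanket", "pillow", "candle", "lantern",
    "keyboard", "screen", "battery", "charger", "headphones", "playlist",
    "podcast", "episode", "season", "trailer", "cinema", "theater",
    "stadium", "soccer", "tennis", "cricket", "swimming", "yoga", "hiking",
    "camping", "recipe", "garlic", "pepper", "basil", "lemon", "mango",
    "banana", "orange", "grape", "cherry", "walnut", "almond", "honey",
    "teapot", "saucer", "spoon", "fork", "plate", "basket", "bucket",
    "ladder", "hammer", "wrench", "garage", "driveway", "balcony", "ceiling",
    "carpet", "curtain", "mirror", "drawer", "shelf", "closet", "doorbell",
    "mailbox", "envelope", "stamp", "postcard", "calendar", "notebook",
    "pencil", "eraser", "marker", "scissors", "glue", "ribbon", "thread",
]


@dataclasses.dataclass
class Vocabulary:
    """Disjoint word pools: per-category, per-theme, and filler."""
    category_words: dict[str, list[str]]
    theme_words: dict[str, list[str]]
    filler: list[str]

    def validate_disjoint(self, lexicon: Lexicon) -> None:
        """Fail if any theme/filler word matches a lexicon entry, or any word
        sits in two pools — the separation that keeps linguistic and thematic
        recovery unconfounded."""
        for theme, words in self.theme_words.items():
            for w in words:
                if lexicon.match_token(w):
                    raise ValueError(
                        f"theme word {w!r} ({theme}) matches lexicon "
                        f"categories {set(lexicon.match_token(w))}")
        for w in self.filler:
            if lexicon.match_token(w):
                raise ValueError(f"filler word {w!r} matches the lexicon")
        all_theme = [w for ws in self.theme_words.values() for w in ws]
        if len(all_theme) != len(set(all_theme)):
            raise ValueError("a word appears in two theme pools")
        overlap = set(all_theme) & set(self.filler)
        if overlap:
            raise ValueError(f"theme/filler overlap: {overlap}")


def default_vocabulary(lexicon: Optional[Lexicon] = None) -> Vocabulary:
    """Generation pools derived from the open lexicon and default seed lists.

    Category pools are the lexicon's own patterns (stems keep their prefix
    semantics: the stem itself is emitted and matches its entry).  Theme and
    filler words that would collide with the lexicon are dropped defensively.
    """
    lex = lexicon or open_fixture_lexicon()
    cat_words: dict[str, list[str]] = {c: [] for c in lex.categories}
    for pattern, cats in lex.entries:
        word = pattern.rstrip("*")
        for c in cats:
            if len(cats) == 1:  # keep pools unambiguous
                cat_words[c].append(word)
    theme_words = {
        t: [w for w in _DEFAULT_SEEDS[t] + _THEME_EXTRAS[t]
            if not lex.match_token(w)]
        for t in THEMES
    }
    filler = sorted({w for w in _FILLER if not lex.match_token(w)})
    vocab = Vocabulary(cat_words, theme_words, filler)
    vocab.validate_disjoint(lex)
    return vocab


def _zipf_weights(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


@dataclasses.dataclass
class SimulationConfig:
    """Study-condition parameters; defaults reproduce the observed scale."""
    n_gad: int = 1316
    n_control: int = 1463
    tweets_per_user: dict = dataclasses.field(default_factory=lambda: {
        "GAD": (2559.0, 1316.0), "CONTROL": (2697.0, 918.0)})
    min_tweets: int = 100          # truncation floor so default corpora pass filters
    tokens_per_tweet: tuple[int, int] = (5, 25)
    category_rates: dict = dataclasses.field(default_factory=dict)
    theme_prevalence: dict = dataclasses.field(default_factory=lambda: {
        "symptoms": {"GAD": 10.0, "CONTROL": 5.0},
        "life_problems": {"GAD": 11.0, "CONTROL": 7.0},
        "relationships": {"GAD": 13.0, "CONTROL": 7.0},
        "feelings": {"GAD": 9.0, "CONTROL": 4.0},
    })
    theme_token_share: float = 0.9  # share of non-category tokens that are theme words
    flag_means: dict = dataclasses.field(default_factory=lambda: {
        "reply": {"GAD": 0.41, "CONTROL": 0.29},
        "retweet": {"GAD": 0.29, "CONTROL": 0.49},
        "hashtag": {"GAD": 0.087, "CONTROL": 0.16},
        "mention": {"GAD": 0.32, "CONTROL": 0.51},
    })
    flag_concentration: float = 20.0   # Beta a+b for per-user flag probabilities
    severity_theme_loading: float = 0.5
    severity_flag_loading: dict = dataclasses.field(default_factory=lambda: {
        "reply": 0.6, "retweet": 0.0, "hashtag": 0.4, "mention": 0.3})
    tweets_per_day: dict = dataclasses.field(default_factory=lambda: {
        "GAD": (2.85, 0.8), "CONTROL": (3.09, 0.8)})   # (mean, lognormal sigma)
    follower_scale: dict = dataclasses.field(default_factory=lambda: {
        "GAD": (1493.0, 2.0), "CONTROL": (2148.0, 2.2)})
    friend_scale: dict = dataclasses.field(default_factory=lambda: {
        "GAD": (860.0, 1.5), "CONTROL": (1620.0, 1.8)})
    listed_scale: dict = dataclasses.field(default_factory=lambda: {
        "GAD": (14.0, 1.5), "CONTROL": (20.6, 1.5)})
    favorites_given_scale: dict = dataclasses.field(default_factory=lambda: {
        "GAD": (25480.0, 1.2), "CONTROL": (37215.0, 1.2)})
    p_tweet_favorited: dict = dataclasses.field(default_factory=lambda: {
        "GAD": 0.35, "CONTROL": 0.50})
    p_tweet_retweeted: dict = dataclasses.field(default_factory=lambda: {
        "GAD": 0.34, "CONTROL": 0.53})
    english_noise_fraction: float = 0.0  # users with <80% English, to exercise filters
    low_volume_fraction: float = 0.0     # users with <100 tweets, to exercise filters
    api_cap: Optional[int] = None        # optional per-user history cap (off)
    rng_seed: int = 0
    vocabulary: Optional[Vocabulary] = None

    def __post_init__(self) -> None:
        if not self.category_rates:
            self.category_rates = copy.deepcopy(_TABLE_CATEGORY_RATES)
            for cat, d, ctl_mean, sd in PLANTED_CATEGORY_EFFECTS:
                gad_mean = ctl_mean + d * sd * (
                    -1.0 if cat == "communication" else 1.0)
                self.category_rates[cat] = {
                    "GAD": (gad_mean, sd), "CONTROL": (ctl_mean, sd)}
        if self.vocabulary is None:
            self.vocabulary = default_vocabulary()
        for cat, groups in self.category_rates.items():
            for g, (m, s) in groups.items():
                if m < 0 or s < 0:
                    raise ValueError(f"negative rate parameters for {cat}/{g}")
        for t, groups in self.theme_prevalence.items():
            for g, p in groups.items():
                if not 0.0 <= p <= 100.0:
                    raise ValueError(f"theme prevalence out of range: {t}/{g}")
        for f, groups in self.flag_means.items():
            for g, p in groups.items():
                if not 0.0 < p < 1.0:
                    raise ValueError(f"flag mean out of range: {f}/{g}")
        if not 0.0 <= self.theme_token_share <= 1.0:
            raise ValueError("theme_token_share must lie in [0, 1]")
        lo, hi = self.tokens_per_tweet
        if lo < 1 or hi < lo:
            raise ValueError("invalid tokens_per_tweet range")

    def planted_category_d(self, category: str) -> float:
        """Pooled-SD effect size implied by the configured rate parameters."""
        (m1, s1), (m2, s2) = (self.category_rates[category]["GAD"],
                              self.category_rates[category]["CONTROL"])
        pooled = np.sqrt((s1 ** 2 + s2 ** 2) / 2.0)
        return abs(m1 - m2) / pooled


def recovery_config(n_per_group: int = 200,
                    tweets_mean: float = 150.0,
                    tweets_sd: float = 30.0,
                    rng_seed: int = 0) -> SimulationConfig:
    """Desk-scale preset for parameter-recovery runs.

    Same planted effects and distributions as the full-scale defaults, with
    group sizes and per-user volumes reduced so the end-to-end pipeline runs
    in minutes on one CPU.
    """
    return SimulationConfig(
        n_gad=n_per_group,
        n_control=n_per_group,
        tweets_per_user={"GAD": (tweets_mean, tweets_sd),
                         "CONTROL": (tweets_mean, tweets_sd)},
        rng_seed=rng_seed,
    )


# ---------------------------------------------------------------------------
# Calibration and stratified draws
# ---------------------------------------------------------------------------

_HERM_X, _HERM_W = np.polynomial.hermite.hermgauss(41)
_NODES = np.sqrt(2.0) * _HERM_X          # standard-normal quadrature nodes
_WEIGHTS = _HERM_W / np.sqrt(np.pi)


def _calibrate_intercept(target: float, loading: float) -> float:
    """Intercept a with E_s[expit(a + loading·s)] = target, s ~ N(0,1)."""
    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf
    if loading == 0.0:
        return float(logit(target))

    def gap(a: float) -> float:
        return float(np.dot(_WEIGHTS, expit(a + loading * _NODES))) - target

    return float(brentq(gap, -30.0, 30.0, xtol=1e-12))


def _calibrate_offset(base_logits: np.ndarray, loading: float,
                      target: float) -> float:
    """Offset c with mean over users/severity of expit(l_i + loading·s + c)
    equal to target — keeps tilted flag means exactly on their plant."""
    if loading == 0.0:
        return 0.0

    def gap(c: float) -> float:
        vals = expit(base_logits[:, None] + loading * _NODES[None, :] + c)
        return float((vals @ _WEIGHTS).mean()) - target

    return float(brentq(gap, -20.0, 20.0, xtol=1e-12))


def _stratified_normal(n: int, mean: float, sd: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Quantile-stratified normal sample in random order: the realized mean
    and SD match their targets up to finite-n quadrature error."""
    z = norm.ppf((np.arange(n) + 0.5) / n)
    rng.shuffle(z)
    return mean + sd * z


def _stratified_beta(n: int, mean: float, concentration: float,
                     rng: np.random.Generator) -> np.ndarray:
    a = mean * concentration
    b = (1.0 - mean) * concentration
    u = (np.arange(n) + 0.5) / n
    rng.shuffle(u)
    return beta_dist.ppf(u, a, b)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class UserTruth:
    user_id: str
    group: str
    severity: float
    category_rates: dict[str, float]      # percent of words
    theme_probs: dict[str, float]         # per-tweet probabilities
    flag_probs: dict[str, float]          # marginal per-tweet flag probabilities
    n_tweets: int


@dataclasses.dataclass
class GroundTruth:
    users: dict[str, UserTruth]
    tweet_themes: dict[str, Optional[str]]
    config: SimulationConfig

    def realized_category_d(self, category: str) -> float:
        """Pooled-SD d over the realized per-user planted rates."""
        g = np.array([u.category_rates[category] for u in self.users.values()
                      if u.group == "GAD"])
        c = np.array([u.category_rates[category] for u in self.users.values()
                      if u.group == "CONTROL"])
        pooled = np.sqrt(((g.size - 1) * g.var(ddof=1)
                          + (c.size - 1) * c.var(ddof=1))
                         / (g.size + c.size - 2))
        return float(abs(g.mean() - c.mean()) / pooled)

    def realized_theme_prevalence(self, theme: str, group: str) -> float:
        """Mean planted per-tweet theme probability, in percent."""
        vals = [u.theme_probs[theme] for u in self.users.values()
                if u.group == group]
        return 100.0 * float(np.mean(vals))

    def realized_flag_mean(self, flag: str, group: str) -> float:
        vals = [u.flag_probs[flag] for u in self.users.values()
                if u.group == group]
        return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Per-user simulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class _UserParams:
    user_id: str
    group: str
    severity: float
    n_tweets: int
    category_rates: np.ndarray        # aligned with sorted category names
    theme_probs: np.ndarray           # aligned with THEMES
    flag_probs: dict[str, float]
    tweets_per_day: float
    follower: int
    friend: int
    listed: int
    favorites_given: int
    english_noise: bool = False


def _category_names(config: SimulationConfig) -> list[str]:
    return sorted(config.category_rates)


def simulate_user_tweets(
    params: _UserParams, config: SimulationConfig, rng: np.random.Generator,
) -> tuple[list[TweetRecord], dict[str, Optional[str]]]:
    """Generate one user's tweet history plus per-tweet true theme labels.

    Token process per tweet: each token is a category word with its planted
    per-category probability (over *all* tokens, so realized category shares
    are theme-independent); remaining tokens are theme words with probability
    ``theme_token_share`` when the tweet carries a theme, else filler words.
    """
    vocab = config.vocabulary
    cats = _category_names(config)
    n = params.n_tweets
    lo, hi = config.tokens_per_tweet
    lengths = rng.integers(lo, hi + 1, size=n)
    total = int(lengths.sum())
    tweet_of = np.repeat(np.arange(n), lengths)

    # Per-tweet theme: categorical over the four themes + none.
    theme_cum = np.cumsum(params.theme_probs)
    u_theme = rng.random(n)
    theme_idx = np.searchsorted(theme_cum, u_theme)  # len(THEMES) = none

    # Token classes.
    cat_cum = np.cumsum(params.category_rates / 100.0)
    r = rng.random(total)
    cls = np.searchsorted(cat_cum, r)                # < len(cats): category
    themed_token = theme_idx[tweet_of] < len(THEMES)
    is_theme_word = (cls >= len(cats)) & themed_token & (
        rng.random(total) < config.theme_token_share)

    words = np.empty(total, dtype=object)
    for ci, cat in enumerate(cats):
        mask = cls == ci
        k = int(mask.sum())
        if k:
            pool = vocab.category_words[cat]
            words[mask] = rng.choice(pool, size=k, p=_zipf_weights(len(pool)))
    for ti, theme in enumerate(THEMES):
        mask = is_theme_word & (theme_idx[tweet_of] == ti)
        k = int(mask.sum())
        if k:
            pool = vocab.theme_words[theme]
            words[mask] = rng.choice(pool, size=k, p=_zipf_weights(len(pool)))
    mask = (cls >= len(cats)) & ~is_theme_word
    k = int(mask.sum())
    if k:
        words[mask] = rng.choice(vocab.filler, size=k)

    # Behavioral flags: retweet wins over reply so the categories stay
    # disjoint while both keep their planted marginals.
    p_rt = params.flag_probs["retweet"]
    p_rep = min(params.flag_probs["reply"] / max(1.0 - p_rt, 1e-9), 0.95)
    u1 = rng.random(n)
    is_retweet = u1 < p_rt
    is_reply = (~is_retweet) & (rng.random(n) < p_rep)
    has_hashtag = rng.random(n) < params.flag_probs["hashtag"]
    has_mention = rng.random(n) < params.flag_probs["mention"]

    # Timestamps over the user's observed span.
    span_days = max(n / max(params.tweets_per_day, 1e-6), 1.0)
    offsets = np.sort(rng.random(n)) * span_days

    favorited = rng.random(n) < config.p_tweet_favorited[params.group]
    retweeted = rng.random(n) < config.p_tweet_retweeted[params.group]
    fav_counts = np.where(favorited, rng.geometric(0.3, size=n), 0)
    rt_counts = np.where(retweeted, rng.geometric(0.4, size=n), 0)

    if params.english_noise:
        non_english = rng.random(n) < 0.5
    else:
        non_english = np.zeros(n, dtype=bool)

    offsets_tok = np.concatenate([[0], np.cumsum(lengths)])
    tweets: list[TweetRecord] = []
    truth: dict[str, Optional[str]] = {}
    for i in range(n):
        toks = list(words[offsets_tok[i]:offsets_tok[i + 1]])
        if has_hashtag[i] and toks:
            j = int(rng.integers(0, len(toks)))
            toks[j] = "#" + toks[j]
        if has_mention[i]:
            j = int(rng.integers(0, len(toks) + 1))
            toks.insert(j, f"@u{rng.integers(0, 10 ** 6)}")
        tid = f"{params.user_id}-{i:06d}"
        tweets.append(TweetRecord(
            tweet_id=tid,
            user_id=params.user_id,
            text=" ".join(toks),
            created_at=_EPOCH + timedelta(days=float(offsets[i])),
            favorite_count=int(fav_counts[i]),
            retweet_count=int(rt_counts[i]),
            reply_to_user_id=(f"u{rng.integers(0, 10 ** 6)}"
                              if is_reply[i] else None),
            is_retweet=bool(is_retweet[i]),
            language="es" if non_english[i] else "en",
        ))
        truth[tid] = THEMES[theme_idx[i]] if theme_idx[i] < len(THEMES) else None
    return tweets, truth


def simulate_behavior_metadata(
    params: _UserParams, config: SimulationConfig, rng: np.random.Generator,
) -> UserRecord:
    """Account-level metadata for one user (heavy-tailed count fields)."""
    return UserRecord(
        user_id=params.user_id,
        status_count=params.n_tweets,
        description="synthetic user",
        verified=False,
        account_created_at=_EPOCH - timedelta(days=1500),
        follower_count=params.follower,
        friend_count=params.friend,
        listed_count=params.listed,
        favorite_count=params.favorites_given,
    )


def _lognormal_counts(n: int, mean: float, sigma: float,
                      rng: np.random.Generator) -> np.ndarray:
    mu = np.log(mean) - sigma ** 2 / 2.0
    return np.floor(rng.lognormal(mu, sigma, size=n)).astype(int)


def _draw_group_params(
    group: str, n: int, config: SimulationConfig, rng: np.random.Generator,
) -> list[_UserParams]:
    cats = _category_names(config)
    severity = rng.standard_normal(n) if group == "GAD" else np.zeros(n)

    rates = np.zeros((n, len(cats)))
    for ci, cat in enumerate(cats):
        m, s = config.category_rates[cat][group]
        rates[:, ci] = np.clip(_stratified_normal(n, m, s, rng), 0.0, None)

    lam = config.severity_theme_loading if group == "GAD" else 0.0
    theme_p = np.zeros((n, len(THEMES)))
    for ti, theme in enumerate(THEMES):
        target = config.theme_prevalence[theme][group] / 100.0
        a = _calibrate_intercept(target, lam)
        theme_p[:, ti] = expit(a + lam * severity)
    # Guard the categorical draw: total themed probability must stay < 1.
    row_sum = theme_p.sum(axis=1)
    over = row_sum > 0.95
    if over.any():
        theme_p[over] *= (0.95 / row_sum[over])[:, None]

    flag_p: dict[str, np.ndarray] = {}
    for flag in FLAGS:
        m = config.flag_means[flag][group]
        base = _stratified_beta(n, m, config.flag_concentration, rng)
        base = np.clip(base, 1e-4, 1.0 - 1e-4)
        load = config.severity_flag_loading.get(flag, 0.0) if group == "GAD" else 0.0
        if load:
            logits = logit(base)
            c = _calibrate_offset(logits, load, m)
            # Integrate severity per user at its realized value.
            flag_p[flag] = expit(logits + load * severity + c)
        else:
            flag_p[flag] = base

    tm, ts = config.tweets_per_user[group]
    n_tweets = np.maximum(
        np.round(rng.normal(tm, ts, size=n)).astype(int), config.min_tweets)
    if config.low_volume_fraction > 0:
        low = rng.random(n) < config.low_volume_fraction
        n_tweets[low] = rng.integers(10, config.min_tweets, size=int(low.sum()))
    if config.api_cap is not None:
        n_tweets = np.minimum(n_tweets, config.api_cap)

    tpd_mean, tpd_sigma = config.tweets_per_day[group]
    tpd = rng.lognormal(np.log(tpd_mean) - tpd_sigma ** 2 / 2, tpd_sigma, size=n)

    followers = _lognormal_counts(n, *config.follower_scale[group], rng)
    friends = _lognormal_counts(n, *config.friend_scale[group], rng)
    listed = _lognormal_counts(n, *config.listed_scale[group], rng)
    favs = _lognormal_counts(n, *config.favorites_given_scale[group], rng)

    noise = (rng.random(n) < config.english_noise_fraction
             if config.english_noise_fraction > 0 else np.zeros(n, dtype=bool))

    prefix = "g" if group == "GAD" else "c"
    out = []
    for i in range(n):
        out.append(_UserParams(
            user_id=f"{prefix}{i:05d}",
            group=group,
            severity=float(severity[i]),
            n_tweets=int(n_tweets[i]),
            category_rates=rates[i],
            theme_probs=theme_p[i],
            flag_probs={f: float(flag_p[f][i]) for f in FLAGS},
            tweets_per_day=float(tpd[i]),
            follower=int(followers[i]),
            friend=int(friends[i]),
            listed=int(listed[i]),
            favorites_given=int(favs[i]),
            english_noise=bool(noise[i]),
        ))
    return out


def simulate_cohort(
    config: Optional[SimulationConfig] = None,
) -> tuple[Cohort, Cohort, GroundTruth]:
    """Generate the full two-group corpus plus ground truth.

    Fully deterministic under ``config.rng_seed``; generated corpora pass the
    corpus module's schema validation and (with default noise knobs) all
    cohort filters.
    """
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(config.rng_seed)
    cats = _category_names(config)
    cohorts = {}
    users_truth: dict[str, UserTruth] = {}
    tweet_truth: dict[str, Optional[str]] = {}
    for group, n in (("GAD", config.n_gad), ("CONTROL", config.n_control)):
        params = _draw_group_params(group, n, config, rng)
        user_corpora = []
        for p in params:
            tweets, t_truth = simulate_user_tweets(p, config, rng)
            record = simulate_behavior_metadata(p, config, rng)
            user_corpora.append(UserCorpus(record, tweets, group=Group(group)))
            tweet_truth.update(t_truth)
            users_truth[p.user_id] = UserTruth(
                user_id=p.user_id,
                group=group,
                severity=p.severity,
                category_rates={c: float(r) for c, r in
                                zip(cats, p.category_rates)},
                theme_probs={t: float(v) for t, v in
                             zip(THEMES, p.theme_probs)},
                flag_probs=dict(p.flag_probs),
                n_tweets=p.n_tweets,
            )
        cohorts[group] = Cohort(user_corpora, group=Group(group))
    truth = GroundTruth(users_truth, tweet_truth, config)
    return cohorts["GAD"], cohorts["CONTROL"], truth


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Persist ground truth as JSON (config without the word pools)."""
    cfg = dataclasses.asdict(truth.config)
    cfg.pop("vocabulary", None)
    payload = {
        "config": cfg,
        "users": {uid: dataclasses.asdict(u)
                  for uid, u in truth.users.items()},
        "tweet_themes": truth.tweet_themes,
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")
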