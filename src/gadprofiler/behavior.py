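"""Metadata-derived behavioral features: 21 per-user activity metrics plus
account-level volume columns.

Conventions (documented so counts are reproducible):

* ``n_tweets`` counts all retained tweets — originals, replies and retweets.
* a tweet is a *retweet* iff its metadata flag is set or its text starts with
  ``RT @``; a tweet is a *reply* iff it has a reply target and is not a
  retweet (quote-style reply-retweets count as retweets only, keeping the
  categories disjoint);
* hashtags and mentions are extracted from the raw text with the corpus
  module's platform regexes;
* per-day rates divide by the observed tweet span (retrieved histories are
  truncated, so account age would deflate rates); the alternative
  ``account_age`` denominator is available by flag.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd

from .corpus import Cohort, MENTION_RE, TweetRecord, UserCorpus

#: Column order of the behavioral feature matrix.
BEHAVIOR_COLUMNS = [
    "ff_ratio",
    "mentions_per_tweet",
    "n_tweets",
    "n_replies",
    "reply_to_tweet_ratio",
    "n_hashtag_tweets",
    "hashtag_ratio",
    "n_retweets",
    "retweet_to_tweet_ratio",
    "n_mentions_total",
    "n_mentions_excl_replies",
    "mention_ratio",
    "n_tweets_with_favorites",
    "tweets_with_favorites_ratio",
    "n_tweets_with_retweets",
    "tweets_with_retweets_ratio",
    "tweets_per_day",
    "replies_per_day",
    "retweets_per_day",
    "mentions_per_day",
    "hashtag_tweets_per_day",
]

ACCOUNT_COLUMNS = [
    "follower_count",
    "friend_count",
    "listed_count",
    "favorite_count",
    "status_count",
    "retweets_received_total",
]


def ratio(numerator: float, denominator: float) -> float:
    """Exact numerator/denominator; NaN when the denominator is zero.

    This is the single ratio primitive behind every ``*_ratio`` column.
    """
    if denominator == 0:
        return math.nan
    return numerator / denominator


def observation_window(user: UserCorpus) -> int:
    """Observed span in whole days, inclusive: floor(Δt in days) + 1, min 1."""
    if not user.tweets:
        raise ValueError(f"user {user.user.user_id} has zero tweets")
    first = user.tweets[0].created_at
    last = user.tweets[-1].created_at
    return int((last - first).total_seconds() // 86400) + 1


def _is_reply(t: TweetRecord) -> bool:
    return t.reply_to_user_id is not None and not t.retweet_like()


def _leading_mention(t: TweetRecord) -> bool:
    stripped = t.text.lstrip()
    m = MENTION_RE.match(stripped)
    return m is not None and m.start() == 0


def compute_behavior_profile(user: UserCorpus) -> dict[str, float]:
    """The 21 activity metrics for one user, as a plain dict.

    ``n_mentions_excl_replies`` drops, in reply tweets, the single leading
    mention of the reply target.  ``ff_ratio`` is missing (NaN) when the user
    follows nobody — never infinite.
    """
    tweets = user.tweets
    n = len(tweets)
    if n == 0:
        raise ValueError(f"user {user.user.user_id} has zero tweets")
    days = observation_window(user)

    n_retweets = sum(1 for t in tweets if t.retweet_like())
    n_replies = sum(1 for t in tweets if _is_reply(t))
    mention_counts = [len(t.mentions()) for t in tweets]
    n_mentions_total = sum(mention_counts)
    n_mentions_excl = sum(
        c - 1 if (_is_reply(t) and _leading_mention(t) and c > 0) else c
        for t, c in zip(tweets, mention_counts)
    )
    n_mention_tweets = sum(1 for c in mention_counts if c > 0)
    n_hashtag_tweets = sum(1 for t in tweets if t.hashtags())
    n_fav = sum(1 for t in tweets if t.favorite_count >= 1)
    n_rt_recv = sum(1 for t in tweets if t.retweet_count >= 1)

    friend = user.user.friend_count
    follower = user.user.follower_count
    return {
        "ff_ratio": ratio(follower, friend),
        "mentions_per_tweet": ratio(n_mentions_total, n),
        "n_tweets": n,
        "n_replies": n_replies,
        "reply_to_tweet_ratio": ratio(n_replies, n),
        "n_hashtag_tweets": n_hashtag_tweets,
        "hashtag_ratio": ratio(n_hashtag_tweets, n),
        "n_retweets": n_retweets,
        "retweet_to_tweet_ratio": ratio(n_retweets, n),
        "n_mentions_total": n_mentions_total,
        "n_mentions_excl_replies": n_mentions_excl,
        "mention_ratio": ratio(n_mention_tweets, n),
        "n_tweets_with_favorites": n_fav,
        "tweets_with_favorites_ratio": ratio(n_fav, n),
        "n_tweets_with_retweets": n_rt_recv,
        "tweets_with_retweets_ratio": ratio(n_rt_recv, n),
        "tweets_per_day": n / days,
        "replies_per_day": n_replies / days,
        "retweets_per_day": n_retweets / days,
        "mentions_per_day": n_mention_tweets / days,
        "hashtag_tweets_per_day": n_hashtag_tweets / days,
    }


def cohort_behavior_matrix(cohort: Cohort) -> pd.DataFrame:
    """User × feature table: 21 activity metrics plus account-level columns.

    Missing values (``ff_ratio`` with zero followees) are NaN and are dropped
    pairwise by downstream statistics.
    """
    rows = {}
    for uc in cohort.users:
        row = compute_behavior_profile(uc)
        row["follower_count"] = uc.user.follower_count
        row["friend_count"] = uc.user.friend_count
        row["listed_count"] = uc.user.listed_count
        row["favorite_count"] = uc.user.favorite_count
        row["status_count"] = uc.user.status_count
        row["retweets_received_total"] = sum(t.retweet_count for t in uc.tweets)
        rows[uc.user.user_id] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    return frame[BEHAVIOR_COLUMNS + ACCOUNT_COLUMNS]


def cohort_descriptives(matrix: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Per-feature mean/SD/median/IQR, NaN dropped."""
    out = {}
    for col in matrix.columns:
        vals = matrix[col].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        out[col] = {
            "n": int(vals.size),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else math.nan,
            "median": float(med),
            "iqr_low": float(q1),
            "iqr_high": float(q3),
        }
    return out
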