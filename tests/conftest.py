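"""Shared fixtures: tiny hand-built cohorts and corpus builders."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import pytest

from gadprofiler.corpus import Cohort, Group, TweetRecord, UserCorpus, UserRecord

EPOCH = datetime(2023, 1, 1, tzinfo=timezone.utc)


def make_tweet(uid: str, i: int, text: str = "hello world", *,
               hours: float | None = None, **kwargs) -> TweetRecord:
    return TweetRecord(
        tweet_id=f"{uid}-{i:04d}",
        user_id=uid,
        text=text,
        created_at=EPOCH + timedelta(hours=i if hours is None else hours),
        language=kwargs.pop("language", "en"),
        **kwargs,
    )


def make_user(uid: str, texts: list[str] | int, group: Group = Group.UNLABELED,
              tweet_kwargs: list[dict] | None = None, **user_kwargs) -> UserCorpus:
    if isinstance(texts, int):
        texts = [f"tweet number {i}" for i in range(texts)]
    tweet_kwargs = tweet_kwargs or [{}] * len(texts)
    tweets = [make_tweet(uid, i, t, **kw)
              for i, (t, kw) in enumerate(zip(texts, tweet_kwargs))]
    return UserCorpus(UserRecord(user_id=uid, **user_kwargs), tweets, group=group)


@pytest.fixture
def two_user_cohort() -> Cohort:
    return Cohort([
        make_user("alice", ["first post", "second post", "third post"],
                  follower_count=10, friend_count=4),
        make_user("bob", ["one", "two", "three"],
                  follower_count=3, friend_count=0),
    ])
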