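"""Tweet corpus data model, JSON-lines I/O, and cohort construction.

A corpus on disk is a directory holding two JSON-lines files, ``tweets.jsonl``
and ``users.jsonl``.  The first line of each file is a schema header; every
subsequent line is one record.  Cohort construction mirrors the collection
protocol of self-reported-diagnosis studies: a diagnosis-statement regex finds
candidate users, heuristic flags build a human review worksheet, and fixed
filters (English fraction, minimum history length) plus group-overlap removal
produce the analysis cohorts.  Every exclusion is logged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

SCHEMA_VERSION = 1

#: Platform-faithful extraction patterns (bit-exact; see README).
MENTION_RE = re.compile(r"@[A-Za-z0-9_]{1,15}")
HASHTAG_RE = re.compile(r"#\w+", re.UNICODE)

#: Default self-reported diagnosis statement.  Case-insensitive, tolerates the
#: parenthetical abbreviation being absent and variable whitespace.
DIAGNOSIS_PATTERN = re.compile(
    r"i\s+was\s+diagnosed\s+with\s+generali[sz]ed\s+anxiety\s+disorder"
    r"(?:\s*\(\s*gad\s*\))?",
    re.IGNORECASE,
)


class Group(str, Enum):
    GAD = "GAD"
    CONTROL = "CONTROL"
    UNLABELED = "UNLABELED"


def _parse_ts(value: str) -> datetime:
    ts = datetime.fromisoformat(value)
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


@dataclasses.dataclass
class TweetRecord:
    tweet_id: str
    user_id: str
    text: str
    created_at: datetime
    favorite_count: int = 0
    retweet_count: int = 0
    reply_to_user_id: Optional[str] = None
    is_retweet: bool = False
    language: Optional[str] = None

    def __post_init__(self) -> None:
        if self.favorite_count < 0 or self.retweet_count < 0:
            raise ValueError(f"negative engagement count on tweet {self.tweet_id}")
        if isinstance(self.created_at, str):
            self.created_at = _parse_ts(self.created_at)

    def to_json(self) -> dict:
        return {
            "tweet_id": self.tweet_id,
            "user_id": self.user_id,
            "text": self.text,
            "created_at": self.created_at.isoformat(),
            "favorite_count": self.favorite_count,
            "retweet_count": self.retweet_count,
            "reply_to_user_id": self.reply_to_user_id,
            "is_retweet": self.is_retweet,
            "language": self.language,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "TweetRecord":
        return cls(
            tweet_id=str(obj["tweet_id"]),
            user_id=str(obj["user_id"]),
            text=obj["text"],
            created_at=_parse_ts(obj["created_at"]),
            favorite_count=int(obj.get("favorite_count", 0)),
            retweet_count=int(obj.get("retweet_count", 0)),
            reply_to_user_id=obj.get("reply_to_user_id"),
            is_retweet=bool(obj.get("is_retweet", False)),
            language=obj.get("language"),
        )

    def mentions(self) -> list[str]:
        """Mention occurrences in the raw text (extract before cleaning)."""
        return MENTION_RE.findall(self.text)

    def hashtags(self) -> list[str]:
        return HASHTAG_RE.findall(self.text)

    def retweet_like(self) -> bool:
        """Retweet by metadata flag OR classic ``RT @`` text prefix."""
        return self.is_retweet or self.text.startswith("RT @")


@dataclasses.dataclass
class UserRecord:
    user_id: str
    status_count: int = 0
    description: str = ""
    verified: bool = False
    account_created_at: Optional[datetime] = None
    follower_count: int = 0
    friend_count: int = 0
    listed_count: int = 0
    favorite_count: int = 0

    def __post_init__(self) -> None:
        for f in ("status_count", "follower_count", "friend_count",
                  "listed_count", "favorite_count"):
            if getattr(self, f) < 0:
                raise ValueError(f"negative {f} for user {self.user_id}")
        if isinstance(self.account_created_at, str):
            self.account_created_at = _parse_ts(self.account_created_at)

    def to_json(self) -> dict:
        return {
            "user_id": self.user_id,
            "status_count": self.status_count,
            "description": self.description,
            "verified": self.verified,
            "account_created_at": (
                self.account_created_at.isoformat()
                if self.account_created_at else None
            ),
            "follower_count": self.follower_count,
            "friend_count": self.friend_count,
            "listed_count": self.listed_count,
            "favorite_count": self.favorite_count,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "UserRecord":
        ts = obj.get("account_created_at")
        return cls(
            user_id=str(obj["user_id"]),
            status_count=int(obj.get("status_count", 0)),
            description=obj.get("description", ""),
            verified=bool(obj.get("verified", False)),
            account_created_at=_parse_ts(ts) if ts else None,
            follower_count=int(obj.get("follower_count", 0)),
            friend_count=int(obj.get("friend_count", 0)),
            listed_count=int(obj.get("listed_count", 0)),
            favorite_count=int(obj.get("favorite_count", 0)),
        )


def _tweet_sort_key(t: TweetRecord):
    # Ties in created_at broken by tweet_id lexicographic order.
    return (t.created_at, t.tweet_id)


@dataclasses.dataclass
class UserCorpus:
    user: UserRecord
    tweets: list[TweetRecord]
    group: Group = Group.UNLABELED

    def __post_init__(self) -> None:
        for t in self.tweets:
            if t.user_id != self.user.user_id:
                raise ValueError(
                    f"tweet {t.tweet_id} does not belong to user {self.user.user_id}"
                )
        self.tweets = sorted(self.tweets, key=_tweet_sort_key)


@dataclasses.dataclass
class FilterEvent:
    user_id: str
    rule: str
    detail: str = ""


@dataclasses.dataclass
class CorpusError:
    line_no: int
    message: str


@dataclasses.dataclass
class Cohort:
    users: list[UserCorpus]
    group: Group = Group.UNLABELED
    provenance: list[FilterEvent] = dataclasses.field(default_factory=list)
    errors: list[CorpusError] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [u.user.user_id for u in self.users]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate user ids in cohort")

    def __len__(self) -> int:
        return len(self.users)

    def user_ids(self) -> list[str]:
        return [u.user.user_id for u in self.users]

    def n_tweets(self) -> int:
        return sum(len(u.tweets) for u in self.users)

    def get(self, user_id: str) -> UserCorpus:
        for u in self.users:
            if u.user.user_id == user_id:
                return u
        raise KeyError(user_id)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _header(kind: str) -> dict:
    return {"format": "gadprofiler-corpus", "version": SCHEMA_VERSION, "kind": kind}


def write_corpus(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as ``tweets.jsonl`` + ``users.jsonl`` under ``path``.

    Output is bit-stable for identical input: user order, tweet order and JSON
    key order are all deterministic.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "users.jsonl", "w", encoding="utf-8") as fh:
        fh.write(json.dumps(_header("users"), sort_keys=True) + "\n")
        for uc in cohort.users:
            fh.write(json.dumps(uc.user.to_json(), sort_keys=True) + "\n")
    with open(path / "tweets.jsonl", "w", encoding="utf-8") as fh:
        fh.write(json.dumps(_header("tweets"), sort_keys=True) + "\n")
        for uc in cohort.users:
            for t in uc.tweets:
                fh.write(json.dumps(t.to_json(), sort_keys=True) + "\n")


def _read_jsonl(path: Path, kind: str, errors: list[CorpusError]):
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        try:
            head = json.loads(first)
            if head.get("kind") != kind:
                raise ValueError(f"expected kind={kind!r}")
        except (json.JSONDecodeError, ValueError) as exc:
            raise ValueError(f"{path}: bad or missing header line: {exc}") from exc
        for line_no, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            try:
                yield line_no, json.loads(line)
            except json.JSONDecodeError as exc:
                errors.append(CorpusError(line_no, f"{path.name}: {exc}"))


def read_corpus(path: str | Path, group_label: Group = Group.UNLABELED,
                salt: Optional[str] = None) -> Cohort:
    """Read a corpus directory into a :class:`Cohort`.

    Malformed lines are recorded in ``cohort.errors`` (line number and reason)
    and skipped — never silently dropped.  If ``salt`` is given, a stable
    salted-hash anonymization pass is applied to all identifiers on ingest.
    """
    path = Path(path)
    if not (path / "tweets.jsonl").exists():
        raise FileNotFoundError(f"no tweets.jsonl under {path}")
    errors: list[CorpusError] = []
    users: dict[str, UserRecord] = {}
    for line_no, obj in _read_jsonl(path / "users.jsonl", "users", errors):
        try:
            rec = UserRecord.from_json(obj)
            users[rec.user_id] = rec
        except (KeyError, ValueError, TypeError) as exc:
            errors.append(CorpusError(line_no, f"users.jsonl: {exc}"))
    tweets: dict[str, list[TweetRecord]] = {}
    for line_no, obj in _read_jsonl(path / "tweets.jsonl", "tweets", errors):
        try:
            rec = TweetRecord.from_json(obj)
            tweets.setdefault(rec.user_id, []).append(rec)
        except (KeyError, ValueError, TypeError) as exc:
            errors.append(CorpusError(line_no, f"tweets.jsonl: {exc}"))
    ucs = []
    for uid, urec in users.items():
        ucs.append(UserCorpus(urec, tweets.pop(uid, []), group=group_label))
    for uid, orphan in tweets.items():  # tweets with no user record
        ucs.append(UserCorpus(UserRecord(user_id=uid), orphan, group=group_label))
    cohort = Cohort(ucs, group=group_label, errors=errors)
    if salt is not None:
        cohort = anonymize_cohort(cohort, salt)
    return cohort


# ---------------------------------------------------------------------------
# Anonymization
# ---------------------------------------------------------------------------

def _hash_id(value: str, salt: str) -> str:
    return hashlib.sha256(f"{salt}:{value}".encode("utf-8")).hexdigest()[:12]


def anonymize_cohort(cohort: Cohort, salt: str) -> Cohort:
    """De-identify user and tweet ids with a stable salted hash.

    The same (salt, id) pair always maps to the same pseudonym, so joins
    across files remain valid while raw platform identifiers are dropped.
    """
    out = []
    for uc in cohort.users:
        user = dataclasses.replace(uc.user, user_id=_hash_id(uc.user.user_id, salt))
        tws = [
            dataclasses.replace(
                t,
                tweet_id=_hash_id(t.tweet_id, salt),
                user_id=user.user_id,
                reply_to_user_id=(
                    _hash_id(t.reply_to_user_id, salt)
                    if t.reply_to_user_id else None
                ),
            )
            for t in uc.tweets
        ]
        out.append(UserCorpus(user, tws, group=uc.group))
    return Cohort(out, group=cohort.group,
                  provenance=list(cohort.provenance), errors=list(cohort.errors))


# ---------------------------------------------------------------------------
# Diagnosis-statement search and review flagging
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DiagnosisCandidate:
    tweet: TweetRecord
    start: int
    end: int

    @property
    def span_text(self) -> str:
        return self.tweet.text[self.start:self.end]


def detect_diagnosis_candidates(
    tweets: Iterable[TweetRecord],
    pattern: re.Pattern | str = DIAGNOSIS_PATTERN,
) -> list[DiagnosisCandidate]:
    """Scan tweets for the self-reported diagnosis statement.

    Returns every matching tweet with its matched span.  No per-user
    deduplication happens here; that belongs to cohort assembly.
    """
    if isinstance(pattern, str):
        try:
            pattern = re.compile(pattern, re.IGNORECASE)
        except re.error as exc:
            raise ValueError(f"invalid diagnosis pattern: {exc}") from exc
    out = []
    for t in tweets:
        m = pattern.search(t.text)
        if m:
            out.append(DiagnosisCandidate(t, m.start(), m.end()))
    return out


_REPORTED_RE = re.compile(r"\b(said|says|saying|told me|according to)\b", re.IGNORECASE)
_THIRD_PERSON_RE = re.compile(r"\b(she|he|they)\b", re.IGNORECASE)
_NEGATION_RE = re.compile(r"\b(never|not|n't)\b|n't\b", re.IGNORECASE)
_QUOTE_CHARS = "\"“”«»‘’'"


@dataclasses.dataclass
class ReviewFlag:
    candidate: DiagnosisCandidate
    status: str  # "auto_ok" | "needs_review"
    reasons: list[str]


def flag_for_review(candidate: DiagnosisCandidate) -> ReviewFlag:
    """Heuristic review flags for a diagnosis candidate.

    These are worksheet hints for the human verification step, never an
    automatic exclusion: quotation marks around the span, reported-speech
    markers, third-person subjects, and negation each add a reason.
    """
    text = candidate.tweet.text
    reasons = []
    before = text[:candidate.start]
    after = text[candidate.end:]
    if any(c in before for c in "\"“«") and any(
            c in after for c in "\"”»"):
        reasons.append("quotation")
    if _REPORTED_RE.search(text):
        reasons.append("reported-speech")
    if _THIRD_PERSON_RE.search(text):
        reasons.append("third-person")
    if _NEGATION_RE.search(text):
        reasons.append("negation")
    status = "needs_review" if reasons else "auto_ok"
    return ReviewFlag(candidate, status, reasons)


def write_review_worksheet(flags: Sequence[ReviewFlag], path: str | Path) -> None:
    """TSV worksheet: tweet_id, user_id, matched_span, status, reasons."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("tweet_id\tuser_id\tmatched_span\tstatus\treasons\n")
        for fl in flags:
            span = fl.candidate.span_text.replace("\t", " ").replace("\n", " ")
            fh.write(
                f"{fl.candidate.tweet.tweet_id}\t{fl.candidate.tweet.user_id}\t"
                f"{span}\t{fl.status}\t{','.join(fl.reasons)}\n"
            )


# ---------------------------------------------------------------------------
# Cohort filters
# ---------------------------------------------------------------------------

def apply_cohort_filters(
    cohort: Cohort,
    min_tweets: int = 100,
    min_english_fraction: float = 0.8,
    language_classifier: Optional[Callable[[str], str]] = None,
) -> Cohort:
    """Apply the fixed cohort inclusion rules, logging every exclusion.

    Order of operations:

    1. drop users whose English tweet fraction is below ``min_english_fraction``;
    2. for surviving users, drop their non-English tweets;
    3. drop users whose remaining history is shorter than ``min_tweets``.

    Per-tweet language tags are trusted when present; otherwise
    ``language_classifier`` must be supplied (text -> 2-letter tag).
    """
    def lang_of(t: TweetRecord) -> str:
        if t.language is not None:
            return t.language
        if language_classifier is None:
            raise ValueError(
                f"tweet {t.tweet_id} has no language tag and no classifier was given"
            )
        return language_classifier(t.text)

    kept: list[UserCorpus] = []
    log: list[FilterEvent] = list(cohort.provenance)
    for uc in cohort.users:
        if not uc.tweets:
            log.append(FilterEvent(uc.user.user_id, "min_tweets", "0 tweets"))
            continue
        langs = [lang_of(t) for t in uc.tweets]
        n_en = sum(1 for l in langs if l == "en")
        frac = n_en / len(uc.tweets)
        if frac < min_english_fraction:
            log.append(FilterEvent(
                uc.user.user_id, "english_fraction",
                f"{n_en}/{len(uc.tweets)} English ({100 * frac:.1f}%)"))
            continue
        en_tweets = [t for t, l in zip(uc.tweets, langs) if l == "en"]
        if len(en_tweets) < min_tweets:
            log.append(FilterEvent(
                uc.user.user_id, "min_tweets",
                f"{len(en_tweets)} English tweets after language filter"))
            continue
        kept.append(UserCorpus(uc.user, en_tweets, group=uc.group))
    return Cohort(kept, group=cohort.group, provenance=log, errors=list(cohort.errors))


def remove_group_overlap(gad: Cohort, control: Cohort) -> tuple[Cohort, Cohort]:
    """Drop users present in both groups from the control group only."""
    gad_ids = set(gad.user_ids())
    kept, log = [], list(control.provenance)
    for uc in control.users:
        if uc.user.user_id in gad_ids:
            log.append(FilterEvent(uc.user.user_id, "group_overlap",
                                   "present in diagnosed group"))
        else:
            kept.append(uc)
    return gad, Cohort(kept, group=control.group, provenance=log,
                       errors=list(control.errors))
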