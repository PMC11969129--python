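"""Text cleaning and the tokenize → stopword → POS → lemmatize chain.

Two token streams leave this module.  ``raw_tokens`` (post-cleaning,
pre-stopword) feed lexicon scoring, because several scored categories —
tentativeness, discrepancy, differentiation — live largely in stopword-like
function words and would be zeroed by a stopword pass.  ``topic_tokens``
(stopword-free, lemmatized) feed the topic model.  The default tagger and
lemmatizer are small shipped lookup tables plus suffix rules; any external
tagger/lemmatizer with the same signature can be injected.
"""

from __future__ import annotations

import dataclasses
import html
import re
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

from .corpus import Cohort, MENTION_RE, TweetRecord

URL_RE = re.compile(r"(?:https?://\S+|www\.\S+)", re.IGNORECASE)
HTML_TAG_RE = re.compile(r"<[^>]+>")
_WS_RE = re.compile(r"\s+")

#: Common sideways emoticons survive tokenization as single tokens so literal
#: emoticon lexicon entries can match them.
_EMOTICON = r"[:;=8][\-o^']?[()\[\]dDpP/\\|*]"
TOKEN_RE = re.compile(_EMOTICON + r"|@user\b|\w+(?:'\w+)*|[^\w\s]", re.UNICODE)

COARSE_TAGS = ("NOUN", "VERB", "ADJ", "ADV", "OTHER")


def clean_text(text: str) -> str:
    """Lower-case; strip URLs, HTML tags/entities; neutralize mentions.

    Mentions are replaced by the anonymous placeholder ``@user``.  Hashtag and
    mention lists must be extracted from the raw text (corpus module) *before*
    this op — cleaning is for content analysis only.  Idempotent.
    """
    text = html.unescape(text)
    text = HTML_TAG_RE.sub(" ", text)
    text = URL_RE.sub(" ", text)
    text = text.lower()
    text = MENTION_RE.sub("@user", text)
    return _WS_RE.sub(" ", text).strip()


def tokenize(text: str) -> list[str]:
    """Split cleaned text into word tokens.

    Intra-word apostrophes are preserved (``can't`` is one token); punctuation
    is emitted as separate tokens and removed downstream; the ``#`` of a
    hashtag separates from its word, so hashtag words enter the text stream.
    """
    return TOKEN_RE.findall(text)


@lru_cache(maxsize=1)
def default_stopwords() -> frozenset[str]:
    data = resources.files("gadprofiler.data").joinpath("stopwords.txt")
    return frozenset(
        w.strip() for w in data.read_text(encoding="utf-8").splitlines() if w.strip()
    )


def _is_punct(token: str) -> bool:
    return not any(ch.isalnum() for ch in token)


def remove_stopwords_and_punct(
    tokens: Sequence[str], stoplist: Optional[frozenset[str]] = None
) -> list[str]:
    """Drop stoplist members and pure-punctuation tokens, preserving order."""
    if stoplist is None:
        stoplist = default_stopwords()
    return [t for t in tokens if t not in stoplist and not _is_punct(t)]


@lru_cache(maxsize=1)
def default_tag_lexicon() -> Mapping[str, str]:
    data = resources.files("gadprofiler.data").joinpath("pos_lexicon.tsv")
    out = {}
    for line in data.read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        token, tag = line.split("\t")
        out[token] = tag
    return out


_SUFFIX_RULES: tuple[tuple[str, str], ...] = (
    ("ly", "ADV"),
    ("ing", "VERB"),
    ("ed", "VERB"),
    ("ize", "VERB"),
    ("ise", "VERB"),
    ("ous", "ADJ"),
    ("ful", "ADJ"),
    ("ive", "ADJ"),
    ("able", "ADJ"),
    ("ible", "ADJ"),
    ("ish", "ADJ"),
    ("less", "ADJ"),
    ("tion", "NOUN"),
    ("sion", "NOUN"),
    ("ness", "NOUN"),
    ("ment", "NOUN"),
    ("ity", "NOUN"),
    ("ism", "NOUN"),
)


def pos_tag(
    tokens: Sequence[str], tag_lexicon: Optional[Mapping[str, str]] = None
) -> list[str]:
    """Coarse tags from a lookup table plus suffix rules; default tag NOUN.

    Pure punctuation tokens and the ``@user`` placeholder tag as OTHER.
    """
    if tag_lexicon is None:
        tag_lexicon = default_tag_lexicon()
    tags = []
    for tok in tokens:
        if tok == "@user" or _is_punct(tok):
            tags.append("OTHER")
            continue
        tag = tag_lexicon.get(tok)
        if tag is None:
            for suffix, rule_tag in _SUFFIX_RULES:
                if len(tok) > len(suffix) + 2 and tok.endswith(suffix):
                    tag = rule_tag
                    break
        tags.append(tag or "NOUN")
    return tags


@lru_cache(maxsize=1)
def default_lemma_lexicon() -> Mapping[tuple[str, str], str]:
    data = resources.files("gadprofiler.data").joinpath("lemma_lexicon.tsv")
    out = {}
    for line in data.read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        token, tag, lemma = line.split("\t")
        out[(token, tag)] = lemma
    return out


def lemmatize(
    tokens: Sequence[str],
    tags: Sequence[str],
    lemma_lexicon: Optional[Mapping[tuple[str, str], str]] = None,
) -> list[str]:
    """Map each token via (token, tag), falling back to (token, NOUN), then identity."""
    if len(tokens) != len(tags):
        raise ValueError(f"{len(tokens)} tokens but {len(tags)} tags")
    if lemma_lexicon is None:
        lemma_lexicon = default_lemma_lexicon()
    return [
        lemma_lexicon.get((tok, tag), lemma_lexicon.get((tok, "NOUN"), tok))
        for tok, tag in zip(tokens, tags)
    ]


@dataclasses.dataclass
class TokenizedTweet:
    tweet_id: str
    raw_tokens: list[str]      # post-cleaning, pre-stopword; feeds lexicon scoring
    topic_tokens: list[str]    # stopword-free lemmas; feeds the topic model
    pos_tags: list[str]        # one coarse tag per raw token

    def __post_init__(self) -> None:
        if len(self.pos_tags) != len(self.raw_tokens):
            raise ValueError("pos_tags must align with raw_tokens")


def preprocess_for_topics(
    tweet: TweetRecord | str,
    stoplist: Optional[frozenset[str]] = None,
    tag_lexicon: Optional[Mapping[str, str]] = None,
    lemma_lexicon: Optional[Mapping[tuple[str, str], str]] = None,
) -> TokenizedTweet:
    """Run the full chain: clean → tokenize → stopword/punct → POS → lemmatize.

    The ``@user`` placeholder is excluded from the topic stream (an anonymized
    mention carries no content); raw_tokens keep it so behavioral and lexicon
    bookkeeping stay faithful to the cleaned text.
    """
    if isinstance(tweet, TweetRecord):
        tweet_id, text = tweet.tweet_id, tweet.text
    else:
        tweet_id, text = "", tweet
    raw = tokenize(clean_text(text))
    tags = pos_tag(raw, tag_lexicon)
    if stoplist is None:
        stoplist = default_stopwords()
    kept_idx = [
        i for i, tok in enumerate(raw)
        if tok != "@user" and tok not in stoplist and not _is_punct(tok)
    ]
    lemmas = lemmatize(
        [raw[i] for i in kept_idx], [tags[i] for i in kept_idx], lemma_lexicon
    )
    return TokenizedTweet(tweet_id, raw, lemmas, tags)


def preprocess_cohort(
    cohort: Cohort, **kwargs
) -> dict[str, list[TokenizedTweet]]:
    """Tokenize every tweet; returns user_id → tokenized tweets in tweet order."""
    return {
        uc.user.user_id: [preprocess_for_topics(t, **kwargs) for t in uc.tweets]
        for uc in cohort.users
    }
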