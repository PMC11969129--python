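"""Closed-dictionary category scoring over word lists (open .dic dialect).

The dictionary file format is the classic word-count tool dialect: a
category-id map between two ``%`` lines, then entry lines
``pattern<TAB>id[<TAB>id...]``.  A pattern is a literal word or a prefix stem
ending in ``*``.  Scoring reports, per user, the percentage of words falling
in each category.  The shipped ``open_fixture.dic`` is an open, compact
dictionary for tests and demos — it is NOT the proprietary LIWC dictionary,
and scores on real prose are not claimed comparable to LIWC output.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .corpus import Cohort
from .preprocess import clean_text, tokenize, _is_punct


@dataclasses.dataclass
class Lexicon:
    categories: list[str]
    entries: list[tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        if len(self.categories) != len(set(self.categories)):
            raise ValueError("duplicate category names")
        known = set(self.categories)
        for pattern, cats in self.entries:
            if pattern != pattern.lower():
                raise ValueError(f"pattern {pattern!r} is not lower-case")
            missing = cats - known
            if missing:
                raise ValueError(f"entry {pattern!r} references unknown {missing}")
        self._literals: dict[str, frozenset[str]] = {}
        # Prefix patterns live in a character trie; the trie is purely an
        # optimization and must be indistinguishable from brute force.
        self._trie: dict = {}
        for pattern, cats in self.entries:
            if pattern.endswith("*"):
                node = self._trie
                for ch in pattern[:-1]:
                    node = node.setdefault(ch, {})
                node["$"] = node.get("$", frozenset()) | cats
            else:
                self._literals[pattern] = self._literals.get(
                    pattern, frozenset()) | cats

    def match_token(self, token: str) -> frozenset[str]:
        """Union of categories over all matching entries.

        Literal entries match the whole token; ``abc*`` matches any token with
        prefix ``abc``.  All matches count — no longest-match shadowing.
        """
        cats = self._literals.get(token, frozenset())
        node = self._trie
        for ch in token:
            if "$" in node:
                cats = cats | node["$"]
            node = node.get(ch)
            if node is None:
                return cats
        if "$" in node:
            cats = cats | node["$"]
        return cats


def match_token(token: str, lexicon: Lexicon) -> frozenset[str]:
    return lexicon.match_token(token)


def load_lexicon(path: str | Path) -> Lexicon:
    """Parse a .dic-dialect dictionary file with line-level error reporting."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    marks = [i for i, l in enumerate(lines) if l.strip() == "%"]
    if len(marks) < 2:
        raise ValueError(f"{path}: missing '%' category delimiters")
    id_to_name: dict[str, str] = {}
    for i in range(marks[0] + 1, marks[1]):
        line = lines[i].strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{i + 1}: bad category line {line!r}")
        cid, name = parts
        if cid in id_to_name:
            raise ValueError(f"{path}:{i + 1}: duplicate category id {cid}")
        id_to_name[cid] = name
    merged: dict[str, set[str]] = {}
    for i in range(marks[1] + 1, len(lines)):
        line = lines[i].strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{i + 1}: bad entry line {line!r}")
        pattern, ids = parts[0].lower(), parts[1:]
        for cid in ids:
            if cid not in id_to_name:
                raise ValueError(
                    f"{path}:{i + 1}: entry {pattern!r} references "
                    f"undefined category id {cid}"
                )
        merged.setdefault(pattern, set()).update(id_to_name[c] for c in ids)
    entries = [(p, frozenset(cats)) for p, cats in sorted(merged.items())]
    return Lexicon(categories=list(id_to_name.values()), entries=entries)


def open_fixture_lexicon() -> Lexicon:
    """The shipped open dictionary (23 categories; not LIWC)."""
    with resources.as_file(
        resources.files("gadprofiler.data").joinpath("open_fixture.dic")
    ) as p:
        return load_lexicon(p)


@dataclasses.dataclass
class CategoryProfile:
    user_id: str
    total_words: int
    percent: dict[str, float]


def _countable(token: str, lexicon: Lexicon) -> bool:
    # Word-count denominator: exclude the @user placeholder and pure
    # punctuation, except punctuation that matches an entry (emoticons).
    if token == "@user":
        return False
    if any(ch.isalnum() for ch in token):
        return True
    return bool(lexicon.match_token(token))


def score_user(
    user_tokens: Sequence[str], lexicon: Lexicon, user_id: str = ""
) -> CategoryProfile:
    """Percent-of-words per category over a user's raw token stream.

    A token belonging to k categories contributes once to each of the k.
    Raises on an empty word count (caller should flag and exclude the user).
    """
    counts = {c: 0 for c in lexicon.categories}
    total = 0
    for tok in user_tokens:
        if not _countable(tok, lexicon):
            continue
        total += 1
        for c in lexicon.match_token(tok):
            counts[c] += 1
    if total == 0:
        raise ValueError(f"user {user_id!r} has zero countable words")
    percent = {c: 100.0 * n / total for c, n in counts.items()}
    return CategoryProfile(user_id=user_id, total_words=total, percent=percent)


def score_cohort(
    cohort: Cohort, lexicon: Lexicon
) -> tuple[list[CategoryProfile], list[str]]:
    """One profile per user over the concatenated (cleaned) tweet history.

    Returns (profiles, flagged) where ``flagged`` lists users with zero
    countable words; those are excluded from group statistics.
    """
    profiles, flagged = [], []
    for uc in cohort.users:
        tokens: list[str] = []
        for t in uc.tweets:
            tokens.extend(tokenize(clean_text(t.text)))
        try:
            profiles.append(score_user(tokens, lexicon, uc.user.user_id))
        except ValueError:
            flagged.append(uc.user.user_id)
    return profiles, flagged


@dataclasses.dataclass
class MeasurementSchema:
    name: str
    categories: list[str]


#: The three composite linguistic measurements, in report order.
DEFAULT_SCHEMAS: list[MeasurementSchema] = [
    MeasurementSchema("cognitive_style", [
        "insight", "causation", "discrepancy", "tentativeness",
        "certitude", "differentiation", "memory",
    ]),
    MeasurementSchema("personal_needs", [
        "need", "want", "lack", "reward", "risk", "curiosity",
        "substances", "food", "death", "interpersonal_conflict",
        "communication",
    ]),
    MeasurementSchema("emotional_expressiveness", [
        "negative_tone", "anxiety", "anger", "sadness", "swear_words",
    ]),
]


def profiles_frame(profiles: Iterable[CategoryProfile]) -> pd.DataFrame:
    """Users × categories percentage matrix."""
    rows = {p.user_id: p.percent for p in profiles}
    return pd.DataFrame.from_dict(rows, orient="index")


def compose_measurements(
    profiles: Iterable[CategoryProfile] | pd.DataFrame,
    schemas: Optional[Sequence[MeasurementSchema]] = None,
) -> pd.DataFrame:
    """Reshape category percentages into the named measurement blocks.

    No aggregation across categories happens — each category stays its own
    row under its measurement heading.  Columns: users.  Index: MultiIndex
    (measurement, category) in schema order.
    """
    if schemas is None:
        schemas = DEFAULT_SCHEMAS
    frame = (
        profiles if isinstance(profiles, pd.DataFrame)
        else profiles_frame(profiles)
    )
    index, rows = [], []
    for schema in schemas:
        for cat in schema.categories:
            if cat not in frame.columns:
                raise KeyError(
                    f"schema {schema.name!r} expects category {cat!r}, "
                    "absent from profiles"
                )
            index.append((schema.name, cat))
            rows.append(frame[cat])
    out = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["measurement", "category"])
    )
    return out


def write_profiles_tsv(profiles: Iterable[CategoryProfile], path: str | Path) -> None:
    profiles_frame(profiles).to_csv(path, sep="\t", index_label="user_id")
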