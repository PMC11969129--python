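"""Group descriptives, one-tailed two-sample t tests, pooled-SD Cohen's d,
marker-table assembly, and theme × behavior correlation matrices.

Effect sizes use the pooled-SD (Student) form of Cohen's d and are reported
unsigned; magnitudes are graded small (< 0.20), medium (0.20–0.50) and large
(≥ 0.50).  One-tailed directions are a required configuration artifact —
they are never inferred from the data, which would invalidate the p values.
No multiple-testing adjustment is applied by default; Benjamini–Hochberg
q-values are available as an optional extra column.
"""

from __future__ import annotations

import dataclasses
import math
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps


@dataclasses.dataclass
class GroupSummary:
    feature: str
    group: str
    n: int
    mean: float
    sd: float
    median: float
    iqr_low: float
    iqr_high: float


def descriptives(values, feature: str = "", group: str = "") -> GroupSummary:
    """Mean, sample SD (n−1), median and IQR (linear-interpolation quartiles).

    Missing values are dropped first; an empty sample is an error.
    """
    vals = np.asarray(pd.Series(values).dropna(), dtype=float)
    if vals.size == 0:
        raise ValueError(f"no observations for {feature!r}/{group!r}")
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    sd = float(vals.std(ddof=1)) if vals.size >= 2 else math.nan
    return GroupSummary(feature, group, int(vals.size), float(vals.mean()),
                        sd, float(med), float(q1), float(q3))


def cohens_d(mean1: float, sd1: float, n1: int,
             mean2: float, sd2: float, n2: int) -> float:
    """Unsigned pooled-SD (Student) Cohen's d.

    ``d = |m1 − m2| / s_p`` with
    ``s_p = sqrt(((n1−1) sd1² + (n2−1) sd2²) / (n1 + n2 − 2))``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("both group SDs are zero; d is undefined")
    pooled = math.sqrt(((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2)
                       / (n1 + n2 - 2))
    return abs(mean1 - mean2) / pooled


def d_magnitude(d: float) -> str:
    """Effect-size grade: small < 0.20 ≤ medium < 0.50 ≤ large."""
    if d < 0.20:
        return "small"
    if d < 0.50:
        return "medium"
    return "large"


def two_sample_t(
    sample1, sample2, alternative: str, variant: str = "pooled"
) -> tuple[float, float]:
    """Two-sample t statistic and one-tailed p for a declared direction.

    ``alternative`` is "greater" (mean1 > mean2), "less" or "two-sided" and
    must be declared a priori per feature.  ``variant`` selects the pooled
    (Student) or "welch" unequal-variance statistic.
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"invalid alternative {alternative!r}")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"invalid variant {variant!r}")
    a = np.asarray(pd.Series(sample1).dropna(), dtype=float)
    b = np.asarray(pd.Series(sample2).dropna(), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per group")
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"),
                        alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def load_default_directions() -> dict[str, dict[str, str]]:
    """Shipped a-priori directions, block → feature → greater/less."""
    raw = yaml.safe_load(
        resources.files("gadprofiler.data")
        .joinpath("directions.yaml").read_text(encoding="utf-8")
    )
    return raw


@dataclasses.dataclass
class MarkerRow:
    feature: str
    block: str
    n1: int
    mean1: float
    sd1: float
    n2: int
    mean2: float
    sd2: float
    t: float
    p_value: float
    cohen_d: float
    significant: bool
    d_magnitude: str
    q_value: Optional[float] = None


BLOCK_ORDER = ("linguistic", "theme", "volume", "behavior")


def compare_groups(
    blocks: Mapping[str, tuple[pd.DataFrame, pd.DataFrame]],
    directions: Mapping[str, Mapping[str, str]],
    alpha: float = 0.05,
    variant: str = "pooled",
    benjamini_hochberg: bool = False,
) -> pd.DataFrame:
    """One marker row per feature across the named blocks.

    ``blocks`` maps block name → (group1 frame, group2 frame), users × features
    (group1 = diagnosed).  Every tested feature must have a declared direction;
    a missing declaration is an error, by design.  Rows keep block order
    (linguistic, theme, volume, behavior) then input column order.
    """
    rows: list[MarkerRow] = []
    ordered = [b for b in BLOCK_ORDER if b in blocks]
    ordered += [b for b in blocks if b not in BLOCK_ORDER]
    for block in ordered:
        f1, f2 = blocks[block]
        block_dirs = directions.get(block, {})
        for feature in f1.columns:
            if feature not in f2.columns:
                raise KeyError(f"feature {feature!r} missing from second group")
            if feature not in block_dirs:
                raise ValueError(
                    f"no a-priori direction declared for {block}/{feature}"
                )
            s1 = f1[feature].dropna()
            s2 = f2[feature].dropna()
            t, p = two_sample_t(s1, s2, block_dirs[feature], variant)
            d = cohens_d(s1.mean(), s1.std(ddof=1), len(s1),
                         s2.mean(), s2.std(ddof=1), len(s2))
            rows.append(MarkerRow(
                feature=feature, block=block,
                n1=len(s1), mean1=float(s1.mean()), sd1=float(s1.std(ddof=1)),
                n2=len(s2), mean2=float(s2.mean()), sd2=float(s2.std(ddof=1)),
                t=t, p_value=p, cohen_d=d,
                significant=bool(p <= alpha), d_magnitude=d_magnitude(d),
            ))
    frame = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    if benjamini_hochberg:
        frame["q_value"] = _bh_adjust(frame["p_value"].to_numpy())
    else:
        frame = frame.drop(columns=["q_value"])
    return frame


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def format_p(p: float) -> str:
    """Report-style p: "<.001" below 0.001, otherwise 2–3 decimals."""
    if p < 0.001:
        return "<.001"
    return f"{p:.3f}".lstrip("0") if p < 0.995 else f"{p:.2f}"


def format_marker_table(markers: pd.DataFrame) -> pd.DataFrame:
    """Human-readable marker table: feature, mean (SD) per group, P, d."""
    return pd.DataFrame({
        "block": markers["block"],
        "feature": markers["feature"],
        "group1_mean_sd": [
            f"{m:.2f} ({s:.2f})" for m, s in zip(markers["mean1"], markers["sd1"])],
        "group2_mean_sd": [
            f"{m:.2f} ({s:.2f})" for m, s in zip(markers["mean2"], markers["sd2"])],
        "P": [format_p(p) for p in markers["p_value"]],
        "cohen_d": [f"{d:.2f}" for d in markers["cohen_d"]],
    })


THEME_ROWS = ("symptoms", "life_problems", "relationships", "feelings", "overall")


def theme_behavior_correlation(
    theme_profiles: pd.DataFrame,
    behavior_matrix: pd.DataFrame,
    method: str = "spearman",
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Theme × behavior correlation matrix within one group.

    Rows: the four themes plus "overall" (per-user sum of the four theme
    percentages).  Cells: rank correlation (Spearman ρ by default; Pearson by
    flag) over pairwise-complete users; cells with fewer than ``min_pairs``
    complete pairs are NaN.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"invalid correlation method {method!r}")
    users = theme_profiles.index.intersection(behavior_matrix.index)
    themes = theme_profiles.loc[users]
    behav = behavior_matrix.loc[users]
    theme_cols = [c for c in THEME_ROWS[:-1] if c in themes.columns]
    data = {c: themes[c] for c in theme_cols}
    data["overall"] = themes[theme_cols].sum(axis=1)
    out = pd.DataFrame(index=list(data), columns=behav.columns, dtype=float)
    for rname, rvals in data.items():
        for col in behav.columns:
            pair = pd.concat([rvals, behav[col]], axis=1).dropna()
            if len(pair) < min_pairs:
                out.loc[rname, col] = np.nan
                continue
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if x.nunique() < 2 or y.nunique() < 2:
                out.loc[rname, col] = np.nan
                continue
            if method == "spearman":
                rho = sps.spearmanr(x, y).statistic
            else:
                rho = sps.pearsonr(x, y).statistic
            out.loc[rname, col] = float(rho)
    return out


# ---------------------------------------------------------------------------
# Worked-example reference statistics
# ---------------------------------------------------------------------------

#: Published group summary statistics from a large GAD-vs-control cohort
#: (n1 = 1316 diagnosed, n2 = 1463 control), used as worked-example inputs:
#: feature → (mean1, sd1, mean2, sd2, printed_d).  The printed effect sizes
#: reproduce from the printed means/SDs under the pooled-SD estimator.
WORKED_EXAMPLE_N = (1316, 1463)
WORKED_EXAMPLE_MARKERS: dict[str, tuple[float, float, float, float, float]] = {
    "causation": (1.028, 0.39, 0.60, 0.44, 1.03),
    "certitude": (0.57, 0.29, 0.30, 0.31, 0.90),
    "need": (0.35, 0.18, 0.20, 0.18, 0.83),
    "communication": (3.50, 1.64, 4.80, 2.35, 0.64),
    "sadness": (0.22, 0.22, 0.13, 0.15, 0.48),
    "memory": (0.10, 0.07, 0.07, 0.09, 0.37),
    "reply_to_tweet_ratio": (0.41, 0.24, 0.29, 0.27, 0.47),
    "retweet_to_tweet_ratio": (0.29, 0.24, 0.49, 0.33, 0.69),
    "mention_ratio": (0.32, 0.23, 0.51, 0.32, 0.68),
}

#: Published corpus bookkeeping pairs (numerator, denominator) behind three
#: reported percentages: diagnosed-group share of retained tweets, diagnosed
#: hashtag-tweet proportion, control mention-tweet proportion.
WORKED_EXAMPLE_COUNTS = {
    "gad_tweet_share": (3_367_581, 7_313_769),
    "gad_hashtag_tweet_share": (289_611, 3_367_581),
    "control_mention_tweet_share": (2_012_555, 3_946_188),
}


def worked_example_d(feature: str) -> float:
    """Recompute a worked-example effect size from its published summary."""
    m1, s1, m2, s2, _ = WORKED_EXAMPLE_MARKERS[feature]
    n1, n2 = WORKED_EXAMPLE_N
    return cohens_d(m1, s1, n1, m2, s2, n2)
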