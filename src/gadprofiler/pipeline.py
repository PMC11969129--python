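"""End-to-end pipeline: cohorts → preprocessing → lexicon scoring → seeded
topic model → behavior matrix → marker table → theme×behavior correlations.

``run_pipeline`` composes the stage modules with no hidden state — running
the stages individually on the intermediate artifacts gives identical
results.  Every applied default and every exclusion is logged, and a
machine-readable run-metadata JSON (config hash, seed, versions, timings)
accompanies the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .behavior import ACCOUNT_COLUMNS, cohort_behavior_matrix, cohort_descriptives
from .corpus import Cohort, Group, apply_cohort_filters, read_corpus, \
    remove_group_overlap
from .lexicon import Lexicon, open_fixture_lexicon, load_lexicon, \
    profiles_frame, score_cohort
from .preprocess import preprocess_cohort
from .stats import compare_groups, format_marker_table, \
    load_default_directions, theme_behavior_correlation
from .topics import LdaConfig, ThemeAssignmentConfig, assign_tweet_themes, \
    fit_model, load_seed_specs, save_model, theme_profile, theme_profiles_frame

#: Feature split between the volume and behavior marker blocks.
VOLUME_FEATURES = [
    "follower_count", "friend_count", "listed_count", "favorite_count",
    "status_count", "retweets_received_total", "n_tweets", "n_replies",
    "n_hashtag_tweets", "n_retweets", "n_mentions_total",
    "n_mentions_excl_replies", "n_tweets_with_retweets",
    "n_tweets_with_favorites",
]
BEHAVIOR_FEATURES = [
    "ff_ratio", "reply_to_tweet_ratio", "hashtag_ratio",
    "retweet_to_tweet_ratio", "mention_ratio", "mentions_per_tweet",
    "tweets_with_retweets_ratio", "tweets_with_favorites_ratio",
    "tweets_per_day", "replies_per_day", "retweets_per_day",
    "mentions_per_day", "hashtag_tweets_per_day",
]


@dataclasses.dataclass
class PipelineConfig:
    lda: LdaConfig = dataclasses.field(default_factory=LdaConfig)
    assignment: ThemeAssignmentConfig = dataclasses.field(
        default_factory=ThemeAssignmentConfig)
    lexicon_path: Optional[str] = None      # None -> shipped open fixture
    seeds_path: Optional[str] = None        # None -> shipped defaults
    directions: Optional[dict] = None       # None -> shipped defaults
    apply_filters: bool = True
    min_tweets: int = 100
    min_english_fraction: float = 0.8
    correlation_method: str = "spearman"
    t_variant: str = "pooled"
    benjamini_hochberg: bool = False
    alpha: float = 0.05


@dataclasses.dataclass
class PipelineResult:
    markers: pd.DataFrame
    markers_display: pd.DataFrame
    correlations: dict[str, pd.DataFrame]
    category_profiles: dict[str, pd.DataFrame]
    theme_profiles: dict[str, pd.DataFrame]
    behavior: dict[str, pd.DataFrame]
    model: object
    descriptives: dict[str, dict]
    log: list[str]
    metadata: dict


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    gad: Cohort,
    control: Cohort,
    config: Optional[PipelineConfig] = None,
    outdir: Optional[str | Path] = None,
) -> PipelineResult:
    """Execute the full analysis on two labeled cohorts.

    Writes the report bundle (marker tables, correlation matrices and
    heatmaps, per-user profile tables, topic-model dump, log, metadata)
    under ``outdir`` when given.
    """
    cfg = config or PipelineConfig()
    log: list[str] = []
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    def tick(stage: str) -> None:
        timings[stage] = round(time.perf_counter() - t0, 3)
        log.append(f"[{stage}] done at +{timings[stage]}s")

    lex = (load_lexicon(cfg.lexicon_path) if cfg.lexicon_path
           else open_fixture_lexicon())
    log.append(f"lexicon: {len(lex.categories)} categories, "
               f"{len(lex.entries)} entries"
               + ("" if cfg.lexicon_path else " (shipped open fixture)"))
    specs = load_seed_specs(cfg.seeds_path)
    directions = cfg.directions or load_default_directions()
    if cfg.directions is None:
        log.append("directions: shipped a-priori defaults")

    gad, control = remove_group_overlap(gad, control)
    if cfg.apply_filters:
        gad = apply_cohort_filters(gad, cfg.min_tweets, cfg.min_english_fraction)
        control = apply_cohort_filters(control, cfg.min_tweets,
                                       cfg.min_english_fraction)
        for c in (gad, control):
            for ev in c.provenance:
                log.append(f"excluded {ev.user_id}: {ev.rule} ({ev.detail})")
    if not gad.users or not control.users:
        raise ValueError("a cohort is empty after filtering")
    tick("cohorts")

    tokenized = {"GAD": preprocess_cohort(gad), "CONTROL": preprocess_cohort(control)}
    tick("preprocess")

    category_profiles = {}
    for name, cohort in (("GAD", gad), ("CONTROL", control)):
        profiles, flagged = score_cohort(cohort, lex)
        for uid in flagged:
            log.append(f"flagged {uid}: zero countable words, "
                       "excluded from group statistics")
        category_profiles[name] = profiles_frame(profiles)
    tick("lexicon")

    docs, doc_meta = [], []
    for gname, cohort in (("GAD", gad), ("CONTROL", control)):
        for uc in cohort.users:
            for tt in tokenized[gname][uc.user.user_id]:
                docs.append(tt.topic_tokens)
                doc_meta.append((gname, uc.user.user_id, tt.tweet_id))
    model = fit_model(docs, specs, cfg.lda)
    themes_per_doc = assign_tweet_themes(model, cfg.assignment)
    theme_names = [s.name for s in specs]
    by_user: dict[tuple[str, str], list] = {}
    for (gname, uid, _tid), tset in zip(doc_meta, themes_per_doc):
        by_user.setdefault((gname, uid), []).append(tset)
    theme_profiles = {}
    for gname in ("GAD", "CONTROL"):
        plist = [theme_profile(uid, tsets, theme_names)
                 for (g, uid), tsets in by_user.items() if g == gname]
        theme_profiles[gname] = theme_profiles_frame(plist)
    tick("topics")

    behavior = {"GAD": cohort_behavior_matrix(gad),
                "CONTROL": cohort_behavior_matrix(control)}
    desc = {g: cohort_descriptives(behavior[g]) for g in behavior}
    tick("behavior")

    blocks = {
        "linguistic": (category_profiles["GAD"], category_profiles["CONTROL"]),
        "theme": (theme_profiles["GAD"], theme_profiles["CONTROL"]),
        "volume": (behavior["GAD"][VOLUME_FEATURES],
                   behavior["CONTROL"][VOLUME_FEATURES]),
        "behavior": (behavior["GAD"][BEHAVIOR_FEATURES],
                     behavior["CONTROL"][BEHAVIOR_FEATURES]),
    }
    markers = compare_groups(blocks, directions, alpha=cfg.alpha,
                             variant=cfg.t_variant,
                             benjamini_hochberg=cfg.benjamini_hochberg)
    tick("markers")

    correlations = {}
    for gname in ("GAD", "CONTROL"):
        correlations[gname] = theme_behavior_correlation(
            theme_profiles[gname], behavior[gname][BEHAVIOR_FEATURES],
            method=cfg.correlation_method)
    tick("correlations")

    metadata = {
        "gadprofiler_version": __version__,
        "config_hash": _config_hash(cfg),
        "rng_seed": cfg.lda.rng_seed,
        "n_users": {"GAD": len(gad), "CONTROL": len(control)},
        "n_tweets": {"GAD": gad.n_tweets(), "CONTROL": control.n_tweets()},
        "assignment": dataclasses.asdict(cfg.assignment),
        "correlation_method": cfg.correlation_method,
        "timings_s": timings,
    }
    result = PipelineResult(
        markers=markers,
        markers_display=format_marker_table(markers),
        correlations=correlations,
        category_profiles=category_profiles,
        theme_profiles=theme_profiles,
        behavior=behavior,
        model=model,
        descriptives=desc,
        log=log,
        metadata=metadata,
    )
    if outdir is not None:
        write_bundle(result, outdir)
    return result


def write_bundle(result: PipelineResult, outdir: str | Path) -> None:
    """Persist the report bundle as TSV/JSON plus correlation heatmaps."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.markers.to_csv(outdir / "markers.tsv", sep="\t", index=False)
    result.markers_display.to_csv(
        outdir / "markers_display.tsv", sep="\t", index=False)
    for g, frame in result.correlations.items():
        frame.to_csv(outdir / f"correlations_{g.lower()}.tsv", sep="\t")
        _heatmap(frame, outdir / f"correlations_{g.lower()}.png",
                 f"Theme × behavior correlation ({g})")
    for g in result.category_profiles:
        result.category_profiles[g].to_csv(
            outdir / f"category_profiles_{g.lower()}.tsv", sep="\t",
            index_label="user_id")
        result.theme_profiles[g].to_csv(
            outdir / f"theme_profiles_{g.lower()}.tsv", sep="\t",
            index_label="user_id")
        result.behavior[g].to_csv(
            outdir / f"behavior_{g.lower()}.tsv", sep="\t",
            index_label="user_id")
    save_model(result.model, outdir / "model")
    (outdir / "descriptives.json").write_text(
        json.dumps(result.descriptives, indent=2), encoding="utf-8")
    (outdir / "run_metadata.json").write_text(
        json.dumps(result.metadata, indent=2), encoding="utf-8")
    (outdir / "run_log.txt").write_text(
        "\n".join(result.log) + "\n", encoding="utf-8")


def _heatmap(frame: pd.DataFrame, path: Path, title: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(6.0, 0.45 * frame.shape[1]), 0.6 * frame.shape[0] + 1.5))
    im = ax.imshow(frame.to_numpy(dtype=float), vmin=-1, vmax=1, cmap="RdBu_r",
                   aspect="auto")
    ax.set_xticks(range(frame.shape[1]), frame.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(frame.shape[0]), frame.index, fontsize=8)
    ax.set_title(title, fontsize=10)
    fig.colorbar(im, ax=ax, label="ρ")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_from_paths(
    gad_dir: str | Path,
    control_dir: str | Path,
    config: Optional[PipelineConfig] = None,
    outdir: Optional[str | Path] = None,
) -> PipelineResult:
    """File-based entry point: read both corpora, then ``run_pipeline``."""
    cfg = config or PipelineConfig()
    if cfg.lexicon_path and not Path(cfg.lexicon_path).exists():
        raise FileNotFoundError(f"lexicon file not found: {cfg.lexicon_path}")
    if cfg.seeds_path and not Path(cfg.seeds_path).exists():
        raise FileNotFoundError(f"seed spec not found: {cfg.seeds_path}")
    gad = read_corpus(gad_dir, Group.GAD)
    control = read_corpus(control_dir, Group.CONTROL)
    return run_pipeline(gad, control, cfg, outdir)
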