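"""Per-score random forests, voting aggregation and contig ranking.

One binary random-forest classifier is trained per single score, mapping the
contig feature vector to that score's good/bad class. At prediction time each
forest votes: S_i is the majority class over trees and P_i the fraction of
trees voting for it. The final contig score is

    sum_i S_i * P_i

so only scores predicted good contribute, weighted by the forest's
confidence; it lives in [0, |S|] and larger means better. Contigs are ranked
by this score (descending), ties broken by contig length (longer first).

Scores whose training classes are single-valued carry no learnable signal
(typical for near-perfect training assemblies) and are excluded with a
warning rather than fitted to noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .feature_extraction import FEATURE_SCHEMA
from .reference_scoring import SCORE_NAMES, ThresholdSet

logger = logging.getLogger(__name__)

BUNDLE_FORMAT_VERSION = 1

DEFAULT_N_TREES = 500


@dataclass
class Hyperparams:
    """Forest hyperparameters; the defaults are the contract.

    500 trees, sqrt(p) candidate features per split, unlimited depth — the
    usual random-forest settings that adapt across scenarios without tuning.
    """

    n_trees: int = DEFAULT_N_TREES
    max_features: str | int | float = "sqrt"
    max_depth: int | None = None


@dataclass
class ModelBundle:
    """Trained per-score forests plus everything needed to apply them."""

    feature_schema: list[str]
    score_names: list[str]                       # scores with a trained forest
    models: dict[str, RandomForestClassifier]
    thresholds: ThresholdSet
    excluded_scores: dict[str, str]              # score -> reason
    training_meta: dict
    format_version: int = BUNDLE_FORMAT_VERSION


def train_models(
    features: pd.DataFrame,
    classes: pd.DataFrame,
    hyperparams: Hyperparams | None = None,
    seed: int = 0,
    thresholds: ThresholdSet | None = None,
) -> ModelBundle:
    """Train one forest per learnable score.

    ``features`` and ``classes`` must cover the same contig ids; rows are
    joined on contig_id. Deterministic given ``seed``.
    """
    hp = hyperparams or Hyperparams()
    feat_ids = list(features["contig_id"])
    class_ids = list(classes["contig_id"])
    if sorted(feat_ids) != sorted(class_ids):
        raise ValueError("feature table and class table cover different contig ids")
    if len(features) < 20:
        raise ValueError(f"training needs >= 20 contigs, got {len(features)}")

    classes = classes.set_index("contig_id").loc[feat_ids].reset_index()
    X = features[FEATURE_SCHEMA].to_numpy(dtype=float)

    models: dict[str, RandomForestClassifier] = {}
    excluded: dict[str, str] = {}
    balance: dict[str, float] = {}
    oob: dict[str, float] = {}
    if thresholds is not None:
        for name in thresholds.degenerate_scores():
            excluded[name] = "degenerate score (0 for every training contig)"

    rng = np.random.RandomState(seed)
    for name in SCORE_NAMES:
        if name not in classes.columns:
            raise ValueError(f"class column {name!r} missing")
        if name in excluded:
            logger.warning("score %s excluded: %s", name, excluded[name])
            continue
        y = classes[name].to_numpy(dtype=int)
        if len(np.unique(y)) < 2:
            excluded[name] = f"single-valued training classes (all {int(y[0])})"
            logger.warning("score %s excluded: %s", name, excluded[name])
            continue
        forest = RandomForestClassifier(
            n_estimators=hp.n_trees,
            max_features=hp.max_features,
            max_depth=hp.max_depth,
            oob_score=True,
            random_state=rng.randint(2**31 - 1),
        )
        forest.fit(X, y)
        models[name] = forest
        balance[name] = float(y.mean())
        oob[name] = float(forest.oob_score_)

    if not models:
        raise ValueError(
            "training data has no quality variance: every score class is single-valued"
        )

    return ModelBundle(
        feature_schema=list(FEATURE_SCHEMA),
        score_names=list(models),
        models=models,
        thresholds=thresholds or ThresholdSet(),
        excluded_scores=excluded,
        training_meta={
            "n_contigs": len(features),
            "class_balance": balance,
            "oob_accuracy": oob,
            "hyperparams": {"n_trees": hp.n_trees, "max_features": hp.max_features,
                            "max_depth": hp.max_depth},
            "seed": seed,
        },
    )


def _vote_fractions(forest: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Per-sample fraction of trees voting class 1 (hard majority votes)."""
    votes = np.zeros(len(X))
    for est in forest.estimators_:
        # individual trees predict class indices into forest.classes_
        idx = est.predict(X).astype(int)
        votes += forest.classes_.take(idx) == 1
    return votes / len(forest.estimators_)


def predict_scores(bundle: ModelBundle, features: pd.DataFrame) -> pd.DataFrame:
    """Predict (S_i, P_i) per contig and score.

    S_i is the majority class over the forest's trees, P_i the vote fraction
    for that class. A 50/50 tie resolves to the bad class with P = 0.5, so
    P_i >= 0.5 always.
    """
    cols = [c for c in features.columns if c != "contig_id"]
    if list(cols) != list(bundle.feature_schema):
        missing = [c for c in bundle.feature_schema if c not in cols]
        extra = [c for c in cols if c not in bundle.feature_schema]
        raise ValueError(
            f"feature table does not match the bundle's schema "
            f"(missing: {missing}, extra: {extra}, order must match)"
        )
    X = features[bundle.feature_schema].to_numpy(dtype=float)
    out = {"contig_id": features["contig_id"].to_numpy()}
    for name in bundle.score_names:
        p1 = _vote_fractions(bundle.models[name], X)
        s = (p1 > 0.5).astype(int)
        out[f"S_{name}"] = s
        out[f"P_{name}"] = np.where(s == 1, p1, 1.0 - p1)
    return pd.DataFrame(out)


def surankco_score(predictions: pd.DataFrame, score_names: list[str]) -> np.ndarray:
    """Final contig score: sum over scores of S_i * P_i (0-class terms vanish)."""
    if not score_names:
        raise ValueError("need at least one score")
    total = np.zeros(len(predictions))
    for name in score_names:
        total += predictions[f"S_{name}"].to_numpy(dtype=float) * \
                 predictions[f"P_{name}"].to_numpy(dtype=float)
    return total


def rank_contigs(
    entries: pd.DataFrame,
    lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Sort descending by surankco_score and assign ranks 1..n (1 = best).

    Ties broken by descending contig length when lengths are given, else by
    ascending contig id; ties still receive distinct ranks under that order.
    """
    ids = list(entries["contig_id"])
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate contig ids in ranking input: {dupes}")
    df = entries.copy()
    if lengths is not None:
        df["_tiebreak"] = [-lengths.get(i, 0) for i in df["contig_id"]]
    else:
        df["_tiebreak"] = df["contig_id"]
    df = df.sort_values(
        ["surankco_score", "_tiebreak", "contig_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).drop(columns="_tiebreak")
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df.reset_index(drop=True)


def rank_table(
    bundle: ModelBundle,
    features: pd.DataFrame,
    lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Predict, aggregate and rank in one step; columns: rank, contig_id,
    surankco_score, then each S_i and P_i."""
    preds = predict_scores(bundle, features)
    preds.insert(1, "surankco_score", surankco_score(preds, bundle.score_names))
    if lengths is None:
        lengths = dict(zip(features["contig_id"], features["length_padded"].astype(int)))
    return rank_contigs(preds, lengths)


def save_bundle(bundle: ModelBundle, path) -> None:
    joblib.dump({"format_version": BUNDLE_FORMAT_VERSION, "bundle": bundle}, path)


def load_bundle(path) -> ModelBundle:
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ValueError(f"cannot load model bundle from {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path} is not a contigrank model bundle")
    if payload["format_version"] != BUNDLE_FORMAT_VERSION:
        raise ValueError(
            f"bundle format version {payload['format_version']} unsupported "
            f"(expected {BUNDLE_FORMAT_VERSION})"
        )
    return payload["bundle"]
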