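"""Convenience driver: run the full train/predict workflow on fixture directories.

Thin orchestration over the stage modules, used by the benchmark script and
tests; each stage remains independently callable and file-compatible with the
CLI.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import evaluation, reference_scoring
from .classifier import Hyperparams, ModelBundle, rank_table, train_models
from .feature_extraction import extract_feature_table
from .formats_io import read_contigs, read_psl, read_read_alignments, read_table


@dataclass
class BenchmarkResult:
    ranking: pd.DataFrame          # rank, contig_id, surankco_score, S_i, P_i
    evaluation: pd.DataFrame       # contig_id, pIdent, qcovhsp, eval_score, group
    bundle: ModelBundle
    roc_auc: float                 # vs the simulator's truth labels
    pearson: float                 # surankco score vs harmonic-mean eval score
    spearman: float


def stage_tables(fixture_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """(features, single scores, PSL records) for one fixture directory."""
    d = Path(fixture_dir)
    contigs = read_contigs(d / "contigs.fasta")
    features = extract_feature_table(contigs, read_read_alignments(d / "reads.sam"))
    psl = read_psl(d / "truth.psl")
    scores = reference_scoring.score_table(contigs, psl)
    return features, scores, psl


def run_benchmark(
    train_dir: str | Path,
    test_dir: str | Path,
    seed: int = 0,
    quantile: float = reference_scoring.DEFAULT_QUANTILE,
    hyperparams: Hyperparams | None = None,
) -> BenchmarkResult:
    """Train on one fixture, predict and evaluate on another.

    Measures ROC AUC of the contig score against the simulator's good/bad
    truth labels, and Pearson/Spearman correlation against the harmonic-mean
    evaluation score from the test fixture's reference alignments.
    """
    feat_tr, score_tr, _ = stage_tables(train_dir)
    feat_te, _, psl_te = stage_tables(test_dir)

    thresholds = reference_scoring.fit_class_thresholds(score_tr, q=quantile)
    classes = reference_scoring.assign_classes(score_tr, thresholds)
    bundle = train_models(feat_tr, classes, hyperparams, seed=seed,
                          thresholds=thresholds)
    ranking = rank_table(bundle, feat_te)

    truth = read_table(Path(test_dir) / "truth.tsv")
    ev = evaluation.evaluation_scores(psl_te, list(ranking["contig_id"]))
    merged = ranking.merge(truth, on="contig_id").merge(ev, on="contig_id")
    labels = (merged["label"] == "good").astype(int)
    roc = evaluation.roc_curve(labels, merged["surankco_score"])
    pearson, spearman = evaluation.correlations(
        merged["surankco_score"], merged["eval_score"])
    return BenchmarkResult(ranking=ranking, evaluation=ev, bundle=bundle,
                           roc_auc=roc.auc, pearson=pearson, spearman=spearman)
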