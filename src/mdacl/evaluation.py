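"""Evaluation: confusion metrics, AUC, cross-validation, ranking, stability.

Metric definitions follow the usual confusion-matrix identities

    ACC = (TP+TN)/(TP+TN+FP+FN)      SPE = TN/(TN+FP)
    SEN = TP/(TP+FN) (= REC)         PRE = TP/(TP+FP)
    F1  = 2*PRE*SEN/(PRE+SEN)

with a fixed 0.5 probability threshold and AUC computed as the rank
(Mann–Whitney) statistic, ties counted one half.  The k-fold harness
retrains the full pipeline (encoder + classifier head) per fold with the
test positives removed from the visible graph, scores held-out positives
against matched sampled negatives, and reports per-fold rows plus their
mean.  Leave-one-out case-study ranking retrains without any edge incident
to the target node before scoring all opposite-side candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .classifier import HeadConfig, concat_pairs, predict_pairs, train_classifier
from .graph import BipartiteGraph, derive_seed, kfold_split
from .training import TrainConfig, ablation_config, train_encoder

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion",
    "metrics",
    "auc",
    "cross_validate",
    "rank_candidates",
    "stability_summary",
]

METRIC_COLUMNS = ["AUC", "ACC", "SPE", "PRE", "REC", "F1"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class EvalReport:
    """Per-fold metric table with an appended mean row and run metadata."""

    table: pd.DataFrame  # one row per fold plus "Average", columns METRIC_COLUMNS
    seed: int
    config: TrainConfig | None = None
    ablation: str = "full"

    @property
    def mean(self) -> pd.Series:
        return self.table.loc["Average"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, float_format="%.6f")


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Thresholded confusion counts; ``score >= threshold`` predicts positive."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        FP=int(np.sum(pred & ~pos)),
        TN=int(np.sum(~pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      stacklevel=3)
        return float("nan")
    return num / den


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """ACC/SPE/SEN(REC)/PRE/F1 from confusion counts."""
    acc = _ratio(counts.TP + counts.TN, counts.total, "ACC")
    spe = _ratio(counts.TN, counts.TN + counts.FP, "SPE")
    sen = _ratio(counts.TP, counts.TP + counts.FN, "SEN")
    pre = _ratio(counts.TP, counts.TP + counts.FP, "PRE")
    if np.isnan(pre) or np.isnan(sen) or (pre + sen) == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * pre * sen / (pre + sen)
    return {"ACC": acc, "SPE": spe, "SEN": sen, "REC": sen, "PRE": pre, "F1": f1}


def auc(labels, scores) -> float:
    """Probability a random positive outranks a random negative (ties = 1/2)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    return float(
        (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def _fit_and_score_fold(graph, fold, cfg, head_cfg, fold_seed):
    """Train encoder + head on one fold's training data; score its test pairs."""
    model = train_encoder(graph, cfg, train_pos=fold.train_pos)
    Xm = model.embeddings.readout_mirna
    Xd = model.embeddings.readout_disease
    train_pairs = np.vstack([fold.train_pos, fold.train_neg])
    train_labels = np.concatenate(
        [np.ones(len(fold.train_pos)), np.zeros(len(fold.train_neg))]
    )
    head = train_classifier(
        concat_pairs(Xm, Xd, train_pairs),
        train_labels,
        head_cfg,
        seed=derive_seed(fold_seed, 901),
    )
    test_pairs = np.vstack([fold.test_pos, fold.test_neg])
    test_labels = np.concatenate(
        [np.ones(len(fold.test_pos)), np.zeros(len(fold.test_neg))]
    )
    scores = predict_pairs(head, Xm, Xd, test_pairs)
    return test_labels, scores, model, head


def cross_validate(
    graph: BipartiteGraph,
    config: TrainConfig | None = None,
    k: int = 5,
    seed: int = 0,
    ablation: str = "full",
    neg_ratio: float = 1.0,
    head_config: HeadConfig | None = None,
) -> EvalReport:
    """K-fold cross-validation of the full pipeline.

    Each fold's test positives are hidden from the propagation operator and
    the training losses; ablations zero the corresponding contrastive loss
    weights while keeping seeds, splits and initial conditions identical to
    the full model.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    base_cfg = config or TrainConfig()
    cfg = ablation_config(base_cfg, ablation)
    folds = kfold_split(graph, k, seed=derive_seed(seed, 902), neg_ratio=neg_ratio)
    rows = []
    for fold in folds:
        fold_cfg = TrainConfig(
            **{**cfg.__dict__, "seed": derive_seed(seed, 903, fold.fold_id)}
        )
        labels, scores, _, _ = _fit_and_score_fold(
            graph, fold, fold_cfg, head_config, derive_seed(seed, 904, fold.fold_id)
        )
        counts = confusion(labels, scores, 0.5)
        row = metrics(counts)
        rows.append({"AUC": auc(labels, scores), **{c: row[c] for c in
                     ("ACC", "SPE", "PRE", "REC", "F1")}})
    table = pd.DataFrame(rows, index=[f"fold{f.fold_id + 1}" for f in folds])
    table.loc["Average"] = table.mean(axis=0)
    table = table[METRIC_COLUMNS]
    return EvalReport(table=table, seed=seed, config=base_cfg, ablation=ablation)


def rank_candidates(
    graph: BipartiteGraph,
    target: int,
    side: str = "disease",
    config: TrainConfig | None = None,
    seed: int = 0,
    head_config: HeadConfig | None = None,
) -> pd.DataFrame:
    """Leave-one-out case-study ranking for one node.

    All edges incident to ``target`` are removed, the full pipeline is
    retrained on the remainder (negatives for the classifier are resampled
    from non-edges), and every opposite-side candidate is scored.  Returns
    candidates sorted by descending probability, ties broken by node index.
    """
    cfg = config or TrainConfig()
    if side not in ("disease", "mirna"):
        raise ValueError("side must be 'disease' or 'mirna'")
    col = 1 if side == "disease" else 0
    n_side = graph.n_disease if side == "disease" else graph.n_mirna
    if not (0 <= target < n_side):
        raise IndexError(f"unknown {side} id: {target}")
    keep = graph.edges[:, col] != target
    train_pos = graph.edges[keep]
    if train_pos.shape[0] == 0:
        raise ValueError("no training edges remain after removing the target")

    cfg = TrainConfig(**{**cfg.__dict__, "seed": derive_seed(seed, 905)})
    model = train_encoder(graph, cfg, train_pos=train_pos)
    Xm = model.embeddings.readout_mirna
    Xd = model.embeddings.readout_disease

    # Balanced classifier training set from the leave-one-out positives.
    rng = np.random.default_rng(derive_seed(seed, 906))
    train_graph = graph.with_edges(train_pos)
    from .graph import _sample_non_edges

    negs = _sample_non_edges(
        train_graph, train_pos.shape[0], rng, np.array([], dtype=np.int64)
    )
    pairs = np.vstack([train_pos, negs])
    labels = np.concatenate([np.ones(len(train_pos)), np.zeros(len(negs))])
    head = train_classifier(
        concat_pairs(Xm, Xd, pairs), labels, head_config,
        seed=derive_seed(seed, 907),
    )

    n_cand = graph.n_mirna if side == "disease" else graph.n_disease
    cand = np.arange(n_cand)
    if side == "disease":
        score_pairs = np.column_stack([cand, np.full(n_cand, target)])
        names = graph.mirna_names
    else:
        score_pairs = np.column_stack([np.full(n_cand, target), cand])
        names = graph.disease_names
    probs = predict_pairs(head, Xm, Xd, score_pairs)
    order = np.lexsort((cand, -probs))
    out = pd.DataFrame({
        "candidate": cand[order],
        "probability": probs[order],
    })
    if names is not None:
        out.insert(1, "name", [names[i] for i in out["candidate"]])
    return out.reset_index(drop=True)


def stability_summary(reports: list[EvalReport]) -> pd.DataFrame:
    """Five-number summary and outlier flags of the mean metrics across runs.

    Quartiles use linear interpolation; a run is flagged as an outlier for
    a metric when its value falls outside ``[Q1 - 1.5 IQR, Q3 + 1.5 IQR]``.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports")
    values = pd.DataFrame([r.mean for r in reports])
    rows = {}
    for col in values.columns:
        v = values[col].to_numpy(dtype=np.float64)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        out_mask = (v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)
        rows[col] = {
            "min": v.min(), "Q1": q1, "median": med, "Q3": q3, "max": v.max(),
            "n_outliers": int(out_mask.sum()),
        }
    return pd.DataFrame(rows).T[["min", "Q1", "median", "Q3", "max", "n_outliers"]]
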