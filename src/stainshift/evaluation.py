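"""Internal / external evaluation protocol.

F1 (robust to class imbalance) and ROC AUC (robust to miscalibrated
decision thresholds) per partition, aggregated over random-initialization
seeds as mean +/- sample standard deviation; paired Wilcoxon signed-rank
comparison between method combinations; and 2-D feature-embedding export
for qualitative inspection of domain mixing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skmetrics
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "PredictionSet",
    "ExperimentResult",
    "f1_score",
    "auc_score",
    "optimal_threshold",
    "compare_methods",
    "aggregate",
    "results_table",
    "export_embeddings",
    "domain_probe_accuracy",
    "knn_domain_purity",
]


@dataclass(frozen=True)
class PredictionSet:
    """Per-record predictions of one fitted model on one partition."""

    ids: np.ndarray
    probabilities: np.ndarray
    labels: np.ndarray
    domains: np.ndarray
    partition: str
    seed: int
    method: str

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        n = len(p)
        for name in ("ids", "labels", "domains"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match probabilities")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "probability": self.probabilities,
                "task_label": self.labels,
                "domain_label": self.domains,
                "partition": self.partition,
                "seed": self.seed,
                "method": self.method,
            }
        )


@dataclass
class ExperimentResult:
    """Per-seed and aggregated metrics for one method combination."""

    method: str
    per_seed: pd.DataFrame  # columns: seed, partition, f1, auc
    summary: pd.DataFrame = field(init=False)  # partition x (mean, sd) per metric

    def __post_init__(self) -> None:
        grouped = self.per_seed.groupby("partition")[["f1", "auc"]]
        mean = grouped.mean()
        n = grouped.count()
        sd = grouped.std(ddof=1).where(n > 1)  # sd undefined for a single run
        self.summary = pd.concat(
            {"mean": mean, "sd": sd}, axis=1
        ).swaplevel(axis=1).sort_index(axis=1)


def f1_score(preds: PredictionSet, threshold: float = 0.5) -> float:
    """Harmonic mean of precision and recall at the probability threshold;
    0 by convention when precision or recall is undefined."""
    pred = (np.asarray(preds.probabilities) >= threshold).astype(int)
    return float(
        skmetrics.f1_score(preds.labels, pred, zero_division=0)
    )


def auc_score(preds: PredictionSet) -> float:
    """Area under the ROC curve: the probability that a random positive
    outranks a random negative, ties counted 1/2."""
    labels = np.asarray(preds.labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(skmetrics.roc_auc_score(labels, preds.probabilities))


def optimal_threshold(preds: PredictionSet) -> float:
    """Decision threshold maximizing F1 on (typically validation) data."""
    probs = np.asarray(preds.probabilities)
    candidates = np.unique(probs)
    best_t, best_f1 = 0.5, -1.0
    for t in candidates:
        f1 = f1_score(preds, threshold=t)
        if f1 > best_f1:
            best_t, best_f1 = float(t), f1
    return best_t


def compare_methods(
    preds_a: PredictionSet,
    preds_b: PredictionSet,
    pairing: str = "probability",
    threshold: float = 0.5,
    method: str = "auto",
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired per-record values.

    ``pairing='probability'`` pairs predicted probabilities;
    ``'correctness'`` pairs 0/1 correctness indicators at ``threshold``.
    Zero differences are dropped (classic Wilcoxon treatment); the exact
    null distribution is used for up to 25 non-zero pairs, the
    continuity-corrected normal approximation beyond (``method`` can force
    either path).  All-zero differences return (0, 1) — there is nothing
    to test.
    """
    ids_a, ids_b = np.asarray(preds_a.ids), np.asarray(preds_b.ids)
    if len(ids_a) != len(ids_b) or np.any(ids_a != ids_b):
        raise ValueError("prediction sets are not paired (record ids differ)")
    if pairing == "probability":
        a = np.asarray(preds_a.probabilities, dtype=float)
        b = np.asarray(preds_b.probabilities, dtype=float)
    elif pairing == "correctness":
        a = ((np.asarray(preds_a.probabilities) >= threshold).astype(int)
             == np.asarray(preds_a.labels)).astype(float)
        b = ((np.asarray(preds_b.probabilities) >= threshold).astype(int)
             == np.asarray(preds_b.labels)).astype(float)
    else:
        raise ValueError("pairing must be 'probability' or 'correctness'")
    diff = a - b
    nonzero = np.count_nonzero(diff)
    if nonzero == 0:
        return 0.0, 1.0
    if method == "auto":
        method = "exact" if nonzero <= 25 else "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", method=method,
                         correction=(method == "approx"),
                         alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def aggregate(runs: list[PredictionSet], threshold: float = 0.5) -> ExperimentResult:
    """Mean and sample standard deviation of F1/AUC across seeds, per
    partition, for one method combination."""
    methods = {r.method for r in runs}
    if len(methods) != 1:
        raise ValueError(f"runs mix method tags: {sorted(methods)}")
    rows = []
    for r in runs:
        rows.append(
            {
                "seed": r.seed,
                "partition": r.partition,
                "f1": f1_score(r, threshold=threshold),
                "auc": auc_score(r),
            }
        )
    return ExperimentResult(method=methods.pop(), per_seed=pd.DataFrame(rows))


def results_table(results: list[ExperimentResult]) -> pd.DataFrame:
    """Wide table: rows = metric x partition, columns = method
    combinations, cells = "mean (+/-sd)"."""
    cols = {}
    for res in results:
        cells = {}
        for partition, row in res.summary.iterrows():
            for metric in ("f1", "auc"):
                mean = row[(metric, "mean")]
                sd = row[(metric, "sd")]
                text = f"{mean:.4f}" if pd.isna(sd) else f"{mean:.4f} (±{sd:.4f})"
                cells[(metric, partition)] = text
        cols[res.method] = cells
    table = pd.DataFrame(cols)
    table.index.names = ["metric", "partition"]
    return table


def export_embeddings(
    fit_result,
    records,
    n_samples: int = 80,
    seed: int = 0,
) -> pd.DataFrame:
    """2-D manifold projection of the embedding-layer features.

    Samples ``n_samples`` records, extracts the task branch's first
    dense-layer activations (128-d for the compact model) and projects them
    with UMAP; returns a table (id, dim1, dim2, task_label, domain_label)
    ready for plotting.
    """
    import umap  # heavy import, keep local

    records = list(records)
    if n_samples > len(records):
        raise ValueError(f"n_samples {n_samples} exceeds {len(records)} records")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(records), size=n_samples, replace=False)
    chosen = [records[i] for i in pick]
    feats = fit_result.task_features(chosen)
    reducer = umap.UMAP(n_components=2, random_state=seed,
                        n_neighbors=min(15, n_samples - 1))
    proj = reducer.fit_transform(feats)
    return pd.DataFrame(
        {
            "id": pick,
            "dim1": proj[:, 0],
            "dim2": proj[:, 1],
            "task_label": [r.task_label for r in chosen],
            "domain_label": [r.domain_label for r in chosen],
        }
    )


def domain_probe_accuracy(
    features: np.ndarray,
    domains: np.ndarray,
    seed: int = 0,
    test_fraction: float = 0.3,
) -> float:
    """Held-out accuracy of a linear (logistic) probe predicting the
    domain from features — low accuracy means domain-invariant features."""
    x_tr, x_te, y_tr, y_te = train_test_split(
        features, domains, test_size=test_fraction, random_state=seed,
        stratify=domains,
    )
    probe = LogisticRegression(max_iter=2000)
    probe.fit(x_tr, y_tr)
    return float(probe.score(x_te, y_te))


def knn_domain_purity(features: np.ndarray, domains: np.ndarray, k: int = 10) -> float:
    """Fraction of k nearest neighbors sharing a point's domain, averaged
    over points; chance level is the domain frequency mix."""
    domains = np.asarray(domains)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(features)
    _, idx = nn.kneighbors(features)
    same = domains[idx[:, 1:]] == domains[:, None]
    return float(same.mean())
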