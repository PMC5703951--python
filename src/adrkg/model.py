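"""Per-ADR scoring model: scaled adjacency features, Youden-J-optimal weights.

The feature matrix D has one row per drug and one column per feature type;
D[i, j] is drug i's total adjacency with the enriched predictors of type j,
min-max scaled per column to [0, 1]. A drug's score is D @ w for a
non-negative, L2-normalised weight vector w. The weights and the score
threshold are chosen to maximise Youden's J = sensitivity + specificity - 1
on the training labels (known cause vs not), by exhaustive search over a
lattice of weight directions and all informative thresholds. Drugs above
the threshold that are not known causes are the model's new predictions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .enrich import PredictorSet
from .graph import KnowledgeGraph, NodeRef, adjacency_count


class ModelError(ValueError):
    pass


@dataclass
class FeatureMatrix:
    """Scaled per-drug adjacency features for one predictor set.

    ``scaling_params[j] = (min_j, max_j)`` are the raw adjacency extrema of
    column j over the training drugs; they are stored so unseen drugs can be
    scored on the same scale (and clipped to [0, 1]).
    """

    drugs: list[NodeRef]
    feature_types: list[str]
    values: np.ndarray  # (n_drugs, n_types), scaled to [0, 1]
    raw: np.ndarray  # unscaled adjacency counts
    scaling_params: list[tuple[float, float]]

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)


def scale_columns(raw: np.ndarray, params: list[tuple[float, float]]) -> np.ndarray:
    """Min-max scale each column with stored (min, max); constant columns map to 0."""
    raw = np.asarray(raw, dtype=float)
    out = np.zeros_like(raw)
    for j, (lo, hi) in enumerate(params):
        if hi > lo:
            out[:, j] = np.clip((raw[:, j] - lo) / (hi - lo), 0.0, 1.0)
    return out


def build_feature_matrix(g: KnowledgeGraph, ps: PredictorSet) -> FeatureMatrix:
    """Raw adjacency of every drug with each type's predictors, min-max scaled per column.

    Feature scaling matters because drugs typically have far more known ADRs
    than targets or indications; without it the ADR column would dominate
    every weighted score.
    """
    types = ps.feature_types
    if not types:
        raise ModelError("predictor set has no feature types")
    drugs = sorted(g.drugs)
    pred_nodes = [ps.predictor_nodes(t) for t in types]
    raw = np.array(
        [[adjacency_count(g, d, nodes) for nodes in pred_nodes] for d in drugs], dtype=float
    )
    params = [(float(raw[:, j].min()), float(raw[:, j].max())) for j in range(raw.shape[1])]
    return FeatureMatrix(drugs, list(types), scale_columns(raw, params), raw, params)


@dataclass
class AdrModel:
    """Trained scoring model for one ADR."""

    adr: NodeRef
    predictor_set: PredictorSet
    feature_types: list[str]
    w: np.ndarray
    threshold: float
    j: float
    scaling_params: list[tuple[float, float]]
    scores: dict[NodeRef, float]

    def score_drugs(self, g: KnowledgeGraph, drugs=None) -> dict[NodeRef, float]:
        """Score drugs of ``g`` with the stored predictors and scaling parameters."""
        drugs = sorted(g.drugs) if drugs is None else list(drugs)
        pred_nodes = [self.predictor_set.predictor_nodes(t) for t in self.feature_types]
        raw = np.array(
            [[adjacency_count(g, d, nodes) for nodes in pred_nodes] for d in drugs], dtype=float
        )
        scaled = scale_columns(raw, self.scaling_params)
        return dict(zip(drugs, (scaled @ self.w).tolist()))

    def to_dict(self) -> dict:
        return {
            "adr": self.adr.identifier,
            "feature_types": list(self.feature_types),
            "w": self.w.tolist(),
            "threshold": self.threshold,
            "j": self.j,
            "scaling_params": [list(p) for p in self.scaling_params],
            "predictors": self.predictor_set.to_dict()["predictors"],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def youden_j(labels, scores, threshold: float) -> float:
    """J = TP/P + TN/N - 1 with a prediction positive iff score > threshold (strict)."""
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    pos, neg = int(y.sum()), int((~y).sum())
    if pos == 0 or neg == 0:
        raise ModelError("labels must contain at least one positive and one negative")
    pred = s > threshold
    tp = int((pred & y).sum())
    tn = int((~pred & ~y).sum())
    return tp / pos + tn / neg - 1.0


def lattice_directions(n_cols: int, grid_step: float = 0.05) -> np.ndarray:
    """Deduplicated non-negative weight directions, L2-normalised.

    The lattice is the integer grid {0, step, 2*step, ..., 1}^n minus the
    origin; points sharing a direction are reduced to their primitive
    integer vector and kept in first-seen (lexicographic) order, which fixes
    the tie-breaking order of the optimizer.
    """
    m = round(1.0 / grid_step)
    if not math.isclose(m * grid_step, 1.0, rel_tol=1e-9):
        raise ModelError("grid_step must evenly divide 1")
    seen: dict[tuple[int, ...], None] = {}
    import itertools

    for point in itertools.product(range(m + 1), repeat=n_cols):
        if not any(point):
            continue
        g = math.gcd(*point)
        seen.setdefault(tuple(v // g for v in point))
    W = np.array(list(seen), dtype=float)
    return W / np.linalg.norm(W, axis=1, keepdims=True)


def optimize_model(
    D: FeatureMatrix,
    labels,
    grid_step: float = 0.05,
    *,
    adr: NodeRef | None = None,
) -> AdrModel:
    """Exhaustive search for the weight direction and threshold maximising J.

    Ties are broken deterministically: higher specificity first, then the
    lower lattice index of the weight direction, then the lower threshold.
    J is compared on an exact integer scale (TP*N + TN*P - P*N) so float
    noise cannot reorder ties.
    """
    y = np.asarray(labels, dtype=bool)
    if y.shape[0] != D.n_drugs:
        raise ModelError("labels must align with the feature matrix rows")
    pos, neg = int(y.sum()), int((~y).sum())
    if pos == 0 or neg == 0:
        raise ModelError("labels must contain at least one positive and one negative")
    if D.values.size == 0:
        raise ModelError("empty feature matrix")

    W = lattice_directions(len(D.feature_types), grid_step)
    S = D.values @ W.T  # (n, G)
    n, G = S.shape
    order = np.argsort(-S, axis=0, kind="stable")
    s_sorted = np.take_along_axis(S, order, axis=0)
    y_sorted = y[order]

    # boundary k = number of top-scoring drugs predicted positive, k in 0..n;
    # interior boundaries are valid only between distinct score values
    cum_tp = np.vstack([np.zeros((1, G), dtype=np.int64), np.cumsum(y_sorted, axis=0)])
    k = np.arange(n + 1)[:, None]
    tn = neg - (k - cum_tp)
    j_int = cum_tp * neg + tn * pos - pos * neg
    allowed = np.ones((n + 1, G), dtype=bool)
    allowed[1:n] = s_sorted[:-1] > s_sorted[1:]
    key = j_int * (neg + 1) + tn
    key = np.where(allowed, key, np.iinfo(np.int64).min)

    best_k = np.argmax(key, axis=0)  # per direction; first max = fewest positives
    per_dir = key[best_k, np.arange(G)]
    g_best = int(np.argmax(per_dir))  # first max = lowest lattice index
    kb = int(best_k[g_best])

    col = s_sorted[:, g_best]
    if kb == 0:
        threshold = float(col[0] + 0.5)  # sentinel above max score
    elif kb == n:
        threshold = float(col[-1] - 0.5)  # sentinel below min score
    else:
        threshold = float((col[kb - 1] + col[kb]) / 2.0)

    j_val = float(j_int[kb, g_best]) / (pos * neg)
    scores = dict(zip(D.drugs, S[:, g_best].tolist()))
    ps = None
    model_adr = adr
    return AdrModel(
        adr=model_adr,
        predictor_set=ps,
        feature_types=list(D.feature_types),
        w=W[g_best],
        threshold=threshold,
        j=j_val,
        scaling_params=list(D.scaling_params),
        scores=scores,
    )


def train_model(
    g: KnowledgeGraph, ps: PredictorSet, grid_step: float = 0.05
) -> AdrModel:
    """Build features from ``g`` for ``ps`` and fit weights/threshold.

    Labels are adjacency with the modelled ADR in ``g`` (known causes are
    positives, every other drug a negative).
    """
    D = build_feature_matrix(g, ps)
    labels = np.array([g.has_edge(d, ps.adr) for d in D.drugs])
    model = optimize_model(D, labels, grid_step, adr=ps.adr)
    model.predictor_set = ps
    return model


def predict_new(m: AdrModel, g: KnowledgeGraph) -> set[NodeRef]:
    """Drugs scoring above the threshold that are not known causes of the ADR in ``g``."""
    scores = m.score_drugs(g)
    return {
        d for d, s in scores.items() if s > m.threshold and not g.has_edge(d, m.adr)
    }


def compute_auc(labels, scores) -> float:
    """Mann–Whitney AUC of the scores against the labels (ties credited 1/2)."""
    y = np.asarray(labels, dtype=int)
    if y.min() == y.max():
        raise ModelError("labels must contain at least one positive and one negative")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))
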