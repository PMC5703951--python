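"""Evaluation machinery: edge-deletion cross-validation, confidence binning,
random-model significance against an observation table, and benchmark
classifiers.

The cross-validation scheme mirrors the intended use of the predictor: the
known-cause edges of an ADR are split into k folds and each fold's edges are
deleted from the graph *while the drug nodes remain*, so the deleted drugs
are treated as true negatives during training. Recovery is the fraction of
deleted drugs that reappear among the model's new predictions. Raw
confidence compares that recovery with the expected recovery of a random
model making the same number of predictions.

Significance of a trained model's new predictions against an externally
observed drug–ADR table is assessed with a Monte-Carlo null: random models
pick the same number N of drugs uniformly from the eligible non-cause pool,
and the trained model is significant when fewer than 5% of random models
validate at least as many predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrich import NoModel, select_predictors
from .graph import KnowledgeGraph, NodeRef
from .model import AdrModel, FeatureMatrix, ModelError, build_feature_matrix, optimize_model, predict_new

BENCHMARK_METHODS = ("LR", "DT", "SVM")


class EvaluationError(ValueError):
    pass


@dataclass
class CvFold:
    deleted_drugs: frozenset[NodeRef]
    trained: bool
    n_new_predictions: int | None = None
    n_recovered: int | None = None
    pool_size: int | None = None

    @property
    def recovery(self) -> float | None:
        if not self.trained or not self.deleted_drugs:
            return None
        return self.n_recovered / len(self.deleted_drugs)


@dataclass
class CvReport:
    adr: NodeRef
    folds: list[CvFold]
    mean_recovery: float | None
    expected_random_recovery: float | None
    raw_confidence: float | None
    confidence_bin: str | None = None

    @property
    def n_successful(self) -> int:
        return sum(1 for f in self.folds if f.trained)

    def to_dict(self) -> dict:
        return {
            "adr": self.adr.identifier,
            "n_folds": len(self.folds),
            "n_successful": self.n_successful,
            "mean_recovery": self.mean_recovery,
            "expected_random_recovery": self.expected_random_recovery,
            "raw_confidence": self.raw_confidence,
            "confidence_bin": self.confidence_bin,
        }


def expected_random_recovery(n_predictions: int, pool_size: int) -> float:
    """Expected fraction of deleted drugs hit by a uniform random choice of
    ``n_predictions`` drugs from a pool of ``pool_size`` non-causes."""
    if pool_size <= 0:
        raise EvaluationError("pool_size must be positive")
    if not 0 <= n_predictions <= pool_size:
        raise EvaluationError("n_predictions must lie in [0, pool_size]")
    return n_predictions / pool_size


def _fit_predict_benchmark(D: FeatureMatrix, labels: np.ndarray, method: str):
    """Fit a benchmark classifier on the full feature matrix.

    Returns the fitted estimator and its training-set predictions.
    Settings emulate the comparator configurations: RBF-kernel SVM at
    defaults, decision tree with min 5 samples per leaf, L2 logistic
    regression at defaults.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    if method == "LR":
        clf = LogisticRegression()  # default = L2 regularisation
    elif method == "DT":
        clf = DecisionTreeClassifier(min_samples_leaf=5, random_state=0)
    elif method == "SVM":
        clf = SVC(kernel="rbf")
    else:
        raise EvaluationError(f"unknown benchmark method {method!r}")
    clf.fit(D.values, labels.astype(int))
    return clf, clf.predict(D.values).astype(bool)


def train_benchmarks(D: FeatureMatrix, labels, method: str):
    """Fit one benchmark classifier and return (estimator, new-prediction set).

    New predictions are the training-set false positives: drugs predicted
    positive whose label is negative.
    """
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ModelError("labels must contain at least one positive and one negative")
    clf, pred = _fit_predict_benchmark(D, y, method)
    new = {d for d, p, lab in zip(D.drugs, pred, y) if p and not lab}
    return clf, new


def edge_deletion_cv(
    g: KnowledgeGraph,
    adr: NodeRef,
    k: int = 10,
    seed: int = 0,
    *,
    alpha: float = 0.05,
    grid_step: float = 0.05,
    method: str = "youden",
) -> CvReport:
    """k-fold edge-deletion cross-validation for one ADR.

    Known-cause edges are shuffled with ``seed`` and split into k near-equal
    folds. Per fold the edges are deleted (drug nodes retained as true
    negatives), predictors re-selected and a model re-trained on the
    modified graph, and recovery is the fraction of deleted drugs among the
    model's new predictions. Deleted edges are restored before the next
    fold. A fold is unsuccessful when it is empty, predictor selection
    returns NoModel, or training is degenerate; averages cover successful
    folds only. ``method`` may name a benchmark classifier (LR/DT/SVM)
    instead of the Youden-J optimizer, in which case new predictions are the
    classifier's training-set false positives.
    """
    if k < 2:
        raise EvaluationError("k must be at least 2")
    causes = sorted(g.neighbors(adr))
    if not causes:
        raise EvaluationError(f"{adr} has no known causes")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(causes))
    fold_indices = np.array_split(perm, k)
    n_drugs = len(g.drugs)

    folds: list[CvFold] = []
    for idx in fold_indices:
        deleted = frozenset(causes[i] for i in idx)
        if not deleted:
            folds.append(CvFold(deleted, trained=False))
            continue
        g2 = g.copy()
        for drug in deleted:
            g2.remove_edge(drug, adr)
        remaining = g2.neighbors(adr) if g2.has_node(adr) else set()
        if not remaining:
            folds.append(CvFold(deleted, trained=False))
            continue
        ps = select_predictors(g2, adr, alpha)
        if isinstance(ps, NoModel):
            folds.append(CvFold(deleted, trained=False))
            continue
        D = build_feature_matrix(g2, ps)
        labels = np.array([g2.has_edge(d, adr) for d in D.drugs])
        try:
            if method == "youden":
                model = optimize_model(D, labels, grid_step, adr=adr)
                model.predictor_set = ps
                new = predict_new(model, g2)
            else:
                _, new = train_benchmarks(D, labels, method)
        except ModelError:
            folds.append(CvFold(deleted, trained=False))
            continue
        pool = n_drugs - len(remaining)  # drugs not known causes after deletion
        folds.append(
            CvFold(
                deleted,
                trained=True,
                n_new_predictions=len(new),
                n_recovered=len(new & deleted),
                pool_size=pool,
            )
        )

    good = [f for f in folds if f.trained]
    if good:
        mean_recovery = float(np.mean([f.recovery for f in good]))
        expected = float(np.mean([f.n_new_predictions / f.pool_size for f in good]))
        raw = mean_recovery / expected if expected > 0 else None
    else:
        mean_recovery = expected = raw = None
    return CvReport(adr, folds, mean_recovery, expected, raw)


def assign_confidence(reports: list[CvReport], min_successful_folds: int = 6) -> list[CvReport]:
    """Set confidence bins in place across a collection of per-ADR CV reports.

    The median raw confidence is taken over ADRs with at least
    ``min_successful_folds`` successful folds. Bins: high if raw > median,
    mid if 1 < raw <= median, low if raw <= 1, raw is undefined, or the ADR
    had too few successful folds.
    """
    eligible = [
        r
        for r in reports
        if r.n_successful >= min_successful_folds and r.raw_confidence is not None
    ]
    eligible_ids = {id(r) for r in eligible}
    median = float(np.median([r.raw_confidence for r in eligible])) if eligible else None
    for r in reports:
        if id(r) not in eligible_ids or median is None:
            r.confidence_bin = "low"
        elif r.raw_confidence > median:
            r.confidence_bin = "high"
        elif r.raw_confidence > 1:
            r.confidence_bin = "mid"
        else:
            r.confidence_bin = "low"
    return reports


# -- observation table and random-model significance -----------------------


class ObservationTable:
    """Externally observed drug–ADR associations (one row per drug–ADR pair).

    A drug is *eligible* for an ADR when it has a row for that ADR — the
    observation source could in principle have detected the association
    (e.g. the drug was prescribed in the health-record system). ``observed``
    marks pairs the source actually saw associated.
    """

    COLUMNS = ("drug_id", "adr_id", "observed")

    def __init__(self, df: pd.DataFrame) -> None:
        for col in self.COLUMNS:
            if col not in df.columns:
                raise EvaluationError(f"observation table missing column {col!r}")
        if df.duplicated(subset=["drug_id", "adr_id"]).any():
            raise EvaluationError("observation table has duplicate (drug, adr) rows")
        self.df = df.reset_index(drop=True)

    @classmethod
    def load(cls, path) -> "ObservationTable":
        df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "adr_id": str})
        df["observed"] = df["observed"].astype(int).astype(bool)
        return cls(df)

    def save(self, path) -> None:
        out = self.df.copy()
        out["observed"] = out["observed"].astype(int)
        out.to_csv(path, sep="\t", index=False)

    def eligible_drugs(self, adr: NodeRef) -> set[str]:
        return set(self.df.loc[self.df["adr_id"] == adr.identifier, "drug_id"])

    def observed_drugs(self, adr: NodeRef) -> set[str]:
        mask = (self.df["adr_id"] == adr.identifier) & self.df["observed"]
        return set(self.df.loc[mask, "drug_id"])


@dataclass
class ValidationReport:
    """Random-model significance of a model's new predictions.

    N: new predictions testable in the observation source; V: validated
    (observed) among them; E: expected validated under the uniform null;
    p_random: fraction of random models with >= V validated predictions.
    """

    adr: NodeRef
    n_predictions: int
    n_validated: int
    expected_validated: float | None
    p_random: float | None
    significant: bool
    pool_size: int = 0
    pool_observed: int = 0

    def to_dict(self) -> dict:
        return {
            "adr": self.adr.identifier,
            "N": self.n_predictions,
            "V": self.n_validated,
            "E": self.expected_validated,
            "p_random": self.p_random,
            "significant": self.significant,
        }


def random_model_significance(
    m: AdrModel,
    g: KnowledgeGraph,
    obs: ObservationTable,
    n_iter: int = 100_000,
    seed: int = 0,
) -> ValidationReport:
    """Monte-Carlo significance of ``m``'s new predictions against ``obs``.

    Predictions are restricted to drugs eligible in the observation source.
    Each of ``n_iter`` random models draws N drugs uniformly without
    replacement from the M eligible non-cause drugs, of which K are observed
    associated; p_random is the fraction of random models with at least V
    validated predictions, and significance is strict: p_random < 0.05.
    With N = 0 the report carries a no-predictions outcome (p undefined).
    """
    adr = m.adr
    eligible = obs.eligible_drugs(adr)
    observed = obs.observed_drugs(adr)
    causes = {d.identifier for d in g.neighbors(adr)} if g.has_node(adr) else set()
    pool = eligible - causes
    M, K = len(pool), len(observed & pool)

    preds = {d.identifier for d in predict_new(m, g)} & pool
    N = len(preds)
    if N == 0:
        return ValidationReport(adr, 0, 0, None, None, False, M, K)
    if N > M:
        raise EvaluationError("more predictions than eligible non-cause drugs")
    V = len(preds & observed)
    E = N * K / M
    rng = np.random.default_rng(seed)
    # validated count of a uniform draw of N drugs from the pool is
    # hypergeometric(K successes, M-K failures, N draws)
    draws = rng.hypergeometric(K, M - K, N, size=n_iter)
    p = float(np.count_nonzero(draws >= V)) / n_iter
    return ValidationReport(adr, N, V, E, p, p < 0.05, M, K)
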