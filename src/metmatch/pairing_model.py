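"""Positive-unlabeled SVM ensemble and phenotype transfer.

The ensemble resamples balanced training sets (all positives plus an equal
number of unlabeled pairs), fits one probability-producing SVM per set, and
scores candidate pairs with the mean member probability.  Phenotype terms
of metabolites predicted similar to a natural product are transferred to it
as predicted therapeutic effects.
"""

from __future__ import annotations

import logging
import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.impute import SimpleImputer
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .data_io import DataError, PairLabelSet, PhenotypeAnnotation
from .similarity_features import FEATURE_COLUMNS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainingConfig:
    n_resamples: int = 100
    cv_folds: int = 10
    rng_seed: int = 0
    decision_threshold: float = 0.5
    svm_kernel: str = "rbf"
    svm_params: dict = field(default_factory=lambda: {"C": 1.0, "gamma": "scale"})

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise DataError("n_resamples must be >= 1")
        if self.cv_folds < 2:
            raise DataError("cv_folds must be >= 2")


@dataclass
class MemberModel:
    """One resample: a fitted imputer+scaler+SVM pipeline and its bookkeeping."""

    pipeline: Pipeline
    sampled_negatives: tuple[tuple[str, str], ...]
    cv_auroc: float


@dataclass
class EnsembleModel:
    members: list[MemberModel]
    config: TrainingConfig
    feature_names: tuple[str, ...] = tuple(FEATURE_COLUMNS)


@dataclass(frozen=True)
class PairPrediction:
    pair: tuple[str, str]
    ensemble_score: float
    is_similar: bool


@dataclass(frozen=True)
class TransferredPhenotype:
    natural_product_id: str
    phenotype_term: str
    source_metabolite_ids: frozenset[str]


def sample_training_sets(
    labels: PairLabelSet, n_resamples: int, rng_seed: int
) -> list[list[tuple[tuple[str, str], bool]]]:
    """Balanced resamples: all positives + an equal-size fresh uniform draw
    of unlabeled pairs (without replacement within a set).

    Deterministic given ``rng_seed``; fatal when the unlabeled pool is
    smaller than the positive set.
    """
    positives = sorted(labels.positives)
    unlabeled = sorted(labels.unlabeled)
    if not positives:
        raise DataError("no positive pairs: cannot build training sets")
    if len(unlabeled) < len(positives):
        raise DataError(
            f"only {len(unlabeled)} unlabeled pairs for {len(positives)} positives"
        )
    rng = np.random.default_rng(rng_seed)
    sets = []
    for _ in range(n_resamples):
        idx = rng.choice(len(unlabeled), size=len(positives), replace=False)
        sampled = [unlabeled[i] for i in sorted(idx)]
        sets.append([(p, True) for p in positives] + [(u, False) for u in sampled])
    return sets


def _feature_lookup(features: pd.DataFrame) -> dict[tuple[str, str], np.ndarray]:
    lookup = {}
    mat = features[FEATURE_COLUMNS].to_numpy(dtype=float)
    for i, row in enumerate(features.itertuples(index=False)):
        lookup[(row.partner_id, row.metabolite_id)] = mat[i]
    return lookup


@contextmanager
def _quiet_sklearn():
    # scikit-learn 1.9 deprecates SVC(probability=True); the pinned runtime
    # still supports it and Platt scaling is what we want per member
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=FutureWarning, module=r"sklearn\..*")
        yield


def _make_pipeline(config: TrainingConfig, random_state: int) -> Pipeline:
    return Pipeline(
        [
            ("impute", SimpleImputer(strategy="median", keep_empty_features=True)),
            ("scale", StandardScaler()),
            (
                "svm",
                SVC(
                    kernel=config.svm_kernel,
                    probability=True,
                    random_state=random_state,
                    **config.svm_params,
                ),
            ),
        ]
    )


def train_ensemble(
    features: pd.DataFrame,
    training_sets: list[list[tuple[tuple[str, str], bool]]],
    config: TrainingConfig,
) -> EnsembleModel:
    """Fit one SVM per balanced training set.

    Missing features are imputed with the member's training-set median and
    standardized per member.  A cross-validated AUROC is recorded per
    member for reporting; the final member is fit on its full training set.
    """
    lookup = _feature_lookup(features)
    rng = np.random.default_rng(config.rng_seed)
    members = []
    for k, tset in enumerate(training_sets):
        missing_pairs = [pair for pair, _ in tset if pair not in lookup]
        if missing_pairs:
            raise DataError(
                f"training set {k}: {len(missing_pairs)} pair(s) without features, "
                f"e.g. {missing_pairs[0]}"
            )
        X = np.vstack([lookup[pair] for pair, _ in tset])
        y = np.array([label for _, label in tset], dtype=bool)
        if y.all() or not y.any():
            raise DataError(f"training set {k} is single-class")
        seed = int(rng.integers(0, 2**31 - 1))
        pipeline = _make_pipeline(config, seed)
        folds = min(config.cv_folds, int(y.sum()), int((~y).sum()))
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        with _quiet_sklearn():
            proba = cross_val_predict(pipeline, X, y, cv=cv, method="predict_proba")[:, 1]
            cv_auroc = float(roc_auc_score(y, proba))
            pipeline.fit(X, y)
        members.append(
            MemberModel(
                pipeline=pipeline,
                sampled_negatives=tuple(pair for pair, label in tset if not label),
                cv_auroc=cv_auroc,
            )
        )
    logger.info(
        "trained %d members; mean CV AUROC %.3f",
        len(members),
        float(np.mean([m.cv_auroc for m in members])),
    )
    return EnsembleModel(members=members, config=config)


def predict_pairs(model: EnsembleModel, features: pd.DataFrame) -> list[PairPrediction]:
    """Score every pair in the feature table with the mean member probability."""
    if features.empty:
        return []
    X = features[list(model.feature_names)].to_numpy(dtype=float)
    scores = np.zeros(len(features))
    with _quiet_sklearn():
        for member in model.members:
            scores += member.pipeline.predict_proba(X)[:, 1]
    scores /= len(model.members)
    threshold = model.config.decision_threshold
    return [
        PairPrediction(
            pair=(row.partner_id, row.metabolite_id),
            ensemble_score=float(s),
            is_similar=bool(s >= threshold),
        )
        for row, s in zip(features.itertuples(index=False), scores)
    ]


def member_scores(model: EnsembleModel, features: pd.DataFrame) -> np.ndarray:
    """Per-member probabilities, shape (n_members, n_pairs); for diagnostics."""
    X = features[list(model.feature_names)].to_numpy(dtype=float)
    with _quiet_sklearn():
        return np.vstack([m.pipeline.predict_proba(X)[:, 1] for m in model.members])


def transfer_phenotypes(
    predictions: list[PairPrediction],
    annotations: list[PhenotypeAnnotation],
) -> list[TransferredPhenotype]:
    """Map each similar metabolite's phenotype terms onto its natural product.

    Terms are deduplicated per natural product; source metabolites
    accumulate.  A similar metabolite with no annotation contributes
    nothing (logged).
    """
    ann = {a.compound_id: a.phenotype_terms for a in annotations}
    acc: dict[tuple[str, str], set[str]] = {}
    for pred in predictions:
        if not pred.is_similar:
            continue
        np_id, met_id = pred.pair
        terms = ann.get(met_id)
        if not terms:
            logger.info("metabolite %s has no phenotype annotation; nothing transferred", met_id)
            continue
        for term in terms:
            acc.setdefault((np_id, term), set()).add(met_id)
    return [
        TransferredPhenotype(
            natural_product_id=np_id,
            phenotype_term=term,
            source_metabolite_ids=frozenset(sources),
        )
        for (np_id, term), sources in sorted(acc.items())
    ]


# ---------------------------------------------------------------------------
# persistence and TSV output
# ---------------------------------------------------------------------------

ARCHIVE_VERSION = 1


def save_model(model: EnsembleModel, path) -> None:
    import joblib

    joblib.dump({"version": ARCHIVE_VERSION, "model": model}, path)


def load_model(path) -> EnsembleModel:
    import joblib

    bundle = joblib.load(path)
    if bundle.get("version") != ARCHIVE_VERSION:
        raise DataError(f"unsupported model archive version {bundle.get('version')!r}")
    return bundle["model"]


def predictions_to_frame(predictions: list[PairPrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "partner_id": p.pair[0],
                "metabolite_id": p.pair[1],
                "ensemble_score": p.ensemble_score,
                "is_similar": int(p.is_similar),
            }
            for p in predictions
        ],
        columns=["partner_id", "metabolite_id", "ensemble_score", "is_similar"],
    )


def transfers_to_frame(transfers: list[TransferredPhenotype]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "natural_product_id": t.natural_product_id,
                "phenotype_term": t.phenotype_term,
                "source_metabolite_ids": ",".join(sorted(t.source_metabolite_ids)),
            }
            for t in transfers
        ],
        columns=["natural_product_id", "phenotype_term", "source_metabolite_ids"],
    )
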