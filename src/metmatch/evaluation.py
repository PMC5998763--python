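"""Evaluation battery: feature ablation, indication precision/recall and
literature co-occurrence statistics."""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .data_io import DataError, PairLabelSet, PhenotypeAnnotation, _read_tsv
from .pairing_model import (
    TrainingConfig,
    TransferredPhenotype,
    predict_pairs,
    sample_training_sets,
    train_ensemble,
    transfer_phenotypes,
)
from .similarity_features import FEATURE_COLUMNS

logger = logging.getLogger(__name__)

FEATURE_SUBSETS = {
    "structure": ("s_structure",),
    "target": ("s_target",),
    "phenotype": ("s_phenotype",),
    "all": tuple(FEATURE_COLUMNS),
}


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the rank-sum formulation, midranks for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUROC requires both classes")
    ranks = scipy.stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# ablation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AblationSpec:
    feature_subsets: tuple[str, ...] = ("structure", "target", "phenotype", "all")
    test_mode: str = "random_negatives"  # or "structure_filtered"
    tanimoto_floor: float = 0.77
    test_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.tanimoto_floor <= 1.0:
            raise DataError("tanimoto_floor must be in [0, 1]")
        unknown = [s for s in self.feature_subsets if s not in FEATURE_SUBSETS]
        if unknown:
            raise DataError(f"unknown feature subsets: {unknown}")
        if self.test_mode not in ("random_negatives", "structure_filtered"):
            raise DataError(f"unknown test mode {self.test_mode!r}")


def _holdout_split(
    features: pd.DataFrame,
    labels: PairLabelSet,
    spec: AblationSpec,
    rng: np.random.Generator,
):
    """Test positives + mode-specific test negatives; training pairs exclude both."""
    positives = sorted(labels.positives)
    n_test = max(1, int(round(spec.test_fraction * len(positives))))
    test_pos_idx = rng.choice(len(positives), size=n_test, replace=False)
    test_pos = {positives[i] for i in sorted(test_pos_idx)}
    train_pos = set(positives) - test_pos

    unlabeled = sorted(labels.unlabeled)
    if spec.test_mode == "structure_filtered":
        struct = dict(
            zip(
                zip(features["partner_id"], features["metabolite_id"]),
                features["s_structure"].to_numpy(dtype=float),
            )
        )
        pool = [
            p
            for p in unlabeled
            if p in struct and np.isfinite(struct[p]) and struct[p] > spec.tanimoto_floor
        ]
        if len(pool) < n_test:
            raise DataError(
                f"structure_filtered test set needs {n_test} negatives with "
                f"s_structure > {spec.tanimoto_floor}, only {len(pool)} qualify"
            )
    else:
        pool = unlabeled
    neg_idx = rng.choice(len(pool), size=n_test, replace=False)
    test_neg = {pool[i] for i in sorted(neg_idx)}

    train_universe = labels.universe - test_pos - test_neg
    train_labels = PairLabelSet(
        positives=frozenset(train_pos), universe=frozenset(train_universe)
    )
    return train_labels, sorted(test_pos), sorted(test_neg)


def run_ablation(
    features: pd.DataFrame,
    labels: PairLabelSet,
    spec: AblationSpec,
    config: TrainingConfig,
) -> pd.DataFrame:
    """AUROC per feature subset on a held-out test set built per test mode.

    Positives are split into train/test with the config seed; test
    negatives are drawn from the unlabeled pool (restricted to pairs above
    the Tanimoto floor in ``structure_filtered`` mode) to match the test
    positive count.  The same split is reused for every subset so the
    comparison is paired.
    """
    rng = np.random.default_rng(config.rng_seed)
    train_labels, test_pos, test_neg = _holdout_split(features, labels, spec, rng)
    test_pairs = test_pos + test_neg
    test_y = np.array([True] * len(test_pos) + [False] * len(test_neg))

    rows = []
    for subset_name in spec.feature_subsets:
        cols = FEATURE_SUBSETS[subset_name]
        sub = features.copy()
        for col in FEATURE_COLUMNS:
            if col not in cols:
                sub[col] = 0.0  # blind the model to excluded features
        training_sets = sample_training_sets(
            train_labels, config.n_resamples, config.rng_seed
        )
        model = train_ensemble(sub, training_sets, config)
        index = {(r.partner_id, r.metabolite_id): i for i, r in enumerate(sub.itertuples(index=False))}
        test_df = sub.iloc[[index[p] for p in test_pairs]].reset_index(drop=True)
        preds = predict_pairs(model, test_df)
        scores = [p.ensemble_score for p in preds]
        rows.append(
            {
                "subset": subset_name,
                "test_mode": spec.test_mode,
                "auroc": auroc(scores, test_y),
                "n_test_pos": len(test_pos),
                "n_test_neg": len(test_neg),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# indication precision / recall
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndicationSet:
    drug_id: str
    indications: frozenset[str]

    def __post_init__(self) -> None:
        if not self.indications:
            raise DataError(f"drug {self.drug_id!r}: empty indication set")


_PUNCT = re.compile(r"[^\w\s]")
_WS = re.compile(r"\s+")


def normalize_term(term: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace."""
    return _WS.sub(" ", _PUNCT.sub(" ", term.lower())).strip()


@dataclass(frozen=True)
class PrecisionRecall:
    precision: float | None  # None when nothing was predicted
    recall: float
    precision_per_drug: float | None
    recall_per_drug: float
    n_predicted_pairs: int
    n_true_pairs: int


def _transfer_pairs(
    transfers: list[TransferredPhenotype], truth_drugs: set[str]
) -> set[tuple[str, str]]:
    return {
        (t.natural_product_id, normalize_term(t.phenotype_term))
        for t in transfers
        if t.natural_product_id in truth_drugs
    }


def indication_precision_recall(
    transferred: list[TransferredPhenotype],
    truth: list[IndicationSet],
    baseline: str = "model",
    rng_seed: int = 0,
    *,
    annotations: list[PhenotypeAnnotation] | None = None,
    natural_product_ids: list[str] | None = None,
    metabolite_ids: list[str] | None = None,
    n_pairs: int | None = None,
) -> PrecisionRecall:
    """Precision/recall of transferred terms against known drug indications.

    Per-pair counting is primary: precision is the fraction of predicted
    (drug, term) pairs that are true indications, recall the fraction of
    true (drug, indication) pairs predicted.  A per-drug "at least one
    indication" variant is reported alongside.  With ``baseline="random"``
    the transfer is recomputed over uniformly random product-metabolite
    pairings of the same cardinality (requires the keyword inputs).
    """
    if baseline not in ("model", "random"):
        raise DataError(f"unknown baseline {baseline!r}")
    if baseline == "random":
        if annotations is None or natural_product_ids is None or metabolite_ids is None:
            raise DataError("random baseline needs annotations and id pools")
        if n_pairs is None:
            n_pairs = sum(1 for _ in transferred)
        rng = np.random.default_rng(rng_seed)
        nps = sorted(natural_product_ids)
        mets = sorted(metabolite_ids)
        all_pairs = [(a, b) for a in nps for b in mets]
        k = min(n_pairs, len(all_pairs))
        idx = rng.choice(len(all_pairs), size=k, replace=False)
        from .pairing_model import PairPrediction

        preds = [
            PairPrediction(pair=all_pairs[i], ensemble_score=1.0, is_similar=True)
            for i in sorted(idx)
        ]
        transferred = transfer_phenotypes(preds, annotations)

    truth_pairs = {
        (t.drug_id, normalize_term(ind)) for t in truth for ind in t.indications
    }
    truth_drugs = {t.drug_id for t in truth}
    predicted = _transfer_pairs(transferred, truth_drugs)

    hits = predicted & truth_pairs
    precision = len(hits) / len(predicted) if predicted else None
    recall = len(hits) / len(truth_pairs) if truth_pairs else 0.0

    pred_by_drug: dict[str, set[str]] = {}
    for d, term in predicted:
        pred_by_drug.setdefault(d, set()).add(term)
    hit_drugs = {d for d, _ in hits}
    precision_per_drug = (
        len(hit_drugs) / len(pred_by_drug) if pred_by_drug else None
    )
    recall_per_drug = len(hit_drugs) / len(truth_drugs) if truth_drugs else 0.0
    return PrecisionRecall(
        precision=precision,
        recall=recall,
        precision_per_drug=precision_per_drug,
        recall_per_drug=recall_per_drug,
        n_predicted_pairs=len(predicted),
        n_true_pairs=len(truth_pairs),
    )


# ---------------------------------------------------------------------------
# literature co-occurrence statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoOccurrenceRecord:
    """Abstract counts for one term pair: co-occurrence and marginals."""

    term_a: str
    term_b: str
    n_c: int
    n_a: int
    n_b: int
    N: int

    def __post_init__(self) -> None:
        if min(self.n_c, self.n_a, self.n_b, self.N) < 0:
            raise DataError(f"({self.term_a}, {self.term_b}): negative count")
        if self.n_c > min(self.n_a, self.n_b):
            raise DataError(
                f"({self.term_a}, {self.term_b}): n_c={self.n_c} exceeds a marginal"
            )
        if self.n_a + self.n_b - self.n_c > self.N:
            raise DataError(
                f"({self.term_a}, {self.term_b}): union of abstracts exceeds N"
            )


def jaccard_index(rec: CoOccurrenceRecord) -> float:
    """JI = n_c / (n_a + n_b - n_c), with 0/0 defined as 0."""
    denom = rec.n_a + rec.n_b - rec.n_c
    if denom == 0:
        return 0.0
    return rec.n_c / denom


def fisher_exact(rec: CoOccurrenceRecord) -> float:
    """Two-sided hypergeometric p-value for the 2x2 co-occurrence table."""
    table = [
        [rec.n_c, rec.n_a - rec.n_c],
        [rec.n_b - rec.n_c, rec.N - rec.n_a - rec.n_b + rec.n_c],
    ]
    if min(min(row) for row in table) < 0:
        raise DataError(f"({rec.term_a}, {rec.term_b}): negative contingency cell")
    return float(scipy.stats.fisher_exact(table, alternative="two-sided")[1])


@dataclass(frozen=True)
class LiteratureReport:
    mean_cooccurrence: float
    mean_jaccard: float
    n_fisher_significant: int
    random_mean_cooccurrence: float
    random_mean_jaccard: float
    random_n_fisher_significant: int
    mannwhitney_p_cooccurrence: float
    mannwhitney_p_jaccard: float
    alpha: float
    n_records: int
    n_random_records: int


def _mannwhitney(x, y) -> float:
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    use_exact = (
        max(len(x), len(y)) <= 20 and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    )
    method = "exact" if use_exact else "asymptotic"
    return float(
        scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def literature_report(
    records: list[CoOccurrenceRecord],
    random_records: list[CoOccurrenceRecord],
    alpha: float = 0.001,
) -> LiteratureReport:
    """Summary statistics comparing result-pair counts with random pairs.

    Means of co-occurrence and Jaccard index per list, Fisher-significant
    counts at ``alpha``, and two-sided Mann-Whitney U p-values comparing
    the two lists on co-occurrence and Jaccard separately.
    """
    if not records or not random_records:
        raise DataError("both record lists must be non-empty")
    nc = [r.n_c for r in records]
    nc_rand = [r.n_c for r in random_records]
    ji = [jaccard_index(r) for r in records]
    ji_rand = [jaccard_index(r) for r in random_records]
    return LiteratureReport(
        mean_cooccurrence=float(np.mean(nc)),
        mean_jaccard=float(np.mean(ji)),
        n_fisher_significant=sum(fisher_exact(r) < alpha for r in records),
        random_mean_cooccurrence=float(np.mean(nc_rand)),
        random_mean_jaccard=float(np.mean(ji_rand)),
        random_n_fisher_significant=sum(fisher_exact(r) < alpha for r in random_records),
        mannwhitney_p_cooccurrence=_mannwhitney(nc, nc_rand),
        mannwhitney_p_jaccard=_mannwhitney(ji, ji_rand),
        alpha=alpha,
        n_records=len(records),
        n_random_records=len(random_records),
    )


# ---------------------------------------------------------------------------
# readers for evaluation inputs
# ---------------------------------------------------------------------------


def read_indications(path: str | Path) -> list[IndicationSet]:
    """Read known drug indications (columns drug_id, indication)."""
    df = _read_tsv(path, ["drug_id", "indication"])
    by_drug: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        by_drug.setdefault(row.drug_id, set()).add(row.indication)
    return [
        IndicationSet(drug_id=d, indications=frozenset(inds))
        for d, inds in sorted(by_drug.items())
    ]


def read_cooccurrence(path: str | Path) -> list[CoOccurrenceRecord]:
    """Read precomputed literature counts (term_a, term_b, n_c, n_a, n_b, N)."""
    df = _read_tsv(path, ["term_a", "term_b", "n_c", "n_a", "n_b", "N"])
    return [
        CoOccurrenceRecord(
            term_a=row.term_a,
            term_b=row.term_b,
            n_c=int(row.n_c),
            n_a=int(row.n_a),
            n_b=int(row.n_b),
            N=int(row.N),
        )
        for row in df.itertuples(index=False)
    ]


def write_cooccurrence(records: list[CoOccurrenceRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "term_a": r.term_a,
                "term_b": r.term_b,
                "n_c": r.n_c,
                "n_a": r.n_a,
                "n_b": r.n_b,
                "N": r.N,
            }
            for r in records
        ],
        columns=["term_a", "term_b", "n_c", "n_a", "n_b", "N"],
    ).to_csv(path, sep="\t", index=False)


def write_indications(truth: list[IndicationSet], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"drug_id": t.drug_id, "indication": ind}
            for t in truth
            for ind in sorted(t.indications)
        ],
        columns=["drug_id", "indication"],
    ).to_csv(path, sep="\t", index=False)
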