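"""Hierarchical evaluation: E/OP/IA/IM, example-based metrics, CV harness.

Predicted (PE) and true (TE) labels — EC numbers of any depth, or Non-enzyme —
are compared into four exhaustive categories:

* E  (Equality): PE identical to TE, or both Non-enzyme;
* OP (Overprediction): at least one assigned digit of PE contradicts TE, or
  an enzyme predicted where TE is Non-enzyme;
* IA (Insufficient Annotation): PE correct but shallower than TE, or a
  Non-enzyme prediction where TE is an enzyme — incomplete yet never wrong,
  so IA adds coverage without adding error;
* IM (Improvement): PE extends TE, i.e. TE is the parent family of PE.

The example-based precision/recall used for multi-level comparison decomposes
every enzyme label into its four per-level renderings (``1.1.-.-`` becomes
``1``, ``1.1``, ``1.1.-``, ``1.1.-.-``; Non-enzyme stays a singleton) and
averages per-protein set overlaps:

    precision = (1/m) sum_i |TE_i ∩ PE_i| / |PE_i|
    recall    = (1/m) sum_i |TE_i ∩ PE_i| / |TE_i|

Per-level accuracy counts a prediction correct at level k only when all of its
first k digits are assigned and match the truth.
"""

from __future__ import annotations

import enum
import logging
import random
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple, Union

from .core import (
    DomSignError,
    ECNumber,
    PredictionResult,
    ProteinRecord,
    Status,
    ec_prefix,
)
from .predict import EngineConfig, predict_batch
from .training import build_level_model, build_specific_ds, ingest_training, LEVELS

logger = logging.getLogger(__name__)

NON_ENZYME_LABEL = "Non-enzyme"

#: A comparison label: an EC number, or None for Non-enzyme.
Label = Optional[ECNumber]


class Category(enum.Enum):
    E = "E"
    OP = "OP"
    IA = "IA"
    IM = "IM"


@dataclass(frozen=True)
class ComparisonOutcome:
    category: Category
    pe: Label
    te: Label


def prediction_label(result: Union[PredictionResult, Label]) -> Label:
    """Collapse a prediction to its comparison label.

    NO_DOMAIN, NON_ENZYME and UNRESOLVED_ENZYME all count as a Non-enzyme
    prediction: none of them assigns any EC digit.
    """
    if isinstance(result, PredictionResult):
        return result.ec if result.status is Status.ANNOTATED else None
    return result


def classify(pe: Union[PredictionResult, Label], te: Label) -> ComparisonOutcome:
    """Classify one (prediction, truth) pair into E/OP/IA/IM.

    Total over all inputs: exactly one category applies to every pair.
    """
    pe_label = prediction_label(pe)
    if te is None:
        cat = Category.E if pe_label is None else Category.OP
        return ComparisonOutcome(cat, pe_label, te)
    if pe_label is None:
        return ComparisonOutcome(Category.IA, pe_label, te)
    common = min(pe_label.depth, te.depth)
    if pe_label.tokens[:common] != te.tokens[:common]:
        cat = Category.OP
    elif pe_label.depth == te.depth:
        cat = Category.E
    elif pe_label.depth < te.depth:
        cat = Category.IA
    else:
        cat = Category.IM
    return ComparisonOutcome(cat, pe_label, te)


def decompose(label: Label) -> FrozenSet[str]:
    """Per-level label set: 4 dash-truncated renderings, or {Non-enzyme}."""
    if label is None:
        return frozenset({NON_ENZYME_LABEL})
    return frozenset(label.partial(level) for level in LEVELS)


def example_metrics(
    pairs: Sequence[Tuple[Union[PredictionResult, Label], Label]],
) -> Tuple[float, float]:
    """Example-based precision and recall over (PE, TE) pairs."""
    if not pairs:
        raise DomSignError("example-based metrics need at least one (PE, TE) pair")
    precision = Fraction(0)
    recall = Fraction(0)
    for pe, te in pairs:
        pe_set = decompose(prediction_label(pe))
        te_set = decompose(te)
        overlap = len(pe_set & te_set)
        precision += Fraction(overlap, len(pe_set))
        recall += Fraction(overlap, len(te_set))
    m = len(pairs)
    return float(precision / m), float(recall / m)


def accuracy_at_level(
    pairs: Sequence[Tuple[Union[PredictionResult, Label], Label]], level: int
) -> float:
    """Fraction of completely correct annotations at one EC hierarchy level.

    Only pairs whose truth is annotated to at least ``level`` are eligible; a
    prediction shallower than ``level`` counts as incorrect.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be 1-4, got {level}")
    eligible = 0
    correct = 0
    for pe, te in pairs:
        if te is None or te.depth < level:
            continue
        eligible += 1
        pe_label = prediction_label(pe)
        if (
            pe_label is not None
            and pe_label.depth >= level
            and pe_label.tokens[:level] == te.tokens[:level]
        ):
            correct += 1
    if eligible == 0:
        raise DomSignError(f"no truth labels annotated to level {level}")
    return correct / eligible


def filter_min_subsubfamily(
    records: Iterable[ProteinRecord], min_members: int = 50
) -> List[ProteinRecord]:
    """Drop enzymes from sub-subfamilies (level-3 prefixes) below a size floor.

    Sub-subfamilies with *fewer than* ``min_members`` members in the input are
    removed (a family of exactly ``min_members`` stays).  Records that carry
    no level-3 prefix are untouched.
    """
    records = list(records)
    counts: Counter = Counter()
    for rec in records:
        if rec.ec is not None and rec.ec.depth >= 3:
            counts[ec_prefix(rec.ec, 3)] += 1
    out = []
    for rec in records:
        if rec.ec is not None and rec.ec.depth >= 3:
            if counts[ec_prefix(rec.ec, 3)] < min_members:
                continue
        out.append(rec)
    return out


@dataclass
class FoldResult:
    """Classification tallies for one cross-validation fold."""

    fold: int
    n: int
    categories: Counter = field(default_factory=Counter)
    statuses: Counter = field(default_factory=Counter)


@dataclass
class CVReport:
    """Pooled cross-validation results.

    Fractions are over all classified (prediction, truth) pairs and sum to 1.
    ``depth_distribution`` counts annotated depths 1-4 plus the non-annotated
    statuses.  Per-level accuracy is restricted to enzyme truths annotated to
    that level and may be absent for levels with no eligible pair.
    """

    k: int
    seed: int
    threshold: Fraction
    folds: List[FoldResult]
    categories: Counter
    depth_distribution: Counter
    precision: float
    recall: float
    accuracy_by_level: Dict[int, float]
    n_classified: int
    skipped_folds: int = 0

    @property
    def fractions(self) -> Dict[str, float]:
        total = sum(self.categories.values())
        return {c.value: self.categories.get(c, 0) / total for c in Category}


def _fold_indices(n: int, k: int, seed: int) -> List[List[int]]:
    """Uniform random partition into k folds of size floor/ceil(n/k)."""
    rng = random.Random(seed)
    perm = list(range(n))
    rng.shuffle(perm)
    base, extra = divmod(n, k)
    folds = []
    start = 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        folds.append(perm[start : start + size])
        start += size
    return folds


def cross_validate(
    records: Sequence[ProteinRecord],
    nonenzyme_records: Sequence[ProteinRecord] = (),
    k: int = 10,
    threshold: Union[Fraction, float, str] = Fraction(4, 5),
    seed: int = 0,
    config: Optional[EngineConfig] = None,
) -> CVReport:
    """k-fold cross-validation of the full train/predict/classify chain.

    Records are shuffled with ``seed`` and split into k near-equal folds; each
    fold is predicted by models — including the specific-enzyme-DS set —
    rebuilt from the remaining folds only.  ``nonenzyme_records`` is the
    reliable non-enzyme corpus used for the specific-DS subtraction (its DSs
    are removed whole, not folded).  Multi-EC truths are rejected: the
    classification scheme is defined for single or no EC numbers.
    """
    records = list(records)
    if k < 2:
        raise ValueError(f"k must be at least 2, got {k}")
    if k > len(records):
        raise ValueError(f"k={k} exceeds the {len(records)} records available")
    for rec in records:
        if rec.multi_ec:
            raise DomSignError(
                f"record {rec.id} has multiple EC numbers; pre-filter the corpus "
                "before cross-validation"
            )
    if config is None:
        config = EngineConfig(threshold=Fraction(threshold))
    folds = _fold_indices(len(records), k, seed)

    fold_results: List[FoldResult] = []
    categories: Counter = Counter()
    depth_distribution: Counter = Counter()
    pairs: List[Tuple[PredictionResult, Label]] = []
    skipped = 0
    for fold_no, test_idx in enumerate(folds):
        test_set = set(test_idx)
        train_records = [rec for i, rec in enumerate(records) if i not in test_set]
        test_records = [records[i] for i in test_idx]
        try:
            trainable = ingest_training(train_records)
        except DomSignError:
            logger.warning("fold %d: no trainable enzymes; fold skipped", fold_no)
            skipped += 1
            continue
        models = {level: build_level_model(trainable, level) for level in LEVELS}
        specific = build_specific_ds(trainable, nonenzyme_records)
        results = predict_batch(test_records, models, specific, config)
        fold_res = FoldResult(fold=fold_no, n=len(test_records))
        for rec, res in zip(test_records, results):
            outcome = classify(res, rec.ec)
            fold_res.categories[outcome.category] += 1
            fold_res.statuses[res.status] += 1
            categories[outcome.category] += 1
            if res.status is Status.ANNOTATED:
                depth_distribution[res.ec.depth] += 1
            else:
                depth_distribution[res.status.value] += 1
            pairs.append((res, rec.ec))
        fold_results.append(fold_res)

    if not pairs:
        raise DomSignError("cross-validation produced no classified pairs")
    precision, recall = example_metrics(pairs)
    accuracy_by_level: Dict[int, float] = {}
    for level in LEVELS:
        try:
            accuracy_by_level[level] = accuracy_at_level(pairs, level)
        except DomSignError:
            pass
    return CVReport(
        k=k,
        seed=seed,
        threshold=config.threshold,
        folds=fold_results,
        categories=categories,
        depth_distribution=depth_distribution,
        precision=precision,
        recall=recall,
        accuracy_by_level=accuracy_by_level,
        n_classified=len(pairs),
        skipped_folds=skipped,
    )


def evaluate_predictions(
    results: Sequence[PredictionResult], truth: Sequence[ProteinRecord]
) -> Dict[str, object]:
    """Compare a prediction file with a gold standard (joined on protein id)."""
    truth_by_id = {rec.id: rec for rec in truth}
    pairs: List[Tuple[PredictionResult, Label]] = []
    categories: Counter = Counter()
    for res in results:
        rec = truth_by_id.get(res.id)
        if rec is None:
            raise DomSignError(f"prediction for unknown protein {res.id}")
        if rec.multi_ec:
            raise DomSignError(
                f"truth record {rec.id} has multiple EC numbers; pre-filter first"
            )
        outcome = classify(res, rec.ec)
        categories[outcome.category] += 1
        pairs.append((res, rec.ec))
    if not pairs:
        raise DomSignError("no (prediction, truth) pairs to evaluate")
    precision, recall = example_metrics(pairs)
    total = sum(categories.values())
    report: Dict[str, object] = {
        "n": total,
        "precision": precision,
        "recall": recall,
    }
    for cat in Category:
        report[f"count_{cat.value}"] = categories.get(cat, 0)
        report[f"fraction_{cat.value}"] = categories.get(cat, 0) / total
    for level in LEVELS:
        try:
            report[f"accuracy_level_{level}"] = accuracy_at_level(pairs, level)
        except DomSignError:
            pass
    return report
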