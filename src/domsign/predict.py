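"""Top-down annotation engine.

A query protein is first gated by the specific-enzyme-DS set: no DS means
NO_DOMAIN, a DS outside the set means NON_ENZYME.  A candidate then descends
the four EC levels.  At level k the engine picks the best subgroup of the
query's DS group among those *extending* the digits already assigned at level
k-1 (level 1 is unrestricted), with the subgroup's abundance within the whole
group as its specificity.  The descent stops the first time no subgroup exists
or the specificity drops below the threshold; the digits assigned so far are
the output, their specificities the per-level confidence scores.  A candidate
that fails already at level 1 is reported UNRESOLVED_ENZYME (``EC = -.-.-.-``).

Because each level-(k+1) subgroup is nested inside its level-k parent and all
abundances share the group size as denominator, confidences are guaranteed
non-increasing down the levels.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Optional

from .core import (
    DomainSignature,
    PredictionResult,
    ProteinRecord,
    Status,
)
from .training import LEVELS, LevelModel, SpecificDSSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EngineConfig:
    """Prediction-time knobs.

    threshold
        Specificity threshold in [0, 1]; descent stops when a DS-EC pair's
        specificity falls below it (a value exactly equal passes).  0.80 is
        the default operating point: stricter thresholds buy precision at the
        cost of annotation depth, looser ones the reverse.
    merge_unresolved
        Report UNRESOLVED_ENZYME as NON_ENZYME.
    conditioned
        Restrict level-k candidates to subgroups extending the level-(k-1)
        assignment so the output is a single EC lineage (default).  When off,
        each level's unconditioned dominant is used and the descent truncates
        at the first inconsistency with the emitted prefix.
    """

    threshold: Fraction = Fraction(4, 5)
    merge_unresolved: bool = False
    conditioned: bool = True

    def __post_init__(self) -> None:
        t = Fraction(self.threshold)
        if not 0 <= t <= 1:
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")
        object.__setattr__(self, "threshold", t)


def predict_one(
    protein_id: str,
    signature: Optional[DomainSignature],
    models: Mapping[int, LevelModel],
    specific_ds: SpecificDSSet,
    config: EngineConfig = EngineConfig(),
) -> PredictionResult:
    """Annotate one query protein from its domain signature."""
    if signature is None:
        return PredictionResult(id=protein_id, status=Status.NO_DOMAIN)
    if signature not in specific_ds:
        return PredictionResult(id=protein_id, status=Status.NON_ENZYME)

    digits: Optional = None
    confidences: List[Fraction] = []
    for level in LEVELS:
        model = models.get(level)
        if model is None:
            break
        if config.conditioned:
            entry = model.best_extending(signature, digits)
        else:
            entry = model.dominant(signature)
            if entry is not None and digits is not None:
                if entry.ec.tokens[: digits.depth] != digits.tokens:
                    break  # dominant contradicts the emitted prefix: truncate
        if entry is None or entry.specificity < config.threshold:
            break
        digits = entry.ec
        confidences.append(entry.specificity)

    if digits is None:
        if models.get(1) is not None and models[1].groups.get(signature) is None:
            logger.warning(
                "DS %s passed the specific-DS filter but has no level-1 model entry",
                signature.render(),
            )
        status = Status.NON_ENZYME if config.merge_unresolved else Status.UNRESOLVED_ENZYME
        return PredictionResult(id=protein_id, status=status)
    return PredictionResult(
        id=protein_id, status=Status.ANNOTATED, ec=digits, confidences=tuple(confidences)
    )


def predict_batch(
    records: Iterable[ProteinRecord],
    models: Mapping[int, LevelModel],
    specific_ds: SpecificDSSet,
    config: EngineConfig = EngineConfig(),
) -> List[PredictionResult]:
    """Order-preserving elementwise prediction with a status summary log."""
    results = [
        predict_one(rec.id, rec.signature, models, specific_ds, config) for rec in records
    ]
    summary = Counter(res.status.value for res in results)
    logger.info("prediction summary: %s", dict(summary))
    return results
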