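"""Model training: per-level DS -> EC associations and the specific-enzyme-DS set.

Training proteins are grouped by domain signature.  Within each group,
subgroups share an EC prefix at the model's level; the *specificity* of a
DS-EC pair is the abundance of that subgroup within its group,

    A(DS_i, EC_j) = N(DS_i, EC_j) / N(DS_i),

kept as an exact rational so that threshold comparisons at printed values such
as 0.80 or 0.99 are never decided by floating-point drift.  Four models are
built, one per EC hierarchy level; a model at level *k* counts proteins by
their first *k* EC digits.

The specific-enzyme-DS set gates enzyme-candidate selection: it is the set of
enzyme-derived DSs minus every DS also observed in reliably non-enzymatic
proteins, where "reliably non-enzymatic" means the protein has no EC number
and its description/keyword/cross-reference text contains none of nine terms
that hint at catalytic activity or annotation uncertainty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

from .core import (
    DomSignError,
    DomainSignature,
    ECNumber,
    ProteinRecord,
    ec_prefix,
    ec_sort_key,
)
from .io import FlatFileEntry

logger = logging.getLogger(__name__)

#: Terms whose presence in the annotation text disqualifies an EC-less protein
#: from the reliable non-enzyme set (case-insensitive substring match; "ase"
#: deliberately matches e.g. "synthase").
NONENZYME_EXCLUSION_TERMS: Tuple[str, ...] = (
    "iron sulfur",
    "uncharacterized",
    "biosynthesis",
    "ferredoxin",
    "ase",
    "enzyme",
    "hypothetic",
    "putative",
    "predicted",
)

LEVELS = (1, 2, 3, 4)


@dataclass(frozen=True)
class ModelEntry:
    """Dominant subgroup of one DS group at one level."""

    ec: ECNumber
    specificity: Fraction
    group_size: int


@dataclass
class DSGroup:
    """All training proteins sharing one DS, split into EC-prefix subgroups."""

    signature: DomainSignature
    subgroup_counts: Dict[ECNumber, int] = field(default_factory=dict)

    @property
    def member_count(self) -> int:
        return sum(self.subgroup_counts.values())

    def dominant(self) -> Tuple[ECNumber, int]:
        """Largest subgroup; ties broken by smallest EC prefix (numeric-aware)."""
        return min(
            self.subgroup_counts.items(), key=lambda kv: (-kv[1], ec_sort_key(kv[0]))
        )


@dataclass
class LevelModel:
    """Trained per-level predictor: DS -> EC-prefix subgroup counts.

    The full subgroup table is retained (not only the dominant pair) because
    prediction restricts level-k candidates to subgroups extending the digits
    already assigned at level k-1.
    """

    level: int
    groups: Dict[DomainSignature, DSGroup] = field(default_factory=dict)

    @property
    def entries(self) -> Dict[DomainSignature, ModelEntry]:
        """Spec view: DS -> (dominant EC prefix, specificity, group size)."""
        out = {}
        for ds, group in self.groups.items():
            ec, count = group.dominant()
            out[ds] = ModelEntry(ec, Fraction(count, group.member_count), group.member_count)
        return out

    def dominant(self, ds: DomainSignature) -> Optional[ModelEntry]:
        group = self.groups.get(ds)
        if group is None:
            return None
        ec, count = group.dominant()
        return ModelEntry(ec, Fraction(count, group.member_count), group.member_count)

    def best_extending(
        self, ds: DomainSignature, prefix: Optional[ECNumber]
    ) -> Optional[ModelEntry]:
        """Dominant subgroup among those whose digits extend ``prefix``.

        Specificity is still the abundance within the whole DS group, so the
        returned value can never exceed the parent subgroup's abundance.
        ``prefix=None`` places no restriction (level 1).
        """
        group = self.groups.get(ds)
        if group is None:
            return None
        if prefix is None:
            candidates = group.subgroup_counts
        else:
            candidates = {
                ec: n
                for ec, n in group.subgroup_counts.items()
                if ec.tokens[: prefix.depth] == prefix.tokens
            }
        if not candidates:
            return None
        ec, count = min(
            candidates.items(), key=lambda kv: (-kv[1], ec_sort_key(kv[0]))
        )
        return ModelEntry(ec, Fraction(count, group.member_count), group.member_count)


@dataclass(frozen=True)
class SpecificDSSet:
    """Enzyme-derived DSs not observed in reliable non-enzymes."""

    signatures: FrozenSet[DomainSignature]

    def __contains__(self, ds: DomainSignature) -> bool:
        return ds in self.signatures

    def __len__(self) -> int:
        return len(self.signatures)


@dataclass
class TrainedModel:
    """Bundle of the four per-level models plus the candidate filter."""

    models: Dict[int, LevelModel]
    specific_ds: SpecificDSSet


def ingest_training(records: Iterable[ProteinRecord]) -> List[ProteinRecord]:
    """Keep only trainable records: single-EC enzymes that carry a DS.

    Non-enzymes, multi-EC proteins and enzymes without domains are dropped;
    the exclusion tallies are logged.  Raises if nothing survives.
    """
    kept: List[ProteinRecord] = []
    dropped = {"non_enzyme": 0, "multi_ec": 0, "no_signature": 0}
    for rec in records:
        if rec.multi_ec:
            dropped["multi_ec"] += 1
        elif rec.ec is None:
            dropped["non_enzyme"] += 1
        elif rec.signature is None:
            dropped["no_signature"] += 1
        else:
            kept.append(rec)
    logger.info(
        "training ingest: kept %d, dropped %d non-enzymes, %d multi-EC, %d without DS",
        len(kept),
        dropped["non_enzyme"],
        dropped["multi_ec"],
        dropped["no_signature"],
    )
    if not kept:
        raise DomSignError("no trainable enzymes (single EC + domain signature) in input")
    return kept


def build_level_model(records: Sequence[ProteinRecord], level: int) -> LevelModel:
    """Count EC prefixes at ``level`` within each DS group.

    Records annotated shallower than ``level`` contribute nothing here: a
    depth-2 EC carries no level-3 information.  A DS whose every member is too
    shallow is absent from this level's table.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be 1-4, got {level}")
    model = LevelModel(level=level)
    for rec in records:
        if rec.ec is None or rec.signature is None or rec.ec.depth < level:
            continue
        prefix = ec_prefix(rec.ec, level)
        group = model.groups.setdefault(rec.signature, DSGroup(rec.signature))
        group.subgroup_counts[prefix] = group.subgroup_counts.get(prefix, 0) + 1
    return model


def filter_reliable_nonenzymes(
    entries: Iterable[FlatFileEntry],
    signatures: Optional[Mapping[str, DomainSignature]] = None,
    terms: Sequence[str] = NONENZYME_EXCLUSION_TERMS,
) -> List[ProteinRecord]:
    """Extract reliably non-enzymatic proteins from EC-less flat-file entries.

    An entry survives only if its concatenated DE/KW/DR text contains none of
    ``terms`` (case-insensitive substring match).  ``signatures`` optionally
    maps protein ids to their DS (from a separate domain-assignment step).
    Entries that still carry an EC number are a caller error.
    """
    lowered = [t.lower() for t in terms]
    out: List[ProteinRecord] = []
    n_dropped = 0
    for entry in entries:
        if entry.ec_list:
            raise DomSignError(
                f"entry {entry.id} has EC annotations; split enzymes out before "
                "the non-enzyme filter"
            )
        text = entry.annotation_text.lower()
        if any(term in text for term in lowered):
            n_dropped += 1
            continue
        sig = signatures.get(entry.id) if signatures else None
        out.append(ProteinRecord(id=entry.id, signature=sig))
    logger.info(
        "non-enzyme filter: kept %d reliable non-enzymes, dropped %d", len(out), n_dropped
    )
    return out


def build_specific_ds(
    enzyme_records: Iterable[ProteinRecord],
    nonenzyme_records: Iterable[ProteinRecord],
) -> SpecificDSSet:
    """Set difference: enzyme DSs minus DSs seen in reliable non-enzymes."""
    enzyme_ds = {r.signature for r in enzyme_records if r.signature is not None}
    nonenzyme_ds = {r.signature for r in nonenzyme_records if r.signature is not None}
    specific = frozenset(enzyme_ds - nonenzyme_ds)
    if enzyme_ds and not specific:
        logger.warning(
            "every enzyme DS also occurs in non-enzymes; specific DS set is empty"
        )
    return SpecificDSSet(specific)


def train(
    records: Iterable[ProteinRecord],
    nonenzyme_records: Iterable[ProteinRecord] = (),
) -> TrainedModel:
    """Full training run: ingest, build the four level models, build the filter.

    Deterministic for fixed input.  With no non-enzyme corpus, every enzyme DS
    is specific.
    """
    trainable = ingest_training(records)
    models = {level: build_level_model(trainable, level) for level in LEVELS}
    specific = build_specific_ds(trainable, nonenzyme_records)
    return TrainedModel(models=models, specific_ds=specific)
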