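"""Synthetic corpora with controlled DS -> EC structure.

The generator emulates the shape of a curated training corpus at the level the
pipeline consumes: groups of proteins sharing a domain signature, each group
carrying a prescribed mixture of four-digit EC numbers (so dominant fractions
— the specificities the trainer must recover — are known exactly), plus an
optional non-enzyme population of which a controlled fraction shares DSs with
the enzyme groups to exercise the specific-DS subtraction.  Accessions come
from a reserved fake namespace (``PFTEST#####``) so synthetic signatures can
never collide with real Pfam families in mixed tests.

It does not simulate amino-acid sequences, HMM scores or annotation text
beyond a benign description; the synthetic layer starts at domain assignments.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .core import (
    DomSignError,
    DomainSignature,
    ECNumber,
    ProteinRecord,
    make_signature,
    parse_ec,
)
from .io import FlatFileEntry


@dataclass(frozen=True)
class GroupSpec:
    """One enzyme DS group: signature size and exact EC composition."""

    ec_counts: Tuple[Tuple[str, int], ...]
    signature_size: int = 2

    def __post_init__(self) -> None:
        if self.signature_size < 1:
            raise DomSignError("signature_size must be >= 1")
        if not self.ec_counts:
            raise DomSignError("group needs at least one (EC, count) pair")
        for ec, count in self.ec_counts:
            parse_ec(ec)
            if count < 1:
                raise DomSignError(f"EC composition counts must be >= 1, got {count}")

    @property
    def member_count(self) -> int:
        return sum(count for _, count in self.ec_counts)


@dataclass(frozen=True)
class NonEnzymeGroupSpec:
    """One non-enzyme DS group."""

    member_count: int
    signature_size: int = 2

    def __post_init__(self) -> None:
        if self.member_count < 1 or self.signature_size < 1:
            raise DomSignError("non-enzyme group counts must be >= 1")


@dataclass(frozen=True)
class CorpusSpec:
    """Full corpus description; deterministic given ``seed``."""

    groups: Tuple[GroupSpec, ...]
    nonenzyme_groups: Tuple[NonEnzymeGroupSpec, ...] = ()
    shared_ds_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_ds_fraction <= 1.0:
            raise DomSignError("shared_ds_fraction must be in [0, 1]")
        if self.shared_ds_fraction > 0 and self.nonenzyme_groups and not self.groups:
            raise DomSignError("cannot share DSs without enzyme groups")

    @classmethod
    def from_dict(cls, data: dict) -> "CorpusSpec":
        groups = tuple(
            GroupSpec(
                ec_counts=tuple((str(ec), int(n)) for ec, n in g["ec_counts"]),
                signature_size=int(g.get("signature_size", 2)),
            )
            for g in data.get("groups", [])
        )
        nonenzyme = tuple(
            NonEnzymeGroupSpec(
                member_count=int(g["member_count"]),
                signature_size=int(g.get("signature_size", 2)),
            )
            for g in data.get("nonenzyme_groups", [])
        )
        return cls(
            groups=groups,
            nonenzyme_groups=nonenzyme,
            shared_ds_fraction=float(data.get("shared_ds_fraction", 0.0)),
            seed=int(data.get("seed", 0)),
        )


def _fake_accessions(start: int, n: int) -> List[str]:
    return [f"PFTEST{start + i:05d}" for i in range(n)]


def generate(spec: CorpusSpec) -> Tuple[List[ProteinRecord], List[ProteinRecord]]:
    """Materialize a corpus: (enzyme records, non-enzyme records).

    Every enzyme group gets a distinct signature and exactly the EC
    composition in its spec.  Of the non-enzyme groups, a
    ``shared_ds_fraction`` share (rounded) is assigned signatures copied from
    randomly chosen enzyme groups; the rest get fresh signatures.  Output is
    byte-identical across runs for a fixed spec.
    """
    rng = random.Random(spec.seed)
    acc_counter = 1
    enzyme_signatures: List[DomainSignature] = []
    enzymes: List[ProteinRecord] = []
    pid = 1
    for group in spec.groups:
        sig = make_signature(_fake_accessions(acc_counter, group.signature_size))
        acc_counter += group.signature_size
        enzyme_signatures.append(sig)
        for ec_str, count in group.ec_counts:
            ec = parse_ec(ec_str)
            for _ in range(count):
                enzymes.append(ProteinRecord(id=f"E{pid:06d}", signature=sig, ec=ec))
                pid += 1

    nonenzymes: List[ProteinRecord] = []
    n_shared = round(spec.shared_ds_fraction * len(spec.nonenzyme_groups))
    shared_idx = set(
        rng.sample(range(len(spec.nonenzyme_groups)), n_shared)
        if spec.nonenzyme_groups
        else []
    )
    npid = 1
    for i, group in enumerate(spec.nonenzyme_groups):
        if i in shared_idx and enzyme_signatures:
            sig = enzyme_signatures[rng.randrange(len(enzyme_signatures))]
        else:
            sig = make_signature(_fake_accessions(acc_counter, group.signature_size))
            acc_counter += group.signature_size
        for _ in range(group.member_count):
            nonenzymes.append(ProteinRecord(id=f"N{npid:06d}", signature=sig))
            npid += 1
    return enzymes, nonenzymes


def nonenzyme_flatfile_entries(records: Sequence[ProteinRecord]) -> List[FlatFileEntry]:
    """Dress non-enzyme records as flat-file entries with benign descriptions.

    The description deliberately contains none of the exclusion terms, so the
    entries pass the reliable-non-enzyme keyword filter unchanged.
    """
    return [
        FlatFileEntry(
            id=rec.id,
            ec_list=(),
            annotation_text=f"Ribosomal protein component {rec.id}",
        )
        for rec in records
    ]


def random_corpus_spec(
    rng: random.Random,
    max_groups: int = 8,
    max_members: int = 80,
    max_nonenzyme_groups: int = 4,
) -> CorpusSpec:
    """Draw a random, structurally valid corpus spec (for property tests)."""
    n_groups = rng.randint(1, max_groups)
    groups = []
    for _ in range(n_groups):
        n_ecs = rng.randint(1, 5)
        ec_counts = []
        seen = set()
        for _ in range(n_ecs):
            ec = ".".join(str(rng.randint(1, 4)) for _ in range(4))
            if ec in seen:
                continue
            seen.add(ec)
            ec_counts.append((ec, rng.randint(1, max_members // n_ecs or 1)))
        groups.append(
            GroupSpec(ec_counts=tuple(ec_counts), signature_size=rng.randint(1, 3))
        )
    nonenzyme = tuple(
        NonEnzymeGroupSpec(member_count=rng.randint(1, 10), signature_size=rng.randint(1, 3))
        for _ in range(rng.randint(0, max_nonenzyme_groups))
    )
    shared = rng.choice([0.0, 0.25, 0.5]) if nonenzyme else 0.0
    return CorpusSpec(
        groups=tuple(groups),
        nonenzyme_groups=nonenzyme,
        shared_ds_fraction=shared,
        seed=rng.randrange(2**31),
    )


def perturb_labels(
    records: Sequence[ProteinRecord], flip_fraction: float, seed: int
) -> List[ProteinRecord]:
    """Flip a fraction of enzyme EC labels to random other ECs from the corpus.

    Simulates annotation error in automatically annotated corpora; useful for
    checking that the overprediction rate responds to label noise.  Flipped
    records keep their signatures; non-enzymes are untouched.
    """
    if not 0.0 <= flip_fraction <= 1.0:
        raise DomSignError(f"flip_fraction must be in [0, 1], got {flip_fraction}")
    rng = random.Random(seed)
    records = list(records)
    enzyme_idx = [i for i, rec in enumerate(records) if rec.ec is not None]
    pool = sorted({rec.ec for rec in records if rec.ec is not None})
    n_flip = round(flip_fraction * len(enzyme_idx))
    flip_set = set(rng.sample(enzyme_idx, n_flip))
    out: List[ProteinRecord] = []
    for i, rec in enumerate(records):
        if i not in flip_set:
            out.append(rec)
            continue
        others = [ec for ec in pool if ec != rec.ec]
        if others:
            new_ec = others[rng.randrange(len(others))]
        else:
            # corpus has a single EC: mutate the serial digit instead
            new_ec = ECNumber(rec.ec.tokens[:-1] + (rec.ec.tokens[-1] + "0",))
        out.append(
            ProteinRecord(id=rec.id, signature=rec.signature, ec=new_ec)
        )
    return out


#: The worked single-DS training group used throughout the documentation: one
#: hundred proteins sharing a DS, with a 90/88/85/43-dominant EC mixture.
WORKED_EXAMPLE_SPEC = CorpusSpec(
    groups=(
        GroupSpec(
            ec_counts=(
                ("1.1.1.1", 43),
                ("1.1.1.2", 42),
                ("1.1.2.1", 3),
                ("1.2.1.1", 2),
                ("2.1.1.1", 10),
            ),
            signature_size=2,
        ),
    ),
)
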