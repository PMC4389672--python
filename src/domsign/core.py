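"""Core domain types: EC numbers, domain signatures, protein records, predictions.

The Enzyme Commission (EC) system classifies catalytic function with four
hierarchical digits (class.subclass.sub-subclass.serial).  Annotations may be
partial: a protein known only to be an oxidoreductase acting on CH-OH groups is
written ``1.1.-.-``.  A protein's *domain signature* (DS) is the deduplicated
set of Pfam-A families detected in its sequence; DomSign transfers EC digits
between proteins that share a DS.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional, Sequence, Tuple


class DomSignError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(DomSignError):
    """Malformed input text (EC strings, tables, flat files, model files)."""


_EC_PREFIX_RE = re.compile(r"^EC[=\s]+", re.IGNORECASE)


@dataclass(frozen=True, order=True)
class ECNumber:
    """A 1-4 level EC number with explicit annotated depth.

    ``tokens`` holds only the annotated levels; unannotated deeper levels are
    rendered as ``-``.  Tokens are opaque strings: ordinary numerals and
    preliminary identifiers such as ``n5`` are both legal, and only token
    equality matters to the annotation algorithm.
    """

    tokens: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.tokens) <= 4:
            raise ParseError(
                f"EC number must have 1-4 annotated levels, got {len(self.tokens)}"
            )
        for tok in self.tokens:
            if not tok or tok == "-":
                raise ParseError(f"EC token may not be empty or '-': {self.tokens!r}")

    @property
    def depth(self) -> int:
        """Number of annotated levels (1-4)."""
        return len(self.tokens)

    def render(self) -> str:
        """Dash-padded four-position rendering, e.g. ``1.1.-.-``."""
        return ".".join(self.tokens + ("-",) * (4 - self.depth))

    def partial(self, level: int) -> str:
        """Rendering truncated to ``level`` positions (used by decomposition).

        A depth-2 number at level 3 renders ``x.x.-``; at level 1 just ``x``.
        """
        if not 1 <= level <= 4:
            raise ValueError(f"level must be 1-4, got {level}")
        parts = [self.tokens[i] if i < self.depth else "-" for i in range(level)]
        return ".".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def parse_ec(text: str) -> ECNumber:
    """Parse an EC string such as ``1.2.3.4``, ``1.2.-.-`` or ``EC 1.2.-.-``.

    Depth is the number of tokens before the first dash; every token after a
    dash must also be a dash.  Raises :class:`ParseError` naming the offending
    string otherwise.
    """
    original = text
    text = _EC_PREFIX_RE.sub("", text.strip()).rstrip(";")
    if not text:
        raise ParseError(f"empty EC string: {original!r}")
    raw = text.split(".")
    if len(raw) > 4:
        raise ParseError(f"EC string has more than 4 levels: {original!r}")
    tokens: list[str] = []
    seen_dash = False
    for tok in raw:
        tok = tok.strip()
        if not tok:
            raise ParseError(f"EC string has an empty level token: {original!r}")
        if tok == "-":
            seen_dash = True
        elif seen_dash:
            raise ParseError(
                f"annotated token after a dash in EC string: {original!r}"
            )
        else:
            tokens.append(tok)
    if not tokens:
        raise ParseError(f"EC string has no annotated digits: {original!r}")
    return ECNumber(tuple(tokens))


def ec_prefix(ec: ECNumber, level: int) -> ECNumber:
    """Truncate ``ec`` to its first ``level`` annotated digits.

    ``level`` may not exceed the annotated depth: a depth-2 number carries no
    level-3 information.
    """
    if not 1 <= level <= 4:
        raise ValueError(f"level must be 1-4, got {level}")
    if level > ec.depth:
        raise DomSignError(
            f"cannot truncate EC {ec.render()} (depth {ec.depth}) to level {level}"
        )
    return ECNumber(ec.tokens[:level])


def ec_sort_key(ec: ECNumber) -> Tuple[Tuple[int, int, str], ...]:
    """Numeric-aware ordering key: ``1.2`` < ``1.10``, numerals before ``n``-tokens."""
    out = []
    for tok in ec.tokens:
        if tok.isdigit():
            out.append((0, int(tok), ""))
        else:
            out.append((1, 0, tok))
    return tuple(out)


@dataclass(frozen=True, order=True)
class DomainSignature:
    """Canonical deduplicated set of Pfam-A accessions for one protein.

    Stored sorted so that equality and hashing are insensitive to the order
    and multiplicity of the input domain hits.
    """

    accessions: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.accessions:
            raise DomSignError("domain signature must have at least one accession")
        if list(self.accessions) != sorted(set(self.accessions)):
            raise DomSignError(
                "domain signature accessions must be unique and sorted; "
                "use make_signature()"
            )

    def render(self) -> str:
        return ";".join(self.accessions)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def make_signature(accessions: Iterable[str]) -> DomainSignature:
    """Build the canonical DS from an arbitrary sequence of accessions.

    Duplicates are collapsed and order discarded, so two proteins whose domain
    hits differ only in recurrence or order share one signature.
    """
    cleaned = sorted({a.strip() for a in accessions if a and a.strip()})
    if not cleaned:
        raise DomSignError("cannot build a domain signature from zero accessions")
    return DomainSignature(tuple(cleaned))


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: identifier, optional DS, optional (single) EC annotation.

    ``multi_ec`` marks proteins whose source listed more than one EC number;
    such records never enter training.
    """

    id: str
    signature: Optional[DomainSignature] = None
    ec: Optional[ECNumber] = None
    multi_ec: bool = False

    @property
    def is_enzyme(self) -> bool:
        return self.ec is not None or self.multi_ec


class Status(enum.Enum):
    """Outcome class of one prediction."""

    NO_DOMAIN = "NO_DOMAIN"
    NON_ENZYME = "NON_ENZYME"
    UNRESOLVED_ENZYME = "UNRESOLVED_ENZYME"
    ANNOTATED = "ANNOTATED"


@dataclass(frozen=True)
class PredictionResult:
    """Prediction for one query protein.

    UNRESOLVED_ENZYME is the ``EC = -.-.-.-`` outcome: the DS passed the
    enzyme-candidate filter but even the first EC digit fell below the
    specificity threshold.  ``confidences`` carries the per-level dominant
    subgroup specificities for each annotated digit and is non-increasing
    across levels.
    """

    id: str
    status: Status
    ec: Optional[ECNumber] = None
    confidences: Tuple[Fraction, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.status is Status.ANNOTATED:
            if self.ec is None or self.ec.depth != len(self.confidences):
                raise DomSignError(
                    f"annotated result for {self.id} must carry one confidence "
                    "per EC digit"
                )
            if any(
                self.confidences[i] < self.confidences[i + 1]
                for i in range(len(self.confidences) - 1)
            ):
                raise DomSignError(
                    f"confidences must be non-increasing across levels: "
                    f"{self.confidences}"
                )
        else:
            if self.ec is not None or self.confidences:
                raise DomSignError(
                    f"non-annotated result for {self.id} may not carry EC/confidences"
                )

    @property
    def predicted_enzyme(self) -> bool:
        return self.status is Status.ANNOTATED
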