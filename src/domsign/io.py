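"""Readers and writers for every external format the pipeline touches.

Formats:

* HMMER3 per-domain tabular output (``--domtblout``) for domain assignments;
* Swiss-Prot-style flat files (``ID``/``AC``/``DE``/``KW``/``DR`` lines,
  entries terminated by ``//``) for EC extraction and the non-enzyme keyword
  filter — only those five line types are read, everything else is ignored;
* a simple three-column protein table (id, semicolon-joined Pfam accessions,
  EC string) used as the fixture/interchange format;
* a model file holding the four level models plus the specific-enzyme-DS set,
  with specificities stored as exact integer counts so a written model reads
  back bit-identically;
* an annotation TSV for prediction output.

An in-process hmmsearch driver (pyhmmer) applies each Pfam model's trusted
cutoff, mirroring ``hmmsearch --cut_tc`` with defaults otherwise.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, TextIO, Tuple

from .core import (
    DomSignError,
    DomainSignature,
    ECNumber,
    ParseError,
    PredictionResult,
    ProteinRecord,
    Status,
    make_signature,
    parse_ec,
)

logger = logging.getLogger(__name__)

_VERSION_SUFFIX_RE = re.compile(r"\.\d+$")
_EC_TAG_RE = re.compile(r"EC=([^;\s]+)")

#: Minimum column count of a HMMER3 domtblout data row (before the free-text
#: target description).
_DOMTBLOUT_MIN_COLS = 22

MODEL_FORMAT_HEADER = "#domsign-model\t1"


def strip_version(accession: str) -> str:
    """Drop a trailing ``.N`` release suffix: ``PF00001.21`` -> ``PF00001``."""
    return _VERSION_SUFFIX_RE.sub("", accession)


@dataclass(frozen=True)
class DomainHit:
    """One domain row from hmmsearch output."""

    protein_id: str
    pfam_accession: str
    score: Optional[float] = None
    evalue: Optional[float] = None


@dataclass(frozen=True)
class FlatFileEntry:
    """One Swiss-Prot-style entry reduced to what the pipeline uses."""

    id: str
    ec_list: Tuple[str, ...]
    annotation_text: str
    bad_ec: Tuple[str, ...] = ()


def read_domtblout(stream: Iterable[str], query_is_protein: bool = False) -> List[DomainHit]:
    """Parse HMMER3 per-domain tabular output into domain hits.

    Default column mapping assumes Pfam HMMs were searched against a protein
    database (protein id in the target-name column, Pfam accession in the
    query-accession column); ``query_is_protein`` transposes this for the
    opposite search direction.  Version suffixes on Pfam accessions are
    stripped.
    """
    hits: List[DomainHit] = []
    for lineno, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < _DOMTBLOUT_MIN_COLS:
            raise ParseError(
                f"domtblout line {lineno}: expected at least "
                f"{_DOMTBLOUT_MIN_COLS} columns, got {len(cols)}"
            )
        if query_is_protein:
            protein = cols[3]
            accession = cols[1] if cols[1] != "-" else cols[0]
        else:
            protein = cols[0]
            accession = cols[4] if cols[4] != "-" else cols[3]
        try:
            evalue = float(cols[12])
            score = float(cols[13])
        except ValueError as exc:
            raise ParseError(f"domtblout line {lineno}: bad numeric field: {exc}")
        hits.append(
            DomainHit(
                protein_id=protein,
                pfam_accession=strip_version(accession),
                score=score,
                evalue=evalue,
            )
        )
    return hits


def signatures_from_hits(hits: Iterable[DomainHit]) -> Dict[str, DomainSignature]:
    """Collapse domain hits into one DS per protein."""
    by_protein: Dict[str, set] = {}
    for hit in hits:
        by_protein.setdefault(hit.protein_id, set()).add(hit.pfam_accession)
    return {pid: make_signature(accs) for pid, accs in by_protein.items()}


def read_flatfile(stream: Iterable[str]) -> List[FlatFileEntry]:
    """Parse Swiss-Prot-style entries delimited by ``//``.

    The entry id comes from the ID line; EC strings are pulled from ``EC=``
    tags on DE lines (several are allowed — downstream treats >1 as multi-EC);
    the annotation text is the concatenation of all DE, KW and DR line bodies.
    An EC tag that fails structural validation is kept as a raw string on
    ``bad_ec`` rather than aborting the parse.
    """
    entries: List[FlatFileEntry] = []
    entry_id: Optional[str] = None
    saw_lines = False
    ec_list: List[str] = []
    bad_ec: List[str] = []
    text_parts: List[str] = []

    def flush() -> None:
        nonlocal entry_id, saw_lines, ec_list, bad_ec, text_parts
        if not saw_lines:
            return
        if entry_id is None:
            raise ParseError("flat-file entry without an ID line")
        entries.append(
            FlatFileEntry(
                id=entry_id,
                ec_list=tuple(ec_list),
                annotation_text=" ".join(text_parts),
                bad_ec=tuple(bad_ec),
            )
        )
        entry_id, saw_lines = None, False
        ec_list, bad_ec, text_parts = [], [], []

    for line in stream:
        line = line.rstrip("\n")
        if line.startswith("//"):
            flush()
            continue
        if not line.strip():
            continue
        code, _, body = line.partition("   ")
        code = code.strip()
        body = body.strip()
        if code in {"ID", "AC", "DE", "KW", "DR"}:
            saw_lines = True
        if code == "ID":
            entry_id = body.split()[0] if body else None
            if not entry_id:
                raise ParseError("ID line without an identifier")
        elif code in {"DE", "KW", "DR"}:
            text_parts.append(body)
            if code == "DE":
                for raw in _EC_TAG_RE.findall(body):
                    try:
                        parse_ec(raw)
                    except ParseError:
                        logger.warning("entry %s: unparseable EC tag %r", entry_id, raw)
                        bad_ec.append(raw)
                    else:
                        ec_list.append(raw.rstrip(";"))
    flush()
    return entries


def read_protein_table(stream: Iterable[str]) -> List[ProteinRecord]:
    """Read the tab-separated protein table: id, accessions, EC.

    The accession field is semicolon-joined and may be empty (no DS); the EC
    field may be empty or ``-`` (non-enzyme) or hold several semicolon-joined
    EC strings (multi-EC record, excluded from training downstream).
    """
    records: List[ProteinRecord] = []
    seen: set = set()
    for lineno, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"protein table line {lineno}: expected 3 tab-separated columns"
            )
        pid, acc_field, ec_field = fields[0].strip(), fields[1].strip(), fields[2].strip()
        if not pid:
            raise ParseError(f"protein table line {lineno}: empty protein id")
        if pid in seen:
            raise ParseError(f"protein table line {lineno}: duplicate id {pid!r}")
        seen.add(pid)
        signature = None
        if acc_field:
            signature = make_signature(acc_field.split(";"))
        ec = None
        multi = False
        if ec_field and ec_field != "-":
            ec_strings = [e for e in ec_field.split(";") if e.strip()]
            if len(ec_strings) > 1:
                for e in ec_strings:
                    parse_ec(e)  # validate even though the record is untrainable
                multi = True
            else:
                ec = parse_ec(ec_strings[0])
        records.append(ProteinRecord(id=pid, signature=signature, ec=ec, multi_ec=multi))
    return records


def write_protein_table(records: Iterable[ProteinRecord], stream: TextIO) -> None:
    """Inverse of :func:`read_protein_table` for single-EC and non-enzyme records."""
    stream.write("#id\tdomains\tec\n")
    for rec in records:
        acc = rec.signature.render() if rec.signature else ""
        ec = rec.ec.render() if rec.ec else "-"
        stream.write(f"{rec.id}\t{acc}\t{ec}\n")


def write_model(models: Mapping[int, "LevelModel"], specific_ds, stream: TextIO) -> None:
    """Serialize the four level models and the specific-DS set.

    One row per (level, DS, EC-prefix subgroup) with the exact member count
    and group size — abundances are ratios of integers, so the round-trip is
    lossless; a decimal column is included for human readers only.  Specific
    DSs are stored under the pseudo-level ``S``.
    """
    stream.write(MODEL_FORMAT_HEADER + "\n")
    stream.write("#level\tsignature\tec\tcount\tgroup_size\tspecificity\n")
    for level in sorted(models):
        model = models[level]
        for ds in sorted(model.groups):
            group = model.groups[ds]
            size = group.member_count
            for ec in sorted(group.subgroup_counts, key=lambda e: e.tokens):
                n = group.subgroup_counts[ec]
                stream.write(
                    f"{level}\t{ds.render()}\t{ec.render()}\t{n}\t{size}\t{n / size:.6f}\n"
                )
    for ds in sorted(specific_ds.signatures):
        stream.write(f"S\t{ds.render()}\n")


def read_model(stream: Iterable[str]):
    """Read a model file back into (level models, specific-DS set)."""
    from .training import LEVELS, DSGroup, LevelModel, SpecificDSSet

    lines = iter(stream)
    try:
        header = next(lines).rstrip("\n")
    except StopIteration:
        raise ParseError("empty model file")
    if header != MODEL_FORMAT_HEADER:
        raise ParseError(f"unrecognized model file header: {header!r}")
    models = {level: LevelModel(level=level) for level in LEVELS}
    specific: set = set()
    for lineno, line in enumerate(lines, start=2):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        tag = fields[0]
        if tag == "S":
            if len(fields) < 2:
                raise ParseError(f"model file line {lineno}: malformed specific-DS row")
            specific.add(make_signature(fields[1].split(";")))
            continue
        if tag not in {"1", "2", "3", "4"}:
            raise ParseError(f"model file line {lineno}: unknown level {tag!r}")
        if len(fields) < 5:
            raise ParseError(f"model file line {lineno}: truncated model row")
        level = int(tag)
        ds = make_signature(fields[1].split(";"))
        ec = parse_ec(fields[2])
        if ec.depth != level:
            raise ParseError(
                f"model file line {lineno}: EC depth {ec.depth} does not match "
                f"level {level}"
            )
        count = int(fields[3])
        model = models[level]
        group = model.groups.setdefault(ds, DSGroup(ds))
        group.subgroup_counts[ec] = group.subgroup_counts.get(ec, 0) + count
    return models, SpecificDSSet(frozenset(specific))


_STATUS_EC_FIELD = {
    Status.NO_DOMAIN: "-",
    Status.NON_ENZYME: "-",
    Status.UNRESOLVED_ENZYME: "-.-.-.-",
}


def write_annotations(
    results: Iterable[PredictionResult], stream: TextIO, merge_statuses: bool = False
) -> None:
    """Write the annotation TSV: id, status, EC, per-level confidences.

    ``merge_statuses`` folds NO_DOMAIN and UNRESOLVED_ENZYME into NON_ENZYME,
    the merged view used when reporting coverage.
    """
    stream.write("#id\tstatus\tec\tconfidences\n")
    for res in results:
        status = res.status
        if merge_statuses and status in (Status.NO_DOMAIN, Status.UNRESOLVED_ENZYME):
            status = Status.NON_ENZYME
        if res.status is Status.ANNOTATED:
            ec_field = res.ec.render()
            conf_field = ";".join(f"{float(c):.4f}" for c in res.confidences)
        else:
            ec_field = _STATUS_EC_FIELD[status]
            conf_field = ""
        stream.write(f"{res.id}\t{status.value}\t{ec_field}\t{conf_field}\n")


def read_annotations(stream: Iterable[str]) -> List[PredictionResult]:
    """Read an annotation TSV back (confidences as 4-decimal fractions)."""
    results: List[PredictionResult] = []
    for lineno, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"annotation file line {lineno}: truncated row")
        pid, status_str, ec_field = fields[0], fields[1], fields[2]
        conf_field = fields[3] if len(fields) > 3 else ""
        try:
            status = Status(status_str)
        except ValueError:
            raise ParseError(
                f"annotation file line {lineno}: unknown status {status_str!r}"
            )
        if status is Status.ANNOTATED:
            ec = parse_ec(ec_field)
            confs = tuple(
                Fraction(c).limit_denominator(10**4) for c in conf_field.split(";") if c
            )
            results.append(PredictionResult(id=pid, status=status, ec=ec, confidences=confs))
        else:
            results.append(PredictionResult(id=pid, status=status))
    return results


def run_hmmsearch(fasta_path, hmm_path, workdir=None) -> List[DomainHit]:
    """Search Pfam profile HMMs against a protein FASTA, trusted cutoffs applied.

    Runs HMMER in process (pyhmmer) with each model's trusted cutoff as the
    reporting threshold and all other parameters at their defaults, then
    returns one hit per reported domain.  Proteins with no family above its
    trusted cutoff are simply absent (downstream NO_DOMAIN).
    """
    import pyhmmer

    fasta_path = Path(fasta_path)
    hmm_path = Path(hmm_path)
    if not fasta_path.exists():
        raise DomSignError(f"query FASTA not found: {fasta_path}")
    if not hmm_path.exists():
        raise DomSignError(f"profile HMM library not found: {hmm_path}")
    if fasta_path.stat().st_size == 0:
        return []

    with pyhmmer.easel.SequenceFile(str(fasta_path), digital=True) as seq_file:
        sequences = seq_file.read_block()
    if len(sequences) == 0:
        return []
    hits: List[DomainHit] = []
    try:
        with pyhmmer.plan7.HMMFile(str(hmm_path)) as hmm_file:
            def _text(value):
                return value.decode() if isinstance(value, bytes) else value

            for top_hits in pyhmmer.hmmsearch(hmm_file, sequences, bit_cutoffs="trusted"):
                query = top_hits.query
                accession = _text(query.accession) or _text(query.name)
                accession = strip_version(accession)
                for hit in top_hits:
                    if not hit.included:
                        continue
                    for domain in hit.domains:
                        if not domain.included:
                            continue
                        hits.append(
                            DomainHit(
                                protein_id=_text(hit.name),
                                pfam_accession=accession,
                                score=domain.score,
                                evalue=domain.i_evalue,
                            )
                        )
    except pyhmmer.errors.MissingCutoffs as exc:
        raise DomSignError(
            f"profile HMM library {hmm_path} lacks trusted (TC) cutoffs: {exc}"
        )
    return hits


def attach_signatures(
    records: Iterable[ProteinRecord], signatures: Mapping[str, DomainSignature]
) -> List[ProteinRecord]:
    """Return records with signatures filled in from a domain-assignment map."""
    out = []
    for rec in records:
        sig = signatures.get(rec.id, rec.signature)
        out.append(ProteinRecord(id=rec.id, signature=sig, ec=rec.ec, multi_ec=rec.multi_ec))
    return out
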