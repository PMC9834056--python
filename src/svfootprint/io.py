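"""Readers and writers for the formats the pipeline touches.

FASTA genomes, SV call sets (VCF >= 4.1 with breakend/BND records plus
DEL/INS/DUP records) and repeat-class BED tracks.  All readers accept
gzip-compressed files.  Internally every coordinate is 0-based half-open;
VCF positions are converted on read and write, BED is consumed natively.

The breakend ALT grammar (the four bracket shapes ``t[p[``, ``t]p]``,
``]p]t``, ``[p[t``) is parsed here into :class:`BreakendRecord`; its
biological interpretation lives in :mod:`svfootprint.breakends`.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
import pysam
from Bio import SeqIO

from ._seq import SequenceAlphabetError, validate_seq

logger = logging.getLogger(__name__)

__all__ = [
    "Genome",
    "BreakendRecord",
    "IndelRecord",
    "RepeatTrack",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_sv_vcf",
    "write_sv_vcf",
    "read_repeats",
]


class FormatError(ValueError):
    """Malformed input file."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass
class Genome:
    """A named collection of contig sequences (uppercase A/C/G/T/N)."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not name:
                raise FormatError("empty contig name")
            self.contigs[name] = validate_seq(seq)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def __getitem__(self, contig: str) -> str:
        return self.contigs[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def fetch(self, contig: str, start0: int, end0: int) -> str:
        """Substring of ``contig`` in 0-based half-open coordinates.

        Raises :class:`KeyError` for unknown contigs and
        :class:`IndexError` when the window leaves the contig.
        """
        seq = self.contigs[contig]
        if start0 < 0 or end0 > len(seq):
            raise IndexError(
                f"window [{start0},{end0}) outside contig {contig!r} "
                f"of length {len(seq)}"
            )
        return seq[start0:end0]

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}


#: regex for the four breakend ALT shapes; group layout:
#: 1 = sequence before the bracket, 2 = bracket char, 3 = mate contig,
#: 4 = mate position, 5 = sequence after the bracket.
_BND_RE = re.compile(
    r"^([A-Za-z]*)([\[\]])([^\[\]:]+):(\d+)([\[\]])([A-Za-z]*)$"
)


@dataclass
class BreakendRecord:
    """One side of a sequence fusion, as encoded by a VCF BND record."""

    record_id: str
    contig: str
    pos: int  # 1-based position of the REF base, as in the VCF
    ref_base: str
    alt: str
    mate_id: str | None = None
    ci_pos: tuple[int, int] = (0, 0)
    filter_pass: bool = False
    sample_id: str = ""

    def __post_init__(self) -> None:
        shape = parse_breakend_alt(self.alt)
        if self.ci_pos[0] > 0 or self.ci_pos[1] < 0:
            raise FormatError(f"CIPOS {self.ci_pos} does not bracket 0")
        self._shape = shape

    @property
    def pos0(self) -> int:
        """0-based coordinate of the REF base."""
        return self.pos - 1

    @property
    def mate_contig(self) -> str:
        return self._shape.mate_contig

    @property
    def mate_pos(self) -> int:
        return self._shape.mate_pos

    @property
    def insert_seq(self) -> str:
        """Junction-inserted bases: local ALT sequence minus the padding base."""
        return self._shape.insert_seq

    @property
    def shape(self) -> int:
        """Bracket shape class 1..4 (see :mod:`svfootprint.breakends`)."""
        return self._shape.shape


@dataclass(frozen=True)
class _BreakendShape:
    shape: int
    mate_contig: str
    mate_pos: int
    insert_seq: str


def parse_breakend_alt(alt: str) -> _BreakendShape:
    """Decompose a breakend ALT string into shape, mate locus and insert.

    The four shapes are 1: ``t[p[``, 2: ``t]p]``, 3: ``]p]t``, 4: ``[p[t``.
    The single REF padding base (first base of a leading ``t``, last base
    of a trailing ``t``) is stripped from the reported insert.
    """
    m = _BND_RE.match(alt)
    if not m or m.group(2) != m.group(5):
        raise FormatError(f"ALT {alt!r} is not a valid breakend")
    before, bracket, mate_contig, mate_pos, _, after = m.groups()
    if bool(before) == bool(after):
        raise FormatError(f"ALT {alt!r} is not a valid breakend")
    if before:
        shape = 1 if bracket == "[" else 2
        insert = validate_seq(before[1:])
    else:
        shape = 3 if bracket == "]" else 4
        insert = validate_seq(after[:-1])
    return _BreakendShape(shape, mate_contig, int(mate_pos), insert)


@dataclass
class IndelRecord:
    """A deletion, insertion or tandem duplication call.

    ``start``/``end`` are 1-based inclusive bounds of the affected bases;
    for an insertion both equal the base after which the insert occurs.
    """

    kind: str  # deletion | insertion | tandem_duplication
    contig: str
    start: int
    end: int
    filter_pass: bool = False
    sample_id: str = ""
    deleted_seq: str | None = None
    record_id: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "insertion", "tandem_duplication"):
            raise FormatError(f"unknown indel kind {self.kind!r}")
        if self.end < self.start:
            raise FormatError(f"end {self.end} < start {self.start}")
        if self.deleted_seq is not None:
            self.deleted_seq = validate_seq(self.deleted_seq)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def start0(self) -> int:
        return self.start - 1

    @property
    def end0(self) -> int:
        """0-based exclusive end."""
        return self.end

    def fetch_deleted_seq(self, genome: Genome) -> str:
        """Deleted bases, from the record if present else from ``genome``."""
        if self.deleted_seq is not None:
            return self.deleted_seq
        if self.kind != "deletion":
            raise ValueError("deleted_seq only defined for deletions")
        return genome.fetch(self.contig, self.start0, self.end0)


@dataclass
class RepeatTrack:
    """Repeat-class annotation intervals (0-based half-open)."""

    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for contig, start0, end0, cls in self.intervals:
            if end0 <= start0:
                raise FormatError(
                    f"repeat interval [{start0},{end0}) on {contig} is empty"
                )
            if not cls:
                raise FormatError("empty repeat class")
        self.intervals.sort()

    def classes_at(self, contig: str, pos0: int) -> set[str]:
        """Repeat classes whose interval covers the position."""
        return {
            cls
            for c, s, e, cls in self.intervals
            if c == contig and s <= pos0 < e
        }

    def classes_overlapping(self, contig: str, start0: int, end0: int) -> set[str]:
        return {
            cls
            for c, s, e, cls in self.intervals
            if c == contig and s < end0 and e > start0
        }


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> Genome:
    """Read a (possibly gzipped) FASTA file into a :class:`Genome`.

    Lowercase is normalized to uppercase; characters outside A/C/G/T/N are
    rejected with an error naming the offending record.
    """
    contigs: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in contigs:
                raise FormatError(f"duplicate contig name {rec.id!r}")
            if len(rec.seq) == 0:
                raise FormatError(f"empty sequence for contig {rec.id!r}")
            try:
                contigs[rec.id] = validate_seq(str(rec.seq))
            except SequenceAlphabetError as exc:
                raise FormatError(f"contig {rec.id!r}: {exc}") from exc
    if not contigs:
        raise FormatError(f"no FASTA records in {path}")
    return Genome(contigs)


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --------------------------------------------------------------------------
# VCF
# --------------------------------------------------------------------------


def _filter_pass(rec) -> bool:
    # "." (no filter applied) is deliberately treated as non-PASS: only
    # records that affirmatively passed all caller filters are kept.
    keys = list(rec.filter.keys())
    return keys == ["PASS"]


def read_sv_vcf(path, sample_id: str | None = None):
    """Read SV calls from a VCF into breakend and indel records.

    Returns ``(breakends, indels)``.  BND records whose ALT does not match
    any of the four breakend shapes are skipped with a logged warning
    (record-level errors never abort the file).  Symbolic ``<DEL>`` (with
    END) and explicit REF/ALT deletions are both normalized to
    :class:`IndelRecord`.
    """
    vcf = pysam.VariantFile(str(path))
    if sample_id is None:
        samples = list(vcf.header.samples)
        sample_id = samples[0] if samples else Path(path).name.split(".")[0]

    breakends: list[BreakendRecord] = []
    indels: list[IndelRecord] = []
    skipped: list[str] = []
    for rec in vcf:
        alt = rec.alts[0] if rec.alts else None
        if alt is None:
            continue
        svtype = _info_get(rec, "SVTYPE")
        is_bnd = svtype == "BND" or ("[" in alt or "]" in alt)
        try:
            if is_bnd:
                breakends.append(_bnd_from_pysam(rec, alt, sample_id))
            else:
                indel = _indel_from_pysam(rec, alt, svtype, sample_id)
                if indel is not None:
                    indels.append(indel)
        except FormatError as exc:
            skipped.append(f"{rec.id or rec.pos}: {exc}")
    if skipped:
        logger.warning(
            "%s: skipped %d malformed record(s): %s",
            path,
            len(skipped),
            "; ".join(skipped[:10]),
        )
    return breakends, indels


def _info_get(rec, key, default=None):
    # tolerate both absent keys and keys missing from the header
    try:
        return rec.info[key]
    except (KeyError, ValueError):
        return default


def _bnd_from_pysam(rec, alt: str, sample_id: str) -> BreakendRecord:
    mate_id = _info_get(rec, "MATEID")
    if isinstance(mate_id, tuple):
        mate_id = mate_id[0]
    ci = _info_get(rec, "CIPOS")
    ci_pos = (int(ci[0]), int(ci[1])) if ci is not None else (0, 0)
    return BreakendRecord(
        record_id=rec.id or f"{rec.contig}:{rec.pos}",
        contig=rec.contig,
        pos=rec.pos,
        ref_base=(rec.ref or "N")[0],
        alt=alt,
        mate_id=mate_id,
        ci_pos=ci_pos,
        filter_pass=_filter_pass(rec),
        sample_id=sample_id,
    )


def _indel_from_pysam(rec, alt: str, svtype, sample_id: str):
    ref = rec.ref or ""
    rid = rec.id or f"{rec.contig}:{rec.pos}"
    common = dict(
        contig=rec.contig,
        filter_pass=_filter_pass(rec),
        sample_id=sample_id,
        record_id=rid,
    )
    if alt.startswith("<"):
        end = _info_get(rec, "END", rec.stop)
        if alt == "<DEL>":
            return IndelRecord("deletion", start=rec.pos + 1, end=int(end), **common)
        if alt == "<INS>":
            return IndelRecord("insertion", start=rec.pos, end=rec.pos, **common)
        if alt in ("<DUP>", "<DUP:TANDEM>"):
            return IndelRecord(
                "tandem_duplication", start=rec.pos + 1, end=int(end), **common
            )
        return None  # other symbolic alleles are out of scope
    # explicit REF/ALT representation
    ref = validate_seq(ref)
    alt = validate_seq(alt)
    if len(ref) > len(alt) and ref.startswith(alt) and len(alt) >= 1:
        deleted = ref[len(alt) :]
        start = rec.pos + len(alt)
        return IndelRecord(
            "deletion",
            start=start,
            end=start + len(deleted) - 1,
            deleted_seq=deleted,
            **common,
        )
    if len(alt) > len(ref) and alt.startswith(ref):
        return IndelRecord("insertion", start=rec.pos, end=rec.pos, **common)
    return None  # SNVs / complex substitutions are not SVs we consume


_VCF_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=MATEID,Number=.,Type=String,Description="ID of mate breakend">',
    '##INFO=<ID=CIPOS,Number=2,Type=Integer,Description="Confidence interval around POS">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed length of the variant">',
    '##FILTER=<ID=MinQUAL,Description="Did not pass caller quality filters">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]


def write_sv_vcf(
    records: Iterable[BreakendRecord | IndelRecord],
    contig_lengths: dict[str, int],
    path,
    sample_id: str | None = None,
) -> None:
    """Write breakend and indel records to an uncompressed VCF.

    ``contig_lengths`` supplies the header; a record on an unknown contig
    is an error.  The written file round-trips through
    :func:`read_sv_vcf` for every field the pipeline consumes.
    """
    records = list(records)
    header = pysam.VariantHeader()
    for line in _VCF_HEADER_LINES:
        header.add_line(line)
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    if sample_id is None:
        sample_ids = {r.sample_id for r in records if r.sample_id}
        sample_id = sorted(sample_ids)[0] if sample_ids else "SAMPLE"
    header.add_sample(sample_id)

    vcf = pysam.VariantFile(str(path), "w", header=header)
    try:
        for r in records:
            if r.contig not in contig_lengths:
                raise FormatError(f"contig {r.contig!r} absent from header info")
            rec = vcf.new_record()
            rec.contig = r.contig
            if isinstance(r, BreakendRecord):
                if r.mate_contig not in contig_lengths:
                    raise FormatError(
                        f"mate contig {r.mate_contig!r} absent from header info"
                    )
                rec.pos = r.pos
                rec.id = r.record_id
                rec.alleles = (r.ref_base, r.alt)
                rec.info["SVTYPE"] = "BND"
                if r.mate_id is not None:
                    rec.info["MATEID"] = r.mate_id
                if r.ci_pos != (0, 0):
                    rec.info["CIPOS"] = r.ci_pos
                rec.stop = r.pos
            else:
                rec.id = r.record_id or None
                if r.kind == "deletion" and r.deleted_seq is not None:
                    rec.pos = r.start - 1 if r.start > 1 else r.start
                    # explicit representation preserves the deleted bases;
                    # padding base is unknown without the genome, use N
                    pad = "N"
                    rec.alleles = (pad + r.deleted_seq, pad)
                    rec.info["SVTYPE"] = "DEL"
                    rec.info["SVLEN"] = -r.length
                    rec.stop = r.end
                elif r.kind == "deletion":
                    rec.pos = max(r.start - 1, 1)
                    rec.alleles = ("N", "<DEL>")
                    rec.info["SVTYPE"] = "DEL"
                    rec.info["SVLEN"] = -r.length
                    rec.stop = r.end
                elif r.kind == "insertion":
                    rec.pos = r.start
                    rec.alleles = ("N", "<INS>")
                    rec.info["SVTYPE"] = "INS"
                    rec.stop = r.start
                else:
                    rec.pos = max(r.start - 1, 1)
                    rec.alleles = ("N", "<DUP:TANDEM>")
                    rec.info["SVTYPE"] = "DUP"
                    rec.info["SVLEN"] = r.length
                    rec.stop = r.end
            rec.filter.add("PASS" if r.filter_pass else "MinQUAL")
            rec.samples[sample_id]["GT"] = (0, 1)
            vcf.write(rec)
    finally:
        vcf.close()


# --------------------------------------------------------------------------
# BED repeats
# --------------------------------------------------------------------------


def read_repeats(path) -> RepeatTrack:
    """Read a BED4 repeat track (column 4 = repeat class)."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            dtype={0: str},
        )
    except pd.errors.EmptyDataError:
        return RepeatTrack([])
    if df.shape[1] < 4:
        raise FormatError("repeat BED requires 4 columns (class in column 4)")
    intervals = [
        (str(c), int(s), int(e), str(cls))
        for c, s, e, cls in zip(df[0], df[1], df[2], df[3])
    ]
    return RepeatTrack(intervals)


def write_repeats(track: RepeatTrack, path) -> None:
    with open(path, "w") as fh:
        for contig, s, e, cls in track.intervals:
            fh.write(f"{contig}\t{s}\t{e}\t{cls}\n")
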