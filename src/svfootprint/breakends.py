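"""Breakend geometry: mate pairing, the four fusion types, and junction flanks.

A translocation (any inter- or intra-chromosomal fusion) is reported in a
VCF as two mated BND records.  The ALT bracket shape determines how the
two loci are joined:

* shape 1 ``t[p[``   - 3' sense strand fused to 5' sense strand
* shape 2 ``t]p]``   - 3' sense strand fused to 5' anti-sense strand
* shape 3 ``]p]t``   - the shape-1 fusion annotated from its other end
* shape 4 ``[p[t``   - 3' anti-sense strand fused to 5' sense strand

Shape 3 is canonicalized into type 1, leaving three fusion types
{1, 2, 4}.  Each break site carries a *joined side* describing which
piece of the reference enters the fusion product:

* ``left-of``       - sequence ending at the position, sense strand
* ``right-of``      - sequence starting at the position, sense strand
* ``revcomp-left``  - reverse complement of the sequence ending there
* ``revcomp-right`` - reverse complement of the sequence starting there

Flank conventions for the 2w-mers around the junction: positions are
labeled so that 0 is the junction-adjacent base *included* in the fusion
product, +1..+(w-1) are the further included bases, and -1..-w are the
bases beyond the break that are not part of the product.  The left flank
string is stored 5'->3' in fusion orientation with labels
``[+(w-1) .. 0, -1 .. -w]``; the right flank likewise with labels
``[-w .. -1, 0 .. +(w-1)]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp
from .io import BreakendRecord, FormatError, Genome

logger = logging.getLogger(__name__)

__all__ = [
    "BreakSite",
    "Translocation",
    "FlankPair",
    "classify_breakend",
    "pair_mates",
    "canonicalize",
    "extract_flanks",
    "flank_label_positions",
    "LEFT_SIDES",
    "RIGHT_SIDES",
]

#: joined-side values playing the "left partner" role in the fusion product
LEFT_SIDES = ("left-of", "revcomp-right")
#: joined-side values playing the "right partner" role
RIGHT_SIDES = ("right-of", "revcomp-left")


def classify_breakend(alt: str) -> int:
    """Return the bracket shape class 1..4 of a breakend ALT string."""
    from .io import parse_breakend_alt

    return parse_breakend_alt(alt).shape


@dataclass(frozen=True, order=True)
class BreakSite:
    """One break locus with its joined side (0-based position)."""

    contig: str
    pos0: int
    side: str = field(compare=False)

    def __post_init__(self) -> None:
        if self.side not in LEFT_SIDES + RIGHT_SIDES:
            raise ValueError(f"unknown joined side {self.side!r}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.contig, self.pos0)


@dataclass
class Translocation:
    """A canonicalized fusion of two break sites.

    ``break_a`` <= ``break_b`` lexicographically by (contig, pos0); the
    junction roles are carried by each site's ``side``.  ``insert_seq``
    is the inserted sequence read 5'->3' in fusion-product orientation.
    """

    break_a: BreakSite
    break_b: BreakSite
    ttype: int
    insert_seq: str = ""
    ci_a: tuple[int, int] = (0, 0)
    ci_b: tuple[int, int] = (0, 0)
    source_ids: tuple[str, ...] = ()
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.ttype not in (1, 2, 4):
            raise ValueError(f"canonical type must be 1, 2 or 4, got {self.ttype}")
        if self.break_a.key > self.break_b.key:
            raise ValueError("break_a must sort before break_b")

    @property
    def left_site(self) -> BreakSite:
        return self.break_a if self.break_a.side in LEFT_SIDES else self.break_b

    @property
    def right_site(self) -> BreakSite:
        return self.break_b if self.break_a.side in LEFT_SIDES else self.break_a

    @property
    def ci_left(self) -> tuple[int, int]:
        return self.ci_a if self.break_a.side in LEFT_SIDES else self.ci_b

    @property
    def ci_right(self) -> tuple[int, int]:
        return self.ci_b if self.break_a.side in LEFT_SIDES else self.ci_a

    @property
    def key(self):
        return (self.break_a.key, self.break_b.key)


@dataclass
class FlankPair:
    """Oriented 2w-mers around the junction of one translocation."""

    left_flank: str
    right_flank: str
    w: int

    def __post_init__(self) -> None:
        if len(self.left_flank) != 2 * self.w or len(self.right_flank) != 2 * self.w:
            raise ValueError("flanks must have length 2w")

    @property
    def left_labels(self) -> list[int]:
        w = self.w
        return list(range(w - 1, -w - 1, -1))

    @property
    def right_labels(self) -> list[int]:
        w = self.w
        return list(range(-w, w))


# --------------------------------------------------------------------------
# mate pairing
# --------------------------------------------------------------------------


def pair_mates(
    records: list[BreakendRecord],
) -> list[tuple[BreakendRecord, BreakendRecord]]:
    """Resolve BND records into mate pairs.

    Pairing uses MATEID when present; records lacking MATEID are paired
    by reciprocal coordinates within the merged confidence intervals.
    Unpaired singletons are dropped with a logged warning.
    """
    by_id = {r.record_id: r for r in records}
    pairs: list[tuple[BreakendRecord, BreakendRecord]] = []
    used: set[str] = set()
    leftovers: list[BreakendRecord] = []

    for rec in records:
        if rec.record_id in used:
            continue
        mate = by_id.get(rec.mate_id) if rec.mate_id else None
        if mate is not None and mate.record_id not in used:
            pairs.append((rec, mate))
            used.update((rec.record_id, mate.record_id))
        elif rec.mate_id is None:
            leftovers.append(rec)
        else:
            used.add(rec.record_id)
            logger.warning("dropping breakend %s: mate %s not found",
                           rec.record_id, rec.mate_id)

    # coordinate-reciprocal fallback for records without MATEID
    remaining = list(leftovers)
    while remaining:
        rec = remaining.pop(0)
        match_idx = None
        for i, other in enumerate(remaining):
            tol = max(map(abs, rec.ci_pos + other.ci_pos))
            if (
                other.contig == rec.mate_contig
                and rec.contig == other.mate_contig
                and abs(other.pos - rec.mate_pos) <= tol
                and abs(rec.pos - other.mate_pos) <= tol
            ):
                match_idx = i
                break
        if match_idx is None:
            logger.warning("dropping unpaired breakend %s", rec.record_id)
        else:
            pairs.append((rec, remaining.pop(match_idx)))
    return pairs


# --------------------------------------------------------------------------
# canonicalization
# --------------------------------------------------------------------------


def canonicalize(pair: tuple[BreakendRecord, BreakendRecord]) -> Translocation:
    """Turn a mate pair into a canonical :class:`Translocation`.

    Shape-3 records are re-expressed as type 1 viewed from the other
    partner.  For the strand-symmetric types 2 and 4 the view whose left
    partner is lexicographically smallest is chosen, so the result does
    not depend on which mate record was read first.
    """
    r1, r2 = pair
    shapes = {r1.shape, r2.shape}
    if shapes == {1, 3} or shapes == {1} or shapes == {3}:
        return _canonical_type1(r1, r2)
    if shapes == {2}:
        return _canonical_symmetric(r1, r2, ttype=2)
    if shapes == {4}:
        return _canonical_symmetric(r1, r2, ttype=4)
    raise FormatError(
        f"inconsistent mate shapes {sorted(shapes)} for "
        f"({r1.record_id}, {r2.record_id})"
    )


def _ordered(site_x, ci_x, site_y, ci_y, ttype, insert, ids, sample):
    if site_x.key <= site_y.key:
        a, ca, b, cb = site_x, ci_x, site_y, ci_y
    else:
        a, ca, b, cb = site_y, ci_y, site_x, ci_x
    return Translocation(
        break_a=a, break_b=b, ttype=ttype, insert_seq=insert,
        ci_a=ca, ci_b=cb, source_ids=ids, sample_id=sample,
    )


def _canonical_type1(r1: BreakendRecord, r2: BreakendRecord) -> Translocation:
    rec1 = r1 if r1.shape == 1 else r2  # the t[p[ view, if present
    rec3 = r2 if r1.shape == 1 else r1
    if rec1.shape == 1:
        left = BreakSite(rec1.contig, rec1.pos0, "left-of")
        right = BreakSite(rec1.mate_contig, rec1.mate_pos - 1, "right-of")
        ci_l, ci_r = rec1.ci_pos, rec3.ci_pos if rec3.shape == 3 else (0, 0)
        insert = rec1.insert_seq
    else:  # both records shape 3 cannot happen via pair_mates; single shape-3
        left = BreakSite(rec3.mate_contig, rec3.mate_pos - 1, "left-of")
        right = BreakSite(rec3.contig, rec3.pos0, "right-of")
        ci_l, ci_r = (0, 0), rec3.ci_pos
        insert = rec3.insert_seq
    if rec1.shape == 1 and rec3.shape == 3:
        ci_l, ci_r = rec1.ci_pos, rec3.ci_pos
    ids = tuple(sorted({r1.record_id, r2.record_id}))
    return _ordered(left, ci_l, right, ci_r, 1, insert, ids, r1.sample_id)


def _canonical_symmetric(
    r1: BreakendRecord, r2: BreakendRecord, ttype: int
) -> Translocation:
    # choose the record whose own locus takes the lexicographically
    # smaller role-defining position
    if ttype == 2:
        # each record's own locus is a left partner (sequence ending there)
        rec = r1 if (r1.contig, r1.pos0) <= (r2.contig, r2.pos0) else r2
        other = r2 if rec is r1 else r1
        left = BreakSite(rec.contig, rec.pos0, "left-of")
        right = BreakSite(rec.mate_contig, rec.mate_pos - 1, "revcomp-left")
        ci_l, ci_r = rec.ci_pos, other.ci_pos
        insert = rec.insert_seq  # left-partner record is fusion-oriented
    else:
        # each record's own locus is a right partner (sequence starting there)
        rec = r1 if (r1.mate_contig, r1.mate_pos) <= (r2.mate_contig, r2.mate_pos) else r2
        other = r2 if rec is r1 else r1
        left = BreakSite(rec.mate_contig, rec.mate_pos - 1, "revcomp-right")
        right = BreakSite(rec.contig, rec.pos0, "right-of")
        ci_l, ci_r = other.ci_pos, rec.ci_pos
        insert = rec.insert_seq  # right-partner record is fusion-oriented
    ids = tuple(sorted({r1.record_id, r2.record_id}))
    return _ordered(left, ci_l, right, ci_r, ttype, insert, ids, r1.sample_id)


# --------------------------------------------------------------------------
# flank extraction
# --------------------------------------------------------------------------

#: per-side mapping label -> (position offset, complement?) so that
#: genome position = pos0 + sign * label with the tabulated sign.
_SIDE_GEOMETRY = {
    # side: (label_sign, complement)
    "left-of": (-1, False),
    "revcomp-right": (+1, True),
    "right-of": (+1, False),
    "revcomp-left": (-1, True),
}


def flank_label_positions(site: BreakSite, w: int) -> list[tuple[int, int, bool]]:
    """Map each flank label to its genome coordinate and strand.

    Returns ``[(label, pos0, complement), ...]`` in flank-string order.
    This single mapping is used both to extract flanks and, in the
    simulator, to write bases through the junction orientation so that
    planted microhomology is exact by construction.
    """
    sign, comp = _SIDE_GEOMETRY[site.side]
    if site.side in LEFT_SIDES:
        labels = range(w - 1, -w - 1, -1)
    else:
        labels = range(-w, w)
    return [(lab, site.pos0 + sign * lab, comp) for lab in labels]


class FlankUnavailable(Exception):
    """A flank window exceeds its contig bounds."""


def _extract_side(site: BreakSite, genome: Genome, w: int) -> str:
    length = len(genome[site.contig])
    mapping = flank_label_positions(site, w)
    positions = [p for _, p, _ in mapping]
    if min(positions) < 0 or max(positions) >= length:
        raise FlankUnavailable(
            f"window of w={w} around {site.contig}:{site.pos0} "
            f"exceeds contig bounds"
        )
    seq = genome[site.contig]
    comp = mapping[0][2]
    s = "".join(seq[p] for p in positions)
    if comp:
        # positions already run 3'->5', so complementing (without another
        # reversal) yields the 5'->3' reverse complement
        from ._seq import complement

        s = complement(s)
    return s


def extract_flanks(
    t: Translocation, genome: Genome, w: int = 4
) -> FlankPair | None:
    """Extract the oriented junction flanks of a translocation.

    Returns ``None`` (with a logged warning) when either window exceeds
    its contig bounds; such translocations are excluded from grid
    statistics.
    """
    try:
        left = _extract_side(t.left_site, genome, w)
        right = _extract_side(t.right_site, genome, w)
    except FlankUnavailable as exc:
        logger.warning("excluding translocation %s: %s", t.key, exc)
        return None
    return FlankPair(left_flank=left, right_flank=right, w=w)


def valid_position_range(contig_length: int, w: int) -> tuple[int, int]:
    """Inclusive range of break positions with full flank windows.

    Position p admits every side geometry iff w <= p <= length-1-w.
    """
    return (w, contig_length - 1 - w)
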