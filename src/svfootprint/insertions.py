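"""Junction-insertion categorization: none / miscellaneous / templated.

A templated insert — a hallmark of polymerase-theta-mediated end joining —
is an inserted sequence of >= 3 bp whose template occurs within +/- 25 bp
of one of the two break points, in any of the four literal string
transforms: normal, reverse, complement, reverse complement.  Insertions
below 3 bp, or >= 3 bp with no template hit, are miscellaneous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import complement, revcomp
from .breakends import Translocation
from .io import Genome

__all__ = [
    "InsertionCall",
    "TemplateHit",
    "classify_insertion",
    "insertion_distribution",
    "ORIENTATIONS",
]

ORIENTATIONS = ("normal", "reverse", "complement", "reverse_complement")

_TRANSFORMS = {
    "normal": lambda s: s,
    "reverse": lambda s: s[::-1],
    "complement": complement,
    "reverse_complement": revcomp,
}


@dataclass(frozen=True)
class TemplateHit:
    """One exact template match within a break-site window."""

    break_site: str  # "A" or "B"
    offset: int  # start of the hit relative to the breakend base
    orientation: str


@dataclass
class InsertionCall:
    category: str  # no_insertion | miscellaneous | templated
    insert_len: int
    template_hits: list[TemplateHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category == "templated" and (
            self.insert_len < 3 or not self.template_hits
        ):
            raise ValueError("templated calls need insert_len >= 3 and hits")
        if self.category == "no_insertion" and self.insert_len != 0:
            raise ValueError("no_insertion calls must have empty inserts")


def _site_window(genome: Genome, contig: str, pos0: int, window: int):
    """The (2*window + 1)-bp sense-strand window around a breakend base,
    truncated at contig ends.  Returns (sequence, start0)."""
    seq = genome[contig]
    start = max(0, pos0 - window)
    end = min(len(seq), pos0 + window + 1)
    return seq[start:end], start


def classify_insertion(
    t: Translocation, genome: Genome, window: int = 25, minlen: int = 3
) -> InsertionCall:
    """Categorize the junction insertion of one translocation.

    Searches the insert (and its reverse, complement and reverse
    complement) as exact substrings of the +/- ``window`` bp around each
    break site; every hit is recorded.  Category per the footprint
    definition: empty -> no_insertion; >= ``minlen`` bp with >= 1 hit ->
    templated; anything else -> miscellaneous.

    The search depends only on the canonical fusion, not on which mate
    record represented it.
    """
    insert = t.insert_seq
    if not insert:
        return InsertionCall("no_insertion", 0)
    hits: list[TemplateHit] = []
    sites = (("A", t.break_a), ("B", t.break_b))
    for label, site in sites:
        win, win_start = _site_window(genome, site.contig, site.pos0, window)
        for orient in ORIENTATIONS:
            query = _TRANSFORMS[orient](insert)
            start = win.find(query)
            while start != -1:
                if "N" not in win[start : start + len(query)]:
                    hits.append(
                        TemplateHit(label, win_start + start - site.pos0, orient)
                    )
                start = win.find(query, start + 1)
    if len(insert) >= minlen and hits:
        return InsertionCall("templated", len(insert), hits)
    return InsertionCall("miscellaneous", len(insert), hits)


def insertion_distribution(calls: list[InsertionCall]) -> dict[str, float]:
    """Fractions of the three categories (plus ``n``).

    Empty input yields all-zero fractions with ``n`` = 0.
    """
    n = len(calls)
    out = {"no_insertion": 0.0, "miscellaneous": 0.0, "templated": 0.0, "n": n}
    if n == 0:
        return out
    for c in calls:
        out[c.category] += 1
    for k in ("no_insertion", "miscellaneous", "templated"):
        out[k] /= n
    return out
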