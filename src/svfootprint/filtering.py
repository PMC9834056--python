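"""De novo SV filtering cascade.

Reduces raw offspring call sets to de novo, non-repeat, deduplicated
events: caller-PASS only, removal of anything overlapping a parental SV,
repeat-region removal, and breakend deduplication within confidence
intervals.  The stage order is fixed (pass -> parental -> repeat ->
dedupe) and each stage's removals are tallied in a :class:`FilterReport`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .breakends import Translocation, canonicalize, pair_mates
from .io import BreakendRecord, IndelRecord, RepeatTrack

__all__ = [
    "FilterReport",
    "filter_pass_only",
    "filter_against_parents",
    "filter_repeats",
    "dedupe_breakends",
    "run_filter_cascade",
]


@dataclass
class FilterReport:
    """Accounting of how many events each stage removed, per SV kind."""

    counts_in: dict[str, int] = field(default_factory=dict)
    removed_by_stage: dict[str, dict[str, int]] = field(default_factory=dict)
    counts_out: dict[str, int] = field(default_factory=dict)

    def record_stage(self, stage: str, before: dict[str, int], after: dict[str, int]):
        self.removed_by_stage[stage] = {
            k: before.get(k, 0) - after.get(k, 0) for k in before
        }
        self.counts_out = dict(after)

    def check_conservation(self) -> bool:
        for kind, n_in in self.counts_in.items():
            removed = sum(
                stage.get(kind, 0) for stage in self.removed_by_stage.values()
            )
            if n_in != self.counts_out.get(kind, 0) + removed:
                return False
        return True

    def to_json(self) -> str:
        return json.dumps(
            {
                "counts_in": self.counts_in,
                "removed_by_stage": self.removed_by_stage,
                "counts_out": self.counts_out,
            },
            indent=2,
        )

    def to_tsv(self) -> str:
        lines = ["stage\tkind\tremoved"]
        for stage, kinds in self.removed_by_stage.items():
            for kind, n in kinds.items():
                lines.append(f"{stage}\t{kind}\t{n}")
        return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------


def filter_pass_only(records):
    """Keep only records that passed all caller quality filters."""
    return [r for r in records if r.filter_pass]


def _site_tol(ci_x: tuple[int, int], ci_y: tuple[int, int]) -> int:
    """Positional tolerance for matching two break sites: the largest
    absolute confidence-interval bound of either record."""
    return max(abs(v) for v in (*ci_x, *ci_y))


def _sites_match(key_x, ci_x, key_y, ci_y) -> bool:
    return key_x[0] == key_y[0] and abs(key_x[1] - key_y[1]) <= _site_tol(ci_x, ci_y)


def translocations_match(t1: Translocation, t2: Translocation) -> bool:
    """Two fusions share start and end break points within their
    confidence intervals, in either partner order."""
    a1, b1 = t1.break_a, t1.break_b
    a2, b2 = t2.break_a, t2.break_b
    direct = _sites_match(a1.key, t1.ci_a, a2.key, t2.ci_a) and _sites_match(
        b1.key, t1.ci_b, b2.key, t2.ci_b
    )
    crossed = _sites_match(a1.key, t1.ci_a, b2.key, t2.ci_b) and _sites_match(
        b1.key, t1.ci_b, a2.key, t2.ci_a
    )
    return direct or crossed


def _interval_forest(indels: list[IndelRecord]) -> dict[str, IntervalTree]:
    forest: dict[str, IntervalTree] = {}
    for r in indels:
        forest.setdefault(r.contig, IntervalTree()).addi(r.start0, r.end0 + 1)
    return forest


def filter_against_parents(
    offspring_translocations: list[Translocation],
    offspring_indels: list[IndelRecord],
    parent_translocations: list[Translocation],
    parent_indels: list[IndelRecord],
) -> tuple[list[Translocation], list[IndelRecord]]:
    """Remove offspring events overlapping any parental SV.

    An indel/duplication is removed when its interval shares >= 1 bp with
    any parental SV interval.  A breakend pair is removed when any
    parental breakend pair has both break sites within the merged
    confidence windows of the offspring's sites, in either partner order.
    """
    forest = _interval_forest(parent_indels)
    kept_indels = [
        r
        for r in offspring_indels
        if not (r.contig in forest and forest[r.contig].overlaps(r.start0, r.end0 + 1))
    ]
    kept_tl = [
        t
        for t in offspring_translocations
        if not any(translocations_match(t, p) for p in parent_translocations)
    ]
    return kept_tl, kept_indels


def filter_repeats(
    translocations: list[Translocation],
    indels: list[IndelRecord],
    repeats: RepeatTrack,
) -> tuple[list[Translocation], list[IndelRecord]]:
    """Apply the repeat-region filter.

    Indels intersecting any repeat interval are removed.  A breakend pair
    is removed only when *both* break sites overlap a repeat interval and
    the two repeat classes are identical.
    """
    kept_indels = [
        r
        for r in indels
        if not repeats.classes_overlapping(r.contig, r.start0, r.end0 + 1)
    ]
    kept_tl = []
    for t in translocations:
        classes_a = repeats.classes_at(t.break_a.contig, t.break_a.pos0)
        classes_b = repeats.classes_at(t.break_b.contig, t.break_b.pos0)
        if classes_a & classes_b:
            continue
        kept_tl.append(t)
    return kept_tl, kept_indels


def dedupe_breakends(translocations: list[Translocation]) -> list[Translocation]:
    """Collapse duplicate annotations of the same physical fusion.

    Among candidates matching within confidence intervals in any partner
    order, the lexicographically smallest (contig, position) representative
    is retained.
    """
    kept: list[Translocation] = []
    for t in sorted(translocations, key=lambda t: t.key):
        if not any(translocations_match(t, k) for k in kept):
            kept.append(t)
    return kept


# --------------------------------------------------------------------------
# full cascade
# --------------------------------------------------------------------------


def _counts(translocations, indels) -> dict[str, int]:
    counts = {"breakend": len(translocations)}
    for kind in ("deletion", "insertion", "tandem_duplication"):
        counts[kind] = sum(1 for r in indels if r.kind == kind)
    return counts


def run_filter_cascade(
    offspring_breakends: list[BreakendRecord],
    offspring_indels: list[IndelRecord],
    parent_sets: list[tuple[list[BreakendRecord], list[IndelRecord]]],
    repeats: RepeatTrack | None = None,
) -> tuple[list[Translocation], list[IndelRecord], FilterReport]:
    """Run pass -> parental -> repeat -> dedupe on raw offspring calls.

    Parental call sets are PASS-filtered and mate-resolved with the same
    conventions before being used for overlap removal.  Returns the
    surviving unique translocations, the surviving indels, and the
    per-stage :class:`FilterReport`.
    """
    report = FilterReport()

    # raw counts use breakend *records* (two per fusion) until mates are
    # resolved; the report therefore counts fusions from the pass stage on
    tl = [canonicalize(p) for p in pair_mates(filter_pass_only(offspring_breakends))]
    indels = filter_pass_only(offspring_indels)
    report.counts_in = _counts(tl, indels)
    before = _counts(tl, indels)

    parent_tl: list[Translocation] = []
    parent_indels: list[IndelRecord] = []
    for p_bnd, p_ind in parent_sets:
        parent_tl.extend(
            canonicalize(p) for p in pair_mates(filter_pass_only(p_bnd))
        )
        parent_indels.extend(filter_pass_only(p_ind))

    tl, indels = filter_against_parents(tl, indels, parent_tl, parent_indels)
    report.record_stage("parental_overlap", before, _counts(tl, indels))
    before = _counts(tl, indels)

    if repeats is not None:
        tl, indels = filter_repeats(tl, indels, repeats)
    report.record_stage("repeat_region", before, _counts(tl, indels))
    before = _counts(tl, indels)

    tl = dedupe_breakends(tl)
    report.record_stage("dedupe", before, _counts(tl, indels))
    return tl, indels, report
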