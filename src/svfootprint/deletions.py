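"""Deletion junction homology footprints and binomial over-representation tests.

Small deletions (8-200 bp) are categorized by the homology between the
deleted sequence and the retained sequence that follows it: the junction
footprint of microhomology-mediated end joining.  Two conventions are
supported: the *C. elegans* scheme (exactly 1 bp homology is "micro")
and the human scheme (2-6 bp homology is "micro").  Over-representation
of the micro category is tested against fixed chance expectations with a
one-sided exact binomial test.

The chance constants are configuration values, not re-derived: under a
single first-base comparison with match probability 1/4 the non-homology
chance is 3/4 = 75%, matching the stated expectation, but the published
micro/macro splits (16.66% / 8.33%, and for the human scheme 91.66% /
8.325% / 1:12288) do not follow from that simple geometric model and are
used as given.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.stats import binomtest

from ._seq import bases_match
from .breakends import BreakSite, Translocation
from .io import Genome, IndelRecord, RepeatTrack

__all__ = [
    "DeletionJunction",
    "FootprintResult",
    "SCHEMES",
    "size_filter",
    "left_align",
    "deletion_homology_length",
    "categorize",
    "footprint_test",
    "trio_denovo_filter",
    "stratify_by_origin",
    "filter_same_class_repeats",
    "build_deletion_junctions",
    "deletion_to_translocation",
    "chance_category_probs",
]

#: chance category probabilities per scheme, as published constants
SCHEMES: dict[str, dict[str, float]] = {
    "celegans_1bp": {"non": 0.75, "micro": 0.1666, "macro": 0.0833},
    "human_2to6bp": {"non": 0.9166, "micro": 0.08325, "macro": 1 / 12288},
}


@dataclass
class DeletionJunction:
    """One deletion with its junction homology annotation."""

    deletion: IndelRecord
    deleted_seq: str
    homology_len: int
    category: str | None = None

    @property
    def length(self) -> int:
        return len(self.deleted_seq)


@dataclass
class FootprintResult:
    """Category counts with the binomial micro over-representation test."""

    scheme: str
    counts: dict[str, int]
    n: int
    null_probs: dict[str, float]
    binom_p: float | None

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "counts": self.counts,
            "n": self.n,
            "null_probs": self.null_probs,
            "binom_p": self.binom_p,
        }


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------


def size_filter(
    deletions: list[IndelRecord], lo: int = 8, hi: int = 200
) -> list[IndelRecord]:
    """Keep deletions with lo <= length <= hi (bounds inclusive)."""
    return [d for d in deletions if lo <= d.length <= hi]


def left_align(start0: int, end0: int, seq: str) -> tuple[int, int]:
    """Left-align a deletion interval [start0, end0) on sequence ``seq``.

    The interval shifts left one base at a time while the base preceding
    the deletion equals its last deleted base (the two representations
    delete the same allele).
    """
    while start0 > 0 and bases_match(seq[start0 - 1], seq[end0 - 1]):
        start0 -= 1
        end0 -= 1
    return start0, end0


def deletion_homology_length(deletion: IndelRecord, genome: Genome) -> int:
    """Junction homology length of a deletion.

    After left-alignment, the length of the longest common prefix of the
    deleted sequence and the retained sequence immediately following the
    deletion.  N breaks any run.  Capped at the deletion length.
    """
    seq = genome[deletion.contig]
    start0, end0 = left_align(deletion.start0, deletion.end0, seq)
    k = 0
    length = end0 - start0
    while k < length and end0 + k < len(seq) and bases_match(
        seq[start0 + k], seq[end0 + k]
    ):
        k += 1
    return k


def categorize(homology_len: int, scheme: str) -> str:
    """Map a homology length to non / micro / macro under a scheme."""
    if scheme == "celegans_1bp":
        if homology_len == 0:
            return "non"
        return "micro" if homology_len == 1 else "macro"
    if scheme == "human_2to6bp":
        if homology_len <= 1:
            return "non"
        return "micro" if homology_len <= 6 else "macro"
    raise ValueError(f"unknown scheme {scheme!r}")


def footprint_test(
    junctions: list[DeletionJunction], scheme: str
) -> FootprintResult:
    """Count categories and test micro over-representation.

    One-sided (greater) exact binomial test of the micro count against
    the scheme's chance probability.  With n = 0 the counts are reported
    and the p-value is None.
    """
    null_probs = SCHEMES[scheme]
    counts = {"non": 0, "micro": 0, "macro": 0}
    for j in junctions:
        j.category = categorize(j.homology_len, scheme)
        counts[j.category] += 1
    n = len(junctions)
    if n == 0:
        return FootprintResult(scheme, counts, 0, null_probs, None)
    p = binomtest(
        counts["micro"], n, null_probs["micro"], alternative="greater"
    ).pvalue
    return FootprintResult(scheme, counts, n, null_probs, float(p))


def trio_denovo_filter(
    child_deletions: list[IndelRecord],
    father_deletions: list[IndelRecord],
    mother_deletions: list[IndelRecord],
) -> list[IndelRecord]:
    """Keep child deletions overlapping (>= 1 bp) no parental deletion."""
    parental = father_deletions + mother_deletions
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for d in parental:
        by_contig.setdefault(d.contig, []).append((d.start0, d.end0))
    kept = []
    for d in child_deletions:
        ivals = by_contig.get(d.contig, ())
        if not any(s < d.end0 and e > d.start0 for s, e in ivals):
            kept.append(d)
    return kept


def stratify_by_origin(
    deletions: list[IndelRecord], origin_labels: dict[str, str]
) -> tuple[list[IndelRecord], list[IndelRecord]]:
    """Split deletions by gamete of origin into (father, mother) sets.

    ``origin_labels`` maps record ids to "father" / "mother" / "unknown";
    unlabeled or unknown deletions are dropped.
    """
    father, mother = [], []
    for d in deletions:
        origin = origin_labels.get(d.record_id, "unknown")
        if origin == "father":
            father.append(d)
        elif origin == "mother":
            mother.append(d)
        elif origin != "unknown":
            raise ValueError(f"unknown origin label {origin!r}")
    return father, mother


def filter_same_class_repeats(
    deletions: list[IndelRecord], repeats: RepeatTrack
) -> list[IndelRecord]:
    """Remove deletions whose two break sites lie in the same repeat class.

    The break sites are the last retained base before the deletion and
    the first retained base after it.
    """
    kept = []
    for d in deletions:
        left = repeats.classes_at(d.contig, max(d.start0 - 1, 0))
        right = repeats.classes_at(d.contig, d.end0)
        if left & right:
            continue
        kept.append(d)
    return kept


def build_deletion_junctions(
    deletions: list[IndelRecord], genome: Genome
) -> list[DeletionJunction]:
    """Annotate deletions with deleted sequence and homology length.

    Deletions whose junction flanks fall off the contig are excluded.
    """
    out = []
    for d in deletions:
        seq = genome[d.contig]
        if d.start0 < 1 or d.end0 >= len(seq):
            continue  # flank unavailable at contig end
        out.append(
            DeletionJunction(
                deletion=d,
                deleted_seq=d.fetch_deleted_seq(genome),
                homology_len=deletion_homology_length(d, genome),
            )
        )
    return out


def deletion_to_translocation(d: IndelRecord) -> Translocation:
    """View a deletion's junction as a type-1 fusion for grid statistics.

    The left partner ends at the base before the deletion; the right
    partner starts at the first retained base after it.  This routes the
    16 x 16 deletion grid through the identical grid/permutation code
    path used for translocations.
    """
    left = BreakSite(d.contig, d.start0 - 1, "left-of")
    right = BreakSite(d.contig, d.end0, "right-of")
    return Translocation(
        break_a=left,
        break_b=right,
        ttype=1,
        source_ids=(d.record_id,) if d.record_id else (),
        sample_id=d.sample_id,
    )


def chance_category_probs(p_match: float = 0.25, scheme: str = "celegans_1bp"):
    """Category probabilities under the single-comparison junction model.

    One base comparison per junction position, match probability
    ``p_match``; homology length h has probability
    (1 - p_match) * p_match**h.  The non-homology chance for the
    *C. elegans* scheme is therefore 1 - p_match = 75%, in agreement with
    the published expectation; the derived micro/macro masses differ from
    the published constants (see module docstring), which is why
    :data:`SCHEMES` stores the published values verbatim.
    """
    q = 1.0 - p_match
    if scheme == "celegans_1bp":
        return {
            "non": q,
            "micro": q * p_match,
            "macro": p_match**2,
        }
    if scheme == "human_2to6bp":
        return {
            "non": q + q * p_match,
            "micro": sum(q * p_match**h for h in range(2, 7)),
            "macro": p_match**7,
        }
    raise ValueError(f"unknown scheme {scheme!r}")
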