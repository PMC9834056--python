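"""Synthetic genomes, repeat tracks and parent/offspring SV call sets.

Every pipeline stage gets a desk-scale test surface with exact truth
labels: translocations of the three canonical fusion types with
controllable junction microhomology, templated inserts copied from the
+/- 25 bp break-point flanks in four orientations, miscellaneous inserts,
deletions with a controllable junction-homology distribution, inherited
background SVs shared with the parents, and repeat tracks.

Junction structure is planted by *editing the genome before the FASTA is
finalized*: the desired microhomology run is written through the same
label-to-coordinate mapping used by flank extraction, and the bases that
would extend the run are forced to mismatch, so the truth table is exact
by construction rather than by rejection sampling.  A single RNG stream
is seeded from the configuration; all outputs are byte-identical under a
fixed seed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import COMP_CODES, decode, revcomp
from .breakends import (
    BreakSite,
    LEFT_SIDES,
    Translocation,
    flank_label_positions,
)
from .insertions import ORIENTATIONS, _TRANSFORMS
from .io import (
    BreakendRecord,
    Genome,
    IndelRecord,
    RepeatTrack,
    write_fasta,
    write_repeats,
    write_sv_vcf,
)

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate",
    "simulate_genome",
    "simulate_repeats",
    "random_translocations",
]

#: minimum distance between break sites of different events; covers the
#: +/-25 bp template windows plus the +/-(w+1) microhomology edit zone
MARGIN = 80

_TYPE_SIDES = {1: ("left-of", "right-of"),
               2: ("left-of", "revcomp-left"),
               4: ("revcomp-right", "right-of")}

_SIDE_GEOMETRY = {
    "left-of": (-1, False),
    "revcomp-right": (+1, True),
    "right-of": (+1, False),
    "revcomp-left": (-1, True),
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; ``seed`` is mandatory.

    Probability maps must be normalized; rates must lie in [0, 1].
    """

    seed: int
    contig_lengths: dict[str, int] = field(
        default_factory=lambda: {"chrI": 400_000, "chrII": 300_000, "chrIII": 200_000}
    )
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_translocations: int = 100
    type_mix: dict[int, float] = field(
        default_factory=lambda: {1: 1 / 3, 2: 1 / 3, 4: 1 / 3}
    )
    mh_length_dist: dict[int, float] = field(
        default_factory=lambda: {0: 0.35, 1: 0.30, 2: 0.20, 3: 0.10, 4: 0.05}
    )
    templated_insert_rate: float = 0.06
    misc_insert_rate: float = 0.17
    templated_insert_len_range: tuple[int, int] = (3, 10)
    misc_insert_len_range: tuple[int, int] = (1, 2)
    n_deletions: int = 100
    deletion_homology_dist: dict[int, float] = field(
        default_factory=lambda: {0: 0.75, 1: 0.1666, 2: 0.0834}
    )
    deletion_size_range: tuple[int, int] = (8, 200)
    n_inherited_background_svs: int = 20
    nonpass_rate: float = 0.05
    repeat_density: float = 0.05
    repeat_classes: tuple[str, ...] = (
        "LTR", "LINE", "DNA", "Satellite", "Simple_repeat",
    )
    ci_width: int = 0
    flank_w: int = 4
    offspring_id: str = "F1"
    parent_ids: tuple[str, str] = ("P0_a", "P0_b")
    insert_window: int = 25

    def __post_init__(self) -> None:
        for dist, name in (
            (self.type_mix, "type_mix"),
            (self.mh_length_dist, "mh_length_dist"),
            (self.deletion_homology_dist, "deletion_homology_dist"),
        ):
            total = sum(dist.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"{name} must be normalized (sums to {total})")
            if any(p < 0 for p in dist.values()):
                raise ValueError(f"{name} has negative probabilities")
        for rate in (self.templated_insert_rate, self.misc_insert_rate,
                     self.nonpass_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.templated_insert_rate + self.misc_insert_rate > 1:
            raise ValueError("insert rates sum above 1")
        if not 0 <= self.repeat_density < 1:
            raise ValueError("repeat_density must lie in [0, 1)")
        if max(self.mh_length_dist) > self.flank_w:
            raise ValueError(
                f"microhomology length {max(self.mh_length_dist)} infeasible "
                f"for flank window w={self.flank_w}"
            )
        if min(l for l in self.contig_lengths.values()) < 2 * MARGIN:
            raise ValueError("contigs must be at least 2x the event margin")


@dataclass
class SimulatedDataset:
    """Genome, repeat track, per-sample call sets and the truth table."""

    genome: Genome
    repeats: RepeatTrack
    samples: dict[str, tuple[list[BreakendRecord], list[IndelRecord]]]
    truth: pd.DataFrame
    config: SimulationConfig

    def write(self, outdir) -> dict[str, Path]:
        """Materialize FASTA, per-sample VCFs, BED and truth TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["genome"] = outdir / "genome.fa"
        write_fasta(self.genome, paths["genome"])
        lengths = self.genome.lengths()
        for sample, (bnds, indels) in self.samples.items():
            p = outdir / f"{sample}.vcf"
            write_sv_vcf([*bnds, *indels], lengths, p, sample_id=sample)
            paths[sample] = p
        paths["repeats"] = outdir / "repeats.bed"
        write_repeats(self.repeats, paths["repeats"])
        paths["truth"] = outdir / "truth.tsv"
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


# --------------------------------------------------------------------------
# genome draft and site allocation
# --------------------------------------------------------------------------


class _Draft:
    """Mutable encoded genome plus an interval allocator."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.names = list(config.contig_lengths)
        freqs = np.asarray(config.base_freqs, dtype=float)
        freqs = freqs / freqs.sum()
        self.codes = {
            name: rng.choice(4, size=length, p=freqs).astype(np.int8)
            for name, length in config.contig_lengths.items()
        }
        self.lengths = dict(config.contig_lengths)
        self._weights = np.array([self.lengths[n] for n in self.names], float)
        self._weights /= self._weights.sum()
        # per-contig sorted occupied intervals (start, end)
        self.occupied: dict[str, list[tuple[int, int]]] = {
            n: [] for n in self.names
        }
        self.rng = rng

    def _free(self, contig: str, start: int, end: int) -> bool:
        ivals = self.occupied[contig]
        i = bisect.bisect_left(ivals, (start, start))
        for j in (i - 1, i):
            if 0 <= j < len(ivals):
                s, e = ivals[j]
                if s < end and e > start:
                    return False
        return True

    def allocate(self, length: int = 1, contig: str | None = None) -> tuple[str, int]:
        """Reserve ``[start, start+length)`` plus MARGIN on both sides."""
        for _ in range(2000):
            c = contig or str(self.rng.choice(self.names, p=self._weights))
            L = self.lengths[c]
            lo, hi = MARGIN, L - MARGIN - length
            if hi <= lo:
                continue
            start = int(self.rng.integers(lo, hi))
            if self._free(c, start - MARGIN, start + length + MARGIN):
                bisect.insort(self.occupied[c], (start, start + length))
                return c, start
        raise RuntimeError(
            "could not place event: genome too small for the configured "
            "event count and spacing"
        )

    def read(self, site: BreakSite, label: int) -> int:
        sign, comp = _SIDE_GEOMETRY[site.side]
        code = self.codes[site.contig][site.pos0 + sign * label]
        return int(COMP_CODES[code]) if comp else int(code)

    def write_base(self, site: BreakSite, label: int, code: int) -> None:
        sign, comp = _SIDE_GEOMETRY[site.side]
        value = int(COMP_CODES[code]) if comp else code
        self.codes[site.contig][site.pos0 + sign * label] = value

    def mutate_away(self, site: BreakSite, label: int, avoid_code: int) -> None:
        """Force the base at (site, label) to differ from ``avoid_code``."""
        choices = [c for c in range(4) if c != avoid_code]
        self.write_base(site, label, int(self.rng.choice(choices)))

    def base(self, contig: str, pos0: int) -> str:
        return decode(self.codes[contig][pos0 : pos0 + 1])

    def substring(self, contig: str, start0: int, end0: int) -> str:
        return decode(self.codes[contig][start0:end0])

    def finalize(self) -> Genome:
        return Genome({n: decode(self.codes[n]) for n in self.names})


def _draw(rng: np.random.Generator, dist: dict) -> int:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys], float)
    return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]


# --------------------------------------------------------------------------
# translocations
# --------------------------------------------------------------------------


def _plant_microhomology(
    draft: _Draft, left: BreakSite, right: BreakSite, m: int, w: int
) -> None:
    """Write an exact direction-1 microhomology run of length m.

    Direction 1 compares the left flank's included bases (labels 0, +1,
    ...) with the right flank's excluded bases (labels -1, -2, ...); the
    opposite direction's first comparison is forced to mismatch so the
    recovered length equals m exactly (saturating at w).
    """
    for i in range(m):
        draft.write_base(right, -1 - i, draft.read(left, i))
    if m < w:
        if draft.read(right, -1 - m) == draft.read(left, m):
            draft.mutate_away(right, -1 - m, draft.read(left, m))
    if draft.read(left, -1) == draft.read(right, 0):
        draft.mutate_away(left, -1, draft.read(right, 0))


def _make_translocation(
    draft: _Draft, config: SimulationConfig, rng: np.random.Generator
) -> tuple[Translocation, int]:
    ttype = _draw(rng, config.type_mix)
    site1 = draft.allocate()
    site2 = draft.allocate()
    side_l, side_r = _TYPE_SIDES[ttype]
    if ttype in (2, 4):
        # strand-symmetric types: canonical form puts the left partner at
        # the lexicographically smaller locus
        if site1 > site2:
            site1, site2 = site2, site1
        left = BreakSite(site1[0], site1[1], side_l)
        right = BreakSite(site2[0], site2[1], side_r)
    else:
        if rng.random() < 0.5:
            site1, site2 = site2, site1
        left = BreakSite(site1[0], site1[1], side_l)
        right = BreakSite(site2[0], site2[1], side_r)
    m = _draw(rng, config.mh_length_dist)
    _plant_microhomology(draft, left, right, m, config.flank_w)
    a, b = sorted((left, right), key=lambda s: s.key)
    ci = (-config.ci_width, config.ci_width)
    return (
        Translocation(break_a=a, break_b=b, ttype=ttype, ci_a=ci, ci_b=ci),
        m,
    )


def _search_windows(draft, t: Translocation, window: int):
    for site in (t.break_a, t.break_b):
        L = draft.lengths[site.contig]
        start = max(0, site.pos0 - window)
        end = min(L, site.pos0 + window + 1)
        yield site, draft.substring(site.contig, start, end)


def _has_template(draft, t: Translocation, insert: str, window: int) -> bool:
    for _, win in _search_windows(draft, t, window):
        for orient in ORIENTATIONS:
            if _TRANSFORMS[orient](insert) in win:
                return True
    return False


def _choose_insert(
    draft: _Draft, t: Translocation, config: SimulationConfig,
    rng: np.random.Generator,
):
    """Draw the junction insertion for one translocation.

    Returns (insert_seq, category, template fields...).  Templated
    inserts are copied from the final local genome so detection is exact;
    miscellaneous inserts of >= 3 bp are rejection-sampled until no
    template exists in either window.
    """
    u = rng.random()
    win = config.insert_window
    if u < config.templated_insert_rate:
        lo, hi = config.templated_insert_len_range
        L = int(rng.integers(max(lo, 3), hi + 1))
        which = "A" if rng.random() < 0.5 else "B"
        site = t.break_a if which == "A" else t.break_b
        offset = int(rng.integers(-win, win - L + 2))
        template = draft.substring(
            site.contig, site.pos0 + offset, site.pos0 + offset + L
        )
        orient = ORIENTATIONS[int(rng.integers(4))]
        return _TRANSFORMS[orient](template), "templated", which, offset, orient
    if u < config.templated_insert_rate + config.misc_insert_rate:
        lo, hi = config.misc_insert_len_range
        for _ in range(100):
            L = int(rng.integers(lo, hi + 1))
            insert = decode(rng.integers(0, 4, size=L).astype(np.int8))
            if L < 3 or not _has_template(draft, t, insert, win):
                return insert, "miscellaneous", "", 0, ""
        insert = decode(rng.integers(0, 4, size=min(lo, 2)).astype(np.int8))
        return insert, "miscellaneous", "", 0, ""
    return "", "no_insertion", "", 0, ""


def _emit_mates(
    draft: _Draft, t: Translocation, event_id: str, filter_pass: bool,
    sample_id: str, ci_width: int,
) -> list[BreakendRecord]:
    """Write a canonical translocation as its two mated VCF breakends."""
    left, right = t.left_site, t.right_site
    ins = t.insert_seq
    ref_l = draft.base(left.contig, left.pos0)
    ref_r = draft.base(right.contig, right.pos0)
    lpos, rpos = left.pos0 + 1, right.pos0 + 1
    id1, id2 = f"{event_id}_1", f"{event_id}_2"
    if t.ttype == 1:
        alt1 = f"{ref_l}{ins}[{right.contig}:{rpos}["
        alt2 = f"]{left.contig}:{lpos}]{ins}{ref_r}"
        locs = ((left, ref_l, alt1), (right, ref_r, alt2))
    elif t.ttype == 2:
        alt1 = f"{ref_l}{ins}]{right.contig}:{rpos}]"
        alt2 = f"{ref_r}{revcomp(ins)}]{left.contig}:{lpos}]"
        locs = ((left, ref_l, alt1), (right, ref_r, alt2))
    else:  # type 4: mate records both carry the [p[t shape
        alt1 = f"[{left.contig}:{lpos}[{ins}{ref_r}"
        alt2 = f"[{right.contig}:{rpos}[{revcomp(ins)}{ref_l}"
        locs = ((right, ref_r, alt1), (left, ref_l, alt2))
    recs = []
    for (site, ref, alt), rid, mid in zip(locs, (id1, id2), (id2, id1)):
        recs.append(
            BreakendRecord(
                record_id=rid,
                contig=site.contig,
                pos=site.pos0 + 1,
                ref_base=ref,
                alt=alt,
                mate_id=mid,
                ci_pos=(-ci_width, ci_width),
                filter_pass=filter_pass,
                sample_id=sample_id,
            )
        )
    return recs


# --------------------------------------------------------------------------
# deletions
# --------------------------------------------------------------------------


def _make_deletion(
    draft: _Draft, config: SimulationConfig, rng: np.random.Generator
) -> tuple[str, int, int, int]:
    """Allocate a deletion and plant its junction homology.

    Returns (contig, start0, end0, homology).  The interval is
    left-aligned by construction and the homology run is exact.
    """
    lo, hi = config.deletion_size_range
    length = int(rng.integers(lo, hi + 1))
    contig, start0 = draft.allocate(length=length)
    end0 = start0 + length
    h = _draw(rng, config.deletion_homology_dist)
    codes = draft.codes[contig]
    for i in range(h):
        codes[end0 + i] = codes[start0 + i]
    if codes[end0 + h] == codes[start0 + h]:
        choices = [c for c in range(4) if c != codes[start0 + h]]
        codes[end0 + h] = int(rng.choice(choices))
    if codes[start0 - 1] == codes[end0 - 1]:
        # force left-alignment so the emitted coordinates are canonical
        choices = [c for c in range(4) if c != codes[end0 - 1]]
        codes[start0 - 1] = int(rng.choice(choices))
    return contig, start0, end0, h


# --------------------------------------------------------------------------
# repeats
# --------------------------------------------------------------------------


def simulate_repeats(
    config: SimulationConfig,
    genome: Genome,
    rng: np.random.Generator | None = None,
    avoid: dict[str, list[tuple[int, int]]] | None = None,
) -> RepeatTrack:
    """Non-overlapping repeat intervals with classes from a small vocabulary.

    ``avoid`` lists per-contig intervals (typically planted event
    neighborhoods) that repeats must not touch, so that synthetic de novo
    events are never swallowed by the repeat filter.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    intervals: list[tuple[str, int, int, str]] = []
    if config.repeat_density == 0:
        return RepeatTrack([])
    for name, seq in genome.contigs.items():
        L = len(seq)
        target = int(config.repeat_density * L)
        placed: list[tuple[int, int]] = sorted(
            [(s - MARGIN, e + MARGIN) for s, e in (avoid or {}).get(name, [])]
        )
        covered = 0
        for _ in range(50 * max(1, target // 300)):
            if covered >= target:
                break
            length = int(rng.integers(100, 1001))
            if L <= length:
                break
            start = int(rng.integers(0, L - length))
            end = start + length
            if any(s < end and e > start for s, e in placed):
                continue
            placed.append((start, end))
            placed.sort()
            cls = config.repeat_classes[int(rng.integers(len(config.repeat_classes)))]
            intervals.append((name, start, end, cls))
            covered += length
    return RepeatTrack(intervals)


# --------------------------------------------------------------------------
# top level
# --------------------------------------------------------------------------


def simulate_genome(config: SimulationConfig) -> Genome:
    """An i.i.d. random genome at the configured base frequencies."""
    rng = np.random.default_rng(config.seed)
    return _Draft(config, rng).finalize()


def random_translocations(
    genome: Genome,
    n: int,
    type_mix: dict[int, float] | None = None,
    rng: np.random.Generator | int | None = None,
    w: int = 4,
) -> list[Translocation]:
    """Uniformly placed junctions with no planted structure.

    This is the same placement model the permutation null uses; it gives
    a calibration set whose match grid should be flat at the base-match
    chance level.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    type_mix = type_mix or {1: 1 / 3, 2: 1 / 3, 4: 1 / 3}
    names = list(genome.contigs)
    weights = np.array([len(genome[n]) for n in names], float)
    weights /= weights.sum()
    out = []
    for _ in range(n):
        ttype = _draw(rng, type_mix)
        sites = []
        for _ in range(2):
            c = names[int(rng.choice(len(names), p=weights))]
            pos = int(rng.integers(w, len(genome[c]) - w))
            sites.append((c, pos))
        side_l, side_r = _TYPE_SIDES[ttype]
        if ttype in (2, 4) and sites[0] > sites[1]:
            sites.reverse()
        left = BreakSite(sites[0][0], sites[0][1], side_l)
        right = BreakSite(sites[1][0], sites[1][1], side_r)
        a, b = sorted((left, right), key=lambda s: s.key)
        out.append(Translocation(break_a=a, break_b=b, ttype=ttype))
    return out


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full parent/offspring dataset with truth labels."""
    rng = np.random.default_rng(config.seed)
    draft = _Draft(config, rng)
    truth_rows: list[dict] = []

    n_bg = config.n_inherited_background_svs
    n_bg_tl = n_bg // 2
    n_bg_del = n_bg - n_bg_tl

    # --- allocate and plant all genome edits first -----------------------
    planted_tl = []
    for i in range(config.n_translocations + n_bg_tl):
        inherited = i >= config.n_translocations
        t, m = _make_translocation(draft, config, rng)
        planted_tl.append((t, m, inherited))

    planted_del = []
    for i in range(config.n_deletions + n_bg_del):
        inherited = i >= config.n_deletions
        contig, s0, e0, h = _make_deletion(draft, config, rng)
        planted_del.append((contig, s0, e0, h, inherited))

    # --- derive inserts from the (now frozen) local sequence -------------
    samples: dict[str, tuple[list, list]] = {
        config.offspring_id: ([], []),
        config.parent_ids[0]: ([], []),
        config.parent_ids[1]: ([], []),
    }

    for i, (t, m, inherited) in enumerate(planted_tl):
        insert, category, tsite, toffset, torient = _choose_insert(
            draft, t, config, rng
        )
        t = replace(t, insert_seq=insert)
        event_id = f"tl{i:05d}"
        filter_pass = inherited or rng.random() >= config.nonpass_rate
        carriers = [config.offspring_id]
        if inherited:
            carriers.append(config.parent_ids[int(rng.integers(2))])
        for sample in carriers:
            recs = _emit_mates(
                draft, t, f"{event_id}_{sample}", filter_pass, sample,
                config.ci_width,
            )
            samples[sample][0].extend(recs)
        truth_rows.append(
            dict(
                event_id=event_id,
                kind="translocation",
                status="inherited" if inherited else "denovo",
                filter_pass=filter_pass,
                contig_a=t.break_a.contig, pos_a=t.break_a.pos0,
                side_a=t.break_a.side,
                contig_b=t.break_b.contig, pos_b=t.break_b.pos0,
                side_b=t.break_b.side,
                ttype=t.ttype,
                mh_len=m,
                insert_category=category,
                insert_len=len(insert),
                insert_seq=insert,
                template_site=tsite,
                template_offset=toffset,
                template_orientation=torient,
            )
        )

    for i, (contig, s0, e0, h, inherited) in enumerate(planted_del):
        event_id = f"del{i:05d}"
        filter_pass = inherited or rng.random() >= config.nonpass_rate
        carriers = [config.offspring_id]
        if inherited:
            carriers.append(config.parent_ids[int(rng.integers(2))])
        for sample in carriers:
            samples[sample][1].append(
                IndelRecord(
                    "deletion",
                    contig=contig,
                    start=s0 + 1,
                    end=e0,
                    deleted_seq=draft.substring(contig, s0, e0),
                    filter_pass=filter_pass,
                    sample_id=sample,
                    record_id=f"{event_id}_{sample}",
                )
            )
        truth_rows.append(
            dict(
                event_id=event_id,
                kind="deletion",
                status="inherited" if inherited else "denovo",
                filter_pass=filter_pass,
                contig_a=contig, pos_a=s0 - 1, side_a="left-of",
                contig_b=contig, pos_b=e0, side_b="right-of",
                ttype=1,
                del_start0=s0, del_end0=e0, del_len=e0 - s0,
                del_homology=h,
            )
        )

    genome = draft.finalize()
    avoid = {
        n: [iv for iv in draft.occupied[n]] for n in draft.names
    }
    repeats = simulate_repeats(
        config, genome, np.random.default_rng(config.seed + 1), avoid=avoid
    )
    truth = pd.DataFrame(truth_rows)
    return SimulatedDataset(
        genome=genome, repeats=repeats, samples=samples, truth=truth,
        config=config,
    )
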