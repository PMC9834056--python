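"""End-to-end orchestration of the junction-signature analyses.

Two workflows: the translocation analysis (filter cascade -> type counts
-> insertion categorization -> match grid with permutation null -> base
composition) and the deletion footprint analysis (size filter -> repeat
filter -> optional trio de novo filter -> homology categorization ->
binomial test -> 16 x 16 grid).  A :class:`RunConfig` holds every knob;
its defaults are the analysis' reference parameters and every run writes
its resolved configuration alongside its outputs so each number is
recomputable from inputs plus config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import deletions as dels
from .breakends import Translocation, extract_flanks
from .filtering import FilterReport, run_filter_cascade
from .homology import (
    BaseComposition,
    HomologyGrid,
    base_composition,
    build_homology_grid,
    grid_to_tsv,
    microhomology_length,
    permutation_null,
)
from .insertions import InsertionCall, classify_insertion, insertion_distribution
from .io import Genome, IndelRecord, RepeatTrack, read_fasta, read_repeats, read_sv_vcf

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "TranslocationReport", "DeletionReport",
           "run_translocation_analysis", "run_deletion_footprint"]

#: permutation counts per profile; "paper" matches the reference analysis,
#: "test" is the desk-scale profile (the two differ in nothing else)
PROFILES = {
    "paper": {"n_perm_grid": 100_000, "n_perm_basecomp": 25_000},
    "test": {"n_perm_grid": 9_999, "n_perm_basecomp": 2_500},
}


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    genome_fasta: str | None = None
    offspring_vcfs: list[str] = field(default_factory=list)
    parent_vcfs: list[str] = field(default_factory=list)
    repeats_bed: str | None = None
    origin_labels_tsv: str | None = None
    flank_w: int = 4
    deletion_grid_w: int = 8
    insert_window: int = 25
    insert_minlen: int = 3
    n_perm_grid: int = 100_000
    n_perm_basecomp: int = 25_000
    deletion_size_bounds: tuple[int, int] = (8, 200)
    scheme: str = "celegans_1bp"
    seed: int = 0
    exclude_templated_from_grid: bool = True
    plot: bool = False
    output_dir: str | None = None

    def with_profile(self, profile: str) -> "RunConfig":
        return dataclasses.replace(self, **PROFILES[profile])

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=str)


@dataclass
class TranslocationReport:
    filter_report: FilterReport
    translocations: list[Translocation]
    type_counts: dict[int, int]
    insertion_calls: list[InsertionCall]
    insertion_summary: dict[str, float]
    grid: HomologyGrid
    mh_histogram: dict[int, int]
    basecomp: BaseComposition | None
    resolved_config: RunConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "resolved_config.json").write_text(self.resolved_config.to_json())
        (outdir / "filter_report.json").write_text(self.filter_report.to_json())
        (outdir / "filter_report.tsv").write_text(self.filter_report.to_tsv())
        summary = {
            "n_translocations": len(self.translocations),
            "type_counts": {str(k): v for k, v in self.type_counts.items()},
            "insertion_distribution": self.insertion_summary,
            "mh_length_histogram": {str(k): v for k, v in self.mh_histogram.items()},
            "grid_n": self.grid.n,
            "grid_n_perm": self.grid.n_perm,
            "seed": self.resolved_config.seed,
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
        (outdir / "grid_matrix.tsv").write_text(grid_to_tsv(self.grid, "matrix"))
        if self.grid.p_values is not None:
            (outdir / "grid_p.tsv").write_text(grid_to_tsv(self.grid, "p_values"))
            (outdir / "grid_q.tsv").write_text(grid_to_tsv(self.grid, "q_values"))
        if self.resolved_config.plot:
            from .homology import plot_grid

            plot_grid(self.grid, outdir / "grid.png")
        rows = []
        for t, call in zip(self.translocations, self.insertion_calls):
            best = call.template_hits[0] if call.template_hits else None
            rows.append(
                {
                    "break_a": f"{t.break_a.contig}:{t.break_a.pos0}",
                    "break_b": f"{t.break_b.contig}:{t.break_b.pos0}",
                    "ttype": t.ttype,
                    "insert_category": call.category,
                    "insert_len": call.insert_len,
                    "best_hit": (
                        f"{best.break_site}:{best.offset}:{best.orientation}"
                        if best
                        else ""
                    ),
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "translocations.tsv", sep="\t", index=False)
        if self.basecomp is not None:
            bc = self.basecomp
            df = pd.DataFrame(
                {
                    "position": bc.labels,
                    **{f"{b}_pct": bc.observed[b] for b in "ACGT"},
                    **{f"{b}_bg_pct": bc.background[b] for b in "ACGT"},
                }
            )
            df.to_csv(outdir / "base_composition.tsv", sep="\t", index=False)


@dataclass
class DeletionReport:
    junctions: list[dels.DeletionJunction]
    footprint: dels.FootprintResult
    strata: dict[str, dels.FootprintResult]
    grid: HomologyGrid | None
    resolved_config: RunConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "resolved_config.json").write_text(self.resolved_config.to_json())
        payload = {"all": self.footprint.to_dict()}
        payload.update({k: v.to_dict() for k, v in self.strata.items()})
        (outdir / "footprint.json").write_text(json.dumps(payload, indent=2))
        rows = [
            {
                "contig": j.deletion.contig,
                "start": j.deletion.start,
                "end": j.deletion.end,
                "length": j.length,
                "homology_len": j.homology_len,
                "category": j.category,
            }
            for j in self.junctions
        ]
        pd.DataFrame(rows).to_csv(outdir / "deletions.tsv", sep="\t", index=False)
        if self.grid is not None:
            (outdir / "grid_matrix.tsv").write_text(grid_to_tsv(self.grid, "matrix"))
            if self.grid.p_values is not None:
                (outdir / "grid_q.tsv").write_text(grid_to_tsv(self.grid, "q_values"))


# --------------------------------------------------------------------------
# workflows
# --------------------------------------------------------------------------


def _load_inputs(config: RunConfig):
    if config.genome_fasta is None:
        raise ValueError("genome FASTA is required")
    genome = read_fasta(config.genome_fasta)
    offspring = [read_sv_vcf(p) for p in config.offspring_vcfs]
    parents = [read_sv_vcf(p) for p in config.parent_vcfs]
    repeats = read_repeats(config.repeats_bed) if config.repeats_bed else None
    return genome, offspring, parents, repeats


def run_translocation_analysis(
    config: RunConfig,
    genome: Genome | None = None,
    offspring=None,
    parents=None,
    repeats: RepeatTrack | None = None,
    run_permutations: bool = True,
) -> TranslocationReport:
    """Full translocation workflow; inputs may be passed pre-loaded."""
    if genome is None:
        genome, offspring, parents, repeats = _load_inputs(config)
    all_bnd = [b for bnds, _ in offspring for b in bnds]
    all_ind = [i for _, inds in offspring for i in inds]
    parent_sets = list(parents or [])

    translocations, _indels, report = run_filter_cascade(
        all_bnd, all_ind, parent_sets, repeats
    )
    logger.info("filter cascade kept %d unique translocations", len(translocations))

    type_counts: dict[int, int] = {1: 0, 2: 0, 4: 0}
    for t in translocations:
        type_counts[t.ttype] += 1

    calls = [
        classify_insertion(t, genome, config.insert_window, config.insert_minlen)
        for t in translocations
    ]
    summary = insertion_distribution(calls)

    if config.exclude_templated_from_grid:
        grid_tl = [
            t for t, c in zip(translocations, calls) if c.category != "templated"
        ]
    else:
        grid_tl = list(translocations)

    mh_hist: dict[int, int] = {}
    mh1: list[Translocation] = []
    for t in grid_tl:
        pair = extract_flanks(t, genome, config.flank_w)
        if pair is None:
            continue
        m = microhomology_length(pair)
        mh_hist[m] = mh_hist.get(m, 0) + 1
        if m == 1:
            mh1.append(t)

    grid = build_homology_grid(grid_tl, genome, config.flank_w)
    if run_permutations:
        grid = permutation_null(
            grid, grid_tl, genome, n_perm=config.n_perm_grid, seed=config.seed
        )

    basecomp = None
    if mh1 and run_permutations:
        basecomp = base_composition(
            mh1,
            genome,
            w=config.flank_w,
            n_perm=config.n_perm_basecomp,
            seed=config.seed,
        )

    out = TranslocationReport(
        filter_report=report,
        translocations=translocations,
        type_counts=type_counts,
        insertion_calls=calls,
        insertion_summary=summary,
        grid=grid,
        mh_histogram=mh_hist,
        basecomp=basecomp,
        resolved_config=config,
    )
    if config.output_dir:
        out.write(config.output_dir)
    return out


def read_origin_labels(path) -> dict[str, str]:
    """TSV mapping deletion record id -> father/mother/unknown."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "origin"])
    return dict(zip(df["id"].astype(str), df["origin"].astype(str)))


def run_deletion_footprint(
    config: RunConfig,
    genome: Genome | None = None,
    deletions: list[IndelRecord] | None = None,
    father: list[IndelRecord] | None = None,
    mother: list[IndelRecord] | None = None,
    repeats: RepeatTrack | None = None,
    origin_labels: dict[str, str] | None = None,
    run_permutations: bool = False,
) -> DeletionReport:
    """Deletion footprint workflow.

    ``deletions`` defaults to the deletions of the offspring VCFs; when
    father/mother sets are given the trio de novo filter is applied; when
    origin labels are given the binomial test is additionally run per
    gamete of origin.  An empty post-filter set yields an explicit n=0
    report rather than an error.
    """
    if genome is None:
        genome, offspring, parents, repeats = _load_inputs(config)
        deletions = [
            d for _, inds in offspring for d in inds if d.kind == "deletion"
        ]
        if len(parents) == 2:
            father = [d for d in parents[0][1] if d.kind == "deletion"]
            mother = [d for d in parents[1][1] if d.kind == "deletion"]
        if config.origin_labels_tsv:
            origin_labels = read_origin_labels(config.origin_labels_tsv)

    lo, hi = config.deletion_size_bounds
    deletions = [d for d in deletions or [] if d.filter_pass]
    deletions = dels.size_filter(deletions, lo, hi)
    if repeats is not None:
        deletions = dels.filter_same_class_repeats(deletions, repeats)
    if father is not None and mother is not None:
        deletions = dels.trio_denovo_filter(deletions, father, mother)

    junctions = dels.build_deletion_junctions(deletions, genome)
    footprint = dels.footprint_test(junctions, config.scheme)
    if footprint.n == 0:
        logger.warning("no deletions survive filtering; reporting n=0")

    strata: dict[str, dels.FootprintResult] = {}
    if origin_labels:
        f_set, m_set = dels.stratify_by_origin(deletions, origin_labels)
        for name, subset in (("father", f_set), ("mother", m_set)):
            sub_j = dels.build_deletion_junctions(subset, genome)
            strata[name] = dels.footprint_test(sub_j, config.scheme)

    grid = None
    if junctions:
        micro = [
            j.deletion for j in junctions if j.category == "micro"
        ]
        grid_set = micro if micro else [j.deletion for j in junctions]
        as_tl = [dels.deletion_to_translocation(d) for d in grid_set]
        grid = build_homology_grid(as_tl, genome, config.deletion_grid_w)
        if run_permutations:
            grid = permutation_null(
                grid, as_tl, genome, n_perm=config.n_perm_grid, seed=config.seed
            )

    out = DeletionReport(
        junctions=junctions,
        footprint=footprint,
        strata=strata,
        grid=grid,
        resolved_config=config,
    )
    if config.output_dir:
        out.write(config.output_dir)
    return out
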