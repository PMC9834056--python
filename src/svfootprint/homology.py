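"""Microhomology match-grid statistics with permutation nulls.

For each junction the 2w bases flanking both break sites (w included in
the fusion product, w beyond the break) are compared all-against-all in a
2w x 2w grid: 1 where the bases are identical, 0 otherwise, with N never
matching.  Grids are averaged over junctions into a match-frequency heat
map.  Each bin is tested against a null in which the same number of
junctions (with the same fusion-type mix) is placed uniformly at random
on the genome, and per-bin one-sided upper-tail p-values are
Benjamini-Hochberg adjusted over all bins.

The junction microhomology signal lives on the grid's main diagonal in
storage order: label pairs (0, -1), (+1, -2), ... at indices
(w-1, w-1), (w-2, w-2), ... for one junction-shift direction and
(-1, 0), (-2, +1), ... at (w, w), (w+1, w+1), ... for the other.

The same code path serves the translocation 8 x 8 grid (w = 4) and the
deletion 16 x 16 grid (w = 8).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from ._seq import COMP_CODES, N_CODE, encode
from .breakends import (
    FlankPair,
    Translocation,
    extract_flanks,
    flank_label_positions,
)
from .io import Genome

__all__ = [
    "HomologyGrid",
    "BaseComposition",
    "junction_match_grid",
    "aggregate_grids",
    "build_homology_grid",
    "permutation_null",
    "bh_adjust",
    "microhomology_length",
    "base_composition",
    "junction_spanning_bins",
    "grid_to_tsv",
]


# --------------------------------------------------------------------------
# grids
# --------------------------------------------------------------------------


@dataclass
class HomologyGrid:
    """Aggregated 2w x 2w match-frequency matrix with optional statistics.

    ``matrix[i, j]`` is the fraction of junctions whose left-flank base at
    string index i equals the right-flank base at index j.  Row labels run
    ``+(w-1) .. -w`` (left flank), column labels ``-w .. +(w-1)`` (right
    flank).
    """

    w: int
    matrix: np.ndarray
    n: int
    p_values: np.ndarray | None = None
    q_values: np.ndarray | None = None
    n_perm: int = 0
    seed: int | None = None
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2 * self.w, 2 * self.w):
            raise ValueError("matrix must be 2w x 2w")
        if (self.matrix < 0).any() or (self.matrix > 1).any():
            raise ValueError("match frequencies must lie in [0, 1]")

    @property
    def row_labels(self) -> list[int]:
        return list(range(self.w - 1, -self.w - 1, -1))

    @property
    def col_labels(self) -> list[int]:
        return list(range(-self.w, self.w))


def junction_match_grid(pair: FlankPair) -> np.ndarray:
    """Binary 2w x 2w match grid of one junction's flanks.

    ``grid[i, j] = 1`` iff ``left[i] == right[j]`` and neither is N.
    """
    left = encode(pair.left_flank)
    right = encode(pair.right_flank)
    return (
        (left[:, None] == right[None, :])
        & (left[:, None] != N_CODE)
        & (right[None, :] != N_CODE)
    ).astype(np.int8)


def aggregate_grids(grids: list[np.ndarray]) -> np.ndarray:
    """Element-wise mean of binary grids (the heat-map frequencies)."""
    if not grids:
        raise ValueError("cannot aggregate zero grids")
    return np.mean([np.asarray(g, dtype=float) for g in grids], axis=0)


def build_homology_grid(
    translocations: list[Translocation], genome: Genome, w: int = 4
) -> HomologyGrid:
    """Aggregate the match grids of a set of junctions.

    Junctions whose flank windows exceed contig bounds are excluded and
    counted in ``n_excluded``.
    """
    grids = []
    excluded = 0
    for t in translocations:
        pair = extract_flanks(t, genome, w)
        if pair is None:
            excluded += 1
            continue
        grids.append(junction_match_grid(pair))
    if not grids:
        raise ValueError("no junction with extractable flanks")
    return HomologyGrid(
        w=w, matrix=aggregate_grids(grids), n=len(grids), n_excluded=excluded
    )


def junction_spanning_bins(w: int, m: int, direction: int = 1):
    """Matrix indices of the m junction-spanning bins for microhomology
    of length m (direction 1: left-included vs right-excluded)."""
    if direction == 1:
        return [(w - 1 - k, w - 1 - k) for k in range(m)]
    return [(w + k, w + k) for k in range(m)]


# --------------------------------------------------------------------------
# permutation null
# --------------------------------------------------------------------------


class _EncodedGenome:
    """Concatenated int8 genome with a pool of flank-safe positions."""

    def __init__(self, genome: Genome, w: int):
        parts = []
        pools = []
        offset = 0
        for name, seq in genome.contigs.items():
            codes = encode(seq)
            parts.append(codes)
            L = len(codes)
            if L >= 2 * w + 1:
                # positions whose +/- w window stays inside the contig
                # and contains no N
                is_n = (codes == N_CODE).astype(np.int32)
                cum = np.concatenate([[0], np.cumsum(is_n)])
                starts = np.arange(w, L - w)
                n_in_window = cum[starts + w + 1] - cum[starts - w]
                pools.append(offset + starts[n_in_window == 0])
            offset += L
        if not parts:
            raise ValueError("empty genome")
        self.codes = np.concatenate(parts)
        if not pools or all(len(p) == 0 for p in pools):
            raise ValueError(f"no contig admits a +/-{w} bp flank window")
        self.pool = np.concatenate([p for p in pools if len(p)])

    def sample_positions(self, rng: np.random.Generator, shape) -> np.ndarray:
        idx = rng.integers(0, len(self.pool), size=shape)
        return self.pool[idx]


#: flank-string offset patterns per joined side, indexed label-order;
#: complement flag applied after the gather.
def _side_offsets(side: str, w: int) -> tuple[np.ndarray, bool]:
    if side == "left-of":
        return np.arange(-w + 1, w + 1), False
    if side == "right-of":
        return np.arange(-w, w), False
    if side == "revcomp-left":
        return np.arange(w, -w, -1), True
    if side == "revcomp-right":
        return np.arange(w - 1, -w - 1, -1), True
    raise ValueError(side)


_TYPE_SIDES = {1: ("left-of", "right-of"),
               2: ("left-of", "revcomp-left"),
               4: ("revcomp-right", "right-of")}


def _gather_flanks(codes, positions, side: str, w: int) -> np.ndarray:
    offs, comp = _side_offsets(side, w)
    out = codes[positions[..., None] + offs]
    if comp:
        out = COMP_CODES[out]
    return out


def permutation_null(
    grid: HomologyGrid,
    translocations: list[Translocation],
    genome: Genome,
    n_perm: int = 100_000,
    seed: int | None = 0,
    chunk: int = 2_000,
) -> HomologyGrid:
    """Permutation-test every grid bin against random genomic placement.

    Per permutation the same number of junctions, with the same
    fusion-type mix, is placed uniformly at random on the genome (both
    break sites drawn independently, contigs weighted by length,
    positions at least w from contig ends and outside N runs), flanks are
    extracted with the type-specific orientations, and bins are averaged.
    The one-sided upper-tail p-value of a bin is (r + 1) / (n_perm + 1)
    where r counts permutations whose bin frequency reaches the observed
    one.  Deterministic given ``seed``.  Returns a new grid carrying
    ``p_values`` and BH-adjusted ``q_values``.
    """
    w = grid.w
    types = [t.ttype for t in translocations]
    if len(types) < grid.n:
        raise ValueError("need at least as many translocations as grid n")
    enc = _EncodedGenome(genome, w)
    rng = np.random.default_rng(seed)

    # integer comparison: observed total matches per bin over n junctions
    obs_counts = np.rint(grid.matrix * grid.n).astype(np.int64)
    n = grid.n

    type_counts = {tt: types.count(tt) for tt in set(types)}
    r = np.zeros((2 * w, 2 * w), dtype=np.int64)
    done = 0
    while done < n_perm:
        block = min(chunk, n_perm - done)
        totals = np.zeros((block, 2 * w, 2 * w), dtype=np.int32)
        for tt, cnt in sorted(type_counts.items()):
            side_l, side_r = _TYPE_SIDES[tt]
            pos_l = enc.sample_positions(rng, (block, cnt))
            pos_r = enc.sample_positions(rng, (block, cnt))
            L = _gather_flanks(enc.codes, pos_l, side_l, w)
            R = _gather_flanks(enc.codes, pos_r, side_r, w)
            match = (
                (L[:, :, :, None] == R[:, :, None, :])
                & (L[:, :, :, None] != N_CODE)
                & (R[:, :, None, :] != N_CODE)
            )
            totals += match.sum(axis=1, dtype=np.int32)
        r += (totals >= obs_counts[None, :, :]).sum(axis=0)
        done += block

    p = (r + 1) / (n_perm + 1)
    q = bh_adjust(p)
    return HomologyGrid(
        w=w,
        matrix=grid.matrix,
        n=grid.n,
        p_values=p,
        q_values=q,
        n_perm=n_perm,
        seed=seed,
        n_excluded=grid.n_excluded,
    )


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up over all bins (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    q = multipletests(p.ravel(), method="fdr_bh")[1]
    return q.reshape(p.shape)


# --------------------------------------------------------------------------
# microhomology length
# --------------------------------------------------------------------------


def microhomology_length(pair: FlankPair) -> int:
    """Junction microhomology length from a flank pair.

    The maximal run of junction-spanning matches in one shift direction:
    left-included labels 0, +1, ... against right-excluded labels -1, -2,
    ... (and vice versa), compared base-by-base moving away from the
    junction; N breaks any run.  Returns the larger of the two runs, 0
    when the first comparison fails in both directions.  Capped at w.
    """
    w = pair.w
    left = pair.left_flank
    right = pair.right_flank

    def run(indices) -> int:
        k = 0
        for i, j in indices:
            a, b = left[i], right[j]
            if a != b or a == "N":
                break
            k += 1
        return k

    # direction 1: left label +k (index w-1-k) vs right label -1-k (index w-1-k)
    d1 = run(((w - 1 - k, w - 1 - k) for k in range(w)))
    # direction 2: left label -1-k (index w+k) vs right label +k (index w+k)
    d2 = run(((w + k, w + k) for k in range(w)))
    return max(d1, d2)


# --------------------------------------------------------------------------
# base composition
# --------------------------------------------------------------------------


@dataclass
class BaseComposition:
    """Per-position base percentages at junctions vs a resampled background.

    ``observed[base][label]`` holds percentages over both flanks of the
    supplied junctions; ``background`` the mean percentages over
    ``n_perm`` draws of equally many uniform random genomic positions.
    Positions contributing N are dropped and counted in ``n_dropped``.
    """

    labels: list[int]
    observed: dict[str, np.ndarray]
    background: dict[str, np.ndarray]
    n_sites: int
    n_perm: int
    seed: int | None
    n_dropped: int = 0


_BASES = "ACGT"


def _percentages(codes: np.ndarray) -> tuple[dict[str, np.ndarray], int]:
    """Column-wise base percentages of an (n, 2w) code matrix, ignoring N."""
    ncols = codes.shape[1]
    counts = np.zeros((4, ncols), dtype=np.int64)
    for b in range(4):
        counts[b] = (codes == b).sum(axis=0)
    valid = counts.sum(axis=0)
    dropped = int((codes == N_CODE).sum())
    with np.errstate(invalid="ignore"):
        pct = 100.0 * counts / valid
    return {base: pct[i] for i, base in enumerate(_BASES)}, dropped


def base_composition(
    translocations: list[Translocation],
    genome: Genome,
    w: int = 4,
    n_perm: int = 25_000,
    seed: int | None = 0,
) -> BaseComposition:
    """Base composition around break points vs random genomic background.

    Typically applied to the junctions with microhomology length 1.  Each
    junction contributes both oriented flanks, tallied per position label
    (-w .. +(w-1)).  The background samples ``len(translocations)``
    random positions per draw and averages percentages over ``n_perm``
    draws; deterministic given ``seed``.
    """
    if not translocations:
        raise ValueError("empty site list")
    rows = []
    for t in translocations:
        pair = extract_flanks(t, genome, w)
        if pair is None:
            continue
        left = encode(pair.left_flank)
        # re-order the left flank into ascending label order so both
        # flanks share the column layout -w .. +(w-1)
        rows.append(left[::-1])
        rows.append(encode(pair.right_flank))
    if not rows:
        raise ValueError("no junction with extractable flanks")
    observed, dropped = _percentages(np.stack(rows))

    enc = _EncodedGenome(genome, w)
    rng = np.random.default_rng(seed)
    n_sites = len(rows) // 2
    positions = enc.sample_positions(rng, (n_perm * n_sites,))
    windows = enc.codes[positions[:, None] + np.arange(-w, w)]
    background, _ = _percentages(windows)

    return BaseComposition(
        labels=list(range(-w, w)),
        observed=observed,
        background=background,
        n_sites=n_sites,
        n_perm=n_perm,
        seed=seed,
        n_dropped=dropped,
    )


# --------------------------------------------------------------------------
# output helpers
# --------------------------------------------------------------------------


def plot_grid(grid: HomologyGrid, path, title: str | None = None) -> None:
    """Render the match-frequency heat map to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(grid.matrix, cmap="Blues", vmin=0, vmax=1)
    ax.set_xticks(range(2 * grid.w), [str(c) for c in grid.col_labels])
    ax.set_yticks(range(2 * grid.w), [str(r) for r in grid.row_labels])
    ax.set_xlabel("right flank position")
    ax.set_ylabel("left flank position")
    if title is None:
        title = f"match frequency (n={grid.n})"
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="match frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def grid_to_tsv(grid: HomologyGrid, which: str = "matrix") -> str:
    """Serialize a grid matrix (or its p/q values) with signed labels."""
    mat = {
        "matrix": grid.matrix,
        "p_values": grid.p_values,
        "q_values": grid.q_values,
    }[which]
    if mat is None:
        raise ValueError(f"grid has no {which}")
    lines = ["\t" + "\t".join(str(c) for c in grid.col_labels)]
    for lab, row in zip(grid.row_labels, mat):
        lines.append(str(lab) + "\t" + "\t".join(f"{v:.6g}" for v in row))
    return "\n".join(lines) + "\n"
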