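"""Pairwise alignment of Rmaps against reference fragment maps.

A molecule's ordered fragment masses are matched to a reference map by
a dynamic program over *blocks*: a block pairs up to ``max_block``
consecutive query fragments with up to ``max_block`` consecutive
reference fragments.  The block cost is a squared sizing z-score plus a
fixed penalty for every interior cut consumed on either side (a missing
reference cut or an extra query cut).  Molecule ends are random shear
breaks, so the first and last query fragments match partial reference
fragments at zero cost.

An alignment is accepted when its mean cost per aligned query fragment
(terminals included) does not exceed ``accept_threshold``; this
mean-cost rule is a deterministic stand-in for a p-value based filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._dp import dp_fill, traceback
from .core_maps import FragmentMap, GenomeMaps, Rmap

STATUS_ALIGNED = "aligned"
STATUS_REJECTED_SHORT = "rejected_short"
STATUS_REJECTED_SCORE = "rejected_score"


@dataclass
class AlignmentParams:
    """Tunable penalties of the map aligner.

    sizing_cv
        Relative standard deviation assumed for fragment sizing error;
        the sizing cost of a block is ``((q-r)/(sizing_cv*r))**2``.
    miss_penalty / extra_penalty
        Cost per unmatched reference / query interior cut.
    max_block
        Maximum consecutive fragments merged into one block per side.
    accept_threshold
        Maximum mean cost per aligned query fragment.
    min_second_gap
        Minimum margin, in mean-cost units, by which the best placement
        must beat the best *distinct* placement (a different chromosome
        or a location separated by more than the molecule span).  This
        mapping-quality-style uniqueness test rejects molecules whose
        best placement is a chance hit; 0 disables it.  When no
        distinct second placement exists (reference barely longer than
        the molecule) the margin is treated as infinite.
    min_aligned_frags
        Molecules with fewer fragments are not alignable (too little
        information content) and are rejected outright.
    sizing_cap
        Optional cap on the per-block sizing cost.  Used by assembly's
        rescue realignment so a single large indel does not veto an
        otherwise clean alignment; 0 disables capping.
    """

    sizing_cv: float = 0.06
    miss_penalty: float = 9.0
    extra_penalty: float = 9.0
    max_block: int = 4
    accept_threshold: float = 6.0
    min_second_gap: float = 1.0
    min_aligned_frags: int = 8
    sizing_cap: float = 0.0

    def __post_init__(self) -> None:
        if self.sizing_cv <= 0 or self.miss_penalty <= 0 or self.extra_penalty <= 0:
            raise ValueError("alignment penalties must be positive")
        if self.max_block < 1:
            raise ValueError("max_block must be >= 1")


@dataclass
class RmapAlignment:
    """A monotone block matching of query fragments to a reference map."""

    molecule_id: str
    chrom: str
    orientation: str  # '+' or '-'
    blocks: list[tuple[int, int, int, int]]  # (ref_i0, ref_i1, q_i0, q_i1)
    total_cost: float
    n_missing_cuts: int
    n_extra_cuts: int
    ref_start_bp: int
    ref_end_bp: int
    midpoint_bp: int
    mean_cost: float
    n_query_frags: int
    capped_blocks: list[int] = field(default_factory=list)  # indices into blocks

    @property
    def start_boundary(self) -> int:
        return self.blocks[0][0] if self.blocks else 0

    @property
    def end_boundary(self) -> int:
        return self.blocks[-1][1] if self.blocks else 0


def block_cost(
    query_mass_kb: float,
    ref_mass_kb: float,
    params: AlignmentParams,
    q_frags: int = 1,
    r_frags: int = 1,
) -> float:
    """Cost of matching one query block against one reference block."""
    if query_mass_kb <= 0 or ref_mass_kb <= 0:
        raise ValueError("block masses must be positive")
    z = (query_mass_kb - ref_mass_kb) / (params.sizing_cv * ref_mass_kb)
    z2 = z * z
    if params.sizing_cap > 0:
        z2 = min(z2, params.sizing_cap)
    return z2 + (q_frags - 1) * params.extra_penalty + (r_frags - 1) * params.miss_penalty


def _align_oriented(
    qfrags: np.ndarray, ref: FragmentMap, params: AlignmentParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """DP table final row for an oriented query on one reference map.

    Returns (per-end-boundary mean costs, backpointer table, rcum) or
    None if the query has no interior fragment to score.
    """
    Q = qfrags.size
    if Q < 3:
        return None
    rcum = np.empty(ref.n_fragments + 1)
    rcum[0] = 0.0
    np.cumsum(ref.fragments, out=rcum[1:])
    qcum = np.empty(Q + 1)
    qcum[0] = 0.0
    np.cumsum(qfrags, out=qcum[1:])
    D, BP = dp_fill(
        rcum,
        qcum,
        params.max_block,
        params.sizing_cv,
        params.miss_penalty,
        params.extra_penalty,
        params.sizing_cap,
    )
    return D[Q - 2, :] / Q, BP, rcum


def _capped_block_indices(
    blocks: list[tuple[int, int, int, int]],
    qfrags: np.ndarray,
    ref: FragmentMap,
    params: AlignmentParams,
) -> list[int]:
    if params.sizing_cap <= 0:
        return []
    out = []
    for k, (ri0, ri1, qi0, qi1) in enumerate(blocks):
        q = float(qfrags[qi0:qi1].sum())
        r = float(ref.fragments[ri0:ri1].sum())
        z2 = ((q - r) / (params.sizing_cv * r)) ** 2
        if z2 > params.sizing_cap:
            out.append(k)
    return out


def align_rmap(
    rmap: Rmap,
    reference: GenomeMaps | FragmentMap,
    params: AlignmentParams | None = None,
) -> RmapAlignment | str:
    """Align one Rmap against a reference; return the best placement.

    Both orientations and all chromosomes are searched.  Ties break
    toward the forward orientation, then the lowest chromosome id, then
    the leftmost start.  Returns a status string (``rejected_short`` /
    ``rejected_score``) instead of an alignment when the molecule is
    uninformative or scores above the acceptance threshold.
    """
    params = params or AlignmentParams()
    if rmap.n_fragments < params.min_aligned_frags:
        return STATUS_REJECTED_SHORT
    if isinstance(reference, FragmentMap):
        ref_maps = {reference.chrom or reference.map_id: reference}
    else:
        ref_maps = reference.maps
    span_kb = rmap.total_mass_kb
    results = {}  # (chrom, orientation) -> (mean_costs, BP, rcum)
    best = None  # (sort_key, (chrom, orientation, end_i))
    for chrom in sorted(ref_maps):
        ref = ref_maps[chrom]
        for orientation in ("+", "-"):
            qfrags = rmap.fragments if orientation == "+" else rmap.fragments[::-1]
            res = _align_oriented(qfrags, ref, params)
            if res is None:
                continue
            mean_costs, BP, rcum = res
            end_i = int(np.argmin(mean_costs))
            if not np.isfinite(mean_costs[end_i]):
                continue
            results[(chrom, orientation)] = (mean_costs, BP, rcum)
            key = (float(mean_costs[end_i]), orientation != "+", chrom, float(rcum[end_i]))
            if best is None or key < best[0]:
                best = (key, (chrom, orientation, end_i))
    if best is None:
        return STATUS_REJECTED_SHORT
    chrom, orientation, end_i = best[1]
    mean_cost = best[0][0]
    if mean_cost > params.accept_threshold:
        return STATUS_REJECTED_SCORE
    if params.min_second_gap > 0:
        best_end_kb = float(results[(chrom, orientation)][2][end_i])
        second = np.inf
        for (c, _o), (mc, _bp, rc) in results.items():
            if c == chrom:
                distinct = np.abs(rc[: mc.size] - best_end_kb) > span_kb
                vals = mc[distinct]
            else:
                vals = mc
            if vals.size:
                second = min(second, float(np.min(vals)))
        if second - mean_cost < params.min_second_gap:
            return STATUS_REJECTED_SCORE
    mean_costs, BP, rcum = results[(chrom, orientation)]
    qfrags = rmap.fragments if orientation == "+" else rmap.fragments[::-1]
    blocks = traceback(BP, end_i, rmap.n_fragments)
    total = mean_cost * rmap.n_fragments
    ref = ref_maps[chrom]
    start_bp = max(0, ref.boundary_bp(blocks[0][0]) - int(round(qfrags[0] * 1000)))
    end_bp = min(
        ref.start_bp + ref.span_bp,
        ref.boundary_bp(blocks[-1][1]) + int(round(qfrags[-1] * 1000)),
    )
    n_miss = sum(b[1] - b[0] - 1 for b in blocks)
    n_extra = sum(b[3] - b[2] - 1 for b in blocks)
    return RmapAlignment(
        molecule_id=rmap.molecule_id,
        chrom=chrom,
        orientation=orientation,
        blocks=blocks,
        total_cost=total,
        n_missing_cuts=n_miss,
        n_extra_cuts=n_extra,
        ref_start_bp=start_bp,
        ref_end_bp=end_bp,
        midpoint_bp=(start_bp + end_bp) // 2,
        mean_cost=mean_cost,
        n_query_frags=rmap.n_fragments,
        capped_blocks=_capped_block_indices(blocks, qfrags, ref, params),
    )


ALIGNMENT_COLUMNS = [
    "molecule_id",
    "chrom",
    "start",
    "end",
    "orientation",
    "n_blocks",
    "cost",
    "midpoint",
    "status",
    "source_label",
]


def align_batch(
    rmaps: list[Rmap],
    reference: GenomeMaps | FragmentMap,
    params: AlignmentParams | None = None,
) -> tuple[pd.DataFrame, dict[str, RmapAlignment]]:
    """Align a collection of Rmaps; per-molecule results are independent.

    Returns the alignment table (one row per molecule, status in
    {aligned, rejected_short, rejected_score}) and the accepted
    alignments keyed by molecule id.
    """
    params = params or AlignmentParams()
    rows = []
    alignments: dict[str, RmapAlignment] = {}
    for rmap in rmaps:
        res = align_rmap(rmap, reference, params)
        if isinstance(res, str):
            rows.append(
                (rmap.molecule_id, ".", -1, -1, ".", 0, np.nan, -1, res, rmap.source_label)
            )
        else:
            alignments[rmap.molecule_id] = res
            rows.append(
                (
                    rmap.molecule_id,
                    res.chrom,
                    res.ref_start_bp,
                    res.ref_end_bp,
                    res.orientation,
                    len(res.blocks),
                    res.total_cost,
                    res.midpoint_bp,
                    STATUS_ALIGNED,
                    rmap.source_label,
                )
            )
    table = pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)
    return table, alignments
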