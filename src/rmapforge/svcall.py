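"""Classification of consensus-vs-reference map differences into
optical structural alterations (OSAs).

A window consensus map is aligned back to the in-silico reference map
(small reference fragments merged first) and each aligned block is
inspected:

* an unmatched reference interior cut is a **missing cut** (MC);
* an unmatched consensus interior cut is an **extra cut** (EC);
* a one-to-one block whose sizes differ by at least
  ``max(indel_rel * r, indel_min_kb)`` is an **insertion** (INS,
  consensus larger) or **deletion** (DEL, smaller);
* two or more cut and/or size differences within a short run of
  reference fragments collapse into one complex **OTHER** event.

Sub-threshold size differences are never called as indels; they
surface, if at all, as the cut differences they produce.

Each candidate is then scored against the single-molecule error model
(partial digestion, spurious cutting, sizing noise, desorption of
small fragments) and calls that are not significant after Bonferroni
correction over the tested loci are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignmentParams, align_rmap
from .assemble import ConsensusMap
from .core_maps import FragmentMap, GenomeMaps, Rmap, merge_small_fragments

OSA_CLASSES = ("EC", "MC", "INS", "DEL", "OTHER")


@dataclass
class CallThresholds:
    indel_rel: float = 0.13  # relative size change calling an indel
    indel_min_kb: float = 4.5  # absolute floor of the indel threshold
    merge_min_kb: float = 0.4  # reference small-fragment merging
    other_window_frags: int = 3  # run length that collapses into OTHER
    alpha: float = 0.05
    min_indel_evidence: int = 8  # molecules measuring the fragment mass

    def __post_init__(self) -> None:
        if min(self.indel_rel, self.indel_min_kb, self.merge_min_kb, self.alpha) <= 0:
            raise ValueError("thresholds must be positive")

    def indel_threshold_kb(self, ref_mass_kb: float) -> float:
        return max(self.indel_rel * ref_mass_kb, self.indel_min_kb)


@dataclass
class ErrorModelParams:
    """Single-molecule error rates used for significance scoring."""

    digest_efficiency: float = 0.8
    false_cut_rate_per_mb: float = 5.0
    sizing_cv: float = 0.06
    desorption_min_kb: float = 0.8
    desorption_drop_prob: float = 0.75
    resolution_kb: float = 3.0  # fragments below this are unreliably resolved


@dataclass
class OSA:
    """One optical structural alteration call."""

    osa_class: str
    chrom: str
    start_bp: int
    end_bp: int
    size_delta_kb: float  # signed; 0 for EC/MC
    n_support: int
    confidence_p: float = 1.0
    window_id: str = "."
    annotation: str = "."
    # evidence for scoring
    n_spanning: int = 0
    n_concordant: int = 0
    local_frag_kb: float = 0.0
    deviations_kb: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.osa_class not in OSA_CLASSES:
            raise ValueError(f"unknown OSA class {self.osa_class!r}")
        if self.osa_class in ("EC", "MC") and self.size_delta_kb != 0:
            raise ValueError("cut-difference calls carry no size delta")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start_bp, self.end_bp)


@dataclass
class _Event:
    kind: str  # 'EC' | 'MC' | 'SIZE'
    frag_lo: int  # reference fragment index range touched
    frag_hi: int
    start_bp: int
    end_bp: int
    delta_kb: float
    n_spanning: int
    n_concordant: int
    local_frag_kb: float
    deviations: list[float]


def _nearest_deleted_cut(consensus: ConsensusMap, pos_kb: float, tol_kb: float = 15.0):
    best = None
    for off, sp, co in consensus.deleted_cuts:
        d = abs(off - pos_kb)
        if d < tol_kb and (best is None or d < best[0]):
            best = (d, sp, co)
    return (best[1], best[2]) if best else (0, 0)


def classify_differences(
    consensus: ConsensusMap,
    reference: FragmentMap,
    thresholds: CallThresholds | None = None,
    align_params: AlignmentParams | None = None,
) -> list[OSA]:
    """Align a consensus map to the reference and classify differences.

    ``reference`` must already have small fragments merged
    (``merge_small_fragments`` at ``thresholds.merge_min_kb``).  Calls
    are restricted to the window core (margins belong to the adjacent
    windows) and returned sorted by coordinate.
    """
    thresholds = thresholds or CallThresholds()
    ap = align_params or AlignmentParams()
    # Classification wants a faithful decomposition, not a molecule filter:
    # accept the best placement unconditionally, cap the sizing cost (so a
    # large indel stays a 1:1 size difference instead of being reinterpreted
    # as a phantom extra-cut/missing-cut pair) and make cut differences
    # expensive enough that the DP invokes them only when unavoidable.
    ap = replace(
        ap,
        accept_threshold=float("inf"),
        min_second_gap=0.0,
        miss_penalty=50.0,
        extra_penalty=50.0,
        sizing_cap=100.0,
        min_aligned_frags=3,
    )
    # restrict the reference to the consensus neighborhood for speed
    sub_ref, offset_idx = _reference_neighborhood(consensus, reference)
    pseudo = Rmap(molecule_id=consensus.window_id, fragments=consensus.fragments)
    aln = align_rmap(pseudo, sub_ref, ap)
    if isinstance(aln, str):
        raise ValueError(f"consensus {consensus.window_id} failed to align: {aln}")
    if aln.orientation != "+":
        raise ValueError(f"consensus {consensus.window_id} aligned in reverse")
    events: list[_Event] = []
    qb = np.concatenate([[0.0], np.cumsum(consensus.fragments)])
    for ri0, ri1, qi0, qi1 in aln.blocks:
        r_mass = float(sub_ref.fragments[ri0:ri1].sum())
        q_mass = float(qb[qi1] - qb[qi0])
        blk_start = sub_ref.boundary_bp(ri0)
        blk_end = sub_ref.boundary_bp(ri1)
        # missing cuts: interior reference cuts consumed by the block
        for k in range(ri0 + 1, ri1):
            cut_bp = sub_ref.boundary_bp(k)
            cut_kb = (cut_bp - consensus.anchor_bp) / 1000.0
            sp, co = _nearest_deleted_cut(consensus, cut_kb)
            events.append(_Event(
                "MC", ri0, ri1, cut_bp, cut_bp + 1, 0.0, sp, co,
                min(float(sub_ref.fragments[k - 1]), float(sub_ref.fragments[k])),
                [],
            ))
        # extra cuts: interior consensus cuts inside the block
        for qc in range(qi0 + 1, qi1):
            frac = (qb[qc] - qb[qi0]) / max(q_mass, 1e-9)
            cut_bp = int(round(blk_start + frac * (blk_end - blk_start)))
            sp, co = (consensus.cut_support[qc - 1]
                      if 0 <= qc - 1 < len(consensus.cut_support) else (0, 0))
            events.append(_Event(
                "EC", ri0, ri1, cut_bp, cut_bp + 1, 0.0, sp, co,
                r_mass, [],
            ))
        # size difference over the block
        delta = q_mass - r_mass
        if abs(delta) >= thresholds.indel_threshold_kb(r_mass):
            devs: list[float] = []
            if qi1 - qi0 == 1 and qi0 < len(consensus.mass_evidence):
                devs = [m - r_mass for m in consensus.mass_evidence[qi0]]
            if len(devs) >= thresholds.min_indel_evidence:
                events.append(_Event(
                    "SIZE", ri0, ri1, blk_start, blk_end, delta,
                    len(devs), 0, r_mass, devs,
                ))
    osas = _collapse_events(events, consensus, thresholds)
    core_lo, core_hi = consensus.core_start_bp, consensus.core_end_bp
    if core_hi > core_lo:
        osas = [o for o in osas if core_lo <= (o.start_bp + o.end_bp) // 2 < core_hi]
    return sorted(osas, key=lambda o: (o.chrom, o.start_bp))


def _reference_neighborhood(
    consensus: ConsensusMap, reference: FragmentMap
) -> tuple[FragmentMap, int]:
    span_bp = int(round(float(consensus.fragments.sum()) * 1000))
    lo = max(0, consensus.anchor_bp - 100_000)
    hi = min(reference.span_bp, consensus.anchor_bp + span_bp + 100_000)
    if reference.cut_coords is None:
        return reference, 0
    cuts = reference.cut_coords
    i0 = int(np.searchsorted(cuts, lo, side="right"))
    i1 = int(np.searchsorted(cuts, hi, side="left"))
    inside = cuts[i0:i1]
    boundaries = np.concatenate([[lo], inside, [hi]])
    frags = np.diff(boundaries) / 1000.0
    sub = FragmentMap(
        map_id=f"{reference.map_id}_sub",
        chrom=reference.chrom,
        fragments=frags,
        cut_coords=inside if inside.size else None,
        origin=reference.origin,
        start_bp=lo,
    )
    return sub, i0


def _collapse_events(
    events: list[_Event], consensus: ConsensusMap, thresholds: CallThresholds
) -> list[OSA]:
    """Cluster nearby events; runs of >= 2 within the OTHER window
    become one complex call, singletons keep their own class."""
    if not events:
        return []
    events = sorted(events, key=lambda e: (e.frag_lo, e.start_bp))
    clusters: list[list[_Event]] = [[events[0]]]
    for ev in events[1:]:
        prev = clusters[-1]
        if ev.frag_lo - max(e.frag_hi for e in prev) < thresholds.other_window_frags - 1:
            prev.append(ev)
        else:
            clusters.append([ev])
    osas: list[OSA] = []
    for cl in clusters:
        if len(cl) == 1:
            ev = cl[0]
            if ev.kind == "SIZE":
                osa_class = "INS" if ev.delta_kb > 0 else "DEL"
                osas.append(OSA(
                    osa_class, consensus.chrom, ev.start_bp, ev.end_bp,
                    round(ev.delta_kb, 3), max(ev.n_spanning, len(ev.deviations)),
                    window_id=consensus.window_id,
                    n_spanning=ev.n_spanning, local_frag_kb=ev.local_frag_kb,
                    deviations_kb=ev.deviations,
                ))
            else:
                osas.append(OSA(
                    ev.kind, consensus.chrom, ev.start_bp, ev.end_bp, 0.0,
                    ev.n_concordant if ev.kind == "EC" else ev.n_spanning,
                    window_id=consensus.window_id,
                    n_spanning=ev.n_spanning, n_concordant=ev.n_concordant,
                    local_frag_kb=ev.local_frag_kb,
                ))
        else:
            start = min(e.start_bp for e in cl)
            end = max(e.end_bp for e in cl)
            delta = sum(e.delta_kb for e in cl)
            osas.append(OSA(
                "OTHER", consensus.chrom, start, end, round(delta, 3),
                max(max(e.n_spanning, e.n_concordant) for e in cl),
                window_id=consensus.window_id,
                n_spanning=max(e.n_spanning for e in cl),
                n_concordant=max(e.n_concordant for e in cl),
                local_frag_kb=float(np.mean([e.local_frag_kb for e in cl])),
                deviations_kb=sum((e.deviations for e in cl), []),
            ))
    return osas


# ---------------------------------------------------------------------------
# Significance scoring
# ---------------------------------------------------------------------------


def cut_detection_prob(error: ErrorModelParams, flank_left_kb: float,
                       flank_right_kb: float) -> float:
    """Per-molecule probability of observing a reference cut as a
    distinct, matchable cut.

    The site must be digested; when a flanking fragment is below the
    desorption threshold that fragment must also be retained (a
    desorbed fragment collapses its two cuts into one); and a flanking
    fragment below the platform's resolution makes the cut position
    unreliable in proportion to its size."""
    p = error.digest_efficiency
    for flank in (flank_left_kb, flank_right_kb):
        if flank < error.desorption_min_kb:
            p *= 1.0 - error.desorption_drop_prob
        elif flank < error.resolution_kb:
            p *= flank / error.resolution_kb
    return p


def score_variant(osa: OSA, error: ErrorModelParams | None = None,
                  flanks_kb: tuple[float, float] | None = None) -> float:
    """Significance of an OSA under the single-molecule error model.

    EC: binomial tail for >= k molecules showing a spurious cut over
    the local fragment.  MC: binomial tail for <= k molecules showing
    a cut that should be detected with the desorption-aware detection
    probability.  INS/DEL: two-sided normal tail for the mean block
    sizing deviation.  OTHER is scored as its strongest component.
    """
    error = error or ErrorModelParams()
    if osa.osa_class == "EC":
        n, k = osa.n_spanning, osa.n_concordant
        if n == 0:
            raise ValueError("EC with no spanning molecules")
        p_false = min(1.0, error.false_cut_rate_per_mb * osa.local_frag_kb / 1000.0)
        return float(stats.binom.sf(k - 1, n, p_false))
    if osa.osa_class == "MC":
        n, k = osa.n_spanning, osa.n_concordant
        if n == 0:
            raise ValueError("MC with no spanning molecules")
        if flanks_kb is None:
            flanks_kb = (osa.local_frag_kb, osa.local_frag_kb)  # min flank twice
        p_det = cut_detection_prob(error, *flanks_kb)
        return float(stats.binom.cdf(k, n, p_det))
    if osa.osa_class in ("INS", "DEL"):
        devs = np.asarray(osa.deviations_kb, dtype=float)
        if devs.size == 0:
            raise ValueError("indel call without supporting mass evidence")
        se = error.sizing_cv * osa.local_frag_kb / np.sqrt(devs.size)
        z = float(np.mean(devs)) / max(se, 1e-9)
        return float(2.0 * stats.norm.sf(abs(z)))
    # OTHER: strongest component interpretation
    ps = []
    if osa.n_spanning > 0:
        ec = replace(osa, osa_class="EC", size_delta_kb=0.0)
        ps.append(score_variant(ec, error))
        mc = replace(osa, osa_class="MC", size_delta_kb=0.0)
        ps.append(score_variant(mc, error))
    if osa.deviations_kb:
        ind = replace(osa, osa_class="INS" if osa.size_delta_kb >= 0 else "DEL")
        ps.append(score_variant(ind, error))
    return float(min(ps)) if ps else 1.0


def osa_from_targeted_verdict(
    chrom: str,
    start_bp: int,
    size_bp: int,
    verdict,
) -> OSA | None:
    """Report a rearrangement established by targeted assembly.

    Inversions are not emitted by the block classifier; a supported
    hypothesis becomes an OTHER call annotated as inversion-supported,
    with the weaker breakpoint's bridge count as support.
    """
    if not verdict.supported:
        return None
    return OSA(
        "OTHER", chrom, start_bp, start_bp + size_bp, 0.0,
        min(verdict.bridge_left, verdict.bridge_right),
        annotation="inversion-supported",
    )


def call_genome(
    consensus_maps: dict[str, ConsensusMap],
    reference: GenomeMaps,
    thresholds: CallThresholds | None = None,
    error: ErrorModelParams | None = None,
    align_params: AlignmentParams | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify and score every assembled window; deduplicate calls
    shared by overlapping windows (keep the higher-support call).

    Returns the OSA table and per-class counts.
    """
    from .compare import IntersectionRules  # local import, no cycle at module load

    thresholds = thresholds or CallThresholds()
    error = error or ErrorModelParams()
    rules = IntersectionRules()
    merged_ref = {c: merge_small_fragments(m, thresholds.merge_min_kb)
                  for c, m in reference.maps.items()}
    candidates: list[OSA] = []
    for wid in sorted(consensus_maps):
        cm = consensus_maps[wid]
        if cm.status != "assembled":
            continue
        candidates.extend(
            classify_differences(cm, merged_ref[cm.chrom], thresholds, align_params)
        )
    # every reference cut is an implicit missing-cut test and every
    # fragment an implicit indel / extra-cut test, so the multiple-testing
    # burden is the number of loci examined, not the number of candidates
    n_tested = max(sum(2 * m.n_fragments - 1 for m in merged_ref.values()), 1)
    kept: list[OSA] = []
    for osa in candidates:
        try:
            osa.confidence_p = score_variant(osa, error)
        except ValueError:
            osa.confidence_p = 1.0
        if osa.confidence_p <= thresholds.alpha / n_tested:
            kept.append(osa)
    deduped = _dedup(kept, rules)
    counts = {c: 0 for c in OSA_CLASSES}
    rows = []
    for osa in deduped:
        counts[osa.osa_class] += 1
        rows.append({
            "chrom": osa.chrom,
            "start": osa.start_bp,
            "end": osa.end_bp,
            "class": osa.osa_class,
            "delta_kb": osa.size_delta_kb,
            "support": osa.n_support,
            "confidence_p": osa.confidence_p,
            "window_id": osa.window_id,
            "annotation": osa.annotation,
        })
    table = pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "class", "delta_kb", "support",
        "confidence_p", "window_id", "annotation",
    ])
    return table, counts


def _dedup(osas: list[OSA], rules) -> list[OSA]:
    """Collapse same-class calls from overlapping windows whose
    class-window-expanded intervals overlap, keeping higher support."""
    out: list[OSA] = []
    for osa in sorted(osas, key=lambda o: (o.chrom, o.osa_class, o.start_bp)):
        w = rules.om_windows.get(osa.osa_class, 0)
        merged = False
        for prev in out:
            if prev.chrom != osa.chrom or prev.osa_class != osa.osa_class:
                continue
            if prev.start_bp - w < osa.end_bp + w and osa.start_bp - w < prev.end_bp + w:
                if osa.n_support > prev.n_support or (
                    osa.n_support == prev.n_support
                    and osa.confidence_p < prev.confidence_p
                ):
                    out[out.index(prev)] = osa
                merged = True
                break
        if merged:
            continue
        out.append(osa)
    return sorted(out, key=lambda o: (o.chrom, o.start_bp))
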