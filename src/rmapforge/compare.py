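"""Intersection of OSA call sets with variant panels and gene annotation.

Matching is type-aware: only events of corresponding types are
compared, and each OSA class carries its own intersection window
reflecting its positional uncertainty (a missing cut is located to
within ~100 bp, an extra cut only to within a few kb, indels and
complex events are anchored to reference fragments and use no window).
Sequence-derived external panels are routed by event size: events
below 3 kb are under the optical resolution limit and manifest, if at
all, as cut differences, so they are compared against ECs and MCs;
larger events are compared against INS/DEL/OTHER directly.

"Intersection window" means symmetric expansion of the OSA interval by
w bp followed by a >= 1 bp half-open overlap test; cut-class OSAs are
treated as 1 bp intervals at the inferred cut coordinate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

OM_PANEL = "om"
SNP_PANEL = "snp"
EXTERNAL_PANEL = "external"


@dataclass
class IntersectionRules:
    om_windows: dict[str, int] = field(
        default_factory=lambda: {"MC": 100, "EC": 4200, "INS": 0, "DEL": 0, "OTHER": 0}
    )
    snp_windows: dict[str, int] = field(
        default_factory=lambda: {"MC": 100, "EC": 3000}
    )
    external_size_partition_bp: int = 3000

    def __post_init__(self) -> None:
        if any(w < 0 for w in {**self.om_windows, **self.snp_windows}.values()):
            raise ValueError("intersection windows must be >= 0")


def _panel_trees(panel: pd.DataFrame) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for row in panel.to_dict("records"):
        key = (str(row["chrom"]), str(row["name"]))
        trees.setdefault(key, IntervalTree()).addi(
            int(row["start"]), max(int(row["end"]), int(row["start"]) + 1)
        )
    return trees


def _classes_and_window(
    osa_class: str, panel_kind: str, event_size_bp: int, rules: IntersectionRules
) -> tuple[list[str], int] | None:
    """Panel record classes an OSA of ``osa_class`` is compared to, and
    the window, or None when the types do not correspond."""
    if panel_kind == OM_PANEL:
        return [osa_class], rules.om_windows[osa_class]
    if panel_kind == SNP_PANEL:
        if osa_class in rules.snp_windows:
            return ["SNP"], rules.snp_windows[osa_class]
        return None
    if panel_kind == EXTERNAL_PANEL:
        small = event_size_bp < rules.external_size_partition_bp
        if osa_class in ("EC", "MC"):
            return (["INS", "DEL", "SNP", "SV"], rules.om_windows[osa_class]) if small else None
        if osa_class in ("INS", "DEL", "OTHER"):
            return (None if small else (["INS", "DEL", "SV", "OTHER"], 0))
        return None
    raise ValueError(f"unknown panel kind {panel_kind!r}")


def intersect(
    osas: pd.DataFrame,
    panel: pd.DataFrame,
    rules: IntersectionRules | None = None,
    panel_kind: str = OM_PANEL,
) -> pd.DataFrame:
    """Match OSAs against one typed panel.

    ``osas`` needs columns chrom/start/end/class; ``panel`` is BED4+
    with the record type in the name column.  Returns the OSA table
    with ``matched`` and ``nearest_bp`` columns appended.
    """
    rules = rules or IntersectionRules()
    known = {"EC", "MC", "INS", "DEL", "OTHER", "SNP", "SV"}
    bad = set(panel["name"].astype(str)) - known
    if bad:
        raise ValueError(f"unknown class in panel: {sorted(bad)}")
    trees = _panel_trees(panel)
    matched = []
    nearest = []
    for row in osas.to_dict("records"):
        if panel_kind == EXTERNAL_PANEL:
            # routing is per panel record; test both partitions
            hit, near = _match_external(row, trees, rules)
        else:
            cw = _classes_and_window(row["class"], panel_kind, 0, rules)
            hit, near = _match(row, trees, cw)
        matched.append(hit)
        nearest.append(near)
    out = osas.copy()
    out["matched"] = matched
    out["nearest_bp"] = nearest
    return out


def _osa_interval(row: dict) -> tuple[int, int]:
    start, end = int(row["start"]), int(row["end"])
    if row["class"] in ("EC", "MC"):
        cut = (start + end) // 2
        return cut, cut + 1
    return start, end


def _match(row: dict, trees, cw) -> tuple[bool, float]:
    if cw is None:
        return False, np.inf
    classes, w = cw
    a, b = _osa_interval(row)
    hit = False
    near = np.inf
    for cls in classes:
        tree = trees.get((str(row["chrom"]), cls))
        if tree is None:
            continue
        if tree.overlap(a - w, b + w):
            hit = True
        for iv in tree:
            d = max(iv.begin - b + 1, a - iv.end + 1, 0)
            near = min(near, d)
    return hit, near


def _match_external(row: dict, trees, rules) -> tuple[bool, float]:
    cls = row["class"]
    a, b = _osa_interval(row)
    hit = False
    near = np.inf
    for (chrom, _pcls), tree in trees.items():
        if chrom != str(row["chrom"]):
            continue
        for iv in tree:
            size = iv.end - iv.begin
            small = size < rules.external_size_partition_bp
            if cls in ("EC", "MC"):
                if not small:
                    continue
                w = rules.om_windows[cls]
            elif cls in ("INS", "DEL", "OTHER"):
                if small:
                    continue
                w = 0
            else:
                continue
            d = max(iv.begin - b + 1, a - iv.end + 1, 0)
            near = min(near, d)
            if iv.begin < b + w and a - w < iv.end:
                hit = True
    return hit, near


def filter_somatic(
    osas: pd.DataFrame,
    panels: dict[str, tuple[pd.DataFrame, str]],
    rules: IntersectionRules | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Remove OSAs matched in any panel; keep the rest as candidates.

    ``panels`` maps panel name to (BED4+ DataFrame, panel kind).
    Returns (candidates, removed, per-panel match tallies);
    candidates and removed partition the input.
    """
    rules = rules or IntersectionRules()
    if not panels:
        warnings.warn("no panels supplied; every OSA is a candidate", stacklevel=2)
        return osas.copy(), osas.iloc[0:0].copy(), {}
    matched_any = np.zeros(len(osas), dtype=bool)
    tallies: dict[str, int] = {}
    for name in panels:
        panel, kind = panels[name]
        res = intersect(osas, panel, rules, panel_kind=kind)
        hits = res["matched"].to_numpy(dtype=bool)
        tallies[name] = int(hits.sum())
        matched_any |= hits
    candidates = osas.loc[~matched_any].copy()
    removed = osas.loc[matched_any].copy()
    return candidates, removed, tallies


def annotate_genes(osas: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Append overlapping gene names (half-open, >= 1 bp overlap)."""
    trees: dict[str, IntervalTree] = {}
    for row in genes.to_dict("records"):
        trees.setdefault(str(row["chrom"]), IntervalTree()).addi(
            int(row["start"]), int(row["end"]), str(row["name"])
        )
    out = osas.copy()
    hits = []
    for row in osas.to_dict("records"):
        tree = trees.get(str(row["chrom"]))
        names = (sorted({iv.data for iv in tree.overlap(int(row["start"]), int(row["end"]))})
                 if tree else [])
        hits.append(",".join(names) if names else ".")
    out["genes"] = hits
    return out
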