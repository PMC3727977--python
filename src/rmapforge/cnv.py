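"""Copy-number inference from aligned-Rmap coverage.

Each accepted alignment is summarized by its midpoint.  Midpoints from
a *normal* (diploid) dataset define intervals holding a fixed number
``m`` of normal midpoints each: where restriction sites are dense and
alignment is easy the intervals are narrow, where coverage is
intrinsically thin they are wide, so equal tumor counts per interval
mean equal relative copy number.  Tumor midpoint counts per interval
are then modeled with a hidden Markov chain over integer copy states
whose negative-binomial emissions have mean proportional to the state;
the Viterbi path segments the genome into constant-copy-number runs.

Per-slice analysis repeats the whole chain per source label and
reports the intervals where the decoded states disagree — the
signature of intra-tumor heterogeneity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .align import STATUS_ALIGNED


@dataclass
class CoverageInterval:
    chrom: str
    start_bp: int
    end_bp: int
    normal_count: int
    tumor_count: int = 0


@dataclass
class CnvModel:
    """Negative-binomial emission HMM over integer copy-number states.

    The emission mean of state ``k`` is ``baseline_rate * k / 2``
    (state 0 floored at 5% of baseline so the likelihood stays proper);
    the variance is ``mean + dispersion * mean**2``.  ``stay_prob``
    close to 1 encodes that copy number changes rarely along the
    genome, favoring arm-scale segments.
    """

    states: tuple[int, ...] = (0, 1, 2, 3, 4)
    baseline_rate: float = 10.0  # expected count per interval at copy 2
    dispersion: float = 0.01
    stay_prob: float = 1 - 1e-4

    def __post_init__(self) -> None:
        if not 0 < self.stay_prob < 1:
            raise ValueError("stay_prob must be in (0, 1)")
        if self.baseline_rate <= 0 or self.dispersion < 0:
            raise ValueError("baseline_rate and dispersion must be positive")

    def state_mean(self, state: int) -> float:
        return max(self.baseline_rate * state / 2.0, 0.05 * self.baseline_rate)

    def emission_logpmf(self, counts: np.ndarray) -> np.ndarray:
        """Log-likelihood matrix, shape (n_intervals, n_states)."""
        counts = np.asarray(counts)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        out = np.empty((counts.size, len(self.states)))
        phi = max(self.dispersion, 1e-9)
        r = 1.0 / phi  # NB size parameter; variance = m + phi m^2
        for j, k in enumerate(self.states):
            m = self.state_mean(k)
            p = r / (r + m)
            out[:, j] = (
                gammaln(counts + r) - gammaln(r) - gammaln(counts + 1)
                + r * np.log(p) + counts * np.log1p(-p)
            )
        return out


@dataclass
class CopyNumberSegment:
    chrom: str
    start_bp: int
    end_bp: int
    state: int
    mean_normalized_count: float
    n_intervals: int


def midpoints(alignment_table: pd.DataFrame) -> dict[str, np.ndarray]:
    """Sorted alignment midpoints per chromosome (accepted alignments only)."""
    out: dict[str, np.ndarray] = {}
    if len(alignment_table) == 0:
        return out
    ok = alignment_table[alignment_table["status"] == STATUS_ALIGNED]
    for chrom, grp in ok.groupby("chrom"):
        out[str(chrom)] = np.sort(grp["midpoint"].to_numpy(dtype=np.int64))
    return out


def build_intervals(
    normal_midpoints: dict[str, np.ndarray],
    chrom_lengths: dict[str, int],
    m: int = 10,
) -> list[CoverageInterval]:
    """Per chromosome, boundaries after every ``m``-th normal midpoint.

    Interval boundaries bisect consecutive midpoints so each interval
    holds exactly ``m`` normal midpoints (the last keeps the
    remainder).  A chromosome with fewer than ``m`` midpoints becomes
    a single whole-chromosome interval, with a warning.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    intervals: list[CoverageInterval] = []
    for chrom in sorted(chrom_lengths):
        L = int(chrom_lengths[chrom])
        mids = np.sort(np.asarray(normal_midpoints.get(chrom, np.empty(0)), dtype=np.int64))
        if mids.size < m:
            warnings.warn(
                f"{chrom}: only {mids.size} normal midpoints (< m={m}); "
                "using one whole-chromosome interval",
                stacklevel=2,
            )
            intervals.append(CoverageInterval(chrom, 0, L, int(mids.size)))
            continue
        cut_idx = np.arange(m, mids.size, m)
        # drop a trailing boundary that would isolate fewer than m midpoints?
        # no: the last interval holds the remainder, so merge the tail
        if mids.size - (cut_idx[-1] if cut_idx.size else 0) < 1:
            cut_idx = cut_idx[:-1]
        bounds = [0]
        for i in cut_idx:
            b = int((mids[i - 1] + mids[i]) // 2)
            b = min(max(b, bounds[-1] + 1), L - 1)
            bounds.append(b)
        bounds.append(L)
        for a, b in zip(bounds[:-1], bounds[1:]):
            n_in = int(np.searchsorted(mids, b) - np.searchsorted(mids, a))
            intervals.append(CoverageInterval(chrom, a, b, n_in))
    return intervals


def count_in_intervals(
    intervals: list[CoverageInterval], mids: dict[str, np.ndarray]
) -> np.ndarray:
    counts = np.zeros(len(intervals), dtype=np.int64)
    for i, iv in enumerate(intervals):
        x = mids.get(iv.chrom)
        if x is None:
            continue
        counts[i] = np.searchsorted(x, iv.end_bp) - np.searchsorted(x, iv.start_bp)
    return counts


def fit_model(
    tumor_counts: np.ndarray,
    states: tuple[int, ...] = (0, 1, 2, 3, 4),
    stay_prob: float = 1 - 1e-4,
) -> CnvModel:
    """Anchor the diploid rate at the median count and estimate the
    negative-binomial overdispersion by method of moments.

    The median-as-diploid anchor assumes aberrations cover less than
    half the genome; when they cover more, the baseline is wrong by
    construction.  A strongly bimodal count histogram triggers a
    warning for that failure mode.
    """
    counts = np.asarray(tumor_counts, dtype=float)
    if counts.size < 20:
        raise ValueError(f"need >= 20 intervals to fit, got {counts.size}")
    mu = float(np.median(counts))
    if mu <= 0:
        raise ValueError("median tumor count is zero; data too thin")
    central = counts[(counts >= 0.5 * mu) & (counts <= 1.5 * mu)]
    mean_c = float(np.mean(central))
    var_c = float(np.var(central, ddof=1)) if central.size > 1 else mean_c
    phi = max(0.0, (var_c - mean_c) / mean_c**2)
    frac_low = float(np.mean(counts < 0.65 * mu))
    frac_high = float(np.mean(counts > 1.55 * mu))
    frac_center = float(np.mean((counts >= 0.85 * mu) & (counts <= 1.15 * mu)))
    if frac_low > 0.25 or frac_high > 0.25 or frac_center < 0.25:
        # a thin center means the median fell into the valley between two
        # copy-number modes
        warnings.warn(
            "count histogram looks bimodal; the median-as-diploid anchor "
            "may be misplaced (more than half the genome aberrant?)",
            stacklevel=2,
        )
    return CnvModel(states=tuple(states), baseline_rate=mu, dispersion=phi,
                    stay_prob=stay_prob)


def viterbi_decode(
    intervals: list[CoverageInterval],
    tumor_counts: np.ndarray,
    model: CnvModel,
) -> tuple[np.ndarray, list[CopyNumberSegment]]:
    """Max-product decoding in log space, restarted per chromosome.

    Returns the per-interval state path and the maximal constant-state
    segments (which tile the decoded intervals).
    """
    counts = np.asarray(tumor_counts)
    if counts.size != len(intervals):
        raise ValueError("counts and intervals differ in length")
    K = len(model.states)
    log_trans = np.full((K, K), np.log((1 - model.stay_prob) / (K - 1)))
    np.fill_diagonal(log_trans, np.log(model.stay_prob))
    log_init = np.full(K, -np.log(K))
    path = np.empty(counts.size, dtype=np.int64)
    chroms = [iv.chrom for iv in intervals]
    segments: list[CopyNumberSegment] = []
    i = 0
    while i < len(intervals):
        j = i
        while j < len(intervals) and chroms[j] == chroms[i]:
            j += 1
        emis = model.emission_logpmf(counts[i:j])
        path[i:j] = _viterbi(emis, log_init, log_trans)
        segments.extend(
            _segments_from_path(intervals[i:j], counts[i:j], path[i:j], model)
        )
        i = j
    return path, segments


def _viterbi(emis: np.ndarray, log_init: np.ndarray, log_trans: np.ndarray) -> np.ndarray:
    n, K = emis.shape
    delta = log_init + emis[0]
    back = np.zeros((n, K), dtype=np.int64)
    for t in range(1, n):
        scores = delta[:, None] + log_trans
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(K)] + emis[t]
    out = np.empty(n, dtype=np.int64)
    out[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        out[t - 1] = back[t, out[t]]
    return out


def _segments_from_path(intervals, counts, path, model) -> list[CopyNumberSegment]:
    segs = []
    i = 0
    while i < len(intervals):
        j = i
        while j < len(intervals) and path[j] == path[i]:
            j += 1
        segs.append(
            CopyNumberSegment(
                chrom=intervals[i].chrom,
                start_bp=intervals[i].start_bp,
                end_bp=intervals[j - 1].end_bp,
                state=int(model.states[path[i]]),
                mean_normalized_count=float(np.mean(counts[i:j])) / model.baseline_rate,
                n_intervals=j - i,
            )
        )
        i = j
    return segs


@dataclass
class SliceCnvResult:
    intervals: list[CoverageInterval]
    per_label: dict[str, tuple[np.ndarray, list[CopyNumberSegment]]]
    discordant: pd.DataFrame  # intervals whose decoded state differs


def per_slice_cnv(
    alignment_table: pd.DataFrame,
    normal_midpoints: dict[str, np.ndarray],
    chrom_lengths: dict[str, int],
    m: int = 10,
    states: tuple[int, ...] = (0, 1, 2, 3, 4),
) -> SliceCnvResult:
    """Run the full coverage pipeline separately per source label and
    report intervals whose decoded copy state differs between labels."""
    intervals = build_intervals(normal_midpoints, chrom_lengths, m)
    labels = sorted(
        set(alignment_table.loc[alignment_table["status"] == STATUS_ALIGNED,
                                "source_label"])
    )
    per_label = {}
    for label in labels:
        sub = alignment_table[alignment_table["source_label"] == label]
        mids = midpoints(sub)
        counts = count_in_intervals(intervals, mids)
        try:
            model = fit_model(counts, states=states)
        except ValueError as exc:
            warnings.warn(f"slice {label!r} skipped: {exc}", stacklevel=2)
            continue
        path, segs = viterbi_decode(intervals, counts, model)
        per_label[label] = (path, segs)
    rows = []
    if len(per_label) >= 2:
        labs = sorted(per_label)
        paths = np.stack([per_label[l][0] for l in labs])
        diff = np.any(paths != paths[0], axis=0)
        for i in np.where(diff)[0]:
            rows.append({
                "chrom": intervals[i].chrom,
                "start": intervals[i].start_bp,
                "end": intervals[i].end_bp,
                **{f"state_{l}": int(paths[k][i]) for k, l in enumerate(labs)},
            })
    discordant = pd.DataFrame(rows)
    return SliceCnvResult(intervals=intervals, per_label=per_label, discordant=discordant)
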