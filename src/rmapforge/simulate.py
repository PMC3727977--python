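"""Synthetic tumor optical-mapping datasets with a machine-readable truth set.

The generator emulates the data a single-molecule optical-mapping run
produces from a solid tumor: a reference genome, tumor genomes derived
from it by implanted structural variants and per-"slice" copy-number
profiles, and single-molecule Rmaps drawn under a parameterized error
model (partial digestion, spurious cuts, multiplicative sizing noise,
and desorption of small fragments).

Every source of randomness flows from the single configuration seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_maps import SWAI_CUT_OFFSET, SWAI_SITE, FragmentMap, GenomeMaps, Rmap

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

VARIANT_TYPES = ("INS", "DEL", "INV", "SITE_GAIN", "SITE_LOSS")


@dataclass
class VariantSpec:
    """A structural variant to implant into a simulated genome."""

    type: str
    chrom: str
    position_bp: int
    size_bp: int = 0  # 0 for site changes

    def __post_init__(self) -> None:
        if self.type not in VARIANT_TYPES:
            raise ValueError(f"unknown variant type {self.type!r}")
        if self.type in ("INS", "DEL", "INV") and self.size_bp <= 0:
            raise ValueError(f"{self.type} requires size_bp > 0")

    @property
    def ref_span(self) -> tuple[int, int]:
        if self.type in ("DEL", "INV"):
            return (self.position_bp, self.position_bp + self.size_bp)
        if self.type in ("SITE_GAIN", "SITE_LOSS"):
            return (self.position_bp, self.position_bp + len(SWAI_SITE))
        return (self.position_bp, self.position_bp)  # INS


@dataclass
class MoleculeLength:
    """Gamma-distributed molecule length, truncated from below.

    High-molecular-weight DNA preparations yield right-skewed length
    distributions in the 300 kb - >500 kb range with a mean above
    400 kb; a gamma with moderate shape, resampled below ``min_kb``,
    reproduces that.
    """

    mean_kb: float = 420.0
    min_kb: float = 300.0
    shape: float = 7.0


@dataclass
class Desorption:
    """Small surface-bound fragments detach and go unobserved."""

    min_kb: float = 0.8
    drop_prob: float = 0.75


@dataclass
class Subclone:
    """One tumor cell population ("slice") with its own genome."""

    label: str
    fraction: float
    copy_profile: list[tuple[str, int, int, int]] = field(default_factory=list)
    #: regions as (chrom, start_bp, end_bp, copy); unlisted regions are copy 2
    variants: list[VariantSpec] = field(default_factory=list)


@dataclass
class SimulationConfig:
    seed: int = 0
    coverage: float = 30.0
    molecule_length: MoleculeLength = field(default_factory=MoleculeLength)
    digest_efficiency: float = 0.8  # probability a true site is cut
    false_cut_rate_per_mb: float = 5.0
    sizing_cv: float = 0.06
    desorption: Desorption = field(default_factory=Desorption)
    subclones: list[Subclone] = field(default_factory=lambda: [Subclone("s1", 1.0)])
    chimera_rate: float = 0.0  # chimeric molecules off by default

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not self.subclones:
            raise ValueError("at least one subclone is required")
        if not 0 < self.digest_efficiency <= 1:
            raise ValueError("digest_efficiency must be in (0, 1]")
        if self.false_cut_rate_per_mb < 0 or self.sizing_cv < 0:
            raise ValueError("rates must be >= 0")
        total = sum(s.fraction for s in self.subclones)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subclone fractions sum to {total}, expected 1")


@dataclass
class TruthSet:
    """Ground truth of a simulation: implanted variants per subclone
    (with post-implant coordinates) and copy number per region."""

    variants: pd.DataFrame  # subclone, type, chrom, ref_pos, post_pos, size_bp
    copy_profile: pd.DataFrame  # subclone, chrom, start, end, copy

    def to_json(self, path: str | Path) -> None:
        payload = {
            "variants": self.variants.to_dict(orient="records"),
            "copy_profile": self.copy_profile.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def simulate_reference(
    chrom_lengths: dict[str, int],
    gc_fraction: float = 0.41,
    seed: int = 0,
) -> tuple[dict[str, str], GenomeMaps]:
    """Simulate an i.i.d. reference genome and its in-silico digest.

    The default GC fraction of 0.41 mirrors the human genome; because
    the recognition site is AT-rich, GC content controls cut density
    (lower GC, denser cuts).
    """
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    at = (1 - gc_fraction) / 2
    gc = gc_fraction / 2
    p = np.array([at, gc, gc, at])
    sequences = {}
    for chrom, L in chrom_lengths.items():
        if L <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length")
        idx = rng.choice(4, size=L, p=p)
        sequences[chrom] = _BASES[idx].tobytes().decode("ascii")
    return sequences, GenomeMaps.from_sequences(sequences)


def _random_site_free(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, 4, size=n)
    seq = bytearray(_BASES[idx].tobytes())
    site = SWAI_SITE.encode()
    pos = bytes(seq).find(site)
    while pos != -1:
        seq[pos + SWAI_CUT_OFFSET] = ord("G")  # break the site
        pos = bytes(seq).find(site, pos)
    return seq.decode("ascii")


def find_site_gain_positions(sequence: str, limit: int = 1000) -> list[tuple[int, int, str]]:
    """Positions where one substitution creates a recognition site.

    Returns (window_start, offset_in_window, new_base) triples for
    windows at Hamming distance 1 from the site, skipping windows that
    already contain or abut a site.
    """
    site = SWAI_SITE
    seq = sequence.upper()
    out = []
    k = len(site)
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        mism = [j for j in range(k) if window[j] != site[j]]
        if len(mism) == 1:
            out.append((i, mism[0], site[mism[0]]))
            if len(out) >= limit:
                break
    return out


def implant_variants(
    sequences: dict[str, str],
    specs: list[VariantSpec],
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Apply variants to a genome; return the altered sequences and a
    truth table with post-implant coordinates.

    DEL removes ``size_bp`` bases; INS inserts ``size_bp`` novel
    site-free bases; INV reverse-complements the interval; SITE_GAIN /
    SITE_LOSS apply a single-base substitution creating / destroying
    exactly one recognition site (the position must be at Hamming
    distance 1 from / contain a site).
    """
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[VariantSpec]] = {}
    for s in specs:
        by_chrom.setdefault(s.chrom, []).append(s)
    comp = str.maketrans("ACGTN", "TGCAN")
    out_seqs = dict(sequences)
    records = []
    for chrom, chrom_specs in by_chrom.items():
        seq = sequences[chrom]
        L = len(seq)
        chrom_specs = sorted(chrom_specs, key=lambda s: s.position_bp)
        prev_end = -1
        for s in chrom_specs:
            a, b = s.ref_span
            if a < prev_end:
                raise ValueError(f"overlapping variant specs on {chrom}")
            if b > L or a < 0:
                raise ValueError(f"variant outside chromosome {chrom}")
            prev_end = max(b, a + 1)
        # apply right-to-left so earlier coordinates stay valid
        shift = 0  # cumulative length change left of a position (built L->R)
        pieces = []
        cursor = 0
        for s in chrom_specs:
            p = s.position_bp
            post_pos = p + shift
            if s.type == "DEL":
                pieces.append(seq[cursor:p])
                cursor = p + s.size_bp
                shift -= s.size_bp
                size = -s.size_bp
            elif s.type == "INS":
                pieces.append(seq[cursor:p])
                pieces.append(_random_site_free(rng, s.size_bp))
                cursor = p
                shift += s.size_bp
                size = s.size_bp
            elif s.type == "INV":
                pieces.append(seq[cursor:p])
                segment = seq[p : p + s.size_bp]
                pieces.append(segment.translate(comp)[::-1])
                cursor = p + s.size_bp
                size = s.size_bp
            elif s.type == "SITE_LOSS":
                if seq[p : p + len(SWAI_SITE)].upper() != SWAI_SITE:
                    raise ValueError(f"SITE_LOSS at {chrom}:{p}: no site present")
                pieces.append(seq[cursor : p + SWAI_CUT_OFFSET])
                pieces.append("G")
                cursor = p + SWAI_CUT_OFFSET + 1
                size = 0
            elif s.type == "SITE_GAIN":
                window = seq[p : p + len(SWAI_SITE)].upper()
                mism = [j for j in range(len(SWAI_SITE)) if window[j] != SWAI_SITE[j]]
                if len(mism) != 1:
                    raise ValueError(
                        f"SITE_GAIN at {chrom}:{p}: window not at Hamming distance 1"
                    )
                j = mism[0]
                pieces.append(seq[cursor : p + j])
                pieces.append(SWAI_SITE[j])
                cursor = p + j + 1
                size = 0
            records.append(
                {
                    "type": s.type,
                    "chrom": chrom,
                    "ref_pos": p,
                    "post_pos": post_pos,
                    "size_bp": size if s.type in ("INS", "DEL") else s.size_bp,
                }
            )
        pieces.append(seq[cursor:])
        out_seqs[chrom] = "".join(pieces)
    return out_seqs, pd.DataFrame(records)


def _copy_weights(
    genome: GenomeMaps, profile: list[tuple[str, int, int, int]]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome piecewise-constant copy weights as (boundaries, copies)."""
    out = {}
    for chrom, fmap in genome.maps.items():
        L = fmap.span_bp
        cuts = sorted({0, L} | {
            min(max(x, 0), L)
            for (c, s, e, _copy) in profile
            if c == chrom
            for x in (s, e)
        })
        bounds = np.asarray(cuts, dtype=np.int64)
        copies = np.full(len(bounds) - 1, 2.0)
        for (c, s, e, copy) in profile:
            if c != chrom:
                continue
            for i in range(len(bounds) - 1):
                if bounds[i] >= s and bounds[i + 1] <= e:
                    copies[i] = copy
        out[chrom] = (bounds, copies)
    return out


def _sample_molecule_length(rng: np.random.Generator, ml: MoleculeLength) -> float:
    scale = ml.mean_kb / ml.shape
    for _ in range(1000):
        x = rng.gamma(ml.shape, scale)
        if x >= ml.min_kb:
            return x
    return ml.min_kb


def simulate_rmaps(
    subclone_genomes: dict[str, GenomeMaps],
    config: SimulationConfig,
    reference_length_bp: int | None = None,
) -> list[Rmap]:
    """Draw single-molecule Rmaps from subclone genomes.

    Molecules are drawn from subclones in proportion to fraction times
    regional copy number (copy 2 = neutral) until the configured fold
    coverage of the reference genome is reached.  Each molecule gets a
    random start, a truncated-gamma length, true cuts retained with
    probability ``digest_efficiency``, spurious cuts from a Poisson
    process, multiplicative Gaussian sizing noise, and desorption of
    small fragments (the flanking cuts of a desorbed fragment collapse
    into one).  Each Rmap records its subclone label and a truth record
    (chromosome, start, orientation).
    """
    rng = np.random.default_rng(config.seed)
    labels = [s.label for s in config.subclones]
    if reference_length_bp is None:
        reference_length_bp = int(
            round(
                sum(
                    s.fraction * subclone_genomes[s.label].total_length_bp
                    for s in config.subclones
                )
            )
        )
    # sampling weights: subclone fraction x segment length x copy/2
    seg_rows = []  # (label, chrom, start, end, weight)
    for sub in config.subclones:
        genome = subclone_genomes[sub.label]
        weights = _copy_weights(genome, sub.copy_profile)
        for chrom, (bounds, copies) in weights.items():
            for i in range(len(copies)):
                w = sub.fraction * (bounds[i + 1] - bounds[i]) * copies[i] / 2.0
                if w > 0:
                    seg_rows.append((sub.label, chrom, int(bounds[i]), int(bounds[i + 1]), w))
    seg_w = np.array([r[4] for r in seg_rows])
    seg_p = seg_w / seg_w.sum()
    target_mass_kb = config.coverage * reference_length_bp / 1000.0
    rmaps: list[Rmap] = []
    total_mass = 0.0
    mol_i = 0
    while total_mass < target_mass_kb:
        seg = seg_rows[int(rng.choice(len(seg_rows), p=seg_p))]
        label, chrom, seg_start, seg_end = seg[0], seg[1], seg[2], seg[3]
        genome = subclone_genomes[label]
        fmap = genome.maps[chrom]
        L = fmap.span_bp
        length_bp = int(round(_sample_molecule_length(rng, config.molecule_length) * 1000))
        start = int(rng.integers(seg_start, seg_end))
        end = min(start + length_bp, L)
        if end - start < 1000:
            continue
        frags = _one_molecule(rng, fmap, start, end, config)
        if frags is None:
            continue
        orientation = "+" if rng.random() < 0.5 else "-"
        if orientation == "-":
            frags = frags[::-1]
        mol_i += 1
        rmaps.append(
            Rmap(
                molecule_id=f"mol{mol_i:06d}",
                fragments=frags,
                source_label=label,
                truth={
                    "true_chrom": chrom,
                    "true_start_bp": start,
                    "true_end_bp": end,
                    "true_orientation": orientation,
                },
            )
        )
        total_mass += float(frags.sum())
    return rmaps


def _one_molecule(
    rng: np.random.Generator,
    fmap: FragmentMap,
    start: int,
    end: int,
    config: SimulationConfig,
) -> np.ndarray | None:
    cuts = fmap.cut_coords
    if cuts is None:
        raise ValueError("simulation requires a reference map with cut coordinates")
    lo, hi = np.searchsorted(cuts, start, side="right"), np.searchsorted(cuts, end, side="left")
    true_cuts = cuts[lo:hi].astype(float)
    if config.digest_efficiency < 1.0 and true_cuts.size:
        keep = rng.random(true_cuts.size) < config.digest_efficiency
        true_cuts = true_cuts[keep]
    n_false = rng.poisson(config.false_cut_rate_per_mb * (end - start) / 1e6)
    if n_false:
        false_cuts = rng.uniform(start, end, size=n_false)
        all_cuts = np.sort(np.concatenate([true_cuts, false_cuts]))
    else:
        all_cuts = true_cuts
    boundaries = np.concatenate([[start], all_cuts, [end]])
    frags = np.diff(boundaries) / 1000.0
    frags = frags[frags > 1e-6]
    if config.sizing_cv > 0:
        frags = frags * (1.0 + rng.normal(0.0, config.sizing_cv, size=frags.size))
        frags = np.maximum(frags, 1e-3)
    if config.desorption.drop_prob > 0:
        small = frags < config.desorption.min_kb
        drop = small & (rng.random(frags.size) < config.desorption.drop_prob)
        frags = frags[~drop]
    if frags.size == 0:
        return None
    return frags


def truth_table(rmaps: list[Rmap]) -> pd.DataFrame:
    rows = [
        {
            "molecule_id": r.molecule_id,
            "source_label": r.source_label,
            **(r.truth or {}),
        }
        for r in rmaps
    ]
    return pd.DataFrame(rows)


def place_default_truth_set(
    sequences: dict[str, str],
    genome: GenomeMaps,
    rng: np.random.Generator,
    ins_sizes: tuple[int, ...] = (10_000, 30_000),
    del_size: int = 10_000,
    min_host_frag_kb: float = 25.0,
    min_site_frag_kb: float = 10.0,
    edge_margin_bp: int = 500_000,
) -> list[VariantSpec]:
    """Choose implant positions for a standard sensitivity truth set.

    Insertions and the deletion are placed inside distinct reference
    fragments of at least ``min_host_frag_kb`` so the size change falls
    on a single fragment; the site gain is placed at a Hamming-1 window
    inside a large fragment; the site loss removes an existing cut
    whose flanking fragments are both at least ``min_site_frag_kb``.
    """
    specs: list[VariantSpec] = []
    used: list[tuple[str, int, int]] = []

    def clashes(chrom: str, a: int, b: int) -> bool:
        return any(c == chrom and a < e + 50_000 and s - 50_000 < b for c, s, e in used)

    # candidate large fragments (interior, away from chromosome edges where
    # molecule coverage thins out)
    hosts = []
    for chrom, fmap in genome.maps.items():
        L = fmap.span_bp
        for i in range(1, fmap.n_fragments - 1):
            if fmap.fragments[i] >= min_host_frag_kb:
                start = fmap.boundary_bp(i)
                end = fmap.boundary_bp(i + 1)
                if start >= edge_margin_bp and end <= L - edge_margin_bp:
                    hosts.append((chrom, start, end))
    rng.shuffle(hosts)
    host_iter = iter(hosts)

    def next_host(margin: int) -> tuple[str, int, int]:
        for chrom, s, e in host_iter:
            if e - s > 2 * margin and not clashes(chrom, s, e):
                return chrom, s, e
        raise RuntimeError("no suitable host fragment found")

    for size in ins_sizes:
        chrom, s, e = next_host(6000)
        pos = (s + e) // 2
        specs.append(VariantSpec("INS", chrom, pos, size))
        used.append((chrom, s, e))
    chrom, s, e = next_host(del_size // 2 + 6000)
    pos = (s + e) // 2 - del_size // 2
    specs.append(VariantSpec("DEL", chrom, pos, del_size))
    used.append((chrom, s, e))
    # SITE_GAIN: Hamming-1 window inside a big fragment, away from edges
    gain_placed = False
    for chrom, s, e in hosts:
        if clashes(chrom, s, e):
            continue
        region = sequences[chrom][s + 5000 : e - 5000]
        cands = find_site_gain_positions(region, limit=5)
        if cands:
            w, _off, _base = cands[0]
            specs.append(VariantSpec("SITE_GAIN", chrom, s + 5000 + w, 0))
            used.append((chrom, s, e))
            gain_placed = True
            break
    if not gain_placed:
        raise RuntimeError("no SITE_GAIN candidate found")
    # SITE_LOSS: existing cut with large flanking fragments
    loss_placed = False
    for chrom, fmap in genome.maps.items():
        assert fmap.cut_coords is not None
        L = fmap.span_bp
        for i in range(1, fmap.n_fragments - 1):
            if (
                fmap.fragments[i] >= min_site_frag_kb
                and fmap.fragments[i + 1] >= min_site_frag_kb
            ):
                cut_bp = int(fmap.cut_coords[i])
                if not edge_margin_bp <= cut_bp <= L - edge_margin_bp:
                    continue
                site_start = cut_bp - SWAI_CUT_OFFSET
                if sequences[chrom][site_start : site_start + len(SWAI_SITE)].upper() != SWAI_SITE:
                    continue
                if clashes(chrom, site_start, site_start + 8):
                    continue
                specs.append(VariantSpec("SITE_LOSS", chrom, site_start, 0))
                used.append((chrom, site_start - 20_000, site_start + 20_000))
                loss_placed = True
                break
        if loss_placed:
            break
    if not loss_placed:
        raise RuntimeError("no SITE_LOSS candidate found")
    return specs
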