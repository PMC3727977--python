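"""Core containers and formats for ordered restriction maps.

An ordered restriction map is the sequence of fragment masses (in kb)
produced by a restriction enzyme cutting a DNA molecule.  The whole
pipeline trades in three flavors of map:

* the *in-silico* reference map, computed by locating the enzyme's
  recognition sites in a genome sequence;
* single-molecule Rmaps measured (here: simulated) from individual
  genomic DNA molecules;
* consensus and hypothesis maps produced by assembly.

Coordinates are 0-based half-open base pairs; cuts fall *between* bases.
Masses are kilobases at 0.001 kb resolution.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

KB_PER_BP = 1e-3
MASS_RESOLUTION_KB = 0.001

#: SwaI recognition site; a blunt cutter, cleaving between positions 4 and 5.
SWAI_SITE = "ATTTAAAT"
SWAI_CUT_OFFSET = 4


class MapFormatError(ValueError):
    """Raised for malformed on-disk map records."""


class MapOrigin(str, Enum):
    REFERENCE = "reference"
    CONSENSUS = "consensus"
    HYPOTHESIS = "hypothesis"
    MOLECULE = "molecule"


@dataclass
class FragmentMap:
    """An ordered sequence of restriction-fragment masses.

    Parameters
    ----------
    map_id : str
        Identifier of the map.
    fragments : array-like of float
        Fragment masses in kb, all strictly positive.
    chrom : str, optional
        Chromosome of origin, when known.
    cut_coords : array-like of int, optional
        Genomic bp coordinates of the interior cuts (one fewer than
        fragments).  Cut ``i`` separates fragment ``i`` from ``i+1``.
    origin : MapOrigin
        Provenance of the map.
    """

    map_id: str
    fragments: np.ndarray
    chrom: str | None = None
    cut_coords: np.ndarray | None = None
    origin: MapOrigin = MapOrigin.REFERENCE
    start_bp: int = 0

    def __post_init__(self) -> None:
        self.fragments = np.asarray(self.fragments, dtype=float)
        if self.fragments.ndim != 1 or self.fragments.size == 0:
            raise ValueError(f"map {self.map_id!r}: needs >= 1 fragment")
        if np.any(self.fragments <= 0):
            raise ValueError(f"map {self.map_id!r}: all fragment masses must be > 0")
        if self.cut_coords is not None:
            self.cut_coords = np.asarray(self.cut_coords, dtype=np.int64)
            if self.cut_coords.size != self.fragments.size - 1:
                raise ValueError(
                    f"map {self.map_id!r}: {self.cut_coords.size} cut coords "
                    f"for {self.fragments.size} fragments"
                )
            if self.cut_coords.size and np.any(np.diff(self.cut_coords) <= 0):
                raise ValueError(f"map {self.map_id!r}: cut coords not increasing")
            if self.cut_coords.size > 1:
                spans_kb = np.diff(self.cut_coords) * KB_PER_BP
                if np.any(np.abs(spans_kb - self.fragments[1:-1]) > MASS_RESOLUTION_KB + 1e-9):
                    raise ValueError(
                        f"map {self.map_id!r}: cut coords inconsistent with masses"
                    )

    @property
    def n_fragments(self) -> int:
        return int(self.fragments.size)

    @property
    def total_mass_kb(self) -> float:
        return float(self.fragments.sum())

    @property
    def span_bp(self) -> int:
        return int(round(self.total_mass_kb / KB_PER_BP))

    def boundaries_kb(self) -> np.ndarray:
        """Cumulative mass at every fragment boundary (length n+1)."""
        out = np.empty(self.n_fragments + 1)
        out[0] = 0.0
        np.cumsum(self.fragments, out=out[1:])
        return out

    def boundary_bp(self, i: int) -> int:
        """Genomic bp coordinate of fragment boundary ``i`` (0..n)."""
        if i == 0:
            return self.start_bp
        if self.cut_coords is not None and i <= self.cut_coords.size:
            return int(self.cut_coords[i - 1])
        return self.start_bp + int(round(float(self.fragments[:i].sum()) * 1000))


@dataclass
class Rmap:
    """A single molecule's ordered restriction map."""

    molecule_id: str
    fragments: np.ndarray
    source_label: str = "."
    truth: dict | None = None  # {true_chrom, true_start_bp, true_orientation}

    def __post_init__(self) -> None:
        self.fragments = np.asarray(self.fragments, dtype=float)
        if self.fragments.size == 0:
            raise ValueError(f"rmap {self.molecule_id!r}: needs >= 1 fragment")
        if np.any(self.fragments <= 0):
            raise ValueError(f"rmap {self.molecule_id!r}: all masses must be > 0")

    @property
    def n_fragments(self) -> int:
        return int(self.fragments.size)

    @property
    def total_mass_kb(self) -> float:
        return float(self.fragments.sum())


@dataclass
class GenomeMaps:
    """In-silico restriction maps for a whole genome, keyed by chromosome."""

    maps: dict[str, FragmentMap]

    def __post_init__(self) -> None:
        for chrom, fmap in self.maps.items():
            if fmap.chrom is None:
                fmap.chrom = chrom

    @property
    def chroms(self) -> list[str]:
        return list(self.maps)

    @property
    def total_length_bp(self) -> int:
        return sum(m.span_bp for m in self.maps.values())

    def merged(self, min_kb: float) -> "GenomeMaps":
        return GenomeMaps(
            {c: merge_small_fragments(m, min_kb) for c, m in self.maps.items()}
        )

    @classmethod
    def from_sequences(
        cls,
        sequences: dict[str, str],
        site: str = SWAI_SITE,
        cut_offset: int = SWAI_CUT_OFFSET,
    ) -> "GenomeMaps":
        return cls(
            {
                chrom: in_silico_digest(seq, site=site, cut_offset=cut_offset,
                                        map_id=f"ref_{chrom}", chrom=chrom)
                for chrom, seq in sequences.items()
            }
        )


def find_sites(sequence: str, site: str = SWAI_SITE) -> np.ndarray:
    """Start positions of all (possibly overlapping) site occurrences.

    Windows containing N (or any non-ACGT symbol) never match, so
    assembly gaps cannot create phantom cuts.
    """
    pattern = re.compile(f"(?={re.escape(site.upper())})")
    return np.fromiter(
        (m.start() for m in pattern.finditer(sequence.upper())), dtype=np.int64
    )


def in_silico_digest(
    sequence: str,
    site: str = SWAI_SITE,
    cut_offset: int = SWAI_CUT_OFFSET,
    map_id: str = "ref",
    chrom: str | None = None,
) -> FragmentMap:
    """Digest a nucleotide sequence in silico.

    Returns the fragments between successive cut positions plus the two
    terminal fragments.  A sequence without any site occurrence yields a
    single fragment covering the whole sequence.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    if not 0 < cut_offset < len(site):
        raise ValueError("cut offset must be interior to the recognition site")
    L = len(sequence)
    cuts = find_sites(sequence, site) + cut_offset
    # cuts at the extreme ends would create zero-mass fragments; with an
    # interior cut offset this cannot happen, but guard for safety
    cuts = cuts[(cuts > 0) & (cuts < L)]
    boundaries = np.concatenate([[0], cuts, [L]])
    fragments = np.diff(boundaries) * KB_PER_BP
    return FragmentMap(
        map_id=map_id,
        chrom=chrom,
        fragments=fragments,
        cut_coords=cuts,
        origin=MapOrigin.REFERENCE,
    )


def merge_small_fragments(fmap: FragmentMap, min_kb: float = 0.4) -> FragmentMap:
    """Merge fragments smaller than ``min_kb`` into their left neighbor.

    The leftmost fragment, having no left neighbor, merges rightward;
    a run of small leading fragments cascades into the first fragment
    that reaches ``min_kb``.  Total mass is conserved exactly.  If the
    whole map sums below ``min_kb`` a single undersized fragment is
    returned.
    """
    if min_kb <= 0:
        raise ValueError("min_kb must be positive")
    frags = fmap.fragments
    if frags.size == 0:
        raise ValueError("cannot merge an empty map")
    out_mass: list[float] = []
    out_last_idx: list[int] = []  # index of last source fragment in each output
    carry = 0.0
    for i, f in enumerate(frags):
        mass = f + carry
        carry = 0.0
        if mass < min_kb:
            if out_mass:
                out_mass[-1] += mass
                out_last_idx[-1] = i
            else:
                carry = mass
        else:
            out_mass.append(mass)
            out_last_idx.append(i)
    if carry > 0.0:
        if out_mass:
            out_mass[-1] += carry
            out_last_idx[-1] = len(frags) - 1
        else:
            out_mass.append(carry)
            out_last_idx.append(len(frags) - 1)
    # trailing undersized fragment merges into its left neighbor
    while len(out_mass) > 1 and out_mass[-1] < min_kb:
        out_mass[-2] += out_mass[-1]
        out_last_idx[-2] = out_last_idx[-1]
        out_mass.pop()
        out_last_idx.pop()
    cut_coords = None
    if fmap.cut_coords is not None and len(out_mass) > 1:
        cut_coords = fmap.cut_coords[np.asarray(out_last_idx[:-1], dtype=int)]
    return FragmentMap(
        map_id=fmap.map_id,
        chrom=fmap.chrom,
        fragments=np.asarray(out_mass),
        cut_coords=cut_coords,
        origin=fmap.origin,
        start_bp=fmap.start_bp,
    )


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------

_MAP_HEADER = (
    "# rmapforge map v1\n"
    "# coordinates: 0-based half-open bp; masses: kb, 3 decimals\n"
    "# map_id\tchrom\tn_frags\tfragments_kb\tsource_label\n"
)


def write_maps(
    maps: Iterable[Rmap | FragmentMap],
    path: str | Path,
    annotations: dict[str, str] | None = None,
) -> None:
    """Write maps in the tab-separated map dialect.

    One record per line: map id, chromosome (``.`` if unknown), fragment
    count, comma-separated masses at 3 decimals, and source label
    (``.`` for reference/consensus maps).  ``annotations`` adds a
    comment line (e.g. ``#support=...``) before the named records.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_MAP_HEADER)
        for m in maps:
            if isinstance(m, Rmap):
                map_id, chrom, label = m.molecule_id, ".", m.source_label or "."
            else:
                map_id, chrom, label = m.map_id, m.chrom or ".", "."
            if annotations and map_id in annotations:
                fh.write(f"#{annotations[map_id]}\n")
            masses = ",".join(f"{f:.3f}" for f in m.fragments)
            fh.write(f"{map_id}\t{chrom}\t{m.n_fragments}\t{masses}\t{label}\n")


def read_maps(path: str | Path) -> list[Rmap | FragmentMap]:
    """Read a map TSV file.

    Records with a source label parse as :class:`Rmap`; records without
    one (label ``.``) parse as :class:`FragmentMap`.  Malformed lines
    raise :class:`MapFormatError` naming the offending line number.
    """
    path = Path(path)
    out: list[Rmap | FragmentMap] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise MapFormatError(
                    f"{path}:{lineno}: expected 5 tab-separated fields, got {len(fields)}"
                )
            map_id, chrom, n_str, masses_str, label = fields
            try:
                n = int(n_str)
                masses = np.array([float(x) for x in masses_str.split(",")])
            except ValueError as exc:
                raise MapFormatError(f"{path}:{lineno}: unparseable record: {exc}") from exc
            if masses.size != n:
                raise MapFormatError(
                    f"{path}:{lineno}: declared {n} fragments, found {masses.size}"
                )
            if np.any(masses <= 0):
                raise MapFormatError(f"{path}:{lineno}: non-positive fragment mass")
            if label != ".":
                out.append(Rmap(molecule_id=map_id, fragments=masses, source_label=label))
            else:
                out.append(
                    FragmentMap(
                        map_id=map_id,
                        chrom=None if chrom == "." else chrom,
                        fragments=masses,
                        origin=MapOrigin.CONSENSUS,
                    )
                )
    if not out:
        warnings.warn(f"{path}: no map records found", stacklevel=2)
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with Path(path).open("w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED4+ file into a DataFrame (chrom, start, end, name[, ...])."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BED_COLUMNS[:4])
    if df.shape[1] < 4:
        raise MapFormatError(f"{path}: BED4+ requires >= 4 columns")
    df.columns = BED_COLUMNS[: df.shape[1]] + list(df.columns[6:])
    bad = df.index[
        ~df["start"].astype(str).str.fullmatch(r"\d+")
        | ~df["end"].astype(str).str.fullmatch(r"\d+")
    ]
    if len(bad):
        raise MapFormatError(f"{path}: malformed BED at data line {bad[0] + 1}")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)
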