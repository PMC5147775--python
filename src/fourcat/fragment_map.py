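"""In-silico restriction digestion and the fragment coordinate system.

All downstream 4C analysis counts ligation events *per restriction
fragment*, so the ordered fragment map produced here is the coordinate
system for every other module.  Conventions:

* coordinates are 0-based half-open internally (conversion to 1-based SAM
  happens only at I/O boundaries);
* a cut is placed at the first base of each recognition-site occurrence
  (DpnII cuts ^GATC blunt at the site start, and downstream analysis only
  needs consistent fragment identity, not sticky-end bookkeeping);
* ``N`` bases never match a recognition site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import CoordinateError, InputError

_VALID_BASES = frozenset("ACGTN")
_UNAMBIGUOUS = frozenset("ACGT")

DPNII_SITE = "GATC"


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome of plain uppercase A/C/G/T/N sequence."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError("genome sequence is empty")
        seq = self.sequence.upper()
        extra = set(seq) - _VALID_BASES
        if extra:
            raise InputError(f"genome contains non-ACGTN characters: {sorted(extra)!r}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_fasta(cls, path, name: str | None = None) -> "GenomeSequence":
        """Load one record from a FASTA file (the first, or the named one)."""
        for record in SeqIO.parse(str(path), "fasta"):
            if name is None or record.id == name:
                return cls(name=record.id, sequence=str(record.seq))
        raise InputError(f"no FASTA record {name!r} in {path}")

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n")
            for i in range(0, self.length, 80):
                fh.write(self.sequence[i : i + 80] + "\n")


@dataclass(frozen=True)
class RestrictionFragment:
    """One digestion fragment, 0-based half-open."""

    chrom: str
    start: int
    end: int
    index: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InputError(f"empty fragment [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FragmentMap:
    """Ordered restriction fragments tiling one chromosome without gaps.

    Stored internally as a boundary array ``bounds`` of length
    ``n_fragments + 1`` with ``bounds[0] == 0`` and
    ``bounds[-1] == genome length``; fragment ``i`` is
    ``[bounds[i], bounds[i + 1])``.
    """

    chrom: str
    recognition_site: str
    bounds: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        bounds = np.asarray(self.bounds, dtype=np.int64)
        if bounds.ndim != 1 or bounds.size < 2:
            raise InputError("fragment map needs at least one fragment")
        if bounds[0] != 0 or np.any(np.diff(bounds) <= 0):
            raise InputError("fragment boundaries must start at 0 and strictly increase")
        object.__setattr__(self, "bounds", bounds)

    # -- basic geometry -------------------------------------------------

    @property
    def n_fragments(self) -> int:
        return self.bounds.size - 1

    @property
    def genome_length(self) -> int:
        return int(self.bounds[-1])

    @property
    def starts(self) -> np.ndarray:
        return self.bounds[:-1]

    @property
    def ends(self) -> np.ndarray:
        return self.bounds[1:]

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2

    def fragment(self, index: int) -> RestrictionFragment:
        if not 0 <= index < self.n_fragments:
            raise CoordinateError(f"fragment index {index} out of range")
        return RestrictionFragment(
            self.chrom, int(self.bounds[index]), int(self.bounds[index + 1]), index
        )

    def __len__(self) -> int:
        return self.n_fragments

    def __iter__(self):
        for i in range(self.n_fragments):
            yield self.fragment(i)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FragmentMap)
            and self.chrom == other.chrom
            and self.recognition_site == other.recognition_site
            and self.bounds.shape == other.bounds.shape
            and bool(np.all(self.bounds == other.bounds))
        )

    # -- lookups --------------------------------------------------------

    def locate(self, position: int) -> int:
        """Index of the fragment whose half-open interval contains ``position``."""
        return int(self.locate_many(np.asarray([position]))[0])

    def locate_many(self, positions: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`locate` via binary search on the boundary array."""
        positions = np.asarray(positions, dtype=np.int64)
        if positions.size and (positions.min() < 0 or positions.max() >= self.genome_length):
            bad = positions[(positions < 0) | (positions >= self.genome_length)][0]
            raise CoordinateError(
                f"position {bad} outside chromosome [0, {self.genome_length})"
            )
        return np.searchsorted(self.bounds, positions, side="right") - 1

    def window_around(self, center: int, width: int) -> tuple[int, int]:
        """Contiguous half-open fragment-index range of exactly ``width`` fragments.

        The range is anchored so that the fragment containing ``center`` is
        the ``(width - 1) // 2``-th element, i.e. an even width puts the
        extra fragment on the downstream (higher-coordinate) side.  Near a
        chromosome end the range is shifted inward so that it keeps exactly
        ``width`` fragments.
        """
        if width < 1:
            raise InputError("window width must be >= 1")
        if width > self.n_fragments:
            raise InputError(
                f"window width {width} exceeds fragment count {self.n_fragments}"
            )
        c = self.locate(center)
        lo = c - (width - 1) // 2
        lo = max(0, min(lo, self.n_fragments - width))
        return lo, lo + width

    # -- I/O ------------------------------------------------------------

    def to_bed(self, path) -> None:
        """Write fragments as 4-column BED (name column = fragment index)."""
        df = pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.starts,
                "end": self.ends,
                "name": np.arange(self.n_fragments),
            }
        )
        df.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path, recognition_site: str = DPNII_SITE) -> "FragmentMap":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "name"]
        )
        chroms = df["chrom"].unique()
        if len(chroms) != 1:
            raise InputError("fragment BED must cover exactly one chromosome")
        bounds = np.concatenate([df["start"].to_numpy(), [df["end"].iloc[-1]]])
        return cls(chrom=str(chroms[0]), recognition_site=recognition_site, bounds=bounds)


def digest_genome(genome: GenomeSequence, recognition_site: str = DPNII_SITE) -> FragmentMap:
    """Digest a chromosome at every occurrence of ``recognition_site``.

    Cut positions are the start coordinates of all (including overlapping)
    occurrences of the site; fragments are the intervals between
    consecutive cuts plus the chromosome ends, with zero-length fragments
    discarded (a site at position 0 produces no empty leading fragment).
    """
    if not recognition_site:
        raise InputError("recognition site is empty")
    site = recognition_site.upper()
    if set(site) - _UNAMBIGUOUS:
        raise InputError(f"recognition site {recognition_site!r} contains non-ACGT characters")

    seq = genome.sequence
    cuts: list[int] = []
    pos = seq.find(site)
    while pos != -1:
        cuts.append(pos)
        pos = seq.find(site, pos + 1)  # step 1 => overlapping occurrences included

    bounds = [0] + cuts + [genome.length]
    arr = np.array(sorted(set(bounds)), dtype=np.int64)  # drops a cut at 0
    return FragmentMap(chrom=genome.name, recognition_site=site, bounds=arr)


def locate_fragment(fmap: FragmentMap, position: int) -> int:
    """Functional alias for :meth:`FragmentMap.locate`."""
    return fmap.locate(position)


def window_around(fmap: FragmentMap, center: int, width: int) -> tuple[int, int]:
    """Functional alias for :meth:`FragmentMap.window_around`."""
    return fmap.window_around(center, width)
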