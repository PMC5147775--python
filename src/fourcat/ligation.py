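"""Mapped 4C reads -> deduplicated ligation events -> contact profiles.

A 4C read is primed from inside the bait fragment and crosses the ligation
junction into the captured restriction fragment, so the read's 5'-most
aligned base sits at the captured fragment's restriction boundary and the
distal read end is the sonication shear point.  Identical shear points
identify PCR duplicates of the same template molecule, which is why
deduplication collapses events on the exact (viewpoint, fragment,
breakpoint) key with no tolerance window.

Bulk data is carried in :class:`pandas.DataFrame` tables; the dataclasses
exist for single-record construction and documentation of the schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .errors import ConfigError, CoordinateError, InputError
from .fragment_map import FragmentMap

READ_COLUMNS = ["chrom", "start", "end", "strand", "viewpoint"]
EVENT_COLUMNS = ["viewpoint", "fragment", "breakpoint", "multiplicity"]


@dataclass(frozen=True)
class MappedReadRecord:
    """One mapped read: 0-based half-open interval plus its viewpoint tag."""

    chrom: str
    start: int
    end: int
    strand: str
    viewpoint: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InputError(f"read interval [{self.start}, {self.end}) is empty")
        if self.strand not in ("+", "-"):
            raise InputError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class LigationEvent:
    """One captured ligation: fragment index plus exact shear coordinate."""

    viewpoint: str
    fragment: int
    breakpoint: int
    multiplicity: int = 1


def reads_to_dataframe(reads) -> pd.DataFrame:
    """Normalize a list of :class:`MappedReadRecord` (or a DataFrame) to a table."""
    if isinstance(reads, pd.DataFrame):
        missing = [c for c in READ_COLUMNS if c not in reads.columns]
        if missing:
            raise InputError(f"read table lacks columns {missing}")
        return reads
    return pd.DataFrame(
        [(r.chrom, r.start, r.end, r.strand, r.viewpoint) for r in reads],
        columns=READ_COLUMNS,
    )


def reads_to_ligations(
    reads,
    fmap: FragmentMap,
    known_viewpoints=None,
) -> pd.DataFrame:
    """Convert mapped reads into one ligation event each (not yet deduplicated).

    The captured fragment is the one containing the read's 5'-most aligned
    base (start for forward reads, ``end - 1`` for reverse reads); the
    sonication breakpoint is the opposite read coordinate, the one farthest
    from the captured fragment's restriction boundary on the read's side.
    """
    df = reads_to_dataframe(reads)
    if len(df) == 0:
        return pd.DataFrame(columns=EVENT_COLUMNS).astype(
            {"fragment": np.int64, "breakpoint": np.int64, "multiplicity": np.int64}
        )
    if not (df["chrom"] == fmap.chrom).all():
        bad = df.loc[df["chrom"] != fmap.chrom, "chrom"].iloc[0]
        raise CoordinateError(f"read on chromosome {bad!r}, map covers {fmap.chrom!r}")
    if known_viewpoints is not None:
        unknown = set(df["viewpoint"]) - set(known_viewpoints)
        if unknown:
            raise ConfigError(f"unknown viewpoint tags: {sorted(unknown)}")

    start = df["start"].to_numpy(np.int64)
    end = df["end"].to_numpy(np.int64)
    fwd = df["strand"].to_numpy() == "+"
    five_prime = np.where(fwd, start, end - 1)
    fragment = fmap.locate_many(five_prime)
    breakpoint = np.where(fwd, end, start)
    return pd.DataFrame(
        {
            "viewpoint": df["viewpoint"].to_numpy(),
            "fragment": fragment,
            "breakpoint": breakpoint,
            "multiplicity": np.ones(len(df), dtype=np.int64),
        }
    )


def dedup_by_sonication_site(events: pd.DataFrame) -> pd.DataFrame:
    """Collapse PCR duplicates on the exact (viewpoint, fragment, breakpoint) key.

    Multiplicity records how many input events shared the key.  Output is
    sorted by viewpoint, fragment, then breakpoint, so the result is
    deterministic regardless of input order, and the operation is
    idempotent.
    """
    if len(events) == 0:
        return events.copy()
    vp_codes, vp_labels = pd.factorize(events["viewpoint"], sort=True)
    frag = events["fragment"].to_numpy(np.int64)
    bp = events["breakpoint"].to_numpy(np.int64)
    mult = events["multiplicity"].to_numpy(np.int64)
    bp_span = int(bp.max()) + 1
    frag_span = int(frag.max()) + 1
    key = (vp_codes.astype(np.int64) * frag_span + frag) * bp_span + bp
    unique_keys, inverse = np.unique(key, return_inverse=True)
    summed = np.bincount(inverse, weights=mult).astype(np.int64)
    frag_bp = unique_keys % (frag_span * bp_span)
    return pd.DataFrame(
        {
            "viewpoint": vp_labels[(unique_keys // (frag_span * bp_span)).astype(np.intp)],
            "fragment": frag_bp // bp_span,
            "breakpoint": frag_bp % bp_span,
            "multiplicity": summed,
        }
    )


@dataclass
class ContactProfile:
    """Per-fragment unique-ligation counts for one viewpoint x condition."""

    fmap: FragmentMap
    viewpoint: str
    condition: str
    counts: np.ndarray = field(repr=False)
    bait_fragment: int | None = None
    exclusion_halfwidth: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (self.fmap.n_fragments,):
            raise InputError(
                f"counts length {counts.shape} does not match "
                f"{self.fmap.n_fragments} fragments"
            )
        if np.any(counts < 0):
            raise InputError("negative ligation counts")
        self.counts = counts

    @property
    def n(self) -> int:
        """Total unique ligation events outside the bait exclusion zone."""
        return int(self.counts.sum())

    def excluded_range(self) -> tuple[int, int] | None:
        if self.bait_fragment is None:
            return None
        lo = max(0, self.bait_fragment - self.exclusion_halfwidth)
        hi = min(self.fmap.n_fragments, self.bait_fragment + self.exclusion_halfwidth + 1)
        return lo, hi

    # -- I/O ------------------------------------------------------------

    def to_bedgraph(self, path) -> None:
        pd.DataFrame(
            {
                "chrom": self.fmap.chrom,
                "start": self.fmap.starts,
                "end": self.fmap.ends,
                "value": self.counts,
            }
        ).to_csv(path, sep="\t", header=False, index=False)

    def write(self, bedgraph_path, sidecar_path) -> None:
        self.to_bedgraph(bedgraph_path)
        meta = {
            "viewpoint": self.viewpoint,
            "condition": self.condition,
            "n": self.n,
            "chrom": self.fmap.chrom,
            "n_fragments": self.fmap.n_fragments,
            "bait_fragment": self.bait_fragment,
            "exclusion_halfwidth": self.exclusion_halfwidth,
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, bedgraph_path, sidecar_path, fmap: FragmentMap) -> "ContactProfile":
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        df = pd.read_csv(
            bedgraph_path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
        )
        if len(df) != fmap.n_fragments:
            raise InputError("bedgraph row count does not match fragment map")
        return cls(
            fmap=fmap,
            viewpoint=meta["viewpoint"],
            condition=meta["condition"],
            counts=df["value"].to_numpy(np.int64),
            bait_fragment=meta.get("bait_fragment"),
            exclusion_halfwidth=meta.get("exclusion_halfwidth", 0),
        )


def profile_from_events(
    events: pd.DataFrame,
    fmap: FragmentMap,
    condition: str,
    viewpoint: str | None = None,
    bait_position: int | None = None,
    exclusion_halfwidth: int = 2,
) -> ContactProfile:
    """Count deduplicated events per fragment into a :class:`ContactProfile`.

    Fragments within ``exclusion_halfwidth`` of the bait fragment are
    zeroed (self-ligation and undigested-template products) and the total
    ``n`` shrinks accordingly.  ``events`` is expected to be deduplicated;
    each row contributes one unique ligation regardless of multiplicity.
    """
    if viewpoint is None:
        tags = events["viewpoint"].unique() if len(events) else []
        viewpoint = str(tags[0]) if len(tags) == 1 else "mixed"
    if len(events):
        frags = events["fragment"].to_numpy(np.int64)
        if frags.min() < 0 or frags.max() >= fmap.n_fragments:
            raise CoordinateError("event fragment index outside map")
        counts = np.bincount(frags, minlength=fmap.n_fragments)
    else:
        counts = np.zeros(fmap.n_fragments, dtype=np.int64)

    bait_fragment = None
    if bait_position is not None:
        bait_fragment = fmap.locate(bait_position)
        lo = max(0, bait_fragment - exclusion_halfwidth)
        hi = min(fmap.n_fragments, bait_fragment + exclusion_halfwidth + 1)
        counts[lo:hi] = 0
    return ContactProfile(
        fmap=fmap,
        viewpoint=viewpoint,
        condition=condition,
        counts=counts,
        bait_fragment=bait_fragment,
        exclusion_halfwidth=exclusion_halfwidth if bait_position is not None else 0,
    )


# -- read I/O -----------------------------------------------------------


def read_reads_bed(path) -> pd.DataFrame:
    """Read mapped reads from 6-column BED (name column = viewpoint tag)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(np.int64),
            "end": df["end"].astype(np.int64),
            "strand": df["strand"],
            "viewpoint": df["name"],
        }
    )


def write_reads_bed(reads: pd.DataFrame, path) -> None:
    df = reads_to_dataframe(reads)
    pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": df["viewpoint"],
            "score": 0,
            "strand": df["strand"],
        }
    ).to_csv(path, sep="\t", header=False, index=False)


def read_reads_sam(path, min_mapq: int = 0, keep_multimappers: bool = True) -> pd.DataFrame:
    """Read mapped reads from SAM/BAM; the viewpoint tag is the ``VP`` aux tag.

    ``min_mapq`` filters on mapping quality; ``keep_multimappers`` set to
    False additionally drops MAPQ-0 records, the usual multi-mapper
    convention.
    """
    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            if not keep_multimappers and aln.mapping_quality == 0:
                continue
            rows.append(
                (
                    aln.reference_name,
                    aln.reference_start,
                    aln.reference_end,
                    "-" if aln.is_reverse else "+",
                    aln.get_tag("VP") if aln.has_tag("VP") else "unknown",
                )
            )
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def write_reads_sam(reads: pd.DataFrame, path, fmap: FragmentMap) -> None:
    """Write reads as minimal single-reference SAM with a ``VP`` aux tag."""
    df = reads_to_dataframe(reads)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": fmap.chrom, "LN": fmap.genome_length}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for i, row in enumerate(df.itertuples(index=False)):
            aln = pysam.AlignedSegment(fh.header)
            aln.query_name = f"read{i}"
            aln.reference_id = 0
            aln.reference_start = int(row.start)
            aln.cigartuples = [(0, int(row.end) - int(row.start))]
            aln.flag = 16 if row.strand == "-" else 0
            aln.mapping_quality = 60
            aln.set_tag("VP", str(row.viewpoint))
            fh.write(aln)
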