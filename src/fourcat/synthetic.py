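"""Synthetic 4C libraries with the statistical structure the analysis assumes.

The generator emulates a single-viewpoint 4C experiment on a ~2 Mb cis
region: a distance-decay contact background, an asymmetric contact domain
around the bait (~250 kb downstream, ~125 kb upstream), discrete
long-range contact peaks, condition-dependent window multipliers,
sonication shear points, and PCR duplicates.

Two modelling choices matter for interpreting recovery experiments:

* Condition effects are injected on *post-normalization window means* —
  the quantity the differential stage reports — by multiplying in-window
  probabilities and rescaling only the out-of-window mass.  The configured
  window-mean ratio versus the untreated ("naive") vector therefore holds
  exactly at the probability level.
* A molecule's identity is its (captured fragment, shear coordinate) pair,
  exactly the key deduplication collapses on.  Two independent ligation
  events that shear at the same base are indistinguishable, in simulation
  as in a real library, and count as one unique molecule in the stored
  ground truth.  Shear offsets are drawn uniformly over a wide range
  (default 50-1500 bp from the restriction boundary, on either strand) so
  that such coincidental collisions stay rare at the simulated depths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .differential import WindowSpec
from .errors import ConfigError, InputError
from .fragment_map import FragmentMap, GenomeSequence
from .ligation import write_reads_bed, write_reads_sam

DEFAULT_CHROM = "chrXsim"
DEFAULT_GENOME_LENGTH = 2_000_000


# -- study geometry ------------------------------------------------------


@dataclass(frozen=True)
class ViewpointSpec:
    """A named anchor on the cis region: a 4C bait or a contact partner."""

    name: str
    chrom: str
    anchor: int
    role: str = "bait"  # "bait" or "contact"

    def __post_init__(self) -> None:
        if self.role not in ("bait", "contact"):
            raise ConfigError(f"viewpoint role must be 'bait' or 'contact', got {self.role!r}")


def default_viewpoints(chrom: str = DEFAULT_CHROM) -> dict[str, ViewpointSpec]:
    """The two BR-C baits and three long-range contact anchors (X chromosome
    coordinates of the primer table, which all fall inside the 2 Mb synthetic
    region verbatim)."""
    specs = [
        ViewpointSpec("B1", chrom, 1_609_904, "bait"),
        ViewpointSpec("B2", chrom, 1_619_649, "bait"),
        ViewpointSpec("X1", chrom, 1_587_064, "contact"),
        ViewpointSpec("X2", chrom, 1_829_722, "contact"),
        ViewpointSpec("X3", chrom, 1_945_463, "contact"),
    ]
    return {v.name: v for v in specs}


def default_windows() -> dict[str, WindowSpec]:
    """Analysis windows: 200 fragments for X1 and X2, 30 for X3, plus the
    40-fragment X1 window used for the imaginal-disc comparison."""
    windows = [
        WindowSpec("X1", 1_587_064, 200),
        WindowSpec("X2", 1_829_722, 200),
        WindowSpec("X3", 1_945_463, 30),
        WindowSpec("X1_disc", 1_587_064, 40),
    ]
    return {w.name: w for w in windows}


# -- contact model -------------------------------------------------------


@dataclass(frozen=True)
class ContactModelConfig:
    """Baseline contact landscape around one bait.

    Per fragment at distance ``d`` fragments from the bait, the
    unnormalized contact weight is::

        (1 + d) ** -decay_exponent  * enrichment (inside the asymmetric domain)
                                    * peak height (inside a peak window)
        + far_background_floor

    with the ``viewpoint_exclusion_halfwidth`` fragments around the bait
    zeroed (self-ligation and undigested products carry no information).
    ``far_background_floor`` is on the same unnormalized scale as the decay
    term, whose maximum after exclusion is below 1.
    """

    decay_exponent: float = 1.0
    domain_upstream_extent: int = 125_000
    domain_downstream_extent: int = 250_000
    domain_enrichment_factor: float = 3.0
    peaks: tuple[tuple[WindowSpec, float], ...] = ()
    far_background_floor: float = 0.25
    viewpoint_exclusion_halfwidth: int = 2

    def __post_init__(self) -> None:
        if self.decay_exponent < 0:
            raise ConfigError("decay_exponent must be >= 0")
        if self.domain_upstream_extent <= 0 or self.domain_downstream_extent <= 0:
            raise ConfigError("domain extents must be > 0")
        if self.domain_enrichment_factor <= 0:
            raise ConfigError("domain_enrichment_factor must be > 0")
        if any(h <= 0 for _, h in self.peaks):
            raise ConfigError("peak heights must be > 0")
        if self.far_background_floor < 0:
            raise ConfigError("far_background_floor must be >= 0")


def default_peaks() -> tuple[tuple[WindowSpec, float], ...]:
    """Discrete long-range contact peaks at the X1-X3 anchors, present in
    every condition (the contacts pre-exist ligand exposure)."""
    return (
        (WindowSpec("X1_peak", 1_587_064, 31), 3.0),
        (WindowSpec("X2_peak", 1_829_722, 31), 2.5),
        (WindowSpec("X3_peak", 1_945_463, 31), 2.5),
    )


def default_model() -> ContactModelConfig:
    return ContactModelConfig(peaks=default_peaks())


@dataclass(frozen=True)
class ConditionScenario:
    """Post-normalization window-mean multipliers relative to the naive state.

    Keys are ``(viewpoint name, window name)``; a multiplier ``m`` makes the
    scenario's window mean exactly ``m`` times the naive window mean at the
    probability level.
    """

    name: str
    multipliers: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.multipliers.values()):
            raise ConfigError("scenario multipliers must be > 0")

    def for_viewpoint(self, viewpoint_name: str) -> dict[str, float]:
        return {
            window: m
            for (vp, window), m in self.multipliers.items()
            if vp == viewpoint_name
        }


def default_scenarios() -> dict[str, ConditionScenario]:
    """The five study conditions.

    The X1 increases (1.27 for B1, 1.22 for B2) are the reported effect
    sizes; the remaining magnitudes realize effects reported only as
    significant directions (X3 increase with B2, X2 decrease, attenuated X1
    response under Cg knockdown, reduced X1 contact in mutant discs) and
    are configuration, not code constants.
    """
    return {
        "naive": ConditionScenario("naive"),
        "ecdysone": ConditionScenario(
            "ecdysone",
            {
                ("B1", "X1"): 1.27,
                ("B2", "X1"): 1.22,
                ("B2", "X3"): 1.50,
                ("B1", "X2"): 0.85,
                ("B2", "X2"): 0.85,
            },
        ),
        "cg_kd_ecdysone": ConditionScenario(
            "cg_kd_ecdysone",
            {
                ("B1", "X1"): 1.08,
                ("B2", "X1"): 1.08,
                ("B2", "X3"): 1.50,
                ("B1", "X2"): 0.85,
                ("B2", "X2"): 0.85,
            },
        ),
        "disc_wt": ConditionScenario("disc_wt"),
        "disc_cg_mutant": ConditionScenario(
            "disc_cg_mutant",
            {
                ("B1", "X1_disc"): 0.70,
                ("B2", "X1_disc"): 0.70,
            },
        ),
    }


# -- simulation config ---------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Library-scale parameters: depth, duplication, shear-offset range."""

    seed: int
    n_events: int = 1_000_000
    duplication_rate: float = 0.3
    offset_range: tuple[int, int] = (50, 1500)
    genome_length: int = DEFAULT_GENOME_LENGTH

    def __post_init__(self) -> None:
        if self.n_events <= 0:
            raise ConfigError("n_events must be > 0")
        if self.duplication_rate < 0:
            raise ConfigError("duplication_rate must be >= 0")
        lo, hi = self.offset_range
        if lo <= 0 or hi < lo:
            raise ConfigError("offset_range must be positive and ordered")


@dataclass
class SimulatedLibrary:
    """Generator output: read records plus exact ground truth.

    ``records`` carry a ``molecule`` column with the unique-molecule
    identity (the rank of the molecule's (fragment, breakpoint) key);
    the analysis pipeline never looks at it, tests do.
    """

    viewpoint: ViewpointSpec
    scenario: str
    seed: int
    records: pd.DataFrame = field(repr=False)
    truth_probabilities: np.ndarray = field(repr=False)
    truth_unique: pd.DataFrame = field(repr=False)
    fmap: FragmentMap = field(repr=False)

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_unique(self) -> int:
        return len(self.truth_unique)

    def truth_unique_counts(self) -> np.ndarray:
        """Unique molecules per fragment (what dedup should recover)."""
        return np.bincount(
            self.truth_unique["fragment"].to_numpy(), minlength=self.fmap.n_fragments
        )


# -- generation ----------------------------------------------------------


def random_genome(
    length: int = DEFAULT_GENOME_LENGTH, seed: int = 0, name: str = DEFAULT_CHROM
) -> GenomeSequence:
    """Uniform random A/C/G/T chromosome (a 4-bp site lands every ~256 bp)."""
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = alphabet[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
    return GenomeSequence(name=name, sequence=seq)


def build_contact_probabilities(
    fmap: FragmentMap,
    viewpoint: ViewpointSpec,
    model: ContactModelConfig,
    scenario: ConditionScenario | None = None,
    windows: dict[str, WindowSpec] | None = None,
) -> np.ndarray:
    """Per-fragment capture probabilities for one viewpoint x condition.

    The naive baseline combines distance decay, the asymmetric domain, the
    peak list and the background floor; scenario multipliers then scale
    in-window mass and the out-of-window mass is rescaled to restore total
    probability 1, which preserves each configured window-mean ratio
    exactly.
    """
    if viewpoint.chrom != fmap.chrom:
        raise ConfigError(
            f"viewpoint {viewpoint.name!r} on {viewpoint.chrom!r}, map covers {fmap.chrom!r}"
        )
    bait = fmap.locate(viewpoint.anchor)
    n = fmap.n_fragments

    d = np.abs(np.arange(n) - bait).astype(float)
    weight = (1.0 + d) ** (-model.decay_exponent)

    delta = fmap.midpoints.astype(np.int64) - viewpoint.anchor
    in_domain = ((delta >= 0) & (delta <= model.domain_downstream_extent)) | (
        (delta < 0) & (-delta <= model.domain_upstream_extent)
    )
    weight[in_domain] *= model.domain_enrichment_factor

    for peak_window, height in model.peaks:
        lo, hi = peak_window.resolve(fmap)
        weight[lo:hi] *= height

    weight += model.far_background_floor

    hw = model.viewpoint_exclusion_halfwidth
    weight[max(0, bait - hw) : min(n, bait + hw + 1)] = 0.0

    total = weight.sum()
    if total <= 0:
        raise ConfigError("contact model produced zero total mass")
    q = weight / total

    if scenario is None:
        return q
    mults = scenario.for_viewpoint(viewpoint.name)
    if not mults:
        return q

    if windows is None:
        windows = default_windows()
    in_any = np.zeros(n, dtype=bool)
    p = q.copy()
    window_mass = 0.0
    scaled_mass = 0.0
    for wname, m in sorted(mults.items()):
        if wname not in windows:
            raise ConfigError(f"scenario {scenario.name!r} references unknown window {wname!r}")
        lo, hi = windows[wname].resolve(fmap)
        if in_any[lo:hi].any():
            raise ConfigError(f"scenario windows overlap at {wname!r}")
        in_any[lo:hi] = True
        mass = q[lo:hi].sum()
        window_mass += mass
        scaled_mass += m * mass
        p[lo:hi] = m * q[lo:hi]

    out_mass = 1.0 - window_mass
    if out_mass <= 0:
        raise ConfigError("scenario windows cover the whole region")
    rescale = (1.0 - scaled_mass) / out_mass
    if rescale <= 0:
        raise ConfigError("scenario multipliers demand more than the total probability mass")
    p[~in_any] *= rescale
    return p


def simulate_library(
    fmap: FragmentMap,
    viewpoint: ViewpointSpec,
    model: ContactModelConfig,
    scenario: ConditionScenario,
    sim: SimConfig,
    windows: dict[str, WindowSpec] | None = None,
) -> SimulatedLibrary:
    """Draw one 4C library: molecules, shear points, duplicates, read records.

    ``n_events`` capture events are drawn from the contact probability
    vector.  Each event ligates at one restriction boundary of its fragment
    (uniformly left or right) and shears at a uniform offset from that
    boundary, which fixes both the emitted read interval and the
    deduplication key.  PCR then emits each molecule ``1 + k`` times with
    ``k`` geometric with mean ``duplication_rate``.  Output is a pure
    function of the seed.
    """
    p = build_contact_probabilities(fmap, viewpoint, model, scenario, windows)
    rng = np.random.default_rng(sim.seed)
    n = sim.n_events
    L = fmap.genome_length

    frag = rng.choice(fmap.n_fragments, size=n, p=p)
    left_anchor = rng.integers(0, 2, size=n).astype(bool)  # ligation boundary side
    lo, hi = sim.offset_range
    offset = rng.integers(lo, hi + 1, size=n)

    starts = fmap.starts[frag]
    ends = fmap.ends[frag]
    # forward read: anchored at the fragment's left boundary, shear at start+offset
    # reverse read: anchored at the right boundary, shear at end-offset
    read_start = np.where(left_anchor, starts, np.maximum(ends - offset, 0))
    read_end = np.where(left_anchor, np.minimum(starts + offset, L), ends)
    breakpoint = np.where(left_anchor, read_end, read_start)
    strand = np.where(left_anchor, "+", "-")

    key = frag.astype(np.int64) * (L + 1) + breakpoint
    unique_keys, molecule = np.unique(key, return_inverse=True)
    truth_unique = pd.DataFrame(
        {
            "fragment": pd.Series((unique_keys // (L + 1)).astype(np.int64), copy=False),
            "breakpoint": pd.Series((unique_keys % (L + 1)).astype(np.int64), copy=False),
        },
        copy=False,
    )

    if sim.duplication_rate > 0:
        # geometric number of extra PCR copies, mean = duplication_rate
        reps = rng.geometric(1.0 / (1.0 + sim.duplication_rate), size=n)
    else:
        reps = np.ones(n, dtype=np.int64)

    m = int(reps.sum())
    order = rng.permutation(m)
    # one block per column (copy=False Series) to avoid a consolidation copy
    records = pd.DataFrame(
        {
            "chrom": pd.Series(np.full(m, fmap.chrom, dtype=object), copy=False),
            "start": pd.Series(np.repeat(read_start, reps)[order], copy=False),
            "end": pd.Series(np.repeat(read_end, reps)[order], copy=False),
            "strand": pd.Series(np.repeat(strand, reps)[order], copy=False),
            "viewpoint": pd.Series(np.full(m, viewpoint.name, dtype=object), copy=False),
            "molecule": pd.Series(np.repeat(molecule, reps)[order], copy=False),
        },
        copy=False,
    )
    return SimulatedLibrary(
        viewpoint=viewpoint,
        scenario=scenario.name,
        seed=sim.seed,
        records=records,
        truth_probabilities=p,
        truth_unique=truth_unique,
        fmap=fmap,
    )


def write_library(lib: SimulatedLibrary, prefix, sam: bool = False) -> list[str]:
    """Serialize a library: reads as BED (optionally SAM), truth as BedGraph."""
    if lib.n_records == 0:
        raise InputError("refusing to write an empty library")
    prefix = str(prefix)
    paths = []
    bed = prefix + ".reads.bed"
    write_reads_bed(lib.records, bed)
    paths.append(bed)
    if sam:
        sam_path = prefix + ".reads.sam"
        write_reads_sam(lib.records, sam_path, lib.fmap)
        paths.append(sam_path)
    truth = prefix + ".truth.bedgraph"
    pd.DataFrame(
        {
            "chrom": lib.fmap.chrom,
            "start": lib.fmap.starts,
            "end": lib.fmap.ends,
            "value": lib.truth_probabilities,
        }
    ).to_csv(truth, sep="\t", header=False, index=False, float_format="%.10g")
    paths.append(truth)
    return paths


def scenario_with_multiplier(
    base: ConditionScenario, viewpoint: str, window: str, multiplier: float
) -> ConditionScenario:
    """Convenience: a copy of ``base`` with one multiplier overridden."""
    mults = dict(base.multipliers)
    mults[(viewpoint, window)] = multiplier
    return replace(base, multipliers=mults)
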