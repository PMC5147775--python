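# Methods

## Scope and data model

`fourcat` analyses single-viewpoint 4C data on one cis region. The
coordinate system is the ordered map of restriction fragments produced by
in-silico digestion: every occurrence of the recognition site (default
`GATC`, the 4-cutter DpnII) cuts at the first base of the site, fragments
are the intervals between consecutive cuts plus the chromosome ends, and
zero-length fragments are discarded. Coordinates are 0-based half-open
internally; 1-based SAM conventions are converted only at I/O boundaries.
`N` bases never match a site. Multi-enzyme digests and trans-chromosomal
contacts are out of scope.

The unit of observation is the *ligation event*: one captured ligation
between the bait and another fragment. A mapped read is primed from the
bait side and crosses the junction into the captured fragment, so the
read's 5'-most aligned base sits at the captured fragment's restriction
boundary; the captured fragment is therefore the one containing that base
(strand-aware), and the distal read coordinate is the sonication shear
point. PCR duplicates are collapsed on the exact key (viewpoint, captured
fragment, shear coordinate) — shear points are treated at single-bp
resolution with no tolerance window, which is what makes duplicate removal
deterministic and order-independent. Fragments within a configurable
halfwidth of the bait (default 2 on each side) are zeroed in every
profile: self-ligation and undigested templates dominate there and carry
no contact information. The library total `N` counts unique events outside
this exclusion zone.

## Contact trends and domainograms

Smoothed trends are windowed means of per-fragment counts. Windows are
fixed-width and centered, with the center fragment at position
`(k - 1) // 2` of the window (even widths put the extra fragment
downstream); at chromosome edges the window is shifted inward so every
position averages exactly `k` observed fragments. We chose shifting over
shrinking the edge windows because it fabricates no counts *and* preserves
a useful invariant: at `k` equal to the region width the trend is exactly
the global mean everywhere. The error band is ± 2 · sd/√k by default —
"two standard deviations of the estimated mean" is read as twice the
standard error of the window mean; twice the window sd is available via
`band="sd"`.

A domainogram stacks these windowed means for scales 10 through 300
fragments (inclusive, 291 rows) into a scales × positions grid. The
intensity is the raw windowed mean (no transform); rendering rank-scales
each row only for display, and plotting is cosmetic and untested
numerics-wise. The differential domainogram scales both profiles to the
geometric mean of their totals, applies a pseudocount of 0.5 ligations per
fragment, and shows log2 ratios; the geometric-mean target (rather than
scaling one library onto the other) makes the grid exactly antisymmetric
under swapping conditions even with the pseudocount. Each cell also gets a
Pearson chi-square p-value from the raw in/out-window table at that cell's
window, evaluated in closed form across all positions.

## Differential window tests

Coverage normalization scales library B's counts by `N_A / N_B`; percent
change is computed on the resulting window means, so it is invariant to
the common scale. The significance test deliberately does *not* use scaled
counts: it is a Pearson chi-square (df = 1) on the raw 2×2 table of
in-window vs out-of-window unique ligation totals, whose margins embody
the same total-coverage normalization without breaking countness. The
out-of-window complement is the analyzed cis region minus the window and
the bait exclusion zone. Yates continuity correction is off by default —
window totals here are in the thousands, where the correction is
negligible and the uncorrected statistic matches the textbook
Σ(O−E)²/E — and available as a flag. If any expected cell falls below 1
the result is flagged `low_count` but the p-value is still reported.
Significance tiers are `*` for p < 0.05 and `**` for p < 0.001, with no
multiple-testing correction across a panel (tiers are reported
per-comparison). Replicate-level biological variance is not modelled;
libraries are pooled totals.

## The synthetic library generator

The generator is first-class, tested code: it defines the study conditions
under which recovery is demonstrated. Per fragment at distance `d`
fragments from the bait, the unnormalized contact weight is

```
(1 + d)^-decay_exponent × enrichment (inside the asymmetric domain)
                        × peak height (inside a peak window)
+ far_background_floor
```

with the bait exclusion zone zeroed and the vector normalized to sum 1.
Defaults: decay exponent 1.0; domain extent 250 kb downstream and 125 kb
upstream of the bait with enrichment 3.0; discrete 31-fragment contact
peaks at the X1/X2/X3 anchors (heights 3.0/2.5/2.5) present in every
condition, since the long-range contacts pre-exist ligand exposure; floor
0.25. The floor was fixed by a design calculation, before any recovery was
measured, to cap the expected number of draws on the hottest fragment at
roughly 15% of the shear-key space (see below); it corresponds to a
substantial far-cis background, which keeps the simulation conservative —
domain and peak signal sit on a non-negligible background rather than on
zero.

Condition effects are injected on the quantity the pipeline reports:
post-normalization window means. For each (viewpoint, window) multiplier
`m`, in-window probabilities are multiplied by `m` and only the
out-of-window mass is rescaled to restore sum 1, so the window-mean ratio
against the naive vector equals `m` to machine precision. Default
scenario calibration: ecdysone = X1 ×1.27 (B1) and ×1.22 (B2), X2 ×0.85
(both baits), X3 ×1.50 (B2); Cg knockdown + ecdysone attenuates X1 to
×1.08; mutant imaginal discs reduce X1 (40-fragment window) to ×0.70 vs
wild type. The two X1 magnitudes are reported effect sizes; the others
realize effects reported only as significant directions and are
configuration values, not code constants.

Each drawn capture event ligates at one restriction boundary of its
fragment (uniformly left or right, which fixes the read strand) and shears
at an offset drawn uniformly from 50–1500 bp beyond that boundary; the
read interval runs from the boundary to the shear point, clipped to the
chromosome. PCR duplication emits each molecule `1 + k` times with `k`
geometric (mean = `duplication_rate`, default 0.3, emulating libraries of
1–3 M reads yielding ~1 M inferred events); records are then shuffled.
Output is a pure function of the seed.

A molecule's identity *is* its (fragment, shear coordinate) key — exactly
what deduplication collapses on. Two independent capture events that shear
at the same base are indistinguishable, in simulation as in a real
library, so the stored ground truth is the set of distinct keys and
"dedup recovers the pre-duplication unique set exactly" is well-posed.
Because the key space per fragment is finite (~2 × 1451 coordinates),
hot fragments lose a few percent of their draws to such coincidental
collisions; at the default depth this compresses a injected ×1.27 window
ratio by about one percentage point, which is why recovery is contracted
to ±3 points rather than to sampling noise alone. The offset range
default (50–1500 bp) was chosen a priori by this collision calculation:
narrower supports make the compression a dominant artifact rather than a
minor correction. What the generator does *not* emulate: sequencing error,
mappability bias, fragment-length-dependent capture efficiency,
trans-chromosomal contacts, or replicate-to-replicate biological
variance — so passing recovery tests demonstrates correctness of the
pipeline's accounting, not robustness to real-data artifacts.

## Summary statistics

`ttest_from_summary` computes the two-sample t-test directly from printed
(mean, sd, n) summaries; the default is the pooled-variance variant with
`df = n_a + n_b − 2` (Welch available). Printed summaries are rounded, so
p-values from published tables reproduce only to order of magnitude.
`mann_whitney` offers exact enumeration of all C(n_a+n_b, n_a) group
assignments (combined n ≤ 16; ties via midranks; two-sided p =
2·min(tail probabilities) capped at 1) and a tie-corrected normal
approximation with a continuity correction clamped at the mean, so
identical samples give p = 1 exactly; the two modes agree to ~0.01 for
moderate tie-free samples. `ddct_fold_change` averages Ct replicates per
condition, then returns 2^(−ΔΔCt); amplification-efficiency corrections
are out of scope.

## Pipeline, determinism and problem sizes

One YAML config drives digestion → simulation → extraction → profiling →
domainograms → the differential panel. Per-library seeds are spawned
deterministically from the top-level seed via `numpy`'s `SeedSequence`,
all output formatting is fixed, and re-running a config is byte-identical.
The run manifest records the config SHA-256, the seed, every output file
and per-library event counts; the run aborts if a listed file is missing.

Problem sizes used in the test suite are the study conditions themselves
where the contract names them (10⁶ unique events for effect recovery, 10⁵
for duplicate-removal fidelity and for each of the 200 null replicate
pairs) and deliberately smaller elsewhere (demo config 5 × 10⁴ events,
integration tests 1.5 × 10⁴) where the property under test does not depend
on depth. The null-calibration check accepts rejection rates inside the
99% binomial band around 0.05 for 200 pairs, i.e. [0.014, 0.096].

## Known limitations

Single chromosome, single enzyme, pooled libraries; no mapping-quality
model beyond a minimum filter and a multimapper flag; the chi-square
complement set ("rest of the analyzed region") is one of several defensible
choices and is recorded in configuration rather than asserted as uniquely
correct; domainogram rendering is not part of the numeric contract.
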