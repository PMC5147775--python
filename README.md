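# fourcat

4C-seq (circularized chromosome conformation capture) quantifies which
genomic loci contact one chosen "viewpoint" (bait) restriction fragment.
`fourcat` is a tested, reusable pipeline for single-viewpoint 4C analysis
on a cis region: in-silico restriction digestion (DpnII, `GATC`),
conversion of mapped reads into ligation events, PCR-duplicate removal via
exact sonication breakpoints, multiscale domainograms, and chi-square
differential contact testing between conditions. It ships a calibrated
synthetic 4C library generator, so every analysis stage can be exercised
as a parameter-recovery experiment with known ground truth — no sequencing
data required. A small `summary_stats` module adds the companion
statistics such experiments typically need: two-sample t-tests from
printed group summaries, exact/asymptotic Mann-Whitney U for per-cell spot
counts, and ΔΔCt qPCR fold changes.

The default study geometry models the *Drosophila* *BR-C* locus: baits B1
(X:1,609,904) and B2 (X:1,619,649) and long-range contact partners X1–X3,
with an asymmetric contact domain (~250 kb downstream, ~125 kb upstream of
the bait) and ecdysone/Combgap-dependent contact changes injected as exact
window-mean multipliers (e.g. +27% at X1 for B1 after ligand exposure).

## Core quantities

For a viewpoint *v*, fragments are the intervals between `GATC` cut sites.
A contact profile is the vector of unique ligation counts
*c<sub>i</sub>* per fragment *i* after collapsing PCR duplicates on the
exact key (viewpoint, fragment, shear coordinate), with total
*N* = Σ*c<sub>i</sub>*.

* **Window mean** — for a window *W* of *k* fragments,
  m(W) = (1/k) Σ<sub>i∈W</sub> c̃<sub>i</sub>, where c̃ are counts scaled
  to a common library total ("normalization for total sequence coverage").
* **Percent change** — 100 · (m_A(W) − m_B(W)) / m_B(W) between
  conditions A and B.
* **Chi-square window test** — Pearson χ² (df = 1, no continuity
  correction by default) on the 2×2 table
  [[in<sub>A</sub>, N<sub>A</sub>−in<sub>A</sub>],
  [in<sub>B</sub>, N<sub>B</sub>−in<sub>B</sub>]] of raw in-window vs
  out-of-window unique ligation totals; tiers `*` (p < 0.05) and `**`
  (p < 0.001).
* **Domainogram** — windowed means at every scale k = 10…300 fragments,
  stacked into a scales × positions grid; the differential variant shows
  log2 ratios of coverage-normalized means with a per-cell χ² mask.

## Worked example

Simulate naive and ecdysone-treated libraries for bait B1 (10⁶ unique
ligation events each, duplication rate 0.3), run extraction and
deduplication, and test the 200-fragment X1 window:

```python
import fourcat

fm = fourcat.digest_genome(fourcat.random_genome(seed=0))   # 7733 fragments
vp, wins = fourcat.default_viewpoints(), fourcat.default_windows()
model, scen = fourcat.default_model(), fourcat.default_scenarios()

def profile(name, seed):
    lib = fourcat.simulate_library(fm, vp["B1"], model, scen[name],
                                   fourcat.SimConfig(seed=seed), wins)
    ev = fourcat.dedup_by_sonication_site(fourcat.reads_to_ligations(lib.records, fm))
    return fourcat.profile_from_events(ev, fm, name, viewpoint="B1",
                                       bait_position=vp["B1"].anchor)

naive, ecd = profile("naive", 101), profile("ecdysone", 102)
res = fourcat.chisq_window_test(ecd, naive, wins["X1"])
print(f"X1 percent change: {res.percent_change:.2f}%  "
      f"chi2={res.chi2:.1f}  p={res.pvalue:.3g}  tier={res.tier}")
```

prints

```
X1 percent change: 25.88%  chi2=985.7  p=2.3e-216  tier=**
```

i.e. the injected 27% contact gain is recovered from the deduplicated
libraries (the small shortfall is coincidental shear-point collisions plus
sampling noise; see `docs/methods.md`), and the window test lands in the
top significance tier.

The same machinery is scriptable from the shell:

```sh
fourcat run --config src/fourcat/data/demo_config.yaml --out-dir out/
fourcat stats ttest --csv groups.csv --a control --b mutant
# t=3.554  df=62  p=0.0007322
fourcat stats mannwhitney --csv spots.csv --a ctrl --b ecd --mode exact
# U=0  p=0.1
```

`fourcat run` executes digestion → simulation → extraction → profiling →
domainograms → the differential panel from one YAML config and writes a
manifest with per-library event counts, the config hash and all seeds;
re-running with the same config and seed is byte-identical.

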