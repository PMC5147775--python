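# Demo run: synthetic 2 Mb cis region, both baits, three cell-culture
# conditions, at reduced depth so the full pipeline finishes in seconds.
seed: 7
genome:
  synthetic:
    length: 2000000
    chrom: chrXsim
digestion:
  site: GATC
viewpoints:
  - {name: B1, anchor: 1609904, role: bait}
  - {name: B2, anchor: 1619649, role: bait}
  - {name: X1, anchor: 1587064, role: contact}
  - {name: X2, anchor: 1829722, role: contact}
  - {name: X3, anchor: 1945463, role: contact}
windows:
  - {name: X1, anchor: 1587064, width: 200}
  - {name: X2, anchor: 1829722, width: 200}
  - {name: X3, anchor: 1945463, width: 30}
  - {name: X1_disc, anchor: 1587064, width: 40}
model:
  decay_exponent: 1.0
  domain_upstream_extent: 125000
  domain_downstream_extent: 250000
  domain_enrichment_factor: 3.0
  far_background_floor: 0.25
  viewpoint_exclusion_halfwidth: 2
  peaks:
    - {anchor: 1587064, width: 31, height: 3.0}
    - {anchor: 1829722, width: 31, height: 2.5}
    - {anchor: 1945463, width: 31, height: 2.5}
scenarios:
  naive: {}
  ecdysone:
    B1:X1: 1.27
    B2:X1: 1.22
    B2:X3: 1.50
    B1:X2: 0.85
    B2:X2: 0.85
  cg_kd_ecdysone:
    B1:X1: 1.08
    B2:X1: 1.08
    B2:X3: 1.50
    B1:X2: 0.85
    B2:X2: 0.85
scenarios_to_run: [naive, ecdysone, cg_kd_ecdysone]
simulation:
  n_events: 50000
  duplication_rate: 0.3
  offset_min: 50
  offset_max: 1500
extraction:
  exclusion_halfwidth: 2
smoothing:
  scales: {start: 10, stop: 100, step: 10}
  band: sem
comparisons:
  - {a: ecdysone, b: naive, viewpoints: [B1, B2], windows: [X1, X2, X3]}
  - {a: ecdysone, b: cg_kd_ecdysone, viewpoints: [B1, B2], windows: [X1, X2, X3]}
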