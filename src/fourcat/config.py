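"""Run configuration and pipeline orchestration.

One structured YAML file drives the whole pipeline: genome source,
digestion, viewpoints, windows, contact model, scenarios, simulation
depth, extraction, smoothing scales and the comparison plan.  A run is a
pure function of (config, seed): per-library seeds are spawned
deterministically from the top-level seed, and every numeric output is
byte-identical across re-runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .differential import WindowSpec, chisq_window_test, panel_to_frame
from .errors import ConfigError
from .fragment_map import GenomeSequence, digest_genome
from .ligation import dedup_by_sonication_site, profile_from_events, reads_to_ligations
from .multiscale import build_domainogram
from .synthetic import (
    ConditionScenario,
    ContactModelConfig,
    SimConfig,
    ViewpointSpec,
    random_genome,
    simulate_library,
    write_library,
)


@dataclass
class RunConfig:
    """Thin typed view over the raw YAML mapping (kept for round-tripping)."""

    raw: dict = field(repr=False)
    path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a mapping")
        return cls(raw=raw, path=str(path))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.raw, fh, sort_keys=False)

    def sha256(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()

    # -- typed accessors -------------------------------------------------

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    def genome(self) -> GenomeSequence:
        g = self.raw.get("genome", {})
        if "fasta" in g:
            return GenomeSequence.from_fasta(g["fasta"], g.get("chrom"))
        syn = g.get("synthetic", {})
        return random_genome(
            length=int(syn.get("length", 2_000_000)),
            seed=int(syn.get("seed", self.seed)),
            name=str(syn.get("chrom", "chrXsim")),
        )

    @property
    def site(self) -> str:
        return str(self.raw.get("digestion", {}).get("site", "GATC"))

    def viewpoints(self, chrom: str) -> dict[str, ViewpointSpec]:
        out = {}
        for v in self.raw.get("viewpoints", []):
            spec = ViewpointSpec(
                str(v["name"]), chrom, int(v["anchor"]), str(v.get("role", "bait"))
            )
            out[spec.name] = spec
        return out

    def windows(self) -> dict[str, WindowSpec]:
        out = {}
        for w in self.raw.get("windows", []):
            spec = WindowSpec(str(w["name"]), int(w["anchor"]), int(w["width"]))
            out[spec.name] = spec
        return out

    def model(self) -> ContactModelConfig:
        m = dict(self.raw.get("model", {}))
        peaks = tuple(
            (WindowSpec(f"peak{i}", int(p["anchor"]), int(p["width"])), float(p["height"]))
            for i, p in enumerate(m.pop("peaks", []))
        )
        return ContactModelConfig(peaks=peaks, **m)

    def scenarios(self) -> dict[str, ConditionScenario]:
        out = {}
        for name, mults in self.raw.get("scenarios", {}).items():
            parsed = {}
            for key, m in (mults or {}).items():
                vp, _, window = str(key).partition(":")
                if not window:
                    raise ConfigError(
                        f"scenario {name!r}: multiplier key {key!r} is not 'viewpoint:window'"
                    )
                parsed[(vp, window)] = float(m)
            out[str(name)] = ConditionScenario(str(name), parsed)
        return out

    def sim_config(self, seed: int) -> SimConfig:
        s = self.raw.get("simulation", {})
        return SimConfig(
            seed=seed,
            n_events=int(s.get("n_events", 1_000_000)),
            duplication_rate=float(s.get("duplication_rate", 0.3)),
            offset_range=(int(s.get("offset_min", 50)), int(s.get("offset_max", 1500))),
        )

    @property
    def exclusion_halfwidth(self) -> int:
        return int(self.raw.get("extraction", {}).get("exclusion_halfwidth", 2))

    def scales(self) -> list[int]:
        s = self.raw.get("smoothing", {}).get("scales", {})
        if isinstance(s, list):
            return [int(k) for k in s]
        return list(
            range(int(s.get("start", 10)), int(s.get("stop", 300)) + 1, int(s.get("step", 1)))
        )

    @property
    def scenarios_to_run(self) -> list[str]:
        return [str(s) for s in self.raw.get("scenarios_to_run", [])] or list(
            self.raw.get("scenarios", {}).keys()
        )

    def comparisons(self) -> list[dict]:
        return list(self.raw.get("comparisons", []))


def validate_config(config: RunConfig) -> list[str]:
    """Collect every config invariant violation; empty list means valid."""
    problems: list[str] = []
    raw = config.raw
    sim = raw.get("simulation", {})
    if int(sim.get("n_events", 1)) <= 0:
        problems.append("simulation.n_events must be > 0")
    if float(sim.get("duplication_rate", 0)) < 0:
        problems.append("simulation.duplication_rate must be >= 0")

    try:
        genome = config.genome()
        fmap = digest_genome(genome, config.site)
    except Exception as exc:  # noqa: BLE001 - reported, not raised
        problems.append(f"genome/digestion: {exc}")
        return problems

    try:
        windows = config.windows()
        viewpoints = config.viewpoints(fmap.chrom)
        scenarios = config.scenarios()
    except Exception as exc:  # noqa: BLE001
        problems.append(f"config parse: {exc}")
        return problems

    for w in windows.values():
        if w.width > fmap.n_fragments:
            problems.append(
                f"window {w.name!r} wider ({w.width}) than fragment count ({fmap.n_fragments})"
            )
        elif not 0 <= w.anchor < fmap.genome_length:
            problems.append(f"window {w.name!r} anchor outside the genome")
    for v in viewpoints.values():
        if not 0 <= v.anchor < fmap.genome_length:
            problems.append(f"viewpoint {v.name!r} anchor outside the genome")
    for name, sc in scenarios.items():
        for vp, window in sc.multipliers:
            if vp not in viewpoints:
                problems.append(f"scenario {name!r} references unknown viewpoint {vp!r}")
            if window not in windows:
                problems.append(f"scenario {name!r} references unknown window {window!r}")
    for name in config.scenarios_to_run:
        if name not in scenarios:
            problems.append(f"scenarios_to_run entry {name!r} is not a defined scenario")
    for comp in config.comparisons():
        for cond in (comp.get("a"), comp.get("b")):
            if cond not in scenarios:
                problems.append(f"comparison references unknown scenario {cond!r}")
        for vp in comp.get("viewpoints", []):
            if vp not in viewpoints:
                problems.append(f"comparison references unknown viewpoint {vp!r}")
        for wname in comp.get("windows", []):
            if wname not in windows:
                problems.append(f"comparison references unknown window {wname!r}")
    return problems


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute digestion -> simulation -> extraction -> profiling -> differential.

    Returns (and writes) a manifest listing every output file, per-library
    event counts, the config hash and the seed.
    """
    problems = validate_config(config)
    if problems:
        raise ConfigError("invalid config: " + "; ".join(problems))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    def register(path) -> str:
        files.append(str(Path(path).relative_to(out)))
        return str(path)

    genome = config.genome()
    fmap = digest_genome(genome, config.site)
    fmap.to_bed(register(out / "fragments.bed"))

    viewpoints = config.viewpoints(fmap.chrom)
    windows = config.windows()
    model = config.model()
    scenarios = config.scenarios()
    baits = [v for v in viewpoints.values() if v.role == "bait"]
    run_names = config.scenarios_to_run

    # deterministic per-library seeds spawned from the top-level seed
    n_libs = len(baits) * len(run_names)
    lib_seeds = (
        np.random.SeedSequence(config.seed).generate_state(n_libs, dtype=np.uint64)
        % (2**31)
    ).astype(int)

    profiles: dict[tuple[str, str], object] = {}
    library_info: dict[str, dict] = {}
    i = 0
    for bait in baits:
        for scen_name in run_names:
            lib = simulate_library(
                fmap, bait, model, scenarios[scen_name],
                config.sim_config(int(lib_seeds[i])), windows,
            )
            i += 1
            prefix = out / f"{bait.name}_{scen_name}"
            for p in write_library(lib, prefix):
                register(p)

            events = dedup_by_sonication_site(
                reads_to_ligations(lib.records, fmap, known_viewpoints=viewpoints)
            )
            profile = profile_from_events(
                events,
                fmap,
                condition=scen_name,
                viewpoint=bait.name,
                bait_position=bait.anchor,
                exclusion_halfwidth=config.exclusion_halfwidth,
            )
            profile.write(
                register(prefix.with_suffix(".profile.bedgraph")),
                register(prefix.with_suffix(".profile.json")),
            )
            dg = build_domainogram(profile, scales=config.scales())
            dg.to_tsv(register(prefix.with_suffix(".domainogram.tsv")))
            profiles[(bait.name, scen_name)] = profile
            library_info[f"{bait.name}:{scen_name}"] = {
                "seed": int(lib.seed),
                "n_records": int(lib.n_records),
                "n_unique_truth": int(lib.n_unique),
                "n_profile": int(profile.n),
            }

    results = []
    for comp in config.comparisons():
        for vp_name in comp.get("viewpoints", []):
            for wname in comp.get("windows", []):
                res = chisq_window_test(
                    profiles[(vp_name, comp["a"])],
                    profiles[(vp_name, comp["b"])],
                    windows[wname],
                )
                results.append((vp_name, res))
    if results:
        frame = panel_to_frame([r for _, r in results])
        frame.insert(0, "viewpoint", [vp for vp, _ in results])
        frame.to_csv(register(out / "differential_panel.tsv"), sep="\t", index=False,
                     float_format="%.6g")
        with open(register(out / "differential_panel.json"), "w") as fh:
            json.dump(frame.to_dict(orient="records"), fh, indent=2, default=float)
            fh.write("\n")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config.sha256(),
        "files": sorted(files),
        "libraries": library_info,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    missing = [f for f in files if not (out / f).exists()]
    if missing:
        raise ConfigError(f"manifest lists missing files: {missing}")
    return manifest
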