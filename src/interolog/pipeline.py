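"""Config-driven runs tying the analysis stages into reproducible reports.

A run is described by a YAML (or plain dict) configuration naming the
per-species interaction files, the homology inputs per species pair, the
stages to execute and the estimation settings. All randomness flows from the
single configured seed, outputs are written as deterministically ordered
TSV/JSON reports, and a manifest records seeds, input checksums and stage
status -- re-running an identical configuration reproduces every report
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .conservation import estimate_coverage_and_conservation, loss_rate
from .error_models import source_subsampling, target_subsampling
from .homology import HomologyMap, load_curated_orthologs, read_blast_tabular, \
    reciprocal_best_hits, reciprocal_hits
from .inference import family_size_filter, infer_across, infer_within, score
from .interactome import Interactome, read_interactions, summarize, write_summary
from .nulls import likelihood_ratio, rewiring_ratio
from .synthetic import ObservationParams, WorldParams, generate_world, observe

ALL_STAGES = ("summarize", "transfer", "within", "nulls", "errors", "estimate",
              "lossrate")
WITHIN_MODES = ("one_same", "both_different_1", "both_different_2")


@dataclass
class RunConfig:
    """Validated run configuration (see ``RunConfig.from_dict``)."""

    species: dict[str, dict]
    homology: dict[tuple[str, str], dict]
    stages: list[str]
    out_dir: Path
    seed: int = 0
    reference: Optional[str] = None
    modes: list[str] = field(default_factory=lambda: list(WITHIN_MODES))
    n_rewirings: int = 10
    subsample_fractions: list[float] = field(default_factory=lambda: [0.25, 0.5, 0.75])
    subsample_reps: int = 10
    divergence_times: dict[tuple[str, str], dict] = field(default_factory=dict)

    @staticmethod
    def _pair_key(key: str) -> tuple[str, str]:
        parts = key.split(":")
        if len(parts) != 2:
            raise ValueError(f"homology key {key!r} must be 'SPECIES:SPECIES'")
        return (parts[0], parts[1])

    @classmethod
    def from_dict(cls, raw: dict, out_dir: str | Path) -> "RunConfig":
        stages = list(raw.get("stages", ALL_STAGES))
        unknown = set(stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        species = raw.get("species", {})
        if not species:
            raise ValueError("config names no species")
        for name, spec in species.items():
            if "edges" not in spec:
                raise ValueError(f"species {name!r} has no 'edges' path")
            if not Path(spec["edges"]).exists():
                raise ValueError(f"missing input file: {spec['edges']}")
        homology = {cls._pair_key(k): v for k, v in raw.get("homology", {}).items()}
        for (s, t), spec in homology.items():
            for p in (spec.get("path"), spec.get("ab"), spec.get("ba")):
                if p is not None and not Path(p).exists():
                    raise ValueError(f"missing input file: {p}")
        return cls(
            species=species,
            homology=homology,
            stages=stages,
            out_dir=Path(out_dir),
            seed=int(raw.get("seed", 0)),
            reference=raw.get("reference"),
            modes=list(raw.get("modes", WITHIN_MODES)),
            n_rewirings=int(raw.get("n_rewirings", 10)),
            subsample_fractions=list(raw.get("subsample_fractions", [0.25, 0.5, 0.75])),
            subsample_reps=int(raw.get("subsample_reps", 10)),
            divergence_times={
                cls._pair_key(k): v for k, v in raw.get("divergence_times", {}).items()
            },
        )

    @classmethod
    def from_yaml(cls, path: str | Path, out_dir: str | Path,
                  seed: Optional[int] = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if seed is not None:
            raw["seed"] = seed
        return cls.from_dict(raw, out_dir)


def _load_map(spec: dict, s: str, t: str) -> HomologyMap:
    kind = spec.get("kind", "tsv")
    if kind == "tsv":
        hmap = HomologyMap.from_tsv(spec["path"], s, t)
    elif kind == "curated":
        hmap = load_curated_orthologs(spec["path"], s, t)
    elif kind in ("reciprocal_hits", "reciprocal_best_hits"):
        ab = read_blast_tabular(spec["ab"], s, t)
        ba = read_blast_tabular(spec["ba"], t, s)
        if kind == "reciprocal_hits":
            hmap = reciprocal_hits(ab, ba, float(spec.get("threshold", 1e-10)))
        else:
            hmap = reciprocal_best_hits(ab, ba, float(spec.get("e_cap", 1e-10)))
    else:
        raise ValueError(f"unknown homology kind {kind!r}")
    if spec.get("max_homologs"):
        hmap = family_size_filter(hmap, int(spec["max_homologs"]))
    return hmap


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; return the manifest.

    A stage failure is recorded in the manifest (written before the error
    propagates) and previously completed outputs are retained.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "inputs": {},
        "outputs": [],
    }
    for name, spec in sorted(config.species.items()):
        manifest["inputs"][spec["edges"]] = _sha256(spec["edges"])

    interactomes: dict[str, Interactome] = {}
    for name, spec in config.species.items():
        interactomes[name] = read_interactions(
            spec["edges"], name,
            format=spec.get("format", "edge-list"),
            evidence_filter=spec.get("evidence_filter"),
            proteome_size=spec.get("proteome_size"),
        )
    maps = {pair: _load_map(spec, *pair) for pair, spec in config.homology.items()}
    across = {pair: m for pair, m in maps.items() if pair[0] != pair[1]}
    within = {pair[0]: m for pair, m in maps.items() if pair[0] == pair[1]}

    f_obs: dict[tuple[str, str], float] = {}
    f_true_by_target: dict[str, float] = {}
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {stage: int(s) % (2**31)
                   for stage, s in zip(ALL_STAGES, ss.generate_state(len(ALL_STAGES)))}

    def emit(name: str) -> Path:
        manifest["outputs"].append(name)
        return out / name

    try:
        for stage in [s for s in ALL_STAGES if s in config.stages]:
            if stage == "summarize":
                write_summary(
                    [summarize(interactomes[n]) for n in sorted(interactomes)],
                    emit("summary.tsv"),
                )
            elif stage == "transfer":
                rows = []
                for (s, t), hmap in sorted(across.items()):
                    for src, tgt in ((s, t), (t, s)):
                        res = score(infer_across(interactomes[src], hmap), interactomes[tgt])
                        if res.defined:
                            f_obs[(src, tgt)] = res.f_obs
                        rows.append([src, tgt, hmap.kind,
                                     _threshold_label(config.homology[(s, t)]),
                                     res.n_predictions, res.n_correct, res.f_obs])
                _write_tsv(emit("transfer.tsv"),
                           ["source", "target", "homology_kind", "threshold",
                            "n_predictions", "n_correct", "f_obs"], rows)
            elif stage == "within":
                rows = []
                for sp, hmap in sorted(within.items()):
                    for mode in config.modes:
                        if mode not in WITHIN_MODES:
                            continue
                        res = score(infer_within(interactomes[sp], hmap, mode),
                                    interactomes[sp])
                        rows.append([sp, mode, hmap.kind, res.n_predictions,
                                     res.n_correct, res.f_obs])
                _write_tsv(emit("within.tsv"),
                           ["species", "mode", "homology_kind", "n_predictions",
                            "n_correct", "f_obs"], rows)
            elif stage == "nulls":
                rows = []
                seed0 = stage_seeds["nulls"]
                for (s, t), hmap in sorted(across.items()):
                    for src, tgt in ((s, t), (t, s)):
                        res = score(infer_across(interactomes[src], hmap),
                                    interactomes[tgt])
                        if not res.defined:
                            continue
                        lik = likelihood_ratio(res, interactomes[tgt], hmap,
                                               interactomes[src], "across")
                        rew = rewiring_ratio(interactomes[src], hmap,
                                             interactomes[tgt], "across",
                                             config.n_rewirings, seed0)
                        rows.append([src, tgt, "across", hmap.kind,
                                     _threshold_label(config.homology[(s, t)]),
                                     res.f_obs, lik.L, rew.ratio, rew.sd,
                                     rew.n_rewirings, seed0])
                _write_tsv(emit("nulls.tsv"),
                           ["source", "target", "mode", "homology_kind", "threshold",
                            "f_obs", "L", "ratio", "sd", "n_rewirings", "seed"], rows)
            elif stage == "errors":
                rows, summaries = [], {}
                seed0 = stage_seeds["errors"]
                for (s, t), hmap in sorted(across.items()):
                    for which, fn in (("target", target_subsampling),
                                      ("source", source_subsampling)):
                        exp = fn(interactomes[s], hmap, interactomes[t],
                                 config.subsample_fractions, config.subsample_reps,
                                 seed0)
                        for level in exp.levels:
                            for rep, f in enumerate(exp.f_obs_by_level[level]):
                                rows.append([f"{s}->{t}:{which}", level, rep, f])
                        summaries[f"{s}->{t}:{which}"] = {
                            "r": exp.r, "slope": exp.slope,
                            "intercept": exp.intercept, "seed": seed0,
                        }
                _write_tsv(emit("errors.tsv"),
                           ["experiment", "level", "rep", "f_obs"], rows)
                emit("errors_summary.json").write_text(
                    json.dumps(summaries, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")
            elif stage == "estimate":
                if config.reference is None:
                    raise ValueError("estimate stage needs a reference species")
                if not f_obs:
                    raise ValueError("estimate stage needs the transfer stage")
                counts = {n: i.n_edges for n, i in interactomes.items()}
                ests = estimate_coverage_and_conservation(
                    f_obs, counts, config.reference)
                rows = [[e.source, e.target, "NA", e.f_obs_st, e.f_obs_ts,
                         e.f_true, e.c_t, e.interactome_size,
                         int(e.coverage_violation)] for e in ests]
                for e in ests:
                    if e.source == config.reference:
                        f_true_by_target[e.target] = e.f_true
                _write_tsv(emit("estimates.tsv"),
                           ["source", "target", "threshold", "f_obs_st", "f_obs_ts",
                            "f_true", "c_t", "size", "violation_flag"], rows)
            elif stage == "lossrate":
                rows = []
                for (s, t), times in sorted(config.divergence_times.items()):
                    f = f_true_by_target.get(t if s == config.reference else s)
                    if f is None or not 0 < f <= 1:
                        continue
                    t_mid = float(times["t"])
                    t_range = (
                        (float(times["low"]), float(times["high"]))
                        if "low" in times and "high" in times else None
                    )
                    est = loss_rate(f, t_mid, t_range)
                    rows.append([f"{s}:{t}", est.T,
                                 t_range[0] if t_range else None,
                                 t_range[1] if t_range else None,
                                 est.q, est.q_low, est.q_high])
                _write_tsv(emit("lossrate.tsv"),
                           ["pair", "T", "T_low", "T_high", "q", "q_low", "q_high"],
                           rows)
            manifest["stages"][stage] = "ok"
    except Exception as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        _write_manifest(out, manifest)
        raise
    _write_manifest(out, manifest)
    return manifest


def _threshold_label(spec: dict):
    return spec.get("threshold", spec.get("e_cap"))


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def demo(
    out_dir: str | Path,
    seed: int = 0,
    world_params: Optional[WorldParams] = None,
    obs_params: Optional[ObservationParams] = None,
) -> dict:
    """Generate a small synthetic two-species world and run every stage on it.

    The world's files are written under ``out/world`` and the full report
    bundle under ``out``; returns the run manifest.
    """
    out = Path(out_dir)
    ss = np.random.SeedSequence(seed)
    s_world, s_obs, s_run = (int(x) % (2**31) for x in ss.generate_state(3))
    wp = world_params or WorldParams(
        n_ancestral_proteins=300, mean_degree=2.5, T=10, q_true=0.02,
        duplication_rate=0.1, seed=s_world,
    )
    wp = dataclasses.replace(wp, seed=s_world)
    op = obs_params or ObservationParams(coverage_s=1.0, coverage_t=0.4, seed=s_obs)
    op = dataclasses.replace(op, seed=s_obs)
    world = observe(generate_world(wp), op)
    world_dir = out / "world"
    world.save(world_dir)
    sp_a, sp_b = world.species
    raw = {
        "seed": s_run,
        "reference": sp_a,
        "species": {
            sp_a: {"edges": str(world_dir / f"observed_{sp_a}.tsv")},
            sp_b: {"edges": str(world_dir / f"observed_{sp_b}.tsv")},
        },
        "homology": {
            f"{sp_a}:{sp_b}": {"kind": "tsv", "path": str(world_dir / "orthologs.tsv")},
            f"{sp_a}:{sp_a}": {"kind": "tsv", "path": str(world_dir / f"paralogs_{sp_a}.tsv")},
            f"{sp_b}:{sp_b}": {"kind": "tsv", "path": str(world_dir / f"paralogs_{sp_b}.tsv")},
        },
        "divergence_times": {
            f"{sp_a}:{sp_b}": {"t": wp.T, "low": 0.8 * wp.T, "high": 1.2 * wp.T}
        },
        "stages": list(ALL_STAGES),
    }
    config = RunConfig.from_dict(raw, out)
    return run(config)
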