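"""Paired-species synthetic interactomes with known ground truth.

The generator emulates the evolutionary and observational processes the rest
of the package tries to invert. An ancestral network of randomly placed
interactions is copied into two descendant lineages. Within each lineage,
genes duplicate with a fixed per-gene probability (the duplicate inherits
its template's interactions and becomes a within-species paralog), then
every interaction independently survives each of T time units with
probability 1 - q. Cross-species homology is the identity map on ancestral
proteins plus duplicate-to-counterpart pairs; E-value-like scores weaken
with duplication depth so threshold sweeps have something to act on.

Observation is a separate layer: each true interaction is reported with the
species' coverage probability, multiplied (up to 1) by a reporting-bias
factor beta when its homologous counterpart has already been reported in the
other species -- bias affects observation, not biology. False interactions
are injected so that the reported list carries the requested false-positive
rate. Every random draw descends from the parameter seeds, so a world is
reproducible from its parameters alone.

Two ground-truth conservation numbers are recorded. The ordered-pair
conditional fractions (``f_true``) are what homology transfer estimates: the
fraction of transferred source interactions present in the target's *true*
network. The shared ancestral fraction is the probability that an ancestral
interaction survives in both lineages, expectation (1 - q)^(2T) -- the
quantity the loss-rate closed form inverts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .conservation import loss_rate
from .conservation import estimate_coverage_and_conservation
from .homology import HomologyMap, PairScore
from .inference import infer_across, score
from .interactome import Edge, Interactome, canonical_edge, write_interactions


@dataclass(frozen=True)
class SimilarityModel:
    """E-value-like scores as a function of duplication depth.

    Orthologs (depth 0) score around ``10**log10_evalue_orthologs``; every
    duplication on the path between two proteins weakens the score by
    ``decades_per_duplication`` decades, with uniform jitter so that sweeps
    over thresholds split the pairs.
    """

    log10_evalue_orthologs: float = -50.0
    decades_per_duplication: float = 10.0
    jitter_decades: float = 2.0
    identity_orthologs: float = 90.0
    identity_drop_per_duplication: float = 20.0

    def score(self, depth: int, rng: np.random.Generator) -> PairScore:
        exponent = (
            self.log10_evalue_orthologs
            + self.decades_per_duplication * depth
            + rng.uniform(-self.jitter_decades, self.jitter_decades)
        )
        identity = max(
            5.0,
            self.identity_orthologs
            - self.identity_drop_per_duplication * depth
            + rng.uniform(-2.0, 2.0),
        )
        return PairScore(10.0 ** min(exponent, 0.0), identity)


@dataclass(frozen=True)
class WorldParams:
    n_ancestral_proteins: int = 2000
    mean_degree: float = 2.5  # interactions per protein (edges / proteins)
    T: int = 10  # divergence time units per lineage
    q_true: float = 0.02  # per-unit-time loss probability per lineage
    duplication_rate: float = 0.05  # per-protein duplicate probability per lineage
    similarity: SimilarityModel = field(default_factory=SimilarityModel)
    species: tuple[str, str] = ("A", "B")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ancestral_proteins < 2:
            raise ValueError("need at least two ancestral proteins")
        for name in ("q_true", "duplication_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.T < 0 or self.mean_degree <= 0:
            raise ValueError("T must be >= 0 and mean_degree positive")


@dataclass(frozen=True)
class ObservationParams:
    coverage_s: float = 1.0  # fraction of true edges reported, first species
    coverage_t: float = 0.3  # second species
    fp_rate_s: float = 0.0  # fraction of reported edges that are false
    fp_rate_t: float = 0.0
    bias_beta: float = 1.0  # reporting multiplier when the counterpart is reported
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("coverage_s", "coverage_t"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        for name in ("fp_rate_s", "fp_rate_t"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.bias_beta < 1:
            raise ValueError("bias_beta must be >= 1")


@dataclass
class SyntheticWorld:
    params: WorldParams
    species: tuple[str, str]
    true: dict[str, Interactome]
    ortholog_map: HomologyMap
    paralog_maps: dict[str, HomologyMap]
    ancestral_edges: frozenset[Edge]
    surviving_ancestral: dict[str, frozenset[Edge]]
    shared_ancestral_fraction: float
    f_true: dict[tuple[str, str], float]  # conditional, per ordered pair
    observed: Optional[dict[str, Interactome]] = None
    obs_params: Optional[ObservationParams] = None
    realized_coverage: Optional[dict[str, float]] = None

    def save(self, directory: str | Path) -> None:
        """Serialize to edge-list TSVs, homology TSVs and a JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for sp, net in self.true.items():
            write_interactions(net, directory / f"true_{sp}.tsv")
        if self.observed:
            for sp, net in self.observed.items():
                write_interactions(net, directory / f"observed_{sp}.tsv")
        self.ortholog_map.to_tsv(directory / "orthologs.tsv")
        for sp, pmap in self.paralog_maps.items():
            pmap.to_tsv(directory / f"paralogs_{sp}.tsv")
        sidecar = {
            "species": list(self.species),
            "q_true": self.params.q_true,
            "T": self.params.T,
            "duplication_rate": self.params.duplication_rate,
            "n_ancestral_proteins": self.params.n_ancestral_proteins,
            "mean_degree": self.params.mean_degree,
            "seed": self.params.seed,
            "shared_ancestral_fraction": self.shared_ancestral_fraction,
            "f_true_realized": {f"{s}->{t}": v for (s, t), v in self.f_true.items()},
            "observation": (
                None
                if self.obs_params is None
                else {
                    "coverage": [self.obs_params.coverage_s, self.obs_params.coverage_t],
                    "fp_rate": [self.obs_params.fp_rate_s, self.obs_params.fp_rate_t],
                    "bias_beta": self.obs_params.bias_beta,
                    "seed": self.obs_params.seed,
                    "realized_coverage": self.realized_coverage,
                }
            ),
        }
        (directory / "ground_truth.json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )


def _sample_edges(
    rng: np.random.Generator, proteins: list[str], n_edges: int
) -> frozenset[Edge]:
    n = len(proteins)
    total = n * (n - 1) // 2
    if n_edges > 0.4 * total:
        raise ValueError(
            f"requested {n_edges} edges among {n} proteins: too dense to sample"
        )
    out: set[Edge] = set()
    while len(out) < n_edges:
        i, j = rng.integers(0, n, size=2)
        if i != j:
            out.add(canonical_edge(proteins[int(i)], proteins[int(j)]))
    return frozenset(out)


def generate_world(params: WorldParams) -> SyntheticWorld:
    """Generate true networks, homology, and ground-truth conservation."""
    survival = (1.0 - params.q_true) ** params.T
    if survival == 0.0:
        raise ValueError(
            f"q_true={params.q_true} over T={params.T} loses every interaction: "
            "descendant networks would be empty"
        )
    rng = np.random.default_rng(params.seed)
    n = params.n_ancestral_proteins
    proteins = [f"P{i:05d}" for i in range(n)]
    n_edges = max(1, round(params.mean_degree * n))
    ancestral = _sample_edges(rng, proteins, n_edges)
    anc_sorted = sorted(ancestral)

    sp_a, sp_b = params.species
    true: dict[str, Interactome] = {}
    paralog_maps: dict[str, HomologyMap] = {}
    surviving_ancestral: dict[str, frozenset[Edge]] = {}
    duplicates: dict[str, dict[str, str]] = {}  # species -> template -> duplicate

    for sp in (sp_a, sp_b):
        dup_mask = rng.random(n) < params.duplication_rate
        dups = {p: f"{p}~{sp}" for p, m in zip(proteins, dup_mask) if m}
        duplicates[sp] = dups
        lineage_edges: list[Edge] = list(anc_sorted)
        for a, b in anc_sorted:
            if a in dups:
                lineage_edges.append(canonical_edge(dups[a], b))
            if b in dups:
                lineage_edges.append(canonical_edge(a, dups[b]))
        keep = rng.random(len(lineage_edges)) < survival
        kept = frozenset(e for e, k in zip(lineage_edges, keep) if k)
        if not kept:
            raise ValueError(
                f"lineage {sp} lost every interaction (q_true={params.q_true}, "
                f"T={params.T}); use more ancestral edges or a lower loss rate"
            )
        surviving_ancestral[sp] = kept & ancestral
        true[sp] = Interactome(sp, kept)
        paralog_maps[sp] = HomologyMap(
            "reciprocal_hits", sp, sp,
            {
                tuple(sorted((p, d))): params.similarity.score(1, rng)
                for p, d in sorted(dups.items())
            },
        )

    ortho_pairs: dict[tuple[str, str], PairScore] = {}
    dups_a, dups_b = duplicates[sp_a], duplicates[sp_b]
    for p in proteins:
        ortho_pairs[(p, p)] = params.similarity.score(0, rng)
        if p in dups_a:
            ortho_pairs[(dups_a[p], p)] = params.similarity.score(1, rng)
        if p in dups_b:
            ortho_pairs[(p, dups_b[p])] = params.similarity.score(1, rng)
        if p in dups_a and p in dups_b:
            ortho_pairs[(dups_a[p], dups_b[p])] = params.similarity.score(2, rng)
    ortholog_map = HomologyMap("reciprocal_hits", sp_a, sp_b, ortho_pairs)

    shared = len(surviving_ancestral[sp_a] & surviving_ancestral[sp_b]) / len(ancestral)
    f_true: dict[tuple[str, str], float] = {}
    for s, t in ((sp_a, sp_b), (sp_b, sp_a)):
        res = score(infer_across(true[s], ortholog_map), true[t])
        f_true[(s, t)] = res.f_obs if res.defined else float("nan")
    return SyntheticWorld(
        params=params,
        species=(sp_a, sp_b),
        true=true,
        ortholog_map=ortholog_map,
        paralog_maps=paralog_maps,
        ancestral_edges=ancestral,
        surviving_ancestral=surviving_ancestral,
        shared_ancestral_fraction=shared,
        f_true=f_true,
    )


def _inject_false_edges(
    rng: np.random.Generator,
    reported: set[Edge],
    true_edges: frozenset[Edge],
    proteins: list[str],
    fp_rate: float,
) -> set[Edge]:
    if fp_rate == 0:
        return set()
    k = round(fp_rate * len(reported) / (1.0 - fp_rate))
    n = len(proteins)
    available = n * (n - 1) // 2 - len(true_edges)
    if k > available:
        raise ValueError(
            f"cannot inject {k} false edges: only {available} non-edges available"
        )
    out: set[Edge] = set()
    tries = 0
    while len(out) < k:
        tries += 1
        if tries > 500 * max(k, 1):
            raise ValueError("false-edge injection failed to converge")
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        e = canonical_edge(proteins[int(i)], proteins[int(j)])
        if e not in true_edges and e not in reported and e not in out:
            out.add(e)
    return out


def observe(world: SyntheticWorld, obs: ObservationParams) -> SyntheticWorld:
    """Apply incomplete, biased, error-prone observation to the true networks.

    Two-pass order: the first species is reported without bias at its
    coverage; the second species' true edges whose homologous counterpart
    was reported in the first species have their reporting probability
    multiplied by ``bias_beta`` (capped at 1). False edges are then injected
    per species to reach the requested false-positive rates.
    """
    rng = np.random.default_rng(obs.seed)
    sp_a, sp_b = world.species
    observed: dict[str, Interactome] = {}
    realized: dict[str, float] = {}

    # pass 1: unbiased species
    edges_a = sorted(world.true[sp_a].edges)
    kept_a = {e for e in edges_a if rng.random() < obs.coverage_s}
    # pass 2: biased species, conditioned on what species A reported
    lookup = world.ortholog_map.oriented(sp_b)
    edges_b = sorted(world.true[sp_b].edges)
    kept_b: set[Edge] = set()
    for x, y in edges_b:
        counterpart = any(
            canonical_edge(x2, y2) in kept_a
            for x2, _ in lookup.get(x, ())
            for y2, _ in lookup.get(y, ())
        )
        p = obs.coverage_t * (obs.bias_beta if counterpart else 1.0)
        if rng.random() < min(1.0, p):
            kept_b.add((x, y))

    for sp, kept, fp in (
        (sp_a, kept_a, obs.fp_rate_s),
        (sp_b, kept_b, obs.fp_rate_t),
    ):
        true_net = world.true[sp]
        proteins = sorted(true_net.proteins)
        false = _inject_false_edges(rng, set(kept), true_net.edges, proteins, fp)
        observed[sp] = Interactome(sp, frozenset(kept) | frozenset(false))
        realized[sp] = len(kept) / true_net.n_edges
    return dataclasses.replace(
        world, observed=observed, obs_params=obs, realized_coverage=realized
    )


def run_world_pipeline(world: SyntheticWorld) -> dict:
    """Estimate coverage, conservation, size and loss rate from one observed world.

    The first species is taken as the complete reference (the intended use
    pairs this with coverage_s = 1). Returns estimates alongside the world's
    ground truth for direct comparison.
    """
    if world.observed is None:
        raise ValueError("world has no observations; call observe() first")
    sp_a, sp_b = world.species
    obs_a, obs_b = world.observed[sp_a], world.observed[sp_b]
    res_ab = score(infer_across(obs_a, world.ortholog_map), obs_b)
    res_ba = score(infer_across(obs_b, world.ortholog_map), obs_a)
    if not (res_ab.defined and res_ba.defined):
        raise ValueError("undefined f_obs: no predictions in one direction")
    est = estimate_coverage_and_conservation(
        {(sp_a, sp_b): res_ab.f_obs, (sp_b, sp_a): res_ba.f_obs},
        {sp_b: obs_b.n_edges, sp_a: obs_a.n_edges},
        reference=sp_a,
    )[0]
    T = world.params.T
    out = {
        "f_obs_ab": res_ab.f_obs,
        "f_obs_ba": res_ba.f_obs,
        "n_predictions_ab": res_ab.n_predictions,
        "c_hat": est.c_t,
        "f_true_hat": est.f_true,
        "size_hat": est.interactome_size,
        "coverage_violation": est.coverage_violation,
        # ground truth
        "c_true": (world.realized_coverage or {}).get(sp_b),
        "f_true_cond": world.f_true[(sp_b, sp_a)],
        "f_true_cond_ab": world.f_true[(sp_a, sp_b)],
        "size_true": world.true[sp_b].n_edges,
        "shared_ancestral_fraction": world.shared_ancestral_fraction,
        "q_true": world.params.q_true,
        "T": T,
    }
    # loss rate: the joint-retention fraction is the square of the symmetric
    # conditional estimate, since f_cond = (1-q)^T and f_joint = (1-q)^(2T)
    f_joint_hat = est.f_true ** 2
    out["q_hat_data"] = (
        loss_rate(f_joint_hat, T).q if 0 < f_joint_hat <= 1 and T > 0 else None
    )
    out["q_hat_shared"] = (
        loss_rate(world.shared_ancestral_fraction, T).q
        if 0 < world.shared_ancestral_fraction <= 1 and T > 0
        else None
    )
    return out


def recovery_experiment(
    cells: list[tuple[WorldParams, ObservationParams]],
    n_worlds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the full pipeline over a parameter grid of independent worlds.

    Returns one row per world with estimates, ground truth and relative
    errors; pipeline failures are recorded per world rather than raised.
    """
    if not cells:
        raise ValueError("empty parameter grid")
    ss = np.random.SeedSequence(seed)
    child = iter(ss.generate_state(2 * len(cells) * n_worlds))
    rows = []
    for cell_idx, (wp, op) in enumerate(cells):
        for world_idx in range(n_worlds):
            wseed = int(next(child)) % (2**31)
            oseed = int(next(child)) % (2**31)
            row: dict = {
                "cell": cell_idx,
                "world": world_idx,
                "coverage_t": op.coverage_t,
                "fp_rate_s": op.fp_rate_s,
                "fp_rate_t": op.fp_rate_t,
                "bias_beta": op.bias_beta,
            }
            try:
                world = observe(
                    generate_world(dataclasses.replace(wp, seed=wseed)),
                    dataclasses.replace(op, seed=oseed),
                )
                row.update(run_world_pipeline(world))
                if row["c_true"]:
                    row["c_rel_err"] = row["c_hat"] / row["c_true"] - 1.0
                if row["f_true_cond"]:
                    row["f_true_rel_err"] = row["f_true_hat"] / row["f_true_cond"] - 1.0
                if row["size_true"]:
                    row["size_rel_err"] = row["size_hat"] / row["size_true"] - 1.0
            except ValueError as exc:
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


def recovery_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Bias and RMSE of the estimators per grid cell."""
    ok = df[df["error"].isna()] if "error" in df.columns else df

    def rmse(x):
        return float(np.sqrt(np.mean(np.square(x))))
    return ok.groupby("cell").agg(
        n_worlds=("world", "count"),
        c_bias=("c_rel_err", "mean"),
        c_rmse=("c_rel_err", rmse),
        f_true_bias=("f_true_rel_err", "mean"),
        f_true_rmse=("f_true_rel_err", rmse),
        size_bias=("size_rel_err", "mean"),
        size_rmse=("size_rel_err", rmse),
    )
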