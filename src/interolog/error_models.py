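"""Effects of interactome errors on observed conservation rates.

False positives in the *source* species dilute the inference pool with
predictions from spurious interactions and so push the observed fraction of
correct inferences down; false positives in the *target* species let some
predictions match spurious interactions and push it up. Under a linear
mixture of true- and false-positive contributions the two effects can be
bounded; whenever the source error rate does not exceed the target's, the
overestimation is at least as large as the underestimation -- so false
positives cannot explain away low observed conservation.

False negatives (incompleteness) are probed by subsampling: uniformly
subsampling the target interaction list scales the observed fraction of
correct inferences linearly with coverage, while subsampling the source list
leaves it unchanged. These two facts are exactly what licenses the
f_obs = f_true * c coverage correction.

The target-side overestimation formula used here,
delta_over = f_obs * FP_t / (1 - FP_t), is a reconstruction from the
independence argument (the fraction of inferences falsely judged correct is
the target's false-positive rate); its direction is validated by the
simulation tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .homology import HomologyMap
from .inference import infer_across, score
from .interactome import Edge, Interactome, canonical_edge

log = logging.getLogger(__name__)


@dataclass
class FPBounds:
    fp_source: float
    fp_target: float
    f_obs: float
    f_tp: float  # fraction correct expected with an error-free source
    max_underestimation: float
    overestimation: float
    inequality_holds: bool  # underestimation strictly below overestimation


def fp_bias_bounds(fp_source: float, fp_target: float, f_obs: float) -> FPBounds:
    """Bound the f_obs distortion caused by false positives on either side.

    Source side: with f_obs = (1-FP_s)*f_TP + FP_s*f_FP and the worst case
    f_FP = 0, the underestimation is at most FP_s*f_TP where
    f_TP = f_obs/(1-FP_s). Target side: matches to spurious target edges
    inflate f_obs by delta_over = f_obs*FP_t/(1-FP_t).
    """
    for name, rate in (("fp_source", fp_source), ("fp_target", fp_target)):
        if not 0 <= rate < 1:
            raise ValueError(f"{name} must be in [0, 1)")
    if not 0 <= f_obs <= 1:
        raise ValueError("f_obs must be in [0, 1]")
    f_tp = f_obs / (1.0 - fp_source)
    delta_under = fp_source * f_tp
    delta_over = f_obs * fp_target / (1.0 - fp_target)
    return FPBounds(
        fp_source=fp_source,
        fp_target=fp_target,
        f_obs=f_obs,
        f_tp=f_tp,
        max_underestimation=delta_under,
        overestimation=delta_over,
        inequality_holds=delta_under < delta_over,
    )


def _random_nonedges(
    rng: np.random.Generator,
    proteins: Sequence[str],
    exclude: frozenset[Edge],
    k: int,
    max_tries_factor: int = 200,
) -> list[Edge]:
    """Sample k distinct uniform non-self pairs outside ``exclude``."""
    n = len(proteins)
    n_pairs = n * (n - 1) // 2
    if n_pairs - len(exclude) < k:
        raise ValueError(f"cannot place {k} false edges among {n} proteins")
    out: set[Edge] = set()
    tries = 0
    while len(out) < k:
        tries += 1
        if tries > max_tries_factor * max(k, 1):
            raise ValueError("false-edge sampling failed to converge")
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        e = canonical_edge(proteins[i], proteins[j])
        if e not in exclude and e not in out:
            out.add(e)
    return sorted(out)


@dataclass
class FPSimulation:
    fp_rate: float
    f_obs_unperturbed: Optional[float]
    f_obs: list[float]
    mean_f_obs: Optional[float]
    sd_f_obs: Optional[float]
    n_reps: int
    seed: int


def simulate_source_fp(
    source: Interactome,
    hmap: HomologyMap,
    target: Interactome,
    fp_rate: float,
    n_reps: int = 10,
    seed: int = 0,
) -> FPSimulation:
    """Measure f_obs after corrupting a fraction of source edges.

    Each replicate replaces round(fp_rate * |E|) uniformly chosen source
    edges with uniformly random non-edges over the source protein set, then
    re-infers and re-scores.
    """
    if not 0 <= fp_rate < 1:
        raise ValueError("fp_rate must be in [0, 1)")
    base = score(infer_across(source, hmap), target)
    proteins = sorted(source.proteins)
    edges = sorted(source.edges)
    k = round(fp_rate * len(edges))
    rngs = [np.random.default_rng(s) for s in
            np.random.SeedSequence(seed).generate_state(max(n_reps, 1))]
    f_vals: list[float] = []
    for rng in rngs[:n_reps]:
        if k == 0:
            perturbed = source
        else:
            drop = set(map(int, rng.choice(len(edges), size=k, replace=False)))
            kept = [e for i, e in enumerate(edges) if i not in drop]
            false = _random_nonedges(rng, proteins, source.edges, k)
            perturbed = Interactome(
                source.species, frozenset(kept) | frozenset(false),
                proteome_size=source.proteome_size,
            )
        res = score(infer_across(perturbed, hmap), target)
        if res.defined:
            f_vals.append(res.f_obs)
    mean = float(np.mean(f_vals)) if f_vals else None
    sd = float(np.std(f_vals, ddof=1)) if len(f_vals) > 1 else (0.0 if f_vals else None)
    return FPSimulation(fp_rate, base.f_obs, f_vals, mean, sd, n_reps, seed)


@dataclass
class CoverageExperiment:
    """Subsampling experiment over interaction-list coverage levels."""

    which: str  # 'target' or 'source'
    levels: list[float]
    f_obs_by_level: dict[float, list[float]]
    r: Optional[float]  # Pearson correlation over all (level, f_obs) points
    slope: Optional[float]
    intercept: Optional[float]
    slope_stderr: Optional[float]
    n_skipped: int
    seed: int
    undefined_r_reason: str = ""
    df: int = 0  # residual degrees of freedom of the fit

    def level_means(self) -> dict[float, float]:
        return {
            lvl: float(np.mean(v))
            for lvl, v in self.f_obs_by_level.items() if v
        }

    def level_sds(self) -> dict[float, float]:
        return {
            lvl: (float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
            for lvl, v in self.f_obs_by_level.items() if v
        }

    def slope_ci(self, alpha: float = 0.05) -> Optional[tuple[float, float]]:
        """Two-sided confidence interval for the fitted slope."""
        if self.slope is None or self.slope_stderr is None or self.df < 1:
            return None
        t = stats.t.ppf(1 - alpha / 2, self.df)
        return (self.slope - t * self.slope_stderr, self.slope + t * self.slope_stderr)


def _fit(points: list[tuple[float, float]]) -> tuple:
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    if len(set(xs.tolist())) < 2:
        return None, None, None, None, 0, "single coverage level: r undefined"
    if np.std(ys) == 0:
        # a perfectly flat response has no defined correlation coefficient
        fit = stats.linregress(xs, ys)
        return None, fit.slope, fit.intercept, fit.stderr, len(xs) - 2, \
            "zero variance in f_obs: r undefined"
    fit = stats.linregress(xs, ys)
    return float(fit.rvalue), fit.slope, fit.intercept, fit.stderr, len(xs) - 2, ""


def _subsample_edges(
    rng: np.random.Generator, edges: list[Edge], fraction: float
) -> frozenset[Edge]:
    k = round(fraction * len(edges))
    if k >= len(edges):
        return frozenset(edges)
    idx = rng.choice(len(edges), size=k, replace=False)
    return frozenset(edges[int(i)] for i in idx)


def _check_fractions(fractions: Sequence[float]) -> list[float]:
    fr = sorted(set(float(f) for f in fractions) | {1.0})
    if any(not 0 < f <= 1 for f in fr):
        raise ValueError("fractions must lie in (0, 1]")
    return fr


def target_subsampling(
    source: Interactome,
    hmap: HomologyMap,
    target: Interactome,
    fractions: Sequence[float] = (0.25, 0.5, 0.75),
    n_reps: int = 10,
    seed: int = 0,
) -> CoverageExperiment:
    """Linearity of f_obs in target coverage, by uniform edge subsampling.

    The full data set (coverage 1.0) is always included. Predictions are
    computed once; only the confirmation set varies.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    fractions = _check_fractions(fractions)
    inferences = infer_across(source, hmap)
    edges = sorted(target.edges)
    rng = np.random.default_rng(np.random.SeedSequence(seed).generate_state(1)[0])
    points: list[tuple[float, float]] = []
    by_level: dict[float, list[float]] = {f: [] for f in fractions}
    n_skipped = 0
    for f in fractions:
        for _ in range(n_reps):
            sub = Interactome(target.species, _subsample_edges(rng, edges, f))
            if not sub.edges:
                n_skipped += 1
                continue
            res = score(inferences, sub)
            if not res.defined:
                n_skipped += 1
                continue
            by_level[f].append(res.f_obs)
            points.append((f, res.f_obs))
    r, slope, intercept, stderr, dof, reason = _fit(points)
    return CoverageExperiment(
        "target", fractions, by_level, r, slope, intercept, stderr,
        n_skipped, seed, reason, dof,
    )


def source_subsampling(
    source: Interactome,
    hmap: HomologyMap,
    target: Interactome,
    fractions: Sequence[float] = (0.25, 0.5, 0.75),
    n_reps: int = 10,
    seed: int = 0,
) -> CoverageExperiment:
    """Independence of f_obs from source coverage, by edge subsampling.

    Inference is recomputed for every subsample. Replicates with zero
    predictions (undefined f_obs) are skipped and counted.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    fractions = _check_fractions(fractions)
    edges = sorted(source.edges)
    rng = np.random.default_rng(np.random.SeedSequence(seed).generate_state(1)[0])
    points: list[tuple[float, float]] = []
    by_level: dict[float, list[float]] = {f: [] for f in fractions}
    n_skipped = 0
    for f in fractions:
        for _ in range(n_reps):
            sub = Interactome(
                source.species, _subsample_edges(rng, edges, f),
                proteome_size=source.proteome_size,
            )
            if not sub.edges:
                n_skipped += 1
                continue
            res = score(infer_across(sub, hmap), target)
            if not res.defined:
                n_skipped += 1
                continue
            by_level[f].append(res.f_obs)
            points.append((f, res.f_obs))
    r, slope, intercept, stderr, dof, reason = _fit(points)
    return CoverageExperiment(
        "source", fractions, by_level, r, slope, intercept, stderr,
        n_skipped, seed, reason, dof,
    )
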