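"""Randomization baselines for interolog inference.

Two complementary baselines quantify how much better homology-based transfer
is than chance:

* the **likelihood ratio** L = O_post / O_prior compares the odds that a
  transferred interaction is a true interaction after seeing the interaction
  data (O_post, from the observed fraction of correct inferences) with the
  prior odds that a random pair of homolog-bearing target proteins interacts;
* **degree-preserving rewiring** randomizes the source-species interactions
  while keeping each protein's number of interaction partners fixed, so the
  comparison controls for how often each protein appears in the interaction
  list rather than for which partners it has.

L = 1 (or a rewiring ratio of 1) means transfer is no better than guessing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .homology import HomologyMap
from .inference import InferenceSet, TransferResult, infer_across, infer_within, score
from .interactome import Edge, Interactome

log = logging.getLogger(__name__)


@dataclass
class LikelihoodResult:
    L: Optional[float]  # None when the prior odds are zero; inf when f_obs == 1
    o_post: Optional[float]
    o_prior: float
    n_homolog_bearing: int
    n_possible: int
    n_possible_positive: int
    flagged: str = ""  # non-empty when L is undefined or infinite


def _homolog_bearing(
    target: Interactome, hmap: HomologyMap, source: Interactome
) -> set[str]:
    """Target-side proteins with at least one homolog in the source interactome."""
    lookup = hmap.oriented(target.species)
    source_proteins = source.proteins
    universe = set(target.proteins) | set(lookup)
    return {
        p
        for p in universe
        if any(q in source_proteins for q, _ in lookup.get(p, ()))
    }


def likelihood_ratio(
    result: TransferResult,
    target: Interactome,
    hmap: HomologyMap,
    source: Interactome,
    mode: str = "across",
) -> LikelihoodResult:
    """Posterior-to-prior odds that an inference is a true interaction.

    For across-species and both-different inferences the possible-inference
    universe is every unordered pair (self-pairs included) of the N target
    proteins that have homologs in the source interactome: N(N+1)/2 pairs,
    of which the possible positives are target edges with both endpoints
    homolog-bearing. One-same inferences can reach any pair in which one
    protein is in the interactome and the other has a homolog elsewhere in
    the interactome, so the corresponding counts are used instead.
    """
    if not result.defined:
        raise ValueError("likelihood ratio needs a defined f_obs")
    H = _homolog_bearing(target, hmap, source)
    if mode in ("across", "both_different_1", "both_different_2"):
        n_hb = len(H)
        n_possible = n_hb * (n_hb + 1) // 2
        P = sum(1 for a, b in target.edges if a in H and b in H)
    elif mode == "one_same":
        proteins = sorted(target.proteins)
        in_h = [p in H for p in proteins]
        a = sum(in_h)  # interactome proteins that are homolog-bearing
        b = len(proteins) - a
        # pairs (u, v) over the interactome with at least one endpoint
        # homolog-bearing, self-pairs included
        n_possible = a * (a + 1) // 2 + a * b
        n_hb = a
        P = sum(1 for x, y in target.edges if x in H or y in H)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    flagged = ""
    o_prior = P / (n_possible - P) if n_possible > P else math.inf
    f = result.f_obs
    if f == 1.0:
        o_post: Optional[float] = math.inf
        L: Optional[float] = math.inf
        flagged = "f_obs=1: infinite posterior odds"
    else:
        o_post = f / (1.0 - f)
        if P == 0:
            L = None
            flagged = "no possible positives: prior odds zero, L undefined"
        else:
            L = o_post / o_prior
    return LikelihoodResult(L, o_post, o_prior, n_hb, n_possible, P, flagged)


def rewire(
    interactome: Interactome,
    seed: int | np.random.Generator,
    n_attempts: Optional[int] = None,
) -> Interactome:
    """Degree-preserving randomization by repeated double-edge swaps.

    Each accepted swap replaces edges (a, b), (c, d) with (a, d), (c, b),
    preserving every protein's partner count. Swaps creating self-loops or
    duplicate edges are rejected. Self-edges are held fixed (a swap move on
    a self-edge is ill-defined under the partner-count constraint). The
    attempt budget defaults to 10x the number of edges.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fixed = [e for e in sorted(interactome.edges) if e[0] == e[1]]
    edges: list[Edge] = [e for e in sorted(interactome.edges) if e[0] != e[1]]
    if len(edges) < 2:
        log.warning("fewer than two swappable edges: rewiring returns input unchanged")
        return Interactome(interactome.species, interactome.edges,
                           proteome_size=interactome.proteome_size)
    current = set(edges)
    if n_attempts is None:
        n_attempts = 10 * len(interactome.edges)
    n_accepted = 0
    for _ in range(n_attempts):
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.integers(0, 2):
            c, d = d, c
        if a == d or c == b:
            continue
        new1 = (a, d) if a <= d else (d, a)
        new2 = (c, b) if c <= b else (b, c)
        if new1 == new2 or new1 in current or new2 in current:
            continue
        current.discard(edges[i])
        current.discard(edges[j])
        current.add(new1)
        current.add(new2)
        edges[i], edges[j] = new1, new2
        n_accepted += 1
    if n_accepted == 0:
        log.warning("no valid degree-preserving swap found: interactome unchanged")
    return Interactome(
        interactome.species,
        frozenset(edges) | frozenset(fixed),
        proteome_size=interactome.proteome_size,
    )


@dataclass
class RewiringResult:
    ratio: Optional[float]  # f_obs(real) / mean f_obs(rewired)
    sd: Optional[float]  # sd of the per-rewiring ratios
    n_rewirings: int
    n_excluded: int  # rewirings with undefined f_obs
    f_obs_real: Optional[float]
    f_obs_rewired: list[float]
    seed: int


def rewiring_ratio(
    source: Interactome,
    hmap: HomologyMap,
    target: Interactome,
    mode: str = "across",
    n_rewirings: int = 10,
    seed: int = 0,
    infer: Optional[Callable[[Interactome], InferenceSet]] = None,
) -> RewiringResult:
    """Observed transfer success relative to rewired source interactions.

    The source interactome is rewired ``n_rewirings`` times; each rewired
    version is pushed through the same inference and scored against the
    (unchanged) target data. Rewirings yielding zero predictions are
    excluded and counted.
    """
    if n_rewirings < 1:
        raise ValueError("n_rewirings must be >= 1")
    if infer is None:
        if mode == "across":
            infer = lambda src: infer_across(src, hmap)  # noqa: E731
        else:
            infer = lambda src: infer_within(src, hmap, mode)  # noqa: E731
    real = score(infer(source), target)
    if not real.defined:
        raise ValueError("f_obs undefined on the real data (no predictions)")
    rngs = [np.random.default_rng(s) for s in
            np.random.SeedSequence(seed).generate_state(n_rewirings)]
    f_rewired: list[float] = []
    n_excluded = 0
    for rng in rngs:
        res = score(infer(rewire(source, rng)), target)
        if res.defined:
            f_rewired.append(res.f_obs)
        else:
            n_excluded += 1
    if not f_rewired or np.mean(f_rewired) == 0:
        return RewiringResult(None, None, n_rewirings, n_excluded, real.f_obs,
                              f_rewired, seed)
    ratio = real.f_obs / float(np.mean(f_rewired))
    ratios = [real.f_obs / f for f in f_rewired if f > 0]
    sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
    return RewiringResult(ratio, sd, n_rewirings, n_excluded, real.f_obs,
                          f_rewired, seed)


def homolog_pair_propensity(
    target: Interactome, hmap: HomologyMap, source: Interactome
) -> Optional[float]:
    """How much likelier homolog-bearing target pairs are to interact.

    Ratio of the edge density among pairs of homolog-bearing target proteins
    to the edge density among all target pairs, with the same self-inclusive
    pair counting as the likelihood prior. None when a denominator is zero.
    """
    proteins = target.proteins
    H = _homolog_bearing(target, hmap, source) & proteins
    m = len(proteins)
    n = len(H)
    all_pairs = m * (m + 1) // 2
    hb_pairs = n * (n + 1) // 2
    if all_pairs == 0 or hb_pairs == 0 or not target.edges:
        return None
    hb_edges = sum(1 for a, b in target.edges if a in H and b in H)
    dens_hb = hb_edges / hb_pairs
    dens_all = target.n_edges / all_pairs
    return dens_hb / dens_all
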