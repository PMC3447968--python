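"""Brute-force reference implementations for small inputs.

These enumerate every inference route and every candidate protein pair with
plain nested loops and no shared code with the package internals, so that
agreement on small random worlds is meaningful evidence of correctness.
"""

from __future__ import annotations

import math


def canon(a, b):
    return (a, b) if a <= b else (b, a)


def sym_partners(pairs):
    """Symmetric partner dict from within-species (a, b) -> evalue pairs."""
    out = {}
    for (a, b), ev in pairs.items():
        out.setdefault(a, []).append((b, ev))
        out.setdefault(b, []).append((a, ev))
    return out


def brute_across(edges, pairs):
    """All across-species predictions: pair -> list of route evalues.

    ``pairs`` maps (source_protein, target_protein) -> evalue.
    """
    preds = {}
    for a, b in edges:
        for (s1, t1), e1 in pairs.items():
            for (s2, t2), e2 in pairs.items():
                if s1 == a and s2 == b:
                    preds.setdefault(canon(t1, t2), []).append(max(e1, e2))
    return preds


def brute_within_routes(edges, pairs):
    """Every within-species route: list of (pred, kind, evalue, source)."""
    partners = sym_partners(pairs)
    routes = []
    for x, y in edges:
        endpoints = [(x, y), (y, x)] if x != y else [(x, x)]
        for keep, swap in endpoints:
            for p2, ev in partners.get(swap, []):
                pred = canon(keep, p2)
                if pred != canon(x, y):
                    routes.append((pred, "one_same", ev, canon(x, y)))
        for x2, e1 in partners.get(x, []):
            for y2, e2 in partners.get(y, []):
                pred = canon(x2, y2)
                if pred != canon(x, y):
                    routes.append((pred, "both_different", max(e1, e2), canon(x, y)))
    return routes


def brute_within(edges, pairs, mode):
    """Predicted pair set for a within-species mode."""
    routes = brute_within_routes(edges, pairs)
    if mode == "one_same":
        return {p for p, kind, _, _ in routes if kind == "one_same"}
    if mode == "both_different_1":
        return {p for p, kind, _, _ in routes if kind == "both_different"}
    if mode == "both_different_2":
        best = {}
        for pred, kind, ev, src in routes:
            key = (ev, 0 if kind == "one_same" else 1, src)
            if pred not in best or key < best[pred][0]:
                best[pred] = (key, kind)
        return {p for p, (_, kind) in best.items() if kind == "both_different"}
    raise ValueError(mode)


def brute_f_obs(predictions, target_edges):
    if not predictions:
        return None
    correct = sum(1 for p in predictions if p in target_edges)
    return correct / len(predictions)


def brute_likelihood_across(f_obs, target_edges, target_universe, bearing):
    """Likelihood ratio by full pair enumeration (self-pairs included)."""
    universe = sorted(set(target_universe))
    n_possible = 0
    for i, u in enumerate(universe):
        for v in universe[i:]:
            if u in bearing and v in bearing:
                n_possible += 1
    positives = sum(1 for a, b in target_edges if a in bearing and b in bearing)
    if n_possible == positives:
        o_prior = math.inf
    else:
        o_prior = positives / (n_possible - positives)
    if f_obs == 1.0:
        return math.inf
    o_post = f_obs / (1 - f_obs)
    if positives == 0:
        return None
    return o_post / o_prior


def brute_likelihood_one_same(f_obs, target_edges, interactome_proteins, bearing):
    """One-same prior by enumeration: pairs with one endpoint in the
    interactome and the other having a homolog elsewhere in it."""
    universe = sorted(interactome_proteins)
    n_possible = 0
    for i, u in enumerate(universe):
        for v in universe[i:]:
            if (u in interactome_proteins and v in bearing) or (
                v in interactome_proteins and u in bearing
            ):
                n_possible += 1
    positives = sum(1 for a, b in target_edges if a in bearing or b in bearing)
    if f_obs == 1.0:
        return math.inf
    if positives == 0:
        return None
    o_prior = positives / (n_possible - positives) if n_possible > positives else math.inf
    return (f_obs / (1 - f_obs)) / o_prior
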