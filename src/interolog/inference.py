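"""Interolog inference: transfer interactions by homolog substitution.

Across species, every source interaction (A, B) predicts the interaction
(A', B') in the target species for every homolog A' of A and B' of B. Within
a species there are three inference classes:

* **one-same** -- one endpoint is kept and the other replaced by a homolog:
  (X, Y) predicts (X, Y');
* **both-different-1** -- both endpoints replaced: (X, Y) predicts (X', Y');
  one-same substitutions are excluded as inference instances, but a target
  pair remains predicted if any genuine both-different route reaches it;
* **both-different-2** -- for every predicted pair only the single
  evolutionarily closest route (smallest inference E-value) is kept, and the
  pair is discarded when that closest route is a one-same inference. This is
  the most aggressive control for the known power of one-same prediction.

A route's inference E-value is the larger (weaker) of the E-values of the
homolog substitutions it uses; a one-same route uses its single substitution
E-value. A target pair predicted by several routes counts once, carrying the
number of routes and its best E-value. A prediction identical to its own
source edge is never emitted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .homology import HomologyMap
from .interactome import Edge, Interactome, canonical_edge

log = logging.getLogger(__name__)

MODES = ("across", "one_same", "both_different_1", "both_different_2")

_KIND_RANK = {"one_same": 0, "across": 1, "both_different": 1}


@dataclass(frozen=True)
class Provenance:
    """One inference route: the source edge, its class, and its E-value."""

    source_edge: Edge
    kind: str  # across | one_same | both_different
    evalue: Optional[float]

    def sort_key(self):
        # unscored routes (curated maps) order after scored ones, then by
        # class (one-same wins exact ties, the conservative choice for
        # both-different-2), then by source-edge canonical order
        ev = self.evalue if self.evalue is not None else math.inf
        return (ev, _KIND_RANK[self.kind], self.source_edge)


@dataclass
class Prediction:
    pair: Edge
    n_provenance: int
    best_evalue: Optional[float]
    closest: Provenance


@dataclass
class InferenceSet:
    """Unique predicted target pairs for one mode, with provenance."""

    mode: str
    species_source: str
    species_target: str
    predictions: dict[Edge, Prediction] = field(default_factory=dict)

    @property
    def pairs(self) -> frozenset[Edge]:
        return frozenset(self.predictions)

    def __len__(self) -> int:
        return len(self.predictions)

    def to_tsv(self, path: str | Path, target: Optional[Interactome] = None) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write(
                "protein_a\tprotein_b\tmode\tbest_evalue\tn_provenance\tcorrect_flag\n"
            )
            for pair in sorted(self.predictions):
                p = self.predictions[pair]
                ev = "NA" if p.best_evalue is None else repr(p.best_evalue)
                flag = "NA" if target is None else str(int(pair in target.edges))
                fh.write(
                    f"{pair[0]}\t{pair[1]}\t{self.mode}\t{ev}\t{p.n_provenance}\t{flag}\n"
                )


@dataclass
class TransferResult:
    """Scoring of an inference set against the target interaction data."""

    mode: str
    n_predictions: int
    n_correct: int
    f_obs: Optional[float]  # None when no predictions were made
    species_source: str = ""
    species_target: str = ""
    homology_kind: str = ""
    threshold: Optional[float] = None

    @property
    def defined(self) -> bool:
        return self.f_obs is not None


def _merge(
    store: dict[Edge, list], pair: Edge, prov: Provenance
) -> None:
    # store entry: [n, best_ev (min non-None), closest_key, closest_prov]
    key = prov.sort_key()
    entry = store.get(pair)
    if entry is None:
        store[pair] = [1, prov.evalue, key, prov]
        return
    entry[0] += 1
    if prov.evalue is not None and (entry[1] is None or prov.evalue < entry[1]):
        entry[1] = prov.evalue
    if key < entry[2]:
        entry[2], entry[3] = key, prov


def _pair_evalue(e1: Optional[float], e2: Optional[float]) -> Optional[float]:
    if e1 is None or e2 is None:
        return None
    return max(e1, e2)


def infer_across(source: Interactome, hmap: HomologyMap) -> InferenceSet:
    """Transfer every source edge through all homolog pair substitutions."""
    lookup = hmap.oriented(source.species)
    target_species = hmap.other_species(source.species) if not hmap.within else hmap.species_s
    if not hmap.pairs:
        log.warning("empty homology map: no across-species inferences")
    store: dict[Edge, list] = {}
    for edge in sorted(source.edges):
        a, b = edge
        for a2, e1 in lookup.get(a, ()):
            for b2, e2 in lookup.get(b, ()):
                prov = Provenance(edge, "across", _pair_evalue(e1, e2))
                _merge(store, canonical_edge(a2, b2), prov)
    return InferenceSet(
        "across",
        source.species,
        target_species,
        {
            pair: Prediction(pair, n, best, closest)
            for pair, (n, best, _key, closest) in store.items()
        },
    )


def _within_routes(interactome: Interactome, lookup):
    """Yield (predicted pair, Provenance) over all within-species routes.

    Routes predicting their own source edge are vacuous and skipped.
    """
    for edge in sorted(interactome.edges):
        x, y = edge
        # one-same: substitute exactly one endpoint
        subs = ((x, y), (y, x)) if x != y else ((x, x),)
        for keep, swap in subs:
            for p2, ev in lookup.get(swap, ()):
                pair = canonical_edge(keep, p2)
                if pair != edge:
                    yield pair, Provenance(edge, "one_same", ev)
        # both-different: substitute both endpoints
        for x2, e1 in lookup.get(x, ()):
            for y2, e2 in lookup.get(y, ()):
                pair = canonical_edge(x2, y2)
                if pair != edge:
                    yield pair, Provenance(edge, "both_different", _pair_evalue(e1, e2))


def infer_within(
    interactome: Interactome, hmap: HomologyMap, mode: str
) -> InferenceSet:
    """Within-species inference in one of the three modes (see module docs)."""
    if mode not in ("one_same", "both_different_1", "both_different_2"):
        raise ValueError(f"unknown within-species mode {mode!r}")
    if not hmap.within or hmap.species_s != interactome.species:
        raise ValueError("within-species inference needs a matching within-species map")
    lookup = hmap.oriented(interactome.species)

    if mode == "both_different_2":
        # closest route over the union of one-same and both-different routes
        store: dict[Edge, list] = {}
        for pair, prov in _within_routes(interactome, lookup):
            _merge(store, pair, prov)
        predictions = {
            pair: Prediction(pair, 1, closest.evalue, closest)
            for pair, (_n, _best, _key, closest) in store.items()
            if closest.kind == "both_different"
        }
    else:
        wanted = "one_same" if mode == "one_same" else "both_different"
        store = {}
        for pair, prov in _within_routes(interactome, lookup):
            if prov.kind == wanted:
                _merge(store, pair, prov)
        predictions = {
            pair: Prediction(pair, n, best, closest)
            for pair, (n, best, _key, closest) in store.items()
        }
    return InferenceSet(mode, interactome.species, interactome.species, predictions)


def score(inferences: InferenceSet, target: Interactome) -> TransferResult:
    """Count predictions confirmed by the target interaction data.

    With zero predictions the observed fraction is undefined and reported as
    None (never silently 0/0). Predictions to proteins absent from the
    target data set stay in the denominator: they are real, falsifiable
    predictions, and incompleteness is handled by the coverage correction.
    """
    n_pred = len(inferences)
    n_correct = sum(1 for pair in inferences.predictions if pair in target.edges)
    f_obs = n_correct / n_pred if n_pred else None
    return TransferResult(
        mode=inferences.mode,
        n_predictions=n_pred,
        n_correct=n_correct,
        f_obs=f_obs,
        species_source=inferences.species_source,
        species_target=inferences.species_target,
    )


def family_size_filter(hmap: HomologyMap, max_homologs: int = 10) -> HomologyMap:
    """Drop pairs in which either protein has more than ``max_homologs`` partners.

    Mirrors the restriction of inferences to proteins outside large families.
    """
    if max_homologs < 1:
        raise ValueError("max_homologs must be >= 1")
    left, right = hmap.partner_counts()
    kept = {
        (a, b): score
        for (a, b), score in hmap.pairs.items()
        if left.get(a, 0) <= max_homologs and right.get(b, 0) <= max_homologs
    }
    return HomologyMap(hmap.kind, hmap.species_s, hmap.species_t, kept)
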