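"""Homology maps from pairwise-alignment hit tables.

Three operational definitions of homology are supported, from laxest to
strictest:

* **reciprocal hits** -- protein pairs found as query->hit in both alignment
  directions with both E-values below a threshold; many-to-many;
* **reciprocal best hits (RBH)** -- mutual unique best hits in both
  directions, additionally capped by an E-value; one-to-one;
* **curated** -- externally supplied ortholog pair lists (e.g. from
  gene-tree/species-tree reconciliation), consumed as two-column TSVs.

Hit tables arrive in the standard 12-column BLAST tabular layout; only the
query, subject, percent-identity, alignment-length, E-value and bitscore
columns are consumed. Multiple HSPs per (query, subject) pair are collapsed
to the single best record before any reciprocal logic runs.

Scoring conventions: a pair's E-value is the *larger* (weaker) of its two
directional E-values, so thresholding a pair means both directions pass; a
pair's percent identity is the smaller of the two directions. An E-value of
exactly 0.0 (underflow of a perfect hit) compares as below every threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional

import pandas as pd

log = logging.getLogger(__name__)

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

#: log10 stand-in for an underflowed E-value of exactly 0.0, used only for
#: log-scale binning; comparisons use the raw value (0.0 <= any threshold)
LOG10_EVALUE_FLOOR = -180.0


class PairScore(NamedTuple):
    evalue: Optional[float]
    identity: Optional[float]


@dataclass
class HitTable:
    """HSP-collapsed alignment hits for one ordered species pair."""

    species_query: str
    species_subject: str
    hits: pd.DataFrame  # columns: query, subject, pident, length, evalue, bitscore
    n_rejected: int = 0

    def best_hits(self) -> dict[str, str]:
        """Unique best subject per query (lowest E, then highest bitscore).

        Queries whose two top candidates tie on both keys are dropped: a
        best hit that is not unique is not a best hit.
        """
        out: dict[str, str] = {}
        df = self.hits.sort_values(
            ["query", "evalue", "bitscore", "subject"],
            ascending=[True, True, False, True],
            kind="mergesort",
        )
        for query, grp in df.groupby("query", sort=False):
            if len(grp) > 1:
                a, b = grp.iloc[0], grp.iloc[1]
                if a.evalue == b.evalue and a.bitscore == b.bitscore:
                    log.warning("ambiguous best hit for %s dropped", query)
                    continue
            out[query] = grp.iloc[0].subject
        return out

    def lookup(self) -> dict[tuple[str, str], tuple[float, float]]:
        """(query, subject) -> (evalue, pident)."""
        return {
            (q, s): (e, p)
            for q, s, e, p in zip(
                self.hits["query"], self.hits["subject"],
                self.hits["evalue"], self.hits["pident"],
            )
        }


def read_blast_tabular(
    path: str | Path, species_query: str, species_subject: str
) -> HitTable:
    """Read 12-column BLAST tabular output and collapse HSPs."""
    raw = pd.read_csv(
        path, sep="\t", header=None, names=BLAST_COLUMNS, comment="#",
        usecols=["qseqid", "sseqid", "pident", "length", "evalue", "bitscore"],
        dtype={"qseqid": str, "sseqid": str},
    )
    raw = raw.rename(columns={"qseqid": "query", "sseqid": "subject"})
    return collapse_hsps(raw, species_query, species_subject)


def collapse_hsps(
    raw: pd.DataFrame, species_query: str, species_subject: str
) -> HitTable:
    """Collapse raw hit rows to one record per (query, subject).

    The kept record has the minimum E-value; ties are broken by maximum
    bitscore, then by the identity of the longer aligned region, then first
    occurrence. Rows with a negative E-value or identity outside [0, 100]
    are rejected and counted. Within-species tables drop self hits (a
    protein is not its own homolog for inference purposes).
    """
    df = raw.copy()
    if "length" not in df.columns:
        df["length"] = 0
    bad = (df["evalue"] < 0) | (df["pident"] < 0) | (df["pident"] > 100)
    n_rejected = int(bad.sum())
    if n_rejected:
        log.warning("rejected %d malformed hit rows", n_rejected)
        df = df[~bad]
    if species_query == species_subject:
        df = df[df["query"] != df["subject"]]
    df = df.sort_values(
        ["query", "subject", "evalue", "bitscore", "length"],
        ascending=[True, True, True, False, False],
        kind="mergesort",
    )
    df = df.groupby(["query", "subject"], as_index=False, sort=True).first()
    df = df[["query", "subject", "pident", "length", "evalue", "bitscore"]]
    return HitTable(species_query, species_subject, df.reset_index(drop=True), n_rejected)


@dataclass
class HomologyMap:
    """Scored protein pairs between (or within) species.

    ``pairs`` maps an ordered (protein_s, protein_t) tuple to its PairScore.
    Within-species maps (equal species labels) store each unordered pair
    once in sorted order and never contain the identity pair (p, p).
    """

    kind: str  # reciprocal_hits | reciprocal_best_hits | curated
    species_s: str
    species_t: str
    pairs: dict[tuple[str, str], PairScore] = field(default_factory=dict)

    @property
    def within(self) -> bool:
        return self.species_s == self.species_t

    def __len__(self) -> int:
        return len(self.pairs)

    def __post_init__(self) -> None:
        if self.within:
            fixed = {}
            for (a, b), score in self.pairs.items():
                if a == b:
                    raise ValueError(f"within-species identity pair ({a!r})")
                fixed[(a, b) if a <= b else (b, a)] = score
            self.pairs = fixed

    # -- lookups ----------------------------------------------------------

    def oriented(self, source_species: str) -> dict[str, list[tuple[str, Optional[float]]]]:
        """Partner lists keyed by source-side protein.

        For within-species maps the lookup is symmetric. Partner lists are
        sorted for deterministic iteration.
        """
        out: dict[str, list[tuple[str, Optional[float]]]] = {}
        if self.within:
            if source_species != self.species_s:
                raise ValueError(f"map does not involve species {source_species!r}")
            for (a, b), score in self.pairs.items():
                out.setdefault(a, []).append((b, score.evalue))
                out.setdefault(b, []).append((a, score.evalue))
        elif source_species == self.species_s:
            for (a, b), score in self.pairs.items():
                out.setdefault(a, []).append((b, score.evalue))
        elif source_species == self.species_t:
            for (a, b), score in self.pairs.items():
                out.setdefault(b, []).append((a, score.evalue))
        else:
            raise ValueError(f"map does not involve species {source_species!r}")
        for partners in out.values():
            partners.sort(key=lambda t: (t[0], t[1] is None, t[1]))
        return out

    def other_species(self, species: str) -> str:
        if species == self.species_s:
            return self.species_t
        if species == self.species_t:
            return self.species_s
        raise ValueError(f"map does not involve species {species!r}")

    def partner_counts(self) -> tuple[dict[str, int], dict[str, int]]:
        """Pair-participation counts per protein, by side.

        Within-species maps return the same symmetric counter twice.
        """
        left: dict[str, int] = {}
        right: dict[str, int] = {}
        for a, b in self.pairs:
            left[a] = left.get(a, 0) + 1
            right[b] = right.get(b, 0) + 1
        if self.within:
            sym = {p: left.get(p, 0) + right.get(p, 0) for p in set(left) | set(right)}
            return sym, sym
        return left, right

    def filter_by_identity(self, min_identity: float) -> "HomologyMap":
        """Keep pairs with pair_identity >= min_identity."""
        if any(score.identity is None for score in self.pairs.values()):
            raise ValueError(f"{self.kind} map carries no identity scores")
        kept = {
            pair: score
            for pair, score in self.pairs.items()
            if score.identity >= min_identity
        }
        return HomologyMap(self.kind, self.species_s, self.species_t, kept)

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("protein_s\tprotein_t\tpair_evalue\tpair_identity\tkind\n")
            for (a, b) in sorted(self.pairs):
                ev, ident = self.pairs[(a, b)]
                fh.write(
                    f"{a}\t{b}\t{'NA' if ev is None else repr(ev)}\t"
                    f"{'NA' if ident is None else repr(ident)}\t{self.kind}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path, species_s: str, species_t: str) -> "HomologyMap":
        pairs: dict[tuple[str, str], PairScore] = {}
        kind = "curated"
        with Path(path).open(encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {name: i for i, name in enumerate(header)}
            for line in fh:
                f = line.rstrip("\n").split("\t")
                ev = None if f[idx["pair_evalue"]] == "NA" else float(f[idx["pair_evalue"]])
                ident = (
                    None if f[idx["pair_identity"]] == "NA" else float(f[idx["pair_identity"]])
                )
                pairs[(f[idx["protein_s"]], f[idx["protein_t"]])] = PairScore(ev, ident)
                kind = f[idx["kind"]]
        return cls(kind, species_s, species_t, pairs)


def reciprocal_hits(
    hits_ab: HitTable, hits_ba: HitTable, e_threshold: float
) -> HomologyMap:
    """Many-to-many map of pairs hit in both directions at the threshold.

    A pair (a, b) is kept when a->b and b->a are both present and both
    directional E-values are <= ``e_threshold``.
    """
    if e_threshold <= 0:
        raise ValueError("e_threshold must be positive")
    ba = hits_ba.lookup()
    pairs: dict[tuple[str, str], PairScore] = {}
    within = hits_ab.species_query == hits_ab.species_subject
    for q, s, e_qs, p_qs in zip(
        hits_ab.hits["query"], hits_ab.hits["subject"],
        hits_ab.hits["evalue"], hits_ab.hits["pident"],
    ):
        rec = ba.get((s, q))
        if rec is None:
            continue
        e_sq, p_sq = rec
        if e_qs <= e_threshold and e_sq <= e_threshold:
            key = (q, s) if not within or q <= s else (s, q)
            pairs[key] = PairScore(max(e_qs, e_sq), min(p_qs, p_sq))
    return HomologyMap(
        "reciprocal_hits", hits_ab.species_query, hits_ab.species_subject, pairs
    )


def reciprocal_best_hits(
    hits_ab: HitTable, hits_ba: HitTable, e_cap: float = 1e-10
) -> HomologyMap:
    """One-to-one map of mutual unique best hits below the E-value cap."""
    best_ab = hits_ab.best_hits()
    best_ba = hits_ba.best_hits()
    ab = hits_ab.lookup()
    ba = hits_ba.lookup()
    within = hits_ab.species_query == hits_ab.species_subject
    pairs: dict[tuple[str, str], PairScore] = {}
    for a, b in best_ab.items():
        if best_ba.get(b) != a:
            continue
        e_ab, p_ab = ab[(a, b)]
        e_ba, p_ba = ba[(b, a)]
        if e_ab <= e_cap and e_ba <= e_cap:
            key = (a, b) if not within or a <= b else (b, a)
            pairs[key] = PairScore(max(e_ab, e_ba), min(p_ab, p_ba))
    return HomologyMap(
        "reciprocal_best_hits", hits_ab.species_query, hits_ab.species_subject, pairs
    )


def load_curated_orthologs(
    path: str | Path, species_s: str, species_t: str
) -> HomologyMap:
    """Load a two-column TSV of curated ortholog pairs (may be many-to-many).

    Duplicate rows are deduplicated silently (counted in the log); rows with
    empty fields are rejected.
    """
    pairs: dict[tuple[str, str], PairScore] = {}
    n_dup = n_bad = 0
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 2 or not f[0] or not f[1]:
                n_bad += 1
                continue
            if species_s == species_t and f[0] == f[1]:
                n_bad += 1  # a protein is not its own homolog
                continue
            key = (f[0], f[1])
            if species_s == species_t:
                key = tuple(sorted(key))  # type: ignore[assignment]
            if key in pairs:
                n_dup += 1
            pairs[key] = PairScore(None, None)
    if n_dup or n_bad:
        log.info("curated orthologs: %d duplicates collapsed, %d rows rejected", n_dup, n_bad)
    return HomologyMap("curated", species_s, species_t, pairs)
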