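"""Canonical binary-interactome container, readers, and summary statistics.

A binary protein-protein interaction carries no direction, so every edge is
stored exactly once as the lexicographically sorted pair of protein
identifiers. Self-interactions are legitimate edges and are retained
throughout. Two on-disk dialects are supported: a plain tab-separated edge
list (optionally with per-row publication evidence) and PSI-MI TAB 2.5, from
which only direct physical-interaction rows are usually wanted -- the
evidence vocabulary is caller-supplied because label spellings vary between
database exports.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

log = logging.getLogger(__name__)

Edge = tuple[str, str]

#: default vocabulary of direct-interaction evidence labels, matched
#: case-insensitively against PSI-MI detection-method / interaction-type text
DIRECT_EVIDENCE_LABELS = frozenset(
    {
        "physical association",
        "biophysical",
        "protein complementation",
        "reconstituted complex",
        "pca",
        "co-crystal structure",
        "yeast-two-hybrid",
        "two hybrid",
    }
)


def _validate_token(token: str) -> str:
    if not token or "\t" in token or "\n" in token or token != token.strip():
        raise ValueError(f"invalid protein identifier: {token!r}")
    return token


def canonical_edge(a: str, b: str) -> Edge:
    """Return the unordered pair (a, b) in canonical (sorted) form."""
    _validate_token(a)
    _validate_token(b)
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PublicationRecord:
    """A supporting publication and the number of interactions it reports."""

    pub_id: str
    n_reported: Optional[int] = None


@dataclass
class LoadReport:
    """Row accounting for a file read or an identifier remap."""

    n_rows: int = 0
    n_kept: int = 0
    n_dropped_filter: int = 0
    n_malformed: int = 0
    n_duplicates_collapsed: int = 0
    unmapped_ids: list[str] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)


@dataclass
class Interactome:
    """One species' observed binary interactions in canonical form.

    ``evidence`` maps an edge to the set of publications supporting it;
    ``proteome_size`` is the number of proteins in the species counting one
    isoform per gene.
    """

    species: str
    edges: frozenset[Edge]
    evidence: Optional[dict[Edge, frozenset[PublicationRecord]]] = None
    proteome_size: Optional[int] = None
    load_report: Optional[LoadReport] = field(
        default=None, compare=False, repr=False
    )

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if (a, b) != canonical_edge(a, b):
                raise ValueError(f"non-canonical edge ({a!r}, {b!r})")
        if self.proteome_size is not None and len(self.proteins) > self.proteome_size:
            raise ValueError(
                f"{len(self.proteins)} proteins appear in edges but "
                f"proteome_size={self.proteome_size}"
            )

    @classmethod
    def from_pairs(
        cls,
        species: str,
        pairs: Iterable[tuple[str, str]],
        evidence: Optional[Mapping[tuple[str, str], Iterable[PublicationRecord]]] = None,
        proteome_size: Optional[int] = None,
        load_report: Optional[LoadReport] = None,
    ) -> "Interactome":
        """Canonicalize and deduplicate raw pairs into an Interactome."""
        edges = frozenset(canonical_edge(a, b) for a, b in pairs)
        ev = None
        if evidence is not None:
            merged: dict[Edge, set[PublicationRecord]] = {}
            for (a, b), pubs in evidence.items():
                merged.setdefault(canonical_edge(a, b), set()).update(pubs)
            ev = {e: frozenset(p) for e, p in merged.items()}
        return cls(species, edges, ev, proteome_size, load_report)

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(p for e in self.edges for p in e)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> Counter:
        """Number of interaction partners per protein.

        A self-interaction contributes one partner (the protein itself).
        """
        deg: Counter = Counter()
        for a, b in self.edges:
            deg[a] += 1
            if b != a:
                deg[b] += 1
        return deg


@dataclass
class SummaryRow:
    """Headline statistics for one species' interaction data set."""

    species: str
    n_interactions: int
    n_proteins_in_interactome: int
    mean_degree_interactome: float
    proteome_size: Optional[int] = None
    mean_degree_all: Optional[float] = None
    low_throughput_fraction: Optional[float] = None


def summary_from_counts(
    species: str,
    n_interactions: int,
    n_proteins_in_interactome: int,
    proteome_size: Optional[int] = None,
    low_throughput_fraction: Optional[float] = None,
) -> SummaryRow:
    """Build a SummaryRow from bare counts (interactions-per-protein means)."""
    if n_proteins_in_interactome <= 0:
        raise ValueError("n_proteins_in_interactome must be positive")
    mean_all = None
    if proteome_size is not None:
        if proteome_size <= 0:
            raise ValueError("proteome_size must be positive")
        mean_all = n_interactions / proteome_size
    return SummaryRow(
        species=species,
        n_interactions=n_interactions,
        n_proteins_in_interactome=n_proteins_in_interactome,
        mean_degree_interactome=n_interactions / n_proteins_in_interactome,
        proteome_size=proteome_size,
        mean_degree_all=mean_all,
        low_throughput_fraction=low_throughput_fraction,
    )


def summarize(interactome: Interactome, low_throughput_cutoff: int = 100) -> SummaryRow:
    """Summarize an interactome.

    An edge is low-throughput when at least one of its supporting
    publications reports fewer than ``low_throughput_cutoff`` interactions.
    If the interactome carries no evidence metadata the fraction is reported
    as absent (None), never as zero.
    """
    if interactome.n_edges == 0:
        raise ValueError("cannot summarize an empty interactome")
    if low_throughput_cutoff < 1:
        raise ValueError("low_throughput_cutoff must be >= 1")
    lt_fraction = None
    if interactome.evidence is not None:
        n_lt = 0
        for edge in interactome.edges:
            pubs = interactome.evidence.get(edge, frozenset())
            if any(
                p.n_reported is not None and p.n_reported < low_throughput_cutoff
                for p in pubs
            ):
                n_lt += 1
        lt_fraction = n_lt / interactome.n_edges
    return summary_from_counts(
        interactome.species,
        interactome.n_edges,
        len(interactome.proteins),
        interactome.proteome_size,
        lt_fraction,
    )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _psimi_labels(cell: str) -> list[str]:
    """Extract human-readable labels from a PSI-MI cell.

    Cells look like ``psi-mi:"MI:0915"(physical association)``; multiple
    values are pipe-separated. Returns the lower-cased parenthesised labels.
    """
    labels = []
    for part in cell.split("|"):
        lo = part.find("(")
        hi = part.rfind(")")
        if 0 <= lo < hi:
            labels.append(part[lo + 1 : hi].strip().lower())
    return labels


def _psimi_id(cell: str) -> str:
    """First identifier of a PSI-MI interactor cell, db prefix stripped."""
    first = cell.split("|")[0].strip()
    return first.split(":", 1)[1] if ":" in first else first


def read_interactions(
    path: str | Path,
    species: str,
    format: str = "edge-list",
    evidence_filter: Optional[Iterable[str]] = None,
    proteome_size: Optional[int] = None,
    malformed_tolerance: float = 0.1,
) -> Interactome:
    """Read an interaction file into a canonical Interactome.

    ``format`` is ``"edge-list"`` (TSV: protein_a, protein_b, and optionally
    publication_id, publication_size) or ``"psi-mi-tab"`` (PSI-MI TAB 2.5).
    For PSI-MI, rows are kept when any detection-method or interaction-type
    label is in ``evidence_filter`` (case-insensitive); with no filter every
    row is kept. Reading aborts when more than ``malformed_tolerance`` of
    rows are malformed.
    """
    path = Path(path)
    if format not in ("edge-list", "psi-mi-tab"):
        raise ValueError(f"unknown format {format!r}")
    filt = (
        frozenset(s.lower() for s in evidence_filter)
        if evidence_filter is not None
        else None
    )
    report = LoadReport()
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    evidence: dict[tuple[str, str], set[PublicationRecord]] = {}
    has_evidence = False

    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            report.n_rows += 1
            fields = line.split("\t")
            try:
                if format == "edge-list":
                    a, b = _validate_token(fields[0]), _validate_token(fields[1])
                    pub = None
                    if len(fields) >= 3 and fields[2]:
                        size = (
                            int(fields[3])
                            if len(fields) >= 4 and fields[3]
                            else None
                        )
                        pub = PublicationRecord(fields[2], size)
                else:
                    if len(fields) < 12:
                        raise ValueError("PSI-MI TAB row has fewer than 12 columns")
                    labels = _psimi_labels(fields[6]) + _psimi_labels(fields[11])
                    if filt is not None and not (set(labels) & filt):
                        report.n_dropped_filter += 1
                        continue
                    a, b = _psimi_id(fields[0]), _psimi_id(fields[1])
                    _validate_token(a)
                    _validate_token(b)
                    pub = None
                    if fields[8]:
                        pub = PublicationRecord(fields[8].split("|")[0], None)
            except (ValueError, IndexError) as exc:
                report.n_malformed += 1
                report.messages.append(f"row {report.n_rows}: {exc}")
                continue
            edge = canonical_edge(a, b)
            if edge in seen:
                report.n_duplicates_collapsed += 1
            seen.add(edge)
            pairs.append(edge)
            report.n_kept += 1
            if pub is not None:
                has_evidence = True
                evidence.setdefault(edge, set()).add(pub)

    if report.n_rows and report.n_malformed / report.n_rows > malformed_tolerance:
        raise ValueError(
            f"{report.n_malformed}/{report.n_rows} rows malformed in {path} "
            f"(tolerance {malformed_tolerance:.0%}); first: "
            f"{report.messages[0] if report.messages else 'n/a'}"
        )
    if not pairs:
        log.warning("no interactions read from %s", path)
    return Interactome.from_pairs(
        species,
        pairs,
        evidence if has_evidence else None,
        proteome_size,
        load_report=report,
    )


def write_interactions(interactome: Interactome, path: str | Path) -> None:
    """Write edges as a deterministic (sorted) two-column TSV."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for a, b in sorted(interactome.edges):
            fh.write(f"{a}\t{b}\n")


def write_summary(rows: Iterable[SummaryRow], path: str | Path) -> None:
    """Write summary rows as a TSV with species as columns."""
    rows = list(rows)

    def fmt(value) -> str:
        if value is None:
            return "NA"
        if isinstance(value, float):
            return f"{value:.4f}"
        return str(value)

    lines = [
        ("species", [r.species for r in rows]),
        ("n_interactions", [fmt(r.n_interactions) for r in rows]),
        ("low_throughput_fraction", [fmt(r.low_throughput_fraction) for r in rows]),
        ("n_proteins_in_interactome", [fmt(r.n_proteins_in_interactome) for r in rows]),
        ("mean_degree_interactome", [fmt(r.mean_degree_interactome) for r in rows]),
        ("proteome_size", [fmt(r.proteome_size) for r in rows]),
        ("mean_degree_all", [fmt(r.mean_degree_all) for r in rows]),
    ]
    with Path(path).open("w", encoding="utf-8") as fh:
        for name, values in lines:
            fh.write("\t".join([name] + list(values)) + "\n")


def apply_id_mapping(
    interactome: Interactome,
    mapping: Mapping[str, str],
    unmapped: str = "drop",
    collapse_duplicates: bool = False,
) -> Interactome:
    """Rewrite protein identifiers through a lookup table.

    ``unmapped`` is ``"drop"`` (edges touching an unmapped identifier are
    removed and reported) or ``"keep"`` (identifier passes through).
    ``mapping`` must be one-to-one on its keys; a table with duplicate keys
    should be collapsed to first occurrence *before* this call, which is what
    ``load_id_mapping(..., collapse_duplicates=True)`` does.
    """
    if unmapped not in ("drop", "keep"):
        raise ValueError("unmapped policy must be 'drop' or 'keep'")
    del collapse_duplicates  # collapse happens at table load; kept for API clarity
    report = LoadReport()
    pairs = []
    evidence: dict[tuple[str, str], set[PublicationRecord]] = {}
    for a, b in sorted(interactome.edges):
        new = []
        ok = True
        for p in (a, b):
            if p in mapping:
                new.append(mapping[p])
            elif unmapped == "keep":
                new.append(p)
            else:
                report.unmapped_ids.append(p)
                ok = False
        if not ok:
            report.n_dropped_filter += 1
            continue
        edge = canonical_edge(*new)
        pairs.append(edge)
        report.n_kept += 1
        if interactome.evidence and (a, b) in interactome.evidence:
            evidence.setdefault(edge, set()).update(interactome.evidence[(a, b)])
    return Interactome.from_pairs(
        interactome.species,
        pairs,
        evidence if evidence else None,
        interactome.proteome_size,
        load_report=report,
    )


def load_id_mapping(path: str | Path, collapse_duplicates: bool = False) -> dict[str, str]:
    """Load a two-column old-ID -> new-ID TSV.

    Duplicate keys raise unless ``collapse_duplicates`` keeps the first
    occurrence (the documented collapse rule).
    """
    mapping: dict[str, str] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            old, new = line.split("\t")[:2]
            if old in mapping and mapping[old] != new:
                if not collapse_duplicates:
                    raise ValueError(f"one-to-many mapping for {old!r}")
                continue
            mapping[_validate_token(old)] = _validate_token(new)
    return mapping
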