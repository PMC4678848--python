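"""Gene Ontology structure and annotation handling.

Positive (DNA-binding) training proteins are those annotated with
GO:0003677 (DNA binding), GO:0003700 (DNA-binding transcription factor
activity) or any of their descendants, under an evidence-code policy
(by default only IDA, function inferred from direct assay). Negatives
are proteins whose allowed-evidence molecular-function annotations all
fall outside that closure.

Only the ``is_a`` hierarchy is used for the descendant closure by default;
``part_of`` can be enabled but rarely matters within molecular function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet
import pandas as pd

#: GO term roots defining the DNA-binding positive class.
DNA_BINDING_ROOTS: tuple[str, str] = ("GO:0003677", "GO:0003700")

MOLECULAR_FUNCTION = "molecular_function"

_ASPECT_ALIASES = {
    "F": MOLECULAR_FUNCTION,
    "molecular_function": MOLECULAR_FUNCTION,
    "P": "biological_process",
    "biological_process": "biological_process",
    "C": "cellular_component",
    "cellular_component": "cellular_component",
}

#: GO evidence codes (controlled vocabulary subset relevant here).
EVIDENCE_CODES = frozenset(
    {
        "EXP", "IDA", "IPI", "IMP", "IGI", "IEP",
        "HTP", "HDA", "HMP", "HGI", "HEP",
        "IBA", "IBD", "IKR", "IRD",
        "ISS", "ISO", "ISA", "ISM", "IGC", "RCA",
        "TAS", "NAS", "IC", "ND", "IEA",
    }
)


@dataclass(frozen=True)
class EvidencePolicy:
    """Which GO evidence codes count when selecting training proteins."""

    allowed_codes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.allowed_codes:
            raise ValueError("allowed_codes must be non-empty")
        unknown = set(self.allowed_codes) - EVIDENCE_CODES
        if unknown:
            raise ValueError(f"unknown evidence codes: {sorted(unknown)}")

    @classmethod
    def experimental_direct(cls) -> "EvidencePolicy":
        """Direct-assay evidence only (IDA)."""
        return cls(frozenset({"IDA"}))

    @classmethod
    def manual(cls) -> "EvidencePolicy":
        """Manually curated evidence codes."""
        return cls(frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "TAS", "IC"}))


@dataclass(frozen=True)
class AnnotationRecord:
    protein_id: str
    go_term: str
    evidence_code: str
    aspect: str

    def __post_init__(self) -> None:
        if self.evidence_code not in EVIDENCE_CODES:
            raise ValueError(
                f"annotation for {self.protein_id}: unknown evidence code "
                f"{self.evidence_code!r}"
            )
        if self.aspect not in _ASPECT_ALIASES.values():
            raise ValueError(f"unknown GO aspect {self.aspect!r}")


class GoDag:
    """A GO term DAG restricted to id and parent (``is_a``) edges."""

    def __init__(self, parents: Mapping[str, Iterable[str]]):
        self.parents: dict[str, frozenset[str]] = {
            term: frozenset(ps) for term, ps in parents.items()
        }
        # every parent must itself be a term
        for term, ps in self.parents.items():
            for p in ps:
                if p not in self.parents:
                    raise ValueError(f"parent {p!r} of {term!r} is not a term in the DAG")
        graph = nx.DiGraph(
            (term, p) for term, ps in self.parents.items() for p in ps
        )
        graph.add_nodes_from(self.parents)
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("GO term graph contains a cycle")
        self._children: dict[str, set[str]] = {t: set() for t in self.parents}
        for term, ps in self.parents.items():
            for p in ps:
                self._children[p].add(term)

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.parents)

    @classmethod
    def from_obo(cls, path: str | Path, include_part_of: bool = False) -> "GoDag":
        """Parse an OBO 1.2 flat file; only id and is_a (optionally part_of) used."""
        graph = obonet.read_obo(str(path))
        wanted = {"is_a"} | ({"part_of"} if include_part_of else set())
        parents: dict[str, set[str]] = {t: set() for t in graph.nodes}
        for child, parent, key in graph.edges(keys=True):
            if key in wanted:
                parents[child].add(parent)
        return cls(parents)

    def term_closure(self, roots: Iterable[str]) -> frozenset[str]:
        """Roots plus every descendant term (reachable against is_a edges)."""
        roots = list(roots)
        unknown = [r for r in roots if r not in self.parents]
        if unknown:
            raise KeyError(f"root term(s) not in DAG: {unknown}")
        seen: set[str] = set()
        stack = list(roots)
        while stack:
            term = stack.pop()
            if term in seen:
                continue
            seen.add(term)
            stack.extend(self._children[term])
        return frozenset(seen)


def term_closure(dag: GoDag, roots: Iterable[str]) -> frozenset[str]:
    """Module-level convenience for :meth:`GoDag.term_closure`."""
    return dag.term_closure(roots)


def read_annotations(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read an annotation TSV with columns protein_id, go_term, evidence_code, aspect.

    ``column_map`` renames source columns onto those names, which also covers
    GAF-style exports (e.g. ``{"DB_Object_ID": "protein_id", ...}``). Aspect
    single-letter codes (F/P/C) are expanded.
    """
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    required = ["protein_id", "go_term", "evidence_code", "aspect"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    frame = frame[required].copy()
    frame["aspect"] = frame["aspect"].map(lambda a: _ASPECT_ALIASES.get(a, a))
    bad = set(frame["aspect"]) - set(_ASPECT_ALIASES.values())
    if bad:
        raise ValueError(f"unknown GO aspects in table: {sorted(bad)}")
    return frame


def select_by_terms(
    annotations: pd.DataFrame | Sequence[AnnotationRecord],
    term_set: Iterable[str],
    policy: EvidencePolicy,
    positive: bool = True,
) -> set[str]:
    """Select protein ids by GO-term membership under an evidence policy.

    With ``positive=True`` a protein qualifies if it has at least one
    allowed-evidence molecular-function annotation inside ``term_set``.
    With ``positive=False`` it must have at least one allowed-evidence
    molecular-function annotation and none inside ``term_set`` — proteins
    carrying both a DNA-binding and another function are excluded from the
    negative class to avoid label noise.
    """
    if not isinstance(annotations, pd.DataFrame):
        annotations = pd.DataFrame(
            [
                {
                    "protein_id": a.protein_id,
                    "go_term": a.go_term,
                    "evidence_code": a.evidence_code,
                    "aspect": a.aspect,
                }
                for a in annotations
            ],
            columns=["protein_id", "go_term", "evidence_code", "aspect"],
        )
    term_set = set(term_set)
    usable = annotations[
        (annotations["aspect"] == MOLECULAR_FUNCTION)
        & annotations["evidence_code"].isin(policy.allowed_codes)
    ]
    if usable.empty:
        return set()
    in_set = usable.groupby("protein_id")["go_term"].agg(
        lambda terms: any(t in term_set for t in terms)
    )
    if positive:
        return set(in_set[in_set].index)
    return set(in_set[~in_set].index)
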