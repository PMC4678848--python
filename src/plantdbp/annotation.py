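"""Proteome-scale annotation of predicted DNA-binding proteins.

After thresholding, each predicted protein is compared against existing
annotation and classified as GOA-DB (already annotated DNA-binding),
GOA-Other (annotated with some other molecular function) or GOA-Unknown
(no informative annotation). Three companion statistics assess the
predicted set as a whole:

* nuclear-localisation fold enrichment,
  (nNL_DBP / nDBP) / (nNL_proteome / n_proteome) — DNA-binding proteins
  should be over-represented among predicted-nuclear proteins;
* GO term over-representation, one-sided Fisher's exact test per term
  with Benjamini-Hochberg FDR control;
* three-set overlap (Venn region counts) against independent protein sets
  such as database annotations and chromatin-proteomics hits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests


class GoaClass(str, Enum):
    GOA_DB = "GOA_DB"
    GOA_OTHER = "GOA_OTHER"
    GOA_UNKNOWN = "GOA_UNKNOWN"


#: Domain-label keywords (regex, case-insensitive) taken as DNA-binding evidence.
DEFAULT_DNA_DOMAIN_KEYWORDS: tuple[str, ...] = (
    r"DNA[- ]binding",
    r"transcription factor",
    r"histone",
    r"helix-turn-helix",
    r"zinc finger.*DNA",
)


def classify_goa(
    protein_id: str,
    go_terms: Iterable[str],
    domain_labels: Iterable[str],
    dna_binding_term_set: Iterable[str],
    dna_binding_domain_keywords: Sequence[str] = DEFAULT_DNA_DOMAIN_KEYWORDS,
) -> GoaClass:
    """Assign one annotation class to a predicted protein.

    GOA-DB if any GO term falls in the DNA-binding closure or any domain
    label matches a DNA-binding keyword; GOA-Unknown if the protein has
    no GO term and no domain label at all; GOA-Other otherwise.
    """
    go_terms = list(go_terms)
    domain_labels = list(domain_labels)
    term_set = set(dna_binding_term_set)
    patterns = [re.compile(k, re.IGNORECASE) for k in dna_binding_domain_keywords]
    if any(t in term_set for t in go_terms):
        return GoaClass.GOA_DB
    if any(p.search(label) for label in domain_labels for p in patterns):
        return GoaClass.GOA_DB
    if not go_terms and not domain_labels:
        return GoaClass.GOA_UNKNOWN
    return GoaClass.GOA_OTHER


def classify_goa_table(
    protein_ids: Sequence[str],
    go_terms_by_protein: Mapping[str, Iterable[str]],
    domains_by_protein: Mapping[str, Iterable[str]],
    dna_binding_term_set: Iterable[str],
    dna_binding_domain_keywords: Sequence[str] = DEFAULT_DNA_DOMAIN_KEYWORDS,
) -> dict[str, str]:
    """Classify many proteins; returns id -> class-name string."""
    term_set = set(dna_binding_term_set)
    return {
        pid: classify_goa(
            pid,
            go_terms_by_protein.get(pid, ()),
            domains_by_protein.get(pid, ()),
            term_set,
            dna_binding_domain_keywords,
        ).value
        for pid in protein_ids
    }


@dataclass(frozen=True)
class NlEnrichmentInput:
    """Counts for the nuclear-localisation fold-enrichment ratio."""

    nNL_DNA_BP: int  # predicted-nuclear proteins among predicted DNA-BPs
    nDNA_BP: int  # predicted DNA-BPs
    nNL_TProt: int  # predicted-nuclear proteins in the whole proteome
    nTProt: int  # proteome size

    def __post_init__(self) -> None:
        if min(self.nNL_DNA_BP, self.nDNA_BP, self.nNL_TProt, self.nTProt) < 0:
            raise ValueError("counts must be non-negative")
        if self.nNL_DNA_BP > self.nDNA_BP:
            raise ValueError("nNL_DNA_BP cannot exceed nDNA_BP")
        if self.nNL_TProt > self.nTProt:
            raise ValueError("nNL_TProt cannot exceed nTProt")


def nl_enrichment(inp: NlEnrichmentInput) -> float:
    """Fold enrichment of nuclear-localised proteins in the predicted set."""
    if inp.nDNA_BP == 0 or inp.nTProt == 0 or inp.nNL_TProt == 0:
        raise ValueError("enrichment ratio has a zero denominator")
    return (inp.nNL_DNA_BP / inp.nDNA_BP) / (inp.nNL_TProt / inp.nTProt)


def count_nuclear_rank1(nl_table: pd.DataFrame, protein_ids: Iterable[str] | None = None) -> int:
    """Count rank-1 nuclear-localisation calls, optionally within an id set.

    Expects columns ``protein_id`` and ``nuclear_rank``; rank 1 is the
    highest-confidence nuclear call of the upstream localisation predictor.
    """
    frame = nl_table[nl_table["nuclear_rank"].astype(int) == 1]
    if protein_ids is not None:
        frame = frame[frame["protein_id"].isin(set(protein_ids))]
    return int(frame["protein_id"].nunique())


@dataclass(frozen=True)
class EnrichmentResult:
    go_term: str
    set_with_term: int
    set_total: int
    reference_with_term: int
    reference_total: int
    p_value: float
    q_value: float
    significant: bool


def term_enrichment(
    set_annotations: Mapping[str, Iterable[str]],
    reference_annotations: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """GO-term over-representation in a protein set versus a reference.

    Both mappings are protein id -> GO terms; proteins without any term
    are dropped from both sides before testing. For every term present in
    the set, a one-sided (greater) Fisher exact test compares the term's
    frequency in the set against the reference-only proteins (reference
    minus set), followed by Benjamini-Hochberg FDR adjustment. Results are
    sorted by q then p.
    """
    set_terms = {p: set(ts) for p, ts in set_annotations.items() if set(ts)}
    ref_terms = {p: set(ts) for p, ts in reference_annotations.items() if set(ts)}
    if not set_terms:
        raise ValueError("no annotated proteins in the query set")
    ref_only = {p: ts for p, ts in ref_terms.items() if p not in set_terms}
    n_set = len(set_terms)
    n_ref_only = len(ref_only)
    terms = sorted({t for ts in set_terms.values() for t in ts})
    raw = []
    for term in terms:
        a = sum(1 for ts in set_terms.values() if term in ts)
        c = sum(1 for ts in ref_only.values() if term in ts)
        table = [[a, n_set - a], [c, n_ref_only - c]]
        _, p = fisher_exact(table, alternative="greater")
        raw.append((term, a, c, float(p)))
    pvals = [p for *_, p in raw]
    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    results = [
        EnrichmentResult(
            go_term=term,
            set_with_term=a,
            set_total=n_set,
            reference_with_term=c,
            reference_total=n_ref_only,
            p_value=p,
            q_value=float(q),
            significant=bool(sig),
        )
        for (term, a, c, p), q, sig in zip(raw, qvals, reject)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, r.go_term))
    return results


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def overlap_report(
    set_a_ids: Iterable[str],
    set_b_ids: Iterable[str],
    set_c_ids: Iterable[str],
) -> dict[str, int]:
    """All seven region counts of a three-set Venn diagram.

    Keys name the regions by membership (``a_only`` .. ``abc``); the
    region counts sum to the size of the union.
    """
    a, b, c = set(set_a_ids), set(set_b_ids), set(set_c_ids)
    abc = a & b & c
    report = {
        "a_only": len(a - b - c),
        "b_only": len(b - a - c),
        "c_only": len(c - a - b),
        "ab_only": len((a & b) - c),
        "ac_only": len((a & c) - b),
        "bc_only": len((b & c) - a),
        "abc": len(abc),
    }
    report["union"] = len(a | b | c)
    assert sum(v for k, v in report.items() if k != "union") == report["union"]
    return report
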