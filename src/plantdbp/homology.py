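"""Homology reduction of sequence sets.

Benchmark datasets must not contain near-duplicate sequences, otherwise
train/test splits leak information through homologs. Pairs are linked when
a local alignment reaches >= 35% identity over >= 90% of both sequence
lengths; clusters are the connected components (single linkage) and one
representative per cluster is drawn at random under a seed.

The alignment engine is Biopython's PairwiseAligner with BLOSUM62 and
affine gaps (open 11, extend 1, BLAST convention). Coverage is required on
BOTH sequences — the conservative choice, which can only remove more
redundancy than a one-sided rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .sequences import ProteinRecord
from .tables import write_tsv

#: Residues without a BLOSUM62 row are scored as X (ambiguous).
_TO_X = str.maketrans({"J": "X", "U": "X", "O": "X"})


@dataclass(frozen=True)
class ScoringConfig:
    """Local-alignment scoring used for redundancy detection."""

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1

    def build_aligner(self) -> PairwiseAligner:
        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        # BLAST convention: a gap of length L costs open + L*extend
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


@dataclass(frozen=True)
class PairwiseSimilarity:
    id_a: str
    id_b: str
    percent_identity: float  # 0..100, identical columns / alignment columns
    coverage_a: float  # fraction of sequence a spanned by the local alignment
    coverage_b: float


@dataclass(frozen=True)
class ClusterAssignment:
    cluster_id: int
    member_ids: frozenset[str]
    representative_id: str

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a cluster member")


def pairwise_similarity(
    rec_a: ProteinRecord,
    rec_b: ProteinRecord,
    scoring: ScoringConfig | None = None,
    _aligner: PairwiseAligner | None = None,
) -> PairwiseSimilarity:
    """Best local alignment identity and mutual coverage for one pair."""
    aligner = _aligner or (scoring or ScoringConfig()).build_aligner()
    seq_a = rec_a.sequence.translate(_TO_X)
    seq_b = rec_b.sequence.translate(_TO_X)
    alignments = aligner.align(seq_a, seq_b)
    try:
        best = alignments[0]
    except IndexError:
        best = None
    if best is None or best.score <= 0 or len(best.aligned[0]) == 0:
        return PairwiseSimilarity(rec_a.id, rec_b.id, 0.0, 0.0, 0.0)
    counts = best.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / columns if columns else 0.0
    blocks_a, blocks_b = best.aligned
    span_a = blocks_a[-1][1] - blocks_a[0][0]
    span_b = blocks_b[-1][1] - blocks_b[0][0]
    return PairwiseSimilarity(
        rec_a.id,
        rec_b.id,
        percent_identity=identity,
        coverage_a=span_a / len(rec_a),
        coverage_b=span_b / len(rec_b),
    )


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def is_redundant_pair(
    sim: PairwiseSimilarity,
    id_threshold: float = 35.0,
    coverage_threshold: float = 0.9,
) -> bool:
    return (
        sim.percent_identity >= id_threshold
        and min(sim.coverage_a, sim.coverage_b) >= coverage_threshold
    )


def homology_reduce(
    records: Sequence[ProteinRecord],
    id_threshold: float = 35.0,
    coverage_threshold: float = 0.9,
    seed: int | None = None,
    scoring: ScoringConfig | None = None,
) -> tuple[list[ProteinRecord], list[ClusterAssignment]]:
    """Cluster redundant sequences and keep one random representative each.

    Edges link pairs at >= ``id_threshold`` % identity with >=
    ``coverage_threshold`` coverage of both sequences; clusters are
    connected components. Representatives are drawn uniformly per cluster
    under ``seed`` and returned in input order. Cluster membership is
    seed-independent; only the representative choice is randomised.
    """
    if not records:
        raise ValueError("homology_reduce requires at least one record")
    aligner = (scoring or ScoringConfig()).build_aligner()
    n = len(records)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim = pairwise_similarity(records[i], records[j], _aligner=aligner)
            if is_redundant_pair(sim, id_threshold, coverage_threshold):
                uf.union(i, j)
    members: dict[int, list[int]] = {}
    for i in range(n):  # input order fixes cluster numbering before seeding
        members.setdefault(uf.find(i), []).append(i)
    rng = np.random.default_rng(seed)
    assignments: list[ClusterAssignment] = []
    rep_indices: set[int] = set()
    for cluster_id, root in enumerate(sorted(members)):
        idx = members[root]
        rep = idx[rng.integers(len(idx))]
        rep_indices.add(rep)
        assignments.append(
            ClusterAssignment(
                cluster_id=cluster_id,
                member_ids=frozenset(records[i].id for i in idx),
                representative_id=records[rep].id,
            )
        )
    representatives = [records[i] for i in range(n) if i in rep_indices]
    return representatives, assignments


def write_cluster_table(
    assignments: Sequence[ClusterAssignment],
    path: str | Path,
    metadata: dict | None = None,
) -> None:
    rows = []
    for a in assignments:
        for member in sorted(a.member_ids):
            rows.append(
                {
                    "cluster_id": a.cluster_id,
                    "representative_flag": int(member == a.representative_id),
                    "protein_id": member,
                }
            )
    write_tsv(pd.DataFrame(rows), path, metadata)
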