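import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from plantdbp.homology import (
    ClusterAssignment,
    ScoringConfig,
    homology_reduce,
    is_redundant_pair,
    pairwise_similarity,
)
from plantdbp.sequences import ProteinRecord

from conftest import random_protein

BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN = 12  # cost of a length-1 gap (BLAST open 11 + extend 1)
GAP_EXTEND = 1


def local_affine_score(a: str, b: str) -> float:
    """Exhaustive Smith-Waterman with affine gaps (independent oracle)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - GAP_OPEN, E[i][j - 1] - GAP_EXTEND)
            F[i][j] = max(H[i - 1][j] - GAP_OPEN, F[i - 1][j] - GAP_EXTEND)
            diag = H[i - 1][j - 1] + BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestPairwiseSimilarity:
    def test_identical_sequences(self):
        rec = ProteinRecord("a", "MKVLAWRTYHEDSGNQICFP")
        sim = pairwise_similarity(rec, ProteinRecord("b", rec.sequence))
        assert sim.percent_identity == 100.0
        assert sim.coverage_a == sim.coverage_b == 1.0

    def test_unalignable_pair_scores_zero(self):
        sim = pairwise_similarity(
            ProteinRecord("a", "MKKKKKKKKK"), ProteinRecord("b", "WWWWWWWWWW")
        )
        # oracle: no positive-scoring local alignment exists at all
        assert local_affine_score("MKKKKKKKKK", "WWWWWWWWWW") == 0.0
        assert sim.percent_identity == 0.0

    def test_containment_coverage(self):
        full = ProteinRecord("a", "MKVLAWRTYHEDSGNQICFP" * 2)
        half = ProteinRecord("b", full.sequence[: len(full) // 2])
        sim = pairwise_similarity(full, half)
        assert sim.coverage_b == pytest.approx(1.0)
        assert sim.coverage_a == pytest.approx(0.5)

    def test_engine_score_matches_dp_oracle_on_short_peptides(self, rng):
        aligner = ScoringConfig().build_aligner()
        for _ in range(25):
            a = random_protein(rng, int(rng.integers(5, 15)), "a").sequence
            b = random_protein(rng, int(rng.integers(5, 15)), "b").sequence
            expected = local_affine_score(a, b)
            got = aligner.align(a, b).score if expected > 0 else 0.0
            if expected == 0.0:
                sim = pairwise_similarity(ProteinRecord("x", a), ProteinRecord("y", b))
                assert sim.percent_identity == 0.0
            else:
                assert got == pytest.approx(expected)


def mutate(rng, seq: str, n_changes: int) -> str:
    from plantdbp.sequences import CANONICAL_RESIDUES

    out = list(seq)
    for pos in rng.choice(len(seq), size=n_changes, replace=False):
        out[pos] = CANONICAL_RESIDUES[
            (CANONICAL_RESIDUES.index(out[pos]) + 1) % len(CANONICAL_RESIDUES)
        ]
    return "".join(out)


def brute_force_clusters(records, id_threshold=35.0, coverage_threshold=0.9):
    """All-pairs edge list + connected components (independent oracle)."""
    edges = {
        (i, j)
        for i, j in itertools.combinations(range(len(records)), 2)
        if is_redundant_pair(
            pairwise_similarity(records[i], records[j]),
            id_threshold, coverage_threshold,
        )
    }
    clusters = []
    unseen = set(range(len(records)))
    while unseen:
        stack = [min(unseen)]
        comp = set()
        while stack:
            i = stack.pop()
            if i in comp:
                continue
            comp.add(i)
            for j in range(len(records)):
                if (min(i, j), max(i, j)) in edges and j not in comp:
                    stack.append(j)
        clusters.append(frozenset(records[i].id for i in comp))
        unseen -= comp
    return set(clusters)


class TestHomologyReduce:
    def test_identical_pair_collapses(self):
        rec = ProteinRecord("a", "MKVLAWRTYHEDSGNQICFP" * 3)
        reps, clusters = homology_reduce([rec, ProteinRecord("b", rec.sequence)], seed=0)
        assert len(reps) == 1 and len(clusters) == 1
        assert clusters[0].member_ids == {"a", "b"}

    def test_single_linkage_transitivity(self, rng):
        # A~B and B~C are linked, A~C alone is not: one cluster by transitivity
        base = random_protein(rng, 100, "A").sequence
        a = ProteinRecord("A", base)
        b = ProteinRecord("B", mutate(rng, base, 45))  # ~55% id to A
        c = ProteinRecord("C", mutate(rng, b.sequence, 45))
        sim_ab = pairwise_similarity(a, b)
        sim_bc = pairwise_similarity(b, c)
        sim_ac = pairwise_similarity(a, c)
        assert is_redundant_pair(sim_ab) and is_redundant_pair(sim_bc)
        assert sim_ac.percent_identity < sim_ab.percent_identity
        reps, clusters = homology_reduce([a, b, c], seed=0)
        expected = brute_force_clusters([a, b, c])
        assert {cl.member_ids for cl in clusters} == expected

    def test_dissimilar_records_stay_singletons(self, rng):
        records = [random_protein(rng, 60, "p", i) for i in range(10)]
        assert brute_force_clusters(records) == {
            frozenset({r.id}) for r in records
        }
        reps, clusters = homology_reduce(records, seed=0)
        assert [r.id for r in reps] == [r.id for r in records]

    def test_clusters_match_oracle_on_mixed_instance(self, rng):
        records = []
        for fam in range(4):
            parent = random_protein(rng, 80, f"f{fam}m", 0)
            records.append(parent)
            for member in range(1, 4):
                records.append(
                    ProteinRecord(f"f{fam}m{member}", mutate(rng, parent.sequence, 4))
                )
        rng.shuffle(records)
        reps, clusters = homology_reduce(records, seed=7)
        assert {cl.member_ids for cl in clusters} == brute_force_clusters(records)
        # no two representatives are linked under the thresholds
        for r1, r2 in itertools.combinations(reps, 2):
            assert not is_redundant_pair(pairwise_similarity(r1, r2))

    def test_seed_determinism_and_membership_stability(self, rng):
        parent = random_protein(rng, 80, "q", 0)
        records = [parent] + [
            ProteinRecord(f"q{i}", mutate(rng, parent.sequence, 4)) for i in range(1, 5)
        ]
        reps1, cl1 = homology_reduce(records, seed=1)
        reps2, cl2 = homology_reduce(records, seed=1)
        assert [r.id for r in reps1] == [r.id for r in reps2]
        _, cl3 = homology_reduce(records, seed=99)
        assert [c.member_ids for c in cl1] == [c.member_ids for c in cl3]

    def test_raising_identity_threshold_never_merges_clusters(self, rng):
        parent = random_protein(rng, 60, "r", 0)
        records = [parent] + [
            ProteinRecord(f"r{i}", mutate(rng, parent.sequence, i * 6))
            for i in range(1, 6)
        ]
        counts = [
            len(homology_reduce(records, id_threshold=t, seed=0)[1])
            for t in (35.0, 60.0, 85.0, 99.0)
        ]
        assert counts == sorted(counts)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            homology_reduce([])

    def test_representative_must_be_member(self):
        with pytest.raises(ValueError):
            ClusterAssignment(0, frozenset({"a"}), "b")
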