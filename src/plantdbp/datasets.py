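"""Labeled training/test set assembly.

Three dataset designs are supported, mirroring how curated benchmarks for
DNA-binding-protein classifiers are built:

* *equal* (balanced) sets — the same number of DNA-binding and
  non-DNA-binding proteins in train and test;
* *realistic* sets — roughly ten non-binders per binder, the class ratio
  expected inside a proteome (DNA-binding proteins are estimated at 6-7%
  of eukaryotic proteomes);
* a *combined* lineage pool merging positives from several source species
  with negatives sampled per source.

All sampling is uniform without replacement under a single seeded
generator; train and test are id-disjoint by construction and checked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .homology import ScoringConfig, is_redundant_pair, pairwise_similarity
from .sequences import ProteinRecord
from .tables import write_tsv

DNA_BP = "DNA_BP"
NON_DNA_BP = "NON_DNA_BP"
LABELS = (DNA_BP, NON_DNA_BP)


@dataclass
class LabeledDataset:
    """Proteins with binary DNA-binding labels and provenance."""

    entries: list[tuple[ProteinRecord, str]]
    provenance: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        ids = [rec.id for rec, _ in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate protein ids in dataset: {dupes[:5]}")
        bad = {label for _, label in self.entries if label not in LABELS}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def records(self) -> list[ProteinRecord]:
        return [rec for rec, _ in self.entries]

    @property
    def labels(self) -> list[str]:
        return [label for _, label in self.entries]

    @property
    def ids(self) -> set[str]:
        return {rec.id for rec, _ in self.entries}

    def count(self, label: str) -> int:
        return sum(1 for _, lab in self.entries if lab == label)

    @property
    def n_pos(self) -> int:
        return self.count(DNA_BP)

    @property
    def n_neg(self) -> int:
        return self.count(NON_DNA_BP)

    def to_frame(self, split: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": [rec.id for rec, _ in self.entries],
                "label": self.labels,
                "split": split,
                "provenance": self.provenance,
            }
        )


@dataclass(frozen=True)
class SplitSpec:
    """Explicit per-class train/test counts for a balanced split."""

    n_train_pos: int
    n_train_neg: int
    n_test_pos: int
    n_test_neg: int

    def __post_init__(self) -> None:
        for name in ("n_train_pos", "n_train_neg", "n_test_pos", "n_test_neg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _sample(pool: Sequence[ProteinRecord], n: int, rng: np.random.Generator,
            what: str) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Draw n records without replacement; return (drawn, remainder)."""
    if n > len(pool):
        raise ValueError(f"requested {n} {what} but pool has only {len(pool)}")
    idx = rng.choice(len(pool), size=n, replace=False)
    chosen = set(idx.tolist())
    return [pool[i] for i in sorted(chosen)], [pool[i] for i in range(len(pool)) if i not in chosen]


def _check_disjoint(train: LabeledDataset, test: LabeledDataset) -> None:
    overlap = train.ids & test.ids
    if overlap:  # defensive: sampling without replacement should preclude this
        raise AssertionError(f"train/test share ids: {sorted(overlap)[:5]}")


def balanced_split(
    pos_pool: Sequence[ProteinRecord],
    neg_pool: Sequence[ProteinRecord],
    spec: SplitSpec,
    seed: int | None = None,
    provenance: str = "equal",
) -> tuple[LabeledDataset, LabeledDataset]:
    """Sample disjoint train and test sets with exact per-class counts."""
    if {r.id for r in pos_pool} & {r.id for r in neg_pool}:
        raise ValueError("positive and negative pools overlap")
    rng = np.random.default_rng(seed)
    train_pos, rest_pos = _sample(pos_pool, spec.n_train_pos, rng, "positives")
    test_pos, _ = _sample(rest_pos, spec.n_test_pos, rng, "test positives")
    train_neg, rest_neg = _sample(neg_pool, spec.n_train_neg, rng, "negatives")
    test_neg, _ = _sample(rest_neg, spec.n_test_neg, rng, "test negatives")
    train = LabeledDataset(
        [(r, DNA_BP) for r in train_pos] + [(r, NON_DNA_BP) for r in train_neg],
        provenance=f"{provenance}_train", seed=seed,
    )
    test = LabeledDataset(
        [(r, DNA_BP) for r in test_pos] + [(r, NON_DNA_BP) for r in test_neg],
        provenance=f"{provenance}_test", seed=seed,
    )
    _check_disjoint(train, test)
    return train, test


def realistic_split(
    pos_pool: Sequence[ProteinRecord],
    neg_pool: Sequence[ProteinRecord],
    ratio: int = 10,
    seed: int | None = None,
    provenance: str = "realistic",
) -> tuple[LabeledDataset, LabeledDataset]:
    """Split with the proteome-like class imbalance (default 10:1).

    Negatives are halved between train and test (the larger half to
    train, e.g. 1767 -> 884/883); positives per side are
    floor(negatives_per_side / ratio), capped by the positive pool.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    n_neg = len(neg_pool)
    n_neg_train = math.ceil(n_neg / 2)
    n_neg_test = n_neg - n_neg_train
    n_pos_side = min(n_neg_test // ratio, n_neg_train // ratio, len(pos_pool) // 2)
    spec = SplitSpec(
        n_train_pos=n_pos_side,
        n_train_neg=n_neg_train,
        n_test_pos=n_pos_side,
        n_test_neg=n_neg_test,
    )
    return balanced_split(pos_pool, neg_pool, spec, seed=seed, provenance=provenance)


def exclude_cross_homologs(
    candidate_records: Sequence[ProteinRecord],
    reference_records: Sequence[ProteinRecord],
    id_threshold: float = 35.0,
    coverage_threshold: float = 0.9,
    scoring: ScoringConfig | None = None,
) -> list[ProteinRecord]:
    """Drop candidates with a homolog in the reference set.

    A candidate is removed if any reference sequence aligns at
    >= ``id_threshold`` % identity with >= ``coverage_threshold`` coverage
    of both sequences — preventing leakage between independently built
    datasets (e.g. an other-species pool versus an existing benchmark).
    """
    aligner = (scoring or ScoringConfig()).build_aligner()
    kept = []
    for cand in candidate_records:
        hit = any(
            is_redundant_pair(
                pairwise_similarity(cand, ref, _aligner=aligner),
                id_threshold,
                coverage_threshold,
            )
            for ref in reference_records
        )
        if not hit:
            kept.append(cand)
    return kept


def combine_plant_pool(
    pos_sources: Sequence[Sequence[ProteinRecord]],
    neg_sources: Sequence[Sequence[ProteinRecord]],
    neg_counts: Sequence[int],
    seed: int | None = None,
    provenance: str = "combined",
) -> LabeledDataset:
    """Merge positives from several sources with per-source negative samples.

    All positives are taken; negatives are drawn without replacement from
    each negative source at the stated counts, which must sum to the total
    number of positives (the combined set is balanced by design).
    """
    if len(neg_sources) != len(neg_counts):
        raise ValueError("one negative count required per negative source")
    positives: list[ProteinRecord] = [r for src in pos_sources for r in src]
    if len({r.id for r in positives}) != len(positives):
        raise ValueError("positive sources overlap")
    if sum(neg_counts) != len(positives):
        raise ValueError(
            f"negative counts sum to {sum(neg_counts)} but there are "
            f"{len(positives)} positives"
        )
    rng = np.random.default_rng(seed)
    negatives: list[ProteinRecord] = []
    for src, count in zip(neg_sources, neg_counts):
        drawn, _ = _sample(src, count, rng, "negatives")
        negatives.extend(drawn)
    return LabeledDataset(
        [(r, DNA_BP) for r in positives] + [(r, NON_DNA_BP) for r in negatives],
        provenance=provenance,
        seed=seed,
    )


def write_dataset_table(
    datasets: dict[str, LabeledDataset], path: str | Path, metadata: dict | None = None
) -> None:
    """Write splits to one TSV: protein_id, label, split, provenance."""
    frame = pd.concat(
        [ds.to_frame(split=name) for name, ds in datasets.items()], ignore_index=True
    )
    write_tsv(frame, path, metadata)
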