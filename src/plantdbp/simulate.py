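"""Seedable synthetic proteomes with controlled compositional class separation.

Because the classifier sees nothing but amino-acid composition, a
per-residue i.i.d. model is sufficient to exercise every stage of the
pipeline: two classes share a base composition on the 20-simplex and the
positive (DNA-binding-like) class receives extra probability mass delta
on a chosen residue subset — by default the positively charged residues
K and R, echoing the charge bias of real DNA-binding surfaces. Optional
homolog families (a parent plus seeded point mutants at <10% of
positions) give the redundancy-removal stage something to find.

Same seed, same spec: byte-identical FASTA output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import DNA_BP, NON_DNA_BP, LabeledDataset
from .sequences import CANONICAL_RESIDUES, ProteinRecord


def _uniform_composition() -> tuple[float, ...]:
    return tuple([1.0 / len(CANONICAL_RESIDUES)] * len(CANONICAL_RESIDUES))


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic two-class proteome.

    ``effect_delta`` is the total probability mass added to
    ``effect_residues`` in the positive class (split evenly across the
    subset and taken proportionally from the remaining residues).
    """

    n_pos: int = 200
    n_neg: int = 200
    length_range: tuple[int, int] = (40, 600)
    base_composition: tuple[float, ...] = field(default_factory=_uniform_composition)
    effect_residues: tuple[str, ...] = ("K", "R")
    effect_delta: float = 0.08
    homolog_groups: int = 0
    homolog_group_size: int = 4
    mutation_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (len(CANONICAL_RESIDUES),) or (comp < 0).any() or \
                not np.isclose(comp.sum(), 1.0):
            raise ValueError("base_composition must be a point on the 20-simplex")
        if not 0 <= self.effect_delta <= 0.5:
            raise ValueError("effect_delta must be in [0, 0.5]")
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length_range")
        unknown = set(self.effect_residues) - set(CANONICAL_RESIDUES)
        if unknown:
            raise ValueError(f"unknown effect residues: {sorted(unknown)}")
        if not 0 <= self.mutation_rate < 0.10:
            raise ValueError("mutation_rate must be < 10% so family members stay homologous")
        if self.homolog_groups * self.homolog_group_size > self.n_pos:
            raise ValueError("homolog families exceed the positive class size")

    def positive_composition(self) -> np.ndarray:
        """Base composition shifted by the effect mass."""
        comp = np.asarray(self.base_composition, dtype=float).copy()
        idx = [CANONICAL_RESIDUES.index(r) for r in self.effect_residues]
        others = [i for i in range(len(comp)) if i not in idx]
        other_mass = comp[others].sum()
        if self.effect_delta > other_mass:
            raise ValueError("effect_delta exceeds available probability mass")
        comp[others] -= comp[others] / other_mass * self.effect_delta
        for i in idx:
            comp[i] += self.effect_delta / len(idx)
        return comp

    def negative_composition(self) -> np.ndarray:
        return np.asarray(self.base_composition, dtype=float)


def _draw_sequence(rng: np.random.Generator, comp: np.ndarray, length: int) -> str:
    letters = rng.choice(len(CANONICAL_RESIDUES), size=length, p=comp)
    return "".join(CANONICAL_RESIDUES[i] for i in letters)


def _mutate(rng: np.random.Generator, sequence: str, rate: float) -> str:
    seq = list(sequence)
    n_mut = int(round(rate * len(seq)))
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    for pos in positions:
        current = seq[pos]
        choices = [r for r in CANONICAL_RESIDUES if r != current]
        seq[pos] = choices[rng.integers(len(choices))]
    return "".join(seq)


def generate(spec: SyntheticSpec) -> tuple[LabeledDataset, pd.DataFrame]:
    """Generate a labeled synthetic dataset and its truth table.

    Sequences are drawn i.i.d. per residue from class-specific
    compositions, lengths uniform in ``length_range``. If homolog
    families are requested, the first ``homolog_groups *
    homolog_group_size`` positives are family members: one parent per
    family plus point mutants at ``mutation_rate`` of positions. The
    truth table records id, class and family (empty for i.i.d. records).
    """
    rng = np.random.default_rng(spec.seed)
    pos_comp = spec.positive_composition()
    neg_comp = spec.negative_composition()
    lo, hi = spec.length_range
    entries: list[tuple[ProteinRecord, str]] = []
    truth_rows: list[dict[str, object]] = []

    def add(record: ProteinRecord, label: str, family: str) -> None:
        entries.append((record, label))
        truth_rows.append({"protein_id": record.id, "label": label, "family": family})

    n_family_members = spec.homolog_groups * spec.homolog_group_size
    for fam in range(spec.homolog_groups):
        length = int(rng.integers(lo, hi + 1))
        parent_seq = _draw_sequence(rng, pos_comp, length)
        family = f"fam{fam}"
        add(ProteinRecord(id=f"pos_{family}_0", sequence=parent_seq), DNA_BP, family)
        for member in range(1, spec.homolog_group_size):
            add(
                ProteinRecord(
                    id=f"pos_{family}_{member}",
                    sequence=_mutate(rng, parent_seq, spec.mutation_rate),
                ),
                DNA_BP,
                family,
            )
    for i in range(spec.n_pos - n_family_members):
        length = int(rng.integers(lo, hi + 1))
        add(
            ProteinRecord(id=f"pos_{i:05d}", sequence=_draw_sequence(rng, pos_comp, length)),
            DNA_BP,
            "",
        )
    for i in range(spec.n_neg):
        length = int(rng.integers(lo, hi + 1))
        add(
            ProteinRecord(id=f"neg_{i:05d}", sequence=_draw_sequence(rng, neg_comp, length)),
            NON_DNA_BP,
            "",
        )
    dataset = LabeledDataset(entries, provenance=f"synthetic_seed{spec.seed}", seed=spec.seed)
    return dataset, pd.DataFrame(truth_rows)


# GO terms of the miniature ontology emitted for pipeline tests.
SYNTHETIC_DNA_TERMS = ("GO:0003677", "GO:0003700", "GO:0043565")
SYNTHETIC_OTHER_TERM = "GO:0016301"  # kinase activity


def synthetic_ontology_obo() -> str:
    """A miniature molecular-function ontology in OBO 1.2 (synthetic)."""
    stanzas = [
        "format-version: 1.2\nontology: go",
        "",
        "[Term]\nid: GO:0003674\nname: molecular_function",
        "[Term]\nid: GO:0005488\nname: binding\nis_a: GO:0003674",
        "[Term]\nid: GO:0003676\nname: nucleic acid binding\nis_a: GO:0005488",
        "[Term]\nid: GO:0003677\nname: DNA binding\nis_a: GO:0003676",
        "[Term]\nid: GO:0003700\nname: DNA-binding transcription factor activity\nis_a: GO:0003674",
        "[Term]\nid: GO:0043565\nname: sequence-specific DNA binding\nis_a: GO:0003677",
        "[Term]\nid: GO:0003824\nname: catalytic activity\nis_a: GO:0003674",
        "[Term]\nid: GO:0016301\nname: kinase activity\nis_a: GO:0003824",
    ]
    return "\n\n".join(stanzas) + "\n"


def synthetic_annotations(dataset: LabeledDataset) -> pd.DataFrame:
    """Class-consistent fake GO annotations for a synthetic dataset.

    Positives receive a DNA-binding term (IDA), negatives a kinase term
    (IDA), so the ontology-driven selection stage reconstructs the true
    classes exactly.
    """
    rows = []
    for rec, label in dataset.entries:
        term = "GO:0003677" if label == DNA_BP else SYNTHETIC_OTHER_TERM
        rows.append(
            {
                "protein_id": rec.id,
                "go_term": term,
                "evidence_code": "IDA",
                "aspect": "molecular_function",
            }
        )
    return pd.DataFrame(rows)
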