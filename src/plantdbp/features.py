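"""Amino-acid composition: the classifier's single feature vector.

Each protein is represented by 20 fractions, one per canonical residue in
fixed alphabetical order (A,C,D,E,F,G,H,I,K,L,M,N,P,Q,R,S,T,V,W,Y).
Noncanonical residues (X,B,Z,J,U,O) are excluded from both numerator and
denominator, so the fractions always sum to one; records that are more
than 10% noncanonical are rejected as junk.

Composition alone ignores residue order entirely — it is permutation
invariant — which is exactly what makes it cheap enough for proteome-wide
prediction and is the deliberate alternative to evolutionary-profile
features that are unavailable for most plant species.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sequences import CANONICAL_RESIDUES, ProteinRecord
from .tables import write_tsv

#: Maximum tolerated fraction of noncanonical residues per record.
MAX_NONCANONICAL_FRACTION = 0.10

_INDEX = {res: i for i, res in enumerate(CANONICAL_RESIDUES)}


def amino_acid_composition(record: ProteinRecord) -> np.ndarray:
    """20-vector of canonical-residue fractions for one protein.

    Raises ``ValueError`` if the sequence has no canonical residue or is
    more than 10% noncanonical.
    """
    counts = Counter(record.sequence)
    n_canonical = sum(counts[r] for r in CANONICAL_RESIDUES)
    if n_canonical == 0:
        raise ValueError(f"record {record.id!r}: no canonical residues")
    n_noncanonical = len(record.sequence) - n_canonical
    # a single ambiguous residue is always tolerated; the fraction guard
    # targets junk records, not short peptides with one X
    if n_noncanonical > 1 and \
            n_noncanonical / len(record.sequence) > MAX_NONCANONICAL_FRACTION:
        raise ValueError(
            f"record {record.id!r}: {n_noncanonical} of {len(record.sequence)} "
            f"residues noncanonical (> {MAX_NONCANONICAL_FRACTION:.0%} tolerated)"
        )
    vec = np.zeros(len(CANONICAL_RESIDUES))
    for res, i in _INDEX.items():
        vec[i] = counts[res] / n_canonical
    return vec


def composition_matrix(records: Sequence[ProteinRecord]) -> pd.DataFrame:
    """Feature matrix, one row per record, columns in the fixed residue order."""
    data = np.vstack([amino_acid_composition(r) for r in records]) if records else \
        np.empty((0, len(CANONICAL_RESIDUES)))
    return pd.DataFrame(
        data,
        index=pd.Index([r.id for r in records], name="protein_id"),
        columns=list(CANONICAL_RESIDUES),
    )


def write_feature_table(
    records: Sequence[ProteinRecord], path: str | Path, metadata: dict | None = None
) -> None:
    write_tsv(composition_matrix(records).reset_index(), path, metadata)
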