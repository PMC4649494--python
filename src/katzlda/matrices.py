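"""Labeled matrix containers and their TSV serialization.

Every similarity used by the model (semantic SS, expression ES, functional
FS, Gaussian interaction-profile kernels KD/KL, integrated DS/LS) travels as
a :class:`SimilarityMatrix`: a square real matrix with an ordered identifier
list and a role tag. The prediction output is a :class:`ScoreMatrix`, the
lncRNA x disease block of the KATZ series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import StructuralError

SYMMETRY_TOL = 1e-10

#: roles whose diagonal must be exactly 1 and entries in (0, 1]
_KERNEL_ROLES = {"KD", "KL"}
_VALID_ROLES = {"SS", "ES", "FS", "KD", "KL", "DS", "LS"}


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric nonnegative labeled similarity matrix with a role tag."""

    ids: tuple[str, ...]
    values: np.ndarray
    role: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "values", values)
        n = len(self.ids)
        if values.shape != (n, n):
            raise StructuralError(
                f"{self.role}: matrix shape {values.shape} does not match {n} ids"
            )
        if self.role not in _VALID_ROLES:
            raise StructuralError(f"unknown similarity role {self.role!r}")
        if n and not np.all(np.isfinite(values)):
            raise StructuralError(f"{self.role}: non-finite entries")
        if n and np.max(np.abs(values - values.T)) > SYMMETRY_TOL:
            raise StructuralError(f"{self.role}: asymmetry exceeds {SYMMETRY_TOL}")
        if self.role in _KERNEL_ROLES and n:
            if not np.allclose(np.diag(values), 1.0, rtol=0, atol=0):
                raise StructuralError(f"{self.role}: kernel diagonal must be exactly 1")
            # raw Gaussian kernel entries lie in (0, 1]; exact zeros appear
            # only via the identity fallback for zero-degree entities
            if np.min(values) < 0 or np.max(values) > 1:
                raise StructuralError(f"{self.role}: kernel entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, entity_id: str) -> int:
        try:
            return self.ids.index(entity_id)
        except ValueError:
            raise StructuralError(f"id {entity_id!r} not in {self.role} matrix") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


@dataclass(frozen=True)
class ScoreMatrix:
    """KATZ association scores: rows are lncRNAs, columns are diseases."""

    lncrna_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "lncrna_ids", tuple(self.lncrna_ids))
        object.__setattr__(self, "disease_ids", tuple(self.disease_ids))
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.lncrna_ids), len(self.disease_ids)):
            raise StructuralError("score matrix shape does not match id lists")
        if values.size and not np.all(np.isfinite(values)):
            raise StructuralError("score matrix has non-finite entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.lncrna_ids), columns=list(self.disease_ids)
        )


def write_labeled_tsv(values: np.ndarray, ids_rows: Sequence[str],
                      ids_cols: Sequence[str], path) -> None:
    pd.DataFrame(np.asarray(values), index=list(ids_rows),
                 columns=list(ids_cols)).to_csv(path, sep="\t")


def read_labeled_tsv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str).str.strip()
    frame.columns = frame.columns.astype(str).str.strip()
    return frame
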