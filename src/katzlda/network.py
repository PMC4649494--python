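"""Known lncRNA-disease association network.

The gold-standard input is a two-column table of experimentally confirmed
(lncRNA, disease) pairs. Duplicate pairs reported with different evidences
collapse to a single association, yielding the binary adjacency matrix
``A`` of shape ``nl x nd`` on which everything else (interaction profiles,
Gaussian kernels, the KATZ walk count) is built.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import EntityNotFoundError, InputError, StructuralError, TableParseError

Side = Literal["lncrna", "disease"]


@dataclass(frozen=True)
class AssociationNetwork:
    """Binary bipartite adjacency between lncRNAs (rows) and diseases (columns)."""

    lncrna_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    adjacency: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        adjacency = np.asarray(self.adjacency)
        object.__setattr__(self, "lncrna_ids", tuple(self.lncrna_ids))
        object.__setattr__(self, "disease_ids", tuple(self.disease_ids))
        object.__setattr__(self, "adjacency", adjacency.astype(np.int8))
        if len(set(self.lncrna_ids)) != len(self.lncrna_ids):
            raise StructuralError("duplicate lncRNA identifiers")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise StructuralError("duplicate disease identifiers")
        if self.nl < 1 or self.nd < 1:
            raise StructuralError("network needs at least one lncRNA and one disease")
        if adjacency.shape != (self.nl, self.nd):
            raise StructuralError(
                f"adjacency shape {adjacency.shape} != ({self.nl}, {self.nd})"
            )
        if not np.isin(adjacency, (0, 1)).all():
            raise StructuralError("adjacency must be binary")

    @property
    def nl(self) -> int:
        return len(self.lncrna_ids)

    @property
    def nd(self) -> int:
        return len(self.disease_ids)

    @property
    def n_associations(self) -> int:
        return int(self.adjacency.sum())

    def lncrna_index(self, lncrna_id: str) -> int:
        try:
            return self.lncrna_ids.index(lncrna_id)
        except ValueError:
            raise EntityNotFoundError(f"unknown lncRNA id {lncrna_id!r}") from None

    def disease_index(self, disease_id: str) -> int:
        try:
            return self.disease_ids.index(disease_id)
        except ValueError:
            raise EntityNotFoundError(f"unknown disease id {disease_id!r}") from None

    def known_pairs(self) -> list[tuple[str, str]]:
        rows, cols = np.nonzero(self.adjacency)
        return [(self.lncrna_ids[i], self.disease_ids[j]) for i, j in zip(rows, cols)]

    def with_masked(self, pairs: Iterable[tuple[str, str]]) -> "AssociationNetwork":
        """Copy of the network with the given known pairs set to 0 (CV masking)."""
        adjacency = self.adjacency.copy()
        for lncrna_id, disease_id in pairs:
            i, j = self.lncrna_index(lncrna_id), self.disease_index(disease_id)
            adjacency[i, j] = 0
        return AssociationNetwork(self.lncrna_ids, self.disease_ids, adjacency)


@dataclass(frozen=True)
class InteractionProfile:
    """Binary vector of an entity's known partners: a row or column of A."""

    entity_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values).astype(np.int8)
        object.__setattr__(self, "values", values)
        if not np.isin(values, (0, 1)).all():
            raise StructuralError("interaction profile must be binary")


def _normalize(token: str, case_insensitive: bool) -> str:
    token = token.strip()
    return token.lower() if case_insensitive else token


def load_associations(path, *, case_insensitive: bool = False) -> AssociationNetwork:
    """Read a (lncRNA, disease[, evidence...]) table into an AssociationNetwork.

    Duplicate pairs (same association backed by different evidences) collapse
    to a single 1 in the adjacency. Identifiers are whitespace-trimmed and by
    default matched case-sensitively; ids are sorted lexicographically so the
    matrix layout is independent of input row order.
    """
    text = Path(path).read_text(encoding="utf-8")
    pairs = parse_association_rows(text.splitlines(), case_insensitive=case_insensitive)
    return network_from_pairs(pairs)


def parse_association_rows(lines: Iterable[str], *,
                           case_insensitive: bool = False) -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    for lineno, raw in enumerate(lines, start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise TableParseError(
                f"line {lineno}: expected at least lncrna_id<TAB>disease_id, got {raw!r}"
            )
        lncrna = _normalize(fields[0], case_insensitive)
        disease = _normalize(fields[1], case_insensitive)
        # header detection: a literal column-name first row is not data
        if lineno == 1 and lncrna.lower() in {"lncrna", "lncrna_id"} \
                and disease.lower() in {"disease", "disease_id"}:
            continue
        pairs.append((lncrna, disease))
    if not pairs:
        raise InputError("association table contains no data rows")
    return pairs


def network_from_pairs(pairs: Iterable[tuple[str, str]]) -> AssociationNetwork:
    pairs = list(pairs)
    if not pairs:
        raise InputError("no association pairs given")
    lncrna_ids = tuple(sorted({l for l, _ in pairs}))
    disease_ids = tuple(sorted({d for _, d in pairs}))
    lncrna_pos = {l: i for i, l in enumerate(lncrna_ids)}
    disease_pos = {d: j for j, d in enumerate(disease_ids)}
    adjacency = np.zeros((len(lncrna_ids), len(disease_ids)), dtype=np.int8)
    for lncrna, disease in pairs:
        adjacency[lncrna_pos[lncrna], disease_pos[disease]] = 1
    return AssociationNetwork(lncrna_ids, disease_ids, adjacency)


def save_associations(net: AssociationNetwork, path) -> None:
    """Write the known pairs back to the two-column TSV format."""
    with io.open(path, "w", encoding="utf-8") as handle:
        handle.write("lncrna_id\tdisease_id\n")
        for lncrna_id, disease_id in net.known_pairs():
            handle.write(f"{lncrna_id}\t{disease_id}\n")


def interaction_profile(net: AssociationNetwork, entity_id: str,
                        side: Side) -> InteractionProfile:
    """Exact row (lncRNA) or column (disease) of the adjacency matrix."""
    if side == "lncrna":
        return InteractionProfile(entity_id, net.adjacency[net.lncrna_index(entity_id)])
    if side == "disease":
        return InteractionProfile(entity_id, net.adjacency[:, net.disease_index(entity_id)])
    raise ValueError(f"side must be 'lncrna' or 'disease', got {side!r}")


def association_stats(net: AssociationNetwork) -> dict[str, float]:
    """Average number of known partners per disease and per lncRNA."""
    ones = float(net.adjacency.sum())
    return {
        "mean_lncrnas_per_disease": ones / net.nd,
        "mean_diseases_per_lncrna": ones / net.nl,
    }


def to_frame(net: AssociationNetwork) -> pd.DataFrame:
    return pd.DataFrame(net.adjacency, index=list(net.lncrna_ids),
                        columns=list(net.disease_ids))
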