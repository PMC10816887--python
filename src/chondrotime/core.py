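"""Shared domain types and validation for the time-course multi-omics pipeline.

The containers here are thin, validated wrappers around pandas / numpy /
networkx objects.  Each wrapper enforces the invariants the downstream
stages rely on (no duplicate identifiers, finite non-negative abundances,
an explicit timepoint order) and fails loudly, naming the offending record,
rather than coercing silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "SampleDesign",
    "ExpressionMatrix",
    "MetaboliteTable",
    "TfAnnotation",
    "PwmLibrary",
    "PromoterSet",
    "InteractionNetwork",
    "GeneSetCollection",
    "PathwayMap",
]

PROMOTER_ALPHABET = set("ACGTN")
BASES = "ACGT"


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass(frozen=True)
class SampleDesign:
    """Binds sample ids to an ordered timepoint label and a replicate index.

    Timepoint order is the order of first appearance in the design table
    (never lexicographic: ``D12`` must sort after ``D4``).
    """

    table: pd.DataFrame  # index: sample ids; columns: timepoint, replicate

    def __post_init__(self) -> None:
        t = self.table
        if list(t.columns[:2]) != ["timepoint", "replicate"]:
            raise ValidationError(
                "design table must have columns ['timepoint', 'replicate']"
            )
        _check_unique(list(t.index), "sample")
        if (t["replicate"].astype(int) < 1).any():
            bad = t.index[t["replicate"].astype(int) < 1][0]
            raise ValidationError(f"replicate index < 1 for sample {bad!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def timepoints(self) -> list[str]:
        """Timepoint labels in declared (temporal) order."""
        seen: dict[str, None] = {}
        for tp in self.table["timepoint"]:
            seen.setdefault(tp, None)
        return list(seen)

    def samples_at(self, timepoint: str) -> list[str]:
        mask = self.table["timepoint"] == timepoint
        if not mask.any():
            raise KeyError(f"unknown timepoint {timepoint!r}")
        return list(self.table.index[mask])

    def timepoint_of(self, sample: str) -> str:
        return str(self.table.loc[sample, "timepoint"])


def _validate_abundance(values: pd.DataFrame, design: SampleDesign, what: str) -> None:
    _check_unique(list(values.index), f"{what}")
    _check_unique(list(values.columns), "sample")
    missing = [s for s in values.columns if s not in set(design.sample_ids)]
    if missing:
        raise ValidationError(
            f"sample {missing[0]!r} in {what} table absent from design"
        )
    arr = values.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        i, j = np.argwhere(~np.isfinite(arr))[0]
        raise ValidationError(
            f"non-finite value at ({values.index[i]!r}, {values.columns[j]!r})"
        )
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValidationError(
            f"negative value at ({values.index[i]!r}, {values.columns[j]!r})"
        )


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples non-negative abundance grid bound to a `SampleDesign`."""

    values: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        _validate_abundance(self.values, self.design, "gene")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class MetaboliteTable:
    """Metabolites x samples concentration grid bound to a `SampleDesign`."""

    values: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        _validate_abundance(self.values, self.design, "metabolite")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class TfAnnotation:
    """gene id -> TF family; genes absent from the mapping are not TFs."""

    family_of: Mapping[str, str]

    def is_tf(self, gene: str) -> bool:
        return gene in self.family_of

    @property
    def families(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for g, fam in self.family_of.items():
            out.setdefault(fam, set()).add(g)
        return out


@dataclass(frozen=True)
class PwmLibrary:
    """Per-motif position probability matrices (rows A,C,G,T) + background."""

    motifs: Mapping[str, np.ndarray]  # 4 x width, columns sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )  # A,C,G,T frequencies

    def __post_init__(self) -> None:
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or (bg <= 0).any() or abs(bg.sum() - 1) > 1e-9:
            raise ValidationError("background must be 4 strictly-positive freqs summing to 1")
        for mid, m in self.motifs.items():
            m = np.asarray(m, dtype=float)
            if m.ndim != 2 or m.shape[0] != 4 or m.shape[1] < 1:
                raise ValidationError(f"motif {mid!r}: matrix must be 4 x width>=1")
            colsums = m.sum(axis=0)
            if np.abs(colsums - 1).max() > 1e-9:
                j = int(np.abs(colsums - 1).argmax())
                raise ValidationError(
                    f"motif {mid!r}: column {j} sums to {colsums[j]:.6g}, not 1"
                )

    def width(self, motif_id: str) -> int:
        return int(np.asarray(self.motifs[motif_id]).shape[1])


@dataclass(frozen=True)
class PromoterSet:
    """gene id -> upstream promoter sequence over ACGTN (nominally 1 kb)."""

    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        for gid, seq in self.sequences.items():
            if not seq:
                raise ValidationError(f"promoter for {gid!r} is empty")
            bad = set(seq.upper()) - PROMOTER_ALPHABET
            if bad:
                raise ValidationError(
                    f"promoter for {gid!r} contains invalid characters {sorted(bad)}"
                )


@dataclass(frozen=True)
class InteractionNetwork:
    """Undirected interaction graph; edges deduplicated irrespective of orientation."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValidationError(f"self-loop on node {loops[0][0]!r}")

    @classmethod
    def from_edges(
        cls, edges: Sequence[tuple[str, str]] | Sequence[tuple[str, str, float]]
    ) -> "InteractionNetwork":
        g = nx.Graph()
        for e in edges:
            a, b = e[0], e[1]
            if a == b:
                raise ValidationError(f"self-loop on node {a!r}")
            w = float(e[2]) if len(e) > 2 else None
            if w is not None:
                if not 0.0 <= w <= 1.0:
                    raise ValidationError(f"edge ({a!r},{b!r}) weight {w} outside [0,1]")
                g.add_edge(a, b, weight=w)
            else:
                g.add_edge(a, b)
        return cls(g)

    def neighbors(self, node: str) -> set[str]:
        if node not in self.graph:
            return set()
        return set(self.graph.neighbors(node))


@dataclass(frozen=True)
class GeneSetCollection:
    """set id -> (description, member gene ids); members deduplicated, non-empty."""

    sets: Mapping[str, tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        for sid, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {sid!r} has no members")
            _check_unique(members, f"member of set {sid!r}")

    def members(self, set_id: str) -> tuple[str, ...]:
        return self.sets[set_id][1]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class PathwayMap:
    """pathway id -> (gene members, metabolite members)."""

    pathways: Mapping[str, tuple[tuple[str, ...], tuple[str, ...]]]

    def __post_init__(self) -> None:
        for pid, (genes, mets) in self.pathways.items():
            if not genes and not mets:
                raise ValidationError(f"pathway {pid!r} has no members of either kind")

    def genes(self, pathway_id: str) -> tuple[str, ...]:
        return self.pathways[pathway_id][0]

    def metabolites(self, pathway_id: str) -> tuple[str, ...]:
        return self.pathways[pathway_id][1]
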