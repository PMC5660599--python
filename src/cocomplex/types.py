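"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Expression matrices are genes x samples; missing values are ``NaN``.
* Gene and sample identifiers are opaque strings.  Mapping to a canonical
  namespace (e.g. ENTREZ) is the caller's responsibility.
* Interaction networks are simple undirected graphs without self-loops.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: closed vocabulary of mutation classes
MUTATION_CLASSES = (
    "missense",
    "splice_site",
    "insertion",
    "deletion",
    "nonsense",
    "synonymous",
    "other",
)

#: mutation classes that count as a (protein-affecting) mutation event
DAMAGING_MUTATION_CLASSES = frozenset(
    {"missense", "splice_site", "insertion", "deletion", "nonsense"}
)

#: allowed discretized copy-number calls (GISTIC-style)
COPY_NUMBER_CALLS = frozenset({-2, -1, 0, 1, 2})


class ParseError(ValueError):
    """Raised when an input file violates its documented dialect."""


@dataclass
class ExpressionMatrix:
    """A genes x samples real matrix with missing entries encoded as NaN.

    Duplicate row (gene) identifiers are permitted so that multiple protein
    isoforms of the same gene can coexist before isoform collapsing; sample
    identifiers must be unique.
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique()
            raise ParseError(f"duplicate sample identifiers: {list(dupes)!r}")
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def missing_fraction(self) -> pd.Series:
        """Per-gene fraction of missing samples."""
        return self.data.isna().mean(axis=1)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), dict(self.meta))


class InteractionNetwork:
    """Undirected simple graph over gene identifiers.

    Self-loops are rejected; duplicate edges (in either orientation) collapse
    to a single edge.  Each edge may carry a non-negative ``score`` attribute
    (the shared-partner score, see :mod:`cocomplex.network`).
    """

    def __init__(self, edges: Iterable[tuple[str, str]] = (), nodes: Iterable[str] = ()):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            g.add_edge(a, b)
        self.graph = g

    @classmethod
    def from_graph(cls, graph: nx.Graph) -> "InteractionNetwork":
        net = cls.__new__(cls)
        if any(u == v for u, v in graph.edges):
            raise ValueError("interaction network must not contain self-loops")
        net.graph = graph
        return net

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def neighbors(self, node: str) -> set[str]:
        return set(self.graph.neighbors(node))

    def edge_score(self, a: str, b: str) -> float | None:
        if not self.graph.has_edge(a, b):
            return None
        return self.graph.edges[a, b].get("score")

    @property
    def edge_scores(self) -> dict[tuple[str, str], float]:
        return {
            tuple(sorted((u, v))): d["score"]
            for u, v, d in self.graph.edges(data=True)
            if "score" in d
        }


@dataclass(frozen=True)
class Complex:
    """A named set of member genes with an optional score decomposition."""

    name: str
    members: frozenset[str]
    llr_expr: float | None = None
    llr_int: float | None = None

    @property
    def llr_integrated(self) -> float | None:
        if self.llr_expr is None or self.llr_int is None:
            return None
        return self.llr_expr + self.llr_int

    @property
    def size(self) -> int:
        return len(self.members)


class ComplexSet:
    """A collection of named gene sets.

    Used both for discovered complexes (disjoint by construction) and for
    reference catalogues (where genes may belong to several complexes).
    """

    def __init__(self, complexes: Iterable[Complex], disjoint: bool = False):
        self.complexes: list[Complex] = list(complexes)
        self.disjoint = disjoint
        names = [c.name for c in self.complexes]
        if len(set(names)) != len(names):
            raise ValueError("complex names must be unique")
        for c in self.complexes:
            if not c.members:
                raise ValueError(f"complex {c.name!r} has no members")
        if disjoint:
            seen: set[str] = set()
            for c in self.complexes:
                overlap = seen & c.members
                if overlap:
                    raise ValueError(
                        f"disjoint ComplexSet has shared genes: {sorted(overlap)!r}"
                    )
                seen |= c.members

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self) -> Iterator[Complex]:
        return iter(self.complexes)

    def __getitem__(self, name: str) -> Complex:
        for c in self.complexes:
            if c.name == name:
                return c
        raise KeyError(name)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for c in self.complexes:
            out |= c.members
        return out

    def member_sets(self) -> list[frozenset[str]]:
        return [c.members for c in self.complexes]

    def co_annotated_pairs(self, max_size: int | None = None) -> set[frozenset[str]]:
        """All unordered gene pairs co-annotated in some complex.

        ``max_size`` restricts to complexes with at most that many members
        (used to keep very large assemblies out of training sets).
        """
        pairs: set[frozenset[str]] = set()
        for c in self.complexes:
            if max_size is not None and len(c.members) > max_size:
                continue
            members = sorted(c.members)
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    pairs.add(frozenset((a, b)))
        return pairs


@dataclass
class CopyNumberMatrix:
    """Genes x samples matrix of discretized copy-number calls in {-2..2}."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.columns.has_duplicates or self.data.index.has_duplicates:
            raise ParseError("copy-number matrix has duplicate gene or sample IDs")
        values = self.data.to_numpy()
        bad = ~np.isin(values, sorted(COPY_NUMBER_CALLS))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ParseError(
                f"copy-number call {values[i, j]!r} for gene "
                f"{self.data.index[i]!r} sample {self.data.columns[j]!r} "
                "outside {-2,-1,0,1,2}"
            )
        self.data = self.data.astype(int)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class MutationTable:
    """Long-form table of (sample_id, gene_id, mutation_class) records."""

    records: pd.DataFrame  # columns: sample_id, gene_id, mutation_class

    def __post_init__(self) -> None:
        required = {"sample_id", "gene_id", "mutation_class"}
        missing = required - set(self.records.columns)
        if missing:
            raise ParseError(f"mutation table lacks columns {sorted(missing)!r}")
        bad = ~self.records["mutation_class"].isin(MUTATION_CLASSES)
        if bad.any():
            raise ParseError(
                "mutation_class outside closed vocabulary: "
                f"{sorted(self.records.loc[bad, 'mutation_class'].unique())!r}"
            )

    @property
    def samples(self) -> set[str]:
        return set(self.records["sample_id"])

    def damaging(self) -> pd.DataFrame:
        """Records whose class counts as a protein-affecting mutation."""
        keep = self.records["mutation_class"].isin(DAMAGING_MUTATION_CLASSES)
        return self.records.loc[keep]


@dataclass
class SampleAnnotation:
    """Per-sample subtype label plus optional extra covariates."""

    data: pd.DataFrame  # index: sample_id; column 'subtype' required

    def __post_init__(self) -> None:
        if "subtype" not in self.data.columns:
            raise ParseError("sample annotation requires a 'subtype' column")
        if self.data.index.has_duplicates:
            raise ParseError("duplicate sample IDs in annotation")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def subtypes(self) -> pd.Series:
        return self.data["subtype"]

    def labels(self) -> list[str]:
        return sorted(self.data["subtype"].unique())


class ChromosomeMap(dict):
    """gene_id -> chromosome label (one chromosome per gene)."""

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "ChromosomeMap":
        return cls(mapping)

    def same_chromosome(self, a: str, b: str) -> bool:
        ca, cb = self.get(a), self.get(b)
        return ca is not None and ca == cb
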