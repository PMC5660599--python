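"""Readers and writers for the plain-text dialects the pipeline consumes.

Dialects
--------
expression matrix
    TSV; first column gene IDs, header row sample IDs.  Empty cells or a
    configurable token (default ``NA``) denote missing values.
edge list
    Two tab-separated gene IDs per line; an optional third column is ignored.
    Self-loops are dropped (counted in the log); duplicate edges collapse.
GMT gene sets
    ``name <tab> description <tab> member...``.  Per-complex scores are
    stored in the description field as ``key=value`` pairs separated by
    semicolons, keeping the file valid GMT.
copy-number matrix
    TSV like the expression matrix but with integer calls in {-2..2}.
mutation table (MAF-lite)
    TSV with header ``sample_id  gene_id  mutation_class``; common MAF
    variant-classification spellings are normalized via an alias map and
    unknown classes map to ``other`` with a warning.
sample annotation
    TSV with header ``sample_id  subtype [extra columns...]``.
chromosome map
    Two columns: ``gene_id  chromosome``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .types import (
    ChromosomeMap,
    Complex,
    ComplexSet,
    CopyNumberMatrix,
    ExpressionMatrix,
    InteractionNetwork,
    MutationTable,
    MUTATION_CLASSES,
    ParseError,
    SampleAnnotation,
)

logger = logging.getLogger(__name__)

DEFAULT_MISSING_TOKENS = ("", "NA")

#: spellings of mutation classes seen in MAF-style exports
MUTATION_CLASS_ALIASES = {
    "missense": "missense",
    "missense_mutation": "missense",
    "splice_site": "splice_site",
    "splice_site_mutation": "splice_site",
    "splice_region": "splice_site",
    "insertion": "insertion",
    "frame_shift_ins": "insertion",
    "in_frame_ins": "insertion",
    "ins": "insertion",
    "deletion": "deletion",
    "frame_shift_del": "deletion",
    "in_frame_del": "deletion",
    "del": "deletion",
    "nonsense": "nonsense",
    "nonsense_mutation": "nonsense",
    "stop_gained": "nonsense",
    "synonymous": "synonymous",
    "silent": "synonymous",
    "synonymous_variant": "synonymous",
}


def _check_matrix_header(path: Path, sep: str = "\t") -> None:
    """Fail early on a ragged table (naming the line) or duplicate sample IDs
    in the header (pandas would silently mangle them)."""
    with open(path) as fh:
        header = fh.readline()
        if not header:
            raise ParseError(f"{path}: empty file")
        samples = header.rstrip("\n").split(sep)[1:]
        if len(set(samples)) != len(samples):
            dupes = sorted({s for s in samples if samples.count(s) > 1})
            raise ParseError(f"{path}: duplicate sample identifiers {dupes!r}")
        width = header.rstrip("\n").count(sep)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            if line.rstrip("\n").count(sep) != width:
                raise ParseError(f"{path}: ragged row at line {lineno}")


def read_expression_matrix(
    path: str | Path,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
) -> ExpressionMatrix:
    """Read a genes x samples TSV matrix; see module docstring for dialect."""
    path = Path(path)
    _check_matrix_header(path)
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=list(missing_tokens),
        keep_default_na=False,
    )
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, meta={"source": str(path)})


def write_expression_matrix(em: ExpressionMatrix, path: str | Path) -> None:
    df = em.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def read_network(path: str | Path) -> InteractionNetwork:
    """Read a 2-column TSV edge list (extra columns ignored)."""
    path = Path(path)
    edges = []
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}: line {lineno} has fewer than 2 fields")
            a, b = fields[0], fields[1]
            if a == b:
                n_self += 1
                continue
            edges.append((a, b))
    if n_self:
        logger.info("dropped %d self-loop(s) while reading %s", n_self, path)
    return InteractionNetwork(edges)


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(net.edges):
            score = net.edge_score(a, b)
            if score is None:
                fh.write(f"{a}\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\t{score:.6g}\n")


def _format_scores(c: Complex) -> str:
    if c.llr_expr is None or c.llr_int is None:
        return "na"
    return (
        f"llr_expr={c.llr_expr:.10g};llr_int={c.llr_int:.10g};"
        f"llr_integrated={c.llr_integrated:.10g}"
    )


def _parse_scores(desc: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for token in desc.split(";"):
        if "=" in token:
            key, _, value = token.partition("=")
            try:
                out[key.strip()] = float(value)
            except ValueError:
                continue
    return out


def read_gmt(path: str | Path, disjoint: bool = False) -> ComplexSet:
    """Read a GMT gene-set file into a :class:`ComplexSet` (file order kept)."""
    path = Path(path)
    complexes: list[Complex] = []
    names: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno} has fewer than 3 fields (name, "
                    "description, members...)"
                )
            name, desc = fields[0], fields[1]
            if name in names:
                raise ParseError(f"{path}: duplicate complex name {name!r}")
            names.add(name)
            members = frozenset(m for m in fields[2:] if m)
            scores = _parse_scores(desc)
            complexes.append(
                Complex(
                    name,
                    members,
                    llr_expr=scores.get("llr_expr"),
                    llr_int=scores.get("llr_int"),
                )
            )
    return ComplexSet(complexes, disjoint=disjoint)


def write_complexes(cs: ComplexSet, path: str | Path) -> None:
    """Write a :class:`ComplexSet` as GMT; scores go in the description."""
    with open(path, "w") as fh:
        for c in cs:
            members = "\t".join(sorted(c.members))
            fh.write(f"{c.name}\t{_format_scores(c)}\t{members}\n")


def read_copy_number(path: str | Path) -> CopyNumberMatrix:
    path = Path(path)
    _check_matrix_header(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    values = df.to_numpy()
    if not np.isfinite(values).all() or not (values == values.astype(int)).all():
        raise ParseError(f"{path}: non-integer copy-number entry")
    return CopyNumberMatrix(df.astype(int))


def write_copy_number(cnv: CopyNumberMatrix, path: str | Path) -> None:
    df = cnv.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_mutations(path: str | Path) -> MutationTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "gene_id", "mutation_class"}
    if not required <= set(df.columns):
        raise ParseError(
            f"{path}: mutation table needs columns {sorted(required)!r}"
        )
    normalized = []
    unknown: set[str] = set()
    for raw in df["mutation_class"]:
        key = str(raw).strip().lower()
        cls = MUTATION_CLASS_ALIASES.get(key)
        if cls is None:
            cls = key if key in MUTATION_CLASSES else "other"
            if cls == "other" and key != "other":
                unknown.add(str(raw))
        normalized.append(cls)
    if unknown:
        logger.warning(
            "%s: unknown mutation classes mapped to 'other': %s",
            path,
            sorted(unknown),
        )
    out = df[["sample_id", "gene_id"]].copy()
    out["mutation_class"] = normalized
    out = out.astype(object)  # stable dtypes even for an empty table
    return MutationTable(out)


def write_mutations(mt: MutationTable, path: str | Path) -> None:
    mt.records.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> SampleAnnotation:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: annotation table needs a 'sample_id' column")
    df = df.set_index("sample_id")
    return SampleAnnotation(df)


def write_annotations(ann: SampleAnnotation, path: str | Path) -> None:
    df = ann.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_chromosomes(path: str | Path) -> ChromosomeMap:
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()  # gene_id <tab> chromosome
        if header and "\t" not in header:
            raise ParseError(f"{path}: expected 2 tab-separated columns")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}: line {lineno} has fewer than 2 fields")
            gene, chrom = fields[0], fields[1]
            if gene in mapping and mapping[gene] != chrom:
                raise ParseError(
                    f"{path}: gene {gene!r} mapped to two chromosomes"
                )
            mapping[gene] = chrom
    return ChromosomeMap(mapping)


def write_chromosomes(cm: ChromosomeMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchromosome\n")
        for gene in sorted(cm):
            fh.write(f"{gene}\t{cm[gene]}\n")


def write_association_table(
    table: pd.DataFrame, path: str | Path, metadata: dict | None = None
) -> None:
    """Write an association table as TSV with a '#'-prefixed metadata header."""
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        table.to_csv(fh, sep="\t", index=False)
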