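"""Synthetic tumor-proteome test bed with planted, verifiable structure.

The generator emulates the statistical regularities the discovery method
relies on, without attempting to be a realistic mass-spectrometry noise
model:

* each planted complex draws a latent per-sample factor f_c ~ N(0, 1); a
  member's expression is a*f_c + eps with unit-variance noise and loading
  a = sqrt(r / (1 - r)), which yields exchangeable within-complex pairwise
  correlation exactly r;
* planted complexes are densely connected (each within pair is an edge with
  probability ``p_edge_within``) on top of a uniform background edge set;
* missingness is completely at random, at a per-gene rate drawn uniformly
  from a configured range (protein matrix only);
* a subtype shift adds delta (in units of the gene's marginal SD) to member
  means in the designated subtype;
* a collateral event depresses the altered gene by delta_gene SD and its
  complex partners by delta_partners SD in the altered samples of the
  *protein* matrix; in the matched mRNA matrix only the altered gene is
  depressed, reproducing the post-transcriptional signature;
* decoy sets are planted as negative controls: correlated-only sets (a
  latent factor but no planted edges) and clique-only sets (a full clique
  with independent expression).

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

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
    SampleAnnotation,
)


@dataclass(frozen=True)
class CollateralEvent:
    """A planted mutation/deletion of one subunit with a trans effect.

    ``kind`` controls how the event is emitted: ``mutation`` adds missense
    records to the mutation table, ``homozygous``/``hemizygous`` set the
    GISTIC-style call (-2 / -1) in the copy-number matrix.
    """

    complex_index: int
    member_index: int = 0
    fraction_altered: float = 0.15
    delta_gene: float = 1.5
    delta_partners: float = 0.8
    kind: str = "mutation"


@dataclass(frozen=True)
class SubtypeShift:
    complex_index: int
    subtype_index: int
    delta: float  # in units of the member gene's marginal SD


@dataclass
class SimulationConfig:
    n_genes: int = 1000
    n_samples: int = 60
    n_complexes: int = 25
    complex_size_range: tuple[int, int] = (3, 12)
    within_complex_r: float = 0.7
    p_edge_within: float = 0.9
    n_background_edges: int = 2000
    missing_rate_range: tuple[float, float] = (0.0, 0.3)
    n_subtypes: int = 3
    subtype_shifts: tuple[SubtypeShift, ...] = ()
    collateral_events: tuple[CollateralEvent, ...] = ()
    n_correlated_decoys: int = 0
    n_clique_decoys: int = 0
    decoy_size: int = 6
    n_chromosomes: int = 23
    same_chromosome_complex_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.complex_size_range
        if lo < 2:
            raise ValueError("complex sizes must be >= 2")
        if not 0.0 <= self.within_complex_r < 1.0:
            raise ValueError("within_complex_r must be in [0, 1)")
        for p in (self.p_edge_within, self.same_chromosome_complex_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be within [0, 1]")
        for ev in self.collateral_events:
            if not 0 <= ev.complex_index < self.n_complexes:
                raise ValueError("collateral event references a missing complex")


@dataclass
class GroundTruth:
    planted: ComplexSet
    correlated_decoys: list[frozenset[str]]
    clique_decoys: list[frozenset[str]]
    subtype_shifts: pd.DataFrame  # complex, subtype, delta
    collateral_events: pd.DataFrame  # gene, complex, kind, deltas, n_altered

    def to_json(self, path: str | Path) -> None:
        doc = {
            "planted": {c.name: sorted(c.members) for c in self.planted},
            "correlated_decoys": [sorted(d) for d in self.correlated_decoys],
            "clique_decoys": [sorted(d) for d in self.clique_decoys],
            "subtype_shifts": self.subtype_shifts.to_dict(orient="records"),
            "collateral_events": self.collateral_events.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(doc, indent=2))


@dataclass
class SimulatedData:
    protein: ExpressionMatrix
    mrna: ExpressionMatrix
    network: InteractionNetwork
    annotations: SampleAnnotation
    mutations: MutationTable
    copy_number: CopyNumberMatrix
    chromosomes: ChromosomeMap
    truth: GroundTruth
    config: SimulationConfig


def _factor_loading(r: float) -> float:
    # one-factor model: corr = a^2 / (a^2 + 1)  =>  a^2 = r / (1 - r)
    return float(np.sqrt(r / (1.0 - r)))


def generate(config: SimulationConfig) -> SimulatedData:
    """Generate the full set of pipeline inputs plus ground truth."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.complex_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_complexes)
    n_decoy_genes = (config.n_correlated_decoys + config.n_clique_decoys) * config.decoy_size
    if sizes.sum() + n_decoy_genes > config.n_genes:
        raise ValueError(
            "infeasible config: planted complexes and decoys exceed the gene budget"
        )
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    samples = [f"S{j + 1:04d}" for j in range(config.n_samples)]

    # --- partition genes: planted complexes, then decoys, rest background
    cursor = 0
    planted_members: list[list[str]] = []
    for size in sizes:
        planted_members.append(genes[cursor:cursor + size])
        cursor += int(size)
    correlated_decoys: list[list[str]] = []
    for _ in range(config.n_correlated_decoys):
        correlated_decoys.append(genes[cursor:cursor + config.decoy_size])
        cursor += config.decoy_size
    clique_decoys: list[list[str]] = []
    for _ in range(config.n_clique_decoys):
        clique_decoys.append(genes[cursor:cursor + config.decoy_size])
        cursor += config.decoy_size

    gene_index = {g: i for i, g in enumerate(genes)}
    n, m = config.n_genes, config.n_samples
    a = _factor_loading(config.within_complex_r)
    gene_sd = np.ones(n)

    # --- expression: latent one-factor blocks on an independent background
    protein = rng.standard_normal((n, m))
    mrna = rng.standard_normal((n, m))
    factor_groups = planted_members + correlated_decoys
    for members in factor_groups:
        f = rng.standard_normal(m)
        idx = [gene_index[g] for g in members]
        protein[idx] = a * f + protein[idx]
        mrna[idx] = a * f + mrna[idx]
        gene_sd[idx] = np.sqrt(a * a + 1.0)

    # --- subtypes
    subtype_labels = [f"subtype{k + 1}" for k in range(config.n_subtypes)]
    assignment = [subtype_labels[j % config.n_subtypes] for j in range(m)]
    shift_rows = []
    for shift in config.subtype_shifts:
        members = planted_members[shift.complex_index]
        idx = [gene_index[g] for g in members]
        cols = [j for j, s in enumerate(assignment) if s == subtype_labels[shift.subtype_index]]
        delta = shift.delta * gene_sd[idx][:, None]
        protein[np.ix_(idx, cols)] += delta
        mrna[np.ix_(idx, cols)] += delta
        shift_rows.append(
            {
                "complex": f"PC{shift.complex_index + 1:03d}",
                "subtype": subtype_labels[shift.subtype_index],
                "delta": shift.delta,
            }
        )

    # --- collateral events; trans effect in the protein matrix only
    cnv = np.zeros((n, m), dtype=int)
    mutation_rows = []
    event_rows = []
    for ev in config.collateral_events:
        members = planted_members[ev.complex_index]
        gene = members[ev.member_index % len(members)]
        gi = gene_index[gene]
        n_alt = max(1, int(round(ev.fraction_altered * m)))
        altered_cols = np.sort(rng.choice(m, size=n_alt, replace=False))
        protein[gi, altered_cols] -= ev.delta_gene * gene_sd[gi]
        mrna[gi, altered_cols] -= ev.delta_gene * gene_sd[gi]
        partners = [gene_index[g] for g in members if g != gene]
        protein[np.ix_(partners, altered_cols)] -= (
            ev.delta_partners * gene_sd[partners][:, None]
        )
        if ev.kind == "mutation":
            for j in altered_cols:
                mutation_rows.append(
                    {"sample_id": samples[j], "gene_id": gene, "mutation_class": "missense"}
                )
        elif ev.kind == "homozygous":
            cnv[gi, altered_cols] = -2
        elif ev.kind == "hemizygous":
            cnv[gi, altered_cols] = -1
        else:
            raise ValueError(f"unknown collateral event kind {ev.kind!r}")
        event_rows.append(
            {
                "gene": gene,
                "complex": f"PC{ev.complex_index + 1:03d}",
                "kind": ev.kind,
                "n_altered": int(n_alt),
                "delta_gene": ev.delta_gene,
                "delta_partners": ev.delta_partners,
            }
        )

    # --- missingness (protein matrix only), completely at random per gene
    rate_lo, rate_hi = config.missing_rate_range
    rates = rng.uniform(rate_lo, rate_hi, size=n)
    mask = rng.random((n, m)) < rates[:, None]
    protein = protein.astype(float)
    protein[mask] = np.nan

    # --- interaction network
    edges: set[tuple[str, str]] = set()
    for members in planted_members:
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < config.p_edge_within:
                    edges.add((members[i], members[j]))
    for decoy in clique_decoys:
        for i in range(len(decoy)):
            for j in range(i + 1, len(decoy)):
                edges.add((decoy[i], decoy[j]))
    planted_pair_block: set[frozenset[str]] = set()
    for members in planted_members + clique_decoys:
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                planted_pair_block.add(frozenset((members[i], members[j])))
    n_bg = 0
    attempts = 0
    while n_bg < config.n_background_edges and attempts < 100 * config.n_background_edges:
        attempts += 1
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        pair = (genes[min(i, j)], genes[max(i, j)])
        if frozenset(pair) in planted_pair_block or pair in edges:
            continue
        edges.add(pair)
        n_bg += 1
    network = InteractionNetwork(sorted(edges), nodes=genes)

    # --- chromosomes
    chroms = [f"chr{k + 1}" for k in range(config.n_chromosomes)]
    chrom_of = {g: chroms[int(rng.integers(0, config.n_chromosomes))] for g in genes}
    for ci, members in enumerate(planted_members):
        if rng.random() < config.same_chromosome_complex_rate:
            shared = chroms[int(rng.integers(0, config.n_chromosomes))]
            for g in members:
                chrom_of[g] = shared

    planted_set = ComplexSet(
        [
            Complex(f"PC{ci + 1:03d}", frozenset(members))
            for ci, members in enumerate(planted_members)
        ],
        disjoint=True,
    )
    truth = GroundTruth(
        planted=planted_set,
        correlated_decoys=[frozenset(d) for d in correlated_decoys],
        clique_decoys=[frozenset(d) for d in clique_decoys],
        subtype_shifts=pd.DataFrame(shift_rows, columns=["complex", "subtype", "delta"]),
        collateral_events=pd.DataFrame(
            event_rows,
            columns=["gene", "complex", "kind", "n_altered", "delta_gene", "delta_partners"],
        ),
    )
    return SimulatedData(
        protein=ExpressionMatrix(pd.DataFrame(protein, index=genes, columns=samples)),
        mrna=ExpressionMatrix(pd.DataFrame(mrna, index=genes, columns=samples)),
        network=network,
        annotations=SampleAnnotation(
            pd.DataFrame({"subtype": assignment}, index=pd.Index(samples, name="sample_id"))
        ),
        mutations=MutationTable(
            pd.DataFrame(mutation_rows, columns=["sample_id", "gene_id", "mutation_class"])
        ),
        copy_number=CopyNumberMatrix(pd.DataFrame(cnv, index=genes, columns=samples)),
        chromosomes=ChromosomeMap(chrom_of),
        truth=truth,
        config=config,
    )


def perturb_reference(
    planted: ComplexSet,
    gene_pool: Sequence[str],
    drop_frac: float = 0.2,
    add_frac: float = 0.2,
    seed: int = 0,
) -> ComplexSet:
    """A deliberately imperfect reference catalogue for LLR calibration.

    Emulates incomplete curation: a fraction of each planted complex's
    members is dropped (keeping at least two) and a fraction of random
    genes is added.
    """
    rng = np.random.default_rng(seed)
    pool = sorted(set(gene_pool))
    out = []
    for cx in planted:
        members = sorted(cx.members)
        n_drop = min(int(round(drop_frac * len(members))), len(members) - 2)
        if n_drop > 0:
            drop = set(rng.choice(len(members), size=n_drop, replace=False))
            members = [g for k, g in enumerate(members) if k not in drop]
        n_add = int(round(add_frac * len(members)))
        if n_add > 0:
            extras = rng.choice(len(pool), size=n_add, replace=False)
            members = sorted(set(members) | {pool[e] for e in extras})
        out.append(Complex(f"REF_{cx.name}", frozenset(members)))
    return ComplexSet(out, disjoint=False)


def jaccard(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


@dataclass
class RecoveryMetrics:
    recall: float
    precision: float | None  # None when nothing was found
    best_jaccard_per_planted: dict[str, float]
    decoy_capture: dict[str, float]  # kind -> fraction captured at J >= 0.5
    n_found: int

    def as_dict(self) -> dict:
        return asdict(self)


def evaluate_recovery(
    found: ComplexSet,
    truth: GroundTruth,
    jaccard_min: float = 0.5,
    precision_jaccard_min: float = 0.2,
) -> RecoveryMetrics:
    """Ground-truth recovery metrics.

    recall: fraction of planted complexes whose best-matching found complex
    reaches ``jaccard_min``.  precision: fraction of found complexes whose
    best match against any planted complex reaches ``precision_jaccard_min``.
    Decoy capture is reported separately per decoy kind at J >= 0.5.
    """
    found_sets = found.member_sets()
    best_per_planted: dict[str, float] = {}
    for cx in truth.planted:
        best = max((jaccard(cx.members, f) for f in found_sets), default=0.0)
        best_per_planted[cx.name] = best
    recall = float(
        np.mean([bj >= jaccard_min for bj in best_per_planted.values()])
    ) if best_per_planted else 0.0

    if found_sets:
        planted_sets = truth.planted.member_sets()
        precision = float(
            np.mean(
                [
                    max((jaccard(f, p) for p in planted_sets), default=0.0)
                    >= precision_jaccard_min
                    for f in found_sets
                ]
            )
        )
    else:
        precision = None

    decoy_capture = {}
    for kind, decoys in (
        ("correlated_only", truth.correlated_decoys),
        ("clique_only", truth.clique_decoys),
    ):
        if decoys:
            decoy_capture[kind] = float(
                np.mean(
                    [
                        max((jaccard(d, f) for f in found_sets), default=0.0) >= 0.5
                        for d in decoys
                    ]
                )
            )
    return RecoveryMetrics(
        recall=recall,
        precision=precision,
        best_jaccard_per_planted=best_per_planted,
        decoy_capture=decoy_capture,
        n_found=len(found_sets),
    )
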