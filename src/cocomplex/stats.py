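"""Inference on top of a complex catalogue.

Four analyses:

* subtype-specific complex expression — a rank test (a variant of 1D
  annotation enrichment) asking whether a complex's subunits sit at one end
  of the per-protein median-difference ranking for a subtype;
* genotype -> complex "collateral loss" — whether samples carrying a
  mutation or deletion of one subunit show a lower within-sample mean
  abundance rank of the remaining subunits;
* catalogue overlap — hypergeometric enrichment of discovered complexes
  against a reference catalogue;
* isogenic differential expression — Welch t-tests on label-free
  quantification intensities from an engineered cell-line pair.

Effect sizes for the rank tests are reported as the rank-biserial
correlation s = 2U/(n1*n2) - 1 in [-1, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .types import (
    ChromosomeMap,
    ComplexSet,
    CopyNumberMatrix,
    DAMAGING_MUTATION_CLASSES,
    ExpressionMatrix,
    MutationTable,
    SampleAnnotation,
)

logger = logging.getLogger(__name__)

EXACT_MW_MAX_N = 12
DEFAULT_MIN_ALTERED = 3

_ALTERNATIVES = {"less": "less", "greater": "greater", "two_sided": "two-sided"}


def mann_whitney(
    x: Sequence[float], y: Sequence[float], alternative: str = "two_sided"
) -> tuple[float, float]:
    """Mann-Whitney U test of two independent samples.

    Returns (U of x, p).  Exact by enumeration when the combined sample is
    small (n <= 12) and untied; otherwise the normal approximation with tie
    and continuity corrections.  If every value is tied across both groups
    the test is uninformative and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {sorted(_ALTERNATIVES)}")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= EXACT_MW_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative=_ALTERNATIVES[alternative], method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def rank_biserial(U: float, n_x: int, n_y: int) -> float:
    """Signed effect size in [-1, 1]; positive when x tends to exceed y."""
    return 2.0 * U / (n_x * n_y) - 1.0


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up BH q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def subtype_complex_enrichment(
    expr: ExpressionMatrix,
    ann: SampleAnnotation,
    complexes: ComplexSet,
    fdr_target: float = 0.10,
    min_members: int = 3,
) -> pd.DataFrame:
    """Test each (complex, subtype) for coordinated over/under-expression.

    For each protein, the difference between its median expression in the
    subtype and its median in all other samples is computed; a two-sided
    Mann-Whitney test then asks whether a complex's members sit at one end of
    that median-difference ranking.  Complexes need at least ``min_members``
    measured members (i.e. more than two).  BH correction is applied jointly
    across all complex x subtype tests.
    """
    samples = [s for s in expr.sample_ids if s in set(ann.sample_ids)]
    labels = ann.subtypes.reindex(samples)
    subtype_names = sorted(labels.dropna().unique())
    if len(subtype_names) < 2:
        raise ValueError("at least two subtypes are required")
    data = expr.data[samples]

    rows = []
    for subtype in subtype_names:
        in_group = data.loc[:, (labels == subtype).to_numpy()]
        out_group = data.loc[:, (labels != subtype).to_numpy()]
        med_diff = in_group.median(axis=1, skipna=True) - out_group.median(
            axis=1, skipna=True
        )
        med_diff = med_diff.dropna()
        measured = set(med_diff.index)
        for cx in complexes:
            members = sorted(cx.members & measured)
            if len(members) < min_members:
                logger.debug(
                    "subtype test: %s skipped for %s (<%d measured members)",
                    cx.name,
                    subtype,
                    min_members,
                )
                continue
            others = med_diff.index.difference(members)
            mx = med_diff.loc[members].to_numpy()
            my = med_diff.loc[others].to_numpy()
            U, p = mann_whitney(mx, my, alternative="two_sided")
            rows.append(
                {
                    "unit": cx.name,
                    "contrast": subtype,
                    "effect": rank_biserial(U, len(mx), len(my)),
                    "p": p,
                    "n_members": len(mx),
                    "n_other": len(my),
                    "direction": "two_sided",
                }
            )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["q"] = benjamini_hochberg(table["p"].to_numpy())
        table["significant"] = table["q"] <= fdr_target
        table = table.sort_values(["p", "unit", "contrast"]).reset_index(drop=True)
    return table


@dataclass
class AlterationProfile:
    """Per-gene sets of altered samples under a fixed alteration definition."""

    altered: dict[str, set[str]]
    samples: set[str]
    definition: dict = field(default_factory=dict)

    @property
    def mode(self) -> str:
        return self.definition.get("mode", "unknown")

    def altered_samples(self, gene: str) -> set[str]:
        return self.altered.get(gene, set()) & self.samples


ALTERATION_MODES = ("mut_or_homdel", "hemizygous", "homozygous", "mutation_only")


def build_alteration_profile(
    mutations: MutationTable | None,
    cnv: CopyNumberMatrix | None,
    mode: str,
    samples: Iterable[str] | None = None,
) -> AlterationProfile:
    """Annotate samples as altered per gene under the requested definition.

    Modes: ``mutation_only`` (protein-affecting mutation classes only;
    synonymous and 'other' never count), ``homozygous`` (copy-number call
    -2), ``hemizygous`` (call -1), ``mut_or_homdel`` (mutation or call -2).
    The sample universe is the intersection of the provided datasets' sample
    universes (and ``samples`` when given).
    """
    if mode not in ALTERATION_MODES:
        raise ValueError(f"mode must be one of {ALTERATION_MODES}")
    needs_mut = mode in ("mutation_only", "mut_or_homdel")
    needs_cnv = mode in ("hemizygous", "homozygous", "mut_or_homdel")
    if needs_mut and mutations is None:
        raise ValueError(f"mode {mode!r} requires a mutation table")
    if needs_cnv and cnv is None:
        raise ValueError(f"mode {mode!r} requires a copy-number matrix")

    universe: set[str] | None = set(samples) if samples is not None else None
    if needs_cnv:
        cnv_samples = set(cnv.sample_ids)
        universe = cnv_samples if universe is None else universe & cnv_samples
    if universe is None:
        raise ValueError(
            "mutation_only mode requires an explicit sample universe "
            "(mutation tables list only mutated samples)"
        )
    if not universe:
        raise ValueError("empty intersection of sample universes")

    altered: dict[str, set[str]] = {}
    if needs_mut:
        dam = mutations.damaging()
        for _, row in dam.iterrows():
            if row["sample_id"] in universe:
                altered.setdefault(row["gene_id"], set()).add(row["sample_id"])
    if needs_cnv:
        call = -2 if mode in ("homozygous", "mut_or_homdel") else -1
        cols = [s for s in cnv.sample_ids if s in universe]
        sub = cnv.data[cols]
        hits = sub.to_numpy() == call
        for gi, gene in enumerate(sub.index):
            js = np.flatnonzero(hits[gi])
            if js.size:
                altered.setdefault(gene, set()).update(sub.columns[j] for j in js)
    return AlterationProfile(
        altered,
        universe,
        definition={
            "mode": mode,
            "mutation_classes": sorted(DAMAGING_MUTATION_CLASSES) if needs_mut else [],
            "copy_number_calls": [-2] if mode in ("homozygous", "mut_or_homdel")
            else ([-1] if mode == "hemizygous" else []),
        },
    )


def single_gene_alteration_test(
    expr: ExpressionMatrix,
    profile: AlterationProfile,
    gene: str,
    min_altered: int = 1,
) -> tuple[float, str] | None:
    """One-sided test that altered samples have lower abundance of the
    gene's own protein.  Returns (p, 'down') or None when untestable."""
    if gene not in expr.data.index:
        logger.info("single_gene_alteration_test: %s not measured, skipped", gene)
        return None
    values = expr.data.loc[gene].dropna()
    usable = [s for s in values.index if s in profile.samples]
    altered = profile.altered_samples(gene) & set(usable)
    unaltered = [s for s in usable if s not in altered]
    if len(altered) < min_altered or not unaltered:
        return None
    _, p = mann_whitney(
        values.loc[sorted(altered)].to_numpy(),
        values.loc[unaltered].to_numpy(),
        alternative="less",
    )
    return p, "down"


def within_sample_ranks(expr: ExpressionMatrix) -> pd.DataFrame:
    """Ascending within-sample abundance ranks (1 = lowest); average ranks
    for ties, missing values excluded from that sample's ranking."""
    return expr.data.rank(axis=0, method="average", na_option="keep")


def complex_collateral_test(
    expr: ExpressionMatrix,
    profile: AlterationProfile,
    complexes: ComplexSet,
    chrom: ChromosomeMap | None = None,
    fdr_target: float = 0.10,
    min_altered: int = DEFAULT_MIN_ALTERED,
    min_remaining: int = 2,
    exclude_same_chromosome: bool | None = None,
) -> pd.DataFrame:
    """Test whether alteration of one subunit depresses the rest of its complex.

    Protein abundances are converted to within-sample ranks; the per-sample
    statistic is the mean rank of the complex members, always excluding the
    altered gene itself and — for deletion-containing alteration modes — any
    member on the same chromosome as the altered gene (so co-deletion cannot
    masquerade as a trans effect).  Altered and unaltered samples are compared
    with a one-sided Mann-Whitney test (altered lower); BH correction is
    applied jointly across all (gene, complex) tests of the run.
    """
    if exclude_same_chromosome is None:
        exclude_same_chromosome = profile.mode in (
            "hemizygous",
            "homozygous",
            "mut_or_homdel",
        )
    if exclude_same_chromosome and chrom is None:
        raise ValueError("chromosome map required for same-chromosome exclusion")
    ranks = within_sample_ranks(expr)
    samples = [s for s in expr.sample_ids if s in profile.samples]
    measured = set(expr.gene_ids)

    rows = []
    for cx in complexes:
        for gene in sorted(cx.members):
            altered = profile.altered_samples(gene) & set(samples)
            if len(altered) < min_altered:
                continue
            unaltered = [s for s in samples if s not in altered]
            if not unaltered:
                continue
            remaining = (cx.members - {gene}) & measured
            if exclude_same_chromosome:
                remaining = {
                    g for g in remaining if not chrom.same_chromosome(g, gene)
                }
            if len(remaining) < min_remaining:
                logger.debug(
                    "collateral test: %s/%s skipped (<%d members after exclusions)",
                    gene,
                    cx.name,
                    min_remaining,
                )
                continue
            mean_rank = ranks.loc[sorted(remaining), samples].mean(
                axis=0, skipna=True
            )
            x = mean_rank.loc[sorted(altered)].dropna().to_numpy()
            y = mean_rank.loc[unaltered].dropna().to_numpy()
            if x.size == 0 or y.size == 0:
                continue
            U, p = mann_whitney(x, y, alternative="less")
            rows.append(
                {
                    "unit": cx.name,
                    "contrast": f"{gene}:{profile.mode}",
                    "gene": gene,
                    "effect": rank_biserial(U, x.size, y.size),
                    "p": p,
                    "n_altered": x.size,
                    "n_unaltered": y.size,
                    "n_members_tested": len(remaining),
                    "direction": "down",
                }
            )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["q"] = benjamini_hochberg(table["p"].to_numpy())
        table["significant"] = table["q"] <= fdr_target
        table = table.sort_values(["p", "unit", "gene"]).reset_index(drop=True)
    return table


def catalogue_overlap(
    complexes: ComplexSet,
    reference: ComplexSet,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Best hypergeometric overlap of each discovered complex with a
    reference catalogue, over a fixed background gene universe."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty background universe")
    N = len(universe)
    ref_sets = [(r.name, r.members & universe) for r in reference]
    rows = []
    for cx in complexes:
        members = cx.members & universe
        best = None
        for ref_name, ref_members in ref_sets:
            if not ref_members:
                continue
            k = len(members & ref_members)
            p = float(sps.hypergeom.sf(k - 1, N, len(ref_members), len(members))) if k else 1.0
            union = len(members | ref_members)
            jaccard = k / union if union else 0.0
            coverage = k / len(ref_members)
            entry = (p, -jaccard, ref_name, k, jaccard, coverage)
            if best is None or entry < best:
                best = entry
        if best is None:
            continue
        p, _, ref_name, k, jaccard, coverage = best
        rows.append(
            {
                "unit": cx.name,
                "contrast": ref_name,
                "effect": jaccard,
                "p": p,
                "n_overlap": k,
                "coverage": coverage,
                "direction": "two_sided",
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["q"] = benjamini_hochberg(table["p"].to_numpy())
        table = table.sort_values(["p", "unit"]).reset_index(drop=True)
    return table


def isogenic_differential_expression(
    lfq: ExpressionMatrix,
    design: Mapping[str, tuple[str, str]],
) -> pd.DataFrame:
    """Differential expression between two conditions of an isogenic pair.

    ``design`` maps each raw sample column to (condition, biological
    replicate).  Technical replicates of the same biological replicate are
    averaged, missing values are imputed with each sample's minimum observed
    intensity, intensities are log2-transformed and a two-sided Welch t-test
    is applied per protein with BH correction.  The effect is the mean log2
    difference (first condition minus second, in sorted condition order).
    """
    cols = [s for s in lfq.sample_ids if s in design]
    if not cols:
        raise ValueError("design covers no sample columns")
    groups: dict[tuple[str, str], list[str]] = {}
    for s in cols:
        groups.setdefault(tuple(design[s]), []).append(s)
    averaged = pd.DataFrame(
        {
            f"{cond}:{rep}": lfq.data[ss].mean(axis=1, skipna=True)
            for (cond, rep), ss in sorted(groups.items())
        }
    )
    conditions = sorted({cond for cond, _ in groups})
    if len(conditions) != 2:
        raise ValueError("exactly two conditions are required")
    for cond in conditions:
        n = sum(1 for c, _ in groups if c == cond)
        if n < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 biological replicates")

    averaged = averaged.dropna(how="all")
    imputed = averaged.copy()
    for col in imputed.columns:
        observed_min = imputed[col].min(skipna=True)
        imputed[col] = imputed[col].fillna(observed_min)
    if (imputed.to_numpy() <= 0).any():
        raise ValueError("LFQ intensities must be positive for log2 transform")
    log2 = np.log2(imputed)

    a_cols = [c for c in log2.columns if c.startswith(f"{conditions[0]}:")]
    b_cols = [c for c in log2.columns if c.startswith(f"{conditions[1]}:")]
    A = log2[a_cols].to_numpy()
    B = log2[b_cols].to_numpy()
    t, p = sps.ttest_ind(A, B, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical groups
    table = pd.DataFrame(
        {
            "unit": log2.index,
            "contrast": f"{conditions[0]}_vs_{conditions[1]}",
            "effect": A.mean(axis=1) - B.mean(axis=1),
            "p": p,
            "t": np.where(np.isnan(t), 0.0, t),
            "direction": "two_sided",
        }
    )
    table["q"] = benjamini_hochberg(table["p"].to_numpy())
    return table.sort_values(["p", "unit"]).reset_index(drop=True)
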