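"""Downstream statistics: rank tests, alteration profiles, DE pipeline."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from cocomplex.stats import (
    benjamini_hochberg,
    build_alteration_profile,
    catalogue_overlap,
    complex_collateral_test,
    isogenic_differential_expression,
    mann_whitney,
    rank_biserial,
    single_gene_alteration_test,
    subtype_complex_enrichment,
    within_sample_ranks,
)
from cocomplex.types import (
    ChromosomeMap,
    Complex,
    ComplexSet,
    CopyNumberMatrix,
    ExpressionMatrix,
    MutationTable,
    SampleAnnotation,
)


def mw_exact_enumeration(x, y, alternative):
    """Oracle: exact Mann-Whitney p by enumerating all group assignments."""
    x, y = list(x), list(y)
    combined = x + y
    n, nx = len(combined), len(x)

    def u_of(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    u_obs = u_of(x, y)
    us = []
    for idx in itertools.combinations(range(n), nx):
        xs = [combined[i] for i in idx]
        ys = [combined[i] for i in range(n) if i not in idx]
        us.append(u_of(xs, ys))
    total = len(us)
    if alternative == "less":
        p = sum(1 for u in us if u <= u_obs) / total
    elif alternative == "greater":
        p = sum(1 for u in us if u >= u_obs) / total
    else:
        p_less = sum(1 for u in us if u <= u_obs) / total
        p_greater = sum(1 for u in us if u >= u_obs) / total
        p = min(1.0, 2 * min(p_less, p_greater))
    return p


class TestMannWhitney:
    def test_worked_example(self):
        U, p = mann_whitney([1, 2], [3, 4], alternative="less")
        assert U == 0.0
        assert p == pytest.approx(1 / 6)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney([1.0, 1.0, 1.0], [1.0, 1.0], alternative="two_sided")
        assert p == 1.0

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            x = rng.permutation(12)[:5].astype(float)
            y = np.setdiff1d(np.arange(12), x)[:5].astype(float)
            for alt in ("less", "greater", "two_sided"):
                _, p = mann_whitney(x, y, alternative=alt)
                assert p == pytest.approx(mw_exact_enumeration(x, y, alt), abs=1e-12)

    def test_exact_and_approximate_agree(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            x = rng.standard_normal(6)
            y = rng.standard_normal(6)
            _, p_exact = mann_whitney(x, y, alternative="less")  # n=12: exact path
            from scipy import stats as sps

            p_approx = sps.mannwhitneyu(
                x, y, alternative="less", method="asymptotic", use_continuity=True
            ).pvalue
            assert abs(p_exact - p_approx) < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestBenjaminiHochberg:
    def test_step_up_example(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_and_saturated(self):
        assert benjamini_hochberg([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_matches_reference_step_up(self):
        def reference_bh(p):
            p = np.asarray(p, float)
            order = np.argsort(p)
            m = len(p)
            q = np.empty(m)
            prev = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                prev = min(prev, p[i] * m / rank)
                q[i] = prev
            return q

        rng = np.random.default_rng(3)
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(benjamini_hochberg(p), reference_bh(p), atol=1e-12)


def _subtype_setup(n_genes=30, n_samples=24, shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    data = rng.standard_normal((n_genes, n_samples))
    labels = ["A" if j < n_samples // 2 else "B" for j in range(n_samples)]
    members = genes[:5]
    if shift:
        cols = [j for j, s in enumerate(labels) if s == "A"]
        data[np.ix_(range(5), cols)] += shift
    em = ExpressionMatrix(pd.DataFrame(data, index=genes, columns=samples))
    ann = SampleAnnotation(
        pd.DataFrame({"subtype": labels}, index=pd.Index(samples, name="sample_id"))
    )
    cs = ComplexSet([Complex("cx", frozenset(members))])
    return em, ann, cs


class TestSubtypeEnrichment:
    def test_extreme_separation_gives_s_plus_one(self):
        em, ann, cs = _subtype_setup(shift=25.0)
        table = subtype_complex_enrichment(em, ann, cs)
        row = table[(table.unit == "cx") & (table.contrast == "A")].iloc[0]
        assert row.effect == pytest.approx(1.0)
        assert row.p < 0.01

    def test_small_complexes_skipped(self):
        em, ann, _ = _subtype_setup()
        cs = ComplexSet([Complex("tiny", frozenset(["g0", "g1"]))])
        table = subtype_complex_enrichment(em, ann, cs)
        assert table.empty

    def test_invariance_under_positive_affine_transform(self):
        # medians are affine-equivariant, so rescaling and shifting the
        # matrix preserves the ranking of per-protein median differences
        em, ann, cs = _subtype_setup(shift=1.0, seed=5)
        t1 = subtype_complex_enrichment(em, ann, cs)
        em2 = ExpressionMatrix(3.0 * em.data + 7.0)
        t2 = subtype_complex_enrichment(em2, ann, cs)
        assert np.allclose(t1.p.to_numpy(), t2.p.to_numpy())
        assert np.allclose(t1.effect.to_numpy(), t2.effect.to_numpy())

    def test_one_subtype_rejected(self):
        em, _, cs = _subtype_setup()
        ann = SampleAnnotation(
            pd.DataFrame({"subtype": ["A"] * em.n_samples},
                         index=pd.Index(em.sample_ids, name="sample_id"))
        )
        with pytest.raises(ValueError):
            subtype_complex_enrichment(em, ann, cs)


def _alteration_setup():
    cnv = CopyNumberMatrix(
        pd.DataFrame(
            {"s1": [-2, -1], "s2": [0, -1], "s3": [-1, 0]},
            index=["gA", "gB"],
        )
    )
    muts = MutationTable(
        pd.DataFrame(
            {
                "sample_id": ["s2", "s3"],
                "gene_id": ["gA", "gB"],
                "mutation_class": ["missense", "synonymous"],
            }
        )
    )
    return muts, cnv


class TestAlterationProfile:
    def test_homozygous_and_combined_modes(self):
        muts, cnv = _alteration_setup()
        homo = build_alteration_profile(None, cnv, "homozygous")
        assert homo.altered_samples("gA") == {"s1"}
        combined = build_alteration_profile(muts, cnv, "mut_or_homdel")
        assert combined.altered_samples("gA") == {"s1", "s2"}

    def test_hemizygous_mode(self):
        _, cnv = _alteration_setup()
        hemi = build_alteration_profile(None, cnv, "hemizygous")
        assert hemi.altered_samples("gA") == {"s3"}
        assert hemi.altered_samples("gB") == {"s1", "s2"}

    def test_synonymous_never_counts(self):
        muts, cnv = _alteration_setup()
        for mode in ("mutation_only", "mut_or_homdel"):
            profile = build_alteration_profile(muts, cnv, mode, samples=cnv.sample_ids)
            assert profile.altered_samples("gB") <= {"s1", "s2"}  # no s3 via mutation
        mut_only = build_alteration_profile(muts, cnv, "mutation_only",
                                            samples=cnv.sample_ids)
        assert mut_only.altered_samples("gB") == set()

    def test_empty_universe_rejected(self):
        muts, cnv = _alteration_setup()
        with pytest.raises(ValueError):
            build_alteration_profile(muts, cnv, "hemizygous", samples=["nope"])


class TestSingleGeneTest:
    def test_extreme_case_reaches_minimal_p(self):
        genes = ["gA"]
        samples = [f"s{j}" for j in range(8)]
        values = np.array([[0.0, 0.1, 5, 6, 7, 8, 9, 10]])
        em = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
        profile = build_alteration_profile(
            MutationTable(pd.DataFrame({
                "sample_id": ["s0", "s1"],
                "gene_id": ["gA", "gA"],
                "mutation_class": ["missense", "nonsense"],
            })),
            None,
            "mutation_only",
            samples=samples,
        )
        p, direction = single_gene_alteration_test(em, profile, "gA")
        assert direction == "down"
        assert p == pytest.approx(1 / math.comb(8, 2))  # minimal achievable

    def test_no_altered_samples_skipped(self):
        em = ExpressionMatrix(pd.DataFrame([[1.0, 2.0]], index=["gA"], columns=["s1", "s2"]))
        profile = build_alteration_profile(
            MutationTable(pd.DataFrame(columns=["sample_id", "gene_id", "mutation_class"])),
            None, "mutation_only", samples=["s1", "s2"],
        )
        assert single_gene_alteration_test(em, profile, "gA") is None

    def test_unmeasured_gene_skipped(self):
        em = ExpressionMatrix(pd.DataFrame([[1.0]], index=["gA"], columns=["s1"]))
        profile = build_alteration_profile(None, CopyNumberMatrix(
            pd.DataFrame([[-2]], index=["gB"], columns=["s1"])), "homozygous")
        assert single_gene_alteration_test(em, profile, "gB") is None


class TestCollateralTest:
    def test_within_sample_rank_example(self):
        em = ExpressionMatrix(
            pd.DataFrame({"s1": [10.0, 9.0, 2.0, 1.0]}, index=["P1", "P2", "P3", "P4"])
        )
        ranks = within_sample_ranks(em)
        assert list(ranks["s1"]) == [4.0, 3.0, 2.0, 1.0]
        assert ranks.loc[["P1", "P2"], "s1"].mean() == pytest.approx(3.5)

    def _collateral_inputs(self, chrom_map):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(20)]
        samples = [f"s{j}" for j in range(30)]
        data = rng.standard_normal((20, 30))
        altered = samples[:5]
        data[1:4, :5] -= 3.0  # partners depressed in altered samples
        em = ExpressionMatrix(pd.DataFrame(data, index=genes, columns=samples))
        calls = np.zeros((20, 30), dtype=int)
        calls[0, :5] = -1
        cnv = CopyNumberMatrix(pd.DataFrame(calls, index=genes, columns=samples))
        cs = ComplexSet([Complex("cx", frozenset(genes[:4]))])
        profile = build_alteration_profile(None, cnv, "hemizygous")
        return em, profile, cs, ChromosomeMap(chrom_map)

    def test_detects_planted_collateral_loss(self):
        chrom = {f"g{i}": f"chr{i}" for i in range(20)}
        em, profile, cs, cmap = self._collateral_inputs(chrom)
        table = complex_collateral_test(em, profile, cs, cmap)
        row = table[(table.gene == "g0") & (table.unit == "cx")].iloc[0]
        assert row.p < 0.01
        assert row.effect < 0

    def test_same_chromosome_members_excluded(self):
        # all partners share g0's chromosome: nothing left to test
        chrom = {f"g{i}": "chr1" for i in range(20)}
        em, profile, cs, cmap = self._collateral_inputs(chrom)
        table = complex_collateral_test(em, profile, cs, cmap)
        assert table.empty

    def test_mutation_mode_skips_chromosome_exclusion(self):
        chrom = {f"g{i}": "chr1" for i in range(20)}
        em, _, cs, cmap = self._collateral_inputs(chrom)
        muts = MutationTable(pd.DataFrame({
            "sample_id": [f"s{j}" for j in range(5)],
            "gene_id": ["g0"] * 5,
            "mutation_class": ["missense"] * 5,
        }))
        profile = build_alteration_profile(muts, None, "mutation_only",
                                           samples=em.sample_ids)
        table = complex_collateral_test(em, profile, cs, cmap)
        assert len(table) == 1  # only the altered gene itself is excluded

    def test_rank_invariance_under_monotone_transform(self):
        chrom = {f"g{i}": f"chr{i}" for i in range(20)}
        em, profile, cs, cmap = self._collateral_inputs(chrom)
        t1 = complex_collateral_test(em, profile, cs, cmap)
        em2 = ExpressionMatrix(np.exp(em.data / 3.0))
        t2 = complex_collateral_test(em2, profile, cs, cmap)
        assert np.allclose(t1.p.to_numpy(), t2.p.to_numpy())


class TestCatalogueOverlap:
    def test_identical_complex(self):
        universe = [f"g{i}" for i in range(1000)]
        cs = ComplexSet([Complex("found", frozenset(universe[:5]))])
        ref = ComplexSet([Complex("ref", frozenset(universe[:5]))])
        table = catalogue_overlap(cs, ref, universe)
        row = table.iloc[0]
        assert row.effect == 1.0  # Jaccard
        assert row.p == pytest.approx(1 / math.comb(1000, 5), rel=1e-6)

    def test_disjoint_sets(self):
        universe = [f"g{i}" for i in range(50)]
        cs = ComplexSet([Complex("found", frozenset(universe[:5]))])
        ref = ComplexSet([Complex("ref", frozenset(universe[5:10]))])
        table = catalogue_overlap(cs, ref, universe)
        assert table.iloc[0].effect == 0.0
        assert table.iloc[0].p == 1.0

    def test_matches_tail_enumeration_small_universe(self):
        rng = np.random.default_rng(7)
        universe = [f"g{i}" for i in range(30)]
        for trial in range(30):
            a = frozenset(rng.choice(universe, size=6, replace=False))
            b = frozenset(rng.choice(universe, size=8, replace=False))
            cs = ComplexSet([Complex("found", a)])
            ref = ComplexSet([Complex("ref", b)])
            p = catalogue_overlap(cs, ref, universe).iloc[0].p
            k = len(a & b)
            if k == 0:
                assert p == 1.0
                continue
            expected = Fraction(0)
            for kk in range(k, min(len(a), len(b)) + 1):
                expected += Fraction(
                    math.comb(len(b), kk) * math.comb(30 - len(b), len(a) - kk),
                    math.comb(30, len(a)),
                )
            assert p == pytest.approx(float(expected), rel=1e-10)

    def test_empty_universe_rejected(self):
        cs = ComplexSet([Complex("found", frozenset(["g1", "g2"]))])
        with pytest.raises(ValueError):
            catalogue_overlap(cs, cs, [])


class TestIsogenicDE:
    def _lfq(self, values, samples):
        genes = [f"p{i}" for i in range(values.shape[0])]
        return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))

    def test_identical_groups_p_one(self):
        samples = [f"wt_{r}_t{t}" for r in range(3) for t in range(2)]
        samples += [f"ko_{r}_t{t}" for r in range(3) for t in range(2)]
        values = np.tile(np.array([100.0, 200.0, 400.0])[:, None], (1, 12))
        design = {
            s: (s.split("_")[0], s.split("_")[1]) for s in samples
        }
        table = isogenic_differential_expression(self._lfq(values, samples), design)
        assert np.allclose(table.p, 1.0)
        assert np.allclose(table.effect, 0.0)

    def test_missing_imputed_with_sample_minimum(self):
        samples = ["a_1", "a_2", "b_1", "b_2"]
        values = np.array(
            [
                [100.0, 100.0, 100.0, 100.0],
                [np.nan, 50.0, 50.0, 50.0],
                [10.0, 10.0, 10.0, 10.0],
            ]
        )
        design = {s: (s.split("_")[0], s.split("_")[1]) for s in samples}
        table = isogenic_differential_expression(self._lfq(values, samples), design)
        # p1's missing a_1 entry was imputed with a_1's minimum (10), so the
        # a-group mean for p1 is pulled below the b-group mean
        row = table[table.unit == "p1"].iloc[0]
        expected_effect = (np.log2(10) + np.log2(50)) / 2 - np.log2(50)
        assert row.effect == pytest.approx(expected_effect)

    def test_technical_replicates_averaged_before_testing(self):
        samples = ["a_1_t1", "a_1_t2", "a_2_t1", "b_1_t1", "b_2_t1"]
        values = np.array([[64.0, 256.0, 128.0, 128.0, 128.0]])
        design = {
            "a_1_t1": ("a", "1"), "a_1_t2": ("a", "1"), "a_2_t1": ("a", "2"),
            "b_1_t1": ("b", "1"), "b_2_t1": ("b", "2"),
        }
        table = isogenic_differential_expression(self._lfq(values, samples), design)
        # technical pair (64, 256) averages to 160 before the log transform
        assert table.iloc[0].effect == pytest.approx(
            (np.log2(160) + np.log2(128)) / 2 - np.log2(128)
        )

    def test_planted_fold_change_power(self):
        """A 2-fold change with 0.3 log2-unit noise per technical measurement,
        3 vs 3 biological replicates each with 2 averaged technical
        replicates, is detected at p < 0.05 with power around 0.95 (the value
        a noncentral-t / simulation oracle gives for this design)."""
        rng = np.random.default_rng(10)
        hits = 0
        n_sims = 60
        for _ in range(n_sims):
            # 2 technical replicates per biological replicate, both conditions
            base = 10.0 + rng.normal(0, 0.3, (1, 12))
            base[0, 6:] += 1.0  # one log2 unit = 2-fold
            values = np.vstack([2 ** base, 2 ** rng.normal(10, 0.3, (30, 12))])
            samples = [f"a_{r}_t{t}" for r in range(3) for t in range(2)]
            samples += [f"b_{r}_t{t}" for r in range(3) for t in range(2)]
            design = {s: (s.split("_")[0], s.split("_")[1]) for s in samples}
            table = isogenic_differential_expression(self._lfq(values, samples), design)
            if table[table.unit == "p0"].iloc[0].p < 0.05:
                hits += 1
        assert hits / n_sims >= 0.85

    def test_single_replicate_rejected(self):
        samples = ["a_1", "b_1", "b_2"]
        values = np.ones((2, 3))
        design = {s: (s.split("_")[0], s.split("_")[1]) for s in samples}
        with pytest.raises(ValueError, match="fewer than 2"):
            isogenic_differential_expression(self._lfq(values, samples), design)


def test_rank_biserial_bounds():
    assert rank_biserial(0, 4, 5) == -1.0
    assert rank_biserial(20, 4, 5) == 1.0
    assert rank_biserial(10, 4, 5) == 0.0
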