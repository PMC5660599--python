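"""Constrained agglomerative discovery of co-regulated protein complexes.

The search looks for disjoint protein sets whose summed pairwise integrated
LLR is high *on both evidence channels*: a set qualifies only if its total
expression LLR and its total interaction LLR are each positive, so that
neither dense connectivity alone nor co-expression alone can produce a
complex.

Algorithm
---------
1. *Seeding* — every directly interacting pair and every network triangle is
   scored; candidates positive on both channels are kept.  The best remaining
   candidate (by integrated LLR) is repeatedly selected, discarding
   overlapping candidates, until none remain; unassigned genes become
   singletons.
2. *Refinement* — local search over three moves: merging two clusters,
   removing one protein into a singleton, and switching one protein between
   clusters.  At each iteration the move with the largest integrated-LLR gain
   is applied, but only moves that increase the expression LLR *and* the
   interaction LLR strictly are eligible.  The search stops when no eligible
   move remains; the total integrated score is strictly increasing, so the
   procedure terminates.
3. *Empirical FDR* — the discovery is re-run on randomized inputs in which
   the assignment of expression profiles to gene identifiers is shuffled
   (network and calibrated models untouched).  For a score threshold t the
   FDR is the mean number of genes clustered in the randomized runs at >= t
   divided by the number of genes clustered in the real run at >= t.

Switch moves are only proposed toward clusters containing at least one
interaction partner of the moving protein, and merges only between clusters
joined by at least one network edge; a move that fails the dual-increase
constraint through such a pairing could never be accepted anyway, because a
positive interaction gain requires at least one cross edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .llr import (
    EdgeScoreFeatures,
    LLRModel,
    PairLLRTable,
    expression_llr_matrix,
    fit_llr_model,
    sample_training_pairs,
    score_pairs,
)
from .network import weight_network
from .preprocess import CorrelationTable, pairwise_correlation
from .types import Complex, ComplexSet, ExpressionMatrix, InteractionNetwork

logger = logging.getLogger(__name__)

_TOL = 1e-12


@dataclass
class DiscoveryConfig:
    fdr_target: float = 0.10
    min_overlap: int = 10
    neg_ratio: int = 300
    max_complex_size: int = 30  # training-set size filter on the reference
    n_random: int = 100
    max_iterations: int = 10_000
    min_size: int = 2
    seed: int = 0


@dataclass(frozen=True)
class Candidate:
    members: tuple[int, ...]  # gene indices, sorted
    llr_expr: float
    llr_int: float

    @property
    def llr_integrated(self) -> float:
        return self.llr_expr + self.llr_int


@dataclass
class MoveRecord:
    iteration: int
    kind: str  # merge | remove | switch
    genes: tuple[str, ...]
    d_expr: float
    d_int: float

    @property
    def d_integrated(self) -> float:
        return self.d_expr + self.d_int


@dataclass
class ClusterState:
    """Disjoint clustering over the PairLLRTable gene universe."""

    pairs: PairLLRTable
    clusters: dict[int, list[int]]
    cluster_of: np.ndarray
    move_log: list[MoveRecord] = field(default_factory=list)
    _next_cid: int = 0

    @classmethod
    def from_clusters(
        cls, pairs: PairLLRTable, clusters: Iterable[Sequence[int]]
    ) -> "ClusterState":
        assigned: dict[int, list[int]] = {}
        cluster_of = np.full(pairs.n_genes, -1, dtype=np.int64)
        cid = 0
        for members in clusters:
            members = sorted(members)
            assigned[cid] = members
            for g in members:
                if cluster_of[g] != -1:
                    raise ValueError("clusters must be disjoint")
                cluster_of[g] = cid
            cid += 1
        for g in range(pairs.n_genes):
            if cluster_of[g] == -1:
                assigned[cid] = [g]
                cluster_of[g] = cid
                cid += 1
        return cls(pairs, assigned, cluster_of, [], cid)

    def cluster_score(self, cid: int) -> tuple[float, float, float]:
        return self.pairs.score_indices(self.clusters[cid])

    def total_scores(self) -> tuple[float, float, float]:
        e = i = 0.0
        for members in self.clusters.values():
            ce, ci, _ = self.pairs.score_indices(members)
            e += ce
            i += ci
        return e, i, e + i

    def multi_clusters(self) -> list[tuple[int, list[int]]]:
        return [(cid, m) for cid, m in self.clusters.items() if len(m) >= 2]

    def to_complex_set(
        self, min_score: float | None = None, min_size: int = 2
    ) -> ComplexSet:
        rows = []
        for cid, members in self.clusters.items():
            if len(members) < min_size:
                continue
            e, i, t = self.pairs.score_indices(members)
            if e <= 0 or i <= 0:
                continue
            if min_score is not None and t < min_score:
                continue
            names = tuple(sorted(self.pairs.genes[g] for g in members))
            rows.append((t, names, e, i))
        rows.sort(key=lambda r: (-r[0], r[1]))
        complexes = [
            Complex(f"C{k + 1:03d}", frozenset(names), llr_expr=e, llr_int=i)
            for k, (t, names, e, i) in enumerate(rows)
        ]
        return ComplexSet(complexes, disjoint=True)


def score_set(genes: Iterable[str], pairs: PairLLRTable) -> tuple[float, float, float]:
    """Summed (llr_expr, llr_int, llr_integrated) over all unordered pairs."""
    return pairs.score_set(genes)


def network_adjacency(net: InteractionNetwork, pairs: PairLLRTable) -> list[set[int]]:
    """Adjacency sets by gene index, restricted to the table's gene universe."""
    adj: list[set[int]] = [set() for _ in range(pairs.n_genes)]
    for a, b in net.edges:
        ia, ib = pairs.index.get(a), pairs.index.get(b)
        if ia is None or ib is None:
            continue
        adj[ia].add(ib)
        adj[ib].add(ia)
    return adj


def enumerate_seeds(
    net: InteractionNetwork, pairs: PairLLRTable
) -> list[Candidate]:
    """Score all directly interacting pairs and all network triangles.

    Only candidates positive on both evidence channels are returned.
    """
    adj = network_adjacency(net, pairs)
    E, I = pairs.llr_expr, pairs.llr_int
    out: list[Candidate] = []
    for i in range(pairs.n_genes):
        for j in adj[i]:
            if j <= i:
                continue
            e, q = E[i, j], I[i, j]
            if e > 0 and q > 0:
                out.append(Candidate((i, j), float(e), float(q)))
            common = adj[i] & adj[j]
            for k in sorted(common):
                if k <= j:
                    continue
                e3 = E[i, j] + E[i, k] + E[j, k]
                q3 = I[i, j] + I[i, k] + I[j, k]
                if e3 > 0 and q3 > 0:
                    out.append(Candidate((i, j, k), float(e3), float(q3)))
    return out


def greedy_seed_clusters(
    candidates: Sequence[Candidate], pairs: PairLLRTable
) -> ClusterState:
    """Select disjoint seeds greedily by integrated LLR (ties: smallest
    member-name tuple); every unassigned gene becomes a singleton."""
    def sort_key(c: Candidate):
        names = tuple(pairs.genes[g] for g in c.members)
        return (-c.llr_integrated, names)

    used = np.zeros(pairs.n_genes, dtype=bool)
    selected: list[tuple[int, ...]] = []
    for cand in sorted(candidates, key=sort_key):
        if cand.llr_integrated <= 0:
            continue
        if any(used[g] for g in cand.members):
            continue
        selected.append(cand.members)
        for g in cand.members:
            used[g] = True
    return ClusterState.from_clusters(pairs, selected)


class _MoveEngine:
    """Incremental best-move search with a delta cache.

    Deltas depend only on the composition of the clusters a move touches, so
    after applying a move only entries referencing changed clusters need
    recomputation.  Changed clusters always receive fresh ids, which makes
    stale cache keys identifiable.
    """

    def __init__(self, state: ClusterState, adj: list[set[int]], exact: bool = False):
        self.state = state
        self.adj = adj
        self.exact = exact
        self.E = state.pairs.llr_expr
        self.I = state.pairs.llr_int
        self.cache: dict[tuple, tuple[float, float]] = {}
        for cid in list(state.clusters):
            self._generate_for_cluster(cid)

    # -- delta computation -------------------------------------------------
    def _delta(self, key: tuple) -> tuple[float, float]:
        clusters = self.state.clusters
        if key[0] == "merge":
            _, c1, c2 = key
            m1, m2 = clusters[c1], clusters[c2]
            block = np.ix_(m1, m2)
            return float(self.E[block].sum()), float(self.I[block].sum())
        if key[0] == "remove":
            _, g = key
            members = clusters[self.state.cluster_of[g]]
            others = [x for x in members if x != g]
            return -float(self.E[g, others].sum()), -float(self.I[g, others].sum())
        # switch
        _, g, target = key
        others = [x for x in clusters[self.state.cluster_of[g]] if x != g]
        m2 = clusters[target]
        d_e = float(self.E[g, m2].sum()) - float(self.E[g, others].sum())
        d_i = float(self.I[g, m2].sum()) - float(self.I[g, others].sum())
        return d_e, d_i

    def _generate_for_cluster(self, cid: int) -> None:
        clusters = self.state.clusters
        cluster_of = self.state.cluster_of
        members = clusters[cid]
        if len(members) >= 2:
            for g in members:
                key = ("remove", g)
                if key not in self.cache:
                    self.cache[key] = self._delta(key)
        if self.exact:
            for other in clusters:
                if other == cid:
                    continue
                mkey = ("merge", min(cid, other), max(cid, other))
                if mkey not in self.cache:
                    self.cache[mkey] = self._delta(mkey)
                for g in members:
                    skey = ("switch", g, other)
                    if skey not in self.cache:
                        self.cache[skey] = self._delta(skey)
                for g in clusters[other]:
                    tkey = ("switch", g, cid)
                    if tkey not in self.cache:
                        self.cache[tkey] = self._delta(tkey)
            return
        for g in members:
            for nb in self.adj[g]:
                cn = int(cluster_of[nb])
                if cn == cid:
                    continue
                mkey = ("merge", min(cid, cn), max(cid, cn))
                if mkey not in self.cache:
                    self.cache[mkey] = self._delta(mkey)
                skey = ("switch", g, cn)
                if skey not in self.cache:
                    self.cache[skey] = self._delta(skey)
                tkey = ("switch", nb, cid)
                if tkey not in self.cache:
                    self.cache[tkey] = self._delta(tkey)

    # -- move application --------------------------------------------------
    def _fresh_cid(self) -> int:
        cid = self.state._next_cid
        self.state._next_cid += 1
        return cid

    def apply(self, key: tuple) -> tuple[str, tuple[str, ...], float, float]:
        state = self.state
        clusters = state.clusters
        d_e, d_i = self.cache[key]
        dead: set[int] = set()
        new_cids: list[int] = []
        if key[0] == "merge":
            _, c1, c2 = key
            union = sorted(clusters[c1] + clusters[c2])
            genes = tuple(sorted(state.pairs.genes[g] for g in union))
            dead.update((c1, c2))
            nc = self._fresh_cid()
            clusters[nc] = union
            for g in union:
                state.cluster_of[g] = nc
            new_cids.append(nc)
            kind = "merge"
        elif key[0] == "remove":
            _, g = key
            src = int(state.cluster_of[g])
            remaining = [x for x in clusters[src] if x != g]
            dead.add(src)
            nc1 = self._fresh_cid()
            clusters[nc1] = remaining
            for x in remaining:
                state.cluster_of[x] = nc1
            nc2 = self._fresh_cid()
            clusters[nc2] = [g]
            state.cluster_of[g] = nc2
            new_cids.extend((nc1, nc2))
            genes = (state.pairs.genes[g],)
            kind = "remove"
        else:
            _, g, target = key
            src = int(state.cluster_of[g])
            remaining = [x for x in clusters[src] if x != g]
            dead.update((src, target))
            new_target = self._fresh_cid()
            clusters[new_target] = sorted(clusters[target] + [g])
            for x in clusters[new_target]:
                state.cluster_of[x] = new_target
            new_cids.append(new_target)
            if remaining:
                nc = self._fresh_cid()
                clusters[nc] = remaining
                for x in remaining:
                    state.cluster_of[x] = nc
                new_cids.append(nc)
            genes = (state.pairs.genes[g],)
            kind = "switch"
        for cid in dead:
            del clusters[cid]

        moved = {g for nc in new_cids for g in clusters[nc]}
        stale = []
        for k in self.cache:
            if k[0] == "merge":
                if k[1] in dead or k[2] in dead:
                    stale.append(k)
            elif k[0] == "remove":
                if k[1] in moved:
                    stale.append(k)
            else:
                if k[1] in moved or k[2] in dead:
                    stale.append(k)
        for k in stale:
            del self.cache[k]
        for nc in new_cids:
            self._generate_for_cluster(nc)
        return kind, genes, d_e, d_i

    # -- best-move selection -----------------------------------------------
    def _signature(self, key: tuple) -> tuple:
        genes = self.state.pairs.genes
        clusters = self.state.clusters
        if key[0] == "merge":
            names = sorted(
                genes[g] for g in clusters[key[1]] + clusters[key[2]]
            )
            return (0, tuple(names))
        if key[0] == "remove":
            return (1, (genes[key[1]],))
        target = tuple(sorted(genes[g] for g in clusters[key[2]]))
        return (2, (genes[key[1]],) + target)

    def best_move(self) -> tuple | None:
        best_key = None
        best_total = -np.inf
        ties: list[tuple] = []
        for key, (d_e, d_i) in self.cache.items():
            if d_e <= _TOL or d_i <= _TOL:
                continue
            total = d_e + d_i
            if total > best_total + _TOL:
                best_total = total
                best_key = key
                ties = [key]
            elif abs(total - best_total) <= _TOL:
                ties.append(key)
        if best_key is None:
            return None
        if len(ties) > 1:
            ties.sort(key=self._signature)
            best_key = ties[0]
        return best_key


def refine_clusters(
    state: ClusterState,
    adj: list[set[int]],
    max_iterations: int = 10_000,
    exact: bool = False,
) -> ClusterState:
    """Local search over merge/remove/switch moves under the dual-increase
    constraint; mutates and returns ``state`` with a populated move log.

    With ``exact=True`` every cluster pair and every (protein, cluster)
    switch is considered at each iteration; the default restricts proposals
    to clusters joined by at least one network edge, which covers every move
    whose interaction gain can be positive on the target side but may miss
    moves whose benefit comes purely from leaving a negative-scoring cluster.
    """
    engine = _MoveEngine(state, adj, exact=exact)
    iteration = len(state.move_log)
    while True:
        key = engine.best_move()
        if key is None:
            break
        iteration += 1
        kind, genes, d_e, d_i = engine.apply(key)
        state.move_log.append(MoveRecord(iteration, kind, genes, d_e, d_i))
        if iteration >= max_iterations:
            logger.warning("refine_clusters: iteration cap (%d) reached", max_iterations)
            break
    return state


def _discover_core(
    E: np.ndarray,
    I: np.ndarray,
    genes: list[str],
    net: InteractionNetwork,
    max_iterations: int,
) -> ClusterState:
    pairs = PairLLRTable(genes, E, I)
    candidates = enumerate_seeds(net, pairs)
    state = greedy_seed_clusters(candidates, pairs)
    adj = network_adjacency(net, pairs)
    return refine_clusters(state, adj, max_iterations=max_iterations)


@dataclass
class FDRCurve:
    """Empirical FDR as a function of the cluster-score threshold."""

    thresholds: np.ndarray  # ascending
    genes_real: np.ndarray
    mean_genes_random: np.ndarray
    fdr: np.ndarray  # regularized, non-increasing in threshold
    raw_fdr: np.ndarray
    n_randomizations: int
    seed: int

    def threshold_for(self, fdr_target: float) -> float | None:
        """Smallest threshold achieving ``fdr <= fdr_target`` (None if none)."""
        ok = np.flatnonzero(self.fdr <= fdr_target)
        if ok.size == 0:
            return None
        return float(self.thresholds[ok[0]])

    def estimated_fdr_at(self, threshold: float) -> float:
        idx = np.searchsorted(self.thresholds, threshold)
        idx = min(idx, len(self.thresholds) - 1)
        return float(self.fdr[idx])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "genes_real": self.genes_real,
                "mean_genes_random": self.mean_genes_random,
                "fdr": self.fdr,
                "raw_fdr": self.raw_fdr,
            }
        )


def _qualifying_clusters(state: ClusterState) -> list[tuple[int, float]]:
    """(size, llr_integrated) of clusters eligible for output."""
    out = []
    for _, members in state.multi_clusters():
        e, i, t = state.pairs.score_indices(members)
        if e > 0 and i > 0:
            out.append((len(members), t))
    return out


def estimate_fdr(
    corr: CorrelationTable,
    weighted_net: InteractionNetwork,
    expr_model: LLRModel,
    int_model: LLRModel,
    n_random: int = 100,
    seed: int = 0,
    real_state: ClusterState | None = None,
    genes: list[str] | None = None,
    max_iterations: int = 10_000,
) -> FDRCurve:
    """Empirical FDR by shuffling the gene-ID-to-profile assignment.

    Each randomization permutes which measured expression profile each gene
    carries (the network and the fitted LLR models stay fixed, so thresholds
    remain comparable), reruns the full seeding + refinement, and records how
    many genes land in qualifying clusters at each score threshold.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    if genes is None:
        genes = sorted(set(corr.genes) & weighted_net.nodes)
    table = score_pairs(corr, weighted_net, expr_model, int_model, genes)
    if real_state is None:
        candidates = enumerate_seeds(weighted_net, table)
        real_state = greedy_seed_clusters(candidates, table)
        adj = network_adjacency(weighted_net, table)
        refine_clusters(real_state, adj, max_iterations=max_iterations)
    real = _qualifying_clusters(real_state)

    # interaction channel is shared by all randomized runs
    I = table.llr_int
    measured_pos = np.array([corr.index[g] for g in genes if g in corr.index])
    gene_rows = [k for k, g in enumerate(genes) if g in corr.index]

    rng = np.random.default_rng(seed)
    random_clusters: list[list[tuple[int, float]]] = []
    for _ in range(n_random):
        perm = rng.permutation(len(corr.genes))
        mapped = perm[measured_pos]
        r_perm = corr.r[np.ix_(mapped, mapped)]
        E = np.zeros((len(genes), len(genes)))
        E[np.ix_(gene_rows, gene_rows)] = expression_llr_matrix(r_perm, expr_model)
        state = _discover_core(E, I, genes, weighted_net, max_iterations)
        random_clusters.append(_qualifying_clusters(state))

    thresholds = np.array(sorted({t for _, t in real}))
    if thresholds.size == 0:
        return FDRCurve(
            thresholds,
            np.array([]),
            np.array([]),
            np.array([]),
            np.array([]),
            n_random,
            seed,
        )
    genes_real = np.array(
        [sum(s for s, t in real if t >= thr) for thr in thresholds], dtype=float
    )
    mean_rand = np.array(
        [
            np.mean(
                [sum(s for s, t in rc if t >= thr) for rc in random_clusters]
            )
            for thr in thresholds
        ]
    )
    raw = np.where(genes_real > 0, mean_rand / np.maximum(genes_real, 1), np.nan)
    fdr = np.minimum.accumulate(raw)  # non-increasing in threshold
    return FDRCurve(thresholds, genes_real, mean_rand, fdr, raw, n_random, seed)


@dataclass
class DiscoveryResult:
    complexes: ComplexSet
    fdr_curve: FDRCurve
    state: ClusterState
    expr_model: LLRModel
    int_model: LLRModel
    pairs: PairLLRTable
    threshold: float | None

    def __iter__(self):
        # allows: complexes, fdr_curve = discover_complexes(...)
        return iter((self.complexes, self.fdr_curve))


def discover_complexes(
    expression: ExpressionMatrix,
    network: InteractionNetwork,
    reference: ComplexSet,
    config: DiscoveryConfig | None = None,
) -> DiscoveryResult:
    """End-to-end discovery: correlations -> edge weighting -> LLR
    calibration -> seeding -> refinement -> empirical FDR thresholding.

    Returns the complexes whose integrated LLR meets the smallest threshold
    achieving the configured FDR target, with per-complex score
    decompositions, plus the FDR curve and the full cluster state.
    """
    config = config or DiscoveryConfig()
    corr = pairwise_correlation(expression, min_overlap=config.min_overlap)
    weighted = weight_network(network)

    measured = expression.gene_ids
    expr_training = sample_training_pairs(
        reference,
        measured,
        corr,
        neg_ratio=config.neg_ratio,
        max_complex_size=config.max_complex_size,
        seed=config.seed,
    )
    expr_model = fit_llr_model(expr_training, kind="expression")
    int_training = sample_training_pairs(
        reference,
        measured,
        EdgeScoreFeatures(weighted),
        neg_ratio=config.neg_ratio,
        max_complex_size=config.max_complex_size,
        seed=config.seed + 1,
    )
    int_model = fit_llr_model(int_training, kind="interaction", transform="log1p")

    genes = sorted(set(corr.genes) & weighted.nodes)
    table = score_pairs(corr, weighted, expr_model, int_model, genes)
    candidates = enumerate_seeds(weighted, table)
    state = greedy_seed_clusters(candidates, table)
    adj = network_adjacency(weighted, table)
    refine_clusters(state, adj, max_iterations=config.max_iterations)

    curve = estimate_fdr(
        corr,
        weighted,
        expr_model,
        int_model,
        n_random=config.n_random,
        seed=config.seed + 2,
        real_state=state,
        genes=genes,
        max_iterations=config.max_iterations,
    )
    threshold = curve.threshold_for(config.fdr_target)
    if threshold is None:
        complexes = ComplexSet([], disjoint=True)
    else:
        complexes = state.to_complex_set(min_score=threshold, min_size=config.min_size)
    return DiscoveryResult(
        complexes, curve, state, expr_model, int_model, table, threshold
    )
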