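"""Calibration of per-pair evidence into additive log-likelihood ratios.

Each evidence channel (co-expression correlation; shared-partner interaction
score) is calibrated independently against a reference complex catalogue.
Positive training pairs are co-annotated in a reference complex (very large
complexes are excluded to avoid a handful of assemblies dominating the
training set); negatives are sampled at random from measured genes that are
not co-annotated, at a fixed prior ratio of negatives to positives.

A logistic regression of the label on the single feature gives the posterior
probability p(feature) of co-complex membership.  The log-likelihood ratio of
the observation under the co-complex model versus background follows from the
Bayes identity

    LLR(x) = logit(p(x)) - logit(prior) = beta0 + beta1 * x + ln(neg_ratio)

which equals log[P(x | co-complex) / P(x | background)] when the logistic
model is the true posterior.  This closed form avoids estimating the
background feature density by binning, and keeps the LLR monotone in the
feature.  LLRs from the two channels are additive; a pair lacking one
evidence source contributes zero from that source (neutral, not a penalty).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .preprocess import CorrelationTable
from .types import ComplexSet, InteractionNetwork

logger = logging.getLogger(__name__)

DEFAULT_NEG_RATIO = 300
DEFAULT_MAX_COMPLEX_SIZE = 30


@dataclass
class TrainingPairs:
    pairs: list[tuple[str, str]]
    features: np.ndarray
    labels: np.ndarray  # True = positive (co-complex)
    provenance: dict = field(default_factory=dict)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int((~self.labels).sum())


_TRANSFORMS = {
    "identity": lambda x: x,
    "log1p": np.log1p,
}


@dataclass
class LLRModel:
    """Single-feature logistic calibration of one evidence channel.

    ``transform`` is a fixed monotone map applied to the feature before the
    linear term (so the LLR stays monotone in the raw feature).  The
    correlation channel uses the identity; the shared-partner channel uses
    ``log1p``, because the first shared partner is a qualitative jump in
    evidence while further -log10(p) units add progressively less.
    """

    kind: str  # "expression" or "interaction"
    beta0: float
    beta1: float
    neg_ratio: float  # achieved negatives per positive in training
    feature_range: tuple[float, float]
    transform: str = "identity"

    def _t(self, feature):
        return _TRANSFORMS[self.transform](feature)

    def llr(self, feature: float) -> float:
        return self.beta0 + self.beta1 * self._t(feature) + np.log(self.neg_ratio)

    def llr_array(self, features: np.ndarray) -> np.ndarray:
        return self.beta0 + self.beta1 * self._t(features) + np.log(self.neg_ratio)

    def posterior(self, feature: float) -> float:
        from scipy.special import expit

        return float(expit(self.beta0 + self.beta1 * self._t(feature)))

    @property
    def prior(self) -> float:
        return 1.0 / (1.0 + self.neg_ratio)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "kind": self.kind,
                    "beta0": self.beta0,
                    "beta1": self.beta1,
                    "neg_ratio": self.neg_ratio,
                    "feature_range": list(self.feature_range),
                    "transform": self.transform,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LLRModel":
        d = json.loads(Path(path).read_text())
        return cls(
            kind=d["kind"],
            beta0=d["beta0"],
            beta1=d["beta1"],
            neg_ratio=d["neg_ratio"],
            feature_range=tuple(d["feature_range"]),
            transform=d.get("transform", "identity"),
        )


class EdgeScoreFeatures:
    """Total feature map for the interaction channel.

    The shared-partner score of a non-interacting pair is 0, the same value
    as an edge whose endpoints share no partners, so that the background
    (negative) class is drawn from *all* measured pairs rather than from
    edges only: being an edge at all is then part of the evidence the model
    calibrates.
    """

    def __init__(self, weighted_net: InteractionNetwork):
        self._scores = weighted_net.edge_scores

    def get(self, a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        return self._scores.get(key, 0.0)


def _lookup(features, a: str, b: str):
    """Feature of an unordered pair from a dict keyed by tuple/frozenset or
    an object with a ``get(a, b)`` method (e.g. CorrelationTable)."""
    if isinstance(features, CorrelationTable):
        return features.get(a, b)
    if isinstance(features, dict):
        value = features.get((a, b))
        if value is None:
            value = features.get((b, a))
        if value is None:
            value = features.get(frozenset((a, b)))
        return value
    return features.get(a, b)


def sample_training_pairs(
    reference: ComplexSet,
    measured_genes: Iterable[str],
    features,
    neg_ratio: int = DEFAULT_NEG_RATIO,
    max_complex_size: int = DEFAULT_MAX_COMPLEX_SIZE,
    seed: int = 0,
    candidate_negatives: Sequence[tuple[str, str]] | None = None,
) -> TrainingPairs:
    """Build a labelled training set for one evidence channel.

    Positives: pairs co-annotated in a reference complex of size at most
    ``max_complex_size``, both genes measured, feature defined.  Negatives:
    sampled without replacement from ``candidate_negatives`` if given
    (e.g. network edges for the interaction channel), otherwise from random
    pairs of measured genes; pairs co-annotated in *any* reference complex
    are never negatives.  Deterministic given ``seed``.
    """
    if len(reference) == 0:
        raise ValueError("reference catalogue is empty")
    measured = sorted(set(measured_genes))
    measured_set = set(measured)
    rng = np.random.default_rng(seed)

    all_co_annotated = reference.co_annotated_pairs(max_size=None)
    eligible = reference.co_annotated_pairs(max_size=max_complex_size)
    positives: list[tuple[str, str]] = []
    pos_features: list[float] = []
    n_skipped = 0
    for pair in sorted(eligible, key=sorted):
        a, b = sorted(pair)
        if a not in measured_set or b not in measured_set:
            continue
        feat = _lookup(features, a, b)
        if feat is None:
            n_skipped += 1
            continue
        positives.append((a, b))
        pos_features.append(float(feat))
    if n_skipped:
        logger.info("sample_training_pairs: skipped %d positive pair(s) without a feature", n_skipped)
    if not positives:
        raise ValueError(
            "no positive training pairs remain after the complex-size filter "
            "and feature coverage"
        )

    n_neg_target = neg_ratio * len(positives)
    negatives: list[tuple[str, str]] = []
    neg_features: list[float] = []
    if candidate_negatives is not None:
        pool = sorted(
            {tuple(sorted(p)) for p in candidate_negatives}
            - {tuple(sorted(p)) for p in positives}
        )
        pool = [
            p
            for p in pool
            if frozenset(p) not in all_co_annotated
            and p[0] in measured_set
            and p[1] in measured_set
            and _lookup(features, *p) is not None
        ]
        take = min(n_neg_target, len(pool))
        idx = rng.choice(len(pool), size=take, replace=False)
        for i in sorted(idx):
            a, b = pool[i]
            negatives.append((a, b))
            neg_features.append(float(_lookup(features, a, b)))
    else:
        seen: set[tuple[str, str]] = set()
        attempts = 0
        max_attempts = 60 * n_neg_target + 1000
        n_genes = len(measured)
        while len(negatives) < n_neg_target and attempts < max_attempts:
            attempts += 1
            i, j = rng.integers(0, n_genes, size=2)
            if i == j:
                continue
            a, b = (measured[i], measured[j]) if measured[i] < measured[j] else (measured[j], measured[i])
            if (a, b) in seen or frozenset((a, b)) in all_co_annotated:
                continue
            feat = _lookup(features, a, b)
            if feat is None:
                continue
            seen.add((a, b))
            negatives.append((a, b))
            neg_features.append(float(feat))
    if len(negatives) < n_neg_target:
        logger.warning(
            "sample_training_pairs: only %d of %d requested negatives available",
            len(negatives),
            n_neg_target,
        )
    if not negatives:
        raise ValueError("no negative training pairs available")

    pairs = positives + negatives
    feats = np.array(pos_features + neg_features, dtype=float)
    labels = np.array([True] * len(positives) + [False] * len(negatives))
    return TrainingPairs(
        pairs,
        feats,
        labels,
        provenance={
            "neg_ratio_requested": neg_ratio,
            "neg_ratio_achieved": len(negatives) / len(positives),
            "max_complex_size": max_complex_size,
            "seed": seed,
            "n_positive": len(positives),
            "n_negative": len(negatives),
        },
    )


def fit_llr_model(
    training: TrainingPairs, kind: str = "expression", transform: str = "identity"
) -> LLRModel:
    """Fit the single-feature logistic model for one evidence channel.

    Uses an essentially unpenalized fit; if the classes are (near-)separable
    the coefficients diverge, in which case a ridge-regularized fit is used
    instead (logged).  The stored ``neg_ratio`` is the achieved ratio of
    negatives to positives, which keeps the Bayes identity exact.
    """
    if training.n_positive == 0 or training.n_negative == 0:
        raise ValueError("both classes must be present to fit an LLR model")
    feats = _TRANSFORMS[transform](training.features)
    X = feats.reshape(-1, 1)
    y = training.labels.astype(int)
    spread = float(np.ptp(feats))
    if spread == 0.0:
        # feature carries no information: the posterior is the class prior
        # and the LLR is identically zero
        from scipy.special import logit

        logger.warning("fit_llr_model(%s): constant feature, LLR fixed at 0", kind)
        return LLRModel(
            kind=kind,
            beta0=float(logit(training.n_positive / len(training.labels))),
            beta1=0.0,
            neg_ratio=training.n_negative / training.n_positive,
            feature_range=(float(training.features.min()), float(training.features.max())),
            transform=transform,
        )

    model = LogisticRegression(C=1e6, solver="lbfgs", max_iter=2000)
    model.fit(X, y)
    beta1 = float(model.coef_[0, 0])
    # near-separation: slope diverges on the scale of the feature spread
    if spread > 0 and abs(beta1) * spread > 200:
        logger.warning(
            "fit_llr_model(%s): near-perfect separation, refitting with ridge penalty",
            kind,
        )
        model = LogisticRegression(C=1.0, solver="lbfgs", max_iter=2000)
        model.fit(X, y)
        beta1 = float(model.coef_[0, 0])
    beta0 = float(model.intercept_[0])
    return LLRModel(
        kind=kind,
        beta0=beta0,
        beta1=beta1,
        neg_ratio=training.n_negative / training.n_positive,
        feature_range=(float(training.features.min()), float(training.features.max())),
        transform=transform,
    )


class PairLLRTable:
    """Per-pair LLRs over a fixed gene universe, stored as dense matrices.

    ``llr_expr[i, j]`` is the expression LLR of genes i and j (0 where the
    correlation is undefined), ``llr_int[i, j]`` the interaction LLR (0 for
    non-edges).  The integrated LLR of a pair is the sum of the two.
    """

    def __init__(self, genes: list[str], llr_expr: np.ndarray, llr_int: np.ndarray):
        self.genes = list(genes)
        self.index = {g: i for i, g in enumerate(self.genes)}
        self.llr_expr = llr_expr
        self.llr_int = llr_int

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def get(self, a: str, b: str) -> tuple[float, float]:
        ia, ib = self.index[a], self.index[b]
        return float(self.llr_expr[ia, ib]), float(self.llr_int[ia, ib])

    def score_indices(self, idx: Sequence[int]) -> tuple[float, float, float]:
        """Summed (llr_expr, llr_int, llr_integrated) over all unordered pairs."""
        if len(idx) < 2:
            return 0.0, 0.0, 0.0
        ix = np.asarray(idx)
        e = float(self.llr_expr[np.ix_(ix, ix)].sum() / 2.0)
        i = float(self.llr_int[np.ix_(ix, ix)].sum() / 2.0)
        return e, i, e + i

    def score_set(self, genes: Iterable[str]) -> tuple[float, float, float]:
        return self.score_indices([self.index[g] for g in genes])

    def to_frame(self):
        import pandas as pd

        ii, jj = np.triu_indices(self.n_genes, k=1)
        mask = (self.llr_expr[ii, jj] != 0) | (self.llr_int[ii, jj] != 0)
        ii, jj = ii[mask], jj[mask]
        return pd.DataFrame(
            {
                "gene_a": [self.genes[i] for i in ii],
                "gene_b": [self.genes[j] for j in jj],
                "llr_expr": self.llr_expr[ii, jj],
                "llr_int": self.llr_int[ii, jj],
                "llr_integrated": self.llr_expr[ii, jj] + self.llr_int[ii, jj],
            }
        )


def expression_llr_matrix(
    corr_r: np.ndarray, expr_model: LLRModel
) -> np.ndarray:
    """Expression LLR matrix from a correlation matrix; NaN r maps to 0."""
    defined = np.isfinite(corr_r)
    E = np.where(defined, expr_model.llr_array(np.nan_to_num(corr_r)), 0.0)
    np.fill_diagonal(E, 0.0)
    return E


def score_pairs(
    corr: CorrelationTable,
    weighted_net: InteractionNetwork,
    expr_model: LLRModel,
    int_model: LLRModel,
    genes: Sequence[str] | None = None,
) -> PairLLRTable:
    """Assemble the PairLLRTable over ``genes`` (default: genes present in
    both the correlation table and the network)."""
    if genes is None:
        genes = sorted(set(corr.genes) & weighted_net.nodes)
    genes = list(genes)
    index = {g: i for i, g in enumerate(genes)}
    n = len(genes)

    # expression channel
    corr_idx = [corr.index.get(g) for g in genes]
    have_corr = [i for i, ci in enumerate(corr_idx) if ci is not None]
    E = np.zeros((n, n))
    if have_corr:
        sub = np.array([corr_idx[i] for i in have_corr])
        r_sub = corr.r[np.ix_(sub, sub)]
        e_sub = expression_llr_matrix(r_sub, expr_model)
        E[np.ix_(have_corr, have_corr)] = e_sub

    # interaction channel
    I = np.zeros((n, n))
    for (a, b), score in weighted_net.edge_scores.items():
        ia, ib = index.get(a), index.get(b)
        if ia is None or ib is None:
            continue
        value = int_model.llr(score)
        I[ia, ib] = I[ib, ia] = value
    return PairLLRTable(genes, E, I)
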