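"""Prior-constrained gradient-boosting inference of a signed TF -> target network.

For each target gene, a least-squares gradient-boosted tree ensemble is fit
on the expression of the target's candidate TFs (its parents in the active
binding network) augmented with "shadow" features — row-permuted copies of
the real TF columns that carry the same marginal distribution but no signal.
A candidate edge survives only if its cumulative impurity-reduction
importance exceeds the largest shadow importance for that target; this
permutation-null gate is what prunes prior edges unsupported by expression.
Edge signs come from the Spearman correlation between TF and target, and
regulons are the per-TF target sets split by sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingRegressor

from .binding import BindingNetwork
from .types import ExpressionMatrix, ValidationError

logger = logging.getLogger("matam")


@dataclass
class InferenceConfig:
    """Boosting and regulon-assembly hyperparameters.

    All desk-scale defaults: 200 depth-2 trees with shrinkage 0.05 and 0.9
    row subsampling per target. ``n_shadow_features`` defaults to 8x the
    number of candidate TFs for the target, capped at ``shadow_cap``:
    shadows must clearly outnumber real candidates, otherwise a pure-noise
    target beats the max-shadow gate half the time by exchangeability.
    """

    n_trees: int = 200
    tree_depth: int = 2
    shrinkage: float = 0.05
    row_subsample: float = 0.9
    n_shadow_features: int | None = None
    shadow_multiple: int = 8
    shadow_cap: int = 64
    min_regulon_size: int = 10
    max_regulon_size: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.shrinkage <= 1):
            raise ValidationError("shrinkage must lie in (0, 1]")
        if self.tree_depth < 1:
            raise ValidationError("tree_depth must be >= 1")
        if not (0 < self.row_subsample <= 1):
            raise ValidationError("row_subsample must lie in (0, 1]")


@dataclass
class RegulatoryNetwork:
    """Weighted, signed TF -> target edges with the config that produced them."""

    edges: list[tuple[str, str, float, int]]  # (tf, target, weight, sign)
    config: InferenceConfig | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        seen = set()
        for tf, target, weight, sign in self.edges:
            if not np.isfinite(weight) or weight < 0:
                raise ValidationError(f"edge {tf}->{target} has invalid weight {weight}")
            if sign not in (1, -1):
                raise ValidationError(f"edge {tf}->{target} has invalid sign {sign}")
            if (tf, target) in seen:
                raise ValidationError(f"duplicate edge {tf}->{target}")
            seen.add((tf, target))

    def sorted_edges(self) -> list[tuple[str, str, float, int]]:
        return sorted(self.edges, key=lambda e: (e[0], e[1]))

    def edges_by_tf(self) -> dict[str, list[tuple[str, float, int]]]:
        out: dict[str, list[tuple[str, float, int]]] = {}
        for tf, target, weight, sign in self.edges:
            out.setdefault(tf, []).append((target, weight, sign))
        return out

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class Regulon:
    """A TF's inferred targets split by regulation sign."""

    tf: str
    positive_targets: frozenset[str]
    negative_targets: frozenset[str]

    def __post_init__(self) -> None:
        if self.positive_targets & self.negative_targets:
            raise ValidationError(f"regulon {self.tf}: overlapping signed target sets")

    def __len__(self) -> int:
        return len(self.positive_targets) + len(self.negative_targets)


def rank_tf_importance(
    target_expr: np.ndarray,
    tf_expr: pd.DataFrame,
    config: InferenceConfig | None = None,
    seed: int = 0,
) -> tuple[pd.Series, np.ndarray]:
    """Boosted-tree importance of each candidate TF for one target.

    ``tf_expr`` is samples x TFs. Returns (importances indexed by TF,
    shadow importances). Importances are the ensemble's cumulative
    squared-error-reduction shares; real and shadow features are normalized
    jointly, so real importances are non-negative and sum to <= 1 with the
    remainder attributed to shadows. A constant target yields a zero vector
    with a warning.
    """
    config = config or InferenceConfig()
    y = np.asarray(target_expr, dtype=float)
    n_samples, n_tfs = tf_expr.shape
    if n_samples < 5:
        raise ValidationError("boosting needs >= 5 samples")
    if n_tfs < 1:
        raise ValidationError("need >= 1 candidate TF")
    n_shadow = config.n_shadow_features
    if n_shadow is None:
        n_shadow = min(config.shadow_multiple * n_tfs, config.shadow_cap)
    if np.ptp(y) == 0:
        logger.warning("constant target: returning zero importances")
        return pd.Series(0.0, index=tf_expr.columns), np.zeros(n_shadow)

    rng = np.random.default_rng(seed)

    X_real = tf_expr.to_numpy(dtype=float)
    shadow_cols = []
    for k in range(n_shadow):
        col = X_real[:, k % n_tfs].copy()
        rng.shuffle(col)
        shadow_cols.append(col)
    X = np.column_stack([X_real] + shadow_cols) if shadow_cols else X_real

    model = GradientBoostingRegressor(
        loss="squared_error",
        n_estimators=config.n_trees,
        max_depth=config.tree_depth,
        learning_rate=config.shrinkage,
        subsample=config.row_subsample,
        random_state=int(rng.integers(2**31 - 1)),
    )
    model.fit(X, y)
    imp = model.feature_importances_
    real = pd.Series(imp[:n_tfs], index=tf_expr.columns)
    shadows = imp[n_tfs:]
    return real, shadows


def infer_network(
    expr: ExpressionMatrix,
    abn: BindingNetwork,
    config: InferenceConfig | None = None,
) -> RegulatoryNetwork:
    """Infer weighted edges for every target with >= 1 prior parent.

    Per target, candidate TFs are its ABN parents present in the matrix; an
    edge is kept iff its importance exceeds the target's maximum shadow
    importance. Targets with no ABN parent in the matrix are skipped and
    logged. Deterministic given (expr, abn, config.seed).
    """
    config = config or InferenceConfig()
    if abn.n_edges == 0:
        raise ValidationError("empty active binding network")

    parents_by_target: dict[str, list[str]] = {}
    for tf in abn.tfs:
        for target in abn.targets_of(tf):
            parents_by_target.setdefault(target, []).append(tf)

    genes = set(expr.genes)
    data_t = expr.data.T  # samples x genes
    edges: list[tuple[str, str, float, int]] = []
    root = np.random.SeedSequence(config.seed)
    skipped = 0
    targets = sorted(parents_by_target)
    seeds = root.generate_state(len(targets)) % (2**31 - 1)
    for target, sub_seed in zip(targets, seeds):
        parents = sorted(p for p in parents_by_target[target] if p in genes and p != target)
        if target not in genes or not parents:
            skipped += 1
            continue
        imp, shadows = rank_tf_importance(
            data_t[target].to_numpy(), data_t[parents], config, seed=int(sub_seed)
        )
        gate = shadows.max() if len(shadows) else 0.0
        for tf, weight in imp.items():
            if weight > gate:
                edges.append((tf, target, float(weight), 1))
    if skipped:
        logger.info("%d targets skipped (absent from matrix or no usable parent)", skipped)
    logger.info("inferred network: %d edges from %d candidate prior edges",
                len(edges), abn.n_edges)
    net = RegulatoryNetwork(edges=edges, config=config, seed=config.seed)
    return assign_edge_signs(net, expr)


def assign_edge_signs(net: RegulatoryNetwork, expr: ExpressionMatrix) -> RegulatoryNetwork:
    """Sign each edge by the Spearman correlation of TF and target expression.

    An exact zero correlation is assigned +1 and logged.
    """
    signed = []
    data = expr.data
    for tf, target, weight, _ in net.edges:
        rho = stats.spearmanr(data.loc[tf], data.loc[target]).statistic
        if rho == 0 or np.isnan(rho):
            logger.info("edge %s->%s has zero Spearman correlation; sign set to +1",
                        tf, target)
            sign = 1
        else:
            sign = 1 if rho > 0 else -1
        signed.append((tf, target, weight, sign))
    return RegulatoryNetwork(edges=signed, config=net.config, seed=net.seed)


def build_regulons(
    net: RegulatoryNetwork, config: InferenceConfig | None = None
) -> list[Regulon]:
    """Per-TF signed target sets, weight-truncated and size-filtered.

    Targets are sorted by weight descending (ties by target id), truncated
    at ``max_regulon_size``, then split by sign. TFs whose truncated regulon
    is smaller than ``min_regulon_size`` are excluded and logged.
    """
    config = config or InferenceConfig()
    regulons = []
    for tf, targets in sorted(net.edges_by_tf().items()):
        ranked = sorted(targets, key=lambda t: (-t[1], t[0]))[: config.max_regulon_size]
        if len(ranked) < config.min_regulon_size:
            logger.info("TF %s excluded: regulon size %d < %d",
                        tf, len(ranked), config.min_regulon_size)
            continue
        pos = frozenset(t for t, _, s in ranked if s > 0)
        neg = frozenset(t for t, _, s in ranked if s < 0)
        regulons.append(Regulon(tf, pos, neg))
    if not regulons:
        raise ValidationError("no regulon passes the size filter")
    return regulons
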