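"""Single-sample signature scores, regulator activity, and group comparisons.

The scorer is the mean of gene-wise z-scores: each gene row of the
log2(RPKM+1) matrix is standardized across samples, and a sample's score
for a gene set is the mean standardized value over set genes present in the
matrix. Master-regulator activity is the sign-aware variant: mean z over
positively regulated targets minus mean z over negatively regulated ones.
Both are deterministic and monotone-equivalent to rank-based single-sample
scorers for the stratification they feed.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix, GeneSet, ScoreTable, ValidationError
from .types import LOG2P1

logger = logging.getLogger("matam")


def _gene_zscores(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene z across samples (ddof=1); constant genes dropped with warning."""
    if expr.space != LOG2P1:
        raise ValidationError("scoring expects a log2p1-space matrix")
    if expr.shape[1] < 2:
        raise ValidationError("gene-wise z-scores need >= 2 samples")
    values = expr.data
    sd = values.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant genes excluded from z-scoring", int(constant.sum()))
    values = values.loc[~constant]
    return values.sub(values.mean(axis=1), axis=0).div(sd[~constant], axis=0)


def single_sample_score(expr: ExpressionMatrix, gene_set: GeneSet) -> ScoreTable:
    """Mean gene-wise z over the set genes present in the matrix."""
    z = _gene_zscores(expr)
    used = z.index.intersection(sorted(gene_set.members))
    if len(used) == 0:
        raise ValidationError(
            f"gene set {gene_set.name!r} shares no non-constant genes with the matrix"
        )
    scores = z.loc[used].mean(axis=0)
    logger.info("score %s: %d/%d set genes used", gene_set.name, len(used), len(gene_set))
    return ScoreTable(scores, score_name=gene_set.name, method="mean_z",
                      n_genes_used=len(used))


def regulator_activity(expr: ExpressionMatrix, regulon) -> ScoreTable:
    """Sign-aware activity: mean z(positive targets) - mean z(negative targets).

    If the regulon has no negative targets the second term is zero. Requires
    at least one positive target present in the matrix.
    """
    z = _gene_zscores(expr)
    pos = z.index.intersection(sorted(regulon.positive_targets))
    neg = z.index.intersection(sorted(regulon.negative_targets))
    if len(pos) == 0:
        raise ValidationError(
            f"regulon {regulon.tf!r}: no positive targets present in matrix"
        )
    activity = z.loc[pos].mean(axis=0)
    if len(neg):
        activity = activity - z.loc[neg].mean(axis=0)
    return ScoreTable(activity, score_name=f"{regulon.tf}_activity", method="mean_z",
                      n_genes_used=len(pos) + len(neg))


def stratify_samples(scores: ScoreTable, rule: str = "median") -> pd.Series:
    """Assign 'high'/'low' labels by median or tertile cut.

    Median rule: score > median -> high, else low (ties at the cut go low);
    covers all samples. Tertile rule: upper third high, lower third low,
    middle excluded (label 'mid' dropped from the result).
    """
    s = scores.scores
    if len(s) < 2:
        raise ValidationError("stratification needs >= 2 samples")
    if s.nunique() == 1:
        raise ValidationError("all scores equal: no stratification possible")
    if rule == "median":
        cut = s.median()
        return pd.Series(np.where(s > cut, "high", "low"), index=s.index, name="group")
    if rule == "tertile":
        # order statistics, not interpolated quantiles: with n distinct
        # scores exactly floor(n/3) samples fall in each outer group
        k = len(s) // 3
        a = np.sort(s.to_numpy())
        hi_cut = a[len(s) - k - 1]   # largest value NOT in the top k
        lo_cut = a[k]                # smallest value NOT in the bottom k
        labels = pd.Series("mid", index=s.index, name="group")
        labels[s > hi_cut] = "high"
        labels[s < lo_cut] = "low"
        return labels[labels != "mid"]
    raise ValidationError(f"unknown stratification rule {rule!r}")


def score_correlation(a: ScoreTable, b: ScoreTable) -> tuple[float, float]:
    """Pearson r and two-sided p (t distribution, n-2 df) on shared samples."""
    shared = a.samples.intersection(b.samples)
    if len(shared) < 3:
        raise ValidationError("correlation needs >= 3 shared samples")
    x = a.scores.loc[shared].to_numpy()
    y = b.scores.loc[shared].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant score vector: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def longitudinal_shift_analysis(
    pairs: pd.DataFrame,
    transition_labels: Mapping[str, str] | pd.Series,
) -> tuple[pd.Series, float, float]:
    """Per-pair score shifts and a Welch t comparing transition groups.

    ``pairs`` needs columns ``pair_id``, ``timepoint`` ('primary' or
    'recurrent') and ``score``; every pair must be complete.
    ``transition_labels`` maps pair_id to a group (e.g. 'mesenchymal' vs
    'non_mesenchymal'). Returns (deltas indexed by pair_id, t, p); the
    degenerate all-identical case reports (t=0, p=1) so that permutation
    loops remain well-defined.
    """
    required = {"pair_id", "timepoint", "score"}
    if not required <= set(pairs.columns):
        raise ValidationError(f"pairs table needs columns {sorted(required)}")
    labels = pd.Series(dict(transition_labels)) if not isinstance(
        transition_labels, pd.Series) else transition_labels

    deltas = {}
    incomplete = []
    for pid, grp in pairs.groupby("pair_id"):
        tp = grp.set_index("timepoint")["score"]
        if not {"primary", "recurrent"} <= set(tp.index):
            incomplete.append(pid)
            continue
        deltas[pid] = float(tp["recurrent"] - tp["primary"])
    if incomplete:
        raise ValidationError(f"incomplete longitudinal pairs: {incomplete}")
    deltas = pd.Series(deltas, name="delta")

    groups = labels.loc[deltas.index]
    names = sorted(groups.unique())
    if len(names) != 2:
        raise ValidationError("longitudinal comparison needs exactly 2 groups")
    g1 = deltas[groups == names[0]].to_numpy()
    g2 = deltas[groups == names[1]].to_numpy()
    if len(g1) < 2 or len(g2) < 2:
        raise ValidationError("each transition group needs >= 2 pairs")
    if np.ptp(g1) == 0 and np.ptp(g2) == 0 and g1.mean() == g2.mean():
        return deltas, 0.0, 1.0
    t, p = stats.ttest_ind(g2, g1, equal_var=False)
    return deltas, float(t), float(p)


def group_score_comparison(
    scores: ScoreTable, groups: Mapping[str, str] | pd.Series
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA across >= 2 groups plus BH-adjusted pairwise Welch t.

    Returns (F, p, pairwise table with columns group_a/group_b/t/p/q).
    """
    g = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    shared = scores.samples.intersection(g.index)
    s = scores.scores.loc[shared]
    g = g.loc[shared]
    names = sorted(g.unique())
    if len(names) < 2:
        raise ValidationError("group comparison needs >= 2 groups")
    arrays = []
    for name in names:
        arr = s[g == name].to_numpy()
        if len(arr) < 2:
            raise ValidationError(f"group {name!r} has n < 2")
        arrays.append(arr)
    if all(np.ptp(a) == 0 for a in arrays) and len({a.mean() for a in arrays}) == 1:
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = stats.f_oneway(*arrays)
        if np.isnan(f_stat):  # zero within-group variance, identical means
            f_stat, p_val = 0.0, 1.0
    from statsmodels.stats.multitest import multipletests

    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            t, p = stats.ttest_ind(arrays[i], arrays[j], equal_var=False)
            rows.append((names[i], names[j], float(t), float(p)))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "t", "p"])
    pairwise["q"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    return float(f_stat), float(p_val), pairwise
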