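"""Outcome statistics: Kaplan-Meier stratification, alteration enrichment,
and limiting-dilution clonogenic frequency.

Kaplan-Meier curves and the log-rank test are delegated to lifelines; the
2x2 alteration tests use Fisher's exact test (two-sided by the
point-probability method, i.e. the sum of table probabilities no larger
than the observed one) with a Haldane-Anscombe-corrected odds ratio when a
cell is zero. The limiting-dilution estimator fits the single-hit Poisson
model ln(fraction of negative wells) = -f * dose by least squares through
the origin, the model underlying extreme limiting dilution analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .scoring import single_sample_score, stratify_samples
from .signature import log_transform
from .types import (
    AlterationMatrix,
    ExpressionMatrix,
    GeneSet,
    LINEAR_RPKM,
    SurvivalTable,
    ValidationError,
)

logger = logging.getLogger("matam")


@dataclass
class KMCurve:
    """Product-limit survival estimate for one group."""

    event_times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    group: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.event_times) < 0):
            raise ValidationError("event times must be ascending")
        s = self.survival
        if len(s) and (np.any(np.diff(s) > 1e-12) or s[0] > 1 + 1e-12 or s[-1] < -1e-12):
            raise ValidationError("survival curve must be non-increasing within [0, 1]")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.event_times, "survival": self.survival,
             "n_at_risk": self.n_at_risk}
        )


@dataclass
class LDAResult:
    """Clonogenic (stem-cell) frequency from a limiting-dilution assay."""

    frequency: float
    ci_low: float
    ci_high: float
    doses_used: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (0 <= self.frequency <= 1):
            raise ValidationError("frequency must lie in [0, 1]")

    @property
    def one_over_frequency(self) -> float:
        """The '1/stem cell frequency' convention (cells per clonogenic cell)."""
        return 1.0 / self.frequency if self.frequency > 0 else np.inf


def km_estimate(records: SurvivalTable, group: str = "") -> KMCurve:
    """Kaplan-Meier product-limit estimator for one group of records.

    Individuals censored exactly at an event time are counted at risk for
    that time (the standard convention; lifelines implements it).
    """
    if len(records.table) == 0:
        raise ValidationError("no survival records")
    kmf = KaplanMeierFitter()
    kmf.fit(records.table["time"], records.table["event"])
    event_times = np.sort(records.table.loc[records.table["event"] == 1, "time"].unique())
    if len(event_times) == 0:  # all censored: survival identically 1
        return KMCurve(np.array([]), np.array([]), np.array([]), group=group)
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    at_risk = np.array(
        [(records.table["time"] >= t).sum() for t in event_times], dtype=int
    )
    return KMCurve(event_times, surv, at_risk, group=group)


def logrank_test(group_a: SurvivalTable, group_b: SurvivalTable) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, 1-df p-value)."""
    ta, tb = group_a.table, group_b.table
    if len(ta) == 0 or len(tb) == 0:
        raise ValidationError("both groups must be non-empty")
    if ta["event"].sum() + tb["event"].sum() == 0:
        raise ValidationError("log-rank test needs at least one event")
    res = _ll_logrank(ta["time"], tb["time"], ta["event"], tb["event"])
    return float(res.test_statistic), float(res.p_value)


def survival_by_signature(
    expr: ExpressionMatrix,
    signature: GeneSet,
    records: SurvivalTable,
    rule: str = "median",
) -> tuple[pd.Series, dict[str, KMCurve], tuple[float, float]]:
    """Score -> stratify -> KM per group -> log-rank, end to end.

    Returns (group labels, {'high': KMCurve, 'low': KMCurve},
    (chi_square, p)).
    """
    if expr.space == LINEAR_RPKM:
        expr = log_transform(expr)
    scores = single_sample_score(expr, signature)
    shared = scores.samples.intersection(records.samples)
    if len(shared) < 4:
        raise ValidationError("need >= 4 samples shared by scores and survival records")
    from .types import ScoreTable

    groups = stratify_samples(
        ScoreTable(scores.scores.loc[shared], scores.score_name,
                   n_genes_used=scores.n_genes_used),
        rule=rule,
    )
    curves = {}
    tables = {}
    for name in ("high", "low"):
        members = groups.index[groups == name]
        if len(members) == 0:
            raise ValidationError(f"stratification produced an empty {name!r} group")
        tables[name] = SurvivalTable(records.table.loc[members], records.time_unit)
        curves[name] = km_estimate(tables[name], group=name)
    chi2, p = logrank_test(tables["high"], tables["low"])
    logger.info("signature survival split: chi2=%.3f p=%.3g (%d high / %d low)",
                chi2, p, (groups == "high").sum(), (groups == "low").sum())
    return groups, curves, (chi2, p)


def _odds_ratio(table: np.ndarray) -> float:
    """Sample odds ratio; Haldane-Anscombe +0.5 applied when any cell is 0."""
    t = table.astype(float)
    if (t == 0).any():
        t = t + 0.5
    return float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))


def alteration_enrichment(
    calls: AlterationMatrix,
    groups: Mapping[str, str] | pd.Series,
    pathways: Sequence[GeneSet] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene Fisher tests of alteration vs group, plus pathway fractions.

    ``groups`` maps sample id to 'high'/'low'. Per gene, the 2x2 table is
    (altered x group); two-sided Fisher exact p with BH q across genes.
    Per pathway, the aggregate is the fraction of samples in each group
    altered in at least one member gene.
    """
    g = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    shared = calls.samples.intersection(g.index)
    g = g.loc[shared]
    names = sorted(g.unique())
    if len(names) != 2:
        raise ValidationError("alteration enrichment needs exactly 2 groups")
    idx_a = g.index[g == names[0]]
    idx_b = g.index[g == names[1]]
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValidationError("empty group in alteration enrichment")

    rows = []
    for gene in calls.genes:
        alt = calls.calls.loc[gene]
        a1 = int(alt[idx_a].sum())
        b1 = int(alt[idx_b].sum())
        table = np.array([[a1, b1], [len(idx_a) - a1, len(idx_b) - b1]])
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append((gene, _odds_ratio(table), float(p),
                     a1 / len(idx_a), b1 / len(idx_b)))
    per_gene = pd.DataFrame(
        rows, columns=["gene", "odds_ratio", "p",
                       f"frac_{names[0]}", f"frac_{names[1]}"]
    ).set_index("gene")
    per_gene["q"] = multipletests(per_gene["p"], method="fdr_bh")[1]

    path_rows = []
    for gs in pathways:
        members = calls.genes.intersection(sorted(gs.members))
        if len(members) == 0:
            logger.warning("pathway %s has no gene in the alteration matrix", gs.name)
            continue
        any_alt = calls.calls.loc[members].max(axis=0)
        path_rows.append((gs.name,
                          float(any_alt[idx_a].mean()),
                          float(any_alt[idx_b].mean())))
    per_pathway = pd.DataFrame(
        path_rows, columns=["pathway", f"frac_{names[0]}", f"frac_{names[1]}"]
    ).set_index("pathway") if path_rows else pd.DataFrame()
    return per_gene, per_pathway


def limiting_dilution_frequency(
    doses: Sequence[float],
    wells_total: Sequence[int],
    wells_negative: Sequence[int],
) -> LDAResult:
    """Single-hit Poisson estimate of clonogenic frequency.

    Under the single-hit model a well seeded with ``d`` cells is negative
    (no sphere) with probability exp(-f*d), so ln(fraction negative) is
    linear in dose through the origin with slope -f. Doses where every
    well or no well is negative carry no slope information on the log
    scale and are excluded with a warning. The Wald CI is computed on
    log f with a delta-method variance for each log-fraction and
    inverse-variance weighting.
    """
    doses = np.asarray(doses, dtype=float)
    total = np.asarray(wells_total, dtype=float)
    neg = np.asarray(wells_negative, dtype=float)
    if len(doses) < 2:
        raise ValidationError("limiting dilution needs >= 2 doses")
    if np.any(neg > total) or np.any(doses <= 0) or np.any(total <= 0):
        raise ValidationError("invalid limiting-dilution counts")

    frac = neg / total
    usable = (frac > 0) & (frac < 1)
    if not usable.any():
        raise ValidationError(
            "all doses are degenerate (0% or 100% negative wells); "
            "frequency is not identifiable"
        )
    if (~usable).any():
        logger.warning("excluding %d degenerate dose(s) from the LDA fit",
                       int((~usable).sum()))
    d = doses[usable]
    y = np.log(frac[usable])
    # least squares through the origin: y = -f * d
    f = float(-(d @ y) / (d @ d))
    f = min(max(f, 0.0), 1.0)

    # delta-method variance of each log-fraction, then weighted variance of f
    var_y = (1 - frac[usable]) / (total[usable] * frac[usable])
    with np.errstate(divide="ignore"):
        var_f = 1.0 / np.sum(d**2 / var_y)
    if f > 0 and np.isfinite(var_f):
        se_log_f = np.sqrt(var_f) / f
        ci_low = f * np.exp(-1.96 * se_log_f)
        ci_high = f * np.exp(1.96 * se_log_f)
    else:
        ci_low, ci_high = 0.0, 1.0
    return LDAResult(f, float(ci_low), float(min(ci_high, 1.0)),
                     tuple(doses[usable]))
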