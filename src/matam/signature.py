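"""Three-stage extraction of the macrophage (TAM) gene signature.

Stage 1 — expression floor: log2(RPKM+1)-transform the TAM matrix and drop
genes whose maximum transformed value across samples falls below a floor
(default 1, i.e. never reaching 1 RPKM).

Stage 2 — activity correlation: score each matched tumor sample for
mesenchymal activity (mean z over a mesenchymal reference gene set) and
keep TAM genes whose expression across matched samples correlates with
that activity (Pearson r > r_min and two-sided P < p_max, both strict).

Stage 3 — stromal filter: retain only candidates that behave like bona fide
tumor-associated stromal/immune genes in two-compartment PDX profiles —
expressed in the stromal compartment (mean log2 >= stromal_min_log2) and
enriched over the tumor compartment (mean difference >= stromal_delta_min_log2,
i.e. >= 2-fold in linear scale at the defaults).

The surviving genes are the signature; per-stage survivor counts are
reported so the filter ladder is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import single_sample_score
from .types import (
    ExpressionMatrix,
    GeneSet,
    LINEAR_RPKM,
    LOG2P1,
    ScoreTable,
    ValidationError,
)

logger = logging.getLogger("matam")


@dataclass
class SignatureConfig:
    """Thresholds of the three-stage signature filter.

    expression_floor
        Minimum per-gene maximum of log2(RPKM+1); genes with max below the
        floor are removed (equality kept).
    r_min, p_max
        Strict correlation thresholds for stage 2 (defaults 0.7 and 0.05).
    stromal_min_log2, stromal_delta_min_log2
        Stage-3 thresholds: minimum stromal-compartment mean log2 and
        minimum stromal-minus-tumor mean difference.
    restrict_to_condition
        Optional condition label; when set, the activity correlation uses
        only matched pairs whose TAM sample carries this condition.
    """

    expression_floor: float = 1.0
    r_min: float = 0.7
    p_max: float = 0.05
    stromal_min_log2: float = 1.0
    stromal_delta_min_log2: float = 1.0
    restrict_to_condition: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.r_min < 1):
            raise ValidationError("r_min must lie in (0, 1)")
        for v in (self.expression_floor, self.p_max,
                  self.stromal_min_log2, self.stromal_delta_min_log2):
            if not np.isfinite(v):
                raise ValidationError("signature thresholds must be finite")


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """log2(RPKM + 1) transform; errors if the matrix is already in log space."""
    if expr.space != LINEAR_RPKM:
        raise ValidationError("matrix is already log-transformed")
    return ExpressionMatrix(np.log2(expr.data + 1.0), space=LOG2P1)


def filter_low_expression(expr: ExpressionMatrix, floor: float = 1.0) -> ExpressionMatrix:
    """Keep genes with max log2(RPKM+1) >= floor (strict removal below)."""
    if expr.space != LOG2P1:
        raise ValidationError("expression floor applies to log2p1 matrices")
    keep = expr.data.max(axis=1) >= floor
    if not keep.any():
        raise ValidationError("no gene survives the expression floor")
    logger.info("expression floor %.3g: %d of %d genes retained",
                floor, int(keep.sum()), len(keep))
    return ExpressionMatrix(expr.data.loc[keep], space=LOG2P1)


def mesenchymal_activity(
    tumor_expr: ExpressionMatrix, mesenchymal_set: GeneSet
) -> ScoreTable:
    """Per-tumor-sample mesenchymal activity: mean z over the reference set."""
    return single_sample_score(tumor_expr, mesenchymal_set)


def gene_activity_correlation(
    tam_expr: ExpressionMatrix,
    activity: ScoreTable,
    pairing: pd.Series,
) -> pd.DataFrame:
    """Per-gene Pearson correlation of TAM expression with tumor activity.

    ``pairing`` maps each TAM sample id to its matched tumor sample id
    (explicit key, never column order). Returns a DataFrame indexed by gene
    with columns r, p, n; constant genes get r = NaN and are never
    selectable downstream.
    """
    tam_samples = [s for s in tam_expr.samples if s in pairing.index]
    if not tam_samples:
        raise ValidationError("no TAM sample has a matched tumor sample in the pairing")
    tumor_samples = pairing.loc[tam_samples]
    missing = [t for t in tumor_samples if t not in activity.samples]
    if missing:
        raise ValidationError(f"matched tumor samples missing activity scores: {missing}")
    n = len(tam_samples)
    if n < 3:
        raise ValidationError("activity correlation needs >= 3 matched pairs")

    x = tam_expr.data[tam_samples].to_numpy()          # genes x n
    y = activity.scores.loc[tumor_samples].to_numpy()  # n

    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = xc.std(axis=1, ddof=1)
    sy = yc.std(ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / ((n - 1) * sx * sy)
    r = np.where(sx == 0, np.nan, np.clip(r, -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) == 1.0, 0.0, p)
    return pd.DataFrame({"r": r, "p": p, "n": n}, index=tam_expr.genes)


def select_correlated_genes(stats_table: pd.DataFrame, config: SignatureConfig) -> GeneSet:
    """Genes with r > r_min and p < p_max (both strict); NaN r never selected."""
    if stats_table.empty:
        raise ValidationError("empty correlation table")
    mask = (stats_table["r"] > config.r_min) & (stats_table["p"] < config.p_max)
    mask &= stats_table["r"].notna()
    selected = stats_table.index[mask]
    if len(selected) == 0:
        raise ValidationError(
            "no gene passes the correlation thresholds; review r_min/p_max"
        )
    logger.info("correlation filter (r > %.2f, p < %.3g): %d genes selected",
                config.r_min, config.p_max, len(selected))
    return GeneSet("activity_correlated", frozenset(selected))


def stromal_filter(
    candidates: GeneSet,
    pdx_stromal: ExpressionMatrix,
    pdx_tumor: ExpressionMatrix,
    config: SignatureConfig,
) -> GeneSet:
    """Keep candidates expressed in stroma and enriched over the tumor compartment."""
    if pdx_stromal.space != LOG2P1 or pdx_tumor.space != LOG2P1:
        raise ValidationError("PDX matrices must be in log2p1 space")
    kept = []
    for gene in sorted(candidates.members):
        if gene not in pdx_stromal.genes or gene not in pdx_tumor.genes:
            logger.warning("candidate %s absent from a PDX compartment; excluded", gene)
            continue
        s_mean = float(pdx_stromal.data.loc[gene].mean())
        t_mean = float(pdx_tumor.data.loc[gene].mean())
        if s_mean >= config.stromal_min_log2 and (
            s_mean - t_mean
        ) >= config.stromal_delta_min_log2:
            kept.append(gene)
    if not kept:
        raise ValidationError("no candidate passes the stromal filter")
    logger.info("stromal filter: %d of %d candidates retained", len(kept), len(candidates))
    return GeneSet("tam_signature", frozenset(kept))


def extract_signature(
    tam_expr: ExpressionMatrix,
    tumor_expr: ExpressionMatrix,
    mesenchymal_set: GeneSet,
    pdx_stromal: ExpressionMatrix,
    pdx_tumor: ExpressionMatrix,
    pairing: pd.Series,
    config: SignatureConfig | None = None,
    annotation=None,
) -> tuple[GeneSet, pd.DataFrame, dict[str, int]]:
    """Run the full three-stage signature ladder.

    ``tam_expr`` is the TAM matrix in linear RPKM space; ``tumor_expr``,
    ``pdx_stromal`` and ``pdx_tumor`` may be linear or already log2p1 (linear
    inputs are transformed). Returns (signature GeneSet, per-gene correlation
    stats, stage-count dictionary).
    """
    config = config or SignatureConfig()

    def _logged(m: ExpressionMatrix) -> ExpressionMatrix:
        return log_transform(m) if m.space == LINEAR_RPKM else m

    tam_log = _logged(tam_expr)
    counts = {"input_genes": tam_log.shape[0]}
    tam_floor = filter_low_expression(tam_log, config.expression_floor)
    counts["after_expression_floor"] = tam_floor.shape[0]

    activity = mesenchymal_activity(_logged(tumor_expr), mesenchymal_set)

    use_pairing = pairing
    if config.restrict_to_condition is not None:
        if annotation is None:
            raise ValidationError(
                "restrict_to_condition requires a sample annotation"
            )
        cond = annotation.table["condition"]
        keep = [s for s in pairing.index
                if s in cond.index and cond[s] == config.restrict_to_condition]
        use_pairing = pairing.loc[keep]

    corr = gene_activity_correlation(tam_floor, activity, use_pairing)
    correlated = select_correlated_genes(corr, config)
    counts["after_correlation"] = len(correlated)

    signature = stromal_filter(correlated, _logged(pdx_stromal), _logged(pdx_tumor), config)
    counts["signature_genes"] = len(signature)
    logger.info("signature ladder: %s", counts)
    return signature, corr, counts
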