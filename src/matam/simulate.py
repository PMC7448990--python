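"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the study conditions the pipeline was designed for:
3 condition (MA) vs 6 control (non-MA) macrophage profiles whose planted
signature genes track a per-tumor latent mesenchymal activity; a planted
TF -> target system with a handful of condition-active master regulators
and a decoy-laden binding prior; two-compartment PDX profiles with
stromal-specific genes; 91 longitudinal score pairs; survival times whose
hazard scales with a signature score; and single-hit limiting-dilution
well counts. Every generator is deterministic given (config, seed): a
single root seed derives per-generator substreams by fixed offsets.

Expression is built in log2(RPKM+1) space and exported in linear RPKM
space via 2^x - 1 floored at 0, so the pipeline's own log transform is
exercised explicitly.

Planted signature genes are constructed by projection so that their sample
Pearson correlation with the latent activity equals the drawn target r
exactly (not merely in expectation); with only 9 samples the sampling
noise of an approximate construction would otherwise swamp the planted
r window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .binding import BindingNetwork
from .types import (
    ExpressionMatrix,
    GeneSet,
    GenomicInterval,
    LINEAR_RPKM,
    SampleAnnotation,
    SurvivalTable,
    ValidationError,
)

logger = logging.getLogger("matam")

# fixed substream offsets: one root seed reproduces everything
_STREAM_REGULATORY = 0
_STREAM_PDX = 1
_STREAM_LONGITUDINAL = 2
_STREAM_SURVIVAL = 3
_STREAM_INTERVALS = 4
_STREAM_LDA = 5


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study, with the study-condition defaults.

    Sample counts mirror the emulated design: 3 condition vs 6 control
    macrophage profiles, 91 longitudinal pairs, 373 patients. The inference
    cohort (no condition structure) stands in for the large tumor cohort
    on which the regulatory network is inferred before regulons are scored
    on the 9 macrophage profiles.
    """

    n_tfs: int = 20
    n_targets: int = 300
    n_master_regulators: int = 4
    n_ma_samples: int = 3
    n_nonma_samples: int = 6
    n_cohort_samples: int = 60
    regulon_size_range: tuple[int, int] = (10, 30)
    effect_size: float = 2.0            # condition shift of planted regulators, in sd
    edge_weight_range: tuple[float, float] = (0.5, 1.5)
    positive_edge_prob: float = 0.7
    noise_sd: float = 0.5
    n_signature_genes: int = 60
    n_stromal_genes: int = 80           # includes the signature genes
    n_background_genes: int = 150
    n_low_expression_genes: int = 40
    signature_r_range: tuple[float, float] = (0.75, 0.95)
    n_mesenchymal_set_genes: int = 30
    decoy_edge_factor: float = 3.0
    n_pdx_samples: int = 8
    n_longitudinal_pairs: int = 91
    n_transition_pairs: int = 30
    longitudinal_delta: float = 1.0
    longitudinal_sigma: float = 1.0
    n_patients: int = 373
    hazard_ratio_per_sd: float = 2.0
    baseline_median: float = 12.0       # survival-time units (months)
    max_follow_up: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_tfs, self.n_targets, self.n_master_regulators,
                  self.n_ma_samples, self.n_nonma_samples, self.n_cohort_samples,
                  self.n_signature_genes, self.n_stromal_genes,
                  self.n_background_genes, self.n_longitudinal_pairs,
                  self.n_patients, self.n_pdx_samples)
        if any(c <= 0 for c in counts):
            raise ValidationError("all simulation counts must be positive")
        if self.n_master_regulators > self.n_tfs:
            raise ValidationError("n_master_regulators must be <= n_tfs")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if self.n_stromal_genes < self.n_signature_genes:
            raise ValidationError("n_stromal_genes must be >= n_signature_genes")
        if not (0 < self.signature_r_range[0] <= self.signature_r_range[1] < 1):
            raise ValidationError("signature_r_range must lie in (0, 1)")
        if self.regulon_size_range[0] > self.regulon_size_range[1]:
            raise ValidationError("invalid regulon_size_range")


@dataclass
class GroundTruth:
    """Planted structure, the acceptance surface for recovery tests."""

    planted_regulators: tuple[str, ...]
    true_edges: frozenset[tuple[str, str, int]]
    planted_signature_genes: frozenset[str]
    planted_stromal_genes: frozenset[str]
    latent_activity: pd.Series
    seed: int


@dataclass
class RegulatorySystem:
    """Everything simulate_regulatory_system emits."""

    tam: ExpressionMatrix
    tumor: ExpressionMatrix
    cohort: ExpressionMatrix
    annotation: SampleAnnotation
    pairing: pd.Series               # TAM sample id -> matched tumor sample id
    binding: BindingNetwork
    mesenchymal_set: GeneSet
    truth: GroundTruth


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def _exact_corr(rng: np.random.Generator, z_ref: np.ndarray, r: float) -> np.ndarray:
    """Zero-mean unit-sd vector whose sample Pearson r with z_ref is exactly r."""
    n = len(z_ref)
    e = rng.standard_normal(n)
    e = e - e.mean()
    e = e - (e @ z_ref) / (z_ref @ z_ref) * z_ref
    z_e = e / e.std(ddof=1)
    return r * z_ref + np.sqrt(1.0 - r**2) * z_e


def _to_linear(log_df: pd.DataFrame) -> ExpressionMatrix:
    return ExpressionMatrix(np.maximum(2.0**log_df - 1.0, 0.0), space=LINEAR_RPKM)


def simulate_regulatory_system(config: SimulationConfig | None = None,
                               seed: int | None = None) -> RegulatorySystem:
    """Planted TF -> target system, matched tumor profiles, and binding prior.

    TF log-expression is Normal(mu_tf, 1), with mu shifted by
    ``effect_size`` in MA samples for planted regulators only. Each TF
    draws a regulon from ``regulon_size_range``; each target's
    log-expression is the signed-weight sum of its parents' centered
    log-expression plus Normal(0, noise_sd). The exported binding network
    is the true edges plus ``decoy_edge_factor`` times as many decoys. A
    latent mesenchymal activity per tumor sample drives both the tumor
    mesenchymal reference genes and the planted macrophage signature genes.
    """
    config = config or SimulationConfig()
    root_seed = config.seed if seed is None else seed
    rng = _rng(root_seed, _STREAM_REGULATORY)

    n_ma, n_nm = config.n_ma_samples, config.n_nonma_samples
    n_samples = n_ma + n_nm
    tam_samples = [f"TAM_MA_{i+1}" for i in range(n_ma)] + [
        f"TAM_NM_{i+1}" for i in range(n_nm)]
    tumor_samples = [f"TUM_MA_{i+1}" for i in range(n_ma)] + [
        f"TUM_NM_{i+1}" for i in range(n_nm)]
    is_ma = np.array([1] * n_ma + [0] * n_nm, dtype=float)

    tf_names = [f"TF_{i+1:02d}" for i in range(config.n_tfs)]
    target_names = [f"TG_{i+1:03d}" for i in range(config.n_targets)]
    sig_names = [f"SIG_{i+1:03d}" for i in range(config.n_signature_genes)]
    n_str_extra = config.n_stromal_genes - config.n_signature_genes
    str_names = [f"STR_{i+1:03d}" for i in range(n_str_extra)]
    bg_names = [f"BG_{i+1:03d}" for i in range(config.n_background_genes)]
    low_names = [f"LOW_{i+1:03d}" for i in range(config.n_low_expression_genes)]
    mes_names = [f"MES_{i+1:02d}" for i in range(config.n_mesenchymal_set_genes)]

    planted = tuple(sorted(str(tf) for tf in rng.choice(
        tf_names, size=config.n_master_regulators, replace=False)))
    planted_set = set(planted)

    # latent mesenchymal activity per tumor/TAM pair
    activity = config.effect_size * is_ma + rng.standard_normal(n_samples)
    z_act = _standardize(activity)

    # TF expression: TAM samples and inference cohort
    mu_tf = rng.uniform(3.0, 6.0, size=config.n_tfs)
    shift = np.array([config.effect_size if tf in planted_set else 0.0
                      for tf in tf_names])
    # plant the condition shift exactly: remove the within-condition mean of
    # the TF noise so the realized group difference equals effect_size, making
    # the planted structure re-measurable even at 3 vs 6 samples
    tf_noise = rng.standard_normal((config.n_tfs, n_samples))
    ma_cols = is_ma == 1
    tf_noise[:, ma_cols] -= tf_noise[:, ma_cols].mean(axis=1, keepdims=True)
    tf_noise[:, ~ma_cols] -= tf_noise[:, ~ma_cols].mean(axis=1, keepdims=True)
    tam_tf = mu_tf[:, None] + shift[:, None] * is_ma[None, :] + tf_noise
    cohort_samples = [f"C_{i+1:03d}" for i in range(config.n_cohort_samples)]
    cohort_tf = mu_tf[:, None] + rng.standard_normal(
        (config.n_tfs, config.n_cohort_samples))

    # true regulons and signed weights
    lo, hi = config.regulon_size_range
    true_edges: dict[tuple[str, str], tuple[float, int]] = {}
    for i, tf in enumerate(tf_names):
        size = int(rng.integers(lo, hi + 1))
        targets = [str(t) for t in rng.choice(target_names, size=size, replace=False)]
        for target in targets:
            w = float(rng.uniform(*config.edge_weight_range))
            s = 1 if rng.random() < config.positive_edge_prob else -1
            true_edges[(tf, target)] = (w, s)

    parents: dict[str, list[str]] = {t: [] for t in target_names}
    for (tf, target) in true_edges:
        parents[target].append(tf)

    def _targets_from(tf_matrix: np.ndarray, n_cols: int,
                      gen: np.random.Generator) -> np.ndarray:
        centered = tf_matrix - mu_tf[:, None]
        out = np.empty((config.n_targets, n_cols))
        base = rng_target_base
        for j, target in enumerate(target_names):
            val = base[j] + gen.standard_normal(n_cols) * config.noise_sd
            for tf in parents[target]:
                w, s = true_edges[(tf, target)]
                val = val + w * s * centered[tf_names.index(tf)]
            out[j] = val
        return out

    rng_target_base = rng.uniform(3.0, 6.0, size=config.n_targets)
    tam_targets = _targets_from(tam_tf, n_samples, rng)
    cohort_targets = _targets_from(cohort_tf, config.n_cohort_samples, rng)

    # planted signature genes: exact correlation with the latent activity
    r_targets = rng.uniform(*config.signature_r_range, size=config.n_signature_genes)
    sig_rows = np.vstack([3.5 + _exact_corr(rng, z_act, r) for r in r_targets])

    str_rows = 3.5 + rng.standard_normal((n_str_extra, n_samples)) * 0.8
    bg_rows = (rng.uniform(2.0, 5.0, size=config.n_background_genes)[:, None]
               + rng.standard_normal((config.n_background_genes, n_samples)))
    low_rows = rng.uniform(0.0, 0.5, size=(config.n_low_expression_genes, n_samples))

    tam_log = pd.DataFrame(
        np.vstack([tam_tf, tam_targets, sig_rows, str_rows, bg_rows, low_rows]),
        index=tf_names + target_names + sig_names + str_names + bg_names + low_names,
        columns=tam_samples,
    )

    # tumor profiles: mesenchymal reference genes track the latent activity
    mes_r = rng.uniform(0.90, 0.98, size=config.n_mesenchymal_set_genes)
    mes_rows = np.vstack([4.0 + _exact_corr(rng, z_act, r) for r in mes_r])
    tbg_names = [f"TBG_{i+1:03d}" for i in range(100)]
    tbg_rows = (rng.uniform(2.0, 5.0, size=100)[:, None]
                + rng.standard_normal((100, n_samples)))
    tumor_log = pd.DataFrame(
        np.vstack([mes_rows, tbg_rows]),
        index=mes_names + tbg_names, columns=tumor_samples,
    )

    cohort_log = pd.DataFrame(
        np.vstack([cohort_tf, cohort_targets]),
        index=tf_names + target_names, columns=cohort_samples,
    )

    # binding prior: true edges plus decoys
    n_true = len(true_edges)
    n_decoy = int(round(config.decoy_edge_factor * n_true))
    all_pairs = [(tf, t) for tf in tf_names for t in target_names
                 if (tf, t) not in true_edges]
    decoy_idx = rng.choice(len(all_pairs), size=min(n_decoy, len(all_pairs)),
                           replace=False)
    edges: dict[str, set[str]] = {tf: set() for tf in tf_names}
    for (tf, t) in true_edges:
        edges[tf].add(t)
    for k in decoy_idx:
        tf, t = all_pairs[k]
        edges[tf].add(t)
    binding = BindingNetwork(edges={tf: ts for tf, ts in edges.items() if ts})

    condition = ["MA_TAM"] * n_ma + ["non_MA_TAM"] * n_nm
    ann = pd.DataFrame({
        "sample_id": tam_samples + tumor_samples,
        "condition": condition + condition,
        "compartment": ["tam"] * n_samples + ["tumor"] * n_samples,
        "pair_id": [f"P{i+1}" for i in range(n_samples)] * 2,
    }).set_index("sample_id")
    pairing = pd.Series(dict(zip(tam_samples, tumor_samples)), name="tumor_sample")

    truth = GroundTruth(
        planted_regulators=planted,
        true_edges=frozenset((tf, t, s) for (tf, t), (_w, s) in true_edges.items()),
        planted_signature_genes=frozenset(sig_names),
        planted_stromal_genes=frozenset(sig_names + str_names),
        latent_activity=pd.Series(activity, index=tumor_samples, name="activity"),
        seed=root_seed,
    )
    logger.info("simulated regulatory system: %d TFs (%d planted), %d targets, "
                "%d true edges, %d prior edges", config.n_tfs, len(planted),
                config.n_targets, n_true, binding.n_edges)
    return RegulatorySystem(
        tam=_to_linear(tam_log),
        tumor=_to_linear(tumor_log),
        cohort=_to_linear(cohort_log),
        annotation=SampleAnnotation(ann.drop(columns=["pair_id"])
                                    .assign(pair_id=ann["pair_id"])),
        pairing=pairing,
        binding=binding,
        mesenchymal_set=GeneSet("mesenchymal_reference", frozenset(mes_names)),
        truth=truth,
    )


@dataclass
class PdxProfiles:
    """Two-compartment PDX expression with planted stromal-specific genes."""

    stromal: ExpressionMatrix
    tumor: ExpressionMatrix
    planted_stromal_genes: frozenset[str]
    seed: int


def simulate_pdx_profiles(config: SimulationConfig | None = None,
                          seed: int | None = None,
                          gene_universe: Sequence[str] | None = None) -> PdxProfiles:
    """Tumor- vs stromal-compartment profiles over the macrophage gene universe.

    Planted stromal genes have stromal-compartment mean log2 >= 3 and
    tumor-compartment mean <= 0.2; every other gene has a shared baseline in
    both compartments.
    """
    config = config or SimulationConfig()
    root_seed = config.seed if seed is None else seed
    rng = _rng(root_seed, _STREAM_PDX)

    sig_names = [f"SIG_{i+1:03d}" for i in range(config.n_signature_genes)]
    n_str_extra = config.n_stromal_genes - config.n_signature_genes
    str_names = [f"STR_{i+1:03d}" for i in range(n_str_extra)]
    stromal_genes = sig_names + str_names
    if gene_universe is None:
        tf_names = [f"TF_{i+1:02d}" for i in range(config.n_tfs)]
        target_names = [f"TG_{i+1:03d}" for i in range(config.n_targets)]
        bg_names = [f"BG_{i+1:03d}" for i in range(config.n_background_genes)]
        low_names = [f"LOW_{i+1:03d}" for i in range(config.n_low_expression_genes)]
        gene_universe = (tf_names + target_names + sig_names + str_names
                         + bg_names + low_names)
    others = [g for g in gene_universe if g not in set(stromal_genes)]
    if config.n_stromal_genes >= len(gene_universe):
        raise ValidationError("n_stromal_genes must be < total genes")

    n = config.n_pdx_samples
    s_cols = [f"PDX_S_{i+1}" for i in range(n)]
    t_cols = [f"PDX_T_{i+1}" for i in range(n)]

    stromal = pd.DataFrame(index=list(gene_universe), columns=s_cols, dtype=float)
    tumor = pd.DataFrame(index=list(gene_universe), columns=t_cols, dtype=float)

    stromal.loc[stromal_genes] = 3.5 + rng.standard_normal((len(stromal_genes), n)) * 0.3
    tumor.loc[stromal_genes] = np.clip(
        0.1 + rng.standard_normal((len(stromal_genes), n)) * 0.03, 0.0, None)
    base = rng.uniform(1.5, 4.0, size=len(others))
    stromal.loc[others] = base[:, None] + rng.standard_normal((len(others), n)) * 0.3
    tumor.loc[others] = base[:, None] + rng.standard_normal((len(others), n)) * 0.3

    return PdxProfiles(
        stromal=_to_linear(stromal.clip(lower=0.0)),
        tumor=_to_linear(tumor.clip(lower=0.0)),
        planted_stromal_genes=frozenset(stromal_genes),
        seed=root_seed,
    )


def simulate_longitudinal_pairs(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Primary/recurrent score pairs with a planted transition-group shift.

    Pairs labelled as mesenchymal transitions receive a recurrent-minus-
    primary score delta of Normal(delta, sigma); the rest Normal(0, sigma).
    Returns (long-format table with pair_id/timepoint/score, labels).
    """
    config = config or SimulationConfig()
    root_seed = config.seed if seed is None else seed
    rng = _rng(root_seed, _STREAM_LONGITUDINAL)
    n = config.n_longitudinal_pairs
    n_trans = min(config.n_transition_pairs, n)
    pair_ids = [f"LP_{i+1:03d}" for i in range(n)]
    transition = np.array([1] * n_trans + [0] * (n - n_trans))
    rng.shuffle(transition)
    primary = rng.standard_normal(n)
    delta = (config.longitudinal_delta * transition
             + rng.standard_normal(n) * config.longitudinal_sigma)
    recurrent = primary + delta
    rows = []
    for pid, p_score, r_score in zip(pair_ids, primary, recurrent):
        rows.append((pid, "primary", p_score))
        rows.append((pid, "recurrent", r_score))
    table = pd.DataFrame(rows, columns=["pair_id", "timepoint", "score"])
    labels = pd.Series(
        np.where(transition == 1, "mesenchymal", "non_mesenchymal"),
        index=pair_ids, name="transition",
    )
    return table, labels


def simulate_survival(
    scores: pd.Series,
    hazard_ratio_per_sd: float = 2.0,
    max_follow_up: float = 60.0,
    seed: int = 0,
    baseline_median: float = 12.0,
    time_unit: str = "months",
) -> SurvivalTable:
    """Exponential event times with hazard h0 * HR^z(score), censored at follow-up."""
    rng = _rng(seed, _STREAM_SURVIVAL)
    z = _standardize(scores.to_numpy(dtype=float))
    h0 = np.log(2.0) / baseline_median
    rate = h0 * hazard_ratio_per_sd**z
    times = rng.exponential(scale=1.0 / rate)
    event = (times <= max_follow_up).astype(int)
    times = np.minimum(times, max_follow_up)
    table = pd.DataFrame({"time": times, "event": event}, index=scores.index)
    return SurvivalTable(table, time_unit=time_unit)


@dataclass
class IntervalFixture:
    """Motif/TSS/chromatin-state fixture with a brute-force expected ABN."""

    motif_sites: list[GenomicInterval]
    tss: pd.DataFrame
    states: list[GenomicInterval]
    expected_edges: dict[str, set[str]]
    expected_support: dict[tuple[str, str], int]
    seed: int


_INACTIVE_STATES = ("Quies", "ReprPC", "Het", "ZNF_Rpts")
_ACTIVE_STATES = ("TssA", "Tx", "EnhG1", "EnhA1")


def simulate_interval_fixture(
    seed: int = 0,
    n_genes: int = 30,
    n_tfs: int = 5,
    sites_per_tf: int = 40,
    flank: int = 5000,
    chrom_length: int = 1_000_000,
) -> IntervalFixture:
    """Random motif sites, TSS table, and a chromatin-state tiling.

    The expected binding network is computed here by a per-base brute-force
    oracle (explicit base sets), independent of the sorted-sweep
    implementation it is meant to check.
    """
    rng = _rng(seed, _STREAM_INTERVALS)
    genes = [f"G_{i+1:02d}" for i in range(n_genes)]
    tss_pos = np.sort(rng.choice(
        np.arange(flank, chrom_length - flank), size=n_genes, replace=False))
    tss = pd.DataFrame({"gene": genes, "chrom": "chr1", "position": tss_pos})

    sites = []
    for t in range(n_tfs):
        tf = f"TF_{chr(ord('A') + t)}"
        for _ in range(sites_per_tf):
            if rng.random() < 0.6:  # drop near a promoter
                center = int(rng.choice(tss_pos)) + int(rng.integers(-flank - 500,
                                                                     flank + 500))
            else:
                center = int(rng.integers(0, chrom_length))
            width = int(rng.integers(8, 21))
            start = max(0, center - width // 2)
            sites.append(GenomicInterval("chr1", start, start + width, label=tf))

    states = []
    pos = 0
    labels = list(_ACTIVE_STATES + _INACTIVE_STATES)
    while pos < chrom_length:
        seg_len = int(rng.integers(500, 4000))
        label = labels[int(rng.integers(len(labels)))]
        states.append(GenomicInterval("chr1", pos, min(pos + seg_len, chrom_length),
                                      label=label))
        pos += seg_len

    # --- per-base brute-force oracle ---------------------------------------
    active_bases: set[int] = set()
    for seg in states:
        if seg.label in _ACTIVE_STATES:
            active_bases.update(range(seg.start, seg.end))
    promoter_bases = {
        g: set(range(max(0, p - flank), p + flank))
        for g, p in zip(genes, tss_pos)
    }
    expected_edges: dict[str, set[str]] = {}
    expected_support: dict[tuple[str, str], int] = {}
    for site in sites:
        bases = set(range(site.start, site.end))
        if not bases & active_bases:
            continue
        for gene, pb in promoter_bases.items():
            if bases & pb:
                expected_edges.setdefault(site.label, set()).add(gene)
                expected_support[(site.label, gene)] = (
                    expected_support.get((site.label, gene), 0) + 1)

    return IntervalFixture(sites, tss, states, expected_edges, expected_support, seed)


def simulate_limiting_dilution(
    frequency: float,
    doses: Sequence[float],
    wells_per_dose: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Binomial negative-well counts under the single-hit Poisson model."""
    if not (0 <= frequency <= 1):
        raise ValidationError("frequency must lie in [0, 1]")
    rng = _rng(seed, _STREAM_LDA)
    doses = np.asarray(doses, dtype=float)
    p_neg = np.exp(-frequency * doses)
    neg = rng.binomial(wells_per_dose, p_neg)
    return pd.DataFrame({"dose": doses, "wells_total": wells_per_dose,
                         "wells_negative": neg})
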