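"""A-priori "active binding network" (ABN) construction.

The ABN is the mechanistic prior for network inference: a TF -> target
adjacency built from (1) TF motif occurrences, (2) promoter windows around
transcription start sites, and (3) chromatin-state segmentations. An edge
TF -> gene is recorded when a motif site for the TF falls (>= ``min_overlap``
shared bases) inside the gene's promoter window and the site also overlaps
at least one transcriptionally active chromatin-state segment.

Motif scanning and chromatin-state learning are upstream of this package;
their interval outputs are consumed as BED files. All arithmetic is 0-based
half-open, so "at least 1 bp of overlap" means ``min(end) - max(start) >= 1``
and book-ended intervals ([100,200) next to [200,300)) share no base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import GenomicInterval, ValidationError

logger = logging.getLogger("matam")

#: Chromatin-state labels treated as transcriptionally active by default,
#: matched by exact string against the segmentation's label column.
DEFAULT_ACTIVE_STATES = frozenset(
    {"TssA", "TssFlnkm", "TssFlnkU", "TssFlnkD", "Tx", "EnhG1", "EnhG2", "EnhA1m", "EnhA1"}
)


@dataclass
class AbnConfig:
    """Parameters of active-binding-network construction.

    promoter_flank
        Half-width of the symmetric promoter window around each TSS, in
        bases (default 5000, i.e. +-5 kb).
    active_state_labels
        Chromatin-state names counted as active.
    min_overlap
        Minimum shared bases for an intersection to count (default 1).
    pool_states
        With several segmentations (epigenomes), ``"union"`` calls a site
        active if it is active in ANY of them; ``"intersection"`` requires
        all of them.
    """

    promoter_flank: int = 5000
    active_state_labels: frozenset[str] = DEFAULT_ACTIVE_STATES
    min_overlap: int = 1
    pool_states: str = "union"

    def __post_init__(self) -> None:
        if self.promoter_flank <= 0:
            raise ValidationError("promoter_flank must be > 0")
        self.active_state_labels = frozenset(self.active_state_labels)
        if not self.active_state_labels:
            raise ValidationError("active_state_labels must be non-empty")
        if self.min_overlap < 1:
            raise ValidationError("min_overlap must be >= 1")
        if self.pool_states not in ("union", "intersection"):
            raise ValidationError("pool_states must be 'union' or 'intersection'")


@dataclass
class BindingNetwork:
    """A-priori TF -> target adjacency with per-edge supporting-site counts."""

    edges: dict[str, set[str]]
    support: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tf, targets in self.edges.items():
            for t in targets:
                self.support.setdefault((tf, t), 1)

    @property
    def tfs(self) -> list[str]:
        return sorted(self.edges)

    @property
    def n_edges(self) -> int:
        return sum(len(t) for t in self.edges.values())

    def targets_of(self, tf: str) -> set[str]:
        return self.edges.get(tf, set())

    def parents_of(self, gene: str) -> list[str]:
        return sorted(tf for tf, targets in self.edges.items() if gene in targets)

    def edge_list(self) -> list[tuple[str, str, int]]:
        out = []
        for tf in sorted(self.edges):
            for target in sorted(self.edges[tf]):
                out.append((tf, target, self.support.get((tf, target), 1)))
        return out


def promoter_windows(tss: pd.DataFrame, flank: int) -> list[GenomicInterval]:
    """Symmetric +-``flank`` windows around transcription start sites.

    ``tss`` needs columns ``gene``, ``chrom``, ``position`` (0-based TSS
    coordinate) and optionally ``strand``; strand does not alter the window
    because the flank is symmetric. Windows truncated at 0 on the left.
    Duplicate genes with conflicting coordinates are an error.
    """
    required = {"gene", "chrom", "position"}
    missing = required - set(tss.columns)
    if missing:
        raise ValidationError(f"TSS table missing columns {sorted(missing)}")
    if (tss["position"] < 0).any():
        raise ValidationError("TSS positions must be >= 0")
    dup = tss[tss.duplicated("gene", keep=False)]
    if len(dup):
        for gene, grp in dup.groupby("gene"):
            if grp[["chrom", "position"]].drop_duplicates().shape[0] > 1:
                raise ValidationError(f"gene {gene!r} has conflicting TSS records")
        tss = tss.drop_duplicates("gene")
    windows = []
    for row in tss.itertuples(index=False):
        pos = int(row.position)
        start = max(0, pos - flank)
        strand = getattr(row, "strand", None)
        windows.append(
            GenomicInterval(row.chrom, start, pos + flank, label=row.gene, strand=strand)
        )
    return windows


def merge_intervals(sites: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge intervals that share at least one base into disjoint spans.

    Half-open adjacency ([a,b) followed by [b,c)) shares no base and is NOT
    merged. Output is sorted by (chrom, start); labels of merged members are
    dropped (the merged span represents coverage, not provenance).
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in sites:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start < cur_end:  # >=1 shared base
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def intersect_labeled(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> list[tuple[str, str, int]]:
    """All (a-label, b-label, shared-bases) pairs with overlap >= min_overlap.

    Sorted-sweep per chromosome; output order follows a's sorted order then
    b's, deterministically. Used both for motif x promoter and for
    site x chromatin-state intersection.
    """
    out: list[tuple[str, str, int]] = []
    a_by: dict[str, list[GenomicInterval]] = {}
    b_by: dict[str, list[GenomicInterval]] = {}
    for iv in a:
        a_by.setdefault(iv.chrom, []).append(iv)
    for iv in b:
        b_by.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(set(a_by) & set(b_by)):
        a_sorted = sorted(a_by[chrom], key=lambda iv: (iv.start, iv.end, iv.label))
        b_sorted = sorted(b_by[chrom], key=lambda iv: (iv.start, iv.end, iv.label))
        b_starts = [iv.start for iv in b_sorted]
        max_b_len = max((len(iv) for iv in b_sorted), default=0)
        lo = 0
        for av in a_sorted:
            # b intervals starting before av.end can overlap; those starting
            # earlier than av.start - max_b_len cannot. Advance lo lazily.
            while lo < len(b_sorted) and b_starts[lo] + max_b_len <= av.start:
                lo += 1
            j = lo
            while j < len(b_sorted) and b_starts[j] < av.end:
                bv = b_sorted[j]
                shared = min(av.end, bv.end) - max(av.start, bv.start)
                if shared >= min_overlap:
                    out.append((av.label, bv.label, shared))
                j += 1
    return out


def build_binding_network(
    motif_sites: Sequence[GenomicInterval],
    tss: pd.DataFrame,
    state_segments: Sequence[GenomicInterval] | Sequence[Sequence[GenomicInterval]],
    config: AbnConfig | None = None,
) -> BindingNetwork:
    """Assemble the active binding network.

    Pipeline: promoter windows -> motif x promoter intersection -> keep hits
    whose motif site overlaps >= 1 active-state segment -> TF -> gene edges
    with supporting-site counts. ``state_segments`` may be a single
    segmentation or a list of segmentations (one per epigenome), pooled per
    ``config.pool_states``.
    """
    config = config or AbnConfig()
    windows = promoter_windows(tss, config.promoter_flank)

    if state_segments and isinstance(state_segments[0], GenomicInterval):
        segmentations: list[Sequence[GenomicInterval]] = [state_segments]  # type: ignore[list-item]
    else:
        segmentations = list(state_segments)  # type: ignore[arg-type]

    seen_labels = {iv.label for segs in segmentations for iv in segs}
    unknown = config.active_state_labels - seen_labels
    if unknown and seen_labels:
        logger.warning(
            "active-state labels absent from segmentation: %s", sorted(unknown)
        )

    # Key motif sites by identity so per-site activity can be looked up after
    # the promoter intersection. Labels carry "TF|index".
    keyed_sites = [
        GenomicInterval(iv.chrom, iv.start, iv.end, label=f"{iv.label}|{i}")
        for i, iv in enumerate(motif_sites)
    ]

    active_keys: set[str] | None = None
    for segs in segmentations:
        active_segs = [iv for iv in segs if iv.label in config.active_state_labels]
        hits = intersect_labeled(keyed_sites, active_segs, config.min_overlap)
        keys = {site_key for site_key, _, _ in hits}
        if config.pool_states == "union":
            active_keys = keys if active_keys is None else (active_keys | keys)
        else:
            active_keys = keys if active_keys is None else (active_keys & keys)
    active_keys = active_keys or set()

    promoter_hits = intersect_labeled(keyed_sites, windows, config.min_overlap)

    edges: dict[str, set[str]] = {}
    support: dict[tuple[str, str], int] = {}
    for site_key, gene, _shared in promoter_hits:
        if site_key not in active_keys:
            continue
        tf = site_key.rsplit("|", 1)[0]
        if tf == gene:
            logger.info("self-loop retained: %s regulates its own promoter", tf)
        edges.setdefault(tf, set()).add(gene)
        support[(tf, gene)] = support.get((tf, gene), 0) + 1

    if not edges:
        raise ValidationError(
            "active binding network is empty: no motif site passed both the "
            "promoter and active-state intersections"
        )
    net = BindingNetwork(edges=edges, support=support)
    logger.info(
        "ABN built: %d TFs, %d edges, %d supporting sites",
        len(net.tfs), net.n_edges, sum(support.values()),
    )
    return net
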