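"""Shared domain types for the TAM master-regulator pipeline.

Conventions enforced here and relied upon everywhere else:

* Expression matrices are gene-by-sample, dense, finite, with unique ids,
  and carry an explicit ``space`` flag (``linear_rpkm`` or ``log2p1``) so
  that the log2(RPKM+1) transform is applied exactly once.
* Genomic coordinates are 0-based half-open (BED-native) throughout.
  Callers holding 1-based data must convert before constructing intervals.
* Survival times carry their unit as declared metadata; no unit conversion
  is ever attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

LINEAR_RPKM = "linear_rpkm"
LOG2P1 = "log2p1"
_SPACES = (LINEAR_RPKM, LOG2P1)


class ValidationError(ValueError):
    """An input violates a domain-type invariant."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample abundance table with an explicit scale flag.

    Parameters
    ----------
    data
        DataFrame with gene ids as index and sample ids as columns.
    space
        ``"linear_rpkm"`` for raw RPKM values (must be non-negative) or
        ``"log2p1"`` for log2(RPKM + 1)-transformed values.
    """

    data: pd.DataFrame
    space: str

    def __post_init__(self) -> None:
        if self.space not in _SPACES:
            raise ValidationError(f"unknown expression space {self.space!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValidationError("expression values must be finite (no NaN/inf)")
        if self.space == LINEAR_RPKM and (values < 0).any():
            raise ValidationError("negative values are not valid in linear_rpkm space")
        self.data = self.data.astype(float)

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        keep = self.data.index.intersection(pd.Index(genes))
        return ExpressionMatrix(self.data.loc[keep], self.space)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic span [start, end) with a free-text label."""

    chrom: str
    start: int
    end: int
    label: str = ""
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"negative interval start {self.start}")
        if self.start >= self.end:
            raise ValidationError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in (None, "+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SampleAnnotation:
    """Per-sample metadata: condition, compartment, timepoint, pairing.

    Stored as a DataFrame indexed by sample id with optional columns
    ``condition``, ``compartment``, ``timepoint``, ``pair_id``, ``subtype``.
    ``pair_id``, when present, must group exactly two samples with distinct
    timepoints (a primary/recurrent longitudinal pair, or a TAM/tumor pair
    keyed for matched-sample correlation).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate sample ids in annotation")
        if "pair_id" in self.table.columns:
            pairs = self.table.dropna(subset=["pair_id"])
            for pid, grp in pairs.groupby("pair_id"):
                if len(grp) != 2:
                    raise ValidationError(
                        f"pair_id {pid!r} groups {len(grp)} samples, expected 2"
                    )
                if "timepoint" in grp.columns and grp["timepoint"].nunique() != 2:
                    raise ValidationError(
                        f"pair_id {pid!r} members do not have distinct timepoints"
                    )

    @property
    def samples(self) -> pd.Index:
        return self.table.index

    def condition_of(self, sample: str) -> str:
        return self.table.loc[sample, "condition"]


@dataclass
class SurvivalTable:
    """Right-censored survival records for a cohort.

    Columns: ``time`` (positive, in ``time_unit``), ``event`` (1 = event,
    0 = censored), optional ``group``. Indexed by sample id.
    """

    table: pd.DataFrame
    time_unit: str

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate sample ids in survival table")
        for col in ("time", "event"):
            if col not in self.table.columns:
                raise ValidationError(f"survival table missing column {col!r}")
        if (self.table["time"] <= 0).any():
            raise ValidationError("survival times must be > 0")
        if not self.table["event"].isin([0, 1]).all():
            raise ValidationError("event indicator must be 0 or 1")
        if not self.time_unit:
            raise ValidationError("survival table must declare a time unit")

    @property
    def samples(self) -> pd.Index:
        return self.table.index


@dataclass
class AlterationMatrix:
    """Binary gene-by-sample genomic alteration calls (SNV/indel/CNA)."""

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        if self.calls.index.has_duplicates or self.calls.columns.has_duplicates:
            raise ValidationError("duplicate ids in alteration matrix")
        vals = self.calls.to_numpy()
        if not np.isin(vals, [0, 1]).all():
            raise ValidationError("alteration calls must be 0/1")
        self.calls = self.calls.astype(int)

    @property
    def genes(self) -> pd.Index:
        return self.calls.index

    @property
    def samples(self) -> pd.Index:
        return self.calls.columns


@dataclass
class ScoreTable:
    """Per-sample scalar scores (signature score or regulator activity)."""

    scores: pd.Series
    score_name: str
    method: str = "mean_z"
    n_genes_used: int = 0

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates:
            raise ValidationError("duplicate sample ids in score table")
        if not np.all(np.isfinite(self.scores.to_numpy(dtype=float))):
            raise ValidationError("scores must be finite")
        self.scores = self.scores.astype(float)

    @property
    def samples(self) -> pd.Index:
        return self.scores.index
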