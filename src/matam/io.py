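"""Readers and writers for the pipeline's on-disk formats.

Formats: tab-separated expression/annotation/survival/alteration tables,
GMT gene sets, BED intervals, and TSV edge lists. Every reader validates the
domain-type invariants and fails loudly instead of coercing; every
reader/writer pair round-trips losslessly up to the declared print
precision (6 decimals for floating-point values).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    AlterationMatrix,
    ExpressionMatrix,
    GeneSet,
    GenomicInterval,
    SampleAnnotation,
    SurvivalTable,
    ValidationError,
)

logger = logging.getLogger("matam")

FLOAT_FORMAT = "%.6f"


class ParseError(ValueError):
    """A file could not be parsed into the expected format."""


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path, space: str) -> ExpressionMatrix:
    """Read a gene-by-sample TSV (first column gene ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any():
            row = df.index[bad.isna()][0]
            raise ParseError(
                f"{path}: non-numeric value at gene {row!r}, sample {col!r}"
            )
        df[col] = bad
    em = ExpressionMatrix(df, space=space)
    logger.info("read expression matrix %s: %d genes x %d samples (%s)",
                path, *em.shape, space)
    return em


def write_expression_matrix(em: ExpressionMatrix, path: str | Path) -> None:
    em.data.to_csv(path, sep="\t", index_label="gene", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read GMT: one set per line, fields name, description, members..."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name, _desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
            if len(set(members)) < len(members):
                logger.warning("%s:%d: duplicate members in %s de-duplicated",
                               path, lineno, name)
            sets.append(GeneSet(name, frozenset(members)))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na", *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# intervals (BED)
# ---------------------------------------------------------------------------

def read_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read BED (>= 3 columns); column 4 = label, column 6 = strand."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED line has < 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            label = fields[3] if len(fields) >= 4 else ""
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else None
            try:
                out.append(GenomicInterval(chrom, start, end, label=label, strand=strand))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_intervals(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end), iv.label or "."]
            if iv.strand is not None:
                fields += ["0", iv.strand]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# sample tables (annotation / survival / alterations)
# ---------------------------------------------------------------------------

_ANNOTATION_OPTIONAL = ("condition", "compartment", "timepoint", "pair_id", "subtype")


def read_sample_table(path: str | Path, schema: str):
    """Dispatch on declared schema: 'annotation', 'survival' or 'alterations'."""
    if schema == "annotation":
        return read_annotation(path)
    if schema == "survival":
        return read_survival(path)
    if schema == "alterations":
        return read_alterations(path)
    raise ParseError(f"unknown sample-table schema {schema!r}")


def read_annotation(path: str | Path) -> SampleAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: annotation table missing 'sample_id' column")
    df = df.set_index("sample_id")
    keep = [c for c in df.columns if c in _ANNOTATION_OPTIONAL]
    return SampleAnnotation(df[keep])


def write_annotation(ann: SampleAnnotation, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t", index_label="sample_id")


def read_survival(path: str | Path) -> SurvivalTable:
    """Read survival TSV whose first line declares units: ``# time_unit=...``."""
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# time_unit="):
            raise ParseError(
                f"{path}: survival file must declare units in its first line "
                "('# time_unit=<unit>'); no unit conversion is attempted"
            )
        unit = first.split("=", 1)[1]
        df = pd.read_csv(fh, sep="\t")
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise ParseError(f"{path}: survival table missing column {col!r}")
    df = df.set_index("sample_id")
    df["time"] = pd.to_numeric(df["time"])
    df["event"] = pd.to_numeric(df["event"])
    return SurvivalTable(df, time_unit=unit)


def write_survival(surv: SurvivalTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# time_unit={surv.time_unit}\n")
        surv.table.to_csv(fh, sep="\t", index_label="sample_id",
                          float_format=FLOAT_FORMAT)


def read_alterations(path: str | Path) -> AlterationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return AlterationMatrix(df)


def write_alterations(alt: AlterationMatrix, path: str | Path) -> None:
    alt.calls.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# networks (TSV edge lists)
# ---------------------------------------------------------------------------

def write_network(net, path: str | Path) -> None:
    """Write a RegulatoryNetwork as TSV (tf, target, weight, sign)."""
    with open(path, "w") as fh:
        fh.write("tf\ttarget\tweight\tsign\n")
        for tf, target, weight, sign in net.sorted_edges():
            fh.write(f"{tf}\t{target}\t{weight:.6f}\t{sign:+d}\n")


def read_network(path: str | Path):
    """Read a TSV edge list back into a RegulatoryNetwork."""
    from .inference import RegulatoryNetwork

    edges = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["tf", "target", "weight", "sign"]:
            raise ParseError(f"{path}: expected header tf/target/weight/sign")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            tf, target, weight_s, sign_s = fields[:4]
            try:
                weight = float(weight_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad weight {weight_s!r}") from exc
            if sign_s not in ("+1", "-1", "1"):
                raise ParseError(f"{path}:{lineno}: unknown sign token {sign_s!r}")
            edges.append((tf, target, weight, 1 if sign_s in ("+1", "1") else -1))
    return RegulatoryNetwork(edges=edges)


def write_binding_network(net, path: str | Path) -> None:
    """Write a BindingNetwork as TSV (tf, target, n_sites)."""
    with open(path, "w") as fh:
        fh.write("tf\ttarget\tn_sites\n")
        for tf, target, n_sites in net.edge_list():
            fh.write(f"{tf}\t{target}\t{n_sites}\n")


def read_binding_network(path: str | Path):
    from .binding import BindingNetwork

    edges: dict[str, set[str]] = {}
    support: dict[tuple[str, str], int] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["tf", "target"]:
            raise ParseError(f"{path}: expected header tf/target[/n_sites]")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected >= 2 columns")
            tf, target = fields[0], fields[1]
            n = int(fields[2]) if len(fields) > 2 else 1
            edges.setdefault(tf, set()).add(target)
            support[(tf, target)] = n
    return BindingNetwork(edges=edges, support=support)
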