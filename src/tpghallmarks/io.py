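"""Readers and writers for every on-disk format the pipeline touches.

All tabular formats are plain TSV with mandatory headers; genomic tracks use
BED (3-6 column) and bedGraph.  Writers sort records and format numbers
deterministically so that identical in-memory data always produces identical
bytes.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import (
    CategoryMap,
    ContactMatrix,
    DomainAnnotation,
    ExpressionTable,
    FormatError,
    GeneModel,
    IntervalRecord,
    IntervalTrack,
    SignalProfile,
    Translocation,
)

_MISSING = "."


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

def parse_bed_record(line: str, line_number: int = 0) -> IntervalRecord:
    """Parse one BED line into a 0-based half-open interval record."""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise FormatError(f"line {line_number}: BED needs >= 3 fields")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise FormatError(f"line {line_number}: non-integer coordinates") from exc
    if start >= end:
        raise FormatError(f"line {line_number}: start {start} >= end {end}")
    name = fields[3] if len(fields) > 3 and fields[3] != _MISSING else None
    score = None
    if len(fields) > 4 and fields[4] != _MISSING:
        score = float(fields[4])
    return IntervalRecord(chrom, start, end, name, score)


def read_bed(path: str | Path) -> IntervalTrack:
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            records.append(parse_bed_record(line, i))
    return IntervalTrack(records)


def write_bed(track: IntervalTrack, path: str | Path) -> None:
    recs = sorted(track.records, key=lambda r: (r.chrom, r.start, r.end, r.name or ""))
    with open(path, "w") as fh:
        for r in recs:
            cols = [r.chrom, str(r.start), str(r.end)]
            if r.name is not None or r.score is not None:
                cols.append(r.name if r.name is not None else _MISSING)
            if r.score is not None:
                cols.append(_fmt(r.score))
            fh.write("\t".join(cols) + "\n")


def read_bedgraph(path: str | Path, kind: str = "signal") -> SignalProfile:
    """Load a bedGraph; each interval's value is assigned to its midpoint."""
    by_chrom: dict[str, list[tuple[int, float]]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise FormatError(f"line {i}: bedGraph needs 4 fields")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if start >= end:
                raise FormatError(f"line {i}: start >= end")
            by_chrom.setdefault(chrom, []).append(((start + end) // 2, value))
    data = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        pos = np.array([p for p, _ in pairs], dtype=np.int64)
        val = np.array([v for _, v in pairs], dtype=float)
        if np.any(np.diff(pos) == 0):
            raise FormatError(f"{chrom}: duplicate midpoint positions")
        data[chrom] = (pos, val)
    return SignalProfile(data, kind=kind)


def write_bedgraph(profile: SignalProfile, path: str | Path, span: int = 1) -> None:
    """Write point samples back as ``span``-wide intervals centred on positions."""
    half = span // 2
    with open(path, "w") as fh:
        for chrom in profile.chromosomes():
            pos, val = profile.data[chrom]
            for p, v in zip(pos, val):
                start = max(0, int(p) - half)
                fh.write(f"{chrom}\t{start}\t{start + span}\t{_fmt(float(v))}\n")


# ---------------------------------------------------------------------------
# Gene models, translocations, domains, categories
# ---------------------------------------------------------------------------

_GENE_COLS = ["gene_id", "chrom", "strand", "tx_start", "tx_end",
              "cds_start_nt", "utr3_start", "utr3_end"]


def read_gene_models(path: str | Path) -> dict[str, GeneModel]:
    df = _read_tsv(path, _GENE_COLS)
    catalog: dict[str, GeneModel] = {}
    for row in df.itertuples(index=False):
        utr_s = None if row.utr3_start == _MISSING else int(row.utr3_start)
        utr_e = None if row.utr3_end == _MISSING else int(row.utr3_end)
        g = GeneModel(
            gene_id=row.gene_id, chrom=row.chrom, strand=row.strand,
            tx_start=int(row.tx_start), tx_end=int(row.tx_end),
            cds_start_nt=int(row.cds_start_nt),
            utr3_start=utr_s, utr3_end=utr_e,
        )
        if g.gene_id in catalog:
            raise FormatError(f"duplicated gene_id {g.gene_id}")
        catalog[g.gene_id] = g
    return catalog


def write_gene_models(catalog: dict[str, GeneModel], path: str | Path) -> None:
    rows = []
    for g in sorted(catalog.values(), key=lambda g: g.gene_id):
        rows.append([
            g.gene_id, g.chrom, g.strand, g.tx_start, g.tx_end, g.cds_start_nt,
            g.utr3_start if g.utr3_start is not None else _MISSING,
            g.utr3_end if g.utr3_end is not None else _MISSING,
        ])
    _write_tsv(path, _GENE_COLS, rows)


_TRANSLOC_COLS = ["fusion_id", "five_gene", "three_gene", "five_bp_nt",
                  "three_bp_nt", "lineage", "report_count"]


def read_translocations(path: str | Path) -> list[Translocation]:
    df = _read_tsv(path, _TRANSLOC_COLS)
    out = []
    for row in df.itertuples(index=False):
        rc = int(row.report_count)
        if rc < 0:
            raise FormatError(f"{row.fusion_id}: negative report_count")
        out.append(Translocation(
            fusion_id=row.fusion_id, five_gene=row.five_gene,
            three_gene=row.three_gene, five_bp_nt=int(row.five_bp_nt),
            three_bp_nt=int(row.three_bp_nt), lineage=row.lineage,
            report_count=rc, self_fusion=row.five_gene == row.three_gene,
        ))
    return out


def write_translocations(translocs: Sequence[Translocation], path: str | Path) -> None:
    rows = [[t.fusion_id, t.five_gene, t.three_gene, t.five_bp_nt,
             t.three_bp_nt, t.lineage, t.report_count]
            for t in sorted(translocs, key=lambda t: t.fusion_id)]
    _write_tsv(path, _TRANSLOC_COLS, rows)


def deduplicate_translocations(
    translocs: Sequence[Translocation],
    mode: str = "pairs",
    profile_key=None,
) -> list[Translocation]:
    """Reduce a translocation list to unique entries.

    mode 'pairs'    - unique (5' gene, 3' gene) pairs;
    mode 'profile'  - unique (5' gene, 3' gene, retained-domain composition),
                      where ``profile_key(t)`` supplies the composition;
    mode 'none'     - identity.

    The first occurrence in ``fusion_id`` order is kept, making the result
    independent of input order and idempotent.
    """
    if mode == "none":
        return list(translocs)
    ordered = sorted(translocs, key=lambda t: t.fusion_id)
    seen: set = set()
    out: list[Translocation] = []
    for t in ordered:
        if mode == "pairs":
            key = t.gene_pair
        elif mode == "profile":
            if profile_key is None:
                raise ValueError("mode 'profile' requires profile_key")
            key = (t.five_gene, t.three_gene, profile_key(t))
        else:
            raise ValueError(f"unknown dedup mode {mode!r}")
        if key not in seen:
            seen.add(key)
            out.append(t)
    return out


def unique_genes(translocs: Sequence[Translocation], side: str) -> list[str]:
    """Unique gene instances for one fusion side ('five' or 'three')."""
    if side not in ("five", "three"):
        raise ValueError("side must be 'five' or 'three'")
    attr = "five_gene" if side == "five" else "three_gene"
    return sorted({getattr(t, attr) for t in translocs})


_DOMAIN_COLS = ["gene_id", "feature_id", "aa_start", "aa_end", "is_pii", "partners"]


def read_domain_annotations(path: str | Path) -> list[DomainAnnotation]:
    df = _read_tsv(path, _DOMAIN_COLS)
    out = []
    for row in df.itertuples(index=False):
        is_pii = str(row.is_pii) in ("1", "True", "true")
        partners = frozenset() if row.partners == _MISSING else frozenset(str(row.partners).split(","))
        out.append(DomainAnnotation(
            gene_id=row.gene_id, feature_id=row.feature_id,
            aa_start=int(row.aa_start), aa_end=int(row.aa_end),
            is_pii=is_pii, partners=partners,
        ))
    return out


def write_domain_annotations(annotations: Sequence[DomainAnnotation], path: str | Path) -> None:
    rows = []
    for a in sorted(annotations, key=lambda a: (a.gene_id, a.feature_id, a.aa_start)):
        rows.append([
            a.gene_id, a.feature_id, a.aa_start, a.aa_end,
            1 if a.is_pii else 0,
            ",".join(sorted(a.partners)) if a.partners else _MISSING,
        ])
    _write_tsv(path, _DOMAIN_COLS, rows)


def read_category_map(path: str | Path) -> CategoryMap:
    df = _read_tsv(path, ["feature_id", "category"])
    cmap = CategoryMap()
    for row in df.itertuples(index=False):
        cmap[row.feature_id] = row.category
    return cmap


def write_category_map(cmap: CategoryMap, path: str | Path) -> None:
    _write_tsv(path, ["feature_id", "category"],
               [[k, cmap[k]] for k in sorted(cmap)])


# ---------------------------------------------------------------------------
# Contact matrices (bin table + COO triplets)
# ---------------------------------------------------------------------------

def read_contact_matrix(bins_path: str | Path, triplets_path: str | Path) -> ContactMatrix:
    bins = _read_tsv(bins_path, ["bin_id", "chrom", "start", "end"])
    bins = bins.astype({"bin_id": int, "start": int, "end": int})
    n = len(bins)
    id_to_index = {int(b): i for i, b in enumerate(bins["bin_id"])}
    values = np.zeros((n, n))
    seen: set[tuple[int, int]] = set()
    trip = _read_tsv(triplets_path, ["bin_i", "bin_j", "value"], allow_empty=True)
    for row in trip.itertuples(index=False):
        bi, bj, v = int(row.bin_i), int(row.bin_j), float(row.value)
        if bi not in id_to_index or bj not in id_to_index:
            raise FormatError(f"unknown bin id in triplet ({bi}, {bj})")
        if v < 0:
            raise FormatError(f"negative contact value at ({bi}, {bj})")
        key = (min(bi, bj), max(bi, bj))
        if key in seen:
            raise FormatError(f"duplicate triplet for bins {key}")
        seen.add(key)
        i, j = id_to_index[bi], id_to_index[bj]
        values[i, j] = v
        values[j, i] = v
    return ContactMatrix(bins, values)


def write_contact_matrix(matrix: ContactMatrix, bins_path: str | Path,
                         triplets_path: str | Path) -> None:
    _write_tsv(bins_path, ["bin_id", "chrom", "start", "end"],
               matrix.bins[["bin_id", "chrom", "start", "end"]].values.tolist())
    ids = matrix.bins["bin_id"].to_numpy()
    rows = []
    iu, ju = np.nonzero(np.triu(matrix.values != 0))
    for i, j in zip(iu, ju):
        rows.append([int(ids[i]), int(ids[j]), _fmt(matrix.values[i, j])])
    _write_tsv(triplets_path, ["bin_i", "bin_j", "value"], rows)


# ---------------------------------------------------------------------------
# Expression and report counts
# ---------------------------------------------------------------------------

def read_expression(matrix_path: str | Path, metadata_path: str | Path) -> ExpressionTable:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    metadata = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample_id", "tissue", "lineage_group"}
    if not required.issubset(metadata.columns):
        raise FormatError(f"metadata missing columns {required - set(metadata.columns)}")
    return ExpressionTable(matrix, metadata)


def write_expression(table: ExpressionTable, matrix_path: str | Path,
                     metadata_path: str | Path) -> None:
    m = table.matrix.sort_index()
    m = m[sorted(m.columns)]
    m.to_csv(matrix_path, sep="\t", float_format="%.6g", index_label="gene_id")
    md = table.metadata.reset_index(drop=True).sort_values("sample_id")
    md[["sample_id", "tissue", "lineage_group"]].to_csv(metadata_path, sep="\t", index=False)


def read_report_counts(path: str | Path) -> dict[tuple[str, str], int]:
    df = _read_tsv(path, ["five_gene", "three_gene", "report_count"])
    out: dict[tuple[str, str], int] = {}
    for row in df.itertuples(index=False):
        rc = int(row.report_count)
        if rc < 0:
            raise FormatError("negative report_count")
        out[(row.five_gene, row.three_gene)] = rc
    return out


def write_report_counts(counts: dict[tuple[str, str], int], path: str | Path) -> None:
    rows = [[f, t, c] for (f, t), c in sorted(counts.items())]
    _write_tsv(path, ["five_gene", "three_gene", "report_count"], rows)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    if x == math.floor(x) and abs(x) < 1e15:
        return str(int(x))
    return format(x, ".10g")


def _read_tsv(path: str | Path, required: Iterable[str], allow_empty: bool = False) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file without header") from exc
    missing = set(required) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df.empty and not allow_empty:
        return df
    return df


def _write_tsv(path: str | Path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")
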