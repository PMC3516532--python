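"""Domain types shared by every stage of the pipeline.

Coordinate conventions
----------------------
Genomic intervals are 0-based half-open (BED convention).  Transcript
nucleotide positions and protein amino-acid positions are 1-based; amino-acid
intervals are inclusive (annotation convention).  The transcription start site
of a gene is ``tx_start`` on the plus strand and ``tx_end`` on the minus
strand (under the half-open convention ``tx_end`` is the coordinate just
upstream of the first transcribed base of a minus-strand gene).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

LINEAGES = ("HEM-L", "HEM-M", "both")
#: Functional categories of protein domains: DNA-binding, protein
#: interaction, histone modification, kinase, other.  ``N`` denotes a fusion
#: side that retains no categorizable domain at all.
CATEGORIES = ("D", "P", "H", "K", "O")
CATEGORIES_WITH_N = ("D", "P", "H", "K", "O", "N")
#: Type-1 partners retain at least one domain with recognized oncogenic
#: potential; type-2 partners retain only O (or nothing).
TYPE1_CATEGORIES = frozenset({"D", "P", "H", "K"})


class FormatError(ValueError):
    """Raised when an on-disk record violates its format contract."""


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene with TSS, CDS start and optional 3'-UTR."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start_nt: int
    utr3_start: int | None = None
    utr3_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start must be < tx_end")
        if self.cds_start_nt < 1:
            raise ValueError(f"{self.gene_id}: cds_start_nt must be >= 1")
        has_s, has_e = self.utr3_start is not None, self.utr3_end is not None
        if has_s != has_e:
            raise ValueError(f"{self.gene_id}: partial 3'-UTR interval")
        if has_s:
            if not self.utr3_start < self.utr3_end:  # type: ignore[operator]
                raise ValueError(f"{self.gene_id}: utr3_start must be < utr3_end")
            if self.utr3_start < self.tx_start or self.utr3_end > self.tx_end:  # type: ignore[operator]
                raise ValueError(f"{self.gene_id}: 3'-UTR outside gene span")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def midpoint(self) -> int:
        return (self.tx_start + self.tx_end) // 2

    @property
    def has_utr3(self) -> bool:
        return self.utr3_start is not None

    @property
    def utr3_length(self) -> int | None:
        if self.utr3_start is None:
            return None
        return self.utr3_end - self.utr3_start  # type: ignore[operator]


@dataclass(frozen=True)
class Translocation:
    """One 5'/3' fusion pair with transcript-coordinate breakpoints."""

    fusion_id: str
    five_gene: str
    three_gene: str
    five_bp_nt: int
    three_bp_nt: int
    lineage: str
    report_count: int
    self_fusion: bool = False

    def __post_init__(self) -> None:
        if self.five_gene == self.three_gene and not self.self_fusion:
            raise ValueError(
                f"{self.fusion_id}: identical partners without self_fusion flag"
            )
        if self.five_bp_nt < 1 or self.three_bp_nt < 1:
            raise ValueError(f"{self.fusion_id}: breakpoints must be >= 1")
        if self.lineage not in LINEAGES:
            raise ValueError(f"{self.fusion_id}: unknown lineage {self.lineage!r}")
        if self.report_count < 0:
            raise ValueError(f"{self.fusion_id}: report_count must be >= 0")

    @property
    def gene_pair(self) -> tuple[str, str]:
        return (self.five_gene, self.three_gene)


@dataclass(frozen=True)
class DomainAnnotation:
    """An InterPro-like domain or protein interaction interface (PII).

    Coordinates are 1-based inclusive amino-acid positions.  ``partners``
    names the interacting proteins of a PII and must be empty otherwise.
    """

    gene_id: str
    feature_id: str
    aa_start: int
    aa_end: int
    is_pii: bool = False
    partners: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.aa_start < 1 or self.aa_start > self.aa_end:
            raise ValueError(f"{self.feature_id}: invalid aa interval")
        if self.partners and not self.is_pii:
            raise ValueError(f"{self.feature_id}: partners on a non-PII entry")


class CategoryMap(dict):
    """feature_id -> functional category in {D, P, H, K, O}."""

    def __init__(self, mapping: Mapping[str, str] | None = None):
        super().__init__()
        if mapping:
            for k, v in mapping.items():
                self[k] = v

    def __setitem__(self, key: str, value: str) -> None:
        if value not in CATEGORIES:
            raise ValueError(f"unknown category {value!r} for {key}")
        super().__setitem__(key, value)


@dataclass(frozen=True)
class IntervalRecord:
    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"interval start {self.start} >= end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


class IntervalTrack:
    """A collection of genomic intervals (peaks, conserved elements, sites).

    Overlap queries use the >=1 bp intersection rule on half-open intervals.
    """

    def __init__(self, records: Iterable[IntervalRecord] = ()):
        self.records: list[IntervalRecord] = list(records)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def _index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        if self._by_chrom is None:
            by: dict[str, list[tuple[int, int]]] = {}
            for r in self.records:
                by.setdefault(r.chrom, []).append((r.start, r.end))
            self._by_chrom = {
                c: (
                    np.array([s for s, _ in iv], dtype=np.int64),
                    np.array([e for _, e in iv], dtype=np.int64),
                )
                for c, iv in by.items()
            }
        return self._by_chrom

    def append(self, record: IntervalRecord) -> None:
        self.records.append(record)
        self._by_chrom = None

    def count_overlaps(self, chrom: str, start: int, end: int) -> int:
        idx = self._index().get(chrom)
        if idx is None:
            return 0
        starts, ends = idx
        return int(np.count_nonzero((starts < end) & (ends > start)))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.count_overlaps(chrom, start, end) > 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


class SignalProfile:
    """Per-chromosome sorted (position, value) samples of a genomic signal.

    ``kind`` distinguishes generic signal (e.g. H3K4me3 coverage) from
    replication-timing profiles on the normalized early/late scale.
    """

    def __init__(self, data: Mapping[str, tuple[np.ndarray, np.ndarray]], kind: str = "signal"):
        if kind not in ("signal", "replication_timing"):
            raise ValueError(f"unknown profile kind {kind!r}")
        self.kind = kind
        self.data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos, val) in data.items():
            pos = np.asarray(pos, dtype=np.int64)
            val = np.asarray(val, dtype=float)
            if pos.shape != val.shape:
                raise ValueError(f"{chrom}: position/value length mismatch")
            if pos.size > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(f"{chrom}: positions must be strictly increasing")
            self.data[chrom] = (pos, val)

    def chromosomes(self) -> list[str]:
        return sorted(self.data)

    def values_in(self, chrom: str, start: int, end: int) -> tuple[np.ndarray, np.ndarray]:
        if chrom not in self.data:
            return np.empty(0, dtype=np.int64), np.empty(0)
        pos, val = self.data[chrom]
        lo, hi = np.searchsorted(pos, [start, end])
        return pos[lo:hi], val[lo:hi]


class ContactMatrix:
    """Symmetric binned interchromosomal contact frequencies.

    ``bins`` is a genome-ordered DataFrame with columns bin_id, chrom,
    start, end (0-based half-open, tiling each chromosome without overlap).
    """

    def __init__(self, bins: pd.DataFrame, values: np.ndarray):
        bins = bins.reset_index(drop=True)
        required = {"bin_id", "chrom", "start", "end"}
        if not required.issubset(bins.columns):
            raise ValueError(f"bin table missing columns {required - set(bins.columns)}")
        n = len(bins)
        values = np.asarray(values, dtype=float)
        if values.shape != (n, n):
            raise ValueError(f"value grid shape {values.shape} != ({n}, {n})")
        if np.any(values < 0):
            raise ValueError("contact values must be >= 0")
        if not np.allclose(values, values.T):
            raise ValueError("contact matrix must be symmetric")
        self.bins = bins
        self.values = values
        self._chrom_codes = pd.factorize(bins["chrom"])[0]
        self._starts_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, grp in bins.groupby("chrom", sort=False):
            order = np.argsort(grp["start"].to_numpy())
            self._starts_by_chrom[chrom] = (
                grp["start"].to_numpy()[order],
                grp.index.to_numpy()[order],
            )

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def chrom_codes(self) -> np.ndarray:
        return self._chrom_codes

    def bin_for(self, chrom: str, position: int) -> int:
        """Index of the bin containing ``position`` (half-open bins)."""
        if chrom not in self._starts_by_chrom:
            raise KeyError(f"chromosome {chrom!r} not in bin table")
        starts, idx = self._starts_by_chrom[chrom]
        i = int(np.searchsorted(starts, position, side="right")) - 1
        if i < 0:
            raise KeyError(f"position {position} before first bin of {chrom}")
        row = self.bins.iloc[idx[i]]
        if position >= row["end"]:
            raise KeyError(f"position {position} outside binned region of {chrom}")
        return int(idx[i])

    def trans_mask(self) -> np.ndarray:
        """Boolean matrix, True where the two bins lie on different chromosomes."""
        return self._chrom_codes[:, None] != self._chrom_codes[None, :]


class ExpressionTable:
    """Gene x sample expression values with sample metadata."""

    def __init__(self, matrix: pd.DataFrame, metadata: pd.DataFrame):
        if matrix.index.duplicated().any():
            raise ValueError("duplicated gene ids in expression matrix")
        if matrix.columns.duplicated().any():
            raise ValueError("duplicated sample ids in expression matrix")
        required = {"sample_id", "tissue", "lineage_group"}
        if not required.issubset(metadata.columns):
            raise ValueError(f"metadata missing columns {required - set(metadata.columns)}")
        meta = metadata.set_index("sample_id", drop=False)
        missing = set(matrix.columns) - set(meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        self.matrix = matrix
        self.metadata = meta.loc[list(matrix.columns)]

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index


@dataclass
class EnrichmentResult:
    """Observed statistic against a permuted or analytic null."""

    observed: float
    null_mean: float
    fold: float
    p_value: float
    direction: str  # {over, under}
    q_value: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("over", "under"):
            raise ValueError(f"direction must be over/under, got {self.direction!r}")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p_value must lie in (0, 1]")
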