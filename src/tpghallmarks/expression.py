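"""Expression aggregation and regulatory-feature statistics for TPGs.

Covers tissue/lineage expression summaries, paired 5'-3' partner
comparisons, promoter Pol2 peak frequency and H3K4me3 meta-profiles, 3'-UTR
features, and the fusion "gain" statistics comparing type-1 vs type-2
partners.  Group tests are delegated to scipy (Mann-Whitney for unpaired
comparisons, Wilcoxon signed-rank for paired, t-test for gain statistics);
this module owns the statistic construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import ExpressionTable, GeneModel, IntervalTrack, SignalProfile, Translocation
from .stats import zscore_normalize

LINEAGE_GROUPS = ("EPI", "HEM", "MES")


# ---------------------------------------------------------------------------
# Expression aggregation
# ---------------------------------------------------------------------------

def aggregate_by_tissue(expr: ExpressionTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene tissue means and lineage-group means.

    The tissue mean averages that tissue's donor samples only; the group
    mean averages the tissue means within the lineage group (so tissues
    with unequal donor counts contribute equally).
    """
    meta = expr.metadata
    tissue_means = {}
    for tissue, grp in meta.groupby("tissue"):
        samples = list(grp["sample_id"])
        if not samples:
            raise ValueError(f"tissue {tissue!r} has zero samples")
        tissue_means[tissue] = expr.matrix[samples].mean(axis=1)
    tissues = pd.DataFrame(tissue_means)
    tissue_to_group = meta.drop_duplicates("tissue").set_index("tissue")["lineage_group"]
    group_means = {}
    for group in sorted(tissue_to_group.unique()):
        cols = [t for t in tissues.columns if tissue_to_group[t] == group]
        group_means[group] = tissues[cols].mean(axis=1)
    return tissues, pd.DataFrame(group_means)


@dataclass
class PairedDifference:
    differences: np.ndarray
    median: float
    p_value: float
    all_zero: bool = False


def paired_partner_difference(values_a: Sequence[float],
                              values_b: Sequence[float]) -> PairedDifference:
    """Matched differences a-b with a two-sided Wilcoxon signed-rank p.

    When every pair is tied the test is undefined and p is reported as 1
    with a flag.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("matched sequences must have equal length")
    d = a - b
    if d.size == 0 or np.all(d == 0):
        return PairedDifference(differences=d, median=0.0, p_value=1.0, all_zero=True)
    p = float(sps.wilcoxon(d).pvalue)
    return PairedDifference(differences=d, median=float(np.median(d)), p_value=p)


# ---------------------------------------------------------------------------
# Promoter features
# ---------------------------------------------------------------------------

def promoter_window(gene: GeneModel, flank: int = 3000) -> tuple[str, int, int]:
    """[TSS-flank, TSS+flank) around the strand-resolved TSS, clipped at 0."""
    tss = gene.tss
    return gene.chrom, max(0, tss - flank), tss + flank


def pol2_peak_frequency(
    genes: Sequence[GeneModel],
    peak_tracks: Mapping[str, IntervalTrack],
    groups: Mapping[str, str],
    flank: int = 3000,
) -> pd.DataFrame:
    """Per-gene Pol2 peak frequency and its z-score, per cell-line group.

    The frequency is the proportion of the group's cell lines with at least
    one peak overlapping (>=1 bp) the promoter window; proportions are then
    z-normalized across all genes separately within each group.
    """
    group_lines: dict[str, list[str]] = {}
    for line, group in groups.items():
        group_lines.setdefault(group, []).append(line)
    for group, lines in group_lines.items():
        if not lines:
            raise ValueError(f"empty cell-line group {group!r}")
    rows = {}
    for g in genes:
        chrom, start, end = promoter_window(g, flank)
        row = {}
        for group, lines in sorted(group_lines.items()):
            hits = sum(peak_tracks[line].overlaps(chrom, start, end) for line in lines)
            row[f"prop_{group}"] = hits / len(lines)
        rows[g.gene_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene_id"
    for group in sorted(group_lines):
        col = f"prop_{group}"
        try:
            df[f"z_{group}"] = zscore_normalize(df[col].to_numpy())
        except ValueError:
            df[f"z_{group}"] = 0.0  # constant proportions: no spread to normalize
    return df


def signal_metaprofile(signal: SignalProfile, genes: Sequence[GeneModel],
                       flank: int = 3000, n_bins: int = 60) -> np.ndarray:
    """Averaged log2 signal profile around promoters, normalized to its max.

    Each gene's [TSS-flank, TSS+flank) window is split into ``n_bins`` bins
    oriented so bin 0 is the most upstream (minus-strand windows are
    mirrored); per-bin means of log2(value+1) are averaged over genes and
    the profile is divided by its maximum.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    width = 2 * flank
    any_overlap = False
    for g in genes:
        chrom, start, end = promoter_window(g, flank)
        pos, val = signal.values_in(chrom, start, end)
        if pos.size == 0:
            continue
        any_overlap = True
        rel = (pos - (g.tss - flank)) / width
        bins = np.clip((rel * n_bins).astype(int), 0, n_bins - 1)
        if g.strand == "-":
            bins = n_bins - 1 - bins
        np.add.at(sums, bins, np.log2(val + 1.0))
        np.add.at(counts, bins, 1.0)
    if not any_overlap:
        raise ValueError("no gene promoter overlaps the signal")
    with np.errstate(invalid="ignore"):
        profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    peak = np.nanmax(profile)
    if peak == 0:
        return profile
    return profile / peak


# ---------------------------------------------------------------------------
# 3'-UTR features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Utr3Features:
    gene_id: str
    utr_length: int
    n_conserved: int
    n_mirna_sites: int


def utr3_features(gene: GeneModel, conserved_track: IntervalTrack,
                  mirna_track: IntervalTrack) -> Utr3Features | None:
    """3'-UTR length plus counts of overlapping conserved elements and
    microRNA target sites; None when the gene has no annotated 3'-UTR."""
    if not gene.has_utr3:
        return None
    s, e = gene.utr3_start, gene.utr3_end
    return Utr3Features(
        gene_id=gene.gene_id,
        utr_length=e - s,  # type: ignore[operator]
        n_conserved=conserved_track.count_overlaps(gene.chrom, s, e),  # type: ignore[arg-type]
        n_mirna_sites=mirna_track.count_overlaps(gene.chrom, s, e),  # type: ignore[arg-type]
    )


# ---------------------------------------------------------------------------
# Fusion gain statistics (type-1 vs type-2 partner comparisons)
# ---------------------------------------------------------------------------

@dataclass
class GainComparison:
    values: pd.DataFrame           # per-translocation statistics + types
    tests: dict[str, tuple[float, float]]   # statistic -> (t, p)
    n_excluded: int


def fusion_gain_stats(
    translocations: Sequence[Translocation],
    pol2_occupancy: Mapping[str, float],
    utr_lengths: Mapping[str, float],
    expression_values: Mapping[str, float],
    partner_types: Mapping[str, tuple[int, int]],
) -> GainComparison:
    """Per-translocation gain statistics and type-1 vs type-2 comparisons.

    pol2_gain    = occupancy(5' promoter) - occupancy(3' promoter),
                   compared between 5'-type-1 and 5'-type-2 fusions;
    utr_log2     = log2(UTR length 5' / UTR length 3'),
                   compared between 3'-type groups;
    expr_gain    = expression(5') / expression(3') - 1,
                   compared between 5'-type groups.

    Fusions with a zero 3'-UTR length or zero 3' expression are excluded
    from the affected ratio with a warning.
    """
    rows = []
    excluded = 0
    for t in translocations:
        ty5, ty3 = partner_types[t.fusion_id]
        row: dict[str, object] = {"fusion_id": t.fusion_id, "type5": ty5, "type3": ty3}
        if t.five_gene in pol2_occupancy and t.three_gene in pol2_occupancy:
            row["pol2_gain"] = pol2_occupancy[t.five_gene] - pol2_occupancy[t.three_gene]
        l5, l3 = utr_lengths.get(t.five_gene), utr_lengths.get(t.three_gene)
        if l5 is not None and l3 is not None:
            if l3 == 0 or l5 == 0:
                warnings.warn(f"{t.fusion_id}: zero 3'-UTR length, excluded from ratio")
                excluded += 1
            else:
                row["utr_log2_ratio"] = float(np.log2(l5 / l3))
        e5, e3 = expression_values.get(t.five_gene), expression_values.get(t.three_gene)
        if e5 is not None and e3 is not None and e3 != 0:
            row["expr_gain"] = e5 / e3 - 1.0
        rows.append(row)
    df = pd.DataFrame(rows).set_index("fusion_id")
    tests: dict[str, tuple[float, float]] = {}
    for col, type_col in (("pol2_gain", "type5"), ("utr_log2_ratio", "type3"),
                          ("expr_gain", "type5")):
        if col not in df.columns:
            continue
        g1 = df.loc[df[type_col] == 1, col].dropna()
        g2 = df.loc[df[type_col] == 2, col].dropna()
        if len(g1) >= 2 and len(g2) >= 2:
            res = sps.ttest_ind(g1, g2, equal_var=False)
            tests[col] = (float(res.statistic), float(res.pvalue))
    return GainComparison(values=df, tests=tests, n_excluded=excluded)
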