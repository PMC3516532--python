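"""Nuclear-proximity statistics on binned Hi-C contact matrices.

Contact frequency is used directly as the proximity measure (higher =
spatially closer); only interchromosomal (trans) contacts enter any pair
statistic.  Genes map to bins by gene-body midpoint.

The pair-proximity test compares the mean trans contact of observed 5'-3'
gene pairs against four permutation nulls: shuffling the pairing itself,
replacing either side with random genes from a universe, or replacing both.
Replacement draws that land both genes on one chromosome are redrawn (the
pair count stays constant); shuffled pairings that become cis are dropped
from that permutation's mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.cluster import KMeans

from .models import ContactMatrix, GeneModel

SCHEMES = ("shuffle", "replace5", "replace3", "random")


class CisPairError(ValueError):
    """A same-chromosome pair was queried where only trans pairs are defined."""


def gene_bin_index(gene: GeneModel, matrix: ContactMatrix,
                   anchor: str = "midpoint") -> int:
    """Bin containing the gene-body midpoint (or the TSS when requested)."""
    pos = gene.midpoint if anchor == "midpoint" else gene.tss
    return matrix.bin_for(gene.chrom, pos)


def pair_contact_frequency(matrix: ContactMatrix, gene_a: GeneModel,
                           gene_b: GeneModel, anchor: str = "midpoint") -> float:
    """Trans contact value of two genes' bins; cis pairs are excluded."""
    ia = gene_bin_index(gene_a, matrix, anchor)
    ib = gene_bin_index(gene_b, matrix, anchor)
    if matrix.chrom_codes[ia] == matrix.chrom_codes[ib]:
        raise CisPairError(f"{gene_a.gene_id}/{gene_b.gene_id} share a chromosome")
    return float(matrix.values[ia, ib])


@dataclass
class PairProximityResult:
    observed_mean: float
    n_pairs: int
    null_means: dict[str, float]
    null_sds: dict[str, float]
    p_values: dict[str, float]
    n_perm: int


def _map_pairs(pairs: Sequence[tuple[GeneModel, GeneModel]], matrix: ContactMatrix,
               anchor: str) -> tuple[np.ndarray, np.ndarray]:
    b5 = np.array([gene_bin_index(a, matrix, anchor) for a, _ in pairs])
    b3 = np.array([gene_bin_index(b, matrix, anchor) for _, b in pairs])
    return b5, b3


def tpg_pair_proximity_test(
    pairs: Sequence[tuple[GeneModel, GeneModel]],
    matrix: ContactMatrix,
    gene_universe: Sequence[GeneModel],
    n_perm: int = 100_000,
    seed: int | np.random.Generator = 0,
    anchor: str = "midpoint",
    schemes: Sequence[str] = SCHEMES,
) -> PairProximityResult:
    """Mean trans contact of gene pairs against four permutation nulls.

    p per scheme is the add-one empirical fraction of permuted means that
    are >= the observed mean, i.e. small p means the observed pairs are
    closer than the null predicts.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two pairs")
    if len(gene_universe) < len(pairs):
        raise ValueError("universe smaller than pair count")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chrom = matrix.chrom_codes
    M = matrix.values

    b5, b3 = _map_pairs(pairs, matrix, anchor)
    trans = chrom[b5] != chrom[b3]
    if not trans.any():
        raise ValueError("no interchromosomal pairs")
    b5t, b3t = b5[trans], b3[trans]
    n_pairs = int(trans.sum())
    observed = float(M[b5t, b3t].mean())

    uni_bins = np.array([gene_bin_index(g, matrix, anchor) for g in gene_universe])

    null_means: dict[str, float] = {}
    null_sds: dict[str, float] = {}
    p_values: dict[str, float] = {}
    for scheme in schemes:
        stats = np.empty(n_perm)
        for p in range(n_perm):
            if scheme == "shuffle":
                perm = rng.permutation(n_pairs)
                a, b = b5t, b3t[perm]
                keep = chrom[a] != chrom[b]
                if not keep.any():
                    stats[p] = np.nan
                    continue
                stats[p] = M[a[keep], b[keep]].mean()
            else:
                if scheme == "replace5":
                    a = _draw_trans(rng, uni_bins, b3t, chrom)
                    b = b3t
                elif scheme == "replace3":
                    a = b5t
                    b = _draw_trans(rng, uni_bins, b5t, chrom)
                else:  # random: both sides random, cis combinations redrawn
                    a = uni_bins[rng.integers(0, len(uni_bins), n_pairs)]
                    b = _draw_trans(rng, uni_bins, a, chrom)
                stats[p] = M[a, b].mean()
        valid = stats[~np.isnan(stats)]
        null_means[scheme] = float(valid.mean())
        null_sds[scheme] = float(valid.std())
        p_values[scheme] = (1 + int(np.count_nonzero(valid >= observed))) / (valid.size + 1)
    return PairProximityResult(observed_mean=observed, n_pairs=n_pairs,
                               null_means=null_means, null_sds=null_sds,
                               p_values=p_values, n_perm=n_perm)


def _draw_trans(rng: np.random.Generator, uni_bins: np.ndarray,
                fixed: np.ndarray, chrom: np.ndarray) -> np.ndarray:
    """Uniform draws from the universe, redrawn until trans vs ``fixed``."""
    n = fixed.size
    out = uni_bins[rng.integers(0, uni_bins.size, n)]
    bad = chrom[out] == chrom[fixed]
    guard = 0
    while bad.any():
        out[bad] = uni_bins[rng.integers(0, uni_bins.size, int(bad.sum()))]
        bad = chrom[out] == chrom[fixed]
        guard += 1
        if guard > 10_000:
            raise ValueError("universe too small after chromosome exclusions")
    return out


# ---------------------------------------------------------------------------
# Central / peripheral partition and centrality
# ---------------------------------------------------------------------------

@dataclass
class CompartmentPartition:
    labels: np.ndarray             # 'central' / 'peripheral' per bin
    cluster_mean_contact: dict[str, float]
    central_mask: np.ndarray


def _trans_profile(matrix: ContactMatrix) -> np.ndarray:
    """Per-bin trans-contact feature rows; cis entries imputed with the
    bin's own mean trans contact so chromosome identity carries no signal."""
    M = matrix.values.copy()
    trans = matrix.trans_mask()
    row_means = np.where(trans, M, np.nan)
    row_means = np.nanmean(row_means, axis=1)
    cis = ~trans
    M[cis] = np.repeat(row_means, cis.sum(axis=1))
    return M


def partition_contact_clusters(matrix: ContactMatrix, k: int = 2,
                               seed: int = 0, restarts: int = 10,
                               ) -> CompartmentPartition:
    """K-means partition of bins into central and peripheral compartments.

    Rows of the trans-only contact profile are clustered; the cluster with
    the higher mean trans contact is labelled central.
    """
    if k > matrix.n_bins:
        raise ValueError("k exceeds number of bins")
    X = _trans_profile(matrix)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    raw = km.fit_predict(X)
    trans = matrix.trans_mask()
    mean_contact = {}
    for c in range(k):
        rows = raw == c
        mean_contact[c] = float(matrix.values[rows][trans[rows]].mean()) \
            if rows.any() and trans[rows].any() else -np.inf
    central_cluster = max(mean_contact, key=mean_contact.get)  # type: ignore[arg-type]
    labels = np.where(raw == central_cluster, "central", "peripheral")
    central_mask = raw == central_cluster
    return CompartmentPartition(
        labels=labels,
        cluster_mean_contact={
            "central": mean_contact[central_cluster],
            "peripheral": float(np.mean([v for c, v in mean_contact.items()
                                         if c != central_cluster])),
        },
        central_mask=central_mask,
    )


def locus_centrality(matrix: ContactMatrix, gene: GeneModel,
                     anchor: str = "midpoint") -> float:
    """Mean trans contact of the gene's bin with bins on other chromosomes."""
    i = gene_bin_index(gene, matrix, anchor)
    trans = matrix.chrom_codes != matrix.chrom_codes[i]
    if not trans.any():
        raise ValueError("no trans bins for centrality")
    return float(matrix.values[i, trans].mean())


def bin_centrality(matrix: ContactMatrix) -> np.ndarray:
    """Mean trans contact per bin (vectorized locus centrality)."""
    trans = matrix.trans_mask()
    vals = np.where(trans, matrix.values, np.nan)
    return np.nanmean(vals, axis=1)


# ---------------------------------------------------------------------------
# Lineage comparison and chromosome-pair closeness
# ---------------------------------------------------------------------------

@dataclass
class LineageContrast:
    differences: dict[str, np.ndarray]
    wilcoxon_p: dict[str, float]
    between_p: float | None
    spearman_r: float
    spearman_p: float
    n_dropped: int


def lineage_contact_difference(
    pairs_by_lineage: Mapping[str, Sequence[tuple[GeneModel, GeneModel]]],
    matrix_a: ContactMatrix, matrix_b: ContactMatrix,
    epsilon: float = 1.0, anchor: str = "midpoint",
) -> LineageContrast:
    """Per-pair log2 contact differences between two cell-line matrices.

    For each lineage set: difference log2(a+eps) - log2(b+eps) per pair and
    a Wilcoxon signed-rank test; a Mann-Whitney test between lineage sets;
    Spearman correlation of pair values across the two matrices.
    """
    diffs: dict[str, np.ndarray] = {}
    wilcoxon: dict[str, float] = {}
    all_a: list[float] = []
    all_b: list[float] = []
    dropped = 0
    for lineage, pairs in pairs_by_lineage.items():
        va, vb = [], []
        for ga, gb in pairs:
            try:
                va.append(pair_contact_frequency(matrix_a, ga, gb, anchor))
                vb.append(pair_contact_frequency(matrix_b, ga, gb, anchor))
            except (KeyError, CisPairError):
                dropped += 1
        va_arr, vb_arr = np.array(va), np.array(vb)
        d = np.log2(va_arr + epsilon) - np.log2(vb_arr + epsilon)
        diffs[lineage] = d
        if d.size and np.any(d != 0):
            wilcoxon[lineage] = float(sps.wilcoxon(d).pvalue)
        else:
            wilcoxon[lineage] = 1.0
        all_a.extend(va)
        all_b.extend(vb)
    lineages = sorted(diffs)
    if len(lineages) == 2 and all(diffs[l].size for l in lineages):
        between = float(sps.mannwhitneyu(diffs[lineages[0]], diffs[lineages[1]],
                                         alternative="two-sided").pvalue)
    else:
        between = None
    if len(all_a) >= 2 and len(set(all_a)) > 1 and len(set(all_b)) > 1:
        rho = sps.spearmanr(all_a, all_b)
        spearman_r, spearman_p = float(rho.statistic), float(rho.pvalue)
    else:
        spearman_r, spearman_p = 1.0 if all_a == all_b else float("nan"), float("nan")
    return LineageContrast(differences=diffs, wilcoxon_p=wilcoxon, between_p=between,
                           spearman_r=spearman_r, spearman_p=spearman_p,
                           n_dropped=dropped)


@dataclass
class ChromosomePairCloseness:
    values: np.ndarray
    median: float
    iqr: float


def chromosome_pair_closeness(matrix: ContactMatrix, chrom_a: str,
                              chrom_b: str) -> ChromosomePairCloseness:
    """All bin-pair trans contact values between two chromosomes."""
    if chrom_a == chrom_b:
        raise ValueError("closeness is defined for distinct chromosomes only")
    bins_a = matrix.bins.index[matrix.bins["chrom"] == chrom_a].to_numpy()
    bins_b = matrix.bins.index[matrix.bins["chrom"] == chrom_b].to_numpy()
    if bins_a.size == 0 or bins_b.size == 0:
        raise KeyError("chromosome absent from bin table")
    vals = matrix.values[np.ix_(bins_a, bins_b)].ravel()
    q1, q3 = np.percentile(vals, [25, 75])
    return ChromosomePairCloseness(values=vals, median=float(np.median(vals)),
                                   iqr=float(q3 - q1))


def compare_chromosome_pairs(a: ChromosomePairCloseness,
                             b: ChromosomePairCloseness) -> float:
    """Two-sided Mann-Whitney p comparing two chromosome-pair distributions."""
    return float(sps.mannwhitneyu(a.values, b.values, alternative="two-sided").pvalue)
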