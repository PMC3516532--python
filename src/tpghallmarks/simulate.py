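"""Synthetic inputs with known planted structure for every pipeline stage.

The generator emulates the statistical structure of the real data sources
(curated translocation tables, gene models, domain annotations, expression
matrices, peak/signal tracks, normalized Hi-C matrices, replication-timing
profiles and report counts) without attempting to mimic real chromosome
lengths, real gene names or probe-level microarray noise.  Every planted
effect - domain-category co-occurrence folds, the hematopoietic expression
shift of 5' partners, 3'-UTR shortening of 3' partners, the central nuclear
compartment with boosted trans contacts, the RT-centrality coupling and
Zipf-like report counts - is recoverable by the corresponding analysis
module, and the planted parameters are returned as ground truth.

Planted co-occurrence is realized by exact sampling from a tilted joint
distribution: the achievable retained-category sets of each fusion side are
enumerated from the gene catalog (genes x candidate breakpoints), the
independent joint of the two empirical set distributions is tilted by the
planted fold matrix, set pairs are drawn from that discrete law, and each
draw is realized by a uniformly chosen gene/breakpoint producing that set.
Marginal category frequencies stay interpretable and no rejection loop is
needed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import io as tio
from .domains import breakpoint_nt_to_aa, partner_category_set, retained_and_lost
from .models import (
    CATEGORIES,
    CATEGORIES_WITH_N,
    CategoryMap,
    ContactMatrix,
    DomainAnnotation,
    ExpressionTable,
    GeneModel,
    IntervalRecord,
    IntervalTrack,
    SignalProfile,
    Translocation,
)

_CAT_IDX = {c: i for i, c in enumerate(CATEGORIES_WITH_N)}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study, with planted effect sizes as defaults."""

    seed: int = 0
    n_chrom: int = 5
    n_genes: int = 1000
    n_bins: int = 500
    bin_size: int = 1_000_000
    n_transloc: int = 300
    #: planted fold on category co-occurrence, keyed "c5,c3"; unlisted = 1.0
    cooccurrence_folds: dict[str, float] = field(default_factory=dict)
    #: log2 expression shift of 5' TPGs in hematopoietic samples
    expression_shift: float = 1.0
    #: 3' TPG 3'-UTR length as a fraction of its original length
    utr_ratio: float = 0.5
    contact_decay: float = 1.0
    central_fraction: float = 0.2
    contact_boost: float = 5.0
    contact_noise_sigma: float = 0.2
    #: correlation between replication timing and bin centrality
    rt_centrality_corr: float = 0.9
    rt_noise_sigma: float = 1.0
    zipf_exponent: float = 2.0
    #: sampling weight of central-bin genes when realizing each fusion side
    central_weight_5p: float = 3.0
    central_weight_3p: float = 1.0
    #: domain category frequencies (5 categories D/P/H/K/O)
    category_weights: tuple[float, ...] = (0.30, 0.30, 0.10, 0.10, 0.20)
    mean_domains_per_gene: float = 3.5
    pii_gene_fraction: float = 0.4
    pol2_background_prob: float = 0.3
    pol2_tpg_hem_prob: float = 0.8

    def __post_init__(self) -> None:
        if min(self.n_chrom, self.n_genes, self.n_bins, self.bin_size,
               self.n_transloc) <= 0:
            raise ValueError("counts must be positive")
        for frac in (self.central_fraction, self.utr_ratio):
            if not 0 < frac < 1:
                raise ValueError("fractions must lie in (0, 1)")
        if any(f <= 0 for f in self.cooccurrence_folds.values()):
            raise ValueError("planted folds must be > 0")

    @property
    def chrom_length(self) -> int:
        bins_per_chrom = self.n_bins // self.n_chrom
        return bins_per_chrom * self.bin_size

    def fold_matrix(self) -> np.ndarray:
        M = np.ones((6, 6))
        for key, fold in self.cooccurrence_folds.items():
            c5, c3 = key.split(",")
            M[_CAT_IDX[c5], _CAT_IDX[c3]] = fold
        return M


@dataclass
class Bundle:
    """Everything one pipeline run consumes, plus the planted ground truth."""

    config: SimulationConfig
    catalog: dict[str, GeneModel]
    cmap: CategoryMap
    annotations: list[DomainAnnotation]
    translocations: list[Translocation]
    matrix_a: ContactMatrix
    matrix_b: ContactMatrix
    central_mask: np.ndarray
    rt_profile: SignalProfile
    expression: ExpressionTable
    pol2_tracks: dict[str, IntervalTrack]
    cell_line_groups: dict[str, str]
    h3k4me3: SignalProfile
    conserved: IntervalTrack
    mirna: IntervalTrack
    report_counts: dict[tuple[str, str], int]
    truth: dict


# ---------------------------------------------------------------------------
# Genome, domains, categories
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[dict[str, GeneModel], CategoryMap, list[DomainAnnotation]]:
    """Gene catalog tiled on chromosomes, with domains, PIIs and categories."""
    rng = rng or np.random.default_rng(config.seed)
    per_chrom = config.n_genes // config.n_chrom
    remainder = config.n_genes - per_chrom * config.n_chrom
    slot = config.chrom_length // (per_chrom + 1)
    if slot < 10_000:
        raise ValueError("genome too small for requested gene count")
    catalog: dict[str, GeneModel] = {}
    cmap = CategoryMap()
    annotations: list[DomainAnnotation] = []
    gid = 0
    all_gene_ids = [f"G{g:04d}" for g in range(config.n_genes)]
    for c in range(config.n_chrom):
        n_here = per_chrom + (1 if c < remainder else 0)
        for s in range(n_here):
            gene_id = all_gene_ids[gid]
            gid += 1
            tx_len = int(rng.integers(3000, 9000))
            utr_len = int(rng.integers(300, 2000))
            cds_start = int(rng.integers(50, 300))
            start = s * slot + int(rng.integers(0, max(1, slot - tx_len)))
            strand = "+" if rng.random() < 0.5 else "-"
            end = start + tx_len
            if strand == "+":
                utr_s, utr_e = end - utr_len, end
            else:
                utr_s, utr_e = start, start + utr_len
            gene = GeneModel(gene_id=gene_id, chrom=f"chr{c + 1}", strand=strand,
                             tx_start=start, tx_end=end, cds_start_nt=cds_start,
                             utr3_start=utr_s, utr3_end=utr_e)
            catalog[gene_id] = gene
            protein_len = max(60, (tx_len - cds_start - utr_len) // 3)
            n_dom = min(int(rng.poisson(config.mean_domains_per_gene)), 6)
            if n_dom > 0:
                edges = np.sort(rng.choice(np.arange(1, protein_len),
                                           size=min(n_dom * 2, protein_len - 1),
                                           replace=False))
                for d in range(min(n_dom, edges.size // 2)):
                    a, b = int(edges[2 * d]), int(edges[2 * d + 1])
                    feature_id = f"DOM_{gene_id}_{d}"
                    cat = CATEGORIES[rng.choice(5, p=config.category_weights)]
                    cmap[feature_id] = cat
                    annotations.append(DomainAnnotation(
                        gene_id=gene_id, feature_id=feature_id,
                        aa_start=a, aa_end=b))
            if rng.random() < config.pii_gene_fraction:
                n_pii = int(rng.integers(1, 3))
                for p in range(n_pii):
                    a = int(rng.integers(1, max(2, protein_len - 20)))
                    b = min(protein_len, a + int(rng.integers(10, 60)))
                    partners = frozenset(
                        all_gene_ids[i] for i in
                        rng.choice(config.n_genes, size=int(rng.integers(1, 4)),
                                   replace=False)
                    )
                    annotations.append(DomainAnnotation(
                        gene_id=gene_id, feature_id=f"PII_{gene_id}_{p}",
                        aa_start=a, aa_end=b, is_pii=True, partners=partners))
    return catalog, cmap, annotations


def _protein_length(gene: GeneModel) -> int:
    utr = gene.utr3_length or 0
    return max(60, (gene.tx_end - gene.tx_start - gene.cds_start_nt - utr) // 3)


# ---------------------------------------------------------------------------
# Contact matrix and compartments
# ---------------------------------------------------------------------------

def _contiguous_mask(n: int, bins_per_chrom: int, fraction: float,
                     rng: np.random.Generator, segment: int = 10) -> np.ndarray:
    """Central compartment as contiguous multi-bin segments per chromosome.

    Real central regions span megabase blocks, so the planted compartment is
    laid down in ~``segment``-bin runs rather than isolated bins; this also
    keeps the compartment visible to locally smoothed profiles (RT)."""
    mask = np.zeros(n, dtype=bool)
    target = int(round(fraction * n))
    guard = 0
    while mask.sum() < target and guard < 10_000:
        chrom = int(rng.integers(0, n // bins_per_chrom))
        length = max(2, int(rng.geometric(1.0 / segment)))
        start = chrom * bins_per_chrom + int(rng.integers(0, bins_per_chrom))
        stop = min((chrom + 1) * bins_per_chrom, start + length)
        room = target - int(mask.sum())
        mask[start:min(stop, start + room + (stop - start))] = True
        if mask.sum() > target:
            extra = int(mask.sum()) - target
            on = np.nonzero(mask[start:stop])[0]
            mask[start + on[-extra:]] = False
        guard += 1
    return mask


def simulate_contact_matrix(config: SimulationConfig,
                            rng: np.random.Generator | None = None,
                            central_mask: np.ndarray | None = None,
                            ) -> tuple[ContactMatrix, np.ndarray]:
    """Distance-decay matrix with a planted high-trans-contact compartment.

    Trans values are base * (1 + boost * central_i * central_j) * lognormal
    noise; cis values follow a power-law distance decay (they are present
    in the matrix but every downstream pair statistic masks them out).
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    bins_per_chrom = config.n_bins // config.n_chrom
    n = bins_per_chrom * config.n_chrom
    rows = []
    for c in range(config.n_chrom):
        for b in range(bins_per_chrom):
            rows.append({"bin_id": len(rows), "chrom": f"chr{c + 1}",
                         "start": b * config.bin_size,
                         "end": (b + 1) * config.bin_size})
    bins = pd.DataFrame(rows)
    chrom_codes = np.repeat(np.arange(config.n_chrom), bins_per_chrom)
    if central_mask is None:
        central_mask = _contiguous_mask(n, bins_per_chrom, config.central_fraction, rng)
    central = central_mask.astype(float)

    base = 1.0
    boost = 1.0 + config.contact_boost * np.outer(central, central)
    noise = rng.lognormal(mean=0.0, sigma=config.contact_noise_sigma, size=(n, n))
    values = base * boost * noise
    # cis block: power-law distance decay
    offset = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]).astype(float)
    cis = chrom_codes[:, None] == chrom_codes[None, :]
    decay = 20.0 / np.power(offset + 1.0, config.contact_decay)
    values = np.where(cis, decay * noise, values)
    values = np.triu(values) + np.triu(values, 1).T  # symmetrize
    return ContactMatrix(bins, values), central_mask


def gene_central_flags(catalog: dict[str, GeneModel], matrix: ContactMatrix,
                       central_mask: np.ndarray) -> dict[str, bool]:
    """Whether each gene's midpoint bin carries the central label."""
    flags = {}
    for gene_id, g in catalog.items():
        try:
            flags[gene_id] = bool(central_mask[matrix.bin_for(g.chrom, g.midpoint)])
        except KeyError:
            flags[gene_id] = False
    return flags


# ---------------------------------------------------------------------------
# Translocations with planted co-occurrence
# ---------------------------------------------------------------------------

def _candidate_sets(catalog: dict[str, GeneModel],
                    annotations: Sequence[DomainAnnotation],
                    cmap: CategoryMap, rng: np.random.Generator,
                    breakpoints_per_gene: int = 8,
                    ) -> tuple[list[tuple[str, int, frozenset]], list[tuple[str, int, frozenset]]]:
    """Enumerate (gene, breakpoint_nt, retained category set) per fusion side."""
    by_gene: dict[str, list[DomainAnnotation]] = {}
    for a in annotations:
        by_gene.setdefault(a.gene_id, []).append(a)
    cand5, cand3 = [], []
    for gene_id, g in catalog.items():
        plen = _protein_length(g)
        aas = rng.integers(1, plen + 1, size=breakpoints_per_gene)
        anns = by_gene.get(gene_id, [])
        for aa in aas:
            bp_nt = g.cds_start_nt + 3 * (int(aa) - 1)  # inside the CDS
            aa_pos, _ = breakpoint_nt_to_aa(bp_nt, g.cds_start_nt)
            r5 = retained_and_lost(anns, aa_pos, "five_prime", "")
            r3 = retained_and_lost(anns, aa_pos, "three_prime", "")
            s5, _ = partner_category_set(r5, cmap)
            s3, _ = partner_category_set(r3, cmap)
            cand5.append((gene_id, bp_nt, s5))
            cand3.append((gene_id, bp_nt, s3))
    return cand5, cand3


def _calibrated_joint(sets5: list[frozenset], sets3: list[frozenset],
                      p5: np.ndarray, p3: np.ndarray, folds: np.ndarray,
                      n_iter: int = 500, tol: float = 1e-8) -> np.ndarray:
    """Joint law over (5' set, 3' set) whose category-pair cells sit at the
    planted folds *relative to its own marginals*.

    A naive exponential tilt of the independent joint inflates the two
    category marginals, so the realized fold against a marginal-preserving
    permutation null undershoots the planted target (a single-cell
    odds-ratio tilt cannot even reach moderate folds).  Instead, for each
    planted cell (c5, c3) the 2x2 "quadrant" law over membership indicators
    (c5 in set5) x (c3 in set3) is driven to a target that keeps both
    category marginals at their base values and places fold x m5 x m3 mass
    on the (1,1) quadrant.  Weights are constant within a quadrant, so a
    single planted cell is matched exactly in one step; multiple planted
    cells interact and are handled by a damped fixed-point iteration.
    Infeasible targets (quadrant mass outside [0, 1]) raise a config error.
    """
    ind5 = np.array([[c in s for c in CATEGORIES_WITH_N] for s in sets5], dtype=float)
    ind3 = np.array([[c in s for c in CATEGORIES_WITH_N] for s in sets3], dtype=float)
    base = np.outer(p5, p3)
    base /= base.sum()
    planted = [(i, j) for i in range(6) for j in range(6) if folds[i, j] != 1.0]
    if not planted:
        return base

    m5_base = p5 @ ind5
    m3_base = p3 @ ind3
    targets: dict[tuple[int, int], np.ndarray] = {}
    for i, j in planted:
        m5, m3 = m5_base[i], m3_base[j]
        cell = folds[i, j] * m5 * m3
        T = np.array([[1 - m5 - m3 + cell, m3 - cell],
                      [m5 - cell, cell]])
        if np.any(T <= 0):
            raise ValueError(
                f"planted fold {folds[i, j]} on "
                f"({CATEGORIES_WITH_N[i]},{CATEGORIES_WITH_N[j]}) infeasible "
                f"for marginals ({m5:.3f}, {m3:.3f})")
        targets[(i, j)] = T

    weights = {cell: np.ones((2, 2)) for cell in targets}
    joint = base
    for _ in range(n_iter):
        logw = np.zeros_like(base)
        for (i, j), w in weights.items():
            a = ind5[:, i].astype(int)[:, None]
            b = ind3[:, j].astype(int)[None, :]
            logw += np.log(w)[a, b]
        joint = base * np.exp(logw)
        joint /= joint.sum()
        err = 0.0
        for (i, j), T in targets.items():
            a = ind5[:, i].astype(int)
            b = ind3[:, j].astype(int)
            R = np.zeros((2, 2))
            for qa in (0, 1):
                for qb in (0, 1):
                    R[qa, qb] = joint[np.ix_(a == qa, b == qb)].sum()
            err = max(err, float(np.abs(R - T).max()))
            weights[(i, j)] *= np.power(T / np.maximum(R, 1e-300), 0.5)
        if err < tol:
            break
    return joint


def simulate_translocation_set(
    config: SimulationConfig,
    catalog: dict[str, GeneModel],
    annotations: Sequence[DomainAnnotation],
    cmap: CategoryMap,
    rng: np.random.Generator | None = None,
    central_flags: dict[str, bool] | None = None,
) -> list[Translocation]:
    """Translocations whose retained-category co-occurrence follows the
    planted fold matrix applied to independence expectations.

    Breakpoints lie inside the CDS.  When central flags are supplied, the
    gene realizing each side is drawn with extra weight on central-bin genes
    (5' and 3' weights configured separately), emulating the nuclear-position
    bias of partner genes.  Report counts are Zipf-distributed.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    cand5, cand3 = _candidate_sets(catalog, annotations, cmap, rng)
    folds = config.fold_matrix()

    def group(cands):
        by_set: dict[frozenset, list[int]] = {}
        for i, (_, _, s) in enumerate(cands):
            by_set.setdefault(s, []).append(i)
        sets = sorted(by_set, key=sorted)
        probs = np.array([len(by_set[s]) for s in sets], dtype=float)
        return sets, probs / probs.sum(), by_set

    sets5, p5, by5 = group(cand5)
    sets3, p3, by3 = group(cand3)

    # feasibility: every planted non-unit fold must have support on both sides
    support5 = set().union(*sets5)
    support3 = set().union(*sets3)
    for i, c5 in enumerate(CATEGORIES_WITH_N):
        for j, c3 in enumerate(CATEGORIES_WITH_N):
            if folds[i, j] != 1.0 and (c5 not in support5 or c3 not in support3):
                raise ValueError(
                    f"planted fold on ({c5},{c3}) infeasible: no candidate support")

    joint = _calibrated_joint(sets5, sets3, p5, p3, folds)

    def pick(cands, indices, weight_central):
        if central_flags is None or weight_central == 1.0:
            return cands[indices[int(rng.integers(0, len(indices)))]]
        w = np.array([weight_central if central_flags.get(cands[i][0], False)
                      else 1.0 for i in indices])
        w /= w.sum()
        return cands[indices[int(rng.choice(len(indices), p=w))]]

    p_heml = 177 / 378  # lymphoid vs myeloid proportions of the study frame
    translocs: list[Translocation] = []
    flat_p = joint.ravel()
    for k in range(config.n_transloc):
        for _ in range(1000):
            flat = int(rng.choice(joint.size, p=flat_p))
            i5, i3 = np.unravel_index(flat, joint.shape)
            s5, s3 = sets5[i5], sets3[i3]
            g5, bp5, _ = pick(cand5, by5[s5], config.central_weight_5p)
            idx3 = [i for i in by3[s3] if cand3[i][0] != g5]
            if idx3:
                g3, bp3, _ = pick(cand3, idx3, config.central_weight_3p)
                break
        else:
            raise ValueError("could not draw distinct partner genes")
        rc = min(int(rng.zipf(config.zipf_exponent)), 1000)
        lineage = "HEM-L" if rng.random() < p_heml else "HEM-M"
        translocs.append(Translocation(
            fusion_id=f"F{k:04d}", five_gene=g5, three_gene=g3,
            five_bp_nt=bp5, three_bp_nt=bp3, lineage=lineage, report_count=rc))
    return translocs


# ---------------------------------------------------------------------------
# Replication timing
# ---------------------------------------------------------------------------

def simulate_rt_profile(config: SimulationConfig, matrix: ContactMatrix,
                        central_mask: np.ndarray,
                        rng: np.random.Generator | None = None) -> SignalProfile:
    """RT profile correlated with bin centrality, on the -1.5..1.5 scale.

    Raw values are rho * standardized centrality + sqrt(1-rho^2) * noise,
    then linearly rescaled so the 1st/99th percentiles sit at -/+1.5.
    """
    rng = rng or np.random.default_rng(config.seed + 3)
    trans = matrix.trans_mask()
    centrality = np.where(trans, matrix.values, np.nan)
    centrality = np.nanmean(centrality, axis=1)
    # couple RT to the normal scores of centrality rank: the boosted
    # compartment makes raw centrality nearly bimodal, and the coupling is
    # monotone, so rank-based coupling keeps the configured correlation on
    # the (rank) scale the analysis measures
    ranks = sps.rankdata(centrality) / (centrality.size + 1)
    z = sps.norm.ppf(ranks)
    rho = config.rt_centrality_corr
    # spatially correlated noise (3-bin Gaussian kernel): RT varies on the
    # scale of neighbouring bins, as real profiles do, so that local
    # smoothing attenuates noise without erasing the planted coupling
    white = rng.normal(0, 1.0, size=z.size)
    kernel = np.exp(-0.5 * (np.arange(-4, 5) / 1.5) ** 2)
    smooth_noise = np.convolve(white, kernel / kernel.sum(), mode="same")
    smooth_noise /= max(smooth_noise.std(), 1e-12)
    raw = rho * z + np.sqrt(max(0.0, 1 - rho ** 2)) * config.rt_noise_sigma * smooth_noise
    lo, hi = np.percentile(raw, [1, 99])
    scaled = (raw - (hi + lo) / 2) * (3.0 / max(hi - lo, 1e-12))
    data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in matrix.bins.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        mids = ((grp["start"] + grp["end"]) // 2).to_numpy()
        order = np.argsort(mids)
        data[chrom] = (mids[order].astype(np.int64), scaled[idx][order])
    return SignalProfile(data, kind="replication_timing")


# ---------------------------------------------------------------------------
# Expression and regulatory tracks
# ---------------------------------------------------------------------------

HEM_CELL_LINES = ("hem_cl1", "hem_cl2", "hem_cl3", "hem_cl4")
NONHEM_CELL_LINES = ("nonhem_cl1", "nonhem_cl2", "nonhem_cl3", "nonhem_cl4")
_TISSUES = {
    "EPI": ("colon", "lung_epi", "mammary", "panc_duct"),
    "HEM": ("bone_marrow", "pbmc", "spleen", "t_cells"),
    "MES": ("adipose", "cartilage", "fibroblast", "smooth_muscle"),
}


def simulate_expression_and_tracks(
    config: SimulationConfig,
    catalog: dict[str, GeneModel],
    translocations: Sequence[Translocation],
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionTable, dict[str, IntervalTrack], dict[str, str],
           SignalProfile, IntervalTrack, IntervalTrack, dict[str, GeneModel]]:
    """Expression matrix plus Pol2/H3K4me3/conserved/miRNA tracks.

    Plants: a log2 expression shift for 5' TPGs in hematopoietic samples,
    elevated Pol2 peak probability for 5' TPG promoters in hematopoietic
    cell lines, and 3' TPG 3'-UTRs shortened to ``utr_ratio`` of their
    simulated length (regulatory-element counts scale with length).
    Returns the updated catalog with the shortened UTRs.
    """
    rng = rng or np.random.default_rng(config.seed + 4)
    genes = sorted(catalog)
    five_tpgs = {t.five_gene for t in translocations}
    three_tpgs = {t.three_gene for t in translocations}
    heml_five = {t.five_gene for t in translocations if t.lineage == "HEM-L"}

    # --- expression matrix (log2 scale), 3 lineages x 4 tissues x 3 donors
    baseline = rng.normal(6.0, 1.5, size=len(genes))
    cols, meta_rows = {}, []
    for group, tissues in _TISSUES.items():
        for tissue in tissues:
            for donor in range(3):
                sid = f"{tissue}_d{donor + 1}"
                vals = baseline + rng.normal(0, 0.5, size=len(genes))
                if group == "HEM":
                    shift = np.array([config.expression_shift if g in five_tpgs else 0.0
                                      for g in genes])
                    vals = vals + shift
                cols[sid] = vals
                meta_rows.append({"sample_id": sid, "tissue": tissue,
                                  "lineage_group": group})
    # two cell-line samples for lineage-specific contrasts
    for sid, bias_set in (("lymphoid_cl", heml_five), ("myeloid_cl", five_tpgs - heml_five)):
        vals = baseline + rng.normal(0, 0.5, size=len(genes))
        vals = vals + np.array([config.expression_shift / 2 if g in bias_set else 0.0
                                for g in genes])
        cols[sid] = vals
        meta_rows.append({"sample_id": sid, "tissue": sid, "lineage_group": "CL"})
    matrix = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    expr = ExpressionTable(matrix, pd.DataFrame(meta_rows))

    # --- Pol2 peaks per cell line
    groups = {cl: "hematopoietic" for cl in HEM_CELL_LINES}
    groups.update({cl: "non_hematopoietic" for cl in NONHEM_CELL_LINES})
    pol2_tracks: dict[str, IntervalTrack] = {}
    for cl, grp in groups.items():
        recs = []
        for gid in genes:
            g = catalog[gid]
            p = config.pol2_background_prob
            if grp == "hematopoietic" and gid in five_tpgs:
                p = config.pol2_tpg_hem_prob
            if rng.random() < p:
                centre = g.tss + int(rng.integers(-500, 500))
                recs.append(IntervalRecord(g.chrom, max(0, centre - 250),
                                           centre + 250, f"{cl}_{gid}"))
        pol2_tracks[cl] = IntervalTrack(recs)

    # --- H3K4me3 signal: promoter-centred bumps, larger for 5' TPGs
    bump: dict[str, dict[int, float]] = {}
    for gid in genes:
        g = catalog[gid]
        amp = 8.0 if gid in five_tpgs else 3.0
        for off in range(-3000, 3000, 100):
            pos = g.tss + off
            if pos < 0:
                continue
            v = amp * np.exp(-(off / 1200.0) ** 2) + rng.exponential(0.2)
            bump.setdefault(g.chrom, {})
            bump[g.chrom][pos] = max(bump[g.chrom].get(pos, 0.0), v)
    h3k4 = SignalProfile({
        c: (np.array(sorted(d)), np.array([d[p] for p in sorted(d)]))
        for c, d in bump.items()
    })

    # --- shorten 3' TPG UTRs and place UTR elements
    new_catalog = dict(catalog)
    for gid in three_tpgs:
        g = catalog[gid]
        if not g.has_utr3:
            continue
        new_len = max(30, int((g.utr3_length or 0) * config.utr_ratio))
        if g.strand == "+":
            us, ue = g.utr3_end - new_len, g.utr3_end  # type: ignore[operator]
        else:
            us, ue = g.utr3_start, g.utr3_start + new_len  # type: ignore[operator]
        new_catalog[gid] = dataclasses.replace(g, utr3_start=us, utr3_end=ue)

    conserved_recs, mirna_recs = [], []
    for gid in genes:
        g = new_catalog[gid]
        if not g.has_utr3:
            continue
        length = g.utr3_length or 0
        for track_recs, density, width in ((conserved_recs, 1 / 300, 20),
                                           (mirna_recs, 1 / 500, 8)):
            for _ in range(rng.poisson(length * density)):
                s = g.utr3_start + int(rng.integers(0, max(1, length - width)))  # type: ignore[operator]
                track_recs.append(IntervalRecord(g.chrom, s, s + width))
    return (expr, pol2_tracks, groups, h3k4,
            IntervalTrack(conserved_recs), IntervalTrack(mirna_recs), new_catalog)


# ---------------------------------------------------------------------------
# Helpers for planted spatial gene sets
# ---------------------------------------------------------------------------

def sample_central_pairs(catalog: dict[str, GeneModel], matrix: ContactMatrix,
                         central_mask: np.ndarray, n_pairs: int,
                         rng: np.random.Generator,
                         ) -> list[tuple[GeneModel, GeneModel]]:
    """Interchromosomal gene pairs drawn independently from central bins."""
    flags = gene_central_flags(catalog, matrix, central_mask)
    central_genes = [catalog[g] for g, f in sorted(flags.items()) if f]
    if len(central_genes) < 4:
        raise ValueError("too few central genes to sample pairs")
    pairs = []
    guard = 0
    while len(pairs) < n_pairs:
        a, b = rng.choice(len(central_genes), size=2, replace=False)
        ga, gb = central_genes[a], central_genes[b]
        if ga.chrom != gb.chrom:
            pairs.append((ga, gb))
        guard += 1
        if guard > 100 * n_pairs:
            raise ValueError("could not sample enough trans pairs")
    return pairs


def plant_central_gene_set(catalog: dict[str, GeneModel], matrix: ContactMatrix,
                           central_mask: np.ndarray, fold: float, size: int,
                           rng: np.random.Generator) -> list[str]:
    """A gene set whose central-bin fraction is ``fold`` times the background."""
    flags = gene_central_flags(catalog, matrix, central_mask)
    ids = sorted(flags)
    central = [g for g in ids if flags[g]]
    peripheral = [g for g in ids if not flags[g]]
    p_bg = len(central) / len(ids)
    target = fold * p_bg
    if not 0 < target < 1:
        raise ValueError("planted fold outside achievable range")
    k = int(round(target * size))
    if k > len(central) or size - k > len(peripheral):
        raise ValueError("planted fold infeasible for this genome")
    chosen = list(rng.choice(central, size=k, replace=False))
    chosen += list(rng.choice(peripheral, size=size - k, replace=False))
    return chosen


# ---------------------------------------------------------------------------
# Bundle generation and serialization
# ---------------------------------------------------------------------------

def simulate_bundle(config: SimulationConfig) -> Bundle:
    """Generate every pipeline input from one seed, with ground truth."""
    root = np.random.default_rng(config.seed)
    rngs = root.spawn(7)
    catalog, cmap, annotations = simulate_genome(config, rngs[0])
    matrix_a, central_mask = simulate_contact_matrix(config, rngs[1])
    matrix_b, _ = simulate_contact_matrix(config, rngs[2], central_mask=central_mask)
    flags = gene_central_flags(catalog, matrix_a, central_mask)
    translocs = simulate_translocation_set(config, catalog, annotations, cmap,
                                           rngs[3], central_flags=flags)
    rt_profile = simulate_rt_profile(config, matrix_a, central_mask, rngs[4])
    (expr, pol2_tracks, groups, h3k4, conserved, mirna,
     catalog) = simulate_expression_and_tracks(config, catalog, translocs, rngs[5])
    report_counts = {t.gene_pair: t.report_count for t in translocs}
    truth = {
        "seed": config.seed,
        "cooccurrence_folds": config.cooccurrence_folds,
        "expression_shift": config.expression_shift,
        "utr_ratio": config.utr_ratio,
        "contact_boost": config.contact_boost,
        "central_fraction": config.central_fraction,
        "rt_centrality_corr": config.rt_centrality_corr,
        "central_bins": [int(i) for i in np.nonzero(central_mask)[0]],
        "five_tpgs": sorted({t.five_gene for t in translocs}),
        "three_tpgs": sorted({t.three_gene for t in translocs}),
    }
    return Bundle(config=config, catalog=catalog, cmap=cmap,
                  annotations=annotations, translocations=translocs,
                  matrix_a=matrix_a, matrix_b=matrix_b, central_mask=central_mask,
                  rt_profile=rt_profile, expression=expr,
                  pol2_tracks=pol2_tracks, cell_line_groups=groups,
                  h3k4me3=h3k4, conserved=conserved, mirna=mirna,
                  report_counts=report_counts, truth=truth)


def write_bundle(bundle: Bundle, outdir: str | Path) -> None:
    """Serialize a bundle to the pipeline's on-disk formats."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tio.write_gene_models(bundle.catalog, out / "genes.tsv")
    tio.write_category_map(bundle.cmap, out / "categories.tsv")
    tio.write_domain_annotations(bundle.annotations, out / "domains.tsv")
    tio.write_translocations(bundle.translocations, out / "translocations.tsv")
    tio.write_contact_matrix(bundle.matrix_a, out / "bins.tsv", out / "contacts_a.tsv")
    tio.write_contact_matrix(bundle.matrix_b, out / "bins_b.tsv", out / "contacts_b.tsv")
    tio.write_bedgraph(bundle.rt_profile, out / "rt.bedgraph",
                       span=bundle.config.bin_size)
    tio.write_expression(bundle.expression, out / "expression.tsv",
                         out / "samples.tsv")
    for cl, track in sorted(bundle.pol2_tracks.items()):
        tio.write_bed(track, out / f"pol2_{cl}.bed")
    tio.write_bedgraph(bundle.h3k4me3, out / "h3k4me3.bedgraph", span=100)
    tio.write_bed(bundle.conserved, out / "conserved.bed")
    tio.write_bed(bundle.mirna, out / "mirna_sites.bed")
    tio.write_report_counts(bundle.report_counts, out / "report_counts.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(bundle.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
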