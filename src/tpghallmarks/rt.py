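"""Replication-timing smoothing, per-gene values, and early/late enrichment.

Profiles are on the normalized early/late scale (nominal range -1.5..1.5,
positive = early).  Genes with RT strictly greater than 0.5 are classified
as early-replicating.  Smoothing is LOESS (tricube-weighted local linear
regression) per chromosome, evaluated at the input positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .models import EnrichmentResult, GeneModel, SignalProfile
from .stats import fold_enrichment_binomial

EARLY_THRESHOLD = 0.5


@dataclass(frozen=True)
class RtGeneValue:
    gene_id: str
    rt: float

    @property
    def is_early(self) -> bool:
        return self.rt > EARLY_THRESHOLD


def loess_smooth(profile: SignalProfile, span: float = 0.3) -> SignalProfile:
    """LOESS-smooth a replication-timing profile chromosome by chromosome."""
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    data = {}
    for chrom, (pos, val) in profile.data.items():
        if pos.size < 10:
            raise ValueError(f"{chrom}: need >= 10 points for smoothing")
        smoothed = lowess(val, pos.astype(float), frac=span, it=1,
                          return_sorted=False)
        data[chrom] = (pos.copy(), np.asarray(smoothed, dtype=float))
    return SignalProfile(data, kind=profile.kind)


def gene_rt_value(profile: SignalProfile, gene: GeneModel) -> RtGeneValue:
    """RT at the gene midpoint, by linear interpolation along the profile."""
    if gene.chrom not in profile.data:
        raise KeyError(f"chromosome {gene.chrom!r} not covered by RT profile")
    pos, val = profile.data[gene.chrom]
    mid = gene.midpoint
    if mid < pos[0] or mid > pos[-1]:
        raise ValueError(f"{gene.gene_id}: midpoint outside profile extent")
    rt = float(np.interp(mid, pos.astype(float), val))
    return RtGeneValue(gene_id=gene.gene_id, rt=rt)


def gene_rt_values(profile: SignalProfile, genes: Iterable[GeneModel],
                   skip_uncovered: bool = True) -> dict[str, RtGeneValue]:
    out: dict[str, RtGeneValue] = {}
    for g in genes:
        try:
            out[g.gene_id] = gene_rt_value(profile, g)
        except (KeyError, ValueError):
            if not skip_uncovered:
                raise
    return out


def early_late_enrichment(gene_set: Iterable[str], background_set: Iterable[str],
                          rt_values: Mapping[str, RtGeneValue]) -> EnrichmentResult:
    """Enrichment of early-replicating genes in a set vs the background.

    Reports the percentage early in the set, the fold against the
    background percentage, and the exact binomial tail p-value with the
    background percentage as the success probability.
    """
    set_ids = [g for g in gene_set if g in rt_values]
    bg_ids = [g for g in background_set if g in rt_values]
    if not set_ids or not bg_ids:
        raise ValueError("gene set and background must both have RT values")
    k = sum(rt_values[g].is_early for g in set_ids)
    n = len(set_ids)
    bg_early = sum(rt_values[g].is_early for g in bg_ids)
    p0 = bg_early / len(bg_ids)
    if p0 in (0.0, 1.0):
        raise ValueError("background early percentage is degenerate (0 or 1)")
    return fold_enrichment_binomial(k, n, p0)


def rescale_to_nominal_range(profile: SignalProfile, genes: Iterable[GeneModel],
                             limit: float = 1.5) -> SignalProfile:
    """Linear rescale mapping the gene-level 1st/99th percentiles to +/-limit.

    Optional: input profiles are normally assumed to be pre-normalized; when
    this transform is applied the pipeline records it in output metadata.
    """
    vals = [v.rt for v in gene_rt_values(profile, genes).values()]
    lo, hi = np.percentile(vals, [1, 99])
    if hi == lo:
        raise ValueError("degenerate RT distribution")
    scale = 2 * limit / (hi - lo)
    mid = (hi + lo) / 2
    data = {c: (p.copy(), (v - mid) * scale) for c, (p, v) in profile.data.items()}
    return SignalProfile(data, kind=profile.kind)
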