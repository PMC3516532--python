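"""Breakpoint-relative domain retention and fusion functional analysis.

A translocation joins the upstream part of the 5' partner gene to the
downstream part of the 3' partner.  A domain is retained by the fusion
protein only when it lies *entirely* on the contributed side of the
breakpoint; breakpoint-spanning domains are lost on both sides, which keeps
the accounting identity retained + lost = all annotations.

Retained domains are mapped to five functional categories - DNA-binding (D),
protein interaction (P), histone modification (H), kinase (K) and other (O) -
with N standing for a side that retains nothing categorizable.  Partners
retaining at least one D/P/H/K domain are "type 1"; partners with only O/N
are "type 2".  Protein interaction interfaces (PIIs) enter retention counts
and the interactor network but not the categorization.

The co-occurrence of 5' and 3' categories is tested against a permutation
null that shuffles the 3' category sets across translocations while keeping
the 5' sets fixed, preserving both marginal category-set multisets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .models import (
    CATEGORIES,
    CATEGORIES_WITH_N,
    TYPE1_CATEGORIES,
    CategoryMap,
    DomainAnnotation,
    EnrichmentResult,
    Translocation,
)
from .stats import benjamini_hochberg, fisher_exact_2x2

_CAT_INDEX = {c: i for i, c in enumerate(CATEGORIES_WITH_N)}


# ---------------------------------------------------------------------------
# Retention
# ---------------------------------------------------------------------------

@dataclass
class RetentionRecord:
    fusion_id: str
    side: str  # five_prime | three_prime
    retained: list[DomainAnnotation]
    lost: list[DomainAnnotation]
    breakpoint_aa: int
    upstream_of_cds: bool = False


def breakpoint_nt_to_aa(bp_nt: int, cds_start_nt: int) -> tuple[int, bool]:
    """Convert a 1-based transcript breakpoint to a 1-based amino-acid position.

    Breakpoints upstream of the CDS clamp to aa 0 and are flagged; the
    three-prime retention rule then keeps every domain of that gene.
    """
    if bp_nt < 1:
        raise ValueError("breakpoint must be >= 1")
    aa = (bp_nt - cds_start_nt) // 3 + 1
    if aa < 1:
        return 0, True
    return aa, False


def retained_and_lost(annotations: Iterable[DomainAnnotation], breakpoint_aa: int,
                      side: str, fusion_id: str = "", upstream_flag: bool = False,
                      ) -> RetentionRecord:
    """Split annotations into retained and lost for one fusion side.

    The 5' partner contributes everything strictly upstream of the
    breakpoint (aa_end < breakpoint); the 3' partner everything strictly
    downstream (aa_start > breakpoint).  Everything else, including
    breakpoint-spanning features, is lost.
    """
    if side not in ("five_prime", "three_prime"):
        raise ValueError(f"unknown side {side!r}")
    retained, lost = [], []
    for a in annotations:
        if side == "five_prime":
            keep = a.aa_end < breakpoint_aa
        else:
            keep = a.aa_start > breakpoint_aa
        (retained if keep else lost).append(a)
    return RetentionRecord(fusion_id=fusion_id, side=side, retained=retained,
                           lost=lost, breakpoint_aa=breakpoint_aa,
                           upstream_of_cds=upstream_flag)


def partner_category_set(retention: RetentionRecord, cmap: CategoryMap,
                         ) -> tuple[frozenset[str], int]:
    """Functional categories of a partner's retained domains, plus its type.

    PIIs are skipped.  An empty category set encodes as {N}.  Type 1 means
    at least one retained D/P/H/K domain; otherwise type 2.
    """
    cats: set[str] = set()
    for a in retention.retained:
        if a.is_pii:
            continue
        if a.feature_id not in cmap:
            raise KeyError(f"feature {a.feature_id} missing from category map")
        cats.add(cmap[a.feature_id])
    if not cats:
        return frozenset({"N"}), 2
    ptype = 1 if cats & TYPE1_CATEGORIES else 2
    return frozenset(cats), ptype


@dataclass
class FusionProfile:
    """Per-translocation category sets, partner types, and the 10-bit profile."""

    fusion_id: str
    set5: frozenset[str]
    set3: frozenset[str]
    type5: int
    type3: int

    @property
    def bits(self) -> np.ndarray:
        """10 binary indicators: 5' side D/P/H/K/O then 3' side D/P/H/K/O."""
        v = np.zeros(10, dtype=np.int8)
        for c in self.set5 - {"N"}:
            v[CATEGORIES.index(c)] = 1
        for c in self.set3 - {"N"}:
            v[5 + CATEGORIES.index(c)] = 1
        return v


def fusion_profiles(
    translocations: Sequence[Translocation],
    annotations_by_gene: Mapping[str, Sequence[DomainAnnotation]],
    cds_start_by_gene: Mapping[str, int],
    cmap: CategoryMap,
) -> tuple[list[FusionProfile], dict[str, dict[str, RetentionRecord]]]:
    """Compute retention records and functional profiles for every fusion."""
    profiles: list[FusionProfile] = []
    retentions: dict[str, dict[str, RetentionRecord]] = {}
    for t in translocations:
        aa5, flag5 = breakpoint_nt_to_aa(t.five_bp_nt, cds_start_by_gene[t.five_gene])
        aa3, flag3 = breakpoint_nt_to_aa(t.three_bp_nt, cds_start_by_gene[t.three_gene])
        r5 = retained_and_lost(annotations_by_gene.get(t.five_gene, ()), aa5,
                               "five_prime", t.fusion_id, flag5)
        r3 = retained_and_lost(annotations_by_gene.get(t.three_gene, ()), aa3,
                               "three_prime", t.fusion_id, flag3)
        s5, ty5 = partner_category_set(r5, cmap)
        s3, ty3 = partner_category_set(r3, cmap)
        profiles.append(FusionProfile(t.fusion_id, s5, s3, ty5, ty3))
        retentions[t.fusion_id] = {"five_prime": r5, "three_prime": r3}
    return profiles, retentions


# ---------------------------------------------------------------------------
# Co-occurrence counting and permutation test
# ---------------------------------------------------------------------------

def _indicator(category_sets: Sequence[frozenset[str]]) -> np.ndarray:
    """n x 6 binary indicator matrix over D/P/H/K/O/N."""
    out = np.zeros((len(category_sets), 6), dtype=np.float64)
    for i, s in enumerate(category_sets):
        for c in s:
            out[i, _CAT_INDEX[c]] = 1.0
    return out


def cooccurrence_counts(set5s: Sequence[frozenset[str]],
                        set3s: Sequence[frozenset[str]]) -> np.ndarray:
    """6x6 counts of (5' category, 3' category) co-occurrence.

    Each translocation contributes one count to every (c5, c3) cell with
    c5 in its 5' set and c3 in its 3' set.
    """
    if len(set5s) != len(set3s):
        raise ValueError("5' and 3' set lists must match")
    return _indicator(set5s).T @ _indicator(set3s)


@dataclass
class CooccurrenceResult:
    categories: tuple[str, ...]
    observed: np.ndarray           # 6x6 counts
    null_mean: np.ndarray
    fold: np.ndarray               # nan where undefined
    p_value: np.ndarray
    q_value: np.ndarray            # nan for cells excluded from FDR
    reject: np.ndarray
    tested: np.ndarray             # bool: included in FDR
    n_perm: int

    def cell(self, c5: str, c3: str) -> EnrichmentResult:
        i, j = _CAT_INDEX[c5], _CAT_INDEX[c3]
        fold = self.fold[i, j]
        return EnrichmentResult(
            observed=float(self.observed[i, j]),
            null_mean=float(self.null_mean[i, j]),
            fold=float(fold) if np.isfinite(fold) else float("nan"),
            p_value=float(self.p_value[i, j]),
            direction="over" if self.observed[i, j] >= self.null_mean[i, j] else "under",
            q_value=float(self.q_value[i, j]) if np.isfinite(self.q_value[i, j]) else None,
        )


def _permuted_counts(A: np.ndarray, B: np.ndarray, n_perm: int,
                     rng: np.random.Generator, batch: int = 20000) -> np.ndarray:
    """Stack of 6x6 count matrices under random pairings (3' sets shuffled)."""
    n = A.shape[0]
    out = np.empty((n_perm, 6, 6))
    done = 0
    while done < n_perm:
        m = min(batch, n_perm - done)
        perms = np.argsort(rng.random((m, n)), axis=1)
        out[done:done + m] = np.einsum("ci,pik->pck", A.T, B[perms])
        done += m
    return out


def cooccurrence_permutation_test(
    set5s: Sequence[frozenset[str]],
    set3s: Sequence[frozenset[str]],
    n_perm: int = 1_000_000,
    q: float = 0.10,
    seed: int | np.random.Generator = 0,
) -> CooccurrenceResult:
    """Permutation test for category co-occurrence enrichment.

    The null shuffles the 3' category sets across translocations (5' sets
    fixed), preserving both marginal multisets.  Per cell: fold = observed
    count / mean permuted count, two-sided empirical p (add-one convention),
    and BH q-values across all cells with any observed or permuted support;
    structurally empty cells are excluded from the FDR.
    """
    if len(set5s) < 1:
        raise ValueError("need at least one translocation")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    A, B = _indicator(set5s), _indicator(set3s)
    observed = A.T @ B
    null = _permuted_counts(A, B, n_perm, rng)
    null_mean = null.mean(axis=0)

    n_ge = (null >= observed[None, :, :]).sum(axis=0)
    n_le = (null <= observed[None, :, :]).sum(axis=0)
    p_ge = (1.0 + n_ge) / (n_perm + 1)
    p_le = (1.0 + n_le) / (n_perm + 1)
    p = np.minimum(1.0, 2.0 * np.minimum(p_ge, p_le))

    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(null_mean > 0, observed / null_mean, np.nan)
    tested = (observed > 0) | (null_mean > 0)
    qvals = np.full((6, 6), np.nan)
    reject = np.zeros((6, 6), dtype=bool)
    if tested.any():
        rej, qv = benjamini_hochberg(p[tested], q=q)
        qvals[tested] = qv
        reject[tested] = rej
    return CooccurrenceResult(
        categories=CATEGORIES_WITH_N, observed=observed, null_mean=null_mean,
        fold=fold, p_value=p, q_value=qvals, reject=reject, tested=tested,
        n_perm=n_perm,
    )


@dataclass
class TypeDependency:
    table: np.ndarray              # rows: 5' type 1/2; cols: 3' type 1/2
    fisher_p: float | None
    odds_ratio: float | None
    type2_type2_fraction: float
    type2_type2_fold: float | None
    type2_type2_p: float | None
    skipped: bool = False


def type_dependency_test(profiles: Sequence[FusionProfile],
                         n_perm: int = 100_000,
                         seed: int | np.random.Generator = 0) -> TypeDependency:
    """Dependence between 5' and 3' partner types, and the type2-type2 cell.

    Fisher's exact test on the 2x2 type table; the type2/type2 fraction is
    additionally compared with the mean under the 3'-shuffling permutation
    null (same null as the co-occurrence test).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t5 = np.array([p.type5 for p in profiles])
    t3 = np.array([p.type3 for p in profiles])
    n = len(profiles)
    table = np.array([
        [np.sum((t5 == 1) & (t3 == 1)), np.sum((t5 == 1) & (t3 == 2))],
        [np.sum((t5 == 2) & (t3 == 1)), np.sum((t5 == 2) & (t3 == 2))],
    ])
    frac22 = float(table[1, 1]) / n
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return TypeDependency(table=table, fisher_p=None, odds_ratio=None,
                              type2_type2_fraction=frac22, type2_type2_fold=None,
                              type2_type2_p=None, skipped=True)
    oratio, p_fisher = fisher_exact_2x2(table)

    # permutation null for the type2-type2 count: shuffle 3' types
    is2_5 = (t5 == 2).astype(float)
    is2_3 = (t3 == 2).astype(float)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    null_counts = is2_3[perms] @ is2_5
    mean_null = float(null_counts.mean())
    fold = table[1, 1] / mean_null if mean_null > 0 else None
    n_ge = int(np.count_nonzero(null_counts >= table[1, 1]))
    n_le = int(np.count_nonzero(null_counts <= table[1, 1]))
    p_perm = min(1.0, 2.0 * min((1 + n_ge) / (n_perm + 1), (1 + n_le) / (n_perm + 1)))
    return TypeDependency(table=table, fisher_p=p_fisher, odds_ratio=oratio,
                          type2_type2_fraction=frac22, type2_type2_fold=fold,
                          type2_type2_p=p_perm)


# ---------------------------------------------------------------------------
# Bernoulli-mixture clustering of functional profiles
# ---------------------------------------------------------------------------

_PROB_CLAMP = (1e-4, 1.0 - 1e-4)


@dataclass
class BernoulliMixture:
    weights: np.ndarray   # (k,)
    probs: np.ndarray     # (k, d) per-cluster indicator probabilities
    log_likelihood: float

    def log_prob(self, X: np.ndarray) -> np.ndarray:
        """Per-sample per-component joint log density, shape (n, k)."""
        lp = np.log(self.probs)
        lq = np.log1p(-self.probs)
        return np.log(self.weights)[None, :] + X @ lp.T + (1 - X) @ lq.T

    def responsibilities(self, X: np.ndarray) -> np.ndarray:
        lj = self.log_prob(X)
        lj -= lj.max(axis=1, keepdims=True)
        r = np.exp(lj)
        return r / r.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.log_prob(X), axis=1)

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        lj = self.log_prob(X)
        mx = lj.max(axis=1)
        return mx + np.log(np.exp(lj - mx[:, None]).sum(axis=1))


def _em_fit_once(X: np.ndarray, k: int, rng: np.random.Generator,
                 max_iter: int = 300, tol: float = 1e-7) -> BernoulliMixture:
    n, d = X.shape
    lo, hi = _PROB_CLAMP
    probs = np.clip(rng.random((k, d)) * 0.5 + 0.25 + 0.5 * (rng.random((k, d)) - 0.5),
                    lo, hi)
    weights = np.full(k, 1.0 / k)
    model = BernoulliMixture(weights, probs, -np.inf)
    prev = -np.inf
    for _ in range(max_iter):
        r = model.responsibilities(X)
        nk = r.sum(axis=0) + 1e-12
        weights = nk / n
        probs = np.clip((r.T @ X) / nk[:, None], lo, hi)
        model = BernoulliMixture(weights, probs, -np.inf)
        ll = float(model.score_samples(X).sum())
        model.log_likelihood = ll
        if ll - prev < tol * abs(ll + 1):
            break
        prev = ll
    return model


def fit_bernoulli_mixture(X: np.ndarray, k: int, rng: np.random.Generator,
                          n_restarts: int = 10) -> BernoulliMixture:
    """Mixture of independent per-bit Bernoulli components fitted by EM.

    Best of ``n_restarts`` random initializations by training likelihood;
    component probabilities are clamped away from 0/1 so held-out profiles
    never have -inf likelihood.
    """
    X = np.asarray(X, dtype=float)
    best: BernoulliMixture | None = None
    for _ in range(max(1, n_restarts)):
        m = _em_fit_once(X, k, rng)
        if best is None or m.log_likelihood > best.log_likelihood:
            best = m
    assert best is not None
    return best


@dataclass
class ClusteringResult:
    k: int
    assignments: np.ndarray
    cluster_probs: np.ndarray       # (k, d)
    weights: np.ndarray
    cv_log_likelihoods: dict[int, float]
    model: BernoulliMixture


def cluster_functional_profiles(profiles: np.ndarray | Sequence[FusionProfile],
                                seed: int | np.random.Generator = 0,
                                max_k: int = 10, n_folds: int = 10,
                                n_restarts: int = 10) -> ClusteringResult:
    """Cluster 10-bit fusion profiles with an EM Bernoulli mixture.

    The number of clusters is chosen by increasing k from 1 while the mean
    held-out log-likelihood over ``n_folds`` cross-validation folds keeps
    improving; the first k that fails to improve stops the search and the
    previous k is selected.  The final model is refitted on all profiles.
    """
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    if len(profiles) and isinstance(profiles[0], FusionProfile):  # type: ignore[index]
        X = np.stack([p.bits for p in profiles]).astype(float)  # type: ignore[union-attr]
    else:
        X = np.asarray(profiles, dtype=float)
    n = X.shape[0]
    if n < n_folds:
        raise ValueError("need at least n_folds profiles")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    fold_ids = np.tile(np.arange(n_folds), n // n_folds + 1)[:n]
    rng.shuffle(fold_ids)

    cv_ll: dict[int, float] = {}
    best_k = 1
    prev_score = -np.inf
    for k in range(1, max_k + 1):
        total = 0.0
        for f in range(n_folds):
            train, test = X[fold_ids != f], X[fold_ids == f]
            m = fit_bernoulli_mixture(train, k, rng, n_restarts=n_restarts)
            total += float(m.score_samples(test).sum())
        score = total / n
        cv_ll[k] = score
        # ties (e.g. all profiles identical) must not grow k: require a
        # genuine improvement beyond floating jitter
        if score <= prev_score + 1e-6 * max(1.0, abs(prev_score)):
            break
        best_k, prev_score = k, score

    model = fit_bernoulli_mixture(X, best_k, rng, n_restarts=n_restarts)
    return ClusteringResult(k=best_k, assignments=model.predict(X),
                            cluster_probs=model.probs, weights=model.weights,
                            cv_log_likelihoods=cv_ll, model=model)


# ---------------------------------------------------------------------------
# Interactor network
# ---------------------------------------------------------------------------

def build_interactor_network(
    retentions: Mapping[str, Mapping[str, RetentionRecord]],
    side: str = "three_prime",
) -> tuple[list[tuple[str, str, str]], list[str]]:
    """Edges from TPGs to interaction partners via retained PIIs.

    Returns (edges, partner multiset).  Each edge is (tpg gene side label,
    partner, fusion_id).  A partner interacting with multiple TPGs appears
    once per TPG in the multiset, preserving multiplicity.
    """
    edges: list[tuple[str, str, str]] = []
    multiset: list[str] = []
    for fusion_id in sorted(retentions):
        rec = retentions[fusion_id][side]
        seen_partners: set[str] = set()
        for a in rec.retained:
            if not a.is_pii:
                continue
            for partner in sorted(a.partners):
                edges.append((a.gene_id, partner, fusion_id))
                seen_partners.add(partner)
        multiset.extend(sorted(seen_partners))
    return edges, multiset


def fusion_network_edges(translocations: Sequence[Translocation],
                         assignments: Mapping[str, int]) -> list[tuple[str, str, int, int]]:
    """Fusion-gene network: (5' gene, 3' gene, cluster, variant count)."""
    counts: dict[tuple[str, str, int], int] = {}
    for t in translocations:
        cl = int(assignments.get(t.fusion_id, -1))
        key = (t.five_gene, t.three_gene, cl)
        counts[key] = counts.get(key, 0) + 1
    return [(f, g, c, n) for (f, g, c), n in sorted(counts.items())]
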