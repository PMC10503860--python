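"""Variant/sample QC: missingness, MAF, exact HWE, kinship, LD pruning, PCs.

Filter defaults follow standard GWAS practice: drop variants with call
missingness > 2%, minor allele frequency < 1%, Hardy-Weinberg exact
p < 1e-6, or imputation info < 0.1 (when info scores are supplied).
Relatedness uses the robust heterozygote-concordance kinship estimator with
the second-degree cutoff 0.0884; stratification is adjusted with principal
components of the LD-pruned standardized dosage matrix (classical MDS of
genotype similarity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import GenotypeSet


# ------------------------------------------------------------------ HWE test


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test (two-sided, Wigginton-style).

    Enumerates the conditional distribution of the heterozygote count given
    the allele counts and sums the probabilities of all configurations no
    more probable than the observed one.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    n_a = 2 * n_hom_ref + n_het  # REF allele count
    n_b = 2 * n_hom_alt + n_het
    rare = min(n_a, n_b)

    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = (max(n_a, n_b) - hets) // 2
    # P(n_het | allele counts) via log multinomial coefficients
    logp = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
        + hets * np.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[hets == n_het]
    if obs.size == 0:  # inconsistent het count for the allele totals
        raise ValueError("heterozygote count inconsistent with allele counts")
    p = probs[probs <= obs[0] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


# ------------------------------------------------------------ variant filter


@dataclass
class FilterReport:
    n_input: int
    removed_info: int
    removed_missing: int
    removed_maf: int
    removed_hwe: int
    n_kept: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def filter_variants(
    g: GenotypeSet,
    max_missing: float = 0.02,
    min_maf: float = 0.01,
    hwe_p_min: float = 1e-6,
    min_info: float = 0.1,
    info: np.ndarray | None = None,
) -> tuple[GenotypeSet, FilterReport]:
    """Remove variants failing any QC rule, in order info -> missingness ->
    MAF -> HWE; each removal is attributed to the first failing rule."""
    for name, thr in (
        ("max_missing", max_missing),
        ("min_maf", min_maf),
        ("hwe_p_min", hwe_p_min),
        ("min_info", min_info),
    ):
        if not (0.0 <= thr <= 1.0):
            raise ValueError(f"{name} must be within [0, 1]")

    alive = np.ones(g.n_variants, dtype=bool)
    counts = {}

    if info is not None:
        fail = np.asarray(info, dtype=float) < min_info
        counts["info"] = int(fail.sum())
        alive &= ~fail
    else:
        counts["info"] = 0

    fail = (g.missing_rate() > max_missing) & alive
    counts["missing"] = int(fail.sum())
    alive &= ~fail

    fail = (g.maf() < min_maf) & alive
    counts["maf"] = int(fail.sum())
    alive &= ~fail

    gt_counts = g.genotype_counts()
    hwe_fail = np.zeros(g.n_variants, dtype=bool)
    for j in np.flatnonzero(alive):
        p = hwe_exact_test(*gt_counts[j])
        hwe_fail[j] = p < hwe_p_min
    counts["hwe"] = int(hwe_fail.sum())
    alive &= ~hwe_fail

    report = FilterReport(
        n_input=g.n_variants,
        removed_info=counts["info"],
        removed_missing=counts["missing"],
        removed_maf=counts["maf"],
        removed_hwe=counts["hwe"],
        n_kept=int(alive.sum()),
    )
    return g.subset_variants(np.flatnonzero(alive)), report


# ---------------------------------------------------------------- relatedness


def kinship_matrix(g: GenotypeSet) -> pd.DataFrame:
    """Robust pairwise kinship from heterozygote concordance.

    phi_ij = (N_het,het - 2 N_opposite-hom) / (N_het(i) + N_het(j)), counted
    over variants non-missing in both samples. Duplicates/MZ twins give 0.5,
    parent-offspring about 0.25, unrelated samples about 0. Diagonal is 0.5.
    """
    d = g.dosages
    if np.isnan(d).all(axis=1).any():
        raise ValueError("a sample has all-missing genotypes")
    obs = ~np.isnan(d)
    het = (d == 1.0) & obs
    hom0 = (d == 0.0) & obs
    hom2 = (d == 2.0) & obs

    het_f = het.astype(float)
    n_hh = het_f @ het_f.T
    n_opp = hom0.astype(float) @ hom2.astype(float).T
    n_opp = n_opp + n_opp.T
    obs_f = obs.astype(float)
    het_i = het_f @ obs_f.T  # het count of sample i over sites shared with j

    denom = het_i + het_i.T
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (n_hh - 2.0 * n_opp) / denom
    phi[denom == 0] = 0.0
    np.fill_diagonal(phi, 0.5)
    return pd.DataFrame(phi, index=g.sample_ids, columns=g.sample_ids)


def remove_related(
    kinship: pd.DataFrame,
    threshold: float = 0.0884,
    missingness: pd.Series | None = None,
) -> list[str]:
    """Greedy relatedness pruning; returns the retained sample ids.

    While any retained pair exceeds the kinship threshold, drop the member
    with the most over-threshold partners (ties: higher missingness, then
    lexicographically larger id). The retained set has no pair above the
    threshold.
    """
    ids = list(kinship.index)
    k = kinship.to_numpy(copy=True)
    np.fill_diagonal(k, 0.0)
    miss = (
        missingness.reindex(ids).to_numpy()
        if missingness is not None
        else np.zeros(len(ids))
    )
    alive = np.ones(len(ids), dtype=bool)
    over = k > threshold
    while True:
        deg = (over & alive[None, :] & alive[:, None]).sum(axis=1)
        deg[~alive] = 0
        if deg.max() == 0:
            break
        worst = _pick_worst(np.flatnonzero(deg == deg.max()), miss, ids)
        alive[worst] = False
    return [s for s, a in zip(ids, alive) if a]


def _pick_worst(candidates: np.ndarray, miss: np.ndarray, ids: list[str]) -> int:
    """Tie-break: highest missingness, then lexicographically last id."""
    best = candidates[0]
    for c in candidates[1:]:
        if (miss[c], ids[c]) > (miss[best], ids[best]):
            best = c
    return int(best)


# ----------------------------------------------------------------- LD pruning


def _r2_matrix(d: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlation of dosage columns (mean-imputed)."""
    x = d.copy()
    mu = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(mu, inds[1])
    x = x - x.mean(axis=0)
    denom = np.sqrt((x**2).sum(axis=0))
    denom[denom == 0] = np.nan
    r = (x.T @ x) / np.outer(denom, denom)
    return r**2


def ld_prune(
    g: GenotypeSet, window: int = 50, step: int = 5, r2_max: float = 0.2
) -> list[int]:
    """Sliding-window greedy LD pruning (plink --indep-pairwise semantics).

    Within each window of ``window`` variants, pairs with r^2 > ``r2_max``
    are broken by removing the later variant of the pair, repeating until no
    such pair remains; the window then advances by ``step`` variants.
    Removal is permanent. Returns the retained variant indices.
    """
    if window < step:
        raise ValueError("window must be >= step")
    alive = np.ones(g.n_variants, dtype=bool)
    for start in range(0, max(g.n_variants - 1, 1), step):
        idx = np.flatnonzero(alive[start : start + window]) + start
        if len(idx) < 2:
            continue
        r2 = _r2_matrix(g.dosages[:, idx])
        changed = True
        while changed:
            changed = False
            live = np.flatnonzero(alive[idx])
            for a in range(len(live)):
                for b in range(a + 1, len(live)):
                    ia, ib = live[a], live[b]
                    if r2[ia, ib] > r2_max:
                        alive[idx[ib]] = False
                        changed = True
                        break
                if changed:
                    break
    return list(np.flatnonzero(alive))


# --------------------------------------------------------------------- PCs


def compute_pcs(g: GenotypeSet, n_components: int = 10) -> pd.DataFrame:
    """Principal components of standardized dosages (classical MDS).

    Missing calls are mean-imputed per variant; columns are standardized,
    the sample x sample similarity is eigendecomposed via SVD, and the
    orthonormal left singular vectors are returned ordered by decreasing
    eigenvalue, each column's sign fixed so its largest-magnitude entry is
    positive.
    """
    if g.n_variants < 2:
        raise ValueError("need at least 2 variants")
    if g.n_samples < n_components + 1:
        raise ValueError("need more samples than components")
    x = g.dosages.copy()
    mu = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(mu, inds[1])
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 0
    x = x[:, keep] / sd[keep]

    u, s, _ = np.linalg.svd(x, full_matrices=False)
    u = u[:, :n_components]
    for j in range(u.shape[1]):
        if u[np.abs(u[:, j]).argmax(), j] < 0:
            u[:, j] = -u[:, j]
    return pd.DataFrame(
        u, index=g.sample_ids, columns=[f"PC{i+1}" for i in range(u.shape[1])]
    )
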