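"""Per-variant linear association, LD clumping into loci, and thresholds.

Model 1 regresses the transformed median measured slope on genotype plus the
transformed median predicted normal-aging slope, 10 PCs, sex, and
transformed median age; Model 2 omits the predicted-slope covariate. The
effect allele is ALT; p-values come from the finite-sample t distribution.

Loci are built the standard lead-SNP way: candidates at p < 1e-5, clumping
of nearby candidates at r^2 >= 0.6 into independent significant SNPs,
re-pruning of those at r^2 >= 0.1 into lead SNPs, and merging of loci
separated by less than 250 kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeSet

ASSOC_COLUMNS = ["rsid", "chrom", "pos", "ref", "alt", "beta", "se", "t", "p", "n", "flag"]


def assoc_linear(
    phenotype: np.ndarray,
    g: GenotypeSet,
    covariates: np.ndarray,
    predicted_slope: np.ndarray | None = None,
    model: int = 1,
) -> pd.DataFrame:
    """Per-variant OLS of phenotype on dosage + covariates.

    Model 1 includes ``predicted_slope`` as an extra covariate; Model 2
    omits it. Complete cases per variant; rank-deficient designs are
    flagged (beta/se/p set to NaN), never silently dropped. The phenotype
    and continuous covariates are expected already inverse-normal
    transformed by the caller.
    """
    if model not in (1, 2):
        raise ValueError("model must be 1 or 2")
    y = np.asarray(phenotype, dtype=float)
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != y.size:
        cov = cov.T
    base = [np.ones_like(y), *cov.T]
    if model == 1:
        if predicted_slope is None:
            raise ValueError("model 1 requires the predicted-slope covariate")
        base.append(np.asarray(predicted_slope, dtype=float))
    base = np.column_stack(base)
    if base.shape[0] != y.size:
        raise ValueError("covariate rows do not match phenotype length")

    rows = []
    for j in range(g.n_variants):
        dose = g.dosages[:, j]
        ok = ~np.isnan(dose) & np.isfinite(y) & np.isfinite(base).all(axis=1)
        x = np.column_stack([base[ok], dose[ok]])
        yy = y[ok]
        n, k = x.shape
        rec = g.variants.iloc[j]
        if n <= k or np.linalg.matrix_rank(x) < k:
            rows.append((rec.rsid, rec.chrom, rec.pos, rec.ref, rec.alt,
                         np.nan, np.nan, np.nan, np.nan, n, "rank_deficient"))
            continue
        xtx_inv = np.linalg.inv(x.T @ x)
        beta = xtx_inv @ (x.T @ yy)
        resid = yy - x @ beta
        df = n - k
        sigma2 = resid @ resid / df
        se = np.sqrt(sigma2 * np.diag(xtx_inv))
        b, s = beta[-1], se[-1]
        t = b / s
        p = 2.0 * stats.t.sf(abs(t), df)
        rows.append((rec.rsid, rec.chrom, rec.pos, rec.ref, rec.alt,
                     b, s, t, max(p, np.finfo(float).tiny), n, "ok"))
    return pd.DataFrame(rows, columns=ASSOC_COLUMNS)


def pairwise_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over complete pairs."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = ~np.isnan(g1) & ~np.isnan(g2)
    if ok.sum() < 2:
        raise ValueError("need at least 2 overlapping non-missing samples")
    a, b = g1[ok], g2[ok]
    if a.std() == 0 or b.std() == 0:
        return float("nan")  # undefined for monomorphic vectors
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class Locus:
    """A clumped association locus."""

    lead_rsid: str
    chrom: str
    start: int
    end: int
    lead_p: float
    lead_pos: int
    member_rsids: list[str] = field(default_factory=list)
    merged_from: list[str] = field(default_factory=list)


def define_loci(
    results: pd.DataFrame,
    g: GenotypeSet,
    p_lead: float = 1e-5,
    r2_clump: float = 0.6,
    r2_indep: float = 0.1,
    merge_kb: float = 250.0,
    ld_window_kb: float = 1000.0,
) -> list[Locus]:
    """Lead-SNP clumping and locus merging.

    1. Candidates: variants with p < ``p_lead``, ordered by (p, chrom, pos).
    2. Clumping: repeatedly take the best remaining candidate and absorb
       candidates within ``ld_window_kb`` at r^2 >= ``r2_clump`` — the
       independent significant SNPs.
    3. Lead SNPs: re-prune the independent significant SNPs at
       r^2 >= ``r2_indep`` (same window), merging member sets.
    4. Loci: merge lead-SNP loci on one chromosome whose boundary gap is
       less than ``merge_kb``; the merged lead is the smallest p.
    """
    res = results.dropna(subset=["p"])
    cand = res[res["p"] < p_lead].sort_values(["p", "chrom", "pos"]).reset_index(drop=True)
    if cand.empty:
        return []

    rsid_col = {r.rsid: j for j, r in g.variants.iterrows()}

    def dose(rsid: str) -> np.ndarray:
        return g.dosages[:, rsid_col[rsid]]

    window_bp = ld_window_kb * 1000.0

    def clump(frame: pd.DataFrame, r2_thr: float) -> list[dict]:
        remaining = frame.copy()
        signals = []
        while not remaining.empty:
            top = remaining.iloc[0]
            near = remaining[
                (remaining["chrom"] == top["chrom"])
                & ((remaining["pos"] - top["pos"]).abs() <= window_bp)
            ]
            absorbed = [top["rsid"]]
            for _, other in near.iloc[1:].iterrows():
                if pairwise_r2(dose(top["rsid"]), dose(other["rsid"])) >= r2_thr:
                    absorbed.append(other["rsid"])
            signals.append({"lead": top, "members": absorbed})
            remaining = remaining[~remaining["rsid"].isin(absorbed)].reset_index(drop=True)
        return signals

    # step 2: independent significant SNPs
    indep = clump(cand, r2_clump)
    member_map = {s["lead"]["rsid"]: list(s["members"]) for s in indep}

    # step 3: lead SNPs among the independent significant SNPs
    indep_frame = (
        pd.DataFrame([s["lead"] for s in indep])
        .sort_values(["p", "chrom", "pos"])
        .reset_index(drop=True)
    )
    lead_signals = clump(indep_frame, r2_indep)

    pos_of = dict(zip(cand["rsid"], cand["pos"]))
    loci = []
    for sig in lead_signals:
        members: list[str] = []
        for rsid in sig["members"]:
            members.extend(member_map[rsid])
        positions = [pos_of[m] for m in members]
        top = sig["lead"]
        loci.append(
            Locus(
                lead_rsid=top["rsid"],
                chrom=str(top["chrom"]),
                start=int(min(positions)),
                end=int(max(positions)),
                lead_p=float(top["p"]),
                lead_pos=int(top["pos"]),
                member_rsids=sorted(members, key=lambda m: pos_of[m]),
            )
        )

    # step 4: merge loci separated by less than merge_kb
    merge_bp = merge_kb * 1000.0
    loci.sort(key=lambda l: (l.chrom, l.start))
    merged: list[Locus] = []
    for locus in loci:
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and locus.chrom == prev.chrom
            and locus.start - prev.end < merge_bp
        ):
            keep, drop = (prev, locus) if prev.lead_p <= locus.lead_p else (locus, prev)
            keep.start = min(prev.start, locus.start)
            keep.end = max(prev.end, locus.end)
            keep.member_rsids = sorted(
                set(prev.member_rsids) | set(locus.member_rsids), key=lambda m: pos_of[m]
            )
            keep.merged_from = sorted(
                set(prev.merged_from) | set(locus.merged_from) | {drop.lead_rsid}
            )
            merged[-1] = keep
        else:
            merged.append(locus)
    merged.sort(key=lambda l: l.lead_p)
    return merged


def loci_to_frame(loci: list[Locus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lead_rsid": l.lead_rsid,
                "chrom": l.chrom,
                "lead_pos": l.lead_pos,
                "start": l.start,
                "end": l.end,
                "lead_p": l.lead_p,
                "n_members": len(l.member_rsids),
                "members": ",".join(l.member_rsids),
                "merged_from": ",".join(l.merged_from),
            }
            for l in loci
        ]
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
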