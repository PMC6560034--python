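"""Association testing between molecular features and segment shape PCs.

Every (feature, segment) pair is tested with a canonical correlation
analysis (CCA): the first canonical correlation ``r`` between the
single-variate feature and the segment's retained PC scores, with
significance from Rao's F approximation (right-tail).  With one variate on
the feature side Wilks' lambda is ``1 - r^2`` and

    F = (r^2 / (1 - r^2)) * (df2 / df1),  df1 = q,  df2 = N - c - q - 1,

where ``q`` is the number of PCs and ``c`` the number of covariates.
Covariates are handled by residualizing both the feature and the scores on
them (with an intercept) before the CCA — partial CCA.

Multiple testing over all feature x segment tests of one scan is
controlled with the Benjamini-Yekutieli step-up rule, which is valid under
arbitrary dependence; its data-dependent p-value cutoff is referred to as
the FDRd threshold.  A genome-wide scan tests every SNP (additive dosage
coding, 0/1/2) against every segment after covariate adjustment, and the
significant SNPs are grouped into loci by greedy clumping with a base-pair
window and an LD r-squared floor against the locus seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "cca_association",
    "by_fdr_threshold",
    "bh_fdr_threshold",
    "feature_scan",
    "gwas_scan",
    "ld_r_squared",
    "clump_loci",
]


@dataclass
class AssociationResult:
    """One (feature, segment) CCA test."""

    canonical_correlation: float
    rao_f: float
    df1: float
    df2: float
    p_value: float
    saturated: bool = False  # r ~ 1, p underflowed


def _residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residuals of ``y`` (1- or 2-D) on [1, covariates] by least squares."""
    y = np.asarray(y, float)
    n = y.shape[0]
    if covariates is None:
        X = np.ones((n, 1))
    else:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([np.ones(n), C])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def cca_association(
    feature_values: np.ndarray,
    segment_scores: np.ndarray,
    covariates: np.ndarray | None = None,
) -> AssociationResult:
    """CCA of one molecular feature against a segment's PC scores.

    With a single variate on the feature side the first canonical
    correlation is the multiple correlation of the feature with the score
    columns; Rao's F and its right-tail p-value follow from Wilks' lambda.
    """
    f = np.asarray(feature_values, float).ravel()
    S = np.asarray(segment_scores, float)
    if S.ndim == 1:
        S = S[:, None]
    N, q = S.shape
    if len(f) != N:
        raise ValueError("feature and scores must share individuals")
    if not np.all(np.isfinite(f)):
        raise ValueError("missing feature values; recode upstream")
    c = 0
    if covariates is not None:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        c = C.shape[1]
    if N <= q + c + 2:
        raise ValueError(f"N={N} too small for q={q} PCs and c={c} covariates")
    fr = _residualize(f, covariates)
    Sr = _residualize(S, covariates)
    fr = fr - fr.mean()
    Sr = Sr - Sr.mean(axis=0)
    denom = float(fr @ fr)
    if denom < 1e-30:
        raise ValueError("feature has zero variance after residualization")
    Q, R = np.linalg.qr(Sr)
    rank = int(np.sum(np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(R).max())))
    if rank < q:
        raise ValueError("segment scores are rank deficient")
    proj = Q.T @ fr
    r2 = float(proj @ proj) / denom
    r2 = min(r2, 1.0)
    df1 = float(q)
    df2 = float(N - c - q - 1)
    saturated = False
    if r2 >= 1.0 - 1e-12:
        r2 = 1.0 - 1e-12
        saturated = True
    F = (r2 / (1.0 - r2)) * (df2 / df1)
    p = float(stats.f.sf(F, df1, df2))
    if p <= 0.0:
        p = float(np.nextafter(0.0, 1.0))
        saturated = True
    return AssociationResult(
        canonical_correlation=float(np.sqrt(r2)),
        rao_f=float(F),
        df1=df1,
        df2=df2,
        p_value=p,
        saturated=saturated,
    )


def by_fdr_threshold(p_values, alpha: float = 0.05) -> float:
    """Benjamini-Yekutieli step-up p-value cutoff (0.0 if nothing passes).

    With m tests and c(m) = sum_{k<=m} 1/k, the cutoff is the largest
    sorted p_(i) with p_(i) <= i * alpha / (m * c(m)); valid under any test
    dependency structure.
    """
    p = np.asarray(list(p_values), float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    ps = np.sort(p)
    crit = np.arange(1, m + 1) * alpha / (m * c_m)
    passing = np.flatnonzero(ps <= crit)
    if passing.size == 0:
        return 0.0
    return float(ps[passing[-1]])


def bh_fdr_threshold(p_values, alpha: float = 0.05) -> float:
    """Benjamini-Hochberg step-up cutoff (for comparison; no c(m) factor)."""
    p = np.asarray(list(p_values), float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    m = p.size
    ps = np.sort(p)
    crit = np.arange(1, m + 1) * alpha / m
    passing = np.flatnonzero(ps <= crit)
    if passing.size == 0:
        return 0.0
    return float(ps[passing[-1]])


def feature_scan(
    features: dict[str, np.ndarray],
    segment_scores: dict[int, np.ndarray],
    covariates: np.ndarray | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Test a batch of molecular features against every facial segment.

    Same test as :func:`cca_association` for each (feature, segment) pair,
    vectorized over features; feature values must be complete.  Returns
    the long table (feature, segment, r, F, df1, df2, p) and the pooled
    Benjamini-Yekutieli threshold over all tests.
    """
    names = list(features)
    M = np.column_stack([np.asarray(features[n], float) for n in names])
    if not np.all(np.isfinite(M)):
        raise ValueError("feature values must be complete")
    N = M.shape[0]
    c = 0
    if covariates is not None:
        C = np.asarray(covariates, float)
        c = 1 if C.ndim == 1 else C.shape[1]
    Mr = _residualize(M, covariates)
    Mr = Mr - Mr.mean(axis=0)
    ss = np.sum(Mr**2, axis=0)
    if np.any(ss < 1e-30):
        bad = [names[j] for j in np.flatnonzero(ss < 1e-30)]
        raise ValueError(f"zero-variance features after residualization: {bad}")
    rows: list[tuple] = []
    for sid in sorted(segment_scores):
        Sr = _residualize(segment_scores[sid], covariates)
        Sr = Sr - Sr.mean(axis=0)
        Q, _ = np.linalg.qr(Sr)
        q = Q.shape[1]
        df1, df2 = float(q), float(N - c - q - 1)
        proj = Q.T @ Mr
        r2 = np.minimum(np.sum(proj**2, axis=0) / ss, 1.0 - 1e-12)
        F = (r2 / (1.0 - r2)) * (df2 / df1)
        p = np.maximum(stats.f.sf(F, df1, df2), np.nextafter(0.0, 1.0))
        for j, name in enumerate(names):
            rows.append(
                (name, sid, float(np.sqrt(r2[j])), float(F[j]), df1, df2, float(p[j]))
            )
    table = pd.DataFrame(
        rows, columns=["feature", "segment", "r", "F", "df1", "df2", "p"]
    )
    fdrd = by_fdr_threshold(table["p"], alpha=alpha)
    return table, fdrd


# --------------------------------------------------------------------------
# genome-wide scan


def minor_allele_frequency(dosages: np.ndarray) -> np.ndarray:
    """Per-SNP MAF of additive dosages, ignoring missing entries."""
    G = np.asarray(dosages, float)
    with np.errstate(invalid="ignore"):
        af = np.nanmean(G, axis=0) / 2.0
    return np.minimum(af, 1.0 - af)


def gwas_scan(
    genotypes: np.ndarray,
    snp_ids,
    segment_scores: dict[int, np.ndarray],
    covariates: np.ndarray | None = None,
    maf_min: float = 0.05,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Additive-model scan of every SNP against every facial segment.

    Dosages are tested per segment with covariate-adjusted CCA.  SNPs with
    MAF below ``maf_min`` or with constant dosage are skipped (logged).
    Missing dosages make a SNP fall back to a per-individual-complete
    test, mirroring tests that simply ignore missing genotypes.

    Returns the long association table (snp, segment, r, F, df1, df2, p)
    and the pooled Benjamini-Yekutieli FDRd threshold over all tests run.
    """
    G = np.asarray(genotypes, float)
    snp_ids = list(snp_ids)
    N, S = G.shape
    maf = minor_allele_frequency(G)
    keep = np.flatnonzero(np.nan_to_num(maf) >= maf_min)
    dropped = S - keep.size
    if dropped:
        logger.info("gwas_scan: dropped %d SNPs below MAF %.3g", dropped, maf_min)

    # residualize scores once, orthonormalize per segment
    seg_ids = sorted(segment_scores)
    seg_Q: dict[int, np.ndarray] = {}
    for sid in seg_ids:
        Sr = _residualize(segment_scores[sid], covariates)
        Sr = Sr - Sr.mean(axis=0)
        Q, _ = np.linalg.qr(Sr)
        seg_Q[sid] = Q
    c = 0
    if covariates is not None:
        C = np.asarray(covariates, float)
        c = 1 if C.ndim == 1 else C.shape[1]

    complete = keep[~np.isnan(G[:, keep]).any(axis=0)]
    with_missing = keep[np.isnan(G[:, keep]).any(axis=0)]

    rows: list[tuple] = []
    if complete.size:
        Gr = _residualize(G[:, complete], covariates)
        Gr = Gr - Gr.mean(axis=0)
        ss = np.sum(Gr**2, axis=0)
        const = ss < 1e-30
        if const.any():
            logger.info("gwas_scan: %d constant dosage columns skipped", const.sum())
        ok = ~const
        for sid in seg_ids:
            Q = seg_Q[sid]
            q = Q.shape[1]
            df1 = float(q)
            df2 = float(N - c - q - 1)
            proj = Q.T @ Gr[:, ok]
            r2 = np.minimum(np.sum(proj**2, axis=0) / ss[ok], 1.0 - 1e-12)
            F = (r2 / (1.0 - r2)) * (df2 / df1)
            p = stats.f.sf(F, df1, df2)
            p = np.maximum(p, np.nextafter(0.0, 1.0))
            for j, snp_j in enumerate(complete[ok]):
                rows.append(
                    (snp_ids[snp_j], sid, float(np.sqrt(r2[j])), float(F[j]),
                     df1, df2, float(p[j]))
                )
    for snp_j in with_missing:
        g = G[:, snp_j]
        m = np.isfinite(g)
        if np.unique(g[m]).size < 2:
            logger.info("gwas_scan: SNP %s constant; skipped", snp_ids[snp_j])
            continue
        cov_m = None if covariates is None else np.asarray(covariates, float)[m]
        for sid in seg_ids:
            res = cca_association(g[m], np.asarray(segment_scores[sid])[m], cov_m)
            rows.append(
                (snp_ids[snp_j], sid, res.canonical_correlation, res.rao_f,
                 res.df1, res.df2, res.p_value)
            )
    table = pd.DataFrame(
        rows, columns=["snp", "segment", "r", "F", "df1", "df2", "p"]
    )
    fdrd = by_fdr_threshold(table["p"], alpha=alpha) if len(table) else 0.0
    return table, fdrd


# --------------------------------------------------------------------------
# LD and locus clumping


def ld_r_squared(a: np.ndarray, b: np.ndarray) -> float:
    """Composite LD: squared Pearson correlation of additive dosages.

    Pairs with a missing dosage in either SNP are dropped.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    m = np.isfinite(a) & np.isfinite(b)
    a, b = a[m], b[m]
    if a.size < 3 or a.std() < 1e-12 or b.std() < 1e-12:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def clump_loci(
    significant: pd.DataFrame,
    genotypes: np.ndarray,
    snp_ids,
    window_bp: int = 500_000,
    ld_r2_min: float = 0.5,
) -> pd.DataFrame:
    """Greedy clumping of significant SNPs into loci.

    ``significant`` needs columns id, chrom, pos, p (best p over segments).
    Repeatedly: the most significant unassigned SNP seeds a locus; any
    unassigned significant SNP on the same chromosome within ``window_bp``
    of any current member AND with LD r^2 above ``ld_r2_min`` against the
    seed joins (the window grows transitively with the membership).  The
    seed is the locus's peak SNP by construction.
    """
    sig = significant.reset_index(drop=True).copy()
    if len(sig) == 0:
        return pd.DataFrame(
            columns=["locus", "peak_snp", "chrom", "pos", "p", "maf", "n_snps",
                     "member_snps"]
        )
    snp_index = {s: j for j, s in enumerate(snp_ids)}
    G = np.asarray(genotypes, float)
    maf_all = minor_allele_frequency(G)
    unassigned = set(range(len(sig)))
    loci = []
    order = np.argsort(sig["p"].to_numpy(), kind="stable")
    for seed_row in order:
        if seed_row not in unassigned:
            continue
        seed = sig.iloc[seed_row]
        g_seed = G[:, snp_index[seed["id"]]]
        members = {seed_row}
        unassigned.discard(seed_row)
        grown = True
        while grown:
            grown = False
            member_pos = sig.iloc[sorted(members)]
            for cand in sorted(unassigned):
                row = sig.iloc[cand]
                if row["chrom"] != seed["chrom"]:
                    continue
                near = np.any(np.abs(member_pos["pos"].to_numpy() - row["pos"]) <= window_bp)
                if not near:
                    continue
                if ld_r_squared(g_seed, G[:, snp_index[row["id"]]]) > ld_r2_min:
                    members.add(cand)
                    unassigned.discard(cand)
                    grown = True
        loci.append(
            {
                "locus": len(loci) + 1,
                "peak_snp": seed["id"],
                "chrom": seed["chrom"],
                "pos": int(seed["pos"]),
                "p": float(seed["p"]),
                "maf": float(maf_all[snp_index[seed["id"]]]),
                "n_snps": len(members),
                "member_snps": [sig.iloc[m]["id"] for m in sorted(members)],
            }
        )
    return pd.DataFrame(loci)
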