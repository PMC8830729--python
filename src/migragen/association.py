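"""Kinship-corrected single-SNP association with the migration phenotypes.

Each SNP is tested one at a time in the univariate linear mixed model

    y = W a + x b + u + e,   u ~ N(0, s2 * lambda * K),  e ~ N(0, s2 * I)

where K is the centred relatedness matrix, W the covariate design
(intercept only by default) and lambda the ratio of genetic to residual
variance.  K is eigendecomposed once; the likelihood is profiled over
lambda on a 61-point log grid refined by parabolic interpolation, per
SNP under the alternative (a faster null-lambda approximation is
available).  Significance is a Wald test of b against chi-square(1),
with Bonferroni adjustment across SNPs.  The binary migrant/resident
phenotype is analysed by the same linear model on 0/1.

Per-SNP variance explained follows the GWAS-standard formula

    PVE = 2 b^2 f(1-f) / (2 b^2 f(1-f) + se(b)^2 * 2 n f(1-f))

with f the minor allele frequency, and relative PVE renormalizes the
significant SNPs to sum to 100%.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MixedLMM",
    "MixedLMMResults",
    "bonferroni_adjust",
    "genomic_inflation",
    "compute_pve",
    "relative_pve",
    "annotate_snps",
]

_LOG10_GRID = np.linspace(-5.0, 5.0, 61)


def _reml_ll(n, p, rss_w, log_v_sum, log_det_xwx):
    """Restricted log-likelihood profiled over the scale parameter.

    REML (rather than plain ML) for the variance ratio: the centred
    relatedness matrix has a zero eigenvalue aligned with the intercept,
    under which the ML profile of lambda drifts to the upper boundary;
    the restricted likelihood integrates the fixed effects out and is
    flat there instead.
    """
    df = n - p
    return -0.5 * (df * (np.log(2 * np.pi) + 1.0) + df * np.log(rss_w / df)
                   + log_v_sum + log_det_xwx)


class MixedLMM:
    """Univariate linear mixed model with one random polygenic effect.

    Parameters
    ----------
    y : array (n,)
        Phenotype, complete (mask individuals upstream).
    k : array (n, n)
        Relatedness matrix, symmetric PSD.
    w : array (n, p), optional
        Fixed covariates; default intercept only.
    """

    def __init__(self, y, k, w=None):
        self.y = np.asarray(y, dtype=float)
        n = self.y.shape[0]
        if np.isnan(self.y).any():
            raise ValueError("phenotype contains missing values; mask upstream")
        if np.ptp(self.y) == 0:
            raise ValueError("degenerate phenotype: constant y")
        k = np.asarray(k, dtype=float)
        if k.shape != (n, n):
            raise ValueError("K must be n x n")
        if not np.allclose(k, k.T, atol=1e-8):
            raise ValueError("K must be symmetric")
        self.w = np.ones((n, 1)) if w is None else np.asarray(w, dtype=float)
        try:
            s, u = np.linalg.eigh(k)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(
                f"eigendecomposition of K failed (cond issues): {exc}"
            ) from exc
        self.s = np.maximum(s, 0.0)  # clip tiny negative eigenvalues
        self.u = u
        self.yt = u.T @ self.y
        self.wt = u.T @ self.w
        self.n = n

    # -- likelihood machinery -------------------------------------------------

    def _gls(self, xt, lam):
        """Weighted LS of rotated y on [rotated W, xt]; returns (beta, se2_raw,
        rss, log|V|)."""
        v = lam * self.s + 1.0
        wgt = 1.0 / v
        design = self.wt if xt is None else np.column_stack([self.wt, xt])
        a = design.T * wgt
        xtx = a @ design
        xty = a @ self.yt
        coef = np.linalg.solve(xtx, xty)
        resid = self.yt - design @ coef
        rss = float((wgt * resid**2).sum())
        return coef, xtx, rss, float(np.log(v).sum())

    def _profile_ll(self, lam, xt=None):
        _, xtx, rss, logv = self._gls(xt, lam)
        sign, logdet = np.linalg.slogdet(np.atleast_2d(xtx))
        return _reml_ll(self.n, np.atleast_2d(xtx).shape[0], rss, logv, logdet)

    def _optimize_lambda(self, xt=None):
        lls = np.array([self._profile_ll(10.0**g, xt) for g in _LOG10_GRID])
        i = int(np.argmax(lls))
        from scipy.optimize import minimize_scalar

        lo = _LOG10_GRID[max(i - 1, 0)]
        hi = _LOG10_GRID[min(i + 1, len(_LOG10_GRID) - 1)]
        res = minimize_scalar(lambda g: -self._profile_ll(10.0**g, xt),
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-4})
        return float(10.0**res.x), float(-res.fun)

    def fit(self):
        """Profile the null model over lambda; returns MixedLMMResults."""
        lam, ll = self._optimize_lambda(xt=None)
        return MixedLMMResults(self, lam, ll)


class MixedLMMResults:
    """Null-model fit carrying the eigen cache; tests SNPs via Wald."""

    def __init__(self, model, lambda_null, loglik_null):
        self.model = model
        self.lambda_null = lambda_null
        self.loglik = loglik_null

    def test_snps(self, genotypes, per_snp_lambda=True, snp_ids=None):
        """Wald test of each SNP column; returns a results DataFrame.

        Missing genotypes are mean-imputed per locus; monomorphic SNPs
        are skipped with a reason.  With ``per_snp_lambda`` the variance
        ratio is re-optimized under each alternative (grid + parabolic
        refinement); otherwise the null-model lambda is reused.
        """
        m = self.model
        g = np.asarray(genotypes, dtype=float)
        if g.ndim == 1:
            g = g[:, None]
        nan = np.isnan(g)
        if nan.any():
            means = np.nanmean(g, axis=0)
            g = np.where(nan, means[None, :], g)
        mono = np.ptp(g, axis=0) == 0
        if mono.any():
            logger.warning("%d monomorphic SNPs skipped", int(mono.sum()))
        xt_all = m.u.T @ g
        n = m.n
        p_cov = m.wt.shape[1]
        dof = n - p_cov - 1

        if per_snp_lambda:
            with np.errstate(invalid="ignore", divide="ignore"):
                lam = self._grid_lambda_vectorized(xt_all)
        else:
            lam = np.full(g.shape[1], self.lambda_null)

        # final GLS at the chosen per-SNP lambda, vectorized
        v = lam[None, :] * m.s[:, None] + 1.0          # (n, m)
        wgt = 1.0 / v
        wt1 = m.wt[:, 0]                                # intercept-only fast path
        if p_cov == 1:
            errstate = np.errstate(invalid="ignore", divide="ignore")
            errstate.__enter__()
            sww = (wgt * wt1[:, None] ** 2).sum(axis=0)
            swx = (wgt * wt1[:, None] * xt_all).sum(axis=0)
            swy = (wgt * (wt1 * m.yt)[:, None]).sum(axis=0)
            sxx = (wgt * xt_all**2).sum(axis=0)
            sxy = (wgt * xt_all * m.yt[:, None]).sum(axis=0)
            syy = (wgt * (m.yt**2)[:, None]).sum(axis=0)
            det = sww * sxx - swx**2
            beta = (sww * sxy - swx * swy) / det
            alpha = (sxx * swy - swx * sxy) / det
            rss = syy - alpha * swy - beta * sxy
            sigma2 = rss / dof
            se = np.sqrt(sigma2 * sww / det)
            errstate.__exit__(None, None, None)
        else:
            beta = np.empty(g.shape[1])
            se = np.empty(g.shape[1])
            for j in range(g.shape[1]):
                coef, xtx, rss_j, _ = m._gls(xt_all[:, j], lam[j])
                beta[j] = coef[-1]
                cov = np.linalg.inv(xtx) * (rss_j / dof)
                se[j] = np.sqrt(cov[-1, -1])
        wald = (beta / se) ** 2
        p = stats.chi2.sf(wald, df=1)

        f = g.mean(axis=0) / 2.0
        maf = np.minimum(f, 1.0 - f)
        out = pd.DataFrame(
            {
                "snp": snp_ids if snp_ids is not None else np.arange(g.shape[1]),
                "beta": beta,
                "se": se,
                "wald": wald,
                "p_wald": p,
                "lambda": lam,
                "maf": maf,
                "skipped": mono,
            }
        )
        out.loc[mono, ["beta", "se", "wald", "p_wald"]] = np.nan
        return out

    def _grid_lambda_vectorized(self, xt_all):
        """Per-SNP ML lambda: coarse 61-point grid + parabolic refinement."""
        m = self.model
        n = m.n
        wt1 = m.wt[:, 0]
        grid = 10.0**_LOG10_GRID
        lls = np.empty((len(grid), xt_all.shape[1]))
        for gi, lam in enumerate(grid):
            v = lam * m.s + 1.0
            wgt = 1.0 / v
            sww = float((wgt * wt1**2).sum())
            swy = float((wgt * wt1 * m.yt).sum())
            syy = float((wgt * m.yt**2).sum())
            swx = (wgt * wt1) @ xt_all
            sxy = (wgt * m.yt) @ xt_all
            sxx = wgt @ (xt_all**2)
            det = sww * sxx - swx**2
            det = np.where(np.abs(det) < 1e-300, np.nan, det)
            beta = (sww * sxy - swx * swy) / det
            alpha = (sxx * swy - swx * sxy) / det
            rss = np.maximum(syy - alpha * swy - beta * sxy, 1e-300)
            lls[gi] = _reml_ll(n, 2, rss, float(np.log(v).sum()),
                               np.log(np.maximum(det, 1e-300)))
        lls = np.nan_to_num(lls, nan=-np.inf)
        best = lls.argmax(axis=0)
        # parabolic refinement in log10-lambda where an interior max exists
        lo = np.clip(best - 1, 0, len(grid) - 1)
        hi = np.clip(best + 1, 0, len(grid) - 1)
        idx = np.arange(xt_all.shape[1])
        y0, y1, y2 = lls[lo, idx], lls[best, idx], lls[hi, idx]
        denom = y0 - 2 * y1 + y2
        interior = (best > 0) & (best < len(grid) - 1) & (denom < -1e-12)
        shift = np.zeros_like(y1)
        step = _LOG10_GRID[1] - _LOG10_GRID[0]
        shift[interior] = 0.5 * (y0 - y2)[interior] / denom[interior] * step
        log_lam = _LOG10_GRID[best] - shift
        return 10.0**np.clip(log_lam, _LOG10_GRID[0], _LOG10_GRID[-1])

    def summary(self):
        return (
            "Linear mixed model (single polygenic random effect)\n"
            f"n = {self.model.n}, covariates p = {self.model.wt.shape[1]}\n"
            f"null variance ratio lambda = {self.lambda_null:.4g}\n"
            f"null log-likelihood = {self.loglik:.3f}"
        )


def bonferroni_adjust(p_values, m=None, alpha=0.05):
    """Bonferroni adjustment p_adj = min(1, p*m) and significance flags."""
    p = np.asarray(p_values, dtype=float)
    m = int(m) if m is not None else p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    p_adj = np.minimum(1.0, p * m)
    return p_adj, p_adj < alpha


def genomic_inflation(wald_stats):
    """Genomic inflation factor: median observed chi-square / null median."""
    w = np.asarray(wald_stats, dtype=float)
    w = w[np.isfinite(w)]
    if w.size < 100:
        raise ValueError("need >= 100 test statistics for a stable lambda_GC")
    return float(np.median(w) / stats.chi2.ppf(0.5, df=1))


def compute_pve(beta, se, maf, n):
    """Per-SNP proportion of phenotypic variance explained.

    PVE = 2 b^2 f(1-f) / (2 b^2 f(1-f) + se^2 * 2 n f(1-f)); undefined
    (NaN) at maf = 0.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    maf = np.asarray(maf, dtype=float)
    if np.any(maf > 0.5):
        raise ValueError("maf must be <= 0.5")
    if n < 2:
        raise ValueError("n must be >= 2")
    het = 2.0 * maf * (1.0 - maf)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = beta**2 * het
        pve = num / (num + se**2 * 2.0 * n * maf * (1.0 - maf))
    return np.where(maf > 0, pve, np.nan)


def relative_pve(pve_values):
    """Normalize the significant SNPs' PVEs to percentages summing to 100."""
    v = np.asarray(pve_values, dtype=float)
    total = np.nansum(v)
    if total <= 0:
        raise ValueError("total PVE must be positive to normalize")
    return 100.0 * v / total


PROMOTER_BP = 2000


def annotate_snps(loci, gene_table, promoter_bp=PROMOTER_BP):
    """Classify SNPs as exon / intron / promoter / intergenic.

    ``loci`` needs columns chrom, pos (1-based, VCF convention);
    ``gene_table`` is BED-like with 0-based half-open intervals and
    columns chrom, start, end, strand, gene_name, feature where feature
    is 'gene' (body) or 'exon'.  A SNP within an exon is 'exon'; inside
    a gene body otherwise 'intron'; within ``promoter_bp`` upstream of a
    gene start (strand-aware) 'promoter'; else 'intergenic'.  Priority
    exon > intron > promoter.
    """
    genes = gene_table.copy()
    if not genes[["chrom", "start"]].equals(
        genes.sort_values(["chrom", "start"])[["chrom", "start"]].reset_index(drop=True)
    ):
        logger.warning("gene table unsorted; sorting internally")
        genes = genes.sort_values(["chrom", "start"]).reset_index(drop=True)
    out = []
    for _, snp in loci.iterrows():
        pos0 = int(snp["pos"]) - 1  # to 0-based
        sub = genes[genes["chrom"] == snp["chrom"]]
        label = "intergenic"
        exons = sub[sub["feature"] == "exon"]
        bodies = sub[sub["feature"] != "exon"]
        if ((exons["start"] <= pos0) & (pos0 < exons["end"])).any():
            label = "exon"
        elif ((bodies["start"] <= pos0) & (pos0 < bodies["end"])).any():
            label = "intron"
        else:
            plus = bodies[bodies["strand"] == "+"]
            minus = bodies[bodies["strand"] == "-"]
            in_plus = ((plus["start"] - promoter_bp <= pos0)
                       & (pos0 < plus["start"])).any()
            in_minus = ((minus["end"] <= pos0)
                        & (pos0 < minus["end"] + promoter_bp)).any()
            if in_plus or in_minus:
                label = "promoter"
        out.append(label)
    return pd.Series(out, index=loci.index, name="annotation")
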