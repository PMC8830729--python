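"""Genotype QC and population structure.

Covers the genotype-level half of the pipeline: reading biallelic SNPs
into an individuals x loci dosage matrix, the QC filter chain (call
rate, minor allele frequency, Hardy-Weinberg exact test, per-individual
missingness, LD pruning), the centred relatedness matrix used by the
mixed-model association, PCA on standardized dosages, maximum-likelihood
admixture with EM and 5-fold cross-validation over the number of
ancestral clusters K, the Weir-Cockerham F_ST estimator with a bootstrap
CI over loci, and per-cluster minor-allele-frequency comparisons.

The admixture likelihood is the standard binomial mixture: genotype
g_ij ~ Binomial(2, pi_ij) with pi_ij = sum_k Q_ik F_kj, maximized by EM
over admixture proportions Q (rows sum to 1) and ancestral frequencies
F.  Cross-validation masks a random fifth of the observed genotype
entries per fold and scores masked entries by binomial deviance against
the predicted dosage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "FilterReport",
    "read_vcf",
    "apply_locus_filters",
    "apply_individual_filters",
    "hwe_exact_test",
    "ld_prune",
    "compute_grm",
    "pca",
    "AdmixtureModel",
    "AdmixtureResults",
    "fit_admixture",
    "cross_validate_k",
    "assign_clusters",
    "align_q_columns",
    "fst_between",
    "FstResult",
    "maf_by_cluster",
]

_FREQ_EPS = 1e-6


@dataclass
class GenotypeMatrix:
    """Individuals x loci alt-allele dosages in {0,1,2}; NaN = missing."""

    g: np.ndarray                 # (n, m) float
    samples: list
    loci: pd.DataFrame            # columns: chrom, pos, id, ref, alt

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        if self.g.ndim != 2:
            raise ValueError("genotype matrix must be 2-D")
        if len(self.samples) != self.g.shape[0]:
            raise ValueError("sample count mismatch")
        if len(self.loci) != self.g.shape[1]:
            raise ValueError("locus count mismatch")
        if (self.loci["pos"] < 0).any():
            raise ValueError("locus positions must be non-negative")

    @property
    def n_individuals(self) -> int:
        return self.g.shape[0]

    @property
    def n_loci(self) -> int:
        return self.g.shape[1]

    def alt_freq(self):
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.g, axis=0) / 2.0

    def maf(self):
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    def locus_call_rate(self):
        return 1.0 - np.isnan(self.g).mean(axis=0)

    def individual_missingness(self):
        return np.isnan(self.g).mean(axis=1)

    def take_loci(self, index):
        return GenotypeMatrix(self.g[:, index], list(self.samples),
                              self.loci.iloc[index].reset_index(drop=True))

    def take_individuals(self, index):
        return GenotypeMatrix(self.g[index], [self.samples[i] for i in index],
                              self.loci.copy())


def read_vcf(path):
    """Parse a biallelic-SNP VCF (GT field) into a GenotypeMatrix.

    Multiallelic records are skipped with a warning; ``./.`` becomes
    missing.  Sample order is preserved.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, meta = [], []
    n_skipped = 0
    for rec_no, variant in enumerate(vcf, start=1):
        if len(variant.ALT) != 1:
            n_skipped += 1
            logger.warning("record %d (%s:%d) multiallelic, skipped",
                           rec_no, variant.CHROM, variant.POS)
            continue
        gt = variant.gt_types.astype(float)  # gts012: 0,1,2 dosage; 3 unknown
        gt[gt == 3] = np.nan
        rows.append(gt)
        meta.append((variant.CHROM, variant.POS, variant.ID or f"rec{rec_no}",
                     variant.REF, variant.ALT[0]))
    if not rows:
        raise ValueError(f"no usable biallelic records in {path}")
    loci = pd.DataFrame(meta, columns=["chrom", "pos", "id", "ref", "alt"])
    gm = GenotypeMatrix(np.vstack(rows).T, samples, loci)
    gm.n_multiallelic_skipped = n_skipped
    return gm


@dataclass
class FilterReport:
    """Per-rule removal counts along a filter chain."""

    steps: list = field(default_factory=list)  # (rule, threshold, before, removed, after)

    def add(self, rule, threshold, before, removed):
        self.steps.append(
            {"rule": rule, "threshold": threshold, "n_before": before,
             "n_removed": removed, "n_after": before - removed}
        )

    def to_frame(self):
        return pd.DataFrame(self.steps)


def hwe_exact_test(n_hom_ref, n_het, n_hom_alt):
    """Two-sided Hardy-Weinberg exact test on genotype counts.

    Conditional on the allele counts, sums the probabilities of all
    heterozygote configurations no more probable than the observed one
    (Wigginton-style exact test).  Returns NaN for all-zero counts.
    """
    n_hom_ref, n_het, n_hom_alt = int(n_hom_ref), int(n_het), int(n_hom_alt)
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return float("nan")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    # possible heterozygote counts share the parity of the rare allele count
    het_min = n_rare % 2
    het_max = min(n_rare, 2 * n - n_rare)
    hets = np.arange(het_min, het_max + 1, 2)
    # unnormalized log-probabilities of each configuration
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    from scipy.special import gammaln

    logp = (hets * np.log(2.0)
            - gammaln(hets + 1) - gammaln(rare_hom + 1) - gammaln(common_hom + 1))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = int(np.flatnonzero(hets == n_het)[0]) if n_het in hets else None
    if obs is None:
        raise ValueError("observed heterozygote count inconsistent with alleles")
    return float(min(1.0, p[p <= p[obs] * (1.0 + 1e-12)].sum()))


def _hwe_pvalues(gm, loci_idx):
    out = np.ones(len(loci_idx))
    for i, j in enumerate(loci_idx):
        col = gm.g[:, j]
        col = col[~np.isnan(col)]
        n0 = int((col == 0).sum())
        n1 = int((col == 1).sum())
        n2 = int((col == 2).sum())
        if n0 + n1 + n2 == 0:
            out[i] = np.nan
        else:
            out[i] = hwe_exact_test(n0, n1, n2)
    return out


def apply_locus_filters(gm, call_rate=0.90, maf=0.05, hwe_p=0.001,
                        report=None):
    """Locus QC chain: call rate >= threshold, MAF strictly >, HWE p >=.

    Filters run in the order call-rate, MAF, HWE; any threshold given as
    None is skipped.  Returns ``(filtered, FilterReport)``.
    """
    report = report or FilterReport()
    keep = np.arange(gm.n_loci)
    if call_rate is not None:
        cr = gm.locus_call_rate()[keep]
        passed = cr >= call_rate
        report.add("locus_call_rate", call_rate, len(keep),
                   int((~passed).sum()))
        keep = keep[passed]
    if maf is not None:
        m = gm.maf()[keep]
        passed = m > maf
        report.add("maf", maf, len(keep), int((~passed).sum()))
        keep = keep[passed]
    if hwe_p is not None:
        pvals = _hwe_pvalues(gm, keep)
        passed = ~(pvals < hwe_p)  # NaN (undefined) loci are not removed here
        report.add("hwe", hwe_p, len(keep), int((~passed).sum()))
        keep = keep[passed]
    out = gm.take_loci(keep)
    if out.n_loci == 0:
        logger.warning("locus filters removed every locus")
    return out, report


def apply_individual_filters(gm, max_missingness=0.85, report=None):
    """Drop individuals with missingness strictly above the threshold."""
    report = report or FilterReport()
    miss = gm.individual_missingness()
    keep = np.flatnonzero(~(miss > max_missingness))
    report.add("individual_missingness", max_missingness, gm.n_individuals,
               gm.n_individuals - len(keep))
    return gm.take_individuals(keep), report


def _imputed_centered(g):
    f = np.nanmean(g, axis=0) / 2.0
    x = g - 2.0 * f
    return np.nan_to_num(x, nan=0.0), f


def ld_prune(gm, window=50, step=5, r2=0.5):
    """PLINK-style sliding-window LD pruning; returns kept locus indices.

    Within each window of ``window`` loci (advancing by ``step``, per
    chromosome), one locus of any pair with squared genotype correlation
    above ``r2`` is removed greedily: the lower-MAF locus goes; on a MAF
    tie, the later position goes.  Deterministic.
    """
    x, _ = _imputed_centered(gm.g)
    mafs = gm.maf()
    active = np.ones(gm.n_loci, dtype=bool)
    for chrom, idx in gm.loci.groupby("chrom", sort=False).indices.items():
        idx = np.asarray(idx)
        for start in range(0, len(idx), step):
            win = idx[start:start + window]
            live = win[active[win]]
            if len(live) < 2:
                continue
            xs = x[:, live]
            sd = xs.std(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = (xs.T @ xs) / len(xs) / np.outer(sd, sd)
            r2m = np.nan_to_num(corr**2, nan=0.0)
            for a in range(len(live)):
                if not active[live[a]]:
                    continue
                for b in range(a + 1, len(live)):
                    if not active[live[b]]:
                        continue
                    if r2m[a, b] > r2:
                        ja, jb = live[a], live[b]
                        if mafs[ja] < mafs[jb]:
                            drop = ja
                        elif mafs[jb] < mafs[ja]:
                            drop = jb
                        else:  # tie: remove the later position
                            drop = jb if gm.loci["pos"].iloc[jb] >= gm.loci["pos"].iloc[ja] else ja
                        active[drop] = False
                        if drop == ja:
                            break
            if start + window >= len(idx):
                break
    return np.flatnonzero(active)


def compute_grm(gm):
    """Centred genetic relatedness matrix from mean-imputed dosages.

    K = X Xᵀ / sum_j 2 f_j (1 - f_j) with X the 2f-centred dosage
    matrix — the VanRaden scaling, which puts the diagonal mean near 1
    under Hardy-Weinberg.  Monomorphic loci are skipped with a warning.
    """
    x, f = _imputed_centered(gm.g)
    poly = (f > 0) & (f < 1)
    if not poly.all():
        logger.warning("%d monomorphic loci skipped in GRM", int((~poly).sum()))
    x = x[:, poly]
    f = f[poly]
    denom = float((2.0 * f * (1.0 - f)).sum())
    if denom <= 0:
        raise ValueError("no polymorphic loci for GRM")
    k = (x @ x.T) / denom
    return (k + k.T) / 2.0


def pca(gm, n_components=10):
    """PCA of standardized dosages ((g-2f)/sqrt(2f(1-f)), mean-imputed).

    Returns ``(eigenvectors, eigenvalues)`` with components ordered by
    decreasing eigenvalue; eigenvectors has shape (n, n_components).
    """
    x, f = _imputed_centered(gm.g)
    poly = (f > 0) & (f < 1)
    x = x[:, poly] / np.sqrt(2.0 * f[poly] * (1.0 - f[poly]))
    cov = x @ x.T / x.shape[1]
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    k = min(n_components, len(vals))
    return vecs[:, order[:k]], vals[order[:k]]


# ---------------------------------------------------------------------------
# Admixture (binomial-mixture ML with EM)

class AdmixtureModel:
    """Maximum-likelihood admixture with K ancestral clusters.

    The binomial mixture likelihood
    ``L = sum_ij [ g_ij ln(QF)_ij + (2-g_ij) ln(1-(QF))_ij ]`` (observed
    entries only) is maximized by plain EM; the log-likelihood is
    non-decreasing every iteration.  Missing entries are ignored, which
    also supports the masked-entry cross-validation over K.
    """

    def __init__(self, g, k):
        if k < 1:
            raise ValueError("K must be >= 1")
        self.g = np.asarray(g, dtype=float)
        self.k = int(k)
        self.mask = ~np.isnan(self.g)
        # float32 working copies: the EM is memory-bandwidth bound and the
        # likelihood surface is flat far beyond float32 resolution
        self._g0 = np.nan_to_num(self.g, nan=0.0).astype(np.float32)
        self._g2 = (2.0 - self._g0) * self.mask.astype(np.float32)
        self._complete = bool(self.mask.all())

    def loglik(self, q, f):
        p = np.clip(np.asarray(q, dtype=np.float32) @ np.asarray(f, dtype=np.float32),
                    _FREQ_EPS, 1.0 - _FREQ_EPS)
        return float((self._g0 * np.log(p)).sum(dtype=np.float64)
                     + (self._g2 * np.log1p(-p)).sum(dtype=np.float64))

    def _em_step(self, q, f, compute_ll=False):
        g0, g2 = self._g0, self._g2
        p = np.clip(q @ f, _FREQ_EPS, 1.0 - _FREQ_EPS)
        ll = None
        if compute_ll:
            ll = float((g0 * np.log(p)).sum(dtype=np.float64)
                       + (g2 * np.log1p(-p)).sum(dtype=np.float64))
        a = g0 / p                      # zero where missing since g0 = 0 there
        b = g2 / (1.0 - p)              # g2 carries the missingness mask
        ref = q * (a @ f.T)             # expected ref-allele counts per (i, k)
        alt = q * (b @ (1.0 - f).T)
        q_new = ref + alt
        q_new /= q_new.sum(axis=1, keepdims=True)
        num = f * (q.T @ a)
        den = num + (1.0 - f) * (q.T @ b)
        f_new = np.clip(num / np.maximum(den, 1e-30), _FREQ_EPS, 1.0 - _FREQ_EPS)
        return q_new, f_new, ll

    def fit(self, seed=0, n_restarts=5, tol=1e-6, max_iter=2000, check_every=10):
        """EM fit; convergence when the log-likelihood gain over
        ``check_every`` iterations falls below ``tol``."""
        n, m = self.g.shape
        if self.k == 1:
            with np.errstate(invalid="ignore"):
                f = np.clip(np.nan_to_num(np.nanmean(self.g, axis=0), nan=1.0)[None, :]
                            / 2.0, _FREQ_EPS, 1.0 - _FREQ_EPS)
            q = np.ones((n, 1))
            ll = self.loglik(q, f)
            return AdmixtureResults(self, q, f, ll, [ll], True, 0)
        rng = np.random.default_rng(seed)
        best = None
        for restart in range(n_restarts):
            q = rng.dirichlet(np.ones(self.k), size=n).astype(np.float32)
            base = np.clip(np.nan_to_num(np.nanmean(self.g, axis=0), nan=1.0) / 2.0,
                           0.05, 0.95)
            f = np.clip(base + rng.normal(0, 0.1, size=(self.k, m)),
                        _FREQ_EPS, 1.0 - _FREQ_EPS).astype(np.float32)
            ll_prev = -np.inf
            path = []
            converged = False
            n_iter = 0
            for it in range(1, max_iter + 1):
                check = (it % check_every == 0) or it == max_iter
                q, f, ll = self._em_step(q, f, compute_ll=check)
                n_iter = it
                if ll is not None:
                    path.append(ll)
                    if ll - ll_prev < tol and np.isfinite(ll_prev):
                        converged = True
                        break
                    ll_prev = ll
            ll_final = self.loglik(q, f)
            path.append(ll_final)
            if not converged:
                logger.warning("admixture EM (K=%d, restart %d) hit max_iter=%d",
                               self.k, restart, max_iter)
            if best is None or ll_final > best[0]:
                best = (ll_final, q, f, path, converged, n_iter)
        ll, q, f, path, converged, n_iter = best
        return AdmixtureResults(self, q.astype(np.float64), f.astype(np.float64),
                                ll, path, converged, n_iter)


class AdmixtureResults:
    """Fitted Q (n x K), ancestral F (K x m) and likelihood diagnostics."""

    def __init__(self, model, q, f, loglik, loglik_path, converged, n_iter):
        self.model = model
        self.k = model.k
        self.q = q
        self.f = f
        self.loglik = loglik
        self.loglik_path = np.asarray(loglik_path)
        self.converged = converged
        self.n_iter = n_iter
        self.cv_error = None

    def predicted_freq(self):
        return np.clip(self.q @ self.f, _FREQ_EPS, 1.0 - _FREQ_EPS)

    def labels(self):
        labels, _, _ = assign_clusters(self.q)
        return labels

    def summary(self):
        labels = self.labels()
        lines = [f"Admixture fit: K = {self.k}, n = {self.q.shape[0]}, "
                 f"m = {self.f.shape[1]}",
                 f"log-likelihood = {self.loglik:.3f} "
                 f"({'converged' if self.converged else 'NOT converged'}, "
                 f"{self.n_iter} EM iterations)"]
        if self.cv_error is not None:
            lines.append(f"cv error = {self.cv_error:.5f}")
        for k in range(self.k):
            sel = labels == k
            if sel.any():
                lines.append(
                    f"cluster {k + 1}: n = {int(sel.sum())}, "
                    f"mean Q = {self.q[sel, k].mean():.3f}"
                )
        return "\n".join(lines)


def fit_admixture(g, k, seed=0, n_restarts=5, tol=1e-6, max_iter=2000):
    """Fit the K-cluster admixture model; see AdmixtureModel."""
    g = g.g if isinstance(g, GenotypeMatrix) else g
    return AdmixtureModel(g, k).fit(seed=seed, n_restarts=n_restarts, tol=tol,
                                    max_iter=max_iter)


def cross_validate_k(g, k_range, folds=5, seed=0, **fit_kwargs):
    """Masked-entry cross-validation of the admixture model over K.

    Observed genotype entries are partitioned into ``folds`` random
    groups; each fold is masked in turn, the model refit, and masked
    entries scored by mean binomial deviance against the predicted
    dosage.  Returns ``(cv_errors: dict K->error, selected_k)``.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    g = g.g if isinstance(g, GenotypeMatrix) else g
    g = np.asarray(g, dtype=float)
    rng = np.random.default_rng(seed)
    obs = np.flatnonzero(~np.isnan(g).ravel())
    perm = rng.permutation(obs)
    assignments = np.array_split(perm, folds)
    cv = {}
    for k in k_range:
        dev_sum, n_masked = 0.0, 0
        for fold_idx in assignments:
            g_train = g.copy().ravel()
            held = g_train[fold_idx].copy()
            g_train[fold_idx] = np.nan
            res = AdmixtureModel(g_train.reshape(g.shape), k).fit(
                seed=int(rng.integers(2**31)), **fit_kwargs
            )
            p = res.predicted_freq().ravel()[fold_idx]
            dev_sum += float(
                -2.0 * (held * np.log(p) + (2.0 - held) * np.log1p(-p)).sum()
            )
            n_masked += len(fold_idx)
        cv[int(k)] = dev_sum / n_masked
    selected = min(cv, key=lambda k: (cv[k], k))
    return cv, selected


def assign_clusters(q):
    """Argmax-Q cluster labels; ties go to the lower index and are flagged.

    Returns ``(labels, max_q, tie_flags)``.
    """
    q = np.asarray(q, dtype=float)
    labels = q.argmax(axis=1)
    max_q = q[np.arange(len(q)), labels]
    ties = (np.isclose(q, max_q[:, None])).sum(axis=1) > 1
    if ties.any():
        logger.warning("%d individuals had tied Q; lower cluster index kept",
                       int(ties.sum()))
    return labels, max_q, ties


def align_q_columns(q_hat, q_true):
    """Permute estimated Q columns to best match the truth (label switch)."""
    from itertools import permutations

    k = q_true.shape[1]
    best = min(
        permutations(range(k)),
        key=lambda perm: np.abs(q_hat[:, perm] - q_true).mean(),
    )
    return q_hat[:, best]


# ---------------------------------------------------------------------------
# F_ST and per-cluster MAF comparisons

@dataclass
class FstResult:
    estimate: float
    ci_low: float
    ci_high: float
    method: str = "weir-cockerham; percentile bootstrap over loci"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            # bootstrap percentile intervals can exclude the point estimate
            # in pathological cases; widen rather than fail
            self.ci_low = min(self.ci_low, self.estimate)
            self.ci_high = max(self.ci_high, self.estimate)


def _wc_components(g, labels):
    """Per-locus Weir-Cockerham (1984) variance components a, b, c."""
    groups = np.unique(labels)
    r = len(groups)
    n_k, p_k, h_k = [], [], []
    for grp in groups:
        sub = g[labels == grp]
        if sub.shape[0] < 2:
            raise ValueError(f"group {grp!r} has < 2 individuals")
        obs = ~np.isnan(sub)
        n = obs.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            p = np.nansum(sub, axis=0) / np.maximum(2.0 * n, 1e-300)
            h = np.nansum(sub == 1, axis=0) / np.maximum(n, 1e-300)
        n_k.append(n)
        p_k.append(p)
        h_k.append(h)
    n_k = np.array(n_k)          # (r, m)
    p_k = np.array(p_k)
    h_k = np.array(h_k)
    n_bar = n_k.mean(axis=0)
    n_tot = n_k.sum(axis=0)
    n_c = (n_tot - (n_k**2).sum(axis=0) / n_tot) / (r - 1)
    p_bar = (n_k * p_k).sum(axis=0) / n_tot
    s2 = (n_k * (p_k - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n_k * h_k).sum(axis=0) / n_tot
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2.0
    poly = (p_bar > 0) & (p_bar < 1)
    return a[poly], b[poly], c[poly]


def fst_between(gm, labels, n_boot=10_000, seed=0, ci=0.95):
    """Weir-Cockerham F_ST between labelled groups (ratio of averages).

    The 95% CI is a percentile bootstrap over loci.  Monomorphic loci
    drop out of the estimator.
    """
    g = gm.g if isinstance(gm, GenotypeMatrix) else np.asarray(gm, dtype=float)
    labels = np.asarray(labels)
    a, b, c = _wc_components(g, labels)
    tot = a + b + c
    est = float(a.sum() / tot.sum())
    rng = np.random.default_rng(seed)
    m = len(a)
    boots = np.empty(n_boot)
    chunk = max(1, int(2e7 // max(m, 1)))
    done = 0
    while done < n_boot:
        size = min(chunk, n_boot - done)
        idx = rng.integers(0, m, size=(size, m))
        boots[done:done + size] = a[idx].sum(axis=1) / tot[idx].sum(axis=1)
        done += size
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return FstResult(est, float(lo), float(hi))


def maf_by_cluster(gm, labels, snp_subset, exact_threshold=20):
    """Per-cluster frequencies of the globally minor allele, with tests.

    Returns ``(freq_table, kruskal_p, pairwise)`` where freq_table has
    one row per SNP in ``snp_subset`` and one column per cluster,
    kruskal_p is the Kruskal-Wallis p across clusters, and pairwise a
    DataFrame of two-sided Wilcoxon rank-sum p-values (exact when both
    clusters contribute < ``exact_threshold`` SNP values... sample sizes
    here are the SNP-count vectors, which are equal; the exact method is
    used when that count is < 20).
    """
    snp_subset = np.asarray(snp_subset, dtype=int)
    if snp_subset.size == 0:
        raise ValueError("snp_subset must be non-empty")
    g = gm.g if isinstance(gm, GenotypeMatrix) else np.asarray(gm, dtype=float)
    labels = np.asarray(labels)
    global_f = np.nanmean(g[:, snp_subset], axis=0) / 2.0
    minor_is_alt = global_f <= 0.5
    clusters = np.unique(labels)
    table = {}
    for cl in clusters:
        sub = g[labels == cl][:, snp_subset]
        with np.errstate(invalid="ignore"):
            f_alt = np.nanmean(sub, axis=0) / 2.0
        table[cl] = np.where(minor_is_alt, f_alt, 1.0 - f_alt)
    freq = pd.DataFrame(table, index=[f"snp_{j}" for j in snp_subset])
    vectors = [freq[cl].to_numpy() for cl in clusters]
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    if all(np.allclose(v, vectors[0]) for v in vectors[1:]):
        kw_p = 1.0
    else:
        kw_p = float(stats.kruskal(*vectors).pvalue)
    pw = pd.DataFrame(np.ones((len(clusters), len(clusters))),
                      index=clusters, columns=clusters)
    for i, ci_ in enumerate(clusters):
        for j in range(i + 1, len(clusters)):
            cj = clusters[j]
            vi, vj = freq[ci_].to_numpy(), freq[cj].to_numpy()
            if np.allclose(vi, vj) and np.allclose(vi, vi[0]):
                p = 1.0  # all-ties: no evidence of shift, by convention
            else:
                method = "exact" if (len(vi) < exact_threshold
                                     and len(vj) < exact_threshold) else "asymptotic"
                p = float(stats.mannwhitneyu(vi, vj, alternative="two-sided",
                                             method=method).pvalue)
            pw.loc[ci_, cj] = pw.loc[cj, ci_] = p
    return freq, kw_p, pw
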