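"""SNP quality control and per-SNP linear-regression GWAS.

QC excludes a SNP if its call rate, minor allele frequency, or
Hardy-Weinberg exact-test p-value falls strictly below the configured
threshold (values equal to a threshold are kept).  The HWE test is the
standard exact conditional test: the sum, over all heterozygote counts
consistent with the observed allele counts, of configuration probabilities
no larger than the observed configuration's (not mid-p).

The GWAS is ordinary least squares of phenotype on allele count plus an
intercept and the requested covariates, with a two-sided t-test on the
allele-count coefficient; individuals missing a call at a SNP are dropped
for that SNP only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .config import QcThresholds
from .containers import MISSING, GenotypeMatrix

__all__ = ["hwe_exact_test", "qc_filter", "linear_gwas", "GwasEngine"]


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value for genotype counts.

    Conditions on the observed allele counts; sums the probabilities of all
    heterozygote configurations whose probability does not exceed the
    observed one.  Monomorphic samples return 1.0.
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("at least one genotype call is required")
    # rare allele count and total allele count
    rare = 2 * min(n_AA, n_aa) + n_Aa
    # attainable heterozygote counts share the parity of the rare allele count
    h_obs = n_Aa
    h_max = min(rare, 2 * n - rare)
    if h_max == 0:
        return 1.0
    h = np.arange(rare % 2, h_max + 1, 2)
    # log P(h) ∝ h log 2 − log[( (rare−h)/2 )! h! ( (2n−rare−h)/2 − ... )!]
    rare_hom = (rare - h) // 2
    common_hom = n - h - rare_hom
    logp = h * np.log(2.0) - gammaln(rare_hom + 1) - gammaln(h + 1) - gammaln(common_hom + 1)
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[np.searchsorted(h, h_obs)]
    # relative tolerance absorbs float noise in mathematically tied configs
    return float(min(1.0, prob[prob <= p_obs * (1.0 + 1e-10)].sum()))


def _genotype_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP (n_AA, n_Aa, n_aa, n_missing) over the columns of ``calls``."""
    n0 = (calls == 0).sum(axis=0)
    n1 = (calls == 1).sum(axis=0)
    n2 = (calls == 2).sum(axis=0)
    nm = (calls == MISSING).sum(axis=0)
    return n0, n1, n2, nm


def qc_filter(
    genotypes: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Apply call-rate, MAF and HWE filters.

    Returns ``(kept_snp_ids, report)``; the report has one row per SNP with
    each criterion's value and pass flag.  MAF and HWE are computed over
    non-missing calls.
    """
    thresholds = thresholds or QcThresholds()
    if genotypes.n_snps == 0:
        raise ValueError("genotype matrix has no SNPs")
    n0, n1, n2, nm = _genotype_counts(genotypes.calls)
    n_called = n0 + n1 + n2
    call_rate = n_called / genotypes.n_individuals
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(n_called > 0, (2 * n2 + n1) / (2 * n_called), np.nan)
    maf = np.minimum(af, 1.0 - af)
    hwe_p = np.array(
        [
            hwe_exact_test(int(a), int(b), int(c)) if a + b + c > 0 else np.nan
            for a, b, c in zip(n0, n1, n2)
        ]
    )
    pass_cr = call_rate >= thresholds.call_rate_min
    pass_maf = maf >= thresholds.maf_min
    pass_hwe = hwe_p >= thresholds.hwe_p_min
    keep = pass_cr & pass_maf & pass_hwe
    report = pd.DataFrame(
        {
            "snp_id": genotypes.snp_ids,
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe_p,
            "pass_call_rate": pass_cr,
            "pass_maf": pass_maf,
            "pass_hwe": pass_hwe,
            "kept": keep,
        }
    )
    return list(genotypes.snp_ids[keep]), report


@dataclass(frozen=True)
class _CovariateDesign:
    C: np.ndarray  # n x (1 + n_cov), intercept first
    CtC_inv: np.ndarray


def _design(phenotypes: pd.DataFrame, covariates) -> np.ndarray:
    cols = [np.ones(len(phenotypes))]
    for cov in covariates:
        if cov not in ("age", "sex"):
            raise ValueError(f"unknown covariate {cov!r}")
        cols.append(phenotypes[cov].to_numpy(dtype=float))
    return np.column_stack(cols)


class GwasEngine:
    """Per-SNP OLS engine with the genotype-side cross-products cached.

    When several traits are analysed on the same cohort (same genotypes and
    covariate values), the expensive genotype projections are shared and
    each additional trait costs one matrix-vector product.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        covariate_frame: pd.DataFrame,
        covariates: tuple[str, ...] = ("age", "sex"),
    ) -> None:
        self.genotypes = genotypes
        self.covariates = tuple(covariates)
        self.C = _design(covariate_frame, self.covariates)
        n = genotypes.n_individuals
        self.n_params = self.C.shape[1] + 1
        self.df = n - self.n_params
        if self.df < 1:
            raise ValueError("not enough individuals for the requested model")
        G = genotypes.calls
        self.has_missing = (G == MISSING).any(axis=0)
        self.complete = ~self.has_missing
        self.CtC_inv = np.linalg.inv(self.C.T @ self.C)
        if self.complete.any():
            Gc = G[:, self.complete].astype(float)
            self._Gc = Gc
            A = Gc.T @ self.C
            self._A = A
            gMg = (Gc * Gc).sum(axis=0) - np.einsum("ij,jk,ik->i", A, self.CtC_inv, A)
            self._gMg = gMg

    def run(self, phenotypes: pd.DataFrame) -> pd.DataFrame:
        if len(phenotypes) != self.genotypes.n_individuals:
            raise ValueError("phenotype table and genotype matrix disagree on individuals")
        for cov in self.covariates:
            if not np.array_equal(
                phenotypes[cov].to_numpy(dtype=float), self.C[:, 1 + self.covariates.index(cov)]
            ):
                raise ValueError(f"covariate {cov!r} differs from the engine's cohort values")
        y = phenotypes["phenotype"].to_numpy(dtype=float)
        genotypes, C = self.genotypes, self.C
        n = genotypes.n_individuals
        G = genotypes.calls
        m = genotypes.n_snps

        beta = np.full(m, np.nan)
        se = np.full(m, np.nan)
        tstat = np.full(m, np.nan)
        pval = np.full(m, np.nan)
        n_used = np.full(m, 0, dtype=int)

        if self.complete.any():
            Gc, A, gMg, CtC_inv, df = self._Gc, self._A, self._gMg, self.CtC_inv, self.df
            alpha = CtC_inv @ (C.T @ y)
            y_res_ss = float(y @ y - (C.T @ y) @ alpha)
            gMy = Gc.T @ y - A @ alpha
            ok = gMg > 1e-10 * n  # genotype not constant after covariate projection
            b = np.where(ok, gMy / np.where(ok, gMg, 1.0), np.nan)
            rss = np.maximum(y_res_ss - b * b * gMg, 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                s = np.sqrt(rss / df / gMg)
                t = b / s
            p = 2.0 * stats.t.sf(np.abs(t), df)
            # a perfect fit gives rss 0 -> t infinite -> p 0; report smallest positive
            p = np.where(np.isinf(t), np.nextafter(0, 1), p)
            for arr in (b, s, t, p):
                arr[~ok] = np.nan
            idx = np.flatnonzero(self.complete)
            beta[idx], se[idx], tstat[idx], pval[idx] = b, s, t, p
            n_used[idx] = n
        return self._finish(phenotypes, beta, se, tstat, pval, n_used)

    def _finish(self, phenotypes, beta, se, tstat, pval, n_used):
        genotypes, C = self.genotypes, self.C
        y = phenotypes["phenotype"].to_numpy(dtype=float)
        G = genotypes.calls

        for j in np.flatnonzero(self.has_missing):
            g = G[:, j].astype(float)
            mask = g != MISSING
            if mask.sum() < self.n_params + 1:
                continue
            X = np.column_stack([g[mask], C[mask]])
            res = _ols_first_coef(X, y[mask])
            if res is not None:
                beta[j], se[j], tstat[j], pval[j] = res
                n_used[j] = int(mask.sum())

        testable = np.isfinite(pval)
        return pd.DataFrame(
            {
                "snp_id": genotypes.snp_ids,
                "chromosome": genotypes.snp_map["chromosome"].to_numpy(),
                "position": genotypes.snp_map["position"].to_numpy(),
                "beta": beta,
                "se": se,
                "t": tstat,
                "p_value": pval,
                "n": n_used,
                "testable": testable,
            }
        )


def linear_gwas(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> pd.DataFrame:
    """Per-SNP OLS of phenotype on allele count (+ intercept + covariates).

    Returns a table with ``snp_id``, ``chromosome``, ``position``, ``beta``,
    ``se``, ``t``, ``p_value``, ``n`` and ``testable``; constant-genotype
    (or otherwise degenerate) SNPs are flagged not testable with NaN
    statistics instead of raising.  Individuals with a missing call at a
    SNP are dropped for that SNP only (complete-case per SNP).
    """
    return GwasEngine(genotypes, phenotypes, covariates).run(phenotypes)


def _ols_first_coef(X: np.ndarray, y: np.ndarray):
    """OLS of y on X; (beta, se, t, p) for the first column, or None if the
    design is rank-deficient in that column."""
    n, k = X.shape
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        return None
    b = XtX_inv @ (X.T @ y)
    resid = y - X @ b
    df = n - k
    if df < 1:
        return None
    sigma2 = float(resid @ resid) / df
    var_b0 = sigma2 * XtX_inv[0, 0]
    if not np.isfinite(var_b0) or XtX_inv[0, 0] <= 0 or XtX_inv[0, 0] > 1e12:
        return None
    se = np.sqrt(var_b0)
    if se == 0:
        return float(b[0]), 0.0, np.inf, np.nextafter(0, 1)
    t = b[0] / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(b[0]), float(se), float(t), float(p)
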