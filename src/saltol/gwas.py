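"""Mixed-linear-model association scan of the tolerance score.

The model is the standard kinship MLM: for phenotype y (the comprehensive
tolerance score D),

    y = X beta + g beta_snp + u + e,    u ~ N(0, sigma_g^2 K),  e ~ N(0, sigma_e^2 I)

with K the VanRaden genomic relationship matrix.  The variance ratio
delta = sigma_e^2 / sigma_g^2 is estimated once under the null model by
REML on the spectrum of K (the EMMA trick) and then held fixed for every
marker (P3D), each marker being tested by generalized least squares with
a two-sided t test.  Population-structure adjustment uses the leading
eigenvectors of K as fixed covariates (default 3).

Genome-wide significance uses the Bonferroni cutoff on the -log10 scale,
-log10(1/m) = log10(m) for m tested markers; the genomic inflation factor
lambda = median(chi2) / 0.4549 is always reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import GenotypeMatrix, read_genotypes  # noqa: F401  (re-export)

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300
_CHI2_MEDIAN = 0.4549  # median of chi-square(1)


def kinship(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """VanRaden method-1 genomic relationship matrix.

    K = Z Z' / (2 * sum_k p_k (1 - p_k)) with Z the mean-imputed dosage
    matrix centered at twice the alt-allele frequency.
    """
    if genotypes.n_markers < 2:
        raise ValueError("kinship needs at least 2 markers")
    M = genotypes.imputed()
    p = M.mean(axis=0) / 2.0
    Z = M - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom == 0:
        raise ValueError("all markers monomorphic; kinship undefined")
    K = (Z @ Z.T) / denom
    acc = genotypes.accessions
    return pd.DataFrame(K, index=acc, columns=acc)


def bonferroni_threshold(n_markers: int) -> float:
    """-log10(1/m) = log10(m) genome-wide cutoff."""
    if n_markers < 1:
        raise ValueError("need at least one marker")
    return float(np.log10(n_markers))


def _reml_delta(y_rot: np.ndarray, X_rot: np.ndarray, s: np.ndarray) -> float:
    """Restricted ML estimate of delta = sigma_e^2 / sigma_g^2.

    Works on data rotated into the eigenbasis of K (eigenvalues s);
    profiles sigma_g^2 out and optimizes the restricted log-likelihood
    over log10(delta) on [-5, 5].
    """
    n, p = X_rot.shape
    nf = n - p

    def neg_rll(log_delta: float) -> float:
        delta = 10.0 ** log_delta
        w = 1.0 / (s + delta)
        XtWX = X_rot.T @ (w[:, None] * X_rot)
        XtWy = X_rot.T @ (w * y_rot)
        beta = np.linalg.solve(XtWX, XtWy)
        resid = y_rot - X_rot @ beta
        rss = float(resid @ (w * resid))
        sign, logdet_xwx = np.linalg.slogdet(XtWX)
        if sign <= 0 or rss <= 0:
            return np.inf
        ll = -0.5 * (
            nf * np.log(rss / nf) + np.sum(np.log(s + delta)) + logdet_xwx + nf
        )
        return -ll

    res = optimize.minimize_scalar(neg_rll, bounds=(-5.0, 5.0), method="bounded",
                                   options={"xatol": 1e-6})
    log_delta = float(res.x)
    if log_delta <= -4.99 or log_delta >= 4.99:
        warnings.warn("variance-ratio estimate at search boundary; "
                      "polygenic signal may be absent or dominate entirely")
    return 10.0 ** log_delta


@dataclass
class GwasResults:
    """Per-marker association results plus genome-wide diagnostics."""

    table: pd.DataFrame              # marker, chrom, pos, beta, se, p, neglog10p
    threshold: float                 # -log10 scale
    lambda_gc: float
    delta: float                     # REML sigma_e^2 / sigma_g^2 under the null
    n_accessions: int
    n_pcs: int
    provenance: dict = field(default_factory=dict)

    @property
    def significant(self) -> pd.DataFrame:
        """Markers at or above the Bonferroni -log10 cutoff."""
        return self.table[self.table["neglog10p"] >= self.threshold]

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.nsmallest(n, "p")

    def summary(self) -> pd.DataFrame:
        sig = self.significant
        return pd.DataFrame({
            "value": [len(self.table), self.n_accessions, self.threshold,
                      self.lambda_gc, self.delta, len(sig)],
        }, index=["n_markers", "n_accessions", "threshold_neglog10",
                  "lambda_gc", "delta_null", "n_significant"])

    def manhattan_frame(self) -> pd.DataFrame:
        """Manhattan export: chrom, pos, -log10 p, cumulative coordinate."""
        df = self.table[["marker", "chrom", "pos", "neglog10p"]].copy()
        offset, cum = 0, []
        for _, grp in df.groupby("chrom", sort=False):
            cum.append(grp["pos"] + offset)
            offset += int(grp["pos"].max())
        df["cum_pos"] = pd.concat(cum)
        return df

    def qq_frame(self) -> pd.DataFrame:
        """QQ export: expected vs observed -log10 p for ascending p ranks."""
        obs = np.sort(self.table["p"].to_numpy())
        m = obs.size
        expected = (np.arange(1, m + 1) - 0.5) / m
        return pd.DataFrame({
            "expected_neglog10p": -np.log10(expected),
            "observed_neglog10p": -np.log10(np.maximum(obs, _P_FLOOR)),
        })

    def export(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "gwas_scan.tsv", sep="\t", index=False)
        self.significant.to_csv(out / "gwas_significant.tsv", sep="\t", index=False)
        self.manhattan_frame().to_csv(out / "manhattan.tsv", sep="\t", index=False)
        self.qq_frame().to_csv(out / "qq.tsv", sep="\t", index=False)


class MixedLMGwas:
    """Single-marker MLM scan with P3D variance components.

    Parameters
    ----------
    phenotype : Series
        Per-accession score (e.g. the comprehensive tolerance score D),
        indexed by accession id.
    genotypes : GenotypeMatrix
        Filtered marker set; missing dosages are mean-imputed.
    K : DataFrame, optional
        Kinship; computed with :func:`kinship` when omitted.
    n_pcs : int
        Leading eigenvectors of K included as fixed covariates.
    """

    def __init__(self, phenotype: pd.Series, genotypes: GenotypeMatrix,
                 K: pd.DataFrame = None, n_pcs: int = 3):
        common = phenotype.index.intersection(genotypes.accessions)
        if len(common) < 10:
            raise ValueError("fewer than 10 accessions shared by phenotype and genotypes")
        if len(common) < len(phenotype):
            warnings.warn(
                f"dropping {len(phenotype) - len(common)} accession(s) without genotypes")
        order = [a for a in genotypes.accessions if a in set(common)]
        self.y = phenotype.loc[order].astype(float)
        if self.y.isna().any():
            raise ValueError("phenotype contains missing values")
        self.genotypes = GenotypeMatrix(
            genotypes.dosages.loc[order], genotypes.markers.copy())
        self.K = kinship(self.genotypes) if K is None else K.loc[order, order]
        if not np.allclose(self.K.to_numpy(), self.K.to_numpy().T, atol=1e-8):
            raise ValueError("kinship matrix is not symmetric")
        self.n_pcs = int(n_pcs)

    def fit(self) -> GwasResults:
        y = self.y.to_numpy()
        n = y.size
        Kmat = self.K.to_numpy()
        s, U = np.linalg.eigh(Kmat)
        if s.min() < -1e-6 * max(1.0, s.max()):
            raise ValueError("kinship is not positive semidefinite; "
                             "add a small diagonal jitter")
        s = np.clip(s, 0.0, None)
        # eigh returns ascending order; PCs are the trailing columns
        X = np.ones((n, 1))
        if self.n_pcs > 0:
            X = np.hstack([X, U[:, ::-1][:, : self.n_pcs]])
        p_cov = X.shape[1]

        y_rot, X_rot = U.T @ y, U.T @ X
        delta = _reml_delta(y_rot, X_rot, s)
        w = 1.0 / (s + delta)
        sw = np.sqrt(w)

        yw = sw * y_rot
        Xw = sw[:, None] * X_rot
        G = self.genotypes.imputed()
        Gw = sw[:, None] * (U.T @ G)

        Q, _ = np.linalg.qr(Xw)
        y_res = yw - Q @ (Q.T @ yw)
        G_res = Gw - Q @ (Q.T @ Gw)

        den = np.einsum("ij,ij->j", G_res, G_res)
        num = G_res.T @ y_res
        dfree = n - p_cov - 1
        if dfree <= 0:
            raise ValueError("not enough accessions for the covariate set")
        ok = den > 1e-12
        beta = np.where(ok, num / np.where(ok, den, 1.0), np.nan)
        yss = float(y_res @ y_res)
        sigma2 = np.where(ok, (yss - beta * num) / dfree, np.nan)
        sigma2 = np.clip(sigma2, 1e-300, None)
        se = np.sqrt(sigma2 / np.where(ok, den, np.nan))
        tstat = beta / se
        pvals = np.where(ok, 2.0 * stats.t.sf(np.abs(tstat), dfree), 1.0)
        pvals = np.clip(pvals, _P_FLOOR, 1.0)

        chi2 = stats.chi2.isf(pvals[ok], df=1)
        lam = float(np.median(chi2) / _CHI2_MEDIAN) if ok.any() else np.nan

        tab = self.genotypes.markers[["marker", "chrom", "pos"]].copy()
        tab["beta"] = beta
        tab["se"] = se
        tab["p"] = pvals
        tab["neglog10p"] = -np.log10(pvals)
        res = GwasResults(
            table=tab,
            threshold=bonferroni_threshold(tab.shape[0]),
            lambda_gc=lam,
            delta=delta,
            n_accessions=n,
            n_pcs=self.n_pcs,
            provenance={"n_markers": int(tab.shape[0]),
                        "n_monomorphic": int((~ok).sum())},
        )
        logger.info("MLM scan: m=%d n=%d delta=%.3g lambda=%.3f",
                    tab.shape[0], n, delta, lam)
        return res


def mlm_scan(phenotype: pd.Series, genotypes: GenotypeMatrix,
             K: pd.DataFrame = None, n_pcs: int = 3) -> GwasResults:
    """Functional wrapper around :class:`MixedLMGwas`."""
    return MixedLMGwas(phenotype, genotypes, K=K, n_pcs=n_pcs).fit()


def filter_markers(genotypes: GenotypeMatrix, maf_min: float = 0.05,
                   missing_max: float = 0.2) -> GenotypeMatrix:
    """MAF / missingness marker filter (delegates to the container)."""
    return genotypes.filter_markers(maf_min=maf_min, missing_max=missing_max)


def export_manhattan_qq(result: GwasResults):
    """Return the (manhattan, qq) frame pair for plotting tools."""
    return result.manhattan_frame(), result.qq_frame()
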