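"""Gene-content association with the wild/selection contrast.

Markers are 0/1 gene-presence calls; the phenotype is the binary
population label (0 = wild, 1 = selection) treated as continuous, the
convention of standard mixed-model GWAS tools on case/control-like traits.

Three models are provided:

* **glm** — ordinary least squares of phenotype on marker, intercept and
  optional covariates (principal components), with a t-test on the marker
  coefficient;
* **mlm** — EMMA-style linear mixed model y = W a + x b + u + e with
  u ~ N(0, sg^2 K). The kinship K is eigendecomposed once and the variance
  ratio delta = se^2/sg^2 is estimated by REML on the null (no-marker)
  model and then fixed across markers (the P3D approximation); each marker
  is tested by generalized least squares with a Wald t-test;
* **fisher** — two-sided Fisher exact test on the 2x2 presence-by-phenotype
  table, the natural nonparametric baseline for a binary marker and binary
  trait; its effect size is the log odds ratio (Haldane-Anscombe corrected
  when a cell is empty).

Marker QC follows strict inequalities: keep a gene iff MAF > 0.05 and
missing rate < 0.15 (a marker at exactly either bound is removed).
Significance is reported two ways — Bonferroni at family alpha 0.05 and a
fixed -log10(p) >= 5 line — so either convention can be read off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .matrix import MISSING, PRESENT, PAVMatrix, PavError
from .popgen import _impute_presence


# ---------------------------------------------------------------------------
# marker QC
# ---------------------------------------------------------------------------


def marker_qc(matrix: PAVMatrix) -> pd.DataFrame:
    """Per-gene MAF (minor presence-state frequency over non-missing calls)
    and missing rate."""
    nm = matrix.calls != MISSING
    n_nm = nm.sum(axis=1)
    pres = (matrix.calls == PRESENT).sum(axis=1)
    with np.errstate(invalid="ignore"):
        p = np.divide(pres, n_nm, out=np.zeros(matrix.n_genes), where=n_nm > 0)
    maf = np.minimum(p, 1 - p)
    missing_rate = 1 - n_nm / matrix.n_samples
    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "maf": maf,
            "missing_rate": missing_rate,
        }
    )


def filter_markers(
    matrix: PAVMatrix, maf_min: float = 0.05, miss_max: float = 0.15
) -> tuple[PAVMatrix, pd.DataFrame]:
    """Strict-inequality marker filter: keep iff maf > maf_min and
    missing_rate < miss_max."""
    qc = marker_qc(matrix)
    qc["pass_flag"] = (qc["maf"] > maf_min) & (qc["missing_rate"] < miss_max)
    return matrix.subset_genes(qc["pass_flag"].to_numpy()), qc


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


def kinship(matrix: PAVMatrix) -> tuple[np.ndarray, list[str]]:
    """VanRaden-type genomic relationship matrix from presence calls.

    Calls are mean-imputed, centred per gene by the presence frequency p_j,
    and K = Z'Z / sum p_j (1 - p_j). Eigenvalues are floored at 0 so K is
    positive semidefinite to numerical tolerance.
    """
    if matrix.n_samples < 2:
        raise PavError("need >= 2 samples")
    X = _impute_presence(matrix)
    p = X.mean(axis=1, keepdims=True)
    poly = ((p > 0) & (p < 1)).ravel()
    if not poly.any():
        raise PavError("no polymorphic gene after filtering")
    Z = X[poly] - p[poly]
    denom = float((p[poly] * (1 - p[poly])).sum())
    K = (Z.T @ Z) / denom
    evals, evecs = np.linalg.eigh(K)
    if evals.min() < 0:
        K = (evecs * np.clip(evals, 0, None)) @ evecs.T
        K = (K + K.T) / 2
    return K, list(matrix.sample_ids)


# ---------------------------------------------------------------------------
# shared linear-model machinery
# ---------------------------------------------------------------------------


def _design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    W = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, float))
        if C.shape[0] != n:
            C = C.T
        W = np.column_stack([W, C])
    return W


def _marker_t_tests(
    y: np.ndarray, X: np.ndarray, W: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column marker regression of y on [W, x] via Frisch-Waugh.

    X is markers x samples. Returns (beta, se, p); columns collinear with W
    (zero residual variance) come back NaN.
    """
    n, pcov = W.shape
    Q, _ = np.linalg.qr(W)
    yr = y - Q @ (Q.T @ y)
    Xr = X.T - Q @ (Q.T @ X.T)  # samples x markers
    xx = (Xr**2).sum(axis=0)
    xy = Xr.T @ yr
    df = n - pcov - 1
    valid = xx > 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(valid, xy / xx, np.nan)
        rss = (yr @ yr) - np.where(valid, xy**2 / xx, 0.0)
        sigma2 = np.clip(rss, 0.0, None) / df
        se = np.sqrt(sigma2 / xx)
        tstat = beta / se  # +-inf on a perfect fit (rss = 0) -> p = 0
        p = 2 * stats.t.sf(np.abs(tstat), df)
    p = np.where(valid, p, np.nan)
    return np.where(valid, beta, np.nan), np.where(valid, se, np.nan), p


def _records(
    matrix: PAVMatrix, model: str, beta: np.ndarray, se: np.ndarray, p: np.ndarray
) -> pd.DataFrame:
    with np.errstate(divide="ignore"):
        neglog = -np.log10(p)
    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "model": model,
            "effect": beta,
            "se": se,
            "p": p,
            "neglog10p": neglog,
        }
    )


def glm_assoc(
    matrix: PAVMatrix, phenotype: np.ndarray, covariates: np.ndarray | None = None
) -> pd.DataFrame:
    """OLS association per marker (general linear model)."""
    y = np.asarray(phenotype, float)
    if np.allclose(y, y[0]):
        raise PavError("phenotype is constant")
    if len(y) != matrix.n_samples:
        raise PavError("phenotype length mismatch")
    X = _impute_presence(matrix)
    W = _design(len(y), covariates)
    beta, se, p = _marker_t_tests(y, X, W)
    return _records(matrix, "glm", beta, se, p)


# -- REML for the variance ratio --------------------------------------------


def _reml_neg_loglik(log_delta: float, lam: np.ndarray, yt: np.ndarray, Wt: np.ndarray) -> float:
    """-2 x REML log-likelihood (up to a constant) of the null model in the
    eigenbasis of K; lam are K's eigenvalues, delta = se^2/sg^2."""
    delta = np.exp(log_delta)
    v = lam + delta
    wi = 1.0 / v
    WtW = (Wt * wi[:, None]).T @ Wt
    Wty = (Wt * wi[:, None]).T @ yt
    coef = np.linalg.solve(WtW, Wty)
    resid = yt - Wt @ coef
    rss = float(resid @ (wi * resid))
    n, pcov = Wt.shape
    sign, logdet_WtW = np.linalg.slogdet(WtW)
    return (
        (n - pcov) * np.log(rss / (n - pcov))
        + float(np.sum(np.log(v)))
        + logdet_WtW
    )


def estimate_delta_reml(
    lam: np.ndarray, yt: np.ndarray, Wt: np.ndarray, bounds: tuple[float, float] = (-10.0, 10.0)
) -> float:
    """REML estimate of delta = se^2/sg^2 by 1-D search over log delta.

    A coarse grid locates the basin; Brent refines it. The grid doubles as
    the fallback if Brent fails to converge.
    """
    grid = np.linspace(bounds[0], bounds[1], 81)
    vals = np.array([_reml_neg_loglik(g, lam, yt, Wt) for g in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    try:
        res = optimize.minimize_scalar(
            _reml_neg_loglik, bounds=(lo, hi), args=(lam, yt, Wt), method="bounded"
        )
        if res.success and np.isfinite(res.fun) and res.fun <= vals[i] + 1e-9:
            return float(np.exp(res.x))
    except Exception:  # pragma: no cover - scipy failures fall back to grid
        pass
    return float(np.exp(grid[i]))


def mlm_assoc(
    matrix: PAVMatrix,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    K: np.ndarray | None = None,
) -> pd.DataFrame:
    """EMMA-style mixed-model association with P3D variance components."""
    y = np.asarray(phenotype, float)
    if np.allclose(y, y[0]):
        raise PavError("phenotype is constant")
    n = matrix.n_samples
    if len(y) != n:
        raise PavError("phenotype length mismatch")
    if K is None:
        K, _ = kinship(matrix)
    K = np.asarray(K, float)
    if K.shape != (n, n):
        raise PavError("kinship not conformable with samples")
    evals = np.linalg.eigvalsh(K)
    if evals.min() < -1e-8 * max(1.0, float(evals.max())):
        raise PavError("kinship matrix is not positive semidefinite")
    lam, U = np.linalg.eigh(K)
    lam = np.clip(lam, 0, None)
    X = _impute_presence(matrix)
    W = _design(n, covariates)
    yt = U.T @ y
    Wt = U.T @ W
    Xt = (U.T @ X.T).T  # markers x samples, rotated
    delta = estimate_delta_reml(lam, yt, Wt)
    # GLS in the eigenbasis == OLS after whitening by 1/sqrt(lam + delta)
    sw = 1.0 / np.sqrt(lam + delta)
    beta, se, p = _marker_t_tests(yt * sw, Xt * sw[None, :], Wt * sw[:, None])
    rec = _records(matrix, "mlm", beta, se, p)
    rec.attrs["delta"] = delta
    return rec


def fisher_assoc(matrix: PAVMatrix, phenotype: np.ndarray) -> pd.DataFrame:
    """Two-sided Fisher exact test per marker on the 2x2 presence x phenotype
    table (missing calls dropped); effect is the Haldane-Anscombe log OR."""
    y = np.asarray(phenotype)
    if len(y) != matrix.n_samples:
        raise PavError("phenotype length mismatch")
    y1 = y.astype(float) > 0.5
    beta = np.empty(matrix.n_genes)
    p = np.empty(matrix.n_genes)
    for i in range(matrix.n_genes):
        calls = matrix.calls[i]
        nm = calls != MISSING
        pres = calls[nm] == PRESENT
        pheno = y1[nm]
        a = int((pres & pheno).sum())
        b = int((pres & ~pheno).sum())
        c = int((~pres & pheno).sum())
        d = int((~pres & ~pheno).sum())
        _, p[i] = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        beta[i] = np.log(a * d / (b * c))
    se = np.full(matrix.n_genes, np.nan)
    return _records(matrix, "fisher", beta, se, p)


# ---------------------------------------------------------------------------
# significance + diagnostics
# ---------------------------------------------------------------------------


def significance(
    records: pd.DataFrame,
    n_markers: int | None = None,
    alpha: float = 0.05,
    fixed_neglog10: float = 5.0,
) -> pd.DataFrame:
    """Attach Bonferroni (p <= alpha/m) and fixed-line (-log10 p >= cut) flags."""
    out = records.copy()
    m = n_markers if n_markers is not None else int(records["p"].notna().sum())
    if m < 1:
        raise PavError("no markers")
    with np.errstate(invalid="ignore"):
        out["significant_bonferroni"] = records["p"] <= alpha / m
        out["significant_fixed"] = records["neglog10p"] >= fixed_neglog10
    out[["significant_bonferroni", "significant_fixed"]] = out[
        ["significant_bonferroni", "significant_fixed"]
    ].fillna(False)
    return out


@dataclass
class QqSummary:
    observed: np.ndarray  # sorted -log10 p, most significant first
    expected: np.ndarray  # -log10((i - 0.5)/m)
    lambda_gc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"expected": self.expected, "observed": self.observed})


def qq_summary(records: pd.DataFrame) -> QqSummary:
    """Q-Q data and the genomic inflation factor lambda_gc.

    lambda_gc = median(chi2_obs) / median(chi2(1)), with chi2_obs the 1-df
    quantile transform of the p-values.
    """
    p = records["p"].to_numpy(dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise PavError("no defined p-value")
    m = p.size
    obs = np.sort(-np.log10(np.clip(p, 1e-300, 1)))[::-1]
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    chi2_obs = stats.chi2.isf(np.clip(p, 1e-300, 1), df=1)
    lam = float(np.median(chi2_obs) / stats.chi2.ppf(0.5, df=1))
    return QqSummary(obs, expected, lam)


def manhattan_table(records: pd.DataFrame, gene_meta: pd.DataFrame) -> pd.DataFrame:
    """Plotting-ready (chrom, pos, -log10 p, flags) table, sorted by position;
    genes on unplaced sequence sort onto the trailing ``novel`` pseudo-contig."""
    meta = gene_meta.loc[records["gene_id"]]
    out = records.copy()
    out["chrom"] = np.where(meta["source"].to_numpy() == "novel", "novel", meta["chrom"].to_numpy())
    out["pos"] = meta["start"].to_numpy()
    out["_novel"] = out["chrom"] == "novel"
    out = (
        out.sort_values(["_novel", "chrom", "pos"], kind="stable")
        .drop(columns="_novel")
        .reset_index(drop=True)
    )
    cols = ["chrom", "pos", "gene_id", "model", "effect", "se", "p", "neglog10p"]
    cols += [c for c in ("significant_bonferroni", "significant_fixed") if c in out.columns]
    return out[cols]
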