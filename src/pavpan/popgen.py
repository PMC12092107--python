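"""PAV-based population structure and differentiation.

Markers are haploid binary alleles: each accession carries either the
"present" (G) or "absent" (A) state of a gene. On such data:

* pairwise distance is the p-distance — the proportion of genes with
  differing calls among genes non-missing in both accessions;
* the tree is Saitou–Nei neighbour-joining on that distance matrix;
* structure is summarized by PCA of the standardized presence matrix
  (GRM-style: per-gene centring by presence frequency and division by
  sqrt(p(1-p)));
* per-gene differentiation between the wild and selection populations is
  measured by a Weir–Cockerham-type variance-component F_ST specialized
  to haploid allele counts (default), or a Hudson-type estimator
  1 - Hw/Hb with the unbiased within-population heterozygosity
  p(1-p) n/(n-1). Estimates are reported raw (negative values are not
  clamped); monomorphic genes are flagged undefined.
* the selection scan flags genes at or above the empirical top-1%
  F_ST quantile (linear interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as SkbioDistanceMatrix
from skbio.tree import nj

from .matrix import ABSENT, MISSING, PRESENT, PAVMatrix, PavError, SampleSheet


# ---------------------------------------------------------------------------
# distance + tree
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise PavError("distance matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise PavError("distance matrix not symmetric")
        if np.diag(v).any():
            raise PavError("distance matrix diagonal not zero")
        self.values = v

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.sample_ids)}\n")
            for i, s in enumerate(self.sample_ids):
                row = " ".join(f"{x:.6f}" for x in self.values[i])
                fh.write(f"{s}\t{row}\n")


def pav_distance(matrix: PAVMatrix) -> DistanceMatrix:
    """p-distance between accessions over pairwise non-missing genes."""
    if matrix.n_samples < 2:
        raise PavError("need >= 2 samples")
    P = (matrix.calls == PRESENT).astype(np.float64)
    A = (matrix.calls == ABSENT).astype(np.float64)
    nm = (matrix.calls != MISSING).astype(np.float64)
    all_missing = np.flatnonzero(nm.sum(axis=0) == 0)
    if all_missing.size:
        raise PavError(f"sample {matrix.sample_ids[all_missing[0]]} has no non-missing calls")
    shared = nm.T @ nm
    diff = P.T @ A + A.T @ P
    off = ~np.eye(matrix.n_samples, dtype=bool)
    if (shared[off] == 0).any():
        i, j = np.argwhere((shared == 0) & off)[0]
        raise PavError(
            f"samples {matrix.sample_ids[i]} and {matrix.sample_ids[j]} share no genes"
        )
    with np.errstate(invalid="ignore"):
        d = diff / np.maximum(shared, 1)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # symmetrize away float asymmetry
    return DistanceMatrix(list(matrix.sample_ids), d)


@dataclass
class NjTree:
    """Unrooted NJ tree; negative branch lengths are clamped to 0 and flagged."""

    tree: object  # skbio.TreeNode
    negative_branch_clamped: bool

    @property
    def leaf_names(self) -> set[str]:
        return {t.name for t in self.tree.tips()}

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the smaller-side leaf set."""
        leaves = frozenset(self.leaf_names)
        out = set()
        for node in self.tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(leaves) - 1:
                other = leaves - side
                out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return out


def nj_tree(d: DistanceMatrix) -> NjTree:
    """Saitou–Nei neighbour joining."""
    if len(d.sample_ids) < 3:
        raise PavError("neighbour joining needs >= 3 taxa")
    dm = SkbioDistanceMatrix(d.values, ids=d.sample_ids)
    raw = nj(dm, neg_as_zero=False)
    clamped = False
    for node in raw.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped = True
    return NjTree(raw, clamped)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x k
    explained: np.ndarray  # variance fractions, non-increasing
    k: int

    def to_frame(self) -> pd.DataFrame:
        cols = {f"PC{i + 1}": self.coordinates[:, i] for i in range(self.k)}
        return pd.DataFrame({"sample_id": self.sample_ids, **cols})


def _impute_presence(matrix: PAVMatrix) -> np.ndarray:
    """0/1 encoding with per-gene mean imputation of missing cells."""
    X = matrix.presence()  # genes x samples, NaN missing
    mean = np.nanmean(X, axis=1, keepdims=True)
    mean = np.nan_to_num(mean, nan=0.0)
    idx = np.where(np.isnan(X))
    X[idx] = np.broadcast_to(mean, X.shape)[idx]
    return X


def pav_pca(matrix: PAVMatrix, k: int = 10, standardize: bool = True) -> PcaResult:
    """PCA of the (optionally GRM-standardized) presence matrix.

    Per gene: centre by presence frequency p and, when ``standardize``,
    divide by sqrt(p(1-p)). Coordinates are the top-k eigenvectors of the
    sample-by-sample covariance scaled by root-eigenvalues; each component's
    sign is fixed so its largest-magnitude entry is positive.
    """
    if matrix.n_samples < 2:
        raise PavError("need >= 2 samples")
    X = _impute_presence(matrix)
    p = X.mean(axis=1, keepdims=True)
    poly = ((p > 0) & (p < 1)).ravel()
    if not poly.any():
        raise PavError("no polymorphic gene")
    Z = X[poly] - p[poly]
    if standardize:
        Z = Z / np.sqrt(p[poly] * (1 - p[poly]))
    m, n = Z.shape
    K = (Z.T @ Z) / m
    if k > n - 1:
        k = n - 1
    evals, evecs = np.linalg.eigh(K)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0, None)
    total = evals.sum()
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    for c in range(k):
        imax = np.argmax(np.abs(coords[:, c]))
        if coords[imax, c] < 0:
            coords[:, c] = -coords[:, c]
    explained = evals[:k] / total if total > 0 else np.zeros(k)
    return PcaResult(list(matrix.sample_ids), coords, explained, k)


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------


def _pop_counts(matrix: PAVMatrix, sheet: SampleSheet) -> tuple[np.ndarray, ...]:
    pops = sheet.population_of(matrix.sample_ids)
    for label in ("wild", "selection"):
        if (pops == label).sum() == 0:
            raise PavError(f"population {label!r} absent from sheet")
    w = pops == "wild"
    s = pops == "selection"
    nm = matrix.calls != MISSING
    pres = matrix.calls == PRESENT
    n1 = (nm[:, w]).sum(axis=1)
    n2 = (nm[:, s]).sum(axis=1)
    x1 = (pres[:, w]).sum(axis=1)
    x2 = (pres[:, s]).sum(axis=1)
    return n1, x1, n2, x2


def fst_weir_cockerham_haploid(
    n1: np.ndarray, x1: np.ndarray, n2: np.ndarray, x2: np.ndarray
) -> np.ndarray:
    """Weir–Cockerham variance-component F_ST for haploid biallelic counts.

    With r = 2 populations of sizes n_i and presence frequencies p_i:
    MSP = sum n_i (p_i - pbar)^2 / (r - 1)  (between),
    MSG = sum n_i p_i (1 - p_i) / sum (n_i - 1)  (within),
    n_c = (sum n_i - sum n_i^2 / sum n_i) / (r - 1),
    theta = (MSP - MSG) / (MSP + (n_c - 1) MSG).
    Returns NaN where the denominator vanishes (monomorphic overall).
    """
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    p1 = np.divide(x1, n1, out=np.zeros_like(n1), where=n1 > 0)
    p2 = np.divide(x2, n2, out=np.zeros_like(n2), where=n2 > 0)
    ntot = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / ntot
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # r - 1 = 1
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n1 + n2 - 2)
    nc = ntot - (n1**2 + n2**2) / ntot
    denom = msp + (nc - 1) * msg
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom != 0, (msp - msg) / denom, np.nan)
    return theta


def fst_hudson_haploid(
    n1: np.ndarray, x1: np.ndarray, n2: np.ndarray, x2: np.ndarray
) -> np.ndarray:
    """Hudson-type F_ST = 1 - Hw/Hb on haploid counts.

    Hw averages the unbiased within-population heterozygosities
    p_i(1-p_i) n_i/(n_i-1); Hb = p1(1-p2) + p2(1-p1). NaN where Hb = 0.
    """
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    p1 = np.divide(x1, n1, out=np.zeros_like(n1), where=n1 > 0)
    p2 = np.divide(x2, n2, out=np.zeros_like(n2), where=n2 > 0)
    hw = (p1 * (1 - p1) * n1 / (n1 - 1) + p2 * (1 - p2) * n2 / (n2 - 1)) / 2
    hb = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(hb != 0, 1 - hw / hb, np.nan)


_ESTIMATORS = {
    "weir_cockerham": fst_weir_cockerham_haploid,
    "hudson": fst_hudson_haploid,
}


def fst_per_gene(
    matrix: PAVMatrix, sheet: SampleSheet, estimator: str = "weir_cockerham"
) -> pd.DataFrame:
    """Per-gene two-population F_ST records.

    Genes monomorphic across both populations, or with fewer than two
    non-missing calls in either population, are flagged ``undefined``
    (fst = NaN). Estimates are raw — negative values are kept.
    """
    if estimator not in _ESTIMATORS:
        raise PavError(f"unknown estimator {estimator!r}")
    n1, x1, n2, x2 = _pop_counts(matrix, sheet)
    fst = _ESTIMATORS[estimator](n1, x1, n2, x2)
    enough = (n1 >= 2) & (n2 >= 2)
    monomorphic = ((x1 + x2) == 0) | ((x1 + x2) == (n1 + n2))
    fst = np.where(enough & ~monomorphic, fst, np.nan)
    with np.errstate(invalid="ignore"):
        p1 = np.divide(x1, n1, out=np.full(len(n1), np.nan), where=n1 > 0)
        p2 = np.divide(x2, n2, out=np.full(len(n2), np.nan), where=n2 > 0)
    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "n1": n1,
            "n2": n2,
            "p1": p1,
            "p2": p2,
            "abs_freq_diff": np.abs(p1 - p2),
            "fst": fst,
            "undefined": ~np.isfinite(fst),
        }
    )


def _wc_components(
    n1: np.ndarray, x1: np.ndarray, n2: np.ndarray, x2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (numerator, denominator) of the haploid WC estimator."""
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    p1 = np.divide(x1, n1, out=np.zeros_like(n1), where=n1 > 0)
    p2 = np.divide(x2, n2, out=np.zeros_like(n2), where=n2 > 0)
    ntot = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / ntot
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n1 + n2 - 2)
    nc = ntot - (n1**2 + n2**2) / ntot
    return msp - msg, msp + (nc - 1) * msg


def fst_global(
    matrix: PAVMatrix, sheet: SampleSheet, estimator: str = "weir_cockerham"
) -> tuple[float, float]:
    """Genome-wide F_ST as the multi-locus ratio of sums, with a
    leave-one-locus-out jackknife standard error.

    Summing the variance components across loci before taking the ratio is
    the standard multi-locus form of both estimators; unlike the mean of
    per-locus ratios it is nearly unbiased (a per-locus ratio with two
    populations has ~1 between-population degree of freedom, so averaging
    raw ratios is Jensen-biased downward).
    """
    if estimator not in _ESTIMATORS:
        raise PavError(f"unknown estimator {estimator!r}")
    n1, x1, n2, x2 = _pop_counts(matrix, sheet)
    if estimator == "weir_cockerham":
        num, den = _wc_components(n1, x1, n2, x2)
    else:
        n1f = np.asarray(n1, float)
        n2f = np.asarray(n2, float)
        p1 = np.divide(x1, n1f, out=np.zeros_like(n1f), where=n1f > 0)
        p2 = np.divide(x2, n2f, out=np.zeros_like(n2f), where=n2f > 0)
        hw = (p1 * (1 - p1) * n1f / (n1f - 1) + p2 * (1 - p2) * n2f / (n2f - 1)) / 2
        hb = p1 * (1 - p2) + p2 * (1 - p1)
        num, den = hb - hw, hb
    ok = (n1 >= 2) & (n2 >= 2) & (den != 0)
    num, den = num[ok], den[ok]
    if num.size == 0:
        raise PavError("no informative locus")
    theta = float(num.sum() / den.sum())
    L = num.size
    loo = (num.sum() - num) / (den.sum() - den)
    se = float(np.sqrt((L - 1) / L * ((loo - loo.mean()) ** 2).sum()))
    return theta, se


def top_fraction(records: pd.DataFrame, fraction: float = 0.01) -> tuple[float, pd.DataFrame]:
    """Empirical top-``fraction`` F_ST scan.

    Threshold is the (1 - fraction) quantile (linear interpolation) of the
    defined estimates; every record with fst >= threshold is flagged (ties
    included). Returns (threshold, records with a ``top_flag`` column).
    """
    if not (0 < fraction < 1):
        raise PavError("fraction must be in (0, 1)")
    defined = records["fst"].to_numpy(dtype=float)
    defined = defined[np.isfinite(defined)]
    if defined.size == 0:
        raise PavError("no defined F_ST value")
    threshold = float(np.quantile(defined, 1 - fraction, method="linear"))
    out = records.copy()
    with np.errstate(invalid="ignore"):
        out["top_flag"] = np.isfinite(records["fst"]) & (records["fst"] >= threshold)
    return threshold, out


def frequency_divergence(matrix: PAVMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Per-gene presence frequencies in each population and the signed shift.

    ``direction`` is +1 when presence is more frequent under selection,
    -1 when less frequent, 0 when unchanged.
    """
    n1, x1, n2, x2 = _pop_counts(matrix, sheet)
    with np.errstate(invalid="ignore"):
        p1 = np.divide(x1, n1, out=np.full(len(n1), np.nan), where=n1 > 0)
        p2 = np.divide(x2, n2, out=np.full(len(n2), np.nan), where=n2 > 0)
    delta = p2 - p1
    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "p_wild": p1,
            "p_selection": p2,
            "delta": delta,
            "direction": np.sign(np.nan_to_num(delta)).astype(int),
        }
    )
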