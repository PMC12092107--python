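"""Marker QC, kinship, GLM/MLM/Fisher association and diagnostics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pavpan import (
    PAVMatrix,
    PavError,
    filter_markers,
    fisher_assoc,
    glm_assoc,
    kinship,
    manhattan_table,
    marker_qc,
    mlm_assoc,
    qq_summary,
    significance,
)

from conftest import random_matrix


def matrix_from_calls(calls, rng=None):
    calls = np.asarray(calls, dtype=np.int8)
    g, s = calls.shape
    m = random_matrix(rng or np.random.default_rng(0), g, s)
    m.calls = calls
    return PAVMatrix(m.gene_ids, m.sample_ids, calls, m.gene_meta)


# ---------------------------------------------------------------------------
# marker filter: strict inequalities
# ---------------------------------------------------------------------------


def test_maf_exactly_005_removed():
    """MAF must be strictly above 0.05: a 1-in-20 presence marker is dropped."""
    calls = np.zeros((1, 20), dtype=np.int8)
    calls[0, 0] = 1  # p = 0.05
    m = matrix_from_calls(calls)
    filtered, qc = filter_markers(m, maf_min=0.05)
    assert qc.loc[0, "maf"] == pytest.approx(0.05)
    assert not qc.loc[0, "pass_flag"] and filtered.n_genes == 0


def test_missing_exactly_15pct_removed():
    """Missing rate must be strictly below 0.15."""
    calls = np.ones((1, 20), dtype=np.int8)
    calls[0, :10] = 0
    calls[0, :3] = -1  # 3/20 = 0.15 missing
    m = matrix_from_calls(calls)
    filtered, qc = filter_markers(m)
    assert qc.loc[0, "missing_rate"] == pytest.approx(0.15)
    assert filtered.n_genes == 0
    calls[0, 0] = 0  # 2/20 = 0.10 missing, maf stays > 0.05
    filtered, qc = filter_markers(matrix_from_calls(calls))
    assert filtered.n_genes == 1


def test_monomorphic_removed_and_maf_over_nonmissing(rng):
    calls = np.ones((2, 10), dtype=np.int8)
    calls[1, :5] = -1
    calls[1, 5] = 0  # maf over non-missing = 1/5 = 0.2, missing 0.5
    m = matrix_from_calls(calls)
    qc = marker_qc(m)
    assert qc.loc[0, "maf"] == 0
    assert qc.loc[1, "maf"] == pytest.approx(0.2)
    filtered, _ = filter_markers(m)
    assert filtered.n_genes == 0  # first monomorphic, second too missing


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


def kinship_oracle(calls):
    """Direct double-sum VanRaden implementation on imputed 0/1 calls."""
    X = calls.astype(float)
    X[calls == -1] = np.nan
    G, S = X.shape
    p = np.nanmean(X, axis=1)
    for i in range(G):
        X[i, np.isnan(X[i])] = p[i]
    denom = np.sum(p * (1 - p))
    K = np.zeros((S, S))
    for a in range(S):
        for b in range(S):
            K[a, b] = sum((X[g, a] - p[g]) * (X[g, b] - p[g]) for g in range(G)) / denom
    return K


def test_kinship_matches_double_sum_oracle(rng):
    m = random_matrix(rng, 200, 20, missing_rate=0.05)
    K, ids = kinship(m)
    oracle = kinship_oracle(m.calls)
    # PSD flooring may perturb at 1e-10 scale only
    np.testing.assert_allclose(K, oracle, atol=1e-8)
    assert ids == m.sample_ids
    evals = np.linalg.eigvalsh(K)
    assert evals.min() >= -1e-8


def test_kinship_duplicate_samples_maximal(rng):
    m = random_matrix(rng, 100, 6)
    m.calls[:, 3] = m.calls[:, 0]
    K, _ = kinship(PAVMatrix(m.gene_ids, m.sample_ids, m.calls, m.gene_meta))
    off = K - np.diag(np.diag(K))
    assert off[0, 3] == pytest.approx(off.max())


def test_kinship_permutation_equivariance(rng):
    m = random_matrix(rng, 80, 8)
    K, _ = kinship(m)
    perm = rng.permutation(8)
    m2 = m.subset_samples([m.sample_ids[j] for j in perm])
    K2, _ = kinship(m2)
    np.testing.assert_allclose(K2, K[np.ix_(perm, perm)], atol=1e-10)


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------


def test_glm_marker_identical_to_phenotype(rng):
    m = random_matrix(rng, 5, 40)
    y = m.calls[0].astype(float)
    rec = glm_assoc(m, y)
    assert rec.loc[0, "p"] < 1e-10
    # Fisher oracle agrees on direction
    fis = fisher_assoc(m, y)
    assert fis.loc[0, "p"] < 1e-6
    assert np.sign(fis.loc[0, "effect"]) == np.sign(rec.loc[0, "effect"]) == 1


def test_glm_matches_statsmodels(rng):
    """Vectorized marker regression equals a per-marker OLS fit."""
    import statsmodels.api as sm

    m = random_matrix(rng, 20, 50)
    y = rng.normal(size=50)
    covars = rng.normal(size=(50, 2))
    rec = glm_assoc(m, y, covars)
    for i in range(20):
        X = sm.add_constant(np.column_stack([covars, m.calls[i].astype(float)]))
        fit = sm.OLS(y, X).fit()
        assert rec.loc[i, "effect"] == pytest.approx(fit.params[-1], abs=1e-10)
        assert rec.loc[i, "se"] == pytest.approx(fit.bse[-1], abs=1e-10)
        assert rec.loc[i, "p"] == pytest.approx(fit.pvalues[-1], abs=1e-10)


def test_glm_null_p_uniform(rng):
    """5000 independent null markers give uniform p (KS below alpha=0.001 cut)."""
    n = 268
    y = (np.arange(n) < 91).astype(float)
    freqs = rng.beta(2, 2, size=5000)
    calls = (rng.random((5000, n)) < freqs[:, None]).astype(np.int8)
    m = matrix_from_calls(calls, rng)
    rec = glm_assoc(m, y)
    ks = stats.kstest(rec["p"].dropna(), "uniform").statistic
    crit = stats.ksone.isf(0.001 / 2, 5000)  # two-sided alpha = 0.001
    assert ks < crit


def test_glm_zero_variance_marker_flagged(rng):
    m = random_matrix(rng, 3, 20)
    m.calls[1, :] = 1
    rec = glm_assoc(m, np.arange(20.0))
    assert np.isnan(rec.loc[1, "p"]) and np.isnan(rec.loc[1, "effect"])


def test_glm_constant_phenotype_errors(rng):
    with pytest.raises(PavError):
        glm_assoc(random_matrix(rng, 3, 10), np.ones(10))


def test_glm_ranks_like_fisher(rng):
    """On binary marker/phenotype data, GLM and Fisher give the same ranking."""
    n = 60
    y = rng.integers(0, 2, n).astype(float)
    rhos = []
    for _ in range(20):
        freqs = rng.beta(2, 2, size=50)
        calls = (rng.random((50, n)) < freqs[:, None]).astype(np.int8)
        m = matrix_from_calls(calls, rng)
        g = glm_assoc(m, y)["p"].to_numpy()
        f = fisher_assoc(m, y)["p"].to_numpy()
        ok = np.isfinite(g)  # monomorphic markers have no GLM p
        rhos.append(stats.spearmanr(g[ok], f[ok]).statistic)
    assert np.mean(rhos) > 0.95


# ---------------------------------------------------------------------------
# MLM
# ---------------------------------------------------------------------------


def test_mlm_identity_kinship_collapses_to_glm(rng):
    m = random_matrix(rng, 50, 40)
    y = rng.normal(size=40)
    covars = rng.normal(size=(40, 2))
    g = glm_assoc(m, y, covars)
    ml = mlm_assoc(m, y, covars, np.eye(40))
    ok = g["p"].notna()
    np.testing.assert_allclose(ml.loc[ok, "p"], g.loc[ok, "p"], atol=1e-8)
    np.testing.assert_allclose(ml.loc[ok, "effect"], g.loc[ok, "effect"], atol=1e-8)


def test_mlm_nonconformable_or_nonpsd_errors(rng):
    m = random_matrix(rng, 5, 10)
    y = rng.normal(size=10)
    with pytest.raises(PavError, match="conformable"):
        mlm_assoc(m, y, None, np.eye(7))
    bad = -np.eye(10)
    with pytest.raises(PavError, match="positive semidefinite"):
        mlm_assoc(m, y, None, bad)


def block_null(rng, n_blocks=4, per_block=25, m=2000, h2=0.5):
    """Markers and phenotype sharing block (family) structure, no causal marker."""
    n = n_blocks * per_block
    block = np.repeat(np.arange(n_blocks), per_block)
    K = (block[:, None] == block[None, :]).astype(float) * 0.9 + 0.1 * np.eye(n)
    pf = rng.beta(2, 2, (m, n_blocks)) * 0.8 + 0.1
    X = (rng.random((m, n)) < pf[:, block]).astype(np.int8)
    u = rng.normal(0, 1, n_blocks)[block] * np.sqrt(0.9)
    y = np.sqrt(h2) * u + rng.normal(0, np.sqrt(1 - h2), n)
    return matrix_from_calls(X, rng), y, K


def test_mlm_structured_null_calibrated(rng):
    """Type-I error at nominal 0.05 within [0.03, 0.07]; lambda_gc closer to 1
    than GLM under family structure."""
    rej_m, rej_g, lam_m, lam_g = [], [], [], []
    for _ in range(10):
        mat, y, K = block_null(rng)
        recm = mlm_assoc(mat, y, None, K)
        recg = glm_assoc(mat, y, None)
        rej_m.append(np.nanmean(recm["p"] < 0.05))
        rej_g.append(np.nanmean(recg["p"] < 0.05))
        lam_m.append(qq_summary(recm).lambda_gc)
        lam_g.append(qq_summary(recg).lambda_gc)
    assert 0.03 <= np.mean(rej_m) <= 0.07
    assert abs(np.mean(lam_m) - 1) < abs(np.mean(lam_g) - 1)


def test_mlm_reml_recovers_variance_ratio(rng):
    """REML delta estimate tracks the generating noise/genetic variance ratio."""
    n = 150
    A = rng.normal(size=(n, 300)) / np.sqrt(300)
    K = A @ A.T
    lam, U = np.linalg.eigh(K)
    sg2, se2 = 2.0, 1.0  # true delta = 0.5
    deltas = []
    for _ in range(20):
        u = U @ (rng.normal(size=n) * np.sqrt(np.clip(lam, 0, None) * sg2))
        y = 1.0 + u + rng.normal(0, np.sqrt(se2), n)
        from pavpan.association import estimate_delta_reml

        yt = U.T @ y
        Wt = U.T @ np.ones((n, 1))
        deltas.append(estimate_delta_reml(np.clip(lam, 0, None), yt, Wt))
    mean = np.mean(deltas)
    se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
    assert abs(mean - 0.5) <= 3 * max(se, 0.02)


def test_mlm_power_on_selection_shift():
    """A marker shifting 0.60 -> 0.26 between 91 wild and 177 selection
    accessions is detected beyond the -log10(p) >= 5 line in the median."""
    rng = np.random.default_rng(77)
    n1, n2 = 91, 177
    n = n1 + n2
    y = np.r_[np.zeros(n1), np.ones(n2)]
    # fixed background for kinship (P3D: delta estimated once on the null)
    bg = (np.random.default_rng(3).random((500, n)) < 0.5).astype(np.int8)
    K, _ = kinship(matrix_from_calls(bg, rng))
    reps = 200
    p_causal = np.r_[np.full(n1, 0.60), np.full(n2, 0.26)]
    causal = (rng.random((reps, n)) < p_causal[None, :]).astype(np.int8)
    rec = mlm_assoc(matrix_from_calls(causal, rng), y, None, K)
    med = np.nanmedian(rec["p"])
    assert -np.log10(med) >= 5


# ---------------------------------------------------------------------------
# Fisher
# ---------------------------------------------------------------------------


def test_fisher_extreme_table_enumeration_oracle():
    """(10,0 / 0,10): two-sided p equals the exhaustive hypergeometric sum."""
    calls = np.r_[np.ones(10), np.zeros(10)].astype(np.int8).reshape(1, -1)
    y = np.r_[np.ones(10), np.zeros(10)]
    rec = fisher_assoc(matrix_from_calls(calls), y)
    # enumeration over all tables with the same margins
    from math import comb

    total = comb(20, 10)
    p_obs = comb(10, 10) * comb(10, 0) / total
    p_two = sum(
        comb(10, k) * comb(10, 10 - k) / total
        for k in range(11)
        if comb(10, k) * comb(10, 10 - k) / total <= p_obs + 1e-15
    )
    assert rec.loc[0, "p"] == pytest.approx(p_two, rel=1e-10)
    assert rec.loc[0, "p"] == pytest.approx(2 / comb(20, 10), rel=1e-10)
    assert rec.loc[0, "effect"] > 0  # Haldane-corrected log OR


def test_fisher_independent_balanced_table(rng):
    calls = np.tile(np.array([1, 1, 0, 0], dtype=np.int8), (1, 10))
    y = np.tile([1, 0, 1, 0], 10).astype(float)
    rec = fisher_assoc(matrix_from_calls(calls), y)
    assert rec.loc[0, "p"] == pytest.approx(1.0)


def test_fisher_symmetry(rng):
    m = random_matrix(rng, 30, 24)
    y = rng.integers(0, 2, 24).astype(float)
    a = fisher_assoc(m, y)["p"]
    b = fisher_assoc(m, 1 - y)["p"]
    np.testing.assert_allclose(a, b, atol=1e-12)


# ---------------------------------------------------------------------------
# significance + QQ + manhattan
# ---------------------------------------------------------------------------


def test_significance_flags():
    rec = pd.DataFrame({"p": [1e-6, 1e-4], "neglog10p": [6.0, 4.0]})
    out = significance(rec, n_markers=1000)
    assert out.loc[0, "significant_fixed"] and out.loc[0, "significant_bonferroni"]
    assert not out.loc[1, "significant_fixed"] and not out.loc[1, "significant_bonferroni"]


def test_significance_monotone_in_p(rng):
    p = np.sort(rng.random(100)) * 1e-3
    rec = pd.DataFrame({"p": p, "neglog10p": -np.log10(p)})
    out = significance(rec, n_markers=100)
    for col in ("significant_bonferroni", "significant_fixed"):
        flags = out[col].to_numpy()
        assert (flags[:-1] >= flags[1:]).all()  # once false, stays false


def test_qq_summary_formula_and_null_lambda(rng):
    rec = pd.DataFrame({"p": [0.5]})
    qq = qq_summary(rec)
    assert qq.expected[0] == pytest.approx(-np.log10((1 - 0.5) / 1))
    null = pd.DataFrame({"p": rng.random(10_000)})
    lam = qq_summary(null).lambda_gc
    assert 0.95 <= lam <= 1.05
    # ordering invariance
    shuffled = null.sample(frac=1, random_state=1)
    assert qq_summary(shuffled).lambda_gc == pytest.approx(lam)


def test_manhattan_table_sorted_with_novel_trailing(rng):
    m = random_matrix(rng, 30, 10)
    rec = significance(glm_assoc(m, rng.normal(size=10)), n_markers=30)
    tab = manhattan_table(rec, m.gene_meta)
    assert len(tab) == 30
    novel_pos = np.flatnonzero((tab["chrom"] == "novel").to_numpy())
    if novel_pos.size:
        assert novel_pos.min() == len(tab) - novel_pos.size  # all trailing
    for chrom, sub in tab[tab["chrom"] != "novel"].groupby("chrom"):
        assert sub["pos"].is_monotonic_increasing
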