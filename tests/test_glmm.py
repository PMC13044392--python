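"""Unit tests for the NB2 fits, Wald tests, BH and fold-change summaries.

Oracles here are independent reimplementations: statsmodels' discrete
NegativeBinomial for the fixed-effect fit and a from-scratch step-up
procedure for BH.
"""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from reactionome import glmm, synthetic


def _design_and_gene(seed=21, family_sd=0.0):
    design = synthetic.generate_design(seed=seed)
    truth = synthetic.GeneTruth("g", "T_and_P", beta0=4.5, betaT=1.2,
                                betaP=-0.8, betaS=0.3, betaTP=0.5,
                                dispersion=0.15, family_sd=family_sd)
    ds = synthetic.generate_counts(design, [truth], seed=seed)
    return design, ds


def test_fixed_nb_glm_matches_statsmodels():
    design, ds = _design_and_gene()
    y = ds.counts.loc["g"]
    sf = pd.Series(ds.size_factors_true, index=ds.counts.columns)
    fit = glmm.fit_nb_glm(y, design, sf)
    assert fit.converged
    codes = synthetic.design_codes(design)
    X = np.column_stack([np.ones(96), codes["xT"], codes["xP"],
                         codes["xS"], codes["xTP"]])
    sm_fit = sm.NegativeBinomial(y.to_numpy(), X, offset=np.log(sf.to_numpy()),
                                 loglike_method="nb2").fit(disp=0, maxiter=200)
    assert np.max(np.abs(fit.beta - sm_fit.params[:5])) < 1e-3
    # statsmodels' trailing parameter is the same NB2 dispersion alpha
    assert abs(fit.dispersion - sm_fit.params[5]) < 1e-2


def test_glmm_recovers_truth_within_wald_error():
    design, ds = _design_and_gene(seed=22, family_sd=0.3)
    sf = pd.Series(ds.size_factors_true, index=ds.counts.columns)
    fit = glmm.fit_gene(ds.counts.loc["g"], design, sf)
    assert fit.converged
    truth = np.array([4.5, 1.2, -0.8, 0.3, 0.5])
    z = np.abs(fit.beta - truth) / fit.se
    assert (z < 4.0).all()
    assert fit.sigma2_u > 0


def test_glmm_falls_back_when_no_family_variance():
    design, ds = _design_and_gene(seed=23, family_sd=0.0)
    sf = pd.Series(ds.size_factors_true, index=ds.counts.columns)
    fit = glmm.fit_gene(ds.counts.loc["g"], design, sf)
    assert fit.converged
    assert fit.sigma2_u == 0.0


def test_wald_pvalues_in_unit_interval():
    design, ds = _design_and_gene(seed=24)
    sf = pd.Series(ds.size_factors_true, index=ds.counts.columns)
    fit = glmm.fit_nb_glm(ds.counts.loc["g"], design, sf)
    p = glmm.wald_tests(fit)
    assert set(p) == set(glmm.TERMS)
    for v in p.values():
        assert 0.0 <= v <= 1.0


def _bh_step_up_oracle(p):
    """Plain step-up BH: sort, scale by m/rank, backward cumulative min."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        scaled[i] = min(scaled[i], scaled[i + 1])
    q = np.empty(m)
    q[order] = np.minimum(scaled, 1.0)
    return q


def test_bh_matches_step_up_oracle():
    rng = np.random.default_rng(9)
    p = np.concatenate([rng.uniform(size=500), [0.0, 1.0, 0.5, 0.5]])
    assert np.max(np.abs(glmm.bh_adjust(p) - _bh_step_up_oracle(p))) < 1e-15


def test_bh_properties():
    rng = np.random.default_rng(10)
    p = rng.uniform(size=100)
    q = glmm.bh_adjust(p)
    assert (q >= p - 1e-15).all() and (q <= 1.0).all()
    # permutation equivariance
    perm = rng.permutation(100)
    assert np.allclose(glmm.bh_adjust(p[perm]), q[perm])
    with pytest.raises(ValueError):
        glmm.bh_adjust([0.5, 1.5])


def test_predict_cell_means_identity_case():
    """All effects zero: every design cell predicts exp(beta0) counts."""
    beta = np.array([np.log(10.0), 0, 0, 0, 0])
    fit = glmm.GeneFit("g", beta, np.ones(5), np.eye(5), 0.1, 0.0, True, 0.0, 96)
    grid = glmm.predict_cell_means(fit)
    assert len(grid) == 8
    assert np.allclose(grid["mu"], 10.0)


def _grid_from_cells(cells):
    rows = []
    for (pop, temp), mu in cells.items():
        for sex in ("female", "male"):
            rows.append({"population": pop, "temperature": temp,
                         "sex": sex, "mu": mu})
    return pd.DataFrame(rows)


def test_lfc_uniform_doubling():
    grid = _grid_from_cells({("Finland", 25): 10, ("Finland", 34): 20,
                             ("Spain", 25): 6, ("Spain", 34): 12})
    lfc = glmm.compute_lfcs(grid)
    assert np.isclose(lfc["lfc_T"], 1.0, atol=1e-12)
    assert np.isclose(lfc["lfc_TP"], 0.0, atol=1e-12)


def test_lfc_opposite_population_responses():
    grid = _grid_from_cells({("Finland", 25): 4, ("Finland", 34): 2,
                             ("Spain", 25): 2, ("Spain", 34): 4})
    lfc = glmm.compute_lfcs(grid)
    assert np.isclose(lfc["lfc_TP"], 2.0, atol=1e-12)
    assert np.isclose(lfc["lfc_T"], 0.0, atol=1e-12)
    assert np.isclose(lfc["lfc_P"], 0.0, atol=1e-12)


def test_fit_all_genes_q_and_sig_invariants(small_dataset):
    ds = small_dataset
    sf = pd.Series(ds.size_factors_true, index=ds.counts.columns)
    de = glmm.fit_all_genes(ds.counts, ds.metadata, sf, random_effect=False)
    t = de.table
    assert len(t) == 26
    for term in ("T", "P", "TP", "S"):
        ok = t[f"p_{term}"].notna()
        assert (t.loc[ok, f"q_{term}"] >= t.loc[ok, f"p_{term}"] - 1e-12).all()
    # significance flags require q < cutoff, and (except sex) |lfc| > cutoff
    for term in ("T", "P", "TP"):
        flagged = t[t[f"sig_{term}"]]
        assert (flagged[f"q_{term}"] < 0.05).all()
        assert (flagged[f"lfc_{term}"].abs() > 1.0).all()
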