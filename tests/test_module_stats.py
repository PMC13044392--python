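"""Unit tests for the bimodality index and quantile-regression inference."""

import numpy as np
import pandas as pd
import pytest

from reactionome import module_stats as ms

from conftest import balanced_meta


def _series(x):
    return pd.Series(np.asarray(x, dtype=float))


def test_bi_closed_form_balanced_mixture():
    """BI of a huge balanced mixture approaches delta * sqrt(pi (1-pi))."""
    rng = np.random.default_rng(31)
    n = 4000
    meta = balanced_meta(n)
    for delta in (2.0, 3.0):
        comp = rng.random(n) < 0.5
        x = np.where(comp, delta / 2.0, -delta / 2.0) + rng.normal(size=n)
        res = ms.bimodality_index(_series(x), meta, seed=1)
        expected = delta * 0.5
        assert abs(res.bi - expected) / expected < 0.05
        assert res.is_bimodal


def test_bi_location_scale_invariance():
    rng = np.random.default_rng(32)
    n = 96
    meta = balanced_meta(n)
    comp = rng.random(n) < 0.5
    x = np.where(comp, 1.5, -1.5) + rng.normal(size=n)
    a = ms.bimodality_index(_series(x), meta, seed=3)
    b = ms.bimodality_index(_series(5.0 * x + 2.0), meta, seed=3)
    # residuals scale by 5; mu and sigma scale together, BI is invariant
    assert abs(a.bi - b.bi) < 1e-6
    assert abs(a.delta - b.delta) < 1e-6


def test_bi_removes_design_main_effects():
    """A pure temperature shift is not bimodality of the residuals."""
    n = 96
    meta = balanced_meta(n)
    rng = np.random.default_rng(33)
    x = np.where(meta["temperature"] == 34, 3.0, -3.0) + 0.5 * rng.normal(size=n)
    res = ms.bimodality_index(_series(x), meta, seed=0)
    assert not res.is_bimodal


def test_bi_requires_enough_samples():
    meta = balanced_meta(10)
    with pytest.raises(ValueError):
        ms.bimodality_index(_series(np.arange(10.0)), meta)


def _quantile_setup(n=96, seed=40, beta=(0.5, 1.0, -0.7, 0.2, 0.9)):
    from reactionome.synthetic import design_codes, generate_design
    meta = generate_design(seed=seed)
    codes = design_codes(meta)
    X = np.column_stack([np.ones(n), codes["xT"], codes["xP"],
                         codes["xS"], codes["xTP"]])
    rng = np.random.default_rng(seed)
    y = X @ np.asarray(beta) + rng.normal(0.0, 0.5, size=n)
    return meta, _series(y), np.asarray(beta)


def test_quantile_fit_recovers_median_coefficients():
    meta, y, beta = _quantile_setup()
    fit = ms.quantile_fit(y, meta, tau=0.5, n_boot=200, seed=2)
    assert list(fit.coef.index) == list(ms.COEF_NAMES)
    z = np.abs(fit.coef.to_numpy() - beta) / fit.boot_se.to_numpy()
    assert (z < 4.0).all()
    assert (fit.boot_p.to_numpy() <= 1.0).all()


def test_quantile_translation_equivariance():
    """Adding c to Spain samples moves intercept by c/2 and population by c."""
    meta, y, _ = _quantile_setup(seed=41)
    shift = 0.9
    y2 = y + np.where(meta["population"] == "Spain", shift, 0.0)
    f1 = ms.quantile_fit(y, meta, tau=0.5, n_boot=100, seed=5)
    f2 = ms.quantile_fit(y2, meta, tau=0.5, n_boot=100, seed=5)
    delta = (f2.coef - f1.coef).to_numpy()
    expected = np.array([shift / 2.0, 0.0, shift, 0.0, 0.0])
    assert np.max(np.abs(delta - expected)) < 1e-6


def test_quantile_fit_validation_and_determinism():
    meta, y, _ = _quantile_setup(seed=42)
    with pytest.raises(ValueError):
        ms.quantile_fit(y, meta, tau=1.5)
    with pytest.raises(ValueError):
        ms.quantile_fit(y, meta, n_boot=10)
    one_pop = meta.copy()
    one_pop["population"] = "Finland"
    with pytest.raises(ValueError):
        ms.quantile_fit(y, one_pop)
    a = ms.quantile_fit(y, meta, n_boot=100, seed=8)
    b = ms.quantile_fit(y, meta, n_boot=100, seed=8)
    assert np.allclose(a.boot_se, b.boot_se)


def _fake_qfit(beta, spread=0.01, n_boot=200, seed=50):
    rng = np.random.default_rng(seed)
    boot = np.asarray(beta) + spread * rng.normal(size=(n_boot, 5))
    se = boot.std(axis=0, ddof=1)
    below = (boot <= 0).sum(axis=0)
    above = (boot >= 0).sum(axis=0)
    p = np.minimum(1.0, 2.0 * (np.minimum(below, above) + 1.0) / (n_boot + 1.0))
    return ms.QuantileFit(0.5, pd.Series(beta, index=ms.COEF_NAMES),
                          pd.Series(se, index=ms.COEF_NAMES),
                          pd.Series(p, index=ms.COEF_NAMES), n_boot, boot)


def test_module_posthoc_labels_and_gates():
    # assimilation pattern on the eigengene scale
    assim = _fake_qfit([0.0, 1.0, 1.0, 0.0, -2.0])
    assert ms.module_posthoc(assim, bimodal=False) == "assimilation"
    assert ms.module_posthoc(assim, bimodal=True) == "not_tested"
    comp = _fake_qfit([0.0, 1.0, -1.0, 0.0, -2.0])
    assert ms.module_posthoc(comp, bimodal=False) == "compensation"
    parallel = _fake_qfit([0.0, 1.0, 1.0, 0.0, 0.0])
    assert ms.module_posthoc(parallel, bimodal=False) == "neither"
    no_main = _fake_qfit([0.0, 0.0, 0.0, 0.0, 0.0], spread=1.0)
    assert ms.module_posthoc(no_main, bimodal=False) == "not_tested"


def test_analyse_modules_table():
    from reactionome import network as net
    from reactionome.synthetic import design_codes, generate_design
    meta = generate_design(seed=60)
    codes = design_codes(meta)
    rng = np.random.default_rng(60)
    factor = codes["xT"].to_numpy() * 2.0 + rng.normal(0, 0.3, 96)
    vals = np.outer(np.ones(55), factor) + 0.4 * rng.normal(size=(55, 96))
    logm = pd.DataFrame(vals, index=[f"g{i}" for i in range(55)],
                        columns=meta["sample_id"])
    mod = net.compute_eigengene(logm, "M1")
    tab = ms.analyse_modules([mod], meta, n_boot=100, seed=1)
    assert len(tab) == 1
    row = tab.iloc[0]
    assert row["n_genes"] == 55
    assert {"bimodality_index", "is_bimodal", "plasticity_label",
            "coef_temperature_q0.5"} <= set(tab.columns)
    # the planted temperature effect is picked up at the median
    assert row["p_temperature_q0.5"] < 0.05
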