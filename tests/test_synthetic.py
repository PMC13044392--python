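"""Unit tests for the synthetic data generator."""

import numpy as np
import pandas as pd
import pytest

from reactionome import synthetic as syn


def test_default_design_composition(meta96):
    assert len(meta96) == 96
    assert meta96["sample_id"].is_unique
    assert set(meta96["population"]) == {"Finland", "Spain"}
    assert meta96["population"].value_counts().tolist() == [48, 48]
    # 4 families per population, 12 individuals each
    fam_sizes = meta96.groupby("family").size()
    assert len(fam_sizes) == 8 and (fam_sizes == 12).all()
    # each family is split 6/6 across the two temperatures
    cell = meta96.groupby(["family", "temperature"]).size()
    assert (cell == 6).all()
    assert set(meta96["temperature"]) == {25, 34}


def test_design_layout_deterministic_only_sex_stochastic():
    a = syn.generate_design(seed=1)
    b = syn.generate_design(seed=2)
    fixed = [c for c in a.columns if c != "sex"]
    pd.testing.assert_frame_equal(a[fixed], b[fixed])
    pd.testing.assert_frame_equal(a, syn.generate_design(seed=1))


def test_invalid_design_rejected():
    with pytest.raises(syn.InvalidDesignError):
        syn.generate_design(syn.DesignSpec(families_per_population=0))
    with pytest.raises(syn.InvalidDesignError):
        syn.generate_design(syn.DesignSpec(sex_ratio=1.5))
    with pytest.raises(syn.InvalidDesignError):
        syn.generate_design(syn.DesignSpec(temperatures=(25,)))


def test_design_codes_sum_to_zero(meta96):
    codes = syn.design_codes(meta96)
    assert set(np.unique(codes[["xT", "xP", "xS"]])) == {-0.5, 0.5}
    assert codes["xT"].sum() == 0
    assert codes["xP"].sum() == 0
    assert np.allclose(codes["xTP"], codes["xT"] * codes["xP"])


def test_generate_counts_shape_dtype_determinism(small_dataset):
    ds = small_dataset
    assert ds.counts.shape == (26, 96)
    assert (ds.counts.to_numpy() >= 0).all()
    assert np.issubdtype(ds.counts.to_numpy().dtype, np.integer)
    design = syn.generate_design(seed=11)
    again = syn.generate_counts(design, ds.truth, seed=11)
    pd.testing.assert_frame_equal(ds.counts, again.counts)
    other = syn.generate_counts(design, ds.truth, seed=12)
    assert not ds.counts.equals(other.counts)


def test_true_size_factors_geometric_mean_one(small_dataset):
    s = small_dataset.size_factors_true
    assert np.isclose(np.log(s).mean(), 0.0, atol=1e-12)


def test_temperature_effect_direction():
    """A strong temperature-only gene shows the generated fold change."""
    design = syn.generate_design(seed=3)
    up = syn.GeneTruth("g_up", "T_only_up", beta0=5.0, betaT=2.0,
                       family_sd=0.0, dispersion=0.05)
    flat = syn.GeneTruth("g_flat", "null", beta0=5.0, family_sd=0.0,
                         dispersion=0.05)
    ds = syn.generate_counts(design, [up, flat], size_factor_sd=0.0, seed=3)
    hot = design["temperature"] == 34
    lr = np.log(ds.counts.loc["g_up", hot.values].mean()
                / ds.counts.loc["g_up", (~hot).values].mean())
    assert abs(lr - 2.0) < 0.15
    lr_flat = np.log(ds.counts.loc["g_flat", hot.values].mean()
                     / ds.counts.loc["g_flat", (~hot).values].mean())
    assert abs(lr_flat) < 0.15


def test_parameter_validation():
    design = syn.generate_design(seed=0)
    bad = syn.GeneTruth("g", "null", beta0=3.0, dispersion=0.0)
    with pytest.raises(syn.InvalidParameterError):
        syn.generate_counts(design, [bad], seed=0)
    dup = [syn.GeneTruth("g", "null", 3.0), syn.GeneTruth("g", "null", 3.0)]
    with pytest.raises(syn.InvalidParameterError):
        syn.generate_counts(design, dup, seed=0)
    with pytest.raises(syn.InvalidParameterError):
        syn.generate_counts(design, [], seed=0)


def test_truth_panel_category_balance():
    truths = syn.default_truth_panel(n_genes_per_category=4, seed=1)
    tab = syn.truth_table(truths)
    counts = tab["category"].value_counts()
    assert set(counts.index) == set(syn.CATEGORIES)
    assert (counts == 4).all()
    # null genes carry no design effects
    nulls = tab[tab["category"] == "null"]
    assert (nulls[["betaT", "betaP", "betaS", "betaTP"]] == 0).all().all()


def test_bimodal_switch_creates_two_modes_at_hot():
    design = syn.generate_design(seed=5)
    genes = tuple(f"m{i}" for i in range(40))
    truths = [syn.GeneTruth(g, "null", beta0=5.0, family_sd=0.0,
                            dispersion=0.05) for g in genes]
    mod = syn.ModuleTruth("M1", genes, factor_loading_sd=0.8,
                          bimodal_switch=True, switch_shift=4.0,
                          mixed_signs=False)
    ds = syn.generate_counts(design, truths, [mod], size_factor_sd=0.0, seed=5)
    logc = np.log1p(ds.counts)
    score = logc.mean(axis=0)          # module average tracks the factor
    hot = (design["temperature"] == 34).to_numpy()
    # at 34C the factor is +-shift/2: spread across samples far exceeds 25C
    assert score[hot].std() > 2.0 * score[~hot].std()
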