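"""Unit tests for the signed co-expression network machinery.

The TOM oracle is a literal triple loop over the textbook definition,
independent of the vectorized implementation.
"""

import numpy as np
import pandas as pd
import pytest

from reactionome import network as net


def _random_logm(n_genes=50, n_samples=30, seed=4):
    rng = np.random.default_rng(seed)
    vals = rng.normal(size=(n_genes, n_samples))
    return pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)],
                        columns=[f"s{j}" for j in range(n_samples)])


def test_signed_adjacency_basic_properties():
    logm = _random_logm()
    a = net.signed_adjacency(logm, power=6).to_numpy()
    assert a.shape == (50, 50)
    assert np.allclose(a, a.T)
    assert (a >= 0).all() and (a <= 1 + 1e-12).all()
    assert np.allclose(np.diag(a), 1.0)
    # perfectly anticorrelated genes get adjacency 0 in a signed network
    x = np.arange(10.0)
    two = pd.DataFrame([x, -x], index=["u", "v"])
    a2 = net.signed_adjacency(two, power=6)
    assert a2.loc["u", "v"] < 1e-12


def test_adjacency_shrinks_with_power():
    logm = _random_logm(seed=5)
    a2 = net.signed_adjacency(logm, power=2).to_numpy()
    a6 = net.signed_adjacency(logm, power=6).to_numpy()
    off = ~np.eye(50, dtype=bool)
    assert (a6[off] <= a2[off] + 1e-12).all()


def test_constant_gene_raises():
    logm = _random_logm()
    logm.iloc[3] = 7.0
    with pytest.raises(net.DegenerateCorrelationError):
        net.signed_adjacency(logm, power=6)
    cleaned = net.drop_zero_variance(logm)
    assert "g3" not in cleaned.index
    net.signed_adjacency(cleaned, power=6)   # no longer raises


def _tom_triple_loop(a):
    """Literal TOM formula with explicit loops (k excludes the unit diagonal)."""
    n = a.shape[0]
    k = a.sum(axis=1) - np.diag(a)
    w = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            w[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return w


def test_tom_matches_triple_loop_oracle():
    logm = _random_logm(n_genes=40, seed=6)
    adj = net.signed_adjacency(logm, power=4)
    got = net.topological_overlap(adj).to_numpy()
    want = _tom_triple_loop(adj.to_numpy())
    assert np.max(np.abs(got - want)) < 1e-10
    assert (got >= -1e-12).all() and (got <= 1 + 1e-12).all()


def test_connectivity_excludes_self():
    logm = _random_logm(seed=7)
    adj = net.signed_adjacency(logm, power=4)
    k = net.connectivity(adj)
    want = adj.to_numpy().sum(axis=1) - 1.0
    assert np.allclose(k.to_numpy(), want)


def test_scale_free_fit_on_exact_power_law():
    # connectivities whose binned log-frequency is exactly linear in log k
    centers = np.exp(np.linspace(np.log(2), np.log(200), 8))
    k = np.concatenate([np.full(max(int(round(5e4 * c ** -2.0)), 1), c)
                        for c in centers])
    assert net.scale_free_fit(k, n_bins=8) > 0.95


def test_pick_soft_threshold_self_consistent():
    rng = np.random.default_rng(8)
    # two planted blocks give the diagnostics something to qualify on
    f = rng.normal(size=(2, 40))
    load = np.repeat(np.eye(2), 30, axis=0)
    vals = load @ f + 0.5 * rng.normal(size=(60, 40))
    logm = pd.DataFrame(vals, index=[f"g{i}" for i in range(60)])
    power, diag = net.pick_soft_threshold(logm, candidate_powers=(1, 2, 3, 4, 6))
    assert set(diag.columns) >= {"power", "r2", "mean_connectivity",
                                 "selected", "selected_by_fallback"}
    sel = diag[diag["selected"]]
    assert len(sel) == 1 and int(sel["power"].iloc[0]) == power
    qualifying = diag[(diag["r2"] > 0.8) & (diag["mean_connectivity"] > 100.0)]
    if len(qualifying):
        assert power == int(qualifying["power"].min())
        assert not sel["selected_by_fallback"].iloc[0]
    else:
        assert power == int(diag.loc[diag["r2"].idxmax(), "power"])
        assert sel["selected_by_fallback"].iloc[0]
    with pytest.raises(ValueError):
        net.pick_soft_threshold(logm, candidate_powers=(1, 2))
    with pytest.raises(ValueError):
        net.pick_soft_threshold(logm.iloc[:20])


def _two_block_logm(n_per=60, n_samples=50, noise=0.3, seed=9):
    rng = np.random.default_rng(seed)
    f1, f2 = rng.normal(size=(2, n_samples))
    rows = [f1 + noise * rng.normal(size=n_samples) for _ in range(n_per)]
    rows += [f2 + noise * rng.normal(size=n_samples) for _ in range(n_per)]
    return pd.DataFrame(rows, index=[f"g{i}" for i in range(2 * n_per)])


def test_cut_modules_recovers_two_clean_blocks():
    logm = _two_block_logm()
    adj = net.signed_adjacency(logm, power=6)
    tom = net.topological_overlap(adj)
    labels = net.cut_modules(tom, net.NetworkConfig(min_module_size=50))
    assigned = labels[labels != "unassigned"]
    assert len(assigned) == 120
    a = set(labels.index[labels == labels["g0"]])
    b = set(labels.index[labels == labels["g119"]])
    assert a == {f"g{i}" for i in range(60)}
    assert b == {f"g{i}" for i in range(60, 120)}


def test_eigengene_orientation_and_scale():
    logm = _two_block_logm(n_per=30)
    mod = net.compute_eigengene(logm.iloc[:30], "M1")
    e = mod.eigengene.to_numpy()
    assert np.isclose(e.std(ddof=0), 1.0)
    mean_profile = logm.iloc[:30].sub(logm.iloc[:30].mean(axis=1), axis=0).mean(axis=0)
    assert np.corrcoef(e, mean_profile)[0, 1] > 0.9
    assert 0 < mod.variance_explained <= 1
    with pytest.raises(ValueError):
        net.compute_eigengene(logm.iloc[:0])


def test_merge_modules_joins_correlated_splits():
    logm = _two_block_logm(n_per=40, noise=0.2, seed=10)
    # split the first block artificially in two; keep the second separate
    m1a = net.compute_eigengene(logm.iloc[:20], "A")
    m1b = net.compute_eigengene(logm.iloc[20:40], "B")
    m2 = net.compute_eigengene(logm.iloc[40:80], "C")
    merged = net.merge_modules([m1a, m1b, m2], logm, threshold=0.75)
    assert len(merged) == 2
    sizes = sorted(len(m.genes) for m in merged)
    assert sizes == [40, 40]
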