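"""Self-contained benchmark instances and recovery metrics.

Each function builds a synthetic instance with known ground truth, runs
the relevant part of the analysis, and returns plain-number metrics.
The classifier and null-calibration benchmarks supply the generator's
TRUE size factors as offsets: they exercise the count-model inference and
the reaction-norm classifier, while the size-factor estimator is checked
separately against a brute-force oracle.  (A fully balanced benchmark
panel is impossible here: assimilation patterns must be
temperature-downregulated and compensation patterns upregulated for the
count-scale fold-change gate to be reachable, which leaves a one-sided
block of differential mass that median-of-ratios — like any
majority-null normalization — partially absorbs.  See docs/methods.md.)
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd
from scipy import stats

from . import classify, enrichment, glmm, module_stats, network, preprocess, synthetic


def namespaced_seed(base: int, label: str) -> int:
    """Deterministic per-benchmark seed derived from a master seed."""
    h = hashlib.sha256(f"{base}:{label}".encode()).hexdigest()
    return int(h, 16) % (2 ** 31)


# -------------------------------------------------------------------- design

def design_size() -> int:
    """Number of individuals produced by the default factorial design."""
    return len(synthetic.generate_design(synthetic.DesignSpec(), seed=0))


# --------------------------------------------------------------- classifier recovery

def classifier_benchmark(seed: int, n_per_category: int = 100,
                         effect_log2: float = 2.0, dispersion: float = 0.2,
                         family_sd: float = 0.3) -> dict:
    """Venn-category recovery and assimilation/compensation recall.

    Fits with the generator's true size factors as offsets (see module
    docstring).  Recall denominators are the full planted category sizes,
    so genes that never reach significance count as misses.
    """
    design = synthetic.generate_design(synthetic.DesignSpec(), seed=seed)
    truths = synthetic.default_truth_panel(
        n_genes_per_category=n_per_category, effect_log2=effect_log2,
        dispersion=dispersion, family_sd=family_sd, seed=seed)
    ds = synthetic.generate_counts(design, truths, seed=seed)
    counts = preprocess.filter_low_expression(ds.counts)
    de = glmm.fit_all_genes(counts, ds.metadata, ds.size_factors_true)
    calls = classify.classify_all(de)
    if "gene_id" in calls.columns:
        calls = calls.set_index("gene_id")
    truth = synthetic.truth_table(ds.truth).set_index("gene_id")
    merged = calls.join(truth["category"])
    expected = merged["category"].map(synthetic.EXPECTED_VENN)
    correct = (merged["venn_category"] == expected)
    label_of = {}
    for cat in ("assimilation", "compensation"):
        sub = merged[merged["category"] == cat]["plasticity_label"]
        label_of[cat] = sub.value_counts().to_dict()
    n_a = int((truth["category"] == "assimilation").sum())
    n_c = int((truth["category"] == "compensation").sum())
    return {
        "n_significant": int(len(merged)),
        "venn_recovery": float(correct.mean()) if len(merged) else 0.0,
        "assimilation_recall": label_of["assimilation"].get("assimilation", 0) / n_a,
        "compensation_recall": label_of["compensation"].get("compensation", 0) / n_c,
        "assim_called_comp": int(label_of["assimilation"].get("compensation", 0)),
        "comp_called_assim": int(label_of["compensation"].get("assimilation", 0)),
        "n_assimilation": n_a,
        "n_compensation": n_c,
    }


# --------------------------------------------------------------- null calibration

def null_calibration(seed: int, n_genes: int = 2000, dispersion: float = 0.2,
                     family_sd: float = 0.3) -> dict:
    """False-positive rate and p-value uniformity on an all-null panel."""
    rng = np.random.default_rng(seed)
    design = synthetic.generate_design(synthetic.DesignSpec(), seed=seed)
    truths = [synthetic.GeneTruth(gene_id=f"null_{i:05d}", category="null",
                                  beta0=float(rng.uniform(3.0, 6.0)),
                                  dispersion=dispersion, family_sd=family_sd)
              for i in range(n_genes)]
    ds = synthetic.generate_counts(design, truths, seed=seed)
    counts = preprocess.filter_low_expression(ds.counts)
    de = glmm.fit_all_genes(counts, ds.metadata, ds.size_factors_true)
    tab = de.table[de.table["converged"]]
    n = len(tab)
    frac = float((tab["q_T"] < 0.05).mean())
    bound = 0.05 + 3.0 * np.sqrt(0.05 * 0.95 / n)
    ks = stats.kstest(tab["p_T"].to_numpy(), "uniform")
    return {"n_genes": n, "frac_q_T_lt_05": frac, "bound": float(bound),
            "ks_stat": float(ks.statistic), "ks_pvalue": float(ks.pvalue)}


# --------------------------------------------------------------- fold-change identities

def lfc_formula_checks() -> dict:
    """Hand-constructed cell-mean grids with known exact fold changes."""
    def grid(cells: dict) -> pd.DataFrame:
        rows = []
        for (pop, temp), mu in cells.items():
            for sex in ("female", "male"):
                rows.append((pop, temp, sex, float(mu)))
        return pd.DataFrame(rows, columns=["population", "temperature", "sex", "mu"])

    # every 34C cell exactly double its 25C cell
    doubling = glmm.compute_lfcs(grid({("Finland", 25): 10, ("Finland", 34): 20,
                                       ("Spain", 25): 6, ("Spain", 34): 12}))
    # Spain doubles, Finland halves, population means balance across temperature
    opposite = glmm.compute_lfcs(grid({("Finland", 25): 4, ("Finland", 34): 2,
                                       ("Spain", 25): 2, ("Spain", 34): 4}))
    return {
        "doubling_lfc_T": doubling["lfc_T"],            # exactly 1
        "doubling_lfc_TP": doubling["lfc_TP"],          # exactly 0
        "opposite_lfc_TP": opposite["lfc_TP"],          # exactly 2
        "opposite_lfc_T": opposite["lfc_T"],            # exactly 0
    }


# --------------------------------------------------------------- module recovery

PLANTED_BLOCK_SIZES = (60, 120, 180, 240, 300)
PLANTED_NOISE_GENES = 600


def planted_module_dataset(seed: int, loading_sd: float = 0.6):
    """Five sign-coherent planted modules plus unstructured noise genes.

    Counts come from the full NB generator, so the log matrix carries the
    mean-variance and weak global structure of a real expression matrix —
    which is what gives a realistic connectivity distribution for the
    soft-threshold diagnostics.  Module factor loadings are half-normal,
    so each block contains a continuum from hub genes down to members
    whose loading is too small to carry recoverable signal (as in real
    modules).  family_sd is 0: a family intercept shared by EVERY gene is
    itself a global co-expression factor and would swamp the planted
    blocks the benchmark measures.
    """
    rng = np.random.default_rng(seed)
    design = synthetic.generate_design(synthetic.DesignSpec(), seed=seed)
    n_genes = sum(PLANTED_BLOCK_SIZES) + PLANTED_NOISE_GENES
    truths = [synthetic.GeneTruth(gene_id=f"g{i:05d}", category="null",
                                  beta0=float(rng.uniform(3.0, 6.0)),
                                  family_sd=0.0)
              for i in range(n_genes)]
    gene_ids = [t.gene_id for t in truths]
    modules, start, labels = [], 0, {}
    for m, size in enumerate(PLANTED_BLOCK_SIZES):
        members = tuple(gene_ids[start:start + size])
        modules.append(synthetic.ModuleTruth(
            module_id=f"true_{m}", member_genes=members,
            factor_loading_sd=loading_sd, mixed_signs=False))
        labels.update({g: f"true_{m}" for g in members})
        start += size
    labels.update({g: "noise" for g in gene_ids[start:]})
    ds = synthetic.generate_counts(design, truths, modules, seed=seed)
    return ds, pd.Series(labels, name="true_module")


def module_recovery(seed: int) -> dict:
    """End-to-end module detection on the planted benchmark.

    Returns labels for two adjusted-Rand comparisons: over the genes the
    detector assigned to modules (the standard module-recovery view —
    genes left unassigned are the network analogue of the grey module and
    include planted members whose half-normal loading is too small to be
    recoverable), and over all genes.
    """
    ds, true_labels = planted_module_dataset(seed)
    counts = preprocess.filter_low_expression(ds.counts)
    sf = preprocess.compute_size_factors(counts)
    logm = preprocess.moderated_log(counts, sf)
    cfg = network.NetworkConfig()
    modules, assignment, power, diag = network.detect_modules(logm.values, cfg)
    sel = diag[diag["selected"]].iloc[0]
    truth = true_labels.reindex(assignment.index)
    return {
        "n_genes": int(len(assignment)),
        "n_modules": len(modules),
        "assignment": assignment,
        "true_labels": truth,
        "power": int(power),
        "power_r2": float(sel["r2"]),
        "power_mean_connectivity": float(sel["mean_connectivity"]),
        "fallback": bool(sel["selected_by_fallback"]),
    }


# ---------------------------------------------------------------- bimodality

def _switch_module_bi(seed: int, bimodal: bool, n_genes: int = 60,
                      shift: float = 3.0) -> float:
    """BI of the eigengene of one simulated 60-gene module."""
    rng = np.random.default_rng(seed)
    design = synthetic.generate_design(synthetic.DesignSpec(), seed=seed)
    truths = [synthetic.GeneTruth(gene_id=f"g{i:04d}", category="null",
                                  beta0=float(rng.uniform(3.0, 6.0)))
              for i in range(n_genes)]
    mod = synthetic.ModuleTruth(
        module_id="m", member_genes=tuple(t.gene_id for t in truths),
        factor_loading_sd=0.6, bimodal_switch=bimodal,
        switch_shift=shift, mixed_signs=False)
    ds = synthetic.generate_counts(design, truths, [mod], seed=seed)
    counts = preprocess.filter_low_expression(ds.counts)
    sf = preprocess.compute_size_factors(counts)
    logm = preprocess.moderated_log(counts, sf)
    eig = network.compute_eigengene(logm.values, module_id="m")
    res = module_stats.bimodality_index(eig.eigengene, ds.metadata, seed=seed)
    return float(res.bi)


def _dummy_meta(n: int) -> pd.DataFrame:
    """Balanced factorial metadata of size n, independent of any response."""
    reps = -(-n // 8)
    return pd.DataFrame({
        "population": np.tile(np.repeat(["Finland", "Spain"], 4), reps)[:n],
        "temperature": np.tile(np.repeat([25, 34], 2), 2 * reps)[:n],
        "sex": np.tile(["female", "male"], 4 * reps)[:n],
        "family": np.arange(n) // 8,
    })


def _null_bi(seed: int, n: int = 95) -> float:
    """BI of standard-normal residuals (the analytic unimodal null)."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, n)
    res = module_stats.bimodality_index(pd.Series(x), _dummy_meta(n), seed=seed)
    return float(res.bi)


def bimodality_benchmark(seed: int, n_reps: int = 100, shift: float = 3.0,
                         threshold: float = 1.0) -> dict:
    """Detection rate on planted-switch modules, false-call rate on
    standard-normal null residuals (n = 95)."""
    hits = sum(_switch_module_bi(namespaced_seed(seed, f"sw{r}"), True,
                                 shift=shift) > threshold for r in range(n_reps))
    false = sum(_null_bi(namespaced_seed(seed, f"nu{r}")) > threshold
                for r in range(n_reps))
    return {"n_reps": n_reps, "switch_detect_rate": hits / n_reps,
            "null_detect_rate": false / n_reps}


def bi_closed_form(seed: int, delta: float = 3.0, pi: float = 0.5,
                   n: int = 8000) -> dict:
    """Large-sample BI of an explicit two-component mixture vs its limit.

    For components separated by delta standard deviations with upper-mode
    weight pi, BI converges to delta * sqrt(pi (1 - pi)).
    """
    rng = np.random.default_rng(seed)
    upper = rng.random(n) < pi
    x = rng.normal(np.where(upper, delta / 2.0, -delta / 2.0), 1.0)
    # balanced dummy design independent of x: residuals are x re-centred
    res = module_stats.bimodality_index(pd.Series(x), _dummy_meta(n), seed=seed)
    expected = delta * np.sqrt(pi * (1.0 - pi))
    return {"bi": float(res.bi), "expected": float(expected),
            "rel_err": float(abs(res.bi - expected) / expected), "n": n}


# --------------------------------------------------------------- quantile regression

QUANTILE_TRUTH = np.array([1.0, 0.8, -0.6, 0.3, 1.2])


def quantile_benchmark(seed: int, n_boot: int = 500,
                       family_sd: float = 0.3, shift: float = 0.7) -> dict:
    """Median-regression recovery and exact location-shift equivariance.

    The response is a linear design signal plus family intercepts and
    symmetric noise, so every tau = 0.5 coefficient targets the generating
    value.  Adding a constant to one population is a pure location shift:
    the fitted coefficients at EVERY quantile must move by exactly that
    shift decomposed on the design (intercept + shift/2, population
    + shift), because the check-loss objective is translation-equivariant.
    """
    rng = np.random.default_rng(seed)
    meta = synthetic.generate_design(synthetic.DesignSpec(), seed=seed)
    codes = synthetic.design_codes(meta)
    X = np.column_stack([np.ones(len(meta)), codes["xT"], codes["xP"],
                         codes["xS"], codes["xTP"]])
    fams = meta["family"].to_numpy()
    fam_levels = pd.unique(fams)
    fam_eff = dict(zip(fam_levels, rng.normal(0.0, family_sd, len(fam_levels))))
    y = (X @ QUANTILE_TRUTH
         + np.array([fam_eff[f] for f in fams])
         + rng.normal(0.0, 1.0, len(meta)))
    fit = module_stats.quantile_fit(pd.Series(y), meta, tau=0.5,
                                    n_boot=n_boot, seed=seed)
    z = (fit.coef.to_numpy() - QUANTILE_TRUTH) / fit.boot_se.to_numpy()
    y2 = y + shift * (meta["population"] == "Spain").to_numpy(float)
    expected_delta = np.array([shift / 2.0, 0.0, shift, 0.0, 0.0])
    max_shift_err = 0.0
    for tau in (0.25, 0.5, 0.75):
        f1 = module_stats.quantile_fit(pd.Series(y), meta, tau=tau,
                                       n_boot=100, seed=seed)
        f2 = module_stats.quantile_fit(pd.Series(y2), meta, tau=tau,
                                       n_boot=100, seed=seed)
        delta = f2.coef.to_numpy() - f1.coef.to_numpy()
        max_shift_err = max(max_shift_err, float(np.abs(delta - expected_delta).max()))
    return {"coef": fit.coef, "boot_se": fit.boot_se,
            "max_abs_z": float(np.abs(z).max()),
            "shift_max_abs_err": max_shift_err, "n_boot": fit.n_boot}


# --------------------------------------------------------------- oracle equivalences

def oracle_checks(seed: int) -> dict:
    """Agreement of each computational primitive with a restated oracle.

    Each oracle below is the textbook definition written out directly
    (brute-force loops, scipy's Fisher test), so agreement certifies the
    optimized implementations.  The unit-test suite re-implements these
    oracles independently of this module.
    """
    rng = np.random.default_rng(seed)
    out = {}

    # median-of-ratios vs brute force on an all-positive count matrix
    counts = pd.DataFrame(
        rng.negative_binomial(20, 0.05, size=(200, 96)) + 1,
        index=[f"g{i}" for i in range(200)],
        columns=[f"s{j}" for j in range(96)])
    sf = preprocess.compute_size_factors(counts).size_factors.to_numpy()
    x = counts.to_numpy(float)
    ref = np.exp(np.log(x).mean(axis=1))          # per-gene geometric mean
    brute = np.median(x / ref[:, None], axis=0)   # per-sample median ratio
    out["sf_max_abs_diff"] = float(np.abs(sf - brute).max())

    # BH vs the step-up oracle, with ties and endpoint values
    p = np.concatenate([rng.uniform(0, 1, 400), [0.0, 1.0, 0.5, 0.5, 0.5]])
    q = glmm.bh_adjust(p)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    stepped = p[order] * m / (np.arange(m) + 1.0)
    for i in range(m - 2, -1, -1):                # enforce monotonicity
        stepped[i] = min(stepped[i], stepped[i + 1])
    oracle_q = np.empty(m)
    oracle_q[order] = np.minimum(stepped, 1.0)
    out["bh_max_abs_diff"] = float(np.abs(q - oracle_q).max())

    # TOM vs the triple loop on 50 genes
    expr = pd.DataFrame(rng.normal(0, 1, (50, 96)),
                        index=[f"g{i}" for i in range(50)],
                        columns=[f"s{j}" for j in range(96)])
    adj = network.signed_adjacency(expr, power=4)
    tom = network.topological_overlap(adj).to_numpy()
    a = adj.to_numpy()
    k = a.sum(axis=1) - np.diag(a)     # connectivity excludes the self-edge
    loop = np.empty_like(a)
    for i in range(50):
        for j in range(50):
            if i == j:
                loop[i, j] = 1.0
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(50) if u not in (i, j))
            loop[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    out["tom_max_abs_diff"] = float(np.abs(tom - loop).max())

    # ORA vs scipy's one-sided Fisher exact test
    genes = [f"g{i}" for i in range(400)]
    annot = {g: {f"T{rng.integers(0, 12)}" for _ in range(rng.integers(1, 4))}
             for g in genes}
    universe = set(genes)
    query = set(rng.choice(genes, 60, replace=False))
    tab = enrichment.ora(query, universe, annot)
    diffs = []
    for _, row in tab.iterrows():
        k_ = int(row["k"])
        K_ = int(row["K"])
        n_ = int(row["n"])
        N_ = int(row["N"])
        _, pf = stats.fisher_exact(
            [[k_, K_ - k_], [n_ - k_, N_ - K_ - n_ + k_]],
            alternative="greater")
        diffs.append(abs(row["p"] - pf))
    out["ora_max_abs_diff"] = float(max(diffs))

    # GLMM objective pinned at sigma_u ~ 0 vs the fixed-effects NB GLM
    design = synthetic.generate_design(synthetic.DesignSpec(), seed=seed)
    truth = synthetic.GeneTruth(gene_id="g", category="T_only_up", beta0=4.5,
                                betaT=0.7, betaP=-0.4, betaS=0.2, betaTP=0.3,
                                dispersion=0.2, family_sd=0.0)
    ds = synthetic.generate_counts(design, [truth], seed=seed)
    y = ds.counts.iloc[0].to_numpy()
    glm = glmm.fit_nb_glm(y, ds.metadata, ds.size_factors_true)
    from scipy import optimize
    X = np.column_stack([np.ones(len(design))] + [
        synthetic.design_codes(design)[c] for c in ("xT", "xP", "xS", "xTP")])
    off = np.log(ds.size_factors_true)
    fam = pd.Categorical(design["family"]).codes.astype(np.int64)
    log_sigma_floor = np.log(1e-4)

    def obj(theta):
        return glmm._nll_random(np.concatenate([theta, [log_sigma_floor]]),
                                y, X, off, fam, int(fam.max()) + 1)

    x0 = np.concatenate([glm.beta, [np.log(glm.dispersion)]])
    res = optimize.minimize(obj, x0, method="L-BFGS-B",
                            options={"maxiter": 500, "ftol": 1e-13})
    out["glmm_sigma0_max_beta_diff"] = float(np.abs(res.x[:5] - glm.beta).max())
    return out
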