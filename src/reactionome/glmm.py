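"""Per-gene negative-binomial mixed models for a 2x2 factorial with families.

Model: counts y_gj ~ NB2(mu_gj, alpha_g) with
    ln mu_gj = beta0 + bT*xT + bP*xP + bS*xS + bTP*xT*xP + u_f(j) + ln s_j,
family random intercepts u_f ~ N(0, sigma_u^2), and sum-to-zero (+-1/2)
codes so each coefficient is the main effect (or interaction) on the
natural-log scale and the per-term Wald test z = beta/se tests exactly
that effect.  The marginal likelihood integrates the family intercepts
out by a per-family Laplace approximation (the integrand is log-concave
in u, so the inner Newton solve is well behaved).  Dispersion alpha and
the random-intercept SD are estimated jointly with beta on the log scale,
which keeps both positive; fits whose sigma_u collapses to the boundary
are refit as fixed-effects NB GLMs.

Log2 fold changes are computed from model-predicted cell means at random
effect zero and size factor one, averaged over the nuisance factors on
the count scale by default (a log-scale alternative is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .synthetic import design_codes

TERMS = ("temperature", "population", "sex", "interaction")
TERM_INDEX = {"temperature": 1, "population": 2, "sex": 3, "interaction": 4}

_ETA_CAP = 30.0
_SIGMA_FLOOR = 1e-3          # below this the random intercept is treated as absent


class InestimableDesignError(ValueError):
    """A required factor level is entirely absent from the design."""


@dataclass
class GeneFit:
    gene_id: str
    beta: np.ndarray             # (5,) intercept, temperature, population, sex, interaction
    se: np.ndarray               # (5,)
    vcov: np.ndarray             # (5, 5)
    dispersion: float            # NB2 alpha
    sigma2_u: float              # family random-intercept variance
    converged: bool
    loglik: float
    n_obs: int = 0


# ---------------------------------------------------------------- NB2 pieces

def _nb_ll(y, eta, r):
    """Elementwise NB2 log-likelihood at linear predictor eta, size r=1/alpha."""
    mu = np.exp(eta)
    return (gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
            + r * np.log(r) + y * eta - (y + r) * np.log(r + mu))

def _nb_score_eta(y, eta, r):
    mu = np.exp(eta)
    return y - (y + r) * mu / (r + mu)

def _nb_weight_eta(y, eta, r):
    mu = np.exp(eta)
    return (y + r) * r * mu / (r + mu) ** 2


def _solve_family_modes(y, eta0, r, sig2, fam_idx, n_fam, max_iter=50, tol=1e-10):
    """Newton solve of the penalized modes u_f; returns (u, sum-of-weights per family)."""
    u = np.zeros(n_fam)
    for _ in range(max_iter):
        eta = np.clip(eta0 + u[fam_idx], -_ETA_CAP, _ETA_CAP)
        g = np.bincount(fam_idx, weights=_nb_score_eta(y, eta, r), minlength=n_fam)
        w = np.bincount(fam_idx, weights=_nb_weight_eta(y, eta, r), minlength=n_fam)
        grad = g - u / sig2
        hess = w + 1.0 / sig2
        step = grad / hess
        u = u + step
        if np.max(np.abs(step)) < tol:
            break
    eta = np.clip(eta0 + u[fam_idx], -_ETA_CAP, _ETA_CAP)
    w = np.bincount(fam_idx, weights=_nb_weight_eta(y, eta, r), minlength=n_fam)
    return u, w


def _nll_random(theta, y, X, off, fam_idx, n_fam):
    p = X.shape[1]
    beta = theta[:p]
    r = np.exp(-theta[p])                      # r = 1/alpha
    sig2 = np.exp(2.0 * theta[p + 1])
    eta0 = X @ beta + off
    u, w = _solve_family_modes(y, eta0, r, sig2, fam_idx, n_fam)
    eta = np.clip(eta0 + u[fam_idx], -_ETA_CAP, _ETA_CAP)
    ll = _nb_ll(y, eta, r).sum() - (u ** 2).sum() / (2.0 * sig2) \
        - 0.5 * np.log1p(sig2 * w).sum()
    return -ll if np.isfinite(ll) else 1e12


def _nll_fixed(theta, y, X, off):
    p = X.shape[1]
    beta = theta[:p]
    r = np.exp(-theta[p])
    eta = np.clip(X @ beta + off, -_ETA_CAP, _ETA_CAP)
    ll = _nb_ll(y, eta, r).sum()
    return -ll if np.isfinite(ll) else 1e12


def _num_hessian(f, x, args, step=1e-4):
    n = len(x)
    H = np.empty((n, n))
    hs = step * (1.0 + np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = hs[i]
            ej = np.zeros(n); ej[j] = hs[j]
            fpp = f(x + ei + ej, *args)
            fpm = f(x + ei - ej, *args)
            fmp = f(x - ei + ej, *args)
            fmm = f(x - ei - ej, *args)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * hs[i] * hs[j])
    return H


def _design_matrix(meta: pd.DataFrame) -> np.ndarray:
    codes = design_codes(meta)
    n = len(meta)
    return np.column_stack([np.ones(n), codes["xT"], codes["xP"], codes["xS"], codes["xTP"]])


def _check_design(meta: pd.DataFrame) -> None:
    if meta["population"].nunique() < 2 or meta["temperature"].nunique() < 2:
        raise InestimableDesignError("both populations and both temperatures must be present")


def _start_values(y, X, off):
    z = np.log(y + 0.5) - off
    beta0, *_ = np.linalg.lstsq(X, z, rcond=None)
    mu0 = np.exp(np.clip(X @ beta0 + off, -_ETA_CAP, _ETA_CAP))
    with np.errstate(divide="ignore", invalid="ignore"):
        a = ((y - mu0) ** 2 - mu0) / np.maximum(mu0 ** 2, 1e-12)
    alpha0 = float(np.clip(np.nanmedian(a), 1e-3, 5.0))
    return beta0, alpha0


def fit_nb_glm(counts_g, meta: pd.DataFrame, size_factors, gene_id: str = "",
               max_iter: int = 200) -> GeneFit:
    """Fixed-effects NB2 GLM (no family term); also the boundary fallback."""
    _check_design(meta)
    y = np.asarray(counts_g, dtype=float)
    X = _design_matrix(meta)
    off = np.log(np.asarray(size_factors, dtype=float))
    beta0, alpha0 = _start_values(y, X, off)
    x0 = np.concatenate([beta0, [np.log(alpha0)]])
    bounds = [(-50, 50)] * X.shape[1] + [(np.log(1e-8), np.log(50.0))]
    res = optimize.minimize(_nll_fixed, x0, args=(y, X, off),
                            method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-9})
    H = _num_hessian(_nll_fixed, res.x, (y, X, off))
    return _pack_fit(gene_id, res, H, X.shape[1], len(y), sigma2_u=0.0)


def _pack_fit(gene_id, res, H, p, n, sigma2_u):
    try:
        cov = np.linalg.pinv(H, hermitian=True)
        se_full = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        cov = np.full_like(H, np.nan)
        se_full = np.full(H.shape[0], np.nan)
    se = se_full[:p]
    ok = bool(res.success) and np.all(np.isfinite(se)) and np.all(se > 0)
    return GeneFit(
        gene_id=gene_id,
        beta=res.x[:p].copy(),
        se=se,
        vcov=cov[:p, :p],
        dispersion=float(np.exp(res.x[p])),
        sigma2_u=float(sigma2_u),
        converged=ok,
        loglik=-float(res.fun),
        n_obs=n,
    )


def fit_gene(counts_g, meta: pd.DataFrame, size_factors, gene_id: str = "",
             max_iter: int = 200, tol: float = 1e-8) -> GeneFit:
    """NB2 mixed model for one gene (Laplace marginal likelihood).

    Never raises on numerical failure: a fit that cannot be completed is
    returned with converged=False.  If the random-intercept SD collapses
    to the boundary the gene is refit as a fixed-effects NB GLM.
    """
    _check_design(meta)
    y = np.asarray(counts_g, dtype=float)
    X = _design_matrix(meta)
    off = np.log(np.asarray(size_factors, dtype=float))
    fam = pd.Categorical(meta["family"]).codes.astype(np.int64)
    n_fam = int(fam.max()) + 1

    beta0, alpha0 = _start_values(y, X, off)
    x0 = np.concatenate([beta0, [np.log(alpha0)], [np.log(0.2)]])
    bounds = ([(-50, 50)] * X.shape[1]
              + [(np.log(1e-8), np.log(50.0))]
              + [(np.log(1e-4), np.log(5.0))])
    args = (y, X, off, fam, n_fam)
    res = optimize.minimize(_nll_random, x0, args=args,
                            method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-9})
    sigma_u = float(np.exp(res.x[-1]))
    if sigma_u < _SIGMA_FLOOR:
        return fit_nb_glm(counts_g, meta, size_factors, gene_id=gene_id, max_iter=max_iter)
    H = _num_hessian(_nll_random, res.x, args)
    return _pack_fit(gene_id, res, H, X.shape[1], len(y), sigma2_u=sigma_u ** 2)


# -------------------------------------------------------------------- tests

def wald_tests(fit: GeneFit) -> dict:
    """Two-sided Wald p per model term; NaN when the fit did not converge."""
    if not fit.converged:
        return {t: np.nan for t in TERMS}
    out = {}
    for term, idx in TERM_INDEX.items():
        z = fit.beta[idx] / fit.se[idx]
        out[term] = float(2.0 * norm.sf(abs(z)))
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs pass through untouched."""
    p = np.asarray(p, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if finite.sum():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return q


# ------------------------------------------------------------- fold changes

def predict_cell_means(fit: GeneFit) -> pd.DataFrame:
    """Predicted mean count per (population, temperature, sex) cell.

    Evaluated at random effect zero and size factor one.
    """
    rows = []
    for pop, xp in (("Finland", -0.5), ("Spain", 0.5)):
        for temp, xt in ((25, -0.5), (34, 0.5)):
            for sex, xs in (("female", -0.5), ("male", 0.5)):
                eta = (fit.beta[0] + fit.beta[1] * xt + fit.beta[2] * xp
                       + fit.beta[3] * xs + fit.beta[4] * xt * xp)
                rows.append((pop, temp, sex, float(np.exp(eta))))
    return pd.DataFrame(rows, columns=["population", "temperature", "sex", "mu"])


def _cell_avg(grid: pd.DataFrame, by: list, scale: str) -> pd.Series:
    if scale == "count":
        return grid.groupby(by, sort=True)["mu"].mean()
    if scale == "log":
        return np.exp(np.log(grid["mu"]).groupby([grid[b] for b in by]).mean())
    raise ValueError("scale must be 'count' or 'log'")


def compute_lfcs(grid: pd.DataFrame, scale: str = "count") -> dict:
    """Three log2 fold changes from the cell-mean grid.

    Nuisance factors are averaged on the count scale (default) or the log
    scale before log2 differencing:
      lfc_T  = log2 mean(34C) - log2 mean(25C)          (over population, sex)
      lfc_P  = log2 mean(Spain) - log2 mean(Finland)    (over temperature, sex)
      lfc_TP = [log2 m(SP,34) - log2 m(SP,25)] - [log2 m(FI,34) - log2 m(FI,25)]
    Per-population temperature slopes (log2) are returned as well.
    """
    by_T = _cell_avg(grid, ["temperature"], scale)
    by_P = _cell_avg(grid, ["population"], scale)
    by_PT = _cell_avg(grid, ["population", "temperature"], scale)
    lfc_T = float(np.log2(by_T.loc[34]) - np.log2(by_T.loc[25]))
    lfc_P = float(np.log2(by_P.loc["Spain"]) - np.log2(by_P.loc["Finland"]))
    slope_FI = float(np.log2(by_PT.loc[("Finland", 34)]) - np.log2(by_PT.loc[("Finland", 25)]))
    slope_SP = float(np.log2(by_PT.loc[("Spain", 34)]) - np.log2(by_PT.loc[("Spain", 25)]))
    return {"lfc_T": lfc_T, "lfc_P": lfc_P, "lfc_TP": slope_SP - slope_FI,
            "slope_FI": slope_FI, "slope_SP": slope_SP}


# ------------------------------------------------------------- gene screens

@dataclass
class DEResults:
    table: pd.DataFrame                       # one row per gene
    fits: dict = field(default_factory=dict)  # gene_id -> GeneFit


def fit_all_genes(counts: pd.DataFrame, meta: pd.DataFrame, size_factors,
                  q_cutoff: float = 0.05, lfc_cutoff: float = 1.0,
                  lfc_scale: str = "count", random_effect: bool = True,
                  progress: bool = False) -> DEResults:
    """Fit every gene, BH-adjust each term across genes, derive LFCs and flags.

    Non-converged genes keep NaN statistics and False flags but remain in
    the table (and hence in any downstream universe).
    """
    _check_design(meta)
    sf = np.asarray(size_factors, dtype=float)
    rows, fits = [], {}
    iterator = counts.index
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, desc="NB GLMM")
    for g in iterator:
        y = counts.loc[g].to_numpy()
        fit = (fit_gene(y, meta, sf, gene_id=g) if random_effect
               else fit_nb_glm(y, meta, sf, gene_id=g))
        fits[g] = fit
        p = wald_tests(fit)
        if fit.converged:
            lf = compute_lfcs(predict_cell_means(fit), scale=lfc_scale)
        else:
            lf = {k: np.nan for k in ("lfc_T", "lfc_P", "lfc_TP", "slope_FI", "slope_SP")}
        rows.append({
            "gene_id": g, "converged": fit.converged,
            "beta0": fit.beta[0], "betaT": fit.beta[1], "betaP": fit.beta[2],
            "betaS": fit.beta[3], "betaTP": fit.beta[4],
            "se_T": fit.se[1], "se_P": fit.se[2], "se_S": fit.se[3], "se_TP": fit.se[4],
            "dispersion": fit.dispersion, "sigma2_u": fit.sigma2_u,
            "p_T": p["temperature"], "p_P": p["population"],
            "p_TP": p["interaction"], "p_S": p["sex"],
            **lf,
        })
    tab = pd.DataFrame(rows).set_index("gene_id", drop=False)
    for term in ("T", "P", "TP", "S"):
        tab[f"q_{term}"] = bh_adjust(tab[f"p_{term}"].to_numpy())
    for term in ("T", "P", "TP"):
        tab[f"sig_{term}"] = (
            (tab[f"q_{term}"] < q_cutoff) & (tab[f"lfc_{term}"].abs() > lfc_cutoff)
        ).fillna(False)
    # sex: q-value screen only (no fold-change threshold by default)
    tab["sig_S"] = (tab["q_S"] < q_cutoff).fillna(False)
    return DEResults(table=tab, fits=fits)
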