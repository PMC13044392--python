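"""Signed weighted co-expression network: adjacency, TOM, modules, eigengenes.

Pairwise Pearson correlations on the moderated-log matrix are mapped to a
signed adjacency a_ij = ((1 + cor)/2)^beta and combined with shared-
neighbour information into the topological overlap matrix (TOM).  Genes
are clustered by average linkage on 1 - TOM and modules extracted by a
deterministic height scan (fine to coarse; clusters reaching the minimum
size are frozen as modules, leftovers stay unassigned).  Each module is
summarized by its eigengene — the first principal component of the
standardized member expression, unit variance, oriented to correlate
non-negatively with the mean member profile — and modules whose
eigengenes correlate above a threshold are merged greedily.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


class DegenerateCorrelationError(ValueError):
    """A gene with zero variance makes Pearson correlation undefined."""


@dataclass
class NetworkConfig:
    candidate_powers: tuple = (1, 2, 3, 4, 5, 6, 7, 8, 10, 12)
    signed: bool = True
    min_module_size: int = 50
    merge_eigengene_cor: float = 0.75
    r2_threshold: float = 0.8
    min_mean_connectivity: float = 100.0
    deep_split: int = 4
    merge_cut_height: float = 0.1   # recorded for provenance; merging uses the cor rule


@dataclass
class CoexpressionModule:
    module_id: str
    genes: list
    eigengene: pd.Series             # per-sample, unit variance
    variance_explained: float


def _check_variances(vals: np.ndarray, gene_ids) -> None:
    sd = vals.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateCorrelationError(
            f"zero-variance gene(s): {[gene_ids[i] for i in bad[:5]]}"
            + ("..." if bad.size > 5 else ""))


def drop_zero_variance(logm: pd.DataFrame) -> pd.DataFrame:
    """Remove genes with zero variance across samples (caller-facing helper)."""
    sd = logm.to_numpy().std(axis=1)
    return logm.loc[sd > 0]


def signed_adjacency(logm: pd.DataFrame, power: int) -> pd.DataFrame:
    """a_ij = ((1 + cor_ij)/2)^power with unit diagonal (genes x genes)."""
    vals = logm.to_numpy(dtype=float)
    _check_variances(vals, list(logm.index))
    cor = np.corrcoef(vals)
    a = ((1.0 + np.clip(cor, -1.0, 1.0)) / 2.0) ** power
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=logm.index, columns=logm.index)


def connectivity(adj: pd.DataFrame) -> pd.Series:
    """k_i = sum_{j != i} a_ij."""
    a = adj.to_numpy()
    return pd.Series(a.sum(axis=1) - np.diag(a), index=adj.index, name="k")


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Slope-signed R^2 of log10 p(k) vs log10 k on binned connectivity.

    Positive values indicate the scale-free-like decreasing tail; a fit
    with positive slope is reported as negative R^2, mirroring the usual
    soft-threshold diagnostic convention.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < n_bins or k.min() == k.max():
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)   # equal-width bins
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    df = pd.DataFrame({"k": k, "bin": which})
    g = df.groupby("bin")["k"]
    kmean = g.mean().to_numpy()
    freq = g.size().to_numpy() / k.size
    keep = (kmean > 0) & (freq > 0)
    if keep.sum() < 3:
        return 0.0
    x, y = np.log10(kmean[keep]), np.log10(freq[keep])
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = ((y - yhat) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2)


def pick_soft_threshold(logm: pd.DataFrame, candidate_powers=None,
                        cfg: NetworkConfig = None):
    """Smallest power meeting the R^2 and mean-connectivity criteria.

    Returns (power, diagnostics DataFrame).  If no candidate qualifies the
    power maximizing R^2 is returned and the diagnostics carry a warning
    flag in the `selected_by_fallback` attribute column.
    """
    cfg = cfg or NetworkConfig()
    powers = list(candidate_powers if candidate_powers is not None else cfg.candidate_powers)
    if len(powers) < 3:
        raise ValueError("need at least 3 candidate powers")
    if logm.shape[0] < 50:
        raise ValueError("need at least 50 genes for soft-threshold diagnostics")
    vals = logm.to_numpy(dtype=float)
    _check_variances(vals, list(logm.index))
    cor = np.corrcoef(vals)
    base = (1.0 + np.clip(cor, -1.0, 1.0)) / 2.0
    np.fill_diagonal(base, 0.0)      # exclude self from connectivity
    rows = []
    for b in powers:
        k = (base ** b).sum(axis=1)
        rows.append({"power": b, "r2": scale_free_fit(k),
                     "mean_connectivity": float(k.mean()),
                     "median_connectivity": float(np.median(k))})
    diag = pd.DataFrame(rows)
    ok = diag[(diag["r2"] > cfg.r2_threshold)
              & (diag["mean_connectivity"] > cfg.min_mean_connectivity)]
    if len(ok):
        power = int(ok["power"].iloc[0])
        fallback = False
    else:
        power = int(diag.loc[diag["r2"].idxmax(), "power"])
        fallback = True
    diag["selected"] = diag["power"] == power
    diag["selected_by_fallback"] = fallback
    return power, diag


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """TOM: w_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), unit diagonal."""
    a = adj.to_numpy(dtype=float)
    k = a.sum(axis=1) - np.diag(a)
    # l_ij = sum_{u != i,j} a_iu a_uj = (A^2)_ij - a_ii*a_ij - a_ij*a_jj
    l = a @ a
    l -= np.diag(a)[:, None] * a
    l -= a * np.diag(a)[None, :]
    kmin = np.minimum.outer(k, k)
    w = (l + a) / (kmin + 1.0 - a)
    np.fill_diagonal(w, 1.0)
    return pd.DataFrame(w, index=adj.index, columns=adj.columns)


def cut_modules(tom: pd.DataFrame, cfg: NetworkConfig = None) -> pd.Series:
    """Module assignment by height scan of the average-linkage tree on 1-TOM.

    Two deterministic phases.  Core phase: cut heights run fine to coarse
    and any cluster of at least `min_module_size` still-unassigned genes is
    frozen as a module core (higher deep_split scans more, finer, height
    levels).  Assignment phase: every remaining gene joins the core with
    the highest average TOM to it, provided that similarity clears the
    midpoint between the core's median internal similarity and the median
    background (unassigned-to-core) similarity; genes clearing no core's
    threshold stay 'unassigned'.
    """
    cfg = cfg or NetworkConfig()
    gene_ids = list(tom.index)
    n = len(gene_ids)
    labels = pd.Series("unassigned", index=tom.index, name="module")
    if n < cfg.min_module_size:
        return labels
    dis = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dis, 0.0)
    dis = np.clip((dis + dis.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dis, checks=False), method="average")
    heights = Z[:, 2]
    n_levels = 8 * (2 ** cfg.deep_split)
    grid = np.quantile(heights, np.linspace(0.0, 1.0, min(n_levels, len(heights))))
    grid = np.unique(grid)
    assign = np.zeros(n, dtype=int)          # 0 = unassigned
    next_id = 1
    for h in grid:
        cl = fcluster(Z, t=h, criterion="distance")
        for c in np.unique(cl):
            members = np.flatnonzero(cl == c)
            if members.size >= cfg.min_module_size and not assign[members].any():
                assign[members] = next_id
                next_id += 1

    # assignment phase: attach leftovers to the most similar core
    tom_vals = tom.to_numpy(dtype=float)
    free = np.flatnonzero(assign == 0)
    cores = [np.flatnonzero(assign == m) for m in range(1, next_id)]
    if free.size and cores:
        sims = np.stack([tom_vals[np.ix_(free, idx)].mean(axis=1) for idx in cores], axis=1)
        thresholds = []
        for ci, idx in enumerate(cores):
            sub = tom_vals[np.ix_(idx, idx)]
            internal = float(np.median((sub.sum(axis=1) - 1.0) / (idx.size - 1)))
            background = float(np.median(sims[:, ci]))
            thresholds.append(0.5 * (internal + background))
        best = np.argmax(sims, axis=1)
        accept = sims[np.arange(free.size), best] >= np.array(thresholds)[best]
        assign[free[accept]] = best[accept] + 1

    for mid in range(1, next_id):
        labels.iloc[np.flatnonzero(assign == mid)] = f"M{mid}"
    return labels


def compute_eigengene(logm_rows: pd.DataFrame, module_id: str = "M") -> CoexpressionModule:
    """First PC of the standardized member expression, oriented and unit-variance."""
    if logm_rows.shape[0] == 0:
        raise ValueError("empty module")
    vals = logm_rows.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    zs = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    if zs.shape[0] == 1:
        e = zs[0].copy()
        var_exp = 1.0
    else:
        u, svals, vt = np.linalg.svd(zs, full_matrices=False)
        e = vt[0]
        var_exp = float(svals[0] ** 2 / (svals ** 2).sum())
    mean_profile = zs.mean(axis=0)
    if np.corrcoef(e, mean_profile)[0, 1] < 0:
        e = -e
    e = e / e.std(ddof=0)
    return CoexpressionModule(
        module_id=module_id,
        genes=list(logm_rows.index),
        eigengene=pd.Series(e, index=logm_rows.columns, name=module_id),
        variance_explained=var_exp,
    )


def merge_modules(modules: list, logm: pd.DataFrame,
                  threshold: float = 0.75) -> list:
    """Greedy merge: repeatedly join the pair with the highest eigengene
    correlation above `threshold`, recomputing the merged eigengene."""
    mods = list(modules)
    while len(mods) > 1:
        best, best_cor = None, threshold
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                c = float(np.corrcoef(mods[i].eigengene, mods[j].eigengene)[0, 1])
                if c > best_cor:
                    best, best_cor = (i, j), c
        if best is None:
            break
        i, j = best
        genes = mods[i].genes + mods[j].genes
        merged = compute_eigengene(logm.loc[genes], module_id=mods[i].module_id)
        mods = [m for idx, m in enumerate(mods) if idx not in (i, j)] + [merged]
    # stable renaming by size (largest first)
    mods.sort(key=lambda m: (-len(m.genes), m.module_id))
    out = []
    for idx, m in enumerate(mods, start=1):
        out.append(CoexpressionModule(f"M{idx}", m.genes,
                                      m.eigengene.rename(f"M{idx}"),
                                      m.variance_explained))
    return out


def detect_modules(logm: pd.DataFrame, cfg: NetworkConfig = None,
                   power: int = None):
    """Full network stage: soft threshold, adjacency, TOM, cut, eigengenes, merge.

    Returns (modules, assignment Series, power, diagnostics).
    """
    cfg = cfg or NetworkConfig()
    clean = drop_zero_variance(logm)
    if power is None:
        power, diag = pick_soft_threshold(clean, cfg=cfg)
    else:
        diag = None
    adj = signed_adjacency(clean, power)
    tom = topological_overlap(adj)
    labels = cut_modules(tom, cfg)
    modules = []
    for mid in [m for m in labels.unique() if m != "unassigned"]:
        genes = labels.index[labels == mid]
        modules.append(compute_eigengene(clean.loc[genes], module_id=mid))
    modules = merge_modules(modules, clean, threshold=cfg.merge_eigengene_cor)
    merged_labels = pd.Series("unassigned", index=clean.index, name="module")
    for m in modules:
        merged_labels.loc[m.genes] = m.module_id
    return modules, merged_labels, power, diag
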