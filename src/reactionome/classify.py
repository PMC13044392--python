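"""Reaction-norm taxonomy: Venn categories, direction subtypes, plasticity labels.

A gene significant for any of temperature (T), population (P) or their
interaction (TxP) falls in exactly one Venn cell given by the subset of
significant terms.  Direction subtypes record up/down-regulation with
temperature, the higher-expressing population, the more temperature-
responsive population, and whether the two population norms cross
(reversal).  Genes significant for at least T and TxP are then screened
with four post-hoc contrasts for genetic assimilation (plasticity lost in
the heat-tolerant population, which constitutively expresses the induced
level: populations differ at 25C only) or genetic compensation (the
heat-tolerant population suppresses the plastic response and stays at the
uninduced level: populations differ at 34C only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .glmm import DEResults, GeneFit

VENN_CELLS = ("T", "P", "TxP", "T+P", "T+TxP", "P+TxP", "T+P+TxP")

# contrast vectors on (intercept, bT, bP, bS, bTP); natural-log scale
CONTRASTS = {
    "FI_34_vs_25": np.array([0.0, 1.0, 0.0, 0.0, -0.5]),
    "SP_34_vs_25": np.array([0.0, 1.0, 0.0, 0.0, 0.5]),
    "SP_vs_FI_at_25": np.array([0.0, 0.0, 1.0, 0.0, -0.5]),
    "SP_vs_FI_at_34": np.array([0.0, 0.0, 1.0, 0.0, 0.5]),
}


class NotClassifiableError(ValueError):
    """Venn classification requires at least one significant term."""


@dataclass
class PosthocContrasts:
    """The four simple-effect contrasts (log scale), with Wald inference."""
    table: pd.DataFrame      # index = contrast name; estimate, se, p, significant
    alpha: float

    def sig(self, name: str) -> bool:
        return bool(self.table.loc[name, "significant"])


def classify_venn(row: pd.Series) -> dict:
    """Venn cell and direction subtype for one gene's DE summary row.

    `row` needs sig_T/sig_P/sig_TP, lfc_T/lfc_P and the two per-population
    log2 temperature slopes (slope_FI, slope_SP).
    """
    terms = [t for t, f in (("T", row["sig_T"]), ("P", row["sig_P"]), ("TxP", row["sig_TP"])) if f]
    if not terms:
        raise NotClassifiableError(f"{row.get('gene_id', '?')}: no significant term")
    cell = "+".join(terms)

    direction = {}
    if row["sig_T"]:
        direction["temperature"] = "up" if row["lfc_T"] > 0 else "down"
    if row["sig_P"]:
        direction["higher_population"] = "Spain" if row["lfc_P"] > 0 else "Finland"
    reversal = False
    if row["sig_TP"]:
        sFI, sSP = row["slope_FI"], row["slope_SP"]
        # exact |slope| ties break toward Spain (lexicographically later label)
        direction["more_responsive"] = "Finland" if abs(sFI) > abs(sSP) else "Spain"
        reversal = (cell == "TxP") and (np.sign(sFI) * np.sign(sSP) < 0)
    direction["reversal"] = reversal
    if reversal:
        assert np.sign(row["slope_FI"]) * np.sign(row["slope_SP"]) < 0
    return {"venn_category": cell, **{f"dir_{k}": v for k, v in direction.items()}}


def posthoc_contrasts(fit: GeneFit, alpha: float = 0.05,
                      bonferroni: bool = False) -> PosthocContrasts:
    """Delta-method Wald inference for the four simple-effect contrasts.

    Sex is averaged out implicitly: the model is additive in sex on the
    log scale, so it cancels from every contrast.  P-values are
    unadjusted within gene by default (Bonferroni-4 optional).
    """
    rows = []
    a = alpha / (4.0 if bonferroni else 1.0)
    for name, c in CONTRASTS.items():
        est = float(c @ fit.beta)
        se = float(np.sqrt(c @ fit.vcov @ c))
        p = float(2.0 * norm.sf(abs(est) / se)) if se > 0 else np.nan
        rows.append({"contrast": name, "estimate": est, "se": se, "p": p,
                     "significant": bool(p < a) if np.isfinite(p) else False})
    return PosthocContrasts(table=pd.DataFrame(rows).set_index("contrast"), alpha=alpha)


def label_plasticity(contrasts: PosthocContrasts, row: pd.Series) -> str:
    """Assimilation / compensation / neither from the four contrast calls.

    Only genes significant for at least temperature AND the interaction are
    tested; everything else is 'not_tested'.
    """
    if not (bool(row["sig_T"]) and bool(row["sig_TP"])):
        return "not_tested"
    fi = contrasts.sig("FI_34_vs_25")
    sp = contrasts.sig("SP_34_vs_25")
    at25 = contrasts.sig("SP_vs_FI_at_25")
    at34 = contrasts.sig("SP_vs_FI_at_34")
    if fi and not sp and at25 and not at34:
        return "assimilation"
    if fi and not sp and at34 and not at25:
        return "compensation"
    return "neither"


def classify_all(de: DEResults, alpha: float = 0.05,
                 bonferroni: bool = False) -> pd.DataFrame:
    """Per-gene calls for every gene with at least one significant term."""
    rows = []
    for g, row in de.table.iterrows():
        if not (row["sig_T"] or row["sig_P"] or row["sig_TP"]):
            continue
        call = classify_venn(row)
        fit = de.fits.get(g)
        if fit is not None and fit.converged:
            ph = posthoc_contrasts(fit, alpha=alpha, bonferroni=bonferroni)
            label = label_plasticity(ph, row)
        else:
            label = "not_tested"
        rows.append({"gene_id": g, **call, "plasticity_label": label})
    cols = ["gene_id", "venn_category", "dir_temperature", "dir_higher_population",
            "dir_more_responsive", "dir_reversal", "plasticity_label"]
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=cols).set_index("gene_id", drop=False)
    for c in cols:
        if c not in out:
            out[c] = pd.NA
    return out[cols].set_index("gene_id", drop=False)


def category_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts and shares of significant genes per Venn cell (plus labels)."""
    n = len(calls)
    rows = []
    for cell in VENN_CELLS:
        k = int((calls["venn_category"] == cell).sum())
        rows.append({"venn_category": cell, "n_genes": k,
                     "share_of_significant": k / n if n else 0.0})
    for lab in ("assimilation", "compensation"):
        k = int((calls["plasticity_label"] == lab).sum())
        rows.append({"venn_category": lab, "n_genes": k,
                     "share_of_significant": k / n if n else 0.0})
    return pd.DataFrame(rows)
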