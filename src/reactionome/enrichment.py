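"""GO-term overrepresentation analysis by upper-tail hypergeometric tests.

For a query gene list against a universe of expressed, annotated genes,
each term of acceptable size is tested with P(X >= k) where k is the
query/term overlap, and p-values are BH-adjusted across the tested
terms.  The universe convention is the literature-standard one: genes must be
both expressed (post-filter) and annotated; unannotated query genes drop
out of the test silently.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy.stats import hypergeom

from .glmm import bh_adjust


def read_annotation(path) -> dict:
    """Two-column TSV (gene, term) or GAF-like (gene in col 2, GO id in col 5).

    Returns gene id -> set of term ids; empty term sets are never stored.
    """
    annot: dict = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith(("!", "#")) or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 5 and parts[4].startswith("GO:"):
                gene, term = parts[1], parts[4]       # GAF-like
            elif len(parts) >= 2:
                gene, term = parts[0], parts[1]
            else:
                continue
            if gene and term:
                annot.setdefault(gene, set()).add(term)
    return annot


def ora(query, universe, annot: dict, min_term_size: int = 2,
        max_term_size: int = 5000, q_cutoff: float = 0.05) -> pd.DataFrame:
    """Hypergeometric overrepresentation of annotation terms in `query`.

    `universe` is restricted to annotated genes, and `query` to annotated
    members of the universe, so adding unannotated genes to either set
    cannot change any p-value.
    """
    query = set(query)
    universe = set(universe)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    uni = {g for g in universe if annot.get(g)}
    qry = query & uni
    if not qry:
        warnings.warn("no annotated query genes; empty enrichment result")
        return pd.DataFrame(columns=["term", "k", "n", "K", "N",
                                     "gene_ratio", "p", "q", "significant"])
    term_members: dict = {}
    for g in uni:
        for t in annot[g]:
            term_members.setdefault(t, set()).add(g)
    N, n = len(uni), len(qry)
    rows = []
    for t, members in term_members.items():
        K = len(members)
        if not min_term_size <= K <= max_term_size:
            continue
        k = len(members & qry)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": t, "k": k, "n": n, "K": K, "N": N,
                     "gene_ratio": k / n, "p": p})
    out = pd.DataFrame(rows)
    if out.empty:
        out["q"] = []
        out["significant"] = []
        return out
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < q_cutoff
    return out.sort_values(["q", "p", "term"]).reset_index(drop=True)
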