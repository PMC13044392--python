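"""Synthetic RNA-seq counts with known reaction-norm structure.

Emulates a split-brood common-garden design: two source populations
(a northern, heat-sensitive one and a southern, heat-tolerant one),
families nested in population, larvae reared at two temperatures, with
replicate rearing groups and several individuals per group.  Counts are
negative-binomial (NB2) with per-gene dispersion, family random
intercepts, latent co-expression module factors (optionally with a
bimodal high-temperature switch) and log-normal library-size factors.

Fixed effects act on the natural-log mean through sum-to-zero (+-1/2)
codes for temperature, population and sex, so each coefficient is the
ANOVA-style main effect (or interaction) on the log scale.  Every gene
carries a ground-truth category from the reaction-norm taxonomy, which
downstream stages are expected to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LN2 = float(np.log(2.0))

#: reaction-norm truth categories (direction subtypes included)
CATEGORIES = (
    "T_only_up",
    "T_only_down",
    "P_only_FI",
    "P_only_SP",
    "TxP_only_reversal",
    "T_and_P",
    "T_and_TxP",
    "P_and_TxP",
    "T_P_TxP",
    "assimilation",
    "compensation",
    "sex",
    "null",
)

#: expected Venn cell for each truth category (None = not expected significant)
EXPECTED_VENN = {
    "T_only_up": "T",
    "T_only_down": "T",
    "P_only_FI": "P",
    "P_only_SP": "P",
    "TxP_only_reversal": "TxP",
    "T_and_P": "T+P",
    "T_and_TxP": "T+TxP",
    "P_and_TxP": "P+TxP",
    "T_P_TxP": "T+P+TxP",
    "assimilation": "T+P+TxP",
    "compensation": "T+P+TxP",
    "sex": None,
    "null": None,
}

POPULATIONS = ("Finland", "Spain")


class InvalidDesignError(ValueError):
    """Design factor counts must all be positive."""


class InvalidParameterError(ValueError):
    """Generative parameters must be finite and in range."""


@dataclass(frozen=True)
class DesignSpec:
    """Factorial split-brood design; defaults give the 96-sample study layout."""

    n_populations: int = 2
    families_per_population: int = 4
    temperatures: tuple = (25, 34)
    replicates_per_family_per_temperature: int = 2
    individuals_per_replicate: int = 3
    sex_ratio: float = 0.5

    @property
    def n_samples(self) -> int:
        return (
            self.n_populations
            * self.families_per_population
            * len(self.temperatures)
            * self.replicates_per_family_per_temperature
            * self.individuals_per_replicate
        )

    def validate(self) -> None:
        counts = (
            self.n_populations,
            self.families_per_population,
            self.replicates_per_family_per_temperature,
            self.individuals_per_replicate,
        )
        if any(int(c) < 1 for c in counts):
            raise InvalidDesignError(f"all design factor counts must be >= 1, got {counts}")
        if len(set(self.temperatures)) < 2:
            raise InvalidDesignError("need at least two distinct temperature labels")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise InvalidDesignError("sex_ratio must lie in [0, 1]")


@dataclass
class GeneTruth:
    """Per-gene generative parameters (sum-to-zero coding, natural-log scale)."""

    gene_id: str
    category: str
    beta0: float
    betaT: float = 0.0
    betaP: float = 0.0
    betaS: float = 0.0
    betaTP: float = 0.0
    dispersion: float = 0.2
    family_sd: float = 0.3

    def validate(self) -> None:
        vals = (self.beta0, self.betaT, self.betaP, self.betaS, self.betaTP)
        if not all(np.isfinite(vals)):
            raise InvalidParameterError(f"{self.gene_id}: non-finite coefficient")
        if not np.isfinite(self.dispersion) or self.dispersion <= 0:
            raise InvalidParameterError(f"{self.gene_id}: dispersion must be > 0")
        if not np.isfinite(self.family_sd) or self.family_sd < 0:
            raise InvalidParameterError(f"{self.gene_id}: family_sd must be >= 0")


@dataclass
class ModuleTruth:
    """Latent co-expression factor: member genes share a per-sample factor."""

    module_id: str
    member_genes: tuple
    factor_loading_sd: float = 0.5
    bimodal_switch: bool = False
    switch_probability_by_population: dict = field(
        default_factory=lambda: {"Finland": 0.5, "Spain": 0.5}
    )
    switch_shift: float = 3.0  # mode separation at 34C, in factor SD units
    # +- loading signs make a signed network split the module into two
    # anti-correlated halves; set False for sign-coherent planted modules
    mixed_signs: bool = True

    def validate(self) -> None:
        if self.factor_loading_sd <= 0 or not np.isfinite(self.factor_loading_sd):
            raise InvalidParameterError(f"{self.module_id}: factor_loading_sd must be > 0")
        for pop, p in self.switch_probability_by_population.items():
            if not 0.0 <= p <= 1.0:
                raise InvalidParameterError(f"{self.module_id}: switch prob for {pop} not in [0,1]")


@dataclass
class SyntheticDataset:
    counts: pd.DataFrame          # genes x samples, integer
    metadata: pd.DataFrame        # one row per sample
    truth: list                   # list[GeneTruth]
    module_truth: list            # list[ModuleTruth]
    size_factors_true: np.ndarray
    seed: int


def generate_design(spec: DesignSpec = DesignSpec(), seed: int = 0) -> pd.DataFrame:
    """One metadata row per individual of the factorial split-brood design.

    Only the sex column is stochastic (Bernoulli(sex_ratio) per individual);
    the factor layout itself is deterministic.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    rows = []
    pops = [POPULATIONS[i % 2] if spec.n_populations == 2 else f"pop{i+1}"
            for i in range(spec.n_populations)]
    if spec.n_populations == 2:
        pops = list(POPULATIONS)
    for pop in pops:
        for fam in range(1, spec.families_per_population + 1):
            family = f"{pop[:2].upper()}_f{fam}"
            for temp in spec.temperatures:
                for rep in range(1, spec.replicates_per_family_per_temperature + 1):
                    for ind in range(1, spec.individuals_per_replicate + 1):
                        rows.append((pop, family, temp, rep, ind))
    meta = pd.DataFrame(rows, columns=["population", "family", "temperature", "replicate", "individual"])
    meta["sex"] = np.where(rng.random(len(meta)) < spec.sex_ratio, "male", "female")
    meta.insert(0, "sample_id", [
        f"{r.family}_T{r.temperature}_r{r.replicate}_i{r.individual}"
        for r in meta.itertuples()
    ])
    return meta


def design_codes(meta: pd.DataFrame) -> pd.DataFrame:
    """Sum-to-zero (+-1/2) codes for temperature, population and sex.

    High temperature, the southern population and males take +1/2.
    """
    temps = sorted(meta["temperature"].unique())
    xT = np.where(meta["temperature"] == temps[-1], 0.5, -0.5)
    xP = np.where(meta["population"] == "Spain", 0.5, -0.5)
    xS = np.where(meta["sex"] == "male", 0.5, -0.5)
    return pd.DataFrame({"xT": xT, "xP": xP, "xS": xS, "xTP": xT * xP},
                        index=meta.index)


def generate_counts(
    design: pd.DataFrame,
    truths: list,
    modules: list = (),
    size_factor_sd: float = 0.2,
    seed: int = 0,
) -> SyntheticDataset:
    """Draw NB2 counts for every gene under the stated generative model."""
    if len(truths) == 0:
        raise InvalidParameterError("need at least one GeneTruth")
    gene_ids = [t.gene_id for t in truths]
    if len(set(gene_ids)) != len(gene_ids):
        raise InvalidParameterError("gene ids must be unique")
    for t in truths:
        t.validate()
    for m in modules:
        m.validate()
    if not np.isfinite(size_factor_sd) or size_factor_sd < 0:
        raise InvalidParameterError("size_factor_sd must be >= 0")

    rng = np.random.default_rng(seed)
    n = len(design)
    codes = design_codes(design)
    X = codes[["xT", "xP", "xS", "xTP"]].to_numpy()

    # size factors: log-normal, rescaled to geometric mean exactly 1
    log_s = rng.normal(0.0, size_factor_sd, size=n) if size_factor_sd > 0 else np.zeros(n)
    log_s -= log_s.mean()
    s = np.exp(log_s)

    # shared family base effects; each gene scales them by its family_sd
    fams = design["family"].to_numpy()
    fam_levels = pd.unique(fams)
    fam_z = rng.normal(0.0, 1.0, size=len(fam_levels))
    fam_idx = pd.Categorical(fams, categories=fam_levels).codes
    z_sample = fam_z[fam_idx]                      # per-sample standardized family effect

    # latent module factors
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    factor_term = np.zeros((len(truths), n))
    at_hot = codes["xT"].to_numpy() > 0
    for m in modules:
        F = rng.normal(0.0, 1.0, size=n)
        if m.bimodal_switch:
            p_switch = design["population"].map(m.switch_probability_by_population).to_numpy(float)
            up = rng.random(n) < p_switch
            F_hot = np.where(up, m.switch_shift, -m.switch_shift) / 2.0
            F = np.where(at_hot, F_hot, F)
        members = [g for g in m.member_genes if g in gene_pos]
        loadings = np.abs(rng.normal(0.0, m.factor_loading_sd, size=len(members)))
        signs = (rng.choice([-1.0, 1.0], size=len(members)) if m.mixed_signs
                 else np.ones(len(members)))
        for g, lo, sg in zip(members, loadings, signs):
            factor_term[gene_pos[g]] += sg * lo * F

    beta = np.array([[t.beta0, t.betaT, t.betaP, t.betaS, t.betaTP] for t in truths])
    eta = (
        beta[:, [0]]
        + beta[:, 1:].dot(np.vstack([X.T]))        # (G, n)
        + np.array([t.family_sd for t in truths])[:, None] * z_sample[None, :]
        + factor_term
        + log_s[None, :]
    )
    mu = np.exp(eta)
    alpha = np.maximum(np.array([t.dispersion for t in truths]), 1e-8)[:, None]
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    counts = rng.poisson(lam).astype(np.int64)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=design["sample_id"].to_numpy())
    return SyntheticDataset(
        counts=counts_df,
        metadata=design.reset_index(drop=True),
        truth=list(truths),
        module_truth=list(modules),
        size_factors_true=s,
        seed=seed,
    )


def _panel_patterns(e: float):
    """Sum-to-zero coefficient patterns (bT, bP, bS, bTP) per category.

    `e` is the main-effect magnitude in natural-log units.  Assimilation
    uses a temperature-DOWNregulated plastic response and compensation an
    UPregulated one: with count-scale cell-mean averaging the temperature
    log2 fold change of an assimilation pattern is log2(2*exp(s)/(1+exp(s))),
    bounded above by 1 for upward responses, so only the downward variant
    can clear the |log2FC| > 1 gate (and mirror-image for compensation).
    """
    return {
        "T_only_up": (e, 0.0, 0.0, 0.0),
        "T_only_down": (-e, 0.0, 0.0, 0.0),
        "P_only_FI": (0.0, -e, 0.0, 0.0),
        "P_only_SP": (0.0, e, 0.0, 0.0),
        # interaction twice the main-effect size => per-population slopes +-e
        "TxP_only_reversal": (0.0, 0.0, 0.0, 2.0 * e),
        "T_and_P": (e, e, 0.0, 0.0),
        "T_and_TxP": (e, 0.0, 0.0, e),
        "P_and_TxP": (0.0, e, 0.0, e),
        "T_P_TxP": (e, e, 0.0, e),
        # FI slope s = -e: flat southern norm, populations differ at 25C only
        "assimilation": (-e / 2.0, -e / 2.0, 0.0, e),
        # FI slope s = +e: flat southern norm, populations differ at 34C only
        "compensation": (e / 2.0, -e / 2.0, 0.0, -e),
        "sex": (0.0, 0.0, e, 0.0),
        "null": (0.0, 0.0, 0.0, 0.0),
    }


def default_truth_panel(
    n_genes_per_category: int = 100,
    effect_log2: float = 2.0,
    seed: int = 0,
    dispersion: float = 0.2,
    family_sd: float = 0.3,
    baseline_log_mean: tuple = (3.0, 6.0),
) -> list:
    """Balanced truth panel: one block of genes per reaction-norm category.

    Effect sizes are `effect_log2` on the log2 scale, converted to
    natural-log coefficients.  Baselines are drawn uniformly on the
    natural-log scale so the panel spans low- to high-expressed genes.
    """
    if effect_log2 <= 0:
        raise InvalidParameterError("effect_log2 must be > 0")
    rng = np.random.default_rng(seed)
    e = effect_log2 * LN2
    patterns = _panel_patterns(e)
    # directionally free categories alternate mirror-image sign patterns so
    # the panel stays balanced per condition (median-of-ratios assumes most
    # genes are not shifted in any one direction)
    mirrorable = {"TxP_only_reversal", "T_and_P", "T_and_TxP", "P_and_TxP",
                  "T_P_TxP", "sex"}
    truths = []
    for cat in CATEGORIES:
        base = patterns[cat]
        for i in range(n_genes_per_category):
            sign = -1.0 if (cat in mirrorable and i % 2) else 1.0
            bT, bP, bS, bTP = (sign * b for b in base)
            b0 = rng.uniform(*baseline_log_mean)
            truths.append(GeneTruth(
                gene_id=f"{cat}_{i:04d}",
                category=cat,
                beta0=b0, betaT=bT, betaP=bP, betaS=bS, betaTP=bTP,
                dispersion=dispersion, family_sd=family_sd,
            ))
    return truths


def truth_table(truths: list) -> pd.DataFrame:
    """Flat table of the per-gene ground truth (for TSV export)."""
    return pd.DataFrame([{
        "gene_id": t.gene_id, "category": t.category, "beta0": t.beta0,
        "betaT": t.betaT, "betaP": t.betaP, "betaS": t.betaS, "betaTP": t.betaTP,
        "dispersion": t.dispersion, "family_sd": t.family_sd,
    } for t in truths])
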