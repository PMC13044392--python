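"""End-to-end orchestration: simulate/load -> preprocess -> DE -> classify ->
network -> module stats -> enrichment, from a single YAML-able config.

Every stage writes TSV outputs under the configured output directory and
the run finishes with a JSON manifest recording seeds, input hashes,
gene/sample counts in and out of each stage, warnings, and the category
summary.  Seeds are namespaced per stage, so changing the enrichment
seed cannot alter DE results, and identical config + seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classify, enrichment, glmm, module_stats, network, preprocess, synthetic

log = logging.getLogger("reactionome")

STAGES = ("simulate", "preprocess", "de", "classify", "network", "modules", "enrich")


@dataclass
class RunConfig:
    # input paths (either counts+metadata, or a simulation stage)
    counts_path: str = None
    metadata_path: str = None
    annotation_path: str = None
    out_dir: str = "reactionome_out"
    # simulation block
    n_genes_per_category: int = 100
    effect_log2: float = 2.0
    dispersion: float = 0.2
    family_sd: float = 0.3
    size_factor_sd: float = 0.2
    # thresholds (the study's constants)
    q_cutoff: float = 0.05
    lfc_cutoff: float = 1.0
    filter_min_count: int = 5
    filter_max_low_samples: int = 80
    pseudocount: float = 1.0
    outlier_height_mads: float = 3.0
    bi_threshold: float = 1.0
    merge_eigengene_cor: float = 0.75
    min_module_size: int = 50
    deep_split: int = 4
    candidate_powers: tuple = (1, 2, 3, 4, 5, 6, 7, 8, 10, 12)
    lfc_scale: str = "count"
    n_boot: int = 500
    seed: int = 1
    stages: tuple = STAGES

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("candidate_powers", "stages"):
            if key in known:
                known[key] = tuple(known[key])
        return cls(**known)


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, manifest: dict, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
    manifest["outputs"][path.name] = _sha(path)


def _stage_seed(base: int, stage: str) -> int:
    h = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in asdict(config).items()},
                "stages": {}, "outputs": {}, "warnings": []}
    t_start = time.time()

    counts = meta = None
    truths = []
    # ---------------------------------------------------------------- input
    if "simulate" in config.stages and config.counts_path is None:
        seed = _stage_seed(config.seed, "simulate")
        design = synthetic.generate_design(synthetic.DesignSpec(), seed=seed)
        truths = synthetic.default_truth_panel(
            n_genes_per_category=config.n_genes_per_category,
            effect_log2=config.effect_log2, seed=seed,
            dispersion=config.dispersion, family_sd=config.family_sd)
        ds = synthetic.generate_counts(design, truths,
                                       size_factor_sd=config.size_factor_sd, seed=seed)
        counts, meta = ds.counts, ds.metadata
        _write(counts, out / "counts.tsv", manifest, index=True)
        _write(meta, out / "metadata.tsv", manifest)
        _write(synthetic.truth_table(truths), out / "truth.tsv", manifest)
        manifest["stages"]["simulate"] = {
            "n_genes": int(counts.shape[0]), "n_samples": int(counts.shape[1]),
            "seed": seed}
        log.info("simulate: %d genes x %d samples", *counts.shape)
    else:
        if config.counts_path is None or config.metadata_path is None:
            raise FileNotFoundError(
                "no simulation stage enabled and counts_path/metadata_path missing")
        for p in (config.counts_path, config.metadata_path):
            if not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")
        counts = pd.read_csv(config.counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(config.metadata_path, sep="\t")
        manifest["inputs"] = {"counts": _sha(Path(config.counts_path)),
                              "metadata": _sha(Path(config.metadata_path))}

    # ----------------------------------------------------------- preprocess
    sf = None
    logm = None
    if "preprocess" in config.stages:
        n0 = counts.shape[0]
        filtered = preprocess.filter_low_expression(
            counts, config.filter_min_count, config.filter_max_low_samples)
        norm = preprocess.compute_size_factors(filtered)
        sf = norm.size_factors
        logm = preprocess.moderated_log(filtered, norm, config.pseudocount)
        outliers = preprocess.flag_outlier_samples(logm, config.outlier_height_mads)
        if outliers:
            manifest["warnings"].append(f"outlier samples flagged: {outliers}")
        _write(filtered, out / "counts_filtered.tsv", manifest, index=True)
        _write(sf.to_frame(), out / "size_factors.tsv", manifest, index=True)
        _write(logm.values, out / "log_matrix.tsv", manifest, index=True)
        manifest["stages"]["preprocess"] = {
            "genes_in": int(n0), "genes_out": int(filtered.shape[0]),
            "reference_genes": norm.reference_genes_used,
            "outliers_flagged": outliers}
        counts = filtered
        log.info("preprocess: %d -> %d genes, %d outliers",
                 n0, counts.shape[0], len(outliers))

    # -------------------------------------------------------------------- DE
    de = None
    if "de" in config.stages:
        de = glmm.fit_all_genes(counts, meta, sf.to_numpy(),
                                q_cutoff=config.q_cutoff,
                                lfc_cutoff=config.lfc_cutoff,
                                lfc_scale=config.lfc_scale)
        _write(de.table.drop(columns=["gene_id"]), out / "de_results.tsv",
               manifest, index=True)
        n_conv = int(de.table["converged"].sum())
        n_sig = int((de.table[["sig_T", "sig_P", "sig_TP"]].any(axis=1)).sum())
        manifest["stages"]["de"] = {
            "genes": int(len(de.table)), "converged": n_conv,
            "non_converged": int(len(de.table)) - n_conv,
            "significant_any": n_sig}
        log.info("de: %d genes, %d converged, %d significant",
                 len(de.table), n_conv, n_sig)

    # -------------------------------------------------------------- classify
    calls = None
    if "classify" in config.stages and de is not None:
        calls = classify.classify_all(de, alpha=config.q_cutoff)
        summary = classify.category_summary(calls)
        _write(calls.drop(columns=["gene_id"]), out / "reactionome_calls.tsv",
               manifest, index=True)
        _write(summary, out / "category_summary.tsv", manifest)
        manifest["stages"]["classify"] = {
            "significant_genes": int(len(calls)),
            "assimilation": int((calls["plasticity_label"] == "assimilation").sum()),
            "compensation": int((calls["plasticity_label"] == "compensation").sum())}
        manifest["category_summary"] = summary.to_dict(orient="records")

    # --------------------------------------------------------------- network
    modules = None
    if "network" in config.stages and logm is not None:
        cfg = network.NetworkConfig(
            candidate_powers=tuple(config.candidate_powers),
            min_module_size=config.min_module_size,
            merge_eigengene_cor=config.merge_eigengene_cor,
            deep_split=config.deep_split)
        modules, labels, power, diag = network.detect_modules(logm.values, cfg)
        _write(labels.to_frame(), out / "module_assignment.tsv", manifest, index=True)
        if diag is not None:
            _write(diag, out / "soft_threshold_diagnostics.tsv", manifest)
            if bool(diag["selected_by_fallback"].iloc[0]):
                manifest["warnings"].append("soft-threshold fallback used")
        eig = pd.DataFrame({m.module_id: m.eigengene for m in modules}).T
        _write(eig, out / "eigengenes.tsv", manifest, index=True)
        manifest["stages"]["network"] = {
            "power": int(power), "n_modules": len(modules),
            "n_unassigned": int((labels == "unassigned").sum()),
            "module_sizes": {m.module_id: len(m.genes) for m in modules}}
        log.info("network: power %d, %d modules", power, len(modules))

    # --------------------------------------------------------------- modules
    mod_table = None
    if "modules" in config.stages and modules:
        mod_table = module_stats.analyse_modules(
            modules, meta, n_boot=config.n_boot,
            bi_threshold=config.bi_threshold, alpha=config.q_cutoff,
            seed=_stage_seed(config.seed, "modules"))
        _write(mod_table, out / "module_statistics.tsv", manifest)
        manifest["stages"]["modules"] = {
            "n_modules": int(len(mod_table)),
            "n_bimodal": int(mod_table["is_bimodal"].sum())}

    # ---------------------------------------------------------------- enrich
    if "enrich" in config.stages and config.annotation_path and calls is not None:
        annot = enrichment.read_annotation(config.annotation_path)
        universe = set(counts.index)
        seedless_queries = {"temperature": calls.index[calls["venn_category"].str.contains("T")],
                            "population": calls.index[calls["venn_category"].str.contains("P")]}
        enr_info = {}
        for name, genes in seedless_queries.items():
            res = enrichment.ora(set(genes) & universe, universe, annot,
                                 q_cutoff=config.q_cutoff)
            _write(res, out / f"enrichment_{name}.tsv", manifest)
            enr_info[name] = {"terms_tested": int(len(res)),
                              "significant": int(res["significant"].sum()) if len(res) else 0}
        manifest["stages"]["enrich"] = enr_info

    manifest["elapsed_s"] = round(time.time() - t_start, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
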