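"""End-to-end orchestration of the two contrasted workflows.

``run_pipeline`` chains simulate/load -> QC -> per-trait GWAS ->
candidate sets -> wrapper selection -> evaluation (internal CV and
external stratified bootstrap, for both the stringent-GWAS feature
source and the wrapper-selected marker source) -> optional rule mining
and eQTL annotation, writing every artifact as headered TSV/JSON into a
run directory.  Discovery and external cohorts must be disjoint by
sample id; overlap is a hard leakage error before any stage runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .annotation import AnnotationConfig, eqtl_join, filter_palindromic
from .classifiers import ClassifierSpec, build_classifier
from .comorbidity import mine_rules
from .containers import GenotypeMatrix, PhenotypeTable
from .evaluation import (
    BootstrapConfig,
    CVConfig,
    repeated_stratified_cv,
    stratified_bootstrap_external,
)
from .gwas import (
    CovariateModel,
    ThresholdConfig,
    candidate_union,
    lambda_gc,
    logistic_assoc,
    multiple_testing,
    pca_covariates,
)
from .qc import QCThresholds, apply_qc
from .selection import SearchConfig, fixed_subset_workflow
from .simulate import SimConfig, TraitModel, simulate_genotypes, simulate_phenotypes

_HEADER = "# snpwrap output; coordinates 1-based; genotypes = minor-allele counts\n"


class LeakageError(RuntimeError):
    """Discovery and external cohorts share sample ids."""


@dataclass
class SimulateSpec:
    """Synthetic-cohort settings for a pipeline run."""

    genotypes: SimConfig
    traits: dict[str, TraitModel]
    external_n_samples: int = 0


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    simulate: SimulateSpec | None = None
    genotype_prefix: str | None = None
    phenotype_path: str | None = None
    external_prefix: str | None = None
    external_phenotype_path: str | None = None
    visits_path: str | None = None
    rule_anchor: str | None = None
    eqtl_path: str | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    search: SearchConfig = field(default_factory=SearchConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    selection_classifier: str = "knn"
    #: hyperparameters for the wrapper classifier; 5-NN smooths the
    #: high-variance 1-NN LOOCV score during subset search
    selection_hyperparameters: dict = field(default_factory=lambda: {"n_neighbors": 5})
    final_classifier: str = "random_forest"
    n_pcs: int = 0
    run_qc: bool = True
    run_selection: bool = True
    run_evaluation: bool = True

    def validate(self) -> None:
        if self.simulate is None and self.genotype_prefix is None:
            raise ValueError(
                "no input: set either simulate or genotype_prefix/phenotype_path"
            )
        if self.genotype_prefix is not None and self.phenotype_path is None:
            raise ValueError("genotype_prefix requires phenotype_path")


def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df, index=True).values.tobytes()
    ).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER)
        df.to_csv(fh, sep="\t", index=False)


def _load_discovery(config: PipelineConfig):
    if config.simulate is not None:
        sim = config.simulate
        G = simulate_genotypes(sim.genotypes)
        phen, truth = simulate_phenotypes(G, sim.traits, seed=config.seed + 1)
        external = None
        if sim.external_n_samples > 0:
            ext_cfg = SimConfig(
                n_samples=sim.external_n_samples,
                n_snps=sim.genotypes.n_snps,
                maf_low=sim.genotypes.maf_low,
                maf_high=sim.genotypes.maf_high,
                ld_block_size=sim.genotypes.ld_block_size,
                ld_rho=sim.genotypes.ld_rho,
                missing_rate=sim.genotypes.missing_rate,
                seed=config.seed + 1_000_003,
            )
            G_ext = simulate_genotypes(ext_cfg)
            G_ext.sample_ids = [f"E{s}" for s in G_ext.sample_ids]
            phen_ext, _ = simulate_phenotypes(
                G_ext, sim.traits, seed=config.seed + 1_000_004
            )
            phen_ext.table["sample_id"] = [
                f"E{s}" if not s.startswith("E") else s
                for s in phen_ext.table["sample_id"]
            ]
            external = (G_ext, phen_ext)
        return G, phen, truth, external
    G, _ = sio.read_genotypes(config.genotype_prefix)
    phen = sio.read_phenotypes(config.phenotype_path)
    external = None
    if config.external_prefix is not None:
        G_ext, _ = sio.read_genotypes(config.external_prefix)
        phen_ext = sio.read_phenotypes(config.external_phenotype_path)
        external = (G_ext, phen_ext)
    return G, phen, None, external


def _align_external(G_ext: GenotypeMatrix, snp_ids: list[str]) -> np.ndarray:
    """External genotype columns for the given SNPs, mean-imputed."""
    pos = {s: j for j, s in enumerate(G_ext.snp_ids)}
    missing = [s for s in snp_ids if s not in pos]
    if missing:
        raise ValueError(f"external cohort lacks selected SNPs: {missing[:5]}")
    X = G_ext.genotypes[:, [pos[s] for s in snp_ids]]
    if np.isnan(X).any():
        X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
    return X


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; return a manifest of artifacts."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    G, phen, truth, external = _load_discovery(config)
    manifest: dict = {
        "seed": config.seed,
        "n_samples": G.n_samples,
        "n_snps": G.n_snps,
        "traits": phen.traits,
        "artifacts": [],
        "input_digests": {
            "genotypes": _digest(pd.DataFrame(np.nan_to_num(G.genotypes, nan=-1.0))),
            "phenotypes": _digest(phen.table),
        },
    }

    # leakage guard: discovery and external ids must be disjoint
    if external is not None:
        overlap = set(G.sample_ids) & set(external[0].sample_ids)
        if overlap:
            raise LeakageError(
                f"discovery/external sample overlap: {sorted(overlap)[:5]}"
            )
        manifest["external_ids_disjoint"] = True
        manifest["n_external"] = external[0].n_samples

    if truth is not None:
        sio.write_ground_truth(
            {
                "causal_snp_ids": truth.causal_snp_ids,
                "interaction_pairs": [list(p) for p in truth.interaction_pairs],
                "prevalence": truth.prevalence,
            },
            outdir / "ground_truth.json",
        )
        manifest["artifacts"].append("ground_truth.json")

    # ---------------------------------------------------------------- QC
    if config.run_qc:
        strict_controls = np.ones(G.n_samples, dtype=bool)
        for trait in phen.traits:
            y = phen.binary(trait, G.sample_ids)
            strict_controls &= y == 0
        mask = strict_controls if strict_controls.any() else None
        G, report = apply_qc(G, mask, config.qc)
        _write_tsv(report.to_frame(), outdir / "qc_report.tsv")
        report.to_json(outdir / "qc_report.json")
        manifest["artifacts"] += ["qc_report.tsv", "qc_report.json"]
        manifest["n_snps_post_qc"] = G.n_snps
        manifest["n_samples_post_qc"] = G.n_samples

    # ---------------------------------------------------------------- GWAS
    sex = G.sex if G.sex is not None else np.zeros(G.n_samples)
    if config.n_pcs > 0:
        pcs = pca_covariates(G, config.n_pcs)
        model = CovariateModel.sex_plus_pcs(sex, pcs)
    else:
        model = CovariateModel.sex_only(sex)

    assoc: dict[str, pd.DataFrame] = {}
    inflation: dict[str, float] = {}
    for trait in phen.traits:
        y = phen.binary(trait, G.sample_ids)
        res = logistic_assoc(G, y, model)
        assoc[trait] = res
        _write_tsv(res, outdir / f"assoc_{trait}.tsv")
        ok_p = res.loc[res["status"] == "ok", "p_value"].to_numpy()
        rep = lambda_gc(ok_p, n_qq=1000)
        rep.to_json(outdir / f"lambda_{trait}.json")
        inflation[trait] = rep.lambda_gc
        bonf, _ = multiple_testing(ok_p, config.thresholds)
        manifest["artifacts"] += [f"assoc_{trait}.tsv", f"lambda_{trait}.json"]
        manifest.setdefault("bonferroni_cutoff", bonf)
    manifest["lambda_gc"] = inflation

    stringent_union, stringent_sets = candidate_union(assoc, config.thresholds.stringent_p)
    lenient_union, lenient_sets = candidate_union(assoc, config.thresholds.lenient_p)
    with open(outdir / "candidates.json", "w") as fh:
        json.dump(
            {
                "stringent_p": config.thresholds.stringent_p,
                "lenient_p": config.thresholds.lenient_p,
                "stringent": {t: sorted(s) for t, s in stringent_sets.items()},
                "lenient": {t: sorted(s) for t, s in lenient_sets.items()},
                "stringent_union": sorted(stringent_union),
                "lenient_union": sorted(lenient_union),
            },
            fh,
            indent=2,
        )
    manifest["artifacts"].append("candidates.json")
    manifest["stringent_union_size"] = len(stringent_union)
    manifest["lenient_union_size"] = len(lenient_union)

    # ---------------------------------------------------------------- selection
    markers: dict[str, list[str]] = {}
    if config.run_selection:
        snp_index = {s: j for j, s in enumerate(G.snp_ids)}
        hp = config.selection_hyperparameters if config.selection_classifier == "knn" else {}
        spec = ClassifierSpec(config.selection_classifier, hp, seed=config.seed)
        rows = []
        for trait in phen.traits:
            y = phen.binary(trait, G.sample_ids)
            pool = sorted(lenient_sets[trait])
            if not pool:
                markers[trait] = []
                continue
            cand = np.array([snp_index[s] for s in pool])
            complete = ~np.isnan(y)
            X = np.nan_to_num(
                G.genotypes[complete],
                nan=0.0,
            )
            result = fixed_subset_workflow(
                X, y[complete].astype(int), spec, config.search, cand
            )
            chosen = [G.snp_ids[j] for j in result.features]
            markers[trait] = chosen
            rows += [
                {"trait": trait, "snp_id": s, "rank": r + 1}
                for r, s in enumerate(chosen)
            ]
        _write_tsv(pd.DataFrame(rows, columns=["trait", "snp_id", "rank"]),
                   outdir / "markers.tsv")
        manifest["artifacts"].append("markers.tsv")
        manifest["marker_counts"] = {t: len(s) for t, s in markers.items()}

    # ---------------------------------------------------------------- evaluation
    if config.run_evaluation and config.run_selection:
        snp_index = {s: j for j, s in enumerate(G.snp_ids)}
        grid_rows = []
        for trait in phen.traits:
            y = phen.binary(trait, G.sample_ids)
            complete = ~np.isnan(y)
            yb = y[complete].astype(int)
            sources = {
                "gwas_stringent": sorted(stringent_sets[trait]),
                "marker_selection": markers.get(trait, []),
            }
            for source, snps in sources.items():
                row = {"trait": trait, "feature_source": source, "n_snps": len(snps)}
                if snps and len(np.unique(yb)) == 2:
                    cols = [snp_index[s] for s in snps]
                    X = np.nan_to_num(G.genotypes[complete][:, cols], nan=0.0)
                    clf = build_classifier(config.final_classifier, seed=config.seed)
                    counts = np.bincount(yb)
                    k = min(config.cv.k, counts[counts > 0].min())
                    if k >= 2:
                        cv_cfg = CVConfig(k=k, repeats=config.cv.repeats,
                                          seed=config.seed)
                        internal = repeated_stratified_cv(X, yb, clf, cv_cfg)
                        row["cv_accuracy_mean"] = internal["accuracy"].mean
                        row["cv_accuracy_sd"] = internal["accuracy"].sd
                        row["cv_auc_mean"] = internal["auc"].mean
                    model = clf.fit(X, yb)
                    if external is not None:
                        G_ext, phen_ext = external
                        y_ext = phen_ext.binary(trait, G_ext.sample_ids)
                        ce = ~np.isnan(y_ext)
                        X_ext = _align_external(G_ext.take_samples(ce), snps)
                        ye = y_ext[ce].astype(int)
                        if len(np.unique(ye)) == 2:
                            boot_cfg = BootstrapConfig(
                                B=config.bootstrap.B,
                                ci_level=config.bootstrap.ci_level,
                                seed=config.seed,
                            )
                            ext = stratified_bootstrap_external(model, X_ext, ye, boot_cfg)
                            row["ext_accuracy_mean"] = ext["accuracy"].mean
                            row["ext_accuracy_sd"] = ext["accuracy"].sd
                            row["ext_accuracy_ci_low"] = ext["accuracy"].ci_low
                            row["ext_accuracy_ci_high"] = ext["accuracy"].ci_high
                            row["ext_auc_mean"] = ext["auc"].mean
                grid_rows.append(row)
        _write_tsv(pd.DataFrame(grid_rows), outdir / "evaluation_grid.tsv")
        manifest["artifacts"].append("evaluation_grid.tsv")

    # ---------------------------------------------------------------- rules
    if config.visits_path is not None and config.rule_anchor is not None:
        visits = sio.read_visits(config.visits_path)
        rules, edges = mine_rules(visits, config.rule_anchor)
        _write_tsv(rules, outdir / "rules.tsv")
        _write_tsv(edges, outdir / "rule_edges.tsv")
        manifest["artifacts"] += ["rules.tsv", "rule_edges.tsv"]

    # ---------------------------------------------------------------- annotation
    if config.eqtl_path is not None and config.run_selection:
        eqtl = pd.read_csv(config.eqtl_path, sep="\t")
        selected_ids = sorted({s for snps in markers.values() for s in snps})
        sel = G.variants[G.variants["snp_id"].isin(selected_ids)].copy()
        from .qc import compute_maf

        maf = compute_maf(G)
        sel["maf"] = [maf[G.snp_ids.index(s)] for s in sel["snp_id"]]
        retained, excluded = filter_palindromic(sel, config.annotation)
        ann = eqtl_join(retained, eqtl, config.annotation)
        _write_tsv(ann, outdir / "annotation.tsv")
        _write_tsv(excluded, outdir / "annotation_excluded.tsv")
        manifest["artifacts"] += ["annotation.tsv", "annotation_excluded.tsv"]

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
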