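"""End-to-end orchestration: simulate/ingest -> stratify -> DE -> enrichment ->
signature scoring -> predictor comparison -> dependency -> target nomination ->
perturbation clustering -> survival, with a run manifest for provenance.

Stages communicate through on-disk TSV/GMT/JSON artifacts so each is
independently inspectable and resumable; every run is a pure function of
(inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import biomarker, clinical, cohort, dependency, diffexpr, genesets, mutclass
from . import perturbcluster, synthetic
from .core_io import Config, PanelBundle, file_digest, write_gmt, write_json, write_matrix

logger = logging.getLogger("depresist")


@dataclass
class RunManifest:
    config: dict
    seed: int
    outputs: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    digests: dict = field(default_factory=dict)

    def record(self, stage: str, path: Path, elapsed: float) -> None:
        self.outputs[stage] = str(path)
        self.timings[stage] = round(elapsed, 4)
        if path.exists() and path.is_file():
            self.digests[stage] = file_digest(path)

    def write(self, path: Path) -> None:
        write_json(self.__dict__, path)


def run_all(
    config: Config,
    out_dir: str | Path,
    recipe: synthetic.PanelRecipe | None = None,
    bundle: PanelBundle | None = None,
    druggable_genes: list[str] | None = None,
) -> RunManifest:
    """Execute the full analysis on a simulated (or supplied) panel.

    With ``recipe`` (or neither argument) a synthetic panel is generated at
    ``config.seed``; with ``bundle`` the supplied data are analysed.  Stage
    failures abort with the failing stage named.  Returns the manifest, also
    written to ``out_dir/manifest.json``.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)
    truth = None

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest.timings[name] = round(time.perf_counter() - t0, 4)
        return result

    # --- data ---
    if bundle is None:
        recipe = recipe or synthetic.PanelRecipe(seed=config.seed)
        panel = stage("simulate", lambda: synthetic.generate_panel(recipe, seed=config.seed))
        bundle = panel.bundle
        truth = panel.truth
        write_matrix(bundle.expression, out / "expression.tsv")
        write_matrix(bundle.responses, out / "responses.tsv")
        bundle.mutations.to_csv(out / "mutations.tsv", sep="\t", index=False)
        write_matrix(bundle.effects, out / "effects.tsv")
        write_gmt(truth["planted_sets"], out / "gene_sets.gmt")
        with open(out / "truth.json", "w") as fh:
            json.dump(
                {
                    "classV_lines": truth["classV_lines"],
                    "signature_genes": truth["signature_genes"],
                    "dep_genes": truth["dep_genes"],
                    "sensitive_tail": truth["sensitive_tail"],
                    "resistant_tail": truth["resistant_tail"],
                },
                fh, indent=2,
            )
        manifest.record("simulate", out / "expression.tsv", manifest.timings["simulate"])
    collection = truth["planted_sets"] if truth else {}
    if druggable_genes is None and truth is not None:
        druggable = [g for g, (side, _) in truth["dep_genes"].items() if side == "R"]
        druggable = druggable + list(bundle.effects.index[:10])
    else:
        druggable = druggable_genes or []

    # --- stratify ---
    mean_auc = bundle.responses.mean(axis=1)
    groups = stage("stratify", lambda: cohort.assign_sensitivity_groups(mean_auc, config.fraction))
    groups.labels().to_frame().to_csv(out / "groups.tsv", sep="\t")
    manifest.record("stratify", out / "groups.tsv", manifest.timings["stratify"])

    # --- mutation classes ---
    classes = stage("mutclass", lambda: mutclass.classify_panel(
        bundle.mutations, bundle.cell_lines))
    assoc = mutclass.class_auc_association(mean_auc, classes)
    assoc.to_csv(out / "class_auc_association.tsv", sep="\t")
    manifest.record("mutclass", out / "class_auc_association.tsv", manifest.timings["mutclass"])

    # --- differential expression (R vs S: logFC = R minus S) ---
    de = stage("de", lambda: diffexpr.moderated_t_test(
        bundle.expression, groups.resistant, groups.sensitive))
    de["direction"] = diffexpr.direction_labels(de, config.de_fdr, config.de_fc)
    de.drop(columns=["zero_variance"]).to_csv(out / "de.tsv", sep="\t")
    manifest.record("de", out / "de.tsv", manifest.timings["de"])

    # --- GSEA on the DE ranking ---
    ranked = de["t"].sort_values(ascending=False)
    nperm = config.gsea_nperm
    gsea_res = stage("gsea", lambda: genesets.gsea(
        ranked, collection, nperm=nperm, min_size=config.gsea_min_size,
        max_size=config.gsea_max_size, seed=config.seed))
    gsea_out = gsea_res.drop(columns=["leading_edge"]).copy()
    gsea_out["pathway_score"] = [
        genesets.pathway_score(r.NES, r.FDR, nperm) if pd.notna(r.NES) and pd.notna(r.FDR)
        else float("nan")
        for r in gsea_res.itertuples()
    ]
    gsea_out.to_csv(out / "gsea.tsv", sep="\t")
    manifest.record("gsea", out / "gsea.tsv", manifest.timings["gsea"])

    # --- ssGSEA signature scores + predictor comparison ---
    sig_scores = stage("ssgsea", lambda: genesets.ssgsea_matrix(
        bundle.expression, collection, alpha=config.ssgsea_alpha))
    sig_scores.T.to_csv(out / "ssgsea.tsv", sep="\t")
    manifest.record("ssgsea", out / "ssgsea.tsv", manifest.timings["ssgsea"])

    mut_scores = classes.map(lambda c: mutclass.mutation_score(c))
    predictors = sig_scores.T.copy()
    predictors["mutation_score"] = mut_scores
    labels = biomarker.sensitivity_labels(groups, bundle.cell_lines)
    pred_cmp = stage("predict", lambda: biomarker.compare_predictors(
        predictors, labels, n_boot=200, seed=config.seed))
    pred_cmp.to_csv(out / "predictors.tsv", sep="\t")
    manifest.record("predict", out / "predictors.tsv", manifest.timings["predict"])

    # --- dependency + nomination ---
    if bundle.effects is not None:
        viable = stage("viability", lambda: dependency.viability_filter(
            bundle.effects, groups.sensitive, groups.resistant, config.dependency_tau))
        dep = stage("dependency", lambda: dependency.differential_dependency(
            bundle.effects.loc[viable] if viable else bundle.effects,
            groups.sensitive, groups.resistant))
        dep.to_csv(out / "dependency.tsv", sep="\t")
        manifest.record("dependency", out / "dependency.tsv", manifest.timings["dependency"])
        nom = stage("nominate", lambda: dependency.nominate_targets(
            dep, druggable, config.dependency_top_k))
        nom.to_csv(out / "targets.tsv", sep="\t")
        manifest.record("nominate", out / "targets.tsv", manifest.timings["nominate"])

    # --- perturbation clustering ---
    pert, pert_truth = stage("perturb_sim", lambda: synthetic.generate_perturbation_experiment(
        seed=config.seed))
    z = perturbcluster.z_transform(pert)
    assign = stage("cluster", lambda: perturbcluster.hierarchical_clusters(z, config.cluster_k))
    assign.labels.to_frame().to_csv(out / "clusters.tsv", sep="\t")
    enr = perturbcluster.cluster_enrichment(assign, pert_truth["cluster_sets"], top_n=5)
    enr.to_csv(out / "cluster_enrichment.tsv", sep="\t", index=False)
    coords, explained = perturbcluster.pca_projection(z, n_components=2)
    coords.to_csv(out / "pca.tsv", sep="\t")
    manifest.record("cluster", out / "clusters.tsv", manifest.timings["cluster"])

    # --- survival ---
    surv, _ = stage("survival_sim", lambda: synthetic.generate_survival_cohort(
        n=500, hr=3.0, seed=config.seed))
    chi2, lr_p = clinical.log_rank_test(surv)
    cox = clinical.cox_hr(surv)
    surv_summary = {"logrank_chi2": chi2, "logrank_p": lr_p, **cox}
    write_json(surv_summary, out / "survival.json")
    manifest.record("survival", out / "survival.json", manifest.timings.get("survival_sim", 0))

    manifest.write(out / "manifest.json")
    return manifest
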