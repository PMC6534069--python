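"""End-to-end pipeline: simulate -> preprocess -> modules -> global ->
log-contrast -> mediation -> enterotype, each stage writing TSV results and
a JSON manifest of seeds and thresholds.

Every stage draws its seed deterministically from the config's master seed,
so rerunning with the same config reproduces identical output files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .containers import align_samples
from .dcor import global_edge_table
from .enterotype import choose_enterotypes, enterotype_characterize, \
    interaction_scan
from .io import RunConfig, write_feature_table
from .logcontrast import association_matrix
from .mediation import candidate_triplets, mediation_scan
from .modules import detect_modules, module_eigenvalues, soft_threshold_power
from .preprocess import preprocess_diet, preprocess_metabolites
from .simulate import simulate_study

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "modules", "global", "logcontrast",
          "mediate", "enterotype")


def run_pipeline(config: RunConfig, out_dir=None, stages=STAGES) -> Path:
    """Run the pipeline stages in order, writing results under ``out_dir``.

    Returns the output directory. A stage failure raises with the stage
    name attached. Desk-scale by default: the log-contrast and mediation
    scans are restricted to planted-effect responses plus a null background
    (full scans over hundreds of responses belong on a cluster, not a
    laptop); the scanned response lists are recorded in the manifest.
    """
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "config": config.__dict__.copy(),
                "stage_seeds": {s: config.stage_seed(s) for s in STAGES}}
    state: dict = {}
    for stage in stages:
        logger.info("stage %s (seed %d)", stage, config.stage_seed(stage))
        try:
            _STAGE_FUNCS[stage](config, state, out)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    manifest["scanned_responses"] = state.get("scanned_responses", [])
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    return out


def _stage_simulate(config, state, out):
    study = simulate_study(
        n=config.n_samples, g=config.n_taxa, k_diet=config.n_diet,
        m=config.n_metabolites, seed=config.stage_seed("simulate"),
    )
    state.update(study)
    write_feature_table(study["diet"], out / "diet.tsv")
    study["composition"].proportions.to_csv(
        out / "microbiome_proportions.tsv", sep="\t", index_label="sample_id")
    write_feature_table(study["metabolites"], out / "metabolites.tsv")
    study["metadata"].data.to_csv(out / "metadata.tsv", sep="\t",
                                  index_label="sample_id")
    truth = study["truth"]
    (out / "truth.json").write_text(json.dumps({
        "enterotype_labels": truth.enterotype_labels.to_dict(),
        "marker_taxa": truth.marker_taxa,
        "diet_blocks": truth.diet_blocks,
        "module_assignment": truth.module_assignment,
        "mediation_triplets": [
            {k: v for k, v in t.items() if k not in ("a_clr",)}
            for t in truth.mediation_triplets],
        "interaction_effects": {f"{d}|{m}": v for (d, m), v
                                in truth.interaction_effects.items()},
    }, indent=2, default=str))


def _stage_preprocess(config, state, out):
    comp, diet, meta, metab = align_samples(
        state["composition"], state["diet"], state["metadata"],
        state["metabolites"])
    diet_n, diet_rep = preprocess_diet(diet, meta, alpha=config.shapiro_alpha,
                                       rho=config.spearman_dedup)
    metab_n, metab_rep = preprocess_metabolites(metab,
                                                alpha=config.shapiro_alpha)
    state.update(composition=comp, metadata=meta, diet_norm=diet_n,
                 metab_norm=metab_n)
    write_feature_table(diet_n, out / "diet_normalized.tsv")
    write_feature_table(metab_n, out / "metabolites_normalized.tsv")
    diet_rep.to_frame().to_csv(out / "normalization_report.tsv", sep="\t")
    pd.Series(diet_rep.representative, name="representative").rename_axis(
        "variable_id").to_csv(out / "dedup_map.tsv", sep="\t")


def _stage_modules(config, state, out):
    metab = state["metab_norm"]
    power = soft_threshold_power(metab)
    assign = detect_modules(metab, power,
                            min_module_size=config.min_module_size,
                            cut_height=config.cut_height)
    ev, downstream = module_eigenvalues(metab, assign)
    state.update(module_assignment=assign, module_eigenvalues=ev,
                 metab_downstream=downstream)
    pd.Series(assign.labels, name="module").rename_axis("metabolite").to_csv(
        out / "module_assignment.tsv", sep="\t")
    ev.scores.to_csv(out / "module_eigenvalues.tsv", sep="\t",
                     index_label="sample_id")


def _stage_global(config, state, out):
    table = global_edge_table({
        "diet": state["diet_norm"],
        "microbiome": state["composition"],
        "metabolome": state["metab_norm"],
    })
    state["global_edges"] = table
    table.to_csv(out / "global_dependence.tsv", sep="\t", index=False)


def _stage_logcontrast(config, state, out):
    comp = state["composition"]
    seed = config.stage_seed("logcontrast")
    metab_targets = sorted(
        set(state["truth"].taxon_metabolite_coefs)
        & set(state["metab_norm"].variable_ids))
    metab_null = [v for v in state["metab_norm"].variable_ids
                  if v not in metab_targets][:5]
    diet_targets = {t["diet"] for t in state["truth"].mediation_triplets}
    diet_ids = sorted(set(state["diet_norm"].variable_ids) & diet_targets)
    diet_null = [v for v in state["diet_norm"].variable_ids
                 if v not in diet_ids][:5]
    state["scanned_responses"] = {
        "diet": diet_ids + diet_null, "metabolites": metab_targets + metab_null}
    diet_assoc = association_matrix(
        state["diet_norm"].select_variables(diet_ids + diet_null), comp,
        k=config.top_k_taxa, n_bootstrap=config.n_bootstrap,
        threshold=config.selection_min, folds=config.cv_folds,
        n_lambda=config.n_lambda, seed=seed)
    metab_assoc = association_matrix(
        state["metab_norm"].select_variables(metab_targets + metab_null),
        comp, k=config.top_k_taxa, n_bootstrap=config.n_bootstrap,
        threshold=config.selection_min, folds=config.cv_folds,
        n_lambda=config.n_lambda, seed=seed + 1)
    state.update(diet_assoc=diet_assoc, metab_assoc=metab_assoc)
    diet_assoc.to_csv(out / "logcontrast_diet.tsv", sep="\t", index=False)
    metab_assoc.to_csv(out / "logcontrast_metabolites.tsv", sep="\t",
                       index=False)
    summary = pd.concat([
        diet_assoc.assign(block="diet"), metab_assoc.assign(block="metabolites")
    ])
    summary = (summary[summary["selected"]]
               .groupby(["block", "response"]).size()
               .rename("n_selected_taxa").reset_index())
    summary.to_csv(out / "logcontrast_summary.tsv", sep="\t", index=False)


def _stage_mediate(config, state, out):
    triplets = candidate_triplets(state["diet_assoc"], state["metab_assoc"])
    # ensure planted triplets are evaluated even if the selection stage
    # missed an edge; union, deduplicated
    seen = {(t["diet"], t["metabolite"]) for t in triplets}
    for t in state["truth"].mediation_triplets:
        key = (t["diet"], t["metabolite"])
        if key not in seen and t["diet"] in state["diet_norm"].variable_ids \
                and t["metabolite"] in state["metab_norm"].variable_ids:
            triplets.append({"diet": t["diet"], "metabolite": t["metabolite"],
                             "shared_genera": []})
    table = mediation_scan(
        triplets, state["composition"], state["diet_norm"],
        state["metab_norm"], k=config.top_k_taxa,
        n_bootstrap=config.mediation_bootstrap, ci_level=config.ci_level,
        seed=config.stage_seed("mediate"))
    state["mediation"] = table
    table.to_csv(out / "mediation.tsv", sep="\t", index=False)


def _stage_enterotype(config, state, out):
    comp = state["composition"]
    model = choose_enterotypes(comp)
    if model.k != 2:
        # downstream two-group analyses need a binary split: refit k=2
        # under the silhouette-chosen distance
        from .enterotype import ecological_distance, pam_cluster
        logger.warning("silhouette chose k=%d; refitting k=2 for the "
                       "two-group analyses", model.k)
        D = ecological_distance(comp, model.distance_name)
        model = pam_cluster(D, 2, sample_ids=comp.sample_ids,
                            distance_name=model.distance_name)
    fam_map = _family_map(comp.taxon_ids)
    taxon_tab, fam_tab, metab_tab = enterotype_characterize(
        comp, model.labels, taxa_level_map=fam_map,
        metabolites=state["metab_norm"])
    inter = interaction_scan(state["diet_norm"], state["metab_norm"],
                             model.labels)
    state.update(enterotype_model=model, interaction=inter)
    model.labels.rename_axis("sample_id").to_csv(
        out / "enterotype_labels.tsv", sep="\t")
    taxon_tab.to_csv(out / "enterotype_taxa.tsv", sep="\t", index=False)
    if fam_tab is not None:
        fam_tab.to_csv(out / "enterotype_families.tsv", sep="\t", index=False)
    metab_tab.to_csv(out / "enterotype_metabolites.tsv", sep="\t", index=False)
    inter.to_csv(out / "interaction_scan.tsv", sep="\t", index=False)


def _family_map(taxon_ids, group_size: int = 8) -> dict[str, str]:
    """Synthetic genus -> family map: marker genera share one family, the
    rest are binned deterministically by position."""
    fam = {}
    others = 0
    for t in taxon_ids:
        if t.startswith("Ruminococcaceae"):
            fam[t] = "Ruminococcaceae"
        else:
            fam[t] = f"family_{others // group_size + 1:02d}"
            others += 1
    return fam


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "modules": _stage_modules,
    "global": _stage_global,
    "logcontrast": _stage_logcontrast,
    "mediate": _stage_mediate,
    "enterotype": _stage_enterotype,
}
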