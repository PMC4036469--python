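"""End-to-end orchestration: simulate -> preprocess -> derive -> score ->
classify -> survival -> drug response.

A single configuration dictionary (YAML-friendly) drives the run; every
artifact is written under the output directory and recorded, with its
SHA-256 hash, in ``manifest.json`` together with the resolved parameters.
All randomness flows from one seed through named per-stage generators, so
reruns with the same configuration are byte-identical.
"""

from __future__ import annotations

import contextlib
import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from . import io as xio
from ._utils import sha256_file
from .drug import correlate_score_ic50
from .preprocess import collapse_probesets, median_center_iqr_normalize
from .scoring import classify, normalize_scores, score_by_group, score_samples
from .signature import ALLELES, build_signature, derive_allele_gene_lists, \
    fit_allele_models, venn_counts
from .simulate import CELL_LINE_COMPOUNDS, SimConfig, make_homolog_map, \
    simulate_cell_lines, simulate_gemm_cohort, simulate_human_cohort
from .survival import clinical_enrichment, endpoint_suite

log = logging.getLogger(__name__)

class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


@contextlib.contextmanager
def _stage(name: str):
    try:
        yield
    except Exception as err:
        raise StageError(f"pipeline stage {name!r} failed: {err}") from err


DEFAULT_PARAMS = {
    "alpha": 0.01,            # per-gene significance threshold for gene lists
    "k": 100,                 # signature size per arm
    "top_n_variable": 500,    # exploratory top-variable gene count
    "min_coverage": 0.5,      # minimum signature-arm coverage when scoring
    "survival_cutoff": 84.0,  # months of administrative truncation
}


def run_pipeline(config: dict | None = None, out_dir: str | Path = "runs/out",
                 seed: int = 0) -> dict:
    """Execute the full analysis and return the manifest.

    ``config`` may carry a ``sim`` block (SimConfig fields), parameter
    overrides (alpha, k, min_coverage, survival_cutoff), and optional
    external inputs (``expression``, ``annotation``, ``design`` paths) that
    replace the mouse simulation stage.
    """
    config = dict(config or {})
    params = {**DEFAULT_PARAMS, **{k: v for k, v in config.items()
                                   if k in DEFAULT_PARAMS}}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save(name: str, writer, *args) -> None:
        path = out / name
        writer(*args, path)
        artifacts[name] = sha256_file(path)

    sim_cfg = SimConfig(seed=seed, **config.get("sim", {}))

    # --- mouse cohort (simulated unless supplied externally) -------------
    stage = "simulated"
    with _stage("mouse_cohort"):
        if "expression" in config:
            stage = "external"
            expr = xio.read_expression_tsv(config["expression"])
            ann = xio.read_annotation_csv(config["annotation"])
            design = xio.read_design_csv(config["design"])
            truth = None
        else:
            expr, ann, design, truth = simulate_gemm_cohort(sim_cfg)
            save("gemm_expression.tsv", xio.write_expression_tsv, expr)
            save("gemm_annotation.csv", xio.write_annotation_csv, ann)
            save("gemm_design.csv", xio.write_table_csv, design)
            save("gemm_ground_truth.json", xio.write_ground_truth_json, truth)
    log.info("mouse cohort (%s): %d probesets x %d samples", stage,
             *expr.shape)

    # --- preprocess ------------------------------------------------------
    with _stage("preprocess"):
        genes = collapse_probesets(expr, ann)
        norm = median_center_iqr_normalize(genes)
        save("gemm_gene_matrix.tsv", xio.write_expression_tsv, genes)

    # --- derive signatures ----------------------------------------------
    effects = fit_allele_models(genes, design)
    lists = derive_allele_gene_lists(effects, alpha=params["alpha"])
    signatures = {a: build_signature(a, lists[a], effects, k=params["k"],
                                     alpha=params["alpha"])
                  for a in ALLELES}
    save("allele_effects.tsv",
         lambda df, p: df.to_csv(p, sep="\t", index=False,
                                 float_format=xio.FLOAT_FMT), effects)
    save("signatures.gmt", xio.write_signatures_gmt, signatures)
    venn = {"up": venn_counts({a: lists[a]["up"] for a in ALLELES}),
            "down": venn_counts({a: lists[a]["down"] for a in ALLELES})}
    save("venn_counts.json",
         lambda v, p: Path(p).write_text(json.dumps(
             {d: {"+".join(k): c for k, c in v[d].items()} for d in v},
             indent=1, sort_keys=True)), venn)

    # --- internal validation: scores per genotype ------------------------
    rows = []
    for allele, sig in signatures.items():
        sv = normalize_scores(score_samples(norm, sig,
                                            params["min_coverage"]))
        for s, val in sv.scores.items():
            rows.append({"sample": s, "genotype": design.loc[s, "genotype"],
                         "allele": allele, "score": val})
    save("gemm_scores.csv",
         lambda df, p: df.to_csv(p, index=False, float_format=xio.FLOAT_FMT),
         pd.DataFrame(rows))

    # --- human cohort ----------------------------------------------------
    homologs = make_homolog_map(genes.index, seed=seed)
    h_expr, h_labels, h_surv, h_truth = simulate_human_cohort(
        sim_cfg, signatures, homologs)
    m2h = pd.Series(homologs["target"].values, index=homologs["source"].values)
    h_norm = median_center_iqr_normalize(h_expr)
    kras_sig = signatures["Kras"].translated(m2h)
    h_scores = normalize_scores(score_samples(h_norm, kras_sig,
                                              params["min_coverage"]))
    call = classify(h_scores, mode="zero_threshold")
    groups = score_by_group(h_scores, h_labels)
    surv_table = endpoint_suite(h_surv, call, cutoff=params["survival_cutoff"])
    enrich = clinical_enrichment(
        call, h_surv[["kras_status", "braf_status", "stage", "msi",
                      "mucinous", "site"]])
    save("human_scores.csv",
         lambda df, p: df.to_csv(p, float_format=xio.FLOAT_FMT),
         pd.DataFrame({"score": h_scores.scores, "call": call,
                       "kras_status": h_labels}))
    save("human_survival.csv", xio.write_table_csv, h_surv)
    save("survival_endpoints.csv", xio.write_table_csv, surv_table)
    save("clinical_enrichment.csv", xio.write_table_csv, enrich)

    # --- cell lines ------------------------------------------------------
    c_expr, dose, c_truth = simulate_cell_lines(sim_cfg, kras_sig)
    c_scores = normalize_scores(score_samples(
        median_center_iqr_normalize(c_expr), kras_sig,
        params["min_coverage"]))
    drug_stats = {comp: correlate_score_ic50(c_scores, dose, comp)
                  for comp in CELL_LINE_COMPOUNDS}
    save("cell_line_ic50.csv",
         lambda df, p: df.to_csv(p, index=False, float_format=xio.FLOAT_FMT),
         dose)
    save("drug_response.json",
         lambda d, p: Path(p).write_text(json.dumps(d, indent=1,
                                                    sort_keys=True)), drug_stats)

    manifest = {
        "seed": seed,
        "parameters": params,
        "sim_config": {k: (dict(v) if isinstance(v, dict) else v)
                       for k, v in dataclasses.asdict(sim_cfg).items()},
        "mouse_stage": stage,
        "artifacts": artifacts,
        "summary": {
            "n_genes": int(genes.shape[0]),
            "signature_sizes": {a: [len(s.up_genes), len(s.down_genes)]
                                for a, s in signatures.items()},
            "human_rank_sum_p": groups["p"],
            "survival": {e: {"hr": float(r["hr"]), "p": float(r["p"])}
                         for e, r in surv_table.iterrows()},
            "drug": {c: {"slope": d["slope"], "r": d["r"]}
                     for c, d in drug_stats.items()},
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest
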