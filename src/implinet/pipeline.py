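"""End-to-end orchestration of the synthetic study.

``run_pipeline`` executes the stages in dependency order on generated
inputs — two expression cohorts with shared planted structure, dependency
screens, survival data and drug activities — and records a manifest with the
config, thresholds, per-stage outputs and SHA-256 digests.  Re-running the
same config reproduces identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from pathlib import Path

import pandas as pd

from . import io as iio
from .assembly import annotate_proliferation, seed_filter
from .config import PipelineConfig
from .discretize import average_housekeeping_n, discretize_expression
from .drug_response import categorize_records, de_by_response
from .implication import infer_network, intersect_cohorts
from .screens import normalize_crispr, normalize_rnai, proliferation_genes_count, \
    proliferation_genes_majority
from .signatures import build_mechanism_signature, drug_sensitive_genes
from .survival import fit_risk_model, km_logrank, random_partition, score_and_stratify
from .synthetic import SyntheticSpec, gen_dependency_screen, gen_drug_activity, \
    gen_expression_cohort, gen_survival, seed_network_edges

log = logging.getLogger(__name__)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the synthetic end-to-end analysis; returns the manifest dict.

    On a stage failure the partial manifest (with the failing stage and
    cause) is still written to ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    syn = dict(config.synthetic)
    if "planted_edges" not in syn:
        # plant a seed-gene network so the assembly stage has work to do
        syn.setdefault("n_samples", 500)
        syn["planted_edges"] = seed_network_edges(
            seeds=tuple(config.seed_genes), n_targets=5, n_decoys=5,
            strength=0.95, seed=config.seed,
        )
    spec = SyntheticSpec(seed=config.seed, **syn)
    manifest: dict = {
        "tool": "implinet",
        "python": sys.version.split()[0],
        "config": config.to_dict(),
        "stages": {},
    }
    state: dict = {}
    stages = [
        ("synthetic", _stage_synthetic),
        ("discretize", _stage_discretize),
        ("implication", _stage_implication),
        ("assembly", _stage_assembly),
        ("screens", _stage_screens),
        ("survival", _stage_survival),
        ("drug_response", _stage_drug_response),
        ("signatures", _stage_signatures),
    ]
    try:
        for name, fn in stages:
            outputs = fn(config, spec, state, out)
            manifest["stages"][name] = {
                "status": "ok",
                "outputs": {str(p.relative_to(out)): _digest(p) for p in outputs},
            }
    except Exception as exc:
        manifest["stages"][name] = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
        _dump_json(manifest, out / "manifest.json")
        raise
    _dump_json(manifest, out / "manifest.json")
    return manifest


def _stage_synthetic(config, spec, state, out: Path) -> list[Path]:
    paths = []
    for cid in (0, 1):
        expr, truth = gen_expression_cohort(spec, cohort_id=cid)
        state[f"expr{cid}"] = expr
        p = out / f"cohort{cid}_expression.tsv"
        iio.write_matrix_tsv(expr.values, p)
        t = out / f"cohort{cid}_truth.json"
        _dump_json(truth, t)
        paths += [p, t]
    state["truth_edges"] = truth["planted_edges"]
    for assay in ("CRISPR", "RNAi"):
        screen, truth_s = gen_dependency_screen(spec, assay)
        state[f"screen_{assay}"] = screen
        state[f"truth_{assay}"] = truth_s
        p = out / f"screen_{assay.lower()}.tsv"
        iio.write_matrix_tsv(screen.scores, p)
        t = out / f"screen_{assay.lower()}_truth.json"
        _dump_json(truth_s, t)
        paths += [p, t]
    surv, truth_surv = gen_survival(spec)
    state["survival"] = surv
    p = out / "clinical.tsv"
    iio.write_clinical_tsv(surv, p)
    t = out / "clinical_truth.json"
    _dump_json(truth_surv, t)
    paths += [p, t]
    records, drug_expr, truth_d = gen_drug_activity(spec)
    state["drug_records"] = records
    state["drug_expr"] = drug_expr
    p = out / "drug_activity.csv"
    iio.write_drug_activity_csv(records, p)
    t = out / "drug_truth.json"
    _dump_json(truth_d, t)
    paths += [p, t]
    return paths


def _stage_discretize(config, spec, state, out: Path) -> list[Path]:
    paths = []
    for cid in (0, 1):
        expr = state[f"expr{cid}"]
        n = average_housekeeping_n(expr, config.target_fraction)
        calls = discretize_expression(expr, n)
        state[f"calls{cid}"] = calls
        p = out / f"cohort{cid}_calls.tsv"
        iio.write_discretized(calls, p, sidecar={
            "target_fraction": config.target_fraction,
            "housekeeping_found": list(expr.housekeeping_ids),
        })
        paths += [p, p.with_suffix(p.suffix + ".json")]
    return paths


def _stage_implication(config, spec, state, out: Path) -> list[Path]:
    pairs = [(e["gene_a"], e["gene_b"]) for e in state["truth_edges"]]
    per_cohort = []
    for cid in (0, 1):
        calls = state[f"calls{cid}"]
        rules = infer_network(calls, calls, pairs, z_crit=config.z_crit,
                              variance=config.variance, min_samples=config.min_samples)
        per_cohort.append(rules)
        p = out / f"cohort{cid}_edges.tsv"
        iio.write_edges_tsv(rules, p)
    shared = intersect_cohorts(*per_cohort, labels=["cohort0", "cohort1"])
    state["shared_edges"] = shared
    p = out / "edges_intersected.tsv"
    iio.write_edges_tsv(shared, p)
    return [out / "cohort0_edges.tsv", out / "cohort1_edges.tsv", p]


def _stage_assembly(config, spec, state, out: Path) -> list[Path]:
    network = seed_filter(state["shared_edges"], seeds=tuple(config.seed_genes),
                          min_seed_degree=config.min_seed_degree)
    state["network"] = network
    p = out / "network.graphml"
    iio.write_graphml(network, p)
    s = out / "network.sif"
    iio.write_sif(network, s)
    return [p, s]


def _stage_screens(config, spec, state, out: Path) -> list[Path]:
    crispr = normalize_crispr(state["screen_CRISPR"])
    rnai, _avgs = normalize_rnai(state["screen_RNAi"])
    state["crispr_norm"], state["rnai_norm"] = crispr, rnai
    if config.proliferation_rule == "count":
        genes = proliferation_genes_count(crispr, rnai, config.proliferation_min_lines,
                                          threshold=config.dependency_threshold)
    else:
        genes = proliferation_genes_majority(crispr, rnai,
                                             threshold=config.dependency_threshold)
    state["proliferation"] = genes
    annotate_proliferation(state["network"], genes)
    p = out / "proliferation_genes.grp"
    iio.write_grp(sorted(genes), p)
    return [p]


def _stage_survival(config, spec, state, out: Path) -> list[Path]:
    table = state["survival"]
    train, test = random_partition(table, config.partition_fraction, config.seed)
    model = fit_risk_model(train)
    results = {}
    for label, part in (("training", train), ("testing", test)):
        scored = score_and_stratify(part, model, config.risk_cutoff)
        km = km_logrank(scored)
        curves = km.pop("curves")
        curves.to_csv(out / f"km_{label}.tsv", sep="\t", index=False)
        results[label] = km
    results["betas"] = {k: float(v) for k, v in model.betas.items()}
    results["risk_cutoff"] = config.risk_cutoff
    p = out / "survival_results.json"
    _dump_json(results, p)
    return [p, out / "km_training.tsv", out / "km_testing.tsv"]


def _stage_drug_response(config, spec, state, out: Path) -> list[Path]:
    records = categorize_records(state["drug_records"])
    cats = pd.Series({r.cell_line: r.category for r in records})
    de = de_by_response(state["drug_expr"], cats, fc_bounds=tuple(config.fc_bounds))
    state["de_table"] = de
    p = out / "de_by_response.tsv"
    de.to_csv(p, sep="\t")
    c = out / "drug_categories.csv"
    iio.write_drug_activity_csv(records, c)
    return [p, c]


def _stage_signatures(config, spec, state, out: Path) -> list[Path]:
    ds = drug_sensitive_genes([state["de_table"]])
    prolif = proliferation_genes_count(
        state["crispr_norm"], state["rnai_norm"], config.proliferation_min_lines,
        threshold=config.dependency_threshold)
    sig = build_mechanism_signature(drug_sensitive_genes=sorted(ds),
                                    proliferation_count_genes=prolif)
    paths = iio.write_signature(sig, out / "signatures")
    meta = out / "signatures" / "mechanism_provenance.json"
    _dump_json(dataclasses.asdict(sig), meta)
    return [*paths, meta]
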