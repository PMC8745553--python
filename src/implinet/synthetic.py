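"""Synthetic cohorts with planted, parameterized structure.

Every input the pipeline consumes can be generated here together with a
ground-truth record, so each inference stage has a recovery test that reads
only (data, truth).  Expression cohorts anchor 27 housekeeping genes at unit
variance; implication pairs are planted through a shared latent factor whose
loading (the edge *strength*) maps monotonically to rule precision; CNV
dosage shifts a target gene's expression per copy-number state; survival
times follow an exponential proportional-hazards model over the seven
signature covariates with uniform censoring calibrated to a target rate;
dependency screens carry essential/non-essential control sets and planted
majority-dependent genes; drug activities place IC50/EC50 values inside or
outside the assay dose window.

Defaults mirror the study conditions: 200 samples per expression cohort,
edge strength 0.9, 30% censoring, 78 CRISPR / 92 RNAi cell lines, and the
0.0006–10 µM PRISM dose window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discretize import HOUSEKEEPING_GENES, ExpressionMatrix
from .drug_response import DEFAULT_DOSE_WINDOW, DrugActivityRecord
from .screens import DependencyScreen
from .survival import SEVEN_GENES, SurvivalTable


@dataclass(frozen=True)
class PlantedEdge:
    """A planted pairwise relation: positive/negative co-expression or a
    CNV→expression dosage effect, with loading strength in (0, 1]."""

    gene_a: str
    gene_b: str
    relation: str = "positive"  # positive | negative | cnv_dosage
    strength: float = 0.9

    def __post_init__(self):
        if self.relation not in ("positive", "negative", "cnv_dosage"):
            raise ValueError(f"unknown relation {self.relation!r}")
        if not 0.0 < self.strength <= 1.0:
            raise ValueError("strength must lie in (0, 1]")


def default_planted_edges(n: int = 10, strength: float = 0.9) -> tuple[PlantedEdge, ...]:
    """``n`` disjoint planted pairs among the background genes, alternating
    positive and negative relations."""
    edges = []
    for i in range(n):
        rel = "positive" if i % 2 == 0 else "negative"
        edges.append(PlantedEdge(f"G{2 * i + 1:03d}", f"G{2 * i + 2:03d}", rel, strength))
    return tuple(edges)


def seed_network_edges(
    seeds: tuple[str, ...] = SEVEN_GENES,
    n_targets: int = 12,
    n_decoys: int = 20,
    strength: float = 0.9,
    seed: int = 0,
) -> tuple[PlantedEdge, ...]:
    """Planted edges forming a seed-gene network: each target gene
    co-expresses with two distinct seeds, each decoy with exactly one."""
    rng = np.random.default_rng((seed, 99))
    edges: list[PlantedEdge] = []
    for i in range(n_targets):
        pair = rng.choice(len(seeds), size=2, replace=False)
        for k in pair:
            edges.append(PlantedEdge(seeds[k], f"T{i + 1:02d}", "positive", strength))
    for i in range(n_decoys):
        k = int(rng.integers(len(seeds)))
        edges.append(PlantedEdge(seeds[k], f"D{i + 1:02d}", "positive", strength))
    return tuple(edges)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study; a fixed seed gives byte-identical
    outputs."""

    seed: int = 0
    n_samples: int = 200
    n_genes: int = 50
    n_housekeeping: int = 27
    planted_edges: tuple[PlantedEdge, ...] = field(default_factory=default_planted_edges)
    survival_betas: dict = field(
        default_factory=lambda: dict(zip(SEVEN_GENES, (0.5, -0.5, 0.3, 0.0, 0.0, 0.0, 0.2)))
    )
    n_patients: int = 1000
    censoring_rate: float = 0.30
    baseline_median_months: float = 30.0
    # dependency screens
    n_cell_lines_crispr: int = 78
    n_cell_lines_rnai: int = 92
    n_essential_controls: int = 30
    n_nonessential_controls: int = 30
    n_screen_genes: int = 40
    planted_dependent: tuple[str, ...] = ("DEP01", "DEP02", "DEP03", "DEP04", "DEP05")
    dependent_fraction: float = 0.8
    missing_rate: float = 0.05
    # drug response
    n_drug_lines: int = 60
    dose_window: tuple[float, float] = DEFAULT_DOSE_WINDOW
    n_sensitive: int = 20
    n_resistant: int = 20
    planted_de_genes: tuple[str, ...] = ("DRG01", "DRG02", "DRG03")
    de_effect_sd: float = 1.5

    def rng(self, *streams: int) -> np.random.Generator:
        return np.random.default_rng((self.seed, *streams))


def _gene_names(spec: SyntheticSpec) -> list[str]:
    return [f"G{i + 1:03d}" for i in range(spec.n_genes)]


def gen_expression_cohort(
    spec: SyntheticSpec, cohort_id: int = 0
) -> tuple[ExpressionMatrix, dict]:
    """One expression cohort with planted co-expression structure.

    Housekeeping genes are iid unit-variance Gaussians; background genes are
    iid Gaussians except planted pair members, which load on a shared latent
    factor: ``x = s·f ± sqrt(1 − s²)·ε`` with the sign set by the relation.
    Distinct ``cohort_id`` values reuse the same truth with independent noise,
    so two cohorts exercise cross-cohort intersection realistically.
    """
    rng = spec.rng(1, cohort_id)
    samples = [f"S{cohort_id}_{j + 1:03d}" for j in range(spec.n_samples)]
    genes = _gene_names(spec)
    hk = list(HOUSEKEEPING_GENES[: spec.n_housekeeping])
    extra = sorted({g for e in spec.planted_edges if e.relation != "cnv_dosage"
                    for g in (e.gene_a, e.gene_b)} - set(genes))
    all_genes = genes + extra
    data = pd.DataFrame(
        rng.normal(size=(len(all_genes) + len(hk), spec.n_samples)),
        index=all_genes + hk, columns=samples,
    )
    # one latent factor per planted edge; genes accumulate loadings so a gene
    # may take part in several edges (loadings rescaled to keep variance ≈ 1)
    loadings: dict[str, list[tuple[np.ndarray, float]]] = {}
    for edge in spec.planted_edges:
        if edge.relation == "cnv_dosage":
            continue
        f = rng.normal(size=spec.n_samples)
        sign = 1.0 if edge.relation == "positive" else -1.0
        loadings.setdefault(edge.gene_a, []).append((f, edge.strength))
        loadings.setdefault(edge.gene_b, []).append((f, sign * edge.strength))
    for gene, parts in loadings.items():
        total = sum(l * l for _, l in parts)
        scale = np.sqrt(0.95 / total) if total > 0.95 else 1.0
        signal = sum(l * scale * f for f, l in parts)
        resid_var = max(1.0 - total * scale**2, 0.05)
        data.loc[gene] = signal + np.sqrt(resid_var) * rng.normal(size=spec.n_samples)
    truth = {
        "kind": "expression_cohort",
        "cohort_id": cohort_id,
        "planted_edges": [
            {"gene_a": e.gene_a, "gene_b": e.gene_b,
             "relation": e.relation, "strength": e.strength}
            for e in spec.planted_edges if e.relation != "cnv_dosage"
        ],
        "housekeeping": hk,
    }
    return ExpressionMatrix(values=data, housekeeping_ids=tuple(hk)), truth


def gen_cnv_with_dosage(
    spec: SyntheticSpec, cohort_id: int = 0,
    state_freqs: tuple[float, float, float] = (0.2, 0.6, 0.2),
) -> tuple[pd.DataFrame, ExpressionMatrix, dict]:
    """CNV states plus an expression cohort with planted dosage effects.

    CNV calls are drawn iid from {−1, 0, 1} at ``state_freqs``.  For each
    planted ``cnv_dosage`` edge the target gene's expression mean is shifted
    by ``strength · state`` standard deviations per sample.
    """
    expr, truth = gen_expression_cohort(spec, cohort_id)
    rng = spec.rng(2, cohort_id)
    genes = _gene_names(spec)
    cnv = pd.DataFrame(
        rng.choice([-1, 0, 1], size=(len(genes), spec.n_samples), p=state_freqs),
        index=genes, columns=expr.sample_ids,
    )
    dosage = []
    for edge in spec.planted_edges:
        if edge.relation != "cnv_dosage":
            continue
        states = cnv.loc[edge.gene_a].to_numpy()
        row = expr.values.loc[edge.gene_b].to_numpy()
        expr.values.loc[edge.gene_b] = row + edge.strength * row.std(ddof=0) * states
        dosage.append({"cnv_gene": edge.gene_a, "target_gene": edge.gene_b,
                       "strength": edge.strength})
    truth = dict(truth, kind="cnv_dosage_cohort", dosage_edges=dosage)
    return cnv, expr, truth


def _calibrate_censoring(event_times: np.ndarray, rate: float) -> float:
    """Upper bound c of Uniform(0, c) censoring hitting the target rate.

    P(censored) = mean(min(T/c, 1)) is continuous and decreasing in c;
    solved by bisection on the empirical times.
    """
    if rate <= 0:
        return float(np.inf)
    lo, hi = 1e-6, float(event_times.max()) * 100
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        realized = float(np.minimum(event_times / mid, 1.0).mean())
        if realized > rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gen_survival(spec: SyntheticSpec) -> tuple[SurvivalTable, dict]:
    """Proportional-hazards survival data over the seven signature covariates.

    Event times are exponential with hazard ``λ0·exp(Σ β·x)`` where λ0 sets
    the baseline median to ``baseline_median_months``; censoring times are
    Uniform(0, c) with c calibrated to the target censoring rate.  Stage and
    radiotherapy columns are included so clinical group filters can run.
    """
    rng = spec.rng(3)
    betas = pd.Series(spec.survival_betas, dtype=float)
    n = spec.n_patients
    x = pd.DataFrame(rng.normal(size=(n, len(betas))), columns=list(betas.index),
                     index=[f"P{i + 1:04d}" for i in range(n)])
    lp = x.to_numpy() @ betas.to_numpy()
    lam0 = np.log(2.0) / spec.baseline_median_months
    event_times = rng.exponential(1.0 / (lam0 * np.exp(lp)))
    c = _calibrate_censoring(event_times, spec.censoring_rate)
    censor_times = rng.uniform(0.0, c, size=n) if np.isfinite(c) else np.full(n, np.inf)
    time = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)
    stage = rng.choice(["I", "II", "III", "IV"], size=n, p=(0.35, 0.25, 0.25, 0.15))
    radio = np.where(np.isin(stage, ("III", "IV")),
                     rng.random(n) < 0.8, rng.random(n) < 0.1).astype(int)
    df = x.copy()
    df["time"] = np.maximum(time, 1e-6)
    df["event"] = event
    df["stage"] = stage
    df["radiotherapy"] = radio
    truth = {
        "kind": "survival",
        "betas": dict(betas),
        "censoring_rate_target": spec.censoring_rate,
        "censoring_rate_realized": float(1 - event.mean()),
        "baseline_median_months": spec.baseline_median_months,
    }
    return SurvivalTable(df, covariates=tuple(betas.index)), truth


def gen_dependency_screen(
    spec: SyntheticSpec, assay: str = "CRISPR"
) -> tuple[DependencyScreen, dict]:
    """A dependency screen with controls and planted majority-dependent genes.

    Essential controls center at −1 and non-essential controls at 0
    (sd 0.15) before noise; planted dependent genes score around −0.8 in a
    ``dependent_fraction`` of their lines and near 0 elsewhere, so they pass
    the ≥50% majority rule after normalization.  A missing mask at
    ``missing_rate`` is applied to non-control genes.
    """
    if assay not in ("CRISPR", "RNAi"):
        raise ValueError("assay must be CRISPR or RNAi")
    rng = spec.rng(4 if assay == "CRISPR" else 5)
    n_lines = spec.n_cell_lines_crispr if assay == "CRISPR" else spec.n_cell_lines_rnai
    lines = [f"{assay}_L{j + 1:03d}" for j in range(n_lines)]
    ess = [f"ESS{i + 1:02d}" for i in range(spec.n_essential_controls)]
    ne = [f"NEG{i + 1:02d}" for i in range(spec.n_nonessential_controls)]
    others = [f"OTH{i + 1:02d}" for i in range(spec.n_screen_genes)]
    dep = list(spec.planted_dependent)

    blocks = {
        **{g: rng.normal(-1.0, 0.15, n_lines) for g in ess},
        **{g: rng.normal(0.0, 0.15, n_lines) for g in ne},
        **{g: rng.normal(0.0, 0.15, n_lines) for g in others},
    }
    for g in dep:
        hit = rng.random(n_lines) < spec.dependent_fraction
        blocks[g] = np.where(hit, rng.normal(-0.8, 0.1, n_lines), rng.normal(0.0, 0.1, n_lines))
    scores = pd.DataFrame(blocks, index=lines).T
    mask = rng.random(scores.shape) < spec.missing_rate
    noncontrol = ~scores.index.isin(ess + ne)
    scores.values[mask & noncontrol[:, None]] = np.nan
    screen = DependencyScreen(
        scores=scores,
        essential_controls=frozenset(ess),
        nonessential_controls=frozenset(ne),
        assay=assay,
    )
    truth = {
        "kind": "dependency_screen",
        "assay": assay,
        "planted_dependent": dep,
        "dependent_fraction": spec.dependent_fraction,
        "essential_controls": ess,
        "nonessential_controls": ne,
        "missing_rate": spec.missing_rate,
    }
    return screen, truth


def gen_drug_activity(
    spec: SyntheticSpec, drug: str = "cisplatin", metric: str = "IC50"
) -> tuple[list[DrugActivityRecord], pd.DataFrame, dict]:
    """Drug activities with planted sensitive/resistant labels plus an
    expression matrix with planted response-linked genes.

    Sensitive lines get activities log-uniform below the minimum dose,
    resistant lines above the maximum dose, the remainder inside the window.
    Planted genes are shifted between the sensitive and resistant groups by
    ``de_effect_sd`` standard deviations on a linear scale.
    """
    rng = spec.rng(6)
    lo, hi = spec.dose_window
    n = spec.n_drug_lines
    if spec.n_sensitive + spec.n_resistant > n:
        raise ValueError("sensitive + resistant exceeds the number of lines")
    lines = [f"DL{j + 1:03d}" for j in range(n)]
    labels = (["sensitive"] * spec.n_sensitive + ["resistant"] * spec.n_resistant
              + ["partial"] * (n - spec.n_sensitive - spec.n_resistant))
    rng.shuffle(labels)
    values = np.empty(n)
    for j, lab in enumerate(labels):
        if lab == "sensitive":
            values[j] = 10 ** rng.uniform(np.log10(lo) - 2, np.log10(lo) - 0.05)
        elif lab == "resistant":
            values[j] = 10 ** rng.uniform(np.log10(hi) + 0.05, np.log10(hi) + 2)
        else:
            values[j] = 10 ** rng.uniform(np.log10(lo), np.log10(hi))
    records = [
        DrugActivityRecord(cell_line=line, drug=drug, metric=metric,
                           value=float(v), min_dose=lo, max_dose=hi)
        for line, v in zip(lines, values)
    ]

    genes = list(spec.planted_de_genes) + [f"NUL{i + 1:02d}" for i in range(20)]
    expr = pd.DataFrame(rng.normal(10.0, 1.0, size=(len(genes), n)),
                        index=genes, columns=lines)
    sens_mask = np.array([lab == "sensitive" for lab in labels])
    for g in spec.planted_de_genes:
        expr.loc[g, sens_mask] += spec.de_effect_sd
    truth = {
        "kind": "drug_activity",
        "drug": drug,
        "metric": metric,
        "labels": dict(zip(lines, labels)),
        "planted_de_genes": list(spec.planted_de_genes),
        "de_effect_sd": spec.de_effect_sd,
        "dose_window": [lo, hi],
    }
    return records, expr, truth
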