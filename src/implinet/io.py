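"""Readers and writers for the plain-text formats the pipeline speaks.

Expression/CNV matrices: TSV (genes in rows, header = sample ids, NA for
missing) and GCT 1.2.  Gene lists: GRP (one symbol per line) and GMT.  Edge
lists: TSV plus SIF and GraphML for network viewers.  Dependency matrices:
CSV/TSV tolerant of DepMap column naming ("SYMBOL (entrez)" is parsed to the
symbol, and cell-lines-in-rows orientation is auto-detected).  Clinical
tables: TSV with time/event plus covariates.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import networkx as nx
import pandas as pd

from .assembly import MultiOmicsNetwork
from .discretize import DiscretizedMatrix, ExpressionMatrix
from .drug_response import DrugActivityRecord
from .implication import ImplicationRule, RuleType
from .screens import DependencyScreen
from .signatures import QuerySignature
from .survival import SEVEN_GENES, SurvivalTable

_DEPMAP_COL = re.compile(r"^\s*(\S+)\s*\((\d+)\)\s*$")


# ---------------------------------------------------------------- matrices

def read_expression_tsv(path, housekeeping_ids=None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "NaN", ""])
    hk = tuple(housekeeping_ids) if housekeeping_ids is not None else tuple(
        g for g in df.index if g in set(_default_hk())
    )
    return ExpressionMatrix(values=df, housekeeping_ids=hk)


def _default_hk():
    from .discretize import HOUSEKEEPING_GENES

    return HOUSEKEEPING_GENES


def read_gct(path, housekeeping_ids=None) -> ExpressionMatrix:
    """GCT 1.2: version line, dims line, then Name/Description + samples."""
    with open(path) as fh:
        version = fh.readline().strip()
        if version not in ("#1.2", "1.2"):
            raise ValueError(f"unsupported GCT version line {version!r}")
        fh.readline()  # dims, unused
        df = pd.read_csv(fh, sep="\t", na_values=["NA", "NaN", ""])
    df = df.set_index(df.columns[0]).drop(columns=[df.columns[1]], errors="ignore")
    if "Description" in df.columns:
        df = df.drop(columns=["Description"])
    hk = tuple(housekeeping_ids) if housekeeping_ids is not None else tuple(
        g for g in df.index if g in set(_default_hk())
    )
    return ExpressionMatrix(values=df.astype(float), housekeeping_ids=hk)


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "NaN", ""])


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA")


def write_discretized(matrix: DiscretizedMatrix, path, sidecar: dict | None = None) -> None:
    """Write calls TSV plus a JSON sidecar with provenance metadata."""
    path = Path(path)
    matrix.calls.to_csv(path, sep="\t")
    meta = {"layer": matrix.layer, "n_used": matrix.n_used}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_discretized(path) -> DiscretizedMatrix:
    path = Path(path)
    calls = pd.read_csv(path, sep="\t", index_col=0)
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return DiscretizedMatrix(
        calls=calls, layer=meta.get("layer", "GE"), n_used=meta.get("n_used")
    )


# ---------------------------------------------------------------- gene lists

def read_grp(path) -> list[str]:
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes


def write_grp(genes, path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets = {}
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) >= 3:
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(named_sets: dict[str, list[str]], path, description: str = "implinet") -> None:
    lines = [
        "\t".join([name, description, *genes]) for name, genes in named_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_signature(sig: QuerySignature, out_dir) -> list[Path]:
    """Export one signature as <name>_up.grp, <name>_down.grp and a GMT."""
    sig.validate_for_export()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for side, genes in (("up", sig.up_genes), ("down", sig.down_genes)):
        p = out_dir / f"{sig.name}_{side}.grp"
        write_grp(genes, p)
        paths.append(p)
    gmt = out_dir / f"{sig.name}.gmt"
    write_gmt({f"{sig.name}_up": list(sig.up_genes),
               f"{sig.name}_down": list(sig.down_genes)}, gmt)
    paths.append(gmt)
    return paths


# ---------------------------------------------------------------- edges

_EDGE_COLS = ["source", "source_layer", "target", "target_layer", "rule_type",
              "scope", "precision", "z", "e_obs", "e_exp", "n", "significant",
              "cohorts"]


def write_edges_tsv(rules: list[ImplicationRule], path) -> None:
    rows = [
        {
            "source": r.source, "source_layer": r.source_layer,
            "target": r.target, "target_layer": r.target_layer,
            "rule_type": r.rule_type.name, "scope": r.scope_U,
            "precision": r.precision_del, "z": r.z, "e_obs": r.e_obs,
            "e_exp": r.e_exp, "n": r.n, "significant": r.significant,
            "cohorts": ",".join(r.cohorts),
        }
        for r in rules
    ]
    pd.DataFrame(rows, columns=_EDGE_COLS).to_csv(path, sep="\t", index=False)


def read_edges_tsv(path) -> list[ImplicationRule]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    rules = []
    for row in df.itertuples(index=False):
        rules.append(ImplicationRule(
            source=row.source, target=row.target,
            rule_type=RuleType[row.rule_type],
            e_obs=float(row.e_obs), e_exp=float(row.e_exp),
            scope_U=float(row.scope), precision_del=float(row.precision),
            z=float(row.z), significant=str(row.significant) in ("True", "true", "1"),
            n=int(row.n), source_layer=row.source_layer,
            target_layer=row.target_layer,
            cohorts=tuple(c for c in str(row.cohorts).split(",") if c),
        ))
    return rules


def write_sif(network: MultiOmicsNetwork, path) -> None:
    lines = []
    for u, v, d in network.graph.edges(data=True):
        lines.append(f"{u[0]}|{u[1]}\t{d['rule_type']}\t{v[0]}|{v[1]}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_graphml(network: MultiOmicsNetwork, path) -> None:
    g = nx.MultiDiGraph()
    for (gene, layer), d in network.graph.nodes(data=True):
        g.add_node(f"{gene}|{layer}", **{k: v for k, v in d.items()})
    for u, v, d in network.graph.edges(data=True):
        g.add_edge(f"{u[0]}|{u[1]}", f"{v[0]}|{v[1]}", **d)
    g.graph["seeds"] = ",".join(network.seeds)
    nx.write_graphml(g, path)


def read_graphml(path) -> MultiOmicsNetwork:
    g = nx.read_graphml(path, force_multigraph=True)
    out = nx.MultiDiGraph()
    for node, d in g.nodes(data=True):
        gene, layer = node.split("|")
        attrs = dict(d)
        attrs["is_seed"] = _to_bool(attrs.get("is_seed", False))
        attrs["is_proliferation"] = _to_bool(attrs.get("is_proliferation", False))
        attrs.setdefault("gene", gene)
        attrs.setdefault("layer", layer)
        out.add_node((gene, layer), **attrs)
    for u, v, d in g.edges(data=True):
        out.add_edge(tuple(u.split("|")), tuple(v.split("|")), **d)
    seeds = tuple(g.graph.get("seeds", ",".join(SEVEN_GENES)).split(","))
    return MultiOmicsNetwork(graph=out, seeds=seeds)


def _to_bool(x) -> bool:
    if isinstance(x, str):
        return x.lower() in ("true", "1", "yes")
    return bool(x)


# ---------------------------------------------------------------- clinical

def read_clinical_tsv(path, covariates=SEVEN_GENES) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    present = tuple(c for c in covariates if c in df.columns)
    return SurvivalTable(df, covariates=present)


def write_clinical_tsv(table: SurvivalTable, path) -> None:
    table.data.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------- screens

def parse_depmap_gene(col: str) -> str:
    """'SOX10 (6663)' → 'SOX10'; plain symbols pass through."""
    m = _DEPMAP_COL.match(col)
    return m.group(1) if m else col.strip()


def read_dependency_csv(
    path,
    essential_controls,
    nonessential_controls,
    assay: str = "CRISPR",
    *,
    sep: str | None = None,
    genes_in: str = "auto",
) -> DependencyScreen:
    """Read a DepMap-style score matrix.

    ``genes_in`` is "rows", "columns" or "auto" (detected by matching control
    genes against the parsed row/column labels).
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    controls = set(essential_controls) | set(nonessential_controls)
    cols = [parse_depmap_gene(c) for c in df.columns]
    rows = [parse_depmap_gene(r) for r in df.index]
    if genes_in == "auto":
        genes_in = "columns" if len(controls & set(cols)) >= len(controls & set(rows)) else "rows"
    if genes_in == "columns":
        df.columns = cols
        df = df.T
    else:
        df.index = rows
    return DependencyScreen(
        scores=df.astype(float),
        essential_controls=frozenset(essential_controls),
        nonessential_controls=frozenset(nonessential_controls),
        assay=assay,
    )


# ---------------------------------------------------------------- drug CSV

def read_drug_activity_csv(path) -> list[DrugActivityRecord]:
    """CSV with columns cell_line, drug, metric, value, min_dose, max_dose."""
    df = pd.read_csv(path)
    required = {"cell_line", "drug", "metric", "value", "min_dose", "max_dose"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"drug activity CSV missing columns: {sorted(missing)}")
    return [
        DrugActivityRecord(
            cell_line=row.cell_line, drug=row.drug, metric=row.metric,
            value=float(row.value), min_dose=float(row.min_dose),
            max_dose=float(row.max_dose),
        )
        for row in df.itertuples(index=False)
    ]


def write_drug_activity_csv(records: list[DrugActivityRecord], path) -> None:
    pd.DataFrame([
        {"cell_line": r.cell_line, "drug": r.drug, "metric": r.metric,
         "value": r.value, "min_dose": r.min_dose, "max_dose": r.max_dose,
         "category": r.category or ""}
        for r in records
    ]).to_csv(path, index=False)
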