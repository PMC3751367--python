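"""File formats, run configuration and the end-to-end pipeline.

All on-disk formats are plain tab-separated UTF-8 text:

* expression matrix — first column ``probe_id``, remaining columns sample
  ids; ``NA`` or empty cells are missing values;
* sample sheet — columns ``sample_id``, ``condition``, ``replicate``,
  ``timepoint``;
* GRN edge list — two columns ``gene_a``, ``gene_b``; ``#`` comments;
* probe map — columns ``probe_id``, ``gene_id``;
* transaction DB — columns ``timepoint`` (1-based), ``probe_id``,
  ``direction``, ``quantity``, with DB metadata in ``#`` header lines;
* impact table — columns ``gene_id``, ``impact_degree``, ``significant``;
* itemset lists — TSV and a JSON mirror carrying exact rational values.

Output files contain no timestamps, so a rerun with the same configuration
is byte-identical.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .impact import (
    ImpactDegreeTable,
    build_grn,
    build_impact_table,
    significant_genes,
)
from .miner import ScoredItemset, TopKResult, mine_top_k, run_mode
from .relations import RelationSet, disassemble
from .transactions import (
    DOWN,
    UP,
    ExpressionDataset,
    GeneItem,
    InputError,
    TransactionDB,
    item_key,
)

log = logging.getLogger(__name__)

MODE_ALIASES = {
    "tiim": "tiim",
    "undiff": "undifferentiation",
    "undifferentiation": "undifferentiation",
    "constant": "constant_degree",
    "constant_degree": "constant_degree",
}


# ---------------------------------------------------------------------------
# readers / writers

def read_expression(path, sample_sheet_path) -> ExpressionDataset:
    """Read an expression matrix TSV plus its sample sheet."""
    values = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    if values.empty:
        raise InputError(f"expression matrix {path} is empty")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "condition", "replicate", "timepoint"}
    if not required <= set(sheet.columns):
        raise InputError(
            f"sample sheet {sample_sheet_path} must have columns {sorted(required)}"
        )
    sheet = sheet.set_index("sample_id")
    return ExpressionDataset(values, sheet)


def write_expression(dataset: ExpressionDataset, path, sample_sheet_path) -> None:
    dataset.values.rename_axis("probe_id").to_csv(path, sep="\t")
    dataset.samples.rename_axis("sample_id").to_csv(sample_sheet_path, sep="\t")


def read_grn_tsv(path) -> nx.Graph:
    """Two-column edge-list TSV; lines starting with '#' are ignored."""
    edges = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputError(f"GRN line needs two columns: {line!r}")
            edges.append((parts[0], parts[1]))
    return build_grn(edges)


def read_grn_biogrid(path) -> nx.Graph:
    """Reader for a BioGRID tab-style export, keeping the official-symbol columns."""
    df = pd.read_csv(path, sep="\t", comment=None)
    cols = [c for c in df.columns if c.lower().startswith("official symbol")]
    if len(cols) < 2:
        raise InputError(
            f"{path}: expected two 'Official Symbol …' columns, found {cols}"
        )
    edges = list(zip(df[cols[0]].astype(str), df[cols[1]].astype(str)))
    return build_grn(edges)


def write_grn(grn: nx.Graph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in grn.edges):
            fh.write(f"{a}\t{b}\n")


def read_probe_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene_id"} <= set(df.columns):
        raise InputError(f"probe map {path} needs columns probe_id, gene_id")
    return dict(zip(df["probe_id"], df["gene_id"]))


def write_transaction_db(db: TransactionDB, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# condition={db.condition}\n")
        fh.write(f"# stage={db.stage}\n")
        fh.write(f"# replicates={db.n_replicates}\n")
        fh.write(f"# timepoints={','.join(str(t) for t in db.timepoints)}\n")
        fh.write("timepoint\tprobe_id\tdirection\tgene_id\tquantity\n")
        for y, t in enumerate(db.transactions, start=1):
            for item in sorted(t, key=item_key):
                fh.write(f"{y}\t{item.probe}\t{item.direction}\t{item.gene}\t{t[item]}\n")


def read_transaction_db(path) -> TransactionDB:
    meta: dict[str, str] = {}
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val
            elif line and not line.startswith("timepoint\t"):
                rows.append(line.split("\t"))
    for key in ("condition", "stage", "replicates", "timepoints"):
        if key not in meta:
            raise InputError(f"{path}: missing '# {key}=' header")
    timepoints = meta["timepoints"].split(",") if meta["timepoints"] else []
    try:
        timepoints = [int(t) for t in timepoints]
    except ValueError:
        pass
    transactions: list[dict] = [{} for _ in timepoints]
    for y, probe, direction, gene, q in rows:
        transactions[int(y) - 1][GeneItem(probe, direction, gene)] = int(q)
    return TransactionDB(
        condition=meta["condition"],
        timepoints=timepoints,
        transactions=transactions,
        n_replicates=int(meta["replicates"]),
        stage=meta["stage"],
    )


def write_impact_table(table: ImpactDegreeTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if table.alpha is not None:
            fh.write(f"# alpha={table.alpha}\n")
        fh.write("gene_id\timpact_degree\tsignificant\n")
        genes = sorted(set(table.degrees) | set(table.significant))
        for g in genes:
            fh.write(f"{g}\t{table.degree(g)}\t{1 if g in table.significant else 0}\n")


def read_impact_table(path) -> ImpactDegreeTable:
    alpha = None
    degrees: dict[str, int] = {}
    significant = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                if key.strip() == "alpha":
                    alpha = float(val)
            elif line and not line.startswith("gene_id\t"):
                g, d, s = line.split("\t")
                degrees[g] = int(d)
                if s == "1":
                    significant.add(g)
    return ImpactDegreeTable(degrees=degrees, significant=frozenset(significant), alpha=alpha)


def _fmt_value(v: Fraction) -> str:
    return f"{float(v):g}"


def _items_field(s: ScoredItemset) -> str:
    return ";".join(f"{i.probe}:{i.direction}" for i in sorted(s.items, key=item_key))


def write_itemsets_tsv(topk: TopKResult, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\timpactful_value\tlength\titems\tsupporting_timepoints\n")
        for rank, s in enumerate(topk.itemsets, start=1):
            fh.write(
                f"{rank}\t{_fmt_value(s.value)}\t{s.length}\t{_items_field(s)}\t"
                f"{','.join(str(y) for y in s.support)}\n"
            )


def write_itemsets_json(topk: TopKResult, path) -> None:
    payload = {
        "mode": topk.mode,
        "condition": topk.condition,
        "k": topk.k,
        "itemsets": [
            {
                "rank": rank,
                "impactful_value": float(s.value),
                "impactful_value_exact": str(s.value),
                "length": s.length,
                "items": [[i.probe, i.direction, i.gene]
                          for i in sorted(s.items, key=item_key)],
                "supporting_timepoints": list(s.support),
            }
            for rank, s in enumerate(topk.itemsets, start=1)
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_itemsets_json(path) -> TopKResult:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    itemsets = [
        ScoredItemset(
            items=tuple(GeneItem(p, d, g) for p, d, g in rec["items"]),
            value=Fraction(rec["impactful_value_exact"]),
            support=tuple(rec["supporting_timepoints"]),
        )
        for rec in payload["itemsets"]
    ]
    return TopKResult(
        itemsets=itemsets, k=payload["k"], mode=payload["mode"],
        condition=payload["condition"],
    )


def write_pairs_tsv(relset: RelationSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("item_a\titem_b\tn_source_itemsets\tbest_rank\tbest_impactful_value\n")
        for r in relset.relations:
            if relset.gene_level:
                a, b = r.a, r.b
            else:
                a, b = f"{r.a.probe}:{r.a.direction}", f"{r.b.probe}:{r.b.direction}"
            fh.write(
                f"{a}\t{b}\t{r.n_sources}\t{r.best_rank}\t{_fmt_value(r.best_value)}\n"
            )


# ---------------------------------------------------------------------------
# configuration and pipeline

@dataclass
class RunConfig:
    """Everything one end-to-end run needs."""

    expression: str
    sample_sheet: str
    grn: str
    out_dir: str
    probe_map: str | None = None
    k: int = 50
    mode: str = "tiim"
    alpha: float = 0.05
    up_threshold: float = 0.2
    down_threshold: float = -0.2
    max_len: int | None = None
    keep_zero_degree: bool = False
    gene_pairs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.mode = MODE_ALIASES.get(self.mode, self.mode)
        if self.mode not in set(MODE_ALIASES.values()):
            raise InputError(f"unknown mode {self.mode!r}")
        if self.k < 1:
            raise InputError(f"k must be >= 1, got {self.k}")
        if not 0 < self.alpha < 1:
            raise InputError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not self.up_threshold > self.down_threshold:
            raise InputError("up_threshold must exceed down_threshold")


def load_config(path, **overrides) -> RunConfig:
    """Read a flat-key YAML config; keyword overrides win over file values."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise InputError(f"config {path} must be a flat mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


@dataclass
class PipelineResult:
    """In-memory artifacts of one pipeline run."""

    dataset: ExpressionDataset
    results: dict[str, TopKResult]
    relations: dict[str, RelationSet]
    impact_table: ImpactDegreeTable | None
    manifest: dict


def _safe(label) -> str:
    return "".join(c if c.isalnum() else "_" for c in str(label))


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full pipeline and write its artifacts to ``out_dir``.

    Stages: discretize -> integrate -> differentiate (mode-dependent) ->
    t-tests -> impact table -> top-k mining per condition -> pair
    disassembly.  On failure every file written so far is removed and the
    error is re-raised with the failing stage's name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _open_out(name: str) -> Path:
        p = out / name
        written.append(p)
        return p

    stage = "read inputs"
    try:
        dataset = read_expression(config.expression, config.sample_sheet)
        grn = read_grn_tsv(config.grn)
        probe_map = read_probe_map(config.probe_map) if config.probe_map else None

        from .transactions import differentiate, discretize, integrate

        stage = "discretize/integrate"
        disc = discretize(dataset, config.up_threshold, config.down_threshold, probe_map)
        c1, c2 = dataset.conditions
        integrated = {c: integrate(disc, c) for c in (c1, c2)}
        for c, db in integrated.items():
            write_transaction_db(db, _open_out(f"transactions_{_safe(c)}_integrated.tsv"))
        log.info("integrated DBs: %s",
                 {c: sum(len(t) for t in db.transactions) for c, db in integrated.items()})

        impact_table = None
        if config.mode == "undifferentiation":
            from .impact import uniform_degree_table

            dbs = integrated
            degrees = uniform_degree_table()
        else:
            stage = "differentiate"
            d1, d2 = differentiate(integrated[c1], integrated[c2])
            dbs = {c1: d1, c2: d2}
            for c, db in dbs.items():
                write_transaction_db(db, _open_out(f"transactions_{_safe(c)}_differentiated.tsv"))
            stage = "impact degrees"
            sig = significant_genes(dataset, config.alpha, probe_map)
            impact_table = build_impact_table(grn, sig, config.alpha)
            write_impact_table(impact_table, _open_out("impact_table.tsv"))
            log.info("significant genes: %d; GRN genes: %d", len(sig), grn.number_of_nodes())
            if config.mode == "constant_degree":
                from .impact import constant_degree_table

                degrees = constant_degree_table(impact_table)
            else:
                degrees = impact_table

        stage = "mine"
        results: dict[str, TopKResult] = {}
        relations: dict[str, RelationSet] = {}
        counts = {}
        for c, db in dbs.items():
            topk = mine_top_k(
                db, degrees, config.k,
                max_len=config.max_len,
                keep_zero_degree=config.keep_zero_degree,
                mode=config.mode,
            )
            results[c] = topk
            write_itemsets_tsv(topk, _open_out(f"itemsets_{_safe(c)}.tsv"))
            write_itemsets_json(topk, _open_out(f"itemsets_{_safe(c)}.json"))
            stage = "disassemble pairs"
            relset = disassemble(topk, gene_level=config.gene_pairs)
            relations[c] = relset
            write_pairs_tsv(relset, _open_out(f"pairs_{_safe(c)}.tsv"))
            counts[c] = {"itemsets": len(topk), "pairs": len(relset)}
            stage = "mine"

        stage = "manifest"
        manifest = {
            "config": asdict(config),
            "version": __version__,
            "seed": config.seed,
            "conditions": [c1, c2],
            "counts": {
                "probes": len(dataset.probes),
                "timepoints": dataset.n_timepoints,
                "grn_nodes": grn.number_of_nodes(),
                "grn_edges": grn.number_of_edges(),
                "significant_genes": (
                    len(impact_table.significant) if impact_table else None
                ),
                "per_condition": counts,
            },
        }
        with open(_open_out("manifest.json"), "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise type(exc)(f"pipeline stage '{stage}' failed: {exc}") from exc
    return PipelineResult(
        dataset=dataset, results=results, relations=relations,
        impact_table=impact_table, manifest=manifest,
    )
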