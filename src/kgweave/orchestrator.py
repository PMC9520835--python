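"""Config-driven, dependency-aware build runner.

The build is a small DAG: one ingest stage per source feeding a single
merge stage, then canonicalization, then the report / degree / meta-triple
statistics stages.  Stages communicate through files in the output
directory, which makes skipping cheap: an ingest stage whose source file's
content hash is unchanged from the previous build (and whose output
exists) is marked skippable and its prior output is reused — unchanged
sources are ignored until the merge step.  Source digests are content
hashes, never timestamps.  Independent ingest stages may run on a worker
pool; outputs are byte-identical regardless of worker count because every
stage owns its own files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

from . import report as report_mod
from .canonicalize import canonicalize as _canonicalize
from .canonicalize import write_canonicalization_log
from .errors import EstimationError, PlanError, StageFailure
from .graph_model import GraphDocument, read_json, write_json, write_kgx_tsv
from .ingest import BuildConfig, ingest_source
from .merge import merge_graphs, write_merge_log
from .semantic_model import SemanticModel, load_model

__all__ = ["BuildPlan", "Stage", "plan_build", "run_build"]

CHECKSUM_FILE = "checksums.json"


@dataclass
class Stage:
    name: str
    inputs: list[str] = field(default_factory=list)    # files hashed for skipping
    depends: list[str] = field(default_factory=list)   # upstream stage names
    outputs: list[str] = field(default_factory=list)
    skippable: bool = False


@dataclass
class BuildPlan:
    stages: dict[str, Stage]
    checksums: dict[str, str]          # input file -> digest (current build)
    order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.order:
            self.order = _topological_order(self.stages)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _topological_order(stages: dict[str, Stage]) -> list[str]:
    for stage in stages.values():
        for dep in stage.depends:
            if dep not in stages:
                raise PlanError(f"stage {stage.name!r} depends on missing {dep!r}")
    order: list[str] = []
    mark: dict[str, int] = {}

    def visit(name: str, path: tuple[str, ...]) -> None:
        state = mark.get(name, 0)
        if state == 1:
            cycle = path[path.index(name):] + (name,)
            raise PlanError(f"cyclic dependency: {' -> '.join(cycle)}")
        if state == 2:
            return
        mark[name] = 1
        for dep in stages[name].depends:
            visit(dep, path + (name,))
        mark[name] = 2
        order.append(name)

    for name in stages:
        visit(name, ())
    return order


def plan_build(config: BuildConfig, out_dir: str | Path,
               previous_checksums: dict[str, str] | None = None) -> BuildPlan:
    """Lay out the stage DAG and mark unchanged ingest stages skippable."""
    previous_checksums = previous_checksums or {}
    out_dir = Path(out_dir)
    stages: dict[str, Stage] = {}
    checksums: dict[str, str] = {}

    ingest_names = []
    for src in config.sources:
        src_path = config.source_path(src)
        digest = _digest(src_path)
        checksums[str(src_path)] = digest
        out = out_dir / "ingest" / f"{src.name}.json"
        name = f"ingest:{src.name}"
        ingest_names.append(name)
        stages[name] = Stage(
            name=name,
            inputs=[str(src_path)],
            outputs=[str(out)],
            skippable=(previous_checksums.get(str(src_path)) == digest and out.exists()),
        )

    stages["merge"] = Stage(
        name="merge", depends=list(ingest_names),
        outputs=[str(out_dir / "kg2pre.json"),
                 str(out_dir / "kg2pre_tsv"),
                 str(out_dir / "merge_log.tsv"),
                 str(out_dir / "report_pre_coalesce.json")])
    stages["canonicalize"] = Stage(
        name="canonicalize", depends=["merge"],
        outputs=[str(out_dir / "kg2c.json"),
                 str(out_dir / "canonicalize_log.tsv")])
    stages["report"] = Stage(
        name="report", depends=["merge", "canonicalize"],
        outputs=[str(out_dir / "report_post_merge.json"),
                 str(out_dir / "report_canonical.json")])
    stages["degree-stats"] = Stage(
        name="degree-stats", depends=["canonicalize"],
        outputs=[str(out_dir / "degree_stats.json")])
    stages["meta-triples"] = Stage(
        name="meta-triples", depends=["canonicalize"],
        outputs=[str(out_dir / "meta_triples.tsv")])
    return BuildPlan(stages, checksums)


# ---------------------------------------------------------------------------
# stage bodies


def _run_ingest(config: BuildConfig, model: SemanticModel, src, out: Path) -> dict:
    resolved = dataclasses.replace(src, path=str(config.source_path(src)))
    doc = ingest_source(resolved, model, config.iri_bases)
    out.parent.mkdir(parents=True, exist_ok=True)
    write_json(doc, out)
    return {"nodes": len(doc.nodes), "edges": len(doc.edges)}


def _run_merge(config: BuildConfig, model: SemanticModel, out_dir: Path) -> dict:
    parts = [read_json(out_dir / "ingest" / f"{src.name}.json")
             for src in config.sources]
    merged, log = merge_graphs(parts, config.ranks_by_source_node,
                               {"model_version": model.version})
    write_json(merged, out_dir / "kg2pre.json")
    write_kgx_tsv(merged, out_dir / "kg2pre_tsv")
    write_merge_log(log, out_dir / "merge_log.tsv")
    # pre-coalesce view: unified nodes, raw edge multiset (before joining)
    raw = GraphDocument(merged.nodes, [e for p in parts for e in p.edges],
                        {"stage": "pre_coalesce"})
    report_mod.write_report(report_mod.compute_report(raw, "pre_coalesce"),
                            json_path=out_dir / "report_pre_coalesce.json")
    return {"nodes": len(merged.nodes), "edges": len(merged.edges),
            "coalesced": log.coalesced_count, "dangling": log.dangling_count}


def _run_canonicalize(config: BuildConfig, model: SemanticModel, out_dir: Path) -> dict:
    pre = read_json(out_dir / "kg2pre.json")
    graph, _partition, log = _canonicalize(pre, model, config.ranks_by_source_node)
    write_json(graph, out_dir / "kg2c.json")
    write_canonicalization_log(log, out_dir / "canonicalize_log.tsv")
    return {"nodes": len(graph.nodes), "edges": len(graph.edges),
            "blocks": log.block_count}


def _run_report(config: BuildConfig, model: SemanticModel, out_dir: Path) -> dict:
    pre = read_json(out_dir / "kg2pre.json")
    post = read_json(out_dir / "kg2c.json")
    report_mod.write_report(report_mod.compute_report(pre, "post_merge"),
                            json_path=out_dir / "report_post_merge.json",
                            text_path=out_dir / "report_post_merge.txt")
    report_mod.write_report(report_mod.compute_report(post, "canonical"),
                            json_path=out_dir / "report_canonical.json",
                            text_path=out_dir / "report_canonical.txt")
    return {}


def _run_degree_stats(config: BuildConfig, model: SemanticModel, out_dir: Path) -> dict:
    graph = read_json(out_dir / "kg2c.json")
    hist = report_mod.degree_histogram(graph)
    payload: dict = {
        "n": hist.n,
        "counts": {str(k): c for k, c in sorted(hist.counts.items())},
    }
    try:
        fit = report_mod.fit_power_law(hist, xmin=1)
        payload["power_law"] = {"alpha": fit.alpha, "xmin": fit.xmin,
                                "n_tail": fit.n_tail, "degenerate": fit.degenerate}
    except EstimationError as exc:
        payload["power_law"] = {"error": str(exc)}
    with open(out_dir / "degree_stats.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")
    return {"n": hist.n}


def _run_meta_triples(config: BuildConfig, model: SemanticModel, out_dir: Path) -> dict:
    graph = read_json(out_dir / "kg2c.json")
    table = report_mod.count_meta_triples(graph)
    with open(out_dir / "meta_triples.tsv", "w", encoding="utf-8") as fh:
        fh.write("subject_category\tpredicate\tobject_category\tcount\n")
        for cs, p, co, n in table.to_rows():
            fh.write(f"{cs}\t{p}\t{co}\t{n}\n")
    return {"distinct": table.distinct}


def run_build(plan: BuildPlan, config: BuildConfig, out_dir: str | Path,
              model: SemanticModel | None = None, workers: int = 1) -> dict:
    """Execute the plan; returns a structured per-stage log.

    A stage failure aborts its dependents (and is re-raised as
    :class:`StageFailure`); independent ingest stages run concurrently
    when ``workers > 1``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if model is None:
        model_path = Path(config.model_path)
        if not model_path.is_absolute():
            model_path = config.base_dir / model_path
        model = load_model(model_path)

    log: dict[str, dict] = {}

    def execute(name: str) -> None:
        stage = plan.stages[name]
        started = time.perf_counter()
        if stage.skippable:
            log[name] = {"status": "skipped", "seconds": 0.0}
            return
        if name.startswith("ingest:"):
            src = next(s for s in config.sources if s.name == name.split(":", 1)[1])
            counts = _run_ingest(config, model, src, Path(stage.outputs[0]))
        elif name == "merge":
            counts = _run_merge(config, model, out_dir)
        elif name == "canonicalize":
            counts = _run_canonicalize(config, model, out_dir)
        elif name == "report":
            counts = _run_report(config, model, out_dir)
        elif name == "degree-stats":
            counts = _run_degree_stats(config, model, out_dir)
        elif name == "meta-triples":
            counts = _run_meta_triples(config, model, out_dir)
        else:
            raise PlanError(f"unknown stage {name!r}")
        log[name] = {"status": "done",
                     "seconds": round(time.perf_counter() - started, 4), **counts}

    ingest_stages = [n for n in plan.order if n.startswith("ingest:")]
    rest = [n for n in plan.order if not n.startswith("ingest:")]
    try:
        if workers > 1 and len(ingest_stages) > 1:
            with ThreadPoolExecutor(max_workers=workers) as pool:
                futures = {pool.submit(execute, n): n for n in ingest_stages}
                for fut, name in futures.items():
                    try:
                        fut.result()
                    except Exception as exc:
                        raise StageFailure(name, exc) from exc
        else:
            for name in ingest_stages:
                try:
                    execute(name)
                except StageFailure:
                    raise
                except Exception as exc:
                    raise StageFailure(name, exc) from exc
        for name in rest:
            try:
                execute(name)
            except StageFailure:
                raise
            except Exception as exc:
                raise StageFailure(name, exc) from exc
    finally:
        with open(out_dir / "build_log.json", "w", encoding="utf-8") as fh:
            json.dump(log, fh, indent=1)
            fh.write("\n")

    with open(out_dir / CHECKSUM_FILE, "w", encoding="utf-8") as fh:
        json.dump(plan.checksums, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return log


def load_previous_checksums(out_dir: str | Path) -> dict[str, str]:
    path = Path(out_dir) / CHECKSUM_FILE
    if not path.exists():
        return {}
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
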