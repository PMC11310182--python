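"""Configuration-driven end-to-end pipeline.

Chains the cyclic workflow into one reproducible batch run: read (or
simulate) a log, clean and abstract it, tabulate variants, filter noise,
sequentialize with domain rules, then incrementally discover a process tree
batch by batch, optionally freezing subtrees between batches. Every stage
writes its artifact to the output directory and appends a structured line
to a JSON-lines decision log, so the expert choices encoded in the
configuration remain auditable.
"""

from __future__ import annotations

import json
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import event_log as el
from . import model as md
from . import sequentializer as sq
from . import synthetic as syn
from . import variants as vr


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative description of one pipeline run.

    ``input`` either names a log file (``path`` + ``format``) or carries a
    ``simulate`` section with generator parameters. ``discovery.batches``
    lists fractions of the (frequency-ordered) variants to incorporate per
    batch; ``freeze`` entries mark subtree paths immutable after a given
    batch. Explicit variant selection is supported via
    ``discovery.explicit`` (lists of canonical serializations per batch).
    """

    input: Mapping[str, Any]
    output_dir: str
    hierarchy: Mapping[str, Any] | None = None
    filters: Sequence[Mapping[str, Any]] = ()
    rules: Mapping[str, Any] | str | None = None
    discovery: Mapping[str, Any] = field(
        default_factory=lambda: {"order": "frequency", "batches": [1.0]}
    )
    freeze: Sequence[Mapping[str, Any]] = ()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass(frozen=True)
class RunReport:
    """Per-stage counts, fitness per discovery batch, and the final tree."""

    stages: tuple[dict, ...]
    fitness_per_batch: tuple[float, ...]
    final_tree: str

    def to_dict(self) -> dict:
        return {
            "stages": list(self.stages),
            "fitness_per_batch": list(self.fitness_per_batch),
            "final_tree": self.final_tree,
        }


class _Logbook:
    def __init__(self, path: Path):
        self._fh = open(path, "w", encoding="utf-8")

    def write(self, stage: str, **payload) -> None:
        self._fh.write(json.dumps({"stage": stage, **payload}) + "\n")
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()


def _batch_sizes(n: int, fractions: Sequence[float]) -> list[int]:
    """Split n items into batches by fractions; remainders go to the last."""
    sizes = [int(round(f * n)) for f in fractions]
    assigned = sum(sizes)
    if sizes:
        sizes[-1] += n - assigned
        sizes = [max(0, s) for s in sizes]
    overflow = sum(sizes) - n
    if overflow > 0:
        sizes[-1] -= overflow
    return sizes


def run_pipeline(config: PipelineConfig) -> RunReport:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_book = _Logbook(outdir / "decisions.jsonl")
    stages: list[dict] = []

    def stage(name: str):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                log_book.write(name, error=str(exc))
                log_book.close()
                raise PipelineError(name, exc) from exc

        return wrap

    # -- input ------------------------------------------------------------
    def load() -> el.EventLog:
        if "simulate" in config.input:
            params = dict(config.input["simulate"])
            params.setdefault("seed", config.seed)
            gen = syn.GeneratorConfig.from_dict(params)
            log, ledger = syn.simulate_log(gen)
            (outdir / "ledger.json").write_text(
                json.dumps(ledger.to_dict(), indent=2)
            )
            return log
        return el.read_event_log(
            config.input["path"],
            format=config.input.get("format", "csv"),
            column_map=config.input.get("column_map"),
            date_format=config.input.get("date_format", el.DEFAULT_DATE_FORMAT),
        )

    log = stage("input")(load)
    el.write_event_log(log, outdir / "log.csv")
    stages.append({"stage": "input", "cases": len(log), "events": log.n_events})
    log_book.write("input", cases=len(log), events=log.n_events)

    # -- cleaning / abstraction -------------------------------------------
    def clean() -> el.EventLog:
        current = log
        if config.hierarchy:
            hierarchy = el.ActivityHierarchy.from_dict(config.hierarchy)
            current = el.relabel_activities(current, hierarchy)
            if hierarchy.drop:
                current = el.drop_activities(current, hierarchy.drop)
        return current

    log2 = stage("clean")(clean)
    stages.append(
        {
            "stage": "clean",
            "cases": len(log2),
            "events": log2.n_events,
            "activities": len(log2.activity_universe),
        }
    )
    log_book.write("clean", cases=len(log2), events=log2.n_events)

    # -- variants ----------------------------------------------------------
    table = stage("variants")(lambda: vr.variant_table(log2))
    (outdir / "variants.json").write_text(json.dumps(table.to_dict(), indent=2))
    stages.append({"stage": "variants", "variants": len(table)})
    log_book.write("variants", variants=len(table))

    # -- filtering ---------------------------------------------------------
    def run_filters() -> vr.VariantTable:
        current = table
        universe = log2.activity_universe
        for spec in config.filters:
            if spec.get("predicate") == "default_noise":
                pred = vr.noise_predicate()
            else:
                pred = vr.predicate_from_dict(spec["predicate"])
            current, report = vr.filter_variant_table(
                current, pred, mode=spec.get("mode", "remove"), universe=universe
            )
            for removed in report["removed_variants"]:
                log_book.write("filter", predicate=str(spec), **removed)
        return current

    table2 = stage("filter")(run_filters)
    stages.append(
        {
            "stage": "filter",
            "variants": len(table2),
            "cases": table2.total_cases,
        }
    )

    # -- sequentialization --------------------------------------------------
    def run_rules() -> vr.VariantTable:
        if config.rules is None:
            log_book.write("sequentialize", applied=False)
            return table2
        if config.rules == "default":
            ruleset = syn.default_ruleset()
        elif isinstance(config.rules, str):
            ruleset = sq.load_ruleset(config.rules)
        else:
            ruleset = sq.parse_ruleset(config.rules)
        rewritten, report = sq.apply_ruleset(ruleset, table2)
        (outdir / "rewrite_report.json").write_text(
            json.dumps(report.to_dict(), indent=2)
        )
        for entry in report.rewritten:
            log_book.write("sequentialize", **entry)
        return rewritten

    table3 = stage("sequentialize")(run_rules)
    (outdir / "variants_processed.json").write_text(
        json.dumps(table3.to_dict(), indent=2)
    )
    stages.append(
        {
            "stage": "sequentialize",
            "variants": len(table3),
            "cases": table3.total_cases,
        }
    )

    # -- incremental discovery ----------------------------------------------
    def discover() -> tuple[md.DiscoveryState, list[float]]:
        if len(table3) == 0:
            raise ValueError("no variants left to discover from")
        order = config.discovery.get("order", "frequency")
        if order == "explicit":
            batches = [
                [vr.parse_variant(s) for s in batch]
                for batch in config.discovery["explicit"]
            ]
        elif order == "frequency":
            ranked = [v for v, _ in table3.by_frequency()]
            fractions = config.discovery.get("batches", [1.0])
            sizes = _batch_sizes(len(ranked), fractions)
            batches, at = [], 0
            for s in sizes:
                batches.append(ranked[at : at + s])
                at += s
        else:
            raise ValueError(f"unknown discovery order {order!r}")
        freeze_after = {
            int(d["after_batch"]): [tuple(p) for p in d.get("paths", [d.get("path")])]
            for d in config.freeze
        }
        state: md.DiscoveryState | None = None
        trajectory: list[float] = []
        for batch_no, batch in enumerate(batches, start=1):
            for variant in batch:
                if state is None:
                    state = md.discover_initial([variant])
                else:
                    state = md.add_variant(state, variant)
            if state is not None:
                result = md.fitness(state.tree, table3)
                trajectory.append(result.percent)
                log_book.write(
                    "discover", batch=batch_no, fitness_percent=result.percent
                )
            for path in freeze_after.get(batch_no, []):
                if path is not None:
                    state = md.DiscoveryState(
                        tree=md.freeze_subtree(state.tree, path),
                        incorporated=state.incorporated,
                    )
                    log_book.write("freeze", batch=batch_no, path=list(path))
        if state is None:
            raise ValueError("discovery produced no model")
        return state, trajectory

    state, trajectory = stage("discover")(discover)
    tree_text = md.serialize_tree(state.tree)
    (outdir / "model.tree").write_text(tree_text + "\n")
    stages.append(
        {
            "stage": "discover",
            "incorporated": len(state.incorporated),
            "final_fitness_percent": trajectory[-1] if trajectory else None,
        }
    )

    report = RunReport(
        stages=tuple(stages),
        fitness_per_batch=tuple(trajectory),
        final_tree=tree_text,
    )
    (outdir / "run_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    log_book.close()
    return report
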