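"""Synthetic clinical-pathway event logs.

Generates logs with the statistical structure that coarse-timestamp
hospital logs exhibit: many cases, same-day timestamp collisions that turn
genuinely ordered activities into parallel groups, truncated one- or
two-event traces from data-entry errors, single-activity traces, and
guideline-violating orderings where an invasive procedure is stamped before
the non-invasive exam that must precede it.

The generator is driven by a ground-truth process tree describing a
three-phase pathway (diagnostics, surgery, follow-up). Clean traces are
random runs of that tree; every parallel block is stamped onto one calendar
day, consecutive blocks advance by a geometric day gap. A per-case emission
ledger records the ground truth (clean / truncated / singleton / violating
and the clean template), so recovery of the injected noise by the shipped
filters can be verified exactly.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .event_log import Event, EventLog, Trace, build_log
from .model import (
    ACTIVITY,
    PT_LOOP,
    PT_PAR,
    PT_SEQ,
    PT_XOR,
    TAU,
    ProcessTree,
    activity,
    parse_tree,
    pt_loop,
    pt_par,
    pt_seq,
    pt_xor,
    serialize_tree,
    tau,
)
from .sequentializer import RuleSet, parse_ruleset
from .variants import DEFAULT_INVASIVE, DEFAULT_NONINVASIVE

#: Activity categories in the canonical CSV dialect.
ACTIVITY_CATEGORIES: dict[str, str] = {
    "Lab Test": "Examination",
    "Spirometry": "Examination",
    "Electrocardiogram": "Examination",
    "PET scan": "Examination",
    "Pulmonary Function Test": "Examination",
    "Blood Gas Analysis": "Examination",
    "X-ray": "Examination",
    "CT scan": "Examination",
    "Biopsy": "Examination",
    "Bronchoscopy": "Examination",
    "Excision of Lung and Bronchus": "Surgery",
    "Computer Aided Surgery": "Surgery",
    "Removal of Therapeutic Appliances": "Surgery",
    "Other Non-Operative Procedure": "Treatment",
    "Non-Operative Intubation": "Treatment",
    "Oncology Consultation": "Treatment",
    "Physiotherapy": "Treatment",
    "Pleural Drainage": "Treatment",
}


def default_pathway_tree() -> ProcessTree:
    """The fixed ground-truth pathway: diagnostics, surgery, follow-up.

    The diagnostic phase opens with a general physical examination and a
    repeatable block of non-invasive exams, then mandatory imaging (X-ray
    and CT scan in parallel — one radiology day), then an optional invasive
    procedure. Placing the invasive choice strictly after the imaging block
    encodes the clinical guideline that invasive diagnostics follow
    non-invasive ones; clean runs can therefore never violate it. The
    surgical phase is a single-day parallel block (the true within-day order
    is deliberately hidden by the day-granularity stamping), and follow-up
    is a repeatable choice of treatments. 19 distinct activity labels.
    """
    diag_loop = pt_loop(
        pt_xor(
            activity("Lab Test"),
            activity("Spirometry"),
            activity("Electrocardiogram"),
            activity("PET scan"),
            activity("Pulmonary Function Test"),
            activity("Blood Gas Analysis"),
        )
    )
    follow_up = pt_loop(
        pt_xor(
            activity("Other Non-Operative Procedure"),
            activity("Lab Test"),
            activity("Non-Operative Intubation"),
            activity("Oncology Consultation"),
            activity("Physiotherapy"),
            activity("Pleural Drainage"),
        )
    )
    return pt_seq(
        activity("General Physical Examination"),
        diag_loop,
        pt_par(activity("X-ray"), activity("CT scan")),
        pt_xor(activity("Biopsy"), activity("Bronchoscopy"), tau()),
        pt_par(
            activity("Excision of Lung and Bronchus"),
            activity("Computer Aided Surgery"),
            activity("X-ray"),
            activity("Removal of Therapeutic Appliances"),
        ),
        follow_up,
    )


def default_ruleset() -> RuleSet:
    """Sequentialization rules matching the pathway's domain knowledge.

    The surgical block happens on one day; its true order (excision, then
    the control X-ray, then removal of the therapeutic appliance) is
    re-imposed. Invasive diagnostics stamped onto the imaging day are
    ordered after the CT scan.
    """
    return parse_ruleset(
        {
            "rules": [
                {
                    "name": "surgery-order",
                    "source": "+( 'Excision of Lung and Bronchus', 'X-ray', "
                    "'Removal of Therapeutic Appliances', ... )",
                    "target": "+( ->( 'Excision of Lung and Bronchus', 'X-ray', "
                    "'Removal of Therapeutic Appliances' ), ... )",
                },
                {
                    "name": "ct-before-biopsy",
                    "source": "+( 'CT scan', 'Biopsy', ... )",
                    "target": "+( ->( 'CT scan', 'Biopsy' ), ... )",
                },
                {
                    "name": "ct-before-bronchoscopy",
                    "source": "+( 'CT scan', 'Bronchoscopy', ... )",
                    "target": "+( ->( 'CT scan', 'Bronchoscopy' ), ... )",
                },
            ]
        }
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for synthetic log generation.

    ``mean_day_gap`` is the mean (in days, geometric, minimum 1) of the gap
    between consecutive same-day blocks. ``p_loop_repeat`` is the chance of
    another loop round after each completed one. Noise probabilities are
    mutually exclusive per case, drawn in the order singleton, truncate,
    violation.
    """

    tree: ProcessTree = field(default_factory=default_pathway_tree)
    n_cases: int = 200
    mean_day_gap: float = 3.0
    p_loop_repeat: float = 0.4
    p_truncate: float = 0.05
    p_singleton: float = 0.05
    p_violation: float = 0.1
    singleton_max_repeats: int = 3
    start_date: dt.date = dt.date(2017, 1, 1)
    start_spread_days: int = 365
    invasive: tuple[str, ...] = tuple(DEFAULT_INVASIVE)
    noninvasive: tuple[str, ...] = tuple(DEFAULT_NONINVASIVE)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_truncate", "p_singleton", "p_violation", "p_loop_repeat"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.p_truncate + self.p_singleton + self.p_violation > 1.0:
            raise ValueError("noise probabilities may not sum above 1")
        if self.n_cases < 1:
            raise ValueError("n_cases must be at least 1")
        if self.mean_day_gap < 1.0:
            raise ValueError("mean_day_gap must be at least 1 day")

    def to_dict(self) -> dict:
        return {
            "tree": serialize_tree(self.tree),
            "n_cases": self.n_cases,
            "mean_day_gap": self.mean_day_gap,
            "p_loop_repeat": self.p_loop_repeat,
            "p_truncate": self.p_truncate,
            "p_singleton": self.p_singleton,
            "p_violation": self.p_violation,
            "singleton_max_repeats": self.singleton_max_repeats,
            "start_date": self.start_date.isoformat(),
            "start_spread_days": self.start_spread_days,
            "invasive": list(self.invasive),
            "noninvasive": list(self.noninvasive),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, config: Mapping) -> "GeneratorConfig":
        kwargs = dict(config)
        if "tree" in kwargs and isinstance(kwargs["tree"], str):
            kwargs["tree"] = parse_tree(kwargs["tree"])
        if "start_date" in kwargs and isinstance(kwargs["start_date"], str):
            kwargs["start_date"] = dt.date.fromisoformat(kwargs["start_date"])
        for key in ("invasive", "noninvasive"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass(frozen=True)
class CaseRecord:
    case_id: str
    flag: str  # clean | truncated | singleton | violating
    template: str | None  # serialization of the underlying clean variant
    n_events: int


@dataclass(frozen=True)
class EmissionLedger:
    """Per-case ground truth of what the generator emitted."""

    records: tuple[CaseRecord, ...]

    def cases_with_flag(self, *flags: str) -> frozenset[str]:
        return frozenset(r.case_id for r in self.records if r.flag in flags)

    @property
    def noise_cases(self) -> frozenset[str]:
        return self.cases_with_flag("truncated", "singleton", "violating")

    def __getitem__(self, case_id: str) -> CaseRecord:
        for r in self.records:
            if r.case_id == case_id:
                return r
        raise KeyError(case_id)

    def to_dict(self) -> dict:
        return {
            r.case_id: {
                "flag": r.flag,
                "template": r.template,
                "n_events": r.n_events,
            }
            for r in self.records
        }


def _sample_blocks(
    tree: ProcessTree, rng: np.random.Generator, p_loop_repeat: float
) -> list[list[str]]:
    """One random run of the tree as a sequence of same-day blocks.

    A parallel subtree collapses into a single block: with day-granularity
    stamping, everything it emits lands on one day.
    """
    if tree.kind == ACTIVITY:
        return [[tree.label]]
    if tree.kind == TAU:
        return []
    if tree.kind == PT_SEQ:
        return [
            b
            for c in tree.children
            for b in _sample_blocks(c, rng, p_loop_repeat)
        ]
    if tree.kind == PT_XOR:
        child = tree.children[rng.integers(len(tree.children))]
        return _sample_blocks(child, rng, p_loop_repeat)
    if tree.kind == PT_PAR:
        block = [
            label
            for c in tree.children
            for b in _sample_blocks(c, rng, p_loop_repeat)
            for label in b
        ]
        return [block] if block else []
    blocks = _sample_blocks(tree.children[0], rng, p_loop_repeat)
    while rng.random() < p_loop_repeat:
        blocks.extend(_sample_blocks(tree.children[1], rng, p_loop_repeat))
        blocks.extend(_sample_blocks(tree.children[0], rng, p_loop_repeat))
    return blocks


def _blocks_to_events(
    case_id: str,
    blocks: Sequence[Sequence[str]],
    rng: np.random.Generator,
    config: GeneratorConfig,
) -> list[Event]:
    start = config.start_date + dt.timedelta(
        days=int(rng.integers(config.start_spread_days + 1))
    )
    day = start
    events = []
    for i, block in enumerate(blocks):
        if i > 0:
            day = day + dt.timedelta(
                days=int(rng.geometric(1.0 / config.mean_day_gap))
            )
        for label in block:
            events.append(
                Event(
                    case_id=case_id,
                    activity=label,
                    timestamp=day,
                    category=ACTIVITY_CATEGORIES.get(label),
                )
            )
    return events


def _draw_flag(rng: np.random.Generator, config: GeneratorConfig) -> str:
    u = rng.random()
    if u < config.p_singleton:
        return "singleton"
    if u < config.p_singleton + config.p_truncate:
        return "truncated"
    if u < config.p_singleton + config.p_truncate + config.p_violation:
        return "violating"
    return "clean"


def _apply_noise(
    events: list[Event],
    flag: str,
    rng: np.random.Generator,
    config: GeneratorConfig,
    universe: Sequence[str],
) -> tuple[list[Event], str]:
    """Transform a clean event list per the drawn flag.

    Returns (events, realized flag): a violation draw falls back to clean
    when the trace has no invasive procedure to displace.
    """
    if flag == "singleton":
        label = str(rng.choice(np.asarray(sorted(universe), dtype=object)))
        repeats = int(rng.integers(1, config.singleton_max_repeats + 1))
        day = events[0].timestamp
        case_id = events[0].case_id
        out = []
        for k in range(repeats):
            out.append(
                Event(
                    case_id=case_id,
                    activity=label,
                    timestamp=day + dt.timedelta(days=k),
                    category=ACTIVITY_CATEGORIES.get(label),
                )
            )
        return out, "singleton"
    if flag == "truncated":
        keep = int(rng.integers(1, 3))
        return list(events[:keep]), "truncated"
    if flag == "violating":
        inv_idx = next(
            (i for i, e in enumerate(events) if e.activity in config.invasive),
            None,
        )
        if inv_idx is None:
            return events, "clean"
        inv_day = events[inv_idx].timestamp
        nin_idx = next(
            (
                i
                for i, e in enumerate(events)
                if e.activity in config.noninvasive and e.timestamp < inv_day
            ),
            None,
        )
        if nin_idx is None:
            return events, "clean"
        out = list(events)
        out[inv_idx] = replace(events[inv_idx], timestamp=events[nin_idx].timestamp)
        out[nin_idx] = replace(events[nin_idx], timestamp=inv_day)
        return out, "violating"
    return events, "clean"


def simulate_log(config: GeneratorConfig) -> tuple[EventLog, EmissionLedger]:
    """Simulate a full log: clean runs of the tree plus injected noise.

    Deterministic under the config seed: identical configs give
    byte-identical CSV exports.
    """
    from .variants import variant_of_trace

    rng = np.random.default_rng(config.seed)
    universe = sorted(config.tree.labels())
    events_all: list[Event] = []
    records: list[CaseRecord] = []
    for i in range(config.n_cases):
        case_id = f"P{i + 1:04d}"
        blocks = _sample_blocks(config.tree, rng, config.p_loop_repeat)
        events = _blocks_to_events(case_id, blocks, rng, config)
        template = variant_of_trace(
            Trace(case_id=case_id, events=tuple(events))
        ).serialization
        flag = _draw_flag(rng, config)
        events, flag = _apply_noise(events, flag, rng, config, universe)
        events.sort(key=lambda e: e.timestamp)  # stable: same-day order kept
        events_all.extend(events)
        records.append(
            CaseRecord(
                case_id=case_id,
                flag=flag,
                template=template,
                n_events=len(events),
            )
        )
    return build_log(events_all), EmissionLedger(records=tuple(records))


def inject_noise(
    log: EventLog, config: GeneratorConfig
) -> tuple[EventLog, EmissionLedger]:
    """Apply the truncation/singleton/violation transforms to an existing log.

    Deterministic under the config seed; the ledger templates record each
    trace's variant before transformation.
    """
    from .variants import variant_of_trace

    rng = np.random.default_rng(config.seed)
    universe = sorted(log.activity_universe)
    events_all: list[Event] = []
    records: list[CaseRecord] = []
    for trace in log:
        template = variant_of_trace(trace).serialization
        flag = _draw_flag(rng, config)
        events, flag = _apply_noise(list(trace.events), flag, rng, config, universe)
        events.sort(key=lambda e: e.timestamp)
        events_all.extend(events)
        records.append(
            CaseRecord(
                case_id=trace.case_id,
                flag=flag,
                template=template,
                n_events=len(events),
            )
        )
    return build_log(events_all), EmissionLedger(records=tuple(records))
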