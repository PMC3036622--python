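"""Dependency-aware planning, scheduling and caching of basic tasks.

Complex analyses (model fitting, pairwise comparison, alignment,
clustering) decompose into 8 basic task types:

    model_generation, counting_graphlets, rgf_distance, gdd_agreement,
    graal_execution, signature_similarities, kmedoids_clustering,
    basic_properties_comparison

Tasks carry explicit dependencies (e.g. an RGF-distance or GDD-agreement
task needs the graphlet counts of both of its networks first), so a run is
a topological traversal of an acyclic task graph.  At any moment only the
*ready* tasks (all prerequisites done) are eligible, up to the worker
limit.  Every task result is cached on disk under a content-derived key,
so interrupted analyses resume without recomputing anything, and follow-up
analyses (say, re-clustering with a different k) reuse the expensive
graphlet counts.

As a sizing example, fitting 3 data networks against 10 instances of each
of the 7 models plans 3*7*10 = 210 generation tasks, 3 + 210 = 213
counting tasks and 3 * 630 comparison task-triples = 630 comparison
tasks: 1,053 basic tasks in total.
"""

from __future__ import annotations

import hashlib
import json
from concurrent.futures import FIRST_COMPLETED, ThreadPoolExecutor, wait
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

__all__ = [
    "TASK_TYPES",
    "BasicTask",
    "TaskPlan",
    "ResultStore",
    "plan_model_fit",
    "ready_tasks",
    "cache_lookup",
    "run_plan",
]

TASK_TYPES = (
    "model_generation",
    "counting_graphlets",
    "rgf_distance",
    "gdd_agreement",
    "graal_execution",
    "signature_similarities",
    "kmedoids_clustering",
    "basic_properties_comparison",
)


@dataclass(frozen=True)
class BasicTask:
    """One schedulable unit of work.

    ``inputs`` names the artifacts the task consumes (network ids or
    upstream task ids); ``params`` are the task's own parameters.  The
    cache key is a stable digest of all three, so identical work always
    hits the same cache slot.
    """

    task_type: str
    inputs: tuple[str, ...]
    params: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if self.task_type not in TASK_TYPES:
            raise ValueError(f"unknown task type {self.task_type!r}")

    @property
    def task_id(self) -> str:
        parts = [self.task_type, *self.inputs]
        parts += [f"{k}={v}" for k, v in self.params]
        return "|".join(parts)

    @property
    def cache_key(self) -> str:
        payload = json.dumps(
            [self.task_type, list(self.inputs),
             [[k, repr(v)] for k, v in self.params]],
        )
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class TaskPlan:
    tasks: list[BasicTask] = field(default_factory=list)
    #: (prerequisite task_id, dependent task_id) pairs
    deps: set[tuple[str, str]] = field(default_factory=set)

    def add(self, task: BasicTask, after: Iterable[BasicTask] = ()) -> BasicTask:
        self.tasks.append(task)
        for pre in after:
            self.deps.add((pre.task_id, task.task_id))
        return task

    def by_type(self, task_type: str) -> list[BasicTask]:
        return [t for t in self.tasks if t.task_type == task_type]

    def prerequisites(self, task: BasicTask) -> set[str]:
        return {pre for pre, dep in self.deps if dep == task.task_id}

    def validate_acyclic(self) -> None:
        """Raise if the dependency graph contains a cycle."""
        import networkx as nx

        dag = nx.DiGraph()
        dag.add_nodes_from(t.task_id for t in self.tasks)
        dag.add_edges_from(self.deps)
        if not nx.is_directed_acyclic_graph(dag):
            raise ValueError("task dependency graph has a cycle")


def plan_model_fit(n_data: int, n_models: int = 7, n_instances: int = 30,
                   data_ids: Iterable[str] | None = None,
                   model_names: Iterable[str] | None = None) -> TaskPlan:
    """Plan a best-fitting-model analysis.

    For each of ``n_data`` data networks, ``n_instances`` instances of
    each of ``n_models`` models are generated and counted, and each
    data-instance pair is compared three ways (GDD-agreement,
    RGF-distance, basic properties).  Task totals:

        generation  = n_data * n_models * n_instances
        counting    = n_data + n_data * n_models * n_instances
        comparisons = 3 * n_data * n_models * n_instances
    """
    if n_data < 1 or n_models < 1 or n_instances < 1:
        raise ValueError("all counts must be >= 1")
    data_ids = list(data_ids) if data_ids is not None else [
        f"data{d}" for d in range(n_data)
    ]
    model_names = list(model_names) if model_names is not None else [
        f"model{m}" for m in range(n_models)
    ]
    if len(data_ids) != n_data or len(model_names) != n_models:
        raise ValueError("id lists must match the counts")

    plan = TaskPlan()
    count_data: dict[str, BasicTask] = {}
    for d in data_ids:
        count_data[d] = plan.add(BasicTask("counting_graphlets", (d,)))
    for d in data_ids:
        for mod in model_names:
            for i in range(n_instances):
                inst = f"{d}:{mod}:{i}"
                gen = plan.add(BasicTask(
                    "model_generation", (d,),
                    params=(("model", mod), ("instance", i)),
                ))
                cnt = plan.add(
                    BasicTask("counting_graphlets", (inst,)), after=[gen]
                )
                plan.add(BasicTask("gdd_agreement", (d, inst)),
                         after=[count_data[d], cnt])
                plan.add(BasicTask("rgf_distance", (d, inst)),
                         after=[count_data[d], cnt])
                plan.add(BasicTask("basic_properties_comparison", (d, inst)),
                         after=[gen])
    plan.validate_acyclic()
    return plan


def ready_tasks(plan: TaskPlan, completed: Iterable[str]) -> list[BasicTask]:
    """Tasks whose prerequisites are all completed and that are not done.

    ``completed`` holds task ids.  Applying this repeatedly, completing
    the returned tasks each time, visits every task exactly once in a
    topological order.
    """
    done = set(completed)
    known = {t.task_id for t in plan.tasks}
    unknown = done - known
    if unknown:
        raise ValueError(f"unknown completed task ids: {sorted(unknown)[:3]}")
    out = []
    for t in plan.tasks:
        if t.task_id in done:
            continue
        if plan.prerequisites(t) <= done:
            out.append(t)
    return out


class ResultStore:
    """File-backed cache of task results, keyed by the task cache key."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)

    def _path(self, key: str) -> Path:
        return self.root / f"{key}.json"

    def put(self, task: BasicTask, result: object) -> None:
        self._path(task.cache_key).write_text(
            json.dumps({"task_id": task.task_id, "result": result})
        )

    def get(self, task: BasicTask) -> object:
        payload = json.loads(self._path(task.cache_key).read_text())
        return payload["result"]

    def __contains__(self, task: BasicTask) -> bool:
        return cache_lookup(self, task)


def cache_lookup(store: ResultStore, task: BasicTask) -> bool:
    """True iff a readable cached artifact exists for this task."""
    path = store._path(task.cache_key)
    if not path.exists():
        return False
    try:
        json.loads(path.read_text())
        return True
    except (json.JSONDecodeError, OSError):
        import warnings

        warnings.warn(f"corrupt cache artifact {path}; treating as a miss")
        return False


def run_plan(plan: TaskPlan,
             runner: Callable[[BasicTask, Mapping[str, object]], object],
             workers: int = 1,
             store: ResultStore | None = None) -> dict[str, object]:
    """Execute a plan, scheduling ready tasks onto up to ``workers`` threads.

    ``runner(task, upstream)`` computes one task given the results of its
    prerequisites (a task_id -> result mapping).  Cached tasks are not
    recomputed.  Results are independent of the worker count because the
    task graph fixes all data flow.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    plan.validate_acyclic()
    results: dict[str, object] = {}
    by_id = {t.task_id: t for t in plan.tasks}

    def upstream(task: BasicTask) -> dict[str, object]:
        return {pre: results[pre] for pre in plan.prerequisites(task)}

    with ThreadPoolExecutor(max_workers=workers) as pool:
        pending: dict = {}
        scheduled: set[str] = set()
        while len(results) < len(by_id):
            for task in ready_tasks(plan, results.keys()):
                if task.task_id in scheduled:
                    continue
                scheduled.add(task.task_id)
                if store is not None and cache_lookup(store, task):
                    results[task.task_id] = store.get(task)
                    continue
                pending[pool.submit(runner, task, upstream(task))] = task
            if not pending:
                continue
            done, _ = wait(pending.keys(), return_when=FIRST_COMPLETED)
            for fut in done:
                task = pending.pop(fut)
                results[task.task_id] = fut.result()
                if store is not None:
                    store.put(task, fut.result())
    return results
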