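"""Replicate simulation, stabilization stopping, and efficiency sweeps.

Exploration efficiency is summarised two ways, each as mean +/- standard
error over replicate walks per memory size m:

* **coverage at a fixed hop count** — how much of the building an agent
  has seen after a hop budget;
* **hops to a target coverage** — how long an agent needs to see a
  given fraction of the building.

Replicates are seeded by a counter-based spawn from one master seed, so
ensembles are reproducible and embarrassingly parallel in principle.
Instead of a fixed replicate count, an ensemble may run in batches until
the running variance of the radius of gyration of the generated walks
stabilizes (relative change below a tolerance for a number of
consecutive batches), capped at 30,000 replicates by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .agents import TerminationRule, run_agent
from .environment import EnvironmentGraph
from .markov import build_context_table
from .metrics import radius_of_gyration
from .trajectories import TrajectoryCorpus, coverage

logger = logging.getLogger(__name__)


@dataclass
class StabilizationPolicy:
    """Stop adding replicates once the running variance of the radius of
    gyration settles: relative change below ``rel_tol`` for
    ``consecutive`` consecutive batches, capped at ``cap`` replicates."""

    batch: int = 500
    rel_tol: float = 0.01
    consecutive: int = 3
    cap: int = 30_000


@dataclass
class EnsembleResult:
    """Per-replicate records for one agent specification."""

    spec: dict
    master_seed: int
    records: list[dict] = field(default_factory=list)
    stabilized: bool | None = None

    @property
    def n_replicates(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(
            self.records,
            columns=["replicate", "hops", "coverage", "rog", "truncated"],
        )

    def summary(self, column: str, exclude_truncated: bool = False) -> tuple[float, float, int]:
        """(mean, standard error, n) of a per-replicate column."""
        vals = [
            r[column]
            for r in self.records
            if not (exclude_truncated and r["truncated"])
        ]
        n = len(vals)
        if n == 0:
            return (math.nan, math.nan, 0)
        mean = float(np.mean(vals))
        se = float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        return (mean, se, n)


@dataclass
class SummaryPoint:
    """One point of an efficiency sweep: mean +/- SE at memory size m."""

    m: int
    mean: float
    se: float
    n: int
    excluded: int = 0


def _spec_label(spec: dict) -> int:
    if spec["kind"] == "random":
        return 0
    if spec["kind"] == "memory":
        return int(spec["m"])
    return int(spec["table"].order)


def _run_one(
    spec: dict,
    env: EnvironmentGraph,
    rule: TerminationRule,
    master_seed: int,
    index: int,
    start: str | None,
) -> dict:
    traj = run_agent(
        spec["kind"],
        env,
        rule,
        np.random.SeedSequence((master_seed, index)),
        start=start,
        m=spec.get("m"),
        table=spec.get("table"),
    )
    return {
        "replicate": index,
        "hops": traj.n_hops,
        "coverage": coverage(traj, env),
        "rog": radius_of_gyration(traj, env),
        "truncated": traj.truncated,
    }


def run_ensemble(
    spec: dict,
    env: EnvironmentGraph,
    rule: TerminationRule,
    master_seed: int = 0,
    n_replicates: int | None = None,
    policy: StabilizationPolicy | None = None,
    start: str | None = None,
) -> EnsembleResult:
    """Run replicate walks for one agent spec.

    ``spec`` is e.g. ``{"kind": "random"}``, ``{"kind": "memory", "m": 7}``
    or ``{"kind": "markov", "table": table}``.  Give either a fixed
    ``n_replicates`` or a :class:`StabilizationPolicy`.
    """
    if n_replicates is None and policy is None:
        raise ValueError("give n_replicates or a stabilization policy")
    result = EnsembleResult(
        spec={k: v for k, v in spec.items() if k != "table"}
        | ({"order": spec["table"].order} if spec.get("table") is not None else {}),
        master_seed=master_seed,
    )
    if n_replicates is not None:
        if n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for i in range(n_replicates):
            result.records.append(_run_one(spec, env, rule, master_seed, i, start))
        return result
    # stabilization mode
    prev_var: float | None = None
    conforming = 0
    index = 0
    while index < policy.cap:
        n_batch = min(policy.batch, policy.cap - index)
        for _ in range(n_batch):
            result.records.append(_run_one(spec, env, rule, master_seed, index, start))
            index += 1
        rogs = np.array([r["rog"] for r in result.records])
        var = float(rogs.var(ddof=1)) if len(rogs) > 1 else 0.0
        if prev_var is not None and prev_var > 0:
            rel = abs(var - prev_var) / prev_var
            conforming = conforming + 1 if rel < policy.rel_tol else 0
            logger.info(
                "stabilization: n=%d var=%.4f rel_change=%.4f (%d/%d conforming)",
                index, var, rel, conforming, policy.consecutive,
            )
            if conforming >= policy.consecutive:
                result.stabilized = True
                return result
        prev_var = var
    result.stabilized = False
    return result


def coverage_at_hops(
    specs: Sequence[dict],
    env: EnvironmentGraph,
    hops: int,
    n_replicates: int = 1000,
    master_seed: int = 0,
    start: str | None = None,
) -> list[SummaryPoint]:
    """Mean +/- SE of coverage after exactly ``hops`` hops, per spec."""
    if hops < 0:
        raise ValueError("hops must be >= 0")
    rule = TerminationRule("fixed_hops", hops, cap=max(hops, 1))
    points = []
    for k, spec in enumerate(specs):
        res = run_ensemble(
            spec, env, rule, master_seed=master_seed + k, n_replicates=n_replicates,
            start=start,
        )
        mean, se, n = res.summary("coverage")
        points.append(SummaryPoint(_spec_label(spec), mean, se, n))
    return points


def hops_to_coverage(
    specs: Sequence[dict],
    env: EnvironmentGraph,
    coverage_target: float,
    n_replicates: int = 1000,
    master_seed: int = 0,
    cap: int = 100_000,
    start: str | None = None,
) -> list[SummaryPoint]:
    """Mean +/- SE of the first hop count reaching ``coverage_target`` %.

    Replicates that fail to reach the target before the cap are excluded
    from the mean; the excluded count is reported on each point.
    """
    if not 0 < coverage_target <= 100:
        raise ValueError("coverage_target must be in (0, 100]")
    rule = TerminationRule("target_coverage", coverage_target, cap=cap)
    points = []
    for k, spec in enumerate(specs):
        res = run_ensemble(
            spec, env, rule, master_seed=master_seed + k, n_replicates=n_replicates,
            start=start,
        )
        mean, se, n = res.summary("hops", exclude_truncated=True)
        excluded = res.n_replicates - n
        if excluded:
            logger.warning(
                "hops_to_coverage: excluded %d/%d truncated replicates (m=%s)",
                excluded, res.n_replicates, _spec_label(spec),
            )
        points.append(SummaryPoint(_spec_label(spec), mean, se, n, excluded))
    return points


def summary_table(points: Sequence[SummaryPoint]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [vars(p) for p in points], columns=["m", "mean", "se", "n", "excluded"]
    )


def dataset_size_sensitivity(
    corpus: TrajectoryCorpus,
    env: EnvironmentGraph,
    m: int,
    fractions: Sequence[float],
    coverage_target: float = 50.0,
    n_replicates: int = 200,
    master_seed: int = 0,
    start: str | None = None,
) -> pd.DataFrame:
    """How Markov-agent efficiency depends on training-corpus size.

    For each subsample fraction, a random trajectory subsample is drawn,
    the context table rebuilt, and the Markov agent's hops-to-coverage
    summarised.  Subsample seeds are included in the output.
    """
    rows = []
    ids = sorted(t.player_id for t in corpus)
    for j, frac in enumerate(fractions):
        if not 0 < frac <= 1:
            raise ValueError(f"fractions must be in (0, 1], got {frac}")
        n_keep = int(round(frac * len(ids)))
        if n_keep < 1:
            raise ValueError(f"fraction {frac} yields zero trajectories")
        sub_seed = master_seed + 1000 * (j + 1)
        rng = np.random.default_rng(np.random.SeedSequence((sub_seed,)))
        keep = list(rng.choice(ids, size=n_keep, replace=False)) if frac < 1 else ids
        sub = corpus.subset(keep)
        table = build_context_table(sub, m)
        (point,) = hops_to_coverage(
            [{"kind": "markov", "table": table}],
            env,
            coverage_target,
            n_replicates=n_replicates,
            master_seed=master_seed,
            start=start,
        )
        rows.append(
            {
                "fraction": frac,
                "n_trajectories": n_keep,
                "subsample_seed": sub_seed,
                "mean_hops": point.mean,
                "se_hops": point.se,
                "n": point.n,
                "excluded": point.excluded,
            }
        )
    return pd.DataFrame.from_records(rows)
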