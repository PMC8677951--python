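"""Best-first-search inverse design over a substitution compound space.

The search greedily optimizes one site group at a time: all library fragments
are tried on the current group with the other groups frozen, each candidate
switch is scored by the chosen contrast objective (both switch states are
evaluated, since the objective is an ON/OFF contrast), and the strictly best
improvement is accepted.  Sweeps over all groups repeat until a full sweep
yields no improvement — the convergence rule — or a sweep cap is hit.  Under
the independent-site approximation (additive landscapes) a single sweep finds
the global optimum; with inter-site couplings the result is a monotone
lower bound on the exhaustive optimum.

Structure evaluations are cached by canonical key and frequency, and the
trajectory of every evaluation/acceptance is logged (JSONL-serializable), so
interrupted campaigns can be resumed and the influence of each substituent on
each site can be inspected afterwards.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import chemspace as cs
from . import contrast as ct

__all__ = [
    "BFSConfig",
    "TrajectoryRecord",
    "Trajectory",
    "BFSResult",
    "random_initial_assignment",
    "run_bfs",
    "exhaustive_search",
    "BFSError",
]

EXHAUSTIVE_GUARD = 100_000


class BFSError(RuntimeError):
    """Search configuration or evaluator failure."""


@dataclass(frozen=True)
class BFSConfig:
    """Search settings.

    ``objective`` is "ratio" or "difference"; ``on_state``/``off_state`` name
    the two switch states whose β_HRS the evaluator must supply.  The error
    policy decides what an evaluator failure on a candidate does: ``abort``
    re-raises, ``neg_inf`` scores the candidate as -inf and continues.
    """

    seed: int = 0
    max_global_sweeps: int = 10
    site_order: tuple[int, ...] | None = None
    objective: str = "ratio"
    on_state: str = "26R"
    off_state: str = "28R"
    frequency: float = 0.0
    clamp_threshold: float = ct.DEFAULT_CLAMP_THRESHOLD
    clamp_value: float = ct.DEFAULT_CLAMP_VALUE
    on_error: str = "abort"  # abort | neg_inf

    def __post_init__(self):
        if self.max_global_sweeps < 1:
            raise BFSError("max_global_sweeps must be >= 1")
        if self.objective not in ct.OBJECTIVES:
            raise BFSError(f"unknown objective {self.objective!r}")
        if self.on_error not in ("abort", "neg_inf"):
            raise BFSError(f"unknown error policy {self.on_error!r}")


@dataclass(frozen=True)
class TrajectoryRecord:
    sweep: int
    group: int
    candidate: str
    key: str
    objective_value: float
    accepted: bool


@dataclass
class Trajectory:
    """Ordered evaluation log plus bookkeeping counters."""

    records: list[TrajectoryRecord] = field(default_factory=list)
    evaluations_performed: int = 0
    cache_hits: int = 0

    def accepted_values(self) -> list[float]:
        return [r.objective_value for r in self.records if r.accepted]

    def to_jsonl(self, path, header: dict | None = None) -> None:
        with Path(path).open("w") as fh:
            if header is not None:
                fh.write(json.dumps({"header": header}) + "\n")
            for r in self.records:
                fh.write(json.dumps(asdict(r)) + "\n")


@dataclass(frozen=True)
class BFSResult:
    best_assignment: cs.Assignment
    best_objective: float
    trajectory: Trajectory
    converged: bool


def random_initial_assignment(
    pattern: cs.SubstitutionPattern, library, seed: int
) -> cs.Assignment:
    """Uniform random starting point; reproducible for a fixed seed."""
    if not library:
        raise cs.ChemSpaceError("library must be non-empty")
    rng = np.random.default_rng(seed)
    lib = tuple(library)
    choices = tuple(lib[i] for i in rng.integers(0, len(lib), size=pattern.n_groups))
    return cs.Assignment(pattern, choices)


class _SwitchScorer:
    """Scores assignments as switches; caches per structure key + frequency."""

    def __init__(self, evaluator, config: BFSConfig, trajectory: Trajectory):
        self.evaluator = evaluator
        self.config = config
        self.trajectory = trajectory
        self._beta_cache: dict[tuple[str, float], float] = {}
        self._objective_cache: dict[str, float] = {}

    def _beta(self, state: str, assignment: cs.Assignment) -> float:
        key = (cs.SwitchStructure(state, assignment).key, self.config.frequency)
        if key in self._beta_cache:
            return self._beta_cache[key]
        value = self.evaluator(state, assignment, self.config.frequency)
        self._beta_cache[key] = value
        return value

    def objective(self, assignment: cs.Assignment) -> float:
        cfg = self.config
        cache_key = assignment.key_body
        if cache_key in self._objective_cache:
            self.trajectory.cache_hits += 1
            return self._objective_cache[cache_key]
        self.trajectory.evaluations_performed += 1
        try:
            pair = ct.SwitchPair(
                beta_on=self._beta(cfg.on_state, assignment),
                beta_off=self._beta(cfg.off_state, assignment),
                on_label=cfg.on_state,
                off_label=cfg.off_state,
                frequency=cfg.frequency,
            )
            result = ct.evaluate_switch(
                pair, cfg.objective, cfg.clamp_threshold, cfg.clamp_value
            )
            value = result.objective_value
        except Exception:
            if cfg.on_error == "abort":
                raise
            value = -math.inf
        self._objective_cache[cache_key] = value
        return value


def run_bfs(
    pattern: cs.SubstitutionPattern,
    library,
    evaluator,
    config: BFSConfig,
    initial: cs.Assignment | None = None,
) -> BFSResult:
    """Greedy site-by-site contrast maximization with sweep convergence.

    Improvement means *strictly* greater objective (equal-valued candidates
    never replace the incumbent, which guarantees termination); ties among
    improving candidates break toward the earliest library fragment.
    """
    lib = tuple(library)
    current = initial if initial is not None else random_initial_assignment(
        pattern, lib, config.seed
    )
    order = config.site_order or tuple(range(pattern.n_groups))
    if sorted(order) != list(range(pattern.n_groups)):
        raise BFSError(f"site_order must permute group indices, got {order}")

    trajectory = Trajectory()
    scorer = _SwitchScorer(evaluator, config, trajectory)
    current_value = scorer.objective(current)
    trajectory.records.append(
        TrajectoryRecord(0, -1, "<initial>", current.key_body, current_value, True)
    )

    converged = False
    for sweep in range(1, config.max_global_sweeps + 1):
        improved = False
        for group in order:
            best_candidate = None
            best_value = current_value
            for fragment in lib:
                choices = list(current.choices)
                choices[group] = fragment
                candidate = cs.Assignment(pattern, tuple(choices))
                value = scorer.objective(candidate)
                accepted = value > best_value  # strict: prevents cycling
                trajectory.records.append(
                    TrajectoryRecord(sweep, group, fragment,
                                     candidate.key_body, value, False)
                )
                if accepted:
                    best_candidate, best_value = candidate, value
            if best_candidate is not None:
                current, current_value = best_candidate, best_value
                improved = True
                trajectory.records.append(
                    TrajectoryRecord(sweep, group, current.choices[group],
                                     current.key_body, current_value, True)
                )
        if not improved:
            converged = True
            break

    return BFSResult(current, current_value, trajectory, converged)


def exhaustive_search(
    pattern: cs.SubstitutionPattern,
    library,
    evaluator,
    config: BFSConfig | None = None,
) -> tuple[cs.Assignment, float]:
    """Global optimum by full enumeration (oracle for the greedy search).

    Ties break toward the earliest assignment in enumeration order.  Refuses
    spaces larger than ``EXHAUSTIVE_GUARD`` points.
    """
    cfg = config if config is not None else BFSConfig()
    n = cs.space_size(pattern, library)
    if n > EXHAUSTIVE_GUARD:
        raise BFSError(
            f"space has {n} points, above the exhaustive-search guard "
            f"({EXHAUSTIVE_GUARD}); use run_bfs instead"
        )
    trajectory = Trajectory()
    scorer = _SwitchScorer(evaluator, cfg, trajectory)
    best_assignment = None
    best_value = -math.inf
    for assignment in cs.enumerate_space(pattern, library):
        value = scorer.objective(assignment)
        if value > best_value:
            best_assignment, best_value = assignment, value
    return best_assignment, best_value
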