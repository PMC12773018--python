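"""Hyperparameter search: seeded random sampling over typed spaces.

Log-scale parameters are drawn uniformly in log space.  The default
sampler is pure random search so every search is reproducible from one
integer seed; an adaptive sampler can be plugged in behind the same
interface.  Budgets are expressed purely as trial counts (defaults 200 /
50 / 20 depending on head cost).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from .metrics import MetricReport

__all__ = [
    "Uniform",
    "LogUniform",
    "IntUniform",
    "Categorical",
    "SearchSpace",
    "TrialRecord",
    "sample_params",
    "run_search",
    "select_best",
    "TRIAL_BUDGETS",
]

#: Default trial budgets: classical heads / neural heads / long-running ones.
TRIAL_BUDGETS = {"classical": 200, "neural": 50, "long": 20}


@dataclass(frozen=True)
class Uniform:
    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError("require low < high")

    def sample(self, rng: np.random.Generator):
        return float(rng.uniform(self.low, self.high))


@dataclass(frozen=True)
class LogUniform:
    low: float
    high: float

    def __post_init__(self):
        if not (0 < self.low < self.high):
            raise ValueError("loguniform requires 0 < low < high")

    def sample(self, rng: np.random.Generator):
        return float(np.exp(rng.uniform(math.log(self.low), math.log(self.high))))


@dataclass(frozen=True)
class IntUniform:
    low: int
    high: int  # inclusive

    def __post_init__(self):
        if not self.low <= self.high:
            raise ValueError("require low <= high")

    def sample(self, rng: np.random.Generator):
        return int(rng.integers(self.low, self.high + 1))


@dataclass(frozen=True)
class Categorical:
    choices: tuple

    def __init__(self, choices):
        object.__setattr__(self, "choices", tuple(choices))
        if not self.choices:
            raise ValueError("empty categorical")

    def sample(self, rng: np.random.Generator):
        return self.choices[int(rng.integers(0, len(self.choices)))]


SearchSpace = Dict[str, object]


@dataclass
class TrialRecord:
    trial_id: int
    params: dict
    value: Optional[float]
    status: str  # "ok" or "failed"
    seed: int
    error: str = ""


def sample_params(space: SearchSpace, rng: np.random.Generator) -> dict:
    """Draw one parameter set; log-scale entries are uniform in log space."""
    return {name: dist.sample(rng) for name, dist in space.items()}


def run_search(
    space: SearchSpace,
    objective_fn: Callable[[dict], float],
    n_trials: int,
    seed: int = 0,
    direction: str = "maximize",
) -> Tuple[TrialRecord, List[TrialRecord]]:
    """Random search; returns (best trial, full history).

    Failed trials (objective raised, or returned a non-finite value) are
    recorded but excluded from selection.  Raises if every trial failed.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if direction not in ("maximize", "minimize"):
        raise ValueError("direction must be maximize or minimize")
    rng = np.random.default_rng(seed)
    history: List[TrialRecord] = []
    for t in range(n_trials):
        params = sample_params(space, rng)
        try:
            value = float(objective_fn(params))
            if not math.isfinite(value):
                raise ValueError(f"non-finite objective {value}")
            history.append(TrialRecord(t, params, value, "ok", seed))
        except Exception as exc:  # noqa: BLE001 - trial isolation
            history.append(TrialRecord(t, params, None, "failed", seed, error=str(exc)))
    ok = [h for h in history if h.status == "ok"]
    if not ok:
        raise RuntimeError("all trials failed")
    sign = 1.0 if direction == "maximize" else -1.0
    best = max(ok, key=lambda h: (sign * h.value, -h.trial_id))
    return best, history


def select_best(
    results: Dict[str, MetricReport], task_type: str
) -> Tuple[str, MetricReport]:
    """Pick the winning head family.

    Classification is ranked by best-F1 (ties: MCC, then family name);
    regression (incl. affinity) by Spearman rho (ties: R^2, then name).
    """
    if not results:
        raise ValueError("empty results")

    def val(x: Optional[float]) -> float:
        return -math.inf if x is None else x

    if task_type == "binary":
        key = lambda kv: (-val(kv[1].best_f1), -val(kv[1].mcc), kv[0])
    else:
        key = lambda kv: (-val(kv[1].spearman_rho), -val(kv[1].r2), kv[0])
    name, report = min(results.items(), key=key)
    return name, report
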