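"""Assessment design: invert the mastery computation.

Rather than asking "what confidence does this criterion give me?", the
planner answers the design questions a practitioner faces before the
assessment:

* ``min_trials_for_confidence`` -- the smallest number of trials n such
  that a student meeting criterion tau (by default 100%) yields
  Pr(p >= p*) at or above a target confidence;
* ``min_correct_for_confidence`` -- for a fixed n, the smallest correct
  count x reaching the target confidence.

The required correct count for a proportion criterion is ceil(tau * n): a
fractional trial cannot be partially correct and the criterion is a floor.
The search over n is a linear scan up to a configurable bound -- b at
x = ceil(tau * n) is not monotone in n for tau < 1 (the ceiling creates a
sawtooth), so bisection would be unsound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .posterior import JEFFREYS, PriorSpec, TrialCount, mastery_prob, posterior_from_counts

__all__ = ["DesignQuery", "PlanResult", "min_trials_for_confidence", "min_correct_for_confidence"]

DEFAULT_MAX_TRIALS = 10_000


@dataclass(frozen=True)
class DesignQuery:
    """A design question: reach confidence ``b_target`` that p >= ``p_star``.

    ``mode="min_n"`` searches over trial counts with a fixed proportion
    criterion ``tau``; ``mode="min_x"`` searches over correct counts for a
    fixed ``n``.
    """

    p_star: float
    b_target: float
    mode: str = "min_n"
    tau: float = 1.0
    n: Optional[int] = None
    prior: PriorSpec = JEFFREYS
    max_trials: int = DEFAULT_MAX_TRIALS

    def __post_init__(self) -> None:
        if not 0.0 < self.p_star < 1.0:
            raise ValueError(f"p_star must be in (0, 1), got {self.p_star}")
        if not 0.0 < self.b_target < 1.0:
            raise ValueError(f"b_target must be in (0, 1), got {self.b_target}")
        if self.mode not in ("min_n", "min_x"):
            raise ValueError(f"mode must be 'min_n' or 'min_x', got {self.mode!r}")
        if self.mode == "min_n" and not 0.0 < self.tau <= 1.0:
            raise ValueError(f"tau must be in (0, 1], got {self.tau}")
        if self.mode == "min_x":
            if self.n is None or self.n < 1:
                raise ValueError("mode 'min_x' requires a fixed n >= 1")
        if self.max_trials < 1:
            raise ValueError(f"max_trials must be >= 1, got {self.max_trials}")


@dataclass(frozen=True)
class PlanResult:
    """Outcome of a design query; ``found=False`` means no solution in bounds."""

    found: bool
    query: DesignQuery
    n: Optional[int] = None
    x: Optional[int] = None
    achieved_b: Optional[float] = None

    def as_dict(self) -> dict:
        q = self.query
        return {
            "found": self.found,
            "n": self.n,
            "x": self.x,
            "achieved_b": self.achieved_b,
            "query": {
                "mode": q.mode,
                "p_star": q.p_star,
                "b_target": q.b_target,
                "tau": q.tau if q.mode == "min_n" else None,
                "fixed_n": q.n,
                "max_trials": q.max_trials,
            },
        }


def _b(n: int, x: int, p_star: float, prior: PriorSpec) -> float:
    return mastery_prob(posterior_from_counts(TrialCount(n=n, x=x), prior), p_star)


def min_trials_for_confidence(q: DesignQuery) -> PlanResult:
    """Smallest n with Pr(p >= p_star | x = ceil(tau*n) of n) >= b_target.

    Exhausting the ``max_trials`` bound returns an explicit no-solution
    result rather than raising.
    """
    if q.mode != "min_n":
        raise ValueError(f"query mode must be 'min_n', got {q.mode!r}")
    for n in range(1, q.max_trials + 1):
        x = math.ceil(q.tau * n)
        b = _b(n, x, q.p_star, q.prior)
        if b >= q.b_target:
            return PlanResult(found=True, query=q, n=n, x=x, achieved_b=b)
    return PlanResult(found=False, query=q)


def min_correct_for_confidence(q: DesignQuery) -> PlanResult:
    """Smallest x in 0..n with Pr(p >= p_star | x of n) >= b_target.

    b is strictly increasing in x, so the first x reaching the target is
    the unique minimum.
    """
    if q.mode != "min_x":
        raise ValueError(f"query mode must be 'min_x', got {q.mode!r}")
    assert q.n is not None
    for x in range(q.n + 1):
        b = _b(q.n, x, q.p_star, q.prior)
        if b >= q.b_target:
            return PlanResult(found=True, query=q, n=q.n, x=x, achieved_b=b)
    return PlanResult(found=False, query=q)
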