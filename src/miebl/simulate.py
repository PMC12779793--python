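"""Monte Carlo validation of the framework's operating characteristics.

``simulate_criterion`` is the frequentist mirror of the Bayesian statement:
draw a population of students with true mastery p distributed as the prior,
give each an n-trial assessment, keep those who meet the criterion, and
measure (a) the fraction whose true mastery is below the desired level
(the misclassification rate, which converges to 1 - b) and (b) their mean
true mastery (which converges to the posterior mean).  This quantifies the
selection bias between an observed criterion tau and true mastery p that
inflates apparent skill loss at maintenance.

``expected_maintenance_proportion`` gives the posterior-predictive expected
success proportion over future trials -- the mastery level one should
actually expect to see at maintenance, absent any real skill loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .posterior import JEFFREYS, PriorSpec, TrialCount, posterior_from_counts, posterior_mean

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "simulate_criterion",
    "expected_maintenance_proportion",
]


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation run.

    ``conditioning="exact"`` keeps replicates with X = x_criterion, matching
    the core model; ``"at_least"`` keeps X >= x_criterion, the reading the
    published notation Pr(p >= p* | x/n >= tau) suggests, so the notational
    ambiguity can be explored empirically.  ``prior`` doubles as the
    population distribution of true mastery, making the simulation the exact
    frequentist mirror of the Bayesian computation; pass a different
    PriorSpec to probe robustness.
    """

    n: int
    x_criterion: int
    p_star: float
    prior: PriorSpec = JEFFREYS
    reps: int = 200_000
    seed: int = 0
    conditioning: str = "exact"

    def __post_init__(self) -> None:
        TrialCount(n=self.n, x=self.x_criterion)  # reuse bounds validation
        if not 0.0 <= self.p_star <= 1.0:
            raise ValueError(f"p_star must be in [0, 1], got {self.p_star}")
        if self.reps < 1:
            raise ValueError(f"reps must be >= 1, got {self.reps}")
        if self.conditioning not in ("exact", "at_least"):
            raise ValueError(
                f"conditioning must be 'exact' or 'at_least', got {self.conditioning!r}"
            )


@dataclass(frozen=True)
class SimulationResult:
    """Monte Carlo operating characteristics of one criterion.

    When no replicate meets the criterion (``n_meeting = 0``) the fractions
    are undefined and reported as None with ``degenerate=True``, never as
    silent NaN.
    """

    reps: int
    n_meeting: int
    misclassified_frac: Optional[float]
    mean_true_p_given_criterion: Optional[float]
    mc_se: Optional[float]
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "reps": self.reps,
            "n_meeting": self.n_meeting,
            "misclassified_frac": self.misclassified_frac,
            "mean_true_p_given_criterion": self.mean_true_p_given_criterion,
            "mc_se": self.mc_se,
            "degenerate": self.degenerate,
        }


def simulate_criterion(cfg: SimulationConfig, return_draws: bool = False):
    """Simulate students meeting a criterion and their true mastery.

    Draws p ~ prior and X ~ Binomial(n, p) per replicate with a dedicated
    generator seeded from ``cfg.seed`` (no global random state); identical
    configs give bit-identical results.  With ``return_draws=True`` also
    returns the per-replicate (p, X, met) arrays for audit dumps.
    """
    rng = np.random.default_rng(cfg.seed)
    p = rng.beta(cfg.prior.prior_alpha, cfg.prior.prior_beta, size=cfg.reps)
    x = rng.binomial(cfg.n, p)
    if cfg.conditioning == "exact":
        met = x == cfg.x_criterion
    else:
        met = x >= cfg.x_criterion
    n_meeting = int(met.sum())
    if n_meeting == 0:
        result = SimulationResult(
            reps=cfg.reps,
            n_meeting=0,
            misclassified_frac=None,
            mean_true_p_given_criterion=None,
            mc_se=None,
            degenerate=True,
        )
    else:
        p_met = p[met]
        frac = float(np.mean(p_met < cfg.p_star))
        result = SimulationResult(
            reps=cfg.reps,
            n_meeting=n_meeting,
            misclassified_frac=frac,
            mean_true_p_given_criterion=float(p_met.mean()),
            mc_se=math.sqrt(frac * (1.0 - frac) / n_meeting),
        )
    if return_draws:
        return result, (p, x, met)
    return result


def expected_maintenance_proportion(
    counts: TrialCount, prior: PriorSpec = JEFFREYS, m: int = 10
) -> tuple[float, int]:
    """Expected success proportion over m future trials, given (n, x).

    Under the posterior-predictive distribution the expected proportion of
    correct responses in any number of future exchangeable trials equals
    the posterior mean; m is echoed for reporting.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return posterior_mean(posterior_from_counts(counts, prior)), m
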