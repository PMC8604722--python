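"""Design-stage machinery: power, randomization, and the Bayesian go/no-go.

The trial was sized on a two-sample comparison of normal means: an 11-point
UAS7 difference, s.d. 13, two-sided alpha 0.10 and a 10% dropout rate give
roughly 90% power at 30 patients per arm.  Randomization uses stratified
permuted blocks (stratified by country).  The interim decision rule computes,
under a normal model with flat prior and known s.d., the posterior-predictive
probability that a future phase-3 trial's estimate meets a prespecified
effect threshold; probabilities > 0.60 trigger "go" and < 0.25 "no-go".

Effect magnitudes here are positive-is-better: UAS7 improvements (negative
changes) should be entered as positive differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PowerSpec",
    "InterimDecision",
    "compute_power",
    "simulate_power",
    "posterior_predictive_go_nogo",
    "randomize_patients",
]

GO_CUTOFF = 0.60
NOGO_CUTOFF = 0.25


@dataclass(frozen=True)
class PowerSpec:
    """Two-arm power calculation inputs (score points / fractions)."""

    difference: float
    sd: float
    alpha: float = 0.10
    n_per_arm: int = 30
    dropout: float = 0.10

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def n_evaluable(self) -> int:
        return int(np.floor(self.n_per_arm * (1.0 - self.dropout)))


def compute_power(spec: PowerSpec, method: str = "normal") -> float:
    """Power of the two-sided two-sample test at the dropout-adjusted n.

    ``method='normal'`` uses the normal approximation; ``'t'`` the exact
    noncentral-t power of the equal-variance t-test.
    """
    n = spec.n_evaluable
    if n < 2:
        raise ValueError(f"evaluable n per arm must be >= 2, got {n}")
    se = spec.sd * np.sqrt(2.0 / n)
    ncp = spec.difference / se
    if method == "normal":
        z = stats.norm.ppf(1.0 - spec.alpha / 2.0)
        return float(stats.norm.sf(z - ncp) + stats.norm.cdf(-z - ncp))
    if method == "t":
        dof = 2 * n - 2
        tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, dof)
        return float(stats.nct.sf(tcrit, dof, ncp) + stats.nct.cdf(-tcrit, dof, ncp))
    raise ValueError(f"unknown method {method!r}")


def simulate_power(
    spec: PowerSpec, replicates: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Monte Carlo power of the two-sided t-test; returns (power, MC s.e.)."""
    if replicates < 1000:
        raise ValueError("use >= 1000 replicates for a stable estimate")
    n = spec.n_evaluable
    if n < 2:
        raise ValueError(f"evaluable n per arm must be >= 2, got {n}")
    rng = np.random.default_rng(seed)
    dof = 2 * n - 2
    tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, dof)
    rej = 0
    chunk = 20_000
    done = 0
    while done < replicates:
        b = min(chunk, replicates - done)
        x = rng.normal(spec.difference, spec.sd, (b, n))
        y = rng.normal(0.0, spec.sd, (b, n))
        sp = np.sqrt((x.var(axis=1, ddof=1) + y.var(axis=1, ddof=1)) / 2.0)
        tstat = (x.mean(axis=1) - y.mean(axis=1)) / (sp * np.sqrt(2.0 / n))
        rej += int((np.abs(tstat) > tcrit).sum())
        done += b
    p = rej / replicates
    return p, float(np.sqrt(p * (1 - p) / replicates))


@dataclass
class InterimDecision:
    """Posterior-predictive go/no-go evaluation at an interim look."""

    estimate: float          # interim effect estimate (positive = benefit)
    n_interim: int
    sd: float                # known s.d. of individual outcomes
    threshold: float         # phase-3 effect size to meet or exceed
    n_phase3: int
    probability: float = np.nan
    decision: str = ""


def posterior_predictive_go_nogo(
    estimate: float,
    n_interim: int,
    threshold: float,
    n_phase3: int,
    sd: float = 13.0,
    predictive: bool = True,
) -> InterimDecision:
    """Probability that a future trial meets the effect threshold, and the
    resulting go (> 0.60) / no-go (< 0.25) / consider-zone decision.

    With a flat prior and known s.d., the posterior of the true two-arm
    difference is Normal(estimate, sd^2 * 2/n_interim).  The phase-3
    estimate adds sampling variance sd^2 * 2/n_phase3 (``predictive=True``);
    ``predictive=False`` instead evaluates the posterior probability that the
    true effect exceeds the threshold.
    """
    if sd <= 0:
        raise ValueError("sd must be > 0")
    if n_interim < 2 or n_phase3 < 2:
        raise ValueError("per-arm sample sizes must be >= 2")
    var = sd**2 * 2.0 / n_interim
    if predictive:
        var += sd**2 * 2.0 / n_phase3
    prob = float(stats.norm.sf(threshold, loc=estimate, scale=np.sqrt(var)))
    if prob > GO_CUTOFF:
        decision = "go"
    elif prob < NOGO_CUTOFF:
        decision = "no-go"
    else:
        decision = "zone"
    return InterimDecision(
        estimate=estimate, n_interim=n_interim, sd=sd, threshold=threshold,
        n_phase3=n_phase3, probability=prob, decision=decision,
    )


def randomize_patients(
    strata: list[str] | np.ndarray,
    arms: list[str],
    ratio: list[int] | None = None,
    block_size: int | None = None,
    seed: int = 0,
) -> list[str]:
    """Stratified permuted-block randomization.

    ``strata`` gives each patient's stratum (e.g. country) in enrolment
    order; blocks are permuted independently within each stratum, so every
    complete block is exactly balanced at the allocation ratio.  The block
    size must be a multiple of the ratio total (default: one ratio-unit per
    block).  Deterministic for a given seed.
    """
    ratio = list(ratio) if ratio is not None else [1] * len(arms)
    if len(ratio) != len(arms) or any(r < 1 for r in ratio):
        raise ValueError("ratio must give a positive integer per arm")
    unit = sum(ratio)
    block_size = unit if block_size is None else int(block_size)
    if block_size % unit != 0:
        raise ValueError(
            f"block size {block_size} must be a multiple of the ratio total {unit}"
        )
    reps = block_size // unit
    template = [a for a, r in zip(arms, ratio) for _ in range(r * reps)]

    assignments: dict[int, str] = {}
    order: dict[str, list[int]] = {}
    for i, s in enumerate(strata):
        order.setdefault(str(s), []).append(i)
    for k, (s, idxs) in enumerate(sorted(order.items())):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7, k)))
        pos = 0
        while pos < len(idxs):
            block = list(template)
            rng.shuffle(block)
            for a in block:
                if pos >= len(idxs):
                    break
                assignments[idxs[pos]] = a
                pos += 1
    return [assignments[i] for i in range(len(strata))]
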