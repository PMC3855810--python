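"""Generic MCMC machinery.

Two samplers are provided, mirroring the two model-fitting strategies used
downstream: a *full scan* that updates every parameter sequentially per
iteration with per-parameter Gaussian random-walk proposals (a hybrid of
Metropolis–Hastings and Gibbs), and a *single-site* sampler that updates
exactly one parameter per iteration in cyclic order.  Proposal step sizes
are adapted multiplicatively during burn-in toward a target acceptance rate
of 0.25 and frozen afterwards, so the sampling phase is a valid fixed-kernel
chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

TARGET_ACCEPTANCE = 0.25
#: Iterations between step-size adaptations during burn-in.
ADAPT_WINDOW = 50
#: Gain of the multiplicative adaptation: step *= exp(gain * (rate - target)).
ADAPT_GAIN = 2.0


@dataclass
class ParameterSpec:
    """Name, support, initial value and proposal step of one scalar parameter."""

    name: str
    initial: float
    step: float = 1.0
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower bound must be below upper bound")
        if not (self.lower <= self.initial <= self.upper):
            raise ValueError(f"{self.name}: initial value outside support")
        if self.step < 0:
            raise ValueError(f"{self.name}: negative step size")


@dataclass
class Trace:
    """Posterior draws (iterations x parameters) of one chain."""

    names: list[str]
    draws: np.ndarray
    chain_id: int = 0
    burn_in: int = 0

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 2 or self.draws.shape[1] != len(self.names):
            raise ValueError("draws must be (iterations, n_parameters)")
        if self.draws.shape[0] == 0:
            raise ValueError("empty trace")
        if not np.isfinite(self.draws).all():
            raise ValueError("non-finite draws in trace")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=self.names)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# chain={self.chain_id} burn_in={self.burn_in}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def mh_scan(
    log_posterior: Callable[[np.ndarray], float],
    state: np.ndarray,
    specs: Sequence[ParameterSpec],
    rng: np.random.Generator,
    steps: np.ndarray | None = None,
    current_logp: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One full scan: update each parameter in sequence by Gaussian proposal.

    Proposals outside the declared support are rejected outright.  Returns
    the new state, per-parameter accept flags, and the log posterior at the
    new state.
    """
    state = np.array(state, dtype=float)
    if steps is None:
        steps = np.array([s.step for s in specs], dtype=float)
    if current_logp is None:
        current_logp = log_posterior(state)
    if np.isnan(current_logp):
        raise ValueError("log posterior is NaN at the current state")
    accepted = np.zeros(len(specs), dtype=bool)
    for i, spec in enumerate(specs):
        prop = state[i] + steps[i] * rng.standard_normal()
        if prop < spec.lower or prop > spec.upper:
            continue
        old = state[i]
        state[i] = prop
        prop_logp = log_posterior(state)
        if np.log(rng.uniform()) < prop_logp - current_logp:
            accepted[i] = True
            current_logp = prop_logp
        else:
            state[i] = old
    return state, accepted, current_logp


def single_site_scan(
    log_posterior: Callable[[np.ndarray], float],
    state: np.ndarray,
    specs: Sequence[ParameterSpec],
    rng: np.random.Generator,
    index: int,
    steps: np.ndarray | None = None,
    current_logp: float | None = None,
) -> tuple[np.ndarray, bool, float]:
    """Update exactly one parameter (``index`` in cyclic order)."""
    state = np.array(state, dtype=float)
    if steps is None:
        steps = np.array([s.step for s in specs], dtype=float)
    if current_logp is None:
        current_logp = log_posterior(state)
    if np.isnan(current_logp):
        raise ValueError("log posterior is NaN at the current state")
    i = index % len(specs)
    spec = specs[i]
    prop = state[i] + steps[i] * rng.standard_normal()
    if prop < spec.lower or prop > spec.upper:
        return state, False, current_logp
    old = state[i]
    state[i] = prop
    prop_logp = log_posterior(state)
    if np.log(rng.uniform()) < prop_logp - current_logp:
        return state, True, prop_logp
    state[i] = old
    return state, False, current_logp


def tune_steps(
    accept_window: np.ndarray,
    steps: np.ndarray,
    target: float = TARGET_ACCEPTANCE,
    gain: float = ADAPT_GAIN,
) -> np.ndarray:
    """Multiplicative step adaptation toward the target acceptance rate.

    ``accept_window`` holds per-parameter acceptance fractions over the last
    adaptation window; each step is multiplied by
    ``exp(gain * (rate - target))``, so a window acceptance above the target
    grows the step and one below shrinks it, with the correction
    proportional to the miss.  Intended for use during burn-in only; the
    caller freezes steps afterwards.
    """
    rate = np.asarray(accept_window, dtype=float)
    steps = np.asarray(steps, dtype=float).copy()
    return steps * np.exp(gain * (rate - target))


def run_adaptive_chain(
    log_posterior: Callable[[np.ndarray], float],
    specs: Sequence[ParameterSpec],
    rng: np.random.Generator,
    burn_in: int,
    samples: int,
    chain_id: int = 0,
    thin: int = 1,
) -> tuple[Trace, float]:
    """Full-scan adaptive MH chain.

    Steps are tuned every ``ADAPT_WINDOW`` scans during burn-in and frozen
    for the sampling phase.  Returns the post-burn-in trace and the mean
    realized acceptance rate over the sampling phase.
    """
    state = np.array([s.initial for s in specs], dtype=float)
    steps = np.array([s.step for s in specs], dtype=float)
    names = [s.name for s in specs]
    logp = log_posterior(state)
    if not np.isfinite(logp):
        raise ValueError("log posterior not finite at the initial state")

    acc_count = np.zeros(len(specs))
    for it in range(burn_in):
        state, acc, logp = mh_scan(log_posterior, state, specs, rng, steps, logp)
        acc_count += acc
        if (it + 1) % ADAPT_WINDOW == 0:
            steps = tune_steps(acc_count / ADAPT_WINDOW, steps)
            acc_count[:] = 0.0

    draws = np.empty((samples // thin, len(specs)))
    n_acc = 0
    kept = 0
    for it in range(samples):
        state, acc, logp = mh_scan(log_posterior, state, specs, rng, steps, logp)
        n_acc += int(acc.sum())
        if (it + 1) % thin == 0:
            draws[kept] = state
            kept += 1
    trace = Trace(names=names, draws=draws[:kept], chain_id=chain_id, burn_in=burn_in)
    acceptance = n_acc / (samples * len(specs))
    return trace, acceptance


def gelman_rubin(traces: Sequence[Trace]) -> pd.Series:
    """Potential scale reduction factor per parameter.

    R-hat = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B the between-chain variance of the chain means; values
    below 1.1 indicate convergence.  Requires at least two chains of equal
    length with burn-in already removed; reported values are floored at 1.
    """
    if len(traces) < 2:
        raise ValueError("Gelman-Rubin diagnostic needs at least two chains")
    names = traces[0].names
    n = traces[0].draws.shape[0]
    for t in traces[1:]:
        if t.names != names or t.draws.shape[0] != n:
            raise ValueError("chains must share parameters and length")
    stacked = np.stack([t.draws for t in traces])  # (m, n, p)
    means = stacked.mean(axis=1)  # (m, p)
    W = stacked.var(axis=1, ddof=1).mean(axis=0)  # (p,)
    B = n * means.var(axis=0, ddof=1)  # (p,)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_hat = (n - 1) / n * W + B / n
        rhat = np.sqrt(var_hat / W)
    rhat = np.where(W == 0, 1.0, rhat)
    return pd.Series(np.maximum(rhat, 1.0), index=names, name="rhat")


def summarize(traces: Trace | Sequence[Trace]) -> pd.DataFrame:
    """Posterior mean and 95% credible interval (2.5/97.5% quantiles).

    Quantiles use linear interpolation of order statistics.  Multiple chains
    are pooled.
    """
    if isinstance(traces, Trace):
        traces = [traces]
    draws = np.concatenate([t.draws for t in traces], axis=0)
    names = traces[0].names
    mean = draws.mean(axis=0)
    lo, hi = np.quantile(draws, [0.025, 0.975], axis=0)
    return pd.DataFrame(
        {"mean": mean, "ci_low": lo, "ci_high": hi}, index=pd.Index(names, name="parameter")
    )
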