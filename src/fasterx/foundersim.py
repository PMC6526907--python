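"""Recurrent founder-event simulations of X and autosomal diversity.

Because Ne_X < Ne_A, the X compartment tracks any change of the demographic
regime faster than the autosomes (the Pool-Nielsen effect). When recurrent
founder events begin, overall diversity relaxes toward a much lower dynamic
equilibrium over a timescale of order Ne generations, and during that whole
relaxation piX/piA sits below its constant-size value because X has moved
further toward the new equilibrium. Both compartments experience the same
crash schedule; only their effective sizes differ (defaults 15,000 vs 20,000,
chosen with mu = 1.2e-8 to match RAD-scale diversity). Simulation is a
backward (coalescent) sample of independent 100-bp loci at chosen time points
in the cycle.

Crashes can be parameterized as a fraction of the standing size (1% or 10%)
or as an absolute founder propagule size in chromosome copies (5 vs 50); both
appear in the literature describing the same scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent import SizeHistory, simulate_pi


@dataclass(frozen=True)
class DemographyScenario:
    """Recurrent-bottleneck scenario shared by the X and A compartments."""

    ne_a: float = 20_000.0
    ne_x: float = 15_000.0
    mu: float = 1.2e-8
    n_loci: int = 20_000
    locus_len: int = 100
    cycle_len: float = 50.0
    crash_frac: float = 0.01
    crash_duration: float = 1.0
    founder_chromosomes: float | None = None  # overrides crash_frac if set
    n_cycles: int = 20
    recovery: str = "instant"  # or "exponential"
    n_samples: int = 20
    seed: int = 0
    label: str = ""

    def __post_init__(self):
        if not 0.0 < self.crash_frac < 1.0:
            raise ValueError("crash_frac must lie in (0, 1)")
        if self.ne_x > self.ne_a:
            raise ValueError("ne_x must not exceed ne_a")
        if self.recovery not in ("instant", "exponential"):
            raise ValueError("recovery must be 'instant' or 'exponential'")

    def crash_size(self, ne: float) -> float:
        if self.founder_chromosomes is not None:
            base = max(self.founder_chromosomes / 2.0, 1.0)
            return base * ne / self.ne_a
        return max(self.crash_frac * ne, 1.0)


@dataclass
class SimResult:
    scenario: DemographyScenario
    sample_times: np.ndarray
    pi_a: np.ndarray
    pi_x: np.ndarray
    ratio: np.ndarray = field(init=False)

    def __post_init__(self):
        with np.errstate(divide="ignore", invalid="ignore"):
            self.ratio = np.where(self.pi_a > 0, self.pi_x / self.pi_a, np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": self.sample_times,
                "pi_a": self.pi_a,
                "pi_x": self.pi_x,
                "ratio": self.ratio,
            }
        )


def backward_history(
    scenario: DemographyScenario, ne: float, sample_time: float
) -> SizeHistory:
    """Piecewise-constant Ne looking backward from ``sample_time``.

    Forward timeline: full size from generation 0, crashes at c*cycle_len
    (c = 1..n_cycles) each lasting ``crash_duration`` generations, recovery
    instantaneous or as an 8-step exponential ramp over the rest of the
    cycle. Before generation 0 the population sits at full size.
    """
    crash = scenario.crash_size(ne)
    events: list[tuple[float, float]] = [(0.0, ne)]  # forward (time, size)
    c = 1
    while c * scenario.cycle_len < sample_time and c <= scenario.n_cycles:
        t0 = c * scenario.cycle_len
        events.append((t0, crash))
        t1 = t0 + scenario.crash_duration
        if scenario.recovery == "instant":
            events.append((t1, ne))
        else:
            ramp_end = min((c + 1) * scenario.cycle_len, sample_time)
            steps = 8
            dt = max((ramp_end - t1) / steps, 1e-9)
            for s in range(steps):
                size = crash * (ne / crash) ** ((s + 1) / steps)
                events.append((t1 + s * dt, size))
        c += 1
    # convert to backward epochs: the forward interval [t_i, t_{i+1}) at size
    # s_i becomes the backward interval [T - t_{i+1}, T - t_i) at size s_i
    events = [(t, s) for t, s in events if t < sample_time]
    rev = list(reversed(events))  # most recent event first
    times = [0.0]
    sizes = [rev[0][1]]
    for i in range(1, len(rev)):
        start_back = sample_time - rev[i - 1][0]
        if start_back > times[-1]:
            times.append(start_back)
            sizes.append(rev[i][1])
        else:  # zero-length forward interval: overwrite
            sizes[-1] = rev[i][1]
    return SizeHistory(np.array(times), np.array(sizes))


def simulate_compartment(
    ne_history: SizeHistory,
    mu: float,
    n_loci: int,
    locus_len: int,
    n_samples: int = 20,
    seed: int | None = None,
) -> np.ndarray:
    """Per-locus pi for one compartment under one backward size history."""
    rng = np.random.default_rng(seed)
    return simulate_pi(n_samples, ne_history, mu, locus_len, n_loci, rng)


def run_scenario(
    scenario: DemographyScenario, sample_times: np.ndarray | None = None
) -> SimResult:
    """Simulate both compartments on the same crash schedule.

    Default sampling times sit immediately before each crash (the maximally
    recovered phase of the cycle).
    """
    if sample_times is None:
        sample_times = np.arange(1, scenario.n_cycles + 1) * scenario.cycle_len
    rng = np.random.default_rng(scenario.seed)
    pi_a = np.empty(len(sample_times))
    pi_x = np.empty(len(sample_times))
    for i, t in enumerate(sample_times):
        hist_a = backward_history(scenario, scenario.ne_a, float(t))
        hist_x = backward_history(scenario, scenario.ne_x, float(t))
        pi_a[i] = simulate_pi(
            scenario.n_samples, hist_a, scenario.mu, scenario.locus_len,
            scenario.n_loci, rng,
        ).mean()
        pi_x[i] = simulate_pi(
            scenario.n_samples, hist_x, scenario.mu, scenario.locus_len,
            scenario.n_loci, rng,
        ).mean()
    return SimResult(scenario, np.asarray(sample_times, float), pi_a, pi_x)


def summarize_pn(
    results: dict[str, list[SimResult]], burn_in_cycles: int = 5
) -> pd.DataFrame:
    """Mean and normal-theory CI of the equilibrium piX/piA per scenario.

    Uses ratio values at sampling times after ``burn_in_cycles`` full cycles;
    replicates (seeds) of the same scenario are pooled.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 scenarios to compare")
    rows = []
    for label, runs in results.items():
        vals = []
        for r in runs:
            cutoff = burn_in_cycles * r.scenario.cycle_len
            vals.extend(r.ratio[r.sample_times > cutoff])
        vals = np.asarray(vals, float)
        vals = vals[np.isfinite(vals)]
        se = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
        rows.append(
            {
                "scenario": label,
                "mean_ratio": float(vals.mean()),
                "ci_low": float(vals.mean() - 1.96 * se),
                "ci_high": float(vals.mean() + 1.96 * se),
                "n_points": int(len(vals)),
            }
        )
    return pd.DataFrame(rows)
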