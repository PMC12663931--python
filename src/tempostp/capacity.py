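"""Storage-capacity estimation from convergence-time divergence.

The critical load alpha_c of a neuron/synapse model is estimated as the
pole of the expected median convergence time

    Gamma(alpha) = Gamma_0 / (1 - alpha / alpha_c)^gamma,

fitted to a staged sweep of learning loads: loads increase multiplicatively
until the median convergence time (over many independent task
realizations) reaches a cutoff L_max, the cutoff is raised over successive
stages, and the curve is fitted to the highest ``n_data`` consecutive
loads whose medians stayed below the final cutoff.  Because training
without a convergence proof can only bound solvability, the estimates are
lower bounds on the true capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .learning import (
    LearnConfig,
    default_neuron_config,
    init_params,
    train_until_convergence,
)
from .patterns import gen_latency_batch, round_half_up

__all__ = [
    "TaskSpec",
    "SweepConfig",
    "ConvergenceRecord",
    "CapacityFit",
    "measure_convergence_time",
    "staged_load_sweep",
    "fit_capacity_curve",
    "stability_analysis",
    "capacity_scaling_exponent",
]


@dataclass(frozen=True)
class TaskSpec:
    """Storage-capacity task geometry."""

    n_afferents: int
    n_spikes: int
    duration: float = 0.5
    model: str = "static"
    tau_coeff: float = 5.67

    @property
    def pattern_afferents(self) -> int:
        """Afferent count of the generated patterns.

        Ordinal-type models operate on the rank-expanded representation but
        patterns are generated in the native N x nspikes geometry.
        """
        return self.n_afferents


@dataclass
class SweepConfig:
    """Staged-sweep protocol parameters.

    Full-scale defaults follow the published protocol (three stages with
    cutoffs 1e4/1e5/1e6, 1%/1%/0.5% load steps, 1,001 realizations, 10
    repeated median measurements); reduced values are used for desk runs.
    """

    stage_cutoffs: tuple[int, ...] = (10_000, 100_000, 1_000_000)
    stage_steps: tuple[float, ...] = (0.01, 0.01, 0.005)
    n_realizations: int = 1001
    n_repeats: int = 10
    start_load: float = 1.0
    max_loads: int = 2000
    seed: int = 0
    learn: LearnConfig | None = None


@dataclass
class ConvergenceRecord:
    """Median convergence time at one learning load."""

    load: float
    median_ct: float  # mean of the repeat medians
    repeat_medians: list[float]
    n_realizations: int
    cutoff: int

    @property
    def censored(self) -> bool:
        """True when any repeat's median hit the learning-time cutoff."""
        return any(m >= self.cutoff for m in self.repeat_medians)


@dataclass
class CapacityFit:
    gamma0: float
    alpha_c: float
    gamma_exp: float
    epsilon: float
    window_loads: np.ndarray
    window_cts: np.ndarray
    degenerate: bool = False

    def predict(self, loads: np.ndarray) -> np.ndarray:
        return _gamma_curve(np.asarray(loads, float), self.gamma0,
                            self.alpha_c, self.gamma_exp)


def measure_convergence_time(task: TaskSpec, load: float, cutoff: int,
                             n_realizations: int, seed: int,
                             learn: LearnConfig | None = None) -> float:
    """Median convergence time over independent task realizations.

    Each realization draws a fresh batch and fresh initial parameters; the
    convergence time of one realization is the number of error epochs
    before the first clean pass, censored at ``cutoff``.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.generate_state(2 * n_realizations) % (2**31)
    cts = np.empty(n_realizations)
    n_aff, n_spk = task.n_afferents, task.n_spikes
    neuron = default_neuron_config(n_aff, n_spk, task.duration,
                                   tau_coeff=task.tau_coeff)
    for r in range(n_realizations):
        batch = gen_latency_batch(n_aff, n_spk, task.duration, load,
                                  seed=int(children[2 * r]))
        params = init_params(task.model, n_aff, n_spk,
                             seed=int(children[2 * r + 1]))
        base = learn if learn is not None else LearnConfig()
        cfg = replace(base, max_epochs=cutoff, seed=int(children[2 * r + 1]))
        res = train_until_convergence(batch, task.model, params, cfg,
                                      neuron_config=neuron)
        cts[r] = res.convergence_epochs if res.converged else cutoff
    return float(np.median(cts))


def staged_load_sweep(task: TaskSpec, sweep: SweepConfig) -> list[ConvergenceRecord]:
    """Sweep learning loads upward until the final-stage cutoff is reached.

    Loads grow multiplicatively by the stage's step.  When a load's median
    convergence time reaches the current stage cutoff, the sweep advances
    to the next stage and re-measures the same load under the higher
    cutoff; the sweep ends when the final cutoff is reached.  Each record
    averages ``n_repeats`` independent median measurements.
    """
    if len(sweep.stage_cutoffs) != len(sweep.stage_steps):
        raise ValueError("need one step size per stage")
    records: list[ConvergenceRecord] = []
    stage = 0
    load = sweep.start_load
    rng_seq = np.random.SeedSequence(sweep.seed)
    seeds = iter(rng_seq.generate_state(sweep.max_loads * sweep.n_repeats * 4)
                 % (2**31))
    for _ in range(sweep.max_loads):
        cutoff = int(sweep.stage_cutoffs[stage])
        medians = [
            measure_convergence_time(task, load, cutoff,
                                     sweep.n_realizations, int(next(seeds)),
                                     learn=sweep.learn)
            for _ in range(sweep.n_repeats)
        ]
        rec = ConvergenceRecord(load, float(np.mean(medians)), medians,
                                sweep.n_realizations, cutoff)
        records.append(rec)
        if rec.censored:
            if stage + 1 < len(sweep.stage_cutoffs):
                stage += 1  # re-measure same load under the raised cutoff
                continue
            break
        load = load * (1.0 + sweep.stage_steps[stage])
    return records


def _gamma_curve(alpha, gamma0, alpha_c, gamma_exp):
    return gamma0 / np.power(1.0 - alpha / alpha_c, gamma_exp)


def select_fit_window(records: list[ConvergenceRecord], n_data: int,
                      shift: int = 0) -> list[ConvergenceRecord]:
    """The ``n_data`` highest consecutive uncensored loads, shifted down by ``shift``."""
    clean = [r for r in records if not r.censored]
    if len(clean) < n_data + shift:
        raise ValueError(
            f"need at least {n_data + shift} uncensored records, have {len(clean)}"
        )
    hi = len(clean) - shift
    return clean[hi - n_data: hi]


def fit_capacity_curve(records: list[ConvergenceRecord], n_data: int = 20,
                       shift: int = 0) -> CapacityFit:
    """Nonlinear least-squares fit of the divergence curve on the top window.

    Initial guesses: Gamma_0 = smallest convergence time in the window,
    alpha_c = 1.05x the largest fitted load, with a multistart over the
    exponent gamma in {1, 2, 3}; the fit with the lowest mean absolute
    relative error epsilon is kept.  A flat window (no divergence) is
    flagged degenerate since the pole is then unidentifiable.
    """
    window = select_fit_window(records, n_data, shift)
    x = np.array([r.load for r in window])
    y = np.array([r.median_ct for r in window])
    if np.ptp(y) <= 1e-12 * max(1.0, abs(y.mean())):
        return CapacityFit(float(y.mean()), np.inf, 0.0, 0.0, x, y,
                           degenerate=True)
    best = None
    alpha0 = 1.05 * x.max()
    for gamma_guess in (1.0, 2.0, 3.0):
        try:
            popt, _ = curve_fit(
                _gamma_curve, x, y,
                p0=[max(y.min(), 1e-6), alpha0, gamma_guess],
                bounds=([1e-12, x.max() * (1 + 1e-9), 1e-6],
                        [np.inf, np.inf, 20.0]),
                maxfev=20_000,
            )
        except RuntimeError:
            continue
        pred = _gamma_curve(x, *popt)
        eps = float(np.mean(np.abs(y - pred) / pred))
        if best is None or eps < best[1]:
            best = (popt, eps)
    if best is None:
        raise RuntimeError("capacity-curve fit failed from every start")
    (g0, ac, ge), eps = best
    degenerate = ge < 1e-3
    return CapacityFit(float(g0), float(ac), float(ge), eps, x, y,
                       degenerate=degenerate)


@dataclass
class StabilityResult:
    window_fits: list[CapacityFit]
    alpha_c_values: np.ndarray
    relative_sd: float


def stability_analysis(records: list[ConvergenceRecord], n_data: int = 20,
                       n_windows: int = 10) -> StabilityResult:
    """Re-fit over windows successively shifted toward lower loads.

    The spread of the per-window pole estimates (and their approach, from
    below, toward the top-window value) quantifies the reliability of the
    capacity estimator.
    """
    fits = []
    for shift in range(n_windows):
        fits.append(fit_capacity_curve(records, n_data, shift))
    ac = np.array([f.alpha_c for f in fits])
    finite = ac[np.isfinite(ac)]
    rel_sd = float(np.std(finite) / np.mean(finite)) if finite.size else np.nan
    return StabilityResult(fits, ac, rel_sd)


def robust_alpha_c(records: list[ConvergenceRecord], n_data: int = 20,
                   n_windows: int = 5) -> float:
    """Median pole estimate over shifted fit windows.

    Single-window pole fits can be erratic when the top records sit close
    to the censoring cutoff (their medians carry the largest sampling
    noise); the median over a few window shifts discards such outliers.
    Windows whose fit is degenerate or fails are skipped.
    """
    fits = []
    for shift in range(n_windows):
        try:
            f = fit_capacity_curve(records, n_data=n_data, shift=shift)
        except (ValueError, RuntimeError):
            continue
        if not f.degenerate and np.isfinite(f.alpha_c):
            fits.append(f.alpha_c)
    if not fits:
        raise RuntimeError("no usable fit window for the pole estimate")
    return float(np.median(fits))


def capacity_scaling_exponent(nspikes_values: Sequence[int],
                              alpha_c_values: Sequence[float]) -> float:
    """Log-log slope of normalized capacity alpha_c/nspikes versus nspikes.

    Fits alpha_c/nspikes = alpha_1 * nspikes^lambda; returns lambda.
    Static synapses show lambda near -1 (capacity does not grow with
    spikes per afferent); ordinal synapses show lambda near 0.
    """
    ns = np.asarray(nspikes_values, float)
    ac = np.asarray(alpha_c_values, float)
    if ns.size < 2:
        raise ValueError("need at least two spike counts")
    slope, _ = np.polyfit(np.log(ns), np.log(ac / ns), 1)
    return float(slope)
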