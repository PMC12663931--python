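"""Tempotron error-correction learning for all synapse models.

On each error trial the single-pattern cost E = -V(tmax) (missed target)
or E = +V(tmax) (false alarm on a null pattern) is reduced by moving every
synaptic parameter along the voltage gradient at tmax, the time of the
maximal unreset membrane potential:

    delta = +/- eta * dV(tmax)/dparam + mu * delta_previous.

The momentum term follows model-specific invocation rules: for static and
ordinal synapses it is applied only where the gradient contribution is
nonzero, whereas for Tsodyks-Markram synapses it is applied to all four
parameters of every afferent that fired before tmax, enforcing concurrent
updates of the parameters that jointly shape the efficacy dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _fast
from .neuron import KernelParams, NeuronConfig, task_tau
from .patterns import PatternBatch, SpikePattern
from .synapses import (
    OrdinalParams,
    SignConstrainedParams,
    StaticParams,
    TMParams,
)

__all__ = [
    "LearnConfig",
    "UpdateState",
    "TrainResult",
    "init_params",
    "voltage_gradient_static",
    "voltage_gradient_sign_constrained",
    "voltage_gradient_tm",
    "apply_update",
    "train_until_convergence",
    "batch_to_arrays",
    "default_neuron_config",
]

MODELS = ("static", "ordinal", "sign_constrained", "tm")

# package-default learning hyperparameters; the voltage-scale learning rate
# eta_omega = ETA_OMEGA_COEFF * theta / N keeps single-update voltage changes
# a fixed small fraction of threshold independent of network size
ETA_OMEGA_COEFF = 3e-3
ETA_SLOW_FRACTION = 0.1  # eta_U = eta_tau = eta_omega / 10
MU_DEFAULT = 0.99


@dataclass
class LearnConfig:
    """Learning rates, momentum factors, epoch cutoff and seed.

    Rates left as ``None`` resolve at training time to the package
    defaults: ``eta_omega = 3e-3 * theta / N``, ``eta_U = eta_tau =
    eta_omega / 10``, ``eta_z = 3e-3 * theta`` (z magnitudes are order one
    rather than order 1/N), momentum 0.99 everywhere.
    """

    eta_omega: float | None = None
    eta_u: float | None = None
    eta_tau: float | None = None
    eta_z: float | None = None
    mu: float = MU_DEFAULT
    max_epochs: int = 10_000
    seed: int = 0
    train: tuple[str, ...] = ("omega", "U", "tau_rec", "tau_fac", "z")
    eta_slow_fraction: float = ETA_SLOW_FRACTION

    def resolved_rates(self, n_afferents: int, theta: float = 1.0) -> dict[str, float]:
        eta_w = self.eta_omega if self.eta_omega is not None \
            else ETA_OMEGA_COEFF * theta / n_afferents
        eta_u = self.eta_u if self.eta_u is not None else eta_w * self.eta_slow_fraction
        eta_tau = self.eta_tau if self.eta_tau is not None else eta_w * self.eta_slow_fraction
        eta_z = self.eta_z if self.eta_z is not None else ETA_OMEGA_COEFF * theta
        return {"omega": eta_w, "U": eta_u, "tau_rec": eta_tau,
                "tau_fac": eta_tau, "z": eta_z}


@dataclass
class UpdateState:
    """Previous applied update per parameter (the momentum memory)."""

    prev: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def zeros_like(cls, params) -> "UpdateState":
        if isinstance(params, StaticParams):
            return cls({"omega": np.zeros_like(params.omega)})
        if isinstance(params, OrdinalParams):
            return cls({"omega": np.zeros_like(params.omega)})
        if isinstance(params, SignConstrainedParams):
            return cls({"omega": np.zeros_like(params.omega),
                        "z": np.zeros_like(params.z)})
        if isinstance(params, TMParams):
            return cls({"omega": np.zeros_like(params.omega),
                        "U": np.zeros_like(params.U),
                        "tau_rec": np.zeros_like(params.tau_rec),
                        "tau_fac": np.zeros_like(params.tau_fac)})
        raise TypeError(f"unknown parameter type {type(params)}")


@dataclass
class TrainResult:
    params: object
    convergence_epochs: int
    error_history: np.ndarray
    converged: bool
    state: UpdateState | None = None


def default_neuron_config(n_afferents: int, n_spikes: int,
                          duration: float, theta: float = 1.0,
                          tau_ratio: float = 2.0,
                          tau_coeff: float = 5.67) -> NeuronConfig:
    """Neuron with integration scale matched to the task's spike density."""
    tau = task_tau(duration, n_afferents, n_spikes, tau_coeff)
    return NeuronConfig(KernelParams.from_tau(tau, tau_ratio), threshold=theta)


def init_params(model: str, n_afferents: int, n_spikes: int,
                seed: int | np.random.Generator | None = None,
                theta: float = 1.0):
    """Random initial synaptic parameters.

    Weight-like scales start at N(0, (theta/(N*nspikes))^2) so the initial
    voltage is a small fraction of threshold; TM dynamics start at broad,
    biologically plausible ranges (U uniform on (0.1, 0.9), time constants
    log-uniform on 10 ms..1 s); z magnitudes start uniform positive.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = theta / (n_afferents * n_spikes)
    if model == "static":
        return StaticParams(rng.normal(0.0, sd, n_afferents))
    if model == "ordinal":
        return OrdinalParams(rng.normal(0.0, sd, (n_afferents, n_spikes)))
    if model == "sign_constrained":
        return SignConstrainedParams(
            rng.normal(0.0, sd * n_spikes, n_afferents),
            rng.uniform(0.5, 1.5, (n_afferents, n_spikes)),
        )
    if model == "tm":
        return TMParams(
            rng.normal(0.0, sd * n_spikes, n_afferents),
            rng.uniform(0.1, 0.9, n_afferents),
            np.exp(rng.uniform(np.log(0.01), np.log(1.0), n_afferents)),
            np.exp(rng.uniform(np.log(0.01), np.log(1.0), n_afferents)),
        )
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# voltage gradients at tmax
# ---------------------------------------------------------------------------

def voltage_gradient_static(pattern: SpikePattern, params, t_max: float,
                            kernel: KernelParams) -> np.ndarray:
    """dV(tmax)/d(omega): kernel-weighted sums over spikes before tmax.

    For ``OrdinalParams`` the sums are taken per (afferent, rank) and the
    result has the parameter table's (N, nspikes) shape.
    """
    ts, aff, rank = pattern.merged()
    if isinstance(params, OrdinalParams):
        R = params.n_ranks
        g = np.zeros(params.n_afferents * R)
        _fast.grad_static(ts, aff * R + rank, t_max,
                          kernel.tau_m, kernel.tau_s, kernel.v0, g)
        return g.reshape(params.n_afferents, R)
    g = np.zeros(params.n_afferents)
    _fast.grad_static(ts, aff, t_max, kernel.tau_m, kernel.tau_s, kernel.v0, g)
    return g


def voltage_gradient_sign_constrained(
    pattern: SpikePattern, params: SignConstrainedParams, t_max: float,
    kernel: KernelParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (d V/d omega, dV/dz, active mask) for the sign-constrained synapse."""
    ts, aff, rank = pattern.merged()
    n = params.n_afferents
    g_w = np.zeros(n)
    g_z = np.zeros_like(params.z)
    active = np.zeros(n, dtype=bool)
    _fast.grad_signcon(ts, aff, rank, t_max, kernel.tau_m, kernel.tau_s,
                       kernel.v0, params.omega, params.z, params.z1,
                       g_w, g_z, active)
    return g_w, g_z, active


def voltage_gradient_tm(
    pattern: SpikePattern, params: TMParams, t_max: float, kernel: KernelParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Four TM gradient components plus the active-afferent mask."""
    ts, aff, _ = pattern.merged()
    n = params.n_afferents
    g_w = np.zeros(n)
    g_U = np.zeros(n)
    g_r = np.zeros(n)
    g_f = np.zeros(n)
    active = np.zeros(n, dtype=bool)
    _fast.grad_tm(ts, aff, n, t_max, kernel.tau_m, kernel.tau_s, kernel.v0,
                  params.omega, params.U, params.tau_rec, params.tau_fac,
                  g_w, g_U, g_r, g_f, active)
    return g_w, g_U, g_r, g_f, active


# ---------------------------------------------------------------------------
# parameter updates
# ---------------------------------------------------------------------------

def apply_update(params, gradient, label_error_sign: int, config: LearnConfig,
                 state: UpdateState, active_mask: np.ndarray | None = None):
    """Apply one gradient + momentum step in place; returns ``params``.

    ``label_error_sign`` is +1 after a missed target and -1 after a false
    alarm.  ``gradient`` matches :func:`voltage_gradient_*` output for the
    parameter type.  Static/ordinal momentum fires only on nonzero gradient
    entries; TM momentum fires on every active afferent for all four
    parameters (``active_mask`` required).
    """
    sign = float(label_error_sign)
    rates = config.resolved_rates(params.n_afferents)
    mu = config.mu
    if isinstance(params, (StaticParams, OrdinalParams)):
        g = np.asarray(gradient)
        mask = g != 0.0
        d = sign * rates["omega"] * g + mu * state.prev["omega"]
        params.omega[mask] += d[mask]
        state.prev["omega"][mask] = d[mask]
        return params
    if isinstance(params, SignConstrainedParams):
        g_w, g_z, _active = gradient
        mask_w = g_w != 0.0
        d_w = sign * rates["omega"] * g_w + mu * state.prev["omega"]
        params.omega[mask_w] += d_w[mask_w]
        state.prev["omega"][mask_w] = d_w[mask_w]
        mask_z = g_z != 0.0
        d_z = sign * rates["z"] * g_z + mu * state.prev["z"]
        old_z = params.z.copy()
        params.z[mask_z] += d_z[mask_z]
        state.prev["z"][mask_z] = d_z[mask_z]
        np.clip(params.z, 0.0, None, out=params.z)
        dead = params.z.sum(axis=1) <= 0
        if dead.any():  # degenerate normalization: revert those afferents
            params.z[dead] = old_z[dead]
        return params
    if isinstance(params, TMParams):
        if active_mask is None:
            raise ValueError("TM updates require the active-afferent mask")
        g_w, g_U, g_r, g_f = gradient
        a = active_mask
        for name, g, arr in (("omega", g_w, params.omega),
                             ("U", g_U, params.U),
                             ("tau_rec", g_r, params.tau_rec),
                             ("tau_fac", g_f, params.tau_fac)):
            if name not in config.train:
                continue
            d = sign * rates[name] * g + mu * state.prev[name]
            arr[a] += d[a]
            state.prev[name][a] = d[a]
        params.project()
        return params
    raise TypeError(f"unknown parameter type {type(params)}")


# ---------------------------------------------------------------------------
# batch training
# ---------------------------------------------------------------------------

def batch_to_arrays(batch: PatternBatch) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Flatten a uniform-size batch into (times, afferents, ranks, labels) arrays."""
    sizes = {p.n_total_spikes for p in batch.patterns}
    if len(sizes) != 1:
        raise ValueError("fast training requires equal spike counts across patterns")
    S = sizes.pop()
    p = len(batch)
    times = np.empty((p, S))
    affs = np.empty((p, S), dtype=np.int64)
    ranks = np.empty((p, S), dtype=np.int64)
    for m, pat in enumerate(batch.patterns):
        ts, aff, rank = pat.merged()
        times[m] = ts
        affs[m] = aff
        ranks[m] = rank
    return times, affs, ranks, np.asarray(batch.labels, dtype=np.int64)


def train_until_convergence(
    batch: PatternBatch,
    model: str,
    params,
    config: LearnConfig,
    neuron_config: NeuronConfig | None = None,
    state: UpdateState | None = None,
) -> TrainResult:
    """Online tempotron training until a full error-free pass or the cutoff.

    Patterns are presented in a fresh random order every epoch; every
    misclassified pattern triggers an immediate update.  The convergence
    time is the number of epochs that contained at least one error before
    the first clean pass.  ``params`` is not modified; the trained copy is
    returned.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    times, affs, ranks, labels = batch_to_arrays(batch)
    pat0 = batch.patterns[0]
    n_aff = pat0.n_afferents
    n_spk = pat0.n_spikes_per_afferent or times.shape[1] // n_aff
    if neuron_config is None:
        neuron_config = default_neuron_config(n_aff, n_spk, pat0.duration)
    kernel = neuron_config.kernel
    theta = neuron_config.threshold
    t_end = pat0.duration + 5.0 * kernel.tau_m
    rates = config.resolved_rates(n_aff, theta)
    l_max = config.max_epochs
    err_hist = np.zeros(l_max, dtype=np.int64)
    params = params.copy()
    if state is None:
        state = UpdateState.zeros_like(params)

    if model in ("static", "ordinal"):
        if model == "ordinal":
            R = params.n_ranks
            widx = affs * R + ranks
            omega = params.omega.reshape(-1)
        else:
            widx = affs
            omega = params.omega
        prev = state.prev["omega"].reshape(-1)
        ct = _fast.train_static_nb(times, widx, labels, omega, prev,
                                   rates["omega"], config.mu, l_max,
                                   config.seed, kernel.tau_m, kernel.tau_s,
                                   kernel.v0, theta, t_end, err_hist)
    elif model == "sign_constrained":
        ct = _fast.train_signcon_nb(times, affs, ranks, labels,
                                    params.omega, params.z,
                                    state.prev["omega"], state.prev["z"],
                                    rates["omega"], rates["z"],
                                    config.mu, config.mu, l_max, config.seed,
                                    kernel.tau_m, kernel.tau_s, kernel.v0,
                                    theta, t_end, err_hist)
    else:  # tm
        tr = config.train
        ct = _fast.train_tm_nb(times, affs, labels,
                               params.omega, params.U,
                               params.tau_rec, params.tau_fac,
                               state.prev["omega"], state.prev["U"],
                               state.prev["tau_rec"], state.prev["tau_fac"],
                               rates["omega"], rates["U"],
                               rates["tau_rec"], rates["tau_fac"],
                               config.mu, config.mu, config.mu, config.mu,
                               "omega" in tr, "U" in tr,
                               "tau_rec" in tr, "tau_fac" in tr,
                               l_max, config.seed, kernel.tau_m, kernel.tau_s,
                               kernel.v0, theta, t_end, err_hist)
    converged = ct < l_max
    n_epochs = ct + 1 if converged else l_max
    return TrainResult(params, int(ct), err_hist[:n_epochs].copy(),
                       converged, state)


def classify_batch(batch: PatternBatch, model: str, params,
                   neuron_config: NeuronConfig) -> np.ndarray:
    """Binary fired/silent prediction for every pattern in a batch."""
    from .synapses import instantaneous_efficacies
    from .neuron import simulate_response

    preds = np.zeros(len(batch), dtype=np.int8)
    for m, pat in enumerate(batch.patterns):
        eff = instantaneous_efficacies(pat, model, params)
        resp = simulate_response(pat, eff, neuron_config, with_reset=False)
        preds[m] = 1 if resp.v_max >= neuron_config.threshold else 0
    return preds
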