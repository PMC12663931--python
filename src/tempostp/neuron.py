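"""Current-based leaky integrate-and-fire neuron with unit PSP kernel.

The membrane potential is a weighted sum of causal double-exponential
postsynaptic potentials,

    V(t) = sum_ij W_ij * K(t - t_ij) + V_rest,
    K(dt) = V0 * (exp(-dt / tau_m) - exp(-dt / tau_s)),   dt >= 0,

with V0 chosen so the kernel peaks at 1.  An output spike is elicited
when V crosses the threshold (theta = 1); the reset is "smooth": all
input spikes arriving after the output spike are shunted (contribute
nothing), which relaxes the voltage back to rest along the tail of the
already-integrated PSPs.

The membrane/synaptic time-constant ratio is fixed at tau_m = 2 tau_s;
the characteristic integration scale tau = sqrt(tau_m * tau_s) is matched
to the input spike density as tau = 5.67 * T / (N * nspikes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import _fast
from .patterns import SpikePattern

__all__ = [
    "KernelParams",
    "NeuronConfig",
    "NeuronResponse",
    "task_tau",
    "psp_kernel",
    "simulate_response",
]

TAU_RATIO_DEFAULT = 2.0
TAU_SCALE_COEFF = 5.67
WINDOW_MARGIN_TAU_M = 5.0  # simulate over [0, T + 5 tau_m]


def task_tau(duration: float, n_afferents: int, n_spikes: int,
             coeff: float = TAU_SCALE_COEFF) -> float:
    """Integration scale matched to input spike density: tau = coeff*T/(N*nspikes)."""
    return coeff * duration / (n_afferents * n_spikes)


@dataclass(frozen=True)
class KernelParams:
    """Double-exponential PSP kernel time constants and normalization."""

    tau_m: float
    tau_s: float

    def __post_init__(self) -> None:
        if not self.tau_m > self.tau_s > 0:
            raise ValueError("require tau_m > tau_s > 0")

    @classmethod
    def from_tau(cls, tau: float, ratio: float = TAU_RATIO_DEFAULT) -> "KernelParams":
        """Build from the characteristic scale tau = sqrt(tau_m*tau_s) and ratio tau_m/tau_s."""
        if tau <= 0 or ratio <= 1:
            raise ValueError("tau must be positive and ratio > 1")
        r = np.sqrt(ratio)
        return cls(tau_m=tau * r, tau_s=tau / r)

    @property
    def tau(self) -> float:
        return float(np.sqrt(self.tau_m * self.tau_s))

    @property
    def peak_delay(self) -> float:
        """Time to kernel peak: (tau_m tau_s / (tau_m - tau_s)) ln(tau_m/tau_s)."""
        tm, ts = self.tau_m, self.tau_s
        return tm * ts / (tm - ts) * np.log(tm / ts)

    @property
    def v0(self) -> float:
        """Normalization putting the kernel peak at exactly 1."""
        d = self.peak_delay
        return 1.0 / (np.exp(-d / self.tau_m) - np.exp(-d / self.tau_s))


@dataclass(frozen=True)
class NeuronConfig:
    kernel: KernelParams
    threshold: float = 1.0
    v_rest: float = 0.0
    v_reset: float = 0.0

    def __post_init__(self) -> None:
        if not self.threshold > self.v_rest:
            raise ValueError("threshold must exceed resting potential")


@dataclass
class NeuronResponse:
    """Outcome of one pattern presentation.

    ``t_max``/``v_max`` locate the maximum of the *unreset* voltage (the
    anchor point of all tempotron gradients); ``output_spikes`` are the
    threshold crossings of the voltage with shunt reset active.  The flat
    zero-voltage segment before the first input spike is excluded from the
    maximization, so on trials where the voltage never rises above rest
    ``v_max`` can be negative and ``t_max`` still has input spikes before
    it (otherwise error-trial gradients would vanish identically).
    """

    t_max: float
    v_max: float
    output_spikes: list[float] = field(default_factory=list)
    trace: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def fired(self) -> bool:
        return len(self.output_spikes) > 0


def psp_kernel(dt, kernel: KernelParams):
    """Unit-amplitude causal PSP kernel K(dt); accepts scalars or arrays."""
    dt = np.asarray(dt, dtype=float)
    out = np.where(
        dt > 0,
        kernel.v0 * (np.exp(-np.clip(dt, 0, None) / kernel.tau_m)
                     - np.exp(-np.clip(dt, 0, None) / kernel.tau_s)),
        0.0,
    )
    return out if out.ndim else float(out)


def _voltage_fn(ts: np.ndarray, ws: np.ndarray, kernel: KernelParams):
    """Closure evaluating the unreset voltage at arbitrary times."""

    def V(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        dt = t[:, None] - ts[None, :]
        k = np.where(
            dt > 0,
            kernel.v0 * (np.exp(-np.clip(dt, 0, None) / kernel.tau_m)
                         - np.exp(-np.clip(dt, 0, None) / kernel.tau_s)),
            0.0,
        )
        out = k @ ws
        return out if out.size > 1 else float(out[0])

    return V


def _find_output_spikes(
    ts: np.ndarray, ws: np.ndarray, config: NeuronConfig, t_end: float
) -> list[float]:
    """Threshold crossings under shunt reset.

    After each output spike every later-arriving input spike is removed and
    the search continues on the remaining (already integrated) PSPs.
    """
    kernel = config.kernel
    theta = config.threshold
    spikes: list[float] = []
    ts_cur, ws_cur = ts, ws
    t_from = 0.0
    while True:
        vmax, tmax = _fast.vmax_tmax(ts_cur, ws_cur, kernel.tau_m,
                                     kernel.tau_s, kernel.v0, t_end)
        if vmax < theta:
            break
        # bracket the first upward crossing in [t_from, tmax]
        V = _voltage_fn(ts_cur, ws_cur, kernel)
        grid_pts = np.unique(np.concatenate([
            ts_cur[(ts_cur > t_from) & (ts_cur < tmax)], [t_from, tmax]
        ]))
        t_cross = None
        for a, b in zip(grid_pts[:-1], grid_pts[1:]):
            # refine on a fine grid inside the interval to find the first crossing
            tt = np.linspace(a, b, 64)
            vv = np.atleast_1d(V(tt))
            above = vv >= theta
            if above.any():
                j = int(np.argmax(above))
                if j == 0:
                    t_cross = tt[0]
                else:
                    t_cross = brentq(lambda t: V(t) - theta, tt[j - 1], tt[j],
                                     xtol=1e-12)
                break
        if t_cross is None:  # numerical corner: maximum grazes threshold
            break
        spikes.append(float(t_cross))
        keep = ts_cur <= t_cross
        ts_cur, ws_cur = ts_cur[keep], ws_cur[keep]
        t_from = t_cross
        if len(spikes) > 100:  # safety against pathological parameter sets
            break
    return spikes


def simulate_response(
    pattern: SpikePattern,
    efficacies: list[np.ndarray] | np.ndarray,
    config: NeuronConfig,
    with_reset: bool = True,
    record_trace: bool = False,
    trace_dt: float | None = None,
) -> NeuronResponse:
    """Integrate one pattern with per-spike instantaneous efficacies.

    ``efficacies`` is aligned with the pattern: a list of arrays (one per
    afferent, one value per spike) or a flat array aligned with the
    time-sorted merged view.  ``t_max`` is always located on the unreset
    voltage, which defines the tempotron gradient point even on trials
    where the neuron fired.
    """
    ts, aff, rank = pattern.merged()
    if isinstance(efficacies, np.ndarray) and efficacies.ndim == 1 and \
            efficacies.size == ts.size and not isinstance(efficacies, list):
        ws = np.asarray(efficacies, dtype=float)
    else:
        per_aff = [np.asarray(e, dtype=float) for e in efficacies]
        if len(per_aff) != pattern.n_afferents or any(
            per_aff[i].size != pattern.times[i].size for i in range(len(per_aff))
        ):
            raise ValueError("efficacy table does not align with the pattern")
        ws = np.array([per_aff[a][r] for a, r in zip(aff, rank)], dtype=float)

    kernel = config.kernel
    t_end = pattern.duration + WINDOW_MARGIN_TAU_M * kernel.tau_m
    v_max, t_max = _fast.vmax_tmax(ts, ws, kernel.tau_m, kernel.tau_s,
                                   kernel.v0, t_end)
    v_max += config.v_rest

    out_spikes: list[float] = []
    if with_reset and v_max >= config.threshold:
        out_spikes = _find_output_spikes(ts, ws, config, t_end)

    trace = None
    if record_trace:
        dt = trace_dt if trace_dt is not None else kernel.tau_s / 20.0
        tt = np.arange(0.0, t_end, dt)
        if with_reset and out_spikes:
            vv = np.zeros_like(tt)
            # rebuild trace respecting the shunt: each input spike contributes
            # only if it precedes the first output spike after it
            for t_in, w in zip(ts, ws):
                shunted = any(s < t_in for s in out_spikes)
                if not shunted:
                    vv += w * psp_kernel(tt - t_in, kernel)
        else:
            vv = np.atleast_1d(_voltage_fn(ts, ws, kernel)(tt))
        trace = (tt, vv + config.v_rest)

    return NeuronResponse(t_max=float(t_max), v_max=float(v_max),
                          output_spikes=out_spikes, trace=trace)
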