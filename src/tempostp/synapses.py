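"""Instantaneous synaptic efficacy models.

Four models of how the efficacy seen by the j-th spike of afferent i
depends on the afferent's activity history:

- static:            W_ij = omega_i                       (no history)
- ordinal:           W_ij = omega_{i,j}                   (rank order only)
- sign-constrained:  W_ij = omega_i * z_{ij} / ||z_i||_1  (one sign per afferent)
- Tsodyks-Markram:   W_ij = omega_i * u_ij * x_ij         (facilitation/depression)

The Tsodyks-Markram (TM) state recursions start both factors at the unit
baseline on the first spike of a pattern,

    u_i1 = 1,  x_i1 = 1,
    u_ij = u_{i,j-1} (1 - U_i) exp(-dt/tau_fac) + 1,
    x_ij = x_{i,j-1} (1 - U_i u_{i,j-1}) exp(-dt/tau_rec) + 1 - exp(-dt/tau_rec),

a refactored form in which the utilization scale is absorbed into
omega_i, so a single-spike train reduces exactly to the static synapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _fast
from .patterns import SpikePattern

__all__ = [
    "StaticParams",
    "OrdinalParams",
    "SignConstrainedParams",
    "TMParams",
    "TMState",
    "tm_state_sequence",
    "instantaneous_efficacies",
    "U_BOUNDS",
    "TAU_BOUNDS",
]

# projection bounds applied to TM parameters after learning updates
U_BOUNDS = (_fast.U_MIN, _fast.U_MAX)
TAU_BOUNDS = (_fast.TAU_MIN, _fast.TAU_MAX)


@dataclass
class StaticParams:
    """Scalar efficacy per afferent."""

    omega: np.ndarray

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        if not np.all(np.isfinite(self.omega)):
            raise ValueError("omega must be finite")

    @property
    def n_afferents(self) -> int:
        return self.omega.size

    def copy(self) -> "StaticParams":
        return StaticParams(self.omega.copy())


@dataclass
class OrdinalParams:
    """One independent efficacy per (afferent, spike rank)."""

    omega: np.ndarray  # (N, nspikes)

    def __post_init__(self) -> None:
        self.omega = np.atleast_2d(np.asarray(self.omega, dtype=float))
        if not np.all(np.isfinite(self.omega)):
            raise ValueError("omega must be finite")

    @property
    def n_afferents(self) -> int:
        return self.omega.shape[0]

    @property
    def n_ranks(self) -> int:
        return self.omega.shape[1]

    def copy(self) -> "OrdinalParams":
        return OrdinalParams(self.omega.copy())


@dataclass
class SignConstrainedParams:
    """Signed per-afferent scale times L1-normalized nonnegative rank magnitudes."""

    omega: np.ndarray  # (N,)
    z: np.ndarray  # (N, nspikes), z >= 0, not all-zero per afferent

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.z = np.atleast_2d(np.asarray(self.z, dtype=float))
        if self.z.shape[0] != self.omega.size:
            raise ValueError("z rows must match omega length")
        if np.any(self.z < 0):
            raise ValueError("z magnitudes must be nonnegative")
        if np.any(self.z.sum(axis=1) <= 0):
            raise ValueError("each afferent needs at least one positive z entry")

    @property
    def n_afferents(self) -> int:
        return self.omega.size

    @property
    def z1(self) -> np.ndarray:
        return self.z.sum(axis=1)

    def copy(self) -> "SignConstrainedParams":
        return SignConstrainedParams(self.omega.copy(), self.z.copy())


@dataclass
class TMParams:
    """Per-afferent Tsodyks-Markram parameters (omega, U, tau_rec, tau_fac)."""

    omega: np.ndarray
    U: np.ndarray
    tau_rec: np.ndarray
    tau_fac: np.ndarray

    def __post_init__(self) -> None:
        self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        self.U = np.atleast_1d(np.asarray(self.U, dtype=float))
        self.tau_rec = np.atleast_1d(np.asarray(self.tau_rec, dtype=float))
        self.tau_fac = np.atleast_1d(np.asarray(self.tau_fac, dtype=float))
        n = self.omega.size
        if not (self.U.size == self.tau_rec.size == self.tau_fac.size == n):
            raise ValueError("all TM parameter arrays must share one length")
        if np.any(self.U <= 0) or np.any(self.U > 1):
            raise ValueError("U must lie in (0, 1]")
        if np.any(self.tau_rec <= 0) or np.any(self.tau_fac <= 0):
            raise ValueError("time constants must be positive")

    @property
    def n_afferents(self) -> int:
        return self.omega.size

    def copy(self) -> "TMParams":
        return TMParams(self.omega.copy(), self.U.copy(),
                        self.tau_rec.copy(), self.tau_fac.copy())

    def project(self) -> None:
        """Clip U and the time constants back into their valid ranges."""
        np.clip(self.U, *U_BOUNDS, out=self.U)
        np.clip(self.tau_rec, *TAU_BOUNDS, out=self.tau_rec)
        np.clip(self.tau_fac, *TAU_BOUNDS, out=self.tau_fac)


@dataclass
class TMState:
    """Per-spike TM state (u, x) of one spike train, with optional partials."""

    u: np.ndarray
    x: np.ndarray
    du_dU: np.ndarray | None = None
    dx_dU: np.ndarray | None = None
    dx_dtau_rec: np.ndarray | None = None
    du_dtau_fac: np.ndarray | None = None
    dx_dtau_fac: np.ndarray | None = None

    @property
    def efficacy_factor(self) -> np.ndarray:
        return self.u * self.x


def tm_state_sequence(
    spike_times: np.ndarray,
    U: float,
    tau_rec: float,
    tau_fac: float,
    with_partials: bool = False,
) -> TMState:
    """Run the TM recursions along one sorted spike train.

    Returns per-spike (u, x), and when ``with_partials`` the five
    partial-derivative sequences d u/dU, dx/dU, dx/dtau_rec, du/dtau_fac,
    dx/dtau_fac needed by the learning rule.
    """
    ts = np.asarray(spike_times, dtype=float)
    if ts.size > 1 and np.any(np.diff(ts) < 0):
        raise ValueError("spike_times must be sorted ascending")
    n = ts.size
    aff = np.zeros(n, dtype=np.int64)
    Ua = np.array([float(U)])
    tra = np.array([float(tau_rec)])
    tfa = np.array([float(tau_fac)])
    u = np.empty(n)
    x = np.empty(n)
    if not with_partials:
        _fast.tm_ux(ts, aff, 1, Ua, tra, tfa, u, x)
        return TMState(u, x)
    du_dU = np.empty(n)
    dx_dU = np.empty(n)
    dx_dr = np.empty(n)
    du_df = np.empty(n)
    dx_df = np.empty(n)
    _fast.tm_ux_partials(ts, aff, 1, Ua, tra, tfa,
                         u, x, du_dU, dx_dU, dx_dr, du_df, dx_df)
    return TMState(u, x, du_dU, dx_dU, dx_dr, du_df, dx_df)


def instantaneous_efficacies(pattern: SpikePattern, model: str, params) -> list[np.ndarray]:
    """Per-spike efficacy table for a pattern under the given synapse model.

    Returns one array per afferent, aligned with ``pattern.times``.
    """
    n_aff = pattern.n_afferents
    if model == "static":
        if not isinstance(params, StaticParams) or params.n_afferents != n_aff:
            raise ValueError("static model needs StaticParams of matching size")
        return [np.full(t.size, params.omega[i])
                for i, t in enumerate(pattern.times)]
    if model == "ordinal":
        if not isinstance(params, OrdinalParams) or params.n_afferents != n_aff:
            raise ValueError("ordinal model needs OrdinalParams of matching size")
        out = []
        for i, t in enumerate(pattern.times):
            if t.size > params.n_ranks:
                raise ValueError(f"afferent {i}: spike rank exceeds parameter table")
            out.append(params.omega[i, : t.size].copy())
        return out
    if model == "sign_constrained":
        if not isinstance(params, SignConstrainedParams) or params.n_afferents != n_aff:
            raise ValueError("sign-constrained model needs matching SignConstrainedParams")
        z1 = params.z1
        out = []
        for i, t in enumerate(pattern.times):
            if t.size > params.z.shape[1]:
                raise ValueError(f"afferent {i}: spike rank exceeds z table")
            out.append(params.omega[i] * params.z[i, : t.size] / z1[i])
        return out
    if model == "tm":
        if not isinstance(params, TMParams) or params.n_afferents != n_aff:
            raise ValueError("tm model needs TMParams of matching size")
        out = []
        for i, t in enumerate(pattern.times):
            st = tm_state_sequence(t, params.U[i], params.tau_rec[i],
                                   params.tau_fac[i])
            out.append(params.omega[i] * st.efficacy_factor)
        return out
    raise ValueError(f"unknown synapse model {model!r}")
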