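"""Short-term-plasticity induction/recovery analysis of 12-pulse recordings.

The standard STP characterization protocol delivers 12 stimulation pulses
in two groups - 8 then 4 pulses at 50 Hz (20 ms inter-pulse interval)
separated by a 250 ms gap.  Per-pulse response amplitudes A_1..A_12
(trial medians) summarize a connection; two normalized statistics capture
its short-term plasticity:

    STP_ind = (Abar_6-8  - A_1)      / A_max      (induction)
    STP_rec = (Abar_9-12 - Abar_1-4) / A_max      (recovery after the gap)

with group means Abar_1-4, Abar_6-8, Abar_9-12 and A_max the maximal
response amplitude of the connection.  For inhibitory (negative-going)
connections A_max is taken as the maximal-magnitude amplitude with its
sign retained, so the statistics measure changes in response *magnitude*:
depression is negative and facilitation positive for either polarity, and
both statistics stay within [-1, 1] on single-polarity amplitude vectors.

Connections are fitted by the Tsodyks-Markram model via multistart
bounded least squares over all 12 amplitudes; a synthetic-recording
generator provides trial tables of the same shape for end-to-end tests
(it stands in for external electrophysiology datasets and is labelled
synthetic throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import ks_2samp

from .synapses import TMParams, tm_state_sequence

__all__ = [
    "PROTOCOL_TIMES",
    "ConnectionRecording",
    "STPMeasures",
    "TMFitResult",
    "QCRejection",
    "qc_and_amplitudes",
    "stp_measures",
    "simulate_protocol_amplitudes",
    "fit_tm_to_connection",
    "compare_distributions",
    "synth_connection_generator",
    "population_stp",
    "read_recording_csv",
    "write_recording_csv",
]

# 8 pulses at 50 Hz, 250 ms gap, then 4 more pulses at 50 Hz
PROTOCOL_TIMES = np.concatenate([
    np.arange(8) * 0.020,
    0.140 + 0.250 + np.arange(4) * 0.020,
])
N_PULSES = 12

FIT_W_GRID = (0.01, 0.05, 0.5, 1.0, 5.0, 10.0)
FIT_U_GRID = (0.01, 0.1, 0.25, 0.5, 0.75, 0.9, 0.99)
FIT_TAU_GRID = (0.01, 0.1, 1.0)

GROUPS = {
    "first": slice(0, 1),
    "g1_4": slice(0, 4),
    "g6_8": slice(5, 8),
    "g9_12": slice(8, 12),
}


class QCRejection(Exception):
    """Raised when a recording fails quality control; carries the reason."""


@dataclass
class ConnectionRecording:
    """Trial x 12-pulse amplitude table of one synaptic connection.

    Missing trials for a pulse are NaN.  ``polarity`` is the inferred sign
    of the connection ('excitatory' or 'inhibitory'); amplitudes carry the
    connection's sign (negative for inhibitory).
    """

    trial_amplitudes: np.ndarray
    polarity: str
    species: str = ""
    cell_type: str = ""
    qc_pass: bool = True
    units: str = "mV"

    def __post_init__(self) -> None:
        self.trial_amplitudes = np.atleast_2d(
            np.asarray(self.trial_amplitudes, dtype=float))
        if self.trial_amplitudes.shape[1] != N_PULSES:
            raise ValueError(f"expected {N_PULSES} pulse columns")
        if self.trial_amplitudes.shape[0] < 1:
            raise ValueError("need at least one trial")
        if self.polarity not in ("excitatory", "inhibitory"):
            raise ValueError("polarity must be 'excitatory' or 'inhibitory'")

    @property
    def n_trials(self) -> int:
        return self.trial_amplitudes.shape[0]


@dataclass
class STPMeasures:
    """Per-pulse median amplitudes and the derived STP statistics."""

    A: np.ndarray
    A_max: float
    stp_ind: float
    stp_rec: float
    group_means: dict[str, float]


def stp_measures(A: np.ndarray) -> tuple[float, float]:
    """STP induction and recovery statistics of 12 response amplitudes.

    ``A_max`` is the maximal-magnitude amplitude with its sign retained;
    dividing the signed group differences by the signed ``A_max`` makes the
    statistics measure magnitude changes, so depression is negative for
    both excitatory and inhibitory connections and both values stay within
    [-1, 1] on single-polarity amplitude vectors.
    """
    A = np.asarray(A, dtype=float)
    if A.size != N_PULSES:
        raise ValueError(f"need exactly {N_PULSES} amplitudes")
    a_max = A[np.argmax(np.abs(A))]
    if a_max == 0.0:
        raise ValueError("A_max is zero; STP statistics undefined")
    g68 = A[GROUPS["g6_8"]].mean()
    g14 = A[GROUPS["g1_4"]].mean()
    g912 = A[GROUPS["g9_12"]].mean()
    stp_ind = (g68 - A[0]) / a_max
    stp_rec = (g912 - g14) / a_max
    return float(stp_ind), float(stp_rec)


def qc_and_amplitudes(rec: ConnectionRecording, min_trials: int = 4) -> STPMeasures:
    """Quality-control a recording and reduce it to per-pulse median amplitudes.

    Rejects (raises :class:`QCRejection`) when the provided quality flag is
    unset, when any pulse has fewer than ``min_trials`` valid trials, or
    when the mean amplitude over all 12 pulses has a sign inconsistent with
    the connection's polarity.
    """
    if not rec.qc_pass:
        raise QCRejection("recording flagged qc_pass=False")
    valid_counts = np.sum(~np.isnan(rec.trial_amplitudes), axis=0)
    if np.any(valid_counts < min_trials):
        bad = int(np.argmin(valid_counts))
        raise QCRejection(
            f"pulse {bad + 1} has {int(valid_counts[bad])} trials (< {min_trials})")
    A = np.nanmedian(rec.trial_amplitudes, axis=0)
    mean_amp = A.mean()
    if rec.polarity == "excitatory" and mean_amp < 0:
        raise QCRejection("negative mean amplitude on an excitatory connection")
    if rec.polarity == "inhibitory" and mean_amp > 0:
        raise QCRejection("positive mean amplitude on an inhibitory connection")
    stp_ind, stp_rec = stp_measures(A)
    a_max = float(A[np.argmax(np.abs(A))])
    return STPMeasures(A, a_max, stp_ind, stp_rec,
                       {k: float(A[s].mean()) for k, s in GROUPS.items()})


def simulate_protocol_amplitudes(params: TMParams | tuple[float, float, float, float]
                                 ) -> np.ndarray:
    """Model response amplitudes A_j = omega * u_j * x_j under the 12-pulse protocol.

    Amplitudes inherit the sign of omega so excitatory and inhibitory
    connections produce directly comparable tables.
    """
    if isinstance(params, TMParams):
        if params.n_afferents != 1:
            raise ValueError("simulate one connection at a time")
        w, U, tr, tf = (params.omega[0], params.U[0],
                        params.tau_rec[0], params.tau_fac[0])
    else:
        w, U, tr, tf = params
    st = tm_state_sequence(PROTOCOL_TIMES, U, tr, tf)
    return w * st.efficacy_factor


@dataclass
class TMFitResult:
    params: TMParams
    mse: float
    r2: float  # coefficient of determination over the 12 amplitudes
    group_means_model: dict[str, float]
    group_means_data: dict[str, float]
    stp_ind: float
    stp_rec: float
    n_starts: int


def _protocol_mse(theta: np.ndarray, A: np.ndarray) -> float:
    model = simulate_protocol_amplitudes(tuple(theta))
    d = model - A
    return float(d @ d) / N_PULSES


def fit_tm_to_connection(A: np.ndarray, n_starts: str | int = "grid") -> TMFitResult:
    """Multistart bounded least-squares fit of the TM model to 12 amplitudes.

    Local minimizations (L-BFGS-B; U in (0,1], time constants in
    [1 ms, 10 s], omega unbounded) are run from the full grid of
    6 x 7 x 3 x 3 = 378 initial guesses over (omega, U, tau_rec, tau_fac)
    and the lowest-MSE solution is kept.  The fitted model's group means
    and STP statistics are reported alongside the data's.
    """
    A = np.asarray(A, dtype=float)
    if A.size != N_PULSES or not np.all(np.isfinite(A)):
        raise ValueError(f"need {N_PULSES} finite amplitudes")
    sign = 1.0 if A.mean() >= 0 else -1.0
    bounds = [(None, None), (1e-3, 1.0), (1e-3, 10.0), (1e-3, 10.0)]
    best = None
    tried = 0
    for w0, U0, tr0, tf0 in product(FIT_W_GRID, FIT_U_GRID,
                                    FIT_TAU_GRID, FIT_TAU_GRID):
        tried += 1
        x0 = np.array([sign * w0, U0, tr0, tf0])
        res = minimize(_protocol_mse, x0, args=(A,), method="L-BFGS-B",
                       bounds=bounds, tol=1e-10)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("TM fit failed from every initial guess")
    w, U, tr, tf = best.x
    params = TMParams(np.array([w]), np.array([U]),
                      np.array([tr]), np.array([tf]))
    model_A = simulate_protocol_amplitudes(params)
    ss_res = float(np.sum((A - model_A) ** 2))
    ss_tot = float(np.sum((A - A.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res < 1e-20 else 0.0)
    stp_ind, stp_rec = stp_measures(model_A)
    return TMFitResult(
        params, float(best.fun), r2,
        {k: float(model_A[s].mean()) for k, s in GROUPS.items()},
        {k: float(A[s].mean()) for k, s in GROUPS.items()},
        stp_ind, stp_rec, tried)


def compare_distributions(sample_a, sample_b) -> float:
    """Two-sample Kolmogorov-Smirnov statistic D = sup |ECDF_a - ECDF_b|."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    return float(ks_2samp(a, b).statistic)


def synth_connection_generator(params: TMParams, n_trials: int = 50,
                               trial_noise_sd: float = 0.1,
                               seed: int | None = None,
                               species: str = "synthetic",
                               cell_type: str = "synthetic") -> ConnectionRecording:
    """Synthetic recording: simulated 12-pulse amplitudes plus iid trial noise.

    A stand-in for externally recorded connection tables; polarity follows
    the sign of omega.  ``trial_noise_sd`` is in the amplitude's units.
    """
    if n_trials < 4:
        raise ValueError("need at least 4 trials to pass quality control")
    rng = np.random.default_rng(seed)
    A = simulate_protocol_amplitudes(params)
    trials = A[None, :] + rng.normal(0.0, trial_noise_sd, (n_trials, N_PULSES))
    polarity = "excitatory" if params.omega[0] >= 0 else "inhibitory"
    return ConnectionRecording(trials, polarity, species=species,
                               cell_type=cell_type, qc_pass=True)


def population_stp(params: TMParams) -> pd.DataFrame:
    """STP statistics of every synapse in a trained parameter set.

    Simulates the 12-pulse protocol per synapse and splits the population
    into excitatory and inhibitory groups by the sign of omega - the
    pipeline used to compare trained synapse populations with recorded
    connection types.
    """
    rows = []
    for i in range(params.n_afferents):
        w = params.omega[i]
        if w == 0.0:
            continue
        A = simulate_protocol_amplitudes(
            (w, params.U[i], params.tau_rec[i], params.tau_fac[i]))
        ind, rec = stp_measures(A)
        rows.append({"synapse": i, "omega": w,
                     "polarity": "excitatory" if w > 0 else "inhibitory",
                     "stp_ind": ind, "stp_rec": rec})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV interchange: columns trial, pulse_1..pulse_12, polarity, species, type, qc_pass
# ---------------------------------------------------------------------------

_PULSE_COLS = [f"pulse_{i}" for i in range(1, N_PULSES + 1)]


def write_recording_csv(rec: ConnectionRecording, path: str | Path) -> None:
    df = pd.DataFrame(rec.trial_amplitudes, columns=_PULSE_COLS)
    df.insert(0, "trial", np.arange(rec.n_trials))
    df["polarity"] = rec.polarity
    df["species"] = rec.species
    df["type"] = rec.cell_type
    df["qc_pass"] = rec.qc_pass
    df.to_csv(path, index=False)


def read_recording_csv(path: str | Path) -> ConnectionRecording:
    df = pd.read_csv(path)
    missing = [c for c in _PULSE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"recording CSV missing columns: {missing}")
    return ConnectionRecording(
        df[_PULSE_COLS].to_numpy(dtype=float),
        polarity=str(df["polarity"].iloc[0]),
        species=str(df["species"].iloc[0]) if "species" in df else "",
        cell_type=str(df["type"].iloc[0]) if "type" in df else "",
        qc_pass=bool(df["qc_pass"].iloc[0]) if "qc_pass" in df else True,
    )
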