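"""Shared independent oracles for the test suite."""

import numpy as np


def voltage_at(pattern, efficacy_table, kernel, t):
    """Dense-evaluation oracle for the unreset voltage at time(s) t."""
    ts, aff, rank = pattern.merged()
    ws = np.array([efficacy_table[a][q] for a, q in zip(aff, rank)])
    t = np.atleast_1d(np.asarray(t, float))
    dt = t[:, None] - ts[None, :]
    k = np.where(dt > 0,
                 kernel.v0 * (np.exp(-np.clip(dt, 0, None) / kernel.tau_m)
                              - np.exp(-np.clip(dt, 0, None) / kernel.tau_s)),
                 0.0)
    out = k @ ws
    return out if out.size > 1 else float(out[0])
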