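"""Serialization, configuration and result files.

Plain-text interchange formats: spike patterns as JSON lines (one pattern
per line), synaptic parameter sets as JSON keyed by model, convergence
records as CSV, and a hierarchical YAML run configuration.  Any run is
reproducible from (config, seed); every protocol constant is a named
config default rather than a magic number.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .capacity import CapacityFit, ConvergenceRecord
from .patterns import PatternBatch, SpikePattern
from .synapses import (
    OrdinalParams,
    SignConstrainedParams,
    StaticParams,
    TMParams,
)

__all__ = [
    "SCHEMA_VERSION",
    "RunConfig",
    "write_patterns_jsonl",
    "read_patterns_jsonl",
    "write_pattern_csv",
    "read_pattern_csv",
    "params_to_dict",
    "params_from_dict",
    "save_params",
    "load_params",
    "records_to_csv",
    "records_from_csv",
    "capacity_fit_to_dict",
    "capacity_fit_from_dict",
]

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """Serialized object does not match the expected schema."""


# ---------------------------------------------------------------------------
# spike patterns: JSON lines, one pattern per line
# ---------------------------------------------------------------------------

def write_patterns_jsonl(batch: PatternBatch, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pat, label in zip(batch.patterns, batch.labels):
            fh.write(json.dumps({
                "T": pat.duration,
                "times": [t.tolist() for t in pat.times],
                "label": int(label),
            }) + "\n")


def write_pattern_csv(pattern: SpikePattern, path: str | Path,
                      label: int | None = None) -> None:
    """CSV alternative for one pattern: columns afferent,index,time_s."""
    rows = [{"afferent": i, "index": j, "time_s": t}
            for i, ts in enumerate(pattern.times) for j, t in enumerate(ts)]
    df = pd.DataFrame(rows, columns=["afferent", "index", "time_s"])
    if label is not None:
        df["label"] = label
    df.attrs["duration"] = pattern.duration
    with open(path, "w") as fh:
        fh.write(f"# duration_s={pattern.duration}\n")
        df.to_csv(fh, index=False)


def read_pattern_csv(path: str | Path) -> SpikePattern:
    with open(path) as fh:
        first = fh.readline()
        duration = None
        if first.startswith("# duration_s="):
            duration = float(first.split("=", 1)[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    if not {"afferent", "index", "time_s"} <= set(df.columns):
        raise SchemaError("pattern CSV needs columns afferent,index,time_s")
    n_aff = int(df["afferent"].max()) + 1 if len(df) else 0
    times = [np.sort(df.loc[df["afferent"] == i, "time_s"].to_numpy())
             for i in range(n_aff)]
    if duration is None:
        duration = float(df["time_s"].max()) if len(df) else 1.0
    counts = {t.size for t in times}
    nspk = counts.pop() if len(counts) == 1 else None
    return SpikePattern(duration, times, nspk)


def read_patterns_jsonl(path: str | Path) -> PatternBatch:
    patterns, labels = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            for key in ("T", "times", "label"):
                if key not in obj:
                    raise SchemaError(f"pattern record missing key {key!r}")
            counts = {len(t) for t in obj["times"]}
            nspk = counts.pop() if len(counts) == 1 else None
            patterns.append(SpikePattern(obj["T"],
                                         [np.asarray(t) for t in obj["times"]],
                                         nspk))
            labels.append(int(obj["label"]))
    return PatternBatch(patterns, np.asarray(labels, dtype=np.int8))


# ---------------------------------------------------------------------------
# synaptic parameters: JSON per neuron
# ---------------------------------------------------------------------------

_MODEL_BY_TYPE = {
    StaticParams: "static",
    OrdinalParams: "ordinal",
    SignConstrainedParams: "sign_constrained",
    TMParams: "tm",
}


def params_to_dict(params) -> dict:
    model = _MODEL_BY_TYPE.get(type(params))
    if model is None:
        raise TypeError(f"cannot serialize {type(params)}")
    out: dict = {"schema_version": SCHEMA_VERSION, "model": model}
    if isinstance(params, (StaticParams, OrdinalParams)):
        out["omega"] = params.omega.tolist()
    elif isinstance(params, SignConstrainedParams):
        out["omega"] = params.omega.tolist()
        out["z"] = params.z.tolist()
    else:
        out["omega"] = params.omega.tolist()
        out["U"] = params.U.tolist()
        out["tau_rec"] = params.tau_rec.tolist()
        out["tau_fac"] = params.tau_fac.tolist()
    return out


def params_from_dict(obj: dict):
    if obj.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(
            f"schema_version mismatch: got {obj.get('schema_version')!r}, "
            f"expected {SCHEMA_VERSION}")
    model = obj.get("model")
    try:
        if model == "static":
            return StaticParams(np.asarray(obj["omega"]))
        if model == "ordinal":
            return OrdinalParams(np.asarray(obj["omega"]))
        if model == "sign_constrained":
            return SignConstrainedParams(np.asarray(obj["omega"]),
                                         np.asarray(obj["z"]))
        if model == "tm":
            return TMParams(np.asarray(obj["omega"]), np.asarray(obj["U"]),
                            np.asarray(obj["tau_rec"]),
                            np.asarray(obj["tau_fac"]))
    except KeyError as e:
        raise SchemaError(f"parameter record missing key {e.args[0]!r}") from e
    raise SchemaError(f"unknown model {model!r}")


def save_params(params, path: str | Path) -> None:
    Path(path).write_text(json.dumps(params_to_dict(params)))


def load_params(path: str | Path):
    return params_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# convergence records and capacity fits
# ---------------------------------------------------------------------------

def records_to_csv(records: list[ConvergenceRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        for rep, med in enumerate(rec.repeat_medians):
            rows.append({"load": rec.load, "median_ct": med,
                         "repeat_index": rep, "cutoff": rec.cutoff,
                         "n_realizations": rec.n_realizations})
    pd.DataFrame(rows).to_csv(path, index=False)


def records_from_csv(path: str | Path) -> list[ConvergenceRecord]:
    df = pd.read_csv(path)
    records = []
    for (load, cutoff), grp in df.groupby(["load", "cutoff"], sort=False):
        meds = grp.sort_values("repeat_index")["median_ct"].tolist()
        records.append(ConvergenceRecord(
            float(load), float(np.mean(meds)), meds,
            int(grp["n_realizations"].iloc[0]), int(cutoff)))
    records.sort(key=lambda r: (r.load, r.cutoff))
    return records


def capacity_fit_to_dict(fit: CapacityFit) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "gamma0": fit.gamma0,
        "alpha_c": fit.alpha_c,
        "gamma_exp": fit.gamma_exp,
        "epsilon": fit.epsilon,
        "window_loads": np.asarray(fit.window_loads).tolist(),
        "window_cts": np.asarray(fit.window_cts).tolist(),
        "degenerate": fit.degenerate,
    }


def capacity_fit_from_dict(obj: dict) -> CapacityFit:
    if obj.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError("schema_version mismatch for capacity fit")
    return CapacityFit(obj["gamma0"], obj["alpha_c"], obj["gamma_exp"],
                       obj["epsilon"], np.asarray(obj["window_loads"]),
                       np.asarray(obj["window_cts"]), obj["degenerate"])


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Hierarchical run configuration; every protocol constant is named here.

    ``task``: N, nspikes, duration (s), tau_coeff (integration-scale
    coefficient), tau_ratio.  ``model``: synapse model name.  ``learning``:
    learning rates, momentum, epoch cutoff.  ``protocol``: staged-sweep
    sizes.  All blocks serialize to/from YAML.
    """

    task: dict = field(default_factory=lambda: {
        "n_afferents": 100, "n_spikes": 4, "duration": 0.5,
        "tau_coeff": 5.67, "tau_ratio": 2.0, "threshold": 1.0,
    })
    model: str = "tm"
    learning: dict = field(default_factory=lambda: {
        "eta_omega": None, "eta_u": None, "eta_tau": None, "eta_z": None,
        "mu": 0.99, "max_epochs": 10_000,
    })
    protocol: dict = field(default_factory=lambda: {
        "stage_cutoffs": [10_000, 100_000, 1_000_000],
        "stage_steps": [0.01, 0.01, 0.005],
        "n_realizations": 1001, "n_repeats": 10, "n_data": 20,
    })
    seed: int = 0
    out_dir: str = "results"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        obj = yaml.safe_load(Path(path).read_text())
        known = {"task", "model", "learning", "protocol", "seed", "out_dir"}
        unknown = set(obj) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)
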