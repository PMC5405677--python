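"""File formats: text netlists, waveform CSVs, JSON configs and summaries.

Netlist text format (one component per line, ``#`` comments, identifiers
case-sensitive)::

    KIND name node_from node_to key=value ...

Waveform CSVs carry a ``time_s`` column plus ``P_<node>_mmHg`` pressure
and ``Q_<name>_mls`` flow columns. Scalars round-trip at 17 significant
digits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .circuit import ComponentSpec, Netlist
from .errors import ConfigurationError, DataError
from .simulate import SimulationResult

_FLOAT_FMT = "%.17g"


def write_netlist(netlist: Netlist, path: str | Path) -> None:
    lines = [
        "# shuntloop netlist",
        "# units: mmHg, ml/s, ml, s; KIND name node_from node_to key=value ...",
        f"# ground {netlist.ground}",
    ]
    for c in netlist.components:
        params = " ".join(f"{k}={_FLOAT_FMT % v}" for k, v in sorted(c.parameters.items()))
        lines.append(f"{c.kind} {c.name} {c.node_from} {c.node_to} {params}".rstrip())
    Path(path).write_text("\n".join(lines) + "\n")


def read_netlist(path: str | Path) -> Netlist:
    comps = []
    ground = "ground"
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if line.startswith("# ground "):
            ground = line.split()[-1]
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 4:
            raise ConfigurationError(f"{path}:{lineno}: expected KIND name node_from node_to")
        kind, name, node_from, node_to = fields[:4]
        params = {}
        for token in fields[4:]:
            if "=" not in token:
                raise ConfigurationError(f"{path}:{lineno}: malformed parameter {token!r}")
            key, value = token.split("=", 1)
            try:
                params[key] = float(value)
            except ValueError as exc:
                raise ConfigurationError(
                    f"{path}:{lineno}: non-numeric value for {key!r}: {value!r}"
                ) from exc
        try:
            comps.append(ComponentSpec(kind, name, node_from, node_to, params))
        except Exception as exc:
            raise ConfigurationError(f"{path}:{lineno}: {exc}") from exc
    return Netlist(comps, ground=ground)


def write_waveform_csv(
    path: str | Path,
    time_s: np.ndarray,
    pressures: Mapping[str, np.ndarray] | None = None,
    flows: Mapping[str, np.ndarray] | None = None,
) -> None:
    data = {"time_s": np.asarray(time_s, dtype=float)}
    for node, values in (pressures or {}).items():
        data[f"P_{node}_mmHg"] = np.asarray(values, dtype=float)
    for name, values in (flows or {}).items():
        data[f"Q_{name}_mls"] = np.asarray(values, dtype=float)
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_waveform_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if "time_s" not in frame.columns:
        raise DataError(f"{path}: missing required column 'time_s'")
    t = frame["time_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise DataError(f"{path}: time_s must be strictly increasing")
    return frame


def read_series(path: str | Path, column: str) -> tuple[np.ndarray, np.ndarray]:
    """One (time, values) pair from a waveform CSV; accepts the bare column
    name or the decorated P_/Q_ form."""
    frame = read_waveform_csv(path)
    if column not in frame.columns:
        matches = [c for c in frame.columns if c != "time_s" and column in c]
        if len(matches) != 1:
            raise DataError(
                f"{path}: column {column!r} not found; available {list(frame.columns)}"
            )
        column = matches[0]
    return frame["time_s"].to_numpy(), frame[column].to_numpy()


def result_to_frame(
    result: SimulationResult,
    nodes: list[str] | None = None,
    branches: list[str] | None = None,
) -> pd.DataFrame:
    nodes = nodes if nodes is not None else result.node_names
    branches = branches if branches is not None else result.flow_names
    data = {"time_s": result.time}
    for node in nodes:
        data[f"P_{node}_mmHg"] = result.node_pressure(node)
    for name in branches:
        data[f"Q_{name}_mls"] = result.branch_flow(name)
    return pd.DataFrame(data)


def write_result_csv(result: SimulationResult, path: str | Path, **kwargs) -> None:
    result_to_frame(result, **kwargs).to_csv(path, index=False, float_format=_FLOAT_FMT)


def load_json(path: str | Path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"{path}: invalid JSON ({exc})") from exc


def dump_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def summary_to_dict(summary) -> dict:
    return {
        "pressures": {
            site: {"mean": s.mean, "systolic": s.systolic,
                   "diastolic": s.diastolic, "pulse": s.pulse}
            for site, s in summary.pressures.items()
        },
        "flows": dict(summary.flows),
        "indices": summary.indices(),
    }
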