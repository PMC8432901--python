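"""Plain-text readers/writers for event streams, rate series and catalogs.

All formats are line-oriented text: ``#key value`` metadata headers
followed by whitespace-delimited numeric rows, so that fixture output
and simulation output are interchangeable everywhere downstream.
Numeric round-trips are at full precision (write-then-read is the
identity on every field).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .model import ModelParams
from .simulate import NetworkState, RateTimeSeries, SpikeEventStream
from .avalanches import AvalancheCatalog

__all__ = [
    "write_event_stream", "read_event_stream",
    "write_series", "read_series",
    "write_catalog", "read_catalog",
]

_PARAM_FIELDS = ("alpha", "beta", "w_e", "w_i", "h", "n")


def _fmt(v) -> str:
    """Shortest exact decimal for floats; plain digits for integers."""
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    return repr(float(v))


class ParseError(ValueError):
    """Malformed file; carries the offending line number."""

    def __init__(self, path, lineno: int, msg: str) -> None:
        super().__init__(f"{path}:{lineno}: {msg}")
        self.lineno = lineno


def _write_params(fh, params: ModelParams) -> None:
    for name in _PARAM_FIELDS:
        fh.write(f"#param {name}={_fmt(getattr(params, name))}\n")


def _parse_headers(path) -> tuple[dict, list[tuple[int, str]]]:
    meta: dict[str, str] = {}
    rows: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                try:
                    key, value = line[1:].split(None, 1)
                except ValueError:
                    raise ParseError(path, lineno, f"malformed header {line!r}")
                if key == "param":
                    name, val = value.split("=", 1)
                    meta[f"param:{name}"] = val
                else:
                    meta[key] = value
            else:
                rows.append((lineno, line))
    return meta, rows


def _params_from_meta(meta: dict, path) -> ModelParams | None:
    if not any(k.startswith("param:") for k in meta):
        return None
    kwargs = {}
    for name in _PARAM_FIELDS:
        raw = meta.get(f"param:{name}")
        if raw is None:
            raise ParseError(path, 0, f"missing #param {name}")
        kwargs[name] = int(raw) if name == "n" else float(raw)
    return ModelParams(**kwargs)


def write_event_stream(path, stream: SpikeEventStream) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        _write_params(fh, stream.params)
        if stream.seed is not None:
            fh.write(f"#seed {stream.seed}\n")
        fh.write(f"#initial {stream.initial_state.k} {stream.initial_state.l}\n")
        if stream.t_max is not None:
            fh.write(f"#tmax {_fmt(stream.t_max)}\n")
        fh.write("#columns t_ms pop delta\n")
        for t, p, d in zip(stream.times, stream.pops, stream.deltas):
            fh.write(f"{_fmt(t)} {'E' if p == 0 else 'I'} {'+1' if d > 0 else '-1'}\n")


def read_event_stream(path) -> SpikeEventStream:
    meta, rows = _parse_headers(path)
    params = _params_from_meta(meta, path)
    if params is None:
        raise ParseError(path, 0, "event stream lacks #param headers")
    if "initial" not in meta:
        raise ParseError(path, 0, "missing #initial header")
    k0, l0 = (int(x) for x in meta["initial"].split())
    times, pops, deltas = [], [], []
    for lineno, line in rows:
        parts = line.split()
        if len(parts) != 3 or parts[1] not in ("E", "I") or parts[2] not in ("+1", "-1"):
            raise ParseError(path, lineno, f"malformed event row {line!r}")
        times.append(float(parts[0]))
        pops.append(0 if parts[1] == "E" else 1)
        deltas.append(int(parts[2]))
    try:
        return SpikeEventStream(
            initial_state=NetworkState(k=k0, l=l0),
            times=np.array(times), pops=np.array(pops, np.int8),
            deltas=np.array(deltas, np.int8), params=params,
            seed=int(meta["seed"]) if "seed" in meta else None,
            t_max=float(meta["tmax"]) if "tmax" in meta else None,
        )
    except ValueError as exc:
        raise ParseError(path, 0, f"validation failed: {exc}") from exc


def write_series(path, series: RateTimeSeries) -> None:
    path = Path(path)
    cols = ["t_ms", "rate_per_ms"]
    arrays = [series.t, series.rate]
    if series.k is not None:
        cols += ["k", "l"]
        arrays += [series.k, series.l]
    if series.spike_counts is not None:
        cols.append("spikes")
        arrays.append(series.spike_counts)
    with open(path, "w") as fh:
        if series.params is not None:
            _write_params(fh, series.params)
        fh.write(f"#dt {_fmt(series.dt)}\n#t0 {_fmt(series.t0)}\n")
        fh.write("#columns " + " ".join(cols) + "\n")
        for row in zip(*arrays):
            fh.write(" ".join(_fmt(v) for v in row) + "\n")


def read_series(path) -> RateTimeSeries:
    meta, rows = _parse_headers(path)
    if "dt" not in meta or "columns" not in meta:
        raise ParseError(path, 0, "missing #dt or #columns header")
    cols = meta["columns"].split()
    data = []
    for lineno, line in rows:
        parts = line.split()
        if len(parts) != len(cols):
            raise ParseError(path, lineno, f"expected {len(cols)} columns, got {len(parts)}")
        data.append([float(x) for x in parts])
    arr = np.array(data) if data else np.empty((0, len(cols)))
    get = {c: arr[:, i] for i, c in enumerate(cols)}
    return RateTimeSeries(
        dt=float(meta["dt"]),
        t0=float(meta.get("t0", 0.0)),
        rate=get["rate_per_ms"],
        k=get["k"] if "k" in get else None,
        l=get["l"] if "l" in get else None,
        spike_counts=get["spikes"].astype(np.int64) if "spikes" in get else None,
        params=_params_from_meta(meta, path),
    )


def write_catalog(path, catalog: AvalancheCatalog) -> None:
    with open(path, "w") as fh:
        fh.write(f"#method {catalog.method}\n")
        for name in ("delta", "theta", "size_def"):
            val = getattr(catalog, name)
            if val is not None:
                fh.write(f"#{name} {_fmt(val)}\n")
        fh.write("#columns size duration_ms\n")
        for s, d in zip(catalog.sizes, catalog.durations):
            fh.write(f"{_fmt(s)} {_fmt(d)}\n")


def read_catalog(path) -> AvalancheCatalog:
    meta, rows = _parse_headers(path)
    sizes, durations = [], []
    for lineno, line in rows:
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(path, lineno, f"expected 2 columns, got {len(parts)}")
        sizes.append(float(parts[0]))
        durations.append(float(parts[1]))
    return AvalancheCatalog(
        sizes=np.array(sizes), durations=np.array(durations),
        method=meta.get("method", "unknown"),
        delta=float(meta["delta"]) if "delta" in meta else None,
        theta=float(meta["theta"]) if "theta" in meta else None,
        size_def=int(float(meta["size_def"])) if "size_def" in meta else None,
    )
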