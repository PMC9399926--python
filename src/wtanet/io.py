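"""Configuration files, spike/summary readers and writers, run manifests."""
from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import ConfigError, NetworkConfig
from .simulator import SpikeRecord

__all__ = [
    "load_config",
    "save_config",
    "write_spikes",
    "read_spikes",
    "write_manifest",
]

_SPIKE_HEADER = ["time_ms", "neuron_id", "population"]


def load_config(path: str | Path) -> NetworkConfig:
    """Read a YAML (or JSON) config file, merged over the defaults.

    An empty file yields the full default parameterization; unknown keys
    and invariant violations raise :class:`ConfigError` naming the problem.
    """
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return NetworkConfig.from_dict(data)


def save_config(config: NetworkConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def config_hash(config: NetworkConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_spikes(record: SpikeRecord, path: str | Path) -> None:
    """Spike TSV: ``time_ms<TAB>neuron_id<TAB>population``, time-sorted.

    Times are serialized with fixed microsecond precision (finer than the
    0.1 ms step, so the round trip is lossless and files stay diffable).
    A header comment carries the population id ranges and the horizon.
    """
    path = Path(path)
    order = np.argsort(record.times, kind="stable")
    pop_of = np.empty(len(record.times), dtype=object)
    for label, r in record.populations.items():
        mask = (record.neuron_ids >= r.start) & (record.neuron_ids < r.stop)
        pop_of[mask] = label
    meta = {
        "populations": {k: [r.start, r.stop] for k, r in record.populations.items()},
        "t_total": record.t_total,
    }
    with path.open("w") as fh:
        fh.write(f"# {json.dumps(meta)}\n")
        fh.write("\t".join(_SPIKE_HEADER) + "\n")
        for i in order:
            fh.write(f"{record.times[i]:.3f}\t{record.neuron_ids[i]}\t{pop_of[i]}\n")


def read_spikes(path: str | Path) -> SpikeRecord:
    """Inverse of :func:`write_spikes`; empty spike sections are valid."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise ConfigError(f"{path}: missing metadata header")
        meta = json.loads(first[2:])
        header = fh.readline().strip().split("\t")
        if header != _SPIKE_HEADER:
            raise ConfigError(f"{path}: unexpected column header {header}")
        times, ids = [], []
        for line in fh:
            t, nid, _pop = line.rstrip("\n").split("\t")
            times.append(float(t))
            ids.append(int(nid))
    populations = {k: range(a, b) for k, (a, b) in meta["populations"].items()}
    return SpikeRecord(
        times=np.array(times, dtype=float),
        neuron_ids=np.array(ids, dtype=np.int32),
        populations=populations,
        t_total=float(meta["t_total"]),
    )


def write_manifest(
    path: str | Path,
    config: NetworkConfig,
    seed,
    outputs: dict[str, str],
    extra: dict | None = None,
) -> None:
    """Reproducibility manifest: config hash + seed + output inventory."""
    from . import __version__

    manifest = {
        "version": __version__,
        "config_hash": config_hash(config),
        "config": config.to_dict(),
        "seed": seed if isinstance(seed, (int, list)) else str(seed),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "outputs": outputs,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
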