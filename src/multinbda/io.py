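"""CSV/YAML readers and writers and run manifests.

All tables are plain RFC-4180 CSV with documented headers; floats are
written with ``repr`` precision so simulated data round-trip losslessly.
Times are seconds unless a rescaling factor is applied on ingest.
"""

from __future__ import annotations

import csv
import hashlib
import json
import time
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import (
    DEFAULT_BLOCK_SECONDS,
    DEFAULT_TIE_WINDOW_S,
    DiffusionData,
    IndividualCovariates,
    NetworkStack,
    ValidationError,
)
from .networks import AssociationNetwork, ObservationStream

__all__ = [
    "read_visits",
    "read_adjacency",
    "write_adjacency",
    "write_edgelist",
    "read_attributes",
    "read_covariates",
    "read_network_manifest",
    "read_diffusions",
    "write_diffusions",
    "load_config",
    "CONFIG_DEFAULTS",
    "RunManifest",
]

#: all tunable defaults in one place
CONFIG_DEFAULTS: dict = {
    "baseline": "constant",
    "ilv_mode": "none",
    "layer_constraint": "free",
    "zero_layers": [],
    "ilv_names": [],
    "use_ties": True,
    "tie_window_s": DEFAULT_TIE_WINDOW_S,
    "block_seconds": DEFAULT_BLOCK_SECONDS,
    "ci_level": 0.95,
    "n_starts": 5,
}


def _fmt(x: float) -> str:
    return repr(float(x))


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )


# ---------------------------------------------------------------------------
# observation streams
# ---------------------------------------------------------------------------


def read_visits(path, block_seconds: int = DEFAULT_BLOCK_SECONDS) -> ObservationStream:
    """Visits CSV: ``id,location,time_block`` or ``id,location,timestamp``.

    ISO-8601 timestamps are binned into ``block_seconds`` windows counted
    from the Unix epoch.
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["id", "location"], path)
    if "time_block" in df.columns:
        try:
            blocks = df["time_block"].astype(int)
        except ValueError as exc:
            raise ValidationError(f"{path}: non-integer time_block: {exc}") from exc
    elif "timestamp" in df.columns:
        ts = pd.to_datetime(df["timestamp"], utc=True, errors="raise")
        blocks = (ts.astype("int64") // 10**9 // block_seconds).astype(int)
    else:
        raise ValidationError(f"{path}: need a 'time_block' or 'timestamp' column")
    return ObservationStream(zip(df["id"], df["location"], blocks))


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


def write_adjacency(net: AssociationNetwork, path) -> None:
    """Square adjacency CSV with an id header row and column."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id"] + net.node_ids)
        for i, nid in enumerate(net.node_ids):
            w.writerow([nid] + [_fmt(x) for x in net.weights[i]])


def read_adjacency(path) -> AssociationNetwork:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    ids = [str(i) for i in df.index]
    if [str(c) for c in df.columns] != ids:
        raise ValidationError(f"{path}: adjacency row and column ids differ")
    return AssociationNetwork(ids, df.to_numpy(float))


def write_edgelist(net: AssociationNetwork, path) -> None:
    """Edge-list CSV ``id_a,id_b,weight``: only w > 0, a < b lexicographic."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id_a", "id_b", "weight"])
        for i, a in enumerate(net.node_ids):
            for j, b in enumerate(net.node_ids):
                if a < b and net.weights[i, j] > 0:
                    w.writerow([a, b, _fmt(net.weights[i, j])])


def read_network_manifest(path) -> NetworkStack:
    """Manifest CSV ``layer_name,path`` (paths relative to the manifest)."""
    base = Path(path).parent
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["layer_name", "path"], path)
    layers, names = [], []
    for _, row in df.iterrows():
        p = Path(row["path"])
        layers.append(read_adjacency(p if p.is_absolute() else base / p))
        names.append(row["layer_name"])
    return NetworkStack(layers=layers, layer_names=names)


# ---------------------------------------------------------------------------
# attributes / covariates
# ---------------------------------------------------------------------------


def read_attributes(path) -> pd.DataFrame:
    """Attribute CSV ``id,species[,site,...]`` indexed by id."""
    df = pd.read_csv(path, dtype={"id": str})
    _require_columns(df, ["id"], path)
    return df.set_index("id")


def read_covariates(
    path, reference: Mapping[str, str] | None = None,
    standardize: Sequence[str] = ("n_obs",),
) -> IndividualCovariates:
    df = pd.read_csv(path, dtype={"id": str})
    _require_columns(df, ["id"], path)
    return IndividualCovariates(df, reference=reference, standardize=standardize)


# ---------------------------------------------------------------------------
# diffusions
# ---------------------------------------------------------------------------


def write_diffusions(diffusions: Sequence[DiffusionData], arrivals_path, trials_path) -> None:
    """Arrivals CSV ``trial,site,id,arrival_s`` + trial metadata CSV
    ``trial,site,t_end_s,tie_window_s``."""
    with open(arrivals_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trial", "site", "id", "arrival_s"])
        for d in diffusions:
            for ind, t in sorted(d.arrivals.items(), key=lambda kv: kv[1]):
                w.writerow([d.trial_id, d.site, ind, _fmt(t)])
    with open(trials_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trial", "site", "t_end_s", "tie_window_s", "seeded"])
        for d in diffusions:
            w.writerow([d.trial_id, d.site, _fmt(d.t_end), _fmt(d.tie_window),
                        ";".join(d.seeded)])


def read_diffusions(arrivals_path, trials_path, time_unit: float = 1.0) -> list[DiffusionData]:
    """Inverse of :func:`write_diffusions`.

    Blank ``arrival_s`` rows mark individuals known present but censored;
    they are ignored (the risk set is the site network's node set).
    ``time_unit`` rescales every time column to seconds on ingest.
    """
    trials = pd.read_csv(trials_path, dtype={"trial": str, "site": str},
                         float_precision="round_trip")
    _require_columns(trials, ["trial", "site", "t_end_s"], trials_path)
    arr = pd.read_csv(arrivals_path, dtype={"trial": str, "site": str, "id": str},
                      float_precision="round_trip")
    _require_columns(arr, ["trial", "site", "id", "arrival_s"], arrivals_path)
    out = []
    for _, row in trials.iterrows():
        sub = arr[arr["trial"] == row["trial"]]
        arrivals = {
            r["id"]: float(r["arrival_s"]) * time_unit
            for _, r in sub.iterrows()
            if pd.notna(r["arrival_s"]) and str(r["arrival_s"]).strip() != ""
        }
        tie = (
            float(row["tie_window_s"]) * time_unit
            if "tie_window_s" in trials.columns and pd.notna(row["tie_window_s"])
            else DEFAULT_TIE_WINDOW_S
        )
        seeded: tuple[str, ...] = ()
        if "seeded" in trials.columns and pd.notna(row["seeded"]):
            seeded = tuple(x for x in str(row["seeded"]).split(";") if x)
        out.append(
            DiffusionData(
                trial_id=row["trial"],
                site=row["site"],
                t_end=float(row["t_end_s"]) * time_unit,
                arrivals=arrivals,
                tie_window=tie,
                seeded=seeded,
            )
        )
    return out


# ---------------------------------------------------------------------------
# config + manifest
# ---------------------------------------------------------------------------


def load_config(path) -> dict:
    """YAML config merged over :data:`CONFIG_DEFAULTS`, with key validation."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    unknown = set(user) - set(CONFIG_DEFAULTS)
    if unknown:
        raise ValidationError(
            f"{path}: unknown config key(s) {sorted(unknown)}; "
            f"valid keys: {sorted(CONFIG_DEFAULTS)}"
        )
    cfg = dict(CONFIG_DEFAULTS)
    cfg.update(user)
    return cfg


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI output."""

    command: str
    inputs: dict[str, str]
    seed: int | None
    version: str
    timestamp: str

    @classmethod
    def create(cls, command: str, input_paths: Mapping[str, str], seed: int | None):
        return cls(
            command=command,
            inputs={k: _hash_file(p) for k, p in input_paths.items()},
            seed=seed,
            version=__version__,
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")
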