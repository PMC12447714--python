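"""File formats: parameter JSON, moment JSON, sample CSV, study configs.

Parameters and moments are small and human-auditable, so they live in
JSON; samples and study tables are CSV.  Every file written by a command
embeds provenance metadata (library version, command line, seed) — JSON
files under a ``"meta"`` key, CSV files as leading ``#`` comment lines.
Floats are serialized with ``repr``, which round-trips IEEE doubles
exactly.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .params import DenominatorSpec, GaussianParams, MomentPair

__all__ = [
    "read_params",
    "write_params",
    "read_moments",
    "write_moments",
    "read_samples_csv",
    "write_samples_csv",
    "read_study_config",
    "make_meta",
]


def make_meta(seed=None) -> dict:
    """Provenance block recorded in every output file."""
    return {
        "version": __version__,
        "command": " ".join(sys.argv),
        "seed": seed,
    }


def write_params(path, g: GaussianParams, den: DenominatorSpec | None = None, meta: dict | None = None) -> None:
    payload = {
        "n": g.n,
        "mu": g.mu.tolist(),
        "sigma": g.sigma.tolist(),
        "B": None if den is None or den.is_identity else den.matrix(g.n).tolist(),
        "c": 0.0 if den is None else den.c,
    }
    if meta is not None:
        payload["meta"] = meta
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_params(path):
    """Read a parameter file; returns ``(GaussianParams, DenominatorSpec)``."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise ValueError(f"{path}: not valid JSON ({err})") from err
    for key in ("mu", "sigma"):
        if key not in payload:
            raise ValueError(f"{path}: missing required key {key!r}")
    g = GaussianParams(np.asarray(payload["mu"]), np.asarray(payload["sigma"]))
    if "n" in payload and int(payload["n"]) != g.n:
        raise ValueError(f"{path}: declared n={payload['n']} but mu has length {g.n}")
    B = payload.get("B")
    den = DenominatorSpec(B=None if B is None else np.asarray(B), c=float(payload.get("c", 0.0)))
    return g, den


def write_moments(
    path, moments: MomentPair, method: str, seed=None, meta: dict | None = None
) -> None:
    payload = {
        "gamma": moments.gamma.tolist(),
        "second_moment": moments.second_moment.tolist(),
        "psi": moments.psi.tolist(),
        "method": method,
        "seed": seed,
    }
    if meta is not None:
        payload["meta"] = meta
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_moments(path) -> MomentPair:
    """Read a moments file: needs ``gamma`` plus ``psi`` and/or ``second_moment``."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise ValueError(f"{path}: not valid JSON ({err})") from err
    if "gamma" not in payload or ("psi" not in payload and "second_moment" not in payload):
        raise ValueError(f"{path}: needs 'gamma' and 'psi' (or 'second_moment')")
    return MomentPair(
        gamma=np.asarray(payload["gamma"]),
        second_moment=(
            np.asarray(payload["second_moment"]) if "second_moment" in payload else None
        ),
        psi=np.asarray(payload["psi"]) if "psi" in payload else None,
    )


def write_samples_csv(path, samples: np.ndarray, meta: dict | None = None) -> None:
    """Samples as CSV, one row per draw, columns indexed 0..n-1."""
    samples = np.asarray(samples)
    with open(path, "w") as fh:
        if meta is not None:
            for key, value in meta.items():
                fh.write(f"# {key}={value}\n")
        pd.DataFrame(samples, columns=[str(j) for j in range(samples.shape[1])]).to_csv(
            fh, index=False
        )


def read_samples_csv(path) -> np.ndarray:
    return pd.read_csv(path, comment="#").to_numpy(dtype=float)


def read_study_config(path) -> dict:
    """Study configuration from YAML or JSON (by file extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)
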