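"""Reading and writing response samples and reports.

Responses travel as a two-column CSV (``subsample``, ``response``; UTF-8,
comma-separated, '.' decimal) with a JSON sidecar of the same stem echoing
the design parameters, seed and schema version, so a simulated data set is
fully reproducible from its files.  Paired double-response data keep
respondent order: row i of subsample 1 pairs with row i of subsample 2.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .designs import ResponseSample

SCHEMA_VERSION = 1

__all__ = ["write_sample", "read_sample", "sidecar_path"]


def sidecar_path(csv_path) -> Path:
    return Path(csv_path).with_suffix(".json")


def write_sample(sample: ResponseSample, csv_path) -> Path:
    """Write a response sample as CSV plus JSON sidecar; returns the sidecar
    path."""
    csv_path = Path(csv_path)
    df = pd.DataFrame({
        "subsample": np.concatenate([
            np.ones(sample.n1, dtype=int), np.full(sample.n2, 2, dtype=int)
        ]),
        "response": np.concatenate([sample.responses1, sample.responses2]),
    })
    # %.17g guarantees a bit-exact float64 round trip through text
    df.to_csv(csv_path, index=False, float_format="%.17g")
    side = {
        "schema_version": SCHEMA_VERSION,
        "design_kind": sample.design_kind,
        "paired": sample.paired,
        "seed": sample.seed,
        "meta": {k: (v if not isinstance(v, np.generic) else v.item())
                 for k, v in sample.meta.items()},
        "n1": sample.n1,
        "n2": sample.n2,
    }
    sp = sidecar_path(csv_path)
    sp.write_text(json.dumps(side, indent=2))
    return sp


def read_sample(csv_path) -> ResponseSample:
    """Read a response sample written by :func:`write_sample` (or any CSV
    with ``subsample`` and ``response`` columns)."""
    csv_path = Path(csv_path)
    try:
        df = pd.read_csv(csv_path, float_precision="round_trip")
    except Exception as exc:  # surface a diagnostic, not a stack trace
        raise ValueError(f"could not parse {csv_path}: {exc}") from exc
    missing = {"subsample", "response"} - set(df.columns)
    if missing:
        raise ValueError(f"{csv_path} lacks required column(s) {sorted(missing)}")
    labels = sorted(df["subsample"].unique())
    if not set(labels) <= {1, 2}:
        raise ValueError(f"subsample labels must be 1 and 2, got {labels}")
    r1 = df.loc[df["subsample"] == 1, "response"].to_numpy(float)
    r2 = df.loc[df["subsample"] == 2, "response"].to_numpy(float)
    kind, paired, seed, meta = "unknown", False, None, {}
    sp = sidecar_path(csv_path)
    if sp.exists():
        side = json.loads(sp.read_text())
        kind = side.get("design_kind", kind)
        paired = bool(side.get("paired", False))
        seed = side.get("seed")
        meta = side.get("meta", {})
    return ResponseSample(r1, r2, design_kind=kind, paired=paired, seed=seed, meta=meta)
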