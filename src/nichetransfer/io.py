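"""Reading and writing the pipeline's file formats.

Multi-band grids travel as TIFF (via tifffile) with layer names, period,
provenance, mask and any pass-through georeferencing metadata stored as a JSON
description tag; occurrences as CSV with header ``species,x,y,period,source``;
cleaning reports and summaries as JSON.  Grids are planar — affine/CRS
metadata supplied by the user is carried through untouched.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import EnvStack, OccurrenceSet, SuitabilityMap
from .errors import DataError

__all__ = [
    "write_env_stack",
    "read_env_stack",
    "write_suitability",
    "write_occurrences",
    "read_occurrences",
    "write_json",
]


def write_env_stack(env: EnvStack, path: "str | Path") -> None:
    meta = {
        "names": env.names,
        "period": env.period,
        "provenance": env.provenance,
        "origin": list(env.origin),
        "aligned_to": env.aligned_to,
        "crs_meta": env.crs_meta,
    }
    data = env.layers.astype("float32")
    tifffile.imwrite(
        path, data, description=json.dumps(meta),
        photometric="minisblack", planarconfig="separate",
    )


def read_env_stack(path: "str | Path") -> EnvStack:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray().astype(float)
        desc = tf.pages[0].description
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError) as exc:
        raise DataError(f"{path} carries no readable stack metadata") from exc
    if data.ndim == 2:
        data = data[None]
    mask = np.all(np.isfinite(data), axis=0)
    data = data.copy()
    data[:, ~mask] = np.nan
    return EnvStack(
        layers=data,
        names=list(meta["names"]),
        mask=mask,
        period=meta.get("period", "unknown"),
        provenance=meta.get("provenance", "raw"),
        origin=tuple(meta.get("origin", (0, 0))),
        aligned_to=meta.get("aligned_to"),
        crs_meta=meta.get("crs_meta", {}),
    )


def write_monthly_climate(mc, path: "str | Path") -> None:
    """Write the 36 monthly bands (tmin/tmax/prec x 12) as one TIFF stack."""
    names = [f"{v}{m + 1:02d}" for v in ("tmin", "tmax", "prec") for m in range(12)]
    data = np.concatenate([mc.tmin, mc.tmax, mc.prec]).astype("float32")
    meta = {"names": names, "period": mc.period, "kind": "monthly_climate"}
    tifffile.imwrite(
        path, data, description=json.dumps(meta),
        photometric="minisblack", planarconfig="separate",
    )


def write_suitability(map_: SuitabilityMap, path: "str | Path") -> None:
    meta = {"source": map_.source, "origin": list(map_.origin)}
    tifffile.imwrite(
        path, map_.values.astype("float32"), description=json.dumps(meta),
        photometric="minisblack",
    )


def write_occurrences(occ: OccurrenceSet, path: "str | Path") -> None:
    occ.records.to_csv(path, index=False)


def read_occurrences(path: "str | Path") -> OccurrenceSet:
    return OccurrenceSet(pd.read_csv(path))


def write_json(obj: dict, path: "str | Path") -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer, np.bool_)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))
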