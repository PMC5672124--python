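"""Plain-text containers: sessions, feature matrices, models, configs.

A session on disk is three sibling files sharing a prefix:
``<prefix>_signals.csv`` (columns left,right), ``<prefix>_events.csv``
(stimulus_time_s,response_time_s,label) and ``<prefix>_meta.txt``
(key=value lines, at minimum ``fs``).  Feature matrices are one row per
trial with named feature columns plus trial_id, label and a provenance
column (original|bootstrap); the band map travels as a JSON sidecar.
Floats are written with 17 significant digits and parsed with round-trip
precision, so write→read reproduces every value bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bandfeat import BANDS, FeatureVector, N_FEATURES, feature_names, realized_edges
from .ensemble import EnsembleModel
from .errors import FileFormatError
from .synthlfp import EventRecord, LfpSession

_FLOAT_FMT = "%.17g"  # shortest-exact is repr; 17 significant digits round-trips


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------


def write_session(session: LfpSession, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    sig = pd.DataFrame({"left": session.left, "right": session.right})
    sig.to_csv(f"{prefix}_signals.csv", index=False, float_format=_FLOAT_FMT)
    rows = [
        {
            "stimulus_time_s": e.stimulus_time_s,
            "response_time_s": "" if e.response_time_s is None else repr(e.response_time_s),
            "label": e.label,
        }
        for e in session.events
    ]
    pd.DataFrame(rows).to_csv(f"{prefix}_events.csv", index=False, float_format=_FLOAT_FMT)
    with open(f"{prefix}_meta.txt", "w") as fh:
        fh.write(f"fs={session.fs!r}\n")


def read_session(prefix: str | Path) -> LfpSession:
    prefix = Path(prefix)
    meta = read_keyvalue(f"{prefix}_meta.txt")
    if "fs" not in meta:
        raise FileFormatError(f"{prefix}_meta.txt: missing required key 'fs'")
    sig = pd.read_csv(f"{prefix}_signals.csv", float_precision="round_trip")
    for col in ("left", "right"):
        if col not in sig.columns:
            raise FileFormatError(f"{prefix}_signals.csv: missing column {col!r}")
    ev = pd.read_csv(f"{prefix}_events.csv", float_precision="round_trip")
    events = []
    for i, row in ev.iterrows():
        resp = row["response_time_s"]
        resp = None if (pd.isna(resp) or resp == "") else float(resp)
        try:
            events.append(EventRecord(float(row["stimulus_time_s"]), resp, str(row["label"])))
        except Exception as e:
            raise FileFormatError(f"{prefix}_events.csv row {i}: {e}") from e
    return LfpSession(left=sig["left"].to_numpy(), right=sig["right"].to_numpy(),
                      fs=float(meta["fs"]), events=events)


def read_keyvalue(path: str | Path) -> dict:
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FileFormatError(f"{path}:{lineno}: expected key=value, got {line!r}")
            k, v = line.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def write_keyvalue(d: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, v in d.items():
            fh.write(f"{k}={v}\n")


# ---------------------------------------------------------------------------
# feature matrices
# ---------------------------------------------------------------------------


def write_features(features: list[FeatureVector], path: str | Path,
                   provenance=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if provenance is None:
        provenance = ["original"] * len(features)
    if len(provenance) != len(features):
        raise FileFormatError("provenance length must match features")
    names = feature_names()
    rows = []
    for fv, prov in zip(features, provenance):
        row = {"trial_id": fv.trial_id, "label": fv.label, "provenance": prov}
        row.update(dict(zip(names, fv.values)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
    write_band_map(path.with_suffix(".bands.json"))


def read_features(path: str | Path):
    """Returns (features, provenance) parsed from a feature CSV."""
    names = feature_names()
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as e:
        raise FileFormatError(f"{path}: cannot parse CSV: {e}") from e
    missing = [c for c in ("trial_id", "label", *names) if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing columns {missing[:3]}...")
    feats, prov = [], []
    for i, row in df.iterrows():
        vals = row[names].to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            raise FileFormatError(f"{path} row {i}: non-finite or missing feature value")
        feats.append(FeatureVector(values=vals, label=str(row["label"]),
                                   trial_id=int(row["trial_id"])))
        prov.append(str(row.get("provenance", "original")))
    return feats, prov


def write_band_map(path: str | Path) -> None:
    bands = [
        {
            "name": b.name,
            "nominal_hz": [b.f_lo, b.f_hi],
            "realized_hz": list(realized_edges(b)),
            "wpt_nodes": list(b.wpt_nodes),
        }
        for b in BANDS
    ]
    with open(path, "w") as fh:
        json.dump({"n_features": N_FEATURES, "bands": bands}, fh, indent=1)


def features_to_arrays(features: list[FeatureVector]):
    X = np.vstack([fv.values for fv in features])
    y = np.array([fv.label for fv in features])
    ids = np.array([fv.trial_id for fv in features])
    return X, y, ids


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


def write_model(model: EnsembleModel, path: str | Path, *, meta: dict | None = None) -> None:
    doc = model.to_dict()
    doc["meta"] = meta or {}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_model(path: str | Path) -> EnsembleModel:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as e:
        raise FileFormatError(f"{path}: invalid JSON at line {e.lineno}") from e
    if "stage1" not in doc or "stage2" not in doc:
        raise FileFormatError(f"{path}: model JSON must contain stage1 and stage2")
    return EnsembleModel.from_dict(doc)
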