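"""Readers, writers, configuration and run manifests.

Formats: expression matrices as TSV (rows = genes, columns labelled CT/ZT plus
hours), activity as CSV (minute, count), gene sets as GMT, image stacks as
multi-page TIFF, masks as TIFF/PNG, configuration as YAML, summaries and run
manifests as JSON.  All text output uses '.' decimals, UTF-8 and Unix
newlines so outputs are bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .rhythmdet import ActivityRecord, ExpressionMatrix
from .synthio import GeneSetCollection, ImageStack

__all__ = [
    "read_expression_tsv", "write_expression_tsv",
    "read_activity_csv", "write_activity_csv",
    "read_gmt", "write_gmt",
    "read_stack_tiff", "write_stack_tiff", "read_mask",
    "load_config", "save_config",
    "write_results",
]

_TIME_LABEL = re.compile(r"^(CT|ZT)(\d+(?:\.\d+)?)$", re.IGNORECASE)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _parse_time_label(label: str) -> float:
    m = _TIME_LABEL.match(label.strip())
    if not m:
        raise ValueError(f"unparseable time label {label!r} (expected CT<h> or ZT<h>)")
    return float(m.group(2))


def read_expression_tsv(path, filter_background: bool = False) -> ExpressionMatrix:
    """Read a gene x time-point TPM TSV with CT/ZT-labelled columns.

    With ``filter_background=True`` only genes with mean TPM >= 1 are kept
    (the filtered-background convention of the detection and enrichment
    stages).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate gene ids: {dups[:5]}")
    times = np.array([_parse_time_label(c) for c in df.columns])
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("non-numeric or missing cells in expression matrix")
    matrix = ExpressionMatrix(list(df.index.astype(str)), times, values)
    return matrix.filtered_background() if filter_background else matrix


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# activity records
# ---------------------------------------------------------------------------

def read_activity_csv(path) -> ActivityRecord:
    df = pd.read_csv(path)
    if not {"minute", "count"} <= set(df.columns):
        raise ValueError("activity CSV needs 'minute' and 'count' columns")
    return ActivityRecord(counts=df["count"].to_numpy(dtype=float), bin_minutes=1.0)


def write_activity_csv(record: ActivityRecord, path) -> None:
    pd.DataFrame({"minute": np.arange(record.counts.size),
                  "count": record.counts.astype(int)}
                 ).to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """GMT: one term per line — term id, description, then member genes."""
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line {ln}: needs term, description "
                             "and at least one member")
        term, desc, members = parts[0], parts[1], [g for g in parts[2:] if g]
        if not members:
            raise ValueError(f"GMT line {ln}: empty member list")
        sets[term] = set(members)
        names[term] = desc
    return GeneSetCollection(sets=sets, names=names)


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = []
    for term in sorted(collection.sets):
        members = sorted(collection.sets[term])
        lines.append("\t".join([term, collection.names.get(term, term), *members]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# image stacks and masks
# ---------------------------------------------------------------------------

def read_stack_tiff(path, frame_interval_h: float = 1.0) -> ImageStack:
    frames = tifffile.imread(path).astype(float)
    return ImageStack(frames=frames, frame_interval_h=frame_interval_h)


def write_stack_tiff(stack: ImageStack, path) -> None:
    data = np.clip(np.round(stack.frames), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(path, data.astype(np.uint16))


def read_mask(path) -> np.ndarray:
    if str(path).lower().endswith((".tif", ".tiff")):
        img = tifffile.imread(path)
    else:
        from PIL import Image  # PNG masks
        img = np.asarray(Image.open(path).convert("L"))
    return np.asarray(img) > 0


# ---------------------------------------------------------------------------
# config and manifests
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    if "seed" not in cfg:
        raise ValueError("config must declare a seed")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(tables: dict[str, pd.DataFrame], out_dir,
                  config: dict | None = None,
                  inputs: list[str] | None = None) -> Path:
    """Write result tables plus a JSON run manifest; returns the manifest path.

    Table names ending in .tsv/.csv pick the separator; everything else is
    written as TSV.  The manifest records the config snapshot, input-file
    checksums and per-table row counts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in tables.items():
        fname = name if name.endswith((".tsv", ".csv", ".json")) else name + ".tsv"
        path = out / fname
        if fname.endswith(".json"):
            path.write_text(json.dumps(df, indent=2, default=_jsonable) + "\n")
            written[fname] = {"rows": None, "sha256": _sha256(path)}
        else:
            sep = "," if fname.endswith(".csv") else "\t"
            df.to_csv(path, sep=sep, index=False, lineterminator="\n")
            written[fname] = {"rows": int(len(df)), "sha256": _sha256(path)}
    manifest = {
        "artifact": "circaflow",
        "config": config or {},
        "inputs": {str(p): _sha256(Path(p)) for p in (inputs or [])},
        "outputs": written,
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return mpath


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
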