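"""Reading and writing the package's plain-text formats.

Phenotype tables are long-format CSV/TSV with header columns
``env, block, line, rep, count``; marker tables have the line label in the
first column and one 0/1/NA column per marker.  Chain exports are one CSV
row per retained draw plus a JSON run manifest (seed, iteration counts,
priors, package version) sufficient to reproduce a run bit-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .design import CountPanel, MarkerMatrix
from .model import PosteriorChains

__all__ = [
    "auto_fix_r",
    "load_panel",
    "load_markers",
    "write_panel",
    "write_chains",
    "read_chains_frame",
    "write_report",
    "write_manifest",
]


def auto_fix_r(mean_count_estimate: float) -> float:
    """Dispersion to fix for the Poisson model, chosen from the mean count.

    The NB with large r approximates the Poisson well when mean ≈ variance;
    r = 1000 suffices below a mean of 50, r = 5000 up to 200, and r = 10000
    beyond.  Boundary values go to the larger (safer) r.
    """
    m = float(mean_count_estimate)
    if not np.isfinite(m) or m < 0:
        raise ValueError("mean count estimate must be a finite non-negative number")
    if m < 50:
        return 1000.0
    if m < 200:
        return 5000.0
    return 10000.0


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path} is empty") from None
    if len(df) == 0:
        raise ValueError(f"{path} has a header but no rows")
    return df


def load_panel(path, line_levels=None) -> CountPanel:
    """Load and validate a phenotype CSV/TSV (env, block, line, rep, count)."""
    df = _read_table(path)
    try:
        return CountPanel.from_frame(df, line_levels=line_levels)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_panel(panel: CountPanel, path) -> None:
    panel.frame.to_csv(path, index=False)


def load_markers(path) -> MarkerMatrix:
    """Load a marker CSV/TSV: first column line labels, then 0/1/NA markers.

    Missing calls are tolerated here and must be removed via
    :func:`bmnb.design.maf_filter` before building a GRM.
    """
    df = _read_table(path)
    lines = df.iloc[:, 0].astype(str).tolist()
    if len(set(lines)) != len(lines):
        raise ValueError(f"{path}: duplicate line labels in first column")
    W = df.iloc[:, 1:].to_numpy(dtype=float)
    if W.shape[1] < 1:
        raise ValueError(f"{path}: no marker columns found")
    finite = W[np.isfinite(W)]
    if not np.isin(finite, (0.0, 1.0)).all():
        bad_col = int(
            np.flatnonzero(~np.isin(np.where(np.isfinite(W), W, 0.0), (0.0, 1.0)).all(axis=0))[0]
        )
        raise ValueError(
            f"{path}: non 0/1/NA marker code in column {df.columns[1 + bad_col]!r}"
        )
    markers = df.columns[1:].tolist()
    if np.isfinite(W).all():
        return MarkerMatrix(W=W.astype(np.int64), lines=lines, markers=markers)
    # defer binariness enforcement: carry NaNs for maf_filter via a raw array
    mm = MarkerMatrix.__new__(MarkerMatrix)
    mm.W = W
    mm.lines = lines
    mm.markers = markers
    return mm


def write_chains(chains: PosteriorChains, path_prefix) -> None:
    """Write chains to ``<prefix>.csv`` and metadata to ``<prefix>.meta.json``."""
    prefix = Path(path_prefix)
    chains.to_frame().to_csv(prefix.with_suffix(".csv"), index=False)
    meta = dict(chains.meta)
    meta.update(iterations=chains.iterations, burn_in=chains.burn_in)
    with open(prefix.with_suffix(".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2, default=_jsonable)


def read_chains_frame(path_prefix) -> pd.DataFrame:
    return pd.read_csv(Path(path_prefix).with_suffix(".csv"))


def write_report(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_manifest(path, **entries) -> None:
    """Write a reproducibility manifest (config, seed, package version)."""
    payload = {"bmnb_version": __version__}
    payload.update(entries)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)
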