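"""Shared plumbing: spectra tables, structured configs, run manifests.

All tabular interfaces are delimited text keyed by ``wavelength_nm``;
spectra read from other grids are linearly interpolated onto the 1-nm
working grid and rows outside 400-2500 nm are dropped (and counted).
Every CLI run writes a JSON manifest (config hash, seed, package version)
sufficient to reproduce deterministic stages bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from ._grid import WAVELENGTHS, WL_MAX, WL_MIN

log = logging.getLogger("lianaspec")

__all__ = ["read_spectra", "write_spectra", "load_config", "write_manifest", "SpectraTable"]


@dataclass
class SpectraTable:
    """Spectra interpolated to the working grid, with read metadata."""

    wavelengths: np.ndarray
    values: np.ndarray  # (n_spectra, n_wl) or (n_wl,)
    columns: list
    source_grid: np.ndarray
    n_dropped: int


def read_spectra(path, step: int = 1) -> SpectraTable:
    """Read a delimited spectra table (wavelength_nm + value columns).

    Values are interpolated to the 1-nm grid (optionally subsampled by
    ``step``); rows outside [400, 2500] nm are dropped with a logged count.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if "wavelength_nm" not in df.columns:
        raise ValueError("spectra table needs a 'wavelength_nm' column")
    wl_src = df["wavelength_nm"].to_numpy(float)
    if np.any(np.diff(wl_src) <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    keep = (wl_src >= WL_MIN) & (wl_src <= WL_MAX)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("read_spectra: dropped %d rows outside [%d, %d] nm",
                 n_dropped, WL_MIN, WL_MAX)
    df = df.loc[keep]
    wl_src = wl_src[keep]
    if wl_src.size < 2:
        raise ValueError("fewer than 2 in-range wavelengths")
    grid = WAVELENGTHS[::step]
    grid = grid[(grid >= wl_src[0]) & (grid <= wl_src[-1])]
    cols = [c for c in df.columns if c != "wavelength_nm"]
    vals = np.vstack([np.interp(grid, wl_src, df[c].to_numpy(float)) for c in cols])
    return SpectraTable(
        wavelengths=grid,
        values=vals if len(cols) > 1 else vals[0],
        columns=cols,
        source_grid=wl_src,
        n_dropped=n_dropped,
    )


def write_spectra(path, wavelengths, columns: dict) -> None:
    """Write spectra as tab-delimited text: wavelength_nm plus named columns."""
    df = pd.DataFrame({"wavelength_nm": np.asarray(wavelengths, float)})
    for name, vals in columns.items():
        df[name] = np.asarray(vals, float)
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# Config handling
# ---------------------------------------------------------------------------

_KNOWN_BLOCKS = {"leaf", "canopy", "geometry", "soil", "priors", "sampler",
                 "scene", "sensitivity", "synth", "output"}


def load_config(path, strict: bool = True) -> dict:
    """Load and validate a structured YAML run configuration.

    Collects *all* violations before raising, so a bad config reports every
    problem at once.  Unknown top-level blocks are rejected in strict mode.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config root must be a mapping")
    errors = []
    if strict:
        for key in cfg:
            if key not in _KNOWN_BLOCKS:
                errors.append(f"unknown config block {key!r}")
    from .canopy import CANOPY_BOUNDS
    from .leaf import LEAF_BOUNDS

    bounds = {"leaf": LEAF_BOUNDS, "canopy": CANOPY_BOUNDS}
    for block, bnds in bounds.items():
        for key, val in (cfg.get(block) or {}).items():
            if key in bnds and isinstance(val, (int, float)):
                lo, hi = bnds[key]
                if not (lo <= val <= hi):
                    errors.append(
                        f"{block}.{key} = {val} violates bound [{lo}, {hi}]"
                    )
    geom = cfg.get("geometry") or {}
    for key, (lo, hi) in (("theta_s", (0, 90)), ("theta_o", (0, 90)), ("psi", (0, 360))):
        if key in geom and not (lo <= geom[key] < hi):
            errors.append(f"geometry.{key} = {geom[key]} violates bound [{lo}, {hi})")
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(path, cfg: dict, seed: int | None, outputs=()) -> dict:
    """Write the reproducibility manifest for a CLI run."""
    from . import __version__

    manifest = {
        "package": "lianaspec",
        "version": __version__,
        "config_hash": config_hash(cfg),
        "seed": seed,
        "outputs": list(map(str, outputs)),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
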