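"""Multi-frame XYZ serialization and run manifests.

Ensembles are stored as plain multi-frame XYZ (atom-count line, comment
line, then one ``C x y z`` line per bead) with coordinates printed to 9
decimals, so write -> read is the identity at the printed precision.  Run
manifests are JSON files holding everything needed to reproduce an output
bitwise (command, parameters, seeds, sampling metadata, package version).
"""

from __future__ import annotations

import json
import warnings
from datetime import datetime, timezone
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from .errors import MalformedFrameError

__all__ = ["read_xyz", "write_xyz", "write_ensemble_xyz",
           "write_manifest", "read_manifest"]

XYZ_PRECISION = 9


def write_xyz(path, frames, comments: Optional[List[str]] = None,
              precision: int = XYZ_PRECISION) -> None:
    """Write conformations as multi-frame XYZ (atom symbol "C" per bead)."""
    frames = [np.asarray(f, dtype=float) for f in frames]
    if comments is None:
        comments = [f"frame {i}" for i in range(len(frames))]
    fmt = f"C {{:.{precision}f}} {{:.{precision}f}} {{:.{precision}f}}\n"
    with open(path, "w") as fh:
        for frame, comment in zip(frames, comments):
            fh.write(f"{frame.shape[0]}\n")
            fh.write(f"{comment}\n")
            for x, y, z in frame:
                fh.write(fmt.format(x, y, z))


def write_ensemble_xyz(path, ensemble, precision: int = XYZ_PRECISION) -> None:
    """Write an Ensemble with per-frame Rg (and knot label if annotated)."""
    comments = []
    for i in range(ensemble.n):
        c = f"frame {i} rg {ensemble.rg[i]:.6f}"
        if ensemble.knot_labels is not None:
            c += f" knot {ensemble.knot_labels[i]}"
        comments.append(c)
    write_xyz(path, ensemble.coords, comments, precision)


def read_xyz(path) -> Tuple[List[np.ndarray], List[str]]:
    """Read a multi-frame XYZ file; returns (frames, comment lines).

    Raises MalformedFrameError (naming the frame) on a bad atom-count line,
    a truncated frame, or an unparseable coordinate line.  An empty file
    yields an empty list with a warning.
    """
    text = Path(path).read_text().splitlines()
    frames: List[np.ndarray] = []
    comments: List[str] = []
    i = 0
    n_lines = len(text)
    while i < n_lines and text[i].strip() == "" and not frames:
        i += 1
    if i >= n_lines:
        warnings.warn(f"{path}: empty XYZ file", stacklevel=2)
        return frames, comments
    frame_idx = 0
    while i < n_lines:
        if text[i].strip() == "":
            i += 1
            continue
        try:
            n_atoms = int(text[i].strip())
        except ValueError:
            raise MalformedFrameError(frame_idx,
                                      f"bad atom-count line {text[i]!r}")
        if n_atoms <= 0:
            raise MalformedFrameError(frame_idx, "non-positive atom count")
        if i + 2 + n_atoms > n_lines:
            raise MalformedFrameError(frame_idx, "truncated frame")
        comment = text[i + 1]
        coords = np.empty((n_atoms, 3))
        for a in range(n_atoms):
            parts = text[i + 2 + a].split()
            if len(parts) < 4:
                raise MalformedFrameError(frame_idx,
                                          f"bad coordinate line {a}")
            try:
                coords[a] = [float(parts[1]), float(parts[2]),
                             float(parts[3])]
            except ValueError:
                raise MalformedFrameError(frame_idx,
                                          f"bad coordinate line {a}")
        frames.append(coords)
        comments.append(comment)
        i += 2 + n_atoms
        frame_idx += 1
    return frames, comments


def write_manifest(path, command: str, parameters: dict,
                   seed, extra: Optional[dict] = None) -> dict:
    """Write a JSON run manifest; returns the manifest dict."""
    from . import __version__
    manifest = {
        "command": command,
        "parameters": parameters,
        "seed": seed,
        "code_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return manifest


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
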