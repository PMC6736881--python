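"""Landmark and mesh file I/O.

Landmarks travel either as per-specimen CSV (columns ``id,x,y,z,missing``,
coordinates in mm) or in the classic TPS file dialect (``LM3=k`` blocks with
one ``x y z`` line per landmark and an ``ID=`` line per specimen; missing
landmarks encoded as ``9999 9999 9999``).  Meshes go through trimesh
(PLY/OBJ).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import LandmarkConfiguration

MISSING_SENTINEL = 9999.0


def write_landmarks_csv(config: LandmarkConfiguration, path) -> None:
    coords = config.coords.copy()
    coords[config.missing] = np.nan
    df = pd.DataFrame({
        "id": np.arange(config.n_landmarks),
        "x": coords[:, 0],
        "y": coords[:, 1],
        "z": coords[:, 2],
        "missing": config.missing.astype(int),
    })
    df.to_csv(path, index=False)


def read_landmarks_csv(path, specimen_id: str | None = None, group: str | None = None) -> LandmarkConfiguration:
    df = pd.read_csv(path)
    required = {"x", "y", "z"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: landmark CSV needs columns x,y,z")
    if "id" in df.columns:
        df = df.sort_values("id")
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    if "missing" in df.columns:
        missing = df["missing"].to_numpy().astype(bool)
    else:
        missing = ~np.isfinite(coords).all(axis=1)
    missing |= ~np.isfinite(coords).all(axis=1)
    coords[missing] = np.nan
    if specimen_id is None:
        specimen_id = Path(path).stem
    return LandmarkConfiguration(specimen_id, coords, missing, group=group)


def write_tps(configs: list[LandmarkConfiguration], path) -> None:
    """Write configurations as a classic TPS file with LM3= blocks."""
    with open(path, "w") as fh:
        for c in configs:
            fh.write(f"LM3={c.n_landmarks}\n")
            for i in range(c.n_landmarks):
                if c.missing[i]:
                    fh.write(f"{MISSING_SENTINEL:g} {MISSING_SENTINEL:g} {MISSING_SENTINEL:g}\n")
                else:
                    x, y, z = c.coords[i]
                    fh.write(f"{x:.10g} {y:.10g} {z:.10g}\n")
            fh.write(f"ID={c.specimen_id}\n")


def read_tps(path) -> list[LandmarkConfiguration]:
    """Read a TPS file with 3D (LM3=) blocks; 9999-triplets become missing."""
    configs: list[LandmarkConfiguration] = []
    coords: list[list[float]] = []
    expected = 0
    specimen_id = None

    def flush():
        nonlocal coords, specimen_id, expected
        if expected == 0:
            return
        if len(coords) != expected:
            raise ValueError(
                f"{path}: block for {specimen_id!r} has {len(coords)} landmarks, expected {expected}"
            )
        arr = np.array(coords, dtype=float)
        missing = np.all(arr == MISSING_SENTINEL, axis=1)
        arr[missing] = np.nan
        sid = specimen_id if specimen_id is not None else f"specimen_{len(configs)}"
        configs.append(LandmarkConfiguration(sid, arr, missing))
        coords, specimen_id, expected = [], None, 0

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3="):
                flush()
                expected = int(line.split("=", 1)[1])
            elif upper.startswith("ID="):
                specimen_id = line.split("=", 1)[1].strip()
                flush()
            elif upper.startswith(("LM=", "IMAGE=", "SCALE=")):
                if upper.startswith("LM="):
                    raise ValueError(f"{path}: 2D (LM=) blocks unsupported; use LM3=")
            else:
                coords.append([float(v) for v in line.split()])
    flush()
    return configs


def load_mesh(path):
    import trimesh

    mesh = trimesh.load(path, force="mesh", process=False)
    return mesh


def save_mesh(mesh, path) -> None:
    path = Path(path)
    kwargs = {"encoding": "ascii"} if path.suffix.lower() == ".ply" else {}
    mesh.export(path, **kwargs)
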