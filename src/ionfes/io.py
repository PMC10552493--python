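"""Plain-text file formats shared by all stages.

* multi-frame XYZ trajectories (element column = particle role tag),
* COLVAR-style whitespace tables with a ``#! FIELDS ...`` header,
* a window manifest (CSV: one row per umbrella window with its bias center,
  spring constant and series path),
* YAML run configurations.

All writers store full double precision so write-then-read round-trips are
exact; all readers raise :class:`FileFormatError` with a line number on
malformed input.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cvs import CVSeries

ROLE_TAGS = {"ion": "ION", "ligand_oxygen": "OL", "backbone": "BB",
             "solvent_oxygen": "OW"}
TAG_ROLES = {v: k for k, v in ROLE_TAGS.items()}


class FileFormatError(ValueError):
    """Malformed input file; the message carries the offending line number."""


# ---------------------------------------------------------------------------
# XYZ trajectories


def write_xyz(path, frames: np.ndarray, roles: list[str], comment: str = "") -> None:
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    tags = [ROLE_TAGS.get(r, r) for r in roles]
    with open(path, "w") as fh:
        for t, frame in enumerate(frames):
            fh.write(f"{len(roles)}\n")
            fh.write(f"frame {t} {comment}".rstrip() + "\n")
            for tag, (x, y, z) in zip(tags, frame):
                fh.write(f"{tag} {x:.17g} {y:.17g} {z:.17g}\n")


def read_xyz(path) -> tuple[np.ndarray, list[str]]:
    """Read a multi-frame XYZ trajectory -> ((T, N, 3) array, roles)."""
    frames = []
    roles: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise FileFormatError(f"{path}:{i + 1}: expected an atom count")
        if i + 1 + n >= len(lines) + 1:
            raise FileFormatError(f"{path}:{i + 1}: truncated frame (need {n} atoms)")
        frame = np.empty((n, 3))
        frame_roles = []
        for a in range(n):
            parts = lines[i + 2 + a].split()
            if len(parts) < 4:
                raise FileFormatError(f"{path}:{i + 3 + a}: expected 'tag x y z'")
            frame_roles.append(TAG_ROLES.get(parts[0], parts[0]))
            try:
                frame[a] = [float(p) for p in parts[1:4]]
            except ValueError:
                raise FileFormatError(f"{path}:{i + 3 + a}: non-numeric coordinate")
        if not roles:
            roles = frame_roles
        elif frame_roles != roles or len(frame_roles) != len(roles):
            raise FileFormatError(
                f"{path}:{i + 1}: inconsistent atom count or roles across frames")
        frames.append(frame)
        i += 2 + n
    if not frames:
        raise FileFormatError(f"{path}:1: no frames found")
    return np.stack(frames), roles


# ---------------------------------------------------------------------------
# COLVAR tables


def write_colvar(path, series: CVSeries) -> None:
    cols = ["time", series.label]
    data = [series.time, series.primary]
    if series.secondary is not None:
        cols.append(series.secondary_label)
        data.append(series.secondary)
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(cols) + "\n")
        if series.center is not None:
            fh.write(f"#! SET bias_center {series.center:.17g}\n")
            fh.write(f"#! SET bias_k {series.k:.17g}\n")
        for row in zip(*data):
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_colvar(path) -> CVSeries:
    """Read a COLVAR table; bias metadata comes from '#! SET' lines if present."""
    with open(path) as fh:
        lines = fh.readlines()
    if not lines or not lines[0].startswith("#! FIELDS"):
        raise FileFormatError(
            f"{path}:1: expected a '#! FIELDS time <cv> [...]' header line")
    fields = lines[0].split()[2:]
    if len(fields) < 2 or fields[0] != "time":
        raise FileFormatError(f"{path}:1: FIELDS must start with 'time' plus >=1 CV")
    center = k = None
    rows = []
    for ln, line in enumerate(lines[1:], start=2):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#! SET"):
            parts = line.split()
            if len(parts) >= 4 and parts[2] == "bias_center":
                center = float(parts[3])
            elif len(parts) >= 4 and parts[2] == "bias_k":
                k = float(parts[3])
            continue
        if line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != len(fields):
            raise FileFormatError(
                f"{path}:{ln}: expected {len(fields)} columns, got {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError:
            raise FileFormatError(f"{path}:{ln}: non-numeric value")
    arr = np.array(rows, dtype=float).reshape(-1, len(fields))
    secondary = arr[:, 2] if len(fields) >= 3 else None
    sec_label = fields[2] if len(fields) >= 3 else "cv_water"
    return CVSeries(arr[:, 0], arr[:, 1], secondary, center, k,
                    label=fields[1], secondary_label=sec_label)


# ---------------------------------------------------------------------------
# window manifest


def write_manifest(path, windows, colvar_paths) -> None:
    df = pd.DataFrame({"center": [w.center for w in windows],
                       "k": [w.k for w in windows],
                       "series": [str(p) for p in colvar_paths]})
    df.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    """Read the window manifest, checking every series file exists before
    any computation starts."""
    df = pd.read_csv(path)
    for col in ("center", "k", "series"):
        if col not in df.columns:
            raise FileFormatError(f"{path}: manifest is missing column {col!r}")
    base = Path(path).parent
    missing = [s for s in df["series"]
               if not (Path(s).is_absolute() and Path(s).exists()
                       or (base / s).exists())]
    if missing:
        raise FileNotFoundError(f"manifest {path} references absent series "
                                f"files: {missing}")
    return df


def load_series_from_manifest(path) -> list[CVSeries]:
    df = read_manifest(path)
    base = Path(path).parent
    out = []
    for _, row in df.iterrows():
        p = Path(row["series"])
        if not p.is_absolute():
            p = base / p
        s = read_colvar(p)
        s.center = float(row["center"])
        s.k = float(row["k"])
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# run configuration


REQUIRED_CONFIG_KEYS = {"system", "windows", "simulation", "estimator",
                        "seed", "output_dir"}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    if not isinstance(cfg, dict):
        raise FileFormatError("config must be a mapping")
    missing = REQUIRED_CONFIG_KEYS - cfg.keys()
    if missing:
        raise FileFormatError(f"config is missing sections: {sorted(missing)}")
    w = cfg["windows"]
    for key in ("start", "stop", "step", "k"):
        if key not in w:
            raise FileFormatError(f"config windows section needs {key!r}")
    if w["step"] <= 0 or w["stop"] < w["start"]:
        raise FileFormatError("config windows range is empty or inverted")
    sim = cfg["simulation"]
    for key in ("n_steps", "dt"):
        if key not in sim:
            raise FileFormatError(f"config simulation section needs {key!r}")


def save_config(cfg: dict, path) -> None:
    validate_config(cfg)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
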