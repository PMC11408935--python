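"""Annotated point clouds: container, PLY/CSV I/O, and 905-nm intensity calibration.

The cloud carries the channels every downstream stage relies on:

* ``xyz`` — coordinates in metres, right-handed, z vertical;
* ``intensity`` — apparent time-of-flight return strength (R_ToF), either raw
  sensor units or percent reflectance after :func:`calibrate_intensity`;
* ``temperature`` — surface temperature in °C, NaN where unannotated;
* ``label`` — structural class code (wood / leaf / fruit / unknown);
* ``fruit_id`` — per-point fruit membership, 0 for non-fruit points.

Missing temperature is always NaN (never 0 °C); missing whole channels are
``None`` and survive an I/O round trip as missing.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

# structural class codes used across the package
UNKNOWN = 0
WOOD = 1
LEAF = 2
FRUIT = 3

LABEL_NAMES = {UNKNOWN: "unknown", WOOD: "wood", LEAF: "leaf", FRUIT: "fruit"}
LABEL_CODES = {v: k for k, v in LABEL_NAMES.items()}

_CSV_COLUMNS = ["x", "y", "z", "intensity", "temperature", "label", "fruit_id"]


class CloudError(ValueError):
    """Raised on malformed cloud files or inconsistent channels."""


@dataclass
class PointCloud:
    """Point cloud with optional per-point annotation channels.

    All channels are either ``None`` (absent) or 1-D arrays of length
    ``len(cloud)``. Coordinates must be finite.
    """

    xyz: np.ndarray
    intensity: Optional[np.ndarray] = None
    temperature: Optional[np.ndarray] = None
    label: Optional[np.ndarray] = None
    fruit_id: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64).reshape(-1, 3)
        if self.xyz.size and not np.all(np.isfinite(self.xyz)):
            raise CloudError("coordinates must be finite")
        n = len(self.xyz)
        for name in ("intensity", "temperature"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=np.float64).ravel()
                if len(v) != n:
                    raise CloudError(f"channel {name!r} has length {len(v)}, expected {n}")
                setattr(self, name, v)
        for name in ("label", "fruit_id"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=np.int64).ravel()
                if len(v) != n:
                    raise CloudError(f"channel {name!r} has length {len(v)}, expected {n}")
                setattr(self, name, v)

    def __len__(self) -> int:
        return len(self.xyz)

    def select(self, index: np.ndarray) -> "PointCloud":
        """Sub-cloud at the given integer or boolean index, all channels."""
        pick = lambda v: None if v is None else v[index]
        return PointCloud(
            self.xyz[index],
            intensity=pick(self.intensity),
            temperature=pick(self.temperature),
            label=pick(self.label),
            fruit_id=pick(self.fruit_id),
        )

    def copy(self) -> "PointCloud":
        cp = lambda v: None if v is None else v.copy()
        return PointCloud(self.xyz.copy(), cp(self.intensity), cp(self.temperature),
                          cp(self.label), cp(self.fruit_id))


@dataclass(frozen=True)
class ReflectanceReferences:
    """White (100 %) and black (0 %) checkerboard reference intensities."""

    white_value: float
    black_value: float

    def __post_init__(self) -> None:
        if not self.white_value > self.black_value:
            raise ValueError(
                f"white reference ({self.white_value}) must exceed black ({self.black_value})"
            )


def calibrate_intensity(
    raw: np.ndarray, refs: ReflectanceReferences
) -> tuple[np.ndarray, int]:
    """Map raw return intensities to percent reflectance via the two references.

    Linear map sending ``black_value`` to 0 and ``white_value`` to 100; values
    falling outside are clipped to [0, 100] (downstream thresholds assume
    percent semantics). Returns ``(percent, n_clipped)``.
    """
    raw = np.asarray(raw, dtype=np.float64)
    span = refs.white_value - refs.black_value
    pct = (raw - refs.black_value) / span * 100.0
    n_clipped = int(np.count_nonzero((pct < 0.0) | (pct > 100.0)))
    return np.clip(pct, 0.0, 100.0), n_clipped


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _write_csv(cloud: PointCloud, path: Path) -> None:
    cols: dict[str, np.ndarray] = {
        "x": cloud.xyz[:, 0], "y": cloud.xyz[:, 1], "z": cloud.xyz[:, 2]
    }
    if cloud.intensity is not None:
        cols["intensity"] = cloud.intensity
    if cloud.temperature is not None:
        cols["temperature"] = cloud.temperature
    if cloud.label is not None:
        cols["label"] = cloud.label
    if cloud.fruit_id is not None:
        cols["fruit_id"] = cloud.fruit_id
    df = pd.DataFrame(cols)
    # repr-precision floats so the round trip is bit-stable; NaN -> empty field
    df.to_csv(path, index=False, float_format="%.17g")


def _read_csv(path: Path) -> PointCloud:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise CloudError(f"malformed CSV {path}: {exc}") from exc
    for c in ("x", "y", "z"):
        if c not in df.columns:
            raise CloudError(f"CSV {path} lacks required column {c!r}")
    unknown = set(df.columns) - set(_CSV_COLUMNS)
    if unknown:
        raise CloudError(f"CSV {path} has unrecognised columns {sorted(unknown)}")
    xyz = df[["x", "y", "z"]].to_numpy(dtype=np.float64)
    get = lambda c, dt: df[c].to_numpy(dtype=dt) if c in df.columns else None
    return PointCloud(
        xyz,
        intensity=get("intensity", np.float64),
        temperature=get("temperature", np.float64),
        label=None if "label" not in df.columns else df["label"].fillna(0).to_numpy(np.int64),
        fruit_id=None if "fruit_id" not in df.columns else df["fruit_id"].fillna(0).to_numpy(np.int64),
    )


# ---------------------------------------------------------------------------
# PLY dialect (ascii and binary_little_endian), fixed per-vertex properties
# ---------------------------------------------------------------------------

_PLY_FLOAT = {"float": ("<f4", "f"), "float32": ("<f4", "f"),
              "double": ("<f8", "d"), "float64": ("<f8", "d")}
_PLY_INT = {"char": ("<i1", "b"), "int8": ("<i1", "b"),
            "uchar": ("<u1", "B"), "uint8": ("<u1", "B"),
            "short": ("<i2", "h"), "int16": ("<i2", "h"),
            "ushort": ("<u2", "H"), "uint16": ("<u2", "H"),
            "int": ("<i4", "i"), "int32": ("<i4", "i"),
            "uint": ("<u4", "I"), "uint32": ("<u4", "I")}
_PLY_TYPES = {**_PLY_FLOAT, **_PLY_INT}


def _write_ply(cloud: PointCloud, path: Path, binary: bool = True) -> None:
    props: list[tuple[str, str, np.ndarray]] = [
        ("x", "double", cloud.xyz[:, 0]),
        ("y", "double", cloud.xyz[:, 1]),
        ("z", "double", cloud.xyz[:, 2]),
    ]
    if cloud.intensity is not None:
        props.append(("intensity", "double", cloud.intensity))
    if cloud.temperature is not None:
        props.append(("temperature", "double", cloud.temperature))
    if cloud.label is not None:
        props.append(("label", "uchar", cloud.label))
    if cloud.fruit_id is not None:
        props.append(("fruit_id", "int", cloud.fruit_id))

    fmt = "binary_little_endian" if binary else "ascii"
    header = ["ply", f"format {fmt} 1.0",
              f"element vertex {len(cloud)}"]
    header += [f"property {t} {n}" for n, t, _ in props]
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if not len(cloud):
            return
        arrays = [np.asarray(a, dtype=_PLY_TYPES[t][0]) for _, t, a in props]
        if binary:
            rec = np.rec.fromarrays(arrays, names=[n for n, _, _ in props])
            fh.write(rec.tobytes())
        else:
            out = []
            for row in zip(*arrays):
                out.append(" ".join(
                    format(float(v), ".17g") if np.issubdtype(type(v), np.floating)
                    else str(int(v)) for v in row))
            fh.write(("\n".join(out) + "\n").encode("ascii"))


def _read_ply(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise CloudError(f"{path}: not a PLY file (header line 1)")
        fmt = None
        n_vertex = None
        props: list[tuple[str, str]] = []
        lineno = 1
        while True:
            line = fh.readline()
            lineno += 1
            if not line:
                raise CloudError(f"{path}: truncated header at line {lineno}")
            tok = line.decode("ascii", "replace").split()
            if not tok or tok[0] == "comment":
                continue
            if tok[0] == "format":
                fmt = tok[1]
            elif tok[0] == "element":
                if tok[1] != "vertex":
                    raise CloudError(f"{path}: unsupported element {tok[1]!r} (line {lineno})")
                n_vertex = int(tok[2])
            elif tok[0] == "property":
                if tok[1] == "list":
                    raise CloudError(f"{path}: list properties unsupported (line {lineno})")
                if tok[1] not in _PLY_TYPES:
                    raise CloudError(f"{path}: unknown property type {tok[1]!r} (line {lineno})")
                props.append((tok[2], tok[1]))
            elif tok[0] == "end_header":
                break
            else:
                raise CloudError(f"{path}: unexpected header token {tok[0]!r} (line {lineno})")
        if fmt not in ("ascii", "binary_little_endian"):
            raise CloudError(f"{path}: unsupported format {fmt!r}")
        if n_vertex is None:
            raise CloudError(f"{path}: no vertex element declared")

        names = [n for n, _ in props]
        if fmt == "ascii":
            data = {n: [] for n in names}
            for i in range(n_vertex):
                row = fh.readline().split()
                if len(row) != len(props):
                    raise CloudError(
                        f"{path}: vertex row {i} has {len(row)} fields, expected {len(props)}")
                for (n, t), v in zip(props, row):
                    data[n].append(float(v) if t in _PLY_FLOAT else int(v))
            cols = {n: np.asarray(data[n],
                                  dtype=np.float64 if t in _PLY_FLOAT else np.int64)
                    for n, t in props}
        else:
            dtype = np.dtype([(n, _PLY_TYPES[t][0]) for n, t in props])
            buf = fh.read(dtype.itemsize * n_vertex)
            if len(buf) != dtype.itemsize * n_vertex:
                raise CloudError(f"{path}: binary body truncated")
            rec = np.frombuffer(buf, dtype=dtype)
            cols = {n: np.asarray(rec[n]) for n, _ in props}

    for c in ("x", "y", "z"):
        if c not in cols:
            raise CloudError(f"{path}: missing coordinate property {c!r}")
    if n_vertex == 0:
        cols = {n: np.empty(0) for n, _ in props} or {"x": np.empty(0), "y": np.empty(0), "z": np.empty(0)}
    xyz = np.column_stack([cols["x"], cols["y"], cols["z"]]).astype(np.float64)
    return PointCloud(
        xyz.reshape(-1, 3),
        intensity=cols.get("intensity"),
        temperature=cols.get("temperature"),
        label=None if "label" not in cols else cols["label"].astype(np.int64),
        fruit_id=None if "fruit_id" not in cols else cols["fruit_id"].astype(np.int64),
    )


def write_cloud(cloud: PointCloud, path, dialect: str | None = None, *,
                binary: bool = True) -> None:
    """Write a cloud as PLY (``.ply``) or headed CSV (``.csv``/``.xyz``)."""
    path = Path(path)
    dialect = dialect or ("ply" if path.suffix.lower() == ".ply" else "csv")
    if dialect == "ply":
        _write_ply(cloud, path, binary=binary)
    elif dialect == "csv":
        _write_csv(cloud, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'ply' or 'csv')")


def read_cloud(path, dialect: str | None = None) -> PointCloud:
    """Read a PLY or CSV cloud written by :func:`write_cloud` (or compatible)."""
    path = Path(path)
    dialect = dialect or ("ply" if path.suffix.lower() == ".ply" else "csv")
    if dialect == "ply":
        return _read_ply(path)
    if dialect == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'ply' or 'csv')")
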