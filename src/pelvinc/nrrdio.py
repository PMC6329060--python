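"""Minimal NRRD reader/writer for 3D scalar volumes.

Covers the subset this package emits: raw little-endian encoding, 3D,
``space directions`` + ``space origin`` in left-posterior-superior space.
Implemented here because no NRRD library is available in the target
environment; the format is a plain-text header followed by raw data.
"""

from __future__ import annotations

import numpy as np

from .volume_io import CTVolume

_TYPE_TO_DTYPE = {
    "signed char": np.int8, "int8": np.int8,
    "uchar": np.uint8, "unsigned char": np.uint8, "uint8": np.uint8,
    "short": np.int16, "int16": np.int16,
    "ushort": np.uint16, "uint16": np.uint16,
    "int": np.int32, "int32": np.int32,
    "uint": np.uint32, "uint32": np.uint32,
    "float": np.float32, "double": np.float64,
}
_DTYPE_TO_TYPE = {
    np.dtype(np.int8): "int8", np.dtype(np.uint8): "uint8",
    np.dtype(np.int16): "int16", np.dtype(np.uint16): "uint16",
    np.dtype(np.int32): "int32", np.dtype(np.uint32): "uint32",
    np.dtype(np.float32): "float", np.dtype(np.float64): "double",
}


def _parse_vector(text: str) -> np.ndarray:
    return np.array([float(x) for x in text.strip().lstrip("(").rstrip(")").split(",")])


def read_nrrd(path: str) -> CTVolume:
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise ValueError(f"{path} is not a NRRD file")
        fields: dict[str, str] = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("ascii").strip()
            if text.startswith("#") or ":" not in text:
                continue
            key, _, value = text.partition(":")
            fields[key.strip().lower()] = value.lstrip("=").strip()
        raw = fh.read()

    if int(fields.get("dimension", "0")) != 3:
        raise ValueError(f"expected a 3D NRRD, got dimension {fields.get('dimension')}")
    if fields.get("encoding", "raw") != "raw":
        raise ValueError(f"unsupported NRRD encoding {fields.get('encoding')!r}")
    dtype = np.dtype(_TYPE_TO_DTYPE[fields["type"]])
    if fields.get("endian", "little") == "big":
        dtype = dtype.newbyteorder(">")
    sizes = [int(s) for s in fields["sizes"].split()]
    data = np.frombuffer(raw, dtype=dtype, count=int(np.prod(sizes)))
    # NRRD is fastest-axis-first; numpy C order is fastest-axis-last.
    voxels = data.reshape(sizes[::-1]).transpose(2, 1, 0)

    directions = np.column_stack(
        [_parse_vector(v) for v in fields["space directions"].split(") (")]
    )
    spacing = np.linalg.norm(directions, axis=0)
    origin = (
        _parse_vector(fields["space origin"]) if "space origin" in fields else np.zeros(3)
    )
    space = fields.get("space", "left-posterior-superior")
    flip = np.ones(3)
    if space in ("right-anterior-superior", "RAS"):
        flip = np.array([-1.0, -1.0, 1.0])
    directions = flip[:, None] * directions
    origin = flip * origin
    return CTVolume(voxels=voxels, spacing=spacing, origin=origin,
                    orientation=directions / spacing)


def write_nrrd(vol: CTVolume, path: str) -> None:
    dtype = np.dtype(vol.voxels.dtype)
    if dtype not in _DTYPE_TO_TYPE:
        raise ValueError(f"unsupported dtype {dtype} for NRRD export")
    directions = vol.orientation * vol.spacing
    dirs = " ".join(
        "(" + ",".join(repr(float(x)) for x in directions[:, m]) + ")" for m in range(3)
    )
    origin = "(" + ",".join(repr(float(x)) for x in vol.origin) + ")"
    header = (
        "NRRD0004\n"
        f"type: {_DTYPE_TO_TYPE[dtype]}\n"
        "dimension: 3\n"
        "space: left-posterior-superior\n"
        f"sizes: {vol.shape[0]} {vol.shape[1]} {vol.shape[2]}\n"
        f"space directions: {dirs}\n"
        "kinds: domain domain domain\n"
        "endian: little\n"
        "encoding: raw\n"
        f"space origin: {origin}\n"
        "\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.ascontiguousarray(vol.voxels.transpose(2, 1, 0)).astype(
            dtype.newbyteorder("<"), copy=False).tobytes())
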