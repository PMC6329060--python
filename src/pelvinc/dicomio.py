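"""Minimal DICOM CT-series reader (and writer for round-trip testing).

Supports uncompressed single-frame axial CT series in Implicit or Explicit
VR Little Endian. Slices are ordered by spatial position along the slice
normal, never by filename. A hand-rolled parser is used because no DICOM
library is available in the target runtime; only the tags this pipeline
needs are interpreted.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass

import numpy as np

from .volume_io import CTVolume

_IMPLICIT_LE = "1.2.840.10008.1.2"
_EXPLICIT_LE = "1.2.840.10008.1.2.1"

# tags we interpret
TAG_SERIES_UID = (0x0020, 0x000E)
TAG_IPP = (0x0020, 0x0032)
TAG_IOP = (0x0020, 0x0037)
TAG_ROWS = (0x0028, 0x0010)
TAG_COLS = (0x0028, 0x0011)
TAG_PIXEL_SPACING = (0x0028, 0x0030)
TAG_BITS_ALLOCATED = (0x0028, 0x0100)
TAG_PIXEL_REP = (0x0028, 0x0103)
TAG_RESCALE_INTERCEPT = (0x0028, 0x1052)
TAG_RESCALE_SLOPE = (0x0028, 0x1053)
TAG_PIXEL_DATA = (0x7FE0, 0x0010)

_LONG_VRS = {b"OB", b"OW", b"OF", b"OD", b"OL", b"SQ", b"UC", b"UR", b"UT", b"UN"}


def _read_elements(buf: bytes, pos: int, explicit: bool) -> dict[tuple[int, int], bytes]:
    elements: dict[tuple[int, int], bytes] = {}
    n = len(buf)
    while pos + 8 <= n:
        group, elem = struct.unpack_from("<HH", buf, pos)
        pos += 4
        if explicit:
            vr = buf[pos : pos + 2]
            if vr in _LONG_VRS:
                (length,) = struct.unpack_from("<I", buf, pos + 4)
                pos += 8
            else:
                (length,) = struct.unpack_from("<H", buf, pos + 2)
                pos += 4
        else:
            (length,) = struct.unpack_from("<I", buf, pos)
            pos += 4
        if length == 0xFFFFFFFF:
            raise ValueError(
                f"undefined-length element ({group:04x},{elem:04x}) is not supported"
            )
        elements[(group, elem)] = buf[pos : pos + length]
        pos += length
    return elements


def _decode_str(raw: bytes) -> str:
    return raw.decode("ascii", errors="replace").strip("\x00 ").strip()


def _decode_ds(raw: bytes) -> list[float]:
    text = _decode_str(raw)
    return [float(x) for x in text.split("\\")] if text else []


def _decode_us(raw: bytes) -> int:
    return struct.unpack("<H", raw[:2])[0]


@dataclass
class _Slice:
    path: str
    series_uid: str
    ipp: np.ndarray
    iop: np.ndarray
    pixel_spacing: np.ndarray
    stored: np.ndarray  # (rows, cols)
    slope: float
    intercept: float


def _read_dicom_file(path: str) -> _Slice:
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 132 + 8 or buf[128:132] != b"DICM":
        raise ValueError(f"{path}: missing DICM magic (not a DICOM part-10 file)")
    # File meta (group 0002) is always Explicit VR LE; walk it to find the
    # transfer syntax and the start of the data set.
    pos = 132
    transfer_syntax = _EXPLICIT_LE
    while pos + 8 <= len(buf):
        group, elem = struct.unpack_from("<HH", buf, pos)
        if group != 0x0002:
            break
        vr = buf[pos + 4 : pos + 6]
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", buf, pos + 8)
            header = 12
        else:
            (length,) = struct.unpack_from("<H", buf, pos + 6)
            header = 8
        value = buf[pos + header : pos + header + length]
        if (group, elem) == (0x0002, 0x0010):
            transfer_syntax = _decode_str(value)
        pos += header + length
    if transfer_syntax not in (_IMPLICIT_LE, _EXPLICIT_LE):
        raise ValueError(f"{path}: unsupported transfer syntax {transfer_syntax!r}")

    el = _read_elements(buf, pos, explicit=transfer_syntax == _EXPLICIT_LE)
    for tag, name in [
        (TAG_RESCALE_SLOPE, "RescaleSlope"),
        (TAG_RESCALE_INTERCEPT, "RescaleIntercept"),
    ]:
        if tag not in el:
            raise ValueError(f"{path}: missing rescale tag {name}; cannot convert to HU")
    for tag, name in [
        (TAG_IPP, "ImagePositionPatient"),
        (TAG_IOP, "ImageOrientationPatient"),
        (TAG_PIXEL_SPACING, "PixelSpacing"),
        (TAG_ROWS, "Rows"),
        (TAG_COLS, "Columns"),
        (TAG_PIXEL_DATA, "PixelData"),
    ]:
        if tag not in el:
            raise ValueError(f"{path}: missing required tag {name}")

    rows, cols = _decode_us(el[TAG_ROWS]), _decode_us(el[TAG_COLS])
    bits = _decode_us(el.get(TAG_BITS_ALLOCATED, struct.pack("<H", 16)))
    if bits != 16:
        raise ValueError(f"{path}: only 16-bit pixel data supported, got {bits}")
    signed = _decode_us(el.get(TAG_PIXEL_REP, b"\x00\x00")) == 1
    dtype = np.dtype("<i2") if signed else np.dtype("<u2")
    stored = np.frombuffer(el[TAG_PIXEL_DATA], dtype=dtype, count=rows * cols)
    return _Slice(
        path=path,
        series_uid=_decode_str(el.get(TAG_SERIES_UID, b"")),
        ipp=np.array(_decode_ds(el[TAG_IPP])),
        iop=np.array(_decode_ds(el[TAG_IOP])),
        pixel_spacing=np.array(_decode_ds(el[TAG_PIXEL_SPACING])),
        stored=stored.reshape(rows, cols),
        slope=_decode_ds(el[TAG_RESCALE_SLOPE])[0],
        intercept=_decode_ds(el[TAG_RESCALE_INTERCEPT])[0],
    )


def read_dicom_series(directory: str | os.PathLike) -> CTVolume:
    """Read a single axial CT series from ``directory`` into a canonical CTVolume.

    Slices are sorted by spatial position along the slice normal. Errors on
    mixed series, missing rescale tags, duplicate slice positions, and slice
    gaps that deviate more than 1% from uniform.
    """
    directory = str(directory)
    paths = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if os.path.isfile(os.path.join(directory, f))
    )
    slices = []
    for p in paths:
        try:
            slices.append(_read_dicom_file(p))
        except ValueError as exc:
            if "DICM magic" in str(exc):
                continue  # ignore stray non-DICOM files
            raise
    if not slices:
        raise ValueError(f"no DICOM files found in {directory}")

    uids = sorted({s.series_uid for s in slices})
    if len(uids) > 1:
        raise ValueError(f"directory contains {len(uids)} series: {', '.join(uids)}")

    row_cos, col_cos = slices[0].iop[:3], slices[0].iop[3:]
    normal = np.cross(row_cos, col_cos)
    order = sorted(slices, key=lambda s: float(np.dot(s.ipp, normal)))
    positions = np.array([np.dot(s.ipp, normal) for s in order])

    if len(order) > 1:
        gaps = np.diff(positions)
        gap = float(np.median(gaps))
        dup = np.where(np.abs(gaps) < 1e-6)[0]
        if dup.size:
            raise ValueError(
                f"duplicate slice position at {positions[dup[0]]:.4f} mm along the slice normal"
            )
        if np.any(np.abs(gaps - gap) > 0.01 * abs(gap)):
            raise ValueError(
                f"non-uniform slice spacing: gaps range "
                f"{gaps.min():.4f}..{gaps.max():.4f} mm (tolerance 1%)"
            )
    else:
        gap = 1.0

    hu = np.stack(
        [
            (s.stored.astype(np.float32) * np.float32(s.slope) + np.float32(s.intercept)).T
            for s in order
        ],
        axis=-1,
    )
    spacing = np.array([slices[0].pixel_spacing[1], slices[0].pixel_spacing[0], gap])
    if len(order) > 1:
        d_k = (order[-1].ipp - order[0].ipp) / (positions[-1] - positions[0])
    else:
        d_k = normal
    orientation = np.column_stack([row_cos, col_cos, d_k / np.linalg.norm(d_k)])
    return CTVolume(voxels=hu, spacing=spacing, origin=order[0].ipp.copy(),
                    orientation=orientation)


# ---------------------------------------------------------------------------
# Writing (test fixtures and interoperability checks)

def _element(group: int, elem: int, vr: bytes, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr in (b"UI", b"OB") else b" "
    head = struct.pack("<HH", group, elem)
    if vr in _LONG_VRS:
        return head + vr + b"\x00\x00" + struct.pack("<I", len(value)) + value
    return head + vr + struct.pack("<H", len(value)) + value


def _ds(values) -> bytes:
    return "\\".join(f"{float(v):.10g}" for v in np.atleast_1d(values)).encode("ascii")


def write_ct_series(
    directory: str | os.PathLike,
    vol: CTVolume,
    slope: float = 1.0,
    intercept: float = -1024.0,
    series_uid: str = "1.2.826.0.1.3680043.9999.1",
    filenames: list[str] | None = None,
) -> list[str]:
    """Write ``vol`` as an Explicit VR LE CT series; returns the file paths.

    Stored values are ``(HU - intercept) / slope`` as int16. Intended for
    fixtures and round-trip checks, not for clinical interchange.
    """
    directory = str(directory)
    os.makedirs(directory, exist_ok=True)
    ni, nj, nk = vol.shape
    if filenames is None:
        filenames = [f"slice_{k:04d}.dcm" for k in range(nk)]
    row_cos, col_cos, d_k = vol.orientation.T
    paths = []
    for k in range(nk):
        stored = np.round(
            (vol.voxels[:, :, k].astype(np.float64) - intercept) / slope
        ).astype("<i2").T  # (rows=j, cols=i)
        ipp = vol.origin + d_k * vol.spacing[2] * k
        body = b"".join(
            [
                _element(0x0008, 0x0016, b"UI", b"1.2.840.10008.5.1.4.1.1.2"),
                _element(0x0008, 0x0018, b"UI", f"{series_uid}.{k + 1}".encode()),
                _element(0x0008, 0x0060, b"CS", b"CT"),
                _element(0x0020, 0x000D, b"UI", f"{series_uid}.0".encode()),
                _element(0x0020, 0x000E, b"UI", series_uid.encode()),
                _element(0x0020, 0x0013, b"IS", str(k + 1).encode()),
                _element(0x0020, 0x0032, b"DS", _ds(ipp)),
                _element(0x0020, 0x0037, b"DS", _ds(np.r_[row_cos, col_cos])),
                _element(0x0028, 0x0002, b"US", struct.pack("<H", 1)),
                _element(0x0028, 0x0010, b"US", struct.pack("<H", nj)),
                _element(0x0028, 0x0011, b"US", struct.pack("<H", ni)),
                _element(0x0028, 0x0030, b"DS", _ds([vol.spacing[1], vol.spacing[0]])),
                _element(0x0028, 0x0100, b"US", struct.pack("<H", 16)),
                _element(0x0028, 0x0101, b"US", struct.pack("<H", 16)),
                _element(0x0028, 0x0102, b"US", struct.pack("<H", 15)),
                _element(0x0028, 0x0103, b"US", struct.pack("<H", 1)),
                _element(0x0028, 0x1052, b"DS", _ds([intercept])),
                _element(0x0028, 0x1053, b"DS", _ds([slope])),
                _element(0x7FE0, 0x0010, b"OW", np.ascontiguousarray(stored).tobytes()),
            ]
        )
        meta_body = b"".join(
            [
                _element(0x0002, 0x0001, b"OB", b"\x00\x01"),
                _element(0x0002, 0x0002, b"UI", b"1.2.840.10008.5.1.4.1.1.2"),
                _element(0x0002, 0x0003, b"UI", f"{series_uid}.{k + 1}".encode()),
                _element(0x0002, 0x0010, b"UI", _EXPLICIT_LE.encode()),
            ]
        )
        meta = _element(0x0002, 0x0000, b"UL", struct.pack("<I", len(meta_body))) + meta_body
        path = os.path.join(directory, filenames[k])
        with open(path, "wb") as fh:
            fh.write(b"\x00" * 128 + b"DICM" + meta + body)
        paths.append(path)
    return paths
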