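"""Tiny DICOM reader/writer for uncompressed explicit-VR little-endian files.

Supports exactly the subset needed to stack single-frame monochrome slice
series into volumes (geometry tags + 16-bit pixel data). Anything else —
implicit VR, compressed transfer syntaxes, sequences — is rejected with an
explicit error rather than mis-parsed. Real clinical archives should be
converted upstream.
"""

from __future__ import annotations

import struct
from pathlib import Path

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"

# VRs that use the 4-byte length form (2 reserved bytes precede the length)
_LONG_VRS = {b"OB", b"OW", b"OF", b"OD", b"OL", b"SQ", b"UC", b"UR", b"UT", b"UN"}

TAG_TRANSFER_SYNTAX = (0x0002, 0x0010)
TAG_INSTANCE_NUMBER = (0x0020, 0x0013)
TAG_IMAGE_POSITION = (0x0020, 0x0032)
TAG_IMAGE_ORIENTATION = (0x0020, 0x0037)
TAG_SAMPLES_PER_PIXEL = (0x0028, 0x0002)
TAG_ROWS = (0x0028, 0x0010)
TAG_COLUMNS = (0x0028, 0x0011)
TAG_PIXEL_SPACING = (0x0028, 0x0030)
TAG_SLICE_THICKNESS = (0x0018, 0x0050)
TAG_BITS_ALLOCATED = (0x0028, 0x0100)
TAG_PIXEL_REPRESENTATION = (0x0028, 0x0103)
TAG_PIXEL_DATA = (0x7FE0, 0x0010)


class DicomParseError(ValueError):
    pass


def read_elements(path: str | Path) -> dict[tuple[int, int], tuple[bytes, bytes]]:
    """Parse a file into {tag: (vr, raw value bytes)}."""
    data = Path(path).read_bytes()
    if len(data) < 132 or data[128:132] != b"DICM":
        raise DicomParseError(f"{path}: missing DICM magic; not a part-10 file")
    pos = 132
    out: dict[tuple[int, int], tuple[bytes, bytes]] = {}
    while pos + 8 <= len(data):
        group, elem = struct.unpack_from("<HH", data, pos)
        vr = data[pos + 4:pos + 6]
        if not (vr.isalpha() and vr.isupper()):
            raise DicomParseError(
                f"{path}: implicit-VR or corrupt element at offset {pos}; "
                "only explicit VR little endian is supported")
        if vr in _LONG_VRS:
            if vr == b"SQ":
                raise DicomParseError(f"{path}: sequences are not supported")
            (length,) = struct.unpack_from("<I", data, pos + 8)
            vstart = pos + 12
        else:
            (length,) = struct.unpack_from("<H", data, pos + 6)
            vstart = pos + 8
        if length == 0xFFFFFFFF:
            raise DicomParseError(f"{path}: undefined-length element unsupported")
        value = data[vstart:vstart + length]
        if len(value) != length:
            raise DicomParseError(f"{path}: truncated element ({group:04x},{elem:04x})")
        out[(group, elem)] = (vr, value)
        pos = vstart + length
    ts = out.get(TAG_TRANSFER_SYNTAX)
    if ts is not None and ts[1].rstrip(b"\x00 ").decode() != EXPLICIT_VR_LE:
        raise DicomParseError(
            f"{path}: unsupported transfer syntax {ts[1]!r}")
    return out


def get_ds(elements, tag) -> list[float]:
    vr, raw = elements[tag]
    return [float(v) for v in raw.decode("ascii").strip("\x00 ").split("\\") if v]


def get_is(elements, tag) -> int:
    _, raw = elements[tag]
    return int(raw.decode("ascii").strip("\x00 "))


def get_us(elements, tag) -> int:
    _, raw = elements[tag]
    return struct.unpack("<H", raw[:2])[0]


def _enc(group: int, elem: int, vr: bytes, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr in (b"OB", b"UI") else b" "
    head = struct.pack("<HH", group, elem) + vr
    if vr in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(value)) + value
    return head + struct.pack("<H", len(value)) + value


def write_slice(path: str | Path, pixels, *, instance_number: int,
                position: tuple[float, float, float],
                pixel_spacing: tuple[float, float],
                slice_thickness: float,
                orientation=(1, 0, 0, 0, 1, 0)) -> None:
    """Write one int16 monochrome slice as explicit-VR-LE part-10 DICOM."""
    import numpy as np

    px = np.ascontiguousarray(np.asarray(pixels, dtype="<i2"))
    if px.ndim != 2:
        raise ValueError("slice pixels must be 2-D")
    rows, cols = px.shape

    def ds(values) -> bytes:
        return "\\".join(f"{v:.6f}".rstrip("0").rstrip(".") for v in values
                         ).encode("ascii")

    meta = b"".join([
        _enc(0x0002, 0x0001, b"OB", b"\x00\x01"),
        _enc(0x0002, 0x0010, b"UI", EXPLICIT_VR_LE.encode()),
    ])
    body = b"".join([
        _enc(0x0018, 0x0050, b"DS", ds([slice_thickness])),
        _enc(0x0020, 0x0013, b"IS", str(instance_number).encode()),
        _enc(0x0020, 0x0032, b"DS", ds(position)),
        _enc(0x0020, 0x0037, b"DS", ds(orientation)),
        _enc(0x0028, 0x0002, b"US", struct.pack("<H", 1)),
        _enc(0x0028, 0x0010, b"US", struct.pack("<H", rows)),
        _enc(0x0028, 0x0011, b"US", struct.pack("<H", cols)),
        _enc(0x0028, 0x0030, b"DS", ds(pixel_spacing)),
        _enc(0x0028, 0x0100, b"US", struct.pack("<H", 16)),
        _enc(0x0028, 0x0101, b"US", struct.pack("<H", 16)),
        _enc(0x0028, 0x0102, b"US", struct.pack("<H", 15)),
        _enc(0x0028, 0x0103, b"US", struct.pack("<H", 1)),
        _enc(0x7FE0, 0x0010, b"OW", px.tobytes()),
    ])
    Path(path).write_bytes(b"\x00" * 128 + b"DICM" + meta + body)
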