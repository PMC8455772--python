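"""Minimal DICOM reading for frontal chest radiographs.

Supports uncompressed little-endian transfer syntaxes (implicit and
explicit VR) and exactly the attributes the pipeline needs: pixel data,
PixelSpacing (0028,0030) / ImagerPixelSpacing (0018,1164), ViewPosition
(0018,5101), PatientID (0010,0020) and PhotometricInterpretation.
MONOCHROME1 images are inverted to the MONOCHROME2 convention.

A tiny writer is included so the test suite can build its own fixtures at
run time; it is not part of the tool's external contract (DICOM is
read-only for the pipeline).
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .geometry import PixelSpacing
from .io import ExamRecord, View

IMPLICIT_LE = "1.2.840.10008.1.2"
EXPLICIT_LE = "1.2.840.10008.1.2.1"

# VRs whose explicit encoding uses a 2-byte reserved field + 4-byte length.
_LONG_VRS = {b"OB", b"OW", b"OF", b"OL", b"OD", b"SQ", b"UC", b"UR", b"UT", b"UN"}

_WANTED = {
    (0x0008, 0x0008),  # ImageType (unused, harmless)
    (0x0010, 0x0020),  # PatientID
    (0x0018, 0x1164),  # ImagerPixelSpacing
    (0x0018, 0x5101),  # ViewPosition
    (0x0028, 0x0004),  # PhotometricInterpretation
    (0x0028, 0x0010),  # Rows
    (0x0028, 0x0011),  # Columns
    (0x0028, 0x0030),  # PixelSpacing
    (0x0028, 0x0100),  # BitsAllocated
    (0x0028, 0x0103),  # PixelRepresentation
    (0x7FE0, 0x0010),  # PixelData
}


class DicomError(ValueError):
    pass


def _skip_undefined(buf: bytes, pos: int) -> int:
    """Skip an undefined-length sequence/item to past its delimiter."""
    depth = 1
    while depth > 0:
        if pos + 8 > len(buf):
            raise DicomError("truncated undefined-length sequence")
        group, elem, length = struct.unpack_from("<HHI", buf, pos)
        pos += 8
        if (group, elem) == (0xFFFE, 0xE0DD):  # sequence delimiter
            depth -= 1
        elif (group, elem) == (0xFFFE, 0xE000):  # item
            if length == 0xFFFFFFFF:
                pass  # contents parsed element-wise; delimiters balance depth
            else:
                pos += length
        elif (group, elem) == (0xFFFE, 0xE00D):  # item delimiter
            pass
        elif length == 0xFFFFFFFF:
            depth += 1
        else:
            pos += length
    return pos


def _parse_elements(buf: bytes, pos: int, explicit: bool) -> dict:
    out: dict[tuple[int, int], bytes] = {}
    n = len(buf)
    while pos + 8 <= n:
        group, elem = struct.unpack_from("<HH", buf, pos)
        pos += 4
        if explicit and group != 0xFFFE:
            vr = buf[pos:pos + 2]
            if vr in _LONG_VRS:
                length = struct.unpack_from("<I", buf, pos + 4)[0]
                pos += 8
            else:
                length = struct.unpack_from("<H", buf, pos + 2)[0]
                pos += 4
        else:
            length = struct.unpack_from("<I", buf, pos)[0]
            pos += 4
        if length == 0xFFFFFFFF:
            pos = _skip_undefined(buf, pos)
            continue
        if pos + length > n:
            raise DicomError("element extends past end of file")
        if (group, elem) in _WANTED:
            out[(group, elem)] = buf[pos:pos + length]
        pos += length
    return out


def _read_meta(buf: bytes) -> tuple[dict, int]:
    """Parse the explicit-VR file meta group; returns (elements, dataset offset)."""
    if buf[128:132] != b"DICM":
        raise DicomError("not a DICOM part-10 file (missing DICM marker)")
    pos = 132
    meta: dict[tuple[int, int], bytes] = {}
    while pos + 8 <= len(buf):
        group, elem = struct.unpack_from("<HH", buf, pos)
        if group != 0x0002:
            break
        vr = buf[pos + 4:pos + 6]
        if vr in _LONG_VRS:
            length = struct.unpack_from("<I", buf, pos + 8)[0]
            val_pos = pos + 12
        else:
            length = struct.unpack_from("<H", buf, pos + 6)[0]
            val_pos = pos + 8
        meta[(group, elem)] = buf[val_pos:val_pos + length]
        pos = val_pos + length
    return meta, pos


def _decode_str(raw: bytes | None) -> str | None:
    if raw is None:
        return None
    return raw.decode("ascii", errors="replace").strip("\x00 ").strip()


def _decode_ds_pair(raw: bytes | None) -> tuple[float, float] | None:
    if raw is None:
        return None
    parts = _decode_str(raw).split("\\")
    if len(parts) != 2:
        return None
    try:
        return float(parts[0]), float(parts[1])
    except ValueError:
        return None


def read_dicom(path: str | Path) -> ExamRecord:
    """Decode a DICOM radiograph into an :class:`ExamRecord`.

    Spacing comes from PixelSpacing, falling back to ImagerPixelSpacing,
    else absent (downstream cm computation is then gated).  ViewPosition
    AP/PA maps to FRONTAL.  Pixel values are rescaled to float32 in [0, 1].
    """
    buf = Path(path).read_bytes()
    try:
        meta, pos = _read_meta(buf)
    except DicomError:
        raise
    except Exception as e:  # truncated/garbled header
        raise DicomError(f"unparseable DICOM file: {e}") from e
    ts = _decode_str(meta.get((0x0002, 0x0010))) or EXPLICIT_LE
    if ts not in (IMPLICIT_LE, EXPLICIT_LE):
        raise DicomError(f"unsupported transfer syntax {ts!r} (uncompressed LE only)")
    elems = _parse_elements(buf, pos, explicit=(ts == EXPLICIT_LE))

    pixel_raw = elems.get((0x7FE0, 0x0010))
    if pixel_raw is None:
        raise DicomError("missing pixel data")
    rows_raw = elems.get((0x0028, 0x0010))
    cols_raw = elems.get((0x0028, 0x0011))
    if rows_raw is None or cols_raw is None:
        raise DicomError("missing Rows/Columns")
    rows = struct.unpack("<H", rows_raw[:2])[0]
    cols = struct.unpack("<H", cols_raw[:2])[0]
    bits = struct.unpack("<H", elems.get((0x0028, 0x0100), b"\x10\x00")[:2])[0]
    signed = struct.unpack("<H", elems.get((0x0028, 0x0103), b"\x00\x00")[:2])[0]
    if bits == 8:
        dtype = np.int8 if signed else np.uint8
    elif bits == 16:
        dtype = np.int16 if signed else np.uint16
    else:
        raise DicomError(f"unsupported BitsAllocated {bits}")
    expected = rows * cols * (bits // 8)
    if len(pixel_raw) < expected:
        raise DicomError("pixel data shorter than Rows*Columns")
    img = np.frombuffer(pixel_raw[:expected], dtype=dtype).reshape(rows, cols)
    img = img.astype(np.float32)

    photometric = _decode_str(elems.get((0x0028, 0x0004))) or "MONOCHROME2"
    if photometric == "MONOCHROME1":
        img = img.max() - img
    lo, hi = float(img.min()), float(img.max())
    img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)

    spacing_pair = _decode_ds_pair(elems.get((0x0028, 0x0030)))
    if spacing_pair is None:
        spacing_pair = _decode_ds_pair(elems.get((0x0018, 0x1164)))
    spacing = PixelSpacing(*spacing_pair) if spacing_pair else None

    view_raw = _decode_str(elems.get((0x0018, 0x5101)))
    if view_raw in ("AP", "PA"):
        view = View.FRONTAL
    elif view_raw:
        view = View.OTHER
    else:
        view = View.UNKNOWN

    patient_id = _decode_str(elems.get((0x0010, 0x0020))) or "UNKNOWN"
    return ExamRecord(
        exam_id=Path(path).stem,
        patient_id=patient_id,
        image=img,
        spacing=spacing,
        view=view,
    )


# fixture writer ----------------------------------------------------------

def _elem_explicit(group: int, elem: int, vr: bytes, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr not in (b"US", b"OW") else b"\x00"
    if vr in _LONG_VRS:
        return struct.pack("<HH2sHI", group, elem, vr, 0, len(value)) + value
    return struct.pack("<HH2sH", group, elem, vr, len(value)) + value


def write_dicom(
    path: str | Path,
    image: np.ndarray,
    spacing: tuple[float, float] | None = None,
    view: str | None = "AP",
    patient_id: str = "TEST",
    photometric: str = "MONOCHROME2",
    imager_spacing: tuple[float, float] | None = None,
) -> Path:
    """Write a minimal explicit-VR-LE part-10 file (test/demo fixture only)."""
    image = np.asarray(image)
    if image.dtype != np.uint16:
        raise ValueError("fixture writer expects uint16 pixels")
    rows, cols = image.shape

    meta_body = b"".join([
        _elem_explicit(0x0002, 0x0010, b"UI", EXPLICIT_LE.encode()),
    ])
    meta = _elem_explicit(0x0002, 0x0000, b"UL", struct.pack("<I", len(meta_body)))
    out = [b"\x00" * 128, b"DICM", meta, meta_body]

    def ds(vals: tuple[float, float]) -> bytes:
        return f"{vals[0]}\\{vals[1]}".encode()

    out.append(_elem_explicit(0x0010, 0x0020, b"LO", patient_id.encode()))
    if imager_spacing is not None:
        out.append(_elem_explicit(0x0018, 0x1164, b"DS", ds(imager_spacing)))
    if view is not None:
        out.append(_elem_explicit(0x0018, 0x5101, b"CS", view.encode()))
    out.append(_elem_explicit(0x0028, 0x0004, b"CS", photometric.encode()))
    out.append(_elem_explicit(0x0028, 0x0010, b"US", struct.pack("<H", rows)))
    out.append(_elem_explicit(0x0028, 0x0011, b"US", struct.pack("<H", cols)))
    if spacing is not None:
        out.append(_elem_explicit(0x0028, 0x0030, b"DS", ds(spacing)))
    out.append(_elem_explicit(0x0028, 0x0100, b"US", struct.pack("<H", 16)))
    out.append(_elem_explicit(0x0028, 0x0103, b"US", struct.pack("<H", 0)))
    out.append(_elem_explicit(0x7FE0, 0x0010, b"OW", image.tobytes()))

    path = Path(path)
    path.write_bytes(b"".join(out))
    return path
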