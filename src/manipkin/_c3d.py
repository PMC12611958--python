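"""Minimal C3D reader/writer (float storage, Intel byte order).

Covers the subset of the C3D interchange layout this package produces and
consumes: one POINT group (mm, float coordinates + residual) and one ANALOG
group (float samples, integer analog/point rate ratio).  Integer-scaled
files, DEC/MIPS byte orders and multi-block parameter records beyond what we
emit are out of scope; unreadable structure raises
:class:`~manipkin.errors.FileFormatError` naming the offset.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import FileFormatError

BLOCK = 512
PROC_INTEL = 84


@dataclass
class C3DData:
    points: np.ndarray       # (n_frames, n_points, 4): x, y, z (mm), residual
    point_labels: list
    point_rate: float
    analog: np.ndarray       # (n_samples, n_channels)
    analog_labels: list
    analog_rate: float


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------

def _param_record(name: bytes, group_id: int, dtype: int, dims: list, payload: bytes) -> bytes:
    rec = struct.pack("bb", len(name), group_id) + name
    body = struct.pack("b", dtype) + struct.pack("B", len(dims))
    body += bytes(dims) + payload + b"\x00"  # zero-length description
    rec += struct.pack("<h", 2 + len(body)) + body
    return rec


def _group_record(name: bytes, group_id: int) -> bytes:
    rec = struct.pack("bb", len(name), -group_id) + name
    body = b"\x00"  # zero-length description
    rec += struct.pack("<h", 2 + len(body)) + body
    return rec


def _char_matrix(labels: list) -> tuple[bytes, list]:
    width = max((len(lb) for lb in labels), default=1)
    width = max(width, 1)
    payload = b"".join(lb.encode("ascii").ljust(width) for lb in labels)
    return payload, [width, len(labels)]


def write_c3d(path: Path, data: C3DData) -> None:
    n_frames, n_points, _ = data.points.shape
    n_channels = data.analog.shape[1] if data.analog.size else 0
    if n_channels:
        ratio = data.analog_rate / data.point_rate
        subframes = int(round(ratio))
        if abs(ratio - subframes) > 1e-9:
            raise ValueError("analog rate must be an integer multiple of point rate")
        if data.analog.shape[0] != n_frames * subframes:
            raise ValueError(
                f"analog length {data.analog.shape[0]} != frames*ratio {n_frames * subframes}"
            )
    else:
        subframes = 0
    if n_frames > 32767:
        raise ValueError("C3D header limits trials to 32767 frames")

    # -- parameter section ------------------------------------------------
    params = bytearray()
    params += _group_record(b"POINT", 1)
    params += _param_record(b"USED", 1, 2, [], struct.pack("<h", n_points))
    params += _param_record(b"FRAMES", 1, 2, [], struct.pack("<h", n_frames))
    params += _param_record(b"RATE", 1, 4, [], struct.pack("<f", data.point_rate))
    params += _param_record(b"SCALE", 1, 4, [], struct.pack("<f", -1.0))
    lbl_payload, lbl_dims = _char_matrix(data.point_labels)
    params += _param_record(b"LABELS", 1, -1, lbl_dims, lbl_payload)

    params += _group_record(b"ANALOG", 2)
    params += _param_record(b"USED", 2, 2, [], struct.pack("<h", n_channels))
    params += _param_record(b"RATE", 2, 4, [], struct.pack("<f", data.analog_rate))
    if n_channels:
        albl_payload, albl_dims = _char_matrix(data.analog_labels)
        params += _param_record(b"LABELS", 2, -1, albl_dims, albl_payload)
        params += _param_record(b"GEN_SCALE", 2, 4, [], struct.pack("<f", 1.0))
        params += _param_record(
            b"SCALE", 2, 4, [n_channels], struct.pack(f"<{n_channels}f", *([1.0] * n_channels))
        )
        params += _param_record(
            b"OFFSET", 2, 2, [n_channels], struct.pack(f"<{n_channels}h", *([0] * n_channels))
        )
    params += b"\x00\x00\x00\x00"  # terminator record

    n_param_blocks = -(-(4 + len(params)) // BLOCK)
    data_start_block = 2 + n_param_blocks  # 1-based

    # -- header block -----------------------------------------------------
    header = bytearray(BLOCK)
    header[0] = 2          # first parameter block
    header[1] = 0x50
    struct.pack_into("<h", header, 2, n_points)
    struct.pack_into("<h", header, 4, n_channels * subframes)
    struct.pack_into("<h", header, 6, 1)                 # first frame
    struct.pack_into("<h", header, 8, n_frames)          # last frame
    struct.pack_into("<h", header, 10, 0)                # max interpolation gap
    struct.pack_into("<f", header, 12, -1.0)             # scale: negative = float
    struct.pack_into("<h", header, 16, data_start_block)
    struct.pack_into("<h", header, 18, subframes)
    struct.pack_into("<f", header, 20, data.point_rate)

    param_section = bytearray(n_param_blocks * BLOCK)
    param_section[0] = 1
    param_section[1] = 0x50
    param_section[2] = n_param_blocks
    param_section[3] = PROC_INTEL
    param_section[4: 4 + len(params)] = params

    # -- data section -----------------------------------------------------
    frames = np.ascontiguousarray(data.points, dtype="<f4").reshape(n_frames, n_points * 4)
    if n_channels:
        analog = np.ascontiguousarray(data.analog, dtype="<f4").reshape(
            n_frames, subframes * n_channels
        )
        interleaved = np.hstack([frames, analog])
    else:
        interleaved = frames

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(param_section)
        fh.write(interleaved.tobytes())
        pad = (-fh.tell()) % BLOCK
        fh.write(b"\x00" * pad)


# ---------------------------------------------------------------------------
# reader
# ---------------------------------------------------------------------------

def _parse_params(buf: bytes) -> dict:
    """Parse the parameter section into {GROUP: {PARAM: numpy array/str list}}."""
    if len(buf) < 4:
        raise FileFormatError("parameter section truncated before byte 4")
    proc = buf[3]
    if proc != PROC_INTEL:
        raise FileFormatError(f"unsupported processor type {proc} at parameter byte 3 (only Intel/{PROC_INTEL})")
    groups_by_id: dict = {}
    params_raw = []
    pos = 4
    while pos + 2 <= len(buf):
        nchar = struct.unpack_from("b", buf, pos)[0]
        if nchar == 0:
            break
        gid = struct.unpack_from("b", buf, pos + 1)[0]
        name_len = abs(nchar)
        name = buf[pos + 2: pos + 2 + name_len].decode("ascii", "replace")
        off_pos = pos + 2 + name_len
        if off_pos + 2 > len(buf):
            raise FileFormatError(f"parameter record truncated at byte {off_pos}")
        next_off = struct.unpack_from("<h", buf, off_pos)[0]
        if gid < 0:
            groups_by_id[-gid] = name
        else:
            params_raw.append((gid, name, buf[off_pos + 2: off_pos + next_off if next_off else len(buf)]))
        if next_off == 0:
            break
        pos = off_pos + next_off

    out: dict = {}
    for gid, name, body in params_raw:
        try:
            dtype = struct.unpack_from("b", body, 0)[0]
            ndims = body[1]
            dims = list(body[2: 2 + ndims])
            dpos = 2 + ndims
            count = int(np.prod(dims)) if dims else 1
            itemsize = {-1: 1, 1: 1, 2: 2, 4: 4}[dtype]
            raw = body[dpos: dpos + count * itemsize]
            if dtype == -1:
                if len(dims) >= 2:
                    width = dims[0]
                    value = [
                        raw[i * width: (i + 1) * width].decode("ascii", "replace").rstrip()
                        for i in range(count // width)
                    ]
                else:
                    value = raw.decode("ascii", "replace").rstrip()
            elif dtype == 2:
                value = np.frombuffer(raw, dtype="<i2").copy()
            elif dtype == 4:
                value = np.frombuffer(raw, dtype="<f4").astype(float)
            else:
                value = np.frombuffer(raw, dtype="i1").copy()
            if isinstance(value, np.ndarray) and value.size == 1 and not dims:
                value = value[0]
        except (struct.error, KeyError, IndexError) as exc:
            raise FileFormatError(f"cannot parse parameter {name!r} of group id {gid}") from exc
        group = groups_by_id.get(gid, f"GROUP{gid}")
        out.setdefault(group, {})[name] = value
    return out


def read_c3d(path: Path) -> C3DData:
    raw = Path(path).read_bytes()
    if len(raw) < 2 * BLOCK:
        raise FileFormatError(f"{path}: file shorter than two 512-byte blocks")
    if raw[1] != 0x50:
        raise FileFormatError(f"{path}: byte 1 is 0x{raw[1]:02x}, expected 0x50 (not a C3D file)")
    param_block = raw[0]
    n_points = struct.unpack_from("<h", raw, 2)[0]
    analog_per_frame = struct.unpack_from("<h", raw, 4)[0]
    first_frame = struct.unpack_from("<h", raw, 6)[0]
    last_frame = struct.unpack_from("<h", raw, 8)[0]
    scale = struct.unpack_from("<f", raw, 12)[0]
    data_block = struct.unpack_from("<h", raw, 16)[0]
    subframes = struct.unpack_from("<h", raw, 18)[0]
    point_rate = struct.unpack_from("<f", raw, 20)[0]
    if scale >= 0:
        raise FileFormatError(f"{path}: integer-scaled point data (header scale {scale}) not supported")
    n_frames = last_frame - first_frame + 1

    params = _parse_params(raw[(param_block - 1) * BLOCK:])
    point_group = params.get("POINT", {})
    labels = point_group.get("LABELS") or [f"point_{i}" for i in range(n_points)]
    labels = list(labels)[:n_points]
    analog_group = params.get("ANALOG", {})
    n_channels = int(analog_group.get("USED", analog_per_frame // subframes if subframes else 0))
    analog_labels = list(analog_group.get("LABELS", []))[:n_channels]
    analog_rate = float(analog_group.get("RATE", point_rate * subframes if subframes else 0.0))
    if "RATE" in point_group:
        point_rate = float(point_group["RATE"])

    words_per_frame = n_points * 4 + subframes * n_channels
    start = (data_block - 1) * BLOCK
    need = start + n_frames * words_per_frame * 4
    if need > len(raw):
        raise FileFormatError(
            f"{path}: data section needs {need} bytes but file has {len(raw)} (offset {start})"
        )
    flat = np.frombuffer(raw, dtype="<f4", count=n_frames * words_per_frame, offset=start)
    flat = flat.reshape(n_frames, words_per_frame).astype(float)
    points = flat[:, : n_points * 4].reshape(n_frames, n_points, 4)
    if n_channels:
        analog = flat[:, n_points * 4:].reshape(n_frames * subframes, n_channels)
    else:
        analog = np.zeros((0, 0))
    return C3DData(
        points=points,
        point_labels=labels,
        point_rate=point_rate,
        analog=analog,
        analog_labels=analog_labels,
        analog_rate=analog_rate,
    )
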