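"""Minimal uncompressed RGB AVI (RIFF) reader/writer.

Handles exactly one flavor of AVI: a single 'vids' stream of uncompressed
24-bit bottom-up DIB frames (biCompression = BI_RGB), the layout produced by
VirtualDub-style "uncompress" exports. Pixel values round-trip exactly.
Audio streams and compressed codecs are rejected.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .errors import FormatError, InputError

_AVIF_HASINDEX = 0x00000010


def _pad_row(width: int) -> int:
    return (width * 3 + 3) & ~3


def write_avi(path: str | Path, frames: np.ndarray, fps: float = 30.0) -> None:
    """Write ``frames`` (n, H, W, 3) uint8 RGB as an uncompressed AVI."""
    frames = np.asarray(frames)
    if frames.ndim != 4 or frames.shape[-1] != 3 or frames.dtype != np.uint8:
        raise FormatError("write_avi needs (n,H,W,3) uint8 frames")
    n, h, w, _ = frames.shape
    row_bytes = _pad_row(w)
    frame_bytes = row_bytes * h
    fps = float(fps) if fps and fps > 0 else 30.0
    rate = int(round(fps * 1000))
    scale = 1000

    # DIB frames are bottom-up BGR with rows padded to 4 bytes.
    pad = row_bytes - w * 3
    payloads = []
    for f in frames:
        bgr = f[::-1, :, ::-1]
        if pad:
            rows = np.zeros((h, row_bytes), dtype=np.uint8)
            rows[:, : w * 3] = bgr.reshape(h, w * 3)
            payloads.append(rows.tobytes())
        else:
            payloads.append(bgr.tobytes())

    avih = struct.pack(
        "<14I",
        int(round(1e6 / fps)), frame_bytes * int(np.ceil(fps)), 0,
        _AVIF_HASINDEX, n, 0, 1, frame_bytes, w, h, 0, 0, 0, 0)
    strh = struct.pack(
        "<4s4sI2H8IH2hH",
        b"vids", b"DIB ", 0, 0, 0, 0, scale, rate, 0, n, frame_bytes,
        0xFFFFFFFF & (2**32 - 1), 0, 0, 0, w, h)
    # BITMAPINFOHEADER, biCompression = 0 (BI_RGB)
    strf = struct.pack("<I2i2H2I2i2I", 40, w, h, 1, 24, 0, frame_bytes,
                       0, 0, 0, 0)

    def chunk(fourcc: bytes, data: bytes) -> bytes:
        return fourcc + struct.pack("<I", len(data)) + data + (
            b"\x00" if len(data) % 2 else b"")

    def lst(fourcc: bytes, data: bytes) -> bytes:
        return chunk(b"LIST", fourcc + data)

    strl = lst(b"strl", chunk(b"strh", strh) + chunk(b"strf", strf))
    hdrl = lst(b"hdrl", chunk(b"avih", avih) + strl)
    movi_body = b"".join(chunk(b"00db", p) for p in payloads)
    movi = lst(b"movi", movi_body)

    # idx1: offsets relative to the start of the 'movi' fourcc
    idx_entries = []
    off = 4
    for p in payloads:
        idx_entries.append(struct.pack("<4s3I", b"00db", 0x10, off, len(p)))
        off += 8 + len(p) + (len(p) % 2)
    idx1 = chunk(b"idx1", b"".join(idx_entries))

    body = b"AVI " + hdrl + movi + idx1
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(body)) + body)


def _iter_chunks(buf: bytes, start: int, end: int):
    pos = start
    while pos + 8 <= end:
        fourcc = buf[pos:pos + 4]
        (size,) = struct.unpack_from("<I", buf, pos + 4)
        yield fourcc, pos + 8, size
        pos += 8 + size + (size % 2)


def read_avi(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an uncompressed 24-bit AVI; returns ``(frames, fps)``."""
    path = Path(path)
    buf = path.read_bytes()
    if len(buf) < 12 or buf[:4] != b"RIFF" or buf[8:12] != b"AVI ":
        raise InputError(f"not an AVI file: {path}")

    width = height = None
    bitcount = compression = None
    fps = 30.0
    frame_payloads: list[tuple[int, int]] = []

    def walk(start: int, end: int) -> None:
        nonlocal width, height, bitcount, compression, fps
        for fourcc, dstart, size in _iter_chunks(buf, start, end):
            dend = dstart + size
            if fourcc == b"LIST":
                walk(dstart + 4, dend)
            elif fourcc == b"strh" and size >= 48:
                typ, handler = struct.unpack_from("<4s4s", buf, dstart)
                if typ == b"vids":
                    scale, rate = struct.unpack_from("<2I", buf, dstart + 20)
                    if scale and rate:
                        fps = rate / scale
                elif typ == b"auds":
                    raise FormatError(f"{path}: AVI files with audio tracks "
                                      f"are not supported")
            elif fourcc == b"strf" and size >= 40 and width is None:
                (_, w, h, _, bc, comp) = struct.unpack_from("<I2i2HI",
                                                            buf, dstart)
                width, height, bitcount, compression = w, abs(h), bc, comp
            elif fourcc in (b"00db", b"00dc") and size > 0:
                frame_payloads.append((dstart, size))

    walk(12, 12 + struct.unpack_from("<I", buf, 4)[0])

    if width is None or not frame_payloads:
        raise InputError(f"AVI contains no readable video frames: {path}")
    if compression != 0 or bitcount != 24:
        raise FormatError(
            f"{path}: only uncompressed 24-bit AVI is supported "
            f"(biCompression={compression}, biBitCount={bitcount}); "
            f"re-export the video uncompressed")

    row_bytes = _pad_row(width)
    frames = np.empty((len(frame_payloads), height, width, 3), dtype=np.uint8)
    for i, (off, size) in enumerate(frame_payloads):
        if size < row_bytes * height:
            raise FormatError(f"{path}: truncated frame {i}")
        rows = np.frombuffer(buf, np.uint8, row_bytes * height, off)
        rows = rows.reshape(height, row_bytes)[:, : width * 3]
        frames[i] = rows.reshape(height, width, 3)[::-1, :, ::-1]
    return frames, fps
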