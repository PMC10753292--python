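"""Compact self-indexed stranded coverage files (``.cov``).

Layout: a BGZF stream (concatenated gzip members readable by any gzip
decompressor) whose first block holds a fixed-size header (magic, version,
virtual offset and length of the index, JSON chromosome table), followed by
run-length coverage records ``(depth int32, run uint32)`` per
(stratum, chromosome), a JSON index block with genomic-position -> virtual
offset anchors every ``spacing`` bases, and the standard BGZF EOF block.
The header block is written with stored (level-0) deflate so its compressed
size is independent of content and can be patched in place once the index
position is known.  Queries seek to the nearest anchor and decompress only
the overlapping blocks.
"""

from __future__ import annotations

import gzip
import json
import struct
import warnings
import zlib
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import bgzf as _bgzf

from .bam_engine import CoverageTrack

MAGIC = b"SWCOV01\0"
VERSION = 1
HEADER_PAYLOAD = 4096
DEFAULT_SPACING = 16384
STRATA = ("unstranded", "plus", "minus")
_REC = struct.Struct("<iI")
_BGZF_EOF = _bgzf._bgzf_eof


class CovFormatError(ValueError):
    """Raised for malformed or truncated .cov files."""


# ---------------------------------------------------------------------------
# low-level BGZF block writer
# ---------------------------------------------------------------------------

def _bgzf_block(payload: bytes, level: int) -> bytes:
    c = zlib.compressobj(level, zlib.DEFLATED, -15)
    cdata = c.compress(payload) + c.flush()
    bsize = len(cdata) + 26  # 18 header + cdata + 8 footer
    if bsize > 65536:
        raise CovFormatError("BGZF block overflow")
    header = struct.pack(
        "<4BI2BH2BH H", 31, 139, 8, 4, 0, 0, 255, 6, 66, 67, 2, bsize - 1
    )
    footer = struct.pack("<II", zlib.crc32(payload), len(payload) & 0xFFFFFFFF)
    return header + cdata + footer


class _BlockWriter:
    """Buffers bytes into BGZF blocks and tracks virtual offsets."""

    MAX_PAYLOAD = 60000

    def __init__(self, fh, level: int = 6):
        self.fh = fh
        self.level = level
        self.buf = bytearray()

    def virtual_tell(self) -> int:
        return (self.fh.tell() << 16) | len(self.buf)

    def write(self, data: bytes) -> None:
        self.buf += data
        while len(self.buf) >= self.MAX_PAYLOAD:
            chunk = bytes(self.buf[: self.MAX_PAYLOAD])
            del self.buf[: self.MAX_PAYLOAD]
            self.fh.write(_bgzf_block(chunk, self.level))

    def flush(self) -> None:
        if self.buf:
            self.fh.write(_bgzf_block(bytes(self.buf), self.level))
            self.buf.clear()


def _header_payload(index_voffset: int, index_len: int, meta: dict) -> bytes:
    body = json.dumps(meta, sort_keys=True).encode()
    payload = MAGIC + struct.pack("<HQI I", VERSION, index_voffset, index_len, len(body)) + body
    if len(payload) > HEADER_PAYLOAD:
        raise CovFormatError("header metadata too large")
    return payload + b"\0" * (HEADER_PAYLOAD - len(payload))


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_cov(tracks: dict[str, CoverageTrack], path, *, spacing: int = DEFAULT_SPACING,
              level: int = 6) -> None:
    """Write coverage tracks (by stratum) to a ``.cov`` file.

    Only the strata present are stored (an unstranded experiment stores one
    stratum); chromosome tables must agree across strata.  Output bytes are
    deterministic for fixed input, spacing and compression level.
    """
    strata = [s for s in STRATA if s in tracks]
    if not strata:
        raise ValueError("no coverage tracks supplied")
    chrom_lengths = tracks[strata[0]].chrom_lengths
    for s in strata:
        if tracks[s].chrom_lengths != chrom_lengths:
            raise CovFormatError("inconsistent chromosome tables across strata")

    chroms = sorted(chrom_lengths)
    meta = {
        "chroms": [[c, int(chrom_lengths[c])] for c in chroms],
        "strata": strata,
        "spacing": int(spacing),
    }
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(_bgzf_block(_header_payload(0, 0, meta), 0))
        header_size = fh.tell()
        bw = _BlockWriter(fh, level=level)
        anchors: dict[str, dict[str, list[list[int]]]] = {s: {} for s in strata}
        for s in strata:
            track = tracks[s]
            for chrom in chroms:
                depths, runs = track.rle.get(
                    chrom, (np.zeros(1, np.int32), np.array([chrom_lengths[chrom]], np.int64))
                )
                if chrom_lengths[chrom] == 0:
                    anchors[s][chrom] = []
                    continue
                if int(runs.sum()) != chrom_lengths[chrom]:
                    raise CovFormatError(f"run lengths for {chrom} do not sum to chromosome length")
                if depths.size and int(depths.max(initial=0)) > 2**31 - 1:
                    raise CovFormatError("depth exceeds int32 range")
                alist: list[list[int]] = []
                pos = 0
                next_anchor = 0
                for d, r in zip(depths.tolist(), runs.tolist()):
                    if pos >= next_anchor:
                        alist.append([pos, bw.virtual_tell()])
                        next_anchor = (pos // spacing + 1) * spacing
                    bw.write(_REC.pack(int(d), int(r)))
                    pos += int(r)
                anchors[s][chrom] = alist
        bw.flush()
        index_voffset = fh.tell() << 16
        index_payload = json.dumps({"anchors": anchors}, sort_keys=True).encode()
        bw.write(index_payload)
        bw.flush()
        fh.write(_BGZF_EOF)

    # patch the header block in place with the final index location
    patched = _bgzf_block(_header_payload(index_voffset, len(index_payload), meta), 0)
    if len(patched) != header_size:
        raise CovFormatError("header block size changed on patch")
    with open(path, "r+b") as fh:
        fh.write(patched)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

@dataclass
class CovReader:
    """Open ``.cov`` file with cached header and index."""

    path: str
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    strata: list[str] = field(default_factory=list)
    spacing: int = DEFAULT_SPACING
    _anchors: dict = field(default_factory=dict)

    def __post_init__(self):
        self.path = str(self.path)
        with open(self.path, "rb") as raw:
            head = raw.read(4)
            if len(head) < 4 or head[:2] != b"\x1f\x8b":
                raise CovFormatError(f"{self.path}: not a BGZF file")
        reader = _bgzf.BgzfReader(self.path, "rb")
        try:
            payload = reader.read(HEADER_PAYLOAD)
            if len(payload) < HEADER_PAYLOAD or payload[:8] != MAGIC:
                raise CovFormatError(f"{self.path}: bad magic; not a .cov file")
            version, index_voffset, index_len, meta_len = struct.unpack_from("<HQII", payload, 8)
            if version != VERSION:
                raise CovFormatError(f"{self.path}: unsupported version {version}")
            meta = json.loads(payload[26:26 + meta_len].decode())
            self.chrom_lengths = {c: l for c, l in meta["chroms"]}
            self.strata = list(meta["strata"])
            self.spacing = int(meta["spacing"])
            reader.seek(index_voffset)
            index = json.loads(reader.read(index_len).decode())
            self._anchors = index["anchors"]
        finally:
            reader.close()

    def query(self, stratum: str, chrom: str, start: int, end: int) -> np.ndarray:
        """Exact per-base depths over [start, end)."""
        if stratum not in STRATA:
            raise KeyError(f"unknown stratum {stratum!r}")
        if chrom not in self.chrom_lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        clen = self.chrom_lengths[chrom]
        if not (0 <= start <= end <= clen):
            raise IndexError(f"interval [{start},{end}) outside {chrom} (len {clen})")
        if stratum not in self.strata:
            warnings.warn(f"stratum {stratum!r} absent from {self.path}; returning zeros")
            return np.zeros(end - start, np.int32)
        if end == start:
            return np.zeros(0, np.int32)
        alist = self._anchors[stratum][chrom]
        positions = [a[0] for a in alist]
        i = bisect_right(positions, start) - 1
        pos, voffset = alist[max(i, 0)]
        out = np.zeros(end - start, np.int32)
        reader = _bgzf.BgzfReader(self.path, "rb")
        try:
            reader.seek(voffset)
            buf = b""
            while pos < end:
                if len(buf) < _REC.size:
                    more = reader.read(_REC.size * 4096)
                    if not more:
                        raise CovFormatError(f"{self.path}: truncated record stream")
                    buf += more
                n = len(buf) // _REC.size
                for depth, run in _REC.iter_unpack(buf[: n * _REC.size]):
                    lo, hi = max(pos, start), min(pos + run, end)
                    if hi > lo:
                        out[lo - start:hi - start] = depth
                    pos += run
                    if pos >= end:
                        break
                buf = buf[n * _REC.size:]
        finally:
            reader.close()
        return out

    def binned_means(self, stratum: str, chrom: str, start: int, end: int,
                     n_bins: int) -> np.ndarray:
        """Mean depth per bin; bins partition [start,end), last absorbs remainder."""
        if n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if end - start < n_bins:
            raise ValueError("interval shorter than number of bins")
        depths = self.query(stratum, chrom, start, end)
        width = (end - start) // n_bins
        edges = np.arange(n_bins) * width
        sums = np.add.reduceat(depths.astype(np.float64), edges)
        counts = np.diff(np.append(edges, end - start))
        return sums / counts


def read_cov(path, stratum: str, chrom: str, interval: tuple[int, int]) -> np.ndarray:
    return CovReader(path).query(stratum, chrom, interval[0], interval[1])


def binned_means(path, stratum: str, chrom: str, interval: tuple[int, int],
                 n_bins: int) -> np.ndarray:
    return CovReader(path).binned_means(stratum, chrom, interval[0], interval[1], n_bins)


# ---------------------------------------------------------------------------
# validation and export
# ---------------------------------------------------------------------------

@dataclass
class CovReport:
    path: str
    failures: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def validate_cov(path) -> CovReport:
    """Integrity report: magic/version, gzip stream, run-length sums, index, EOF."""
    report = CovReport(str(path))
    try:
        raw = Path(path).read_bytes()
    except OSError as exc:
        report.failures.append(f"unreadable: {exc}")
        return report
    if len(raw) < 28 or raw[-28:] != _BGZF_EOF:
        report.failures.append("missing BGZF EOF marker block")
    try:
        data = gzip.decompress(raw)
    except Exception as exc:
        report.failures.append(f"BGZF/gzip stream corrupt: {exc}")
        return report
    if len(data) < HEADER_PAYLOAD or data[:8] != MAGIC:
        report.failures.append("bad magic")
        return report
    version, index_voffset, index_len, meta_len = struct.unpack_from("<HQII", data, 8)
    if version != VERSION:
        report.failures.append(f"unsupported version {version}")
        return report
    try:
        meta = json.loads(data[26:26 + meta_len].decode())
    except Exception as exc:
        report.failures.append(f"header JSON corrupt: {exc}")
        return report
    body = data[HEADER_PAYLOAD:len(data) - index_len]
    try:
        index = json.loads(data[len(data) - index_len:].decode())
    except Exception as exc:
        report.failures.append(f"index corrupt: {exc}")
        index = None

    offset = 0
    for s in meta["strata"]:
        for chrom, clen in meta["chroms"]:
            total = 0
            while total < clen:
                if offset + _REC.size > len(body):
                    report.failures.append(f"truncated records in {s}/{chrom}")
                    return report
                _d, run = _REC.unpack_from(body, offset)
                offset += _REC.size
                total += run
            if total != clen:
                report.failures.append(
                    f"run lengths in {s}/{chrom} sum to {total}, expected {clen}"
                )
    if offset != len(body):
        report.failures.append(f"{len(body) - offset} trailing bytes after records")

    if index is not None:
        for s, per_chrom in index["anchors"].items():
            for chrom, alist in per_chrom.items():
                positions = [a[0] for a in alist]
                if positions != sorted(set(positions)):
                    report.failures.append(f"index anchors not strictly increasing in {s}/{chrom}")
                for _pos, voff in alist:
                    if (voff >> 16) >= len(raw):
                        report.failures.append(f"index anchor beyond EOF in {s}/{chrom}")
                        break
    return report


def write_bedgraph(cov_path, out_path, stratum: str = "unstranded") -> None:
    """Text bedGraph export of one stratum (interoperability helper)."""
    reader = CovReader(cov_path)
    with open(out_path, "w") as fh:
        for chrom in sorted(reader.chrom_lengths):
            depths = reader.query(stratum, chrom, 0, reader.chrom_lengths[chrom])
            from .bam_engine import rle_encode

            d, r = rle_encode(depths)
            pos = 0
            for depth, run in zip(d.tolist(), r.tolist()):
                if depth != 0:
                    fh.write(f"{chrom}\t{pos}\t{pos + run}\t{depth}\n")
                pos += run
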