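"""Single-pass BAM processing: junction counts, stranded coverage, IntronDepth.

Junction reads are spliced alignments whose CIGAR contains an N operation;
each N contributes one count to the junction keyed by the skipped interval.
Coverage counts aligned (M/=/X/D) bases only.  Read filters: unmapped,
secondary, supplementary, QC-fail and duplicate alignments are dropped;
MAPQ is not filtered by default (``min_mapq=0``).  Overlapping mate bases
are counted twice (no overlap clipping) for single-pass simplicity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pysam

logger = logging.getLogger(__name__)

PROTOCOLS = ("unstranded", "fr-firststrand", "fr-secondstrand")

# key: (chrom, intron_start, intron_end, strand) with strand in {+,-,.}
JunctionKey = tuple[str, int, int, str]


@dataclass
class JunctionCounts:
    """Per-sample junction-read counts keyed by skipped intron interval."""

    sample_id: str
    counts: dict[JunctionKey, int] = field(default_factory=dict)

    def add(self, key: JunctionKey, n: int = 1) -> None:
        self.counts[key] = self.counts.get(key, 0) + n

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class CoverageTrack:
    """Per-sample, per-stratum run-length encoded per-base depth.

    ``rle`` maps chrom -> (depths, run_lengths) arrays; runs are maximal and
    their lengths sum to the chromosome length.
    """

    sample_id: str
    stratum: str  # unstranded | plus | minus
    chrom_lengths: dict[str, int]
    rle: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_arrays(cls, sample_id, stratum, arrays: dict[str, np.ndarray]) -> "CoverageTrack":
        track = cls(sample_id, stratum, {c: len(a) for c, a in arrays.items()})
        for chrom, arr in arrays.items():
            track.rle[chrom] = rle_encode(arr)
        return track

    def depth_array(self, chrom: str, start: int = 0, end: int | None = None) -> np.ndarray:
        """Exact per-base depths over [start, end) of one chromosome."""
        if chrom not in self.chrom_lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        clen = self.chrom_lengths[chrom]
        if end is None:
            end = clen
        if not (0 <= start <= end <= clen):
            raise IndexError(f"interval [{start},{end}) outside chromosome {chrom} (len {clen})")
        depths, runs = self.rle.get(chrom, (np.zeros(1, np.int32), np.array([clen], np.int64)))
        return rle_slice(depths, runs, start, end)


def rle_encode(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximal run-length encoding of a 1-D depth array."""
    arr = np.asarray(arr)
    if arr.size == 0:
        return np.zeros(0, np.int32), np.zeros(0, np.int64)
    change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [arr.size]))
    return arr[starts].astype(np.int32), (ends - starts).astype(np.int64)


def rle_decode(depths: np.ndarray, runs: np.ndarray) -> np.ndarray:
    return np.repeat(depths, runs)


def rle_slice(depths: np.ndarray, runs: np.ndarray, start: int, end: int) -> np.ndarray:
    """Decode one slice of an RLE track without expanding the whole array."""
    if end <= start:
        return np.zeros(0, np.int32)
    bounds = np.cumsum(runs)
    i0 = int(np.searchsorted(bounds, start, side="right"))
    i1 = int(np.searchsorted(bounds, end - 1, side="right"))
    seg = rle_decode(depths[i0:i1 + 1], runs[i0:i1 + 1])
    seg_start = int(bounds[i0 - 1]) if i0 > 0 else 0
    return seg[start - seg_start:end - seg_start]


# ---------------------------------------------------------------------------
# read-level helpers
# ---------------------------------------------------------------------------

def _keep(read: pysam.AlignedSegment, min_mapq: int) -> bool:
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_qcfail
        or read.is_duplicate
        or read.mapping_quality < min_mapq
    )


def _read_strand(read: pysam.AlignedSegment, protocol: str) -> str:
    """Transcript strand implied by a read under a library protocol."""
    if protocol == "unstranded":
        return "."
    rev = read.is_reverse
    if read.is_paired and read.is_read2:
        rev = not rev  # mate-aware: read2 reports the opposite orientation
    if protocol == "fr-secondstrand":
        return "-" if rev else "+"
    return "+" if rev else "-"  # fr-firststrand: read antisense to transcript


def _iter_alignments(bam_path):
    try:
        af = pysam.AlignmentFile(str(bam_path), "rb" if str(bam_path).endswith(".bam") else "r")
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot open alignment file {bam_path!r}: {exc}") from exc
    if af.header.get("HD", {}).get("SO", "unknown") != "coordinate":
        logger.warning("%s is not flagged coordinate-sorted; run samtools sort/index", bam_path)
    return af


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def extract_junctions(bam_path, protocol: str = "unstranded", *,
                      sample_id: str | None = None, min_mapq: int = 0) -> JunctionCounts:
    """Count junction reads: one count per N CIGAR operation per alignment."""
    _check_protocol(protocol)
    jc = JunctionCounts(sample_id or str(bam_path))
    with _iter_alignments(bam_path) as af:
        for read in af:
            if not _keep(read, min_mapq):
                continue
            if "N" not in (read.cigarstring or ""):
                continue
            strand = _read_strand(read, protocol)
            pos = read.reference_start
            for op, length in read.cigartuples:
                if op in (0, 7, 8, 2):  # M, =, X, D advance the reference
                    pos += length
                elif op == 3:  # N: skipped intron
                    jc.add((read.reference_name, pos, pos + length, strand))
                    pos += length
    return jc


def compute_coverage(bam_path, protocol: str = "unstranded", *,
                     sample_id: str | None = None, min_mapq: int = 0) -> dict[str, CoverageTrack]:
    """Per-base alignment depth, stratified by strand for stranded protocols.

    Returns a dict of :class:`CoverageTrack` keyed by stratum.  The
    unstranded track is the pointwise sum of plus and minus for stranded
    protocols, and the sole stratum otherwise.
    """
    _check_protocol(protocol)
    jc, tracks, _ = _single_pass(bam_path, protocol, sample_id=sample_id, min_mapq=min_mapq)
    return tracks


def _single_pass(bam_path, protocol, *, sample_id=None, min_mapq=0):
    """One sweep over the BAM producing junction counts + coverage + QC."""
    _check_protocol(protocol)
    sid = sample_id or str(bam_path)
    jc = JunctionCounts(sid)
    with _iter_alignments(bam_path) as af:
        chrom_lengths = dict(zip(af.references, af.lengths))
        per_strand = {
            s: {c: np.zeros(l, np.int32) for c, l in chrom_lengths.items()}
            for s in (("+", "-") if protocol != "unstranded" else (".",))
        }
        n_total = n_junc = 0
        for read in af:
            if not _keep(read, min_mapq):
                continue
            n_total += 1
            strand = _read_strand(read, protocol)
            arr = per_strand[strand][read.reference_name]
            pos = read.reference_start
            has_junc = False
            for op, length in read.cigartuples:
                if op in (0, 7, 8, 2):  # aligned segment (deletions covered)
                    arr[pos:pos + length] += 1
                    pos += length
                elif op == 3:
                    jc.add((read.reference_name, pos, pos + length, strand))
                    has_junc = True
                    pos += length
            n_junc += has_junc

    tracks = {}
    if protocol == "unstranded":
        tracks["unstranded"] = CoverageTrack.from_arrays(sid, "unstranded", per_strand["."])
    else:
        tracks["plus"] = CoverageTrack.from_arrays(sid, "plus", per_strand["+"])
        tracks["minus"] = CoverageTrack.from_arrays(sid, "minus", per_strand["-"])
        combined = {c: per_strand["+"][c] + per_strand["-"][c] for c in chrom_lengths}
        tracks["unstranded"] = CoverageTrack.from_arrays(sid, "unstranded", combined)
    qc = {"total_reads": n_total, "junction_reads": n_junc, "protocol": protocol}
    return jc, tracks, qc


def intron_depth(track: CoverageTrack, chrom: str, intron: tuple[int, int],
                 trim_fraction: float = 0.30) -> float:
    """Trimmed mean of per-base depth across an intron (IntronDepth).

    The trim is symmetric: floor(trim_fraction/2 * n) bases are removed from
    each end of the sorted depth multiset.  If trimming empties the list the
    median is returned.
    """
    if not 0 <= trim_fraction < 1:
        raise ValueError("trim_fraction must be in [0, 1)")
    start, end = intron
    if end - start < 1:
        raise ValueError("intron length must be >= 1")
    d = np.sort(track.depth_array(chrom, start, end))
    k = int(np.floor(trim_fraction / 2 * d.size))
    kept = d[k:d.size - k]
    if kept.size == 0:
        return float(np.median(d))
    return float(kept.mean())


def infer_strandedness(bam_path, ref, *, max_reads: int = 20000, min_agreement: float = 0.9,
                       min_junction_reads: int = 1000) -> tuple[str, float]:
    """Infer the library protocol by comparing junction strands to annotation.

    Counts, over a sample of junction reads, how often the strand implied by
    the fr-firststrand hypothesis matches the annotated intron strand.
    Agreement > ``min_agreement`` calls fr-firststrand; agreement below
    1 - ``min_agreement`` calls fr-secondstrand; otherwise unstranded.
    """
    annotated: dict[tuple[str, int, int], str] = {}
    for m in ref.models:
        for _, exons in m.transcripts:
            for intr in m.introns(exons):
                annotated[(m.chrom, intr[0], intr[1])] = m.strand

    n = agree = 0
    with _iter_alignments(bam_path) as af:
        for read in af:
            if not _keep(read, 0) or "N" not in (read.cigarstring or ""):
                continue
            strand = _read_strand(read, "fr-firststrand")
            pos = read.reference_start
            for op, length in read.cigartuples:
                if op in (0, 7, 8, 2):
                    pos += length
                elif op == 3:
                    truth = annotated.get((read.reference_name, pos, pos + length))
                    if truth is not None:
                        n += 1
                        agree += strand == truth
                    pos += length
            if n >= max_reads:
                break
    if n < min_junction_reads:
        logger.warning("only %d annotated junction reads; defaulting to unstranded", n)
        return "unstranded", 0.5
    frac = agree / n
    if frac > min_agreement:
        return "fr-firststrand", frac
    if frac < 1 - min_agreement:
        return "fr-secondstrand", 1 - frac
    return "unstranded", max(frac, 1 - frac)


def write_junction_table(jc: JunctionCounts, path) -> None:
    """Plain TSV export: chrom, start, end, strand, count."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tcount\n")
        for (chrom, start, end, strand), n in sorted(jc.counts.items()):
            fh.write(f"{chrom}\t{start}\t{end}\t{strand}\t{n}\n")


def _check_protocol(protocol: str) -> None:
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; expected one of {PROTOCOLS}")
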