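"""Per-sample ASE quantification and collation into an experiment container.

PSI = Included / (Included + Excluded).  Junction-based isoforms use raw
junction-read counts (tandem isoforms: the mean of their two junctions);
retained introns use the trimmed-mean IntronDepth for the included isoform
and a spliced-abundance metric for the excluded isoform.  Three spliced
metrics are available for IR, in increasing inclusiveness:

* SpliceExact — count of the junction exactly spanning the intron;
* SpliceMax — max of the donor-sharing and acceptor-sharing junction sums;
* SpliceOver — max of the junction sums arising from the two flanking exon
  groups (the default; robust when neither splice site is shared with the
  major isoform).

Junction counts and IntronDepth are treated as commensurate depth units:
both approximate transcript depth at the locus.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bam_engine, cov_store
from .bam_engine import CoverageTrack, JunctionCounts
from .reference import ASEvent, ExonGroup, Reference

logger = logging.getLogger(__name__)

EXC_METRICS = ("spliceover", "splicemax", "spliceexact")


@dataclass
class EventQuant:
    """Quantification of one event in one sample."""

    event_id: str
    inc_count: float
    exc_count: float
    psi: float | None
    splice_exact: float = math.nan
    splice_max: float = math.nan
    splice_over: float = math.nan
    intron_depth: float = math.nan


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _strand_counts(jc: JunctionCounts, chrom: str, strand: str):
    """Junction counts on one chromosome consistent with an event's strand."""
    for (c, s, e, st), n in jc.counts.items():
        if c == chrom and st in (strand, "."):
            yield (s, e), n


def splice_metrics(jc: JunctionCounts, chrom: str, strand: str, intron: tuple[int, int],
                   left_group: ExonGroup, right_group: ExonGroup) -> tuple[float, float, float]:
    """(SpliceExact, SpliceMax, SpliceOver) for one intron.

    Donor coordinates are intron starts (== flanking exon ends), so group
    membership for the donor side is ``span.start < start <= span.end``;
    acceptor coordinates are intron ends (== exon starts), membership
    ``span.start <= end < span.end``.
    """
    ok_left = left_group.span[0] < intron[0] <= left_group.span[1]
    ok_right = right_group.span[0] <= intron[1] < right_group.span[1]
    if not (ok_left and ok_right and left_group.span[0] < right_group.span[0]):
        raise ValueError(
            f"exon groups {left_group.group_id}/{right_group.group_id} do not flank {intron}"
        )
    exact = donor = acceptor = left_sum = right_sum = 0
    ls, le = left_group.span
    rs, re_ = right_group.span
    for (s, e), n in _strand_counts(jc, chrom, strand):
        if (s, e) == intron:
            exact += n
        if s == intron[0]:
            donor += n
        if e == intron[1]:
            acceptor += n
        if ls < s <= le and e > intron[0]:
            left_sum += n
        if rs <= e < re_ and s < intron[1]:
            right_sum += n
    return float(exact), float(max(donor, acceptor)), float(max(left_sum, right_sum))


def ir_ratio(intron_depth: float, spliced_abundance: float) -> float | None:
    """IR-ratio = intronic / (intronic + spliced abundance); None when 0/0."""
    if intron_depth < 0 or spliced_abundance < 0:
        raise ValueError("abundances must be non-negative")
    denom = intron_depth + spliced_abundance
    if denom == 0:
        return None
    return intron_depth / denom


def _junction_count(jc: JunctionCounts, chrom: str, strand: str, j: tuple[int, int]) -> float:
    n = jc.counts.get((chrom, j[0], j[1], strand), 0)
    if strand != ".":
        n += jc.counts.get((chrom, j[0], j[1], "."), 0)
    return float(n)


def _isoform_count(jc: JunctionCounts, e: ASEvent, junctions) -> float:
    """Single junction count, or the mean of two for tandem isoforms."""
    vals = [_junction_count(jc, e.chrom, e.strand, j) for j in junctions]
    if not vals:
        return 0.0
    return float(np.mean(vals))


def quantify_event(e: ASEvent, jc: JunctionCounts, track: CoverageTrack,
                   groups: dict[str, ExonGroup], *, exc_metric: str = "spliceover",
                   trim_fraction: float = 0.30) -> EventQuant:
    """Quantify one event in one sample.

    Missing junction keys count as zero.  PSI is None (undefined) when
    included + excluded == 0.
    """
    if exc_metric not in EXC_METRICS:
        raise ValueError(f"exc_metric must be one of {EXC_METRICS}")
    if e.uses_intron_depth:
        idepth = bam_engine.intron_depth(track, e.chrom, e.region, trim_fraction)
        lg, rg = groups.get(e.left_group), groups.get(e.right_group)
        if lg is None or rg is None:
            raise KeyError(f"event {e.event_id}: flanking exon groups not in reference")
        se, sm, so = splice_metrics(jc, e.chrom, e.strand, e.region, lg, rg)
        exc = {"spliceover": so, "splicemax": sm, "spliceexact": se}[exc_metric]
        psi = ir_ratio(idepth, exc)
        return EventQuant(e.event_id, idepth, exc, psi,
                          splice_exact=se, splice_max=sm, splice_over=so, intron_depth=idepth)
    inc = _isoform_count(jc, e, e.inc_junctions)
    exc = _isoform_count(jc, e, e.exc_junctions)
    psi = inc / (inc + exc) if inc + exc > 0 else None
    return EventQuant(e.event_id, inc, exc, psi)


# ---------------------------------------------------------------------------
# per-sample processing
# ---------------------------------------------------------------------------

@dataclass
class SampleBundle:
    """Paths and QC for one processed sample."""

    sample_id: str
    directory: Path
    cov_path: Path
    qc: dict


def process_sample(bam_path, ref: Reference, out_dir, *, sample_id: str | None = None,
                   protocol: str = "infer", exc_metric: str = "spliceover",
                   min_mapq: int = 0) -> SampleBundle:
    """One pass over a BAM: junction table, EventQuants, ``.cov`` file, QC.

    ``protocol='infer'`` calls :func:`bam_engine.infer_strandedness` first.
    Outputs are deterministic for fixed inputs.
    """
    sid = sample_id or Path(bam_path).stem
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if protocol == "infer":
        protocol, confidence = bam_engine.infer_strandedness(bam_path, ref)
    else:
        confidence = None

    jc, tracks, qc = bam_engine._single_pass(bam_path, protocol,
                                             sample_id=sid, min_mapq=min_mapq)
    cov_path = out_dir / f"{sid}.cov"
    cov_store.write_cov(tracks, cov_path)
    bam_engine.write_junction_table(jc, out_dir / f"{sid}.junctions.tsv")

    stranded = protocol != "unstranded"
    rows = []
    for e in ref.events:
        track = tracks["plus" if e.strand == "+" else "minus"] if stranded else tracks["unstranded"]
        q = quantify_event(e, jc, track, ref.groups, exc_metric=exc_metric)
        rows.append([q.event_id, q.inc_count, q.exc_count,
                     math.nan if q.psi is None else q.psi,
                     q.splice_exact, q.splice_max, q.splice_over, q.intron_depth])
    quants = pd.DataFrame(rows, columns=["event_id", "inc", "exc", "psi",
                                         "splice_exact", "splice_max", "splice_over",
                                         "intron_depth"])
    quants.to_csv(out_dir / f"{sid}.quants.tsv", sep="\t", index=False, float_format="%.6g")

    qc.update({
        "sample_id": sid,
        "strandedness_confidence": confidence,
        "reference_checksum": ref.checksum,
        "exc_metric": exc_metric,
    })
    (out_dir / f"{sid}.qc.json").write_text(json.dumps(qc, indent=2, sort_keys=True) + "\n")
    return SampleBundle(sid, out_dir, cov_path, qc)


# ---------------------------------------------------------------------------
# experiment container
# ---------------------------------------------------------------------------

@dataclass
class Experiment:
    """Collated included/excluded count matrices plus per-event metrics.

    ``inc``/``exc`` are events x samples DataFrames; ``metrics`` is a long
    DataFrame (event_id, sample_id, splice_exact, splice_max, splice_over,
    intron_depth) for IR events; ``samples`` carries condition/batch
    annotations and .cov paths.
    """

    events: pd.DataFrame
    samples: pd.DataFrame
    inc: pd.DataFrame
    exc: pd.DataFrame
    metrics: pd.DataFrame = field(default_factory=pd.DataFrame)
    meta: dict = field(default_factory=dict)

    def psi(self) -> pd.DataFrame:
        """PSI per event/sample; NaN where included + excluded == 0."""
        denom = self.inc + self.exc
        return (self.inc / denom.where(denom > 0)).astype(float)

    def cov_path(self, sample_id: str) -> Path:
        return Path(self.samples.loc[sample_id, "cov_path"])

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, df in (("inc", self.inc), ("exc", self.exc)):
            df.to_csv(path / f"{name}.tsv.gz", sep="\t", compression={"method": "gzip", "mtime": 0})
        self.metrics.to_csv(path / "metrics.tsv.gz", sep="\t", index=False,
                            compression={"method": "gzip", "mtime": 0})
        self.samples.to_csv(path / "samples.tsv", sep="\t")
        self.events.to_csv(path / "events.tsv.gz", sep="\t",
                           compression={"method": "gzip", "mtime": 0})
        (path / "meta.json").write_text(json.dumps(self.meta, indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "Experiment":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        inc = pd.read_csv(path / "inc.tsv.gz", sep="\t", index_col=0)
        exc = pd.read_csv(path / "exc.tsv.gz", sep="\t", index_col=0)
        metrics = pd.read_csv(path / "metrics.tsv.gz", sep="\t")
        samples = pd.read_csv(path / "samples.tsv", sep="\t", index_col=0)
        samples.index = samples.index.astype(str)
        events = pd.read_csv(path / "events.tsv.gz", sep="\t", index_col=0)
        return cls(events=events, samples=samples, inc=inc, exc=exc, metrics=metrics, meta=meta)


class CollationError(RuntimeError):
    pass


def collate(bundles: list[SampleBundle], ref: Reference, out_path=None,
            sample_info: pd.DataFrame | None = None) -> Experiment:
    """Unify per-sample outputs into events x samples matrices.

    Refuses to mix bundles built against a different reference (verified by
    the events-file checksum recorded in each sample's QC).  ``sample_info``
    may carry condition/batch columns indexed by sample_id.
    """
    for b in bundles:
        if b.qc.get("reference_checksum") != ref.checksum:
            raise CollationError(
                f"sample {b.sample_id} was processed against a different reference"
            )
    sample_ids = [b.sample_id for b in bundles]
    if len(set(sample_ids)) != len(sample_ids):
        raise CollationError("duplicate sample ids")

    inc_cols, exc_cols, metric_rows = {}, {}, []
    for b in bundles:
        df = pd.read_csv(b.directory / f"{b.sample_id}.quants.tsv", sep="\t",
                         index_col="event_id")
        inc_cols[b.sample_id] = df["inc"]
        exc_cols[b.sample_id] = df["exc"]
        ir = df.dropna(subset=["intron_depth"])
        for eid, row in ir.iterrows():
            metric_rows.append([eid, b.sample_id, row["splice_exact"], row["splice_max"],
                                row["splice_over"], row["intron_depth"]])

    event_ids = [e.event_id for e in ref.events]
    inc = pd.DataFrame(inc_cols).reindex(event_ids)[sample_ids]
    exc = pd.DataFrame(exc_cols).reindex(event_ids)[sample_ids]
    metrics = pd.DataFrame(metric_rows, columns=["event_id", "sample_id", "splice_exact",
                                                 "splice_max", "splice_over", "intron_depth"])
    events = pd.DataFrame(
        {
            "type": [e.type for e in ref.events],
            "gene_id": [e.gene_id for e in ref.events],
            "chrom": [e.chrom for e in ref.events],
            "start": [e.region[0] for e in ref.events],
            "end": [e.region[1] for e in ref.events],
            "strand": [e.strand for e in ref.events],
            "tscore_eligible": [e.tscore_eligible for e in ref.events],
        },
        index=pd.Index(event_ids, name="event_id"),
    )
    samples = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    samples["cov_path"] = [str(b.cov_path) for b in bundles]
    samples["condition"] = ""
    samples["batch"] = ""
    if sample_info is not None:
        for col in sample_info.columns:
            samples.loc[sample_info.index.astype(str), col] = sample_info[col].values

    meta = {
        "format": "splicequant-experiment",
        "reference_checksum": ref.checksum,
        "exc_metric": bundles[0].qc.get("exc_metric", "spliceover"),
        "n_events": len(event_ids),
        "n_samples": len(sample_ids),
    }
    x = Experiment(events=events, samples=samples, inc=inc, exc=exc, metrics=metrics, meta=meta)
    if out_path is not None:
        x.save(out_path)
    return x


def reference_checksum(path) -> str:
    """Checksum of a reference bundle's event table (used to guard collation)."""
    return hashlib.sha256((Path(path) / "events.tsv.gz").read_bytes()).hexdigest()
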