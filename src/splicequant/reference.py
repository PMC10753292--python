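"""Splicing reference: gene models, exon groups and binary ASE annotation.

An alternative-splicing event (ASE) is a binary choice between an
*included* and an *excluded* isoform at one locus.  Seven basic forms are
annotated: skipped exons (SE), mutually exclusive exons (MXE), alternative
5'/3' splice sites (A5SS/A3SS), alternative first/last exons (AFE/ALE) and
intron retention (IR).  All internal coordinates are 0-based half-open on
the genome; GTF input is converted from its native 1-based inclusive form.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

FORMAT_VERSION = "1"

EVENT_TYPES = ("IR", "SE", "MXE", "A5SS", "A3SS", "AFE", "ALE")

Interval = tuple[int, int]


class GtfFormatError(ValueError):
    """Raised when a GTF record violates the expected structure."""


class ReferenceFormatError(ValueError):
    """Raised when a saved reference bundle cannot be loaded."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """All annotated transcripts of one gene on one chromosome/strand.

    ``transcripts`` maps transcript_id -> ordered tuple of exon intervals
    (disjoint, sorted by start).  Gaps between consecutive exons are the
    transcript's introns.
    """

    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[tuple[str, tuple[Interval, ...]], ...]

    def introns(self, exons: Sequence[Interval]) -> list[Interval]:
        return [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]

    @property
    def span(self) -> Interval:
        starts = [e[0] for _, exons in self.transcripts for e in exons]
        ends = [e[1] for _, exons in self.transcripts for e in exons]
        return (min(starts), max(ends))


@dataclass(frozen=True)
class ExonGroup:
    """A maximal genomic region occupied by mutually overlapping exons.

    Groups are the connected components of the exon-overlap graph of one
    gene; ``span`` is the union-hull of the member exons.
    """

    group_id: str
    chrom: str
    strand: str
    span: Interval
    member_exons: tuple[Interval, ...]


@dataclass(frozen=True)
class ASEvent:
    """One binary alternative-splicing event.

    ``region`` is the alternatively spliced region (the genomic difference
    between the included and excluded isoforms).  ``inc_junctions`` /
    ``exc_junctions`` are the intron intervals whose junction reads support
    each isoform.  IR events measure the included isoform by intronic
    coverage instead of junction reads (``uses_intron_depth``) and carry
    the ids of the two flanking exon groups for the SpliceOver metric.
    """

    event_id: str
    type: str
    gene_id: str
    chrom: str
    strand: str
    region: Interval
    inc_junctions: tuple[Interval, ...]
    exc_junctions: tuple[Interval, ...]
    left_group: str = ""
    right_group: str = ""
    uses_intron_depth: bool = False
    tandem: bool = False
    tscore_eligible: bool = True
    tscore_region: Interval | None = None


# ---------------------------------------------------------------------------
# GTF parsing
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def parse_gene_models(gtf_path) -> list[GeneModel]:
    """Parse exon features of a GTF file into :class:`GeneModel` objects.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    Features on strand ``.`` are dropped with a warning; single-exon
    transcripts are retained (they simply generate no junctions).
    Overlapping exons within one transcript raise :class:`GtfFormatError`;
    abutting exons (zero-length intron) are fused with a warning so that
    every remaining intron has length >= 1.
    """
    genes: dict[str, dict] = {}
    try:
        handle = _open_text(gtf_path)
    except OSError as exc:
        raise OSError(f"cannot read GTF {gtf_path!r}: {exc}") from exc
    with handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfFormatError(f"line {lineno}: expected 9 tab-separated fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            if strand not in ("+", "-"):
                logger.warning("line %d: dropping exon on unknown strand %r", lineno, strand)
                continue
            attr = dict(_ATTR_RE.findall(attrs))
            gene_id = attr.get("gene_id")
            tx_id = attr.get("transcript_id")
            if not gene_id:
                raise GtfFormatError(f"line {lineno}: exon without gene_id attribute")
            if not tx_id:
                raise GtfFormatError(f"line {lineno}: exon without transcript_id attribute")
            iv = (int(start) - 1, int(end))
            if iv[0] >= iv[1]:
                raise GtfFormatError(f"line {lineno}: empty exon interval")
            g = genes.setdefault(gene_id, {"chrom": chrom, "strand": strand, "tx": {}})
            if g["chrom"] != chrom or g["strand"] != strand:
                raise GtfFormatError(
                    f"line {lineno}: gene {gene_id} spans multiple chromosomes/strands"
                )
            g["tx"].setdefault(tx_id, []).append(iv)

    models = []
    for gene_id in sorted(genes):
        g = genes[gene_id]
        txs = []
        for tx_id in sorted(g["tx"]):
            exons = sorted(g["tx"][tx_id])
            merged: list[Interval] = []
            for iv in exons:
                if merged and iv[0] < merged[-1][1]:
                    raise GtfFormatError(
                        f"transcript {tx_id}: overlapping exons {merged[-1]} and {iv}"
                    )
                if merged and iv[0] == merged[-1][1]:
                    logger.warning("transcript %s: fusing abutting exons at %d", tx_id, iv[0])
                    merged[-1] = (merged[-1][0], iv[1])
                else:
                    merged.append(iv)
            txs.append((tx_id, tuple(merged)))
        models.append(
            GeneModel(gene_id=gene_id, chrom=g["chrom"], strand=g["strand"], transcripts=tuple(txs))
        )
    models.sort(key=lambda m: (m.chrom, m.span[0], m.gene_id))
    return models


# ---------------------------------------------------------------------------
# exon groups
# ---------------------------------------------------------------------------

def build_exon_groups(g: GeneModel) -> list[ExonGroup]:
    """Connected components of the exon-overlap graph of one gene.

    Exons overlap when their half-open intervals intersect; abutting exons
    (end == start) do not overlap.  Exons that fully span an intron of
    another transcript of the same gene (intron-retaining exons) are left
    out of the graph: including them would fuse the exon groups flanking
    every annotated retained intron and leave the SpliceOver metric without
    flanking groups.  Returned sorted by span start.
    """
    introns = {
        intr
        for tid, exons in g.transcripts
        for intr in g.introns(exons)
    }

    def _retaining(e: Interval) -> bool:
        return any(e[0] <= i0 and i1 <= e[1] for i0, i1 in introns)

    exons = sorted({e for _, exs in g.transcripts for e in exs if not _retaining(e)})
    groups: list[ExonGroup] = []
    cur: list[Interval] = []
    cur_end = -1
    idx = 0

    def _flush():
        nonlocal idx, cur
        if cur:
            span = (cur[0][0], cur_end)
            groups.append(
                ExonGroup(
                    group_id=f"{g.gene_id}:G{idx}",
                    chrom=g.chrom,
                    strand=g.strand,
                    span=span,
                    member_exons=tuple(cur),
                )
            )
            idx += 1
            cur = []

    for e in exons:
        if cur and e[0] < cur_end:
            cur.append(e)
            cur_end = max(cur_end, e[1])
        else:
            _flush()
            cur = [e]
            cur_end = e[1]
    _flush()
    return groups


def _group_of(groups: Sequence[ExonGroup], point_interval: Interval) -> ExonGroup | None:
    """Group whose span contains the given exon interval (groups disjoint)."""
    for grp in groups:
        if point_interval[0] >= grp.span[0] and point_interval[1] <= grp.span[1]:
            return grp
    return None


# ---------------------------------------------------------------------------
# polarity
# ---------------------------------------------------------------------------

def _spans_region(junctions: Iterable[Interval], region: Interval) -> bool:
    return any(j[0] <= region[0] and region[1] <= j[1] for j in junctions)


def _first_intron_len(junctions: Sequence[Interval], strand: str) -> int:
    """Length of the 5'-most junction in transcript orientation."""
    if strand == "-":
        j = max(junctions, key=lambda x: x[1])
    else:
        j = min(junctions, key=lambda x: x[0])
    return j[1] - j[0]


def assign_polarity(e: ASEvent) -> ASEvent:
    """Orient a candidate event so the Included isoform is well defined.

    For IR/SE/A5SS/A3SS the isoform with the larger alternatively spliced
    region (the one that expresses ``region``) is Included.  For MXE/AFE/ALE
    the isoform with the shorter first intron (5'-most in transcript
    orientation) is Included; ties break to the lexicographically smaller
    junction set and are logged.
    """
    if e.type in ("MXE", "AFE", "ALE"):
        li = _first_intron_len(e.inc_junctions, e.strand)
        le = _first_intron_len(e.exc_junctions, e.strand)
        if li > le or (li == le and sorted(e.inc_junctions) > sorted(e.exc_junctions)):
            if li == le:
                logger.info("event %s: first-intron tie broken by coordinates", e.event_id)
            return replace(e, inc_junctions=e.exc_junctions, exc_junctions=e.inc_junctions)
        return e
    if e.uses_intron_depth:  # IR: included isoform is coverage-measured
        return e
    inc_spans = _spans_region(e.inc_junctions, e.region)
    exc_spans = _spans_region(e.exc_junctions, e.region)
    if inc_spans and not exc_spans:
        return replace(e, inc_junctions=e.exc_junctions, exc_junctions=e.inc_junctions)
    if inc_spans == exc_spans:
        logger.info("event %s: degenerate polarity, tie broken by coordinates", e.event_id)
        if sorted(e.inc_junctions) > sorted(e.exc_junctions):
            return replace(e, inc_junctions=e.exc_junctions, exc_junctions=e.inc_junctions)
    return e


# ---------------------------------------------------------------------------
# ASE enumeration
# ---------------------------------------------------------------------------

def _annotate_gene(g: GeneModel, groups: list[ExonGroup], all_introns: bool) -> list[ASEvent]:
    tx = list(g.transcripts)
    intron_sets = {tid: tuple(g.introns(exons)) for tid, exons in tx}
    all_junc = {j for js in intron_sets.values() for j in js}
    exon_sets = {tid: set(exons) for tid, exons in tx}
    all_exons = {e for s in exon_sets.values() for e in s}
    events: list[ASEvent] = []
    seen: set[tuple] = set()

    def emit(ev: ASEvent):
        key = (ev.type, tuple(sorted(ev.inc_junctions)), tuple(sorted(ev.exc_junctions)), ev.region)
        if key in seen:
            return
        seen.add(key)
        events.append(assign_polarity(ev))

    base = dict(gene_id=g.gene_id, chrom=g.chrom, strand=g.strand)

    # --- IR: intron fully contained in an exon of another transcript
    for tid, exons in tx:
        for i, intr in enumerate(intron_sets[tid]):
            retained = any(
                e[0] <= intr[0] and intr[1] <= e[1]
                for otid, es in exon_sets.items()
                if otid != tid
                for e in es
            )
            if not (retained or all_introns):
                continue
            lg = _group_of(groups, exons[i])
            rg = _group_of(groups, exons[i + 1])
            emit(
                ASEvent(
                    event_id="",
                    type="IR",
                    region=intr,
                    inc_junctions=(),
                    exc_junctions=(intr,),
                    left_group=lg.group_id if lg else "",
                    right_group=rg.group_id if rg else "",
                    uses_intron_depth=True,
                    **base,
                )
            )

    # --- SE: tandem junctions around a middle exon vs the direct skip junction
    for tid, exons in tx:
        introns = intron_sets[tid]
        for i in range(len(introns) - 1):
            j1, j2 = introns[i], introns[i + 1]
            skip = (j1[0], j2[1])
            if skip in all_junc:
                emit(
                    ASEvent(
                        event_id="",
                        type="SE",
                        region=(j1[1], j2[0]),
                        inc_junctions=(j1, j2),
                        exc_junctions=(skip,),
                        tandem=True,
                        **base,
                    )
                )

    # --- MXE: two non-overlapping middle exons sharing both flanking boundaries
    middles = []  # (outer_start, outer_end, middle_exon, (j1, j2))
    for tid, exons in tx:
        introns = intron_sets[tid]
        for i in range(len(introns) - 1):
            j1, j2 = introns[i], introns[i + 1]
            middles.append((j1[0], j2[1], (j1[1], j2[0]), (j1, j2)))
    for a in range(len(middles)):
        for b in range(a + 1, len(middles)):
            s1, e1, m1, js1 = middles[a]
            s2, e2, m2, js2 = middles[b]
            if (s1, e1) != (s2, e2) or m1 == m2:
                continue
            if m1[1] <= m2[0] or m2[1] <= m1[0]:  # non-overlapping
                cooccur = any(m1 in es and m2 in es for es in exon_sets.values())
                if cooccur:
                    continue
                lo, hi = (m1, m2) if m1 < m2 else (m2, m1)
                emit(
                    ASEvent(
                        event_id="",
                        type="MXE",
                        region=(lo[0], hi[1]),
                        inc_junctions=js1,
                        exc_junctions=js2,
                        tandem=True,
                        **base,
                    )
                )

    # --- A5SS / A3SS: two junctions sharing exactly one boundary whose
    # exons at the differing boundary overlap (otherwise the pair belongs
    # to a mutually-exclusive-exon structure, not an alternative splice site)
    flanked = []  # (junction, donor exon, acceptor exon), deduplicated
    seen_j = set()
    for tid, exons in tx:
        for i, intr in enumerate(intron_sets[tid]):
            key = (intr, exons[i], exons[i + 1])
            if key not in seen_j:
                seen_j.add(key)
                flanked.append(key)

    def _overlap(e1: Interval, e2: Interval) -> bool:
        return e1[0] < e2[1] and e2[0] < e1[1]

    for a in range(len(flanked)):
        for b in range(a + 1, len(flanked)):
            ja, da, aa = flanked[a]
            jb, db, ab_ = flanked[b]
            if ja[1] == jb[1] and ja[0] != jb[0] and _overlap(da, db):
                # shared right boundary; differing left boundary
                lo, hi = (ja, jb) if ja[0] < jb[0] else (jb, ja)
                etype = "A5SS" if g.strand == "+" else "A3SS"
                emit(
                    ASEvent(
                        event_id="",
                        type=etype,
                        region=(lo[0], hi[0]),
                        inc_junctions=(hi,),
                        exc_junctions=(lo,),
                        **base,
                    )
                )
            elif ja[0] == jb[0] and ja[1] != jb[1] and _overlap(aa, ab_):
                lo, hi = (ja, jb) if ja[1] < jb[1] else (jb, ja)
                etype = "A3SS" if g.strand == "+" else "A5SS"
                emit(
                    ASEvent(
                        event_id="",
                        type=etype,
                        region=(lo[1], hi[1]),
                        inc_junctions=(lo,),
                        exc_junctions=(hi,),
                        **base,
                    )
                )

    # --- AFE / ALE: distinct terminal exons splicing into a shared exon group
    def _terminal(which: str):
        # which == "first": 5'-terminal exon in transcript orientation
        cands = []
        for tid, exons in tx:
            if len(exons) < 2:
                continue
            if (which == "first") == (g.strand == "+"):
                term, adj = exons[0], exons[1]
                jn = (exons[0][1], exons[1][0])
            else:
                term, adj = exons[-1], exons[-2]
                jn = (exons[-2][1], exons[-1][0])
            cands.append((term, adj, jn))
        return cands

    for which, etype in (("first", "AFE"), ("last", "ALE")):
        cands = _terminal(which)
        for a in range(len(cands)):
            for b in range(a + 1, len(cands)):
                t1, adj1, j1 = cands[a]
                t2, adj2, j2 = cands[b]
                if not (t1[1] <= t2[0] or t2[1] <= t1[0]):
                    continue  # overlapping terminal exons: A5SS/A3SS territory
                g1 = _group_of(groups, adj1)
                g2 = _group_of(groups, adj2)
                if g1 is None or g2 is None or g1.group_id != g2.group_id:
                    continue
                if j1 == j2:
                    continue
                lo, hi = (t1, t2) if t1 < t2 else (t2, t1)
                emit(
                    ASEvent(
                        event_id="",
                        type=etype,
                        region=(lo[0], hi[1]),
                        inc_junctions=(j1,),
                        exc_junctions=(j2,),
                        **base,
                    )
                )

    return events


def _tscore_eligibility(e: ASEvent, chrom_introns: dict[tuple[str, str], set[Interval]]):
    """Event-type eligibility for the per-nucleotide T-score, and the scored region.

    IR and SE are eligible (regions: intron / skipped exon).  MXE/AFE/ALE are
    excluded because their alternative regions are mutually exclusive.
    A5SS/A3SS are excluded when an annotated intron of an interfering
    transcript lies inside the inter-splice-site region.
    """
    if e.type in ("MXE", "AFE", "ALE"):
        return False, None, "mutually exclusive regions"
    if e.type in ("IR", "SE"):
        return True, e.region, ""
    own = set(e.inc_junctions) | set(e.exc_junctions)
    foreign = chrom_introns.get((e.chrom, e.strand), set())
    for intr in foreign:
        if intr in own:
            continue
        if intr[0] >= e.region[0] and intr[1] <= e.region[1]:
            return False, None, "interfering annotated intron in alternative region"
    return True, e.region, ""


def annotate_ases(models: Iterable[GeneModel], all_introns: bool = False) -> list[ASEvent]:
    """Enumerate binary ASEs across all gene models.

    IR events are restricted to annotated retained introns unless
    ``all_introns`` is set.  Event ids are deterministic:
    ``TYPE:gene:chrom:start-end`` with a ``/n`` suffix disambiguating
    multiple variants at one region.
    """
    models = list(models)
    chrom_introns: dict[tuple[str, str], set[Interval]] = {}
    for m in models:
        key = (m.chrom, m.strand)
        s = chrom_introns.setdefault(key, set())
        for _, exons in m.transcripts:
            s.update(m.introns(exons))

    events: list[ASEvent] = []
    for m in models:
        groups = build_exon_groups(m)
        events.extend(_annotate_gene(m, groups, all_introns))

    events.sort(key=lambda e: (e.chrom, e.region, e.type, e.inc_junctions, e.exc_junctions))
    counts: dict[str, int] = {}
    out = []
    for e in events:
        base_id = f"{e.type}:{e.gene_id}:{e.chrom}:{e.region[0]}-{e.region[1]}"
        n = counts.get(base_id, 0)
        counts[base_id] = n + 1
        eid = base_id if n == 0 else f"{base_id}/{n}"
        ok, tregion, _reason = _tscore_eligibility(e, chrom_introns)
        out.append(replace(e, event_id=eid, tscore_eligible=ok, tscore_region=tregion))
    return out


# ---------------------------------------------------------------------------
# reference bundle I/O
# ---------------------------------------------------------------------------

def _fmt_juncs(js: Sequence[Interval]) -> str:
    return ";".join(f"{a}-{b}" for a, b in js) or "."


def _parse_juncs(s: str) -> tuple[Interval, ...]:
    if s == ".":
        return ()
    return tuple(tuple(int(x) for x in part.split("-")) for part in s.split(";"))


def write_reference(
    events: Sequence[ASEvent],
    groups: Sequence[ExonGroup],
    models: Sequence[GeneModel],
    path,
    genome_build: str = "unknown",
) -> None:
    """Write the reference bundle: events, exon groups and abridged models.

    The bundle is a directory of gzipped TSVs plus ``meta.json``; output is
    byte-deterministic for a fixed input (fixed ordering, fixed mtime=0 in
    the gzip headers).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    def _gz(name: str, text: str) -> bytes:
        import io

        buf = io.BytesIO()
        with gzip.GzipFile(name, "wb", fileobj=buf, mtime=0) as fh:
            fh.write(text.encode())
        (path / name).write_bytes(buf.getvalue())
        return buf.getvalue()

    lines = ["\t".join(
        ["chrom", "start", "end", "event_id", "type", "strand", "gene_id",
         "inc_junctions", "exc_junctions", "left_group", "right_group",
         "uses_intron_depth", "tandem", "tscore_eligible", "tscore_region"]
    )]
    for e in events:
        tr = "." if e.tscore_region is None else f"{e.tscore_region[0]}-{e.tscore_region[1]}"
        lines.append("\t".join(map(str, [
            e.chrom, e.region[0], e.region[1], e.event_id, e.type, e.strand, e.gene_id,
            _fmt_juncs(e.inc_junctions), _fmt_juncs(e.exc_junctions),
            e.left_group or ".", e.right_group or ".",
            int(e.uses_intron_depth), int(e.tandem), int(e.tscore_eligible), tr,
        ])))
    events_gz = _gz("events.tsv.gz", "\n".join(lines) + "\n")

    glines = []
    for grp in sorted(groups, key=lambda x: (x.chrom, x.span, x.group_id)):
        glines.append("\t".join(map(str, [
            grp.chrom, grp.span[0], grp.span[1], grp.group_id, ".", grp.strand,
            _fmt_juncs(grp.member_exons),
        ])))
    _gz("exon_groups.bed.gz", "\n".join(glines) + ("\n" if glines else ""))

    mlines = ["\t".join(["gene_id", "transcript_id", "chrom", "strand", "exons"])]
    for m in models:
        for tid, exons in m.transcripts:
            mlines.append("\t".join([m.gene_id, tid, m.chrom, m.strand, _fmt_juncs(exons)]))
    _gz("models.tsv.gz", "\n".join(mlines) + "\n")

    meta = {
        "format": "splicequant-reference",
        "format_version": FORMAT_VERSION,
        "genome_build": genome_build,
        "n_events": len(events),
        "n_groups": len(groups),
        "n_genes": len(models),
        "events_sha256": hashlib.sha256(events_gz).hexdigest(),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


@dataclass
class Reference:
    """Loaded reference bundle."""

    events: list[ASEvent]
    groups: dict[str, ExonGroup]
    models: list[GeneModel]
    meta: dict

    @property
    def checksum(self) -> str:
        return self.meta["events_sha256"]

    def events_by_id(self) -> dict[str, ASEvent]:
        return {e.event_id: e for e in self.events}


def load_reference(path) -> Reference:
    """Load a bundle written by :func:`write_reference` (lossless round trip)."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise ReferenceFormatError(f"{path}: not a reference bundle (missing meta.json)")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise ReferenceFormatError(f"{path}: corrupted meta.json: {exc}") from exc
    if meta.get("format") != "splicequant-reference":
        raise ReferenceFormatError(f"{path}: unrecognized bundle format")
    if meta.get("format_version") != FORMAT_VERSION:
        raise ReferenceFormatError(
            f"{path}: format version {meta.get('format_version')!r} != {FORMAT_VERSION!r}"
        )

    events = []
    with gzip.open(path / "events.tsv.gz", "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            tr = row["tscore_region"]
            events.append(ASEvent(
                event_id=row["event_id"],
                type=row["type"],
                gene_id=row["gene_id"],
                chrom=row["chrom"],
                strand=row["strand"],
                region=(int(row["start"]), int(row["end"])),
                inc_junctions=_parse_juncs(row["inc_junctions"]),
                exc_junctions=_parse_juncs(row["exc_junctions"]),
                left_group="" if row["left_group"] == "." else row["left_group"],
                right_group="" if row["right_group"] == "." else row["right_group"],
                uses_intron_depth=bool(int(row["uses_intron_depth"])),
                tandem=bool(int(row["tandem"])),
                tscore_eligible=bool(int(row["tscore_eligible"])),
                tscore_region=None if tr == "." else tuple(int(x) for x in tr.split("-")),
            ))

    groups = {}
    with gzip.open(path / "exon_groups.bed.gz", "rt") as fh:
        for line in fh:
            chrom, start, end, gid, _score, strand, members = line.rstrip("\n").split("\t")
            groups[gid] = ExonGroup(
                group_id=gid, chrom=chrom, strand=strand,
                span=(int(start), int(end)), member_exons=_parse_juncs(members),
            )

    per_gene: dict[str, dict] = {}
    with gzip.open(path / "models.tsv.gz", "rt") as fh:
        fh.readline()
        for line in fh:
            gene_id, tid, chrom, strand, exons = line.rstrip("\n").split("\t")
            g = per_gene.setdefault(gene_id, {"chrom": chrom, "strand": strand, "tx": []})
            g["tx"].append((tid, _parse_juncs(exons)))
    models = [
        GeneModel(gene_id=gid, chrom=g["chrom"], strand=g["strand"], transcripts=tuple(g["tx"]))
        for gid, g in sorted(per_gene.items())
    ]
    models.sort(key=lambda m: (m.chrom, m.span[0], m.gene_id))
    return Reference(events=events, groups=groups, models=models, meta=meta)


def build_reference(gtf_path, out_path, all_introns: bool = False, genome_build: str = "unknown") -> Reference:
    """Parse a GTF, annotate ASEs and write the bundle; returns the loaded result."""
    models = parse_gene_models(gtf_path)
    groups = [grp for m in models for grp in build_exon_groups(m)]
    events = annotate_ases(models, all_introns=all_introns)
    write_reference(events, groups, models, out_path, genome_build=genome_build)
    return load_reference(out_path)
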