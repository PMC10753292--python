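"""Synthetic fixtures: toy genomes, read-level BAMs, count-level experiments.

Three layers, all pure functions of (scenario, seed):

* named toy gene scenarios, including a seven-transcript multi-isoform
  locus with a retained-intron transcript, an exact-splicing transcript,
  donor/acceptor-sharing variants, and two transcripts splicing from
  alternative flanking exons that share neither splice site of the intron
  of interest (the case the SpliceOver metric exists for);
* a read-level simulator that draws uniform fragments from transcripts in
  proportion to abundance x length and writes sorted, indexed BAMs with
  correct N CIGAR operations (no sequencing-error or GC-bias model);
* a count-level simulator drawing per-sample PSIs from a beta distribution
  and included counts from a binomial, with a labelled fraction of truly
  differential events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from . import reference as refmod
from .quantify import Experiment
from .reference import ASEvent, GeneModel, Reference

logger = logging.getLogger(__name__)

SCENARIOS = ("fig_multi_isoform", "simple_ir", "simple_se", "a5ss_interfering", "mxe")


@dataclass
class Scenario:
    """Deterministic toy genome: gene models plus per-sample abundances.

    ``abundances`` maps sample_id -> {transcript_id -> expected per-base
    depth}.  All randomness downstream is fixed by ``seed``.
    """

    name: str
    chrom_lengths: dict[str, int]
    models: list[GeneModel]
    abundances: dict[str, dict[str, float]] = field(default_factory=dict)
    read_length: int = 100
    paired: bool = False
    protocol: str = "unstranded"
    seed: int = 0

    def transcript_exons(self) -> dict[str, tuple]:
        return {tid: exons for m in self.models for tid, exons in m.transcripts}

    def build_reference(self, out_dir) -> Reference:
        models = self.models
        groups = [g for m in models for g in refmod.build_exon_groups(m)]
        events = refmod.annotate_ases(models)
        refmod.write_reference(events, groups, models, out_dir, genome_build=self.name)
        return refmod.load_reference(out_dir)

    def write_gtf(self, path) -> None:
        with open(path, "w") as fh:
            for m in self.models:
                for tid, exons in m.transcripts:
                    for s, t in exons:
                        fh.write(
                            f"{m.chrom}\ttoy\texon\t{s + 1}\t{t}\t.\t{m.strand}\t.\t"
                            f'gene_id "{m.gene_id}"; transcript_id "{tid}";\n'
                        )

    def write_fasta(self, path) -> None:
        rng = np.random.default_rng(self.seed)
        with open(path, "w") as fh:
            for chrom, clen in sorted(self.chrom_lengths.items()):
                seq = "".join(rng.choice(list("ACGT"), size=clen))
                fh.write(f">{chrom}\n")
                for i in range(0, clen, 70):
                    fh.write(seq[i:i + 70] + "\n")


def _gene(gene_id, chrom, strand, tx: dict[str, list[tuple[int, int]]]) -> GeneModel:
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand,
        transcripts=tuple((tid, tuple(exons)) for tid, exons in sorted(tx.items())),
    )


def make_scenario(name: str, abundances: dict[str, dict[str, float]] | None = None,
                  **kwargs) -> Scenario:
    """Build a named deterministic toy scenario.

    ``fig_multi_isoform``: transcripts RI (retained intron), A (exact
    splice), B/C/D (share one splice site of the intron of interest) and
    E/F (splice between the flanking exon groups sharing neither site).
    """
    chrom = "chrS"
    if name == "fig_multi_isoform":
        models = [_gene("G1", chrom, "+", {
            "RI": [(800, 2400)],
            "A": [(800, 1200), (2000, 2400)],
            "B": [(800, 1200), (2050, 2400)],
            "C": [(800, 1150), (2000, 2400)],
            "D": [(800, 1200), (2100, 2400)],
            "E": [(800, 1100), (2050, 2400)],
            "F": [(800, 1050), (2150, 2400)],
        })]
        clen = 3200
    elif name == "simple_ir":
        models = [_gene("G1", chrom, "+", {
            "spliced": [(800, 1200), (2000, 2400)],
            "retained": [(800, 2400)],
        })]
        clen = 3200
    elif name == "simple_se":
        models = [_gene("G1", chrom, "+", {
            "inc": [(800, 1200), (1600, 1900), (2300, 2700)],
            "exc": [(800, 1200), (2300, 2700)],
        })]
        clen = 3500
    elif name == "a5ss_interfering":
        models = [_gene("G1", chrom, "+", {
            "short": [(800, 1200), (2000, 2400)],
            "long": [(800, 1400), (2000, 2400)],
            "interferer": [(800, 1250), (1350, 2400)],
        })]
        clen = 3200
    elif name == "mxe":
        models = [_gene("G1", chrom, "+", {
            "iso1": [(800, 1200), (1600, 1900), (2600, 3000)],
            "iso2": [(800, 1200), (2100, 2400), (2600, 3000)],
        })]
        clen = 3800
    else:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    if abundances is None:
        tids = [tid for m in models for tid, _ in m.transcripts]
        abundances = {"s1": {tid: 10.0 for tid in tids}}
    return Scenario(name=name, chrom_lengths={chrom: clen}, models=models,
                    abundances=abundances, **kwargs)


def ir_panel(n_events: int, n_per_group: int, *, depth: float = 50.0,
             psi_base_range: tuple[float, float] = (0.05, 0.35),
             dpsi_range: tuple[float, float] = (0.10, 0.30),
             diff_fraction: float = 0.10, precision: float = 100.0,
             mirror: bool = False, seed: int = 0) -> tuple[Scenario, pd.DataFrame]:
    """Panel of independent retained-intron genes with labelled differential IR.

    Each gene is a two-isoform locus (spliced/retained).  Group mean PSIs
    are drawn from ``psi_base_range``; a ``diff_fraction`` of events also
    get a PSI shift from ``dpsi_range`` in group B.  Per-sample PSIs are
    beta-distributed around the group mean; the default precision of 100
    corresponds to a replicate-to-replicate PSI standard deviation of
    about 0.03-0.04 at low PSI, in line with the high replicate
    concordance reported for intron retention in bulk RNA-seq.  Isoform
    depths are ``depth * psi`` (retained) and ``depth * (1 - psi)``
    (spliced).  ``mirror`` reflects the drawn PSIs to ``1 - psi``, building
    a high-PSI panel that is the exact reflection of the low-PSI one.
    """
    rng = np.random.default_rng(seed)
    stride, intron_len, exon_len = 2000, 800, 400
    chrom = "chrP"
    models, rows = [], []
    n_diff = int(round(diff_fraction * n_events))
    samples = [f"A{i + 1}" for i in range(n_per_group)] + \
              [f"B{i + 1}" for i in range(n_per_group)]
    abundances: dict[str, dict[str, float]] = {s: {} for s in samples}
    for i in range(n_events):
        o = 800 + i * stride
        gid = f"G{i:04d}"
        sp, rt = f"{gid}.spliced", f"{gid}.retained"
        models.append(_gene(gid, chrom, "+", {
            sp: [(o, o + exon_len), (o + exon_len + intron_len, o + 2 * exon_len + intron_len)],
            rt: [(o, o + 2 * exon_len + intron_len)],
        }))
        psi_a = rng.uniform(*psi_base_range)
        is_diff = i < n_diff
        psi_b = psi_a + (rng.uniform(*dpsi_range) if is_diff else 0.0)
        for s in samples:
            mean = psi_b if (is_diff and s.startswith("B")) else psi_a
            psi = rng.beta(mean * precision, (1 - mean) * precision)
            if mirror:
                # exact reflection of the low-PSI panel: identical seeds give
                # identical realized PSIs mirrored to 1 - psi, so the two
                # panels differ only in how coverage encodes the same signal
                psi = 1.0 - psi
            abundances[s][rt] = depth * psi
            abundances[s][sp] = depth * (1 - psi)
        rows.append([gid, o + exon_len, o + exon_len + intron_len, is_diff,
                     (1 - psi_a) if mirror else psi_a, (1 - psi_b) if mirror else psi_b])
    truth = pd.DataFrame(rows, columns=["gene_id", "intron_start", "intron_end",
                                        "differential", "psi_A", "psi_B"])
    scenario = Scenario(
        name="ir_panel_high" if mirror else "ir_panel_low",
        chrom_lengths={chrom: 800 + n_events * stride + 1000},
        models=models, abundances=abundances, seed=seed,
    )
    return scenario, truth


# ---------------------------------------------------------------------------
# ground truth PSI
# ---------------------------------------------------------------------------

def true_event_psi(s: Scenario, e: ASEvent, sample_id: str) -> float | None:
    """Ground-truth PSI of one event from the known transcript abundances.

    IR: sum of abundances of transcripts whose exon spans the intron over
    that plus the abundance of transcripts spliced across the region from
    the flanking exon groups.  Other events: included-compatible abundance
    over total compatible abundance.  None when no transcript is compatible.
    """
    ab = s.abundances[sample_id]
    exons_of = s.transcript_exons()
    models = {m.gene_id: m for m in s.models}
    g = models[e.gene_id]
    introns_of = {tid: set(g.introns(exons)) for tid, exons in g.transcripts}

    if e.uses_intron_depth:
        retained = sum(
            ab.get(tid, 0.0)
            for tid, exons in g.transcripts
            if any(x0 <= e.region[0] and e.region[1] <= x1 for x0, x1 in exons)
        )
        spliced = sum(
            ab.get(tid, 0.0)
            for tid, introns in introns_of.items()
            if any(j0 <= e.region[0] and e.region[1] <= j1 for j0, j1 in introns)
        )
        total = retained + spliced
        return retained / total if total > 0 else None

    inc = sum(ab.get(tid, 0.0) for tid, intr in introns_of.items()
              if set(e.inc_junctions) <= intr)
    exc = sum(ab.get(tid, 0.0) for tid, intr in introns_of.items()
              if set(e.exc_junctions) <= intr)
    total = inc + exc
    return inc / total if total > 0 else None


# ---------------------------------------------------------------------------
# read-level simulation
# ---------------------------------------------------------------------------

def _tx_to_genome_cigar(exons, tx_start: int, read_len: int):
    """Genome start + CIGAR tuples for a read at transcript offset tx_start."""
    blocks = []
    remaining = read_len
    pos = tx_start
    genome_start = None
    for (es, ee) in exons:
        elen = ee - es
        if pos >= elen:
            pos -= elen
            continue
        take = min(elen - pos, remaining)
        gstart = es + pos
        if genome_start is None:
            genome_start = gstart
        blocks.append((gstart, take))
        remaining -= take
        pos = 0
        if remaining == 0:
            break
    if remaining > 0:
        raise ValueError("read extends past transcript end")
    cigar = []
    for i, (gs, ln) in enumerate(blocks):
        if i > 0:
            gap = gs - (blocks[i - 1][0] + blocks[i - 1][1])
            cigar.append((3, gap))  # N
        cigar.append((0, ln))  # M
    return genome_start, cigar


def simulate_reads(s: Scenario, out_dir, *, seed: int | None = None) -> dict[str, Path]:
    """Write one sorted, indexed BAM per sample plus a ground-truth table.

    Reads per transcript: ``round(abundance * (length - read_length + 1) /
    read_length)`` with uniform start positions, so interior per-base depth
    and junction counts both approximate the abundance in depth units.  Transcripts shorter
    than the read length are skipped with a warning.  Deterministic per
    seed (defaults to ``s.seed``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(s.seed if seed is None else seed)
    exons_of = s.transcript_exons()
    strand_of = {tid: m.strand for m in s.models for tid, _ in m.transcripts}
    chroms = sorted(s.chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": s.chrom_lengths[c]} for c in chroms],
    }
    chrom_of = {tid: m.chrom for m in s.models for tid, _ in m.transcripts}
    tid_index = {c: i for i, c in enumerate(chroms)}

    bam_paths = {}
    for sample_id in sorted(s.abundances):
        reads = []
        for tid in sorted(s.abundances[sample_id]):
            ab = s.abundances[sample_id][tid]
            exons = exons_of[tid]
            L = sum(e - b for b, e in exons)
            if L < s.read_length:
                if ab > 0:
                    logger.warning("transcript %s shorter than read length; skipped", tid)
                continue
            n = int(round(ab * (L - s.read_length + 1) / s.read_length))
            if n <= 0:
                continue
            starts = rng.integers(0, L - s.read_length + 1, size=n)
            if s.protocol == "unstranded":
                flips = rng.integers(0, 2, size=n).astype(bool)
            elif s.protocol == "fr-firststrand":
                flips = np.full(n, strand_of[tid] == "+")  # read antisense
            else:
                flips = np.full(n, strand_of[tid] == "-")
            for k, (st, fl) in enumerate(zip(starts.tolist(), flips.tolist())):
                gstart, cigar = _tx_to_genome_cigar(exons, st, s.read_length)
                reads.append((tid_index[chrom_of[tid]], gstart, tuple(cigar), fl,
                              f"{tid}.{k}"))
        reads.sort()
        bam_path = out_dir / f"{sample_id}.bam"
        with pysam.AlignmentFile(bam_path, "wb", header=header) as bam:
            for ref_id, gstart, cigar, rev, qname in reads:
                a = pysam.AlignedSegment(bam.header)
                a.query_name = qname
                a.reference_id = ref_id
                a.reference_start = gstart
                a.cigartuples = list(cigar)
                a.mapping_quality = 60
                a.flag = 16 if rev else 0
                a.query_sequence = "A" * s.read_length
                bam.write(a)
        pysam.index(str(bam_path))
        bam_paths[sample_id] = bam_path

    events = refmod.annotate_ases(s.models)
    rows = []
    for e in events:
        for sample_id in sorted(s.abundances):
            psi = true_event_psi(s, e, sample_id)
            rows.append([e.event_id, sample_id, np.nan if psi is None else psi])
    pd.DataFrame(rows, columns=["event_id", "sample_id", "true_psi"]).to_csv(
        out_dir / "truth.tsv", sep="\t", index=False, float_format="%.6g")
    return bam_paths


# ---------------------------------------------------------------------------
# count-level simulation
# ---------------------------------------------------------------------------

def _default_depth(rng: np.random.Generator, size: int) -> np.ndarray:
    return 50 + rng.poisson(20, size=size)


def simulate_count_experiment(n_events: int, n_per_group: int, *,
                              depth_dist=None, beta_precision: float = 30.0,
                              diff_fraction: float = 0.10, min_dpsi: float = 0.10,
                              max_dpsi: float = 0.40,
                              seed: int = 0) -> tuple[Experiment, pd.DataFrame]:
    """Count-level beta-PSI simulation with labelled differential events.

    Per event, group mean PSIs are drawn uniformly; the first
    ``round(diff_fraction * n_events)`` events receive a group-B shift of at
    least ``min_dpsi``.  Per sample, PSI ~ Beta around the group mean with
    the given precision (infinite precision degenerates to the mean),
    total N ~ ``depth_dist``, Included ~ Binomial(N, PSI).
    """
    if not 0 <= diff_fraction <= 1:
        raise ValueError("diff_fraction must be in [0, 1]")
    if beta_precision <= 0:
        raise ValueError("beta_precision must be positive")
    if not 0 < min_dpsi <= max_dpsi:
        raise ValueError("need 0 < min_dpsi <= max_dpsi")
    rng = np.random.default_rng(seed)
    depth_dist = depth_dist or _default_depth
    n_diff = int(round(diff_fraction * n_events))
    samples = [f"A{i + 1}" for i in range(n_per_group)] + \
              [f"B{i + 1}" for i in range(n_per_group)]
    group_b = np.array([s.startswith("B") for s in samples])

    psi_a = rng.uniform(0.05, 0.95, size=n_events)
    delta = np.zeros(n_events)
    if n_diff:
        mag = rng.uniform(min_dpsi, max_dpsi, size=n_diff)
        sign = rng.choice([-1.0, 1.0], size=n_diff)
        headroom_up = 0.98 - psi_a[:n_diff]
        headroom_dn = psi_a[:n_diff] - 0.02
        sign = np.where(mag > np.where(sign > 0, headroom_up, headroom_dn), -sign, sign)
        mag = np.minimum(mag, np.where(sign > 0, headroom_up, headroom_dn))
        mag = np.maximum(mag, min_dpsi)
        delta[:n_diff] = sign * mag
    psi_b = np.clip(psi_a + delta, 0.01, 0.99)

    inc = np.zeros((n_events, len(samples)))
    exc = np.zeros((n_events, len(samples)))
    psi_sample = np.zeros((n_events, len(samples)))
    for j, is_b in enumerate(group_b):
        mean = np.where(is_b, psi_b, psi_a)
        if np.isinf(beta_precision):
            psi = mean
        else:
            psi = rng.beta(mean * beta_precision, (1 - mean) * beta_precision)
        n = depth_dist(rng, n_events)
        m = rng.binomial(n, psi)
        inc[:, j] = m
        exc[:, j] = n - m
        psi_sample[:, j] = psi

    ids = pd.Index([f"EV{i:05d}" for i in range(n_events)], name="event_id")
    events = pd.DataFrame({"type": "SE", "gene_id": [f"G{i:05d}" for i in range(n_events)],
                           "chrom": "chrC", "start": 0, "end": 1, "strand": "+",
                           "tscore_eligible": True}, index=ids)
    sdf = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    sdf["cov_path"] = ""
    sdf["condition"] = np.where(group_b, "B", "A")
    sdf["batch"] = ""
    x = Experiment(
        events=events, samples=sdf,
        inc=pd.DataFrame(inc, index=ids, columns=samples),
        exc=pd.DataFrame(exc, index=ids, columns=samples),
        metrics=pd.DataFrame(columns=["event_id", "sample_id", "splice_exact",
                                      "splice_max", "splice_over", "intron_depth"]),
        meta={"format": "splicequant-experiment", "simulated": True, "seed": seed},
    )
    realized_a = psi_sample[:, ~group_b].mean(axis=1)
    realized_b = psi_sample[:, group_b].mean(axis=1)
    truth = pd.DataFrame({
        "differential": delta != 0, "psi_A": psi_a, "psi_B": psi_b,
        "delta_psi": psi_b - psi_a,
        # realized group means of the drawn per-sample PSIs: the quantity an
        # estimator of group mean PSI actually targets at finite n
        "psi_A_realized": realized_a, "psi_B_realized": realized_b,
        "delta_psi_realized": realized_b - realized_a,
    }, index=ids)
    return x, truth
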