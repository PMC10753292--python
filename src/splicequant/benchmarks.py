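"""Self-contained benchmark computations on synthetic data.

Each function regenerates its inputs from a seed, runs the relevant slice
of the pipeline and returns summary metrics.  They back both the
acceptance script and the acceptance test suite; problem sizes are chosen
so every benchmark completes in minutes on one CPU while keeping the
summary statistics stable (see the methods note).
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import bam_engine, cov_store, covplot, differential, quantify, simdata
from .util import auroc


def _workdir(base=None) -> Path:
    return Path(base) if base is not None else Path(tempfile.mkdtemp(prefix="sqbench"))


def _process_panel(scenario, seed, workdir):
    ref = scenario.build_reference(workdir / "ref")
    bams = simdata.simulate_reads(scenario, workdir / "sim", seed=seed)
    bundles = [
        quantify.process_sample(bam, ref, workdir / "proc" / sid, sample_id=sid,
                                protocol="unstranded")
        for sid, bam in bams.items()
    ]
    n_per_group = len(bams) // 2
    info = pd.DataFrame(
        {"condition": ["A"] * n_per_group + ["B"] * n_per_group},
        index=pd.Index(sorted(bams), name="sample_id"),
    )
    x = quantify.collate(bundles, ref, sample_info=info)
    return ref, x


# ---------------------------------------------------------------------------
# 1. splice-metric correctness on the multi-isoform locus
# ---------------------------------------------------------------------------

def splice_metric_benchmark(seed: int, n_samples: int = 3, scale: float = 30.0) -> dict:
    """IR-ratio error of SpliceOver vs SpliceMax with alternative-flank isoforms.

    Expresses the retained-intron transcript with the exact-splicing
    transcript plus the two transcripts that splice between the flanking
    exon groups without sharing either splice site (true IR-ratio 0.2), and
    measures the absolute IR-ratio error under each spliced-abundance
    metric, averaged over samples.  Also verifies the metric ordering
    SpliceOver >= SpliceMax >= SpliceExact on every IR event and sample.
    """
    work = _workdir()
    ab = {f"s{i}": {"RI": scale, "A": 2 * scale, "E": scale, "F": scale,
                    "B": 0.0, "C": 0.0, "D": 0.0} for i in range(1, n_samples + 1)}
    s = simdata.make_scenario("fig_multi_isoform", abundances=ab, seed=seed)
    ref = s.build_reference(work / "ref")
    bams = simdata.simulate_reads(s, work / "sim", seed=seed)
    truth = 0.2
    so_err, sm_err, ordering_ok = [], [], True
    for sid, bam in bams.items():
        quantify.process_sample(bam, ref, work / sid, sample_id=sid, protocol="unstranded")
        q = pd.read_csv(work / sid / f"{sid}.quants.tsv", sep="\t", index_col="event_id")
        ir = q.dropna(subset=["intron_depth"])
        ordering_ok &= bool(
            ((ir.splice_over >= ir.splice_max - 1e-9)
             & (ir.splice_max >= ir.splice_exact - 1e-9)).all()
        )
        r = q.loc["IR:G1:chrS:1200-2000"]
        so_err.append(abs(r.intron_depth / (r.intron_depth + r.splice_over) - truth))
        sm_err.append(abs(r.intron_depth / (r.intron_depth + r.splice_max) - truth))
    return {
        "true_ir_ratio": truth,
        "spliceover_abs_error": float(np.mean(so_err)),
        "splicemax_abs_error": float(np.mean(sm_err)),
        "metric_ordering_ok": bool(ordering_ok),
        "n": n_samples,
    }


# ---------------------------------------------------------------------------
# 2. coverage normalization anchoring
# ---------------------------------------------------------------------------

def anchoring_benchmark(seed: int, n_samples: int = 3, depth: float = 60.0,
                        psi: float = 0.2) -> dict:
    """Normalized-coverage anchoring on a two-isoform IR locus.

    Flanking-exon normalized coverage should sit at 1; mean normalized
    intron coverage should match the junction-based IR-ratio.
    """
    work = _workdir()
    ab = {f"s{i}": {"spliced": depth * (1 - psi), "retained": depth * psi}
          for i in range(1, n_samples + 1)}
    s = simdata.make_scenario("simple_ir", abundances=ab, seed=seed)
    ref = s.build_reference(work / "ref")
    bams = simdata.simulate_reads(s, work / "sim", seed=seed)
    e = next(ev for ev in ref.events if ev.type == "IR")
    flank_means, intron_vs_ratio = [], []
    for sid, bam in bams.items():
        b = quantify.process_sample(bam, ref, work / sid, sample_id=sid,
                                    protocol="unstranded")
        q = pd.read_csv(work / sid / f"{sid}.quants.tsv", sep="\t",
                        index_col="event_id").loc[e.event_id]
        factor, _ = covplot.normalization_factor(
            e, q.inc, q.exc, splice_over=q.splice_over, intron_depth=q.intron_depth)
        reader = cov_store.CovReader(b.cov_path)
        window = covplot.event_window(e, reader.chrom_lengths[e.chrom], 100)
        tr = covplot.normalized_coverage(
            reader.query("unstranded", e.chrom, *window), e, sid, factor, window)
        flank = np.r_[tr.values[:100], tr.values[-100:]]
        flank_means.append(flank.mean())
        intron_vs_ratio.append(abs(tr.values[100:-100].mean() - q.psi))
    return {
        "flank_norm_coverage": float(np.mean(flank_means)),
        "intron_cov_vs_ir_ratio_absdiff": float(np.mean(intron_vs_ratio)),
        "depth": depth,
        "n": n_samples,
    }


# ---------------------------------------------------------------------------
# 3. T-score discrimination
# ---------------------------------------------------------------------------

def tscore_panel_benchmark(seed: int, n_events: int = 300, n_per_group: int = 3,
                           depth: float = 50.0) -> dict:
    """Event T-score AUROC on low-PSI and mirrored high-PSI IR panels.

    10% of events are truly differential (dPSI in [0.1, 0.3], baseline PSI
    below 0.5); the high-PSI panel is the exact reflection of the low-PSI
    one, isolating the asymmetry of coverage-based visualization.
    """
    out = {}
    for mirror, label in ((False, "low_psi"), (True, "high_psi")):
        work = _workdir()
        s, truth = simdata.ir_panel(n_events, n_per_group, depth=depth,
                                    mirror=mirror, seed=seed)
        ref, x = _process_panel(s, seed + 1, work)
        ir_events = {(e.region[0], e.region[1]): e for e in ref.events if e.type == "IR"}
        scores, labels = [], []
        for _, row in truth.iterrows():
            e = ir_events[(row.intron_start, row.intron_end)]
            scores.append(covplot.event_tscore(x, e, "A", "B").event_tscore)
            labels.append(bool(row.differential))
        out[f"tscore_auroc_{label}"] = auroc(labels, scores)
    out["n"] = n_events
    return out


# ---------------------------------------------------------------------------
# 4. statistical calibration under the null
# ---------------------------------------------------------------------------

def null_calibration_benchmark(seed: int, n_events: int = 2000,
                               n_per_group: int = 3) -> dict:
    """Type-I error and p-value uniformity of both differential methods."""
    x, _ = simdata.simulate_count_experiment(n_events, n_per_group,
                                             diff_fraction=0.0, seed=seed)
    design = differential.DesignSpec(condition=x.samples["condition"].to_dict(),
                                     contrast=("A", "B"))
    mask = differential.filter_events(x, design)
    out = {"n": n_events}
    for name, res in (
        ("glm", differential.fit_interaction_glm(x, design, mask=mask)),
        ("betabin", differential.fit_betabin(x, ("A", "B"), mask=mask)),
    ):
        p = res["p"].dropna().to_numpy()
        out[f"{name}_null_rejection_rate"] = float((p < 0.05).mean())
        out[f"{name}_null_ks"] = float(stats.kstest(p, "uniform").statistic)
    return out


# ---------------------------------------------------------------------------
# 5. power and dPSI recovery
# ---------------------------------------------------------------------------

def power_benchmark(seed: int, n_events: int = 2000, n_per_group: int = 3) -> dict:
    """Ranking AUROC and dPSI recovery on a 10%-differential count panel."""
    x, truth = simdata.simulate_count_experiment(n_events, n_per_group,
                                                 diff_fraction=0.10, seed=seed)
    design = differential.DesignSpec(condition=x.samples["condition"].to_dict(),
                                     contrast=("A", "B"))
    mask = differential.filter_events(x, design)
    out = {"n": n_events}
    for name, res in (
        ("glm", differential.fit_interaction_glm(x, design, mask=mask)),
        ("betabin", differential.fit_betabin(x, ("A", "B"), mask=mask)),
    ):
        r = res.dropna(subset=["p"])
        labels = truth.loc[r.index, "differential"].to_numpy()
        out[f"{name}_power_auroc"] = auroc(labels, -r["p"].to_numpy())
        out[f"{name}_mean_abs_dpsi_error"] = float(
            np.abs(r["delta_psi"] - truth.loc[r.index, "delta_psi_realized"]).mean())
    return out


# ---------------------------------------------------------------------------
# 6. coverage-format fidelity
# ---------------------------------------------------------------------------

def _random_tracks(rng, chroms):
    tracks = {}
    for stratum in ("unstranded", "plus", "minus"):
        arrays = {}
        for chrom, clen in chroms.items():
            vals = rng.integers(0, 50, size=max(clen // 5, 1))
            runs = rng.integers(1, 12, size=vals.size)
            arr = np.repeat(vals, runs)[:clen].astype(np.int32)
            if arr.size < clen:
                arr = np.concatenate([arr, np.zeros(clen - arr.size, np.int32)])
            arrays[chrom] = arr
        tracks[stratum] = bam_engine.CoverageTrack.from_arrays("b", stratum, arrays)
    return tracks


def cov_format_benchmark(seed: int, n_tracks: int = 200) -> dict:
    """Roundtrip exactness, binned-mean oracle agreement, corruption detection."""
    rng = np.random.default_rng(seed)
    work = _workdir()
    mismatches = 0
    max_bin_err = 0.0
    for t in range(n_tracks):
        clen = int(rng.integers(50, 5000))
        chroms = {"c": clen}
        tracks = _random_tracks(rng, chroms)
        path = work / f"t{t}.cov"
        cov_store.write_cov(tracks, path, spacing=int(rng.choice([256, 1024, 16384])))
        reader = cov_store.CovReader(path)
        for stratum in ("unstranded", "plus", "minus"):
            want = tracks[stratum].depth_array("c")
            if not np.array_equal(reader.query(stratum, "c", 0, clen), want):
                mismatches += 1
            a, b = sorted(int(v) for v in rng.integers(0, clen + 1, 2))
            if not np.array_equal(reader.query(stratum, "c", a, b), want[a:b]):
                mismatches += 1
        if clen >= 64:
            n_bins = int(rng.integers(1, min(64, clen)))
            got = reader.binned_means("unstranded", "c", 0, clen, n_bins)
            d = tracks["unstranded"].depth_array("c").astype(float)
            width = clen // n_bins
            brute = np.array([
                d[i * width:(i + 1) * width].mean() if i < n_bins - 1
                else d[(n_bins - 1) * width:].mean()
                for i in range(n_bins)
            ])
            max_bin_err = max(max_bin_err, float(np.abs(got - brute).max()))

    # corruption classes: truncation, mid-stream bit flip, missing EOF
    tracks = _random_tracks(rng, {"c": 30000})
    path = work / "corrupt_base.cov"
    cov_store.write_cov(tracks, path)
    raw = path.read_bytes()
    detected = 0
    (work / "c1.cov").write_bytes(raw[: len(raw) * 2 // 3])
    detected += not cov_store.validate_cov(work / "c1.cov").ok
    flipped = bytearray(raw)
    flipped[len(raw) // 2] ^= 0xFF
    (work / "c2.cov").write_bytes(bytes(flipped))
    detected += not cov_store.validate_cov(work / "c2.cov").ok
    (work / "c3.cov").write_bytes(raw[:-28])
    detected += not cov_store.validate_cov(work / "c3.cov").ok
    return {
        "roundtrip_mismatches": mismatches,
        "binned_means_max_abs_error": max_bin_err,
        "corruption_classes_detected": detected,
        "n": n_tracks,
    }


# ---------------------------------------------------------------------------
# 7. oracle equivalence
# ---------------------------------------------------------------------------

def brute_force_events(model) -> set:
    """Independent pairwise-transcript ASE comparator for small genes.

    Enumerates (type, inc_junctions, exc_junctions) triples by direct
    comparison of every transcript pair, with the polarity rules applied
    explicitly.  Used only as a test oracle.
    """
    out = set()
    tx = list(model.transcripts)

    def introns(exons):
        return [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]

    for ti, (tid_a, ex_a) in enumerate(tx):
        for tid_b, ex_b in tx:
            if tid_a == tid_b:
                continue
            # IR: intron of A inside an exon of B
            for intr in introns(ex_a):
                if any(s <= intr[0] and intr[1] <= t for s, t in ex_b):
                    out.add(("IR", (), (intr,)))
            ia, ib = introns(ex_a), introns(ex_b)
            # SE: two consecutive introns of A vs the skip junction in B
            for k in range(len(ia) - 1):
                j1, j2 = ia[k], ia[k + 1]
                if (j1[0], j2[1]) in ib:
                    out.add(("SE", (j1, j2), ((j1[0], j2[1]),)))
            # A5SS/A3SS: junction pairs sharing one boundary, requiring the
            # exons at the differing boundary to overlap
            def _ov(e1, e2):
                return e1[0] < e2[1] and e2[0] < e1[1]

            for ka, ja in enumerate(ia):
                for kb, jb in enumerate(ib):
                    if ja == jb:
                        continue
                    if (ja[1] == jb[1] and ja[0] != jb[0]
                            and _ov(ex_a[ka], ex_b[kb])):
                        lo, hi = sorted([ja, jb])
                        t = "A5SS" if model.strand == "+" else "A3SS"
                        out.add((t, (hi,), (lo,)))
                    if (ja[0] == jb[0] and ja[1] != jb[1]
                            and _ov(ex_a[ka + 1], ex_b[kb + 1])):
                        lo, hi = sorted([ja, jb], key=lambda j: j[1])
                        t = "A3SS" if model.strand == "+" else "A5SS"
                        out.add((t, (lo,), (hi,)))
            # MXE: same outer introns boundaries, disjoint middle exons
            for k in range(len(ia) - 1):
                for m in range(len(ib) - 1):
                    j1, j2 = ia[k], ia[k + 1]
                    q1, q2 = ib[m], ib[m + 1]
                    e1, e2 = (j1[1], j2[0]), (q1[1], q2[0])
                    if (j1[0], j2[1]) != (q1[0], q2[1]) or e1 == e2:
                        continue
                    if not (e1[1] <= e2[0] or e2[1] <= e1[0]):
                        continue
                    if any(e1 in set(ex) and e2 in set(ex) for _, ex in tx):
                        continue
                    first = lambda js: (max(js, key=lambda j: j[1])
                                        if model.strand == "-" else min(js))
                    l1 = first([j1, j2]); l1 = l1[1] - l1[0]
                    l2 = first([q1, q2]); l2 = l2[1] - l2[0]
                    if (l1, sorted([j1, j2])) <= (l2, sorted([q1, q2])):
                        out.add(("MXE", (j1, j2), (q1, q2)))
                    else:
                        out.add(("MXE", (q1, q2), (j1, j2)))
    return out


def oracle_benchmark(seed: int) -> dict:
    """Coverage vs pileup, enumeration vs brute force, t-test vs closed form."""
    rng = np.random.default_rng(seed)
    work = _workdir()

    # coverage vs pysam count_coverage pileup on a simulated BAM
    ab = {"s1": {"RI": 12.0, "A": 25.0, "B": 8.0, "C": 5.0, "D": 4.0,
                 "E": 6.0, "F": 3.0}}
    s = simdata.make_scenario("fig_multi_isoform", abundances=ab, seed=seed)
    bams = simdata.simulate_reads(s, work / "sim", seed=seed)
    import pysam

    tracks = bam_engine.compute_coverage(bams["s1"], "unstranded")
    got = tracks["unstranded"].depth_array("chrS")
    with pysam.AlignmentFile(bams["s1"]) as af:
        acgt = af.count_coverage("chrS", 0, s.chrom_lengths["chrS"],
                                 quality_threshold=0, read_callback="nofilter")
    pileup = np.array(acgt).sum(axis=0)
    coverage_mismatch = int((got != pileup).sum())

    # ASE enumeration vs the brute-force pairwise comparator on random genes
    from . import reference as refmod

    enum_mismatches = 0
    n_genes = 40
    for g in range(n_genes):
        n_tx = int(rng.integers(2, 5))
        strand = str(rng.choice(["+", "-"]))
        boundaries = np.sort(rng.choice(np.arange(100, 3000, 50),
                                        size=12, replace=False))
        txs = {}
        for t in range(n_tx):
            n_ex = int(rng.integers(2, 4))
            idx = np.sort(rng.choice(np.arange(6), size=n_ex, replace=False))
            exons = [(int(boundaries[2 * i]), int(boundaries[2 * i + 1])) for i in idx]
            txs[f"T{t}"] = exons
        model = refmod.GeneModel(
            gene_id=f"R{g}", chrom="chrR", strand=strand,
            transcripts=tuple((tid, tuple(ex)) for tid, ex in sorted(txs.items())),
        )
        got_set = {
            (e.type, tuple(sorted(e.inc_junctions)), tuple(sorted(e.exc_junctions)))
            for e in refmod.annotate_ases([model])
            if e.type in ("IR", "SE", "MXE", "A5SS", "A3SS")
        }
        want = {
            (t, tuple(sorted(inc)), tuple(sorted(exc)))
            for t, inc, exc in brute_force_events(model)
        }
        enum_mismatches += got_set != want

    # pointwise t-test vs scipy closed form
    a = rng.normal(0.3, 0.1, size=(4, 500))
    b = rng.normal(0.35, 0.1, size=(3, 500))
    p_ours = covplot.pointwise_ttest(a, b)
    p_ref = stats.ttest_ind(a, b, axis=0, equal_var=True).pvalue
    ttest_max_err = float(np.abs(p_ours - p_ref).max())

    return {
        "coverage_pileup_mismatched_bases": coverage_mismatch,
        "enumeration_mismatched_genes": enum_mismatches,
        "enumeration_genes_checked": n_genes,
        "ttest_max_abs_error": ttest_max_err,
        "n": n_genes,
    }
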