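"""Group-normalized coverage traces and the per-nucleotide T-score track.

Each sample's raw coverage over an event window is divided by a single
event-level normalization factor estimating local transcript depth (for IR:
SpliceOver + IntronDepth; junction events: included + excluded counts).
After normalization, constitutive regions sit near 1 and the mean coverage
across an alternatively spliced region reflects its PSI, so replicate
traces can be averaged per condition and compared across conditions with a
per-base two-tailed Student's t-test.  The event T-score is the mean of
-log10 p over the alternatively spliced region excluding five boundary
nucleotides at each end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import cov_store
from .quantify import Experiment
from .reference import ASEvent, Reference

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300
NEGLOG_CAP = 300.0
BOUNDARY_EXCLUSION = 5


@dataclass
class NormalizedTrace:
    """One sample's normalized per-base coverage over an event window."""

    event_id: str
    sample_id: str
    chrom: str
    window: tuple[int, int]
    values: np.ndarray
    factor: float


@dataclass
class GroupTrace:
    """Pointwise mean/sd of the normalized traces of one condition."""

    condition: str
    window: tuple[int, int]
    mean: np.ndarray
    sd: np.ndarray
    n: int


@dataclass
class TScoreTrack:
    """-log10 p per base plus the region-averaged event T-score."""

    event_id: str
    window: tuple[int, int]
    neglog10p: np.ndarray
    event_tscore: float
    scored_region: tuple[int, int]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalization_factor(e: ASEvent, inc_count: float, exc_count: float, *,
                         splice_over: float | None = None,
                         intron_depth: float | None = None,
                         min_factor: float = 1.0) -> tuple[float, bool]:
    """Event-level transcript-depth estimate for one sample.

    IR: SpliceOver + IntronDepth.  Other events: included + excluded
    junction counts.  Returns ``(factor, eligible)``; samples whose factor
    falls below ``min_factor`` are flagged ineligible rather than erroring.
    """
    if e.uses_intron_depth:
        if splice_over is None or intron_depth is None:
            raise ValueError("IR normalization needs splice_over and intron_depth")
        factor = splice_over + intron_depth
    else:
        factor = inc_count + exc_count
    return factor, factor >= min_factor


def normalized_coverage(depths: np.ndarray, e: ASEvent, sample_id: str, factor: float,
                        window: tuple[int, int]) -> NormalizedTrace:
    """Per-base depth over the window divided by the normalization factor."""
    if factor <= 0:
        raise ValueError("normalization factor must be positive")
    return NormalizedTrace(
        event_id=e.event_id, sample_id=sample_id, chrom=e.chrom,
        window=window, values=np.asarray(depths, float) / factor, factor=factor,
    )


def event_window(e: ASEvent, chrom_length: int, flank: int = 100) -> tuple[int, int]:
    start = max(0, e.region[0] - flank)
    end = min(chrom_length, e.region[1] + flank)
    if (start, end) != (e.region[0] - flank, e.region[1] + flank):
        logger.warning("event %s window clipped to chromosome bounds", e.event_id)
    return start, end


def sample_traces(x: Experiment, e: ASEvent, sample_ids, *, flank: int = 100,
                  min_factor: float = 1.0) -> list[NormalizedTrace]:
    """Normalized traces for the eligible subset of the given samples."""
    traces = []
    stratum = "unstranded"
    for sid in sample_ids:
        reader = cov_store.CovReader(x.cov_path(sid))
        if e.strand == "+" and "plus" in reader.strata:
            stratum = "plus"
        elif e.strand == "-" and "minus" in reader.strata:
            stratum = "minus"
        window = event_window(e, reader.chrom_lengths[e.chrom], flank)
        inc = float(x.inc.loc[e.event_id, sid])
        exc = float(x.exc.loc[e.event_id, sid])
        kw = {}
        if e.uses_intron_depth:
            m = x.metrics
            row = m[(m.event_id == e.event_id) & (m.sample_id == sid)]
            if len(row):
                kw = {"splice_over": float(row.splice_over.iloc[0]),
                      "intron_depth": float(row.intron_depth.iloc[0])}
            else:
                kw = {"splice_over": exc, "intron_depth": inc}
        factor, ok = normalization_factor(e, inc, exc, min_factor=min_factor, **kw)
        if not ok:
            logger.info("sample %s ineligible for %s (factor %.3g)", sid, e.event_id, factor)
            continue
        depths = reader.query(stratum, e.chrom, window[0], window[1])
        traces.append(normalized_coverage(depths, e, sid, factor, window))
    return traces


def group_traces(x: Experiment, e: ASEvent, condition: str, *, flank: int = 100,
                 min_factor: float = 1.0) -> GroupTrace:
    """Pointwise mean and SD of the condition's eligible normalized traces."""
    sample_ids = x.samples.index[x.samples["condition"] == condition]
    traces = sample_traces(x, e, sample_ids, flank=flank, min_factor=min_factor)
    if not traces:
        raise ValueError(f"no eligible samples in condition {condition!r} for {e.event_id}")
    if len(traces) < len(sample_ids):
        logger.warning("condition %s: %d/%d samples eligible for %s",
                       condition, len(traces), len(sample_ids), e.event_id)
    vals = np.stack([t.values for t in traces])
    return GroupTrace(condition=condition, window=traces[0].window,
                      mean=vals.mean(axis=0), sd=vals.std(axis=0, ddof=1) if len(traces) > 1
                      else np.zeros(vals.shape[1]), n=len(traces))


# ---------------------------------------------------------------------------
# T-score
# ---------------------------------------------------------------------------

def pointwise_ttest(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-tailed pooled-variance Student's t-test per base.

    ``a``/``b`` are (n_samples, window) matrices.  Degenerate bases (both
    variances zero) give p = 1 when the means agree and the p floor when
    they differ.
    """
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 samples for the t-test")
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    se = np.sqrt(sp2 * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / se
    p = 2 * stats.t.sf(np.abs(t), df)
    # relative tolerance: float means of identical values differ at ~1e-16
    scale = np.maximum(np.abs(ma) + np.abs(mb), 1e-30)
    degenerate = se <= 1e-12 * scale
    means_equal = np.abs(ma - mb) <= 1e-12 * scale
    p[degenerate & means_equal] = 1.0
    p[degenerate & ~means_equal] = P_FLOOR
    return np.maximum(p, P_FLOOR)


def tscore_track(group_a: list[NormalizedTrace], group_b: list[NormalizedTrace],
                 e: ASEvent) -> TScoreTrack:
    """Per-base -log10 p between two groups plus the event T-score.

    The event T-score averages -log10 p over the scored region minus
    ``BOUNDARY_EXCLUSION`` bases at each end; regions of 10 bases or fewer
    are used whole (logged).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 eligible samples")
    window = group_a[0].window
    a = np.stack([t.values for t in group_a])
    b = np.stack([t.values for t in group_b])
    p = pointwise_ttest(a, b)
    neglog = np.minimum(-np.log10(p), NEGLOG_CAP)
    region = e.tscore_region or e.region
    lo = region[0] - window[0] + BOUNDARY_EXCLUSION
    hi = region[1] - window[0] - BOUNDARY_EXCLUSION
    if hi <= lo:
        logger.info("event %s: region too short for boundary exclusion; using whole region",
                    e.event_id)
        lo, hi = region[0] - window[0], region[1] - window[0]
    lo, hi = max(lo, 0), min(hi, len(neglog))
    return TScoreTrack(event_id=e.event_id, window=window, neglog10p=neglog,
                       event_tscore=float(neglog[lo:hi].mean()), scored_region=region)


def tscore_eligible(e: ASEvent, ref: Reference) -> tuple[bool, str]:
    """Whether the event type admits a meaningful T-score, and why not.

    Eligibility and the scored region are pre-computed at annotation time;
    this accessor re-reports them with a human-readable reason.
    """
    if e.tscore_eligible:
        return True, ""
    if e.type in ("MXE", "AFE", "ALE"):
        return False, "mutually exclusive regions"
    return False, "interfering annotated intron in alternative region"


def event_tscore(x: Experiment, e: ASEvent, condition_a: str, condition_b: str, *,
                 flank: int = 100, min_factor: float = 1.0) -> TScoreTrack:
    """Convenience: traces for both conditions, then the T-score track."""
    sa = x.samples.index[x.samples["condition"] == condition_a]
    sb = x.samples.index[x.samples["condition"] == condition_b]
    ta = sample_traces(x, e, sa, flank=flank, min_factor=min_factor)
    tb = sample_traces(x, e, sb, flank=flank, min_factor=min_factor)
    return tscore_track(ta, tb, e)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_event(x: Experiment, ref: Reference, event_id: str, conditions: list[str],
                 out_prefix, *, flank: int = 100, min_factor: float = 1.0):
    """Three-track figure (group means, T-score, transcripts) plus TSV export.

    Returns the matplotlib figure; writes ``<prefix>.svg`` and
    ``<prefix>.tsv``.  With a single condition only coverage is drawn.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    e = ref.events_by_id()[event_id]
    ok, reason = tscore_eligible(e, ref)
    if len(conditions) >= 2 and not ok:
        raise ValueError(f"event {event_id} is not T-score eligible: {reason}")

    groups = [group_traces(x, e, c, flank=flank, min_factor=min_factor) for c in conditions]
    window = groups[0].window
    pos = np.arange(window[0], window[1])
    two_group = len(conditions) >= 2
    n_rows = 3 if two_group else 2
    fig, axes = plt.subplots(n_rows, 1, figsize=(9, 2.2 * n_rows), sharex=True,
                             gridspec_kw={"height_ratios": [3, 2, 1][:n_rows]})
    ax0 = axes[0]
    export = {"chrom": np.full(len(pos), e.chrom), "position": pos}
    for g in groups:
        ax0.plot(pos, g.mean, label=f"{g.condition} (n={g.n})")
        ax0.fill_between(pos, g.mean - g.sd, g.mean + g.sd, alpha=0.25)
        export[f"mean_{g.condition}"] = g.mean
        export[f"sd_{g.condition}"] = g.sd
    ax0.axhline(1.0, ls=":", lw=0.8, color="grey")
    ax0.set_ylabel("normalized coverage")
    ax0.legend(fontsize=8)

    ts = None
    if two_group:
        ts = event_tscore(x, e, conditions[0], conditions[1], flank=flank,
                          min_factor=min_factor)
        axes[1].plot(pos, ts.neglog10p, color="firebrick", lw=1)
        axes[1].axvspan(ts.scored_region[0], ts.scored_region[1], color="grey", alpha=0.2)
        axes[1].set_ylabel("-log10 p")
        axes[1].set_title(f"event T-score = {ts.event_tscore:.2f}", fontsize=9)
        export["neglog10p"] = ts.neglog10p

    axt = axes[-1]
    y = 0
    for m in ref.models:
        if m.gene_id != e.gene_id:
            continue
        for tid, exons in m.transcripts:
            tx_start, tx_end = exons[0][0], exons[-1][1]
            axt.hlines(y, tx_start, tx_end, color="black", lw=0.8)
            for s, t in exons:
                axt.add_patch(plt.Rectangle((s, y - 0.3), t - s, 0.6, color="steelblue"))
            axt.text(tx_start, y + 0.35, tid, fontsize=7)
            y += 1
    axt.set_ylim(-1, max(y, 1))
    axt.set_yticks([])
    axt.set_xlim(window[0], window[1])
    axt.set_xlabel(f"{e.chrom} position")
    fig.suptitle(event_id, fontsize=10)
    fig.tight_layout()
    fig.savefig(f"{out_prefix}.svg")
    pd.DataFrame(export).to_csv(f"{out_prefix}.tsv", sep="\t", index=False,
                                float_format="%.6g")
    plt.close(fig)
    return fig, ts
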