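"""Poisson peak calling of calling-card insertions against a TTAA background.

The caller adapts the MACS ChIP-seq strategy to insertion data.  Insertions
("hops") from the transcription-factor experiment are compared with hops from
an unfused-transposase background over the universe of TTAA sites:

1. scan each chromosome with a sliding window (default 1 kb, step 500 bp)
   and flag windows whose experiment hop count is Poisson-improbable given
   the depth-scaled background count;
2. merge overlapping/abutting enriched windows into candidate peaks and take
   the median experiment-hop position as the peak center;
3. estimate the local background rate lambda (hops per TTAA) as the maximum
   of the genome-wide rate and the rates in 1/5/10 kb windows around the
   center — the MACS "local lambda" guard against regional biases;
4. score each candidate with the Poisson upper tail at expectation
   max(lambda * TTAAs-in-peak * R, pseudocounts), where R scales background
   depth to experiment depth, and keep peaks below the final p-value cutoff.

Hops are unique insertion events: each collapsed qBED record counts once
regardless of its read count.  All intervals are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .formats_io import Insertion, Peak, TTAAIndex

__all__ = [
    "PeakCallingParams",
    "HopFrame",
    "EnrichedWindow",
    "CandidatePeak",
    "poisson_sf",
    "scan_windows",
    "merge_windows",
    "local_lambda",
    "score_peak",
    "call_peaks",
    "uniform_ttaa_background",
]


@dataclass(frozen=True)
class PeakCallingParams:
    """Peak caller tuning.  Defaults are the published run parameters:
    window 1000, step 500, window-stage p 0.01, final p 0.001 ("pc"),
    pseudocounts 0.2, local-lambda full widths 1/5/10 kb."""

    window_size: int = 1000
    step_size: int = 500
    peak_finder_pvalue: float = 0.01
    pvalue_cutoff: float = 0.001
    pseudocounts: float = 0.2
    lambda_windows: Tuple[int, ...] = (1000, 5000, 10000)
    depth_scale: bool = True
    literal_expectation: bool = False
    trim_to_hops: bool = True

    def __post_init__(self) -> None:
        if self.step_size > self.window_size:
            raise ValueError("step_size must be <= window_size")
        for c in (self.peak_finder_pvalue, self.pvalue_cutoff):
            if not (0.0 < c <= 1.0):
                raise ValueError("p-value cutoffs must lie in (0, 1]")
        if self.pseudocounts < 0:
            raise ValueError("pseudocounts must be >= 0")


class HopFrame:
    """Insertion events as sorted per-chromosome position arrays.

    Hops are unique insertion events: records identical in (chrom, start,
    strand, barcode) are the same event listed twice and count once; a
    collapsed insertion with read count 40 is likewise a single hop.
    Distinct barcodes at one TTAA are distinct hops.  ``total_hops`` is the
    unique-event count over all chromosomes.
    """

    def __init__(self, insertions: Iterable[Insertion]):
        seen = set()
        by_chrom: Dict[str, List[int]] = {}
        for ins in insertions:
            key = (ins.chrom, ins.start, ins.strand, ins.barcode)
            if key in seen:
                continue
            seen.add(key)
            by_chrom.setdefault(ins.chrom, []).append(ins.start)
        self._pos: Dict[str, np.ndarray] = {
            c: np.asarray(sorted(p), dtype=np.int64)
            for c, p in by_chrom.items()
        }
        self.total_hops = int(sum(a.size for a in self._pos.values()))

    @property
    def chroms(self) -> List[str]:
        return list(self._pos)

    def positions(self, chrom: str) -> np.ndarray:
        return self._pos.get(chrom, np.empty(0, dtype=np.int64))

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Hops whose TTAA start lies in the half-open window [start, end)."""
        pos = self.positions(chrom)
        return int(np.searchsorted(pos, end) - np.searchsorted(pos, start))


@dataclass(frozen=True)
class EnrichedWindow:
    chrom: str
    start: int
    end: int
    exp_hops: int
    bg_hops: int
    pvalue: float


@dataclass(frozen=True)
class CandidatePeak:
    chrom: str
    start: int
    end: int
    center: int


def poisson_sf(observed: int, expected: float) -> float:
    """Upper-tail Poisson probability P(X >= observed) at rate ``expected``,
    by exact regularized-gamma evaluation.  P(X >= 0) is 1 for any rate;
    a zero rate gives 1 for observed 0 and 0 otherwise."""
    if observed < 0:
        raise ValueError("observed count must be >= 0")
    if expected < 0:
        raise ValueError("expected count must be >= 0")
    if observed == 0:
        return 1.0
    if expected == 0.0:
        return 0.0
    # sf(k) = P(X > k) = P(X >= k + 1), so shift by one.
    return float(stats.poisson.sf(observed - 1, expected))


def _depth_ratio(exp: HopFrame, bg: HopFrame, params: PeakCallingParams) -> float:
    return exp.total_hops / bg.total_hops if params.depth_scale else 1.0


def scan_windows(
    exp: HopFrame,
    bg: HopFrame,
    params: PeakCallingParams = PeakCallingParams(),
) -> List[EnrichedWindow]:
    """Slide a window along each chromosome and keep windows where the
    experiment hop count beats the depth-scaled background Poisson
    expectation at the window-stage cutoff.

    Windows tile from the first to the last event position (union of
    experiment and background hops) in steps of ``step_size``; a window is
    enriched iff poisson_sf(obs_exp, (obs_bg + pseudocounts) * R) is at most
    ``peak_finder_pvalue``, with R the experiment/background depth ratio.
    """
    if exp.total_hops == 0 or bg.total_hops == 0:
        raise ValueError("experiment and background frames must be non-empty")
    ratio = _depth_ratio(exp, bg, params)
    enriched: List[EnrichedWindow] = []
    chroms = sorted(set(exp.chroms) | set(bg.chroms))
    for chrom in chroms:
        pos = np.concatenate([exp.positions(chrom), bg.positions(chrom)])
        if pos.size == 0:
            continue
        lo, hi = int(pos.min()), int(pos.max())
        start = lo
        while start <= hi:
            end = start + params.window_size
            obs_exp = exp.count_in(chrom, start, end)
            obs_bg = bg.count_in(chrom, start, end)
            p = poisson_sf(obs_exp, (obs_bg + params.pseudocounts) * ratio)
            if p <= params.peak_finder_pvalue:
                enriched.append(EnrichedWindow(
                    chrom, start, end, obs_exp, obs_bg, p))
            start += params.step_size
    return enriched


def _median_position(pos: np.ndarray) -> int:
    # Lower median: deterministic and always an actual hop position.
    return int(pos[(pos.size - 1) // 2])


def merge_windows(
    windows: Sequence[EnrichedWindow],
    exp: HopFrame,
) -> List[CandidatePeak]:
    """Merge overlapping or abutting enriched windows per chromosome into
    candidate peaks [min start, max end) and set each candidate's center to
    the (lower) median experiment-hop position inside the merged span,
    falling back to the interval midpoint when the span holds no hops."""
    candidates: List[CandidatePeak] = []
    by_chrom: Dict[str, List[EnrichedWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom in sorted(by_chrom):
        ws = sorted(by_chrom[chrom], key=lambda w: (w.start, w.end))
        cur_start, cur_end = ws[0].start, ws[0].end
        spans: List[Tuple[int, int]] = []
        for w in ws[1:]:
            if w.start <= cur_end:  # overlapping or abutting
                cur_end = max(cur_end, w.end)
            else:
                spans.append((cur_start, cur_end))
                cur_start, cur_end = w.start, w.end
        spans.append((cur_start, cur_end))
        pos = exp.positions(chrom)
        for start, end in spans:
            inside = pos[(pos >= start) & (pos < end)]
            center = _median_position(inside) if inside.size else (start + end) // 2
            candidates.append(CandidatePeak(chrom, start, end, center))
    return candidates


def local_lambda(
    peak: CandidatePeak,
    bg: HopFrame,
    index: TTAAIndex,
    params: PeakCallingParams = PeakCallingParams(),
) -> Tuple[float, str]:
    """Background hops per TTAA around the peak: the max of the genome-wide
    rate lambda_bg and the rates in each full-width window of
    ``lambda_windows`` centered on the peak center (windows with no TTAAs
    are skipped).  Returns (lambda, which-window-won) for diagnostics."""
    if index.total_sites == 0:
        raise ValueError("TTAA index is empty")
    best = bg.total_hops / index.total_sites
    best_name = "bg"
    for width in params.lambda_windows:
        lo = peak.center - width // 2
        hi = lo + width
        n_ttaa = index.count_in(peak.chrom, lo, hi)
        if n_ttaa == 0:
            continue
        lam = bg.count_in(peak.chrom, lo, hi) / n_ttaa
        if lam > best:
            best, best_name = lam, f"{width}"
    return best, best_name


def score_peak(
    peak: CandidatePeak,
    lam: float,
    index: TTAAIndex,
    exp: HopFrame,
    bg: HopFrame,
    params: PeakCallingParams = PeakCallingParams(),
    lambda_type: str = "bg",
) -> Optional[Peak]:
    """Score one candidate: Poisson upper tail of the experiment hop count
    at expectation max(lambda * n_ttaa * R, pseudocounts).

    By default the reported interval is trimmed to the span of TTAA sites
    actually carrying experiment hops, [first hop, last hop + 4); all counts
    (experiment, background, TTAA) are then taken over the reported
    interval.  Candidates whose span holds no experiment hops score p = 1.
    ``literal_expectation`` replaces the depth ratio R with the peak's own
    experiment hop count (the printed formula read literally).
    """
    start, end = peak.start, peak.end
    pos = exp.positions(peak.chrom)
    inside = pos[(pos >= start) & (pos < end)]
    if params.trim_to_hops and inside.size:
        start = int(inside.min())
        end = int(inside.max()) + 4
    exp_hops = exp.count_in(peak.chrom, start, end)
    bg_hops = bg.count_in(peak.chrom, start, end)
    n_ttaa = index.count_in(peak.chrom, start, end)
    if params.literal_expectation:
        scale = float(exp_hops)
    else:
        scale = _depth_ratio(exp, bg, params)
    expected = max(lam * n_ttaa * scale, params.pseudocounts)
    pvalue = poisson_sf(exp_hops, expected)
    center = min(max(peak.center, start), end)
    return Peak(
        chrom=peak.chrom, start=start, end=end, center=center,
        exp_hops=exp_hops, frac_exp=exp_hops / exp.total_hops,
        bg_hops=bg_hops, frac_bg=bg_hops / bg.total_hops,
        pvalue=pvalue, lambda_used=lam, lambda_type=lambda_type,
        n_ttaa=n_ttaa,
    )


def _bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (diagnostic only)."""
    n = pvalues.size
    order = np.argsort(pvalues, kind="mergesort")
    ranked = pvalues[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def call_peaks(
    exp: Iterable[Insertion] | HopFrame,
    bg: Iterable[Insertion] | HopFrame,
    index: TTAAIndex,
    params: PeakCallingParams = PeakCallingParams(),
) -> List[Peak]:
    """Full pipeline: scan -> merge -> local lambda -> score, filtered at
    the final cutoff ``pvalue_cutoff`` and sorted by (chrom, start).
    Deterministic for fixed inputs."""
    exp_frame = exp if isinstance(exp, HopFrame) else HopFrame(exp)
    bg_frame = bg if isinstance(bg, HopFrame) else HopFrame(bg)
    windows = scan_windows(exp_frame, bg_frame, params)
    candidates = merge_windows(windows, exp_frame)
    peaks: List[Peak] = []
    for cand in candidates:
        lam, lam_type = local_lambda(cand, bg_frame, index, params)
        peak = score_peak(cand, lam, index, exp_frame, bg_frame, params,
                          lambda_type=lam_type)
        if peak is not None and peak.pvalue <= params.pvalue_cutoff:
            peaks.append(peak)
    peaks.sort(key=lambda p: (p.chrom, p.start))
    if peaks:
        q = _bh_qvalues(np.array([p.pvalue for p in peaks]))
        peaks = [replace(p, qvalue=float(qi)) for p, qi in zip(peaks, q)]
    return peaks


def uniform_ttaa_background(index: TTAAIndex) -> HopFrame:
    """Synthetic background with one hop at every TTAA site, for runs
    lacking an unfused-transposase control experiment."""
    insertions = [
        Insertion(chrom=c, start=int(p), end=int(p) + 4)
        for c in index.chroms
        for p in index.positions(c)
    ]
    return HopFrame(insertions)
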