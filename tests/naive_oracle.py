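"""Independent naive reimplementations used as test oracles.

Everything here is deliberately dumb and self-contained: plain-Python list
scans, a direct Poisson series, no imports from srtcards.  Insertion events
are (chrom, start, strand, barcode) tuples; the TTAA universe is a mapping
chrom -> sorted list of motif starts.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple

Event = Tuple[str, int, str, str]


def poisson_sf_series(observed: int, expected: float) -> float:
    """P(X >= observed) for X ~ Poisson(expected), by direct summation of
    e^-mu mu^k / k!.

    The upper tail is summed directly when observed > expected (terms are
    then strictly decreasing); otherwise the lower tail (fewer terms, no
    cancellation risk) is summed and complemented.
    """
    if observed == 0:
        return 1.0
    if expected == 0.0:
        return 0.0
    if observed > expected:
        term = math.exp(-expected) * expected ** observed \
            / math.factorial(observed)
        terms = [term]
        k = observed
        while term > math.fsum(terms) * 1e-20:
            k += 1
            term *= expected / k
            terms.append(term)
        return min(math.fsum(terms), 1.0)
    term = math.exp(-expected)
    lower = [term]
    for k in range(1, observed):
        term *= expected / k
        lower.append(term)
    return min(max(1.0 - math.fsum(lower), 0.0), 1.0)


def _dedupe(events: Sequence[Event]) -> List[Event]:
    seen, out = set(), []
    for e in events:
        if e not in seen:
            seen.add(e)
            out.append(e)
    return out


def _count(events: Sequence[Event], chrom: str, lo: int, hi: int) -> int:
    return sum(1 for (c, p, _, _) in events if c == chrom and lo <= p < hi)


def _ttaa_count(ttaa: Dict[str, Sequence[int]], chrom: str, lo: int, hi: int) -> int:
    return sum(1 for p in ttaa.get(chrom, []) if lo <= p < hi)


def naive_call_peaks(
    exp_events: Sequence[Event],
    bg_events: Sequence[Event],
    ttaa: Dict[str, Sequence[int]],
    window_size: int = 1000,
    step_size: int = 500,
    peak_finder_pvalue: float = 0.01,
    pvalue_cutoff: float = 0.001,
    pseudocounts: float = 0.2,
    lambda_windows: Sequence[int] = (1000, 5000, 10000),
) -> List[Dict]:
    """Brute-force peak caller: same contract as the real one, implemented
    with linear scans.  Returns dicts with the nine peak-table fields."""
    exp_events = _dedupe(exp_events)
    bg_events = _dedupe(bg_events)
    total_exp, total_bg = len(exp_events), len(bg_events)
    total_ttaa = sum(len(v) for v in ttaa.values())
    ratio = total_exp / total_bg

    chroms = sorted({c for (c, _, _, _) in exp_events}
                    | {c for (c, _, _, _) in bg_events})

    # Stage 1: enriched windows.
    enriched: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    for chrom in chroms:
        pos = [p for (c, p, _, _) in exp_events + bg_events if c == chrom]
        if not pos:
            continue
        start, hi = min(pos), max(pos)
        while start <= hi:
            end = start + window_size
            obs_exp = _count(exp_events, chrom, start, end)
            obs_bg = _count(bg_events, chrom, start, end)
            p = poisson_sf_series(obs_exp, (obs_bg + pseudocounts) * ratio)
            if p <= peak_finder_pvalue:
                enriched[chrom].append((start, end))
            start += step_size

    # Stage 2: merge overlapping/abutting windows; center = lower median of
    # experiment positions in the span (midpoint when empty).
    peaks: List[Dict] = []
    for chrom in chroms:
        spans: List[List[int]] = []
        for (s, e) in enriched[chrom]:
            if spans and s <= spans[-1][1]:
                spans[-1][1] = max(spans[-1][1], e)
            else:
                spans.append([s, e])
        for s, e in spans:
            inside = sorted(p for (c, p, _, _) in exp_events
                            if c == chrom and s <= p < e)
            center = inside[(len(inside) - 1) // 2] if inside else (s + e) // 2

            # Stage 3: local lambda.
            lam = total_bg / total_ttaa
            for width in lambda_windows:
                lo = center - width // 2
                hi2 = lo + width
                n = _ttaa_count(ttaa, chrom, lo, hi2)
                if n == 0:
                    continue
                lam = max(lam, _count(bg_events, chrom, lo, hi2) / n)

            # Stage 4: trim to hop span, score, filter.
            start, end = s, e
            if inside:
                start, end = inside[0], inside[-1] + 4
            exp_hops = _count(exp_events, chrom, start, end)
            bg_hops = _count(bg_events, chrom, start, end)
            n_ttaa = _ttaa_count(ttaa, chrom, start, end)
            expected = max(lam * n_ttaa * ratio, pseudocounts)
            pvalue = poisson_sf_series(exp_hops, expected)
            if pvalue <= pvalue_cutoff:
                peaks.append({
                    "Chr": chrom,
                    "Start": start,
                    "End": end,
                    "Center": min(max(center, start), end),
                    "Experiment Hops": exp_hops,
                    "Fraction Experiment": exp_hops / total_exp,
                    "Background Hops": bg_hops,
                    "Fraction Background": bg_hops / total_bg,
                    "Poisson P-value": pvalue,
                })
    peaks.sort(key=lambda d: (d["Chr"], d["Start"]))
    return peaks
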