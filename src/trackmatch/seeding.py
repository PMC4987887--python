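"""Seed detection and merging: find fixed-width windows where query and
target correlate strongly, then merge connected runs of windows into the
starting regions for boundary refinement.

A note on thresholds: with R = ln(C + 1.001) + alpha*ln(L), a 1000-base
window at alpha = 0.01 can score at most ln(2.001) + 0.01*ln(1000) ~ 0.763
(attained at C = 1), so a correlation threshold of 0.8 can never be paired
with a score threshold of 0.9 on such windows.  The correlation cutoff
``seed_c_min`` (default 0.8) is therefore the operative seeding criterion
here, and the default score cutoff ``seed_r_min`` is 0.5 — attainable at
C ~ 0.8 on a 1000-base window under natural log.  Both are config knobs.
"""

from __future__ import annotations

import math
from typing import List, Optional, Tuple

import numpy as np

from .genome import Region, ScoredRegion, SearchConfig, SignalTrack
from .scoring import RegionScorer, make_scorer

# (start, end, correlation, score) tuples used on the fast internal path.
RegionTuple = Tuple[int, int, float, float]


def seed_window_arrays(
    scorer: RegionScorer, config: SearchConfig
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized seed scan: starts, correlations and scores of every
    qualifying window (C >= seed_c_min and R >= seed_r_min)."""
    starts, corr, scores = scorer.window_stats(config.seed_window)
    with np.errstate(invalid="ignore"):
        keep = (corr >= config.seed_c_min) & (scores >= config.seed_r_min)
    keep &= ~np.isnan(corr)
    return starts[keep], corr[keep], scores[keep]


def find_seeds(
    query: SignalTrack,
    target: SignalTrack,
    chrom: str,
    config: SearchConfig,
    scorer: Optional[RegionScorer] = None,
    target_id: str = "",
) -> List[ScoredRegion]:
    """Slide a ``seed_window``-base window one bin at a time across a
    chromosome and emit every window passing both seed thresholds.

    Windows where either track is flat (zero variance, which includes the
    all-zero stretches that dominate real genomes) have undefined
    correlation and are never emitted.
    """
    if scorer is None:
        scorer = make_scorer(query, target, chrom, config.bin_size, config.alpha)
    starts, corr, scores = seed_window_arrays(scorer, config)
    w = (config.seed_window // config.bin_size) * config.bin_size
    return [
        ScoredRegion(
            Region(chrom, int(s), int(s) + w), float(c), float(r), target_id
        )
        for s, c, r in zip(starts, corr, scores)
    ]


def _merge_pass(
    regions: List[RegionTuple], scorer: RegionScorer
) -> Tuple[List[RegionTuple], bool]:
    """One merge sweep over runs of connected regions.

    Regions are connected when they overlap or are exactly adjacent.  Each
    maximal run is replaced by its union iff the union scores strictly
    higher than every member; otherwise the best-scoring member represents
    the run.
    """
    if len(regions) <= 1:
        return list(regions), False
    regions = sorted(regions)
    starts = np.array([r[0] for r in regions], dtype=np.int64)
    ends = np.array([r[1] for r in regions], dtype=np.int64)
    cummax_end = np.maximum.accumulate(ends)
    # run starts where a region begins strictly after everything seen so far
    breaks = np.flatnonzero(starts[1:] > cummax_end[:-1]) + 1
    run_bounds = np.concatenate(([0], breaks, [len(regions)]))
    out: List[RegionTuple] = []
    changed = False
    for a, b in zip(run_bounds[:-1], run_bounds[1:]):
        if b - a == 1:
            out.append(regions[a])
            continue
        u_start = int(starts[a])
        u_end = int(cummax_end[b - 1])
        member_scores = [regions[i][3] for i in range(a, b)]
        best_i = a + int(np.argmax(member_scores))
        u_c = scorer.correlation(u_start, u_end)
        if math.isnan(u_c):
            out.append(regions[best_i])
            changed = True
            continue
        u_r = math.log(u_c + 1.001) + scorer.alpha * math.log(u_end - u_start)
        if u_r > max(member_scores):
            out.append((u_start, u_end, u_c, u_r))
        else:
            out.append(regions[best_i])
        changed = True
    return out, changed


def merge_region_tuples(
    regions: List[RegionTuple], scorer: RegionScorer
) -> List[RegionTuple]:
    """Merge connected regions to a fixed point (fast internal path)."""
    current = list(regions)
    while True:
        current, changed = _merge_pass(current, scorer)
        if not changed:
            return current
        # After one pass runs are separated by >= 1 base, so a second pass
        # normally changes nothing; the loop guards the fixed-point contract.
        nxt, changed2 = _merge_pass(current, scorer)
        if not changed2 or nxt == current:
            return nxt
        current = nxt


def merge_connected_seeds(
    seeds: List[ScoredRegion],
    query: SignalTrack,
    target: SignalTrack,
    config: SearchConfig,
    scorer: Optional[RegionScorer] = None,
) -> List[ScoredRegion]:
    """Merge runs of overlapping/adjacent seeds into single regions when the
    union outscores every member; otherwise keep each run's best member.

    Output regions are non-overlapping and sorted.  All seeds must lie on
    one chromosome.
    """
    if not seeds:
        return []
    chroms = {s.region.chrom for s in seeds}
    if len(chroms) > 1:
        raise ValueError("seeds must all be on one chromosome")
    chrom = seeds[0].region.chrom
    if scorer is None:
        scorer = make_scorer(query, target, chrom, config.bin_size, config.alpha)
    tuples = [
        (s.region.start, s.region.end, s.correlation, s.score) for s in seeds
    ]
    merged = merge_region_tuples(tuples, scorer)
    tid = seeds[0].target_id
    return [
        ScoredRegion(Region(chrom, s, e), c, r, tid) for s, e, c, r in merged
    ]
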