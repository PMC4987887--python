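"""Metropolis-Hastings refinement of region boundaries.

Each merged seed starts a single chain whose state is a candidate region
(i1, i2).  A proposal shifts one boundary (fair coin) by a uniform draw of
up to ``delta`` in either direction; shifts that exit the chromosome are
clamped to its edge, with the proposal probability q = 1/2 * u/(2*delta+1)
tracking the clamping multiplicity u.  A move is accepted with probability
min(1, R_proposed * q_back / (R_current * q_fwd)), the score R acting as an
unnormalized density.  The best-scoring visited state is tracked and
returned, so refinement never does worse than the seed.

The score ratio is only meaningful for positive scores: proposals with
R <= 0 or undefined R are rejected outright, and a chain that (with
user-lowered thresholds) starts at R <= 0 falls back to greedy ascent until
it reaches the positive domain.

The chain operates on the bin lattice of the comparison grid — boundaries
are multiples of ``bin_size`` and ``delta`` is converted to lattice units.
For any fixed set of overlapped bins, the score is maximized at bin-aligned
boundaries (same correlation, maximal length), so restricting the chain to
the lattice loses none of the attainable optima while keeping every score
evaluation O(1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .genome import GenomeLayout, Region, ScoredRegion, SearchConfig, SignalTrack
from .scoring import RegionScorer, make_scorer


@dataclass
class ChainState:
    """State of a refinement chain at one step."""

    step: int
    region: Region
    score: float
    best: ScoredRegion


@dataclass(frozen=True)
class ProposalDraw:
    """Bookkeeping of one proposal: which boundary moved (``move_left``),
    the uniform draw B in {1, ..., 2*delta+1}, whether the shifted boundary
    was clamped at a chromosome edge, and the clamping multiplicity u
    (1 + positions beyond the edge; u = 1 for interior moves)."""

    move_left: bool
    draw: int
    clamped: bool
    u: int


def propose_move(
    region: Region,
    delta: int,
    layout: GenomeLayout,
    rng: np.random.Generator,
    step: int = 1,
) -> Tuple[Optional[Region], ProposalDraw]:
    """Draw one boundary-shift proposal.

    A fair coin picks the boundary; B ~ Uniform{1, ..., 2*delta+1} shifts it
    by (B - (delta+1)) * step, so B = delta+1 is the null move.  A shift
    beyond [0, chrom_length] is clamped to the edge with u = 1 + (positions
    beyond).  Proposals that would invert the region (i1 >= i2) are invalid
    and returned as ``None`` (the caller counts the step and stays put).
    """
    if delta < 1:
        raise ValueError("delta must be >= 1")
    chrom_len = layout.length(region.chrom)
    hi = (chrom_len // step) * step or chrom_len
    move_left = bool(rng.integers(0, 2))
    draw = int(rng.integers(1, 2 * delta + 2))
    offset = (draw - (delta + 1)) * step
    coord = (region.start if move_left else region.end) + offset
    u = 1
    clamped = False
    if coord < 0:
        u = 1 + (-coord) // step
        coord = 0
        clamped = True
    elif coord > hi:
        u = 1 + (coord - hi) // step
        coord = hi
        clamped = True
    pd = ProposalDraw(move_left, draw, clamped, int(u))
    if move_left:
        i1, i2 = coord, region.end
    else:
        i1, i2 = region.start, coord
    if i1 >= i2:
        return None, pd
    return Region(region.chrom, i1, i2), pd


def proposal_probability(draw: ProposalDraw, delta: int) -> float:
    """q of the drawn move: 1/2 * u / (2*delta + 1)."""
    return 0.5 * draw.u / (2 * delta + 1)


def acceptance_probability(
    r_current: float, r_proposed: float, q_forward: float, q_backward: float
) -> float:
    """Metropolis-Hastings acceptance probability for the score ratio.

    min(1, (R_proposed * q_back) / (R_current * q_fwd)) when both scores are
    positive; 0 when the proposal's score is undefined or non-positive; a
    greedy rule (accept iff strictly better) when the current score is
    non-positive, where the ratio is ill-defined.
    """
    if q_forward <= 0 or q_backward <= 0:
        raise ValueError("proposal probabilities must be > 0")
    if math.isnan(r_proposed) or r_proposed <= 0:
        return 0.0
    if math.isnan(r_current) or r_current <= 0:
        return 1.0 if r_proposed > r_current or math.isnan(r_current) else 0.0
    return min(1.0, (r_proposed * q_backward) / (r_current * q_forward))


def _snap_seed(
    start: int, end: int, bin_size: int, hi: int
) -> Tuple[int, int]:
    """Snap a seed region outward onto the bin lattice, enforcing the
    2-bin minimum length needed for a defined correlation."""
    i1 = (start // bin_size) * bin_size
    i2 = min(-(-end // bin_size) * bin_size, hi)
    if i2 - i1 < 2 * bin_size:
        i2 = min(i1 + 2 * bin_size, hi)
        i1 = max(0, i2 - 2 * bin_size)
    return i1, i2


def refine_region(
    query: SignalTrack,
    target: SignalTrack,
    seed: ScoredRegion,
    config: SearchConfig,
    rng: np.random.Generator,
    scorer: Optional[RegionScorer] = None,
) -> ScoredRegion:
    """Run ``config.mcmc_iterations`` Metropolis-Hastings steps from a seed
    and return the best-scoring region visited (never worse than the seed).

    Deterministic given the generator state; zero iterations return the
    (lattice-snapped) seed unchanged.
    """
    chrom = seed.region.chrom
    B = config.bin_size
    if scorer is None:
        scorer = make_scorer(query, target, chrom, B, config.alpha)
    chrom_len = scorer.chrom_length
    hi = (chrom_len // B) * B or chrom_len
    d = max(1, config.delta // B)
    span = 2 * d + 1
    min_len = 2 * B

    i1, i2 = _snap_seed(seed.region.start, seed.region.end, B, hi)
    cur = scorer.score(i1, i2)
    best_score, best_i1, best_i2 = cur, i1, i2

    n = config.mcmc_iterations
    if n > 0:
        coin = rng.integers(0, 2, size=n)
        draws = rng.integers(1, span + 1, size=n)
        unif = rng.random(size=n)
        for k in range(n):
            offset = (int(draws[k]) - (d + 1)) * B
            uf = 1
            if coin[k]:
                p1 = i1 + offset
                p2 = i2
                if p1 < 0:
                    uf = 1 + (-p1) // B
                    p1 = 0
                elif p1 > hi:  # cannot happen while i1 < i2 <= hi, kept for safety
                    uf = 1 + (p1 - hi) // B
                    p1 = hi
            else:
                p1 = i1
                p2 = i2 + offset
                if p2 > hi:
                    uf = 1 + (p2 - hi) // B
                    p2 = hi
                elif p2 < 0:
                    uf = 1 + (-p2) // B
                    p2 = 0
            if p2 - p1 < min_len:
                continue  # degenerate proposal: step consumed, no move
            r_prop = scorer.score(p1, p2)
            if math.isnan(r_prop) or r_prop <= 0.0:
                continue
            if math.isnan(cur) or cur <= 0.0:
                accept = r_prop > cur or math.isnan(cur)
            else:
                # interior reverse move is exact and unclamped (u_back = 1)
                accept = unif[k] < r_prop / (cur * uf)
            if accept:
                i1, i2, cur = p1, p2, r_prop
                if cur > best_score or math.isnan(best_score):
                    best_score, best_i1, best_i2 = cur, i1, i2

    best_corr = scorer.correlation(best_i1, best_i2)
    return ScoredRegion(
        Region(chrom, best_i1, best_i2), best_corr, best_score, seed.target_id
    )
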