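"""Synthetic benchmark generation with known ground truth, and evaluation
of search output against it.

Three designs are covered:

* matched-pair tracks — query and target share identical "matched regions"
  (1-10 signal segments of 100-2000 bp each) at identical positions, with
  additional decoy segments inserted at random positions in the target
  only, or in both files;
* noise replacement — a track keeps its signal inside a set of positive
  regions while everything else is replaced by Gaussian point noise at
  Poisson-process locations (rate lambda per base, so consecutive noise
  points sit ~1/lambda bases apart);
* self-search positives — the top-k regions of a track searched against
  itself, used as the positive set for the noise-replacement design.

Evaluation uses a >= 1 base overlap rule: a returned region is a true
positive iff it comes from the expected target and overlaps a truth
region.  Overlaps with randomly inserted decoy segments are deliberately
not credited, which under-estimates precision when decoys land in both
files — a conservative convention.

Scale: the default synthetic genome is 10 chromosomes of 5 Mb.  All
per-region rates and lengths are kept at their full-genome values, so
per-region behavior is unchanged; only the number of places a region can
land shrinks.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genome import GenomeLayout, Region, ScoredRegion, SearchConfig, SignalTrack
from .search import ResultSet, TargetIndex, run_search

logger = logging.getLogger(__name__)


def default_genome(n_chromosomes: int = 10, chrom_length: int = 5_000_000) -> GenomeLayout:
    """Reduced synthetic genome: ``simC01..simCnn`` of equal length."""
    width = max(2, len(str(n_chromosomes)))
    return GenomeLayout(
        (f"simC{i + 1:0{width}d}", chrom_length) for i in range(n_chromosomes)
    )


@dataclass
class MatchedRegionSpec:
    """Design of the matched-region simulations.

    Each matched region holds ``segments_per_region`` (uniform 1-10)
    signal segments of uniform length 100-2000 bp, separated by short gaps;
    each segment carries a constant intensity drawn Uniform(1, 10).
    Regions are placed by rejection sampling so they never overlap.
    """

    n_regions: int
    genome: GenomeLayout = field(default_factory=default_genome)
    segments_min: int = 1
    segments_max: int = 10
    segment_len_min: int = 100
    segment_len_max: int = 2000
    gap_min: int = 0
    gap_max: int = 500
    value_min: float = 1.0
    value_max: float = 10.0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if not (1 <= self.segments_min <= self.segments_max):
            raise ValueError("bad segments range")
        if not (1 <= self.segment_len_min <= self.segment_len_max):
            raise ValueError("bad segment length range")


@dataclass
class NoiseSpec:
    """Poisson-located Gaussian noise: locations at per-base rate
    ``lam`` (inter-location gaps ~ Exponential(lam)), values ~ N(mu,
    sigma2) floored at 0.  ``mu``/``sigma2`` default to the mean and
    variance of the positive regions' intensities."""

    lam: float = 0.01
    mu: Optional[float] = None
    sigma2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.sigma2 is not None and self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")


@dataclass
class TruthSet:
    """Ground-truth positive regions: sorted and non-overlapping."""

    regions: List[Region]
    provenance: str = "dataset1"

    def __post_init__(self) -> None:
        self.regions = sorted(self.regions)
        for a, b in zip(self.regions, self.regions[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError(f"overlapping truth regions: {a} / {b}")

    def __len__(self) -> int:
        return len(self.regions)

    @classmethod
    def from_regions(
        cls, regions: Sequence[Region], provenance: str = "dataset1"
    ) -> "TruthSet":
        """Build a TruthSet, merging any overlapping or adjacent regions."""
        merged: List[Region] = []
        for r in sorted(regions):
            if merged and r.chrom == merged[-1].chrom and r.start <= merged[-1].end:
                last = merged.pop()
                merged.append(Region(r.chrom, last.start, max(last.end, r.end)))
            else:
                merged.append(r)
        return cls(merged, provenance)


class _Occupancy:
    """Per-chromosome sorted interval bookkeeping for rejection placement."""

    def __init__(self) -> None:
        self._by_chrom: Dict[str, List[Tuple[int, int]]] = {}

    def conflicts(self, chrom: str, start: int, end: int) -> bool:
        ivs = self._by_chrom.get(chrom)
        if not ivs:
            return False
        i = bisect_left(ivs, (start, start))
        if i < len(ivs) and ivs[i][0] < end:
            return True
        return i > 0 and ivs[i - 1][1] > start

    def add(self, chrom: str, start: int, end: int) -> None:
        insort(self._by_chrom.setdefault(chrom, []), (start, end))


def _place(
    lengths: Sequence[int],
    genome: GenomeLayout,
    rng: np.random.Generator,
    occupancy: _Occupancy,
    max_attempts_per_region: int = 1000,
) -> List[Tuple[str, int]]:
    """Uniformly place intervals of the given lengths without overlap."""
    chroms = genome.names
    weights = np.array([genome.length(c) for c in chroms], dtype=np.float64)
    weights /= weights.sum()
    placements = []
    for length in lengths:
        for _ in range(max_attempts_per_region):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            limit = genome.length(chrom) - length
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit + 1))
            if not occupancy.conflicts(chrom, start, start + length):
                occupancy.add(chrom, start, start + length)
                placements.append((chrom, start))
                break
        else:
            raise RuntimeError(
                f"could not place a {length}-bp region after "
                f"{max_attempts_per_region} attempts; use a larger genome or "
                "fewer regions"
            )
    return placements


def _draw_region_layout(
    spec: MatchedRegionSpec, rng: np.random.Generator
) -> Tuple[List[Tuple[int, int, float]], int]:
    """Segments of one matched region as (offset, length, value) plus the
    region's total extent."""
    n_seg = int(rng.integers(spec.segments_min, spec.segments_max + 1))
    seg_lens = rng.integers(spec.segment_len_min, spec.segment_len_max + 1, n_seg)
    gaps = rng.integers(spec.gap_min, spec.gap_max + 1, max(0, n_seg - 1))
    values = rng.uniform(spec.value_min, spec.value_max, n_seg)
    segments = []
    offset = 0
    for i in range(n_seg):
        segments.append((offset, int(seg_lens[i]), float(values[i])))
        offset += int(seg_lens[i])
        if i < n_seg - 1:
            offset += int(gaps[i])
    return segments, offset


def simulate_matched_pair(
    spec: MatchedRegionSpec,
    extra_segments_target: int = 0,
    extra_segments_query: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[SignalTrack, SignalTrack, TruthSet]:
    """Simulate a query/target pair sharing identical matched regions.

    The matched regions carry identical signal at identical positions in
    both files.  ``extra_segments_target`` decoy segments are inserted at
    random positions outside the truth regions in the target only;
    ``extra_segments_query`` adds independent decoys to the query as well
    (the harder, no-gold-standard design).
    """
    rng = rng if rng is not None else np.random.default_rng()
    genome = spec.genome
    layouts = [_draw_region_layout(spec, rng) for _ in range(spec.n_regions)]
    occupancy = _Occupancy()
    placements = _place([ext for _, ext in layouts], genome, rng, occupancy)

    q_ivs: Dict[str, List[Tuple[int, int, float]]] = {}
    t_ivs: Dict[str, List[Tuple[int, int, float]]] = {}
    truth_regions = []
    for (chrom, start), (segments, extent) in zip(placements, layouts):
        truth_regions.append(Region(chrom, start, start + extent))
        for off, length, value in segments:
            iv = (start + off, start + off + length, value)
            q_ivs.setdefault(chrom, []).append(iv)
            t_ivs.setdefault(chrom, []).append(iv)

    def add_extras(n: int, ivs: Dict[str, List[Tuple[int, int, float]]], occ: _Occupancy):
        lengths = rng.integers(
            spec.segment_len_min, spec.segment_len_max + 1, n
        )
        values = rng.uniform(spec.value_min, spec.value_max, n)
        spots = _place([int(l) for l in lengths], genome, rng, occ)
        for (chrom, start), length, value in zip(spots, lengths, values):
            ivs.setdefault(chrom, []).append(
                (start, start + int(length), float(value))
            )

    if extra_segments_target:
        add_extras(extra_segments_target, t_ivs, occupancy)
    if extra_segments_query:
        # query decoys avoid the truth and each other, but are placed
        # independently of the target's decoys (they may coincide — the
        # "matching typos" the conservative evaluation refuses to credit)
        q_occ = _Occupancy()
        for r in truth_regions:
            q_occ.add(r.chrom, r.start, r.end)
        add_extras(extra_segments_query, q_ivs, q_occ)

    query = SignalTrack.from_interval_lists(genome, q_ivs)
    target = SignalTrack.from_interval_lists(genome, t_ivs)
    provenance = "dataset2" if extra_segments_query else "dataset1"
    return query, target, TruthSet(truth_regions, provenance)


def _poisson_locations(
    n_bases: int, lam: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson-process locations on [0, n_bases) via cumulative
    Exponential(lam) gaps, rounded to integer bases and deduplicated."""
    expected = int(n_bases * lam)
    positions: List[np.ndarray] = []
    total = 0.0
    while total < n_bases:
        gaps = rng.exponential(1.0 / lam, size=max(1024, expected // 4))
        cum = total + np.cumsum(gaps)
        positions.append(cum)
        total = float(cum[-1])
    locs = np.concatenate(positions)
    locs = locs[locs < n_bases].astype(np.int64)
    return np.unique(locs)


def replace_with_noise(
    track: SignalTrack,
    positives: TruthSet,
    noise: NoiseSpec,
    layout: GenomeLayout,
    rng: Optional[np.random.Generator] = None,
    point_width: int = 10,
) -> SignalTrack:
    """Keep the track's signal inside the positive regions and replace
    everything else with Poisson-located Gaussian point noise.

    Each noise point is written as a ``point_width``-base interval;
    negative Gaussian draws are floored at 0, as intensities are
    non-negative in signal-track practice.
    """
    rng = rng if rng is not None else np.random.default_rng()
    mu, sigma2 = noise.mu, noise.sigma2
    if mu is None or sigma2 is None:
        total, total_sq, count = 0.0, 0.0, 0
        for r in positives.regions:
            vals = track.values_per_base(r.chrom, r.start, r.end)
            total += float(vals.sum())
            total_sq += float((vals * vals).sum())
            count += len(vals)
        if count == 0:
            raise ValueError("empty positive set; cannot estimate noise moments")
        est_mu = total / count
        est_var = max(0.0, total_sq / count - est_mu * est_mu)
        mu = est_mu if mu is None else mu
        sigma2 = est_var if sigma2 is None else sigma2

    pos_by_chrom: Dict[str, List[Region]] = {}
    for r in positives.regions:
        pos_by_chrom.setdefault(r.chrom, []).append(r)

    out: Dict[str, List[Tuple[int, int, float]]] = {}
    for chrom, length in layout:
        pos = pos_by_chrom.get(chrom, [])
        ivs: List[Tuple[int, int, float]] = []
        # kept signal: the original intervals clipped to the positives
        starts, ends, values = track.intervals(chrom)
        for r in pos:
            lo = int(np.searchsorted(ends, r.start, side="right"))
            hi = int(np.searchsorted(starts, r.end, side="left"))
            for i in range(lo, hi):
                s = max(int(starts[i]), r.start)
                e = min(int(ends[i]), r.end)
                if s < e:
                    ivs.append((s, e, float(values[i])))
        # noise elsewhere
        locs = _poisson_locations(length, noise.lam, rng)
        draws = rng.normal(mu, np.sqrt(sigma2), size=len(locs))
        if len(pos) > 0:
            pos_starts = np.array([r.start for r in pos])
            pos_ends = np.array([r.end for r in pos])
            idx = np.searchsorted(pos_ends, locs, side="right")
            inside = (idx < len(pos)) & (pos_starts[idx.clip(max=len(pos) - 1)] < locs + point_width)
            keep_loc = ~inside
        else:
            keep_loc = np.ones(len(locs), dtype=bool)
        prev_end = -1
        for loc, value in zip(locs[keep_loc], draws[keep_loc]):
            s = int(loc)
            e = min(s + point_width, length)
            if s < prev_end:
                s = prev_end  # trim points closer than one width apart
            if s < e:
                ivs.append((s, e, max(0.0, float(value))))
                prev_end = e
        out[chrom] = sorted(ivs)
    return SignalTrack.from_interval_lists(layout, out)


def derive_positives_by_self_search(
    track: SignalTrack,
    index: TargetIndex,
    k: int,
    config: SearchConfig,
    target_id: Optional[str] = None,
) -> TruthSet:
    """Search a track against itself (through the index) and return the
    top-k matched regions as the positive set."""
    if target_id is None:
        if len(index.entries) != 1:
            raise ValueError("target_id required for a multi-entry index")
        target_id = index.entries[0].target_id
    cfg = SearchConfig.from_dict({**config.to_dict(), "result_cap": max(k, config.result_cap)})
    res = run_search(track, index, {"target_id": [target_id]}, cfg)
    if len(res) < k:
        logger.warning(
            "self-search found only %d regions (requested %d)", len(res), k
        )
    top = res.results[:k]
    return TruthSet.from_regions(
        [r.region for r in top], provenance="noise_replacement"
    )


@dataclass
class EvaluationReport:
    """Sensitivity/precision of a result set against a truth set.

    ``precision`` is None (not applicable) when there are no results.
    """

    sensitivity: float
    precision: Optional[float]
    n_results: int
    n_truth: int
    true_positives: List[ScoredRegion]
    matched_truth: List[Region]

    def summary(self) -> str:
        prec = "NA" if self.precision is None else f"{self.precision:.4f}"
        return (
            f"sensitivity={self.sensitivity:.4f} precision={prec} "
            f"({len(self.true_positives)}/{self.n_results} true positives, "
            f"{len(self.matched_truth)}/{self.n_truth} truth regions hit)"
        )


def evaluate(
    results: "ResultSet | Sequence[ScoredRegion]",
    truth: TruthSet,
    expected_target: str = "any",
) -> EvaluationReport:
    """Score results against truth under the >= 1 base overlap rule.

    A result is a true positive iff it comes from ``expected_target``
    (or any target when ``expected_target == 'any'``) and overlaps at least
    one truth region.  Sensitivity is the fraction of truth regions hit by
    at least one true positive; precision the fraction of results that are
    true positives.
    """
    if len(truth) == 0:
        raise ValueError("empty truth set: sensitivity is undefined")
    regions = results.results if isinstance(results, ResultSet) else list(results)
    tps: List[ScoredRegion] = []
    hit = [False] * len(truth.regions)
    for res in regions:
        if expected_target != "any" and res.target_id != expected_target:
            continue
        overlapped = False
        for i, t in enumerate(truth.regions):
            if res.region.overlaps(t):
                hit[i] = True
                overlapped = True
        if overlapped:
            tps.append(res)
    matched = [t for t, h in zip(truth.regions, hit) if h]
    sensitivity = len(matched) / len(truth)
    precision = len(tps) / len(regions) if regions else None
    return EvaluationReport(
        sensitivity, precision, len(regions), len(truth), tps, matched
    )
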