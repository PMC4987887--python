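"""Core domain types: genome layout, signal tracks, regions, configuration.

All coordinates are 0-based, half-open ``[start, end)`` (the BED convention).
A :class:`SignalTrack` is a piecewise-constant, per-chromosome signal; bases
not covered by any stored interval have implicit value 0.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple

import numpy as np
import yaml


class GenomeLayout:
    """Ordered set of chromosomes with their lengths in bases.

    This is the coordinate universe for every track, region and simulator:
    chromosome names must be unique and lengths strictly positive.
    """

    def __init__(self, entries: Iterable[Tuple[str, int]]):
        names: List[str] = []
        lengths: Dict[str, int] = {}
        for name, length in entries:
            name = str(name)
            length = int(length)
            if name in lengths:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            names.append(name)
            lengths[name] = length
        self._names = names
        self._lengths = lengths

    @property
    def names(self) -> List[str]:
        return list(self._names)

    def length(self, chrom: str) -> int:
        return self._lengths[chrom]

    @property
    def total_size(self) -> int:
        """Total genome size in bases (sum of chromosome lengths)."""
        return sum(self._lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __len__(self) -> int:
        return len(self._names)

    def __iter__(self) -> Iterator[Tuple[str, int]]:
        for name in self._names:
            yield name, self._lengths[name]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeLayout):
            return NotImplemented
        return list(self) == list(other)

    def __repr__(self) -> str:
        return f"GenomeLayout({len(self)} chromosomes, {self.total_size} bp)"


@dataclass(frozen=True, order=True)
class Region:
    """A half-open genomic interval on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class ScoredRegion:
    """A region with its Pearson correlation and local similarity score
    against one target track.

    ``correlation`` is NaN when undefined (zero variance in either track on
    the region); ``score`` is then NaN too.
    """

    region: Region
    correlation: float
    score: float
    target_id: str = ""

    @property
    def defined(self) -> bool:
        return not math.isnan(self.score)


@dataclass
class TargetEntry:
    """One indexed target track with optional matched control and metadata."""

    target_id: str
    path: str
    format: str = "auto"
    control_path: Optional[str] = None
    control_format: str = "auto"
    metadata: Dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "TargetEntry":
        return cls(
            target_id=str(d["target_id"]),
            path=str(d["path"]),
            format=str(d.get("format", "auto")),
            control_path=d.get("control_path"),
            control_format=str(d.get("control_format", "auto")),
            metadata=dict(d.get("metadata", {})),
        )


@dataclass
class SearchConfig:
    """All engine tunables.

    Parameters
    ----------
    alpha:
        Weight of the region-length bonus in the local similarity score
        R = ln(C + 1.001) + alpha * ln(length).
    delta:
        Maximum boundary shift per MCMC proposal, in bases.
    seed_window:
        Width of the fixed seed windows, in bases.
    seed_c_min, seed_r_min:
        Correlation and score thresholds a window must reach to seed a chain.
    result_cap:
        Maximum number of regions returned by a search.
    min_score:
        Strict lower bound on reported scores (regions with R <= min_score
        are dropped).
    bin_size:
        Resolution (bases) of the comparison grid for correlations.
    mcmc_iterations:
        Number of Metropolis-Hastings steps per refined seed.
    threads, subsets:
        Worker count and number of non-overlapping target groups.
    control_mode:
        'subtract' (floored background subtraction) or 'log_ratio'.
    """

    alpha: float = 0.01
    delta: int = 100
    seed_window: int = 1000
    seed_c_min: float = 0.8
    seed_r_min: float = 0.5
    result_cap: int = 1000
    min_score: float = 0.0
    bin_size: int = 10
    mcmc_iterations: int = 2000
    threads: int = 1
    subsets: int = 100
    rng_seed: int = 0
    control_mode: str = "subtract"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.delta < 1:
            raise ValueError("delta must be >= 1")
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.seed_window < 2 * self.bin_size:
            raise ValueError("seed_window must be >= 2 * bin_size")
        if self.result_cap < 1:
            raise ValueError("result_cap must be >= 1")
        if not (1 <= self.threads <= 24):
            raise ValueError("threads must be in [1, 24]")
        if not (1 <= self.subsets <= 100):
            raise ValueError("subsets must be in [1, 100]")
        if self.mcmc_iterations < 0:
            raise ValueError("mcmc_iterations must be >= 0")
        if self.control_mode not in ("subtract", "log_ratio"):
            raise ValueError("control_mode must be 'subtract' or 'log_ratio'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SearchConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{k: d[k] for k in d})

    @classmethod
    def from_yaml(cls, path: str) -> "SearchConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


IntervalArrays = Tuple[np.ndarray, np.ndarray, np.ndarray]  # starts, ends, values


class SignalTrack:
    """Piecewise-constant per-chromosome signal.

    Intervals are half-open, non-overlapping and sorted by start; uncovered
    bases have implicit value 0.  ``resolution`` is ``None`` for native-
    resolution tracks or the bin width (bases) for binned tracks.
    """

    def __init__(
        self,
        layout: GenomeLayout,
        data: Mapping[str, IntervalArrays],
        resolution: Optional[int] = None,
        validate: bool = True,
    ):
        self.layout = layout
        self.resolution = resolution
        self._data: Dict[str, IntervalArrays] = {}
        for chrom, (starts, ends, values) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if validate:
                self._check(chrom, starts, ends, values)
            self._data[chrom] = (starts, ends, values)

    def _check(self, chrom: str, starts, ends, values) -> None:
        if chrom not in self.layout:
            raise ValueError(f"chromosome {chrom!r} not in genome layout")
        if not (len(starts) == len(ends) == len(values)):
            raise ValueError("interval array length mismatch")
        if len(starts) == 0:
            return
        if np.any(starts >= ends):
            raise ValueError(f"empty or inverted interval on {chrom}")
        if np.any(starts < 0) or np.any(ends > self.layout.length(chrom)):
            raise ValueError(f"interval outside chromosome bounds on {chrom}")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping or unsorted intervals on {chrom}")

    @classmethod
    def from_interval_lists(
        cls,
        layout: GenomeLayout,
        intervals: Mapping[str, Iterable[Tuple[int, int, float]]],
        resolution: Optional[int] = None,
    ) -> "SignalTrack":
        data = {}
        for chrom, ivs in intervals.items():
            ivs = sorted(ivs)
            starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
            ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
            values = np.array([v for _, _, v in ivs], dtype=np.float64)
            data[chrom] = (starts, ends, values)
        return cls(layout, data, resolution=resolution)

    @property
    def chroms(self) -> List[str]:
        return [c for c in self.layout.names if c in self._data]

    def intervals(self, chrom: str) -> IntervalArrays:
        if chrom in self._data:
            return self._data[chrom]
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, np.empty(0, dtype=np.float64)

    def n_intervals(self) -> int:
        return sum(len(s) for s, _, _ in self._data.values())

    def is_empty(self) -> bool:
        return all(len(s) == 0 for s, _, _ in self._data.values())

    def total_mass(self) -> float:
        """Sum over the genome of value * interval width."""
        total = 0.0
        for starts, ends, values in self._data.values():
            total += float(np.sum((ends - starts) * values))
        return total

    def values_per_base(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-base values over ``[start, end)`` (zeros where uncovered)."""
        if chrom not in self.layout:
            raise KeyError(chrom)
        if not (0 <= start < end <= self.layout.length(chrom)):
            raise ValueError(f"region {chrom}:{start}-{end} outside chromosome")
        out = np.zeros(end - start, dtype=np.float64)
        starts, ends, values = self.intervals(chrom)
        if len(starts) == 0:
            return out
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            s = max(int(starts[i]), start)
            e = min(int(ends[i]), end)
            if s < e:
                out[s - start : e - start] = values[i]
        return out

    def dense_bins(self, chrom: str, bin_size: int) -> np.ndarray:
        """Per-bin mean signal across the whole chromosome.

        Bin b covers ``[b*bin_size, (b+1)*bin_size)`` clipped at the
        chromosome end; uncovered bases contribute 0 and the (possibly
        shorter) final bin is averaged over its true width.
        """
        if bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        n = self.layout.length(chrom)
        nb = -(-n // bin_size)
        base = np.zeros(nb * bin_size, dtype=np.float64)
        starts, ends, values = self.intervals(chrom)
        for i in range(len(starts)):
            base[starts[i] : ends[i]] = values[i]
        sums = base.reshape(nb, bin_size).sum(axis=1)
        widths = np.full(nb, bin_size, dtype=np.float64)
        widths[-1] = n - (nb - 1) * bin_size
        return sums / widths

    @classmethod
    def from_dense_bins(
        cls,
        layout: GenomeLayout,
        bins: Mapping[str, np.ndarray],
        bin_size: int,
    ) -> "SignalTrack":
        """Run-length-encode per-bin value arrays into a binned track.

        Zero-valued runs are left implicit, so sparse genomes stay compact.
        """
        data = {}
        for chrom, vals in bins.items():
            vals = np.asarray(vals, dtype=np.float64)
            n = layout.length(chrom)
            if len(vals) == 0:
                continue
            change = np.flatnonzero(vals[1:] != vals[:-1]) + 1
            run_starts = np.concatenate(([0], change))
            run_ends = np.concatenate((change, [len(vals)]))
            run_vals = vals[run_starts]
            keep = run_vals != 0.0
            starts = (run_starts[keep] * bin_size).astype(np.int64)
            ends = np.minimum(run_ends[keep] * bin_size, n).astype(np.int64)
            data[chrom] = (starts, ends, run_vals[keep])
        return cls(layout, data, resolution=bin_size)

    def __repr__(self) -> str:
        res = "native" if self.resolution is None else f"{self.resolution}bp bins"
        return f"SignalTrack({len(self._data)} chroms, {self.n_intervals()} intervals, {res})"


def bin_track(track: SignalTrack, bin_size: int) -> SignalTrack:
    """Resample a track onto a fixed grid of ``bin_size``-base bins.

    Each bin's value is the coverage-weighted mean of the native signal over
    the bin (uncovered bases count as 0), so total signal mass is conserved
    for tracks aligned to whole bins.
    """
    bins = {c: track.dense_bins(c, bin_size) for c in track.chroms}
    return SignalTrack.from_dense_bins(track.layout, bins, bin_size)
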