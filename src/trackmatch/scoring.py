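"""Control normalization, windowed Pearson correlation and the local
similarity score.

The score of a candidate region is

    R = ln(C + 1.001) + alpha * ln(L)

where C is the Pearson correlation of the two binned signals over the
region and L the region length in bases.  Natural logarithms are used for
both terms; the choice of base only rescales R monotonically and leaves
every ranking unchanged, and all thresholds in this package are stated in
this base.  Since C >= -1 the first argument is >= 0.001, so R is finite
whenever C is defined; C is undefined (NaN) when either binned signal has
zero variance on the region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .genome import GenomeLayout, Region, SignalTrack

logger = logging.getLogger(__name__)

# Relative tolerance for declaring a binned segment zero-variance.  The
# variance term n*Sxx - Sx^2 of an exactly-constant segment only differs
# from 0 by accumulated rounding, which this threshold absorbs.
_VAR_RTOL = 1e-10


@dataclass(frozen=True)
class ScoreParams:
    """Tuning parameters of the local similarity score."""

    alpha: float = 0.01

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


def local_score(
    correlation: float, region_length: int, params: ScoreParams = ScoreParams()
) -> float:
    """R = ln(correlation + 1.001) + alpha * ln(region_length).

    NaN (undefined) correlations propagate to a NaN score.
    """
    if region_length < 1:
        raise ValueError("region_length must be >= 1")
    if math.isnan(correlation):
        return math.nan
    return math.log(correlation + 1.001) + params.alpha * math.log(region_length)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation; NaN when either vector is constant."""
    n = len(x)
    if n < 2:
        return math.nan
    sx, sy = float(x.sum()), float(y.sum())
    sxx, syy, sxy = float(x @ x), float(y @ y), float(x @ y)
    vx = n * sxx - sx * sx
    vy = n * syy - sy * sy
    if vx <= _VAR_RTOL * max(1.0, n * sxx) or vy <= _VAR_RTOL * max(1.0, n * syy):
        return math.nan
    c = (n * sxy - sx * sy) / math.sqrt(vx * vy)
    return min(1.0, max(-1.0, c))


def _region_bin_means(
    track: SignalTrack, region: Region, bin_size: int
) -> np.ndarray:
    """Bin a region on a grid anchored at region.start; the partial last bin
    is averaged over its true width."""
    base = track.values_per_base(region.chrom, region.start, region.end)
    L = len(base)
    nb = -(-L // bin_size)
    padded = np.zeros(nb * bin_size, dtype=np.float64)
    padded[:L] = base
    sums = padded.reshape(nb, bin_size).sum(axis=1)
    widths = np.full(nb, bin_size, dtype=np.float64)
    widths[-1] = L - (nb - 1) * bin_size
    return sums / widths


def pearson_in_region(
    query: SignalTrack, target: SignalTrack, region: Region, bin_size: int
) -> float:
    """Pearson correlation of two tracks over a region at bin resolution.

    Both tracks are binned over the region on the same grid (anchored at the
    region start, partial last bin included).  Returns NaN when either bin
    vector has zero variance.
    """
    if region.length < 2 * bin_size:
        raise ValueError("region length must be >= 2 * bin_size")
    if region.chrom not in query.layout or region.end > query.layout.length(region.chrom):
        raise ValueError(f"region {region} outside chromosome")
    qx = _region_bin_means(query, region, bin_size)
    tx = _region_bin_means(target, region, bin_size)
    return _pearson(qx, tx)


def normalize_to_control(
    target: SignalTrack,
    control: SignalTrack,
    bin_size: int = 10,
    mode: str = "subtract",
) -> SignalTrack:
    """Normalize a target track to its matched control (e.g. an IgG ChIP).

    Both tracks are binned, then scaled so that the genome-wide mean of
    their nonzero bins is 1 (this removes depth differences without letting
    the empty majority of the genome dominate).  In ``subtract`` mode the
    output is max(0, target_scaled - control_scaled) per bin — background
    removal semantics; ``log_ratio`` gives max(0, log2((t+1)/(c+1))).

    An all-zero control yields the scaled target with a logged warning.
    """
    if mode not in ("subtract", "log_ratio"):
        raise ValueError("mode must be 'subtract' or 'log_ratio'")
    layout = target.layout
    tb = {c: target.dense_bins(c, bin_size) for c in layout.names}
    cb = {c: control.dense_bins(c, bin_size) for c in layout.names}

    def nonzero_mean(bins: Dict[str, np.ndarray]) -> float:
        total, count = 0.0, 0
        for arr in bins.values():
            nz = arr[arr != 0.0]
            total += float(nz.sum())
            count += len(nz)
        return total / count if count else 0.0

    tm = nonzero_mean(tb)
    cm = nonzero_mean(cb)
    ts = 1.0 / tm if tm else 1.0
    if cm == 0.0:
        logger.warning("control track is all-zero; returning scaled target only")
        out = {c: tb[c] * ts for c in tb}
        return SignalTrack.from_dense_bins(layout, out, bin_size)
    cs = 1.0 / cm
    out = {}
    for c in tb:
        t, ctl = tb[c] * ts, cb[c] * cs
        if mode == "subtract":
            out[c] = np.maximum(0.0, t - ctl)
        else:
            out[c] = np.maximum(0.0, np.log2((t + 1.0) / (ctl + 1.0)))
    return SignalTrack.from_dense_bins(layout, out, bin_size)


class RegionScorer:
    """O(1) correlation and score queries on one chromosome via prefix sums.

    Built from the two dense bin vectors of a (query, target) pair, this
    serves both the vectorized seed-window scan and the many small region
    evaluations made by the MCMC refinement.  Regions are mapped to the set
    of global-grid bins they overlap; because binned tracks are constant
    within a bin, a partial bin's mean equals the bin value, so this is the
    exact binned correlation.
    """

    def __init__(
        self,
        query_bins: np.ndarray,
        target_bins: np.ndarray,
        bin_size: int,
        alpha: float,
        chrom_length: int,
    ):
        x = np.asarray(query_bins, dtype=np.float64)
        y = np.asarray(target_bins, dtype=np.float64)
        if len(x) != len(y):
            raise ValueError("query and target bin vectors differ in length")
        self.bin_size = int(bin_size)
        self.alpha = float(alpha)
        self.chrom_length = int(chrom_length)
        self.n_bins = len(x)
        z = np.zeros(1)
        self._cx = np.concatenate((z, np.cumsum(x)))
        self._cy = np.concatenate((z, np.cumsum(y)))
        self._cxx = np.concatenate((z, np.cumsum(x * x)))
        self._cyy = np.concatenate((z, np.cumsum(y * y)))
        self._cxy = np.concatenate((z, np.cumsum(x * y)))

    def _bin_range(self, start: int, end: int) -> Tuple[int, int]:
        b1 = start // self.bin_size
        b2 = min(self.n_bins, -(-end // self.bin_size))
        return b1, b2

    def correlation(self, start: int, end: int) -> float:
        """Pearson correlation over the bins overlapping [start, end)."""
        if not (0 <= start < end <= self.chrom_length):
            raise ValueError(f"region [{start}, {end}) outside chromosome")
        b1, b2 = self._bin_range(start, end)
        n = b2 - b1
        if n < 2:
            return math.nan
        sx = self._cx[b2] - self._cx[b1]
        sy = self._cy[b2] - self._cy[b1]
        sxx = self._cxx[b2] - self._cxx[b1]
        syy = self._cyy[b2] - self._cyy[b1]
        sxy = self._cxy[b2] - self._cxy[b1]
        vx = n * sxx - sx * sx
        vy = n * syy - sy * sy
        if vx <= _VAR_RTOL * max(1.0, n * sxx) or vy <= _VAR_RTOL * max(1.0, n * syy):
            return math.nan
        c = (n * sxy - sx * sy) / math.sqrt(vx * vy)
        return min(1.0, max(-1.0, c))

    def score(self, start: int, end: int) -> float:
        """Local similarity score R over [start, end); NaN when C undefined."""
        c = self.correlation(start, end)
        if math.isnan(c):
            return math.nan
        return math.log(c + 1.001) + self.alpha * math.log(end - start)

    def window_stats(
        self, window_bases: int
    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Correlation and score for every window of ``window_bases`` bases
        slid one bin at a time.

        Returns ``(starts, correlations, scores)`` over all fully-contained
        window positions; undefined windows carry NaN.
        """
        w = window_bases // self.bin_size
        if w < 2:
            raise ValueError("window must span at least 2 bins")
        m = self.n_bins - w + 1
        if m <= 0:
            return (
                np.empty(0, dtype=np.int64),
                np.empty(0),
                np.empty(0),
            )
        sx = self._cx[w:] - self._cx[:-w]
        sy = self._cy[w:] - self._cy[:-w]
        sxx = self._cxx[w:] - self._cxx[:-w]
        syy = self._cyy[w:] - self._cyy[:-w]
        sxy = self._cxy[w:] - self._cxy[:-w]
        vx = w * sxx - sx * sx
        vy = w * syy - sy * sy
        defined = (vx > _VAR_RTOL * np.maximum(1.0, w * sxx)) & (
            vy > _VAR_RTOL * np.maximum(1.0, w * syy)
        )
        corr = np.full(m, np.nan)
        np.divide(
            w * sxy - sx * sy,
            np.sqrt(vx * vy, where=defined, out=np.ones_like(vx)),
            where=defined,
            out=corr,
        )
        np.clip(corr, -1.0, 1.0, out=corr)
        scores = np.log(corr + 1.001) + self.alpha * math.log(w * self.bin_size)
        starts = np.arange(m, dtype=np.int64) * self.bin_size
        return starts, corr, scores


def make_scorer(
    query: SignalTrack,
    target: SignalTrack,
    chrom: str,
    bin_size: int,
    alpha: float,
    layout: Optional[GenomeLayout] = None,
) -> RegionScorer:
    """Build a RegionScorer for one chromosome of a track pair."""
    layout = layout or query.layout
    return RegionScorer(
        query.dense_bins(chrom, bin_size),
        target.dense_bins(chrom, bin_size),
        bin_size,
        alpha,
        layout.length(chrom),
    )
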