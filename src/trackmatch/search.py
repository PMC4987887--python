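"""End-to-end search orchestration: index targets, fan the per-target
searches out over workers, assemble, rank and cap the results.

Determinism is a hard contract: per-target RNG streams are derived from
(rng_seed, target_id), and assembly and ranking are order-independent, so
the output is byte-identical whatever the thread count or scheduling.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

import numpy as np

from . import io as tmio
from .genome import (
    GenomeLayout,
    Region,
    ScoredRegion,
    SearchConfig,
    SignalTrack,
)
from .genome import TargetEntry
from .mcmc import refine_region
from .scoring import RegionScorer, normalize_to_control
from .seeding import merge_region_tuples, seed_window_arrays

logger = logging.getLogger(__name__)


@dataclass
class TargetIndex:
    """A local collection of target tracks with metadata for filtering."""

    genome: GenomeLayout
    entries: List[TargetEntry] = field(default_factory=list)
    errors: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.target_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate target_id in index: {dup}")

    def vocabulary(self) -> Dict[str, List[str]]:
        """Distinct values per metadata field (plus target_id)."""
        vocab: Dict[str, set] = {"target_id": set()}
        for e in self.entries:
            vocab["target_id"].add(e.target_id)
            for k, v in e.metadata.items():
                vocab.setdefault(k, set()).add(v)
        return {k: sorted(v) for k, v in vocab.items()}

    def save(self, path: str) -> None:
        doc = {
            "genome": [[name, length] for name, length in self.genome],
            "entries": [e.to_dict() for e in self.entries],
            "errors": self.errors,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")

    @classmethod
    def load(cls, path: str) -> "TargetIndex":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            genome=GenomeLayout((n, l) for n, l in doc["genome"]),
            entries=[TargetEntry.from_dict(d) for d in doc["entries"]],
            errors=list(doc.get("errors", [])),
        )


def build_index(
    track_specs: Sequence[Mapping],
    layout: GenomeLayout,
    out_path: Optional[str] = None,
) -> TargetIndex:
    """Validate track specs and assemble a TargetIndex.

    Each spec is a mapping with keys ``path`` (required), ``target_id``,
    ``format``, ``control_path``, ``control_format`` and ``metadata``.
    Unreadable or layout-disjoint tracks are recorded in ``index.errors``
    and the index is built from the valid remainder.
    """
    entries: List[TargetEntry] = []
    errors: List[str] = []
    for spec in track_specs:
        entry = TargetEntry.from_dict(
            {
                "target_id": spec.get("target_id")
                or str(spec["path"]).rsplit("/", 1)[-1].rsplit(".", 1)[0],
                **{k: spec[k] for k in spec if k != "target_id"},
            }
        )
        try:
            track = tmio.read_signal(entry.path, entry.format, layout)
            if entry.control_path is not None:
                tmio.read_signal(entry.control_path, entry.control_format, layout)
            if not track.chroms and not track.is_empty():
                raise tmio.EmptyTrackError(entry.path)
        except (OSError, ValueError) as exc:
            msg = f"{entry.target_id}: {exc}"
            errors.append(msg)
            logger.warning("skipping target %s", msg)
            continue
        entries.append(entry)
    index = TargetIndex(genome=layout, entries=entries, errors=errors)
    if out_path is not None:
        index.save(out_path)
    return index


def filter_targets(
    index: TargetIndex, filters: Mapping[str, Iterable[str]]
) -> List[TargetEntry]:
    """Select entries matching every filter field (conjunction across
    fields, disjunction within a field).  Empty filters select all."""
    vocab = index.vocabulary()
    for fld in filters:
        if fld not in vocab:
            raise KeyError(
                f"unknown filter field {fld!r}; known fields: {sorted(vocab)}"
            )
    out = []
    for e in index.entries:
        ok = True
        for fld, allowed in filters.items():
            allowed = set(allowed)
            value = e.target_id if fld == "target_id" else e.metadata.get(fld)
            if value not in allowed:
                ok = False
                break
        if ok:
            out.append(e)
    return out


def _target_rng(rng_seed: int, target_id: str) -> np.random.Generator:
    """Per-target generator derived from (rng_seed, target_id), so the
    parallel schedule can never change what any one target computes."""
    digest = hashlib.sha256(target_id.encode()).digest()
    tid_word = int.from_bytes(digest[:4], "little")
    return np.random.default_rng([int(rng_seed) & 0x7FFFFFFF, tid_word])


def _dedup_keep_best(regions: List[ScoredRegion]) -> List[ScoredRegion]:
    """Drop regions overlapping an already-kept higher-scoring region."""
    kept: List[ScoredRegion] = []
    for r in sorted(
        regions, key=lambda r: (-r.score, r.region.start, r.region.end)
    ):
        if not any(r.region.overlaps(k.region) for k in kept):
            kept.append(r)
    return kept


def search_one_target(
    query: SignalTrack,
    entry: TargetEntry,
    config: SearchConfig,
    rng: Optional[np.random.Generator] = None,
    query_bins: Optional[Dict[str, np.ndarray]] = None,
    target_track: Optional[SignalTrack] = None,
) -> List[ScoredRegion]:
    """Search the query against one target: per chromosome, seed, merge and
    refine; then deduplicate overlaps (keep the higher score) and filter to
    scores strictly above ``config.min_score``.

    When metadata provides a matched control track, the target is
    normalized to it before scoring.
    """
    layout = query.layout
    if rng is None:
        rng = _target_rng(config.rng_seed, entry.target_id)
    if target_track is None:
        target_track = tmio.read_signal(entry.path, entry.format, layout)
    if entry.control_path is not None:
        control = tmio.read_signal(entry.control_path, entry.control_format, layout)
        target_track = normalize_to_control(
            target_track, control, config.bin_size, mode=config.control_mode
        )
    B = config.bin_size
    results: List[ScoredRegion] = []
    for chrom in layout.names:
        qb = (
            query_bins[chrom]
            if query_bins is not None
            else query.dense_bins(chrom, B)
        )
        tb = target_track.dense_bins(chrom, B)
        if not qb.any() or not tb.any():
            continue
        scorer = RegionScorer(qb, tb, B, config.alpha, layout.length(chrom))
        starts, corr, scores = seed_window_arrays(scorer, config)
        if len(starts) == 0:
            continue
        w = (config.seed_window // B) * B
        tuples = [
            (int(s), int(s) + w, float(c), float(r))
            for s, c, r in zip(starts, corr, scores)
        ]
        merged = merge_region_tuples(tuples, scorer)
        refined = [
            refine_region(
                query,
                target_track,
                ScoredRegion(Region(chrom, s, e), c, r, entry.target_id),
                config,
                rng,
                scorer=scorer,
            )
            for s, e, c, r in merged
        ]
        # chains started from nearby seeds can converge on overlapping
        # optima; apply the same union-if-better rule used for seeds, then
        # drop whatever overlaps still remain, keeping the higher score
        refined_tuples = merge_region_tuples(
            [
                (r.region.start, r.region.end, float(r.correlation), float(r.score))
                for r in refined
                if r.defined
            ],
            scorer,
        )
        deduped = _dedup_keep_best(
            [
                ScoredRegion(Region(chrom, s, e), c, r, entry.target_id)
                for s, e, c, r in refined_tuples
            ]
        )
        results.extend(deduped)
    return [
        r for r in results if r.defined and r.score > config.min_score
    ]


@dataclass
class ResultSet:
    """Ranked search output: regions sorted by score (descending), capped
    at ``result_cap``, all scores strictly above ``min_score``."""

    results: List[ScoredRegion]
    config: SearchConfig
    target_logs: Dict[str, dict] = field(default_factory=dict)
    failures: Dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.results)

    def write(self, path: str, manifest_path: Optional[str] = None) -> None:
        tmio.write_results(self.results, path, self.config, manifest_path)


def _rank(results: List[ScoredRegion], cap: int) -> List[ScoredRegion]:
    ranked = sorted(
        results,
        key=lambda r: (
            -r.score,
            r.region.chrom,
            r.region.start,
            r.region.end,
            r.target_id,
        ),
    )
    return ranked[:cap]


def run_search(
    query: Union[str, SignalTrack],
    index: TargetIndex,
    filters: Optional[Mapping[str, Iterable[str]]] = None,
    config: Optional[SearchConfig] = None,
) -> ResultSet:
    """Search a query track against every (filtered) target in an index.

    Targets are split into ``min(subsets, n_targets)`` non-overlapping
    groups processed on up to ``config.threads`` workers.  Output is
    independent of thread count: per-target RNG streams and a global
    re-sort make scheduling unobservable.
    """
    config = config or SearchConfig()
    layout = index.genome
    if isinstance(query, (str, bytes)):
        query_track = tmio.read_signal(str(query), "auto", layout)
    else:
        query_track = query
    entries = filter_targets(index, filters or {})
    if not entries:
        logger.warning("no targets to search after filtering")
        return ResultSet([], config)
    query_bins = {
        c: query_track.dense_bins(c, config.bin_size) for c in layout.names
    }

    n_groups = min(config.subsets, len(entries))
    groups = [entries[i::n_groups] for i in range(n_groups)]

    def process_group(group: List[TargetEntry]):
        out = []
        for entry in group:
            t0 = time.perf_counter()
            try:
                res = search_one_target(
                    query_track, entry, config, query_bins=query_bins
                )
                out.append(
                    (entry.target_id, res, {"n_regions": len(res),
                                            "seconds": time.perf_counter() - t0},
                     None)
                )
            except (OSError, ValueError) as exc:
                logger.warning("target %s failed: %s", entry.target_id, exc)
                out.append((entry.target_id, [], {}, str(exc)))
        return out

    if config.threads > 1 and len(groups) > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            group_outputs = list(pool.map(process_group, groups))
    else:
        group_outputs = [process_group(g) for g in groups]

    all_results: List[ScoredRegion] = []
    logs: Dict[str, dict] = {}
    failures: Dict[str, str] = {}
    for out in group_outputs:
        for tid, res, log, err in out:
            all_results.extend(res)
            logs[tid] = log
            if err is not None:
                failures[tid] = err
    if failures and len(failures) == len(entries):
        logger.warning("all %d targets failed", len(entries))
    return ResultSet(
        _rank(all_results, config.result_cap), config, logs, failures
    )
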