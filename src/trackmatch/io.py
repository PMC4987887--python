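"""Readers and writers for the on-disk formats the engine touches.

Supported inputs: bigWig, bedGraph, fixedStep/variableStep WIG, BED3+ and
two-column ``chrom.sizes`` files.  Outputs: bedGraph, BED6+ result files
with a JSON manifest.

Internally everything is 0-based half-open; WIG's 1-based starts are
converted on read.  Unknown chromosomes are skipped with a warning — tracks
from slightly different assembly patch levels are common in practice.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .genome import GenomeLayout, Region, ScoredRegion, SearchConfig, SignalTrack

logger = logging.getLogger(__name__)

BIGWIG_MAGIC = 0x888FFC26

FORMATS = ("bigWig", "bedGraph", "WIG", "BED")


class FormatError(ValueError):
    """Raised when a file does not parse under its declared format."""


class EmptyTrackError(ValueError):
    """Raised when no chromosome of an input file matches the genome layout."""


def read_chrom_sizes(path: str) -> GenomeLayout:
    """Read a two-column ``chrom<TAB>length`` file into a GenomeLayout."""
    entries = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{ln}: expected 'chrom length'")
            try:
                entries.append((parts[0], int(parts[1])))
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: bad length {parts[1]!r}") from exc
    return GenomeLayout(entries)


def write_chrom_sizes(layout: GenomeLayout, path: str) -> None:
    with open(path, "w") as fh:
        for name, length in layout:
            fh.write(f"{name}\t{length}\n")


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _is_int(token: str) -> bool:
    try:
        int(token)
        return True
    except ValueError:
        return False


def detect_format(path: str) -> str:
    """Classify a file as bigWig, bedGraph, WIG or BED.

    bigWig is recognised by its 4-byte magic number; text files are
    classified from their header keywords and column structure: a
    ``fixedStep``/``variableStep`` declaration means WIG, four columns with a
    numeric fourth column mean bedGraph, three-or-more columns with integer
    coordinates and no numeric fourth column mean BED.
    """
    with open(path, "rb") as fh:
        head = fh.read(4)
    if len(head) == 4:
        for order in ("<", ">"):
            if int.from_bytes(head, "little" if order == "<" else "big") == BIGWIG_MAGIC:
                return "bigWig"
    try:
        text_lines: List[str] = []
        with open(path, "r", errors="strict") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "browser")):
                    continue
                text_lines.append(line)
                if len(text_lines) >= 50:
                    break
    except UnicodeDecodeError as exc:
        raise FormatError(
            f"{path}: not a recognised format (accepted: {', '.join(FORMATS)})"
        ) from exc

    declared = None
    for line in text_lines:
        if line.startswith(("fixedStep", "variableStep")):
            return "WIG"
        if line.startswith("track"):
            if "type=bedGraph" in line:
                declared = "bedGraph"
            elif "type=wiggle_0" in line:
                return "WIG"
            continue
        parts = line.split()
        if len(parts) >= 3 and _is_int(parts[1]) and _is_int(parts[2]):
            if declared == "bedGraph":
                return "bedGraph"
            if len(parts) >= 4 and _is_number(parts[3]):
                return "bedGraph"
            return "BED"
        if len(parts) == 2 and _is_int(parts[0]) and _is_number(parts[1]):
            return "WIG"  # variableStep body without a seen declaration
        break
    raise FormatError(
        f"{path}: not a recognised format (accepted: {', '.join(FORMATS)})"
    )


def _assemble(
    layout: GenomeLayout,
    per_chrom: Dict[str, List[Tuple[int, int, float]]],
    path: str,
    skipped: Iterable[str],
    union: bool = False,
) -> SignalTrack:
    skipped = sorted(set(skipped))
    if skipped:
        logger.warning(
            "%s: skipped %d chromosome(s) absent from the genome layout: %s",
            path,
            len(skipped),
            ", ".join(skipped[:5]) + ("..." if len(skipped) > 5 else ""),
        )
    if not per_chrom and skipped:
        raise EmptyTrackError(
            f"{path}: no chromosome matches the genome layout "
            f"(file chromosomes: {', '.join(skipped[:5])})"
        )
    data = {}
    for chrom, ivs in per_chrom.items():
        ivs.sort()
        if union:
            merged: List[List[float]] = []
            for s, e, v in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e, v])
            ivs = [(int(s), int(e), float(v)) for s, e, v in merged]
        else:
            for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise FormatError(
                        f"{path}: overlapping intervals on {chrom} at {s2}"
                    )
        n = layout.length(chrom)
        ivs = [(s, min(e, n), v) for s, e, v in ivs if s < n]
        data[chrom] = (
            np.array([s for s, _, _ in ivs], dtype=np.int64),
            np.array([e for _, e, _ in ivs], dtype=np.int64),
            np.array([v for _, _, v in ivs], dtype=np.float64),
        )
    return SignalTrack(layout, data)


def _read_bed(path: str, layout: GenomeLayout, binarize: bool = True) -> SignalTrack:
    per_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
    skipped = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: BED record needs >= 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{ln}: start >= end")
            if chrom not in layout:
                skipped.add(chrom)
                continue
            per_chrom.setdefault(chrom, []).append((start, end, 1.0))
    return _assemble(layout, per_chrom, path, skipped, union=True)


def _read_bedgraph(path: str, layout: GenomeLayout) -> SignalTrack:
    per_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
    skipped = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: bedGraph record needs 4 columns")
            chrom = parts[0]
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: bad bedGraph record") from exc
            if start >= end:
                raise FormatError(f"{path}:{ln}: start >= end")
            if chrom not in layout:
                skipped.add(chrom)
                continue
            if value != 0.0:
                per_chrom.setdefault(chrom, []).append((start, end, value))
            elif chrom not in per_chrom:
                per_chrom.setdefault(chrom, [])
    return _assemble(layout, per_chrom, path, skipped)


def _parse_kv(parts: Sequence[str]) -> Dict[str, str]:
    out = {}
    for p in parts:
        if "=" in p:
            k, v = p.split("=", 1)
            out[k] = v
    return out


def _read_wig(path: str, layout: GenomeLayout) -> SignalTrack:
    per_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
    skipped = set()
    mode = None  # ("fixed", chrom, next_start0, step, span) | ("variable", chrom, span)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = _parse_kv(line.split()[1:])
                try:
                    chrom = kv["chrom"]
                    start0 = int(kv["start"]) - 1  # WIG is 1-based
                    step = int(kv.get("step", 1))
                    span = int(kv.get("span", 1))
                except (KeyError, ValueError) as exc:
                    raise FormatError(f"{path}:{ln}: bad fixedStep header") from exc
                if start0 < 0 or step < 1 or span < 1:
                    raise FormatError(f"{path}:{ln}: bad fixedStep header")
                mode = ["fixed", chrom, start0, step, span]
                continue
            if line.startswith("variableStep"):
                kv = _parse_kv(line.split()[1:])
                if "chrom" not in kv:
                    raise FormatError(f"{path}:{ln}: variableStep needs chrom=")
                mode = ["variable", kv["chrom"], int(kv.get("span", 1))]
                continue
            if mode is None:
                raise FormatError(f"{path}:{ln}: WIG data before any declaration line")
            if mode[0] == "fixed":
                _, chrom, start0, step, span = mode
                try:
                    value = float(line.split()[0])
                except ValueError as exc:
                    raise FormatError(f"{path}:{ln}: bad WIG value") from exc
                if chrom in layout:
                    per_chrom.setdefault(chrom, []).append(
                        (start0, start0 + span, value)
                    )
                else:
                    skipped.add(chrom)
                mode[2] = start0 + step
            else:
                _, chrom, span = mode
                parts = line.split()
                if len(parts) < 2:
                    raise FormatError(f"{path}:{ln}: variableStep record needs 2 columns")
                try:
                    start0 = int(parts[0]) - 1
                    value = float(parts[1])
                except ValueError as exc:
                    raise FormatError(f"{path}:{ln}: bad variableStep record") from exc
                if start0 < 0:
                    raise FormatError(f"{path}:{ln}: WIG position must be >= 1")
                if chrom in layout:
                    per_chrom.setdefault(chrom, []).append((start0, start0 + span, value))
                else:
                    skipped.add(chrom)
    return _assemble(layout, per_chrom, path, skipped)


def _read_bigwig(path: str, layout: GenomeLayout) -> SignalTrack:
    import pyBigWig

    per_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
    skipped = set()
    bw = pyBigWig.open(path)
    try:
        for chrom in bw.chroms():
            if chrom not in layout:
                skipped.add(chrom)
                continue
            ivs = bw.intervals(chrom)
            per_chrom[chrom] = (
                [(int(s), int(e), float(v)) for s, e, v in ivs if v != 0.0]
                if ivs
                else []
            )
    finally:
        bw.close()
    return _assemble(layout, per_chrom, path, skipped)


def read_signal(path: str, format: str, layout: GenomeLayout) -> SignalTrack:
    """Read a signal file into a SignalTrack.

    ``format`` is one of bigWig/bedGraph/WIG/BED or ``auto`` (magic-byte and
    column-structure sniffing).  BED records are binarized to value 1.0 and
    overlapping records are unioned; the other formats carry intensities.
    """
    if format == "auto":
        format = detect_format(path)
    if format == "BED":
        return _read_bed(path, layout)
    if format == "bedGraph":
        return _read_bedgraph(path, layout)
    if format == "WIG":
        return _read_wig(path, layout)
    if format == "bigWig":
        return _read_bigwig(path, layout)
    raise ValueError(f"unknown format {format!r}; accepted: {', '.join(FORMATS)}")


def write_bedgraph(track: SignalTrack, path: str) -> None:
    """Write a track's stored intervals as 4-column bedGraph."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values = track.intervals(chrom)
            for i in range(len(starts)):
                fh.write(f"{chrom}\t{starts[i]}\t{ends[i]}\t{values[i]:.10g}\n")


def read_bed_regions(path: str, layout: GenomeLayout) -> List[Region]:
    """Read plain regions (e.g. a truth set) from a BED3+ file."""
    regions = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: BED record needs >= 3 columns")
            if parts[0] not in layout:
                continue
            regions.append(Region(parts[0], int(parts[1]), int(parts[2])))
    return sorted(regions)


def write_bed_regions(regions: Iterable[Region], path: str) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def write_results(
    results: Sequence[ScoredRegion],
    path: str,
    config: Optional[SearchConfig] = None,
    manifest_path: Optional[str] = None,
) -> None:
    """Write ranked results as BED6+ plus a JSON manifest.

    BED columns: chrom, start, end, name (target id), score (R clamped to
    the UCSC 0-1000 range), strand '.', then full-precision score and
    correlation as extra columns.  The manifest echoes the config and keeps
    exact scores/correlations.
    """
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tscore_full\tcorrelation\n")
        for r in results:
            clamped = int(min(1000, max(0, round(1000 * r.score))))
            corr = "NA" if np.isnan(r.correlation) else f"{r.correlation:.10g}"
            fh.write(
                f"{r.region.chrom}\t{r.region.start}\t{r.region.end}\t"
                f"{r.target_id}\t{clamped}\t.\t{r.score:.10g}\t{corr}\n"
            )
    manifest = {
        "n_results": len(results),
        "config": config.to_dict() if config is not None else None,
        "results": [
            {
                "chrom": r.region.chrom,
                "start": int(r.region.start),
                "end": int(r.region.end),
                "target_id": r.target_id,
                "score": float(r.score),
                "correlation": None if np.isnan(r.correlation) else float(r.correlation),
            }
            for r in results
        ],
    }
    if manifest_path is None:
        manifest_path = os.fspath(path) + ".json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")
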