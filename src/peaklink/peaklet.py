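"""500bp peaklets from significance-filtered peak calls.

A peaklet is a fixed 500bp window of accessible chromatin anchored on the
mode (summit) of the peak signal; only peaks passing a p-value threshold
(default 1e-10) yield peaklets.  Accessibility is quantified by counting
fragments sharing at least one base with the peaklet window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome_model import GenomicInterval

PEAKLET_WIDTH = 500
DEFAULT_P_THRESHOLD = 1e-10
HALF_WIDTH = PEAKLET_WIDTH // 2


@dataclass
class PeakCall:
    """One called peak: region, p-value, and a summit (offset or signal).

    ``summit_offset`` is the offset of the signal mode from ``region.start``.
    Alternatively ``signal`` gives a per-base non-negative vector over the
    region, whose leftmost argmax defines the mode.
    """

    region: GenomicInterval
    p_value: float
    summit_offset: int | None = None
    signal: Sequence[float] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not self.p_value > 0:
            raise ValueError(f"p_value must be positive, got {self.p_value}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < len(self.region)
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside region of length "
                f"{len(self.region)}"
            )
        if self.signal is not None and len(self.signal) != len(self.region):
            raise ValueError("signal length must equal region length")

    @property
    def mode(self) -> int:
        """Absolute 0-based coordinate of the signal mode (leftmost on ties)."""
        if self.summit_offset is not None:
            return self.region.start + self.summit_offset
        if self.signal is not None:
            return self.region.start + int(np.argmax(self.signal))
        raise ValueError(
            f"peak {self.name or self.region} has neither summit_offset nor signal"
        )


@dataclass(frozen=True)
class Peaklet:
    """A 500bp (boundary-clipped) accessibility window around a peak mode."""

    id: str
    interval: GenomicInterval
    mode: int
    source_p_value: float
    truncated: bool = False

    def __post_init__(self) -> None:
        if not self.interval.contains(self.mode):
            raise ValueError(f"peaklet {self.id}: interval does not contain mode")
        if len(self.interval) != PEAKLET_WIDTH and not self.truncated:
            raise ValueError(
                f"peaklet {self.id}: width {len(self.interval)} without truncated flag"
            )


def derive_peaklets(
    peaks: Iterable[PeakCall],
    contig_lengths: Mapping[str, int],
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> list[Peaklet]:
    """Derive mode-centered 500bp peaklets from peaks with p < ``p_threshold``.

    The window is ``[mode - 250, mode + 250)`` clipped to
    ``[0, contig_length)``; clipped windows carry ``truncated=True``.
    Peaklet ids are ``contig:mode`` (unique because a mode position pins the
    window).  Output is sorted by (contig, mode).
    """
    out: list[Peaklet] = []
    seen: set[str] = set()
    for peak in peaks:
        if not peak.p_value < p_threshold:
            continue
        mode = peak.mode  # raises when neither summit nor signal present
        contig = peak.region.contig
        length = contig_lengths.get(contig)
        if length is None:
            raise KeyError(f"contig {contig!r} absent from contig_lengths")
        start = max(mode - HALF_WIDTH, 0)
        end = min(mode + HALF_WIDTH, length)
        pid = f"{contig}:{mode}"
        if pid in seen:
            continue  # identical mode -> identical window; keep first
        seen.add(pid)
        out.append(
            Peaklet(
                id=pid,
                interval=GenomicInterval(contig, start, end),
                mode=mode,
                source_p_value=peak.p_value,
                truncated=(end - start) != PEAKLET_WIDTH,
            )
        )
    out.sort(key=lambda p: (p.interval.contig, p.mode))
    return out


def count_overlaps(
    peaklets: Sequence[Peaklet], fragments: Iterable[GenomicInterval]
) -> pd.DataFrame:
    """Count fragments sharing >= 1 base with each peaklet (half-open).

    Returns a DataFrame with columns ``peaklet_id`` and ``count``, one row
    per peaklet in input order.
    """
    trees: dict[str, IntervalTree] = {}
    counts = {p.id: 0 for p in peaklets}
    for p in peaklets:
        trees.setdefault(p.interval.contig, IntervalTree()).addi(
            p.interval.start, p.interval.end, p.id
        )
    for frag in fragments:
        tree = trees.get(frag.contig)
        if tree is None:
            continue
        for hit in tree.overlap(frag.start, frag.end):
            counts[hit.data] += 1
    return pd.DataFrame(
        {"peaklet_id": [p.id for p in peaklets], "count": [counts[p.id] for p in peaklets]}
    )


# ---------------------------------------------------------------------------
# file I/O: narrowPeak, BED
# ---------------------------------------------------------------------------


def read_narrowpeak(path: str) -> list[PeakCall]:
    """Read ENCODE narrowPeak (BED6+4).

    Column 8 is -log10(p); column 10 is the summit offset from the region
    start (-1 means no summit, rejected here since a summit or signal is
    required downstream).
    """
    peaks: list[PeakCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise ValueError(
                    f"{path}:{lineno}: narrowPeak needs 10 columns, got {len(parts)}"
                )
            contig, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if parts[5] in "+-" else "."
            neglog_p = float(parts[7])
            summit = int(parts[9])
            if summit < 0:
                raise ValueError(f"{path}:{lineno}: peak {name!r} lacks a summit")
            peaks.append(
                PeakCall(
                    region=GenomicInterval(contig, start, end, strand),
                    p_value=10.0 ** (-neglog_p),
                    summit_offset=summit,
                    name=name,
                )
            )
    return peaks


def read_bed_with_signal(bed_path: str, bedgraph_path: str) -> list[PeakCall]:
    """Read BED6 regions plus a bedGraph sidecar of per-base signal.

    The BED score column (5) is taken as -log10(p).  Signal values default
    to 0 where the bedGraph has no coverage.
    """
    cover: dict[str, list[tuple[int, int, float]]] = {}
    with open(bedgraph_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            c, s, e, v = line.split("\t")[:4]
            cover.setdefault(c, []).append((int(s), int(e), float(v)))
    peaks: list[PeakCall] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{bed_path}:{lineno}: BED6 needs >= 5 columns")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"peak{lineno}"
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            signal = np.zeros(end - start)
            for s, e, v in cover.get(contig, []):
                lo, hi = max(s, start), min(e, end)
                if lo < hi:
                    signal[lo - start : hi - start] = v
            peaks.append(
                PeakCall(
                    region=GenomicInterval(contig, start, end, strand),
                    p_value=10.0 ** (-float(parts[4])),
                    signal=signal,
                    name=name,
                )
            )
    return peaks


def write_peaklets_bed(peaklets: Sequence[Peaklet], path: str) -> None:
    """Write peaklets as BED4 (contig, start, end, id)."""
    with open(path, "w") as fh:
        for p in peaklets:
            fh.write(f"{p.interval.contig}\t{p.interval.start}\t{p.interval.end}\t{p.id}\n")


def read_peaklets_bed(path: str) -> list[Peaklet]:
    """Re-read a BED4 written by :func:`write_peaklets_bed`.

    The mode is recovered from the ``contig:mode`` id; the source p-value is
    not stored in BED and comes back as the derivation threshold.
    """
    peaklets: list[Peaklet] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            contig, start, end, pid = line.split("\t")[:4]
            mode = int(pid.rsplit(":", 1)[1])
            start_i, end_i = int(start), int(end)
            peaklets.append(
                Peaklet(
                    id=pid,
                    interval=GenomicInterval(contig, start_i, end_i),
                    mode=mode,
                    source_p_value=DEFAULT_P_THRESHOLD,
                    truncated=(end_i - start_i) != PEAKLET_WIDTH,
                )
            )
    return peaklets
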