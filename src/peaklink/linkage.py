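"""Peaklet-to-gene linkage: proximal/distal classification and export.

A peaklet is *proximal* to a transcript when its interval contains the TSS
or its mode lies within ±1kb of the TSS, and *distal* when the mode lies
within ±100kb but the pair is not proximal.  Peaklets within 50bp of exonic
sequence that do not cover any TSS may optionally be dropped as *exonic*.
The correspondence is many-to-many: one peaklet may link several
transcripts and one transcript may receive several peaklets.
"""

from __future__ import annotations

import bisect
import csv
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyfaidx import Fasta

from .genome_model import Annotation, GeneModel, GenomicInterval, exon_union
from .peaklet import Peaklet

logger = logging.getLogger("peaklink")

PROXIMAL_BP = 1000
DISTAL_BP = 100_000
EXON_MARGIN_BP = 50


@dataclass(frozen=True)
class CorrespondenceRecord:
    """One (peaklet, transcript) link.

    ``distance`` is mode - TSS adjusted to gene orientation: positive means
    downstream of the TSS on the gene's strand.
    """

    peaklet_id: str
    transcript_id: str
    gene_id: str
    link_class: str  # 'proximal' | 'distal'
    distance: int
    exonic: bool

    def __post_init__(self) -> None:
        if self.link_class not in ("proximal", "distal"):
            raise ValueError(f"invalid link_class {self.link_class!r}")


def classify(
    peaklet: Peaklet,
    model: GeneModel,
    proximal_bp: int = PROXIMAL_BP,
    distal_bp: int = DISTAL_BP,
) -> str:
    """Label a (peaklet, transcript) pair 'proximal', 'distal' or 'none'.

    Proximal: the peaklet interval contains the TSS (half-open membership)
    or |mode - tss| <= proximal_bp.  Distal: |mode - tss| <= distal_bp and
    not proximal.  Pairs on different contigs are 'none'.
    """
    if not 0 < proximal_bp < distal_bp:
        raise ValueError("need 0 < proximal_bp < distal_bp")
    if peaklet.interval.contig != model.span.contig:
        return "none"
    tss = model.tss
    d = abs(peaklet.mode - tss)
    if peaklet.interval.contains(tss) or d <= proximal_bp:
        return "proximal"
    if d <= distal_bp:
        return "distal"
    return "none"


def signed_distance(peaklet: Peaklet, model: GeneModel) -> int:
    """mode - TSS, sign-flipped on '-' strand so positive = downstream."""
    d = peaklet.mode - model.tss
    return -d if model.strand == "-" else d


def flag_exonic(
    peaklet: Peaklet,
    exons: Sequence[GenomicInterval],
    tss_positions: Iterable[int],
    margin_bp: int = EXON_MARGIN_BP,
) -> bool:
    """True iff the peaklet is within ``margin_bp`` of an exon (overlap =
    gap 0) on its contig and contains no TSS.

    ``exons`` is the genome-wide merged exon union; ``tss_positions`` are
    all TSS coordinates on the peaklet's contig.
    """
    iv = peaklet.interval
    for t in tss_positions:
        if iv.contains(t):
            return False
    for ex in exons:
        if ex.contig != iv.contig:
            continue
        if iv.gap_to(ex) <= margin_bp:
            return True
    return False


def build_correspondence(
    peaklets: Sequence[Peaklet],
    annotation: Annotation,
    remove_exonic: bool = False,
    gene_subset: set[str] | None = None,
    proximal_bp: int = PROXIMAL_BP,
    distal_bp: int = DISTAL_BP,
    exon_margin_bp: int = EXON_MARGIN_BP,
) -> list[CorrespondenceRecord]:
    """All (peaklet, transcript) links with class != 'none'.

    Candidate transcripts are found by a sorted-TSS window query per contig
    (every pair within ``distal_bp`` of the mode, which is a superset of
    proximal hits since any contained TSS is within half a peaklet width of
    the mode).  ``gene_subset`` keeps only records of those gene ids;
    ``remove_exonic`` drops records whose peaklet is exonic-flagged against
    the genome-wide exon union and TSS set.  Output sorted by (contig,
    mode, transcript_id).
    """
    if gene_subset is not None:
        missing = set(gene_subset) - annotation.gene_ids
        if missing:
            warnings.warn(
                f"gene_subset ids absent from annotation: {sorted(missing)}",
                stacklevel=2,
            )

    # sorted TSS index per contig
    by_contig: dict[str, list[tuple[int, str]]] = {}
    for m in annotation.models.values():
        by_contig.setdefault(m.span.contig, []).append((m.tss, m.transcript_id))
    for entries in by_contig.values():
        entries.sort()

    exonic_cache: dict[str, bool] = {}
    if remove_exonic:
        exons = exon_union(annotation)
        tss_by_contig = {c: [t for t, _ in entries] for c, entries in by_contig.items()}
        for p in peaklets:
            exonic_cache[p.id] = flag_exonic(
                p, exons, tss_by_contig.get(p.interval.contig, []), exon_margin_bp
            )

    records: list[CorrespondenceRecord] = []
    for p in peaklets:
        if remove_exonic and exonic_cache[p.id]:
            continue
        entries = by_contig.get(p.interval.contig, [])
        if not entries:
            continue
        positions = [t for t, _ in entries]
        lo = bisect.bisect_left(positions, p.mode - distal_bp)
        hi = bisect.bisect_right(positions, p.mode + distal_bp)
        for tss, tx_id in entries[lo:hi]:
            model = annotation.models[tx_id]
            label = classify(p, model, proximal_bp, distal_bp)
            if label == "none":
                continue
            if gene_subset is not None and model.gene_id not in gene_subset:
                continue
            records.append(
                CorrespondenceRecord(
                    peaklet_id=p.id,
                    transcript_id=tx_id,
                    gene_id=model.gene_id,
                    link_class=label,
                    distance=signed_distance(p, model),
                    exonic=exonic_cache.get(p.id, False),
                )
            )

    mode_of = {p.id: (p.interval.contig, p.mode) for p in peaklets}
    records.sort(key=lambda r: (*mode_of[r.peaklet_id], r.transcript_id))
    return records


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "peaklet_id",
    "contig",
    "start",
    "end",
    "mode",
    "transcript_id",
    "gene_id",
    "link_class",
    "distance",
    "exonic",
]


def records_to_frame(
    records: Sequence[CorrespondenceRecord], peaklets: Sequence[Peaklet]
) -> pd.DataFrame:
    """Flatten records (joined to peaklet coordinates) into a DataFrame."""
    by_id = {p.id: p for p in peaklets}
    rows = []
    for r in records:
        p = by_id[r.peaklet_id]
        rows.append(
            {
                "peaklet_id": r.peaklet_id,
                "contig": p.interval.contig,
                "start": p.interval.start,
                "end": p.interval.end,
                "mode": p.mode,
                "transcript_id": r.transcript_id,
                "gene_id": r.gene_id,
                "link_class": r.link_class,
                "distance": r.distance,
                "exonic": r.exonic,
            }
        )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def export_records(
    records: Sequence[CorrespondenceRecord],
    peaklets: Sequence[Peaklet],
    genome_fasta: str,
    out_prefix: str,
) -> dict[str, str]:
    """Write the correspondence as CSV, BED and FASTA.

    CSV: one row per record.  BED4/FASTA: one entry per distinct peaklet
    (deduplicated across records); FASTA sequences are forward-strand
    genome slices named by peaklet id.  Returns the paths written.
    """
    paths = {
        "csv": f"{out_prefix}.csv",
        "bed": f"{out_prefix}.bed",
        "fasta": f"{out_prefix}.fa",
    }
    df = records_to_frame(records, peaklets)
    df.to_csv(paths["csv"], index=False)

    by_id = {p.id: p for p in peaklets}
    linked_ids = sorted(
        {r.peaklet_id for r in records},
        key=lambda pid: (by_id[pid].interval.contig, by_id[pid].mode),
    )
    genome = Fasta(genome_fasta)
    missing = {by_id[pid].interval.contig for pid in linked_ids} - set(genome.keys())
    if missing:
        raise KeyError(f"contigs absent from genome FASTA: {sorted(missing)}")

    with open(paths["bed"], "w") as bed, open(paths["fasta"], "w") as fa:
        for pid in linked_ids:
            iv = by_id[pid].interval
            bed.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{pid}\n")
            seq = genome[iv.contig][iv.start : iv.end].seq
            fa.write(f">{pid}\n{seq}\n")
    return paths


def read_records_csv(path: str) -> tuple[list[CorrespondenceRecord], pd.DataFrame]:
    """Re-parse a correspondence CSV into records (plus the raw frame)."""
    df = pd.read_csv(path)
    if len(df) == 0:
        return [], df
    records = [
        CorrespondenceRecord(
            peaklet_id=row.peaklet_id,
            transcript_id=row.transcript_id,
            gene_id=row.gene_id,
            link_class=row.link_class,
            distance=int(row.distance),
            exonic=bool(row.exonic),
        )
        for row in df.itertuples()
    ]
    return records, df
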