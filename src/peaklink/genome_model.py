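"""Strand-aware gene models from GTF/GFF3 annotation.

All coordinates inside the package are 0-based half-open ``[start, end)``;
GTF/GFF3 files are 1-based closed and are converted at the file boundary
only.  The transcription start site (TSS) is per transcript and strand
aware: the 5' end of the transcript span.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

logger = logging.getLogger("peaklink")

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic range: 0-based half-open ``[start, end)`` on ``contig``.

    ``strand`` is '+', '-' or '.' (unstranded).
    """

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """Half-open membership: ``start <= pos < end``."""
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Bases separating two intervals on the same contig; 0 if they touch
        or overlap."""
        if self.contig != other.contig:
            raise ValueError("gap undefined across contigs")
        return max(self.start - other.end, other.start - self.end, 0)


@dataclass
class GeneModel:
    """One transcript of one gene, with merged exons and a strand-aware TSS."""

    gene_id: str
    transcript_id: str
    span: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = merge_intervals(self.exons)
        for ex in self.exons:
            if ex.contig != self.span.contig or ex.start < self.span.start or ex.end > self.span.end:
                raise ValueError(
                    f"exon {ex} outside span of transcript {self.transcript_id}"
                )

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def tss(self) -> int:
        """0-based TSS position: span.start on '+', span.end - 1 on '-'."""
        if self.span.strand == "-":
            return self.span.end - 1
        return self.span.start


@dataclass
class Annotation:
    """A set of gene models keyed by transcript id, plus contig lengths."""

    models: dict[str, GeneModel]
    contig_lengths: dict[str, int]

    def __post_init__(self) -> None:
        for m in self.models.values():
            length = self.contig_lengths.get(m.span.contig)
            if length is not None and m.span.end > length:
                raise ValueError(
                    f"transcript {m.transcript_id} extends past contig "
                    f"{m.span.contig} length {length}"
                )

    def __len__(self) -> int:
        return len(self.models)

    @property
    def gene_ids(self) -> set[str]:
        return {m.gene_id for m in self.models.values()}

    def transcripts_of(self, gene_id: str) -> list[GeneModel]:
        return [m for m in self.models.values() if m.gene_id == gene_id]


# ---------------------------------------------------------------------------
# interval utilities
# ---------------------------------------------------------------------------


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or abutting intervals into a disjoint sorted list.

    Intervals on different contigs never merge.  Strand is dropped (merged
    intervals are unstranded).
    """
    by_key = sorted(intervals, key=lambda iv: (iv.contig, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in by_key:
        if merged and merged[-1].contig == iv.contig and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.contig, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.contig, iv.start, iv.end))
    return merged


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_TRANSCRIPT_FEATURES = {"transcript", "mRNA"}


def _read_contig_lengths(path: str) -> dict[str, int]:
    """Read contig lengths from a .fai or two-column chrom.sizes file."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            lengths[parts[0]] = int(parts[1])
    return lengths


def parse_annotation(
    path: str,
    dialect: str | None = None,
    contig_lengths: Mapping[str, int] | str | None = None,
) -> Annotation:
    """Parse a GTF or GFF3 file into an :class:`Annotation`.

    Parameters
    ----------
    path:
        Annotation file.  1-based closed coordinates in the file become
        0-based half-open internally.
    dialect:
        ``"GTF"`` or ``"GFF3"``; inferred from the extension when omitted
        (``.gff``/``.gff3`` -> GFF3, otherwise GTF).
    contig_lengths:
        Mapping of contig name to length, or path to a ``.fai`` /
        ``chrom.sizes`` file.  When absent, lengths are inferred as the
        maximum feature end per contig.

    Only ``transcript``/``mRNA`` and ``exon`` features are consumed; exons
    are merged per transcript.  A transcript without exons yields a
    span-only model with a warning.
    """
    if dialect is None:
        ext = os.path.splitext(path)[1].lower()
        dialect = "GFF3" if ext in (".gff", ".gff3") else "GTF"
    dialect = dialect.upper()
    if dialect not in ("GTF", "GFF3"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")

    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils wraps line-level failures
        raise ValueError(f"failed to parse annotation {path!r}: {exc}") from exc

    models: dict[str, GeneModel] = {}
    exons_by_tx: dict[str, list[GenomicInterval]] = {}
    tx_meta: dict[str, tuple[str, GenomicInterval]] = {}

    for feat in db.all_features():
        if feat.featuretype in _TRANSCRIPT_FEATURES:
            tx_id = _feature_id(feat, dialect, transcript=True)
            gene_id = _gene_id_of(feat, db, dialect)
            iv = GenomicInterval(
                feat.seqid, feat.start - 1, feat.end, feat.strand if feat.strand in "+-" else "."
            )
            if tx_id in tx_meta:
                raise ValueError(f"duplicate transcript id {tx_id!r} in {path}")
            tx_meta[tx_id] = (gene_id, iv)
        elif feat.featuretype == "exon":
            tx_id = _feature_id(feat, dialect, transcript=False)
            iv = GenomicInterval(
                feat.seqid, feat.start - 1, feat.end, feat.strand if feat.strand in "+-" else "."
            )
            exons_by_tx.setdefault(tx_id, []).append(iv)

    for tx_id, (gene_id, span) in tx_meta.items():
        exons = exons_by_tx.get(tx_id, [])
        if not exons:
            warnings.warn(
                f"transcript {tx_id} has no exons; keeping span-only model",
                stacklevel=2,
            )
        models[tx_id] = GeneModel(gene_id, tx_id, span, exons)

    if isinstance(contig_lengths, str):
        lengths = _read_contig_lengths(contig_lengths)
    elif contig_lengths is not None:
        lengths = dict(contig_lengths)
    else:
        lengths = {}
        for m in models.values():
            lengths[m.span.contig] = max(lengths.get(m.span.contig, 0), m.span.end)

    return Annotation(models=models, contig_lengths=lengths)


def _feature_id(feat, dialect: str, transcript: bool) -> str:
    if dialect == "GTF":
        key = "transcript_id"
        if key in feat.attributes:
            return feat.attributes[key][0]
    else:
        key = "ID" if transcript else "Parent"
        if key in feat.attributes:
            return feat.attributes[key][0]
        if "transcript_id" in feat.attributes:
            return feat.attributes["transcript_id"][0]
    raise ValueError(
        f"feature at {feat.seqid}:{feat.start}-{feat.end} lacks a transcript identifier"
    )


def _gene_id_of(feat, db, dialect: str) -> str:
    if "gene_id" in feat.attributes:
        return feat.attributes["gene_id"][0]
    if dialect == "GFF3" and "Parent" in feat.attributes:
        return feat.attributes["Parent"][0]
    raise ValueError(
        f"transcript at {feat.seqid}:{feat.start}-{feat.end} lacks a gene identifier"
    )


# ---------------------------------------------------------------------------
# derived views
# ---------------------------------------------------------------------------


def exon_union(annotation: Annotation) -> list[GenomicInterval]:
    """Genome-wide union of all exons across all transcripts, as disjoint
    sorted intervals (per contig, contigs in lexicographic order)."""
    all_exons: list[GenomicInterval] = []
    for m in annotation.models.values():
        all_exons.extend(m.exons)
    return merge_intervals(all_exons)


def tss_table(annotation: Annotation) -> pd.DataFrame:
    """One row per transcript: transcript_id, gene_id, contig, tss, strand.

    Deterministic order: (contig, tss, transcript_id).
    """
    rows = [
        {
            "transcript_id": m.transcript_id,
            "gene_id": m.gene_id,
            "contig": m.span.contig,
            "tss": m.tss,
            "strand": m.strand,
        }
        for m in annotation.models.values()
    ]
    df = pd.DataFrame(rows, columns=["transcript_id", "gene_id", "contig", "tss", "strand"])
    if len(df):
        df = df.sort_values(["contig", "tss", "transcript_id"]).reset_index(drop=True)
    return df


def write_gtf(annotation: Annotation, path: str) -> None:
    """Write models back to Ensembl-dialect GTF (transcript + exon lines).

    Internal 0-based half-open coordinates become 1-based closed.
    """
    def attr(m: GeneModel) -> str:
        return f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'

    with open(path, "w") as fh:
        for tx_id in sorted(annotation.models):
            m = annotation.models[tx_id]
            strand = m.strand if m.strand in "+-" else "."
            fh.write(
                f"{m.span.contig}\tpeaklink\ttranscript\t{m.span.start + 1}\t"
                f"{m.span.end}\t.\t{strand}\t.\t{attr(m)}\n"
            )
            for ex in m.exons:
                fh.write(
                    f"{ex.contig}\tpeaklink\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{strand}\t.\t{attr(m)}\n"
                )
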