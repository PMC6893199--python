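"""Cross-species gene-set projection and multi-set overlap accounting.

User gene lists from a supported organism are projected into the reference
(zebrafish) transcript space through a static homology table (BioMart-style
export), optionally narrowed to transcripts differentially expressed after
injury, and compared across species via Venn-partition counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

FDR_THRESHOLD = 0.05
ANY_TIMEPOINT = "ANY"

_TOKEN_SPLIT = re.compile(r"[\s,;]+")


@dataclass(frozen=True)
class HomologyRecord:
    """One homology link: source gene -> reference gene/transcript."""

    source_species: str
    source_gene_id: str
    target_gene_id: str
    target_transcript_id: str

    def __post_init__(self) -> None:
        for f in (self.source_species, self.source_gene_id, self.target_gene_id, self.target_transcript_id):
            if not f:
                raise ValueError("homology record fields must be non-empty")


def load_homology(path: str) -> list[HomologyRecord]:
    """Read a homology TSV: source_species, source_gene_id, target_gene_id,
    target_transcript_id (header optional, detected by column names)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["source_species", "source_gene_id", "target_gene_id", "target_transcript_id"]
    if list(df.columns[:4]) != expected:
        df = pd.read_csv(path, sep="\t", dtype=str, header=None, names=expected)
    records = [
        HomologyRecord(r.source_species, r.source_gene_id, r.target_gene_id, r.target_transcript_id)
        for r in df.itertuples()
    ]
    seen: set[tuple[str, str]] = set()
    deduped = []
    for r in records:
        key = (r.source_gene_id, r.target_transcript_id)
        if key not in seen:
            seen.add(key)
            deduped.append(r)
    return deduped


def tokenize_ids(text: str) -> list[str]:
    """Split a pasted id list on whitespace/comma/semicolon/newline,
    preserving case and first-seen order, deduplicated."""
    seen: set[str] = set()
    out: list[str] = []
    for tok in _TOKEN_SPLIT.split(text):
        if tok and tok not in seen:
            seen.add(tok)
            out.append(tok)
    return out


def map_genes(
    ids: Sequence[str],
    homology: Sequence[HomologyRecord],
    species: str,
) -> tuple[list[HomologyRecord], list[str]]:
    """Project source gene ids into the reference transcript space.

    Many-to-many: every matching homology record for an input id is
    returned.  Duplicated input ids count once; ids without a match come
    back verbatim in the unmapped list.  Unknown species is an error
    listing those available.
    """
    available = sorted({r.source_species for r in homology})
    if species not in available:
        raise KeyError(f"species {species!r} not in homology table; available: {available}")
    by_gene: dict[str, list[HomologyRecord]] = {}
    for r in homology:
        if r.source_species == species:
            by_gene.setdefault(r.source_gene_id, []).append(r)
    mapped: list[HomologyRecord] = []
    unmapped: list[str] = []
    seen: set[str] = set()
    for gid in ids:
        if gid in seen:
            continue
        seen.add(gid)
        hits = by_gene.get(gid)
        if hits:
            mapped.extend(hits)
        else:
            unmapped.append(gid)
    return mapped, unmapped


# ---------------------------------------------------------------------------
# DE subsetting
# ---------------------------------------------------------------------------


def load_de_table(path: str) -> pd.DataFrame:
    """Read a DE table TSV: transcript_id, timepoint, log_fc, fdr."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "timepoint": str})
    required = {"transcript_id", "timepoint", "log_fc", "fdr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    bad = df[(df["fdr"] < 0) | (df["fdr"] > 1)]
    if len(bad):
        raise ValueError("fdr values outside [0, 1]")
    return df


def subset_de(
    transcripts: set[str],
    de: pd.DataFrame,
    fdr_threshold: float = FDR_THRESHOLD,
    timepoint: str = ANY_TIMEPOINT,
) -> set[str]:
    """Keep transcripts with fdr strictly below the threshold at the named
    time point, or at >= 1 time point when ``timepoint == "ANY"``."""
    labels = set(de["timepoint"].unique())
    if timepoint != ANY_TIMEPOINT:
        if timepoint not in labels:
            raise KeyError(
                f"unknown timepoint {timepoint!r}; available: {sorted(labels)}"
            )
        de = de[de["timepoint"] == timepoint]
    hits = set(de.loc[de["fdr"] < fdr_threshold, "transcript_id"])
    return transcripts & hits


# ---------------------------------------------------------------------------
# Venn partition
# ---------------------------------------------------------------------------


def overlap_partition(named_sets: Mapping[str, set[str]]) -> dict[frozenset[str], int]:
    """Counts for every non-empty membership pattern of 2-4 named sets.

    Keys are frozensets of set names (the exact membership pattern: an
    element counts toward the pattern of precisely the sets containing
    it); values sum to the size of the union.
    """
    names = list(named_sets)
    if not 2 <= len(names) <= 4:
        raise ValueError(f"overlap_partition supports 2-4 sets, got {len(names)}")
    counts: dict[frozenset[str], int] = {}
    for m in range(1, len(names) + 1):
        for combo in combinations(names, m):
            counts[frozenset(combo)] = 0
    union = set().union(*named_sets.values())
    for el in union:
        pattern = frozenset(n for n in names if el in named_sets[n])
        counts[pattern] += 1
    return counts


def partition_table(counts: Mapping[frozenset[str], int]) -> pd.DataFrame:
    """Venn counts as a readable table sorted by pattern size then name."""
    rows = [
        {"region": " & ".join(sorted(k)), "n_sets": len(k), "count": v}
        for k, v in counts.items()
    ]
    return (
        pd.DataFrame(rows, columns=["region", "n_sets", "count"])
        .sort_values(["n_sets", "region"])
        .reset_index(drop=True)
    )
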