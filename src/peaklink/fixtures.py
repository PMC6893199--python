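"""Deterministic synthetic data bundles with known ground truth.

The generator writes a coherent toy dataset — genome FASTA, GTF annotation,
narrowPeak calls, fragment BED, TPM and differential-expression tables, a
small GO ontology with gene annotations, and a homology table — in which
every peak's intended relationship to a gene (proximal / distal /
background, and whether its peaklet is exonic) is known by construction.

Gene placement uses one 210kb slot per gene with the TSS at the slot
center, so the ±100kb distal window of one gene can never reach another
gene's peaks: intended labels are unambiguous.  Summits keep a guard band
around the 1kb and 100kb classification boundaries (proximal |d| <= 600bp,
distal 2.5-98kb, background 102-104kb).  Every file type draws from its own
RNG stream derived from the master seed, so adding one file type never
perturbs another.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_model import Annotation, GeneModel, GenomicInterval
from .linkage import CorrespondenceRecord, flag_exonic
from .genome_model import exon_union
from .peaklet import HALF_WIDTH, Peaklet

GENE_SLOT = 210_000  # one gene per slot; TSS at the slot center
GENE_SPAN = 5_000
TIMEPOINT_LABELS = ("0dpi", "2dpi", "4dpi", "7dpi", "12dpi")

# log2(TPM) templates over the injury time course: ramp up, ramp down,
# transient mid-course peak.  Amplitude 5 on the log2 scale.
CLUSTER_TEMPLATES = (
    (6.0, 7.5, 9.0, 10.0, 11.0),
    (11.0, 10.0, 9.0, 7.5, 6.0),
    (6.0, 10.5, 11.0, 7.5, 6.0),
)


@dataclass
class FixtureSpec:
    """Parameters of one synthetic bundle."""

    seed: int = 0
    n_contigs: int = 6
    contig_length: int = 450_000
    n_genes: int = 12
    n_peaks: int = 40
    fraction_proximal: float = 0.4
    fraction_distal: float = 0.4
    fraction_background: float = 0.2
    fraction_filtered: float = 0.0  # peaks above the p threshold
    n_timepoints: int = 5
    de_fraction: float = 0.3
    n_clusters: int = 3
    noise_sd: float = 0.5
    n_fragments: int = 300

    def __post_init__(self) -> None:
        fr = (
            self.fraction_proximal
            + self.fraction_distal
            + self.fraction_background
            + self.fraction_filtered
        )
        if not abs(fr - 1.0) < 1e-9:
            raise ValueError(f"label fractions must sum to 1, got {fr}")
        for name in ("n_contigs", "contig_length", "n_genes", "n_peaks", "n_timepoints", "n_clusters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")
        slots = self.n_contigs * (self.contig_length // GENE_SLOT)
        if self.n_genes > slots:
            raise ValueError(
                f"{self.n_genes} genes need more than the {slots} available "
                f"{GENE_SLOT}bp slots; raise n_contigs or contig_length"
            )
        if not 1 <= self.n_timepoints <= len(TIMEPOINT_LABELS):
            raise ValueError(f"n_timepoints must be in [1, {len(TIMEPOINT_LABELS)}]")
        if self.n_clusters > len(CLUSTER_TEMPLATES):
            raise ValueError(f"at most {len(CLUSTER_TEMPLATES)} planted clusters")


@dataclass
class GroundTruth:
    """Intended labels, consistent with the emitted files by construction."""

    # peaklet_id -> (intended label, partner transcript or "", partner gene
    # or "", exonic flag); 'filtered' marks peaks above the p threshold
    peaks: pd.DataFrame
    de_status: dict[str, bool]
    cluster_of: dict[str, int]
    annotation: Annotation = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def _build_annotation(spec: FixtureSpec, rng: np.random.Generator) -> Annotation:
    """One transcript per gene, one gene per slot, alternating strand."""
    models: dict[str, GeneModel] = {}
    slots_per_contig = spec.contig_length // GENE_SLOT
    for g in range(spec.n_genes):
        contig = f"chr{g // slots_per_contig + 1}"
        slot_start = (g % slots_per_contig) * GENE_SLOT
        tss = slot_start + GENE_SLOT // 2
        strand = "+" if g % 2 == 0 else "-"
        if strand == "+":
            span = GenomicInterval(contig, tss, tss + GENE_SPAN, "+")
        else:
            span = GenomicInterval(contig, tss - GENE_SPAN + 1, tss + 1, "-")
        n_exons = int(rng.integers(2, 5))
        # alternate exon/intron blocks across the span, 5' exon first
        edges = np.linspace(0, GENE_SPAN, 2 * n_exons).astype(int)
        exons = [
            GenomicInterval(contig, span.start + int(edges[2 * i]), span.start + int(edges[2 * i + 1]))
            for i in range(n_exons)
        ]
        gid, tid = f"g{g + 1}", f"t{g + 1}"
        models[tid] = GeneModel(gid, tid, span, exons)
    contig_lengths = {f"chr{c + 1}": spec.contig_length for c in range(spec.n_contigs)}
    return Annotation(models=models, contig_lengths=contig_lengths)


def _plan_peaks(
    spec: FixtureSpec, annotation: Annotation, rng: np.random.Generator
) -> pd.DataFrame:
    """Choose summit positions realizing the intended labels."""
    counts = {
        "proximal": int(round(spec.fraction_proximal * spec.n_peaks)),
        "distal": int(round(spec.fraction_distal * spec.n_peaks)),
        "filtered": int(round(spec.fraction_filtered * spec.n_peaks)),
    }
    counts["none"] = spec.n_peaks - sum(counts.values())
    labels = (
        ["proximal"] * counts["proximal"]
        + ["distal"] * counts["distal"]
        + ["none"] * counts["none"]
        + ["filtered"] * counts["filtered"]
    )
    rng.shuffle(labels)

    tx_ids = sorted(annotation.models, key=lambda t: int(t[1:]))
    exons = exon_union(annotation)
    tss_by_contig: dict[str, list[int]] = {}
    for m in annotation.models.values():
        tss_by_contig.setdefault(m.span.contig, []).append(m.tss)

    rows = []
    used: set[tuple[str, int]] = set()
    for i, label in enumerate(labels):
        model = annotation.models[tx_ids[i % len(tx_ids)]]
        contig, tss = model.span.contig, model.tss
        for _ in range(100):
            if label == "proximal":
                d = int(rng.integers(-600, 601))
            elif label in ("distal", "filtered"):
                d = int(rng.integers(2_500, 98_001)) * (1 if rng.random() < 0.5 else -1)
            else:  # background: beyond the distal window of every gene
                d = int(rng.integers(102_000, 104_001)) * (1 if rng.random() < 0.5 else -1)
            summit = tss + d
            if (contig, summit) not in used:
                used.add((contig, summit))
                break
        else:
            raise RuntimeError("could not place a unique summit")
        significant = label != "filtered"
        neglog_p = float(rng.uniform(11, 15)) if significant else float(rng.uniform(5, 9))
        length = annotation.contig_lengths[contig]
        pk_start = max(summit - HALF_WIDTH, 0)
        pk_end = min(summit + HALF_WIDTH, length)
        peaklet = Peaklet(
            id=f"{contig}:{summit}",
            interval=GenomicInterval(contig, pk_start, pk_end),
            mode=summit,
            source_p_value=10.0 ** -neglog_p,
            truncated=(pk_end - pk_start) != 2 * HALF_WIDTH,
        )
        exonic = flag_exonic(peaklet, exons, tss_by_contig[contig])
        partner = "" if label in ("none", "filtered") else model.transcript_id
        rows.append(
            {
                "peak_name": f"peak{i + 1}",
                "peaklet_id": peaklet.id,
                "contig": contig,
                "summit": summit,
                "neglog_p": neglog_p,
                "intended_label": label,
                "partner_transcript": partner,
                "partner_gene": model.gene_id if partner else "",
                "exonic": exonic,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(["contig", "summit"]).reset_index(drop=True)


def _write_genome(spec: FixtureSpec, rng: np.random.Generator, path: str) -> None:
    bases = np.frombuffer(b"ACGT", dtype="S1")
    with open(path, "w") as fh:
        for c in range(spec.n_contigs):
            fh.write(f">chr{c + 1}\n")
            seq = bases[rng.integers(0, 4, size=spec.contig_length)].tobytes().decode()
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def _write_obo(path: str) -> None:
    """A fixed 8-term BP ontology containing a diamond (two is_a paths from
    the 'sterol biosynthesis' leaf to 'metabolic process')."""
    stanzas = [
        ("GO:0008150", "biological_process", []),
        ("GO:0008152", "metabolic process", ["GO:0008150"]),
        ("GO:0006629", "lipid metabolic process", ["GO:0008152"]),
        ("GO:0044249", "cellular biosynthetic process", ["GO:0008152"]),
        ("GO:0016126", "sterol biosynthetic process", ["GO:0006629", "GO:0044249"]),
        ("GO:0030154", "cell differentiation", ["GO:0008150"]),
        ("GO:0031103", "axon regeneration", ["GO:0030154"]),
        ("GO:0007399", "nervous system development", ["GO:0008150"]),
    ]
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: go-toy\n")
        for tid, name, parents in stanzas:
            fh.write(f"\n[Term]\nid: {tid}\nname: {name}\nnamespace: biological_process\n")
            for p in parents:
                fh.write(f"is_a: {p}\n")


def generate(spec: FixtureSpec, out_dir: str) -> tuple[dict[str, str], GroundTruth]:
    """Write the bundle into ``out_dir`` and return (paths, ground truth).

    Identical spec (including seed) -> byte-identical files.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        name: os.path.join(out_dir, fname)
        for name, fname in [
            ("genome", "genome.fa"),
            ("chrom_sizes", "genome.chrom.sizes"),
            ("annotation", "genes.gtf"),
            ("peaks", "peaks.narrowPeak"),
            ("fragments", "fragments.bed"),
            ("tpm", "tpm.tsv"),
            ("de", "de.tsv"),
            ("obo", "go.obo"),
            ("gene2go", "gene2go.tsv"),
            ("homology", "homology.tsv"),
        ]
    }

    annotation = _build_annotation(spec, _rng(spec, 1))
    from .genome_model import write_gtf

    write_gtf(annotation, paths["annotation"])
    with open(paths["chrom_sizes"], "w") as fh:
        for c in range(spec.n_contigs):
            fh.write(f"chr{c + 1}\t{spec.contig_length}\n")

    _write_genome(spec, _rng(spec, 0), paths["genome"])

    peaks = _plan_peaks(spec, annotation, _rng(spec, 2))
    with open(paths["peaks"], "w") as fh:
        for r in peaks.itertuples():
            start, end = r.summit - 500, r.summit + 500
            fh.write(
                f"{r.contig}\t{start}\t{end}\t{r.peak_name}\t0\t.\t"
                f"0.0\t{r.neglog_p:.4f}\t-1\t{r.summit - start}\n"
            )

    # fragments: uniform placement, lengths 50-150bp
    frag_rng = _rng(spec, 3)
    with open(paths["fragments"], "w") as fh:
        for i in range(spec.n_fragments):
            contig = f"chr{int(frag_rng.integers(1, spec.n_contigs + 1))}"
            length = int(frag_rng.integers(50, 151))
            start = int(frag_rng.integers(0, spec.contig_length - length))
            fh.write(f"{contig}\t{start}\t{start + length}\tfrag{i + 1}\n")

    # expression with planted cluster profiles
    expr_rng = _rng(spec, 4)
    tx_ids = sorted(annotation.models, key=lambda t: int(t[1:]))
    labels = list(TIMEPOINT_LABELS[: spec.n_timepoints])
    cluster_of = {tid: (i % spec.n_clusters) + 1 for i, tid in enumerate(tx_ids)}
    tpm_rows = {}
    for tid in tx_ids:
        template = np.array(CLUSTER_TEMPLATES[cluster_of[tid] - 1][: spec.n_timepoints])
        log_tpm = template + expr_rng.normal(0, spec.noise_sd, size=len(labels))
        tpm_rows[tid] = np.power(2.0, log_tpm) - 1.0
    tpm = pd.DataFrame.from_dict(tpm_rows, orient="index", columns=labels)
    tpm.index.name = "transcript_id"
    tpm.round(4).to_csv(paths["tpm"], sep="\t")

    # DE table: planted FDRs per (transcript, post-injury timepoint)
    de_rng = _rng(spec, 5)
    n_de = int(round(spec.de_fraction * len(tx_ids)))
    de_set = set(tx_ids[:n_de])
    de_rows = []
    for tid in tx_ids:
        for lab in labels[1:]:
            if tid in de_set:
                fdr = float(de_rng.uniform(1e-4, 0.01))
            else:
                fdr = float(de_rng.uniform(0.2, 0.9))
            lfc = float(de_rng.normal(0, 2))
            de_rows.append((tid, lab, round(lfc, 4), round(fdr, 6)))
    pd.DataFrame(de_rows, columns=["transcript_id", "timepoint", "log_fc", "fdr"]).to_csv(
        paths["de"], sep="\t", index=False
    )

    _write_obo(paths["obo"])
    # annotate DE genes to the sterol-biosynthesis leaf, others elsewhere
    with open(paths["gene2go"], "w") as fh:
        for tid in tx_ids:
            gid = annotation.models[tid].gene_id
            term = "GO:0016126" if tid in de_set else ("GO:0031103" if int(tid[1:]) % 2 else "GO:0007399")
            fh.write(f"{gid}\t{term}\n")

    # homology: one mouse homolog per gene, plus one one-to-many case
    with open(paths["homology"], "w") as fh:
        fh.write("source_species\tsource_gene_id\ttarget_gene_id\ttarget_transcript_id\n")
        for i, tid in enumerate(tx_ids):
            gid = annotation.models[tid].gene_id
            fh.write(f"mus_musculus\tMmG{i + 1}\t{gid}\t{tid}\n")
            if i < len(tx_ids) // 2:
                fh.write(f"homo_sapiens\tHsG{i + 1}\t{gid}\t{tid}\n")
        if len(tx_ids) >= 2:
            fh.write(f"mus_musculus\tMmG_multi\tg1\tt1\n")
            fh.write(f"mus_musculus\tMmG_multi\tg2\tt2\n")

    truth = GroundTruth(
        peaks=peaks[
            ["peaklet_id", "intended_label", "partner_transcript", "partner_gene", "exonic"]
        ].copy(),
        de_status={tid: tid in de_set for tid in tx_ids},
        cluster_of=cluster_of,
        annotation=annotation,
    )
    return paths, truth


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

LABELS = ("proximal", "distal", "none")


def truth_report(
    truth: GroundTruth, records: list[CorrespondenceRecord]
) -> pd.DataFrame:
    """Confusion table of intended vs observed linkage labels.

    For each ground-truth peaklet with an intended partner, the observed
    label is the class of the (peaklet, partner) record, or 'none' when no
    such record exists.  Background peaklets observe 'none' only when no
    record links them to anything.  Peaks above the p threshold
    ('filtered') are excluded: no peaklet should exist for them.
    """
    by_pair: dict[tuple[str, str], str] = {}
    by_peaklet: dict[str, list[str]] = {}
    for r in records:
        by_pair[(r.peaklet_id, r.transcript_id)] = r.link_class
        by_peaklet.setdefault(r.peaklet_id, []).append(r.link_class)

    table = pd.DataFrame(0, index=list(LABELS), columns=list(LABELS))
    table.index.name = "intended"
    for row in truth.peaks.itertuples():
        if row.intended_label == "filtered":
            continue
        if row.partner_transcript:
            observed = by_pair.get((row.peaklet_id, row.partner_transcript), "none")
        else:
            classes = by_peaklet.get(row.peaklet_id, [])
            observed = classes[0] if classes else "none"
        table.loc[row.intended_label, observed] += 1
    return table
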