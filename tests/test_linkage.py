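import numpy as np
import pytest

import peaklink as pl
from conftest import make_peaklet

iv = pl.GenomicInterval


def model_at(tss, strand="+", contig="chr1", gene="g", tx="t"):
    if strand == "+":
        span = iv(contig, tss, tss + 2000, "+")
    else:
        span = iv(contig, tss - 1999, tss + 1, "-")
    return pl.GeneModel(gene, tx, span, [span])


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def test_interval_containing_tss_is_proximal():
    pk = pl.Peaklet("chr1:1200", iv("chr1", 950, 1450), 1200, 1e-12)
    assert pl.classify(pk, model_at(1200)) == "proximal"
    # containment holds even when the mode is placed off-center (truncated)
    pk2 = pl.Peaklet("chr1:1400", iv("chr1", 1150, 1450), 1400, 1e-12, truncated=True)
    assert pl.classify(pk2, model_at(1160)) == "proximal"


@pytest.mark.parametrize(
    "distance,expected",
    [
        (0, "proximal"),
        (999, "proximal"),
        (1000, "proximal"),
        (1001, "distal"),
        (50_000, "distal"),
        (99_999, "distal"),
        (100_000, "distal"),
        (100_001, "none"),
        (150_000, "none"),
    ],
)
@pytest.mark.parametrize("sign", [1, -1])
def test_mode_distance_boundaries(distance, expected, sign):
    tss = 500_000
    pk = make_peaklet("chr1", tss + sign * distance)
    assert pl.classify(pk, model_at(tss)) == expected


def test_different_contig_is_none():
    pk = make_peaklet("chr2", 1000)
    assert pl.classify(pk, model_at(1000, contig="chr1")) == "none"


def test_classification_is_a_partition():
    rng = np.random.default_rng(3)
    tss = 500_000
    for d in rng.integers(-120_000, 120_000, size=300):
        pk = make_peaklet("chr1", tss + int(d))
        label = pl.classify(pk, model_at(tss))
        assert label in ("proximal", "distal", "none")
        # recomputing gives the same single label
        assert pl.classify(pk, model_at(tss)) == label


def test_shrinking_proximal_radius_moves_links_to_distal_not_none():
    tss = 500_000
    pk = make_peaklet("chr1", tss + 900)
    assert pl.classify(pk, model_at(tss), proximal_bp=1000) == "proximal"
    assert pl.classify(pk, model_at(tss), proximal_bp=500) == "distal"


def test_signed_distance_is_strand_oriented():
    pk = make_peaklet("chr1", 501_000)
    assert pl.signed_distance(pk, model_at(500_000, "+")) == 1000
    assert pl.signed_distance(pk, model_at(500_000, "-")) == -1000


# ---------------------------------------------------------------------------
# exonic flag
# ---------------------------------------------------------------------------


def test_exonic_within_margin_without_tss():
    pk = make_peaklet("chr1", 10_000)  # interval [9750, 10250)
    exon_30bp_away = [iv("chr1", 10_280, 10_400)]
    assert pl.flag_exonic(pk, exon_30bp_away, tss_positions=[]) is True


def test_exonic_false_when_peaklet_contains_a_tss():
    pk = make_peaklet("chr1", 10_000)
    overlapping_exon = [iv("chr1", 9_900, 10_100)]
    assert pl.flag_exonic(pk, overlapping_exon, tss_positions=[10_050]) is False
    assert pl.flag_exonic(pk, overlapping_exon, tss_positions=[]) is True


def test_exonic_false_beyond_margin():
    pk = make_peaklet("chr1", 10_000)
    exon_60bp_away = [iv("chr1", 10_310, 10_400)]
    assert pl.flag_exonic(pk, exon_60bp_away, tss_positions=[]) is False
    # exactly at the margin counts
    exon_50bp_away = [iv("chr1", 10_300, 10_400)]
    assert pl.flag_exonic(pk, exon_50bp_away, tss_positions=[]) is True


# ---------------------------------------------------------------------------
# correspondence
# ---------------------------------------------------------------------------


def brute_force_records(peaklets, annotation, proximal_bp=1000, distal_bp=100_000):
    """O(P x T) all-pairs oracle reimplementing the rule directly."""
    out = set()
    for p in peaklets:
        for m in annotation.models.values():
            if m.span.contig != p.interval.contig:
                continue
            d = abs(p.mode - m.tss)
            contains = p.interval.start <= m.tss < p.interval.end
            if contains or d <= proximal_bp:
                label = "proximal"
            elif d <= distal_bp:
                label = "distal"
            else:
                continue
            out.add((p.id, m.transcript_id, label))
    return out


def test_one_peaklet_links_two_genes_many_to_many():
    models = {
        "tA": pl.GeneModel("gA", "tA", iv("chr1", 500_000, 502_000, "+"), []),
        "tB": pl.GeneModel("gB", "tB", iv("chr1", 580_000, 582_000, "+"), []),
    }
    ann = pl.Annotation(models=models, contig_lengths={"chr1": 1_000_000})
    pk = make_peaklet("chr1", 540_000)  # 40kb from both TSSs
    records = pl.build_correspondence([pk], ann)
    assert {(r.transcript_id, r.link_class) for r in records} == {
        ("tA", "distal"), ("tB", "distal"),
    }


def test_gene_subset_filters_records_and_warns_on_unknown_ids():
    models = {
        "tA": pl.GeneModel("gA", "tA", iv("chr1", 500_000, 502_000, "+"), []),
        "tB": pl.GeneModel("gB", "tB", iv("chr1", 540_500, 542_000, "+"), []),
    }
    ann = pl.Annotation(models=models, contig_lengths={"chr1": 1_000_000})
    pk = make_peaklet("chr1", 540_000)
    only_a = pl.build_correspondence([pk], ann, gene_subset={"gA"})
    assert {r.gene_id for r in only_a} == {"gA"}
    with pytest.warns(UserWarning, match="gX"):
        pl.build_correspondence([pk], ann, gene_subset={"gA", "gX"})


def random_case(seed, n_peaklets=200, n_transcripts=50):
    rng = np.random.default_rng(seed)
    contigs = ["chr1", "chr2"]
    length = 2_000_000
    models = {}
    for t in range(n_transcripts):
        contig = contigs[int(rng.integers(0, 2))]
        strand = "+" if rng.random() < 0.5 else "-"
        tss = int(rng.integers(5_000, length - 5_000))
        span = (iv(contig, tss, tss + 2000, "+") if strand == "+"
                else iv(contig, tss - 1999, tss + 1, "-"))
        models[f"t{t}"] = pl.GeneModel(f"g{t // 2}", f"t{t}", span, [])
    ann = pl.Annotation(models=models, contig_lengths={c: length for c in contigs})
    modes = rng.choice(np.arange(300, length - 300), size=n_peaklets, replace=False)
    peaklets = [make_peaklet(contigs[i % 2], int(m), length) for i, m in enumerate(modes)]
    return peaklets, ann


@pytest.mark.parametrize("seed", range(8))
def test_correspondence_matches_all_pairs_oracle(seed):
    peaklets, ann = random_case(seed)
    records = pl.build_correspondence(peaklets, ann)
    got = {(r.peaklet_id, r.transcript_id, r.link_class) for r in records}
    assert got == brute_force_records(peaklets, ann)


def test_remove_exonic_output_is_a_subset(bundle):
    _, paths, _ = bundle
    ann = pl.parse_annotation(paths["annotation"], contig_lengths=paths["chrom_sizes"])
    pls = pl.derive_peaklets(pl.read_narrowpeak(paths["peaks"]), ann.contig_lengths)
    keep_all = pl.build_correspondence(pls, ann, remove_exonic=False)
    dropped = pl.build_correspondence(pls, ann, remove_exonic=True)
    as_set = lambda rs: {(r.peaklet_id, r.transcript_id) for r in rs}
    assert as_set(dropped) <= as_set(keep_all)


def test_output_sorted_by_contig_mode_transcript(bundle):
    _, paths, _ = bundle
    ann = pl.parse_annotation(paths["annotation"], contig_lengths=paths["chrom_sizes"])
    pls = pl.derive_peaklets(pl.read_narrowpeak(paths["peaks"]), ann.contig_lengths)
    records = pl.build_correspondence(pls, ann)
    mode_of = {p.id: (p.interval.contig, p.mode) for p in pls}
    keys = [(*mode_of[r.peaklet_id], r.transcript_id) for r in records]
    assert keys == sorted(keys)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def test_export_fasta_bed_csv_integrity(bundle, tmp_path):
    _, paths, _ = bundle
    ann = pl.parse_annotation(paths["annotation"], contig_lengths=paths["chrom_sizes"])
    pls = pl.derive_peaklets(pl.read_narrowpeak(paths["peaks"]), ann.contig_lengths)
    records = pl.build_correspondence(pls, ann)
    out = pl.export_records(records, pls, paths["genome"], str(tmp_path / "linked"))

    bed_rows = [l.split("\t") for l in open(out["bed"]).read().splitlines()]
    widths = {r[3]: int(r[2]) - int(r[1]) for r in bed_rows}
    from Bio import SeqIO

    fasta = {rec.id: str(rec.seq) for rec in SeqIO.parse(out["fasta"], "fasta")}
    assert set(fasta) == set(widths) == {r.peaklet_id for r in records}
    for pid, seq in fasta.items():
        assert len(seq) == widths[pid]
        assert set(seq) <= set("ACGTN")
    # one FASTA/BED entry per distinct peaklet, one CSV row per record
    assert len(bed_rows) == len({r.peaklet_id for r in records})
    reparsed, df = pl.read_records_csv(out["csv"])
    assert set(reparsed) == set(records)


def test_export_empty_records_writes_valid_empty_files(bundle, tmp_path):
    import pandas as pd
    from peaklink.linkage import CSV_COLUMNS

    _, paths, _ = bundle
    out = pl.export_records([], [], paths["genome"], str(tmp_path / "empty"))
    records, _ = pl.read_records_csv(out["csv"])
    assert records == []
    assert list(pd.read_csv(out["csv"]).columns) == CSV_COLUMNS
    assert open(out["bed"]).read() == "" and open(out["fasta"]).read() == ""


def test_export_missing_contig_is_an_error(tmp_path):
    genome = tmp_path / "g.fa"
    genome.write_text(">chrZ\n" + "A" * 1000 + "\n")
    pk = make_peaklet("chr1", 500, contig_length=1000)
    rec = pl.CorrespondenceRecord(pk.id, "t", "g", "proximal", 0, False)
    with pytest.raises(KeyError, match="chr1"):
        pl.export_records([rec], [pk], str(genome), str(tmp_path / "x"))
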