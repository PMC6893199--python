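import pytest

import peaklink as pl


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One default synthetic bundle shared across the session."""
    out = tmp_path_factory.mktemp("bundle")
    spec = pl.FixtureSpec(seed=11)
    paths, truth = pl.generate(spec, str(out))
    return spec, paths, truth


@pytest.fixture()
def toy_annotation():
    """3 transcripts over 2 genes on 2 contigs, built in memory."""
    iv = pl.GenomicInterval
    models = {
        "t1": pl.GeneModel("gA", "t1", iv("chr1", 100, 1100, "+"),
                           [iv("chr1", 100, 300), iv("chr1", 800, 1100)]),
        "t2": pl.GeneModel("gA", "t2", iv("chr1", 100, 900, "+"),
                           [iv("chr1", 100, 250), iv("chr1", 700, 900)]),
        "t3": pl.GeneModel("gB", "t3", iv("chr2", 5000, 9000, "-"),
                           [iv("chr2", 5000, 5600), iv("chr2", 8500, 9000)]),
    }
    return pl.Annotation(models=models, contig_lengths={"chr1": 20000, "chr2": 20000})


def make_peaklet(contig, mode, contig_length=10_000_000):
    """Standard 500bp peaklet around a mode, clipped at the contig edge."""
    start = max(mode - 250, 0)
    end = min(mode + 250, contig_length)
    return pl.Peaklet(
        id=f"{contig}:{mode}",
        interval=pl.GenomicInterval(contig, start, end),
        mode=mode,
        source_p_value=1e-12,
        truncated=(end - start) != 500,
    )
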