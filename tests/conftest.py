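"""Shared fixtures: small synthetic datasets built at session scope."""

from __future__ import annotations

import textwrap

import pytest

from scapa.gene_models import load_gene_models
from scapa.simulate import default_scenario, generate_scenario, write_fixture_files


@pytest.fixture(scope="session")
def scenario():
    """Default two-population scenario with one usage-switching gene."""
    return generate_scenario(default_scenario(seed=1))


@pytest.fixture(scope="session")
def fixture_dir(scenario, tmp_path_factory):
    """On-disk BAM/GTF/FASTA/whitelist files for the default scenario."""
    out = tmp_path_factory.mktemp("fixture")
    paths = write_fixture_files(scenario, out)
    return paths


@pytest.fixture(scope="session")
def gene_models(fixture_dir):
    return load_gene_models(fixture_dir["gtf"])


@pytest.fixture()
def mini_gtf(tmp_path):
    """Two-transcript gene: tx1 with a 3'UTR, tx2 whose intron covers it."""
    text = textwrap.dedent(
        """\
        chr1\ttest\tgene\t1000\t9000\t.\t+\t.\tgene_id "GX";
        chr1\ttest\ttranscript\t1000\t5000\t.\t+\t.\tgene_id "GX"; transcript_id "GX.t1";
        chr1\ttest\texon\t1000\t2000\t.\t+\t.\tgene_id "GX"; transcript_id "GX.t1";
        chr1\ttest\texon\t3000\t5000\t.\t+\t.\tgene_id "GX"; transcript_id "GX.t1";
        chr1\ttest\tCDS\t1000\t2000\t.\t+\t.\tgene_id "GX"; transcript_id "GX.t1";
        chr1\ttest\tCDS\t3000\t3999\t.\t+\t.\tgene_id "GX"; transcript_id "GX.t1";
        chr1\ttest\tthree_prime_utr\t4000\t5000\t.\t+\t.\tgene_id "GX"; transcript_id "GX.t1";
        chr1\ttest\ttranscript\t1000\t9000\t.\t+\t.\tgene_id "GX"; transcript_id "GX.t2";
        chr1\ttest\texon\t1000\t2000\t.\t+\t.\tgene_id "GX"; transcript_id "GX.t2";
        chr1\ttest\texon\t8000\t9000\t.\t+\t.\tgene_id "GX"; transcript_id "GX.t2";
        chr1\ttest\tCDS\t1000\t2000\t.\t+\t.\tgene_id "GX"; transcript_id "GX.t2";
        chr1\ttest\tCDS\t8000\t8500\t.\t+\t.\tgene_id "GX"; transcript_id "GX.t2";
        """
    )
    path = tmp_path / "mini.gtf"
    path.write_text(text)
    return path
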