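import pytest


@pytest.fixture
def toy_gtf_text():
    """Three genes on chr1: one +, one -, and one long gene."""
    return (
        "# toy reference\n"
        'chr1\ttoy\tgene\t1000\t2000\t.\t+\t.\tgene_id "gA"; gene_name "ALPHA"; gene_biotype "protein_coding";\n'
        'chr1\ttoy\tgene\t5000\t6000\t.\t-\t.\tgene_id "gB"; gene_name "BETA"; gene_biotype "lincRNA";\n'
        'chr1\ttoy\tgene\t10000\t40000\t.\t+\t.\tgene_id "gC"; gene_name "GAMMA"; gene_biotype "protein_coding";\n'
        'chr1\ttoy\ttranscript\t1000\t2000\t.\t+\t.\tgene_id "gA"; transcript_id "tA1";\n'
    )


@pytest.fixture
def toy_features(toy_gtf_text):
    from peakanno.io_genomic import read_gtf

    return read_gtf(toy_gtf_text)
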