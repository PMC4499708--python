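import textwrap

import pytest


@pytest.fixture
def write_file(tmp_path):
    def _write(name, content):
        path = tmp_path / name
        path.write_text(textwrap.dedent(content).lstrip())
        return path

    return _write


@pytest.fixture
def toy_gff(write_file):
    """Three plus-strand genes on one chromosome, one with an intron."""
    return write_file(
        "toy.gff3",
        """
        ##gff-version 3
        chr1\tsrc\tgene\t10\t309\t.\t+\t.\tID=gA
        chr1\tsrc\tmRNA\t10\t309\t.\t+\t.\tID=gA.1;Parent=gA
        chr1\tsrc\texon\t10\t309\t.\t+\t.\tParent=gA.1
        chr1\tsrc\tgene\t500\t1001\t.\t+\t.\tID=gB
        chr1\tsrc\tmRNA\t500\t1001\t.\t+\t.\tID=gB.1;Parent=gB
        chr1\tsrc\texon\t500\t599\t.\t+\t.\tParent=gB.1
        chr1\tsrc\texon\t700\t1001\t.\t+\t.\tParent=gB.1
        chr1\tsrc\tgene\t900\t1199\t.\t+\t.\tID=gC
        chr1\tsrc\tmRNA\t900\t1199\t.\t+\t.\tID=gC.1;Parent=gC
        chr1\tsrc\texon\t900\t1199\t.\t+\t.\tParent=gC.1
        """.replace("        ", ""),
    )
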