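import pytest

from orfeval import Annotation, CdsFeature


def F(start, end, strand="+", contig="c", source="x", **attrs):
    """Terse CdsFeature constructor for fixtures."""
    return CdsFeature(contig, start, end, strand, source=source,
                      attributes={k: str(v) for k, v in attrs.items()})


@pytest.fixture
def make_annotation():
    return lambda *features: Annotation(features)


@pytest.fixture
def toy_gff3(tmp_path):
    """3 CDS rows (one duplicate), a gene row and a tRNA row."""
    path = tmp_path / "toy.gff3"
    path.write_text(
        "##gff-version 3\n"
        "# a comment\n"
        "c\tens\tgene\t5\t702\t.\t+\t.\tID=g1\n"
        "c\tens\tCDS\t10\t309\t.\t+\t0\tID=c1\n"
        "c\tens\tCDS\t400\t702\t.\t-\t0\tID=c2\n"
        "c\tens\tCDS\t400\t702\t.\t-\t0\tID=c2dup\n"
        "c\tens\ttRNA\t800\t875\t.\t+\t.\tID=t1\n"
    )
    return path
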