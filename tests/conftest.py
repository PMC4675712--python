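import numpy as np
import pytest
from hypothesis import settings

from anablast import GenomeRegion, ScoringScheme, SearchConfig

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture(scope="session")
def search_config() -> SearchConfig:
    return SearchConfig()


@pytest.fixture()
def toy_region() -> GenomeRegion:
    return GenomeRegion("c1", 100, 112, "ATGGCCTAAGGG")


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))


@pytest.fixture(scope="session")
def gff3_file(tmp_path_factory):
    """Two single-exon genes and one two-exon gene on a 500 bp chromosome."""
    text = "\n".join(
        [
            "##gff-version 3",
            "chr1\ttest\tgene\t101\t200\t.\t+\t.\tID=gA",
            "chr1\ttest\tmRNA\t101\t200\t.\t+\t.\tID=tA;Parent=gA",
            "chr1\ttest\texon\t101\t200\t.\t+\t.\tID=tA.e1;Parent=tA",
            "chr1\ttest\tgene\t301\t400\t.\t-\t.\tID=gB",
            "chr1\ttest\tmRNA\t301\t400\t.\t-\t.\tID=tB;Parent=gB",
            "chr1\ttest\texon\t301\t400\t.\t-\t.\tID=tB.e1;Parent=tB",
            "chr2\ttest\tgene\t101\t200\t.\t+\t.\tID=gC",
            "chr2\ttest\tmRNA\t101\t200\t.\t+\t.\tID=tC;Parent=gC",
            "chr2\ttest\texon\t101\t140\t.\t+\t.\tID=tC.e1;Parent=tC",
            "chr2\ttest\texon\t161\t200\t.\t+\t.\tID=tC.e2;Parent=tC",
            "",
        ]
    )
    path = tmp_path_factory.mktemp("gff") / "annotation.gff3"
    path.write_text(text)
    return path


@pytest.fixture(scope="session")
def toy_genome() -> dict[str, str]:
    rng = np.random.default_rng(7)
    return {"chr1": random_dna(rng, 500), "chr2": random_dna(rng, 500)}
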