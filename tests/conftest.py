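import pytest

from evohotspot import synthetic_data as synth
from evohotspot.genome_io import GeneFeature, ReferenceGenome


@pytest.fixture(scope="session")
def toy_genome():
    """Small seeded genome shared by read-only tests."""
    return synth.make_toy_genome(30_000, 20, seed=1)


@pytest.fixture()
def two_gene_genome():
    """Hand-built genome with one CDS per strand and known codons.

    Layout (length 120, linear for easy reasoning):
      geneA: [30, 60) on '+', coding ATG AAA GAC CTG TGG TTT GGG CCC TAA
      geneB: [80, 110) on '-', same coding sequence reverse-complemented
    """
    coding = "ATG" + "AAA" + "GAC" + "CTG" + "TGG" + "TTT" + "GGG" + "CCC" + "TAA"
    assert len(coding) == 27
    filler = ("ACGT" * 40)[:30]
    seq = (
        filler  # 0-30
        + coding + "AGA"  # 30-57 geneA (27bp) + pad to 60
        + ("TTAACCGGTTAACCGGTTAA")  # 60-80
        + _revcomp(coding) + "CAT"  # 80-107 geneB + pad
        + ("GACTGACTGACT"[: 120 - 110])
    )
    seq = seq[:120].ljust(120, "A")
    features = [
        GeneFeature(locus_tag="geneA", start=30, end=57, strand="+"),
        GeneFeature(locus_tag="geneB", start=80, end=107, strand="-"),
    ]
    return ReferenceGenome(id="mini", sequence=seq, topology="linear", features=features)


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@pytest.fixture(scope="session")
def small_cohort(toy_genome):
    """Seeded 10-strain mutagenized cohort plus ground truth."""
    cfg = synth.MutagenesisConfig(
        n_strains=10, mean_load=40, load_range=(10, 100), seed=11,
        planted_hotspots=[synth.PlantedHotspot("TOY0005", 0.5)],
    )
    cohort, truth = synth.simulate_mutagenesis(toy_genome, cfg)
    return cohort, truth
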