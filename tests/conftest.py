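import pytest

from spliceforge.gene_model import GeneModel, Interval
from spliceforge.simulate import SimConfig, build_cwp_like_gene, cwp_catalog
from spliceforge.splice import enumerate_variants


@pytest.fixture(scope="session")
def cwp_model():
    return build_cwp_like_gene()


@pytest.fixture(scope="session")
def cwp_events():
    return cwp_catalog()


@pytest.fixture(scope="session")
def cwp_variants(cwp_model, cwp_events):
    return enumerate_variants(cwp_model, cwp_events)


@pytest.fixture(scope="session")
def cwp_proteins(cwp_model, cwp_variants):
    from spliceforge.orf import find_orf, locate_stop_exon

    out = {}
    for v in cwp_variants:
        out[v.name] = locate_stop_exon(v, find_orf(v.seq), cwp_model)
    return out


@pytest.fixture
def toy_model():
    """Three exons of 6 nt separated by 6-nt introns; trivially checkable."""
    #        eee111 EEE222 GGG
    seq = "AAACCCGTTTAGGGCTTTGTTTAGCCCTTT"
    #      exon1    intron1  exon2    intron2  exon3
    #      [0,6)    [6,12)   [12,18)  [18,24)  [24,30)
    return GeneModel(
        gene_id="toy",
        seq=seq,
        exons=[Interval(0, 6), Interval(12, 18), Interval(24, 30)],
    )


@pytest.fixture
def sim_cfg():
    return SimConfig(seed=7)
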