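import pytest
from hypothesis import HealthCheck, settings

from mirreg.catalog import (
    Catalog,
    ConservationClass,
    GeneRecord,
    MiRNARecord,
    SiteConservation,
    SiteType,
    TargetSite,
)
from mirreg.expression import Thresholds

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def thresholds() -> Thresholds:
    return Thresholds()


def make_site(mature="miR-a", gene="G1", offset=10, site_type=SiteType.EIGHT_MER,
              conservation=SiteConservation.CONSERVED, targetscan=True,
              microt=None, mirsvr=None) -> TargetSite:
    return TargetSite(mature, gene, offset, site_type, conservation,
                      targetscan, microt, mirsvr)


@pytest.fixture
def tiny_catalog() -> Catalog:
    """Three genes, two miRNAs, a handful of sites; miR-a targets G1+G2."""
    genes = (GeneRecord("G1", 1000), GeneRecord("G2", 2000), GeneRecord("G3", 500))
    mirnas = (
        MiRNARecord("miR-a", "hsa-mir-a", ConservationClass.BROADLY_CONSERVED),
        MiRNARecord("miR-b", "hsa-mir-b", ConservationClass.PRIMATE_SPECIFIC),
    )
    sites = (
        make_site("miR-a", "G1", 100, microt=0.6, mirsvr=-0.5),
        make_site("miR-a", "G2", 200, microt=0.7, mirsvr=-0.4),
        make_site("miR-b", "G3", 50, conservation=SiteConservation.NONCONSERVED,
                  microt=0.5, mirsvr=-0.3),
    )
    return Catalog(genes, mirnas, sites)
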