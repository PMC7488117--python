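import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gtconcord.callset_io import (
    GenotypeCall,
    GenotypeClass,
    PairedCall,
    Platform,
    Site,
)

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


VCF_FIXTURE = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=248956422>
##FILTER=<ID=LowQual,Description="Low quality call">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=RGQ,Number=1,Type=Integer,Description="Reference genotype confidence">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
1\t109711919\trs1633365\tT\tC\t100\tPASS\t.\tGT:DP:GQ\t0/1:30:99
1\t200\tsnp_nocall\tG\tA\t50\tPASS\t.\tGT\t./.
1\t300\tins_homalt\tA\tAG\t80\tPASS\t.\tGT:DP:GQ\t1/1:25:75
1\t400\tsnp_filtered\tT\tC\t10\tLowQual\t.\tGT\t0/1
1\t500\thomref\tA\t.\t30\t.\t.\tGT:DP:RGQ\t0/0:28:90
"""

BEADCHIP_FIXTURE = "\n".join([
    "[Header]",
    "GSGT Version\t2.0.4",
    "Processing Date\t2026-01-01",
    "Num SNPs\t3",
    "Num Samples\t1",
    "[Data]",
    "SNP Name\tChr\tPosition\tAllele1 - Plus\tAllele2 - Plus\tGC Score\t"
    "GT Score\tCluster Sep\tTheta\tR\tX\tY\tB Allele Freq",
    # intensity values below are fixture-invented, not transcribed data
    "rs3832043\t2\t233671807\tI\tI\t0.78\t0.81\t0.9\t0.02\t1.1\t1.0\t0.1\t0.0",
    "rs_nocall\t1\t150\t-\t-\t0.0\t0.5\t0.5\t0.5\t1.0\t0.5\t0.5\t0.5",
    "rs_het\t1\t250\tA\tG\t0.9\t0.9\t0.9\t0.5\t1.0\t0.5\t0.5\t0.5",
]) + "\n"


@pytest.fixture
def vcf_path(tmp_path):
    p = tmp_path / "fixture.vcf"
    p.write_text(VCF_FIXTURE)
    return p


@pytest.fixture
def beadchip_path(tmp_path):
    p = tmp_path / "fixture_beadchip.txt"
    p.write_text(BEADCHIP_FIXTURE)
    return p


def make_pair(chrom="1", pos=100, concordant=True, rsid=None):
    """A minimal PairedCall for counting-level tests."""
    site = Site(chrom, pos, rsid or f"{chrom}:{pos}", "T", ("C",))
    truth = GenotypeCall(site, ("T", "T"), Platform.WGS)
    if concordant:
        test = GenotypeCall(site, ("T", "T"), Platform.BEADCHIP)
        cls = GenotypeClass.AA
    else:
        test = GenotypeCall(site, ("C", "T"), Platform.BEADCHIP)
        cls = GenotypeClass.AB
    return PairedCall(site, truth, test, GenotypeClass.AA, cls)


@pytest.fixture
def make_paired_calls():
    def _make(n, n_discordant, chrom="1"):
        return [
            make_pair(chrom, pos=i + 1, concordant=i >= n_discordant)
            for i in range(n)
        ]
    return _make
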