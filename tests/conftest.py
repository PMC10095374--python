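import pytest
from hypothesis import settings

from metformin_ra_mr import load_metformin_ra_instruments
from metformin_ra_mr.sumstats_io import GwasRecord, HarmonizedInstrument

settings.register_profile("ci", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundled_instruments():
    """The 32 published metformin/RA instruments."""
    return load_metformin_ra_instruments()


def make_record(snp_id="rs1", chrom="1", ea="A", oa="C", beta=0.01, se=0.002,
                pvalue=1e-9, eaf=0.3, n=None, pos=None):
    return GwasRecord(snp_id=snp_id, chrom=chrom, effect_allele=ea, other_allele=oa,
                      beta=beta, se=se, pvalue=pvalue, eaf=eaf, n=n, pos=pos)


def make_instrument(snp_id="rs1", chrom="1", ea="A", oa="C", eaf=0.3,
                    beta_exp=0.01, se_exp=0.002, p_exp=1e-9,
                    beta_out=-0.03, se_out=0.02, p_out=0.1,
                    f_stat=None, n_exp=None, n_out=None):
    return HarmonizedInstrument(
        snp_id=snp_id, chrom=chrom, effect_allele=ea, other_allele=oa,
        eaf_exposure=eaf, beta_exp=beta_exp, se_exp=se_exp, p_exp=p_exp,
        beta_out=beta_out, se_out=se_out, p_out=p_out,
        f_stat=f_stat, n_exp=n_exp, n_out=n_out,
    )
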