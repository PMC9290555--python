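import numpy as np
import pytest

from dnmpipe.io import trio_records_from_table
from dnmpipe.model import CandidateMutation, GenotypeCall
from dnmpipe.simulate import make_table1_fixture


@pytest.fixture(scope="session")
def trio_table():
    return make_table1_fixture()


@pytest.fixture(scope="session")
def trio_records(trio_table):
    return trio_records_from_table(trio_table)


def make_call(gt="het", dp=40, gq=99, ad=(20, 20), adf=10, adr=10):
    return GenotypeCall(
        gt=gt, dp=dp, gq=gq, ad_ref=ad[0], ad_alt=ad[1], adf=adf, adr=adr
    )


def make_candidate(
    child=None, father=None, mother=None, nondescendant_carriers=0, ref="A", alt="G"
):
    return CandidateMutation(
        trio="C00",
        chrom="1",
        pos=1000,
        ref=ref,
        alt=alt,
        child_call=child or make_call(),
        father_call=father or make_call(gt="hom_ref", ad=(40, 0), adf=0, adr=0),
        mother_call=mother or make_call(gt="hom_ref", ad=(40, 0), adf=0, adr=0),
        nondescendant_carriers=nondescendant_carriers,
    )
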