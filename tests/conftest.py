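import numpy as np
import pytest

from iambcf import CompoundRecord, CompoundTable


@pytest.fixture
def rng():
    return np.random.default_rng(20221111)


@pytest.fixture
def small_table():
    """Three hand-written compounds with a couple of descriptors."""
    return CompoundTable(
        records=[
            CompoundRecord(
                id="c1", name="benzene", log_kw_iam=1.20,
                descriptors={"TPSA": 0.0, "F_Csp3": 0.0, "HD": 0, "logKow": 2.13},
            ),
            CompoundRecord(
                id="c2", name="phenol", log_kw_iam=1.05,
                descriptors={"TPSA": 20.23, "F_Csp3": 0.0, "HD": 1, "logKow": 1.46},
                log_bcf_epi=0.72,
            ),
            CompoundRecord(
                id="c3", log_kw_iam=2.50,
                descriptors={"TPSA": 0.0, "F_Csp3": 0.5, "HD": 0, "logKow": 3.9},
                log_bcf_vivo=1.85,
            ),
        ]
    )
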