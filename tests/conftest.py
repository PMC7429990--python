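import numpy as np
import pytest
from hypothesis import settings

import stedot as st

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def single_te_protocol():
    """Full STE protocol at one echo time (231 DWIs + interleaved b0s)."""
    return st.ste_protocol(tes=(88.0,))


@pytest.fixture(scope="session")
def multi_te_protocol():
    return st.ste_protocol(tes=st.DEFAULT_TES)


@pytest.fixture(scope="session")
def cgm_model():
    """Two-pool cerebellar-GM-like model without T2 (TE-independent)."""
    return st.TissueModel(
        (
            st.Compartment("ball", 0.097, d_par=0.12, d_perp=0.12),
            st.Compartment("ball", 0.903, d_par=1.0, d_perp=1.0),
        )
    )


def noiseless_signals(model, protocol):
    """Noiseless normalised signal vector aligned to a protocol."""
    te_min = float(np.min(protocol.te))
    s0 = st.signal_with_t2(model, 0.0, te_min)
    return np.array(
        [
            st.signal_with_t2(model, float(b), float(te)) / s0
            for b, te in zip(protocol.b, protocol.te)
        ]
    )
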