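import numpy as np
import pytest

from mrkit import HarmonizedSet


@pytest.fixture
def make_h():
    """Factory for small HarmonizedSet fixtures from effect vectors."""

    def _make(beta_x, beta_y, se_y=None, se_x=None, n_x=100_000, n_y=100_000):
        beta_x = np.asarray(beta_x, dtype=float)
        beta_y = np.asarray(beta_y, dtype=float)
        J = len(beta_x)
        se_y = np.full(J, 0.05) if se_y is None else np.asarray(se_y, dtype=float)
        se_x = np.full(J, 0.01) if se_x is None else np.asarray(se_x, dtype=float)
        return HarmonizedSet(
            snp_ids=[f"rs{i + 1}" for i in range(J)],
            beta_x=beta_x,
            se_x=se_x,
            beta_y=beta_y,
            se_y=se_y,
            eaf=np.full(J, 0.3),
            n_x=np.full(J, float(n_x)),
            n_y=np.full(J, float(n_y)),
        )

    return _make
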