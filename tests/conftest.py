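import numpy as np
import pytest
from hypothesis import settings

import hairbundle as hb

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# Control-condition ensemble means: K = 0.85 pN/nm, F_G = 17 pN, X_0 = -2 nm;
# delta = 20 nm (package default for synthesis), F_null set so F(0) = 0.
CONTROL = hb.with_force_zero_at_origin(
    hb.GatingSpringParams(K=0.85, F_G=17.0, X_0=-2.0, delta=20.0)
)


@pytest.fixture
def control_params() -> hb.GatingSpringParams:
    return CONTROL


@pytest.fixture
def geometry() -> hb.BundleGeometry:
    return hb.BundleGeometry()  # gamma = 0.14, K_SP = 0.17 pN/nm


@pytest.fixture
def make_relation():
    """Factory for synthetic force-displacement records from the control
    parameters (optionally with a different gating force and added force
    noise)."""

    def _make(F_G: float = 17.0, noise_sd: float = 0.0, seed: int = 0,
              n: int = 18, span: float = 150.0) -> hb.FDRelation:
        p = hb.with_force_zero_at_origin(
            hb.GatingSpringParams(K=0.85, F_G=F_G, X_0=-2.0, delta=20.0)
        )
        X = np.linspace(-span, span, n)
        F = np.asarray(hb.fd_force(X, p), dtype=float)
        if noise_sd > 0:
            F = F + np.random.default_rng(seed).normal(0.0, noise_sd, n)
        return hb.FDRelation(X, F, cell_id="c0")

    return _make
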