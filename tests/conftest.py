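import numpy as np
import pytest
from hypothesis import settings

import pedpeel as pp
from pedpeel.model import ModelParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def trio():
    """Founder pair and one child."""
    return pp.Pedigree.from_records([("F", "0", "0"), ("M", "0", "0"),
                                     ("C", "F", "M")])


@pytest.fixture
def fixed_params():
    """Single-locus parameters matching the worked examples (no estimation)."""
    def make(n_loci=1, p=0.5, eps=0.01, delta=0.001, gamma=0.01):
        return ModelParams(p=np.full(n_loci, p), eps=np.full(n_loci, eps),
                           delta=np.full(n_loci, delta),
                           gamma=np.full(max(n_loci - 1, 1), gamma))
    return make


def run_fixed(ped, obs, params, **kw):
    """Peel with all per-cycle estimation off (worked-example conditions)."""
    kw.setdefault("tol", 1e-10)
    kw.setdefault("n_cycles", 30)
    return pp.run_single_locus(ped, obs, params, est_maf=False,
                               est_errors=False, **kw)
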