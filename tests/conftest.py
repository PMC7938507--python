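import numpy as np
import pytest
from hypothesis import settings

from duomr.sumstats import HarmonizedInstrument, SnpAssociation

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_instrument(rsid, bx, sx, by, sy, status="kept", **kwargs):
    return HarmonizedInstrument(
        rsid=rsid,
        beta_exposure=bx,
        se_exposure=sx,
        beta_outcome=by,
        se_outcome=sy,
        status=status,
        **kwargs,
    )


def make_instruments(bx, sx, by, sy):
    """Vector inputs -> harmonized instrument list."""
    return [
        make_instrument(f"rs{i}", float(b), float(s), float(o), float(t))
        for i, (b, s, o, t) in enumerate(zip(bx, sx, by, sy))
    ]


@pytest.fixture
def instrument_factory():
    return make_instruments


@pytest.fixture
def assoc_factory():
    def make(rsid="rs1", ea="A", oa="G", beta=0.1, se=0.02, eaf=0.3, pvalue=1e-6, n=1000):
        return SnpAssociation(
            rsid=rsid, effect_allele=ea, other_allele=oa, beta=beta, se=se,
            eaf=eaf, pvalue=pvalue, n=n,
        )

    return make


@pytest.fixture
def random_instruments():
    """Seeded random instrument sets for oracle comparisons."""

    def make(seed, n=8, theta=0.2):
        rng = np.random.default_rng(seed)
        bx = rng.uniform(0.05, 0.3, n) * rng.choice([-1, 1], n)
        sx = rng.uniform(0.005, 0.03, n)
        sy = rng.uniform(0.005, 0.05, n)
        by = theta * bx + rng.normal(0, sy)
        return make_instruments(bx, sx, by, sy)

    return make
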