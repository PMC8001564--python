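import numpy as np
import pytest

from mrkit.harmonize import Action, HarmonizedSet, HarmonizedVariant


def make_hset(beta_exp, beta_out, se_out, se_exp=None, exposure="x", outcome="y"):
    """Build a harmonized set directly from effect arrays (all variants kept)."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    se_out = np.asarray(se_out, dtype=float)
    se_exp = (
        np.full_like(beta_exp, 0.01) if se_exp is None else np.asarray(se_exp, dtype=float)
    )
    variants = [
        HarmonizedVariant(
            rsid=f"rs{i}",
            effect_allele="A",
            beta_exp=float(be),
            se_exp=float(se),
            beta_out=float(bo),
            se_out=float(so),
            action=Action.KEPT_AS_IS,
        )
        for i, (be, se, bo, so) in enumerate(zip(beta_exp, se_exp, beta_out, se_out))
    ]
    return HarmonizedSet(exposure, outcome, variants)


def random_hset(rng, m=16):
    """A random m-SNP harmonized set with realistic magnitudes."""
    be = rng.uniform(0.03, 0.2, m) * rng.choice([-1.0, 1.0], m)
    se_e = rng.uniform(0.004, 0.01, m)
    se_o = rng.uniform(0.001, 0.004, m)
    bo = rng.normal(0.0, 0.02, m)
    return make_hset(be, bo, se_o, se_e)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
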