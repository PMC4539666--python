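import numpy as np
import pytest

from fpdisconnect import DoseDesign, ExpressionProfile, IN_VITRO, IN_VIVO


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_profile(values, dose_idx=None, system=IN_VITRO, gene="g1",
                 compound="c1"):
    values = np.asarray(values, float)
    if dose_idx is None:
        # two replicates per dose over ceil(n/2) doses
        dose_idx = np.repeat(np.arange(1, values.size // 2 + 1), 2)[: values.size]
    return ExpressionProfile(gene_id=gene, compound_id=compound, system=system,
                             dose_idx=dose_idx, values=values)


def random_profile(rng, design=None, mu=None, sigma=0.3, system=IN_VITRO,
                   gene="g1", compound="c1"):
    design = design or DoseDesign((2, 2, 2, 2))
    idx = design.dose_indices
    mean = np.zeros(design.m) if mu is None else np.asarray(mu, float)
    values = mean[idx - 1] + rng.normal(0, sigma, idx.size)
    return ExpressionProfile(gene_id=gene, compound_id=compound, system=system,
                             dose_idx=idx, values=values)


@pytest.fixture
def vitro_vivo_pair(rng):
    """A flat null in vitro / in vivo pair on the TG-GATEs-like design."""
    vitro = random_profile(rng, DoseDesign((2, 2, 2, 2)), system=IN_VITRO)
    vivo = random_profile(rng, DoseDesign((3, 3, 3, 3)), system=IN_VIVO)
    return vitro, vivo
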