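import numpy as np
import pytest

from tagbias import CausalGLM, HaplotypeJoint, get_link, haplotypes_from_ld


@pytest.fixture
def table1_joint() -> HaplotypeJoint:
    """Worked-example joint: marker MAF 0.1, causal MAF 0.05, D'=1
    (causal allele on half the minor-marker chromosomes)."""
    return HaplotypeJoint(h_DM=0.05, h_Dm=0.0, h_dM=0.05, h_dm=0.9)


@pytest.fixture
def gwas_joint() -> HaplotypeJoint:
    """Typical GWAS tagging: both MAFs 0.2, r² = 0.8, positive delta."""
    return haplotypes_from_ld(0.2, 0.2, "r2", 0.8, "+")


@pytest.fixture
def rare_log_model() -> CausalGLM:
    """Log-link causal model: baseline risk 0.01, per-allele risk ratio 2."""
    return CausalGLM(
        link=get_link("log"), beta0=np.log(0.01), beta_d=np.log(2), beta_x=0.0
    )


def random_feasible_joint(
    rng: np.random.Generator,
    min_mass: float = 0.0,
    freq_lo: float = 0.05,
    freq_hi: float = 0.95,
) -> HaplotypeJoint:
    """Draw a random haplotype joint with both loci polymorphic.

    ``min_mass`` > 0 keeps every haplotype class populated (needed when a
    downstream computation divides by a cell mass).
    """
    while True:
        p_D = rng.uniform(freq_lo, freq_hi)
        p_M = rng.uniform(freq_lo, freq_hi)
        d_prime = rng.uniform(-0.95, 0.95)
        joint = haplotypes_from_ld(p_D, p_M, "d_prime", d_prime, "+")
        masses = joint.as_array()
        if masses.min() > min_mass:
            return joint
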