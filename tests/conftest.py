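import numpy as np
import pytest

from exportkinetics.model import KineticParams
from exportkinetics.synthetic import (
    GroundTruthGene,
    NoiseSpec,
    gamma_pulse_profile,
    generate_cohort,
    generate_gene_timecourse,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Three synthetic genes with the default noise structure."""
    return generate_cohort(3, noise=NoiseSpec(sigma_b=0.2, sigma_t=1.0, seed=42))


@pytest.fixture(scope="session")
def single_gene(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def well_identified_gene():
    """A gene whose four rates are all comfortably identifiable."""
    params = KineticParams(k1_prime=0.3, k2=0.15, k2_prime=0.1, k_cyto_deg=np.log(2) / 60)
    return GroundTruthGene(
        "well_identified",
        params,
        gamma_pulse_profile(5.0, 30.0, t_peak=20.0),
        basal_ca=5.0,
    )


@pytest.fixture(scope="session")
def noiseless_gene():
    """Latent trajectories with no biological or timepoint noise."""
    params = KineticParams(k1_prime=0.4, k2=0.2, k2_prime=0.08, k_cyto_deg=0.02)
    gene = GroundTruthGene(
        "noiseless", params, gamma_pulse_profile(5.0, 25.0, t_peak=22.0), basal_ca=5.0
    )
    return generate_gene_timecourse(
        gene, noise=NoiseSpec(sigma_b=0.0, sigma_t=0.0, library_sizes=1e9, seed=0)
    )
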