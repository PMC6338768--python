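import numpy as np
import pandas as pd
import pytest

from geostrat.simpop import (
    SimulationConfig,
    TraitSpec,
    simulate_source_freqs,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_sim():
    """One modest clinal cohort shared by read-only tests."""
    cfg = SimulationConfig(
        n_individuals=800,
        n_variants=400,
        n_sources=3,
        fst=0.08,
        gradient_strength=3.0,
        seed=123,
        trait_specs=[
            TraitSpec("geo_trait", geo_weight=1.0, noise_sd=1.0, cline_coupling=0.9),
            TraitSpec("gen_trait", genetic_weight=1.0, noise_sd=1.0),
        ],
    )
    src = simulate_source_freqs(cfg)
    return simulate_cohort(cfg, src)


@pytest.fixture()
def toy_genotypes():
    """2 individuals x 3 variants with fixed dosages for hand arithmetic."""
    from geostrat.simpop import GenotypeMatrix

    dosages = np.array([[0.0, 1.0, 2.0], [2.0, 0.5, 1.0]])
    variants = pd.DataFrame(
        {
            "variant_id": ["v1", "v2", "v3"],
            "chrom": [1, 1, 2],
            "pos": [1000, 600_000, 1000],
            "effect_allele": ["A", "A", "A"],
            "other_allele": ["G", "G", "G"],
            "maf": [0.3, 0.2, 0.4],
            "info": [1.0, 1.0, 1.0],
        }
    )
    return GenotypeMatrix(dosages=dosages, variants=variants, sample_ids=np.array(["i1", "i2"]))
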