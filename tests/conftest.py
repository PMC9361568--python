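import pytest

from admixne import maps, simulate


@pytest.fixture(scope="session")
def uniform_map() -> maps.RecombinationMap:
    """1 cM/Mb over 10 Mb."""
    return maps.RecombinationMap(chrom="1", starts=[0], ends=[10_000_000], rates=[1e-8])


@pytest.fixture(scope="session")
def hotspot_map() -> maps.RecombinationMap:
    spec = simulate.GeneticMapSpec(
        chrom_length_bp=10_000_000, background_rate=1e-8, hotspot_rate=1.0,
        hotspot_width_bp=2000, intensity_fold=20.0, seed=42,
    )
    return simulate.synth_map(spec)


@pytest.fixture(scope="session")
def small_cohort() -> simulate.Cohort:
    """Three-way admixed cohort with alleles, truth tracts and pedigree."""
    spec = simulate.GeneticMapSpec(
        chrom_length_bp=10_000_000, background_rate=1.5e-8, hotspot_rate=1.0, seed=7
    )
    gmap = simulate.synth_map(spec)
    founders = simulate.generate_founders(11, 800, 0.15, 10_000_000, seed=3)
    return simulate.simulate_admixture(
        founders, simulate.three_way_schedule(), gmap,
        n_individuals=40, n_generations=14, seed=5,
    )
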