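import numpy as np
import pytest

from chromatlas.genome import Assembly
from chromatlas.scab import build_scab_matrix
from chromatlas.staging import stage_granule_cells
from chromatlas.synth import make_synthetic_genome, preset_library, simulate_cohort

STAGE_AGES = (0.2, 1.0, 10.0, 30.0, 80.0)


@pytest.fixture(scope="session")
def small_assembly():
    return Assembly.from_dict({"chr1": 3_000_000, "chr2": 2_000_000, "chrX": 1_000_000})


@pytest.fixture(scope="session")
def genome():
    """Default synthetic genome: 5 autosomes + X, 100 Mb each, 5-Mb blocks."""
    return make_synthetic_genome(seed=0)


@pytest.fixture(scope="session")
def lib():
    return preset_library()


@pytest.fixture(scope="session")
def granule_cohort(genome, lib):
    """Lifespan cohort: 20 cells per human granule stage, 50 k contacts."""
    design = [
        (lib[f"human_granule_S{k + 1}"], 20, STAGE_AGES[k]) for k in range(5)
    ]
    return simulate_cohort(genome, design, 50_000, seed=11)


@pytest.fixture(scope="session")
def granule_matrix(genome, granule_cohort):
    return build_scab_matrix(granule_cohort, genome.cpg_track)


@pytest.fixture(scope="session")
def granule_truth(granule_cohort):
    return np.array([c.meta["structure_type"] for c in granule_cohort])


@pytest.fixture(scope="session")
def granule_ages(granule_matrix):
    return granule_matrix.meta["age"].to_numpy(float)


@pytest.fixture(scope="session")
def granule_stages(granule_matrix, granule_ages):
    return stage_granule_cells(granule_matrix, ages=granule_ages, k=5)
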