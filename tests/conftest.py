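import pytest

from paleosap.pipeline import run_synthetic_experiment
from paleosap.sim import SimulationConfig


@pytest.fixture(scope="session")
def small_experiment():
    """A modest but non-trivial end-to-end simulated experiment.

    Two databases at chimp-like and orangutan-like divergence, six
    pseudo-datasets, a couple of contaminants, and some dropped /
    mispredicted proteins so every filtering rule is exercised.
    """
    config = SimulationConfig(
        n_proteins=50,
        protein_length_range=(150, 400),
        divergence_per_db=(1.0, 2.5),
        drop_fraction=0.05,
        mispredict_fraction=0.05,
        n_contaminants=2,
        n_individuals=3,
        files_per_individual=2,
        seed=20260331,
    )
    return run_synthetic_experiment(config)
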