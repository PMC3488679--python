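import warnings

import pytest

from guildnet import genotyper
from guildnet.intron_annotator import ReferenceProfile, annotate_set
from guildnet.synthdata import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def profile():
    return ReferenceProfile.default()


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic dataset under default (study-condition) settings."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_dataset(SimulationConfig())


@pytest.fixture(scope="session")
def default_annotations(default_dataset, profile):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return annotate_set(default_dataset.intron_set, profile)


@pytest.fixture(scope="session")
def default_genotypes(default_dataset, default_annotations):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        genos = genotyper.collapse_introns(
            default_dataset.intron_set, default_annotations
        )
    genotyper.assign_subgroups(genos)
    genotyper.name_genotypes(genos)
    return genos
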