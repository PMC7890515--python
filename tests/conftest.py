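import warnings

import numpy as np
import pytest

import snakeid as sk
from snakeid import reference as ref
from snakeid.taxonomy import TaxonRecord, Taxonomy

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def example_taxonomy() -> Taxonomy:
    """Small hand-built taxonomy spanning three families and MIVS statuses."""
    return Taxonomy([
        TaxonRecord("Bitis arietans", "Bitis", "Viperidae",
                    synonyms=("Bitis lachesis",), common_names=("puff adder",),
                    is_mivs=True, regions=frozenset({"Africa"})),
        TaxonRecord("Bitis gabonica", "Bitis", "Viperidae",
                    common_names=("gaboon viper",), is_mivs=True,
                    regions=frozenset({"Africa"})),
        TaxonRecord("Echis ocellatus", "Echis", "Viperidae",
                    is_mivs=True, regions=frozenset({"Africa"})),
        TaxonRecord("Lampropeltis getula", "Lampropeltis", "Colubridae",
                    common_names=("common kingsnake",), is_mivs=False,
                    regions=frozenset({"NorthAmerica"})),
        TaxonRecord("Lampropeltis triangulum", "Lampropeltis", "Colubridae",
                    is_mivs=False, regions=frozenset({"NorthAmerica"})),
        TaxonRecord("Pantherophis guttatus", "Pantherophis", "Colubridae",
                    is_mivs=False, regions=frozenset({"NorthAmerica"})),
        TaxonRecord("Micrurus diastema", "Micrurus", "Elapidae",
                    is_mivs=True, regions=frozenset({"NorthAmerica"})),
        TaxonRecord("Micrurus fulvius", "Micrurus", "Elapidae",
                    is_mivs=True, regions=frozenset({"NorthAmerica"})),
    ])


SMALL_ALLOCATION = {"Colubridae": 8, "Viperidae": 6, "Elapidae": 6,
                    "Boidae": 4, "Pythonidae": 6}


@pytest.fixture(scope="session")
def small_challenge():
    """A small simulated challenge with answer strings, for end-to-end tests."""
    cfg = sk.SimConfig(n_participants=12, n_species=30, photos_per_species=4,
                       photos_per_participant=60,
                       family_allocation=dict(SMALL_ALLOCATION), seed=4)
    taxonomy = sk.synthetic_taxonomy(cfg)
    responses, truth = sk.simulate_challenge(cfg, taxonomy)
    responses = sk.attach_answer_strings(responses, taxonomy, seed=5)
    return cfg, taxonomy, responses, truth


@pytest.fixture(scope="session")
def recovery_fits():
    """Three replicate simulate-and-fit runs at the recovery study size.

    150 participants x 300 photos (100 species x 3), ~80 photos answered per
    participant, generating effects at the reference medians; the full
    20-effect model is refitted to each replicate.
    """
    spec = [s for s in sk.model_grid() if s.name == "home_x_region"][0]
    fits = []
    for rep in range(3):
        cfg = sk.SimConfig(n_participants=150, n_species=100, photos_per_species=3,
                           photos_per_participant=80, seed=100 + rep)
        responses, truth = sk.simulate_challenge(cfg)
        design = sk.build_design(responses, spec)
        post = sk.fit_grm(design, chains=2, warmup=500, draws=500,
                          seed=200 + rep, max_leapfrog=64)
        fits.append((design, truth, post))
    return fits


@pytest.fixture(scope="session")
def reference_truth_vector():
    def _get(colnames):
        return ref.fixed_effect_vector(colnames)
    return _get
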