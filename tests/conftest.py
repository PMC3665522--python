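import pytest

import domainhotspots as dh


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale scenario used by most integration-level tests."""
    return dh.ScenarioConfig(
        seed=11, n_domains=12, redundancy_factor=3,
        n_proteins_per_species=30, n_mutations_per_species=150,
        domain_length_range=(40, 80),
        hotspot_plan=(
            dh.PlantedHotspot(superfamily=0, species="yeast", fraction=0.1),
            dh.PlantedHotspot(superfamily=1, species="both", fraction=0.06),
        ),
        cooccurrence_plan=(dh.PlantedCooccurrence("deafness", "mating_defect", 5),),
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return dh.generate(small_config)


@pytest.fixture(scope="session")
def small_dataset_dir(tmp_path_factory, small_dataset):
    dataset, ledger = small_dataset
    d = tmp_path_factory.mktemp("dataset")
    dh.write_dataset(dataset, d, ledger)
    return d


@pytest.fixture(scope="session")
def small_tables(small_dataset):
    """Mapped count tables for the small dataset."""
    dataset, _ = small_dataset
    reps = dh.select_representative_proteins(dataset.proteins)
    kept = dh.filter_hits(dataset.hits)
    tables = dh.build_tables(dataset.mutations, kept, reps, dataset.domains,
                             proteins=dataset.proteins)
    return {t.domain_accession: t for t in tables}
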