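import pytest

from atpsdesign import builtin_fixtures, fixture_phases, interfacial_energy_table

#: published reference grid of group-mean interfacial energies, mJ/m²,
#: keyed (phase, phenotype, concentration)
REFERENCE_GROUP_MEANS = {
    ("PEG", "healthy_hCh", 10.0): 13.48,
    ("PEG", "healthy_hCh", 15.0): 13.23,
    ("PEG", "healthy_hCh", 20.0): 12.72,
    ("PEG", "OA_hCh", 10.0): 29.67,
    ("PEG", "OA_hCh", 15.0): 29.37,
    ("PEG", "OA_hCh", 20.0): 28.73,
    ("Dex", "healthy_hCh", 10.0): 25.79,
    ("Dex", "healthy_hCh", 15.0): 24.99,
    ("Dex", "healthy_hCh", 20.0): 24.74,
    ("Dex", "OA_hCh", 10.0): 43.58,
    ("Dex", "OA_hCh", 15.0): 42.74,
    ("Dex", "OA_hCh", 20.0): 42.48,
    ("PEG", "particle", 10.0): 0.88,
    ("PEG", "particle", 15.0): 0.95,
    ("PEG", "particle", 20.0): 1.11,
    ("Dex", "particle", 10.0): 0.48,
    ("Dex", "particle", 15.0): 0.35,
    ("Dex", "particle", 20.0): 0.32,
}


@pytest.fixture(scope="session")
def reference_dataset():
    """Built-in tensions, solids and EOS parameters."""
    return builtin_fixtures()


@pytest.fixture(scope="session")
def group_mean_table(reference_dataset):
    """Computed group means over the full fixture grid, keyed like REFERENCE_GROUP_MEANS."""
    _, solids, params = reference_dataset
    records, summaries = interfacial_energy_table(solids, fixture_phases(), params)
    by_key = {}
    for s in summaries:
        phase, rest = s.label.split("—")
        phenotype, conc = rest.rsplit(" ", 1)
        by_key[(phase, phenotype, float(conc.rstrip("%")))] = s
    return by_key
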