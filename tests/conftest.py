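import numpy as np
import pandas as pd
import pytest

from hybridtrace import GenotypeMatrix, SampleTable
from hybridtrace.simulate import (PopulationSpec, SimLandscapeSpec,
                                  SimPanelSpec, simulate_admixed_landscape)


@pytest.fixture
def tiny_genotypes():
    """Two individuals, two diploid loci, one value of each dosage class."""
    g = GenotypeMatrix(["a", "b"], ["L1", "L2"],
                       np.array([[0.0, 1.0], [2.0, np.nan]]),
                       np.array([2, 2]))
    s = SampleTable(pd.DataFrame({
        "individual": ["a", "b"], "population": ["p1", "p1"],
        "cohort": ["study", "study"], "species": ["unknown", "unknown"],
        "lat": [39.0, 39.0], "lon": [-9.0, -9.0]}))
    return g, s


@pytest.fixture(scope="session")
def reference_panel():
    """Default synthetic reference cohorts (54-of-60 diagnostic + mtDNA)."""
    from hybridtrace import simulate_reference_panels
    return simulate_reference_panels(SimPanelSpec(seed=20))


def two_cluster_landscape(seed, n_per=30, n_loci=30, delta=0.9):
    """Two well-differentiated populations; used for K-selection tests."""
    panel = SimPanelSpec(n_loci_nuclear=n_loci, n_diagnostic=n_loci,
                         include_mtdna=False, delta=delta, missing_rate=0.0,
                         seed=seed)
    land = SimLandscapeSpec(populations=[
        PopulationSpec("A", 39.0, -9.0, n_per, q_mean=0.0),
        PopulationSpec("B", 40.0, -8.0, n_per, q_mean=1.0)],
        q_sd=0.02, seed=seed)
    return simulate_admixed_landscape(panel, land)
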