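import logging

import numpy as np
import pandas as pd
import pytest

from migragen.popgen import GenotypeMatrix
from migragen.simulate import (
    SimulationConfig,
    simulate_ancestral_freqs,
    simulate_admixture_q,
    simulate_genotypes,
)
from migragen.telemetry import TelemetryTrack

logging.getLogger("migragen").setLevel(logging.ERROR)


def make_genotype_matrix(g, chrom="chr1", pos=None):
    g = np.asarray(g, dtype=float)
    m = g.shape[1]
    loci = pd.DataFrame({
        "chrom": chrom if not isinstance(chrom, (list, np.ndarray)) else chrom,
        "pos": np.arange(1, m + 1) * 100 if pos is None else pos,
        "id": [f"snp_{j}" for j in range(m)],
        "ref": "A",
        "alt": "G",
    })
    return GenotypeMatrix(g, [f"ind_{i}" for i in range(g.shape[0])], loci)


def two_population_genotypes(n_per_group=100, m=5000, fst=0.05, seed=0):
    """Balding-Nichols two-population cohort with one-hot ancestry."""
    freqs = simulate_ancestral_freqs(m, 2, fst, seed=seed)
    q = np.zeros((2 * n_per_group, 2))
    q[:n_per_group, 0] = 1.0
    q[n_per_group:, 1] = 1.0
    g = simulate_genotypes(freqs, q, seed=seed + 1).astype(float)
    labels = np.repeat([0, 1], n_per_group)
    return make_genotype_matrix(g), labels


def make_track(timestamps, xy, animal_id="a1"):
    df = pd.DataFrame({
        "timestamp": pd.to_datetime(timestamps),
        "x_km": np.asarray(xy)[:, 0],
        "y_km": np.asarray(xy)[:, 1],
    })
    return TelemetryTrack(animal_id, df)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A small synthetic cohort written to disk once per session."""
    from migragen.simulate import write_fixture_set

    out = tmp_path_factory.mktemp("fixtures")
    cfg = SimulationConfig(n_individuals=24, n_snps=400, n_causal=8,
                           fst_divergence=0.2, n_years=1,
                           missing_fix_rate=0.02, seed=11)
    paths = write_fixture_set(cfg, out)
    paths["config_obj"] = cfg
    return paths
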