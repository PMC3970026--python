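import numpy as np
import pytest

import kernova as kv


@pytest.fixture(scope="session")
def small_genotypes():
    """QC'd, complete 120 x 80 LE genotype matrix."""
    cfg = kv.SimulationConfig(n_individuals=120, n_markers=80, seed=11)
    return kv.qc_filter(kv.simulate_genotypes(cfg))


@pytest.fixture(scope="session")
def hwe_genotypes():
    """Larger LE panel for kernel diagonal expectations."""
    cfg = kv.SimulationConfig(n_individuals=400, n_markers=600, seed=12)
    return kv.qc_filter(kv.simulate_genotypes(cfg))


@pytest.fixture()
def tiny_matrix_file(tmp_path):
    """3x2 plain-matrix genotype file with known frequencies."""
    path = tmp_path / "geno.tsv"
    path.write_text(
        "id\tm1\tm2\n"
        "a\t0\t1\n"
        "b\t2\t1\n"
        "c\t1\t0\n"
    )
    return path


def make_genotype_matrix(dosages, prefix="x"):
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    return kv.GenotypeMatrix(
        dosages,
        [f"{prefix}m{j}" for j in range(p)],
        [f"{prefix}i{i}" for i in range(n)],
    )
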