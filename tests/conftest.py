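import numpy as np
import pandas as pd
import pytest

from pgxpersona.containers import DosageMatrix
from pgxpersona.simdata import LdBlockSpec, TraitArchitecture, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest end-to-end synthetic study shared across test modules."""
    return simulate_cohort(
        n_samples=600,
        ld_spec=LdBlockSpec(n_blocks=60, snps_per_block=10),
        arch=TraitArchitecture(n_causal=12, h2_snp=0.15, gwas_n=100_000, seed=7),
        seed=11,
    )


def make_dosage_matrix(dosages, chrom=None, bp=None, a1=None, a2=None, info=None):
    """Build a DosageMatrix from a raw array with simple default metadata."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    chrom = np.ones(m, dtype=int) if chrom is None else np.asarray(chrom)
    bp = np.arange(1, m + 1) * 1000 if bp is None else np.asarray(bp)
    a1 = np.full(m, "G") if a1 is None else np.asarray(a1, dtype=object)
    a2 = np.full(m, "A") if a2 is None else np.asarray(a2, dtype=object)
    info = np.ones(m) if info is None else np.asarray(info, dtype=float)
    variants = pd.DataFrame(
        {"CHR": chrom, "BP": bp, "A1": a1, "A2": a2, "INFO": info},
        index=pd.Index([f"v{j}" for j in range(m)], name="SNP"),
    )
    samples = pd.Index([f"S{i}" for i in range(n)], name="IID")
    return DosageMatrix(dosages, samples, variants)


@pytest.fixture
def dosage_factory():
    return make_dosage_matrix
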