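"""Shared fixtures: one small synthetic study reused across unit tests."""
import numpy as np
import pandas as pd
import pytest

from seedomics.simdata import SimConfig, simulate_study
from seedomics.types import GenotypeMatrix


@pytest.fixture(scope="session")
def tiny_cfg():
    return SimConfig(
        seed=7,
        n_accessions=150,
        n_variants=600,
        n_genes=150,
        n_subpops=2,
        n_chromosomes=3,
        chrom_length_bp=8_000_000,
        panel_size=80,
        module_size=30,
        n_trait_causal=100,
        genes_per_hotspot=10,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_cfg):
    return simulate_study(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_geno(tiny_study):
    return tiny_study.genotypes


def make_geno(dosages, chrom="chr1", start_pos=1000, spacing=1000, haplotypes=None):
    """GenotypeMatrix from a raw dosage array with evenly spaced positions."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "id": [f"v{j}" for j in range(m)],
            "chrom": [chrom] * m,
            "pos": [start_pos + spacing * j for j in range(m)],
            "ref": ["A"] * m,
            "alt": ["T"] * m,
        }
    )
    accessions = pd.DataFrame({"id": [f"a{i}" for i in range(n)]})
    return GenotypeMatrix(dosages, variants, accessions, haplotypes=haplotypes)
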