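import numpy as np
import pandas as pd
import pytest

from pedrecomb.pedio import GenotypeMatrix, NuclearFamily, Pedigree
from pedrecomb.synthetic_data import ChromosomeConfig, SimConfig, simulate_cohort


def make_family_matrix(transmitted: np.ndarray, positions=None,
                       co_parent_dosage: int = 0, chrom: int = 1):
    """Build a minimal (family, GenotypeMatrix) in which the mother is
    heterozygous at every marker, the father homozygous, and each child's
    call encodes the given transmitted maternal allele (0/1).

    ``transmitted``: (n_children, n_markers) array of alleles from the
    heterozygous mother.
    """
    transmitted = np.asarray(transmitted, dtype=np.int8)
    n_children, n_markers = transmitted.shape
    if positions is None:
        positions = (np.arange(n_markers) + 1) * 100_000
    markers = pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(n_markers)],
        "chrom": chrom, "pos": positions, "allele_a": "A", "allele_b": "B"})
    father_call = np.full(n_markers, co_parent_dosage, dtype=np.int8)
    mother_call = np.ones(n_markers, dtype=np.int8)
    child_calls = transmitted + (co_parent_dosage // 2)
    samples = ["dad", "mum"] + [f"kid{j}" for j in range(n_children)]
    calls = np.column_stack([father_call, mother_call] + list(child_calls))
    gm = GenotypeMatrix(markers, samples, calls.astype(np.int8))
    fam = NuclearFamily("dad", "mum", tuple(f"kid{j}" for j in range(n_children)))
    return fam, gm


def make_pedigree(rows, parental_ages=None, current_ages=None) -> Pedigree:
    df = pd.DataFrame(rows, columns=["fid", "iid", "father", "mother",
                                     "sex", "affected"])
    return Pedigree(df, parental_ages=parental_ages or {},
                    current_ages=current_ages or {})


@pytest.fixture(scope="session")
def small_cohort():
    """10 three-child families, 2 chromosomes x 400 SNPs, clean genotypes."""
    cfg = SimConfig(
        n_families=10, children_per_family=3,
        chromosomes=[ChromosomeConfig(60_000_000, a_maternal=2.0),
                     ChromosomeConfig(60_000_000, a_maternal=2.0)],
        snps_per_chromosome=400, seed=11)
    ped, gm, truth = simulate_cohort(cfg)
    return cfg, ped, gm, truth
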