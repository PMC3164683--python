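"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own algorithms: the phasing oracle
enumerates every possible parental haplotype sequence, and the HWE oracle
enumerates every genotype table with the observed allele counts.
"""

from fractions import Fraction
from itertools import product
from math import comb

import numpy as np


def min_recombinant_total(transmitted: np.ndarray) -> int:
    """Minimum total number of crossovers over all children, by exhaustive
    enumeration of the parent's haplotype allele sequence.

    ``transmitted[j, m]`` is the allele child j received from the
    heterozygous parent at informative marker m.  For every candidate
    haplotype sequence h in {0,1}^M, child j's inheritance state at m is
    [t[j,m] != h[m]]; the cost is the total number of state switches.
    """
    t = np.asarray(transmitted, dtype=int)
    n_children, m = t.shape
    best = None
    for bits in product((0, 1), repeat=m):
        h = np.array(bits)
        states = t != h[None, :]
        switches = int((states[:, 1:] != states[:, :-1]).sum())
        best = switches if best is None else min(best, switches)
    return best


def hwe_enumeration_pvalue(n_het: int, n_hom_a: int, n_hom_b: int) -> float:
    """Exact HWE p-value by full enumeration of genotype tables with the
    observed allele counts, using exact rational arithmetic.

    P(n_ab | n, n_a) = C(n; n_aa, n_ab, n_bb) 2^n_ab / C(2n, n_a).
    """
    n = n_het + n_hom_a + n_hom_b
    n_a = 2 * n_hom_a + n_het

    def prob(h: int) -> Fraction:
        aa = (n_a - h) // 2
        bb = n - aa - h
        if aa < 0 or bb < 0 or (n_a - h) % 2:
            return Fraction(0)
        return Fraction(comb(n, aa) * comb(n - aa, h) * 2 ** h, comb(2 * n, n_a))

    p_obs = prob(n_het)
    total = sum(p for h in range(n + 1) if (p := prob(h)) <= p_obs)
    return float(total)


def binomial_at_least(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p) by direct pmf summation."""
    return float(sum(comb(n, i) * p ** i * (1 - p) ** (n - i)
                     for i in range(k, n + 1)))
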