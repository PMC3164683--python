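"""Chromosome-specific maternal-age effects.

Transmissions are split at maternal age 30 (a parent aged exactly 30 counts
as "old"), and each chromosome's shift in mean crossover count between the
two groups is tested by permutation.  To calibrate how many chromosomes
would reach significance if the genome-wide effect were shared evenly, each
transmission's total is redistributed across chromosomes by multinomial
draws — with probabilities proportional to the cohort's per-chromosome means
("proportional", preserving that long chromosomes recombine more) or equal
("uniform") — and the per-chromosome tests are rerun on every simulated
dataset.  Normalized counts (count divided by the cohort mean for that
chromosome) put chromosomes on a common scale for comparing shifts between
chromosome groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

AGE_THRESHOLD = 30.0


def chrom_columns(records: pd.DataFrame) -> list[str]:
    return [c for c in records.columns if c.startswith("chr")]


def normalize_counts(records: pd.DataFrame) -> pd.DataFrame:
    """Divide each per-chromosome count by that chromosome's cohort mean, so
    every chromosome's normalized cohort mean is 1."""
    cols = chrom_columns(records)
    out = records.copy()
    for c in cols:
        mean = records[c].mean()
        if mean <= 0:
            raise ValueError(f"cohort mean for {c} is not positive")
        out[c] = records[c] / mean
    return out


@dataclass
class ShiftResult:
    chromosome: str
    mean_young: float
    mean_old: float
    delta: float
    se_young: float
    se_old: float
    p_perm: float
    n_young: int
    n_old: int
    threshold: float = AGE_THRESHOLD


def _shift_p(counts: np.ndarray, old: np.ndarray, n_perm: int,
             rng: np.random.Generator, alternative: str) -> tuple[float, float]:
    """Observed delta (old - young) and its label-permutation p-value."""
    delta_obs = counts[old].mean() - counts[~old].mean()
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(old)
        delta = counts[perm].mean() - counts[~perm].mean()
        if alternative == "less":
            b += delta <= delta_obs + 1e-12
        elif alternative == "greater":
            b += delta >= delta_obs - 1e-12
        else:
            b += abs(delta) >= abs(delta_obs) - 1e-12
    return float(delta_obs), (b + 1) / (n_perm + 1)


def age_group_shift(records: pd.DataFrame, chromosome: str,
                    threshold: float = AGE_THRESHOLD, n_perm: int = 1000,
                    seed: int = 0, alternative: str = "less",
                    normalized: bool = False) -> ShiftResult:
    """Shift in mean count for one chromosome between mothers under and
    at-or-over ``threshold`` years; p by permuting the age-group labels,
    one-sided for a decrease by default."""
    df = normalize_counts(records) if normalized else records
    counts = df[chromosome].to_numpy(dtype=float)
    old = records["age_at_birth"].to_numpy() >= threshold
    if not old.any() or old.all():
        raise ValueError("both age groups must be non-empty")
    rng = np.random.default_rng(seed)
    delta, p = _shift_p(counts, old, n_perm, rng, alternative)
    young_c, old_c = counts[~old], counts[old]
    return ShiftResult(
        chromosome=chromosome,
        mean_young=float(young_c.mean()), mean_old=float(old_c.mean()),
        delta=delta,
        se_young=float(young_c.std(ddof=1) / np.sqrt(len(young_c))),
        se_old=float(old_c.std(ddof=1) / np.sqrt(len(old_c))),
        p_perm=float(p), n_young=int((~old).sum()), n_old=int(old.sum()),
        threshold=threshold)


def all_shifts(records: pd.DataFrame, threshold: float = AGE_THRESHOLD,
               n_perm: int = 1000, seed: int = 0, alternative: str = "less",
               normalized: bool = False) -> pd.DataFrame:
    """Per-chromosome shift table (Supplementary-table style layout)."""
    rows = []
    for i, c in enumerate(chrom_columns(records)):
        r = age_group_shift(records, c, threshold, n_perm, seed + i,
                            alternative, normalized)
        rows.append(r.__dict__)
    return pd.DataFrame(rows)


def redistribute_simulation(records: pd.DataFrame, mode: str = "proportional",
                            n_sim: int = 500, alpha: float = 0.05,
                            n_perm: int = 200, seed: int = 0,
                            threshold: float = AGE_THRESHOLD) -> dict:
    """Null distribution of the number of significant chromosomes when each
    transmission's crossovers land on chromosomes at random.

    Per simulation, every transmission's total is reallocated by a
    multinomial draw with probabilities proportional to the cohort
    per-chromosome means (``proportional``) or equal (``uniform``); the
    per-chromosome one-sided shift tests are rerun and significant
    chromosomes (p < alpha) counted.  Returns the simulated counts, the
    observed count, and P(simulated >= observed).
    """
    if mode not in ("proportional", "uniform"):
        raise ValueError(f"unknown redistribution mode {mode!r}")
    if n_sim < 100:
        warnings.warn("n_sim < 100 gives a coarse null distribution")
    cols = chrom_columns(records)
    k = len(cols)
    probs = (records[cols].mean().to_numpy() / records[cols].mean().sum()
             if mode == "proportional" else np.full(k, 1.0 / k))
    totals = records[cols].sum(axis=1).to_numpy(dtype=int)
    old = records["age_at_birth"].to_numpy() >= threshold
    rng = np.random.default_rng(seed)

    observed = int((all_shifts(records, threshold, n_perm, seed)["p_perm"]
                    < alpha).sum())
    sim_counts = np.empty(n_sim, dtype=int)
    for s in range(n_sim):
        sim = rng.multinomial(totals, probs)  # (n_transmissions, k)
        n_sig = 0
        for j in range(k):
            _, p = _shift_p(sim[:, j].astype(float), old, n_perm, rng, "less")
            n_sig += p < alpha
        sim_counts[s] = n_sig
    p_tail = float((np.sum(sim_counts >= observed) + 1) / (n_sim + 1))
    return {"mode": mode, "observed_significant": observed,
            "simulated_counts": sim_counts, "p_at_least_observed": p_tail,
            "alpha": alpha}


def compare_shift_groups(shifts: pd.DataFrame, group_a: list[str],
                         group_b: list[str], n_perm: int = 10000,
                         seed: int = 0) -> tuple[float, float]:
    """One-tailed test that group A's mean (normalized) downward shift
    exceeds group B's, by permuting chromosome group membership.

    ``shifts`` is an :func:`all_shifts` table; groups are disjoint lists of
    its ``chromosome`` labels.  The statistic is
    mean(delta_B) - mean(delta_A): positive when A decreases more.
    """
    if set(group_a) & set(group_b):
        raise ValueError("chromosome groups overlap")
    table = shifts.set_index("chromosome")["delta"]
    a = table.loc[group_a].to_numpy()
    b = table.loc[group_b].to_numpy()
    obs = b.mean() - a.mean()
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        count += (perm[len(a):].mean() - perm[:len(a)].mean()) >= obs - 1e-12
    return float(obs), (count + 1) / (n_perm + 1)


def submetacentric_enrichment(significant: list[str], class_table: dict[str, str],
                              target_class: str = "submetacentric") -> float:
    """Hypergeometric enrichment of a centromere-position class among the
    significant chromosomes, for a user-supplied classification.

    Chromosome classifications vary between sources, so no classification is
    packaged; this is a convenience around the one-sided hypergeometric tail.
    """
    import scipy.stats
    population = list(class_table)
    n_class = sum(1 for c in population if class_table[c] == target_class)
    hits = sum(1 for c in significant if class_table.get(c) == target_class)
    return float(scipy.stats.hypergeom.sf(hits - 1, len(population), n_class,
                                          len(significant)))
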