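"""Synthetic nuclear-family cohorts with known crossover truth.

The generator emulates the structure the downstream analyses need: multi-child
nuclear families genotyped at dense biallelic SNPs, child genotypes built as
mosaics of parental haplotypes with crossovers placed per meiosis, and a
maternal (and optionally paternal) age effect on the expected crossover
count.  Per chromosome ``c`` and parent of age ``t`` at the child's birth the
crossover count is Poisson with mean ``max(0, a_c + b_c * t)``; positions are
uniform on physical length (no interference), or hotspot-weighted when a
hotspot fraction is configured.  Genotyping error flips codes by single
steps (0<->1, 2<->1, rarely 0<->2), producing the tight spurious double
recombinants the caller's pre-treatment removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .pedio import MISSING, GenotypeMatrix, Pedigree, write_plink, write_ages

TRUTH_COLUMNS = ["parent_id", "child_id", "chrom", "pos_bp"]


@dataclass
class ChromosomeConfig:
    """Physical length and per-sex linear age model for crossover counts.

    ``a_*`` is the Poisson-mean intercept (expected crossovers per meiosis at
    age 0 on the linear scale), ``b_*`` the slope per year of parental age at
    birth; the mean is truncated at 0.
    """

    length_bp: int
    a_maternal: float
    b_maternal: float = 0.0
    a_paternal: float = 1.4
    b_paternal: float = 0.0

    def rate(self, sex: str, age: float) -> float:
        a, b = ((self.a_maternal, self.b_maternal) if sex == "maternal"
                else (self.a_paternal, self.b_paternal))
        return max(0.0, a + b * age)


def default_chromosomes(n: int = 4, length_bp: int = 150_000_000,
                        genome_slope: float = -0.5) -> list[ChromosomeConfig]:
    """Desk-scale genome: ``n`` equal chromosomes sharing a genome-wide
    maternal age slope.  Intercepts are set so the maternal mean at age 28 is
    about 2 crossovers per chromosome (a large-autosome female rate) and the
    paternal mean is age-invariant at 1.4."""
    b = genome_slope / n
    return [ChromosomeConfig(length_bp, a_maternal=2.0 - b * 28, b_maternal=b)
            for _ in range(n)]


@dataclass
class SimConfig:
    """Full description of a simulated cohort; ``seed`` is mandatory.

    Defaults give the desk-scale study condition used throughout the test
    suite: 40 three-child families, 4 chromosomes x 2,000 SNPs, genome-wide
    maternal slope -0.5 crossovers/year, clean genotypes.
    """

    n_families: int = 40
    children_per_family: int | tuple[int, ...] = 3
    chromosomes: list[ChromosomeConfig] = field(default_factory=default_chromosomes)
    snps_per_chromosome: int = 2000
    maf_low: float = 0.1
    maf_high: float = 0.5
    base_age_mean: float = 26.0
    base_age_sd: float = 4.0
    base_age_range: tuple[float, float] = (18.0, 40.0)
    spacing_shape: float = 2.0
    spacing_scale: float = 1.25
    spacing_min: float = 1.0
    paternal_age_offset: float = 2.0
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0
    obligate_crossover: bool = False
    hotspot_fraction: float = 0.0
    hotspots: dict[int, np.ndarray] | None = None  # chrom -> (k, 2) bp intervals
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.genotyping_error_rate, self.missing_rate,
                     self.hotspot_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")
        if self.n_families < 1 or self.snps_per_chromosome < 1:
            raise ValueError("need at least one family and one marker")
        if not self.chromosomes:
            raise ValueError("need at least one chromosome")

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "chromosomes" in raw:
            raw["chromosomes"] = [ChromosomeConfig(**c) for c in raw["chromosomes"]]
        return cls(**raw)


def _marker_positions(rng: np.random.Generator, length_bp: int, n: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length_bp + 1, size=n))
    while len(pos) < n:  # top up the rare duplicate collisions
        extra = rng.integers(1, length_bp + 1, size=n - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return pos[:n]


def _draw_crossovers(rng: np.random.Generator, cfg: SimConfig, chrom: int,
                     chrom_cfg: ChromosomeConfig, sex: str, age: float) -> np.ndarray:
    lam = chrom_cfg.rate(sex, age)
    n = rng.poisson(lam) + (1 if cfg.obligate_crossover else 0)
    if n == 0:
        return np.empty(0)
    u = rng.random(n)
    pos = rng.random(n) * chrom_cfg.length_bp
    if cfg.hotspot_fraction > 0 and cfg.hotspots:
        iv = np.asarray(cfg.hotspots.get(chrom, ()))
        if iv.size:
            lengths = iv[:, 1] - iv[:, 0]
            in_hot = u < cfg.hotspot_fraction
            k = rng.choice(len(iv), size=int(in_hot.sum()), p=lengths / lengths.sum())
            pos[in_hot] = iv[k, 0] + rng.random(int(in_hot.sum())) * lengths[k]
    return np.sort(pos)


def _gamete(rng: np.random.Generator, haps: np.ndarray, positions: np.ndarray,
            xo_pos: np.ndarray) -> np.ndarray:
    """Mosaic of the two parental haplotypes: phase flips at each crossover."""
    phase0 = rng.integers(2)
    phase = (phase0 + np.searchsorted(xo_pos, positions, side="left")) % 2
    return haps[phase, np.arange(len(positions))]


def simulate_cohort(cfg: SimConfig) -> tuple[Pedigree, GenotypeMatrix, pd.DataFrame]:
    """Simulate a cohort; returns (pedigree with ages, genotypes, truth table).

    The truth table has one row per true crossover
    (``parent_id, child_id, chrom, pos_bp``).  Identical config (including
    seed) yields identical output.
    """
    rng = np.random.default_rng(cfg.seed)

    # marker map
    marker_frames, freqs = [], []
    for ci, cc in enumerate(cfg.chromosomes, start=1):
        pos = _marker_positions(rng, cc.length_bp, cfg.snps_per_chromosome)
        marker_frames.append(pd.DataFrame({
            "snp_id": [f"snp{ci}_{k}" for k in range(len(pos))],
            "chrom": ci, "pos": pos, "allele_a": "A", "allele_b": "B",
        }))
        freqs.append(rng.uniform(cfg.maf_low, cfg.maf_high, size=len(pos)))
    markers = pd.concat(marker_frames, ignore_index=True)
    freq_b = np.concatenate(freqs)
    chrom_arr = markers["chrom"].to_numpy()
    pos_arr = markers["pos"].to_numpy()

    n_children_list = []
    for _ in range(cfg.n_families):
        if isinstance(cfg.children_per_family, int):
            n_children_list.append(cfg.children_per_family)
        else:
            n_children_list.append(int(rng.choice(cfg.children_per_family)))

    individuals, calls_cols, sample_ids = [], [], []
    parental_ages: dict[tuple[str, str], float] = {}
    current_ages: dict[str, float] = {}
    truth_rows: list[tuple[str, str, int, int]] = []

    for fam_i, n_children in enumerate(n_children_list, start=1):
        fid = f"fam{fam_i}"
        father, mother = f"{fid}_f", f"{fid}_m"
        # founder haplotypes: (2, n_snps) per parent
        hap = {p: (rng.random((2, len(markers))) < freq_b).astype(np.int8)
               for p in (father, mother)}
        for pid, sex in ((father, 1), (mother, 2)):
            individuals.append((fid, pid, "0", "0", sex, 0))
            sample_ids.append(pid)
            calls_cols.append(hap[pid].sum(axis=0))

        base = float(np.clip(rng.normal(cfg.base_age_mean, cfg.base_age_sd),
                             *cfg.base_age_range))
        mat_ages = [base]
        for _ in range(n_children - 1):
            spacing = cfg.spacing_min + rng.gamma(cfg.spacing_shape, cfg.spacing_scale)
            mat_ages.append(mat_ages[-1] + spacing)

        for k in range(n_children):
            cid = f"{fid}_c{k + 1}"
            individuals.append((fid, cid, father, mother, int(rng.integers(1, 3)), 0))
            sample_ids.append(cid)
            mat_age = mat_ages[k]
            pat_age = mat_age + cfg.paternal_age_offset
            parental_ages[(mother, cid)] = mat_age
            parental_ages[(father, cid)] = pat_age
            gametes = {}
            for pid, sex, age in ((mother, "maternal", mat_age),
                                  (father, "paternal", pat_age)):
                gamete = np.empty(len(markers), dtype=np.int8)
                for ci, cc in enumerate(cfg.chromosomes, start=1):
                    sel = chrom_arr == ci
                    xo = _draw_crossovers(rng, cfg, ci, cc, sex, age)
                    gamete[sel] = _gamete(rng, hap[pid][:, sel], pos_arr[sel], xo)
                    truth_rows += [(pid, cid, ci, int(x)) for x in xo]
                gametes[pid] = gamete
            calls_cols.append(gametes[mother] + gametes[father])

        # sampling-time ages: mother observed 10y after her last birth
        current_ages[mother] = mat_ages[-1] + 10.0
        current_ages[father] = mat_ages[-1] + cfg.paternal_age_offset + 10.0
        for k in range(n_children):
            current_ages[f"{fid}_c{k + 1}"] = current_ages[mother] - mat_ages[k]

    calls = np.column_stack(calls_cols).astype(np.int8)

    if cfg.genotyping_error_rate > 0:
        err = rng.random(calls.shape) < cfg.genotyping_error_rate
        big_step = rng.random(calls.shape) < 0.05  # rare 0<->2 flips
        up = rng.random(calls.shape) < 0.5
        new = calls.copy()
        new[err & (calls == 0)] = np.where(big_step[err & (calls == 0)], 2, 1)
        new[err & (calls == 2)] = np.where(big_step[err & (calls == 2)], 0, 1)
        new[err & (calls == 1)] = np.where(up[err & (calls == 1)], 2, 0)
        calls = new
    if cfg.missing_rate > 0:
        calls[rng.random(calls.shape) < cfg.missing_rate] = MISSING

    ped = Pedigree(
        pd.DataFrame(individuals,
                     columns=["fid", "iid", "father", "mother", "sex", "affected"]),
        parental_ages=parental_ages, current_ages=current_ages)
    gm = GenotypeMatrix(markers, sample_ids, calls)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS).sort_values(
        TRUTH_COLUMNS).reset_index(drop=True)
    return ped, gm, truth


def write_truth(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index=False, columns=TRUTH_COLUMNS)


def read_truth(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       dtype={"parent_id": str, "child_id": str,
                              "chrom": int, "pos_bp": int})


def write_cohort(ped: Pedigree, gm: GenotypeMatrix, truth: pd.DataFrame,
                 prefix: str) -> None:
    """Write the PLINK triplet, ages TSV and truth TSV under ``prefix``."""
    write_plink(ped, gm, prefix)
    write_ages(ped, prefix + ".ages.tsv")
    write_truth(truth, prefix + ".truth.tsv")


def thin_markers(gm: GenotypeMatrix, fraction: float, seed: int) -> GenotypeMatrix:
    """Keep each SNP independently with probability ``fraction``."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return gm
    rng = np.random.default_rng(seed)
    keep = rng.random(gm.n_snps) < fraction
    return gm.take_snps(keep)


def round_ages(ped: Pedigree, multiple: int = 5) -> Pedigree:
    """Round every individual's sampling-time age UP to the nearest multiple
    and recompute ages at birth as rounded(parent) - rounded(child).

    Emulates age approximation from coarse records; requires
    ``ped.current_ages``.
    """
    if not ped.current_ages:
        raise ValueError("pedigree carries no sampling-time ages to round")
    rounded = {i: float(np.ceil(a / multiple) * multiple)
               for i, a in ped.current_ages.items()}
    new_ages = {(p, c): rounded[p] - rounded[c]
                for (p, c) in ped.parental_ages
                if p in rounded and c in rounded}
    return replace(ped, parental_ages=new_ages, current_ages=rounded)
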