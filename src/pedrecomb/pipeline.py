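"""End-to-end orchestration: simulate/load -> QC -> call -> statistics.

Runs the stages in order with per-stage derived seeds, writes the event BED,
transmission-record TSV and a JSON stats report, and keeps filter-count
bookkeeping so SNPs in = SNPs retained + removals at every step.  Also hosts
the power-analysis recipes (marker thinning, age rounding) and the
family-level bootstrap.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import age_stats, chromosome_effects, genome_position
from .crossover_calling import count_transmissions, events_to_bed
from .pedio import (GenotypeMatrix, Pedigree, extract_nuclear_families,
                    filter_family_missing, qc_filter, read_ages, read_plink)
from .synthetic_data import SimConfig, simulate_cohort, thin_markers, round_ages

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration; unset input paths mean 'simulate'."""

    out_dir: str = "pedrecomb_out"
    seed: int = 0
    sim: SimConfig | None = None
    bfile: str | None = None
    ages_path: str | None = None
    run_qc: bool = True
    call_rate_min: float = 0.95
    hwe_alpha: float = 0.01
    min_children: int = 2
    window_bp: int = 1_000_000
    unique_only: bool = True
    reduced_families: bool = True
    age_threshold: float = 30.0
    bin_width: float = 0.05
    n_perm: int = 1000
    n_sim: int = 200
    run_stats: bool = True
    run_chrom: bool = True
    run_bins: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = SimConfig(**raw["sim"])
        return cls(**raw)


def _sub_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0]
               % (2 ** 31))


def load_inputs(cfg: RunConfig) -> tuple[Pedigree, GenotypeMatrix]:
    if cfg.bfile is not None:
        ped, gm = read_plink(cfg.bfile)
        if cfg.ages_path:
            ped.parental_ages.update(read_ages(cfg.ages_path))
        return ped, gm
    sim = cfg.sim if cfg.sim is not None else SimConfig(seed=_sub_seed(cfg.seed, 0))
    ped, gm, _ = simulate_cohort(sim)
    return ped, gm


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages; returns the report dict (also written to
    ``out_dir`` as JSON + TSVs)."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    report: dict = {"seed": cfg.seed}
    ped, gm = load_inputs(cfg)
    report["n_snps_input"] = gm.n_snps
    report["n_samples"] = len(gm.samples)

    if cfg.run_qc:
        gm, qc = qc_filter(gm, ped, cfg.call_rate_min, cfg.hwe_alpha)
        report["qc"] = {"removed_call_rate": qc.removed_call_rate,
                        "removed_hwe": qc.removed_hwe,
                        "removed_mendel": qc.removed_mendel,
                        "n_retained": qc.n_retained}

    families = extract_nuclear_families(ped, genotyped=set(gm.samples),
                                        min_children=cfg.min_children)
    report["n_nuclear_families"] = len(families)
    gm, removed = filter_family_missing(gm, families)
    report["family_missing_removed"] = removed
    report["n_snps_evaluated"] = gm.n_snps

    events, records = count_transmissions(
        families, gm, ped, window_bp=cfg.window_bp,
        unique_only=cfg.unique_only, reduced=cfg.reduced_families)
    events_to_bed(events, os.path.join(cfg.out_dir, "events.bed"))
    records.to_csv(os.path.join(cfg.out_dir, "records.tsv"), sep="\t",
                   index=False)
    maternal = records[records["parent_sex"] == "maternal"]
    paternal = records[records["parent_sex"] == "paternal"]
    report["n_events"] = int(len(events))
    report["n_transmissions"] = {"maternal": int(len(maternal)),
                                 "paternal": int(len(paternal))}
    report["mean_count"] = {
        "maternal": float(maternal["total_count"].mean()) if len(maternal) else None,
        "paternal": float(paternal["total_count"].mean()) if len(paternal) else None}

    if cfg.run_stats and len(maternal) >= 3:
        reg = age_stats.adjusted_regression(
            maternal["total_count"], maternal["age_at_birth"],
            maternal["parent_id"], n_perm=cfg.n_perm,
            seed=_sub_seed(cfg.seed, 1))
        mm = age_stats.mixed_model(
            maternal["total_count"], maternal["age_at_birth"],
            maternal["parent_id"], n_perm=min(cfg.n_perm, 200),
            seed=_sub_seed(cfg.seed, 2))
        f_var, p_var = age_stats.variation_among_parents(
            maternal["total_count"], maternal["parent_id"],
            n_perm=cfg.n_perm, seed=_sub_seed(cfg.seed, 3))
        cats = age_stats.age_category_tests(
            maternal["total_count"], maternal["age_at_birth"],
            n_perm=cfg.n_perm, seed=_sub_seed(cfg.seed, 4))
        report["stats"] = {
            "adjusted_regression": {k: v for k, v in reg.__dict__.items()},
            "mixed_model": {k: v for k, v in mm.__dict__.items()},
            "variation_among_mothers": {"F": f_var, "p": p_var},
            "age_categories": {k: (v if not isinstance(v, pd.DataFrame)
                                   else v.to_dict("records"))
                               for k, v in cats.items()}}

    if cfg.run_chrom and len(maternal) >= 3:
        shifts = chromosome_effects.all_shifts(
            maternal, cfg.age_threshold, n_perm=cfg.n_perm,
            seed=_sub_seed(cfg.seed, 5))
        shifts.to_csv(os.path.join(cfg.out_dir, "chromosome_shifts.tsv"),
                      sep="\t", index=False)
        nonsig = shifts[shifts["p_perm"] >= 0.05]
        report["chromosomes"] = {
            "n_significant": int((shifts["p_perm"] < 0.05).sum()),
            "sign_test_nonsignificant": age_stats.sign_test(
                int((nonsig["delta"] < 0).sum()), int(len(nonsig)))
            if len(nonsig) else None}

    if cfg.run_bins and len(events) and len(records):
        cen = genome_position.load_centromeres()
        sim_chroms = sorted(gm.markers["chrom"].unique())
        if cfg.sim is not None or cfg.bfile is None:
            # desk-scale simulated genomes: mid-chromosome centromeres
            cen = pd.DataFrame({
                "chrom": sim_chroms,
                "centromere_bp": [int(0.4 * c.length_bp)
                                  for c in (cfg.sim or SimConfig()).chromosomes],
                "length_bp": [c.length_bp
                              for c in (cfg.sim or SimConfig()).chromosomes]})
        binned = genome_position.bin_distribution(
            events, records, cen, width=cfg.bin_width,
            threshold=cfg.age_threshold, n_perm=min(cfg.n_perm, 200),
            seed=_sub_seed(cfg.seed, 6))
        binned.to_csv(os.path.join(cfg.out_dir, "arm_bins.tsv"), sep="\t",
                      index=False)
        report["bins_written"] = True

    with open(os.path.join(cfg.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    return report


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


def power_analysis(ped: Pedigree, gm: GenotypeMatrix,
                   thin_fractions=(0.8, 0.4, 0.3, 0.2, 0.05),
                   n_datasets_per_fraction: int = 4,
                   round_ages_flag: bool = False, window_bp: int = 1_000_000,
                   n_perm: int = 500, seed: int = 0) -> pd.DataFrame:
    """Effect of marker density (and optional age rounding) on the detected
    maternal age effect.

    For each thinning fraction x replicate: keep a random fraction of SNPs,
    re-call events, and re-estimate the family-adjusted regression.  With
    ``round_ages_flag`` the ages are coarsened (rounded up to 5-year
    multiples and differenced) and the categorical ANOVA is used, mirroring
    marker-sparse, age-approximate study designs.  Returns one row per
    condition with slope and p.
    """
    if not thin_fractions:
        raise ValueError("no thinning fractions given")
    families = extract_nuclear_families(ped, genotyped=set(gm.samples),
                                        min_children=2)
    rows = []
    ped_used = round_ages(ped) if round_ages_flag else ped
    for fi, fraction in enumerate(thin_fractions):
        for rep in range(n_datasets_per_fraction):
            sub_seed = _sub_seed(seed, 100 + fi * 10 + rep)
            gm_thin = thin_markers(gm, fraction, sub_seed)
            gm_thin, _ = filter_family_missing(gm_thin, families)
            _, records = count_transmissions(families, gm_thin, ped_used,
                                             window_bp=window_bp,
                                             reduced=False)
            mat = records[records["parent_sex"] == "maternal"]
            if len(mat) < 3:
                continue
            reg = age_stats.adjusted_regression(
                mat["total_count"], mat["age_at_birth"], mat["parent_id"],
                n_perm=n_perm, seed=sub_seed)
            row = {"fraction": fraction, "replicate": rep,
                   "n_snps": gm_thin.n_snps, "slope": reg.slope,
                   "p_perm": reg.p_perm,
                   "mean_count": float(mat["total_count"].mean())}
            if round_ages_flag:
                cats = age_stats.age_category_tests(
                    mat["total_count"], mat["age_at_birth"],
                    n_perm=n_perm, seed=sub_seed)
                row["anova_p"] = cats["anova_p"]
            rows.append(row)
    return pd.DataFrame(rows)


def bootstrap_families(records: pd.DataFrame, statistic_fn, n_boot: int = 1000,
                       seed: int = 0, ci: float = 0.95
                       ) -> tuple[float, float, float]:
    """Percentile bootstrap CI resampling whole families with replacement
    (respects within-family correlation).  Returns (estimate, lo, hi)."""
    fams = records["family_id"].unique()
    if len(fams) < 2:
        raise ValueError("bootstrap needs at least two families")
    rng = np.random.default_rng(seed)
    groups = {f: g for f, g in records.groupby("family_id")}
    est = float(statistic_fn(records))
    stats = np.empty(n_boot)
    for b in range(n_boot):
        draw = rng.choice(fams, size=len(fams), replace=True)
        stats[b] = statistic_fn(pd.concat([groups[f] for f in draw],
                                          ignore_index=True))
    alpha = (1.0 - ci) / 2
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return est, float(lo), float(hi)


def jackknife_families(records: pd.DataFrame, statistic_fn) -> pd.DataFrame:
    """Leave-one-family-out statistic values."""
    rows = []
    for f in records["family_id"].unique():
        rest = records[records["family_id"] != f]
        rows.append({"left_out": f, "statistic": float(statistic_fn(rest))})
    return pd.DataFrame(rows)
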