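"""Centromere-relative event positions, arm binning, and hotspot congruence.

Event locations are taken at the interval midpoint and rescaled along their
chromosomal arm: 0 at the centromere, 1 at the telomere of whichever arm
contains the midpoint.  Binned distributions of events per transmission
along this [0, 1] axis expose where on the arms an age effect acts.
Hotspot congruence asks what fraction of tightly-localized events (interval
narrower than 30 kb) intersect population-inferred hotspot intervals,
against the chance expectation for a uniformly placed interval of the same
length (interval-dilation argument, capped at 1, edge effects ignored).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
import scipy.stats


def load_centromeres(path: str | None = None) -> pd.DataFrame:
    """Centromere/length table: columns ``chrom, centromere_bp, length_bp``.

    The packaged default is an approximate NCBI36-era autosome table;
    supply ``path`` to override.
    """
    if path is None:
        ref = resources.files("pedrecomb.data").joinpath("centromeres_ncbi36.tsv")
        with resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t")
    return pd.read_csv(path, sep="\t")


def _arm_table(centromeres: pd.DataFrame) -> dict[int, tuple[float, float]]:
    bad = centromeres[(centromeres["centromere_bp"] <= 0)
                      | (centromeres["centromere_bp"] >= centromeres["length_bp"])]
    if len(bad):
        raise ValueError(f"centromere outside (0, length) for {list(bad['chrom'])}")
    return {int(r.chrom): (float(r.centromere_bp), float(r.length_bp))
            for r in centromeres.itertuples()}


def relative_positions(events: pd.DataFrame,
                       centromeres: pd.DataFrame) -> pd.Series:
    """Midpoint position of each event on the [0, 1] centromere-telomere
    axis of its arm.  Events whose interval spans the centromere are
    assigned by midpoint (a warning-worthy but rare situation at these
    interval sizes)."""
    arms = _arm_table(centromeres)
    out = np.empty(len(events), dtype=float)
    for i, r in enumerate(events.itertuples()):
        if r.chrom not in arms:
            raise KeyError(f"chromosome {r.chrom} not in centromere table")
        cen, length = arms[r.chrom]
        mid = 0.5 * (r.left_bp + r.right_bp)
        arm_len = cen if mid <= cen else length - cen
        out[i] = abs(mid - cen) / arm_len
    return pd.Series(np.clip(out, 0.0, 1.0), index=events.index,
                     name="relative_position")


def bin_distribution(events: pd.DataFrame, records: pd.DataFrame,
                     centromeres: pd.DataFrame, width: float = 0.05,
                     threshold: float = 30.0, n_perm: int = 1000,
                     seed: int = 0) -> pd.DataFrame:
    """Mean events per transmission in relative-distance bins, by parent sex
    and age group, with per-bin under/over-threshold shift tests.

    Returns one row per (parent_sex, bin): the young/old group means, the
    shift, and a label-permutation p (one-sided for a decrease).  Bin index
    is floor(position / width); position 1.0 closes into the last bin.
    """
    if width not in (0.05, 0.1):
        import warnings
        warnings.warn(f"non-standard bin width {width}")
    n_bins = int(round(1.0 / width))
    ev = events[events["assigned"]].copy()
    ev["relpos"] = relative_positions(ev, centromeres)
    ev["bin"] = np.minimum((ev["relpos"] / width).astype(int), n_bins - 1)

    ages = {(r.parent_id, r.child_id): r.age_at_birth
            for r in records.itertuples()}
    ev["age_at_birth"] = [ages.get((p, c), np.nan)
                          for p, c in zip(ev["parent_id"], ev["child_id"])]
    ev = ev.dropna(subset=["age_at_birth"])

    rng = np.random.default_rng(seed)
    rows = []
    for sex in ("maternal", "paternal"):
        recs = records[records["parent_sex"] == sex]
        n_trans = recs.groupby(recs["age_at_birth"] >= threshold).size()
        n_young = int(n_trans.get(False, 0))
        n_old = int(n_trans.get(True, 0))
        sub = ev[ev["parent_sex"] == sex]
        # per-transmission bin counts for the permutation test
        key = recs[["parent_id", "child_id", "age_at_birth"]].copy()
        counts = np.zeros((len(key), n_bins))
        index = {(p, c): i for i, (p, c) in
                 enumerate(zip(key["parent_id"], key["child_id"]))}
        for r in sub.itertuples():
            i = index.get((r.parent_id, r.child_id))
            if i is not None:
                counts[i, r.bin] += 1
        old = key["age_at_birth"].to_numpy() >= threshold
        for b in range(n_bins):
            young_mean = counts[~old, b].mean() if n_young else np.nan
            old_mean = counts[old, b].mean() if n_old else np.nan
            delta_obs = old_mean - young_mean
            cnt = 0
            for _ in range(n_perm):
                perm = rng.permutation(old)
                delta = counts[perm, b].mean() - counts[~perm, b].mean()
                cnt += delta <= delta_obs + 1e-12
            rows.append({"parent_sex": sex, "bin": b,
                         "bin_low": b * width, "bin_high": (b + 1) * width,
                         "mean_young": young_mean, "mean_old": old_mean,
                         "delta": delta_obs,
                         "p_perm": (cnt + 1) / (n_perm + 1),
                         "n_young": n_young, "n_old": n_old})
    return pd.DataFrame(rows)


def distance_count_correlation(binned: pd.DataFrame, n_perm: int = 10000,
                               seed: int = 0) -> tuple[float, float]:
    """Pearson correlation between bin midpoint distance and mean events per
    transmission, p by permuting counts across bins."""
    if len(binned) < 3:
        raise ValueError("need at least 3 bins")
    x = ((binned["bin_low"] + binned["bin_high"]) / 2).to_numpy()
    counts = binned[["mean_young", "mean_old"]].mean(axis=1).to_numpy() \
        if "mean_young" in binned else binned["mean"].to_numpy()
    r_obs = scipy.stats.pearsonr(x, counts).statistic
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        r = scipy.stats.pearsonr(x, rng.permutation(counts)).statistic
        b += abs(r) >= abs(r_obs) - 1e-12
    return float(r_obs), (b + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# hotspots
# ---------------------------------------------------------------------------

def read_hotspots_bed(path: str) -> pd.DataFrame:
    """BED3 (0-based half-open) -> 1-based closed intervals, merged."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      names=["chrom", "start", "end"], usecols=[0, 1, 2])
    bed["chrom"] = (bed["chrom"].astype(str).str.replace("chr", "", regex=False)
                    .astype(int))
    bed["left_bp"] = bed["start"] + 1
    bed["right_bp"] = bed["end"]
    return merge_hotspots(bed[["chrom", "left_bp", "right_bp"]])


def merge_hotspots(hotspots: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent closed intervals per chromosome."""
    out = []
    for chrom, grp in hotspots.groupby("chrom"):
        iv = grp.sort_values("left_bp")[["left_bp", "right_bp"]].to_numpy()
        merged = [iv[0].tolist()]
        for left, right in iv[1:]:
            if left <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], right)
            else:
                merged.append([left, right])
        for left, right in merged:
            out.append({"chrom": chrom, "left_bp": left, "right_bp": right})
    return pd.DataFrame(out, columns=["chrom", "left_bp", "right_bp"])


def hotspot_overlap(events: pd.DataFrame, hotspots: pd.DataFrame,
                    chrom_lengths: dict[int, float],
                    max_interval_bp: int = 30_000) -> tuple[float, float, int]:
    """Observed vs chance hotspot overlap for tightly localized events.

    Only events with interval width < ``max_interval_bp`` enter.  Observed:
    fraction whose closed interval intersects at least one (merged) hotspot.
    Expected: mean over events of min(1, sum_h (hotspot_len + event_len) /
    chrom_len) — the probability that a uniformly placed interval of the
    same length hits a hotspot.  Returns (observed, expected, n_events).
    """
    ev = events[(events["right_bp"] - events["left_bp"]) < max_interval_bp]
    if len(ev) == 0:
        return np.nan, np.nan, 0
    hs_by_chrom = {c: grp[["left_bp", "right_bp"]].to_numpy()
                   for c, grp in hotspots.groupby("chrom")} if len(hotspots) else {}
    n_overlap = 0
    expected = np.empty(len(ev))
    for i, r in enumerate(ev.itertuples()):
        iv = hs_by_chrom.get(r.chrom)
        ev_len = r.right_bp - r.left_bp
        if iv is None or len(iv) == 0:
            expected[i] = 0.0
            continue
        hit = ((iv[:, 0] <= r.right_bp) & (iv[:, 1] >= r.left_bp)).any()
        n_overlap += hit
        hs_len = (iv[:, 1] - iv[:, 0] + 1).sum()
        expected[i] = min(1.0, (hs_len + len(iv) * ev_len)
                          / chrom_lengths[r.chrom])
    return n_overlap / len(ev), float(expected.mean()), int(len(ev))


def hotspot_usage_by_group(events: pd.DataFrame, records: pd.DataFrame,
                           hotspots: pd.DataFrame,
                           centromeres: pd.DataFrame,
                           max_interval_bp: int = 30_000,
                           threshold: float = 30.0, width: float = 0.1,
                           n_perm: int = 1000, seed: int = 0) -> dict:
    """Hotspot overlap per age group plus a permutation test for a
    difference in where (along arms) hotspot-overlapping events sit.

    The statistic is the total variation distance between the two groups'
    binned relative-position distributions of hotspot events; the null
    permutes age-group labels across events.
    """
    lengths = dict(zip(centromeres["chrom"].astype(int),
                       centromeres["length_bp"].astype(float)))
    ages = {(r.parent_id, r.child_id): r.age_at_birth
            for r in records.itertuples()}
    ev = events[(events["right_bp"] - events["left_bp"]) < max_interval_bp].copy()
    ev["age_at_birth"] = [ages.get((p, c), np.nan)
                          for p, c in zip(ev["parent_id"], ev["child_id"])]
    ev = ev.dropna(subset=["age_at_birth"]).reset_index(drop=True)
    old = ev["age_at_birth"].to_numpy() >= threshold

    fractions = {}
    for label, sel in (("young", ~old), ("old", old)):
        obs, exp, n = hotspot_overlap(ev[sel], hotspots, lengths,
                                      max_interval_bp)
        fractions[label] = {"observed": obs, "expected": exp, "n": n}

    # arm positions of hotspot-overlapping events
    hs_by_chrom = {c: grp[["left_bp", "right_bp"]].to_numpy()
                   for c, grp in hotspots.groupby("chrom")} if len(hotspots) else {}
    hits = np.zeros(len(ev), dtype=bool)
    for i, r in enumerate(ev.itertuples()):
        iv = hs_by_chrom.get(r.chrom)
        if iv is not None and len(iv):
            hits[i] = ((iv[:, 0] <= r.right_bp) & (iv[:, 1] >= r.left_bp)).any()
    hot = ev[hits].copy()
    hot_old = old[hits]
    if len(hot) == 0 or hot_old.all() or not hot_old.any():
        return {"fractions": fractions, "position_p": np.nan}
    relpos = relative_positions(hot, centromeres).to_numpy()
    n_bins = int(round(1.0 / width))
    bins = np.minimum((relpos / width).astype(int), n_bins - 1)

    def tv(labels: np.ndarray) -> float:
        a = np.bincount(bins[labels], minlength=n_bins) / max(1, labels.sum())
        b = np.bincount(bins[~labels], minlength=n_bins) / max(1, (~labels).sum())
        return 0.5 * np.abs(a - b).sum()

    obs_tv = tv(hot_old)
    rng = np.random.default_rng(seed)
    b = sum(tv(rng.permutation(hot_old)) >= obs_tv - 1e-12
            for _ in range(n_perm))
    return {"fractions": fractions, "position_statistic": float(obs_tv),
            "position_p": (b + 1) / (n_perm + 1)}
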