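"""Crossover localization in nuclear families by sibling-comparison phasing.

At an *informative* marker one parent is heterozygous and the other
homozygous, so the allele the heterozygous parent transmitted to each child
is unambiguous.  Along a chromosome, each child's transmitted alleles are
compared with a reference sibling's: runs of agreement/disagreement define
which parental haplotype (H1/H2) the child carries, and a state switch
between adjacent informative markers is a crossover in that parental
meiosis, localized to the flanking-marker interval.

Three refinements on top of the basic heuristic:

* tight double recombinants (a single marker whose state disagrees with both
  neighbours within a 1 Mb span) are treated as genotyping artifacts and the
  offending *marker* is removed before calling;
* events appearing in two or more children of a family at the same interval
  are discarded ("unique events only") in families of every size;
* because unique-only counting biases large families downward, families of
  four or more children are partitioned into all 3-child subsets ("reduced
  families") and per-child counts averaged over the subsets containing the
  child.

With two children a switch cannot be assigned to a specific child (the
reference sibling may equally well carry the crossover), so 2-child families
contribute pair-level events flagged ``assigned=False`` and no per-child
counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .pedio import GenotypeMatrix, NuclearFamily, Pedigree

EVENT_COLUMNS = ["family_id", "parent_id", "child_id", "parent_sex", "chrom",
                 "left_bp", "right_bp", "n_children_sharing", "assigned"]


@dataclass
class InformativeTrack:
    """Phased inheritance states of all children over one chromosome's
    informative markers for one parent.

    ``states[j, i]`` is 0 (H1) or 1 (H2): which haplotype of ``parent_id``
    child ``j`` carries at informative marker ``i``.  Child 0 is the phase
    reference.  ``assignable`` is False for 2-child families.
    """

    family: NuclearFamily
    parent_id: str
    parent_sex: str  # "maternal" | "paternal"
    chromosome: int
    positions: np.ndarray
    states: np.ndarray
    removed_positions: tuple[int, ...] = ()

    @property
    def assignable(self) -> bool:
        return self.states.shape[0] >= 3


def find_informative_markers(family: NuclearFamily, parent_id: str,
                             gm: GenotypeMatrix) -> dict[int, np.ndarray]:
    """Per-chromosome indices of markers informative for ``parent_id``.

    Informative: parent heterozygous, co-parent homozygous, every child
    called and Mendelian-consistent with the homozygous co-parent.
    """
    co_parent = family.mother_id if parent_id == family.father_id else family.father_id
    p = gm.col(parent_id)
    q = gm.col(co_parent)
    kids = gm.calls[:, gm.sample_indices(family.child_ids)]
    ok = (p == 1) & ((q == 0) | (q == 2))
    # children must carry the co-parent's obligate allele and not be missing
    lo = (q // 2).astype(np.int8)  # transmitted co-parent allele count
    ok &= ((kids >= lo[:, None]) & (kids <= lo[:, None] + 1)).all(axis=1)
    chrom = gm.markers["chrom"].to_numpy()
    return {int(c): np.nonzero(ok & (chrom == c))[0]
            for c in np.unique(chrom) if (ok & (chrom == c)).any()}


def phase_family(family: NuclearFamily, parent_id: str,
                 gm: GenotypeMatrix) -> list[InformativeTrack]:
    """Phase all children against the first child; one track per chromosome.

    The reference child starts in state H1.  With three or more children, a
    simultaneous switch in *all* non-reference children at one inter-marker
    interval is re-attributed to the reference child: its state toggles
    there and the others' apparent switches are removed.
    """
    if family.n_children < 2:
        raise ValueError("phasing requires at least two children")
    parent_sex = "maternal" if parent_id == family.mother_id else "paternal"
    co_parent = family.mother_id if parent_sex == "paternal" else family.father_id
    lo = (gm.col(co_parent) // 2).astype(np.int8)
    kids = gm.calls[:, gm.sample_indices(family.child_ids)]
    transmitted = (kids - lo[:, None]).astype(np.int8)  # allele from het parent

    tracks = []
    pos_all = gm.markers["pos"].to_numpy()
    for chrom, idx in find_informative_markers(family, parent_id, gm).items():
        t = transmitted[idx].T  # (n_children, M)
        s = (t ^ t[0]).astype(np.int8)  # relative to reference child
        if family.n_children >= 3 and t.shape[1] >= 2:
            toggles = s[1:, 1:] != s[1:, :-1]
            all_switch = toggles.all(axis=0)
            rseq = np.concatenate([[0], np.cumsum(all_switch) % 2]).astype(np.int8)
            states = s ^ rseq
        else:
            states = s
        tracks.append(InformativeTrack(family, parent_id, parent_sex, chrom,
                                       pos_all[idx], states))
    return tracks


def pretreat_double_recombinants(track: InformativeTrack,
                                 window_bp: int = 1_000_000) -> InformativeTrack:
    """Remove single-marker state blips implying a double crossover within
    ``window_bp``; left-to-right, repeated to a fixpoint.

    A marker is removed (for all children) when some child's state there
    differs from its state at both flanking informative markers and those
    flanking markers are less than ``window_bp`` apart.
    """
    pos = track.positions.copy()
    states = track.states.copy()
    removed: list[int] = []
    while True:
        if states.shape[1] < 3:
            break
        mid = states[:, 1:-1]
        blip = ((states[:, :-2] == states[:, 2:]) & (mid != states[:, :-2])).any(axis=0)
        tight = (pos[2:] - pos[:-2]) < window_bp
        hits = np.nonzero(blip & tight)[0]
        if hits.size == 0:
            break
        i = int(hits[0]) + 1  # leftmost offending marker
        removed.append(int(pos[i]))
        pos = np.delete(pos, i)
        states = np.delete(states, i, axis=1)
    return replace(track, positions=pos, states=states,
                   removed_positions=track.removed_positions + tuple(removed))


def call_events(track: InformativeTrack) -> pd.DataFrame:
    """One event per state switch per child, with flanking-marker interval.

    ``n_children_sharing`` counts children of the family switching in the
    same inter-marker interval for the same parent.
    """
    fam = track.family
    switches = track.states[:, 1:] != track.states[:, :-1]
    sharing = switches.sum(axis=0)
    rows = []
    for j, child in enumerate(fam.child_ids):
        for i in np.nonzero(switches[j])[0]:
            rows.append((fam.father_id + "+" + fam.mother_id, track.parent_id,
                         child, track.parent_sex, track.chromosome,
                         int(track.positions[i]), int(track.positions[i + 1]),
                         int(sharing[i]), track.assignable))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def deduplicate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Keep only unique events: those seen in exactly one child of the family
    at a given inter-marker interval (shared ones are likely artifacts or
    phase errors and are removed entirely)."""
    if events.empty:
        return events
    return events[events["n_children_sharing"] < 2].reset_index(drop=True)


def call_family(family: NuclearFamily, gm: GenotypeMatrix,
                window_bp: int = 1_000_000, unique_only: bool = True,
                pretreat: bool = True) -> pd.DataFrame:
    """Full caller for one family, both parents: phase, pre-treat, call,
    deduplicate.  Returns the event table (possibly empty)."""
    frames = []
    for parent_id in (family.mother_id, family.father_id):
        for track in phase_family(family, parent_id, gm):
            if pretreat:
                track = pretreat_double_recombinants(track, window_bp)
            ev = call_events(track)
            if unique_only:
                ev = deduplicate_events(ev)
            frames.append(ev)
    if not frames:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def reduced_family_counts(family: NuclearFamily, parent_id: str,
                          gm: GenotypeMatrix, window_bp: int = 1_000_000,
                          pretreat: bool = True) -> dict[str, float]:
    """Unbiased per-child genome-wide counts for families of >= 4 children.

    Every 3-child subset is re-called independently (phase, pre-treat, call,
    deduplicate within the subset); a child's unbiased count is the mean of
    its counts over the C(n-1, 2) subsets containing it.  Families with
    fewer than 4 children pass through with their standard counts.
    """
    if family.n_children < 4:
        ev = call_family(family, gm, window_bp, pretreat=pretreat)
        ev = ev[(ev["parent_id"] == parent_id) & ev["assigned"]]
        return {c: float((ev["child_id"] == c).sum()) for c in family.child_ids}
    sums = {c: 0.0 for c in family.child_ids}
    n_sub = {c: 0 for c in family.child_ids}
    for subset in itertools.combinations(family.child_ids, 3):
        sub = NuclearFamily(family.father_id, family.mother_id, subset)
        ev = call_family(sub, gm, window_bp, pretreat=pretreat)
        ev = ev[ev["parent_id"] == parent_id]
        for c in subset:
            sums[c] += float((ev["child_id"] == c).sum())
            n_sub[c] += 1
    return {c: sums[c] / n_sub[c] for c in family.child_ids}


def count_transmissions(families: list[NuclearFamily], gm: GenotypeMatrix,
                        ped: Pedigree, window_bp: int = 1_000_000,
                        unique_only: bool = True, pretreat: bool = True,
                        reduced: bool = True, require_ages: bool = True,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call the whole cohort; returns (events, transmission records).

    Events come from every family with >= 2 children.  Per-child records
    (one per parent-child transmission) require >= 3 children, since with
    two children events cannot be assigned to a child; 2-child families'
    events carry ``assigned=False``.  Records hold the genome-wide total,
    per-chromosome counts (``chr<k>`` columns), the unbiased reduced-family
    count, and the parent's age at the child's birth.
    """
    chroms = sorted(gm.markers["chrom"].unique())
    event_frames, records = [], []
    for family in families:
        ev = call_family(family, gm, window_bp, unique_only=unique_only,
                         pretreat=pretreat)
        event_frames.append(ev)
        if family.n_children < 3:
            continue
        for parent_id in (family.mother_id, family.father_id):
            parent_sex = ("maternal" if parent_id == family.mother_id
                          else "paternal")
            pe = ev[(ev["parent_id"] == parent_id)]
            unbiased = (reduced_family_counts(family, parent_id, gm, window_bp,
                                              pretreat=pretreat)
                        if reduced and family.n_children >= 4 else None)
            for child in family.child_ids:
                ce = pe[pe["child_id"] == child]
                per_chrom = {f"chr{c}": int((ce["chrom"] == c).sum())
                             for c in chroms}
                total = int(len(ce))
                if require_ages:
                    try:
                        age = ped.age_at_birth(parent_id, child)
                    except KeyError as exc:
                        raise KeyError(str(exc)) from None
                else:
                    age = ped.parental_ages.get((parent_id, child), np.nan)
                records.append({
                    "family_id": family.father_id + "+" + family.mother_id,
                    "parent_id": parent_id, "child_id": child,
                    "parent_sex": parent_sex, "age_at_birth": age,
                    "total_count": total,
                    "unbiased_count": (unbiased[child] if unbiased is not None
                                       else float(total)),
                    **per_chrom})
    events = (pd.concat(event_frames, ignore_index=True) if event_frames
              else pd.DataFrame(columns=EVENT_COLUMNS))
    rec_cols = ["family_id", "parent_id", "child_id", "parent_sex",
                "age_at_birth", "total_count", "unbiased_count",
                *[f"chr{c}" for c in chroms]]
    records_df = pd.DataFrame(records, columns=rec_cols)
    return events, records_df


def events_to_bed(events: pd.DataFrame, path: str) -> None:
    """Write events as BED6-like lines: chrom, 0-based half-open interval,
    parent:child, n_children_sharing, parent_sex."""
    out = pd.DataFrame({
        "chrom": events["chrom"],
        "start": events["left_bp"] - 1,
        "end": events["right_bp"],
        "name": events["parent_id"] + ":" + events["child_id"],
        "score": events["n_children_sharing"],
        "parent_sex": events["parent_sex"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)
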