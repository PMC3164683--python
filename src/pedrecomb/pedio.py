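"""Pedigree genotype I/O, structure, and SNP quality control.

Genotypes live in a :class:`GenotypeMatrix`: one int8 call per (SNP,
individual) counting copies of ``allele_b`` (0, 1, 2), with :data:`MISSING`
(-1) as the missing sentinel.  Files are read and written in the PLINK v1
binary triplet (bed/bim/fam, SNP-major).  Coordinates are 1-based as in BIM;
intervals elsewhere in the package are closed ``[left_bp, right_bp]``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.int8(-1)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit bed codes -> dosage of allele_b; 0b01 is missing
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_BED_ENCODE = {0: 0b00, 1: 0b10, 2: 0b11, int(MISSING): 0b01}


class PlinkFormatError(ValueError):
    """Malformed PLINK file (bad magic bytes, truncated bed, ...)."""


class ConsistencyError(ValueError):
    """Dimensions of bed/bim/fam disagree, or pedigree links are invalid."""


@dataclass
class GenotypeMatrix:
    """SNP x individual genotype calls plus the marker map.

    ``markers`` is a DataFrame with columns ``snp_id, chrom, pos, allele_a,
    allele_b`` (autosomes only, positions sorted within chromosome);
    ``calls[i, j]`` is the allele_b dosage of sample ``j`` at SNP ``i``.
    """

    markers: pd.DataFrame
    samples: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.markers), len(self.samples)):
            raise ConsistencyError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.markers)} SNPs, {len(self.samples)} samples)"
            )
        self._sample_index = {s: j for j, s in enumerate(self.samples)}

    def col(self, sample_id: str) -> np.ndarray:
        return self.calls[:, self._sample_index[sample_id]]

    def sample_indices(self, ids) -> np.ndarray:
        return np.array([self._sample_index[s] for s in ids])

    @property
    def n_snps(self) -> int:
        return len(self.markers)

    def take_snps(self, mask_or_index) -> "GenotypeMatrix":
        """New matrix restricted to the given SNP boolean mask / index."""
        m = self.markers.iloc[mask_or_index].reset_index(drop=True) \
            if not (isinstance(mask_or_index, np.ndarray) and mask_or_index.dtype == bool) \
            else self.markers.loc[mask_or_index].reset_index(drop=True)
        return GenotypeMatrix(m, list(self.samples), self.calls[mask_or_index])


@dataclass
class Pedigree:
    """Individuals with parent links, plus optional age information.

    ``individuals``: DataFrame with columns ``fid, iid, father, mother, sex,
    affected`` (sex 1=male, 2=female; '0' marks a missing parent).
    ``parental_ages`` maps (parent_id, child_id) -> age of that parent at the
    child's birth, in years (fractional allowed).  ``current_ages`` maps
    individual -> age at sampling time, used only by the age-rounding
    power analysis.
    """

    individuals: pd.DataFrame
    parental_ages: dict[tuple[str, str], float] = field(default_factory=dict)
    current_ages: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ind = self.individuals
        self._row = {iid: i for i, iid in enumerate(ind["iid"])}
        sex = dict(zip(ind["iid"], ind["sex"]))
        for _, r in ind.iterrows():
            if r["father"] in sex and sex[r["father"]] == 2:
                raise ConsistencyError(f"father {r['father']} has female sex code")
            if r["mother"] in sex and sex[r["mother"]] == 1:
                raise ConsistencyError(f"mother {r['mother']} has male sex code")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parents = {
            r["iid"]: {p for p in (r["father"], r["mother"]) if p != "0"}
            for _, r in self.individuals.iterrows()
        }
        state: dict[str, int] = {}

        def visit(i: str) -> None:
            state[i] = 1
            for p in parents.get(i, ()):
                if state.get(p) == 1:
                    raise ConsistencyError(f"pedigree cycle through {i}")
                if state.get(p) is None:
                    visit(p)
            state[i] = 2

        for i in parents:
            if state.get(i) is None:
                visit(i)

    def family_of(self, iid: str) -> str:
        return self.individuals.iloc[self._row[iid]]["fid"]

    def age_at_birth(self, parent_id: str, child_id: str) -> float:
        try:
            return self.parental_ages[(parent_id, child_id)]
        except KeyError:
            raise KeyError(
                f"no parental age recorded for parent={parent_id} child={child_id}"
            ) from None


@dataclass(frozen=True)
class NuclearFamily:
    """A (father, mother) couple and their ordered children."""

    father_id: str
    mother_id: str
    child_ids: tuple[str, ...]

    @property
    def n_children(self) -> int:
        return len(self.child_ids)

    def members(self) -> tuple[str, ...]:
        return (self.father_id, self.mother_id) + self.child_ids


# ---------------------------------------------------------------------------
# PLINK binary triplet
# ---------------------------------------------------------------------------

def _pack_codes(codes: np.ndarray) -> bytes:
    """Pack one SNP row of 2-bit codes (n_samples,) into bed bytes."""
    n = len(codes)
    padded = np.zeros(-(-n // 4) * 4, dtype=np.uint8)
    padded[:n] = codes
    quads = padded.reshape(-1, 4)
    byte = quads[:, 0] | (quads[:, 1] << 2) | (quads[:, 2] << 4) | (quads[:, 3] << 6)
    return byte.astype(np.uint8).tobytes()


def write_plink(ped: Pedigree, gm: GenotypeMatrix, prefix: str) -> None:
    """Write bed/bim/fam under ``prefix`` (SNP-major, v1 magic)."""
    ind = ped.individuals.set_index("iid").loc[gm.samples].reset_index()
    fam = ind[["fid", "iid", "father", "mother", "sex", "affected"]]
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)
    bim = gm.markers.assign(cm=0)[["chrom", "snp_id", "cm", "pos", "allele_a", "allele_b"]]
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)

    encode = np.zeros(4, dtype=np.uint8)
    for dosage, code in _BED_ENCODE.items():
        encode[dosage] = code  # index -1 wraps to the last slot for MISSING
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        for i in range(gm.n_snps):
            fh.write(_pack_codes(encode[gm.calls[i]]))


def read_plink(prefix_or_bed: str, bim_path: str | None = None,
               fam_path: str | None = None) -> tuple[Pedigree, GenotypeMatrix]:
    """Read a PLINK binary triplet.

    Accepts either a common prefix or explicit bed/bim/fam paths.
    Non-autosomal SNPs (chromosome outside 1..22) are dropped with a logged
    count.  Raises :class:`PlinkFormatError` on bad magic bytes and
    :class:`ConsistencyError` if the bed size disagrees with bim x fam.
    """
    if bim_path is None:
        bed_path = prefix_or_bed + ".bed"
        bim_path = prefix_or_bed + ".bim"
        fam_path = prefix_or_bed + ".fam"
    else:
        bed_path = prefix_or_bed

    fam = pd.read_csv(fam_path, sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "affected"],
                      dtype=str)
    fam["sex"] = fam["sex"].astype(int)
    fam["affected"] = pd.to_numeric(fam["affected"], errors="coerce").fillna(0).astype(int)
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None,
                      names=["chrom", "snp_id", "cm", "pos", "allele_a", "allele_b"],
                      dtype={"snp_id": str, "allele_a": str, "allele_b": str})
    bim["chrom"] = pd.to_numeric(bim["chrom"], errors="coerce").fillna(0).astype(int)

    n_samples, n_snps = len(fam), len(bim)
    with open(bed_path, "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise PlinkFormatError(f"bad bed magic bytes {magic!r} in {bed_path}")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_snp = -(-n_samples // 4)
    if raw.size != n_snps * bytes_per_snp:
        raise ConsistencyError(
            f"bed payload {raw.size} bytes, expected {n_snps}x{bytes_per_snp}"
        )
    quads = raw.reshape(n_snps, bytes_per_snp)
    codes = np.empty((n_snps, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (quads >> (2 * k)) & 0b11
    calls = _BED_DECODE[codes[:, :n_samples]]

    autosomal = bim["chrom"].between(1, 22).to_numpy()
    n_dropped = int((~autosomal).sum())
    if n_dropped:
        logger.info("dropping %d non-autosomal SNPs", n_dropped)
    markers = bim.loc[autosomal, ["snp_id", "chrom", "pos", "allele_a", "allele_b"]]
    markers = markers.reset_index(drop=True)
    if markers["snp_id"].duplicated().any():
        raise ConsistencyError("duplicate SNP ids in bim")

    gm = GenotypeMatrix(markers, list(fam["iid"]), calls[autosomal])
    ped = Pedigree(fam[["fid", "iid", "father", "mother", "sex", "affected"]].copy())
    return ped, gm


def read_ages(path: str) -> dict[tuple[str, str], float]:
    """Read a headered ages TSV: family_id, parent_id, child_id, age_at_birth."""
    df = pd.read_csv(path, sep="\t", dtype={"parent_id": str, "child_id": str})
    return {(r.parent_id, r.child_id): float(r.age_at_birth) for r in df.itertuples()}


def write_ages(ped: Pedigree, path: str) -> None:
    rows = [
        {"family_id": ped.family_of(c), "parent_id": p, "child_id": c,
         "age_at_birth": age}
        for (p, c), age in sorted(ped.parental_ages.items())
    ]
    pd.DataFrame(rows, columns=["family_id", "parent_id", "child_id",
                                "age_at_birth"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_het: int, n_hom_a: int, n_hom_b: int) -> float:
    """Exact Hardy-Weinberg test p-value (Wigginton et al. style).

    Sums the probabilities, under HWE with the observed allele counts fixed,
    of all heterozygote counts no more probable than the observed one.
    """
    n = n_het + n_hom_a + n_hom_b
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_a, n_hom_b) + n_het
    # possible het counts share the parity of n_rare
    het_values = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    # unnormalized probabilities via the recurrence
    # P(h+2)/P(h) = (n_rare-h)(2n-n_rare-h) / ((h+2)(h+1))
    probs = np.empty(len(het_values), dtype=float)
    probs[0] = 1.0
    for i in range(len(het_values) - 1):
        h = het_values[i]
        probs[i + 1] = probs[i] * (n_rare - h) * (2 * n - n_rare - h) / ((h + 2) * (h + 1))
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(het_values, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# allowed child dosages for (father, mother) dosage pairs
_MENDEL_OK = np.zeros((3, 3, 3), dtype=bool)
for _f, _m in itertools.product(range(3), range(3)):
    tf = {0: (0,), 1: (0, 1), 2: (1,)}[_f]
    tm = {0: (0,), 1: (0, 1), 2: (1,)}[_m]
    for _a, _b in itertools.product(tf, tm):
        _MENDEL_OK[_f, _m, _a + _b] = True


def mendel_inconsistencies(gm: GenotypeMatrix, ped: Pedigree) -> pd.DataFrame:
    """Per-trio Mendelian errors: DataFrame (snp_index, child) of violations.

    Trios with any missing member call at a SNP are not checkable there.
    """
    rows = []
    for _, r in ped.individuals.iterrows():
        if r["father"] == "0" or r["mother"] == "0":
            continue
        if not all(x in gm._sample_index for x in (r["iid"], r["father"], r["mother"])):
            continue
        c, f, m = gm.col(r["iid"]), gm.col(r["father"]), gm.col(r["mother"])
        ok = np.ones(gm.n_snps, dtype=bool)
        known = (c >= 0) & (f >= 0) & (m >= 0)
        ok[known] = _MENDEL_OK[f[known], m[known], c[known]]
        for i in np.nonzero(~ok)[0]:
            rows.append((int(i), r["iid"]))
    return pd.DataFrame(rows, columns=["snp_index", "child"])


@dataclass
class QCReport:
    n_input: int
    removed_call_rate: int = 0
    removed_hwe: int = 0
    removed_mendel: int = 0
    cells_set_missing: int = 0

    @property
    def n_retained(self) -> int:
        return (self.n_input - self.removed_call_rate - self.removed_hwe
                - self.removed_mendel)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__ | {"n_retained": self.n_retained}])


def founder_mask(ped: Pedigree, samples: list[str]) -> np.ndarray:
    ind = ped.individuals.set_index("iid")
    return np.array([
        ind.loc[s, "father"] == "0" and ind.loc[s, "mother"] == "0"
        for s in samples
    ])


def qc_filter(gm: GenotypeMatrix, ped: Pedigree, call_rate_min: float = 0.95,
              hwe_alpha: float = 0.01, drop_mendelian_errors: bool = True,
              max_mendel_families: int = 1) -> tuple[GenotypeMatrix, QCReport]:
    """Standard SNP QC: call rate, founder HWE, Mendelian errors.

    SNPs with call rate below ``call_rate_min`` or founder HWE exact p below
    ``hwe_alpha`` are removed.  Mendelian-inconsistent trio genotypes are set
    to missing (all three members), and SNPs with inconsistencies in more
    than ``max_mendel_families`` families are removed.
    """
    if not (0 < call_rate_min < 1) or not (0 < hwe_alpha < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    report = QCReport(n_input=gm.n_snps)

    call_rate = (gm.calls >= 0).mean(axis=1)
    keep = call_rate >= call_rate_min
    report.removed_call_rate = int((~keep).sum())

    founders = founder_mask(ped, gm.samples)
    fc = gm.calls[:, founders]
    n_het = (fc == 1).sum(axis=1)
    n_a = (fc == 0).sum(axis=1)
    n_b = (fc == 2).sum(axis=1)
    hwe_p = np.array([hwe_exact_pvalue(h, a, b) for h, a, b in zip(n_het, n_a, n_b)])
    hwe_fail = (hwe_p < hwe_alpha) & keep
    report.removed_hwe = int(hwe_fail.sum())
    keep &= ~hwe_fail

    calls = gm.calls.copy()
    if drop_mendelian_errors:
        errors = mendel_inconsistencies(gm, ped)
        if len(errors):
            ind = ped.individuals.set_index("iid")
            fam_of_child = dict(zip(ped.individuals["iid"], ped.individuals["fid"]))
            errors = errors.assign(fid=[fam_of_child[c] for c in errors["child"]])
            for snp_i, grp in errors.groupby("snp_index"):
                for child in grp["child"]:
                    trio = [child, ind.loc[child, "father"], ind.loc[child, "mother"]]
                    cols = gm.sample_indices(trio)
                    report.cells_set_missing += int((calls[snp_i, cols] >= 0).sum())
                    calls[snp_i, cols] = MISSING
                if grp["fid"].nunique() > max_mendel_families and keep[snp_i]:
                    keep[snp_i] = False
                    report.removed_mendel += 1

    if not keep.any():
        raise ValueError("no SNPs survive QC filtering")
    out = GenotypeMatrix(gm.markers.loc[keep].reset_index(drop=True),
                         list(gm.samples), calls[keep])
    logger.info("QC: %d -> %d SNPs (call rate %d, HWE %d, Mendel %d)",
                report.n_input, report.n_retained, report.removed_call_rate,
                report.removed_hwe, report.removed_mendel)
    return out, report


def filter_family_missing(gm: GenotypeMatrix,
                          families: list[NuclearFamily]) -> tuple[GenotypeMatrix, int]:
    """Drop every SNP with a missing call in any member of any listed family.

    Guarantees the surviving SNP set is fully called, hence identical, across
    all calling-eligible nuclear families.
    """
    member_ids = sorted({m for fam in families for m in fam.members()})
    missing_ids = [m for m in member_ids if m not in gm._sample_index]
    if missing_ids:
        raise ConsistencyError(f"family members absent from genotypes: {missing_ids}")
    cols = gm.sample_indices(member_ids)
    any_missing = (gm.calls[:, cols] < 0).any(axis=1)
    removed = int(any_missing.sum())
    logger.info("family-missingness filter removed %d SNPs", removed)
    return gm.take_snps(~any_missing), removed


def extract_nuclear_families(ped: Pedigree, genotyped: set[str] | None = None,
                             min_children: int = 2) -> list[NuclearFamily]:
    """All (father, mother) couples with >= ``min_children`` genotyped children.

    Multi-generation pedigrees decompose into overlapping nuclear families:
    an individual can be a child in one and a parent in another.  If
    ``genotyped`` is given, children outside it are not counted and families
    whose parents are ungenotyped are skipped.
    """
    ind = ped.individuals
    out = []
    linked = ind[(ind["father"] != "0") & (ind["mother"] != "0")]
    for (father, mother), grp in linked.groupby(["father", "mother"], sort=True):
        children = list(grp["iid"])
        if genotyped is not None:
            if father not in genotyped or mother not in genotyped:
                continue
            children = [c for c in children if c in genotyped]
        if len(children) >= min_children:
            out.append(NuclearFamily(father, mother, tuple(children)))
    return out
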