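"""Reading, validation and quality control of X-linked case-parent triad genotypes.

A *case-parent triad* is an affected child together with both parents. On the
X chromosome, mothers carry two alleles per locus, fathers and sons one
(hemizygous), and daughters two — one maternal, one paternal (the paternal one
obligately transmitted). Genotypes are stored as variant-allele dose: mothers
and girls in {0, 1, 2}, fathers and boys in {0, 1}; ``-1`` codes a missing
call throughout.

The module reads the PLINK ped/map text dialect and a native long-format TSV,
detects X-specific Mendelian inconsistencies, computes hemizygosity-aware
minor-allele frequencies, performs the Hardy-Weinberg exact test on the
mothers, and applies the standard QC cascade (individual missingness -> SNP
missingness -> MAF -> Mendelian errors).
"""

from __future__ import annotations

import logging
from dataclasses import InitVar, dataclass, field
from math import lgamma
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("xpoo")

MISSING = -1

FEMALE = "female"
MALE = "male"

CONSISTENT = "consistent"
INCONSISTENT = "inconsistent"
UNKNOWN = "unknown"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpInfo:
    """A single X-linked SNP: identifier, 1-based map position, allele labels."""

    snp_id: str
    position: int
    allele_ref: str
    allele_var: str

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError(f"SNP {self.snp_id}: position must be positive")
        if self.allele_ref == self.allele_var:
            raise ValueError(f"SNP {self.snp_id}: identical ref/var alleles")


@dataclass
class TriadRecord:
    """Variant-allele doses of one mother/father/affected-child triad.

    Doses are per-SNP arrays aligned with ``TriadDataset.snps``; -1 is missing.
    Boys and fathers are hemizygous and never carry dose 2.
    """

    triad_id: str
    child_sex: str  # FEMALE or MALE
    mother_dose: np.ndarray
    father_dose: np.ndarray
    child_dose: np.ndarray

    def validate(self, n_snps: int) -> None:
        if self.child_sex not in (FEMALE, MALE):
            raise ValueError(f"triad {self.triad_id}: unknown child sex {self.child_sex!r}")
        for name, arr, hi in (
            ("mother", self.mother_dose, 2),
            ("father", self.father_dose, 1),
            ("child", self.child_dose, 2 if self.child_sex == FEMALE else 1),
        ):
            if len(arr) != n_snps:
                raise ValueError(f"triad {self.triad_id}: {name} has {len(arr)} genotype "
                                 f"slots, expected {n_snps}")
            bad = (arr != MISSING) & ((arr < 0) | (arr > hi))
            if bad.any():
                raise ValueError(f"triad {self.triad_id}: {name} dose out of range")


@dataclass
class TriadDataset:
    """Ordered SNPs plus the triads genotyped at them.

    ``validate=False`` skips per-record range checks — used by the simulator,
    whose draws are valid by construction.
    """

    snps: list[SnpInfo]
    triads: list[TriadRecord]
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool = True) -> None:
        self._dose_cache = None
        if not validate:
            return
        seen: set[str] = set()
        for s in self.snps:
            if s.snp_id in seen:
                raise ValueError(f"duplicate SNP id {s.snp_id!r}")
            seen.add(s.snp_id)
        for t in self.triads:
            t.validate(len(self.snps))

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_triads(self) -> int:
        return len(self.triads)

    def snp_index(self, snp_id: str) -> int:
        for i, s in enumerate(self.snps):
            if s.snp_id == snp_id:
                return i
        raise KeyError(snp_id)

    def subset_snps(self, keep: Sequence[int]) -> "TriadDataset":
        keep = list(keep)
        snps = [self.snps[i] for i in keep]
        triads = [
            TriadRecord(t.triad_id, t.child_sex,
                        t.mother_dose[keep].copy(),
                        t.father_dose[keep].copy(),
                        t.child_dose[keep].copy())
            for t in self.triads
        ]
        return TriadDataset(snps, triads)

    def dose_matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(mother, father, child) dose matrices (n_triads x n_snps) and a
        boolean girl indicator per triad."""
        if self._dose_cache is not None:
            return self._dose_cache
        m = np.array([t.mother_dose for t in self.triads], dtype=np.int8).reshape(self.n_triads, self.n_snps)
        f = np.array([t.father_dose for t in self.triads], dtype=np.int8).reshape(self.n_triads, self.n_snps)
        c = np.array([t.child_dose for t in self.triads], dtype=np.int8).reshape(self.n_triads, self.n_snps)
        girl = np.array([t.child_sex == FEMALE for t in self.triads], dtype=bool)
        return m, f, c, girl


@dataclass
class QcReport:
    """What apply_qc removed and why, plus per-SNP summary statistics."""

    individuals_removed: list[tuple[str, str, str]] = field(default_factory=list)  # (triad, member, reason)
    snps_removed: list[tuple[str, str]] = field(default_factory=list)  # (snp_id, reason)
    mendelian_errors: dict[str, int] = field(default_factory=dict)
    maf: dict[str, float] = field(default_factory=dict)
    hwe_p: dict[str, float] = field(default_factory=dict)

    @property
    def n_individuals_removed(self) -> int:
        return len(self.individuals_removed)

    @property
    def n_snps_removed(self) -> int:
        return len(self.snps_removed)

    def snp_frame(self) -> pd.DataFrame:
        ids = sorted(set(self.mendelian_errors) | set(self.maf) | set(self.hwe_p))
        return pd.DataFrame({
            "snp_id": ids,
            "mendelian_errors": [self.mendelian_errors.get(i, np.nan) for i in ids],
            "maf": [self.maf.get(i, np.nan) for i in ids],
            "hwe_p": [self.hwe_p.get(i, np.nan) for i in ids],
        })

    def write(self, path: str | Path) -> None:
        path = Path(path)
        self.snp_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")
        log_path = path.with_suffix(path.suffix + ".log")
        with open(log_path, "w") as fh:
            fh.write(self.summary())

    def summary(self) -> str:
        lines = [f"individuals removed: {self.n_individuals_removed}"]
        for triad, member, reason in self.individuals_removed:
            lines.append(f"  triad {triad} {member}: {reason}")
        lines.append(f"snps removed: {self.n_snps_removed}")
        for snp, reason in self.snps_removed:
            lines.append(f"  {snp}: {reason}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Parsing: PLINK ped/map dialect and native TSV
# ---------------------------------------------------------------------------

class ParseError(ValueError):
    pass


def _read_map(map_path: str | Path) -> list[tuple[str, int]]:
    entries: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{map_path}:{lineno}: expected 4 map columns, got {len(parts)}")
            snp_id, pos = parts[1], parts[3]
            if snp_id in seen:
                raise ParseError(f"{map_path}:{lineno}: duplicate SNP id {snp_id!r}")
            seen.add(snp_id)
            try:
                position = int(pos)
            except ValueError as e:
                raise ParseError(f"{map_path}:{lineno}: bad position {pos!r}") from e
            entries.append((snp_id, position))
    return entries


def read_triads(ped_path: str | Path, map_path: str | Path) -> TriadDataset:
    """Read a PLINK-style ped/map pair of X-linked triads.

    The ped file carries six leading columns (family, individual, father,
    mother, sex with 1=male/2=female, phenotype with 2=affected) followed by
    two space-separated allele columns per SNP; ``0`` is the missing allele.
    Triads are linked through the child's father/mother pointers; families
    without an affected child with both parents present are rejected. Male X
    genotypes may be coded homozygous ("a a"); heterozygous male calls are set
    to missing with a warning.
    """
    map_entries = _read_map(map_path)
    n_snps = len(map_entries)

    rows: dict[tuple[str, str], dict] = {}
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_snps:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} columns "
                    f"({n_snps} SNPs), got {len(parts)}")
            fam, iid, pat, mat, sex, pheno = parts[:6]
            alleles = np.array(parts[6:], dtype=object).reshape(n_snps, 2)
            rows[(fam, iid)] = {
                "pat": pat, "mat": mat, "sex": sex, "pheno": pheno,
                "alleles": alleles, "lineno": lineno,
            }

    # per-SNP allele labels: variant = minor allele among observed calls
    allele_labels: list[tuple[str, str]] = []
    for j in range(n_snps):
        counts: dict[str, int] = {}
        for row in rows.values():
            for a in row["alleles"][j]:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        labels = sorted(counts, key=lambda a: (-counts[a], a))
        if len(labels) > 2:
            raise ParseError(f"SNP {map_entries[j][0]}: more than two alleles {labels}")
        if not labels:
            labels = ["A", "B"]  # fully missing SNP; arbitrary labels
        elif len(labels) == 1:
            labels.append("B" if labels[0] != "B" else "A")
        allele_labels.append((labels[0], labels[1]))

    snps = [SnpInfo(snp_id, pos, ref, var)
            for (snp_id, pos), (ref, var) in zip(map_entries, allele_labels)]

    def dose_vector(row: dict, male: bool, who: str) -> np.ndarray:
        out = np.full(n_snps, MISSING, dtype=np.int8)
        for j in range(n_snps):
            a1, a2 = row["alleles"][j]
            if a1 == "0" or a2 == "0":
                continue
            var = snps[j].allele_var
            d = int(a1 == var) + int(a2 == var)
            if male:
                if a1 != a2:
                    logger.warning(
                        "heterozygous male call for %s at SNP %s set to missing",
                        who, snps[j].snp_id)
                    continue
                d = min(d, 1)
            out[j] = d
        return out

    triads: list[TriadRecord] = []
    for (fam, iid), row in sorted(rows.items(), key=lambda kv: kv[1]["lineno"]):
        if row["pat"] == "0" or row["mat"] == "0":
            continue  # founder row
        if row["pheno"] != "2":
            continue  # not an affected child
        if row["sex"] == "1":
            sex = MALE
        elif row["sex"] == "2":
            sex = FEMALE
        else:
            raise ParseError(f"{ped_path}: child {iid} in family {fam} has unknown sex "
                             f"code {row['sex']!r}")
        father = rows.get((fam, row["pat"]))
        mother = rows.get((fam, row["mat"]))
        if father is None or mother is None:
            raise ParseError(f"{ped_path}: family {fam}: child {iid} references missing "
                             f"parent rows")
        triads.append(TriadRecord(
            triad_id=fam,
            child_sex=sex,
            mother_dose=dose_vector(mother, male=False, who=f"{fam}/mother"),
            father_dose=dose_vector(father, male=True, who=f"{fam}/father"),
            child_dose=dose_vector(row, male=(sex == MALE), who=f"{fam}/child"),
        ))
    if not triads:
        raise ParseError(f"{ped_path}: no complete affected-child triads found")
    return TriadDataset(snps, triads)


def read_triads_tsv(path: str | Path) -> TriadDataset:
    """Read the native long-format TSV: one row per triad per SNP with columns
    triad_id, snp_id, mother_dose, father_dose, child_dose, child_sex
    (position and allele columns optional; missing dose is blank or -1)."""
    df = pd.read_csv(path, sep="\t", dtype={"triad_id": str, "snp_id": str})
    required = {"triad_id", "snp_id", "mother_dose", "father_dose", "child_dose", "child_sex"}
    if missing := required - set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    snp_ids = list(dict.fromkeys(df["snp_id"]))
    positions = {}
    if "position" in df.columns:
        positions = dict(zip(df["snp_id"], df["position"]))
    snps = [SnpInfo(s, int(positions.get(s, i + 1)), "A", "B")
            for i, s in enumerate(snp_ids)]
    snp_pos = {s: i for i, s in enumerate(snp_ids)}

    triads = []
    for triad_id, grp in df.groupby("triad_id", sort=False):
        sexes = set(grp["child_sex"])
        if len(sexes) != 1 or sexes & {FEMALE, MALE} != sexes:
            raise ParseError(f"{path}: triad {triad_id}: bad child_sex {sexes}")
        sex = sexes.pop()
        m = np.full(len(snps), MISSING, dtype=np.int8)
        f = np.full(len(snps), MISSING, dtype=np.int8)
        c = np.full(len(snps), MISSING, dtype=np.int8)
        for _, r in grp.iterrows():
            j = snp_pos[r["snp_id"]]
            for arr, col in ((m, "mother_dose"), (f, "father_dose"), (c, "child_dose")):
                v = r[col]
                arr[j] = MISSING if pd.isna(v) else int(v)
        triads.append(TriadRecord(str(triad_id), sex, m, f, c))
    return TriadDataset(snps, triads)


def write_triads_tsv(dataset: TriadDataset, path: str | Path) -> None:
    rows = []
    for t in dataset.triads:
        for j, s in enumerate(dataset.snps):
            rows.append({
                "triad_id": t.triad_id, "snp_id": s.snp_id, "position": s.position,
                "mother_dose": t.mother_dose[j], "father_dose": t.father_dose[j],
                "child_dose": t.child_dose[j], "child_sex": t.child_sex,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# X-linked Mendelian consistency
# ---------------------------------------------------------------------------

def _consistent_complete(m: int, f: int, c: int, child_sex: str) -> bool:
    """X-linked transmission check for a fully observed triad at one SNP."""
    if child_sex == MALE:
        # a boy's single allele must be one of his mother's
        return (c == 1 and m >= 1) or (c == 0 and m <= 1)
    # a girl carries the father's allele plus one maternal allele
    maternal = c - f
    if maternal not in (0, 1):
        return False
    return (maternal == 1 and m >= 1) or (maternal == 0 and m <= 1)


def check_triad_consistency(mother_dose: int, father_dose: int, child_dose: int,
                            child_sex: str) -> str:
    """Classify a single-SNP triad genotype as consistent / inconsistent /
    unknown under X-linked inheritance.

    With missing members, all completions are tried: if every completion is
    consistent the verdict is ``consistent``, if none is it is
    ``inconsistent``, otherwise ``unknown``.
    """
    m_opts = [mother_dose] if mother_dose != MISSING else [0, 1, 2]
    f_opts = [father_dose] if father_dose != MISSING else [0, 1]
    c_hi = 2 if child_sex == FEMALE else 1
    c_opts = [child_dose] if child_dose != MISSING else list(range(c_hi + 1))
    verdicts = {
        _consistent_complete(m, f, c, child_sex)
        for m in m_opts for f in f_opts for c in c_opts
    }
    if verdicts == {True}:
        return CONSISTENT
    if verdicts == {False}:
        return INCONSISTENT
    return UNKNOWN


def count_mendelian_errors(dataset: TriadDataset, snp_index: int) -> int:
    """Number of triads Mendelian-inconsistent at the given SNP."""
    if not 0 <= snp_index < dataset.n_snps:
        raise IndexError(snp_index)
    n = 0
    for t in dataset.triads:
        verdict = check_triad_consistency(
            int(t.mother_dose[snp_index]), int(t.father_dose[snp_index]),
            int(t.child_dose[snp_index]), t.child_sex)
        if verdict == INCONSISTENT:
            n += 1
    return n


def mask_mendelian_errors(dataset: TriadDataset) -> TriadDataset:
    """Set all members of a Mendelian-inconsistent triad to missing at the
    offending SNP (the triad keeps its other SNPs)."""
    dataset._dose_cache = None
    for j in range(dataset.n_snps):
        for t in dataset.triads:
            verdict = check_triad_consistency(
                int(t.mother_dose[j]), int(t.father_dose[j]),
                int(t.child_dose[j]), t.child_sex)
            if verdict == INCONSISTENT:
                t.mother_dose[j] = MISSING
                t.father_dose[j] = MISSING
                t.child_dose[j] = MISSING
    return dataset


# ---------------------------------------------------------------------------
# Allele frequency and Hardy-Weinberg
# ---------------------------------------------------------------------------

def compute_maf(dataset: TriadDataset, snp_index: int) -> float:
    """Minor-allele frequency with hemizygosity-aware counting: females
    (mothers, girls) contribute two alleles, males (fathers, boys) one."""
    var = 0.0
    total = 0.0
    for t in dataset.triads:
        m, f, c = (int(t.mother_dose[snp_index]), int(t.father_dose[snp_index]),
                   int(t.child_dose[snp_index]))
        if m != MISSING:
            var += m
            total += 2
        if f != MISSING:
            var += f
            total += 1
        if c != MISSING:
            var += c
            total += 2 if t.child_sex == FEMALE else 1
    if total == 0:
        raise ValueError(f"SNP index {snp_index}: all genotypes missing")
    freq = var / total
    return min(freq, 1.0 - freq)


def hwe_exact_test(mother_genotype_counts: tuple[int, int, int]) -> float:
    """Exact Hardy-Weinberg test p-value from female genotype counts
    (n_AA, n_Aa, n_aa).

    The null distribution conditions on the allele counts; the p-value sums
    the probabilities of all heterozygote counts no more probable than the
    observed one (two-sided exact test). Monomorphic samples return 1.0.
    """
    n_aa_hom, n_het, n_bb_hom = mother_genotype_counts
    if min(mother_genotype_counts) < 0:
        raise ValueError("negative genotype count")
    n = n_aa_hom + n_het + n_bb_hom
    if n == 0:
        raise ValueError("empty genotype counts")
    n_a = 2 * n_aa_hom + n_het
    n_b = 2 * n_bb_hom + n_het
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0

    def log_prob(h: int) -> float:
        # P(het = h | n, n_a) for h with the parity of rare
        na_hom = (n_a - h) // 2
        nb_hom = (n_b - h) // 2
        return (lgamma(n + 1) - lgamma(na_hom + 1) - lgamma(h + 1) - lgamma(nb_hom + 1)
                + h * np.log(2) + lgamma(n_a + 1) + lgamma(n_b + 1) - lgamma(2 * n + 1))

    hs = [h for h in range(rare % 2, rare + 1, 2)]
    logs = np.array([log_prob(h) for h in hs])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = hs.index(n_het)
    p = probs[probs <= probs[obs] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def mother_genotype_counts(dataset: TriadDataset, snp_index: int) -> tuple[int, int, int]:
    doses = [int(t.mother_dose[snp_index]) for t in dataset.triads
             if t.mother_dose[snp_index] != MISSING]
    return (sum(d == 0 for d in doses), sum(d == 1 for d in doses),
            sum(d == 2 for d in doses))


# ---------------------------------------------------------------------------
# QC cascade
# ---------------------------------------------------------------------------

def _individual_missingness(t: TriadRecord, member: str) -> float:
    arr = getattr(t, f"{member}_dose")
    return float(np.mean(arr == MISSING))


def apply_qc(dataset: TriadDataset, ind_miss_max: float = 0.10,
             snp_miss_max: float = 0.01, maf_min: float = 0.01,
             mendel_max: int = 30) -> tuple[TriadDataset, QcReport]:
    """Filter individuals and SNPs.

    Order: individual missingness first (strictly > ``ind_miss_max`` masks
    that member; a failing child drops the triad), then Mendelian-inconsistent
    triads are masked per SNP (their per-SNP error counts are recorded before
    masking), then SNP missingness, MAF and the Mendelian count filter
    (strictly > ``mendel_max`` drops the SNP) are applied on the masked data.
    Masking before the per-SNP statistics makes the whole cascade idempotent:
    a second pass removes nothing.
    """
    if dataset.n_triads == 0 or dataset.n_snps == 0:
        raise ValueError("empty dataset")
    report = QcReport()

    # deep copy so QC never mutates the caller's dataset
    ds = TriadDataset(
        list(dataset.snps),
        [TriadRecord(t.triad_id, t.child_sex, t.mother_dose.copy(),
                     t.father_dose.copy(), t.child_dose.copy())
         for t in dataset.triads],
    )

    # 1. individuals with too much missingness: mask the member entirely;
    #    a removed child drops the triad (the likelihood conditions on it).
    #    Members already fully missing carry no data and are left alone.
    logger.info("QC step 1: individual missingness > %.0f%%", 100 * ind_miss_max)
    kept_triads = []
    for t in ds.triads:
        drop_triad = False
        for member in ("mother", "father", "child"):
            miss = _individual_missingness(t, member)
            if miss > ind_miss_max and miss < 1.0:
                report.individuals_removed.append(
                    (t.triad_id, member, f"missingness > {ind_miss_max:g}"))
                if member == "child":
                    drop_triad = True
                else:
                    getattr(t, f"{member}_dose")[:] = MISSING
        if not drop_triad:
            kept_triads.append(t)
    ds = TriadDataset(list(ds.snps), kept_triads)
    if ds.n_triads == 0:
        raise ValueError("all triads removed by individual-missingness filter")

    # 2. count and mask Mendelian inconsistencies per SNP
    logger.info("QC step 2: mask Mendelian-inconsistent triads per SNP")
    mendel_counts = {snp.snp_id: count_mendelian_errors(ds, j)
                     for j, snp in enumerate(ds.snps)}
    mask_mendelian_errors(ds)

    # 3-5. SNP filters on the masked data
    logger.info("QC steps 3-5: SNP missingness > %.0f%%, MAF < %g, Mendelian > %d",
                100 * snp_miss_max, maf_min, mendel_max)
    keep: list[int] = []
    for j, snp in enumerate(ds.snps):
        calls = np.concatenate([
            np.array([t.mother_dose[j], t.father_dose[j], t.child_dose[j]])
            for t in ds.triads])
        miss = float(np.mean(calls == MISSING))
        if miss > snp_miss_max:
            report.snps_removed.append((snp.snp_id, f"missingness {miss:.3g} > {snp_miss_max:g}"))
            continue
        try:
            maf = compute_maf(ds, j)
        except ValueError:
            report.snps_removed.append((snp.snp_id, "all genotypes missing"))
            continue
        report.maf[snp.snp_id] = maf
        if maf < maf_min:
            report.snps_removed.append((snp.snp_id, f"MAF {maf:.4g} < {maf_min:g}"))
            continue
        n_err = mendel_counts[snp.snp_id]
        report.mendelian_errors[snp.snp_id] = n_err
        if n_err > mendel_max:
            report.snps_removed.append((snp.snp_id, f"{n_err} Mendelian errors > {mendel_max}"))
            continue
        report.hwe_p[snp.snp_id] = hwe_exact_test(mother_genotype_counts(ds, j))
        keep.append(j)

    if not keep:
        raise ValueError("all SNPs removed by QC; review thresholds")
    return ds.subset_snps(keep), report
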