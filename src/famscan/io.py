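"""File I/O and SNP quality control.

Formats handled here are plain-text dialects common in statistical genetics:

* pedigree files in the 6-column FAM dialect
  (``family individual father mother sex phenotype``, whitespace separated,
  missing parents encoded as ``"0"``);
* genotype tables as TSV with one row per SNP, the first five columns holding
  SNP metadata (id, chromosome, position, allele frequency, imputation info
  score) and the remaining columns one best-guess dosage in {0,1,2} per
  individual;
* BED-like gene annotation (``chrom start end gene_id``), converted to
  1-based inclusive coordinates on load;
* per-SNP summary statistics as TSV.

All genomic coordinates in this package are 1-based inclusive.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MISSING_PARENT = "0"

PEDIGREE_COLUMNS = ["family_id", "individual_id", "father_id", "mother_id", "sex", "phenotype"]

SUMMARY_COLUMNS = ["snp_id", "chromosome", "position", "effect", "robust_se", "statistic", "p_value"]


class MalformedLineError(ValueError):
    """A text record that does not parse; carries the 1-based line number."""

    def __init__(self, path, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: {message}")


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass
class Pedigree:
    """A set of families: individuals with optional parent links and a role.

    ``table`` holds one row per individual with columns ``family_id``,
    ``individual_id``, ``father_id``, ``mother_id`` (missing encoded as "0"),
    ``sex`` (1 male, 2 female, 0 unknown), ``phenotype`` (placeholder column
    of the FAM dialect) and ``role`` in {"founder", "offspring", "spouse"}.

    The role column drives relationship inference for the liability
    simulator: within a family all ``offspring`` are full siblings, the
    (at most two) non-offspring members form a spouse pair, and
    parent–offspring pairs follow the explicit parent links.
    """

    table: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        t = self.table
        dup = t["individual_id"][t["individual_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate individual id: {dup.iloc[0]!r}")
        known = dict(zip(t["individual_id"], t["family_id"]))
        for _, row in t.iterrows():
            for pid in (row["father_id"], row["mother_id"]):
                if pid == MISSING_PARENT:
                    continue
                if pid == row["individual_id"]:
                    raise ValueError(
                        f"individual {row['individual_id']!r} is its own parent"
                    )
                if pid not in known:
                    raise ValueError(
                        f"dangling parent reference {pid!r} for individual "
                        f"{row['individual_id']!r}"
                    )
                if known[pid] != row["family_id"]:
                    raise ValueError(
                        f"parent {pid!r} of {row['individual_id']!r} is in a "
                        "different family"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parent = {
            r.individual_id: [p for p in (r.father_id, r.mother_id) if p != MISSING_PARENT]
            for r in self.table.itertuples()
        }
        state: dict[str, int] = {}

        def visit(node: str) -> None:
            state[node] = 1
            for p in parent.get(node, ()):  # walk up to ancestors
                s = state.get(p, 0)
                if s == 1:
                    raise ValueError(f"pedigree cycle involving individual {node!r}")
                if s == 0:
                    visit(p)
            state[node] = 2

        for iid in parent:
            if state.get(iid, 0) == 0:
                visit(iid)

    # -- derived views ----------------------------------------------------

    @property
    def individual_ids(self) -> list[str]:
        return list(self.table["individual_id"])

    @property
    def family_ids(self) -> list[str]:
        return list(self.table["family_id"])

    @property
    def n_families(self) -> int:
        return self.table["family_id"].nunique()

    def cluster_codes(self) -> np.ndarray:
        """Integer family codes aligned with the row order (GEE/Cox clusters)."""
        return pd.factorize(self.table["family_id"])[0]

    def relationship_pairs(self) -> pd.DataFrame:
        """Enumerate within-family relative pairs.

        Returns a frame with columns ``id1``, ``id2``, ``kind`` where kind is
        one of ``spouse``, ``sib``, ``po``.  Siblings are all pairs of
        offspring in the same family (the package models full sibships only);
        the spouse pair of a family is its pair of non-offspring members;
        parent–offspring pairs come from explicit links.
        """
        rows = []
        for _, fam in self.table.groupby("family_id", sort=False):
            off = fam[fam["role"] == "offspring"]
            par = fam[fam["role"] != "offspring"]
            ids_off = list(off["individual_id"])
            for i in range(len(ids_off)):
                for j in range(i + 1, len(ids_off)):
                    rows.append((ids_off[i], ids_off[j], "sib"))
            ids_par = list(par["individual_id"])
            if len(ids_par) == 2:
                rows.append((ids_par[0], ids_par[1], "spouse"))
            for r in fam.itertuples():
                for pid in (r.father_id, r.mother_id):
                    if pid != MISSING_PARENT:
                        rows.append((pid, r.individual_id, "po"))
        return pd.DataFrame(rows, columns=["id1", "id2", "kind"])


def _infer_roles(table: pd.DataFrame) -> pd.Series:
    """Assign roles from link structure: parents are founders, linked
    children offspring; members of two-person childless families are
    labelled spouses, everyone else defaults to founder."""
    parents = set(table["father_id"]) | set(table["mother_id"])
    parents.discard(MISSING_PARENT)
    has_parent = (table["father_id"] != MISSING_PARENT) | (table["mother_id"] != MISSING_PARENT)
    role = np.where(table["individual_id"].isin(parents), "founder",
                    np.where(has_parent, "offspring", "founder"))
    role = pd.Series(role, index=table.index)
    fam_sizes = table.groupby("family_id")["individual_id"].transform("size")
    childless_pair = (fam_sizes == 2) & ~has_parent & ~table["individual_id"].isin(parents)
    role[childless_pair] = "spouse"
    return role


def read_pedigree(path) -> Pedigree:
    """Read a whitespace-delimited FAM-dialect pedigree file."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            tok = line.split()
            if len(tok) != 6:
                raise MalformedLineError(path, lineno, f"expected 6 fields, got {len(tok)}")
            if tok[4] not in {"0", "1", "2"}:
                raise MalformedLineError(path, lineno, f"invalid sex code {tok[4]!r}")
            rows.append(tok)
    table = pd.DataFrame(rows, columns=PEDIGREE_COLUMNS)
    table["sex"] = table["sex"].astype(int)
    table["role"] = _infer_roles(table)
    return Pedigree(table)


def write_pedigree(pedigree: Pedigree, path) -> None:
    """Write the 6-column FAM dialect; round-trips with :func:`read_pedigree`."""
    with open(path, "w") as fh:
        for r in pedigree.table.itertuples():
            fh.write(f"{r.family_id} {r.individual_id} {r.father_id} "
                     f"{r.mother_id} {r.sex} {r.phenotype}\n")


# ---------------------------------------------------------------------------
# SNP metadata and genotypes
# ---------------------------------------------------------------------------

SNPMETA_COLUMNS = ["snp_id", "chromosome", "position", "allele_freq", "info_score"]


@dataclass
class GenotypeDataset:
    """Best-guess genotypes: individuals x SNPs dosages in {0,1,2}.

    ``snps`` is a DataFrame with columns snp_id, chromosome, position,
    allele_freq, info_score plus the derived ``maf``; ``dosages`` has shape
    (n_individuals, n_snps).
    """

    individuals: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.individuals), len(self.snps)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be best-guess genotypes in {0, 1, 2}")
        if "maf" not in self.snps.columns:
            self.snps = self.snps.copy()
            self.snps["maf"] = np.minimum(self.snps["allele_freq"], 1 - self.snps["allele_freq"])

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def sample_allele_freqs(self) -> np.ndarray:
        """Counted allele frequencies in the current sample (axis: SNPs)."""
        return self.dosages.mean(axis=0) / 2.0

    def genotype_counts(self) -> np.ndarray:
        """Per-SNP counts of dosage 0/1/2, shape (n_snps, 3)."""
        return np.stack([(self.dosages == k).sum(axis=0) for k in (0, 1, 2)], axis=1)

    def subset_snps(self, mask) -> "GenotypeDataset":
        mask = np.asarray(mask)
        return GenotypeDataset(
            individuals=list(self.individuals),
            snps=self.snps.loc[mask].reset_index(drop=True),
            dosages=self.dosages[:, mask],
        )


def read_genotypes(path) -> GenotypeDataset:
    """Read the genotype TSV (rows = SNPs, first five columns = metadata)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != SNPMETA_COLUMNS:
            raise MalformedLineError(path, 1, f"expected header starting {SNPMETA_COLUMNS}")
        individuals = header[5:]
        meta_rows, geno_rows = [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            tok = line.rstrip("\n").split("\t")
            if len(tok) != 5 + len(individuals):
                raise MalformedLineError(path, lineno,
                                         f"expected {5 + len(individuals)} fields, got {len(tok)}")
            try:
                meta_rows.append((tok[0], int(tok[1]), int(tok[2]), float(tok[3]), float(tok[4])))
                geno = [int(g) for g in tok[5:]]
            except ValueError as exc:
                raise MalformedLineError(path, lineno, str(exc)) from exc
            if any(g not in (0, 1, 2) for g in geno):
                raise MalformedLineError(path, lineno, "dosages must be integers in {0,1,2}")
            geno_rows.append(geno)
    snps = pd.DataFrame(meta_rows, columns=SNPMETA_COLUMNS)
    dosages = np.asarray(geno_rows, dtype=np.int8).T if geno_rows else \
        np.empty((len(individuals), 0), dtype=np.int8)
    return GenotypeDataset(individuals=individuals, snps=snps, dosages=dosages)


def write_genotypes(data: GenotypeDataset, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SNPMETA_COLUMNS + list(data.individuals)) + "\n")
        for j, r in enumerate(data.snps.itertuples()):
            row = [r.snp_id, str(r.chromosome), str(r.position),
                   f"{r.allele_freq:.6g}", f"{r.info_score:.6g}"]
            row += [str(int(g)) for g in data.dosages[:, j]]
            fh.write("\t".join(row) + "\n")


def read_vcf(path) -> GenotypeDataset:
    """Read GT fields of a VCF into best-guess dosages (requires cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    meta_rows, geno_rows = [], []
    for var in vcf:
        gt = np.asarray(var.gt_types)  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        if (gt == 2).any():
            raise ValueError(f"missing genotype at {var.ID or var.POS}; not supported")
        dos = np.where(gt == 3, 2, gt)
        af = dos.mean() / 2.0
        info = float(var.INFO.get("INFO", var.INFO.get("R2", 1.0)))
        chrom = int(str(var.CHROM).removeprefix("chr"))
        meta_rows.append((var.ID or f"{var.CHROM}:{var.POS}", chrom, var.POS, af, info))
        geno_rows.append(dos)
    snps = pd.DataFrame(meta_rows, columns=SNPMETA_COLUMNS)
    dosages = np.asarray(geno_rows, dtype=np.int8).T
    return GenotypeDataset(individuals=individuals, snps=snps, dosages=dosages)


def read_genes(path) -> pd.DataFrame:
    """Read BED-like gene annotation into 1-based inclusive coordinates.

    Input columns: chrom, start (0-based half-open, BED convention), end,
    gene_id.  Returned frame has columns gene_id, chromosome, start, end
    with start/end 1-based inclusive.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            tok = line.split()
            if len(tok) < 4:
                raise MalformedLineError(path, lineno, "expected chrom start end gene_id")
            try:
                chrom = int(tok[0].removeprefix("chr"))
                start, end = int(tok[1]), int(tok[2])
            except ValueError as exc:
                raise MalformedLineError(path, lineno, str(exc)) from exc
            if end < start:
                raise MalformedLineError(path, lineno, "end before start")
            rows.append((tok[3], chrom, start + 1, end))
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"])


# ---------------------------------------------------------------------------
# Hardy-Weinberg test
# ---------------------------------------------------------------------------

def hwe_chisq_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """1-df chi-square goodness-of-fit p-value against Hardy-Weinberg
    proportions computed from the sample allele frequency.

    Monomorphic input (one allele absent) returns p = 1 by convention.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("no observations")
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p in (0.0, 1.0):
        logger.debug("monomorphic genotype counts; HWE p set to 1")
        return 1.0
    expected = n * np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
    chisq = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chisq, df=1))


def hwe_exact_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test (sum of heterozygote-count probabilities
    not exceeding the observed one, conditional on allele counts)."""
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no observations")
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    logprob = np.array([
        math.lgamma(n + 1) - math.lgamma((rare - h) // 2 + 1) - math.lgamma(h + 1)
        - math.lgamma((2 * n - rare - h) // 2 + 1) + h * math.log(2)
        for h in hets
    ])
    logprob -= math.lgamma(2 * n + 1) - math.lgamma(rare + 1) - math.lgamma(2 * n - rare + 1)
    prob = np.exp(logprob - logprob.max())
    prob /= prob.sum()
    p_obs = prob[hets == n_Aa][0]
    return float(prob[prob <= p_obs * (1 + 1e-12)].sum())


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

@dataclass
class QcThresholds:
    """SNP retention thresholds.

    A SNP is retained when maf > maf_min (strict), info > info_min (strict)
    and HWE p >= hwe_alpha.
    """

    maf_min: float = 0.01
    info_min: float = 0.8
    hwe_alpha: float = 1e-4

    def __post_init__(self):
        for name in ("maf_min", "info_min", "hwe_alpha"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must be in [0, 1); got {v}")


def qc_filter_snps(
    data: GenotypeDataset,
    thresholds: QcThresholds | None = None,
    exact_hwe: bool = False,
) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Apply MAF / imputation-info / HWE filters to a genotype dataset.

    Returns the filtered dataset (input untouched) and a per-SNP report with
    the first failing criterion (``maf``, ``info`` or ``hwe``) for removed
    SNPs and ``pass`` for retained ones.
    """
    if thresholds is None:
        thresholds = QcThresholds()
    hwe = hwe_exact_pvalue if exact_hwe else hwe_chisq_pvalue
    counts = data.genotype_counts()
    hwe_p = np.array([hwe(int(c[2]), int(c[1]), int(c[0])) for c in counts])
    maf = data.snps["maf"].to_numpy(dtype=float)
    info = data.snps["info_score"].to_numpy(dtype=float)

    reason = np.where(maf <= thresholds.maf_min, "maf",
                      np.where(info <= thresholds.info_min, "info",
                               np.where(hwe_p < thresholds.hwe_alpha, "hwe", "pass")))
    report = pd.DataFrame({
        "snp_id": data.snps["snp_id"],
        "maf": maf,
        "info_score": info,
        "hwe_p": hwe_p,
        "status": reason,
    })
    keep = reason == "pass"
    if not keep.any():
        logger.warning("QC filter removed every SNP")
    return data.subset_snps(keep), report


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def write_summary_stats(results: pd.DataFrame, path) -> None:
    """Write a per-SNP summary-statistics table as TSV.

    P-values are serialized in scientific notation; non-finite standard
    errors are written as the ``NA`` sentinel and logged.
    """
    out = results[SUMMARY_COLUMNS].copy()
    n_bad = int((~np.isfinite(out["robust_se"].to_numpy(dtype=float))).sum())
    if n_bad:
        logger.warning("%d rows with non-finite robust SE written as NA", n_bad)
    with open(path, "w") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for r in out.itertuples(index=False):
            se = "NA" if not np.isfinite(r.robust_se) else f"{r.robust_se:.12g}"
            stat = "NA" if not np.isfinite(r.statistic) else f"{r.statistic:.12g}"
            pv = "NA" if not np.isfinite(r.p_value) else f"{r.p_value:.12e}"
            fh.write(f"{r.snp_id}\t{r.chromosome}\t{r.position}\t"
                     f"{r.effect:.12g}\t{se}\t{stat}\t{pv}\n")


def read_summary_stats(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in SUMMARY_COLUMNS if c not in table.columns]
    if missing:
        raise MalformedLineError(path, 1, f"missing columns {missing}")
    return table
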