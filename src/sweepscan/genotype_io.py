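"""Genotype input, QC filtering and breed-sliced access.

Reads diploid biallelic genotypes from VCF (via cyvcf2) or the PLINK text
``.ped``/``.map`` dialect, attaches a sample-to-breed membership table, and
applies the array-QC filters standard for SNP-chip selection scans: per-sample
call rate, per-locus call rate, minor-allele frequency and restriction to
autosomes.

Conventions
-----------
* Genotypes are stored as alt-allele dosages in ``G`` (variants x samples,
  int8) with ``MISSING`` (-1) for uncalled genotypes.
* Fully phased, fully called input additionally populates ``H`` (variants x
  2*samples, uint8); haplotype columns ``2i`` and ``2i+1`` belong to sample
  ``i``.  ``H`` never contains missing entries.
* Coordinates are 1-based inclusive; BED conversion happens only at output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Missing-genotype sentinel in the dosage matrix G.
MISSING = -1

#: Ovine autosomes; override via QCConfig for other taxa.
DEFAULT_AUTOSOMES = tuple(str(c) for c in range(1, 27))

VARIANT_COLUMNS = ["chrom", "pos", "vid", "ref", "alt"]


def make_variant_table(chrom, pos, vid, ref, alt) -> pd.DataFrame:
    """Build and validate a variant table (sorted positions, biallelic)."""
    df = pd.DataFrame(
        {
            "chrom": pd.Series(chrom, dtype=str),
            "pos": pd.Series(pos, dtype=np.int64),
            "vid": pd.Series(vid, dtype=str),
            "ref": pd.Series(ref, dtype=str),
            "alt": pd.Series(alt, dtype=str),
        }
    )
    validate_variant_table(df)
    return df


def validate_variant_table(df: pd.DataFrame) -> None:
    for chrom, sub in df.groupby("chrom", sort=False):
        d = np.diff(sub["pos"].to_numpy())
        if (d <= 0).any():
            raise ValueError(f"positions not strictly increasing on chrom {chrom}")


@dataclass
class QCConfig:
    """Quality-control thresholds (fractions in [0, 1]).

    Defaults reproduce the standard PLINK flags for array-based selection
    scans: ``--maf 0.05 --geno 0.01 --mind 0.05 --chr 1-26``.
    """

    maf_min: float = 0.05
    locus_missing_max: float = 0.01
    sample_missing_max: float = 0.05
    autosomes: tuple = DEFAULT_AUTOSOMES

    def __post_init__(self):
        for name in ("maf_min", "locus_missing_max", "sample_missing_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        self.autosomes = tuple(str(c) for c in self.autosomes)


@dataclass
class QCReport:
    """Counts removed by each ordered QC step."""

    n_non_autosomal: int = 0
    n_samples_removed: int = 0
    n_locus_missing: int = 0
    n_maf: int = 0
    samples_removed: list = field(default_factory=list)


@dataclass
class GenotypeDataset:
    """Variant table plus breed-partitioned genotype (and haplotype) matrices."""

    variants: pd.DataFrame
    samples: list
    breed_of: dict
    G: np.ndarray
    H: np.ndarray | None = None
    group_of: dict | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = list(self.samples)
        if self.G.shape != (len(self.variants), len(self.samples)):
            raise ValueError("G shape does not match variants x samples")
        missing = [s for s in self.samples if s not in self.breed_of]
        if missing:
            raise ValueError(f"samples without breed assignment: {missing}")
        if self.H is not None:
            if self.H.shape != (len(self.variants), 2 * len(self.samples)):
                raise ValueError("H shape does not match variants x 2*samples")
            called = self.G != MISSING
            if not np.array_equal(
                (self.H[:, ::2] + self.H[:, 1::2])[called], self.G[called]
            ):
                raise ValueError("H column pairs inconsistent with G")

    # -- breed slicing ----------------------------------------------------
    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def breeds(self) -> list:
        seen = dict.fromkeys(self.breed_of[s] for s in self.samples)
        return list(seen)

    def sample_indices(self, breed: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples) if self.breed_of[s] == breed]
        if not idx:
            raise KeyError(f"no samples for breed {breed!r}")
        return np.asarray(idx)

    def genotypes_of(self, breed: str) -> np.ndarray:
        return self.G[:, self.sample_indices(breed)]

    def haplotypes_of(self, breed: str) -> np.ndarray:
        if self.H is None:
            raise ValueError("dataset is unphased: no haplotype matrix")
        idx = self.sample_indices(breed)
        cols = np.empty(2 * len(idx), dtype=int)
        cols[0::2] = 2 * idx
        cols[1::2] = 2 * idx + 1
        return self.H[:, cols]

    def subset_variants(self, mask: np.ndarray) -> "GenotypeDataset":
        mask = np.asarray(mask, bool)
        return replace(
            self,
            variants=self.variants.loc[mask].reset_index(drop=True),
            G=self.G[mask],
            H=None if self.H is None else self.H[mask],
        )

    def subset_samples(self, keep: list) -> "GenotypeDataset":
        keep_set = set(keep)
        idx = [i for i, s in enumerate(self.samples) if s in keep_set]
        hap_cols = np.empty(2 * len(idx), dtype=int)
        hap_cols[0::2] = [2 * i for i in idx]
        hap_cols[1::2] = [2 * i + 1 for i in idx]
        return replace(
            self,
            samples=[self.samples[i] for i in idx],
            G=self.G[:, idx],
            H=None if self.H is None else self.H[:, hap_cols],
        )

    # -- frequencies ------------------------------------------------------
    def allele_counts(self, breed: str | None = None):
        """Return (alt_count, called_allele_count) per variant."""
        G = self.G if breed is None else self.genotypes_of(breed)
        called = G != MISSING
        alt = np.where(called, G, 0).sum(axis=1)
        return alt, 2 * called.sum(axis=1)


# ---------------------------------------------------------------------------
# breed table
# ---------------------------------------------------------------------------

def read_breed_table(path):
    """Read a 2- or 3-column TSV: sample, breed[, group].

    Returns ``(breed_of, group_of)``; ``group_of`` maps breed -> group and is
    None when the third column is absent.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("breed table needs at least 2 columns (sample, breed)")
    breed_of = dict(zip(df[0], df[1]))
    group_of = None
    if df.shape[1] >= 3 and df[2].notna().any():
        group_of = dict(zip(df[1], df[2]))
    return breed_of, group_of


def write_breed_table(breed_of: dict, path, group_of: dict | None = None) -> None:
    with open(path, "w") as fh:
        for s, b in breed_of.items():
            if group_of is not None:
                fh.write(f"{s}\t{b}\t{group_of[b]}\n")
            else:
                fh.write(f"{s}\t{b}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, breed_table, multiallelic: str = "skip") -> GenotypeDataset:
    """Read a GT-only VCF into a :class:`GenotypeDataset`.

    ``breed_table`` is either a path to a breed TSV or a ``(breed_of,
    group_of)`` pair / plain dict.  Multiallelic records are skipped (with a
    logged count) or rejected according to ``multiallelic``.  The haplotype
    matrix is populated only when every genotype in the file is phased and
    called.
    """
    from cyvcf2 import VCF

    if isinstance(breed_table, tuple):
        breed_of, group_of = breed_table
    elif isinstance(breed_table, dict):
        breed_of, group_of = breed_table, None
    else:
        breed_of, group_of = read_breed_table(breed_table)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in breed_of]
    if unknown:
        raise ValueError(f"VCF samples absent from breed table: {unknown}")

    chroms, pos, vid, ref, alt = [], [], [], [], []
    g_rows, h_rows = [], []
    all_phased = True
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            if multiallelic == "error":
                raise ValueError(f"multiallelic record at {rec.CHROM}:{rec.POS}")
            n_skipped += 1
            continue
        gt = np.asarray(rec.genotypes, dtype=int)  # (n_samples, 3): a0, a1, phased
        a = gt[:, 0:2]
        phased = gt[:, 2].astype(bool)
        miss = (a < 0).any(axis=1)
        row_g = np.where(miss, MISSING, a.clip(min=0).sum(axis=1)).astype(np.int8)
        if miss.any() or not phased.all():
            all_phased = False
        h_rows.append(a.clip(min=0).astype(np.uint8).reshape(-1))
        g_rows.append(row_g)
        chroms.append(rec.CHROM)
        pos.append(rec.POS)
        vid.append(rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}")
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
    if n_skipped:
        logger.warning("skipped %d multiallelic record(s)", n_skipped)
    if not g_rows:
        raise ValueError("no biallelic records in VCF")

    variants = make_variant_table(chroms, pos, vid, ref, alt)
    G = np.vstack(g_rows)
    H = np.vstack(h_rows) if all_phased else None
    ds = GenotypeDataset(
        variants=variants, samples=samples, breed_of=breed_of, G=G, H=H,
        group_of=group_of, meta={"n_skipped_multiallelic": n_skipped},
    )
    return ds


def write_vcf(ds: GenotypeDataset, path) -> None:
    """Write a minimal GT-only VCF 4.2 (phased if the dataset carries H)."""
    v = ds.variants
    sep = "|" if ds.H is not None else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(v["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(ds.samples) + "\n")
        for i in range(ds.n_variants):
            row = v.iloc[i]
            if ds.H is not None:
                h = ds.H[i]
                gts = [f"{h[2*j]}{sep}{h[2*j+1]}" for j in range(ds.n_samples)]
            else:
                g = ds.G[i]
                conv = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
                gts = [conv[int(x)] for x in g]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.vid}\t{row.ref}\t{row.alt}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# PLINK text dialect
# ---------------------------------------------------------------------------

def read_plink_text(ped_path, map_path, breed_table) -> GenotypeDataset:
    """Read whitespace-delimited PLINK ``.ped``/``.map`` text files.

    Alleles are recoded to alt-allele dosages with alt = the minor allele
    computed across all samples; ties are broken by taking the
    lexicographically larger allele as alt.  "0 0" genotypes become MISSING.
    The result is unphased (no haplotype matrix).
    """
    if isinstance(breed_table, tuple):
        breed_of, group_of = breed_table
    elif isinstance(breed_table, dict):
        breed_of, group_of = breed_table, None
    else:
        breed_of, group_of = read_breed_table(breed_table)

    mp = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "vid", "cm", "pos"], dtype={0: str, 1: str},
    )
    n_snps = len(mp)

    samples, rows = [], []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise ValueError(
                    f".ped/.map SNP-count mismatch: sample {parts[1] if len(parts) > 1 else '?'}"
                    f" has {(len(parts) - 6) / 2} genotype pairs, .map has {n_snps}"
                )
            samples.append(parts[1])
            rows.append(np.asarray(parts[6:], dtype=object).reshape(n_snps, 2))
    if not rows:
        raise ValueError("empty .ped file")
    unknown = [s for s in samples if s not in breed_of]
    if unknown:
        raise ValueError(f".ped samples absent from breed table: {unknown}")

    allele_arr = np.stack(rows, axis=2)  # (n_snps, 2, n_samples)
    G = np.empty((n_snps, len(samples)), dtype=np.int8)
    ref_alleles, alt_alleles = [], []
    for i in range(n_snps):
        a = allele_arr[i]  # (2, n_samples)
        flat = a.reshape(-1)
        called = flat != "0"
        alleles, counts = np.unique(flat[called], return_counts=True)
        if len(alleles) > 2:
            raise ValueError(f"variant {mp.vid[i]} has >2 alleles")
        if len(alleles) == 0:
            ref, alt = "N", "N"
        elif len(alleles) == 1:
            ref, alt = alleles[0], "."
        else:
            # alt = minor allele; tie -> lexicographically larger allele
            if counts[0] < counts[1]:
                alt, ref = alleles[0], alleles[1]
            elif counts[1] < counts[0]:
                alt, ref = alleles[1], alleles[0]
            else:
                alt = max(alleles)
                ref = min(alleles)
        ref_alleles.append(ref)
        alt_alleles.append(alt)
        miss = (a == "0").any(axis=0)
        dosage = (a == alt).sum(axis=0)
        G[i] = np.where(miss, MISSING, dosage)

    variants = make_variant_table(
        mp["chrom"], mp["pos"], mp["vid"], ref_alleles, alt_alleles
    )
    return GenotypeDataset(
        variants=variants, samples=samples, breed_of=breed_of, G=G,
        group_of=group_of,
    )


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def apply_qc(ds: GenotypeDataset, qc: QCConfig | None = None):
    """Apply ordered QC filters; returns ``(filtered_dataset, QCReport)``.

    Order: autosome restriction (a coordinate restriction applied first),
    then per-sample missingness, per-locus missingness and MAF, mirroring
    the behaviour of the PLINK toolkit.  Raises if all samples or all
    variants would be removed.
    """
    if qc is None:
        qc = QCConfig()
    report = QCReport()

    auto = ds.variants["chrom"].isin(qc.autosomes).to_numpy()
    report.n_non_autosomal = int((~auto).sum())
    ds = ds.subset_variants(auto)
    if ds.n_variants == 0:
        raise ValueError("QC removed all variants (autosome filter)")

    miss = ds.G == MISSING
    sample_rate = miss.mean(axis=0)
    bad = sample_rate > qc.sample_missing_max
    report.n_samples_removed = int(bad.sum())
    report.samples_removed = [s for s, b in zip(ds.samples, bad) if b]
    if bad.all():
        raise ValueError("QC removed all samples")
    if bad.any():
        ds = ds.subset_samples([s for s, b in zip(ds.samples, bad) if not b])

    miss = ds.G == MISSING
    locus_rate = miss.mean(axis=1)
    keep_locus = locus_rate <= qc.locus_missing_max
    report.n_locus_missing = int((~keep_locus).sum())
    ds = ds.subset_variants(keep_locus)
    if ds.n_variants == 0:
        raise ValueError("QC removed all variants (locus missingness)")

    alt, n_alleles = ds.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    maf = np.minimum(p, 1 - p)
    keep_maf = maf >= qc.maf_min
    keep_maf &= ~np.isnan(maf)
    report.n_maf = int((~keep_maf).sum())
    ds = ds.subset_variants(keep_maf)
    if ds.n_variants == 0:
        raise ValueError("QC removed all variants (MAF filter)")

    return ds, report
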