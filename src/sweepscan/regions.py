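"""Selection-region calling, candidate-gene identification and ranking.

A region is a maximal run of consecutive SNPs with q <= ``bound_q`` that
contains at least one SNP with q < ``seed_q``; its boundaries are the
positions of the first and last SNP of the run (a single-SNP run yields a
1-bp region).  Candidate genes are collected from the contiguous stretch of
SNPs around the peak whose statistic stays within one (robust) sigma of the
peak value, and ranked by distance from the peak SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracks import QValueTrack, StatTrack

logger = logging.getLogger(__name__)

GENE_COLUMNS = ["gene_id", "name", "chrom", "start", "end", "strand"]


@dataclass
class SelectionRegion:
    """A called interval (1-based inclusive bp) with its peak SNP."""

    chrom: str
    start: int
    end: int
    peak_vid: str
    peak_pos: int
    peak_stat: float
    q_min: float
    unit: str = ""
    method: str = "DCMS"
    n_snps: int = 0

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("region start > end")
        if not self.start <= self.peak_pos <= self.end:
            raise ValueError("peak position outside region")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class RankedGene:
    """A candidate gene with its bp distance from the region peak."""

    gene_id: str
    name: str
    chrom: str
    start: int
    end: int
    distance: int
    rank: int


# ---------------------------------------------------------------------------
# gene annotation I/O
# ---------------------------------------------------------------------------

def read_annotation(path) -> pd.DataFrame:
    """Read gene intervals from GFF3 or BED into a 1-based gene table.

    GFF3: only ``gene`` features are kept; the Name attribute is preferred,
    ID is the fallback.  BED: columns chrom/start/end/name.  Coordinates are
    returned 1-based inclusive.
    """
    import pyranges as pr

    path = str(path)
    if path.endswith((".gff", ".gff3")):
        df = pr.read_gff3(path).df
        df = df[df["Feature"] == "gene"].copy()
        name = df["Name"] if "Name" in df else pd.Series(index=df.index, dtype=str)
        gid = df["ID"] if "ID" in df else name
        out = pd.DataFrame(
            {
                "gene_id": gid.astype(str),
                "name": name.fillna(gid).astype(str),
                "chrom": df["Chromosome"].astype(str),
                "start": df["Start"].astype(np.int64) + 1,  # pyranges is 0-based
                "end": df["End"].astype(np.int64),
                "strand": df.get("Strand", "."),
            }
        )
    elif path.endswith(".bed"):
        df = pr.read_bed(path).df
        out = pd.DataFrame(
            {
                "gene_id": df.get("Name", df.index.astype(str)).astype(str),
                "name": df.get("Name", df.index.astype(str)).astype(str),
                "chrom": df["Chromosome"].astype(str),
                "start": df["Start"].astype(np.int64) + 1,
                "end": df["End"].astype(np.int64),
                "strand": df.get("Strand", "."),
            }
        )
    else:
        raise ValueError(f"unsupported annotation format: {path}")
    if (out["start"] > out["end"]).any():
        raise ValueError("gene with start > end in annotation")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# region calling
# ---------------------------------------------------------------------------

def call_regions(
    qtrack: QValueTrack,
    variants: pd.DataFrame,
    seed_q: float = 0.01,
    bound_q: float = 0.1,
    stat_track: StatTrack | None = None,
    unit: str = "",
    method: str = "DCMS",
) -> list:
    """Call selection regions from a q-value track.

    The peak SNP is the one with the highest statistic value inside the run
    when ``stat_track`` is given, otherwise the SNP with the smallest q.
    Regions never span chromosomes; output is sorted and pairwise disjoint.
    """
    q = qtrack.values
    if not np.isfinite(q[~np.isnan(q)]).all():
        raise ValueError("q-track contains non-finite values")
    regions = []
    for chrom, idx in variants.groupby("chrom", sort=False).indices.items():
        idx = np.sort(idx)
        pos = variants["pos"].to_numpy()[idx]
        if (np.diff(pos) <= 0).any():
            raise ValueError(f"unsorted positions on chrom {chrom}")
        qc = q[idx]
        inrun = np.where(np.isnan(qc), False, qc <= bound_q)
        if not inrun.any():
            continue
        bounded = np.concatenate([[False], inrun, [False]]).astype(int)
        edges = np.flatnonzero(np.diff(bounded))
        for lo, hi in zip(edges[::2], edges[1::2]):  # [lo, hi) in local index
            run_q = qc[lo:hi]
            if not (run_q < seed_q).any():
                continue
            gidx = idx[lo:hi]
            if stat_track is not None:
                stat_vals = stat_track.values[gidx]
                peak_local = int(np.nanargmax(stat_vals))
                peak_stat = float(stat_vals[peak_local])
            else:
                peak_local = int(np.nanargmin(run_q))
                peak_stat = float("nan")
            peak = gidx[peak_local]
            regions.append(
                SelectionRegion(
                    chrom=str(chrom),
                    start=int(pos[lo]),
                    end=int(pos[hi - 1]),
                    peak_vid=str(variants["vid"].iloc[peak]),
                    peak_pos=int(variants["pos"].iloc[peak]),
                    peak_stat=peak_stat,
                    q_min=float(np.nanmin(run_q)),
                    unit=unit,
                    method=method,
                    n_snps=int(hi - lo),
                )
            )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


# ---------------------------------------------------------------------------
# candidate genes
# ---------------------------------------------------------------------------

def identify_genes(
    region: SelectionRegion,
    stat_track: StatTrack,
    variants: pd.DataFrame,
    annotation: pd.DataFrame,
    sigma: float,
    sigma_multiplier: float = 1.0,
) -> pd.DataFrame:
    """Genes overlapping the near-peak plateau of a region.

    The plateau is the maximal contiguous run of SNPs containing the peak in
    which every SNP's statistic is >= peak - sigma_multiplier * sigma; it
    never extends beyond the region.  Genes whose intervals overlap the
    plateau's [first, last] SNP positions are returned.
    """
    chrom_mask = (variants["chrom"] == region.chrom).to_numpy()
    pos = variants["pos"].to_numpy()
    inside = chrom_mask & (pos >= region.start) & (pos <= region.end)
    idx = np.flatnonzero(inside)
    vals = stat_track.values[idx]
    peak_local = int(np.argmin(np.abs(pos[idx] - region.peak_pos)))
    threshold = vals[peak_local] - sigma_multiplier * sigma
    keep = np.where(np.isnan(vals), False, vals >= threshold)
    lo = peak_local
    while lo > 0 and keep[lo - 1]:
        lo -= 1
    hi = peak_local
    while hi < len(idx) - 1 and keep[hi + 1]:
        hi += 1
    win_start, win_end = int(pos[idx][lo]), int(pos[idx][hi])

    ann = annotation[annotation["chrom"].astype(str) == region.chrom]
    if ann.empty:
        logger.warning("no annotated genes on chromosome %s", region.chrom)
        return annotation.iloc[0:0]
    hit = (ann["start"] <= win_end) & (ann["end"] >= win_start)
    return ann[hit].reset_index(drop=True)


def rank_genes(genes: pd.DataFrame, peak_pos: int) -> list:
    """Rank genes by bp distance from the peak SNP (0 if the gene spans it).

    Ties are broken by gene start, then gene_id; ranks are 1..m.
    """
    if genes.empty:
        raise ValueError("empty gene list")
    recs = []
    for _, g in genes.iterrows():
        if g["start"] <= peak_pos <= g["end"]:
            d = 0
        else:
            d = min(abs(int(g["start"]) - peak_pos), abs(int(g["end"]) - peak_pos))
        recs.append((d, int(g["start"]), str(g["gene_id"]), g))
    recs.sort(key=lambda t: (t[0], t[1], t[2]))
    return [
        RankedGene(
            gene_id=str(g["gene_id"]), name=str(g["name"]), chrom=str(g["chrom"]),
            start=int(g["start"]), end=int(g["end"]), distance=int(d), rank=i + 1,
        )
        for i, (d, _, _, g) in enumerate(recs)
    ]


# ---------------------------------------------------------------------------
# overlap between region sets
# ---------------------------------------------------------------------------

def overlap_regions(set_a: list, set_b: list) -> dict:
    """Overlap report of region set A against region set B (1-based bp).

    Returns counts and fraction of A regions with any bp overlap in B, and
    the total shared bp (union of pairwise intersections).
    """
    by_chrom = {}
    for r in set_b:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    n_overlap = 0
    shared = 0
    for r in set_a:
        ivals = []
        for s, e in by_chrom.get(r.chrom, []):
            lo, hi = max(r.start, s), min(r.end, e)
            if lo <= hi:
                ivals.append((lo, hi))
        if ivals:
            n_overlap += 1
            ivals.sort()
            cur_s, cur_e = ivals[0]
            for s, e in ivals[1:]:
                if s > cur_e + 1:
                    shared += cur_e - cur_s + 1
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            shared += cur_e - cur_s + 1
    n = len(set_a)
    return {
        "n_regions": n,
        "n_overlapping": n_overlap,
        "fraction_overlapping": (n_overlap / n) if n else 0.0,
        "shared_bp": int(shared),
    }


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def _cluster_shorthand(ranked: list) -> str:
    """Semicolon-joined "name(rank)" list with gene-cluster shorthand.

    Three or more rank-consecutive genes sharing a letter prefix collapse to
    "PREFIX@ (i-j)" in the style used for HOXA@/KRT@ gene clusters.
    """

    def prefix(name: str) -> str:
        return name.rstrip("0123456789")

    parts = []
    i = 0
    genes = sorted(ranked, key=lambda g: g.rank)
    while i < len(genes):
        j = i
        pref = prefix(genes[i].name)
        while (
            j + 1 < len(genes)
            and pref
            and prefix(genes[j + 1].name) == pref
            and genes[j + 1].name != pref
            and genes[j].name != pref
            and genes[j + 1].rank == genes[j].rank + 1
        ):
            j += 1
        if j - i + 1 >= 3:
            parts.append(f"{pref}@ ({genes[i].rank}–{genes[j].rank})")
        else:
            parts.extend(f"{g.name}({g.rank})" for g in genes[i : j + 1])
        i = j + 1
    return ";".join(parts)


REGION_TSV_COLUMNS = [
    "chrom", "start_bp", "end_bp", "q_min", "unit", "method", "n_snps",
    "peak_vid", "peak_pos", "peak_stat", "candidate_genes",
]


def write_regions(regions: list, ranked_genes: dict | None, bed_path, tsv_path) -> None:
    """Write regions as BED (0-based half-open) and a summary TSV.

    ``ranked_genes`` maps region index -> list of RankedGene (may be None).
    BED score is -10*log10(q_min) capped at 1000; BED name is unit:method.
    """
    with open(bed_path, "w") as bed:
        for r in regions:
            if r.q_min > 0:
                score = min(int(round(-10.0 * np.log10(r.q_min))), 1000)
            else:
                score = 1000
            bed.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.unit}:{r.method}"
                f"\t{score}\t.\n"
            )
    rows = []
    for i, r in enumerate(regions):
        genes = (ranked_genes or {}).get(i, [])
        rows.append(
            {
                "chrom": r.chrom, "start_bp": r.start, "end_bp": r.end,
                "q_min": r.q_min, "unit": r.unit, "method": r.method,
                "n_snps": r.n_snps, "peak_vid": r.peak_vid,
                "peak_pos": r.peak_pos, "peak_stat": r.peak_stat,
                "candidate_genes": _cluster_shorthand(genes) if genes else "",
            }
        )
    pd.DataFrame(rows, columns=REGION_TSV_COLUMNS).to_csv(
        tsv_path, sep="\t", index=False, float_format="%.10g"
    )


def read_regions_tsv(path) -> list:
    """Re-read a region TSV written by :func:`write_regions`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for _, row in df.iterrows():
        out.append(
            SelectionRegion(
                chrom=str(row["chrom"]), start=int(row["start_bp"]),
                end=int(row["end_bp"]), peak_vid=str(row["peak_vid"]),
                peak_pos=int(row["peak_pos"]),
                peak_stat=float(row["peak_stat"]), q_min=float(row["q_min"]),
                unit=str(row["unit"]) if not pd.isna(row["unit"]) else "",
                method=str(row["method"]), n_snps=int(row["n_snps"]),
            )
        )
    return out
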