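"""Synthetic multi-breed genotype data with known truth.

Generates datasets with the statistical structure the scan assumes: an
ancestral allele-frequency pool, per-breed Balding-Nichols drift (optionally
structured along a population tree), hard sweeps injected by haplotype
copying, genotype missingness, and toy gene annotations.  Every stochastic
element flows from a single integer seed and the generating truth (sweep
windows, drift tree, kinship matrix) is recorded for test matchers.

The neutral baseline is linkage-equilibrium between sites: background
haplotype homozygosity is therefore lower than in real SNP-array data, while
injected sweep windows carry forced linkage.  See docs/methods.md for what
this does and does not exercise.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset, make_variant_table

DEFAULT_BREED_NAMES = [f"BREED{i + 1}" for i in range(26)]


@dataclass
class SweepSpec:
    """A hard sweep: one haplotype driven to high frequency in chosen breeds."""

    chrom: str
    start_snp_index: int   # 0-based index within the chromosome
    width_snps: int
    breeds: list
    final_freq: float = 0.95

    def __post_init__(self):
        if not 0.5 < self.final_freq <= 1.0:
            raise ValueError("final_freq must be in (0.5, 1]")
        if self.width_snps < 1 or self.start_snp_index < 0:
            raise ValueError("invalid sweep window")


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic genotype generator.

    Defaults mirror the design the scan targets: 20 diploid individuals
    (40 autosomes) per breed genotyped on a dense array with ~4 kb median
    marker spacing; per-breed drift F = 0.1, a typical one-vs-rest
    differentiation level for livestock breed panels; ancestral frequencies
    bounded away from fixation by ``maf_floor`` = 0.05 matching the array's
    ascertainment and the MAF filter.  ``drift`` is either a scalar
    per-breed Balding-Nichols F or a rooted newick string whose leaves name
    the breeds and whose branch lengths are drift amounts.
    """

    n_breeds: int = 4
    n_per_breed: int = 20
    n_snps: int = 20_000
    n_chroms: int = 2
    spacing_bp: int = 4_000
    drift: object = 0.1
    maf_floor: float = 0.05
    sweeps: list = field(default_factory=list)
    missing_rate: float = 0.0
    seed: int = 0
    breed_names: list | None = None

    def __post_init__(self):
        if min(self.n_breeds, self.n_per_breed, self.n_snps, self.n_chroms) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.breed_names is None:
            self.breed_names = DEFAULT_BREED_NAMES[: self.n_breeds]
        if len(self.breed_names) != self.n_breeds:
            raise ValueError("breed_names length != n_breeds")
        if isinstance(self.drift, (int, float)):
            if not 0 < float(self.drift) < 1:
                raise ValueError("drift F must be in (0, 1)")


def _positions(cfg: SimConfig, rng: np.random.Generator):
    """Chromosome labels and positions: cumulative geometric spacing."""
    per = np.full(cfg.n_chroms, cfg.n_snps // cfg.n_chroms)
    per[: cfg.n_snps % cfg.n_chroms] += 1
    chroms, pos = [], []
    for c in range(cfg.n_chroms):
        gaps = rng.geometric(1.0 / cfg.spacing_bp, size=per[c])
        p = np.cumsum(gaps)
        chroms.extend([str(c + 1)] * per[c])
        pos.extend(p.tolist())
    return np.asarray(chroms), np.asarray(pos, dtype=np.int64)


def _bn_step(p: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """One Balding-Nichols drift step: Beta with mean p, variance d*p*(1-p)."""
    alpha = (1.0 - d) / d
    out = rng.beta(np.maximum(alpha * p, 1e-12), np.maximum(alpha * (1.0 - p), 1e-12))
    return out


def _dataset_from_breed_freqs(cfg, chroms, pos, breed_freqs, rng):
    """Draw phased haplotypes per breed from per-breed frequencies."""
    n_hap = 2 * cfg.n_per_breed
    H_parts, samples, breed_of = [], [], {}
    for j, breed in enumerate(cfg.breed_names):
        Hb = (rng.random((cfg.n_snps, n_hap)) < breed_freqs[:, j, None]).astype(np.uint8)
        H_parts.append(Hb)
        for i in range(cfg.n_per_breed):
            sid = f"{breed}_{i + 1:03d}"
            samples.append(sid)
            breed_of[sid] = breed
    H = np.concatenate(H_parts, axis=1)
    G = (H[:, ::2] + H[:, 1::2]).astype(np.int8)
    variants = make_variant_table(
        chroms, pos, [f"snp{i + 1}" for i in range(cfg.n_snps)],
        ["A"] * cfg.n_snps, ["G"] * cfg.n_snps,
    )
    return GenotypeDataset(
        variants=variants, samples=samples, breed_of=breed_of, G=G, H=H
    )


def simulate_neutral(cfg: SimConfig):
    """Neutral Balding-Nichols dataset; returns ``(dataset, truth)``.

    Ancestral frequencies are Uniform(maf_floor, 1 - maf_floor); each breed
    draws its frequency from the Balding-Nichols Beta around the ancestral
    value; haplotype alleles are independent Bernoulli draws per site
    (linkage-equilibrium baseline).  Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    chroms, pos = _positions(cfg, rng)
    p0 = rng.uniform(cfg.maf_floor, 1.0 - cfg.maf_floor, size=cfg.n_snps)
    if isinstance(cfg.drift, str):
        raise ValueError("tree-structured drift: use simulate_tree_drift")
    F = np.broadcast_to(np.atleast_1d(np.asarray(cfg.drift, float)), (cfg.n_breeds,))
    breed_freqs = np.column_stack(
        [_bn_step(p0, float(F[j]), rng) for j in range(cfg.n_breeds)]
    )
    ds = _dataset_from_breed_freqs(cfg, chroms, pos, breed_freqs, rng)
    truth = {
        "model": "balding-nichols-star",
        "ancestral_freqs": p0,
        "breed_freqs": breed_freqs,
        "F": {b: float(F[j]) for j, b in enumerate(cfg.breed_names)},
        "sweeps": [],
        "seed": cfg.seed,
    }
    ds.meta["truth"] = truth
    if cfg.sweeps:
        for spec in cfg.sweeps:
            ds, _ = inject_sweep(ds, spec, seed=cfg.seed)
    if cfg.missing_rate > 0:
        ds = inject_missingness(ds, cfg.missing_rate, seed=cfg.seed)
    return ds, ds.meta["truth"]


def simulate_tree_drift(cfg: SimConfig):
    """Dataset with tree-structured drift; returns ``(dataset, truth)``.

    ``cfg.drift`` must be a rooted newick string whose leaves are the breed
    names and whose branch lengths d in (0, 0.5) are per-branch drift.  The
    truth kinship matrix (shared-branch sums, breed order of
    ``cfg.breed_names``) is recorded in the truth dict.
    """
    from skbio import TreeNode

    from .flk import kinship_from_tree

    if not isinstance(cfg.drift, str):
        raise ValueError("simulate_tree_drift needs a newick drift string")
    tree = TreeNode.read(io.StringIO(cfg.drift))
    leaves = [t.name for t in tree.tips()]
    if sorted(leaves) != sorted(cfg.breed_names):
        raise ValueError("tree leaves must equal the configured breed names")
    for node in tree.traverse(include_self=False):
        if node.length is None or not 0 <= node.length < 0.5:
            raise ValueError("branch drift lengths must be in [0, 0.5)")

    rng = np.random.default_rng(cfg.seed)
    chroms, pos = _positions(cfg, rng)
    p0 = rng.uniform(cfg.maf_floor, 1.0 - cfg.maf_floor, size=cfg.n_snps)
    freq_at = {id(tree): p0}
    leaf_freq = {}
    for node in tree.preorder(include_self=False):
        parent_p = freq_at[id(node.parent)]
        d = node.length
        p = _bn_step(parent_p, d, rng) if d > 0 else parent_p.copy()
        freq_at[id(node)] = p
        if node.is_tip():
            leaf_freq[node.name] = p
    breed_freqs = np.column_stack([leaf_freq[b] for b in cfg.breed_names])
    ds = _dataset_from_breed_freqs(cfg, chroms, pos, breed_freqs, rng)
    pops, F = kinship_from_tree(tree)
    perm = [pops.index(b) for b in cfg.breed_names]
    truth = {
        "model": "balding-nichols-tree",
        "newick": cfg.drift,
        "ancestral_freqs": p0,
        "breed_freqs": breed_freqs,
        "F_matrix": F[np.ix_(perm, perm)],
        "pops": list(cfg.breed_names),
        "sweeps": [],
        "seed": cfg.seed,
    }
    ds.meta["truth"] = truth
    return ds, truth


def inject_sweep(ds: GenotypeDataset, spec: SweepSpec, seed: int = 0):
    """Copy one carrier haplotype over the sweep window in chosen breeds.

    Within the window, a randomly chosen carrier haplotype's allele string
    is copied onto randomly chosen haplotypes of each affected breed until
    the carrier frequency reaches ``final_freq`` there; nothing changes
    outside the window.  Returns ``(dataset, truth_record)``; overlapping a
    previously injected sweep is an error.
    """
    if ds.H is None:
        raise ValueError("sweep injection requires phased data")
    chrom_idx = np.flatnonzero((ds.variants["chrom"] == spec.chrom).to_numpy())
    if spec.start_snp_index + spec.width_snps > len(chrom_idx):
        raise ValueError("sweep window outside chromosome")
    rows = chrom_idx[spec.start_snp_index : spec.start_snp_index + spec.width_snps]
    start_bp = int(ds.variants["pos"].iloc[rows[0]])
    end_bp = int(ds.variants["pos"].iloc[rows[-1]])
    for prev in ds.meta.get("truth", {}).get("sweeps", []):
        if prev["chrom"] == spec.chrom and not (
            end_bp < prev["start_bp"] or start_bp > prev["end_bp"]
        ):
            raise ValueError("sweep window overlaps a previously injected sweep")

    rng = np.random.default_rng([seed, rows[0], len(rows)])
    H = ds.H.copy()
    # donor haplotype: one random haplotype among the affected breeds
    hap_cols = {}
    all_cols = []
    for breed in spec.breeds:
        idx = ds.sample_indices(breed)
        cols = np.empty(2 * len(idx), dtype=int)
        cols[0::2] = 2 * idx
        cols[1::2] = 2 * idx + 1
        hap_cols[breed] = cols
        all_cols.extend(cols.tolist())
    donor = int(rng.choice(all_cols))
    donor_string = H[np.ix_(rows, [donor])][:, 0].copy()
    for breed, cols in hap_cols.items():
        n_hap = len(cols)
        target = int(round(spec.final_freq * n_hap))
        # recipients: the donor itself (if in this breed) plus random others
        others = [c for c in cols if c != donor]
        need = target - (1 if donor in cols else 0)
        need = max(need, 0)
        chosen = rng.choice(others, size=min(need, len(others)), replace=False)
        H[np.ix_(rows, chosen)] = donor_string[:, None]
    G = (H[:, ::2] + H[:, 1::2]).astype(np.int8)
    out = GenotypeDataset(
        variants=ds.variants, samples=ds.samples, breed_of=ds.breed_of,
        G=G, H=H, group_of=ds.group_of, meta=dict(ds.meta),
    )
    record = {
        "chrom": spec.chrom,
        "start_bp": start_bp,
        "end_bp": end_bp,
        "breeds": list(spec.breeds),
        "final_freq": spec.final_freq,
        "width_snps": spec.width_snps,
    }
    truth = dict(out.meta.get("truth", {"sweeps": []}))
    truth["sweeps"] = list(truth.get("sweeps", [])) + [record]
    out.meta["truth"] = truth
    return out, record


def inject_missingness(ds: GenotypeDataset, rate: float, seed: int = 0) -> GenotypeDataset:
    """Set each genotype to MISSING independently with probability ``rate``.

    Any positive rate drops the haplotype matrix (the dataset becomes
    unphased); rate 0 is the identity.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return ds
    rng = np.random.default_rng([seed, ds.n_variants, ds.n_samples])
    mask = rng.random(ds.G.shape) < rate
    G = ds.G.copy()
    G[mask] = MISSING
    return GenotypeDataset(
        variants=ds.variants, samples=ds.samples, breed_of=ds.breed_of,
        G=G, H=None, group_of=ds.group_of, meta=dict(ds.meta),
    )


# ---------------------------------------------------------------------------
# toy gene annotation
# ---------------------------------------------------------------------------

def make_annotation(
    variants: pd.DataFrame,
    n_genes: int = 50,
    seed: int = 0,
    sweeps: list | None = None,
    gene_length: int = 20_000,
    cluster_prefixes: list | None = None,
) -> pd.DataFrame:
    """Non-overlapping toy gene intervals over the simulated coordinates.

    At least one gene is forced inside every truth sweep window.  Optional
    ``cluster_prefixes`` (e.g. ["KRT"]) add triples of adjacently numbered
    same-prefix genes to exercise gene-cluster shorthand.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng([seed, n_genes])
    rows = []
    occupied = {}

    def try_place(chrom, start, end, name, gid):
        for s, e in occupied.get(chrom, []):
            if not (end < s or start > e):
                return False
        occupied.setdefault(chrom, []).append((start, end))
        rows.append(
            {
                "gene_id": gid, "name": name, "chrom": chrom,
                "start": int(max(start, 1)), "end": int(end),
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
        return True

    counter = 0
    for sw in sweeps or []:
        counter += 1
        mid = (sw["start_bp"] + sw["end_bp"]) // 2
        half = min(gene_length // 2, (sw["end_bp"] - sw["start_bp"]) // 2 or 1)
        try_place(sw["chrom"], mid - half, mid + half,
                  f"SWEEPGENE{counter:04d}", f"gene:SWEEPGENE{counter:04d}")

    chrom_span = {
        str(c): (int(g["pos"].min()), int(g["pos"].max()))
        for c, g in variants.groupby("chrom", sort=False)
    }
    chrom_labels = list(chrom_span)
    n_cluster = 0
    for pref in cluster_prefixes or []:
        # a block of three adjacently numbered genes with a shared prefix
        chrom = chrom_labels[n_cluster % len(chrom_labels)]
        lo, hi = chrom_span[chrom]
        for attempt in range(100):
            anchor = int(rng.integers(lo, max(hi - 4 * gene_length, lo + 1)))
            ok = all(
                try_place(chrom, anchor + i * (gene_length + 100),
                          anchor + i * (gene_length + 100) + gene_length - 1,
                          f"{pref}7{i + 1}", f"gene:{pref}7{i + 1}")
                for i in range(3)
            )
            if ok:
                break
        n_cluster += 1

    attempts = 0
    n_random = 0
    while counter < n_genes and attempts < 50 * n_genes:
        attempts += 1
        chrom = chrom_labels[int(rng.integers(len(chrom_labels)))]
        lo, hi = chrom_span[chrom]
        start = int(rng.integers(lo, max(hi - gene_length, lo + 1)))
        if try_place(chrom, start, start + gene_length - 1,
                     f"GENE{counter + 1:04d}", f"gene:GENE{counter + 1:04d}"):
            counter += 1
            n_random += 1
    df = pd.DataFrame(rows, columns=["gene_id", "name", "chrom", "start", "end", "strand"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_gff3(annotation: pd.DataFrame, path) -> None:
    """Write the gene table as GFF3 (1-based inclusive, gene features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in annotation.iterrows():
            fh.write(
                f"{g['chrom']}\tsweepscan\tgene\t{g['start']}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\tID={g['gene_id']};Name={g['name']}\n"
            )


def write_truth_json(truth: dict, path) -> None:
    """Serialise a truth record (arrays are summarised, sweeps kept exact)."""
    doc = {
        "model": truth.get("model"),
        "seed": truth.get("seed"),
        "sweeps": truth.get("sweeps", []),
    }
    if "F" in truth:
        doc["F"] = truth["F"]
    if "newick" in truth:
        doc["newick"] = truth["newick"]
    if "F_matrix" in truth:
        doc["F_matrix"] = np.asarray(truth["F_matrix"]).tolist()
        doc["pops"] = truth["pops"]
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
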