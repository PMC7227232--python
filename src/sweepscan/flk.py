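"""Single-SNP FLK test with tree-derived population kinship.

The FLK family tests allele-frequency differentiation between populations
against the expectation under pure drift, encoded by a kinship matrix F
derived from a population tree: F_ij is the drift shared by populations i
and j (branch lengths on the common part of their root paths), F_ii the
total root-to-leaf drift.  The tree is built by neighbour joining on
Reynolds distances and midpoint-rooted.

For each SNP with population frequency vector p-hat,

    p0 = (1' F^-1 p) / (1' F^-1 1)
    T  = (p - p0 1)' [p0 (1 - p0) F]^-1 (p - p0 1)

T is approximately chi-squared with n_pops - 1 degrees of freedom under
neutral drift.  Following common practice for genome scans, significance is
assessed not against the chi-squared but by robust-normal fitting of the
genome-wide track (see :func:`flk_pvalues`), which also applies unchanged to
externally computed haplotype-based (hapFLK) tracks.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dcms import NormalFit, fit_normal_robust, normal_pvalues, storey_qvalues
from .genotype_io import MISSING, GenotypeDataset
from .tracks import PValueTrack, QValueTrack, StatTrack

logger = logging.getLogger(__name__)


@dataclass
class AlleleFreqMatrix:
    """Variant-aligned per-population alt-allele frequencies and counts."""

    pops: list
    freqs: np.ndarray   # (n_variants, n_pops), NaN where no calls
    counts: np.ndarray  # called allele counts, same shape

    def __post_init__(self):
        if len(self.pops) < 1:
            raise ValueError("need >= 1 population")


@dataclass
class KinshipModel:
    """Reynolds distances, rooted drift tree, and the kinship matrix F."""

    pops: list
    D_R: np.ndarray
    tree: object  # skbio TreeNode, rooted
    F: np.ndarray

    def newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf)
        return buf.getvalue().strip()


@dataclass
class FLKResult:
    """Per-SNP FLK statistic T, ancestral frequency estimate and df."""

    T: np.ndarray
    p0: np.ndarray
    df: int

    def chi2_pvalues(self) -> np.ndarray:
        """Upper-tail chi-squared reference p-values (df = n_pops - 1)."""
        return sps.chi2.sf(self.T, self.df)


# ---------------------------------------------------------------------------
# population frequencies and Reynolds distances
# ---------------------------------------------------------------------------

def allele_frequencies(ds: GenotypeDataset, pops: list | dict | None = None) -> AlleleFreqMatrix:
    """Per-population alt-allele frequencies.

    ``pops`` is a list of breed labels (default: all breeds) or a mapping
    label -> list of sample ids (for arbitrary breed groupings).  SNPs with
    no called genotypes in a population get NaN there.
    """
    if pops is None:
        pops = ds.breeds
    if isinstance(pops, dict):
        items = list(pops.items())
        sample_pos = {s: i for i, s in enumerate(ds.samples)}
        cols = [np.asarray([sample_pos[s] for s in members]) for _, members in items]
        labels = [lab for lab, _ in items]
    else:
        labels = list(pops)
        cols = [ds.sample_indices(b) for b in labels]
    freqs = np.empty((ds.n_variants, len(labels)))
    counts = np.empty_like(freqs)
    for j, idx in enumerate(cols):
        if len(idx) == 0:
            raise ValueError(f"population {labels[j]!r} is empty")
        G = ds.G[:, idx]
        called = G != MISSING
        n = 2.0 * called.sum(axis=1)
        alt = np.where(called, G, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[:, j] = np.where(n > 0, alt / n, np.nan)
        counts[:, j] = n
    return AlleleFreqMatrix(pops=labels, freqs=freqs, counts=counts)


def reynolds_distances(
    freqs: AlleleFreqMatrix, bias_correction: bool = False
) -> np.ndarray:
    """Pairwise Reynolds (coancestry) distances between populations.

    Default is the sample-size-uncorrected estimator; for each pair the sum
    runs over loci with defined frequencies in both populations:

        D_R = [sum_l ((p_a - p_b)^2 + (q_a - q_b)^2) / 2]
              / [sum_l (1 - p_a p_b - q_a q_b)]

    Uncorrected, the numerator retains the binomial sampling variance of the
    frequency estimates (~1/(2n) per population), which the drift tree then
    absorbs into leaf branches — desirable when the tree feeds the FLK test
    on the same sample.  With ``bias_correction=True`` the per-locus
    sampling variance p-hat*q-hat/(m-1) (m = called allele count) is
    subtracted, giving an unbiased estimate of the generating drift —
    appropriate when the tree itself is the quantity of interest.
    """
    P = freqs.freqs
    k = P.shape[1]
    D = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            pa, pb = P[:, a], P[:, b]
            ok = ~np.isnan(pa) & ~np.isnan(pb)
            if not ok.any():
                raise ValueError(
                    f"no loci shared between {freqs.pops[a]} and {freqs.pops[b]}"
                )
            qa, qb = 1.0 - pa[ok], 1.0 - pb[ok]
            num = (((pa[ok] - pb[ok]) ** 2) + ((qa - qb) ** 2)).sum() / 2.0
            if bias_correction:
                ma = freqs.counts[ok, a]
                mb = freqs.counts[ok, b]
                num -= (pa[ok] * qa / np.maximum(ma - 1, 1)).sum()
                num -= (pb[ok] * qb / np.maximum(mb - 1, 1)).sum()
                num = max(num, 0.0)
            den = (1.0 - pa[ok] * pb[ok] - qa * qb).sum()
            if den == 0:
                raise ValueError(
                    f"Reynolds denominator zero for {freqs.pops[a]}/{freqs.pops[b]}"
                    " (all loci fixed identically)"
                )
            D[a, b] = D[b, a] = num / den
    return D


# ---------------------------------------------------------------------------
# tree building and kinship
# ---------------------------------------------------------------------------

def nj_tree(D: np.ndarray, pops: list):
    """Neighbour-joining tree (unrooted) from a distance matrix.

    Negative branch lengths are clamped to zero with a warning.  Two
    populations yield a single-edge two-leaf tree.
    """
    from skbio import DistanceMatrix, TreeNode
    from skbio.tree import nj

    D = np.asarray(D, float)
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if len(pops) == 2:
        d = D[0, 1]
        return TreeNode.read(io.StringIO(f"({pops[0]}:{d / 2},{pops[1]}:{d / 2});"))
    tree = nj(DistanceMatrix(D, ids=list(pops)))
    n_clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            n_clamped += 1
    if n_clamped:
        logger.warning("clamped %d negative NJ branch length(s) to 0", n_clamped)
    return tree


def midpoint_root(tree):
    """Root a tree at the midpoint of its longest leaf-to-leaf path."""
    n_leaves = tree.count(tips=True)
    if n_leaves == 2:
        root = tree.copy()
        if len(root.children) == 2:
            total = sum(c.length or 0.0 for c in root.children)
            for c in root.children:
                c.length = total / 2.0
            return root
    return tree.root_at_midpoint()


def kinship_from_tree(rooted_tree) -> tuple:
    """Kinship matrix F from a rooted drift tree.

    F_ij = sum of branch lengths shared by the root->i and root->j paths;
    F_ii = total root-to-leaf drift.  Returns ``(pops, F)`` with leaves in
    tree tip order.
    """
    tips = list(rooted_tree.tips())
    if len(rooted_tree.children) > 2:
        raise ValueError("tree is unrooted (root has > 2 children); root it first")
    pops = [t.name for t in tips]
    pos = {t.name: i for i, t in enumerate(tips)}
    k = len(pops)
    F = np.zeros((k, k))
    for node in rooted_tree.traverse(include_self=False):
        length = node.length or 0.0
        if length == 0.0:
            continue
        under = [pos[t.name] for t in ([node] if node.is_tip() else node.tips())]
        F[np.ix_(under, under)] += length
    return pops, F


def build_kinship(freqs: AlleleFreqMatrix, bias_correction: bool = False) -> KinshipModel:
    """Reynolds distances -> NJ -> midpoint root -> kinship, in one call.

    The Reynolds distance between two populations estimates the *mean* of
    their per-population drifts, (F_a + F_b)/2, so the additive patristic
    matrix of the drift tree is 2 * D_R; NJ runs on the doubled matrix and
    the resulting branch lengths are drift amounts directly.  Because the
    distances are computed from sample frequencies, finite-sample noise
    (~1/(2n) per population) is absorbed into the leaf branches, which is
    exactly what keeps the FLK statistic chi-squared calibrated when tested
    with the estimated kinship.
    """
    D = reynolds_distances(freqs, bias_correction=bias_correction)
    tree = midpoint_root(nj_tree(2.0 * D, freqs.pops))
    pops, F = kinship_from_tree(tree)
    # reorder F to the frequency-matrix population order
    perm = [pops.index(p) for p in freqs.pops]
    F = F[np.ix_(perm, perm)]
    return KinshipModel(pops=list(freqs.pops), D_R=D, tree=tree, F=F)


# ---------------------------------------------------------------------------
# the test
# ---------------------------------------------------------------------------

def flk_test(freqs: AlleleFreqMatrix, F: np.ndarray) -> FLKResult:
    """Single-SNP FLK statistic for every variant.

    SNPs with an estimated ancestral frequency of exactly 0 or 1 (ancestrally
    monomorphic) or any undefined population frequency get NaN.
    """
    k = len(freqs.pops)
    F = np.asarray(F, float)
    if F.shape != (k, k):
        raise ValueError("kinship matrix shape does not match populations")
    try:
        Finv = np.linalg.inv(F)
    except np.linalg.LinAlgError as err:
        zeros = [freqs.pops[i] for i in range(k) if F[i, i] == 0]
        raise np.linalg.LinAlgError(
            f"singular kinship matrix (zero drift branches for {zeros})"
        ) from err
    ones = np.ones(k)
    w = Finv @ ones
    denom = ones @ w
    P = freqs.freqs
    defined = ~np.isnan(P).any(axis=1)
    p0 = np.full(len(P), np.nan)
    p0[defined] = (P[defined] @ w) / denom
    T = np.full(len(P), np.nan)
    usable = defined & (p0 > 0) & (p0 < 1)
    dev = P[usable] - p0[usable, None]
    quad = np.einsum("li,ij,lj->l", dev, Finv, dev)
    T[usable] = quad / (p0[usable] * (1.0 - p0[usable]))
    return FLKResult(T=T, p0=p0, df=k - 1)


# ---------------------------------------------------------------------------
# external hapFLK tracks and p-value post-processing
# ---------------------------------------------------------------------------

def read_hapflk_track(path, variants: pd.DataFrame) -> StatTrack:
    """Read a whitespace-delimited SNP/chr/pos/statistic file onto the grid.

    Rows are matched to the loaded variant table by (chromosome, position);
    a header line is tolerated, unmatched rows are dropped with a logged
    count, duplicated positions are an error.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] < 4:
        raise ValueError("hapFLK track needs >= 4 columns (rs, chr, pos, value)")
    first = df.iloc[0]
    try:
        float(first[2]), float(first[3])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    chrom = df[1].astype(str).to_numpy()
    pos = df[2].astype(np.int64).to_numpy()
    val = df[3].astype(float).to_numpy()
    keys = pd.MultiIndex.from_arrays([chrom, pos])
    if keys.duplicated().any():
        raise ValueError("duplicated chromosome/position in hapFLK track")
    grid = pd.MultiIndex.from_arrays(
        [variants["chrom"].astype(str), variants["pos"]]
    )
    lookup = pd.Series(val, index=keys)
    matched = lookup.reindex(grid)
    n_dropped = int(len(lookup) - matched.notna().sum())
    if matched.notna().sum() == 0:
        raise ValueError("no hapFLK rows match the loaded variants")
    if n_dropped:
        logger.warning("dropped %d hapFLK row(s) at unknown positions", n_dropped)
    return StatTrack(name="HAPFLK", breed="", values=matched.to_numpy())


def flk_pvalues(track: StatTrack, fit: NormalFit | None = None):
    """Robust-normal p- and q-values for an FLK or hapFLK track.

    Fits a Huber-robust normal to the genome-wide track (outlying selected
    regions are down-weighted), converts to upper-tail p-values and Storey
    q-values.  Returns ``(pvalues, qvalues, fit)``.
    """
    if fit is None:
        fit = fit_normal_robust(track)
    pv = normal_pvalues(track, fit)
    qv = storey_qvalues(pv)
    return pv, qv, fit
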