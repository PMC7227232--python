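"""Per-breed selection statistics on a variant-aligned grid.

Implements the five statistics combined downstream into the DCMS composite:

* H1 and H12 haplotype homozygosity (Garud et al.) over sliding windows of a
  fixed number of SNPs,
* Tajima's D over the same windows,
* per-SNP one-vs-rest Weir & Cockerham (1984) F_ST,
* per-site nucleotide diversity pi,

plus the running-median smoother (R ``runmed`` semantics with the "constant"
end rule) applied to the noisier single-SNP statistics.

Window statistics are anchored at the window's centre SNP so that all five
statistics live on one variant-aligned grid; the first and last (w-1)/2 SNPs
of each chromosome are undefined (NaN).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset
from .tracks import StatTrack

logger = logging.getLogger(__name__)


@dataclass
class WindowSpec:
    """Sliding-window definition in SNP units.

    ``size_snps`` must be odd so a centre SNP exists.  ``mismatch_allow``
    fixed at 0 means haplotypes are compared as exact strings and windows
    containing missing entries are undefined.
    """

    size_snps: int = 25
    step_snps: int = 1
    mismatch_allow: int = 0

    def __post_init__(self):
        if self.size_snps % 2 == 0:
            raise ValueError("window size must be odd (centre SNP required)")
        if self.step_snps < 1:
            raise ValueError("step must be >= 1")
        if self.mismatch_allow != 0:
            raise ValueError("only mismatch_allow = 0 is supported")


@dataclass
class TajimaWindowSummary:
    """Ingredients of Tajima's D for a single window."""

    n: int
    S: int
    pi_hat: float
    theta_w: float
    D: float


# ---------------------------------------------------------------------------
# haplotype spectrum, H1 / H12
# ---------------------------------------------------------------------------

def haplotype_spectrum(H_window: np.ndarray) -> np.ndarray:
    """Descending haplotype-frequency spectrum of a window.

    ``H_window`` is a (size_snps x n_haplotypes) binary matrix with no
    missing entries; haplotypes are compared as exact strings.
    """
    H_window = np.asarray(H_window)
    if H_window.ndim != 2 or H_window.shape[1] < 1:
        raise ValueError("H_window must be 2-D with >= 1 haplotype")
    if not np.isin(H_window, (0, 1)).all():
        raise ValueError("H_window contains missing or non-binary entries")
    cols = np.ascontiguousarray(H_window.T.astype(np.uint8))
    view = cols.view([("s", f"V{cols.shape[1]}")]).ravel()
    _, counts = np.unique(view, return_counts=True)
    freqs = np.sort(counts)[::-1] / cols.shape[0]
    return freqs


def h1_h12(spectrum: np.ndarray):
    """Return (H1, H12) from a haplotype-frequency spectrum.

    H1 = sum p_i^2; H12 = (p1 + p2)^2 + sum_{i>=3} p_i^2 = H1 + 2 p1 p2.
    """
    p = np.asarray(spectrum, dtype=float)
    if p.size == 0:
        raise ValueError("empty haplotype spectrum")
    if not math.isclose(p.sum(), 1.0, abs_tol=1e-8):
        raise ValueError("spectrum must sum to 1")
    h1 = float(np.sum(p**2))
    p2 = p[1] if p.size > 1 else 0.0
    h12 = h1 + 2.0 * p[0] * p2
    return h1, h12


def _window_codes(H: np.ndarray, w: int):
    """Yield (start_index, uint64 haplotype codes) per sliding window.

    Encodes each haplotype's w-SNP string as bits of a uint64 (w <= 64) with
    a rolling update; falls back to byte-string hashing for wider windows.
    """
    n_snps, n_hap = H.shape
    Hu = H.astype(np.uint64)
    if w <= 64:
        codes = np.zeros(n_hap, dtype=np.uint64)
        for k in range(w):
            codes |= Hu[k] << np.uint64(k)
        yield 0, codes
        top = np.uint64(w - 1)
        for start in range(1, n_snps - w + 1):
            codes = (codes >> np.uint64(1)) | (Hu[start + w - 1] << top)
            yield start, codes
    else:  # pragma: no cover - windows wider than 64 SNPs are unusual
        for start in range(n_snps - w + 1):
            cols = np.ascontiguousarray(H[start : start + w].T.astype(np.uint8))
            yield start, cols.view([("s", f"V{w}")]).ravel()


def _spectrum_from_codes(codes: np.ndarray) -> np.ndarray:
    _, counts = np.unique(codes, return_counts=True)
    return np.sort(counts)[::-1] / codes.size


def scan_h_stats(H: np.ndarray, variants: pd.DataFrame, spec: WindowSpec | None = None):
    """Windowed H1/H12 scan over all chromosomes of one breed.

    Returns ``(h1_track, h12_track)`` aligned to ``variants``; values sit at
    window centres, chromosome edges are NaN.
    """
    spec = spec or WindowSpec()
    w = spec.size_snps
    half = (w - 1) // 2
    n = len(variants)
    h1 = np.full(n, np.nan)
    h12 = np.full(n, np.nan)
    for chrom, idx in variants.groupby("chrom", sort=False).indices.items():
        idx = np.sort(idx)
        if len(idx) < w:
            logger.warning(
                "chromosome %s has %d SNPs < window %d; all undefined",
                chrom, len(idx), w,
            )
            continue
        Hc = H[idx]
        for start, codes in _window_codes(Hc, w):
            if start % spec.step_snps:
                continue
            p = _spectrum_from_codes(codes)
            a, b = h1_h12(p)
            centre = idx[start + half]
            h1[centre] = a
            h12[centre] = b
    return (
        StatTrack(name="H1", breed="", values=h1),
        StatTrack(name="H12", breed="", values=h12),
    )


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int):
    """Standard constants a1, a2, b1, b2, c1, c2, e1, e2 for n haplotypes."""
    if n < 4:
        raise ValueError("Tajima's D requires >= 4 haplotypes")
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, a2, b1, b2, c1, c2, e1, e2


def tajima_d_summary(H_window: np.ndarray) -> TajimaWindowSummary:
    """Tajima's D and its ingredients for one haplotype window."""
    Hw = np.asarray(H_window)
    n = Hw.shape[1]
    a1, _, _, _, _, _, e1, e2 = tajima_constants(n)
    derived = Hw.sum(axis=1)
    seg = (derived > 0) & (derived < n)
    S = int(seg.sum())
    diffs = derived * (n - derived)  # pairwise differences per site
    pi_hat = float(diffs.sum()) / (n * (n - 1) / 2.0)
    theta_w = S / a1
    if S == 0:
        return TajimaWindowSummary(n=n, S=0, pi_hat=pi_hat, theta_w=0.0, D=float("nan"))
    D = (pi_hat - theta_w) / math.sqrt(e1 * S + e2 * S * (S - 1))
    return TajimaWindowSummary(n=n, S=S, pi_hat=pi_hat, theta_w=theta_w, D=D)


def tajima_d_windows(
    H: np.ndarray, variants: pd.DataFrame, spec: WindowSpec | None = None
) -> StatTrack:
    """Tajima's D per sliding window, anchored at window centres."""
    spec = spec or WindowSpec()
    w = spec.size_snps
    half = (w - 1) // 2
    n_hap = H.shape[1]
    a1, _, _, _, _, _, e1, e2 = tajima_constants(n_hap)
    out = np.full(len(variants), np.nan)
    denom_pairs = n_hap * (n_hap - 1) / 2.0
    for chrom, idx in variants.groupby("chrom", sort=False).indices.items():
        idx = np.sort(idx)
        if len(idx) < w:
            continue
        Hc = H[idx]
        derived = Hc.sum(axis=1).astype(float)
        seg = ((derived > 0) & (derived < n_hap)).astype(float)
        diffs = derived * (n_hap - derived)
        # rolling window sums via cumulative sums
        cs_seg = np.concatenate([[0.0], np.cumsum(seg)])
        cs_dif = np.concatenate([[0.0], np.cumsum(diffs)])
        starts = np.arange(0, len(idx) - w + 1, spec.step_snps)
        S = cs_seg[starts + w] - cs_seg[starts]
        pi_hat = (cs_dif[starts + w] - cs_dif[starts]) / denom_pairs
        theta = S / a1
        with np.errstate(invalid="ignore", divide="ignore"):
            D = (pi_hat - theta) / np.sqrt(e1 * S + e2 * S * (S - 1))
        D[S == 0] = np.nan
        out[idx[starts + half]] = D
    return StatTrack(name="TajimaD", breed="", values=out)


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST (one breed vs pooled rest)
# ---------------------------------------------------------------------------

def _wc_theta(n1, p1, h1, n2, p2, h2):
    """Per-SNP Weir & Cockerham (1984) two-population theta-hat.

    ``n_i`` diploid sample sizes, ``p_i`` alt-allele frequencies, ``h_i``
    observed heterozygote frequencies; all arrays over SNPs.
    """
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1.0) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
        theta = a / (a + b + c)
    return theta, a, b, c


def fst_one_vs_rest(ds: GenotypeDataset, focal_breed: str, truncate: bool = True) -> StatTrack:
    """Per-SNP W&C F_ST of one breed against the pooled remaining breeds.

    Missing genotypes are excluded per SNP.  Negative estimates are truncated
    at zero (``truncate=False`` returns the raw estimator).  SNPs where either
    pool has fewer than one called diploid (or the denominator a+b+c is zero,
    i.e. no variation) are 0 when monomorphic and NaN when uncallable.
    """
    if focal_breed not in ds.breeds:
        raise KeyError(f"focal breed {focal_breed!r} not in dataset")
    if len(ds.breeds) < 2:
        raise ValueError("need >= 2 breeds for one-vs-rest F_ST")
    idx1 = ds.sample_indices(focal_breed)
    idx2 = np.setdiff1d(np.arange(ds.n_samples), idx1)

    def pool_stats(cols):
        G = ds.G[:, cols]
        called = G != MISSING
        n = called.sum(axis=1).astype(float)
        alt = np.where(called, G, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / (2.0 * n)
            h = np.where(called, G == 1, False).sum(axis=1) / n
        return n, p, h

    n1, p1, h1 = pool_stats(idx1)
    n2, p2, h2 = pool_stats(idx2)
    theta, a, b, c = _wc_theta(n1, p1, h1, n2, p2, h2)
    denom = a + b + c
    # monomorphic SNPs (no variation anywhere): define as 0
    theta = np.where((denom == 0) & np.isfinite(denom), 0.0, theta)
    theta = np.where((n1 < 1) | (n2 < 1), np.nan, theta)
    if truncate:
        theta = np.where(np.isnan(theta), np.nan, np.clip(theta, 0.0, 1.0))
    return StatTrack(name="FST", breed=focal_breed, values=theta)


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

def site_pi(ds: GenotypeDataset, breed: str) -> StatTrack:
    """Per-site pi = n_ref * n_alt / C(n, 2) within one breed."""
    alt, n = ds.allele_counts(breed)
    n = n.astype(float)
    refc = n - alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = (refc * alt) / (n * (n - 1) / 2.0)
    pi = np.where(n < 2, np.nan, pi)
    return StatTrack(name="PI", breed=breed, values=pi)


# ---------------------------------------------------------------------------
# running-median smoothing
# ---------------------------------------------------------------------------

def smooth_runmed(track: StatTrack, variants: pd.DataFrame, k: int = 31) -> StatTrack:
    """Running median per chromosome with the "constant" end rule.

    Mirrors R ``runmed(x, k, endrule="constant")``: interior value i is the
    median of the k values centred on i; the first and last (k-1)/2 values
    are set to the first/last interior median.  Undefined values are excluded
    before smoothing and reinserted as NaN afterwards.  Chromosomes with
    fewer than k defined values are returned unsmoothed with a warning.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    half = (k - 1) // 2
    out = np.full(len(track.values), np.nan)
    for chrom, idx in variants.groupby("chrom", sort=False).indices.items():
        idx = np.sort(idx)
        vals = track.values[idx]
        ok = ~np.isnan(vals)
        x = vals[ok]
        if len(x) < k:
            if len(x):
                logger.warning(
                    "chromosome %s has %d < k=%d defined values; not smoothed",
                    chrom, len(x), k,
                )
            out[idx[ok]] = x
            continue
        win = np.lib.stride_tricks.sliding_window_view(x, k)
        med = np.median(win, axis=1)
        sm = np.empty_like(x)
        sm[half:-half] = med
        sm[:half] = med[0]
        sm[-half:] = med[-1]
        out[idx[ok]] = sm
    return StatTrack(name=track.name, breed=track.breed, values=out)
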