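"""De-correlated composite of multiple signals (DCMS).

The composite score at locus l combines one-tailed rank p-values p_{l,i} of
k selection statistics,

    DCMS_l = sum_i log((1 - p_{l,i}) / p_{l,i}) / s_i ,

where the weight s_i = sum_j |r_ij| is the sum of absolute correlations of
statistic i with all k statistics (including itself), estimated robustly via
the minimum covariance determinant (MCD) on a random sample of SNPs.  The
genome-wide DCMS track is then fitted with a robust (Huber M-estimated)
normal, converted to upper-tail p-values, and corrected to Storey q-values.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .tracks import PValueTrack, QValueTrack, StatTrack

logger = logging.getLogger(__name__)

#: Columns whose robust variance falls below this are treated as degenerate
#: (constant) statistics and excluded from the MCD fit.
_DEGENERATE_VAR = 1e-12


@dataclass
class CorrelationModel:
    """Robust covariance/correlation of the k statistics and DCMS weights."""

    stats: list
    Sigma: np.ndarray
    R: np.ndarray
    s: np.ndarray
    n_sampled: int
    alpha: float
    seed: int

    def to_json(self, path) -> None:
        doc = {
            "stats": list(self.stats),
            "Sigma": np.asarray(self.Sigma).tolist(),
            "R": np.asarray(self.R).tolist(),
            "s": np.asarray(self.s).tolist(),
            "n_sampled": int(self.n_sampled),
            "alpha": float(self.alpha),
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CorrelationModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            stats=doc["stats"],
            Sigma=np.asarray(doc["Sigma"]),
            R=np.asarray(doc["R"]),
            s=np.asarray(doc["s"]),
            n_sampled=doc["n_sampled"],
            alpha=doc["alpha"],
            seed=doc["seed"],
        )


@dataclass
class NormalFit:
    """Robust location/scale of a genome-wide statistic distribution."""

    mu: float
    sigma: float
    method: str = "huber"

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")


# ---------------------------------------------------------------------------
# rank-based one-tailed p-values
# ---------------------------------------------------------------------------

def rank_pvalues(track: StatTrack, tail: str) -> PValueTrack:
    """Genome-wide rank p-values of a statistic track.

    right tail: p_i = #{j : x_j >= x_i} / (n + 1);
    left tail:  p_i = #{j : x_j <= x_i} / (n + 1).
    The n+1 denominator keeps p strictly inside (0, 1); ties count every
    value at least as extreme.  Undefined entries propagate as NaN.
    """
    if tail not in ("left", "right"):
        raise ValueError("tail must be 'left' or 'right'")
    x = track.values
    ok = ~np.isnan(x)
    n = int(ok.sum())
    if n < 2:
        raise ValueError("need >= 2 defined values for rank p-values")
    xs = np.sort(x[ok])
    p = np.full(len(x), np.nan)
    if xs[0] == xs[-1]:
        warnings.warn(
            f"statistic {track.name!r} is constant; all rank p-values equal",
            RuntimeWarning,
        )
    if tail == "right":
        cnt = n - np.searchsorted(xs, x[ok], side="left")
    else:
        cnt = np.searchsorted(xs, x[ok], side="right")
    p[ok] = cnt / (n + 1.0)
    return PValueTrack(values=p, tail=tail)


# ---------------------------------------------------------------------------
# robust covariance / correlation of the statistics
# ---------------------------------------------------------------------------

def fit_robust_covariance(
    stat_matrix: np.ndarray,
    stats: list | None = None,
    n_sample: int = 300_000,
    alpha: float = 0.75,
    seed: int = 0,
) -> CorrelationModel:
    """MCD covariance/correlation of the statistic columns and DCMS weights.

    Rows containing any undefined value are dropped; up to ``n_sample`` of
    the remaining rows are sampled without replacement (seeded).  Columns
    with (near-)zero robust variance — degenerate statistics — are excluded
    from the MCD and assigned identity correlation (s_i = 1).
    """
    from sklearn.covariance import MinCovDet

    X = np.asarray(stat_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("stat_matrix must be 2-D with k >= 1 columns")
    k = X.shape[1]
    stats = list(stats) if stats is not None else [f"stat{i}" for i in range(k)]
    complete = ~np.isnan(X).any(axis=1)
    Xc = X[complete]
    if len(Xc) < 10 * k:
        raise ValueError(f"only {len(Xc)} complete rows; need >= {10 * k}")
    rng = np.random.default_rng(seed)
    if len(Xc) > n_sample:
        take = rng.choice(len(Xc), size=n_sample, replace=False)
        Xc = Xc[take]
    n_used = len(Xc)

    # screen degenerate columns by MAD
    mad = sps.median_abs_deviation(Xc, axis=0)
    live = mad**2 > _DEGENERATE_VAR
    Sigma = np.zeros((k, k))
    if live.sum() >= 1:
        Xl = Xc[:, live]
        try:
            mcd = MinCovDet(
                support_fraction=alpha, random_state=int(seed) % (2**32)
            ).fit(Xl)
            cov = mcd.covariance_
        except Exception:  # singular MCD subset: classical covariance fallback
            logger.warning("MCD failed (singular subset); using classical covariance")
            cov = np.cov(Xl, rowvar=False).reshape(live.sum(), live.sum())
        Sigma[np.ix_(live, live)] = cov
    for i in np.where(~live)[0]:
        Sigma[i, i] = max(float(np.var(Xc[:, i])), 0.0)
        logger.warning("statistic %s is degenerate (zero robust variance)", stats[i])

    d = np.sqrt(np.diag(Sigma).copy())
    d[d == 0] = 1.0
    R = Sigma / np.outer(d, d)
    # degenerate columns: identity correlation
    for i in np.where(~live)[0]:
        R[i, :] = 0.0
        R[:, i] = 0.0
        R[i, i] = 1.0
    np.fill_diagonal(R, 1.0)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    s = np.abs(R).sum(axis=1)
    return CorrelationModel(
        stats=stats, Sigma=Sigma, R=R, s=s, n_sampled=n_used, alpha=alpha,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# the composite
# ---------------------------------------------------------------------------

def dcms_combine(p_tracks: list, model: CorrelationModel) -> StatTrack:
    """Combine k aligned p-value tracks into the DCMS statistic track.

    A SNP with any undefined p-value gets an undefined DCMS value; p exactly
    0 or 1 is an error (the rank construction prevents both).
    """
    if len(p_tracks) != len(model.stats):
        raise ValueError("number of p-value tracks does not match model.stats")
    P = np.column_stack([t.values for t in p_tracks])
    defined = ~np.isnan(P).any(axis=1)
    if ((P[defined] <= 0) | (P[defined] >= 1)).any():
        raise ValueError("p-values must lie strictly in (0, 1)")
    with np.errstate(invalid="ignore"):
        contrib = np.log((1.0 - P) / P) / np.asarray(model.s)[None, :]
    vals = contrib.sum(axis=1)
    vals[~defined] = np.nan
    return StatTrack(name="DCMS", breed="", values=vals)


# ---------------------------------------------------------------------------
# robust normal fit and p/q-values
# ---------------------------------------------------------------------------

def fit_normal_robust(track: StatTrack) -> NormalFit:
    """Huber M-estimated location and scale of a statistic track.

    Intercept-only robust linear model with Huber weighting (tuning constant
    1.345, MAD-anchored scale, iterated to 1e-8 / max 50 iterations), as used
    to normalise genome-wide DCMS and (hap)FLK tracks where outliers come
    from the selected regions themselves.
    """
    import statsmodels.api as sm

    x = track.values
    x = x[~np.isnan(x)]
    if np.isinf(x).any():
        raise ValueError("non-finite statistic values present")
    if len(x) < 100:
        raise ValueError("need >= 100 defined values for a robust normal fit")
    res = sm.RLM(x, np.ones((len(x), 1)), M=sm.robust.norms.HuberT(t=1.345)).fit(
        maxiter=50, tol=1e-8
    )
    return NormalFit(mu=float(res.params[0]), sigma=float(res.scale))


def normal_pvalues(track: StatTrack, fit: NormalFit) -> PValueTrack:
    """Upper-tail normal p-values of a track under a robust normal fit."""
    z = (track.values - fit.mu) / fit.sigma
    p = sps.norm.sf(z)
    # keep p strictly positive so downstream logs/q-values stay finite
    tiny = np.finfo(float).tiny
    p = np.where(np.isnan(p), np.nan, np.clip(p, tiny, 1.0))
    return PValueTrack(values=p, tail="upper")


def storey_qvalues(pvals: PValueTrack, pi0: float | None = None) -> QValueTrack:
    """Storey q-values with smoother-based pi0 estimation.

    pi0 is estimated on the lambda grid 0.05..0.95 (step 0.05) with a cubic
    polynomial smoother evaluated at the largest lambda, clamped to (0, 1].
    Fewer than 100 p-values falls back to pi0 = 1 (Benjamini-Hochberg) with
    a warning.  ``pi0`` may be forced explicitly.
    """
    p = pvals.values
    ok = ~np.isnan(p)
    ps = p[ok]
    n = len(ps)
    if n == 0:
        raise ValueError("no defined p-values")
    if pi0 is None:
        if n < 100:
            warnings.warn(
                "fewer than 100 p-values; falling back to pi0 = 1 (BH)",
                RuntimeWarning,
            )
            pi0 = 1.0
        else:
            lam = np.arange(0.05, 0.951, 0.05)
            pi0_lam = np.array([(ps > l).sum() / (n * (1.0 - l)) for l in lam])
            coef = np.polyfit(lam, pi0_lam, 3)
            pi0 = float(np.polyval(coef, lam.max()))
            pi0 = min(max(pi0, 1.0 / n), 1.0)
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order]
    q = pi0 * n * ranked / np.arange(1, n + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    qs = np.empty(n)
    qs[order] = q
    out = np.full(len(p), np.nan)
    out[ok] = qs
    return QValueTrack(values=out, pi0=float(pi0))
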