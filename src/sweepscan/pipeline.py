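"""End-to-end scan orchestration: QC -> statistics -> DCMS / FLK -> regions.

The library entry points are :func:`dcms_scan`, :func:`flk_scan` and
:func:`overlap_report`; the CLI in :mod:`sweepscan.cli` is a thin shell over
these plus the artifact writers.  All randomness (MCD subsampling) flows
from the seed in :class:`ScanConfig`; identical inputs and config produce
identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dcms as dcms_mod
from . import flk as flk_mod
from . import popgen_stats as ps
from . import regions as reg
from .genotype_io import GenotypeDataset, QCConfig
from .tracks import PValueTrack, QValueTrack, StatTrack, write_tracks

logger = logging.getLogger(__name__)

#: one-tailed direction per statistic: low pi / low Tajima's D and high
#: H1 / H12 / F_ST are the sweep-like extremes.
STAT_TAILS = {"H1": "right", "H12": "right", "FST": "right", "PI": "left", "TajimaD": "left"}
STAT_ORDER = ["H1", "H12", "TajimaD", "FST", "PI"]


@dataclass
class ScanConfig:
    """Tunable parameters of the scan (see docs/methods.md for rationale)."""

    window: ps.WindowSpec = field(default_factory=ps.WindowSpec)
    qc: QCConfig = field(default_factory=QCConfig)
    runmed_k: int = 31
    n_sample: int = 300_000
    mcd_alpha: float = 0.75
    seed: int = 0
    seed_q: float = 0.01
    bound_q: float = 0.1
    sigma_multiplier: float = 1.0


@dataclass
class BreedScanResult:
    """Everything the DCMS scan produces for one breed."""

    breed: str
    tracks: dict           # name -> StatTrack (smoothed where applicable)
    p_tracks: dict         # name -> PValueTrack
    model: dcms_mod.CorrelationModel
    dcms: StatTrack
    fit: dcms_mod.NormalFit
    pvalues: PValueTrack
    qvalues: QValueTrack
    regions: list
    ranked_genes: dict     # region index -> list[RankedGene]


@dataclass
class UnitScanResult:
    """FLK scan output for one analysis unit (all breeds or one group)."""

    unit: str
    pops: list
    kinship: flk_mod.KinshipModel
    flk: flk_mod.FLKResult
    track: StatTrack
    fit: dcms_mod.NormalFit
    pvalues: PValueTrack
    qvalues: QValueTrack
    regions: list
    ranked_genes: dict


def breed_stat_tracks(ds: GenotypeDataset, breed: str, config: ScanConfig) -> dict:
    """The five per-breed statistic tracks on the shared variant grid.

    H1/H12 and Tajima's D need phased haplotypes; per-SNP F_ST and pi are
    smoothed with the k=31 constant-end running median.
    """
    if ds.H is None:
        raise ValueError(
            "phased input required for H1/H12/TajimaD (dataset has no haplotypes)"
        )
    H = ds.haplotypes_of(breed)
    h1, h12 = ps.scan_h_stats(H, ds.variants, config.window)
    h1.breed = h12.breed = breed
    tajd = ps.tajima_d_windows(H, ds.variants, config.window)
    tajd.breed = breed
    fst = ps.fst_one_vs_rest(ds, breed)
    fst = ps.smooth_runmed(fst, ds.variants, k=config.runmed_k)
    pi = ps.site_pi(ds, breed)
    pi = ps.smooth_runmed(pi, ds.variants, k=config.runmed_k)
    return {"H1": h1, "H12": h12, "TajimaD": tajd, "FST": fst, "PI": pi}


def _informative_stats(tracks: dict) -> list:
    """Statistics with non-zero robust variance, in canonical order.

    A statistic whose median absolute deviation is zero is constant at the
    method's resolution: its rank p-values are one big tie, and the log-odds
    transform would turn the few off-tie values into discrete jumps rather
    than evidence.  Such statistics are excluded from the composite for the
    breed (with a warning).  On real LD-rich data all five statistics vary
    continuously and nothing is excluded; the guard matters for
    linkage-equilibrium simulations where background H1/H12 are degenerate.
    """
    from scipy.stats import median_abs_deviation

    live = []
    for name in STAT_ORDER:
        vals = tracks[name].values
        vals = vals[~np.isnan(vals)]
        if len(vals) and median_abs_deviation(vals) ** 2 > 1e-12:
            live.append(name)
        else:
            logger.warning(
                "statistic %s is degenerate for this breed; excluded from DCMS",
                name,
            )
    if not live:
        raise ValueError("all statistics degenerate; cannot form a composite")
    return live


def dcms_scan(
    ds: GenotypeDataset,
    breeds: list | None = None,
    annotation: pd.DataFrame | None = None,
    config: ScanConfig | None = None,
) -> dict:
    """Per-breed DCMS scan; returns breed -> :class:`BreedScanResult`.

    Pipeline per breed: five statistics -> one-tailed rank p-values ->
    robust (MCD) correlation model -> DCMS composite -> Huber-normal fit ->
    upper-tail p-values -> Storey q-values -> regions -> ranked genes.
    """
    config = config or ScanConfig()
    breeds = list(breeds) if breeds is not None else ds.breeds
    results = {}
    for breed in breeds:
        tracks = breed_stat_tracks(ds, breed, config)
        live = _informative_stats(tracks)
        p_tracks = {
            name: dcms_mod.rank_pvalues(tracks[name], STAT_TAILS[name])
            for name in live
        }
        stat_matrix = np.column_stack([tracks[n].values for n in live])
        model = dcms_mod.fit_robust_covariance(
            stat_matrix,
            stats=live,
            n_sample=config.n_sample,
            alpha=config.mcd_alpha,
            seed=config.seed,
        )
        composite = dcms_mod.dcms_combine([p_tracks[n] for n in live], model)
        composite.breed = breed
        fit = dcms_mod.fit_normal_robust(composite)
        pvals = dcms_mod.normal_pvalues(composite, fit)
        qvals = dcms_mod.storey_qvalues(pvals)
        regions = reg.call_regions(
            qvals, ds.variants, seed_q=config.seed_q, bound_q=config.bound_q,
            stat_track=composite, unit=breed, method="DCMS",
        )
        ranked = _rank_region_genes(
            regions, composite, ds.variants, annotation, fit.sigma,
            config.sigma_multiplier,
        )
        results[breed] = BreedScanResult(
            breed=breed, tracks=tracks, p_tracks=p_tracks, model=model,
            dcms=composite, fit=fit, pvalues=pvals, qvalues=qvals,
            regions=regions, ranked_genes=ranked,
        )
    return results


def _rank_region_genes(regions, stat_track, variants, annotation, sigma, sigma_mult):
    ranked = {}
    if annotation is None:
        return ranked
    for i, region in enumerate(regions):
        genes = reg.identify_genes(
            region, stat_track, variants, annotation, sigma, sigma_mult
        )
        if len(genes):
            ranked[i] = reg.rank_genes(genes, region.peak_pos)
    return ranked


def analysis_units(ds: GenotypeDataset) -> dict:
    """Default FLK analysis units: all breeds plus each configured group."""
    units = {"ALL": ds.breeds}
    if ds.group_of:
        groups = {}
        for breed in ds.breeds:
            g = ds.group_of.get(breed)
            if g:
                groups.setdefault(g, []).append(breed)
        for g, members in groups.items():
            if len(members) >= 2:
                units[g] = members
    return units


def flk_scan(
    ds: GenotypeDataset,
    units: dict | None = None,
    annotation: pd.DataFrame | None = None,
    config: ScanConfig | None = None,
) -> dict:
    """Single-SNP FLK scan per analysis unit; unit -> :class:`UnitScanResult`.

    Per unit: population frequencies -> Reynolds distances -> NJ tree ->
    midpoint root -> kinship F -> FLK -> robust-normal p -> q -> regions.
    """
    config = config or ScanConfig()
    units = units or analysis_units(ds)
    results = {}
    for unit, pops in units.items():
        freqs = flk_mod.allele_frequencies(ds, pops)
        kin = flk_mod.build_kinship(freqs)
        res = flk_mod.flk_test(freqs, kin.F)
        track = StatTrack(name="FLK", breed=unit, values=res.T)
        pvals, qvals, fit = flk_mod.flk_pvalues(track)
        regions = reg.call_regions(
            qvals, ds.variants, seed_q=config.seed_q, bound_q=config.bound_q,
            stat_track=track, unit=unit, method="FLK",
        )
        ranked = _rank_region_genes(
            regions, track, ds.variants, annotation, fit.sigma,
            config.sigma_multiplier,
        )
        results[unit] = UnitScanResult(
            unit=unit, pops=list(pops), kinship=kin, flk=res, track=track,
            fit=fit, pvalues=pvals, qvalues=qvals, regions=regions,
            ranked_genes=ranked,
        )
    return results


def overlap_report(regions_a: list, regions_b: list) -> dict:
    """Pairwise overlap summary between two region sets (A vs B and B vs A)."""
    ab = reg.overlap_regions(regions_a, regions_b)
    ba = reg.overlap_regions(regions_b, regions_a)
    return {"a_vs_b": ab, "b_vs_a": ba}


# ---------------------------------------------------------------------------
# artifact writers (used by the CLI)
# ---------------------------------------------------------------------------

def write_dcms_outputs(results: dict, variants: pd.DataFrame, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for breed, r in results.items():
        cols = {n: r.tracks[n] for n in STAT_ORDER}
        cols["DCMS"] = r.dcms
        cols["p"] = r.pvalues
        cols["q"] = r.qvalues
        write_tracks(variants, cols, outdir / f"dcms_tracks_{breed}.tsv")
        r.model.to_json(outdir / f"dcms_model_{breed}.json")
        reg.write_regions(
            r.regions, r.ranked_genes,
            outdir / f"dcms_regions_{breed}.bed",
            outdir / f"dcms_regions_{breed}.tsv",
        )


def write_flk_outputs(results: dict, variants: pd.DataFrame, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for unit, r in results.items():
        write_tracks(
            variants,
            {"FLK": r.track, "p": r.pvalues, "q": r.qvalues},
            outdir / f"flk_tracks_{unit}.tsv",
        )
        with open(outdir / f"flk_tree_{unit}.nwk", "w") as fh:
            fh.write(r.kinship.newick() + "\n")
        pd.DataFrame(r.kinship.F, index=r.kinship.pops, columns=r.kinship.pops).to_csv(
            outdir / f"flk_kinship_{unit}.tsv", sep="\t"
        )
        pd.DataFrame(r.kinship.D_R, index=r.kinship.pops, columns=r.kinship.pops).to_csv(
            outdir / f"flk_reynolds_{unit}.tsv", sep="\t"
        )
        reg.write_regions(
            r.regions, r.ranked_genes,
            outdir / f"flk_regions_{unit}.bed",
            outdir / f"flk_regions_{unit}.tsv",
        )


def write_manifest(outdir, config: ScanConfig, inputs: dict) -> None:
    """Record inputs, parameters and seed so a run can be reproduced."""
    doc = {
        "inputs": {k: str(v) for k, v in inputs.items()},
        "config": {
            "window": asdict(config.window),
            "qc": {**asdict(config.qc), "autosomes": list(config.qc.autosomes)},
            "runmed_k": config.runmed_k,
            "n_sample": config.n_sample,
            "mcd_alpha": config.mcd_alpha,
            "seed": config.seed,
            "seed_q": config.seed_q,
            "bound_q": config.bound_q,
            "sigma_multiplier": config.sigma_multiplier,
        },
    }
    with open(Path(outdir) / "manifest.json", "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def config_from_yaml(path) -> ScanConfig:
    """Build a ScanConfig from a YAML document (missing keys -> defaults)."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    window = ps.WindowSpec(**doc.get("window", {}))
    qc = QCConfig(**doc.get("qc", {}))
    kwargs = {
        k: doc[k]
        for k in (
            "runmed_k", "n_sample", "mcd_alpha", "seed", "seed_q", "bound_q",
            "sigma_multiplier",
        )
        if k in doc
    }
    return ScanConfig(window=window, qc=qc, **kwargs)
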