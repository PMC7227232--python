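"""Variant-aligned statistic, p-value and q-value tracks.

Every per-SNP quantity in the pipeline (the five selection statistics, the
DCMS composite, FLK, p- and q-values) is carried as a track aligned 1:1 with
a variant table.  Positions where a statistic is undefined (e.g. chromosome
edges where a window cannot be centred, or SNPs with insufficient data) hold
NaN, printed as "NA" on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for an undefined per-variant value.
UNDEFINED = np.nan

STAT_NAMES = ("H1", "H12", "TajimaD", "FST", "PI", "DCMS", "FLK", "HAPFLK")


def _as_float_array(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("track values must be one-dimensional")
    return arr


@dataclass
class StatTrack:
    """One per-SNP statistic for one breed (or breed group).

    Parameters
    ----------
    name : str
        Statistic label, one of :data:`STAT_NAMES`.
    breed : str
        Breed or group label the track belongs to.
    values : ndarray of float
        One value per variant; NaN where undefined.
    """

    name: str
    breed: str
    values: np.ndarray

    def __post_init__(self):
        self.values = _as_float_array(self.values)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of positions carrying a defined value."""
        return ~np.isnan(self.values)

    @property
    def n_defined(self) -> int:
        return int(self.defined.sum())


@dataclass
class PValueTrack:
    """Per-SNP p-values from a one-tailed test.

    ``tail`` records which direction of the source statistic was treated as
    evidence for selection ("right" for H1/H12/FST, "left" for pi/Tajima's D,
    "upper" for normal upper-tail p-values).
    """

    values: np.ndarray
    tail: str = "right"

    def __post_init__(self):
        self.values = _as_float_array(self.values)
        ok = self.values[~np.isnan(self.values)]
        if ok.size and (ok.min() <= 0 or ok.max() > 1):
            raise ValueError("p-values must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass
class QValueTrack:
    """Per-SNP Storey q-values plus the estimated null proportion pi0."""

    values: np.ndarray
    pi0: float = 1.0

    def __post_init__(self):
        self.values = _as_float_array(self.values)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


def tracks_to_frame(variants: pd.DataFrame, tracks: dict) -> pd.DataFrame:
    """Combine variant coordinates and named tracks into one table.

    ``tracks`` maps column name -> StatTrack/PValueTrack/QValueTrack/array.
    """
    out = variants[["chrom", "pos", "vid"]].copy().reset_index(drop=True)
    for col, tr in tracks.items():
        vals = tr.values if hasattr(tr, "values") else np.asarray(tr, float)
        if len(vals) != len(out):
            raise ValueError(f"track {col!r} not aligned with variants")
        out[col] = vals
    return out


def write_tracks(variants: pd.DataFrame, tracks: dict, path) -> None:
    """Serialise tracks to TSV (undefined values printed as NA)."""
    tracks_to_frame(variants, tracks).to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format="%.10g"
    )


def read_tracks(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tracks`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"chrom": str})
    return df
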