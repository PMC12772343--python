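"""Tabular I/O, abundance normalisation, and altitude binning.

Abundance tables are features x samples (TSV, feature ids in the first
column, sample ids in the header).  Altitudes are binned two ways:

* 26 bands of 100 m starting at 1,400 m, the last band open-ended
  ("above 3,900 m"), used as an equally spaced ordinal axis;
* six strata of 400 m starting at 1,400 m, the last open-ended
  ("above 3,400 m"), used for per-stratum network construction.

Both binnings use half-open intervals [low, high) so assignment is a
total, deterministic function on [1400, inf).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

BAND_BASE_M = 1400.0
BAND_WIDTH_M = 100.0
N_BANDS = 26

STRATA = (
    "S1400_1800",
    "S1800_2200",
    "S2200_2600",
    "S2600_3000",
    "S3000_3400",
    "S3400_plus",
)
#: lower edges of the six strata; the last stratum is open-ended
STRATUM_EDGES_M = (1400.0, 1800.0, 2200.0, 2600.0, 3000.0, 3400.0)

#: representative altitude per stratum (midpoint; 3,900 m for the open top stratum)
STRATUM_MIDPOINTS_M = dict(
    zip(STRATA, (1600.0, 2000.0, 2400.0, 2800.0, 3200.0, 3900.0))
)

RANKS = frozenset({"species", "genus", "family", "phylum", "function", "cazyme"})
DOMAINS = ("Bacteria", "Archaea", "Eukaryota", "Viruses")

NDVI_SCALE_FACTOR = 1e-4


def assign_band(altitude_m):
    """Map altitude(s) in metres to the 100 m band index 1..26.

    Bands k = 1..25 cover [1400 + 100(k-1), 1400 + 100k); every altitude
    at or above 3,900 m falls in the open-ended band 26.
    """
    alt = np.asarray(altitude_m, dtype=float)
    if np.any(alt < BAND_BASE_M):
        raise ValueError(f"altitude below {BAND_BASE_M:.0f} m: {alt[alt < BAND_BASE_M]}")
    band = np.floor((alt - BAND_BASE_M) / BAND_WIDTH_M).astype(int) + 1
    band = np.minimum(band, N_BANDS)
    return int(band) if np.isscalar(altitude_m) else band


def assign_stratum(altitude_m):
    """Map altitude(s) in metres to one of the six stratum labels."""
    alt = np.asarray(altitude_m, dtype=float)
    if np.any(alt < STRATUM_EDGES_M[0]):
        raise ValueError(
            f"altitude below {STRATUM_EDGES_M[0]:.0f} m: {alt[alt < STRATUM_EDGES_M[0]]}"
        )
    idx = np.searchsorted(STRATUM_EDGES_M[1:], alt, side="right")
    labels = np.asarray(STRATA, dtype=object)[idx]
    return str(labels) if np.isscalar(altitude_m) else labels


def scale_ndvi(stored_value):
    """Convert stored integer NDVI to the physical value (scale factor 0.0001).

    Values outside [-1, 1] are kept but trigger a warning.
    """
    ndvi = np.asarray(stored_value, dtype=float) * NDVI_SCALE_FACTOR
    if np.any(np.abs(ndvi) > 1.0):
        warnings.warn("scaled NDVI outside [-1, 1]; value kept", stacklevel=2)
    return float(ndvi) if np.isscalar(stored_value) else ndvi


@dataclass
class AbundanceTable:
    """Features x samples abundance matrix with optional annotations.

    Parameters
    ----------
    data
        DataFrame with feature ids as index and sample ids as columns;
        non-negative counts, proportions, or TPM.
    rank
        One of ``species, genus, family, phylum, function, cazyme``.
    lineage
        Optional per-feature taxonomy (columns such as phylum/family/genus).
    lengths_bp
        Optional per-feature lengths in bp (functional features; required
        for TPM normalisation).
    domain_label
        Optional per-feature domain in {Bacteria, Archaea, Eukaryota, Viruses}.
    """

    data: pd.DataFrame
    rank: str
    lineage: pd.DataFrame | None = None
    lengths_bp: pd.Series | None = None
    domain_label: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}; expected one of {sorted(RANKS)}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated feature ids: {dup}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicated sample ids: {dup}")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("abundance values must be numeric")
        neg = np.argwhere(vals < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"negative abundance at feature {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}: {vals[i, j]}"
            )
        if self.lengths_bp is not None:
            ln = self.lengths_bp.reindex(self.data.index)
            if ln.isna().any() or (ln <= 0).any():
                raise ValueError("lengths_bp must cover all features and be positive")
            self.lengths_bp = ln

    @property
    def feature_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def column(self, sample_id) -> np.ndarray:
        return self.data[sample_id].to_numpy(dtype=float)

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        return replace(self, data=self.data.loc[:, list(sample_ids)])

    def aggregate_by(self, level: str) -> "AbundanceTable":
        """Sum features sharing the same lineage value at ``level``."""
        if self.lineage is None or level not in self.lineage.columns:
            raise ValueError(f"no lineage column {level!r} available")
        groups = self.lineage.reindex(self.data.index)[level]
        agg = self.data.groupby(groups, sort=False).sum()
        agg.index.name = self.data.index.name
        return AbundanceTable(data=agg, rank=level if level in RANKS else self.rank)


def read_abundance_table(
    path,
    rank: str,
    lineage_path=None,
    lengths_path=None,
) -> AbundanceTable:
    """Read a features x samples TSV (and optional companion TSVs)."""
    data = pd.read_csv(path, sep="\t", index_col=0)
    lineage = None
    if lineage_path is not None:
        lineage = pd.read_csv(lineage_path, sep="\t", index_col=0)
    lengths = None
    if lengths_path is not None:
        lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    return AbundanceTable(data=data, rank=rank, lineage=lineage, lengths_bp=lengths)


def write_abundance_table(table: AbundanceTable, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(path, sep="\t")


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Divide each sample column by its sum so columns sum to one.

    Idempotent on already-normalised tables; an all-zero sample column is
    an error (it has no composition).
    """
    sums = table.data.sum(axis=0)
    zero = sums[sums == 0].index.tolist()
    if zero:
        raise ValueError(f"all-zero sample column(s): {zero}")
    return replace(table, data=table.data.div(sums, axis=1))


def make_sample_frame(
    sample_ids,
    altitude_m,
    ndvi=None,
    quadrat_id=None,
) -> pd.DataFrame:
    """Build the per-sample frame: altitude plus derived band and stratum."""
    alt = np.asarray(altitude_m, dtype=float)
    frame = pd.DataFrame(
        {
            "altitude_m": alt,
            "band_index": assign_band(alt),
            "stratum": assign_stratum(alt),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if ndvi is not None:
        frame["ndvi"] = np.asarray(ndvi, dtype=float)
    if quadrat_id is not None:
        frame["quadrat_id"] = list(quadrat_id)
    if frame.index.duplicated().any():
        raise ValueError("duplicated sample ids in metadata")
    return frame


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV (sample_id, altitude_m, optional ndvi_stored,
    quadrat_id) and derive band_index, stratum, and scaled ndvi."""
    raw = pd.read_csv(path, sep="\t")
    if "sample_id" not in raw.columns or "altitude_m" not in raw.columns:
        raise ValueError("metadata must have sample_id and altitude_m columns")
    ndvi = None
    if "ndvi" in raw.columns:
        ndvi = raw["ndvi"].to_numpy(dtype=float)
    elif "ndvi_stored" in raw.columns:
        ndvi = scale_ndvi(raw["ndvi_stored"].to_numpy())
    return make_sample_frame(
        raw["sample_id"],
        raw["altitude_m"],
        ndvi=ndvi,
        quadrat_id=raw["quadrat_id"] if "quadrat_id" in raw.columns else None,
    )


def write_metadata(frame: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t")
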