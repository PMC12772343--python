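"""Seeded synthetic datasets with the gradient structure the analysis assumes.

The generator emulates a field survey of gut metagenomes along a
1,400-4,400 m transect: compositional species counts with

* planted monotone altitude responders (log-abundance slope per km),
* a mid-altitude diversity bump (extra taxa whose log-abundance carries
  a Gaussian envelope centred on the peak altitude),
* per-stratum latent-factor correlation blocks (shared Gaussian factor
  per block with signed, jittered loadings), densest in the
  2,200-2,600 m stratum,

plus a CAZyme-style functional table with feature lengths for TPM, and
a three-phase NDVI series.  Counts follow a lognormal-multinomial
model: per-sample log-abundances are exponentiated, closed to
proportions, and multinomially sampled at a fixed sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io_meta import (
    AbundanceTable,
    STRATA,
    assign_stratum,
    make_sample_frame,
)

#: default correlated-block sizes per stratum; densest at S2200_2600.
#: Large mid-altitude blocks yield cohesive, high-degree subnetworks;
#: the small dyad/triad blocks elsewhere yield sparse, fragile ones.
DEFAULT_BLOCK_SIZES = {
    "S1400_1800": [2, 2, 2, 2, 2, 2, 2],
    "S1800_2200": [2, 2, 2, 2, 2, 2, 2],
    "S2200_2600": [16, 14, 12],
    "S2600_3000": [2, 2, 2, 2, 2, 2, 2],
    "S3000_3400": [2, 2, 2, 2, 2, 2, 2],
    "S3400_plus": [2, 2, 2, 2, 2],
}

#: latent-factor strength multiplier per stratum (scales the loading)
DEFAULT_BLOCK_STRENGTH = {s: 1.0 for s in STRATA}

_BACTERIAL_PHYLA = (
    "Bacillota",
    "Bacteroidota",
    "Pseudomonadota",
    "Verrucomicrobiota",
    "Actinomycetota",
    "Elusimicrobiota",
)
_BACTERIAL_PHYLUM_P = (0.34, 0.26, 0.18, 0.10, 0.08, 0.04)
_CAZYME_CLASS_P = {"GH": 0.40, "GT": 0.25, "CBM": 0.15, "CE": 0.10, "AA": 0.06, "PL": 0.04}

#: log-abundance penalty for an absent (non-occupied) bump taxon
_ABSENT_PENALTY = 9.0


@dataclass
class SynthConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the survey being emulated: 121 samples over
    1,400-4,400 m, 300 species, 20 planted responders in each
    direction with slope 1.5 log-units per km, a diversity peak at
    2,400 m, and correlation blocks densest in the mid stratum.
    """

    n_samples: int = 121
    altitude_range_m: tuple = (1400.0, 4400.0)
    n_taxa: int = 300
    n_monotone_up: int = 20
    n_monotone_down: int = 20
    monotone_effect: float = 1.5  # log-abundance slope per km
    diversity_peak_m: float = 2400.0
    diversity_peak_width_m: float = 500.0
    n_bump_taxa: int = 80  # bump amplitude: extra taxa active near the peak
    block_sizes_per_stratum: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_BLOCK_SIZES.items()})
    block_strength_per_stratum: dict = field(default_factory=lambda: dict(DEFAULT_BLOCK_STRENGTH))
    block_rho: float = 0.95  # target within-block correlation on the log scale
    noise_sd: float = 1.0  # lognormal dispersion
    depth: int = 100_000  # sequencing depth (multinomial total per sample)
    n_functions: int = 150
    n_function_up: int = 15
    n_function_down: int = 15
    length_range_bp: tuple = (300, 3000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_taxa <= 0 or self.depth <= 0:
            raise ValueError("n_samples, n_taxa, and depth must be positive")
        if self.n_monotone_up + self.n_monotone_down + self.n_bump_taxa > self.n_taxa:
            raise ValueError("planted taxa exceed n_taxa")
        if not 0.0 <= self.block_rho < 1.0:
            raise ValueError("block_rho must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive (degenerate config)")
        lo, hi = self.altitude_range_m
        if not lo < hi or lo < 1400.0:
            raise ValueError("invalid altitude range")
        if self.diversity_peak_width_m <= 0:
            raise ValueError("diversity_peak_width_m must be positive")
        unknown = set(self.block_sizes_per_stratum) - set(STRATA)
        if unknown:
            raise ValueError(f"unknown strata in block sizes: {sorted(unknown)}")
        total_block = sum(sum(v) for v in self.block_sizes_per_stratum.values())
        n_background = self.n_taxa - self.n_monotone_up - self.n_monotone_down - self.n_bump_taxa
        if total_block > n_background:
            raise ValueError(
                f"block sizes need {total_block} background taxa, only {n_background} available"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["altitude_range_m"] = list(self.altitude_range_m)
        d["length_range_bp"] = list(self.length_range_bp)
        return d


class SyntheticDataset(NamedTuple):
    sample_frame: pd.DataFrame
    counts: AbundanceTable
    functional: AbundanceTable
    ndvi: pd.Series
    truth: dict


def _lognormal_multinomial(rng, eta: np.ndarray, depth: int) -> np.ndarray:
    """Close per-sample log-abundances to proportions and draw counts."""
    eta = eta - eta.max(axis=0, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=0, keepdims=True)
    counts = np.empty_like(p, dtype=np.int64)
    for j in range(p.shape[1]):
        counts[:, j] = rng.multinomial(depth, p[:, j])
    return counts


def _make_lineage(rng, taxa: list[str]) -> tuple[pd.DataFrame, pd.Series]:
    domains = rng.choice(
        ["Bacteria", "Archaea", "Eukaryota", "Viruses"],
        size=len(taxa),
        p=[0.85, 0.05, 0.05, 0.05],
    )
    phyla = np.empty(len(taxa), dtype=object)
    bact = domains == "Bacteria"
    phyla[bact] = rng.choice(_BACTERIAL_PHYLA, size=int(bact.sum()), p=_BACTERIAL_PHYLUM_P)
    phyla[domains == "Archaea"] = "Euryarchaeota"
    phyla[domains == "Eukaryota"] = "Ascomycota"
    phyla[domains == "Viruses"] = "Uroviricota"
    fam_no = rng.integers(1, 4, size=len(taxa))
    families = np.array([f"{p}_fam{i}" for p, i in zip(phyla, fam_no)], dtype=object)
    gen_no = rng.integers(1, 3, size=len(taxa))
    genera = np.array([f"{f}_gen{i}" for f, i in zip(families, gen_no)], dtype=object)
    lineage = pd.DataFrame(
        {"phylum": phyla, "family": families, "genus": genera, "species": taxa},
        index=pd.Index(taxa, name="feature_id"),
    )
    return lineage, pd.Series(domains, index=lineage.index, name="domain")


def generate_dataset(config: SynthConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """Generate one seeded dataset: sample frame, species counts,
    functional (CAZyme) counts with lengths, and an NDVI series.

    Fully reproducible: the same config (including its seed) yields
    identical tables.  ``seed`` overrides ``config.seed``.
    """
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    lo, hi = cfg.altitude_range_m
    n, T = cfg.n_samples, cfg.n_taxa

    # stratified-uniform placement: one draw per equal-width slot, giving
    # even transect coverage with a uniform marginal over the range
    altitudes = lo + (np.arange(n) + rng.random(n)) * (hi - lo) / n
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    km = (altitudes - lo) / 1000.0

    taxa = [f"sp{i + 1:04d}" for i in range(T)]
    up = np.arange(cfg.n_monotone_up)
    down = np.arange(cfg.n_monotone_up, cfg.n_monotone_up + cfg.n_monotone_down)
    bump = np.arange(T - cfg.n_bump_taxa, T)
    background = np.setdiff1d(np.arange(T), np.concatenate([up, down, bump]))

    base = rng.normal(0.0, 1.0, size=T)
    eta = np.tile(base[:, None], (1, n))
    # monotone trend centred on the diversity peak: responders stay within a
    # realistic abundance envelope at both ends instead of dominating one end
    km_c = km - (cfg.diversity_peak_m - lo) / 1000.0
    eta[up] += cfg.monotone_effect * km_c[None, :]
    eta[down] -= cfg.monotone_effect * km_c[None, :]
    if cfg.n_bump_taxa:
        # independent Bernoulli presence with a Gaussian occupancy profile:
        # plants the richness bump without correlating bump taxa with each
        # other inside a stratum (occupancy noise dominates the shared trend)
        occupancy = np.exp(
            -((altitudes - cfg.diversity_peak_m) ** 2) / (2.0 * cfg.diversity_peak_width_m**2)
        )
        present = rng.random((cfg.n_bump_taxa, n)) < occupancy[None, :]
        eta[bump] += np.where(present, 0.0, -_ABSENT_PENALTY)

    # per-stratum latent-factor blocks on disjoint background taxa: rare,
    # low-dispersion members so blocks drive correlations, not dominance
    strata_of_samples = assign_stratum(altitudes)
    pool = rng.permutation(background)
    cursor = 0
    block_members: dict[str, list[list[int]]] = {}
    sigma_block = 0.5 * cfg.noise_sd
    c_load = sigma_block * np.sqrt(cfg.block_rho / (1.0 - cfg.block_rho)) if cfg.block_rho > 0 else 0.0
    block_set = []
    for stratum in STRATA:
        sizes = cfg.block_sizes_per_stratum.get(stratum, [])
        strength = float(cfg.block_strength_per_stratum.get(stratum, 1.0))
        in_stratum = strata_of_samples == stratum
        members_here = []
        for size in sizes:
            members = pool[cursor : cursor + size]
            cursor += size
            members_here.append([int(m) for m in members])
            block_set.extend(members)
            if c_load > 0 and in_stratum.any():
                f = rng.normal(0.0, 1.0, size=int(in_stratum.sum()))
                signs = rng.choice([-1.0, 1.0], size=size)
                loads = rng.uniform(0.8, 1.0, size=size)
                eta[np.ix_(members, np.where(in_stratum)[0])] += (
                    signs[:, None] * loads[:, None] * (strength * c_load) * f[None, :]
                )
        block_members[stratum] = members_here

    noise = rng.normal(0.0, cfg.noise_sd, size=(T, n))
    if block_set:
        block_idx = np.asarray(block_set, dtype=int)
        eta[block_idx] += -1.5 - base[block_idx][:, None]  # rare, fixed baseline
        noise[block_idx] *= 0.5  # tighter dispersion keeps block correlations clean
    eta += noise
    counts = _lognormal_multinomial(rng, eta, cfg.depth)

    lineage, domains = _make_lineage(rng, taxa)
    counts_table = AbundanceTable(
        data=pd.DataFrame(counts, index=lineage.index, columns=sample_ids),
        rank="species",
        lineage=lineage,
        domain_label=domains,
    )

    # functional (CAZyme-family) table with planted responders and lengths
    F = cfg.n_functions
    classes = rng.choice(list(_CAZYME_CLASS_P), size=F, p=list(_CAZYME_CLASS_P.values()))
    func_ids = pd.Index([f"{c}{i + 1}" for i, c in enumerate(classes)], name="feature_id")
    fbase = rng.normal(0.0, 1.0, size=F)
    feta = np.tile(fbase[:, None], (1, n))
    feta[: cfg.n_function_up] += cfg.monotone_effect * km[None, :]
    feta[cfg.n_function_up : cfg.n_function_up + cfg.n_function_down] -= cfg.monotone_effect * km[None, :]
    feta += rng.normal(0.0, cfg.noise_sd, size=(F, n))
    fcounts = _lognormal_multinomial(rng, feta, cfg.depth)
    lengths = pd.Series(
        rng.integers(cfg.length_range_bp[0], cfg.length_range_bp[1] + 1, size=F),
        index=func_ids,
        name="length_bp",
    )
    functional_table = AbundanceTable(
        data=pd.DataFrame(fcounts, index=func_ids, columns=sample_ids),
        rank="cazyme",
        lengths_bp=lengths,
    )

    # three-phase NDVI (decline, rise, decline) with breakpoints ~2300/3000 m
    ndvi_mean = np.piecewise(
        altitudes,
        [altitudes < 2300.0, (altitudes >= 2300.0) & (altitudes < 3000.0), altitudes >= 3000.0],
        [
            lambda a: 0.80 - 3.5e-4 * (a - lo),
            lambda a: 0.485 + 3.0e-4 * (a - 2300.0),
            lambda a: 0.695 - 3.8e-4 * (a - 3000.0),
        ],
    )
    ndvi = pd.Series(
        np.clip(ndvi_mean + rng.normal(0.0, 0.03, size=n), -1.0, 1.0),
        index=pd.Index(sample_ids, name="sample_id"),
        name="ndvi",
    )

    frame = make_sample_frame(sample_ids, altitudes, ndvi=ndvi.to_numpy())
    truth = {
        "monotone_up": [taxa[i] for i in up],
        "monotone_down": [taxa[i] for i in down],
        "bump_taxa": [taxa[i] for i in bump],
        "blocks": {s: [[taxa[i] for i in b] for b in bs] for s, bs in block_members.items()},
        "function_up": list(func_ids[: cfg.n_function_up]),
        "function_down": list(func_ids[cfg.n_function_up : cfg.n_function_up + cfg.n_function_down]),
        "ndvi_breakpoints_m": [2300.0, 3000.0],
    }
    return SyntheticDataset(frame, counts_table, functional_table, ndvi, truth)


def generate_piecewise_series(
    breakpoints,
    slopes,
    intercept: float,
    noise_sd: float,
    n: int,
    x_range=(1400.0, 4400.0),
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous piecewise-linear mean plus iid Gaussian noise.

    ``slopes`` has one more entry than ``breakpoints``; breakpoints must
    be sorted and strictly inside ``x_range``.
    """
    bps = np.asarray(breakpoints, dtype=float)
    slopes = np.asarray(slopes, dtype=float)
    lo, hi = float(x_range[0]), float(x_range[1])
    if n <= 0:
        raise ValueError("n must be positive")
    if bps.size + 1 != slopes.size:
        raise ValueError("need len(slopes) == len(breakpoints) + 1")
    if bps.size and (np.any(np.diff(bps) <= 0)):
        raise ValueError("breakpoints must be strictly increasing")
    if bps.size and (bps[0] <= lo or bps[-1] >= hi):
        raise ValueError("breakpoints must lie strictly inside x_range")
    rng = np.random.default_rng(seed)
    x = np.sort(rng.uniform(lo, hi, size=n))
    y = np.full(n, float(intercept)) + slopes[0] * (x - lo)
    for bp, ds in zip(bps, np.diff(slopes)):
        y += ds * np.maximum(0.0, x - bp)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    return x, y
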