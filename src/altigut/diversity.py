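"""Per-sample alpha diversity, phylum ratio, and functional normalisation.

Alpha diversity is computed from species-level abundances: observed
species S (count of taxa present), Shannon H = -sum p_i ln p_i (natural
log), and Pielou evenness J = H / ln S (undefined for S <= 1, reported
as NaN rather than raised).
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .io_meta import AbundanceTable, to_relative

CAZYME_CLASSES = ("AA", "CBM", "CE", "GH", "GT", "PL")
_CAZYME_RE = re.compile(r"^(CBM|AA|CE|GH|GT|PL)")


def observed_species(counts_column) -> int:
    """Number of features with strictly positive abundance."""
    x = np.asarray(counts_column, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative abundance")
    return int(np.count_nonzero(x > 0))


def shannon(counts_column) -> float:
    """Shannon diversity H = -sum p_i ln p_i over positive entries."""
    x = np.asarray(counts_column, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative abundance")
    total = x.sum()
    if total <= 0:
        raise ValueError("zero-sum abundance vector")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def pielou(counts_column) -> float:
    """Pielou evenness J = H / ln S; NaN when S <= 1 (undefined)."""
    s = observed_species(counts_column)
    if s <= 1:
        return float("nan")
    return shannon(counts_column) / np.log(s)


def alpha_diversity(table: AbundanceTable | pd.DataFrame) -> pd.DataFrame:
    """Observed species, Shannon, and Pielou for every sample column."""
    data = table.data if isinstance(table, AbundanceTable) else table
    rows = {}
    for sample in data.columns:
        col = data[sample].to_numpy(dtype=float)
        rows[sample] = {
            "observed_species": observed_species(col),
            "shannon": shannon(col),
            "pielou": pielou(col),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def bb_ratio(phylum_table: AbundanceTable, sample_id=None):
    """Bacillota/Bacteroidota ratio of relative abundances.

    Scale-invariant per sample (counts and proportions give the same
    value).  A zero Bacteroidota abundance yields NaN (flagged
    undefined), not an error; a missing phylum row is an error.
    """
    data = phylum_table.data
    for phylum in ("Bacillota", "Bacteroidota"):
        if phylum not in data.index:
            raise ValueError(f"phylum {phylum!r} missing from table")
    num = data.loc["Bacillota"].astype(float)
    den = data.loc["Bacteroidota"].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den
    ratio = ratio.where(den > 0, np.nan)
    ratio.name = "bb_ratio"
    if sample_id is not None:
        return float(ratio[sample_id])
    return ratio


def tpm_normalize(feature_counts, lengths_bp) -> np.ndarray:
    """Transcripts Per Million: length-normalised rates scaled to 1e6.

    tpm_i = (x_i / L_i) / sum_j (x_j / L_j) * 1e6.
    """
    x = np.asarray(feature_counts, dtype=float)
    L = np.asarray(lengths_bp, dtype=float)
    if np.any(L <= 0):
        raise ValueError("feature lengths must be positive")
    if np.any(x < 0):
        raise ValueError("negative counts")
    rate = x / L
    total = rate.sum()
    if total <= 0:
        raise ValueError("no positive counts; TPM undefined")
    return rate / total * 1e6


def tpm_table(table: AbundanceTable) -> AbundanceTable:
    """TPM-normalise every sample column of a functional table."""
    if table.lengths_bp is None:
        raise ValueError("table has no feature lengths; TPM needs lengths_bp")
    L = table.lengths_bp.to_numpy(dtype=float)
    cols = {s: tpm_normalize(table.data[s].to_numpy(dtype=float), L) for s in table.data.columns}
    out = pd.DataFrame(cols, index=table.data.index)
    return AbundanceTable(data=out, rank=table.rank, lineage=table.lineage,
                          lengths_bp=table.lengths_bp, domain_label=table.domain_label)


def cazyme_class_of(feature_id: str) -> str:
    m = _CAZYME_RE.match(str(feature_id))
    if m is None:
        raise ValueError(f"unknown CAZyme class for feature {feature_id!r}")
    return m.group(1)


def cazyme_class_totals(cazyme_tpm_table: AbundanceTable) -> pd.DataFrame:
    """Per-sample TPM totals by CAZyme class plus natural-log totals.

    Returns a long frame indexed by (class, sample) with columns
    ``total`` and ``log_e``; class 'ALL' is the overall total.  log_e
    uses a pseudocount of 1 only when the total is exactly 0 (so
    log_e(0) is reported as 0.0 and flagged), leaving positive totals
    untouched.
    """
    data = cazyme_tpm_table.data
    classes = pd.Series([cazyme_class_of(f) for f in data.index], index=data.index)
    totals = data.groupby(classes, sort=False).sum()
    totals = totals.reindex([c for c in CAZYME_CLASSES if c in totals.index])
    totals.loc["ALL"] = data.sum(axis=0)
    long = totals.stack().rename("total").reset_index()
    long.columns = ["cazyme_class", "sample_id", "total"]
    zero = long["total"] == 0
    # pseudocount 1 applied only to zero totals: log_e(0 + 1) = 0.0, flagged
    long["log_e"] = np.log(long["total"].where(~zero, 1.0))
    long["zero_flagged"] = zero
    return long.set_index(["cazyme_class", "sample_id"])


def phylum_relative_abundance(table: AbundanceTable, phylum: str) -> pd.Series:
    """Per-sample relative abundance of one phylum from a phylum-rank table."""
    rel = to_relative(table)
    if phylum not in rel.data.index:
        raise ValueError(f"phylum {phylum!r} missing from table")
    out = rel.data.loc[phylum].astype(float)
    out.name = phylum
    return out
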