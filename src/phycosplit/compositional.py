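"""Compositional preprocessing shared by every analysis stage.

Amplicon count tables are compositional: only relative abundances carry
information, and log-ratio methods require strictly positive entries.  This
module provides the canonical container for taxa x samples count data with
per-sample metadata (:class:`CountTable`), closure to relative abundance,
rare-taxon removal by a maximum-relative-abundance cutoff, the centered
log-ratio (CLR) transform with a pseudocount, and Shannon diversity.

Conventions used throughout the package:

* natural logarithm everywhere (diversity, CLR, divergences);
* the pseudocount is added *after* rare-taxon removal;
* Shannon diversity is computed on the unfiltered table, while ordination,
  attribution and enrichment operate on the rare-filtered table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "ClrMatrix",
    "DEFAULT_RARE_LOG_THRESHOLD",
    "DEFAULT_PSEUDOCOUNT",
    "relative_abundance",
    "remove_rare_taxa",
    "clr_transform",
    "shannon_diversity",
    "read_count_table",
]

#: log(max relative abundance) below which a taxon is considered absent
#: from the experiment; exp(-8.2) ~ 0.00027.
DEFAULT_RARE_LOG_THRESHOLD = -8.2

#: added to every count before the CLR transform to remove zeros.
DEFAULT_PSEUDOCOUNT = 1.0

SOILS = ("A", "B")
TREATMENTS = ("hybrid", "control")
GROWTH_PERIODS = (3, 6, 9, 12)

_META_COLUMNS = ["soil", "treatment", "growth_period_days", "round", "replicate"]


@dataclass
class CountTable:
    """Taxa x samples integer count matrix with per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by taxon id with one column per sample id;
        entries are nonnegative integers.
    samples
        DataFrame indexed by sample id with columns ``soil`` (A/B),
        ``treatment`` (hybrid/control), ``growth_period_days``, ``round``
        and ``replicate``.  Row order must match ``counts.columns``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate taxon ids: {dup}")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)[:5]}")
        self.samples = self.samples.loc[self.counts.columns]
        absent = [c for c in _META_COLUMNS if c not in self.samples.columns]
        if absent:
            raise ValueError(f"sample sheet lacks columns: {absent}")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")

    # -- convenience ----------------------------------------------------
    @property
    def taxon_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def select_samples(self, mask: pd.Series) -> "CountTable":
        """Return the sub-table for samples where ``mask`` is True."""
        ids = self.samples.index[mask.loc[self.samples.index]]
        return CountTable(self.counts[ids].copy(), self.samples.loc[ids].copy())

    def where(self, **conditions) -> "CountTable":
        """Filter samples by metadata equality, e.g. ``where(soil="B", treatment="hybrid")``.

        A condition value may be a list/tuple/set, interpreted as membership.
        """
        mask = pd.Series(True, index=self.samples.index)
        for key, value in conditions.items():
            col = self.samples[key]
            if isinstance(value, (list, tuple, set, frozenset)):
                mask &= col.isin(list(value))
            else:
                mask &= col == value
        return self.select_samples(mask)

    def write(self, counts_path: str | Path, samples_path: str | Path) -> None:
        """Write counts as TSV (taxa rows x sample columns) and the sample sheet as CSV."""
        self.counts.rename_axis("taxon_id").to_csv(counts_path, sep="\t")
        self.samples.rename_axis("sample_id").to_csv(samples_path)


@dataclass
class ClrMatrix:
    """Centered log-ratio transformed abundances (taxa x samples).

    Each sample (column) sums to zero: values are log abundances relative to
    the sample's geometric mean.  ``pseudocount`` and ``rare_log_threshold``
    record the provenance of the matrix.
    """

    values: pd.DataFrame
    pseudocount: float
    rare_log_threshold: float | None = None
    samples: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        colsum = self.values.sum(axis=0).to_numpy()
        if not np.allclose(colsum, 0.0, atol=1e-9):
            raise ValueError("CLR columns must sum to zero")

    @property
    def taxon_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Convert counts to per-sample relative abundances (columns sum to 1)."""
    totals = table.counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"samples with zero total counts: {zero}")
    return table.counts / totals


def remove_rare_taxa(
    table: CountTable,
    log_threshold: float = DEFAULT_RARE_LOG_THRESHOLD,
) -> tuple[CountTable, list]:
    """Drop taxa whose maximum relative abundance over all samples is below a cutoff.

    A taxon is removed when ``max_s p[taxon, s] < exp(log_threshold)``
    (strict inequality: a taxon exactly at the cutoff is retained).  The
    default ``exp(-8.2)`` corresponds to a relative abundance of 0.00027.

    Returns
    -------
    (filtered_table, dropped_taxa)
    """
    rel = relative_abundance(table)
    max_rel = rel.max(axis=1)
    keep = max_rel >= np.exp(log_threshold)
    if not keep.any():
        raise ValueError("rare-taxon filter removed every taxon")
    dropped = table.taxon_ids[~keep].tolist()
    filtered = CountTable(table.counts.loc[keep].copy(), table.samples.copy())
    return filtered, dropped


def clr_transform(
    table: CountTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    rare_log_threshold: float | None = None,
) -> ClrMatrix:
    """Centered log-ratio transform with a pseudocount.

    Per sample, ``x_i = ln((c_i + pseudocount) / g)`` where ``g`` is the
    geometric mean of the pseudocounted counts.  The transform is applied to
    counts directly; because CLR is scale-invariant the result equals the CLR
    of the (pseudocounted) relative abundances.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logc = np.log(table.counts.to_numpy(dtype=float) + pseudocount)
    clr = logc - logc.mean(axis=0, keepdims=True)
    values = pd.DataFrame(clr, index=table.taxon_ids, columns=table.sample_ids)
    return ClrMatrix(
        values,
        pseudocount=pseudocount,
        rare_log_threshold=rare_log_threshold,
        samples=table.samples.copy(),
    )


def shannon_diversity(table: CountTable) -> pd.Series:
    """Shannon diversity H = -sum_i p_i ln p_i per sample.

    Computed on the table as given (no rare-taxon removal, no pseudocount);
    zero-abundance taxa contribute nothing (0 * ln 0 := 0).
    """
    rel = relative_abundance(table).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(rel > 0, rel * np.log(rel), 0.0)
    return pd.Series(-terms.sum(axis=0), index=table.sample_ids, name="shannon")


def read_count_table(counts_path: str | Path, samples_path: str | Path) -> CountTable:
    """Read a taxa x samples TSV and its sample-sheet CSV into a :class:`CountTable`."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, index_col=0)
    return CountTable(counts, samples)
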