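"""Per-taxon attribution of community displacement along a principal axis.

The displacement of a community along a principal component between the
first and last sequenced dilution rounds is decomposed into per-taxon
contributions ``o_k = |x_start,k - x_end,k| * p_k`` where ``x`` are the
mean-centered CLR abundances (centered exactly as by the PCA fit) and
``p_k`` is the taxon's loading.  Medians over replicates give the
community-level contribution; taxa above a high percentile of the pooled
contribution distribution are selected as the drivers of that axis.

Because the printed contribution keeps the *signed* loading, the sign of a
principal axis (which is arbitrary) would flip every contribution; we
therefore orient the axis so that the group's total contribution is
nonnegative, and additionally report the fully sign-free diagnostic
``|x_start - x_end| * |p_k|``.

Driver sets from hybrid and control communities are compared with a
per-taxon Fisher's exact test under the null that selection is independent
of treatment, with Bonferroni correction across the selected taxa.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .compositional import ClrMatrix
from .ordination import PcaModel

__all__ = [
    "ContributionSet",
    "DriverSelection",
    "taxon_contributions",
    "select_drivers",
    "selection_overlap",
    "selection_independence_test",
    "bonferroni_cutoff",
]


@dataclass
class ContributionSet:
    """Per-taxon contributions to one community group's displacement along an axis.

    ``contributions`` is taxa x replicates (signed, oriented loading);
    ``medians`` its median over replicates; ``abs_medians`` the sign-free
    diagnostic; ``displacements`` the per-replicate projection displacement
    ``|<x_start - x_end, p>|``.
    """

    axis: int  # 1-based principal-component index
    group: dict
    contributions: pd.DataFrame
    medians: pd.Series
    abs_medians: pd.Series
    displacements: pd.Series
    orientation: int  # +1/-1 sign applied to the stored loadings
    round_start: int
    round_end: int


@dataclass
class DriverSelection:
    """Taxa whose median contribution exceeds the pooled percentile cutoff."""

    selected: set
    cutoff: float
    percentile: float
    per_group: dict = field(default_factory=dict)

    def __contains__(self, taxon) -> bool:
        return taxon in self.selected

    def __len__(self) -> int:
        return len(self.selected)


def taxon_contributions(
    pca: PcaModel,
    clr: ClrMatrix,
    axis: int,
    round_start: int = 2,
    round_end: int = 10,
    **group,
) -> ContributionSet:
    """Contribution of every taxon to a group's displacement along one axis.

    ``axis`` is 1-based (axis=2 attributes displacement along PC2).  The
    keyword filters (e.g. ``soil="B", treatment="hybrid",
    growth_period_days=12``) define the community group; every replicate in
    the group must have samples at both ``round_start`` and ``round_end``.
    """
    if clr.samples is None:
        raise ValueError("ClrMatrix must carry sample metadata")
    if not 1 <= axis <= pca.n_components:
        raise ValueError(f"axis must be in 1..{pca.n_components}")
    meta = clr.samples
    mask = pd.Series(True, index=meta.index)
    for key, value in group.items():
        mask &= meta[key] == value
    sub = meta[mask]
    if sub.empty:
        raise ValueError(f"no samples match group {group}")

    loading = pca.axis(axis - 1)
    centered = pca.centered(clr)

    deltas: dict = {}
    missing: list = []
    for rep, rep_meta in sub.groupby("replicate"):
        start_ids = rep_meta.index[rep_meta["round"] == round_start]
        end_ids = rep_meta.index[rep_meta["round"] == round_end]
        if len(start_ids) != 1 or len(end_ids) != 1:
            missing.append(rep)
            continue
        deltas[rep] = (
            centered[start_ids[0]] - centered[end_ids[0]]
        )
    if missing:
        raise ValueError(
            f"replicates missing round {round_start} or {round_end}: {missing}"
        )

    delta_df = pd.DataFrame(deltas)  # taxa x replicates
    abs_delta = delta_df.abs()
    # orient the axis so the group's summed contribution is nonnegative
    sign = float(np.sign((abs_delta.median(axis=1) * loading).sum()))
    orientation = int(sign) if sign != 0 else 1
    oriented = loading * orientation

    contributions = abs_delta.mul(oriented, axis=0)
    displacements = delta_df.mul(loading, axis=0).sum(axis=0).abs()
    return ContributionSet(
        axis=axis,
        group=dict(group),
        contributions=contributions,
        medians=contributions.median(axis=1),
        abs_medians=abs_delta.mul(loading.abs(), axis=0).median(axis=1),
        displacements=displacements,
        orientation=orientation,
        round_start=round_start,
        round_end=round_end,
    )


def select_drivers(
    contribs: ContributionSet | Sequence[ContributionSet],
    percentile: float = 97.5,
) -> DriverSelection:
    """Select taxa whose median contribution exceeds a pooled percentile cutoff.

    When several :class:`ContributionSet` objects are given (e.g. the
    communities of one growth period), their median contributions are pooled
    to form the cutoff distribution, and each group's taxa are selected
    against that common cutoff (strictly greater; ties at the cutoff are
    excluded).
    """
    if isinstance(contribs, ContributionSet):
        contribs = [contribs]
    pooled = pd.concat([c.medians for c in contribs])
    if pooled.index.nunique() < 40:
        warnings.warn(
            "percentile cutoff over fewer than 40 taxa is hardly meaningful",
            stacklevel=2,
        )
    cutoff = float(np.percentile(pooled.to_numpy(), percentile))
    per_group = {}
    selected: set = set()
    for c in contribs:
        chosen = set(c.medians.index[c.medians > cutoff])
        key = tuple(sorted(c.group.items()))
        per_group[key] = chosen
        selected |= chosen
    return DriverSelection(
        selected=selected, cutoff=cutoff, percentile=percentile, per_group=per_group
    )


def selection_overlap(a: set, b: set) -> dict:
    """Overlap report for two driver-taxon sets.

    ``percent_in_common`` is ``100 * |a & b| / min(|a|, |b|)``; undefined
    (None) when both sets are empty.
    """
    a, b = set(a), set(b)
    inter = a & b
    union = a | b
    if not a and not b:
        return {
            "intersection": 0,
            "union": 0,
            "percent_in_common": None,
            "note": "both selections empty; overlap undefined",
        }
    denom = min(len(a), len(b)) if a and b else 0
    pct = 100.0 * len(inter) / denom if denom else 0.0
    return {"intersection": len(inter), "union": len(union), "percent_in_common": pct}


def bonferroni_cutoff(alpha: float, n_tests: int) -> float:
    """Family-wise corrected per-test significance cutoff ``alpha / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def selection_independence_test(
    selected: Iterable,
    hybrid_selections: Sequence[set],
    control_selections: Sequence[set],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float, set]:
    """Fisher's exact test of whether driver selection depends on treatment.

    For each taxon in ``selected`` a 2x2 table of community counts is built:
    rows are treatment (hybrid / control), columns are whether that
    community's selection contains the taxon.  Two-sided p-values come from
    the hypergeometric distribution of the table (Fisher's exact test);
    tables with a degenerate margin (taxon in all or no communities) carry
    no information and are assigned p = 1 with a flag.

    Returns ``(per-taxon results, Bonferroni cutoff, significant taxa)``.
    """
    if not hybrid_selections or not control_selections:
        raise ValueError("need at least one hybrid and one control selection")
    selected = sorted(set(selected))
    if not selected:
        raise ValueError("no selected taxa to test")
    cutoff = bonferroni_cutoff(alpha, len(selected))
    rows = {}
    for taxon in selected:
        h_in = sum(taxon in s for s in hybrid_selections)
        c_in = sum(taxon in s for s in control_selections)
        h_out = len(hybrid_selections) - h_in
        c_out = len(control_selections) - c_in
        table = np.array([[h_in, h_out], [c_in, c_out]])
        degenerate = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
        if degenerate:
            p = 1.0
        else:
            _, p = stats.fisher_exact(table, alternative="two-sided")
        rows[taxon] = {
            "hybrid_in": h_in,
            "hybrid_out": h_out,
            "control_in": c_in,
            "control_out": c_out,
            "p_value": float(p),
            "degenerate": bool(degenerate),
        }
    results = pd.DataFrame.from_dict(rows, orient="index")
    significant = set(results.index[results["p_value"] < cutoff])
    return results, cutoff, significant
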