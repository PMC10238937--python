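"""Jensen-Shannon divergence and distributional comparisons between communities.

Communities are compared as probability distributions over taxa.  The JSD
with equal weights and natural log is symmetric and bounded by ln 2.  The
inter/intra bootstrap test asks whether hybrid communities are farther from
control communities than hybrid replicates are from each other: it
bootstraps the two sets of pairwise divergences and reports the probability
that the difference of medians (inter minus intra) is <= 0.  Shannon
diversity distributions across treatments are compared with a two-sample
Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats

from .compositional import CountTable

__all__ = ["DivergenceTest", "jsd", "hybrid_control_separation", "ks_compare"]

LN2 = float(np.log(2.0))


def _entropy(p: np.ndarray) -> float:
    # natural log, 0 * ln 0 := 0
    return float(stats.entropy(p))


def jsd(
    x: np.ndarray, y: np.ndarray, w1: float = 0.5, w2: float = 0.5
) -> float:
    """Weighted Jensen-Shannon divergence between two compositions.

    ``J = H(w1 x + w2 y) - w1 H(x) - w2 H(y)`` with Shannon entropy in nats.
    With equal weights the value lies in [0, ln 2].  Inputs must be
    nonnegative and sum to 1; weights must sum to 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("compositions must be nonnegative")
    if not (np.isclose(x.sum(), 1.0, atol=1e-8) and np.isclose(y.sum(), 1.0, atol=1e-8)):
        raise ValueError("compositions must each sum to 1")
    if not np.isclose(w1 + w2, 1.0):
        raise ValueError("weights must sum to 1")
    mix = w1 * x + w2 * y
    return _entropy(mix) - w1 * _entropy(x) - w2 * _entropy(y)


@dataclass
class DivergenceTest:
    """Inter/intra JSD sets and the bootstrap difference-of-medians test."""

    inter_distances: np.ndarray
    intra_distances: np.ndarray
    d_samples: np.ndarray
    p_value: float
    d_observed: float


def _compositions(table: CountTable, pseudocount: float) -> pd.DataFrame:
    cts = table.counts + pseudocount
    return cts / cts.sum(axis=0)


def hybrid_control_separation(
    table: CountTable,
    soil: str,
    growth_period_days: int,
    round: int,
    n_boot: int = 1000,
    seed: int | None = None,
    pseudocount: float = 1.0,
) -> DivergenceTest:
    """Bootstrap test of hybrid-control separation at one experimental cell.

    Inter distances are the JSDs between every hybrid-control pair at the
    given (soil, growth period, round); intra distances are the JSDs between
    distinct hybrid replicates.  Both sets are resampled with replacement
    ``n_boot`` times and ``d = median(inter*) - median(intra*)`` recorded;
    the one-sided p-value is the bootstrap probability that ``d <= 0``
    (null: hybrids are no farther from controls than from each other).
    """
    cell = table.where(soil=soil, growth_period_days=growth_period_days, round=round)
    hyb_ids = cell.samples.index[cell.samples["treatment"] == "hybrid"]
    ctl_ids = cell.samples.index[cell.samples["treatment"] == "control"]
    if len(hyb_ids) < 2:
        raise ValueError("need at least two hybrid replicates for intra distances")
    if len(ctl_ids) < 1:
        raise ValueError("need at least one control replicate")
    comp = _compositions(cell, pseudocount)
    inter = np.array(
        [jsd(comp[h].to_numpy(), comp[c].to_numpy()) for h, c in product(hyb_ids, ctl_ids)]
    )
    intra = np.array(
        [jsd(comp[a].to_numpy(), comp[b].to_numpy()) for a, b in combinations(hyb_ids, 2)]
    )
    rng = np.random.default_rng(seed)
    d_samples = np.empty(n_boot)
    for b in range(n_boot):
        d_samples[b] = np.median(rng.choice(inter, inter.size)) - np.median(
            rng.choice(intra, intra.size)
        )
    return DivergenceTest(
        inter_distances=inter,
        intra_distances=intra,
        d_samples=d_samples,
        p_value=float(np.mean(d_samples <= 0)),
        d_observed=float(np.median(inter) - np.median(intra)),
    )


def ks_compare(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test (statistic, p-value)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two observations")
    res = stats.ks_2samp(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
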