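"""Synthetic serial-dilution community data with planted ground truth.

Generates count tables, growth curves and trait matrices with the
statistical structure the analysis pipeline assumes, so that every stage can
be tested against a known answer.  The experimental design emulated is:

* two soil source pools (A and B) with distinct taxon compositions;
* "hybrid" communities grown with an alga and "control" communities without;
* growth periods (days between dilutions) of 3, 6, 9 and 12 days, ten
  64-fold serial dilutions, sequencing after every other round (2..10);
* 5 hybrid replicates per soil, 3 (soil A) or 2 (soil B) controls.

The latent model is log-linear: per-sample log abundances are a soil-specific
log-normal baseline, plus a shared dilution-driven drift slope per round
(the abiotic axis, common to all treatments), plus an algal suppression term
applied to a planted set of soil-B taxa in hybrid communities (the biotic
axis), plus replicate and sample noise; counts are then multinomial at fixed
sequencing depth.  Algal exposure scales as ``max(0, tau - 3) / 9`` so that
3-day hybrids are essentially unaffected (the alga only saturates after
about 3 days) while 12-day hybrids feel the full effect.

There is no mechanistic consumer-resource dynamics here: the generator
plants exactly the statistical signatures (a drift direction, a convergent
suppression direction, a linear trait-to-enrichment map) that the pipeline
is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compositional import CountTable, GROWTH_PERIODS
from .traits import GrowthCurve, UtilizationMatrix

__all__ = [
    "DesignSpec",
    "GroundTruth",
    "make_ground_truth",
    "simulate_counts",
    "simulate_growth_curves",
    "simulate_trait_data",
]

SEQUENCED_ROUNDS = (2, 4, 6, 8, 10)


@dataclass
class DesignSpec:
    """Shape of the simulated enrichment experiment."""

    n_taxa: int = 400
    growth_periods: tuple[int, ...] = GROWTH_PERIODS
    sequenced_rounds: tuple[int, ...] = SEQUENCED_ROUNDS
    n_hybrid_reps: int = 5
    n_control_reps: dict = field(default_factory=lambda: {"A": 3, "B": 2})
    depth: int = 20_000
    seed: int = 0
    soils: tuple[str, ...] = ("A", "B")

    def __post_init__(self) -> None:
        if self.n_taxa < 1 or self.n_hybrid_reps < 1 or self.depth < 1:
            raise ValueError("all counts must be >= 1")
        if any(v < 1 for v in self.n_control_reps.values()):
            raise ValueError("all counts must be >= 1")
        if list(self.sequenced_rounds) != sorted(set(self.sequenced_rounds)):
            raise ValueError("sequenced_rounds must be strictly increasing")
        if self.depth < 10 * self.n_taxa:
            raise ValueError(
                f"depth {self.depth} too small to represent {self.n_taxa} taxa "
                f"(need >= {10 * self.n_taxa})"
            )

    @property
    def taxon_ids(self) -> pd.Index:
        width = len(str(self.n_taxa))
        return pd.Index([f"OTU{i + 1:0{width}d}" for i in range(self.n_taxa)])


@dataclass
class GroundTruth:
    """Planted structure underlying a simulated dataset.

    ``suppressed_set`` are soil-B-pool taxa whose log abundance declines by
    ``suppression_slope`` per dilution round (scaled by algal exposure) in
    hybrid communities; ``drift_vector`` is the per-taxon log slope per round
    shared by every community; ``soil_log_baseline`` holds the per-soil
    latent log abundances; ``utilization`` and ``beta_true``/``beta0`` define
    the planted linear map from carbon-utilization profiles to enrichment
    rates.
    """

    suppressed_set: list
    drift_vector: pd.Series
    suppression_slope: float
    soil_log_baseline: pd.DataFrame
    utilization: UtilizationMatrix
    beta_true: pd.Series
    beta0: float
    replicate_sd: float = 0.25
    sample_sd: float = 0.10

    def exposure(self, growth_period_days: float) -> float:
        """Algal exposure weight: ``(tau - 3) / 9`` for tau >= 9, else 0.

        The alga needs about 3 days to saturate after each dilution, so only
        long growth periods leave a post-saturation window in which exudates
        shape the bacteria; short growth periods (3 and 6 days) are treated
        as unexposed, matching the regime where communities do not converge.
        """
        if growth_period_days < 9:
            return 0.0
        return (growth_period_days - 3.0) / 9.0

    def to_dict(self) -> dict:
        return {
            "suppressed_set": list(self.suppressed_set),
            "drift_vector": self.drift_vector.to_dict(),
            "suppression_slope": self.suppression_slope,
            "beta_true": self.beta_true.to_dict(),
            "beta0": self.beta0,
        }


def make_ground_truth(
    design: DesignSpec,
    n_suppressed: int = 8,
    n_soil_b_specific: int = 10,
    suppression_slope: float = 0.35,
    drift_sd: float = 0.10,
    baseline_sd: float = 1.5,
    soil_b_boost: float = 1.3,
    n_isolates: int = 21,
    n_carbon_sources: int = 7,
    utilization_p: float = 0.45,
    beta_scale: tuple[float, ...] = (0.06, -0.05, 0.04),
    beta0: float = 0.02,
) -> GroundTruth:
    """Draw a ground truth consistent with ``design`` (seeded from it).

    Soil pools share a heavy-tailed (log-normal) baseline; a small set of
    taxa is made soil-B specific (boosted in B, depressed in A), and the
    planted suppressed set is a subset of those, so that algal suppression
    moves soil-B hybrid communities toward soil A (convergence) along a
    single latent direction rather than adding an extra soil axis.
    """
    if n_suppressed > n_soil_b_specific:
        raise ValueError("suppressed set must fit inside the soil-B-specific set")
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 1]))
    taxa = design.taxon_ids

    base = rng.normal(0.0, baseline_sd, design.n_taxa)
    baseline = pd.DataFrame(
        {s: base.copy() for s in design.soils}, index=taxa, dtype=float
    )
    b_specific = rng.choice(design.n_taxa, size=n_soil_b_specific, replace=False)
    baseline.iloc[b_specific, baseline.columns.get_loc("B")] += soil_b_boost
    baseline.iloc[b_specific, baseline.columns.get_loc("A")] -= soil_b_boost

    # suppress the more abundant members of the soil-B pool: taxa near the
    # count floor would saturate the CLR and carry no recoverable signal
    by_abundance = b_specific[np.argsort(base[b_specific])[::-1]]
    suppressed = taxa[np.sort(by_abundance[:n_suppressed])].tolist()
    drift = pd.Series(rng.normal(0.0, drift_sd, design.n_taxa), index=taxa)

    sources = pd.Index([f"carbon_{j + 1}" for j in range(n_carbon_sources)])
    g = pd.DataFrame(
        rng.binomial(1, utilization_p, size=(n_isolates, n_carbon_sources)),
        index=pd.Index([f"isolate_{i + 1:02d}" for i in range(n_isolates)]),
        columns=sources,
    )
    beta = pd.Series(0.0, index=sources)
    support = rng.choice(n_carbon_sources, size=len(beta_scale), replace=False)
    beta.iloc[support] = beta_scale

    return GroundTruth(
        suppressed_set=suppressed,
        drift_vector=drift,
        suppression_slope=suppression_slope,
        soil_log_baseline=baseline,
        utilization=UtilizationMatrix(g=g),
        beta_true=beta,
        beta0=beta0,
    )


def latent_log_abundance(
    truth: GroundTruth,
    soil: str,
    treatment: str,
    growth_period_days: int,
    round_index: int,
) -> pd.Series:
    """Noise-free latent log abundance for one experimental cell.

    Exposes the generative mean so recovery tests can check monotonicity and
    effect directions against the model actually sampled from.
    """
    lam = truth.soil_log_baseline[soil] + round_index * truth.drift_vector
    if treatment == "hybrid":
        expo = truth.exposure(growth_period_days)
        lam = lam.copy()
        lam.loc[truth.suppressed_set] -= truth.suppression_slope * expo * round_index
    return lam


def simulate_counts(design: DesignSpec, truth: GroundTruth) -> CountTable:
    """Sample a full count table (one sample per soil/treatment/tau/round/replicate).

    Counts are multinomial at ``design.depth`` around softmax of the latent
    log abundances; replicate identity contributes a per-taxon offset held
    fixed across rounds so that replicate trajectories are coherent.
    Bit-identical for a fixed ``design.seed``.
    """
    missing = set(truth.soil_log_baseline.index) - set(design.taxon_ids)
    if missing:
        raise ValueError("ground-truth taxa must be a subset of the design's taxa")
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 2]))
    taxa = design.taxon_ids

    columns: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    for soil in design.soils:
        for treatment in ("hybrid", "control"):
            n_reps = (
                design.n_hybrid_reps
                if treatment == "hybrid"
                else design.n_control_reps[soil]
            )
            for tau in design.growth_periods:
                for rep in range(1, n_reps + 1):
                    rep_offset = rng.normal(0.0, truth.replicate_sd, design.n_taxa)
                    for rnd in design.sequenced_rounds:
                        lam = latent_log_abundance(
                            truth, soil, treatment, tau, rnd
                        ).to_numpy()
                        lam = lam + rep_offset + rng.normal(
                            0.0, truth.sample_sd, design.n_taxa
                        )
                        p = np.exp(lam - lam.max())
                        p /= p.sum()
                        counts = rng.multinomial(design.depth, p)
                        sid = f"{soil}_{treatment}_t{tau}_r{rnd:02d}_rep{rep}"
                        columns[sid] = counts
                        meta_rows.append(
                            {
                                "sample_id": sid,
                                "soil": soil,
                                "treatment": treatment,
                                "growth_period_days": tau,
                                "round": rnd,
                                "replicate": rep,
                            }
                        )
    counts_df = pd.DataFrame(columns, index=taxa)
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    return CountTable(counts_df, samples)


def simulate_growth_curves(
    n_points: int = 50,
    lag: float = 12.0,
    rate: float = 0.25,
    capacity: float = 1e7,
    noise_sd: float = 0.0,
    seed: int = 0,
    n0: float | None = None,
    t_max: float | None = None,
    co_lag_factor: float = 1.0,
    co_rate_factor: float = 1.0,
    co_capacity_factor: float = 1.0,
) -> tuple[GrowthCurve, GrowthCurve]:
    """Logistic mono- and co-culture growth curves on shared time points.

    The co-culture curve applies multiplicative changes to lag, rate and
    carrying capacity; with all factors 1 and ``noise_sd`` 0 the two curves
    are identical (downstream AUC ratio exactly 1).  Noise is multiplicative
    log-normal with standard deviation ``noise_sd`` on the log scale.
    """
    if min(n_points, lag, rate, capacity) <= 0 or noise_sd < 0:
        raise ValueError("parameters must be positive (noise_sd nonnegative)")
    if n0 is None:
        n0 = capacity / 1e4
    if t_max is None:
        t_max = lag + (np.log(capacity / n0) + 4.0) / rate
    times = np.linspace(0.0, t_max, n_points)
    rng = np.random.default_rng(seed)

    def logistic(lag_, rate_, cap_):
        g = np.exp(rate_ * np.maximum(0.0, times - lag_))
        vals = cap_ * n0 * g / (cap_ + n0 * (g - 1.0))
        if noise_sd > 0:
            vals = vals * np.exp(rng.normal(0.0, noise_sd, vals.size))
        return vals

    mono = GrowthCurve(times, logistic(lag, rate, capacity), label="mono")
    co = GrowthCurve(
        times,
        logistic(lag * co_lag_factor, rate * co_rate_factor, capacity * co_capacity_factor),
        label="co",
    )
    return mono, co


def simulate_trait_data(
    truth: GroundTruth,
    n_isolates: int | None = None,
    noise_sd: float = 0.035,
    seed: int = 0,
) -> tuple[UtilizationMatrix, pd.Series]:
    """Enrichment rates generated from the planted trait model.

    ``r = beta0 + G beta_true + eps`` with Gaussian noise of standard
    deviation ``noise_sd`` (CLR units per sequenced-round step).  The
    default noise level places the typical cross-validated held-out R^2 of
    the planted model, at the default isolate count, in the weak-but-real
    predictability regime (roughly 0.3-0.4) that the analysis targets.
    """
    g = truth.utilization
    if n_isolates is not None and g.g.shape[0] != n_isolates:
        raise ValueError(
            f"utilization has {g.g.shape[0]} isolates, expected {n_isolates}"
        )
    rng = np.random.default_rng(seed)
    r = (
        truth.beta0
        + g.g.to_numpy(dtype=float) @ truth.beta_true.to_numpy()
        + rng.normal(0.0, noise_sd, g.g.shape[0])
    )
    return g, pd.Series(r, index=g.isolates, name="enrichment_rate")
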