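"""End-to-end orchestration: preprocess -> diversity -> PCA -> attribution ->
enrichment -> divergence (-> traits), with seeded stages and a JSON report.

The stage order mirrors the analysis the package implements: Shannon
diversity is computed on the unfiltered table; everything downstream runs on
the rare-filtered, pseudocounted, CLR-transformed table; a single PCA is fit
jointly over all samples and per-condition analyses are views of that one
model, never refits.  Driver attribution is only performed along components
the permutation test finds significant.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import attribution, divergence, enrichment, ordination
from .compositional import (
    CountTable,
    clr_transform,
    read_count_table,
    remove_rare_taxa,
    shannon_diversity,
    DEFAULT_PSEUDOCOUNT,
    DEFAULT_RARE_LOG_THRESHOLD,
    GROWTH_PERIODS,
    SOILS,
    TREATMENTS,
)

__all__ = ["PipelineConfig", "PipelineError", "validate_inputs", "analyze", "run_full"]

logger = logging.getLogger("phycosplit")

# named sub-seed channels so each stochastic stage draws independently
_SEED_CHANNELS = {"permutation": 11, "divergence": 13, "convergence": 17, "traits": 19}


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Flat, file-round-trippable configuration for a full pipeline run."""

    counts_path: str = ""
    samples_path: str = ""
    output_dir: str = "phycosplit_out"
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    rare_log_threshold: float = DEFAULT_RARE_LOG_THRESHOLD
    percentile: float = 97.5
    n_perm: int = 200
    n_boot: int = 1000
    alpha: float = 0.05
    seed: int = 0
    traits_path: str | None = None
    enrichment_path: str | None = None

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")
        if self.n_perm < 1 or self.n_boot < 1:
            raise ValueError("n_perm and n_boot must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def stage_seed(self, stage: str) -> int:
        return int(
            np.random.SeedSequence([self.seed, _SEED_CHANNELS[stage]]).generate_state(1)[0]
            % (2**31)
        )


def validate_inputs(counts_path: str | Path, samples_path: str | Path) -> list[dict]:
    """Schema checks on a counts TSV and sample-sheet CSV; returns an issue list."""
    issues: list[dict] = []
    try:
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, index_col=0)
    except (OSError, pd.errors.ParserError) as exc:
        raise PipelineError("validate", f"unreadable input: {exc}") from exc

    arr = counts.to_numpy()
    bad = np.argwhere(~(np.isfinite(arr) & (arr >= 0) & (arr == np.round(arr))))
    for i, j in bad[:20]:
        issues.append(
            {
                "severity": "error",
                "message": f"count at taxon {counts.index[i]!r}, sample "
                f"{counts.columns[j]!r} is not a nonnegative integer ({arr[i, j]})",
            }
        )
    for sid in counts.columns:
        if sid not in samples.index:
            issues.append(
                {"severity": "error", "message": f"sample {sid!r} missing from sample sheet"}
            )
    required = ["soil", "treatment", "growth_period_days", "round", "replicate"]
    for col in required:
        if col not in samples.columns:
            issues.append(
                {"severity": "error", "message": f"sample sheet lacks column {col!r}"}
            )
    present = [c for c in required if c in samples.columns]
    for sid, row in samples.iterrows():
        for col in present:
            if pd.isna(row[col]):
                issues.append(
                    {"severity": "error", "message": f"sample {sid!r} missing {col}"}
                )
    if "soil" in samples.columns:
        bad_soil = set(samples["soil"].dropna()) - set(SOILS)
        if bad_soil:
            issues.append(
                {"severity": "error", "message": f"unknown soil levels: {sorted(bad_soil)}"}
            )
    if "treatment" in samples.columns:
        bad_t = set(samples["treatment"].dropna()) - set(TREATMENTS)
        if bad_t:
            issues.append(
                {"severity": "error", "message": f"unknown treatments: {sorted(bad_t)}"}
            )
    if "growth_period_days" in samples.columns:
        bad_g = set(samples["growth_period_days"].dropna()) - set(GROWTH_PERIODS)
        if bad_g:
            issues.append(
                {
                    "severity": "error",
                    "message": f"unknown growth periods: {sorted(bad_g)}",
                }
            )
    if not issues and set(present) == set(required):
        grouped = samples.groupby(
            ["soil", "treatment", "growth_period_days", "replicate"]
        )["round"].nunique()
        for key, n in grouped.items():
            if n < 2:
                issues.append(
                    {
                        "severity": "warning",
                        "message": f"group {key} covers fewer than two sequenced rounds",
                    }
                )
    return issues


# ---------------------------------------------------------------------------


def _diversity_stage(table: CountTable, final_round: int) -> dict:
    """Shannon diversity plus KS comparisons of its distributions."""
    shannon = shannon_diversity(table)
    meta = table.samples
    out: dict = {"per_sample_median": float(shannon.median()), "ks_tests": {}}

    def pool(treatment: str, tau: int) -> np.ndarray:
        ids = meta.index[
            (meta["treatment"] == treatment)
            & (meta["growth_period_days"] == tau)
            & (meta["round"] == final_round)
        ]
        return shannon.loc[ids].to_numpy()

    taus = sorted(meta["growth_period_days"].unique())
    for tau in taus:
        h, c = pool("hybrid", tau), pool("control", tau)
        if h.size >= 2 and c.size >= 2:
            stat, p = divergence.ks_compare(h, c)
            out["ks_tests"][f"hybrid_vs_control_tau{tau}"] = {"statistic": stat, "p": p}
    if len(taus) >= 2:
        h_short, h_long = pool("hybrid", taus[0]), pool("hybrid", taus[-1])
        if h_short.size >= 2 and h_long.size >= 2:
            stat, p = divergence.ks_compare(h_short, h_long)
            out["ks_tests"][f"hybrid_tau{taus[0]}_vs_tau{taus[-1]}"] = {
                "statistic": stat,
                "p": p,
            }
    return out


def _pc1_driver_stage(
    pca: ordination.PcaModel,
    clr,
    config: PipelineConfig,
    first_round: int,
    final_round: int,
) -> dict:
    """Per-replicate PC1 selections and the treatment-independence test."""
    meta = clr.samples
    out: dict = {}
    for tau in sorted(meta["growth_period_days"].unique()):
        groups = {}
        for soil in sorted(meta["soil"].unique()):
            for treatment in TREATMENTS:
                sel = meta[
                    (meta["soil"] == soil)
                    & (meta["treatment"] == treatment)
                    & (meta["growth_period_days"] == tau)
                ]
                if sel.empty:
                    continue
                groups[(soil, treatment)] = attribution.taxon_contributions(
                    pca, clr, axis=1, round_start=first_round, round_end=final_round,
                    soil=soil, treatment=treatment, growth_period_days=tau,
                )
        if not groups:
            continue
        # pooled per-replicate contribution distribution for this growth period
        pooled = np.concatenate(
            [c.contributions.to_numpy().ravel() for c in groups.values()]
        )
        cutoff = float(np.percentile(pooled, config.percentile))
        per_soil: dict = {}
        for soil in sorted({s for s, _ in groups}):
            hyb_sets, ctl_sets = [], []
            for (s, treatment), contrib in groups.items():
                if s != soil:
                    continue
                for rep in contrib.contributions.columns:
                    col = contrib.contributions[rep]
                    chosen = set(col.index[col > cutoff])
                    (hyb_sets if treatment == "hybrid" else ctl_sets).append(chosen)
            selected = set().union(*hyb_sets, *ctl_sets) if (hyb_sets or ctl_sets) else set()
            entry: dict = {"n_selected": len(selected)}
            if selected and hyb_sets and ctl_sets:
                results, bcut, significant = attribution.selection_independence_test(
                    selected, hyb_sets, ctl_sets, alpha=config.alpha
                )
                entry.update(
                    {
                        "bonferroni_cutoff": bcut,
                        "n_treatment_specific": len(significant),
                        "treatment_specific": sorted(significant),
                    }
                )
            per_soil[soil] = entry
        out[f"tau{tau}"] = {"cutoff": cutoff, "per_soil": per_soil}
    return out


def analyze(
    table: CountTable,
    config: PipelineConfig,
    traits: "pd.DataFrame | None" = None,
    trait_enrichment: "pd.Series | None" = None,
) -> dict:
    """Run the full statistical analysis on an in-memory count table.

    Returns a JSON-serializable report; see :func:`run_full` for the
    file-based entry point.  ``traits``/``trait_enrichment`` optionally feed
    the LASSO stage.
    """
    report: dict = {"config": dataclasses.asdict(config)}
    meta = table.samples
    rounds = sorted(int(r) for r in meta["round"].unique())
    first_round, final_round = rounds[0], rounds[-1]
    taus = sorted(int(t) for t in meta["growth_period_days"].unique())

    logger.info("[diversity] %d samples, %d taxa", table.n_samples, table.n_taxa)
    report["diversity"] = _diversity_stage(table, final_round)

    try:
        filtered, dropped = remove_rare_taxa(table, config.rare_log_threshold)
    except ValueError as exc:
        raise PipelineError("preprocess", str(exc)) from exc
    report["preprocess"] = {
        "n_taxa_input": table.n_taxa,
        "n_taxa_retained": filtered.n_taxa,
        "n_taxa_dropped": len(dropped),
        "rare_log_threshold": config.rare_log_threshold,
        "pseudocount": config.pseudocount,
    }
    logger.info("[preprocess] retained %d/%d taxa", filtered.n_taxa, table.n_taxa)

    clr = clr_transform(
        filtered, pseudocount=config.pseudocount,
        rare_log_threshold=config.rare_log_threshold,
    )
    try:
        pca = ordination.fit_pca(clr)
    except ValueError as exc:
        raise PipelineError("ordination", str(exc)) from exc
    n_sig, spectra = ordination.permutation_significance(
        filtered,
        n_perm=config.n_perm,
        seed=config.stage_seed("permutation"),
        alpha=config.alpha,
        pseudocount=config.pseudocount,
    )
    pca.n_significant = n_sig
    pca.permutation_spectra = spectra
    report["ordination"] = {
        "variance_fractions": pca.variance_fractions[:10].tolist(),
        "pc1_variance_pct": float(100 * pca.variance_fractions[0]),
        "pc2_variance_pct": float(100 * pca.variance_fractions[1]),
        "n_significant": n_sig,
    }
    logger.info("[ordination] %d significant components", n_sig)

    # attribution and enrichment run only along axes the permutation test supports
    report["attribution"] = {}
    report["enrichment"] = {}
    if n_sig >= 2:
        pc2_sets = {}
        for tau in [t for t in taus if t >= 9]:
            try:
                contrib = attribution.taxon_contributions(
                    pca, clr, axis=2, round_start=first_round, round_end=final_round,
                    soil="B", treatment="hybrid", growth_period_days=tau,
                )
            except ValueError as exc:
                raise PipelineError("attribution", str(exc)) from exc
            pc2_sets[tau] = attribution.select_drivers(contrib, config.percentile)
        report["attribution"]["pc2_drivers"] = {
            f"tau{tau}": sorted(sel.selected) for tau, sel in pc2_sets.items()
        }
        if len(pc2_sets) >= 2:
            t_a, t_b = sorted(pc2_sets)[-2:]
            report["attribution"]["pc2_overlap"] = attribution.selection_overlap(
                pc2_sets[t_a].selected, pc2_sets[t_b].selected
            )
        for tau, sel in pc2_sets.items():
            if not sel.selected:
                continue
            try:
                records = enrichment.enrichment_rates(
                    clr, soil="B", growth_period_days=tau, taxa=sorted(sel.selected)
                )
            except ValueError as exc:
                raise PipelineError("enrichment", str(exc)) from exc
            classified = enrichment.quadrant_classify(records)
            suppressed = classified[
                classified["quadrant"].isin(["II", "III"]) & classified["above_diagonal"]
            ]
            report["enrichment"][f"tau{tau}"] = {
                "records": classified.reset_index()
                .rename(columns={"index": "taxon_id"})
                .to_dict(orient="records"),
                "quadrant_counts": classified["quadrant"].value_counts().to_dict(),
                "fraction_suppressed_side": float(len(suppressed) / len(classified)),
            }
    if n_sig >= 1:
        report["attribution"]["pc1_drivers"] = _pc1_driver_stage(
            pca, clr, config, first_round, final_round
        )

    report["divergence"] = {"separation": {}, "convergence": {}}
    div_seed = config.stage_seed("divergence")
    conv_seed = config.stage_seed("convergence")
    for i, tau in enumerate(taus):
        for soil in sorted(meta["soil"].unique()):
            try:
                test = divergence.hybrid_control_separation(
                    table, soil=soil, growth_period_days=tau, round=final_round,
                    n_boot=config.n_boot, seed=div_seed + i,
                    pseudocount=config.pseudocount,
                )
            except ValueError:
                continue
            report["divergence"]["separation"][f"{soil}_tau{tau}"] = {
                "p_value": test.p_value,
                "d_observed": test.d_observed,
            }
        if n_sig >= 2:
            conv = soil_convergence(
                pca, meta, growth_period_days=tau, axis=2,
                first_round=first_round, final_round=final_round,
                n_boot=config.n_boot, seed=conv_seed + i,
            )
            if conv is not None:
                report["divergence"]["convergence"][f"tau{tau}"] = conv
    report["converged_growth_periods"] = [
        tau
        for tau in taus
        if report["divergence"]["convergence"].get(f"tau{tau}", {}).get("converged")
    ]

    if traits is not None and trait_enrichment is not None:
        from . import traits as trait_models

        fit = trait_models.lasso_trait_regression(
            traits, trait_enrichment, seed=config.stage_seed("traits"),
            n_boot=config.n_boot,
        )
        report["traits"] = fit.to_dict()
    return report


def soil_convergence(
    pca: ordination.PcaModel,
    meta: pd.DataFrame,
    growth_period_days: int,
    axis: int = 2,
    first_round: int = 2,
    final_round: int = 10,
    treatment: str = "hybrid",
    n_boot: int = 1000,
    seed: int | None = None,
    min_decline: float = 0.25,
    p_threshold: float = 0.01,
) -> dict | None:
    """Test whether the two soils' communities converge along a principal axis.

    Convergence is a decline, over dilution rounds, of the distance between
    the soil-A and soil-B community centroids along the given principal
    component (the axis the algal effect acts on).  Replicates are
    bootstrapped within each soil at the first and final rounds; the flag is
    set when the decline is significant (bootstrap ``P(decline <= 0) <
    p_threshold``) and substantial (at least ``min_decline`` fractionally).
    Returns None when a soil has no samples at either round.
    """
    rng = np.random.default_rng(seed)
    groups: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for rnd in (first_round, final_round):
        sel = meta[
            (meta["treatment"] == treatment)
            & (meta["growth_period_days"] == growth_period_days)
            & (meta["round"] == rnd)
        ]
        a = pca.scores.loc[sel.index[sel["soil"] == "A"], f"PC{axis}"].to_numpy()
        b = pca.scores.loc[sel.index[sel["soil"] == "B"], f"PC{axis}"].to_numpy()
        if a.size == 0 or b.size == 0:
            return None
        groups[rnd] = (a, b)
    (a0, b0), (a1, b1) = groups[first_round], groups[final_round]
    d_first = abs(a0.mean() - b0.mean())
    d_final = abs(a1.mean() - b1.mean())
    decline_samples = np.empty(n_boot)
    for i in range(n_boot):
        d0 = abs(
            rng.choice(a0, a0.size).mean() - rng.choice(b0, b0.size).mean()
        )
        d1 = abs(
            rng.choice(a1, a1.size).mean() - rng.choice(b1, b1.size).mean()
        )
        decline_samples[i] = d0 - d1
    p = float(np.mean(decline_samples <= 0))
    decline = 1.0 - d_final / d_first if d_first > 0 else 0.0
    return {
        "axis": axis,
        "distance_first": float(d_first),
        "distance_final": float(d_final),
        "decline_fraction": float(decline),
        "p_value": p,
        "converged": bool(p < p_threshold and decline >= min_decline),
    }


def run_full(config: PipelineConfig) -> dict:
    """File-based pipeline entry point: read, validate, analyze, write artifacts.

    Writes ``report.json`` (with the resolved configuration embedded),
    ``shannon.tsv``, ``pca_scores.tsv`` and ``pca_loadings.tsv`` into
    ``config.output_dir``.
    """
    issues = validate_inputs(config.counts_path, config.samples_path)
    errors = [i for i in issues if i["severity"] == "error"]
    if errors:
        raise PipelineError("validate", "; ".join(i["message"] for i in errors[:5]))
    table = read_count_table(config.counts_path, config.samples_path)

    traits = trait_enrichment = None
    if config.traits_path and config.enrichment_path:
        traits = pd.read_csv(config.traits_path, index_col=0)
        trait_enrichment = pd.read_csv(
            config.enrichment_path, sep="\t", index_col=0
        ).iloc[:, 0]

    report = analyze(table, config, traits=traits, trait_enrichment=trait_enrichment)
    report["validation_issues"] = issues

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    shannon_diversity(table).to_csv(out / "shannon.tsv", sep="\t")
    filtered, _ = remove_rare_taxa(table, config.rare_log_threshold)
    clr = clr_transform(filtered, pseudocount=config.pseudocount)
    pca = ordination.fit_pca(clr)
    pca.scores.iloc[:, :10].to_csv(out / "pca_scores.tsv", sep="\t")
    pca.loadings.iloc[:10].T.to_csv(out / "pca_loadings.tsv", sep="\t")
    (out / "report.json").write_text(json.dumps(report, indent=2, default=_json_default))
    logger.info("[report] written to %s", out / "report.json")
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
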