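"""Study orchestration: quality check, hypotheses, multiverse, power.

The analyses mirror a pre-registered brain-state occupancy study:

* an outcome-neutral **quality check** that the two high-occupancy states
  are separated from the three low-occupancy states;
* the **primary** hypothesis — beta regression of the average high-state
  occupancy on log WMH volume (zero indicator when needed), adjusted for
  age and sex, reported as an odds ratio per interquartile ratio of the
  analyzed sample's non-zero WMH distribution;
* the **secondary** hypothesis — Gamma regression of TMT-B completion time
  on high-state occupancy adjusted for WMH, age, sex and education,
  reported as a multiplier per 5 percentage points of occupancy;
* a **multiverse** grid crossing confound-regression variants,
  parcellations and WMH components (total / periventricular / deep), with
  nominal significance flags and no multiplicity correction — the grid
  informs robustness, not hypothesis tests;
* a **bootstrap power curve**: resampling the reference cohort with
  replacement at a ladder of sample sizes and recording how often the
  primary null is rejected.

All regression analyses are complete-case: rows missing any model variable
are dropped and the count of dropped rows is reported.
"""

from __future__ import annotations

import dataclasses
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import caps, regression, synth

__all__ = [
    "SeparationEstimate",
    "AnalysisResult",
    "MultiverseGrid",
    "ScenarioResult",
    "PowerCurve",
    "quality_check",
    "run_primary",
    "run_secondary",
    "default_grid",
    "run_multiverse",
    "multiverse_summary",
    "synthetic_cohort_factory",
    "power_bootstrap",
    "cohort_with_occupancy",
]

PRIMARY_COVARIATES = ("ln_wmh", "wmh_zero", "age", "female")
SECONDARY_COVARIATES = (
    "fo_high",
    "ln_wmh",
    "wmh_zero",
    "age",
    "female",
    "education_years",
)


@dataclass
class SeparationEstimate:
    """Mean high-vs-low occupancy separation with a normal-approx 95% CI."""

    difference: float
    ci_lower: float
    ci_upper: float
    n: int


@dataclass
class AnalysisResult:
    """A fitted hypothesis model plus its headline effect size."""

    fit: regression.RegressionResult
    effect: regression.EffectEstimate
    n_complete: int
    n_dropped: int
    q1: float | None = None
    q3: float | None = None

    def coefficient_table(self) -> pd.DataFrame:
        """Coefficient table on the link scale with Wald CIs."""
        ci = self.fit.conf_int()
        return pd.DataFrame(
            {
                "estimate": self.fit.params,
                "se": self.fit.se,
                "p": self.fit.pvalues,
                "ci_lower": ci["lower"],
                "ci_upper": ci["upper"],
            }
        )


def quality_check(occupancy: pd.DataFrame, top_two: tuple[int, int] | None = None) -> SeparationEstimate:
    """Mean per-participant difference between high- and low-state FO.

    ``d_i = mean FO(top two states) - mean FO(remaining states)``; the CI is
    ``mean(d) +/- 1.96 sd(d)/sqrt(n)``.  With identical rows the CI has
    width zero.
    """
    n = len(occupancy)
    if n < 2:
        raise ValueError("quality check needs at least two participants")
    if top_two is None:
        top_two = caps.select_high_occupancy(occupancy).top_two
    k = occupancy.shape[1]
    top_cols = [occupancy.columns[s - 1] for s in top_two]
    low_cols = [c for c in occupancy.columns if c not in top_cols]
    if not low_cols:
        raise ValueError("need at least one low-occupancy state")
    d = occupancy[top_cols].mean(axis=1) - occupancy[low_cols].mean(axis=1)
    m = float(d.mean())
    half = 1.959963984540054 * float(d.std(ddof=1)) / np.sqrt(n)
    return SeparationEstimate(m, m - half, m + half, n)


def _complete_cases(df: pd.DataFrame, cols) -> tuple[pd.DataFrame, int]:
    sub = df[list(cols)]
    mask = sub.notna().all(axis=1)
    return df.loc[mask], int((~mask).sum())


def run_primary(cohort: pd.DataFrame, wmh_col: str = "wmh_total_ml") -> AnalysisResult:
    """Beta regression of fo_high on log WMH, adjusted for age and sex.

    The odds ratio is reported per interquartile ratio of the analyzed
    sample's non-zero WMH volumes.
    """
    needed = ["fo_high", wmh_col, "age", "sex"]
    data, n_dropped = _complete_cases(cohort, needed)
    if len(data) < 10:
        raise ValueError("fewer than 10 complete cases for the primary model")
    data = regression.add_wmh_columns(data, wmh_col)
    X = regression.build_design(data, PRIMARY_COVARIATES)
    fit = regression.beta_regression(data["fo_high"].to_numpy(), X)
    nonzero = data.loc[data[wmh_col] > 0.0, wmh_col]
    q1, q3 = nonzero.quantile([0.25, 0.75])
    effect = regression.effect_per_iqr(fit, float(q1), float(q3))
    return AnalysisResult(fit, effect, len(data), n_dropped, float(q1), float(q3))


def run_secondary(cohort: pd.DataFrame, wmh_col: str = "wmh_total_ml") -> AnalysisResult:
    """Gamma regression of TMT-B on fo_high, WMH, age, sex and education."""
    needed = ["tmt_b_s", "fo_high", wmh_col, "age", "sex", "education_years"]
    data, n_dropped = _complete_cases(cohort, needed)
    if len(data) < 10:
        raise ValueError("fewer than 10 complete cases for the secondary model")
    data = regression.add_wmh_columns(data, wmh_col)
    X = regression.build_design(data, SECONDARY_COVARIATES)
    fit = regression.gamma_glm(data["tmt_b_s"].to_numpy(), X)
    effect = regression.effect_per_k_pp(fit, 5.0)
    return AnalysisResult(fit, effect, len(data), n_dropped)


# ---------------------------------------------------------------------------
# multiverse
# ---------------------------------------------------------------------------

#: Named confound-regression variants, emulated as generator perturbations:
#: ``noise_scale`` multiplies the BOLD noise, ``censor_frac`` drops volumes
#: (emulating scrubbing/spike removal), ``shared_sd`` adds a spatially
#: loaded shared component (residual global signal).
DEFAULT_CONFOUND_VARIANTS: dict[str, dict[str, float]] = {
    "24p": {"noise_scale": 1.3, "shared_sd": 0.3},
    "24p+gsr": {"noise_scale": 1.3},
    "36p": {"noise_scale": 1.0},
    "36p+spikereg": {"noise_scale": 1.0, "censor_frac": 0.05},
    "36p+despike": {"noise_scale": 0.9},
    "36p+scrub": {"noise_scale": 1.0, "censor_frac": 0.10},
    "acompcor": {"noise_scale": 1.1, "shared_sd": 0.15},
    "tcompcor": {"noise_scale": 1.15, "shared_sd": 0.15},
    "aroma": {"noise_scale": 1.6, "shared_sd": 0.4},
}

#: Parcellation name -> parcel count (coarse structural atlases through
#: functional parcellations of increasing resolution).
DEFAULT_PARCELLATIONS: dict[str, int] = {
    "desikan-killiany": 86,
    "aal": 116,
    "harvard-oxford": 112,
    "glasser360": 360,
    "gordon333": 333,
    "power264": 264,
    "schaefer100": 100,
    "schaefer200": 200,
    "schaefer400": 400,
}

WMH_COMPONENTS = ("total", "periventricular", "deep")
_WMH_COLUMN = {
    "total": "wmh_total_ml",
    "periventricular": "wmh_peri_ml",
    "deep": "wmh_deep_ml",
}


@dataclass(frozen=True)
class MultiverseGrid:
    """The scenario grid: confound variants x parcellations x WMH splits."""

    confound_variants: dict[str, dict[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONFOUND_VARIANTS)
    )
    parcellations: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PARCELLATIONS)
    )
    wmh_components: tuple[str, ...] = WMH_COMPONENTS

    @property
    def n_scenarios(self) -> int:
        return (
            len(self.confound_variants)
            * len(self.parcellations)
            * len(self.wmh_components)
        )


@dataclass
class ScenarioResult:
    """One multiverse cell."""

    confound_variant: str
    parcellation: str
    n_parcels: int
    wmh_component: str
    or_per_iqr: float | None
    ci_lower: float | None
    ci_upper: float | None
    pvalue: float | None
    nominal_significant: bool
    direction: int  # sign of the log effect; 0 on failure/no effect
    error: str | None = None


def default_grid(wmh_components: tuple[str, ...] = WMH_COMPONENTS) -> MultiverseGrid:
    return MultiverseGrid(wmh_components=tuple(wmh_components))


def cohort_with_occupancy(
    config: synth.GeneratorConfig,
    use_clustering: bool = True,
    bold: list[np.ndarray] | None = None,
    n_restarts: int = 5,
    cluster_seed: int | None = None,
) -> tuple[pd.DataFrame, "synth.GroundTruth", caps.HighOccupancySelection, pd.DataFrame]:
    """Generate a cohort and attach fo_high, via clustering or label counts.

    With ``use_clustering`` the BOLD volumes are pooled and clustered by
    correlation-distance k-means; otherwise occupancies come directly from
    the generator's label sequences.  Returns ``(cohort, truth, selection,
    occupancy)``.
    """
    cohort, truth = synth.generate_cohort(config)
    ids = cohort["id"].tolist()
    if use_clustering:
        if bold is None:
            bold = synth.generate_cohort_bold(config, truth)
        series = [
            caps.ParcelTimeSeries(pid, arr, parcellation=f"synthetic-{config.n_parcels}")
            for pid, arr in zip(ids, bold)
        ]
        X, index = caps.build_feature_matrix(series)
        model = caps.kmeans_corr(
            X.T,
            k=config.k_states,
            n_restarts=n_restarts,
            seed=config.seed if cluster_seed is None else cluster_seed,
        )
        occ = caps.fractional_occupancy(model.labels, index, config.k_states)
    else:
        occ = caps.occupancy_from_sequences(truth.sequences, ids, config.k_states)
    sel = caps.select_high_occupancy(occ)
    cohort = cohort.set_index("id")
    cohort["fo_high"] = sel.fo_high.reindex(cohort.index)
    cohort = cohort.reset_index()
    return cohort, truth, sel, occ


def synthetic_cohort_factory(
    base_config: synth.GeneratorConfig,
    n_restarts: int = 3,
):
    """Factory for multiverse cells on synthetic data.

    The phenotype cohort (covariates, WMH, label sequences) is generated
    once from ``base_config``; each (variant, parcellation) cell re-derives
    the BOLD data with the variant's perturbations at the parcellation's
    resolution, clusters it, and returns the cohort with that cell's
    ``fo_high`` attached.
    """
    base_cohort, base_truth = synth.generate_cohort(base_config)
    ids = base_cohort["id"].tolist()

    def factory(variant: str, params: dict, parcellation: str, n_parcels: int) -> pd.DataFrame:
        cfg = dataclasses.replace(
            base_config,
            n_parcels=n_parcels,
            noise_sd=base_config.noise_sd * params.get("noise_scale", 1.0),
        )
        # stable across processes (unlike the builtin string hash)
        cell_seed = (
            zlib.crc32(f"{variant}|{parcellation}".encode()) + base_config.seed
        ) % (2**31)
        rng = np.random.default_rng(cell_seed)
        centroids = synth.make_centroids(cfg)
        censor = params.get("censor_frac", 0.0)
        shared_sd = params.get("shared_sd", 0.0)
        loading = rng.normal(size=n_parcels) if shared_sd > 0 else None
        series = []
        sequences = []
        for pid, seq in zip(ids, base_truth.sequences):
            if censor > 0.0:
                keep = rng.uniform(size=seq.size) >= censor
                if not keep.any():
                    keep[0] = True
                seq = seq[keep]
            arr = synth.gen_bold(cfg, seq, rng, centroids=centroids)
            if loading is not None:
                arr = arr + np.outer(loading, rng.normal(0.0, shared_sd, size=seq.size))
            sequences.append(seq)
            series.append(caps.ParcelTimeSeries(pid, arr, parcellation=parcellation))
        X, index = caps.build_feature_matrix(series)
        model = caps.kmeans_corr(
            X.T, k=cfg.k_states, n_restarts=n_restarts, seed=cell_seed
        )
        occ = caps.fractional_occupancy(model.labels, index, cfg.k_states)
        sel = caps.select_high_occupancy(occ)
        out = base_cohort.set_index("id")
        out["fo_high"] = sel.fo_high.reindex(out.index)
        return out.reset_index()

    return factory


def run_multiverse(
    grid: MultiverseGrid,
    cohort_factory,
    include_secondary: bool = False,
) -> pd.DataFrame:
    """Execute every scenario of the grid; failures are recorded, not fatal.

    Clustering happens once per (variant, parcellation) pair; the three WMH
    components reuse that cell's occupancies.  Returns a tidy table with one
    row per scenario.  No multiplicity correction is applied.
    """
    rows = []
    for variant, params in grid.confound_variants.items():
        for parcellation, n_parcels in grid.parcellations.items():
            try:
                cohort = cohort_factory(variant, params, parcellation, n_parcels)
                cell_error = None
            except Exception as exc:  # noqa: BLE001 - robustness by design
                cohort = None
                cell_error = f"{type(exc).__name__}: {exc}"
            for component in grid.wmh_components:
                base = {
                    "confound_variant": variant,
                    "parcellation": parcellation,
                    "n_parcels": n_parcels,
                    "wmh_component": component,
                }
                if cohort is None:
                    rows.append(
                        {**base, "or_per_iqr": np.nan, "ci_lower": np.nan,
                         "ci_upper": np.nan, "pvalue": np.nan,
                         "nominal_significant": False, "direction": 0,
                         "error": cell_error}
                    )
                    continue
                try:
                    res = run_primary(cohort, wmh_col=_WMH_COLUMN[component])
                    e = res.effect
                    extra = {}
                    if include_secondary:
                        sec = run_secondary(cohort, wmh_col=_WMH_COLUMN[component])
                        extra = {
                            "tmt_multiplier_per_5pp": sec.effect.estimate,
                            "tmt_pvalue": sec.effect.pvalue,
                        }
                    rows.append(
                        {**base, "or_per_iqr": e.estimate, "ci_lower": e.ci_lower,
                         "ci_upper": e.ci_upper, "pvalue": e.pvalue,
                         "nominal_significant": bool(e.pvalue < 0.05),
                         "direction": int(np.sign(np.log(e.estimate)))
                         if e.estimate > 0 else 0,
                         "error": None, **extra}
                    )
                except Exception as exc:  # noqa: BLE001
                    rows.append(
                        {**base, "or_per_iqr": np.nan, "ci_lower": np.nan,
                         "ci_upper": np.nan, "pvalue": np.nan,
                         "nominal_significant": False, "direction": 0,
                         "error": f"{type(exc).__name__}: {exc}"}
                    )
    return pd.DataFrame(rows)


def multiverse_summary(table: pd.DataFrame) -> dict[str, int]:
    """Counts of nominally significant cells by direction, plus failures."""
    ok = table["error"].isna()
    sig = table["nominal_significant"] & ok
    return {
        "n_scenarios": int(len(table)),
        "n_failed": int((~ok).sum()),
        "n_significant_negative": int((sig & (table["direction"] < 0)).sum()),
        "n_significant_positive": int((sig & (table["direction"] > 0)).sum()),
    }


# ---------------------------------------------------------------------------
# bootstrap power analysis
# ---------------------------------------------------------------------------


@dataclass
class PowerCurve:
    """Rejection proportion of the primary null per bootstrap sample size."""

    sample_sizes: tuple[int, ...]
    power: tuple[float, ...]
    n_reps: int
    alpha: float
    seed: int | None
    smallest_n_for_target: int | None = None
    power_target: float = 0.8

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if any(not (0.0 <= p <= 1.0) for p in self.power):
            raise ValueError("power values must lie in [0, 1]")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n": self.sample_sizes, "power": self.power})


def power_bootstrap(
    cohort: pd.DataFrame,
    sample_sizes,
    n_reps: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    power_target: float = 0.8,
    wmh_col: str = "wmh_total_ml",
) -> PowerCurve:
    """Bootstrap power curve for the primary hypothesis.

    For every sample size, ``n_reps`` resamples of the reference cohort are
    drawn with replacement and the primary beta regression re-fitted; the
    power estimate is the proportion of resamples rejecting the null at
    ``alpha``.  One master seed spawns an independent substream per
    (size, rep) cell, so curves are reproducible and parallelizable.
    Degenerate resamples (e.g. all-identical WMH) count as non-rejections
    with a warning.
    """
    needed = ["fo_high", wmh_col, "age", "sex"]
    data, _ = _complete_cases(cohort, needed)
    data = data.reset_index(drop=True)
    sizes = tuple(int(n) for n in sample_sizes)
    master = np.random.SeedSequence(seed)
    streams = iter(master.spawn(len(sizes) * n_reps))
    powers = []
    for n in sizes:
        rejections = 0
        for _ in range(n_reps):
            rng = np.random.default_rng(next(streams))
            idx = rng.integers(0, len(data), size=n)
            sample = data.iloc[idx]
            try:
                res = run_primary(sample, wmh_col=wmh_col)
                if res.effect.pvalue < alpha:
                    rejections += 1
            except Exception as exc:  # noqa: BLE001 - degenerate resample
                warnings.warn(
                    f"bootstrap resample (n={n}) failed and counts as "
                    f"non-rejection: {exc}",
                    RuntimeWarning,
                    stacklevel=2,
                )
        powers.append(rejections / n_reps)
    smallest = None
    for n, p in zip(sizes, powers):
        if p >= power_target:
            smallest = n
            break
    return PowerCurve(
        sample_sizes=sizes,
        power=tuple(powers),
        n_reps=n_reps,
        alpha=alpha,
        seed=seed,
        smallest_n_for_target=smallest,
        power_target=power_target,
    )
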