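"""Synthetic cohort generation for brain-state occupancy studies.

This module produces cohorts with the statistical structure the downstream
analysis assumes, so that every stage of the pipeline can be exercised with
known ground truth:

* demographic covariates (age, sex, years of education) matching the
  marginal summaries of a middle-aged to elderly population cohort;
* zero-inflated log-normal white-matter-hyperintensity (WMH) volumes;
* per-participant brain-state label sequences whose high-occupancy
  fraction is linked to log-WMH burden through a logistic (beta-mean)
  model with a configurable odds ratio per interquartile ratio;
* parcel-level BOLD volumes built from planted state centroids plus
  Gaussian noise, so co-activation-pattern clustering can be validated
  against the planted labels;
* Trail-Making-Test part B completion times following a Gamma model whose
  conditional mean is log-linear in the high-state occupancy;
* small 3-D lesion/ventricle mask pairs with recorded ground truth for
  the WMH quantification module.

Labels within a scan are drawn i.i.d. given the participant's occupancy
probabilities: the downstream analysis uses fractional occupancy only, which
is invariant to within-scan temporal ordering.  A transition-matrix hook
(`transition_matrix` argument of :func:`gen_state_sequences`) is exposed for
future dwell-time work but defaults to the i.i.d. mechanism.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "SEVEN_NETWORKS",
    "GeneratorConfig",
    "GroundTruth",
    "MaskFixture",
    "default_network_labels",
    "make_centroids",
    "gen_covariates",
    "gen_wmh",
    "split_wmh",
    "gen_state_sequences",
    "gen_bold",
    "gen_tmt",
    "gen_bounded_scores",
    "gen_masks",
    "generate_cohort",
    "generate_cohort_bold",
]

#: Canonical seven large-scale functional networks (Yeo-style ordering).
SEVEN_NETWORKS = (
    "Vis",
    "SomMot",
    "DorsAttn",
    "SalVentAttn",
    "Limbic",
    "Cont",
    "Default",
)

# 75th percentile of the standard normal; converts a log-normal log-sd to an
# interquartile ratio via IQR-ratio = exp(2 * z75 * sigma).
_Z75 = 0.6744897501960817

# Piecewise-linear quantile anchors for the demographic marginals
# (probability, value).  Only medians and quartiles are targeted.
_AGE_QUANTILES = ((0.0, 45.0), (0.25, 59.0), (0.5, 66.0), (0.75, 72.0), (1.0, 90.0))
_EDU_QUANTILES = ((0.0, 8.0), (0.25, 12.0), (0.5, 13.0), (0.75, 16.0), (1.0, 20.0))
_MALE_FRACTION = 940.0 / 1651.0

_AGE_CENTER = 66.0
_EDU_CENTER = 13.0
_TMT_MEDIAN_S = 83.0


def _default_covariate_effects() -> dict[str, float]:
    """Link-scale nuisance coefficients used by the generative models.

    The occupancy (``fo_``) effects act on the logit of the high-state
    occupancy; the completion-time (``tmt_``) effects act on the log of the
    expected TMT-B time.  Defaults reproduce the adjusted effect sizes of a
    population cohort mildly affected by small vessel disease.
    """
    return {
        "fo_age_per_10y": float(np.log(1.04)),
        "fo_female": float(np.log(1.12)),
        "fo_zero_wmh": 0.0,
        "tmt_age_per_10y": float(np.log(1.18)),
        "tmt_female": float(np.log(0.99)),
        "tmt_education_per_y": float(np.log(0.97)),
        "tmt_lnwmh": float(np.log(1.01) / np.log(5.06)),
        "tmt_zero_wmh": 0.0,
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic-cohort generative model.

    Defaults encode the study conditions of a population cohort of 1651
    middle-aged to elderly participants: five brain states with two
    high-occupancy default-mode-related states, zero-inflated log-normal WMH
    volume (median 1.05 mL, interquartile ratio 5.06, ~0.5% exact zeros), an
    odds ratio of 0.95 per interquartile ratio linking log-WMH to
    high-state occupancy, and a TMT-B multiplier of 0.98 per 5 percentage
    points of occupancy.
    """

    n_participants: int = 1651
    seed: int = 0
    n_parcels: int = 100
    network_labels: tuple[str, ...] | None = None
    k_states: int = 5
    target_mean_fo: tuple[float, ...] = (0.248, 0.240, 0.184, 0.168, 0.160)
    activation_amplitude: float = 1.0
    noise_sd: float = 0.5
    volumes_range: tuple[int, int] = (100, 125)
    wmh_logmean: float = float(np.log(1.05))
    wmh_logsd: float = float(np.log(5.06) / (2.0 * _Z75))
    zero_wmh_prob: float = 9.0 / 1651.0
    or_per_iqr: float = 0.95
    beta_dispersion: float = 80.0
    tmt_multiplier_per_5pp: float = 0.98
    gamma_shape: float = 6.0
    covariate_effects: Mapping[str, float] = field(
        default_factory=_default_covariate_effects
    )
    tmt_missing_prob: float = 162.0 / 1651.0
    deep_zero_prob: float = 344.0 / 1651.0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.k_states < 2:
            raise ValueError("k_states must be >= 2")
        t = np.asarray(self.target_mean_fo, dtype=float)
        if t.size != self.k_states:
            raise ValueError("target_mean_fo must have one entry per state")
        if abs(t.sum() - 1.0) > 1e-12:
            raise ValueError("target_mean_fo must sum to 1 within 1e-12")
        if np.any(t <= 0.0):
            raise ValueError("target_mean_fo entries must be > 0")
        if not (0.0 <= self.zero_wmh_prob <= 1.0):
            raise ValueError("zero_wmh_prob must lie in [0, 1]")
        if self.wmh_logsd < 0.0:
            raise ValueError("wmh_logsd must be non-negative")
        if self.or_per_iqr <= 0.0:
            raise ValueError("or_per_iqr must be > 0")
        if self.tmt_multiplier_per_5pp <= 0.0:
            raise ValueError("tmt_multiplier_per_5pp must be > 0")
        if self.noise_sd < 0.0:
            raise ValueError("noise_sd must be >= 0")
        if self.beta_dispersion <= 0.0:
            raise ValueError("beta_dispersion must be > 0")
        if self.gamma_shape <= 0.0:
            raise ValueError("gamma_shape must be > 0")
        lo, hi = self.volumes_range
        if not (1 <= lo <= hi):
            raise ValueError("volumes_range must satisfy 1 <= min <= max")
        if self.network_labels is not None:
            if len(self.network_labels) != self.n_parcels:
                raise ValueError("network_labels length must equal n_parcels")
            unknown = set(self.network_labels) - set(SEVEN_NETWORKS)
            if unknown:
                raise ValueError(f"unknown network names: {sorted(unknown)}")

    # -- derived generative quantities ------------------------------------

    @property
    def iqr_ratio(self) -> float:
        """Theoretical Q3/Q1 ratio of the non-zero WMH volume distribution."""
        return float(np.exp(2.0 * _Z75 * self.wmh_logsd))

    @property
    def lnwmh_slope(self) -> float:
        """Logit-scale slope on ln(WMH) implied by ``or_per_iqr``."""
        if self.or_per_iqr == 1.0:
            return 0.0
        if self.wmh_logsd == 0.0:
            raise ValueError(
                "or_per_iqr != 1 requires wmh_logsd > 0 (IQR ratio of 1 "
                "cannot carry an effect)"
            )
        return float(np.log(self.or_per_iqr) / np.log(self.iqr_ratio))

    @property
    def fo_high_target(self) -> float:
        """Target mean of the average occupancy of the two high states."""
        return float((self.target_mean_fo[0] + self.target_mean_fo[1]) / 2.0)

    @property
    def fo_slope_per_unit(self) -> float:
        """Log-scale TMT slope per unit of occupancy proportion."""
        return float(20.0 * np.log(self.tmt_multiplier_per_5pp))

    def resolved_network_labels(self) -> tuple[str, ...]:
        if self.network_labels is not None:
            return tuple(self.network_labels)
        return default_network_labels(self.n_parcels)


@dataclass
class GroundTruth:
    """Latent quantities of a generated cohort, for parameter-recovery tests."""

    fo_high: np.ndarray  # per-participant true mean high-state occupancy
    sequences: list[np.ndarray]  # state labels in 1..k, one array per participant
    centroids: np.ndarray  # k x n_parcels planted state centroids
    coefficients: dict[str, float]  # true link-scale regression coefficients

    def __post_init__(self) -> None:
        fo = np.asarray(self.fo_high, dtype=float)
        if np.any((fo <= 0.0) | (fo >= 1.0)):
            raise ValueError("true fo_high must lie strictly inside (0, 1)")
        k = self.centroids.shape[0]
        for seq in self.sequences:
            if seq.size and (seq.min() < 1 or seq.max() > k):
                raise ValueError("state labels must take values in 1..k")


def default_network_labels(n_parcels: int) -> tuple[str, ...]:
    """Assign parcels to the seven networks in balanced contiguous blocks."""
    if n_parcels < len(SEVEN_NETWORKS):
        raise ValueError("need at least one parcel per network")
    edges = np.linspace(0, n_parcels, len(SEVEN_NETWORKS) + 1).round().astype(int)
    labels: list[str] = []
    for name, a, b in zip(SEVEN_NETWORKS, edges[:-1], edges[1:]):
        labels.extend([name] * (b - a))
    return tuple(labels)


def make_centroids(config: GeneratorConfig) -> np.ndarray:
    """Planted state centroids (k x n_parcels).

    State 1 activates the default-mode parcels (+amplitude), state 2
    suppresses them (-amplitude); the remaining states activate other
    networks in a fixed order.  Off-network parcels are zero.
    """
    labels = np.asarray(config.resolved_network_labels())
    other_networks = [n for n in SEVEN_NETWORKS if n != "Default"]
    centroids = np.zeros((config.k_states, config.n_parcels))
    dmn = labels == "Default"
    centroids[0, dmn] = config.activation_amplitude
    centroids[1, dmn] = -config.activation_amplitude
    for s in range(2, config.k_states):
        net = other_networks[(s - 2) % len(other_networks)]
        centroids[s, labels == net] = config.activation_amplitude
    return centroids


def _interp_quantiles(u: np.ndarray, anchors) -> np.ndarray:
    p = np.array([a[0] for a in anchors])
    q = np.array([a[1] for a in anchors])
    return np.interp(u, p, q)


def gen_covariates(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw the demographic covariate table.

    Age and years of education are drawn from piecewise-linear quantile
    functions anchored at the cohort's reported median and quartiles; sex is
    Bernoulli with the cohort's male fraction.  Higher moments are not
    targeted.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_participants
    age = _interp_quantiles(rng.uniform(size=n), _AGE_QUANTILES)
    education = np.rint(_interp_quantiles(rng.uniform(size=n), _EDU_QUANTILES))
    sex = np.where(rng.uniform(size=n) < _MALE_FRACTION, "male", "female")
    return pd.DataFrame(
        {
            "id": [f"sub-{i + 1:05d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "education_years": education.astype(int),
        }
    )


def gen_wmh(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw total WMH volumes (mL): zero-inflated log-normal."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_participants
    vol = np.exp(rng.normal(config.wmh_logmean, config.wmh_logsd, size=n))
    zero = rng.uniform(size=n) < config.zero_wmh_prob
    vol[zero] = 0.0
    return vol


def split_wmh(
    config: GeneratorConfig,
    total: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Split total WMH volume into periventricular and deep components.

    The periventricular fraction is Beta-distributed around ~0.89 of the
    total (matching a cohort where the deep component is roughly an order of
    magnitude smaller), with a point mass at 1 producing exact zeros of deep
    volume in about a fifth of participants.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    total = np.asarray(total, dtype=float)
    n = total.size
    conc = 25.0
    frac = rng.beta(0.89 * conc, 0.11 * conc, size=n)
    frac[rng.uniform(size=n) < config.deep_zero_prob] = 1.0
    peri = total * frac
    deep = total - peri
    return peri, deep


def gen_state_sequences(
    config: GeneratorConfig,
    wmh: np.ndarray,
    covariates: pd.DataFrame,
    rng: np.random.Generator | None = None,
    transition_matrix: np.ndarray | None = None,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Draw per-participant state-label sequences and the true FO_high.

    The participant-level mean high-state occupancy ``m_i`` follows a beta
    distribution whose logit mean is affine in ln(WMH) (zeros keep value 0
    and carry a binary indicator, mirroring the analysis transform) and in
    the demographic covariates.  Given ``m_i``, each retained volume is
    assigned independently: the two high states each have probability
    ``m_i`` and the remaining mass is split over the low states in
    proportion to their target occupancies.

    Returns ``(sequences, fo_high_true)`` where ``fo_high_true`` is the
    MEAN-scale high-state occupancy (the quantity the beta regression
    models).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if transition_matrix is not None:
        raise NotImplementedError(
            "Markov persistence hook reserved; occupancy analyses do not use it"
        )
    wmh = np.asarray(wmh, dtype=float)
    n = config.n_participants
    if wmh.size != n or len(covariates) != n:
        raise ValueError("wmh and covariates must match n_participants")
    eff = config.covariate_effects
    zero = wmh == 0.0
    lnw = np.where(zero, 0.0, np.log(np.where(zero, 1.0, wmh)))
    female = (covariates["sex"].to_numpy() == "female").astype(float)
    # covariates enter centered so the marginal mean stays on target
    female_c = female - (1.0 - _MALE_FRACTION)
    eta = (
        special.logit(config.fo_high_target)
        + config.lnwmh_slope * np.where(zero, 0.0, lnw - config.wmh_logmean)
        + eff.get("fo_zero_wmh", 0.0) * (zero - config.zero_wmh_prob)
        + eff.get("fo_age_per_10y", 0.0)
        * (covariates["age"].to_numpy() - _AGE_CENTER)
        / 10.0
        + eff.get("fo_female", 0.0) * female_c
    )
    if not np.all(np.isfinite(eta)):
        raise FloatingPointError("overflow in generative linear predictor")
    mu = special.expit(eta)
    phi = config.beta_dispersion
    m = rng.beta(mu * phi, (1.0 - mu) * phi, size=n)
    # each high state gets probability m; total high mass 2m must stay < 1
    m = np.clip(m, 1e-4, 0.499)

    t = np.asarray(config.target_mean_fo, dtype=float)
    low_weights = t[2:] / t[2:].sum()
    lo, hi = config.volumes_range
    k = config.k_states
    sequences: list[np.ndarray] = []
    for i in range(n):
        T = int(rng.integers(lo, hi + 1))
        p = np.concatenate(([m[i], m[i]], (1.0 - 2.0 * m[i]) * low_weights))
        sequences.append(rng.choice(k, size=T, p=p).astype(np.int64) + 1)
    return sequences, m


def gen_bold(
    config: GeneratorConfig,
    label_sequence: np.ndarray,
    rng: np.random.Generator | None = None,
    centroids: np.ndarray | None = None,
) -> np.ndarray:
    """One participant's BOLD array (n_parcels x T): centroid + noise."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if centroids is None:
        centroids = make_centroids(config)
    if centroids.shape[1] != config.n_parcels:
        raise ValueError("centroid parcel dimension does not match n_parcels")
    seq = np.asarray(label_sequence, dtype=int)
    signal = centroids[seq - 1].T  # n_parcels x T
    if config.noise_sd == 0.0:
        return signal.copy()
    return signal + rng.normal(0.0, config.noise_sd, size=signal.shape)


def gen_tmt(
    config: GeneratorConfig,
    fo_high: np.ndarray,
    covariates: pd.DataFrame,
    wmh: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw TMT-B completion times (seconds); missing values are NaN.

    The conditional mean is log-linear in the high-state occupancy (on the
    proportion scale; the per-5-percentage-point multiplier is converted via
    a factor of 20) and in the nuisance covariates; times follow a Gamma
    distribution with fixed shape.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    fo = np.asarray(fo_high, dtype=float)
    wmh = np.asarray(wmh, dtype=float)
    eff = config.covariate_effects
    zero = wmh == 0.0
    lnw_c = np.where(zero, 0.0, np.log(np.where(zero, 1.0, wmh)) - config.wmh_logmean)
    female = (covariates["sex"].to_numpy() == "female").astype(float)
    eta = (
        np.log(_TMT_MEDIAN_S)
        + config.fo_slope_per_unit * (fo - config.fo_high_target)
        + eff.get("tmt_lnwmh", 0.0) * lnw_c
        + eff.get("tmt_zero_wmh", 0.0) * (zero - config.zero_wmh_prob)
        + eff.get("tmt_age_per_10y", 0.0)
        * (covariates["age"].to_numpy() - _AGE_CENTER)
        / 10.0
        + eff.get("tmt_female", 0.0) * (female - (1.0 - _MALE_FRACTION))
        + eff.get("tmt_education_per_y", 0.0)
        * (covariates["education_years"].to_numpy() - _EDU_CENTER)
    )
    mean = np.exp(eta)
    if np.any(~np.isfinite(mean)) or np.any(mean <= 0.0):
        raise FloatingPointError("non-positive or overflowing TMT mean")
    nu = config.gamma_shape
    y = rng.gamma(shape=nu, scale=mean / nu)
    missing = rng.uniform(size=y.size) < config.tmt_missing_prob
    y[missing] = np.nan
    return y


_BOUNDED_SCORES = {
    # name: (max score, baseline success probability, log-OR per 20 pp FO)
    "mmse": (30, 28.0 / 30.0, float(np.log(1.09))),
    "vocabulary": (37, 32.0 / 37.0, float(np.log(1.09))),
    "word_recall": (10, 8.0 / 10.0, float(np.log(1.19))),
}


def gen_bounded_scores(
    config: GeneratorConfig,
    fo_high: np.ndarray,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Bounded cognitive scores (binomial, logit-linear in occupancy)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    fo = np.asarray(fo_high, dtype=float)
    out = {}
    for name, (max_score, p0, logor_20pp) in _BOUNDED_SCORES.items():
        eta = special.logit(p0) + logor_20pp * 5.0 * (fo - config.fo_high_target)
        out[name] = rng.binomial(max_score, special.expit(eta))
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# mask fixtures for the WMH quantification module
# ---------------------------------------------------------------------------


@dataclass
class MaskFixture:
    """Synthetic lesion/ventricle masks with construction-time ground truth."""

    lesion_mask: np.ndarray
    ventricle_mask: np.ndarray
    voxel_spacing: tuple[float, float, float]
    lesions: pd.DataFrame  # per-lesion: n_voxels, min/max distance, volumes
    truth_total_ml: float
    truth_peri_ml: float
    truth_deep_ml: float


def _blob_indices(
    shape: tuple[int, int, int],
    center: tuple[float, float, float],
    n_voxels: int,
    spacing: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The ``n_voxels`` grid voxels closest (in mm) to ``center``.

    Ties are broken by flat index so the blob is deterministic and compact.
    """
    c = np.asarray(center, dtype=float)
    half = np.ceil((n_voxels ** (1.0 / 3.0)) + 3).astype(int)
    ranges = [
        np.arange(
            max(0, int(c[a]) - half), min(shape[a], int(c[a]) + half + 1)
        )
        for a in range(3)
    ]
    ii, jj, kk = np.meshgrid(*ranges, indexing="ij")
    pts = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    d2 = (((pts - c) * spacing) ** 2).sum(axis=1)
    if pts.shape[0] < n_voxels:
        raise ValueError("lesion overlaps the image boundary")
    order = np.lexsort((np.ravel_multi_index(pts.T, shape), d2))
    sel = pts[order[:n_voxels]]
    return sel[:, 0], sel[:, 1], sel[:, 2]


def gen_masks(
    shape: tuple[int, int, int] = (40, 40, 40),
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    lesion_spec: Sequence[Mapping] = (),
    seed: int = 0,
    cutoff_mm: float = 10.0,
    min_cluster_voxels: int = 30,
    ventricle_radius_mm: float = 6.0,
) -> MaskFixture:
    """Build a lesion mask and a central ventricle blob with known truth.

    ``lesion_spec`` is a sequence of mappings with keys ``center`` (voxel
    coordinates) and ``n_voxels``; each lesion is the set of ``n_voxels``
    voxels nearest its center.  Ground-truth distances are computed by
    brute-force minimisation over ventricle voxel centers, independently of
    any distance-transform implementation.  Lesions smaller than
    ``min_cluster_voxels`` are flagged sub-threshold and excluded from the
    ground-truth volumes, matching the analysis convention that the size
    filter precedes the distance partition.
    """
    spacing = np.asarray(voxel_spacing, dtype=float)
    if np.any(spacing <= 0.0):
        raise ValueError("voxel spacing must be strictly positive (mm)")
    shape = tuple(int(s) for s in shape)

    ventricle = np.zeros(shape, dtype=bool)
    center = (np.asarray(shape) - 1) / 2.0
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    coords_mm = np.stack([g * sp for g, sp in zip(grids, spacing)], axis=-1)
    cmm = center * spacing
    ventricle[np.sqrt(((coords_mm - cmm) ** 2).sum(axis=-1)) <= ventricle_radius_mm] = True

    lesion = np.zeros(shape, dtype=bool)
    vent_pts = np.argwhere(ventricle) * spacing
    voxel_ml = float(spacing.prod()) / 1000.0
    rows = []
    truth_peri = truth_deep = 0.0
    for li, spec in enumerate(lesion_spec):
        n_vox = int(spec["n_voxels"])
        ii, jj, kk = _blob_indices(shape, tuple(spec["center"]), n_vox, spacing)
        if (
            ii.min() == 0
            or jj.min() == 0
            or kk.min() == 0
            or ii.max() == shape[0] - 1
            or jj.max() == shape[1] - 1
            or kk.max() == shape[2] - 1
        ):
            raise ValueError("lesion overlaps the image boundary")
        if lesion[ii, jj, kk].any() or ventricle[ii, jj, kk].any():
            raise ValueError("lesions must not overlap each other or the ventricles")
        lesion[ii, jj, kk] = True
        pts_mm = np.stack([ii, jj, kk], axis=1) * spacing
        # brute-force nearest ventricle voxel center per lesion voxel
        d = np.sqrt(
            ((pts_mm[:, None, :] - vent_pts[None, :, :]) ** 2).sum(axis=2)
        ).min(axis=1)
        sub = n_vox < min_cluster_voxels
        n_peri = int((d <= cutoff_mm).sum())
        n_deep = n_vox - n_peri
        if not sub:
            truth_peri += n_peri * voxel_ml
            truth_deep += n_deep * voxel_ml
        rows.append(
            {
                "lesion": li,
                "n_voxels": n_vox,
                "min_distance_mm": float(d.min()),
                "max_distance_mm": float(d.max()),
                "sub_threshold": sub,
                "peri_ml": 0.0 if sub else n_peri * voxel_ml,
                "deep_ml": 0.0 if sub else n_deep * voxel_ml,
            }
        )
    lesions = pd.DataFrame(
        rows,
        columns=[
            "lesion",
            "n_voxels",
            "min_distance_mm",
            "max_distance_mm",
            "sub_threshold",
            "peri_ml",
            "deep_ml",
        ],
    )
    return MaskFixture(
        lesion_mask=lesion,
        ventricle_mask=ventricle,
        voxel_spacing=tuple(spacing),
        lesions=lesions,
        truth_total_ml=truth_peri + truth_deep,
        truth_peri_ml=truth_peri,
        truth_deep_ml=truth_deep,
    )


# ---------------------------------------------------------------------------
# cohort orchestration
# ---------------------------------------------------------------------------


def _spawned_rngs(config: GeneratorConfig, n_streams: int) -> list[np.random.Generator]:
    seq = np.random.SeedSequence(config.seed)
    return [np.random.default_rng(s) for s in seq.spawn(n_streams)]


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the full phenotype table and its latent ground truth.

    Independent substreams (spawned from ``config.seed``) drive each
    component, so the cohort is bitwise reproducible for a given config.
    BOLD arrays are generated separately by :func:`generate_cohort_bold`.
    """
    r_cov, r_wmh, r_split, r_seq, r_tmt, r_scores, _ = _spawned_rngs(config, 7)
    cov = gen_covariates(config, r_cov)
    wmh = gen_wmh(config, r_wmh)
    peri, deep = split_wmh(config, wmh, r_split)
    sequences, fo_true = gen_state_sequences(config, wmh, cov, r_seq)
    tmt = gen_tmt(config, fo_true, cov, wmh, r_tmt)
    scores = gen_bounded_scores(config, fo_true, r_scores)

    cohort = cov.copy()
    cohort["wmh_total_ml"] = wmh
    cohort["wmh_peri_ml"] = peri
    cohort["wmh_deep_ml"] = deep
    cohort["tmt_b_s"] = tmt
    cohort["n_volumes"] = [len(s) for s in sequences]
    for c in scores.columns:
        cohort[c] = scores[c].to_numpy()

    truth = GroundTruth(
        fo_high=fo_true,
        sequences=sequences,
        centroids=make_centroids(config),
        coefficients={
            "lnwmh_slope": config.lnwmh_slope,
            "fo_slope_per_unit": config.fo_slope_per_unit,
            "or_per_iqr": config.or_per_iqr,
            "tmt_multiplier_per_5pp": config.tmt_multiplier_per_5pp,
            "beta_dispersion": config.beta_dispersion,
            **dict(config.covariate_effects),
        },
    )
    return cohort, truth


def generate_cohort_bold(
    config: GeneratorConfig,
    truth: GroundTruth,
    seed: int | None = None,
    noise_sd: float | None = None,
) -> list[np.ndarray]:
    """BOLD arrays (n_parcels x T_i) for every participant of a cohort."""
    base = config.seed if seed is None else seed
    sd = config.noise_sd if noise_sd is None else noise_sd
    cfg = dataclasses.replace(config, noise_sd=sd)
    seq = np.random.SeedSequence(base).spawn(len(truth.sequences))
    return [
        gen_bold(cfg, labels, np.random.default_rng(s), centroids=truth.centroids)
        for labels, s in zip(truth.sequences, seq)
    ]
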