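"""Mutation burden estimation and the somatic molecular clock.

Microdissected samples of normal epithelium are polyclonal, so the raw
number of called substitutions underestimates the burden carried by the
dominant lineage.  This module implements the standard correction chain:

1. clonality ``c`` = median VAF of a sample's reported calls;
2. the depth rule ``d >= 4/c`` (a call needs at least four variant
   reads, so the dominant clone is only visible where coverage allows
   it), applied over at least 75% of the genome as an inclusion filter;
3. per-call detection sensitivity ``s`` as a function of depth and VAF,
   either the exact binomial tail or a logistic GLM calibrated on
   simulated adjacent-section replicates;
4. the corrected burden ``b_c = b_r / s``;
5. a linear mixed-effects clock ``b_c ~ age + (1 | donor)`` whose slope
   is the somatic mutation rate in mutations/year/clone, and its
   inverse, mapping burdens to chronological ages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

DEFAULT_MIN_ALT_READS = 4
#: corrected burdens explode as s -> 0; below this the sample is excluded
DEFAULT_MIN_SENSITIVITY = 0.05


class UndefinedClonalityError(ValueError):
    """Clonality is undefined without at least one reported call."""


class LowSensitivityError(ValueError):
    """Sensitivity too low for a stable burden correction."""


class ClockError(ValueError):
    """The clock regression is unidentifiable on the given table."""


# ---------------------------------------------------------------------------
# clonality and the depth filter
# ---------------------------------------------------------------------------


def estimate_clonality(vaf_values) -> float:
    """Median VAF of the reported calls; the sample's clonality ``c``."""
    v = np.asarray(vaf_values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise UndefinedClonalityError("clonality undefined: no reported calls")
    return float(np.median(v))


def min_depth_for_clonality(c: float, min_alt_reads: int = DEFAULT_MIN_ALT_READS) -> int:
    """Minimum depth d = ceil(min_alt_reads / c) for robust clonality.

    With four variant reads required per call, a clonal diploid sample
    (c = 0.5) needs depth 8, a polyclonal one at c = 0.1 needs depth 40.
    """
    if not 0 < c <= 1:
        raise ValueError(f"clonality must be in (0, 1], got {c}")
    # guard against float artefacts like 4/0.1 = 40.000000000000006
    return int(math.ceil(min_alt_reads / c - 1e-9))


@dataclass
class DepthProfile:
    """Summary of a sample's genome-wide coverage distribution.

    Either an empirical array of per-site (per-window) depths, or a
    Poisson model around the mean when only the mean is known.
    """

    mean: float
    depths: np.ndarray | None = None

    def __post_init__(self):
        if self.mean <= 0:
            raise ValueError("depth mean must be positive")
        if self.depths is not None:
            self.depths = np.asarray(self.depths, dtype=float)

    @classmethod
    def from_depths(cls, depths) -> "DepthProfile":
        depths = np.asarray(depths, dtype=float)
        return cls(mean=float(depths.mean()), depths=depths)

    @classmethod
    def poisson(cls, mean: float) -> "DepthProfile":
        return cls(mean=float(mean), depths=None)

    def fraction_at_least(self, depth: int) -> float:
        """Fraction of the genome covered to at least ``depth``."""
        if self.depths is not None:
            return float(np.mean(self.depths >= depth))
        return float(stats.poisson.sf(depth - 1, self.mean))


def sample_passes_filter(
    depth_profile: DepthProfile,
    c: float,
    genome_fraction: float = 0.75,
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
) -> bool:
    """True iff depth >= 4/c holds in at least ``genome_fraction`` of the genome."""
    if depth_profile is None:
        raise ValueError("missing depth profile")
    d_min = min_depth_for_clonality(c, min_alt_reads)
    return depth_profile.fraction_at_least(d_min) >= genome_fraction


# ---------------------------------------------------------------------------
# detection sensitivity
# ---------------------------------------------------------------------------


@dataclass
class SensitivityModel:
    """Per-call detection sensitivity as a function of depth and VAF.

    ``binomial_tail`` mode is exact under the calling rule (a call needs
    ``min_alt_reads`` variant reads): s = P(X >= min_alt_reads) with
    X ~ Binomial(depth, vaf).  ``fitted_glm`` mode is a logistic
    regression trained on simulated adjacent-section replicate data via
    :func:`train_sensitivity_glm`.
    """

    min_alt_reads: int = DEFAULT_MIN_ALT_READS
    mode: str = "binomial_tail"
    coef_: np.ndarray | None = None  # intercept, depth, vaf, depth*vaf

    def __call__(self, depth, vaf):
        return detection_sensitivity(depth, vaf, self)


def detection_sensitivity(depth, vaf, model: SensitivityModel | None = None):
    """Probability that a mutation at ``vaf`` is called at ``depth``.

    VAFs above the diploid bound 0.5 are clamped with a warning; scalar
    in, scalar out; arrays broadcast.
    """
    if model is None:
        model = SensitivityModel()
    d = np.asarray(depth, dtype=float)
    v = np.asarray(vaf, dtype=float)
    if np.any(d < 0) or np.any(v < 0):
        raise ValueError("depth and vaf must be non-negative")
    if np.any(v > 0.5):
        warnings.warn("VAF above the diploid bound 0.5; clamping", stacklevel=2)
        v = np.minimum(v, 0.5)
    if model.mode == "binomial_tail":
        s = stats.binom.sf(model.min_alt_reads - 1, np.round(d).astype(int), v)
    elif model.mode == "fitted_glm":
        if model.coef_ is None:
            raise ValueError("fitted_glm mode requires trained coefficients")
        d_b, v_b = np.broadcast_arrays(d, v)
        X = np.column_stack(
            [np.ones(d_b.size), d_b.ravel(), v_b.ravel(), (d_b * v_b).ravel()]
        )
        eta = X @ model.coef_
        s = (1.0 / (1.0 + np.exp(-eta))).reshape(d_b.shape)
        v = v_b
        # a site with VAF 0 is never callable whatever the GLM says
        s = np.where(v == 0, 0.0, s)
    else:
        raise ValueError(f"unknown sensitivity mode {model.mode!r}")
    s = np.clip(s, 0.0, 1.0)
    if np.ndim(depth) == 0 and np.ndim(vaf) == 0:
        return float(s)
    return s


def train_sensitivity_glm(
    rng: np.random.Generator,
    n: int = 20000,
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
    depth_range: tuple[float, float] = (10.0, 60.0),
    vaf_range: tuple[float, float] = (0.02, 0.5),
) -> SensitivityModel:
    """Calibrate a logistic sensitivity model on simulated replicates.

    Emulates the adjacent-section calibration idea: pairs of sections
    share their variants, so a variant known to be present either is or
    is not re-called at the second section's depth and VAF.  Here the
    truth is simulated directly: detected iff a Binomial(depth, vaf)
    draw reaches ``min_alt_reads``.
    """
    mean_depth = rng.uniform(*depth_range, size=n)
    depth = rng.poisson(mean_depth)
    vaf = rng.uniform(*vaf_range, size=n)
    alt = rng.binomial(depth, vaf)
    detected = (alt >= min_alt_reads).astype(float)
    X = np.column_stack([np.ones(n), depth, vaf, depth * vaf])
    fit = sm.GLM(detected, X, family=sm.families.Binomial()).fit()
    return SensitivityModel(
        min_alt_reads=min_alt_reads, mode="fitted_glm", coef_=np.asarray(fit.params)
    )


def sample_sensitivity(
    depth_profile: DepthProfile, clonality: float, model: SensitivityModel | None = None
) -> float:
    """Sample-level sensitivity: mean per-call sensitivity at the
    sample's clonality, averaged over its depth distribution."""
    if model is None:
        model = SensitivityModel()
    vaf = min(clonality, 0.5)
    if depth_profile.depths is not None:
        depths = depth_profile.depths
        return float(np.mean(detection_sensitivity(depths, np.full(depths.shape, vaf), model)))
    dmax = int(depth_profile.mean + 8 * math.sqrt(depth_profile.mean)) + 1
    d = np.arange(dmax + 1)
    w = stats.poisson.pmf(d, depth_profile.mean)
    s = detection_sensitivity(d, np.full(d.shape, vaf), model)
    return float(np.sum(w * s) / np.sum(w))


# ---------------------------------------------------------------------------
# burden correction
# ---------------------------------------------------------------------------


@dataclass
class BurdenEstimate:
    sample_id: str
    raw_burden: int
    clonality: float | None
    sensitivity: float | None
    corrected_burden: float | None
    included: bool
    exclusion_reason: str | None = None


def correct_burden(
    b_r: float, s: float, min_sensitivity: float = DEFAULT_MIN_SENSITIVITY
) -> float:
    """Sensitivity-corrected burden b_c = b_r / s."""
    if not 0 < s <= 1:
        raise ValueError(f"sensitivity must be in (0, 1], got {s}")
    if s <= min_sensitivity:
        raise LowSensitivityError(
            f"sensitivity {s:.3g} <= {min_sensitivity}: correction unstable"
        )
    return float(b_r) / float(s)


def estimate_burdens(
    vaf_matrix,
    depth_profiles: dict[str, DepthProfile] | None = None,
    model: SensitivityModel | None = None,
    genome_fraction: float = 0.75,
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
    min_sensitivity: float = DEFAULT_MIN_SENSITIVITY,
) -> pd.DataFrame:
    """Per-sample burden table from a read-count matrix.

    A call is "reported" in a sample when its alt count reaches
    ``min_alt_reads`` there.  Clonality, the 75%-of-genome depth filter,
    sensitivity and the corrected burden are derived per sample.  When
    no explicit depth profile is given, a Poisson profile around the
    sample's mean depth over reported calls is used.

    Returns a DataFrame with columns sample_id, b_r, c, s, b_c,
    included, reason.
    """
    if model is None:
        model = SensitivityModel(min_alt_reads=min_alt_reads)
    rows = []
    for s_id in vaf_matrix.samples:
        alt = vaf_matrix.alt[s_id].to_numpy()
        depth = vaf_matrix.depth[s_id].to_numpy()
        reported = alt >= min_alt_reads
        b_r = int(reported.sum())
        if b_r == 0:
            rows.append((s_id, 0, np.nan, np.nan, np.nan, False, "no reported calls"))
            continue
        vafs = alt[reported] / depth[reported]
        c = estimate_clonality(vafs)
        profile = (
            depth_profiles.get(s_id)
            if depth_profiles is not None
            else DepthProfile.poisson(depth[reported].mean())
        )
        if not sample_passes_filter(profile, c, genome_fraction, min_alt_reads):
            rows.append((s_id, b_r, c, np.nan, np.nan, False, "insufficient depth for clonality"))
            continue
        s_val = sample_sensitivity(profile, c, model)
        try:
            b_c = correct_burden(b_r, s_val, min_sensitivity)
        except LowSensitivityError:
            rows.append((s_id, b_r, c, s_val, np.nan, False, "sensitivity too low"))
            continue
        rows.append((s_id, b_r, c, s_val, b_c, True, None))
    return pd.DataFrame(
        rows, columns=["sample_id", "b_r", "c", "s", "b_c", "included", "reason"]
    )


# ---------------------------------------------------------------------------
# the molecular clock
# ---------------------------------------------------------------------------


@dataclass
class ClockFit:
    """Linear clock b_c ~ age with a donor random intercept."""

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    donor_sd: float
    residual_sd: float
    n_samples: int
    n_donors: int
    method: str = "mixedlm"

    def predict(self, age) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(age, dtype=float)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_ci95": list(self.slope_ci),
            "intercept_ci95": list(self.intercept_ci),
            "donor_sd": self.donor_sd,
            "residual_sd": self.residual_sd,
            "n_samples": self.n_samples,
            "n_donors": self.n_donors,
            "method": self.method,
        }


def fit_clock(burden_table: pd.DataFrame) -> ClockFit:
    """Fit the mutation-rate clock b_c ~ age + (1 | donor).

    ``burden_table`` needs columns ``b_c``, ``age`` and ``donor``.  The
    model is a linear mixed model (REML) with Wald 95% CIs.  With a
    single donor the random intercept is unidentifiable and an OLS fit
    is returned with a warning; with exactly collinear data (zero
    residual variance) the variance components are unidentifiable and
    the exact interpolating line is returned.
    """
    tab = burden_table.dropna(subset=["b_c", "age"])
    ages = tab["age"].to_numpy(dtype=float)
    y = tab["b_c"].to_numpy(dtype=float)
    if np.unique(ages).size < 2:
        raise ClockError("need at least two distinct donor ages to fit the clock")
    donors = tab["donor"].astype(str).to_numpy()
    n_donors = np.unique(donors).size

    X = sm.add_constant(ages)
    ols = sm.OLS(y, X).fit()
    scale = max(float(np.abs(y).max()), 1.0)
    if np.sqrt(ols.ssr / len(y)) < 1e-8 * scale:
        # perfect line: variance components are 0/unidentifiable
        ci = ols.conf_int()
        return ClockFit(
            slope=float(ols.params[1]),
            intercept=float(ols.params[0]),
            slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
            intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
            donor_sd=0.0,
            residual_sd=0.0,
            n_samples=len(y),
            n_donors=n_donors,
            method="ols_exact",
        )
    if n_donors < 2:
        warnings.warn(
            "single donor: random intercept unidentifiable, falling back to OLS",
            stacklevel=2,
        )
        ci = ols.conf_int()
        return ClockFit(
            slope=float(ols.params[1]),
            intercept=float(ols.params[0]),
            slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
            intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
            donor_sd=0.0,
            residual_sd=float(np.sqrt(ols.scale)),
            n_samples=len(y),
            n_donors=n_donors,
            method="ols",
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = sm.MixedLM(y, X, groups=donors)
        fit = md.fit(reml=True)
    params = np.asarray(fit.fe_params)
    bse = np.asarray(fit.bse_fe)
    z = stats.norm.ppf(0.975)
    return ClockFit(
        slope=float(params[1]),
        intercept=float(params[0]),
        slope_ci=(float(params[1] - z * bse[1]), float(params[1] + z * bse[1])),
        intercept_ci=(float(params[0] - z * bse[0]), float(params[0] + z * bse[0])),
        donor_sd=float(np.sqrt(max(np.asarray(fit.cov_re)[0, 0], 0.0))),
        residual_sd=float(np.sqrt(fit.scale)),
        n_samples=len(y),
        n_donors=n_donors,
        method="mixedlm",
    )


@dataclass
class ClockAge:
    years: float
    clamped: bool = False

    @property
    def floor(self) -> int:
        return int(math.floor(self.years))

    @property
    def ceil(self) -> int:
        return int(math.ceil(self.years))


def clock_age(burden: float, intercept: float, rate: float) -> ClockAge:
    """Invert the clock: age = (burden - intercept) / rate in years.

    Negative ages clamp to zero with a flag.  With intercept ~130 and
    rate 16.4, burdens 300-400 map to roughly ages 10-17 (floor of the
    lower bound, ceiling of the upper).
    """
    if rate <= 0:
        raise ValueError("clock rate must be positive")
    years = (burden - intercept) / rate
    if years < 0:
        return ClockAge(0.0, clamped=True)
    return ClockAge(float(years))


def age_bracket(
    burden_low: float, burden_high: float, intercept: float, rate: float
) -> tuple[int, int]:
    """Integer age bracket for a burden interval (floor low, ceil high)."""
    return (
        clock_age(burden_low, intercept, rate).floor,
        clock_age(burden_high, intercept, rate).ceil,
    )
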