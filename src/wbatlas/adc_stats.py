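"""ADC evaluation statistics.

VOI summary statistics, test-retest repeatability (%RC), Bland-Altman
between-scanner agreement, independent-samples sex comparisons, multiple
linear regression of tissue ADC on age and sex, and voxel-wise Pearson
correlation maps between registered images and a subject covariate.

Conventions: %RC follows the quantitative-imaging-biomarker convention
RC = 2.77 x within-subject coefficient of variation; the within-subject
CV of a test-retest pair (x1, x2) is estimated as wCV^2 = mean over
subjects of d^2 / (2 m^2) with d = x1 - x2 and m = (x1 + x2)/2, on raw
(not log) differences. The sex t-test uses Welch's unequal-variance
form. p-values are uncorrected throughout, matching the single-centre
evaluation design; an optional Benjamini-Hochberg flag is available on
the correlation map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .dwi import ADCMap
from .volume import Volume

__all__ = [
    "VOIStats",
    "RepeatabilityResult",
    "BlandAltman",
    "RegressionFit",
    "CorrelationMap",
    "voi_stats",
    "repeatability_rc",
    "bland_altman",
    "sex_ttest",
    "fit_age_sex_regression",
    "voxelwise_correlation",
]

RC_FACTOR = 2.77  # 1.96 * sqrt(2): 95% repeatability coefficient multiplier


@dataclass(frozen=True)
class VOIStats:
    tissue: str
    adc_mean: float  # mm^2/s
    adc_median: float  # mm^2/s
    size_ml: float
    n_voxels: int


@dataclass(frozen=True)
class RepeatabilityResult:
    wcv: float  # fraction
    rc_pct: float  # percent, = 277 * wcv
    rc_abs: float  # absolute units, 2.77 * within-subject SD
    n_subjects: int


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n_pairs: int


@dataclass(frozen=True)
class RegressionFit:
    beta0: float
    beta_age: float
    beta_sex: float
    p_model: float
    p_age: float
    p_sex: float
    r2: float
    ci_age: tuple[float, float]
    ci_sex: tuple[float, float]


@dataclass(frozen=True)
class CorrelationMap:
    r_map: Volume
    p_map: Volume
    sig_mask: Volume
    defined_mask: Volume
    alpha: float


def voi_stats(adc: ADCMap, voi: Volume, tissue: str = "voi") -> VOIStats:
    """Mean/median ADC and physical size over a VOI (valid-fit voxels only)."""
    if not adc.adc.same_grid(voi):
        raise ValueError("VOI must live on the ADC grid")
    m = np.asarray(voi.values, dtype=bool)
    if not m.any():
        raise ValueError("empty VOI")
    valid = m & np.asarray(adc.valid_mask.values, dtype=bool)
    if not valid.any():
        raise ValueError("VOI contains no valid-fit voxels")
    vals = np.asarray(adc.adc.values)[valid]
    return VOIStats(
        tissue=tissue,
        adc_mean=float(vals.mean()),
        adc_median=float(np.median(vals)),
        size_ml=int(m.sum()) * voi.voxel_volume_ml,
        n_voxels=int(m.sum()),
    )


def repeatability_rc(pairs: Sequence[tuple[float, float]]) -> RepeatabilityResult:
    """Percentage repeatability coefficient from test-retest pairs.

    wCV^2 = mean(d^2 / (2 m^2)); %RC = 2.77 * wCV * 100. The absolute RC
    (2.77 * within-subject SD) is also reported.
    """
    pairs = [(float(a), float(b)) for a, b in pairs]
    if not pairs:
        raise ValueError("at least one pair required")
    ratios, wvars = [], []
    for a, b in pairs:
        m = (a + b) / 2.0
        if m <= 0:
            raise ValueError(f"non-positive pair mean {m}")
        d = a - b
        ratios.append(d**2 / (2.0 * m**2))
        wvars.append(d**2 / 2.0)
    wcv = float(np.sqrt(np.mean(ratios)))
    wsd = float(np.sqrt(np.mean(wvars)))
    return RepeatabilityResult(
        wcv=wcv,
        rc_pct=RC_FACTOR * wcv * 100.0,
        rc_abs=RC_FACTOR * wsd,
        n_subjects=len(pairs),
    )


def bland_altman(pairs: Sequence[tuple[float, float]]) -> BlandAltman:
    """Bland-Altman bias and 95% limits of agreement for paired scalars.

    Differences are a - b; LoA = bias +/- 1.96 * sample SD of the
    differences.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (a, b) pairs")
    diffs = arr[:, 0] - arr[:, 1]
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd_diff=sd,
        n_pairs=len(diffs),
    )


def sex_ttest(values_m: Sequence[float], values_f: Sequence[float]) -> tuple[float, float]:
    """Welch's two-sided independent-samples t-test (male vs female)."""
    m = np.asarray(values_m, dtype=float)
    f = np.asarray(values_f, dtype=float)
    if m.size < 2 or f.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = sps.ttest_ind(m, f, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def fit_age_sex_regression(
    adc: Sequence[float], age: Sequence[float], sex: Sequence[int]
) -> RegressionFit:
    """OLS fit adc = b0 + b_age*age + b_sex*sex (sex: female=0, male=1)."""
    import statsmodels.api as sm

    y = np.asarray(adc, dtype=float)
    a = np.asarray(age, dtype=float)
    s = np.asarray(sex, dtype=float)
    if y.size <= 3:
        raise ValueError("need more than 3 observations")
    if not set(np.unique(s)).issubset({0.0, 1.0}):
        raise ValueError("sex must be coded 0/1")
    if np.ptp(a) == 0 and np.ptp(s) == 0:
        raise ValueError("collinear design: age and sex are both constant")
    X = sm.add_constant(np.column_stack([a, s]))
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return RegressionFit(
        beta0=float(fit.params[0]),
        beta_age=float(fit.params[1]),
        beta_sex=float(fit.params[2]),
        p_model=float(fit.f_pvalue),
        p_age=float(fit.pvalues[1]),
        p_sex=float(fit.pvalues[2]),
        r2=float(fit.rsquared),
        ci_age=(float(ci[1][0]), float(ci[1][1])),
        ci_sex=(float(ci[2][0]), float(ci[2][1])),
    )


def voxelwise_correlation(
    registered_maps: Sequence[Volume],
    covariate: Sequence[float],
    alpha: float = 0.05,
    fdr: bool = False,
) -> CorrelationMap:
    """Voxel-wise Pearson correlation between registered maps and a covariate.

    Returns per-voxel r and two-sided p (from the exact t transform with
    n - 2 df), a significance mask at p < alpha (uncorrected by default;
    ``fdr=True`` applies Benjamini-Hochberg across defined voxels) and a
    mask of voxels where r is defined. A constant covariate leaves every
    voxel undefined; voxels with zero imaging variance are undefined.
    """
    vols = list(registered_maps)
    if len(vols) < 3:
        raise ValueError("need at least 3 subjects")
    cov = np.asarray(covariate, dtype=float)
    if cov.size != len(vols):
        raise ValueError("one covariate value per subject required")
    grid = vols[0]
    stack = np.stack([np.asarray(v.values, dtype=float) for v in vols])
    n = stack.shape[0]

    cov_c = cov - cov.mean()
    cov_ss = float(np.sum(cov_c**2))
    img_c = stack - stack.mean(axis=0)
    img_ss = np.sum(img_c**2, axis=0)
    defined = (cov_ss > 0) & (img_ss > 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        num = np.tensordot(cov_c, img_c, axes=(0, 0))
        r = np.where(defined, num / np.sqrt(np.where(defined, img_ss * cov_ss, 1.0)), np.nan)
        r = np.clip(r, -1.0, 1.0)
        df = n - 2
        rr = np.where(defined, r, 0.0)
        t = rr * np.sqrt(df / np.maximum(1.0 - rr**2, 1e-300))
        p = np.where(defined, 2.0 * sps.t.sf(np.abs(t), df), np.nan)

    if fdr:
        from statsmodels.stats.multitest import multipletests

        flat = p[defined]
        rej = np.zeros_like(flat, dtype=bool)
        if flat.size:
            rej, *_ = multipletests(flat, alpha=alpha, method="fdr_bh")[:1]
        sig = np.zeros(p.shape, dtype=bool)
        sig[defined] = rej
    else:
        sig = defined & (p < alpha)
    return CorrelationMap(
        r_map=grid.with_values(r),
        p_map=grid.with_values(p),
        sig_mask=grid.with_values(sig.astype(np.uint8)),
        defined_mask=grid.with_values(defined.astype(np.uint8)),
        alpha=float(alpha),
    )
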