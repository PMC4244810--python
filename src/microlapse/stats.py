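"""Population-level survival, heterogeneity and dead-cell spatial statistics.

Survival on the microscope side is the fraction of time-zero founders whose
microcolony divided; on the plate side it is the treated/control CFU ratio.
Log reduction uses log10 (the standard disinfectant-efficacy scale) while all
growth quantities use natural log — both conventions are kept explicit to
avoid unit drift.

The spatial statistic formalizes the visual claim that PI-positive cells are
randomly scattered inside a microcolony rather than concentrated at its
center (as nutrient depletion would predict): each dead cell gets a
normalized radial coordinate from the rank of its distance-transform depth
within the colony mask, and the mean squared coordinate is compared to its
Monte-Carlo null under uniform placement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.ndimage import distance_transform_edt

from .baranyi import FitResult
from .config import AnalysisConfig
from .tracking import FounderClassification

__all__ = [
    "ConditionSummary",
    "SpatialDeathTest",
    "survival_microscope",
    "survival_cfu",
    "log_reduction",
    "spearman_permutation",
    "summarize_condition",
    "dead_cell_spatial_test",
    "pool_spatial_tests",
]


def survival_microscope(n_dividing: int, n_total_t0: int) -> float:
    """Percent of time-zero founders that divided."""
    if n_total_t0 <= 0:
        raise ValueError("survival undefined: no founders at time zero")
    if not 0 <= n_dividing <= n_total_t0:
        raise ValueError("need 0 <= n_dividing <= n_total_t0")
    return 100.0 * n_dividing / n_total_t0


def survival_cfu(cfu_treatment: float, cfu_control: float) -> float:
    """Percent survival from plate counts: 100 * treatment / control."""
    if cfu_control <= 0:
        raise ValueError("control CFU must be positive")
    if cfu_treatment < 0:
        raise ValueError("treatment CFU must be non-negative")
    pct = 100.0 * cfu_treatment / cfu_control
    if pct > 100.0:
        warnings.warn("treatment count exceeds control: survival > 100%",
                      stacklevel=2)
    return pct


def log_reduction(log10_cfu_control: float, log10_cfu_treatment: float) -> float:
    """Difference of log10 CFU counts, control minus treatment."""
    if not (math.isfinite(log10_cfu_control) and math.isfinite(log10_cfu_treatment)):
        raise ValueError("log10 CFU inputs must be finite")
    return log10_cfu_control - log10_cfu_treatment


def spearman_permutation(x, y, n_perm: int = 999,
                         seed: int | None = None) -> tuple[float, float]:
    """Spearman rank correlation with a permutation p-value.

    Rank-based because post-stress lag and growth-rate distributions are
    skewed.  Returns (rho, p); (nan, nan) for fewer than 3 pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        return math.nan, math.nan
    rho = float(sps.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        rb = float(sps.spearmanr(x, rng.permutation(y)).statistic)
        if abs(rb) >= abs(rho) - 1e-12:
            count += 1
    return rho, (1 + count) / (n_perm + 1)


@dataclass
class SpatialDeathTest:
    """Monte-Carlo test of uniform dead-cell placement within one colony."""

    statistic: float | None  # mean squared normalized radial rank
    expected: float | None   # null expectation of the statistic
    p_value: float | None    # two-sided MC p; None when no dead cells
    n_dead: int
    n_replicates: int
    seed: int | None


def _radial_ranks(mask: np.ndarray) -> np.ndarray:
    """Normalized radial coordinate per foreground pixel: the fraction of
    mask pixels at least as deep (distance transform), so ~0 at the colony
    center and ~1 at its boundary."""
    depth = distance_transform_edt(mask)[mask.astype(bool)]
    sorted_d = np.sort(depth)
    n = len(depth)
    return (n - np.searchsorted(sorted_d, depth, side="left")) / n


def dead_cell_spatial_test(colony_mask: np.ndarray, dead_centroids,
                           B: int = 199, seed: int | None = None) -> SpatialDeathTest:
    """Two-sided Monte-Carlo test of spatially uniform death in a colony.

    ``dead_centroids`` are (row, col) points inside the mask.  The statistic
    is the mean squared normalized radial rank; small values mean deaths are
    center-concentrated, large values boundary-concentrated.  The p-value is
    (1 + #{|T_b - E| >= |T_obs - E|}) / (B + 1) over B uniform placements,
    with E the exact uniform expectation over the mask.
    """
    if B < 99:
        raise ValueError("need at least 99 Monte-Carlo replicates")
    mask = np.asarray(colony_mask).astype(bool)
    coords = np.argwhere(mask)
    if coords.size == 0:
        raise ValueError("empty colony mask")
    dead = np.atleast_2d(np.asarray(dead_centroids, dtype=float))
    if dead.size == 0:
        return SpatialDeathTest(None, None, None, 0, B, seed)

    r_hat = _radial_ranks(mask)
    # map each centroid to its mask pixel (nearest within a small radius)
    index_of = -np.ones(mask.shape, dtype=np.int64)
    index_of[coords[:, 0], coords[:, 1]] = np.arange(len(coords))
    dead_idx = []
    for rr, cc in dead:
        ri, ci = int(round(rr)), int(round(cc))
        found = -1
        for radius in range(3):
            r0, r1 = max(ri - radius, 0), min(ri + radius + 1, mask.shape[0])
            c0, c1 = max(ci - radius, 0), min(ci + radius + 1, mask.shape[1])
            block = index_of[r0:r1, c0:c1]
            cand = block[block >= 0]
            if cand.size:
                found = int(cand[0])
                break
        if found < 0:
            raise ValueError(f"dead centroid ({rr}, {cc}) lies outside the mask")
        dead_idx.append(found)

    r2 = r_hat**2
    t_obs = float(np.mean(r2[dead_idx]))
    expected = float(np.mean(r2))
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(coords), size=(B, len(dead_idx)))
    t_null = r2[draws].mean(axis=1)
    exceed = int(np.sum(np.abs(t_null - expected) >= abs(t_obs - expected) - 1e-12))
    p = (1 + exceed) / (B + 1)
    return SpatialDeathTest(t_obs, expected, p, len(dead_idx), B, seed)


def pool_spatial_tests(tests: list[SpatialDeathTest]) -> float | None:
    """Fisher's combination of per-colony Monte-Carlo p-values."""
    ps = [t.p_value for t in tests if t.p_value is not None]
    if not ps:
        return None
    chi2 = -2.0 * float(np.sum(np.log(ps)))
    return float(sps.chi2.sf(chi2, 2 * len(ps)))


@dataclass
class ConditionSummary:
    """Everything reported for one experimental condition."""

    condition: str
    n_total_t0: int
    n_dividing: int
    survival_micro: float
    n_fittable: int
    n_non_fittable: int
    median_lag: float | None
    median_mu_max: float | None
    iqr_lag: tuple[float, float] | None
    iqr_mu_max: tuple[float, float] | None
    lag_mu_spearman: float | None
    lag_mu_p_value: float | None
    low_n_warning: bool
    survival_cfu: float | None = None
    log_reduction: float | None = None
    spatial_pooled_p: float | None = None
    spatial_tests: list[SpatialDeathTest] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "spatial_tests"}
        d["spatial_tests"] = [t.__dict__ for t in self.spatial_tests]
        return d


def summarize_condition(classifications: list[FounderClassification],
                        fits: dict[int, FitResult],
                        config: AnalysisConfig,
                        cfu_table: pd.DataFrame | None = None,
                        spatial_tests: list[SpatialDeathTest] | None = None,
                        condition: str = "",
                        seed: int | None = None) -> ConditionSummary:
    """Aggregate per-founder classifications and fits into one summary.

    Medians and IQRs are computed over fittable fits of dividing founders
    only, mirroring the bookkeeping that excludes non-fittable microcolonies.
    A low-n flag (rather than suppression) marks conditions with too few
    fittable curves for the medians to mean much.
    """
    if config.count_pi_positive_t0:
        denom = classifications
    else:
        denom = [c for c in classifications if not c.pi_positive_t0]
    n_total = len(denom)
    n_div = sum(c.label_class == "dividing" for c in denom)
    surv = survival_microscope(n_div, n_total) if n_total else math.nan

    dividing_ids = {c.founder_id for c in classifications
                    if c.label_class == "dividing"}
    div_fits = [fits[i] for i in sorted(dividing_ids) if i in fits]
    fittable = [f for f in div_fits if f.fittable]
    n_fit, n_nofit = len(fittable), len(div_fits) - len(fittable)

    if fittable:
        lags = np.array([f.lag for f in fittable])
        mus = np.array([f.mu_max for f in fittable])
        med_lag, med_mu = float(np.median(lags)), float(np.median(mus))
        iqr_lag = tuple(float(v) for v in np.percentile(lags, [25, 75]))
        iqr_mu = tuple(float(v) for v in np.percentile(mus, [25, 75]))
        rho, pval = spearman_permutation(
            lags, mus, n_perm=config.stats.permutation_replicates,
            seed=config.seed if seed is None else seed)
    else:
        med_lag = med_mu = iqr_lag = iqr_mu = rho = pval = None

    low_n = n_fit < config.stats.min_fittable_for_medians
    if low_n:
        warnings.warn(
            f"condition {condition!r}: only {n_fit} fittable growth curves; "
            "medians are unreliable", stacklevel=2)

    surv_cfu = logred = None
    if cfu_table is not None and len(cfu_table):
        ratios = [survival_cfu(r.cfu_treatment, r.cfu_control)
                  for r in cfu_table.itertuples()]
        surv_cfu = float(np.mean(ratios))
        logred = float(np.mean([
            log_reduction(math.log10(r.cfu_control), math.log10(r.cfu_treatment))
            for r in cfu_table.itertuples()]))

    spatial_tests = spatial_tests or []
    return ConditionSummary(
        condition=condition,
        n_total_t0=n_total,
        n_dividing=n_div,
        survival_micro=surv,
        n_fittable=n_fit,
        n_non_fittable=n_nofit,
        median_lag=med_lag,
        median_mu_max=med_mu,
        iqr_lag=iqr_lag,
        iqr_mu_max=iqr_mu,
        lag_mu_spearman=rho,
        lag_mu_p_value=pval,
        low_n_warning=low_n,
        survival_cfu=surv_cfu,
        log_reduction=logred,
        spatial_pooled_p=pool_spatial_tests(spatial_tests),
        spatial_tests=spatial_tests,
    )
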