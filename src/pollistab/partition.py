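"""Hierarchical variance partitioning and Taylor's power-law fits.

The central object is the decomposition of the temporal coefficient of
variation (CV = temporal SD / temporal mean) of a metacommunity variable
across a 2 x 2 hierarchy of organizational level (population vs community)
and spatial scale (local vs regional). With ``x[u, k, t]`` the value of
unit ``u`` in patch ``k`` at time ``t`` and ``mu`` the temporal mean of
the region-wide total series:

    CV_S,L = sum_{u,k} sd(x[u,k,:]) / mu          (population, local)
    CV_C,L = sum_k sd(sum_u x[u,k,:]) / mu        (community, local)
    CV_S,R = sum_u sd(sum_k x[u,k,:]) / mu        (population, regional)
    CV_C,R = sd(sum_{u,k} x[u,k,:]) / mu          (community, regional)

Synchrony indices are the ratios between adjacent CVs, e.g. species
synchrony Psi_S->C,L = CV_C,L / CV_S,L and spatial synchrony
Psi_C,L->R = CV_C,R / CV_C,L, so the multiplicative chain
CV_C,R = CV_S,L * Psi_S->C,L * Psi_C,L->R holds by construction and every
Psi lies in [0, 1] because a sum's SD never exceeds the sum of the SDs.
Invariability, the stability measure, is the reciprocal 1/CV, so it is
non-decreasing from population to community to region.

Taylor's power law, Var = a * mean^b across units, is estimated by
ordinary least squares on log-log axes. The default regresses
log10(SD) on log10(mean), under which b = 0.5 corresponds to variance
growing linearly with the mean (the Poisson-like benchmark); the literal
variance-on-mean regression is available as ``convention="var_vs_mean"``
(linearity is then slope 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .survey_io import MetacommunityTensor

logger = logging.getLogger(__name__)

_IDENT_RTOL = 1e-12

LEVELS = ("population", "community", "region")


@dataclass
class PartitionResult:
    """The eight partition components plus invariability reciprocals.

    ``cv_*`` are weighted CVs; ``phi_*`` are synchrony ratios in [0, 1]
    (``phi_s2c_*`` species->community at a scale, ``phi_*_l2r``
    local->regional at a level); ``inv_*`` are reciprocal invariabilities
    (+inf when the CV is 0). ``degenerate`` lists the phi fields that were
    0/0 and reported as 1.
    """

    cv_s_l: float
    cv_c_l: float
    cv_s_r: float
    cv_c_r: float
    phi_s2c_l: float
    phi_c_l2r: float
    phi_s_l2r: float
    phi_s2c_r: float
    inv_s_l: float = math.nan
    inv_c_l: float = math.nan
    inv_s_r: float = math.nan
    inv_c_r: float = math.nan
    synchrony_scale: str = "cv_ratio"
    degenerate: list[str] = field(default_factory=list)
    n_units_excluded: int = 0

    CV_FIELDS = ("cv_s_l", "cv_c_l", "cv_s_r", "cv_c_r")
    PHI_FIELDS = ("phi_s2c_l", "phi_c_l2r", "phi_s_l2r", "phi_s2c_r")
    INV_FIELDS = ("inv_s_l", "inv_c_l", "inv_s_r", "inv_c_r")

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in self.CV_FIELDS + self.PHI_FIELDS + self.INV_FIELDS}
        d["synchrony_scale"] = self.synchrony_scale
        d["degenerate"] = list(self.degenerate)
        d["n_units_excluded"] = self.n_units_excluded
        return d


@dataclass
class TaylorFit:
    """Result of a log-log mean-variability regression across units."""

    b: float
    intercept: float
    r_squared: float
    n_units: int
    level: str
    convention: str
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "b": self.b,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_units": self.n_units,
            "level": self.level,
            "convention": self.convention,
            "n_excluded": self.n_excluded,
        }


def temporal_sd_mean(series) -> tuple[float, float]:
    """Sample SD (n-1 denominator) and mean of a temporal series.

    With only two time points (the minimal design) the sample SD reduces
    to |x1 - x2| / sqrt(2).
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("series must be 1-D with length >= 2")
    if not np.all(np.isfinite(arr)):
        raise ValueError("series contains non-finite values")
    return float(np.std(arr, ddof=1)), float(np.mean(arr))


def _complete_case(tensor: MetacommunityTensor) -> tuple[np.ndarray, int]:
    """Drop units with any unobserved cell; count-like tensors pass through."""
    if tensor.observed is None:
        return tensor.values, 0
    keep = tensor.observed.all(axis=(1, 2))
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "%s: dropping %d unit(s) with unobserved cells (complete-case partition)",
            tensor.variable,
            n_dropped,
        )
    if not keep.any():
        raise ValueError("no unit has complete observations across sites and years")
    return tensor.values[keep], n_dropped


def _phi(num: float, den: float, name: str, degenerate: list[str]) -> float:
    if den == 0.0:
        if num != 0.0:  # impossible under SD subadditivity; guard anyway
            raise ArithmeticError(f"synchrony {name}: nonzero/zero ratio")
        degenerate.append(name)
        return 1.0
    return num / den


def var_partition(
    tensor: MetacommunityTensor, synchrony_scale: str = "cv_ratio"
) -> PartitionResult:
    """Partition a tensor's temporal CV across the level x scale hierarchy.

    ``synchrony_scale="cv_ratio"`` (default) reports each synchrony as the
    ratio of the adjacent CVs, so the multiplicative identities
    CV_C,R = CV_C,L * phi_c_l2r etc. hold exactly. ``"variance"`` squares
    those ratios (e.g. var of the community total over the squared sum of
    population SDs), a scale some synchrony indices use; the identities
    then apply to squared CVs.

    Degenerate 0/0 synchronies (all component series constant) are
    reported as 1 and flagged rather than raised, so batch runs over many
    variables survive a constant one.
    """
    if synchrony_scale not in ("cv_ratio", "variance"):
        raise ValueError("synchrony_scale must be 'cv_ratio' or 'variance'")
    values, n_excluded = _complete_case(tensor)
    total = values.sum(axis=(0, 1))  # regional total series over time
    mu = float(total.mean())
    if not np.any(values):
        raise ValueError("degenerate metacommunity: all-zero tensor")
    if mu <= 0:
        raise ValueError("degenerate metacommunity: nonpositive regional mean")

    sd_pop_local = np.std(values, axis=2, ddof=1)            # (U, K)
    sd_comm_local = np.std(values.sum(axis=0), axis=1, ddof=1)   # (K,)
    sd_pop_regional = np.std(values.sum(axis=1), axis=1, ddof=1)  # (U,)
    sd_comm_regional = float(np.std(total, ddof=1))

    cv_s_l = float(sd_pop_local.sum()) / mu
    cv_c_l = float(sd_comm_local.sum()) / mu
    cv_s_r = float(sd_pop_regional.sum()) / mu
    cv_c_r = sd_comm_regional / mu

    degenerate: list[str] = []
    phi_s2c_l = _phi(cv_c_l, cv_s_l, "phi_s2c_l", degenerate)
    phi_c_l2r = _phi(cv_c_r, cv_c_l, "phi_c_l2r", degenerate)
    phi_s_l2r = _phi(cv_s_r, cv_s_l, "phi_s_l2r", degenerate)
    phi_s2c_r = _phi(cv_c_r, cv_s_r, "phi_s2c_r", degenerate)
    if synchrony_scale == "variance":
        phi_s2c_l, phi_c_l2r = phi_s2c_l**2, phi_c_l2r**2
        phi_s_l2r, phi_s2c_r = phi_s_l2r**2, phi_s2c_r**2

    result = PartitionResult(
        cv_s_l=cv_s_l,
        cv_c_l=cv_c_l,
        cv_s_r=cv_s_r,
        cv_c_r=cv_c_r,
        phi_s2c_l=phi_s2c_l,
        phi_c_l2r=phi_c_l2r,
        phi_s_l2r=phi_s_l2r,
        phi_s2c_r=phi_s2c_r,
        synchrony_scale=synchrony_scale,
        degenerate=degenerate,
        n_units_excluded=n_excluded,
    )
    return invariability(result)


def invariability(result: PartitionResult) -> PartitionResult:
    """Fill the invariability fields with reciprocal CVs (1/CV).

    A zero CV (constant series) maps to +inf and is flagged.
    """
    for cv_name, inv_name in zip(result.CV_FIELDS, result.INV_FIELDS):
        cv = getattr(result, cv_name)
        if cv == 0.0:
            setattr(result, inv_name, math.inf)
            flag = f"{inv_name}_infinite"
            if flag not in result.degenerate:
                result.degenerate.append(flag)
        else:
            setattr(result, inv_name, 1.0 / cv)
    return result


def taylor_units(
    tensor: MetacommunityTensor, level: str
) -> tuple[list[tuple[float, float]], int]:
    """Extract (temporal mean, temporal SD) pairs at a hierarchical level.

    ``population`` yields one pair per (unit, patch) series, ``community``
    one per patch-total series, and ``region`` pools both lower levels.
    Series with zero mean or zero SD have no log-log coordinate and are
    dropped; the count of dropped series is returned alongside.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    values, _ = _complete_case(tensor)

    series: list[np.ndarray] = []
    if level in ("population", "region"):
        u, k, _ = values.shape
        series.extend(values[i, j] for i in range(u) for j in range(k))
    if level in ("community", "region"):
        series.extend(values.sum(axis=0)[j] for j in range(values.shape[1]))

    pairs: list[tuple[float, float]] = []
    n_excluded = 0
    for s in series:
        sd, mean = temporal_sd_mean(s)
        if mean > 0 and sd > 0:
            pairs.append((mean, sd))
        else:
            n_excluded += 1
    if n_excluded:
        logger.info(
            "taylor_units(%s, %s): dropped %d zero-mean/zero-SD series",
            tensor.variable,
            level,
            n_excluded,
        )
    return pairs, n_excluded


def taylor_fit(
    pairs,
    convention: str = "sd_vs_mean",
    level: str = "population",
    n_excluded: int = 0,
) -> TaylorFit:
    """OLS fit of the mean-variability scaling exponent on log10 axes.

    ``sd_vs_mean`` (default) regresses log10(SD) on log10(mean): the slope
    b equals 0.5 exactly when variance is proportional to the mean.
    ``var_vs_mean`` regresses log10(SD^2) on log10(mean) and reports the
    slope as-is (linearity of variance in mean then gives slope 1).
    """
    if convention not in ("sd_vs_mean", "var_vs_mean"):
        raise ValueError("convention must be 'sd_vs_mean' or 'var_vs_mean'")
    usable = [(m, s) for m, s in pairs if m > 0 and s > 0]
    if len(usable) < 3:
        raise ValueError(
            f"Taylor fit needs >= 3 units with positive mean and SD, got {len(usable)}"
        )
    means = np.array([m for m, _ in usable])
    sds = np.array([s for _, s in usable])
    x = np.log10(means)
    y = np.log10(sds) if convention == "sd_vs_mean" else np.log10(sds**2)
    if np.ptp(x) == 0:
        raise ValueError("all unit means identical; scaling slope undefined")
    fit = stats.linregress(x, y)
    return TaylorFit(
        b=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_units=len(usable),
        level=level,
        convention=convention,
        n_excluded=n_excluded,
    )
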