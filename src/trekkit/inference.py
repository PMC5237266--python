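"""Inference of core substitution rate constants from age-graded fractions.

For every reference position the fractions of the three non-consensus bases
across the age-graded subfamilies are regressed against subfamily age
(converted to byr, so slopes are byr^-1).  A position reports rates only
when the three stringency criteria hold:

1. depth: >= ``min_depth`` mapped bases at the position in every subfamily;
2. prevalence: the reference's consensus base is the most prevalent variant
   with at least ``min_prevalence`` occurrence in every subfamily;
3. correlation: the fraction-versus-age Pearson correlation exceeds
   ``min_pearson`` (strict), applied per target-base fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import BASES, BASE_CODES
from .alignment import AlignParams, PositionProfile, profile_counts
from .datamodel import ReferenceSeq, SubfamilyPool

MYR_PER_BYR = 1000.0


# ----------------------------------------------------------- small analytics

def expected_fraction(rate: float, dt: float) -> float:
    """Expected substituted-base fraction r*dt after time dt (byr) in the
    single-hit regime."""
    if rate < 0 or dt < 0:
        raise ValueError("rate and dt must be non-negative")
    p = rate * dt
    if p >= 1:
        raise ValueError(f"r*dt = {p:.3g} >= 1: outside the single-hit regime")
    return p


def repeated_substitution_bias(rate: float, dt: float) -> float:
    """Percent underestimation of a rate constant caused by ignoring second
    hits at the same site: 100 * r * dt."""
    return 100.0 * expected_fraction(rate, dt)


# ------------------------------------------------------- stringency criteria

def check_depth(profile: PositionProfile, min_depth: int = 700) -> bool:
    """True iff every subfamily has >= min_depth mapped bases here."""
    return bool((profile.counts.sum(axis=1) >= min_depth).all())


def check_prevalence(profile: PositionProfile, min_frac: float = 0.8) -> bool:
    """True iff the consensus base is the most prevalent variant with at
    least ``min_frac`` occurrence in every subfamily (zero depth fails)."""
    if profile.consensus_base not in BASE_CODES:
        return False
    c = BASE_CODES[profile.consensus_base]
    depth = profile.counts.sum(axis=1)
    if (depth == 0).any():
        return False
    cons = profile.counts[:, c]
    most_prevalent = (cons >= profile.counts.max(axis=1)).all()
    return bool(most_prevalent and (cons / depth >= min_frac).all())


def check_correlation(pearson_r: float, min_r: float = 0.7) -> bool:
    """Strictly-greater-than test; undefined (NaN) correlations fail."""
    return bool(np.isfinite(pearson_r) and pearson_r > min_r)


# -------------------------------------------------------------- line fitting

@dataclass
class FractionSeries:
    """Substituted fractions of one position across the age-graded pools."""

    ages: np.ndarray                      # myr, one per subfamily
    fractions: dict[str, np.ndarray]      # target base -> fraction per subfamily
    depth: np.ndarray                     # mapped-base count per subfamily
    consensus_base: str


def _ols(x: np.ndarray, y: np.ndarray, through_origin: bool) -> tuple[float, float, float]:
    """Slope, Pearson r and slope t-value of y against x."""
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 age points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in ages")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    sxy = float(xc @ yc)
    pearson = sxy / np.sqrt(sxx * syy) if syy > 0 else np.nan
    if through_origin:
        sxx0 = float(x @ x)
        slope = float(x @ y) / sxx0
        resid = y - slope * x
        dof = n - 1
        se = np.sqrt(float(resid @ resid) / dof / sxx0)
    else:
        slope = sxy / sxx
        resid = yc - slope * xc
        dof = n - 2
        se = np.sqrt(float(resid @ resid) / dof / sxx)
    t = slope / se if se > 0 else np.inf * np.sign(slope) if slope != 0 else np.nan
    return slope, pearson, t


def fit_rate(series: FractionSeries, target_base: str,
             through_origin: bool = False) -> tuple[float, float, float]:
    """Least-squares slope of substituted fraction versus age.

    Ages (myr) are converted to byr so the slope is a rate in byr^-1.
    Returns (rate, pearson_r, t_value); the rate is the raw slope (may be
    negative — clamping is the caller's policy).
    """
    if target_base == series.consensus_base:
        raise ValueError("target base equals the consensus base")
    x = np.asarray(series.ages, dtype=float) / MYR_PER_BYR
    y = np.asarray(series.fractions[target_base], dtype=float)
    return _ols(x, y, through_origin)


# ---------------------------------------------------------------- full sweep

@dataclass(frozen=True)
class InferenceConfig:
    min_depth: int = 700
    min_prevalence: float = 0.8
    min_pearson: float = 0.7
    require_all_fits: bool = False
    through_origin: bool = False


@dataclass
class PositionRates:
    """Reported rates at one reference position (only passing targets)."""

    position: int                         # 1-based
    consensus_base: str
    rates: dict[str, float]               # clamped at 0
    raw_slopes: dict[str, float] = field(default_factory=dict)
    pearson: dict[str, float] = field(default_factory=dict)
    t_value: dict[str, float] = field(default_factory=dict)


def infer_rates(pools: list[SubfamilyPool], reference: ReferenceSeq,
                config: InferenceConfig | None = None,
                params: AlignParams | None = None,
                trusted_offsets: bool = False) -> list[PositionRates]:
    """Run the full stringency-filtered sweep over all non-excluded positions.

    Vectorised over positions; equivalent to building a FractionSeries per
    position and calling :func:`fit_rate` per target base.
    """
    if not pools:
        return []
    config = config or InferenceConfig()
    counts = profile_counts(pools, reference, params, trusted_offsets)
    ages_byr = np.array([p.age for p in pools], dtype=float) / MYR_PER_BYR
    if len(set(ages_byr.tolist())) != len(ages_byr):
        raise ValueError("pools must have distinct ages")
    return _infer_from_counts(counts, ages_byr, reference, config)


def _infer_from_counts(counts: np.ndarray, ages_byr: np.ndarray,
                       reference: ReferenceSeq,
                       config: InferenceConfig) -> list[PositionRates]:
    n_sub, L, _ = counts.shape
    if n_sub < 3:
        raise ValueError("need at least 3 age groups for a fit")
    ref_codes = np.array([BASE_CODES.get(b, 4) for b in reference.sequence])

    depth = counts.sum(axis=2)                              # (n_sub, L)
    ok = ~reference.excluded_mask()
    ok &= ref_codes < 4
    ok &= (depth >= config.min_depth).all(axis=0)           # criterion 1

    with np.errstate(invalid="ignore", divide="ignore"):
        frac = counts / depth[:, :, None]                   # (n_sub, L, 4)
    pos_idx = np.arange(L)
    safe_codes = np.minimum(ref_codes, 3)  # N positions are masked out via ok
    cons_count = counts[:, pos_idx, safe_codes]             # (n_sub, L)
    cons_frac = np.where(depth > 0, cons_count / np.maximum(depth, 1), 0.0)
    prevalent = (cons_count >= counts.max(axis=2)).all(axis=0)
    ok &= prevalent & (cons_frac >= config.min_prevalence).all(axis=0) \
        & (depth > 0).all(axis=0)                           # criterion 2

    # vectorised OLS of fraction vs age for every (position, base)
    x = ages_byr
    xc = x - x.mean()
    sxx = float(xc @ xc)
    y = frac                                                # (n_sub, L, 4)
    yc = y - y.mean(axis=0)
    sxy = np.einsum("s,slb->lb", xc, yc)
    syy = np.einsum("slb,slb->lb", yc, yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        pearson = sxy / np.sqrt(sxx * syy)
    if config.through_origin:
        sxx0 = float(x @ x)
        slope = np.einsum("s,slb->lb", x, y) / sxx0
        resid = y - slope[None] * x[:, None, None]
        dof, denom = n_sub - 1, sxx0
    else:
        slope = sxy / sxx
        resid = yc - slope[None] * xc[:, None, None]
        dof, denom = n_sub - 2, sxx
    rss = np.einsum("slb,slb->lb", resid, resid)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(rss / dof / denom)
        tval = np.where(se > 0, slope / se, np.where(slope != 0, np.inf, np.nan))

    corr_ok = np.isfinite(pearson) & (pearson > config.min_pearson)  # criterion 3

    out: list[PositionRates] = []
    for i in np.flatnonzero(ok):
        cons = reference.sequence[i]
        targets = [b for b in BASES if b != cons]
        codes = [BASE_CODES[b] for b in targets]
        passing = [b for b, c in zip(targets, codes) if corr_ok[i, c]]
        if not passing:
            continue
        if config.require_all_fits and len(passing) < 3:
            continue
        pr = PositionRates(position=i + 1, consensus_base=cons, rates={})
        for b in passing:
            c = BASE_CODES[b]
            raw = float(slope[i, c])
            pr.raw_slopes[b] = raw
            pr.rates[b] = max(raw, 0.0)
            pr.pearson[b] = float(pearson[i, c])
            pr.t_value[b] = float(tval[i, c])
        out.append(pr)
    return out
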