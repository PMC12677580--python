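"""Axial circular statistics for dominant-orientation angles.

Alignment angles on a micropattern are *axial*: a fibre at +10° is the
same fibre as one at −170°, so all angles live on the half circle
(−90°, +90°] and are handled by the standard doubling device — multiply
by two, compute ordinary circular statistics on the full circle, and
halve the results back.  The module provides descriptive statistics
(circular mean, circular SD, mean resultant length), a large-sample /
bootstrap confidence interval for the mean direction, the CI-inversion
one-sample mean-angle test, Watson's two-sample U² test with permutation
and asymptotic p-values, and the population-level chirality call
(clockwise when the mean angle is significantly negative, counter-
clockwise when significantly positive, viewed from the culture-medium
side).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import CIUndefinedError, UndefinedMeanError

__all__ = [
    "AngleSample",
    "CircularSummary",
    "OneSampleResult",
    "WatsonTestResult",
    "wrap_axial",
    "double_angles",
    "halve_angles",
    "circular_mean_axial",
    "circular_sd_axial",
    "mean_resultant_axial",
    "ci_mean_axial",
    "one_sample_mean_test",
    "watson_u2_stat",
    "watson_u2_test",
    "summarize",
    "frequency_distribution",
]

_RBAR_EPS = 1e-12


def wrap_axial(angles_deg):
    """Map angles (degrees) to the half circle (−90, 90].

    Axial identity: θ and θ±180° denote the same orientation; −90 maps
    to +90 (half-open interval, tie broken upward).
    """
    a = np.asarray(angles_deg, dtype=float)
    r = np.mod(a, 180.0)
    r = np.where(r > 90.0, r - 180.0, r)
    # mod can return exactly 0.0 for inputs like 180; −90 itself becomes 90
    r = np.where(r == -90.0, 90.0, r)
    return r if r.ndim else float(r)


@dataclass(frozen=True)
class AngleSample:
    """A labelled collection of axial angles, one per surviving rectangle."""

    label: str
    angles_deg: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.angles_deg, dtype=float)
        if a.ndim != 1 or a.size < 1:
            raise ValueError("AngleSample needs a non-empty 1-D angle array")
        if not np.all(np.isfinite(a)):
            raise ValueError("angles must be finite")
        if np.any(a <= -90.0) or np.any(a > 90.0):
            raise ValueError("angles must lie in (-90, 90]; use from_degrees to wrap")
        object.__setattr__(self, "angles_deg", a)

    @classmethod
    def from_degrees(cls, label: str, angles_deg: Iterable[float]) -> "AngleSample":
        """Build a sample, wrapping arbitrary degree values axially."""
        return cls(label, np.atleast_1d(wrap_axial(np.asarray(list(angles_deg), float))))

    @property
    def n(self) -> int:
        return int(self.angles_deg.size)


@dataclass(frozen=True)
class OneSampleResult:
    """Outcome of the CI-inversion one-sample mean-angle test."""

    reject: bool
    mu0_deg: float
    mean_deg: float
    ci95: tuple[float, float]
    level: float

    def __bool__(self) -> bool:
        return self.reject


@dataclass(frozen=True)
class WatsonTestResult:
    u2: float
    p_value: float
    method: Literal["permutation", "asymptotic"]
    n_perm: int | None = None


@dataclass(frozen=True)
class CircularSummary:
    """Descriptive axial statistics and the chirality call for one group."""

    label: str
    mean_deg: float
    sd_deg: float
    rbar: float
    n: int
    ci95: tuple[float, float] | None
    kurtosis: float
    chirality: Literal["CW", "CCW", "indeterminate"]

    def as_dict(self) -> dict:
        d = {
            "label": self.label,
            "mean_deg": self.mean_deg,
            "sd_deg": self.sd_deg,
            "rbar": self.rbar,
            "n": self.n,
            "ci95_low_deg": None if self.ci95 is None else self.ci95[0],
            "ci95_high_deg": None if self.ci95 is None else self.ci95[1],
            "kurtosis": self.kurtosis,
            "chirality": self.chirality,
        }
        return d


def _as_sample(sample) -> AngleSample:
    if isinstance(sample, AngleSample):
        return sample
    return AngleSample("sample", np.atleast_1d(np.asarray(sample, float)))


def double_angles(sample) -> np.ndarray:
    """Doubling transform: half-circle angles θ → 2θ on [0, 360) degrees."""
    s = _as_sample(sample)
    return np.mod(2.0 * s.angles_deg, 360.0)


def halve_angles(full_deg) -> np.ndarray:
    """Inverse of :func:`double_angles`: full-circle → (−90, 90]."""
    return np.atleast_1d(wrap_axial(np.asarray(full_deg, float) / 2.0))


def _doubled_resultant(angles_deg: np.ndarray):
    """(R̄, mean direction in rad) of the doubled angles."""
    alpha = np.deg2rad(2.0 * angles_deg)
    C = np.cos(alpha).sum()
    S = np.sin(alpha).sum()
    n = alpha.size
    rbar = float(np.hypot(C, S) / n)
    mu = float(np.arctan2(S, C))
    return rbar, mu


def mean_resultant_axial(sample) -> float:
    """Mean resultant length R̄ of the doubled angles, in [0, 1]."""
    s = _as_sample(sample)
    rbar, _ = _doubled_resultant(s.angles_deg)
    return min(rbar, 1.0)


def circular_mean_axial(sample) -> float:
    """Axial circular mean in degrees on (−90, 90].

    Computed as ½·atan2(Σ sin 2θ, Σ cos 2θ).  Undefined when the doubled
    resultant vanishes (e.g. the exactly balanced pair {−45°, +45°}).
    """
    s = _as_sample(sample)
    rbar, mu = _doubled_resultant(s.angles_deg)
    if rbar < _RBAR_EPS:
        raise UndefinedMeanError(
            f"mean resultant length {rbar:.2e} ~ 0; axial mean undefined"
        )
    return float(wrap_axial(np.rad2deg(mu) / 2.0))


def circular_sd_axial(sample) -> float:
    """Axial circular standard deviation in degrees (half-circle scale).

    sd = (180/π)·sqrt(−2 ln R̄)/2 with R̄ taken on the doubled circle;
    the final halving mirrors the halving of the mean, so values are
    directly comparable to half-circle angles.
    """
    s = _as_sample(sample)
    rbar, _ = _doubled_resultant(s.angles_deg)
    if rbar < _RBAR_EPS:
        raise UndefinedMeanError("mean resultant length ~ 0; SD undefined")
    rbar = min(rbar, 1.0)
    return float(np.rad2deg(np.sqrt(max(-2.0 * np.log(rbar), 0.0))) / 2.0)


def ci_mean_axial(
    sample,
    level: float = 0.95,
    *,
    n_boot: int = 9999,
    allow_bootstrap: bool = True,
    seed: int = 0,
) -> tuple[float, float]:
    """Confidence interval for the axial mean, degrees on the half-circle scale.

    Default method is the large-sample interval for the mean direction of
    the doubled angles based on the circular dispersion
    δ̂ = (1 − ρ̂₂)/(2 R̄²) (ρ̂₂ the second central trigonometric moment):
    half-width = arcsin(z·sqrt(δ̂/n)).  When n < 25 or the arcsin argument
    reaches 1 the percentile bootstrap (``n_boot`` resamples) is used
    instead.  Endpoints are halved back to the half-circle scale and
    returned centred on the mean (so an interval spanning ±90° is not
    wrapped; the mean is always inside it).
    """
    s = _as_sample(sample)
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    n = s.n
    alpha = np.deg2rad(double_angles(s))
    rbar, mu = _doubled_resultant(s.angles_deg)
    if rbar < _RBAR_EPS:
        raise UndefinedMeanError("mean resultant length ~ 0; CI undefined")
    mean_half = float(wrap_axial(np.rad2deg(mu) / 2.0))

    use_boot = n < 25
    half_rad = None
    if not use_boot:
        rho2 = float(np.mean(np.cos(2.0 * (alpha - mu))))
        delta = (1.0 - rho2) / (2.0 * rbar * rbar)
        arg = _sps.norm.ppf(0.5 + level / 2.0) * np.sqrt(max(delta, 0.0) / n)
        if arg >= 1.0:
            use_boot = True
        else:
            half_rad = float(np.arcsin(arg))

    if use_boot:
        if not allow_bootstrap:
            raise CIUndefinedError(
                "large-sample CI unavailable (dispersion too large or n too "
                "small) and bootstrap disabled"
            )
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        boot = alpha[idx]
        C = np.cos(boot).sum(axis=1)
        S = np.sin(boot).sum(axis=1)
        mus = np.arctan2(S, C)
        # deviations from the observed mean direction, wrapped to (−π, π]
        dev = np.angle(np.exp(1j * (mus - mu)))
        lo, hi = np.quantile(dev, [0.5 - level / 2.0, 0.5 + level / 2.0])
        return (mean_half + float(np.rad2deg(lo)) / 2.0,
                mean_half + float(np.rad2deg(hi)) / 2.0)

    half_deg = np.rad2deg(half_rad) / 2.0
    return (mean_half - half_deg, mean_half + half_deg)


def _axial_diff(a_deg: float, b_deg: float) -> float:
    """Signed axial difference a − b wrapped to (−90, 90]."""
    return float(wrap_axial(a_deg - b_deg))


def one_sample_mean_test(
    sample,
    mu0_deg: float = 0.0,
    level: float = 0.95,
    **ci_kwargs,
) -> OneSampleResult:
    """One-sample test for the mean angle by CI inversion.

    Rejects H0: μ = μ0 iff μ0 (taken axially, mod 180°) lies outside the
    ``level`` confidence interval of the mean.
    """
    s = _as_sample(sample)
    lo, hi = ci_mean_axial(s, level, **ci_kwargs)
    mean = circular_mean_axial(s)
    d = _axial_diff(mu0_deg, mean)
    inside = (lo - mean) <= d <= (hi - mean)
    return OneSampleResult(
        reject=not inside, mu0_deg=float(mu0_deg), mean_deg=mean,
        ci95=(lo, hi), level=level,
    )


def _u2_from_labels(z: np.ndarray, tie_splits: np.ndarray | None,
                    n: int, m: int) -> np.ndarray:
    """Watson U² from 0/1 group labels in pooled sorted order.

    ``z`` may be 1-D (one labelling) or 2-D (stacked permutations).  Over
    a tied block both empirical CDFs jump together, so the cumulative-
    fraction difference d_k = F_a(x_k) − F_b(x_k) is replaced by the
    block average (midpoint of d before and after the block, which is
    independent of the arbitrary within-block ordering and antisymmetric
    under swapping the groups).  ``tie_splits`` gives the block starts.
    """
    z2 = np.atleast_2d(z).astype(float)
    N = z2.shape[1]
    d = np.cumsum(z2 / n - (1.0 - z2) / m, axis=1)
    if tie_splits is not None:
        counts = np.diff(np.append(tie_splits, N))
        ends = np.append(tie_splits[1:], N) - 1
        e = d[:, ends]
        s = np.concatenate([np.zeros((e.shape[0], 1)), e[:, :-1]], axis=1)
        d = np.repeat((s + e) / 2.0, counts, axis=1)
    u2 = (n * m / N**2) * (np.sum(d * d, axis=1) - np.sum(d, axis=1) ** 2 / N)
    return u2 if z.ndim == 2 else u2[0]


def watson_u2_stat(a, b) -> float:
    """Watson's two-sample U² statistic on the doubled angles."""
    sa, sb = _as_sample(a), _as_sample(b)
    xa, xb = double_angles(sa), double_angles(sb)
    pooled = np.concatenate([xa, xb])
    labels = np.concatenate([np.ones(sa.n), np.zeros(sb.n)])
    order = np.argsort(pooled, kind="stable")
    pooled_sorted = pooled[order]
    z = labels[order]
    ties = np.flatnonzero(np.diff(pooled_sorted) != 0.0) + 1
    tie_splits = np.concatenate([[0], ties]) if ties.size < pooled.size - 1 else None
    return float(_u2_from_labels(z, tie_splits, sa.n, sb.n))


def _watson_asymptotic_p(u2: float, n_terms: int = 60) -> float:
    """Asymptotic tail P(U² > u2) = 2 Σ (−1)^{m−1} exp(−2 m² π² u2)."""
    m = np.arange(1, n_terms + 1)
    p = 2.0 * np.sum((-1.0) ** (m - 1) * np.exp(-2.0 * m**2 * np.pi**2 * u2))
    return float(min(max(p, 0.0), 1.0))


def watson_u2_test(
    a,
    b,
    n_perm: int = 9999,
    method: Literal["permutation", "asymptotic"] = "permutation",
    seed: int = 0,
) -> WatsonTestResult:
    """Watson's two-sample U² test on doubled (axial) angles.

    The statistic is rotation invariant on the circle, which makes it the
    natural two-sample test for alignment-angle distributions.  The
    default p-value is obtained by random permutation of group labels
    (exact null guarantee at any sample size); ``method="asymptotic"``
    uses the large-sample series instead.
    """
    sa, sb = _as_sample(a), _as_sample(b)
    if sa.n < 8 or sb.n < 8:
        raise ValueError("watson_u2_test requires at least 8 angles per group")
    xa, xb = double_angles(sa), double_angles(sb)
    pooled = np.concatenate([xa, xb])
    labels = np.concatenate([np.ones(sa.n), np.zeros(sb.n)])
    order = np.argsort(pooled, kind="stable")
    pooled_sorted = pooled[order]
    z = labels[order]
    ties = np.flatnonzero(np.diff(pooled_sorted) != 0.0) + 1
    tie_splits = np.concatenate([[0], ties]) if ties.size < pooled.size - 1 else None
    u2_obs = float(_u2_from_labels(z, tie_splits, sa.n, sb.n))

    if method == "asymptotic":
        return WatsonTestResult(u2_obs, _watson_asymptotic_p(u2_obs), "asymptotic")
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(z, (n_perm, 1)), axis=1)
    u2_perm = _u2_from_labels(perms, tie_splits, sa.n, sb.n)
    p = (1.0 + np.count_nonzero(u2_perm >= u2_obs)) / (n_perm + 1.0)
    return WatsonTestResult(u2_obs, float(p), "permutation", n_perm)


def summarize(
    sample,
    mu0_deg: float = 0.0,
    level: float = 0.95,
    *,
    seed: int = 0,
) -> CircularSummary:
    """Full descriptive summary plus the chirality call for one group.

    Chirality is CW when the one-sample test rejects μ0 = 0 with a
    negative mean angle (left-up → right-down as displayed), CCW when it
    rejects with a positive mean, otherwise indeterminate.  The kurtosis
    reported is the linear excess kurtosis of the half-circle angles, a
    peakedness index used to judge how tightly cells align.
    """
    s = _as_sample(sample)
    mean = circular_mean_axial(s)
    sd = circular_sd_axial(s)
    rbar = mean_resultant_axial(s)
    kurt = float(_sps.kurtosis(s.angles_deg, fisher=True, bias=True))
    if s.n < 10:
        return CircularSummary(s.label, mean, sd, rbar, s.n, None, kurt,
                               "indeterminate")
    res = one_sample_mean_test(s, mu0_deg, level, seed=seed)
    if res.reject and mean < mu0_deg:
        chirality = "CW"
    elif res.reject and mean > mu0_deg:
        chirality = "CCW"
    else:
        chirality = "indeterminate"
    return CircularSummary(s.label, mean, sd, rbar, s.n, res.ci95, kurt, chirality)


def frequency_distribution(sample, bin_width_deg: float = 10.0) -> pd.DataFrame:
    """Histogram of angles over half-open bins (lo, hi] covering (−90, 90].

    ``bin_width_deg`` must divide 180 evenly; counts sum to n.
    """
    s = _as_sample(sample)
    k = 180.0 / bin_width_deg
    if abs(k - round(k)) > 1e-9 or bin_width_deg <= 0:
        raise ValueError("bin_width_deg must divide 180 evenly")
    k = int(round(k))
    idx = np.ceil((s.angles_deg + 90.0) / bin_width_deg).astype(int) - 1
    idx = np.clip(idx, 0, k - 1)
    counts = np.bincount(idx, minlength=k)
    left = -90.0 + bin_width_deg * np.arange(k)
    return pd.DataFrame({
        "bin_left_deg": left,
        "bin_right_deg": left + bin_width_deg,
        "count": counts,
    })
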