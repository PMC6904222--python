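"""Stuck/fast decomposition of microtubule velocity distributions.

Under roadblocks a gliding filament population splits into two velocity
modes: a stuck component centered at 0 nm/s and a fast component above
400 nm/s.  The primary fit is binned least squares of a two-Gaussian model
to the velocity histogram (bin width 50 nm/s), with the component means
constrained to |stuck| <= 50 nm/s and fast >= 400 nm/s; an EM fit on the
raw samples (scikit-learn) is kept as an internal cross-check oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "VelocityMixture",
    "fit_two_gaussians",
    "fit_two_gaussians_em",
    "roadblock_series",
    "by_motor_number",
]

STUCK_MEAN_BOUND = 50.0      # nm/s: |stuck mean| constraint
FAST_MEAN_FLOOR = 400.0      # nm/s: fast-mean constraint


@dataclass(frozen=True)
class VelocityMixture:
    """Two-component Gaussian decomposition of a velocity sample."""

    stuck_weight: float
    stuck_mean: float
    stuck_sd: float
    fast_weight: float
    fast_mean: float
    fast_sd: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isclose(self.stuck_weight + self.fast_weight, 1.0, atol=1e-6):
            raise ValueError("mixture weights must sum to 1")
        if self.stuck_weight < 0 or self.fast_weight < 0:
            raise ValueError("mixture weights must be non-negative")

    @property
    def degenerate(self) -> bool:
        return bool(self.diagnostics.get("degenerate", False))


def _gauss(v, mean, sd):
    return np.exp(-0.5 * ((v - mean) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))


def fit_two_gaussians(samples, bin_width: float = 50.0) -> VelocityMixture:
    """Binned least-squares two-Gaussian fit of a velocity sample (nm/s).

    The histogram (density-normalized, ``bin_width`` nm/s) is fitted with
    ``w N(m1, s1) + (1-w) N(m2, s2)`` under the stuck/fast mean constraints;
    initialization takes the stuck weight from the near-zero histogram mass
    and the fast mean from the histogram mode above 400 nm/s.  Negative
    velocities are retained (the stuck component is centered, not
    truncated).  A vanishing component weight (< 0.5%) flags the fit
    degenerate.
    """
    v = np.asarray(samples, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 200:
        raise ValueError("need at least 200 velocity samples for a mixture fit")
    lo = min(v.min(), -2 * bin_width)
    hi = max(v.max(), FAST_MEAN_FLOOR + 2 * bin_width)
    edges = np.arange(lo - bin_width, hi + 2 * bin_width, bin_width)
    dens, edges = np.histogram(v, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    near_zero = np.abs(v) < 200.0
    w0 = np.clip(near_zero.mean(), 0.02, 0.98)
    fast_sel = centers > FAST_MEAN_FLOOR
    m2_0 = (centers[fast_sel][np.argmax(dens[fast_sel])]
            if fast_sel.any() and dens[fast_sel].max() > 0
            else max(np.median(v), FAST_MEAN_FLOOR + 100))
    p0 = np.array([w0, 0.0, 60.0, m2_0, 150.0])
    lb = [0.0, -STUCK_MEAN_BOUND, 5.0, FAST_MEAN_FLOOR, 5.0]
    ub = [1.0, STUCK_MEAN_BOUND, 400.0, max(2500.0, m2_0 + 500), 1000.0]

    def resid(p):
        w, m1, s1, m2, s2 = p
        model = w * _gauss(centers, m1, s1) + (1 - w) * _gauss(centers, m2, s2)
        return model - dens

    fit = least_squares(resid, p0, bounds=(lb, ub))
    w, m1, s1, m2, s2 = fit.x
    degenerate = bool(min(w, 1 - w) < 0.005)
    return VelocityMixture(
        stuck_weight=float(w), stuck_mean=float(m1), stuck_sd=float(s1),
        fast_weight=float(1 - w), fast_mean=float(m2), fast_sd=float(s2),
        diagnostics={"cost": float(fit.cost), "n": int(v.size),
                     "bin_width": bin_width, "degenerate": degenerate,
                     "success": bool(fit.success)},
    )


def fit_two_gaussians_em(samples, seed: int = 0) -> VelocityMixture:
    """EM (maximum-likelihood) two-Gaussian fit on raw samples.

    Internal cross-check oracle for :func:`fit_two_gaussians`; components
    are ordered so the one nearer zero is reported as stuck.
    """
    from sklearn.mixture import GaussianMixture

    v = np.asarray(samples, dtype=float).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=3,
                         means_init=[[0.0], [max(float(np.median(v)), 600.0)]])
    gm.fit(v)
    means = gm.means_.ravel()
    order = np.argsort(np.abs(means))
    w = gm.weights_[order]
    m = means[order]
    s = np.sqrt(gm.covariances_.ravel()[order])
    return VelocityMixture(
        stuck_weight=float(w[0]), stuck_mean=float(m[0]), stuck_sd=float(s[0]),
        fast_weight=float(w[1]), fast_mean=float(m[1]), fast_sd=float(s[1]),
        diagnostics={"method": "em"},
    )


def _bootstrap_ci(samples, stat, n_boot: int = 200, seed: int = 0,
                  alpha: float = 0.05):
    rng = np.random.default_rng(seed)
    vals = []
    v = np.asarray(samples, dtype=float)
    for _ in range(n_boot):
        try:
            vals.append(stat(rng.choice(v, v.size, replace=True)))
        except Exception:
            continue
    if not vals:
        return (np.nan, np.nan)
    return tuple(np.quantile(vals, [alpha / 2, 1 - alpha / 2]))


def roadblock_series(samples_by_density: dict, bin_width: float = 50.0,
                     n_boot: int = 100, seed: int = 0) -> pd.DataFrame:
    """Stuck fraction and fast mean versus roadblock density.

    ``samples_by_density`` maps linear roadblock density (per µm) to a
    velocity sample.  Each condition is fitted and bootstrap CIs (over
    samples) attached.  Requires at least two densities for a trend; a
    single condition still yields its one-row table.
    """
    rows = []
    for i, dens in enumerate(sorted(samples_by_density)):
        v = np.asarray(samples_by_density[dens], dtype=float)
        mix = fit_two_gaussians(v, bin_width)
        sf_lo, sf_hi = _bootstrap_ci(
            v, lambda s: fit_two_gaussians(s, bin_width).stuck_weight,
            n_boot, seed + i)
        fm_lo, fm_hi = _bootstrap_ci(
            v, lambda s: fit_two_gaussians(s, bin_width).fast_mean,
            n_boot, seed + i + 1000)
        rows.append({"roadblock_density": dens, "n": v.size,
                     "stuck_fraction": mix.stuck_weight,
                     "stuck_fraction_ci_low": sf_lo,
                     "stuck_fraction_ci_high": sf_hi,
                     "fast_mean_nm_s": mix.fast_mean,
                     "fast_mean_ci_low": fm_lo, "fast_mean_ci_high": fm_hi})
    return pd.DataFrame(rows)


def by_motor_number(samples_by_bin: dict, bin_width: float = 50.0,
                    min_samples: int = 200) -> pd.DataFrame:
    """Per-engaged-motor-number velocity mixtures.

    ``samples_by_bin`` maps a bin label (e.g. "1", "2-3", "4-5", "6-8") to
    the velocity samples of filaments carried by that many motors.  Bins
    with fewer than ``min_samples`` samples are flagged; the returned table
    reports the stuck fraction and fast mean per bin.
    """
    rows = []
    for label, v in samples_by_bin.items():
        v = np.asarray(v, dtype=float)
        if v.size >= min_samples:
            mix = fit_two_gaussians(v, bin_width)
            rows.append({"n_motors": label, "n": v.size,
                         "stuck_fraction": mix.stuck_weight,
                         "fast_mean_nm_s": mix.fast_mean,
                         "fast_sd_nm_s": mix.fast_sd,
                         "low_confidence": False})
        else:
            rows.append({"n_motors": label, "n": v.size,
                         "stuck_fraction": np.nan, "fast_mean_nm_s": np.nan,
                         "fast_sd_nm_s": np.nan, "low_confidence": True})
    return pd.DataFrame(rows)
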