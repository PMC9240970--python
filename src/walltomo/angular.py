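"""Axial orientation statistics for fiber angle distributions.

Fiber orientations are axial data: an angle theta and theta + 180 are
the same fiber direction, so all fitting happens on the doubled circle
phi = 2*theta where axial data become ordinary circular data.  The
mixture model is a k-component von Mises mixture on phi, fitted by EM
with deterministic seeded restarts; component mean directions are
halved back to axial modes in [0, 180).

Bimodality of a tomogram's angle distribution is decided by comparing
the one- and two-component fits: the distribution is called bimodal
when the two-component model wins by at least ``DELTA_BIC_MIN`` BIC
points *and* the two axial modes are separated by at least
``MIN_SEPARATION_DEG`` *and* the minor component carries at least
``MIN_WEIGHT`` of the mass.  Hartigan's dip statistic is available as
an optional diagnostic (:func:`dip_statistic`), not as the decision
rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ive, logsumexp

KAPPA_MAX = 1e4
DELTA_BIC_MIN = 6.0
MIN_SEPARATION_DEG = 20.0
MIN_WEIGHT = 0.15
EM_TOL = 1e-8
EM_MAX_ITER = 500
N_RESTARTS = 8


# ---------------------------------------------------------------------------
# von Mises helpers (angles in radians on the doubled circle)


def _vm_logpdf(phi: np.ndarray, mu: float, kappa: float) -> np.ndarray:
    # log I0(kappa) = log ive(0, kappa) + kappa  (ive is exp-scaled, stable)
    return kappa * np.cos(phi - mu) - math.log(2 * math.pi) - (np.log(ive(0, kappa)) + kappa)


def _kappa_from_R(R: float) -> float:
    """Maximum-likelihood concentration from the mean resultant length."""
    R = min(max(R, 0.0), 1.0 - 1e-12)
    if R < 0.53:
        k = 2 * R + R**3 + 5 * R**5 / 6
    elif R < 0.85:
        k = -0.4 + 1.39 * R + 0.43 / (1 - R)
    else:
        k = 1 / (R**3 - 4 * R**2 + 3 * R)
    return float(min(max(k, 1e-6), KAPPA_MAX))


def circular_mean_axial(angles_deg: np.ndarray) -> float:
    """Axial mean direction in [0, 180) via the doubled-angle embedding."""
    phi = np.radians(np.asarray(angles_deg, dtype=float) * 2.0)
    mean = math.atan2(np.sin(phi).mean(), np.cos(phi).mean())
    return (math.degrees(mean) / 2.0) % 180.0


def axial_separation_deg(m1: float, m2: float) -> float:
    """Axial distance between two modes, in [0, 90]."""
    d = abs(m1 - m2) % 180.0
    return min(d, 180.0 - d)


# ---------------------------------------------------------------------------
# results object


@dataclass
class AngularModel:
    """Fitted axial von Mises mixture.

    modes_deg are component mean axial directions in [0, 180);
    concentrations are von Mises kappas on the doubled circle.
    ``bimodal`` is set by :func:`assess_bimodality`.
    """

    k: int
    modes_deg: list[float]
    concentrations: list[float]
    weights: list[float]
    loglik: float
    n: int
    bic_1: float = math.nan
    bic_2: float = math.nan
    bimodal: bool = False
    degenerate: bool = False
    dip: float | None = None
    dip_pvalue: float | None = None

    def __post_init__(self) -> None:
        if self.k not in (1, 2):
            raise ValueError("k must be 1 or 2")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    @property
    def bic(self) -> float:
        p = 3 * self.k - 1  # (mu, kappa) per component + k-1 free weights
        return -2.0 * self.loglik + p * math.log(self.n)

    def mode_separation(self) -> float:
        """Axial separation of the two modes in degrees, [0, 90]."""
        if self.k != 2:
            raise ValueError("mode separation requires a 2-component fit")
        return axial_separation_deg(self.modes_deg[0], self.modes_deg[1])

    def responsibilities(self, angles_deg: np.ndarray) -> np.ndarray:
        """Posterior component membership, shape (n, k)."""
        phi = np.radians(np.asarray(angles_deg, dtype=float) * 2.0)
        logp = np.stack(
            [
                math.log(w) + _vm_logpdf(phi, math.radians(2 * m), kap)
                for w, m, kap in zip(self.weights, self.modes_deg, self.concentrations)
            ],
            axis=1,
        )
        return np.exp(logp - logsumexp(logp, axis=1, keepdims=True))

    def summary(self) -> str:
        lines = [
            f"Axial von Mises mixture (k={self.k}, n={self.n})",
            f"  log-likelihood: {self.loglik:.3f}   BIC: {self.bic:.3f}",
        ]
        for i, (m, kap, w) in enumerate(
            zip(self.modes_deg, self.concentrations, self.weights)
        ):
            sd = math.degrees(1.0 / math.sqrt(kap)) / 2.0 if kap > 0 else float("inf")
            lines.append(
                f"  mode {i}: {m:7.2f} deg   kappa={kap:8.2f} (axial sd ~{sd:.1f} deg)"
                f"   weight={w:.3f}"
            )
        if not math.isnan(self.bic_1):
            lines.append(f"  BIC(k=1)={self.bic_1:.2f}  BIC(k=2)={self.bic_2:.2f}")
            lines.append(f"  bimodal: {self.bimodal}")
        if self.k == 2:
            lines.append(f"  mode separation: {self.mode_separation():.2f} deg")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "k": self.k,
            "modes_deg": [float(v) for v in self.modes_deg],
            "concentrations": [float(v) for v in self.concentrations],
            "weights": [float(v) for v in self.weights],
            "loglik": float(self.loglik),
            "n": self.n,
            "bic_1": None if math.isnan(self.bic_1) else float(self.bic_1),
            "bic_2": None if math.isnan(self.bic_2) else float(self.bic_2),
            "bimodal": self.bimodal,
        }
        if self.k == 2:
            d["mode_separation_deg"] = float(self.mode_separation())
        return d


# ---------------------------------------------------------------------------
# model object


class AxialMixture:
    """k-component axial von Mises mixture model for fiber angles.

    Parameters
    ----------
    angles_deg : axial angles in [0, 180)
    k : number of components (1 or 2)

    ``fit`` runs EM from ``n_restarts`` deterministic seeded starts and
    returns the best :class:`AngularModel`.
    """

    def __init__(self, angles_deg, k: int = 2):
        a = np.asarray(angles_deg, dtype=float)
        if a.ndim != 1 or a.size == 0:
            raise ValueError("angles must be a non-empty 1D array")
        if not np.isfinite(a).all():
            raise ValueError("angles contain non-finite values")
        if a.size < 10 * k:
            raise ValueError(f"need at least {10 * k} angles for k={k}, got {a.size}")
        self.angles_deg = a % 180.0
        self.k = int(k)
        self.phi = np.radians(self.angles_deg * 2.0)

    # -- EM internals ------------------------------------------------------

    def _loglik(self, weights, mus, kappas) -> float:
        logp = np.stack(
            [
                math.log(w) + _vm_logpdf(self.phi, mu, kap)
                for w, mu, kap in zip(weights, mus, kappas)
            ],
            axis=1,
        )
        return float(logsumexp(logp, axis=1).sum())

    def _em_once(self, mus0, kappas0, weights0):
        weights = np.array(weights0, dtype=float)
        mus = np.array(mus0, dtype=float)
        kappas = np.array(kappas0, dtype=float)
        cphi, sphi = np.cos(self.phi), np.sin(self.phi)
        prev_ll = -math.inf
        for _ in range(EM_MAX_ITER):
            # log density: kappa*cos(phi - mu) - log(2*pi*I0(kappa)), expanded so
            # cos/sin of the data are reused across iterations
            log_c = np.log(ive(0, kappas)) + kappas + math.log(2 * math.pi)
            logp = (
                np.log(np.maximum(weights, 1e-300))[None, :]
                + kappas[None, :]
                * (np.cos(mus)[None, :] * cphi[:, None] + np.sin(mus)[None, :] * sphi[:, None])
                - log_c[None, :]
            )
            m = logp.max(axis=1)
            norm = m + np.log(np.exp(logp - m[:, None]).sum(axis=1))
            ll = float(norm.sum())
            resp = np.exp(logp - norm[:, None])
            # M-step
            nk = resp.sum(axis=0)
            weights = nk / nk.sum()
            c = resp.T @ cphi
            s = resp.T @ sphi
            mus = np.arctan2(s, c)
            R = np.hypot(c, s) / np.maximum(nk, 1e-300)
            kappas = np.array([_kappa_from_R(r) for r in R])
            if abs(ll - prev_ll) < EM_TOL:
                prev_ll = ll
                break
            prev_ll = ll
        return prev_ll, weights, mus, kappas

    def fit(self, seed: int = 0, n_restarts: int = N_RESTARTS) -> AngularModel:
        """Fit by EM; deterministic for a given seed."""
        n = self.phi.size
        if self.k == 1:
            c, s = float(np.cos(self.phi).mean()), float(np.sin(self.phi).mean())
            mu = math.atan2(s, c)
            kappa = _kappa_from_R(math.hypot(c, s))
            ll = self._loglik([1.0], [mu], [kappa])
            return AngularModel(
                k=1,
                modes_deg=[(math.degrees(mu) / 2.0) % 180.0],
                concentrations=[kappa],
                weights=[1.0],
                loglik=ll,
                n=n,
            )

        best = None
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            # initial means at two data points; shift-equivariant by design
            idx = rng.choice(n, size=self.k, replace=False)
            mus0 = self.phi[idx]
            kappas0 = np.full(self.k, 2.0)
            weights0 = np.full(self.k, 1.0 / self.k)
            ll, w, mus, kap = self._em_once(mus0, kappas0, weights0)
            if best is None or ll > best[0]:
                best = (ll, w, mus, kap)
        ll, w, mus, kap = best
        degenerate = bool((w < 1e-3).any() or not np.isfinite(ll))
        if degenerate:
            sub = AxialMixture(self.angles_deg, k=1).fit(seed=seed)
            sub.degenerate = True
            return sub
        order = np.argsort([(math.degrees(m) / 2.0) % 180.0 for m in mus])
        return AngularModel(
            k=2,
            modes_deg=[(math.degrees(mus[j]) / 2.0) % 180.0 for j in order],
            concentrations=[float(kap[j]) for j in order],
            weights=[float(w[j]) for j in order],
            loglik=ll,
            n=n,
        )


def fit_axial_mixture(angles_deg, k: int = 2, seed: int = 0) -> AngularModel:
    """Convenience wrapper: build an AxialMixture and fit it."""
    return AxialMixture(angles_deg, k=k).fit(seed=seed)


def assess_bimodality(
    angles_deg,
    seed: int = 0,
    delta_bic_min: float = DELTA_BIC_MIN,
    min_separation_deg: float = MIN_SEPARATION_DEG,
    min_weight: float = MIN_WEIGHT,
) -> AngularModel:
    """Fit k=1 and k=2 and decide whether the distribution is bimodal.

    Returns the selected model (k=2 fit if bimodal, else k=1), carrying
    both BIC scores and the verdict.
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size < 50:
        raise ValueError(f"bimodality assessment needs n >= 50, got {a.size}")
    m1 = fit_axial_mixture(a, k=1, seed=seed)
    m2 = fit_axial_mixture(a, k=2, seed=seed)
    bic_1, bic_2 = m1.bic, m2.bic
    bimodal = False
    if m2.k == 2:  # may have collapsed to 1 on degenerate data
        bimodal = (
            (bic_1 - bic_2 >= delta_bic_min)
            and (m2.mode_separation() >= min_separation_deg)
            and (min(m2.weights) >= min_weight)
        )
    chosen = m2 if bimodal else m1
    chosen.bic_1, chosen.bic_2 = bic_1, bic_2
    chosen.bimodal = bimodal
    return chosen


def mode_separation(model: AngularModel) -> float:
    """Axial separation of a 2-component model's modes, degrees in [0, 90]."""
    return model.mode_separation()


# ---------------------------------------------------------------------------
# histograms


def angle_histogram(angles_deg, bin_deg: float = 5.0):
    """Histogram of axial angles over [0, 180) with fixed-width bins.

    Returns (edges, counts, density); density integrates to 1 over the
    bin width in degrees.
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("cannot histogram an empty angle set")
    if ((a < 0) | (a >= 180)).any():
        raise ValueError("angles must lie in [0, 180)")
    nbins = int(round(180.0 / bin_deg))
    if abs(nbins * bin_deg - 180.0) > 1e-9:
        raise ValueError(f"bin width {bin_deg} must divide 180")
    edges = np.linspace(0.0, 180.0, nbins + 1)
    counts, _ = np.histogram(a, bins=edges)
    density = counts / (a.size * bin_deg)
    return edges, counts, density


# ---------------------------------------------------------------------------
# layering classification


@dataclass
class LayeringCall:
    """Vertical layering pattern of the two orientation modes."""

    pattern: str  # staggered | overlapped | staggered_overlapped | unimodal
    overlap_coefficient: float
    mode_z_means: list[float] = field(default_factory=list)
    mode_z_sds: list[float] = field(default_factory=list)
    low_confidence: bool = False

    def to_dict(self) -> dict:
        return {
            "pattern": self.pattern,
            "overlap_coefficient": float(self.overlap_coefficient),
            "mode_z_means": [float(v) for v in self.mode_z_means],
            "mode_z_sds": [float(v) for v in self.mode_z_sds],
            "low_confidence": self.low_confidence,
        }


def overlap_coefficient(z1: np.ndarray, z2: np.ndarray, n_grid: int = 512) -> float:
    """Overlap integral min(f1, f2) of two Gaussian KDEs (Silverman)."""
    from scipy.stats import gaussian_kde

    lo = min(z1.min(), z2.min())
    hi = max(z1.max(), z2.max())
    pad = 0.1 * (hi - lo) if hi > lo else 1.0
    grid = np.linspace(lo - pad, hi + pad, n_grid)
    try:
        f1 = gaussian_kde(z1)(grid)
        f2 = gaussian_kde(z2)(grid)
    except np.linalg.LinAlgError:  # zero-variance sample
        jitter = 1e-6
        f1 = gaussian_kde(z1 + np.random.default_rng(0).normal(0, jitter, z1.size))(grid)
        f2 = gaussian_kde(z2 + np.random.default_rng(1).normal(0, jitter, z2.size))(grid)
    return float(np.trapezoid(np.minimum(f1, f2), grid))


def classify_layering(
    angles_deg,
    mean_z_nm,
    model: AngularModel,
    staggered_max_overlap: float = 0.25,
    overlapped_min_overlap: float = 0.75,
) -> LayeringCall:
    """Classify how the two orientation modes stack in z.

    Fibers are assigned to their maximum-responsibility mode; the
    overlap coefficient between the two modes' z-height KDEs decides
    the pattern: staggered below ``staggered_max_overlap``, overlapped
    above ``overlapped_min_overlap``, staggered_overlapped in between,
    and unimodal whenever the angular model is not bimodal.
    """
    z = np.asarray(mean_z_nm, dtype=float)
    if not model.bimodal:
        return LayeringCall(
            pattern="unimodal",
            overlap_coefficient=1.0,
            mode_z_means=[float(z.mean())],
            mode_z_sds=[float(z.std())],
        )
    resp = model.responsibilities(np.asarray(angles_deg, dtype=float))
    assign = resp.argmax(axis=1)
    z0, z1 = z[assign == 0], z[assign == 1]
    low_conf = min(z0.size, z1.size) < 10
    if z0.size < 2 or z1.size < 2:
        return LayeringCall("staggered_overlapped", math.nan, low_confidence=True)
    ovl = overlap_coefficient(z0, z1)
    if ovl < staggered_max_overlap:
        pattern = "staggered"
    elif ovl > overlapped_min_overlap:
        pattern = "overlapped"
    else:
        pattern = "staggered_overlapped"
    return LayeringCall(
        pattern=pattern,
        overlap_coefficient=ovl,
        mode_z_means=[float(z0.mean()), float(z1.mean())],
        mode_z_sds=[float(z0.std()), float(z1.std())],
        low_confidence=low_conf,
    )


# ---------------------------------------------------------------------------
# Hartigan's dip (optional diagnostic)


def _convex_minorant(x: np.ndarray, f: np.ndarray, lo: int, hi: int) -> list[int]:
    """Indices of the greatest convex minorant touch points of (x, f) on [lo, hi]."""
    idx = [lo]
    for i in range(lo + 1, hi + 1):
        while len(idx) >= 2:
            a, b = idx[-2], idx[-1]
            # keep hull convex: slope(a, b) <= slope(a, i)
            if (f[b] - f[a]) * (x[i] - x[a]) >= (f[i] - f[a]) * (x[b] - x[a]):
                idx.pop()
            else:
                break
        idx.append(i)
    return idx


def _hull_eval(x: np.ndarray, f: np.ndarray, hull: list[int], xi: float) -> float:
    """Piecewise-linear interpolation of the hull at abscissa xi."""
    xs = x[hull]
    return float(np.interp(xi, xs, f[hull]))


def dip_statistic(values) -> float:
    """Hartigan's dip statistic of a 1D sample.

    Maximum distance between the empirical CDF and its closest unimodal
    CDF, found by iteratively shrinking the candidate modal interval
    using the greatest convex minorant (left flank) and least concave
    majorant (right flank) of the ECDF.  Diagnostic only; the
    bimodality decision in :func:`assess_bimodality` uses BIC.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 4 or x[0] == x[-1]:
        return 0.0
    f = (np.arange(n) + 1.0) / n  # ECDF at the sample points
    low, high = 0, n - 1
    dip = 1.0 / n
    for _ in range(200):
        gcm = _convex_minorant(x, f, low, high)
        # LCM = reflected GCM of the negated ECDF scanned from the right
        lcm_rev = _convex_minorant(-x[::-1], -f[::-1], n - 1 - high, n - 1 - low)
        lcm = [n - 1 - i for i in lcm_rev][::-1]
        # largest vertical gap between the two hulls, tracked with the
        # touch points that bracket it
        d = 0.0
        arg_g, arg_l = gcm[0], lcm[-1]
        for i in gcm:
            gap = _hull_eval(x, f, lcm, x[i]) - f[i]
            if gap > d:
                d = gap
                arg_g = i
                arg_l = lcm[int(np.searchsorted(x[lcm], x[i], side="left").clip(0, len(lcm) - 1))]
        for i in lcm:
            gap = f[i] - _hull_eval(x, f, gcm, x[i])
            if gap > d:
                d = gap
                arg_l = i
                j = int(np.searchsorted(x[gcm], x[i], side="right") - 1)
                arg_g = gcm[max(j, 0)]
        if d <= dip:
            break
        new_low, new_high = arg_g, arg_l
        # deviations of the ECDF from the hulls outside the new modal interval
        dip_l = max(
            (abs(f[i] - _hull_eval(x, f, gcm, x[i])) for i in range(low, new_low + 1)),
            default=0.0,
        )
        dip_r = max(
            (abs(f[i] - _hull_eval(x, f, lcm, x[i])) for i in range(new_high, high + 1)),
            default=0.0,
        )
        dip = max(dip, dip_l, dip_r)
        if new_low <= low and new_high >= high:
            break
        low, high = max(new_low, low), min(new_high, high)
        if low >= high:
            break
    return dip / 2.0


def dip_test(values, n_boot: int = 200, seed: int = 0) -> tuple[float, float]:
    """Dip statistic with a bootstrap p-value against the uniform null."""
    x = np.asarray(values, dtype=float)
    d = dip_statistic(x)
    rng = np.random.default_rng(seed)
    null = np.array([dip_statistic(rng.uniform(size=x.size)) for _ in range(n_boot)])
    p = float((null >= d).mean())
    return d, p
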