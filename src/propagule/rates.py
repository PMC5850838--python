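"""Time-binned coalescence-rate inference and the cross-coalescence-rate (CCR).

Two estimators produce `CoalRateCurve` objects on a shared
`TimeDiscretization`:

* `rates_from_genealogies` -- the genealogy-mode oracle: empirical hazard,
  events per bin divided by lineage-time at risk in the bin;
* `infer_pairwise_smc` -- an expectation-maximization fit of a pairwise
  sequentially-Markovian-coalescent HMM to binarized per-window
  heterozygosity of pseudo-diploid genomes.

The CCR statistic per time bin is ``2*lambda_cross / (lambda_within1 +
lambda_within2)``: ~1 while the ancestral population is uniform, decaying to 0
after a clean split.  `calibrate_ccr_threshold` reproduces the simulation
calibration of where the smoothed CCR curve crosses the true split time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import minimize

from . import _smc
from .coalsim import (
    HaplotypePanel,
    cross_pairs,
    het_windows,
    make_pseudo_diploids,
    simulate_genome,
)
from .demography import DemographicScenario

__all__ = [
    "DEFAULT_CCR_BAND",
    "WIDE_CCR_BAND",
    "TimeDiscretization",
    "CoalRateCurve",
    "CCRCurve",
    "CCRCalibration",
    "SmoothedCurve",
    "SplitTimeEstimate",
    "EMConfig",
    "rates_from_genealogies",
    "infer_pairwise_smc",
    "cross_coalescence",
    "smooth_curve",
    "ccr_from_panel",
    "calibrate_ccr_threshold",
    "estimate_split_time",
    "aggregate_ci",
]

#: Calibrated CCR range crossing the true split time (simulation study).
DEFAULT_CCR_BAND = (0.70, 0.75)
#: Wider expectation band for split-time bracketing.
WIDE_CCR_BAND = (0.70, 0.85)


@dataclass(frozen=True)
class TimeDiscretization:
    """Interval boundaries in generations: [0, ..., inf), strictly increasing."""

    boundaries: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        if b.size < 3 or b[0] != 0 or not np.isinf(b[-1]):
            raise ValueError("boundaries must run from 0 to inf with >= 2 intervals")
        if not np.all(np.diff(b) > 0):
            raise ValueError("boundaries must be strictly increasing")
        object.__setattr__(self, "boundaries", b)

    @classmethod
    def default(
        cls,
        k: int = 32,
        t_min: float = 1e3,
        t_max: float = 4e6,
        generation_time: float = 1.0,
    ) -> "TimeDiscretization":
        """k intervals, log-spaced between t_min and t_max (years-equivalents
        converted by the generation time), padded by [0, t_min) and
        [t_max, inf)."""
        inner = np.geomspace(t_min / generation_time, t_max / generation_time, k - 1)
        return cls(np.concatenate([[0.0], inner, [np.inf]]))

    @property
    def k(self) -> int:
        return self.boundaries.size - 1

    @property
    def midpoints(self) -> np.ndarray:
        """Representative time per interval (geometric means; half/extended
        edges for the two unbounded-ish end intervals)."""
        b = self.boundaries
        mid = np.empty(self.k)
        mid[0] = b[1] / 2
        mid[1:-1] = np.sqrt(b[1:-2] * b[2:-1])
        ratio = b[-2] / b[-3]
        mid[-1] = b[-2] * np.sqrt(ratio)
        return mid

    def bin_of(self, t) -> np.ndarray:
        return np.clip(
            np.searchsorted(self.boundaries, t, side="right") - 1, 0, self.k - 1
        )


@dataclass
class CoalRateCurve:
    """Per-interval pair-coalescence rates (per generation); NaN marks bins
    with no information (zero exposure).  Ne_j = 1 / (2 lambda_j)."""

    disc: TimeDiscretization
    lam: np.ndarray
    provenance: str = "hmm"
    events: np.ndarray | None = None
    exposure: np.ndarray | None = None

    def __post_init__(self):
        self.lam = np.asarray(self.lam, dtype=float)
        if self.lam.size != self.disc.k:
            raise ValueError("rate vector length must match discretization")
        if np.any(self.lam[np.isfinite(self.lam)] < 0):
            raise ValueError("rates must be non-negative")

    @property
    def ne(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return 1.0 / (2.0 * self.lam)

    def scaled(self, factor: float) -> "CoalRateCurve":
        return CoalRateCurve(self.disc, self.lam * factor, self.provenance)


@dataclass
class CCRCurve:
    """Cross-coalescence-rate per time interval: 2*lx / (lw1 + lw2)."""

    disc: TimeDiscretization
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.disc.k:
            raise ValueError("CCR vector length must match discretization")


def rates_from_genealogies(
    times, disc: TimeDiscretization, provenance: str = "genealogy-oracle"
) -> CoalRateCurve:
    """Empirical hazard from per-locus pair coalescence times (generations):
    lambda_j = (#coalescences in bin j) / (lineage-time at risk in bin j)."""
    t = np.asarray(times, dtype=float)
    t = t[np.isfinite(t)]
    if t.size == 0:
        raise ValueError("no coalescence times supplied")
    b = disc.boundaries
    events = np.histogram(t, bins=b)[0].astype(float)
    exposure = np.empty(disc.k)
    for j in range(disc.k):
        hi = b[j + 1] if np.isfinite(b[j + 1]) else np.inf
        exposure[j] = np.clip(np.minimum(t, hi) - b[j], 0.0, None).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(exposure > 0, events / exposure, np.nan)
    return CoalRateCurve(disc, lam, provenance, events=events, exposure=exposure)


def aggregate_ci(values) -> tuple[float, float]:
    """Mean and 1.96*SE half-width across replicates (SE = sd / sqrt(n))."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two replicate values")
    return float(v.mean()), float(1.96 * v.std(ddof=1) / np.sqrt(v.size))


def cross_coalescence(
    w1: CoalRateCurve, w2: CoalRateCurve, x: CoalRateCurve
) -> CCRCurve:
    """CCR_j = 2*lambda_cross / (lambda_within1 + lambda_within2); bins
    inestimable in any input propagate as NaN."""
    if not (
        np.array_equal(w1.disc.boundaries, w2.disc.boundaries)
        and np.array_equal(w1.disc.boundaries, x.disc.boundaries)
    ):
        raise ValueError("curves must share one time discretization")
    denom = w1.lam + w2.lam
    with np.errstate(invalid="ignore", divide="ignore"):
        ccr = np.where(denom > 0, 2.0 * x.lam / denom, np.nan)
    return CCRCurve(w1.disc, ccr)


# ---------------------------------------------------------------------------
# smoothing and split-time estimation
# ---------------------------------------------------------------------------


class SmoothedCurve:
    """A curve interpolated through per-bin medians on a log-time axis with a
    shape-preserving cubic (PCHIP) spline; constant beyond the knot range."""

    def __init__(
        self,
        times: np.ndarray,
        values: np.ndarray,
        smoothed: bool = True,
        log_values: bool = False,
    ):
        self.times = np.asarray(times, dtype=float)
        self.log_values = log_values
        v = np.asarray(values, dtype=float)
        self._v = np.log10(np.clip(v, 1e-300, None)) if log_values else v
        self.values = v
        self.smoothed = smoothed and self.times.size >= 4
        if self.smoothed:
            self._f = PchipInterpolator(np.log10(self.times), self._v)
        else:
            self._f = None

    def __call__(self, t):
        t = np.clip(np.asarray(t, dtype=float), self.times[0], self.times[-1])
        if self._f is not None:
            out = self._f(np.log10(t))
        else:
            out = np.interp(np.log10(t), np.log10(self.times), self._v)
        if self.log_values:
            out = 10**out
        return float(out) if out.ndim == 0 else out


def smooth_curve(curves, kind: str = "auto", log_values: bool = False) -> SmoothedCurve:
    """Cubic smoothing across per-bin medians of one or several curves.

    `curves` is a CoalRateCurve / CCRCurve or a list of them (replicates and/or
    pairs; medians are taken across everything supplied).  Ne curves are
    smoothed as Ne, CCR curves on their natural scale.  With fewer than four
    estimable bins the data are returned unsmoothed (linear) with a warning.
    """
    if not isinstance(curves, (list, tuple)):
        curves = [curves]
    first = curves[0]
    disc = first.disc
    if kind == "auto":
        kind = "ccr" if isinstance(first, CCRCurve) else "ne"
    rows = []
    for c in curves:
        if not np.array_equal(c.disc.boundaries, disc.boundaries):
            raise ValueError("curves must share one time discretization")
        rows.append(c.values if isinstance(c, CCRCurve) else c.ne)
    with warnings.catch_warnings():
        # bins inestimable in every curve yield all-NaN columns by design
        warnings.simplefilter("ignore", category=RuntimeWarning)
        med = np.nanmedian(np.vstack(rows), axis=0)
    ok = np.isfinite(med)
    times = disc.midpoints[ok]
    vals = med[ok]
    if times.size < 4:
        warnings.warn("fewer than 4 estimable bins; returning unsmoothed curve")
        return SmoothedCurve(times, vals, smoothed=False, log_values=log_values)
    return SmoothedCurve(times, vals, smoothed=True, log_values=log_values)


@dataclass
class SplitTimeEstimate:
    expected: float | None
    lower: float | None
    upper: float | None
    conclusive: bool


def estimate_split_time(
    smoothed: SmoothedCurve, band: tuple[float, float] = WIDE_CCR_BAND, n_grid: int = 512
) -> SplitTimeEstimate:
    """Bracket the split time by where the smoothed CCR decay crosses a band.

    The CCR rises from ~0 (recent, post-split) to ~1 (ancestral); the crossing
    time of band value v is the *most recent* upward crossing.  The estimate
    is the midpoint of the two crossing times; if the curve never traverses
    the band the result is flagged inconclusive.
    """
    lo, hi = band
    t = np.geomspace(smoothed.times[0], smoothed.times[-1], n_grid)
    v = np.asarray(smoothed(t))

    def crossing(level):
        above = v >= level
        # most recent upward (below -> above) crossing; a noisy start above
        # the level is ignored as long as the curve later decays through it
        idx = np.where(~above[:-1] & above[1:])[0]
        if idx.size == 0:
            return None
        i = idx[0]
        # linear interpolation in log time
        f = (level - v[i]) / (v[i + 1] - v[i])
        return float(10 ** (np.log10(t[i]) + f * (np.log10(t[i + 1]) - np.log10(t[i]))))

    t_lo = crossing(lo)
    t_hi = crossing(hi)
    if t_lo is None or t_hi is None:
        return SplitTimeEstimate(None, None, None, False)
    lower, upper = min(t_lo, t_hi), max(t_lo, t_hi)
    return SplitTimeEstimate((lower + upper) / 2.0, lower, upper, True)


# ---------------------------------------------------------------------------
# pairwise SMC inference
# ---------------------------------------------------------------------------


@dataclass
class EMConfig:
    max_iter: int = 30
    tol: float = 1e-4  # relative log-likelihood change
    lam_min: float = 1e-9
    lam_max: float = 0.5
    quad_nodes: int = 16
    mstep_maxiter: int = 60


def _finite_bounds(disc: TimeDiscretization) -> np.ndarray:
    return disc.boundaries[:-1].copy()


def infer_pairwise_smc(
    tracks,
    disc: TimeDiscretization,
    mu: float,
    rho: float | None = None,
    window: int = 100,
    em_config: EMConfig | None = None,
    lam_init: np.ndarray | None = None,
    fit_rho: bool = False,
) -> tuple[CoalRateCurve, dict]:
    """EM fit of the pairwise SMC HMM; composite likelihood over all tracks.

    `tracks` is a list of 0/1 arrays (one per pseudo-diploid chromosome);
    states are the discretization's intervals; returns the per-interval rates
    maximizing the composite likelihood plus an info dict (log-likelihood
    trace, convergence flag).  Non-convergence within `max_iter` flags the
    result rather than raising.  Deterministic given inputs.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    cfg = em_config or EMConfig()
    tracks = [np.ascontiguousarray(np.asarray(t, dtype=np.uint8)) for t in tracks]
    if not tracks or sum(t.size for t in tracks) == 0:
        raise ValueError("no observation windows supplied")
    if rho is None:
        rho = mu  # common prior when the recombination rate is unknown
    if fit_rho:
        best = None
        for scale in (0.1, 0.3, 1.0, 3.0):
            _, info = infer_pairwise_smc(
                tracks,
                disc,
                mu,
                rho * scale,
                window,
                EMConfig(max_iter=3, tol=cfg.tol),
                lam_init,
                fit_rho=False,
            )
            if best is None or info["loglik"][-1] > best[1]:
                best = (rho * scale, info["loglik"][-1])
        rho = best[0]

    bounds = _finite_bounds(disc)
    k = disc.k
    mu2w = 2.0 * mu * window
    rho2w = 2.0 * rho * window
    gl_x, gl_w = np.polynomial.legendre.leggauss(cfg.quad_nodes)

    n_windows = sum(t.size for t in tracks)
    het = sum(int(t.sum()) for t in tracks)
    h = het / n_windows
    low_information = het == 0
    if lam_init is None:
        ne0 = max(-np.log(max(1.0 - h, 1e-12)) / (4.0 * mu * window), 1.0)
        lam0 = np.full(k, 1.0 / (2.0 * ne0))
    else:
        lam0 = np.asarray(lam_init, dtype=float).copy()
    lam = np.clip(lam0, cfg.lam_min, cfg.lam_max)

    opt_bounds = [(np.log(cfg.lam_min), np.log(cfg.lam_max))] * k
    loglik_trace: list[float] = []
    converged = False
    for _ in range(cfg.max_iter):
        pi, A, e1, _m = _smc.hmm_params(lam, bounds, mu2w, rho2w, gl_x, gl_w)
        ll = 0.0
        c0 = np.zeros(k)
        C = np.zeros((k, k))
        n1 = np.zeros(k)
        n0 = np.zeros(k)
        for t in tracks:
            ll_t, c0_t, C_t, n1_t, n0_t = _smc.forward_backward(pi, A, e1, t)
            ll += ll_t
            c0 += c0_t
            C += C_t
            n1 += n1_t
            n0 += n0_t
        if loglik_trace and ll < loglik_trace[-1] - 1e-6 * abs(loglik_trace[-1]):
            # EM guarantees monotone likelihood; numerical violation is a bug
            raise AssertionError("EM log-likelihood decreased")
        if loglik_trace and abs(ll - loglik_trace[-1]) <= cfg.tol * abs(loglik_trace[-1]):
            loglik_trace.append(ll)
            converged = True
            break
        loglik_trace.append(ll)
        args = (bounds, mu2w, rho2w, gl_x, gl_w, c0, C, n1, n0)
        res = minimize(
            _smc.neg_q,
            np.log(lam),
            args=args,
            method="L-BFGS-B",
            bounds=opt_bounds,
            options={"maxiter": cfg.mstep_maxiter},
        )
        if res.fun <= _smc.neg_q(np.log(lam), *args):
            lam = np.exp(res.x)
        # else: keep current lam (optimizer failed to improve Q)

    info = {
        "loglik": loglik_trace,
        "converged": converged,
        "n_iter": len(loglik_trace),
        "rho": rho,
        "window": window,
        "low_information": low_information,
        "het_fraction": h,
    }
    return CoalRateCurve(disc, lam, provenance="hmm"), info


# ---------------------------------------------------------------------------
# the CCR pipeline and its calibration
# ---------------------------------------------------------------------------


@dataclass
class CCRResult:
    within_island: CoalRateCurve
    within_mainland: CoalRateCurve
    cross: CoalRateCurve
    ccr: CCRCurve
    info: dict = field(default_factory=dict)


def _pair_tracks(panel: HaplotypePanel, pairs, window: int) -> list[np.ndarray]:
    tracks = []
    for pair in pairs:
        tracks.extend(het_windows(panel, pair, window).values())
    return tracks


def ccr_from_panel(
    panel: HaplotypePanel,
    disc: TimeDiscretization,
    mu: float,
    rho: float,
    window: int = 100,
    n_pairs: int = 2,
    seed: int | None = 0,
    em_config: EMConfig | None = None,
) -> CCRResult:
    """Full CCR pipeline on one panel: build pseudo-diploids per class, fit the
    pairwise SMC to each class (composite likelihood across pairs), and form
    the CCR curve."""
    isl_pairs = make_pseudo_diploids(panel, "island", pairing_seed=seed)[:n_pairs]
    mld_pairs = make_pseudo_diploids(panel, "mainland", pairing_seed=seed)[:n_pairs]
    x_pairs = cross_pairs(panel, n_pairs=n_pairs, seed=seed)
    curves = {}
    infos = {}
    for label, pairs in (
        ("within-island", isl_pairs),
        ("within-mainland", mld_pairs),
        ("cross", x_pairs),
    ):
        curve, info = infer_pairwise_smc(
            _pair_tracks(panel, pairs, window), disc, mu, rho, window, em_config
        )
        curves[label] = curve
        infos[label] = info
    ccr = cross_coalescence(
        curves["within-island"], curves["within-mainland"], curves["cross"]
    )
    return CCRResult(
        curves["within-island"],
        curves["within-mainland"],
        curves["cross"],
        ccr,
        infos,
    )


@dataclass
class CCRCalibration:
    """Distribution of the smoothed CCR value at the true split time, per
    simulated split time, and the pooled central band."""

    values: dict[float, list[float]]
    band: tuple[float, float]
    n_failures: int = 0

    def pooled(self) -> np.ndarray:
        return np.array([v for vals in self.values.values() for v in vals])


def ccr_at_split(
    scenario: DemographicScenario,
    n_island: int = 11,
    n_mainland: int = 20,
    disc: TimeDiscretization | None = None,
    window: int = 100,
    n_pairs: int = 2,
    seed: int | None = 0,
    em_config: EMConfig | None = None,
) -> float:
    """One replicate of the calibration: simulate, run the CCR pipeline, and
    read the smoothed CCR at the scenario's true split time."""
    disc = disc or TimeDiscretization.default(
        generation_time=scenario.generation_time
    )
    panel = simulate_genome(scenario, n_island, n_mainland, seed=seed)
    mu = scenario.layout.mean_mutation_rate()
    rho = (
        np.mean(
            [
                scenario.layout.effective_recombination(c)
                for c in scenario.layout.chromosomes
            ]
        )
    )
    res = ccr_from_panel(panel, disc, mu, float(rho), window, n_pairs, seed, em_config)
    sm = smooth_curve(res.ccr)
    return float(sm(scenario.split_time / scenario.generation_time))


def calibrate_ccr_threshold(
    split_times,
    scenario_base: DemographicScenario,
    n_reps: int,
    seed: int = 0,
    central: float = 0.95,
    **pipeline_kwargs,
) -> CCRCalibration:
    """Simulate the base scenario across split times, run the full pipeline on
    each replicate, and collect the smoothed CCR value at each true split.

    The band is the central ``central`` mass of the pooled per-replicate
    values.  Per-replicate failures are recorded; calibration proceeds as long
    as at least half the replicates succeed.
    """
    split_times = list(split_times)
    if len(split_times) < 2:
        raise ValueError("need at least two split times")
    if n_reps < 2:
        raise ValueError("need at least two replicates")
    rng = np.random.default_rng(seed)
    values: dict[float, list[float]] = {float(t): [] for t in split_times}
    failures = 0
    for t in split_times:
        scen = scenario_base.replace(split_time=float(t))
        for _ in range(n_reps):
            rep_seed = int(rng.integers(1, 2**31 - 1))
            try:
                values[float(t)].append(
                    ccr_at_split(scen, seed=rep_seed, **pipeline_kwargs)
                )
            except Exception:
                failures += 1
    total = len(split_times) * n_reps
    if failures > total / 2:
        raise RuntimeError(f"calibration failed: {failures}/{total} replicates errored")
    pooled = np.array([v for vals in values.values() for v in vals])
    alpha = (1.0 - central) / 2.0
    band = (
        float(np.quantile(pooled, alpha)),
        float(np.quantile(pooled, 1.0 - alpha)),
    )
    return CCRCalibration(values, band, failures)
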