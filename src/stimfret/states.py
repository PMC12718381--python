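"""Conformational-state quantification from FRET series ensembles.

Builds normalized FRET amplitude histograms, fits sums of Gaussians to them
by nonlinear least squares, reports state occupancies (the fractional area
of the designated resting-state component), converts FRET efficiencies to
inter-dye distances through the Förster relation, and counts state
transitions within a time window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import argrelmax

from .qc import FretSeries

__all__ = [
    "FretHistogram",
    "MixtureComponent",
    "MixtureFit",
    "OccupancyReport",
    "TransitionStats",
    "ForsterCalibration",
    "DEFAULT_BIN_EDGES",
    "build_histogram",
    "fit_mixture",
    "occupancy",
    "fret_to_distance",
    "distance_to_fret",
    "count_transitions",
]

# E histograms span [-0.1, 1.1] in 0.02 bins: wide enough to show the noise
# tails around 0 and 1 without letting outliers distort the fit.
DEFAULT_BIN_EDGES = np.round(np.arange(-0.10, 1.10 + 1e-9, 0.02), 10)


@dataclass
class FretHistogram:
    bin_edges: np.ndarray
    density: np.ndarray
    n_molecules: int
    weighting: str  # "per-molecule" | "per-frame"
    density_sd: np.ndarray | None = None  # per-bin sd over molecule resampling

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.density) != len(self.bin_edges) - 1:
            raise ValueError("density length must be n_edges - 1")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_left": self.bin_edges[:-1],
                             "bin_right": self.bin_edges[1:],
                             "density": self.density})


def build_histogram(series: Sequence[FretSeries],
                    bins: np.ndarray | None = None,
                    weighting: str = "per-molecule") -> FretHistogram:
    """Normalized FRET amplitude histogram over an ensemble.

    With the default per-molecule weighting, each molecule's usable frames
    are normalized to unit total weight so long-lived molecules do not
    dominate; "per-frame" pools frames directly.  Density integrates to 1.
    Per-bin uncertainties (used to weight the mixture fit) are estimated by
    bootstrap resampling of molecules with a fixed internal seed.
    """
    if weighting not in {"per-molecule", "per-frame"}:
        raise ValueError(f"unknown weighting {weighting!r}")
    edges = DEFAULT_BIN_EDGES if bins is None else np.asarray(bins, dtype=float)
    per_mol = []
    for s in series:
        e = s.efficiencies[np.isfinite(s.efficiencies)]
        if len(e) == 0:
            continue
        w = np.full(len(e), 1.0 / len(e)) if weighting == "per-molecule" \
            else np.ones(len(e))
        counts, _ = np.histogram(e, bins=edges, weights=w)
        per_mol.append(counts)
    if not per_mol:
        raise ValueError("no usable frames in any molecule")
    per_mol = np.asarray(per_mol)
    n_used = len(per_mol)
    counts = per_mol.sum(axis=0)
    total = counts.sum()
    if total <= 0:
        raise ValueError("all FRET values fall outside the histogram range")
    widths = np.diff(edges)
    density = counts / (total * widths)

    # molecule-level bootstrap of the density, fixed seed for determinism
    rng = np.random.default_rng(1234)
    n_boot = 100
    idx = rng.integers(0, n_used, size=(n_boot, n_used))
    boot_counts = per_mol[idx].sum(axis=1)
    boot_totals = boot_counts.sum(axis=1, keepdims=True)
    boot_density = boot_counts / (boot_totals * widths[None, :])
    density_sd = boot_density.std(axis=0, ddof=1)
    return FretHistogram(bin_edges=edges, density=density,
                         n_molecules=n_used, weighting=weighting,
                         density_sd=density_sd)


@dataclass
class MixtureComponent:
    mean: float
    sigma: float
    area: float  # fractional area, components sum to 1


@dataclass
class MixtureFit:
    components: list[MixtureComponent]
    rss: float
    bic: float
    n_bins: int
    flags: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.components])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([c.sigma for c in self.components])

    @property
    def areas(self) -> np.ndarray:
        return np.array([c.area for c in self.components])

    def density(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for c in self.components:
            out += c.area * np.exp(-0.5 * ((x - c.mean) / c.sigma) ** 2) \
                / (c.sigma * np.sqrt(2 * np.pi))
        return out

    def to_dict(self) -> dict:
        return {"components": [{"mean": c.mean, "sigma": c.sigma, "area": c.area}
                               for c in self.components],
                "rss": self.rss, "bic": self.bic, "n_bins": self.n_bins,
                "flags": self.flags}


def _unpack(params: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    w, mu = params[:k], params[k:2 * k]
    sg = params[2 * k:]
    if len(sg) == 1:  # shared width across components
        sg = np.full(k, sg[0])
    return w, mu, sg


def _gaussian_sum(x: np.ndarray, params: np.ndarray, k: int) -> np.ndarray:
    w, mu, sg = _unpack(params, k)
    return np.sum(w[:, None] * np.exp(-0.5 * ((x[None, :] - mu[:, None]) / sg[:, None]) ** 2)
                  / (sg[:, None] * np.sqrt(2 * np.pi)), axis=0)


def _initial_means(hist: FretHistogram, k: int) -> np.ndarray:
    """Seed component means from histogram peaks, tallest first."""
    y = hist.density
    # light smoothing to suppress single-bin noise peaks
    kernel = np.array([0.25, 0.5, 0.25])
    ys = np.convolve(y, kernel, mode="same")
    idx = argrelmax(ys, order=2)[0]
    idx = idx[np.argsort(ys[idx])[::-1]]
    centers = hist.centers
    means = list(centers[idx[:k]])
    if len(means) < k:
        # fill with quantiles of the distribution
        cdf = np.cumsum(y * hist.widths)
        need = k - len(means)
        qs = (np.arange(need) + 1) / (need + 1)
        means += [float(centers[np.searchsorted(cdf, q)]) for q in qs]
    return np.sort(np.array(means[:k]))


def _bin_sigma(hist: FretHistogram) -> np.ndarray:
    """Per-bin density uncertainty for the weighted fit.

    Prefers the molecule-bootstrap sd attached by :func:`build_histogram`;
    falls back to a multinomial estimate over molecules.  A small floor
    (half a molecule of mass) keeps empty bins from dominating.
    """
    n = max(hist.n_molecules, 1)
    w = hist.widths
    floor = np.sqrt(0.5 / n) / (np.sqrt(n) * w)
    if hist.density_sd is not None:
        return np.maximum(hist.density_sd, floor)
    p = np.maximum(hist.density * w, 0.5 / n)
    return np.maximum(np.sqrt(p * (1 - np.minimum(p, 1.0))) / (np.sqrt(n) * w),
                      floor)


def _fit_k(hist: FretHistogram, k: int, seed_seq: np.random.SeedSequence,
           n_restarts: int,
           prev_params: np.ndarray | None = None,
           shared_sigma: bool = False
           ) -> tuple[np.ndarray, float, float] | None:
    x, y = hist.centers, hist.density
    sig = _bin_sigma(hist)
    lo_mu, hi_mu = x[0], x[-1]
    bin_w = float(np.min(hist.widths))
    n_sg = 1 if shared_sigma else k
    bounds_lo = np.concatenate([np.zeros(k), np.full(k, lo_mu),
                                np.full(n_sg, bin_w / 4)])
    bounds_hi = np.concatenate([np.full(k, 5.0), np.full(k, hi_mu),
                                np.full(n_sg, 0.5)])
    base_mu = _initial_means(hist, k)

    def _pack(w, mu, sg):
        sg = np.atleast_1d(sg)
        sg_part = np.array([np.mean(sg)]) if shared_sigma else \
            np.resize(sg, k)
        return np.concatenate([w, mu, sg_part])

    inits: list[np.ndarray] = []
    if prev_params is not None and k >= 2:
        # hierarchical start: best (k−1)-fit plus one component at the
        # largest positive residual — isolates small shoulders reliably
        resid = y - _gaussian_sum(x, prev_params, k - 1)
        mu_new = float(x[int(np.argmax(resid * (resid > 0)))])
        w_prev, mu_prev, sg_prev = _unpack(prev_params, k - 1)
        w_new = max(float(np.sum(np.maximum(resid, 0)) * bin_w), 0.01)
        inits.append(_pack(np.append(w_prev, w_new),
                           np.append(mu_prev, mu_new),
                           np.append(sg_prev, 0.07)))
    for r, child in enumerate(seed_seq.spawn(n_restarts)):
        rng = np.random.default_rng(child)
        if r % 2 == 0:
            mu0 = np.clip(base_mu + 0.05 * rng.standard_normal(k), lo_mu, hi_mu)
        else:
            # spread means uniformly: finds small components far from peaks
            mu0 = np.sort(rng.uniform(0.0, 1.0, k))
        sg0 = np.clip(np.full(k, 0.07) * np.exp(0.3 * rng.standard_normal(k)),
                      bin_w / 4, 0.5)
        w0 = np.full(k, 1.0 / k) * np.exp(0.3 * rng.standard_normal(k))
        inits.append(_pack(w0, mu0, sg0))

    best = None
    for p0 in inits:
        p0 = np.clip(p0, bounds_lo, bounds_hi)
        try:
            res = least_squares(lambda p: (_gaussian_sum(x, p, k) - y) / sig, p0,
                                bounds=(bounds_lo, bounds_hi), method="trf",
                                xtol=1e-10, ftol=1e-10, max_nfev=2000)
        except Exception:
            continue
        chi2 = float(np.sum(res.fun ** 2))
        if best is None or chi2 < best[1]:
            rss = float(np.sum((_gaussian_sum(x, res.x, k) - y) ** 2))
            best = (res.x, chi2, rss)
    return best


def fit_mixture(hist: FretHistogram, k_range: Sequence[int] = (1, 2, 3, 4),
                seed: int = 0, n_restarts: int = 20,
                bic_threshold: float = 10.0,
                shared_sigma: bool = False) -> MixtureFit:
    """Fit a sum of Gaussians to the binned density by least squares.

    For each candidate component count k, the density is fit with multiple
    random restarts (deterministic sub-seeds of ``seed``), initialized from
    histogram peaks, weighting bins by their multinomial sampling
    uncertainty over molecules.  k is selected by BIC = χ² + 3k·ln(n_bins);
    a larger k is accepted only when it improves BIC by more than
    ``bic_threshold``, ties breaking toward smaller k.  Components are
    returned sorted by mean with fractional areas renormalized to sum to 1.
    With ``shared_sigma`` all components share one width — useful when the
    states are known to broaden identically, and markedly more stable for
    small components.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1 or ks[-1] > 5:
        raise ValueError("k_range must lie within [1, 5]")
    x = hist.centers
    nb = len(x)
    ss = np.random.SeedSequence(seed)
    all_ks = list(range(1, ks[-1] + 1))  # lower k fits seed the next k up
    per_k_seeds = {k: s for k, s in zip(all_ks, ss.spawn(len(all_ks)))}
    fits: dict[int, tuple[np.ndarray, float, float]] = {}
    prev = None
    for k in all_ks:
        # ks outside k_range are fit briefly, only to initialize the chain
        restarts = n_restarts if k in ks else max(4, n_restarts // 4)
        got = _fit_k(hist, k, per_k_seeds[k], restarts, prev_params=prev,
                     shared_sigma=shared_sigma)
        if got is None:
            continue
        params, chi2, rss = got
        prev = params
        if k not in ks:
            continue
        n_params = 2 * k + 1 if shared_sigma else 3 * k
        bic = chi2 + n_params * np.log(nb)
        fits[k] = (params, rss, bic)
    if not fits:
        raise RuntimeError(
            f"mixture fit failed to converge for all k in {ks} "
            f"(n_bins={nb}, mass={float(np.sum(hist.density * hist.widths)):.3f})")

    best_k = min(fits)
    for k in sorted(fits):
        if fits[k][2] < fits[best_k][2] - bic_threshold:
            best_k = k
    params, rss, bic = fits[best_k]
    k = best_k
    w, mu, sg = _unpack(params, k)
    order = np.argsort(mu)
    w, mu, sg = w[order], mu[order], sg[order]
    flags = []
    if w.sum() <= 0:
        raise RuntimeError("degenerate fit: zero total area")
    w = w / w.sum()
    bin_w = float(np.min(hist.widths))
    if np.any(sg < bin_w):
        flags.append("sigma-below-bin-width")
    comps = [MixtureComponent(float(m), float(s), float(a))
             for m, s, a in zip(mu, sg, w)]
    return MixtureFit(components=comps, rss=rss, bic=float(bic),
                      n_bins=nb, flags=flags)


def match_mixture_to_reference(fit: MixtureFit, ref_means: Sequence[float]
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Match fitted components to reference means for parameter recovery.

    Each fitted component is assigned to the nearest reference mean; areas
    accumulate (near-duplicate fitted components pool onto one reference
    state) and matched means are area-weighted.  Returns
    (areas_by_reference, means_by_reference); a reference state receiving no
    fitted mass gets area 0 and mean NaN.
    """
    refs = np.asarray(ref_means, dtype=float)
    areas = np.zeros(len(refs))
    wsum = np.zeros(len(refs))
    musum = np.zeros(len(refs))
    for c in fit.components:
        j = int(np.argmin(np.abs(refs - c.mean)))
        areas[j] += c.area
        wsum[j] += c.area
        musum[j] += c.area * c.mean
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(wsum > 0, musum / np.maximum(wsum, 1e-300), np.nan)
    return areas, means


@dataclass
class OccupancyReport:
    low_fret_occupancy: float
    component_table: pd.DataFrame
    condition: str = ""
    resting_component: int = 0


def occupancy(fit: MixtureFit, rule: str | int = "lowest",
              condition: str = "") -> OccupancyReport:
    """Fractional area of the designated resting-state component.

    ``rule`` selects which component reports the resting state: "lowest"
    (default, the lowest-mean component), "highest", or an explicit
    component index — explicit because for some dye pairs the resting state
    is the high-FRET peak.
    """
    if fit.n_components == 0:
        raise ValueError("empty mixture fit")
    if rule == "lowest":
        idx = 0
    elif rule == "highest":
        idx = fit.n_components - 1
    elif isinstance(rule, int):
        if not (0 <= rule < fit.n_components):
            raise ValueError(f"component index {rule} out of range")
        idx = rule
    else:
        raise ValueError(f"unknown occupancy rule {rule!r}")
    table = pd.DataFrame({"mean": fit.means, "sigma": fit.sigmas,
                          "area": fit.areas})
    return OccupancyReport(low_fret_occupancy=float(fit.areas[idx]),
                           component_table=table, condition=condition,
                           resting_component=idx)


@dataclass(frozen=True)
class ForsterCalibration:
    """Förster radius of the dye pair; 5.8 nm measured for this system."""

    R0: float = 5.8

    def __post_init__(self) -> None:
        if self.R0 <= 0:
            raise ValueError("R0 must be > 0")


def fret_to_distance(E: float | np.ndarray,
                     cal: ForsterCalibration = ForsterCalibration()) -> float | np.ndarray:
    """Inter-dye distance from FRET: R = R0·(1/E − 1)^(1/6), nm.

    Defined for 0 < E < 1; E at or beyond the limits has an undefined or
    infinite distance and raises.
    """
    e = np.asarray(E, dtype=float)
    if np.any(e <= 0) or np.any(e >= 1):
        raise ValueError("E must lie strictly inside (0, 1)")
    r = cal.R0 * (1.0 / e - 1.0) ** (1.0 / 6.0)
    return float(r) if np.isscalar(E) else r


def distance_to_fret(R: float | np.ndarray,
                     cal: ForsterCalibration = ForsterCalibration()) -> float | np.ndarray:
    """FRET from inter-dye distance: E = 1/(1 + (R/R0)^6)."""
    r = np.asarray(R, dtype=float)
    if np.any(r <= 0):
        raise ValueError("R must be > 0")
    e = 1.0 / (1.0 + (r / cal.R0) ** 6)
    return float(e) if np.isscalar(R) else e


@dataclass
class TransitionStats:
    per_molecule_counts: np.ndarray
    window_seconds: float
    frequency_distribution: pd.DataFrame  # columns: count, probability
    n_excluded: int = 0

    @property
    def mean_count(self) -> float:
        return float(np.mean(self.per_molecule_counts)) \
            if len(self.per_molecule_counts) else np.nan


def _assign_states(e: np.ndarray, fit: MixtureFit) -> np.ndarray:
    """Hysteretic component assignment.

    Plain assignment uses midpoint thresholds between adjacent component
    means; a frame switches the running assignment only when it clears the
    threshold by more than one σ of the component on its side (the
    hysteresis band), which suppresses noise-driven double counting.
    """
    mu, sg = fit.means, fit.sigmas
    k = len(mu)
    thr = 0.5 * (mu[:-1] + mu[1:])
    raw = np.searchsorted(thr, e)
    out = np.empty(len(e), dtype=np.int64)
    cur = raw[0]
    out[0] = cur
    for t in range(1, len(e)):
        r = raw[t]
        if r != cur:
            if r > cur:
                # must clear the last threshold below r by σ of component r
                if e[t] > thr[r - 1] + sg[r]:
                    cur = r
            else:
                if e[t] < thr[r] - sg[r]:
                    cur = r
        out[t] = cur
    return out


def _debounced_transitions(assign: np.ndarray, min_dwell: int) -> list[int]:
    """Frames of assignment changes persisting ≥ min_dwell frames."""
    times = []
    cur = assign[0]
    t = 1
    n = len(assign)
    while t < n:
        if assign[t] != cur:
            run_end = t
            while run_end < n and assign[run_end] == assign[t]:
                run_end += 1
            if run_end - t >= min_dwell:
                times.append(t)
                cur = assign[t]
                t = run_end
            else:
                t = run_end  # short excursion: ignore
        else:
            t += 1
    return times


def count_transitions(series: Sequence[FretSeries], fit: MixtureFit,
                      window_seconds: float = 5.0,
                      min_dwell_frames: int = 3) -> TransitionStats:
    """Count state transitions within the first ``window_seconds`` per molecule.

    Frames are assigned to mixture components by midpoint thresholds with a
    ±1σ hysteresis band; a transition is an assignment change that persists
    for at least ``min_dwell_frames``.  Molecules whose analysis window is
    shorter than ``window_seconds`` are excluded and reported.  With fewer
    than two components every count is 0.
    """
    counts = []
    n_excluded = 0
    for s in series:
        n_window = int(round(window_seconds / s.frame_interval))
        e = s.efficiencies
        if len(e) < n_window:
            n_excluded += 1
            continue
        e = e[:n_window]
        good = np.isfinite(e)
        if good.sum() < 2 or fit.n_components < 2:
            counts.append(0)
            continue
        assign = _assign_states(e[good], fit)
        counts.append(len(_debounced_transitions(assign, min_dwell_frames)))
    counts = np.asarray(counts, dtype=np.int64)
    if len(counts):
        max_c = int(counts.max())
        values = np.arange(max_c + 1)
        probs = np.bincount(counts, minlength=max_c + 1) / len(counts)
    else:
        values, probs = np.array([], dtype=int), np.array([])
    dist = pd.DataFrame({"count": values, "probability": probs})
    return TransitionStats(per_molecule_counts=counts,
                           window_seconds=window_seconds,
                           frequency_distribution=dist,
                           n_excluded=n_excluded)
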