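"""Quality control of two-color trajectories.

Detects photobleaching steps, estimates the per-molecule γ correction from
the intensity steps at acceptor bleach, computes γ-corrected FRET time
series, and filters molecules down to the clean single-dimer population the
ensemble analysis assumes (single acceptor bleach, acceptor before donor,
anticorrelated channels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .sim import Trace

__all__ = [
    "BleachEvents",
    "GammaEstimate",
    "FretSeries",
    "QCPolicy",
    "QCRecord",
    "detect_steps",
    "robust_noise_sd",
    "estimate_gamma",
    "compute_fret",
    "qc_filter",
    "fret_series_from_records",
]


@dataclass
class BleachEvents:
    acceptor_bleach_frame: int | None
    donor_bleach_frame: int | None
    acceptor_steps: list[tuple[int, float]] = field(default_factory=list)
    donor_steps: list[tuple[int, float]] = field(default_factory=list)


@dataclass
class GammaEstimate:
    gamma: float
    method: str  # "per-molecule-step" | "ensemble-fallback"
    delta_acceptor: float = np.nan
    delta_donor: float = np.nan


@dataclass
class FretSeries:
    molecule_id: str
    efficiencies: np.ndarray          # raw E, NaN where excluded
    efficiencies_clipped: np.ndarray  # clipped to [-0.1, 1.1]
    window: tuple[int, int]           # [start, end) frames of the analysis window
    gamma_used: float
    frame_interval: float
    n_excluded: int = 0


def robust_noise_sd(y: np.ndarray) -> float:
    """Noise sd from the median absolute first difference.

    For iid Gaussian noise, |y[t+1]−y[t]| has median 0.6745·sd·sqrt(2);
    rare level shifts barely move the median, so staircase signals do not
    inflate the estimate.
    """
    d = np.abs(np.diff(np.asarray(y, dtype=float)))
    if len(d) == 0:
        return 0.0
    return float(np.median(d) / (0.6745 * np.sqrt(2.0)))


def _segment_cost_matrix(y: np.ndarray, min_segment: int) -> np.ndarray:
    n = len(y)
    s1 = np.concatenate(([0.0], np.cumsum(y)))
    s2 = np.concatenate(([0.0], np.cumsum(y * y)))
    i = np.arange(n + 1)[:, None]
    j = np.arange(n + 1)[None, :]
    lens = j - i
    with np.errstate(divide="ignore", invalid="ignore"):
        cost = (s2[None, :] - s2[:, None]) - (s1[None, :] - s1[:, None]) ** 2 / lens
    cost[lens < min_segment] = np.inf
    # guard against tiny negative values from cancellation
    np.maximum(cost, 0.0, where=np.isfinite(cost), out=cost)
    return cost


def detect_steps(series: Sequence[float], max_steps: int = 3,
                 min_segment: int = 4,
                 penalty: float | None = None) -> list[tuple[int, float]]:
    """Optimal piecewise-constant change points of an intensity series.

    Solves, exactly, for each number of steps m ≤ max_steps, the segmentation
    minimizing the within-segment sum of squares (dynamic programming over
    all split points, minimum segment length ``min_segment``), then picks m
    by a penalized cost: m is increased only while the squared-error saving
    exceeds ``penalty``.  The default penalty is 10·σ̂²·ln(n) with σ̂ the
    robust first-difference noise estimate, so clean level shifts of a few σ
    are found and pure noise yields no steps.

    Returns [(frame, signed level change)] with ``frame`` the first index of
    the new level, sorted by frame; [] when no step improves the cost.
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    if max_steps < 1:
        raise ValueError("max_steps must be ≥ 1")
    if n < 2 * min_segment:
        raise ValueError(
            f"series of length {n} too short for change-point search "
            f"(need ≥ {2 * min_segment})")
    if penalty is None:
        sd = robust_noise_sd(y)
        penalty = 10.0 * sd * sd * np.log(n)
    penalty = max(float(penalty), 1e-9 * (1.0 + float(np.var(y))))

    cost = _segment_cost_matrix(y, min_segment)
    max_m = min(max_steps, n // min_segment - 1)
    if max_m < 1:
        return []

    # C[m][j]: optimal cost of y[0:j] with exactly m change points
    C = np.full((max_m + 1, n + 1), np.inf)
    arg = np.zeros((max_m + 1, n + 1), dtype=np.int64)
    C[0] = cost[0]
    for m in range(1, max_m + 1):
        tot = C[m - 1][:, None] + cost
        arg[m] = np.argmin(tot, axis=0)
        C[m] = tot[arg[m], np.arange(n + 1)]

    totals = C[:, n] + penalty * np.arange(max_m + 1)
    best_m = 0
    for m in range(1, max_m + 1):
        if totals[m] < totals[best_m] - 1e-12:
            best_m = m
    if best_m == 0:
        return []

    cps = []
    j = n
    for m in range(best_m, 0, -1):
        j = int(arg[m][j])
        cps.append(j)
    cps = sorted(cps)

    bounds = [0] + cps + [n]
    out = []
    for k, c in enumerate(cps):
        before = y[bounds[k]:c].mean()
        after = y[c:bounds[k + 2]].mean()
        out.append((c, float(after - before)))
    return out


def estimate_gamma(trace: Trace, bleach: BleachEvents,
                   window: int = 10) -> GammaEstimate:
    """γ from the channel steps at acceptor photobleaching.

    γ = |ΔI_A| / ΔI_D with ΔI_A the acceptor drop and ΔI_D the donor rise,
    each a mean over ``window`` frames before vs after the acceptor bleach
    frame (the post window is truncated at donor bleach).  Background cancels
    in the differences.  When the step is unusable (no acceptor bleach, too
    few post-bleach frames, or non-positive donor rise) the estimate is
    returned as an ensemble-fallback placeholder with gamma = NaN, to be
    filled with the ensemble median by the caller.
    """
    ab = bleach.acceptor_bleach_frame
    n = trace.n_frames
    if ab is None or ab < 2 or ab >= n - 1:
        return GammaEstimate(np.nan, "ensemble-fallback")
    pre_lo = max(0, ab - window)
    post_hi = min(n, ab + window)
    if bleach.donor_bleach_frame is not None:
        post_hi = min(post_hi, bleach.donor_bleach_frame)
    if post_hi - ab < 2 or ab - pre_lo < 2:
        return GammaEstimate(np.nan, "ensemble-fallback")
    d_a = float(trace.acceptor[pre_lo:ab].mean() - trace.acceptor[ab:post_hi].mean())
    d_d = float(trace.donor[ab:post_hi].mean() - trace.donor[pre_lo:ab].mean())
    if d_d <= 0 or d_a <= 0:
        return GammaEstimate(np.nan, "ensemble-fallback", d_a, d_d)
    return GammaEstimate(d_a / d_d, "per-molecule-step", d_a, d_d)


def compute_fret(trace: Trace, gamma: GammaEstimate | float,
                 window: tuple[int, int] | None = None,
                 background: float | tuple[float, float] = 0.0) -> FretSeries:
    """γ-corrected FRET efficiency per frame: E = I_A/(I_A + γ·I_D).

    ``background`` (scalar or (donor, acceptor)) is subtracted first.
    Frames whose corrected denominator is ≤ 0 are excluded (NaN in the raw
    series) and counted.  Raw values are kept alongside a copy clipped to
    [−0.1, 1.1] for storage and plotting.
    """
    g = gamma.gamma if isinstance(gamma, GammaEstimate) else float(gamma)
    if not np.isfinite(g) or g <= 0:
        raise ValueError("gamma must be finite and > 0")
    if window is None:
        ab = trace.truth.acceptor_bleach_frame if trace.truth else None
        window = (0, ab if ab is not None else trace.n_frames)
    start, end = window
    if not (0 <= start < end <= trace.n_frames):
        raise ValueError(f"invalid window {window} for trace of {trace.n_frames} frames")
    bg_d, bg_a = (background, background) if np.isscalar(background) else background
    d = trace.donor[start:end] - bg_d
    a = trace.acceptor[start:end] - bg_a
    denom = a + g * d
    raw = np.full(end - start, np.nan)
    ok = denom > 0
    raw[ok] = a[ok] / denom[ok]
    return FretSeries(molecule_id=trace.molecule_id,
                      efficiencies=raw,
                      efficiencies_clipped=np.clip(raw, -0.1, 1.1),
                      window=(start, end),
                      gamma_used=g,
                      frame_interval=trace.frame_interval,
                      n_excluded=int((~ok).sum()))


@dataclass
class QCPolicy:
    """Thresholds for molecule selection; every criterion is explicit here."""

    min_prebleach_frames: int = 20
    gamma_window: int = 30
    max_steps: int = 3
    min_segment: int = 4
    anticorr_max: float = -0.2
    variance_waiver_factor: float = 3.0
    min_background_frames: int = 4
    default_background: float = 0.0
    default_gamma: float = 1.0


@dataclass
class QCRecord:
    trace: Trace
    bleach: BleachEvents
    gamma: GammaEstimate
    background: tuple[float, float]  # (donor, acceptor)


def _classify_bleach(trace: Trace, policy: QCPolicy) -> tuple[BleachEvents, str | None]:
    """Detect bleach steps and apply the ordering/count rules.

    Returns (events, rejection reason or None).
    """
    a_steps = detect_steps(trace.acceptor, policy.max_steps, policy.min_segment)
    d_steps = detect_steps(trace.donor, policy.max_steps, policy.min_segment)
    a_down = [(f, s) for f, s in a_steps if s < 0]
    d_down = [(f, s) for f, s in d_steps if s < 0]
    events = BleachEvents(acceptor_bleach_frame=None, donor_bleach_frame=None,
                          acceptor_steps=a_steps, donor_steps=d_steps)
    if len(a_down) == 0:
        return events, "no-acceptor-bleach"
    if len(a_down) > 1:
        return events, "multi-step-acceptor"
    ab = a_down[0][0]
    events.acceptor_bleach_frame = ab
    if len(d_down) > 1:
        return events, "multi-step-donor"
    db = None
    if d_down:
        db = d_down[0][0]
        events.donor_bleach_frame = db
        # donor-first bleaching collapses both channels at the same frame
        if db <= ab + 1:
            return events, "donor-first"
    # acceptor-first bleaching hands the excitation to the donor: its level
    # must rise across the acceptor bleach.  A sign test on mean levels is
    # robust at any FRET value, unlike requiring a detected donor step.
    w = min(10, ab, trace.n_frames - ab)
    post_hi = ab + w if db is None else min(ab + w, db)
    if w >= 2 and post_hi - ab >= 2:
        if trace.donor[ab:post_hi].mean() <= trace.donor[ab - w:ab].mean():
            return events, "donor-first"
    return events, None


def _anticorrelation_ok(trace: Trace, ab: int, policy: QCPolicy) -> bool:
    d = trace.donor[:ab]
    a = trace.acceptor[:ab]
    if len(d) < 4:
        return False
    sd_a = robust_noise_sd(a)
    sd_d = robust_noise_sd(d)
    # single-state traces carry no signal variance beyond noise: waive
    waiver = policy.variance_waiver_factor
    if (np.var(a) <= waiver * sd_a ** 2 and np.var(d) <= waiver * sd_d ** 2):
        return True
    if np.std(d) == 0 or np.std(a) == 0:
        return True
    r = float(np.corrcoef(d, a)[0, 1])
    return r <= policy.anticorr_max


def qc_filter(traces: Sequence[Trace],
              policy: QCPolicy | None = None) -> tuple[list[QCRecord], pd.DataFrame]:
    """Select analyzable molecules and attach bleach events, γ and background.

    A molecule is accepted when it shows exactly one acceptor bleach step and
    at most one donor bleach step, with the acceptor bleaching first, at
    least ``min_prebleach_frames`` frames before acceptor bleach, and
    donor/acceptor anticorrelation over the pre-bleach window (waived for
    single-state traces, judged by a variance-vs-noise test).  The report
    lists one row per molecule with the accept flag and rejection reason.
    """
    policy = policy or QCPolicy()
    records: list[QCRecord] = []
    rows = []
    backgrounds: list[tuple[float, float]] = []
    for tr in traces:
        events, reason = _classify_bleach(tr, policy)
        if reason is None:
            ab = events.acceptor_bleach_frame
            if ab < policy.min_prebleach_frames:
                reason = "short-prebleach"
            elif not _anticorrelation_ok(tr, ab, policy):
                reason = "no-anticorrelation"
        rows.append({"molecule_id": tr.molecule_id,
                     "accepted": reason is None,
                     "reason": reason or "",
                     "acceptor_bleach_frame": events.acceptor_bleach_frame,
                     "donor_bleach_frame": events.donor_bleach_frame})
        if reason is not None:
            continue
        db = events.donor_bleach_frame
        if db is not None and tr.n_frames - db >= policy.min_background_frames:
            bg = (float(tr.donor[db:].mean()), float(tr.acceptor[db:].mean()))
        else:
            bg = None
        if bg is not None:
            backgrounds.append(bg)
        gamma = estimate_gamma(tr, events, policy.gamma_window)
        records.append(QCRecord(tr, events, gamma, bg))

    # dataset-level fallbacks: background and ensemble-median γ
    if backgrounds:
        bg_fallback = (float(np.median([b[0] for b in backgrounds])),
                       float(np.median([b[1] for b in backgrounds])))
    else:
        bg_fallback = (policy.default_background, policy.default_background)
    for r in records:
        if r.background is None:
            r.background = bg_fallback
    apply_gamma_fallback(records, policy.default_gamma)
    report = pd.DataFrame(rows, columns=["molecule_id", "accepted", "reason",
                                         "acceptor_bleach_frame",
                                         "donor_bleach_frame"])
    return records, report


def apply_gamma_fallback(records: Sequence[QCRecord],
                         default_gamma: float = 1.0) -> float:
    """Fill ensemble-fallback γ placeholders with the ensemble median.

    Molecules whose per-molecule γ step was unusable keep
    method == "ensemble-fallback" and receive the median of the successful
    per-molecule estimates (or ``default_gamma`` when none exist).  Returns
    the fallback value used.
    """
    ok = [r.gamma.gamma for r in records
          if r.gamma.method == "per-molecule-step"]
    fallback = float(np.median(ok)) if ok else float(default_gamma)
    for r in records:
        if r.gamma.method == "ensemble-fallback":
            r.gamma.gamma = fallback
    return fallback


def fret_series_from_records(records: Sequence[QCRecord]) -> list[FretSeries]:
    """FRET series over each accepted molecule's pre-acceptor-bleach window."""
    out = []
    for r in records:
        ab = r.bleach.acceptor_bleach_frame
        out.append(compute_fret(r.trace, r.gamma, window=(0, ab),
                                background=r.background))
    return out
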