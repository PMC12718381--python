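"""Synthetic two-color smFRET trajectory generator.

Produces donor/acceptor intensity time series with the statistical structure
the downstream analysis assumes: hidden-Markov switching between
conformational states with state-specific true FRET, a per-molecule γ
(detection/quantum-yield) factor, single-step irreversible photobleaching of
the acceptor and donor, and additive Gaussian channel noise.  Ground truth
(state path, bleach frames, γ) travels with each trace so estimator recovery
can be checked exactly.

Intensity model, per frame, before any bleaching (background b, summed
pre-bleach intensity T, state FRET E, correction γ)::

    acceptor = b + T·E
    donor    = b + T·(1−E)/γ

so the ratio formula E = I_A/(I_A + γ·I_D) applied to background-subtracted
channels recovers E exactly.  After acceptor bleach the full excitation
appears in the donor channel (donor = b + T/γ, acceptor = b); after donor
bleach both channels sit at background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StateModel",
    "PhotoModel",
    "PhotoPopulation",
    "TraceTruth",
    "Trace",
    "simulate_trace",
    "simulate_ensemble",
    "simulate_state_ensemble",
    "noise_sd_for_fret_sd",
    "write_traces",
    "read_traces",
]


@dataclass(frozen=True)
class StateModel:
    """Markov model of conformational states.

    state_fret
        True FRET efficiency of each state, each in [0, 1].
    transition_rates
        Square matrix of per-second switching rates; entry (i, j) is the
        rate from state i to state j, off-diagonal, ≥ 0.  The diagonal is
        ignored.
    state_probs
        Initial (and, for static models, ensemble) occupancy per state;
        sums to 1.
    """

    state_fret: tuple[float, ...]
    transition_rates: np.ndarray | None = None
    state_probs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        n = len(self.state_fret)
        if n == 0:
            raise ValueError("state model must define at least one state")
        if any(not (0.0 <= e <= 1.0) for e in self.state_fret):
            raise ValueError("state FRET efficiencies must lie in [0, 1]")
        if self.state_probs is None:
            object.__setattr__(self, "state_probs", tuple([1.0 / n] * n))
        probs = np.asarray(self.state_probs, dtype=float)
        if probs.shape != (n,):
            raise ValueError("state_probs length must match state_fret")
        if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ValueError("state_probs must be non-negative and sum to 1")
        if self.transition_rates is None:
            object.__setattr__(self, "transition_rates", np.zeros((n, n)))
        rates = np.asarray(self.transition_rates, dtype=float)
        if rates.shape != (n, n):
            raise ValueError("transition_rates must be square, matching state_fret")
        off = rates[~np.eye(n, dtype=bool)]
        if (off < 0).any():
            raise ValueError("off-diagonal transition rates must be ≥ 0")
        object.__setattr__(self, "transition_rates", rates)
        object.__setattr__(self, "state_fret", tuple(float(e) for e in self.state_fret))
        object.__setattr__(self, "state_probs", tuple(float(p) for p in probs))

    @property
    def n_states(self) -> int:
        return len(self.state_fret)

    @property
    def is_static(self) -> bool:
        r = np.asarray(self.transition_rates)
        return bool(np.all(r[~np.eye(self.n_states, dtype=bool)] == 0.0))


@dataclass(frozen=True)
class PhotoModel:
    """Photophysics of one molecule.

    total_intensity is the mean summed two-channel signal above background
    before acceptor bleach (counts/frame); gamma the per-molecule detection
    correction (> 0); noise_sd the additive Gaussian noise per channel;
    acceptor/donor bleach rates are per-frame hazards in [0, 1]; background
    the per-channel baseline.
    """

    total_intensity: float = 400.0
    gamma: float = 1.0
    noise_sd: float = 0.0
    acceptor_bleach_rate: float = 0.0
    donor_bleach_rate: float = 0.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be ≥ 0")
        for r in (self.acceptor_bleach_rate, self.donor_bleach_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("bleach rates are per-frame hazards in [0, 1]")


@dataclass(frozen=True)
class PhotoPopulation:
    """Distribution over PhotoModel for ensembles.

    γ is drawn log-normally (median ``gamma_median``, log-sd
    ``gamma_sigma_log``) — strictly positive with mild spread, matching the
    premise that γ is measured empirically molecule by molecule.  All other
    fields are shared via ``base``.
    """

    base: PhotoModel = field(default_factory=PhotoModel)
    gamma_median: float = 1.0
    gamma_sigma_log: float = 0.2

    def sample(self, rng: np.random.Generator) -> PhotoModel:
        g = float(np.exp(np.log(self.gamma_median) + self.gamma_sigma_log * rng.standard_normal()))
        return replace(self.base, gamma=g)


@dataclass
class TraceTruth:
    states: np.ndarray
    acceptor_bleach_frame: int | None
    donor_bleach_frame: int | None
    gamma: float
    state_fret: tuple[float, ...] | None = None


@dataclass
class Trace:
    """One molecule's two-color intensity time series."""

    molecule_id: str
    frame_interval: float
    donor: np.ndarray
    acceptor: np.ndarray
    truth: TraceTruth | None = None

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.ndim != 1 or self.donor.shape != self.acceptor.shape:
            raise ValueError(
                f"molecule {self.molecule_id}: donor and acceptor series must be "
                "1-D and of equal length"
            )
        if len(self.donor) < 1:
            raise ValueError(f"molecule {self.molecule_id}: empty trace")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return len(self.donor)


def _simulate_states(model: StateModel, n_frames: int, dt: float,
                     rng: np.random.Generator) -> np.ndarray:
    k = model.n_states
    probs = np.asarray(model.state_probs)
    first = rng.choice(k, p=probs)
    if model.is_static or n_frames == 1:
        return np.full(n_frames, first, dtype=np.int64)
    rates = np.asarray(model.transition_rates, dtype=float).copy()
    np.fill_diagonal(rates, 0.0)
    exit_rates = rates.sum(axis=1)
    # per-frame switch probability 1 − exp(−k_exit·dt); destination ∝ rate
    p_switch = 1.0 - np.exp(-exit_rates * dt)
    dest = np.zeros((k, k))
    for i in range(k):
        if exit_rates[i] > 0:
            dest[i] = rates[i] / exit_rates[i]
    states = np.empty(n_frames, dtype=np.int64)
    states[0] = first
    u = rng.random(n_frames - 1)
    for t in range(1, n_frames):
        s = states[t - 1]
        if u[t - 1] < p_switch[s]:
            states[t] = rng.choice(k, p=dest[s])
        else:
            states[t] = s
    return states


def simulate_trace(model: StateModel, photo: PhotoModel, n_frames: int,
                   frame_interval: float = 0.1, seed: int | np.random.Generator = 0,
                   molecule_id: str = "mol000000") -> Trace:
    """Simulate one two-color trace; ground truth is recorded on the trace.

    Deterministic for a given seed.  Bleach frames are geometric draws from
    the per-frame hazards; a bleach at frame b means frames ≥ b are bleached.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be ≥ 1")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    states = _simulate_states(model, n_frames, frame_interval, rng)
    efret = np.asarray(model.state_fret)[states]

    def _bleach_frame(rate: float) -> int | None:
        if rate <= 0:
            return None
        b = int(rng.geometric(rate))
        return b if b < n_frames else None

    ab = _bleach_frame(photo.acceptor_bleach_rate)
    db = _bleach_frame(photo.donor_bleach_rate)

    bg, total, gamma = photo.background, photo.total_intensity, photo.gamma
    acceptor = bg + total * efret
    donor = bg + total * (1.0 - efret) / gamma
    if ab is not None:
        acceptor[ab:] = bg
        donor[ab:] = bg + total / gamma
    if db is not None:
        donor[db:] = bg
        acceptor[db:] = bg
    if photo.noise_sd > 0:
        donor = donor + photo.noise_sd * rng.standard_normal(n_frames)
        acceptor = acceptor + photo.noise_sd * rng.standard_normal(n_frames)

    truth = TraceTruth(states=states, acceptor_bleach_frame=ab,
                       donor_bleach_frame=db, gamma=gamma,
                       state_fret=model.state_fret)
    return Trace(molecule_id=molecule_id, frame_interval=frame_interval,
                 donor=donor, acceptor=acceptor, truth=truth)


PhotoSource = PhotoModel | PhotoPopulation | Callable[[np.random.Generator], PhotoModel]


def _sample_photo(src: PhotoSource, rng: np.random.Generator) -> PhotoModel:
    if isinstance(src, PhotoModel):
        return src
    if isinstance(src, PhotoPopulation):
        return src.sample(rng)
    return src(rng)


def simulate_ensemble(model: StateModel, photo_population: PhotoSource,
                      n_molecules: int, n_frames: int,
                      frame_interval: float = 0.1, seed: int = 0) -> list[Trace]:
    """Simulate ``n_molecules`` independent traces.

    Per-molecule seeds are spawned deterministically from the master seed, so
    the ensemble is reproducible and individual molecules can be re-simulated
    in isolation.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be ≥ 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_molecules)
    traces = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        photo = _sample_photo(photo_population, rng)
        traces.append(simulate_trace(model, photo, n_frames, frame_interval,
                                     seed=rng, molecule_id=f"mol{i:06d}"))
    return traces


def noise_sd_for_fret_sd(fret_sd: float, total_intensity: float, efret: float,
                         gamma: float = 1.0) -> float:
    """Channel noise_sd giving approximately ``fret_sd`` of per-frame E noise.

    First-order propagation of independent channel noise s through
    E = A/(A + γD) at A = T·E, D = T·(1−E)/γ gives
    var(E) = s²·[(1−E)² + γ²E²]/T², hence s = fret_sd·T/sqrt((1−E)² + γ²E²).
    """
    factor = np.sqrt((1.0 - efret) ** 2 + (gamma * efret) ** 2)
    if factor <= 0:
        factor = 1.0
    return float(fret_sd * total_intensity / factor)


def simulate_state_ensemble(components: Sequence[tuple[float, float]],
                            n_molecules: int,
                            n_frames: int = 300,
                            frame_interval: float = 0.1,
                            seed: int = 0,
                            state_jitter_sd: float = 0.04,
                            frame_fret_sd: float = 0.055,
                            total_intensity: float = 400.0,
                            gamma_sigma_log: float = 0.2,
                            acceptor_bleach_rate: float = 0.01,
                            donor_bleach_rate: float = 0.0025,
                            background: float = 40.0) -> list[Trace]:
    """Static conformational ensemble matching a fitted Gaussian mixture.

    ``components`` is a list of (peak FRET, fractional area).  Each molecule
    is assigned one state with probability equal to the fractional area; its
    true FRET is the component mean plus static heterogeneity of sd
    ``state_jitter_sd`` (truncated to [0.01, 0.99]); intensity noise adds
    ~``frame_fret_sd`` E-units of frame-to-frame spread, so the ensemble
    histogram shows Gaussian components of width
    ≈ sqrt(state_jitter_sd² + frame_fret_sd²) around the given means.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be ≥ 1")
    mus = np.array([c[0] for c in components], dtype=float)
    ws = np.array([c[1] for c in components], dtype=float)
    if (ws < 0).any() or ws.sum() <= 0:
        raise ValueError("fractional areas must be non-negative with positive sum")
    ws = ws / ws.sum()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_molecules)
    traces = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        comp = rng.choice(len(mus), p=ws)
        e_true = float(np.clip(mus[comp] + state_jitter_sd * rng.standard_normal(),
                               0.01, 0.99))
        gamma = float(np.exp(gamma_sigma_log * rng.standard_normal()))
        noise_sd = noise_sd_for_fret_sd(frame_fret_sd, total_intensity, e_true, gamma)
        model = StateModel(state_fret=(e_true,))
        photo = PhotoModel(total_intensity=total_intensity, gamma=gamma,
                           noise_sd=noise_sd,
                           acceptor_bleach_rate=acceptor_bleach_rate,
                           donor_bleach_rate=donor_bleach_rate,
                           background=background)
        tr = simulate_trace(model, photo, n_frames, frame_interval,
                            seed=rng, molecule_id=f"mol{i:06d}")
        traces.append(tr)
    return traces


# ---------------------------------------------------------------------------
# Trace store: tidy CSV (+ JSON truth/metadata sidecar) or single HDF5 file.

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_traces(traces: Sequence[Trace], path: str | Path) -> None:
    """Write traces to ``path``.

    ``.csv`` writes a tidy table (molecule_id, frame, donor, acceptor
    [, state]) plus a ``<name>.csv.meta.json`` sidecar holding per-molecule
    frame_interval and truth scalars; ``.h5``/``.hdf5`` writes one
    hierarchical file with a group per molecule.
    """
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        _write_h5(traces, path)
        return
    frames = []
    meta: dict[str, dict] = {}
    for tr in traces:
        df = pd.DataFrame({
            "molecule_id": tr.molecule_id,
            "frame": np.arange(tr.n_frames),
            "donor": tr.donor,
            "acceptor": tr.acceptor,
        })
        m: dict = {"frame_interval": tr.frame_interval}
        if tr.truth is not None:
            df["state"] = tr.truth.states
            m.update(
                gamma=tr.truth.gamma,
                acceptor_bleach_frame=tr.truth.acceptor_bleach_frame,
                donor_bleach_frame=tr.truth.donor_bleach_frame,
                state_fret=list(tr.truth.state_fret) if tr.truth.state_fret else None,
            )
        meta[tr.molecule_id] = m
        frames.append(df)
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(columns=["molecule_id", "frame", "donor", "acceptor"])
    table.to_csv(path, index=False, float_format="%.17g")
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_traces(path: str | Path) -> list[Trace]:
    """Read traces written by :func:`write_traces`; round-trip is lossless."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        return _read_h5(path)
    table = pd.read_csv(path)
    required = {"molecule_id", "frame", "donor", "acceptor"}
    if not required.issubset(table.columns):
        missing = sorted(required - set(table.columns))
        raise ValueError(f"trace file {path} missing columns: {missing}")
    meta: dict[str, dict] = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    traces = []
    for mol, grp in table.groupby("molecule_id", sort=False):
        frames = grp["frame"].to_numpy()
        if not np.array_equal(frames, np.arange(len(grp))):
            raise ValueError(
                f"molecule {mol}: frames must be contiguous starting at 0 "
                f"(row {int(grp.index[0])})"
            )
        m = meta.get(str(mol), {})
        truth = None
        if "state" in grp.columns and grp["state"].notna().all() and "gamma" in m:
            sf = m.get("state_fret")
            truth = TraceTruth(states=grp["state"].to_numpy(dtype=np.int64),
                               acceptor_bleach_frame=m.get("acceptor_bleach_frame"),
                               donor_bleach_frame=m.get("donor_bleach_frame"),
                               gamma=m["gamma"],
                               state_fret=tuple(sf) if sf else None)
        traces.append(Trace(molecule_id=str(mol),
                            frame_interval=float(m.get("frame_interval", 0.1)),
                            donor=grp["donor"].to_numpy(dtype=float),
                            acceptor=grp["acceptor"].to_numpy(dtype=float),
                            truth=truth))
    return traces


def _write_h5(traces: Sequence[Trace], path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        for tr in traces:
            g = fh.create_group(tr.molecule_id)
            g.create_dataset("donor", data=tr.donor)
            g.create_dataset("acceptor", data=tr.acceptor)
            g.attrs["frame_interval"] = tr.frame_interval
            if tr.truth is not None:
                g.create_dataset("state", data=tr.truth.states)
                g.attrs["gamma"] = tr.truth.gamma
                g.attrs["acceptor_bleach_frame"] = (
                    -1 if tr.truth.acceptor_bleach_frame is None
                    else tr.truth.acceptor_bleach_frame)
                g.attrs["donor_bleach_frame"] = (
                    -1 if tr.truth.donor_bleach_frame is None
                    else tr.truth.donor_bleach_frame)
                if tr.truth.state_fret:
                    g.attrs["state_fret"] = list(tr.truth.state_fret)


def _read_h5(path: Path) -> list[Trace]:
    import h5py

    traces = []
    with h5py.File(path, "r") as fh:
        for mol in fh:
            g = fh[mol]
            donor = g["donor"][:]
            acceptor = g["acceptor"][:]
            if donor.shape != acceptor.shape:
                raise ValueError(f"molecule {mol}: unequal channel lengths")
            truth = None
            if "state" in g and "gamma" in g.attrs:
                ab = int(g.attrs["acceptor_bleach_frame"])
                db = int(g.attrs["donor_bleach_frame"])
                sf = g.attrs.get("state_fret")
                truth = TraceTruth(states=g["state"][:].astype(np.int64),
                                   acceptor_bleach_frame=None if ab < 0 else ab,
                                   donor_bleach_frame=None if db < 0 else db,
                                   gamma=float(g.attrs["gamma"]),
                                   state_fret=tuple(sf) if sf is not None else None)
            traces.append(Trace(molecule_id=mol,
                                frame_interval=float(g.attrs["frame_interval"]),
                                donor=donor, acceptor=acceptor, truth=truth))
    traces.sort(key=lambda t: t.molecule_id)
    return traces
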