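"""Synthetic two-channel smFRET traces and noisy ensemble time courses.

Mechanistic state trajectories from the decoding scheme are rendered into
per-frame donor/acceptor intensity traces that emulate the TIRF recording:
camera integration at a fixed frame rate (frame i integrates the open
interval (i*dt, (i+1)*dt]), state-dependent FRET efficiency, Gaussian
per-channel read noise, donor->acceptor bleed-through, and single-step
photobleaching of either dye.  Ground truth (the source trajectory, bleach
time/mode and the mechanistic trace class) is recorded for every generated
molecule so that every downstream analysis can be validated against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rates import CameraModel, FRETMap, RateSet
from .scheme import SchemeGraph, StateTrajectory, build_scheme, simulate_trajectory

__all__ = [
    "IntensityTrace",
    "TraceSet",
    "render_trace",
    "sample_bleach_time",
    "add_bleedthrough",
    "generate_dataset",
    "generate_ensemble_timecourse",
    "exponential_course",
    "true_trace_class",
]

SCENARIOS = ("injection", "preformed_postdecoding")

#: states that emit FRET signal (acceptor in proximity of the donor)
_VISIBLE_STATES = frozenset(
    {"IB", "CR", "POST_GTP", "ACC_SLOW", "ACCOMMODATED_CLASSICAL", "HYBRID_APstar"}
)
_POST_STATES = frozenset({"ACCOMMODATED_CLASSICAL", "HYBRID_APstar"})


@dataclass
class IntensityTrace:
    """Per-frame two-channel intensities for one molecule."""

    donor: np.ndarray
    acceptor: np.ndarray
    frame_interval: float
    molecule_id: str = ""
    replicate: int = 0
    truncation_index: int | None = None  # set by QC (donor-bleach step)
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape:
            raise ValueError("donor and acceptor must have the same length")

    @property
    def n_frames(self) -> int:
        return self.donor.size

    @property
    def times(self) -> np.ndarray:
        """Frame mid-times (s)."""
        return (np.arange(self.n_frames) + 0.5) * self.frame_interval

    def copy(self) -> "IntensityTrace":
        return IntensityTrace(
            self.donor.copy(),
            self.acceptor.copy(),
            self.frame_interval,
            self.molecule_id,
            self.replicate,
            self.truncation_index,
            dict(self.ground_truth),
        )


@dataclass
class TraceSet:
    """A replicate-structured collection of traces plus its manifest."""

    traces: list[IntensityTrace]
    manifest: dict

    def replicate(self, r: int) -> list[IntensityTrace]:
        return [t for t in self.traces if t.replicate == r]

    @property
    def n_replicates(self) -> int:
        return int(self.manifest.get("n_replicates", 1))

    def ground_truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.traces:
            row = {"molecule_id": t.molecule_id, "replicate": t.replicate}
            row.update({k: v for k, v in t.ground_truth.items() if not isinstance(v, StateTrajectory)})
            rows.append(row)
        return pd.DataFrame(rows)


def sample_bleach_time(cam: CameraModel, rng: int | np.random.Generator) -> float:
    """Draw a single-step photobleach time; +inf when the rate is zero."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if cam.k_photobleach <= 0:
        return float("inf")
    return float(rng.exponential(1.0 / cam.k_photobleach))


def _piecewise_cumulative(breaks: np.ndarray, values: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Cumulative integral of a piecewise-constant function at query times.

    ``values[i]`` holds on [breaks[i], breaks[i+1]).
    """
    seg = np.diff(breaks) * values
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return np.interp(query, breaks, cum)


def render_trace(
    traj: StateTrajectory,
    fmap: FRETMap,
    cam: CameraModel,
    seed: int | np.random.Generator,
    bleach_time: float | None = None,
    bleach_mode: str | None = None,
) -> IntensityTrace:
    """Forward model: state path -> two-channel per-frame intensities.

    Per frame the true FRET efficiency is the occupancy-time-weighted mean
    of the state efficiencies within the frame.  Donor and acceptor are
    I_tot*(1-E) and I_tot*E plus Gaussian read noise; bleed-through is then
    added to the acceptor channel as beta * observed donor.  Acceptor
    bleach sets E to zero from the bleach time on; donor bleach switches
    both channels off (partial frames are occupancy-weighted).
    """
    if not traj.segments:
        raise ValueError("empty trajectory")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = cam.frame_interval
    n = int(round(traj.horizon / dt))
    if n < 1:
        raise ValueError("trajectory shorter than one frame")

    if bleach_time is None:
        bleach_time = sample_bleach_time(cam, rng)
        bleach_mode = bleach_mode or ("acceptor" if rng.random() < 0.5 else "donor")
    elif bleach_mode is None:
        bleach_mode = "acceptor"
    if bleach_mode not in ("acceptor", "donor"):
        raise ValueError(f"unknown bleach mode {bleach_mode!r}")

    breaks = [t0 for _, t0, _ in traj.segments] + [traj.segments[-1][2]]
    breaks = np.asarray(breaks, dtype=float)
    evals = np.array([fmap.mean(s) for s, _, _ in traj.segments])
    # pad to the full window if the trajectory was absorbed early
    if breaks[-1] < n * dt:
        breaks = np.append(breaks, n * dt)
        evals = np.append(evals, evals[-1])

    # apply bleach by splitting the piecewise functions at the bleach time
    tb = min(bleach_time, breaks[-1])
    on = np.ones_like(evals)
    if bleach_time < breaks[-1]:
        idx = np.searchsorted(breaks, tb, side="right")
        breaks = np.insert(breaks, idx, tb)
        evals = np.insert(evals, idx, evals[idx - 1])
        on = np.insert(on, idx, on[idx - 1])
        if bleach_mode == "acceptor":
            evals[idx:] = 0.0
        else:
            on[idx:] = 0.0

    edges = np.arange(n + 1) * dt
    cum_e = _piecewise_cumulative(breaks, evals * on, edges)
    cum_on = _piecewise_cumulative(breaks, on, edges)
    frac_e = np.diff(cum_e) / dt  # mean of on * E per frame
    frac_on = np.diff(cum_on) / dt

    I = cam.total_intensity
    donor = I * (frac_on - frac_e)
    acceptor = I * frac_e
    if cam.noise_sd > 0:
        donor = donor + rng.normal(0.0, cam.noise_sd, size=n)
        acceptor = acceptor + rng.normal(0.0, cam.noise_sd, size=n)
    trace = IntensityTrace(donor, acceptor, dt)
    add_bleedthrough(trace, cam.bleedthrough)
    trace.ground_truth = {
        "bleach_time": float(bleach_time),
        "bleach_mode": bleach_mode,
        "trajectory": traj,
    }
    return trace


def add_bleedthrough(trace: IntensityTrace, beta: float) -> IntensityTrace:
    """Add donor->acceptor bleed-through in place: acceptor += beta*donor."""
    if not 0.0 <= beta < 1.0:
        raise ValueError("beta must be in [0, 1)")
    trace.acceptor = trace.acceptor + beta * trace.donor
    return trace


def true_trace_class(
    traj: StateTrajectory,
    observed_end: float,
    min_visible_s: float = 0.066,
) -> str:
    """Mechanistic class of a trajectory over the observed window.

    Classes mirror the analysis definitions: ``post_decoding`` starts in
    the classical/hybrid cycle, ``decoding`` reaches it during the window,
    ``rejected`` shows binding that returns to dark, ``stalled`` is still
    in a pre-hydrolysis bound state at the end of the window, ``dark``
    never shows a resolvable binding event.  Episodes shorter than
    ``min_visible_s`` (the camera resolvability floor, two frames at the
    default frame rate) are ignored, matching what any frame-based
    analysis could in principle see.
    """
    episodes: list[tuple[float, float, bool]] = []  # (start, end, reached_post)
    cur_start = None
    reached_post = False
    first_state = traj.segments[0][0]
    for state, t0, t1 in traj.segments:
        t0c, t1c = min(t0, observed_end), min(t1, observed_end)
        if t0c >= observed_end:
            break
        if state in _VISIBLE_STATES:
            if cur_start is None:
                cur_start = t0c
                reached_post = False
            if state in _POST_STATES:
                reached_post = True
        else:
            if cur_start is not None:
                episodes.append((cur_start, t0c, reached_post))
                cur_start = None
    open_episode = cur_start is not None
    if open_episode:
        episodes.append((cur_start, observed_end, reached_post))
    episodes = [e for e in episodes if e[1] - e[0] >= min_visible_s]
    if not episodes:
        return "dark"
    if first_state in _POST_STATES and episodes[0][0] == 0.0:
        return "post_decoding"
    if any(post for _, _, post in episodes):
        return "decoding"
    last = episodes[-1]
    if open_episode and last[1] >= observed_end:
        return "stalled"
    return "rejected"


def generate_dataset(
    rates: RateSet,
    fmap: FRETMap,
    cam: CameraModel,
    n_traces: int,
    protocol: str = "wildtype",
    scenario: str = "injection",
    n_replicates: int = 3,
    seed: int = 0,
) -> TraceSet:
    """Generate a replicate-structured synthetic smFRET dataset.

    ``injection`` starts every molecule unbound at t = 0 (ternary-complex
    delivery into the flow chamber); ``preformed_postdecoding`` starts in
    the accommodated/hybrid cycle (complexes that completed decoding before
    imaging started).  Every trace carries its ground-truth trajectory,
    bleach time/mode and mechanistic class.
    """
    if n_traces <= 0:
        raise ValueError("n_traces must be > 0")
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    scheme = build_scheme(rates, protocol=protocol)
    if scenario == "preformed_postdecoding":
        start = "ACCOMMODATED_CLASSICAL"
    else:
        if protocol == "hybrid_only":
            raise ValueError("injection scenario requires a scheme with an unbound state")
        start = "UNBOUND"

    root = np.random.SeedSequence(seed)
    rep_seqs = root.spawn(n_replicates)
    traces: list[IntensityTrace] = []
    for r, rep_seq in enumerate(rep_seqs):
        for m, mol_seq in enumerate(rep_seq.spawn(n_traces)):
            rng = np.random.default_rng(mol_seq)
            traj = simulate_trajectory(scheme, cam.window_s, rng, start=start)
            trace = render_trace(traj, fmap, cam, rng)
            trace.molecule_id = f"rep{r}_mol{m:04d}"
            trace.replicate = r
            gt = trace.ground_truth
            # either bleach mode ends the observable part of the trace
            t_end = min(cam.window_s, gt["bleach_time"])
            gt["class"] = true_trace_class(traj, t_end, min_visible_s=2 * cam.frame_interval)
            gt["rateset_label"] = rates.label
            traces.append(trace)
    manifest = {
        "schema_version": "1.0",
        "n_traces": n_traces,
        "n_replicates": n_replicates,
        "protocol": protocol,
        "scenario": scenario,
        "seed": seed,
        "frame_rate": cam.frame_rate,
        "bleedthrough": cam.bleedthrough,
        "window_s": cam.window_s,
        "k_photobleach": cam.k_photobleach,
        "rates": rates.to_dict(),
    }
    return TraceSet(traces, manifest)


def generate_ensemble_timecourse(
    scheme: SchemeGraph,
    observable_states,
    t_grid,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    start: str | None = None,
) -> pd.DataFrame:
    """Noisy replicate ensemble time courses from the analytic occupancy.

    Each replicate is the matrix-exponential occupancy of the observable
    state set plus i.i.d. Gaussian noise per point.  Returns a DataFrame
    with columns (time, signal, replicate).
    """
    from .scheme import ensemble_timecourse

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    clean = ensemble_timecourse(scheme, observable_states, t_grid, start=start)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    frames = []
    for r in range(n_replicates):
        sig = clean["signal"].to_numpy().copy()
        if noise_sd > 0:
            sig = sig + rng.normal(0.0, noise_sd, size=sig.size)
        frames.append(pd.DataFrame({"time": clean["time"], "signal": sig, "replicate": r}))
    return pd.concat(frames, ignore_index=True)


def exponential_course(
    t_grid,
    rates,
    amplitudes,
    y0: float = 0.0,
    rising: bool = True,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic multi-exponential time course with replicate noise.

    Rising form: y = y0 + sum_i A_i (1 - exp(-k_i t)); decaying form uses
    A_i exp(-k_i t).  Twin of a stopped-flow / quench-flow record with a
    known ground-truth rate, used for fit validation.
    """
    t = np.asarray(t_grid, dtype=float)
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    if rates.shape != amplitudes.shape:
        raise ValueError("rates and amplitudes must match")
    decay = np.exp(-np.outer(t, rates))
    clean = y0 + (amplitudes * ((1.0 - decay) if rising else decay)).sum(axis=1)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    frames = []
    for r in range(n_replicates):
        sig = clean.copy()
        if noise_sd > 0:
            sig = sig + rng.normal(0.0, noise_sd, size=sig.size)
        frames.append(pd.DataFrame({"time": t, "signal": sig, "replicate": r}))
    return pd.concat(frames, ignore_index=True)
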