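"""smFRET trace-analysis chain.

Implements the analysis applied to each two-channel single-molecule
recording: donor->acceptor bleed-through correction, FRET efficiency
computation FI_acceptor/(FI_donor + FI_acceptor), quality selection
(anticorrelated channels, single-step photobleaching), Gaussian-emission
HMM idealization with BIC state-count selection, merging of transitions
smaller than the state noise, Gaussian-sum fitting of FRET histograms,
dwell-time extraction and exponential decay fitting, the photobleach /
observation-window rate correction k_corrected = k_observed -
k_photobleach - 1/T, mechanistic trace classification, replicate class
fractions with Welch tests, and synchronized contour histograms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from scipy import optimize, stats
from sklearn.mixture import GaussianMixture

from .rates import FRETMap
from .simulate import IntensityTrace

__all__ = [
    "FRETTrace",
    "Dwell",
    "IdealizedTrace",
    "DwellDistribution",
    "GaussianMixtureFit",
    "ClassificationResult",
    "correct_bleedthrough",
    "compute_fret",
    "qc_select",
    "idealize",
    "filter_transitions",
    "fit_fret_histogram",
    "select_phase_frames",
    "extract_dwells",
    "fit_dwell",
    "correct_rate",
    "classify_trace",
    "class_fractions",
    "compare_class_fractions",
    "synchronize_contour",
    "assign_level",
]

CLASSES = ("post_decoding", "decoding", "rejected", "stalled")

# near-converged EM chatter is not actionable at trace scale
logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)


# ---------------------------------------------------------------------------
# containers


@dataclass
class FRETTrace:
    """Per-frame FRET efficiency with a validity mask."""

    efficiency: np.ndarray
    valid: np.ndarray
    frame_interval: float
    molecule_id: str = ""
    replicate: int = 0
    truncation_index: int | None = None
    ground_truth: dict = field(default_factory=dict)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_efficiencies(self) -> np.ndarray:
        return self.efficiency[self.valid]


@dataclass
class Dwell:
    mu: float
    sigma: float
    t_start: float
    t_end: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class IdealizedTrace:
    """Piecewise-constant idealization of one FRET trace."""

    dwells: list[Dwell]
    n_states: int
    scores: dict[int, float]  # BIC per candidate state count
    frame_interval: float
    molecule_id: str = ""
    replicate: int = 0
    valid_end: float = 0.0  # end of the valid window (truncation or window end)
    ground_truth: dict = field(default_factory=dict)


@dataclass
class DwellDistribution:
    """Dwell times of one transition class and their exponential decay fit."""

    transition: str
    dwells: np.ndarray
    n_censored: int = 0
    frame_interval: float = 1 / 30.3
    # fit results (filled by fit_dwell)
    y0: float | None = None
    amplitude: float | None = None
    tau: float | None = None
    k_observed: float | None = None
    k_mle: float | None = None
    k_corrected: float | None = None
    corrected_negative: bool = False
    misfit: bool = False
    bin_width: float | None = None
    fit_start: float | None = None

    @property
    def n(self) -> int:
        return int(self.dwells.size)


@dataclass
class GaussianMixtureFit:
    """Sum-of-Gaussians fit of a pooled FRET histogram.

    Components are ordered by mean; replicate-level means are summarized
    as mean +/- s.d. across replicates.
    """

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    replicate_means: np.ndarray  # (n_replicates, n_components)
    mu_mean: np.ndarray
    mu_sd: np.ndarray
    n_frames: int


@dataclass
class ClassificationResult:
    per_trace: pd.DataFrame  # molecule_id, replicate, class
    fractions: pd.DataFrame  # replicate x class (%)
    mean: pd.Series
    sd: pd.Series
    n_unclassified: int = 0


# ---------------------------------------------------------------------------
# corrections and FRET


def correct_bleedthrough(trace: IntensityTrace, beta: float = 0.13) -> IntensityTrace:
    """Subtract donor bleed-through from the acceptor channel, framewise."""
    if not 0.0 <= beta < 1.0:
        raise ValueError("beta must be in [0, 1)")
    out = trace.copy()
    out.acceptor = out.acceptor - beta * out.donor
    return out


def compute_fret(trace: IntensityTrace) -> FRETTrace:
    """E = acceptor / (donor + acceptor) per frame.

    Frames after the truncation index (donor bleach) and frames whose
    total intensity is near zero (both fluorophores dark — the ratio is
    then pure noise) are masked invalid.
    """
    total = trace.donor + trace.acceptor
    ref = float(np.percentile(total, 75))
    valid = total > max(0.25 * ref, 0.0)
    if trace.truncation_index is not None:
        valid[trace.truncation_index:] = False
    eff = np.zeros_like(total)
    np.divide(trace.acceptor, total, out=eff, where=valid)
    return FRETTrace(
        efficiency=eff,
        valid=valid,
        frame_interval=trace.frame_interval,
        molecule_id=trace.molecule_id,
        replicate=trace.replicate,
        truncation_index=trace.truncation_index,
        ground_truth=trace.ground_truth,
    )


# ---------------------------------------------------------------------------
# quality control


def _count_bleach_steps(total: np.ndarray, step_threshold: float, smooth: int = 5):
    """Detect downward intensity steps in the smoothed total intensity.

    Returns (number of steps, frame index of the first step or None).
    """
    if total.size < 2 * smooth:
        return 0, None
    kernel = np.ones(smooth) / smooth
    sm = np.convolve(total, kernel, mode="valid")
    drops = sm[:-smooth] - sm[smooth:]
    steps = []
    i = 0
    while i < drops.size:
        if drops[i] > step_threshold:
            j = i + np.argmax(drops[i : i + 2 * smooth])
            steps.append(j + smooth)
            i = j + 2 * smooth  # skip the remainder of this edge
        else:
            i += 1
    return len(steps), (steps[0] if steps else None)


def qc_select(
    traces: list[IntensityTrace],
    anticorr_max: float = -0.05,
    step_fraction: float = 0.45,
    max_steps: int = 1,
) -> tuple[list[IntensityTrace], pd.DataFrame]:
    """Select traces with anticorrelated channels and <= one bleach step.

    The anticorrelation statistic is the Pearson correlation of the
    frame-to-frame differences of the two channels over the pre-bleach
    region: FRET transitions and acceptor bleaching move the channels in
    opposite directions, while bleed-through noise coupling and shared
    drifts move them together.  Bleach steps are
    downward steps in the smoothed total intensity larger than
    ``step_fraction`` of the initial level; more than ``max_steps`` steps
    indicates an aggregate and rejects the trace.  The truncation index of
    kept traces is set at the detected (donor-)bleach step.
    """
    if not traces:
        raise ValueError("need at least one trace")
    kept = []
    report = []
    for trace in traces:
        total = trace.donor + trace.acceptor
        ref = float(np.median(total[: max(10, total.size // 100)]))
        n_steps, first_step = _count_bleach_steps(total, step_fraction * max(ref, 1e-12))
        stop = first_step if first_step is not None else trace.n_frames
        dd = np.diff(trace.donor[:stop])
        da = np.diff(trace.acceptor[:stop])
        if dd.size > 2 and dd.std() > 0 and da.std() > 0:
            corr = float(np.corrcoef(dd, da)[0, 1])
        else:
            corr = 0.0
        ok = corr <= anticorr_max and n_steps <= max_steps
        if ok:
            t = trace.copy()
            if n_steps >= 1:
                t.truncation_index = first_step
            kept.append(t)
        report.append(
            {
                "molecule_id": trace.molecule_id,
                "replicate": trace.replicate,
                "diff_correlation": corr,
                "n_bleach_steps": n_steps,
                "kept": ok,
            }
        )
    return kept, pd.DataFrame(report)


# ---------------------------------------------------------------------------
# idealization


def _hmm_bic(model: GaussianHMM, X: np.ndarray) -> float:
    logl = model.score(X)
    k = model.n_components
    n_params = k * k - 1 + 2 * k  # transitions+start (k^2-1) and means+vars (2k)
    return -2.0 * logl + n_params * np.log(X.shape[0])


def _init_hmm(n_states: int, x: np.ndarray) -> GaussianHMM:
    """Deterministic quantile-based initialization (no RNG in EM)."""
    model = GaussianHMM(
        n_components=n_states,
        covariance_type="diag",
        n_iter=40,
        tol=1e-3,
        init_params="",
        params="stmc",
        # floor well below real state widths (~0.03-0.05) but high enough
        # to rule out zero-variance spike states on a few coincident frames
        min_covar=5e-5,
    )
    qs = np.linspace(0.05, 0.95, n_states)
    means = np.quantile(x, qs)
    # nudge coincident quantiles apart so EM can separate them
    for i in range(1, n_states):
        if means[i] - means[i - 1] < 1e-3:
            means[i] = means[i - 1] + 1e-3
    model.means_ = means.reshape(-1, 1)
    model.covars_ = np.full((n_states, 1), max(x.var(), 1e-4) / max(n_states, 1))
    model.startprob_ = np.full(n_states, 1.0 / n_states)
    trans = np.full((n_states, n_states), 0.05 / max(n_states - 1, 1))
    np.fill_diagonal(trans, 0.95)
    model.transmat_ = trans / trans.sum(axis=1, keepdims=True)
    return model


def idealize(
    ftrace: FRETTrace,
    max_states: int = 4,
    min_frames: int = 10,
) -> IdealizedTrace | None:
    """Gaussian-emission HMM idealization with BIC state-count selection.

    Fits 1..max_states Gaussian-emission HMMs to the valid frames, picks
    the state count with the lowest BIC, and decodes the most probable
    (Viterbi) state path into contiguous dwells.  Traces with fewer than
    ``min_frames`` valid frames are skipped (returns None).
    """
    x = ftrace.valid_efficiencies()
    if x.size < min_frames:
        return None
    X = x.reshape(-1, 1)
    scores: dict[int, float] = {}
    best = None
    for k in range(1, max_states + 1):
        if x.size < 3 * k:
            break
        model = _init_hmm(k, x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model.fit(X)
                scores[k] = _hmm_bic(model, X)
            except (ValueError, np.linalg.LinAlgError):
                continue
        if best is None or scores[k] < scores[best[0]]:
            best = (k, model)
    if best is None:
        return None
    k, model = best
    path = model.predict(X)
    means = model.means_.ravel()
    sds = np.sqrt(model.covars_.ravel())

    # map decoded states back onto the frame grid (invalid frames break dwells)
    dt = ftrace.frame_interval
    frame_idx = np.flatnonzero(ftrace.valid)
    dwells: list[Dwell] = []
    start = frame_idx[0]
    prev_frame = frame_idx[0]
    prev_state = path[0]
    for fi, st in zip(frame_idx[1:], path[1:]):
        if st != prev_state or fi != prev_frame + 1:
            dwells.append(
                Dwell(float(means[prev_state]), float(sds[prev_state]), start * dt, (prev_frame + 1) * dt)
            )
            start = fi
            prev_state = st
        prev_frame = fi
    dwells.append(
        Dwell(float(means[prev_state]), float(sds[prev_state]), start * dt, (prev_frame + 1) * dt)
    )
    return IdealizedTrace(
        dwells=dwells,
        n_states=k,
        scores=scores,
        frame_interval=dt,
        molecule_id=ftrace.molecule_id,
        replicate=ftrace.replicate,
        valid_end=(frame_idx[-1] + 1) * dt,
        ground_truth=ftrace.ground_truth,
    )


def filter_transitions(itrace: IdealizedTrace) -> IdealizedTrace:
    """Merge transitions smaller than the state noise.

    Adjacent dwells whose mean difference is below the larger of the two
    state standard deviations cannot be distinguished from noise and are
    merged (duration-weighted mean); merging repeats until stable.
    """
    dwells = [Dwell(d.mu, d.sigma, d.t_start, d.t_end) for d in itrace.dwells]
    changed = True
    while changed and len(dwells) > 1:
        changed = False
        out: list[Dwell] = [dwells[0]]
        for d in dwells[1:]:
            prev = out[-1]
            contiguous = abs(d.t_start - prev.t_end) < 0.5 * itrace.frame_interval
            if contiguous and abs(d.mu - prev.mu) < max(d.sigma, prev.sigma):
                w1, w2 = prev.duration, d.duration
                mu = (prev.mu * w1 + d.mu * w2) / (w1 + w2)
                sigma = max(prev.sigma, d.sigma)
                out[-1] = Dwell(mu, sigma, prev.t_start, d.t_end)
                changed = True
            else:
                out.append(d)
        dwells = out
    return IdealizedTrace(
        dwells=dwells,
        n_states=itrace.n_states,
        scores=itrace.scores,
        frame_interval=itrace.frame_interval,
        molecule_id=itrace.molecule_id,
        replicate=itrace.replicate,
        valid_end=itrace.valid_end,
        ground_truth=itrace.ground_truth,
    )


# ---------------------------------------------------------------------------
# state-distribution fitting


def select_phase_frames(
    ftrace: FRETTrace,
    itrace: IdealizedTrace,
    levels: dict[str, float],
    level_name: str,
    trim_frames: int = 0,
) -> np.ndarray:
    """Valid-frame efficiencies belonging to dwells assigned to a level.

    ``trim_frames`` drops that many frames from each end of every dwell:
    frames spanning a transition integrate a mixture of two states and
    blur the state distribution.
    """
    dt = ftrace.frame_interval
    sel = np.zeros(ftrace.efficiency.size, dtype=bool)
    for d in itrace.dwells:
        if assign_level(d.mu, levels) == level_name:
            i0 = int(round(d.t_start / dt)) + trim_frames
            i1 = int(round(d.t_end / dt)) - trim_frames
            if i1 > i0:
                sel[i0:i1] = True
    sel &= ftrace.valid
    return ftrace.efficiency[sel]


def fit_fret_histogram(
    frames_by_replicate: list[np.ndarray],
    n_components: int,
    seed: int = 0,
    min_frames: int = 100,
) -> GaussianMixtureFit:
    """Fit a sum of Gaussians to pooled FRET values.

    The mixture is fitted per replicate and on the pooled frames; the
    replicate-level component means are reported as mean +/- s.d. across
    replicates.  Requires at least ``min_frames`` pooled frames.
    """
    frames_by_replicate = [np.asarray(f, dtype=float) for f in frames_by_replicate]
    pooled = np.concatenate(frames_by_replicate) if frames_by_replicate else np.array([])
    if pooled.size < min_frames:
        raise ValueError(f"need >= {min_frames} frames, got {pooled.size}")

    def _fit(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        qs = np.linspace(0.1, 0.9, n_components)
        init = np.quantile(values, qs).reshape(-1, 1)
        gm = GaussianMixture(
            n_components=n_components,
            covariance_type="diag",
            means_init=init,
            random_state=seed,
            n_init=1,
            max_iter=300,
        )
        gm.fit(values.reshape(-1, 1))
        if not gm.converged_:  # retry from k-means-style restarts
            gm = GaussianMixture(
                n_components=n_components,
                covariance_type="diag",
                random_state=seed,
                n_init=5,
                max_iter=500,
            )
            gm.fit(values.reshape(-1, 1))
        order = np.argsort(gm.means_.ravel())
        return (
            gm.means_.ravel()[order],
            np.sqrt(gm.covariances_.ravel()[order]),
            gm.weights_[order],
        )

    means, sds, weights = _fit(pooled)
    rep_means = []
    for values in frames_by_replicate:
        if values.size >= max(10 * n_components, 30):
            mu, _, _ = _fit(values)
            rep_means.append(mu)
    rep_means = np.asarray(rep_means) if rep_means else means.reshape(1, -1)
    return GaussianMixtureFit(
        means=means,
        sds=sds,
        weights=weights,
        replicate_means=rep_means,
        mu_mean=rep_means.mean(axis=0),
        mu_sd=rep_means.std(axis=0, ddof=1) if rep_means.shape[0] > 1 else np.zeros(n_components),
        n_frames=int(pooled.size),
    )


# ---------------------------------------------------------------------------
# dwell times


def assign_level(mu: float, levels: dict[str, float]) -> str:
    """Name of the nearest named FRET level."""
    names = list(levels)
    dist = [abs(mu - levels[n]) for n in names]
    return names[int(np.argmin(dist))]


def collapse_levels(
    dwells: list[Dwell], levels: dict[str, float]
) -> list[tuple[str, float, float]]:
    """Map dwells onto named levels and merge consecutive same-level runs.

    Gaps in the valid window (non-contiguous dwells) break a run.
    Returns (level, t_start, t_end) tuples.
    """
    out: list[tuple[str, float, float]] = []
    for d in dwells:
        name = assign_level(d.mu, levels)
        if out:
            prev_name, t0, t1 = out[-1]
            if prev_name == name and abs(d.t_start - t1) < 1e-9:
                out[-1] = (name, t0, d.t_end)
                continue
        out.append((name, d.t_start, d.t_end))
    return out


def extract_dwells(
    itraces: list[IdealizedTrace],
    src_level: str,
    dst_level: str,
    levels: dict[str, float] | FRETMap | None = None,
    min_dwell_s: float = 0.0,
    ftraces: list[FRETTrace] | None = None,
    area_ref: float | None = None,
) -> DwellDistribution:
    """Collect dwell times of one transition class from idealized traces.

    Dwells are first collapsed onto the named level set (each fitted HMM
    state maps to its nearest level; consecutive dwells on the same level
    merge — sub-states within one level and single-frame boundary
    artifacts do not terminate a dwell).  A collapsed dwell belongs to the
    class when its level is ``src_level`` and the following dwell is at
    ``dst_level``.  The final dwell of each trace is right-censored (it
    ends at the bleach truncation or the observation window, not by a
    transition) and is excluded from the decay fit but counted.
    ``min_dwell_s`` drops events below the camera resolvability floor.

    When ``ftraces`` (paired by index with ``itraces``) and ``area_ref``
    are given, dwell durations are measured by signal area instead of
    assigned frames: the sum of frame efficiencies over the event window
    (one frame of margin to catch camera-blurred entry/exit frames)
    divided by the reference efficiency.  For binding events on a dark
    background this is unbiased under camera integration, where frame
    counting systematically distorts events only a few frames long;
    durations are then continuous rather than frame-quantized, and the
    resolvability floor is left to the decay fit's own start cut.
    """
    if levels is None:
        levels = FRETMap()
    if isinstance(levels, FRETMap):
        levels = levels.levels
    use_area = ftraces is not None and area_ref is not None
    if use_area and len(ftraces) != len(itraces):
        raise ValueError("ftraces must pair with itraces")
    times = []
    n_censored = 0
    dt = itraces[0].frame_interval if itraces else 1 / 30.3
    for j, it in enumerate(itraces):
        dwells = collapse_levels(it.dwells, levels)
        for i, (level, t0, t1) in enumerate(dwells):
            if level != src_level:
                continue
            if i == len(dwells) - 1:
                n_censored += 1
                continue
            if dwells[i + 1][0] != dst_level:
                continue
            if use_area:
                ft = ftraces[j]
                i0 = max(int(round(t0 / dt)) - 1, 0)
                i1 = min(int(round(t1 / dt)) + 1, ft.efficiency.size)
                seg = ft.efficiency[i0:i1][ft.valid[i0:i1]]
                dur = float(seg.sum()) * dt / area_ref
                if dur > 0:
                    times.append(dur)
            elif t1 - t0 >= min_dwell_s:
                times.append(t1 - t0)
    return DwellDistribution(
        transition=f"{src_level}->{dst_level}",
        dwells=np.asarray(times, dtype=float),
        n_censored=n_censored,
        frame_interval=dt,
    )


def _decay_model(t, y0, A, tau):
    return y0 + A * np.exp(-t / tau)


def fit_decay_histogram(
    t: np.ndarray,
    y: np.ndarray,
    method: str = "poisson",
    counts_scale: float = 1.0,
    tau0: float | None = None,
    tau_min: float = 1e-6,
    tau_max: float = 1e6,
    y0_bound: float = 0.5,
) -> tuple[float, float, float] | None:
    """Fit y = y0 + A*exp(-t/tau) to histogram heights.

    ``method="poisson"`` maximizes the binned Poisson likelihood of the
    counts (heights * ``counts_scale``) — the appropriate noise model for
    a dwell histogram, unbiased where plain least squares on sparse
    exponential bins is not.  ``method="lsq"`` is ordinary least squares.
    Both are exact on noiseless exponential data.  Multi-start over
    initial decay times; returns (y0, A, tau) or None on failure.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if tau0 is None:
        tau0 = max((t[-1] - t[0]) / 3.0, tau_min * 10)
    y_head = float(max(np.interp(t[0], t, y), 1e-6))
    bounds = [(-y0_bound, y0_bound), (0.0, 50.0), (tau_min, tau_max)]

    def nll_poisson(theta):
        lam = np.clip(_decay_model(t, *theta) * counts_scale, 1e-12, None)
        c = y * counts_scale
        return float((lam - c * np.log(lam)).sum())

    def sse(theta):
        return float(((_decay_model(t, *theta) - y) ** 2).sum())

    objective = nll_poisson if method == "poisson" else sse
    if method not in ("poisson", "lsq"):
        raise ValueError(f"unknown method {method!r}")
    best = None
    for scale in (1.0, 0.3, 3.0):
        tau_i = float(np.clip(tau0 * scale, tau_min, tau_max))
        a_i = float(np.clip(y_head * np.exp(min(t[0] / tau_i, 10.0)), 1e-6, 50.0))
        res = optimize.minimize(
            objective,
            x0=np.array([0.0, a_i, tau_i]),
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
        )
        theta = res.x
        val = objective(theta)
        if best is None or val < best[1]:
            best = (theta, val)
    if best is None:
        return None
    y0, A, tau = best[0]
    return float(y0), float(A), float(tau)


def fit_dwell(
    dist: DwellDistribution,
    bin_width: float | None = None,
    fit_start: float | None = None,
    min_dwells: int = 20,
    fit_stop_quantile: float | None = None,
) -> DwellDistribution:
    """Exponential decay fit of the dwell-time histogram.

    The dwell histogram, normalized by its maximum, is fitted by
    y = y0 + A*exp(-t/tau); the decay rate is k_observed = 1/tau.  Bins
    before ``fit_start`` are excluded (events faster than the frame rate
    are not resolvable and only contaminate the first bins).  A
    left-truncated exponential maximum-likelihood estimate is stored as a
    cross-check (``k_mle``).  Refuses to fit fewer than ``min_dwells``
    dwells (the dwells are still reported).
    """
    if dist.n < min_dwells:
        return dist
    dt = dist.frame_interval
    x = dist.dwells
    if bin_width is None:
        # 2 frames by default, widened for slow decays so bins stay populated
        bin_width = max(2 * dt, float(np.quantile(x, 0.9)) / 20.0)
    if fit_start is None:
        fit_start = 2 * dt
    # dwell durations are frame-quantized; bin on the integer frame grid to
    # avoid float edge collisions and partially covered first bins
    nf = np.rint(x / dt).astype(int)
    w = max(2, int(round(bin_width / dt)))
    bin_width = w * dt
    m0 = int(np.ceil(fit_start / dt - 1e-9))
    nf = nf[nf >= m0]
    if nf.size < min_dwells // 2 or nf.size < 8:
        return dist
    edges_f = np.arange(m0, nf.max() + 2 * w, w)
    counts, _ = np.histogram(nf, bins=edges_f)
    centers = (edges_f[:-1] + 0.5 * (w - 1)) * dt
    norm = counts.max()
    keep = np.ones(counts.size, dtype=bool)
    if fit_stop_quantile is not None:
        # optionally cap the fit range: the deep tail can be shaped by
        # observation-window censor depletion rather than the decay
        stop_f = float(np.quantile(nf, fit_stop_quantile)) + w
        keep = edges_f[:-1] <= stop_f
        keep[: min(4, keep.size)] = True
    yc = (counts / norm)[keep]
    xc = centers[keep]
    if xc.size < 4:
        return dist

    tau0 = max(float(np.mean(x[x >= fit_start]) - fit_start), bin_width)
    # the normalized dwell histogram decays to zero; the offset is a small
    # nuisance (baseline) term, not a free asymptote
    fitted = fit_decay_histogram(xc, yc, counts_scale=float(norm), tau0=tau0,
                                 tau_min=dt / 10, tau_max=100 * x.max() + 1.0,
                                 y0_bound=0.1)
    if fitted is None:
        return dist
    y0, A, tau = fitted
    dist.y0, dist.amplitude, dist.tau = float(y0), float(A), float(tau)
    dist.k_observed = 1.0 / tau
    dist.bin_width = float(bin_width)
    dist.fit_start = float(fit_start)
    # maximum-likelihood cross-check: geometric MLE on the left-truncated
    # frame counts (memorylessness removes the truncation point; the
    # discrete version avoids the frame-quantization bias at fast rates)
    m = float(np.mean(nf - m0))
    if m > 0:
        dist.k_mle = float(-np.log(m / (1.0 + m)) / dt)
    # residual misfit diagnostic against Poisson counting noise
    expected = _decay_model(xc, y0, A, tau) * norm
    obs = yc * norm
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.nansum((obs - expected) ** 2 / np.where(expected > 0, expected, np.nan))
    dof = max(xc.size - 3, 1)
    dist.misfit = bool(chi2 / dof > 3.0)
    return dist


def correct_missed_events(
    k_ab: float,
    k_ba: float,
    dead_time: float,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> tuple[float, float]:
    """Missed-event (dead-time) correction for a reversible two-state pair.

    Events shorter than the camera dead time (about one frame interval)
    are not resolved.  A missed visit to the partner state concatenates
    two dwells: the observed dwell is a geometric sum of true dwells
    (success probability p = P(partner dwell > D) = exp(-k_partner*D))
    plus the durations of the missed visits themselves.  Mean-matching
    gives 1/k_true = p * (1/k_obs - m*g) with m = (1-p)/p missed visits
    per observed dwell and g = E[partner dwell | dwell < D] the mean
    hidden gap.  The coupled pair is solved by fixed-point iteration.
    """
    if dead_time < 0:
        raise ValueError("dead_time must be >= 0")
    D = dead_time
    if D == 0:
        return float(k_ab), float(k_ba)

    def _one(k_obs, k_partner):
        p = np.exp(-k_partner * D)
        if p >= 1.0 - 1e-15:
            return k_obs
        m = (1.0 - p) / p
        g = 1.0 / k_partner - D * p / (1.0 - p)
        inv = p * max(1.0 / k_obs - m * g, 1e-12)
        return 1.0 / inv

    ka, kb = k_ab, k_ba
    for _ in range(max_iter):
        ka_new = _one(k_ab, kb)
        kb_new = _one(k_ba, ka)
        if abs(ka_new - ka) < tol and abs(kb_new - kb) < tol:
            ka, kb = ka_new, kb_new
            break
        ka, kb = ka_new, kb_new
    return float(ka), float(kb)


def correct_rate(k_observed: float, k_photobleach: float = 0.03, window_s: float = 33.0):
    """k_corrected = k_observed - k_photobleach - 1/T.

    Returns (k_corrected, warn) where ``warn`` flags a non-positive result
    (a rate indistinguishable from photobleaching at this window).
    """
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    k = k_observed - k_photobleach - 1.0 / window_s
    return k, bool(k < 0)


# ---------------------------------------------------------------------------
# classification


def classify_trace(
    itrace: IdealizedTrace,
    levels: dict[str, float] | FRETMap | None = None,
    detection_threshold: float = 0.125,
    min_frames: int = 2,
    start_tol_frames: int = 2,
    window_s: float | None = None,
) -> str:
    """Mechanistic class of one idealized, transition-filtered trace.

    rejected        FRET appears then returns to dark without any visit to
                    the classical/hybrid (0.8/0.6) levels
    decoding        binding after the start of recording followed by at
                    least one dwell at the classical/hybrid levels
    post_decoding   already at a classical/hybrid level at the start of
                    the recording
    stalled         a bound phase persisting to the end of the valid
                    window without progression past codon reading
    dark            no resolvable binding event (unclassifiable)

    Precedence for ambiguous traces follows the trace's first resolved
    phase, ties broken in the order post_decoding, decoding, rejected,
    stalled.
    """
    if levels is None:
        levels = FRETMap()
    if isinstance(levels, FRETMap):
        levels = levels.levels
    dt = itrace.frame_interval
    min_dur = min_frames * dt
    visible = [
        d
        for d in itrace.dwells
        if d.mu >= detection_threshold and d.duration >= min_dur
    ]
    if not visible:
        return "dark"
    post_names = {"classical", "hybrid"}
    first = visible[0]
    if assign_level(first.mu, levels) in post_names and first.t_start <= start_tol_frames * dt:
        return "post_decoding"
    if any(assign_level(d.mu, levels) in post_names for d in visible):
        return "decoding"
    last = visible[-1]
    end = window_s if window_s is not None else itrace.valid_end
    if last.t_end >= min(itrace.valid_end, end) - 0.5 * dt:
        return "stalled"
    return "rejected"


def class_fractions(per_trace: pd.DataFrame) -> ClassificationResult:
    """Per-replicate class percentages with across-replicate mean +/- s.d.

    ``per_trace`` needs columns (molecule_id, replicate, class); traces
    labelled "dark" are excluded from the denominators and counted as
    unclassified.
    """
    classified = per_trace[per_trace["class"].isin(CLASSES)]
    n_unclassified = int(len(per_trace) - len(classified))
    counts = (
        classified.groupby(["replicate", "class"]).size().unstack(fill_value=0)
    )
    for c in CLASSES:
        if c not in counts.columns:
            counts[c] = 0
    counts = counts[list(CLASSES)]
    fractions = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return ClassificationResult(
        per_trace=per_trace,
        fractions=fractions,
        mean=fractions.mean(axis=0),
        sd=fractions.std(axis=0, ddof=1) if len(fractions) > 1 else fractions.iloc[0] * 0.0,
        n_unclassified=n_unclassified,
    )


def compare_class_fractions(
    a: ClassificationResult, b: ClassificationResult, cls: str
) -> tuple[float, float]:
    """Two-tailed Welch's t-test on per-replicate fractions of one class."""
    fa = a.fractions[cls].to_numpy()
    fb = b.fractions[cls].to_numpy()
    if fa.size < 2 or fb.size < 2:
        raise ValueError("need >= 2 replicates per condition")
    if np.all(fa == fa[0]) and np.all(fb == fb[0]) and fa[0] == fb[0]:
        return 0.0, 1.0  # degenerate: identical constant groups
    t, p = stats.ttest_ind(fa, fb, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# contour plots


def synchronize_contour(
    ftraces: list[FRETTrace],
    detection_threshold: float = 0.125,
    min_frames: int = 2,
    t_max: float = 10.0,
    n_time_bins: int = 100,
    e_bins: int = 40,
    e_range: tuple[float, float] = (-0.2, 1.2),
):
    """Post-synchronized 2D (time x FRET) histogram.

    Each trace is shifted so that its first detected binding transition
    (E above threshold for at least ``min_frames`` consecutive frames) is
    t = 0; all valid post-synchronization frames are pooled on a fixed
    grid.  Traces without a qualifying event are excluded and counted.
    Returns (histogram, time_edges, fret_edges, n_traces_used).
    """
    t_edges = np.linspace(0.0, t_max, n_time_bins + 1)
    f_edges = np.linspace(e_range[0], e_range[1], e_bins + 1)
    H = np.zeros((n_time_bins, e_bins))
    n_used = 0
    for ft in ftraces:
        above = (ft.efficiency >= detection_threshold) & ft.valid
        start = _first_run(above, min_frames)
        if start is None:
            continue
        n_used += 1
        t = (np.arange(ft.efficiency.size) - start) * ft.frame_interval
        sel = (t >= 0) & ft.valid
        h, _, _ = np.histogram2d(t[sel], ft.efficiency[sel], bins=[t_edges, f_edges])
        H += h
    return H, t_edges, f_edges, n_used


def _first_run(mask: np.ndarray, min_len: int) -> int | None:
    count = 0
    for i, m in enumerate(mask):
        count = count + 1 if m else 0
        if count >= min_len:
            return i - min_len + 1
    return None
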