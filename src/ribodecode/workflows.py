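"""End-to-end analysis workflows tying the pipeline stages together.

These are the per-dataset recipes used by the command line and by the
validation runs: QC -> bleed-through correction -> FRET -> HMM
idealization -> transition filtering -> dwell extraction -> exponential
decay fit -> photobleach/window correction, with per-replicate rate
estimates, plus classification and state-distribution summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pipeline import (
    class_fractions,
    classify_trace,
    compute_fret,
    correct_bleedthrough,
    correct_rate,
    extract_dwells,
    filter_transitions,
    fit_dwell,
    fit_fret_histogram,
    idealize,
    qc_select,
    select_phase_frames,
    ClassificationResult,
    DwellDistribution,
    GaussianMixtureFit,
    IdealizedTrace,
    FRETTrace,
)
from .rates import CameraModel, FRETMap
from .simulate import IntensityTrace, TraceSet

logger = logging.getLogger("ribodecode")

__all__ = ["DwellRateResult", "AnalysisBundle", "idealize_dataset", "dwell_rate_analysis", "analyze_dataset"]


@dataclass
class DwellRateResult:
    """Replicate-resolved corrected rate for one transition class."""

    transition: str
    k_per_replicate: np.ndarray
    k_mean: float
    k_sd: float
    n_dwells: int
    n_censored: int
    pooled: DwellDistribution
    warn_negative: bool = False


@dataclass
class AnalysisBundle:
    """Everything the full analysis of one dataset produces."""

    rates: dict[str, DwellRateResult] = field(default_factory=dict)
    classification: ClassificationResult | None = None
    mixtures: dict[str, GaussianMixtureFit] = field(default_factory=dict)
    qc_report: pd.DataFrame | None = None
    n_traces_in: int = 0
    n_traces_kept: int = 0


def idealize_dataset(
    traceset: TraceSet,
    cam: CameraModel,
    max_states: int = 4,
    run_qc: bool = True,
    anticorr_max: float = -0.05,
) -> tuple[list[FRETTrace], list[IdealizedTrace], pd.DataFrame | None]:
    """QC, correct, compute FRET and idealize every trace of a dataset.

    Returns the FRET traces and the (transition-filtered) idealizations,
    paired by index; traces failing QC or too short to idealize are
    dropped.  Stage counts are logged.
    """
    traces = traceset.traces
    qc_report = None
    if run_qc:
        traces, qc_report = qc_select(traces, anticorr_max=anticorr_max)
        logger.info("qc: kept %d/%d traces", len(traces), len(traceset.traces))
    beta = traceset.manifest.get("bleedthrough", cam.bleedthrough)
    ftraces: list[FRETTrace] = []
    itraces: list[IdealizedTrace] = []
    for trace in traces:
        ft = compute_fret(correct_bleedthrough(trace, beta))
        it = idealize(ft, max_states=max_states)
        if it is None:
            logger.debug("trace %s too short; skipped", trace.molecule_id)
            continue
        ftraces.append(ft)
        itraces.append(filter_transitions(it))
    logger.info("idealized %d traces", len(itraces))
    return ftraces, itraces, qc_report


def dwell_rate_analysis(
    traceset: TraceSet,
    cam: CameraModel,
    src_level: str,
    dst_level: str,
    fmap: FRETMap | None = None,
    max_states: int = 4,
    min_dwell_s: float | None = None,
    fit_start: float | None = None,
    run_qc: bool = True,
    itraces: list[IdealizedTrace] | None = None,
    ftraces: list[FRETTrace] | None = None,
    levels: dict[str, float] | None = None,
    area_ref: float | None = None,
) -> DwellRateResult:
    """Recover one corrected transition rate from a synthetic dataset.

    Runs the full chain and fits the dwell decay per replicate; the
    corrected rate applies k_corrected = k_observed - k_photobleach - 1/T
    with the camera's photobleach rate and observation window.
    Precomputed idealizations can be passed to avoid refitting.
    ``levels`` restricts the named FRET levels to those present in the
    experiment (e.g. only dark/high for a GTPase-deficient run, where no
    post-decoding levels exist and intermediate blur frames would
    otherwise be mapped onto them).  ``area_ref`` switches dwell-duration
    measurement to the signal-area estimator (see
    :func:`ribodecode.pipeline.extract_dwells`), appropriate for fast
    binding events on a dark background.
    """
    fmap = fmap or FRETMap()
    if levels is None:
        levels = fmap.levels
    if min_dwell_s is None:
        min_dwell_s = 2 * cam.frame_interval
    if itraces is None:
        ftraces, itraces, _ = idealize_dataset(traceset, cam, max_states=max_states, run_qc=run_qc)
    if area_ref is not None and ftraces is None:
        raise ValueError("area_ref requires the paired FRET traces")
    by_rep: dict[int, tuple[list[IdealizedTrace], list[FRETTrace]]] = {}
    for j, it in enumerate(itraces):
        its, fts = by_rep.setdefault(it.replicate, ([], []))
        its.append(it)
        if ftraces is not None:
            fts.append(ftraces[j])

    def _extract(its, fts):
        return extract_dwells(
            its, src_level, dst_level, levels, min_dwell_s=min_dwell_s,
            ftraces=fts if area_ref is not None else None, area_ref=area_ref,
        )

    ks = []
    pooled_all: tuple[list, list] = ([], [])
    for r in sorted(by_rep):
        its, fts = by_rep[r]
        dist = fit_dwell(_extract(its, fts), fit_start=fit_start)
        if dist.k_observed is not None:
            k_corr, _ = correct_rate(dist.k_observed, cam.k_photobleach, cam.window_s)
            ks.append(k_corr)
        pooled_all[0].extend(its)
        pooled_all[1].extend(fts)
    pooled = fit_dwell(_extract(*pooled_all), fit_start=fit_start)
    warn = False
    if pooled.k_observed is not None:
        pooled.k_corrected, warn = correct_rate(pooled.k_observed, cam.k_photobleach, cam.window_s)
    ks = np.asarray(ks)
    if ks.size == 0 and pooled.k_corrected is not None:
        ks = np.array([pooled.k_corrected])
    if ks.size == 0:
        raise ValueError(f"no fitted dwell decay for {src_level}->{dst_level}")
    return DwellRateResult(
        transition=f"{src_level}->{dst_level}",
        k_per_replicate=ks,
        k_mean=float(ks.mean()),
        k_sd=float(ks.std(ddof=1)) if ks.size > 1 else 0.0,
        n_dwells=pooled.n,
        n_censored=pooled.n_censored,
        pooled=pooled,
        warn_negative=warn,
    )


def hybrid_fluctuation_analysis(
    traceset: TraceSet,
    cam: CameraModel,
    fmap: FRETMap | None = None,
    max_states: int = 4,
    dead_time: float | None = None,
) -> tuple[DwellRateResult, DwellRateResult]:
    """Classical<->hybrid fluctuation rates with missed-event correction.

    Recovers the 0.8->0.6 and 0.6->0.8 transition rates from
    post-decoding traces; because both dwell distributions are fast, the
    reversible pair is corrected jointly for camera dead time (default one
    frame interval) after the photobleach/window correction.
    """
    from .pipeline import correct_missed_events

    fmap = fmap or FRETMap()
    if dead_time is None:
        dead_time = cam.frame_interval
    all_levels = fmap.levels
    levels = {k: v for k, v in all_levels.items() if k in ("dark", "classical", "hybrid")}
    _, itraces, _ = idealize_dataset(traceset, cam, max_states=max_states)
    fwd = dwell_rate_analysis(traceset, cam, "classical", "hybrid", fmap,
                              max_states=max_states, itraces=itraces, levels=levels)
    rev = dwell_rate_analysis(traceset, cam, "hybrid", "classical", fmap,
                              max_states=max_states, itraces=itraces, levels=levels)
    n = min(fwd.k_per_replicate.size, rev.k_per_replicate.size)
    kf, kr = [], []
    for i in range(n):
        a, b = correct_missed_events(fwd.k_per_replicate[i], rev.k_per_replicate[i], dead_time)
        kf.append(a)
        kr.append(b)
    for res, ks in ((fwd, np.asarray(kf)), (rev, np.asarray(kr))):
        res.k_per_replicate = ks
        res.k_mean = float(ks.mean())
        res.k_sd = float(ks.std(ddof=1)) if ks.size > 1 else 0.0
    return fwd, rev


def analyze_dataset(
    traceset: TraceSet,
    cam: CameraModel,
    fmap: FRETMap | None = None,
    max_states: int = 4,
    transitions: list[tuple[str, str]] | None = None,
    mixture_phases: dict[str, int] | None = None,
    seed: int = 0,
) -> AnalysisBundle:
    """Full analysis of one dataset: rates, classes and state distributions.

    ``transitions`` lists (src_level, dst_level) pairs for dwell-rate
    estimation; ``mixture_phases`` maps a level name to the number of
    Gaussian components fitted to the frames of that phase (e.g.
    {"high": 1} for the codon-reading state, {"post": 2} pools classical
    and hybrid frames).
    """
    fmap = fmap or FRETMap()
    levels = fmap.levels
    bundle = AnalysisBundle(n_traces_in=len(traceset.traces))
    ftraces, itraces, qc_report = idealize_dataset(traceset, cam, max_states=max_states)
    bundle.qc_report = qc_report
    bundle.n_traces_kept = len(itraces)

    if transitions is None:
        transitions = [("high", "dark"), ("classical", "hybrid"), ("hybrid", "classical")]
    by_rep: dict[int, list[IdealizedTrace]] = {}
    for it in itraces:
        by_rep.setdefault(it.replicate, []).append(it)
    for src, dst in transitions:
        min_dwell = 2 * cam.frame_interval
        ks = []
        for r in sorted(by_rep):
            dist = fit_dwell(extract_dwells(by_rep[r], src, dst, levels, min_dwell_s=min_dwell))
            if dist.k_observed is not None:
                ks.append(correct_rate(dist.k_observed, cam.k_photobleach, cam.window_s)[0])
        pooled = fit_dwell(extract_dwells(itraces, src, dst, levels, min_dwell_s=min_dwell))
        if pooled.k_observed is None and not ks:
            logger.info("transition %s->%s: too few dwells, skipped", src, dst)
            continue
        if pooled.k_observed is not None:
            pooled.k_corrected, _ = correct_rate(pooled.k_observed, cam.k_photobleach, cam.window_s)
        ks = np.asarray(ks) if ks else np.asarray([pooled.k_corrected])
        bundle.rates[f"{src}->{dst}"] = DwellRateResult(
            transition=f"{src}->{dst}",
            k_per_replicate=ks,
            k_mean=float(ks.mean()),
            k_sd=float(ks.std(ddof=1)) if ks.size > 1 else 0.0,
            n_dwells=pooled.n,
            n_censored=pooled.n_censored,
            pooled=pooled,
            warn_negative=bool(pooled.k_corrected is not None and pooled.k_corrected < 0),
        )

    rows = [
        {
            "molecule_id": it.molecule_id,
            "replicate": it.replicate,
            "class": classify_trace(it, levels, window_s=cam.window_s),
        }
        for it in itraces
    ]
    if rows:
        bundle.classification = class_fractions(pd.DataFrame(rows))

    if mixture_phases:
        for phase, n_comp in mixture_phases.items():
            frames_by_rep = []
            for r in sorted(by_rep):
                frames = []
                for ft, it in zip(ftraces, itraces):
                    if it.replicate != r:
                        continue
                    if phase == "post":
                        vals = np.concatenate(
                            [
                                select_phase_frames(ft, it, levels, "classical", trim_frames=1),
                                select_phase_frames(ft, it, levels, "hybrid", trim_frames=1),
                            ]
                        )
                    else:
                        vals = select_phase_frames(ft, it, levels, phase, trim_frames=1)
                    frames.append(vals)
                frames_by_rep.append(np.concatenate(frames) if frames else np.array([]))
            try:
                bundle.mixtures[phase] = fit_fret_histogram(frames_by_rep, n_comp, seed=seed)
            except ValueError as exc:
                logger.info("mixture fit for phase %r skipped: %s", phase, exc)
    return bundle
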