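"""Ensemble (stopped-flow / quench-flow) time-course fitting.

Signals are normalized (relative fluorescence by the t = 0 value, product
fractions to [0, 1]) and fitted per replicate by one- or two-exponential
functions; apparent rate constants k_app and reaction times tau = 1/k_app
are aggregated across replicates as mean +/- SEM.  Group comparisons use
two-tailed unpaired Student's or Welch's t-tests, without multiplicity
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ExpFitResult",
    "normalize_fluorescence",
    "normalize_product",
    "fit_exponential",
    "fit_exponential_single",
    "delay_between",
    "compare_tau",
]


@dataclass
class ExpFitResult:
    """One- or two-phase exponential fit aggregated over replicates.

    Phases are ordered by descending amplitude; the first entry is the
    major phase.  ``k_app`` and ``tau`` are across-replicate means,
    ``k_sem``/``tau_sem`` the standard errors across replicate fits.
    """

    phases: int
    k_app: np.ndarray
    amplitudes: np.ndarray
    y0: float
    k_sem: np.ndarray
    rising: bool
    end_level: float
    replicate_fits: pd.DataFrame = field(default_factory=pd.DataFrame)
    note: str = ""

    @property
    def tau(self) -> np.ndarray:
        return 1.0 / self.k_app

    @property
    def tau_major(self) -> float:
        return float(1.0 / self.k_app[0])

    @property
    def tau_sem(self) -> np.ndarray:
        return self.k_sem / self.k_app**2

    @property
    def major_amplitude_fraction(self) -> float:
        a = np.abs(self.amplitudes)
        return float(a[0] / a.sum())


def _per_replicate(tc: pd.DataFrame):
    if "replicate" not in tc.columns:
        yield 0, tc
        return
    for r, g in tc.groupby("replicate"):
        yield r, g


def normalize_fluorescence(tc: pd.DataFrame) -> pd.DataFrame:
    """Relative fluorescence: divide by the value at time 0, per replicate."""
    out = []
    for r, g in _per_replicate(tc):
        g = g.sort_values("time").copy()
        v0 = g["signal"].iloc[0]
        if v0 == 0:
            raise ValueError("signal at time 0 is zero; cannot normalize")
        g["signal"] = g["signal"] / v0
        out.append(g)
    return pd.concat(out, ignore_index=True)


def normalize_product(tc: pd.DataFrame) -> pd.DataFrame:
    """Affine rescale of the product signal to [0, 1], per replicate."""
    out = []
    for r, g in _per_replicate(tc):
        g = g.sort_values("time").copy()
        lo, hi = g["signal"].min(), g["signal"].max()
        if hi <= lo:
            raise ValueError("flat series; cannot rescale to [0, 1]")
        g["signal"] = (g["signal"] - lo) / (hi - lo)
        out.append(g)
    return pd.concat(out, ignore_index=True)


def _model(t, y0, amps, ks, rising):
    decay = np.exp(-np.outer(t, ks))
    if rising:
        return y0 + (amps * (1.0 - decay)).sum(axis=1)
    return y0 + (amps * decay).sum(axis=1)


def fit_exponential_single(
    t: np.ndarray,
    y: np.ndarray,
    phases: int = 1,
    rising: bool | None = None,
):
    """Nonlinear least squares exponential fit of one series.

    Returns (y0, amplitudes, rates, rising) with phases ordered by
    descending developed amplitude |A_i (1 - e^(-k_i T))| over the fitted
    window T — the contribution of each phase to the observed signal
    change (a slow phase can carry a large nominal amplitude while barely
    developing within the record).  The rising/decaying form is inferred
    from the sign of the end-minus-start difference unless given.
    Non-convergence triggers a restart grid over initial rates.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 8:
        raise ValueError("need >= 8 points")
    if phases not in (1, 2):
        raise ValueError("phases must be 1 or 2")
    if rising is None:
        head = y[: max(3, t.size // 10)].mean()
        tail = y[-max(3, t.size // 10):].mean()
        rising = tail > head
    span = abs(y.max() - y.min())
    t_scale = t[-1] - t[0]

    def pack(theta):
        y0 = theta[0]
        amps = np.asarray(theta[1 : 1 + phases])
        ks = np.asarray(theta[1 + phases :])
        return y0, amps, ks

    def resid(theta):
        y0, amps, ks = pack(theta)
        return _model(t, y0, amps, ks, rising) - y

    def linear_solve(ks):
        # variable projection: for fixed rates the offset and amplitudes
        # are a linear least-squares problem
        decay = np.exp(-np.outer(t, ks))
        basis = (1.0 - decay) if rising else decay
        A = np.column_stack([np.ones_like(t), basis])
        coef, res_, *_ = np.linalg.lstsq(A, y, rcond=None)
        pred = A @ coef
        return coef, float(((pred - y) ** 2).sum())

    # coarse log-spaced rate grid; robust against the local optima of the
    # fully nonlinear problem when a second phase is weak
    k_lo, k_hi = 0.05 / t_scale, 2000.0 / t_scale
    grid = np.geomspace(k_lo, k_hi, 25)
    best_ks, best_sse = None, np.inf
    if phases == 1:
        for k1 in grid:
            _, sse = linear_solve(np.array([k1]))
            if sse < best_sse:
                best_ks, best_sse = np.array([k1]), sse
    else:
        for i, k1 in enumerate(grid):
            for k2 in grid[: i]:  # k2 < k1
                _, sse = linear_solve(np.array([k1, k2]))
                if sse < best_sse:
                    best_ks, best_sse = np.array([k1, k2]), sse
    coef, _ = linear_solve(best_ks)
    theta0 = np.concatenate([[coef[0]], coef[1:], best_ks])
    lower = [-np.inf] + [-np.inf] * phases + [1e-9] * phases
    upper = [np.inf] + [np.inf] * phases + [np.inf] * phases
    theta0[1 + phases:] = np.clip(theta0[1 + phases:], 1e-9, None)
    sol = optimize.least_squares(resid, theta0, bounds=(lower, upper), max_nfev=5000)
    if not sol.success and sol.cost > 1e-3 * span**2 * t.size:
        raise RuntimeError("exponential fit did not converge")
    y0, amps, ks = pack(sol.x)
    developed = np.abs(amps * (1.0 - np.exp(-ks * t_scale)))
    order = np.argsort(-developed)
    return float(y0), amps[order], ks[order], rising


def fit_exponential(
    tc: pd.DataFrame,
    phases: int = 1,
    rising: bool | None = None,
    min_minor_fraction: float = 0.05,
    min_rate_ratio: float = 3.0,
    average_replicates: bool = False,
) -> ExpFitResult:
    """Per-replicate exponential fits aggregated to mean +/- SEM.

    Fits y0 + sum_i A_i (1 - e^(-k_i t)) (rising) or the decaying form to
    each replicate, orders phases by descending amplitude, and reports
    across-replicate means with SEM.  A two-phase fit falls back to one
    phase when the minor amplitude fraction is below
    ``min_minor_fraction`` or the rate ratio below ``min_rate_ratio``
    (unidentifiable second phase).

    ``average_replicates`` first averages the replicate signals on their
    common time grid and fits the averaged course once — the stopped-flow
    convention, where each displayed course is an average of technical
    replicates; a weak second phase is then much better identified.
    """
    if average_replicates and "replicate" in tc.columns:
        tc = (
            tc.groupby("time", as_index=False)["signal"].mean()
        )
    rows = []
    note = ""
    for r, g in _per_replicate(tc):
        t = g["time"].to_numpy()
        y = g["signal"].to_numpy()
        use_phases = phases
        y0, amps, ks, direction = fit_exponential_single(t, y, phases, rising)
        if phases == 2:
            t_span = t.max() - t.min()
            dev = np.abs(amps * (1.0 - np.exp(-ks * t_span)))
            frac_minor = dev[1] / dev.sum()
            ratio = max(ks) / min(ks)
            if frac_minor < min_minor_fraction or ratio < min_rate_ratio:
                y0, amps, ks, direction = fit_exponential_single(t, y, 1, rising)
                use_phases = 1
                note = "two-phase fit unidentifiable; fell back to one phase"
        row = {"replicate": r, "y0": y0, "phases": use_phases, "rising": direction}
        for i in range(len(ks)):
            row[f"A{i + 1}"] = amps[i]
            row[f"k{i + 1}"] = ks[i]
        rows.append(row)
    fits = pd.DataFrame(rows)
    n_phases = int(fits["phases"].min())
    k_cols = [f"k{i + 1}" for i in range(n_phases)]
    a_cols = [f"A{i + 1}" for i in range(n_phases)]
    k_mean = fits[k_cols].mean().to_numpy()
    k_sem = (
        fits[k_cols].std(ddof=1).to_numpy() / np.sqrt(len(fits))
        if len(fits) > 1
        else np.zeros(n_phases)
    )
    amps = fits[a_cols].mean().to_numpy()
    y0 = float(fits["y0"].mean())
    direction = bool(fits["rising"].iloc[0])
    end_level = y0 + amps.sum() if direction else y0
    return ExpFitResult(
        phases=n_phases,
        k_app=k_mean,
        amplitudes=amps,
        y0=y0,
        k_sem=k_sem,
        rising=direction,
        end_level=float(end_level),
        replicate_fits=fits,
        note=note,
    )


def delay_between(fit_a: ExpFitResult, fit_b: ExpFitResult) -> float:
    """Major-phase reaction-time difference tau_B - tau_A (s)."""
    return fit_b.tau_major - fit_a.tau_major


def compare_tau(
    taus_a,
    taus_b,
    test: str = "student_unpaired",
) -> tuple[float, float]:
    """Two-tailed unpaired t-test on per-replicate reaction times.

    ``test`` is "student_unpaired" (pooled variance) or "welch".  No
    multiplicity adjustment is applied.
    """
    a = np.asarray(taus_a, dtype=float)
    b = np.asarray(taus_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 fits per group")
    if test not in ("student_unpaired", "welch"):
        raise ValueError(f"unknown test {test!r}")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=(test == "student_unpaired"))
    return float(t), float(p)
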