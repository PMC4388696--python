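"""FRAP trace screening, normalization and recovery half-time fitting.

A FRAP experiment on a midcell structure yields, per cell, the average
intensity of the bleached spot and of the whole midcell region in each frame
(frames are numbered from 1; the photobleach occurs during frame
``bleach_frame``, so frame ``bleach_frame + 1`` is the first post-bleach
acquisition).  Analysis follows four steps:

1. screen: keep traces whose bleach ratio (I(1) - I(3)) / I(1) exceeds 40%;
2. normalize each trace to [0, ~1]: zero at the first post-bleach frame,
   maximum given by the mean midcell intensity over the last 60 frames,
   which is far more stable than the tail of the bleached-spot trace;
3. average the normalized traces pointwise and fit a single exponential
   R(t') = A (1 - exp(-k t')), with t' from the first post-bleach frame;
   the recovery half-time is tau_1/2 = ln 2 / k;
4. bootstrap: resample traces with replacement (default 3000 times),
   refitting the average each time; the s.d. of the bootstrap half-times is
   the standard error.

The fit is exposed statsmodels-style: build a :class:`FrapRecoveryModel`
from traces, call :meth:`~FrapRecoveryModel.fit`, read the
:class:`FrapResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "FrapTrace",
    "FrapResults",
    "FrapRecoveryModel",
    "NormalizationError",
    "FrapFitError",
    "bleach_ratio",
    "screen_bleach_ratio",
    "normalize_trace",
    "fit_halftime",
    "bootstrap_se",
    "read_frap_trace",
]


class NormalizationError(ValueError):
    """The normalization denominator is not positive; the trace is unusable."""


class FrapFitError(RuntimeError):
    """The exponential recovery fit failed to converge."""


@dataclass
class FrapTrace:
    """Two-ROI FRAP trace.  ``i_bleach[0]`` is frame 1."""

    i_bleach: np.ndarray
    i_midcell: np.ndarray
    frame_interval: float = 2.0
    bleach_frame: int = 2

    def __post_init__(self):
        self.i_bleach = np.asarray(self.i_bleach, dtype=float)
        self.i_midcell = np.asarray(self.i_midcell, dtype=float)
        if len(self.i_bleach) != len(self.i_midcell):
            raise ValueError("ROI series must have equal length")
        if len(self.i_bleach) <= self.bleach_frame:
            raise ValueError("trace ends before the first post-bleach frame")

    @property
    def n_frames(self) -> int:
        return len(self.i_bleach)

    @property
    def first_postbleach(self) -> int:
        """1-based frame number of the first post-bleach acquisition."""
        return self.bleach_frame + 1


def read_frap_trace(path, frame_interval: float = 2.0, bleach_frame: int = 2):
    """Read a FRAP trace CSV with columns frame, I_bleach, I_midcell
    (a t_s column, if present, is ignored in favour of ``frame_interval``)."""
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    try:
        bleach = df[cols["i_bleach"]].to_numpy(dtype=float)
        midcell = df[cols["i_midcell"]].to_numpy(dtype=float)
    except KeyError as exc:
        raise ValueError(f"missing FRAP column: {exc}") from exc
    return FrapTrace(
        i_bleach=bleach,
        i_midcell=midcell,
        frame_interval=frame_interval,
        bleach_frame=bleach_frame,
    )


def bleach_ratio(trace: FrapTrace) -> float:
    """Bleaching ratio (I_bleach(1) - I_bleach(3)) / I_bleach(1), the
    fractional intensity drop between the prebleach and the first
    post-bleach acquisition."""
    if trace.n_frames < 3:
        raise ValueError("trace needs at least 3 frames")
    i1 = trace.i_bleach[0]
    i3 = trace.i_bleach[trace.first_postbleach - 1]
    if i1 == 0:
        return math.nan
    return float((i1 - i3) / i1)


def screen_bleach_ratio(
    trace: FrapTrace, min_ratio: float = 0.40
) -> tuple[bool, float]:
    """Accept a trace iff its bleach ratio exceeds ``min_ratio`` (a ratio
    that is undefined, I(1) = 0, rejects the trace)."""
    ratio = bleach_ratio(trace)
    return (bool(ratio > min_ratio) if math.isfinite(ratio) else False), ratio


def normalize_trace(
    trace: FrapTrace, plateau_window: tuple[int, int] = (61, 120)
) -> np.ndarray:
    """Normalize a trace to [0, ~1].

    R(N) = (I_bleach(N) - I_bleach(3)) / (<I_midcell(61:120)> - I_bleach(3));
    the first post-bleach frame maps to exactly 0 and the stable midcell
    plateau to 1.  Frames are 1-based; ``plateau_window`` is inclusive.
    """
    lo, hi = plateau_window
    if trace.n_frames < hi:
        raise ValueError(
            f"trace has {trace.n_frames} frames; plateau window needs {hi}"
        )
    i3 = trace.i_bleach[trace.first_postbleach - 1]
    denom = float(np.mean(trace.i_midcell[lo - 1 : hi])) - i3
    if denom <= 0:
        raise NormalizationError("normalization denominator is not positive")
    return (trace.i_bleach - i3) / denom


def _recovery(t, amplitude, k):
    return amplitude * (1.0 - np.exp(-k * t))


@dataclass
class FrapResults:
    """Fitted single-exponential recovery: rate k, half-time ln 2 / k."""

    rate: float
    halftime: float
    amplitude: float
    se_halftime: float
    n_traces: int
    n_bootstrap: int
    n_rejected: int = 0
    bootstrap_halftimes: np.ndarray | None = None

    def summary(self) -> str:
        se = f"{self.se_halftime:.1f}" if self.n_bootstrap else "n/a"
        return (
            "FRAP single-exponential recovery fit\n"
            f"  traces (accepted)   : {self.n_traces}"
            f" ({self.n_rejected} rejected by bleach-ratio screen)\n"
            f"  rate k (1/s)        : {self.rate:.4f}\n"
            f"  half-time (s)       : {self.halftime:.1f}\n"
            f"  amplitude A         : {self.amplitude:.3f}\n"
            f"  bootstrap se (s)    : {se} "
            f"({self.n_bootstrap} resamples)"
        )

    def plot(self, model: "FrapRecoveryModel", ax=None):
        """Average normalized trace with the fitted exponential overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t, mean_trace = model.average_trace()
        ax.plot(t, mean_trace, ".", ms=4, label="average of normalized traces")
        tt = np.linspace(0, t.max(), 200)
        ax.plot(tt, _recovery(tt, self.amplitude, self.rate), "r-", label="fit")
        ax.set_xlabel("time after bleach (s)")
        ax.set_ylabel("normalized recovery")
        ax.legend()
        return ax


class FrapRecoveryModel:
    """Recovery model over a set of FRAP traces.

    Screens traces at construction, keeps the normalized accepted ones, and
    fits the average on :meth:`fit` (optionally with a bootstrap standard
    error).  ``fit(n_boot=3000, seed=...)`` reproduces the standard analysis.
    """

    def __init__(
        self,
        traces,
        min_bleach_ratio: float = 0.40,
        plateau_window: tuple[int, int] = (61, 120),
    ):
        self.normalized: list[np.ndarray] = []
        self.n_rejected = 0
        self.frame_interval = None
        self.first_postbleach = None
        for trace in traces:
            accepted, _ = screen_bleach_ratio(trace, min_bleach_ratio)
            if not accepted:
                self.n_rejected += 1
                continue
            try:
                series = normalize_trace(trace, plateau_window)
            except NormalizationError:
                self.n_rejected += 1
                continue
            self.normalized.append(series)
            self.frame_interval = trace.frame_interval
            self.first_postbleach = trace.first_postbleach
        if not self.normalized:
            raise ValueError("no traces passed screening")
        self._matrix = np.vstack(self.normalized)

    @property
    def n_traces(self) -> int:
        return len(self.normalized)

    def average_trace(self, indices=None):
        """Pointwise average of (a resample of) the normalized traces over
        the post-bleach frames; returns (t', R)."""
        mat = self._matrix if indices is None else self._matrix[indices]
        mean_trace = mat.mean(axis=0)
        post = slice(self.first_postbleach - 1, None)
        n_post = mean_trace[post].shape[0]
        t = np.arange(n_post) * self.frame_interval
        return t, mean_trace[post]

    def _fit_average(self, indices=None):
        t, r = self.average_trace(indices)
        try:
            popt, _ = curve_fit(
                _recovery,
                t,
                r,
                p0=(max(float(r[-10:].mean()), 0.1), 0.05),
                bounds=([1e-6, 1e-6], [1.2, 10.0]),
                maxfev=10000,
            )
        except RuntimeError as exc:
            raise FrapFitError(f"recovery fit failed: {exc}") from exc
        return float(popt[0]), float(popt[1])

    def fit(self, n_boot: int = 0, seed=None, max_failure_frac: float = 0.05):
        """Fit the averaged recovery; with ``n_boot`` > 0, bootstrap the
        traces for a half-time standard error."""
        amplitude, k = self._fit_average()
        se = 0.0
        boots = None
        if n_boot > 0:
            if self.n_traces < 2:
                raise ValueError("bootstrap needs >= 2 traces")
            rng = np.random.default_rng(seed)
            halftimes = []
            failures = 0
            for _ in range(n_boot):
                idx = rng.integers(0, self.n_traces, self.n_traces)
                try:
                    _, kb = self._fit_average(idx)
                    halftimes.append(math.log(2.0) / kb)
                except FrapFitError:
                    failures += 1
            if failures > max_failure_frac * n_boot:
                raise FrapFitError(
                    f"{failures}/{n_boot} bootstrap fits failed"
                )
            boots = np.asarray(halftimes)
            se = float(np.std(boots))
        return FrapResults(
            rate=k,
            halftime=math.log(2.0) / k,
            amplitude=amplitude,
            se_halftime=se,
            n_traces=self.n_traces,
            n_bootstrap=n_boot,
            n_rejected=self.n_rejected,
            bootstrap_halftimes=boots,
        )


def fit_halftime(traces, **fit_kwargs) -> FrapResults:
    """Screen, normalize, average and fit a set of :class:`FrapTrace`."""
    return FrapRecoveryModel(traces).fit(**fit_kwargs)


def bootstrap_se(traces, n_boot: int = 3000, seed=None) -> float:
    """Bootstrap standard error of the recovery half-time."""
    return FrapRecoveryModel(traces).fit(n_boot=n_boot, seed=seed).se_halftime
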