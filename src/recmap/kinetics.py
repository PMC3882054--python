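"""Two-electrode voltage-clamp analysis: single-exponential activation and
deactivation fitting, normalized current-voltage relations, and group
comparison of gating time constants.

The fitted model for a depolarizing test pulse is the three-parameter
mono-exponential

    I(t) = I_ss - dI * exp(-t / tau)

with steady-state current I_ss, time-dependent amplitude dI (so the
instantaneous current at t=0 is I_ss - dI), and activation time constant tau
in milliseconds.  The default fit window is the first 250 ms of the pulse.
Initialization comes from log-linearizing I_ss_est - I(t); refinement is
nonlinear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass(frozen=True)
class ClampProtocol:
    """Voltage-step protocol: holding potential, a family of test pulses,
    and a fixed deactivation pulse after each test pulse."""

    holding_mv: float = -30.0
    test_voltages: tuple[float, ...] = tuple(float(v) for v in range(-80, 81, 20))
    test_duration_ms: float = 2000.0
    deact_voltage: float = -80.0
    deact_duration_ms: float = 500.0

    def __post_init__(self) -> None:
        if self.test_duration_ms <= 0 or self.deact_duration_ms <= 0:
            raise ValueError("pulse durations must be positive")
        if len(set(self.test_voltages)) != len(self.test_voltages):
            raise ValueError("test voltages must be distinct")


@dataclass
class CurrentTrace:
    """Sampled currents of one recording: one current vector per test
    voltage over a shared uniform time base (ms since pulse onset), plus the
    deactivation segment."""

    protocol: ClampProtocol
    time_ms: np.ndarray
    currents: dict[float, np.ndarray]
    deact_time_ms: np.ndarray | None = None
    deact_currents: dict[float, np.ndarray] | None = None

    def __post_init__(self) -> None:
        for v, i in self.currents.items():
            if i.shape != self.time_ms.shape:
                raise ValueError(f"current vector at {v} mV does not match time base")

    def voltage(self, v: float) -> np.ndarray:
        try:
            return self.currents[v]
        except KeyError:
            raise KeyError(f"voltage {v} mV not in trace "
                           f"(has {sorted(self.currents)})") from None


@dataclass(frozen=True)
class ExpFit:
    tau_ms: float
    steady: float
    amplitude: float  # time-dependent amplitude dI
    offset: float  # instantaneous current = steady - amplitude
    rss: float
    converged: bool


def _fit_monoexponential(t: np.ndarray, i: np.ndarray,
                         xtol: float = 1e-10) -> ExpFit:
    if len(t) < 4:
        raise ValueError("need at least 4 samples to fit")
    t = np.asarray(t, dtype=float)
    i = np.asarray(i, dtype=float)
    t0 = t - t[0]
    rng_i = i.max() - i.min()
    scale = max(abs(i).max(), 1.0)
    if rng_i <= 1e-12 * scale:
        # flat segment: no time-dependent component to fit
        return ExpFit(tau_ms=np.nan, steady=float(i.mean()), amplitude=0.0,
                      offset=float(i.mean()), rss=float(((i - i.mean()) ** 2).sum()),
                      converged=False)

    # log-linear initialization on i_ss_est - i
    i_ss0 = float(i[-1])
    resid0 = i_ss0 - i + np.sign(i_ss0 - i[0]) * 1e-12
    sign = np.sign(resid0[0]) or 1.0
    y = sign * resid0
    good = y > 1e-9 * scale
    if good.sum() >= 3:
        slope, intercept = np.polyfit(t0[good], np.log(y[good]), 1)
        tau0 = -1.0 / slope if slope < 0 else (t0[-1] / 3 or 1.0)
        d0 = sign * np.exp(intercept)
    else:
        tau0 = t0[-1] / 3 or 1.0
        d0 = i_ss0 - i[0]
    tau0 = float(np.clip(tau0, 1e-3, 1e7))

    def model(tt, i_ss, d, tau):
        return i_ss - d * np.exp(-tt / tau)

    try:
        popt, _ = optimize.curve_fit(
            model, t0, i, p0=(i_ss0, d0, tau0), maxfev=20000, xtol=xtol
        )
    except RuntimeError:
        return ExpFit(tau_ms=np.nan, steady=i_ss0, amplitude=float(d0), offset=i_ss0 - d0,
                      rss=np.inf, converged=False)
    i_ss, d, tau = (float(x) for x in popt)
    resid = i - model(t0, *popt)
    rss = float((resid**2).sum())
    converged = bool(np.isfinite(tau) and tau > 0)
    rel_amp = abs(d) / max(abs(i_ss), 1e-12)
    if rel_amp < 1e-6:
        converged = False
    return ExpFit(tau_ms=tau, steady=i_ss, amplitude=d, offset=i_ss - d, rss=rss,
                  converged=converged)


def fit_activation(trace: CurrentTrace, voltage: float = 80.0,
                   window_ms: float = 250.0) -> ExpFit:
    """Fit the activation time constant over the first ``window_ms`` of the
    test pulse at ``voltage`` (default +80 mV, 250 ms)."""
    i = trace.voltage(voltage)
    t = trace.time_ms
    if t[-1] < window_ms:
        raise ValueError(f"trace covers only {t[-1]} ms, window is {window_ms} ms")
    mask = t <= window_ms
    return _fit_monoexponential(t[mask], i[mask])


def fit_deactivation(trace: CurrentTrace, voltage: float = 80.0,
                     window_ms: float | None = None) -> ExpFit:
    """Fit the deactivation (relaxation) time constant on the post-pulse
    segment following the test pulse at ``voltage``.  Default window is the
    full deactivation segment."""
    if trace.deact_time_ms is None or trace.deact_currents is None:
        raise ValueError("trace has no deactivation segment")
    t = trace.deact_time_ms
    i = trace.deact_currents[voltage]
    if window_ms is not None:
        mask = t <= window_ms
        t, i = t[mask], i[mask]
    return _fit_monoexponential(t, i)


@dataclass
class IVCurve:
    """Normalized current-voltage relation: mean end-of-pulse current per
    test voltage divided by the +80 mV value, averaged across traces."""

    voltages: np.ndarray
    normalized_mean: np.ndarray
    sem: np.ndarray

    def value_at(self, v: float) -> float:
        j = int(np.argmin(np.abs(self.voltages - v)))
        if self.voltages[j] != v:
            raise KeyError(f"voltage {v} not in curve")
        return float(self.normalized_mean[j])


def normalize_iv(traces: list[CurrentTrace], reference_voltage: float = 80.0,
                 tail_ms: float = 10.0) -> IVCurve:
    """Per trace, read the current at the end of the test pulse (mean of the
    final ``tail_ms``) for each voltage, normalize by the value at the
    reference voltage (+80 mV), then average across traces."""
    if not traces:
        raise ValueError("no traces")
    voltages = np.array(sorted(traces[0].currents), dtype=float)
    per_trace = []
    for tr in traces:
        t = tr.time_ms
        mask = t >= t[-1] - tail_ms
        ref = float(tr.voltage(reference_voltage)[mask].mean())
        if ref == 0.0:
            raise ValueError("zero current at the reference voltage")
        per_trace.append([float(tr.voltage(v)[mask].mean()) / ref for v in voltages])
    arr = np.array(per_trace)
    mean = arr.mean(axis=0)
    sem = arr.std(axis=0, ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else np.zeros(len(voltages))
    return IVCurve(voltages=voltages, normalized_mean=mean, sem=sem)


@dataclass(frozen=True)
class GroupComparison:
    t_statistic: float
    df: float
    p_value: float
    fold_ratio: float  # mean(a) / mean(b)
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float

    def to_dict(self) -> dict:
        return {
            "t_statistic": self.t_statistic,
            "df": self.df,
            "p_value": self.p_value,
            "fold_ratio": self.fold_ratio,
            "mean_a": self.mean_a,
            "sem_a": self.sem_a,
            "mean_b": self.mean_b,
            "sem_b": self.sem_b,
        }


def compare_groups(taus_a: list[float], taus_b: list[float],
                   equal_var: bool = True) -> GroupComparison:
    """Two-sample t-test between two sets of fitted time constants
    (Student's equal-variance by default; Welch with ``equal_var=False``).
    Also reports the fold ratio of group means and means ± s.e.m."""
    a = np.asarray(taus_a, dtype=float)
    b = np.asarray(taus_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        t_stat, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        df = len(a) + len(b) - 2
    else:
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        t_stat, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return GroupComparison(
        t_statistic=t_stat,
        df=df,
        p_value=p,
        fold_ratio=float(a.mean() / b.mean()),
        mean_a=float(a.mean()),
        sem_a=float(a.std(ddof=1) / np.sqrt(len(a))),
        mean_b=float(b.mean()),
        sem_b=float(b.std(ddof=1) / np.sqrt(len(b))),
    )


# --------------------------------------------------------------------------
# trace file I/O (TSV: time_ms column + one current column per test voltage)
# --------------------------------------------------------------------------


def write_trace_tsv(trace: CurrentTrace, path, deact_path=None) -> None:
    cols = {"time_ms": trace.time_ms}
    for v in sorted(trace.currents):
        cols[f"mV_{v:g}"] = trace.currents[v]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6g")
    if deact_path is not None and trace.deact_time_ms is not None:
        cols = {"time_ms": trace.deact_time_ms}
        for v in sorted(trace.deact_currents):
            cols[f"mV_{v:g}"] = trace.deact_currents[v]
        pd.DataFrame(cols).to_csv(deact_path, sep="\t", index=False, float_format="%.6g")


def read_trace_tsv(path, deact_path=None,
                   protocol: ClampProtocol | None = None) -> CurrentTrace:
    df = pd.read_csv(path, sep="\t")
    volts = [float(c[3:]) for c in df.columns if c.startswith("mV_")]
    currents = {v: df[f"mV_{v:g}"].to_numpy() for v in volts}
    deact_t = deact_c = None
    if deact_path is not None:
        dd = pd.read_csv(deact_path, sep="\t")
        deact_t = dd["time_ms"].to_numpy()
        deact_c = {float(c[3:]): dd[c].to_numpy() for c in dd.columns if c.startswith("mV_")}
    proto = protocol or ClampProtocol(
        test_voltages=tuple(sorted(volts)),
        test_duration_ms=float(df["time_ms"].iloc[-1]) or 2000.0,
    )
    return CurrentTrace(
        protocol=proto,
        time_ms=df["time_ms"].to_numpy(),
        currents=currents,
        deact_time_ms=deact_t,
        deact_currents=deact_c,
    )
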