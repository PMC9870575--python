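"""Gas-phase measurement of oxygen uptake and CO2 elimination.

Two measurement routes:

* membrane lung — sweep-gas mass balance.  Outlet gas flow is not measured
  directly; it is recovered from nitrogen conservation (the Haldane
  transformation): all nitrogen entering through the air flow controller
  leaves through the exhaust, so
  ``Q_out = air_inflow * 0.79 / (1 - F_PE_O2 - F_PE_CO2)``.
* native lung — breath-by-breath integration of tidal gas flow with the
  capnography / oximetry fraction traces, averaged over a measurement
  window (default 3 min).

Sign convention for airway flow waveforms: positive = expiratory flow.
Uptake and elimination rates are reported as positive magnitudes, mL/min
(STPD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Waveform",
    "SweepGasSetting",
    "ExhaustFractions",
    "WindowedExchange",
    "haldane_outlet_flow",
    "ecmo_exhaust_exchange",
    "integrate_breath_vco2",
    "integrate_breath_vo2",
    "estimate_sidestream_delay",
    "window_average",
]

#: Minimum exhaust nitrogen fraction for a usable Haldane transformation;
#: at sweep oxygen fractions much above 0.6 the denominator becomes too
#: small and the transformation is unreliable.
MIN_N2_FRACTION = 0.05

#: Hysteresis for breath-phase detection on the flow signal, L/min.
FLOW_HYSTERESIS = 0.1


@dataclass(frozen=True)
class Waveform:
    """Uniformly sampled signal (gas flow in L/min or gas fraction, 0-1)."""

    start_time: float
    sample_rate: float
    values: np.ndarray
    is_fraction: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be > 0, got {self.sample_rate}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("waveform contains non-finite samples")
        if self.is_fraction and (
            np.any(self.values < 0) or np.any(self.values > 1)
        ):
            raise ValueError("fraction waveform outside [0, 1]")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.values.size / self.sample_rate


@dataclass(frozen=True)
class SweepGasSetting:
    """Sweep gas blend at the oxygenator inlet.

    ``fd_o2`` is the blended inlet oxygen fraction; if omitted it is
    computed from the air/O2 flows, otherwise it must agree with the blend
    within 1% absolute.
    """

    air_inflow: float  # L/min
    o2_inflow: float  # L/min
    n2_fraction_of_air: float = 0.79
    fd_o2: float | None = None

    def __post_init__(self) -> None:
        if self.air_inflow < 0 or self.o2_inflow < 0:
            raise ValueError("sweep flows must be >= 0")
        if not 0.0 <= self.n2_fraction_of_air <= 1.0:
            raise ValueError("n2_fraction_of_air must be in [0, 1]")
        blend = self._blend_fd_o2()
        if self.fd_o2 is None:
            object.__setattr__(self, "fd_o2", blend)
        else:
            if not 0.0 <= self.fd_o2 <= 1.0:
                raise ValueError("fd_o2 must be in [0, 1]")
            if blend is not None and abs(self.fd_o2 - blend) > 0.01:
                raise ValueError(
                    f"fd_o2={self.fd_o2:.3f} inconsistent with blend {blend:.3f}"
                )

    def _blend_fd_o2(self) -> float | None:
        total = self.air_inflow + self.o2_inflow
        if total == 0:
            return None
        o2_frac_air = 1.0 - self.n2_fraction_of_air
        return (o2_frac_air * self.air_inflow + self.o2_inflow) / total

    @property
    def total_inflow(self) -> float:
        return self.air_inflow + self.o2_inflow

    @property
    def o2_inflow_total(self) -> float:
        """O2 entering the oxygenator, L/min (air O2 + pure O2 line)."""
        return (1.0 - self.n2_fraction_of_air) * self.air_inflow + self.o2_inflow


@dataclass(frozen=True)
class ExhaustFractions:
    """Dry gas fractions measured in the oxygenator exhaust."""

    f_pe_o2: float
    f_pe_co2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_pe_o2 <= 1.0 or not 0.0 <= self.f_pe_co2 <= 1.0:
            raise ValueError("exhaust fractions must be in [0, 1]")
        if self.f_pe_o2 + self.f_pe_co2 >= 1.0:
            raise ValueError("f_pe_o2 + f_pe_co2 must be < 1")


@dataclass
class WindowedExchange:
    """Gas exchange rates for one measurement window, mL/min (STPD).

    Rates are magnitudes; NaN marks a missing channel.  Default window
    length is the 3-minute measurement interval.
    """

    window_start: float
    vo2_lung: float
    vco2_lung: float
    vo2_ecmo: float
    vco2_ecmo: float
    window_length: float = 180.0

    def __post_init__(self) -> None:
        if self.window_length <= 0:
            raise ValueError("window_length must be > 0")
        for name in ("vo2_lung", "vco2_lung", "vo2_ecmo", "vco2_ecmo"):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise ValueError(f"{name} must be stored as a magnitude, got {v}")


def haldane_outlet_flow(sweep: SweepGasSetting, exhaust: ExhaustFractions) -> float:
    """Oxygenator outlet gas flow, L/min, from nitrogen conservation."""
    n2_fraction_out = 1.0 - exhaust.f_pe_o2 - exhaust.f_pe_co2
    if n2_fraction_out <= MIN_N2_FRACTION:
        raise ValueError(
            "nitrogen fraction too small for Haldane transformation "
            f"(1 - F_PE_O2 - F_PE_CO2 = {n2_fraction_out:.3f} <= {MIN_N2_FRACTION})"
        )
    n2_inflow = sweep.air_inflow * sweep.n2_fraction_of_air
    return n2_inflow / n2_fraction_out


def ecmo_exhaust_exchange(
    sweep: SweepGasSetting, exhaust: ExhaustFractions
) -> tuple[float, float]:
    """Membrane-lung (vo2, vco2) in mL/min from sweep settings and exhaust.

    Inlet CO2 fraction is taken as zero (fresh gas).  Outlet flow comes
    from :func:`haldane_outlet_flow`; O2 uptake is inflow minus outflow of
    oxygen, CO2 elimination is the exhaust CO2 transport.  Magnitudes are
    returned.
    """
    q_out = haldane_outlet_flow(sweep, exhaust)
    vco2 = q_out * exhaust.f_pe_co2 * 1000.0
    vo2 = sweep.o2_inflow_total * 1000.0 - q_out * exhaust.f_pe_o2 * 1000.0
    return abs(vo2), abs(vco2)


def _resample_pair(a: Waveform, b: Waveform) -> tuple[np.ndarray, np.ndarray, float]:
    """Linearly interpolate both signals onto the overlapping time base at
    the higher of the two sample rates."""
    rate = max(a.sample_rate, b.sample_rate)
    t0 = max(a.start_time, b.start_time)
    t1 = min(a.times[-1], b.times[-1])
    if t1 <= t0:
        raise ValueError("waveforms do not overlap in time")
    t = np.arange(t0, t1 + 0.5 / rate, 1.0 / rate)
    va = np.interp(t, a.times, a.values)
    vb = np.interp(t, b.times, b.values)
    return va, vb, rate


def _count_breaths(flow: np.ndarray) -> int:
    """Count expiration onsets with +/- 0.1 L/min hysteresis on the flow
    signal (positive = expiration)."""
    state = 0  # +1 expiration, -1 inspiration
    onsets = 0
    for v in flow:
        if state <= 0 and v > FLOW_HYSTERESIS:
            if state == -1:
                onsets += 1
            state = 1
        elif state >= 0 and v < -FLOW_HYSTERESIS:
            state = -1
    return onsets


def integrate_breath_vco2(flow: Waveform, co2_fraction: Waveform) -> float:
    """CO2 elimination over the window, mL/min, positive.

    Mean of instantaneous transport flow * F_CO2 (expiratory positive),
    i.e. expiratory minus inspiratory CO2 transport.
    """
    f, c, _ = _resample_pair(flow, co2_fraction)
    if _count_breaths(f) < 1:
        raise ValueError("window shorter than one breath")
    return float(np.mean(f * c) * 1000.0)


def integrate_breath_vo2(flow: Waveform, o2_fraction_aligned: Waveform) -> float:
    """O2 uptake over the window, mL/min, positive.

    Net inspired-minus-expired O2 transport; the O2 trace must already be
    delay-corrected against the flow/CO2 time base.
    """
    f, o, _ = _resample_pair(flow, o2_fraction_aligned)
    if _count_breaths(f) < 1:
        raise ValueError("window shorter than one breath")
    return float(-np.mean(f * o) * 1000.0)


def estimate_sidestream_delay(
    mainstream_co2: Waveform,
    sidestream_o2: Waveform,
    max_lag_s: float = 5.0,
) -> float:
    """Transport delay of the side-stream O2 signal, seconds.

    The O2 trace is inverted (respiratory O2 and CO2 modulate in
    antiphase) and cross-correlated with the mainstream CO2 trace over
    lags 0..max_lag_s; resolution is one sample of the common time base.
    """
    c, o, rate = _resample_pair(mainstream_co2, sidestream_o2)
    if np.std(c) < 1e-12 or np.std(o) < 1e-12:
        raise ValueError("no respiratory modulation")
    if _count_breaths_fraction(c, rate) < 5:
        raise ValueError("waveforms must cover at least 5 breaths")
    cz = (c - c.mean()) / c.std()
    oz = -(o - o.mean()) / o.std()
    max_lag = int(round(max_lag_s * rate))
    best_lag, best_corr = 0, -np.inf
    for lag in range(0, max_lag + 1):
        n = cz.size - lag
        if n < 2:
            break
        corr = float(np.dot(cz[:n], oz[lag:]) / n)
        if corr > best_corr:
            best_corr, best_lag = corr, lag
    return best_lag / rate


def _count_breaths_fraction(fraction: np.ndarray, rate: float) -> int:
    """Count modulation cycles of a fraction trace (threshold at midrange)."""
    mid = 0.5 * (fraction.max() + fraction.min())
    above = fraction > mid
    rises = np.count_nonzero(~above[:-1] & above[1:])
    return int(rises)


def window_average(
    timestamps,
    rates,
    window_length: float = 180.0,
    start: float | None = None,
):
    """Average per-breath rates into consecutive windows.

    Parameters
    ----------
    timestamps, rates : array-like
        Breath-start times (s) and per-breath rates (mL/min).
    window_length : float
        Window width, s (default 180).
    start : float, optional
        First window start; defaults to the first timestamp.

    Returns
    -------
    list of (window_start, mean_rate, n_breaths)
        ``mean_rate`` is NaN for a window containing no breaths (flagged
        missing rather than zero).
    """
    if window_length <= 0:
        raise ValueError("window_length must be > 0")
    t = np.asarray(timestamps, dtype=float)
    r = np.asarray(rates, dtype=float)
    if t.size == 0:
        return []
    t0 = float(t.min()) if start is None else float(start)
    t_end = float(t.max())
    out = []
    w = t0
    while w <= t_end:
        mask = (t >= w) & (t < w + window_length)
        n = int(mask.sum())
        mean = float(r[mask].mean()) if n else float("nan")
        out.append((w, mean, n))
        w += window_length
    return out
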