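"""Steady-state circuit simulator: two gas exchangers on one venous return.

The model reproduces the experimental situation the estimator assumes: a
body producing CO2 and consuming O2 at fixed rates, total cardiac output
``q_total`` split between an ECMO circuit (``q_ecmo``, membrane lung run
at V/Q = 1, FdO2 0.6) and the native lung (``q_lung = q_total - q_ecmo``,
with configurable shunt fraction, occluded-perfusion fraction and
ventilator V/Q).  The solver iterates arterial contents to the fixed
point of:

(i)   systemic consumption: mixed venous content = arterial content
      -/+ 100 * Vdot_body / q_total (mL/dL, flows in mL/min);
(ii)  venous return split with an optional O2-content offset
      (``venous_streaming_delta`` = PA minus RA content) applied
      mass-conservingly about the flow-weighted mean;
(iii) native lung: a shunt fraction bypasses exchange; the exchanging
      compartment runs at effective V/Q = lung_vq / (1 - occl) — balloon
      occlusion removes perfusion from ventilated units, raising the
      effective V/Q seen by the exchanging blood;
(iv)  membrane lung: complete oxygenation below rated flow; CO2 removal
      anchored at V/Q = 1 by an equilibration factor (outlet PCO2 = k_eq
      * inlet PCO2) and scaled across V/Q by the same V(x) model the
      normalization inverts: V(x) = V1 * x * (1 + c) / (x + c);
(v)   aortic blood is the flow-weighted mix of lung and ECMO outflow.

Gas-side signals (sweep blend, exhaust fractions, lung FI/FE and minute
ventilation) are generated consistently with the blood-side exchange, so
the gas-phase estimators are exact on noiseless data.  Measurement noise
follows the quoted device accuracies (capnograph: +/-2 mmHg below 41
mmHg, +/-5% of reading above; side-stream module: +/-(0.2 vol% + 2%) for
CO2 and +/-(1 vol% + 2%) for O2), with accuracy bounds interpreted as
95% intervals (SD = bound / 1.96).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .blood import (
    BloodGasSample,
    co2_content,
    o2_content,
    po2_from_so2,
    so2_from_po2,
)
from .fick import normalization_constant
from .gas import ExhaustFractions, SweepGasSetting, Waveform, WindowedExchange

__all__ = [
    "CircuitConfig",
    "CircuitTruth",
    "MeasurementRecord",
    "NoiseModel",
    "PhaseSpec",
    "Period",
    "ProtocolDataset",
    "solve_steady_state",
    "apply_measurement_noise",
    "run_protocol",
    "default_phases",
    "synthesize_waveforms",
    "DEFAULT_LADDER",
]

#: ECMO blood-flow ladder of the experimental protocol, mL/min (4 -> 1
#: L/min in 1-L/min steps).
DEFAULT_LADDER = (4000.0, 3000.0, 2000.0, 1000.0)

#: Barometric minus water-vapor pressure at 37 C, mmHg.
DRY_PRESSURE = 713.0


@dataclass
class CircuitConfig:
    """Physiological and circuit parameters of one simulated state.

    Defaults are the study conditions: a ~45 kg pig (VO2 200 mL/min, VCO2
    160 mL/min at respiratory exchange ratio 0.8, Hb 9 g/dL, porcine ODC
    P50 35 mmHg), total cardiac output 5 L/min, membrane lung at V/Q = 1
    with FdO2 0.6.
    """

    vo2_body: float = 200.0  # mL/min
    vco2_body: float = 160.0  # mL/min
    q_total: float = 5000.0  # mL/min
    q_ecmo: float = 2500.0  # mL/min
    shunt_fraction: float = 0.0
    occluded_perfusion_fraction: float = 0.0
    lung_vq: float = 1.0
    venous_streaming_delta: float = 0.0  # mL O2/dL, PA minus RA
    fd_o2: float = 0.6
    fio2_lung: float = 0.6
    sweep_equals_q_ecmo: bool = True
    sweep_flow: float | None = None  # mL/min; used when the flag is False
    hb: float = 9.0  # g/dL
    p50: float = 35.0  # mmHg
    hill_n: float = 2.8
    membrane_k_eq: float = 0.87  # outlet/inlet PCO2 at V/Q = 1
    lung_k_eq: float = 0.87
    alveolar_po2_gradient: float = 40.0  # mmHg, FiO2*713 - PCO2 - gradient
    rated_flow: float = 5000.0  # mL/min, complete oxygenation below this
    temperature: float = 37.0  # C
    noise_enabled: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vo2_body <= 0 or self.vco2_body <= 0:
            raise ValueError("vo2_body and vco2_body must be > 0")
        if not 0 < self.q_ecmo <= self.q_total:
            raise ValueError("require 0 < q_ecmo <= q_total")
        for name in ("shunt_fraction", "occluded_perfusion_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.lung_vq <= 0:
            raise ValueError("lung_vq must be > 0")
        if not 0.0 < self.fd_o2 <= 1.0 or not 0.0 < self.fio2_lung <= 1.0:
            raise ValueError("oxygen fractions must be in (0, 1]")
        if self.hb <= 0 or self.p50 <= 0 or self.hill_n <= 0:
            raise ValueError("hb, p50 and hill_n must be > 0")
        if not 0.0 < self.membrane_k_eq <= 1.0 or not 0.0 < self.lung_k_eq <= 1.0:
            raise ValueError("equilibration factors must be in (0, 1]")

    @property
    def q_lung(self) -> float:
        return self.q_total - self.q_ecmo

    @property
    def sweep(self) -> float:
        """Sweep gas flow, mL/min."""
        if self.sweep_equals_q_ecmo:
            return self.q_ecmo
        if self.sweep_flow is None:
            raise ValueError("sweep_flow required when sweep_equals_q_ecmo is False")
        return self.sweep_flow


@dataclass
class CircuitTruth:
    """Ground truth of one converged steady state."""

    samples: dict[str, BloodGasSample]
    q_lung: float
    q_ecmo: float
    vo2_lung: float
    vo2_ecmo: float
    vco2_lung: float
    vco2_ecmo: float
    lung_vq_actual: float
    minute_ventilation: float  # lung, mL/min
    fi_o2: float
    fe_o2: float
    fe_co2: float
    sweep: SweepGasSetting
    exhaust: ExhaustFractions
    n_iter: int
    config: CircuitConfig

    @property
    def vo2_total(self) -> float:
        return self.vo2_lung + self.vo2_ecmo

    @property
    def vco2_total(self) -> float:
        return self.vco2_lung + self.vco2_ecmo

    @property
    def q_total(self) -> float:
        return self.q_lung + self.q_ecmo


@dataclass
class NoiseModel:
    """Device noise standard deviations.

    Blood gas analyzer SDs are direct; gas analyzers quote accuracy
    bounds, interpreted as 95% intervals (SD = bound / 1.96).
    """

    po2_sd: float = 2.0  # mmHg
    pco2_sd: float = 1.0  # mmHg
    so2_sd: float = 0.5  # % sat
    hb_sd: float = 0.2  # g/dL

    @staticmethod
    def capnostat_sd(pco2: float | np.ndarray):
        """Mainstream capnograph SD at a given PCO2 reading, mmHg:
        +/-2 mmHg below 41 mmHg, +/-5% of the reading above."""
        bound = np.where(np.asarray(pco2, dtype=float) < 41.0, 2.0, 0.05 * pco2)
        return bound / 1.96

    @staticmethod
    def sidestream_co2_sd(fraction: float | np.ndarray):
        """Side-stream module CO2 fraction SD: +/-(0.2 vol% + 2% of reading)."""
        return (0.002 + 0.02 * np.asarray(fraction, dtype=float)) / 1.96

    @staticmethod
    def sidestream_o2_sd(fraction: float | np.ndarray):
        """Side-stream module O2 fraction SD: +/-(1 vol% + 2% of reading)."""
        return (0.01 + 0.02 * np.asarray(fraction, dtype=float)) / 1.96


@dataclass
class MeasurementRecord:
    """What the devices report for one window (noisy unless disabled)."""

    samples: dict[str, BloodGasSample]
    q_ecmo: float
    q_lung_ref: float
    sweep: SweepGasSetting
    exhaust: ExhaustFractions
    fi_o2: float
    fe_o2: float
    fe_co2: float
    minute_ventilation: float
    window: WindowedExchange


def _ph_of_pco2(pco2: float) -> float:
    """Acute respiratory pH as a log-linear function of PCO2 around
    7.40 at 40 mmHg (constant buffer base)."""
    p = max(pco2, 1.0)
    return float(np.clip(7.4 - 0.65 * math.log10(p / 40.0), 6.5, 8.0))


def _sample_from_contents(
    site: str, c_o2: float, c_co2: float, cfg: CircuitConfig
) -> BloodGasSample:
    """Invert the dissociation models: contents -> (PO2, SO2, PCO2, pH)."""
    hb, t = cfg.hb, cfg.temperature

    def o2_resid(po2: float) -> float:
        return o2_content(hb, so2_from_po2(po2, cfg.p50, cfg.hill_n), po2) - c_o2

    if c_o2 <= 0:
        po2, so2 = 0.0, 0.0
    else:
        hi = 1500.0
        if o2_resid(hi) < 0:  # content above model ceiling: pin to ceiling
            po2 = hi
        else:
            po2 = brentq(o2_resid, 1e-9, hi, xtol=1e-10)
        so2 = so2_from_po2(po2, cfg.p50, cfg.hill_n)

    def co2_resid(p: float) -> float:
        return co2_content(p, _ph_of_pco2(p), hb, so2, t) - c_co2

    if c_co2 <= 0:
        pco2 = 0.0
    else:
        hi = 400.0
        if co2_resid(hi) < 0:
            pco2 = hi
        else:
            pco2 = brentq(co2_resid, 1e-6, hi, xtol=1e-10)
    ph = _ph_of_pco2(pco2) if pco2 > 0 else 7.4
    return BloodGasSample(
        site=site, po2=po2, pco2=pco2, so2=so2, hb=hb, ph=ph, temperature=t
    )


def _co2_exchange(
    inlet_pco2: float,
    inlet_ph: float,
    c_in: float,
    q_blood: float,
    x_vq: float,
    k_eq: float,
    cfg: CircuitConfig,
) -> float:
    """CO2 elimination of one exchanger, mL/min.

    Anchored at V/Q = 1 by outlet PCO2 = k_eq * inlet PCO2 (outlet blood
    fully oxygenated, so outlet content uses SO2 = 100), then scaled by
    V(x) = V1 * x (1 + c) / (x + c) with c from the inlet sample.
    """
    p_out_unity = k_eq * inlet_pco2
    c_out_unity = co2_content(
        p_out_unity, _ph_of_pco2(p_out_unity), cfg.hb, 100.0, cfg.temperature
    )
    v1 = max(q_blood * (c_in - c_out_unity) / 100.0, 0.0)
    venous = BloodGasSample(
        site="RA", po2=40.0, pco2=max(inlet_pco2, 1.0), so2=70.0, hb=cfg.hb,
        ph=inlet_ph, temperature=cfg.temperature,
    )
    c_norm = normalization_constant(venous).c
    v = v1 * x_vq * (1.0 + c_norm) / (x_vq + c_norm)
    # cannot remove more CO2 than the blood delivers
    return min(v, 0.95 * q_blood * c_in / 100.0)


def _o2_exchange(
    c_in: float, q_blood: float, fio2: float, pco2_out: float, cfg: CircuitConfig
) -> tuple[float, float]:
    """O2 uptake (mL/min) and outlet content of one exchanger.

    Complete oxygenation (SO2 100%) below rated flow, with outlet PO2 set
    by the alveolar-style relation FiO2 * 713 - PCO2 - gradient; above
    rated flow the outlet saturation declines linearly.
    """
    if q_blood <= cfg.rated_flow:
        so2_out = 100.0
    else:
        so2_out = max(60.0, 100.0 - 40.0 * (q_blood / cfg.rated_flow - 1.0))
    if so2_out >= 99.999:
        po2_out = max(fio2 * DRY_PRESSURE - pco2_out - cfg.alveolar_po2_gradient, 60.0)
    else:
        po2_out = po2_from_so2(so2_out, cfg.p50, cfg.hill_n)
    c_out = o2_content(cfg.hb, so2_out, po2_out)
    if c_out <= c_in:  # no reverse transfer through the membrane/alveoli
        return 0.0, c_in
    return q_blood * (c_out - c_in) / 100.0, c_out


def solve_steady_state(
    config: CircuitConfig, tol: float = 1e-8, max_iter: int = 10_000
) -> CircuitTruth:
    """Fixed-point solve of the two-exchanger circuit.

    Iterates arterial O2/CO2 contents until successive iterates change by
    less than ``tol`` mL/dL; raises with diagnostics on non-convergence.
    """
    cfg = config
    q_lung, q_ecmo, q_total = cfg.q_lung, cfg.q_ecmo, cfg.q_total
    q_exch = q_lung * (1.0 - cfg.shunt_fraction)
    x_lung = cfg.lung_vq / (1.0 - cfg.occluded_perfusion_fraction)
    x_ecmo = cfg.sweep / q_ecmo

    # initial guess: saturated arterial blood at PCO2 40
    c_ao_o2 = o2_content(cfg.hb, 98.0, 150.0)
    c_ao_co2 = co2_content(40.0, 7.4, cfg.hb, 98.0, cfg.temperature)

    for it in range(1, max_iter + 1):
        cv_o2 = c_ao_o2 - 100.0 * cfg.vo2_body / q_total
        cv_co2 = c_ao_co2 + 100.0 * cfg.vco2_body / q_total
        if cv_o2 <= 0:
            raise RuntimeError(
                "circuit cannot sustain vo2_body: mixed venous O2 content "
                f"fell to {cv_o2:.2f} mL/dL (iteration {it})"
            )
        # venous streaming: offset PA vs RA about the flow-weighted mean
        d = cfg.venous_streaming_delta
        c_pa_o2 = cv_o2 + q_ecmo / q_total * d
        c_ra_o2 = cv_o2 - q_lung / q_total * d
        c_pa_co2 = c_ra_co2 = cv_co2

        pa = _sample_from_contents("PA", c_pa_o2, c_pa_co2, cfg)
        ra = _sample_from_contents("RA", c_ra_o2, c_ra_co2, cfg)

        # membrane lung
        vco2_e = _co2_exchange(
            ra.pco2, ra.ph, c_ra_co2, q_ecmo, x_ecmo, cfg.membrane_k_eq, cfg
        )
        c_pe_co2 = c_ra_co2 - 100.0 * vco2_e / q_ecmo
        pco2_pe = cfg.membrane_k_eq * ra.pco2 if x_ecmo == 1.0 else None
        vo2_e, c_pe_o2 = _o2_exchange(
            c_ra_o2, q_ecmo, cfg.fd_o2,
            pco2_pe if pco2_pe is not None else ra.pco2 * cfg.membrane_k_eq, cfg,
        )

        # native lung exchanging compartment
        if q_exch > 0:
            vco2_x = _co2_exchange(
                pa.pco2, pa.ph, c_pa_co2, q_exch, x_lung, cfg.lung_k_eq, cfg
            )
            c_xout_co2 = c_pa_co2 - 100.0 * vco2_x / q_exch
            vo2_x, c_xout_o2 = _o2_exchange(
                c_pa_o2, q_exch, cfg.fio2_lung, cfg.lung_k_eq * pa.pco2, cfg
            )
        else:
            vco2_x, vo2_x = 0.0, 0.0
            c_xout_co2, c_xout_o2 = c_pa_co2, c_pa_o2

        # shunted blood rejoins unchanged at the left atrium
        if q_lung > 0:
            c_la_o2 = (q_exch * c_xout_o2 + (q_lung - q_exch) * c_pa_o2) / q_lung
            c_la_co2 = (q_exch * c_xout_co2 + (q_lung - q_exch) * c_pa_co2) / q_lung
        else:
            c_la_o2, c_la_co2 = c_pa_o2, c_pa_co2

        new_ao_o2 = (q_lung * c_la_o2 + q_ecmo * c_pe_o2) / q_total
        new_ao_co2 = (q_lung * c_la_co2 + q_ecmo * c_pe_co2) / q_total
        delta = max(abs(new_ao_o2 - c_ao_o2), abs(new_ao_co2 - c_ao_co2))
        c_ao_o2, c_ao_co2 = new_ao_o2, new_ao_co2
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"steady state not converged in {max_iter} iterations "
            f"(last content change {delta:.3e} mL/dL, "
            f"c_ao_o2={c_ao_o2:.3f}, c_ao_co2={c_ao_co2:.3f})"
        )

    vo2_lung, vco2_lung = vo2_x, vco2_x

    la = _sample_from_contents("LA", c_la_o2, c_la_co2, cfg)
    pe = _sample_from_contents("PE", c_pe_o2, c_pe_co2, cfg)
    ao = _sample_from_contents("AO", c_ao_o2, c_ao_co2, cfg)

    # gas-side signals, consistent with the blood-side exchange
    minute_ventilation = x_lung * q_lung  # mL/min
    fi_o2 = cfg.fio2_lung
    fe_o2 = fi_o2 - (vo2_lung / minute_ventilation if minute_ventilation else 0.0)
    fe_co2 = vco2_lung / minute_ventilation if minute_ventilation else 0.0

    sweep_l = cfg.sweep / 1000.0  # L/min
    air = sweep_l * (1.0 - cfg.fd_o2) / 0.79
    o2_line = sweep_l - air
    sweep = SweepGasSetting(air_inflow=air, o2_inflow=o2_line)
    o2_out = sweep_l * cfg.fd_o2 - vo2_e / 1000.0
    co2_out = vco2_e / 1000.0
    n2_out = sweep_l * (1.0 - cfg.fd_o2)
    q_out = o2_out + co2_out + n2_out
    exhaust = ExhaustFractions(f_pe_o2=o2_out / q_out, f_pe_co2=co2_out / q_out)

    return CircuitTruth(
        samples={"PA": pa, "LA": la, "RA": ra, "PE": pe, "AO": ao},
        q_lung=q_lung,
        q_ecmo=q_ecmo,
        vo2_lung=vo2_lung,
        vo2_ecmo=vo2_e,
        vco2_lung=vco2_lung,
        vco2_ecmo=vco2_e,
        lung_vq_actual=x_lung,
        minute_ventilation=minute_ventilation,
        fi_o2=fi_o2,
        fe_o2=fe_o2,
        fe_co2=fe_co2,
        sweep=sweep,
        exhaust=exhaust,
        n_iter=it,
        config=cfg,
    )


def apply_measurement_noise(
    truth: CircuitTruth,
    rng: np.random.Generator | int | None = None,
    noise: NoiseModel | None = None,
    window_start: float = 0.0,
) -> MeasurementRecord:
    """Turn a ground truth into a device measurement record.

    With ``noise_enabled`` False in the config the record equals the
    truth.  Noise is zero-mean Gaussian at the device SDs, deterministic
    per seed.  Saturations are clipped to [0, 100] and pressures to >= 0.
    """
    cfg = truth.config
    noise = noise or NoiseModel()
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(cfg.seed if rng is None else rng)

    if not cfg.noise_enabled:
        samples = dict(truth.samples)
        exhaust = truth.exhaust
        fe_o2, fe_co2 = truth.fe_o2, truth.fe_co2
    else:
        samples = {}
        for site, s in truth.samples.items():
            samples[site] = BloodGasSample(
                site=site,
                po2=max(s.po2 + rng.normal(0.0, noise.po2_sd), 0.0),
                pco2=max(s.pco2 + rng.normal(0.0, noise.pco2_sd), 0.0),
                so2=float(np.clip(s.so2 + rng.normal(0.0, noise.so2_sd), 0.0, 100.0)),
                hb=max(s.hb + rng.normal(0.0, noise.hb_sd), 0.0),
                ph=s.ph,
                temperature=s.temperature,
            )
        f_o2 = float(np.clip(
            truth.exhaust.f_pe_o2
            + rng.normal(0.0, NoiseModel.sidestream_o2_sd(truth.exhaust.f_pe_o2)),
            0.0, 0.98,
        ))
        f_co2 = float(np.clip(
            truth.exhaust.f_pe_co2
            + rng.normal(0.0, NoiseModel.sidestream_co2_sd(truth.exhaust.f_pe_co2)),
            0.0, 0.98 - f_o2,
        ))
        exhaust = ExhaustFractions(f_pe_o2=f_o2, f_pe_co2=f_co2)
        # lung expired CO2 via the mainstream capnograph (pressure domain)
        p_fe_co2 = truth.fe_co2 * DRY_PRESSURE
        p_noisy = max(p_fe_co2 + rng.normal(0.0, float(NoiseModel.capnostat_sd(p_fe_co2))), 0.0)
        fe_co2 = p_noisy / DRY_PRESSURE
        # lung expired O2 via the side-stream module
        fe_o2 = float(np.clip(
            truth.fe_o2 + rng.normal(0.0, float(NoiseModel.sidestream_o2_sd(truth.fe_o2))),
            0.0, 1.0,
        ))

    vo2_ecmo, vco2_ecmo = _exhaust_rates(truth.sweep, exhaust)
    vo2_lung = truth.minute_ventilation * (truth.fi_o2 - fe_o2)
    vco2_lung = truth.minute_ventilation * fe_co2
    window = WindowedExchange(
        window_start=window_start,
        vo2_lung=abs(vo2_lung),
        vco2_lung=abs(vco2_lung),
        vo2_ecmo=vo2_ecmo,
        vco2_ecmo=vco2_ecmo,
    )
    return MeasurementRecord(
        samples=samples,
        q_ecmo=truth.q_ecmo,
        q_lung_ref=truth.q_lung,
        sweep=truth.sweep,
        exhaust=exhaust,
        fi_o2=truth.fi_o2,
        fe_o2=fe_o2,
        fe_co2=fe_co2,
        minute_ventilation=truth.minute_ventilation,
        window=window,
    )


def _exhaust_rates(sweep: SweepGasSetting, exhaust: ExhaustFractions):
    from .gas import ecmo_exhaust_exchange

    return ecmo_exhaust_exchange(sweep, exhaust)


@dataclass(frozen=True)
class PhaseSpec:
    """One experimental phase: condition plus its lung settings."""

    label: str
    condition: str  # "baseline" | "shunt" | "deadspace"
    lung_vq: float
    shunt_fraction: float = 0.0
    occluded_perfusion_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.condition not in ("baseline", "shunt", "deadspace"):
            raise ValueError(f"unknown condition {self.condition!r}")


def default_phases() -> list[PhaseSpec]:
    """The six phases of the protocol: baseline, shunt and dead space,
    each repeated twice with different ventilator V/Q settings."""
    return [
        PhaseSpec("baseline_1", "baseline", lung_vq=1.0),
        PhaseSpec("baseline_2", "baseline", lung_vq=1.5),
        PhaseSpec("shunt_1", "shunt", lung_vq=0.5, shunt_fraction=0.3),
        PhaseSpec("shunt_2", "shunt", lung_vq=0.7, shunt_fraction=0.3),
        PhaseSpec("deadspace_1", "deadspace", lung_vq=1.0,
                  occluded_perfusion_fraction=0.3),
        PhaseSpec("deadspace_2", "deadspace", lung_vq=1.5,
                  occluded_perfusion_fraction=0.3),
    ]


@dataclass
class Period:
    """One measurement period: a phase at one ladder step."""

    animal: int
    phase: str
    condition: str
    step: int
    window_start: float
    truth: CircuitTruth
    record: MeasurementRecord


@dataclass
class ProtocolDataset:
    """All measurement periods of one simulated run."""

    periods: list[Period]
    config: CircuitConfig
    seed: int

    def __len__(self) -> int:
        return len(self.periods)

    def periods_frame(self):
        """Wide per-period DataFrame (one row per measurement window)."""
        import pandas as pd

        rows = []
        for p in self.periods:
            row = {
                "animal": p.animal,
                "phase": p.phase,
                "condition": p.condition,
                "step": p.step,
                "window_start_s": p.window_start,
                "q_ecmo_ml_min": p.record.q_ecmo,
                "q_lung_ref_ml_min": p.record.q_lung_ref,
                "air_inflow_l_min": p.record.sweep.air_inflow,
                "o2_inflow_l_min": p.record.sweep.o2_inflow,
                "f_pe_o2": p.record.exhaust.f_pe_o2,
                "f_pe_co2": p.record.exhaust.f_pe_co2,
                "fi_o2": p.record.fi_o2,
                "fe_o2": p.record.fe_o2,
                "fe_co2": p.record.fe_co2,
                "minute_ventilation_ml_min": p.record.minute_ventilation,
                "vo2_lung_gas_ml_min": p.record.window.vo2_lung,
                "vco2_lung_gas_ml_min": p.record.window.vco2_lung,
            }
            for site, s in p.record.samples.items():
                row.update({
                    f"po2_{site}": s.po2, f"pco2_{site}": s.pco2,
                    f"so2_{site}": s.so2, f"hb_{site}": s.hb,
                    f"ph_{site}": s.ph, f"temp_{site}": s.temperature,
                })
            rows.append(row)
        return pd.DataFrame(rows)

    def truth_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "animal": p.animal,
                "phase": p.phase,
                "condition": p.condition,
                "step": p.step,
                "window_start_s": p.window_start,
                "q_lung_ml_min": p.truth.q_lung,
                "q_ecmo_ml_min": p.truth.q_ecmo,
                "vo2_lung_ml_min": p.truth.vo2_lung,
                "vo2_ecmo_ml_min": p.truth.vo2_ecmo,
                "vco2_lung_ml_min": p.truth.vco2_lung,
                "vco2_ecmo_ml_min": p.truth.vco2_ecmo,
                "lung_vq": p.truth.lung_vq_actual,
            }
            for p in self.periods
        )


def run_protocol(
    config: CircuitConfig,
    phases: list[PhaseSpec] | None = None,
    ladder: tuple[float, ...] = DEFAULT_LADDER,
    animal: int = 0,
    rng: np.random.Generator | None = None,
) -> ProtocolDataset:
    """Simulate the full protocol: each phase over the ECMO-flow ladder.

    Total cardiac output is held constant across ladder steps, so each
    1 L/min ECMO reduction raises true pulmonary blood flow by exactly
    1 L/min.  One truth + measurement record is produced per (phase,
    step); the random stream is seeded from ``config.seed`` for
    byte-identical re-runs.
    """
    phases = default_phases() if phases is None else phases
    for q in ladder:
        if q > config.q_total:
            raise ValueError(f"ladder value {q} exceeds q_total {config.q_total}")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    periods: list[Period] = []
    t = 0.0
    for spec in phases:
        for step, q_ecmo in enumerate(ladder):
            cfg = replace(
                config,
                q_ecmo=q_ecmo,
                lung_vq=spec.lung_vq,
                shunt_fraction=spec.shunt_fraction,
                occluded_perfusion_fraction=spec.occluded_perfusion_fraction,
            )
            truth = solve_steady_state(cfg)
            record = apply_measurement_noise(truth, rng=rng, window_start=t)
            periods.append(
                Period(
                    animal=animal,
                    phase=spec.label,
                    condition=spec.condition,
                    step=step,
                    window_start=t,
                    truth=truth,
                    record=record,
                )
            )
            t += 480.0  # 5 min stabilization + 3 min measurement
    return ProtocolDataset(periods=periods, config=config, seed=config.seed)


def synthesize_waveforms(
    truth: CircuitTruth,
    breath_rate: float = 15.0,
    sample_rate: float = 50.0,
    i_to_e: float = 1.0 / 1.6,
    o2_delay_s: float = 0.0,
    duration_s: float = 180.0,
) -> dict[str, Waveform]:
    """Ventilator-style waveforms whose integrated transports equal the
    truth's lung VO2/VCO2.

    Square-wave breaths (constant inspiratory and expiratory flow, I:E =
    1:1.6), minute ventilation equal to the truth's; the expired CO2 and
    O2 plateau fractions are fitted to the discrete flow trace so the
    breath integrators recover the configured rates exactly up to
    resampling.  The side-stream O2 trace is optionally delayed.
    """
    if breath_rate <= 0 or sample_rate <= 0 or duration_s <= 0:
        raise ValueError("breath_rate, sample_rate and duration_s must be > 0")
    period = 60.0 / breath_rate
    ti = period * i_to_e / (1.0 + i_to_e)
    te = period - ti
    mv_l = truth.minute_ventilation / 1000.0  # L/min
    vt = mv_l / breath_rate  # L per breath
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    phase = np.mod(t, period)
    exp_mask = phase < te  # expiration first, then inspiration
    flow = np.where(exp_mask, vt * 60.0 / te, -vt * 60.0 / ti)

    mean_exp = float(np.mean(flow * exp_mask))  # L/min, positive
    mean_insp = float(np.mean(flow * (~exp_mask)))  # negative
    if mean_exp <= 0:
        fco2_e, fe_o2 = 0.0, truth.fi_o2
    else:
        fco2_e = truth.vco2_lung / 1000.0 / mean_exp
        # choose FE so that -mean(flow * fo2) * 1000 == vo2_lung exactly
        fe_o2 = (-truth.vo2_lung / 1000.0 - mean_insp * truth.fi_o2) / mean_exp
    fco2 = np.where(exp_mask, np.clip(fco2_e, 0.0, 1.0), 0.0)
    fo2 = np.where(exp_mask, np.clip(fe_o2, 0.0, 1.0), truth.fi_o2)

    lag = int(round(o2_delay_s * sample_rate))
    if lag > 0:
        fo2 = np.concatenate([np.full(lag, fo2[0]), fo2[:-lag]])

    return {
        "flow": Waveform(0.0, sample_rate, flow),
        "co2": Waveform(0.0, sample_rate, fco2, is_fraction=True),
        "o2": Waveform(0.0, sample_rate, fo2, is_fraction=True),
    }
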