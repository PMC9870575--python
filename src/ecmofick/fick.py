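"""Modified Fick estimation of native pulmonary blood flow on V-A ECMO.

At steady state the body's gas exchange is carried by two competing
exchangers — the native lung and the membrane lung — fed from one venous
return.  Mass balance over the two circuits,

    Q_total * dC(v-AO) = Q_lung * dC(v-LA) + Q_ecmo * dC(v-PE),

together with Q_total = Q_lung + Q_ecmo, makes the ratio of exchange
rates equal the ratio of blood flows:

    Q_lung = Q_ecmo * |Vdot_lung| / |Vdot_ecmo|

where Vdot is VO2 or VCO2 measured either in blood (content difference x
measured flow) or in the gas phase.  CO2 elimination additionally depends
on the ventilation/perfusion ratio; the lung-side VCO2 is therefore
normalized toward V/Q = 1 before taking the ratio (the membrane lung is
run at V/Q = 1 by protocol and is not normalized):

    f(x) = (x + c) / ((1 + c) * x),   x = V/Q at the lung,

with c = sigma_CO2 * R * T * (1 + Kc), Kc = 10^(pH - pK'), evaluated on a
venous blood gas sample.  The lung V/Q itself comes from the O2 mass
balance  V/Q = (caO2 - cvO2) / (FIO2 - FEO2)  with contents in mL/mL.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

from .blood import BloodGasSample
from .gas import WindowedExchange

__all__ = [
    "Method",
    "ContentDifference",
    "ExchangeRates",
    "NormalizationParams",
    "FlowEstimate",
    "qlung_from_contents",
    "qlung_from_exchange",
    "normalization_constant",
    "normalize_vco2",
    "vq_lung",
    "estimate_all_methods",
    "filter_estimates",
    "MAX_PLAUSIBLE_FLOW",
]

logger = logging.getLogger(__name__)

#: Outlier rule: calculated flows above 10 L/min (or negative) are removed.
MAX_PLAUSIBLE_FLOW = 10_000.0  # mL/min

#: CO2 solubility in plasma at 37 C, mol / (L * mmHg).
SIGMA_CO2 = 3.06e-5
#: Gas constant, L * mmHg / (mol * K).
GAS_CONSTANT_R = 62.36
#: Apparent pK' of the CO2/bicarbonate system.
PK_PRIME = 6.1


class Method(str, Enum):
    """Estimator variants: gas measured, and where it was measured."""

    VO2_BLOOD = "VO2_BLOOD"
    VO2_GAS = "VO2_GAS"
    VCO2_GAS = "VCO2_GAS"
    VCO2_GAS_NORM = "VCO2_GAS_NORM"
    VCO2_BLOOD = "VCO2_BLOOD"


@dataclass(frozen=True)
class ContentDifference:
    """Venous-minus-site blood content difference, mL/dL.

    ``path`` identifies the circuit: V_AO (systemic/total), V_LA (native
    lung), V_PE (membrane lung).
    """

    path: str  # "V_AO" | "V_LA" | "V_PE"
    gas: str  # "O2" | "CO2"
    delta: float

    def __post_init__(self) -> None:
        if self.path not in ("V_AO", "V_LA", "V_PE"):
            raise ValueError(f"unknown path {self.path!r}")
        if self.gas not in ("O2", "CO2"):
            raise ValueError(f"unknown gas {self.gas!r}")
        if not math.isfinite(self.delta):
            raise ValueError("content difference must be finite")


@dataclass(frozen=True)
class ExchangeRates:
    """Lung / ECMO / total exchange for one gas in one window, mL/min.

    Magnitudes are stored; ``phase`` records whether the rates came from
    blood contents or gas-phase measurement.
    """

    vdot_lung: float
    vdot_ecmo: float
    gas: str
    phase: str = "gas"  # "blood" | "gas"
    normalized: bool = False
    vdot_total: float | None = None

    def __post_init__(self) -> None:
        if self.gas not in ("O2", "CO2"):
            raise ValueError(f"unknown gas {self.gas!r}")
        if self.phase not in ("blood", "gas"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.vdot_lung < 0 or self.vdot_ecmo < 0:
            raise ValueError("exchange rates are stored as magnitudes")
        if self.vdot_total is None:
            object.__setattr__(self, "vdot_total", self.vdot_lung + self.vdot_ecmo)
        elif abs(self.vdot_total - (self.vdot_lung + self.vdot_ecmo)) > 1e-6:
            raise ValueError("vdot_total inconsistent with lung + ecmo")


@dataclass
class NormalizationParams:
    """Parameters of the V/Q normalization of lung VCO2."""

    c: float
    vq_lung: float = 1.0
    k_c: float = float("nan")
    sigma_co2: float = SIGMA_CO2
    gas_constant_R: float = GAS_CONSTANT_R
    temperature: float = 310.15  # K

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError(f"normalization constant c must be > 0, got {self.c}")
        if self.vq_lung <= 0:
            raise ValueError(f"vq_lung must be > 0, got {self.vq_lung}")


@dataclass
class FlowEstimate:
    """Calculated pulmonary blood flow for one window and one method."""

    q_lung_calc: float  # mL/min; NaN if the method failed on this window
    q_ecmo: float
    method: Method
    reference_q_lung: float | None = None
    condition: str = "baseline"
    vq_lung: float = float("nan")
    window_start: float = float("nan")

    def __post_init__(self) -> None:
        if self.q_ecmo < 0:
            raise ValueError("q_ecmo must be >= 0")
        self.method = Method(self.method)


def _delta(d) -> float:
    return d.delta if isinstance(d, ContentDifference) else float(d)


def qlung_from_contents(q_ecmo: float, d_v_pe, d_v_ao, d_v_la) -> float:
    """Pulmonary blood flow from the three content differences, mL/min.

    ``q_ecmo * (d_v_pe - d_v_ao) / (d_v_ao - d_v_la)`` — the rearranged
    two-exchanger mass balance.  All three differences must refer to the
    same gas.
    """
    gases = {d.gas for d in (d_v_pe, d_v_ao, d_v_la) if isinstance(d, ContentDifference)}
    if len(gases) > 1:
        raise ValueError(f"content differences mix gases: {sorted(gases)}")
    pe, ao, la = _delta(d_v_pe), _delta(d_v_ao), _delta(d_v_la)
    denom = ao - la
    if abs(denom) < 1e-9:
        raise ValueError("degenerate content configuration")
    return q_ecmo * (pe - ao) / denom


def qlung_from_exchange(q_ecmo: float, vdot_lung, vdot_ecmo=None) -> float:
    """Pulmonary blood flow from the lung/ECMO exchange ratio, mL/min.

    Accepts either an :class:`ExchangeRates` or two rates.  Magnitudes are
    used ("production and elimination are mathematical opposites").
    """
    if isinstance(vdot_lung, ExchangeRates):
        rates = vdot_lung
        vl, ve = rates.vdot_lung, rates.vdot_ecmo
    else:
        vl, ve = float(vdot_lung), float(vdot_ecmo)
    if ve == 0:
        raise ValueError("no membrane exchange; ratio undefined")
    return q_ecmo * abs(vl) / abs(ve)


def normalization_constant(
    venous: BloodGasSample,
    sigma_co2: float = SIGMA_CO2,
    gas_constant_R: float = GAS_CONSTANT_R,
    pk_prime: float = PK_PRIME,
) -> NormalizationParams:
    """Normalization constant c from a venous blood gas sample.

    ``c = sigma_CO2 * R * T * (1 + Kc)`` with ``Kc = 10^(pH - pK')``; at
    physiological pH the bicarbonate term dominates (c around 12).
    """
    t_kelvin = venous.temperature + 273.15
    k_c = 10.0 ** (venous.ph - pk_prime)
    c = sigma_co2 * gas_constant_R * t_kelvin * (1.0 + k_c)
    return NormalizationParams(
        c=c,
        k_c=k_c,
        sigma_co2=sigma_co2,
        gas_constant_R=gas_constant_R,
        temperature=t_kelvin,
    )


def normalize_vco2(vco2_measured: float, params: NormalizationParams) -> float:
    """Normalize a lung VCO2 toward V/Q = 1.

    Multiplies by ``f(x) = (x + c) / ((1 + c) * x)``; f(1) = 1, so a lung
    already at V/Q = 1 is untouched.
    """
    x = params.vq_lung
    if x <= 0:
        raise ValueError(f"vq_lung must be > 0, got {x}")
    f = (x + params.c) / ((1.0 + params.c) * x)
    return vco2_measured * f


def vq_lung(fi_o2: float, fe_o2: float, ca_o2: float, cv_o2: float) -> float:
    """Lung ventilation/perfusion ratio from the O2 mass balance.

    ``(ca_o2 - cv_o2) / 100 / (fi_o2 - fe_o2)`` with contents in mL/dL
    (converted to mL/mL); positive for a lung taking up oxygen.
    """
    if fi_o2 == fe_o2:
        raise ValueError("no gas-side extraction; V/Q undefined")
    return ((ca_o2 - cv_o2) / 100.0) / (fi_o2 - fe_o2)


def estimate_all_methods(
    window: WindowedExchange,
    samples: dict[str, BloodGasSample],
    q_ecmo: float,
    q_lung_ref: float | None = None,
    fi_o2: float | None = None,
    fe_o2: float | None = None,
    condition: str = "baseline",
    norm_site: str = "RA",
    pk_prime: float = PK_PRIME,
    pool_hb: bool = True,
) -> list[FlowEstimate]:
    """Run every estimator variant on one measurement window.

    Parameters
    ----------
    window : WindowedExchange
        Gas-phase exchange rates (lung and ECMO sides).
    samples : dict
        Blood gas samples keyed by site; PA/LA/RA/PE are consumed here.
    q_ecmo : float
        ECMO blood flow, mL/min.
    q_lung_ref : float, optional
        Flow-probe pulmonary blood flow, mL/min.  Needed for the
        blood-phase rates (content difference x measured flow) and stored
        as the comparison reference.
    fi_o2, fe_o2 : float, optional
        Inspired and mixed-expired O2 fractions at the native lung, for
        the V/Q estimate feeding the normalization.
    norm_site : str
        Venous site whose sample sets the normalization constant
        (ECMO drainage by default, configurable to PA).
    pool_hb : bool
        Use the mean hemoglobin of the window's samples for all content
        calculations (default).  The five samples are drawn from the same
        circulating blood within minutes, so hemoglobin is physically
        common to them; pooling removes spurious analyzer noise from the
        content differences.

    Returns
    -------
    list of FlowEstimate
        One entry per method; a method whose inputs are missing or
        degenerate yields ``q_lung_calc = NaN`` (failure is isolated per
        method, not per window).
    """
    from .blood import co2_content as _cco2
    from .blood import o2_content as _co2c

    out: list[FlowEstimate] = []

    if pool_hb and samples:
        hb_common = sum(s.hb for s in samples.values()) / len(samples)
    else:
        hb_common = None

    def _o2(s: BloodGasSample) -> float:
        hb = s.hb if hb_common is None else hb_common
        return _co2c(hb, s.so2, s.po2)

    def _c_co2(s: BloodGasSample) -> float:
        hb = s.hb if hb_common is None else hb_common
        return _cco2(s.pco2, s.ph, hb, s.so2, s.temperature)

    def push(method: Method, value: float, vq: float = float("nan")) -> None:
        out.append(
            FlowEstimate(
                q_lung_calc=value,
                q_ecmo=q_ecmo,
                method=method,
                reference_q_lung=q_lung_ref,
                condition=condition,
                vq_lung=vq,
                window_start=window.window_start,
            )
        )

    def attempt(method: Method, fn) -> None:
        try:
            push(method, *fn())
        except (ValueError, KeyError, ZeroDivisionError) as exc:
            logger.debug("method %s missing on window %.0f: %s",
                         method.value, window.window_start, exc)
            push(method, float("nan"))

    def blood_rates(gas: str) -> tuple[float, float]:
        if q_lung_ref is None:
            raise ValueError("blood-phase rates need the measured lung flow")
        pa, la = samples["PA"], samples["LA"]
        ra, pe = samples["RA"], samples["PE"]
        if gas == "O2":
            dl = _o2(la) - _o2(pa)
            de = _o2(pe) - _o2(ra)
        else:
            dl = _c_co2(pa) - _c_co2(la)
            de = _c_co2(ra) - _c_co2(pe)
        return abs(dl) * q_lung_ref / 100.0, abs(de) * q_ecmo / 100.0

    def est_vo2_blood():
        vl, ve = blood_rates("O2")
        return (qlung_from_exchange(q_ecmo, vl, ve),)

    def est_vco2_blood():
        vl, ve = blood_rates("CO2")
        return (qlung_from_exchange(q_ecmo, vl, ve),)

    def est_vo2_gas():
        if math.isnan(window.vo2_lung) or math.isnan(window.vo2_ecmo):
            raise ValueError("gas-phase VO2 missing")
        return (qlung_from_exchange(q_ecmo, window.vo2_lung, window.vo2_ecmo),)

    def est_vco2_gas():
        if math.isnan(window.vco2_lung) or math.isnan(window.vco2_ecmo):
            raise ValueError("gas-phase VCO2 missing")
        return (qlung_from_exchange(q_ecmo, window.vco2_lung, window.vco2_ecmo),)

    def est_vco2_gas_norm():
        if math.isnan(window.vco2_lung) or math.isnan(window.vco2_ecmo):
            raise ValueError("gas-phase VCO2 missing")
        if fi_o2 is None or fe_o2 is None:
            raise ValueError("lung FI/FE O2 needed for the V/Q estimate")
        pa, la = samples["PA"], samples["LA"]
        x = vq_lung(fi_o2, fe_o2, _o2(la), _o2(pa))
        params = normalization_constant(samples[norm_site], pk_prime=pk_prime)
        params.vq_lung = x  # validated by normalize_vco2
        vl = normalize_vco2(window.vco2_lung, params)
        # the membrane lung runs at V/Q = 1 by protocol: no normalization
        return qlung_from_exchange(q_ecmo, vl, window.vco2_ecmo), x

    attempt(Method.VO2_BLOOD, est_vo2_blood)
    attempt(Method.VO2_GAS, est_vo2_gas)
    attempt(Method.VCO2_GAS, est_vco2_gas)
    attempt(Method.VCO2_GAS_NORM, est_vco2_gas_norm)
    attempt(Method.VCO2_BLOOD, est_vco2_blood)
    return out


def filter_estimates(
    estimates: list[FlowEstimate], max_flow: float = MAX_PLAUSIBLE_FLOW
) -> list[FlowEstimate]:
    """Apply the outlier rule: drop negative or > 10 L/min calculated
    flows (and failed/NaN estimates); order preserved, removals logged."""
    kept = [
        e
        for e in estimates
        if math.isfinite(e.q_lung_calc) and 0.0 <= e.q_lung_calc <= max_flow
    ]
    removed = len(estimates) - len(kept)
    if removed:
        logger.info("filter_estimates removed %d of %d estimates",
                    removed, len(estimates))
    return kept
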