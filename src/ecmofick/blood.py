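"""Blood gas content models.

Oxygen content uses the standard formula (bound + dissolved):

    cO2 = 1.36 * Hb * SO2/100 + 0.003 * PO2          [mL O2 (STPD) / dL]

Carbon dioxide content uses the whole-blood formulation of Douglas, Stapp
& Fenn (1988): a plasma Henderson-Hasselbalch term scaled by a cell-water
correction that carries the Haldane effect (deoxygenated blood holds more
CO2 at the same PCO2).  The oxygen dissociation curve used by the circuit
simulator is a Hill curve with configurable P50 and exponent.

All contents are mL gas (STPD) per dL whole blood; 1 mmol CO2 = 22.26 mL.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "SITES",
    "BloodGasSample",
    "GasContent",
    "SpeciesCorrection",
    "IDENTITY_CORRECTION",
    "PORCINE_CORRECTION",
    "o2_content",
    "co2_content",
    "so2_species_correction",
    "so2_from_po2",
    "po2_from_so2",
]

#: Sampling ports around the circuit: pulmonary artery, left atrium,
#: right atrium / ECMO drainage, post-oxygenator, aorta.
SITES = ("PA", "LA", "RA", "PE", "AO")

#: mL of CO2 gas (STPD) per mmol.
ML_PER_MMOL_CO2 = 22.26

#: Accepted physiological pH range; samples outside are rejected.
PH_RANGE = (6.5, 8.0)


@dataclass(frozen=True)
class BloodGasSample:
    """One site's blood gas panel.

    Parameters
    ----------
    site : str
        One of :data:`SITES`.
    po2, pco2 : float
        Partial pressures, mmHg.
    so2 : float
        Oxygen saturation, percent (0-100).
    hb : float
        Hemoglobin, g/dL.
    ph : float
        Unitless; accepted range 6.5-8.0.
    temperature : float
        Blood temperature, degrees C.
    """

    site: str
    po2: float
    pco2: float
    so2: float
    hb: float
    ph: float
    temperature: float = 37.0

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}; expected one of {SITES}")
        if self.po2 < 0:
            raise ValueError(f"po2 must be >= 0, got {self.po2}")
        if self.pco2 < 0:
            raise ValueError(f"pco2 must be >= 0, got {self.pco2}")
        if not 0.0 <= self.so2 <= 100.0:
            raise ValueError(f"so2 must be in [0, 100], got {self.so2}")
        if self.hb < 0:
            raise ValueError(f"hb must be >= 0, got {self.hb}")
        if not PH_RANGE[0] <= self.ph <= PH_RANGE[1]:
            raise ValueError(f"ph {self.ph} outside accepted range {PH_RANGE}")

    def o2_content(self) -> float:
        return o2_content(self.hb, self.so2, self.po2)

    def co2_content(self) -> float:
        return co2_content(self.pco2, self.ph, self.hb, self.so2, self.temperature)


@dataclass(frozen=True)
class GasContent:
    """A blood gas content value, mL gas (STPD) per dL blood."""

    value: float
    gas: str  # "O2" | "CO2"

    def __post_init__(self) -> None:
        if self.gas not in ("O2", "CO2"):
            raise ValueError(f"gas must be 'O2' or 'CO2', got {self.gas!r}")
        if self.value < 0:
            raise ValueError(f"content must be >= 0, got {self.value}")


def o2_content(hb: float, so2: float, po2: float) -> float:
    """Oxygen content of whole blood, mL O2/dL.

    ``1.36 * hb * so2/100 + 0.003 * po2`` — hemoglobin-bound plus dissolved.

    Parameters
    ----------
    hb : float
        Hemoglobin, g/dL.
    so2 : float
        Saturation, percent.
    po2 : float
        Oxygen partial pressure, mmHg.
    """
    if hb < 0 or po2 < 0:
        raise ValueError("hb and po2 must be non-negative")
    if not 0.0 <= so2 <= 100.0:
        raise ValueError(f"so2 must be in [0, 100], got {so2}")
    return 1.36 * hb * so2 / 100.0 + 0.003 * po2


def co2_content(
    pco2: float,
    ph: float,
    hb: float,
    so2: float,
    temperature: float = 37.0,
) -> float:
    """Total CO2 content of whole blood, mL CO2 (STPD)/dL.

    Douglas-Stapp-Fenn whole-blood model: dissolved + bicarbonate CO2 in
    plasma from Henderson-Hasselbalch, scaled to whole blood by a
    hemoglobin- and saturation-dependent factor.  The saturation term is
    the Haldane effect: at fixed PCO2, content falls as SO2 rises.

    Strictly increasing in ``pco2`` and decreasing in ``so2``.
    """
    if pco2 < 0:
        raise ValueError(f"pco2 must be >= 0, got {pco2}")
    if not PH_RANGE[0] <= ph <= PH_RANGE[1]:
        raise ValueError(f"ph {ph} outside accepted range {PH_RANGE}")
    if hb < 0:
        raise ValueError(f"hb must be >= 0, got {hb}")
    if not 0.0 <= so2 <= 100.0:
        raise ValueError(f"so2 must be in [0, 100], got {so2}")

    # plasma solubility (mmol/L/mmHg) and apparent pK', both T/pH dependent
    alpha = 0.0307 + 0.00057 * (37.0 - temperature) + 2e-5 * (37.0 - temperature) ** 2
    pk = 6.086 + 0.042 * (7.4 - ph) + (38.0 - temperature) * (
        0.00472 + 0.00139 * (7.4 - ph)
    )
    c_plasma = alpha * pco2 * (1.0 + 10.0 ** (ph - pk))  # mmol/L plasma
    # whole-blood correction; (3.352 - 0.456*SO2) carries the Haldane effect
    f_blood = 1.0 - (0.0289 * hb) / (
        (3.352 - 0.456 * so2 / 100.0) * (8.142 - ph)
    )
    c_blood = c_plasma * f_blood  # mmol/L blood
    return c_blood * ML_PER_MMOL_CO2 / 10.0  # -> mL/dL


@dataclass(frozen=True)
class SpeciesCorrection:
    """Monotone recalibration of CO-oximeter saturation between species.

    Maps saturation through odds space:

        s' = 100 * x^gamma / (x^gamma + odds_scale * (1-x)^gamma),  x = s/100

    ``gamma=1, odds_scale=1`` is the identity.  Endpoints 0 and 100 are
    preserved for any positive parameters, and the map is strictly
    increasing.  The porcine defaults are provisional: the published
    porcine recalibration's coefficients are not reproduced here, only its
    monotone endpoint-preserving form.
    """

    gamma: float = 1.0
    odds_scale: float = 1.0
    label: str = "identity"

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.odds_scale <= 0:
            raise ValueError("gamma and odds_scale must be positive")

    def __call__(self, so2_raw: float) -> float:
        return so2_species_correction(so2_raw, self)


IDENTITY_CORRECTION = SpeciesCorrection()
#: Provisional porcine recalibration (human CO-oximeter coefficients read
#: slightly low on pig blood in the mid range).
PORCINE_CORRECTION = SpeciesCorrection(gamma=1.0, odds_scale=0.85, label="porcine")


def so2_species_correction(
    so2_raw: float, species_params: SpeciesCorrection = IDENTITY_CORRECTION
) -> float:
    """Apply a species saturation recalibration; result in [0, 100]."""
    if not 0.0 <= so2_raw <= 100.0:
        raise ValueError(f"so2_raw must be in [0, 100], got {so2_raw}")
    x = so2_raw / 100.0
    if x in (0.0, 1.0):
        return so2_raw
    g = species_params.gamma
    num = x**g
    den = num + species_params.odds_scale * (1.0 - x) ** g
    return 100.0 * num / den


def so2_from_po2(po2: float, p50: float = 35.0, hill_n: float = 2.8) -> float:
    """Hill oxygen dissociation curve: ``100 * po2^n / (po2^n + p50^n)``.

    Defaults are porcine-flavored (P50 above human); strictly increasing
    in ``po2``.
    """
    if po2 < 0:
        raise ValueError(f"po2 must be >= 0, got {po2}")
    if p50 <= 0 or hill_n <= 0:
        raise ValueError("p50 and hill_n must be positive")
    if po2 == 0.0:
        return 0.0
    r = (po2 / p50) ** hill_n
    return 100.0 * r / (r + 1.0)


def po2_from_so2(so2: float, p50: float = 35.0, hill_n: float = 2.8) -> float:
    """Inverse of :func:`so2_from_po2` (so2 strictly inside [0, 100))."""
    if p50 <= 0 or hill_n <= 0:
        raise ValueError("p50 and hill_n must be positive")
    if not 0.0 <= so2 < 100.0:
        raise ValueError(f"so2 must be in [0, 100), got {so2}")
    if so2 == 0.0:
        return 0.0
    s = so2 / 100.0
    return p50 * (s / (1.0 - s)) ** (1.0 / hill_n)
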