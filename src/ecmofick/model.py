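"""Modelling interface: fit the modified Fick estimator to a dataset.

`ModifiedFickModel` wraps a tidy per-window dataset (one row per
measurement window, carrying the five-site blood gases, the sweep/exhaust
gas data, the lung FI/FE traces' window summaries and the reference
flows).  `fit()` runs every estimator variant on every window, applies
the outlier rule, and returns a `ModifiedFickResults` carrying the
estimates plus agreement diagnostics (Bland-Altman, percentage error,
least significant change, trending concordance) and a `summary()` table —
the same evaluation style used to validate cardiac output monitors.
"""

from __future__ import annotations

import math
import numpy as np
import pandas as pd

from .agreement import (
    AgreementResult,
    TrendingResult,
    bland_altman,
    least_significant_change,
    trending_concordance,
)
from .blood import BloodGasSample, SITES
from .fick import (
    MAX_PLAUSIBLE_FLOW,
    Method,
    estimate_all_methods,
)
from .gas import ExhaustFractions, SweepGasSetting, WindowedExchange, ecmo_exhaust_exchange

__all__ = ["ModifiedFickModel", "ModifiedFickResults"]

#: Columns of the per-window ("periods") input frame that must be present.
REQUIRED_COLUMNS = (
    "window_start_s",
    "condition",
    "q_ecmo_ml_min",
    "q_lung_ref_ml_min",
    "air_inflow_l_min",
    "o2_inflow_l_min",
    "f_pe_o2",
    "f_pe_co2",
    "fi_o2",
    "fe_o2",
    "fe_co2",
    "minute_ventilation_ml_min",
)


class ModifiedFickModel:
    """Modified Fick flow estimation over a set of measurement windows.

    Parameters
    ----------
    periods : pandas.DataFrame
        One row per window.  Required columns: :data:`REQUIRED_COLUMNS`
        plus the five-site blood gas columns ``po2_<site>``,
        ``pco2_<site>``, ``so2_<site>``, ``hb_<site>``, ``ph_<site>``,
        ``temp_<site>`` for site in PA, LA, RA, PE, AO.  Optional
        grouping columns ``animal``, ``phase``, ``step`` enable trending
        and least-significant-change diagnostics.
    norm_site : str
        Venous site for the normalization constant (default RA, the
        ECMO drainage; configurable to PA).
    pool_hb : bool
        Pool hemoglobin across each window's samples (see
        :func:`ecmofick.fick.estimate_all_methods`).
    """

    def __init__(
        self,
        periods: pd.DataFrame,
        norm_site: str = "RA",
        pool_hb: bool = True,
    ) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in periods.columns]
        for site in SITES:
            for var in ("po2", "pco2", "so2", "hb", "ph"):
                col = f"{var}_{site}"
                if col not in periods.columns:
                    missing.append(col)
        if missing:
            raise ValueError(f"periods frame missing columns: {missing}")
        if norm_site not in SITES:
            raise ValueError(f"norm_site must be one of {SITES}, got {norm_site!r}")
        self.periods = periods.reset_index(drop=True)
        self.norm_site = norm_site
        self.pool_hb = pool_hb

    @classmethod
    def from_dataset(cls, dataset, **kwargs) -> "ModifiedFickModel":
        """Build from a :class:`~ecmofick.simulate.ProtocolDataset`."""
        return cls(dataset.periods_frame(), **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ModifiedFickModel":
        """Build from a periods CSV (as written by the ``simulate`` CLI)."""
        return cls(pd.read_csv(path), **kwargs)

    def _row_samples(self, row) -> dict[str, BloodGasSample]:
        samples = {}
        for site in SITES:
            samples[site] = BloodGasSample(
                site=site,
                po2=row[f"po2_{site}"],
                pco2=row[f"pco2_{site}"],
                so2=row[f"so2_{site}"],
                hb=row[f"hb_{site}"],
                ph=row[f"ph_{site}"],
                temperature=row.get(f"temp_{site}", 37.0),
            )
        return samples

    def fit(self, max_flow: float = MAX_PLAUSIBLE_FLOW) -> "ModifiedFickResults":
        """Run all estimator variants on every window.

        Returns a results object; estimates outside [0, max_flow] mL/min
        (or failed ones) carry ``excluded_flag = True`` and are dropped
        from the agreement statistics, mirroring the outlier rule.
        """
        rows = []
        for idx, row in self.periods.iterrows():
            samples = self._row_samples(row)
            sweep = SweepGasSetting(
                air_inflow=row["air_inflow_l_min"],
                o2_inflow=row["o2_inflow_l_min"],
            )
            try:
                exhaust = ExhaustFractions(
                    f_pe_o2=row["f_pe_o2"], f_pe_co2=row["f_pe_co2"]
                )
                vo2_ecmo, vco2_ecmo = ecmo_exhaust_exchange(sweep, exhaust)
            except ValueError:
                vo2_ecmo, vco2_ecmo = float("nan"), float("nan")
            mv = row["minute_ventilation_ml_min"]
            window = WindowedExchange(
                window_start=row["window_start_s"],
                vo2_lung=abs(mv * (row["fi_o2"] - row["fe_o2"])),
                vco2_lung=abs(mv * row["fe_co2"]),
                vo2_ecmo=vo2_ecmo,
                vco2_ecmo=vco2_ecmo,
            )
            estimates = estimate_all_methods(
                window,
                samples,
                q_ecmo=row["q_ecmo_ml_min"],
                q_lung_ref=row["q_lung_ref_ml_min"],
                fi_o2=row["fi_o2"],
                fe_o2=row["fe_o2"],
                condition=row["condition"],
                norm_site=self.norm_site,
                pool_hb=self.pool_hb,
            )
            for e in estimates:
                excluded = not (
                    math.isfinite(e.q_lung_calc)
                    and 0.0 <= e.q_lung_calc <= max_flow
                )
                rows.append(
                    {
                        "window_index": idx,
                        "animal": row.get("animal", 0),
                        "phase": row.get("phase", ""),
                        "step": row.get("step", -1),
                        "window_start_s": e.window_start,
                        "condition": e.condition,
                        "method": e.method.value,
                        "q_ecmo_ml_min": e.q_ecmo,
                        "q_lung_calc_ml_min": e.q_lung_calc,
                        "q_lung_ref_ml_min": e.reference_q_lung,
                        "vq_lung": e.vq_lung,
                        "excluded_flag": excluded,
                    }
                )
        estimates_frame = pd.DataFrame(rows)
        return ModifiedFickResults(self, estimates_frame)


class ModifiedFickResults:
    """Per-window flow estimates plus method-agreement diagnostics."""

    def __init__(self, model: ModifiedFickModel, estimates: pd.DataFrame) -> None:
        self.model = model
        self.estimates = estimates

    @property
    def n_excluded(self) -> int:
        return int(self.estimates["excluded_flag"].sum())

    def _select(self, method, condition=None) -> pd.DataFrame:
        method = Method(method).value
        df = self.estimates
        sel = (df["method"] == method) & (~df["excluded_flag"])
        if condition is not None:
            sel &= df["condition"] == condition
        return df[sel]

    def agreement(self, method, condition=None) -> AgreementResult:
        """Bland-Altman agreement of one method against the flow probe."""
        df = self._select(method, condition)
        if len(df) < 2:
            raise ValueError(
                f"not enough retained estimates for {method} / {condition}"
            )
        return bland_altman(df["q_lung_ref_ml_min"], df["q_lung_calc_ml_min"])

    def lsc(self, method, condition=None) -> float:
        """Least significant change, pooled over (animal, condition, step)
        replicate windows (the repeated phases of the protocol)."""
        df = self._select(method, condition)
        groups = [
            g["q_lung_calc_ml_min"].to_numpy()
            for _, g in df.groupby(["animal", "condition", "step"])
        ]
        return least_significant_change(groups)

    def trending(
        self, method, condition=None, exclusion_zone: float | None = None
    ) -> TrendingResult:
        """Four-quadrant concordance of ladder-step changes.

        Deltas are taken between successive ECMO-flow steps within each
        (animal, phase) run.  The exclusion zone defaults to the method's
        least significant change.
        """
        lsc_val = float("nan")
        if exclusion_zone is None:
            try:
                lsc_val = self.lsc(method, condition)
                exclusion_zone = lsc_val
            except ValueError:
                exclusion_zone = 0.0
        df = self._select(method, condition).sort_values(["animal", "phase", "step"])
        d_ref, d_test = [], []
        for _, g in df.groupby(["animal", "phase"]):
            if len(g) < 2:
                continue
            d_ref.extend(np.diff(g["q_lung_ref_ml_min"].to_numpy()))
            d_test.extend(np.diff(g["q_lung_calc_ml_min"].to_numpy()))
        return trending_concordance(
            d_ref, d_test, exclusion_zone=exclusion_zone,
            least_significant_change=lsc_val,
        )

    def summary_frame(self) -> pd.DataFrame:
        """One row per method x condition with the agreement metrics."""
        rows = []
        df = self.estimates
        for method in df["method"].unique():
            for condition in df["condition"].unique():
                sel = self._select(method, condition)
                row = {
                    "method": method,
                    "condition": condition,
                    "n": len(sel),
                    "n_excluded": int(
                        (
                            (df["method"] == method)
                            & (df["condition"] == condition)
                            & df["excluded_flag"]
                        ).sum()
                    ),
                }
                if len(sel) >= 2:
                    ag = self.agreement(method, condition)
                    tr = self.trending(method, condition)
                    row.update(
                        bias_ml_min=ag.bias,
                        loa_lower_ml_min=ag.loa_lower,
                        loa_upper_ml_min=ag.loa_upper,
                        percentage_error_pct=ag.percentage_error,
                        lsc_ml_min=tr.least_significant_change,
                        concordance_pct=tr.concordance_rate,
                    )
                rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable agreement table."""
        frame = self.summary_frame()
        with pd.option_context("display.width", 120, "display.precision", 1):
            body = frame.to_string(index=False)
        win_col = ("window_index" if "window_index" in self.estimates.columns
                   else "window_start_s")
        header = (
            "Modified Fick pulmonary blood flow estimation\n"
            f"windows: {self.estimates[win_col].nunique()}, "
            f"estimates: {len(self.estimates)}, excluded: {self.n_excluded}\n"
        )
        return header + body

    def plot_bland_altman(self, method, condition=None, ax=None):
        """Bland-Altman plot (difference vs pair mean with bias/LoA lines)."""
        import matplotlib.pyplot as plt

        df = self._select(method, condition)
        ag = self.agreement(method, condition)
        if ax is None:
            _, ax = plt.subplots()
        mean = 0.5 * (df["q_lung_calc_ml_min"] + df["q_lung_ref_ml_min"])
        diff = df["q_lung_calc_ml_min"] - df["q_lung_ref_ml_min"]
        ax.scatter(mean, diff, s=12, alpha=0.7)
        for y, style in ((ag.bias, "-"), (ag.loa_lower, "--"), (ag.loa_upper, "--")):
            ax.axhline(y, color="k", linestyle=style, linewidth=1)
        ax.set_xlabel("mean of calculated and reference flow (mL/min)")
        ax.set_ylabel("calculated - reference (mL/min)")
        ax.set_title(f"{Method(method).value}"
                     + (f" / {condition}" if condition else ""))
        return ax

    def plot_four_quadrant(self, method, condition=None, ax=None):
        """Four-quadrant trending plot of ladder-step changes."""
        import matplotlib.pyplot as plt

        df = self._select(method, condition).sort_values(["animal", "phase", "step"])
        d_ref, d_test = [], []
        for _, g in df.groupby(["animal", "phase"]):
            if len(g) >= 2:
                d_ref.extend(np.diff(g["q_lung_ref_ml_min"].to_numpy()))
                d_test.extend(np.diff(g["q_lung_calc_ml_min"].to_numpy()))
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(d_ref, d_test, s=12, alpha=0.7)
        ax.axhline(0, color="k", linewidth=1)
        ax.axvline(0, color="k", linewidth=1)
        lim = max(map(abs, [*d_ref, *d_test, 1.0]))
        ax.plot([-lim, lim], [-lim, lim], "k:", linewidth=1)
        ax.set_xlabel("reference flow change (mL/min)")
        ax.set_ylabel("calculated flow change (mL/min)")
        ax.set_title(f"{Method(method).value} trending"
                     + (f" / {condition}" if condition else ""))
        return ax
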