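"""File formats: dataset CSVs, waveform CSVs, configuration, metadata.

Everything is plain CSV (UTF-8, '.' decimal, header row mandatory) or
YAML.  The blood-gas table dialect has one row per sample:
``time_s, site, po2_mmHg, pco2_mmHg, so2_pct, hb_g_dl, ph, temp_c``.
Waveform CSVs carry a ``# rate_hz=<r>`` comment line before the header,
one file per channel.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .blood import BloodGasSample, SITES
from .gas import Waveform
from .simulate import CircuitConfig, PhaseSpec, ProtocolDataset, default_phases

__all__ = [
    "RunConfig",
    "load_run_config",
    "config_hash",
    "write_dataset",
    "read_periods",
    "read_bloodgas",
    "write_waveform_csv",
    "read_waveform_csv",
    "write_estimates",
    "read_estimates",
    "write_agreement",
]

BLOODGAS_COLUMNS = [
    "time_s", "site", "po2_mmHg", "pco2_mmHg", "so2_pct", "hb_g_dl", "ph", "temp_c",
]


@dataclasses.dataclass
class RunConfig:
    """Top-level pipeline configuration (simulate -> estimate -> agreement)."""

    circuit: CircuitConfig
    animals: int = 3
    ladder: tuple[float, ...] = (4000.0, 3000.0, 2000.0, 1000.0)
    phases: list[PhaseSpec] = dataclasses.field(default_factory=default_phases)
    norm_site: str = "RA"
    pool_hb: bool = True
    exclusion_zone: str | float = "lsc"  # "lsc" or a flow in mL/min
    seed: int = 0
    write_waveforms: bool = False

    def __post_init__(self) -> None:
        if self.animals < 1:
            raise ValueError("animals must be >= 1")
        if self.norm_site not in SITES:
            raise ValueError(f"norm_site must be one of {SITES}")


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys and missing required fields raise with the field named.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    circuit_raw = raw.pop("circuit", {})
    known = {f.name for f in dataclasses.fields(CircuitConfig)}
    unknown = set(circuit_raw) - known
    if unknown:
        raise ValueError(f"unknown circuit config fields: {sorted(unknown)}")
    try:
        circuit = CircuitConfig(**circuit_raw)
    except TypeError as exc:
        raise ValueError(f"invalid circuit config: {exc}") from exc

    phases_raw = raw.pop("phases", None)
    if phases_raw is None:
        phases = default_phases()
    else:
        phases = []
        for i, p in enumerate(phases_raw):
            try:
                phases.append(PhaseSpec(**p))
            except TypeError as exc:
                raise ValueError(f"invalid phase entry {i}: {exc}") from exc

    ladder = tuple(float(q) for q in raw.pop("ladder", (4000, 3000, 2000, 1000)))
    known_top = {"animals", "norm_site", "pool_hb", "exclusion_zone", "seed",
                 "write_waveforms"}
    unknown_top = set(raw) - known_top
    if unknown_top:
        raise ValueError(f"unknown config fields: {sorted(unknown_top)}")
    cfg = RunConfig(circuit=circuit, phases=phases, ladder=ladder, **raw)
    if "seed" in raw or True:
        cfg.circuit = dataclasses.replace(cfg.circuit, seed=cfg.seed)
    return cfg


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the full configuration."""
    payload = {
        "circuit": dataclasses.asdict(config.circuit),
        "animals": config.animals,
        "ladder": list(config.ladder),
        "phases": [dataclasses.asdict(p) for p in config.phases],
        "norm_site": config.norm_site,
        "pool_hb": config.pool_hb,
        "exclusion_zone": config.exclusion_zone,
        "seed": config.seed,
    }
    text = json.dumps(payload, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def write_dataset(
    datasets: list[ProtocolDataset],
    outdir,
    run_config: RunConfig | None = None,
) -> None:
    """Write simulated datasets (one per animal) to a directory.

    Produces ``bloodgas.csv``, ``windows.csv``, ``periods.csv`` (the wide
    per-window table the estimator consumes), ``truth.csv`` and
    ``meta.txt`` (config + seed + hash).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    periods = pd.concat([d.periods_frame() for d in datasets], ignore_index=True)
    truth = pd.concat([d.truth_frame() for d in datasets], ignore_index=True)

    blood_rows = []
    window_rows = []
    for d in datasets:
        for p in d.periods:
            for site, s in p.record.samples.items():
                blood_rows.append({
                    "time_s": p.window_start, "site": site,
                    "po2_mmHg": s.po2, "pco2_mmHg": s.pco2, "so2_pct": s.so2,
                    "hb_g_dl": s.hb, "ph": s.ph, "temp_c": s.temperature,
                })
            w = p.record.window
            window_rows.append({
                "animal": p.animal, "phase": p.phase, "condition": p.condition,
                "step": p.step, "window_start_s": w.window_start,
                "window_length_s": w.window_length,
                "vo2_lung_ml_min": w.vo2_lung, "vco2_lung_ml_min": w.vco2_lung,
                "vo2_ecmo_ml_min": w.vo2_ecmo, "vco2_ecmo_ml_min": w.vco2_ecmo,
            })
    pd.DataFrame(blood_rows, columns=BLOODGAS_COLUMNS).to_csv(
        outdir / "bloodgas.csv", index=False
    )
    pd.DataFrame(window_rows).to_csv(outdir / "windows.csv", index=False)
    periods.to_csv(outdir / "periods.csv", index=False)
    truth.to_csv(outdir / "truth.csv", index=False)

    meta_lines = [f"animals={len(datasets)}"]
    if run_config is not None:
        meta_lines.append(f"config_hash={config_hash(run_config)}")
        meta_lines.append(f"seed={run_config.seed}")
        for k, v in dataclasses.asdict(run_config.circuit).items():
            meta_lines.append(f"circuit.{k}={v}")
    else:
        meta_lines.append(f"seed={datasets[0].seed}")
    (outdir / "meta.txt").write_text("\n".join(meta_lines) + "\n")


def read_periods(directory) -> pd.DataFrame:
    """Read the wide per-window table from a dataset directory."""
    path = Path(directory) / "periods.csv"
    if not path.exists():
        raise FileNotFoundError(f"no periods.csv in {directory}")
    return pd.read_csv(path)


def read_bloodgas(path) -> list[BloodGasSample]:
    """Read a blood-gas table CSV into samples (rows validated)."""
    df = pd.read_csv(path)
    missing = [c for c in BLOODGAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"blood-gas table missing columns: {missing}")
    samples = []
    for i, row in df.iterrows():
        try:
            samples.append(BloodGasSample(
                site=row["site"], po2=row["po2_mmHg"], pco2=row["pco2_mmHg"],
                so2=row["so2_pct"], hb=row["hb_g_dl"], ph=row["ph"],
                temperature=row["temp_c"],
            ))
        except ValueError as exc:
            raise ValueError(f"invalid blood-gas row {i}: {exc}") from exc
    return samples


def write_waveform_csv(path, waveform: Waveform) -> None:
    """One channel per file; ``# rate_hz=`` comment line, then header."""
    with open(path, "w") as fh:
        fh.write(f"# rate_hz={waveform.sample_rate}\n")
        fh.write("time_s,value\n")
        for t, v in zip(waveform.times, waveform.values):
            fh.write(f"{t:.6f},{v:.8g}\n")


def read_waveform_csv(path) -> Waveform:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# rate_hz="):
            raise ValueError(f"{path}: missing '# rate_hz=' comment line")
        rate = float(first.split("=", 1)[1])
    df = pd.read_csv(path, comment="#")
    if "time_s" not in df.columns or "value" not in df.columns:
        raise ValueError(f"{path}: expected columns time_s,value")
    start = float(df["time_s"].iloc[0]) if len(df) else 0.0
    return Waveform(start, rate, df["value"].to_numpy())


ESTIMATE_COLUMNS = [
    "window_start_s", "condition", "method", "q_ecmo_ml_min",
    "q_lung_calc_ml_min", "q_lung_ref_ml_min", "vq_lung", "excluded_flag",
]


def write_estimates(estimates: pd.DataFrame, path) -> None:
    cols = [c for c in ("animal", "phase", "step") if c in estimates.columns]
    estimates[cols + ESTIMATE_COLUMNS].to_csv(path, index=False)


def read_estimates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ESTIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"estimates file missing columns: {missing}")
    return df


def write_agreement(summary: pd.DataFrame, outdir) -> None:
    """Write the per-method x condition agreement table and JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary.to_csv(outdir / "agreement.csv", index=False)
    payload = summary.to_dict(orient="records")
    (outdir / "agreement.json").write_text(json.dumps(payload, indent=2,
                                                      default=float))
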