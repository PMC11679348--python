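"""Readers and writers for the pipeline's CSV/JSON interchange formats.

Dialect is fixed for cross-language reproducibility: comma separator,
header row, dot decimal, UTF-8.  Units are SI internally; column names
carry explicit unit suffixes at the boundary (``_m2_per_s``, ``_M``, ...).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .formulation import FormulationRecord
from .pgse import DecayCurve
from .quantitation import PeakRecord

__all__ = [
    "load_decay_table",
    "write_decay_table",
    "load_peak_table",
    "write_peak_table",
    "load_titration_table",
    "write_titration_table",
    "load_panel_table",
    "write_panel_table",
    "write_run_log",
]

DECAY_COLUMNS = ["gradient_T_per_m", "intensity", "peak_label"]
PEAK_COLUMNS = ["label", "shift_ppm", "integral", "fwhm_hz", "n_protons", "condition"]
TITRATION_COLUMNS = ["host_conc_M", "D_obs_m2_per_s"]


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    return df


def _require_numeric(df: pd.DataFrame, path, columns: list[str]) -> None:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            # +2: header row and 1-based numbering
            raise ValueError(
                f"{Path(path).name}: non-numeric value in column {col!r} "
                f"at row(s) {[int(i) + 2 for i in bad[:5]]}"
            )
        df[col] = coerced


def load_decay_table(path: str | Path) -> dict[str, DecayCurve]:
    """Read per-peak decay curves; one DecayCurve per ``peak_label``.

    Rows are normalised to ascending gradient order.  Duplicate
    (peak, gradient) pairs and non-numeric cells are reported with row
    numbers.
    """
    df = _read_csv(path, DECAY_COLUMNS)
    _require_numeric(df, path, ["gradient_T_per_m", "intensity"])
    dup = df.duplicated(subset=["peak_label", "gradient_T_per_m"], keep=False)
    if dup.any():
        rows = [int(i) + 2 for i in df.index[dup][:5]]
        raise ValueError(f"{Path(path).name}: duplicate (peak, gradient) pairs at row(s) {rows}")
    curves: dict[str, DecayCurve] = {}
    for label, grp in df.groupby("peak_label", sort=True):
        curves[str(label)] = DecayCurve(
            grp["gradient_T_per_m"].to_numpy(),
            grp["intensity"].to_numpy(),
            peak_label=str(label),
        )
    return curves


def write_decay_table(curves, path: str | Path) -> None:
    """Write DecayCurve(s) (single curve or iterable) to the decay CSV."""
    if isinstance(curves, DecayCurve):
        curves = [curves]
    frames = [
        pd.DataFrame(
            {
                "gradient_T_per_m": c.gradient_strengths,
                "intensity": c.intensities,
                "peak_label": c.peak_label or "peak",
            }
        )
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, encoding="utf-8")


def load_peak_table(path: str | Path) -> dict[str, list[PeakRecord]]:
    """Read a peak table grouped by ``condition`` (e.g. pre_hec / post_hec)."""
    df = _read_csv(path, PEAK_COLUMNS)
    _require_numeric(df, path, ["shift_ppm", "integral", "fwhm_hz", "n_protons"])
    out: dict[str, list[PeakRecord]] = {}
    for cond, grp in df.groupby("condition", sort=True):
        out[str(cond)] = [
            PeakRecord(
                shift_ppm=row.shift_ppm,
                integral=row.integral,
                fwhm_hz=row.fwhm_hz,
                n_protons=int(row.n_protons),
                label=str(row.label),
            )
            for row in grp.itertuples()
        ]
    return out


def write_peak_table(tables: dict[str, list[PeakRecord]], path: str | Path) -> None:
    rows = [
        {
            "label": p.label,
            "shift_ppm": p.shift_ppm,
            "integral": p.integral,
            "fwhm_hz": p.fwhm_hz,
            "n_protons": p.n_protons,
            "condition": cond,
        }
        for cond, peaks in tables.items()
        for p in peaks
    ]
    pd.DataFrame(rows, columns=PEAK_COLUMNS).to_csv(path, index=False, encoding="utf-8")


def load_titration_table(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, TITRATION_COLUMNS)
    _require_numeric(df, path, TITRATION_COLUMNS)
    return df.sort_values("host_conc_M").reset_index(drop=True)


def write_titration_table(host_concs, D_obs, path: str | Path) -> None:
    pd.DataFrame({"host_conc_M": host_concs, "D_obs_m2_per_s": D_obs}).to_csv(
        path, index=False, encoding="utf-8"
    )


def load_panel_table(path: str | Path) -> list[FormulationRecord]:
    df = _read_csv(path, ["id", "cpc_dose_pct"])
    numeric = [
        c
        for c in (
            "cpc_dose_pct",
            "cpc_free_conc_M",
            "D_obs_m2_per_s",
            "D_obs_with_hec_m2_per_s",
            "dra_value",
            "log_kill",
            "bound_percent",
        )
        if c in df.columns
    ]
    _require_numeric(df, path, numeric)

    def get(row, col):
        if col not in df.columns:
            return None
        v = getattr(row, col)
        return None if pd.isna(v) else float(v)

    records = []
    for row in df.itertuples():
        flags = getattr(row, "excipient_flags", "") if "excipient_flags" in df.columns else ""
        flags = frozenset(str(flags).split(";")) - {"", "nan"} if flags else frozenset()
        records.append(
            FormulationRecord(
                id=str(row.id),
                cpc_dose_pct=float(row.cpc_dose_pct),
                cpc_free_conc=get(row, "cpc_free_conc_M"),
                D_obs=get(row, "D_obs_m2_per_s"),
                D_obs_with_hec=get(row, "D_obs_with_hec_m2_per_s"),
                dra_value=get(row, "dra_value"),
                log_kill=get(row, "log_kill"),
                bound_percent=get(row, "bound_percent"),
                excipient_flags=flags,
            )
        )
    return records


def write_panel_table(records: list[FormulationRecord], path: str | Path) -> None:
    rows = [
        {
            "id": r.id,
            "cpc_dose_pct": r.cpc_dose_pct,
            "cpc_free_conc_M": r.cpc_free_conc,
            "D_obs_m2_per_s": r.D_obs,
            "D_obs_with_hec_m2_per_s": r.D_obs_with_hec,
            "dra_value": r.dra_value,
            "log_kill": r.log_kill,
            "bound_percent": r.bound_percent,
            "excipient_flags": ";".join(sorted(r.excipient_flags)),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


def write_run_log(path: str | Path, *, config, seed: int, parameters: dict) -> None:
    """Machine-readable provenance record accompanying every output."""
    from . import __version__

    entry = {
        "package": "cpcdosy",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": seed,
        "parameters": parameters,
        "effective_config": config.model_dump(),
    }
    with open(path, "a", encoding="utf-8") as fh:
        fh.write(json.dumps(entry, sort_keys=True) + "\n")
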