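"""CSV/JSON round-tripping for the pipeline's on-disk formats."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationModel, ImpedanceSpectrum, RawSweep


def read_raw_sweep(path) -> RawSweep:
    """Raw sweep CSV: columns frequency_hz, rr, ir (header required)."""
    df = pd.read_csv(path)
    for col in ("frequency_hz", "rr", "ir"):
        if col not in df.columns:
            raise ValueError(f"raw sweep file {path} missing column '{col}'")
    return RawSweep(
        frequencies=df["frequency_hz"].to_numpy(dtype=float),
        rr=df["rr"].to_numpy(dtype=float),
        ir=df["ir"].to_numpy(dtype=float),
    )


def write_raw_sweep(sweep: RawSweep, path) -> None:
    pd.DataFrame(
        {"frequency_hz": sweep.frequencies, "rr": sweep.rr, "ir": sweep.ir}
    ).to_csv(path, index=False)


def read_spectrum(path) -> ImpedanceSpectrum:
    df = pd.read_csv(path)
    for col in ("frequency_hz", "magnitude_ohm", "phase_rad", "real_ohm", "imag_ohm"):
        if col not in df.columns:
            raise ValueError(f"spectrum file {path} missing column '{col}'")
    return ImpedanceSpectrum(
        frequencies=df["frequency_hz"].to_numpy(dtype=float),
        magnitude=df["magnitude_ohm"].to_numpy(dtype=float),
        phase=df["phase_rad"].to_numpy(dtype=float),
        real_part=df["real_ohm"].to_numpy(dtype=float),
        imaginary_part=df["imag_ohm"].to_numpy(dtype=float),
    )


def write_spectrum(spectrum: ImpedanceSpectrum, path) -> None:
    pd.DataFrame(
        {
            "frequency_hz": spectrum.frequencies,
            "magnitude_ohm": spectrum.magnitude,
            "phase_rad": spectrum.phase,
            "real_ohm": spectrum.real_part,
            "imag_ohm": spectrum.imaginary_part,
        }
    ).to_csv(path, index=False)


def read_calibration(path) -> CalibrationModel:
    d = json.loads(Path(path).read_text())
    return CalibrationModel(
        frequencies=np.asarray(d["frequencies"], dtype=float),
        gain_factor=np.asarray(d["gain_factor"], dtype=float),
        system_phase=np.asarray(d["system_phase"], dtype=float),
        calibration_resistance=float(d["calibration_resistance"]),
    )


def write_calibration(model: CalibrationModel, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "calibration_resistance": model.calibration_resistance,
                "frequencies": model.frequencies.tolist(),
                "gain_factor": model.gain_factor.tolist(),
                "system_phase": model.system_phase.tolist(),
            },
            indent=2,
        )
    )


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError(f"feature table {path} missing 'label' column")
    return df


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
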