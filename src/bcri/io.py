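"""File formats and run configuration.

Plain-text interchange formats: correlation curves as whitespace tables with
a ``# key: value`` header, calibration sessions as YAML, per-cell results and
titrations as CSV with units in the column names, images as 16-bit TIFF with
a YAML metadata sidecar.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binding import TitrationDataset
from .calibration import FocalVolumeCalibration, effective_volume
from .correlation import CorrelationCurve
from .imaging import CellQuantification, ChannelImage

__all__ = [
    "RunConfig",
    "read_correlation_curve",
    "write_correlation_curve",
    "read_channel_image",
    "write_channel_image",
    "read_titration_csv",
    "write_titration_csv",
    "write_cell_table",
    "read_calibration_session",
    "write_calibration_session",
    "write_provenance",
]

_RUNCONFIG_KEYS = {
    "calibration_session", "channel_map", "drift_threshold", "spike_sd",
    "saturation_rate_hz", "p_nf", "cpp", "seed", "output_dir", "reference_channel",
}


@dataclass
class RunConfig:
    """Schema-validated configuration of a BCRI quantification run."""

    calibration_session: str = ""
    channel_map: dict = field(default_factory=dict)
    drift_threshold: float = 0.10
    spike_sd: float = 5.0
    saturation_rate_hz: float = 1e6
    p_nf: dict = field(default_factory=lambda: {"egfp": 0.20, "ligand": 0.32})
    cpp: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."
    reference_channel: str = "egfp"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _RUNCONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def write_correlation_curve(curve: CorrelationCurve, path: str | Path) -> None:
    """Write a curve as a two-column table with a ``# key: value`` header."""
    header = (
        f"# channel: {curve.channel}\n"
        f"# duration_s: {curve.duration}\n"
        f"# mean_intensity_kHz: {curve.mean_intensity}\n"
        f"# run_id: {curve.run_id}\n"
        "# lag_s G\n"
    )
    body = "\n".join(f"{l:.9e} {g:.9e}" for l, g in zip(curve.lags, curve.G))
    Path(path).write_text(header + body + "\n")


def read_correlation_curve(path: str | Path) -> CorrelationCurve:
    meta: dict[str, str] = {}
    lags, g = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if ":" in line:
                k, v = line[1:].split(":", 1)
                meta[k.strip()] = v.strip()
            continue
        a, b = line.split()
        lags.append(float(a))
        g.append(float(b))
    return CorrelationCurve(
        lags=np.array(lags), G=np.array(g),
        channel=meta.get("channel", ""),
        mean_intensity=float(meta.get("mean_intensity_kHz", 0.0)),
        duration=float(meta.get("duration_s", 0.0)),
        run_id=int(meta.get("run_id", 0)),
    )


def write_channel_image(img: ChannelImage, path: str | Path) -> None:
    """Write a 16-bit TIFF and a ``<path>.yaml`` acquisition-metadata sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, img.pixels.astype(np.uint16))
    meta = {
        "dwell_time_us": img.dwell_time * 1e6,
        "pixel_size_um": img.pixel_size,
        "channel": img.channel,
        "laser_line_nm": img.laser_line,
        "P_tot_uW": img.P_tot,
    }
    path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(meta))


def read_channel_image(path: str | Path) -> ChannelImage:
    import tifffile

    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar missing: {sidecar}")
    meta = yaml.safe_load(sidecar.read_text())
    for key in ("dwell_time_us", "pixel_size_um", "channel"):
        if key not in meta:
            raise ValueError(f"metadata field missing: {key}")
    return ChannelImage(
        pixels=tifffile.imread(path),
        dwell_time=float(meta["dwell_time_us"]) * 1e-6,
        pixel_size=float(meta["pixel_size_um"]),
        channel=str(meta["channel"]),
        laser_line=float(meta.get("laser_line_nm", 0.0)),
        P_tot=float(meta.get("P_tot_uW", 0.0)),
    )


def write_titration_csv(data: TitrationDataset, path: str | Path) -> None:
    df = pd.DataFrame({
        "c_molar": data.c, "sigma_c": data.sigma_c,
        "theta": data.theta, "sigma_theta": data.sigma_theta,
        "n_cells": data.n_cells if data.n_cells is not None else 0,
    })
    df.to_csv(path, index=False)


def read_titration_csv(path: str | Path) -> TitrationDataset:
    df = pd.read_csv(path)
    return TitrationDataset(
        c=df["c_molar"].to_numpy(), sigma_c=df["sigma_c"].to_numpy(),
        theta=df["theta"].to_numpy(), sigma_theta=df["sigma_theta"].to_numpy(),
        n_cells=df["n_cells"].to_numpy() if "n_cells" in df else None,
    )


def write_cell_table(cells: list[CellQuantification], path: str | Path) -> None:
    rows = [
        {
            "cell_id": c.cell_id, "N_ref": c.N_ref, "N_click": c.N_click,
            "N_ligand": c.N_ligand, "CE": c.CE, "occupancy": c.occupancy,
            "density_per_um2": c.density, "flags": ";".join(c.flags),
        }
        for c in cells
    ]
    pd.DataFrame(
        rows,
        columns=["cell_id", "N_ref", "N_click", "N_ligand", "CE",
                 "occupancy", "density_per_um2", "flags"],
    ).to_csv(path, index=False)


def write_calibration_session(
    calibrations: dict[str, dict], path: str | Path
) -> None:
    """Write per-laser-line calibration entries as YAML.

    Each entry: {w0_um, AR, V_eff_um3, A_eff_um2, standard_dye, tau_D_st_s,
    temperature_C, date}.
    """
    Path(path).write_text(yaml.safe_dump(calibrations))


def read_calibration_session(path: str | Path) -> dict[str, FocalVolumeCalibration]:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = {}
    for line, entry in raw.items():
        out[str(line)] = effective_volume(
            w0=float(entry["w0_um"]),
            AR=float(entry.get("AR", 6.0)),
            laser_line=float(line),
            timestamp=str(entry.get("date", "")),
        )
    return out


def write_provenance(path: str | Path, inputs: dict, config: dict | None = None) -> None:
    """Write a JSON provenance record (inputs, config hash, package versions)."""
    import bcri

    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    record = {
        "inputs": {k: str(v) for k, v in inputs.items()},
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": config or {},
        "versions": {"bcri": bcri.__version__, "numpy": np.__version__},
    }
    Path(path).write_text(json.dumps(record, indent=2, default=str))
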