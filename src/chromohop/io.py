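"""File formats: track/localization/FRAP CSV, TIFF movie stacks, YAML config.

Track CSV columns: track_id, frame, t_s, x_um, y_um, state (ground truth
only), visible (0/1), plus sx_um/sy_um/gap where available.  FRAP curve
CSV: t_s, zone, intensity_norm.  Config YAML mirrors the parameter
dataclasses (kinetic model, geometry, acquisition, bleach protocol).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .frap import FrapCurve, FrapCurveSet
from .models import (
    AcquisitionSettings,
    BleachProtocol,
    KineticModel,
    NucleusGeometry,
)

__all__ = [
    "write_tracks", "read_tracks",
    "write_movie", "read_movie",
    "write_frap_curves", "read_frap_curves",
    "load_config", "save_config",
]


def write_tracks(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_tracks(path: str | Path) -> pd.DataFrame:
    # round_trip parsing keeps write -> read -> write bit-identical
    return pd.read_csv(path, float_precision="round_trip")


def write_movie(stack: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint16),
                     photometric="minisblack")


def read_movie(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_frap_curves(curves: FrapCurveSet | FrapCurve, path: str | Path) -> None:
    if isinstance(curves, FrapCurve):
        curves = FrapCurveSet(curves={curves.zone: curves})
    rows = []
    for zone, c in curves.curves.items():
        rows.append(pd.DataFrame(
            {"t_s": c.t, "zone": zone, "intensity_norm": c.intensity_norm}
        ))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_frap_curves(path: str | Path, n_prebleach: int = 10) -> FrapCurveSet:
    df = pd.read_csv(path)
    curves = {}
    for zone, grp in df.groupby("zone"):
        grp = grp.sort_values("t_s")
        curves[str(zone)] = FrapCurve(
            t=grp["t_s"].to_numpy(float),
            intensity_norm=grp["intensity_norm"].to_numpy(float),
            zone=str(zone),
            n_prebleach=n_prebleach,
        )
    return FrapCurveSet(curves=curves)


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def _model_from_dict(d: dict) -> KineticModel:
    if "bound_fraction" in d:
        return KineticModel.from_bound_fraction(
            D_free=float(d["D_free"]),
            bound_fraction=float(d["bound_fraction"]),
            residence_time=float(d["residence_time"]),
            **{k: float(d.get(k, 0.0)) for k in
               ("bleach_rate", "blink_on", "blink_off", "loss_rate_defocus")},
        )
    return KineticModel(
        state_names=tuple(d["state_names"]),
        D_state=tuple(float(v) for v in d["D_state"]),
        rate_matrix=np.asarray(d["rate_matrix"], dtype=float),
        bleach_rate=float(d.get("bleach_rate", 0.0)),
        blink_on=float(d.get("blink_on", 0.0)),
        blink_off=float(d.get("blink_off", 0.0)),
        loss_rate_defocus=float(d.get("loss_rate_defocus", 0.0)),
    )


def _geometry_from_dict(d: dict) -> NucleusGeometry:
    layout = d.get("site_layout", "uniform")
    if layout != "uniform":
        layout = [np.asarray(line, dtype=float) for line in layout]
    return NucleusGeometry(
        semi_axes=tuple(float(v) for v in d.get("semi_axes", (8.0, 8.0))),
        site_layout=layout,
        capture_distance=float(d.get("capture_distance", 0.05)),
    )


def _settings_from_dict(d: dict) -> AcquisitionSettings:
    return AcquisitionSettings(**{k: float(v) for k, v in d.items()})


def _protocol_from_dict(d: dict) -> BleachProtocol:
    d = dict(d)
    if "frame_times" in d:
        d["frame_times"] = np.asarray(d["frame_times"], dtype=float)
    for key in ("center", "near_band", "far_band"):
        if key in d:
            d[key] = tuple(float(v) for v in d[key])
    return BleachProtocol(**d)


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration, instantiating parameter objects.

    Recognized top-level keys: ``model``, ``geometry``, ``acquisition``,
    ``protocol``; everything else is passed through untouched.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = dict(raw)
    if "model" in raw:
        out["model"] = _model_from_dict(raw["model"])
    if "geometry" in raw:
        out["geometry"] = _geometry_from_dict(raw["geometry"])
    if "acquisition" in raw:
        out["acquisition"] = _settings_from_dict(raw["acquisition"])
    if "protocol" in raw:
        out["protocol"] = _protocol_from_dict(raw["protocol"])
    return out


def save_config(cfg: dict, path: str | Path) -> None:
    """Serialize a configuration (parameter objects back to plain YAML)."""
    out: dict = {}
    for key, val in cfg.items():
        if isinstance(val, KineticModel):
            out[key] = {
                "state_names": list(val.state_names),
                "D_state": [float(v) for v in val.D_state],
                "rate_matrix": np.asarray(val.rate_matrix).tolist(),
                "bleach_rate": val.bleach_rate,
                "blink_on": val.blink_on,
                "blink_off": val.blink_off,
                "loss_rate_defocus": val.loss_rate_defocus,
            }
        elif isinstance(val, NucleusGeometry):
            layout = val.site_layout
            if not isinstance(layout, str):
                layout = [np.asarray(l).tolist() for l in layout]
            out[key] = {
                "semi_axes": list(val.semi_axes),
                "site_layout": layout,
                "capture_distance": val.capture_distance,
            }
        elif isinstance(val, AcquisitionSettings):
            out[key] = {k: getattr(val, k) for k in (
                "dt", "exposure", "pixel_size", "sigma_loc", "psf_sigma",
                "photons_per_frame", "camera_offset", "camera_gain", "read_noise")}
        elif isinstance(val, BleachProtocol):
            out[key] = {
                "kind": val.kind,
                "center": list(val.center),
                "radius": val.radius,
                "edge_sigma": val.edge_sigma,
                "half_edge_x": val.half_edge_x,
                "n_prebleach": val.n_prebleach,
                "prebleach_dt": val.prebleach_dt,
                "frame_times": np.asarray(val.frame_times).tolist(),
                "near_band": list(val.near_band),
                "far_band": list(val.far_band),
            }
        else:
            out[key] = val
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)
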