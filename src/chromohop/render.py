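"""Render simulated molecules into camera frames.

Each frame integrates a pixel-integrated elliptical Gaussian PSF along the
sub-frame path of every visible molecule (motion blur over the exposure),
then applies a camera model: Poisson shot noise x gain + offset + Gaussian
read noise, quantized to 16 bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .models import AcquisitionSettings, ParameterError
from .simulate import SimulatedTracks

__all__ = ["RenderedMovie", "render_movie"]


@dataclass
class RenderedMovie:
    """16-bit movie stack plus the geometry needed to map pixels to µm.

    ``origin`` is the µm position of the image corner: a molecule at
    ``(x, y)`` µm appears at pixel column ``(x - origin[0]) / pixel_size``.
    """

    stack: np.ndarray              # (n_frames, ny, nx), uint16
    origin: tuple[float, float]    # µm
    settings: AcquisitionSettings

    def to_image_um(self, xy: np.ndarray) -> np.ndarray:
        """World µm -> image-frame µm (origin at the image corner)."""
        return np.asarray(xy, dtype=float) - np.asarray(self.origin)


def _pixel_gaussian(x0: float, y0: float, sx: float, sy: float,
                    cols: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Fraction of unit flux collected by each pixel (pixel-integrated PSF).

    Coordinates are in pixel units with pixel j spanning [j, j+1).
    """
    fx = 0.5 * (erf((cols + 1.0 - x0) / (np.sqrt(2) * sx))
                - erf((cols - x0) / (np.sqrt(2) * sx)))
    fy = 0.5 * (erf((rows + 1.0 - y0) / (np.sqrt(2) * sy))
                - erf((rows - y0) / (np.sqrt(2) * sy)))
    return np.outer(fy, fx)


def render_movie(
    sim: SimulatedTracks,
    seed: int = 0,
    shape: tuple[int, int] | None = None,
    margin: float = 1.0,
    noise: bool = True,
) -> RenderedMovie:
    """Render a simulated track set into a 16-bit movie stack.

    Requires the simulation to have been run with ``store_paths=True`` so
    the sub-frame path is available for motion blur.  With ``noise=False``
    the expectation image (in ADU, including offset) is returned, rounded.
    """
    s = sim.settings
    if s.photons_per_frame <= 0:
        raise ParameterError("photons_per_frame must be > 0")
    if sim.truth.paths is None:
        raise ParameterError("render_movie requires store_paths=True in simulate_tracks")

    p = s.pixel_size
    paths = sim.truth.paths  # (n_mol, n_sub+1, 2) in µm
    n_mol = paths.shape[0]
    n_substeps = sim.n_substeps
    n_frames = (paths.shape[1] - 1) // n_substeps
    n_exp = max(1, int(round(s.exposure / s.dt * n_substeps)))

    if shape is None:
        a, b = sim.geometry.semi_axes
        origin = (-a - margin, -b - margin)
        nx = int(np.ceil(2 * (a + margin) / p))
        ny = int(np.ceil(2 * (b + margin) / p))
    else:
        ny, nx = shape
        origin = (-nx * p / 2.0, -ny * p / 2.0)

    vis = sim.tracks.pivot(index="track_id", columns="frame", values="visible")
    vis = vis.reindex(range(n_mol)).to_numpy()

    sig_px = s.psf_sigma / p
    halfw = max(3, int(np.ceil(4 * sig_px)))
    rng = np.random.default_rng(seed)
    stack = np.empty((n_frames, ny, nx), dtype=np.uint16)
    photons_sub = s.photons_per_frame / n_exp

    for f in range(n_frames):
        expect = np.full((ny, nx), float(s.background_photons))
        for m in range(n_mol):
            if not vis[m, f]:
                continue
            for k in range(n_exp):
                x_um, y_um = paths[m, f * n_substeps + k]
                x0 = (x_um - origin[0]) / p
                y0 = (y_um - origin[1]) / p
                j0 = int(np.floor(x0))
                i0 = int(np.floor(y0))
                cols = np.arange(max(j0 - halfw, 0), min(j0 + halfw + 1, nx))
                rows = np.arange(max(i0 - halfw, 0), min(i0 + halfw + 1, ny))
                if cols.size == 0 or rows.size == 0:
                    continue
                expect[np.ix_(rows, cols)] += photons_sub * _pixel_gaussian(
                    x0, y0, sig_px, sig_px, cols, rows
                )
        if noise:
            img = rng.poisson(expect).astype(float) * s.camera_gain
            img += s.camera_offset
            img += s.read_noise * rng.standard_normal(img.shape)
        else:
            img = expect * s.camera_gain + s.camera_offset
        stack[f] = np.clip(np.round(img), 0, 65535).astype(np.uint16)

    return RenderedMovie(stack=stack, origin=origin, settings=s)
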