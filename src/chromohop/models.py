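"""Domain types for chromatin-binding kinetics simulations and inference.

The central object is a :class:`KineticModel`: a continuous-time Markov
chain over molecular states (free diffusion plus one or more chromatin-bound
states), with per-state diffusion coefficients and first-order transition
rates.  The two-state reduction (FREE <-> BOUND with pseudo-first-order
association rate ``k_on*`` and dissociation rate ``k_off``) has equilibrium
bound fraction ``k_on*/(k_on* + k_off)`` and residence time ``1/k_off``.

Geometry (:class:`NucleusGeometry`) is a 2-D elliptical nuclear
cross-section with reflecting boundary; binding sites are either uniform or
restricted to curvilinear paths (mimicking the worm-like cohesin axes,
"vermicelli", of Wapl-deficient cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KineticModel",
    "NucleusGeometry",
    "AcquisitionSettings",
    "BleachProtocol",
    "effective_diffusion",
    "FAST_SETTINGS",
    "SLOW_SETTINGS",
]


class ParameterError(ValueError):
    """Invalid kinetic/acquisition parameter."""


class GeometryError(ValueError):
    """Degenerate or inconsistent geometry."""


class ProtocolError(ValueError):
    """Inconsistent bleach protocol."""


class UnsupportedModelError(ValueError):
    """Operation requires a different state structure."""


@dataclass(frozen=True)
class KineticModel:
    """State-switching diffusion model.

    Parameters
    ----------
    state_names
        Labels, e.g. ``("FREE", "BOUND")``.
    D_state
        Diffusion coefficient per state in µm²/s (0 for bound states).
    rate_matrix
        Square array of off-diagonal transition rates in 1/s;
        ``rate_matrix[i, j]`` is the rate from state i to state j.
        The diagonal is ignored.
    bleach_rate
        Permanent fluorophore loss rate, 1/s.
    blink_on, blink_off
        Rates of the dark->on and on->dark photophysical telegraph, 1/s.
    loss_rate_defocus
        Permanent loss by axial escape from the focal plane, 1/s
        (modelled as an additional irreversible dark process).
    """

    state_names: tuple[str, ...]
    D_state: tuple[float, ...]
    rate_matrix: np.ndarray
    bleach_rate: float = 0.0
    blink_on: float = 0.0
    blink_off: float = 0.0
    loss_rate_defocus: float = 0.0

    def __post_init__(self) -> None:
        Q = np.asarray(self.rate_matrix, dtype=float)
        object.__setattr__(self, "rate_matrix", Q)
        n = len(self.state_names)
        if len(self.D_state) != n or Q.shape != (n, n):
            raise ParameterError("state_names, D_state and rate_matrix sizes disagree")
        off = Q[~np.eye(n, dtype=bool)]
        if np.any(off < 0):
            raise ParameterError("transition rates must be >= 0")
        if any(d < 0 for d in self.D_state):
            raise ParameterError("diffusion coefficients must be >= 0")
        for r in (self.bleach_rate, self.blink_on, self.blink_off, self.loss_rate_defocus):
            if r < 0:
                raise ParameterError("photophysical rates must be >= 0")

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def generator(self) -> np.ndarray:
        """Markov generator Q with diagonal -sum(off-diagonal row)."""
        Q = self.rate_matrix.copy()
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def stationary(self) -> np.ndarray:
        """Stationary distribution pi with pi @ Q = 0, sum(pi) = 1."""
        Q = self.generator()
        n = self.n_states
        A = np.vstack([Q.T, np.ones(n)])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()

    def bound_fraction(self) -> float:
        """Equilibrium probability of the zero-diffusion (bound) states."""
        pi = self.stationary()
        bound = np.asarray(self.D_state) == 0.0
        return float(pi[bound].sum())

    # -- constructors -----------------------------------------------------

    @classmethod
    def two_state(cls, D_free: float, k_on: float, k_off: float, **kw) -> "KineticModel":
        """FREE <-> BOUND model with pseudo-first-order rates."""
        if D_free < 0 or k_on < 0 or k_off < 0:
            raise ParameterError("rates and D_free must be >= 0")
        Q = np.array([[0.0, k_on], [k_off, 0.0]])
        return cls(("FREE", "BOUND"), (float(D_free), 0.0), Q, **kw)

    @classmethod
    def from_bound_fraction(
        cls, D_free: float, bound_fraction: float, residence_time: float, **kw
    ) -> "KineticModel":
        """Two-state model parameterized by its observables.

        ``k_off = 1/residence_time`` and
        ``k_on* = k_off * f_bound / (1 - f_bound)``.
        """
        if not 0.0 < bound_fraction < 1.0:
            raise ParameterError("bound_fraction must lie in (0, 1)")
        if residence_time <= 0:
            raise ParameterError("residence_time must be > 0")
        k_off = 1.0 / residence_time
        k_on = k_off * bound_fraction / (1.0 - bound_fraction)
        return cls.two_state(D_free, k_on, k_off, **kw)

    @classmethod
    def free_only(cls, D_free: float, **kw) -> "KineticModel":
        return cls(("FREE",), (float(D_free),), np.zeros((1, 1)), **kw)

    @classmethod
    def scc2_default(cls, **kw) -> "KineticModel":
        """Three-state default: FREE <-> TRANSIENT_BOUND, FREE <-> STABLE_BOUND.

        Parameterized to give ~37% total bound occupancy, a 55:45 ratio of
        transient to stable binding events, and residence half-lives of
        ~1 s (transient search binding) and ~47 s (stable, cohesin-like
        binding), with D_free = 0.6 µm²/s.
        """
        ln2 = np.log(2.0)
        tau_t = 1.0 / ln2          # transient residence, s (t1/2 = 1 s)
        tau_s = 47.0 / ln2         # stable residence, s (t1/2 = 47 s)
        # occupancies pi_t, pi_s with pi_t + pi_s = 0.37 and event ratio 55:45
        ratio = (55.0 / 45.0) * (tau_t / tau_s)
        pi_bound = 0.37
        pi_s = pi_bound / (1.0 + ratio)
        pi_t = pi_bound - pi_s
        pi_f = 1.0 - pi_bound
        k_on_t = pi_t / (pi_f * tau_t)
        k_on_s = pi_s / (pi_f * tau_s)
        Q = np.array(
            [
                [0.0, k_on_t, k_on_s],
                [1.0 / tau_t, 0.0, 0.0],
                [1.0 / tau_s, 0.0, 0.0],
            ]
        )
        return cls(("FREE", "TRANSIENT_BOUND", "STABLE_BOUND"), (0.6, 0.0, 0.0), Q, **kw)


def effective_diffusion(model: KineticModel) -> float:
    """Macroscopic ("punctuated"/hopping) diffusion coefficient.

    For a two-state model in the fast-exchange regime, repeated transient
    binding slows ensemble spreading to

        D_eff = D_free * k_off / (k_on* + k_off)

    i.e. D_free times the free (mobile) fraction.
    """
    if model.n_states != 2:
        raise UnsupportedModelError("effective_diffusion requires a two-state model")
    D = np.asarray(model.D_state)
    free = int(np.argmax(D))
    bound = 1 - free
    if D[bound] != 0.0:
        raise UnsupportedModelError("one state must be immobile (D = 0)")
    k_on = model.rate_matrix[free, bound]
    k_off = model.rate_matrix[bound, free]
    if k_on == 0.0:
        return float(D[free])
    return float(D[free] * k_off / (k_on + k_off))


@dataclass(frozen=True)
class NucleusGeometry:
    """2-D nuclear cross-section with reflecting elliptical boundary.

    ``site_layout`` is either ``"uniform"`` (binding anywhere) or a list of
    polylines (arrays of shape (k, 2) in µm) to which bound positions are
    snapped, emulating curvilinear cohesin axes.
    """

    semi_axes: tuple[float, float] = (8.0, 8.0)
    site_layout: object = "uniform"  # "uniform" or list of (k,2) polylines
    capture_distance: float = 0.05
    reflecting: bool = True

    _site_points: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            raise GeometryError("nucleus semi-axes must be > 0")
        if not isinstance(self.site_layout, str):
            pts = []
            for line in self.site_layout:
                line = np.asarray(line, dtype=float)
                # densify each polyline to ~50 nm spacing for nearest-site snapping
                for p, q in zip(line[:-1], line[1:]):
                    seg = np.linalg.norm(q - p)
                    k = max(int(np.ceil(seg / 0.05)), 1)
                    ts = np.linspace(0.0, 1.0, k + 1)[:-1]
                    pts.append(p[None, :] + ts[:, None] * (q - p)[None, :])
                pts.append(line[-1:][:])
            object.__setattr__(self, "_site_points", np.concatenate(pts, axis=0))

    @property
    def is_disc(self) -> bool:
        return self.semi_axes[0] == self.semi_axes[1]

    @property
    def radius(self) -> float:
        if not self.is_disc:
            raise GeometryError("radius is defined only for a circular nucleus")
        return self.semi_axes[0]

    def area(self) -> float:
        return float(np.pi * self.semi_axes[0] * self.semi_axes[1])

    def contains(self, xy: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        a, b = self.semi_axes
        r2 = (xy[..., 0] / a) ** 2 + (xy[..., 1] / b) ** 2
        return r2 <= 1.0 + atol

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform points inside the ellipse (rejection-free polar sampling)."""
        a, b = self.semi_axes
        u = np.sqrt(rng.uniform(size=n))
        th = rng.uniform(0.0, 2.0 * np.pi, size=n)
        return np.column_stack([a * u * np.cos(th), b * u * np.sin(th)])

    def reflect(self, xy: np.ndarray) -> np.ndarray:
        """Mirror-reflect overshooting points back inside the boundary.

        Works in the coordinate frame scaled to the unit disc; the radial
        overshoot is mirrored about the boundary.  Preserves a uniform
        equilibrium density for small steps.
        """
        xy = np.array(xy, dtype=float)
        a, b = self.semi_axes
        for _ in range(8):  # repeated reflection for very large overshoots
            u = xy[..., 0] / a
            v = xy[..., 1] / b
            r = np.sqrt(u * u + v * v)
            out = r > 1.0
            if not np.any(out):
                break
            scale = (2.0 - r[out]) / r[out]
            xy[out, 0] *= scale
            xy[out, 1] *= scale
        return xy

    def nearest_site(self, xy: np.ndarray) -> np.ndarray:
        """Nearest binding-site position for each query point."""
        if isinstance(self.site_layout, str):
            return np.asarray(xy, dtype=float)
        from scipy.spatial import cKDTree

        tree = cKDTree(self._site_points)
        _, idx = tree.query(np.atleast_2d(xy))
        return self._site_points[idx]


@dataclass(frozen=True)
class AcquisitionSettings:
    """Camera and optics parameters of one imaging regime.

    The fast regime (15 ms exposure at 64.5 frames/s) resolves diffusing
    molecules; the slow regime (1 s exposure at 1 frame/s) blurs them out
    and keeps only stationary, chromatin-bound spots.
    """

    dt: float = 1.0 / 64.5          # frame interval, s
    exposure: float = 0.015         # s
    pixel_size: float = 0.096       # µm
    sigma_loc: float = 0.025        # localization precision, µm
    psf_sigma: float = 0.11         # PSF Gaussian sd, µm
    photons_per_frame: float = 500.0
    background_photons: float = 200.0  # cellular autofluorescence, per px/frame
    camera_offset: float = 100.0    # ADU
    camera_gain: float = 2.0        # ADU / photoelectron
    read_noise: float = 2.0         # ADU rms

    def __post_init__(self) -> None:
        if self.exposure > self.dt * (1 + 1e-12):
            raise ParameterError("exposure must not exceed the frame interval")
        for name in ("dt", "exposure", "pixel_size", "psf_sigma",
                     "photons_per_frame", "camera_gain"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if (self.sigma_loc < 0 or self.read_noise < 0 or self.camera_offset < 0
                or self.background_photons < 0):
            raise ParameterError(
                "sigma_loc, read_noise, camera_offset, background_photons must be >= 0"
            )


FAST_SETTINGS = AcquisitionSettings()
SLOW_SETTINGS = AcquisitionSettings(dt=1.0, exposure=1.0, photons_per_frame=400.0,
                                    background_photons=50.0)


@dataclass(frozen=True)
class BleachProtocol:
    """FRAP bleach geometry and sampling schedule.

    ``kind`` is ``"disc"`` (circular spot of given radius, Gaussian edge)
    or ``"half"`` (bleach the half-plane x < x_edge through the nucleus).
    Times are seconds relative to the bleach event (prebleach < 0).
    """

    kind: str = "disc"
    center: tuple[float, float] = (0.0, 0.0)
    radius: float = 1.25            # µm; 2.5 µm bleach circle diameter
    edge_sigma: float = 0.25        # µm, Gaussian smoothing of the bleach edge
    half_edge_x: float = 0.0        # µm, for kind="half": bleach x < half_edge_x
    n_prebleach: int = 10
    prebleach_dt: float = 0.5
    frame_times: np.ndarray = field(default_factory=lambda: np.arange(0.25, 120.0, 0.25))
    near_band: tuple[float, float] = (0.0, 2.0)   # distance from bleach edge, µm
    far_band: tuple[float, float] = (4.0, 8.0)
    # optional annular readout zones (disc protocols): (r0, r1) pairs from the
    # bleach centre; they resolve the whole spatial redistribution (spot
    # recovery plus loss from unbleached zones), not just the spot mean
    readout_annuli: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("disc", "half"):
            raise ProtocolError("kind must be 'disc' or 'half'")
        if self.kind == "disc" and self.radius <= 0:
            raise ProtocolError("bleach radius must be > 0")
        if self.n_prebleach < 1:
            raise ProtocolError("need at least one prebleach frame")
        object.__setattr__(self, "frame_times", np.asarray(self.frame_times, dtype=float))

    def all_times(self) -> np.ndarray:
        """Prebleach plus postbleach sample times (s, bleach at t=0)."""
        pre = -self.prebleach_dt * np.arange(self.n_prebleach, 0, -1)
        return np.concatenate([pre, self.frame_times])

    def bleach_survival(self, xy: np.ndarray) -> np.ndarray:
        """Probability that a fluorophore at ``xy`` survives the bleach pulse."""
        from scipy.special import erf

        xy = np.atleast_2d(xy)
        if self.kind == "disc":
            r = np.hypot(xy[:, 0] - self.center[0], xy[:, 1] - self.center[1])
            d = r - self.radius
        else:
            d = xy[:, 0] - self.half_edge_x
        if self.edge_sigma == 0:
            return (d > 0).astype(float)
        return 0.5 * (1.0 + erf(d / (np.sqrt(2.0) * self.edge_sigma)))

    def validate_against(self, geometry: NucleusGeometry) -> None:
        if self.kind == "disc":
            c = np.asarray(self.center)
            if not geometry.contains(c[None, :])[0]:
                raise ProtocolError("bleach region lies outside the nucleus")
            if geometry.is_disc and self.radius > geometry.radius:
                raise ProtocolError("bleach spot larger than the nucleus")
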