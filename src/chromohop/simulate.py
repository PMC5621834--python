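"""Stochastic simulation of state-switching diffusing molecules.

Molecules follow a continuous-time Markov chain over the states of a
:class:`~chromohop.models.KineticModel`; in the free state they perform
Brownian motion (per-substep displacement sd ``sqrt(2 D dt_sub)`` per axis)
reflected at the nuclear boundary, and in bound states they are stationary
(snapped to the nearest binding-site path for curvilinear layouts).
Observed positions are exposure-averaged true positions plus isotropic
Gaussian localization noise.  Fluorescence is lost permanently at an
exponential bleach time (and defocus-escape time) and transiently during
blink-off periods; dark molecules keep moving and binding — only their
fluorescence is removed.

Everything is reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import (
    AcquisitionSettings,
    BleachProtocol,
    GeometryError,
    KineticModel,
    NucleusGeometry,
    ParameterError,
)

__all__ = [
    "GroundTruth",
    "SimulatedTracks",
    "simulate_tracks",
    "simulate_mixture_tracks",
    "simulate_dwell_times",
    "simulate_frap",
    "synthesize_biexp_curves",
]


@dataclass
class GroundTruth:
    """Per-molecule truth: state timeline, loss times, true sub-frame paths."""

    segments: pd.DataFrame            # molecule, state, t_start, t_end
    bleach_time: np.ndarray           # s, inf if never
    defocus_time: np.ndarray
    paths: np.ndarray | None          # (n_mol, n_substeps_total + 1, 2), µm
    substep_times: np.ndarray | None  # (n_substeps_total + 1,), s


@dataclass
class SimulatedTracks:
    """Simulation output: observed track table plus ground truth."""

    tracks: pd.DataFrame
    truth: GroundTruth
    model: KineticModel
    geometry: NucleusGeometry
    settings: AcquisitionSettings
    n_substeps: int


def _gillespie_timeline(model: KineticModel, duration: float,
                        rng: np.random.Generator) -> tuple[list, int]:
    """Exact state timeline for one molecule on [0, duration]."""
    Q = model.rate_matrix
    n = model.n_states
    exit_rates = np.array([Q[i].sum() - Q[i, i] for i in range(n)])
    pi = model.stationary()
    state = int(rng.choice(n, p=pi))
    segs = []
    t = 0.0
    while t < duration:
        rate = exit_rates[state]
        dt = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        t_end = min(t + dt, duration)
        segs.append((state, t, t_end))
        if t + dt >= duration:
            break
        probs = Q[state].copy()
        probs[state] = 0.0
        probs = probs / probs.sum()
        state = int(rng.choice(n, p=probs))
        t = t_end
    return segs, state


def simulate_tracks(
    model: KineticModel,
    geometry: NucleusGeometry,
    settings: AcquisitionSettings,
    n_molecules: int,
    duration: float,
    seed: int,
    n_substeps: int = 20,
    store_paths: bool = False,
) -> SimulatedTracks:
    """Simulate observed single-molecule tracks under the kinetic model.

    Parameters
    ----------
    n_substeps
        Sub-frame integration steps per frame, used for motion and
        (optionally stored) blur paths.
    store_paths
        Keep the full sub-frame true positions in the ground truth;
        required for :func:`render_movie`.
    """
    if n_molecules < 1:
        raise ParameterError("n_molecules must be >= 1")
    if duration < settings.dt:
        raise ParameterError("duration must cover at least one frame")
    if geometry.area() <= 0:
        raise GeometryError("nucleus has zero area")

    rng = np.random.default_rng(seed)
    n_frames = int(round(duration / settings.dt))
    dt_sub = settings.dt / n_substeps
    n_sub_total = n_frames * n_substeps
    n_exp = max(1, int(round(settings.exposure / settings.dt * n_substeps)))

    # -- exact state timelines (Gillespie), then rasterized per substep ----
    seg_rows = []
    state_sub = np.empty((n_molecules, n_sub_total), dtype=np.int8)
    sub_mid = (np.arange(n_sub_total) + 0.5) * dt_sub
    for m in range(n_molecules):
        segs, _ = _gillespie_timeline(model, duration, rng)
        for s, t0, t1 in segs:
            seg_rows.append((m, model.state_names[s], t0, t1))
        bounds = np.array([t1 for _, _, t1 in segs])
        states = np.array([s for s, _, _ in segs], dtype=np.int8)
        state_sub[m] = states[np.searchsorted(bounds, sub_mid, side="right").clip(max=len(states) - 1)]
    segments = pd.DataFrame(seg_rows, columns=["molecule", "state", "t_start", "t_end"])

    # -- photophysics ------------------------------------------------------
    def _exp_or_inf(rate: float) -> np.ndarray:
        if rate > 0:
            return rng.exponential(1.0 / rate, size=n_molecules)
        return np.full(n_molecules, np.inf)

    bleach_time = _exp_or_inf(model.bleach_rate)
    defocus_time = _exp_or_inf(model.loss_rate_defocus)
    blink_on_frame = _blink_visibility(model, n_molecules, n_frames, settings.dt, rng)

    # -- positions ---------------------------------------------------------
    D = np.asarray(model.D_state)
    bound_state = D == 0.0
    pos = geometry.sample_uniform(n_molecules, rng)
    curvi = not isinstance(geometry.site_layout, str)
    init_bound = bound_state[state_sub[:, 0]]
    if curvi and np.any(init_bound):
        pos[init_bound] = geometry.nearest_site(pos[init_bound])

    paths = None
    if store_paths:
        paths = np.empty((n_molecules, n_sub_total + 1, 2), dtype=np.float32)
        paths[:, 0] = pos

    exp_sum = np.zeros((n_molecules, 2))
    obs = np.empty((n_molecules, n_frames, 2))
    prev_state = state_sub[:, 0]
    for k in range(n_sub_total):
        st = state_sub[:, k]
        if curvi:
            newly_bound = bound_state[st] & ~bound_state[prev_state]
            if np.any(newly_bound):
                pos[newly_bound] = geometry.nearest_site(pos[newly_bound])
        in_frame = k % n_substeps
        if in_frame < n_exp:
            exp_sum += pos
        sd = np.sqrt(2.0 * D[st] * dt_sub)
        pos = pos + sd[:, None] * rng.standard_normal((n_molecules, 2))
        pos = geometry.reflect(pos)
        if store_paths:
            paths[:, k + 1] = pos
        if in_frame == n_substeps - 1:
            f = k // n_substeps
            obs[:, f] = exp_sum / n_exp
            exp_sum[:] = 0.0
        prev_state = st

    if settings.sigma_loc > 0:
        obs = obs + settings.sigma_loc * rng.standard_normal(obs.shape)

    # -- observed table ----------------------------------------------------
    frame_t = np.arange(n_frames) * settings.dt
    vis = (
        (frame_t[None, :] < bleach_time[:, None])
        & (frame_t[None, :] < defocus_time[:, None])
        & blink_on_frame
    )
    mol_idx = np.repeat(np.arange(n_molecules), n_frames)
    frames = np.tile(np.arange(n_frames), n_molecules)
    state_at_frame = state_sub[:, ::n_substeps]
    tracks = pd.DataFrame(
        {
            "track_id": mol_idx,
            "frame": frames,
            "t_s": frame_t[frames],
            "x_um": obs[:, :, 0].ravel(),
            "y_um": obs[:, :, 1].ravel(),
            "state": np.asarray(model.state_names)[state_at_frame.ravel()],
            "visible": vis.ravel().astype(np.int8),
        }
    )
    truth = GroundTruth(
        segments=segments,
        bleach_time=bleach_time,
        defocus_time=defocus_time,
        paths=paths,
        substep_times=np.arange(n_sub_total + 1) * dt_sub if store_paths else None,
    )
    return SimulatedTracks(tracks, truth, model, geometry, settings, n_substeps)


def _blink_visibility(model: KineticModel, n_mol: int, n_frames: int,
                      dt: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean (n_mol, n_frames) on/off telegraph sampled at frame starts."""
    if model.blink_off <= 0:
        return np.ones((n_mol, n_frames), dtype=bool)
    frame_t = np.arange(n_frames) * dt
    vis = np.ones((n_mol, n_frames), dtype=bool)
    p_on = model.blink_on / (model.blink_on + model.blink_off) if model.blink_on > 0 else 1.0
    duration = n_frames * dt
    for m in range(n_mol):
        initial_on = bool(rng.uniform() < p_on)
        on = initial_on
        t = 0.0
        toggles = []
        while t < duration:
            rate = model.blink_off if on else model.blink_on
            if rate <= 0:
                break
            t += rng.exponential(1.0 / rate)
            toggles.append(t)
            on = not on
        # on/off at a frame time = initial state XOR parity of prior toggles
        n_tog = np.searchsorted(np.asarray(toggles), frame_t, side="right")
        vis[m] = np.where(n_tog % 2 == 0, initial_on, not initial_on)
    return vis


def simulate_mixture_tracks(
    n_tracks: int,
    immobile_fraction: float,
    D_mobile: float,
    settings: AcquisitionSettings,
    mean_frames: float = 9.0,
    min_steps: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Two-population track mixture at the observation level.

    Draws track lengths from a shifted geometric distribution (mean
    ``mean_frames`` localizations, minimum ``min_steps + 1``), emulating
    stochastic blinking/bleaching-limited track durations.  Immobile tracks
    are a fixed point plus localization noise; mobile tracks are Brownian
    paths sampled at frame times plus noise.  Returns the track table and
    the true immobile labels.
    """
    if not 0.0 <= immobile_fraction <= 1.0:
        raise ParameterError("immobile_fraction must be in [0, 1]")
    mean_excess = mean_frames - (min_steps + 1)
    if mean_excess < 0:
        raise ParameterError("mean_frames must exceed min_steps + 1")
    rng = np.random.default_rng(seed)
    # shifted geometric: n_locs = min_steps + Geom(p), E = min_steps + 1/p
    p = 1.0 / (mean_excess + 1.0)
    n_locs = min_steps + rng.geometric(p, size=n_tracks)
    immobile = rng.uniform(size=n_tracks) < immobile_fraction

    rows_id, rows_frame, xs, ys = [], [], [], []
    sd_step = np.sqrt(2.0 * D_mobile * settings.dt)
    for i in range(n_tracks):
        n = int(n_locs[i])
        if immobile[i]:
            x = np.zeros(n)
            y = np.zeros(n)
        else:
            x = np.concatenate([[0.0], np.cumsum(sd_step * rng.standard_normal(n - 1))])
            y = np.concatenate([[0.0], np.cumsum(sd_step * rng.standard_normal(n - 1))])
        x = x + settings.sigma_loc * rng.standard_normal(n)
        y = y + settings.sigma_loc * rng.standard_normal(n)
        rows_id.append(np.full(n, i))
        rows_frame.append(np.arange(n))
        xs.append(x)
        ys.append(y)
    frame = np.concatenate(rows_frame)
    tracks = pd.DataFrame(
        {
            "track_id": np.concatenate(rows_id),
            "frame": frame,
            "t_s": frame * settings.dt,
            "x_um": np.concatenate(xs),
            "y_um": np.concatenate(ys),
            "state": np.where(np.repeat(immobile, n_locs), "BOUND", "FREE"),
            "visible": np.int8(1),
        }
    )
    return tracks, immobile


def simulate_dwell_times(
    n: int,
    fractions: tuple[float, float],
    half_lives: tuple[float, float],
    t_bleach: float,
    seed: int = 0,
    movie_span: float | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Observed dwell times: true binding mixture censored by observation loss.

    True binding durations are drawn from a two-component exponential
    mixture (``half_lives`` are half-lives, tau = t1/2 / ln 2); each is
    censored by an independent exponential loss process with time constant
    ``t_bleach`` (photobleaching/blinking/defocus), and optionally by the
    end of the movie.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    f1, f2 = fractions
    if not np.isclose(f1 + f2, 1.0):
        raise ParameterError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    taus = np.asarray(half_lives) / np.log(2.0)
    comp = (rng.uniform(size=n) >= f1).astype(int)
    true_dwell = rng.exponential(taus[comp])
    loss = rng.exponential(t_bleach, size=n)
    observed = np.minimum(true_dwell, loss)
    if movie_span is not None:
        observed = np.minimum(observed, movie_span)
    truth = pd.DataFrame({"component": comp, "true_dwell": true_dwell, "loss": loss})
    return observed, truth


# ---------------------------------------------------------------------------
# FRAP particle simulation
# ---------------------------------------------------------------------------

def simulate_frap(
    model: KineticModel,
    geometry: NucleusGeometry,
    protocol: BleachProtocol,
    n_molecules: int,
    seed: int,
    dt_sub: float = 0.02,
    normalize: str = "prebleach",
):
    """Particle-based FRAP: molecules keep switching and moving; the bleach
    pulse at t=0 permanently darkens molecules inside the bleach region
    (with the protocol's smooth edge profile).  Per-zone fluorescent counts
    are normalized as the zone/unbleached count ratio divided by its
    prebleach level.

    ``normalize="prebleach"`` divides by the measured prebleach mean ratio,
    exactly like experimental curves.  ``normalize="area"`` divides by the
    exact zone/unbleached area ratio instead: for synthetic data the areas
    are known, and the measured prebleach mean is a noisy estimate of that
    same quantity (its counting error is correlated over the binding
    residence time and rescales the whole curve, biasing kinetic fits).
    ``normalize="expected"`` reports zone count over its expected
    equilibrium count ``n_molecules * area_fraction`` — per-zone curves with
    independent counting noise, suited to joint spatial fitting.
    """
    if normalize not in ("prebleach", "area", "expected"):
        raise ParameterError("normalize must be 'prebleach', 'area' or 'expected'")
    from .frap import FrapCurve, FrapCurveSet

    protocol.validate_against(geometry)
    if n_molecules < 1:
        raise ParameterError("n_molecules must be >= 1")

    rng = np.random.default_rng(seed)
    times = protocol.all_times()
    t0, t_end = times[0], times[-1]

    n = n_molecules
    Q = model.rate_matrix
    nS = model.n_states
    D = np.asarray(model.D_state)
    bound_state = D == 0.0
    exit_rate = np.array([Q[i].sum() - Q[i, i] for i in range(nS)])
    p_leave = 1.0 - np.exp(-exit_rate * dt_sub)

    pos = geometry.sample_uniform(n, rng)
    state = rng.choice(nS, size=n, p=model.stationary())
    curvi = not isinstance(geometry.site_layout, str)
    if curvi:
        b = bound_state[state]
        pos[b] = geometry.nearest_site(pos[b])
    fluor = np.ones(n, dtype=bool)
    if model.bleach_rate > 0:
        acq_bleach = t0 + rng.exponential(1.0 / model.bleach_rate, size=n)
    else:
        acq_bleach = np.full(n, np.inf)

    zones = _zone_masks_fn(protocol)
    counts = {z: np.empty(len(times)) for z in zones}

    n_steps = int(np.ceil((t_end - t0) / dt_sub))
    sample_idx = 0
    bleached_applied = False
    t = t0
    for k in range(n_steps + 1):
        # bleach pulse fires the moment t crosses 0
        if not bleached_applied and t >= -1e-12:
            surv = protocol.bleach_survival(pos)
            fluor &= rng.uniform(size=n) < surv
            bleached_applied = True
        # record all sample times passed
        while sample_idx < len(times) and times[sample_idx] <= t + 1e-12:
            ts = times[sample_idx]
            lit = fluor & (acq_bleach > ts)
            for z, mask_fn in zones.items():
                counts[z][sample_idx] = np.count_nonzero(lit & mask_fn(pos))
            sample_idx += 1
        if sample_idx >= len(times):
            break
        # advance one substep
        leave = rng.uniform(size=n) < p_leave[state]
        if np.any(leave):
            idx = np.nonzero(leave)[0]
            for i in idx:
                probs = Q[state[i]].copy()
                probs[state[i]] = 0.0
                state[i] = _choice_from(probs, rng)
            if curvi:
                nb = bound_state[state[idx]]
                if np.any(nb):
                    pos[idx[nb]] = geometry.nearest_site(pos[idx[nb]])
        sd = np.sqrt(2.0 * D[state] * dt_sub)
        moving = sd > 0
        if np.any(moving):
            pos[moving] += sd[moving, None] * rng.standard_normal((int(moving.sum()), 2))
            pos = geometry.reflect(pos)
        t += dt_sub

    # -- normalization -----------------------------------------------------
    pre = times < 0
    unb = counts["UNBLEACHED"]
    fracs = _zone_area_fracs(protocol, geometry) if normalize != "prebleach" else {}
    curves = {}
    for z in zones:
        if z == "UNBLEACHED":
            continue
        if normalize == "expected":
            norm = counts[z] / (n * fracs[z])
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = counts[z] / unb
            ratio[~np.isfinite(ratio)] = 0.0
            if normalize == "area":
                pre_mean = fracs[z] / fracs["UNBLEACHED"]
            else:
                pre_mean = ratio[pre].mean()
            norm = ratio / pre_mean if pre_mean > 0 else ratio
        curves[z] = FrapCurve(
            t=times.copy(), intensity_norm=norm, zone=z,
            n_prebleach=protocol.n_prebleach, protocol=protocol,
        )
    return FrapCurveSet(curves=curves, counts=pd.DataFrame({"t_s": times, **counts}))


def _zone_area_fracs(protocol: BleachProtocol, geometry: NucleusGeometry,
                     n_grid: int = 2000) -> dict[str, float]:
    """Zone area fractions of the nucleus, by deterministic grid quadrature."""
    a, b = geometry.semi_axes
    xs = np.linspace(-a, a, n_grid)
    ys = np.linspace(-b, b, n_grid)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    inside = (X / a) ** 2 + (Y / b) ** 2 <= 1.0
    pts = np.column_stack([X[inside], Y[inside]])
    zones = _zone_masks_fn(protocol)
    total = float(len(pts))
    return {z: float(np.count_nonzero(fn(pts))) / total for z, fn in zones.items()}


def _choice_from(weights: np.ndarray, rng: np.random.Generator) -> int:
    c = np.cumsum(weights)
    return int(np.searchsorted(c, rng.uniform() * c[-1], side="right"))


def _zone_masks_fn(protocol: BleachProtocol):
    """Zone membership predicates for a bleach protocol."""
    if protocol.kind == "disc":
        cx, cy = protocol.center
        R = protocol.radius

        def in_disc(xy):
            return np.hypot(xy[:, 0] - cx, xy[:, 1] - cy) <= R

        zones = {"BLEACH": in_disc, "UNBLEACHED": lambda xy: ~in_disc(xy)}
        if protocol.readout_annuli:
            for i, (r0, r1) in enumerate(protocol.readout_annuli):
                def in_ann(xy, r0=r0, r1=r1):
                    r = np.hypot(xy[:, 0] - cx, xy[:, 1] - cy)
                    return (r >= r0) & (r < r1)

                zones[f"ANN{i}"] = in_ann
        return zones
    edge = protocol.half_edge_x
    n0, n1 = protocol.near_band
    f0, f1 = protocol.far_band

    def near(xy):
        d = edge - xy[:, 0]
        return (d >= n0) & (d < n1)

    def far(xy):
        d = edge - xy[:, 0]
        return (d >= f0) & (d < f1)

    return {
        "BLEACH": lambda xy: xy[:, 0] < edge,
        "NEAR": near,
        "FAR": far,
        "UNBLEACHED": lambda xy: xy[:, 0] >= edge,
    }


def synthesize_biexp_curves(
    times: np.ndarray,
    amplitudes: tuple[float, float],
    half_lives: tuple[float, float],
    f0: float | None = None,
    noise_sd: float = 0.01,
    n_curves: int = 14,
    seed: int = 0,
) -> list[np.ndarray]:
    """Noisy spot-FRAP recovery curves from a two-component exponential model.

    F(t) = F0 + A1 (1 - exp(-ln2 t / t_half1)) + A2 (1 - exp(-ln2 t / t_half2)),
    with Gaussian noise of sd ``noise_sd`` (fraction of the plateau).
    """
    rng = np.random.default_rng(seed)
    a1, a2 = amplitudes
    h1, h2 = half_lives
    if f0 is None:
        f0 = max(0.0, 1.0 - a1 - a2)
    k1, k2 = np.log(2.0) / h1, np.log(2.0) / h2
    t = np.asarray(times, dtype=float)
    mean = f0 + a1 * (1.0 - np.exp(-k1 * t)) + a2 * (1.0 - np.exp(-k2 * t))
    return [mean + noise_sd * rng.standard_normal(t.size) for _ in range(n_curves)]
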