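"""Synthetic data generators with ground truth for every pipeline input.

Each generator emulates one class of input the pipeline consumes —
dual-area trial-structured event/fluorescence sessions with a shared
latent cluster process, soma/bouton sets driven by parent spike trains,
Gaussian-blob bead stacks, and lever-task behavior logs — and returns
the latent causes alongside the observables so that every analysis
stage has a parameter-recovery test.

The dual-area session model: per trial, the first area draws a latent
cluster identity uniformly from k clusters; the second area copies it
with probability ``coupling`` and redraws uniformly otherwise.  Neurons
are tuned each to one preferred cluster; their Poisson event rate in
the movement window is baseline + movement gain + cluster gain when the
trial's cluster matches their preference, perturbed by trial-level rate
noise.  Events live on a 30 Hz master grid; each field is then sampled
on its own 5.4 Hz clock (the two clocks interleaved half a period
apart, union rate 10.8 Hz), and fluorescence is events convolved with a
single-exponential calcium kernel (decay 1.40 s / 1.22 s per area) plus
Gaussian noise.  Defaults mirror a typical imaging session: 65 analysed
trials, ~10 latent clusters, 40 neurons per area, rates set so that
same-area trial-to-trial population correlations are low (~0.1), as
observed in motor cortex during this task.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behavior import BehaviorLog
from .traces import EventMatrix, TraceMatrix


class SyntheticError(ValueError):
    """Infeasible generator parameters."""


@dataclass(frozen=True)
class SessionSpec:
    """Conditions of a synthetic dual-area session."""

    n_neurons: int = 40            # per area
    n_trials: int = 65
    k_clusters: int = 10
    coupling: float = 0.5          # P(area-B cluster == area-A cluster)
    baseline_rate_hz: float = 0.15
    movement_gain_hz: float = 0.8  # added to every neuron in the window
    cluster_gain_hz: float = 2.5   # peak tuning gain at zero ring distance
    tuning_width: float = 0.8      # s.d. of the ring tuning kernel (clusters)
    excitability_sd: float = 0.2   # per-trial multiplicative gain on the
                                   # movement response, shared within an area
    rate_noise_hz: float = 0.25    # trial-level rate jitter per neuron
    tau_s: tuple[float, float] = (1.40, 1.22)  # calcium decay per area
    fluor_noise_sd: float = 0.05
    native_rate_hz: float = 30.0
    field_rate_hz: float = 5.4
    move_window_s: tuple[float, float] = (-0.46, 1.85)
    inter_onset_s: tuple[float, float] = (6.0, 7.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling <= 1.0:
            raise SyntheticError("coupling must be in [0, 1]")
        if min(self.tau_s) <= 0:
            raise SyntheticError("calcium decay taus must be positive")
        peak = self.baseline_rate_hz + self.movement_gain_hz + self.cluster_gain_hz
        if peak >= self.native_rate_hz:
            raise SyntheticError("peak event rate exceeds the native frame rate")


@dataclass(frozen=True)
class GroundTruth:
    """Latent causes of one synthetic session."""

    cluster_ids: dict[str, np.ndarray]        # per area, per trial
    preferred_cluster: dict[str, np.ndarray]  # per area, per neuron
    onset_times: np.ndarray
    parentage: dict[int, list[int]] = field(default_factory=dict)
    behavior_archetypes: np.ndarray | None = None


@dataclass(frozen=True)
class AreaData:
    """Observables for one area of a synthetic session."""

    events_native: EventMatrix    # 30 Hz master grid
    events_field: EventMatrix     # per-field acquisition clock
    fluorescence: TraceMatrix     # per-field clock, convolved + noise


def _poisson_amplitude_events(
    rng: np.random.Generator, rates_hz: np.ndarray, dt: float
) -> np.ndarray:
    """Impulse trains: Bernoulli occupancy x Gamma amplitude (mean 1)."""
    occupancy = rng.random(rates_hz.shape) < rates_hz * dt
    amplitudes = rng.gamma(shape=4.0, scale=0.25, size=rates_hz.shape)
    return np.where(occupancy, amplitudes, 0.0)


def _bin_to_clock(
    values: np.ndarray, native_times: np.ndarray, clock: np.ndarray
) -> np.ndarray:
    """Sum native-grid event amplitudes into the acquisition-frame bins."""
    edges = np.concatenate([[native_times[0] - 1.0], clock])
    idx = np.searchsorted(edges, native_times, side="right") - 1
    out = np.zeros((values.shape[0], clock.size))
    valid = (idx >= 0) & (idx < clock.size)
    np.add.at(out.T, idx[valid], values[:, valid].T)
    return out


def _convolve_calcium(
    events: np.ndarray, dt: float, tau_s: float
) -> np.ndarray:
    from scipy.signal import lfilter

    decay = np.exp(-dt / tau_s)
    return lfilter([1.0], [1.0, -decay], events, axis=1)


def gen_dual_area_session(spec: SessionSpec, onset_times: np.ndarray | None = None):
    """One synthetic dual-area session.

    Returns ``(areas, truth)`` with ``areas`` a dict mapping "RFA"/"CFA"
    to :class:`AreaData` and ``truth`` the :class:`GroundTruth`.  The
    two field clocks interleave half a frame period apart, so their
    union clock runs at twice the per-field rate.  ``onset_times``
    overrides the internally drawn trial onsets (e.g. with pull onsets
    from a generated behavior log); it must then match ``spec.n_trials``.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.k_clusters

    # trial onsets
    if onset_times is None:
        gaps = rng.uniform(*spec.inter_onset_s, size=spec.n_trials)
        onsets = 5.0 + np.cumsum(gaps)
    else:
        onsets = np.sort(np.asarray(onset_times, dtype=float))
        if onsets.size != spec.n_trials:
            raise SyntheticError("onset_times must match spec.n_trials")
        if onsets[0] + spec.move_window_s[0] - 3.0 < 0:
            raise SyntheticError("first onset too early for the rest window")
    duration = onsets[-1] + 5.0
    dt = 1.0 / spec.native_rate_hz
    native_times = np.arange(int(round(duration / dt))) * dt

    # latent cluster identities
    ids_a = rng.integers(0, k, size=spec.n_trials)
    copy = rng.random(spec.n_trials) < spec.coupling
    ids_b = np.where(copy, ids_a, rng.integers(0, k, size=spec.n_trials))

    truth_ids = {"RFA": ids_a, "CFA": ids_b}
    preferred = {
        area: np.arange(spec.n_neurons) % k for area in ("RFA", "CFA")
    }
    # heterogeneous per-neuron movement responses: the fixed pattern shared
    # by all trials is what gives real sessions their small positive mean
    # trial-to-trial CC (a uniform response would cancel in across-cell
    # Pearson CCs)
    move_gain = {
        area: rng.uniform(0.25, 1.75, size=spec.n_neurons) * spec.movement_gain_hz
        for area in ("RFA", "CFA")
    }

    in_window = np.zeros((spec.n_trials, native_times.size), dtype=bool)
    for t, onset in enumerate(onsets):
        in_window[t] = (native_times >= onset + spec.move_window_s[0]) & (
            native_times <= onset + spec.move_window_s[1]
        )
    areas: dict[str, AreaData] = {}
    field_period = 1.0 / spec.field_rate_hz
    for a_idx, area in enumerate(("RFA", "CFA")):
        cluster_of_trial = truth_ids[area]
        pref = preferred[area]
        rates = np.full((spec.n_neurons, native_times.size), spec.baseline_rate_hz)
        for t in range(spec.n_trials):
            # ring tuning: cluster identities index movement variants on a
            # continuum shared by both areas, so nearby clusters recruit
            # overlapping neurons and inter-cluster distances carry a
            # geometry the areas can agree on
            ring = np.minimum(
                np.abs(pref - cluster_of_trial[t]),
                k - np.abs(pref - cluster_of_trial[t]),
            )
            kernel = np.exp(-(ring**2) / (2.0 * spec.tuning_width**2))
            excit = 1.0 + rng.normal(0.0, spec.excitability_sd)
            boost = move_gain[area] * excit
            boost = boost + spec.cluster_gain_hz * kernel
            boost += rng.normal(0.0, spec.rate_noise_hz, size=spec.n_neurons)
            rates[:, in_window[t]] += np.clip(boost, 0.0, None)[:, None]
        events = _poisson_amplitude_events(rng, rates, dt)
        events_native = EventMatrix(
            values=events, frame_rate=spec.native_rate_hz, timestamps=native_times
        )
        clock = np.arange(a_idx * field_period / 2.0, duration, field_period)
        clock = clock[clock <= native_times[-1]]
        binned = _bin_to_clock(events, native_times, clock)
        events_field = EventMatrix(
            values=binned, frame_rate=spec.field_rate_hz, timestamps=clock
        )
        fluor_native = _convolve_calcium(events, dt, spec.tau_s[a_idx])
        fluor = np.empty((spec.n_neurons, clock.size))
        for i in range(spec.n_neurons):
            fluor[i] = np.interp(clock, native_times, fluor_native[i])
        fluor += rng.normal(0.0, spec.fluor_noise_sd, size=fluor.shape)
        fluorescence = TraceMatrix(
            values=fluor, frame_rate=spec.field_rate_hz, timestamps=clock
        )
        areas[area] = AreaData(
            events_native=events_native,
            events_field=events_field,
            fluorescence=fluorescence,
        )

    truth = GroundTruth(
        cluster_ids=truth_ids, preferred_cluster=preferred, onset_times=onsets
    )
    return areas, truth


def gen_soma_axon_session(
    n_parents: int = 3,
    boutons_per_parent: int = 7,
    n_background: int = 30,
    rate_hz: float = 0.3,
    jitter_s: float = 0.06,
    amplitude_cv: float = 0.5,
    transmission: float = 0.85,
    background_rate_hz: float = 0.3,
    independent_rate_hz: float = 0.05,
    duration_s: float = 600.0,
    frame_rate_hz: float = 30.0,
    movie_shape: tuple[int, int] = (64, 64),
    movie_duration_s: float | None = 60.0,
    movie_noise_sd: float = 0.1,
    tau_s: float = 1.22,
    seed: int = 0,
):
    """Parent somata, their axonal boutons, and a rendered bouton movie.

    Each parent soma's spike train is copied to its boutons with timing
    jitter, amplitude variation (CV), and release failures (probability
    ``1 - transmission``); a ``independent_rate_hz`` of extra events per
    bouton breaks perfect dependence.  Background boutons fire
    independently.  The movie renders every bouton as a Gaussian blob
    along a per-parent polyline, sharing the bouton's fluorescence.

    Returns ``(soma_events, bouton_events, movie, soma_fluor, truth)``.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate_hz
    n_frames = int(round(duration_s * frame_rate_hz))
    times = np.arange(n_frames) * dt

    soma = np.zeros((n_parents, n_frames))
    parent_event_idx: list[np.ndarray] = []
    for p in range(n_parents):
        n_ev = rng.poisson(rate_hz * duration_s)
        idx = np.sort(rng.choice(n_frames, size=min(n_ev, n_frames), replace=False))
        amps = rng.gamma(4.0, 0.25, size=idx.size)
        soma[p, idx] = amps
        parent_event_idx.append(idx)

    n_boutons = n_parents * boutons_per_parent + n_background
    boutons = np.zeros((n_boutons, n_frames))
    parentage: dict[int, list[int]] = {p: [] for p in range(n_parents)}
    b = 0
    for p in range(n_parents):
        idx = parent_event_idx[p]
        for _ in range(boutons_per_parent):
            keep = rng.random(idx.size) < transmission
            jit = rng.normal(0.0, jitter_s, size=idx.size) / dt
            shifted = np.clip(np.round(idx + jit), 0, n_frames - 1).astype(int)
            amps = soma[p, idx] * np.clip(
                rng.normal(1.0, amplitude_cv, size=idx.size), 0.05, None
            )
            np.add.at(boutons[b], shifted[keep], amps[keep])
            extra = rng.poisson(independent_rate_hz * duration_s)
            if extra:
                eidx = rng.choice(n_frames, size=extra, replace=False)
                boutons[b, eidx] += rng.gamma(4.0, 0.25, size=extra)
            parentage[p].append(b)
            b += 1
    for _ in range(n_background):
        n_ev = rng.poisson(background_rate_hz * duration_s)
        idx = rng.choice(n_frames, size=min(n_ev, n_frames), replace=False)
        boutons[b, idx] = rng.gamma(4.0, 0.25, size=idx.size)
        b += 1

    soma_events = EventMatrix(values=soma, frame_rate=frame_rate_hz, timestamps=times)
    bouton_events = EventMatrix(
        values=boutons, frame_rate=frame_rate_hz, timestamps=times
    )
    soma_fluor = TraceMatrix(
        values=_convolve_calcium(soma, dt, tau_s)
        + rng.normal(0.0, movie_noise_sd, size=soma.shape),
        frame_rate=frame_rate_hz,
        timestamps=times,
    )

    # render boutons as Gaussian blobs along one polyline per parent
    h, w = movie_shape
    yy, xx = np.indices(movie_shape)
    footprints = np.zeros((n_boutons, h, w))
    positions = np.zeros((n_boutons, 2))
    for p in range(n_parents):
        y0, x0 = rng.uniform(5, h - 5), rng.uniform(5, 5 + w * 0.2)
        angle = rng.uniform(-0.3, 0.3)
        for j, bi in enumerate(parentage[p]):
            s = j * (w - 10) / max(1, boutons_per_parent - 1)
            cy = np.clip(y0 + s * np.sin(angle), 2, h - 3)
            cx = np.clip(x0 + s * np.cos(angle), 2, w - 3)
            positions[bi] = (cy, cx)
            footprints[bi] = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 1.5**2))
    for bi in range(n_parents * boutons_per_parent, n_boutons):
        cy, cx = rng.uniform(2, h - 3), rng.uniform(2, w - 3)
        positions[bi] = (cy, cx)
        footprints[bi] = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 1.5**2))

    n_movie = (
        n_frames
        if movie_duration_s is None
        else min(n_frames, int(round(movie_duration_s * frame_rate_hz)))
    )
    bouton_fluor = _convolve_calcium(boutons[:, :n_movie], dt, tau_s)
    movie = np.einsum("bt,byx->tyx", bouton_fluor.astype(np.float32),
                      footprints.astype(np.float32))
    movie += rng.normal(0.0, movie_noise_sd, size=movie.shape).astype(np.float32)

    truth = GroundTruth(
        cluster_ids={}, preferred_cluster={}, onset_times=np.array([]),
        parentage=parentage,
    )
    truth_extras = {"bouton_positions": positions, "footprints": footprints}
    return soma_events, bouton_events, movie, soma_fluor, truth, truth_extras


def gen_bead_volume(
    fwhm_um: tuple[float, float, float] = (1.0, 1.0, 10.0),
    voxel_um: tuple[float, float, float] = (0.249, 0.249, 0.5),
    shape_zyx: tuple[int, int, int] = (100, 41, 41),
    n_beads: int = 1,
    snr: float = 20.0,
    frames_per_plane: int = 5,
    tilt_deg: float = 0.0,
    seed: int = 0,
    max_retries: int = 200,
):
    """Raw bead-stack frames: Gaussian blobs plus per-frame noise.

    ``fwhm_um`` is (x, y, z); ``snr`` is peak amplitude over noise s.d.
    A nonzero ``tilt_deg`` shears the blob in the XZ plane, emulating an
    obliquely elongated PSF.  Beads are placed at non-overlapping random
    positions (error after ``max_retries`` failed placements).  Returns
    ``(raw_frames, centers_zyx)`` with frames ordered z-major, repeats
    innermost.
    """
    rng = np.random.default_rng(seed)
    fx, fy, fz = fwhm_um
    vx, vy, vz = voxel_um
    if fx < 2 * vx or fy < 2 * vy or fz < 2 * vz:
        raise SyntheticError("FWHM must be at least twice the voxel size per axis")
    nz, ny, nx = shape_zyx
    sig_x = fx / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sig_y = fy / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sig_z = fz / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    zz, yy, xx = np.indices(shape_zyx, dtype=float)
    zz, yy, xx = zz * vz, yy * vy, xx * vx
    volume = np.zeros(shape_zyx)
    centers = []
    margin = (3 * sig_z, 3 * sig_y, 3 * sig_x)
    min_sep = 4.0 * max(sig_x, sig_y, sig_z)
    tries = 0
    shear = np.tan(np.radians(tilt_deg))
    while len(centers) < n_beads:
        tries += 1
        if tries > max_retries + n_beads:
            raise SyntheticError("could not place beads without overlap")
        cz = rng.uniform(margin[0], (nz - 1) * vz - margin[0])
        cy = rng.uniform(margin[1], (ny - 1) * vy - margin[1])
        cx = rng.uniform(margin[2], (nx - 1) * vx - margin[2])
        if any(
            np.sqrt((cz - z0) ** 2 + (cy - y0) ** 2 + (cx - x0) ** 2) < min_sep
            for z0, y0, x0 in centers
        ):
            continue
        centers.append((cz, cy, cx))
        dx = (xx - cx) - shear * (zz - cz)
        volume += np.exp(
            -(dx**2) / (2 * sig_x**2)
            - ((yy - cy) ** 2) / (2 * sig_y**2)
            - ((zz - cz) ** 2) / (2 * sig_z**2)
        )

    noise_sd = 1.0 / snr if np.isfinite(snr) else 0.0
    frames = np.repeat(volume, frames_per_plane, axis=0)
    frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)
    frames = np.clip(frames + 0.05, 0.0, None)  # small positive background
    return frames, np.array(centers)


def default_lever_template(
    rate_hz: float = 100.0,
    peak_mm: float = 7.5,
    t_rise: float = 0.3,
    t_hold: float = 0.6,
    t_fall: float = 0.4,
) -> np.ndarray:
    """Canonical successful pull: rise to 7.5 mm in 0.3 s, hold, return."""
    n_rise = int(t_rise * rate_hz)
    n_hold = int(t_hold * rate_hz)
    n_fall = int(t_fall * rate_hz)
    rise = peak_mm * (1 - np.cos(np.linspace(0, np.pi, n_rise))) / 2
    hold = np.full(n_hold, peak_mm)
    fall = peak_mm * (1 + np.cos(np.linspace(0, np.pi, n_fall))) / 2
    return np.concatenate([rise, hold, fall])


def gen_behavior_log(
    n_trials: int = 65,
    template: np.ndarray | None = None,
    noise_sd_mm: float = 0.05,
    shape_jitter: float = 1.0,
    pre_pull_fraction: float = 0.0,
    failure_fraction: float = 0.1,
    rt_mean_s: float = 0.2,
    rt_sd_s: float = 0.05,
    rate_hz: float = 100.0,
    inter_cue_s: tuple[float, float] = (2.5, 3.5),
    seed: int = 0,
):
    """Lever-task session with planted trial outcomes.

    Per trial: the cue sounds, then after a planted reaction time the
    lever follows the pull trajectory (plus sensor noise).  Trained
    mice pull reproducibly but not identically; ``shape_jitter`` scales
    per-trial variation of rise time, hold duration and peak amplitude
    (0 = every pull identical, 1 = strong variation; the default is
    calibrated so the session lever correlation lands near the high
    reproducibility of a trained animal, ~0.88).  A
    ``failure_fraction`` of trials holds too briefly to succeed; a
    ``pre_pull_fraction`` of the successful trials gets a sub-threshold
    bump between cue and pull.  Cues repeat 2.5-3.5 s after lever
    return.  Passing an explicit ``template`` disables shape jitter.
    Returns ``(BehaviorLog, planted_trials_dataframe)``.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    dt = 1.0 / rate_hz

    def _trial_template() -> np.ndarray:
        if template is not None:
            return template.copy()
        j = shape_jitter
        return default_lever_template(
            rate_hz,
            peak_mm=7.5 * (1.0 + j * rng.uniform(-0.26, 0.45)),
            t_rise=0.3 * (1.0 + j * rng.uniform(-0.4, 0.4)),
            t_hold=0.6 + j * rng.uniform(-0.25, 0.8),
            t_fall=0.4 * (1.0 + j * rng.uniform(-0.5, 0.8)),
        )

    segments: list[np.ndarray] = []
    cue_times, reward_times, rows = [], [], []
    t_now = 2.0
    segments.append(np.zeros(int(t_now * rate_hz)))
    for trial in range(n_trials):
        cue = t_now
        fail = rng.random() < failure_fraction
        pre = (not fail) and (rng.random() < pre_pull_fraction)
        rt = float(np.clip(rng.normal(rt_mean_s, rt_sd_s), 0.12, 0.42))
        pieces = []
        if pre:
            bump_len = int(0.08 * rate_hz)
            bump = 1.5 * np.sin(np.linspace(0, np.pi, bump_len))
            gap1 = np.zeros(int(0.05 * rate_hz))
            pieces += [gap1, bump]
            rt_start = 0.05 + 0.08
            rt = max(rt, rt_start + 0.1)
        lead = int(round(rt * rate_hz)) - sum(len(p) for p in pieces)
        pieces.append(np.zeros(max(lead, 0)))
        if fail:
            # short hold: rise, stay above threshold < 400 ms, return
            n_rise = int(0.3 * rate_hz)
            short = np.concatenate([
                7.5 * (1 - np.cos(np.linspace(0, np.pi, n_rise))) / 2,
                np.full(int(0.1 * rate_hz), 7.5),
                7.5 * (1 + np.cos(np.linspace(0, np.pi, n_rise))) / 2,
            ])
            pieces.append(short)
        else:
            pieces.append(_trial_template())
            # variable post-return movement: sub-threshold bumps after the
            # pull are the main source of trial-to-trial trajectory
            # decorrelation in trained animals
            if template is None:
                for _ in range(rng.poisson(2.2 * shape_jitter)):
                    amp = rng.uniform(0.5, 6.5) * min(1.0, shape_jitter + 0.3)
                    width = int(rng.uniform(0.15, 0.6) * rate_hz)
                    gap = np.zeros(int(rng.uniform(0.0, 0.25) * rate_hz))
                    bump = amp * np.sin(np.linspace(0, np.pi, width))
                    pieces += [gap, bump]
        traj = np.concatenate(pieces)
        segments.append(traj)
        pull_time = cue + rt
        rows.append(
            {
                "cue_time": cue,
                "planted_success": not fail,
                "planted_pre_pull": pre,
                "planted_rt": rt if not fail else np.nan,
                "planted_pull_time": pull_time if not fail else np.nan,
            }
        )
        cue_times.append(cue)
        t_now += traj.size * dt
        if not fail:
            reward_times.append(cue + rt + 0.3 + 0.4)  # at hold completion
        gap = rng.uniform(*inter_cue_s)
        segments.append(np.zeros(int(gap * rate_hz)))
        t_now += int(gap * rate_hz) * dt
    segments.append(np.zeros(int(2.0 * rate_hz)))

    lever = np.concatenate(segments)
    lever = lever + rng.normal(0.0, noise_sd_mm, size=lever.size)
    log = BehaviorLog(
        lever_mm=lever,
        rate=rate_hz,
        cue_times=np.array(cue_times),
        reward_times=np.array(reward_times),
    )
    return log, pd.DataFrame(rows)
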