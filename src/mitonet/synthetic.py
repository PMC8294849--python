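"""Seedable synthetic-data generators with ground truth.

Every input the pipeline consumes — mitochondrial particle tracks, SWC
reconstructions, punctate mitochondrial stacks, soma/bouton fluorescence
images, oscillatory LFP, PSC voltage-clamp traces, and zone-structured
trajectories — can be generated here, with the generating parameters
returned alongside, so every downstream estimator is testable against
known truth without any raw microscopy or recordings.

All generators are pure functions of their parameters and seed.  Target
counts (mobile tracks, mito-containing boutons, frames per zone) use
round-half-away-from-zero with any remainder assigned to the lowest-index
items, so constructed fractions are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import allocate_counts, round_half_away, spawn_rng
from .behavior import ZoneMap
from .containers import LFPRecording, Trajectory, VCTrace, VoxelStack
from .errors import ParameterError
from .morphometry import AXON, DENDRITE, SOMA, SWCMorphology, branch_points
from .trafficking import (
    IMMOBILITY_STEP_UM,
    MOBILITY_THRESHOLD_UM,
    MOBILITY_WINDOW_S,
    Track,
    windowed_max_path,
)

# ---------------------------------------------------------------------------
# Ground-truth records


@dataclass
class TrackGroundTruth:
    track_id: str
    is_mobile: bool
    true_speed: float                      # μm/s while moving
    pause_intervals: list[tuple[float, float]]  # (start_s, end_s)


@dataclass
class MitoPlacementTruth:
    centers: np.ndarray                     # (n, 3) world μm (x, y, z)
    branch_nearest_um: np.ndarray | None    # per-branch-point distance to nearest center


@dataclass
class LFPGroundTruth:
    osc_frequency: float  # Hz
    osc_amplitude: float  # mV
    noise_sd: float       # mV
    duration: float       # s
    sample_rate: float    # Hz


@dataclass
class PSCGroundTruth:
    event_times: np.ndarray       # s, strictly increasing
    event_amplitudes: np.ndarray  # pA, > 0 (magnitudes)
    rise_tau: float               # ms
    decay_tau: float              # ms
    noise_sd: float               # pA
    overlapping: np.ndarray | None = None  # events closer than rise_tau to a neighbour


@dataclass
class PauseSpec:
    """Pause model for mobile tracks: how many pauses, how long each."""

    n_pauses: int = 1
    min_s: float = 15.0
    max_s: float = 60.0


# ---------------------------------------------------------------------------
# Particle tracks


def _make_mobile_track(
    tid: str, n_steps: int, frame_dt: float, speed: float,
    pause_spec: PauseSpec | None, rng: np.random.Generator,
) -> tuple[Track, list[tuple[float, float]]]:
    moving = np.ones(n_steps, dtype=bool)
    pauses: list[tuple[float, float]] = []
    if pause_spec is not None and pause_spec.n_pauses > 0:
        lo = max(int(np.ceil(pause_spec.min_s / frame_dt)), 1)
        hi = max(int(np.floor(pause_spec.max_s / frame_dt)), lo)
        for _ in range(pause_spec.n_pauses):
            dur = int(rng.integers(lo, hi + 1))
            free = np.flatnonzero(
                np.convolve(moving.astype(int), np.ones(dur, dtype=int), "valid") == dur
            )
            if free.size == 0:
                break
            s = int(rng.choice(free))
            moving[s:s + dur] = False
            pauses.append((s * frame_dt, (s + dur) * frame_dt))
    # persistent-direction walk: exact step length while moving, zero in pauses
    theta = rng.uniform(0, 2 * np.pi)
    xs = [0.0]
    ys = [0.0]
    for k in range(n_steps):
        if moving[k]:
            theta += rng.normal(0.0, 0.3)
            xs.append(xs[-1] + speed * frame_dt * np.cos(theta))
            ys.append(ys[-1] + speed * frame_dt * np.sin(theta))
        else:
            xs.append(xs[-1])
            ys.append(ys[-1])
    t = np.arange(n_steps + 1) * frame_dt
    return Track(tid, t, np.array(xs), np.array(ys)), sorted(pauses)


def gen_tracks(
    n: int,
    duration: float = 500.0,
    frame_dt: float = 5.0,
    speed: float = 0.17,
    mobile_fraction: float = 0.25,
    pause_spec: PauseSpec | None = None,
    seed: int = 0,
) -> tuple[list[Track], list[TrackGroundTruth]]:
    """Synthetic mitochondrial tracks with an exact mobile count.

    Exactly ``round(n · mobile_fraction)`` tracks are mobile by the
    2 μm / 300 s rule (constant ``speed`` during motion, optional pauses);
    the rest jitter below 0.03 μm/frame so every 300-s window stays under
    2 μm of path.  Defaults mirror the source movies: one frame per 5 s
    over 500 s at a wild-type-like speed of 0.17 μm/s.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if frame_dt <= 0:
        raise ParameterError("frame_dt must be positive")
    if not 0.0 <= mobile_fraction <= 1.0:
        raise ParameterError("mobile_fraction must be in [0, 1]")
    n_steps = int(round(duration / frame_dt))
    if abs(n_steps * frame_dt - duration) > 1e-9:
        raise ParameterError("duration must be a multiple of frame_dt")
    n_mobile = round_half_away(n * mobile_fraction)
    window = min(MOBILITY_WINDOW_S, duration)
    rng = spawn_rng(seed, 0)
    mobile_flags = np.zeros(n, dtype=bool)
    mobile_flags[rng.permutation(n)[:n_mobile]] = True
    tracks, truths = [], []
    for i in range(n):
        tid = f"track{i:04d}"
        trng = spawn_rng(seed, 1, i)
        if mobile_flags[i]:
            track, pauses = _make_mobile_track(tid, n_steps, frame_dt, speed, pause_spec, trng)
            threshold = MOBILITY_THRESHOLD_UM * window / MOBILITY_WINDOW_S
            if windowed_max_path(track, window) <= threshold:
                raise ParameterError(
                    f"mobile track impossible: speed {speed} μm/s with the requested "
                    f"pauses cannot exceed {threshold} μm of path in {window} s"
                )
            truths.append(TrackGroundTruth(tid, True, speed, pauses))
        else:
            # jitter magnitude < 0.03 μm/frame keeps every 300-s window < 1.8 μm
            steps = trng.uniform(0.0, 0.03, size=n_steps)
            ang = trng.uniform(0, 2 * np.pi, size=n_steps)
            x = np.concatenate([[0.0], np.cumsum(steps * np.cos(ang))])
            y = np.concatenate([[0.0], np.cumsum(steps * np.sin(ang))])
            track = Track(tid, np.arange(n_steps + 1) * frame_dt, x, y)
            truths.append(TrackGroundTruth(tid, False, 0.0, []))
        tracks.append(track)
    return tracks, truths


# ---------------------------------------------------------------------------
# Morphologies


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def gen_morphology(
    n_branch_axon: int = 5,
    n_branch_dend: int = 5,
    segment_len: float = 20.0,
    seed: int = 0,
    nodes_per_segment: int = 5,
    soma_radius: float = 5.0,
    neurite_radius: float = 0.5,
) -> SWCMorphology:
    """Random branching reconstruction with exact branch-point counts.

    One soma root at the origin sprouts an axon and a dendrite; each
    compartment is grown by repeatedly extending a random open tip by one
    segment (mean length ``segment_len`` μm) and bifurcating there, which
    plants exactly the requested number of branch points per compartment.
    """
    if n_branch_axon < 0 or n_branch_dend < 0:
        raise ParameterError("branch counts must be >= 0")
    rng = spawn_rng(seed, 10)
    types = [SOMA]
    xyz = [(0.0, 0.0, 0.0)]
    radius = [soma_radius]
    parent = [-1]

    def grow_segment(parent_idx: int, direction: np.ndarray, ntype: int) -> int:
        length = max(float(rng.normal(segment_len, segment_len / 4)), segment_len / 4)
        step = length / nodes_per_segment
        pos = np.array(xyz[parent_idx], dtype=float)
        d = direction.copy()
        idx = parent_idx
        for _ in range(nodes_per_segment):
            d = _unit(d + rng.normal(0.0, 0.15, size=3))
            pos = pos + step * d
            xyz.append(tuple(pos))
            types.append(ntype)
            radius.append(neurite_radius)
            parent.append(idx)
            idx = len(xyz) - 1
        return idx

    for ntype, n_branch, base_dir in (
        (AXON, n_branch_axon, np.array([1.0, 0.0, 0.0])),
        (DENDRITE, n_branch_dend, np.array([-1.0, 0.0, 0.0])),
    ):
        tips: list[tuple[int, np.ndarray]] = [(0, base_dir)]
        for _ in range(n_branch):
            j = int(rng.integers(len(tips)))
            parent_idx, d = tips.pop(j)
            end = grow_segment(parent_idx, d, ntype)
            for sign in (+1.0, -1.0):
                axis = _unit(rng.normal(size=3))
                d2 = _unit(d + sign * 0.7 * axis)
                tips.append((end, d2))
        for parent_idx, d in tips:
            grow_segment(parent_idx, d, ntype)

    n = len(xyz)
    ids = np.arange(1, n + 1)
    return SWCMorphology(ids, np.array(types), np.array(xyz),
                         np.array(radius), np.array(parent))


# ---------------------------------------------------------------------------
# Mitochondrial stacks


def _sample_on_tree(morph: SWCMorphology, n: int, rng, bias_to_soma: float | None):
    """Random points on the neurite centerline, optionally soma-biased."""
    e = morph.edges("all")
    p0 = morph.xyz[e[:, 1]]
    p1 = morph.xyz[e[:, 0]]
    lengths = np.linalg.norm(p1 - p0, axis=1)
    w = lengths.copy()
    if bias_to_soma is not None:
        mid = 0.5 * (p0 + p1)
        d = np.linalg.norm(mid - morph.soma_center, axis=1)
        w = lengths * np.exp(-d / bias_to_soma)
    w = w / w.sum()
    ei = rng.choice(e.shape[0], size=n, p=w)
    t = rng.uniform(size=n)[:, None]
    return p0[ei] + t * (p1[ei] - p0[ei])


def gen_mito_stack(
    morph: SWCMorphology,
    n_mito: int = 200,
    placement: str = "uniform_on_tree",
    voxel_size: float = 0.5,
    psf_sigma: float = 0.3,
    seed: int = 0,
    points: np.ndarray | None = None,
    background: float = 10.0,
    noise_sd: float = 0.0,
    soma_bias_length: float = 30.0,
    margin: float = 3.0,
    origin: tuple[float, float, float] | None = None,
    shape: tuple[int, int, int] | None = None,
) -> tuple[VoxelStack, MitoPlacementTruth]:
    """Punctate mitochondrial stack over a reconstruction's bounding box.

    Each mitochondrion is an isotropic Gaussian blob (σ = ``psf_sigma``)
    whose peak is 10× the mean background, so default binarisation keeps it
    deterministically.  Truth records exact centers and, per branch point,
    the distance to the nearest center.
    """
    if voxel_size <= 0:
        raise ParameterError("voxel_size must be positive")
    if n_mito < 0:
        raise ParameterError("n_mito must be >= 0")
    if voxel_size > 3.0 * psf_sigma:
        import warnings

        warnings.warn(
            "voxel_size exceeds the PSF support; blobs may vanish after binarisation",
            stacklevel=2,
        )
    rng = spawn_rng(seed, 20)
    if placement == "at_given_points":
        centers = np.atleast_2d(np.asarray(points, dtype=float)) if points is not None \
            else np.empty((0, 3))
    elif placement == "uniform_on_tree":
        centers = _sample_on_tree(morph, n_mito, rng, None) if n_mito else np.empty((0, 3))
    elif placement == "biased_to_soma":
        centers = _sample_on_tree(morph, n_mito, rng, soma_bias_length) if n_mito \
            else np.empty((0, 3))
    else:
        raise ParameterError(f"unknown placement {placement!r}")

    if origin is None or shape is None:
        pts = morph.xyz if morph.n_nodes else np.zeros((1, 3))
        allpts = np.vstack([pts, centers]) if centers.size else pts
        lo = allpts.min(axis=0) - margin
        hi = allpts.max(axis=0) + margin
        shape_xyz = np.ceil((hi - lo) / voxel_size).astype(int) + 1
        nz, ny, nx = int(shape_xyz[2]), int(shape_xyz[1]), int(shape_xyz[0])
        origin = (float(lo[2]), float(lo[1]), float(lo[0]))
    else:
        nz, ny, nx = shape
    data = np.full((nz, ny, nx), background, dtype=float)
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=data.shape)
    peak = 10.0 * background
    half = max(int(np.ceil(4.0 * psf_sigma / voxel_size)), 1)
    for cx, cy, cz in centers:
        iz = int(round((cz - origin[0]) / voxel_size))
        iy = int(round((cy - origin[1]) / voxel_size))
        ix = int(round((cx - origin[2]) / voxel_size))
        z0, z1 = max(iz - half, 0), min(iz + half + 1, nz)
        y0, y1 = max(iy - half, 0), min(iy + half + 1, ny)
        x0, x1 = max(ix - half, 0), min(ix + half + 1, nx)
        zz = origin[0] + np.arange(z0, z1) * voxel_size
        yy = origin[1] + np.arange(y0, y1) * voxel_size
        xx = origin[2] + np.arange(x0, x1) * voxel_size
        Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
        r2 = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2
        data[z0:z1, y0:y1, x0:x1] += peak * np.exp(-r2 / (2.0 * psf_sigma**2))
    stack = VoxelStack(data, (voxel_size,) * 3, origin)

    bp = branch_points(morph, "all") if morph.n_nodes else np.empty((0, 3))
    nearest = None
    if bp.shape[0] and centers.shape[0]:
        from scipy.spatial import cKDTree

        nearest, _ = cKDTree(centers).query(bp)
        nearest = np.asarray(nearest, dtype=float)
    return stack, MitoPlacementTruth(centers, nearest)


# ---------------------------------------------------------------------------
# Soma and bouton images


def gen_soma_image(
    size: tuple[int, int] = (200, 200),
    mito_area_fraction: float = 0.3,
    clustered: bool = False,
    seed: int = 0,
    soma_area_px: int = 10000,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Soma mask + mitochondrial mask with an exact in-soma pixel fraction.

    The soma is the ``soma_area_px`` pixels nearest the image center (an
    exact-area disk); mitochondrial pixels number exactly
    ``round(fraction · soma_area_px)``.  ``clustered=True`` grows them as a
    single perinuclear component; otherwise they fill ten small blobs
    scattered through the soma.  Returns (soma_mask, mito_mask,
    realised fraction).
    """
    if not 0.0 <= mito_area_fraction <= 1.0:
        raise ParameterError("mito_area_fraction must be in [0, 1]")
    h, w = size
    if soma_area_px > h * w:
        raise ParameterError("soma larger than image")
    rng = spawn_rng(seed, 30)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ys, xs = np.mgrid[0:h, 0:w]
    d2 = (ys - cy) ** 2 + (xs - cx) ** 2
    order = np.argsort(d2.ravel(), kind="stable")
    soma_mask = np.zeros(h * w, dtype=bool)
    soma_mask[order[:soma_area_px]] = True
    soma_mask = soma_mask.reshape(h, w)
    n_mito = round_half_away(mito_area_fraction * soma_area_px)
    mito_mask = np.zeros((h, w), dtype=bool)
    if n_mito > 0:
        soma_idx = np.flatnonzero(soma_mask.ravel())
        yy = soma_idx // w
        xx = soma_idx % w
        soma_r = np.sqrt(soma_area_px / np.pi)
        if clustered:
            ang = rng.uniform(0, 2 * np.pi)
            seeds = np.array([[cy + 0.3 * soma_r * np.sin(ang),
                               cx + 0.3 * soma_r * np.cos(ang)]])
        else:
            # ten seeds on two staggered rings, far enough apart that the
            # grown blobs stay disjoint up to fractions ~0.5
            a0 = rng.uniform(0, 2 * np.pi)
            inner = a0 + np.linspace(0, 2 * np.pi, 5, endpoint=False)
            outer = a0 + np.pi / 5 + np.linspace(0, 2 * np.pi, 5, endpoint=False)
            seeds = np.vstack([
                np.column_stack([cy + 0.42 * soma_r * np.sin(inner),
                                 cx + 0.42 * soma_r * np.cos(inner)]),
                np.column_stack([cy + 0.85 * soma_r * np.sin(outer),
                                 cx + 0.85 * soma_r * np.cos(outer)]),
            ])
        dist_to_seed = np.min(
            (yy[:, None] - seeds[:, 0]) ** 2 + (xx[:, None] - seeds[:, 1]) ** 2, axis=1
        )
        pick = np.argsort(dist_to_seed, kind="stable")[:n_mito]
        mito_mask.ravel()[soma_idx[pick]] = True
    return soma_mask, mito_mask, n_mito / soma_area_px


def gen_axon_boutons(
    n_boutons: int = 100,
    frac_with_mito: float = 0.74,
    axon_length: float = 250.0,
    seed: int = 0,
    pixel_size: float = 0.1,
    bouton_radius_um: float = 0.55,
    noise_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Biocytin + mitochondria channel pair along a synthetic axon.

    Boutons are bright disks (~0.95 μm², inside the default 0.2–3 μm²
    detection bounds) strung on a dim shaft; exactly
    ``round(n · frac_with_mito)`` of them receive a mitochondrial punctum.
    Returns (biocytin image, mito image, per-bouton has-mito flags).  The
    flag order follows bouton position along the axon (left to right).
    """
    if n_boutons < 1:
        raise ParameterError("n_boutons must be >= 1")
    if not 0.0 <= frac_with_mito <= 1.0:
        raise ParameterError("frac_with_mito must be in [0, 1]")
    rng = spawn_rng(seed, 40)
    r_px = bouton_radius_um / pixel_size
    min_sep = 2.0 * r_px + 4.0  # px between centers; keeps components disjoint
    length_px = axon_length / pixel_size
    if n_boutons * min_sep > length_px:
        raise ParameterError(
            f"{n_boutons} boutons of radius {bouton_radius_um} μm cannot fit on "
            f"{axon_length} μm of axon without overlap"
        )
    w = int(np.ceil(length_px)) + int(4 * r_px) + 20
    h = int(8 * r_px) + 20
    y0 = h // 2
    x_start = int(2 * r_px) + 10
    # jittered even spacing preserves the min separation
    slots = x_start + np.arange(n_boutons) * (length_px / n_boutons) \
        + length_px / (2 * n_boutons)
    jitter = (length_px / n_boutons - min_sep) / 2.0
    centers_x = slots + rng.uniform(-max(jitter, 0.0), max(jitter, 0.0), size=n_boutons)
    ys, xs = np.mgrid[0:h, 0:w]
    bio = np.full((h, w), 5.0)
    bio[y0 - 1:y0 + 2, x_start - int(r_px):int(np.ceil(centers_x[-1] + r_px))] = 25.0
    mito = np.full((h, w), 5.0)
    n_with = round_half_away(n_boutons * frac_with_mito)
    flags = np.zeros(n_boutons, dtype=bool)
    flags[rng.permutation(n_boutons)[:n_with]] = True
    mito_r_px = 0.3 / pixel_size
    for i, cx in enumerate(centers_x):
        disk = (ys - y0) ** 2 + (xs - cx) ** 2 <= r_px**2
        bio[disk] = 200.0
        if flags[i]:
            punct = (ys - y0) ** 2 + (xs - cx) ** 2 <= mito_r_px**2
            mito[punct] = 150.0
    if noise_sd > 0:
        bio = bio + rng.normal(0.0, noise_sd, size=bio.shape)
        mito = mito + rng.normal(0.0, noise_sd, size=mito.shape)
    return bio, mito, flags


# ---------------------------------------------------------------------------
# Electrophysiology


def gen_lfp(truth: LFPGroundTruth, seed: int = 0) -> LFPRecording:
    """Sinusoidal oscillation plus white Gaussian noise."""
    if not truth.sample_rate >= 2 * truth.osc_frequency:
        raise ParameterError("sample_rate must satisfy Nyquist for the oscillator")
    rng = spawn_rng(seed, 50)
    n = int(round(truth.duration * truth.sample_rate))
    t = np.arange(n) / truth.sample_rate
    x = truth.osc_amplitude * np.sin(2 * np.pi * truth.osc_frequency * t)
    if truth.noise_sd > 0:
        x = x + rng.normal(0.0, truth.noise_sd, size=n)
    return LFPRecording(x, truth.sample_rate)


def psc_kernel(rise_tau_ms: float, decay_tau_ms: float, sample_rate: float) -> np.ndarray:
    """Difference-of-exponentials transient, normalised to unit peak."""
    tr, td = rise_tau_ms / 1000.0, decay_tau_ms / 1000.0
    t = np.arange(0, 10 * td, 1.0 / sample_rate)
    k = np.exp(-t / td) - np.exp(-t / tr)
    return k / k.max()


def gen_psc_trace(
    truth: PSCGroundTruth, duration: float, sample_rate: float = 10000.0, seed: int = 0
) -> tuple[VCTrace, PSCGroundTruth]:
    """Voltage-clamp trace with inward (negative) PSC transients.

    Each event contributes a difference-of-exponentials transient whose
    peak magnitude equals its stated amplitude; events closer together than
    the rise time are flagged overlapping in the returned truth.
    """
    times = np.asarray(truth.event_times, dtype=float)
    amps = np.asarray(truth.event_amplitudes, dtype=float)
    if times.size and np.any(np.diff(times) <= 0):
        raise ParameterError("event times must be strictly increasing")
    if np.any(amps <= 0):
        raise ParameterError("amplitudes must be positive magnitudes")
    rng = spawn_rng(seed, 60)
    n = int(round(duration * sample_rate))
    x = np.zeros(n)
    kern = psc_kernel(truth.rise_tau, truth.decay_tau, sample_rate)
    for t0, a in zip(times, amps):
        i0 = int(round(t0 * sample_rate))
        if i0 >= n:
            continue
        seg = min(kern.size, n - i0)
        x[i0:i0 + seg] -= a * kern[:seg]
    if truth.noise_sd > 0:
        x = x + rng.normal(0.0, truth.noise_sd, size=n)
    overlap = np.zeros(times.size, dtype=bool)
    if times.size > 1:
        gaps = np.diff(times)
        close = gaps < truth.rise_tau / 1000.0
        overlap[:-1] |= close
        overlap[1:] |= close
    out_truth = PSCGroundTruth(times, amps, truth.rise_tau, truth.decay_tau,
                               truth.noise_sd, overlap)
    return VCTrace(x, sample_rate), out_truth


def gen_poisson_psc_truth(
    rate_hz: float, duration: float, mean_amp: float = 50.0,
    amp_cv: float = 0.2, rise_tau: float = 0.5, decay_tau: float = 5.0,
    noise_sd: float = 2.0, seed: int = 0, min_gap: float = 0.01,
) -> PSCGroundTruth:
    """Poisson event train with lognormal amplitudes (ground truth only)."""
    rng = spawn_rng(seed, 61)
    times = []
    t = 0.0
    while True:
        t += max(rng.exponential(1.0 / rate_hz), min_gap)
        if t >= duration - 0.05:
            break
        times.append(t)
    times = np.asarray(times)
    sigma = np.sqrt(np.log(1 + amp_cv**2))
    amps = mean_amp * np.exp(rng.normal(-sigma**2 / 2, sigma, size=times.size))
    return PSCGroundTruth(times, amps, rise_tau, decay_tau, noise_sd)


def gen_cc_sweeps(
    currents_pA,
    r_in_mohm: float = 100.0,
    tau_ms: float = 10.0,
    v_rest: float = -70.0,
    threshold_mv: float = -40.0,
    rheobase_pA: float = 100.0,
    gain_hz_per_pA: float = 0.5,
    sample_rate: float = 50000.0,
    step_on: float = 0.1,
    step_off: float = 0.6,
    sweep_len: float = 0.8,
    seed: int = 0,
):
    """Idealised RC-cell current-clamp step family with stereotyped spikes.

    Subthreshold sweeps follow V = V_rest + I·R·(1 − e^(−t/τ)); sweeps at or
    above ``rheobase_pA`` fire regular spikes at rate
    ``gain · (I − rheobase) + 10`` Hz.  Each spike ramps slowly to the
    stated threshold, rises fast to +30 mV and repolarises, so a dV/dt
    criterion recovers the threshold.  Returns a list of CCSweep.
    """
    from .ephys import CCSweep

    n = int(round(sweep_len * sample_rate))
    t = np.arange(n) / sample_rate
    on, off = step_on, step_off
    sweeps = []
    for i_pA in currents_pA:
        v = np.full(n, v_rest)
        inside = (t >= on) & (t < off)
        dv = i_pA * r_in_mohm / 1000.0  # pA·MΩ -> mV
        v[inside] = v_rest + dv * (1 - np.exp(-(t[inside] - on) / (tau_ms / 1000.0)))
        after = t >= off
        v_off = v_rest + dv * (1 - np.exp(-(off - on) / (tau_ms / 1000.0)))
        v[after] = v_rest + (v_off - v_rest) * np.exp(-(t[after] - off) / (tau_ms / 1000.0))
        if i_pA >= rheobase_pA:
            v_ss = min(v_rest + dv, threshold_mv - 2.0)
            v[inside] = np.minimum(v[inside], v_ss)
            rate = gain_hz_per_pA * (i_pA - rheobase_pA) + 10.0
            spike_times = np.arange(on + 0.02, off - 0.01, 1.0 / rate)
            for st in spike_times:
                _insert_spike(v, st, sample_rate, v_ss, threshold_mv)
        sweeps.append(CCSweep(float(i_pA), v, sample_rate, on, off))
    return sweeps


def _insert_spike(v, t0, fs, v_base, v_th, v_peak=30.0):
    """Piecewise-linear AP: 5 V/s approach, 200 V/s upstroke, −100 V/s decay."""
    v_base = float(v[int(round(t0 * fs))])  # continuous with the trace
    ramp_ms = (v_th - v_base) / 5.0     # duration of approach, ms
    rise_ms = (v_peak - v_th) / 200.0
    fall_ms = (v_peak - v_base) / 100.0
    seg_t = np.array([0.0, ramp_ms, ramp_ms + rise_ms, ramp_ms + rise_ms + fall_ms]) / 1000.0
    seg_v = np.array([v_base, v_th, v_peak, v_base])
    i0 = int(round(t0 * fs))
    n = int(round(seg_t[-1] * fs))
    tt = np.arange(n) / fs
    wave = np.interp(tt, seg_t, seg_v)
    i1 = min(i0 + n, v.size)
    v[i0:i1] = wave[: i1 - i0]


def gen_train_trace(
    first_amp_pA: float = 100.0,
    depression: float = 0.8,
    recovery_fracs=(0.5, 0.7, 0.9),
    probe_delays_s=(0.5, 1.0, 2.0),
    n_trains: int = 10,
    train_rate_hz: float = 40.0,
    train_dur_s: float = 2.0,
    inter_train_s: float = 6.0,
    rise_tau: float = 0.5,
    decay_tau: float = 3.0,
    sample_rate: float = 10000.0,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Depressing stimulus-train trace with known probe recoveries.

    Within each train the k-th response is first_amp·depression^k; probes at
    the stated delays after train end have amplitude
    first_amp·recovery_frac.  Returns (trace, train_times, probe_times,
    recovery_percent_truth).
    """
    rng = spawn_rng(seed, 62)
    n_pulses = int(round(train_rate_hz * train_dur_s))
    period = train_dur_s + max(probe_delays_s) + inter_train_s
    total = n_trains * period + 1.0
    n = int(round(total * sample_rate))
    x = np.zeros(n)
    kern = psc_kernel(rise_tau, decay_tau, sample_rate)

    def add(t0, amp):
        i0 = int(round(t0 * sample_rate))
        seg = min(kern.size, n - i0)
        if seg > 0:
            x[i0:i0 + seg] -= amp * kern[:seg]

    train_times, probe_times = [], []
    for k in range(n_trains):
        t0 = 0.5 + k * period
        stims = t0 + np.arange(n_pulses) / train_rate_hz
        for j, st in enumerate(stims):
            add(st, first_amp_pA * depression**j)
        probes = t0 + train_dur_s + np.asarray(probe_delays_s)
        for frac, pt in zip(recovery_fracs, probes):
            add(pt, first_amp_pA * frac)
        train_times.append(stims)
        probe_times.append(probes)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=n)
    truth = 100.0 * np.asarray(recovery_fracs)
    return VCTrace(x, sample_rate), train_times, probe_times, truth


def gen_fepsp(
    amplitude_mv: float = 0.5,
    tau_ms: float = 5.0,
    stim_time: float = 0.05,
    duration: float = 0.3,
    sample_rate: float = 10000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> LFPRecording:
    """Negative-going alpha-function field EPSP: v = −A·(t/τ)·e^(1−t/τ)."""
    rng = spawn_rng(seed, 63)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    v = np.zeros(n)
    rel = (t - stim_time - 0.002)  # response begins after a 2-ms latency
    m = rel > 0
    tau = tau_ms / 1000.0
    v[m] = -amplitude_mv * (rel[m] / tau) * np.exp(1 - rel[m] / tau)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=n)
    return LFPRecording(v, sample_rate)


# ---------------------------------------------------------------------------
# Trajectories


def gen_trajectory(
    zones: ZoneMap,
    occupancy: dict[str, float],
    n_frames: int = 1000,
    frame_rate: float = 25.0,
    seed: int = 0,
) -> Trajectory:
    """Zone-structured trajectory with exact per-zone frame counts.

    Frame counts follow round-half-away allocation of
    ``occupancy · n_frames`` (remainder to the first-listed zones); frames
    for each zone are drawn uniformly inside its polygon and laid out as
    contiguous blocks in the listed zone order.
    """
    names = list(occupancy)
    props = np.array([occupancy[k] for k in names], dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ParameterError("occupancy proportions must sum to 1")
    for name in names:
        if name not in zones.zones:
            raise ParameterError(f"unknown zone {name!r}")
    counts = allocate_counts(n_frames, props)
    rng = spawn_rng(seed, 70)
    xs, ys = [], []
    from shapely.geometry import Point

    for name, cnt in zip(names, counts):
        poly = zones.zones[name]
        minx, miny, maxx, maxy = poly.bounds
        got = 0
        while got < cnt:
            px = rng.uniform(minx, maxx)
            py = rng.uniform(miny, maxy)
            if poly.covers(Point(px, py)):
                xs.append(px)
                ys.append(py)
                got += 1
    t = np.arange(n_frames) / frame_rate
    return Trajectory(t, np.array(xs), np.array(ys))
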