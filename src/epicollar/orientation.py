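"""Orientation normalization: sensor frame to dog frame.

A collar-mounted accelerometer rotates freely about the neck, so the
sensor axes bear no fixed relation to the dog's anatomy.  The transform
exploits the one physical constraint available: averaged over a few
seconds, the sensed specific force is dominated by gravity, which in the
dog frame points along the ventral axis.  Each 4-second block therefore
gets the minimal rotation carrying its smoothed gravity estimate onto
``(0, 0, -1)``; rotations are interpolated across block boundaries so
the correction tracks slow collar roll without discontinuities.

The residual degree of freedom (rotation about gravity) is unobservable
from a single accelerometer at rest.  Because the collar constrains the
device to rotate about the neck (cranial) axis, gravity re-alignment
alone removes the collar-roll nuisance; an optional heuristic that
aligns the dominant horizontal dynamic-energy axis with the cranial axis
is provided for data with other mounting geometries.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .simulate import AccelTrace

VENTRAL_TARGET = np.array([0.0, 0.0, -1.0])

#: blocks whose mean specific-force norm falls below this (in g) are
#: treated as degenerate (free fall / non-collection) and inherit the
#: previous block's rotation.
DEGENERATE_NORM_G = 0.3


@dataclass
class OrientedTrace(AccelTrace):
    """An AccelTrace whose axes are (cranial, lateral, ventral).

    ``block_rotations`` holds the per-block rotation matrices applied
    (sensor -> dog frame); ``degenerate_blocks`` flags blocks where
    gravity could not be estimated and the previous rotation was reused.
    """

    block_rotations: np.ndarray = field(default_factory=lambda: np.zeros((0, 3, 3)))
    block_s: float = 4.0
    degenerate_blocks: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))


def estimate_gravity(
    trace: AccelTrace, cutoff_hz: float = 0.3
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample gravity vector via zero-phase low-pass filtering.

    Returns ``(gravity, degenerate)`` where gravity is (N, 3) in g and
    degenerate flags samples whose gravity norm is implausibly small
    (all-zero input, free fall).  Uses a 2nd-order Butterworth filter
    run forward and backward (zero phase).
    """
    if trace.n_samples == 0:
        raise ValueError("cannot estimate gravity on an empty trace")
    nyq = trace.sample_rate_hz / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist {nyq} Hz")
    x = np.asarray(trace.samples, dtype=np.float64)
    min_len = 3 * 4  # sosfiltfilt needs some padding room
    if trace.n_samples <= min_len:
        gravity = np.repeat(x.mean(axis=0, keepdims=True), trace.n_samples, axis=0)
    else:
        sos = signal.butter(2, cutoff_hz, btype="low", fs=trace.sample_rate_hz, output="sos")
        gravity = signal.sosfiltfilt(sos, x, axis=0)
    degenerate = np.linalg.norm(gravity, axis=1) < DEGENERATE_NORM_G
    return gravity, degenerate


def _block_mean_gravity(
    samples: np.ndarray, fs: float, block_samples: int, cutoff_hz: float
) -> np.ndarray:
    """Block-mean gravity, computed on a decimated signal for speed.

    Gravity lives below ``cutoff_hz`` (default 0.3 Hz), so box-car
    decimation to ~5 Hz before filtering loses nothing while keeping the
    filter state small even for multi-week traces.
    """
    n = samples.shape[0]
    dec = max(int(fs // 5), 1)
    n_dec = n // dec
    if n_dec < 24:
        # too short to decimate+filter: fall back to plain block means
        n_blocks = int(np.ceil(n / block_samples))
        out = np.empty((n_blocks, 3))
        for b in range(n_blocks):
            out[b] = samples[b * block_samples : (b + 1) * block_samples].mean(axis=0)
        return out
    coarse = (
        samples[: n_dec * dec]
        .reshape(n_dec, dec, 3)
        .mean(axis=1, dtype=np.float64)
    )
    fs_dec = fs / dec
    if cutoff_hz < fs_dec / 2:
        sos = signal.butter(2, cutoff_hz, btype="low", fs=fs_dec, output="sos")
        coarse = signal.sosfiltfilt(sos, coarse, axis=0)
    n_blocks = int(np.ceil(n / block_samples))
    centers_s = (np.arange(n_blocks) + 0.5) * block_samples / fs
    coarse_t = (np.arange(n_dec) + 0.5) * dec / fs
    out = np.empty((n_blocks, 3))
    for k in range(3):
        out[:, k] = np.interp(centers_s, coarse_t, coarse[:, k])
    return out


def rotation_to_ventral(g: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix carrying unit vector ``g`` onto (0,0,-1)."""
    g = np.asarray(g, dtype=np.float64)
    g = g / np.linalg.norm(g)
    t = VENTRAL_TARGET
    c = float(np.dot(g, t))
    axis = np.cross(g, t)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antipodal: rotate 180 degrees about any axis orthogonal to g
        perp = np.array([1.0, 0.0, 0.0])
        if abs(g[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(g, perp)
        axis /= np.linalg.norm(axis)
        return _axis_angle_matrix(axis, np.pi)
    axis = axis / s
    angle = np.arctan2(s, c)
    return _axis_angle_matrix(axis, angle)


def _rotations_to_ventral_batch(g_blocks: np.ndarray, skip: np.ndarray) -> np.ndarray:
    """Vectorized minimal rotations g -> (0,0,-1) for all blocks.

    Uses the closed form R = I + [v]x + [v]x^2 (1 - c) / s^2 with
    v = g x t, c = g.t; near-antipodal blocks fall back to the scalar
    path.  Blocks flagged in ``skip`` get identity (filled in later).
    """
    m = g_blocks.shape[0]
    g = np.array(g_blocks, dtype=np.float64)
    norms = np.linalg.norm(g, axis=1)
    safe = ~skip
    g[safe] /= norms[safe, None]
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    c = -gz  # cosine of rotation angle
    s2 = gx * gx + gy * gy  # squared sine
    vx, vy = -gy, gx  # v = g x (0,0,-1); vz = 0
    V = np.zeros((m, 3, 3))
    V[:, 0, 2] = vy
    V[:, 1, 2] = -vx
    V[:, 2, 0] = -vy
    V[:, 2, 1] = vx
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(s2 > 1e-16, (1.0 - c) / np.where(s2 > 1e-16, s2, 1.0), 0.0)
    mats = np.eye(3)[None] + V + (V @ V) * k[:, None, None]
    hard = safe & (s2 <= 1e-16)
    for b in np.flatnonzero(hard):
        mats[b] = rotation_to_ventral(g_blocks[b])
    mats[skip] = np.eye(3)
    return mats


def _axis_angle_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _matrices_to_quats(mats: np.ndarray) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    q = Rotation.from_matrix(mats).as_quat()
    # enforce sign continuity so interpolation never crosses the double cover
    for i in range(1, q.shape[0]):
        if np.dot(q[i], q[i - 1]) < 0:
            q[i] = -q[i]
    return q


def _quats_to_matrices(q: np.ndarray) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.from_quat(q).as_matrix()


def orient_to_dog_frame(
    trace: AccelTrace,
    *,
    block_s: float = 4.0,
    cutoff_hz: float = 0.3,
    resolve_yaw: bool = False,
    interp_subdivisions: int = 8,
) -> OrientedTrace:
    """Rotate a sensor-frame trace into the dog frame.

    Per ``block_s`` block, the smoothed gravity direction is mapped onto
    the ventral axis by the minimal rotation; rotations are interpolated
    (normalized quaternion lerp at ``block_s / interp_subdivisions``
    resolution) across block boundaries.  Every applied matrix is a pure
    rotation, so sample norms are preserved exactly.

    With ``resolve_yaw`` the residual rotation about gravity is fixed by
    aligning the dominant eigenvector of the horizontal dynamic
    covariance with the cranial axis (only in blocks with appreciable
    dynamic energy; quiet blocks inherit the previous yaw).
    """
    if trace.n_samples == 0:
        raise ValueError("cannot orient an empty trace")
    fs = trace.sample_rate_hz
    n = trace.n_samples
    block_samples = max(int(round(block_s * fs)), 1)
    n_blocks = int(np.ceil(n / block_samples))

    g_blocks = _block_mean_gravity(np.asarray(trace.samples), fs, block_samples, cutoff_hz)
    norms = np.linalg.norm(g_blocks, axis=1)
    degenerate = norms < DEGENERATE_NORM_G

    mats = _rotations_to_ventral_batch(g_blocks, degenerate)
    if degenerate.any():
        warnings.warn(
            "degenerate (near-zero gravity) blocks: reusing previous rotation",
            RuntimeWarning,
            stacklevel=2,
        )
        prev = np.eye(3)
        for b in range(n_blocks):
            if degenerate[b]:
                mats[b] = prev
            else:
                prev = mats[b]

    if resolve_yaw:
        mats = _resolve_yaw(trace, mats, block_samples)

    out = np.empty_like(trace.samples)
    _apply_interpolated(np.asarray(trace.samples), mats, block_samples, interp_subdivisions, out)

    return OrientedTrace(
        start_time=trace.start_time,
        sample_rate_hz=fs,
        samples=out,
        wear_mask=list(trace.wear_mask),
        block_rotations=mats,
        block_s=block_samples / fs,
        degenerate_blocks=degenerate,
    )


def _resolve_yaw(trace, mats, block_samples) -> np.ndarray:
    """Fix the gravity-axis degree of freedom from horizontal dynamics."""
    x = np.asarray(trace.samples)
    n_blocks = mats.shape[0]
    out = mats.copy()
    prev_yaw = np.eye(3)
    for b in range(n_blocks):
        seg = x[b * block_samples : (b + 1) * block_samples]
        rot = seg @ mats[b].T  # gravity-aligned
        horiz = rot[:, :2] - rot[:, :2].mean(axis=0)
        energy = float((horiz**2).sum() / max(seg.shape[0], 1))
        if energy < 0.01:  # g^2; quiet block, yaw unobservable
            out[b] = prev_yaw @ mats[b]
            continue
        cov = horiz.T @ horiz
        evals, evecs = np.linalg.eigh(cov)
        v = evecs[:, -1]  # dominant horizontal axis
        if v[0] < 0:
            v = -v
        cy, sy = v[0], v[1]
        yaw = np.array([[cy, sy, 0.0], [-sy, cy, 0.0], [0.0, 0.0, 1.0]])
        out[b] = yaw @ mats[b]
        prev_yaw = yaw
    return out


def _apply_interpolated(x, mats, block_samples, subdivisions, out) -> None:
    """Apply block rotations with sub-block interpolation, vectorized."""
    n = x.shape[0]
    n_blocks = mats.shape[0]
    if n_blocks == 1:
        out[:] = x @ mats[0].T.astype(x.dtype)
        return
    sub = max(int(np.ceil(block_samples / max(subdivisions, 1))), 1)
    n_sub = int(np.ceil(n / sub))
    quats = _matrices_to_quats(mats)
    block_centers = (np.arange(n_blocks) + 0.5) * block_samples
    sub_centers = (np.arange(n_sub) + 0.5) * sub
    qi = np.empty((n_sub, 4))
    for k in range(4):
        qi[:, k] = np.interp(sub_centers, block_centers, quats[:, k])
    qi /= np.linalg.norm(qi, axis=1, keepdims=True)
    sub_mats = _quats_to_matrices(qi)

    R = sub_mats.astype(x.dtype)
    n_full = (n // sub) * sub
    # component-wise broadcast beats numpy's batched matmul on 3x3 blocks
    chunk = 20_000  # sub-blocks per chunk, ~1M samples
    m_full = n_full // sub
    for c0 in range(0, m_full, chunk):
        c1 = min(c0 + chunk, m_full)
        X = x[c0 * sub : c1 * sub].reshape(c1 - c0, sub, 3)
        O = out[c0 * sub : c1 * sub].reshape(c1 - c0, sub, 3)
        Rc = R[c0:c1]
        for i in range(3):
            O[:, :, i] = (
                X[:, :, 0] * Rc[:, i, 0][:, None]
                + X[:, :, 1] * Rc[:, i, 1][:, None]
                + X[:, :, 2] * Rc[:, i, 2][:, None]
            )
    if n_full < n:
        out[n_full:] = x[n_full:] @ R[-1].T


def rotate_trace(trace: AccelTrace, matrix: np.ndarray) -> AccelTrace:
    """Apply a fixed rotation to every sample (test/nuisance helper)."""
    m = np.asarray(matrix, dtype=np.float64)
    if not np.allclose(m @ m.T, np.eye(3), atol=1e-8):
        raise ValueError("matrix is not a rotation")
    rotated = (np.asarray(trace.samples) @ m.T).astype(trace.samples.dtype)
    return AccelTrace(
        start_time=trace.start_time,
        sample_rate_hz=trace.sample_rate_hz,
        samples=rotated,
        wear_mask=list(trace.wear_mask),
    )


def collar_roll_matrix(angle_rad: float) -> np.ndarray:
    """Rotation about the cranial (neck) axis by ``angle_rad``."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
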