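"""Fourier-domain discriminative correlation filter baseline (MOSSE-style).

A single-channel filter is solved in closed form in the frequency domain
from affine-perturbed copies of the initial patch, then applied and
updated online: localization is an element-wise product of spectra, the
filter an exponential moving average of per-frame closed-form solutions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .siamfc.ops import crop_patch
from .trace import Trace

__all__ = [
    "DCFConfig",
    "CorrelationFilterState",
    "init_filter",
    "respond",
    "update_filter",
    "track_sequence_dcf",
    "fft_correlate",
]


@dataclass(frozen=True)
class DCFConfig:
    patch_factor: float = 2.5  # patch side = factor * max(target size)
    learning_rate: float = 0.125
    regularizer: float = 1e-4
    sigma_factor: float = 0.1  # response sigma = factor * target diagonal
    n_aug: int = 8
    aug_rotation: float = 0.1  # radians
    aug_scale: float = 0.05
    log_preprocess: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.learning_rate <= 1.0):
            raise ValueError("learning_rate must lie in [0, 1]")
        if self.regularizer <= 0:
            raise ValueError("regularizer must be positive")


@dataclass
class CorrelationFilterState:
    """Online MOSSE filter state (numerator/denominator spectra)."""

    numerator: np.ndarray  # complex (H, W)
    denominator: np.ndarray  # real non-negative (H, W)
    window: np.ndarray
    desired_spectrum: np.ndarray  # FFT of the Gaussian desired response
    target_size: tuple[float, float]
    patch_side: int
    learning_rate: float
    regularizer: float


def fft_correlate(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Circular cross-correlation via the FFT.

    ``out[dr, dc] = sum_mn a[m, n] * b[(m+dr) % M, (n+dc) % N]``.
    """
    A = np.fft.fft2(a)
    B = np.fft.fft2(b)
    return np.real(np.fft.ifft2(np.conj(A) * B))


def _hann2d(n: int) -> np.ndarray:
    h = np.hanning(n)
    return np.outer(h, h)


def _preprocess(patch: np.ndarray, window: np.ndarray, log: bool) -> np.ndarray:
    p = patch.astype(np.float64)
    if log:
        p = np.log1p(p)
    p -= p.mean()
    norm = np.linalg.norm(p)
    if norm < 1e-12:
        warnings.warn("near-constant patch; correlation filter is degenerate",
                      stacklevel=3)
    else:
        p /= norm
    return p * window


def _gaussian_response(n: int, sigma: float) -> np.ndarray:
    # peak exactly at index n//2, the pixel ifftshift maps to the origin,
    # so a zero displacement lands on the fftshifted grid center
    xs = np.arange(n) - n // 2
    return np.exp(-0.5 * (xs[:, None] ** 2 + xs[None, :] ** 2) / sigma**2)


def _affine_perturb(
    patch: np.ndarray, rng: np.random.Generator, rot: float, scale: float
) -> np.ndarray:
    angle = rng.uniform(-rot, rot)
    s = 1.0 + rng.uniform(-scale, scale)
    ca, sa = np.cos(angle) / s, np.sin(angle) / s
    mat = np.array([[ca, -sa], [sa, ca]])
    c = (np.asarray(patch.shape) - 1) / 2.0
    offset = c - mat @ c
    return ndimage.affine_transform(
        patch.astype(np.float64), mat, offset=offset, order=1, mode="nearest"
    )


def init_filter(
    frame: np.ndarray,
    box: tuple[float, float, float, float],
    config: DCFConfig | None = None,
    n_aug: int | None = None,
    rng: np.random.Generator | None = None,
) -> CorrelationFilterState:
    """Solve the initial filter from augmented copies of the init patch.

    *box* is (cx, cy, w, h); must lie inside the frame.
    """
    config = config or DCFConfig()
    n_aug = config.n_aug if n_aug is None else n_aug
    rng = rng or np.random.default_rng(0)
    cx, cy, w, h = box
    fh, fw = np.asarray(frame).shape
    if not (0 <= cx - w / 2 and cx + w / 2 <= fw and 0 <= cy - h / 2 and cy + h / 2 <= fh):
        raise ValueError(f"init box {box} not inside frame {fw}x{fh}")
    side = int(round(config.patch_factor * max(w, h)))
    side += side % 2  # keep even for a stable fftshift center
    window = _hann2d(side)
    sigma = config.sigma_factor * float(np.hypot(w, h))
    g = np.fft.ifftshift(_gaussian_response(side, sigma))
    G = np.fft.fft2(g)

    patch = crop_patch(frame, (cx, cy), side, side)
    num = np.zeros((side, side), dtype=np.complex128)
    den = np.zeros((side, side), dtype=np.float64)
    for k in range(max(1, n_aug)):
        p = patch if k == 0 else _affine_perturb(patch, rng, config.aug_rotation, config.aug_scale)
        F = np.fft.fft2(_preprocess(p, window, config.log_preprocess))
        num += G * np.conj(F)
        den += np.real(F * np.conj(F))
    k = max(1, n_aug)
    return CorrelationFilterState(
        numerator=num / k,
        denominator=den / k,
        window=window,
        desired_spectrum=G,
        target_size=(float(w), float(h)),
        patch_side=side,
        learning_rate=config.learning_rate,
        regularizer=config.regularizer,
    )


def _subpixel_peak(resp: np.ndarray, r: int, c: int) -> tuple[float, float]:
    """1D quadratic refinement around an argmax on each axis."""
    def refine(vm1, v0, vp1):
        denom = vm1 - 2 * v0 + vp1
        if abs(denom) < 1e-12:
            return 0.0
        d = 0.5 * (vm1 - vp1) / denom
        return float(np.clip(d, -0.5, 0.5))

    h, w = resp.shape
    dy = dx = 0.0
    if 0 < r < h - 1:
        dy = refine(resp[r - 1, c], resp[r, c], resp[r + 1, c])
    if 0 < c < w - 1:
        dx = refine(resp[r, c - 1], resp[r, c], resp[r, c + 1])
    return dx, dy


def respond(
    state: CorrelationFilterState,
    frame: np.ndarray,
    center: tuple[float, float],
    config: DCFConfig | None = None,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Correlate the filter with the patch at *center*; return the
    (fftshifted) response grid and the updated center estimate."""
    config = config or DCFConfig()
    patch = crop_patch(frame, center, state.patch_side, state.patch_side)
    F = np.fft.fft2(_preprocess(patch, state.window, config.log_preprocess))
    H = state.numerator / (state.denominator + state.regularizer)
    resp = np.real(np.fft.ifft2(H * F))
    resp = np.fft.fftshift(resp)
    r, c = np.unravel_index(int(np.argmax(resp)), resp.shape)
    mid = state.patch_side // 2
    dx, dy = _subpixel_peak(resp, r, c)
    new_center = (center[0] + (c - mid) + dx, center[1] + (r - mid) + dy)
    return resp, new_center


def update_filter(
    state: CorrelationFilterState,
    frame: np.ndarray,
    center: tuple[float, float],
    config: DCFConfig | None = None,
) -> CorrelationFilterState:
    """Exponential-moving-average update of the filter at the new center."""
    config = config or DCFConfig()
    lr = state.learning_rate
    patch = crop_patch(frame, center, state.patch_side, state.patch_side)
    F = np.fft.fft2(_preprocess(patch, state.window, config.log_preprocess))
    num = (1.0 - lr) * state.numerator + lr * state.desired_spectrum * np.conj(F)
    den = (1.0 - lr) * state.denominator + lr * np.real(F * np.conj(F))
    return CorrelationFilterState(
        numerator=num,
        denominator=den,
        window=state.window,
        desired_spectrum=state.desired_spectrum,
        target_size=state.target_size,
        patch_side=state.patch_side,
        learning_rate=state.learning_rate,
        regularizer=state.regularizer,
    )


def track_sequence_dcf(
    frames,
    init_box: tuple[float, float, float, float],
    config: DCFConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Trace:
    """Track a sequence with the online correlation filter."""
    config = config or DCFConfig()
    n = len(frames)
    if n == 0:
        raise ValueError("empty frame list")
    frame0 = np.asarray(frames[0])
    fh, fw = frame0.shape
    state = init_filter(frame0, init_box, config, rng=rng or np.random.default_rng(0))
    center = (float(init_box[0]), float(init_box[1]))
    centers = np.empty((n, 2))
    centers[0] = center
    for t in range(1, n):
        frame = np.asarray(frames[t])
        _, center = respond(state, frame, center, config)
        center = (
            float(np.clip(center[0], 0, fw - 1)),
            float(np.clip(center[1], 0, fh - 1)),
        )
        state = update_filter(state, frame, center, config)
        centers[t] = center
    return Trace(centers)
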