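"""Frequency-tuned saliency map for near-uniform trap backgrounds.

The saliency score of a pixel is the Euclidean distance, in CIELAB
space, between the image's mean colour and the Gaussian-blurred colour
at that pixel:

    S(r, c) = || I_mu - [L_blur(r,c), a_blur(r,c), b_blur(r,c)] ||_2

where ``I_mu`` is the (L, a, b) mean vector of the *unblurred* planes.
On a yellow sticky trap the background is close to the mean colour
everywhere, so small dark insects light up while the card stays dark.
The map is rescaled to [0, 1] before thresholding so that the mask
threshold ``alpha`` has a fixed meaning across images.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.color import rgb2lab


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError(f"expected H x W x 3 RGB image, got shape {image.shape}")
    return image


def to_lab(image: np.ndarray) -> np.ndarray:
    """sRGB (uint8 or float in [0,1]) to CIELAB planes, shape H x W x 3.

    Uses the standard D65 conversion; L in [0, 100], a/b roughly
    [-128, 127].
    """
    image = _validate_rgb(image)
    if np.issubdtype(image.dtype, np.integer):
        image = image.astype(np.float64) / 255.0
    return rgb2lab(image)


def gaussian_smooth(plane: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian blur of a single real-valued plane.

    Boundary handling is edge replication, so a constant plane stays
    exactly constant.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    plane = np.asarray(plane, dtype=np.float64)
    return gaussian_filter(plane, sigma=sigma, mode="nearest")


def compute_saliency(image: np.ndarray, sigma: float = 3.0) -> np.ndarray:
    """Raw (unnormalised) saliency map, shape H x W, values >= 0."""
    lab = to_lab(image)
    mu = lab.reshape(-1, 3).mean(axis=0)
    blurred = np.stack(
        [gaussian_smooth(lab[:, :, ch], sigma) for ch in range(3)], axis=-1
    )
    return np.linalg.norm(mu[None, None, :] - blurred, axis=-1)


def normalize_saliency(saliency: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """Rescale a non-negative map so its maximum is 1.

    Maps whose peak is below ``eps`` are numerically indistinguishable
    from a featureless image (floating-point residue of the blur) and
    are returned unscaled, so a uniform image yields an empty mask
    instead of amplified noise.
    """
    saliency = np.asarray(saliency, dtype=np.float64)
    if np.any(saliency < 0):
        raise ValueError("saliency scores must be non-negative")
    peak = saliency.max(initial=0.0)
    if peak > eps:
        return saliency / peak
    return saliency.copy()


def threshold_mask(saliency: np.ndarray, alpha: float) -> np.ndarray:
    """Binary mask: 1 where the normalised saliency is >= alpha."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    saliency = np.asarray(saliency)
    return (saliency >= alpha).astype(np.uint8)
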