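"""k-space undersampling: masks and the Fourier undersampling operator.

The measurement model for single-coil Cartesian CS-MRI is

    y = F_U X + noise,        F_U = M ∘ F,

where ``F`` is the orthonormal 2-D discrete Fourier transform (DC centred,
i.e. fftshift convention) and ``M`` restricts to the acquired k-space
locations.  Because ``F`` is unitary, ``F_Uᴴ F_U`` is diagonal in the
Fourier domain — multiplication by the boolean mask — which is what makes
the solver's image update an exact closed-form solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MASK_PATTERNS = ("variable_density_random", "cartesian_lines", "uniform_random")

__all__ = [
    "SamplingMask",
    "KSpace",
    "make_mask",
    "fft2c",
    "ifft2c",
    "apply_FU",
    "apply_FU_adjoint",
    "MASK_PATTERNS",
]


def fft2c(x: np.ndarray) -> np.ndarray:
    """Orthonormal centred 2-D DFT (DC at the array centre)."""
    return np.fft.fftshift(np.fft.fft2(x, norm="ortho"))


def ifft2c(y: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c`."""
    return np.fft.ifft2(np.fft.ifftshift(y), norm="ortho")


@dataclass(frozen=True)
class SamplingMask:
    """Boolean k-space acquisition support, DC-centred.

    Attributes
    ----------
    support : (P, O) bool array
        True where the k-space location is acquired.
    pattern : str
        One of ``MASK_PATTERNS`` (or "custom").
    seed : int
        RNG seed the mask was drawn with.
    """

    support: np.ndarray
    pattern: str = "custom"
    seed: int = 0

    def __post_init__(self) -> None:
        sup = np.asarray(self.support, dtype=bool)
        if sup.ndim != 2:
            raise ValueError("mask support must be 2-D")
        if not sup.any():
            raise ValueError("mask must acquire at least one sample")
        object.__setattr__(self, "support", sup)

    @property
    def shape(self) -> tuple[int, int]:
        return self.support.shape

    @property
    def fraction(self) -> float:
        """Acquired fraction of k-space."""
        return float(self.support.sum()) / self.support.size


@dataclass(frozen=True)
class KSpace:
    """Acquired k-space samples; exactly zero off the mask support."""

    samples: np.ndarray
    mask: SamplingMask

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=complex)
        if s.shape != self.mask.shape:
            raise ValueError("samples/mask shape mismatch")
        if np.any(s[~self.mask.support] != 0):
            raise ValueError("k-space samples must be zero off the mask support")
        object.__setattr__(self, "samples", s)

    @property
    def shape(self) -> tuple[int, int]:
        return self.samples.shape


def _center_indices(shape: tuple[int, int]) -> tuple[int, int]:
    return shape[0] // 2, shape[1] // 2


def make_mask(
    shape: tuple[int, int],
    pattern: str = "variable_density_random",
    fraction: float = 0.3,
    seed: int = 0,
    density_exponent: float = 3.0,
    center_fraction: float = 0.04,
) -> SamplingMask:
    """Draw a seeded k-space sampling mask.

    Parameters
    ----------
    shape : (P, O)
        k-space grid size.
    pattern : str
        ``variable_density_random`` — pointwise samples with radial density
        ∝ (1 + r/r0)^(−d) plus a fully sampled centre disc; ``cartesian_lines``
        — whole phase-encode rows, centre-weighted; ``uniform_random`` —
        unweighted pointwise samples.
    fraction : float in (0, 1]
        Target acquired fraction.  Pointwise patterns hit the rounded target
        count exactly; ``cartesian_lines`` rounds to whole lines.
    density_exponent, center_fraction
        Variable-density shape parameters (d and the fully sampled centre
        radius as a fraction of the maximum radius).

    The DC location is always acquired for the variable-density and
    Cartesian patterns.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if pattern not in MASK_PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; expected one of {MASK_PATTERNS}")
    P, O = shape
    n = P * O
    rng = np.random.default_rng(seed)
    target = int(round(fraction * n))
    target = max(1, min(target, n))
    support = np.zeros(shape, dtype=bool)
    cr, cc = _center_indices(shape)

    if pattern == "uniform_random":
        chosen = rng.choice(n, size=target, replace=False)
        support.flat[chosen] = True
    elif pattern == "cartesian_lines":
        n_lines = max(1, int(round(fraction * P)))
        rows = np.arange(P)
        r = np.abs(rows - cr) / max(cr, 1)
        w = (1.0 + r * 10.0) ** (-density_exponent)
        w[cr] = 0.0  # DC line forced on below, sample the rest
        picks = [cr]
        if n_lines > 1:
            w = w / w.sum()
            extra = rng.choice(P, size=n_lines - 1, replace=False, p=w)
            picks.extend(extra.tolist())
        support[np.array(picks)] = True
    else:  # variable_density_random
        rr, cc_grid = np.meshgrid(np.arange(P), np.arange(O), indexing="ij")
        rad = np.hypot(rr - cr, cc_grid - cc)
        rmax = rad.max() if rad.max() > 0 else 1.0
        r0 = 0.1 * rmax
        density = (1.0 + rad / r0) ** (-density_exponent)
        center = rad <= center_fraction * rmax
        support |= center
        deficit = target - int(support.sum())
        if deficit > 0:
            avail = ~support.reshape(-1)
            w = density.reshape(-1) * avail
            w = w / w.sum()
            extra = rng.choice(n, size=deficit, replace=False, p=w)
            support.flat[extra] = True
        support[cr, cc] = True

    return SamplingMask(support=support, pattern=pattern, seed=seed)


def apply_FU(image: np.ndarray, mask: SamplingMask) -> KSpace:
    """Undersampled orthonormal Fourier transform: y = M ∘ F(image)."""
    image = np.asarray(image)
    if image.shape != mask.shape:
        raise ValueError(
            f"image shape {image.shape} does not match mask shape {mask.shape}"
        )
    samples = fft2c(image)
    samples[~mask.support] = 0
    return KSpace(samples=samples, mask=mask)


def apply_FU_adjoint(y: KSpace) -> np.ndarray:
    """Zero-filled reconstruction F_Uᴴ y (complex image)."""
    return ifft2c(y.samples)
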