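"""Patch-based directional wavelet sparsifying transform.

The analysis operator B maps an image X to one coefficient vector per
overlapping patch:

    B X = [ W P(ξ₁) Q₁ X, …, W P(ξ_I) Q_I X ],

where Q_i extracts the i-th b×b patch (periodic wrap at the borders,
stride s, so every pixel is covered by exactly p = (b/s)² patches),
P(ξ_i) is a permutation reordering the patch's pixels along the direction
selected for that patch, and W is a 1-D orthonormal wavelet on the
length-b² vector.  Each per-patch operator W P Q_iᵀ-composition is an
isometry, and Σ Q_iᵀQ_i = p·I, so B is a tight frame with frame constant
p: synthesis is the scaled adjoint, X = (1/p)·Bᵀ(BX).

Direction selection picks, per patch, the candidate direction minimizing
the energy left outside the E largest-magnitude wavelet coefficients —
aligning the 1-D transform with the local edge orientation sharpens
sparsity compared with a fixed axis-aligned ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pywt

__all__ = [
    "DEFAULT_DIRECTIONS",
    "PatchGeometry",
    "DirectionSet",
    "DirectionAssignment",
    "CoefficientSet",
    "direction_order",
    "wavelet_matrix",
    "transform_1d",
    "inverse_transform_1d",
    "extract_patches",
    "scatter_patches",
    "assemble_patches",
    "select_direction",
    "export_direction_map",
    "DirectionalPatchTransform",
    "GlobalWaveletTransform",
]

# Eight primitive integer step vectors (Δrow, Δcol): horizontal, vertical,
# the two diagonals, and four "knight's move" orientations.
DEFAULT_DIRECTIONS: tuple[tuple[int, int], ...] = (
    (0, 1),
    (1, 0),
    (1, 1),
    (1, -1),
    (1, 2),
    (2, 1),
    (-1, 2),
    (2, -1),
)


@dataclass(frozen=True)
class PatchGeometry:
    """Overlapping square patch tiling with periodic wrap.

    ``patch_size`` b must be a multiple of ``stride`` s, and s must divide
    both image dimensions; then every pixel is covered by exactly
    p = (b/s)² patches and there are I = (P/s)·(O/s) patches.
    """

    image_shape: tuple[int, int]
    patch_size: int = 8
    stride: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "image_shape", tuple(int(d) for d in self.image_shape))
        P, O = self.image_shape
        b, s = self.patch_size, self.stride
        if b < 1 or s < 1:
            raise ValueError("patch_size and stride must be positive")
        if b % s != 0:
            raise ValueError(f"patch_size {b} must be divisible by stride {s}")
        if P % s != 0 or O % s != 0:
            raise ValueError(
                f"stride {s} must divide both image dimensions {self.image_shape}"
            )

    @property
    def overlap_count(self) -> int:
        """p — number of patches covering each pixel."""
        return (self.patch_size // self.stride) ** 2

    @property
    def patch_origins(self) -> list[tuple[int, int]]:
        P, O = self.image_shape
        s = self.stride
        return [(r * s, c * s) for r in range(P // s) for c in range(O // s)]

    @property
    def n_patches(self) -> int:
        P, O = self.image_shape
        return (P // self.stride) * (O // self.stride)

    @property
    def gather_indices(self) -> np.ndarray:
        """(I, b²) flat indices into the image for each patch, wrapping."""
        return _gather_indices(self.image_shape, self.patch_size, self.stride)


@lru_cache(maxsize=32)
def _gather_indices(
    image_shape: tuple[int, int], patch_size: int, stride: int
) -> np.ndarray:
    P, O = image_shape
    b, s = patch_size, stride
    orows = np.arange(P // s) * s
    ocols = np.arange(O // s) * s
    rr = (orows[:, None] + np.arange(b)[None, :]) % P  # (nr, b)
    cc = (ocols[:, None] + np.arange(b)[None, :]) % O  # (nc, b)
    # index[i_r, i_c, u, v] = flat index of pixel (rr[i_r,u], cc[i_c,v])
    idx = rr[:, None, :, None] * O + cc[None, :, None, :]
    idx = idx.reshape(len(orows) * len(ocols), b * b)
    idx.setflags(write=False)
    return idx


def extract_patches(X: np.ndarray, geom: PatchGeometry) -> np.ndarray:
    """All patches Q_i X as an (I, b²) array, ordered by patch origin."""
    X = np.asarray(X)
    if X.shape != geom.image_shape:
        raise ValueError(f"image shape {X.shape} != geometry {geom.image_shape}")
    return X.reshape(-1)[geom.gather_indices]


def scatter_patches(patches: np.ndarray, geom: PatchGeometry) -> np.ndarray:
    """Unscaled adjoint of extraction: Σ Q_iᵀ(patch_i)."""
    patches = np.asarray(patches)
    idx = geom.gather_indices
    if patches.shape != idx.shape:
        raise ValueError(f"patches shape {patches.shape} != expected {idx.shape}")
    out = np.zeros(geom.image_shape[0] * geom.image_shape[1], dtype=patches.dtype)
    np.add.at(out, idx.reshape(-1), patches.reshape(-1))
    return out.reshape(geom.image_shape)


def assemble_patches(patches: np.ndarray, geom: PatchGeometry) -> np.ndarray:
    """(1/p)·Σ Q_iᵀ(patch_i); inverts :func:`extract_patches` exactly."""
    return scatter_patches(patches, geom) / geom.overlap_count


@lru_cache(maxsize=256)
def _direction_order_cached(direction: tuple[int, int], b: int) -> np.ndarray:
    dr, dc = direction
    if dr == 0 and dc == 0:
        raise ValueError("direction (0, 0) is not a valid step vector")
    idx = np.arange(b * b)
    r, c = np.divmod(idx, b)
    # pixels on a common line parallel to (dr, dc) share r·dc − c·dr
    line = r * dc - c * dr
    t = r * dr + c * dc  # position along the line
    # lines ordered by their first pixel in row-major scan; stable within line
    first = {}
    for i in idx:
        first.setdefault(int(line[i]), int(i))
    rank = {l: k for k, (l, _) in enumerate(sorted(first.items(), key=lambda kv: kv[1]))}
    perm = np.array(
        sorted(idx, key=lambda i: (rank[int(line[i])], int(t[i]), int(i))),
        dtype=np.intp,
    )
    perm.setflags(write=False)
    return perm


def direction_order(direction: tuple[int, int], b: int) -> np.ndarray:
    """Permutation of the b² row-major pixel indices of a b×b patch.

    Pixels are listed along lines parallel to ``direction``; lines are taken
    in order of their first pixel in a row-major scan.  For (0, 1) this is
    row-major order, for (1, 0) column-major.
    """
    perm = _direction_order_cached((int(direction[0]), int(direction[1])), int(b))
    if sorted(perm.tolist()) != list(range(b * b)):  # pragma: no cover - by construction
        raise ValueError(f"direction {direction} does not induce a permutation")
    return perm


@dataclass(frozen=True)
class DirectionSet:
    """Ordered candidate directions; each must permute a b×b patch."""

    candidates: tuple[tuple[int, int], ...] = DEFAULT_DIRECTIONS

    def __post_init__(self) -> None:
        cands = tuple((int(d[0]), int(d[1])) for d in self.candidates)
        if not cands:
            raise ValueError("candidate direction set must be nonempty")
        if len(set(cands)) != len(cands):
            raise ValueError("candidate directions must be pairwise distinct")
        if any(d == (0, 0) for d in cands):
            raise ValueError("direction (0, 0) is not a valid step vector")
        object.__setattr__(self, "candidates", cands)

    def __len__(self) -> int:
        return len(self.candidates)

    def permutations(self, b: int) -> np.ndarray:
        """(C, b²) array of pixel permutations."""
        return np.stack([direction_order(d, b) for d in self.candidates])


@dataclass(frozen=True)
class DirectionAssignment:
    """Per-patch selected direction index and its selection residual."""

    selected: np.ndarray  # (I,) int indices into the DirectionSet
    residuals: np.ndarray  # (I,) the minimized out-of-support energy

    def __post_init__(self) -> None:
        sel = np.asarray(self.selected, dtype=np.intp)
        res = np.asarray(self.residuals, dtype=float)
        if sel.shape != res.shape:
            raise ValueError("selected/residuals length mismatch")
        if np.any(res < -1e-12):
            raise ValueError("residuals must be nonnegative")
        object.__setattr__(self, "selected", sel)
        object.__setattr__(self, "residuals", np.maximum(res, 0.0))

    def __len__(self) -> int:
        return len(self.selected)


@dataclass(frozen=True)
class CoefficientSet:
    """Per-patch wavelet coefficient vectors ∂_i, stacked as an (I, b²) array."""

    coeffs: np.ndarray
    geometry: PatchGeometry
    directions: DirectionAssignment

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs)
        expected = (self.geometry.n_patches, self.geometry.patch_size**2)
        if c.shape != expected:
            raise ValueError(f"coefficient array shape {c.shape} != {expected}")
        if len(self.directions) != self.geometry.n_patches:
            raise ValueError("direction assignment length != patch count")
        object.__setattr__(self, "coeffs", c)


@lru_cache(maxsize=8)
def wavelet_matrix(n: int, wavelet: str = "db4") -> np.ndarray:
    """The n×n orthonormal matrix of a periodized 1-D wavelet decomposition.

    Full multilevel decomposition with mode="periodization", which keeps an
    orthogonal wavelet orthonormal; the level is capped by the 2-adic depth
    of n.  Rows are the analysis functionals: forward transform = W @ v.
    """
    w = pywt.Wavelet(wavelet)
    if not w.orthogonal:
        raise ValueError(f"wavelet {wavelet!r} is not orthogonal")
    two_adic = 0
    m = n
    while m % 2 == 0:
        m //= 2
        two_adic += 1
    level = min(pywt.dwt_max_level(n, w.dec_len), two_adic)
    if level < 1:
        raise ValueError(f"length {n} too short for wavelet {wavelet!r}")
    eye = np.eye(n)
    cols = [
        np.concatenate(pywt.wavedec(eye[:, j], w, mode="periodization", level=level))
        for j in range(n)
    ]
    W = np.stack(cols, axis=1)
    if not np.allclose(W.T @ W, eye, atol=1e-10):  # pragma: no cover - sanity
        raise AssertionError(f"wavelet matrix for {wavelet!r} is not orthonormal")
    W.setflags(write=False)
    return W


def transform_1d(v: np.ndarray, wavelet: str = "db4") -> np.ndarray:
    """Orthonormal 1-D wavelet transform of a length-b² patch vector."""
    v = np.asarray(v)
    if v.ndim != 1:
        raise ValueError("expected a 1-D vector")
    return wavelet_matrix(len(v), wavelet) @ v


def inverse_transform_1d(w: np.ndarray, wavelet: str = "db4") -> np.ndarray:
    """Inverse (= transpose) of :func:`transform_1d`."""
    w = np.asarray(w)
    if w.ndim != 1:
        raise ValueError("expected a 1-D vector")
    return wavelet_matrix(len(w), wavelet).T @ w


def _residual_energy(w: np.ndarray, E: int) -> float:
    """Energy outside the E largest-magnitude entries.

    Summed over the smallest squared magnitudes in ascending order, so the
    value is independent of which equal-magnitude entry a tie-break keeps
    and bitwise reproducible across the scalar and batch code paths.
    """
    sq = np.sort(np.abs(w) ** 2)
    return float(sq[: len(w) - E].sum())


def select_direction(
    patch: np.ndarray,
    dirs: DirectionSet,
    E: int,
    wavelet: str = "db4",
) -> tuple[int, float]:
    """Best direction for one b×b patch.

    For each candidate c the patch's pixels (magnitudes, if complex) are
    reordered along c and wavelet-transformed; the score is the squared
    l2 energy outside the E largest-magnitude coefficients.  Returns the
    argmin index and its score; ties go to the lowest candidate index.
    """
    patch = np.asarray(patch)
    b = patch.shape[0]
    if patch.shape != (b, b):
        raise ValueError("patch must be square")
    if not 1 <= E <= b * b:
        raise ValueError(f"retain count E must be in [1, {b * b}], got {E}")
    v = np.abs(patch).reshape(-1)  # selection scores pixel magnitudes
    W = wavelet_matrix(b * b, wavelet)
    best_c, best_score = 0, np.inf
    for c in range(len(dirs)):
        perm = direction_order(dirs.candidates[c], b)
        w = W @ v[perm]
        score = _residual_energy(w, E)
        if score < best_score:  # strict: ties keep the earlier index
            best_c, best_score = c, score
    return best_c, best_score


class DirectionalPatchTransform:
    """Tight-frame analysis/synthesis with per-patch direction selection.

    Parameters
    ----------
    image_shape : (P, O)
    patch_size, stride : int
        b and s; defaults 8 and 4 give overlap count p = 4.
    wavelet : {"haar", "db4"}
        The 1-D orthonormal transform applied along the selected direction.
    directions : DirectionSet
    retain_count : int, optional
        E used when scoring directions; default ⌈b²/4⌉.
    """

    def __init__(
        self,
        image_shape: tuple[int, int],
        patch_size: int = 8,
        stride: int = 4,
        wavelet: str = "db4",
        directions: DirectionSet | None = None,
        retain_count: int | None = None,
    ):
        self.geometry = PatchGeometry(tuple(image_shape), patch_size, stride)
        self.wavelet = wavelet
        self.directions = directions if directions is not None else DirectionSet()
        b = patch_size
        if retain_count is None:
            retain_count = math.ceil(b * b / 4)
        if not 1 <= retain_count <= b * b:
            raise ValueError(f"retain_count must be in [1, {b * b}]")
        self.retain_count = int(retain_count)
        self.W = wavelet_matrix(b * b, wavelet)
        self._perms = self.directions.permutations(b)

    @property
    def overlap_count(self) -> int:
        return self.geometry.overlap_count

    def select_directions(self, X: np.ndarray) -> DirectionAssignment:
        """Choose the best direction for every patch of X (vectorized)."""
        mags = np.abs(extract_patches(X, self.geometry))  # (I, b²)
        n = mags.shape[1]
        E = self.retain_count
        scores = np.empty((len(self.directions), mags.shape[0]))
        for c, perm in enumerate(self._perms):
            wc = mags[:, perm] @ self.W.T
            if E >= n:
                scores[c] = 0.0
            else:
                sq = np.sort(wc * wc, axis=1)
                scores[c] = sq[:, : n - E].sum(axis=1)
        selected = np.argmin(scores, axis=0)  # first minimum -> lowest index
        residuals = scores[selected, np.arange(mags.shape[0])]
        return DirectionAssignment(selected=selected, residuals=residuals)

    def analyze(self, X: np.ndarray, assignment: DirectionAssignment) -> CoefficientSet:
        """∂_i = W P(ξ_i) Q_i X for every patch."""
        if len(assignment) != self.geometry.n_patches:
            raise ValueError("assignment length != patch count")
        patches = extract_patches(X, self.geometry)
        coeffs = np.empty_like(patches)
        for c, perm in enumerate(self._perms):
            m = assignment.selected == c
            if m.any():
                coeffs[m] = patches[m][:, perm] @ self.W.T
        return CoefficientSet(coeffs=coeffs, geometry=self.geometry, directions=assignment)

    def synthesize_raw(self, coeffs: CoefficientSet) -> np.ndarray:
        """Unscaled adjoint Σ Q_iᵀ Pᵀ(ξ_i) Wᵀ ∂_i."""
        if coeffs.geometry is not self.geometry and coeffs.geometry != self.geometry:
            raise ValueError("coefficient set geometry mismatch")
        patches = np.empty_like(coeffs.coeffs)
        for c, perm in enumerate(self._perms):
            m = coeffs.directions.selected == c
            if m.any():
                v = coeffs.coeffs[m] @ self.W  # Wᵀ per row
                patches[np.ix_(m, perm)] = v
        return scatter_patches(patches, self.geometry)

    def synthesize(self, coeffs: CoefficientSet) -> np.ndarray:
        """Tight-frame synthesis (1/p)·Bᵀ; inverts :meth:`analyze` exactly."""
        return self.synthesize_raw(coeffs) / self.overlap_count


def export_direction_map(
    assignment: DirectionAssignment, geom: PatchGeometry, path
) -> None:
    """Debug export: per-patch selected direction and residual as CSV
    (patch_row, patch_col, direction_index, residual)."""
    import csv

    origins = geom.patch_origins
    if len(assignment) != len(origins):
        raise ValueError("assignment length != patch count")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patch_row", "patch_col", "direction_index", "residual"])
        for (r, c), d, res in zip(
            origins, assignment.selected, assignment.residuals
        ):
            writer.writerow([r, c, int(d), repr(float(res))])


class GlobalWaveletTransform:
    """Single orthonormal 2-D wavelet over the whole image (baseline).

    The conventional CS sparsifier: no patches, no directions, frame
    constant p = 1.  Uses a periodized separable multilevel decomposition,
    which is orthonormal for orthogonal wavelets.
    """

    def __init__(self, image_shape: tuple[int, int], wavelet: str = "db4"):
        self.image_shape = tuple(image_shape)
        self.wavelet = pywt.Wavelet(wavelet)
        if not self.wavelet.orthogonal:
            raise ValueError(f"wavelet {wavelet!r} is not orthogonal")
        n = min(self.image_shape)
        two_adic = 0
        while n % 2 == 0:
            n //= 2
            two_adic += 1
        self.level = min(
            pywt.dwt_max_level(min(self.image_shape), self.wavelet.dec_len), two_adic
        )
        if self.level < 1:
            raise ValueError(f"image too small for wavelet {wavelet!r}")
        # coefficient layout template for flatten/unflatten
        probe = pywt.wavedec2(
            np.zeros(self.image_shape), self.wavelet, mode="periodization",
            level=self.level,
        )
        _, self._slices = pywt.coeffs_to_array(probe)

    @property
    def overlap_count(self) -> int:
        return 1

    def analyze(self, X: np.ndarray) -> np.ndarray:
        """Flattened orthonormal 2-D wavelet coefficients of X."""
        X = np.asarray(X)
        if X.shape != self.image_shape:
            raise ValueError(f"image shape {X.shape} != {self.image_shape}")
        coeffs = pywt.wavedec2(X, self.wavelet, mode="periodization", level=self.level)
        arr, _ = pywt.coeffs_to_array(coeffs)
        return arr

    def synthesize_raw(self, coeffs: np.ndarray) -> np.ndarray:
        """Inverse transform (= adjoint, since orthonormal with p = 1)."""
        c = pywt.array_to_coeffs(coeffs, self._slices, output_format="wavedec2")
        return pywt.waverec2(c, self.wavelet, mode="periodization")

    synthesize = synthesize_raw
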