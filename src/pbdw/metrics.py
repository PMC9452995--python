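"""Reconstruction-quality metrics.

Three scores compare a reconstruction Ā against the ground truth A
(magnitude images, nominal 0–255 intensity scale):

* ``snr`` — a PSNR-style signal-to-noise ratio in dB,
  10·log10(R²·O·P / Σ(A − Ā)²) with full scale R (default 255);
* ``rlne`` — relative l2 norm error ‖A − Ā‖₂ / ‖A‖₂ (lower is better);
* ``gamma`` — the matching degree, in two variants.  The *printed* form
  (‖Ā‖² − ‖A‖²)/(‖Ā‖² + ‖A‖²) is a pure energy comparison that is 0 for a
  perfect match; the *similarity* form 2⟨A, Ā⟩/(‖A‖² + ‖Ā‖²) is a
  normalized correlation that equals 1 iff Ā = A.  Both are reported —
  see docs/methods.md for why the two variants coexist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["MetricsReport", "snr", "rlne", "gamma", "evaluate"]


def _as_magnitude(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    return np.abs(img) if np.iscomplexobj(img) else img.astype(float, copy=False)


def _check_shapes(A: np.ndarray, A_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    A, A_hat = _as_magnitude(A), _as_magnitude(A_hat)
    if A.shape != A_hat.shape:
        raise ValueError(f"image shapes differ: {A.shape} vs {A_hat.shape}")
    return A, A_hat


def snr(A: np.ndarray, A_hat: np.ndarray, value_range: float = 255.0) -> float:
    """Peak-signal-to-noise-style SNR in decibels.

    10·log10(value_range²·O·P / Σ(A − Ā)²).  Identical images give the
    +infinity sentinel (zero error).
    """
    A, A_hat = _check_shapes(A, A_hat)
    if value_range <= 0:
        raise ValueError("value_range must be > 0")
    err = float(np.sum((A - A_hat) ** 2))
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(value_range**2 * A.size / err)


def rlne(A: np.ndarray, A_hat: np.ndarray) -> float:
    """Relative l2 norm error ‖A − Ā‖₂ / ‖A‖₂."""
    A, A_hat = _check_shapes(A, A_hat)
    denom = float(np.linalg.norm(A))
    if denom == 0.0:
        raise ValueError("ground-truth image is all zero; RLNE undefined")
    return float(np.linalg.norm(A - A_hat)) / denom


def gamma(A: np.ndarray, A_hat: np.ndarray) -> tuple[float, float]:
    """Matching degree: (printed, similarity).

    printed    = (‖Ā‖² − ‖A‖²) / (‖Ā‖² + ‖A‖²)   ∈ [−1, 1], 0 at Ā = A
    similarity = 2⟨A, Ā⟩ / (‖A‖² + ‖Ā‖²)          ∈ [0, 1] for nonnegative
                 images, 1 iff Ā = A
    """
    A, A_hat = _check_shapes(A, A_hat)
    ea = float(np.sum(A * A))
    eh = float(np.sum(A_hat * A_hat))
    if ea + eh == 0.0:
        raise ValueError("both images are zero; matching degree undefined")
    printed = (eh - ea) / (eh + ea)
    similarity = 2.0 * float(np.sum(A * A_hat)) / (ea + eh)
    return printed, similarity


@dataclass(frozen=True)
class MetricsReport:
    """All metrics for one (ground truth, reconstruction) pair."""

    snr_db: float
    rlne: float
    gamma_printed: float
    gamma_similarity: float
    width: int
    height: int
    value_range: float
    truth_id: str = ""
    recon_id: str = ""

    def to_dict(self) -> dict:
        return {
            "snr_db": self.snr_db,
            "rlne": self.rlne,
            "gamma_printed": self.gamma_printed,
            "gamma_similarity": self.gamma_similarity,
            "width": self.width,
            "height": self.height,
            "value_range": self.value_range,
            "truth_id": self.truth_id,
            "recon_id": self.recon_id,
        }


def evaluate(
    A: np.ndarray,
    A_hat: np.ndarray,
    value_range: float = 255.0,
    truth_id: str = "",
    recon_id: str = "",
) -> MetricsReport:
    """Compute all three metrics at once (complex inputs reduced to magnitude)."""
    Am, Ah = _check_shapes(A, A_hat)
    g_printed, g_sim = gamma(Am, Ah)
    return MetricsReport(
        snr_db=snr(Am, Ah, value_range=value_range),
        rlne=rlne(Am, Ah),
        gamma_printed=g_printed,
        gamma_similarity=g_sim,
        width=Am.shape[1],
        height=Am.shape[0],
        value_range=value_range,
        truth_id=truth_id,
        recon_id=recon_id,
    )
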