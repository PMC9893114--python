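"""Complex eigenmode hierarchy and oscillation-balance indices.

The asymmetric effective adjacency is eigendecomposed over the complex field;
eigenvalue moduli measure the stretch each mode applies, so layers are ranked
by modulus.  The first (dominant) layer is never subdivided and represents
slow global integration, ``H_in = |L1|^2 / N^2``.  Every deeper layer is split
into up to three submodules by banding its eigenvector component moduli at
``AVG + SD`` and ``AVG + 2 SD`` (weak / balanced / strong deformation), and
contributes ``H_i = |Li|^2 * M_i * (1 - p_i) / N^2`` to the strong-local index
``H_se``, where ``M_i`` counts nonempty bands and ``p_i`` penalizes uneven
module sizes.  The balance index ``H_sb = H_in - H_se`` is reported both raw
and normalized to [-1, 1]; negative values mean strong-local dominance.
Rotation angles are computed and stored but deliberately do not enter the
indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network import EffectiveNetworkSnapshot

BAND_LABELS = ("weak", "balance", "strong")


@dataclass(frozen=True)
class SpectralDecomposition:
    """Eigenvalue moduli/angles and per-layer eigenvector component moduli.

    Layers are sorted by eigenvalue modulus descending (ties: angle
    ascending); eigenvectors are unit 2-norm before taking component moduli.
    """

    eigen_moduli: np.ndarray
    eigen_angles: np.ndarray
    component_moduli: np.ndarray  # (N layers, N components)
    N: int


@dataclass(frozen=True)
class LayerPartition:
    """Band partition of one eigen-layer's component moduli."""

    layer_index: int
    labels: np.ndarray  # per-node band label from BAND_LABELS
    module_sizes: np.ndarray  # sizes of the nonempty bands
    M: int
    p: float


@dataclass(frozen=True)
class OscillationIndices:
    """Slow-global (H_in), strong-local (H_se) and balance (H_sb) indices."""

    H_in: float
    H_se: float
    H_sb_raw: float
    H_sb_norm: float
    time: int = 0


def complex_spectrum(A: np.ndarray) -> SpectralDecomposition:
    """Eigendecompose a (generally asymmetric) adjacency matrix.

    Eigenpairs are sorted by modulus descending with ties broken by angle
    ascending; each eigenvector is normalized to unit 2-norm before its
    component moduli are taken.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    if not np.isfinite(A).all():
        raise ValueError("adjacency contains non-finite entries")
    vals, vecs = np.linalg.eig(A)
    moduli = np.abs(vals)
    angles = np.angle(vals)
    order = np.lexsort((angles, -moduli))  # stable: modulus desc, angle asc
    vals, vecs = vals[order], vecs[:, order]
    norms = np.linalg.norm(vecs, axis=0)
    norms[norms == 0] = 1.0
    comp = np.abs(vecs / norms).T
    return SpectralDecomposition(
        eigen_moduli=np.abs(vals),
        eigen_angles=np.angle(vals),
        component_moduli=comp,
        N=A.shape[0],
    )


def partition_layer(component_moduli: Sequence[float], layer_index: int) -> LayerPartition:
    """Band a deep layer's component moduli into weak / balance / strong.

    Bands are left-open right-closed at ``AVG + SD`` and ``AVG + 2 SD``
    computed from this eigenvector's own component moduli (population SD).
    Components of exactly zero fall in the weak band by convention.  Layer 1
    is never partitioned, hence ``layer_index >= 2``.
    """
    if layer_index < 2:
        raise ValueError("layer 1 is never subdivided; layer_index must be >= 2")
    v = np.asarray(component_moduli, dtype=float)
    if v.size == 0:
        raise ValueError("empty component vector")
    avg = v.mean()
    sd = v.std()
    t1, t2 = avg + sd, avg + 2 * sd
    labels = np.where(v <= t1, "weak", np.where(v <= t2, "balance", "strong"))
    sizes = np.array([int((labels == lab).sum()) for lab in BAND_LABELS])
    nonempty = sizes[sizes > 0]
    M = int(nonempty.size)
    N = v.size
    p = float(np.abs(nonempty - N / M).sum() / N)
    return LayerPartition(
        layer_index=layer_index, labels=labels, module_sizes=nonempty, M=M, p=p
    )


def layer_measure(eigen_modulus: float, part: LayerPartition, N: int) -> float:
    """Layer contribution H_i = |L_i|^2 * M_i * (1 - p_i) / N^2."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return float(eigen_modulus**2 * part.M * (1.0 - part.p) / N**2)


def oscillation_indices(
    spectrum: SpectralDecomposition,
    time: int = 0,
    hsb_normalization: str = "ratio",
) -> OscillationIndices:
    """Compute (H_in, H_se, H_sb) from a spectral decomposition.

    The undivided first layer has one module spanning all nodes (M1 = 1,
    p1 = 0), so ``H_in = |L1|^2 / N^2``; layers 2..N are partitioned and
    summed into H_se (both members of a conjugate pair are kept).  With
    ``hsb_normalization='ratio'`` the balance index is
    ``(H_in - H_se) / (H_in + H_se)``, 0 when both vanish; the alternative
    recording-max normalization lives in :func:`index_time_course`.
    """
    N = spectrum.N
    if N < 2:
        raise ValueError("need at least 2 nodes")
    H_in = float(spectrum.eigen_moduli[0] ** 2 / N**2)
    H_se = 0.0
    for i in range(2, N + 1):
        part = partition_layer(spectrum.component_moduli[i - 1], i)
        H_se += layer_measure(spectrum.eigen_moduli[i - 1], part, N)
    raw = H_in - H_se
    if hsb_normalization == "ratio":
        total = H_in + H_se
        norm = raw / total if total > 0 else 0.0
    elif hsb_normalization == "none":
        norm = raw
    else:
        raise ValueError(f"unknown hsb normalization {hsb_normalization!r}")
    return OscillationIndices(
        H_in=H_in, H_se=H_se, H_sb_raw=raw, H_sb_norm=float(norm), time=time
    )


def index_time_course(
    snapshots: Sequence[EffectiveNetworkSnapshot],
    hsb_normalization: str = "ratio",
) -> list[OscillationIndices]:
    """One OscillationIndices per snapshot, order preserved.

    ``hsb_normalization`` is ``'ratio'`` (per-time-point, default) or
    ``'global_max'`` (divide H_sb_raw by the recording-wide max |H_sb_raw|).
    """
    if not snapshots:
        raise ValueError("need at least one snapshot")
    if hsb_normalization == "global_max":
        raws = [
            oscillation_indices(complex_spectrum(s.A), time=s.time, hsb_normalization="none")
            for s in snapshots
        ]
        scale = max(abs(r.H_sb_raw) for r in raws)
        return [
            OscillationIndices(
                H_in=r.H_in,
                H_se=r.H_se,
                H_sb_raw=r.H_sb_raw,
                H_sb_norm=r.H_sb_raw / scale if scale > 0 else 0.0,
                time=r.time,
            )
            for r in raws
        ]
    return [
        oscillation_indices(complex_spectrum(s.A), time=s.time, hsb_normalization=hsb_normalization)
        for s in snapshots
    ]
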