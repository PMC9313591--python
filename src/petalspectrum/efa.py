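"""Elliptical Fourier analysis, landmark GPA and bilateral-symmetry algebra.

The coefficient convention is the classical chord-length parameterisation:
x(t) = A0 + sum_n a_n cos(2 pi n t / T) + b_n sin(2 pi n t / T) and the same
for y(t) with (C0, c_n, d_n), where t is cumulative arc length and T the
perimeter.  After alignment the bilateral axis lies along +x, so the mirror
image across that axis is exactly (a, -b, -c, d): the (b, c) coefficient
subspace is the mirror-antisymmetric part of shape and (a, d) the symmetric
part.  Removing left-right (within-specimen) asymmetry therefore zeroes b and
c — the coefficient-space average of a shape with its own mirror image.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import DegeneracyError, InputError, MappingError
from .outlines import LANDMARK_COUNT, Outline, SpecimenTable

__all__ = [
    "EFACoefficients",
    "AlignmentResult",
    "HarmonicCalibration",
    "gpa_align",
    "efa_forward",
    "efa_inverse",
    "harmonic_power",
    "calibrate_harmonic_count",
    "mirror_coefficients",
    "remove_asymmetric_component",
    "mean_shape_per_taxon",
]


@dataclass
class EFACoefficients:
    """Per-harmonic (a_n, b_n, c_n, d_n) quadruples for one outline."""

    harmonics: np.ndarray  # (N, 4) columns a, b, c, d
    offset: tuple[float, float] = (0.0, 0.0)  # (A0, C0)
    T: float = 1.0  # outline perimeter
    specimen_id: str = ""
    taxon_id: str = ""
    view: str = "front"
    clade: str | None = None

    def __post_init__(self):
        self.harmonics = np.asarray(self.harmonics, dtype=float)
        if self.harmonics.ndim != 2 or self.harmonics.shape[1] != 4:
            raise InputError("harmonics must be an (N, 4) array")
        if self.harmonics.shape[0] < 1:
            raise InputError("need at least one harmonic")
        if not np.all(np.isfinite(self.harmonics)):
            raise InputError("non-finite coefficient")

    @property
    def N(self) -> int:
        return self.harmonics.shape[0]

    def power(self) -> np.ndarray:
        """Per-harmonic power P_n = (a^2 + b^2 + c^2 + d^2) / 2."""
        return 0.5 * np.sum(self.harmonics**2, axis=1)

    def total_power(self) -> float:
        return float(self.power().sum())

    def truncated(self, N: int) -> "EFACoefficients":
        if not 1 <= N <= self.N:
            raise InputError(f"cannot truncate {self.N} harmonics to N={N}")
        return replace(self, harmonics=self.harmonics[:N].copy())

    def flattened(self) -> np.ndarray:
        """Row-major (a1, b1, c1, d1, a2, ...) vector of length 4N."""
        return self.harmonics.ravel().copy()

    @classmethod
    def from_flat(cls, vec, **meta) -> "EFACoefficients":
        vec = np.asarray(vec, dtype=float)
        if vec.size % 4:
            raise InputError("flat coefficient vector length must be a multiple of 4")
        return cls(vec.reshape(-1, 4), **meta)


@dataclass
class AlignmentResult:
    """Per-specimen similarity transforms plus the GPA consensus landmarks."""

    scales: np.ndarray  # (n,) composite scale applied to each outline
    angles: np.ndarray  # (n,) rotation angle (radians)
    translations: np.ndarray  # (n, 2) translation applied after scale+rotation
    consensus: np.ndarray  # (k, 2) unit-centroid-size consensus landmarks
    iterations: int = 0
    converged: bool = True


def _rotation(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s], [s, c]])


def _procrustes_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimising ||source @ R - target||_F (row vectors)."""
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def gpa_align(outlines, max_iter: int = 200, tol: float = 1e-10):
    """Full generalised Procrustes alignment of landmark configurations.

    The similarity transform (translation, scale, rotation) fitted on each
    specimen's landmarks is applied to the whole outline.  After convergence
    the set is rigidly rotated so the consensus bilateral axis (front:
    top->bottom landmark; side: tube base -> lip midpoint) lies along +x.

    Returns ``(aligned_outlines, AlignmentResult)``.
    """
    outlines = list(outlines)
    if len(outlines) < 2:
        raise InputError("GPA needs at least 2 outlines")
    views = {o.view for o in outlines}
    if len(views) != 1:
        raise InputError(f"all outlines must share one view, got {sorted(views)}")
    view = views.pop()
    k = LANDMARK_COUNT[view]
    for o in outlines:
        if len(o.landmarks) != k:
            raise InputError(
                f"specimen {o.specimen_id!r}: expected {k} landmarks, "
                f"got {len(o.landmarks)}"
            )

    configs = [o.landmark_coords().astype(float) for o in outlines]
    cents = [c.mean(axis=0) for c in configs]
    sizes = []
    for o, c, mu in zip(outlines, configs, cents):
        size = np.sqrt(np.sum((c - mu) ** 2))
        if size <= 0:
            raise DegeneracyError(f"specimen {o.specimen_id!r}: coincident landmarks")
        sv = np.linalg.svd(c - mu, compute_uv=False)
        if sv[-1] <= 1e-9 * sv[0]:
            raise DegeneracyError(
                f"specimen {o.specimen_id!r}: collinear landmark configuration"
            )
        sizes.append(size)
    normed = [(c - mu) / s for c, mu, s in zip(configs, cents, sizes)]

    consensus = normed[0].copy()
    consensus /= np.sqrt(np.sum(consensus**2))
    rotations = [np.eye(2) for _ in normed]
    betas = [1.0 for _ in normed]
    iterations, converged = 0, False
    for iterations in range(1, max_iter + 1):
        fitted = []
        for i, cfg in enumerate(normed):
            R = _procrustes_rotation(cfg, consensus)
            beta = float(np.trace((cfg @ R).T @ consensus) / np.sum(cfg**2))
            rotations[i], betas[i] = R, beta
            fitted.append(beta * (cfg @ R))
        new = np.mean(fitted, axis=0)
        new -= new.mean(axis=0)
        new /= np.sqrt(np.sum(new**2))
        # keep consensus orientation continuous between iterations
        new = new @ _procrustes_rotation(new, consensus)
        change = np.sqrt(np.sum((new - consensus) ** 2))
        consensus = new
        if change < tol:
            converged = True
            break

    # rotate everything so the consensus bilateral axis lies along +x
    if view == "front":
        axis = consensus[3] - consensus[2]  # top -> bottom landmark
    else:
        axis = 0.5 * (consensus[1] + consensus[2]) - consensus[0]
    phi = np.arctan2(axis[1], axis[0])
    R_axis = _rotation(-phi)
    consensus = consensus @ R_axis.T

    aligned, scales, angles, translations = [], [], [], []
    for o, mu, s, R, beta in zip(outlines, cents, sizes, rotations, betas):
        # row-vector transform: y = (x - mu) @ R * beta / s, then axis rotation
        A = (beta / s) * (R @ R_axis.T)
        pts = (o.points - mu) @ A
        aligned.append(o.with_points(pts))
        scales.append(beta / s)
        angles.append(float(np.arctan2(A[0, 1], A[0, 0])))
        translations.append(-(mu @ A))
    result = AlignmentResult(
        scales=np.array(scales),
        angles=np.array(angles),
        translations=np.array(translations),
        consensus=consensus,
        iterations=iterations,
        converged=converged,
    )
    return aligned, result


# ------------------------------------------------------------------- forward


def efa_forward(outline: Outline, N: int) -> EFACoefficients:
    """Elliptical Fourier decomposition of a closed outline at N harmonics."""
    if N < 1:
        raise InputError("N must be >= 1")
    pts = outline.points
    P = len(pts)
    if N > P / 2:
        raise InputError(f"N={N} exceeds n_points/2={P / 2:.0f} (aliasing)")
    closed = np.vstack([pts, pts[:1]])
    dxy = np.diff(closed, axis=0)
    dt = np.linalg.norm(dxy, axis=1)
    if np.any(dt <= 0):
        raise InputError("outline contains a zero-length segment")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    n = np.arange(1, N + 1)[:, None]
    phase = 2 * np.pi * n * t[None, :] / T  # (N, P+1)
    dcos = np.cos(phase[:, 1:]) - np.cos(phase[:, :-1])
    dsin = np.sin(phase[:, 1:]) - np.sin(phase[:, :-1])
    scale = T / (2 * n.ravel() ** 2 * np.pi**2)
    vx = dxy[:, 0] / dt
    vy = dxy[:, 1] / dt
    a = scale * (dcos @ vx)
    b = scale * (dsin @ vx)
    c = scale * (dcos @ vy)
    d = scale * (dsin @ vy)
    # offsets: arc-length mean of the piecewise-linear x(t), y(t)
    mids = 0.5 * (closed[1:] + closed[:-1])
    A0, C0 = (mids * dt[:, None]).sum(axis=0) / T
    return EFACoefficients(
        np.column_stack([a, b, c, d]),
        offset=(float(A0), float(C0)),
        T=float(T),
        specimen_id=outline.specimen_id,
        taxon_id=outline.taxon_id,
        view=outline.view,
        clade=outline.clade,
    )


def efa_inverse(coeffs: EFACoefficients, n_points: int = 300) -> Outline:
    """Reconstruct an outline by summing the truncated Fourier series."""
    t = np.linspace(0.0, coeffs.T, n_points, endpoint=False)
    n = np.arange(1, coeffs.N + 1)[:, None]
    phase = 2 * np.pi * n * t[None, :] / coeffs.T
    cosb, sinb = np.cos(phase), np.sin(phase)
    a, b, c, d = coeffs.harmonics.T
    x = coeffs.offset[0] + a @ cosb + b @ sinb
    y = coeffs.offset[1] + c @ cosb + d @ sinb
    return Outline(
        specimen_id=coeffs.specimen_id or "reconstructed",
        taxon_id=coeffs.taxon_id or "reconstructed",
        view=coeffs.view,
        points=np.column_stack([x, y]),
    )


def harmonic_power(coeffs: EFACoefficients) -> np.ndarray:
    """Cumulative harmonic-power fractions F_m (non-decreasing, F_N = 1)."""
    p = coeffs.power()
    total = p.sum()
    if total <= 0:
        raise DegeneracyError("outline has zero total harmonic power")
    return np.cumsum(p) / total


@dataclass
class HarmonicCalibration:
    n_harmonics: int
    reached: bool  # False if the threshold was never reached below N_max
    threshold: float
    mean_cumulative: np.ndarray

    def __int__(self) -> int:
        return self.n_harmonics


def calibrate_harmonic_count(outlines, threshold: float = 0.99, N_max: int = 64) -> HarmonicCalibration:
    """Smallest N <= N_max whose mean cumulative power fraction reaches ``threshold``.

    Power fractions are taken against the full available spectrum (up to the
    Nyquist harmonic of the coarsest outline, capped at 256), not against the
    N_max truncation — otherwise the fraction at N_max would be 1 by
    construction and an unreachable threshold could never be reported.  If the
    threshold is not reached by N_max, N_max is returned with
    ``reached=False``.
    """
    outlines = list(outlines)
    if not outlines:
        raise InputError("no outlines to calibrate on")
    if not 0.0 < threshold < 1.0:
        raise InputError("threshold must lie in (0, 1)")
    n_ref = min(min(o.n_points for o in outlines) // 2, 256)
    n_ref = max(n_ref, N_max)
    cums = np.array([harmonic_power(efa_forward(o, n_ref)) for o in outlines])
    mean_cum = cums.mean(axis=0)
    hit = np.flatnonzero(mean_cum[:N_max] >= threshold)
    if hit.size:
        return HarmonicCalibration(int(hit[0]) + 1, True, threshold, mean_cum)
    return HarmonicCalibration(N_max, False, threshold, mean_cum)


# ------------------------------------------------------------------ symmetry


def mirror_coefficients(coeffs: EFACoefficients) -> EFACoefficients:
    """Coefficients of the mirror image across the bilateral (+x) axis.

    With traversal direction restored, (a, b, c, d) -> (a, -b, -c, d) and
    (A0, C0) -> (A0, -C0).  An involution.
    """
    h = coeffs.harmonics.copy()
    h[:, 1] *= -1
    h[:, 2] *= -1
    return replace(coeffs, harmonics=h, offset=(coeffs.offset[0], -coeffs.offset[1]))


def remove_asymmetric_component(coeffs: EFACoefficients, component: str = "asymmetric") -> EFACoefficients:
    """Zero one mirror-symmetry subspace of the coefficients.

    ``component='asymmetric'`` (default) removes left-right variation: b_n and
    c_n (and C0) are zeroed, which equals averaging the shape with its own
    mirror image in coefficient space.  ``component='symmetric'`` zeroes a_n,
    d_n and A0 instead, keeping only the asymmetric residual.
    """
    h = coeffs.harmonics.copy()
    A0, C0 = coeffs.offset
    if component == "asymmetric":
        h[:, 1] = 0.0
        h[:, 2] = 0.0
        return replace(coeffs, harmonics=h, offset=(A0, 0.0))
    if component == "symmetric":
        h[:, 0] = 0.0
        h[:, 3] = 0.0
        return replace(coeffs, harmonics=h, offset=(0.0, C0))
    raise InputError("component must be 'asymmetric' or 'symmetric'")


def mean_shape_per_taxon(coeffs_by_specimen, specimen_table: SpecimenTable):
    """Arithmetic per-taxon mean of coefficients across that taxon's specimens.

    Single-specimen taxa pass through unchanged (apart from relabelling).
    Taxa are returned in first-appearance order of their specimens.
    """
    coeffs_by_specimen = list(coeffs_by_specimen)
    if not coeffs_by_specimen:
        return []
    Ns = {c.N for c in coeffs_by_specimen}
    if len(Ns) != 1:
        raise InputError(f"harmonic counts differ across specimens: {sorted(Ns)}")
    groups: dict[str, list[EFACoefficients]] = {}
    order: list[str] = []
    for c in coeffs_by_specimen:
        taxon = specimen_table.taxon_of(c.specimen_id)  # raises MappingError
        if taxon not in groups:
            groups[taxon] = []
            order.append(taxon)
        groups[taxon].append(c)
    means = []
    for taxon in order:
        members = groups[taxon]
        h = np.mean([m.harmonics for m in members], axis=0)
        A0 = float(np.mean([m.offset[0] for m in members]))
        C0 = float(np.mean([m.offset[1] for m in members]))
        T = float(np.mean([m.T for m in members]))
        clade = members[0].clade
        try:
            clade = specimen_table.clade_of_taxon(taxon)
        except MappingError:
            pass
        means.append(
            EFACoefficients(
                h,
                offset=(A0, C0),
                T=T,
                specimen_id=taxon,
                taxon_id=taxon,
                view=members[0].view,
                clade=clade,
            )
        )
    return means
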