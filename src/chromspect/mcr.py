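"""Multivariate curve resolution by alternating regression (MCR-AR).

Beer–Lambert bilinearity means a window of the absorbance surface
factors as D ≈ C·Sᵀ: non-negative concentration profiles (time × k) times
non-negative spectra (wavelength × k). Starting from initial spectral
estimates, alternating constrained least squares — solve C given S, then
S given C — converges to a factorisation whose lack of fit is monotone
non-increasing. The factorisation is defined only up to scale and
permutation; both are fixed here by unit-max spectra and by matching
component order to the initial estimates by correlation.

Also provides the two curve-similarity measures used throughout: squared
Pearson correlation r² and the discrete Fréchet distance. Fréchet
distances are computed on doubly normalised curves — wavelength mapped to
[0, 1] over the common support and absorbance scaled to unit maximum —
so reported values are dimensionless and comparable across spectra;
absolute Fréchet values depend on this convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls

from .io import ValidationError

__all__ = [
    "MCRResult",
    "mcr_ar",
    "unimodality_constraint",
    "discrete_frechet",
    "compare_spectra",
    "r_squared",
]


@dataclass
class MCRResult:
    """Factorisation D ≈ C·Sᵀ with convergence history.

    C has concentration-profile columns (AU per unit spectrum), S has
    unit-max spectra columns; ``residual_history`` is the lack of fit
    (percent) after each iteration.
    """

    C: np.ndarray
    S: np.ndarray
    residual_history: np.ndarray
    converged: bool
    iterations: int

    @property
    def lack_of_fit(self) -> float:
        return float(self.residual_history[-1])

    def reconstruction(self) -> np.ndarray:
        return self.C @ self.S.T


def _nnls_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min ||A·X − B|| with X ≥ 0, column by column of B."""
    k = A.shape[1]
    X = np.empty((k, B.shape[1]))
    for j in range(B.shape[1]):
        X[:, j], _ = nnls(A, B[:, j])
    return X


def _lack_of_fit(D: np.ndarray, C: np.ndarray, S: np.ndarray) -> float:
    resid = D - C @ S.T
    return 100.0 * float(np.sqrt(np.sum(resid**2) / np.sum(D**2)))


def mcr_ar(
    D: np.ndarray,
    S0: np.ndarray,
    unimodal_c: bool = False,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MCRResult:
    """Alternate non-negative least squares for C and S until the
    relative change in lack of fit drops below ``tol``.

    ``S0``: initial spectra, one column per component, on D's wavelength
    grid. Optional unimodality projection of C columns (off by default —
    Gaussian elution makes it redundant when the initial estimates are
    good, but it is available for pathological windows).
    """
    D = np.asarray(D, dtype=float)
    S = np.asarray(S0, dtype=float).copy()
    if S.ndim != 2 or S.shape[0] != D.shape[1]:
        raise ValidationError(
            f"S0 shape {S.shape} incompatible with D shape {D.shape} "
            "(rows of S0 must match D's wavelength count)"
        )
    k = S.shape[1]
    if k > min(D.shape):
        raise ValidationError(f"k={k} exceeds the rank bound min{D.shape}")
    if np.sum(D**2) == 0:
        raise ValidationError("zero data matrix")
    S = np.clip(S, 0.0, None)
    S /= np.maximum(S.max(axis=0, keepdims=True), np.finfo(float).tiny)

    history = []
    C = np.zeros((D.shape[0], k))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # C given S: rows of D regressed on S
        C = _nnls_columns(S, D.T).T
        if unimodal_c:
            for j in range(k):
                C[:, j] = unimodality_constraint(C[:, j])
        # S given C: columns of D regressed on C
        S = _nnls_columns(C, D)
        S = S.T  # (n_wl, k)
        # fix scale: unit-max spectra, push scale into C
        smax = S.max(axis=0)
        smax_safe = np.maximum(smax, np.finfo(float).tiny)
        S /= smax_safe
        C *= smax_safe[None, :]
        lof = _lack_of_fit(D, C, S)
        history.append(lof)
        if lof < 1e-9:  # percent; exact factorisation reached
            converged = True
            break
        if len(history) > 1:
            prev = history[-2]
            if prev == 0 or abs(prev - lof) / max(prev, np.finfo(float).tiny) < tol:
                converged = True
                break

    # match component order to S0 by maximal correlation
    S0n = np.clip(np.asarray(S0, dtype=float), 0.0, None)
    corr = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            corr[i, j] = _pearson(S0n[:, i], S[:, j])
    row, col = linear_sum_assignment(-corr)
    perm = col[np.argsort(row)]
    return MCRResult(
        C=C[:, perm],
        S=S[:, perm],
        residual_history=np.array(history),
        converged=converged,
        iterations=it,
    )


def unimodality_constraint(column: np.ndarray) -> np.ndarray:
    """Project a profile onto the unimodal cone about its global maximum.

    Walking away from the apex in each direction, values are clipped to
    the running minimum (monotone envelope). Idempotent; leaves already
    unimodal profiles unchanged.
    """
    v = np.asarray(column, dtype=float).copy()
    if v.size == 0:
        return v
    m = int(np.argmax(v))
    for i in range(m - 1, -1, -1):
        v[i] = min(v[i], v[i + 1])
    for i in range(m + 1, v.size):
        v[i] = min(v[i], v[i - 1])
    return v


# ---------------------------------------------------------------------------
# curve similarity


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


def r_squared(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two aligned absorbance vectors."""
    return _pearson(np.asarray(a, float), np.asarray(b, float)) ** 2


def discrete_frechet(P: np.ndarray, Q: np.ndarray) -> float:
    """Discrete Fréchet distance between two point sequences.

    Dynamic programme over the coupling lattice: the minimum over
    monotone couplings of the maximum pointwise Euclidean distance.
    Symmetric, zero iff the sequences are identical, and satisfies the
    triangle inequality.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if P.shape[0] == 1 and P.shape[1] > 2:
        P = P.T
    if Q.shape[0] == 1 and Q.shape[1] > 2:
        Q = Q.T
    n, m = P.shape[0], Q.shape[0]
    if n == 0 or m == 0:
        raise ValidationError("empty curve")
    d = np.sqrt(((P[:, None, :] - Q[None, :, :]) ** 2).sum(axis=2))
    ca = np.empty((n, m))
    ca[0, 0] = d[0, 0]
    for i in range(1, n):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
    for j in range(1, m):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, n):
        row_prev = ca[i - 1]
        row = ca[i]
        for j in range(1, m):
            row[j] = max(min(row_prev[j], row_prev[j - 1], row[j - 1]), d[i, j])
    return float(ca[-1, -1])


def compare_spectra(
    wavelength_a: np.ndarray,
    absorbance_a: np.ndarray,
    wavelength_b: np.ndarray,
    absorbance_b: np.ndarray,
    min_overlap: int = 50,
) -> dict:
    """Similarity of two spectra: r² and normalised Fréchet distance.

    The curves are aligned on the overlap of their supports (a's grid
    points inside the overlap; b linearly interpolated onto them). r² is
    the squared Pearson correlation of the aligned absorbances. The
    Fréchet distance is computed after mapping wavelength to [0, 1] over
    the common support and scaling each curve to unit maximum, so it is
    a dimensionless shape distance.
    """
    wa = np.asarray(wavelength_a, float)
    wb = np.asarray(wavelength_b, float)
    aa = np.asarray(absorbance_a, float)
    ab = np.asarray(absorbance_b, float)
    # pairwise-complete: drop NaN positions
    ma = np.isfinite(aa)
    mb = np.isfinite(ab)
    wa, aa = wa[ma], aa[ma]
    wb, ab = wb[mb], ab[mb]
    lo = max(wa.min(), wb.min())
    hi = min(wa.max(), wb.max())
    grid = wa[(wa >= lo) & (wa <= hi)]
    if grid.size < min_overlap:
        raise ValidationError(
            f"insufficient spectral overlap: {grid.size} samples (need >= {min_overlap})"
        )
    ya = np.interp(grid, wa, aa)
    yb = np.interp(grid, wb, ab)
    r2 = r_squared(ya, yb)
    x = (grid - lo) / (hi - lo) if hi > lo else np.zeros_like(grid)
    na = ya / ya.max() if ya.max() > 0 else ya
    nb = yb / yb.max() if yb.max() > 0 else yb
    fd = discrete_frechet(np.column_stack([x, na]), np.column_stack([x, nb]))
    return {"r2": r2, "frechet": fd, "n_overlap": int(grid.size)}
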