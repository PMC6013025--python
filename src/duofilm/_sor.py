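"""Red-black successive over-relaxation kernel (numba-compiled).

Solves (k + D*L) C = P + boundary for one solute on the active block:
lateral edges periodic, substratum mirrored (no flux), the row above the
block held at the bulk value.  Used as the inner linear solver of the
outer Picard iteration; falls back to a sparse direct solve when numba
is unavailable.
"""

from __future__ import annotations

import numba

__all__ = ["sor_solve"]


@numba.njit(cache=False, fastmath=True)
def sor_solve(C, k, P, coef, bulk, omega, tol_abs, max_iters):  # pragma: no cover
    """Relax C in place; returns the last full-sweep max update."""
    ny, nx = C.shape
    delta = 0.0
    for _ in range(max_iters):
        delta = 0.0
        for parity in range(2):
            for i in range(ny):
                row_par = i & 1
                for j in range(nx):
                    if ((row_par + j) & 1) != parity:
                        continue
                    s = C[i, j - 1 if j > 0 else nx - 1] \
                        + C[i, j + 1 if j < nx - 1 else 0]
                    s += C[i - 1, j] if i > 0 else C[i, j]  # mirror below
                    s += C[i + 1, j] if i < ny - 1 else bulk
                    new = (coef * s + P[i, j]) / (k[i, j] + 4.0 * coef)
                    upd = omega * (new - C[i, j])
                    C[i, j] += upd
                    if abs(upd) > delta:
                        delta = abs(upd)
        if delta < tol_abs:
            break
    return delta
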