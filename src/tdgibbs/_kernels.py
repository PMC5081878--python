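"""Numba kernels for the single-site blocked Gibbs sweeps.

Each kernel updates one family of effects by Gauss-Seidel over its columns,
drawing the 4-trait subvector of every level from its multivariate-normal
full conditional and keeping the running residual matrix ``e`` consistent.
Pre-generated standard-normal deviates are passed in (one 4-vector per
column) so that all randomness flows through a single NumPy generator.

Kernels return ``False`` when a 4x4 conditional precision fails its
Cholesky factorisation; the caller turns that into a hard error.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _chol(M, L):
    """Lower Cholesky of a small SPD matrix into L; False if not PD."""
    n = M.shape[0]
    for i in range(n):
        for j in range(i + 1):
            s = M[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    return False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return True


@njit(cache=True)
def _chol_solve(L, b, out):
    """Solve (L L^T) out = b by forward then back substitution."""
    n = L.shape[0]
    for i in range(n):
        s = b[i]
        for k in range(i):
            s -= L[i, k] * out[k]
        out[i] = s / L[i, i]
    for i in range(n - 1, -1, -1):
        s = out[i]
        for k in range(i + 1, n):
            s -= L[k, i] * out[k]
        out[i] = s / L[i, i]


@njit(cache=True)
def _backsolve_t(L, b, out):
    """Solve L^T out = b (back substitution); for N(0, M^{-1}) draws."""
    n = L.shape[0]
    for i in range(n - 1, -1, -1):
        s = b[i]
        for k in range(i + 1, n):
            s -= L[k, i] * out[k]
        out[i] = s / L[i, i]


@njit(cache=True)
def sweep_fixed(e, u, indptr, rows, vals, ss, L_r, z):
    """One Gauss-Seidel pass over the fixed-effect columns (flat prior).

    Column c has full conditional N(r_c / s_c, R0 / s_c) with
    r_c = s_c u_c + sum_i x_ic e_i and s_c = sum_i x_ic^2; ``L_r`` is the
    lower Cholesky factor of R0.
    """
    ncols, nt = u.shape
    r = np.empty(nt)
    delta = np.empty(nt)
    for c in range(ncols):
        s = ss[c]
        if s <= 0.0:
            continue
        for t in range(nt):
            r[t] = 0.0
        for k in range(indptr[c], indptr[c + 1]):
            i = rows[k]
            x = vals[k]
            for t in range(nt):
                r[t] += x * e[i, t]
        inv_sqrt = 1.0 / np.sqrt(s)
        for t in range(nt):
            noise = 0.0
            for k2 in range(t + 1):
                noise += L_r[t, k2] * z[c, k2]
            new = r[t] / s + u[c, t] + noise * inv_sqrt
            delta[t] = new - u[c, t]
            u[c, t] = new
        for k in range(indptr[c], indptr[c + 1]):
            i = rows[k]
            x = vals[k]
            for t in range(nt):
                e[i, t] -= x * delta[t]
    return True


@njit(cache=True)
def sweep_iid(e, u, indptr, rows, R_inv, P_inv, z):
    """One pass over i.i.d. random-effect levels (permanent environment).

    Level c (indicator covariates) has precision n_c R0^{-1} + P0^{-1} and
    mean  M^{-1} R0^{-1} r_c; a level with no records draws from its prior
    N(0, P0).
    """
    ncols, nt = u.shape
    r = np.empty(nt)
    rhs = np.empty(nt)
    mean = np.empty(nt)
    v = np.empty(nt)
    M = np.empty((nt, nt))
    L = np.zeros((nt, nt))
    for c in range(ncols):
        nrec = indptr[c + 1] - indptr[c]
        for t in range(nt):
            r[t] = nrec * u[c, t]
        for k in range(indptr[c], indptr[c + 1]):
            i = rows[k]
            for t in range(nt):
                r[t] += e[i, t]
        for t in range(nt):
            rhs[t] = 0.0
            for t2 in range(nt):
                M[t, t2] = nrec * R_inv[t, t2] + P_inv[t, t2]
                rhs[t] += R_inv[t, t2] * r[t2]
        if not _chol(M, L):
            return False
        _chol_solve(L, rhs, mean)
        _backsolve_t(L, z[c], v)
        for t in range(nt):
            new = mean[t] + v[t]
            v[t] = new - u[c, t]
            u[c, t] = new
        for k in range(indptr[c], indptr[c + 1]):
            i = rows[k]
            for t in range(nt):
                e[i, t] -= v[t]
    return True


@njit(cache=True)
def sweep_cow_joint(
    e, u_an, u_pe, pe_indptr, pe_rows, cow_to_animal,
    ai_indptr, ai_idx, ai_val, R_inv, G_inv, P_inv, z,
):
    """Joint draw of (additive, permanent-environment) per recorded cow.

    The likelihood only sees a + pe for a cow's records, so updating the
    two 4-vectors one at a time mixes extremely slowly; drawing the 8-vector
    from its joint full conditional removes that bottleneck.  Precision

        [[ n R0^-1 + A^-1[a,a] G0^-1 ,  n R0^-1          ],
         [ n R0^-1                   ,  n R0^-1 + P0^-1  ]]

    with linear term (R0^-1 r - G0^-1 off, R0^-1 r), where r sums the
    records' working residuals plus the current a + pe, and ``off`` is the
    pedigree coupling sum_{b != a} A^-1[a,b] u_b.
    """
    ncows = pe_indptr.shape[0] - 1
    nt = u_an.shape[1]
    m = 2 * nt
    r = np.empty(nt)
    off = np.empty(nt)
    rhs = np.empty(m)
    mean = np.empty(m)
    v = np.empty(m)
    M = np.empty((m, m))
    L = np.zeros((m, m))
    for c in range(ncows):
        a = cow_to_animal[c]
        nrec = pe_indptr[c + 1] - pe_indptr[c]
        for t in range(nt):
            r[t] = nrec * (u_an[a, t] + u_pe[c, t])
            off[t] = 0.0
        for k in range(pe_indptr[c], pe_indptr[c + 1]):
            i = pe_rows[k]
            for t in range(nt):
                r[t] += e[i, t]
        d_aa = 0.0
        for k in range(ai_indptr[a], ai_indptr[a + 1]):
            b = ai_idx[k]
            w = ai_val[k]
            if b == a:
                d_aa += w
            else:
                for t in range(nt):
                    off[t] += w * u_an[b, t]
        for t in range(nt):
            rr = 0.0
            go = 0.0
            for t2 in range(nt):
                rr += R_inv[t, t2] * r[t2]
                go += G_inv[t, t2] * off[t2]
                nR = nrec * R_inv[t, t2]
                M[t, t2] = nR + d_aa * G_inv[t, t2]
                M[t, nt + t2] = nR
                M[nt + t, t2] = nR
                M[nt + t, nt + t2] = nR + P_inv[t, t2]
            rhs[t] = rr - go
            rhs[nt + t] = rr
        if not _chol(M, L):
            return False
        _chol_solve(L, rhs, mean)
        _backsolve_t(L, z[c], v)
        for t in range(nt):
            new_a = mean[t] + v[t]
            new_p = mean[nt + t] + v[nt + t]
            v[t] = new_a - u_an[a, t]
            v[nt + t] = new_p - u_pe[c, t]
            u_an[a, t] = new_a
            u_pe[c, t] = new_p
        for k in range(pe_indptr[c], pe_indptr[c + 1]):
            i = pe_rows[k]
            for t in range(nt):
                e[i, t] -= v[t] + v[nt + t]
    return True


@njit(cache=True)
def sweep_animal(e, u, indptr, rows, ai_indptr, ai_idx, ai_val, R_inv, G_inv, z, skip):
    """One pass over additive-genetic levels with the A^{-1} x G0^{-1} prior.

    Animal a has precision n_a R0^{-1} + A^{-1}[a,a] G0^{-1} and linear term
    R0^{-1} r_a - G0^{-1} sum_{b != a} A^{-1}[a,b] u_b; animals without
    records are tied in purely through the pedigree.  Animals flagged in
    ``skip`` (recorded cows handled by :func:`sweep_cow_joint`) are left
    untouched.
    """
    nanim, nt = u.shape
    r = np.empty(nt)
    off = np.empty(nt)
    rhs = np.empty(nt)
    mean = np.empty(nt)
    v = np.empty(nt)
    M = np.empty((nt, nt))
    L = np.zeros((nt, nt))
    for a in range(nanim):
        if skip[a]:
            continue
        nrec = indptr[a + 1] - indptr[a]
        for t in range(nt):
            r[t] = nrec * u[a, t]
            off[t] = 0.0
        for k in range(indptr[a], indptr[a + 1]):
            i = rows[k]
            for t in range(nt):
                r[t] += e[i, t]
        d_aa = 0.0
        for k in range(ai_indptr[a], ai_indptr[a + 1]):
            b = ai_idx[k]
            w = ai_val[k]
            if b == a:
                d_aa += w
            else:
                for t in range(nt):
                    off[t] += w * u[b, t]
        for t in range(nt):
            rhs[t] = 0.0
            for t2 in range(nt):
                M[t, t2] = nrec * R_inv[t, t2] + d_aa * G_inv[t, t2]
                rhs[t] += R_inv[t, t2] * r[t2] - G_inv[t, t2] * off[t2]
        if not _chol(M, L):
            return False
        _chol_solve(L, rhs, mean)
        _backsolve_t(L, z[a], v)
        for t in range(nt):
            new = mean[t] + v[t]
            v[t] = new - u[a, t]
            u[a, t] = new
        for k in range(indptr[a], indptr[a + 1]):
            i = rows[k]
            for t in range(nt):
                e[i, t] -= v[t]
    return True
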