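"""Analytic EEG forward solution for a dipole in a layered conducting sphere.

The potential generated by a current dipole inside concentric conducting
shells has a classical Legendre-series solution. Writing the dipole at
position ``r0`` (eccentricity ``b = |r0|``) and an electrode at unit
direction ``u`` on the outer surface (radius ``R``), the surface potential is

    V = 1/(4 pi sigma_1 R^2) * sum_n  f_n (2n+1)/n * (b/R)^(n-1)
        * [ n P_n(c) (m . rhat0) + P_n'(c) (m . (u - c rhat0)) ]

with ``c = rhat0 . u``, ``sigma_1`` the innermost (brain) conductivity, and
``f_n`` a per-order correction factor determined by the shell radii and
conductivities (``f_n = 1`` for a homogeneous sphere). The ``f_n`` are found
by solving, for each harmonic order, the small linear system expressing
potential and radial-current continuity at every interface and zero normal
current at the scalp.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidArgumentError
from .headmodel import ElectrodeMontage, Leadfield, ShellModel, SourceSpace

#: Hard cap on the Legendre truncation order.
N_MAX = 200
#: Target relative contribution of trailing series terms.
SERIES_RTOL = 1e-10


def shell_mode_factors(model: ShellModel, n_max: int = N_MAX) -> np.ndarray:
    """Per-order correction factors ``f_n`` (n = 1..n_max) for a shell model.

    For each order the boundary-value problem is a linear system in the
    per-shell harmonic coefficients. Unknowns are scaled to their values at
    each shell's outer radius, which keeps all matrix entries within a
    modest dynamic range for realistic radius ratios.
    """
    rho = model.radii / model.r_outer  # normalized radii, rho[-1] == 1
    sig = model.conductivities
    L = model.n_shells
    K = 2 * L - 1
    n = np.arange(1, n_max + 1, dtype=float)[:, None, None]  # (n_max, 1, 1)

    A = np.zeros((n_max, K, K))
    rhs = np.zeros((n_max, K))
    nv = n[:, 0, 0]  # (n_max,)

    def col_A(j):  # column index of the r^n coefficient of shell j (0-based)
        return 0 if j == 0 else 2 * j - 1

    def col_B(j):  # column of the r^-(n+1) coefficient; shell 0 has none
        return 2 * j

    src1 = rho[0] ** (-(nv + 1.0))  # source radial term at the first interface
    row = 0
    for i in range(L - 1):
        alpha = (rho[i] / rho[i + 1]) ** nv
        beta = (rho[i + 1] / rho[i]) ** (nv + 1.0)
        # potential continuity at interface i
        A[:, row, col_A(i)] = 1.0
        if i > 0:
            A[:, row, col_B(i)] = 1.0
        A[:, row, col_A(i + 1)] = -alpha
        A[:, row, col_B(i + 1)] = -beta
        if i == 0:
            rhs[:, row] = -src1
        row += 1
        # radial current continuity (times rho_i)
        A[:, row, col_A(i)] = sig[i] * nv
        if i > 0:
            A[:, row, col_B(i)] = -sig[i] * (nv + 1.0)
        A[:, row, col_A(i + 1)] = -sig[i + 1] * nv * alpha
        A[:, row, col_B(i + 1)] = sig[i + 1] * (nv + 1.0) * beta
        if i == 0:
            rhs[:, row] = sig[0] * (nv + 1.0) * src1
        row += 1
    # zero normal current at the outer surface
    A[:, row, col_A(L - 1)] = nv
    if L > 1:
        A[:, row, col_B(L - 1)] = -(nv + 1.0)
    else:
        rhs[:, row] = nv + 1.0

    x = np.linalg.solve(A, rhs[..., None])[..., 0]
    if L > 1:
        g_surface = x[:, col_A(L - 1)] + x[:, col_B(L - 1)]
    else:
        g_surface = x[:, col_A(0)] + 1.0  # homogeneous: source reaches the surface
    f = g_surface * nv / (2.0 * nv + 1.0)
    if not np.all(np.isfinite(f)):
        raise InvalidArgumentError(
            "mode factors overflowed; shell radius ratios are too extreme"
        )
    return f


def _truncation_order(t_max: float, n_cap: int = N_MAX, rtol: float = SERIES_RTOL) -> int:
    """Order at which the geometric tail of the series is negligible."""
    if t_max <= 0:
        return 1
    t_max = min(t_max, 0.999)
    # terms decay like t^n with slowly varying polynomial factors; demand
    # t^n * n^2 < rtol * (1 - t) and add margin
    n = 1
    while n < n_cap and t_max**n * (n + 1) ** 2 >= rtol * (1.0 - t_max):
        n += 1
    return min(max(n + 5, 10), n_cap)


def _series_kernels(c: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate K1 = sum w_n * n * P_n(c) and K2 = sum w_n * P_n'(c).

    ``c`` has shape (...,); ``weights`` has shape (n_orders,) or broadcasts
    against ``c`` with a leading axis of its own (weights[n] applied per n).
    Uses the stable recurrences P_{n+1} = ((2n+1) c P_n - n P_{n-1})/(n+1)
    and P'_{n+1} = P'_{n-1} + (2n+1) P_n.
    """
    n_orders = weights.shape[0]
    p_prev = np.ones_like(c)  # P_0
    p_cur = c.copy()  # P_1
    dp_prev = np.zeros_like(c)  # P'_0
    dp_cur = np.ones_like(c)  # P'_1
    k1 = weights[0] * 1.0 * p_cur
    k2 = weights[0] * dp_cur
    for idx in range(1, n_orders):
        n = idx  # current known order
        p_next = ((2 * n + 1) * c * p_cur - n * p_prev) / (n + 1)
        dp_next = dp_prev + (2 * n + 1) * p_cur
        p_prev, p_cur = p_cur, p_next
        dp_prev, dp_cur = dp_cur, dp_next
        k1 = k1 + weights[idx] * (n + 1) * p_cur
        k2 = k2 + weights[idx] * dp_cur
    return k1, k2


def sphere_potential(
    dipole_position,
    dipole_moment,
    model: ShellModel,
    electrode_position,
    n_max: int | None = None,
) -> float:
    """Raw (reference-free) scalp potential of one dipole at one electrode.

    The dipole must lie strictly inside the innermost shell; the electrode
    must sit on the outer surface (within 1e-6 m).
    """
    r0 = np.asarray(dipole_position, dtype=float)
    m = np.asarray(dipole_moment, dtype=float)
    e = np.asarray(electrode_position, dtype=float)
    if not (np.all(np.isfinite(r0)) and np.all(np.isfinite(m)) and np.all(np.isfinite(e))):
        raise InvalidArgumentError("inputs must be finite 3-vectors")
    b = float(np.linalg.norm(r0))
    if b >= model.r_brain:
        raise InvalidArgumentError("dipole must lie strictly inside the innermost shell")
    R = model.r_outer
    if abs(np.linalg.norm(e) - R) > 1e-6:
        raise InvalidArgumentError("electrode must lie on the outer shell surface")
    if not np.any(m):
        return 0.0
    if b == 0.0:
        # only the n=1 term survives for a central dipole
        f = shell_mode_factors(model, 1)
        u = e / R
        return float(f[0] * 3.0 / (4.0 * np.pi * model.conductivities[0] * R**2) * (m @ u))

    t = b / R
    order = n_max if n_max is not None else _truncation_order(t)
    f = shell_mode_factors(model, order)
    nv = np.arange(1, order + 1, dtype=float)
    w = f * (2.0 * nv + 1.0) / nv * t ** (nv - 1.0)
    rhat = r0 / b
    u = e / R
    c = np.array(float(rhat @ u))
    k1, k2 = _series_kernels(c, w)
    kappa = 1.0 / (4.0 * np.pi * model.conductivities[0] * R**2)
    return float(kappa * ((k1 - c * k2) * (m @ rhat) + k2 * (m @ u)))


def compute_leadfield(
    model: ShellModel,
    montage: ElectrodeMontage,
    sources: SourceSpace,
    n_max: int | None = None,
) -> Leadfield:
    """Average-referenced gain matrix for all sources x 3 canonical moments.

    Vectorized over electrodes and sources; the Legendre recurrence runs
    once over the full (sources x sensors) angle matrix.
    """
    R = model.r_outer
    pos_e = montage.positions
    if np.max(np.abs(np.linalg.norm(pos_e, axis=1) - R)) > 1e-6:
        raise InvalidArgumentError(
            "montage must be projected onto the model's outer shell"
        )
    pos_s = sources.positions
    b = np.linalg.norm(pos_s, axis=1)
    if np.any(b >= model.r_brain):
        raise InvalidArgumentError("all dipoles must lie inside the innermost shell")

    t = b / R  # (N,)
    order = n_max if n_max is not None else _truncation_order(float(t.max()))
    f = shell_mode_factors(model, order)
    nv = np.arange(1, order + 1, dtype=float)
    base = f * (2.0 * nv + 1.0) / nv  # (order,)
    # per-source weights w[n, i] = base[n] * t_i^(n-1)
    w = base[:, None] * t[None, :] ** (nv[:, None] - 1.0)  # (order, N)

    rhat = pos_s / b[:, None]  # (N, 3)
    u = pos_e / R  # (M, 3)
    c = rhat @ u.T  # (N, M)

    # Legendre accumulation with per-source weights
    p_prev = np.ones_like(c)
    p_cur = c.copy()
    dp_prev = np.zeros_like(c)
    dp_cur = np.ones_like(c)
    k1 = w[0][:, None] * p_cur
    k2 = w[0][:, None] * dp_cur
    for idx in range(1, order):
        n = idx
        p_next = ((2 * n + 1) * c * p_cur - n * p_prev) / (n + 1)
        dp_next = dp_prev + (2 * n + 1) * p_cur
        p_prev, p_cur = p_cur, p_next
        dp_prev, dp_cur = dp_cur, dp_next
        k1 += w[idx][:, None] * (n + 1) * p_cur
        k2 += w[idx][:, None] * dp_cur

    kappa = 1.0 / (4.0 * np.pi * model.conductivities[0] * R**2)
    a = kappa * (k1 - c * k2)  # (N, M): coefficient of (m . rhat)
    bb = kappa * k2  # (N, M): coefficient of (m . u)

    N, M = c.shape
    gain = np.empty((M, 3 * N))
    for d in range(3):
        # V[m, i] for unit moment along axis d
        gain[:, d::3] = (a * rhat[:, d][:, None] + bb * u[:, d][None, :]).T
    gain -= gain.mean(axis=0, keepdims=True)  # average reference
    return Leadfield(
        gain=gain,
        reference="average",
        source_space_id=sources.source_space_id,
        montage_id=montage.montage_id,
        shell_model_id=model.name,
    )
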