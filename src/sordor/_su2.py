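"""Vectorised SU(2) algebra in Cayley-Klein form.

A 2x2 special-unitary matrix is stored as the complex pair ``(a, b)`` with

    U = [[a, b], [-conj(b), conj(a)]],    |a|^2 + |b|^2 = 1.

Equivalently, with the unit quaternion ``q = (q0, q1, q2, q3)`` of the
rotation ``U = q0*1 - i*(q1*sx + q2*sy + q3*sz)`` (Pauli matrices ``s*``),

    a = q0 - i*q3,    b = -q2 - i*q1.

All functions broadcast over arbitrary leading array shapes, which is what
makes offset/B1 ensemble propagation cheap: a pulse of n slices over G grid
points is n sequential products of G-element component arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "su2_identity",
    "su2_from_field",
    "su2_mul",
    "su2_dagger",
    "su2_to_matrix",
    "matrix_to_su2",
    "su2_re_overlap",
    "su2_rotate_vector",
    "quaternion_from_su2",
]


def su2_identity(shape=()):
    """Identity element as an ``(a, b)`` pair of the given array shape."""
    return np.ones(shape, dtype=complex), np.zeros(shape, dtype=complex)


def su2_from_field(wx, wy, wz, dt):
    """Propagator ``exp(-i dt (wx*Ix + wy*Iy + wz*Iz))`` with I = sigma/2.

    Field components in rad/s, ``dt`` in seconds.  Uses the closed-form
    axis-angle exponential; the ``sin(theta/2)/|w|`` factor is evaluated via
    ``sinc`` so the zero-field limit is exact.
    """
    wx, wy, wz = np.broadcast_arrays(wx, wy, wz)
    w = np.sqrt(wx * wx + wy * wy + wz * wz)
    half = 0.5 * dt * w
    s_over_w = 0.5 * dt * np.sinc(half / np.pi)  # = sin(half)/|w|, finite at 0
    a = np.cos(half) - 1j * wz * s_over_w
    b = -(wy + 1j * wx) * s_over_w
    return a, b


def su2_mul(a2, b2, a1, b1):
    """Matrix product ``U2 @ U1`` in component form."""
    return a2 * a1 - b2 * np.conj(b1), a2 * b1 + b2 * np.conj(a1)


def su2_dagger(a, b):
    """Hermitian adjoint (= inverse)."""
    return np.conj(a), -b


def su2_to_matrix(a, b):
    """Expand ``(a, b)`` into explicit 2x2 matrices (stacked in the last axes)."""
    a = np.asarray(a, dtype=complex)
    b = np.asarray(b, dtype=complex)
    out = np.empty(a.shape + (2, 2), dtype=complex)
    out[..., 0, 0] = a
    out[..., 0, 1] = b
    out[..., 1, 0] = -np.conj(b)
    out[..., 1, 1] = np.conj(a)
    return out


def matrix_to_su2(u, atol=1e-9):
    """Project a (2, 2) unitary onto ``(a, b)`` form.

    Accepts a U(2) matrix with ``|det U| = 1``; a global determinant phase is
    divided out (principal square root).  Raises ``ValueError`` if the input
    is not unitary to within ``atol``.
    """
    u = np.asarray(u, dtype=complex)
    if u.shape[-2:] != (2, 2):
        raise ValueError(f"expected trailing shape (2, 2), got {u.shape}")
    herm = u @ np.swapaxes(u.conj(), -1, -2)
    eye = np.eye(2)
    if not np.allclose(herm, eye, atol=atol):
        raise ValueError("matrix is not unitary")
    det = u[..., 0, 0] * u[..., 1, 1] - u[..., 0, 1] * u[..., 1, 0]
    phase = np.sqrt(det)
    u = u / phase[..., None, None]
    return u[..., 0, 0], u[..., 0, 1]


def su2_re_overlap(a_t, b_t, a_u, b_u):
    """``Re tr(UT^dag U) / 2`` — the normalised real propagator overlap.

    In quaternion language this is the 4-vector dot product of the two
    rotations, i.e. ``cos(delta/2)`` with ``delta`` the angle of the error
    rotation ``UT^dag U``.
    """
    return np.real(np.conj(a_t) * a_u + np.conj(b_t) * b_u)


def quaternion_from_su2(a, b):
    """Return ``(q0, q1, q2, q3)`` with ``U = q0 - i (q.sigma)``."""
    a = np.asarray(a)
    b = np.asarray(b)
    return np.real(a), -np.imag(b), -np.real(b), -np.imag(a)


def su2_rotate_vector(a, b, v):
    """Rotate Bloch vectors by the SO(3) image of ``(a, b)``.

    Conjugation ``U (v.sigma) U^dag`` with ``U = exp(-i theta n.sigma/2)`` is
    the right-handed rotation of ``v`` by ``theta`` about ``n``; this is the
    Rodrigues form written with quaternion components.

    Parameters
    ----------
    a, b : array_like, shape ``S``
    v : array_like, shape ``S + (3,)`` or ``(3,)`` (broadcast)

    Returns
    -------
    ndarray, shape ``S + (3,)``
    """
    q0, q1, q2, q3 = quaternion_from_su2(a, b)
    q0 = np.asarray(q0, dtype=float)
    qv = np.stack(np.broadcast_arrays(q1, q2, q3), axis=-1).astype(float)
    v = np.asarray(v, dtype=float)
    v = np.broadcast_to(v, qv.shape[:-1] + (3,))
    dot = np.sum(qv * v, axis=-1, keepdims=True)
    cross = np.cross(qv, v)
    q0 = q0[..., None]
    qq = np.sum(qv * qv, axis=-1, keepdims=True)
    return (q0 * q0 - qq) * v + 2.0 * dot * qv + 2.0 * q0 * cross
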