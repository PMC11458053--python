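"""Independent reference implementations used only to check the package.

Each oracle deliberately takes a different computational route from the
implementation it validates: eigendecomposition instead of SVD, explicit
Gram–Schmidt and Rodrigues formulas, double-loop ANOVA sums, exhaustive
enumeration, homogeneous 4×4 matrix algebra.
"""

import numpy as np


def plane_by_eigendecomposition(points):
    """Total-least-squares plane via the covariance eigenvector of
    smallest eigenvalue (normal-equation route)."""
    pts = np.asarray(points, dtype=float)
    c = pts.mean(axis=0)
    d = pts - c
    cov = d.T @ d
    w, v = np.linalg.eigh(cov)
    n = v[:, 0]  # smallest eigenvalue
    if n[2] < 0 or (n[2] == 0 and (n[1] < 0 or (n[1] == 0 and n[0] < 0))):
        n = -n
    return n, c


def project(p, n, c):
    return p - np.dot(p - c, n) * n


def rodrigues(axis, angle_degrees):
    """Explicit Rodrigues formula R = I + sinθ·K + (1−cosθ)·K²."""
    th = np.deg2rad(angle_degrees)
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]], dtype=float)
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def frame_step_by_step(landmarks, tilt_degrees=20.0):
    """Frame construction by explicit projection + Gram–Schmidt.

    ``landmarks`` is the 4×3 array in LA, LP, RA, RP order. Returns
    (origin, rotation-with-axis-columns).
    """
    pts = np.asarray(landmarks, dtype=float)
    n, c = plane_by_eigendecomposition(pts)
    proj = np.array([project(p, n, c) for p in pts])
    la, lp, ra, rp = proj
    origin = proj.mean(axis=0)
    x = (la + lp) / 2.0 - (ra + rp) / 2.0
    x = x / np.linalg.norm(x)
    ap = (lp + rp) / 2.0 - (la + ra) / 2.0
    y = ap - np.dot(ap, x) * x
    y = y / np.linalg.norm(y)
    z = np.cross(x, y)
    R = rodrigues(x, tilt_degrees)
    return origin, np.column_stack([x, R @ y, R @ z])


def rotation_angle(Ra, Rb):
    """Geodesic angle (radians) between two rotation matrices.

    Uses ‖Ra−Rb‖_F = 2√2·sin(θ/2), which is exact and keeps full
    precision near θ = 0 where the arccos-of-trace form loses digits.
    """
    fro = np.linalg.norm(np.asarray(Ra) - np.asarray(Rb))
    return float(2.0 * np.arcsin(np.clip(fro / (2.0 * np.sqrt(2.0)), -1.0, 1.0)))


def icc_anova_loops(m):
    """Absolute-agreement ICCs from explicit double-loop ANOVA sums.

    Returns (icc_single, icc_average, msr, msc, mse).
    """
    m = np.asarray(m, dtype=float)
    n, k = m.shape
    grand = 0.0
    for i in range(n):
        for j in range(k):
            grand += m[i, j]
    grand /= n * k
    ss_rows = 0.0
    for i in range(n):
        ri = sum(m[i, j] for j in range(k)) / k
        ss_rows += k * (ri - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        cj = sum(m[i, j] for i in range(n)) / n
        ss_cols += n * (cj - grand) ** 2
    ss_tot = 0.0
    for i in range(n):
        for j in range(k):
            ss_tot += (m[i, j] - grand) ** 2
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    single = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    average = (msr - mse) / (msr + (msc - mse) / n)
    return single, average, msr, msc, mse


def homogeneous(R, t):
    H = np.eye(4)
    H[:3, :3] = R
    H[:3, 3] = t
    return H


def apply_homogeneous(H, p):
    q = H @ np.append(np.asarray(p, dtype=float), 1.0)
    return q[:3]
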