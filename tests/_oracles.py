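"""Independent reference implementations used only to check nirsox.

Each oracle is a separate route to the same quantity: the diffusion-dipole
closed form for diffuse reflectance, brute-force normal equations for the
least-squares steps, and the pooled-variance textbook t formula.
"""

import numpy as np
from scipy import stats


def diffusion_reflectance(rho_mm, mu_a, mu_sp):
    """Steady-state diffuse reflectance (per mm^2 per launched photon) of a
    pencil beam on a matched-boundary semi-infinite medium: isotropic
    point-source dipole (source at one transport mean free path, image
    reflected about the extrapolated boundary at 2*A*D with A = 1)."""
    rho = np.asarray(rho_mm, dtype=float)
    mu_tp = mu_a + mu_sp
    z0 = 1.0 / mu_tp
    D = 1.0 / (3.0 * mu_tp)
    zb = 2.0 * D  # matched boundary: A = 1
    mu_eff = np.sqrt(3.0 * mu_a * mu_tp)
    r1 = np.sqrt(rho ** 2 + z0 ** 2)
    r2 = np.sqrt(rho ** 2 + (z0 + 2.0 * zb) ** 2)
    term1 = z0 * (mu_eff + 1.0 / r1) * np.exp(-mu_eff * r1) / r1 ** 2
    term2 = (z0 + 2.0 * zb) * (mu_eff + 1.0 / r2) * np.exp(-mu_eff * r2) / r2 ** 2
    return (term1 + term2) / (4.0 * np.pi)


def normal_equations(design, rhs):
    """Least squares via explicitly formed normal equations A^T A x = A^T b."""
    A = np.asarray(design, float)
    b = np.asarray(rhs, float)
    return np.linalg.solve(A.T @ A, A.T @ b)


def pooled_t_test(a, b):
    """Equal-variance two-sample t statistic and two-sided p from the
    textbook pooled-variance formula."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), na + nb - 2)
    return t, p


def ols_slope(t, y):
    """Least-squares slope via the closed covariance formula."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    tc = t - t.mean()
    return float((tc * (y - y.mean())).sum() / (tc * tc).sum())
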