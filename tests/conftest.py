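"""Shared fixtures and independent Monte-Carlo oracles.

The oracles re-derive the photoselection second moments by brute-force
averaging over explicitly sampled dipole orientations; they share no code
with the closed forms they validate.
"""

import numpy as np
import pytest


def mc_excitation_weight(nu_deg, psi_deg, n=1_000_000, seed=12345):
    """Monte-Carlo <(mu . Y)^2> for dipoles on a cone about the local normal.

    Builds the dipole explicitly from the tilted normal and a random azimuth
    and projects onto the lab Y axis.  Returns (mean, standard error).
    """
    rng = np.random.default_rng(seed)
    nu = np.radians(nu_deg)
    psi = np.radians(psi_deg)
    normal = np.array([0.0, np.cos(psi), np.sin(psi)])
    # orthonormal frame perpendicular to the normal
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.cross(normal, e1)
    alpha = rng.uniform(0.0, 2.0 * np.pi, n)
    mu = (
        np.cos(nu) * normal[None, :]
        + np.sin(nu) * (np.cos(alpha)[:, None] * e1[None, :] + np.sin(alpha)[:, None] * e2[None, :])
    )
    w = mu[:, 1] ** 2
    return float(w.mean()), float(w.std(ddof=1) / np.sqrt(n))


def mc_isotropic_anisotropy(n=1_000_000, seed=321):
    """Photoselection anisotropy of dipoles uniform on the sphere.

    Samples unit vectors, weights emission by the excitation probability
    (mu.Y)^2 and evaluates r = (I_par - I_perp) / (I_par + 2 I_perp) for
    collinear absorption/emission dipoles detected along X.
    """
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    w = v[:, 1] ** 2
    i_par = (w * v[:, 1] ** 2).mean()
    i_perp = (w * v[:, 2] ** 2).mean()
    return (i_par - i_perp) / (i_par + 2 * i_perp)


@pytest.fixture(scope="session")
def small_stack():
    """One modest-budget simulated vesicle (nu = 38 deg) reused across tests."""
    import guvflim as gf

    cfg = gf.SimulationConfig(seed=7, nu_deg=38.0, sector_photon_budget=3e5)
    stack, gt = gf.simulate_guv_stack(cfg)
    return stack, gt
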