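"""Monte-Carlo random-walk simulation of restricted diffusion in a sphere.

An independent numerical oracle for the Gaussian-phase sphere signal:
walkers start uniformly inside an impermeable sphere, take Gaussian steps,
reflect specularly at the surface, and accumulate phase under the effective
gradient.  The signal is the ensemble mean of cos(phase).

This is a physics-level check — it shares nothing with the eigenmode
expansion in :mod:`stedot.sphere` beyond the geometry.  Heavy runs use numba
when available; a pure-numpy path keeps small runs usable everywhere.
"""

from __future__ import annotations

import numpy as np

from .btensor import GAMMA_PROTON, GradientWaveform

__all__ = ["random_walk_sphere_signal"]

try:  # pragma: no cover - exercised only where numba is installed
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _walk_numpy(g, dt, radius, step_sigma, gamma_um, rng, n_walkers):
    pos = _uniform_in_sphere(rng, n_walkers, radius)
    phase = np.zeros(n_walkers)
    for k in range(g.shape[0]):
        phase += gamma_um * dt * (pos @ g[k])
        pos += rng.normal(0.0, step_sigma, size=pos.shape)
        r = np.linalg.norm(pos, axis=1)
        out = r > radius
        if np.any(out):
            # specular reflection: fold the excess radius back inside
            r_out = r[out]
            pos[out] *= ((2.0 * radius - r_out) / r_out)[:, None]
    return float(np.mean(np.cos(phase)))


def _uniform_in_sphere(rng, n, radius):
    pos = np.empty((n, 3))
    filled = 0
    while filled < n:
        cand = rng.uniform(-radius, radius, size=(2 * (n - filled), 3))
        ok = cand[np.sum(cand**2, axis=1) <= radius**2]
        take = min(len(ok), n - filled)
        pos[filled : filled + take] = ok[:take]
        filled += take
    return pos


if _HAVE_NUMBA:

    @numba.njit(cache=False, fastmath=True)
    def _walk_numba(g, dt, radius, step_sigma, gamma_um, seed, n_walkers):  # pragma: no cover
        np.random.seed(seed)
        n_steps = g.shape[0]
        acc = 0.0
        for w in range(n_walkers):
            # uniform start inside the sphere by rejection
            x = y = z = radius
            while x * x + y * y + z * z > radius * radius:
                x = np.random.uniform(-radius, radius)
                y = np.random.uniform(-radius, radius)
                z = np.random.uniform(-radius, radius)
            phase = 0.0
            for k in range(n_steps):
                phase += gamma_um * dt * (g[k, 0] * x + g[k, 1] * y + g[k, 2] * z)
                x += np.random.normal(0.0, step_sigma)
                y += np.random.normal(0.0, step_sigma)
                z += np.random.normal(0.0, step_sigma)
                r2 = x * x + y * y + z * z
                if r2 > radius * radius:
                    r = np.sqrt(r2)
                    s = (2.0 * radius - r) / r
                    x *= s
                    y *= s
                    z *= s
            acc += np.cos(phase)
        return acc / n_walkers


def random_walk_sphere_signal(
    w: GradientWaveform,
    radius: float,
    d_intra: float,
    n_walkers: int = 100_000,
    max_step: float = 0.05,
    seed: int = 0,
    gamma: float = GAMMA_PROTON,
    use_numba: bool | None = None,
) -> float:
    """Sphere attenuation by reflecting random walk under the waveform.

    ``max_step`` caps the per-axis RMS step length (um); the time step is
    set accordingly and the waveform resampled onto it.  Deterministic for
    a given seed within each backend.
    """
    if radius <= 0.0:
        raise ValueError("radius must be positive")
    if d_intra <= 0.0:
        raise ValueError("d_intra must be positive")
    dt_step = max_step**2 / (2.0 * d_intra)
    wf = w.resampled(dt_step)
    g = np.ascontiguousarray(wf.effective_gradient())
    step_sigma = np.sqrt(2.0 * d_intra * wf.dt)
    gamma_um = gamma * 1e-6
    if use_numba is None:
        use_numba = _HAVE_NUMBA
    if use_numba and _HAVE_NUMBA:
        return float(
            _walk_numba(g, wf.dt, radius, step_sigma, gamma_um, seed, n_walkers)
        )
    rng = np.random.default_rng(seed)
    return _walk_numpy(g, wf.dt, radius, step_sigma, gamma_um, rng, n_walkers)
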