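"""Forward signal models for multi-compartment diffusion.

Each compartment attenuates as ``exp(-Tr(B D))`` under Gaussian diffusion;
under spherical tensor encoding (STE) this collapses to ``exp(-b * MD)`` with
MD the compartment's mean diffusivity, independent of orientation and
dispersion.  The module provides the Gaussian compartment zoo (dot, ball,
stick, zeppelin, and Watson-dispersed variants), a two-pool exchange model of
the Karger type, per-compartment T2 weighting, and (via :mod:`stedot.sphere`)
restricted diffusion in an impermeable sphere under arbitrary waveforms.

Units: b in ms/um^2, diffusivities in um^2/ms, T2 and times in ms.  All
attenuations are relative to the b = 0, TE = 0 signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import yaml
from scipy.special import erf, roots_legendre

from .btensor import BTensor

__all__ = [
    "Compartment",
    "TissueModel",
    "KargerSpec",
    "od_to_kappa",
    "kappa_to_od",
    "signal_gaussian",
    "signal_ste_mixture",
    "signal_lte_watson_stick",
    "signal_lte_watson_zeppelin",
    "signal_lte_mixture",
    "signal_karger",
    "signal_with_t2",
    "powder_stick",
    "save_tissue_model",
    "load_tissue_model",
]

_GAUSSIAN_KINDS = {"dot", "ball", "stick", "zeppelin", "watson_stick", "watson_zeppelin"}
_KINDS = _GAUSSIAN_KINDS | {"sphere"}


@dataclass(frozen=True)
class Compartment:
    """One water pool of a tissue model.

    ``kind`` selects the diffusion geometry; only the parameters relevant to
    that kind are used.  ``fraction`` is the signal fraction at TE = 0;
    ``t2`` of ``None`` means no echo-time dependence.
    """

    kind: str
    fraction: float
    d_par: float = 0.0
    d_perp: float = 0.0
    od: float = 1.0
    mean_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    radius: float = 0.0
    d_intra: float = 0.0
    t2: float | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown compartment kind {self.kind!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction must lie in [0, 1], got {self.fraction}")
        if self.kind == "dot" and (self.d_par != 0.0 or self.d_perp != 0.0):
            raise ValueError("dot compartment has all diffusivities identically 0")
        if self.d_par < 0.0 or self.d_perp < 0.0:
            raise ValueError("diffusivities must be non-negative")
        if self.d_perp > self.d_par:
            raise ValueError("require d_par >= d_perp >= 0")
        if self.kind in ("watson_stick", "watson_zeppelin") and not 0.0 < self.od <= 1.0:
            raise ValueError("orientation dispersion must lie in (0, 1]")
        if self.t2 is not None and self.t2 <= 0.0:
            raise ValueError("T2 must be positive (or None)")
        if self.kind == "sphere":
            if not 0.0 <= self.radius <= 20.0:
                raise ValueError("sphere radius must lie in [0, 20] um")
            if self.d_intra <= 0.0:
                raise ValueError("intra-sphere diffusivity must be positive")

    @property
    def mean_diffusivity(self) -> float:
        """Trace/3 of the compartment diffusion tensor (um^2/ms).

        Dispersing a compartment with a Watson distribution does not change
        its mean diffusivity, so the Watson variants share the values of
        their parents.  Spheres are not Gaussian and have no mean ADC here.
        """
        if self.kind == "dot":
            return 0.0
        if self.kind == "ball":
            return self.d_par
        if self.kind in ("stick", "watson_stick"):
            return self.d_par / 3.0
        if self.kind in ("zeppelin", "watson_zeppelin"):
            return (self.d_par + 2.0 * self.d_perp) / 3.0
        raise ValueError(f"{self.kind} compartment has no Gaussian mean diffusivity")

    def t2_weight(self, te: float) -> float:
        if self.t2 is None or te == 0.0:
            return 1.0
        return math.exp(-te / self.t2)


@dataclass(frozen=True)
class KargerSpec:
    """Two-pool exchange: fractions, mean diffusivities, exchange time.

    ``t_ex = 1 / (k12 + k21)`` with first-order rates satisfying equilibrium
    ``f1 k12 = f2 k21``; ``diffusion_time`` is the effective diffusion time
    of the (narrow-pulse idealised) encoding.
    """

    f1: float
    f2: float
    d1: float
    d2: float
    t_ex: float
    diffusion_time: float

    def __post_init__(self):
        if abs(self.f1 + self.f2 - 1.0) > 1e-12:
            raise ValueError("exchange fractions must sum to 1")
        if min(self.f1, self.f2) < 0.0:
            raise ValueError("fractions must be non-negative")
        if self.t_ex <= 0.0:
            raise ValueError("exchange time must be positive (use math.inf for none)")
        if self.diffusion_time <= 0.0:
            raise ValueError("diffusion time must be positive")
        if min(self.d1, self.d2) < 0.0:
            raise ValueError("diffusivities must be non-negative")

    @property
    def rates(self) -> tuple[float, float]:
        """(k12, k21) in 1/ms, satisfying detailed balance."""
        if math.isinf(self.t_ex):
            return 0.0, 0.0
        return self.f2 / self.t_ex, self.f1 / self.t_ex


@dataclass(frozen=True)
class TissueModel:
    """A set of compartments whose fractions sum to one, plus optional exchange."""

    compartments: tuple[Compartment, ...]
    exchange: KargerSpec | None = None

    def __post_init__(self):
        comps = tuple(self.compartments)
        object.__setattr__(self, "compartments", comps)
        total = sum(c.fraction for c in comps)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"compartment fractions must sum to 1, got {total!r}")
        if self.exchange is not None and len(comps) != 2:
            raise ValueError("exchange is defined for exactly two compartments")


# ---------------------------------------------------------------------------
# Watson dispersion
# ---------------------------------------------------------------------------


def od_to_kappa(od: float) -> float:
    """Watson concentration kappa for orientation dispersion OD in (0, 1].

    Uses the convention ``OD = (2/pi) arctan(1/kappa)``: OD -> 1 is the
    uniform distribution (kappa = 0), OD -> 0 perfectly aligned.
    """
    if not 0.0 < od <= 1.0:
        raise ValueError("OD must lie in (0, 1]")
    return 1.0 / math.tan(math.pi * od / 2.0)


def kappa_to_od(kappa: float) -> float:
    """Inverse of :func:`od_to_kappa`."""
    if kappa < 0.0:
        raise ValueError("kappa must be non-negative")
    return (2.0 / math.pi) * math.atan2(1.0, kappa)


def powder_stick(bd: float) -> float:
    """Orientation average of ``exp(-bd cos^2 theta)`` over the sphere.

    Closed form ``sqrt(pi) erf(sqrt(bd)) / (2 sqrt(bd))``; the b -> 0 limit
    is 1.  This is the powder-averaged stick signal with ``bd = b * d_par``.
    """
    if bd < 0.0:
        raise ValueError("bd must be non-negative")
    if bd < 1e-12:
        return 1.0
    s = math.sqrt(bd)
    return math.sqrt(math.pi) * erf(s) / (2.0 * s)


def _watson_kernel_average(kappa: float, a: float, angle: float,
                           tol: float = 1e-6, max_order: int = 4096) -> float:
    """``E[exp(-a (g . n)^2)]`` for n ~ Watson(kappa) about the z axis.

    The encoding axis g lies at ``angle`` from the mean axis.  Gauss-Legendre
    quadrature in cos(theta) and a uniform (spectrally accurate) grid in phi;
    the order doubles until the result is stable to ``tol`` relative.
    """
    sg, cg = math.sin(angle), math.cos(angle)
    prev = None
    order = 32
    while order <= max_order:
        u, wu = roots_legendre(order)
        phi = np.linspace(0.0, 2.0 * math.pi, 2 * order, endpoint=False)
        su = np.sqrt(np.clip(1.0 - u**2, 0.0, None))
        # g.n on the (theta, phi) grid; Watson weight normalised by exp(kappa)
        gn = cg * u[:, None] + sg * su[:, None] * np.cos(phi)[None, :]
        w2d = np.exp(kappa * (u**2 - 1.0))[:, None] * np.exp(-a * gn**2)
        num = float(np.sum(wu[:, None] * w2d))
        den = float(np.sum(wu * np.exp(kappa * (u**2 - 1.0)))) * phi.size
        val = num / den
        if prev is not None and abs(val - prev) <= tol * max(abs(val), 1e-300):
            return val
        prev = val
        order *= 2
    raise RuntimeError(
        f"Watson quadrature did not converge to {tol:g} within order {max_order}"
    )


def signal_lte_watson_stick(b: float, d_par: float, od: float, angle: float = 0.0) -> float:
    """LTE attenuation of Watson-dispersed sticks.

    ``angle`` is the angle between the encoding axis and the Watson mean
    axis.  For OD -> 1 this is the powder-averaged stick.
    """
    if b < 0.0:
        raise ValueError("b must be non-negative")
    if b == 0.0 or d_par == 0.0:
        return 1.0
    return _watson_kernel_average(od_to_kappa(od), b * d_par, angle)


def signal_lte_watson_zeppelin(b: float, d_par: float, d_perp: float, od: float,
                               angle: float = 0.0) -> float:
    """LTE attenuation of Watson-dispersed zeppelins.

    Kernel ``exp(-b d_perp - b (d_par - d_perp) (g.n)^2)``; reduces to a
    ball for d_par = d_perp, independent of OD.
    """
    if b < 0.0:
        raise ValueError("b must be non-negative")
    if b == 0.0:
        return 1.0
    base = math.exp(-b * d_perp)
    if d_par == d_perp:
        return base
    return base * _watson_kernel_average(od_to_kappa(od), b * (d_par - d_perp), angle)


# ---------------------------------------------------------------------------
# Gaussian signals
# ---------------------------------------------------------------------------


def signal_gaussian(B: BTensor, D) -> float:
    """Attenuation ``exp(-Tr(B D))`` of one Gaussian compartment.

    ``D`` is the 3x3 symmetric PSD diffusion tensor in um^2/ms.
    """
    D = np.asarray(D, dtype=float)
    if D.shape != (3, 3):
        raise ValueError("diffusion tensor must be 3x3")
    if not np.allclose(D, D.T, atol=1e-12, rtol=0.0):
        raise ValueError("diffusion tensor must be symmetric")
    lo = np.linalg.eigvalsh(D)[0]
    if lo < -1e-12 * max(1.0, float(np.trace(D))):
        raise ValueError("diffusion tensor must be positive semi-definite")
    return float(np.exp(-np.sum(B.matrix * D)))


def signal_ste_mixture(b: float, model: TissueModel) -> float:
    """STE attenuation of a non-exchanging Gaussian mixture.

    ``sum_i f_i exp(-b MD_i)``; a dot contributes its fraction unattenuated
    at every b, which is the high-b plateau that defines the dot fraction.
    """
    if model.exchange is not None:
        raise ValueError("use signal_karger for exchanging models")
    if b < 0.0:
        raise ValueError("b must be non-negative")
    total = 0.0
    for c in model.compartments:
        total += c.fraction * math.exp(-b * c.mean_diffusivity)
    return total


def signal_lte_mixture(b: float, model: TissueModel, angle: float = 0.0) -> float:
    """LTE attenuation of a Gaussian mixture, encoding axis at ``angle``
    from each compartment's mean axis.

    Dispersed compartments are integrated over their Watson distribution;
    coherent sticks/zeppelins use the plain Gaussian kernel at ``angle``.
    """
    if model.exchange is not None:
        raise ValueError("use signal_karger for exchanging models")
    total = 0.0
    c2 = math.cos(angle) ** 2
    for c in model.compartments:
        if c.kind == "dot":
            s = 1.0
        elif c.kind == "ball":
            s = math.exp(-b * c.d_par)
        elif c.kind == "stick":
            s = math.exp(-b * c.d_par * c2)
        elif c.kind == "zeppelin":
            s = math.exp(-b * (c.d_perp + (c.d_par - c.d_perp) * c2))
        elif c.kind == "watson_stick":
            s = signal_lte_watson_stick(b, c.d_par, c.od, angle)
        elif c.kind == "watson_zeppelin":
            s = signal_lte_watson_zeppelin(b, c.d_par, c.d_perp, c.od, angle)
        else:
            raise ValueError(f"{c.kind} compartment is not Gaussian")
        total += c.fraction * s
    return total


# ---------------------------------------------------------------------------
# Exchange
# ---------------------------------------------------------------------------


def signal_karger(b: float, spec: KargerSpec) -> float:
    """Two-pool exchange attenuation under narrow-pulse idealisation.

    Magnetisation evolves as ``dm/dt = -(q^2 diag(D) + K) m`` over the
    diffusion time, with ``q^2 = b / diffusion_time`` and K the first-order
    exchange matrix; the signal is the sum of the pools at echo.  Evaluated
    through the analytic eigendecomposition of the 2x2 evolution matrix
    (stable for arbitrarily fast exchange, where a matrix exponential loses
    digits): the limits t_ex -> inf and t_ex -> 0 reduce exactly to the
    non-exchanging bi-exponential and the fully averaged mono-exponential.
    """
    if b < 0.0:
        raise ValueError("b must be non-negative")
    k12, k21 = spec.rates
    dt = spec.diffusion_time
    r1, r2 = spec.d1 * b / dt, spec.d2 * b / dt  # per-pool dephasing rates
    if k12 == 0.0 and k21 == 0.0:
        return spec.f1 * math.exp(-r1 * dt) + spec.f2 * math.exp(-r2 * dt)
    # M = [[r1 + k12, -k21], [-k12, r2 + k21]]; lam- via det/lam+ for
    # accuracy when the slow eigenvalue is far below the fast one
    a, d = r1 + k12, r2 + k21
    tr = a + d
    det = r1 * r2 + r1 * k21 + r2 * k12
    disc = math.sqrt(max((a - d) ** 2 + 4.0 * k12 * k21, 0.0))
    lam_hi = 0.5 * (tr + disc)
    lam_lo = det / lam_hi if lam_hi > 0.0 else 0.0
    # eigenvectors v = (k21, a - lam); decompose (f1, f2) onto them
    v_lo = np.array([k21, a - lam_lo])
    v_hi = np.array([k21, a - lam_hi])
    c = np.linalg.solve(np.column_stack([v_lo, v_hi]), [spec.f1, spec.f2])
    s = c[0] * math.exp(-lam_lo * dt) * v_lo.sum() + c[1] * math.exp(
        -lam_hi * dt
    ) * v_hi.sum()
    return float(s)


# ---------------------------------------------------------------------------
# T2 weighting
# ---------------------------------------------------------------------------


def signal_with_t2(model: TissueModel, b: float, te: float) -> float:
    """STE signal with per-compartment T2 weighting, relative to TE = 0.

    ``sum_i f_i exp(-TE / T2_i) exp(-b MD_i)``; compartments with ``t2``
    ``None`` have no TE dependence.  Fractions are defined at TE = 0, so the
    apparent fraction of a short-T2 pool shrinks as TE grows.
    """
    if te < 0.0:
        raise ValueError("TE must be non-negative")
    if model.exchange is not None:
        raise ValueError("use signal_karger for exchanging models")
    total = 0.0
    for c in model.compartments:
        total += c.fraction * c.t2_weight(te) * math.exp(-b * c.mean_diffusivity)
    return total


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------


def save_tissue_model(model: TissueModel, path) -> None:
    """Write a tissue model as a human-readable YAML config."""
    doc: dict = {"compartments": []}
    for c in model.compartments:
        block = {"kind": c.kind, "fraction": float(c.fraction)}
        if c.kind != "dot":
            block["d_par"] = float(c.d_par)
            block["d_perp"] = float(c.d_perp)
        if c.kind in ("watson_stick", "watson_zeppelin"):
            block["od"] = float(c.od)
            block["mean_axis"] = [float(v) for v in c.mean_axis]
        if c.kind == "sphere":
            block["radius"] = float(c.radius)
            block["d_intra"] = float(c.d_intra)
        if c.t2 is not None:
            block["t2"] = float(c.t2)
        doc["compartments"].append(block)
    if model.exchange is not None:
        e = model.exchange
        doc["exchange"] = {
            "f1": e.f1, "f2": e.f2, "d1": e.d1, "d2": e.d2,
            "t_ex": e.t_ex, "diffusion_time": e.diffusion_time,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_tissue_model(path) -> TissueModel:
    """Read a tissue model written by :func:`save_tissue_model`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    comps = []
    for block in doc["compartments"]:
        kwargs = dict(block)
        if "mean_axis" in kwargs:
            kwargs["mean_axis"] = tuple(kwargs["mean_axis"])
        comps.append(Compartment(**kwargs))
    exchange = None
    if doc.get("exchange") is not None:
        exchange = KargerSpec(**doc["exchange"])
    return TissueModel(tuple(comps), exchange)
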