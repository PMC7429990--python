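"""Quantifying the residual STE signal at very high b-values.

At b-values beyond a cut-off ``bs`` the only signal left under spherical
tensor encoding comes from water pools with very low mean diffusivity, so
the decay is well represented by a single exponential

    S(b) ~ A exp(-b D1),    A = S(0) f1,    b > bs.

The stage estimates, voxel-wise: S(0) extrapolated from the two lowest
shells (to suppress CSF), the dot-fraction upper limit ``f_dot =
S(b_max) / S(0)``, the (A, D1) pair by bounded multi-start least squares,
optionally a joint (C, T2, D1) fit across echo times, and the radius of a
restricted sphere with fixed intra-sphere diffusivity.  Fits act on shell
means of Rician-debiased signals, which may legitimately be negative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .btensor import AcquisitionProtocol, GradientWaveform, btensor_from_waveform
from .sphere import signal_sphere_waveform

__all__ = [
    "HighBFit",
    "shell_average",
    "estimate_s0_lowb",
    "fdot_upper_limit",
    "fit_highb_monoexp",
    "fit_highb_t2",
    "fit_sphere_radius",
    "roi_summary",
    "SUMMARY_COLUMNS",
]

#: Default cut-off above which the mono-exponential representation is fitted
#: (ms/um^2); shells with b strictly greater participate.
DEFAULT_BS = 10.0

#: Upper edge of the random-initialisation box for the signal fraction.
_F1_START_MAX = 0.3
#: Upper edge of the random-initialisation box for D1 (um^2/ms).
_D1_START_MAX = 1.0
_T2_BOUNDS = (1e-3, 300.0)
_RS_BOUNDS = (0.0, 20.0)

_LS_KW = dict(method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)


@dataclass
class HighBFit:
    """Result of the high-b characterisation of one voxel."""

    amplitude: float = math.nan  # A = S(0) f1, signal units
    d1_tilde: float = math.nan  # um^2/ms
    f1_tilde: float = math.nan
    fdot_tilde: float = math.nan
    s0_tilde: float = math.nan
    t2_1: float | None = None  # ms
    r_s: float | None = None  # um
    residual_norm: float = math.nan
    n_starts_converged: int = 0
    flags: tuple[str, ...] = field(default_factory=tuple)


def shell_average(values, protocol: AcquisitionProtocol) -> pd.DataFrame:
    """Arithmetic mean and standard deviation per unique (b, TE) shell.

    b0 volumes are excluded (they form the monitoring series, not a
    diffusion shell).  Rows are ordered by b then TE.  A shell with no
    volumes cannot occur by construction; an all-b0 protocol is an error.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != len(protocol):
        raise ValueError(
            f"signal vector length {values.shape[-1]} does not match "
            f"protocol length {len(protocol)}"
        )
    dwi = ~protocol.is_b0
    if not np.any(dwi):
        raise ValueError("protocol contains no diffusion-weighted volumes")
    rows = []
    b, te = protocol.b, protocol.te
    for bv in np.unique(b[dwi]):
        for tev in np.unique(te[dwi & (b == bv)]):
            sel = dwi & (b == bv) & (te == tev)
            v = values[..., sel]
            rows.append(
                {
                    "b": bv,
                    "te": tev,
                    "mean": float(np.mean(v)),
                    "std": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
                    "n": int(np.sum(sel)),
                }
            )
    return pd.DataFrame(rows).sort_values(["b", "te"], ignore_index=True)


def estimate_s0_lowb(shells: pd.DataFrame) -> float:
    """Extrapolate S(0) from the two lowest non-zero shells.

    Log-linear extrapolation to b = 0 through the two lowest shell means;
    using diffusion-weighted rather than b0 images suppresses the fast CSF
    pool, so in CSF-contaminated voxels the estimate deliberately falls
    below the true S(0).  Falls back (with a warning) to the lowest shell
    mean if a mean is non-positive.
    """
    if len(shells) < 2:
        raise ValueError("need at least two non-zero shells to extrapolate S(0)")
    lowest = shells.sort_values("b").iloc[:2]
    b_a, s_a = float(lowest.iloc[0]["b"]), float(lowest.iloc[0]["mean"])
    b_b, s_b = float(lowest.iloc[1]["b"]), float(lowest.iloc[1]["mean"])
    if s_a <= 0.0 or s_b <= 0.0:
        warnings.warn(
            "non-positive shell mean in the two lowest shells; "
            "falling back to the lowest-shell value",
            stacklevel=2,
        )
        return s_a
    slope = (math.log(s_a) - math.log(s_b)) / (b_b - b_a)
    return float(math.exp(math.log(s_a) + b_a * slope))


def fdot_upper_limit(shells: pd.DataFrame, s0_tilde: float) -> float:
    """Upper limit of the dot fraction: mean signal at b_max over S(0).

    With debiased data the value can legitimately be negative when the
    highest shell sits below the noise floor.
    """
    if s0_tilde <= 0.0:
        raise ValueError("S0 estimate must be positive")
    top = shells.loc[shells["b"].idxmax()]
    return float(top["mean"] / s0_tilde)


def _multistart_ls(residual, sample_x0, bounds, n_starts, seed):
    """Run bounded least squares from ``n_starts`` random starts.

    Returns (best_result, n_converged).  Ties on residual norm are broken
    by the smallest last parameter (the diffusivity), making the selection
    order-independent.
    """
    rng = np.random.default_rng(seed)
    best = best_key = None
    n_ok = 0
    for _ in range(n_starts):
        x0 = sample_x0(rng)
        try:
            res = least_squares(residual, x0, bounds=bounds, **_LS_KW)
        except Exception:
            continue
        if not res.success:
            continue
        n_ok += 1
        key = (res.cost, res.x[-1])
        if best_key is None or key < best_key:
            best, best_key = res, key
    return best, n_ok


def _highb_shells(shells: pd.DataFrame, bs: float) -> pd.DataFrame:
    high = shells[shells["b"] > bs]
    if high["b"].nunique() < 2:
        raise ValueError(
            f"need >= 2 shells with b > {bs} ms/um^2, found {high['b'].nunique()}"
        )
    return high


def fit_highb_monoexp(
    shells: pd.DataFrame,
    s0_tilde: float,
    bs: float = DEFAULT_BS,
    n_starts: int = 10,
    seed: int = 0,
    s0_max: float | None = None,
) -> HighBFit:
    """Fit ``A exp(-b D1)`` to the shell means with b strictly above ``bs``.

    Multi-start bounded least squares (trust-region reflective): A is
    initialised as the product of draws from [0, max S(0)] and [0, 0.3]
    (the S(0) and f1 boxes), D1 from [0, 1]; constraints are A in [0, inf)
    and D1 in [0, inf).  The lowest-residual solution is kept and
    ``f1_tilde = A / s0_tilde`` is reported.
    """
    high = _highb_shells(shells, bs)
    if high["te"].nunique() > 1:
        raise ValueError("multi-TE data: use fit_highb_t2")
    b = high["b"].to_numpy()
    y = high["mean"].to_numpy()
    if s0_max is None:
        s0_max = max(float(np.max(np.abs(shells["mean"]))), abs(s0_tilde), 1e-30)

    def residual(x):
        return x[0] * np.exp(-b * x[1]) - y

    def sample_x0(rng):
        return np.array(
            [
                rng.uniform(0.0, s0_max) * rng.uniform(0.0, _F1_START_MAX),
                rng.uniform(0.0, _D1_START_MAX),
            ]
        )

    best, n_ok = _multistart_ls(
        residual, sample_x0, ([0.0, 0.0], [np.inf, np.inf]), n_starts, seed
    )
    fit = HighBFit(s0_tilde=s0_tilde)
    if best is None:
        fit.flags = ("fit_failed",)
        return fit
    fit.amplitude = float(best.x[0])
    fit.d1_tilde = float(best.x[1])
    fit.f1_tilde = fit.amplitude / s0_tilde
    fit.residual_norm = float(np.linalg.norm(best.fun))
    fit.n_starts_converged = n_ok
    flags = []
    # A and D1 are jointly unidentifiable when the fitted curve is
    # indistinguishable from zero over the fitted shells
    if fit.amplitude * math.exp(-float(b.min()) * fit.d1_tilde) <= 1e-6 * s0_max:
        flags.append("unidentifiable_highb")
    if fit.f1_tilde > 1.0:
        flags.append("f1_above_one")
    fit.flags = tuple(flags)
    return fit


def fit_highb_t2(
    shells: pd.DataFrame,
    s0_tilde: float,
    bs: float = DEFAULT_BS,
    n_starts: int = 10,
    seed: int = 0,
    s0_max: float | None = None,
) -> HighBFit:
    """Joint fit of ``C exp(-TE/T2) exp(-b D1)`` over high-b shells.

    Requires at least three distinct echo times above the cut-off; T2 is
    initialised and constrained within [0, 300] ms.  A boundary hit on T2
    is flagged (TE-independent data pushes T2 to the upper bound).
    """
    high = _highb_shells(shells, bs)
    if high["te"].nunique() < 3:
        raise ValueError(
            "need >= 3 distinct TEs for a T2 fit; use fit_highb_monoexp for single-TE data"
        )
    b = high["b"].to_numpy()
    te = high["te"].to_numpy()
    y = high["mean"].to_numpy()
    if s0_max is None:
        s0_max = max(float(np.max(np.abs(shells["mean"]))), abs(s0_tilde), 1e-30)

    def residual(x):
        c, t2, d1 = x
        return c * np.exp(-te / t2) * np.exp(-b * d1) - y

    def sample_x0(rng):
        return np.array(
            [
                rng.uniform(0.0, s0_max) * rng.uniform(0.0, _F1_START_MAX),
                rng.uniform(_T2_BOUNDS[0], _T2_BOUNDS[1]),
                rng.uniform(0.0, _D1_START_MAX),
            ]
        )

    bounds = ([0.0, _T2_BOUNDS[0], 0.0], [np.inf, _T2_BOUNDS[1], np.inf])
    best, n_ok = _multistart_ls(residual, sample_x0, bounds, n_starts, seed)
    fit = HighBFit(s0_tilde=s0_tilde)
    if best is None:
        fit.flags = ("fit_failed",)
        return fit
    c, t2, d1 = (float(v) for v in best.x)
    fit.amplitude = c
    fit.t2_1 = t2
    fit.d1_tilde = d1
    fit.f1_tilde = c / s0_tilde
    fit.residual_norm = float(np.linalg.norm(best.fun))
    fit.n_starts_converged = n_ok
    flags = []
    if t2 >= _T2_BOUNDS[1] * (1.0 - 1e-6):
        flags.append("t2_at_upper_bound")
    fit.flags = tuple(flags)
    return fit


def fit_sphere_radius(
    shells: pd.DataFrame,
    waveform: GradientWaveform,
    s0_tilde: float,
    bs: float = DEFAULT_BS,
    d_s: float = 3.0,
    n_starts: int = 10,
    seed: int = 0,
    s0_max: float | None = None,
) -> HighBFit:
    """Fit an impermeable-sphere compartment to the high-b shells.

    The model is ``A * S_sphere(w_b, r_s, d_s)`` with the acquisition
    waveform amplitude-scaled to each shell's b-value (ln S of the GPD
    signal scales linearly with b at fixed shape and radius).  D_s is held
    fixed (default 3 um^2/ms) because radius and intra-sphere diffusivity
    are not jointly identifiable from a single waveform shape; bounds are
    A in [0, inf) and r_s in [0, 20] um.
    """
    if waveform is None:
        raise ValueError("sphere fitting requires the acquisition gradient waveform")
    high = _highb_shells(shells, bs)
    b = high["b"].to_numpy()
    y = high["mean"].to_numpy()
    b_wave = btensor_from_waveform(waveform).b
    if b_wave <= 0.0:
        raise ValueError("waveform carries no diffusion weighting")
    if s0_max is None:
        s0_max = max(float(np.max(np.abs(shells["mean"]))), abs(s0_tilde), 1e-30)
    scale = b / b_wave

    def residual(x):
        amp, rs = x
        ln_s = math.log(max(signal_sphere_waveform(waveform, rs, d_s), 1e-300))
        return amp * np.exp(scale * ln_s) - y

    def sample_x0(rng):
        return np.array(
            [
                rng.uniform(0.0, s0_max),
                rng.uniform(_RS_BOUNDS[0], _RS_BOUNDS[1]),
            ]
        )

    bounds = ([0.0, _RS_BOUNDS[0]], [np.inf, _RS_BOUNDS[1]])
    best, n_ok = _multistart_ls(residual, sample_x0, bounds, n_starts, seed)
    fit = HighBFit(s0_tilde=s0_tilde)
    if best is None:
        fit.flags = ("fit_failed",)
        return fit
    fit.amplitude = float(best.x[0])
    fit.r_s = float(best.x[1])
    fit.f1_tilde = fit.amplitude / s0_tilde
    fit.residual_norm = float(np.linalg.norm(best.fun))
    fit.n_starts_converged = n_ok
    flags = []
    if fit.r_s >= _RS_BOUNDS[1] * (1.0 - 1e-6):
        flags.append("rs_at_upper_bound")
    fit.flags = tuple(flags)
    return fit


#: Columns reported per ROI, in presentation order.
SUMMARY_COLUMNS = (
    "rel_floor_pct",  # sigma sqrt(pi/2) / S0 * 100
    "snr",
    "tsnr",
    "fdot_pct",
    "f1_pct",
    "d1",
)

_MIN_VOXELS_FOR_PERCENTILES = 10


def roi_summary(voxel_table: pd.DataFrame) -> pd.DataFrame:
    """Median and 10-90 percentiles of the voxel-wise estimates per ROI.

    ``voxel_table`` holds one row per voxel with a ``roi`` label and any of
    the :data:`SUMMARY_COLUMNS`.  Percentiles (linear interpolation) are
    suppressed (NaN) for ROIs with fewer than 10 voxels; empty ROIs are
    omitted with a warning.
    """
    rows = []
    for roi, group in voxel_table.groupby("roi"):
        group = group.dropna(how="all", subset=[c for c in SUMMARY_COLUMNS if c in group])
        if len(group) == 0:
            warnings.warn(f"ROI {roi!r} contains no voxels; omitted", stacklevel=2)
            continue
        row: dict = {"roi": roi, "n_voxels": len(group)}
        if "flags" in group:
            flagged = group["flags"].fillna("").astype(bool)
            row["n_flagged"] = int(flagged.sum())
        if "fdot_pct" in group:
            row["n_negative_fdot"] = int((group["fdot_pct"] < 0.0).sum())
        for col in SUMMARY_COLUMNS:
            if col not in group:
                continue
            vals = group[col].dropna().to_numpy()
            if vals.size == 0:
                continue
            row[f"{col}_median"] = float(np.median(vals))
            if vals.size >= _MIN_VOXELS_FOR_PERCENTILES:
                row[f"{col}_p10"] = float(np.percentile(vals, 10))
                row[f"{col}_p90"] = float(np.percentile(vals, 90))
            else:
                row[f"{col}_p10"] = math.nan
                row[f"{col}_p90"] = math.nan
        rows.append(row)
    return pd.DataFrame(rows)
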