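"""B-tensor algebra, gradient waveforms and acquisition protocols.

Tensor-valued diffusion encoding is summarised by the symmetric positive
semi-definite B-tensor ``B = integral q(t) q(t)^T dt``, with dephasing vector
``q(t) = gamma * integral_0^t g_eff(t') dt'``.  Its trace is the b-value and
its anisotropy ``b_delta`` distinguishes linear (b_delta = 1) from spherical
(b_delta = 0) encoding.

Internal units keep ``b * D`` of order one: b in ms/um^2 (1 ms/um^2 =
1000 s/mm^2), diffusivity in um^2/ms, time in ms, gradient amplitude in mT/m.
External protocol tables use s/mm^2; conversion happens only at the I/O
boundary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GAMMA_PROTON",
    "S_MM2_PER_MS_UM2",
    "BTensor",
    "GradientWaveform",
    "AcquisitionProtocol",
    "make_axisymmetric_btensor",
    "btensor_from_waveform",
    "effective_btensor",
    "make_pgse_waveform",
    "load_waveform",
    "save_waveform",
    "load_protocol",
    "save_protocol",
]

#: Proton gyromagnetic ratio in rad / (ms * mT/m * m).  Multiplying by a
#: gradient in mT/m and a duration in ms gives a dephasing |q| in rad/m.
GAMMA_PROTON = 267.513

#: Unit conversion between the external (s/mm^2) and internal (ms/um^2) b.
S_MM2_PER_MS_UM2 = 1000.0

# q computed from GAMMA_PROTON is in rad/m; 1e-6 converts to rad/um so that
# integral q^2 dt lands in ms/um^2.
_Q_TO_PER_UM = 1e-6


def _as_matrix(m) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        raise ValueError(f"B-tensor matrix must be 3x3, got shape {m.shape}")
    return m


@dataclass(frozen=True)
class BTensor:
    """Symmetric positive semi-definite diffusion-encoding tensor (ms/um^2)."""

    matrix: np.ndarray
    _b_delta_exact: float | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        m = _as_matrix(self.matrix)
        if not np.allclose(m, m.T, atol=1e-12, rtol=0.0):
            raise ValueError("B-tensor matrix must be symmetric")
        m = 0.5 * (m + m.T)
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)
        b = float(np.trace(m))
        lo = np.linalg.eigvalsh(m)[0]
        if lo < -1e-10 * max(b, 1.0):
            raise ValueError(
                f"B-tensor is not positive semi-definite (min eigenvalue {lo:g})"
            )

    @property
    def b(self) -> float:
        """b-value, the trace of the tensor (ms/um^2)."""
        return float(np.trace(self.matrix))

    @property
    def b_delta(self) -> float:
        """Anisotropy of the tensor, in [-0.5, 1].

        For an axially symmetric tensor with eigenvalues (b_par, b_perp,
        b_perp) this is ``(b_par - b_perp) / (b_par + 2 b_perp)``.  For a
        general tensor the eigenvalue farthest from the median plays the role
        of b_par.
        """
        if self._b_delta_exact is not None:
            return self._b_delta_exact
        b = self.b
        if b <= 0.0:
            return 0.0
        lam = np.linalg.eigvalsh(self.matrix)
        med = np.median(lam)
        unique = lam[np.argmax(np.abs(lam - med))]
        return float(3.0 * (unique - b / 3.0) / (2.0 * b))

    def isotropic_part(self) -> float:
        return self.b / 3.0


def make_axisymmetric_btensor(b: float, b_delta: float, axis=(0.0, 0.0, 1.0)) -> BTensor:
    """Build an axially symmetric B-tensor from (b, b_delta, symmetry axis).

    Eigenvalues are ``b_par = b (1 + 2 b_delta) / 3`` along ``axis`` and
    ``b_perp = b (1 - b_delta) / 3`` (twice).  ``b_delta`` must lie in
    [-0.5, 1] for the tensor to remain positive semi-definite.  The axis is
    ignored when b_delta = 0 (spherical encoding).
    """
    b = float(b)
    b_delta = float(b_delta)
    if b < 0.0:
        raise ValueError(f"b must be non-negative, got {b}")
    if not -0.5 <= b_delta <= 1.0:
        raise ValueError(
            f"b_delta must lie in [-0.5, 1] for a PSD tensor, got {b_delta}"
        )
    if b_delta == 0.0:
        return BTensor(np.eye(3) * (b / 3.0), _b_delta_exact=0.0)
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if abs(norm - 1.0) > 1e-6:
        raise ValueError(f"axis must be a unit vector, |axis| = {norm:g}")
    axis = axis / norm
    b_par = b * (1.0 + 2.0 * b_delta) / 3.0
    b_perp = b * (1.0 - b_delta) / 3.0
    m = b_perp * np.eye(3) + (b_par - b_perp) * np.outer(axis, axis)
    return BTensor(m, _b_delta_exact=b_delta)


def effective_btensor(B: BTensor, L) -> BTensor:
    """Voxel-wise effective B-tensor ``L B L^T`` under a linear coil tensor L.

    With L the local gradient-nonlinearity tensor (identity when the coil is
    perfectly linear), the waveform actually played in a voxel is ``L g(t)``
    and the realised encoding becomes ``L B L^T``.
    """
    L = np.asarray(L, dtype=float)
    if L.shape != (3, 3):
        raise ValueError(f"coil tensor must be 3x3, got shape {L.shape}")
    return BTensor(L @ B.matrix @ L.T)


# ---------------------------------------------------------------------------
# Gradient waveforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GradientWaveform:
    """Sampled spin-echo gradient waveform.

    The waveform is piecewise constant: row ``k`` of each segment is the
    3-axis gradient amplitude (mT/m) held over the k-th interval of length
    ``dt`` (ms).  ``samples_pre`` plays before the refocusing pulse,
    ``samples_post`` after it; the pulse itself is a gradient-free gap of
    duration ``gap`` (ms).  The effective gradient negates the post segment,
    so a refocused waveform integrates to zero net dephasing at echo time.
    """

    samples_pre: np.ndarray
    samples_post: np.ndarray
    dt: float
    gap: float = 0.0

    def __post_init__(self):
        pre = np.atleast_2d(np.asarray(self.samples_pre, dtype=float))
        post = np.atleast_2d(np.asarray(self.samples_post, dtype=float))
        if pre.shape[1] != 3 or post.shape[1] != 3:
            raise ValueError("waveform segments must have three gradient axes")
        if not self.dt > 0.0:
            raise ValueError("dt must be strictly positive")
        if self.gap < 0.0:
            raise ValueError("gap must be non-negative")
        pre.setflags(write=False)
        post.setflags(write=False)
        object.__setattr__(self, "samples_pre", pre)
        object.__setattr__(self, "samples_post", post)
        object.__setattr__(self, "dt", float(self.dt))
        object.__setattr__(self, "gap", float(self.gap))

    @property
    def duration(self) -> float:
        """Total duration from first gradient interval to echo (ms)."""
        n = self.samples_pre.shape[0] + self.samples_post.shape[0]
        return n * self.dt + self.gap

    def effective_gradient(self) -> np.ndarray:
        """Effective gradient on a uniform dt grid, post segment negated.

        The refocusing gap is represented by zero-gradient intervals;
        ``gap`` is rounded to the nearest whole number of intervals.
        """
        n_gap = int(round(self.gap / self.dt))
        return np.vstack(
            [
                self.samples_pre,
                np.zeros((n_gap, 3)),
                -self.samples_post,
            ]
        )

    def dephasing(self, gamma: float = GAMMA_PROTON) -> np.ndarray:
        """Dephasing vector q (rad/um) at the interval boundaries.

        Returns an (N+1, 3) array; q[0] = 0 and q[-1] is the residual at echo
        time (zero for a refocused waveform).  Exact for piecewise-constant
        gradients.
        """
        g = self.effective_gradient()
        q = np.vstack([np.zeros(3), np.cumsum(g, axis=0) * self.dt])
        return gamma * _Q_TO_PER_UM * q

    def residual_q(self, gamma: float = GAMMA_PROTON) -> float:
        """Residual |q| at echo relative to the peak |q| along the waveform."""
        q = self.dephasing(gamma)
        peak = float(np.max(np.linalg.norm(q, axis=1)))
        if peak == 0.0:
            return 0.0
        return float(np.linalg.norm(q[-1]) / peak)

    def check_refocused(self, gamma: float = GAMMA_PROTON, tol: float = 1e-6) -> None:
        res = self.residual_q(gamma)
        if res > tol:
            raise ValueError(
                f"waveform is not refocused: residual |q| is {res:.3g} of peak |q|"
            )

    def scaled(self, factor: float) -> "GradientWaveform":
        """Waveform with all gradient amplitudes multiplied by ``factor``."""
        return GradientWaveform(
            self.samples_pre * factor, self.samples_post * factor, self.dt, self.gap
        )

    def resampled(self, dt_new: float) -> "GradientWaveform":
        """Piecewise-constant resampling onto a finer uniform grid.

        Each original interval is split into a whole number of sub-intervals,
        so the waveform (and every derived integral) is unchanged.
        """
        if dt_new >= self.dt:
            return self
        k = int(np.ceil(self.dt / dt_new))
        return GradientWaveform(
            np.repeat(self.samples_pre, k, axis=0),
            np.repeat(self.samples_post, k, axis=0),
            self.dt / k,
            self.gap,
        )


def btensor_from_waveform(w: GradientWaveform, gamma: float = GAMMA_PROTON) -> BTensor:
    """B-tensor of a sampled spin-echo waveform.

    ``B = integral q q^T dt`` with q piecewise linear between interval
    boundaries (exact for the piecewise-constant gradient convention); the
    per-interval product integral uses the exact linear-linear rule
    ``h/6 (2 q0 q0^T + q0 q1^T + q1 q0^T + 2 q1 q1^T)``.
    """
    w.check_refocused(gamma)
    q = w.dephasing(gamma)
    q0, q1 = q[:-1], q[1:]
    h = w.dt
    B = (h / 6.0) * (
        2.0 * q0.T @ q0 + q0.T @ q1 + q1.T @ q0 + 2.0 * q1.T @ q1
    )
    B = 0.5 * (B + B.T)
    # clip tiny negative eigenvalues from accumulated rounding
    return BTensor(B)


def make_pgse_waveform(
    amplitude: float,
    delta: float,
    separation: float,
    axis=(0.0, 0.0, 1.0),
    dt: float = 0.01,
) -> GradientWaveform:
    """Idealised rectangular pulsed-gradient spin-echo pair.

    Two rectangular pulses of ``amplitude`` (mT/m) and duration ``delta``
    (ms) whose leading edges are ``separation`` (ms) apart; the refocusing
    pulse occupies the gap.  The closed-form b-value is
    ``(gamma G delta)^2 (separation - delta/3)``.
    """
    if separation < delta:
        raise ValueError("pulse separation must be at least the pulse duration")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    n = max(1, int(round(delta / dt)))
    dt_eff = delta / n
    pulse = np.tile(axis * amplitude, (n, 1))
    gap = separation - delta
    return GradientWaveform(pulse, pulse, dt_eff, gap)


# ---------------------------------------------------------------------------
# Waveform file I/O
# ---------------------------------------------------------------------------


def save_waveform(w: GradientWaveform, path) -> None:
    """Write a waveform as plain text.

    Header lines ``#dt_ms=`` and ``#gap_ms=``, then one ``gx gy gz`` row
    (mT/m) per interval; a blank line separates the pre- and post-pulse
    segments.
    """
    lines = [f"#dt_ms={float(w.dt)!r}", f"#gap_ms={float(w.gap)!r}"]
    for row in w.samples_pre:
        lines.append(" ".join(repr(float(v)) for v in row))
    lines.append("")
    for row in w.samples_post:
        lines.append(" ".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def load_waveform(path) -> GradientWaveform:
    """Read a waveform written by :func:`save_waveform`."""
    dt = gap = None
    segments: list[list[list[float]]] = [[]]
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            if key.strip() == "dt_ms":
                dt = float(value)
            elif key.strip() == "gap_ms":
                gap = float(value)
            continue
        if not line:
            if segments[-1]:
                segments.append([])
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"{path}: line {lineno}: expected 3 values, got {len(parts)}")
        try:
            segments[-1].append([float(p) for p in parts])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from None
    if dt is None:
        raise ValueError(f"{path}: missing #dt_ms= header")
    if gap is None:
        gap = 0.0
    segments = [s for s in segments if s]
    if len(segments) != 2:
        raise ValueError(
            f"{path}: expected two blank-line-separated segments, got {len(segments)}"
        )
    return GradientWaveform(np.array(segments[0]), np.array(segments[1]), dt, gap)


# ---------------------------------------------------------------------------
# Acquisition protocols
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Ordered per-volume encoding table.

    Arrays are aligned per acquired volume: b (ms/um^2), b_delta, encoding
    symmetry axis, echo time (ms).  Shell ids index the sorted unique
    non-zero b-values; b = 0 volumes carry shell id -1 and is_b0 = True.
    """

    b: np.ndarray
    b_delta: np.ndarray
    axis: np.ndarray
    te: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.b, dtype=float)
        bd = np.asarray(self.b_delta, dtype=float)
        ax = np.asarray(self.axis, dtype=float)
        te = np.asarray(self.te, dtype=float)
        n = b.shape[0]
        if not (bd.shape == (n,) and te.shape == (n,) and ax.shape == (n, 3)):
            raise ValueError("protocol arrays must share the per-volume length")
        for arr, name in ((b, "b"), (bd, "b_delta"), (ax, "axis"), (te, "te")):
            arr.setflags(write=False)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "b_delta", bd)
        object.__setattr__(self, "axis", ax)
        object.__setattr__(self, "te", te)

    def __len__(self) -> int:
        return self.b.shape[0]

    @property
    def is_b0(self) -> np.ndarray:
        return self.b == 0.0

    @property
    def shells(self) -> np.ndarray:
        """Sorted unique non-zero b-values (ms/um^2)."""
        return np.unique(self.b[~self.is_b0])

    @property
    def shell_id(self) -> np.ndarray:
        """Per-volume shell index into :attr:`shells`; -1 for b0 volumes."""
        ids = np.searchsorted(self.shells, self.b)
        ids[self.is_b0] = -1
        return ids

    @property
    def repetitions(self) -> np.ndarray:
        """Number of volumes in each shell of :attr:`shells`."""
        return np.array([int(np.sum(self.b == s)) for s in self.shells])

    @property
    def tes(self) -> np.ndarray:
        return np.unique(self.te)

    def btensor(self, i: int) -> BTensor:
        return make_axisymmetric_btensor(self.b[i], self.b_delta[i], self.axis[i])

    def subset(self, mask) -> "AcquisitionProtocol":
        mask = np.asarray(mask)
        return AcquisitionProtocol(
            self.b[mask], self.b_delta[mask], self.axis[mask], self.te[mask]
        )


def save_protocol(protocol: AcquisitionProtocol, path) -> None:
    """Write a protocol as a whitespace-delimited table.

    Columns: b [s/mm^2], b_delta, axis (3 floats), TE [ms].  Values are
    written with ``repr`` so a load/save round trip is bit-exact.
    """
    lines = ["# b[s/mm2] b_delta ax ay az TE[ms]"]
    for i in range(len(protocol)):
        fields = [
            repr(float(protocol.b[i] * S_MM2_PER_MS_UM2)),
            repr(float(protocol.b_delta[i])),
            repr(float(protocol.axis[i, 0])),
            repr(float(protocol.axis[i, 1])),
            repr(float(protocol.axis[i, 2])),
            repr(float(protocol.te[i])),
        ]
        lines.append(" ".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def load_protocol(path) -> AcquisitionProtocol:
    """Read a protocol table written by :func:`save_protocol`.

    External b is in s/mm^2 and converted to the internal ms/um^2 on read.
    Malformed rows are reported with their line number.
    """
    rows = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 6:
            raise ValueError(
                f"{path}: line {lineno}: expected 6 columns "
                f"(b b_delta ax ay az TE), got {len(parts)}"
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError:
            raise ValueError(f"{path}: line {lineno}: non-numeric field") from None
    if not rows:
        raise ValueError(f"{path}: protocol file contains no encodings")
    arr = np.array(rows)
    return AcquisitionProtocol(
        b=arr[:, 0] / S_MM2_PER_MS_UM2,
        b_delta=arr[:, 1],
        axis=arr[:, 2:5],
        te=arr[:, 5],
    )
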