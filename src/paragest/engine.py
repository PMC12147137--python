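"""Multi-pool Bloch-McConnell simulator.

The magnetization of the free guest pool and of each bound pool evolves
under relaxation, off-resonance precession, continuous rectangular RF
irradiation, and two-site exchange with the free pool (star topology: bound
pools exchange only with the free pool, not with each other).  The coupled
linear system

    dM/dt = A M + b

is made homogeneous by augmenting the state vector with a constant 1, so a
saturation or recovery interval of duration t is the exact linear map
``expm(A_aug * t)``.  This matrix-exponential propagation is the workhorse
behind z-spectra, fingerprints, dictionary generation and z-spectrum
fitting.

State layout: ``[Mx_0, My_0, Mz_0, Mx_1, My_1, Mz_1, ..., 1]`` with pool 0
the free pool and pools 1..N the bound pools, total dimension 3(N+1)+1.
Equilibrium: ``Mz_free = 1`` (the free-pool signal is the unit of
magnetization) and ``Mz_bound,i = f_i * c_i``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .core import (
    AcquisitionProtocol,
    Sample,
    SaturationPoint,
    b1_to_rad_per_s,
    ppm_to_rad_per_s,
)

__all__ = [
    "ZSpectrum",
    "Fingerprint",
    "mixture_free_relaxation",
    "assemble_bm_matrix",
    "equilibrium_state",
    "propagate",
    "simulate_zspectrum",
    "simulate_fingerprint",
]


@dataclass(frozen=True)
class ZSpectrum:
    """Normalized free-pool signal versus saturation offset.

    ``z_values[i]`` is the free-pool longitudinal magnetization after
    saturation at ``offsets[i]``, divided by the same quantity at the far
    off-resonance reference.  Exchange appears as dips at bound-pool
    offsets.
    """

    offsets: np.ndarray
    z_values: np.ndarray
    b1: float
    t_sat: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "offsets", np.asarray(self.offsets, dtype=float))
        object.__setattr__(self, "z_values", np.asarray(self.z_values, dtype=float))
        if self.offsets.shape != self.z_values.shape:
            raise ValueError("offsets and z_values must have the same shape")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "offset_ppm": self.offsets,
                "z": self.z_values,
                "b1_uT": self.b1,
                "t_sat_s": self.t_sat,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ZSpectrum":
        df = pd.read_csv(path)
        return cls(
            offsets=df["offset_ppm"].to_numpy(),
            z_values=df["z"].to_numpy(),
            b1=float(df["b1_uT"].iloc[0]),
            t_sat=float(df["t_sat_s"].iloc[0]),
        )


@dataclass(frozen=True)
class Fingerprint:
    """Ordered vector of normalized signal intensities across a protocol's
    saturation points."""

    values: np.ndarray
    protocol_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("fingerprint must be a nonempty 1-D vector")

    def __len__(self) -> int:
        return len(self.values)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"point_index": np.arange(1, len(self.values) + 1), "signal": self.values}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, protocol_id: str = "") -> "Fingerprint":
        df = pd.read_csv(path).sort_values("point_index")
        return cls(values=df["signal"].to_numpy(), protocol_id=protocol_id)

    def to_json_envelope(self, path=None, **settings) -> str:
        payload = {
            "protocol_id": self.protocol_id,
            "values": self.values.tolist(),
            "settings": settings,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def mixture_free_relaxation(sample: Sample) -> tuple[float, float]:
    """Free-pool relaxation times of a mixture.

    Paramagnetic relaxation enhancement is additive in agent concentration,
    so rates combine as

        1/T1_free(mix) = 1/T1_dia + sum_i c_i (1/T1_free,i - 1/T1_dia)

    (same for T2), where T1_dia/T2_dia are the diamagnetic-pair baseline
    stored on the sample.  For a single pool at c = 1 this reduces exactly
    to that pair's observed free-pool times.
    """
    r1 = 1.0 / sample.t1_dia
    r2 = 1.0 / sample.t2_dia
    for pool, c in zip(sample.pools, sample.concentrations):
        r1 += c * (1.0 / pool.t1_free - 1.0 / sample.t1_dia)
        r2 += c * (1.0 / pool.t2_free - 1.0 / sample.t2_dia)
    if r1 <= 0 or r2 <= 0:
        raise ValueError("mixture relaxation rates must be positive")
    return 1.0 / r1, 1.0 / r2


def _pool_tables(sample: Sample):
    """Per-pool (delta_ppm, T1, T2, M0, k_f, k_r) arrays, free pool first."""
    t1f, t2f = mixture_free_relaxation(sample)
    n = sample.n_pools
    delta = np.zeros(n + 1)
    t1 = np.empty(n + 1)
    t2 = np.empty(n + 1)
    m0 = np.empty(n + 1)
    kf = np.zeros(n + 1)  # free -> bound i
    kr = np.zeros(n + 1)  # bound i -> free
    t1[0], t2[0], m0[0] = t1f, t2f, 1.0
    for i, (pool, c) in enumerate(zip(sample.pools, sample.concentrations), start=1):
        delta[i] = pool.delta_omega
        t1[i], t2[i] = pool.t1_bound, pool.t2_bound
        m0[i] = pool.f * c
        kf[i] = pool.f * c * pool.k_ex
        kr[i] = pool.k_ex
    return delta, t1, t2, m0, kf, kr


def assemble_bm_matrix(sample: Sample, point: SaturationPoint) -> np.ndarray:
    """Assemble the augmented Bloch-McConnell generator for one saturation
    point.

    In the frame rotating at the RF frequency, pool p with resonance
    delta_p sees the frequency offset Delta_p = delta_p - offset (rad/s)
    and the RF field omega_1 along x:

        dMx/dt = -Mx/T2p + Delta_p My
        dMy/dt = -Delta_p Mx - My/T2p + omega_1 Mz
        dMz/dt = -omega_1 My - (Mz - M0p)/T1p

    Exchange couples each bound pool i to the free pool on all three
    components with forward rate k_f,i = f_i c_i k_ex,i (free -> bound)
    and reverse rate k_ex,i (bound -> free); detailed balance
    k_f,i M0_free = k_ex,i M0_bound,i holds by construction.  Constant
    terms M0p/T1p live in the augmentation column; the last row is zero so
    the trailing state component stays 1.
    """
    cfg = sample.spectrometer
    delta, t1, t2, m0, kf, kr = _pool_tables(sample)
    if not (
        np.all(np.isfinite(delta))
        and np.all(np.isfinite(t1))
        and np.all(np.isfinite(t2))
        and np.all(np.isfinite(m0))
    ):
        raise ValueError("non-finite pool parameters")
    n_pools = len(delta)
    w1 = b1_to_rad_per_s(point.b1, cfg)
    dim = 3 * n_pools + 1
    a = np.zeros((dim, dim))
    kf_total = kf.sum()
    for p in range(n_pools):
        ix, iy, iz = 3 * p, 3 * p + 1, 3 * p + 2
        dp = ppm_to_rad_per_s(delta[p] - point.offset, cfg)
        a[ix, ix] = -1.0 / t2[p]
        a[ix, iy] = dp
        a[iy, ix] = -dp
        a[iy, iy] = -1.0 / t2[p]
        a[iy, iz] = w1
        a[iz, iy] = -w1
        a[iz, iz] = -1.0 / t1[p]
        a[iz, -1] = m0[p] / t1[p]
        for comp in range(3):
            j = 3 * p + comp
            if p == 0:
                a[j, j] += -kf_total
                for q in range(1, n_pools):
                    a[j, 3 * q + comp] += kr[q]
            else:
                a[j, j] += -kr[p]
                a[j, comp] += kf[p]
    return a


def equilibrium_state(sample: Sample) -> np.ndarray:
    """Thermal-equilibrium augmented state: Mz_free = 1, Mz_bound,i =
    f_i c_i, transverse components zero, trailing constant 1."""
    _, _, _, m0, _, _ = _pool_tables(sample)
    state = np.zeros(3 * len(m0) + 1)
    state[2::3] = m0
    state[-1] = 1.0
    return state


def propagate(state: np.ndarray, matrix: np.ndarray, t: float) -> np.ndarray:
    """Advance an augmented state by exp(A t)."""
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if t == 0:
        return np.array(state, dtype=float)
    return expm(matrix * t) @ state


def _recovery_propagator(sample: Sample, t_rec: float) -> np.ndarray:
    """Propagator for an RF-free delay.

    With omega_1 = 0 the longitudinal components evolve independently of
    the transverse ones, so the rotating-frame offset only sets the phase
    of the (exponentially vanishing) transverse magnetization; the frame
    at the free-guest resonance is used.
    """
    rest = SaturationPoint(b1=0.0, offset=0.0, t_sat=1.0, t_rec=0.0)
    return expm(assemble_bm_matrix(sample, rest) * t_rec)


def _acquire_point(state, sample, point, sat_propagator=None, rec_propagator=None):
    """Recovery then saturation; returns (new_state, Mz_free readout)."""
    if rec_propagator is None:
        rec_propagator = _recovery_propagator(sample, point.t_rec)
    state = rec_propagator @ state
    if sat_propagator is None:
        sat_propagator = expm(assemble_bm_matrix(sample, point) * point.t_sat)
    state = sat_propagator @ state
    return state, float(state[2])


def simulate_zspectrum(
    sample: Sample,
    offsets,
    b1: float,
    t_sat: float,
    t_rec: float = 9.57,
    reference_offset: float = 200.0,
) -> ZSpectrum:
    """Simulate a z-spectrum: one saturation point per offset, each starting
    from thermal equilibrium (recovery then saturation), normalized by the
    identical pipeline run at the far off-resonance reference."""
    offsets = np.atleast_1d(np.asarray(offsets, dtype=float))
    if offsets.size == 0:
        raise ValueError("offset list must be nonempty")
    eq = equilibrium_state(sample)
    rec = _recovery_propagator(sample, t_rec) if t_rec > 0 else np.eye(len(eq))

    def readout(offset: float) -> float:
        point = SaturationPoint(b1=b1, offset=offset, t_sat=t_sat, t_rec=t_rec)
        _, mz = _acquire_point(eq, sample, point, rec_propagator=rec)
        return mz

    ref = readout(reference_offset)
    z = np.array([readout(off) for off in offsets]) / ref
    return ZSpectrum(offsets=offsets, z_values=z, b1=b1, t_sat=t_sat)


def simulate_fingerprint(sample: Sample, protocol: AcquisitionProtocol) -> Fingerprint:
    """Simulate a fingerprint by propagating the magnetization sequentially
    through every recovery and saturation period of the protocol.

    The state is carried from point to point (no full-reset assumption);
    each readout is the free-pool Mz, and the whole trajectory is
    normalized by the readout at the protocol's off-resonance reference
    point.  If the protocol contains no reference point, a dedicated
    reference acquisition from equilibrium is simulated instead.
    """
    if sample.spectrometer is None:
        raise ValueError("sample must carry a spectrometer configuration")
    state = equilibrium_state(sample)
    rec_cache: dict[float, np.ndarray] = {}
    raw = np.empty(len(protocol))
    for i, point in enumerate(protocol.points):
        if point.t_rec not in rec_cache:
            rec_cache[point.t_rec] = _recovery_propagator(sample, point.t_rec)
        state, raw[i] = _acquire_point(
            state, sample, point, rec_propagator=rec_cache[point.t_rec]
        )
    ref_idx = protocol.reference_index()
    if ref_idx is not None:
        ref = raw[ref_idx]
    else:
        p0 = protocol.points[0]
        ref_point = SaturationPoint(
            b1=p0.b1, offset=protocol.reference_offset, t_sat=p0.t_sat, t_rec=p0.t_rec
        )
        _, ref = _acquire_point(
            equilibrium_state(sample), sample, ref_point,
            rec_propagator=rec_cache[p0.t_rec],
        )
    return Fingerprint(values=raw / ref, protocol_id=protocol.protocol_id())
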