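"""Domain types, unit conversions, and the default 40-point acquisition protocol.

The physical setting: a fluorinated guest molecule in fast-to-intermediate
exchange between its free state in solution and the cavities of
lanthanide-chelating cyclodextrin hosts (Ln-alpha-CD).  Each bound state is a
minor spin pool whose chemical-shift offset (ppm, relative to the free guest
at 0 ppm) is dispersed by the lanthanide's pseudocontact shift.  Selective
saturation of a bound pool is transferred to the free pool by guest exchange
and detected as a loss of the free-guest signal (GEST / saturation transfer).

All frequencies are handled in two unit systems: ppm (chemical shift, what a
spectroscopist reads off a spectrum) and rad/s (what enters the equations of
motion).  Conversions depend only on the spectrometer configuration.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GAMMA_19F",
    "SpectrometerConfig",
    "LanthanidePoolParams",
    "SaturationPoint",
    "AcquisitionProtocol",
    "Sample",
    "ppm_to_rad_per_s",
    "b1_to_rad_per_s",
    "build_default_protocol",
]

TWO_PI = 2.0 * math.pi

#: Gyromagnetic ratio of 19F, rad s^-1 T^-1 (2 pi x 40.078 MHz/T).
GAMMA_19F = TWO_PI * 40.078e6


@dataclass(frozen=True)
class SpectrometerConfig:
    """Static spectrometer parameters for a 19F experiment.

    Parameters
    ----------
    b0_field : float
        Main magnetic flux density in tesla. Default 11.7 T (500 MHz 1H).
    larmor_freq_19f : float
        19F Larmor frequency in MHz.  Default 470.4 MHz at 11.7 T.
    gamma_19f : float
        19F gyromagnetic ratio in rad s^-1 T^-1.
    """

    b0_field: float = 11.7
    larmor_freq_19f: float = 470.4
    gamma_19f: float = GAMMA_19F

    def __post_init__(self) -> None:
        if not (self.b0_field > 0 and self.larmor_freq_19f > 0 and self.gamma_19f > 0):
            raise ValueError("spectrometer parameters must be strictly positive")
        implied_mhz = self.b0_field * self.gamma_19f / TWO_PI / 1e6
        if abs(implied_mhz - self.larmor_freq_19f) / self.larmor_freq_19f > 0.01:
            raise ValueError(
                f"larmor_freq_19f={self.larmor_freq_19f} MHz inconsistent with "
                f"b0_field*gamma/2pi={implied_mhz:.1f} MHz (>1% off)"
            )


def ppm_to_rad_per_s(offset_ppm: float, cfg: SpectrometerConfig) -> float:
    """Convert a chemical-shift offset in ppm to angular frequency in rad/s.

    1 ppm at a Larmor frequency of ``nu`` MHz corresponds to ``nu`` Hz.
    """
    return offset_ppm * cfg.larmor_freq_19f * TWO_PI


def b1_to_rad_per_s(b1_uT: float, cfg: SpectrometerConfig) -> float:
    """Convert a saturation amplitude B1 in microtesla to the nutation
    frequency omega_1 = gamma * B1 in rad/s."""
    if b1_uT < 0:
        raise ValueError(f"b1 must be >= 0, got {b1_uT}")
    return cfg.gamma_19f * b1_uT * 1e-6


@dataclass(frozen=True)
class LanthanidePoolParams:
    """Exchange and relaxation parameters of one host-guest pair.

    These are the five quantities extracted per pair from multi-power
    z-spectrum fitting, plus the (weakly identifiable) bound-pool relaxation
    times the simulator needs.

    Parameters
    ----------
    name : str
        Lanthanide identifier (``"Dy"``, ``"Tb"``, ...).
    delta_omega : float
        Chemical-shift offset of the bound guest, ppm, free guest at 0.
    f : float
        Bound-pool fraction relative to the free pool (dimensionless).
    k_ex : float
        Exchange rate of the guest leaving the bound pool, s^-1.
    t1_free, t2_free : float
        Free-pool relaxation times observed for this pair, s.
    t1_bound, t2_bound : float
        Bound-pool relaxation times, s.  ``t1_bound`` defaults to
        ``t1_free``; ``t2_bound`` defaults to 0.02 s.
    """

    name: str
    delta_omega: float
    f: float
    k_ex: float
    t1_free: float
    t2_free: float
    t1_bound: float | None = None
    t2_bound: float = 0.02

    def __post_init__(self) -> None:
        if self.t1_bound is None:
            object.__setattr__(self, "t1_bound", self.t1_free)
        if not 0.0 <= self.f < 1.0:
            raise ValueError(f"f must be in [0, 1), got {self.f}")
        if self.k_ex <= 0:
            raise ValueError(f"k_ex must be > 0, got {self.k_ex}")
        if not self.t1_free >= self.t2_free > 0:
            raise ValueError("free-pool times must satisfy t1 >= t2 > 0")
        if not self.t1_bound >= self.t2_bound > 0:
            raise ValueError("bound-pool times must satisfy t1 >= t2 > 0")
        if abs(self.delta_omega) > 50.0:
            raise ValueError(f"|delta_omega| must be <= 50 ppm, got {self.delta_omega}")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "delta_omega_ppm": self.delta_omega,
            "f": self.f,
            "k_ex_s": self.k_ex,
            "t1_free_s": self.t1_free,
            "t2_free_s": self.t2_free,
            "t1_bound_s": self.t1_bound,
            "t2_bound_s": self.t2_bound,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LanthanidePoolParams":
        return cls(
            name=str(d["name"]),
            delta_omega=float(d["delta_omega_ppm"]),
            f=float(d["f"]),
            k_ex=float(d["k_ex_s"]),
            t1_free=float(d["t1_free_s"]),
            t2_free=float(d["t2_free_s"]),
            t1_bound=float(d["t1_bound_s"]),
            t2_bound=float(d["t2_bound_s"]),
        )


@dataclass(frozen=True)
class SaturationPoint:
    """One acquisition point: a rectangular saturation pulse plus the
    recovery delay preceding it.

    Attributes
    ----------
    b1 : float
        Saturation amplitude, microtesla.
    offset : float
        Saturation frequency, ppm relative to the free-guest resonance.
    t_sat : float
        Saturation duration, s.
    t_rec : float
        Recovery delay before this point, s.
    """

    b1: float
    offset: float
    t_sat: float
    t_rec: float

    def __post_init__(self) -> None:
        if self.b1 < 0:
            raise ValueError("b1 must be >= 0")
        if self.t_sat <= 0:
            raise ValueError("t_sat must be > 0")
        if self.t_rec < 0:
            raise ValueError("t_rec must be >= 0")


@dataclass(frozen=True)
class AcquisitionProtocol:
    """An ordered sequence of saturation points and the far off-resonance
    reference offset used for normalization."""

    points: tuple[SaturationPoint, ...]
    reference_offset: float = 200.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        if len(self.points) == 0:
            raise ValueError("protocol must contain at least one point")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def offsets(self) -> np.ndarray:
        return np.array([p.offset for p in self.points])

    def reference_index(self) -> int | None:
        """Index of the first point at the reference offset, or None."""
        for i, p in enumerate(self.points):
            if p.offset == self.reference_offset:
                return i
        return None

    # --- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "points": [
                {
                    "b1_uT": p.b1,
                    "offset_ppm": p.offset,
                    "t_sat_s": p.t_sat,
                    "t_rec_s": p.t_rec,
                }
                for p in self.points
            ],
            "reference_offset_ppm": self.reference_offset,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        points = tuple(
            SaturationPoint(
                b1=float(p["b1_uT"]),
                offset=float(p["offset_ppm"]),
                t_sat=float(p["t_sat_s"]),
                t_rec=float(p["t_rec_s"]),
            )
            for p in d["points"]
        )
        return cls(points=points, reference_offset=float(d["reference_offset_ppm"]))

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "AcquisitionProtocol":
        """Load from a JSON string or a file path."""
        text = str(source)
        if not text.lstrip().startswith("{"):
            with open(source) as fh:
                text = fh.read()
        return cls.from_dict(json.loads(text))

    def protocol_id(self) -> str:
        """Stable short hash of the serialized protocol."""
        return hashlib.sha1(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def build_default_protocol(
    library_offsets,
    cfg: SpectrometerConfig | None = None,
    *,
    b1_mild: float = 1.75,
    b1_strong: float = 2.87,
    t_sat_long: float = 4.0,
    t_sat_short: float = 2.0,
    t_rec: float = 9.57,
    reference_offset: float = 200.0,
    sweep_range: tuple[float, float] = (1.0, 11.0),
    n_sweep: int = 10,
) -> AcquisitionProtocol:
    """Build the default three-block, 40-point fingerprinting protocol.

    Block 1 (points 1-15): a mild ``b1_mild`` = 1.75 uT pulse at the 14
    characteristic bound-pool offsets of the library plus one far
    off-resonance reference point.  Block 2 (points 16-30): the same 15
    offsets with a stronger ``b1_strong`` = 2.87 uT pulse.  Block 3
    (points 31-40): ``n_sweep`` offsets evenly spanning ``sweep_range``
    (1-11 ppm, where several bound-pool resonances crowd together) at
    2.87 uT with a shorter saturation time.  Every point is preceded by
    the same ``t_rec`` = 9.57 s recovery delay.

    Within blocks 1-2 the points are ordered with the off-resonance
    reference first, then descending |offset| (ties broken by value); the
    ordering is arbitrary but fixed so fingerprints are comparable.

    Parameters
    ----------
    library_offsets : sequence of float
        Exactly 14 distinct bound-pool offsets in ppm.
    """
    offsets = [float(x) for x in library_offsets]
    if len(offsets) != 14:
        raise ValueError(f"expected exactly 14 library offsets, got {len(offsets)}")
    if len(set(offsets)) != 14:
        raise ValueError("library offsets must be distinct")
    if cfg is None:
        cfg = SpectrometerConfig()
    if t_sat_short >= t_sat_long:
        raise ValueError("block-3 saturation must be shorter than blocks 1-2")

    ordered = [reference_offset] + sorted(offsets, key=lambda x: (-abs(x), x))
    points: list[SaturationPoint] = []
    for off in ordered:  # block 1
        points.append(SaturationPoint(b1=b1_mild, offset=off, t_sat=t_sat_long, t_rec=t_rec))
    for off in ordered:  # block 2
        points.append(SaturationPoint(b1=b1_strong, offset=off, t_sat=t_sat_long, t_rec=t_rec))
    for off in np.linspace(sweep_range[0], sweep_range[1], n_sweep):  # block 3
        points.append(
            SaturationPoint(b1=b1_strong, offset=float(off), t_sat=t_sat_short, t_rec=t_rec)
        )
    return AcquisitionProtocol(points=tuple(points), reference_offset=reference_offset)


@dataclass(frozen=True)
class Sample:
    """A solution of one or more Ln-alpha-CD hosts sharing a single free
    guest pool.

    ``concentrations`` are dimensionless multipliers of each pool's
    reference bound fraction ``f`` (linear scaling holds at large guest
    excess).  ``t1_dia``/``t2_dia`` are the free-pool relaxation times of
    the diamagnetic reference pair, used as the baseline when combining
    per-pair paramagnetic relaxation enhancements in a mixture.
    """

    pools: tuple[LanthanidePoolParams, ...]
    concentrations: tuple[float, ...]
    spectrometer: SpectrometerConfig = field(default_factory=SpectrometerConfig)
    t1_dia: float = 1.50
    t2_dia: float = 0.90

    def __post_init__(self) -> None:
        object.__setattr__(self, "pools", tuple(self.pools))
        object.__setattr__(self, "concentrations", tuple(float(c) for c in self.concentrations))
        if len(self.pools) != len(self.concentrations):
            raise ValueError("one concentration factor per pool required")
        names = [p.name for p in self.pools]
        if len(set(names)) != len(names):
            raise ValueError(f"pool names must be unique, got {names}")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentration factors must be > 0")
        total = sum(p.f * c for p, c in zip(self.pools, self.concentrations))
        if total >= 1.0:
            raise ValueError(f"total bound fraction {total} must be < 1")
        if not self.t1_dia >= self.t2_dia > 0:
            raise ValueError("diamagnetic baseline must satisfy t1 >= t2 > 0")

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    def sample_id(self) -> str:
        """Stable short hash of pools, concentrations and baseline."""
        payload = json.dumps(
            {
                "pools": [p.to_dict() for p in self.pools],
                "concentrations": list(self.concentrations),
                "t1_dia": self.t1_dia,
                "t2_dia": self.t2_dia,
            },
            sort_keys=True,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def with_concentrations(self, concentrations) -> "Sample":
        return replace(self, concentrations=tuple(float(c) for c in concentrations))
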