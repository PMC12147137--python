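"""Synthetic fixture library and synthetic-data generation.

Every stage of the pipeline (simulation, dictionary, matching, fitting) is
exercised on synthetic inputs generated here, so nothing downstream depends
on access to a spectrometer.

The 14-member parameter library is SYNTHETIC: the per-pair values are
plausible fixtures designed to reproduce the qualitative structure of a
real Ln-alpha-CD / fluorinated-guest series, not measured constants.  Three
structural anchors are honored: the bound-pool offsets span roughly 45 ppm
with Dy at -28.6 ppm; the two diamagnetic members (La, Lu) sit only 0.6 ppm
apart; and Gd has a near-zero pseudocontact shift combined with strong
paramagnetic relaxation enhancement, which yields the characteristically
"shallow", nearly featureless fingerprint that makes Gd the hard case for
pattern matching.  Exchange rates vary across the series (hundreds to
~2000 1/s) and the nominal bound fraction is f = 0.005, i.e. a 1:200
host:guest ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AcquisitionProtocol, LanthanidePoolParams, Sample, SpectrometerConfig
from .engine import Fingerprint, simulate_fingerprint

__all__ = [
    "LANTHANIDES",
    "FixtureLibrary",
    "NoiseModel",
    "default_library",
    "generate_sample",
    "generate_noisy_fingerprint",
]

#: The 14 lanthanides of the host library (Pm is excluded: radioactive,
#: no stable isotope, not part of the series studied).
LANTHANIDES = (
    "La", "Ce", "Pr", "Nd", "Sm", "Eu", "Gd",
    "Tb", "Dy", "Ho", "Er", "Tm", "Yb", "Lu",
)

# name: (delta_omega_ppm, f, k_ex_s, t1_free_s, t2_free_s, t1_bound_s, t2_bound_s)
# Synthetic fixture values; anchors: Dy at -28.6 ppm, |La - Lu| = 0.6 ppm,
# Gd near 0 ppm with strong relaxation enhancement, ~45 ppm total span.
_FIXTURE_TABLE = {
    "La": (0.8, 0.005, 800.0, 1.50, 0.90, 1.50, 0.020),
    "Ce": (4.2, 0.005, 900.0, 1.40, 0.75, 1.40, 0.020),
    "Pr": (9.5, 0.005, 1100.0, 1.35, 0.70, 1.35, 0.020),
    "Nd": (6.8, 0.005, 1000.0, 1.38, 0.72, 1.38, 0.020),
    "Sm": (1.5, 0.005, 700.0, 1.45, 0.80, 1.45, 0.020),
    "Eu": (-5.4, 0.005, 600.0, 1.42, 0.78, 1.42, 0.020),
    "Gd": (0.3, 0.005, 1800.0, 0.25, 0.05, 0.25, 0.005),
    "Tb": (-22.0, 0.005, 1500.0, 1.10, 0.55, 1.10, 0.015),
    "Dy": (-28.6, 0.005, 1600.0, 1.05, 0.50, 1.05, 0.015),
    "Ho": (-15.2, 0.005, 1200.0, 1.15, 0.58, 1.15, 0.015),
    "Er": (12.4, 0.005, 900.0, 1.20, 0.62, 1.20, 0.018),
    "Tm": (15.8, 0.005, 700.0, 1.25, 0.65, 1.25, 0.018),
    "Yb": (3.4, 0.005, 500.0, 1.40, 0.70, 1.40, 0.020),
    "Lu": (1.4, 0.005, 400.0, 1.50, 0.90, 1.50, 0.020),
}

#: Library member whose pair defines the diamagnetic relaxation baseline.
DIAMAGNETIC_REFERENCE = "La"

_CSV_COLUMNS = [
    "name", "delta_omega_ppm", "f", "k_ex_s",
    "t1_free_s", "t2_free_s", "t1_bound_s", "t2_bound_s",
]


@dataclass(frozen=True)
class FixtureLibrary:
    """An ordered table of per-pair exchange parameters, one record per
    lanthanide."""

    pools: tuple[LanthanidePoolParams, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pools", tuple(self.pools))
        names = [p.name for p in self.pools]
        if len(set(names)) != len(names):
            raise ValueError("library names must be unique")

    def __len__(self) -> int:
        return len(self.pools)

    def __iter__(self):
        return iter(self.pools)

    def __getitem__(self, name: str) -> LanthanidePoolParams:
        for p in self.pools:
            if p.name == name:
                return p
        raise KeyError(f"unknown lanthanide {name!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.pools)

    @property
    def offsets(self) -> tuple[float, ...]:
        return tuple(p.delta_omega for p in self.pools)

    def to_csv(self, path) -> None:
        pd.DataFrame([p.to_dict() for p in self.pools], columns=_CSV_COLUMNS).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "FixtureLibrary":
        df = pd.read_csv(path)
        missing = set(_CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"library CSV missing columns: {sorted(missing)}")
        return cls(
            pools=tuple(LanthanidePoolParams.from_dict(row) for row in df.to_dict("records"))
        )

    def library_id(self) -> str:
        import hashlib
        import json

        payload = json.dumps([p.to_dict() for p in self.pools], sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def default_library() -> FixtureLibrary:
    """The shipped 14-member synthetic parameter library."""
    return FixtureLibrary(
        pools=tuple(
            LanthanidePoolParams(
                name=name, delta_omega=dw, f=f, k_ex=kex,
                t1_free=t1f, t2_free=t2f, t1_bound=t1b, t2_bound=t2b,
            )
            for name, (dw, f, kex, t1f, t2f, t1b, t2b) in _FIXTURE_TABLE.items()
        )
    )


def generate_sample(
    subset,
    concentrations,
    library: FixtureLibrary | None = None,
    spectrometer: SpectrometerConfig | None = None,
) -> Sample:
    """Assemble a mixture sample from library members.

    ``subset`` is a sequence of lanthanide names and ``concentrations`` the
    matching scaling factors (multipliers of each pair's reference bound
    fraction).  The free-pool relaxation of the mixture follows the
    additive-rate rule with the diamagnetic (La) pair as baseline.
    """
    if library is None:
        library = default_library()
    subset = list(subset)
    concentrations = list(concentrations)
    if len(subset) != len(concentrations):
        raise ValueError("subset and concentrations must have equal length")
    pools = tuple(library[name] for name in subset)
    try:
        dia = library[DIAMAGNETIC_REFERENCE]
    except KeyError:
        # Sub-library without La: the least relaxation-enhanced pair is the
        # closest available stand-in for the diamagnetic baseline.
        dia = max(library, key=lambda p: (p.t2_free, p.t1_free))
    return Sample(
        pools=pools,
        concentrations=tuple(concentrations),
        spectrometer=spectrometer or SpectrometerConfig(),
        t1_dia=dia.t1_free,
        t2_dia=dia.t2_free,
    )


@dataclass(frozen=True)
class NoiseModel:
    """Additive i.i.d. Gaussian noise on the normalized signal."""

    sigma: float
    seed: int

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def generate_noisy_fingerprint(
    sample: Sample,
    protocol: AcquisitionProtocol,
    noise: NoiseModel,
) -> Fingerprint:
    """Noiseless simulation plus seeded Gaussian noise, clipped to
    [0, 1.05]; identical (sample, protocol, noise) inputs give identical
    output."""
    clean = simulate_fingerprint(sample, protocol)
    if noise.sigma == 0:
        return clean
    rng = np.random.default_rng(noise.seed)
    values = clean.values + rng.normal(0.0, noise.sigma, size=len(clean))
    return Fingerprint(values=np.clip(values, 0.0, 1.05), protocol_id=clean.protocol_id)
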