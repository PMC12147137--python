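"""Combinatorial fingerprint dictionary: enumerate mixture hypotheses and
simulate one fingerprint per hypothesis.

A hypothesis is an unordered subset of library lanthanides together with one
concentration scaling factor per member drawn from a grid.  With subset
sizes K and a grid of g factors per member the dictionary holds

    sum_{k in K} C(n, k) * g^k

entries (full Cartesian product of per-member grids).  Entries are generated
in deterministic lexicographic hypothesis order and stored as float32
vectors with a hypothesis index table, either in memory or streamed to an
HDF5 container chunk by chunk.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass

import h5py
import numpy as np

from .core import AcquisitionProtocol, SpectrometerConfig
from .engine import simulate_fingerprint
from .synthetic import FixtureLibrary, generate_sample

__all__ = [
    "MixtureHypothesis",
    "FingerprintDictionary",
    "enumerate_subsets",
    "expected_entry_count",
    "iter_hypotheses",
    "build_dictionary",
]


@dataclass(frozen=True)
class MixtureHypothesis:
    """One candidate mixture: a lanthanide subset plus per-member
    concentration scaling factors (aligned with ``subset``)."""

    subset: tuple[str, ...]
    concentrations: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "subset", tuple(self.subset))
        object.__setattr__(
            self, "concentrations", tuple(float(c) for c in self.concentrations)
        )
        if len(self.subset) != len(self.concentrations):
            raise ValueError("subset and concentrations must have equal length")
        if len(set(self.subset)) != len(self.subset):
            raise ValueError("subset must not contain duplicates")

    def sort_key(self) -> tuple:
        return (self.subset, self.concentrations)

    def label(self) -> str:
        return "+".join(
            f"{n}x{c:g}" for n, c in zip(self.subset, self.concentrations)
        )


def enumerate_subsets(names, sizes) -> list[tuple[str, ...]]:
    """All unordered subsets of the library of each requested size, in
    deterministic lexicographic order (sizes ascending, members sorted)."""
    names = list(names)
    if len(names) == 0:
        raise ValueError("library must be nonempty")
    if len(set(names)) != len(names):
        raise ValueError("library names must be unique")
    sizes = sorted(set(int(s) for s in sizes))
    if not sizes or sizes[0] < 1 or sizes[-1] > len(names):
        raise ValueError(f"sizes must be within 1..{len(names)}, got {sizes}")
    ordered = sorted(names)
    out: list[tuple[str, ...]] = []
    for k in sizes:
        out.extend(itertools.combinations(ordered, k))
    return out


def expected_entry_count(n_names: int, sizes, grid_size: int) -> int:
    """Closed-form entry count sum_k C(n, k) * g^k."""
    return sum(math.comb(n_names, k) * grid_size**k for k in set(sizes))


def iter_hypotheses(names, sizes, grid):
    """Yield hypotheses in deterministic order: subsets lexicographically,
    then the Cartesian product of the grid over subset members."""
    grid = tuple(float(g) for g in grid)
    if len(grid) == 0:
        raise ValueError("grid must be nonempty")
    if any(g <= 0 for g in grid):
        raise ValueError("grid factors must be > 0")
    for subset in enumerate_subsets(names, sizes):
        for conc in itertools.product(grid, repeat=len(subset)):
            yield MixtureHypothesis(subset=subset, concentrations=conc)


class FingerprintDictionary:
    """Simulated fingerprints keyed by mixture hypothesis.

    Vectors are stored row-wise as float32 (adequate for cosine matching;
    7M 40-point entries fit in ~1.1 GB).  ``metadata`` records the
    protocol hash, library hash, sizes and grid so a dictionary can be
    audited and regenerated.
    """

    def __init__(self, vectors: np.ndarray, hypotheses, metadata: dict | None = None):
        vectors = np.asarray(vectors, dtype=np.float32)
        hypotheses = list(hypotheses)
        if vectors.ndim != 2 or vectors.shape[0] != len(hypotheses):
            raise ValueError("need one vector row per hypothesis")
        norms = np.linalg.norm(vectors.astype(np.float64), axis=1)
        if np.any(norms == 0):
            raise ValueError("dictionary vectors must be nonzero")
        self.vectors = vectors
        self.hypotheses = hypotheses
        self.metadata = dict(metadata or {})

    def __len__(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_points(self) -> int:
        return self.vectors.shape[1]

    def iter_chunks(self, chunk_size: int = 8192):
        """Yield (start_index, vector_block) pairs."""
        for start in range(0, len(self), chunk_size):
            yield start, self.vectors[start : start + chunk_size]

    # --- persistence --------------------------------------------------

    def save(self, path) -> None:
        str_dt = h5py.string_dtype()
        vlen_f = h5py.vlen_dtype(np.float64)
        with h5py.File(path, "w") as fh:
            fh.create_dataset(
                "vectors", data=self.vectors, chunks=(min(len(self), 8192), self.n_points)
            )
            fh.create_dataset(
                "subsets",
                data=["+".join(h.subset) for h in self.hypotheses],
                dtype=str_dt,
            )
            conc = fh.create_dataset("concentrations", (len(self),), dtype=vlen_f)
            for i, h in enumerate(self.hypotheses):
                conc[i] = np.asarray(h.concentrations, dtype=np.float64)
            fh.attrs["meta"] = json.dumps(self.metadata)

    @classmethod
    def load(cls, path) -> "FingerprintDictionary":
        with h5py.File(path, "r") as fh:
            vectors = fh["vectors"][...]
            subsets = [s.decode() if isinstance(s, bytes) else s for s in fh["subsets"][...]]
            concentrations = [np.asarray(c, dtype=float) for c in fh["concentrations"][...]]
            metadata = json.loads(fh.attrs.get("meta", "{}"))
        hypotheses = [
            MixtureHypothesis(subset=tuple(s.split("+")), concentrations=tuple(c))
            for s, c in zip(subsets, concentrations)
        ]
        return cls(vectors=vectors, hypotheses=hypotheses, metadata=metadata)


def build_dictionary(
    library: FixtureLibrary,
    sizes,
    grid,
    protocol: AcquisitionProtocol,
    spectrometer: SpectrometerConfig | None = None,
    out: "str | None" = None,
    chunk_size: int = 4096,
    progress: bool = False,
) -> FingerprintDictionary:
    """Simulate one fingerprint per hypothesis.

    Generation is chunked: fingerprints are simulated ``chunk_size``
    hypotheses at a time and, when ``out`` is given, appended to the HDF5
    container as they are produced so peak memory stays bounded by the
    chunk.  The result is reproducible: identical inputs give bit-identical
    vectors in identical order.
    """
    grid = tuple(float(g) for g in grid)
    sizes = sorted(set(int(s) for s in sizes))
    spectrometer = spectrometer or SpectrometerConfig()
    n_total = expected_entry_count(len(library), sizes, len(grid))
    n_points = len(protocol)
    metadata = {
        "protocol_id": protocol.protocol_id(),
        "library_id": library.library_id(),
        "sizes": sizes,
        "grid": list(grid),
        "n_entries": n_total,
        "n_points": n_points,
    }

    hypo_iter = iter_hypotheses(library.names, sizes, grid)
    all_hypotheses: list[MixtureHypothesis] = []

    def simulate_chunk(chunk):
        block = np.empty((len(chunk), n_points), dtype=np.float32)
        for i, hypo in enumerate(chunk):
            sample = generate_sample(
                hypo.subset, hypo.concentrations, library, spectrometer
            )
            block[i] = simulate_fingerprint(sample, protocol).values
        return block

    if out is not None:
        str_dt = h5py.string_dtype()
        vlen_f = h5py.vlen_dtype(np.float64)
        with h5py.File(out, "w") as fh:
            dset = fh.create_dataset(
                "vectors",
                shape=(n_total, n_points),
                dtype=np.float32,
                chunks=(min(n_total, 8192), n_points),
            )
            written = 0
            while True:
                chunk = list(itertools.islice(hypo_iter, chunk_size))
                if not chunk:
                    break
                dset[written : written + len(chunk)] = simulate_chunk(chunk)
                all_hypotheses.extend(chunk)
                written += len(chunk)
                if progress:
                    print(f"  simulated {written}/{n_total} entries", flush=True)
            fh.create_dataset(
                "subsets", data=["+".join(h.subset) for h in all_hypotheses], dtype=str_dt
            )
            conc = fh.create_dataset("concentrations", (n_total,), dtype=vlen_f)
            for i, h in enumerate(all_hypotheses):
                conc[i] = np.asarray(h.concentrations, dtype=np.float64)
            fh.attrs["meta"] = json.dumps(metadata)
        return FingerprintDictionary.load(out)

    blocks = []
    while True:
        chunk = list(itertools.islice(hypo_iter, chunk_size))
        if not chunk:
            break
        blocks.append(simulate_chunk(chunk))
        all_hypotheses.extend(chunk)
        if progress:
            print(f"  simulated {len(all_hypotheses)}/{n_total} entries", flush=True)
    vectors = np.vstack(blocks) if blocks else np.empty((0, n_points), dtype=np.float32)
    return FingerprintDictionary(vectors=vectors, hypotheses=all_hypotheses, metadata=metadata)
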