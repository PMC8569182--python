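"""Synthetic structural connectomes and ground-truth BOLD with planted networks.

The generators stand in for empirical inputs so every downstream stage —
simulation, fitting, network extraction, entropy — can be exercised and
verified against known truth.  Connectomes come from a stochastic block model
with log-normal positive weights (modular, sparse, symmetric, like fiber-count
matrices); ground-truth BOLD is a one-hot mixture of orthonormal sparse
spatial maps recurring with known occupancy probabilities plus Gaussian noise,
band-passed to the conventional 0.01–0.1 Hz BOLD range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .hemodynamics import bandpass_filter

__all__ = [
    "StructuralConnectome",
    "GroundTruthBold",
    "generate_connectome",
    "generate_ground_truth_bold",
]

#: within-module to between-module edge-probability ratio of the block model
MODULARITY_RATIO = 4.0
#: fraction of regions loaded by each planted network map
NETWORK_SPARSITY = 0.2


@dataclass
class StructuralConnectome:
    """Square nonnegative region x region weight matrix with labels.

    Invariants: square, symmetric, zero diagonal, all entries >= 0, and no
    all-zero row (a disconnected region would make its functional row
    undefined downstream).
    """

    weights: np.ndarray
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not self.region_labels:
            self.region_labels = [f"R{i:03d}" for i in range(self.weights.shape[0])]
        self.validate()

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def validate(self) -> None:
        W = self.weights
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("connectome weights must be a square matrix")
        if len(self.region_labels) != W.shape[0]:
            raise ValueError("number of region labels must match matrix size")
        if not np.allclose(W, W.T):
            raise ValueError("connectome must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("connectome diagonal must be zero")
        if np.any(W < 0):
            raise ValueError("connectome weights must be nonnegative")
        if np.any(W.sum(axis=1) == 0):
            raise ValueError("connectome contains an all-zero row")

    # persistence -------------------------------------------------------
    def to_tsv(self, path) -> None:
        from .io import write_connectome_tsv

        write_connectome_tsv(path, self)

    @classmethod
    def from_tsv(cls, path) -> "StructuralConnectome":
        from .io import read_connectome_tsv

        return read_connectome_tsv(path)

    def to_hdf5(self, path, provenance: dict | None = None) -> None:
        from .io import write_connectome_hdf5

        write_connectome_hdf5(path, self, provenance)

    @classmethod
    def from_hdf5(cls, path) -> "StructuralConnectome":
        from .io import read_connectome_hdf5

        return read_connectome_hdf5(path)


@dataclass
class GroundTruthBold:
    """Band-passed BOLD built from planted networks with known occupancy.

    ``networks_true`` is region x component with unit-norm (orthonormal)
    columns; ``occupancy_true`` sums to one; ``states_true`` is the hidden
    one-hot state label per time point.
    """

    bold: np.ndarray
    dt: float
    networks_true: np.ndarray
    occupancy_true: np.ndarray
    seed: int
    states_true: np.ndarray = field(default=None)  # type: ignore[assignment]
    amplitude_true: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.bold = np.asarray(self.bold, dtype=float)
        self.networks_true = np.asarray(self.networks_true, dtype=float)
        self.occupancy_true = np.asarray(self.occupancy_true, dtype=float)
        if abs(self.occupancy_true.sum() - 1.0) > 1e-9:
            raise ValueError("occupancy_true must sum to 1")
        norms = np.linalg.norm(self.networks_true, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("networks_true columns must have unit Euclidean norm")

    @property
    def n_networks(self) -> int:
        return self.networks_true.shape[1]

    def to_tsv(self, path) -> None:
        """TSV (regions x time) plus a YAML sidecar with dt, seed and truth."""
        from .io import write_series_tsv

        write_series_tsv(
            path,
            self.bold,
            sidecar={
                "dt": float(self.dt),
                "seed": int(self.seed),
                "occupancy_true": self.occupancy_true,
                "networks_true": self.networks_true,
            },
        )


def generate_connectome(
    n_regions: int,
    n_modules: int,
    density: float = 0.3,
    weight_scale: float = 0.25,
    seed: int = 0,
) -> StructuralConnectome:
    """Sample a modular, sparse, symmetric connectome (stochastic block model).

    Regions are split into ``n_modules`` contiguous modules; within-module
    edges are ``MODULARITY_RATIO`` times more probable than between-module
    edges while the overall off-diagonal density matches ``density``.  Edge
    weights are log-normal (fiber-count-like) and the matrix is rescaled so
    the mean row sum equals ``weight_scale``, which keeps the total coupling
    a region receives comparable across spatial scales.

    A row that comes out empty (possible at very low density) is repaired by
    inserting one within-module edge, with a warning — an all-zero row is
    never returned.  Identical seeds give bit-identical matrices.
    """
    if not 1 <= n_modules <= n_regions:
        raise ValueError("need 1 <= n_modules <= n_regions")
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    if weight_scale <= 0:
        raise ValueError("weight_scale must be positive")
    rng = np.random.default_rng(seed)

    module = np.repeat(np.arange(n_modules), -(-n_regions // n_modules))[:n_regions]
    same = module[:, None] == module[None, :]
    iu = np.triu_indices(n_regions, k=1)
    same_u = same[iu]
    n_in = int(same_u.sum())
    n_out = same_u.size - n_in
    # solve p_in = ratio * p_out subject to the overall density
    p_out = density * same_u.size / (MODULARITY_RATIO * n_in + n_out) if n_out else density / MODULARITY_RATIO
    p_in = min(1.0, MODULARITY_RATIO * p_out)
    if p_in == 1.0 and n_out:  # ratio capped: put the remaining mass between modules
        p_out = min(1.0, (density * same_u.size - n_in) / n_out)
    probs = np.where(same_u, p_in, p_out)

    present = rng.random(same_u.size) < probs
    weights_u = np.where(present, rng.lognormal(mean=0.0, sigma=1.0, size=same_u.size), 0.0)
    W = np.zeros((n_regions, n_regions))
    W[iu] = weights_u
    W = W + W.T

    empty = np.flatnonzero(W.sum(axis=1) == 0)
    for i in empty:
        candidates = np.flatnonzero((module == module[i]) & (np.arange(n_regions) != i))
        if candidates.size == 0:
            candidates = np.flatnonzero(np.arange(n_regions) != i)
        j = int(rng.choice(candidates))
        w = rng.lognormal(mean=0.0, sigma=1.0)
        W[i, j] = W[j, i] = w
    if empty.size:
        warnings.warn(
            f"density {density} left {empty.size} region(s) unconnected; "
            "inserted one within-module edge each",
            stacklevel=2,
        )

    W *= weight_scale / W.sum(axis=1).mean()
    return StructuralConnectome(weights=W)


def _planted_maps(n_regions: int, n_networks: int, rng: np.random.Generator) -> np.ndarray:
    """Sparse orthonormal spatial maps (region x network).

    Each network loads ~``NETWORK_SPARSITY`` of the regions with positive
    random weights on supports that are disjoint across networks, so the
    columns are orthonormal by construction and ICA separability is
    guaranteed.  Positive loadings are used because the downstream
    point-process events mark upward threshold crossings only and therefore
    cannot represent negative map weights.
    """
    n_loaded = min(max(2, int(round(NETWORK_SPARSITY * n_regions))), n_regions // n_networks)
    if n_loaded < 1:
        raise ValueError("too many networks for this number of regions")
    perm = rng.permutation(n_regions)
    M = np.zeros((n_regions, n_networks))
    for c in range(n_networks):
        support = perm[c * n_loaded : (c + 1) * n_loaded]
        M[support, c] = rng.uniform(0.5, 1.5, size=n_loaded)
    return M / np.linalg.norm(M, axis=0, keepdims=True)


def generate_ground_truth_bold(
    n_regions: int,
    n_networks: int,
    occupancy,
    dt: float = 0.72,
    duration: float = 7200.0,
    snr: float = 10.0,
    seed: int = 0,
) -> GroundTruthBold:
    """Band-limited BOLD in which exactly one planted network is on per sample.

    The hidden state sequence is i.i.d. from ``occupancy``; the clean signal
    is the active network map times a positive per-sample amplitude
    (log-normal around 1, so the planted component structure has full rank
    even though exactly one network is on at a time), Gaussian noise of
    standard deviation ``1 / snr`` relative to the unit baseline amplitude is
    added (``snr=inf`` gives the noiseless mixture), and the result is
    band-passed to 0.01–0.1 Hz.
    """
    occupancy = np.asarray(occupancy, dtype=float)
    if occupancy.size != n_networks:
        raise ValueError("occupancy must have n_networks entries")
    if abs(occupancy.sum() - 1.0) > 1e-9:
        raise ValueError("occupancy must sum to 1 (tolerance 1e-9)")
    if np.any(occupancy < 0):
        raise ValueError("occupancy entries must be nonnegative")
    if n_networks >= n_regions:
        raise ValueError("n_networks must be smaller than n_regions")
    if snr <= 0:
        raise ValueError("snr must be positive")
    n_samples = int(duration / dt)
    if n_samples < 100:
        raise ValueError("duration/dt must give at least 100 samples")

    rng = np.random.default_rng(seed)
    maps = _planted_maps(n_regions, n_networks, rng)
    states = rng.choice(n_networks, size=n_samples, p=occupancy)
    amplitude = rng.lognormal(mean=0.0, sigma=0.5, size=n_samples)
    clean = maps[:, states] * amplitude
    if np.isfinite(snr):
        clean = clean + rng.standard_normal((n_regions, n_samples)) * (1.0 / snr)
    bold = bandpass_filter(clean, dt, 0.01, 0.1)
    return GroundTruthBold(
        bold=bold,
        dt=dt,
        networks_true=maps,
        occupancy_true=occupancy,
        seed=int(seed),
        states_true=states,
        amplitude_true=amplitude,
    )
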