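"""Whole-brain functional-network extraction from point-process events.

A region x time series is reduced to discrete events (upward threshold
crossings of the z-scored signal), the event matrix is z-scored again per
region, the number of latent networks is estimated from the eigenvalues of
the event correlation matrix against the Marchenko–Pastur null, the spatial
networks are unmixed by ICA, and network activity over time is obtained by
projecting event frames onto each network map:

    A[c, b] = (w_c . E_b)^2 = E_b^T (w_c w_c^T) E_b  >= 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "EventMatrix",
    "NetworkSet",
    "ActivityMatrix",
    "point_process_binarize",
    "normalize_events",
    "estimate_n_networks",
    "extract_networks",
    "project_activity",
]


@dataclass
class EventMatrix:
    """Region x time event matrix.

    In raw form entries are binary {0, 1}; after :func:`normalize_events`
    every retained region has zero mean and unit variance, and
    ``excluded_regions`` lists original row indices dropped because their
    event train was constant.  ``region_indices`` maps the rows of ``events``
    back to the original region numbering.
    """

    events: np.ndarray
    raw: bool
    threshold_sd: float
    normalization: str = "none"
    excluded_regions: list[int] = field(default_factory=list)
    region_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if self.region_indices is None:
            self.region_indices = np.arange(self.events.shape[0])
        if self.raw:
            vals = np.unique(self.events)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ValueError("raw event matrix must be binary")

    @property
    def n_regions(self) -> int:
        return self.events.shape[0]

    @property
    def n_samples(self) -> int:
        return self.events.shape[1]


@dataclass
class NetworkSet:
    """Region x component network matrix W with unit-norm columns."""

    W: np.ndarray
    n_networks: int
    seed: int

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape[1] != self.n_networks:
            raise ValueError("W must have n_networks columns")
        if not np.allclose(np.linalg.norm(self.W, axis=0), 1.0, atol=1e-9):
            raise ValueError("columns of W must have unit Euclidean norm")


@dataclass
class ActivityMatrix:
    """Component x time nonnegative network activity (quadratic projection)."""

    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if np.any(self.A < 0):
            raise ValueError("activity matrix must be nonnegative")

    @property
    def n_networks(self) -> int:
        return self.A.shape[0]


def point_process_binarize(
    ts: np.ndarray,
    threshold_sd: float = 1.0,
    mode: str = "crossing",
) -> EventMatrix:
    """Reduce each region's signal to point-process events.

    The signal is z-scored per region; in the default ``crossing`` mode an
    event is marked at samples where the z-scored trace crosses
    ``threshold_sd`` from below (the first sample counts if already above).
    ``mode='level'`` instead marks every supra-threshold sample.
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    sd = ts.std(axis=1)
    bad = np.flatnonzero(sd < 1e-14)
    if bad.size:
        raise ValueError(f"zero-variance region(s) {bad.tolist()} cannot be binarized")
    z = (ts - ts.mean(axis=1, keepdims=True)) / sd[:, None]
    above = z > threshold_sd
    if mode == "crossing":
        events = above.copy()
        events[:, 1:] &= ~above[:, :-1]
    elif mode == "level":
        events = above
    else:
        raise ValueError("mode must be 'crossing' or 'level'")
    return EventMatrix(events=events.astype(float), raw=True, threshold_sd=threshold_sd)


def normalize_events(event_matrix: EventMatrix) -> EventMatrix:
    """z-score the raw event matrix per region (zero mean, unit variance).

    Regions whose event train is constant (no event, or all events) carry no
    signal and are excluded with a warning; the exclusion is recorded so that
    downstream network and activity matrices stay consistent.
    """
    if not event_matrix.raw:
        raise ValueError("normalize_events expects a raw (binary) event matrix")
    E = event_matrix.events
    sd = E.std(axis=1)
    keep = sd > 0
    excluded = np.flatnonzero(~keep)
    if excluded.size:
        warnings.warn(
            f"excluding {excluded.size} region(s) with constant event trains: "
            f"{excluded.tolist()}",
            stacklevel=2,
        )
    if not keep.any():
        raise ValueError("every region has a constant event train")
    kept = E[keep]
    Z = (kept - kept.mean(axis=1, keepdims=True)) / kept.std(axis=1, keepdims=True)
    return EventMatrix(
        events=Z,
        raw=False,
        threshold_sd=event_matrix.threshold_sd,
        normalization="zscore",
        excluded_regions=excluded.tolist(),
        region_indices=event_matrix.region_indices[keep],
    )


def estimate_n_networks(E_norm, enforce_min: bool = True) -> int:
    """Count significant components against the Marchenko–Pastur null.

    The eigenvalues of the region x region correlation matrix of the
    normalized event matrix are compared with the Marchenko–Pastur upper edge
    ``(1 + sqrt(n_regions / n_time))**2`` for unit-variance noise; eigenvalues
    above the edge mark non-noise networks.  With ``enforce_min`` a raw count
    of zero is lifted to 1 (with a warning) so the pipeline stays runnable.
    """
    E = np.asarray(getattr(E_norm, "events", E_norm), dtype=float)
    n, T = E.shape
    if n < 10 or T < 10:
        raise ValueError("need at least 10 regions and 10 time points")
    corr = np.corrcoef(E)
    if not np.all(np.isfinite(corr)):
        raise ValueError("degenerate event matrix (constant rows?)")
    edge = (1.0 + np.sqrt(n / T)) ** 2
    count = int((np.linalg.eigvalsh(corr) > edge).sum())
    if count == 0 and enforce_min:
        warnings.warn(
            "no eigenvalue exceeded the Marchenko–Pastur edge; forcing one component",
            stacklevel=2,
        )
        return 1
    return count


def extract_networks(E_norm, n_networks: int, seed: int = 0) -> NetworkSet:
    """Unmix spatial networks from the normalized event matrix by ICA.

    FastICA (logcosh contrast, symmetric/parallel updates, PCA whitening to
    ``n_networks`` dimensions) is run with time points as samples, so the estimated sources
    are the network time courses and the columns of the mixing matrix are the
    spatial maps W (region x component).  Columns of W are scaled to unit
    Euclidean norm and signed so each column's largest-magnitude loading is
    positive; the same seed gives an identical W.  On non-convergence three
    alternate seeds are tried before failing.
    """
    E = np.asarray(getattr(E_norm, "events", E_norm), dtype=float)
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    if n_networks > min(E.shape):
        raise ValueError("n_networks cannot exceed the rank bound min(n_regions, n_time)")
    last_error: Exception | None = None
    for ica_seed in (seed, seed + 101, seed + 202, seed + 303):
        ica = FastICA(
            n_components=n_networks,
            algorithm="parallel",
            fun="logcosh",
            whiten="unit-variance",
            max_iter=1000,
            tol=1e-6,
            random_state=ica_seed & 0x7FFFFFFF,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                ica.fit_transform(E.T)  # samples = time points
            except ConvergenceWarning as err:  # retry with an alternate seed
                last_error = err
                continue
        W = np.asarray(ica.mixing_, dtype=float)  # regions x components
        W = W / np.linalg.norm(W, axis=0, keepdims=True)
        peak = np.abs(W).argmax(axis=0)
        W = W * np.sign(W[peak, np.arange(n_networks)])
        return NetworkSet(W=W, n_networks=n_networks, seed=int(seed))
    raise RuntimeError(
        f"FastICA failed to converge with seed {seed} and 3 alternates"
    ) from last_error


def project_activity(event_matrix, networks: NetworkSet) -> ActivityMatrix:
    """Track network activity over time: A[c, b] = (w_c . E_b)^2.

    Equivalent to the quadratic form E_b^T (w_c w_c^T) E_b with the rank-one
    projection built from each network map, so the result is nonnegative and
    invariant to the sign of w_c.
    """
    E = np.asarray(getattr(event_matrix, "events", event_matrix), dtype=float)
    if E.shape[0] != networks.W.shape[0]:
        raise ValueError(
            f"event matrix has {E.shape[0]} regions but networks have "
            f"{networks.W.shape[0]}"
        )
    return ActivityMatrix(A=(networks.W.T @ E) ** 2)
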