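"""Dynamical statistics for model fitting and the global-coupling grid search.

Three statistics summarise resting-state BOLD dynamics:

* metastability — the standard deviation over time of the Kuramoto order
  parameter R(t) = |mean_k exp(i phi_k(t))|, indexing fluctuations of global
  phase synchrony;
* the phase-consistency distribution — similarities (Pearson correlations of
  upper triangles) between instantaneous phase-coherence matrices across time
  pairs;
* functional connectivity dynamics (FCD) — correlations between windowed FC
  matrices (80 s windows, 40 s steps), summarised by their off-diagonal
  value distribution.

The global coupling G is selected on a grid by matching these statistics to
target (empirical or synthetic-reference) values: the metastability by its
absolute difference, the two distributions by Kolmogorov–Smirnov distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import detrend, hilbert
from scipy.stats import ks_2samp

from .dmf import PopulationParams, calibrate_fic, simulate_dmf
from .hemodynamics import HemoParams, balloon_windkessel, bandpass_filter

__all__ = [
    "PhaseSeries",
    "FitResult",
    "TargetStats",
    "instantaneous_phase",
    "kuramoto_order",
    "metastability",
    "phase_coherence_matrix",
    "phase_consistency_distribution",
    "phase_consistency_from_phases",
    "fc_matrix",
    "fcd_distribution",
    "ks_distance",
    "compute_target_stats",
    "fit_G",
]


@dataclass
class PhaseSeries:
    """Region x time instantaneous phases (radians, in (-pi, pi])."""

    phases: np.ndarray
    dt: float


@dataclass
class TargetStats:
    """Reference statistics a simulation is fitted against."""

    metastability: float
    phase_sample: np.ndarray
    fcd_sample: np.ndarray

    def to_yaml(self, path) -> None:
        from .io import write_yaml

        write_yaml(
            path,
            {
                "metastability": float(self.metastability),
                "phase_sample": self.phase_sample,
                "fcd_sample": self.fcd_sample,
            },
        )

    @classmethod
    def from_yaml(cls, path) -> "TargetStats":
        from .io import read_yaml

        d = read_yaml(path)
        return cls(
            metastability=float(d["metastability"]),
            phase_sample=np.asarray(d["phase_sample"], dtype=float),
            fcd_sample=np.asarray(d["fcd_sample"], dtype=float),
        )


@dataclass
class FitResult:
    """Grid-search curves and the selected global coupling.

    ``excluded`` flags grid points whose FIC calibration did not converge;
    they are reported but never selected.
    """

    G_grid: np.ndarray
    metastability_diff: np.ndarray
    ks_phase: np.ndarray
    ks_fcd: np.ndarray
    G_opt: float
    selection_rule: str
    excluded: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.G_grid = np.asarray(self.G_grid, dtype=float)
        if self.excluded is None:
            self.excluded = np.zeros(self.G_grid.size, dtype=bool)
        for name in ("metastability_diff", "ks_phase", "ks_fcd"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size != self.G_grid.size:
                raise ValueError(f"{name} must match the grid length")
            setattr(self, name, arr)
        if self.G_opt not in self.G_grid:
            raise ValueError("G_opt must be a grid value")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "G": self.G_grid,
                "metastability_diff": self.metastability_diff,
                "ks_phase": self.ks_phase,
                "ks_fcd": self.ks_fcd,
                "excluded": self.excluded,
            }
        )


def instantaneous_phase(ts: np.ndarray, dt: float) -> PhaseSeries:
    """Per-region instantaneous phase: linear detrend then analytic-signal angle.

    Input should already be band-passed.  A region with (numerically) zero
    analytic amplitude cannot define a phase and is rejected by index.
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    detrended = detrend(ts, axis=1)
    sd = detrended.std(axis=1)
    bad = np.flatnonzero(sd < 1e-12)
    if bad.size:
        raise ValueError(f"constant region(s) {bad.tolist()} have no defined phase")
    return PhaseSeries(phases=np.angle(hilbert(detrended, axis=1)), dt=dt)


def kuramoto_order(phases_at_t: np.ndarray) -> float:
    """Modulus of the mean unit phasor: 1 = full synchrony, 0 = full desynchrony."""
    phases_at_t = np.asarray(phases_at_t, dtype=float)
    if phases_at_t.size == 0:
        raise ValueError("phase vector must be nonempty")
    return float(np.abs(np.exp(1j * phases_at_t).mean()))


def _order_series(phases: np.ndarray) -> np.ndarray:
    return np.abs(np.exp(1j * phases).mean(axis=0))


def metastability(ts: np.ndarray, dt: float) -> float:
    """Population standard deviation over time of the Kuramoto order parameter."""
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    if ts.shape[1] < 2:
        raise ValueError("need at least 2 time points")
    phases = instantaneous_phase(ts, dt).phases
    return float(np.std(_order_series(phases)))


def phase_coherence_matrix(phases_at_t: np.ndarray) -> np.ndarray:
    """Pairwise phase coherence cos(phi_j - phi_k): symmetric, unit diagonal."""
    phi = np.asarray(phases_at_t, dtype=float)
    if phi.size < 2:
        raise ValueError("need at least 2 regions")
    c, s = np.cos(phi), np.sin(phi)
    return np.outer(c, c) + np.outer(s, s)


def phase_consistency_distribution(
    ts: np.ndarray,
    dt: float,
    max_pairs: int = 2_000_000,
    seed: int = 0,
) -> np.ndarray:
    """Similarities of phase-coherence matrices across time pairs.

    For each pair (t1, t2) the similarity is the Pearson correlation of the
    strictly-upper triangles of the two coherence matrices.  All unordered
    pairs are used up to 2,000 time points; beyond that a seeded uniform
    subsample of ``max_pairs`` pairs is drawn.  Time points whose coherence
    triangle is constant carry no correlation and are skipped (counted in a
    warning).
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    if ts.shape[1] < 3:
        raise ValueError("need at least 3 time points")
    phases = instantaneous_phase(ts, dt).phases
    return phase_consistency_from_phases(phases, max_pairs=max_pairs, seed=seed)


def phase_consistency_from_phases(
    phases: np.ndarray,
    max_pairs: int = 2_000_000,
    seed: int = 0,
) -> np.ndarray:
    """Coherence-matrix similarity sample from precomputed phases (radians)."""
    phases = np.atleast_2d(np.asarray(phases, dtype=float))
    n, T = phases.shape
    c, s = np.cos(phases), np.sin(phases)
    ju, ku = np.triu_indices(n, k=1)
    V = (c[ju] * c[ku] + s[ju] * s[ku]).T  # time x pairs-of-regions
    mu = V.mean(axis=1, keepdims=True)
    sd = V.std(axis=1)
    good = sd > 1e-12
    n_bad = int((~good).sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} time point(s) had a constant coherence triangle; "
            "pairs involving them were skipped",
            stacklevel=2,
        )
    Z = (V[good] - mu[good]) / sd[good, None]
    Tg, M = Z.shape
    if Tg < 2:
        raise ValueError("fewer than 2 usable time points")
    if Tg * (Tg - 1) // 2 <= max_pairs and Tg <= 2000:
        R = (Z @ Z.T) / M
        return R[np.triu_indices(Tg, k=1)]
    rng = np.random.default_rng(seed)
    i = rng.integers(0, Tg, size=max_pairs)
    j = rng.integers(0, Tg - 1, size=max_pairs)
    j = np.where(j >= i, j + 1, j)  # j != i, uniform over off-diagonal pairs
    return np.einsum("ij,ij->i", Z[i], Z[j]) / M


def fc_matrix(bold_window: np.ndarray) -> np.ndarray:
    """Pearson-correlation functional connectivity of a region x time window."""
    X = np.atleast_2d(np.asarray(bold_window, dtype=float))
    if X.shape[1] < 3:
        raise ValueError("window must contain at least 3 samples")
    sd = X.std(axis=1)
    bad = np.flatnonzero(sd < 1e-14)
    if bad.size:
        raise ValueError(f"zero-variance region(s) {bad.tolist()} in FC window")
    fc = np.corrcoef(X)
    np.fill_diagonal(fc, 1.0)
    return fc


def fcd_distribution(
    bold: np.ndarray,
    dt: float,
    window_s: float = 80.0,
    step_s: float = 40.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Functional connectivity dynamics matrix and its upper-triangle sample.

    The series is split into sliding windows of ``window_s`` seconds advancing
    by ``step_s`` (80 s windows overlapping by 40 s by default; the trailing
    partial window is dropped), FC is computed per window, and entry (a, b) of
    the FCD matrix is the Pearson correlation of the strictly-upper triangles
    of FC(a) and FC(b).  Returns ``(fcd_matrix, upper_triangle_sample)``.
    """
    X = np.atleast_2d(np.asarray(getattr(bold, "bold", bold), dtype=float))
    n, T = X.shape
    w = int(round(window_s / dt))
    s = int(round(step_s / dt))
    if w < 3 or s < 1:
        raise ValueError("window and step must span at least a few samples")
    n_win = (T - w) // s + 1
    if n_win < 2:
        raise ValueError(
            f"series of {T * dt:.0f} s supports {max(n_win, 0)} window(s); need >= 2"
        )
    iu = np.triu_indices(n, k=1)
    vecs = np.empty((n_win, iu[0].size))
    for a in range(n_win):
        vecs[a] = fc_matrix(X[:, a * s : a * s + w])[iu]
    fcd = np.corrcoef(vecs)
    np.fill_diagonal(fcd, 1.0)
    return fcd, fcd[np.triu_indices(n_win, k=1)]


def ks_distance(sample_a, sample_b) -> float:
    """Kolmogorov–Smirnov distance: sup-norm between the two empirical CDFs."""
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    return float(ks_2samp(a, b).statistic)


def compute_target_stats(
    bold: np.ndarray,
    dt: float,
    window_s: float = 80.0,
    step_s: float = 40.0,
    max_pairs: int = 2_000_000,
    seed: int = 0,
) -> TargetStats:
    """All three fitting statistics of a (band-passed) BOLD series."""
    X = np.atleast_2d(np.asarray(getattr(bold, "bold", bold), dtype=float))
    meta = metastability(X, dt)
    phase = phase_consistency_distribution(X, dt, max_pairs=max_pairs, seed=seed)
    _, fcd = fcd_distribution(X, dt, window_s=window_s, step_s=step_s)
    return TargetStats(metastability=meta, phase_sample=phase, fcd_sample=fcd)


def _select_g(
    G_grid: np.ndarray,
    dmeta: np.ndarray,
    ksp: np.ndarray,
    ksf: np.ndarray,
    excluded: np.ndarray,
    rule: str,
) -> tuple[float, str]:
    valid = ~excluded
    if not valid.any():
        raise RuntimeError("FIC calibration failed on every grid point")

    def norm(x):
        x = np.where(valid, x, np.nan)
        lo, hi = np.nanmin(x), np.nanmax(x)
        return np.zeros_like(x) if hi - lo < 1e-15 else (x - lo) / (hi - lo)

    if rule == "normalized_sum":
        score = norm(dmeta) + norm(ksp) + norm(ksf)
        score[~valid] = np.inf
        return float(G_grid[int(np.argmin(score))]), rule
    if rule != "fcd_gated":
        raise ValueError(f"unknown selection rule {rule!r}")
    # grid subset where metastability and phase agreement are within 110% of
    # their own minima; FCD-KS breaks the tie (the sharpest constraint)
    dm = np.where(valid, dmeta, np.inf)
    kp = np.where(valid, ksp, np.inf)
    gate = valid & (dm <= 1.1 * dm.min() + 1e-15) & (kp <= 1.1 * kp.min() + 1e-15)
    if not gate.any():
        return _select_g(G_grid, dmeta, ksp, ksf, excluded, "normalized_sum")
    kf = np.where(gate, ksf, np.inf)
    return float(G_grid[int(np.argmin(kf))]), rule


def fit_G(
    connectome,
    params: PopulationParams,
    target_stats: TargetStats,
    G_grid,
    n_repeats: int = 2,
    seed: int = 0,
    duration: float = 370.0,
    dt: float = 1e-4,
    record_dt: float = 1e-3,
    out_dt: float = 0.72,
    transient: float = 10.0,
    hemo: HemoParams | None = None,
    selection_rule: str = "fcd_gated",
    window_s: float = 80.0,
    step_s: float = 40.0,
    progress: bool = False,
) -> FitResult:
    """Select the global coupling G by grid search against target statistics.

    For every G on the grid the feedback inhibition is recalibrated, the model
    is simulated ``n_repeats`` times for ``duration`` seconds, the simulated
    BOLD (Balloon–Windkessel at ``out_dt``, transient dropped, band-passed
    0.01–0.1 Hz) is summarised by the three statistics, and the comparisons
    |d metastability|, KS_phase and KS_fcd are averaged over repeats.  Grid
    points whose calibration did not converge are flagged and excluded from
    the selection.  The default rule restricts the grid to points whose
    metastability and phase agreement are within 110% of their minima and
    takes the argmin of KS_fcd there; ``selection_rule='normalized_sum'``
    minimises the sum of min–max-normalised curves instead.
    """
    C = np.asarray(getattr(connectome, "weights", connectome), dtype=float)
    G_grid = np.asarray(G_grid, dtype=float)
    rng = np.random.default_rng(seed)
    dmeta = np.empty(G_grid.size)
    ksp = np.empty(G_grid.size)
    ksf = np.empty(G_grid.size)
    excluded = np.zeros(G_grid.size, dtype=bool)
    drop = int(round(transient / out_dt))
    for gi, G in enumerate(G_grid):
        cal_seed = int(rng.integers(0, 2**31 - 1))
        rep_seeds = [int(rng.integers(0, 2**31 - 1)) for _ in range(n_repeats)]
        cal = calibrate_fic(C, params, G=float(G), seed=cal_seed, dt=dt)
        if not cal.converged:
            excluded[gi] = True
            dmeta[gi] = ksp[gi] = ksf[gi] = np.nan
            warnings.warn(f"FIC did not converge at G={G:g}; grid point excluded", stacklevel=2)
            continue
        d_acc, p_acc, f_acc = [], [], []
        for rep_seed in rep_seeds:
            series = simulate_dmf(C, params, cal, duration=duration, dt=dt,
                                  seed=rep_seed, record_dt=record_dt)
            bts = balloon_windkessel(series.r_E, series.dt, hemo, out_dt=out_dt)
            sim = bandpass_filter(bts.bold[:, drop:], out_dt)
            stats = compute_target_stats(sim, out_dt, window_s=window_s,
                                         step_s=step_s, seed=rep_seed)
            d_acc.append(abs(stats.metastability - target_stats.metastability))
            p_acc.append(ks_distance(stats.phase_sample, target_stats.phase_sample))
            f_acc.append(ks_distance(stats.fcd_sample, target_stats.fcd_sample))
        dmeta[gi] = np.mean(d_acc)
        ksp[gi] = np.mean(p_acc)
        ksf[gi] = np.mean(f_acc)
        if progress:
            print(f"G={G:6.3f}  dmeta={dmeta[gi]:.4f}  ks_phase={ksp[gi]:.4f}  ks_fcd={ksf[gi]:.4f}")
    G_opt, rule = _select_g(G_grid, dmeta, ksp, ksf, excluded, selection_rule)
    return FitResult(
        G_grid=G_grid,
        metastability_diff=dmeta,
        ks_phase=ksp,
        ks_fcd=ksf,
        G_opt=G_opt,
        selection_rule=rule,
        excluded=excluded,
    )
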