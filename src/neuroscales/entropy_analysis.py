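"""Occupancy entropy of functional-network transitions across scales.

The activity matrix is converted to an occupancy distribution
p(c) = sum_b A[c, b] / sum_{c,b} A[c, b] — the share of total activity each
network accounts for — and summarised by the Shannon entropy
H = -sum_c p(c) log p(c) (natural log, 0 log 0 := 0), normalised by
log(n_networks) so that scales with different network counts are comparable
(H_norm in [0, 1]).  A sweep runs the full event/ICA/projection pipeline over
a grid of spatial scales x temporal bins with replicates, and scales are
compared pairwise by rank tests with Benjamini–Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, mannwhitneyu, wilcoxon

from .dmf import bin_timeseries
from .extraction import (
    estimate_n_networks,
    extract_networks,
    normalize_events,
    point_process_binarize,
    project_activity,
)

__all__ = [
    "OccupancyDistribution",
    "EntropyResult",
    "ScaleSweepTable",
    "occupancy",
    "entropy",
    "normalized_entropy",
    "series_entropy",
    "sweep_scales",
    "compare_scales",
    "find_optimal_scale",
    "plot_sweep",
]


@dataclass
class OccupancyDistribution:
    """Probability that each functional network accounts for total activity."""

    p: np.ndarray
    n_networks: int

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.size != self.n_networks:
            raise ValueError("p must have n_networks entries")
        if np.any(self.p < 0) or abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("p must be a probability vector (sum 1, tolerance 1e-9)")


@dataclass
class EntropyResult:
    """Entropy of one pipeline cell (spatial scale x temporal scale x replicate)."""

    H_raw: float
    H_norm: float
    spatial_scale: int
    temporal_scale_ms: float | None
    replicate: int = 0
    n_networks: int = 0


@dataclass
class ScaleSweepTable:
    """Tidy per-cell-and-replicate entropy table plus pairwise scale tests.

    ``table`` has one row per (spatial_scale, temporal_scale_ms, replicate)
    with columns H_raw, H_norm, n_networks, valid, seed; ``tests`` is filled
    by :func:`compare_scales`.
    """

    table: pd.DataFrame
    tests: pd.DataFrame | None = None
    master_seed: int | None = None

    def summary(self) -> pd.DataFrame:
        """Per-cell mean/SD of H_norm over valid replicates."""
        valid = self.table[self.table["valid"]]
        out = (
            valid.groupby(["spatial_scale", "temporal_scale_ms"], dropna=False)["H_norm"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )
        return out.rename(columns={"mean": "H_norm_mean", "std": "H_norm_sd", "count": "n_replicates"})


def occupancy(A) -> OccupancyDistribution:
    """Share of total activity per network: p(c) = sum_b A[c,b] / sum_{c,b} A[c,b]."""
    arr = np.asarray(getattr(A, "A", A), dtype=float)
    if np.any(arr < 0):
        raise ValueError("activity matrix must be nonnegative")
    row = arr.sum(axis=1) if arr.ndim == 2 else arr
    total = row.sum()
    if total <= 0:
        raise ValueError("activity matrix is all zero; occupancy undefined")
    return OccupancyDistribution(p=row / total, n_networks=row.size)


def entropy(p) -> float:
    """Shannon entropy -sum p log p in nats, with 0 log 0 := 0."""
    vec = np.asarray(getattr(p, "p", p), dtype=float)
    nz = vec[vec > 0]
    return float(-(nz * np.log(nz)).sum())


def normalized_entropy(p) -> float:
    """Entropy divided by log(n_networks): 1 for uniform, 0 for degenerate."""
    vec = np.asarray(getattr(p, "p", p), dtype=float)
    if vec.size < 2:
        raise ValueError(
            "normalized entropy is undefined for a single network; "
            "this scale cannot be compared"
        )
    return entropy(vec) / np.log(vec.size)


def series_entropy(
    ts: np.ndarray,
    seed: int = 0,
    threshold_sd: float = 1.0,
    n_networks: int | None = None,
    min_networks: int = 2,
    project: str = "raw",
) -> EntropyResult:
    """Run binarize -> normalize -> count -> ICA -> project -> entropy on a series.

    ``n_networks=None`` estimates the count from the Marchenko–Pastur edge.
    The networks are always unmixed from the normalized event matrix; the
    activity projection uses the binarized event matrix by default
    (``project='raw'``; ``'normalized'`` projects the z-scored one instead).
    Raises ``ValueError`` if fewer than ``min_networks`` networks are found
    (the cell is then not comparable across scales).
    """
    raw = point_process_binarize(ts, threshold_sd=threshold_sd)
    E = normalize_events(raw)
    k = estimate_n_networks(E, enforce_min=False) if n_networks is None else n_networks
    if k < min_networks:
        raise ValueError(f"found {k} network(s); need at least {min_networks}")
    nets = extract_networks(E, k, seed=seed)
    if project == "raw":
        events = raw.events[E.region_indices]
    elif project == "normalized":
        events = E.events
    else:
        raise ValueError("project must be 'raw' or 'normalized'")
    occ = occupancy(project_activity(events, nets))
    return EntropyResult(
        H_raw=entropy(occ),
        H_norm=normalized_entropy(occ),
        spatial_scale=ts.shape[0],
        temporal_scale_ms=None,
        n_networks=k,
    )


def sweep_scales(
    series_provider,
    spatial_scales,
    temporal_bins_ms,
    n_replicates: int = 1,
    seed: int = 0,
    threshold_sd: float = 1.0,
) -> ScaleSweepTable:
    """Entropy of network transitions over spatial scales x temporal bins.

    ``series_provider(spatial_scale, replicate, seed) -> (ts, dt_s)`` supplies
    one region x time series per (scale, replicate) — typically a seeded
    simulation, one replicate standing for one subject group.  Each series is
    binned at every temporal scale (``None`` keeps the native sampling, the
    empirical-style branch) and pushed through the event/ICA/projection
    pipeline.  Cells where fewer than two networks are found are marked
    invalid and reported, not silently dropped.  The same master seed
    reproduces the identical table.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for scale in spatial_scales:
        for rep in range(n_replicates):
            series_seed = int(rng.integers(0, 2**31 - 1))
            ts, dt = series_provider(scale, rep, series_seed)
            for bin_ms in temporal_bins_ms:
                cell_seed = int(rng.integers(0, 2**31 - 1))
                row = {
                    "spatial_scale": int(scale),
                    "temporal_scale_ms": np.nan if bin_ms is None else float(bin_ms),
                    "replicate": rep,
                    "seed": series_seed,
                }
                try:
                    binned = ts if bin_ms is None else bin_timeseries(ts, dt, bin_ms)
                    res = series_entropy(binned, seed=cell_seed, threshold_sd=threshold_sd)
                    row.update(
                        H_raw=res.H_raw,
                        H_norm=res.H_norm,
                        n_networks=res.n_networks,
                        valid=True,
                        reason="",
                    )
                except (ValueError, RuntimeError) as err:
                    row.update(H_raw=np.nan, H_norm=np.nan, n_networks=0,
                               valid=False, reason=str(err))
                    warnings.warn(
                        f"cell (scale={scale}, bin={bin_ms}, rep={rep}) invalid: {err}",
                        stacklevel=2,
                    )
                rows.append(row)
    return ScaleSweepTable(table=pd.DataFrame(rows), master_seed=seed)


def compare_scales(
    sweep: ScaleSweepTable,
    min_replicates: int = 5,
    flavor: str = "rank-sum",
) -> pd.DataFrame:
    """Pairwise spatial-scale comparison of H_norm with FDR correction.

    Within each temporal scale, every pair of spatial scales with at least
    ``min_replicates`` valid replicates is compared by a two-sided rank test
    (Mann–Whitney rank-sum for independent replicates; ``flavor='signed-rank'``
    for replicates paired by seed) and the p-values are Benjamini–Hochberg
    adjusted across all pairs.  Pairs with too few replicates are reported
    with a reason instead of a p-value.
    """
    df = sweep.table
    rows = []
    for t_scale, group in df.groupby("temporal_scale_ms", dropna=False):
        scales = sorted(group["spatial_scale"].unique())
        for i, a in enumerate(scales):
            for b in scales[i + 1 :]:
                xa = group.query("spatial_scale == @a and valid")["H_norm"].to_numpy()
                xb = group.query("spatial_scale == @b and valid")["H_norm"].to_numpy()
                row = {"temporal_scale_ms": t_scale, "scale_a": a, "scale_b": b}
                if min(xa.size, xb.size) < min_replicates:
                    row.update(statistic=np.nan, p_raw=np.nan, p_adj=np.nan,
                               skipped=f"fewer than {min_replicates} valid replicates")
                else:
                    if flavor == "rank-sum":
                        stat, p = mannwhitneyu(xa, xb, alternative="two-sided")
                    elif flavor == "signed-rank":
                        stat, p = wilcoxon(xa, xb, alternative="two-sided")
                    else:
                        raise ValueError("flavor must be 'rank-sum' or 'signed-rank'")
                    row.update(statistic=float(stat), p_raw=float(p), p_adj=np.nan,
                               skipped="")
                rows.append(row)
    tests = pd.DataFrame(rows)
    if len(tests):
        mask = tests["p_raw"].notna()
        if mask.any():
            tests.loc[mask, "p_adj"] = false_discovery_control(
                tests.loc[mask, "p_raw"].to_numpy(), method="bh"
            )
    sweep.tests = tests
    return tests


def find_optimal_scale(sweep: ScaleSweepTable) -> tuple[int, float | None]:
    """Cell with maximal mean H_norm; ties go to the smaller scales.

    Returns ``(spatial_scale, temporal_scale_ms)`` (``None`` for the native
    temporal scale).  Exact ties are broken toward the smaller spatial scale,
    then the smaller temporal bin (parsimony), with a warning.
    """
    summary = sweep.summary()
    if summary.empty:
        raise ValueError("no valid cells in the sweep table")
    best = summary["H_norm_mean"].max()
    ties = summary[summary["H_norm_mean"] == best].sort_values(
        ["spatial_scale", "temporal_scale_ms"], na_position="first"
    )
    if len(ties) > 1:
        warnings.warn(
            f"{len(ties)} cells tie for maximal H_norm; "
            "returning the smallest (spatial, temporal) cell",
            stacklevel=2,
        )
    top = ties.iloc[0]
    t = top["temporal_scale_ms"]
    return int(top["spatial_scale"]), (None if pd.isna(t) else float(t))


def plot_sweep(sweep: ScaleSweepTable, path=None):
    """Heatmap of mean H_norm over spatial x temporal scales (optional export)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = sweep.summary()
    pivot = summary.pivot(index="spatial_scale", columns="temporal_scale_ms",
                          values="H_norm_mean")
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", origin="lower", cmap="viridis")
    ax.set_xticks(range(pivot.shape[1]), [f"{c:g}" for c in pivot.columns])
    ax.set_yticks(range(pivot.shape[0]), [str(i) for i in pivot.index])
    ax.set_xlabel("temporal scale (ms)")
    ax.set_ylabel("spatial scale (regions)")
    fig.colorbar(im, ax=ax, label="mean normalized entropy")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
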