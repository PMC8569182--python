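"""Model/Results interface tying the simulation and fitting stages together.

``WholeBrainModel`` holds a structural connectome plus population and
hemodynamic parameters; ``fit`` grid-searches the global coupling G against
target dynamical statistics and returns a ``WholeBrainFitResults`` carrying
the agreement curves, the selected coupling and a text ``summary()``.
Simulation at the fitted (or any) coupling hangs off both objects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dmf import (
    CouplingConfig,
    NeuronalTimeSeries,
    PopulationParams,
    calibrate_fic,
    simulate_dmf,
)
from .hemodynamics import BoldTimeSeries, HemoParams, balloon_windkessel, bandpass_filter
from .metrics import FitResult, TargetStats, fit_G
from .synthetic import StructuralConnectome

__all__ = ["WholeBrainModel", "WholeBrainFitResults"]


class WholeBrainModel:
    """Dynamic mean-field whole-brain model on a structural connectome.

    Parameters
    ----------
    connectome : StructuralConnectome or square array
        Nonnegative symmetric coupling weights.
    params : PopulationParams, optional
        Population parameters (printed defaults if omitted).
    hemo : HemoParams, optional
        Balloon–Windkessel constants (standard defaults if omitted).

    Examples
    --------
    >>> sc = generate_connectome(30, 3, seed=1)
    >>> model = WholeBrainModel(sc)
    >>> bold = model.simulate_bold(G=1.5, duration=120.0, seed=0)
    """

    def __init__(self, connectome, params: PopulationParams | None = None,
                 hemo: HemoParams | None = None):
        if not isinstance(connectome, StructuralConnectome):
            connectome = StructuralConnectome(weights=np.asarray(connectome, dtype=float))
        self.connectome = connectome
        self.params = params if params is not None else PopulationParams()
        self.hemo = hemo if hemo is not None else HemoParams()
        self._calibrations: dict[tuple[float, int], CouplingConfig] = {}

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "WholeBrainModel":
        """Build from a square DataFrame whose columns name the regions."""
        sc = StructuralConnectome(
            weights=df.to_numpy(dtype=float),
            region_labels=[str(c) for c in df.columns],
        )
        return cls(sc, **kwargs)

    @property
    def n_regions(self) -> int:
        return self.connectome.n_regions

    def calibrate(self, G: float, seed: int = 0, **kwargs) -> CouplingConfig:
        """Feedback-inhibition calibration at coupling G (cached per (G, seed))."""
        key = (float(G), int(seed))
        if key not in self._calibrations:
            self._calibrations[key] = calibrate_fic(
                self.connectome, self.params, G=float(G), seed=seed, **kwargs
            )
        return self._calibrations[key]

    def simulate(
        self,
        G: float | None = None,
        coupling: CouplingConfig | None = None,
        duration: float = 120.0,
        dt: float = 1e-4,
        seed: int = 0,
        record_dt: float = 1e-3,
    ) -> NeuronalTimeSeries:
        """Neuronal trajectory at coupling ``G`` (FIC-calibrated) or explicit J."""
        if coupling is None:
            if G is None:
                raise ValueError("provide either G or an explicit coupling")
            coupling = self.calibrate(G, seed=seed)
        return simulate_dmf(self.connectome, self.params, coupling,
                            duration=duration, dt=dt, seed=seed, record_dt=record_dt)

    def simulate_bold(
        self,
        G: float | None = None,
        coupling: CouplingConfig | None = None,
        duration: float = 120.0,
        dt: float = 1e-4,
        seed: int = 0,
        record_dt: float = 1e-3,
        out_dt: float = 0.72,
        transient: float = 10.0,
        band: tuple[float, float] = (0.01, 0.1),
    ) -> BoldTimeSeries:
        """Simulated band-passed BOLD (transient dropped before filtering)."""
        series = self.simulate(G=G, coupling=coupling, duration=duration,
                               dt=dt, seed=seed, record_dt=record_dt)
        bts = balloon_windkessel(series.r_E, series.dt, self.hemo, out_dt=out_dt)
        drop = int(round(transient / bts.dt))
        filtered = bandpass_filter(bts.bold[:, drop:], bts.dt, *band)
        return BoldTimeSeries(bold=filtered, dt=bts.dt, provenance="simulated")

    def fit(
        self,
        target_stats: TargetStats,
        G_grid=None,
        n_repeats: int = 2,
        seed: int = 0,
        **kwargs,
    ) -> "WholeBrainFitResults":
        """Grid-search G against target statistics (default grid 0–2.5, step 0.025)."""
        if G_grid is None:
            G_grid = np.arange(0.0, 2.5 + 1e-9, 0.025)
        result = fit_G(
            self.connectome, self.params, target_stats, G_grid,
            n_repeats=n_repeats, seed=seed, hemo=self.hemo, **kwargs,
        )
        return WholeBrainFitResults(self, result, target_stats, n_repeats=n_repeats, seed=seed)


class WholeBrainFitResults:
    """Outcome of the global-coupling grid search.

    Attributes
    ----------
    G_opt : float
        Selected global coupling.
    curves : pandas.DataFrame
        Per-grid-point |d metastability|, KS_phase, KS_fcd and exclusion flags.
    """

    def __init__(self, model: WholeBrainModel, fit_result: FitResult,
                 target_stats: TargetStats, n_repeats: int, seed: int):
        self.model = model
        self.fit_result = fit_result
        self.target_stats = target_stats
        self.n_repeats = n_repeats
        self.seed = seed

    @property
    def G_opt(self) -> float:
        return self.fit_result.G_opt

    @property
    def selection_rule(self) -> str:
        return self.fit_result.selection_rule

    @property
    def curves(self) -> pd.DataFrame:
        return self.fit_result.as_frame()

    def simulate_bold(self, duration: float = 120.0, seed: int = 0, **kwargs) -> BoldTimeSeries:
        """Simulate band-passed BOLD at the fitted coupling."""
        return self.model.simulate_bold(G=self.G_opt, duration=duration, seed=seed, **kwargs)

    def summary(self) -> str:
        """Plain-text fit report (grid extent, metric minima, selected G)."""
        fr = self.fit_result
        ok = ~fr.excluded
        lines = [
            "Whole-brain DMF coupling fit",
            "=" * 46,
            f"{'Regions':<28}{self.model.n_regions:>18}",
            f"{'Grid points':<28}{fr.G_grid.size:>18}",
            f"{'Grid range':<28}{f'[{fr.G_grid.min():g}, {fr.G_grid.max():g}]':>18}",
            f"{'Repeats per grid point':<28}{self.n_repeats:>18}",
            f"{'Excluded (FIC failed)':<28}{int(fr.excluded.sum()):>18}",
            f"{'Selection rule':<28}{fr.selection_rule:>18}",
            "-" * 46,
            f"{'Target metastability':<28}{self.target_stats.metastability:>18.4f}",
            f"{'min |d metastability|':<28}{np.nanmin(fr.metastability_diff[ok]):>18.4f}",
            f"{'min KS (phase)':<28}{np.nanmin(fr.ks_phase[ok]):>18.4f}",
            f"{'min KS (FCD)':<28}{np.nanmin(fr.ks_fcd[ok]):>18.4f}",
            "-" * 46,
            f"{'G_opt':<28}{fr.G_opt:>18.4f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<WholeBrainFitResults G_opt={self.G_opt:g} rule={self.selection_rule}>"
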