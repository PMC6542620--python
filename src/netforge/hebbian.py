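"""Activity-driven (Hebbian) rewiring: functional connectivity as the score.

The Hebbian rule is the same batch rewiring engine as topological
reinforcement, with the topological-overlap score replaced by functional
connectivity estimated from SER dynamics on the current graph.  FC is
re-estimated from scratch before every rewiring step; nothing carries over
between activity windows.

FC acts as a dynamical proxy of TO: when the SER regime makes the two
correlate on the initial graph, Hebbian rewiring reproduces topological
reinforcement and modularity emerges; when the correlation is destroyed
(e.g. high spontaneous-activation rates), it does not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph_core import Network, modularity_louvain, topological_overlap
from .rewiring import RewiringConfig, Trajectory, run_topological_reinforcement
from .ser import SERParams, simulate_deterministic_fc, simulate_stochastic_fc

__all__ = ["HebbianConfig", "run_hebbian", "to_fc_correlation", "parameter_sweep"]


@dataclass
class HebbianConfig:
    """SER protocol plus rewiring parameters for one Hebbian run.

    regime:          'deterministic' (f=0, p=1; many short runs per window)
                     or 'stochastic' (one long run per window).
    ser:             transition probabilities (stochastic regime).
    proportions:     fixed initial (e, s, r) proportions for the
                     deterministic regime; None draws them uniformly over
                     the discrete simplex each run.
    window_runs:     runs per FC window (deterministic regime).
    window_steps:    time steps per run (deterministic) or per window
                     (stochastic).  Defaults are desk-scale; the long-run
                     reference values are 5000 runs x 30 steps and 50,000
                     steps respectively.
    rewiring:        shared engine configuration (r = round(λK) as in TR).
    """

    regime: str = "deterministic"
    ser: SERParams = field(default_factory=SERParams)
    proportions: tuple[float, float, float] | None = None
    window_runs: int = 500
    window_steps: int = 30
    rewiring: RewiringConfig = field(default_factory=RewiringConfig)

    def __post_init__(self) -> None:
        if self.regime not in ("deterministic", "stochastic"):
            raise ValueError("regime must be 'deterministic' or 'stochastic'")
        if self.regime == "stochastic" and self.ser.deterministic:
            raise ValueError("stochastic regime requires f > 0 or p < 1")

    def fc_estimator(self, rng: np.random.Generator):
        if self.regime == "deterministic":
            return lambda net: simulate_deterministic_fc(
                net, n_runs=self.window_runs, t_steps=self.window_steps,
                rng=rng, proportions=self.proportions)
        return lambda net: simulate_stochastic_fc(
            net, self.ser, t_steps=self.window_steps, rng=rng)


def run_hebbian(net: Network, cfg: HebbianConfig, n_detect: int = 10,
                snapshot_steps: tuple[int, ...] = ()) -> Trajectory:
    """Evolve a graph by FC-based rewiring; same trajectory records as TR.

    If an FC window comes out all-zero (dead dynamics), the step falls back
    to uniform-random insertion among non-neighbours — all candidates tie
    at score 0 — and a warning is emitted.
    """
    rng = np.random.default_rng(cfg.rewiring.seed)
    estimate_fc = cfg.fc_estimator(rng)

    def score_fn(current: Network) -> np.ndarray:
        fc = estimate_fc(current)
        if not np.any(fc > 0):
            warnings.warn("all-zero FC window (dead dynamics); inserting uniformly at random")
        return fc

    # reuse the TR engine verbatim; only the score function differs
    inner_cfg = RewiringConfig(
        K=cfg.rewiring.K, batch_size=cfg.rewiring.batch_size,
        steps=cfg.rewiring.steps, seed=int(rng.integers(2**31)))
    return run_topological_reinforcement(
        net, inner_cfg, n_detect=n_detect, snapshot_steps=snapshot_steps,
        score_fn=score_fn)


def to_fc_correlation(net: Network, fc: np.ndarray) -> float:
    """Pearson correlation between off-diagonal TO and FC (upper triangle)."""
    to = topological_overlap(net)
    iu = np.triu_indices(net.n_nodes, k=1)
    x, y = to[iu], np.asarray(fc, float)[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance; TO-FC correlation undefined")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def parameter_sweep(net: Network, grid: list[dict], base_cfg: HebbianConfig | None = None,
                    n_runs: int = 150, n_detect: int = 10,
                    seed: int | None = None) -> pd.DataFrame:
    """Sweep SER settings; tabulate initial TO–FC correlation and ΔQ.

    Each grid cell is a dict with regime-specific keys: ``{"regime":
    "stochastic", "f": ..., "p": ...}`` or ``{"regime": "deterministic",
    "e": ..., "s": ..., "r": ...}``.  Per cell, ``n_runs`` Hebbian runs are
    performed and ΔQ = mean final Q − initial-graph Q (each Q averaged over
    ``n_detect`` Louvain detections).  Per-cell failures are logged and the
    sweep continues.
    """
    base_cfg = base_cfg or HebbianConfig()
    rng = np.random.default_rng(seed)
    q0 = float(np.mean([
        modularity_louvain(net, seed=int(rng.integers(2**31))).q
        for _ in range(n_detect)
    ]))
    rows = []
    for setting in grid:
        row = dict(setting)
        try:
            cfg = _cell_config(base_cfg, setting, seed=int(rng.integers(2**31)))
            fc0 = cfg.fc_estimator(np.random.default_rng(int(rng.integers(2**31))))(net)
            row["to_fc_corr"] = to_fc_correlation(net, fc0)
            finals = []
            for _ in range(n_runs):
                cfg_run = _cell_config(base_cfg, setting, seed=int(rng.integers(2**31)))
                traj = run_hebbian(net, cfg_run, n_detect=0)
                finals.append(float(np.mean([
                    modularity_louvain(traj.final, seed=int(rng.integers(2**31))).q
                    for _ in range(n_detect)
                ])))
            row["q_final"] = float(np.mean(finals))
            row["delta_q"] = row["q_final"] - q0
            row["error"] = ""
        except Exception as exc:  # keep sweeping on per-cell failure
            warnings.warn(f"sweep cell {setting} failed: {exc}")
            row.update(to_fc_corr=np.nan, q_final=np.nan, delta_q=np.nan, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)


def _cell_config(base: HebbianConfig, setting: dict, seed: int) -> HebbianConfig:
    regime = setting.get("regime", base.regime)
    rew = RewiringConfig(K=base.rewiring.K, batch_size=base.rewiring.batch_size,
                         steps=base.rewiring.steps, seed=seed)
    if regime == "stochastic":
        return HebbianConfig(
            regime="stochastic",
            ser=SERParams(f=setting["f"], p=setting["p"]),
            window_steps=setting.get("window_steps", max(base.window_steps, 1000)),
            rewiring=rew)
    props = None
    if all(k in setting for k in ("e", "s", "r")):
        props = (setting["e"], setting["s"], setting["r"])
    return HebbianConfig(
        regime="deterministic", proportions=props,
        window_runs=base.window_runs, window_steps=base.window_steps,
        rewiring=rew)
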