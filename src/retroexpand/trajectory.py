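"""Gene-copy-number through time and its correlation with trait series.

``copies_through_time`` computes the lineage-through-time curve N(t): the
number of gene-tree lineages at time t that are ancestral to a focal species'
sampled copies (optionally including lineages lost on the focal path, so that
losses step the curve down). ``correlate_series`` quantifies co-trending of
two time series with a circular-shift permutation test, which preserves the
autocorrelation structure of each series under the null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .trees import Node


@dataclass
class TimeSeries:
    """Values on a time grid in MY before present, descending toward 0.

    ``kind`` records the natural interpolation: ``"step"`` for counts (copy
    number), ``"linear"`` for continuous traits (body mass).
    """

    times: np.ndarray
    values: np.ndarray
    kind: str = "linear"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) < 0):
            raise ValueError("time grid must be strictly decreasing (MY before present)")
        if self.kind not in ("step", "linear"):
            raise ValueError("kind must be 'step' or 'linear'")

    def __len__(self) -> int:
        return self.times.size

    def at(self, grid: np.ndarray) -> np.ndarray:
        """Resample onto a (descending) grid: step-hold or linear in time."""
        grid = np.asarray(grid, dtype=float)
        t_asc = self.times[::-1]
        v_asc = self.values[::-1]
        if self.kind == "linear":
            return np.interp(grid, t_asc, v_asc)
        # step: value at time t is the value of the most recent knot with
        # knot_time >= t (curves change as time moves toward the present)
        idx = np.searchsorted(t_asc, grid, side="left")
        idx = np.clip(idx, 0, t_asc.size - 1)
        return v_asc[idx]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_my": self.times, "value": self.values})


@dataclass
class CorrelationResult:
    r: float
    method: str
    n: int
    p_value: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("correlation coefficient outside [-1, 1]")
        if not 0 < self.p_value <= 1:
            raise ValueError("permutation p-value must lie in (0, 1]")


def copies_through_time(gene_tree: Node, focal_species: Optional[str] = None,
                        grid: Optional[Sequence[float]] = None,
                        origin_age: Optional[float] = None,
                        include_losses: bool = False) -> TimeSeries:
    """Lineage count N(t) ancestral to the focal species' sampled copies.

    The curve steps +1 at each duplication on the focal path and, when loss
    tips are present in the tree (``include_losses``), -1 at each loss age.
    ``origin_age`` extends the stem lineage above the gene-tree root (N=1 on
    the stem). Default grid: 1 MY bins from the family origin to the present.
    """
    leaves = gene_tree.leaves()
    focal = [n for n in leaves
             if (focal_species is None or n.species == focal_species
                 or n.name.startswith(f"{focal_species}_"))
             and (include_losses or n.event != "loss")]
    if not any(n.event != "loss" for n in focal):
        raise ValueError(f"focal species {focal_species!r} has no extant copies")
    focal_ids = {id(n) for n in focal}

    # which nodes have a focal descendant
    has_focal: dict[int, bool] = {}
    for node in gene_tree.postorder():
        if node.is_leaf:
            has_focal[id(node)] = id(node) in focal_ids
        else:
            has_focal[id(node)] = any(has_focal[id(c)] for c in node.children)

    top = origin_age if origin_age is not None else gene_tree.age
    if grid is None:
        grid = np.arange(float(np.ceil(top)), -1.0, -1.0)
        grid = grid[grid <= top]
    grid = np.asarray(list(grid), dtype=float)
    if grid.size and grid.max() > top:
        warnings.warn("grid extends beyond the family origin; clamping to origin")
        grid = grid[grid <= top]

    # edges (parent.age, child.age): a lineage is alive on [child.age, parent.age)
    edges = [(top, gene_tree.age, True)] if top > gene_tree.age else []
    for node in gene_tree.walk():
        for child in node.children:
            edges.append((node.age, child.age, has_focal[id(child)]))

    values = np.zeros(grid.size)
    for hi, lo, relevant in edges:
        if relevant:
            values += (grid < hi) & (grid >= lo)
    # the single founding lineage is counted at the origin instant itself
    values[grid == top] = np.maximum(values[grid == top], 1)
    return TimeSeries(grid, values, kind="step")


def correlate_series(a: TimeSeries, b: TimeSeries, method: str = "pearson",
                     n_perm: int = 10000, seed: int = 0,
                     grid: Optional[Sequence[float]] = None) -> CorrelationResult:
    """Correlation between two time series with a circular-shift permutation p.

    Both series are resampled onto a common 1 MY grid spanning the overlap of
    their ranges (step interpolation for counts, linear for continuous
    traits). Significance comes from circularly shifting one series over the
    grid, which respects autocorrelation; with fewer than ``n_perm`` distinct
    shifts the test is exact over all shifts.
    """
    if grid is None:
        hi = min(a.times.max(), b.times.max())
        lo = max(a.times.min(), b.times.min())
        if hi <= lo:
            raise ValueError("series do not overlap in time")
        grid = np.arange(np.floor(hi), lo - 0.5, -1.0)
    grid = np.asarray(list(grid), dtype=float)
    if grid.size < 3:
        raise ValueError("need at least 3 common grid points")
    x = a.at(grid)
    y = b.at(grid)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("correlation undefined for a constant series")

    if method == "pearson":
        r_obs = float(stats.pearsonr(x, y).statistic)
        def corr(u, v):
            return np.corrcoef(u, v)[0, 1]
    elif method == "spearman":
        r_obs = float(stats.spearmanr(x, y).statistic)
        def corr(u, v):
            return stats.spearmanr(u, v).statistic
    else:
        raise ValueError(f"unknown correlation method {method!r}")

    n = grid.size
    all_shifts = np.arange(1, n)
    if all_shifts.size <= n_perm:
        shifts = all_shifts
    else:
        rng = np.random.default_rng(seed)
        shifts = rng.choice(all_shifts, size=n_perm, replace=False)
    exceed = 0
    for s in shifts:
        r_s = corr(x, np.roll(y, int(s)))
        if abs(r_s) >= abs(r_obs) - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + shifts.size)
    return CorrelationResult(r=r_obs, method=method, n=int(n), p_value=float(p))


def plot_trajectory(copies: TimeSeries, body_size: TimeSeries, path) -> None:
    """Dual-axis plot of copy number (steps) and body mass through time."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax1 = plt.subplots(figsize=(7, 4))
    ax1.step(copies.times, copies.values, where="post", color="tab:blue",
             label="copy number")
    ax1.set_xlabel("time (MY before present)")
    ax1.set_ylabel("gene copies", color="tab:blue")
    ax1.invert_xaxis()
    ax2 = ax1.twinx()
    ax2.plot(body_size.times, body_size.values, color="tab:red", label="body mass")
    ax2.set_ylabel("body mass (kg)", color="tab:red")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
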