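"""Rectangular grids and discretized densities over normalized (v, h) space.

A :class:`DensityField` stores probability *mass per grid cell* (not density
per unit area), which makes mass accounting in the finite-volume solver exact:
the total is simply ``values.sum()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import TextIO, Tuple

import numpy as np

from .model import NormalizationContext

__all__ = ["Grid", "DensityField"]


@dataclass(frozen=True)
class Grid:
    """Uniform rectangular grid over normalized coordinates.

    The domain must exclude zero so the drift exponentials stay finite.
    Defaults elsewhere in the package are 120 x 120 cells on [0.05, 2.5]².
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    ctx: NormalizationContext

    def __post_init__(self) -> None:
        for name, edges in (("x_edges", self.x_edges), ("y_edges", self.y_edges)):
            e = np.asarray(edges, dtype=float)
            if e.ndim != 1 or e.size < 2:
                raise ValueError(f"{name} must be a 1-D array of at least 2 edges")
            d = np.diff(e)
            if np.any(d <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            if not np.allclose(d, d[0], rtol=1e-8):
                raise ValueError(f"{name} must be uniformly spaced")
            if e[0] <= 0:
                raise ValueError("grid domain must exclude zero (drift exponentials diverge)")
            object.__setattr__(self, name, e)

    @classmethod
    def regular(
        cls,
        nx: int = 120,
        ny: int = 120,
        xlim: Tuple[float, float] = (0.05, 2.5),
        ylim: Tuple[float, float] = (0.05, 2.5),
        ctx: NormalizationContext | None = None,
    ) -> "Grid":
        if ctx is None:
            ctx = NormalizationContext(v_bar=90.0, h_bar=30.0)
        return cls(
            x_edges=np.linspace(xlim[0], xlim[1], nx + 1),
            y_edges=np.linspace(ylim[0], ylim[1], ny + 1),
            ctx=ctx,
        )

    @property
    def nx(self) -> int:
        return self.x_edges.size - 1

    @property
    def ny(self) -> int:
        return self.y_edges.size - 1

    @property
    def dx(self) -> float:
        return float(self.x_edges[1] - self.x_edges[0])

    @property
    def dy(self) -> float:
        return float(self.y_edges[1] - self.y_edges[0])

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def meshgrid(self) -> Tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinates as (nx, ny) arrays, indexed [i, j] = (x_i, y_j)."""
        return np.meshgrid(self.x_centers, self.y_centers, indexing="ij")

    def with_ctx(self, ctx: NormalizationContext) -> "Grid":
        return Grid(x_edges=self.x_edges, y_edges=self.y_edges, ctx=ctx)

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.x_edges.shape == other.x_edges.shape
            and self.y_edges.shape == other.y_edges.shape
            and np.allclose(self.x_edges, other.x_edges)
            and np.allclose(self.y_edges, other.y_edges)
        )


@dataclass
class DensityField:
    """Nonnegative mass-per-cell field over a :class:`Grid` at a given time (days)."""

    values: np.ndarray
    grid: Grid
    time: float = 0.0
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.nx, self.grid.ny):
            raise ValueError(f"values shape {v.shape} does not match grid ({self.grid.nx}, {self.grid.ny})")
        if not np.all(np.isfinite(v)):
            raise ValueError("DensityField values must be finite")
        if np.any(v < 0):
            raise ValueError("DensityField values must be nonnegative")
        self.values = v

    @classmethod
    def zeros(cls, grid: Grid, time: float = 0.0) -> "DensityField":
        return cls(values=np.zeros((grid.nx, grid.ny)), grid=grid, time=time)

    @property
    def mass(self) -> float:
        return float(self.values.sum())

    def normalized(self) -> "DensityField":
        m = self.mass
        if m <= 0:
            raise ValueError("cannot normalize an empty field")
        return DensityField(self.values / m, self.grid, self.time, dict(self.diagnostics))

    def copy(self) -> "DensityField":
        return DensityField(self.values.copy(), self.grid, self.time, dict(self.diagnostics))

    def l1_distance(self, other: "DensityField") -> float:
        if not self.grid.same_geometry(other.grid):
            raise ValueError("L1 distance requires identical grids")
        return float(np.abs(self.values - other.values).sum())

    def moments(self) -> dict:
        """Mass-weighted mean and variance of the cell-center coordinates."""
        m = self.mass
        if m <= 0:
            raise ValueError("moments of an empty field are undefined")
        X, Y = self.grid.meshgrid()
        w = self.values / m
        mx = float((w * X).sum())
        my = float((w * Y).sum())
        vx = float((w * (X - mx) ** 2).sum())
        vy = float((w * (Y - my) ** 2).sum())
        return {"mean_x": mx, "mean_y": my, "var_x": vx, "var_y": vy}

    # -- plain-text round trip --------------------------------------------

    def write_text(self, fh: TextIO) -> None:
        header = {
            "x_edges": self.grid.x_edges.tolist(),
            "y_edges": self.grid.y_edges.tolist(),
            "ctx": self.grid.ctx.to_json_dict(),
            "time_days": self.time,
        }
        fh.write(json.dumps(header) + "\n")
        np.savetxt(fh, self.values, fmt="%.17g")

    @classmethod
    def read_text(cls, fh: TextIO) -> "DensityField":
        header = json.loads(fh.readline())
        grid = Grid(
            x_edges=np.asarray(header["x_edges"]),
            y_edges=np.asarray(header["y_edges"]),
            ctx=NormalizationContext.from_json_dict(header["ctx"]),
        )
        values = np.loadtxt(fh, ndmin=2)
        return cls(values=values, grid=grid, time=header["time_days"])
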