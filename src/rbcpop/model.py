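"""Functional forms of the single-RBC volume-hemoglobin population model.

A circulating red blood cell is described by its volume ``v`` (fL) and
hemoglobin mass ``h`` (pg).  All model functions operate in *normalized*
coordinates ``x = v / v_bar`` and ``y = h / h_bar`` where ``(v_bar, h_bar)``
are the population mean volume (MCV) and hemoglobin (MCH) of the sample that
anchors the current analysis segment, so the population mean sits at
``(1, 1)``.

The population density ``P(x, y, t)`` evolves by

* **drift** toward the origin, with an early fast phase in which volume and
  hemoglobin converge toward proportionality (exponents ``beta_v``,
  ``beta_h``) and a later slow phase of coordinated reduction (magnitude
  ``alpha``, expressed per nominal lifespan ``LS`` so that physical drift
  velocity is ``-f / LS`` per day);
* **diffusion** with constant diagonal diffusivities ``(D_v, D_h)``
  capturing cell-to-cell variability in reduction rates;
* **clearance**, a sigmoidal field that switches on as the cell's radial
  position falls inside a boundary at a fraction ``v_c`` of the population
  mean radius; and
* **birth**, a source whose (v, h) distribution is measured directly from
  reticulocytes (cells younger than ~3 days).

The dimensionless ratio ``D_v * v_c / alpha`` summarizes the balance between
a production-dominated response (high ratio) and a clearance-dominated
response (low ratio) to blood loss.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence, Tuple

import numpy as np
from scipy.special import expit

__all__ = [
    "ModelParams",
    "NormalizationContext",
    "drift_field",
    "clearance_probability",
    "birth_density",
    "production_clearance_ratio",
    "time_weighted_ratio",
    "lifetime_summary",
]

#: mean radial position of the normalized population, |(1, 1)|
RBAR = math.sqrt(2.0)

#: sharpness of the clearance sigmoid (fixed by the model definition)
CLEARANCE_GAIN = 100.0


def _require_finite_positive(name: str, value: float) -> None:
    if not np.all(np.isfinite(value)):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if not np.all(np.asarray(value) > 0):
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class NormalizationContext:
    """Reference scales that map raw (fL, pg) cells onto normalized coordinates.

    Parameters
    ----------
    v_bar:
        Reference mean cell volume in fL (the anchoring sample's MCV).
    h_bar:
        Reference mean cell hemoglobin in pg (the anchoring sample's MCH).
    LS:
        Nominal RBC lifespan in days; converts the lifespan-normalized drift
        magnitude into a per-day velocity.  Default 105.
    """

    v_bar: float
    h_bar: float
    LS: float = 105.0

    def __post_init__(self) -> None:
        _require_finite_positive("v_bar", self.v_bar)
        _require_finite_positive("h_bar", self.h_bar)
        _require_finite_positive("LS", self.LS)

    def normalize(self, v: np.ndarray, h: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        return np.asarray(v, float) / self.v_bar, np.asarray(h, float) / self.h_bar

    def to_json_dict(self) -> dict:
        return {"v_bar_fL": self.v_bar, "h_bar_pg": self.h_bar, "LS_days": self.LS}

    @classmethod
    def from_json_dict(cls, d: dict) -> "NormalizationContext":
        return cls(v_bar=d["v_bar_fL"], h_bar=d["h_bar_pg"], LS=d["LS_days"])


@dataclass(frozen=True)
class ModelParams:
    """The six dynamic parameters governing one subject-segment's RBC dynamics.

    ``alpha`` is the slow-phase drift magnitude in lifespan-normalized units;
    ``beta_v`` / ``beta_h`` are the fast-phase exponents; ``D_v`` / ``D_h``
    are diffusivities in normalized-coordinate² per day; ``v_c`` locates the
    clearance boundary as a fraction of the population-mean radial position.
    """

    alpha: float
    beta_v: float
    beta_h: float
    D_v: float
    D_h: float
    v_c: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta_v", "beta_h", "D_v", "D_h", "v_c"):
            _require_finite_positive(name, getattr(self, name))
        if not self.v_c < 1.0:
            raise ValueError(f"v_c must lie inside the population-mean radius (v_c < 1), got {self.v_c}")

    # -- convenience -------------------------------------------------------

    def scaled(self, k_alpha: float = 1.0, k_Dv: float = 1.0, k_vc: float = 1.0) -> "ModelParams":
        """Return a copy with (alpha, D_v, v_c) multiplied by the given factors."""
        return replace(self, alpha=self.alpha * k_alpha, D_v=self.D_v * k_Dv, v_c=self.v_c * k_vc)

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta_v, self.beta_h, self.D_v, self.D_h, self.v_c])

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "ModelParams":
        return cls(*[float(x) for x in a])

    def to_json_dict(self, ctx: NormalizationContext | None = None) -> dict:
        d = {
            "alpha": self.alpha,
            "beta_v": self.beta_v,
            "beta_h": self.beta_h,
            "D_v": self.D_v,
            "D_h": self.D_h,
            "v_c": self.v_c,
        }
        if ctx is not None:
            d["context"] = ctx.to_json_dict()
        return d

    def to_json(self, ctx: NormalizationContext | None = None) -> str:
        return json.dumps(self.to_json_dict(ctx))

    @classmethod
    def from_json_dict(cls, d: dict) -> "ModelParams":
        return cls(
            alpha=d["alpha"], beta_v=d["beta_v"], beta_h=d["beta_h"],
            D_v=d["D_v"], D_h=d["D_h"], v_c=d["v_c"],
        )


def drift_field(
    params: ModelParams,
    x: np.ndarray | float,
    y: np.ndarray | float,
    exp_clip: float | None = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Reduction-rate magnitude vector ``f = alpha * (e^{bv(x-y)}, e^{bh(y-x)})``.

    Both components are positive; cells *lose* volume and hemoglobin, so the
    solver applies the advection velocity ``-f / LS`` (toward the origin, in
    per-day units).  At ``x == y`` the fast-phase exponentials vanish and both
    components equal ``alpha``.

    ``exp_clip`` optionally caps the exponent magnitude (a numerical safeguard
    used by the solver far outside the populated region); the pure model form
    uses no cap.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("drift_field requires finite coordinates")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("drift_field requires strictly positive normalized coordinates")
    ev = params.beta_v * (x - y)
    eh = params.beta_h * (y - x)
    if exp_clip is not None:
        ev = np.clip(ev, -exp_clip, exp_clip)
        eh = np.clip(eh, -exp_clip, exp_clip)
    return params.alpha * np.exp(ev), params.alpha * np.exp(eh)


def clearance_angle(x: np.ndarray | float, y: np.ndarray | float) -> np.ndarray:
    """Angle between a cell's normalized direction and the population-mean direction (1, 1)."""
    return np.pi / 4.0 - np.arctan2(np.asarray(y, float), np.asarray(x, float))


def clearance_probability(
    params: ModelParams,
    ctx: NormalizationContext,
    x: np.ndarray | float,
    y: np.ndarray | float,
) -> np.ndarray:
    """Clearance field ``d = 1 / (1 + exp(Delta))`` in (0, 1).

    ``Delta = 100 * cos(theta) * (r - v_c * rbar) / (v_c * rbar)`` measures the
    cell's relative radial excess over the clearance boundary, angularly
    weighted toward the population-mean direction; ``r = sqrt(x^2 + y^2)`` and
    ``rbar = sqrt(2)`` is the population-mean radius in normalized
    coordinates.  Cells well outside the boundary (healthy mid-distribution
    cells) have ``d ~ 0``; cells well inside it (low-u cells at the end of
    their lifespan) have ``d ~ 1``; the boundary itself sits exactly at 0.5.

    ``ctx`` carries no independent information here because the coordinates
    are already normalized; it is part of the signature so that callers can
    treat this together with the raw-unit operations uniformly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("clearance_probability requires finite coordinates")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("clearance_probability requires strictly positive coordinates")
    r = np.hypot(x, y)
    boundary = params.v_c * RBAR
    delta = CLEARANCE_GAIN * np.cos(clearance_angle(x, y)) * (r - boundary) / boundary
    return expit(-delta)


def birth_density(cells, grid, blur_cells: float = 1.0, min_retics: int = 50):
    """Unit-mass birth density built from the reticulocyte-flagged cells only.

    The flagged cells are binned on the solver grid and smoothed with a small
    Gaussian blur (default one grid cell) to stabilize estimation from the
    typical ~500-1000 reticulocytes per draw.

    Parameters
    ----------
    cells:
        A :class:`rbcpop.stats.CellSample`.
    grid:
        The solver :class:`rbcpop.grid.Grid` (its context defines the
        normalization).
    """
    from scipy.ndimage import gaussian_filter

    from .grid import DensityField

    retic = np.asarray(cells.retic, dtype=bool)
    n_retic = int(retic.sum())
    if n_retic < min_retics:
        raise ValueError(
            f"birth_density requires at least {min_retics} reticulocyte-flagged cells, got {n_retic}"
        )
    x, y = grid.ctx.normalize(cells.v[retic], cells.h[retic])
    hist, _, _ = np.histogram2d(x, y, bins=[grid.x_edges, grid.y_edges])
    if blur_cells > 0:
        hist = gaussian_filter(hist, sigma=blur_cells, mode="constant")
    total = hist.sum()
    if total <= 0:
        raise ValueError("all reticulocytes fall outside the grid domain")
    return DensityField(values=hist / total, grid=grid, time=0.0)


def production_clearance_ratio(params: ModelParams) -> float:
    """Dimensionless production/clearance balance ratio ``D_v * v_c / alpha``."""
    return params.D_v * params.v_c / params.alpha


def time_weighted_ratio(fits: Iterable[Tuple[Tuple[float, float], ModelParams]]) -> float:
    """Duration-weighted average of the production/clearance ratio over segments.

    ``fits`` is a sequence of ``((t_start, t_end), params)`` covering disjoint,
    ordered post-loss intervals; the weight of each segment is its duration in
    days.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("time_weighted_ratio requires at least one segment fit")
    num = 0.0
    den = 0.0
    prev_end = -np.inf
    for (t0, t1), p in fits:
        if t1 <= t0:
            raise ValueError(f"segment interval ({t0}, {t1}) has nonpositive duration")
        if t0 < prev_end:
            raise ValueError("segment intervals must be disjoint and ordered")
        prev_end = t1
        w = t1 - t0
        num += w * production_clearance_ratio(p)
        den += w
    return num / den


def lifetime_summary(
    params: ModelParams,
    ctx: NormalizationContext,
    start_xy: Tuple[float, float],
    kappa: float = 5.0,
    max_days: float = 400.0,
) -> dict:
    """Drift characteristic of the mean cell from birth to median clearance.

    Integrates ``d(x, y)/dt = -f(x, y) / LS`` from the birth mean together
    with the survival ODE ``dS/dt = -kappa * d(x, y) * S`` and reports the
    state at the median survival time (S = 1/2): the cell's age and the
    fractional volume and hemoglobin losses accumulated by then.  Diffusion is
    not included — this is the *mean lifetime trajectory* of the model.
    """
    from scipy.integrate import solve_ivp

    x0, y0 = start_xy

    def rhs(t, state):
        x, y, s = state
        fx, fy = drift_field(params, x, y)
        d = clearance_probability(params, ctx, x, y)
        return [-fx / ctx.LS, -fy / ctx.LS, -kappa * float(d) * s]

    def median_survival(t, state):
        return state[2] - 0.5

    median_survival.terminal = True
    median_survival.direction = -1

    sol = solve_ivp(
        rhs, (0.0, max_days), [x0, y0, 1.0], events=median_survival,
        max_step=1.0, rtol=1e-8, atol=1e-10,
    )
    if sol.t_events[0].size:
        t_med = float(sol.t_events[0][0])
        x_end, y_end, _ = sol.y_events[0][0]
    else:  # never reached median survival inside max_days
        t_med = float(sol.t[-1])
        x_end, y_end = sol.y[0, -1], sol.y[1, -1]
    return {
        "median_lifespan_days": t_med,
        "volume_loss_pct": 100.0 * (1.0 - x_end / x0),
        "hemoglobin_loss_pct": 100.0 * (1.0 - y_end / y0),
        "end_xy": (float(x_end), float(y_end)),
    }
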