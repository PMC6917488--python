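"""Single-cell CBC statistics: indices, the u-[Hb] transform, and tail fractions.

The major axis of the (v, h) distribution — the line through the origin with
slope equal to the MCHC — is the ``u`` axis.  A cell's position along u is a
rough proxy for its age: newborn cells appear at high u and drift toward the
origin as they age.  Two derived fractions quantify the blood-loss response:

* the **old-cell fraction**, the mass of P(u) more than one standard
  deviation below the median u (cells awaiting clearance);
* the **new-cell fraction**, the mass with u more than one SD above the
  median *and* single-cell hemoglobin concentration more than one SD below
  the median (the high-volume, low-[Hb] corner where fresh reticulocytes
  appear).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .grid import DensityField

__all__ = [
    "CellSample",
    "CBCRecord",
    "SubjectSeries",
    "compute_indices",
    "u_projection",
    "hb_concentration",
    "old_cell_fraction",
    "new_cell_fraction",
    "paired_deltas",
    "density_cell_fractions",
]

SQRT2 = np.sqrt(2.0)


@dataclass
class CellSample:
    """Single-cell records from one blood draw: volume (fL), hemoglobin (pg), retic flag."""

    v: np.ndarray
    h: np.ndarray
    retic: np.ndarray

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        self.retic = np.asarray(self.retic, dtype=bool)
        if not (self.v.shape == self.h.shape == self.retic.shape):
            raise ValueError("v, h, retic must have identical shapes")
        if self.v.ndim != 1:
            raise ValueError("cell arrays must be 1-D")
        if np.any(self.v <= 0) or np.any(self.h <= 0):
            raise ValueError("cell volume and hemoglobin must be strictly positive")

    def __len__(self) -> int:
        return self.v.size

    @property
    def hb_conc(self) -> np.ndarray:
        """Per-cell hemoglobin concentration, 100*h/v (g/dL)."""
        return 100.0 * self.h / self.v

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"v_fL": self.v, "h_pg": self.h, "is_retic": self.retic.astype(int)})

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CellSample":
        return cls(
            v=df["v_fL"].to_numpy(float),
            h=df["h_pg"].to_numpy(float),
            retic=df["is_retic"].to_numpy() != 0,
        )


@dataclass
class CBCRecord:
    """One draw: time (days), the cell sample, and optional RBC count concentration (10^6/uL)."""

    time: float
    cells: CellSample
    rbc_concentration: Optional[float] = None
    _indices: Optional[dict] = field(default=None, repr=False)

    @property
    def indices(self) -> dict:
        if self._indices is None:
            self._indices = compute_indices(self.cells, self.rbc_concentration)
        return self._indices


@dataclass
class SubjectSeries:
    """Ordered serial CBCs for one subject, with the blood-loss event time."""

    subject_id: str
    records: List[CBCRecord]
    loss_time: Optional[float] = None

    def __post_init__(self) -> None:
        times = [r.time for r in self.records]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("records must be strictly increasing in time")

    def times(self) -> np.ndarray:
        return np.array([r.time for r in self.records])


def compute_indices(cells: CellSample, rbc_concentration: Optional[float] = None) -> dict:
    """Standard CBC indices from single-cell data.

    MCV/MCH are means of v and h; MCHC = 100*MCH/MCV (g/dL); RDW and CHDW are
    coefficients of variation (percent) of v and of per-cell [Hb]; retic
    indices cover the flagged subset (reported as None when absent).  With a
    count concentration (10^6 cells/uL), HGB (g/dL) and HCT (%) are added.
    """
    if len(cells) < 100:
        raise ValueError("compute_indices requires at least 100 cells")
    mcv = float(cells.v.mean())
    mch = float(cells.h.mean())
    hb = cells.hb_conc
    out = {
        "MCV_fL": mcv,
        "MCH_pg": mch,
        "MCHC_gdL": 100.0 * mch / mcv,
        "RDW_pct": 100.0 * float(cells.v.std()) / mcv,
        "CHDW_pct": 100.0 * float(hb.std()) / float(hb.mean()),
        "rFraction_pct": 100.0 * float(cells.retic.mean()),
    }
    if cells.retic.any():
        rv = cells.v[cells.retic]
        out["rMCV_fL"] = float(rv.mean())
        out["rRDW_pct"] = 100.0 * float(rv.std()) / float(rv.mean())
    else:
        out["rMCV_fL"] = None
        out["rRDW_pct"] = None
    if rbc_concentration is not None:
        # conc in 10^6 cells/uL: 30 pg * 5e6/uL = 150 g/L = 15 g/dL
        out["HGB_gdL"] = mch * rbc_concentration / 10.0
        out["HCT_pct"] = mcv * rbc_concentration / 10.0
    return out


def u_projection(cells: CellSample) -> np.ndarray:
    """Projection of the normalized cell (v/MCV, h/MCH) onto the u axis.

    u_i = (v_i/MCV + h_i/MCH) / sqrt(2): the scalar projection onto the unit
    vector along (1, 1), which in raw units is the line through the origin
    with slope MCHC.  The population mean lies at sqrt(2) by construction,
    and the values are invariant to uniform rescaling of all cells.
    """
    if len(cells) < 100:
        raise ValueError("u_projection requires at least 100 cells")
    x = cells.v / cells.v.mean()
    y = cells.h / cells.h.mean()
    return (x + y) / SQRT2


def hb_concentration(cells: CellSample) -> np.ndarray:
    return cells.hb_conc


def _old_fraction(u: np.ndarray, weights: Optional[np.ndarray] = None) -> float:
    med = _wquantile(u, 0.5, weights)
    sd = _wstd(u, weights)
    cut = med - sd
    if weights is None:
        return float(np.mean(u < cut))
    return float(weights[u < cut].sum() / weights.sum())


def _new_fraction(
    u: np.ndarray,
    hb: np.ndarray,
    weights: Optional[np.ndarray] = None,
    mode: str = "joint",
    min_conditional: int = 50,
) -> float:
    med_u = _wquantile(u, 0.5, weights)
    sd_u = _wstd(u, weights)
    med_c = _wquantile(hb, 0.5, weights)
    sd_c = _wstd(hb, weights)
    high_u = u > med_u + sd_u
    joint = high_u & (hb < med_c - sd_c)
    if weights is None:
        n_high = int(high_u.sum())
        if n_high == 0:
            warnings.warn("no cells above median(u) + sd(u); new-cell fraction set to 0")
            return 0.0
        if n_high < min_conditional:
            warnings.warn(f"high-u conditional subset has only {n_high} cells")
        if mode == "joint":
            return float(joint.mean())
        return float(joint.sum() / n_high)
    w = weights
    w_high = w[high_u].sum()
    if w_high <= 0:
        warnings.warn("no mass above median(u) + sd(u); new-cell fraction set to 0")
        return 0.0
    if mode == "joint":
        return float(w[joint].sum() / w.sum())
    return float(w[joint].sum() / w_high)


def old_cell_fraction(cells: CellSample) -> float:
    """Fraction of cells with u below median(u) - sd(u): the aged, low-u tail."""
    if len(cells) < 1000:
        raise ValueError("old_cell_fraction requires at least 1000 cells")
    return _old_fraction(u_projection(cells))


def new_cell_fraction(cells: CellSample, mode: str = "joint") -> float:
    """Fraction of cells in the young high-u, low-[Hb] corner.

    Thresholds (median and SD of u and of [Hb]) come from the full sample.
    ``mode="joint"`` (default) reports the fraction relative to the whole
    sample; ``mode="conditional"`` reports it relative to the high-u subset.
    """
    if mode not in ("joint", "conditional"):
        raise ValueError("mode must be 'joint' or 'conditional'")
    if len(cells) < 1000:
        raise ValueError("new_cell_fraction requires at least 1000 cells")
    return _new_fraction(u_projection(cells), cells.hb_conc, mode=mode)


def density_cell_fractions(field: DensityField, mode: str = "joint") -> Dict[str, float]:
    """Old- and new-cell fractions computed on a noiseless gridded density."""
    X, Y = field.grid.meshgrid()
    w = field.values.ravel()
    m = w.sum()
    if m <= 0:
        raise ValueError("empty density")
    w = w / m
    mx = (w * X.ravel()).sum()
    my = (w * Y.ravel()).sum()
    x = X.ravel() / mx
    y = Y.ravel() / my
    u = (x + y) / SQRT2
    hb = 100.0 * (Y.ravel() * field.grid.ctx.h_bar) / (X.ravel() * field.grid.ctx.v_bar)
    return {
        "old_cell_fraction": _old_fraction(u, weights=w),
        "new_cell_fraction": _new_fraction(u, hb, weights=w, mode=mode),
    }


def _wquantile(x: np.ndarray, q: float, weights: Optional[np.ndarray]) -> float:
    if weights is None:
        return float(np.quantile(x, q))
    order = np.argsort(x)
    cw = np.cumsum(weights[order])
    cw = cw / cw[-1]
    return float(np.interp(q, cw, x[order]))


def _wstd(x: np.ndarray, weights: Optional[np.ndarray]) -> float:
    if weights is None:
        return float(np.std(x))
    w = weights / weights.sum()
    mu = float((w * x).sum())
    return float(np.sqrt((w * (x - mu) ** 2).sum()))


def paired_deltas(
    series: SubjectSeries,
    early_window: float = 4.0,
    late_min: float = 14.0,
) -> Dict[str, Dict[str, Optional[float]]]:
    """Before/after changes in MCHC, CHDW, and the old/new-cell fractions.

    Draws before the loss define the baseline mean; the first draw within
    ``early_window`` days after the loss gives the "+1-3 d" delta and the
    first draw at least ``late_min`` days after gives the "+21 d" delta.
    Missing timepoint classes yield None deltas.
    """
    if series.loss_time is None:
        raise ValueError("paired_deltas requires a loss event time")
    loss = series.loss_time
    pre = [r for r in series.records if r.time < loss]
    early = [r for r in series.records if loss < r.time <= loss + early_window]
    late = [r for r in series.records if r.time >= loss + late_min]
    if not pre:
        raise ValueError("paired_deltas requires at least one pre-loss draw")

    def stats_of(rec: CBCRecord) -> dict:
        idx = rec.indices
        return {
            "MCHC_gdL": idx["MCHC_gdL"],
            "CHDW_pct": idx["CHDW_pct"],
            "old_cell_fraction": old_cell_fraction(rec.cells),
            "new_cell_fraction": new_cell_fraction(rec.cells),
        }

    base_stats = [stats_of(r) for r in pre]
    baseline = {k: float(np.mean([s[k] for s in base_stats])) for k in base_stats[0]}

    out: Dict[str, Dict[str, Optional[float]]] = {}
    for label, recs in (("early", early), ("late", late)):
        if recs:
            s = stats_of(recs[0])
            out[label] = {k: s[k] - baseline[k] for k in baseline}
        else:
            out[label] = {k: None for k in baseline}
    out["baseline"] = baseline
    return out
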