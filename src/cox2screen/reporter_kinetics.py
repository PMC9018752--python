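"""Deterministic per-well model of growth, death and COX-2/PGE2/reporter dynamics.

The model tracks one imaging field of a well seeded with promoter-reporter
cells.  Cell-population bookkeeping is a logistic growth law with a
drug-induced arrest term and a first-order apoptosis -> secondary-necrosis
cascade.  The molecular layer follows *Ptgs2* mRNA per cell, COX-2 protein
per cell, a destabilized-GFP reporter per cell (d2EGFP, ~2 h half-life, so
fluorescence tracks ongoing transcription on a 2 h imaging grid) and
cumulative PGE2 in the culture medium.

State variables (units):

=============  ====================================================
``N_live``     live cells per field
``N_apop``     apoptotic cells per field (caspase-active, attached)
``N_nec``      secondary-necrotic cells per field (detached)
``m``          *Ptgs2* mRNA per cell (a.u.)
``c``          COX-2 protein per cell (a.u.)
``g``          reporter protein per cell (a.u., proportional to GCU)
``P``          cumulative PGE2 in medium (pg/ml)
=============  ====================================================

with dynamics

.. code-block:: text

    u(t)      = 1 - exp(-t / tau_ind)                 (induction ramp)
    w(t)      = exp(-k_shut * max(0, t - t_shut))     (transcription shutoff
                                                       as cells commit to death)
    dN_live   = r (1 - arrest u) N_live (1 - N_tot/K) - k_d [t > t_death] N_live
    dN_apop   = k_d [t > t_death] N_live - k_n N_apop
    dN_nec    = k_n N_apop
    dm        = alpha0 (1 + (beta - 1) u) w - delta_m m
    dc        = k_c m - delta_c c
    dg        = k_g m - delta_g g
    dP        = k_p c (N_live + eps_apop N_apop)

m, c, g start at their drug-free steady states, so a vehicle (DMSO) well is
flat per cell and only grows.  Integration is fixed-step RK4 (default 0.5 h
internal step) sampled onto the requested grid: deterministic and
reproducible across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "KineticParams",
    "DrugEffect",
    "WellTrajectory",
    "simulate_well",
    "simulate_wells",
    "fold_vs_control",
    "peak_time",
    "release_rate",
    "presets",
    "default_grid",
    "IntegrationError",
    "A_LIVE_UM2",
    "A_APOP_UM2",
    "FIELD_AREA_UM2",
]

#: footprint of an attached live cell, um^2
A_LIVE_UM2 = 400.0
#: footprint of a (shrunken) apoptotic cell, um^2
A_APOP_UM2 = 200.0
#: imaging field area at 10x, um^2 (1.024 mm x 1.024 mm)
FIELD_AREA_UM2 = 1.048576e6

#: reporter decay, 1/h -- the "d2" designation: ~2 h protein half-life
D2EGFP_DECAY = math.log(2.0) / 2.0

_MAX_INTERNAL_STEP_H = 0.5


class IntegrationError(RuntimeError):
    """Raised when the fixed-step integration produces non-finite state."""


def default_grid(t_end: float = 72.0, step: float = 2.0) -> np.ndarray:
    """Imaging time grid in hours: one scan every ``step`` h from 0 to ``t_end``."""
    n = int(round(t_end / step))
    return np.linspace(0.0, step * n, n + 1)


@dataclass(frozen=True)
class KineticParams:
    """Cell-line parameters.

    ``alpha0 = 0`` is legal and models a COX-2-negative line (no baseline
    transcription, hence no mRNA, protein, reporter or PGE2 at any time).
    ``inducible=False`` models a line whose COX-2 is driven by an unrelated
    constitutive promoter: baseline expression is intact but drug induction
    (beta) does not act.
    """

    alpha0: float = 1.0        # baseline Ptgs2 transcription, a.u./h
    delta_m: float = 0.6       # mRNA decay, 1/h
    k_c: float = 0.3           # COX-2 synthesis per mRNA, 1/h
    delta_c: float = 0.15      # COX-2 decay, 1/h
    k_g: float = 0.5           # reporter synthesis per mRNA, 1/h
    delta_g: float = D2EGFP_DECAY  # reporter decay, 1/h
    k_p: float = 1.7e-3        # PGE2 per unit COX-2 per live cell per h, pg/ml
    eps_apop: float = 0.3      # fractional PGE2 contribution of apoptotic cells
    r: float = 0.055           # intrinsic growth rate, 1/h
    K: float = 2400.0          # carrying capacity, cells/field
    N0: float = 1000.0         # seeding density, cells/field
    inducible: bool = True     # endogenous (inducible) promoter?

    def __post_init__(self) -> None:
        for name in ("alpha0", "delta_m", "k_c", "delta_c", "k_g", "delta_g",
                     "k_p", "eps_apop", "r", "K", "N0"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"KineticParams.{name} must be finite and >= 0, got {v!r}")
        for name in ("delta_m", "delta_c", "delta_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"KineticParams.{name} must be > 0")
        if not 0.0 <= self.eps_apop <= 1.0:
            raise ValueError("KineticParams.eps_apop must be in [0, 1]")
        if self.K <= 0:
            raise ValueError("KineticParams.K must be > 0")

    def steady_state(self) -> tuple[float, float, float]:
        """Drug-free per-cell steady state (m0, c0, g0)."""
        m0 = self.alpha0 / self.delta_m
        return m0, self.k_c * m0 / self.delta_c, self.k_g * m0 / self.delta_g


@dataclass(frozen=True)
class DrugEffect:
    """Treatment parameters.

    ``beta`` is the fold increase of *Ptgs2* transcription at full induction
    (beta = 1: no induction).  ``t_shut``/``k_shut`` describe the collapse of
    transcription as cells commit to death; ``t_shut=None`` disables it
    (transcription persists for the whole observation window).
    """

    name: str = "DMSO"
    category: str = "control"
    arrest: float = 0.0        # growth-rate suppression fraction in [0, 1]
    beta: float = 1.0          # transcription fold induction at full effect
    tau_ind: float = 6.0       # induction ramp time constant, h
    t_death: float = 0.0       # onset of apoptosis, h
    k_d: float = 0.0           # apoptosis rate, 1/h
    k_n: float = 0.1           # apoptotic -> secondary-necrotic rate, 1/h
    t_shut: float | None = None  # transcription shutoff onset, h
    k_shut: float = 0.0        # shutoff rate, 1/h
    autofluorescent: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.arrest <= 1.0:
            raise ValueError("DrugEffect.arrest must be in [0, 1]")
        if not np.isfinite(self.beta) or self.beta < 1.0:
            raise ValueError("DrugEffect.beta must be finite and >= 1")
        for name in ("tau_ind", "t_death", "k_d", "k_n", "k_shut"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"DrugEffect.{name} must be finite and >= 0, got {v!r}")
        if self.tau_ind <= 0:
            raise ValueError("DrugEffect.tau_ind must be > 0")
        if self.t_shut is not None and (not np.isfinite(self.t_shut) or self.t_shut < 0):
            raise ValueError("DrugEffect.t_shut must be finite and >= 0 (or None)")


@dataclass
class WellTrajectory:
    """Simulated observables of one well on the imaging grid."""

    times: np.ndarray
    N_live: np.ndarray
    N_apop: np.ndarray
    N_nec: np.ndarray
    m: np.ndarray
    c: np.ndarray
    g: np.ndarray
    P: np.ndarray
    params: KineticParams = field(repr=False, default=None)
    drug: DrugEffect = field(repr=False, default=None)

    @property
    def confluence(self) -> np.ndarray:
        """Percent of the field covered by attached (live + apoptotic) cells."""
        area = A_LIVE_UM2 * self.N_live + A_APOP_UM2 * self.N_apop
        return np.clip(100.0 * area / FIELD_AREA_UM2, 0.0, 100.0)

    @property
    def caspase_signal(self) -> np.ndarray:
        """Apoptotic-cell count, a proxy for a caspase-3/-7 activity readout."""
        return self.N_apop

    def observable(self, name: str) -> np.ndarray:
        try:
            return np.asarray(getattr(self, name))
        except AttributeError:
            raise KeyError(f"unknown observable {name!r}") from None

    def to_frame(self):
        """Long-format table of the trajectory (one row per time point)."""
        import pandas as pd

        return pd.DataFrame({
            "time_h": self.times,
            "n_live": self.N_live,
            "n_apop": self.N_apop,
            "n_nec": self.N_nec,
            "mrna": self.m,
            "cox2": self.c,
            "gfp": self.g,
            "pge2_pg_ml": self.P,
            "confluence_pct": self.confluence,
        })


# ---------------------------------------------------------------------------
# integration

def _validate_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("time grid must be 1-D with at least two points")
    if grid[0] != 0.0:
        raise ValueError("time grid must start at 0")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("time grid must be strictly increasing")
    return grid


def _batch_arrays(params: Sequence[KineticParams], drugs: Sequence[DrugEffect]) -> dict:
    def col(vals):
        return np.asarray(vals, dtype=float)

    out = {}
    for name in ("alpha0", "delta_m", "k_c", "delta_c", "k_g", "delta_g",
                 "k_p", "eps_apop", "r", "K", "N0"):
        out[name] = col([getattr(p, name) for p in params])
    beta = np.array([d.beta if p.inducible else 1.0
                     for p, d in zip(params, drugs)], dtype=float)
    out["beta"] = beta
    for name in ("arrest", "tau_ind", "t_death", "k_d", "k_n", "k_shut"):
        out[name] = col([getattr(d, name) for d in drugs])
    out["t_shut"] = col([np.inf if d.t_shut is None else d.t_shut for d in drugs])
    return out


def _rhs(t: float, y: np.ndarray, p: dict, stop_h: float | None) -> np.ndarray:
    Nl, Na, Nn, m, c, g, P = y
    u = -np.expm1(-t / p["tau_ind"])
    w = np.exp(-p["k_shut"] * np.maximum(0.0, t - p["t_shut"]))
    if stop_h is not None and t >= stop_h:
        w = np.zeros_like(w)
    alpha_t = p["alpha0"] * (1.0 + (p["beta"] - 1.0) * u) * w
    kd_t = np.where(t > p["t_death"], p["k_d"], 0.0)
    Ntot = Nl + Na + Nn
    dNl = p["r"] * (1.0 - p["arrest"] * u) * Nl * (1.0 - Ntot / p["K"]) - kd_t * Nl
    dNa = kd_t * Nl - p["k_n"] * Na
    dNn = p["k_n"] * Na
    dm = alpha_t - p["delta_m"] * m
    dc = p["k_c"] * m - p["delta_c"] * c
    dg = p["k_g"] * m - p["delta_g"] * g
    dP = p["k_p"] * c * (Nl + p["eps_apop"] * Na)
    return np.stack([dNl, dNa, dNn, dm, dc, dg, dP])


def _integrate(p: dict, grid: np.ndarray, step: float,
               stop_h: float | None) -> np.ndarray:
    """Fixed-step RK4 over a batch; returns array (7, n_wells, n_times)."""
    n = p["alpha0"].shape[0]
    m0 = np.where(p["delta_m"] > 0, p["alpha0"] / p["delta_m"], 0.0)
    y = np.zeros((7, n))
    y[0] = p["N0"]
    y[3] = m0
    y[4] = p["k_c"] * m0 / p["delta_c"]
    y[5] = p["k_g"] * m0 / p["delta_g"]

    out = np.empty((7, n, grid.size))
    out[:, :, 0] = y
    for i in range(grid.size - 1):
        t0, t1 = grid[i], grid[i + 1]
        nsub = max(1, int(math.ceil((t1 - t0) / step - 1e-12)))
        h = (t1 - t0) / nsub
        t = t0
        for _ in range(nsub):
            k1 = _rhs(t, y, p, stop_h)
            k2 = _rhs(t + h / 2, y + h / 2 * k1, p, stop_h)
            k3 = _rhs(t + h / 2, y + h / 2 * k2, p, stop_h)
            k4 = _rhs(t + h, y + h * k3, p, stop_h)
            y = y + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            # states are physically non-negative; clamp integrator undershoot
            y = np.maximum(y, 0.0)
            t += h
        if not np.all(np.isfinite(y)):
            raise IntegrationError(f"non-finite state at t={t1:g} h")
        out[:, :, i + 1] = y
    return out


def simulate_wells(params: Sequence[KineticParams], drugs: Sequence[DrugEffect],
                   grid: np.ndarray | None = None, *,
                   internal_step_h: float = _MAX_INTERNAL_STEP_H,
                   transcription_stop_h: float | None = None) -> list[WellTrajectory]:
    """Simulate many wells in one vectorized pass (fast path for whole plates)."""
    if len(params) != len(drugs):
        raise ValueError("params and drugs must have equal length")
    if len(params) == 0:
        return []
    if not 0 < internal_step_h <= _MAX_INTERNAL_STEP_H:
        raise ValueError(f"internal step must be in (0, {_MAX_INTERNAL_STEP_H}] h")
    grid = default_grid() if grid is None else _validate_grid(grid)
    arrs = _batch_arrays(params, drugs)
    y = _integrate(arrs, grid, internal_step_h, transcription_stop_h)
    return [
        WellTrajectory(times=grid.copy(),
                       N_live=y[0, i], N_apop=y[1, i], N_nec=y[2, i],
                       m=y[3, i], c=y[4, i], g=y[5, i], P=y[6, i],
                       params=params[i], drug=drugs[i])
        for i in range(len(params))
    ]


def simulate_well(params: KineticParams, drug: DrugEffect,
                  grid: np.ndarray | None = None, *,
                  internal_step_h: float = _MAX_INTERNAL_STEP_H,
                  transcription_stop_h: float | None = None) -> WellTrajectory:
    """Simulate a single well; see the module docstring for the model."""
    return simulate_wells([params], [drug], grid,
                          internal_step_h=internal_step_h,
                          transcription_stop_h=transcription_stop_h)[0]


# ---------------------------------------------------------------------------
# trajectory statistics

def fold_vs_control(traj: WellTrajectory, control: WellTrajectory,
                    observable: str, t: float, *, floor: float = 0.05) -> float:
    """Ratio of an observable to its control value at time ``t``.

    The control value is floored at ``floor`` so that signal-free control
    wells (e.g. a COX-2-negative line) give a large, finite fold change
    rather than a division by zero.
    """
    if traj.times.shape != control.times.shape or not np.allclose(traj.times, control.times):
        raise ValueError("trajectories must share the same time grid")
    idx = np.flatnonzero(np.isclose(traj.times, t))
    if idx.size == 0:
        raise ValueError(f"t={t!r} h is not on the trajectory grid")
    i = int(idx[0])
    denom = max(float(control.observable(observable)[i]), floor)
    return float(traj.observable(observable)[i]) / denom


def peak_time(times: np.ndarray, values: np.ndarray) -> float:
    """Grid time of the first maximum of a series (ties break earliest)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0 or values.size == 0:
        raise ValueError("series must be non-empty")
    if times.shape != values.shape:
        raise ValueError("times and values must have equal shape")
    return float(times[int(np.argmax(values))])


def release_rate(traj: WellTrajectory) -> np.ndarray:
    """Instantaneous PGE2 release rate dP/dt (pg/ml/h) on the sampling grid."""
    return np.gradient(traj.P, traj.times)


# ---------------------------------------------------------------------------
# presets
#
# Rate constants are pinned by four calibration constraints on the shipped
# defaults, integrated rather than asserted: (1) 5-FU PGE2 fold change vs
# DMSO of 7.0 at 48 h; (2) cisplatin PGE2 release-rate peak at ~8 h;
# (3) reporter peak at ~24 h under cisplatin and ~48 h under 5-FU (cisplatin
# precedes 5-FU); (4) reporter decline once transcription shuts off in dying
# cells.  See docs/methods.md for the reasoning behind each value.

_CELL_PRESETS: dict[str, KineticParams] = {
    "4T1": KineticParams(),
    "4T1_COX2KO": KineticParams(alpha0=0.0),
    "4T1_COX2REST": KineticParams(inducible=False),
}

_DRUG_PRESETS: dict[str, DrugEffect] = {
    "DMSO": DrugEffect(name="DMSO", category="control"),
    # 100 uM 5-fluorouracil: slow ramp, sustained induction, late death
    "5FU_100uM": DrugEffect(
        name="5FU_100uM", category="pos_control",
        arrest=0.95, beta=19.14, tau_ind=16.0,
        t_death=30.0, k_d=0.08, k_n=0.05,
        t_shut=48.0, k_shut=0.3,
    ),
    # 50 uM cisplatin: fast ramp, early death onset, earlier shutoff
    "cisplatin_50uM": DrugEffect(
        name="cisplatin_50uM", category="reference",
        arrest=1.0, beta=8.0, tau_ind=2.5,
        t_death=5.0, k_d=0.22, k_n=0.1,
        t_shut=24.0, k_shut=0.5,
    ),
}


def presets(name: str) -> KineticParams | DrugEffect:
    """Documented default parameter sets for cell lines and treatments."""
    if name in _CELL_PRESETS:
        return _CELL_PRESETS[name]
    if name in _DRUG_PRESETS:
        return _DRUG_PRESETS[name]
    known = sorted(_CELL_PRESETS) + sorted(_DRUG_PRESETS)
    raise KeyError(f"unknown preset {name!r}; known presets: {', '.join(known)}")


def _with(effect: DrugEffect, **kw) -> DrugEffect:
    """Convenience: a modified copy of a preset effect."""
    return replace(effect, **kw)
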