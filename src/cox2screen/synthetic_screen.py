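"""Synthetic compound library, plate layouts, time series and rendered fields.

The generator emulates a 1280-compound approved-drug screen on 384-well
plates: only the inner 240 wells carry cells (the outer two rows and columns
are buffer), each plate carries nine vehicle (DMSO) and nine positive
(5-FU) control wells dispensed as triplets in the upper-left, center and
bottom-right of the inner region, and every well is imaged every 2 h for
72 h.

Ground-truth effect parameters per compound are drawn per therapeutic
category.  Cytostatic/cytotoxic categories (antineoplastic, anthelmintic)
use a coupled draw -- arrest ~ Beta(5, 2), beta = 1 + 9 * arrest^1.5 *
exp(eps), eps ~ Normal(0, 0.15) -- so that compounds which suppress growth
also induce the reporter; inert categories draw arrest ~ 0 and beta ~ 1 with
small noise.  Eight compounds are flagged as intrinsically fluorescent and
add a constant GCU offset from the first scan, mimicking the artifacts a
screen must exclude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .reporter_kinetics import (
    DrugEffect,
    KineticParams,
    default_grid,
    presets,
    simulate_wells,
)

__all__ = [
    "CompoundRecord",
    "LibrarySpec",
    "PlateLayout",
    "RenderParams",
    "ImagePair",
    "build_library",
    "build_plate_layouts",
    "generate_timeseries",
    "render_field",
    "library_to_frame",
    "layouts_to_frame",
    "GCU_KAPPA",
    "GCU_OFFSET",
    "AUTOFLUOR_GCU_OFFSET",
    "DEFAULT_AUTOFLUOR_ROSTER",
]

# fixed linear calibration from per-cell reporter units to Green Calibrated
# Units; chosen so a vehicle-treated reporter well reads ~0.3 GCU
GCU_KAPPA = 0.1165
GCU_OFFSET = 0.02
# constant intrinsic-fluorescence offset of flagged compounds, GCU
AUTOFLUOR_GCU_OFFSET = 1.0

ROW_LABELS = "ABCDEFGHIJKLMNOP"  # 16 rows
N_COLS = 24

#: compounds flagged as intrinsically fluorescent, with their category
DEFAULT_AUTOFLUOR_ROSTER: tuple[tuple[str, str], ...] = (
    ("Merbromin", "antibacterial"),
    ("Verteporfin", "other"),
    ("Pyrvinium pamoate", "anthelmintic"),
    ("1,8-Dihydroxyanthraquinone", "other"),
    ("Dipyridamole", "antihypertensive"),
    ("Quinacrine dihydrochloride hydrate", "other"),
    ("Propidium iodide", "other"),
    ("Chicago sky blue 6B", "other"),
)

#: categories whose compounds draw coupled (arrest, beta) effects
CYTOTOXIC_CATEGORIES = ("antineoplastic", "anthelmintic")


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    name: str
    category: str
    effect: DrugEffect
    autofluorescent: bool = False


@dataclass(frozen=True)
class LibrarySpec:
    """Composition and effect-parameter distributions of the synthetic library."""

    n_total: int = 1280
    # fractional categories (of n_total)
    proportions: tuple[tuple[str, float], ...] = (
        ("antibacterial", 0.13),
        ("anti-inflammatory", 0.08),
        ("antihypertensive", 0.08),
    )
    # fixed-count categories
    counts: tuple[tuple[str, int], ...] = (
        ("antineoplastic", 69),
        ("anthelmintic", 20),
    )
    other_category: str = "other"
    autofluor_roster: tuple[tuple[str, str], ...] = DEFAULT_AUTOFLUOR_ROSTER
    # copula for cytotoxic categories
    copula_beta_gain: float = 9.0
    copula_arrest_exp: float = 1.5
    copula_log_noise_sd: float = 0.15
    # induction ramp time constants, h (uniform draw)
    tau_ind_range: tuple[float, float] = (4.0, 8.0)
    # late-onset death of strong arresters: k_d = gain * arrest^exponent
    # starting at onset_h (cells that stop cycling eventually die)
    death_onset_h: float = 44.0
    death_rate_gain: float = 0.12
    death_arrest_exp: float = 10.0
    # inert-category noise
    inert_arrest_sd: float = 0.02
    inert_beta_sd: float = 0.05

    def category_counts(self) -> dict[str, int]:
        counts = {cat: int(round(f * self.n_total)) for cat, f in self.proportions}
        counts.update({cat: int(n) for cat, n in self.counts})
        used = sum(counts.values())
        if used > self.n_total:
            raise ValueError(
                f"category proportions/counts exceed library size "
                f"({used} > {self.n_total})")
        if used < self.n_total:
            counts[self.other_category] = counts.get(self.other_category, 0) \
                + (self.n_total - used)
        return counts


def _draw_effect(rng: np.random.Generator, spec: LibrarySpec, category: str,
                 name: str) -> DrugEffect:
    tau = float(rng.uniform(*spec.tau_ind_range))
    if category in CYTOTOXIC_CATEGORIES:
        arrest = float(rng.beta(5.0, 2.0))
        eps = float(rng.normal(0.0, spec.copula_log_noise_sd))
        beta = 1.0 + spec.copula_beta_gain * arrest ** spec.copula_arrest_exp \
            * math.exp(eps)
        # at the 10 uM screening dose arrest dominates; only near-complete
        # arresters progress to overt death late in the 72 h window
        k_d = spec.death_rate_gain * arrest ** spec.death_arrest_exp
        return DrugEffect(name=name, category=category, arrest=arrest,
                          beta=beta, tau_ind=tau,
                          t_death=spec.death_onset_h, k_d=k_d, k_n=0.08)
    arrest = float(min(abs(rng.normal(0.0, spec.inert_arrest_sd)), 1.0))
    beta = 1.0 + abs(rng.normal(0.0, spec.inert_beta_sd))
    return DrugEffect(name=name, category=category, arrest=arrest, beta=beta,
                      tau_ind=tau, t_death=200.0, k_d=0.0, k_n=0.1)


def build_library(spec: LibrarySpec | None = None, seed: int = 0) -> list[CompoundRecord]:
    """Deterministically generate the synthetic compound library.

    Pure function of (spec, seed): the same inputs always give the same
    records, including the ground-truth effect parameters.
    """
    spec = spec or LibrarySpec()
    rng = np.random.default_rng(seed)
    counts = spec.category_counts()

    categories: list[str] = []
    for cat, n in counts.items():
        categories.extend([cat] * n)

    # assign the autofluorescent roster to the first unclaimed compound of
    # the matching category
    roster_slots: dict[int, str] = {}
    taken: set[int] = set()
    for name, cat in spec.autofluor_roster:
        idx = next((i for i, c in enumerate(categories)
                    if c == cat and i not in taken), None)
        if idx is None:
            raise ValueError(f"autofluorescent roster category {cat!r} not in library")
        taken.add(idx)
        roster_slots[idx] = name

    records = []
    for i, cat in enumerate(categories):
        autofluor = i in roster_slots
        name = roster_slots[i] if autofluor else f"compound-{i + 1:04d}"
        effect = replace(_draw_effect(rng, spec, cat, name),
                         autofluorescent=autofluor)
        records.append(CompoundRecord(
            compound_id=f"CPD{i + 1:04d}", name=name, category=cat,
            effect=effect, autofluorescent=autofluor))
    return records


# ---------------------------------------------------------------------------
# plate layouts

@dataclass
class PlateLayout:
    """Role and compound assignment of one 384-well (16 x 24) plate."""

    plate_id: str
    roles: dict[str, str]                 # well -> role
    compounds: dict[str, str] = field(default_factory=dict)  # well -> compound_id

    def wells_with_role(self, role: str) -> list[str]:
        return sorted(w for w, r in self.roles.items() if r == role)


def well_name(row: int, col: int) -> str:
    return f"{ROW_LABELS[row]}{col + 1}"


# control triplet anchors inside the usable region (rows C..N, cols 3..22):
# upper-left, center (split over two rows) and bottom-right
_DMSO_WELLS = ("C3", "C4", "C5", "H12", "H13", "H14", "N20", "N21", "N22")
_POS_WELLS = ("D3", "D4", "D5", "I12", "I13", "I14", "M20", "M21", "M22")
COMPOUND_WELLS_PER_PLATE = 240 - len(_DMSO_WELLS) - len(_POS_WELLS)


def _base_layout(plate_id: str) -> tuple[PlateLayout, list[str]]:
    roles = {}
    inner = []
    for col in range(N_COLS):
        for row in range(len(ROW_LABELS)):
            w = well_name(row, col)
            if row < 2 or row >= 14 or col < 2 or col >= 22:
                roles[w] = "buffer"
            else:
                roles[w] = "empty"
                inner.append(w)  # column-major order
    for w in _DMSO_WELLS:
        roles[w] = "dmso_control"
    for w in _POS_WELLS:
        roles[w] = "pos_control"
    free = [w for w in inner if roles[w] == "empty"]
    return PlateLayout(plate_id=plate_id, roles=roles), free


def build_plate_layouts(library: list[CompoundRecord]) -> list[PlateLayout]:
    """Lay the library out over as many plates as needed (column-major fill)."""
    if not library:
        return []
    n_plates = math.ceil(len(library) / COMPOUND_WELLS_PER_PLATE)
    layouts = []
    it = iter(library)
    done = False
    for p in range(n_plates):
        layout, free = _base_layout(f"P{p + 1}")
        for w in free:
            rec = next(it, None)
            if rec is None:
                done = True
                break
            layout.roles[w] = "compound"
            layout.compounds[w] = rec.compound_id
        layouts.append(layout)
        if done:
            break
    return layouts


def library_to_frame(library: list[CompoundRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "compound_id": [r.compound_id for r in library],
        "name": [r.name for r in library],
        "category": [r.category for r in library],
        "arrest": [r.effect.arrest for r in library],
        "beta": [r.effect.beta for r in library],
        "tau_ind_h": [r.effect.tau_ind for r in library],
        "autofluorescent": [r.autofluorescent for r in library],
    })


def layouts_to_frame(layouts: list[PlateLayout]) -> pd.DataFrame:
    rows = []
    for lay in layouts:
        for w, role in sorted(lay.roles.items()):
            rows.append((lay.plate_id, w, role, lay.compounds.get(w, "")))
    return pd.DataFrame(rows, columns=["plate", "well", "role", "compound_id"])


# ---------------------------------------------------------------------------
# fast-path time series

def gcu_from_reporter(g: np.ndarray, autofluorescent: bool = False) -> np.ndarray:
    """Fixed linear calibration from per-cell reporter units to GCU."""
    g_gcu = GCU_KAPPA * np.asarray(g, dtype=float) + GCU_OFFSET
    if autofluorescent:
        g_gcu = g_gcu + AUTOFLUOR_GCU_OFFSET
    return g_gcu


def generate_timeseries(layouts: list[PlateLayout], library: list[CompoundRecord],
                        params: KineticParams | None = None, seed: int = 0, *,
                        grid: np.ndarray | None = None, noise_sd: float = 0.05,
                        field_count: int = 1) -> pd.DataFrame:
    """Per-well measured time series for every non-buffer well.

    Each well's trajectory comes from the kinetic model; the measurement is
    the trajectory's confluence and GCU observables under multiplicative
    log-normal noise (sd ``noise_sd`` per field, averaged over
    ``field_count`` fields).  Deterministic given (layouts, library, seed).
    """
    params = params or presets("4T1")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    by_id = {rec.compound_id: rec for rec in library}
    dmso = presets("DMSO")
    pos = presets("5FU_100uM")

    wells: list[tuple[str, str]] = []
    effects: list[DrugEffect] = []
    autofl: list[bool] = []
    for lay in layouts:
        for w in sorted(lay.roles):
            role = lay.roles[w]
            if role in ("buffer", "empty"):
                continue
            if role == "dmso_control":
                eff, af = dmso, False
            elif role == "pos_control":
                eff, af = pos, False
            else:
                cid = lay.compounds.get(w)
                rec = by_id.get(cid)
                if rec is None:
                    raise KeyError(
                        f"well {lay.plate_id}/{w} references unknown compound "
                        f"{cid!r}")
                eff, af = rec.effect, rec.autofluorescent
            wells.append((lay.plate_id, w))
            effects.append(eff)
            autofl.append(af)

    trajs = simulate_wells([params] * len(effects), effects, grid)
    rng = np.random.default_rng(seed)
    frames = []
    for (plate, w), traj, af in zip(wells, trajs, autofl):
        conf = traj.confluence
        gcu = gcu_from_reporter(traj.g, autofluorescent=af)
        noise = np.exp(rng.normal(0.0, 1.0, size=(2, field_count, grid.size)) * noise_sd)
        if noise_sd > 0:
            conf_meas = np.mean(conf * noise[0], axis=0)
            gcu_meas = np.mean(gcu * noise[1], axis=0)
        else:
            conf_meas, gcu_meas = conf, gcu
        frames.append(pd.DataFrame({
            "plate": plate, "well": w, "time_h": grid,
            "confluence_pct": np.clip(conf_meas, 0.0, 100.0),
            "gfp_mean_gcu": gcu_meas,
        }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["plate", "well", "time_h"], ignore_index=True)


# ---------------------------------------------------------------------------
# image rendering

@dataclass(frozen=True)
class RenderParams:
    shape: tuple[int, int] = (512, 512)
    um_per_px: float = 2.0
    cell_axis_um: tuple[float, float] = (12.0, 30.0)   # full axis lengths
    cell_gfp_log_sd: float = 0.3
    # smooth background: Gaussian random field, length scale >= 100 um
    background_sigma_um: float = 120.0
    background_amplitude_gcu: float = 0.15
    read_noise_gcu: float = 0.02
    precipitate_diam_um: tuple[float, float] = (12.0, 20.0)
    precipitate_gcu: tuple[float, float] = (0.5, 2.0)
    n_precipitates: int = 25
    phase_cell_level: float = 0.6
    phase_cell_speckle: float = 0.15
    phase_bg_noise: float = 0.005


@dataclass
class ImagePair:
    """Two-channel rendered field; values in GCU (green) / arbitrary (phase)."""

    phase: np.ndarray
    green: np.ndarray
    um_per_px: float

    def __post_init__(self):
        if self.phase.shape != self.green.shape:
            raise ValueError("phase and green channels must share a shape")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be > 0")

    def to_uint16(self, gain_gcu_per_count: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
        def conv(a):
            return np.clip(np.round(a / gain_gcu_per_count), 0, 65535).astype(np.uint16)
        return conv(self.phase), conv(self.green)


def _smooth_background(rng, shape, sigma_px, amplitude):
    from scipy.ndimage import gaussian_filter

    f = gaussian_filter(rng.normal(size=shape), sigma_px, mode="reflect")
    peak = np.max(np.abs(f)) or 1.0
    return (f / peak) * amplitude * 0.5 + amplitude * 0.5  # in [0, amplitude]


def _ellipse_mask(shape, cy, cx, ay, ax_, theta):
    """Bounding slice, boolean mask and normalized elliptical radius^2."""
    half = int(math.ceil(max(ay, ax_))) + 2
    y0, y1 = max(0, int(cy) - half), min(shape[0], int(cy) + half + 1)
    x0, x1 = max(0, int(cx) - half), min(shape[1], int(cx) + half + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = (ct * dx + st * dy) / ax_
    v = (-st * dx + ct * dy) / ay
    rho2 = u * u + v * v
    return (slice(y0, y1), slice(x0, x1)), rho2 <= 1.0, rho2


def render_field(n_cells: int, mean_gcu: float,
                 render_params: RenderParams | None = None, seed: int = 0, *,
                 autofluorescent: bool = False) -> tuple[ImagePair, pd.DataFrame]:
    """Render one two-channel field plus its ground-truth object table.

    Cells are domes (bright center, dimmer rim) placed without overlap;
    per-cell mean brightness is ``mean_gcu`` scaled by a log-normal factor.
    Returns the image pair and a table with one row per rendered object
    (kind, centroid in um, area in um^2, true mean GCU).
    """
    from scipy.ndimage import binary_dilation

    rp = render_params or RenderParams()
    rng = np.random.default_rng(seed)
    shape = rp.shape
    px_area = rp.um_per_px ** 2
    field_area = shape[0] * shape[1] * px_area

    requested = n_cells * math.pi * (sum(rp.cell_axis_um) / 4.0) ** 2
    if requested > field_area:
        raise ValueError(
            f"requested {n_cells} cells exceed 100% confluence for this field")

    occupied = np.zeros(shape, dtype=bool)
    green = _smooth_background(rng, shape, rp.background_sigma_um / rp.um_per_px,
                               rp.background_amplitude_gcu)
    phase = 0.25 + 0.5 * _smooth_background(
        rng, shape, rp.background_sigma_um / rp.um_per_px, 0.1)
    truth = []
    struct = np.ones((3, 3), dtype=bool)  # >= 1 px separation when sparse

    for i in range(n_cells):
        # placement tiers: separated (keeps objects resolvable), then merely
        # non-overlapping, then overlapping -- dense cultures do touch
        placed = False
        for attempt in range(401):
            ay = rng.uniform(*rp.cell_axis_um) / 2.0 / rp.um_per_px
            ax_ = rng.uniform(*rp.cell_axis_um) / 2.0 / rp.um_per_px
            theta = rng.uniform(0.0, math.pi)
            cy = rng.uniform(0, shape[0] - 1)
            cx = rng.uniform(0, shape[1] - 1)
            sl, mask, rho2 = _ellipse_mask(shape, cy, cx, ay, ax_, theta)
            if not mask.any():
                continue
            if attempt < 200:
                guard = binary_dilation(mask, structure=struct)
                if (occupied[sl] & guard).any():
                    continue
            elif attempt < 400:
                if (occupied[sl] & mask).any():
                    continue
            new_px = mask & ~occupied[sl]
            occupied[sl] |= mask
            cell_mean = mean_gcu * float(rng.lognormal(0.0, rp.cell_gfp_log_sd))
            profile = 1.0 - 0.7 * rho2[mask]
            profile *= cell_mean / profile.mean()
            green[sl][mask] += profile
            phase[sl][mask] = rp.phase_cell_level \
                + rng.normal(0.0, rp.phase_cell_speckle, size=int(mask.sum()))
            ys, xs = np.nonzero(mask)
            truth.append(("cell",
                          (xs.mean() + sl[1].start) * rp.um_per_px,
                          (ys.mean() + sl[0].start) * rp.um_per_px,
                          new_px.sum() * px_area, cell_mean))
            placed = True
            break
        assert placed  # the final tier always succeeds

    if autofluorescent:
        for _ in range(rp.n_precipitates):
            d = rng.uniform(*rp.precipitate_diam_um) / rp.um_per_px
            inten = rng.uniform(*rp.precipitate_gcu)
            cy = rng.uniform(0, shape[0] - 1)
            cx = rng.uniform(0, shape[1] - 1)
            sl, mask, _ = _ellipse_mask(shape, cy, cx, d / 2, d / 2, 0.0)
            if not mask.any():
                continue
            green[sl][mask] += inten
            ys, xs = np.nonzero(mask)
            truth.append(("precipitate",
                          (xs.mean() + sl[1].start) * rp.um_per_px,
                          (ys.mean() + sl[0].start) * rp.um_per_px,
                          mask.sum() * px_area, inten))

    green = np.maximum(green + rng.normal(0.0, rp.read_noise_gcu, size=shape), 0.0)
    phase = np.maximum(phase + rng.normal(0.0, rp.phase_bg_noise, size=shape), 0.0)

    truth_df = pd.DataFrame(truth, columns=["kind", "x_um", "y_um",
                                            "area_um2", "mean_gcu"])
    return ImagePair(phase=phase, green=green, um_per_px=rp.um_per_px), truth_df
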