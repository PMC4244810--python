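"""Ground-truthed synthetic time-lapse experiments.

Emulates multi-position brightfield + propidium-iodide (PI) imaging of
individual bacteria growing into microcolonies on agar: a 7x7 grid of
positions, 0-14 founder cells per field, per-cell lag-time and growth-rate
heterogeneity, elongating non-dividers, smooth (S-type) and rough (R-type,
internally holed) colony morphologies, colony merging, and PI-positive dead
cells appearing inside colonies.  Every image comes with an exact per-founder
truth mask, so segmentation, tracking, fitting and the survival statistics
can all be validated against known ground truth.

Colony rendering uses a deterministic pixel fill order per founder: the mask
at time t is exactly the first N(t) pixels of that order, where N(t) is the
rounded closed-form colony area.  Masks are therefore nested over time and
their pixel counts match the growth curve exactly (up to field clipping),
which makes truth-based oracles sharp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .baranyi import BaranyiParams, baranyi_y

__all__ = [
    "FateRecord",
    "SimulationParams",
    "paa_like_params",
    "sample_population",
    "colony_area_truth",
    "render_frame",
    "simulate_experiment",
    "PositionRenderer",
    "sample_death_positions",
]

Fate = Literal["grower", "elongater", "non_grower"]
Morphology = Literal["S", "R"]


# ---------------------------------------------------------------------------
# parameters


class LagDistribution(BaseModel):
    """Shifted log-normal single-cell lag time, hours."""

    shift: float = Field(default=1.0, ge=0)
    median: float = Field(default=3.0, gt=0)  # median of the log-normal part
    cv: float = Field(default=0.35, gt=0)


class MuDistribution(BaseModel):
    """Truncated normal maximum specific growth rate, ln pixels / hour."""

    mean: float = Field(default=0.45, gt=0)
    sd: float = Field(default=0.07, gt=0)
    lower: float = Field(default=0.1, gt=0)
    upper: float = Field(default=1.0, gt=0)


class IntensityModel(BaseModel):
    """8-bit rendering intensities; declared conventions, all configurable."""

    background_mean: float = 200.0
    background_sd: float = Field(default=8.0, ge=0)
    cell: float = 60.0
    pi_positive: float = 150.0
    pi_background: float = 5.0
    pi_background_sd: float = Field(default=2.0, ge=0)


class SimulationParams(BaseModel):
    """Full description of one synthetic experiment.

    Defaults emulate the untreated ("control") condition: nearly every
    founder grows, short heterogeneous lags, and mature microcolonies
    plateauing near exp(ymax) ~ 3.1e4 pixels.  Use :func:`paa_like_params`
    for an oxidant-stressed condition (fewer growers, long variable lags,
    slower growth).
    """

    grid_shape: tuple[int, int] = (7, 7)
    field_shape: tuple[int, int] = (512, 512)
    founders_per_field_mean: float = Field(default=6.0, gt=0)
    founders_per_field_max: int = Field(default=14, gt=0)
    grower_fraction: float = Field(default=0.95, ge=0, le=1)
    #: among non-growers, fraction that elongate a little without dividing
    elongater_fraction: float = Field(default=0.4, ge=0, le=1)
    lag: LagDistribution = LagDistribution()
    mu: MuDistribution = MuDistribution()
    #: stationary-phase plateau, ln pixels (exp(10.34) ~ 3.1e4 px)
    ymax: float = Field(default=10.34, gt=0)
    a0_range: tuple[float, float] = (20.0, 40.0)
    #: fraction of founders with smooth compact (S-type) morphology
    s_fraction: float = Field(default=0.5, ge=0, le=1)
    hole_fraction_range: tuple[float, float] = (0.05, 0.3)
    #: pre-division elongation of growers (length factor before lateral growth)
    elongation_factor_range: tuple[float, float] = (2.0, 3.0)
    extreme_elongation_prob: float = Field(default=0.05, ge=0, le=1)
    extreme_elongation_range: tuple[float, float] = (3.0, 6.0)
    #: elongaters: final/initial area factor and ramp duration (h)
    elongater_cap_range: tuple[float, float] = (1.1, 2.0)
    elongater_ramp_hours: tuple[float, float] = (5.0, 15.0)
    death_placement: Literal["uniform_in_colony", "center_biased"] = "uniform_in_colony"
    center_bias_strength: float = Field(default=3.0, gt=0)
    #: fraction of non-growing founders that eventually stain PI-positive
    nongrower_stain_prob: float = Field(default=0.3, ge=0, le=1)
    nongrower_stain_window: tuple[float, float] = (20.0, 48.0)
    #: in-colony deaths: Poisson mean per grower, appearing after the onset
    colony_death_onset: float = Field(default=40.0, ge=0)
    colony_deaths_mean: float = Field(default=3.0, ge=0)
    intensity: IntensityModel = IntensityModel()
    dt: float = Field(default=1.0, gt=0)
    horizon: float = Field(default=48.0, gt=0)
    margin: int = Field(default=20, ge=0)
    min_separation: float = Field(default=25.0, gt=0)
    #: Gompertz-truth mode for fit-robustness experiments
    model_mismatch: bool = False
    seed: int = Field(ge=0, lt=2**31)

    @model_validator(mode="after")
    def _check(self) -> "SimulationParams":
        if self.hole_fraction_range[1] > 0.3 + 1e-9:
            raise ValueError("hole_fraction must stay within [0, 0.3]")
        if self.a0_range[0] <= 0:
            raise ValueError("a0 must be positive")
        if self.lag.shift + 1e-9 < 0:
            raise ValueError("lag shift must be >= 0")
        return self

    @property
    def n_positions(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(0.0, self.horizon + 1e-9, self.dt)

    def position_ids(self) -> list[str]:
        r, c = self.grid_shape
        return [f"r{i}c{j}" for i in range(r) for j in range(c)]


def paa_like_params(seed: int, grower_fraction: float = 0.40) -> SimulationParams:
    """Oxidant-stressed condition: sparse survivors, long heterogeneous lags,
    depressed growth rates."""
    return SimulationParams(
        grower_fraction=grower_fraction,
        lag=LagDistribution(shift=2.0, median=20.0, cv=0.6),
        mu=MuDistribution(mean=0.30, sd=0.10, lower=0.05, upper=0.8),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ground truth records


@dataclass
class FateRecord:
    """Simulator ground truth for one founder cell."""

    founder_id: int
    position: str
    centroid: tuple[float, float]  # (row, col), pixels
    a0: float  # initial area, pixels
    fate: Fate
    morphology: Morphology
    lag: float  # h; 0 for non-growers
    mu_max: float  # ln px/h; 0 for non-growers
    ymax: float  # ln px
    pi_positive_time: float | None  # h, or None if the cell never stains
    hole_fraction: float  # 0 for S-type
    # rendering determinism
    elongation_factor: float = 2.5
    elongater_cap: float = 1.5
    ramp_hours: float = 10.0
    axis_angle: float = 0.0
    shape_seed: int = 0
    n_colony_deaths: int = 0

    def __post_init__(self) -> None:
        if self.fate == "grower":
            if self.lag < 0 or self.mu_max <= 0:
                raise ValueError("growers need lag >= 0 and mu_max > 0")
        if self.morphology == "S" and self.hole_fraction != 0:
            raise ValueError("S-type colonies carry no holes")
        if not (0 <= self.hole_fraction <= 0.3):
            raise ValueError("hole_fraction must lie in [0, 0.3]")
        if self.fate == "elongater" and not (1.0 <= self.elongater_cap <= 2.0):
            raise ValueError("elongater area cap must lie in [1, 2]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FateRecord":
        d = dict(d)
        d["centroid"] = tuple(d["centroid"])
        return cls(**d)


# ---------------------------------------------------------------------------
# population sampling


def _sample_lag(params: SimulationParams, rng: np.random.Generator, n: int) -> np.ndarray:
    sigma = math.sqrt(math.log(1.0 + params.lag.cv**2))
    return params.lag.shift + rng.lognormal(math.log(params.lag.median), sigma, size=n)


def _sample_mu(params: SimulationParams, rng: np.random.Generator, n: int) -> np.ndarray:
    mu = params.mu
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mu.mean, mu.sd, size=2 * (n - filled) + 8)
        ok = draw[(draw >= mu.lower) & (draw <= mu.upper)]
        take = min(len(ok), n - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def _sample_fates(params: SimulationParams, rng: np.random.Generator, n: int) -> list[str]:
    u = rng.random(n)
    fates = []
    for ui in u:
        if ui < params.grower_fraction:
            fates.append("grower")
        elif ui < params.grower_fraction + (1 - params.grower_fraction) * params.elongater_fraction:
            fates.append("elongater")
        else:
            fates.append("non_grower")
    return fates


def _place_founders(params: SimulationParams, rng: np.random.Generator, n: int):
    """Collision-free uniform placement with a field margin."""
    h, w = params.field_shape
    lo_r, hi_r = params.margin, h - params.margin
    lo_c, hi_c = params.margin, w - params.margin
    if hi_r <= lo_r or hi_c <= lo_c:
        raise ValueError("field too small for the configured margin")
    pts: list[tuple[float, float]] = []
    attempts = 0
    while len(pts) < n:
        attempts += 1
        if attempts > 200 * n + 200:
            raise ValueError("field too small for the requested founder density")
        p = (rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c))
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= params.min_separation**2 for q in pts):
            pts.append(p)
    return pts


def sample_population(params: SimulationParams, seed: int | None = None) -> list[FateRecord]:
    """Draw founder cells for every field of the grid.

    Placements are collision-free at time zero, per-field counts follow a
    Poisson law truncated at the configured maximum, and fates are i.i.d.
    draws from the grower/elongater/non-grower mix.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    records: list[FateRecord] = []
    fid = 0
    for pos in params.position_ids():
        n = int(min(rng.poisson(params.founders_per_field_mean), params.founders_per_field_max))
        pts = _place_founders(params, rng, n)
        fates = _sample_fates(params, rng, n)
        lags = _sample_lag(params, rng, n)
        mus = _sample_mu(params, rng, n)
        for k in range(n):
            fate = fates[k]
            morph: Morphology = "S" if rng.random() < params.s_fraction else "R"
            a0 = float(rng.uniform(*params.a0_range))
            hole = 0.0 if morph == "S" else float(rng.uniform(*params.hole_fraction_range))
            if rng.random() < params.extreme_elongation_prob:
                elong = float(rng.uniform(*params.extreme_elongation_range))
            else:
                elong = float(rng.uniform(*params.elongation_factor_range))
            cap = float(rng.uniform(*params.elongater_cap_range))
            ramp = float(rng.uniform(*params.elongater_ramp_hours))
            pi_time: float | None = None
            n_deaths = 0
            if fate == "grower":
                n_deaths = int(rng.poisson(params.colony_deaths_mean))
                if n_deaths > 0 and params.colony_death_onset < params.horizon:
                    pi_time = float(rng.uniform(params.colony_death_onset, params.horizon))
                else:
                    n_deaths = 0
            elif rng.random() < params.nongrower_stain_prob:
                lo, hi = params.nongrower_stain_window
                pi_time = float(rng.uniform(min(lo, params.horizon), min(hi, params.horizon)))
            records.append(FateRecord(
                founder_id=fid,
                position=pos,
                centroid=pts[k],
                a0=a0,
                fate=fate,  # type: ignore[arg-type]
                morphology=morph,
                lag=float(lags[k]) if fate == "grower" else 0.0,
                mu_max=float(mus[k]) if fate == "grower" else 0.0,
                ymax=params.ymax,
                pi_positive_time=pi_time,
                hole_fraction=hole,
                elongation_factor=elong,
                elongater_cap=cap,
                ramp_hours=ramp,
                axis_angle=float(rng.uniform(0, math.pi)),
                shape_seed=int(rng.integers(0, 2**31 - 1)),
                n_colony_deaths=n_deaths,
            ))
            fid += 1
    return records


# ---------------------------------------------------------------------------
# growth truth


def _gompertz_y(t: np.ndarray, y0: float, ymax: float, mu: float, lam: float) -> np.ndarray:
    d = ymax - y0
    return y0 + d * np.exp(-np.exp(mu * math.e / d * (lam - t) + 1.0))


def colony_area_truth(rec: FateRecord, t, params: SimulationParams | None = None):
    """Expected colony area (pixels) of a founder at time ``t`` hours.

    Growers follow the same growth law the fitter assumes (or a Gompertz
    curve in model-mismatch mode); elongaters follow a capped linear ramp;
    non-growers stay at their initial area.  PI-positive non-colony cells
    stop changing at their staining time.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    scalar = np.isscalar(t) or t_arr.ndim == 0

    if rec.fate == "non_grower":
        out = np.full_like(t_arr, rec.a0, dtype=float)
    elif rec.fate == "elongater":
        t_eff = t_arr if rec.pi_positive_time is None else np.minimum(t_arr, rec.pi_positive_time)
        frac = np.minimum(t_eff / rec.ramp_hours, 1.0)
        out = rec.a0 * (1.0 + (rec.elongater_cap - 1.0) * frac)
    else:
        y0 = math.log(rec.a0)
        if params is not None and params.model_mismatch:
            y = _gompertz_y(t_arr, y0, rec.ymax, rec.mu_max, rec.lag)
        else:
            p = BaranyiParams(y0=y0, ymax=rec.ymax, mu_max=rec.mu_max,
                              h0=rec.lag * rec.mu_max)
            y = np.asarray(baranyi_y(t_arr, p))
        out = np.exp(y)
    return float(out) if scalar else out


# ---------------------------------------------------------------------------
# rendering


class _FounderShape:
    """Precomputed deterministic pixel fill order for one founder.

    Fill phases: (1) a fixed-width rod extending along the cell axis until
    the pre-division elongation area is reached, so early growth is length
    extension; (2) lateral expansion in order of geodesic distance from the
    rod — isotropic for S-type, directionally cheapened (lobed) for R-type.
    Geodesic ordering guarantees that every prefix of the fill order is a
    single connected component.  R-type shapes carry interior excluded disks
    ("holes") that are never filled and that growth must route around, so
    the net mask area still equals the requested pixel count while the
    filled extent is larger.
    """

    ROD_WIDTH = 3.5  # px, typical rod cell width

    def __init__(self, rec: FateRecord, params: SimulationParams):
        self.rec = rec
        rng = np.random.default_rng(rec.shape_seed)
        if rec.fate == "grower":
            mature = math.exp(rec.ymax)
            elong_area = rec.a0 * rec.elongation_factor
        elif rec.fate == "elongater":
            mature = rec.a0 * rec.elongater_cap
            elong_area = mature
        else:
            mature = rec.a0
            elong_area = rec.a0

        # generous bounding box around the mature colony
        r_mat = math.sqrt(mature / math.pi)
        rod_half = 0.5 * max(elong_area, rec.a0) / self.ROD_WIDTH + 4
        half = int(math.ceil(max(r_mat * 1.7 + 6, rod_half)))
        self.half = half
        n_side = 2 * half + 1
        dr, dc = np.meshgrid(np.arange(-half, half + 1), np.arange(-half, half + 1),
                             indexing="ij")
        th = rec.axis_angle
        u = dr * math.cos(th) + dc * math.sin(th)
        v = -dr * math.sin(th) + dc * math.cos(th)
        r = np.hypot(dr, dc)

        # lobed radial metric for R-type, isotropic for S-type
        if rec.morphology == "R":
            ang = np.arctan2(v, u)
            f = np.ones_like(r)
            for k in range(2, 6):
                f += rng.uniform(0.04, 0.12) * np.cos(k * ang + rng.uniform(0, 2 * math.pi))
            f = np.clip(f, 0.45, None)
            blob_key = r / f
        else:
            blob_key = r

        # keep holes clear of the rod capsule so the elongation phase stays
        # connected
        rod_half_len = 0.5 * elong_area / self.ROD_WIDTH + 3.0
        rod_capsule = (np.abs(v) <= self.ROD_WIDTH / 2.0 + 1.5) & \
                      (np.abs(u) <= rod_half_len)
        excluded = np.zeros_like(r, dtype=bool)
        if rec.morphology == "R" and rec.hole_fraction > 0 and rec.fate == "grower":
            target = rec.hole_fraction * mature / (1.0 - rec.hole_fraction)
            carved = 0.0
            guard = 0
            while carved < target and guard < 200:
                guard += 1
                rho = rng.uniform(2.0, 5.0)
                rad = rng.uniform(0.2, 0.6) * r_mat
                angh = rng.uniform(0, 2 * math.pi)
                hr, hc = rad * math.sin(angh), rad * math.cos(angh)
                disk = (dr - hr) ** 2 + (dc - hc) ** 2 <= rho**2
                disk &= ~rod_capsule
                new = disk & ~excluded
                excluded |= disk
                carved += float(np.sum(new))

        flat_excl = excluded.ravel()
        rod_band = (np.abs(v) <= self.ROD_WIDTH / 2.0).ravel() & ~flat_excl
        rod_order = np.flatnonzero(rod_band)[np.argsort(np.abs(u).ravel()[rod_band],
                                                        kind="stable")]
        n_elong = min(int(round(elong_area)), len(rod_order))
        rod_idx = rod_order[:n_elong]

        # lateral phase: geodesic distance from the rod, scaled by the lobed
        # metric; every prefix of this order is connected and holes are
        # routed around rather than jumped over
        from skimage.graph import MCP_Geometric

        cost_field = np.where(excluded, np.inf, 1.0)
        if rec.morphology == "R":
            # cheaper travel along the lobes; blob_key = r / f so f = r / key
            with np.errstate(divide="ignore", invalid="ignore"):
                f = np.where(r > 0, r / np.maximum(blob_key, 1e-9), 1.0)
            cost_field = np.where(excluded, np.inf, 1.0 / np.clip(f, 0.45, None))
        starts = np.stack([rod_idx // n_side, rod_idx % n_side], axis=1)
        mcp = MCP_Geometric(cost_field)
        dist, _ = mcp.find_costs(starts=starts)
        flat_dist = dist.ravel()
        rest = np.isfinite(flat_dist)
        rest[rod_idx] = False
        rest_idx = np.flatnonzero(rest)
        rest_order = rest_idx[np.argsort(flat_dist[rest_idx], kind="stable")]
        self.order = np.concatenate([rod_idx, rest_order])
        self.n_side = n_side

        # in-colony death events: (time, rank fraction along the fill order)
        self.deaths: list[tuple[float, float]] = []
        if rec.fate == "grower" and rec.n_colony_deaths > 0 and rec.pi_positive_time is not None:
            times = np.sort(rng.uniform(rec.pi_positive_time, params.horizon + 1e-9,
                                        size=rec.n_colony_deaths))
            for td in times:
                u_ = rng.random()
                if params.death_placement == "center_biased":
                    x = 1.0 - (1.0 - u_) ** (1.0 / (params.center_bias_strength + 1.0))
                else:
                    x = u_
                self.deaths.append((float(td), float(x)))

    def n_pixels(self, t: float, params: SimulationParams) -> int:
        return min(int(round(colony_area_truth(self.rec, t, params))), len(self.order))

    def mask_indices(self, t: float, params: SimulationParams, shape: tuple[int, int]):
        """Field-frame (rows, cols) of the truth mask at time t, clipped."""
        n = self.n_pixels(t, params)
        idx = self.order[:n]
        rr = idx // self.n_side - self.half + int(round(self.rec.centroid[0]))
        cc = idx % self.n_side - self.half + int(round(self.rec.centroid[1]))
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        return rr[keep], cc[keep]

    def death_indices(self, t: float, params: SimulationParams, shape: tuple[int, int]):
        """Field-frame coordinates of dead cells visible at time t."""
        out_r, out_c = [], []
        for td, x in self.deaths:
            if t >= td:
                n_at = self.n_pixels(td, params)
                j = min(int(x * n_at), n_at - 1)
                idx = self.order[j]
                rr = idx // self.n_side - self.half + int(round(self.rec.centroid[0]))
                cc = idx % self.n_side - self.half + int(round(self.rec.centroid[1]))
                if 0 <= rr < shape[0] and 0 <= cc < shape[1]:
                    out_r.append(rr)
                    out_c.append(cc)
        return np.array(out_r, dtype=int), np.array(out_c, dtype=int)


class PositionRenderer:
    """Renders all frames of one imaging position from its fate records."""

    def __init__(self, records: list[FateRecord], params: SimulationParams):
        positions = {r.position for r in records}
        if len(positions) > 1:
            raise ValueError("records must all belong to one position")
        self.params = params
        self.records = records
        self.shapes = {r.founder_id: _FounderShape(r, params) for r in records}

    def truth_mask(self, founder_id: int, t: float) -> np.ndarray:
        mask = np.zeros(self.params.field_shape, dtype=bool)
        rr, cc = self.shapes[founder_id].mask_indices(t, self.params, self.params.field_shape)
        mask[rr, cc] = True
        return mask

    def truth_masks(self, t: float) -> dict[int, np.ndarray]:
        return {r.founder_id: self.truth_mask(r.founder_id, t) for r in self.records}

    def render(self, t: float, channel: str, seed: int | None = None):
        """Render one frame; returns (uint8 image, union truth mask)."""
        params = self.params
        inten = params.intensity
        shape = params.field_shape
        rng = np.random.default_rng(seed)
        union = np.zeros(shape, dtype=bool)
        for s in self.shapes.values():
            rr, cc = s.mask_indices(t, params, shape)
            union[rr, cc] = True

        if channel == "brightfield":
            img = np.full(shape, inten.background_mean, dtype=float)
            img[union] = inten.cell
            noise_sd = inten.background_sd
        elif channel == "pi":
            img = np.full(shape, inten.pi_background, dtype=float)
            for rec in self.records:
                s = self.shapes[rec.founder_id]
                if rec.fate != "grower":
                    if rec.pi_positive_time is not None and t >= rec.pi_positive_time:
                        rr, cc = s.mask_indices(t, params, shape)
                        img[rr, cc] = inten.pi_positive
                else:
                    dr_, dc_ = s.death_indices(t, params, shape)
                    for r0, c0 in zip(dr_, dc_):
                        rr = np.clip(np.arange(r0 - 1, r0 + 2), 0, shape[0] - 1)
                        cc = np.clip(np.arange(c0 - 1, c0 + 2), 0, shape[1] - 1)
                        blk = np.ix_(rr, cc)
                        img[blk] = np.where(union[blk], inten.pi_positive, img[blk])
            noise_sd = inten.pi_background_sd
        else:
            raise ValueError(f"unknown channel {channel!r}")

        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=shape)
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        return img, union


def render_frame(records: list[FateRecord], t: float, channel: str,
                 params: SimulationParams, seed: int | None = None):
    """One-shot frame rendering; see :class:`PositionRenderer`.

    Returns ``(image, truth_masks)`` where ``truth_masks`` maps founder id to
    its noise-free boolean mask.
    """
    rend = PositionRenderer(records, params)
    img, _ = rend.render(t, channel, seed)
    return img, rend.truth_masks(t)


def sample_death_positions(mask: np.ndarray, n: int, mode: str = "uniform_in_colony",
                           strength: float = 3.0,
                           rng: np.random.Generator | None = None) -> np.ndarray:
    """Sample ``n`` dead-cell pixel positions inside a colony mask.

    ``uniform_in_colony`` draws uniformly over foreground pixels;
    ``center_biased`` weights pixels by (1 - r)^strength where r is the
    normalized distance-transform rank (0 = deepest interior, 1 = boundary).
    Returns an (n, 2) array of (row, col).
    """
    from scipy.ndimage import distance_transform_edt

    rng = rng or np.random.default_rng()
    coords = np.argwhere(mask)
    if len(coords) == 0:
        raise ValueError("empty mask")
    if mode == "uniform_in_colony":
        idx = rng.integers(0, len(coords), size=n)
    elif mode == "center_biased":
        depth = distance_transform_edt(mask)[mask]
        sorted_d = np.sort(depth)
        r_hat = (len(depth) - np.searchsorted(sorted_d, depth, side="left")) / len(depth)
        w = (1.0 - r_hat) ** strength
        w /= w.sum()
        idx = rng.choice(len(coords), size=n, p=w)
    else:
        raise ValueError(f"unknown placement mode {mode!r}")
    return coords[idx]


# ---------------------------------------------------------------------------
# whole experiments


def simulate_experiment(params: SimulationParams, seed: int | None = None):
    """Simulate a full multi-position experiment.

    Returns ``(dataset, records)`` where the dataset holds every rendered
    frame and the records are the per-founder ground truth.  Identical
    (params, seed) give bit-identical output.
    """
    from .io import TimelapseDataset

    root = params.seed if seed is None else seed
    records = sample_population(params, seed=root)
    times = params.frame_times
    frames: dict[tuple[str, int, str], np.ndarray] = {}
    by_pos: dict[str, list[FateRecord]] = {p: [] for p in params.position_ids()}
    for rec in records:
        by_pos[rec.position].append(rec)
    for p_idx, pos in enumerate(params.position_ids()):
        rend = PositionRenderer(by_pos[pos], params)
        for t_idx, t in enumerate(times):
            for c_idx, channel in enumerate(("brightfield", "pi")):
                ss = np.random.SeedSequence([root, 1 + p_idx, t_idx, c_idx])
                img, _ = rend.render(float(t), channel, seed=ss.generate_state(1)[0])
                frames[(pos, t_idx, channel)] = img
    ds = TimelapseDataset(
        positions=params.position_ids(),
        grid_shape=params.grid_shape,
        frame_times=[float(t) for t in times],
        channels=["brightfield", "pi"],
        frames=frames,
        missing=set(),
        metadata={
            "frame_interval_h": params.dt,
            "pixel_scale": 1.0,
            "temperature": "23C",
            "pi_concentration": "2.0 ug/ml",
        },
    )
    ds.validate()
    return ds, records
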