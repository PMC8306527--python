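"""Stochastic agent-based simulation of a single germinal center.

The engine tracks every B cell of one GC through founder influx, dark-zone
division with somatic hypermutation, light-zone antigen collection from a
shared FDC antigen pool, competition for polarized Tfh help, asymmetric
division with antigen retention, plasma-cell output and apoptosis.

Space is reduced to well-mixed DZ/LZ compartments: FDC and Tfh encounters are
modeled as per-timestep contact opportunities rather than lattice migration.
FDC-held antigen decays slowly (degradation and consumption by non-GC
processes) and is released to B cells at a rate proportional to what the
FDCs still hold (a presentation-surface limit). The stock therefore falls
exponentially at a rate that is independent of selection stringency, and the
sustainable B-cell population tracks it downward — a gradual contraction
whose duration grows logarithmically with the initial loading (about 9 days
per e-fold), so heavily loaded GCs are long-lived. Encounter logic is isolated in ``_step_collection`` /
``_step_tfh_contact`` so a spatial backend could replace it without touching
the life-cycle bookkeeping.

All per-cell clocks are integer timestep counts, and antigen quantities are
dyadic rationals (integer portions halved at symmetric divisions), so the
antigen conservation audit holds exactly in floating point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from . import shape_space
from .shape_space import Epitope, FounderSpec

__all__ = [
    "GCParams",
    "BCell",
    "FDCPool",
    "GCRun",
    "GCState",
    "assign_divisions",
    "divide_cell",
    "collect_antigen",
    "tfh_interaction",
    "differentiate_or_recycle",
    "update_feedback",
    "init_gc",
    "influx_founders",
    "run_gc",
]

# cell life-cycle states
DIVIDING = 0  # DZ: counting down to the next division
COLLECTING = 1  # LZ: antigen collection window on FDCs
TFH_CONTACT = 2  # LZ: competing for polarized Tfh help
DEAD = 3  # tombstone; slot reclaimed at next compaction


class GCParams(BaseModel):
    """Complete parameterization of one GC run.

    Durations are hours, rates are per hour, antigen is in portions.
    """

    model_config = {"frozen": True}

    dt: float = Field(default=0.1, gt=0.0, description="timestep (h)")
    duration: float = Field(default=960.0, gt=0.0, description="simulated span (h)")
    influx_rate: float = Field(default=2.0, ge=0.0, description="founders per hour")
    influx_duration: float = Field(default=96.0, gt=0.0)
    founder_divisions: int = Field(default=6, ge=0)
    antigen_per_fdc: float = Field(default=3000.0, ge=0.0)
    n_fdc: int = Field(default=200, gt=0)
    n_tfh: int = Field(default=1000, gt=0)
    mutation_prob: float = Field(default=0.5, ge=0.0, le=1.0)
    collection_window: float = Field(default=0.7, gt=0.0)
    tfh_contact_duration: float = Field(default=0.6, gt=0.0)
    polarization_threshold: float = Field(default=0.5, gt=0.0)
    asymmetric_fraction: float = Field(default=0.72, ge=0.0, le=1.0)
    recycling_prob: float = Field(default=0.8, ge=0.0, le=1.0)
    feedback_strength: float = Field(default=0.0, ge=0.0, le=1.0)
    feedback_halfsat: float = Field(default=1000.0, gt=0.0)
    max_divisions: int = Field(default=3, ge=1)
    count_threshold: int = Field(default=100, ge=0)
    division_time_mean: float = Field(default=7.5, gt=0.0)
    division_time_cv: float = Field(default=0.2, ge=0.0)
    fdc_release_rate: float = Field(
        default=0.0001,
        gt=0.0,
        description="max fraction of the FDCs' current antigen released to B "
        "cells per hour (presentation-surface limit)",
    )
    fdc_decay_rate: float = Field(
        default=0.0046,
        ge=0.0,
        description="decay rate of FDC-held antigen (1/h); degradation and "
        "consumption by non-GC processes",
    )
    tfh_adjacency_prob: float = Field(
        default=0.72,
        gt=0.0,
        le=1.0,
        description="per-timestep probability a contacting B cell is adjacent "
        "to its Tfh (motility abstraction)",
    )
    affinity_width: float = Field(default=6.0, gt=0.0)
    shape_bound: int = Field(default=shape_space.DEFAULT_BOUND, gt=1)
    record_every: float = Field(default=6.0, gt=0.0)

    @model_validator(mode="after")
    def _check_clocks(self) -> "GCParams":
        if self.collection_window < self.dt:
            raise ValueError("collection_window must be >= dt")
        if self.tfh_contact_duration < self.dt:
            raise ValueError("tfh_contact_duration must be >= dt")
        if self.polarization_threshold > self.tfh_contact_duration:
            raise ValueError(
                "polarization_threshold must be <= tfh_contact_duration "
                "(no cell could ever be selected otherwise)"
            )
        return self

    # derived integer step counts
    @property
    def window_steps(self) -> int:
        return max(1, round(self.collection_window / self.dt))

    @property
    def contact_steps(self) -> int:
        return max(1, round(self.tfh_contact_duration / self.dt))

    @property
    def polar_steps_needed(self) -> int:
        # "polarized for at least `threshold`": accrued steps * dt >= threshold
        return math.ceil(self.polarization_threshold / self.dt - 1e-9)


@dataclass
class BCell:
    """Scalar B-cell agent used by the cell-level operation contracts.

    The vectorized engine stores the same fields in struct-of-arrays form.
    """

    id: int = 0
    zone: str = "DZ"
    state: str = "dividing"
    position: np.ndarray = field(default_factory=lambda: np.zeros(4, dtype=np.int64))
    divisions_left: int = 0
    antigen_collected: float = 0.0
    clock: float = 0.0
    polarization_time: float = 0.0
    target_epitope: Optional[int] = None


@dataclass
class FDCPool:
    """Shared FDC antigen pool, split per epitope.

    ``masked_fraction`` models antibody feedback: the share of each epitope's
    portions already covered by antibodies from the GC's own output.
    """

    initial: np.ndarray
    remaining: np.ndarray
    masked_fraction: np.ndarray
    plasma_weighted: np.ndarray  # affinity-weighted cumulative output per epitope

    @classmethod
    def from_params(cls, params: GCParams, epitopes: Sequence[Epitope]) -> "FDCPool":
        fractions = np.array([e.abundance_fraction for e in epitopes], dtype=float)
        total = params.antigen_per_fdc * params.n_fdc
        initial = total * fractions
        return cls(
            initial=initial,
            remaining=initial.copy(),
            masked_fraction=np.zeros_like(initial),
            plasma_weighted=np.zeros_like(initial),
        )

    @property
    def total_initial(self) -> float:
        return float(self.initial.sum())

    @property
    def total_remaining(self) -> float:
        return float(self.remaining.sum())


@dataclass
class GCRun:
    """Recorded output of one simulated GC."""

    times: np.ndarray  # hours since this GC's own initiation
    live_cells: np.ndarray
    cumulative_plasma: np.ndarray
    antigen_remaining: np.ndarray
    antigen_held: np.ndarray
    antigen_output: np.ndarray
    antigen_lost: np.ndarray
    antigen_decayed: np.ndarray
    plasma_by_epitope: np.ndarray
    n_founders: int
    init_time: float = 0.0
    seed: Optional[int] = None

    @property
    def volume_proxy(self) -> np.ndarray:
        """GC volume in arbitrary units: the live B-cell count."""
        return self.live_cells.astype(float)

    @property
    def record_dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    @property
    def total_plasma(self) -> int:
        return int(self.cumulative_plasma[-1])


# ---------------------------------------------------------------------------
# cell-level operations (scalar contracts; the vectorized engine mirrors them)
# ---------------------------------------------------------------------------


def assign_divisions(antigen_collected: float, params: GCParams) -> int:
    """Number of post-selection divisions earned by collected antigen.

    Monotone in the collected amount, at least 1, capped at ``max_divisions``:
    ``min(1 + floor(log2(1 + antigen)), max_divisions)``.
    """
    if antigen_collected < 1:
        raise ValueError("assign_divisions requires at least one collected portion")
    return int(min(1 + math.floor(math.log2(1 + antigen_collected)), params.max_divisions))


def _assign_divisions_vec(antigen: np.ndarray, params: GCParams) -> np.ndarray:
    nd = 1 + np.floor(np.log2(1.0 + antigen)).astype(np.int64)
    return np.minimum(nd, params.max_divisions)


def divide_cell(
    cell: BCell, params: GCParams, rng: np.random.Generator
) -> tuple[BCell, BCell]:
    """Divide one DZ B cell into two daughters.

    With probability ``asymmetric_fraction`` the division is asymmetric and one
    daughter inherits all collected antigen; otherwise the antigen splits
    equally. Each daughter's position is independently subjected to somatic
    hypermutation.
    """
    if cell.state != "dividing" or cell.divisions_left < 1:
        raise ValueError("divide_cell called on a cell that is not due to divide")
    asym = rng.random() < params.asymmetric_fraction
    a1 = cell.antigen_collected if asym else cell.antigen_collected / 2.0
    a2 = cell.antigen_collected - a1
    daughters = []
    for a in (a1, a2):
        pos = shape_space.mutate(
            cell.position, params.mutation_prob, rng, bound=params.shape_bound
        )
        daughters.append(
            BCell(
                zone="DZ",
                state="dividing",
                position=pos,
                divisions_left=cell.divisions_left - 1,
                antigen_collected=a,
                clock=_draw_division_hours(rng, params, 1)[0],
                target_epitope=cell.target_epitope,
            )
        )
    return daughters[0], daughters[1]


def collect_antigen(
    cell: BCell,
    fdc: FDCPool,
    epitopes: Sequence[Epitope],
    params: GCParams,
    rng: np.random.Generator,
) -> str:
    """One timestep of the LZ antigen-collection phase for one cell.

    Each step is one binding attempt: the cell engages an epitope with
    probability proportional to remaining portions weighted by its affinity
    (cognate capture), and binding succeeds with probability
    affinity x (1 - feedback_strength x masked_fraction), moving one portion
    onto the cell. An exhausted pool means every attempt fails. When the 0.7 h
    window expires the cell proceeds to seek Tfh help if it holds any antigen,
    and dies otherwise. (At population scale the engine additionally rations
    successful extractions to the FDCs' release capacity; for a single cell
    against a loaded pool that limit is never binding.)

    Returns ``"collected"``, ``"still_trying"`` or ``"failed"``.
    """
    if cell.state != "collecting":
        raise ValueError("collect_antigen called on a cell not in collection phase")
    if fdc.total_remaining >= 1.0:
        affs = np.array([
            shape_space.affinity(
                cell.position, ep, gamma=params.affinity_width,
                bound=params.shape_bound,
            )
            for ep in epitopes
        ])
        # cognate capture: engage an epitope with probability proportional to
        # its remaining portions weighted by the cell's affinity for it
        weights = affs * fdc.remaining
        weights = weights / weights.sum()
        e = int(rng.choice(len(epitopes), p=weights))
        p_success = affs[e] * (1.0 - params.feedback_strength * fdc.masked_fraction[e])
        if fdc.remaining[e] >= 1.0 and rng.random() < p_success:
            fdc.remaining[e] -= 1.0
            cell.antigen_collected += 1.0
            cell.target_epitope = e
    cell.clock -= params.dt
    if cell.clock > 1e-9:
        return "still_trying"
    if cell.antigen_collected > 0:
        cell.state = "tfh_contact"
        cell.clock = params.tfh_contact_duration
        cell.polarization_time = 0.0
        return "collected"
    cell.state = "dead"
    return "failed"


def tfh_interaction(
    cells_in_contact: Sequence[BCell],
    params: GCParams,
    rng: np.random.Generator,
) -> List[bool]:
    """Resolve one Tfh's full 36-min contact with a set of B cells.

    Each timestep the Tfh polarizes to the contact-set member with the highest
    collected antigen (ties uniformly at random), which accrues ``dt`` of
    polarization time. A cell is selected iff its accrued polarization reaches
    the polarization threshold by the end of the contact. Returns a selected
    flag per cell, in input order.

    This is the idealized continuous-contact contract: a lone B cell held in
    contact for the full duration is always selected. In the population
    engine, adjacency within the contact window is additionally sampled per
    timestep (``tfh_adjacency_prob``), standing in for B/Tfh motility.
    """
    cells = list(cells_in_contact)
    if any(c.antigen_collected < 1 for c in cells):
        raise ValueError("every B cell in Tfh contact must hold collected antigen")
    polar_steps = np.zeros(len(cells), dtype=int)
    antigen = np.array([c.antigen_collected for c in cells])
    for _ in range(params.contact_steps):
        best = antigen.max()
        contenders = np.nonzero(antigen == best)[0]
        winner = int(rng.choice(contenders))
        polar_steps[winner] += 1
    selected = polar_steps >= params.polar_steps_needed
    for c, steps, sel in zip(cells, polar_steps, selected):
        c.polarization_time = steps * params.dt
        c.state = "selected" if sel else "dead"
    return [bool(s) for s in selected]


def differentiate_or_recycle(
    cell: BCell, params: GCParams, rng: np.random.Generator
) -> str:
    """Fate of a terminal daughter after post-selection division rounds.

    The antigen-retaining daughter (at least one full portion) differentiates
    into a plasma-cell precursor. A non-retaining daughter re-enters the LZ
    unselected state with probability ``recycling_prob`` (its residual antigen
    is cleared: it was delivered during the Tfh interaction), and otherwise
    exits by death/loss.
    """
    if cell.antigen_collected >= 1.0:
        cell.state = "output_precursor"
        return "output_precursor"
    if rng.random() < params.recycling_prob:
        cell.state = "collecting"
        cell.antigen_collected = 0.0
        cell.clock = params.collection_window
        return "recycled"
    cell.state = "dead"
    return "lost"


def update_feedback(fdc: FDCPool, params: GCParams) -> None:
    """Refresh masked fractions from affinity-weighted cumulative plasma output.

    Saturating form m = P_w / (P_w + K) per epitope; non-decreasing over time
    because P_w only accumulates.
    """
    pw = fdc.plasma_weighted
    fdc.masked_fraction = pw / (pw + params.feedback_halfsat)


# ---------------------------------------------------------------------------
# vectorized engine
# ---------------------------------------------------------------------------


def _draw_division_hours(
    rng: np.random.Generator, params: GCParams, size: int
) -> np.ndarray:
    """Division cycle times: gamma with mean ``division_time_mean`` and the
    configured CV (constant when CV = 0)."""
    if params.division_time_cv <= 0:
        return np.full(size, params.division_time_mean)
    shape = 1.0 / params.division_time_cv**2
    scale = params.division_time_mean / shape
    return rng.gamma(shape, scale, size=size)


def _draw_division_steps(
    rng: np.random.Generator, params: GCParams, size: int
) -> np.ndarray:
    hours = _draw_division_hours(rng, params, size)
    return np.maximum(1, np.round(hours / params.dt)).astype(np.int32)


class _CellArrays:
    """Struct-of-arrays store for the live cell population."""

    def __init__(self, cap: int = 2048):
        self.n = 0
        self.state = np.full(cap, DEAD, dtype=np.int8)
        self.pos = np.zeros((cap, 4), dtype=np.int8)
        self.clock = np.zeros(cap, dtype=np.int32)
        self.ndiv = np.zeros(cap, dtype=np.int8)
        self.antigen = np.zeros(cap, dtype=np.float64)
        self.tfh = np.full(cap, -1, dtype=np.int16)
        self.polar = np.zeros(cap, dtype=np.int16)
        self.postsel = np.zeros(cap, dtype=bool)
        self.tgt = np.full(cap, -1, dtype=np.int8)

    @property
    def cap(self) -> int:
        return self.state.shape[0]

    def _grow(self, need: int) -> None:
        new_cap = self.cap
        while new_cap < need:
            new_cap *= 2
        for name in ("state", "clock", "ndiv", "antigen", "tfh", "polar", "postsel", "tgt"):
            old = getattr(self, name)
            fill = DEAD if name == "state" else (-1 if name in ("tfh", "tgt") else 0)
            new = np.full(new_cap, fill, dtype=old.dtype)
            new[: self.n] = old[: self.n]
            setattr(self, name, new)
        new_pos = np.zeros((new_cap, 4), dtype=np.int8)
        new_pos[: self.n] = self.pos[: self.n]
        self.pos = new_pos

    def append(self, m: int) -> np.ndarray:
        """Reserve m slots at the tail; returns their indices."""
        if self.n + m > self.cap:
            self._grow(self.n + m)
        idx = np.arange(self.n, self.n + m)
        self.n += m
        return idx

    def alive_mask(self) -> np.ndarray:
        return self.state[: self.n] != DEAD

    def n_alive(self) -> int:
        return int(np.count_nonzero(self.alive_mask()))

    def compact(self) -> None:
        keep = np.nonzero(self.alive_mask())[0]
        m = keep.size
        for name in ("state", "clock", "ndiv", "antigen", "tfh", "polar", "postsel", "tgt"):
            arr = getattr(self, name)
            arr[:m] = arr[keep]
            if name == "state":
                arr[m : self.n] = DEAD
        self.pos[:m] = self.pos[keep]
        self.n = m


class GCState:
    """Full mutable state of one in-flight GC simulation."""

    def __init__(
        self,
        params: GCParams,
        epitopes: Sequence[Epitope],
        founder_spec: FounderSpec,
        rng: np.random.Generator,
    ):
        shape_space.validate_epitopes(epitopes, bound=params.shape_bound)
        self.params = params
        self.epitopes = list(epitopes)
        self.founder_spec = founder_spec
        self.rng = rng
        self.pool = FDCPool.from_params(params, epitopes)
        self.cells = _CellArrays()
        self.optima = np.stack([e.optimum for e in epitopes]).astype(np.int64)
        self._founder_candidates = shape_space.founder_candidates(
            founder_spec, epitopes, bound=params.shape_bound
        )
        self.t = 0.0
        self.n_founders = 0
        self.cum_plasma = 0
        self.plasma_by_epitope = np.zeros(len(epitopes), dtype=np.int64)
        self.antigen_output = 0.0
        self.antigen_lost = 0.0
        self.antigen_decayed = 0.0
        self._decay_prob = 1.0 - math.exp(-params.fdc_decay_rate * params.dt)

    # -- founder influx ----------------------------------------------------

    def influx(self, t: float) -> int:
        """Poisson founder arrivals for the step starting at time t."""
        p = self.params
        if t >= p.influx_duration - 1e-12:
            return 0
        k = int(self.rng.poisson(p.influx_rate * p.dt))
        if k == 0:
            return 0
        pos = shape_space.sample_founders(
            k, self.founder_spec, self.epitopes, self.rng, bound=p.shape_bound,
            candidates=self._founder_candidates,
        )
        idx = self.cells.append(k)
        c = self.cells
        c.pos[idx] = pos
        c.antigen[idx] = 0.0
        c.postsel[idx] = False
        c.tgt[idx] = -1
        c.polar[idx] = 0
        c.tfh[idx] = -1
        if p.founder_divisions >= 1:
            c.state[idx] = DIVIDING
            c.ndiv[idx] = p.founder_divisions
            c.clock[idx] = _draw_division_steps(self.rng, p, k)
        else:
            c.state[idx] = COLLECTING
            c.ndiv[idx] = 0
            c.clock[idx] = p.window_steps
        self.n_founders += k
        return k

    # -- division ----------------------------------------------------------

    def _step_division(self) -> None:
        c, p, rng = self.cells, self.params, self.rng
        idx = np.nonzero(c.state[: c.n] == DIVIDING)[0]
        if idx.size == 0:
            return
        c.clock[idx] -= 1
        ripe = idx[c.clock[idx] <= 0]
        if ripe.size == 0:
            return
        m = ripe.size
        par_pos = c.pos[ripe].astype(np.int64)
        par_ant = c.antigen[ripe]
        par_nd = c.ndiv[ripe].astype(np.int64)
        par_post = c.postsel[ripe]
        par_tgt = c.tgt[ripe]
        asym = rng.random(m) < p.asymmetric_fraction
        a1 = np.where(asym, par_ant, par_ant / 2.0)
        a2 = par_ant - a1
        c.state[ripe] = DEAD
        d_pos = shape_space.mutate_many(
            np.concatenate([par_pos, par_pos], axis=0), p.mutation_prob, rng,
            bound=p.shape_bound,
        )
        d_ant = np.concatenate([a1, a2])
        d_nd = np.concatenate([par_nd - 1, par_nd - 1])
        d_post = np.concatenate([par_post, par_post])
        d_tgt = np.concatenate([par_tgt, par_tgt])
        self._route_daughters(d_pos, d_ant, d_nd, d_post, d_tgt)

    def _route_daughters(self, pos, ant, nd, post, tgt) -> None:
        c, p, rng = self.cells, self.params, self.rng
        m = pos.shape[0]
        keep_state = np.empty(m, dtype=np.int8)
        keep = np.ones(m, dtype=bool)

        cont = nd >= 1
        keep_state[cont] = DIVIDING
        term = ~cont
        founder_term = term & ~post
        keep_state[founder_term] = COLLECTING  # acquire LZ phenotype
        post_term = term & post
        if np.any(post_term):
            retain = post_term & (ant >= 1.0)
            if np.any(retain):
                # plasma-cell output: exits immediately, antigen leaves with it
                n_out = int(np.count_nonzero(retain))
                self.cum_plasma += n_out
                self.antigen_output += float(ant[retain].sum())
                out_tgt = tgt[retain].astype(np.int64)
                out_pos = pos[retain]
                for e in np.unique(out_tgt):
                    sel = out_tgt == e
                    self.plasma_by_epitope[e] += int(np.count_nonzero(sel))
                    if p.feedback_strength > 0:
                        aff = shape_space.affinity_many(
                            out_pos[sel], self.optima[e], gamma=p.affinity_width
                        )
                        self.pool.plasma_weighted[e] += float(aff.sum())
                keep[retain] = False
            nonretain = post_term & (ant < 1.0)
            if np.any(nonretain):
                self.antigen_lost += float(ant[nonretain].sum())
                ant[nonretain] = 0.0
                recycle = nonretain & (rng.random(m) < p.recycling_prob)
                keep_state[recycle] = COLLECTING
                keep[nonretain & ~recycle] = False

        idx = c.append(int(np.count_nonzero(keep)))
        c.pos[idx] = pos[keep]
        c.antigen[idx] = ant[keep]
        c.ndiv[idx] = nd[keep]
        c.postsel[idx] = post[keep]
        c.tgt[idx] = tgt[keep]
        c.polar[idx] = 0
        c.tfh[idx] = -1
        st = keep_state[keep]
        c.state[idx] = st
        div_new = st == DIVIDING
        if np.any(div_new):
            c.clock[idx[div_new]] = _draw_division_steps(
                rng, p, int(np.count_nonzero(div_new))
            )
        col_new = st == COLLECTING
        c.clock[idx[col_new]] = p.window_steps

    # -- antigen collection --------------------------------------------------

    def _step_collection(self) -> None:
        c, p, rng = self.cells, self.params, self.rng
        idx = np.nonzero(c.state[: c.n] == COLLECTING)[0]
        if idx.size == 0:
            return
        pool = self.pool
        if pool.total_remaining >= 1.0:
            att = idx
            rem = pool.remaining
            n_ep = len(self.epitopes)
            if n_ep == 1:
                choice = np.zeros(att.size, dtype=np.int64)
                aff_all = shape_space.affinity_many(
                    c.pos[att].astype(np.int64), self.optima[0], gamma=p.affinity_width
                )[:, None]
            else:
                # a B cell engages the epitope it can actually bind among
                # those displayed: cognate capture weights availability by
                # affinity, so cells do not spend attempts on antigen their
                # BCR cannot extract
                aff_all = np.stack(
                    [
                        shape_space.affinity_many(
                            c.pos[att].astype(np.int64), self.optima[e],
                            gamma=p.affinity_width,
                        )
                        for e in range(n_ep)
                    ],
                    axis=1,
                )
                w = aff_all * rem[None, :]
                cum = np.cumsum(w, axis=1)
                draw = rng.random(att.size) * cum[:, -1]
                choice = np.minimum((draw[:, None] >= cum).sum(axis=1), n_ep - 1)
            u = rng.random(att.size)
            for e in range(n_ep):
                sel = choice == e
                grp = att[sel]
                ug = u[sel]
                if grp.size == 0:
                    continue
                aff = aff_all[sel, e]
                prob = aff * (1.0 - p.feedback_strength * pool.masked_fraction[e])
                winners = grp[ug < prob]
                # FDCs release at most a fraction release_rate*dt of their
                # current antigen per step (presentation-surface limit);
                # excess successful binders are rationed at random
                cap_f = p.fdc_release_rate * rem[e] * p.dt
                cap = int(cap_f) + (1 if rng.random() < cap_f - int(cap_f) else 0)
                cap = min(cap, int(rem[e]))
                if winners.size > cap:
                    winners = rng.permutation(winners)[:cap]
                if winners.size:
                    c.antigen[winners] += 1.0
                    c.tgt[winners] = e
                    pool.remaining[e] -= winners.size
        c.clock[idx] -= 1
        done = idx[c.clock[idx] <= 0]
        if done.size:
            got = c.antigen[done] > 0
            ok = done[got]
            fail = done[~got]
            if ok.size:
                c.state[ok] = TFH_CONTACT
                c.tfh[ok] = rng.integers(0, p.n_tfh, size=ok.size)
                c.polar[ok] = 0
                c.clock[ok] = p.contact_steps
            if fail.size:
                c.state[fail] = DEAD  # failed collectors carry no antigen

    # -- Tfh competition -----------------------------------------------------

    def _step_tfh_contact(self) -> None:
        c, p, rng = self.cells, self.params, self.rng
        idx = np.nonzero(c.state[: c.n] == TFH_CONTACT)[0]
        if idx.size == 0:
            return
        # motility abstraction: a contacting B cell is physically adjacent to
        # its Tfh only part of the time; polarized help accrues only to the
        # adjacent contender with the most antigen (ties uniformly at random)
        adj = idx[rng.random(idx.size) < p.tfh_adjacency_prob]
        if adj.size:
            ant = c.antigen[adj]
            tf = c.tfh[adj]
            order = np.lexsort((rng.random(adj.size), ant, tf))
            tf_sorted = tf[order]
            is_last = np.empty(adj.size, dtype=bool)
            is_last[:-1] = tf_sorted[1:] != tf_sorted[:-1]
            is_last[-1] = True
            winners = adj[order[is_last]]
            c.polar[winners] += 1
        c.clock[idx] -= 1
        done = idx[c.clock[idx] <= 0]
        if done.size == 0:
            return
        sel_mask = c.polar[done] >= p.polar_steps_needed
        selected = done[sel_mask]
        rejected = done[~sel_mask]
        if rejected.size:
            self.antigen_lost += float(c.antigen[rejected].sum())
            c.state[rejected] = DEAD
        if selected.size:
            c.state[selected] = DIVIDING
            c.postsel[selected] = True
            c.ndiv[selected] = _assign_divisions_vec(c.antigen[selected], p)
            c.clock[selected] = _draw_division_steps(rng, p, selected.size)

    # -- audit ---------------------------------------------------------------

    def antigen_held(self) -> float:
        c = self.cells
        alive = c.alive_mask()
        return float(c.antigen[: c.n][alive].sum())

    def _step_antigen_decay(self) -> None:
        """FDC-held antigen degrades; each remaining portion survives a step
        with probability exp(-decay_rate * dt) (integer bookkeeping)."""
        if self._decay_prob <= 0.0:
            return
        rem = self.pool.remaining
        for e in range(len(self.epitopes)):
            n = int(rem[e])
            if n > 0:
                d = int(self.rng.binomial(n, self._decay_prob))
                rem[e] -= d
                self.antigen_decayed += d

    def step(self, t: float) -> None:
        """Advance the GC by one timestep starting at simulation time t."""
        self.influx(t)
        self._step_division()
        self._step_collection()
        self._step_tfh_contact()
        self._step_antigen_decay()
        if self.params.feedback_strength > 0:
            update_feedback(self.pool, self.params)
        self.t = t + self.params.dt
        c = self.cells
        if c.n > 4096 and c.n_alive() < c.n // 2:
            c.compact()


def init_gc(
    params: GCParams,
    epitopes: Sequence[Epitope],
    founder_spec: FounderSpec,
    rng: np.random.Generator,
) -> GCState:
    """Construct the initial GC state: empty B-cell pool, fully loaded FDC
    pool, armed influx process."""
    return GCState(params, epitopes, founder_spec, rng)


def influx_founders(
    state: GCState, params: GCParams, rng: np.random.Generator, t: float
) -> int:
    """Founder arrivals for one step (Poisson influx while t < influx_duration)."""
    assert state.params is params or params == state.params
    return state.influx(t)


def run_gc(
    params: GCParams,
    epitopes: Sequence[Epitope],
    founder_spec: FounderSpec,
    seed: int,
    init_time: float = 0.0,
) -> GCRun:
    """Simulate one GC for ``params.duration`` hours; deterministic given seed.

    Time series are recorded every ``params.record_every`` hours, starting at
    time 0. Once the GC is extinct and founder influx has ended the remaining
    records are filled with zeros without stepping the engine.
    """
    rng = np.random.default_rng(seed)
    state = GCState(params, epitopes, founder_spec, rng)
    dt = params.dt
    n_steps = round(params.duration / dt)
    rec_steps = max(1, round(params.record_every / dt))
    times, live, plasma, remaining = [0.0], [0], [0], [state.pool.total_remaining]
    held, out, lost, decayed = [0.0], [0.0], [0.0], [0.0]
    extinct_at = None
    for istep in range(n_steps):
        t = istep * dt
        state.step(t)
        if (istep + 1) % rec_steps == 0:
            n_alive = state.cells.n_alive()
            times.append((istep + 1) * dt)
            live.append(n_alive)
            plasma.append(state.cum_plasma)
            remaining.append(state.pool.total_remaining)
            held.append(state.antigen_held())
            out.append(state.antigen_output)
            lost.append(state.antigen_lost)
            decayed.append(state.antigen_decayed)
            if n_alive == 0 and t >= params.influx_duration:
                extinct_at = istep + 1
                break
    if extinct_at is not None:
        k = extinct_at
        while k < n_steps:
            k += rec_steps
            if k > n_steps:
                break
            times.append(k * dt)
            live.append(0)
            plasma.append(state.cum_plasma)
            remaining.append(state.pool.total_remaining)
            held.append(0.0)
            out.append(state.antigen_output)
            lost.append(state.antigen_lost)
            decayed.append(state.antigen_decayed)
    return GCRun(
        times=np.asarray(times),
        live_cells=np.asarray(live, dtype=np.int64),
        cumulative_plasma=np.asarray(plasma, dtype=np.int64),
        antigen_remaining=np.asarray(remaining),
        antigen_held=np.asarray(held),
        antigen_output=np.asarray(out),
        antigen_lost=np.asarray(lost),
        antigen_decayed=np.asarray(decayed),
        plasma_by_epitope=state.plasma_by_epitope.copy(),
        n_founders=state.n_founders,
        init_time=init_time,
        seed=seed,
    )
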