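"""The in-silico experiment battery.

Encodes the seven experiments the model must reproduce as config-driven
protocols with declarative outcome predicates and seed-ensemble statistics:

========  =======================================================================
E1        unperturbed symmetry breaking: one BMP4 and one Vg1 domain at
          opposite poles (bipolar), strongly anticorrelated
E2        BMP4 bead grafted at the realized Vg1 pole (posterior): Vg1
          suppressed in the footprint, exactly two lateral streaks
E3        BMP4 bead at the antipode (anterior): local Vg1 *induction* (the
          paradoxical effect) and local F_B increase
E4        four equispaced BMP4 beads: streaks form spaced away from beads
E5        Vg1-cell pellet anteriorly: local Vg1 induction and BMP4 suppression
E6        F_B (Gata2) knockdown in the BMP4 domain: local BMP4 downregulation
E7        fragmentation into four sealed arcs before symmetry breaking:
          every fragment develops its own Vg1 domain (twinning)
========  =======================================================================

Perturbation experiments (E2–E6) first run the unperturbed dynamics until
the pattern is established, place the manipulation relative to the realized
pattern (posterior := Vg1-domain centroid, anterior := its antipode — the
model is rotation-equivariant, so position only makes sense relative to
each run's own axis), then score fold-changes of the perturbed continuation
against the same seed's pre-manipulation expression map (paired, never
absolute; the pre-graft state is the tighter control because the
unperturbed pattern's position slowly wanders).  Vg1 induction is read as
the peak over the readout zone — a bright patch of upregulation, the way
in-situ stainings are scored — while suppressions are read as zone means.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .metrics import PatternSummary, call_domains_state, summarize
from .model import homogeneous_steady_states, launch_state
from .params import ModelParameters
from .perturbations import Perturbation, footprint, make_bead, make_knockdown, make_pellet
from .simulate import apply_fragmentation, initialize, integrate
from .state import EmbryoState

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentProtocol", "ExperimentResult", "SeedOutcome",
    "run_experiment", "default_protocols", "calibrate",
    "v_on_level", "streak_threshold",
    "PREDICATES",
]

#: fraction of seeds that must satisfy the outcome predicate for a pass
PASS_FRACTION = 0.8
#: fold-changes defining "induced" / "suppressed" relative to matched control
INDUCTION_FOLD = 2.0
SUPPRESSION_FOLD = 0.5


def v_on_level(params: ModelParameters) -> float:
    """Vg1 level of the 'V-on' uniform attractor (the largest V* over the
    uniform fixed points); sets the model's own expression scale."""
    states = homogeneous_steady_states(params)
    v_max = max(q[1] for q in states)
    if v_max <= 0:
        raise ValueError("parameter set has no uniform state with Vg1 expressed")
    return v_max


def streak_threshold(params: ModelParameters) -> float:
    """Absolute Vg1 threshold for streak calls: half the V-on level, tying
    streak prediction to model scale rather than per-run maxima."""
    return 0.5 * v_on_level(params)


# ---------------------------------------------------------------------------
# Protocol and results

@dataclass(frozen=True)
class ExperimentProtocol:
    """One experiment: parameters, perturbation plan, ensemble size, and the
    named outcome predicate with its expected verdict."""

    id: str
    params: ModelParameters
    predicate: str
    n_seeds: int = 20
    t_end: float = 1200.0
    t_post: float = 400.0          # extra time after placing a perturbation
    dt: float = 0.1
    record_every: float = 100.0
    bead_strength: float | None = None   # None = calibrated default
    bead_radius: int = 3
    knockdown_efficiency: float = 0.9
    n_fragments: int = 4
    n_beads: int = 4

    def __post_init__(self) -> None:
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if self.predicate not in PREDICATES:
            raise ValueError(f"unknown outcome predicate {self.predicate!r}; "
                             f"known: {sorted(PREDICATES)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = self.params.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentProtocol":
        d = dict(d)
        d["params"] = ModelParameters.from_dict(d["params"])
        return cls(**d)


@dataclass
class SeedOutcome:
    """One seed's readouts: summaries of the perturbed final state and (for
    perturbation experiments) the matched control, plus local means."""

    seed: int
    passed: bool
    summary: PatternSummary
    control_summary: PatternSummary | None = None
    detail: dict = field(default_factory=dict)


@dataclass
class ExperimentResult:
    protocol: ExperimentProtocol
    outcomes: list[SeedOutcome]

    @property
    def pass_fraction(self) -> float:
        return sum(o.passed for o in self.outcomes) / len(self.outcomes)

    @property
    def verdict(self) -> bool:
        return self.pass_fraction >= PASS_FRACTION

    def to_dict(self) -> dict:
        return {
            "id": self.protocol.id,
            "n_seeds": len(self.outcomes),
            "pass_fraction": self.pass_fraction,
            "verdict": bool(self.verdict),
            "outcomes": [
                {"seed": o.seed, "passed": o.passed,
                 "summary": o.summary.to_dict(),
                 "control_summary": (o.control_summary.to_dict()
                                     if o.control_summary else None),
                 "detail": o.detail}
                for o in self.outcomes
            ],
        }


# ---------------------------------------------------------------------------
# Geometry helpers

def _posterior_cell(state: EmbryoState, params: ModelParameters) -> int | None:
    """Cell index of the realized Vg1-domain centroid (the posterior pole)."""
    doms = call_domains_state(state, "V")
    if not doms:
        return None
    best = max(doms, key=lambda d: d.peak)
    return int(round(best.centroid / (2 * math.pi) * state.n_cells)) % state.n_cells


def default_bead_strength(params: ModelParameters) -> float:
    """Source rate such that the steady perceived BMP4 at the bead center is
    about twice K_hi (a saturating bead): the footprint's cells settle near
    strength/delta_B, diluted by the perception window."""
    w = 2 * params.coupling_radius + 1
    cov = min(2 * 3 + 1, w)  # default bead radius 3
    return 2.0 * params.K_hi * params.delta_B * w / cov


# ---------------------------------------------------------------------------
# Outcome predicates (each is the quantitative reading of one figure panel)

def _pred_e1(summary: PatternSummary, **_) -> bool:
    return (summary.classification == "bipolar"
            and summary.bv_corr is not None and summary.bv_corr < -0.5
            and summary.centroid_separation is not None
            and summary.centroid_separation > 2 * math.pi / 3)


def _pred_e2(summary: PatternSummary, detail: dict, **_) -> bool:
    return (detail["v_footprint_fold"] < 0.2
            and summary.predicted_streak_count == 2)


def _pred_e3(summary: PatternSummary, detail: dict, **_) -> bool:
    return (detail["v_local_fold"] >= INDUCTION_FOLD
            and detail["fb_local_fold"] > 1.0)


def _pred_e4(summary: PatternSummary, detail: dict, **_) -> bool:
    angles = summary.predicted_streak_angles
    if summary.predicted_streak_count < 1:
        return False
    n = detail["n_cells"]
    min_sep_cells = detail["bead_radius"] + 2
    for a in angles:
        for bc in detail["bead_centers"]:
            d = abs((a - 2 * math.pi * bc / n + math.pi) % (2 * math.pi) - math.pi)
            if d * n / (2 * math.pi) <= min_sep_cells:
                return False
    return True


def _pred_e5(summary: PatternSummary, detail: dict, **_) -> bool:
    return (detail["v_local_fold"] >= INDUCTION_FOLD
            and detail["b_local_fold"] <= SUPPRESSION_FOLD)


def _pred_e6(summary: PatternSummary, detail: dict, **_) -> bool:
    return detail["b_local_fold"] <= SUPPRESSION_FOLD


def _pred_e7(summary: PatternSummary, detail: dict, **_) -> bool:
    return detail["fragments_with_v"] == detail["n_fragments"]


PREDICATES: dict[str, Callable[..., bool]] = {
    "e1_bipolar": _pred_e1,
    "e2_posterior_bead": _pred_e2,
    "e3_anterior_bead": _pred_e3,
    "e4_multi_bead": _pred_e4,
    "e5_anterior_pellet": _pred_e5,
    "e6_fb_knockdown": _pred_e6,
    "e7_fragmentation": _pred_e7,
}


# ---------------------------------------------------------------------------
# Running experiments

def _run_baseline(proto: ExperimentProtocol, seed: int, cuts: tuple[int, ...] = ()):
    params = proto.params
    base = launch_state(params)
    s0 = initialize(params, seed, base, cuts=cuts)
    return integrate(s0, params, t_end=proto.t_end, dt=proto.dt,
                     record_every=proto.record_every, seed=seed)


def _continue_run(state: EmbryoState, proto: ExperimentProtocol,
                  perturbations: list[Perturbation], seed: int):
    t_end = state.time + proto.t_post
    return integrate(state, proto.params, perturbations=perturbations,
                     t_end=t_end, dt=proto.dt,
                     record_every=proto.record_every, seed=seed)


def run_experiment(proto: ExperimentProtocol, master_seed: int = 0) -> ExperimentResult:
    """Run the protocol over its seed ensemble and apply its predicate.

    Seeds are ``master_seed*10000 + i`` for i in 0..n_seeds-1, so distinct
    master seeds give disjoint ensembles while staying reproducible.
    """
    params = proto.params
    thr = streak_threshold(params)
    pred = PREDICATES[proto.predicate]
    strength = (proto.bead_strength if proto.bead_strength is not None
                else default_bead_strength(params))
    outcomes: list[SeedOutcome] = []

    for i in range(proto.n_seeds):
        seed = master_seed * 10000 + i
        detail: dict = {"n_cells": params.n_cells, "bead_radius": proto.bead_radius}
        control_summary = None

        if proto.id == "E1":
            rec = _run_baseline(proto, seed)
            final = rec.final
            summary = summarize(final, thr)

        elif proto.id == "E7":
            n = params.n_cells
            k = proto.n_fragments
            cuts = tuple(int(round(j * n / k)) for j in range(k))
            rec = _run_baseline(proto, seed, cuts=cuts)
            final = rec.final
            summary = summarize(final, thr)
            doms = call_domains_state(final, "V")
            starts = [d.start for d in doms]
            # a domain never spans a cut, so its start cell identifies its fragment
            frag_v = sum(1 for arc in final.arcs
                         if any(s in set(arc.tolist()) for s in starts))
            detail.update(n_fragments=k, fragments_with_v=frag_v)

        else:  # E2..E6: perturb a converged pattern, compare to matched control
            rec = _run_baseline(proto, seed)
            pre = rec.final
            post_cell = _posterior_cell(pre, params)
            if post_cell is None:
                outcomes.append(SeedOutcome(seed=seed, passed=False,
                                            summary=summarize(pre, thr),
                                            detail={"note": "no V domain formed"}))
                continue
            ant_cell = (post_cell + params.n_cells // 2) % params.n_cells
            t0, t1 = pre.time, pre.time + proto.t_post
            perts, readout_center, readout_radius = [], post_cell, proto.bead_radius

            if proto.id == "E2":
                perts = [make_bead(post_cell, "B", strength, proto.bead_radius, t0, t1)]
                readout_center = post_cell
            elif proto.id == "E3":
                perts = [make_bead(ant_cell, "B", strength, proto.bead_radius, t0, t1)]
                readout_center = ant_cell
            elif proto.id == "E4":
                n = params.n_cells
                centers = [(post_cell + int(round(j * n / proto.n_beads))) % n
                           for j in range(proto.n_beads)]
                perts = [make_bead(c, "B", strength, proto.bead_radius, t0, t1)
                         for c in centers]
                detail["bead_centers"] = centers
            elif proto.id == "E5":
                perts = [make_pellet(ant_cell, strength, proto.bead_radius, t0, t1)]
                readout_center = ant_cell
            elif proto.id == "E6":
                # knock F_B down inside the realized BMP4 domain (anterior)
                perts = [make_knockdown("FB", ant_cell, proto.bead_radius,
                                        proto.knockdown_efficiency, t0, t1)]
                readout_center = ant_cell
            else:
                raise ValueError(f"unknown experiment id {proto.id!r}")

            pert_rec = _continue_run(pre, proto, perts, seed)
            final = pert_rec.final
            summary = summarize(final, thr)
            control_summary = summarize(pre, thr)

            # fold-changes are referenced to the same-seed pre-manipulation
            # state: the pattern's position slowly wanders on an unperturbed
            # ring, so the pre-graft expression map is the tighter paired
            # control (and matches how grafted embryos are scored against
            # their own pre-graft geometry)
            eps = 1e-12
            zone = footprint(readout_center, readout_radius
                             + 2 * params.coupling_radius, params.n_cells)
            # inductions are read as zone peaks (a bright patch of
            # upregulation), suppressions as zone means
            for sp, key, stat in (("V", "v_local_fold", np.max),
                                  ("B", "b_local_fold", np.mean),
                                  ("FB", "fb_local_fold", np.max)):
                loc = float(stat(final.species(sp)[zone]))
                ref = float(stat(pre.species(sp)[zone]))
                detail[key] = loc / max(ref, eps)
            fp_idx = footprint(readout_center, proto.bead_radius, params.n_cells)
            detail["v_footprint_fold"] = float(
                final.V[fp_idx].mean() / max(pre.V[fp_idx].mean(), eps))

        passed = pred(summary, detail=detail)
        outcomes.append(SeedOutcome(seed=seed, passed=passed, summary=summary,
                                    control_summary=control_summary, detail=detail))

    return ExperimentResult(protocol=proto, outcomes=outcomes)


def default_protocols(params: ModelParameters | None = None,
                      n_seeds: int = 20) -> dict[str, ExperimentProtocol]:
    """The committed E1–E7 protocol battery at the calibrated defaults."""
    params = params or ModelParameters()
    mk = lambda eid, pred, **kw: ExperimentProtocol(
        id=eid, params=params, predicate=pred, n_seeds=n_seeds, **kw)
    return {
        "E1": mk("E1", "e1_bipolar"),
        "E2": mk("E2", "e2_posterior_bead"),
        "E3": mk("E3", "e3_anterior_bead"),
        "E4": mk("E4", "e4_multi_bead"),
        "E5": mk("E5", "e5_anterior_pellet"),
        "E6": mk("E6", "e6_fb_knockdown"),
        "E7": mk("E7", "e7_fragmentation"),
    }


def run_battery(params: ModelParameters | None = None, n_seeds: int = 20,
                master_seed: int = 0,
                experiments: list[str] | None = None) -> dict[str, ExperimentResult]:
    """Run all (or selected) experiments; returns per-experiment results."""
    protos = default_protocols(params, n_seeds=n_seeds)
    ids = experiments or list(protos)
    out = {}
    for eid in ids:
        out[eid] = run_experiment(protos[eid], master_seed=master_seed)
        logger.info("%s: pass fraction %.2f verdict %s", eid,
                    out[eid].pass_fraction, out[eid].verdict)
    return out


def calibrate(search_space: list[dict] | list[ModelParameters],
              experiments: list[str] | None = None,
              n_seeds: int = 6, master_seed: int = 0,
              budget: int | None = None) -> tuple[ModelParameters | None, list[dict]]:
    """Score candidate parameter sets against the battery.

    ``search_space`` is an explicit list of candidates (dicts of parameter
    overrides, or full ModelParameters).  Each candidate is scored by the
    number of experiments whose ensemble verdict passes; E1 is a mandatory
    gate (candidates failing it score 0).  Returns the best candidate
    passing all requested experiments (or None) plus the full report.
    Invalid candidates (parameter invariant violations) are rejected before
    any simulation.
    """
    if not search_space:
        raise ValueError("empty search space")
    ids = experiments or ["E1", "E2", "E3", "E4", "E5", "E6", "E7"]
    if budget is not None:
        search_space = list(search_space)[:budget]
    report = []
    best: tuple[int, ModelParameters] | None = None
    for cand in search_space:
        if isinstance(cand, ModelParameters):
            params = cand
        else:
            try:
                params = ModelParameters.from_dict({**ModelParameters().to_dict(), **cand})
            except ValueError as e:
                report.append({"candidate": cand, "error": str(e), "score": -1})
                continue
        try:
            results = run_battery(params, n_seeds=n_seeds, master_seed=master_seed,
                                  experiments=ids)
        except (ValueError, RuntimeError) as e:
            report.append({"candidate": params.to_dict(), "error": str(e), "score": -1})
            continue
        verdicts = {eid: res.verdict for eid, res in results.items()}
        score = sum(verdicts.values())
        if "E1" in verdicts and not verdicts["E1"]:
            score = 0
        report.append({"candidate": params.to_dict(), "verdicts": verdicts,
                       "score": score})
        if score == len(ids):
            if best is None or score > best[0]:
                best = (score, params)
    return (best[1] if best else None), report
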