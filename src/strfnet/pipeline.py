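"""Top-level two-state fitting pipeline.

Chains, for each recording state (passive / behavioral): repeated GA fits of
the network to that state's target STRF, a perturbation sensitivity profile
per fit, five-repeat averaging, extraction of the top-2 important
parameters, and the comparison diagram between states.  All randomness flows
from a single master seed through labeled sub-seeds, so a rerun with the
same master seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as io_mod
from .network import Genome
from .optimize import EvalContext, FitResult, GAConfig, run_ga
from .scenarios import make_target
from .sensitivity import (
    SensitivityProfile,
    StateComparison,
    average_profiles,
    build_diagram,
    important_params,
    sensitivity_profile,
)
from .strf import STRF

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "two_state_demo"]


@dataclass
class RunConfig:
    """Settings for a two-state fit-and-compare run.

    The desk-scale defaults fit a small network quickly; the full-scale
    study configuration is ``RunConfig.full()`` (15 neurons, 30 TORCs x 4
    repetitions, population 1000, 100 generations).
    """

    n_neurons: int = 5
    n_torcs: int = 10
    reps: int = 1
    duration_s: float | None = 1.0
    tonic_rate_hz: float = 0.0
    repeats: int = 5
    top_k: int = 2
    population: int = 60
    elite: int = 4
    parents: int = 10
    crossover: int = 28
    mutation: int = 28
    generations: int = 15
    mutation_rate: float = 0.05
    master_seed: int = 0
    out_dir: str | None = None

    @classmethod
    def full(cls, master_seed: int = 0, out_dir: str | None = None) -> "RunConfig":
        return cls(
            n_neurons=15,
            n_torcs=30,
            reps=4,
            duration_s=None,
            tonic_rate_hz=10.0,
            repeats=5,
            population=1000,
            elite=40,
            parents=100,
            crossover=480,
            mutation=480,
            generations=100,
            master_seed=master_seed,
            out_dir=out_dir,
        )

    def ga_config(self, seed: int) -> GAConfig:
        return GAConfig(
            population=self.population,
            elite=self.elite,
            parents=self.parents,
            crossover=self.crossover,
            mutation=self.mutation,
            generations=self.generations,
            mutation_rate=self.mutation_rate,
            seed=seed,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        return cls(**data)


@dataclass
class PipelineResult:
    comparison: StateComparison
    passive_fits: list[FitResult]
    behavioral_fits: list[FitResult]
    passive_profiles: list[SensitivityProfile]
    behavioral_profiles: list[SensitivityProfile]
    recorded_neuron: int

    def per_repeat_top_union(self, k: int = 2) -> list[set[str]]:
        """Union of the two states' top-k important parameters, per repeat."""
        return [
            set(important_params(p, k)) | set(important_params(b, k))
            for p, b in zip(self.passive_profiles, self.behavioral_profiles)
        ]


def run_pipeline(
    passive_target: STRF,
    behavioral_target: STRF,
    cfg: RunConfig,
    *,
    progress: bool = False,
) -> PipelineResult:
    """Fit both states ``cfg.repeats`` times, profile, average and compare.

    Each repeat builds one evaluation context (fresh peripheral discharge
    seeds) shared by the two states, so per-repeat comparisons see identical
    stimulation; GA seeds differ per state and repeat.
    """
    if not passive_target.congruent(behavioral_target):
        raise ValueError("passive and behavioral targets are not congruent")
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        (out / "run_config.yaml").write_text(cfg.to_yaml())

    fits: dict[str, list[FitResult]] = {"passive": [], "behavioral": []}
    profiles: dict[str, list[SensitivityProfile]] = {"passive": [], "behavioral": []}
    recorded = None
    for r in range(cfg.repeats):
        ctx = EvalContext.build(
            n_neurons=cfg.n_neurons,
            n_torcs=cfg.n_torcs,
            reps=cfg.reps,
            seed=io_mod.split_seed(cfg.master_seed, f"ctx/{r}"),
            duration_s=cfg.duration_s,
            tonic_rate_hz=cfg.tonic_rate_hz,
        )
        for state, target in (("passive", passive_target), ("behavioral", behavioral_target)):
            ga_seed = io_mod.split_seed(cfg.master_seed, f"{state}/ga/{r}")
            result = run_ga(target, cfg.ga_config(ga_seed), ctx, progress=progress)
            neuron = ctx.neuron_for_target(target)
            recorded = neuron if recorded is None else recorded
            profile = sensitivity_profile(result.best_genome, target, ctx, neuron)
            fits[state].append(result)
            profiles[state].append(profile)
            if out:
                io_mod.write_genome(out / f"{state}_rep{r}.genome", result.best_genome)
                io_mod.write_profile(out / f"{state}_rep{r}.profile", profile)
                io_mod.write_history(out / f"{state}_rep{r}.history", result)
            if progress:
                print(f"{state} repeat {r}: best cost {result.best_cost:.4f}")

    avg_p = average_profiles(profiles["passive"])
    avg_b = average_profiles(profiles["behavioral"])
    comparison = build_diagram(
        [f.best_genome for f in fits["passive"]],
        avg_p,
        [f.best_genome for f in fits["behavioral"]],
        avg_b,
        recorded_neuron=recorded,
        k=cfg.top_k,
    )
    if out:
        io_mod.write_profile(out / "passive_avg.profile", avg_p)
        io_mod.write_profile(out / "behavioral_avg.profile", avg_b)
        io_mod.write_diagram(out / "comparison.diagram", comparison)
    return PipelineResult(
        comparison=comparison,
        passive_fits=fits["passive"],
        behavioral_fits=fits["behavioral"],
        passive_profiles=profiles["passive"],
        behavioral_profiles=profiles["behavioral"],
        recorded_neuron=recorded,
    )


def demo_ground_truths(n_neurons: int = 5) -> tuple[Genome, Genome, str, int]:
    """Two ground-truth networks differing in exactly one synaptic weight.

    Both states share the same architecture — cochlear drive to the recorded
    (middle) neuron and its lower-frequency neighbor, with a moderate
    inhibitory lateral synapse from the neighbor — and differ only in the
    bottom-up input strength to the recorded neuron (5 passive vs 2
    behavioral), the kind of task-related bottom-up change the comparison is
    meant to detect.  Returns (passive_genome, behavioral_genome, differing
    parameter label, recorded neuron).
    """
    if n_neurons < 2:
        raise ValueError("demo needs at least 2 neurons")
    rec = n_neurons // 2
    nbr = rec - 1
    base = Genome.zeros(n_neurons)
    istr = base.istr.copy()
    idel = base.idel.copy()
    istr[rec] = 5
    idel[rec] = -4
    istr[nbr] = 5
    idel[nbr] = -4
    w = base.w.copy()
    w[nbr, rec] = -3
    passive = Genome(w.copy(), istr.copy(), idel.copy())
    istr_b = istr.copy()
    istr_b[rec] = 2
    behavioral = Genome(w.copy(), istr_b, idel.copy())
    return passive, behavioral, f"istr[{rec}]", rec


def two_state_demo(
    cfg: RunConfig | None = None,
    *,
    progress: bool = False,
) -> tuple[PipelineResult, str]:
    """End-to-end reduced two-state experiment on synthetic targets.

    Generates passive/behavioral targets from ground truths that differ by
    one lateral weight, runs the full fit-profile-compare pipeline, and
    returns the result plus the label of the deliberately changed parameter.
    """
    cfg = cfg or RunConfig()
    passive_gt, behavioral_gt, changed, rec = demo_ground_truths(cfg.n_neurons)
    target_seed = io_mod.split_seed(cfg.master_seed, "targets")
    ctx = EvalContext.build(
        n_neurons=cfg.n_neurons,
        n_torcs=cfg.n_torcs,
        reps=cfg.reps,
        seed=target_seed,
        duration_s=cfg.duration_s,
        recorded_neuron=rec,
        tonic_rate_hz=cfg.tonic_rate_hz,
    )
    from .optimize import evaluate_strf

    passive_target = evaluate_strf(passive_gt, ctx, rec)
    behavioral_target = evaluate_strf(behavioral_gt, ctx, rec)
    result = run_pipeline(passive_target, behavioral_target, cfg, progress=progress)
    return result, changed
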