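"""Elitist genetic algorithm over integer genomes.

The fit minimizes the significance-weighted STRF cost.  Each generation of
the default (full-scale) configuration keeps the best 40 genomes verbatim
(elitism), and refills the population of 1000 with 480 uniform-crossover
offspring and 480 mutants, both drawn from the best-100 parent pool.  Genes
are integers in [-5, 5] throughout.

Evaluation runs the forward pipeline — decode genome, simulate the network on
cached peripheral discharges, reverse-correlate the recorded neuron's spikes
against the TORC dynamic spectra — and compares to the target.  The
peripheral discharge seeds are fixed across all evaluations of a run so the
cost landscape is deterministic and elitism is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from . import strf as strf_mod
from .network import GENE_HIGH, GENE_LOW, Genome, NeuronParams, decode_genome, simulate_network
from .periphery import ChannelBank, RateParams, cf_grid, drive_rate, generate_discharges
from .strf import STRF, EstimationConfig, best_channel, cost, reverse_correlate
from .torc import ChannelAxis, DynamicSpectrum, dynamic_spectrum, make_torc_set

__all__ = [
    "GAConfig",
    "FitResult",
    "EvalContext",
    "init_population",
    "evaluate",
    "evaluate_strf",
    "next_generation",
    "run_ga",
    "GeneticNetworkFitter",
]


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    Defaults are the full-scale run: population 1000, 40 elite, best-100
    parent pool, 480 crossover + 480 mutation offspring, 100 generations.
    ``reduced()`` gives the desk-scale preset used by the test suite.
    """

    population: int = 1000
    elite: int = 40
    parents: int = 100
    crossover: int = 480
    mutation: int = 480
    generations: int = 100
    gene_low: int = GENE_LOW
    gene_high: int = GENE_HIGH
    mutation_rate: float = 0.05
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.elite + self.crossover + self.mutation != self.population:
            raise ValueError("elite + crossover + mutation must equal population size")
        if not (2 <= self.parents <= self.population):
            raise ValueError("parent pool must hold at least 2 and at most population")
        if self.gene_low >= self.gene_high:
            raise ValueError("gene bounds inverted")
        if not (0 <= self.mutation_rate <= 1):
            raise ValueError("mutation rate must be in [0, 1]")

    @classmethod
    def reduced(cls, seed: int | None = 0, generations: int = 15) -> "GAConfig":
        """Desk-scale preset: population 60 = 4 elite + 28 + 28, best-10 parents."""
        return cls(
            population=60,
            elite=4,
            parents=10,
            crossover=28,
            mutation=28,
            generations=generations,
            seed=seed,
        )


@dataclass
class FitResult:
    best_genome: Genome
    best_cost: float
    history_best: list[float]
    history_median: list[float]
    n_evaluations: int
    seed: int | None


@dataclass
class EvalContext:
    """Cached forward-pipeline inputs shared by all evaluations of a run.

    Holds the TORC dynamic spectra and the peripheral discharge trains
    (one per stimulus x repetition, generated once with fixed seeds), the
    neuron parameters, and the estimation settings.  ``recorded_neuron``
    may be fixed here or derived per target from its best frequency.
    """

    bank: ChannelBank
    params: NeuronParams
    dspecs: list[DynamicSpectrum]
    trains: list[list]  # [stimulus][repetition] -> DischargeTrain
    est_cfg: EstimationConfig
    recorded_neuron: int | None = None

    @property
    def n_neurons(self) -> int:
        return self.bank.n_channels

    @classmethod
    def build(
        cls,
        n_neurons: int = 15,
        n_torcs: int = 30,
        reps: int = 4,
        seed: int | None = 0,
        *,
        duration_s: float | None = None,
        params: NeuronParams | None = None,
        rate_params: RateParams | None = None,
        est_cfg: EstimationConfig | None = None,
        recorded_neuron: int | None = None,
        tonic_rate_hz: float = 10.0,
    ) -> "EvalContext":
        """Generate stimuli and peripheral discharges for an evaluation run.

        ``tonic_rate_hz`` defaults to 10 Hz because fitting runs use tonic
        cortical firing (responses are more robust and inhibition becomes
        visible in the STRF); pass 0 to disable.  ``duration_s`` forces a
        single TORC duration; by default durations cycle through 1-2 s.
        """
        params = params or NeuronParams(tonic_rate_hz=tonic_rate_hz)
        bank = cf_grid(n_neurons)
        ss = np.random.SeedSequence(seed)
        torc_seed, periph_seed = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2)]
        kwargs = {}
        if duration_s is not None:
            kwargs["durations_s"] = (duration_s,)
        specs = make_torc_set(n_torcs, bank.axis(), torc_seed, **kwargs)
        dspecs = [dynamic_spectrum(sp) for sp in specs]
        rate_params = rate_params or RateParams()
        rng_seeds = np.random.SeedSequence(periph_seed).spawn(n_torcs * reps)
        trains: list[list] = []
        k = 0
        for d in dspecs:
            rate = drive_rate(d, bank, rate_params)
            row = []
            for _ in range(reps):
                row.append(
                    generate_discharges(rate, int(rng_seeds[k].generate_state(1)[0] % 2**31))
                )
                k += 1
            trains.append(row)
        return cls(bank, params, dspecs, trains, est_cfg or EstimationConfig(), recorded_neuron)

    def neuron_for_target(self, target: STRF) -> int:
        """Recorded neuron = the channel matching the target's best frequency."""
        if self.recorded_neuron is not None:
            return self.recorded_neuron
        return self.bank.channel_of(strf_mod.best_frequency(target))


def evaluate_strf(genome: Genome, ctx: EvalContext, recorded_neuron: int) -> STRF:
    """Forward pipeline: decode, simulate each stimulus/repetition, estimate."""
    config = decode_genome(genome, ctx.params, ctx.bank)
    responses = []
    for d, reps in zip(ctx.dspecs, ctx.trains):
        rep_spikes = []
        for train in reps:
            rec = simulate_network(config, train, d.duration_s * 1000.0)
            rep_spikes.append(rec.spike_times_ms[recorded_neuron] / 1000.0)
        responses.append(rep_spikes)
    return reverse_correlate(ctx.dspecs, responses, ctx.est_cfg)


def evaluate(genome: Genome, target: STRF, ctx: EvalContext) -> float:
    """Cost of a genome against a target STRF (deterministic given ctx)."""
    neuron = ctx.neuron_for_target(target)
    model = evaluate_strf(genome, ctx, neuron)
    return cost(model, target)


def init_population(cfg: GAConfig, n_neurons: int) -> list[Genome]:
    """Uniform random integer genomes; deterministic per cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    n_genes = n_neurons * n_neurons + 2 * n_neurons
    return [
        Genome.from_flat(
            rng.integers(cfg.gene_low, cfg.gene_high + 1, size=n_genes), n_neurons
        )
        for _ in range(cfg.population)
    ]


def next_generation(
    population: list[Genome],
    costs: np.ndarray,
    cfg: GAConfig,
    seed: int | None,
) -> list[Genome]:
    """One elitist GA step.

    Stable-sorts by cost, copies the elite verbatim (they lead the returned
    list), then fills with uniform per-gene crossover children of parent
    pairs sampled without replacement from the top parent pool, and mutants
    of single parents with per-gene resampling.
    """
    if len(population) != len(costs):
        raise ValueError("costs must align with population")
    if len(population) < cfg.parents:
        raise ValueError("population smaller than parent pool")
    n_neurons = population[0].n_neurons
    order = np.argsort(np.asarray(costs), kind="stable")
    ranked = [population[i] for i in order]
    elite = ranked[: cfg.elite]
    pool = np.array([g.flat() for g in ranked[: cfg.parents]])
    rng = np.random.default_rng(seed)
    n_genes = pool.shape[1]
    children: list[Genome] = []
    for _ in range(cfg.crossover):
        i, j = rng.choice(cfg.parents, size=2, replace=False)
        mask = rng.integers(0, 2, size=n_genes).astype(bool)
        children.append(Genome.from_flat(np.where(mask, pool[i], pool[j]), n_neurons))
    for _ in range(cfg.mutation):
        parent = pool[rng.integers(cfg.parents)].copy()
        mask = rng.random(n_genes) < cfg.mutation_rate
        parent[mask] = rng.integers(cfg.gene_low, cfg.gene_high + 1, size=int(mask.sum()))
        children.append(Genome.from_flat(parent, n_neurons))
    return elite + children


def run_ga(
    target: STRF,
    cfg: GAConfig,
    ctx: EvalContext,
    *,
    checkpoint_dir: str | Path | None = None,
    progress: bool = False,
) -> FitResult:
    """Iterate the GA; thin functional wrapper over GeneticNetworkFitter's loop."""
    fitter = GeneticNetworkFitter(
        population=cfg.population,
        elite=cfg.elite,
        parents=cfg.parents,
        crossover=cfg.crossover,
        mutation=cfg.mutation,
        generations=cfg.generations,
        mutation_rate=cfg.mutation_rate,
        seed=cfg.seed,
        checkpoint_dir=checkpoint_dir,
        progress=progress,
    )
    fitter.fit(target, eval_ctx=ctx)
    return fitter.result_


class GeneticNetworkFitter(BaseEstimator):
    """Fit network synaptic parameters to a target STRF with an elitist GA.

    scikit-learn style estimator: ``fit(target)`` searches integer genomes
    minimizing the significance-weighted STRF cost; fitted attributes are
    ``best_genome_``, ``best_cost_``, ``history_`` (per-generation best
    cost), ``result_`` (full :class:`FitResult`) and ``ctx_``.  ``predict()``
    returns the fitted model's STRF.

    Context parameters (``n_neurons`` .. ``tonic_rate_hz``) are used only
    when no prebuilt :class:`EvalContext` is passed to ``fit``.
    """

    def __init__(
        self,
        population: int = 60,
        elite: int = 4,
        parents: int = 10,
        crossover: int = 28,
        mutation: int = 28,
        generations: int = 15,
        mutation_rate: float = 0.05,
        seed: int | None = 0,
        n_neurons: int = 15,
        n_torcs: int = 30,
        reps: int = 4,
        duration_s: float | None = None,
        tonic_rate_hz: float = 10.0,
        checkpoint_dir: str | Path | None = None,
        progress: bool = False,
    ):
        self.population = population
        self.elite = elite
        self.parents = parents
        self.crossover = crossover
        self.mutation = mutation
        self.generations = generations
        self.mutation_rate = mutation_rate
        self.seed = seed
        self.n_neurons = n_neurons
        self.n_torcs = n_torcs
        self.reps = reps
        self.duration_s = duration_s
        self.tonic_rate_hz = tonic_rate_hz
        self.checkpoint_dir = checkpoint_dir
        self.progress = progress

    def _ga_config(self) -> GAConfig:
        return GAConfig(
            population=self.population,
            elite=self.elite,
            parents=self.parents,
            crossover=self.crossover,
            mutation=self.mutation,
            generations=self.generations,
            mutation_rate=self.mutation_rate,
            seed=self.seed,
        )

    def fit(self, target: STRF, y=None, *, eval_ctx: EvalContext | None = None):
        cfg = self._ga_config()
        ctx = eval_ctx or EvalContext.build(
            n_neurons=self.n_neurons,
            n_torcs=self.n_torcs,
            reps=self.reps,
            seed=self.seed,
            duration_s=self.duration_s,
            tonic_rate_hz=self.tonic_rate_hz,
        )
        neuron = ctx.neuron_for_target(target)
        ss = np.random.SeedSequence(cfg.seed)
        gen_seeds = ss.spawn(cfg.generations + 1)

        pop = init_population(cfg, ctx.n_neurons)
        costs = np.array([cost_of(g, target, ctx, neuron) for g in pop])
        n_evals = len(pop)
        history_best: list[float] = []
        history_median: list[float] = []
        best_idx = int(np.argmin(costs))
        best_genome, best_cost = pop[best_idx], float(costs[best_idx])
        ckpt = Path(self.checkpoint_dir) if self.checkpoint_dir else None
        if ckpt:
            ckpt.mkdir(parents=True, exist_ok=True)
        for gen in range(cfg.generations):
            history_best.append(float(costs.min()))
            history_median.append(float(np.median(costs)))
            if self.progress:
                print(
                    f"generation {gen}: best {history_best[-1]:.4f} "
                    f"median {history_median[-1]:.4f}"
                )
            gen_seed = int(gen_seeds[gen].generate_state(1)[0] % 2**31)
            new_pop = next_generation(pop, costs, cfg, gen_seed)
            # elites lead the new population in sorted order: reuse their costs
            elite_costs = np.sort(costs, kind="stable")[: cfg.elite]
            new_costs = np.empty(cfg.population)
            new_costs[: cfg.elite] = elite_costs
            for i in range(cfg.elite, cfg.population):
                new_costs[i] = cost_of(new_pop[i], target, ctx, neuron)
            n_evals += cfg.population - cfg.elite
            pop, costs = new_pop, new_costs
            idx = int(np.argmin(costs))
            if costs[idx] < best_cost:
                best_genome, best_cost = pop[idx], float(costs[idx])
            if ckpt:
                from .io import write_genome  # local import avoids cycle

                write_genome(ckpt / f"gen{gen:04d}_best.genome", best_genome)
        history_best.append(float(costs.min()))
        history_median.append(float(np.median(costs)))

        self.best_genome_ = best_genome
        self.best_cost_ = best_cost
        self.history_ = history_best
        self.ctx_ = ctx
        self.recorded_neuron_ = neuron
        self.result_ = FitResult(
            best_genome=best_genome,
            best_cost=best_cost,
            history_best=history_best,
            history_median=history_median,
            n_evaluations=n_evals,
            seed=cfg.seed,
        )
        return self

    def predict(self, X=None) -> STRF:
        """STRF produced by the fitted genome in the fitting context."""
        if not hasattr(self, "best_genome_"):
            raise RuntimeError("fit the estimator before calling predict")
        return evaluate_strf(self.best_genome_, self.ctx_, self.recorded_neuron_)

    def score(self, target: STRF, y=None) -> float:
        """Negative cost of the fitted genome against ``target``."""
        return -cost(self.predict(), target)


def cost_of(
    genome: Genome, target: STRF, ctx: EvalContext, neuron: int, *, normalize: bool = True
) -> float:
    """Cost with the recorded neuron already resolved (GA inner loop)."""
    return cost(evaluate_strf(genome, ctx, neuron), target, normalize=normalize)
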