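"""Perturbation sensitivity analysis of fitted genomes.

Each parameter of a fitted solution is stepped up and down by one integer
value and the resulting change of the significance-weighted cost is recorded;
the per-parameter score is the mean absolute cost change over the feasible
perturbations (single-sided at the +/-5 bounds), normalized so scores sum
to 1.  Profiles from repeated fits are averaged, the top-k (default 2)
parameters per state are called important, and a comparison diagram is built
whose context edges trace the flow from the cochlear input to the recorded
neuron.

Perturbations are scored with the raw significance-weighted cost (no
per-STRF scale normalization): the normalized cost used for fitting is
deliberately invariant to uniform response gain, which would structurally
hide exactly the gain-type parameters (input strengths) the sensitivity
analysis exists to rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import GENE_HIGH, GENE_LOW, Genome
from .optimize import EvalContext, cost_of
from .strf import STRF

__all__ = [
    "SensitivityProfile",
    "DiagramEdge",
    "StateComparison",
    "param_labels",
    "sensitivity_profile",
    "average_profiles",
    "important_params",
    "build_diagram",
]


def param_labels(n_neurons: int) -> list[str]:
    """Labels aligned with Genome.flat(): w[i->j] row-major, istr, idel."""
    labels = [f"w[{i}->{j}]" for i in range(n_neurons) for j in range(n_neurons)]
    labels += [f"istr[{c}]" for c in range(n_neurons)]
    labels += [f"idel[{c}]" for c in range(n_neurons)]
    return labels


@dataclass(frozen=True)
class SensitivityProfile:
    """Normalized per-parameter cost-perturbation scores (sum to 1)."""

    scores: np.ndarray
    n_neurons: int

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        n = self.n_neurons
        if s.shape != (n * n + 2 * n,):
            raise ValueError("profile length must equal genome length")
        if np.any(s < 0):
            raise ValueError("scores must be nonnegative")
        object.__setattr__(self, "scores", s)

    @property
    def labels(self) -> list[str]:
        return param_labels(self.n_neurons)


def _normalize(raw: np.ndarray) -> np.ndarray:
    total = raw.sum()
    return raw / total if total > 0 else raw


def sensitivity_profile(
    genome: Genome,
    target: STRF,
    ctx: EvalContext,
    recorded_neuron: int | None = None,
) -> SensitivityProfile:
    """Score every parameter by one-step cost perturbation.

    raw(p) = mean over feasible deltas in {+1, -1} of |c(p + delta) - c(p)|;
    at the gene bounds only the feasible direction is used, unscaled.
    The cost is evaluated without scale normalization (see module docs).
    Deterministic given the context's cached discharges.
    """
    neuron = recorded_neuron if recorded_neuron is not None else ctx.neuron_for_target(target)
    flat = genome.flat()
    n = genome.n_neurons
    c0 = cost_of(genome, target, ctx, neuron, normalize=False)
    raw = np.zeros(len(flat))
    for g in range(len(flat)):
        changes = []
        for delta in (+1, -1):
            new_val = flat[g] + delta
            if new_val < GENE_LOW or new_val > GENE_HIGH:
                continue
            pert = flat.copy()
            pert[g] = new_val
            c = cost_of(Genome.from_flat(pert, n), target, ctx, neuron, normalize=False)
            changes.append(abs(c - c0))
        raw[g] = float(np.mean(changes)) if changes else 0.0
    return SensitivityProfile(_normalize(raw), n)


def average_profiles(profiles: list[SensitivityProfile]) -> SensitivityProfile:
    """Element-wise mean of congruent profiles, renormalized to sum 1."""
    if not profiles:
        raise ValueError("need at least one profile to average")
    n = profiles[0].n_neurons
    if any(p.n_neurons != n for p in profiles):
        raise ValueError("profiles are not congruent")
    mean = np.mean([p.scores for p in profiles], axis=0)
    return SensitivityProfile(_normalize(mean), n)


def important_params(profile: SensitivityProfile, k: int = 2) -> list[str]:
    """The k highest-scoring parameter labels; ties broken by parameter index."""
    if k < 1:
        raise ValueError("k must be >= 1")
    order = np.argsort(-profile.scores, kind="stable")
    labels = profile.labels
    return [labels[i] for i in order[:k]]


def _param_index(label: str, n: int) -> int:
    labels = param_labels(n)
    return labels.index(label)


def _neurons_of(label: str) -> list[int]:
    if label.startswith("w["):
        pre, post = label[2:-1].split("->")
        return [int(pre), int(post)]
    return [int(label[label.index("[") + 1 : -1])]


@dataclass(frozen=True)
class DiagramEdge:
    """One highlighted or context parameter of the comparison diagram."""

    label: str
    kind: str           # "w", "istr" or "idel"
    pre: int            # presynaptic neuron, or the channel for inputs
    post: int           # postsynaptic neuron, or the channel for inputs
    passive_mean: float
    passive_sd: float
    behavioral_mean: float
    behavioral_sd: float
    solid_passive: bool
    solid_behavioral: bool


@dataclass(frozen=True)
class StateComparison:
    """Passive-vs-behavioral comparison of fitted networks."""

    passive_genomes: tuple[Genome, ...]
    behavioral_genomes: tuple[Genome, ...]
    passive_profile: SensitivityProfile
    behavioral_profile: SensitivityProfile
    passive_top: tuple[str, ...]
    behavioral_top: tuple[str, ...]
    edges: tuple[DiagramEdge, ...]
    recorded_neuron: int


def build_diagram(
    passive_genomes: list[Genome],
    passive_profile: SensitivityProfile,
    behavioral_genomes: list[Genome],
    behavioral_profile: SensitivityProfile,
    recorded_neuron: int,
    k: int = 2,
) -> StateComparison:
    """Union of the per-state top-k parameters plus information-flow context.

    Context edges: cochlear input strength to every neuron appearing in an
    important parameter, the synapse from each such neuron to the recorded
    neuron, and the recorded neuron's own cochlear input.  Each edge carries
    the mean +/- s.d. of its integer value across the repeat fits, and a
    solid flag per state marking membership in that state's top-k.
    """
    if len(passive_genomes) != len(behavioral_genomes):
        raise ValueError("states must have equal repeat counts")
    if not passive_genomes:
        raise ValueError("need at least one fitted genome per state")
    n = passive_genomes[0].n_neurons
    top_p = important_params(passive_profile, k)
    top_b = important_params(behavioral_profile, k)
    important = list(dict.fromkeys(top_p + top_b))

    involved: set[int] = set()
    for label in important:
        involved.update(_neurons_of(label))
    context: list[str] = [f"istr[{recorded_neuron}]"]
    for m in sorted(involved):
        context.append(f"istr[{m}]")
        if m != recorded_neuron:
            context.append(f"w[{m}->{recorded_neuron}]")
    all_labels = list(dict.fromkeys(important + context))

    p_flat = np.array([g.flat() for g in passive_genomes], dtype=float)
    b_flat = np.array([g.flat() for g in behavioral_genomes], dtype=float)
    ddof = 1 if len(passive_genomes) > 1 else 0
    edges = []
    for label in all_labels:
        idx = _param_index(label, n)
        kind = label.split("[")[0]
        nrns = _neurons_of(label)
        pre, post = (nrns[0], nrns[-1])
        edges.append(
            DiagramEdge(
                label=label,
                kind=kind,
                pre=pre,
                post=post,
                passive_mean=float(p_flat[:, idx].mean()),
                passive_sd=float(p_flat[:, idx].std(ddof=ddof)),
                behavioral_mean=float(b_flat[:, idx].mean()),
                behavioral_sd=float(b_flat[:, idx].std(ddof=ddof)),
                solid_passive=label in top_p,
                solid_behavioral=label in top_b,
            )
        )
    return StateComparison(
        passive_genomes=tuple(passive_genomes),
        behavioral_genomes=tuple(behavioral_genomes),
        passive_profile=passive_profile,
        behavioral_profile=behavioral_profile,
        passive_top=tuple(top_p),
        behavioral_top=tuple(top_b),
        edges=tuple(edges),
        recorded_neuron=recorded_neuron,
    )
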