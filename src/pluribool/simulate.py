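"""Synchronous Boolean dynamics: attractor discovery, basin weighting and
in-silico knockdowns.

All genes update simultaneously from the previous global state; input genes
(no rule) hold their state, and clamped genes are overridden throughout the
simulation — a knockdown clamps to 0, overexpression clamps to 1.  An
attractor is the terminal cycle of the deterministic trajectory; fixed
points are cycles of length 1.  Attractors found from sampled random starts
carry a basin weight B_i, the number of starts whose trajectory reached
them, and the maximum-weight attractor is taken as the stable phenotype.

Perturbation outcomes compare each gene's state in the unperturbed versus
perturbed stable phenotype: 0->1 is up-regulation, 1->0 down-regulation,
anything else unchanged.  Genes that oscillate within a cyclic attractor
with no majority state are flagged and excluded from the classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .logic import BooleanNetwork, evaluate

State = tuple[int, ...]

UP = "up-regulated"
DOWN = "down-regulated"
UNCHANGED = "unchanged"
OSCILLATING = "oscillating"


class Stepper:
    """Compiled synchronous update for one model + clamp assignment."""

    def __init__(self, model: BooleanNetwork,
                 clamps: Mapping[str, int] | None = None):
        clamps = dict(clamps or {})
        unknown = sorted(set(clamps) - set(model.genes))
        if unknown:
            raise ValueError(f"clamped genes not in model: {unknown}")
        self.model = model
        self.genes = list(model.genes)
        self.clamps = clamps
        self._index = {g: i for i, g in enumerate(self.genes)}
        # per gene: ("clamp", v) | ("hold", idx) | ("rule", expr)
        self._plan = []
        for g in self.genes:
            if g in clamps:
                self._plan.append(("clamp", int(clamps[g])))
            elif g in model.functions:
                self._plan.append(("rule", model.functions[g].expression))
            else:
                self._plan.append(("hold", self._index[g]))

    def step_many(self, states: np.ndarray) -> np.ndarray:
        """Advance a (n_states, n_genes) 0/1 matrix one synchronous step."""
        states = np.asarray(states, dtype=np.uint8)
        env = {g: states[:, i].astype(bool) for g, i in self._index.items()}
        out = np.empty_like(states)
        for i, (kind, payload) in enumerate(self._plan):
            if kind == "clamp":
                out[:, i] = payload
            elif kind == "hold":
                out[:, i] = states[:, payload]
            else:
                col = evaluate(payload, env)
                out[:, i] = np.broadcast_to(col, (states.shape[0],))
        return out

    def step(self, state: Sequence[int]) -> State:
        nxt = self.step_many(np.asarray(state, dtype=np.uint8)[None, :])[0]
        return tuple(int(v) for v in nxt)


def synchronous_step(model: BooleanNetwork, state: Sequence[int],
                     clamps: Mapping[str, int] | None = None) -> State:
    """One synchronous update of ``state`` (ordered as ``model.genes``)."""
    return Stepper(model, clamps).step(state)


def _canonical_cycle(cycle: list[State]) -> tuple[State, ...]:
    """Rotate so the cycle starts at its lexicographically smallest state."""
    start = min(range(len(cycle)), key=lambda i: cycle[i])
    return tuple(cycle[start:] + cycle[:start])


def _collapse(states: Sequence[State], genes: Sequence[str]) -> dict[str, object]:
    """Per-gene summary over the cycle: 0/1 if constant or majority;
    'oscillating' on an exact tie."""
    arr = np.asarray(states, dtype=int)
    out: dict[str, object] = {}
    for i, g in enumerate(genes):
        ones = int(arr[:, i].sum())
        zeros = arr.shape[0] - ones
        if ones > zeros:
            out[g] = 1
        elif zeros > ones:
            out[g] = 0
        else:
            out[g] = OSCILLATING
    return out


@dataclass(frozen=True)
class Attractor:
    """A terminal cycle in canonical rotation, with its basin weight."""

    states: tuple[State, ...]
    basin_weight: int
    genes: tuple[str, ...]

    def __post_init__(self):
        assert len(self.states) >= 1

    @property
    def is_fixed_point(self) -> bool:
        return len(self.states) == 1

    @property
    def collapsed(self) -> dict[str, object]:
        return _collapse(self.states, self.genes)

    def key(self) -> tuple[State, ...]:
        return self.states


@dataclass
class AttractorSet:
    """Attractors sorted by basin weight (descending, ties by state order)."""

    attractors: list[Attractor]
    n_starts: int
    genes: tuple[str, ...]

    def __post_init__(self):
        self.attractors.sort(key=lambda a: (-a.basin_weight, a.states))

    @property
    def max_basin(self) -> Attractor:
        return self.attractors[0]

    def total_weight(self) -> int:
        return sum(a.basin_weight for a in self.attractors)


def find_attractor(model: BooleanNetwork, start: Sequence[int],
                   clamps: Mapping[str, int] | None = None,
                   stepper: Stepper | None = None) -> Attractor:
    """Iterate from ``start`` until a state repeats; return the canonical
    terminal cycle (basin weight 1)."""
    stepper = stepper or Stepper(model, clamps)
    state = tuple(int(v) for v in start)
    seen: dict[State, int] = {}
    trail: list[State] = []
    while state not in seen:
        seen[state] = len(trail)
        trail.append(state)
        state = stepper.step(state)
    cycle = trail[seen[state]:]
    return Attractor(_canonical_cycle(cycle), 1, tuple(model.genes))


def _random_starts(model: BooleanNetwork, n_starts: int, seed: int,
                   clamps: Mapping[str, int] | None) -> np.ndarray:
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, 2, size=(n_starts, len(model.genes)),
                          dtype=np.uint8)
    for g, v in (clamps or {}).items():
        starts[:, model.genes.index(g)] = int(v)
    return starts


def sample_attractors(model: BooleanNetwork, n_starts: int = 100,
                      seed: int = 0,
                      clamps: Mapping[str, int] | None = None) -> AttractorSet:
    """Map ``n_starts`` seeded uniform random initial states to their
    attractors and accumulate basin weights.

    The same seed always produces the same initial states, so runs that
    differ only in clamps see identical starts (clamped coordinates are
    overwritten by the clamp value).
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    stepper = Stepper(model, clamps)
    starts = _random_starts(model, n_starts, seed, clamps)
    basins: dict[tuple[State, ...], int] = {}
    state_to_attractor: dict[State, tuple[State, ...]] = {}
    for row in starts:
        state = tuple(int(v) for v in row)
        trail: list[State] = []
        pos: dict[State, int] = {}
        while True:
            if state in state_to_attractor:  # joined a known basin
                key = state_to_attractor[state]
                break
            if state in pos:  # closed a new cycle within this trajectory
                key = _canonical_cycle(trail[pos[state]:])
                break
            pos[state] = len(trail)
            trail.append(state)
            state = stepper.step(state)
        for s in trail:
            state_to_attractor[s] = key
        basins[key] = basins.get(key, 0) + 1
    attractors = [Attractor(k, w, tuple(model.genes))
                  for k, w in basins.items()]
    return AttractorSet(attractors, n_starts, tuple(model.genes))


def exhaustive_attractors(model: BooleanNetwork,
                          clamps: Mapping[str, int] | None = None,
                          ) -> AttractorSet:
    """Enumerate all 2^n states and compute exact basins (n <= 20).

    Clamped coordinates are fixed, so the enumeration covers 2^(n-c)
    distinct reachable starts, each counted once.
    """
    n = len(model.genes)
    if n > 20:
        raise ValueError(
            f"{n} genes is too many for exhaustive enumeration (max 20); "
            "use sample_attractors"
        )
    stepper = Stepper(model, clamps)
    free = [i for i, g in enumerate(model.genes) if g not in (clamps or {})]
    n_free = len(free)
    rows = np.arange(2 ** n_free)
    states = np.zeros((rows.size, n), dtype=np.uint8)
    for j, i in enumerate(free):
        states[:, i] = (rows >> j) & 1
    for g, v in (clamps or {}).items():
        states[:, model.genes.index(g)] = int(v)

    successors = stepper.step_many(states)
    code_of = {tuple(int(v) for v in s): i for i, s in enumerate(states)}
    succ = np.array([code_of[tuple(int(v) for v in s)] for s in successors])

    # functional-graph traversal: colour 0 unvisited, 1 on stack, 2 done
    colour = np.zeros(rows.size, dtype=np.uint8)
    attractor_of = np.full(rows.size, -1, dtype=np.int64)
    cycles: list[tuple[State, ...]] = []
    for s0 in range(rows.size):
        if colour[s0] == 2:
            continue
        path = []
        s = s0
        while colour[s] == 0:
            colour[s] = 1
            path.append(s)
            s = succ[s]
        if colour[s] == 1:  # new cycle discovered on this path
            cyc_start = path.index(s)
            cycle_states = [tuple(int(v) for v in states[i])
                            for i in path[cyc_start:]]
            key = _canonical_cycle(cycle_states)
            cycles.append(key)
            aid = len(cycles) - 1
        else:
            aid = attractor_of[s]
        for i in path:
            attractor_of[i] = aid
            colour[i] = 2
    basin_counts = np.bincount(attractor_of, minlength=len(cycles))
    attractors = [
        Attractor(cycles[i], int(basin_counts[i]), tuple(model.genes))
        for i in range(len(cycles))
    ]
    return AttractorSet(attractors, int(rows.size), tuple(model.genes))


@dataclass
class PerturbationResult:
    """Per-gene knockdown outcome comparing stable phenotypes.

    ``changes[g]`` is up-regulated / down-regulated / unchanged, or
    oscillating when either phenotype has no majority state for g (such
    genes are excluded from the up/down classification).
    """

    knocked: tuple[str, ...]
    unperturbed: dict[str, object]
    perturbed: dict[str, object]
    changes: dict[str, str] = field(default_factory=dict)
    unperturbed_attractors: AttractorSet | None = None
    perturbed_attractors: AttractorSet | None = None

    @property
    def upregulated(self) -> list[str]:
        return sorted(g for g, c in self.changes.items() if c == UP)

    @property
    def downregulated(self) -> list[str]:
        return sorted(g for g, c in self.changes.items() if c == DOWN)

    @property
    def oscillating(self) -> list[str]:
        return sorted(g for g, c in self.changes.items() if c == OSCILLATING)

    @property
    def n_changed(self) -> int:
        return len(self.upregulated) + len(self.downregulated)


def classify_changes(unperturbed: Mapping[str, object],
                     perturbed: Mapping[str, object]) -> dict[str, str]:
    """The per-gene comparison: (0,1)->up, (1,0)->down, equal->unchanged;
    oscillating states are flagged and not classified."""
    changes: dict[str, str] = {}
    for g in unperturbed:
        u, p = unperturbed[g], perturbed[g]
        if u == OSCILLATING or p == OSCILLATING:
            changes[g] = OSCILLATING
        elif (u, p) == (0, 1):
            changes[g] = UP
        elif (u, p) == (1, 0):
            changes[g] = DOWN
        else:
            changes[g] = UNCHANGED
    return changes


def perturbation_experiment(model: BooleanNetwork, knocked: Iterable[str],
                            n_starts: int = 100, seed: int = 0,
                            ) -> PerturbationResult:
    """Knock down ``knocked`` (clamp to OFF throughout) and classify every
    gene by comparing the max-basin attractors of the unperturbed and
    perturbed models, both simulated from the same seeded random starts."""
    knocked = tuple(sorted(set(knocked)))
    if not knocked:
        raise ValueError("empty knockdown set; use sample_attractors instead")
    missing = [g for g in knocked if g not in model.genes]
    if missing:
        raise ValueError(f"knocked genes not in model: {missing}")
    base = sample_attractors(model, n_starts=n_starts, seed=seed)
    pert = sample_attractors(model, n_starts=n_starts, seed=seed,
                             clamps={g: 0 for g in knocked})
    unperturbed = base.max_basin.collapsed
    perturbed = pert.max_basin.collapsed
    return PerturbationResult(
        knocked=knocked,
        unperturbed=unperturbed,
        perturbed=perturbed,
        changes=classify_changes(unperturbed, perturbed),
        unperturbed_attractors=base,
        perturbed_attractors=pert,
    )
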