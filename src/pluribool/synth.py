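"""Ground-truth generators and the packaged pluripotency fixture.

Every stage of the pipeline is testable without downloads: random signed
topologies with a requested number of positive auto-regulatory loops,
synchronous binary trajectories with optional bit-flip noise, and per-gene
bimodal continuous expression (a two-component Gaussian location mixture
whose components correspond to the binary states).  All generators are
seed-deterministic.

The packaged fixture is a SYNTHETIC stand-in for a literature-curated
45-node human pluripotency network: it has the canonical structure (45
nodes; 65 non-self edges plus 4 positive auto-regulatory loops; 19
pluripotency TF / 21 differentiation / 2 epigenetic / 3 other nodes) and
contains the well-known literature-reported interactions of the system,
with the remainder filled in from field-standard pluripotency wiring.  It
is a constructed reconstruction, not a curated edge list; per-edge
provenance ships in ``data/edge_provenance.synthetic.tsv``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .logic import BooleanNetwork, synthesize_logic
from .network import (ACTIVATION, CATEGORIES, INHIBITION, GeneNode,
                      Interaction, SignedNetwork, integrate_networks,
                      read_network)
from .simulate import Stepper


@dataclass
class SynthConfig:
    """Study-condition parameters for the generators.

    Defaults mirror the modelled system: a 45-gene network with 4 positive
    auto-regulatory loops and sparse regulation (mean in-degree 1.5, about
    a quarter of edges inhibitory), and log-scale expression whose low/high
    mixture components (means 2 and 8, sd 0.8) give near-clean but not
    degenerate binarization.
    """

    n_genes: int = 45
    mean_in_degree: float = 1.5
    inhibition_probability: float = 0.25
    self_activation_count: int = 4
    n_timepoints: int = 20
    noise_rate: float = 0.0
    low_mean: float = 2.0
    high_mean: float = 8.0
    low_sd: float = 0.8
    high_sd: float = 0.8
    seed: int = 0

    def __post_init__(self):
        for p in (self.inhibition_probability, self.noise_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_genes < 1 or self.n_timepoints < 1:
            raise ValueError("counts must be positive")
        if self.self_activation_count > self.n_genes:
            raise ValueError("more self-activations than genes")
        if self.low_mean >= self.high_mean:
            raise ValueError("mixture means must be ordered low < high")


def generate_topology(config: SynthConfig) -> SignedNetwork:
    """Random signed DAG-plus-loops with known structure.

    Genes are laid out in a random topological order; gene i draws a
    Poisson(mean_in_degree) number of regulators from its predecessors
    (clipped to what is available), so the non-self topology is acyclic and
    genes that draw none are inputs.  ``self_activation_count`` genes then
    gain a positive auto-regulatory loop.  Categories are assigned
    round-robin.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    names = [f"G{i:02d}" for i in range(config.n_genes)]
    order = list(rng.permutation(config.n_genes))
    net = SignedNetwork(
        GeneNode(names[i], CATEGORIES[i % len(CATEGORIES)])
        for i in range(config.n_genes)
    )
    for pos, i in enumerate(order):
        avail = [names[j] for j in order[:pos]]
        k = min(int(rng.poisson(config.mean_in_degree)), len(avail))
        if k > 0:
            regs = rng.choice(len(avail), size=k, replace=False)
            for r in sorted(regs):
                sign = (INHIBITION
                        if rng.random() < config.inhibition_probability
                        else ACTIVATION)
                net.add_interaction(Interaction(avail[r], names[i], sign))
    if config.self_activation_count > 0:
        chosen = rng.choice(config.n_genes,
                            size=config.self_activation_count, replace=False)
        for i in sorted(chosen):
            net.add_interaction(Interaction(names[i], names[i], ACTIVATION))
    return net


def generate_timeseries(model: BooleanNetwork, n_steps: int = 20,
                        noise_rate: float = 0.0, seed: int = 0,
                        start=None) -> pd.DataFrame:
    """Synchronous binary trajectory as a genes-by-time 0/1 DataFrame.

    Starts from a seeded uniform random state (or ``start``), records
    ``n_steps`` states (including the start) and flips each emitted bit
    independently with probability ``noise_rate``.
    """
    if n_steps < 2:
        raise ValueError("need n_steps >= 2")
    rng = np.random.default_rng(seed)
    n = len(model.genes)
    stepper = Stepper(model)
    if start is None:
        state = rng.integers(0, 2, size=n, dtype=np.uint8)
    else:
        state = np.asarray(start, dtype=np.uint8)
    trajectory = np.empty((n, n_steps), dtype=np.uint8)
    for t in range(n_steps):
        trajectory[:, t] = state
        state = np.asarray(stepper.step(state), dtype=np.uint8)
    if noise_rate > 0:
        flips = rng.random(trajectory.shape) < noise_rate
        trajectory = trajectory ^ flips.astype(np.uint8)
    return pd.DataFrame(trajectory, index=list(model.genes),
                        columns=[f"t{t}" for t in range(n_steps)])


def generate_expression(binary: pd.DataFrame, config: SynthConfig,
                        seed: int | None = None) -> pd.DataFrame:
    """Continuous expression from binary states via a Gaussian location
    mixture: state 0 ~ N(low_mean, low_sd), state 1 ~ N(high_mean, high_sd).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    states = binary.values.astype(int)
    means = np.where(states == 1, config.high_mean, config.low_mean)
    sds = np.where(states == 1, config.high_sd, config.low_sd)
    values = rng.normal(means, sds)
    return pd.DataFrame(values, index=binary.index, columns=binary.columns)


# ---------------------------------------------------------------------------
# Packaged pluripotency fixture (synthetic stand-in)
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(resources.files("pluribool").joinpath("data", name))


def pluripotency_fixture(integrated: bool = False,
                         ) -> tuple[SignedNetwork, BooleanNetwork]:
    """The packaged synthetic 45-node pluripotency network and its logic.

    With ``integrated=False`` returns the curated-style topology (45 nodes,
    65 edges, 4 positive auto-regulatory loops) and the logic synthesized
    from it; KLF4, TBX3 and FGFR2 have no curated regulators and are model
    inputs.  With ``integrated=True`` the nine novel interactions learned
    in the reconstruction step (NANOG -| KLF4; NANOG/POU5F1/SOX2 -> TBX3;
    FGF2 -> FGFR2; FGFR2 -| TCF3, NOG, BMP4; the MYC negative auto-loop)
    are merged in with provenance ``inferred`` and the logic re-derived.

    This fixture is synthetic: see the module docstring and the provenance
    TSV for what is literature-named versus constructed.
    """
    curated = read_network(_data_path("curated_edges.synthetic.tsv"),
                           _data_path("annotations.synthetic.tsv"))
    if not integrated:
        return curated, synthesize_logic(curated)
    novel = read_network(_data_path("novel_edges.synthetic.tsv"),
                         _data_path("annotations.synthetic.tsv"))
    merged, _ = integrate_networks(curated, novel)
    return merged, synthesize_logic(merged)


def snapshot_expression(n_cells: int = 10, n_steps: int = 12,
                        seed: int = 0,
                        config: SynthConfig | None = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic stand-in for the single-cell expression matrix.

    Simulates ``n_cells`` synchronous trajectories of the integrated
    fixture model from random starts (held inputs differ between cells,
    like heterogeneous single cells) and emits bimodal expression for every
    recorded state.  Returns (expression, binary_truth), both genes by
    (cell, time) columns.
    """
    config = config or SynthConfig(seed=seed)
    _, model = pluripotency_fixture(integrated=True)
    rng = np.random.default_rng(seed)
    frames = []
    for c in range(n_cells):
        ts = generate_timeseries(model, n_steps=n_steps,
                                 seed=int(rng.integers(2 ** 31)))
        ts.columns = [f"c{c}_{col}" for col in ts.columns]
        frames.append(ts)
    binary = pd.concat(frames, axis=1)
    expression = generate_expression(binary, config,
                                     seed=int(rng.integers(2 ** 31)))
    return expression, binary
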