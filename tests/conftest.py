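"""Shared fixtures: tiny hand-built models and the packaged network."""

from __future__ import annotations

import numpy as np
import pytest

from pluribool.logic import BooleanNetwork, parse_expression, BooleanFunction
from pluribool.network import (ACTIVATION, INHIBITION, GeneNode, Interaction,
                               SignedNetwork)


def model_from_rules(rules: dict[str, str],
                     extra_inputs: tuple[str, ...] = ()) -> BooleanNetwork:
    """Build a BooleanNetwork from {target: rule-string}."""
    functions = {t: BooleanFunction(t, parse_expression(e))
                 for t, e in rules.items()}
    genes = set(functions) | set(extra_inputs)
    for fn in functions.values():
        genes |= set(fn.regulators)
    return BooleanNetwork(sorted(genes), functions)


@pytest.fixture
def toggle_model() -> BooleanNetwork:
    """A'=B, B'=A: forced 2-cycle from mixed states."""
    return model_from_rules({"A": "B", "B": "A"})


@pytest.fixture
def small_network() -> SignedNetwork:
    net = SignedNetwork([
        GeneNode("A", "pluripotency_tf"),
        GeneNode("B", "pluripotency_tf"),
        GeneNode("C", "differentiation"),
    ])
    net.add_interaction(Interaction("A", "B", ACTIVATION))
    net.add_interaction(Interaction("C", "B", INHIBITION))
    net.add_interaction(Interaction("A", "A", ACTIVATION))
    return net


def random_model(rng: np.random.Generator, n_genes: int = 8,
                 max_k: int = 3) -> BooleanNetwork:
    """Random Boolean model: each gene gets a random truth table over a
    random regulator subset (possibly empty -> input gene)."""
    from pluribool.logic import expr_from_table

    genes = [f"G{i}" for i in range(n_genes)]
    functions = {}
    for g in genes:
        k = int(rng.integers(0, max_k + 1))
        if k == 0:
            continue
        regs = tuple(sorted(rng.choice(genes, size=k, replace=False)))
        table = rng.integers(0, 2, size=2 ** k)
        functions[g] = BooleanFunction(g, expr_from_table(regs, table))
    return BooleanNetwork(genes, functions)
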