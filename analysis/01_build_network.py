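#!/usr/bin/env python
"""Build the signed pluripotency network and derive its Boolean logic.

Loads the packaged curated 45-node topology (a documented synthetic
reconstruction), reports its structure, synthesizes the update rules from
the signed edges (activators OR-joined, any active inhibitor vetoes, the
POU5F1-SOX2 dimer AND-joined), and writes the network and rule files for
the downstream steps.  The integrated variant (curated plus the nine novel
interactions from the reconstruction step) is written alongside.
"""

from pathlib import Path

from pluribool.logic import write_model
from pluribool.network import network_stats
from pluribool.synth import pluripotency_fixture

OUT = Path(__file__).resolve().parent.parent / "results" / "network"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for label, integrated in (("curated", False), ("integrated", True)):
        network, model = pluripotency_fixture(integrated=integrated)
        stats = network_stats(network)
        print(f"{label} network: {stats.n_nodes} nodes, {stats.n_edges} "
              f"edges, {stats.n_self_loops} auto-regulatory loops "
              f"({stats.n_self_activations} positive) -> "
              f"{stats.n_interactions} interactions")
        print(f"  categories: {dict(stats.nodes_per_category)}")
        print(f"  input genes (no regulators): {', '.join(model.inputs)}")
        paths = write_model(network, model, OUT / label)
        print(f"  wrote {', '.join(str(p) for p in paths.values())}")


if __name__ == "__main__":
    main()
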