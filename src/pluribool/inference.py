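"""Rule validation against binarized data, best-fit Boolean rule inference
from time-series states, and topology-guided candidate selection.

The inference is the standard lazy best-fit search: for every gene,
regulator subsets up to ``max_k`` are enumerated, each subset's truth table
is filled by majority vote over the observed one-step transitions (exact
ties enumerate both completions), and the mismatch count over all
transitions scores the candidate.  All candidates achieving the minimal
error are returned with uniform probabilities.  Selection then picks, per
gene, the candidate whose regulator set is most similar to the
topology-derived rule (Jaccard index plus a half-weight bonus for sign
agreement on shared regulators), yielding the reconstructed model.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binarize import BinarizedMatrix
from .logic import (BooleanFunction, BooleanNetwork, Expr, evaluate,
                    expr_from_table, regulator_signs, to_string)

VALIDATED = "validated"
VIOLATED = "violated"
SKIPPED = "skipped"

FIXED_POINT = "fixed_point"
TRANSITION = "transition"


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Per-gene verdicts plus the validated fraction over decided genes."""

    verdicts: dict[str, str]
    mode: str

    @property
    def n_validated(self) -> int:
        return sum(1 for v in self.verdicts.values() if v == VALIDATED)

    @property
    def n_violated(self) -> int:
        return sum(1 for v in self.verdicts.values() if v == VIOLATED)

    @property
    def fraction_validated(self) -> float:
        decided = self.n_validated + self.n_violated
        return self.n_validated / decided if decided else float("nan")


def _states_frame(binarized) -> pd.DataFrame:
    if isinstance(binarized, BinarizedMatrix):
        return binarized.states
    return pd.DataFrame(binarized)


def _gene_level(binarized) -> pd.Series:
    if isinstance(binarized, BinarizedMatrix):
        return binarized.gene_states()
    frame = pd.DataFrame(binarized)
    if frame.shape[1] == 1:
        return frame.iloc[:, 0].astype(int)
    return (frame.mean(axis=1) > 0.5).astype(int)


def validate_functions(model: BooleanNetwork, binarized,
                       mode: str = FIXED_POINT,
                       min_agreement: float = 1.0) -> ValidationReport:
    """Check each rule against observed binary states.

    ``fixed_point`` mode evaluates every rule on the gene-level state
    vector and validates it when the output equals the target's own state —
    the snapshot is treated as a steady state of the logic.  ``transition``
    mode feeds the state at t-1 into the rule and validates when the
    prediction matches the observation at t for at least ``min_agreement``
    of the consecutive pairs.  Genes whose rule references a gene with no
    state are skipped with a warning.
    """
    if mode not in (FIXED_POINT, TRANSITION):
        raise ValueError(f"unknown mode {mode!r}")
    verdicts: dict[str, str] = {}
    if mode == FIXED_POINT:
        states = _gene_level(binarized)
        env = {g: int(states[g]) for g in states.index}
        for gene, fn in sorted(model.functions.items()):
            needed = set(fn.regulators) | {gene}
            if not needed <= set(states.index):
                warnings.warn(f"no state for some regulators of {gene}; "
                              "skipping")
                verdicts[gene] = SKIPPED
                continue
            predicted = int(bool(fn(env)))
            verdicts[gene] = (VALIDATED if predicted == env[gene]
                              else VIOLATED)
    else:
        series = _states_frame(binarized)
        if series.shape[1] < 2:
            raise ValueError("transition mode needs >= 2 time points")
        env = {g: series.loc[g].values[:-1].astype(bool)
               for g in series.index}
        for gene, fn in sorted(model.functions.items()):
            needed = set(fn.regulators) | {gene}
            if not needed <= set(series.index):
                warnings.warn(f"no state for some regulators of {gene}; "
                              "skipping")
                verdicts[gene] = SKIPPED
                continue
            predicted = np.asarray(fn(env), dtype=bool)
            predicted = np.broadcast_to(predicted, (series.shape[1] - 1,))
            observed = series.loc[gene].values[1:].astype(bool)
            agree = float(np.mean(predicted == observed))
            verdicts[gene] = (VALIDATED if agree >= min_agreement
                              else VIOLATED)
    return ValidationReport(verdicts, mode)


# ---------------------------------------------------------------------------
# Best-fit candidate inference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Candidate:
    """One inferred rule: regulator subset + truth table, with its error."""

    function: BooleanFunction
    regulators: tuple[str, ...]
    error: int
    probability: float

    @property
    def rule_string(self) -> str:
        return to_string(self.function.expression)


@dataclass
class CandidateSet:
    """Per-gene minimal-error candidates with uniform probabilities."""

    candidates: dict[str, list[Candidate]]
    truncated: dict[str, bool] = field(default_factory=dict)

    def genes(self) -> list[str]:
        return sorted(self.candidates)

    def to_json(self, path: str | Path,
                max_per_gene: int | None = None) -> None:
        """Serialize per-gene candidates; ``max_per_gene`` truncates the
        written lists (probabilities still describe the full set)."""
        payload = {
            gene: [{"rule": c.rule_string, "error": c.error,
                    "probability": c.probability}
                   for c in cands[:max_per_gene]]
            for gene, cands in sorted(self.candidates.items())
        }
        text = json.dumps(payload, indent=1, separators=(",", ": "))
        Path(path).write_text(text + "\n")


def _collect_transitions(series) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack one-step transitions from one series or a list of series.

    Returns (X, Y, genes): X[t] the full state at time t, Y[t] the state one
    step later, rows pooled across all provided series.
    """
    if isinstance(series, (list, tuple)):
        frames = [pd.DataFrame(s) for s in series]
        genes = list(frames[0].index)
        for f in frames[1:]:
            if list(f.index) != genes:
                raise ValueError("all series must share the same gene order")
    else:
        frames = [pd.DataFrame(series)]
        genes = list(frames[0].index)
    xs, ys = [], []
    for f in frames:
        arr = f.values.astype(np.uint8)
        if arr.shape[1] >= 2:
            xs.append(arr[:, :-1].T)
            ys.append(arr[:, 1:].T)
    if not xs:
        raise ValueError("no transitions: every series has < 2 time points")
    return np.vstack(xs), np.vstack(ys), genes


def infer_candidate_functions(series, max_k: int = 3,
                              allowed_regulators: Mapping[str, Sequence[str]]
                              | Sequence[str] | None = None,
                              max_candidates_per_gene: int = 1000,
                              ) -> CandidateSet:
    """Best-fit truth-table inference from binarized time series.

    ``series`` is a genes-by-time 0/1 DataFrame or a list of them (their
    one-step transitions are pooled).  For each gene, every regulator
    subset of size <= ``max_k`` (restricted to ``allowed_regulators`` when
    given, globally or per gene) is scored by its minimal mismatch count;
    ties in a truth-table cell (including unseen input patterns) enumerate
    both completions.  All candidates at the per-gene minimal error are
    returned, deterministically ordered and capped at
    ``max_candidates_per_gene`` (the cap is recorded per gene).
    """
    if max_k > 5:
        raise ValueError("max_k > 5 is combinatorially unsupported")
    X, Y, genes = _collect_transitions(series)
    gene_index = {g: i for i, g in enumerate(genes)}

    if allowed_regulators is None:
        pools = {g: genes for g in genes}
    elif isinstance(allowed_regulators, Mapping):
        pools = {g: sorted(set(allowed_regulators.get(g, genes)))
                 for g in genes}
    else:
        pool = sorted(set(allowed_regulators))
        pools = {g: pool for g in genes}

    best: dict[str, list[tuple[tuple[str, ...], np.ndarray]]] = {
        g: [] for g in genes}
    best_err: dict[str, int] = {g: X.shape[0] + 1 for g in genes}
    truncated = {g: False for g in genes}

    for gene in genes:
        y = Y[:, gene_index[gene]].astype(np.int64)
        pool = pools[gene]
        for k in range(0, max_k + 1):
            for subset in itertools.combinations(pool, k):
                idx = np.zeros(X.shape[0], dtype=np.int64)
                for j, reg in enumerate(subset):
                    idx |= X[:, gene_index[reg]].astype(np.int64) << j
                n_cells = 1 << k
                ones = np.bincount(idx, weights=y, minlength=n_cells)
                tot = np.bincount(idx, minlength=n_cells)
                err = int(np.minimum(ones, tot - ones).sum())
                if err > best_err[gene]:
                    continue
                if err < best_err[gene]:
                    best_err[gene] = err
                    best[gene] = []
                    truncated[gene] = False
                base = np.where(ones * 2 > tot, 1, 0).astype(np.uint8)
                tie_cells = np.flatnonzero(ones * 2 == tot)
                n_completions = 1 << len(tie_cells)
                for bits in range(n_completions):
                    if len(best[gene]) >= max_candidates_per_gene:
                        truncated[gene] = True
                        break
                    table = base.copy()
                    for b, cell in enumerate(tie_cells):
                        table[cell] = (bits >> b) & 1
                    best[gene].append((subset, table))
                if truncated[gene]:
                    continue

    candidates: dict[str, list[Candidate]] = {}
    for gene in genes:
        entries = best[gene]
        prob = 1.0 / len(entries) if entries else 0.0
        cands = []
        for subset, table in entries:
            expr = expr_from_table(subset, table)
            cands.append(Candidate(BooleanFunction(gene, expr), subset,
                                   best_err[gene], prob))
        candidates[gene] = cands
    return CandidateSet(candidates, truncated)


# ---------------------------------------------------------------------------
# Topology-guided selection
# ---------------------------------------------------------------------------

def _jaccard(a: set[str], b: set[str]) -> float:
    if not a and not b:
        return 1.0
    union = a | b
    return len(a & b) / len(union)


def score_candidate(candidate: Candidate,
                    topology_fn: BooleanFunction | None) -> float:
    """Similarity of a candidate to the topology-derived rule: Jaccard of
    regulator sets plus 0.5 x fraction of shared regulators whose signs
    agree."""
    cand_signs = regulator_signs(candidate.function.expression)
    cand_regs = set(cand_signs)
    if topology_fn is None:
        topo_signs: dict[str, str] = {}
    else:
        topo_signs = regulator_signs(topology_fn.expression)
    topo_regs = set(topo_signs)
    score = _jaccard(cand_regs, topo_regs)
    shared = cand_regs & topo_regs
    if shared:
        agree = sum(1 for g in shared if cand_signs[g] == topo_signs[g])
        score += 0.5 * agree / len(shared)
    return score


def select_functions(candidates: CandidateSet,
                     topology_model: BooleanNetwork) -> BooleanNetwork:
    """Pick one candidate per gene by maximal topology similarity.

    Ties break toward fewer regulators, then lexicographic rule string.
    Genes absent from the candidate set keep their topology rule; genes
    with no topology rule (inputs) are selected purely by the tie-break
    (fewest regulators, then rule string), which favours the sparsest
    minimal-error explanation.
    """
    unknown = sorted(set(candidates.genes()) - set(topology_model.genes))
    if unknown:
        raise ValueError(f"candidate genes not in topology: {unknown}")
    functions: dict[str, BooleanFunction] = dict(topology_model.functions)
    for gene in candidates.genes():
        cands = candidates.candidates[gene]
        if not cands:
            continue
        topo_fn = topology_model.functions.get(gene)
        ranked = sorted(
            cands,
            key=lambda c: (-score_candidate(c, topo_fn),
                           len(regulator_signs(c.function.expression)),
                           c.rule_string),
        )
        chosen = ranked[0]
        if chosen.function.expression[0] == "const" and topo_fn is None:
            # a constant rule for a topology input carries no interaction
            # structure; keep the gene as an input instead
            functions.pop(gene, None)
            continue
        functions[gene] = chosen.function
    return BooleanNetwork(list(topology_model.genes), functions)
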