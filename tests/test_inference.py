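"""Rule validation, best-fit inference, topology-guided selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import model_from_rules, random_model
from pluribool.inference import (FIXED_POINT, TRANSITION, Candidate,
                                 CandidateSet, infer_candidate_functions,
                                 score_candidate, select_functions,
                                 validate_functions)
from pluribool.logic import (BooleanFunction, evaluate, parse_expression,
                             truth_table_equal)
from pluribool.simulate import synchronous_step


def _series(model, starts, n_steps=2):
    """One short series per start (genes x time frames)."""
    frames = []
    for s, start in enumerate(starts):
        cols = {f"s{s}_t0": list(start)}
        state = tuple(start)
        for t in range(1, n_steps):
            state = synchronous_step(model, state)
            cols[f"s{s}_t{t}"] = list(state)
        frames.append(pd.DataFrame(cols, index=list(model.genes)))
    return frames


# -- validation -------------------------------------------------------------

def test_fixed_point_validation_single_function():
    model = model_from_rules({"B": "A & C | D"})
    states = pd.Series({"A": 0, "C": 0, "D": 0, "B": 0})
    report = validate_functions(model, states.to_frame("s"), mode=FIXED_POINT)
    assert report.verdicts["B"] == "validated"
    states["B"] = 1
    report = validate_functions(model, states.to_frame("s"), mode=FIXED_POINT)
    assert report.verdicts["B"] == "violated"


def test_constant_model_matching_states_validates_fully():
    model = model_from_rules({"A": "1", "B": "0"})
    states = pd.DataFrame({"s": {"A": 1, "B": 0}})
    report = validate_functions(model, states, mode=FIXED_POINT)
    assert report.fraction_validated == 1.0


def test_validation_fraction_matches_independent_recount():
    rng = np.random.default_rng(21)
    for _ in range(10):
        model = random_model(rng, n_genes=8)
        states = pd.Series({g: int(v) for g, v in
                            zip(model.genes, rng.integers(0, 2, 8))})
        report = validate_functions(model, states.to_frame("s"),
                                    mode=FIXED_POINT)
        env = states.to_dict()
        recount = sum(
            int(bool(evaluate(fn.expression, env))) == env[g]
            for g, fn in model.functions.items())
        decided = report.n_validated + report.n_violated
        assert report.n_validated == recount
        assert decided == len(model.functions)
        assert report.fraction_validated == pytest.approx(recount / decided)


def test_validation_is_gene_order_invariant():
    rng = np.random.default_rng(3)
    model = random_model(rng, n_genes=8)
    states = pd.Series({g: int(v) for g, v in
                        zip(model.genes, rng.integers(0, 2, 8))})
    a = validate_functions(model, states.to_frame("s"))
    b = validate_functions(model, states[::-1].to_frame("s"))
    assert a.fraction_validated == b.fraction_validated


def test_transition_mode_validates_noise_free_trajectory():
    model = model_from_rules({"B": "A", "C": "!B"}, extra_inputs=("A",))
    start = (1, 0, 0)
    cols, state = {"t0": list(start)}, start
    for t in range(1, 6):
        state = synchronous_step(model, state)
        cols[f"t{t}"] = list(state)
    series = pd.DataFrame(cols, index=list(model.genes))
    report = validate_functions(model, series, mode=TRANSITION)
    assert report.fraction_validated == 1.0


def test_missing_regulator_state_is_skipped_with_warning():
    model = model_from_rules({"B": "A & Z"})
    states = pd.DataFrame({"s": {"A": 1, "B": 1}})
    with pytest.warns(UserWarning, match="skipping"):
        report = validate_functions(model, states)
    assert report.verdicts["B"] == "skipped"


# -- inference --------------------------------------------------------------

def test_identity_dependence_forced_by_coverage():
    """B(t+1)=A(t) observed in both A states leaves one zero-error rule."""
    model = model_from_rules({"B": "A"}, extra_inputs=("A",))
    frames = _series(model, [(0, 0), (1, 0)])
    cands = infer_candidate_functions(frames, max_k=1)
    b = cands.candidates["B"]
    assert all(c.error == 0 for c in b)
    assert len(b) == 1
    assert truth_table_equal(b[0].function.expression,
                             parse_expression("A"))
    assert b[0].probability == 1.0


def test_no_transitions_is_an_error():
    frame = pd.DataFrame({"t0": {"A": 1}})
    with pytest.raises(ValueError, match="transitions"):
        infer_candidate_functions(frame)


def test_generating_tables_among_zero_error_candidates_full_coverage():
    """With every state observed once, the generator is always recovered."""
    rng = np.random.default_rng(17)
    for _ in range(5):
        model = random_model(rng, n_genes=6, max_k=3)
        starts = list(itertools.product([0, 1], repeat=6))
        frames = _series(model, starts)
        cands = infer_candidate_functions(frames, max_k=3,
                                          max_candidates_per_gene=5000)
        for gene, fn in model.functions.items():
            zero = [c for c in cands.candidates[gene] if c.error == 0]
            assert zero, gene
            assert any(truth_table_equal(c.function.expression, fn.expression)
                       for c in zero), gene


def test_candidate_probabilities_are_uniform_and_share_min_error():
    model = model_from_rules({"B": "A"}, extra_inputs=("A", "C"))
    frames = _series(model, [(0, 0, 0), (1, 0, 1), (1, 1, 0), (0, 1, 1)])
    cands = infer_candidate_functions(frames, max_k=2)
    for gene, lst in cands.candidates.items():
        errors = {c.error for c in lst}
        assert len(errors) == 1
        assert sum(c.probability for c in lst) == pytest.approx(1.0)


def test_adding_transitions_never_decreases_candidate_error():
    """Error counts are monotone in the data for any fixed rule."""
    rng = np.random.default_rng(29)
    model = random_model(rng, n_genes=5, max_k=2)
    starts = [tuple(int(v) for v in rng.integers(0, 2, 5)) for _ in range(12)]
    frames = _series(model, starts, n_steps=3)
    # score a fixed candidate under growing data with a naive recount
    target = next(iter(model.functions))
    fn = model.functions[target]
    def error_on(frames_subset):
        err = 0
        for f in frames_subset:
            arr = f.values
            for t in range(arr.shape[1] - 1):
                env = dict(zip(f.index, arr[:, t]))
                pred = int(bool(evaluate(fn.expression, env)))
                err += pred != int(arr[f.index.get_loc(target), t + 1])
        return err
    errors = [error_on(frames[:k]) for k in range(1, len(frames) + 1)]
    assert all(b >= a for a, b in zip(errors, errors[1:]))


def test_allowed_regulator_restriction_is_respected():
    model = model_from_rules({"B": "A"}, extra_inputs=("A", "C"))
    frames = _series(model, list(itertools.product([0, 1], repeat=3)))
    cands = infer_candidate_functions(frames, max_k=2,
                                      allowed_regulators=["A"])
    for lst in cands.candidates.values():
        for c in lst:
            assert set(c.regulators) <= {"A"}


# -- selection --------------------------------------------------------------

def _candidate(gene, rule):
    fn = BooleanFunction(gene, parse_expression(rule))
    return Candidate(fn, fn.regulators, 0, 1.0)


def test_selection_prefers_larger_regulator_overlap():
    topo = model_from_rules({"T": "A & B"})
    cands = CandidateSet({"T": [_candidate("T", "A"),
                                _candidate("T", "A & B")]})
    selected = select_functions(cands, topo)
    assert set(selected.functions["T"].regulators) == {"A", "B"}


def test_selection_identity_dominates():
    topo = model_from_rules({"T": "(A | B) & !C"})
    cands = CandidateSet({"T": [_candidate("T", "A & C"),
                                _candidate("T", "(A | B) & !C"),
                                _candidate("T", "B")]})
    selected = select_functions(cands, topo)
    assert truth_table_equal(selected.functions["T"].expression,
                             topo.functions["T"].expression)


def test_selection_matches_bruteforce_argmax():
    rng = np.random.default_rng(41)
    topo = model_from_rules({"T": "(A | B) & !C"},
                            extra_inputs=("D", "E"))
    pool = ["A", "B", "C", "D", "E"]
    rules = []
    for _ in range(12):
        k = int(rng.integers(1, 4))
        regs = rng.choice(pool, size=k, replace=False)
        rules.append(" | ".join(regs) if rng.random() < 0.5
                     else " & ".join(regs))
    cands = CandidateSet({"T": [_candidate("T", r) for r in rules]})
    selected = select_functions(cands, topo)
    scores = [score_candidate(c, topo.functions["T"])
              for c in cands.candidates["T"]]
    best = max(scores)
    # the chosen candidate achieves the maximal score
    chosen = selected.functions["T"]
    chosen_scores = [s for c, s in zip(cands.candidates["T"], scores)
                     if truth_table_equal(c.function.expression,
                                          chosen.expression)]
    assert max(chosen_scores) == pytest.approx(best)


def test_selection_keeps_topology_rule_when_gene_has_no_candidates():
    topo = model_from_rules({"T": "A", "U": "B"})
    cands = CandidateSet({"T": [_candidate("T", "A")]})
    selected = select_functions(cands, topo)
    assert selected.functions["U"] == topo.functions["U"]


def test_selection_with_full_coverage_recovers_generator():
    """Inference + selection against the true topology reconstructs the
    generating rules truth-table-exactly for >= 95% of regulated genes."""
    rng = np.random.default_rng(53)
    hits = total = 0
    for _ in range(5):
        model = random_model(rng, n_genes=6, max_k=2)
        starts = list(itertools.product([0, 1], repeat=6))
        frames = _series(model, starts)
        cands = infer_candidate_functions(frames, max_k=2,
                                          max_candidates_per_gene=5000)
        selected = select_functions(cands, model)
        for gene, fn in model.functions.items():
            total += 1
            hits += truth_table_equal(selected.functions[gene].expression,
                                      fn.expression)
    assert total and hits / total >= 0.95


def test_candidate_json_serialization(tmp_path):
    cands = CandidateSet({"T": [_candidate("T", "A & !B")]})
    out = tmp_path / "cands.json"
    cands.to_json(out)
    import json
    payload = json.loads(out.read_text())
    assert payload["T"][0]["rule"] == "A & !B"
    assert payload["T"][0]["probability"] == 1.0
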