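"""Boolean rule trees, the BoolNet-style rule-file dialect, and
topology-to-logic synthesis.

A rule is a rooted tree over AND / OR / NOT whose leaves are gene symbols
(or the constants 0/1).  The synthesis rule turns a signed topology into
logic: a gene with activators A1..An and inhibitors I1..Im gets

    psi = (A1 | A2 | ... | An) & !(I1 | I2 | ... | Im)

so several active activators are vetoed by any single active inhibitor.
Genes on the dimer list (POU5F1+SOX2 by default) are AND-joined wherever
they co-regulate a target, modelling obligate heterodimer binding.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .network import ACTIVATION, INHIBITION, UNDEFINED, SignedNetwork

# Expression nodes are nested tuples (hashable, directly comparable):
#   ("var", name) | ("const", 0 or 1) | ("not", child)
#   ("and", (children...)) | ("or", (children...))
Expr = tuple

DEFAULT_DIMERS = (("POU5F1", "SOX2"),)


def var(name: str) -> Expr:
    return ("var", name)


def const(value: int) -> Expr:
    return ("const", int(bool(value)))


def not_(child: Expr) -> Expr:
    return ("not", child)


def and_(*children: Expr) -> Expr:
    """AND node; collapses to its child when given a single operand."""
    if len(children) == 1:
        return children[0]
    return ("and", tuple(children))


def or_(*children: Expr) -> Expr:
    if len(children) == 1:
        return children[0]
    return ("or", tuple(children))


def leaves(expr: Expr) -> set[str]:
    """Gene symbols appearing in the expression."""
    kind = expr[0]
    if kind == "var":
        return {expr[1]}
    if kind == "const":
        return set()
    if kind == "not":
        return leaves(expr[1])
    out: set[str] = set()
    for child in expr[1]:
        out |= leaves(child)
    return out


def evaluate(expr: Expr, state: Mapping[str, object]):
    """Evaluate on a complete state mapping.

    Values may be scalars (0/1, bool) or numpy arrays; logic is applied
    element-wise so one call evaluates a rule over many states at once.
    """
    kind = expr[0]
    if kind == "var":
        return np.asarray(state[expr[1]], dtype=bool)
    if kind == "const":
        return np.bool_(expr[1])
    if kind == "not":
        return np.logical_not(evaluate(expr[1], state))
    vals = [evaluate(c, state) for c in expr[1]]
    op = np.logical_and if kind == "and" else np.logical_or
    out = vals[0]
    for v in vals[1:]:
        out = op(out, v)
    return out


@dataclass(frozen=True)
class BooleanFunction:
    """An update rule for one target gene."""

    target: str
    expression: Expr

    def __post_init__(self):
        _check_arity(self.expression)

    @property
    def regulators(self) -> tuple[str, ...]:
        return tuple(sorted(leaves(self.expression)))

    def __call__(self, state: Mapping[str, object]):
        return evaluate(self.expression, state)

    def __str__(self) -> str:
        return f"{self.target} <- {to_string(self.expression)}"


def _check_arity(expr: Expr) -> None:
    kind = expr[0]
    if kind in ("var", "const"):
        return
    if kind == "not":
        _check_arity(expr[1])
        return
    if kind in ("and", "or"):
        if len(expr[1]) < 2:
            raise ValueError(f"{kind.upper()} node needs >=2 children")
        for child in expr[1]:
            _check_arity(child)
        return
    raise ValueError(f"unknown expression node {kind!r}")


def to_string(expr: Expr) -> str:
    """Serialize with operators ! & | and minimal parentheses.

    Precedence: ! > & > |.  AND/OR children are emitted in stored order so
    the output is deterministic and round-trips through the parser.
    """
    kind = expr[0]
    if kind == "var":
        return expr[1]
    if kind == "const":
        return str(expr[1])
    if kind == "not":
        inner = to_string(expr[1])
        if expr[1][0] in ("and", "or"):
            inner = f"({inner})"
        return f"!{inner}"
    sep = " & " if kind == "and" else " | "
    parts = []
    for child in expr[1]:
        s = to_string(child)
        if kind == "and" and child[0] == "or":
            s = f"({s})"
        parts.append(s)
    return sep.join(parts)


# ---------------------------------------------------------------------------
# Parser (dialect: `target, expr` with header `targets, factors`, or
# `target <- expr`; operators ! & | and parentheses; constants 0/1)
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(?:(?P<name>[A-Za-z_][\w.\-]*)|(?P<const>[01])"
                       r"|(?P<op>[!&|()]))")


class RuleSyntaxError(ValueError):
    pass


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip():
                raise RuleSyntaxError(f"cannot tokenize near {text[pos:]!r}")
            break
        if m.lastgroup == "name":
            tokens.append(("name", m.group("name")))
        elif m.lastgroup == "const":
            tokens.append(("const", m.group("const")))
        else:
            tokens.append(("op", m.group("op")))
        pos = m.end()
    return tokens


def parse_expression(text: str) -> Expr:
    """Parse a rule body; precedence ! > & > |."""
    tokens = _tokenize(text)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else (None, None)

    def take():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> Expr:
        terms = [parse_and()]
        while peek() == ("op", "|"):
            take()
            terms.append(parse_and())
        return or_(*terms)

    def parse_and() -> Expr:
        factors = [parse_unary()]
        while peek() == ("op", "&"):
            take()
            factors.append(parse_unary())
        return and_(*factors)

    def parse_unary() -> Expr:
        kind, value = peek()
        if (kind, value) == ("op", "!"):
            take()
            return not_(parse_unary())
        if (kind, value) == ("op", "("):
            take()
            inner = parse_or()
            if peek() != ("op", ")"):
                raise RuleSyntaxError("missing closing parenthesis")
            take()
            return inner
        if kind == "name":
            take()
            return var(value)
        if kind == "const":
            take()
            return const(int(value))
        raise RuleSyntaxError(f"unexpected token {value!r}")

    expr = parse_or()
    if pos != len(tokens):
        raise RuleSyntaxError(f"trailing input after expression: "
                              f"{tokens[pos:]!r}")
    return expr


# ---------------------------------------------------------------------------
# BooleanNetwork
# ---------------------------------------------------------------------------

@dataclass
class BooleanNetwork:
    """An executable synchronous Boolean model.

    ``genes`` is the ordered universe; every non-input gene has exactly one
    update rule, and ``inputs`` (genes with no regulators, hence no rule)
    hold their state under synchronous update.
    """

    genes: list[str]
    functions: dict[str, BooleanFunction] = field(default_factory=dict)

    def __post_init__(self):
        gene_set = set(self.genes)
        if len(gene_set) != len(self.genes):
            raise ValueError("duplicate gene symbols")
        for target, fn in self.functions.items():
            if target != fn.target:
                raise ValueError(f"function for {fn.target!r} keyed {target!r}")
            if target not in gene_set:
                raise ValueError(f"function target {target!r} not in gene list")
            missing = leaves(fn.expression) - gene_set
            if missing:
                raise ValueError(
                    f"rule for {target} uses unknown genes: {sorted(missing)}"
                )

    @property
    def inputs(self) -> list[str]:
        return [g for g in self.genes if g not in self.functions]

    def function(self, gene: str) -> BooleanFunction | None:
        return self.functions.get(gene)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BooleanNetwork):
            return NotImplemented
        return (sorted(self.genes) == sorted(other.genes)
                and self.functions == other.functions)


def read_functions(path: str | Path) -> BooleanNetwork:
    """Parse a rule file (one `target, expr` or `target <- expr` per line).

    Genes that appear only as rule leaves become input genes.  Two rules for
    one target are a hard error; syntax errors report the line number.
    """
    functions: dict[str, BooleanFunction] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if re.fullmatch(r"targets\s*,\s*factors", line, re.IGNORECASE):
                continue
            if "<-" in line:
                target, _, body = line.partition("<-")
            elif "," in line:
                target, _, body = line.partition(",")
            else:
                raise RuleSyntaxError(
                    f"{path}:{lineno}: expected 'target, expr' or "
                    "'target <- expr'"
                )
            target = target.strip()
            if not re.fullmatch(r"[A-Za-z_][\w.\-]*", target):
                raise RuleSyntaxError(f"{path}:{lineno}: bad target {target!r}")
            if target in functions:
                raise ValueError(f"{path}:{lineno}: second rule for {target}")
            try:
                expr = parse_expression(body)
            except RuleSyntaxError as err:
                raise RuleSyntaxError(f"{path}:{lineno}: {err}") from None
            functions[target] = BooleanFunction(target, expr)
    genes = set(functions)
    for fn in functions.values():
        genes |= leaves(fn.expression)
    return BooleanNetwork(sorted(genes), functions)


def write_functions(model: BooleanNetwork, path: str | Path) -> None:
    """Write the rule file in the `targets, factors` dialect, sorted by gene."""
    with open(path, "w") as fh:
        fh.write("targets, factors\n")
        for gene in sorted(model.functions):
            fn = model.functions[gene]
            fh.write(f"{gene}, {to_string(fn.expression)}\n")


def write_model(network: SignedNetwork, model: BooleanNetwork,
                out_dir: str | Path) -> dict[str, Path]:
    """Write edge TSV + annotation TSV + rule file; byte-stable output."""
    from .network import write_network  # local import to avoid cycle at load

    if set(model.genes) - set(network.genes):
        raise ValueError("model references genes outside the network universe")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": out / "edges.tsv",
        "annotations": out / "annotations.tsv",
        "rules": out / "rules.txt",
    }
    write_network(network, paths["edges"], paths["annotations"])
    write_functions(model, paths["rules"])
    return paths


# ---------------------------------------------------------------------------
# Topology -> logic synthesis
# ---------------------------------------------------------------------------

def synthesize_logic(network: SignedNetwork,
                     dimers: Sequence[Sequence[str]] = DEFAULT_DIMERS,
                     ) -> BooleanNetwork:
    """Derive one update rule per regulated gene from the signed topology.

    Activators are OR-joined, inhibitors are OR-joined under a NOT, and the
    two clauses are AND-joined; a clause is omitted when empty.  Dimer
    partners co-activating a target are AND-joined into a single clause
    term.  Regulator order is lexicographic.  Undefined signs must be
    resolved (by integration) first.
    """
    functions: dict[str, BooleanFunction] = {}
    for gene in network.genes:
        regs = network.regulators(gene)
        if not regs:
            continue  # input gene: no rule, holds state
        undefined = [e for e in regs if e.sign == UNDEFINED]
        if undefined:
            pairs = ", ".join(f"{e.source}->{e.target}" for e in undefined)
            raise ValueError(
                f"undefined interaction sign(s) {pairs}: integrate with an "
                "inferred network or resolve the signs before synthesis"
            )
        activators = sorted(e.source for e in regs if e.sign == ACTIVATION)
        inhibitors = sorted(e.source for e in regs if e.sign == INHIBITION)
        act_terms = _dimerize(activators, dimers)
        clauses = []
        if act_terms:
            clauses.append(or_(*act_terms))
        if inhibitors:
            clauses.append(not_(or_(*[var(i) for i in inhibitors])))
        functions[gene] = BooleanFunction(gene, and_(*clauses))
    return BooleanNetwork(network.genes, functions)


def _dimerize(activators: list[str],
              dimers: Sequence[Sequence[str]]) -> list[Expr]:
    """Group co-occurring dimer partners into AND terms; keep lexicographic
    order of first members for determinism."""
    remaining = list(activators)
    terms: list[Expr] = []
    for partners in dimers:
        if all(p in remaining for p in partners):
            terms.append(and_(*[var(p) for p in sorted(partners)]))
            for p in partners:
                remaining.remove(p)
    terms.extend(var(a) for a in remaining)
    terms.sort(key=lambda t: min(leaves(t)))
    return terms


# ---------------------------------------------------------------------------
# Truth tables and regulator signs
# ---------------------------------------------------------------------------

def truth_table(expr: Expr, order: Sequence[str] | None = None) -> np.ndarray:
    """Truth table over the expression's leaves (<= 20 of them).

    Row index i encodes the assignment where ``order[j]`` holds bit j of i
    (least-significant first).
    """
    if order is None:
        order = sorted(leaves(expr))
    k = len(order)
    if k > 20:
        raise ValueError(f"refusing truth table over {k} variables")
    rows = np.arange(2 ** k)
    state = {g: (rows >> j) & 1 for j, g in enumerate(order)}
    extra = leaves(expr) - set(order)
    if extra:
        raise ValueError(f"order omits leaves: {sorted(extra)}")
    out = evaluate(expr, state)
    return np.broadcast_to(np.asarray(out, dtype=bool), rows.shape).copy()


def truth_table_equal(a: Expr, b: Expr) -> bool:
    order = sorted(leaves(a) | leaves(b))
    return bool(np.array_equal(truth_table(a, order), truth_table(b, order)))


def regulator_signs(expr: Expr) -> dict[str, str]:
    """Classify each leaf by truth-table monotonicity.

    Non-decreasing in a variable -> activation, non-increasing ->
    inhibition, non-monotone -> undefined.  Dummy variables (the table does
    not depend on them) are dropped.
    """
    order = sorted(leaves(expr))
    table = truth_table(expr, order)
    signs: dict[str, str] = {}
    for j, gene in enumerate(order):
        rows = np.arange(table.size)
        lo = table[rows[((rows >> j) & 1) == 0]]
        hi = table[rows[((rows >> j) & 1) == 1]]
        inc = bool(np.all(hi >= lo))
        dec = bool(np.all(hi <= lo))
        if inc and dec:
            continue  # dummy variable
        if inc:
            signs[gene] = ACTIVATION
        elif dec:
            signs[gene] = INHIBITION
        else:
            signs[gene] = UNDEFINED
    return signs


def expr_from_table(order: Sequence[str], table: np.ndarray) -> Expr:
    """Smallest-effort expression for a truth table: constants, single
    literal where possible, else a disjunctive normal form."""
    table = np.asarray(table, dtype=bool)
    k = len(order)
    assert table.size == 2 ** k
    if not table.any():
        return const(0)
    if table.all():
        return const(1)
    if k == 1:
        return var(order[0]) if table[1] else not_(var(order[0]))
    minterms = []
    for row in np.flatnonzero(table):
        lits = [var(g) if (row >> j) & 1 else not_(var(g))
                for j, g in enumerate(order)]
        minterms.append(and_(*lits))
    return or_(*minterms)


def model_to_network(model: BooleanNetwork,
                     annotations: Mapping[str, str] | None = None,
                     provenance: str = "inferred") -> SignedNetwork:
    """Derive the signed topology implied by a rule set (edge per regulator,
    sign from monotonicity; dummy regulators are dropped)."""
    from .network import GeneNode, Interaction

    annotations = annotations or {}
    net = SignedNetwork(
        GeneNode(g, annotations.get(g, "other")) for g in model.genes
    )
    for gene in sorted(model.functions):
        fn = model.functions[gene]
        for reg, sign in sorted(regulator_signs(fn.expression).items()):
            net.add_interaction(
                Interaction(reg, gene, sign, provenance)
            )
    return net
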