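"""Rule grammar: parsing, validation and evaluation of cell-behaviour rules.

A rule is a single statement

    ID: A -> B [+ C], D

where ``A`` is the source cell type, ``B`` the resulting type (or ``empty``),
``C`` an optional second product (used for duplication and migration), and
``D`` either a probability expression or an environment tag. Behavioural
rules change a cell's state or position with probability D; environmental
rules describe the exchange with the microenvironment:

    ID: A -> amount, environment(Glc|O2|YM)

``amount`` may be a non-negative number or the reserved token ``U``, which
resolves to the reference per-cell uptake (or stiffening increment) of the
tagged species.

Probability expressions are arithmetic (``+ - * /``, parentheses, ``min``,
``max``, ``exp``) over the context variables

    TIME  TD  Glc  O2  AGE  TLD  YM  C_<type>

plus any named constants supplied at parse time (the configuration's
parameter set, e.g. ``a``..``e``, ``s``). ``C_<type>`` is the count of cells
of that type divided by the lattice capacity.
"""

from __future__ import annotations

import ast
import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

__all__ = [
    "BehaviouralRule",
    "EnvironmentalRule",
    "RuleContext",
    "RuleSyntaxError",
    "RuleEvaluationError",
    "parse_rule",
    "format_rule",
    "evaluate_probability",
    "build_context",
    "CONTEXT_VARIABLES",
    "EMPTY_TYPE",
]

EMPTY_TYPE = "empty"
CONTEXT_VARIABLES = ("TIME", "TD", "Glc", "O2", "AGE", "TLD", "YM")
ENV_TAGS = ("Glc", "O2", "YM")
_FUNCS = {"min": min, "max": max, "exp": math.exp}

_ENV_TAG_RE = re.compile(r"^environment\s*\(\s*(\w+)\s*\)$")
_IDENT_RE = re.compile(r"^[A-Za-z_]\w*$")


class RuleSyntaxError(ValueError):
    """Malformed rule statement; carries a position hint when available."""


class RuleEvaluationError(ValueError):
    """Probability expression failed to evaluate (reports the rule id)."""


@dataclass(frozen=True)
class BehaviouralRule:
    rule_id: str
    source_type: str
    product_type: str
    extra_product: Optional[str]
    probability_expr: str
    _code: object = field(default=None, compare=False, repr=False)


@dataclass(frozen=True)
class EnvironmentalRule:
    rule_id: str
    source_type: str
    amount: Union[float, str]  # non-negative float, or the token "U"
    tag: str  # "Glc" | "O2" | "YM"


@dataclass(frozen=True)
class RuleContext:
    """Normalized per-cell, per-iteration variables feeding rule probabilities.

    All fields are dimensionless ratios: TIME is iteration/total, Glc and O2
    are local concentration over the fresh-media / incubator value, YM is the
    local stiffness over the scaffold's initial stiffness, AGE and TLD are
    iteration counts over the current iteration, TD is the death iteration
    over the total (0 for living cells). ``type_counts`` maps each declared
    type to its count over the lattice capacity.
    """

    TIME: float
    TD: float
    Glc: float
    O2: float
    AGE: float
    TLD: float
    YM: float
    type_counts: Mapping[str, float] = field(default_factory=dict)

    def as_namespace(self) -> dict[str, float]:
        ns = {v: getattr(self, v) for v in CONTEXT_VARIABLES}
        for t, frac in self.type_counts.items():
            ns[f"C_{t}"] = frac
        return ns


# ---------------------------------------------------------------------------
# expression compilation (ast whitelist)
# ---------------------------------------------------------------------------

_ALLOWED_BINOPS = (ast.Add, ast.Sub, ast.Mult, ast.Div)
_ALLOWED_UNARY = (ast.UAdd, ast.USub)


def _compile_expression(expr: str, rule_id: str, allowed_names: Optional[set[str]]) -> ast.Expression:
    try:
        tree = ast.parse(expr, mode="eval")
    except SyntaxError as exc:
        raise RuleSyntaxError(
            f"rule {rule_id}: invalid probability expression {expr!r} "
            f"(line {exc.lineno}, column {exc.offset})"
        ) from exc
    for node in ast.walk(tree):
        if isinstance(node, (ast.Expression, ast.Constant)):
            if isinstance(node, ast.Constant) and not isinstance(node.value, (int, float)):
                raise RuleSyntaxError(f"rule {rule_id}: non-numeric literal {node.value!r}")
        elif isinstance(node, ast.BinOp):
            if not isinstance(node.op, _ALLOWED_BINOPS):
                raise RuleSyntaxError(f"rule {rule_id}: operator not allowed in {expr!r}")
        elif isinstance(node, ast.UnaryOp):
            if not isinstance(node.op, _ALLOWED_UNARY):
                raise RuleSyntaxError(f"rule {rule_id}: operator not allowed in {expr!r}")
        elif isinstance(node, ast.Call):
            if not isinstance(node.func, ast.Name) or node.func.id not in _FUNCS or node.keywords:
                raise RuleSyntaxError(f"rule {rule_id}: only min/max/exp calls allowed in {expr!r}")
        elif isinstance(node, ast.Name):
            if node.id in _FUNCS:
                continue
            if allowed_names is not None and node.id not in allowed_names:
                raise RuleSyntaxError(
                    f"rule {rule_id}: unknown context variable {node.id!r} in {expr!r}"
                )
        elif isinstance(node, (ast.Load, *(_ALLOWED_BINOPS), *(_ALLOWED_UNARY))):
            continue
        else:
            raise RuleSyntaxError(
                f"rule {rule_id}: construct {type(node).__name__} not allowed in {expr!r}"
            )
    return tree


def _eval_node(node: ast.AST, ns: Mapping[str, float]) -> float:
    if isinstance(node, ast.Expression):
        return _eval_node(node.body, ns)
    if isinstance(node, ast.Constant):
        return float(node.value)
    if isinstance(node, ast.Name):
        try:
            return float(ns[node.id])
        except KeyError:
            raise RuleEvaluationError(f"undefined variable {node.id!r}") from None
    if isinstance(node, ast.BinOp):
        left, right = _eval_node(node.left, ns), _eval_node(node.right, ns)
        if isinstance(node.op, ast.Add):
            return left + right
        if isinstance(node.op, ast.Sub):
            return left - right
        if isinstance(node.op, ast.Mult):
            return left * right
        if isinstance(node.op, ast.Div):
            if right == 0:
                raise RuleEvaluationError("division by zero")
            return left / right
    if isinstance(node, ast.UnaryOp):
        v = _eval_node(node.operand, ns)
        return -v if isinstance(node.op, ast.USub) else v
    if isinstance(node, ast.Call):
        args = [_eval_node(a, ns) for a in node.args]
        return float(_FUNCS[node.func.id](*args))
    raise RuleEvaluationError(f"cannot evaluate node {type(node).__name__}")


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _check_type(token: str, cell_types, rule_id: str) -> str:
    if not _IDENT_RE.match(token):
        raise RuleSyntaxError(f"rule {rule_id}: invalid cell-type token {token!r}")
    if cell_types is not None and token != EMPTY_TYPE and token not in cell_types:
        raise RuleSyntaxError(f"rule {rule_id}: unknown cell type {token!r}")
    return token


def parse_rule(
    line: str,
    cell_types=None,
    constants: Optional[Mapping[str, float]] = None,
) -> Union[BehaviouralRule, EnvironmentalRule]:
    """Parse one rule statement.

    Parameters
    ----------
    line : str
        One statement, e.g. ``"R1: P -> P + P, 0.44"`` or
        ``"E1: P -> U, environment(Glc)"``.
    cell_types : collection of str, optional
        Declared cell-type names; when given, A/B/C tokens are validated
        against it (plus the reserved ``empty``).
    constants : mapping, optional
        Named constants (model parameters) usable inside probability
        expressions in addition to the context variables.
    """
    stmt = line.strip()
    if not stmt or stmt.startswith("#"):
        raise RuleSyntaxError("empty rule statement")
    # separate "ID:" (or "ID =") header from the body
    m = re.match(r"^(\w+)\s*[:=]\s*(.+)$", stmt)
    if not m:
        raise RuleSyntaxError(f"missing 'ID:' header in {stmt!r} (column 1)")
    rule_id, body = m.group(1), m.group(2)

    if "->" not in body:
        raise RuleSyntaxError(f"rule {rule_id}: missing '->' in {body!r}")
    lhs, rhs = body.split("->", 1)
    source = lhs.strip()
    if not source:
        raise RuleSyntaxError(f"rule {rule_id}: missing source type (A term)")

    # D term: split on the LAST top-level comma so expressions may contain
    # commas inside min()/max() calls
    depth, split_at = 0, -1
    for i, ch in enumerate(rhs):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif ch == "," and depth == 0:
            split_at = i
    if split_at < 0:
        raise RuleSyntaxError(f"rule {rule_id}: missing ', D' term")
    products, d_term = rhs[:split_at].strip(), rhs[split_at + 1 :].strip()
    if not products:
        raise RuleSyntaxError(f"rule {rule_id}: missing product (B term)")
    if not d_term:
        raise RuleSyntaxError(f"rule {rule_id}: empty D term")

    env_match = _ENV_TAG_RE.match(d_term)
    if env_match:
        tag = env_match.group(1)
        if tag not in ENV_TAGS:
            raise RuleSyntaxError(
                f"rule {rule_id}: unknown environment tag {tag!r} (expected one of {ENV_TAGS})"
            )
        if "+" in products:
            raise RuleSyntaxError(f"rule {rule_id}: environmental rules take a single B term")
        source = _check_type(source, cell_types, rule_id)
        amount: Union[float, str]
        if products == "U":
            amount = "U"
        else:
            try:
                amount = float(products)
            except ValueError:
                raise RuleSyntaxError(
                    f"rule {rule_id}: amount must be a number or 'U', got {products!r}"
                ) from None
            if amount < 0:
                raise RuleSyntaxError(f"rule {rule_id}: amount must be non-negative")
        return EnvironmentalRule(rule_id=rule_id, source_type=source, amount=amount, tag=tag)

    # behavioural rule
    source = _check_type(source, cell_types, rule_id)
    parts = [p.strip() for p in products.split("+")]
    if len(parts) > 2 or any(not p for p in parts):
        raise RuleSyntaxError(f"rule {rule_id}: products must be 'B' or 'B + C', got {products!r}")
    product = _check_type(parts[0], cell_types, rule_id)
    extra = _check_type(parts[1], cell_types, rule_id) if len(parts) == 2 else None

    allowed = set(CONTEXT_VARIABLES)
    if cell_types is not None:
        allowed |= {f"C_{t}" for t in cell_types}
        if constants:
            allowed |= set(constants)
        names = allowed
    else:
        # without declarations we cannot enumerate C_<type>; accept any C_* name
        names = None
    code = _compile_expression(d_term, rule_id, names)
    if names is None:
        for node in ast.walk(code):
            if (
                isinstance(node, ast.Name)
                and node.id not in _FUNCS
                and node.id not in CONTEXT_VARIABLES
                and not node.id.startswith("C_")
                and not (constants and node.id in constants)
            ):
                raise RuleSyntaxError(
                    f"rule {rule_id}: unknown context variable {node.id!r} in {d_term!r}"
                )
    return BehaviouralRule(
        rule_id=rule_id,
        source_type=source,
        product_type=product,
        extra_product=extra,
        probability_expr=d_term,
        _code=code,
    )


def format_rule(rule: Union[BehaviouralRule, EnvironmentalRule]) -> str:
    """Serialize a rule back to its canonical one-line form (round-trips)."""
    if isinstance(rule, EnvironmentalRule):
        amount = rule.amount if isinstance(rule.amount, str) else repr(rule.amount)
        return f"{rule.rule_id}: {rule.source_type} -> {amount}, environment({rule.tag})"
    prod = rule.product_type
    if rule.extra_product is not None:
        prod += f" + {rule.extra_product}"
    return f"{rule.rule_id}: {rule.source_type} -> {prod}, {rule.probability_expr}"


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_probability(
    rule: BehaviouralRule,
    ctx: RuleContext,
    constants: Optional[Mapping[str, float]] = None,
) -> float:
    """Evaluate a behavioural rule's probability in ``ctx``, clamped to [0, 1].

    Clamping (rather than raising) keeps calibration sweeps alive when an
    expression strays outside the unit interval.
    """
    ns = ctx.as_namespace()
    if constants:
        ns.update(constants)
    code = rule._code
    if code is None:
        code = _compile_expression(rule.probability_expr, rule.rule_id, None)
    try:
        value = _eval_node(code, ns)
    except RuleEvaluationError as exc:
        raise RuleEvaluationError(f"rule {rule.rule_id}: {exc}") from None
    if not math.isfinite(value):
        raise RuleEvaluationError(f"rule {rule.rule_id}: non-finite probability {value}")
    return min(1.0, max(0.0, value))


def build_context(
    cell,
    state,
    iteration: int,
    total_iterations: int,
    media_glucose: float,
    incubator_oxygen: float,
    capacity: Optional[int] = None,
    glucose_field=None,
    oxygen_field=None,
) -> RuleContext:
    """Assemble the normalized rule context for one cell at one iteration.

    AGE and TLD divide by the current iteration and are defined as 0 at
    iteration 0 (denominator guard); TD is 0 for living cells. The count
    fractions use the lattice capacity (sites x capacity-per-site) as the
    maximum population cardinality.
    """
    if cell.cell_id not in state.cells:
        raise KeyError(f"cell {cell.cell_id} is not registered")
    if capacity is None:
        capacity = state.n_sites
    it = int(iteration)
    total = max(int(total_iterations), 1)
    pos = cell.position
    glc_field = state.glucose if glucose_field is None else glucose_field
    o2_field = state.oxygen if oxygen_field is None else oxygen_field
    glc = glc_field[pos] / media_glucose if media_glucose > 0 else 0.0
    o2 = o2_field[pos] / incubator_oxygen if incubator_oxygen > 0 else 0.0
    ym = state.young_modulus[pos] / state.initial_young_modulus
    if it > 0:
        age = (it - cell.birth_iteration) / it
        tld = (it - cell.last_division_iteration) / it
    else:
        age = tld = 0.0
    td = (cell.death_iteration / total) if cell.death_iteration is not None else 0.0
    counts = state.count_by_type()
    type_counts = {t: n / capacity for t, n in counts.items()}
    return RuleContext(
        TIME=it / total,
        TD=td,
        Glc=float(glc),
        O2=float(o2),
        AGE=float(age),
        TLD=float(tld),
        YM=float(ym),
        type_counts=type_counts,
    )
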