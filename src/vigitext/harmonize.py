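"""Harmonization between adverse-event vocabularies.

Registries and trials report AEs under different category systems.  Two
rule kinds map them onto (or out of) the 12-class taxonomy:

* ``frequency_sum`` — a target category's count is the sum of counts of
  named source-table categories (how trial vocabularies such as
  pyrexia/fever sensation/elevated body temperature collapse to "fever");
* ``boolean_expression`` — a target category is a boolean AND/OR/NOT
  expression over the 12 classes, evaluated per report (how disjoint
  registry categories such as "fever with pain" are derived).

Rules are data, not code: they ship as declarative ``category = rule``
text files so further vocabularies can be added without touching the
pipeline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .labels import SYMPTOMS, class_index, stack_labels
from .stats import (
    FrequencyTable,
    correlation,
    fisher_exact_2x2,
    odds_ratio_2x2,
    prevalence_ratio,
)

# Boolean expression AST: ("var", name) | ("not", x) | ("and", x, y) | ("or", x, y)
_TOKEN_RE = re.compile(r"\(|\)|\bAND\b|\bOR\b|\bNOT\b|[A-Za-z_][A-Za-z0-9_]*")


@dataclass(frozen=True)
class MappingRule:
    """One target category with its mapping rule."""

    target: str
    kind: str  # "frequency_sum" | "boolean_expression"
    terms: tuple[str, ...] = ()
    expression: tuple | None = None


class RuleSyntaxError(ValueError):
    pass


def _tokenize(expr: str) -> list[str]:
    tokens = _TOKEN_RE.findall(expr)
    residue = _TOKEN_RE.sub("", expr).strip()
    if residue:
        raise RuleSyntaxError(f"unexpected characters in expression: {residue!r}")
    return tokens


def _parse_expr(tokens: list[str], pos: int = 0) -> tuple[tuple, int]:
    node, pos = _parse_term(tokens, pos)
    while pos < len(tokens) and tokens[pos] == "OR":
        rhs, pos = _parse_term(tokens, pos + 1)
        node = ("or", node, rhs)
    return node, pos


def _parse_term(tokens: list[str], pos: int) -> tuple[tuple, int]:
    node, pos = _parse_factor(tokens, pos)
    while pos < len(tokens) and tokens[pos] == "AND":
        rhs, pos = _parse_factor(tokens, pos + 1)
        node = ("and", node, rhs)
    return node, pos


def _parse_factor(tokens: list[str], pos: int) -> tuple[tuple, int]:
    if pos >= len(tokens):
        raise RuleSyntaxError("unexpected end of expression")
    tok = tokens[pos]
    if tok == "NOT":
        inner, pos = _parse_factor(tokens, pos + 1)
        return ("not", inner), pos
    if tok == "(":
        node, pos = _parse_expr(tokens, pos + 1)
        if pos >= len(tokens) or tokens[pos] != ")":
            raise RuleSyntaxError("unbalanced parentheses")
        return node, pos + 1
    if tok in (")", "AND", "OR"):
        raise RuleSyntaxError(f"unexpected token {tok!r}")
    class_index(tok)  # boolean atoms must be canonical class names
    return ("var", tok), pos + 1


def parse_boolean_expression(expr: str) -> tuple:
    tokens = _tokenize(expr)
    node, pos = _parse_expr(tokens)
    if pos != len(tokens):
        raise RuleSyntaxError(f"trailing tokens in expression: {tokens[pos:]}")
    return node


def evaluate_expression(node: tuple, values: Mapping[str, bool]) -> bool:
    op = node[0]
    if op == "var":
        return bool(values[node[1]])
    if op == "not":
        return not evaluate_expression(node[1], values)
    if op == "and":
        return evaluate_expression(node[1], values) and evaluate_expression(node[2], values)
    if op == "or":
        return evaluate_expression(node[1], values) or evaluate_expression(node[2], values)
    raise RuleSyntaxError(f"unknown node {op!r}")


def parse_rules(text: str) -> list[MappingRule]:
    """Parse a declarative rule file (``target = rule`` per line).

    Lines containing AND/OR/NOT are boolean expressions over the canonical
    classes; all other lines are frequency sums of source-table category
    names joined by ``+`` (single-term sums included).  ``#`` starts a
    comment.
    """
    rules: list[MappingRule] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise RuleSyntaxError(f"line {lineno}: expected 'target = rule'")
        target, rhs = (part.strip() for part in line.split("=", 1))
        if re.search(r"\b(AND|OR|NOT)\b", rhs):
            rules.append(
                MappingRule(
                    target=target,
                    kind="boolean_expression",
                    expression=parse_boolean_expression(rhs),
                )
            )
        else:
            terms = tuple(t.strip() for t in rhs.split("+") if t.strip())
            if not terms:
                raise RuleSyntaxError(f"line {lineno}: empty rule")
            rules.append(MappingRule(target=target, kind="frequency_sum", terms=terms))
    return rules


def load_rules(path: str | Path) -> list[MappingRule]:
    return parse_rules(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# Applying rules
# ---------------------------------------------------------------------------

def aggregate_trial_categories(
    source_table: FrequencyTable, rules: Sequence[MappingRule]
) -> FrequencyTable:
    """Collapse a source-vocabulary frequency table by frequency-sum rules.

    Each target count is the sum of its source-term counts; the denominator
    is preserved.  A missing source term is an error naming the term.
    """
    counts = []
    targets = []
    for rule in rules:
        if rule.kind != "frequency_sum":
            raise ValueError(
                f"rule for {rule.target!r} is {rule.kind}, not frequency_sum"
            )
        total = 0
        for term in rule.terms:
            if term not in source_table.categories:
                raise KeyError(
                    f"source term {term!r} (rule {rule.target!r}) not in source table"
                )
            total += source_table.count(term)
        targets.append(rule.target)
        counts.append(total)
    return FrequencyTable(tuple(targets), np.asarray(counts), source_table.denominator)


def map_registry_categories(
    labels: Sequence[bool], rules: Sequence[MappingRule] | None = None
) -> dict[str, bool]:
    """Evaluate boolean registry categories for one report's label vector."""
    if rules is None:
        rules = argentinian_rules()
    arr = np.asarray(labels, dtype=bool)
    values = {cls: bool(arr[class_index(cls)]) for cls in SYMPTOMS}
    out = {}
    for rule in rules:
        if rule.kind != "boolean_expression":
            raise ValueError(
                f"rule for {rule.target!r} is {rule.kind}, not boolean_expression"
            )
        out[rule.target] = evaluate_expression(rule.expression, values)
    return out


def registry_frequency_table(
    labelsets: Sequence[Sequence[bool]],
    rules: Sequence[MappingRule] | None = None,
    require_any_ae: bool = True,
) -> FrequencyTable:
    """Frequencies of boolean registry categories over a corpus.

    With ``require_any_ae`` the population (denominator) is restricted to
    reports with at least one of the 12 classes positive, matching how
    passive registries only receive reports that mention an AE.
    """
    if rules is None:
        rules = argentinian_rules()
    mat = stack_labels(labelsets)
    if require_any_ae:
        mat = mat[mat.any(axis=1)]
    if mat.shape[0] == 0:
        raise ValueError("no reports selected")
    targets = [r.target for r in rules]
    counts = np.zeros(len(rules), dtype=int)
    for row in mat:
        flags = map_registry_categories(row, rules)
        counts += np.array([flags[t] for t in targets], dtype=int)
    return FrequencyTable(tuple(targets), counts, mat.shape[0])


# ---------------------------------------------------------------------------
# Table-vs-table comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TableComparison:
    """Category-wise comparison of two frequency tables plus overall r."""

    table: pd.DataFrame
    pearson_r: float
    pearson_p: float


def compare_frequency_tables(
    table_a: FrequencyTable,
    table_b: FrequencyTable,
    label_a: str = "a",
    label_b: str = "b",
    percentages_a: Sequence[float] | None = None,
    percentages_b: Sequence[float] | None = None,
) -> TableComparison:
    """Per-category prevalence ratio (a vs b), odds ratio and Fisher p,
    plus the Pearson correlation of the two percentage vectors.

    ``percentages_*`` override the count-derived percentages for the
    correlation (used when a published table's printed percentages are not
    consistent with its printed counts).
    """
    if table_a.categories != table_b.categories:
        raise ValueError(
            f"category mismatch: {table_a.categories} vs {table_b.categories}"
        )
    pa = (
        np.asarray(percentages_a, dtype=float)
        if percentages_a is not None
        else table_a.percentages
    )
    pb = (
        np.asarray(percentages_b, dtype=float)
        if percentages_b is not None
        else table_b.percentages
    )
    rows = []
    for i, cat in enumerate(table_a.categories):
        ca, cb = int(table_a.counts[i]), int(table_b.counts[i])
        na, nb = table_a.denominator, table_b.denominator
        rows.append(
            {
                "category": cat,
                f"{label_a}_count": ca,
                f"{label_a}_percent": round(pa[i], 2),
                f"{label_b}_count": cb,
                f"{label_b}_percent": round(pb[i], 2),
                "prevalence_ratio": round(prevalence_ratio(ca, na, cb, nb), 2),
                "odds_ratio": round(odds_ratio_2x2(ca, na - ca, cb, nb - cb), 2),
                "fisher_p": fisher_exact_2x2(ca, na - ca, cb, nb - cb),
            }
        )
    r, p = correlation(pa, pb, method="pearson")
    return TableComparison(table=pd.DataFrame(rows), pearson_r=r, pearson_p=p)


# ---------------------------------------------------------------------------
# Shipped rule sets
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    from importlib.resources import files

    return Path(str(files("vigitext.data") / name))


def moscow_trial_rules() -> list[MappingRule]:
    """Frequency-sum rules collapsing the trial vocabulary to AE classes."""
    return load_rules(_data_path("moscow_trial.rules"))


def argentinian_rules() -> list[MappingRule]:
    """Boolean rules deriving the registry's disjoint categories."""
    return load_rules(_data_path("argentinian_registry.rules"))
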