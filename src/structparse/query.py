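"""Keyword-filter syntax over collections of structure objects.

A filter key is a double-underscore path with an optional comparator
suffix: ``element="N"`` (equality), ``mass__gt=14`` (numeric comparison),
``het__name__regex="CYS|HIS"`` (unanchored regular-expression search on a
nested attribute). Members missing an attribute along the path, or holding
None there, are silently excluded — never an error — so one criterion set
can run over heterogeneous collections.
"""

import re
from dataclasses import dataclass

OPERATORS = {
    "eq": lambda value, operand: value == operand,
    "regex": lambda value, operand: re.search(operand, str(value)) is not None,
    "gt": lambda value, operand: value > operand,
    "lt": lambda value, operand: value < operand,
    "ge": lambda value, operand: value >= operand,
    "le": lambda value, operand: value <= operand,
}

_SUFFIXES = {"regex", "gt", "lt", "ge", "le"}

# Table-typography em-dash sometimes stands in for the regex alternation bar.
_EM_DASH = "—"


@dataclass
class FilterCriterion:
    """A single parsed filter: attribute path, comparator and operand."""
    attribute_path: list
    operator: str
    operand: object

    def matches(self, member):
        value = member
        for attribute in self.attribute_path:
            value = getattr(value, attribute, None)
            if value is None:
                return False
        operand = self.operand
        if self.operator == "regex" and isinstance(operand, str):
            operand = operand.replace(_EM_DASH, "|")
        try:
            return OPERATORS[self.operator](value, operand)
        except TypeError:
            return False


def parse_filter_key(key, operand=None):
    """Split a ``__``-delimited key into a :class:`FilterCriterion`.

    The trailing segment becomes the operator when it is a recognized
    comparator suffix; otherwise the operator defaults to equality.
    """
    if not key:
        raise ValueError("Filter key must be a non-empty string")
    segments = key.split("__")
    if len(segments) > 1 and segments[-1] in _SUFFIXES:
        operator = segments[-1]
        path = segments[:-1]
    else:
        operator = "eq"
        path = segments
    if not path or not all(path):
        raise ValueError(f"Malformed filter key: {key!r}")
    return FilterCriterion(attribute_path=path, operator=operator, operand=operand)


def _as_criteria(criteria):
    if isinstance(criteria, dict):
        return [parse_filter_key(key, operand) for key, operand in criteria.items()]
    return list(criteria)


def filter_structures(collection, criteria):
    """Members of ``collection`` for which every criterion holds.

    ``criteria`` is either a mapping of filter-key to operand or a list of
    :class:`FilterCriterion`. Regex operands that fail to compile raise
    ``re.error`` up front; an empty criterion set returns the whole
    collection.
    """
    criteria = _as_criteria(criteria)
    for criterion in criteria:
        if criterion.operator == "regex":
            re.compile(str(criterion.operand).replace(_EM_DASH, "|"))
    result = [m for m in collection
              if all(criterion.matches(m) for criterion in criteria)]
    return set(result) if isinstance(collection, (set, frozenset)) else result
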