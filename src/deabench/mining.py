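"""Frequent-pattern mining of workflow option itemsets (FP-growth).

Each workflow becomes a transaction of ``step=option`` items; FP-growth
finds every itemset whose support ratio (fraction of transactions
containing it) reaches a threshold. The miner is the classic FP-tree
construction: items ordered by support (descending, name ascending for
ties), recursive conditional-tree pattern growth. Singleton patterns are
reported; the empty itemset is not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .core import WorkflowSpec, registry_options

__all__ = ["Pattern", "encode_workflow_items", "fp_growth", "mine_levels"]

_STEP_PREFIX = {
    "matrix_type": "matrix",
    "normalization": "norm",
    "imputation": "mvi",
    "dea": "dea",
}


@dataclass(frozen=True)
class Pattern:
    items: frozenset[str]
    support_ratio: float

    def sorted_items(self) -> tuple[str, ...]:
        return tuple(sorted(self.items))


def encode_workflow_items(specs: Sequence[WorkflowSpec]) -> list[frozenset[str]]:
    """Encode workflows as transactions of ``step=option`` items.

    The matrix item is omitted when the workflow's setting registers only
    one matrix type (it carries no information there).
    """
    transactions = []
    for spec in specs:
        items = set()
        for attr, prefix in _STEP_PREFIX.items():
            if attr == "matrix_type":
                try:
                    if len(registry_options(spec.setting, "matrix")) < 2:
                        continue
                except KeyError:
                    pass
            items.add(f"{prefix}={getattr(spec, attr)}")
        transactions.append(frozenset(items))
    return transactions


# ---------------------------------------------------------------------------
# FP-tree
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("item", "count", "parent", "children", "link")

    def __init__(self, item, parent):
        self.item = item
        self.count = 0
        self.parent = parent
        self.children: dict[str, _Node] = {}
        self.link: _Node | None = None


def _build_tree(transactions: Iterable[tuple[tuple[str, ...], int]], min_count: float):
    """Build an FP-tree from (items, count) pairs; returns (root, header)."""
    support: dict[str, int] = {}
    txs = list(transactions)
    for items, count in txs:
        for item in items:
            support[item] = support.get(item, 0) + count
    frequent = {i: s for i, s in support.items() if s >= min_count}
    # deterministic item order: support descending, name ascending
    order = {i: k for k, i in enumerate(sorted(frequent, key=lambda i: (-frequent[i], i)))}
    root = _Node(None, None)
    header: dict[str, _Node] = {}
    for items, count in txs:
        path = sorted((i for i in items if i in frequent), key=order.__getitem__)
        node = root
        for item in path:
            child = node.children.get(item)
            if child is None:
                child = _Node(item, node)
                node.children[item] = child
                if item in header:
                    tail = header[item]
                    while tail.link is not None:
                        tail = tail.link
                    tail.link = child
                else:
                    header[item] = child
            child.count += count
            node = child
    return root, header, frequent, order


def _mine(header, frequent, order, min_count, suffix, out):
    # visit items in reverse frequency order (least frequent first)
    for item in sorted(frequent, key=lambda i: (-order[i],)):
        new_pattern = suffix | {item}
        out[frozenset(new_pattern)] = frequent[item]
        # conditional pattern base: prefix paths of every node carrying item
        conditional = []
        node = header[item]
        while node is not None:
            path = []
            parent = node.parent
            while parent is not None and parent.item is not None:
                path.append(parent.item)
                parent = parent.parent
            if path:
                conditional.append((tuple(path), node.count))
            node = node.link
        if conditional:
            _, sub_header, sub_frequent, sub_order = _build_tree(conditional, min_count)
            if sub_frequent:
                _mine(sub_header, sub_frequent, sub_order, min_count, new_pattern, out)


def fp_growth(
    transactions: Sequence[frozenset[str] | set[str]], min_sr: float = 0.1
) -> list[Pattern]:
    """All itemsets with support ratio >= min_sr, SR descending,
    lexicographic tie-break on the sorted item tuple."""
    if not 0 < min_sr <= 1:
        raise ValueError("min_sr must lie in (0, 1]")
    if not transactions:
        raise ValueError("no transactions to mine")
    n = len(transactions)
    min_count = min_sr * n - 1e-9  # tolerate float round-off at the boundary
    counted = [(tuple(sorted(t)), 1) for t in transactions]
    _, header, frequent, order = _build_tree(counted, min_count)
    out: dict[frozenset[str], int] = {}
    if frequent:
        _mine(header, frequent, order, min_count, frozenset(), out)
    patterns = [Pattern(items, count / n) for items, count in out.items()]
    patterns.sort(key=lambda p: (-p.support_ratio, p.sorted_items()))
    return patterns


def mine_levels(
    ranking: pd.DataFrame,
    specs: Sequence[WorkflowSpec],
    level: str,
    min_sr: float = 0.1,
) -> list[Pattern]:
    """Mine frequent option patterns within one performance level.

    ``ranking`` is an aggregate_ranks table (indexed by str(spec) with a
    ``level`` column); support ratios are relative to the level's workflow
    count.
    """
    by_key = {str(s): s for s in specs}
    keys = ranking.index[ranking["level"] == level]
    if len(keys) == 0:
        raise ValueError(f"no workflows with level {level!r}")
    transactions = encode_workflow_items([by_key[k] for k in keys])
    return fp_growth(transactions, min_sr)


def patterns_to_frame(patterns: Sequence[Pattern]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pattern": [",".join(p.sorted_items()) for p in patterns],
            "size": [len(p.items) for p in patterns],
            "support_ratio": [p.support_ratio for p in patterns],
        }
    )
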