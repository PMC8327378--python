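"""Random condition-tree generator for property tests.

Trees are drawn from the vocabulary actually present in a warehouse dump
(codes, descriptions, contexts), so leaves have a realistic mix of hits
and misses: exact codes, truncated prefix wildcards, description
substrings, patient attributes, and occasional age filters, combined
with AND/OR to a bounded depth.
"""

from __future__ import annotations

import numpy as np

from starcohort import conditions
from starcohort.conditions import make_condition, combine, with_age

from .oracle import CLASS_SEMANTICS, WarehouseDump

LEAF_CLASSES = list(CLASS_SEMANTICS) + ["Encounter", "Patient"]


def vocabulary(dump: WarehouseDump) -> dict[str, list[dict]]:
    """Per-dimension concept vocabulary of a dump."""
    vocab: dict[str, list[dict]] = {}
    for concept in dump.concepts.values():
        vocab.setdefault(concept["dimension"], []).append(concept)
    return vocab


def random_leaf(rng: np.random.Generator, vocab) -> conditions.ConditionNode:
    cls = LEAF_CLASSES[int(rng.integers(0, len(LEAF_CLASSES)))]
    if cls == "Patient":
        kind = rng.random()
        if kind < 0.4:
            return make_condition("Patient", attributes={
                "gender": ["male", "female"][int(rng.integers(0, 2))]
            })
        if kind < 0.7:
            return make_condition("Patient", attributes={
                "deceased": int(rng.integers(0, 2))
            })
        return make_condition("Patient", description=["MALE", "WHITE", "BLACK"][
            int(rng.integers(0, 3))
        ])
    if cls == "Encounter":
        pattern = ["IN", "OUT", "EMERG", "PATIENT", "ICU"][int(rng.integers(0, 5))]
        return make_condition("Encounter", description=pattern)
    dimension = CLASS_SEMANTICS[cls][0]
    pool = vocab.get(dimension, [])
    if not pool:
        return make_condition(cls, description="ZZZ-NOTHING")
    concept = pool[int(rng.integers(0, len(pool)))]
    code_ok = cls != "Metadata"  # the only remaining description-only class
    if code_ok and rng.random() < 0.55:
        code = concept["code"]
        if rng.random() < 0.5 and len(code) > 1:
            cut = int(rng.integers(1, len(code)))
            code = code[:cut] + "%"
        return make_condition(cls, code=code, context=concept["context_name"])
    desc = str(concept["description"])
    words = desc.split()
    pattern = words[int(rng.integers(0, len(words)))] if words else desc
    if rng.random() < 0.3 and len(pattern) > 3:
        pattern = pattern[: int(rng.integers(2, len(pattern)))]
    return make_condition(cls, description=pattern)


def random_tree(rng: np.random.Generator, vocab, max_depth: int = 4):
    """A random condition tree of depth ≤ ``max_depth`` with an optional
    age filter at any node."""
    node = _tree(rng, vocab, max_depth)
    return node


def _tree(rng, vocab, depth):
    if depth <= 1 or rng.random() < 0.35:
        node = random_leaf(rng, vocab)
    else:
        arity = 2 if rng.random() < 0.8 else 3
        children = [_tree(rng, vocab, depth - 1) for _ in range(arity)]
        node = combine("and" if rng.random() < 0.5 else "or", *children)
    if rng.random() < 0.2:
        bounds = [(18.0, None), (None, 70.0), (40.0, 80.0), (0.0, None)]
        lo, hi = bounds[int(rng.integers(0, len(bounds)))]
        node = with_age(node, lo, hi)
    return node
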