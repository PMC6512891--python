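"""Fixed label vocabularies for the three affect domains and the expression classes.

Affect is annotated along three domains of the mental status examination:
*quality* (the emotional tone), *range* (how much the affect varies during
the interview), and *subtype* (a finer-grained characterisation).  Label
order within each vocabulary is fixed and used everywhere a deterministic
tie-break over classes is needed.
"""

from __future__ import annotations

QUALITY_LABELS: tuple[str, ...] = ("dysphoric", "euthymic", "manic")

RANGE_LABELS: tuple[str, ...] = ("full", "restricted", "blunt", "flat")

SUBTYPE_LABELS: tuple[str, ...] = (
    "unknown",
    "stupid",
    "euphoria",
    "empathetic",
    "self_contempt",
    "anxious",
    "suspicious",
    "hopeless",
    "frightened",
    "irritable",
    "vacancy",
    "sense_of_guilt",
)

DOMAINS: dict[str, tuple[str, ...]] = {
    "quality": QUALITY_LABELS,
    "range": RANGE_LABELS,
    "subtype": SUBTYPE_LABELS,
}

#: The seven facial-expression classes scored per frame, in fixed order.
#: "norm" (neutral) is first, so zero-score ties resolve to neutral.
EXPRESSION_CLASSES: tuple[str, ...] = (
    "norm",
    "anger",
    "disgust",
    "fear",
    "happiness",
    "sadness",
    "surprise",
)

#: The five mid-level feature kinds and their vector lengths.
FEATURE_KINDS: dict[str, int] = {
    "expression": 7,
    "label": 1,
    "motion": 1,
    "motion_label": 2,
    "motion_expression": 8,
}


def label_index(domain: str, label: str) -> int:
    """Position of *label* in its domain's fixed order (raises on unknown)."""
    try:
        return DOMAINS[domain].index(label)
    except ValueError:
        raise ValueError(f"label {label!r} not in the {domain} vocabulary") from None
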