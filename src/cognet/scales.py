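"""Questionnaire instruments and construct scoring.

Five self-report instruments measured at each wave:

* PHQ-9 — depressive symptoms, 9 items scored 0-3.
* GAD-7 — generalized anxiety, 7 items scored 0-3.
* RRS — ruminative response scale, 22 items scored 1-4, with three
  subscales: symptom rumination (SR), brooding (BD) and reflective
  pondering (RP).
* ANIS — attention to negative information, 10 items scored 1-5; its
  total is the negative-attention-bias construct (NA).
* ATQ — negative automatic thoughts, short form, 8 items scored 1-5
  (NAT).

Analyses run on seven construct scores: PHQ and GAD totals, the three
RRS subscale totals, and the ANIS and ATQ totals.  All scoring is a
plain item sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ScaleDefinition:
    """One instrument: item count, Likert bounds, and subscale map.

    ``subscales`` maps a construct label to the 1-based item indices
    that score it.  An empty map means the instrument contributes a
    single construct equal to its total, named ``total_label``.
    """

    name: str
    n_items: int
    response_min: int
    response_max: int
    subscales: dict[str, tuple[int, ...]] = field(default_factory=dict)
    total_label: str | None = None

    def __post_init__(self) -> None:
        if self.response_min >= self.response_max:
            raise ValueError(
                f"{self.name}: response_min must be < response_max"
            )
        seen: set[int] = set()
        for label, items in self.subscales.items():
            for i in items:
                if not 1 <= i <= self.n_items:
                    raise ValueError(
                        f"{self.name}/{label}: item index {i} outside "
                        f"[1, {self.n_items}]"
                    )
                if i in seen:
                    raise ValueError(
                        f"{self.name}: item {i} assigned to two subscales"
                    )
                seen.add(i)

    @property
    def constructs(self) -> list[str]:
        """Construct labels this instrument contributes, in order."""
        if self.subscales:
            return list(self.subscales)
        return [self.total_label or self.name]

    def score(self, responses: list[int | None]) -> dict[str, int]:
        """Sum item responses into construct scores.

        Raises ``MissingItemError`` if any required item is missing —
        record-validity filtering guarantees completeness upstream.
        """
        if len(responses) != self.n_items:
            raise ValueError(
                f"{self.name}: expected {self.n_items} responses, "
                f"got {len(responses)}"
            )
        for idx, value in enumerate(responses, start=1):
            if value is None:
                raise MissingItemError(self.name, idx)
        out: dict[str, int] = {}
        if self.subscales:
            for label, items in self.subscales.items():
                out[label] = sum(responses[i - 1] for i in items)
        else:
            out[self.total_label or self.name] = sum(responses)
        return out


class MissingItemError(ValueError):
    """A required item response is absent."""

    def __init__(self, scale: str, item: int) -> None:
        self.scale = scale
        self.item = item
        super().__init__(f"missing response: scale {scale!r}, item {item}")


# RRS subscale item assignment follows the standard three-factor
# decomposition: 5 brooding items, 5 reflective-pondering items, and the
# remaining 12 symptom-focused ("depression-related") rumination items.
_RRS_BROODING = (5, 10, 13, 15, 16)
_RRS_REFLECTION = (7, 11, 12, 20, 21)
_RRS_SYMPTOM = tuple(
    i for i in range(1, 23) if i not in _RRS_BROODING + _RRS_REFLECTION
)

PHQ9 = ScaleDefinition("phq", 9, 0, 3, total_label="PHQ")
GAD7 = ScaleDefinition("gad", 7, 0, 3, total_label="GAD")
RRS = ScaleDefinition(
    "rrs", 22, 1, 4,
    subscales={"SR": _RRS_SYMPTOM, "BD": _RRS_BROODING, "RP": _RRS_REFLECTION},
)
ANIS = ScaleDefinition("anis", 10, 1, 5, total_label="NA")
ATQ = ScaleDefinition("atq", 8, 1, 5, total_label="NAT")

DEFAULT_SCALES: tuple[ScaleDefinition, ...] = (PHQ9, GAD7, RRS, ANIS, ATQ)

#: The seven analysis constructs, in canonical order.
CONSTRUCTS: tuple[str, ...] = ("PHQ", "GAD", "SR", "BD", "RP", "NA", "NAT")

#: Map construct label -> (scale, item indices) for the default battery.
CONSTRUCT_ITEMS: dict[str, tuple[ScaleDefinition, tuple[int, ...]]] = {
    "PHQ": (PHQ9, tuple(range(1, 10))),
    "GAD": (GAD7, tuple(range(1, 8))),
    "SR": (RRS, _RRS_SYMPTOM),
    "BD": (RRS, _RRS_BROODING),
    "RP": (RRS, _RRS_REFLECTION),
    "NA": (ANIS, tuple(range(1, 11))),
    "NAT": (ATQ, tuple(range(1, 9))),
}


def score_bounds(construct: str) -> tuple[int, int]:
    """Attainable [min, max] total for a construct under default scales."""
    scale, items = CONSTRUCT_ITEMS[construct]
    k = len(items)
    return k * scale.response_min, k * scale.response_max
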