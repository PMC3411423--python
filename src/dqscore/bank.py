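"""Instrument definitions: knowledge items and treatment goals.

The decision quality instrument for early-stage breast cancer surgery has two
decision-specific sections: a knowledge test (13 multiple-choice and 2
open-ended items in the initial form) and a set of goals and concerns rated on
an importance scale from 0 (not at all important) to 10 (extremely important).

Only five knowledge items (the screener set) and six goals are published
verbatim; the remaining item wordings are held by the instrument authors, so
the default banks here carry synthetic stand-ins with the published structure
(option counts, screener membership, reduced-set membership).  Real-data users
supply their own bank files (YAML/JSON) with the same schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import yaml

MULTIPLE_CHOICE = "multiple_choice"
OPEN_ENDED = "open_ended"

#: token used for an explicit "I am not sure" response to an open-ended item
#: (multiple-choice items carry "I am not sure" as their last option).
NOT_SURE = "not_sure"

TOWARD_MASTECTOMY = "toward_mastectomy"
TOWARD_LUMPECTOMY = "toward_lumpectomy"


@dataclass(frozen=True)
class ItemPart:
    """One scored sub-part of a knowledge item.

    ``n_options`` (k) counts every printed response choice *including*
    "I am not sure"; a missing response is scored 1/k, the expected score of
    uniform guessing over the printed choices.
    """

    part_id: str
    kind: str
    correct: Union[int, tuple]  # option index, or (lo, hi) numeric interval
    n_options: int
    weight: float = 1.0
    options: tuple = ()

    def __post_init__(self):
        if self.kind not in (MULTIPLE_CHOICE, OPEN_ENDED):
            raise ValueError(f"unknown item kind {self.kind!r}")
        if self.kind == MULTIPLE_CHOICE:
            if self.n_options < 2:
                raise ValueError(f"{self.part_id}: k must be >= 2, got {self.n_options}")
            if not isinstance(self.correct, int):
                raise ValueError(f"{self.part_id}: multiple-choice correct must be an option index")
            if not 0 <= self.correct < self.n_options:
                raise ValueError(f"{self.part_id}: correct index {self.correct} outside 0..{self.n_options - 1}")
            if self.options and len(self.options) != self.n_options:
                raise ValueError(f"{self.part_id}: {len(self.options)} option labels for k={self.n_options}")
        else:
            lo, hi = self.correct
            if not lo <= hi:
                raise ValueError(f"{self.part_id}: open-ended range must satisfy lo <= hi, got [{lo}, {hi}]")
            if self.n_options < 1:
                raise ValueError(f"{self.part_id}: k must be positive")

    @property
    def interval(self) -> tuple:
        if self.kind != OPEN_ENDED:
            raise AttributeError("interval defined for open-ended parts only")
        return tuple(self.correct)


@dataclass(frozen=True)
class KnowledgeItem:
    """A knowledge item; most items have a single part with weight 1.

    Multi-part items carry per-part weights that must sum to one, so the item
    as a whole still contributes one point when fully correct.
    """

    item_id: str
    parts: tuple = ()
    in_screener: bool = False
    in_reduced_set: bool = True

    def __post_init__(self):
        if not self.parts:
            raise ValueError(f"{self.item_id}: item must have at least one part")
        total = sum(p.weight for p in self.parts)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.item_id}: part weights sum to {total}, expected 1")
        ids = [p.part_id for p in self.parts]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.item_id}: duplicate part ids")

    @property
    def multipart(self) -> bool:
        return len(self.parts) > 1

    def response_keys(self) -> list:
        """Column keys under which this item's responses are stored."""
        if not self.multipart:
            return [self.item_id]
        return [f"{self.item_id}__{p.part_id}" for p in self.parts]

    @property
    def kind(self) -> str:
        kinds = {p.kind for p in self.parts}
        return kinds.pop() if len(kinds) == 1 else "mixed"


def mc_item(item_id: str, correct: int, k: int = 4, *, options: Sequence[str] = (),
            in_screener: bool = False, in_reduced_set: bool = True) -> KnowledgeItem:
    """Convenience constructor for a single-part multiple-choice item."""
    part = ItemPart(part_id="a", kind=MULTIPLE_CHOICE, correct=correct,
                    n_options=k, weight=1.0, options=tuple(options))
    return KnowledgeItem(item_id=item_id, parts=(part,),
                         in_screener=in_screener, in_reduced_set=in_reduced_set)


def open_item(item_id: str, lo: float, hi: float, k: int = 2, *,
              in_screener: bool = False, in_reduced_set: bool = True) -> KnowledgeItem:
    """Convenience constructor for a single-part open-ended item.

    The answer is correct iff it falls inside the clinically pre-determined
    closed interval [lo, hi].
    """
    part = ItemPart(part_id="a", kind=OPEN_ENDED, correct=(float(lo), float(hi)),
                    n_options=k, weight=1.0)
    return KnowledgeItem(item_id=item_id, parts=(part,),
                         in_screener=in_screener, in_reduced_set=in_reduced_set)


class ItemBank:
    """Ordered collection of knowledge items with named subsets.

    ``initial`` is every item in the bank, ``reduced`` the post-item-analysis
    set used for the headline knowledge score, and ``screener`` the 5-item
    short form.
    """

    def __init__(self, items: Sequence[KnowledgeItem]):
        self._items = {it.item_id: it for it in items}
        if len(self._items) != len(items):
            raise ValueError("duplicate item ids in bank")
        # map every response key back to (item, part)
        self._key_map = {}
        for it in items:
            for key, part in zip(it.response_keys(), it.parts):
                if key in self._key_map:
                    raise ValueError(f"duplicate response key {key}")
                self._key_map[key] = (it, part)

    def __iter__(self):
        return iter(self._items.values())

    def __len__(self):
        return len(self._items)

    def __contains__(self, item_id):
        return item_id in self._items

    def __getitem__(self, item_id) -> KnowledgeItem:
        return self._items[item_id]

    @property
    def response_keys(self) -> list:
        return list(self._key_map)

    def resolve_key(self, key: str):
        """Return (item, part) for a response-column key."""
        return self._key_map[key]

    def item_set(self, name: str) -> list:
        """Items in the named scoring set: 'initial', 'reduced' or 'screener'."""
        if name == "initial":
            return list(self._items.values())
        if name == "reduced":
            return [it for it in self._items.values() if it.in_reduced_set]
        if name == "screener":
            return [it for it in self._items.values() if it.in_screener]
        raise KeyError(f"unknown item set {name!r}; expected initial/reduced/screener")


@dataclass(frozen=True)
class GoalDefinition:
    """A treatment goal or concern, rated 0-10 by patients.

    ``expected_direction`` records which surgery a high rating should favour;
    it fixes the direction of the one-sided discriminant-validity t-test.
    """

    goal_id: str
    label: str
    expected_direction: str
    in_screener: bool = False
    in_concordance_model: bool = True

    def __post_init__(self):
        if self.expected_direction not in (TOWARD_MASTECTOMY, TOWARD_LUMPECTOMY):
            raise ValueError(f"{self.goal_id}: bad expected_direction {self.expected_direction!r}")


GOAL_SCALE = (0, 10)

# The six published goals, in the order used throughout the package.
CANONICAL_GOALS = (
    "keep_breast",
    "remove_breast",
    "avoid_recurrence",
    "avoid_radiation",
    "avoid_radiation_side_effects",
    "avoid_radiation_hassle",
)


def default_goal_bank() -> list:
    """Eight-goal bank: six published goals plus two synthetic placeholders.

    The instrument carries eight goals; only six are published.  The two
    placeholders stand in for the unpublished wordings and take no part in the
    concordance model or the screener.
    """
    return [
        GoalDefinition("keep_breast", "How important is it to you to keep your breast?",
                       TOWARD_LUMPECTOMY, in_screener=True),
        GoalDefinition("remove_breast", "How important is it to remove your breast for peace of mind?",
                       TOWARD_MASTECTOMY, in_screener=True),
        GoalDefinition("avoid_recurrence", "How important is it to avoid cancer coming back in your breast?",
                       TOWARD_MASTECTOMY, in_screener=True),
        GoalDefinition("avoid_radiation", "How important is it to avoid radiation?",
                       TOWARD_MASTECTOMY, in_screener=True),
        GoalDefinition("avoid_radiation_side_effects",
                       "How important is it to avoid serious side effects of radiation?",
                       TOWARD_MASTECTOMY),
        GoalDefinition("avoid_radiation_hassle",
                       "How important is it to avoid the hassle of radiation?",
                       TOWARD_MASTECTOMY),
        # synthetic placeholders for the two unpublished goals
        GoalDefinition("placeholder_goal_1", "Placeholder goal 1 (synthetic stand-in)",
                       TOWARD_MASTECTOMY, in_concordance_model=False),
        GoalDefinition("placeholder_goal_2", "Placeholder goal 2 (synthetic stand-in)",
                       TOWARD_LUMPECTOMY, in_concordance_model=False),
    ]


def default_item_bank() -> ItemBank:
    """Fifteen-item bank mirroring the initial instrument structure.

    The five screener items are the published ones (survival impact of a
    4-week delay, breast-cancer mortality, re-operation risk, survival
    equivalence, local recurrence).  The other ten are synthetic stand-ins for
    the unpublished items: seven belong to the reduced 12-item set (five
    multiple-choice, two open-ended), two are deliberately easy and one is
    reverse-keyed, matching the three items the item analysis deletes.
    """
    items = [
        # --- published screener items (4-option MC, last option = not sure)
        mc_item("delay_survival", correct=2, k=4, in_screener=True, options=(
            "A lot", "Somewhat", "A little or not at all", "I am not sure")),
        mc_item("die_of_bc", correct=2, k=4, in_screener=True, options=(
            "Most will die of breast cancer", "About half will die of breast cancer",
            "Most will die of something else", "I am not sure")),
        mc_item("reoperation", correct=0, k=4, in_screener=True, options=(
            "Lumpectomy", "Mastectomy", "Equally likely for both", "I am not sure")),
        mc_item("survival_equivalence", correct=2, k=4, in_screener=True, options=(
            "Women who have a mastectomy", "Women who have a lumpectomy and radiation",
            "There is no difference", "I am not sure")),
        mc_item("local_recurrence", correct=1, k=4, in_screener=True, options=(
            "Women who have a mastectomy", "Women who have a lumpectomy and radiation",
            "There is no difference", "I am not sure")),
        # --- synthetic reduced-set items
        mc_item("radiation_duration", correct=1, k=4),
        mc_item("recovery_time", correct=0, k=4),
        mc_item("margins_reexcision", correct=2, k=5),
        mc_item("hormone_therapy", correct=1, k=4),
        mc_item("chemo_need", correct=0, k=4),
        open_item("recurrence_rate_pct", lo=5, hi=15, k=2),
        open_item("survival_rate_pct", lo=80, hi=95, k=2),
        # --- synthetic deleted items (flagged by the item analysis)
        mc_item("easy_radiation_machine", correct=0, k=4, in_reduced_set=False),
        mc_item("easy_surgery_removes", correct=0, k=4, in_reduced_set=False),
        mc_item("reverse_keyed", correct=0, k=4, in_reduced_set=False),
    ]
    return ItemBank(items)


# ---------------------------------------------------------------------------
# YAML serialisation


def _part_to_dict(p: ItemPart) -> dict:
    d = {"part_id": p.part_id, "kind": p.kind, "n_options": p.n_options, "weight": p.weight}
    if p.kind == MULTIPLE_CHOICE:
        d["correct"] = p.correct
        if p.options:
            d["options"] = list(p.options)
    else:
        d["correct"] = list(p.correct)
    return d


def save_banks(path, item_bank: ItemBank, goal_bank: Sequence[GoalDefinition]) -> None:
    doc = {
        "items": [
            {"item_id": it.item_id, "in_screener": it.in_screener,
             "in_reduced_set": it.in_reduced_set,
             "parts": [_part_to_dict(p) for p in it.parts]}
            for it in item_bank
        ],
        "goals": [
            {"goal_id": g.goal_id, "label": g.label,
             "expected_direction": g.expected_direction,
             "in_screener": g.in_screener,
             "in_concordance_model": g.in_concordance_model}
            for g in goal_bank
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_banks(path) -> tuple:
    """Load (item_bank, goal_bank) from a YAML/JSON bank file."""
    doc = yaml.safe_load(Path(path).read_text())
    items = []
    for spec in doc["items"]:
        parts = []
        for p in spec["parts"]:
            correct = p["correct"]
            if p["kind"] == OPEN_ENDED:
                correct = (float(correct[0]), float(correct[1]))
            parts.append(ItemPart(part_id=p["part_id"], kind=p["kind"], correct=correct,
                                  n_options=int(p["n_options"]), weight=float(p.get("weight", 1.0)),
                                  options=tuple(p.get("options", ()))))
        items.append(KnowledgeItem(item_id=spec["item_id"], parts=tuple(parts),
                                   in_screener=bool(spec.get("in_screener", False)),
                                   in_reduced_set=bool(spec.get("in_reduced_set", True))))
    goals = [GoalDefinition(goal_id=g["goal_id"], label=g.get("label", g["goal_id"]),
                            expected_direction=g["expected_direction"],
                            in_screener=bool(g.get("in_screener", False)),
                            in_concordance_model=bool(g.get("in_concordance_model", True)))
             for g in doc["goals"]]
    return ItemBank(items), goals
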