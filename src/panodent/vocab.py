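"""Class vocabulary: countable "thing" classes vs amorphous "stuff" classes.

Default vocabulary is a single ``tooth`` thing class plus a single
``background-tissue`` stuff class.  A 32-way numbered-tooth vocabulary is
available as an option for experiments that want per-tooth identities.

Category ids are 1-based (0 is reserved for void): things take ids
``1..n_things``, stuff classes follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Vocabulary:
    things: tuple[str, ...] = ("tooth",)
    stuffs: tuple[str, ...] = ("background-tissue",)

    def __post_init__(self):
        if not self.stuffs:
            raise ValueError("at least one stuff class is required")
        names = self.things + self.stuffs
        if len(set(names)) != len(names):
            raise ValueError("duplicate class names in vocabulary")

    @property
    def n_things(self) -> int:
        return len(self.things)

    @property
    def n_semantic(self) -> int:
        """Number of semantic classes (things + stuffs)."""
        return len(self.things) + len(self.stuffs)

    # ------------------------------------------------------------ category ids
    def thing_ids(self) -> tuple[int, ...]:
        return tuple(range(1, len(self.things) + 1))

    def stuff_ids(self) -> tuple[int, ...]:
        start = len(self.things) + 1
        return tuple(range(start, start + len(self.stuffs)))

    def is_thing(self, category_id: int) -> bool:
        return 1 <= category_id <= len(self.things)

    def name(self, category_id: int) -> str:
        names = self.things + self.stuffs
        if not 1 <= category_id <= len(names):
            raise ValueError(f"unknown category id {category_id}")
        return names[category_id - 1]

    def id_of(self, name: str) -> int:
        names = self.things + self.stuffs
        try:
            return names.index(name) + 1
        except ValueError:
            raise ValueError(f"unknown class name {name!r}") from None

    def thing_index(self, category_id: int) -> int:
        """0-based index of a thing category in the class-head vocabulary."""
        if not self.is_thing(category_id):
            raise ValueError(f"category {category_id} is not a thing class")
        return category_id - 1

    def semantic_index(self, category_id: int) -> int:
        """0-based index in the semantic-head vocabulary (things then stuffs)."""
        if not 1 <= category_id <= self.n_semantic:
            raise ValueError(f"unknown category id {category_id}")
        return category_id - 1

    def coco_categories(self) -> list[dict]:
        cats = []
        for cid in self.thing_ids():
            cats.append({"id": cid, "name": self.name(cid), "isthing": 1})
        for cid in self.stuff_ids():
            cats.append({"id": cid, "name": self.name(cid), "isthing": 0})
        return cats

    @classmethod
    def numbered_teeth(cls) -> "Vocabulary":
        """32 individually numbered tooth classes (FDI-style ordering)."""
        return cls(things=tuple(f"tooth-{i}" for i in range(1, 33)),
                   stuffs=("background-tissue",))


DEFAULT_VOCABULARY = Vocabulary()
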