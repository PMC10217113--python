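"""Attribute lexicons for TDS tasks.

A TDS task uses a fixed set of q sensory attribute words (buttons on the
recording interface). Index 0 is reserved for the implicit "none" state that
holds before the first button press; user attributes occupy indices 1..q.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .errors import LexiconError

#: Label used for the reserved index-0 "nothing selected yet" state.
NONE_LABEL = "none"


@dataclass(frozen=True)
class AttributeLexicon:
    """Ordered set of attribute labels for a TDS task.

    Parameters
    ----------
    names :
        The q user-facing attribute labels, in button order. They occupy
        indices 1..q; index 0 is always the implicit ``"none"`` state.
    """

    names: tuple[str, ...]

    def __init__(self, names: Iterable[str]):
        object.__setattr__(self, "names", tuple(str(n) for n in names))
        if len(self.names) < 1:
            raise LexiconError("a lexicon needs at least one attribute")
        if len(set(self.names)) != len(self.names):
            raise LexiconError("attribute labels must be unique")
        for n in self.names:
            if not n:
                raise LexiconError("attribute labels must be non-empty")
            if n == NONE_LABEL:
                raise LexiconError(
                    f"label {NONE_LABEL!r} is reserved for the pre-selection state"
                )

    @property
    def q(self) -> int:
        """Number of user attributes (excluding the none state)."""
        return len(self.names)

    @property
    def labels_with_none(self) -> tuple[str, ...]:
        """All q+1 labels, index 0 first."""
        return (NONE_LABEL,) + self.names

    def index(self, label: str) -> int:
        """Map a label to its 0..q index (``"none"`` -> 0)."""
        if label == NONE_LABEL:
            return 0
        try:
            return self.names.index(label) + 1
        except ValueError:
            raise LexiconError(
                f"unknown attribute {label!r}; lexicon has {list(self.names)}"
            ) from None

    def label(self, index: int) -> str:
        if not 0 <= index <= self.q:
            raise LexiconError(f"attribute index {index} outside 0..{self.q}")
        return self.labels_with_none[index]


#: The eight-attribute strawberry lexicon used throughout the examples.
STRAWBERRY_ATTRIBUTES = AttributeLexicon(
    ("sweet", "sour", "fruity", "green", "watery", "juicy", "aromatic", "light")
)
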