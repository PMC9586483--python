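"""Amplicon reference description."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class AmpliconReference:
    """A reference amplicon with its annotated cut site.

    Coordinates are 0-based, half-open throughout. ``cut_site`` is a gap
    coordinate: the double-strand break falls between positions
    ``cut_site - 1`` and ``cut_site``.
    """

    name: str
    sequence: str
    cut_site: int
    guide_strand: str = "+"
    primers: tuple[tuple[int, int], ...] = ()
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not (0 < self.cut_site < len(self.sequence)):
            raise ValueError(
                f"cut_site {self.cut_site} outside reference of length {len(self.sequence)}"
            )
        if self.guide_strand not in "+-":
            raise ValueError("guide_strand must be '+' or '-'")
        for start, end in self.primers:
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(f"primer interval ({start}, {end}) outside reference")

    def __len__(self) -> int:
        return len(self.sequence)
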