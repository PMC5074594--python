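"""The unit record of the pipeline: one pre-miRNA hairpin."""

from __future__ import annotations

from dataclasses import dataclass

from .structure import parse_dotbracket

__all__ = ["HairpinRecord", "LABELS"]

#: recognised class labels
LABELS = ("animal", "plant", "unlabelled")


@dataclass
class HairpinRecord:
    """One pre-miRNA: identifier, RNA sequence, optional dot-bracket
    structure and folding energy (kcal/mol), and a class label."""

    id: str
    sequence: str
    structure: str | None = None
    mfe: float | None = None
    label: str = "unlabelled"

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id}: empty sequence")
        if self.structure is not None:
            if len(self.structure) != len(self.sequence):
                raise ValueError(
                    f"record {self.id}: structure length {len(self.structure)} "
                    f"!= sequence length {len(self.sequence)}"
                )
            parse_dotbracket(self.structure)  # raises on unbalanced/foreign chars

    @property
    def length(self) -> int:
        return len(self.sequence)
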