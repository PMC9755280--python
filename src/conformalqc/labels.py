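"""Label sets for biopsy-level classification tasks.

Two tasks recur throughout the package: binary cancer detection
(benign vs. cancer) and six-class ISUP grading (benign plus ISUP grade
groups 1-5, an ordinal scale derived from Gleason patterns). A
:class:`LabelSet` pins down the class names and their order once; every
table, calibrator and region produced downstream records labels in this
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class LabelSet:
    """An ordered collection of class labels.

    Parameters
    ----------
    labels
        Class names, in the order used for probability columns and
        tie-breaking. At least two, all unique.
    ordinal
        Whether the order carries meaning (true for ISUP grades, where
        adjacent grades are clinically closer than distant ones).
    """

    labels: tuple[str, ...]
    ordinal: bool = False

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 2:
            raise ValueError("a label set needs at least 2 labels")
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate labels in {labels}")

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in self.labels

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in label set {self.labels}") from None

    @property
    def prob_columns(self) -> list[str]:
        """CSV column names for the probability vector, in label order."""
        return [f"p_{lab}" for lab in self.labels]


#: Binary cancer-detection label set (benign vs. cancer).
BINARY = LabelSet(("benign", "cancer"))

#: Six-class grading label set: benign plus ISUP grade groups 1-5 (ordinal).
GRADING = LabelSet(("benign", "ISUP1", "ISUP2", "ISUP3", "ISUP4", "ISUP5"), ordinal=True)
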