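"""Multi-factorial study designs: genotype x diet x week cell bookkeeping.

A design records, for every combination of factor levels, how many
biological samples were collected and how many profile spectra were
acquired from them (technical replicates: up to two sample preparations
with four replicate acquisitions each).  Cells may be empty — sample
collection can fail for some strain/diet/week combinations — and the
rest of the pipeline must tolerate that.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

CellKey = tuple[str, str, int]  # (genotype, diet, week)


@dataclass(frozen=True)
class CellCount:
    """Spectrum/sample tally for one factor-level combination."""

    n_spectra: int
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples < 0 or self.n_spectra < 0:
            raise ValueError("counts must be non-negative")
        if self.n_spectra < self.n_samples:
            raise ValueError(
                f"n_spectra ({self.n_spectra}) < n_samples ({self.n_samples})"
            )
        if self.n_samples == 0 and self.n_spectra > 0:
            raise ValueError("spectra without samples")


@dataclass
class StudyDesign:
    """Factor levels plus per-cell spectrum/sample counts."""

    genotype_levels: list[str]
    diet_levels: list[str]
    week_levels: list[int]
    cell_counts: dict[CellKey, CellCount] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (g, d, w), c in self.cell_counts.items():
            if g not in self.genotype_levels:
                raise ValueError(f"unknown genotype level {g!r}")
            if d not in self.diet_levels:
                raise ValueError(f"unknown diet level {d!r}")
            if w not in self.week_levels:
                raise ValueError(f"unknown week level {w!r}")
            if not isinstance(c, CellCount):
                raise TypeError("cell_counts values must be CellCount")

    @property
    def total_spectra(self) -> int:
        return sum(c.n_spectra for c in self.cell_counts.values())

    @property
    def total_samples(self) -> int:
        return sum(c.n_samples for c in self.cell_counts.values())

    def cells(self) -> Iterator[tuple[CellKey, CellCount]]:
        """Iterate cells in declared level order (deterministic)."""
        for g in self.genotype_levels:
            for d in self.diet_levels:
                for w in self.week_levels:
                    key = (g, d, w)
                    if key in self.cell_counts:
                        yield key, self.cell_counts[key]


def build_design(
    genotype_levels: list[str],
    diet_levels: list[str],
    week_levels: list[int],
    cell_counts: Mapping[CellKey, tuple[int, int]],
) -> StudyDesign:
    """Build a :class:`StudyDesign` from ``(n_spectra, n_samples)`` pairs."""
    counts = {k: CellCount(*v) for k, v in cell_counts.items()}
    return StudyDesign(list(genotype_levels), list(diet_levels),
                       list(week_levels), counts)


# Per-cell (n_spectra, n_samples) counts of the T2DM mouse plasma study
# this package is modelled on: 3 strains x 3 diets x 4 sampling weeks,
# 1122 spectra over 155 biological samples.  SJL mice on the
# carbohydrate-containing high-fat diet yielded no plasma in weeks 3-4,
# so those two cells are empty.
_MOUSE_T2DM_COUNTS: dict[CellKey, tuple[int, int]] = {
    # B6
    ("B6", "SD", 3): (36, 5), ("B6", "HF", 3): (31, 4), ("B6", "CHF", 3): (12, 2),
    ("B6", "SD", 4): (36, 5), ("B6", "HF", 4): (40, 5), ("B6", "CHF", 4): (37, 5),
    ("B6", "SD", 6): (38, 5), ("B6", "HF", 6): (38, 5), ("B6", "CHF", 6): (32, 5),
    ("B6", "SD", 8): (39, 5), ("B6", "HF", 8): (34, 5), ("B6", "CHF", 8): (28, 5),
    # NZO
    ("NZO", "SD", 3): (35, 5), ("NZO", "HF", 3): (35, 5), ("NZO", "CHF", 3): (32, 4),
    ("NZO", "SD", 4): (40, 5), ("NZO", "HF", 4): (36, 5), ("NZO", "CHF", 4): (40, 5),
    ("NZO", "SD", 6): (37, 5), ("NZO", "HF", 6): (38, 5), ("NZO", "CHF", 6): (40, 5),
    ("NZO", "SD", 8): (28, 5), ("NZO", "HF", 8): (34, 5), ("NZO", "CHF", 8): (34, 5),
    # SJL
    ("SJL", "SD", 3): (4, 1), ("SJL", "HF", 3): (0, 0), ("SJL", "CHF", 3): (16, 3),
    ("SJL", "SD", 4): (12, 2), ("SJL", "HF", 4): (0, 0), ("SJL", "CHF", 4): (40, 5),
    ("SJL", "SD", 6): (32, 4), ("SJL", "HF", 6): (40, 5), ("SJL", "CHF", 6): (32, 5),
    ("SJL", "SD", 8): (36, 5), ("SJL", "HF", 8): (40, 5), ("SJL", "CHF", 8): (40, 5),
}


def mouse_t2dm_design() -> StudyDesign:
    """The diet-induced type-2-diabetes mouse design used throughout.

    Three genotypes (B6, NZO, SJL) x three diets (SD standard, HF
    high-fat with carbohydrate, CHF carbohydrate-free high-fat) x four
    blood-collection weeks (3, 4, 6, 8).
    """
    return build_design(["B6", "NZO", "SJL"], ["SD", "HF", "CHF"],
                        [3, 4, 6, 8], _MOUSE_T2DM_COUNTS)
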