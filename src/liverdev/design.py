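"""Experimental design constants for the seven-comparison liver study.

The study collapses a male/female x 3/4/8-wk factorial into seven two-color
competitive hybridizations, each run as a dye-swapped pair of biological
replicates.  Comparison order is fixed and is the order of the seven digits
in a TFS code:

    1. M3 vs F3      (sex comparison at 3 wk)
    2. M4 vs F4      (sex comparison at 4 wk)
    3. M8 vs F8      (sex comparison at 8 wk)
    4. M3 vs M8      (male development, 3 -> 8 wk)
    5. M4 vs M8      (male development, 4 -> 8 wk)
    6. F3 vs F8      (female development, 3 -> 8 wk)
    7. F4 vs F8      (female development, 4 -> 8 wk)

Reported ratios follow the field's reading of these comparisons: the three
sex comparisons are oriented male-over-female, so an up flag (1) means
male-biased; the four developmental comparisons are oriented
adult-over-juvenile, so an up flag means expression rises with age.  This
is the orientation under which the canonical worked TFS example
(28.0022200: female-specific at 8 wk, down-regulated with age in male
liver) decodes correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The six biological conditions (sex x age), in expression-matrix column order.
CONDITIONS = ("M3", "M4", "M8", "F3", "F4", "F8")

#: Comparison ids in canonical (TFS digit) order.
COMPARISON_IDS = ("M3vF3", "M4vF4", "M8vF8", "M3vM8", "M4vM8", "F3vF8", "F4vF8")

#: Canonical ratio orientation per comparison: (numerator, denominator).
#: Sex comparisons are male/female; developmental comparisons are
#: 8wk/(3 or 4 wk) so that flag 1 = up-regulated with age.
COMPARISONS = {
    "M3vF3": ("M3", "F3"),
    "M4vF4": ("M4", "F4"),
    "M8vF8": ("M8", "F8"),
    "M3vM8": ("M8", "M3"),
    "M4vM8": ("M8", "M4"),
    "F3vF8": ("F8", "F3"),
    "F4vF8": ("F8", "F4"),
}

#: Index (0-based) of the adult sex comparison that defines sex specificity.
ADULT_SEX_INDEX = 2


@dataclass
class ExperimentDesign:
    """Array layout of a simulated experiment.

    Parameters
    ----------
    n_probes
        Number of probes per array (the real platform has 39,429 features;
        simulations scale this down).
    n_redundant_genes
        Number of genes represented by two probes each (redundant probes
        share a gene symbol and true expression level).
    replicates_per_comparison
        Arrays per comparison; must be even so dye-swap pairs are complete.
    seed
        Base seed for the simulation RNG stream.
    """

    n_probes: int = 5000
    n_redundant_genes: int = 100
    comparisons: tuple = field(default_factory=lambda: COMPARISON_IDS)
    replicates_per_comparison: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_comparison < 2 or self.replicates_per_comparison % 2:
            raise ValueError(
                "replicates_per_comparison must be an even number >= 2 "
                "(dye-swap pairs)"
            )
        unknown = set(self.comparisons) - set(COMPARISON_IDS)
        if unknown:
            raise ValueError(f"unknown comparison ids: {sorted(unknown)}")
        if self.n_probes < 1:
            raise ValueError("n_probes must be positive")
        if not 0 <= self.n_redundant_genes <= self.n_probes // 2:
            raise ValueError("n_redundant_genes out of range")

    @property
    def n_genes(self) -> int:
        """Distinct genes on the array (redundant genes use two probes)."""
        return self.n_probes - self.n_redundant_genes

    @property
    def arrays(self) -> list[tuple[str, int, bool]]:
        """(comparison_id, replicate index, swapped) for every array.

        Odd replicate indices are dye-swapped: the canonical numerator
        sample is labeled with the green dye instead of the red one.
        """
        return [
            (cid, rep, bool(rep % 2))
            for cid in self.comparisons
            for rep in range(self.replicates_per_comparison)
        ]
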