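"""Shipped sequence-element tables used by the library designer.

All windows are half-open ``[start, end)`` intervals in a signed coordinate
system anchored at the splice site: for a donor site position 0 is the first
intronic base (so ``-3:+6`` spans 3 exonic plus 6 intronic bases); for an
acceptor site position 0 is the first exonic base (so ``-15:+3`` spans 15
intronic plus 3 exonic bases).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

Window = Tuple[int, int]


@dataclass(frozen=True)
class MutationRecipe:
    """A fixed replacement written into a window around a splice site."""

    name: str
    site_kind: str  # "donor" or "acceptor"
    window: Window
    replacement: str

    def __post_init__(self) -> None:
        start, end = self.window
        if end - start != len(self.replacement):
            raise ValueError(
                f"recipe {self.name}: window length {end - start} != "
                f"replacement length {len(self.replacement)}"
            )


# Immediate splice-site replacements (consensus / nonspliceable / minor
# spliceosome variants and the branch point element).
SPLICE_SITE_RECIPES = {
    r.name: r
    for r in [
        MutationRecipe("donor_consensus", "donor", (-3, 6), "CAGGTAAGT"),
        MutationRecipe("donor_nonspliceable", "donor", (0, 6), "CTGCTC"),
        MutationRecipe("donor_gc_consensus", "donor", (-3, 6), "CAGGCAAGT"),
        MutationRecipe("donor_u12_at", "donor", (0, 9), "ATATCCTTT"),
        MutationRecipe("donor_u12_gt", "donor", (0, 9), "GTATCCTTT"),
        MutationRecipe("acceptor_consensus", "acceptor", (-15, 3), "CTCCTTTCCTTTCAGGTC"),
        MutationRecipe("acceptor_u12", "acceptor", (-19, 3), "TTCCTTAACTTCCTTTCAGATC"),
        MutationRecipe("branch_point", "acceptor", (-26, -21), "CTCAC"),
    ]
}

# 9-nt binding sites for common splicing factors.
RBP_MOTIFS = {
    "SRSF1": "TCACACGAC",
    "SRSF2": "TGGCCTCTG",
    "SRSF5": "TTCACAGGC",
    "SRSF6": "CTGCGTCGA",
    "hnRNPA1": "TTAGGGAAC",
    "hnRNPG": "CAAGTGTTC",
    "hnRNPU": "TTGTATTGC",
}

# 9-nt splicing-regulatory motifs from saturation-mutagenesis screens
# (enhancer / silencer / neutral classes).
KE_MOTIFS = {
    "KEenh1": "CGACGTCGA",
    "KEenh2": "CAGAAGAGT",
    "KEenh3": "CGAAGATGT",
    "KEenh4": "CGCAAGAGT",
    "KEsil1": "CCCAGCAGT",
    "KEsil2": "CCTTTTAGT",
    "KEsil3": "CCTAGTAGT",
    "KEneu1": "CAAAGAGGT",
    "KEneu2": "CAAACTTGT",
    "KEneu3": "CAACCTTGT",
}

# Hexamer regulatory elements from a randomized 5'/3' splice-site screen.
# Written into 9-nt windows with the three splice-site-proximal positions
# left unchanged.
HEXAMER_MOTIFS = {
    "GENsil": "GTGGGG",
    "E5enh": "CACCGC",
    "E5sil": "GGTGGG",
    "I5enh": "TTGTTC",
    "I5sil": "CGAACC",
    "E3enh": "CGAAGA",
    "E3sil": "GGGGGG",
    "I3enh": "TCTAAC",
    "I3sil": "CCAAGC",
}

MOTIF_TABLE = {**RBP_MOTIFS, **KE_MOTIFS, **HEXAMER_MOTIFS}

# Allowed insertion windows per site kind (9-nt windows).
ALLOWED_MOTIF_WINDOWS = {
    "acceptor": [(-58, -49), (-49, -40), (-40, -31), (5, 14), (9, 18), (14, 23)],
    "donor": [
        (-30, -21),
        (-21, -12),
        (-14, -5),
        (-12, -3),
        (3, 12),
        (4, 13),
        (6, 15),
        (12, 21),
        (13, 22),
        (15, 24),
    ],
}

# Hairpin insertion windows (9-nt) per site kind.
HAIRPIN_WINDOWS = {
    "donor": [(-24, -15), (0, 9), (3, 12)],
    "acceptor": [(-9, 0), (-12, -3), (16, 25), (17, 26)],
}

# Restriction sites excluded from variable regions (recognition strings;
# RsrII CGGWCCG expands to its two concrete sequences).
RESTRICTION_SITES = {
    "RsrII": ("CGGACCG", "CGGTCCG"),
    "AscI": ("GGCGCGCC",),
    "SpeI": ("ACTAGT",),
    "AatII": ("GACGTC",),
    "XbaI": ("TCTAGA",),
}
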