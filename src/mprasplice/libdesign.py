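"""Design of barcoded oligonucleotide libraries for massively parallel
splicing reporter assays.

Every library member is a fixed-length 210-nt oligo laid out as

    forward primer (18) + barcode (12) [+ cloning cassette (15)]
    + variable region (162 or 147) + reverse primer (18)

where the internal SpeI/AatII cloning cassette is present only for layouts
that need a second cloning step (cassette exons and tandem 3' splice sites),
shrinking the variable-region budget from 162 to 147 nt.

Window coordinates follow the convention documented in :mod:`mprasplice.motifs`:
half-open signed intervals anchored at a splice site, donor position 0 being
the first intronic base and acceptor position 0 the first exonic base.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio.Data import CodonTable

from ._dna import BASES, complement, decode, encode, gc_content, reverse_complement
from .motifs import (
    ALLOWED_MOTIF_WINDOWS,
    HEXAMER_MOTIFS,
    MOTIF_TABLE,
    MutationRecipe,
    RESTRICTION_SITES,
    Window,
)

OLIGO_LENGTH = 210
PRIMER_LENGTH = 18
BARCODE_LENGTH = 12

#: variable-region budget per library layout
VARIABLE_BUDGET = {
    "retained_intron": 162,
    "tandem5": 162,
    "cassette_exon": 147,
    "tandem3": 147,
}

#: SpeI site + 3 nt spacer + AatII site, inserted after the barcode for
#: layouts requiring a subsequent internal cloning step.
CLONING_CASSETTE = "ACTAGT" + "CAT" + "GACGTC"

#: library-specific amplification primers (fixed 18-mers, free of the
#: excluded restriction sites)
PRIMERS = {
    "retained_intron": ("ACCGTCAGTTCAGCGTTA", "TAGCCATGTCGGAACTTG"),
    "cassette_exon": ("TGACCGTTGAGCCTTGAA", "CATGGTCGAACTTAGGCA"),
    "tandem5": ("CGTTAGGCACTGAACCTA", "AACCGGATGTTCAGCTCA"),
    "tandem3": ("GTCAACGGTCTTACCGAA", "TCAGGCTTAACGTCCATG"),
}

#: neutral 3' padding unit for contexts shorter than the budget (no splice
#: motifs, no restriction sites)
PAD_UNIT = "CAT"


class DesignError(ValueError):
    """Base class for library-design failures."""


class BarcodeCapacityError(DesignError):
    """Raised when a barcode code of the requested size cannot be built."""


class ForbiddenSiteError(DesignError):
    def __init__(self, enzyme: str, position: int):
        self.enzyme = enzyme
        self.position = position
        super().__init__(f"forbidden restriction site {enzyme} at position {position}")


class WindowError(DesignError):
    """Raised when a requested edit window falls outside the sequence."""


@dataclass
class SpliceContext:
    """An endogenous sequence context hosting one alternative splicing event.

    ``splice_site_positions`` are indices into ``sequence``: for donor sites
    the index of the first intronic base, for acceptor sites the index of the
    first exonic base, ordered 5'->3'.
    """

    context_id: str
    splicing_type: str
    sequence: str
    splice_site_positions: List[int]
    reading_frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.splicing_type not in VARIABLE_BUDGET:
            raise DesignError(f"unknown splicing type {self.splicing_type!r}")
        budget = VARIABLE_BUDGET[self.splicing_type]
        if len(self.sequence) > budget:
            raise DesignError(
                f"context {self.context_id}: sequence length {len(self.sequence)} "
                f"exceeds the {budget} nt budget for {self.splicing_type}"
            )
        if sorted(self.splice_site_positions) != list(self.splice_site_positions):
            raise DesignError("splice-site anchors must be ordered 5'->3'")
        for p in self.splice_site_positions:
            if not 0 <= p <= len(self.sequence):
                raise DesignError("splice-site anchor outside sequence")
        if self.reading_frame_offset not in (0, 1, 2):
            raise DesignError("reading frame offset must be 0, 1 or 2")


@dataclass
class OligoVariant:
    """One designed 210-nt library member."""

    variant_id: str
    barcode: str
    library: str
    subset: str
    full_sequence: str
    variable_region: str
    context_id: str
    recipe: dict = field(default_factory=dict)


def _check_restriction_sites(seq: str) -> None:
    for enzyme, sites in RESTRICTION_SITES.items():
        for site in sites:
            pos = seq.find(site)
            if pos >= 0:
                raise ForbiddenSiteError(enzyme, pos)


def generate_barcodes(
    n: int,
    length: int = BARCODE_LENGTH,
    min_dist: int = 3,
    seed: int = 0,
    max_attempts: Optional[int] = None,
) -> List[str]:
    """Sample ``n`` distinct barcodes with pairwise Hamming distance >= ``min_dist``.

    Seeded rejection sampling: candidates are drawn uniformly and accepted
    if they clear the distance constraint against all accepted barcodes and
    contain no excluded restriction site.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if length < min_dist and n > 1:
        raise BarcodeCapacityError(
            f"no code of length {length} can have pairwise distance >= {min_dist}"
        )
    rng = np.random.default_rng(seed)
    if max_attempts is None:
        max_attempts = 200 * n + 1000
    accepted = np.empty((n, length), dtype=np.uint8)
    count = 0
    attempts = 0
    forbidden = [s for sites in RESTRICTION_SITES.values() for s in sites]
    while count < n:
        if attempts >= max_attempts:
            raise BarcodeCapacityError(
                f"could not place {n} barcodes after {attempts} attempts "
                f"(reached {count})"
            )
        attempts += 1
        cand = rng.integers(0, 4, size=length, dtype=np.uint8)
        if count:
            dists = (accepted[:count] != cand).sum(axis=1)
            if int(dists.min()) < min_dist:
                continue
        s = decode(cand)
        if any(f in s for f in forbidden):
            continue
        accepted[count] = cand
        count += 1
    return [decode(row) for row in accepted]


def assemble_oligo(
    context: SpliceContext,
    barcode: str,
    library: Optional[str] = None,
    subset: str = "wt",
    variable_region: Optional[str] = None,
    variant_id: Optional[str] = None,
    recipe: Optional[dict] = None,
) -> OligoVariant:
    """Assemble a full 210-nt oligo around a (possibly edited) variable region."""
    library = library or context.splicing_type
    if library not in VARIABLE_BUDGET:
        raise DesignError(f"unknown library {library!r}")
    if len(barcode) != BARCODE_LENGTH:
        raise DesignError(f"barcode must be {BARCODE_LENGTH} nt")
    if set(barcode) - set(BASES):
        raise DesignError("barcode contains non-ACGT characters")
    var = variable_region if variable_region is not None else context.sequence
    budget = VARIABLE_BUDGET[library]
    if len(var) > budget:
        raise DesignError(
            f"variable region length {len(var)} exceeds budget {budget} for {library}"
        )
    _check_restriction_sites(var)
    if len(var) < budget:  # pad 3' with neutral spacer (design decision)
        pad = (PAD_UNIT * budget)[: budget - len(var)]
        var_padded = var + pad
    else:
        var_padded = var
    fwd, rev = PRIMERS[library]
    cassette = CLONING_CASSETTE if library in ("cassette_exon", "tandem3") else ""
    full = fwd + barcode + cassette + var_padded + rev
    if len(full) != OLIGO_LENGTH:  # pragma: no cover - layout arithmetic guard
        raise DesignError(f"assembled oligo has length {len(full)} != {OLIGO_LENGTH}")
    return OligoVariant(
        variant_id=variant_id or f"{context.context_id}_{subset}_{barcode}",
        barcode=barcode,
        library=library,
        subset=subset,
        full_sequence=full,
        variable_region=var_padded,
        context_id=context.context_id,
        recipe=recipe or {},
    )


def _abs_window(seq_len: int, anchor: int, window: Window) -> Tuple[int, int]:
    a, b = anchor + window[0], anchor + window[1]
    if not (0 <= a < b <= seq_len):
        raise WindowError(
            f"window {window} at anchor {anchor} falls outside sequence of length {seq_len}"
        )
    return a, b


def _replace(seq: str, a: int, b: int, replacement: str) -> str:
    return seq[:a] + replacement + seq[b:]


def mutate_splice_site(variant_seq: str, anchor: int, recipe: MutationRecipe) -> str:
    """Write a fixed splice-site replacement into the recipe's window."""
    a, b = _abs_window(len(variant_seq), anchor, recipe.window)
    return _replace(variant_seq, a, b, recipe.replacement)


def insert_motif(
    variant_seq: str,
    anchor: int,
    motif_name: str,
    window: Window,
    site_kind: str = "donor",
) -> str:
    """Insert a regulatory motif into a 9-nt window around a splice site.

    9-nt motifs replace the window wholesale; hexamer motifs leave the three
    splice-site-proximal window positions unchanged and occupy the distal six.
    """
    if motif_name not in MOTIF_TABLE:
        raise DesignError(f"unknown motif {motif_name!r}")
    if site_kind not in ALLOWED_MOTIF_WINDOWS:
        raise DesignError(f"site kind must be donor or acceptor, got {site_kind!r}")
    if tuple(window) not in {tuple(w) for w in ALLOWED_MOTIF_WINDOWS[site_kind]}:
        raise DesignError(f"window {window} not in the allowed set for {site_kind} sites")
    a, b = _abs_window(len(variant_seq), anchor, window)
    motif = MOTIF_TABLE[motif_name]
    if motif_name in HEXAMER_MOTIFS:
        current = variant_seq[a:b]
        if window[1] <= 0:  # window upstream of the site: proximal = last 3
            replacement = motif + current[6:]
        else:  # window downstream: proximal = first 3
            replacement = current[:3] + motif
    else:
        if b - a != len(motif):
            raise DesignError(
                f"window {window} length {b - a} != motif length {len(motif)}"
            )
        replacement = motif
    return _replace(variant_seq, a, b, replacement)


def insert_hairpin(
    variant_seq: str,
    anchor: int,
    source_window: Window,
    insertion_window: Window,
    mode: str = "reverse_complement",
) -> str:
    """Write the (reverse-)complement of a source window into an insertion
    window at least 3 nt away, priming hairpin formation between the two."""
    if mode not in ("complement", "reverse_complement"):
        raise DesignError(f"mode must be complement or reverse_complement, got {mode!r}")
    sa, sb = _abs_window(len(variant_seq), anchor, source_window)
    ia, ib = _abs_window(len(variant_seq), anchor, insertion_window)
    if sb - sa != 9 or ib - ia != 9:
        raise DesignError("hairpin source and insertion windows must be 9 nt")
    gap = ia - sb if ia >= sb else sa - ib
    if gap < 3:
        raise DesignError(f"hairpin windows overlap or are closer than 3 nt (gap {gap})")
    src = variant_seq[sa:sb]
    ins = reverse_complement(src) if mode == "reverse_complement" else complement(src)
    return _replace(variant_seq, ia, ib, ins)


# --- synonymous recoding -----------------------------------------------------

_STANDARD = CodonTable.unambiguous_dna_by_id[1]


def _build_synonym_groups() -> Dict[str, List[str]]:
    by_aa: Dict[str, List[str]] = {}
    for codon, aa in _STANDARD.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    by_aa["*"] = sorted(_STANDARD.stop_codons)
    groups = {}
    for codons in by_aa.values():
        codons = sorted(codons)
        for c in codons:
            groups[c] = codons
    return groups


SYNONYMS = _build_synonym_groups()


def _codon_gc(codon: str) -> int:
    return codon.count("G") + codon.count("C")


def recode_region(
    coding_seq: str,
    frame: int = 0,
    objective: str = "random_synonymous",
    protected: Sequence[Window] = (),
    seed: int = 0,
) -> str:
    """Recode a coding sequence with synonymous codons.

    ``objective`` is ``random_synonymous``, ``max_gc`` or ``min_gc``; GC ties
    are broken by lexicographic codon order so the operation is deterministic.
    Codons overlapping any ``protected`` window (absolute, half-open) are left
    untouched.
    """
    if objective not in ("random_synonymous", "max_gc", "min_gc"):
        raise DesignError(f"unknown recoding objective {objective!r}")
    if frame not in (0, 1, 2):
        raise DesignError("frame must be 0, 1 or 2")
    rng = np.random.default_rng(seed)
    seq = list(coding_seq)
    for start in range(frame, len(coding_seq) - 2, 3):
        end = start + 3
        if any(a < end and start < b for a, b in protected):
            continue
        codon = coding_seq[start:end]
        group = SYNONYMS.get(codon)
        if group is None:
            continue  # ambiguous or non-ACGT codon: leave as-is
        if objective == "random_synonymous":
            new = group[rng.integers(len(group))]
        elif objective == "max_gc":
            new = max(group, key=lambda c: (_codon_gc(c), [-ord(x) for x in c]))
        else:
            new = min(group, key=lambda c: (_codon_gc(c), [ord(x) for x in c]))
        seq[start:end] = new
    return "".join(seq)


def inject_dinucleotides(
    variant_seq: str,
    dinuc: str,
    count: int,
    allowed_region: Window,
    seed: int = 0,
    max_attempts: int = 10000,
) -> str:
    """Raise the number of ``dinuc`` occurrences inside ``allowed_region``
    (absolute, half-open) to at least ``count`` by seeded random placement.
    Sequence outside the region, and the total length, are untouched."""
    if dinuc not in ("CG", "GC"):
        raise DesignError("dinuc must be CG or GC")
    a, b = allowed_region
    if not (0 <= a < b <= len(variant_seq)):
        raise WindowError(f"allowed region {allowed_region} outside sequence")
    from ._dna import count_overlapping

    region = variant_seq[a:b]
    if count_overlapping(region, dinuc) >= count:
        return variant_seq
    if count > (b - a) // 2 + 1:
        raise DesignError(f"count {count} infeasible in a {b - a} nt region")
    rng = np.random.default_rng(seed)
    region_list = list(region)
    for _ in range(max_attempts):
        pos = int(rng.integers(0, b - a - 1))
        region_list[pos : pos + 2] = dinuc
        if count_overlapping("".join(region_list), dinuc) >= count:
            return variant_seq[:a] + "".join(region_list) + variant_seq[b:]
    raise DesignError(f"could not reach {count} {dinuc} occurrences")  # pragma: no cover


def swap_components(
    context: SpliceContext,
    regions: Mapping[str, Window],
    replacements: Mapping[str, Sequence[str]],
) -> List[str]:
    """Enumerate all combinations of component replacements.

    ``regions`` maps component names to absolute half-open windows covering
    the context sequence; ``replacements`` maps a subset of those names to
    candidate sequences (length-matched to the component). Components without
    replacements keep their endogenous sequence. Returns the full cartesian
    product, original combination included when the endogenous sequences are
    listed among the candidates.
    """
    names = list(regions)
    windows = [regions[n] for n in names]
    for i, (a, b) in enumerate(windows):
        if not (0 <= a <= b <= len(context.sequence)):
            raise WindowError(f"region {names[i]} outside sequence")
    choice_lists: List[List[str]] = []
    for name, (a, b) in zip(names, windows):
        endo = context.sequence[a:b]
        cands = list(replacements.get(name, [endo]))
        for c in cands:
            if len(c) != b - a:
                raise DesignError(
                    f"replacement for {name} has length {len(c)}, expected {b - a}"
                )
        choice_lists.append(cands)
    out = []
    for combo in itertools.product(*choice_lists):
        seq = context.sequence
        # apply right-to-left so windows stay valid
        for (a, b), repl in sorted(zip(windows, combo), key=lambda t: -t[0][0]):
            seq = _replace(seq, a, b, repl)
        out.append(seq)
    return out


def duplicate_splice_site(
    context: SpliceContext, source: str = "first", span: Window = (-9, 0)
) -> str:
    """Copy the sequence in ``span`` around one tandem splice site onto the
    other, making the two sites identical over the mirrored span."""
    if context.splicing_type not in ("tandem5", "tandem3"):
        raise DesignError("duplicate_splice_site requires a tandem context")
    if source not in ("first", "second"):
        raise DesignError("source must be 'first' or 'second'")
    if len(context.splice_site_positions) != 2:
        raise DesignError("tandem context must carry exactly two splice-site anchors")
    first, second = context.splice_site_positions
    span_len = span[1] - span[0]
    if span_len > second - first:
        raise DesignError(
            f"span of {span_len} nt exceeds the {second - first} nt inter-site distance"
        )
    src_anchor, dst_anchor = (first, second) if source == "first" else (second, first)
    sa, sb = _abs_window(len(context.sequence), src_anchor, span)
    da, db = _abs_window(len(context.sequence), dst_anchor, span)
    return _replace(context.sequence, da, db, context.sequence[sa:sb])


# --- subset generators -------------------------------------------------------


def design_library(
    contexts: Iterable[SpliceContext],
    subsets: Sequence[str] = ("wt", "constvar"),
    n_barcode_controls: int = 8,
    seed: int = 0,
) -> List[OligoVariant]:
    """Materialize a designed library over the given contexts.

    Supported subsets: ``wt`` (barcode-control replicates of the unmodified
    context), ``constvar`` (immediate splice-site replacements), ``SFvar``
    (splicing-factor motif insertions at the first allowed window), ``secvar``
    (hairpin insertions), ``nuc`` (GC-extreme recoding of the first exonic
    stretch). The returned variants share one barcode code with pairwise
    Hamming distance >= 3.
    """
    contexts = list(contexts)
    plans: List[Tuple[SpliceContext, str, str, dict]] = []
    for ctx in contexts:
        anchors = ctx.splice_site_positions
        if "wt" in subsets:
            for rep in range(n_barcode_controls):
                plans.append((ctx, "wt", ctx.sequence, {"replicate": rep}))
        if "constvar" in subsets:
            from .motifs import SPLICE_SITE_RECIPES

            for rname, recipe in SPLICE_SITE_RECIPES.items():
                kind_anchor = anchors[0] if recipe.site_kind == "donor" else anchors[-1]
                try:
                    seq = mutate_splice_site(ctx.sequence, kind_anchor, recipe)
                except WindowError:
                    continue
                plans.append((ctx, "constvar", seq, {"recipe": rname}))
        if "SFvar" in subsets:
            for mname in MOTIF_TABLE:
                for window in ALLOWED_MOTIF_WINDOWS["donor"][:2]:
                    try:
                        seq = insert_motif(ctx.sequence, anchors[0], mname, window, "donor")
                    except (WindowError, DesignError):
                        continue
                    plans.append((ctx, "SFvar", seq, {"motif": mname, "window": window}))
                    break
        if "secvar" in subsets:
            from .motifs import HAIRPIN_WINDOWS

            for mode in ("complement", "reverse_complement"):
                try:
                    seq = insert_hairpin(
                        ctx.sequence, anchors[0], (-24, -15), (0, 9), mode
                    )
                except (WindowError, DesignError):
                    continue
                plans.append((ctx, "secvar", seq, {"mode": mode}))
        if "nuc" in subsets:
            for objective in ("max_gc", "min_gc", "random_synonymous"):
                stop = anchors[0] if anchors else len(ctx.sequence)
                seq = recode_region(
                    ctx.sequence,
                    frame=ctx.reading_frame_offset,
                    objective=objective,
                    protected=[(max(0, stop - 6), len(ctx.sequence))],
                    seed=seed,
                )
                plans.append((ctx, "nuc", seq, {"objective": objective}))

    barcodes = generate_barcodes(len(plans), seed=seed)
    variants = []
    for i, ((ctx, subset, seq, recipe), bc) in enumerate(zip(plans, barcodes)):
        try:
            variants.append(
                assemble_oligo(
                    ctx,
                    bc,
                    subset=subset,
                    variable_region=seq,
                    variant_id=f"v{i:06d}_{ctx.context_id}_{subset}",
                    recipe=recipe,
                )
            )
        except ForbiddenSiteError:
            continue  # an edit may create a cloning site; such designs are dropped
    return variants
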