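"""Library-design operations: layout constraints, window arithmetic,
recoding and barcode codes."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mprasplice._dna import complement, gc_content, hamming, reverse_complement
from mprasplice import libdesign as ld
from mprasplice.motifs import HEXAMER_MOTIFS, RBP_MOTIFS, SPLICE_SITE_RECIPES, MutationRecipe
from mprasplice.simgen import random_contexts


class TestBarcodes:
    def test_pairwise_distance_constraint(self):
        bcs = ld.generate_barcodes(300, seed=5)
        assert len(set(bcs)) == 300
        arr = np.array([[ord(c) for c in b] for b in bcs], dtype=np.uint8)
        for i in range(len(arr)):
            d = (arr[i + 1 :] != arr[i]).sum(axis=1)
            assert d.size == 0 or int(d.min()) >= 3

    def test_single_barcode_vacuous(self):
        (bc,) = ld.generate_barcodes(1, seed=0)
        assert len(bc) == 12 and set(bc) <= set("ACGT")

    def test_impossible_code_raises(self):
        # brute force: no pair of 2-mers is at Hamming distance >= 3
        all_pairs = itertools.combinations(["".join(p) for p in itertools.product("ACGT", repeat=2)], 2)
        assert max(hamming(a, b) for a, b in all_pairs) == 2
        with pytest.raises(ld.BarcodeCapacityError):
            ld.generate_barcodes(2, length=2, min_dist=3, seed=0)

    def test_deterministic_for_seed(self):
        assert ld.generate_barcodes(50, seed=9) == ld.generate_barcodes(50, seed=9)
        assert ld.generate_barcodes(50, seed=9) != ld.generate_barcodes(50, seed=10)


class TestAssembly:
    def test_total_length_and_layout(self, contexts):
        bc = "ACGTACGTACGT"
        v = ld.assemble_oligo(contexts[0], bc)
        assert len(v.full_sequence) == 210
        fwd, rev = ld.PRIMERS["retained_intron"]
        assert v.full_sequence.startswith(fwd) and v.full_sequence.endswith(rev)
        assert v.full_sequence[18:30] == bc

    def test_cassette_budget_is_147(self):
        ctx = random_contexts(1, "cassette_exon", seed=3, length=147)[0]
        assert ld.VARIABLE_BUDGET["cassette_exon"] == 147
        v = ld.assemble_oligo(ctx, "A" * 12)
        assert len(v.full_sequence) == 210
        # internal cloning cassette sits right after the barcode
        assert v.full_sequence[30:45] == ld.CLONING_CASSETTE

    def test_short_context_padded_to_budget(self, contexts):
        ctx = ld.SpliceContext("short", "retained_intron", contexts[0].sequence[:100],
                               [20, 95])
        v = ld.assemble_oligo(ctx, "A" * 12)
        assert len(v.full_sequence) == 210
        assert v.variable_region.startswith(ctx.sequence)

    def test_forbidden_restriction_site_rejected(self, contexts):
        bad = "ACTAGT" + contexts[0].sequence[6:]
        with pytest.raises(ld.ForbiddenSiteError) as exc:
            ld.assemble_oligo(contexts[0], "A" * 12, variable_region=bad)
        assert exc.value.enzyme == "SpeI" and exc.value.position == 0

    def test_oversized_variable_region_rejected(self, contexts):
        with pytest.raises(ld.DesignError):
            ld.assemble_oligo(contexts[0], "A" * 12, variable_region="A" * 163)


class TestSpliceSiteMutation:
    def test_donor_consensus_replaces_nine_positions(self, contexts):
        ctx = contexts[0]
        donor = ctx.splice_site_positions[0]
        out = ld.mutate_splice_site(ctx.sequence, donor, SPLICE_SITE_RECIPES["donor_consensus"])
        assert len(out) == len(ctx.sequence)
        assert out[donor - 3 : donor + 6] == "CAGGTAAGT"
        diffs = [i for i, (a, b) in enumerate(zip(ctx.sequence, out)) if a != b]
        assert all(donor - 3 <= i < donor + 6 for i in diffs)

    def test_branch_point_replaces_five_positions(self, contexts):
        ctx = contexts[0]
        acceptor = ctx.splice_site_positions[1]
        recipe = SPLICE_SITE_RECIPES["branch_point"]
        assert recipe.window == (-26, -21) and len(recipe.replacement) == 5
        out = ld.mutate_splice_site(ctx.sequence, acceptor, recipe)
        assert out[acceptor - 26 : acceptor - 21] == "CTCAC"
        assert sum(a != b for a, b in zip(ctx.sequence, out)) <= 5

    def test_identity_replacement_is_noop(self, contexts):
        ctx = contexts[0]
        donor = ctx.splice_site_positions[0]
        current = ctx.sequence[donor - 3 : donor + 6]
        recipe = MutationRecipe("same", "donor", (-3, 6), current)
        assert ld.mutate_splice_site(ctx.sequence, donor, recipe) == ctx.sequence

    def test_out_of_bounds_window_raises(self, contexts):
        with pytest.raises(ld.WindowError):
            ld.mutate_splice_site(contexts[0].sequence, 1, SPLICE_SITE_RECIPES["donor_consensus"])


class TestMotifInsertion:
    def test_rbp_motif_written_verbatim(self, contexts):
        ctx = contexts[0]
        donor = ctx.splice_site_positions[0]
        out = ld.insert_motif(ctx.sequence, donor, "hnRNPA1", (-30, -21), "donor")
        assert out[donor - 30 : donor - 21] == RBP_MOTIFS["hnRNPA1"]

    def test_hexamer_keeps_three_proximal_positions(self, contexts):
        ctx = contexts[0]
        donor = ctx.splice_site_positions[0]
        out = ld.insert_motif(ctx.sequence, donor, "GENsil", (-30, -21), "donor")
        window_in, window_out = ctx.sequence[donor - 30 : donor - 21], out[donor - 30 : donor - 21]
        assert window_out[:6] == HEXAMER_MOTIFS["GENsil"]
        assert window_out[6:] == window_in[6:]  # splice-site-proximal 3 nt untouched
        # downstream window: proximal positions are the first three
        out2 = ld.insert_motif(ctx.sequence, donor, "GENsil", (3, 12), "donor")
        w2 = out2[donor + 3 : donor + 12]
        assert w2[:3] == ctx.sequence[donor + 3 : donor + 6] and w2[3:] == HEXAMER_MOTIFS["GENsil"]

    def test_disjoint_insertions_commute(self, contexts):
        ctx = contexts[0]
        donor = ctx.splice_site_positions[0]
        a = ld.insert_motif(ld.insert_motif(ctx.sequence, donor, "SRSF1", (-30, -21), "donor"),
                            donor, "hnRNPU", (3, 12), "donor")
        b = ld.insert_motif(ld.insert_motif(ctx.sequence, donor, "hnRNPU", (3, 12), "donor"),
                            donor, "SRSF1", (-30, -21), "donor")
        assert a == b

    def test_disallowed_window_rejected(self, contexts):
        with pytest.raises(ld.DesignError):
            ld.insert_motif(contexts[0].sequence, contexts[0].splice_site_positions[0],
                            "SRSF1", (-31, -22), "donor")


class TestHairpin:
    def test_reverse_complement_inserted(self, contexts):
        ctx = contexts[0]
        donor = ctx.splice_site_positions[0]
        out = ld.insert_hairpin(ctx.sequence, donor, (-24, -15), (0, 9), "reverse_complement")
        src = ctx.sequence[donor - 24 : donor - 15]
        assert out[donor : donor + 9] == reverse_complement(src)

    def test_complement_mode(self):
        assert complement("ACGTTAGCA") == "TGCAATCGT"
        assert reverse_complement("ACGTTAGCA") == "TGCTAACGT"

    def test_idempotent_from_same_source(self, contexts):
        ctx = contexts[0]
        donor = ctx.splice_site_positions[0]
        once = ld.insert_hairpin(ctx.sequence, donor, (-24, -15), (0, 9))
        twice = ld.insert_hairpin(once, donor, (-24, -15), (0, 9))
        assert once == twice  # source window untouched by the insertion

    def test_too_close_windows_rejected(self, contexts):
        ctx = contexts[0]
        donor = ctx.splice_site_positions[0]
        with pytest.raises(ld.DesignError):
            ld.insert_hairpin(ctx.sequence, donor, (-12, -3), (-3, 6))


TRANSLATE = {}
for c, g in ld.SYNONYMS.items():
    TRANSLATE[c] = g[0]  # group representative as amino-acid proxy


def _translate(seq, frame):
    return [TRANSLATE.get(seq[i : i + 3]) for i in range(frame, len(seq) - 2, 3)]


class TestRecoding:
    def test_translation_preserved(self, contexts, rng):
        seq = contexts[0].sequence
        for objective in ("random_synonymous", "max_gc", "min_gc"):
            out = ld.recode_region(seq, 0, objective, seed=7)
            assert _translate(out, 0) == _translate(seq, 0)

    def test_gc_extremes_bracket_original(self, contexts):
        seq = contexts[0].sequence
        hi = ld.recode_region(seq, 0, "max_gc")
        lo = ld.recode_region(seq, 0, "min_gc")
        assert gc_content(lo) <= gc_content(seq) <= gc_content(hi)

    def test_leucine_tie_broken_lexicographically(self):
        # CTT (Leu): max-GC synonyms are CTC and CTG (both 2 GC); lexicographic
        # tie-break picks CTC, and per-codon GC never decreases
        out = ld.recode_region("CTT", 0, "max_gc")
        assert out == "CTC"
        assert out.count("G") + out.count("C") >= 1

    def test_protected_windows_untouched(self, contexts):
        seq = contexts[0].sequence
        prot = [(30, 66)]  # eleven triplets + one triplet around an acceptor
        out = ld.recode_region(seq, 0, "max_gc", protected=prot)
        assert out[30:66] == seq[30:66]


class TestDinucleotides:
    def test_count_reached_inside_region(self, contexts):
        seq = contexts[0].sequence
        out = ld.inject_dinucleotides(seq, "CG", 10, (20, 120), seed=3)
        from mprasplice._dna import count_overlapping

        assert count_overlapping(out[20:120], "CG") >= 10
        assert len(out) == len(seq)

    def test_flanks_unchanged(self, contexts):
        seq = contexts[0].sequence
        out = ld.inject_dinucleotides(seq, "GC", 8, (40, 100), seed=3)
        assert out[:40] == seq[:40] and out[100:] == seq[100:]

    def test_identity_when_count_met(self, contexts):
        seq = contexts[0].sequence
        assert ld.inject_dinucleotides(seq, "CG", 0, (20, 120), seed=3) == seq


class TestSwapAndDuplicate:
    def test_cartesian_product_count(self, contexts):
        ctx = contexts[0]
        d, a = ctx.splice_site_positions
        regions = {"exon_up": (0, d), "intron": (d, a), "exon_down": (a, len(ctx.sequence))}
        rng = np.random.default_rng(0)
        reps = {
            name: ["".join(rng.choice(list("ACGT"), b - a_)) for _ in range(3)]
            for name, (a_, b) in regions.items()
        }
        out = ld.swap_components(ctx, regions, reps)
        assert len(out) == 27
        assert all(len(s) == len(ctx.sequence) for s in out)

    def test_no_replacement_returns_input(self, contexts):
        ctx = contexts[0]
        d, a = ctx.splice_site_positions
        regions = {"intron": (d, a)}
        assert ld.swap_components(ctx, regions, {}) == [ctx.sequence]

    def test_unswapped_positions_identical(self, contexts):
        ctx = contexts[0]
        d, a = ctx.splice_site_positions
        regions = {"intron": (d, a)}
        repl = {"intron": ["T" * (a - d)]}
        (out,) = ld.swap_components(ctx, regions, repl)
        assert out[:d] == ctx.sequence[:d] and out[a:] == ctx.sequence[a:]

    def test_duplicate_makes_spans_identical(self, tandem_contexts):
        ctx = tandem_contexts[0]
        first, second = ctx.splice_site_positions
        out = ld.duplicate_splice_site(ctx, "first", (-9, 0))
        assert out[first - 9 : first] == out[second - 9 : second]

    def test_duplicate_second_changes_three_positions(self, tandem_contexts):
        ctx = tandem_contexts[0]
        first, _ = ctx.splice_site_positions
        out = ld.duplicate_splice_site(ctx, "second", (-3, 0))
        diffs = [i for i, (x, y) in enumerate(zip(ctx.sequence, out)) if x != y]
        assert all(first - 3 <= i < first for i in diffs)

    def test_mirrored_spans_agree_between_directions(self, tandem_contexts):
        ctx = tandem_contexts[0]
        first, second = ctx.splice_site_positions
        a = ld.duplicate_splice_site(ctx, "first", (-6, 0))
        b = ld.duplicate_splice_site(ctx, "second", (-6, 0))
        assert a[first - 6 : first] == a[second - 6 : second]
        assert b[first - 6 : first] == b[second - 6 : second]

    def test_span_exceeding_intersite_distance_rejected(self, tandem_contexts):
        ctx = tandem_contexts[0]
        first, second = ctx.splice_site_positions
        with pytest.raises(ld.DesignError):
            ld.duplicate_splice_site(ctx, "first", (0, second - first + 3))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_designed_oligos_are_always_210nt(seed):
    ctxs = random_contexts(2, seed=seed % 1000)
    variants = ld.design_library(ctxs, subsets=("wt", "constvar"), n_barcode_controls=2, seed=seed)
    assert variants and all(len(v.full_sequence) == 210 for v in variants)
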