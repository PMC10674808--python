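import itertools
import re

import numpy as np
import pytest

from totikit.io import GenomeRecord, Interval
from totikit.orfs import OrfAnnotation, find_orfs, frame_of
from totikit.prf import (
    LOOP_PENALTY_PER_NT,
    PAIR_ENERGY,
    PK_INIT_PENALTY,
    PkParams,
    PrfElement,
    Pseudoknot,
    SlipperySite,
    assemble_prf,
    find_pseudoknots,
    fusion_protein,
    is_slippery,
    pk_energy,
    scan_slippery,
)

# Independent grammar oracle: regex over the XXXYYYZ definition.
_SLIPPERY_RE = re.compile(r"^(AAA|CCC|GGG|UUU)(AAA|UUU)[ACU]$")


class TestSlipperyGrammar:
    @pytest.mark.parametrize("hept", ["GGGUUUA", "UUUUUUA", "AAAUUUC", "CCCAAAU"])
    def test_accepted(self, hept):
        assert is_slippery(hept)

    @pytest.mark.parametrize("hept", ["GGGUUUG", "GGAUUUA", "GGGCCCA", "AAAUUU", "GGGUUUAA"])
    def test_rejected(self, hept):
        assert not is_slippery(hept)

    def test_exhaustive_against_regex_oracle(self):
        for hept in map("".join, itertools.product("ACGU", repeat=7)):
            assert is_slippery(hept) == bool(_SLIPPERY_RE.match(hept)), hept


def _orf(start, end):
    n = end - start + 1
    return OrfAnnotation(
        interval=Interval(start, end), frame=frame_of(start),
        start_codon="AUG", stop_codon="UAA", protein="M" + "A" * (n // 3 - 2),
    )


class TestScanSlippery:
    def _oracle(self, seq, orf1_start, orf1_end, max_upstream):
        hits = []
        for end in range(max(orf1_start + 6, orf1_end - max_upstream), orf1_end + 1):
            start = end - 6
            if start < 1:
                continue
            h = seq[start - 1 : end]
            if _SLIPPERY_RE.match(h) and (end - orf1_start + 1) % 3 == 0:
                hits.append((start, end, h))
        return hits

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGU"), size=2000))
            orf1 = _orf(7, 7 + 3 * 600 - 1)
            got = [
                (s.interval.start, s.interval.end, s.heptamer)
                for s in scan_slippery(GenomeRecord(id="r", sequence=seq), orf1, 300)
            ]
            assert got == self._oracle(seq, orf1.start, orf1.end, 300)

    def test_codon_boundary_flag(self, gctv2_genome):
        genome, truth = gctv2_genome
        orf1 = _orf(*truth.genome["orf1"])
        sites = scan_slippery(genome, orf1)
        assert len(sites) == 1
        site = sites[0]
        assert site.heptamer == truth.genome["slippery_heptamer"]
        assert site.on_codon_boundary
        assert site.distance_to_orf1_stop == orf1.end - site.interval.end

    def test_site_xyz_fields(self):
        site = SlipperySite(Interval(1958, 1964), "GGGUUUA", 108, True)
        assert (site.x, site.y, site.z) == ("G", "U", "A")

    def test_bad_heptamer_rejected(self):
        with pytest.raises(ValueError, match="XXXYYYZ"):
            SlipperySite(Interval(1, 7), "GGGUUUG", 0, True)


def _make_pk(seq_parts, s1_len, s2_len, offset=1):
    """Build a pseudoknot over explicit S1a/L1/S2a/L2/S1b/L3/S2b blocks."""
    s1a, l1, s2a, l2, s1b, l3, s2b = seq_parts
    p = offset
    pos_s1a = p
    pos_s2a = pos_s1a + len(s1a) + len(l1)
    pos_s1b = pos_s2a + len(s2a) + len(l2)
    pos_s2b = pos_s1b + len(s1b) + len(l3)
    stem1 = tuple((pos_s1a + k, pos_s1b + s1_len - 1 - k) for k in range(s1_len))
    stem2 = tuple((pos_s2a + k, pos_s2b + s2_len - 1 - k) for k in range(s2_len))
    seq = "".join(seq_parts)
    return seq, Pseudoknot(
        stem1=stem1, stem2=stem2,
        span=Interval(pos_s1a, pos_s2b + s2_len - 1),
        loop_lengths=(len(l1), len(l2), len(l3)),
        efe_kcal_mol=0.0,
    )


class TestPkEnergy:
    def test_minimal_pseudoknot_hand_summed(self):
        # two 3-bp GC stems, loops 2/0/2: 6*(-3.0) + 4*0.2 + 7.0 = -10.2
        seq, pk = _make_pk(("GGG", "AA", "GGG", "", "CCC", "AA", "CCC"), 3, 3)
        assert pk_energy(pk, seq) == pytest.approx(-10.2)

    def test_one_more_gc_pair_is_minus_three(self):
        seq1, pk1 = _make_pk(("GGG", "AA", "GGG", "", "CCC", "AA", "CCC"), 3, 3)
        seq2, pk2 = _make_pk(("GGGG", "AA", "GGG", "", "CCCC", "AA", "CCC"), 4, 3)
        assert pk_energy(pk2, seq2) - pk_energy(pk1, seq1) == pytest.approx(-3.0)

    def test_resummation_oracle_on_random_structures(self):
        rng = np.random.default_rng(33)
        comp = {"G": "C", "C": "G", "A": "U", "U": "A"}
        for _ in range(100):
            s1 = "".join(rng.choice(list("ACGU"), size=int(rng.integers(3, 7))))
            s2 = "".join(rng.choice(list("ACGU"), size=int(rng.integers(3, 7))))
            l1 = "A" * int(rng.integers(1, 8))
            l2 = "A" * int(rng.integers(0, 5))
            l3 = "A" * int(rng.integers(1, 12))
            s1b = "".join(comp[c] for c in reversed(s1))
            s2b = "".join(comp[c] for c in reversed(s2))
            seq, pk = _make_pk((s1, l1, s2, l2, s1b, l3, s2b), len(s1), len(s2))
            expected = (
                sum(PAIR_ENERGY[(seq[p - 1], seq[q - 1])] for p, q in pk.stem1 + pk.stem2)
                + LOOP_PENALTY_PER_NT * sum(pk.loop_lengths)
                + PK_INIT_PENALTY
            )
            assert pk_energy(pk, seq) == pytest.approx(expected)

    def test_validate_rejects_non_crossing(self):
        seq, pk = _make_pk(("GGG", "AA", "GGG", "", "CCC", "AA", "CCC"), 3, 3)
        pk.validate(seq)
        bad = Pseudoknot(pk.stem2, pk.stem1, pk.span, pk.loop_lengths, 0.0)
        with pytest.raises(ValueError):
            bad.validate(seq)


class TestFindPseudoknots:
    def test_poly_a_window_empty(self):
        g = GenomeRecord(id="a", sequence="A" * 200)
        assert find_pseudoknots(g, Interval(10, 100)) == []

    def test_planted_structure_top_ranked_with_hand_summed_energy(self):
        seq, pk = _make_pk(
            ("GCGCGC", "CACA", "GGCGG", "A", "GCGCGC", "CACACACA", "CCGCC"), 6, 5
        )
        # pad so planted flanks cannot extend
        full = "A" * 10 + seq + "A" * 10
        g = GenomeRecord(id="p", sequence=full)
        pks = find_pseudoknots(g, Interval(5, min(len(full), 120)))
        top = pks[0]
        assert top.span == Interval(pk.span.start + 10, pk.span.end + 10)
        expected = 11 * -3.0 + LOOP_PENALTY_PER_NT * 13 + PK_INIT_PENALTY
        assert top.efe_kcal_mol == pytest.approx(expected)

    def test_window_too_long_errors(self):
        g = GenomeRecord(id="a", sequence="A" * 400)
        with pytest.raises(ValueError, match="max_window"):
            find_pseudoknots(g, Interval(1, 200))

    def test_deterministic_and_sorted(self, gctv2_genome):
        genome, truth = gctv2_genome
        slip_end = truth.genome["slippery"][1]
        window = Interval(slip_end + 1, slip_end + 120)
        a = find_pseudoknots(genome, window)
        b = find_pseudoknots(genome, window)
        assert a == b
        energies = [pk.efe_kcal_mol for pk in a]
        assert energies == sorted(energies)

    def test_all_outputs_satisfy_invariants(self, gctv2_genome):
        genome, truth = gctv2_genome
        slip_end = truth.genome["slippery"][1]
        for pk in find_pseudoknots(genome, Interval(slip_end + 1, slip_end + 100)):
            pk.validate(genome.sequence)


class TestAssemblePrf:
    def _site(self, start, end, hept):
        return SlipperySite(Interval(start, end), hept, 0, True)

    def _pk_at(self, start, end):
        # geometry is irrelevant for spacer arithmetic; use a plain container
        return Pseudoknot(
            stem1=((start, end),), stem2=((start + 1, end - 1),),
            span=Interval(start, end), loop_lengths=(0, 0, 0), efe_kcal_mol=-5.0,
        )

    def test_published_spacer_4(self):
        els = assemble_prf(self._site(1958, 1964, "GGGUUUA"), [self._pk_at(1969, 2023)])
        assert len(els) == 1 and els[0].spacer_length == 4

    def test_published_spacer_27(self):
        els = assemble_prf(self._site(1943, 1949, "UUUUUUA"), [self._pk_at(1977, 1997)])
        assert len(els) == 1 and els[0].spacer_length == 27

    def test_spacer_zero_excluded_by_default(self):
        els = assemble_prf(self._site(1958, 1964, "GGGUUUA"), [self._pk_at(1965, 1999)])
        assert els == []

    def test_spacer_bounds_inclusive(self):
        pks = [self._pk_at(1966, 1999), self._pk_at(1995, 2020)]
        els = assemble_prf(self._site(1958, 1964, "GGGUUUA"), pks, spacer_bounds=(1, 30))
        assert sorted(e.spacer_length for e in els) == [1, 30]

    def test_negative_spacer_rejected_by_type(self):
        with pytest.raises(ValueError):
            PrfElement(self._site(1958, 1964, "GGGUUUA"), self._pk_at(1960, 1999), -5.0)


class TestFusionProtein:
    def test_toy_genome_hand_translated(self):
        # ORF1 1-12 (AUG GGU UUA UAA) with heptamer GGGUUUA at 3-9 ending on
        # a codon boundary; -1 slip re-reads position 9 and continues in the
        # frame of the stop at 18-20: AUA AGC CGA.  Fusion = MGL + ISR.
        seq = "AUGGGUUUAUAAGCCGAUAAC"
        g = GenomeRecord(id="toy", sequence=seq)
        orf1 = _orf(1, 12)
        orf2 = OrfAnnotation(
            interval=Interval(12, 20), frame=frame_of(12), start_codon="AUG",
            stop_codon="UAA", protein="MA",
        )
        site = SlipperySite(Interval(3, 9), "GGGUUUA", 3, True)
        fp = fusion_protein(g, orf1, site, orf2)
        assert (fp.pre_shift_codons, fp.post_shift_codons) == (3, 3)
        assert fp.protein == "MGLISR"

    def test_fusion_lengths_on_synthetic_fixtures(self, gctv2_genome, gctv4_genome):
        for (genome, truth), expected in ((gctv2_genome, 1508), (gctv4_genome, 1496)):
            t = truth.genome
            orf1 = _orf(*t["orf1"])
            orf2 = _orf(*t["orf2"])
            site = SlipperySite(
                Interval(*t["slippery"]), t["slippery_heptamer"],
                orf1.end - t["slippery"][1], True,
            )
            fp = fusion_protein(genome, orf1, site, orf2)
            assert fp.protein_length == expected == t["fusion_len_aa"]
            assert fp.protein_length == fp.pre_shift_codons + fp.post_shift_codons
            assert "*" not in fp.protein

    def test_heptamer_off_codon_boundary_errors(self, gctv2_genome):
        genome, truth = gctv2_genome
        t = truth.genome
        orf1, orf2 = _orf(*t["orf1"]), _orf(*t["orf2"])
        s, e = t["slippery"]
        bad = SlipperySite(Interval(s - 1, e - 1), "AAAAAAA", 0, False)
        with pytest.raises(ValueError, match="codon boundary"):
            fusion_protein(genome, orf1, bad, orf2)

    def test_post_shift_frame_mismatch_errors(self, gctv2_genome):
        genome, truth = gctv2_genome
        t = truth.genome
        orf1, orf2 = _orf(*t["orf1"]), _orf(*t["orf2"])
        site = SlipperySite(Interval(*t["slippery"]), t["slippery_heptamer"], 0, True)
        shifted_orf2 = _orf(t["orf2"][0] + 1, t["orf2"][1] + 1)
        with pytest.raises(ValueError, match="post-shift"):
            fusion_protein(genome, orf1, site, shifted_orf2)

    def test_pre_shift_codon_count_matches_arithmetic(self, gctv2_genome):
        genome, truth = gctv2_genome
        t = truth.genome
        site = SlipperySite(Interval(*t["slippery"]), t["slippery_heptamer"], 0, True)
        fp = fusion_protein(genome, _orf(*t["orf1"]), site, _orf(*t["orf2"]))
        assert fp.pre_shift_codons == (t["slippery"][1] - t["orf1"][0] + 1) // 3
        assert fp.post_shift_codons == (t["orf2"][1] - 3 - t["slippery"][1] + 1) // 3
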