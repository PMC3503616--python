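"""In-silico digestion and peak-table analysis."""

import numpy as np
import pytest
from scipy import stats

from labstrain import (
    PeakTable,
    abundance_matrix,
    find_primer_site,
    peak_group_anova,
    profile_from_peaks,
    terminal_fragment_length,
)
from labstrain.simulate import GeneratorConfig, simulate_trflp_cohort
from labstrain.trflp import reverse_complement

PRIMER = "AGAGTTTGATCCTGGCTCAG"  # a standard 16S forward primer
REF = {"74": 74.0, "181": 181.0, "189": 189.0, "566": 566.0}


def profiles_of(peaks_df, reference=REF):
    out = []
    for sid, grp in peaks_df.groupby("sample_id", sort=False):
        pt = PeakTable(str(sid), list(zip(grp["size"], grp["area"])))
        out.append(profile_from_peaks(pt, reference))
    return out


class TestPrimerSite:
    def test_verbatim_match(self, rng):
        tpl = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 40)]) + PRIMER + "GTGCCAGCAGCC"
        m = find_primer_site(tpl, PRIMER)
        assert (m.position, m.strand, m.mismatches) == (40, "forward", 0)

    def test_internal_mismatch_tolerated(self):
        tpl = "TTTT" + PRIMER[:10] + "A" + PRIMER[11:] + "TTTT"
        assert PRIMER[10] != "A"
        m = find_primer_site(tpl, PRIMER)
        assert m.mismatches == 1

    def test_three_prime_anchor_mismatch_rejected(self):
        broken = PRIMER[:-1] + ("C" if PRIMER[-1] != "C" else "T")
        tpl = "TTTT" + broken + "TTTT"
        assert find_primer_site(tpl, PRIMER, max_mismatch=0) is None

    def test_reverse_strand_found(self):
        tpl = "GGGG" + reverse_complement(PRIMER) + "GGGG"
        m = find_primer_site(tpl, PRIMER)
        assert m is not None and m.strand == "reverse"

    def test_non_iupac_primer_rejected(self):
        with pytest.raises(ValueError):
            find_primer_site("ACGT" * 20, "ACGTACGTXZ")


class TestTerminalFragment:
    def test_cut_one_base_into_recognition_site(self, rng):
        spacer = "".join(np.array(list("AGT"))[rng.integers(0, 3, 185 - len(PRIMER))])
        tpl = PRIMER + spacer + "CCGG" + "ATATATAT"
        frag = terminal_fragment_length(tpl, PRIMER)
        assert (frag.length, frag.uncut) == (186, False)

    def test_no_site_gives_full_amplicon_uncut(self):
        tpl = PRIMER + "ATATATATATAT"
        frag = terminal_fragment_length(tpl, PRIMER)
        assert frag.uncut and frag.length == len(tpl)

    def test_invariant_to_content_after_first_cut(self, rng):
        head = PRIMER + "ATATAT" + "CCGG"
        lengths = set()
        for _ in range(10):
            tail = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 50)])
            lengths.add(terminal_fragment_length(head + tail, PRIMER).length)
        assert lengths == {len(PRIMER) + 6 + 1}

    def test_missing_primer_returns_none(self):
        assert terminal_fragment_length("ATATATATATATCCGG", PRIMER) is None

    def test_reverse_primer_delimits_amplicon(self):
        rev = "GGTTACCTTGTTACGACTT"
        tpl = PRIMER + "ATAT" + reverse_complement(rev) + "CCGGCCGG"
        frag = terminal_fragment_length(tpl, PRIMER, rev_primer=rev)
        assert frag.uncut  # the cut site lies beyond the amplicon
        assert frag.length == len(PRIMER) + 4 + len(rev)


class TestProfiles:
    def test_relative_abundance_of_assigned_peaks(self):
        pt = PeakTable("s1", [(189.3, 70.0), (74.1, 30.0)])
        prof = profile_from_peaks(pt, {"189": 189.0, "74": 74.0})
        assert prof.abundances == pytest.approx({"189": 0.7, "74": 0.3})
        assert prof.unassigned == 0.0

    def test_single_peak_gets_everything(self):
        prof = profile_from_peaks(PeakTable("s", [(74.0, 5.0)]), REF)
        assert prof.abundances["74"] == 1.0

    def test_unmatched_peak_counts_in_unassigned_with_full_denominator(self):
        pt = PeakTable("s", [(100.0, 50.0), (74.0, 50.0)])
        prof = profile_from_peaks(pt, REF)
        assert prof.abundances["74"] == 0.5 and prof.unassigned == 0.5

    def test_zero_total_area_rejected(self):
        with pytest.raises(ValueError):
            profile_from_peaks(PeakTable("s", [(74.0, 0.0)]), REF)

    def test_abundances_conserve_mass(self, rng):
        for _ in range(50):
            sizes = rng.uniform(50, 600, size=6)
            areas = rng.uniform(0.1, 100, size=6)
            prof = profile_from_peaks(PeakTable("s", list(zip(sizes, areas))), REF)
            assert sum(prof.abundances.values()) + prof.unassigned == pytest.approx(1.0, abs=1e-9)


class TestAbundanceMatrix:
    @pytest.mark.parametrize("value,level", [(0.0, 1), (1.0, 8), (0.5, 5),
                                             (0.124, 1), (0.126, 2)])
    def test_eight_level_bins(self, value, level):
        from labstrain import TRFLPProfile
        prof = TRFLPProfile("s", {"74": value}, 1 - value)
        _, codes = abundance_matrix([prof], levels=8)
        assert codes.loc["s", "74"] == level

    def test_cohort_matrix_shape(self):
        peaks, meta, _ = simulate_trflp_cohort(GeneratorConfig(seed=5, n_samples=50))
        real, codes = abundance_matrix(profiles_of(peaks))
        assert real.shape == (50, 4) and codes.shape == (50, 4)
        assert ((codes >= 1) & (codes <= 8)).all().all()


class TestGroupAnova:
    def two_group_profiles(self, g1, g2):
        from labstrain import TRFLPProfile
        profs, grouping = [], {}
        for i, v in enumerate(g1):
            profs.append(TRFLPProfile(f"a{i}", {"x": v}, 1 - v)); grouping[f"a{i}"] = "g1"
        for i, v in enumerate(g2):
            profs.append(TRFLPProfile(f"b{i}", {"x": v}, 1 - v)); grouping[f"b{i}"] = "g2"
        return profs, grouping

    def test_hand_computed_f_statistic(self):
        profs, grouping = self.two_group_profiles([0.1, 0.2, 0.3], [0.2, 0.3, 0.4])
        r = peak_group_anova(profs, grouping, "x")
        assert r.F == pytest.approx(1.5)
        assert (r.df_between, r.df_within) == (1, 4)

    def test_identical_groups_give_zero_f(self):
        profs, grouping = self.two_group_profiles([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        r = peak_group_anova(profs, grouping, "x")
        assert r.F == pytest.approx(0.0)

    def test_f_invariant_under_constant_shift(self):
        profs1, grouping = self.two_group_profiles([0.1, 0.2, 0.3], [0.2, 0.3, 0.4])
        profs2, _ = self.two_group_profiles([0.2, 0.3, 0.4], [0.3, 0.4, 0.5])
        r1 = peak_group_anova(profs1, grouping, "x")
        r2 = peak_group_anova(profs2, grouping, "x")
        assert r1.F == pytest.approx(r2.F)

    def test_small_group_rejected_by_name(self):
        profs, grouping = self.two_group_profiles([0.1, 0.2], [0.3])
        with pytest.raises(ValueError, match="g2"):
            peak_group_anova(profs, grouping, "x")

    def test_null_pvalues_uniform(self):
        """Under no group effect, per-peak ANOVA p-values are ~U(0,1)."""
        pvals = []
        for seed in range(300):
            peaks, meta, _ = simulate_trflp_cohort(
                GeneratorConfig(seed=seed, group_effect=0.0, n_samples=12))
            profs = profiles_of(peaks)
            grouping = dict(zip(meta["sample_id"], meta["tax_order"]))
            pvals.append(peak_group_anova(profs, grouping, "74").p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_group_effect_detected_null_species_spared(self):
        hits_down, hits_up, hits_null = 0, 0, 0
        n = 25
        for seed in range(n):
            peaks, meta, truth = simulate_trflp_cohort(GeneratorConfig(seed=seed))
            profs = profiles_of(peaks)
            grouping = {s: ("Rodentia" if g == "Rodentia" else "other")
                        for s, g in zip(meta["sample_id"], meta["tax_order"])}
            down, up = truth.shifted_species
            hits_down += peak_group_anova(profs, grouping, down).p < 0.05
            hits_up += peak_group_anova(profs, grouping, up).p < 0.05
            hits_null += peak_group_anova(profs, grouping, "189").p < 0.05
        assert hits_down / n > 0.9 and hits_up / n > 0.9
        assert hits_null / n < 0.35  # mild inflation from peak-area noise only
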