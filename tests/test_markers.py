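"""Marker calling: TSD detection, per-taxon classification, validation."""

import numpy as np
import pytest

import retromark.markers as mk
from retromark import simulate as sim
from retromark.markers import (
    LocusAlignment, classify_taxon, call_locus, detect_tsd,
    discover_candidates, validate_marker,
)

from conftest import OSCINE_PAIR, OSCINES, make_tree, quick_config


# ---------------------------------------------------------------------------
# detect_tsd
# ---------------------------------------------------------------------------

def brute_force_tsd(row, start, end, max_len=20, min_len=4):
    """Independent oracle: try every admissible length, longest first."""
    best = None
    for length in range(min_len, max_len + 1):
        if length > start or end + length > len(row):
            continue
        if row[start - length:start] == row[end:end + length]:
            if best is None or length > len(best):
                best = row[start - length:start]
    return best


class TestDetectTsd:
    def test_constructed_six_nt_duplicate(self):
        elem = "GATTACA" * 3
        row = "AAAT" + "CCGGTT" + elem + "CCGGTT" + "GGGG"
        start = 4 + 6
        end = start + len(elem)
        assert detect_tsd(row, start, end) == "CCGGTT"

    def test_no_repeat_returns_none(self):
        row = "AAAACCCC" + "TTTT" + "GGGGACGT"
        assert detect_tsd(row, 8, 12) is None

    def test_longest_wins_over_nested_repeat(self):
        # 8-nt duplicate whose last 4 nt alone also form a duplicate
        tsd = "ACGGTCAA"
        row = "TT" + tsd + "GGGGGGG" + tsd + "CC"
        start, end = 2 + 8, 2 + 8 + 7
        got = detect_tsd(row, start, end)
        assert got == tsd
        assert got == brute_force_tsd(row, start, end)

    def test_boundary_element_warns_and_returns_none(self):
        with pytest.warns(UserWarning, match="boundary"):
            assert detect_tsd("ACGTACGT", 0, 4) is None

    def test_agrees_with_exhaustive_search_on_random_loci(self):
        """1,000 random constructed loci, half with planted TSDs."""
        rng = np.random.default_rng(11)
        for i in range(1000):
            flank = sim._random_sequence(40, rng)
            elem = sim._random_sequence(25, rng)
            if i % 2 == 0:
                L = int(rng.integers(4, 13))
                tsd = sim._random_sequence(L, rng)
                row = flank + tsd + elem + tsd + flank
                start, end = 40 + L, 40 + L + 25
            else:
                row = flank + elem + flank
                start, end = 40, 65
            assert detect_tsd(row, start, end) == \
                brute_force_tsd(row, start, end)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@pytest.fixture
def concordant_locus(template):
    tree = make_tree()
    cfg = quick_config({OSCINE_PAIR: 1}, seed=21)
    loci, truths = sim.simulate_locus_set(tree, template, cfg)
    return loci[0], truths[0]


class TestClassifyTaxon:
    def test_descendant_is_present(self, concordant_locus, library):
        locus, _ = concordant_locus
        call = classify_taxon(locus, "Corvus", library)
        assert call.state == "present"
        assert call.reasons == []
        assert call.subtype == "TguSINE1_synth"

    def test_outgroup_is_absent(self, concordant_locus, library):
        locus, _ = concordant_locus
        call = classify_taxon(locus, "Gallus", library)
        assert call.state == "absent"

    def test_unknown_taxon_raises(self, concordant_locus, library):
        with pytest.raises(KeyError, match="Archaeopteryx"):
            classify_taxon(concordant_locus[0], "Archaeopteryx", library)

    def test_missing_row_is_ambiguous(self, concordant_locus, library):
        locus, _ = concordant_locus
        rows = dict(locus.rows)
        rows["Corvus"] = "?" * locus.n_columns
        damaged = LocusAlignment(locus.locus_id, rows, locus.element_span,
                                 locus.ref_taxon)
        call = classify_taxon(damaged, "Corvus", library)
        assert call.state == "ambiguous"
        assert call.reasons == [mk.REASON_MISSING]

    def test_reverse_complemented_element_flips_orientation(self, concordant_locus,
                                                            library):
        """Reversing a present row's element must trip the orientation
        criterion, never silently pass."""
        locus, _ = concordant_locus
        s, e = locus.element_span
        row = locus.rows["Corvus"]
        comp = str.maketrans("ACGT", "TGCA")
        flipped = row[:s] + row[s:e].translate(comp)[::-1] + row[e:]
        rows = dict(locus.rows)
        rows["Corvus"] = flipped
        damaged = LocusAlignment(locus.locus_id, rows, locus.element_span,
                                 locus.ref_taxon)
        call = classify_taxon(damaged, "Corvus", library)
        assert call.state == "ambiguous"
        assert mk.REASON_ORIENTATION in call.reasons

    def test_wrong_subtype_flagged(self, concordant_locus, library):
        """Splicing a different element into the span trips the subtype
        criterion."""
        locus, _ = concordant_locus
        s, e = locus.element_span
        other = sim.make_sine_template(sim.SYNTH_TRNA_ASP, sim.SYNTH_CR1_TAIL)
        lib = dict(library)
        # decoy family: same tail, different head, same total length
        lib["PittSINE_synth"] = other.sequence
        rows = dict(locus.rows)
        rows["Corvus"] = (locus.rows["Corvus"][:s] + other.sequence
                          + locus.rows["Corvus"][e:])
        damaged = LocusAlignment(locus.locus_id, rows, locus.element_span,
                                 locus.ref_taxon)
        call = classify_taxon(damaged, "Corvus", lib)
        assert call.state == "ambiguous"
        assert mk.REASON_SUBTYPE in call.reasons


class TestValidateMarker:
    def test_concordant_locus_valid(self, concordant_locus, library):
        locus, truth = concordant_locus
        calls = call_locus(locus, library)
        rec = validate_marker(locus, calls)
        assert rec.valid
        assert rec.re_class == "SINE-TguSINE1"
        assert {c.taxon: c.state for c in calls} == truth.per_taxon_state

    def test_subtype_mismatch_invalidates(self, concordant_locus, library):
        locus, _ = concordant_locus
        s, e = locus.element_span
        other = sim.make_sine_template(sim.SYNTH_TRNA_ASP, sim.SYNTH_CR1_TAIL)
        lib = dict(library)
        lib["PittSINE_synth"] = other.sequence
        rows = dict(locus.rows)
        rows["Corvus"] = (locus.rows["Corvus"][:s] + other.sequence
                          + locus.rows["Corvus"][e:])
        damaged = LocusAlignment(locus.locus_id, rows, locus.element_span,
                                 locus.ref_taxon)
        rec = validate_marker(damaged, call_locus(damaged, lib))
        assert not rec.valid
        assert any("subtype_mismatch" in r for r in rec.failure_reasons)

    def test_all_ambiguous_is_uninformative(self, concordant_locus, library):
        locus, _ = concordant_locus
        rows = {t: "?" * locus.n_columns for t in locus.rows}
        rows[locus.ref_taxon] = locus.rows[locus.ref_taxon]
        damaged = LocusAlignment(locus.locus_id, rows, locus.element_span,
                                 locus.ref_taxon)
        calls = [c for c in call_locus(damaged, library)
                 if c.taxon != locus.ref_taxon]
        rec = validate_marker(damaged, calls)
        assert not rec.valid
        assert "uninformative" in rec.failure_reasons

    def test_fewer_than_three_taxa_rejected(self, concordant_locus, library):
        locus, _ = concordant_locus
        calls = call_locus(locus, library)[:2]
        with pytest.raises(ValueError, match=">= 3"):
            validate_marker(locus, calls)

    def test_validity_monotone_under_added_missing_taxon(self, concordant_locus,
                                                         library):
        """Adding a taxon with no usable data never invalidates a marker."""
        locus, _ = concordant_locus
        rec = validate_marker(locus, call_locus(locus, library))
        assert rec.valid
        rows = dict(locus.rows)
        rows["Extra_taxon"] = "?" * locus.n_columns
        bigger = LocusAlignment(locus.locus_id, rows, locus.element_span,
                                locus.ref_taxon)
        rec2 = validate_marker(bigger, call_locus(bigger, library))
        assert rec2.valid

    def test_zero_divergence_recovery_is_exact(self, template, library):
        """With no flank divergence and no copy decay, calling recovers the
        simulated truth for every taxon of every locus."""
        tree = make_tree(0.0)
        cfg = quick_config({OSCINE_PAIR: 10, OSCINES: 10}, seed=31,
                           copy_divergence=0.0)
        loci, truths = sim.simulate_locus_set(tree, template, cfg)
        for locus, truth in zip(loci, truths):
            calls = call_locus(locus, library)
            rec = validate_marker(locus, calls)
            assert rec.valid
            assert {c.taxon: c.state for c in calls} == truth.per_taxon_state


# ---------------------------------------------------------------------------
# candidate discovery
# ---------------------------------------------------------------------------

class TestDiscoverCandidates:
    def test_constructed_empty_site(self):
        rng = np.random.default_rng(41)
        left = sim._random_sequence(300, rng)
        right = sim._random_sequence(300, rng)
        tsd = "CCGGTTAA"
        elem = sim._random_sequence(220, rng)
        ingroup = left + tsd + elem + tsd + right
        outgroup = left + tsd + right
        e_start = 300 + 8
        e_end = e_start + 220
        cands = discover_candidates(ingroup, [(e_start, e_end)], outgroup,
                                    flank_len=300)
        assert len(cands) == 1 and cands[0].accepted
        # both flank hits claim the single target-site copy: the signed gap
        # magnitude approximates the TSD length
        assert abs(cands[0].interflank_gap) <= len(tsd)

    def test_missing_right_flank_unmapped(self):
        rng = np.random.default_rng(43)
        left = sim._random_sequence(300, rng)
        elem = sim._random_sequence(200, rng)
        ingroup = left + elem + sim._random_sequence(300, rng)
        outgroup = left  # right flank nowhere in the outgroup
        cands = discover_candidates(ingroup, [(300, 500)], outgroup,
                                    flank_len=250)
        assert not cands[0].accepted
        assert cands[0].reason == "flank_unmapped"

    def test_occupied_site_rejected(self):
        rng = np.random.default_rng(44)
        left = sim._random_sequence(300, rng)
        right = sim._random_sequence(300, rng)
        elem = sim._random_sequence(400, rng)
        ingroup = left + elem + right
        outgroup = left + elem + right  # outgroup carries the insertion too
        cands = discover_candidates(ingroup, [(300, 700)], outgroup,
                                    flank_len=250)
        assert not cands[0].accepted
        assert cands[0].reason == "site_occupied"

    def test_recovery_on_simulated_loci(self, template):
        """>= 19/20 simulated insertions rediscovered from the raw ingroup
        and outgroup sequences."""
        tree = make_tree(0.01)
        cfg = quick_config({OSCINE_PAIR: 20}, seed=45, flank_length=300)
        loci, _ = sim.simulate_locus_set(tree, template, cfg)
        found = 0
        for locus in loci:
            row = locus.rows["Taeniopygia"]
            s, e = locus.element_span
            ing = mk.ungap(row)
            us = mk._col_to_ungapped(row, s)
            ue = mk._col_to_ungapped(row, e)
            outg = mk.ungap(locus.rows["Gallus"])
            cands = discover_candidates(ing, [(us, ue)], outg, flank_len=250)
            found += cands[0].accepted
        assert found >= 19
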