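"""Characterization statistics: windows, spectra, motifs, diversity."""

import math

import numpy as np
import pandas as pd
import pytest

from becharlib.library import LibraryConfig, SgRNATargetPair, build_pair
from becharlib.characterize import (
    MotifPWM,
    aggregate_editing,
    annotate_alleles,
    background_probability,
    call_window,
    characterize_editor,
    classify_allele,
    coverage_filter,
    dead_control_cutoff,
    diversity,
    editing_efficiency,
    edits_per_allele,
    harmonize_strand,
    median_low,
    metric_correlation,
    motif_es,
    motif_pwm,
    spectrum,
    substitution_records,
)
from becharlib.quantify import AlleleTable
from becharlib.seqs import revcomp


# --- toy library: one top-strand pair and its exact mirror --------------------

def _toy_pair(strand="top", seed=0):
    rng = np.random.default_rng(seed)
    cfg = LibraryConfig(n_pairs=1, n_negative_controls=0)
    proto = "ATGAATGCATGCATGCATGC"
    return build_pair(proto, cfg, strand, False, rng, pair_id=f"p_{strand}")


def _mirror(pair: SgRNATargetPair) -> SgRNATargetPair:
    """The same designed site with the opposite strand label (the sequenced
    top strand is the reverse complement)."""
    flipped = "bottom" if pair.strand == "top" else "top"
    return SgRNATargetPair(pair.pair_id + "_m", pair.protospacer,
                           revcomp(pair.target_site), flipped, pair.pam_start,
                           pair.is_negative_control)


def _table(rows, sample="ed", totals=None) -> AlleleTable:
    df = pd.DataFrame(rows, columns=["target_id", "allele_seq", "n_inserted",
                                     "n_deleted", "n_mutated", "reads",
                                     "mean_norm_freq"])
    return AlleleTable(sample, None, df, totals or {})


def _sub(site, idx, base):
    return site[:idx] + base + site[idx + 1:]


def _flip(site, idx):
    """Substitute position ``idx`` with a base guaranteed to differ."""
    return _sub(site, idx, "T" if site[idx] != "T" else "A")


class TestCoverageFilter:
    def test_boundaries(self):
        t = _table([("a", "X", 0, 0, 0, 100, 100.0),
                    ("b", "Y", 0, 0, 0, 100, 100.0)],
                   totals={"a": 190, "b": 200})
        out = coverage_filter(t)
        assert set(out.df["target_id"]) == {"b"}  # 150+40=190 removed; 200 kept


class TestHarmonize:
    def test_bottom_strand_mirrors_to_ct(self):
        """A G>A change on the sequenced strand of a bottom-strand target is
        a C>T edit at the mirrored position after harmonization."""
        pair = _toy_pair("bottom")
        lib = [pair]
        harm = pair.harmonized_site
        # pick a harmonized C inside the protospacer and flip it to T
        idx = next(i for i in range(pair.pam_start - 18, pair.pam_start - 5)
                   if harm[i] == "C")
        edited_harm = _sub(harm, idx, "T")
        sequenced = revcomp(edited_harm)  # on disk: G>A somewhere
        t = _table([(pair.pair_id, sequenced, 0, 0, 1, 50, 10.0)])
        recs = substitution_records(t, lib)
        assert len(recs) == 1
        assert recs.iloc[0]["ref"] == "C" and recs.iloc[0]["alt"] == "T"
        assert recs.iloc[0]["pos"] == idx - pair.pam_start

    def test_idempotent(self):
        pair = _toy_pair("bottom")
        t = _table([(pair.pair_id, pair.target_site, 0, 0, 0, 10, 100.0)])
        once = harmonize_strand(t, [pair])
        twice = harmonize_strand(once, [pair])
        pd.testing.assert_frame_equal(once.df, twice.df)

    def test_top_strand_unchanged(self):
        pair = _toy_pair("top")
        t = _table([(pair.pair_id, pair.target_site, 0, 0, 0, 10, 100.0)])
        out = harmonize_strand(t, [pair])
        assert out.df["allele_seq"].iloc[0] == pair.target_site


class TestClassifyAllele:
    def test_classes(self):
        cn = pd.DataFrame({"ref": ["C"], "alt": ["T"]})
        comp = pd.DataFrame({"ref": ["G"], "alt": ["A"]})
        both = pd.DataFrame({"ref": ["C", "G"], "alt": ["T", "A"]})
        other = pd.DataFrame({"ref": ["A"], "alt": ["G"]})
        assert classify_allele(cn) == "C>N"
        assert classify_allele(comp) == "CompC>N"
        assert classify_allele(both) == "both"
        assert classify_allele(other) == "none"


class TestSubstitutionRecords:
    def test_records_carry_full_allele_frequency(self):
        pair = _toy_pair("top")
        site = pair.target_site
        cs = [i for i in range(pair.pam_start - 18, pair.pam_start - 5)
              if site[i] == "C"][:2]
        allele = site
        for i in cs:
            allele = _sub(allele, i, "T")
        t = _table([(pair.pair_id, allele, 0, 0, 2, 40, 10.0),
                    (pair.pair_id, site, 0, 0, 0, 360, 90.0)])
        recs = substitution_records(t, [pair])
        assert len(recs) == 2
        assert (recs["freq"] == 10.0).all()

    def test_reference_and_subcutoff_alleles_excluded(self):
        pair = _toy_pair("top")
        site = pair.target_site
        allele = _sub(site, pair.pam_start - 15, "A")
        t = _table([(pair.pair_id, site, 0, 0, 0, 100, 99.5),
                    (pair.pair_id, allele, 0, 0, 1, 1, 0.5)])
        assert substitution_records(t, [pair]).empty  # 0.5 is not > 0.5


class TestEfficiency:
    def _annotated(self, pair, rows):
        return annotate_alleles(_table(rows), [pair])

    def test_strict_cutoff(self):
        pair = _toy_pair("top")
        site = pair.target_site
        a1 = _flip(site, pair.pam_start - 15)
        a2 = _flip(site, pair.pam_start - 14)
        ann = self._annotated(pair, [
            (pair.pair_id, a1, 0, 0, 1, 10, 0.6),
            (pair.pair_id, a2, 0, 0, 1, 10, 0.4),
            (pair.pair_id, site, 0, 0, 0, 100, 99.0)])
        eff = editing_efficiency(ann, "all")
        assert eff[pair.pair_id] == pytest.approx(0.6)

    def test_no_edited_alleles(self):
        pair = _toy_pair("top")
        ann = self._annotated(pair, [(pair.pair_id, pair.target_site,
                                      0, 0, 0, 100, 100.0)])
        assert editing_efficiency(ann, "all")[pair.pair_id] == 0.0

    def test_indel_filter_on_substitution_only(self):
        pair = _toy_pair("top")
        a1 = _flip(pair.target_site, pair.pam_start - 15)
        ann = self._annotated(pair, [(pair.pair_id, a1, 0, 0, 1, 10, 5.0)])
        assert editing_efficiency(ann, "indel")[pair.pair_id] == 0.0
        assert editing_efficiency(ann, "all")[pair.pair_id] == pytest.approx(5.0)

    def test_window_split_filters(self):
        pair = _toy_pair("top")
        site = pair.target_site
        inside = _flip(site, pair.pam_start - 15)   # pos -15
        outside = _flip(site, pair.pam_start - 25)  # pos -25
        ann = self._annotated(pair, [
            (pair.pair_id, inside, 0, 0, 1, 10, 6.0),
            (pair.pair_id, outside, 0, 0, 1, 10, 4.0)])
        assert editing_efficiency(ann, "window_in")[pair.pair_id] == pytest.approx(6.0)
        assert editing_efficiency(ann, "window_out")[pair.pair_id] == pytest.approx(4.0)


class TestAggregateAndWindow:
    def test_aggregate_arithmetic(self):
        recs = pd.DataFrame({"pos": [-15, -15], "freq": [20.0, 10.0],
                             "ref": ["C", "C"], "alt": ["T", "T"]})
        assert aggregate_editing(recs) == {-15: pytest.approx(0.30)}

    def test_aggregate_linearity(self):
        recs = pd.DataFrame({"pos": [-15, -14], "freq": [20.0, 10.0],
                             "ref": ["C", "C"], "alt": ["T", "T"]})
        doubled = recs.assign(freq=recs["freq"] * 2)
        a1, a2 = aggregate_editing(recs), aggregate_editing(doubled)
        assert all(a2[k] == pytest.approx(2 * v) for k, v in a1.items())

    def test_dead_cutoff_closed_forms(self):
        assert dead_control_cutoff({-1: 0.0, 0: 0.0, 1: 0.0}) == 0.0
        assert dead_control_cutoff({-1: 0.1, 0: 0.1, 1: 0.1}) == pytest.approx(0.1)
        # mean 0.1 + 2 x population sigma 0.1 = 0.3
        assert dead_control_cutoff({0: 0.0, 1: 0.2}) == pytest.approx(0.3)
        with pytest.raises(ValueError):
            dead_control_cutoff({0: 0.1})

    def test_call_window(self):
        profile = {p: (0.4 if -18 <= p <= -13 else 0.1) for p in range(-30, 5)}
        assert call_window(profile, 0.25) == (-18, -13)
        assert call_window(profile, 0.5) is None
        # interior gap below cutoff does not split the window
        gapped = dict(profile)
        gapped[-15] = 0.0
        assert call_window(gapped, 0.25) == (-18, -13)

    def test_boundary_is_excluded(self):
        assert call_window({-15: 0.25}, 0.25) is None  # strictly above


class TestSpectrum:
    def test_pure_ct(self):
        recs = pd.DataFrame({"ref": ["C"] * 3, "alt": ["T"] * 3,
                             "freq": [1.0, 2.0, 3.0], "pos": [-15, -14, -13]})
        spec = spectrum(recs, "C")
        assert spec["C>T"] == pytest.approx(1.0)

    def test_weighted_67_16_18(self):
        # freq-weighted aggregates 6.7 : 1.6 : 1.8 normalize to 67:16:18
        recs = pd.DataFrame({
            "ref": ["C"] * 3, "alt": ["T", "A", "G"],
            "freq": [6.7, 1.6, 1.8], "pos": [-15, -14, -13]})
        spec = spectrum(recs, "C")
        total = 6.7 + 1.6 + 1.8
        assert spec["C>T"] == pytest.approx(6.7 / total)
        assert spec["C>A"] == pytest.approx(1.6 / total)
        assert spec["C>G"] == pytest.approx(1.8 / total)

    def test_empty_gives_none(self):
        recs = pd.DataFrame({"ref": [], "alt": [], "freq": [], "pos": []})
        assert spectrum(recs, "C") is None


class TestMotif:
    def test_single_record_one_hot(self):
        pair = _toy_pair("top")
        site = pair.target_site
        idx = next(i for i in range(pair.pam_start - 18, pair.pam_start - 5)
                   if site[i] == "C")
        recs = pd.DataFrame({"target_id": [pair.pair_id],
                             "pos": [idx - pair.pam_start],
                             "ref": ["C"], "alt": ["T"], "freq": [10.0]})
        pwm = motif_pwm(recs, [pair], "C")
        context = site[idx - 3: idx + 4]
        for offset, base in zip(range(-3, 4), context):
            assert pwm.column(offset)[base] == pytest.approx(1.0)

    def test_two_equal_records_average(self):
        pair = _toy_pair("top")
        site = pair.target_site
        cs = [i for i in range(pair.pam_start - 18, pair.pam_start)
              if site[i] == "C"][:2]
        recs = pd.DataFrame({"target_id": [pair.pair_id] * 2,
                             "pos": [i - pair.pam_start for i in cs],
                             "ref": ["C", "C"], "alt": ["T", "T"],
                             "freq": [5.0, 5.0]})
        pwm = motif_pwm(recs, [pair], "C")
        for offset in range(-3, 4):
            b1 = site[cs[0] + offset]
            b2 = site[cs[1] + offset]
            expected = 1.0 if b1 == b2 else 0.5
            assert pwm.column(offset)[b1] == pytest.approx(expected)

    def test_background_probability_wrc(self):
        # W at -2 (0.48) x R at -1 (0.26 + 0.24 = 0.5) = 0.24
        assert background_probability("WRC", 2, 0.52) == pytest.approx(0.24)

    def test_es_zero_for_background_pwm(self):
        bg = pd.DataFrame(
            {"A": 0.24, "C": 0.26, "G": 0.26, "T": 0.24}, index=range(-3, 4))
        pwm = MotifPWM(bg, weight=1.0)
        for motif, anchor in [("WRC", 2), ("TC", 1), ("GC", 1)]:
            assert motif_es(pwm, motif, anchor, 0.52) == pytest.approx(0.0)

    def test_es_closed_form_for_perfect_wrc(self):
        probs = pd.DataFrame(
            {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}, index=range(-3, 4))
        probs.loc[-2] = [0.5, 0.0, 0.0, 0.5]   # W only
        probs.loc[-1] = [0.5, 0.0, 0.5, 0.0]   # R only
        pwm = MotifPWM(probs, weight=1.0)
        assert motif_es(pwm, "WRC", 2, 0.52) == pytest.approx(
            math.log2(1 / 0.24), abs=1e-9)

    def test_es_scale_invariance(self):
        """Scaling all allele frequencies by a positive constant leaves the
        ES unchanged (the PWM is a normalized distribution)."""
        pair = _toy_pair("top")
        site = pair.target_site
        cs = [i for i in range(pair.pam_start - 18, pair.pam_start)
              if site[i] == "C"][:2]
        recs = pd.DataFrame({"target_id": [pair.pair_id] * 2,
                             "pos": [i - pair.pam_start for i in cs],
                             "ref": ["C", "C"], "alt": ["T", "T"],
                             "freq": [5.0, 2.0]})
        scaled = recs.assign(freq=recs["freq"] * 7.3)
        es1 = motif_es(motif_pwm(recs, [pair], "C"), "WRC", 2)
        es2 = motif_es(motif_pwm(scaled, [pair], "C"), "WRC", 2)
        assert es1 == pytest.approx(es2)

    def test_depleted_motif_is_minus_inf(self):
        probs = pd.DataFrame(
            {"A": 0.0, "C": 0.5, "G": 0.5, "T": 0.0}, index=range(-3, 4))
        pwm = MotifPWM(probs, weight=1.0)
        assert motif_es(pwm, "WRC", 2) == float("-inf")


class TestDiversity:
    def test_unedited_target(self):
        pair = _toy_pair("top")
        t = _table([(pair.pair_id, pair.target_site, 0, 0, 0, 100, 100.0)])
        d = diversity(t, [pair]).iloc[0]
        assert d["n_alleles"] == 0 and d["entropy"] == pytest.approx(0.0)

    def test_fifty_fifty_split_is_ln2(self):
        pair = _toy_pair("top")
        allele = _flip(pair.target_site, pair.pam_start - 15)
        t = _table([(pair.pair_id, pair.target_site, 0, 0, 0, 50, 50.0),
                    (pair.pair_id, allele, 0, 0, 1, 50, 50.0)])
        d = diversity(t, [pair]).iloc[0]
        assert d["n_alleles"] == 1
        assert d["entropy"] == pytest.approx(math.log(2))

    def test_exact_cutoff_excluded(self):
        pair = _toy_pair("top")
        allele = _flip(pair.target_site, pair.pam_start - 15)
        t = _table([(pair.pair_id, pair.target_site, 0, 0, 0, 199, 99.5),
                    (pair.pair_id, allele, 0, 0, 1, 1, 0.5)])
        d = diversity(t, [pair]).iloc[0]
        assert d["n_alleles"] == 0  # 0.5 is not > 0.5
        assert d["entropy"] == pytest.approx(0.0)


class TestEditsPerAllele:
    def test_weighted_proportions(self):
        pair = _toy_pair("top")
        site = pair.target_site
        a1 = _flip(site, pair.pam_start - 15)
        a2 = _flip(a1, pair.pam_start - 14)
        t = _table([(pair.pair_id, a1, 0, 0, 1, 10, 6.0),
                    (pair.pair_id, a2, 0, 0, 2, 5, 3.0),
                    (pair.pair_id, site, 0, 0, 0, 100, 91.0)])
        dist = edits_per_allele(t, [pair])
        assert dist[1] == pytest.approx(2 / 3)
        assert dist[2] == pytest.approx(1 / 3)

    def test_indel_only_alleles_excluded(self):
        pair = _toy_pair("top")
        site = pair.target_site
        indel = site[:60] + site[62:]
        a1 = _flip(site, pair.pam_start - 15)
        t = _table([(pair.pair_id, indel, 0, 2, 0, 10, 5.0),
                    (pair.pair_id, a1, 0, 0, 1, 10, 5.0)])
        dist = edits_per_allele(t, [pair])
        assert list(dist.index) == [1]
        assert dist[1] == pytest.approx(1.0)


class TestCorrelationAndMedian:
    def test_perfect_correlations(self):
        x = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}
        y2 = {k: 2 * v for k, v in x.items()}
        yneg = {k: -v for k, v in x.items()}
        assert metric_correlation(x, y2) == pytest.approx(1.0)
        assert metric_correlation(x, yneg) == pytest.approx(-1.0)

    def test_hand_computed_five_points(self):
        x = {"a": 1, "b": 2, "c": 3, "d": 4, "e": 5}
        y = {"a": 2, "b": 1, "c": 4, "d": 3, "e": 6}
        xv = np.array(list(x.values()), dtype=float)
        yv = np.array(list(y.values()), dtype=float)
        by_hand = np.sum((xv - xv.mean()) * (yv - yv.mean())) / (
            np.sqrt(np.sum((xv - xv.mean()) ** 2))
            * np.sqrt(np.sum((yv - yv.mean()) ** 2)))
        assert metric_correlation(x, y) == pytest.approx(by_hand)

    def test_exclusions_applied(self):
        x = {"a": 1, "b": 2, "c": 3, "d": 100}
        y = {"a": 1, "b": 2, "c": 3, "d": -100}
        assert metric_correlation(x, y, exclusions=["d"]) == pytest.approx(1.0)

    def test_degenerate_inputs(self):
        assert metric_correlation({"a": 1, "b": 2}, {"a": 1, "b": 2}) is None
        flat = {"a": 1, "b": 1, "c": 1}
        assert metric_correlation(flat, {"a": 1, "b": 2, "c": 3}) is None

    def test_median_low(self):
        assert median_low([3.0, 1.0, 2.0]) == 2.0
        assert median_low([4.0, 1.0, 2.0, 3.0]) == 2.0  # lower median
        assert median_low([]) is None


class TestMirrorEquivalence:
    def test_flipped_library_gives_identical_metrics(self):
        """Characterizing a site and its strand-flipped mirror (same edits,
        sequenced from the other strand) yields identical harmonized
        statistics."""
        pair = _toy_pair("top")
        mirror = _mirror(pair)
        harm = pair.harmonized_site
        idx = next(i for i in range(pair.pam_start - 18, pair.pam_start - 5)
                   if harm[i] == "C")
        edited = _sub(harm, idx, "T")

        t_top = _table([(pair.pair_id, edited, 0, 0, 1, 30, 30.0),
                        (pair.pair_id, harm, 0, 0, 0, 70, 70.0)],
                       totals={pair.pair_id: 400})
        t_bot = _table([(mirror.pair_id, revcomp(edited), 0, 0, 1, 30, 30.0),
                        (mirror.pair_id, revcomp(harm), 0, 0, 0, 70, 70.0)],
                       totals={mirror.pair_id: 400})
        rep_top = characterize_editor(t_top, [pair], window_cutoff=0.25)
        rep_bot = characterize_editor(t_bot, [mirror], window_cutoff=0.25)
        assert rep_top.aggregate == rep_bot.aggregate
        assert rep_top.window == rep_bot.window
        assert rep_top.spectrum_c == rep_bot.spectrum_c
        assert rep_top.median_efficiency == rep_bot.median_efficiency
        assert rep_top.es == pytest.approx(rep_bot.es)
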