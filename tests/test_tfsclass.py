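"""TFS encoding, redundancy removal and gene classification."""

import itertools

import numpy as np
import pandas as pd
import pytest

from liverdev import tfsclass
from liverdev.tfsclass import (TFS_WEIGHTS, Thresholds, classify_gene,
                               decode_tfs, encode_tfs, flag_comparison)


class TestFlagComparison:
    @pytest.mark.parametrize("ratio,p,wab,expected", [
        (2.0, 1e-6, True, 1),      # clear up-regulation
        (0.5, 1e-6, True, 2),      # clear down-regulation
        (0.5, 1e-6, False, 0),     # fails well-above-background
        (1.5, 1e-9, True, 0),      # boundary: strict >
        (1 / 1.5, 1e-9, True, 0),  # boundary: strict <
        (2.0, 1e-4, True, 0),      # boundary: p not strictly below cut
        (1.2, 1e-9, True, 0),      # significant but small fold
    ])
    def test_filter_rules(self, ratio, p, wab, expected):
        assert flag_comparison(ratio, p, wab) == expected

    def test_vectorized_agrees_with_scalar(self):
        rng = np.random.default_rng(3)
        log2r = rng.normal(0, 1, 500)
        p = 10 ** rng.uniform(-8, 0, 500)
        wab = rng.random(500) > 0.2
        flags = tfsclass.flag_array(log2r, p, wab)
        for i in range(0, 500, 17):
            assert flags[i] == flag_comparison(2.0 ** log2r[i], p[i], wab[i])


class TestTFSCode:
    def test_worked_example(self):
        code = encode_tfs((0, 0, 2, 2, 2, 0, 0))
        assert code.whole == 28
        assert code.decimal_string == "28.0022200"

    def test_all_zero(self):
        assert encode_tfs((0,) * 7).decimal_string == "0.0000000"

    def test_all_flagged_whole_is_127(self):
        assert encode_tfs((1,) * 7).whole == 127

    def test_round_trip_and_weights_over_all_patterns(self):
        for flags in itertools.product((0, 1, 2), repeat=7):
            code = encode_tfs(flags)
            assert decode_tfs(code.decimal_string) == flags
            brute = sum(w for w, f in zip(TFS_WEIGHTS, flags) if f)
            assert code.whole == brute

    @pytest.mark.parametrize("bad", ["", "28", "28.00222", "28.0022300",
                                     "27.0022200", "x.0022200"])
    def test_malformed_strings_rejected(self, bad):
        with pytest.raises(ValueError):
            decode_tfs(bad)

    def test_invalid_flags_rejected(self):
        with pytest.raises(ValueError):
            encode_tfs((0, 0, 3, 0, 0, 0, 0))
        with pytest.raises(ValueError):
            encode_tfs((0, 0, 1))


def _probe_row(probe_id, gene, flags, pvals, ratios=None, intensity=100.0):
    row = {"gene_id": gene, "probe_id": probe_id}
    for i, (f, p) in enumerate(zip(flags, pvals), start=1):
        row[f"flag_{i}"] = f
        row[f"p_{i}"] = p
        row[f"ratio_{i}"] = 0.0 if ratios is None else ratios[i - 1]
        row[f"int_{i}"] = intensity
        row[f"wab_{i}"] = True
    code = encode_tfs(flags)
    row["tfs_whole"] = code.whole
    row["tfs_decimal"] = code.decimal_string
    return row


class TestRemoveRedundantProbes:
    def test_lowest_p_probe_survives(self):
        flags = (0, 0, 1, 1, 0, 0, 0)
        df = pd.DataFrame([
            _probe_row("P2", "g", flags, [1, 1, 1e-5, 1e-3, 1, 1, 1]),
            _probe_row("P1", "g", flags, [1, 1, 1e-8, 1e-6, 1, 1, 1]),
        ])
        kept = tfsclass.remove_redundant_probes(df)
        assert list(kept["probe_id"]) == ["P1"]

    def test_different_tfs_groups_both_survive(self):
        df = pd.DataFrame([
            _probe_row("P1", "g", (0, 0, 1, 0, 0, 0, 0), [1, 1, 1e-8, 1, 1, 1, 1]),
            _probe_row("P2", "g", (0, 0, 1, 1, 0, 0, 0), [1, 1, 1e-5, 1e-5, 1, 1, 1]),
        ])
        kept = tfsclass.remove_redundant_probes(df)
        assert sorted(kept["probe_id"]) == ["P1", "P2"]

    def test_single_probe_identity(self):
        df = pd.DataFrame([_probe_row("P1", "g", (0,) * 7, [1] * 7)])
        kept = tfsclass.remove_redundant_probes(df)
        pd.testing.assert_frame_equal(kept, df)

    def test_tie_breaks_to_smallest_probe_id(self):
        flags = (1, 0, 0, 0, 0, 0, 0)
        pv = [1e-6, 1, 1, 1, 1, 1, 1]
        df = pd.DataFrame([_probe_row("PB", "g", flags, pv),
                           _probe_row("PA", "g", flags, pv)])
        kept = tfsclass.remove_redundant_probes(df)
        assert list(kept["probe_id"]) == ["PA"]

    def test_only_flagged_comparisons_count(self):
        flags = (0, 0, 1, 0, 0, 0, 0)
        # P1 wins on the flagged comparison even though P2 has smaller
        # p-values on unflagged ones
        df = pd.DataFrame([
            _probe_row("P1", "g", flags, [1, 1, 1e-9, 1, 1, 1, 1]),
            _probe_row("P2", "g", flags, [1e-30, 1e-30, 1e-5, 1, 1, 1, 1]),
        ])
        kept = tfsclass.remove_redundant_probes(df)
        assert list(kept["probe_id"]) == ["P1"]


class TestClassifyGene:
    def test_male_specific_onset_4wk_dev_up(self):
        cls = classify_gene((0, 1, 1, 1, 0, 0, 0))
        assert cls.sex_class == "male-specific"
        assert cls.onset == "4wk"
        assert cls.dev_male == "up"
        assert cls.dev_female == "none"

    def test_worked_example_female_specific(self):
        cls = classify_gene((0, 0, 2, 2, 2, 0, 0))
        assert cls.sex_class == "female-specific"
        assert cls.onset == "8wk"
        assert cls.dev_male == "down"
        assert cls.dev_female == "none"

    def test_all_zero_is_sex_independent(self):
        cls = classify_gene((0,) * 7)
        assert cls.sex_class == "sex-independent"
        assert cls.onset == "n/a"
        assert cls.transient_bias == "none"

    def test_transient_bias_without_adult_call(self):
        cls = classify_gene((1, 0, 0, 0, 0, 0, 0))
        assert cls.sex_class == "sex-independent"
        assert cls.transient_bias == "M-at-3wk"
        assert cls.onset == "n/a"

    def test_opposite_direction_early_bias_is_transient_not_onset(self):
        cls = classify_gene((2, 0, 1, 0, 0, 0, 0))
        assert cls.sex_class == "male-specific"
        assert cls.onset == "8wk"
        assert cls.transient_bias == "F-at-3wk"

    def test_mixed_dev_directions_reported(self):
        cls = classify_gene((0, 0, 0, 1, 2, 0, 0))
        assert cls.dev_male == "mixed"

    def test_interval_calls(self):
        cls = classify_gene((0, 0, 0, 1, 0, 2, 2))
        assert (cls.dev_male_38, cls.dev_male_48) == ("U", "NC")
        assert (cls.dev_female_38, cls.dev_female_48) == ("D", "D")


class TestStringentSexIndependent:
    @pytest.mark.parametrize("ratio,p,intensity,expected", [
        (1.05, 0.5, 100.0, True),
        (1.05, 0.5, 10.0, False),   # intensity below 25
        (1.3, 0.5, 100.0, False),   # ratio bound
        (1.0 / 1.3, 0.5, 100.0, False),  # ratio bound, other direction
        (1.05, 0.005, 100.0, False),     # p must exceed 0.01
        (1.05, 0.5, 25.0, True),         # intensity boundary inclusive
    ])
    def test_rules(self, ratio, p, intensity, expected):
        assert tfsclass.stringent_sex_independent(ratio, p, intensity) is expected


class TestThresholds:
    def test_defaults_match_study_settings(self):
        th = Thresholds()
        assert (th.fold_cut, th.p_cut) == (1.5, 1e-4)
        assert (th.stringent_fold, th.stringent_p) == (1.2, 0.01)
        assert th.min_intensity == 25.0

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            Thresholds(fold_cut=0.9)
        with pytest.raises(ValueError):
            Thresholds(stringent_fold=2.0)


class TestSummaries:
    def _master(self):
        rows = []
        patterns = [
            ("g1", (0, 1, 1, 1, 0, 0, 0)),
            ("g2", (0, 0, 2, 2, 2, 0, 0)),
            ("g3", (0, 0, 0, 1, 1, 1, 1)),
            ("g4", (0, 0, 0, 0, 0, 0, 0)),
            ("g5", (0, 0, 0, 2, 0, 0, 0)),
        ]
        probes = pd.DataFrame([
            _probe_row(f"P{i}", g, flags, [1e-6 if f else 1 for f in flags])
            for i, (g, flags) in enumerate(patterns)
        ])
        return tfsclass.classify_table(probes)

    def test_partition_and_row_sums(self):
        master = self._master()
        counts = tfsclass.summarize_counts(master)
        total = counts["sex_by_onset"].to_numpy().sum()
        assert total == int(master["regulated"].sum()) == 4

    def test_change_location_counts(self):
        counts = tfsclass.summarize_counts(self._master())
        loc = counts["change_location"]["count"]
        assert loc["male_only"] == 3  # g1 up, g2 down, g5 down in male only
        assert loc["both"] == 1       # g3 changes in both sexes
        assert loc["female_only"] == 0
        assert loc.sum() == 4

    def test_classification_invariant_to_probe_order(self):
        master_fwd = self._master()
        rows = list(range(len(master_fwd)))
        shuffled = master_fwd.iloc[rows[::-1]].reset_index(drop=True)
        counts_a = tfsclass.summarize_counts(master_fwd)
        counts_b = tfsclass.summarize_counts(shuffled)
        pd.testing.assert_frame_equal(counts_a["sex_by_onset"],
                                      counts_b["sex_by_onset"])


class TestCandidateRegulators:
    def _inputs(self):
        probes = pd.DataFrame([
            # strong sex-independent regulator candidate
            _probe_row("P1", "tf1", (0, 0, 0, 1, 0, 0, 0),
                       [1, 1, 1, 1e-6, 1, 1, 1],
                       ratios=[0, 0, 0, 1.5, 0, 0, 0]),
            # descriptor lacks the search terms
            _probe_row("P2", "kin1", (0, 0, 0, 1, 0, 0, 0),
                       [1, 1, 1, 1e-6, 1, 1, 1],
                       ratios=[0, 0, 0, 1.5, 0, 0, 0]),
            # sex-biased but 8-wk sex ratio below 2
            _probe_row("P3", "tf2", (0, 0, 1, 1, 0, 0, 0),
                       [1, 1, 1e-6, 1e-6, 1, 1, 1],
                       ratios=[0, 0, 0.85, 1.5, 0, 0, 0]),
            # significant comparison with fold below 2 fails the filter
            _probe_row("P4", "tf3", (0, 0, 0, 1, 0, 0, 0),
                       [1, 1, 1, 1e-6, 1, 1, 1],
                       ratios=[0, 0, 0, 0.8, 0, 0, 0]),
        ])
        master = tfsclass.classify_table(probes)
        annotations = pd.DataFrame({
            "gene_id": ["tf1", "kin1", "tf2", "tf3"],
            "descriptor": ["sequence-specific DNA binding",
                           "kinase activity",
                           "regulation of transcription",
                           "DNA binding"],
        })
        return probes, master, annotations

    def test_filters(self):
        probes, master, annotations = self._inputs()
        kept = tfsclass.filter_candidate_regulators(probes, master, annotations)
        assert list(kept["gene_id"]) == ["tf1"]

    def test_low_intensity_excluded(self):
        probes, master, annotations = self._inputs()
        probes = probes.copy()
        probes.loc[probes["gene_id"] == "tf1", "int_3"] = 10.0
        kept = tfsclass.filter_candidate_regulators(probes, master, annotations)
        assert kept.empty
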