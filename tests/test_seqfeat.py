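"""Sequence feature extraction and the cohort feature matrix."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chrombind import seqfeat as sf

sequences = st.text(alphabet=sf.AA_ALPHABET, min_size=1, max_size=120)


class TestComposition:
    def test_all_positive_sequence(self):
        assert sf.composition_features("RRKK")["frac_positively_charged"] == 1.0

    def test_glycine_not_polar(self):
        assert sf.composition_features("GGGG")["frac_polar"] == 0.0

    def test_full_alphabet_fractions_match_table(self):
        feats = sf.composition_features(sf.AA_ALPHABET)
        for name, members in sf.DEFAULT_CATEGORY_MAP.items():
            assert feats[f"frac_{name}"] == pytest.approx(len(members) / 20)

    def test_unknown_residue_named_in_error(self):
        with pytest.raises(ValueError, match="X"):
            sf.composition_features("AAXA")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            sf.composition_features("")


class TestGravy:
    def test_single_isoleucine(self):
        assert sf.gravy_sum("I") == pytest.approx(4.5)

    def test_two_residue_sum(self):
        assert sf.gravy_sum("IL") == pytest.approx(8.3)

    @given(seq=sequences)
    @settings(max_examples=30, deadline=None)
    def test_reverse_invariance(self, seq):
        assert sf.gravy_sum(seq) == pytest.approx(sf.gravy_sum(seq[::-1]))


class TestChargeRuns:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("RKRK", (4, 0, 0)),  # one positive run of length 4
            ("RARA", (0, 0, 0)),  # alternation: no run >= 2
            ("DDEE", (0, 0, 4)),
            ("RRAADD", (2, 2, 2)),
        ],
    )
    def test_residues_in_runs(self, seq, expected):
        assert sf.charge_run_counts(seq) == expected

    def test_alternative_conventions(self):
        assert sf.charge_run_counts("RRKKAARR", mode="runs") == (2, 1, 0)
        assert sf.charge_run_counts("RRKKAARR", mode="longest") == (4, 2, 0)


class TestDBDNetCharge:
    def test_mixed_charges(self):
        assert sf.dbd_net_charge("KKRDE", [(0, 5, "fam")]) == 1

    def test_no_charged_residues(self):
        assert sf.dbd_net_charge("AAAA", [(0, 4, "fam")]) == 0

    def test_union_over_two_dbds(self):
        seq = "KKAADD"
        assert sf.dbd_net_charge(seq, [(0, 2, "a"), (4, 6, "b")]) == 0

    def test_overlapping_intervals_counted_once(self):
        assert sf.dbd_net_charge("KKKK", [(0, 3, "a"), (1, 4, "b")]) == 4

    def test_empty_interval_list_rejected(self):
        with pytest.raises(ValueError):
            sf.dbd_net_charge("KK", [])


class TestDispersion:
    def test_no_positive_residues(self):
        assert sf.positive_charge_dispersion("AAAAAAA") == 0.0

    def test_uniform_positive(self):
        assert sf.positive_charge_dispersion("RKRKRKRKRK") == 0.0

    def test_clustered_positive(self):
        # window sums (5,4,3,2,1,0): mean 2.5, population variance 35/12
        assert sf.positive_charge_dispersion("RRRRRAAAAA") == pytest.approx(7 / 6)

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            sf.positive_charge_dispersion("RKR")


class TestDisorder:
    def test_run_longer_than_five_counts(self):
        mask = [1] * 6 + [0] * 6
        assert sf.disorder_features(mask) == (6, 0.5)

    def test_run_of_exactly_five_ignored(self):
        assert sf.disorder_features([1] * 5 + [0] * 5) == (0, 0.0)

    def test_fully_disordered(self):
        assert sf.disorder_features([1] * 10) == (10, 1.0)


class TestFeatureOracle:
    """Each feature matches a naive re-implementation on random sequences."""

    @pytest.mark.parametrize("seed", range(10))
    def test_against_naive_implementations(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list(sf.AA_ALPHABET), size=rng.integers(10, 200)))

        frac_pos = sum(c in "RKH" for c in seq) / len(seq)
        assert sf.composition_features(seq)["frac_positively_charged"] == pytest.approx(frac_pos)

        assert sf.gravy_sum(seq) == pytest.approx(
            sum(sf.KYTE_DOOLITTLE[c] for c in seq)
        )

        # runs via regex-free scan
        def naive_runs(seq, members):
            total, run = 0, 0
            for c in seq + "$":
                if c in members:
                    run += 1
                else:
                    if run >= 2:
                        total += run
                    run = 0
            return total

        pos, neu, neg = sf.charge_run_counts(seq)
        assert pos == naive_runs(seq, "RK")
        assert neg == naive_runs(seq, "DE")
        assert neu == naive_runs(seq, set(sf.AA_ALPHABET) - set("RKDE"))

        if len(seq) >= 5:
            w = [sum(c in "RK" for c in seq[i : i + 5]) for i in range(len(seq) - 4)]
            w = np.array(w, dtype=float)
            expect = 0.0 if w.mean() == 0 else w.var() / w.mean()
            assert sf.positive_charge_dispersion(seq) == pytest.approx(expect)


class TestFeatureMatrix:
    def _records(self, n=30, seed=0, with_masks=True):
        rng = np.random.default_rng(seed)
        records = []
        for i in range(n):
            length = int(rng.integers(30, 80))
            seq = "".join(rng.choice(list(sf.AA_ALPHABET), size=length))
            fam = "common" if i < 20 else "rare"
            records.append(
                sf.ProteinRecord(
                    tf_id=f"t{i}",
                    sequence=seq,
                    dbd_intervals=[(0, 10, fam)],
                    disorder_mask=(rng.random(length) < 0.3) if with_masks else None,
                )
            )
        return records

    def test_rare_family_gets_no_column(self):
        matrix = sf.build_feature_matrix(self._records(), family_min_count=10)
        assert "dbd_family_common" in matrix.feature_names
        assert "dbd_family_rare" not in matrix.feature_names

    def test_normalized_columns_span_unit_interval(self):
        matrix = sf.build_feature_matrix(self._records())
        for col in sf.NORMALIZED_COLUMNS:
            assert matrix.values[col].min() == pytest.approx(0.0)
            assert matrix.values[col].max() == pytest.approx(1.0)

    def test_missing_disorder_mask_drops_record(self):
        records = self._records()
        records[3].disorder_mask = None
        matrix = sf.build_feature_matrix(records)
        assert len(matrix.tf_ids) == len(records) - 1
        assert "t3" not in matrix.tf_ids

    def test_record_order_invariance(self):
        records = self._records()
        m1 = sf.build_feature_matrix(records)
        m2 = sf.build_feature_matrix(records[::-1])
        assert m1.values.sort_index().equals(m2.values.sort_index())

    def test_no_missing_values(self):
        matrix = sf.build_feature_matrix(self._records())
        assert not matrix.values.isna().any().any()
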