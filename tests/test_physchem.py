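"""GRAVY and Henderson–Hasselbalch net-charge calculators."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from tapredict import (
    DEFAULT_PKA,
    PkaTable,
    compute_features,
    gravy,
    net_charge,
    round_half_away,
)
from tapredict.segmentation import Segmentation

AA = "ARNDCQEGHILKMFPSTWYV"
peptides = st.text(alphabet=AA, min_size=1, max_size=40)


def brute_force_charge(seq, pH, free_nterm=True, free_cterm=True, pka=DEFAULT_PKA):
    """Independent per-group summation (counts groups, then sums)."""
    total = 0.0
    groups = []
    if free_nterm:
        groups.append(("basic", pka.n_terminus))
    if free_cterm:
        groups.append(("acidic", pka.c_terminus))
    for kind, table in (("basic", pka.basic), ("acidic", pka.acidic)):
        for residue, pk in table.items():
            groups.extend([(kind, pk)] * seq.count(residue))
    for kind, pk in groups:
        if kind == "basic":
            total += 1.0 / (1.0 + 10.0 ** (pH - pk))
        else:
            total -= 1.0 / (1.0 + 10.0 ** (pk - pH))
    return total


class TestGravy:
    def test_single_residue_is_scale_value(self):
        assert gravy("I") == pytest.approx(4.5)

    def test_full_alphabet_mean(self):
        assert gravy(AA) == pytest.approx(-0.49)

    def test_constant_sequence(self):
        assert gravy("LLLLL") == pytest.approx(3.8)

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            gravy("")

    @given(s1=st.text(alphabet=AA, min_size=1, max_size=20), data=st.data())
    @settings(max_examples=100, deadline=None)
    def test_concatenation_of_equal_halves_averages(self, s1, data):
        s2 = data.draw(st.text(alphabet=AA, min_size=len(s1), max_size=len(s1)))
        assert gravy(s1 + s2) == pytest.approx((gravy(s1) + gravy(s2)) / 2)


class TestNetCharge:
    @pytest.mark.parametrize(
        "tail, expected",
        [("QRRRRKLN", 4.9), ("QRARAKLN", 2.9), ("QAAAAKLN", 0.9)],
        ids=["WT", "MUT1", "MUT2"],
    )
    def test_acbd5_tail_series_at_1dp(self, tail, expected):
        """The Arg→Ala mutant series of the ACBD5 tail at pH 7."""
        assert round_half_away(net_charge(tail, 7.0), 1) == pytest.approx(expected)

    def test_no_ionizable_groups_gives_zero(self):
        assert net_charge("AAAA", 7.0, free_nterm=False, free_cterm=False) == 0.0

    def test_ph_bounds(self):
        with pytest.raises(ValueError):
            net_charge("AAAA", 0.0)
        with pytest.raises(ValueError):
            net_charge("AAAA", 14.5)

    @given(seq=peptides, data=st.data())
    @settings(max_examples=100, deadline=None)
    def test_monotone_non_increasing_in_ph(self, seq, data):
        ph1 = data.draw(st.floats(min_value=0.5, max_value=13.0))
        ph2 = data.draw(st.floats(min_value=ph1, max_value=13.5))
        assert net_charge(seq, ph2) <= net_charge(seq, ph1) + 1e-12

    @given(seq=peptides)
    @settings(max_examples=60, deadline=None)
    def test_appending_arg_adds_one_unit(self, seq):
        delta = net_charge(seq + "R", 7.0) - net_charge(seq, 7.0)
        assert delta == pytest.approx(1.0 / (1.0 + 10.0 ** (7.0 - 12.0)), abs=1e-3)

    @given(seq=peptides)
    @settings(max_examples=60, deadline=None)
    def test_acid_limit_all_bases_protonated(self, seq):
        basic_count = sum(seq.count(r) for r in "RKH") + 1  # + free N-terminus
        assert net_charge(seq, 0.5) == pytest.approx(basic_count, abs=0.02)

    @given(seq=st.text(alphabet=AA.replace("R", ""), min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_base_limit_all_acids_deprotonated(self, seq):
        # Arg (pKa 12) is excluded: no attainable pH is far above it.
        acidic_count = sum(seq.count(r) for r in "DECY") + 1  # + free C-terminus
        assert net_charge(seq, 13.5) == pytest.approx(-acidic_count, abs=0.02)

    @given(seq=peptides, ph=st.floats(min_value=1.0, max_value=13.0))
    @settings(max_examples=100, deadline=None)
    def test_matches_per_group_oracle(self, seq, ph):
        assert net_charge(seq, ph) == pytest.approx(
            brute_force_charge(seq, ph), abs=1e-9
        )


class TestPkaTable:
    def test_custom_table_from_file(self, tmp_path):
        p = tmp_path / "pka.cfg"
        p.write_text("# custom\nR=12.5\nc_terminus=3.6\n")
        table = PkaTable.from_file(p)
        assert table.basic["R"] == 12.5
        assert table.c_terminus == 3.6
        assert table.basic["K"] == DEFAULT_PKA.basic["K"]

    def test_invalid_pka_rejected(self):
        with pytest.raises(ValueError):
            PkaTable(n_terminus=-1.0)


class TestRounding:
    @pytest.mark.parametrize(
        "value, expected", [(0.25, 0.3), (-0.25, -0.3), (4.85, 4.9), (1.04, 1.0)]
    )
    def test_half_away_from_zero(self, value, expected):
        assert round_half_away(value, 1) == pytest.approx(expected)


class TestComputeFeatures:
    def test_composition_of_gravy_and_charge(self):
        seg = Segmentation(
            context_seq="S" * 20,
            upstream_seq="S" * 10,
            tmd_seq="L" * 21,
            tail_seq="QRRRRKLN",
        )
        fv = compute_features(seg)
        assert fv.tmd_gravy == pytest.approx(3.8)
        assert round_half_away(fv.tail_charge, 1) == pytest.approx(4.9)
        assert fv.tail_length == 8
        assert fv.upstream_gravy == pytest.approx(-0.8)

    def test_empty_tail_contributes_zero(self):
        seg = Segmentation("", "SS", "L" * 21, "")
        fv = compute_features(seg)
        assert fv.tail_charge == 0.0 and fv.tail_length == 0

    def test_empty_tmd_rejected(self):
        with pytest.raises(ValueError, match="TMD"):
            compute_features(Segmentation("", "SS", "", "QRN"))
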