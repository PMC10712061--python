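"""The nine encoding schemes against per-definition oracles."""

import numpy as np
import pandas as pd
import pytest

from methylcapso import CHANNELS, encode
from methylcapso.encodings import (
    CGR_VERTEX,
    DinucPropertyTable,
    EncodingMatrix,
    PROPERTY_NAMES,
    SPECTRAL_VALUE,
    default_property_table,
    encode_bpf,
    encode_cgr,
    encode_dataset,
    encode_dpcp,
    encode_ncp,
    encode_spectral,
    encode_z,
    normalize_properties,
    zcurve_components,
)


class TestSpectral:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ACGT", [1, 3, 2, 4]), ("A", [1]), ("GGG", [2, 2, 2])],
    )
    def test_mapping(self, seq, expected):
        assert encode_spectral(seq).values.tolist() == [expected]

    def test_column_recovers_base(self):
        inverse = {v: b for b, v in SPECTRAL_VALUE.items()}
        for base in "ACGT":
            assert inverse[encode_spectral(base).values[0, 0]] == base


class TestCgr:
    def test_first_point_is_midpoint_to_vertex(self):
        for base, (vx, vy) in CGR_VERTEX.items():
            m = encode_cgr(base).values
            assert np.allclose(m[:, 0], [vx / 2, vy / 2])

    def test_two_step_example(self):
        m = encode_cgr("AT").values
        assert np.allclose(m[:, 0], [0.5, 0.5])
        assert np.allclose(m[:, 1], [-0.25, -0.25])

    def test_homopolymer_distance_halves(self):
        # for TTTTT the distance to the T vertex is sqrt(2) * 2^{-i}
        m = encode_cgr("TTTTT").values
        for i in range(5):
            d = np.hypot(m[0, i] + 1, m[1, i] + 1)
            assert np.isclose(d, np.sqrt(2) * 2.0 ** -(i + 1))

    def test_matches_per_definition_oracle(self, random_sequences):
        for seq in random_sequences:
            point, oracle = (0.0, 0.0), []
            for s in seq:
                v = CGR_VERTEX[s]
                point = (point[0] - (point[0] - v[0]) / 2, point[1] - (point[1] - v[1]) / 2)
                oracle.append(point)
            assert np.array_equal(encode_cgr(seq).values, np.array(oracle).T)

    def test_points_strictly_inside_square(self, random_sequences):
        for seq in random_sequences:
            m = encode_cgr(seq).values
            assert (np.abs(m) < 1).all()

    def test_invertible(self, random_sequences):
        # g_i = 2 CGR_i - CGR_{i-1} recovers the vertex of base i; the vertex
        # coordinates are +-1 so the quadrant signs identify the base exactly
        vertex_to_base = {v: b for b, v in CGR_VERTEX.items()}
        for seq in random_sequences:
            m = encode_cgr(seq).values
            prev = np.zeros(2)
            for i, s in enumerate(seq):
                g = 2 * m[:, i] - prev
                assert np.allclose(g, CGR_VERTEX[s], atol=1e-9)
                assert vertex_to_base[tuple(np.sign(g))] == s
                prev = m[:, i]


class TestZcurve:
    @pytest.mark.parametrize(
        "seq,expected",
        [("A", [np.sqrt(3)]), ("T", [-1.0])],
    )
    def test_signed_root_examples(self, seq, expected):
        assert np.allclose(encode_z(seq).values[0], expected)

    def test_ac_prefix(self):
        # A=1, C=1 at position 2: X=0, Y=2, Z=0 -> sqrt(2)
        assert np.isclose(encode_z("AC").values[0, 1], np.sqrt(2))

    def test_component_identity_on_random_sequences(self, random_sequences):
        # X_i + Y_i + Z_i = 4 A_i - i on every prefix, by direct counting
        for seq in random_sequences:
            comps = zcurve_components(seq)
            for i in range(1, len(seq) + 1):
                a = seq[:i].count("A")
                assert comps[:, i - 1].sum() == 4 * a - i

    def test_matches_per_definition_oracle(self, random_sequences):
        for seq in random_sequences:
            oracle = []
            for i in range(1, len(seq) + 1):
                prefix = seq[:i]
                a, c = prefix.count("A"), prefix.count("C")
                g, t = prefix.count("G"), prefix.count("T")
                s = ((a + g) - (c + t)) + ((a + c) - (g + t)) + ((a + t) - (c + g))
                oracle.append(np.sign(s) * np.sqrt(abs(s)))
            assert np.array_equal(encode_z(seq).values[0], np.array(oracle))


class TestBpf:
    def test_row_order_a_t_g_c(self):
        assert np.array_equal(encode_bpf("ATGC").values, np.eye(4))

    def test_columns_sum_to_one(self, random_sequences):
        for seq in random_sequences[:20]:
            assert (encode_bpf(seq).values.sum(axis=0) == 1).all()

    def test_column_recovers_base(self):
        rows = "ATGC"
        for base in "ACGT":
            col = encode_bpf(base).values[:, 0]
            assert rows[int(np.argmax(col))] == base


class TestNcp:
    @pytest.mark.parametrize(
        "base,expected",
        [("A", (1, 1, 1)), ("C", (0, 0, 1)), ("G", (1, 0, 0)), ("T", (0, 1, 0))],
    )
    def test_truth_table(self, base, expected):
        assert tuple(encode_ncp(base).values[:, 0]) == expected

    def test_column_recovers_base(self):
        # the four truth-table columns are distinct, hence invertible
        columns = {tuple(encode_ncp(b).values[:, 0]): b for b in "ACGT"}
        assert len(columns) == 4


class TestProperties:
    def test_min_max_scaling(self):
        raw = pd.DataFrame({"p": [1.0, 2.0, 3.0]})
        assert normalize_properties(raw)["p"].tolist() == [0.0, 0.5, 1.0]

    def test_constant_column_maps_to_half(self):
        raw = pd.DataFrame({"p": [5.0] * 16})
        assert (normalize_properties(raw)["p"] == 0.5).all()

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            normalize_properties(pd.DataFrame({"p": [1.0, np.nan]}))

    def test_packaged_table_normalized_range(self):
        table = default_property_table()
        norm = table.normalized.to_numpy()
        assert norm.shape == (16, 6)
        assert norm.min() >= 0 and norm.max() <= 1
        assert np.allclose(norm.min(axis=0), 0) and np.allclose(norm.max(axis=0), 1)


def _toy_table():
    raw = pd.DataFrame(
        0.0, index=[a + b for a in "ACGT" for b in "ACGT"], columns=PROPERTY_NAMES
    )
    # construct raw values whose normalized twist is 0.2 for AC and 0.6 for CG
    raw.loc["AA", "twist"] = 0.0
    raw.loc["TT", "twist"] = 10.0
    raw.loc["AC", "twist"] = 2.0
    raw.loc["CG", "twist"] = 6.0
    return DinucPropertyTable.from_raw(raw)


class TestDpcp:
    def test_homopolymer_columns_constant(self):
        m = encode_dpcp("AAAA").values
        assert np.allclose(m, m[:, :1])
        aa = default_property_table().normalized.loc["AA"].to_numpy()
        assert np.allclose(m[:, 0], aa)

    def test_interior_is_mean_of_flanking_dinucleotides(self):
        table = _toy_table()
        m = encode_dpcp("ACG", table).values
        assert np.isclose(m[0, 1], (0.2 + 0.6) / 2)  # twist row, middle position

    def test_boundary_columns_use_single_dinucleotide(self):
        table = _toy_table()
        m = encode_dpcp("ACG", table).values
        assert np.allclose(m[:, 0], table.normalized.loc["AC"].to_numpy())
        assert np.allclose(m[:, 2], table.normalized.loc["CG"].to_numpy())

    def test_entries_in_unit_interval(self, random_sequences):
        for seq in random_sequences[:30]:
            m = encode_dpcp(seq).values
            assert (m >= 0).all() and (m <= 1).all()

    def test_length_one_rejected(self):
        with pytest.raises(ValueError):
            encode_dpcp("A")


class TestFusionAndDispatch:
    @pytest.mark.parametrize("scheme,channels", sorted(CHANNELS.items()))
    def test_channel_counts(self, scheme, channels):
        m = encode("ACGTACGTACGT", scheme)
        assert m.values.shape == (channels, 12)
        assert len(m.channel_labels) == channels

    def test_code9_stacks_code4_then_code8(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTA"  # length 41
        m9 = encode(seq, "code9")
        assert m9.values.shape == (17, 41)
        assert np.array_equal(m9.values[:4], encode(seq, "code4").values)
        assert np.array_equal(m9.values[4:], encode(seq, "code8").values)

    def test_unknown_scheme(self):
        with pytest.raises(ValueError):
            encode("ACGT", "code10")

    def test_deterministic(self):
        a = encode("ACGTTGCA", "code9").values
        b = encode("ACGTTGCA", "code9").values
        assert np.array_equal(a, b)

    def test_encode_dataset_stacks_and_checks_lengths(self, small_dataset):
        X = encode_dataset(small_dataset[:5], "code4")
        assert X.shape == (5, 4, 21)
        mixed = small_dataset[:2] + [small_dataset[0].__class__("x", "ACGT", 0)]
        with pytest.raises(ValueError):
            encode_dataset(mixed, "code4")

    def test_matrix_shape_validated(self):
        with pytest.raises(ValueError):
            EncodingMatrix("code1", np.zeros((2, 5)), ("a", "b"))


class TestEncodingProperties:
    """Alphabet-wide invariants over arbitrary sequences."""

    from hypothesis import given, settings, strategies as st

    dna = st.text(alphabet="ACGT", min_size=2, max_size=64)

    @given(seq=dna)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_invariants_hold_for_any_sequence(self, seq):
        cgr = encode_cgr(seq).values
        assert (np.abs(cgr) < 1).all()
        bpf = encode_bpf(seq).values
        assert (bpf.sum(axis=0) == 1).all()
        comps = zcurve_components(seq)
        a = np.cumsum([s == "A" for s in seq])
        assert np.array_equal(comps.sum(axis=0), 4 * a - np.arange(1, len(seq) + 1))

    @given(seq=dna)
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_fusion_rows_equal_parts(self, seq):
        m9 = encode(seq, "code9").values
        assert np.array_equal(m9[:4], encode(seq, "code4").values)
        assert np.array_equal(m9[4:], encode(seq, "code8").values)
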