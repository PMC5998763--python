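import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    pearson_abs,
    quantile_linear,
    rwr_linear_solve,
    smith_waterman_affine,
    tanimoto_sets,
)

from metmatch.data_io import (
    AssociationNetwork,
    Compound,
    DataError,
    NodeKind,
    ProteinRecord,
    Role,
)
from metmatch.similarity_features import (
    AlignmentScoreConfig,
    ConvergenceError,
    FeatureConfig,
    Fingerprint,
    NetworkPropagator,
    PhenotypeProfile,
    build_feature_matrix,
    compute_fingerprint,
    normalized_sw,
    phenotype_similarity,
    read_feature_matrix,
    rwr,
    tanimoto,
    target_pair_scores,
    target_similarity,
    top_fraction_threshold,
    write_feature_matrix,
)


def _compound(smiles, cid="c", targets=()):
    return Compound(id=cid, role=Role.DRUG, smiles=smiles, targets=frozenset(targets))


class TestFingerprint:
    def test_deterministic(self):
        a = compute_fingerprint(_compound("c1ccccc1CCO"))
        b = compute_fingerprint(_compound("c1ccccc1CCO"))
        assert a == b

    def test_canonicalization_invariant(self):
        # same molecule spelled two ways
        assert compute_fingerprint(_compound("CCO")) == compute_fingerprint(
            _compound("OCC")
        )

    def test_single_atom(self):
        fp = compute_fingerprint(_compound("C"))
        assert fp is not None and fp.n_set >= 0

    def test_missing_structure_gives_none(self):
        assert compute_fingerprint(_compound(None)) is None

    def test_length_configurable(self):
        fp = compute_fingerprint(_compound("CCO"), length=512)
        assert fp.length == 512 and max(fp.bits, default=0) < 512


class TestTanimoto:
    def test_identical_nonzero(self):
        fp = Fingerprint(bits=(1, 5, 9), length=16)
        assert tanimoto(fp, fp) == 1.0

    def test_disjoint(self):
        a = Fingerprint(bits=(0, 1), length=8)
        b = Fingerprint(bits=(2, 3), length=8)
        assert tanimoto(a, b) == 0.0

    def test_half_overlap(self):
        a = Fingerprint(bits=(1, 2, 3), length=8)
        b = Fingerprint(bits=(2, 3, 4), length=8)
        assert tanimoto(a, b) == 0.5

    def test_both_empty_is_zero(self):
        z = Fingerprint(bits=(), length=8)
        assert tanimoto(z, z) == 0.0

    def test_length_mismatch_fatal(self):
        with pytest.raises(DataError):
            tanimoto(Fingerprint((), 8), Fingerprint((), 16))

    @given(
        st.sets(st.integers(0, 63)),
        st.sets(st.integers(0, 63)),
    )
    def test_matches_set_oracle_and_symmetric(self, sa, sb):
        a = Fingerprint(bits=tuple(sorted(sa)), length=64)
        b = Fingerprint(bits=tuple(sorted(sb)), length=64)
        assert tanimoto(a, b) == tanimoto_sets(sa, sb)
        assert tanimoto(a, b) == tanimoto(b, a)
        assert 0.0 <= tanimoto(a, b) <= 1.0

    @given(
        st.sets(st.integers(0, 63)),
        st.sets(st.integers(0, 63)),
        st.integers(0, 63),
    )
    def test_shared_bit_never_decreases(self, sa, sb, extra):
        before = tanimoto(
            Fingerprint(tuple(sorted(sa)), 64), Fingerprint(tuple(sorted(sb)), 64)
        )
        after = tanimoto(
            Fingerprint(tuple(sorted(sa | {extra})), 64),
            Fingerprint(tuple(sorted(sb | {extra})), 64),
        )
        assert after >= before or math.isclose(after, before)


class TestNormalizedSW:
    def test_self_is_exactly_one(self):
        rec = ProteinRecord("g", "MKTAYIAKQRQISFVK")
        assert normalized_sw(rec, rec) == 1.0

    def test_identical_sequences_any_penalties(self):
        a = ProteinRecord("a", "ACDE")
        b = ProteinRecord("b", "ACDE")
        cfg = AlignmentScoreConfig(gap_open=3.0, gap_extend=1.0)
        assert normalized_sw(a, b, cfg) == 1.0

    def test_known_pair_matches_dp_oracle(self):
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        a, b = "HEAGAWGHEE", "PAWHEAE"
        sab = smith_waterman_affine(a, b, blosum, 10.0, 0.5)
        saa = smith_waterman_affine(a, a, blosum, 10.0, 0.5)
        sbb = smith_waterman_affine(b, b, blosum, 10.0, 0.5)
        expected = sab / math.sqrt(saa * sbb)
        got = normalized_sw(ProteinRecord("a", a), ProteinRecord("b", b))
        assert got == pytest.approx(expected, abs=1e-12)
        # frozen from the oracle: 18 / sqrt(62 * 44)
        assert got == pytest.approx(0.3446278114803676, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_pairs_match_oracle_and_symmetry(self, seed):
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        rng = np.random.default_rng(seed)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        s1 = "".join(aa[i] for i in rng.integers(0, 20, size=30))
        s2 = "".join(aa[i] for i in rng.integers(0, 20, size=25))
        ra, rb = ProteinRecord("a", s1), ProteinRecord("b", s2)
        sab = smith_waterman_affine(s1, s2, blosum, 10.0, 0.5)
        saa = smith_waterman_affine(s1, s1, blosum, 10.0, 0.5)
        sbb = smith_waterman_affine(s2, s2, blosum, 10.0, 0.5)
        assert normalized_sw(ra, rb) == pytest.approx(
            sab / math.sqrt(saa * sbb), abs=1e-12
        )
        assert normalized_sw(ra, rb) == normalized_sw(rb, ra)

    def test_gap_penalties_validated(self):
        with pytest.raises(DataError):
            AlignmentScoreConfig(gap_open=0.0)


class TestTargetPairScores:
    def test_same_single_target(self, small_proteome):
        a = _compound("C", "a", {"G1"})
        b = _compound("C", "b", {"G1"})
        assert target_pair_scores(a, b, small_proteome) == [1.0]

    def test_product_count(self, small_proteome):
        a = _compound("C", "a", {"G1", "G2"})
        b = _compound("C", "b", {"G1", "G2", "G3"})
        assert len(target_pair_scores(a, b, small_proteome)) == 6

    def test_no_targets_missing(self, small_proteome):
        a = _compound("C", "a", {"G1"})
        b = _compound("C", "b", set())
        assert target_pair_scores(a, b, small_proteome) is None

    def test_unknown_target_skipped(self, small_proteome, caplog):
        a = _compound("C", "a", {"G1", "G_unknown"})
        b = _compound("C", "b", {"G1"})
        with caplog.at_level("WARNING"):
            scores = target_pair_scores(a, b, small_proteome)
        assert scores == [1.0]
        assert "without sequence" in caplog.text


class TestThresholdAndTargetSimilarity:
    def test_outlier_distribution(self):
        # 0.95 quantile of 21 values lands exactly on the 19th order
        # statistic under linear interpolation, i.e. the bulk value
        scores = [0.1] * 20 + [0.9]
        thr = top_fraction_threshold(scores, 0.05)
        assert 0.1 <= thr <= 0.9
        assert thr == pytest.approx(quantile_linear(scores, 0.95), abs=1e-12)

    def test_constant_distribution(self):
        assert top_fraction_threshold([0.3] * 10) == 0.3

    def test_quantile_oracle(self):
        scores = [i / 100 for i in range(1, 101)]
        assert top_fraction_threshold(scores, 0.05) == pytest.approx(
            quantile_linear(scores, 0.95), abs=1e-12
        )

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_quantile_oracle_property(self, scores):
        assert top_fraction_threshold(scores, 0.05) == pytest.approx(
            quantile_linear(scores, 0.95), abs=1e-9
        )

    def test_empty_fatal(self):
        with pytest.raises(DataError):
            top_fraction_threshold([])

    def test_mean_of_survivors(self):
        assert target_similarity([0.95, 0.99], 0.9) == pytest.approx(0.97)

    def test_none_survive_is_zero(self):
        assert target_similarity([0.1, 0.2], 0.9) == 0.0

    def test_boundary_inclusive(self):
        assert target_similarity([0.9], 0.9) == pytest.approx(0.9)

    def test_missing_propagates(self):
        assert target_similarity(None, 0.5) is None


class TestRWR:
    def test_isolated_seed_fixed_point(self):
        net = AssociationNetwork(nodes={"A": NodeKind.GENE}, edges=[])
        nodes, p = rwr(net, {"A"})
        assert nodes == ["A"]
        assert p[0] == pytest.approx(1.0, abs=1e-9)

    def test_two_node_closed_form(self):
        net = AssociationNetwork(
            nodes={"a": NodeKind.GENE, "b": NodeKind.GENE},
            edges=[("a", "b", 1.0), ("b", "a", 1.0)],
        )
        nodes, p = rwr(net, {"a"}, restart=0.7, tol=1e-10)
        # closed form p = r (I - (1-r) M^T)^-1 p0
        assert p[nodes.index("a")] == pytest.approx(0.7 / 0.91, abs=1e-6)
        assert p[nodes.index("b")] == pytest.approx(0.21 / 0.91, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_linear_solve_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 5
        adj = (rng.random((n, n)) < 0.5).astype(float) * rng.random((n, n))
        np.fill_diagonal(adj, 0.0)
        names = [f"N{i}" for i in range(n)]
        nodes = {name: NodeKind.GENE for name in names}
        edges = [
            (names[i], names[j], adj[i, j])
            for i in range(n)
            for j in range(n)
            if adj[i, j] > 0
        ]
        net = AssociationNetwork(nodes=nodes, edges=edges)
        seeds = [0, 2]
        _, p = rwr(net, {names[i] for i in seeds}, restart=0.7, tol=1e-8)
        expected = rwr_linear_solve(adj, seeds, 0.7)
        assert np.max(np.abs(p - expected)) < 1e-4

    def test_conserves_probability(self, small_network):
        _, p = rwr(small_network, {"G1", "G3"})
        assert p.sum() == pytest.approx(1.0, abs=1e-4)
        assert np.all(p >= 0)

    def test_no_seed_fatal(self, small_network):
        with pytest.raises(DataError, match="seed"):
            rwr(small_network, {"nope"})

    def test_nonconvergence_fatal(self, small_network):
        with pytest.raises(ConvergenceError, match="residual"):
            rwr(small_network, {"G1"}, tol=1e-12, max_iter=2)


class TestPhenotypeProfile:
    def test_disconnected_target_gives_zero_profile(self, small_network):
        # G3 only reaches P3; profile entries for P1, P2 must be 0
        prop = NetworkPropagator(small_network)
        c = _compound("C", "c", {"G3"})
        profile = prop.phenotype_profile(c)
        idx = {p: i for i, p in enumerate(prop.phenotype_ids)}
        assert profile.scores[idx["P1"]] == 0.0
        assert profile.scores[idx["P2"]] == 0.0
        assert profile.scores[idx["P3"]] > 0.0

    def test_identical_targets_identical_profiles(self, small_network):
        prop = NetworkPropagator(small_network)
        p1 = prop.phenotype_profile(_compound("C", "x", {"G1", "G2"}))
        p2 = prop.phenotype_profile(_compound("CC", "y", {"G2", "G1"}))
        assert np.array_equal(p1.scores, p2.scores)

    def test_profile_matches_linear_oracle(self, small_network):
        prop = NetworkPropagator(small_network)
        profile = prop.phenotype_profile(_compound("C", "c", {"G1", "G2"}), tol=1e-9)
        order = sorted(small_network.nodes)
        n = len(order)
        adj = np.zeros((n, n))
        for s, t, w in small_network.edges:
            adj[order.index(s), order.index(t)] = w
        full = rwr_linear_solve(adj, [order.index("G1"), order.index("G2")], 0.7)
        expected = [full[order.index(p)] for p in prop.phenotype_ids]
        assert np.max(np.abs(profile.scores - expected)) < 1e-4

    def test_no_target_in_network_missing(self, small_network):
        prop = NetworkPropagator(small_network)
        assert prop.phenotype_profile(_compound("C", "c", {"Z9"})) is None


class TestPhenotypeSimilarity:
    def test_identical_profiles(self):
        a = PhenotypeProfile("a", np.array([0.1, 0.2, 0.7]))
        assert phenotype_similarity(a, a) == pytest.approx(1.0)

    def test_sign_symmetry(self):
        a = PhenotypeProfile("a", np.array([0.1, 0.2, 0.7]))
        b = PhenotypeProfile("b", np.array([0.9, 0.8, 0.3]))  # -a + 1
        assert phenotype_similarity(a, b) == pytest.approx(1.0)

    def test_matches_covariance_oracle(self):
        a = PhenotypeProfile("a", np.array([0.1, 0.2, 0.7]))
        b = PhenotypeProfile("b", np.array([0.7, 0.2, 0.1]))
        assert phenotype_similarity(a, b) == pytest.approx(
            pearson_abs(a.scores, b.scores), abs=1e-12
        )

    def test_constant_profile_is_zero(self, caplog):
        a = PhenotypeProfile("a", np.array([0.5, 0.5, 0.5]))
        b = PhenotypeProfile("b", np.array([0.1, 0.2, 0.7]))
        with caplog.at_level("WARNING"):
            assert phenotype_similarity(a, b) == 0.0

    def test_length_mismatch_fatal(self):
        a = PhenotypeProfile("a", np.array([0.1, 0.9]))
        b = PhenotypeProfile("b", np.array([0.1, 0.2, 0.7]))
        with pytest.raises(DataError):
            phenotype_similarity(a, b)


class TestBuildFeatureMatrix:
    @pytest.fixture
    def inputs(self, small_network, small_proteome):
        mets = [
            _compound("CCO", "m1", {"G1"}),
            _compound("CCN", "m2", {"G2"}),
            _compound("CCC", "m3", {"G3"}),
        ]
        partners = [
            _compound("CCO", "p1", {"G1"}),
            _compound(None, "p2", {"G2"}),
        ]
        return mets, partners, small_proteome, small_network

    def test_row_count(self, inputs):
        df = build_feature_matrix(*inputs)
        assert len(df) == 6

    def test_missing_smiles_missing_structure_only(self, inputs):
        df = build_feature_matrix(*inputs)
        row = df[(df.partner_id == "p2") & (df.metabolite_id == "m1")].iloc[0]
        assert np.isnan(row.s_structure)
        assert np.isfinite(row.s_target)
        assert np.isfinite(row.s_phenotype)

    def test_deterministic(self, inputs):
        a = build_feature_matrix(*inputs)
        b = build_feature_matrix(*inputs)
        assert a.equals(b)

    def test_values_in_unit_interval(self, inputs):
        df = build_feature_matrix(*inputs)
        vals = df[["s_structure", "s_target", "s_phenotype"]].to_numpy()
        finite = vals[np.isfinite(vals)]
        assert np.all((finite >= 0) & (finite <= 1))

    def test_empty_inputs(self, small_proteome, small_network):
        df = build_feature_matrix([], [], small_proteome, small_network, FeatureConfig())
        assert df.empty

    def test_tsv_round_trip(self, inputs, tmp_path):
        df = build_feature_matrix(*inputs)
        write_feature_matrix(df, tmp_path / "f.tsv")
        back = read_feature_matrix(tmp_path / "f.tsv")
        assert back["partner_id"].tolist() == df["partner_id"].tolist()
        np.testing.assert_allclose(
            back[["s_structure", "s_target", "s_phenotype"]].to_numpy(),
            df[["s_structure", "s_target", "s_phenotype"]].to_numpy(),
            atol=1e-9,
        )
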