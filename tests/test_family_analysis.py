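import numpy as np
import pytest

from glycomap import family_analysis as fa
from glycomap.family_analysis import SequenceRecord
from glycomap.synthetic_data import FamilySpec, make_family, make_msa

# --- independent brute-force alignment oracle (Gotoh affine DP) -------------

from Bio.Align import substitution_matrices

_BLOSUM = substitution_matrices.load("BLOSUM62")


def gotoh_global_score(a: str, b: str, open_=-10.0, extend=-0.5) -> float:
    n, m = len(a), len(b)
    neg = -1e18
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b
    Y = np.full((n + 1, m + 1), neg)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = open_ + (i - 1) * extend
    for j in range(1, m + 1):
        Y[0, j] = open_ + (j - 1) * extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _BLOSUM[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + open_, X[i - 1, j] + extend, Y[i - 1, j] + open_)
            Y[i, j] = max(M[i, j - 1] + open_, Y[i, j - 1] + extend, X[i, j - 1] + open_)
    return float(max(M[n, m], X[n, m], Y[n, m]))


class TestPairwiseStats:
    def test_identical(self):
        a = SequenceRecord(id="a", sequence="MKTAYIAKQRQISFVKSHFSRQ")
        b = SequenceRecord(id="b", sequence="MKTAYIAKQRQISFVKSHFSRQ")
        edge = fa.pairwise_stats(a, b)
        assert edge.identity == pytest.approx(1.0)
        assert edge.evalue < 1e-3

    def test_empty_errors(self):
        a = SequenceRecord(id="a", sequence="MKT")
        b = SequenceRecord(id="b", sequence="")
        with pytest.raises(ValueError):
            fa.pairwise_stats(a, b)

    def test_reversal_is_background(self):
        rng = np.random.default_rng(23)
        seq = "".join(fa.AMINO[i] for i in rng.permutation(20))  # repeat-free
        a = SequenceRecord(id="f", sequence=seq)
        b = SequenceRecord(id="r", sequence=seq[::-1])
        edge = fa.pairwise_stats(a, b)
        assert edge.identity < 0.35
        assert edge.evalue > fa.EVALUE_CUTOFF

    def test_symmetry(self):
        a = SequenceRecord(id="a", sequence="MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")
        b = SequenceRecord(id="b", sequence="MKTAYIGKQRQISVVKSHFSRQLEERLGL")
        ab = fa.pairwise_stats(a, b)
        ba = fa.pairwise_stats(b, a)
        assert ab.identity == pytest.approx(ba.identity)
        assert ab.evalue == pytest.approx(ba.evalue)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_local_score_vs_global_oracle_on_identical(self, seed):
        # for identical sequences local == global score; check against the
        # independent Gotoh DP oracle
        rng = np.random.default_rng(seed)
        seq = "".join(fa.AMINO[i] for i in rng.integers(0, 20, size=30))
        a = SequenceRecord(id="a", sequence=seq)
        edge = fa.pairwise_stats(a, a)
        assert edge.score == pytest.approx(gotoh_global_score(seq, seq), abs=1e-6)

    def test_karlin_altschul_formula(self):
        a = SequenceRecord(id="a", sequence="MKTAYIAKQRQISFVKSHFSRQ")
        edge = fa.pairwise_stats(a, a)
        m = n = len(a.sequence)
        expected = fa.KA_K * m * n * np.exp(-fa.KA_LAMBDA * edge.score)
        assert edge.evalue == pytest.approx(expected, rel=1e-12)


class TestCollapseNodes:
    def test_identical_sequences_merge(self):
        seqs = [
            SequenceRecord(id="a", sequence="MKTAYIAKQRQISFVKSHFSRQ"),
            SequenceRecord(id="b", sequence="MKTAYIAKQRQISFVKSHFSRQ"),
        ]
        nodes = fa.collapse_nodes(seqs)
        assert len(nodes) == 1
        assert len(nodes[0].members) == 2

    def test_distant_sequences_stay_apart(self):
        seqs = [
            SequenceRecord(id="a", sequence="MKTAYIAKQRQISFVKSHFSRQ"),
            SequenceRecord(id="b", sequence="GGGPLWDENNCVHHTEEEDDDD"),
        ]
        assert len(fa.collapse_nodes(seqs, identity_threshold=0.9)) == 2

    def test_family_of_variants_collapses(self):
        rng = np.random.default_rng(5)
        founder = "".join(fa.AMINO[i] for i in rng.integers(0, 20, size=100))
        seqs = [SequenceRecord(id="founder", sequence=founder)]
        for k in range(10):
            chars = list(founder)
            for pos in rng.choice(100, size=6, replace=False):  # 94% identity
                chars[pos] = fa.AMINO[(fa.AMINO.index(chars[pos]) + 1) % 20]
            seqs.append(SequenceRecord(id=f"v{k}", sequence="".join(chars)))
        nodes = fa.collapse_nodes(seqs, identity_threshold=0.9)
        assert len(nodes) == 1
        assert len(nodes[0].members) == 11

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            fa.collapse_nodes([])


@pytest.fixture(scope="module")
def three_families():
    records, truth = make_family(
        FamilySpec(
            founder_length=100,
            n_species=4,
            families=("A", "B", "C"),
            paralogs_per_species={"A": 2, "B": 2, "C": 1},
            within_family_identity=0.92,
            between_family_identity=0.15,
            seed=31,
        )
    )
    return records, truth


class TestBuildSSN:
    def test_three_components_at_strict_cutoff(self, three_families):
        records, _ = three_families
        nodes = fa.collapse_nodes(records, identity_threshold=0.99)
        graph = fa.build_ssn(nodes, evalue_cutoff=1e-10)
        assert len(graph.components) == 3

    def test_monotone_in_cutoff(self, three_families):
        records, _ = three_families
        nodes = fa.collapse_nodes(records, identity_threshold=0.99)
        prev_edges, prev_comp = -1, np.inf
        for cutoff in (1e-60, 1e-40, 1e-20, 1e-10, 1e-3, 10.0):
            graph = fa.build_ssn(nodes, evalue_cutoff=cutoff)
            assert len(graph.edges) >= prev_edges
            assert len(graph.components) <= prev_comp
            prev_edges, prev_comp = len(graph.edges), len(graph.components)

    def test_single_node(self):
        nodes = fa.collapse_nodes([SequenceRecord(id="x", sequence="MKTAYIAKQRQISFVKSHFSRQ")])
        graph = fa.build_ssn(nodes)
        assert len(graph.components) == 1
        assert graph.edges == []


class TestCoDistribution:
    def test_fixed_paralog_means(self):
        records, truth = make_family(
            FamilySpec(
                n_species=10,
                paralogs_per_species={"A": 4, "B": 1},
                seed=2,
            )
        )
        nodes = fa.collapse_nodes(records, identity_threshold=0.999)
        graph = fa.build_ssn(nodes, evalue_cutoff=10.0)
        labels = {n.id: truth["membership"][n.id] for n in graph.nodes}
        stats = fa.co_distribution(graph, labels)
        assert stats.mean_paralogs == {"A": 4.0, "B": 1.0}
        assert stats.venn_str() == {"A+B": 10}

    def test_constructed_venn(self):
        # 7 species in both clusters, 2 only-A, 1 only-B
        records = []
        labels = {}
        species_list = [f"s{i}" for i in range(10)]
        base = "MKTAYIAKQRQISFVKSHFSRQ"
        k = 0
        for i, sp in enumerate(species_list):
            clusters = ["A", "B"] if i < 7 else (["A"] if i < 9 else ["B"])
            for c in clusters:
                rid = f"m{k}"
                k += 1
                records.append(SequenceRecord(id=rid, sequence=base, species=sp))
                labels[rid] = c
        nodes = [fa.SSNNode(representative=r, members=[r]) for r in records]
        graph = fa.SSNGraph(nodes=nodes)
        stats = fa.co_distribution(graph, labels)
        assert stats.venn_str() == {"A+B": 7, "A": 2, "B": 1}
        assert sum(stats.venn.values()) == 10

    def test_missing_species_errors(self):
        rec = SequenceRecord(id="x", sequence="MKTAYIAKQRQISFVKSHFSRQ", species="")
        node = fa.SSNNode(representative=rec, members=[rec])
        graph = fa.SSNGraph(nodes=[node])
        with pytest.raises(ValueError, match="species"):
            fa.co_distribution(graph, {"x": "A"})


class TestConservation:
    def test_invariant_column_scores_one(self):
        msa = ["AWA", "CWC", "DWD", "EWE", "FWF"]
        profile = fa.conservation_profile(msa)
        assert profile.per_column[1] == pytest.approx(1.0)

    def test_background_column_scores_zero(self):
        rows = [fa.AMINO] * 5  # every column has exactly the uniform background? no:
        # build columns that each contain all 20 residues equally often
        msa = ["".join(fa.AMINO[(r + c) % 20] for c in range(30)) for r in range(20)]
        profile = fa.conservation_profile(msa)
        assert np.allclose(profile.per_column, 0.0, atol=1e-12)

    def test_designed_columns_top_scores(self):
        msa = make_msa(n_rows=12, length=50, conserved_columns=[3, 17, 29, 31, 44], seed=9)
        profile = fa.conservation_profile(msa)
        top5 = set(np.argsort(profile.per_column)[-5:].tolist())
        assert top5 == {3, 17, 29, 31, 44}

    def test_row_order_invariance(self):
        msa = make_msa(n_rows=8, length=40, conserved_columns=[5], seed=4)
        fwd = fa.conservation_profile(msa).per_column
        rev = fa.conservation_profile(msa[::-1]).per_column
        assert np.allclose(fwd, rev)

    def test_ragged_errors(self):
        with pytest.raises(ValueError, match="ragged"):
            fa.conservation_profile(["AAA", "AA", "AAA", "AAA", "AAA"])

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match=">= 5"):
            fa.conservation_profile(["AAA"] * 4)

    def test_gap_flagging(self):
        msa = ["A-A", "A-A", "A-A", "AWA", "AWA"]
        profile = fa.conservation_profile(msa)
        assert profile.low_confidence.tolist() == [False, True, False]


class TestMapConservation:
    def test_identical_rows_map_to_one(self, scaffold):
        from glycomap.superposition import THREE_TO_ONE

        chain = "".join(
            THREE_TO_ONE.get(r.comp_name, "X")
            for r in scaffold.model.residues
            if r.category == "protein"
        )
        msa = [SequenceRecord(id=f"r{i}", sequence=chain) for i in range(5)]
        profile = fa.conservation_profile(msa)
        scores = fa.map_conservation(profile, msa, "r0", scaffold.model)
        assert scores
        assert all(v == pytest.approx(1.0) for v in scores.values())

    def test_short_row_errors(self, scaffold):
        msa = [SequenceRecord(id=f"r{i}", sequence="MKTAY") for i in range(5)]
        profile = fa.conservation_profile(msa)
        with pytest.raises(ValueError, match="shorter"):
            fa.map_conservation(profile, msa, "r0", scaffold.model)

    def test_missing_query_errors(self, scaffold):
        msa = [SequenceRecord(id=f"r{i}", sequence="MKTAY") for i in range(5)]
        profile = fa.conservation_profile(msa)
        with pytest.raises(ValueError, match="not in MSA"):
            fa.map_conservation(profile, msa, "absent", scaffold.model)

    def test_conserved_canyon_positions(self, scaffold):
        from glycomap.superposition import THREE_TO_ONE

        protein = [r for r in scaffold.model.residues if r.category == "protein"]
        chain = "".join(THREE_TO_ONE.get(r.comp_name, "X") for r in protein)
        canyon_cols = list(range(0, 10))
        rng = np.random.default_rng(6)
        msa = [SequenceRecord(id="query", sequence=chain)]
        for k in range(7):
            chars = list(chain)
            for c in range(len(chain)):
                if c not in canyon_cols and rng.random() < 0.8:
                    chars[c] = fa.AMINO[rng.integers(20)]
            msa.append(SequenceRecord(id=f"h{k}", sequence="".join(chars)))
        profile = fa.conservation_profile(msa)
        scores = fa.map_conservation(profile, msa, "query", scaffold.model)
        keys = [(r.chain_id, r.seq_num) for r in protein]
        canyon_mean = np.mean([scores[k] for k in keys[:10]])
        rest_mean = np.mean([scores[k] for k in keys[10:]])
        assert canyon_mean > rest_mean
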