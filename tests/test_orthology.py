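import numpy as np
import pytest

from nemaclock.align import AA_ALPHABET
from nemaclock.orthology import (
    ConservationTable,
    PairwiseStats,
    ProteomeDB,
    best_hit,
    collapse_isoform,
    conservation_matrix,
    cross_phylum_intersection,
    index_proteome,
    reciprocal_best_hit,
)


@pytest.fixture(scope="module")
def stats(matrix):
    return PairwiseStats.calibrate(matrix, seed=0, n_samples=1000)


def random_seq(rng, n):
    return "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, size=n))


class TestProteomeDB:
    def test_fasta_round_trip_preserves_order_and_counts(self, tmp_path):
        p = tmp_path / "x.faa"
        p.write_text(">p1\nMKVL*\n>p2\nACDE\n>p3\nWWWW\n")
        db = index_proteome(p, "sp")
        assert db.ids() == ["p1", "p2", "p3"]
        assert db.get("p1") == "MKVL"  # terminal stop stripped
        assert db.residue_count == 12
        out = tmp_path / "y.faa"
        db.to_fasta(out)
        assert index_proteome(out, "sp").records == db.records

    def test_duplicate_id_reports_both_positions(self, tmp_path):
        p = tmp_path / "dup.faa"
        p.write_text(">p1\nMKVL\n>p1\nACDE\n")
        with pytest.raises(ValueError, match=r"records 0 and 1"):
            index_proteome(p, "sp")

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.faa"
        p.write_text("")
        with pytest.raises(ValueError):
            index_proteome(p, "sp")

    def test_planted_id_lookup(self, small_bench):
        db = small_bench.proteome_db(small_bench.reference)
        fid = small_bench.families[0].id
        pid = small_bench.truth.proteins[fid][small_bench.reference]
        assert db.get(pid) == dict(small_bench.proteomes[small_bench.reference])[pid]


class TestBestHit:
    def test_identical_record_wins_with_tiny_evalue(self, matrix, stats):
        rng = np.random.default_rng(4)
        target = random_seq(rng, 150)
        records = [("self", target)] + [(f"d{i}", random_seq(rng, 150)) for i in range(30)]
        db = ProteomeDB("sp", records)
        hit = best_hit(target, db, matrix, stats, query_id="q")
        assert hit is not None and hit.target == "self"
        assert hit.evalue < 1e-10

    def test_random_query_has_no_hit_at_cutoff(self, matrix, stats):
        rng = np.random.default_rng(6)
        db = ProteomeDB("sp", [(f"d{i}", random_seq(rng, 120)) for i in range(40)])
        false_hits = 0
        for _ in range(30):
            if best_hit(random_seq(rng, 120), db, matrix, stats) is not None:
                false_hits += 1
        assert false_hits <= 1

    def test_infinite_cutoff_always_returns_a_record(self, matrix, stats):
        rng = np.random.default_rng(8)
        db = ProteomeDB("sp", [("only", random_seq(rng, 50))])
        hit = best_hit(random_seq(rng, 50), db, matrix, stats, cutoff=np.inf)
        assert hit is not None and hit.target == "only"

    def test_empty_database_yields_absent_not_error(self, matrix, stats):
        assert best_hit("MKVL", ProteomeDB("sp", []), matrix, stats) is None


class TestRBH:
    def test_identical_proteomes_pair_every_protein_with_itself(self, matrix, stats):
        rng = np.random.default_rng(10)
        records = [(f"p{i}", random_seq(rng, 120)) for i in range(5)]
        a = ProteomeDB("a", records)
        b = ProteomeDB("b", list(records))
        for pid, _ in records:
            pair = reciprocal_best_hit(pid, a, b, matrix, stats)
            assert pair.reciprocal and pair.other_id == pid

    def test_missing_query_id_is_an_error(self, matrix, stats):
        db = ProteomeDB("a", [("p1", "MKVLMKVL")])
        with pytest.raises(KeyError):
            reciprocal_best_hit("nope", db, db, matrix, stats)

    def test_planted_orthologs_are_reciprocal(self, matrix, stats, small_bench):
        ce = small_bench.proteome_db(small_bench.reference)
        other = small_bench.proteome_db(small_bench.species[1])
        for fam in small_bench.families:
            ce_id = small_bench.truth.proteins[fam.id][small_bench.reference]
            pair = reciprocal_best_hit(ce_id, ce, other, matrix, stats)
            assert pair.reciprocal
            assert pair.other_id == small_bench.truth.proteins[fam.id][other.species]

    def test_asymmetric_duplicate_breaks_reciprocity(self, matrix, stats):
        """The target species carries a recent duplicate closer to a different
        reference paralog, so the reverse best hit lands elsewhere."""
        rng = np.random.default_rng(12)
        base = random_seq(rng, 160)

        def mutate(seq, k, rng):
            s = list(seq)
            for pos in rng.choice(len(s), size=k, replace=False):
                s[pos] = AA_ALPHABET[(AA_ALPHABET.index(s[pos]) + 1) % 20]
            return "".join(s)

        paralog_a = base
        paralog_b = mutate(base, 25, rng)  # reference paralogs, 15% apart
        ce = ProteomeDB("ce", [("parA", paralog_a), ("parB", paralog_b)])
        # other species: one gene much closer to parB
        other = ProteomeDB("ot", [("dup", mutate(paralog_b, 5, rng))])
        pair = reciprocal_best_hit("parA", ce, other, matrix, stats)
        assert pair.other_id == "dup" and not pair.reciprocal


class TestIsoforms:
    @pytest.mark.parametrize(
        "pid,locus",
        [
            ("F47F6.1b", "F47F6.1"),
            ("F47F6.1c", "F47F6.1"),
            ("C25A1.11a", "C25A1.11"),
            ("ZK909.2h", "ZK909.2"),
            ("C14B1.4", "C14B1.4"),
            ("GS_18509", "GS_18509"),
            ("nem03_fam01", "nem03_fam01"),
        ],
    )
    def test_collapse(self, pid, locus):
        assert collapse_isoform(pid) == locus


class TestConservationAndIntersection:
    def test_single_identical_species_gives_identity_mapping(self, matrix, stats):
        rng = np.random.default_rng(14)
        records = [(f"p{i}", random_seq(rng, 120)) for i in range(3)]
        ce = ProteomeDB("ce", records)
        other = ProteomeDB("sp1", list(records))
        table = conservation_matrix(
            [(f"q{i}", pid) for i, (pid, _) in enumerate(records)], ce, [other], matrix, stats
        )
        for i, (pid, _) in enumerate(records):
            assert table.cells[(f"q{i}", "sp1")] == pid
            assert table.fully_conserved(f"q{i}")

    def test_family_deleted_from_one_species_breaks_full_conservation(
        self, matrix, stats, small_bench
    ):
        ce = small_bench.proteome_db(small_bench.reference)
        fam = small_bench.families[0]
        ce_id = small_bench.truth.proteins[fam.id][small_bench.reference]
        sp = small_bench.species[1]
        removed_id = small_bench.truth.proteins[fam.id][sp]
        pruned = ProteomeDB(
            sp, [(i, s) for i, s in small_bench.proteomes[sp] if i != removed_id]
        )
        table = conservation_matrix([("q", ce_id)], ce, [pruned], matrix, stats)
        assert not table.fully_conserved("q")

    @staticmethod
    def _table(queries, conserved):
        cells = {(q, "s1"): (f"{q}_s1" if q in conserved else None) for q in queries}
        return ConservationTable(sorted(queries), ["s1"], {q: q for q in queries}, cells)

    def test_disjoint_hit_lists_give_empty_intersection(self):
        class H:
            def __init__(self, q, t, st="accepted"):
                self.query, self.target, self.status = q, t, st

        table = self._table(["x", "y"], {"x", "y"})
        common, _ = cross_phylum_intersection([H("a", "x")], [H("b", "y")], table)
        assert common == set()

    def test_constructed_three_common_two_single_phylum(self):
        class H:
            def __init__(self, q, t, st="accepted"):
                self.query, self.target, self.status = q, t, st

        queries = ["f1", "f2", "f3", "f4", "f5"]
        table = self._table(queries, set(queries))
        insect = [H(f"i{q}", q) for q in ["f1", "f2", "f3", "f4"]]
        mammal = [H(f"m{q}", q) for q in ["f1", "f2", "f3", "f5"]]
        common, reasons = cross_phylum_intersection(insect, mammal, table)
        assert common == {"f1", "f2", "f3"}
        assert reasons["f4"] == "no accepted mammal-query hit"
        assert reasons["f5"] == "no accepted insect-query hit"

    def test_flagged_only_overlap_excluded_by_default_included_by_switch(self):
        class H:
            def __init__(self, q, t, st="accepted"):
                self.query, self.target, self.status = q, t, st

        table = self._table(["f1"], {"f1"})
        insect = [H("i", "f1")]
        mammal = [H("m", "f1", "flagged")]
        common, reasons = cross_phylum_intersection(insect, mammal, table)
        assert common == set() and "f1" in reasons
        common, _ = cross_phylum_intersection(insect, mammal, table, include_flagged=True)
        assert common == {"f1"}

    def test_lowering_cutoff_never_adds_cells(self, matrix, stats, small_bench):
        ce = small_bench.proteome_db(small_bench.reference)
        others = [small_bench.proteome_db(sp) for sp in small_bench.species[1:3]]
        fam = small_bench.families[0]
        accepted = [("q", small_bench.truth.proteins[fam.id][small_bench.reference])]
        loose = conservation_matrix(accepted, ce, others, matrix, stats, cutoff=1e-5)
        strict = conservation_matrix(accepted, ce, others, matrix, stats, cutoff=1e-40)
        for key, val in strict.cells.items():
            if val is not None:
                assert loose.cells[key] is not None
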