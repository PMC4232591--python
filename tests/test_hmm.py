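import numpy as np
import pytest

from nemaclock.align import MSA, AA_ALPHABET
from nemaclock.hmm import (
    ProfileHMM,
    build_profile,
    calibrate,
    dumps_hmm,
    forward_score,
    forward_scores,
    hmmsearch,
    load_hmm,
    match_region,
    save_hmm,
    score_pvalue,
    viterbi_score,
    viterbi_trace,
)
from nemaclock.orthology import ProteomeDB
from nemaclock.synthetic import make_decoys

from oracles import forward_bits_bruteforce, viterbi_bits_bruteforce


def random_msa(rng, nrows, ncols):
    return MSA(
        (f"s{r}", "".join(AA_ALPHABET[c] for c in rng.integers(0, 20, size=ncols)))
        for r in range(nrows)
    )


class TestBuild:
    def test_identical_gapfree_rows_give_one_match_state_per_column(self):
        msa = MSA([(f"s{i}", "ACDEFGHIKLMN") for i in range(3)])
        hmm = build_profile(msa)
        assert hmm.L == 12
        for k, c in enumerate("ACDEFGHIKLMN"):
            assert np.argmax(hmm.match_em[k]) == AA_ALPHABET.index(c)

    def test_majority_gap_column_becomes_insert_region(self):
        msa = MSA([("a", "AC"), ("b", "A-"), ("c", "A-")])
        hmm = build_profile(msa)  # column 2 has gap fraction 2/3 >= 0.5
        assert hmm.L == 1

    def test_all_gap_columns_is_an_error(self):
        with pytest.raises(ValueError):
            build_profile(MSA([("a", "--"), ("b", "AC")]), match_gap_threshold=0.4)

    def test_build_is_deterministic_and_serialization_bit_identical(self):
        rng = np.random.default_rng(2)
        msa = random_msa(rng, 4, 15)
        assert dumps_hmm(build_profile(msa)) == dumps_hmm(build_profile(msa))

    def test_normalization_invariants(self, small_models):
        hmms, _, domains = small_models
        for prof in list(hmms.values()) + list(domains.values()):
            prof.validate()


class TestScores:
    def test_single_match_state_closed_form(self):
        # one match state emitting W with probability p; flanks eta
        p, eta = 0.7, 0.9
        em = np.full((1, 20), (1 - p) / 19)
        em[0, AA_ALPHABET.index("W")] = p
        hmm = ProfileHMM(
            name="w",
            match_em=em,
            insert_em=np.full((1, 20), 1 / 20),
            t_mm=np.zeros(1), t_mi=np.zeros(1), t_md=np.zeros(1), t_me=np.ones(1),
            t_im=np.ones(1), t_ii=np.zeros(1), t_dm=np.ones(1), t_dd=np.zeros(1),
            background=np.full(20, 1 / 20),
            eta=eta,
        )
        hmm.validate()
        # P(model) = (1-eta) * p * (1-eta); P(null) = eta/20 * (1-eta)
        expected = np.log2((1 - eta) * p / (eta / 20))
        assert forward_score(hmm, "W") == pytest.approx(expected, abs=1e-9)
        assert viterbi_score(hmm, "W") == pytest.approx(expected, abs=1e-9)

    def test_forward_and_viterbi_match_path_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            L = int(rng.integers(1, 4))
            hmm = build_profile(random_msa(rng, int(rng.integers(2, 5)), L))
            for slen in range(1, 5):
                codes = rng.integers(0, 20, size=slen)
                seq = "".join(AA_ALPHABET[c] for c in codes)
                assert forward_score(hmm, seq) == pytest.approx(
                    forward_bits_bruteforce(hmm, codes), abs=1e-6
                )
                assert viterbi_score(hmm, seq) == pytest.approx(
                    viterbi_bits_bruteforce(hmm, codes), abs=1e-6
                )

    def test_forward_at_least_viterbi(self):
        rng = np.random.default_rng(8)
        hmm = build_profile(random_msa(rng, 4, 12))
        for _ in range(10):
            seq = "".join(AA_ALPHABET[c] for c in rng.integers(0, 20, size=30))
            assert forward_score(hmm, seq) >= viterbi_score(hmm, seq) - 1e-9

    def test_empty_sequence_is_an_error(self):
        rng = np.random.default_rng(9)
        hmm = build_profile(random_msa(rng, 3, 8))
        with pytest.raises(ValueError):
            forward_score(hmm, "")

    def test_consensus_sequence_traces_through_match_states(self):
        msa = MSA([(f"s{i}", "ACDEFGHIKLW") for i in range(4)])
        hmm = build_profile(msa, pseudocount_weight=0.1)
        score, path = viterbi_trace(hmm, "ACDEFGHIKLW")
        assert [s for s, _, _ in path] == ["M"] * 11
        assert match_region(path) == (0, 11)

    def test_alien_sequence_mostly_avoids_match_states(self):
        msa = MSA([(f"s{i}", "AAAAAAAAAA") for i in range(4)])
        hmm = build_profile(msa, pseudocount_weight=0.01)
        _, path = viterbi_trace(hmm, "WWWWWWWWWWWWWWWW")
        n_match = sum(1 for s, _, _ in path if s == "M")
        assert n_match <= 2  # flanks/inserts absorb the alien residues


@pytest.fixture(scope="module")
def calibrated():
    rng = np.random.default_rng(12)
    hmm = build_profile(random_msa(rng, 5, 20))
    return calibrate(hmm, n_decoys=400, decoy_length=80, seed=3)


class TestCalibration:

    def test_median_decoy_has_pvalue_about_half(self, calibrated):
        med = float(np.median(calibrated.calib_scores))
        assert 0.4 <= score_pvalue(calibrated, med) <= 0.6

    def test_too_few_decoys_rejected(self):
        rng = np.random.default_rng(13)
        hmm = build_profile(random_msa(rng, 3, 10))
        with pytest.raises(ValueError):
            calibrate(hmm, n_decoys=50)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(14)
        msa = random_msa(rng, 3, 12)
        h1 = calibrate(build_profile(msa), n_decoys=300, decoy_length=60, seed=5)
        h2 = calibrate(build_profile(msa), n_decoys=300, decoy_length=60, seed=5)
        assert (h1.mu, h1.lambda_) == (h2.mu, h2.lambda_)
        assert np.array_equal(h1.calib_scores, h2.calib_scores)

    def test_pvalue_monotone_in_score(self, calibrated):
        lo, hi = calibrated.calib_scores[0], calibrated.calib_scores[-1]
        s = np.linspace(lo + 0.1, hi + 30, 80)
        pv = [score_pvalue(calibrated, x) for x in s]
        assert all(a >= b for a, b in zip(pv, pv[1:]))
        # strictly decreasing inside the empirical range and in the far tail
        inner = [score_pvalue(calibrated, x) for x in np.linspace(lo + 0.1, hi - 0.1, 30)]
        assert all(a > b for a, b in zip(inner, inner[1:]))
        far = [score_pvalue(calibrated, x) for x in np.linspace(hi + 20, hi + 40, 10)]
        assert all(a > b for a, b in zip(far, far[1:]))


class TestSearch:
    def test_uncalibrated_model_instructs_to_calibrate(self):
        rng = np.random.default_rng(15)
        hmm = build_profile(random_msa(rng, 3, 10))
        db = ProteomeDB("x", [("p1", "ACDEFGHIKL")])
        with pytest.raises(ValueError, match="calibrate"):
            hmmsearch(hmm, db)

    def test_empty_proteome_gives_empty_list(self, small_models):
        hmms, _, _ = small_models
        model = next(iter(hmms.values()))
        assert hmmsearch(model, ProteomeDB("x", [])) == []

    def test_raising_inclusion_threshold_only_grows_the_included_set(self, small_models, small_bench):
        hmms, _, _ = small_models
        model = next(iter(hmms.values()))
        db = small_bench.proteome_db(small_bench.reference)
        strict = {h.target for h in hmmsearch(model, db, inclusion=0.01) if h.included}
        loose = {h.target for h in hmmsearch(model, db, inclusion=1.0) if h.included}
        assert strict <= loose

    def test_planted_ortholog_ranks_first_among_decoys(self, small_models, small_bench):
        hmms, _, _ = small_models
        for (phylum, fid), model in hmms.items():
            for sp in small_bench.species:
                hits = hmmsearch(model, small_bench.proteome_db(sp))
                assert hits[0].target == small_bench.truth.proteins[fid][sp]
                assert hits[0].included

    def test_hits_sorted_by_evalue_then_score_then_id(self, small_models, small_bench):
        hmms, _, _ = small_models
        model = next(iter(hmms.values()))
        hits = hmmsearch(model, small_bench.proteome_db(small_bench.reference))
        keys = [(h.evalue, -h.score, h.target) for h in hits]
        assert keys == sorted(keys)


class TestSerialization:
    def test_round_trip_preserves_model_and_scores(self, tmp_path, small_models):
        hmms, _, _ = small_models
        model = next(iter(hmms.values()))
        p = tmp_path / "m.nhmm"
        save_hmm(model, p)
        back = load_hmm(p)
        assert dumps_hmm(back) == dumps_hmm(model)
        seq = "ACDEFGHIKLMNPQRSTVWY" * 3
        assert forward_score(back, seq) == pytest.approx(forward_score(model, seq))
        assert back.calibrated

    def test_rejects_foreign_files(self, tmp_path):
        p = tmp_path / "x.nhmm"
        p.write_text("HMMER3/f [3.1]\n")
        with pytest.raises(ValueError):
            load_hmm(p)
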