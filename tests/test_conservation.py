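import itertools
import random

import numpy as np
import pytest

from concysfind import (ConCysFindError, FamilySpec, ParalogSpec, QueryEntry,
                        SearchParams, analyze_residue, assess_position,
                        chance_probabilities, classify_conserved,
                        conservation_score, find_target_positions,
                        generate_family, p_value, presence_flags,
                        search_all_species, summarize_protein)


def enumerate_tail(k, probs):
    """Exhaustive 2^n oracle for the Poisson-binomial upper tail."""
    total = 0.0
    for outcome in itertools.product((0, 1), repeat=len(probs)):
        if sum(outcome) >= k:
            pr = 1.0
            for x, p in zip(outcome, probs):
                pr *= p if x else (1.0 - p)
            total += pr
    return total


class TestTargetPositions:
    @pytest.mark.parametrize("seq,target,expected", [
        ("MKCWC", "C", [3, 5]),
        ("MKW", "C", []),
        ("CSTC", {"C", "S"}, [1, 2, 4]),
    ])
    def test_positions(self, seq, target, expected):
        assert find_target_positions(seq, target) == expected


class TestConservationScore:
    @pytest.mark.parametrize("k,n,expected", [
        (18, 18, 1.0), (16, 18, 16 / 18), (0, 7, 0.0), (10, 19, 10 / 19),
    ])
    def test_exact_fraction(self, k, n, expected):
        assert conservation_score(k, n) == expected

    def test_no_homologs_is_an_error(self):
        with pytest.raises(ConCysFindError):
            conservation_score(0, 0)

    def test_invalid_counts(self):
        with pytest.raises(ConCysFindError):
            conservation_score(5, 3)


class TestPValue:
    def test_k_zero_is_one(self):
        assert p_value(0, [0.3, 0.7, 0.01]) == 1.0

    def test_half_probs_enumeration(self):
        assert p_value(2, [0.5, 0.5, 0.5]) == pytest.approx(0.5)

    def test_k_equals_n_closed_form(self):
        assert p_value(4, [0.2] * 4) == pytest.approx(0.2 ** 4)

    def test_matches_exhaustive_enumeration(self):
        rng = random.Random(99)
        for _ in range(50):
            n = rng.randint(1, 10)
            probs = [rng.random() for _ in range(n)]
            k = rng.randint(0, n)
            assert p_value(k, probs) == pytest.approx(
                max(enumerate_tail(k, probs), 5e-324), rel=1e-10)

    def test_non_increasing_in_k(self):
        rng = random.Random(5)
        probs = [rng.random() for _ in range(8)]
        vals = [p_value(k, probs) for k in range(9)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert vals[0] == 1.0


class TestClassification:
    @pytest.mark.parametrize("p,alpha,expected", [
        (0.008, 0.01, True),
        (0.0387, 0.01, False),
        (0.01, 0.01, True),   # boundary inclusive
    ])
    def test_boundary(self, p, alpha, expected):
        assert classify_conserved(p, alpha) is expected


@pytest.fixture(scope="module")
def family(blosum62):
    """Six species, one decoy paralog per species ranked first (it is
    closer to the query but lacks the target residue) — the scenario
    the up-to-9 candidate iteration exists for."""
    spec = FamilySpec(seed=3, n_species=6, seq_length=140, divergence=0.2,
                      conserved_positions=(40, 90), loss_map={"sp05": (90,)},
                      paralogs=ParalogSpec(count=1, carry_target=False,
                                           divergence_scale=0.5))
    db, query, truth = generate_family(spec)
    params = SearchParams()
    hits = search_all_species(query, db, params, blosum62)
    return db, query, truth, params, hits


class TestAssessPosition:
    def test_decoy_outranks_ortholog_but_iteration_recovers(self, family, blosum62):
        db, query, truth, params, hits = family
        for sp, hl in hits.items():
            assert hl.hits[0][0].id.endswith("para1")  # decoy really is rank 1
            assert hl.hits[1][1].raw_score >= 0.8 * hl.best_score
        ras = assess_position(query, 40, hits, params, blosum62)
        assert all(rec.id.endswith("orth") for rec in ras.representatives.values())
        flags = presence_flags(ras)
        assert all(flags.values())

    def test_no_detecting_candidate_falls_back_to_best(self, family, blosum62):
        db, query, truth, params, hits = family
        ras = assess_position(query, 90, hits, params, blosum62)
        # sp05 lost the residue in ortholog and decoy alike: rank-1 decoy stands in
        assert ras.representatives["sp05"].id == "sp05_para1"
        assert presence_flags(ras)["sp05"] is False

    def test_species_with_empty_hit_list_excluded(self, family, blosum62):
        db, query, truth, params, hits = family
        hits = dict(hits)
        hits["spX"] = type(hits["sp01"])(species="spX", hits=[])
        ras = assess_position(query, 40, hits, params, blosum62)
        assert "spX" not in ras.representatives
        res = analyze_residue(ras)
        assert res.n == 6

    def test_wrong_residue_at_position_rejected(self, family, blosum62):
        db, query, truth, params, hits = family
        pos = next(i for i, c in enumerate(query.sequence, 1) if c != "C")
        with pytest.raises(ConCysFindError):
            assess_position(query, pos, hits, params, blosum62)


class TestChanceProbabilities:
    def test_identical_representative_clamped(self, blosum62):
        spec = FamilySpec(seed=2, n_species=3, seq_length=60, divergence=0.0,
                          conserved_positions=(10,))
        db, query, truth = generate_family(spec)
        params = SearchParams()
        hits = search_all_species(query, db, params, blosum62)
        ras = assess_position(query, 10, hits, params, blosum62)
        probs = chance_probabilities(ras)
        assert all(q == pytest.approx(1e-6) for q in probs.values())

    def test_q_is_one_minus_identity(self, family, blosum62):
        from concysfind.msa import identity_to_query
        db, query, truth, params, hits = family
        ras = assess_position(query, 40, hits, params, blosum62)
        probs = chance_probabilities(ras)
        labels = {lab: i for i, (lab, _) in enumerate(ras.msa.rows)}
        for sp, rec in ras.representatives.items():
            ident = identity_to_query(ras.msa, labels[f"{sp}|{rec.id}"])
            assert probs[sp] == pytest.approx(1.0 - ident)
            assert 0.0 < probs[sp] < 1.0


class TestProteinSummary:
    def test_counts_and_homolog_species(self, family, blosum62):
        db, query, truth, params, hits = family
        results = []
        for pos in (40, 90):
            results.append(analyze_residue(assess_position(
                query, pos, hits, params, blosum62)))
        rep = summarize_protein(query, hits, results)
        assert rep.n_homolog_species == 6
        assert rep.total_count == 2
        assert rep.conserved_count == sum(r.conserved for r in results)
        # score * n == k exactly
        for r in results:
            assert r.score * r.n == r.k

    def test_equal_k_residues_share_p_value(self, blosum62):
        spec = FamilySpec(seed=21, n_species=8, seq_length=150, divergence=0.15,
                          conserved_positions=(30, 60, 120),
                          loss_map={"sp02": (60, 120)})
        db, query, truth = generate_family(spec)
        params = SearchParams()
        hits = search_all_species(query, db, params, blosum62)
        results = {pos: analyze_residue(assess_position(
            query, pos, hits, params, blosum62)) for pos in (30, 60, 120)}
        assert results[60].k == results[120].k
        assert results[60].p_value == results[120].p_value
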