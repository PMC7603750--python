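import math
import random

import pytest

from concysfind import (ConCysFindError, QueryEntry, SearchParams,
                        evalue_from_score, external_search_adapter,
                        search_species, smith_waterman)
from concysfind.fixtures import AA20
from concysfind.homolog_search import sw_score
from concysfind.proteome_db import SpeciesPanel, database_from_records
from concysfind.seqio import ParseError, SequenceRecord

from oracles import brute_local_score


class TestSmithWaterman:
    def test_no_positive_cell_gives_empty_alignment(self, blosum62):
        aln = smith_waterman("CCC", "AAA", blosum62)
        assert aln.raw_score == 0
        assert aln.query_aligned == aln.subject_aligned == ""

    def test_self_alignment_is_diagonal_sum(self, blosum62):
        aln = smith_waterman("ACDE", "ACDE", blosum62)
        assert aln.raw_score == sum(blosum62.score(c, c) for c in "ACDE")
        assert aln.query_aligned == aln.subject_aligned == "ACDE"
        assert (aln.query_start, aln.query_end) == (1, 4)
        assert aln.identity == 1.0

    def test_empty_sequence_rejected(self, blosum62):
        with pytest.raises(ConCysFindError):
            smith_waterman("", "ACDE", blosum62)

    def test_matches_brute_force_oracle(self, blosum62):
        rng = random.Random(42)
        for _ in range(200):
            q = "".join(rng.choice(AA20) for _ in range(rng.randint(1, 8)))
            s = "".join(rng.choice(AA20) for _ in range(rng.randint(1, 8)))
            expected = brute_local_score(q, s, blosum62.score, 11, 1)
            assert smith_waterman(q, s, blosum62).raw_score == expected
            assert sw_score(blosum62.encode(q), blosum62.encode(s),
                            blosum62, 11, 1) == expected

    def test_score_symmetry(self, blosum62):
        rng = random.Random(7)
        for _ in range(50):
            q = "".join(rng.choice(AA20) for _ in range(rng.randint(1, 8)))
            s = "".join(rng.choice(AA20) for _ in range(rng.randint(1, 8)))
            assert (smith_waterman(q, s, blosum62).raw_score
                    == smith_waterman(s, q, blosum62).raw_score)

    def test_appending_subject_never_decreases_score(self, blosum62):
        rng = random.Random(11)
        q = "".join(rng.choice(AA20) for _ in range(12))
        s = "".join(rng.choice(AA20) for _ in range(4))
        prev = smith_waterman(q, s, blosum62).raw_score
        for _ in range(10):
            s += rng.choice(AA20)
            cur = smith_waterman(q, s, blosum62).raw_score
            assert cur >= prev
            prev = cur

    def test_traceback_restores_query_slice(self, blosum62):
        rng = random.Random(5)
        for _ in range(50):
            q = "".join(rng.choice(AA20) for _ in range(rng.randint(2, 15)))
            s = "".join(rng.choice(AA20) for _ in range(rng.randint(2, 15)))
            a = smith_waterman(q, s, blosum62)
            if a.raw_score == 0:
                continue
            assert a.query_aligned.replace("-", "") == q[a.query_start - 1:a.query_end]
            assert a.subject_aligned.replace("-", "") == s[a.subject_start - 1:a.subject_end]
            assert len(a.query_aligned) == len(a.subject_aligned)


class TestEvalue:
    def test_zero_score_gives_kmn(self):
        p = SearchParams()
        _, ev = evalue_from_score(0, 100, 1000, p)
        assert ev == pytest.approx(p.k_gapped * 100 * 1000)

    def test_linear_in_database_size(self):
        p = SearchParams()
        _, e1 = evalue_from_score(50, 100, 10_000, p)
        _, e2 = evalue_from_score(50, 100, 20_000, p)
        assert e2 == pytest.approx(2 * e1)

    def test_closed_form_value(self):
        p = SearchParams(lambda_gapped=0.267, k_gapped=0.041)
        bits, ev = evalue_from_score(100, 100, 10_000, p)
        assert ev == pytest.approx(0.041 * 1e6 * math.exp(-26.7))
        assert bits == pytest.approx((26.7 - math.log(0.041)) / math.log(2))

    def test_strictly_decreasing_in_score(self):
        p = SearchParams()
        evs = [evalue_from_score(s, 100, 1000, p)[1] for s in range(0, 200, 10)]
        assert all(a > b for a, b in zip(evs, evs[1:]))


def _db_with(species_seqs):
    panel = SpeciesPanel(species=tuple(species_seqs),
                         source_files={sp: f"{sp}.fa" for sp in species_seqs})
    records = {
        sp: [SequenceRecord(id=f"{sp}_{i}", description="", species=sp, residues=seq)
             for i, seq in enumerate(seqs)]
        for sp, seqs in species_seqs.items()
    }
    return database_from_records(panel, records)


class TestSearchSpecies:
    QUERY = QueryEntry("q", "", "MKCWAEDRLNPQSTVYHIGF" * 3)

    def _variants(self, n_sub_list):
        rng = random.Random(1)
        out = []
        for n_sub in n_sub_list:
            seq = list(self.QUERY.sequence)
            sites = rng.sample(range(len(seq)), n_sub)
            for i in sites:
                seq[i] = rng.choice([c for c in AA20 if c != seq[i]])
            out.append("".join(seq))
        return out

    def test_relative_cutoff_drops_weak_hits(self, blosum62):
        # 0, 8 and 30 substitutions: the distant hit falls below 0.8 x best
        db = _db_with({"sp": self._variants([0, 8, 30])})
        params = SearchParams(evalue_cutoff=10.0)
        hl = search_species(self.QUERY, db, "sp", params, blosum62)
        scores = [a.raw_score for _, a in hl.hits]
        assert scores == sorted(scores, reverse=True)
        assert all(s >= 0.8 * scores[0] for s in scores)
        assert len(hl) == 2

    def test_max_hits_truncation(self, blosum62):
        db = _db_with({"sp": self._variants([0] * 12)})
        hl = search_species(self.QUERY, db, "sp",
                            SearchParams(evalue_cutoff=10.0), blosum62)
        assert len(hl) == 9

    def test_no_hits_is_valid_empty_list(self, blosum62):
        db = _db_with({"sp": ["WWWWW"]})
        hl = search_species(self.QUERY, db, "sp", SearchParams(), blosum62)
        assert not hl
        assert hl.best_score == 0.0

    def test_order_invariant_to_input_permutation(self, blosum62):
        seqs = self._variants([0, 3, 6, 9])
        params = SearchParams(evalue_cutoff=10.0)
        ids_fwd = [r.id for r, _ in
                   search_species(self.QUERY, _db_with({"sp": seqs}), "sp",
                                  params, blosum62).hits]
        db_rev = _db_with({"sp": seqs[::-1]})
        scores_rev = [a.raw_score for _, a in
                      search_species(self.QUERY, db_rev, "sp", params, blosum62).hits]
        scores_fwd = [a.raw_score for _, a in
                      search_species(self.QUERY, _db_with({"sp": seqs}), "sp",
                                     params, blosum62).hits]
        assert scores_fwd == scores_rev
        assert len(ids_fwd) == len(set(ids_fwd))


class TestExternalAdapter:
    def _row(self, sseqid, evalue, bitscore):
        return (f"q\t{sseqid}\t95.0\t50\t2\t0\t1\t50\t1\t50\t{evalue}\t{bitscore}")

    def test_same_filtering_as_builtin(self):
        db = _db_with({"A": ["MKCW", "MKCA"]})
        text = "\n".join([self._row("A_0", 1e-20, 80.0),
                          self._row("A_1", 1e-10, 60.0)])
        hits = external_search_adapter(text, db, SearchParams())
        assert [r.id for r, _ in hits["A"].hits] == ["A_0"]  # 60 < 0.8*80

    def test_empty_stream_maps_all_species_empty(self):
        db = _db_with({"A": ["MKCW"], "B": ["MKCA"]})
        hits = external_search_adapter("", db, SearchParams())
        assert set(hits) == {"A", "B"}
        assert not hits["A"] and not hits["B"]

    def test_unknown_accession_reports_line(self):
        db = _db_with({"A": ["MKCW"]})
        with pytest.raises(ParseError, match="line 1.*'nope'"):
            external_search_adapter(self._row("nope", 1e-5, 50.0), db, SearchParams())

    def test_malformed_row_reports_line(self):
        db = _db_with({"A": ["MKCW"]})
        with pytest.raises(ParseError, match="line 1"):
            external_search_adapter("q\tA_0\tgarbage\n", db, SearchParams())
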