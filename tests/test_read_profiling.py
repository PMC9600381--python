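import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cobashare import read_profiling as rp
from cobashare.io_formats import ProfileHMMHit, SampleMetadata, TaxonAssignment
from conftest import random_hits


def _hit(read, gene, evalue, bits=50.0, a=1, b=50, L=200, frame=1):
    return ProfileHMMHit(read, frame, gene, "ACC", evalue, bits, a, b, L)


class TestSixFrameTranslate:
    def test_known_codons(self):
        frames = rp.six_frame_translate("ATGTAA")
        assert frames[1] == "M*"
        assert rp.six_frame_translate("ATG")[-1] == "H"  # revcomp CAT

    def test_n_codon_is_x(self):
        assert rp.six_frame_translate("ATNAAA")[1] == "XK"

    def test_too_short(self):
        with pytest.raises(ValueError):
            rp.six_frame_translate("AT")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=3, max_size=90))
    def test_frame_lengths(self, dna):
        frames = rp.six_frame_translate(dna)
        L = len(dna)
        for key, aa in frames.items():
            offset = abs(key) - 1
            assert len(aa) == (L - offset) // 3

    def test_matches_biopython_reverse_complement(self, rng):
        from Bio.Seq import Seq
        for _ in range(20):
            dna = "".join(rng.choice(list("ACGT"), size=30))
            frames = rp.six_frame_translate(dna)
            assert frames[-1] == str(Seq(dna).reverse_complement().translate())


class TestSelectBestHits:
    def test_lowest_evalue_wins(self):
        hits = [_hit("r1", "geneA", 1e-8), _hit("r1", "geneB", 1e-7)]
        out = rp.select_best_hits(hits)
        assert len(out) == 1 and out[0].hmm_name == "geneA"

    def test_evalue_threshold_is_exclusive_above(self):
        assert rp.select_best_hits([_hit("r1", "g", 1e-5)]) == []
        assert len(rp.select_best_hits([_hit("r1", "g", 1e-6)])) == 1

    def test_bitscore_breaks_evalue_ties(self):
        hits = [_hit("r1", "geneA", 1e-8, bits=40),
                _hit("r1", "geneB", 1e-8, bits=90)]
        assert rp.select_best_hits(hits)[0].hmm_name == "geneB"

    def test_name_breaks_residual_ties(self):
        hits = [_hit("r1", "geneB", 1e-8, bits=50),
                _hit("r1", "geneA", 1e-8, bits=50)]
        assert rp.select_best_hits(hits)[0].hmm_name == "geneA"

    def test_matches_bruteforce_on_random_hits(self, rng):
        """Dedup equals an exhaustive per-read argmin scan, ~1000 reads."""
        lengths = {g: 200 for g in "ABCDEFG"}
        hits = random_hits(rng, 1000, list(lengths), lengths)
        params = rp.ProfilingParams()
        out = {h.read_id: h for h in rp.select_best_hits(hits, params)}
        expected = {}
        for h in hits:
            if h.evalue > params.evalue_max:
                continue
            cur = expected.get(h.read_id)
            if (cur is None
                    or (h.evalue, -h.bitscore, h.hmm_name)
                    < (cur.evalue, -cur.bitscore, cur.hmm_name)):
                expected[h.read_id] = h
        assert out == expected


class TestGenePresence:
    def test_union_below_threshold(self):
        hits = [_hit("r1", "g", 1e-9, a=1, b=10, L=100),
                _hit("r2", "g", 1e-9, a=5, b=15, L=100)]
        present, cov = rp.gene_presence(hits, 100)
        assert not present and cov == pytest.approx(0.15)

    def test_boundary_inclusive(self):
        hits = [_hit("r1", "g", 1e-9, a=1, b=10, L=100),
                _hit("r2", "g", 1e-9, a=11, b=20, L=100)]
        present, cov = rp.gene_presence(hits, 100)
        assert present and cov == pytest.approx(0.20)

    def test_empty_hits(self):
        assert rp.gene_presence([], 100) == (False, 0.0)

    def test_coverage_matches_bitmap_oracle(self, rng):
        """Interval-union coverage equals a per-position bitmap count."""
        for _ in range(1000):
            L = int(rng.integers(20, 300))
            n = int(rng.integers(1, 50))
            starts = rng.integers(1, L + 1, size=n)
            ends = np.minimum(L, starts + rng.integers(0, 60, size=n))
            hits = [_hit(f"r{i}", "g", 1e-9, a=int(a), b=int(b), L=L)
                    for i, (a, b) in enumerate(zip(starts, ends))]
            _, cov = rp.gene_presence(hits, L)
            bitmap = np.zeros(L, dtype=bool)
            for a, b in zip(starts, ends):
                bitmap[a - 1:b] = True
            assert cov == pytest.approx(bitmap.sum() / L)

    def test_presence_monotone_under_hit_addition(self, rng):
        L = 150
        hits = [_hit("r0", "g", 1e-9, a=1, b=30, L=L)]
        _, prev = rp.gene_presence(hits, L)
        for i in range(30):
            a = int(rng.integers(1, L))
            b = min(L, a + int(rng.integers(0, 40)))
            hits.append(_hit(f"r{i+1}", "g", 1e-9, a=a, b=b, L=L))
            present, cov = rp.gene_presence(hits, L)
            assert cov >= prev - 1e-15
            prev = cov


def _toy_table():
    """4 reads, one gene (L=200), one taxon, depth 1e6."""
    md = {"S1": SampleMetadata("S1", "study1", "u1", "back", "sebaceous",
                               1_000_000)}
    hits = {"S1": [_hit(f"r{i}", "cobA", 1e-9, a=1, b=50, L=200)
                   for i in range(4)]}
    tax = {"S1": [TaxonAssignment(f"r{i}", 7, "SpA", "species")
                  for i in range(4)]}
    return hits, tax, md


class TestBuildGeneTaxonTable:
    def test_normalization_definitions(self):
        hits, tax, md = _toy_table()
        t = rp.build_gene_taxon_table(hits, tax, md, {"cobA": 200})
        row = t.entries.iloc[0]
        assert row.raw_hits == 4
        assert row.norm_length == pytest.approx(0.02)
        assert row.norm_length_depth == pytest.approx(0.02)  # 0.02/1e6*1e6

    def test_presence_gate_removes_low_coverage_gene(self):
        hits, tax, md = _toy_table()
        # all envelopes identical: coverage 50/300 < 0.2 for L=300
        hits["S1"] = [_hit(f"r{i}", "cobA", 1e-9, a=1, b=50, L=300)
                      for i in range(4)]
        t = rp.build_gene_taxon_table(hits, tax, md, {"cobA": 300})
        assert len(t) == 0

    def test_unclassified_bucket(self):
        hits, tax, md = _toy_table()
        tax["S1"] = tax["S1"][:2]  # two reads have no assignment
        t = rp.build_gene_taxon_table(hits, tax, md, {"cobA": 200})
        assert set(t.entries.taxon) == {"SpA", rp.UNCLASSIFIED}

    def test_missing_sample_metadata(self):
        hits, tax, _ = _toy_table()
        with pytest.raises(KeyError):
            rp.build_gene_taxon_table(hits, tax, {}, {"cobA": 200})

    def test_matches_groupby_oracle(self, small_dataset, small_truth):
        hits, tax, md, truth = small_dataset
        best = {s: rp.select_best_hits(v) for s, v in hits.items()}
        t = rp.build_gene_taxon_table(best, tax, md, truth.hmm_lengths)
        # independent count: group retained reads by (sample, gene, taxon)
        rows = []
        for s, hs in best.items():
            assign = {a.read_id: a.taxon_name for a in tax[s]
                      if a.rank != "unclassified"}
            by_gene = {}
            for h in hs:
                by_gene.setdefault(h.hmm_name, []).append(h)
            for g, ghits in by_gene.items():
                present, _ = rp.gene_presence(ghits, truth.hmm_lengths[g])
                if not present:
                    continue
                for h in ghits:
                    rows.append((s, g, assign.get(h.read_id, rp.UNCLASSIFIED)))
        oracle = (pd.DataFrame(rows, columns=["sample_id", "gene", "taxon"])
                  .value_counts().rename("raw_hits").reset_index())
        merged = t.entries.merge(oracle, on=["sample_id", "gene", "taxon"],
                                 suffixes=("", "_oracle"), how="outer")
        assert not merged.isna().any().any()
        assert (merged.raw_hits == merged.raw_hits_oracle).all()

    def test_normalizations_linear_in_raw_hits(self, small_dataset, small_truth):
        hits, tax, md, truth = small_dataset
        best = {s: rp.select_best_hits(v) for s, v in hits.items()}
        t = rp.build_gene_taxon_table(best, tax, md, truth.hmm_lengths)
        doubled = t.entries.copy()
        doubled["raw_hits"] *= 2
        lengths = doubled.gene.map(truth.hmm_lengths)
        assert np.allclose(doubled.raw_hits / lengths, 2 * t.entries.norm_length)


class TestFilterRarePairs:
    @staticmethod
    def _table_for(samples_by_pair, studies):
        rows, md = [], {}
        for (gene, taxon), samples in samples_by_pair.items():
            for s in samples:
                rows.append((s, gene, taxon, 1, 0.01, 0.01))
        all_samples = {s for ss in samples_by_pair.values() for s in ss}
        for s in all_samples:
            md[s] = SampleMetadata(s, studies[s], "u", "back", "sebaceous", 100)
        df = pd.DataFrame(rows, columns=["sample_id", "gene", "taxon",
                                         "raw_hits", "norm_length",
                                         "norm_length_depth"])
        return rp.GeneTaxonTable(df), md

    def test_single_study_removed(self):
        samples = [f"S{i}" for i in range(6)]
        t, md = self._table_for({("g", "t"): samples},
                                {s: "study1" for s in samples})
        assert len(rp.filter_rare_pairs(t, md)) == 0

    def test_boundary_kept(self):
        samples = [f"S{i}" for i in range(5)]
        studies = {s: ("study1" if i < 3 else "study2")
                   for i, s in enumerate(samples)}
        t, md = self._table_for({("g", "t"): samples}, studies)
        assert len(rp.filter_rare_pairs(t, md)) == 5

    def test_matches_enumeration_oracle(self, rng):
        """Random tables vs brute-force support-set enumeration."""
        params = rp.ProfilingParams()
        total_pairs = 0
        while total_pairs < 1000:
            n_samples = int(rng.integers(6, 15))
            md = {f"S{i}": SampleMetadata(
                f"S{i}", f"study{rng.integers(1, 4)}", "u", "x", "dry", 100)
                for i in range(n_samples)}
            rows = []
            for g in "AB":
                for t in "uvw":
                    for i in range(n_samples):
                        if rng.random() < 0.4:
                            rows.append((f"S{i}", g, t, 1, .01, .01))
            if not rows:
                continue
            df = pd.DataFrame(rows, columns=["sample_id", "gene", "taxon",
                                             "raw_hits", "norm_length",
                                             "norm_length_depth"])
            table = rp.GeneTaxonTable(df)
            out = rp.filter_rare_pairs(table, md, params)
            kept = set(zip(out.entries.gene, out.entries.taxon))
            expected = set()
            for (g, t), sub in df.groupby(["gene", "taxon"]):
                ss = set(sub.sample_id)
                studies = {md[s].study_id for s in ss}
                if len(ss) >= params.min_samples and len(studies) >= params.min_datasets:
                    expected.add((g, t))
            assert kept == expected
            total_pairs += df.groupby(["gene", "taxon"]).ngroups

    def test_idempotent(self, small_dataset, small_truth):
        hits, tax, md, truth = small_dataset
        best = {s: rp.select_best_hits(v) for s, v in hits.items()}
        t = rp.build_gene_taxon_table(best, tax, md, truth.hmm_lengths)
        once = rp.filter_rare_pairs(t, md)
        twice = rp.filter_rare_pairs(once, md)
        pd.testing.assert_frame_equal(once.entries, twice.entries)


class TestRemoveContaminants:
    def test_identity_and_complement(self, small_dataset, small_truth):
        hits, tax, md, truth = small_dataset
        best = {s: rp.select_best_hits(v) for s, v in hits.items()}
        t = rp.build_gene_taxon_table(best, tax, md, truth.hmm_lengths)
        assert len(rp.remove_contaminants(t, set())) == len(t)
        assert len(rp.remove_contaminants(t, t.taxa)) == 0
        some = set(list(t.taxa)[:3])
        out = rp.remove_contaminants(t, some)
        assert out.taxa == t.taxa - some
        assert len(out) == (~t.entries.taxon.isin(some)).sum()


class TestContributionsAndProfiles:
    def test_simple_ratio(self):
        df = pd.DataFrame([
            ("S1", "cobA", "A", 30, 3.0, 3.0),
            ("S1", "cobA", "B", 10, 1.0, 1.0),
        ], columns=["sample_id", "gene", "taxon", "raw_hits", "norm_length",
                    "norm_length_depth"])
        out = rp.taxon_contribution(rp.GeneTaxonTable(df), "S1", {"cobA"})
        assert out == pytest.approx({"A": 0.75, "B": 0.25})

    def test_single_taxon_is_one(self):
        df = pd.DataFrame([("S1", "cobA", "A", 5, 0.5, 0.5)],
                          columns=["sample_id", "gene", "taxon", "raw_hits",
                                   "norm_length", "norm_length_depth"])
        assert rp.taxon_contribution(rp.GeneTaxonTable(df), "S1", {"cobA"}) == {
            "A": 1.0}

    def test_zero_denominator_errors(self):
        df = pd.DataFrame([("S1", "cobA", "A", 5, 0.5, 0.5)],
                          columns=["sample_id", "gene", "taxon", "raw_hits",
                                   "norm_length", "norm_length_depth"])
        with pytest.raises(ValueError, match="no hits"):
            rp.taxon_contribution(rp.GeneTaxonTable(df), "S1", {"cbiL"})

    def test_probability_vectors_on_synthetic(self, small_dataset, small_truth):
        hits, tax, md, truth = small_dataset
        best = {s: rp.select_best_hits(v) for s, v in hits.items()}
        t = rp.build_gene_taxon_table(best, tax, md, truth.hmm_lengths)
        genes = set(rp.MARKER_GENES_11)
        for s in t.samples:
            contrib = rp.taxon_contribution(t, s, genes)
            assert all(v >= 0 for v in contrib.values())
            assert sum(contrib.values()) == pytest.approx(1.0, abs=1e-12)
        for g in t.genes:
            prof = rp.gene_frequency_profile(t, g)
            assert sum(prof.values()) == pytest.approx(1.0, abs=1e-12)

    def test_contribution_matches_manual_ratio(self, small_dataset, small_truth):
        hits, tax, md, truth = small_dataset
        best = {s: rp.select_best_hits(v) for s, v in hits.items()}
        t = rp.build_gene_taxon_table(best, tax, md, truth.hmm_lengths)
        genes = set(rp.MARKER_GENES_11)
        s = sorted(t.samples)[0]
        sub = t.entries.query("sample_id == @s and gene in @genes")
        manual = sub.groupby("taxon").norm_length.sum()
        manual /= manual.sum()
        out = rp.taxon_contribution(t, s, genes)
        for taxon, v in manual.items():
            assert out[taxon] == pytest.approx(v)

    def test_gene_profile_uses_depth_normalization(self):
        df = pd.DataFrame([
            ("S1", "cobA", "A", 1, 1.0, 4.0),
            ("S2", "cobA", "B", 1, 1.0, 12.0),
        ], columns=["sample_id", "gene", "taxon", "raw_hits", "norm_length",
                    "norm_length_depth"])
        prof = rp.gene_frequency_profile(rp.GeneTaxonTable(df), "cobA")
        assert prof == pytest.approx({"A": 0.25, "B": 0.75})


class TestProducerCalls:
    @staticmethod
    def _table_with_markers(marker_counts):
        rows = []
        for taxon, k in marker_counts.items():
            for g in rp.PRODUCER_MARKERS_10[:k]:
                rows.append(("S1", g, taxon, 1, .01, .01))
        df = pd.DataFrame(rows, columns=["sample_id", "gene", "taxon",
                                         "raw_hits", "norm_length",
                                         "norm_length_depth"])
        return rp.GeneTaxonTable(df)

    def test_boundary_five_of_ten(self):
        t = self._table_with_markers({"A": 5, "B": 4})
        assert rp.call_metagenomic_producers(t) == {"A"}

    def test_planted_recovery(self, small_dataset, small_truth):
        hits, tax, md, truth = small_dataset
        best = {s: rp.select_best_hits(v) for s, v in hits.items()}
        t = rp.build_gene_taxon_table(best, tax, md, truth.hmm_lengths)
        t = rp.filter_rare_pairs(t, md)
        assert rp.call_metagenomic_producers(t) == truth.producers


class TestMockFalsePositiveRate:
    def test_simple_ratio(self):
        df = pd.DataFrame([
            ("M1", "cobA", "A", 998, 1.0, 1.0),
            ("M1", "cobA", "X", 2, 0.1, 0.1),
        ], columns=["sample_id", "gene", "taxon", "raw_hits", "norm_length",
                    "norm_length_depth"])
        assert rp.mock_false_positive_rate(
            rp.GeneTaxonTable(df), {"A"}) == pytest.approx(0.002)

    def test_unclassified_excluded(self):
        df = pd.DataFrame([
            ("M1", "cobA", "A", 50, 1.0, 1.0),
            ("M1", "cobA", rp.UNCLASSIFIED, 50, 1.0, 1.0),
        ], columns=["sample_id", "gene", "taxon", "raw_hits", "norm_length",
                    "norm_length_depth"])
        assert rp.mock_false_positive_rate(rp.GeneTaxonTable(df), {"A"}) == 0.0

    def test_zero_total_errors(self):
        df = pd.DataFrame(columns=["sample_id", "gene", "taxon", "raw_hits",
                                   "norm_length", "norm_length_depth"])
        with pytest.raises(ValueError):
            rp.mock_false_positive_rate(rp.GeneTaxonTable(df), {"A"})
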