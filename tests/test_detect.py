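"""BSJ caller: index correctness, junction detection, filters, merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from circsponge import (
    DetectionParams,
    build_index,
    call_sample,
    detect_bsj_in_read,
    filter_candidates,
    merge_across_samples,
    revcomp,
    simulate_reads,
)
from circsponge.detect import BsjCandidate, GenomeIndex, junction_key_to_coords

from _oracles import brute_force_kmer_hits, splice_scan_oracle
from conftest import small_config

Q37 = chr(37 + 33)


def _mk_candidate(support=2, unique=None, phred=37.0, span=500, ambiguous=False):
    c = BsjCandidate(contig="chr1", strand="+", start=1000, end=1000 + span)
    unique = support if unique is None else unique
    for i in range(support):
        c.supporting_read_ids.add(f"r{i}")
        c._unique_frags[f"r{i}"] = i < unique
    c.min_junction_phred = phred
    c.breakpoint_ambiguous = ambiguous
    return c


class TestGenomeIndex:
    def test_simple_contig_positions(self):
        idx = GenomeIndex({"c": "ACGTACGT"}, k=4)
        assert sorted(p for _, p in idx.lookup("ACGT")) == [0, 4]
        assert idx.lookup("AAAA") == []

    def test_query_covers_both_strands(self):
        idx = GenomeIndex({"c": "AAAACCCC"}, k=4)
        # GGGG occurs only as the - strand of CCCC at +strand position 4
        assert idx.query("GGGG") == [("c", 4, "-")]

    def test_matches_brute_force_scan_on_random_kmers(self):
        rng = np.random.default_rng(12)
        contigs = {"c1": "".join(rng.choice(list("ACGT"), 10_000)),
                   "c2": "".join(rng.choice(list("ACGT"), 3_000))}
        idx = GenomeIndex(contigs, k=8)
        for _ in range(100):
            kmer = "".join(rng.choice(list("ACGT"), 8))
            assert set(idx.query(kmer)) == brute_force_kmer_hits(contigs, kmer)

    def test_k_longer_than_shortest_contig_rejected(self):
        with pytest.raises(ValueError):
            GenomeIndex({"c": "ACGT"}, k=10)


@pytest.fixture(scope="module")
def sim():
    cfg = small_config(seed=2)
    from circsponge import generate_genome, plant_circrnas

    genome = generate_genome(cfg)
    truths = plant_circrnas(genome, cfg)
    return genome, truths, build_index(genome, 20)


@pytest.fixture(scope="module")
def sim_index_and_reads(sim):
    genome, truths, index = sim
    t = truths[0]
    return index, t, t.spliced_sequence(genome)


class TestDetectBsjInRead:
    def test_planted_circle_read_yields_exact_coordinates(self, sim):
        genome, truths, index = sim
        for t in truths:
            s = t.spliced_sequence(genome)
            read = s[-30:] + s[:45]  # junction 30 nt from the left end
            ev = detect_bsj_in_read(read, Q37 * 75, index)
            assert ev is not None, t.circ_id
            assert (ev.contig, ev.strand, ev.start, ev.end) == t.key

    def test_reverse_complement_read_maps_to_same_junction(self, sim):
        genome, truths, index = sim
        t = truths[0]
        s = t.spliced_sequence(genome)
        read = revcomp(s[-30:] + s[:45])
        ev = detect_bsj_in_read(read, Q37 * 75, index)
        assert ev is not None and (ev.contig, ev.strand, ev.start, ev.end) == t.key

    def test_colinear_read_returns_none(self, sim):
        genome, _, index = sim
        g = genome.genes[0]
        read = genome.contigs[g.contig][g.exons[0].start : g.exons[0].start + 75]
        assert detect_bsj_in_read(read, Q37 * 75, index) is None

    def test_homologous_junction_flanks_are_ambiguous(self):
        """Identical sequence on both sides of the breakpoint allows two
        equal-score splits; the read must be discarded."""
        rng = np.random.default_rng(5)
        rand = lambda n: "".join(rng.choice(list("ACGT"), n))
        dup = rand(6)
        left_exon = rand(60) + dup  # circle 3' end ...dup
        right_exon = dup + rand(60)  # circle 5' start dup...
        spacer = rand(300)
        contig = rand(100) + "AG" + right_exon + spacer + left_exon + "GT" + rand(100)
        # also write a canonical signal 6 nt earlier so the shifted split stays viable
        idx = build_index({"c": contig}, 20)
        read = left_exon[-38:] + right_exon[:37]
        params = DetectionParams(require_canonical_splice=False)
        assert detect_bsj_in_read(read, Q37 * 75, idx, params) is None

    def test_short_read_returns_none(self, sim):
        *_, index = sim
        assert detect_bsj_in_read("ACGT" * 10, Q37 * 40, index) is None

    def test_agrees_with_exhaustive_splice_scan(self, sim):
        """Oracle equivalence on a small genome: detected coordinates equal an
        exhaustive splice-scan over every breakpoint and placement."""
        genome, truths, _ = sim
        contig = truths[0].contig
        sub = {contig: genome.contigs[contig]}  # single 100 kb contig
        index = build_index(sub, 20)
        rng = np.random.default_rng(7)
        reads = []
        for t in truths:
            if t.contig != contig:
                continue
            s = t.spliced_sequence(genome)
            a = int(rng.integers(20, 56))
            reads.append(s[-a:] + s[: 75 - a])
        g = genome.genes[0]
        reads.append(genome.contigs[g.contig][g.exons[1].start :][:75])  # colinear
        reads.append("".join(rng.choice(list("ACGT"), 75)))  # random
        assert len(reads) > 5
        for read in reads:
            ev = detect_bsj_in_read(read, Q37 * 75, index)
            got = None if ev is None else (ev.contig, ev.strand, ev.start, ev.end)
            assert got == splice_scan_oracle(read, sub)


class TestCallSample:
    def test_two_reads_one_junction_aggregates_support(self, tmp_path, sim_index_and_reads):
        index, t, s = sim_index_and_reads
        fq = tmp_path / "x.fastq"
        fq.write_text(
            f"@r1\n{s[-30:] + s[:45]}\n+\n{Q37 * 75}\n@r2\n{s[-40:] + s[:35]}\n+\n{Q37 * 75}\n"
        )
        cands = call_sample(fq, index)
        assert len(cands) == 1
        assert cands[0].n_support == 2 and cands[0].n_unique_support == 2
        assert cands[0].key == t.key

    def test_paired_mates_count_once_per_fragment(self, tmp_path, sim_index_and_reads):
        index, t, s = sim_index_and_reads
        fq = tmp_path / "p.fastq"
        fq.write_text(
            f"@f1/1\n{s[-30:] + s[:45]}\n+\n{Q37 * 75}\n@f1/2\n{s[-40:] + s[:35]}\n+\n{Q37 * 75}\n"
        )
        cands = call_sample(fq, index)
        assert len(cands) == 1 and cands[0].n_support == 1

    def test_empty_fastq(self, tmp_path, sim_index_and_reads):
        index, *_ = sim_index_and_reads
        fq = tmp_path / "empty.fastq"
        fq.write_text("")
        assert call_sample(fq, index) == []

    def test_malformed_fastq_raises_with_record_index(self, tmp_path, sim_index_and_reads):
        index, *_ = sim_index_and_reads
        fq = tmp_path / "bad.fastq"
        fq.write_text("@r1\nACGT\n+\n" + Q37 * 4 + "\n@r2\nACGTACGT\n+\n" + Q37 * 3 + "\n")
        with pytest.raises(ValueError, match="record"):
            call_sample(fq, index)

    def test_simulated_sample_recovers_planted_junctions(self, tmp_path):
        cfg = small_config(seed=13, n_samples=1, raw_reads_per_sample=5_000)
        from circsponge import generate_genome, plant_circrnas

        genome = generate_genome(cfg)
        truths = plant_circrnas(genome, cfg)
        manifest = simulate_reads(genome, truths, cfg, tmp_path)
        index = build_index(genome, 20)
        cands = filter_candidates(call_sample(manifest.iloc[0]["fastq"], index))
        got = {c.key for c in cands}
        truth_keys = {t.key for t in truths}
        assert len(got & truth_keys) >= len(truths) - 1
        assert not got - truth_keys  # no false junctions


class TestFilters:
    @pytest.mark.parametrize(
        "kwargs,kept",
        [
            (dict(support=1), False),  # fewer than two unique supporting reads
            (dict(support=2, phred=35.0), True),  # Phred exactly at the threshold
            (dict(support=5, phred=34.0), False),  # quality just below threshold
            (dict(support=3, unique=1), False),  # support without uniqueness
            (dict(support=2, span=2_000_000), False),  # exceeds the span cap
            (dict(support=2, ambiguous=True), False),
        ],
    )
    def test_stringency_rules(self, kwargs, kept):
        cands = filter_candidates([_mk_candidate(**kwargs)])
        assert bool(cands) == kept

    @given(
        support=st.integers(1, 6),
        unique=st.integers(0, 6),
        phred=st.floats(20, 45),
        bump_support=st.integers(0, 3),
        bump_phred=st.floats(0, 10),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_raising_thresholds_never_grows_the_set(
        self, support, unique, phred, bump_support, bump_phred
    ):
        cand = _mk_candidate(support=support, unique=min(unique, support), phred=phred)
        lax = DetectionParams()
        strict = DetectionParams(
            min_unique_support=lax.min_unique_support + bump_support,
            min_junction_phred=lax.min_junction_phred + bump_phred,
        )
        kept_strict = filter_candidates([cand], strict)
        kept_lax = filter_candidates([cand], lax)
        assert set(c.key for c in kept_strict) <= set(c.key for c in kept_lax)


class TestMerge:
    def _sampleset(self, n_with, n_without, start=100):
        cand = lambda: _mk_candidate(support=3)
        per_sample = {}
        for i in range(n_with):
            per_sample[f"S{i:02d}"] = [cand()]
        for i in range(n_with, n_with + n_without):
            per_sample[f"S{i:02d}"] = []
        return per_sample

    def test_junction_in_30_of_40_samples_is_retained(self):
        mat = merge_across_samples(self._sampleset(30, 10))
        assert len(mat) == 1 and (mat.iloc[0] > 0).sum() == 30

    def test_junction_in_29_of_40_samples_is_dropped(self):
        assert len(merge_across_samples(self._sampleset(29, 11))) == 0

    def test_default_threshold_is_three_quarters(self):
        # 6 samples -> ceil(4.5) = 5
        assert len(merge_across_samples(self._sampleset(5, 1))) == 1
        assert len(merge_across_samples(self._sampleset(4, 2))) == 0

    def test_identical_samples_reproduce_single_sample_list(self):
        cands = [_mk_candidate(support=4)]
        per_sample = {f"S{i}": cands for i in range(8)}
        mat = merge_across_samples(per_sample)
        assert len(mat) == 1
        contig, strand, start, end = junction_key_to_coords(mat.index[0])
        assert (contig, strand, start, end) == cands[0].key
        assert (mat.values == 4).all()

    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            merge_across_samples([("S1", []), ("S1", [])])

    def test_counts_zero_where_undetected(self):
        per_sample = self._sampleset(5, 1)
        mat = merge_across_samples(per_sample, min_samples=5)
        assert mat.iloc[0, -1] == 0
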