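"""Generator correctness: determinism, planted truth self-consistency, models."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from circsponge import (
    SimulationConfig,
    generate_genome,
    plant_circrnas,
    simulate_mirna_profiles,
    simulate_phenotypes,
    simulate_reads,
    revcomp,
)
from circsponge.simulate import PlacementError

from conftest import small_config


def _dir_digest(d: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(Path(d).rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


class TestGenerateGenome:
    def test_deterministic_bytes(self, tmp_path):
        for sub in ("a", "b"):
            d = tmp_path / sub
            d.mkdir()
            cfg = small_config(seed=9, n_samples=3, raw_reads_per_sample=500)
            genome = generate_genome(cfg)
            truths = plant_circrnas(genome, cfg)
            simulate_mirna_profiles(genome, truths, cfg)
            genome.write_fasta(d / "g.fa")
            genome.write_gtf(d / "g.gtf")
            simulate_reads(genome, truths, cfg, d / "reads")
        assert _dir_digest(tmp_path / "a") == _dir_digest(tmp_path / "b")

    def test_no_genes_gives_contigs_only(self):
        cfg = small_config(n_genes=0, n_circ_per_class={})
        genome = generate_genome(cfg)
        assert genome.genes == [] and len(genome.contigs) == cfg.n_contigs

    def test_exons_within_contig_bounds_exhaustively(self):
        genome = generate_genome(small_config(seed=4))
        assert genome.genes
        for g in genome.genes:
            clen = len(genome.contigs[g.contig])
            for e in g.exons:
                assert 0 <= e.start < e.end <= clen

    def test_intron_boundaries_carry_splice_signal(self):
        genome = generate_genome(small_config(seed=5))
        for g in genome.genes:
            seq = genome.contigs[g.contig]
            for iv in g.introns():
                intron = seq[iv.start : iv.end]
                if g.strand == "-":
                    intron = revcomp(intron)
                assert intron[:2] == "GT" and intron[-2:] == "AG"

    def test_too_small_contig_raises(self):
        with pytest.raises(PlacementError):
            generate_genome(small_config(contig_length=5_000, n_genes=30))


class TestPlantCircrnas:
    def test_requested_class_counts_met_exactly(self, planted_genome):
        cfg, _, truths = planted_genome
        got = {}
        for t in truths:
            got[t.true_class] = got.get(t.true_class, 0) + 1
        assert got == cfg.n_circ_per_class

    def test_spliced_length_is_sum_of_exons(self, planted_genome):
        _, _, truths = planted_genome
        for t in truths:
            assert t.spliced_length() == sum(len(e) for e in t.exons)

    def test_all_junctions_flanked_by_canonical_dinucleotides(self, planted_genome):
        """GT immediately 3' of the donor, AG immediately 5' of the acceptor,
        read on the annotated strand."""
        _, genome, truths = planted_genome
        for t in truths:
            seq = genome.contigs[t.contig]
            before, after = seq[t.start - 2 : t.start], seq[t.end : t.end + 2]
            if t.strand == "+":
                assert (before, after) == ("AG", "GT"), t.circ_id
            else:
                # on -, the + strand reads the reverse complements, swapped
                assert (before, after) == ("AC", "CT"), t.circ_id

    def test_intronic_circles_sit_inside_one_intron(self, planted_genome):
        _, genome, truths = planted_genome
        genes = {g.gene_id: g for g in genome.genes}
        for t in truths:
            if t.true_class != "intronic":
                continue
            host = genes[t.host_gene]
            assert any(iv.start <= t.start and t.end <= iv.end for iv in host.introns())

    def test_intergenic_circles_avoid_genes(self, planted_genome):
        _, genome, truths = planted_genome
        for t in truths:
            if t.true_class != "intergenic":
                continue
            for g in genome.genes:
                if g.contig == t.contig:
                    assert t.end <= g.span.start or t.start >= g.span.end

    def test_not_enough_loci_raises_with_class_name(self):
        cfg = small_config(n_genes=2, n_circ_per_class={"intronic": 500})
        genome = generate_genome(cfg)
        with pytest.raises(PlacementError, match="intronic"):
            plant_circrnas(genome, cfg)


class TestSimulateReads:
    def test_bsj_reads_reconstruct_from_truth_coordinates(self, tmp_path):
        """Every BSJ read is a suffix of the circle followed by its prefix."""
        cfg = small_config(seed=6, n_samples=2, raw_reads_per_sample=300, substitution_rate=0.0)
        genome = generate_genome(cfg)
        truths = plant_circrnas(genome, cfg)
        simulate_reads(genome, truths, cfg, tmp_path)
        circ = {t.circ_id: t.spliced_sequence(genome) for t in truths}
        L = cfg.read_length
        n_checked = 0
        for line_name, line_seq in _fastq_records(tmp_path / "S01.fastq"):
            if ":bsj" not in line_name:
                continue
            _, _, cid, a_tag = line_name.split(":")
            a = int(a_tag[1:])
            s = circ[cid]
            assert line_seq == s[len(s) - a :] + s[: L - a]
            assert a >= cfg.anchor_margin and L - a >= cfg.anchor_margin
            n_checked += 1
        assert n_checked > 0

    def test_manifest_totals_match_record_counts(self, small_study):
        for _, row in small_study["manifest"].iterrows():
            n_lines = sum(1 for _ in open(row["fastq"]))
            assert n_lines == 4 * row["n_reads"]

    def test_zero_abundance_circle_yields_no_reads(self, tmp_path):
        cfg = small_config(seed=8, n_samples=2, raw_reads_per_sample=300)
        genome = generate_genome(cfg)
        truths = plant_circrnas(genome, cfg)
        silenced = truths[0]
        silenced.abundance[:] = 0.0
        simulate_reads(genome, truths, cfg, tmp_path)
        for fq in tmp_path.glob("S*.fastq"):
            assert not any(silenced.circ_id in name for name, _ in _fastq_records(fq))

    def test_read_length_shorter_than_anchors_rejected(self):
        with pytest.raises(ValueError):
            small_config(read_length=40, anchor_margin=20).validate()


class TestMirnaProfiles:
    def test_planted_seed_complement_in_circle_sequence(self, tmp_path):
        cfg = small_config(seed=3)
        genome = generate_genome(cfg)
        truths = plant_circrnas(genome, cfg)
        counts, seqs = simulate_mirna_profiles(genome, truths, cfg)
        planted = [(t, m) for t in truths for m in t.sponge_targets]
        assert len(planted) == cfg.n_sponge_pairs
        for t, m in planted:
            seed_rc = revcomp(seqs[m][1:8].replace("U", "T"))  # positions 2-8
            assert seed_rc in t.spliced_sequence(genome)

    def test_mirna_lengths_in_range(self, small_study):
        lo, hi = small_study["config"].mirna_length_range
        assert all(lo <= len(s) <= hi for s in small_study["mirna_seqs"].values())

    def test_strong_coupling_low_noise_gives_r_near_minus_one(self):
        cfg = small_config(seed=10, n_samples=200, mirna_noise_sd=1e-6, sponge_effect=-1.0)
        genome = generate_genome(cfg)
        truths = plant_circrnas(genome, cfg)
        counts, _ = simulate_mirna_profiles(genome, truths, cfg)
        t = next(t for t in truths if t.sponge_targets)
        r = np.corrcoef(np.log2(t.abundance), np.log2(counts[t.sponge_targets[0]]))[0, 1]
        assert r < -0.999

    def test_nonnegative_effect_warns(self):
        cfg = small_config(seed=3, sponge_effect=0.5)
        genome = generate_genome(cfg)
        truths = plant_circrnas(genome, cfg)
        with pytest.warns(UserWarning, match="negative"):
            simulate_mirna_profiles(genome, truths, cfg)

    def test_null_mirnas_are_independent_of_circles(self):
        """Monte-Carlo: non-sponged miRNA vs circle |r| exceeds the 5% critical
        value in about 5% of null replicates."""
        rng = np.random.default_rng(0)
        n, reps = 40, 1_000
        from scipy import stats

        crit = stats.t.ppf(0.975, n - 2)
        hits = 0
        for _ in range(reps):
            x, y = rng.normal(size=n), rng.normal(size=n)
            r = np.corrcoef(x, y)[0, 1]
            t_stat = abs(r) * np.sqrt((n - 2) / (1 - r**2))
            hits += t_stat > crit
        assert 0.03 < hits / reps < 0.07


class TestSimulatePhenotypes:
    def test_zero_effects_and_noise_give_pure_intercept(self, planted_genome):
        cfg, _, truths = planted_genome
        cfg2 = small_config(
            seed=2,
            fixed_effect_sd=0.0,
            n_causal_circles=0,
            trait_noise_sd={k: 0.0 for k in cfg.trait_noise_sd},
        )
        pheno = simulate_phenotypes(truths, cfg2)
        for tr, mu in cfg2.trait_intercepts.items():
            assert np.allclose(pheno[tr], mu)

    def test_noise_free_causal_trait_is_affine_in_log2_abundance(self, planted_genome):
        cfg, _, truths = planted_genome
        cfg2 = small_config(
            seed=2,
            fixed_effect_sd=0.0,
            n_causal_circles=1,
            trait_noise_sd={k: 0.0 for k in cfg.trait_noise_sd},
            trait_intercepts={**cfg.trait_intercepts, "motile_pct": 50.0},
        )
        pheno = simulate_phenotypes(truths, cfg2)
        t = truths[0]
        (trait, coef), = t.phenotype_effect.items()
        la = np.log2(t.abundance)
        pred = 50.0 + coef * (la - la.mean())
        assert np.allclose(pheno[trait].to_numpy(), pred)

    def test_motile_pct_clipped_to_100(self, planted_genome):
        cfg, _, truths = planted_genome
        cfg2 = small_config(seed=2, trait_intercepts={**cfg.trait_intercepts, "motile_pct": 500.0})
        pheno = simulate_phenotypes(truths, cfg2)
        assert (pheno["motile_pct"] <= 100.0).all() and pheno["motile_pct"].max() == 100.0

    def test_ages_within_declared_range(self, small_study):
        lo, hi = small_study["config"].age_months_range
        assert small_study["phenotypes"]["age_months"].between(lo, hi).all()


def _fastq_records(path):
    with open(path) as fh:
        while True:
            name = fh.readline().strip()
            if not name:
                return
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            yield name[1:], seq
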