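"""Synthetic sperm-RNA-seq study generator with planted ground truth.

Generates, deterministically under a seed, everything the downstream stages
consume: a toy genome with multi-exon genes (canonical GT/AG intron
boundaries), planted circRNAs of each genomic class, per-sample FASTQ reads
containing back-splice-junction (BSJ) spanning reads at known abundance,
miRNA profiles negatively coupled to their sponging circRNAs (with seed-match
target sites written into the circRNA sequence), and CASA motility phenotypes
driven by fixed effects plus selected circRNA abundances.

The point of the generator is that truth is known exactly: every junction
coordinate, class label, sponge pair and phenotype effect is recorded, so
recovery, calibration and error rates of the pipeline can be measured.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomePackage, GeneModel, Interval, revcomp, format_coord

CIRC_CLASSES = ("CDS", "5UTR", "3UTR", "intronic", "intergenic")

# splice dinucleotides as they read on the + strand of the genome:
# a + intron reads GT...AG left to right, a - intron reads CT...AC
_INTRON_SIGNAL = {"+": ("GT", "AG"), "-": ("CT", "AC")}
# flanks of a circle span [start, end): before start / after end
_CIRC_FLANKS = {"+": ("AG", "GT"), "-": ("AC", "CT")}


class PlacementError(RuntimeError):
    """Raised when the genome cannot host the requested planted features."""


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the study's default conditions.

    Defaults emulate the pipeline's target study design: 40 ejaculate
    samples, 75 bp reads, 20 exonic + 3 intronic + 3 intergenic planted
    circles, and 20 miRNAs of which 10 are sponged.
    """

    seed: int = 0
    n_samples: int = 40
    # genome
    n_contigs: int = 3
    contig_length: int = 100_000
    n_genes: int = 24
    exon_length_range: tuple[int, int] = (150, 350)
    intron_length_range: tuple[int, int] = (400, 900)
    exons_per_gene_range: tuple[int, int] = (5, 12)
    intergenic_gap_range: tuple[int, int] = (1_500, 3_000)
    # planted circRNAs
    n_circ_per_class: dict[str, int] = field(
        default_factory=lambda: {"CDS": 12, "5UTR": 4, "3UTR": 4, "intronic": 3, "intergenic": 3}
    )
    max_exons_per_circ: int = 10
    single_exon_circ_length_range: tuple[int, int] = (150, 300)
    # abundance model: per-circle base ~ LogNormal, per-sample multiplicative noise
    abundance_lognorm_mean: float = 3.0  # ln scale; exp(3) ~ 20 expected BSJ reads
    abundance_lognorm_sd: float = 0.7
    sample_lognorm_sd: float = 0.4
    abundance_floor: float = 5.0  # minimum expected BSJ reads per circle (base level)
    # reads
    read_length: int = 75
    paired: bool = False
    fragment_length_range: tuple[int, int] = (150, 300)
    raw_reads_per_sample: int = 20_000
    anchor_margin: int = 20  # junction offset kept >= this far from both read ends
    substitution_rate: float = 0.001
    quality_phred: int = 37
    low_quality_phred: int = 30
    n_low_quality_samples: int = 0
    # miRNAs / sponge coupling
    n_mirnas: int = 20
    n_sponge_pairs: int = 10
    mirna_length_range: tuple[int, int] = (20, 24)
    sponge_effect: float = -1.0  # coupling on log2 abundances; must be negative
    mirna_noise_sd: float = 0.58  # log2 units; with defaults gives true r ~ -0.7
    mirna_baseline_log2_mean: float = 6.0
    mirna_baseline_log2_sd: float = 1.0
    planted_site_span: int = 13  # miRNA positions 1..13 reverse-complemented into the circle
    # phenotypes
    n_causal_circles: int = 5
    # planted per-circle trait correlation; the linear coefficient on log2
    # abundance is derived from it given the trait noise and abundance spread
    phenotype_target_r: float = 0.6
    trait_intercepts: dict[str, float] = field(
        default_factory=lambda: {"motile_pct": 75.0, "vcl": 100.0, "vsl": 50.0, "vap": 70.0}
    )
    trait_noise_sd: dict[str, float] = field(
        default_factory=lambda: {"motile_pct": 5.0, "vcl": 10.0, "vsl": 6.0, "vap": 8.0}
    )
    fixed_effect_sd: float = 3.0
    n_farms: int = 3
    n_age_classes: int = 3
    n_season_years: int = 9
    age_months_range: tuple[float, float] = (9.0, 54.0)

    def validate(self) -> None:
        if self.read_length < 2 * self.anchor_margin + 1:
            raise ValueError("read_length must be >= 2*anchor_margin + 1")
        if self.n_samples < 1 or self.n_contigs < 1 or self.contig_length < 1:
            raise ValueError("sample/contig counts and lengths must be positive")
        for cls in self.n_circ_per_class:
            if cls not in CIRC_CLASSES:
                raise ValueError(f"unknown circRNA class {cls!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]


@dataclass
class TruthCircRNA:
    """A planted circRNA with full ground truth.

    ``start``/``end`` delimit the genomic span [start, end); on ``+`` the
    acceptor is ``start`` and the donor ``end``, reversed on ``-``.
    ``abundance`` holds the expected BSJ read count per sample.
    """

    circ_id: str
    contig: str
    strand: str
    start: int
    end: int
    exons: list[Interval]
    true_class: str
    host_gene: str | None = None
    abundance: np.ndarray | None = None
    sponge_targets: list[str] = field(default_factory=list)
    phenotype_effect: dict[str, float] = field(default_factory=dict)

    @property
    def donor_pos(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def acceptor_pos(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.contig, self.strand, self.start, self.end)

    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def spliced_sequence(self, genome: GenomePackage) -> str:
        return genome.spliced_sequence(self.contig, self.strand, self.exons)

    @property
    def display_coord(self) -> str:
        return format_coord(self.contig, self.start, self.end)


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return [("A", "C", "G", "T")[i] for i in rng.integers(0, 4, size=n)]


def generate_genome(config: SimulationConfig) -> GenomePackage:
    """Build random contigs and lay out genes with canonical splice signals.

    Genes are placed left to right with intergenic gaps; each gene has
    5--12 exons (first two 5'UTR, last two 3'UTR in transcript order, the
    rest CDS) and GT/AG dinucleotides written at every intron boundary on the
    annotated strand.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    contigs: dict[str, list[str]] = {
        f"chr{i + 1}": _random_seq(rng, config.contig_length) for i in range(config.n_contigs)
    }
    contig_ids = list(contigs)
    genes: list[GeneModel] = []
    cursors = {c: int(rng.integers(*config.intergenic_gap_range)) for c in contig_ids}
    ci = 0
    attempts = 0
    while len(genes) < config.n_genes:
        if attempts > config.n_genes * config.n_contigs * 4:
            raise PlacementError(
                f"contigs too small to place {config.n_genes} genes "
                f"(placed {len(genes)})"
            )
        attempts += 1
        contig = contig_ids[ci % len(contig_ids)]
        ci += 1
        n_exons = int(rng.integers(config.exons_per_gene_range[0], config.exons_per_gene_range[1] + 1))
        exon_lens = rng.integers(*config.exon_length_range, size=n_exons)
        intron_lens = rng.integers(*config.intron_length_range, size=n_exons - 1)
        gene_len = int(exon_lens.sum() + intron_lens.sum())
        start = cursors[contig]
        if start + gene_len + config.intergenic_gap_range[1] + 10 > config.contig_length:
            continue  # no room on this contig; try the next
        strand = "+" if rng.random() < 0.5 else "-"
        exons: list[Interval] = []
        pos = start
        for k in range(n_exons):
            exons.append(Interval(pos, pos + int(exon_lens[k])))
            pos += int(exon_lens[k])
            if k < n_exons - 1:
                pos += int(intron_lens[k])
        seq = contigs[contig]
        left_sig, right_sig = _INTRON_SIGNAL[strand]
        for a, b in ((e.end, f.start) for e, f in zip(exons, exons[1:])):
            seq[a], seq[a + 1] = left_sig[0], left_sig[1]
            seq[b - 2], seq[b - 1] = right_sig[0], right_sig[1]
        # transcript-order feature assignment: 2 UTR exons each end, CDS between
        tx_order = exons if strand == "+" else exons[::-1]
        utr5, utr3 = tx_order[:2], tx_order[-2:]
        cds = tx_order[2:-2]
        gid = f"gene{len(genes) + 1:03d}"
        genes.append(
            GeneModel(
                gene_id=gid,
                contig=contig,
                strand=strand,
                exons=exons,
                cds=sorted(cds, key=lambda e: e.start),
                utr5=sorted(utr5, key=lambda e: e.start),
                utr3=sorted(utr3, key=lambda e: e.start),
            )
        )
        cursors[contig] = exons[-1].end + int(rng.integers(*config.intergenic_gap_range))
    pkg = GenomePackage(contigs={c: "".join(s) for c, s in contigs.items()}, genes=genes)
    pkg.validate()
    return pkg


def _feature_exon_indices(gene: GeneModel, cls: str) -> list[int]:
    """Genomic indices of internal exons wholly of one feature class.

    Terminal exons are excluded: a circle junction there would lack a
    flanking intron and hence a canonical splice signal.
    """
    feats = {"CDS": gene.cds, "5UTR": gene.utr5, "3UTR": gene.utr3}[cls]
    idx = []
    for i, e in enumerate(gene.exons):
        if 0 < i < len(gene.exons) - 1 and any(f.contains(e) for f in feats):
            idx.append(i)
    return idx


def _write_flanks(contigs: dict[str, list[str]], t_contig: str, strand: str, start: int, end: int) -> None:
    seq = contigs[t_contig]
    before, after = _CIRC_FLANKS[strand]
    seq[start - 2], seq[start - 1] = before[0], before[1]
    seq[end], seq[end + 1] = after[0], after[1]


def plant_circrnas(genome: GenomePackage, config: SimulationConfig) -> list[TruthCircRNA]:
    """Plant circRNAs of the requested classes and draw their abundances.

    Exonic circles (CDS/5UTR/3UTR) use consecutive same-feature exons of one
    gene, so their junctions reuse the gene's own GT/AG intron boundaries.
    Intronic and intergenic circles are carved out of introns / gene-free
    gaps and get synthetic GT/AG flanks written into the genome so they
    carry a canonical splice signal like every other planted junction.

    Mutates ``genome.contigs`` (flank writing) in place.
    """
    rng = np.random.default_rng(config.seed + 1)
    requested = {c: int(n) for c, n in config.n_circ_per_class.items() if n}
    if any(cls in requested for cls in ("CDS", "5UTR", "3UTR", "intronic")) and not genome.genes:
        raise PlacementError("exonic/intronic circles requested but the genome has no genes")

    contigs_mut = {c: list(s) for c, s in genome.contigs.items()}
    truths: list[TruthCircRNA] = []
    used_junctions: set[tuple] = set()

    def add(contig, strand, exons, cls, host):
        start, end = exons[0].start, exons[-1].end
        key = (contig, strand, start, end)
        if key in used_junctions:
            return False
        used_junctions.add(key)
        truths.append(
            TruthCircRNA(
                circ_id=f"circ{len(truths) + 1:04d}",
                contig=contig,
                strand=strand,
                start=start,
                end=end,
                exons=list(exons),
                true_class=cls,
                host_gene=host,
            )
        )
        return True

    # --- exonic classes -------------------------------------------------
    for cls in ("CDS", "5UTR", "3UTR"):
        need = requested.get(cls, 0)
        genes = [g for g in genome.genes if _feature_exon_indices(g, cls)]
        tries = 0
        while need > 0:
            tries += 1
            if tries > 200 * max(need, 1) or not genes:
                raise PlacementError(f"not enough eligible loci for class {cls}")
            g = genes[int(rng.integers(len(genes)))]
            idx = _feature_exon_indices(g, cls)
            # consecutive run of same-feature exons, 1..max_exons
            runs = []
            for i in range(len(idx)):
                for j in range(i, len(idx)):
                    if idx[j] - idx[i] != j - i:
                        break
                    if j - i + 1 > config.max_exons_per_circ:
                        break
                    runs.append((idx[i], idx[j]))
            if not runs:
                continue
            i0, j0 = runs[int(rng.integers(len(runs)))]
            if add(g.contig, g.strand, g.exons[i0 : j0 + 1], cls, g.gene_id):
                need -= 1

    # --- intronic -------------------------------------------------------
    need = requested.get("intronic", 0)
    intron_pool = [
        (g, iv) for g in genome.genes for iv in g.introns()
        if len(iv) >= config.single_exon_circ_length_range[1] + 8
    ]
    rng.shuffle(intron_pool := list(intron_pool))
    for g, iv in intron_pool:
        if need == 0:
            break
        clen = int(rng.integers(*config.single_exon_circ_length_range))
        lo, hi = iv.start + 4, iv.end - clen - 4
        if hi <= lo:
            continue
        s = int(rng.integers(lo, hi))
        _write_flanks(contigs_mut, g.contig, g.strand, s, s + clen)
        if add(g.contig, g.strand, [Interval(s, s + clen)], "intronic", g.gene_id):
            need -= 1
    if need > 0:
        raise PlacementError("not enough eligible loci for class intronic")

    # --- intergenic -----------------------------------------------------
    need = requested.get("intergenic", 0)
    gaps: list[tuple[str, Interval]] = []
    for contig, seq in genome.contigs.items():
        spans = sorted(
            (g.span for g in genome.genes if g.contig == contig), key=lambda s: s.start
        )
        prev = 100
        for sp in spans:
            if sp.start - prev >= config.single_exon_circ_length_range[1] + 208:
                gaps.append((contig, Interval(prev + 100, sp.start - 100)))
            prev = sp.end
        if len(seq) - 100 - prev >= config.single_exon_circ_length_range[1] + 208:
            gaps.append((contig, Interval(prev + 100, len(seq) - 100)))
    rng.shuffle(gaps)
    for contig, gap in gaps:
        if need == 0:
            break
        clen = int(rng.integers(*config.single_exon_circ_length_range))
        hi = gap.end - clen - 4
        lo = gap.start + 4
        if hi <= lo:
            continue
        s = int(rng.integers(lo, hi))
        strand = "+" if rng.random() < 0.5 else "-"
        _write_flanks(contigs_mut, contig, strand, s, s + clen)
        if add(contig, strand, [Interval(s, s + clen)], "intergenic", None):
            need -= 1
    if need > 0:
        raise PlacementError("not enough eligible loci for class intergenic")

    genome.contigs = {c: "".join(s) for c, s in contigs_mut.items()}

    # --- per-sample expected BSJ abundance ------------------------------
    n = config.n_samples
    for t in truths:
        base = max(
            config.abundance_floor,
            float(np.exp(rng.normal(config.abundance_lognorm_mean, config.abundance_lognorm_sd))),
        )
        t.abundance = base * np.exp(rng.normal(0.0, config.sample_lognorm_sd, size=n))
    return truths


# --------------------------------------------------------------------- reads


def _apply_substitutions(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    s = list(seq)
    for p in pos:
        s[p] = "ACGT"[(("ACGT".index(s[p]) if s[p] in "ACGT" else 0) + int(rng.integers(1, 4))) % 4]
    return "".join(s)


def simulate_reads(
    genome: GenomePackage,
    truths: list[TruthCircRNA],
    config: SimulationConfig,
    out_dir: str | os.PathLike,
) -> pd.DataFrame:
    """Write per-sample FASTQ files and a raw-read-total manifest TSV.

    Each sample holds linear background fragments drawn uniformly from
    annotated exonic transcript sequence, plus Poisson-distributed
    BSJ-spanning reads per planted circle (junction at a uniform offset at
    least ``anchor_margin`` nt from both read ends).  Returns the manifest
    (sample_id, n_reads, fastq paths).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    L = config.read_length

    transcripts = [
        (g.gene_id, genome.spliced_sequence(g.contig, g.strand, g.exons)) for g in genome.genes
    ]
    transcripts = [(gid, s) for gid, s in transcripts if len(s) >= L]
    if not transcripts:
        contig_items = list(genome.contigs.items())
        transcripts = [(f"{c}_raw", s) for c, s in contig_items]
    tx_lens = np.array([len(s) - L + 1 for _, s in transcripts])
    tx_cum = np.cumsum(tx_lens)

    circ_seqs = [t.spliced_sequence(genome) for t in truths]
    for t, s in zip(truths, circ_seqs):
        if len(s) < L:
            raise PlacementError(f"{t.circ_id}: spliced length {len(s)} < read length {L}")

    rows = []
    for si, sample in enumerate(config.sample_ids):
        phred = (
            config.low_quality_phred
            if si < config.n_low_quality_samples
            else config.quality_phred
        )
        qual = chr(phred + 33) * L
        n_bsj = (
            np.array([rng.poisson(t.abundance[si]) for t in truths], dtype=int)
            if truths
            else np.zeros(0, dtype=int)
        )
        n_background = max(0, config.raw_reads_per_sample - int(n_bsj.sum()))
        path1 = out / f"{sample}_1.fastq" if config.paired else out / f"{sample}.fastq"
        path2 = out / f"{sample}_2.fastq" if config.paired else None
        n_written = 0
        fh2 = open(path2, "w") if path2 else None
        with open(path1, "w") as fh1:
            def emit(name: str, frag: str) -> None:
                nonlocal n_written
                if config.paired:
                    r1 = _apply_substitutions(rng, frag[:L], config.substitution_rate)
                    r2 = _apply_substitutions(rng, revcomp(frag[-L:]), config.substitution_rate)
                    fh1.write(f"@{name}/1\n{r1}\n+\n{qual}\n")
                    fh2.write(f"@{name}/2\n{r2}\n+\n{qual}\n")
                    n_written += 2
                else:
                    r = _apply_substitutions(rng, frag[:L], config.substitution_rate)
                    fh1.write(f"@{name}\n{r}\n+\n{qual}\n")
                    n_written += 1

            flo, fhi = config.fragment_length_range
            # linear background
            offsets = rng.integers(0, int(tx_cum[-1]), size=n_background)
            for k in np.sort(offsets):
                ti = int(np.searchsorted(tx_cum, k, side="right"))
                off = int(k - (tx_cum[ti - 1] if ti else 0))
                gid, s = transcripts[ti]
                frag_len = min(len(s) - off, int(rng.integers(flo, fhi))) if config.paired else L
                if frag_len < L:
                    frag_len = L
                    off = min(off, len(s) - L)
                emit(f"{sample}:lin{k:07d}:{gid}", s[off : off + frag_len])
            # BSJ-spanning reads
            for t, cseq, cnt in zip(truths, circ_seqs, n_bsj):
                m = config.anchor_margin
                for j in range(int(cnt)):
                    if config.paired:
                        frag_len = int(rng.integers(flo, min(fhi, len(cseq) + L - 2 * m)))
                        frag_len = max(frag_len, L)
                        a = int(rng.integers(m, min(L - m, frag_len - m) + 1))
                        frag = (cseq * (2 + frag_len // len(cseq)))[
                            len(cseq) - a : len(cseq) - a + frag_len
                        ]
                    else:
                        a = int(rng.integers(m, L - m + 1))
                        frag = cseq[len(cseq) - a :] + cseq[: L - a]
                    emit(f"{sample}:bsj{j:05d}:{t.circ_id}:a{a}", frag)
        if fh2:
            fh2.close()
        row = {"sample_id": sample, "n_reads": n_written, "fastq": str(path1)}
        if path2:
            row["fastq2"] = str(path2)
        rows.append(row)
    manifest = pd.DataFrame(rows)
    # the on-disk manifest stays portable (and byte-stable across out dirs):
    # file names only; the returned frame carries full paths
    on_disk = manifest.copy()
    for col in ("fastq", "fastq2"):
        if col in on_disk:
            on_disk[col] = on_disk[col].map(lambda p: Path(p).name)
    on_disk.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest


# --------------------------------------------------------------------- miRNA


def simulate_mirna_profiles(
    genome: GenomePackage,
    truths: list[TruthCircRNA],
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Generate miRNA sequences + per-sample abundance table with sponge coupling.

    The first ``n_sponge_pairs`` exonic circles (one per host gene) are made
    sponges: the reverse complement of their miRNA's first
    ``planted_site_span`` nt (covering the seed, positions 2-8, plus 3'
    supplementary pairing) is written into the circle's spliced sequence in
    the genome, and the miRNA's log2 abundance is coupled to the circle's
    log2 abundance with coefficient ``sponge_effect`` plus Gaussian noise.

    Returns ``(counts, mirna_seqs)``: a samples x miRNAs abundance table and
    miRNA id -> RNA sequence (5'->3').  Mutates ``genome.contigs`` (site
    planting) and ``truths`` (``sponge_targets``) in place.
    """
    rng = np.random.default_rng(config.seed + 3)
    if config.sponge_effect >= 0 and config.n_sponge_pairs > 0:
        warnings.warn(
            "non-negative sponge effect requested; the network stage keeps "
            "only negative correlations, so planted pairs will not be recovered",
            stacklevel=2,
        )
    mirna_ids = [f"miR-{i + 1}" for i in range(config.n_mirnas)]
    lo, hi = config.mirna_length_range
    mirna_seqs = {
        m: "".join("ACGU"[i] for i in rng.integers(0, 4, size=int(rng.integers(lo, hi + 1))))
        for m in mirna_ids
    }

    exonic = [t for t in truths if t.true_class in ("CDS", "5UTR", "3UTR")]
    sponges: list[TruthCircRNA] = []
    seen_genes: set[str] = set()
    for t in exonic:
        if t.host_gene in seen_genes:
            continue
        seen_genes.add(t.host_gene)
        sponges.append(t)
        if len(sponges) == config.n_sponge_pairs:
            break
    if len(sponges) < config.n_sponge_pairs:
        raise PlacementError(
            f"only {len(sponges)} distinct-gene exonic circles available for "
            f"{config.n_sponge_pairs} sponge pairs"
        )
    if config.n_sponge_pairs > config.n_mirnas:
        raise ValueError("need n_mirnas >= n_sponge_pairs")

    contigs_mut = {c: list(s) for c, s in genome.contigs.items()}
    span = config.planted_site_span
    for t, m in zip(sponges, mirna_ids):
        t.sponge_targets = [m]
        site = revcomp(mirna_seqs[m][:span].replace("U", "T"))
        # place the site in the interior of one exon of the circle (transcript order)
        tx_exons = t.exons if t.strand == "+" else t.exons[::-1]
        exon = max(tx_exons, key=len)
        pad = 6
        off = int(rng.integers(pad, len(exon) - span - pad))
        if t.strand == "+":
            gpos = exon.start + off
            payload = site
        else:
            gpos = exon.end - off - span
            payload = revcomp(site)
        seq = contigs_mut[t.contig]
        seq[gpos : gpos + span] = list(payload)
    genome.contigs = {c: "".join(s) for c, s in contigs_mut.items()}

    n = config.n_samples
    log2 = np.log2
    values = np.empty((n, config.n_mirnas))
    sponge_by_mirna = {m: [] for m in mirna_ids}
    for t in sponges:
        sponge_by_mirna[t.sponge_targets[0]].append(t)
    for k, m in enumerate(mirna_ids):
        baseline = rng.normal(config.mirna_baseline_log2_mean, config.mirna_baseline_log2_sd)
        noise = rng.normal(0.0, config.mirna_noise_sd, size=n)
        coupled = np.zeros(n)
        for t in sponge_by_mirna[m]:
            la = log2(t.abundance)
            coupled = coupled + config.sponge_effect * (la - la.mean())
        values[:, k] = np.maximum(0.0, 2.0 ** (baseline + coupled + noise))
    counts = pd.DataFrame(values, index=config.sample_ids, columns=mirna_ids)
    counts.index.name = "sample_id"
    return counts, mirna_seqs


def write_mirna_fasta(mirna_seqs: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in mirna_seqs.items():
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------- phenotypes


def simulate_phenotypes(truths: list[TruthCircRNA], config: SimulationConfig) -> pd.DataFrame:
    """Simulate CASA motility traits under fixed effects + circRNA effects.

    Each trait = intercept + farm + age-class + season-year effects
    + sum(effect x log2 circRNA abundance) + Gaussian noise; motile_pct is
    clipped to [0, 100].  Boar ages (months) are drawn uniformly from
    ``age_months_range`` and age classes are age tertiles.  Marks the causal
    circles' ``phenotype_effect`` in place.
    """
    rng = np.random.default_rng(config.seed + 4)
    n = config.n_samples
    traits = list(config.trait_intercepts)

    age = np.sort(rng.uniform(*config.age_months_range, size=n))[rng.permutation(n)]
    tertiles = np.quantile(age, [1 / 3, 2 / 3])
    age_class = 1 + (age > tertiles[0]).astype(int) + (age > tertiles[1]).astype(int)
    farm = rng.integers(1, config.n_farms + 1, size=n)
    season_year = rng.integers(1, config.n_season_years + 1, size=n)

    effects = {
        ("farm", lvl): {tr: rng.normal(0, config.fixed_effect_sd) for tr in traits}
        for lvl in range(1, config.n_farms + 1)
    }
    effects.update(
        {
            ("age_class", lvl): {tr: rng.normal(0, config.fixed_effect_sd) for tr in traits}
            for lvl in range(1, config.n_age_classes + 1)
        }
    )
    effects.update(
        {
            ("season_year", lvl): {tr: rng.normal(0, config.fixed_effect_sd) for tr in traits}
            for lvl in range(1, config.n_season_years + 1)
        }
    )

    # causal circles round-robin over traits; coefficient sized so the planted
    # circ-trait correlation is ~phenotype_target_r given noise and log2 spread
    causal = truths[: config.n_causal_circles]
    log2_sd = config.sample_lognorm_sd / np.log(2)
    r_t = config.phenotype_target_r
    for i, t in enumerate(causal):
        tr = traits[i % len(traits)]
        sign = 1.0 if i % 2 == 0 else -1.0
        coef = sign * config.trait_noise_sd[tr] * r_t / np.sqrt(1 - r_t**2) / log2_sd
        t.phenotype_effect = {tr: coef}

    data = {"sample_id": config.sample_ids}
    for tr in traits:
        y = np.full(n, config.trait_intercepts[tr])
        for i in range(n):
            y[i] += effects[("farm", int(farm[i]))][tr]
            y[i] += effects[("age_class", int(age_class[i]))][tr]
            y[i] += effects[("season_year", int(season_year[i]))][tr]
        for t in causal:
            coef = t.phenotype_effect.get(tr, 0.0)
            if coef and t.abundance is not None:
                la = np.log2(t.abundance)
                y = y + coef * (la - la.mean())
        y = y + rng.normal(0, config.trait_noise_sd[tr], size=n)
        if tr == "motile_pct":
            y = np.clip(y, 0.0, 100.0)
        data[tr] = y
    data["farm"] = farm
    data["age_class"] = age_class
    data["season_year"] = season_year
    data["age_months"] = age
    return pd.DataFrame(data)


# ------------------------------------------------------------------- exports


def write_truth_bed(truths: list[TruthCircRNA], path: str | os.PathLike, sample_ids: list[str]) -> None:
    """BED6+ truth table: class, host gene, exon blocks, per-sample abundances."""
    with open(path, "w") as fh:
        fh.write(
            "#contig\tstart\tend\tname\tscore\tstrand\tclass\thost_gene\texon_blocks\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for t in truths:
            blocks = ",".join(f"{e.start}-{e.end}" for e in t.exons)
            ab = "\t".join(f"{x:.4f}" for x in (t.abundance if t.abundance is not None else []))
            fh.write(
                f"{t.contig}\t{t.start}\t{t.end}\t{t.circ_id}\t0\t{t.strand}\t"
                f"{t.true_class}\t{t.host_gene or '.'}\t{blocks}\t{ab}\n"
            )


def simulate_study(config: SimulationConfig, out_dir: str | os.PathLike) -> dict:
    """Run the full generator and write every artifact under ``out_dir``.

    Returns a dict with the in-memory objects (genome, truths, manifest,
    mirna counts/sequences, phenotypes) for programmatic use.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(config)
    truths = plant_circrnas(genome, config)
    mirna_counts, mirna_seqs = simulate_mirna_profiles(genome, truths, config)
    # genome written only after site planting so FASTA matches the reads
    genome.write_fasta(out / "genome.fa")
    genome.write_gtf(out / "annotation.gtf")
    manifest = simulate_reads(genome, truths, config, out / "reads")
    pheno = simulate_phenotypes(truths, config)
    mirna_counts.to_csv(out / "mirna_counts.tsv", sep="\t")
    write_mirna_fasta(mirna_seqs, out / "mirna.fa")
    pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    write_truth_bed(truths, out / "truth.bed", config.sample_ids)
    return {
        "genome": genome,
        "truths": truths,
        "manifest": manifest,
        "mirna_counts": mirna_counts,
        "mirna_seqs": mirna_seqs,
        "phenotypes": pheno,
    }
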