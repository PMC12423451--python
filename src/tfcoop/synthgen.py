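"""Synthetic genomes, motif libraries, expression matrices and variant sets
with machine-readable planted truth.

Every generator takes a frozen config plus a seed and emits both the standard
files (FASTA/GFF3/MEME/VCF/TSV) and a :class:`TruthBundle` recording what was
planted, so each downstream analysis stage can be validated against ground
truth without any external data.

Determinism: every operation draws from a single ``numpy.random.default_rng``
seeded from its config, and all files are written with fixed formatting, so
identical config + seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import DNA, SENSE_CODONS, STOP_CODONS, revcomp, translate_cds


class ConfigError(ValueError):
    """Raised when a simulation config violates its invariants."""


class GenerationError(RuntimeError):
    """Raised when rejection sampling exhausts its retry budget."""


# --------------------------------------------------------------------------
# configs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSimConfig:
    """Layout of a synthetic genome with planted TF clusters.

    ``cluster_spec`` entries are ``(chrom, window_index, families)``: the
    listed family members are planted inside that window of the 250-kb
    tiling, so cluster truth is unambiguous under the window/merge rule.
    """

    n_chromosomes: int = 4
    chrom_length_bp: int | tuple = 1_500_000   # one length, or per chrom
    n_tf_genes: int = 18
    n_sg_genes: int = 12
    n_families: int = 6
    cluster_spec: tuple = ()
    exon_count_range: tuple[int, int] = (1, 5)
    gc_target: float = 0.40
    window_bp: int = 250_000
    seed: int = 0

    def lengths(self) -> dict:
        """Chromosome name -> length in bp."""
        if isinstance(self.chrom_length_bp, int):
            lens = [self.chrom_length_bp] * self.n_chromosomes
        else:
            lens = list(self.chrom_length_bp)
            if len(lens) != self.n_chromosomes:
                raise ConfigError("chrom_length_bp list length must equal "
                                  "n_chromosomes")
        return {f"chr{i + 1}": ln for i, ln in enumerate(lens)}

    def validate(self) -> None:
        lens = self.lengths()
        if self.n_chromosomes < 1 or min(lens.values()) < self.window_bp:
            raise ConfigError("need >=1 chromosome of at least one window")
        if not 0.0 <= self.gc_target <= 1.0:
            raise ConfigError("gc_target must lie in [0, 1]")
        lo, hi = self.exon_count_range
        if lo < 1 or hi < lo:
            raise ConfigError("invalid exon_count_range")
        planted = 0
        for chrom, widx, fams in self.cluster_spec:
            if chrom not in lens:
                raise ConfigError(f"unknown chromosome {chrom!r}")
            if not 0 <= widx < lens[chrom] // self.window_bp:
                raise ConfigError(f"window {widx} out of range for {chrom}")
            planted += len(fams)
        if planted > self.n_tf_genes:
            raise ConfigError("cluster_spec plants more TFs than n_tf_genes")


@dataclass(frozen=True)
class MotifSimConfig:
    """Motif library with planted palindromic half-site pairs.

    ``planted_pairs`` are ``(i, j, k)`` with 0-based motif indices and half
    length ``k >= 3`` (palindrome length ``2k >= 6``).  ``n_decoys`` extra
    motifs are appended and certified palindrome-free against the whole
    library by a brute-force check independent of the production detector.
    """

    n_motifs: int = 4
    motif_length_range: tuple[int, int] = (8, 14)
    planted_pairs: tuple = ((0, 1, 3), (2, 3, 4))
    n_decoys: int = 10
    seed: int = 0
    max_retries: int = 2000

    def validate(self) -> None:
        lo, hi = self.motif_length_range
        if lo < 6 or hi > 25 or hi < lo:
            raise ConfigError("motif_length_range must lie within [6, 25]")
        for i, j, k in self.planted_pairs:
            if k < 3:
                raise ConfigError("half_site_length must be >= 3 (2k >= 6)")
            if not (0 <= i < self.n_motifs and 0 <= j < self.n_motifs):
                raise ConfigError("planted pair indexes a missing motif")
            need = 2 * k if i == j else k
            if need > hi:
                raise ConfigError("half site does not fit in motif length")
        self.stars()

    def stars(self) -> list:
        """Group planted pairs into half-site stars.

        A star is one centre motif carrying a half site plus satellite
        motifs carrying its reverse complement; every centre-satellite
        combination is a planted pair.  Supported topologies are disjoint
        edges, self-pairs and stars (all pairs of a connected component
        share one motif and one half length); anything else cannot be
        planted without creating unplanned palindromes.
        """
        from collections import defaultdict

        incident = defaultdict(list)
        for i, j, k in self.planted_pairs:
            incident[i].append((i, j, k))
            if j != i:
                incident[j].append((i, j, k))
        seen: set = set()
        stars = []
        for i, j, k in self.planted_pairs:
            if (i, j) in seen:
                continue
            centre = i if len(incident[i]) >= len(incident[j]) else j
            edges = incident[centre]
            sats = []
            for (a, b, kk) in edges:
                seen.add((a, b))
                if kk != k:
                    raise ConfigError(
                        "pairs sharing a motif must share one half length")
                other = b if a == centre else a
                if other != centre and len(incident[other]) > 1:
                    raise ConfigError(
                        "planted pairs must form stars: satellites may "
                        "appear in only one pair")
                sats.append(other)
            if centre in sats and len(sats) > 1:
                raise ConfigError("a self-pairing motif cannot take part "
                                  "in other pairs")
            stars.append((centre, sats, k))
        return stars


@dataclass(frozen=True)
class ExprSimConfig:
    """TPM matrix with planted co-expression modules.

    ``module_spec`` entries are ``(size, tissue_profile, noise_sd)`` where
    ``tissue_profile`` gives the module eigengene level per tissue label.
    """

    n_genes: int = 150
    n_samples: int = 60
    module_spec: tuple = (
        (50, (5.0, 1.0, 1.0, 1.0), 0.3),
        (50, (1.0, 5.0, 1.0, 1.0), 0.3),
        (50, (1.0, 1.0, 5.0, 1.0), 0.3),
    )
    n_low_expression: int = 0
    tissue_labels: tuple[str, ...] = ("leaf", "peel", "seed", "pulp")
    seed: int = 0

    def validate(self) -> None:
        sizes = sum(s for s, _, _ in self.module_spec)
        if sizes + self.n_low_expression > self.n_genes:
            raise ConfigError("module sizes + low-expression exceed n_genes")
        for s, prof, sd in self.module_spec:
            if sd <= 0:
                raise ConfigError("noise sd must be > 0")
            if len(prof) != len(self.tissue_labels):
                raise ConfigError("tissue profile length != tissue count")
        if self.n_samples < len(self.tissue_labels):
            raise ConfigError("need at least one sample per tissue")


@dataclass(frozen=True)
class VariantSimConfig:
    """Per-region variant rates (per bp per sample) to plant into a genome."""

    target_rates: tuple = (("CDS", 2e-3), ("intron", 1e-3), ("UTR", 3e-3))
    n_samples: int = 5
    synonymous_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for region, rate in self.target_rates:
            if region not in ("CDS", "intron", "UTR"):
                raise ConfigError(f"unknown region {region!r}")
            if rate < 0:
                raise ConfigError("rates must be >= 0")
        if not 0.0 <= self.synonymous_fraction <= 1.0:
            raise ConfigError("synonymous_fraction must lie in [0, 1]")


# --------------------------------------------------------------------------
# truth + bundles
# --------------------------------------------------------------------------

@dataclass
class TruthBundle:
    """Planted ground truth; every record refers to an emitted entity."""

    genes: list = field(default_factory=list)           # dicts per gene
    clusters: list = field(default_factory=list)        # expected final clusters
    singlet_windows: list = field(default_factory=list)  # (chrom, widx, gene)
    motif_pairs: list = field(default_factory=list)     # (id_a, id_b, k)
    decoy_ids: list = field(default_factory=list)
    promoter_hits: list = field(default_factory=list)   # dicts
    modules: dict = field(default_factory=dict)         # gene -> module label
    low_expression: list = field(default_factory=list)
    variant_counts: dict = field(default_factory=dict)  # region -> site count
    variant_sites: list = field(default_factory=list)   # dicts w/ effect

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        payload = {f.name: getattr(self, f.name)
                   for f in dataclasses.fields(self)}
        (outdir / "truth.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def read(cls, outdir: str | Path) -> "TruthBundle":
        payload = json.loads((Path(outdir) / "truth.json").read_text())
        tb = cls()
        for k, v in payload.items():
            setattr(tb, k, v)
        # JSON turns tuples into lists; normalise pair records
        tb.motif_pairs = [tuple(p) for p in tb.motif_pairs]
        return tb


@dataclass
class SimGene:
    gene_id: str
    family: str          # TF family label, or "SG"
    chrom: str
    strand: str
    start: int           # 1-based inclusive genomic
    end: int
    exons: list          # genomic [start, end] pairs, sorted
    cds: list
    utr5: list
    utr3: list
    coding_seq: str      # spliced CDS on the coding strand

    @property
    def is_tf(self) -> bool:
        return self.family != "SG"


@dataclass
class GenomeBundle:
    """In-memory synthetic genome: sequences, gene models and truth."""

    chroms: dict          # name -> bytearray of sequence
    genes: list           # SimGene
    window_bp: int
    truth: TruthBundle

    def chrom_seq(self, name: str) -> str:
        return self.chroms[name].decode()

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "genome.fa", "w") as fh:
            for name in sorted(self.chroms):
                fh.write(f">{name}\n")
                seq = self.chrom_seq(name)
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        write_gff3(self.genes, outdir / "annotation.gff3",
                   {n: len(s) for n, s in self.chroms.items()})
        with open(outdir / "families.tsv", "w") as fh:
            fh.write("gene_id\tfamily\n")
            for g in self.genes:
                fh.write(f"{g.gene_id}\t{g.family}\n")
        self.truth.write(outdir)


def write_gff3(genes: Sequence[SimGene], path: str | Path,
               chrom_lengths: dict) -> None:
    """Emit a GFF3 with the gene/mRNA/exon/CDS/UTR part-of hierarchy."""
    lines = ["##gff-version 3"]
    for name in sorted(chrom_lengths):
        lines.append(f"##sequence-region {name} 1 {chrom_lengths[name]}")
    for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
        gid, mid = g.gene_id, g.gene_id + ".t1"
        lines.append("\t".join([
            g.chrom, "tfcoop-sim", "gene", str(g.start), str(g.end), ".",
            g.strand, ".", f"ID={gid}"]))
        lines.append("\t".join([
            g.chrom, "tfcoop-sim", "mRNA", str(g.start), str(g.end), ".",
            g.strand, ".", f"ID={mid};Parent={gid}"]))
        for s, e in g.exons:
            lines.append("\t".join([
                g.chrom, "tfcoop-sim", "exon", str(s), str(e), ".",
                g.strand, ".", f"Parent={mid}"]))
        # CDS phase: bases to skip before first full codon, 5'->3'
        cds = g.cds if g.strand == "+" else list(reversed(g.cds))
        consumed = 0
        phased = []
        for s, e in cds:
            phased.append((s, e, (3 - consumed % 3) % 3))
            consumed += e - s + 1
        for s, e, ph in sorted(phased):
            lines.append("\t".join([
                g.chrom, "tfcoop-sim", "CDS", str(s), str(e), ".",
                g.strand, str(ph), f"ID={mid}.cds;Parent={mid}"]))
        for kind, ivs in (("five_prime_UTR", g.utr5),
                          ("three_prime_UTR", g.utr3)):
            for s, e in ivs:
                lines.append("\t".join([
                    g.chrom, "tfcoop-sim", kind, str(s), str(e), ".",
                    g.strand, ".", f"Parent={mid}"]))
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# genome generation
# --------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(DNA))[rng.choice(4, size=n, p=p)])


def _make_gene_parts(rng: np.random.Generator, exon_count: int, gc: float):
    """Build a gene on its coding strand; return (sequence, relative parts).

    Relative intervals are 0-based [start, end] on the coding strand.
    """
    utr5_len = int(rng.integers(60, 121))
    utr3_len = int(rng.integers(60, 121))
    n_codons = int(rng.integers(60, 151))  # incl. start, excl. stop
    codons = ["ATG"] + [SENSE_CODONS[i] for i in
                        rng.integers(0, len(SENSE_CODONS), n_codons - 1)]
    stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
    cds_seq = "".join(codons) + stop
    cds_len = len(cds_seq)

    # split the CDS across exons (chunks >= 20 bp)
    exon_count = min(exon_count, max(1, cds_len // 20))
    if exon_count == 1:
        chunks = [cds_len]
    else:
        cuts = sorted(rng.choice(
            np.arange(20, cds_len - 19), size=exon_count - 1, replace=False))
        # enforce min spacing by rejection-free adjustment
        ok, prev = [], 0
        for c in cuts:
            if c - prev >= 20 and cds_len - c >= 20:
                ok.append(int(c))
                prev = c
        cuts = ok
        bounds = [0] + cuts + [cds_len]
        chunks = [b - a for a, b in zip(bounds, bounds[1:])]
    introns = [int(rng.integers(60, 121)) for _ in range(len(chunks) - 1)]

    seq_parts, pos = [], 0
    utr5 = [(0, utr5_len - 1)]
    seq_parts.append(_random_dna(rng, utr5_len, gc))
    pos += utr5_len
    exons, cds = [], []
    cds_cursor = 0
    for i, chunk in enumerate(chunks):
        exon_start = pos if i > 0 else 0  # first exon includes the 5' UTR
        cds.append((pos, pos + chunk - 1))
        seq_parts.append(cds_seq[cds_cursor:cds_cursor + chunk])
        cds_cursor += chunk
        pos += chunk
        if i < len(chunks) - 1:
            exons.append((exon_start, pos - 1))
            ilen = introns[i]
            seq_parts.append("GT" + _random_dna(rng, ilen - 4, gc) + "AG")
            pos += ilen
    utr3 = [(pos, pos + utr3_len - 1)]
    seq_parts.append(_random_dna(rng, utr3_len, gc))
    pos += utr3_len

    # exon intervals: exon i runs from the end of the previous intron
    exons = []
    cursor = 0
    for i, chunk in enumerate(chunks):
        if i == 0:
            exon_start = 0
            exon_end = utr5_len + chunk - 1
            cursor = exon_end + 1
        else:
            exon_start = cursor + introns[i - 1]
            exon_end = exon_start + chunk - 1
            cursor = exon_end + 1
        if i == len(chunks) - 1:
            exon_end += utr3_len
        exons.append((exon_start, exon_end))
    seq = "".join(seq_parts)
    assert len(seq) == pos == exons[-1][1] + 1
    return seq, exons, cds, utr5, utr3, cds_seq


def _to_genomic(rel, gstart, glen, strand):
    """Map 0-based coding-strand-relative [a,b] to 1-based genomic."""
    out = []
    for a, b in rel:
        if strand == "+":
            out.append((gstart + a, gstart + b))
        else:
            out.append((gstart + glen - 1 - b, gstart + glen - 1 - a))
    return sorted(out)


def _expected_clusters(window_tfs: dict) -> tuple[list, list]:
    """Apply the window/merge rule to the planted layout.

    ``window_tfs``: (chrom, widx) -> list of (gene_id, family).  Windows with
    >= 2 TFs are primary clusters; consecutive-window primaries on one
    chromosome sharing >= 1 family merge transitively.  Returns (final
    clusters, singlet windows).  This is a direct restatement of the planted
    layout, independent of the production catalog code.
    """
    singlets, clusters = [], []
    by_chrom: dict = {}
    for (chrom, widx), members in sorted(window_tfs.items()):
        if len(members) == 1:
            singlets.append((chrom, widx, members[0][0]))
        elif len(members) >= 2:
            by_chrom.setdefault(chrom, []).append((widx, members))
    for chrom, prims in sorted(by_chrom.items()):
        prims.sort()
        run: list = []
        for widx, members in prims:
            if run and widx == run[-1][0] + 1 and (
                    {f for _, f in run[-1][1]} & {f for _, f in members}):
                run.append((widx, members))
            else:
                if run:
                    clusters.append((chrom, run))
                run = [(widx, members)]
        if run:
            clusters.append((chrom, run))
    final = []
    for chrom, run in clusters:
        members = [g for _, mem in run for g, _ in mem]
        fams = sorted({f for _, mem in run for _, f in mem})
        final.append({
            "chrom": chrom,
            "windows": [w for w, _ in run],
            "members": sorted(members),
            "families": fams,
            "kind": "merged" if len(run) > 1 else "primary",
        })
    return final, singlets


def gen_genome(cfg: GenomeSimConfig) -> GenomeBundle:
    """Generate a genome FASTA/GFF3/family table with planted TF clusters."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lens = cfg.lengths()
    chrom_names = list(lens)
    chroms = {name: bytearray(
        _random_dna(rng, lens[name], cfg.gc_target), "ascii")
        for name in chrom_names}
    windows_of = {c: lens[c] // cfg.window_bp for c in chrom_names}
    families = [f"F{i + 1}" for i in range(cfg.n_families)]

    # window occupancy: (chrom, widx) -> list of family labels to plant
    occupancy: dict = {}
    for chrom, widx, fams in cfg.cluster_spec:
        occupancy.setdefault((chrom, widx), []).extend(fams)
    n_planted = sum(len(v) for v in occupancy.values())

    # remaining TFs: one per free window so no accidental cluster forms
    free = [(c, w) for c in chrom_names for w in range(windows_of[c])
            if (c, w) not in occupancy]
    n_single = cfg.n_tf_genes - n_planted
    if n_single > len(free):
        raise ConfigError("not enough free windows for singleton TFs")
    pick = rng.choice(len(free), size=n_single, replace=False)
    for rank, idx in enumerate(sorted(pick)):
        occupancy[free[idx]] = [families[rank % len(families)]]

    # SG genes share windows round-robin (they never cluster)
    sg_slots: dict = {}
    all_windows = [(c, w) for c in chrom_names
                   for w in range(windows_of[c])]
    for i in range(cfg.n_sg_genes):
        key = all_windows[i % len(all_windows)]
        sg_slots[key] = sg_slots.get(key, 0) + 1

    genes: list[SimGene] = []
    window_tfs: dict = {}
    tf_no = sg_no = 0
    for (chrom, widx) in sorted(set(occupancy) | set(sg_slots)):
        labels = list(occupancy.get((chrom, widx), []))
        n_here = len(labels) + sg_slots.get((chrom, widx), 0)
        slot_w = cfg.window_bp // (n_here + 1)
        for slot in range(n_here):
            is_tf = slot < len(labels)
            exon_count = int(rng.integers(cfg.exon_count_range[0],
                                          cfg.exon_count_range[1] + 1))
            seq, exons, cds, utr5, utr3, cds_seq = _make_gene_parts(
                rng, exon_count, cfg.gc_target)
            glen = len(seq)
            jitter = int(rng.integers(0, max(1, slot_w - glen - 10)))
            gstart = widx * cfg.window_bp + slot * slot_w + jitter + 1
            if gstart + glen - 1 > len(chroms[chrom]):
                raise ConfigError("planted gene exceeds chromosome bounds")
            strand = "+" if rng.random() < 0.5 else "-"
            placed = seq if strand == "+" else revcomp(seq)
            chroms[chrom][gstart - 1:gstart - 1 + glen] = placed.encode()
            if is_tf:
                tf_no += 1
                gid, fam = f"TF{tf_no:04d}", labels[slot]
                window_tfs.setdefault((chrom, widx), []).append((gid, fam))
            else:
                sg_no += 1
                gid, fam = f"SG{sg_no:04d}", "SG"
            genes.append(SimGene(
                gene_id=gid, family=fam, chrom=chrom, strand=strand,
                start=gstart, end=gstart + glen - 1,
                exons=_to_genomic(exons, gstart, glen, strand),
                cds=_to_genomic(cds, gstart, glen, strand),
                utr5=_to_genomic(utr5, gstart, glen, strand),
                utr3=_to_genomic(utr3, gstart, glen, strand),
                coding_seq=cds_seq))
            assert translate_cds(cds_seq)  # sanity: translatable ORF

    clusters, singlets = _expected_clusters(window_tfs)
    truth = TruthBundle(
        genes=[{"gene_id": g.gene_id, "family": g.family, "chrom": g.chrom,
                "strand": g.strand, "start": g.start, "end": g.end,
                "window": (g.start - 1) // cfg.window_bp}
               for g in genes],
        clusters=clusters,
        singlet_windows=[list(s) for s in singlets])
    return GenomeBundle(chroms=chroms, genes=genes,
                        window_bp=cfg.window_bp, truth=truth)


# --------------------------------------------------------------------------
# motif library generation
# --------------------------------------------------------------------------

_AC = "AC"


def _canon(w: str) -> str:
    return min(w, revcomp(w))


def _single_class(w: str) -> bool:
    return set(w) <= set("AC") or set(w) <= set("GT")


# 3-mer classes that fragment/flank junction windows can fall into, given
# the construction in gen_motif_library (half sites start with A, flank
# letters adjacent to fragments are C).  Half sites must avoid them so the
# junctions can never complement anything.
_RESERVED_CLASSES = {_canon(w) for w in
                     ("CAG", "CAT", "ATC", "CTC", "GTC", "TTC", "TCC")}


def _brute_pair_exists(a: str, b: str, min_len: int = 6) -> bool:
    """Brute-force: do fragments of a and b form a palindrome >= min_len?

    Exhaustive over substring pairs; used only to certify simulated truth,
    never by the production detector.
    """
    # existence at >= min_len is equivalent to existence at exactly k0 =
    # min_len/2: any longer complementary fragment contains a k0-fragment
    k0 = min_len // 2
    for i in range(len(a) - k0 + 1):
        rc = revcomp(a[i:i + k0])
        for j in range(len(b) - k0 + 1):
            if b[j:j + k0] == rc:
                return True
    return False


def _windows3(s: str) -> list[str]:
    return [s[i:i + 3] for i in range(len(s) - 2)]


def _flank_ac(rng: np.random.Generator, n: int) -> str:
    return "".join(_AC[i] for i in rng.integers(0, 2, n))


def _force_c(flank: str, tail: bool) -> str:
    """Force the (up to) two flank letters adjacent to a fragment to C."""
    if not flank:
        return flank
    if tail:
        return (flank[:-2] + "CC") if len(flank) >= 2 else "C"
    return ("CC" + flank[2:]) if len(flank) >= 2 else "C"


@dataclass
class MotifLibrary:
    """Consensus strings + PWMs with truth about planted palindromic pairs."""

    motif_ids: list
    consensi: list
    source_tfs: list
    truth: TruthBundle

    def pwms(self, dominant: float = 0.91):
        from .motifmap import MotifPWM
        rest = (1.0 - dominant) / 3.0
        out = []
        for mid, cons, src in zip(self.motif_ids, self.consensi,
                                  self.source_tfs):
            mat = np.full((len(cons), 4), rest)
            for row, base in enumerate(cons):
                mat[row, DNA.index(base)] = dominant
            out.append(MotifPWM(motif_id=mid, matrix=mat, source_tf_id=src))
        return out

    def write(self, path: str | Path) -> None:
        from .motifmap import write_meme
        write_meme(self.pwms(), path)


def gen_motif_library(cfg: MotifSimConfig,
                      source_tf_ids: Sequence[str] | None = None
                      ) -> MotifLibrary:
    """Generate a MEME library with planted palindromic pairs and certified
    palindrome-free decoys.

    Construction keeps accidental pairs rare (decoys and flanks use only
    A/C, whose reverse complements never occur outside planted half sites);
    a brute-force certification pass then redraws any motif involved in an
    unplanted pair until the realised pair set equals the planted one.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.motif_length_range
    n_total = cfg.n_motifs + cfg.n_decoys
    planted = {(min(i, j), max(i, j)): k for i, j, k in cfg.planted_pairs}
    stars = cfg.stars()
    in_pair = {idx for pair in planted for idx in pair}

    # Construction by 3-mer reverse-complement classes.  A spurious pair
    # exists iff some 3-mer occurs somewhere while its reverse complement
    # occurs in another motif.  Each planted pair therefore receives
    # PRIVATE classes for the 3-mers of its half-site fragment (both
    # orientations occur, but only in that pair's two motifs), and every
    # other 3-mer in the library (flanks, fragment/flank junctions,
    # decoys) is claimed in a single global orientation, so no unplanned
    # complementarity can arise.  The half sits at a motif edge to keep
    # the junction count down; flanks are {A,C}, whose classes are used
    # in the {A,C} orientation library-wide.
    private: set = set()
    orient: dict = {}
    consensi: list[str | None] = [None] * n_total

    def shared_ok(windows: list[str], pending: dict) -> bool:
        for w in windows:
            c = _canon(w)
            if c in private:
                return False
            prev = orient.get(c) or pending.get(c)
            if prev is not None and prev != w:
                return False
            pending[c] = w
        return True

    for centre, sats, k in stars:
        is_self = sats == [centre]
        built = False
        for _ in range(2000):
            h = "A" + "".join(DNA[b] for b in rng.integers(0, 4, k - 1))
            frag = h + revcomp(h) if is_self else h
            frag_cls = [_canon(w) for w in _windows3(frag)]
            if any(_single_class(w) for w in _windows3(frag)):
                continue
            # a palindromic self fragment repeats classes by construction;
            # plain halves must not (a repeat in opposite orientation
            # would make the carrier pair with itself)
            if not is_self and len(set(frag_cls)) != len(frag_cls):
                continue
            if any(c in private or c in orient
                   or c in _RESERVED_CLASSES for c in frag_cls):
                continue
            flen = len(frag)
            if flen > hi:
                continue

            def rand_len(n):
                return int(rng.integers(max(lo, n), hi + 1))

            fl = _force_c(_flank_ac(rng, rand_len(flen) - flen), tail=True)
            cand = [(centre, fl + frag, len(fl))]
            if not is_self:
                for s in sats:
                    fs = _force_c(_flank_ac(rng, rand_len(k) - k),
                                  tail=False)
                    cand.append((s, revcomp(h) + fs, 0))
            pending: dict = {}
            ok = True
            for _idx, cons, frag_at in cand:
                outside = [w for t, w in enumerate(_windows3(cons))
                           if not (frag_at <= t <= frag_at + flen - 3)]
                if not shared_ok(outside, pending):
                    ok = False
                    break
            if not ok:
                continue
            for idx, cons, _fa in cand:
                consensi[idx] = cons
            private.update(frag_cls)
            orient.update(pending)
            built = True
            break
        if not built:
            raise GenerationError(
                f"could not place the planted star around motif {centre}; "
                "the 3-mer class budget is exhausted (fewer or shorter "
                "half sites)")

    for idx in range(n_total):
        if consensi[idx] is None:
            consensi[idx] = _flank_ac(rng, int(rng.integers(lo, hi + 1)))

    # certification: the brute-force oracle must find exactly the planted
    # pairs; any residual accident is repaired by redrawing the offender
    for _ in range(cfg.max_retries):
        bad = None
        for i in range(n_total):
            for j in range(i, n_total):
                exists = _brute_pair_exists(consensi[i], consensi[j])
                if exists != ((i, j) in planted):
                    bad = (i, j)
                    break
            if bad:
                break
        if bad is None:
            break
        i, j = bad
        if i in in_pair and j in in_pair:
            raise GenerationError(
                "planted motif construction produced an unexpected pair; "
                "this indicates a violated class-privacy invariant")
        redraw = j if j not in in_pair else i
        consensi[redraw] = _flank_ac(rng, int(rng.integers(lo, hi + 1)))
    else:
        raise GenerationError("could not certify decoy motifs within budget")

    ids = [f"M{i + 1}" for i in range(n_total)]
    if source_tf_ids is None:
        source_tfs = [f"AT{i + 1:03d}" for i in range(n_total)]
    else:
        source_tfs = list(source_tf_ids)
    truth = TruthBundle(
        motif_pairs=[(ids[i], ids[j], k)
                     for (i, j), k in sorted(planted.items())],
        decoy_ids=ids[cfg.n_motifs:])
    return MotifLibrary(motif_ids=ids, consensi=consensi,
                        source_tfs=source_tfs, truth=truth)


# --------------------------------------------------------------------------
# promoter hit planting
# --------------------------------------------------------------------------

def plant_promoter_hits(bundle: GenomeBundle, library: MotifLibrary,
                        spec: Sequence[tuple], promoter_bp: int = 500
                        ) -> TruthBundle:
    """Write motif consensus strings into gene promoters, strand-aware.

    ``spec`` entries: ``(gene_id, motif_id, end_upstream, match_strand)``
    with ``end_upstream`` the distance (bp, 1-based) from the TSS to the
    3'-most base of the planted occurrence on the promoter's coding strand.
    Mutates ``bundle.chroms`` in place and returns the hit truth.
    """
    genes = {g.gene_id: g for g in bundle.genes}
    cons = dict(zip(library.motif_ids, library.consensi))
    occupied: dict = {}
    truth = TruthBundle()
    for gene_id, motif_id, end_up, match_strand in spec:
        g = genes[gene_id]
        word = cons[motif_id]
        L = len(word)
        start_up = end_up + L - 1
        if end_up < 1 or start_up > promoter_bp:
            raise ConfigError(
                f"hit [{start_up},{end_up}] outside {promoter_bp}-bp promoter")
        span = set(range(end_up, start_up + 1))
        if occupied.get(gene_id, set()) & span:
            raise ConfigError(f"hit collision in promoter of {gene_id}")
        occupied.setdefault(gene_id, set()).update(span)
        if match_strand == "-":
            word = revcomp(word)
        # promoter coding strand: positions start_up..end_up upstream of TSS
        if g.strand == "+":
            lo = g.start - start_up          # 1-based genomic, leftmost
            if lo < 1:
                raise ConfigError("promoter truncated at chromosome start")
            bundle.chroms[g.chrom][lo - 1:lo - 1 + L] = word.encode()
        else:
            hi = g.end + start_up            # rightmost genomic base
            if hi > len(bundle.chroms[g.chrom]):
                raise ConfigError("promoter truncated at chromosome end")
            placed = revcomp(word)           # coding strand is the reverse
            bundle.chroms[g.chrom][g.end + end_up - 1:
                                   g.end + end_up - 1 + L] = placed.encode()
        truth.promoter_hits.append({
            "gene_id": gene_id, "motif_id": motif_id,
            "start_upstream": start_up, "end_upstream": end_up,
            "strand": match_strand})
    bundle.truth.promoter_hits.extend(truth.promoter_hits)
    return truth


# --------------------------------------------------------------------------
# expression generation
# --------------------------------------------------------------------------

def gen_expression(cfg: ExprSimConfig):
    """TPM matrix + sample metadata with planted modules.

    Module genes are ``loading x eigengene-profile + Gaussian noise``, then
    shifted per gene to nonnegative TPM (an affine map, so planted Pearson
    structure is preserved).  Returns (tpm DataFrame, metadata DataFrame,
    TruthBundle).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_t = len(cfg.tissue_labels)
    tissues = [cfg.tissue_labels[i * n_t // cfg.n_samples]
               for i in range(cfg.n_samples)]
    samples = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]
    meta = pd.DataFrame({"sample": samples, "tissue": tissues,
                         "project": "P1"})

    rows, gene_ids = [], []
    truth = TruthBundle()
    gno = 0
    for m_idx, (size, profile, sd) in enumerate(cfg.module_spec):
        label = f"PM{m_idx + 1}"
        base = np.array([profile[cfg.tissue_labels.index(t)]
                         for t in tissues], dtype=float)
        for _ in range(size):
            gno += 1
            gid = f"G{gno:04d}"
            loading = rng.uniform(0.6, 1.4)
            x = loading * base + rng.normal(0.0, sd, cfg.n_samples)
            x = x - x.min() + 0.5  # shift to nonnegative TPM
            rows.append(x)
            gene_ids.append(gid)
            truth.modules[gid] = label
    for _ in range(cfg.n_low_expression):
        gno += 1
        gid = f"G{gno:04d}"
        x = rng.uniform(0.0, 0.9, cfg.n_samples)
        n_hi = max(0, cfg.n_samples - int(np.ceil(0.95 * cfg.n_samples)))
        if n_hi:
            idx = rng.choice(cfg.n_samples, size=n_hi, replace=False)
            x[idx] = rng.uniform(1.0, 3.0, n_hi)
        rows.append(x)
        gene_ids.append(gid)
        truth.low_expression.append(gid)
    n_bg = cfg.n_genes - gno
    for _ in range(n_bg):
        gno += 1
        gid = f"G{gno:04d}"
        mu = rng.uniform(2.0, 8.0)
        x = mu + rng.normal(0.0, 1.0, cfg.n_samples)
        x = x - x.min() + 0.5
        rows.append(x)
        gene_ids.append(gid)
    tpm = pd.DataFrame(np.round(np.array(rows), 6), index=gene_ids,
                       columns=samples)
    tpm.index.name = "gene_id"
    return tpm, meta, truth


# --------------------------------------------------------------------------
# variant generation
# --------------------------------------------------------------------------

def _region_intervals(bundle: GenomeBundle):
    """Per-region genomic intervals over all genes: CDS, intron, UTR."""
    regions: dict = {"CDS": [], "intron": [], "UTR": []}
    for g in bundle.genes:
        regions["CDS"].extend((g.chrom, s, e) for s, e in g.cds)
        regions["UTR"].extend((g.chrom, s, e)
                              for s, e in list(g.utr5) + list(g.utr3))
        for (s1, e1), (s2, e2) in zip(g.exons, g.exons[1:]):
            regions["intron"].append((g.chrom, e1 + 1, s2 - 1))
    return regions


def region_lengths(bundle: GenomeBundle) -> dict:
    return {r: sum(e - s + 1 for _, s, e in ivs)
            for r, ivs in _region_intervals(bundle).items()}


def _cds_pos_to_genomic(gene: SimGene, idx: int) -> int:
    """0-based position in the spliced coding sequence -> 1-based genomic."""
    ivs = gene.cds if gene.strand == "+" else list(reversed(gene.cds))
    for s, e in ivs:
        n = e - s + 1
        if idx < n:
            return s + idx if gene.strand == "+" else e - idx
        idx -= n
    raise IndexError("CDS position out of range")


def gen_variants(bundle: GenomeBundle, cfg: VariantSimConfig):
    """Plant SNVs at per-region rates; returns (vcf_lines, TruthBundle).

    Per region the planted site count is ``round(rate x length x samples)``
    exactly.  CDS SNVs are built synonymous or nonsynonymous by codon
    arithmetic per ``synonymous_fraction``; stop-creating and stop-touching
    substitutions are never planted so alternate CDSs stay translatable.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lengths = region_lengths(bundle)
    regions = _region_intervals(bundle)
    truth = TruthBundle()
    records = []      # (chrom, pos, ref, alt, region, effect)
    used: set = set()

    tf_like = [g for g in bundle.genes if g.cds]

    def plant_cds(effect: str):
        for _ in range(10_000):
            g = tf_like[int(rng.integers(0, len(tf_like)))]
            cds = g.coding_seq
            ncod = len(cds) // 3 - 1  # skip the stop codon
            ci = int(rng.integers(1, ncod))  # skip ATG to keep starts intact
            off = int(rng.integers(0, 3))
            codon = cds[3 * ci:3 * ci + 3]
            base = codon[off]
            alts = [b for b in DNA if b != base]
            rng.shuffle(alts)
            for alt in alts:
                new = codon[:off] + alt + codon[off + 1:]
                if new in STOP_CODONS:
                    continue
                same = (translate_cds(codon + "TAA")[0]
                        == translate_cds(new + "TAA")[0])
                if same != (effect == "synonymous_SNV"):
                    continue
                gpos = _cds_pos_to_genomic(g, 3 * ci + off)
                if (g.chrom, gpos) in used:
                    continue
                used.add((g.chrom, gpos))
                ref_g = bundle.chrom_seq(g.chrom)[gpos - 1]
                alt_g = alt if g.strand == "+" else revcomp(alt)
                assert ref_g == (base if g.strand == "+" else revcomp(base))
                records.append((g.chrom, gpos, ref_g, alt_g, "CDS", effect))
                return
        raise GenerationError(f"could not plant a {effect} CDS SNV")

    def plant_noncds(region: str):
        ivs = regions[region]
        weights = np.array([e - s + 1 for _, s, e in ivs], dtype=float)
        weights /= weights.sum()
        for _ in range(10_000):
            chrom, s, e = ivs[int(rng.choice(len(ivs), p=weights))]
            pos = int(rng.integers(s, e + 1))
            if (chrom, pos) in used:
                continue
            used.add((chrom, pos))
            ref = bundle.chrom_seq(chrom)[pos - 1]
            alts = [b for b in DNA if b != ref]
            alt = alts[int(rng.integers(0, 3))]
            records.append((chrom, pos, ref, alt, region, "not_applicable"))
            return
        raise GenerationError(f"could not plant a {region} SNV")

    for region, rate in cfg.target_rates:
        if region not in lengths or lengths[region] == 0:
            import warnings
            warnings.warn(f"region {region} absent from annotation; skipped")
            continue
        count = int(round(rate * lengths[region] * cfg.n_samples))
        truth.variant_counts[region] = count
        if region == "CDS":
            n_syn = int(round(count * cfg.synonymous_fraction))
            for _ in range(n_syn):
                plant_cds("synonymous_SNV")
            for _ in range(count - n_syn):
                plant_cds("nonsynonymous_SNV")
        else:
            for _ in range(count):
                plant_noncds(region)

    records.sort(key=lambda r: (r[0], r[1]))
    truth.variant_sites = [
        {"chrom": c, "pos": p, "ref": r, "alt": a,
         "region": reg, "effect": eff}
        for c, p, r, a, reg, eff in records]
    lines = ["##fileformat=VCFv4.2"]
    for name in sorted(bundle.chroms):
        lines.append(f"##contig=<ID={name},length={len(bundle.chroms[name])}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for c, p, r, a, _, _ in records:
        lines.append(f"{c}\t{p}\t.\t{r}\t{a}\t.\tPASS\t.")
    return lines, truth


def write_vcf(lines: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(lines) + "\n")
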