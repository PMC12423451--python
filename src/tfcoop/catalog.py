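"""TF catalog: gene models joined with family labels, gene-structure and
protein statistics, and sliding-window TF cluster detection.

The clustering rule tiles each chromosome with fixed nonoverlapping windows
(default 250 kb, anchored at coordinate 1), assigns each TF gene to the
window containing its start coordinate, calls windows with >= 2 TFs primary
clusters, and merges runs of consecutive-window primary clusters that share
at least one TF family, transitively, into merged clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._seq import gc_fraction as _gc
from ._seq import revcomp, translate_cds


@dataclass
class GeneModel:
    gene_id: str
    family: str            # TF family label or "SG" for structural genes
    chrom: str
    strand: str
    start: int             # 1-based inclusive
    end: int
    exons: list = field(default_factory=list)
    cds: list = field(default_factory=list)
    utr5: list = field(default_factory=list)
    utr3: list = field(default_factory=list)

    @property
    def is_tf(self) -> bool:
        return self.family != "SG"

    def validate(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        for name in ("exons", "cds", "utr5", "utr3"):
            ivs = getattr(self, name)
            for (s, e), nxt in zip(ivs, ivs[1:] + [None]):
                if s > e or s < self.start or e > self.end:
                    raise ValueError(f"{self.gene_id}: bad {name} interval")
                if nxt is not None and nxt[0] <= e:
                    raise ValueError(f"{self.gene_id}: {name} not sorted "
                                     "or overlapping")


@dataclass
class TFCatalog:
    genes: dict                      # gene_id -> GeneModel
    genome: dict                     # chrom -> sequence string
    cds_seqs: dict = field(default_factory=dict)   # spliced, coding strand
    proteins: dict = field(default_factory=dict)

    @property
    def chrom_lengths(self) -> dict:
        return {c: len(s) for c, s in self.genome.items()}

    def tf_genes(self) -> list:
        return [g for g in self.genes.values() if g.is_tf]


@dataclass
class ProteinStats:
    aa_count: int
    molecular_weight_da: float
    theoretical_pi: float


@dataclass
class ClusterSet:
    """Window-based TF clusters.

    ``primary_clusters`` holds every >=2-TF window; ``merged_clusters``
    holds maximal runs of >= 2 family-sharing consecutive primaries.
    ``final_clusters`` is the partition actually reported: merged clusters
    plus primaries not absorbed into any merge.
    """

    window_bp: int
    singlets: list = field(default_factory=list)   # dicts
    primary_clusters: list = field(default_factory=list)
    merged_clusters: list = field(default_factory=list)

    @property
    def final_clusters(self) -> list:
        absorbed = {w for m in self.merged_clusters
                    for w in zip([m["chrom"]] * len(m["windows"]),
                                 m["windows"])}
        out = list(self.merged_clusters)
        out.extend(p for p in self.primary_clusters
                   if (p["chrom"], p["windows"][0]) not in absorbed)
        return out

    def membership_counts(self) -> tuple[int, int]:
        n_singlet = len(self.singlets)
        n_clustered = sum(len(c["members"]) for c in self.final_clusters)
        return n_singlet, n_clustered


# --------------------------------------------------------------------------
# loading
# --------------------------------------------------------------------------

def _read_fasta(path: str | Path) -> dict:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def load_catalog(gff3: str | Path, genome_fasta: str | Path,
                 family_table: str | Path) -> TFCatalog:
    """Load gene models + genome + family labels into a TFCatalog.

    Protein sequences are derived by splicing CDS intervals in genomic
    order, reverse-complementing for minus-strand genes, and translating
    with the standard code (trailing stop trimmed).  Genes whose CDS length
    is not divisible by 3 get a warning and no protein entry.  Genes absent
    from the family table are retained as structural genes ("SG").
    """
    import gffutils

    genome = _read_fasta(genome_fasta)
    fam = pd.read_csv(family_table, sep="\t", dtype=str)
    fam_map = dict(zip(fam.iloc[:, 0], fam.iloc[:, 1]))

    db = gffutils.create_db(str(gff3), dbfn=":memory:",
                            merge_strategy="create_unique", keep_order=True)
    genes: dict = {}
    for gf in db.features_of_type("gene"):
        if gf.seqid not in genome:
            raise ValueError(f"unknown chromosome {gf.seqid!r} in GFF3")
        kinds = {"exon": [], "CDS": [], "five_prime_UTR": [],
                 "three_prime_UTR": []}
        for child in db.children(gf.id):
            if child.featuretype in kinds:
                kinds[child.featuretype].append((child.start, child.end))
        gm = GeneModel(
            gene_id=gf.id, family=fam_map.get(gf.id, "SG"),
            chrom=gf.seqid, strand=gf.strand, start=gf.start, end=gf.end,
            exons=sorted(kinds["exon"]), cds=sorted(kinds["CDS"]),
            utr5=sorted(kinds["five_prime_UTR"]),
            utr3=sorted(kinds["three_prime_UTR"]))
        gm.validate()
        genes[gm.gene_id] = gm

    cat = TFCatalog(genes=genes, genome=genome)
    for gid, gm in genes.items():
        if not gm.cds:
            continue
        chrom = genome[gm.chrom]
        spliced = "".join(chrom[s - 1:e] for s, e in gm.cds)
        if gm.strand == "-":
            spliced = revcomp(spliced)
        cat.cds_seqs[gid] = spliced
        if len(spliced) % 3 != 0:
            warnings.warn(f"{gid}: CDS length not divisible by 3; "
                          "protein stats skipped")
            continue
        cat.proteins[gid] = translate_cds(spliced)
    return cat


# --------------------------------------------------------------------------
# statistics
# --------------------------------------------------------------------------

def _cv(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    m = x.mean()
    if len(x) < 2:
        return float("nan")
    s = x.std(ddof=1)
    return 0.0 if s == 0 else s / m


def gene_structure_stats(catalog: TFCatalog) -> tuple[pd.DataFrame,
                                                      pd.DataFrame]:
    """Per-gene (length, exon count, GC) and per-family mean/CV summary.

    GC is computed over the genomic gene span with ambiguous bases excluded
    from numerator and denominator.
    """
    rows = []
    for gid, gm in catalog.genes.items():
        seq = catalog.genome[gm.chrom][gm.start - 1:gm.end]
        rows.append({
            "gene_id": gid, "family": gm.family,
            "gene_length_bp": gm.end - gm.start + 1,
            "exon_count": max(1, len(gm.exons)),
            "gc_fraction": _gc(seq)})
    per_gene = pd.DataFrame(rows).set_index("gene_id")
    tf = per_gene[per_gene["family"] != "SG"]
    summaries = []
    for famname, grp in tf.groupby("family"):
        rec = {"family": famname, "n_members": len(grp)}
        for col in ("gene_length_bp", "exon_count", "gc_fraction"):
            rec[f"{col}_mean"] = grp[col].mean()
            rec[f"{col}_cv"] = _cv(grp[col].to_numpy())
        summaries.append(rec)
    per_family = pd.DataFrame(summaries).set_index("family")
    return per_gene, per_family


_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def protein_stats(protein_sequence: str) -> ProteinStats:
    """Amino-acid count, average-mass MW and theoretical pI (Bjellqvist
    pK set, bisection on Henderson-Hasselbalch net charge)."""
    from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint
    from Bio.SeqUtils.ProtParam import ProteinAnalysis

    bad = set(protein_sequence) - _STANDARD_AA
    if bad or not protein_sequence:
        raise ValueError(
            f"nonstandard residue(s) {sorted(bad)!r}" if bad
            else "empty protein sequence")
    pa = ProteinAnalysis(protein_sequence)
    # full pH bisection range (the library default clamps to [4.05, 12],
    # which truncates strongly basic or acidic peptides)
    pi = IsoelectricPoint(protein_sequence).pi(min_=0.0, max_=14.0)
    return ProteinStats(
        aa_count=len(protein_sequence),
        molecular_weight_da=float(pa.molecular_weight()),
        theoretical_pi=float(pi))


def protein_charge_at_ph(protein_sequence: str, ph: float) -> float:
    """Net charge at a given pH under the same pK set as protein_stats."""
    from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

    return float(IsoelectricPoint(protein_sequence).charge_at_pH(ph))


# --------------------------------------------------------------------------
# clustering
# --------------------------------------------------------------------------

def cluster_tfs(catalog: TFCatalog, window_bp: int = 250_000,
                max_gap: int = 0,
                exclude_chroms: set | None = None) -> ClusterSet:
    """Detect TF clusters by the fixed-window rule.

    A TF belongs to the window containing its start coordinate.  Windows
    with >= 2 TFs are primary clusters; primary clusters whose window
    indices differ by at most ``max_gap + 1`` (default: strictly
    consecutive) on one chromosome and that share >= 1 family are merged
    transitively.  TFs on ``exclude_chroms`` (e.g. unplaced contigs) are
    ignored.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    exclude = exclude_chroms or set()
    by_window: dict = {}
    for g in catalog.tf_genes():
        if g.chrom in exclude:
            continue
        widx = (g.start - 1) // window_bp
        by_window.setdefault((g.chrom, widx), []).append(g)

    cs = ClusterSet(window_bp=window_bp)
    prim_by_chrom: dict = {}
    for (chrom, widx), members in sorted(by_window.items()):
        members.sort(key=lambda g: g.start)
        if len(members) == 1:
            cs.singlets.append({"chrom": chrom, "window": widx,
                                "gene_id": members[0].gene_id})
        else:
            rec = {"chrom": chrom, "windows": [widx],
                   "members": sorted(g.gene_id for g in members),
                   "families": sorted({g.family for g in members}),
                   "kind": "primary",
                   "span": (widx * window_bp + 1, (widx + 1) * window_bp)}
            cs.primary_clusters.append(rec)
            prim_by_chrom.setdefault(chrom, []).append(rec)

    # merge edges between primaries within the window gap that share a
    # family; merged clusters are the transitive closures (components)
    for chrom, prims in sorted(prim_by_chrom.items()):
        prims.sort(key=lambda r: r["windows"][0])
        parent = list(range(len(prims)))

        def find(u):
            while parent[u] != u:
                parent[u] = parent[parent[u]]
                u = parent[u]
            return u

        for a in range(len(prims)):
            for b in range(a + 1, len(prims)):
                if prims[b]["windows"][0] - prims[a]["windows"][0] \
                        > max_gap + 1:
                    break
                if set(prims[a]["families"]) & set(prims[b]["families"]):
                    parent[find(b)] = find(a)
        comps: dict = {}
        for u in range(len(prims)):
            comps.setdefault(find(u), []).append(prims[u])
        for run in comps.values():
            _flush_run(cs, chrom, run, window_bp)
    return cs


def _flush_run(cs: ClusterSet, chrom: str, run: list, window_bp: int) -> None:
    if len(run) < 2:
        return
    windows = [r["windows"][0] for r in run]
    cs.merged_clusters.append({
        "chrom": chrom, "windows": windows,
        "members": sorted(m for r in run for m in r["members"]),
        "families": sorted({f for r in run for f in r["families"]}),
        "kind": "merged",
        "span": (windows[0] * window_bp + 1, (windows[-1] + 1) * window_bp),
        "contributing_windows": windows})


def family_chrom_summary(catalog: TFCatalog, cluster_set: ClusterSet | None
                         = None) -> dict:
    """Per-family member counts, per-chromosome TF counts and the Pearson
    correlation between TF count and chromosome length."""
    tf = catalog.tf_genes()
    fam_counts = pd.Series([g.family for g in tf]).value_counts().to_dict()
    chrom_counts = {c: 0 for c in catalog.genome}
    for g in tf:
        chrom_counts[g.chrom] = chrom_counts.get(g.chrom, 0) + 1
    lengths = catalog.chrom_lengths
    r = p = None
    if len(lengths) < 3:
        warnings.warn("fewer than 3 chromosomes; correlation omitted")
    else:
        x = np.array([lengths[c] for c in sorted(lengths)], dtype=float)
        y = np.array([chrom_counts.get(c, 0) for c in sorted(lengths)],
                     dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn("zero variance; correlation undefined")
        else:
            r, p = map(float, sps.pearsonr(x, y))
    cluster_participation: dict = {}
    if cluster_set is not None:
        by_gene = {g.gene_id: g.family for g in tf}
        for c in cluster_set.final_clusters:
            for m in c["members"]:
                famname = by_gene.get(m)
                if famname:
                    cluster_participation[famname] = \
                        cluster_participation.get(famname, 0) + 1
    return {"family_counts": fam_counts,
            "chrom_tf_counts": chrom_counts,
            "tf_count_vs_length_r": r,
            "tf_count_vs_length_p": p,
            "family_cluster_members": cluster_participation}
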