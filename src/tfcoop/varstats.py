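"""Variant classification, per-region variation rates and NG86 Ka/Ks.

Variation rates follow the site-count convention: a variant position is
counted once per region regardless of how many samples carry it, and the
rate is ``sites / (region length x sample count)``.  Family rates divide
by the summed region length of the family members that possess the region
(intronless members drop out of the intron denominator).

Ka/Ks uses the Nei-Gojobori (1986) method with Jukes-Cantor correction:
per-codon synonymous site fractions averaged over the two sequences and
pathway-averaged difference counts for codons differing at more than one
position.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ._seq import DNA, STOP_CODONS, revcomp, translate_cds

_REGION_ORDER = ("CDS", "UTR", "intron")   # precedence within a gene


@dataclass
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str | None
    region: str          # CDS | intron | UTR | intergenic
    effect: str          # synonymous_SNV | nonsynonymous_SNV | other |
    #                      not_applicable


@dataclass
class KaKsResult:
    ka: float | None
    ks: float | None
    ratio: float | None
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float


# --------------------------------------------------------------------------
# annotation
# --------------------------------------------------------------------------

def _in_intervals(pos: int, ivs: list) -> bool:
    return any(s <= pos <= e for s, e in ivs)


def _genomic_to_cds_index(gene, pos: int) -> int:
    """1-based genomic position -> 0-based index in the spliced CDS."""
    ivs = gene.cds if gene.strand == "+" else list(reversed(gene.cds))
    idx = 0
    for s, e in ivs:
        if s <= pos <= e:
            return idx + (pos - s if gene.strand == "+" else e - pos)
        idx += e - s + 1
    raise ValueError(f"position {pos} not in CDS of {gene.gene_id}")


def classify_cds_snv(catalog, gene, pos: int, ref: str, alt: str) -> str:
    """Synonymous vs nonsynonymous by codon substitution, strand-aware."""
    cds = catalog.cds_seqs[gene.gene_id]
    idx = _genomic_to_cds_index(gene, pos)
    if gene.strand == "-":
        ref, alt = revcomp(ref), revcomp(alt)
    if cds[idx] != ref:
        raise ValueError(
            f"ref allele {ref} does not match CDS of {gene.gene_id} "
            f"at {gene.chrom}:{pos}")
    ci = idx // 3
    codon = cds[3 * ci:3 * ci + 3]
    mutated = codon[:idx % 3] + alt + codon[idx % 3 + 1:]
    aa_ref = str(translate_cds(codon + "TAA"))[:1] \
        if codon not in STOP_CODONS else "*"
    aa_alt = str(translate_cds(mutated + "TAA"))[:1] \
        if mutated not in STOP_CODONS else "*"
    return "synonymous_SNV" if aa_ref == aa_alt else "nonsynonymous_SNV"


def annotate_variants(vcf: str | Path, catalog) -> list[VariantRecord]:
    """Assign region (CDS > UTR > intron precedence) and coding effect to
    every VCF record; multi-allelic records split per alternate allele."""
    from cyvcf2 import VCF

    by_chrom: dict = {}
    for g in catalog.genes.values():
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.start)

    out: list[VariantRecord] = []
    for rec in VCF(str(vcf)):
        chrom, pos, ref = rec.CHROM, rec.POS, rec.REF
        genome_ref = catalog.genome.get(chrom, "")[pos - 1:pos - 1 + len(ref)]
        if genome_ref and genome_ref != ref:
            raise ValueError(f"ref mismatch at {chrom}:{pos} "
                             f"(VCF {ref}, genome {genome_ref})")
        for alt in rec.ALT:
            gene = next((g for g in by_chrom.get(chrom, [])
                         if g.start <= pos <= g.end), None)
            if gene is None:
                out.append(VariantRecord(chrom, pos, ref, alt, None,
                                         "intergenic", "not_applicable"))
                continue
            if _in_intervals(pos, gene.cds):
                region = "CDS"
            elif _in_intervals(pos, gene.utr5) or \
                    _in_intervals(pos, gene.utr3):
                region = "UTR"
            else:
                region = "intron"
            if region != "CDS":
                effect = "not_applicable"
            elif len(ref) == 1 and len(alt) == 1 and alt in DNA:
                effect = classify_cds_snv(catalog, gene, pos, ref, alt)
            else:
                effect = "other"
            out.append(VariantRecord(chrom, pos, ref, alt,
                                     gene.gene_id, region, effect))
    return out


# --------------------------------------------------------------------------
# rates
# --------------------------------------------------------------------------

def gene_region_lengths(gene) -> dict:
    """bp of CDS, intron and UTR in one gene model."""
    cds = sum(e - s + 1 for s, e in gene.cds)
    utr = sum(e - s + 1 for s, e in list(gene.utr5) + list(gene.utr3))
    intron = sum(s2 - e1 - 1 for (s1, e1), (s2, e2)
                 in zip(gene.exons, gene.exons[1:]))
    return {"CDS": cds, "UTR": utr, "intron": intron}


def project_region_rate(records: list[VariantRecord], region_lengths: dict,
                        n_samples: int) -> pd.DataFrame:
    """rate = unique variant sites / (region length x sample count)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    sites: dict = {}
    for r in records:
        if r.region in region_lengths:
            sites.setdefault(r.region, set()).add((r.chrom, r.pos))
    rows = []
    for region, length in sorted(region_lengths.items()):
        if length <= 0:
            warnings.warn(f"region {region} has zero length; rate omitted")
            continue
        count = len(sites.get(region, set()))
        rows.append({"region": region, "site_count": count,
                     "region_length_bp": length, "n_samples": n_samples,
                     "rate": count / (length * n_samples)})
    return pd.DataFrame(rows).set_index("region")


def family_region_rate(records: list[VariantRecord], catalog,
                       n_samples: int = 90) -> pd.DataFrame:
    """Per-family per-region rate:
    sites / (summed region length of members possessing the region x
    sample count).  Families with no member possessing a region omit that
    row."""
    fam_len: dict = {}
    fam_members: dict = {}
    gene_fam: dict = {}
    for g in catalog.tf_genes():
        gene_fam[g.gene_id] = g.family
        lens = gene_region_lengths(g)
        for region, n in lens.items():
            if n > 0:
                key = (g.family, region)
                fam_len[key] = fam_len.get(key, 0) + n
                fam_members[key] = fam_members.get(key, 0) + 1
    sites: dict = {}
    for r in records:
        fam = gene_fam.get(r.gene_id)
        if fam and r.region in _REGION_ORDER:
            sites.setdefault((fam, r.region), set()).add((r.chrom, r.pos))
    rows = []
    for (fam, region), total_len in sorted(fam_len.items()):
        count = len(sites.get((fam, region), set()))
        rows.append({"family": fam, "region": region, "site_count": count,
                     "region_length_bp": total_len,
                     "n_members_with_region": fam_members[(fam, region)],
                     "n_samples": n_samples,
                     "rate": count / (total_len * n_samples)})
    return pd.DataFrame(rows).set_index(["family", "region"])


# --------------------------------------------------------------------------
# NG86 Ka/Ks
# --------------------------------------------------------------------------

def _aa(codon: str) -> str:
    return "*" if codon in STOP_CODONS else translate_cds(codon + "TAA")[0]


def _syn_fraction(codon: str) -> float:
    """Synonymous fraction of the 9 one-step changes (3 per position);
    changes to stop codons count as nonsynonymous."""
    aa0 = _aa(codon)
    syn = 0
    for i in range(3):
        for b in DNA:
            if b == codon[i]:
                continue
            new = codon[:i] + b + codon[i + 1:]
            if new not in STOP_CODONS and _aa(new) == aa0:
                syn += 1
    return syn / 3.0


def _pathway_diffs(ca: str, cb: str) -> tuple[float, float]:
    """Mean (syn, nonsyn) one-step difference counts over substitution
    orderings; orderings passing through stop codons are excluded unless
    every ordering is blocked."""
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur, syn, nonsyn, blocked = ca, 0, 0, False
        for i in order:
            nxt = cur[:i] + cb[i] + cur[i + 1:]
            if nxt in STOP_CODONS:
                blocked = True
            if _aa(cur) == _aa(nxt):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        paths.append((blocked, syn, nonsyn))
    open_paths = [(s, n) for b, s, n in paths if not b]
    if not open_paths:
        open_paths = [(s, n) for _, s, n in paths]
    ms = sum(s for s, _ in open_paths) / len(open_paths)
    mn = sum(n for _, n in open_paths) / len(open_paths)
    return ms, mn


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_kaks(cds_a: str, cds_b: str) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction."""
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise ValueError("sequences must have equal length")
    if len(cds_a) % 3 != 0 or not cds_a:
        raise ValueError("length must be a positive multiple of 3")
    if set(cds_a + cds_b) - set(DNA):
        raise ValueError("sequences must be gap-free ACGT")
    codons_a = [cds_a[i:i + 3] for i in range(0, len(cds_a), 3)]
    codons_b = [cds_b[i:i + 3] for i in range(0, len(cds_b), 3)]
    if any(c in STOP_CODONS for c in codons_a[:-1] + codons_b[:-1]):
        raise ValueError("internal stop codon")
    # drop a trailing stop codon pair if present
    if codons_a[-1] in STOP_CODONS and codons_b[-1] in STOP_CODONS:
        codons_a, codons_b = codons_a[:-1], codons_b[:-1]
    if any(c in STOP_CODONS for c in codons_a + codons_b):
        raise ValueError("internal stop codon")

    s_sites = sum((_syn_fraction(a) + _syn_fraction(b)) / 2.0
                  for a, b in zip(codons_a, codons_b))
    n_sites = 3.0 * len(codons_a) - s_sites
    sd = nd = 0.0
    for a, b in zip(codons_a, codons_b):
        ds, dn = _pathway_diffs(a, b)
        sd += ds
        nd += dn
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    ratio = None
    if ka is not None and ks is not None and ks > 0:
        ratio = ka / ks
    return KaKsResult(ka=ka, ks=ks, ratio=ratio,
                      syn_sites=s_sites, nonsyn_sites=n_sites,
                      syn_diffs=sd, nonsyn_diffs=nd)


def family_kaks_from_variants(records: list[VariantRecord],
                              catalog) -> pd.DataFrame:
    """Per-family mean Ka/Ks from variant-derived alternate CDSs.

    Each gene's CDS SNVs are applied to the reference CDS to form an
    alternate CDS; NG86 runs on the (reference, alternate) pair; the
    family value is the mean over members with a defined ratio.
    """
    snvs: dict = {}
    for r in records:
        if r.region == "CDS" and r.effect in ("synonymous_SNV",
                                              "nonsynonymous_SNV"):
            snvs.setdefault(r.gene_id, []).append(r)
    rows = []
    for gid, recs in sorted(snvs.items()):
        gene = catalog.genes[gid]
        if not gene.is_tf:
            continue
        cds = list(catalog.cds_seqs[gid])
        for r in recs:
            idx = _genomic_to_cds_index(gene, r.pos)
            alt = r.alt if gene.strand == "+" else revcomp(r.alt)
            cds[idx] = alt
        try:
            res = ng86_kaks(catalog.cds_seqs[gid], "".join(cds))
        except ValueError as err:
            warnings.warn(f"{gid}: Ka/Ks skipped ({err})")
            continue
        rows.append({"gene_id": gid, "family": gene.family,
                     "ka": res.ka, "ks": res.ks, "ratio": res.ratio})
    per_gene = pd.DataFrame(rows)
    if per_gene.empty:
        return pd.DataFrame(columns=["mean_kaks", "n_genes"])
    defined = per_gene.dropna(subset=["ratio"])
    fam = defined.groupby("family")["ratio"].agg(
        mean_kaks="mean", n_genes="count")
    return fam
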