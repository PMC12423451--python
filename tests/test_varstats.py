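"""Variant annotation, variation-rate formulas and NG86 Ka/Ks."""

import itertools

import numpy as np
import pytest

import tfcoop as t
from tfcoop import synthgen as sg
from tfcoop import varstats as vs
from tfcoop._seq import STOP_CODONS, revcomp


@pytest.fixture(scope="module")
def annotated(catalog_dir, catalog, genome_bundle):
    cfg = t.VariantSimConfig(seed=4)
    lines, truth = t.gen_variants(genome_bundle, cfg)
    vcf = catalog_dir / "variants.vcf"
    sg.write_vcf(lines, vcf)
    return vs.annotate_variants(vcf, catalog), truth, cfg


# ------------------------------------------------------------ annotation --

def test_region_partition_and_truth(annotated, genome_bundle):
    records, truth, _ = annotated
    from collections import Counter
    got = Counter(r.region for r in records)
    assert dict(got) == truth.variant_counts
    # genic records carry exactly one region
    assert all(r.region in ("CDS", "intron", "UTR", "intergenic")
               for r in records)


def test_planted_effects_recovered(annotated):
    records, truth, _ = annotated
    planted = {(s["chrom"], s["pos"]): s["effect"]
               for s in truth.variant_sites if s["region"] == "CDS"}
    for r in records:
        if r.region == "CDS":
            assert r.effect == planted[(r.chrom, r.pos)]


def test_effect_self_consistency(annotated, catalog):
    """Re-translate every mutated codon to confirm each call."""
    from Bio.Seq import Seq

    records, _, _ = annotated
    for r in records:
        if r.region != "CDS":
            continue
        gene = catalog.genes[r.gene_id]
        cds = catalog.cds_seqs[r.gene_id]
        idx = vs._genomic_to_cds_index(gene, r.pos)
        alt = r.alt if gene.strand == "+" else revcomp(r.alt)
        mutated = cds[:idx] + alt + cds[idx + 1:]
        same = Seq(cds).translate() == Seq(mutated).translate()
        assert same == (r.effect == "synonymous_SNV")


def test_indel_and_intergenic_classification(tmp_path, catalog,
                                             genome_bundle):
    g = next(g for g in genome_bundle.genes if g.cds)
    pos = g.cds[0][0]
    ref2 = genome_bundle.chrom_seq(g.chrom)[pos - 1:pos + 1]
    lines = ["##fileformat=VCFv4.2",
             f"##contig=<ID={g.chrom},length=2000000>",
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
             f"{g.chrom}\t{pos}\t.\t{ref2}\t{ref2[0]}\t.\tPASS\t."]
    vcf = tmp_path / "indel.vcf"
    sg.write_vcf(lines, vcf)
    recs = vs.annotate_variants(vcf, catalog)
    assert recs[0].region == "CDS" and recs[0].effect == "other"


def test_ref_mismatch_raises(tmp_path, catalog, genome_bundle):
    g = genome_bundle.genes[0]
    pos = g.start
    actual = genome_bundle.chrom_seq(g.chrom)[pos - 1]
    wrong = "A" if actual != "A" else "C"
    lines = ["##fileformat=VCFv4.2",
             f"##contig=<ID={g.chrom},length=2000000>",
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
             f"{g.chrom}\t{pos}\t.\t{wrong}\tG\t.\tPASS\t."]
    vcf = tmp_path / "bad.vcf"
    sg.write_vcf(lines, vcf)
    with pytest.raises(ValueError, match=str(pos)):
        vs.annotate_variants(vcf, catalog)


# ------------------------------------------------------------------ rates --

def test_project_rate_formula():
    recs = [vs.VariantRecord("c", i + 1, "A", "G", "g", "CDS",
                             "synonymous_SNV") for i in range(10)]
    table = vs.project_region_rate(recs, {"CDS": 1000}, 5)
    assert table.loc["CDS", "rate"] == pytest.approx(0.002)
    empty = vs.project_region_rate([], {"CDS": 1000}, 5)
    assert empty.loc["CDS", "rate"] == 0.0


def test_planted_rates_recovered_exactly(annotated, genome_bundle):
    records, truth, cfg = annotated
    lengths = sg.region_lengths(genome_bundle)
    table = vs.project_region_rate(records, lengths, cfg.n_samples)
    for region, count in truth.variant_counts.items():
        assert table.loc[region, "site_count"] == count
        assert table.loc[region, "rate"] == pytest.approx(
            count / (lengths[region] * cfg.n_samples))


def test_rate_linearity_in_samples(annotated, genome_bundle):
    records, _, _ = annotated
    lengths = sg.region_lengths(genome_bundle)
    r1 = vs.project_region_rate(records, lengths, 5)["rate"]
    r2 = vs.project_region_rate(records, lengths, 10)["rate"]
    assert np.allclose(r1.to_numpy(), 2 * r2.to_numpy())


def test_family_rate_formula_hand_example():
    from tfcoop import catalog as cat

    # two family members, each one 500-bp intron, 9 sites, 90 samples
    genes = {}
    for i, start in enumerate((1, 10_001)):
        genes[f"T{i}"] = cat.GeneModel(
            gene_id=f"T{i}", family="FX", chrom="chr1", strand="+",
            start=start, end=start + 1199,
            exons=[(start, start + 349), (start + 850, start + 1199)],
            cds=[(start, start + 349), (start + 850, start + 1199)])
    c = cat.TFCatalog(genes=genes, genome={"chr1": "A" * 20_000})
    recs = [vs.VariantRecord("chr1", 400 + i, "A", "G", "T0", "intron",
                             "not_applicable") for i in range(9)]
    table = vs.family_region_rate(recs, c, n_samples=90)
    assert table.loc[("FX", "intron"), "rate"] == pytest.approx(1e-4)
    assert ("FX", "UTR") not in table.index   # no member has a UTR


def test_family_counts_partition(annotated, catalog):
    records, _, _ = annotated
    table = vs.family_region_rate(records, catalog, n_samples=90)
    tf_cds_sites = {(r.chrom, r.pos) for r in records
                    if r.region == "CDS"
                    and catalog.genes[r.gene_id].is_tf}
    per_family = table.xs("CDS", level="region")["site_count"].sum()
    assert per_family == len(tf_cds_sites)


# ------------------------------------------------------------------ NG86 --

CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
          if a + b + c not in STOP_CODONS]


def oracle_ng86(seq_a, seq_b):
    """Independent pathway-enumeration implementation of NG86."""
    from Bio.Seq import Seq

    def aa(codon):
        return "*" if codon in STOP_CODONS else str(Seq(codon).translate())

    def syn_sites(codon):
        n = 0
        for pos in range(3):
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1:]
                if mut not in STOP_CODONS and aa(mut) == aa(codon):
                    n += 1
        return n / 3

    s_sites = n_sites = sd = nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        s = (syn_sites(ca) + syn_sites(cb)) / 2
        s_sites += s
        n_sites += 3 - s
        diff = [p for p in range(3) if ca[p] != cb[p]]
        if not diff:
            continue
        paths = []
        for order in itertools.permutations(diff):
            cur, ds, dn, blocked = ca, 0, 0, False
            for p in order:
                nxt = cur[:p] + cb[p] + cur[p + 1:]
                blocked = blocked or nxt in STOP_CODONS
                if aa(cur) == aa(nxt):
                    ds += 1
                else:
                    dn += 1
                cur = nxt
            paths.append((blocked, ds, dn))
        ok = [(s_, n_) for b, s_, n_ in paths if not b] or \
        [(s_, n_) for _, s_, n_ in paths]
        sd += sum(p[0] for p in ok) / len(ok)
        nd += sum(p[1] for p in ok) / len(ok)
    return s_sites, n_sites, sd, nd


def test_identical_sequences():
    r = vs.ng86_kaks("ATGAAATTT", "ATGAAATTT")
    assert r.ka == 0 and r.ks == 0 and r.ratio is None


def test_single_synonymous_codon():
    r = vs.ng86_kaks("TTT", "TTC")
    assert r.syn_diffs == 1 and r.nonsyn_diffs == 0
    assert r.ka == 0


def test_site_count_invariant():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(2, 30))
        a = "".join(CODONS[i] for i in rng.integers(0, len(CODONS), n))
        r = vs.ng86_kaks(a, a)
        assert r.syn_sites + r.nonsyn_sites == pytest.approx(3 * n)


def test_ng86_symmetry_and_oracle_agreement():
    rng = np.random.default_rng(17)
    for _ in range(200):
        ca = CODONS[int(rng.integers(0, len(CODONS)))]
        cb = CODONS[int(rng.integers(0, len(CODONS)))]
        r = vs.ng86_kaks(ca, cb)
        r_sym = vs.ng86_kaks(cb, ca)
        assert r.syn_diffs == pytest.approx(r_sym.syn_diffs, abs=1e-12)
        s, n, sd, nd = oracle_ng86(ca, cb)
        assert r.syn_sites == pytest.approx(s, abs=1e-9)
        assert r.nonsyn_sites == pytest.approx(n, abs=1e-9)
        assert r.syn_diffs == pytest.approx(sd, abs=1e-9)
        assert r.nonsyn_diffs == pytest.approx(nd, abs=1e-9)


def test_length_violations_raise():
    with pytest.raises(ValueError):
        vs.ng86_kaks("ATG", "ATGAAA")
    with pytest.raises(ValueError):
        vs.ng86_kaks("AT", "AT")
    with pytest.raises(ValueError):
        vs.ng86_kaks("TAAATG", "TAAATG")   # internal stop


# ------------------------------------------------------------ family K/K --

def test_family_kaks_from_planted_variants(annotated, catalog):
    records, _, _ = annotated
    table = vs.family_kaks_from_variants(records, catalog)
    assert (table["mean_kaks"] >= 0).all()
    assert "SG" not in table.index
    # deterministic given the same inputs
    again = vs.family_kaks_from_variants(records, catalog)
    assert table.equals(again)


def test_purely_synonymous_family_has_zero_kaks(catalog, genome_bundle,
                                                tmp_path):
    lines, truth = t.gen_variants(
        genome_bundle,
        t.VariantSimConfig(target_rates=(("CDS", 2e-3),),
                           synonymous_fraction=1.0, seed=2))
    vcf = tmp_path / "syn.vcf"
    sg.write_vcf(lines, vcf)
    records = vs.annotate_variants(vcf, catalog)
    table = vs.family_kaks_from_variants(records, catalog)
    assert (table["mean_kaks"] == 0).all() and len(table) > 0


def test_no_variants_gives_empty_table(catalog):
    assert vs.family_kaks_from_variants([], catalog).empty
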