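"""Motif transfer, promoter extraction and PWM scanning."""

import itertools
from collections import Counter

import numpy as np
import pytest

import tfcoop as t
from tfcoop import motifmap as mm
from tfcoop._seq import revcomp


def one_hot(word, motif_id="m"):
    mat = np.full((len(word), 4), 1e-9)
    for r, b in enumerate(word):
        mat[r, "ACGT".index(b)] = 1.0
    return mm.MotifPWM(motif_id, mat / mat.sum(axis=1, keepdims=True))


def promoter(seq, gene_id="g"):
    return {gene_id: mm.Promoter(gene_id, seq, "chr1", (1, len(seq)),
                                 "+", len(seq) + 1, False)}


# ----------------------------------------------------------------- MEME --

def test_one_hot_meme_round_trip(tmp_path):
    m = one_hot("ACGT")
    mm.write_meme([m], tmp_path / "m.meme")
    back = mm.read_meme(tmp_path / "m.meme")
    assert len(back) == 1
    assert np.abs(back[0].matrix - m.matrix).max() < 1e-6


def test_empty_meme_file(tmp_path):
    (tmp_path / "e.meme").write_text("MEME version 4\n")
    assert mm.read_meme(tmp_path / "e.meme") == []


def test_bad_row_sum_rejected():
    with pytest.raises(ValueError, match="bad"):
        mm.MotifPWM("bad", np.array([[0.5, 0.1, 0.1, 0.1]]))


def test_meme_read_agrees_with_biopython(tmp_path, motif_library):
    """Independent cross-check of the parser against Bio.motifs (which
    round-trips through integer counts, hence the loose tolerance)."""
    from Bio import motifs as bio_motifs

    path = tmp_path / "lib.meme"
    motif_library.write(path)
    ours = mm.read_meme(path)
    with open(path) as fh:
        theirs = bio_motifs.parse(fh, "minimal")
    assert [m.motif_id for m in ours] == [m.name for m in theirs]
    for a, b in zip(ours, theirs):
        bm = np.array([[b.pwm[ltr][i] for ltr in "ACGT"]
                       for i in range(b.length)])
        assert np.abs(a.matrix - bm).max() < 0.06


# ------------------------------------------------------------- homology --

def test_self_match_dominates():
    rng = np.random.default_rng(0)
    ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    other = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    asg = mm.best_hit_assign({"q": ref}, {"s1": ref, "s2": other},
                             {"s1": "M1", "s2": "M2"})
    assert asg["q"].subject_tf == "s1" and asg["q"].e_value < 1e-50


def test_random_queries_stay_unassigned():
    rng = np.random.default_rng(7)
    refs = {f"s{i}": "".join("ACGT"[b] for b in rng.integers(0, 4, 300))
            for i in range(3)}
    ref_map = {k: f"M{k}" for k in refs}
    unassigned = 0
    for _ in range(100):
        q = "".join("ACGT"[b] for b in rng.integers(0, 4, 300))
        asg = mm.best_hit_assign({"q": q}, refs, ref_map, e_max=1e-3)
        unassigned += "q" not in asg
    assert unassigned >= 95


def test_tie_breaks_lexicographically():
    seq = "ACGTACGTACGTACGTACGTACGTACGTACGT"
    asg = mm.best_hit_assign({"q": seq}, {"sB": seq, "sA": seq},
                             {"sA": "MA", "sB": "MB"})
    assert asg["q"].subject_tf == "sA"


def test_evalue_decreases_with_score():
    evs = [mm.karlin_altschul_evalue(s, 300, 300) for s in range(10, 40)]
    assert all(a > b for a, b in zip(evs, evs[1:]))


def test_ungapped_score_known_cases():
    assert mm.ungapped_local_score("AAAA", "AAAA") == 4
    assert mm.ungapped_local_score("AAAA", "TTTT") == 0
    # match run of 5 with one mismatch inside: 5*1 - 2 + 3 = 6
    assert mm.ungapped_local_score("AAAAACAAA", "AAAAAGAAA") == 6
    with pytest.raises(ValueError):
        mm.ungapped_local_score("AXX", "AAA")


def test_precomputed_hits_bypass_aligner():
    asg = mm.best_hit_assign({"q": "ACGT"}, {"s": "ACGT"}, {"s": "M1"},
                             precomputed_hits=[("q", "s", 100, 1e-20)])
    assert asg["q"].motif_id == "M1"


# ------------------------------------------------------------ promoters --

def _mini_catalog(tmp_path, strand, start, end, chrom_len=1000):
    from tfcoop import catalog as cat

    rng = np.random.default_rng(3)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, chrom_len))
    genes = {"g": cat.GeneModel(gene_id="g", family="F1", chrom="chr1",
                                strand=strand, start=start, end=end)}
    return cat.TFCatalog(genes=genes, genome={"chr1": seq})


def test_plus_strand_promoter_span(tmp_path):
    c = _mini_catalog(tmp_path, "+", 1001, 1100, chrom_len=2000)
    p = mm.extract_promoters(c, length=500)["g"]
    assert p.span == (501, 1000) and len(p.seq) == 500 and not p.truncated
    assert p.seq == c.genome["chr1"][500:1000]


def test_minus_strand_promoter_truncated(tmp_path):
    c = _mini_catalog(tmp_path, "-", 800, 900, chrom_len=1000)
    p = mm.extract_promoters(c, length=500)["g"]
    assert p.span == (901, 1000) and len(p.seq) == 100 and p.truncated
    assert p.seq == revcomp(c.genome["chr1"][900:1000])


def test_gene_at_chromosome_start_gives_empty_promoter(tmp_path):
    c = _mini_catalog(tmp_path, "+", 1, 100)
    with pytest.warns(UserWarning):
        p = mm.extract_promoters(c, length=500)["g"]
    assert p.seq == ""


# ------------------------------------------------------------- scanning --

def test_paper_style_planted_coordinates():
    word = "AAAGATCAAAATAAGAGAAG"
    rng = np.random.default_rng(0)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
    seq = seq[:168] + word + seq[188:]
    hits = mm.pwm_scan(one_hot(word), promoter(seq), p_max=1e-4)
    assert [(h.start_upstream, h.end_upstream, h.strand)
            for h in hits] == [(332, 313, "+")]


def test_absent_motif_stringent_threshold_yields_nothing():
    rng = np.random.default_rng(1)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
    hits = mm.pwm_scan(one_hot("AAAGATCAAAATAAGAGAAG"), promoter(seq),
                       p_max=1e-9)
    assert hits == []


def test_short_promoter_gives_no_hits():
    hits = mm.pwm_scan(one_hot("ACGTACGT"), promoter("ACG"), p_max=1.0)
    assert hits == []


def test_null_distribution_normalised(motif_library):
    for pwm in motif_library.pwms():
        dist, _ = mm.null_score_distribution(pwm)
        assert abs(dist.sum() - 1.0) < 1e-9


@pytest.mark.parametrize("width", [4, 6, 8])
def test_null_distribution_matches_enumeration(width):
    rng = np.random.default_rng(width)
    mat = rng.dirichlet(np.ones(4) * 0.5, size=width)
    pwm = mm.MotifPWM("m", mat)
    iscores = mm._integer_scores(pwm)
    counts = Counter()
    for word in itertools.product(range(4), repeat=width):
        counts[sum(int(iscores[i, c]) for i, c in enumerate(word))] += 1
    dist, offset = mm.null_score_distribution(pwm)
    sf = mm._survival(dist)
    for s in list(counts)[:50] + [max(counts)]:
        brute = sum(v for k, v in counts.items() if k >= s) / 4 ** width
        assert sf[s - offset] == pytest.approx(brute, abs=1e-9)


def test_scan_completeness_vs_brute_force():
    """On short sequences every offset/strand scored by hand must agree."""
    rng = np.random.default_rng(2)
    mat = rng.dirichlet(np.ones(4), size=5)
    pwm = mm.MotifPWM("m", mat)
    iscores = mm._integer_scores(pwm)
    seq = "ACGTACGTACG"
    hits = mm.pwm_scan(pwm, promoter(seq), p_max=1.0)
    # brute force: all offsets, both strands
    expected = []
    rc = iscores[::-1][:, [3, 2, 1, 0]]
    for i in range(len(seq) - 4):
        window = [("ACGT".index(b)) for b in seq[i:i + 5]]
        for strand, sc in (("+", iscores), ("-", rc)):
            score = sum(int(sc[r, c]) for r, c in enumerate(window))
            expected.append((len(seq) - i, strand, score))
    got = [(h.start_upstream, h.strand, round(h.score * 1000))
           for h in hits]
    assert sorted(got) == sorted(expected)


def test_strand_symmetry():
    rng = np.random.default_rng(9)
    mat = rng.dirichlet(np.ones(4), size=6)
    pwm = mm.MotifPWM("m", mat)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
    fwd = mm.pwm_scan(pwm, promoter(seq), p_max=1.0)
    rev = mm.pwm_scan(pwm, promoter(revcomp(seq)), p_max=1.0)
    a = sorted((h.start_upstream, h.strand, round(h.score, 9))
               for h in fwd)
    flip = {"+": "-", "-": "+"}
    b = sorted((len(seq) - h.end_upstream + 1, flip[h.strand],
                round(h.score, 9)) for h in rev)
    assert a == b


# ------------------------------------------------------------ summaries --

def _toy_assignment():
    return {"TF1": mm.Assignment("M1", "ref1", 1e-6, 50),
            "TF2": mm.Assignment("M2", "ref2", 1e-6, 50)}


def test_distribution_summary_counts(catalog):
    asg = {}
    tf_ids = [g.gene_id for g in catalog.tf_genes()][:2]
    sg_ids = [gid for gid, g in catalog.genes.items() if not g.is_tf][:3]
    asg[tf_ids[0]] = mm.Assignment("M1", "r", 0.0, 10)
    fam = catalog.genes[tf_ids[0]].family
    hits = [mm.MotifHit(g, "M1", 30, 25, "+", 5.0, 1e-5) for g in sg_ids]
    table = mm.distribution_summary(hits, catalog, asg)
    assert table.loc[fam, "sg_hits"] == 3
    assert table.loc[fam, "sg_avg_per_motif"] == 3.0
    assert table.loc[fam, "tf_hits"] == 0


def test_self_regulation_detection():
    asg = _toy_assignment()
    hits = [mm.MotifHit("TF1", "M1", 332, 313, "+", 9.9, 1e-6),
            mm.MotifHit("TF2", "M1", 100, 95, "+", 9.9, 1e-6),
            mm.MotifHit("TF3", "M2", 50, 45, "+", 9.9, 1e-6)]
    out = mm.detect_self_regulation(hits, asg)
    assert out == [("TF1", "M1", (332, 313))]
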