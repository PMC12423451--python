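"""Transfer a binding motif by CDS homology and scan promoters.

A query TF whose CDS matches a reference TF inherits that reference's
binding motif (lowest e-value under ungapped local alignment); the motif
is then located in a promoter where it was planted 313 bp upstream of
the TSS — the scanner must report the range 332-313.
"""

import numpy as np

from tfcoop import motifmap as mm

rng = np.random.default_rng(0)
ref_cds = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
query_cds = ref_cds[:150] + "".join("ACGT"[i]
                                    for i in rng.integers(0, 4, 150))
decoy_cds = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))

assignment = mm.best_hit_assign(
    {"AtrTF1": query_cds},
    {"AthA": ref_cds, "AthB": decoy_cds},
    {"AthA": "MotifA", "AthB": "MotifB"},
    e_max=1e-3)
a = assignment["AtrTF1"]
print(f"AtrTF1 <- {a.motif_id} from {a.subject_tf} "
      f"(e = {a.e_value:.2e}, score = {a.score})")
# The 150-bp shared prefix gives an overwhelming e-value; the decoy
# reference never wins.

word = "AAAGATCAAAATAAGAGAAG"
mat = np.full((len(word), 4), 1e-9)
for r, b in enumerate(word):
    mat[r, "ACGT".index(b)] = 1.0
pwm = mm.MotifPWM("MotifA", mat / mat.sum(axis=1, keepdims=True))

promoter_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
promoter_seq = promoter_seq[:168] + word + promoter_seq[188:]
promoters = {"AtrTF1": mm.Promoter("AtrTF1", promoter_seq, "chr1",
                                   (1, 500), "+", 501, False)}
for h in mm.pwm_scan(pwm, promoters, p_max=1e-4):
    print(f"hit in {h.gene_id}: {h.start_upstream}-{h.end_upstream} bp "
          f"upstream, strand {h.strand}, p = {h.p_value:.2e}")
# Coordinates are bp upstream of the TSS (far edge first), matching the
# convention used for self-regulation reports.

selfreg = mm.detect_self_regulation(
    mm.pwm_scan(pwm, promoters, p_max=1e-4), assignment)
print("self-regulation candidates:", selfreg)
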