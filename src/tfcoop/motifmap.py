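"""Binding-motif transfer and promoter scanning.

Motifs are position probability matrices in minimal MEME format.  They are
transferred from a reference TF set to query TFs by best-hit ungapped local
CDS alignment (match +1 / mismatch -2) with Karlin-Altschul e-values, and
promoters (500 bp upstream of the annotated gene start, coding strand) are
scanned with log-odds scores whose p-values come from the exact null score
distribution computed by dynamic programming over scores discretised at
1e-3 granularity — the same construction FIMO uses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seq import DNA, revcomp

# Karlin-Altschul parameters for ungapped +1/-2 nucleotide scoring
KA_LAMBDA = 1.33
KA_K = 0.621

_SCORE_GRANULARITY = 1e-3


@dataclass
class MotifPWM:
    """Position probability matrix over A,C,G,T (rows = positions)."""

    motif_id: str
    matrix: np.ndarray                  # L x 4 probabilities
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    source_tf_id: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 \
                or self.matrix.shape[0] < 1:
            raise ValueError(f"{self.motif_id}: matrix must be L x 4")
        if (self.matrix < 0).any():
            raise ValueError(f"{self.motif_id}: negative probabilities")
        rowsums = self.matrix.sum(axis=1)
        if np.abs(rowsums - 1.0).max() > 1e-6:
            raise ValueError(
                f"{self.motif_id}: rows must sum to 1 (max deviation "
                f"{np.abs(rowsums - 1.0).max():.2e})")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]


@dataclass
class HomologyHit:
    query_id: str
    subject_id: str
    score: int
    bits: float
    e_value: float


@dataclass
class Assignment:
    motif_id: str
    subject_tf: str
    e_value: float
    score: int


@dataclass
class Promoter:
    gene_id: str
    seq: str               # 5'->3' on the coding strand
    chrom: str
    span: tuple            # genomic (start, end), 1-based inclusive
    strand: str
    tss: int
    truncated: bool


@dataclass
class MotifHit:
    gene_id: str
    motif_id: str
    start_upstream: int    # far edge, bp upstream of TSS (1-based)
    end_upstream: int      # near edge; start_upstream >= end_upstream
    strand: str
    score: float           # log2 odds
    p_value: float


# --------------------------------------------------------------------------
# MEME minimal format
# --------------------------------------------------------------------------

def read_meme(path: str | Path) -> list[MotifPWM]:
    """Parse a minimal MEME motif file into probability matrices."""
    text = Path(path).read_text()
    lines = [ln.rstrip() for ln in text.splitlines()]
    background = np.full(4, 0.25)
    motifs: list[MotifPWM] = []
    i = 0
    while i < len(lines):
        ln = lines[i].strip()
        if ln.startswith("Background letter frequencies"):
            i += 1
            toks = lines[i].split()
            freqs = {toks[j]: float(toks[j + 1])
                     for j in range(0, len(toks), 2)}
            background = np.array([freqs.get(b, 0.25) for b in DNA])
        elif ln.startswith("MOTIF"):
            toks = ln.split()
            motif_id = toks[1]
            source = toks[2] if len(toks) > 2 else ""
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                    "letter-probability matrix"):
                i += 1
            header = lines[i]
            width = int(header.split("w=")[1].split()[0])
            rows = []
            for j in range(width):
                i += 1
                rows.append([float(v) for v in lines[i].split()])
            motifs.append(MotifPWM(motif_id=motif_id,
                                   matrix=np.array(rows),
                                   background=background.copy(),
                                   source_tf_id=source))
        i += 1
    return motifs


def write_meme(motifs: list[MotifPWM], path: str | Path) -> None:
    out = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", ""]
    bg = motifs[0].background if motifs else np.full(4, 0.25)
    out.append("Background letter frequencies")
    out.append(" ".join(f"{b} {f:.6f}" for b, f in zip(DNA, bg)))
    out.append("")
    for m in motifs:
        name = f"MOTIF {m.motif_id}"
        if m.source_tf_id:
            name += f" {m.source_tf_id}"
        out.append(name)
        out.append(f"letter-probability matrix: alength= 4 w= {m.width} "
                   f"nsites= 20 E= 0")
        for row in m.matrix:
            out.append(" " + " ".join(f"{v:.6f}" for v in row))
        out.append("")
    Path(path).write_text("\n".join(out))


# --------------------------------------------------------------------------
# homology transfer
# --------------------------------------------------------------------------

def ungapped_local_score(a: str, b: str, match: int = 1,
                         mismatch: int = -2) -> int:
    """Best ungapped local alignment score (Kadane over all diagonals)."""
    if not a or not b:
        return 0
    for s, name in ((a, "query"), (b, "subject")):
        if set(s) - set("ACGTN"):
            raise ValueError(f"{name} contains non-ACGTN characters")
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)
    m, n = len(xa), len(xb)
    eq = xa[:, None] == xb[None, :]
    # N never matches
    isn = (xa[:, None] == ord("N")) | (xb[None, :] == ord("N"))
    s = np.where(eq & ~isn, match, mismatch).astype(np.int64)
    ii, jj = np.meshgrid(np.arange(m), np.arange(n), indexing="ij")
    diag = (jj - ii) + (m - 1)
    pos = np.minimum(ii, jj)
    width = min(m, n)
    D = np.full((m + n - 1, width), -4 * match, dtype=np.int64)
    D[diag, pos] = s
    running = np.zeros(m + n - 1, dtype=np.int64)
    best = 0
    for t in range(width):
        running = np.maximum(0, running + D[:, t])
        best = max(best, int(running.max()))
    return best


def karlin_altschul_evalue(score: int, m: int, n: int,
                           lam: float = KA_LAMBDA, k: float = KA_K) -> float:
    return k * m * n * math.exp(-lam * score)


def best_hit_assign(query_cds: dict, reference_cds: dict,
                    ref_motif_map: dict, e_max: float = 1e-3,
                    precomputed_hits: list | None = None) -> dict:
    """Assign each query TF the motif of its lowest-e-value reference TF.

    ``ref_motif_map`` maps reference TF id -> motif id; references without
    a motif are excluded from candidacy.  Ties on e-value break by higher
    raw score, then lexicographically smaller subject id.  Returns
    query_id -> :class:`Assignment` for queries passing ``e_max``.

    ``precomputed_hits`` (query, subject, score, e_value) tuples bypass the
    internal aligner, e.g. to consume an external homology search.
    """
    candidates = {sid: seq for sid, seq in reference_cds.items()
                  if sid in ref_motif_map}
    hits: dict[str, list[HomologyHit]] = {q: [] for q in query_cds}
    if precomputed_hits is not None:
        for q, sid, score, ev in precomputed_hits:
            if q in hits and sid in ref_motif_map:
                bits = (KA_LAMBDA * score - math.log(KA_K)) / math.log(2)
                hits[q].append(HomologyHit(q, sid, int(score), bits,
                                           float(ev)))
    else:
        for q, qseq in query_cds.items():
            for sid in sorted(candidates):
                score = ungapped_local_score(qseq, candidates[sid])
                ev = karlin_altschul_evalue(score, len(qseq),
                                            len(candidates[sid]))
                bits = (KA_LAMBDA * score - math.log(KA_K)) / math.log(2)
                hits[q].append(HomologyHit(q, sid, score, bits, ev))
    out: dict = {}
    for q, hh in hits.items():
        ok = [h for h in hh if h.e_value <= e_max]
        if not ok:
            continue
        best = min(ok, key=lambda h: (h.e_value, -h.score, h.subject_id))
        out[q] = Assignment(motif_id=ref_motif_map[best.subject_id],
                            subject_tf=best.subject_id,
                            e_value=best.e_value, score=best.score)
    return out


# --------------------------------------------------------------------------
# promoters
# --------------------------------------------------------------------------

def extract_promoters(catalog, length: int = 500) -> dict:
    """Promoter (<= ``length`` bp immediately 5' of the gene start, coding
    strand) for every gene; truncated at chromosome bounds."""
    out: dict = {}
    for gid, g in catalog.genes.items():
        chrom = catalog.genome[g.chrom]
        if g.strand == "+":
            lo = max(1, g.start - length)
            hi = g.start - 1
            seq = chrom[lo - 1:hi] if hi >= lo else ""
            tss = g.start
        else:
            lo = g.end + 1
            hi = min(len(chrom), g.end + length)
            seq = revcomp(chrom[lo - 1:hi]) if hi >= lo else ""
            tss = g.end
        truncated = len(seq) < length
        if not seq:
            warnings.warn(f"{gid}: empty promoter at chromosome edge")
        out[gid] = Promoter(gene_id=gid, seq=seq, chrom=g.chrom,
                            span=(lo, hi) if hi >= lo else (tss, tss),
                            strand=g.strand, tss=tss, truncated=truncated)
    return out


# --------------------------------------------------------------------------
# PWM scanning
# --------------------------------------------------------------------------

def _integer_scores(motif: MotifPWM, pseudocount: float = 1e-3
                    ) -> np.ndarray:
    """Log2-odds scores discretised to integer units of 1e-3."""
    p = (motif.matrix + pseudocount) / (1.0 + 4.0 * pseudocount)
    lo = np.log2(p / motif.background[None, :])
    return np.round(lo / _SCORE_GRANULARITY).astype(np.int64)


def null_score_distribution(motif: MotifPWM, pseudocount: float = 1e-3
                            ) -> tuple[np.ndarray, int]:
    """Exact null distribution of the integer match score under background.

    Returns (probabilities, offset): ``probabilities[s - offset]`` is the
    null probability of integer score ``s``.  Computed by column-wise
    convolution; the total mass is exactly the product of per-column sums,
    so it equals 1 up to float rounding.
    """
    iscores = _integer_scores(motif, pseudocount)
    bg = motif.background
    dist = np.array([1.0])
    offset = 0
    for row in iscores:
        lo, hi = int(row.min()), int(row.max())
        new = np.zeros(len(dist) + hi - lo)
        for base in range(4):
            sh = int(row[base]) - lo
            new[sh:sh + len(dist)] += bg[base] * dist
        dist = new
        offset += lo
    return dist, offset


def _survival(dist: np.ndarray) -> np.ndarray:
    """sf[i] = P(score index >= i), computed right-to-left."""
    return np.cumsum(dist[::-1])[::-1]


_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(DNA):
    _CODE[ord(_b)] = _i
_RC_COLS = np.array([3, 2, 1, 0])


def pwm_scan(motif: MotifPWM, promoters: dict, p_max: float = 1e-4,
             pseudocount: float = 1e-3) -> list[MotifHit]:
    """Scan promoters on both strands; report hits with p <= p_max.

    Coordinates are bp upstream of the TSS, 1-based inclusive, reported as
    (start_upstream, end_upstream) with start >= end (far edge first).
    Windows containing ambiguous bases are skipped.
    """
    L = motif.width
    iscores = _integer_scores(motif, pseudocount)
    dist, offset = null_score_distribution(motif, pseudocount)
    sf = _survival(dist)
    max_idx = len(dist) - 1

    # minus-strand scan uses the reverse-complemented PWM on the given seq
    strand_scores = {"+": iscores, "-": iscores[::-1][:, _RC_COLS]}
    hits: list[MotifHit] = []
    for gid in sorted(promoters):
        prom = promoters[gid]
        P = len(prom.seq)
        if P < L:
            continue
        codes = _CODE[np.frombuffer(prom.seq.encode(), dtype=np.uint8)]
        win = np.lib.stride_tricks.sliding_window_view(codes, L)
        valid = (win < 4).all(axis=1)
        for strand, sc in strand_scores.items():
            padded = np.hstack([sc, np.full((L, 1), -10**9, dtype=np.int64)])
            tot = padded[np.arange(L), win].sum(axis=1)
            idx = np.clip(tot - offset, 0, max_idx)
            pv = np.where(tot - offset <= 0, 1.0,
                          np.where(tot - offset > max_idx, 0.0, sf[idx]))
            for i in np.nonzero(valid & (pv <= p_max))[0]:
                hits.append(MotifHit(
                    gene_id=gid, motif_id=motif.motif_id,
                    start_upstream=P - int(i),
                    end_upstream=P - int(i) - L + 1,
                    strand=strand,
                    score=int(tot[i]) * _SCORE_GRANULARITY,
                    p_value=float(pv[i])))
    hits.sort(key=lambda h: (h.gene_id, -h.start_upstream, h.strand))
    return hits


def scan_all(motifs: list[MotifPWM], promoters: dict,
             p_max: float = 1e-4) -> list[MotifHit]:
    out: list[MotifHit] = []
    for m in motifs:
        out.extend(pwm_scan(m, promoters, p_max=p_max))
    return out


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------

def distribution_summary(hits: list[MotifHit], catalog,
                         assignment: dict):
    """Per-family motif hit totals and per-motif averages, split into SG
    and TF promoters.  A family's motifs are those assigned to its TFs."""
    import pandas as pd

    fam_motifs: dict = {}
    for q, asg in assignment.items():
        g = catalog.genes.get(q)
        if g is None or not g.is_tf:
            continue
        fam_motifs.setdefault(g.family, set()).add(asg.motif_id)
    gene_class = {gid: ("TF" if g.is_tf else "SG")
                  for gid, g in catalog.genes.items()}
    counts: dict = {}
    for h in hits:
        cls = gene_class.get(h.gene_id)
        if cls:
            counts[(h.motif_id, cls)] = counts.get((h.motif_id, cls), 0) + 1
    rows = []
    for famname in sorted(fam_motifs):
        motifs = sorted(fam_motifs[famname])
        sg = sum(counts.get((m, "SG"), 0) for m in motifs)
        tf = sum(counts.get((m, "TF"), 0) for m in motifs)
        rows.append({"family": famname, "n_motifs": len(motifs),
                     "sg_hits": sg, "tf_hits": tf,
                     "sg_avg_per_motif": sg / len(motifs),
                     "tf_avg_per_motif": tf / len(motifs)})
    return pd.DataFrame(rows).set_index("family") if rows else \
        pd.DataFrame(columns=["n_motifs", "sg_hits", "tf_hits",
                              "sg_avg_per_motif", "tf_avg_per_motif"])


def detect_self_regulation(hits: list[MotifHit], assignment: dict) -> list:
    """TFs whose own assigned motif occurs in their own promoter."""
    own = {(q, a.motif_id) for q, a in assignment.items()}
    out = []
    for h in hits:
        if (h.gene_id, h.motif_id) in own:
            out.append((h.gene_id, h.motif_id,
                        (h.start_upstream, h.end_upstream)))
    return sorted(set(out))
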