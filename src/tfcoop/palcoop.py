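"""Candidate TF dimer cooperation via reverse-complement palindromes.

Two binding motifs are candidate dimer partners when a fragment of one and
a fragment of the other can be concatenated into a complete reverse-
complement palindrome of at least 6 bp — equivalently, when some k-mer
(k >= 3) of motif A equals the reverse complement of a k-mer of motif B.
Motifs are reduced to max-probability consensus strings first; self-pairs
(a TF cooperating with itself) are included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from ._seq import DNA, revcomp
from .motifmap import MotifPWM


@dataclass(frozen=True)
class ConsensusMotif:
    motif_id: str
    consensus: str


@dataclass(frozen=True)
class PalindromeMatch:
    """A pair of complementary fragments: the k-mer of A at ``offset_a``
    equals revcomp of the k-mer of B at ``offset_b``; palindrome = 2k bp."""

    offset_a: int
    offset_b: int
    k: int

    def halves(self, cons_a: str, cons_b: str) -> tuple[str, str]:
        return (cons_a[self.offset_a:self.offset_a + self.k],
                cons_b[self.offset_b:self.offset_b + self.k])


def consensus(pwm: MotifPWM) -> ConsensusMotif:
    """Max-probability letter per column; ties break by A < C < G < T."""
    letters = "".join(DNA[int(i)] for i in np.argmax(pwm.matrix, axis=1))
    return ConsensusMotif(motif_id=pwm.motif_id, consensus=letters)


def find_palindromes(cons_a: str, cons_b: str,
                     min_len: int = 6) -> list[PalindromeMatch]:
    """All complementary fragment pairs of length >= min_len/2.

    Returns every (offset_a, offset_b, k) such that
    ``cons_b[offset_b:offset_b+k] == revcomp(cons_a[offset_a:offset_a+k])``,
    longest matches first.  ``min_len`` is the palindrome length 2k and
    must be even (reverse-complement palindromes have even length).
    """
    if min_len % 2 != 0 or min_len < 2:
        raise ValueError("min_len must be even and >= 2")
    for s in (cons_a, cons_b):
        if set(s) - set(DNA):
            raise ValueError("consensus contains non-ACGT letters "
                             "(degenerate codes are rejected)")
    k0 = min_len // 2
    la, lb = len(cons_a), len(cons_b)
    if la < k0 or lb < k0:
        return []
    # longest-common-extension table between A and revcomp(B):
    # ext[i][j] = length of the longest common prefix of A[i:] and RB[j:]
    rb = revcomp(cons_b)
    ext = np.zeros((la + 1, lb + 1), dtype=np.int64)
    for i in range(la - 1, -1, -1):
        for j in range(lb - 1, -1, -1):
            if cons_a[i] == rb[j]:
                ext[i, j] = ext[i + 1, j + 1] + 1
    matches = []
    for i in range(la):
        for j in range(lb):
            e = int(ext[i, j])
            for k in range(k0, e + 1):
                # fragment of RB at j maps to fragment of B at lb - j - k
                matches.append(PalindromeMatch(
                    offset_a=i, offset_b=lb - j - k, k=k))
    matches.sort(key=lambda m: (-m.k, m.offset_a, m.offset_b))
    return matches


def max_palindrome(cons_a: str, cons_b: str, min_len: int = 6) -> int:
    """Maximal palindrome length (2k) formed by fragments of a and b;
    0 when none reaches min_len."""
    m = find_palindromes(cons_a, cons_b, min_len)
    return 2 * m[0].k if m else 0


# --------------------------------------------------------------------------
# cooperation network
# --------------------------------------------------------------------------

def build_coop_network(tf_motifs: dict, tf_families: dict,
                       min_len: int = 6,
                       include_self: bool = True) -> nx.Graph:
    """Cooperation network over TFs.

    ``tf_motifs``: TF id -> consensus string (its assigned motif);
    ``tf_families``: TF id -> family label.  One edge per unordered pair
    (self-loops allowed) carrying the maximal palindrome and the best
    match; edges labelled within_family / cross_family.
    """
    g = nx.Graph()
    for tf, cons in tf_motifs.items():
        g.add_node(tf, family=tf_families.get(tf, "?"), consensus=cons)
    tfs = sorted(tf_motifs)
    for i, a in enumerate(tfs):
        for b in tfs[i:]:
            if a == b and not include_self:
                continue
            matches = find_palindromes(tf_motifs[a], tf_motifs[b], min_len)
            if not matches:
                continue
            best = matches[0]
            ha, hb = best.halves(tf_motifs[a], tf_motifs[b])
            g.add_edge(a, b,
                       max_palindrome_bp=2 * best.k,
                       half_a=ha, offset_a=best.offset_a,
                       half_b=hb, offset_b=best.offset_b,
                       within_family=(tf_families.get(a)
                                      == tf_families.get(b)),
                       n_matches=len(matches))
    return g


def family_degree_summary(g: nx.Graph):
    """Per-family mean within-family and cross-family degree.

    A self-loop contributes 1 to its TF's within-family degree (one
    cooperating pair, not two edge endpoints).
    """
    import pandas as pd

    within: dict = {}
    cross: dict = {}
    for tf in g.nodes:
        w = c = 0
        for nb in g.neighbors(tf):
            if g.edges[tf, nb]["within_family"]:
                w += 1
            else:
                c += 1
        within[tf], cross[tf] = w, c
    rows = []
    fams: dict = {}
    for tf, data in g.nodes(data=True):
        fams.setdefault(data.get("family", "?"), []).append(tf)
    for famname in sorted(fams):
        members = fams[famname]
        rows.append({
            "family": famname, "n_members": len(members),
            "mean_within_degree": float(np.mean([within[t]
                                                 for t in members])),
            "mean_cross_degree": float(np.mean([cross[t]
                                                for t in members]))})
    return pd.DataFrame(rows).set_index("family")


def pair_table(g: nx.Graph):
    import pandas as pd

    rows = []
    for a, b, d in sorted(g.edges(data=True)):
        rows.append({
            "tf_a": a, "tf_b": b,
            "family_a": g.nodes[a].get("family"),
            "family_b": g.nodes[b].get("family"),
            "max_palindrome_bp": d["max_palindrome_bp"],
            "half_a": d["half_a"], "offset_a": d["offset_a"],
            "half_b": d["half_b"], "offset_b": d["offset_b"],
            "within_family": d["within_family"]})
    return pd.DataFrame(rows)


def intersect_with_modules(g: nx.Graph, module_map: dict,
                           background_label: str = "background"):
    """Keep edges whose endpoints share a non-background module; return
    (subgraph, list of connected-component sets).

    TFs absent from ``module_map`` are ineligible.  Self-loops are kept
    whenever the TF itself is in a module.
    """
    if not module_map:
        warnings.warn("empty module map; no co-expressed edges")
    keep = nx.Graph()
    for a, b, d in g.edges(data=True):
        ma, mb = module_map.get(a), module_map.get(b)
        if ma is None or mb is None:
            continue
        if ma == background_label or mb == background_label:
            continue
        if ma == mb:
            keep.add_node(a, **g.nodes[a])
            keep.add_node(b, **g.nodes[b])
            keep.add_edge(a, b, **d)
    sets = []
    for idx, comp in enumerate(sorted(nx.connected_components(keep),
                                      key=lambda c: (-len(c),
                                                     sorted(c)[0]))):
        members = sorted(comp)
        degrees = {tf: sum(1 for _ in keep.neighbors(tf))
                   for tf in members}
        sets.append({"set_id": idx + 1, "size": len(members),
                     "members": members, "degrees": degrees})
    return keep, sets
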