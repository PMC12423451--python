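"""Small shared sequence helpers used across modules."""

from __future__ import annotations

from Bio.Seq import Seq

DNA = "ACGT"
COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# 61 sense codons (standard code), used by the simulators
STOP_CODONS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = [
    a + b + c
    for a in DNA
    for b in DNA
    for c in DNA
    if a + b + c not in STOP_CODONS
]


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard code; trailing stop is trimmed."""
    prot = str(Seq(cds).translate())
    return prot[:-1] if prot.endswith("*") else prot


def gc_fraction(seq: str) -> float:
    """GC over unambiguous bases only; ambiguous bases leave both sides."""
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in DNA)
    if acgt == 0:
        raise ValueError("sequence has no unambiguous bases")
    return (seq.count("G") + seq.count("C")) / acgt
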