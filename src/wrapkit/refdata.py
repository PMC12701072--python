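"""Bundled reference data.

The shipped HLp-like sequence is a synthetic stand-in: it places every
residue with an experimentally assigned identity and position (the
DNA-binding motifs, the leucine zipper of helix α2, the tetramerization
residues and the RD clamp) at its deposited position within the 63-residue
chain, and fills the remaining positions with a histone-like composition
whose theoretical average mass matches the 7.1 kDa reported for the real
protein.  It is suitable for exercising mass arithmetic and sequence
plumbing, not for sequence-level biology.
"""

from __future__ import annotations

from importlib import resources

from .structio import SequenceRecord

__all__ = ["hlp_like_sequence", "HLP_PINNED_RESIDUES"]

# residues with experimentally assigned identity/position (1-based)
HLP_PINNED_RESIDUES = {
    13: "A", 14: "S", 15: "K", 16: "V", 17: "K", 20: "I", 21: "K",
    26: "M", 27: "T", 28: "S", 29: "G", 35: "L", 39: "L", 42: "L",
    47: "L", 49: "R", 52: "S", 53: "N", 54: "K", 55: "R", 56: "T",
    57: "T", 58: "V", 59: "R", 61: "T", 62: "D", 63: "F",
}


def hlp_like_sequence() -> SequenceRecord:
    """The bundled synthetic 63-residue HLp-like protein sequence."""
    text = (resources.files("wrapkit") / "data" /
            "hlp_like_synthetic.fasta").read_text()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    seq = "".join(ln for ln in lines if not ln.startswith(">"))
    return SequenceRecord("HLp_like_synthetic", "protein", seq)
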