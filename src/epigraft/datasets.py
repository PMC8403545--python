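"""Bundled reference data for the IgE FG-loop display designs.

The package ships the published outcome of the FG-loop grafting study as
plain text: the ten 98-residue sequences designed to display the IgE FG
loop (donor: 2Y7Q chain B, residues 420–429, sequence VTHPHLPRAL) on the
*Staphylococcus aureus* EAP scaffold (1YN3 chain A), together with the
shared backbone secondary-structure string of the designs, the wild-type
scaffold's assigned and predicted strings, and a sequence-based prediction
per design. These are inputs for sequence-level evaluation (motif
preservation, consensus, Q3 agreement); no structure download is needed.
"""

from __future__ import annotations

from importlib import resources

__all__ = [
    "FG_LOOP_SEQUENCE",
    "R_LOOP_SEQUENCE",
    "FG_LOOP_RANGE",
    "R_LOOP_RANGE",
    "load_designed_sequences",
    "load_secondary_structures",
]

#: The IgE FG loop: 2Y7Q chain B 420–429.
FG_LOOP_SEQUENCE = "VTHPHLPRAL"
FG_LOOP_RANGE = (420, 429)
#: The IgE receptor-binding R loop: 2Y7Q chain B 331–338.
R_LOOP_SEQUENCE = "SNPRGVSA"
R_LOOP_RANGE = (331, 338)


def _data_text(name: str) -> str:
    return resources.files("epigraft").joinpath("data", name).read_text()


def load_designed_sequences() -> list[str]:
    """The ten designed display sequences, in design order (1–10)."""
    seqs = []
    for line in _data_text("designed_sequences.fasta").splitlines():
        if line.startswith(">"):
            seqs.append("")
        elif line.strip():
            seqs[-1] += line.strip()
    return seqs


def load_secondary_structures() -> dict[str, str]:
    """Secondary-structure strings keyed ``scaffold_actual``,
    ``scaffold_predicted``, ``designed`` and ``predicted_1`` … ``predicted_10``."""
    out = {}
    for line in _data_text("secondary_structures.txt").splitlines():
        if line.startswith("#") or not line.strip():
            continue
        key, value = line.split("\t")
        out[key] = value
    return out
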