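"""Design-specification preparation for an external fixed-backbone designer.

After grafting, every non-motif position of the chimera is opened to
redesign while the epitope itself stays fixed. This module classifies
positions into burial layers from relative solvent accessibility
(core / boundary / surface), assigns torsion-based secondary structure
(H / E / C), restricts the per-position amino-acid palette by
(layer, secondary structure), and emits a resfile-compatible design
specification plus the energy-weight overrides used for the design step:
aa_rep 1.0, aspartimid_penalty 1.0, buried_unsatisfied_penalty 1.0 and
approximate_buried_unsat_penalt 5.0 (term names emitted verbatim; see
docs/methods.md on the spelling of the first and last).

It also carries sequence-set utilities: a Clustal-style consensus line and
Q3 secondary-structure agreement between assigned and predicted strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULT_CONFIG, RunConfig
from .grafting import GraftedStructure
from .structure_core import ChainStructure, dihedral, sasa

__all__ = [
    "LayerLabel",
    "DesignSpec",
    "DesignRow",
    "WEIGHT_OVERRIDES",
    "PALETTE_TABLE",
    "assign_layers",
    "assign_ss",
    "build_design_spec",
    "sequence_consensus",
    "ss_agreement",
]


#: Scoring-term weight overrides handed to the external designer.
WEIGHT_OVERRIDES = {
    "aa_rep": 1.0,
    "aspartimid_penalty": 1.0,
    "buried_unsatisfied_penalty": 1.0,
    "approximate_buried_unsat_penalt": 5.0,
}

#: Allowed amino acids per (layer, secondary structure). Core positions take
#: hydrophobics (plus small residues in loops), surface positions polar and
#: charged residues plus helix/strand formers, boundary positions a broad
#: mixture; loops additionally admit G and P. Editable: pass your own table
#: to build_design_spec.
PALETTE_TABLE: dict[str, dict[str, str]] = {
    "core": {
        "H": "AFILMVW",
        "E": "FILMVWY",
        "C": "AFGILMPV",
    },
    "boundary": {
        "H": "ADEHIKLMNQRSTVWY",
        "E": "DEFHIKLMNQRSTVWY",
        "C": "ADEFGHIKLMNPQRSTVWY",
    },
    "surface": {
        "H": "DEHKNQRST",
        "E": "DEHKNQRST",
        "C": "DEGHKNPQRST",
    },
}

# Clustal conservation groups for the consensus symbol line.
STRONG_GROUPS = ["STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF",
                 "HY", "FYW"]
WEAK_GROUPS = ["CSA", "ATV", "SAG", "STNK", "STPA", "SGND", "SNDEQK",
               "NDEQHK", "NEQHRK", "FVLIM", "HFY"]


@dataclass
class LayerLabel:
    position: int            # residue index, 0-based
    relative_sasa: float
    layer: str               # "core" | "boundary" | "surface"


@dataclass
class DesignRow:
    index: int               # 1-based chimera position
    native: str
    designable: bool
    layer: str
    ss: str
    allowed: str             # sorted palette string; native always included


@dataclass
class DesignSpec:
    rows: list[DesignRow]
    weight_overrides: dict[str, float] = field(
        default_factory=lambda: dict(WEIGHT_OVERRIDES))

    def to_text(self) -> str:
        """Resfile-compatible subset: INDEX NATIVE FIXED|PIKAA <set> LAYER SS."""
        lines = ["# design spec: one row per position",
                 "# INDEX NATIVE FIXED|PIKAA<set> LAYER SS"]
        for r in self.rows:
            action = "FIXED" if not r.designable else f"PIKAA {r.allowed}"
            lines.append(f"{r.index} {r.native} {action} {r.layer} {r.ss}")
        return "\n".join(lines) + "\n"

    def weights_text(self) -> str:
        return "".join(f"{k} {v}\n" for k, v in self.weight_overrides.items())

    def fixed_indices(self) -> list[int]:
        return [r.index for r in self.rows if not r.designable]


# ---------------------------------------------------------------------------
# Layer assignment
# ---------------------------------------------------------------------------


def assign_layers(chain: ChainStructure,
                  core_max: float = DEFAULT_CONFIG.core_max_rsasa,
                  surface_min: float = DEFAULT_CONFIG.surface_min_rsasa,
                  config: RunConfig = DEFAULT_CONFIG) -> list[LayerLabel]:
    """Classify residues as core / boundary / surface by relative SASA.

    Strict inequalities: core iff relative SASA < ``core_max``; surface iff
    it is > ``surface_min``; boundary otherwise (including exact threshold
    values and residues without a tabulated normalization).
    """
    result = sasa(chain, config.sasa_probe_radius, config.sasa_points)
    labels = []
    for i, rsasa in enumerate(result.relative):
        if np.isnan(rsasa):
            layer = "boundary"
        elif rsasa < core_max:
            layer = "core"
        elif rsasa > surface_min:
            layer = "surface"
        else:
            layer = "boundary"
        labels.append(LayerLabel(i, float(rsasa), layer))
    return labels


# ---------------------------------------------------------------------------
# Secondary-structure assignment
# ---------------------------------------------------------------------------

# Torsion windows (degrees). Helix: alpha region. Strand: beta region,
# including the psi wrap-around just below -170.
_HELIX_PHI = (-100.0, -30.0)
_HELIX_PSI = (-80.0, -5.0)
_STRAND_PHI = (-180.0, -80.0)
_STRAND_PSI = (80.0, 180.0)
_STRAND_PSI_WRAP = (-180.0, -170.0)


def _in(window: tuple[float, float], value: float) -> bool:
    return window[0] <= value <= window[1]


def assign_ss(chain: ChainStructure,
              min_run: int = DEFAULT_CONFIG.ss_min_run) -> str:
    """Torsion-window secondary structure: one of H/E/C per residue.

    φ/ψ are computed from backbone coordinates; residues whose φ or ψ is
    undefined (chain termini) are coil. Helix and strand runs shorter than
    ``min_run`` revert to coil, which suppresses single-residue artifacts.
    Deterministic, hydrogen-bond free.
    """
    n = chain.length()
    phi = [None] * n
    psi = [None] * n
    get = lambda i, name: (chain.residues[i].get_atom(name).position
                           if chain.residues[i].get_atom(name) else None)
    for i in range(n):
        if i > 0:
            pts = (get(i - 1, "C"), get(i, "N"), get(i, "CA"), get(i, "C"))
            if all(p is not None for p in pts):
                phi[i] = dihedral(*pts)
        if i < n - 1:
            pts = (get(i, "N"), get(i, "CA"), get(i, "C"), get(i + 1, "N"))
            if all(p is not None for p in pts):
                psi[i] = dihedral(*pts)

    raw = []
    for i in range(n):
        if phi[i] is None or psi[i] is None:
            raw.append("C")
        elif _in(_HELIX_PHI, phi[i]) and _in(_HELIX_PSI, psi[i]):
            raw.append("H")
        elif _in(_STRAND_PHI, phi[i]) and (_in(_STRAND_PSI, psi[i])
                                           or _in(_STRAND_PSI_WRAP, psi[i])):
            raw.append("E")
        else:
            raw.append("C")
    return _smooth_runs("".join(raw), min_run)


def _smooth_runs(ss: str, min_run: int) -> str:
    out = list(ss)
    i = 0
    while i < len(ss):
        j = i
        while j < len(ss) and ss[j] == ss[i]:
            j += 1
        if ss[i] in "HE" and (j - i) < min_run:
            out[i:j] = "C" * (j - i)
        i = j
    return "".join(out)


# ---------------------------------------------------------------------------
# Design spec
# ---------------------------------------------------------------------------


def build_design_spec(grafted: GraftedStructure,
                      layers: list[LayerLabel] | None = None,
                      ss: str | None = None,
                      palette_table: dict[str, dict[str, str]] | None = None,
                      config: RunConfig = DEFAULT_CONFIG) -> DesignSpec:
    """Per-position design rows for a grafted chimera.

    Motif positions are fixed (never designable); every other position is
    designable with the palette looked up by its (layer, secondary
    structure), with the native residue always included. The palette table
    must be total over the six (layer) × three (ss) cells actually used and
    contain no empty cell.
    """
    chimera = grafted.chimera
    if layers is None:
        layers = assign_layers(chimera, config=config)
    if ss is None:
        ss = assign_ss(chimera, config.ss_min_run)
    if len(layers) != chimera.length() or len(ss) != chimera.length():
        raise ValueError("layer/ss inputs must cover every chimera position")
    table = palette_table if palette_table is not None else PALETTE_TABLE

    rows = []
    for i, res in enumerate(chimera.residues):
        layer, letter = layers[i].layer, ss[i]
        try:
            palette = table[layer][letter]
        except KeyError:
            raise ValueError(f"palette table has no cell ({layer}, {letter})")
        if not palette:
            raise ValueError(f"palette table cell ({layer}, {letter}) is empty")
        native = res.one_letter
        if grafted.provenance[i] == "motif":
            rows.append(DesignRow(i + 1, native, False, layer, letter, native))
        else:
            allowed = "".join(sorted(set(palette) | {native}))
            rows.append(DesignRow(i + 1, native, True, layer, letter, allowed))
    return DesignSpec(rows)


# ---------------------------------------------------------------------------
# Sequence-set utilities
# ---------------------------------------------------------------------------


def sequence_consensus(sequences: list[str]) -> str:
    """Clustal-style consensus symbols: '*' identical, ':' strong group,
    '.' weak group, ' ' otherwise. Input order does not matter."""
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("sequences must have equal length")
    out = []
    for col in zip(*sequences):
        letters = set(col)
        if len(letters) == 1:
            out.append("*")
        elif any(letters <= set(g) for g in STRONG_GROUPS):
            out.append(":")
        elif any(letters <= set(g) for g in WEAK_GROUPS):
            out.append(".")
        else:
            out.append(" ")
    return "".join(out)


def ss_agreement(designed_ss: str, predicted_ss: str
                 ) -> tuple[float, dict[tuple[str, str], int]]:
    """Q3 agreement between two secondary-structure strings.

    Returns the fraction of positions with identical letters and the
    per-class confusion counts keyed (designed letter, predicted letter).
    """
    if len(designed_ss) != len(predicted_ss):
        raise ValueError("secondary-structure strings differ in length")
    if not designed_ss:
        raise ValueError("empty secondary-structure strings")
    alphabet = set("HEC")
    if (set(designed_ss) | set(predicted_ss)) - alphabet:
        raise ValueError("secondary-structure letters must be H, E or C")
    confusion: dict[tuple[str, str], int] = {}
    same = 0
    for d, p in zip(designed_ss, predicted_ss):
        confusion[(d, p)] = confusion.get((d, p), 0) + 1
        same += d == p
    return same / len(designed_ss), confusion
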