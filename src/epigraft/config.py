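"""Central configuration for all tunable thresholds.

Every numeric knob used anywhere in the toolkit lives here so that a run
manifest can serialize the exact parameter set that produced a result.
Defaults follow the grafting protocol this package implements: a backbone
window matches the motif when the optimal-superposition RMSD is at most
1.0 Å, and scaffold chains are restricted to fewer than 150 residues.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


@dataclass
class RunConfig:
    """All tunables of the grafting pipeline.

    Attributes
    ----------
    rmsd_threshold:
        Maximum backbone RMSD (Å) between motif and scaffold window for a
        graft candidate to be considered a match.
    clash_distance:
        Heavy-atom distance (Å) below which a (binding partner, scaffold)
        atom pair counts as a steric clash. Strict inequality: a pair at
        exactly this distance does not clash.
    max_scaffold_size:
        Scaffold chains must have strictly fewer residues than this.
    backbone_atoms:
        Atom names used for all backbone RMSD matching. O is included
        because the carbonyl constrains loop pucker.
    chain_break_distance:
        Consecutive Cα–Cα distance (Å) above which a chain break is
        declared; windows spanning a break are never matched.
    sasa_probe_radius / sasa_points:
        Shrake–Rupley solvent probe radius (Å) and sphere points per atom.
    core_max_rsasa / surface_min_rsasa:
        Relative-SASA layer thresholds: core strictly below the first,
        surface strictly above the second, boundary otherwise.
    funnel_q / funnel_rmsd_cut / funnel_score_margin:
        Decoy-funnel parameters: fraction of lowest-scoring decoys
        averaged, RMSD cut (Å) for the best-scoring decoy, and allowed
        energy-unit margin above the relaxed-design baseline score.
    ss_min_run:
        Minimum helix/strand run length; shorter runs revert to coil.
    seed:
        Seed for every stochastic component (fixture generation).
    """

    rmsd_threshold: float = 1.0
    clash_distance: float = 3.0
    max_scaffold_size: int = 150
    backbone_atoms: tuple[str, ...] = ("N", "CA", "C", "O")
    chain_break_distance: float = 4.5
    sasa_probe_radius: float = 1.4
    sasa_points: int = 960
    core_max_rsasa: float = 0.15
    surface_min_rsasa: float = 0.60
    funnel_q: float = 0.01
    funnel_rmsd_cut: float = 2.0
    funnel_score_margin: float = 1.0
    ss_min_run: int = 3
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        if "backbone_atoms" in raw:
            raw["backbone_atoms"] = tuple(raw["backbone_atoms"])
        return cls(**raw)

    def with_overrides(self, **kwargs) -> "RunConfig":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **kwargs)


DEFAULT_CONFIG = RunConfig()
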