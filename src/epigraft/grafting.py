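"""Motif excision, scaffold window search, clash screening and grafting.

This is the core of the toolkit. A contiguous backbone motif (for example
the IgE FG loop, 2Y7Q chain B residues 420–429, sequence VTHPHLPRAL) is
excised from a donor structure together with its binding partner chain
(here the FcεRIα receptor chain). Every equal-length contiguous backbone
window of a candidate scaffold is rigidly superposed onto the motif; a
window matches when the optimal backbone RMSD is at or below a threshold
(default 1.0 Å). For each match the binding partner is carried along by the
same rigid transform and counted for heavy-atom clashes against the
scaffold outside the window — grafts that would point the epitope into the
scaffold body are rejected. An accepted match yields a chimeric chain with
the motif residues replacing the window residues and per-residue
provenance.

Matching is full-window backbone superposition with no insertions or
deletions: the graft is an equal-length backbone replacement.
"""

from __future__ import annotations

import dataclasses
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import DEFAULT_CONFIG, RunConfig
from .scaffold_db import CatalogManifest, load_catalog, load_catalog_chain
from .structure_core import (
    ChainStructure,
    Residue,
    RigidTransform,
    residues_backbone_coords,
    superpose,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Motif",
    "GraftMatch",
    "GraftedStructure",
    "MotifSpec",
    "parse_motif_spec",
    "excise_motif",
    "scan_scaffold",
    "clash_screen",
    "graft",
    "search_database",
    "SearchResult",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class Motif:
    """An excised contiguous backbone segment in its donor coordinate frame.

    ``context`` optionally holds the binding-partner chain (untransformed,
    same frame) used for clash screening.
    """

    source_id: str
    chain_id: str
    start: int
    end: int
    sequence: str
    residues: list[Residue]
    context: ChainStructure | None = None

    def __len__(self) -> int:
        return len(self.residues)

    def backbone(self, atom_set: tuple[str, ...]) -> np.ndarray:
        return residues_backbone_coords(self.residues, atom_set)


@dataclass
class GraftMatch:
    """One candidate placement of a motif on a scaffold window."""

    scaffold_id: str
    window_start: int        # author number of first window residue
    window_length: int
    rmsd: float
    transform: RigidTransform | None
    clash_count: int | None = None
    accepted: bool = False


@dataclass
class GraftedStructure:
    """Chimeric chain with per-residue provenance (motif vs scaffold)."""

    chimera: ChainStructure
    provenance: list[str]          # per residue: "scaffold" | "motif"
    match: GraftMatch
    replaced_sequence: str
    numbering_map: list[tuple[int, str, int]] = field(default_factory=list)
    # (new number, provenance, original author number)

    def motif_indices(self) -> list[int]:
        return [i for i, p in enumerate(self.provenance) if p == "motif"]


@dataclass
class MotifSpec:
    entry: str
    chain_id: str
    start: int
    end: int
    context_chain_id: str | None = None


_SPEC_RE = re.compile(
    r"^(?P<entry>[A-Za-z0-9]+):(?P<chain>[A-Za-z0-9]):(?P<start>-?\d+)-(?P<end>-?\d+)"
    r"(\+(?P<context>[A-Za-z0-9]))?$")


def parse_motif_spec(text: str) -> MotifSpec:
    """Parse ``ENTRY:CHAIN:START-END[+CONTEXTCHAIN]``, e.g. ``2Y7Q:B:420-429+A``."""
    m = _SPEC_RE.match(text.strip())
    if not m:
        raise ValueError(f"bad motif spec {text!r}; expected ENTRY:CHAIN:START-END[+CTX]")
    return MotifSpec(m["entry"].upper(), m["chain"], int(m["start"]),
                     int(m["end"]), m["context"])


# ---------------------------------------------------------------------------
# Excision
# ---------------------------------------------------------------------------


def excise_motif(chains: list[ChainStructure], chain_id: str, start: int,
                 end: int, context_chain_id: str | None = None) -> Motif:
    """Excise residues [start, end] (author numbers, inclusive) of a chain.

    Backbone and side-chain atoms are copied in the donor frame. If
    ``context_chain_id`` is given, that entire chain is attached
    untransformed as the binding partner for clash screening.
    """
    if start > end:
        raise ValueError(f"motif range start {start} > end {end}")
    by_id = {c.chain_id: c for c in chains}
    if chain_id not in by_id:
        raise ValueError(f"chain {chain_id!r} not present")
    chain = by_id[chain_id]
    residues = []
    for num in range(start, end + 1):
        res = chain.find(num)
        if res is None:
            if any(r.seq_number == num for r in chain.residues):
                raise ValueError(f"insertion-coded residue at {num}; motif "
                                 "ranges must use plain contiguous numbering")
            raise ValueError(f"residue {num} missing from chain {chain_id}")
        if not res.is_backbone_complete(require_o=(num < end)):
            raise ValueError(f"residue {res.label} is not backbone-complete")
        residues.append(res.copy())
    context = None
    if context_chain_id is not None:
        if context_chain_id not in by_id:
            raise ValueError(f"context chain {context_chain_id!r} not present")
        context = by_id[context_chain_id].copy()
    sequence = "".join(r.one_letter for r in residues)
    return Motif(chain.source_id, chain_id, start, end, sequence, residues,
                 context)


# ---------------------------------------------------------------------------
# Window scan
# ---------------------------------------------------------------------------


def _window_ok(residues: list[Residue], chain_break_distance: float) -> bool:
    if any(r.insertion_code for r in residues):
        return False
    if not all(r.is_backbone_complete(require_o=False) for r in residues):
        return False
    for a, b in zip(residues, residues[1:]):
        ca0, ca1 = a.get_atom("CA"), b.get_atom("CA")
        if ca0 is None or ca1 is None:
            return False
        if np.linalg.norm(ca1.position - ca0.position) > chain_break_distance:
            return False
    return True


def scan_scaffold(motif: Motif, scaffold: ChainStructure,
                  rmsd_threshold: float = DEFAULT_CONFIG.rmsd_threshold,
                  config: RunConfig = DEFAULT_CONFIG) -> list[GraftMatch]:
    """Superpose the motif backbone onto every contiguous scaffold window.

    Windows have exactly the motif's length (no indels); windows spanning a
    chain break or containing insertion codes are skipped. Matches with
    optimal RMSD at or below the threshold are returned sorted by
    (rmsd, window_start), each carrying the motif→scaffold rigid transform.
    """
    m = len(motif)
    if scaffold.length() < m:
        warnings.warn(f"scaffold {scaffold.source_id} shorter than motif; "
                      "no windows", stacklevel=2)
        return []
    atom_set = config.backbone_atoms
    motif_bb = motif.backbone(atom_set)
    matches = []
    for i in range(scaffold.length() - m + 1):
        window = scaffold.residues[i:i + m]
        if not _window_ok(window, config.chain_break_distance):
            continue
        try:
            window_bb = residues_backbone_coords(window, atom_set)
        except ValueError:
            continue
        transform, rmsd = superpose(motif_bb, window_bb)
        if rmsd <= rmsd_threshold:
            matches.append(GraftMatch(
                scaffold_id=scaffold.source_id,
                window_start=window[0].seq_number,
                window_length=m,
                rmsd=rmsd,
                transform=transform,
            ))
    matches.sort(key=lambda g: (g.rmsd, g.window_start))
    return matches


# ---------------------------------------------------------------------------
# Clash screening
# ---------------------------------------------------------------------------


def _window_residue_indices(scaffold: ChainStructure, match: GraftMatch
                            ) -> list[int]:
    start_idx = scaffold.index_of(match.window_start)
    return list(range(start_idx, start_idx + match.window_length))


def clash_screen(match: GraftMatch, motif: Motif, scaffold: ChainStructure,
                 clash_distance: float = DEFAULT_CONFIG.clash_distance,
                 rmsd_threshold: float = DEFAULT_CONFIG.rmsd_threshold
                 ) -> GraftMatch:
    """Count binding-partner clashes for a match and decide acceptance.

    The motif's context chain is moved by the match transform (the same
    rigid motion that places the motif on the window); every heavy-atom pair
    (context atom, scaffold atom outside the window) strictly closer than
    ``clash_distance`` counts as one clash. A match is accepted iff its RMSD
    is within the threshold and the clash count is zero.
    """
    if motif.context is None:
        raise ValueError(
            "motif has no binding-partner context chain; to search without "
            "clash screening pass skip_clash_screen=True to search_database")
    if match.transform is None:
        raise ValueError("match carries no transform")
    window = set(_window_residue_indices(scaffold, match))
    scaffold_pts = np.array([
        a.position
        for i, res in enumerate(scaffold.residues) if i not in window
        for a in res.heavy_atoms()
    ]).reshape(-1, 3)
    context_pts = np.array([
        a.position for res in motif.context.residues for a in res.heavy_atoms()
    ]).reshape(-1, 3)
    context_pts = match.transform.apply(context_pts)
    if scaffold_pts.size == 0 or context_pts.size == 0:
        count = 0
    else:
        tree_s = cKDTree(scaffold_pts)
        tree_c = cKDTree(context_pts)
        dist = tree_c.sparse_distance_matrix(tree_s, max_distance=clash_distance)
        count = int(sum(1 for d in dist.values() if d < clash_distance))
    return dataclasses.replace(
        match, clash_count=count,
        accepted=(match.rmsd <= rmsd_threshold and count == 0))


# ---------------------------------------------------------------------------
# Grafting
# ---------------------------------------------------------------------------


def graft(match: GraftMatch, motif: Motif, scaffold: ChainStructure,
          force: bool = False,
          clash_distance: float = DEFAULT_CONFIG.clash_distance
          ) -> GraftedStructure:
    """Replace the matched window with the transformed motif residues.

    The chimera keeps the scaffold length (equal-length replacement), is
    renumbered sequentially from 1 and records per-residue provenance; the
    original author numbering survives in ``numbering_map``. Motif side
    chains are kept verbatim; side-chain clashes against the scaffold are
    reported as a warning only, since they are resolved by downstream
    sequence design.
    """
    if match.transform is None:
        raise ValueError("match carries no transform; run scan_scaffold first")
    if not (match.accepted or force):
        raise ValueError("match not accepted; pass force=True to graft anyway")
    window = _window_residue_indices(scaffold, match)
    window_set = set(window)
    replaced = "".join(scaffold.residues[i].one_letter for i in window)

    placed_motif = []
    for res in motif.residues:
        moved = res.copy()
        for atom in moved.atoms:
            atom.position = match.transform.apply(atom.position)
        placed_motif.append(moved)

    residues: list[Residue] = []
    provenance: list[str] = []
    numbering_map: list[tuple[int, str, int]] = []
    motif_iter = iter(zip(placed_motif, motif.residues))
    for i, res in enumerate(scaffold.residues):
        if i in window_set:
            moved, original = next(motif_iter)
            residues.append(moved)
            provenance.append("motif")
            numbering_map.append((len(residues), "motif", original.seq_number))
        else:
            residues.append(res.copy())
            provenance.append("scaffold")
            numbering_map.append((len(residues), "scaffold", res.seq_number))
    for new_number, res in enumerate(residues, start=1):
        res.seq_number = new_number
        res.insertion_code = ""

    chimera = ChainStructure(f"{scaffold.source_id}-graft", scaffold.chain_id,
                             residues)
    _warn_sidechain_clashes(chimera, provenance, clash_distance)
    return GraftedStructure(chimera, provenance, match, replaced, numbering_map)


def _warn_sidechain_clashes(chimera: ChainStructure, provenance: list[str],
                            clash_distance: float) -> None:
    backbone = {"N", "CA", "C", "O", "OXT"}
    side_pts = [a.position for res, p in zip(chimera.residues, provenance)
                if p == "motif" for a in res.heavy_atoms()
                if a.name not in backbone]
    scaf_pts = [a.position for res, p in zip(chimera.residues, provenance)
                if p == "scaffold" for a in res.heavy_atoms()]
    if not side_pts or not scaf_pts:
        return
    tree = cKDTree(np.asarray(scaf_pts))
    n = int(sum(len(hits) for hits in
                tree.query_ball_point(np.asarray(side_pts),
                                      r=clash_distance * 0.999)))
    if n:
        warnings.warn(
            f"{n} motif side-chain/scaffold heavy-atom contacts under "
            f"{clash_distance} Å; left for downstream sequence design",
            stacklevel=3)


# ---------------------------------------------------------------------------
# Database search
# ---------------------------------------------------------------------------


@dataclass
class SearchResult:
    table: pd.DataFrame
    matches: list[GraftMatch]
    scaffolds: dict[str, ChainStructure]


def search_database(motif: Motif, catalog_dir: str | Path,
                    config: RunConfig = DEFAULT_CONFIG,
                    skip_clash_screen: bool = False,
                    manifest: CatalogManifest | None = None) -> SearchResult:
    """Scan and clash-screen every validated scaffold in a catalog.

    Returns a report with one row per window match (scaffold_id,
    window_start, rmsd, clash_count, accepted), sorted by (accepted
    descending, rmsd ascending, window_start, scaffold_id). Duplicate
    catalog entries produce duplicate rows; ordering is deterministic.
    """
    if motif.context is None and not skip_clash_screen:
        raise ValueError("motif has no context chain; pass "
                         "skip_clash_screen=True to search without screening")
    if manifest is None:
        manifest = load_catalog(catalog_dir)
    all_matches: list[GraftMatch] = []
    scaffolds: dict[str, ChainStructure] = {}
    for record in manifest.records:
        if not record.validated:
            continue
        scaffold = load_catalog_chain(catalog_dir, record)
        scaffolds[record.source_id] = scaffold
        for match in scan_scaffold(motif, scaffold, config.rmsd_threshold,
                                   config):
            if skip_clash_screen:
                match = dataclasses.replace(
                    match, clash_count=0,
                    accepted=match.rmsd <= config.rmsd_threshold)
            else:
                match = clash_screen(match, motif, scaffold,
                                     config.clash_distance,
                                     config.rmsd_threshold)
            all_matches.append(match)
    all_matches.sort(key=lambda g: (not g.accepted, g.rmsd,
                                    g.clash_count or 0, g.window_start,
                                    g.scaffold_id))
    table = pd.DataFrame(
        [(g.scaffold_id, g.window_start, round(g.rmsd, 4), g.clash_count,
          g.accepted) for g in all_matches],
        columns=["scaffold_id", "window_start", "rmsd", "clash_count",
                 "accepted"])
    return SearchResult(table, all_matches, scaffolds)
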