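"""Design evaluation: decoy funnels, motif fidelity, trajectory metrics.

A folding simulation of a designed sequence yields decoys, each with an
energy score and an RMSD to the designed structure. A successful design
shows a funnel: the lowest-scoring decoys sit at low RMSD, and the best
decoy score approaches the relaxed-design baseline score. This module
summarizes decoy sets, measures how faithfully an ensemble of models
reproduces the grafted motif geometry, and computes per-frame RMSD and
radius of gyration over multi-frame coordinate sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import DEFAULT_CONFIG, RunConfig
from .grafting import Motif
from .structure_core import (
    ATOMIC_MASS,
    ChainStructure,
    backbone_coords,
    radius_of_gyration,
    superpose,
)

__all__ = [
    "DecoyPoint",
    "FunnelSummary",
    "TrajectoryMetrics",
    "LoadedScores",
    "load_scores",
    "funnel_summary",
    "motif_fidelity",
    "MotifFidelity",
    "trajectory_metrics",
    "plot_funnel",
]


@dataclass
class DecoyPoint:
    tag: str
    score: float
    rmsd_to_design: float

    def __post_init__(self):
        if not math.isfinite(self.score):
            raise ValueError(f"decoy {self.tag}: non-finite score")
        if self.rmsd_to_design < 0:
            raise ValueError(f"decoy {self.tag}: negative RMSD")


@dataclass
class FunnelSummary:
    n_decoys: int
    best_score: float
    rmsd_of_best_score: float
    min_rmsd: float
    low_score_fraction_rmsd: float
    baseline_score: float
    funnel_success: bool


@dataclass
class TrajectoryMetrics:
    rmsd_to_reference: np.ndarray
    radius_of_gyration: np.ndarray
    rmsd_mean: float
    rmsd_sd: float
    rg_mean: float
    rg_sd: float


@dataclass
class LoadedScores:
    points: list[DecoyPoint]
    skipped: int


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------


def load_scores(source: str | Path | list[str],
                score_col: str = "score",
                rmsd_col: str = "rmsd") -> LoadedScores:
    """Read a whitespace-delimited decoy score table with a header row.

    Any dialect with named columns works; rows tagged ``SCORE:`` (the common
    folding-simulation score-file layout) are handled by stripping the tag.
    Malformed data rows are skipped and counted.
    """
    if isinstance(source, Path):
        lines = source.read_text().splitlines()
    elif isinstance(source, str):
        if "\n" not in source and Path(source).is_file():
            lines = Path(source).read_text().splitlines()
        else:
            lines = source.splitlines()
    else:
        lines = [str(l) for l in source]

    rows = []
    for line in lines:
        tokens = line.split()
        if tokens and tokens[0] == "SCORE:":
            tokens = tokens[1:]
        if tokens:
            rows.append(tokens)
    if not rows:
        raise ValueError("empty score table")
    header = rows[0]
    if score_col not in header or rmsd_col not in header:
        raise ValueError(
            f"score table header lacks required columns "
            f"{score_col!r}/{rmsd_col!r}: {header}")
    i_score = header.index(score_col)
    i_rmsd = header.index(rmsd_col)
    i_tag = header.index("description") if "description" in header else None

    points, skipped = [], 0
    for k, tokens in enumerate(rows[1:], start=1):
        try:
            tag = tokens[i_tag] if i_tag is not None else f"decoy_{k}"
            points.append(DecoyPoint(tag, float(tokens[i_score]),
                                     float(tokens[i_rmsd])))
        except (IndexError, ValueError):
            skipped += 1
    if not points:
        raise ValueError("score table contains no parseable data rows")
    return LoadedScores(points, skipped)


# ---------------------------------------------------------------------------
# Funnel summary
# ---------------------------------------------------------------------------


def funnel_summary(points: list[DecoyPoint], baseline_score: float,
                   q: float = DEFAULT_CONFIG.funnel_q,
                   rmsd_cut: float = DEFAULT_CONFIG.funnel_rmsd_cut,
                   score_margin: float = DEFAULT_CONFIG.funnel_score_margin
                   ) -> FunnelSummary:
    """Summarize a (score, RMSD) decoy cloud against a baseline score.

    The funnel succeeds iff the best-scoring decoy (score ties broken by
    lower RMSD) lies within ``rmsd_cut`` of the design and its score is at
    most ``baseline_score + score_margin``. ``low_score_fraction_rmsd`` is
    the mean RMSD of the lowest-scoring ``q`` fraction of decoys (at least
    one decoy); with ``q=1`` it is the mean RMSD of all decoys. Invariant
    under input order.
    """
    if not points:
        raise ValueError("empty decoy set")
    if len(points) < 10:
        raise ValueError("funnel summary requires at least 10 decoys")
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    ordered = sorted(points, key=lambda p: (p.score, p.rmsd_to_design))
    best = ordered[0]
    k = max(1, math.ceil(q * len(ordered)))
    low_rmsd = float(np.mean([p.rmsd_to_design for p in ordered[:k]]))
    success = (best.rmsd_to_design <= rmsd_cut
               and best.score <= baseline_score + score_margin)
    return FunnelSummary(
        n_decoys=len(points),
        best_score=best.score,
        rmsd_of_best_score=best.rmsd_to_design,
        min_rmsd=min(p.rmsd_to_design for p in points),
        low_score_fraction_rmsd=low_rmsd,
        baseline_score=baseline_score,
        funnel_success=success,
    )


def plot_funnel(points: list[DecoyPoint], baseline_score: float,
                path: str | Path, title: str = "score vs RMSD") -> None:
    """Export a simple score-vs-RMSD scatter with the baseline marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter([p.rmsd_to_design for p in points], [p.score for p in points],
               s=6, alpha=0.5)
    ax.axhline(baseline_score, color="green", lw=1,
               label="relaxed-design baseline")
    ax.set_xlabel("RMSD to design (Å)")
    ax.set_ylabel("score (energy units)")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Motif fidelity
# ---------------------------------------------------------------------------


@dataclass
class MotifFidelity:
    per_model: list[float]
    mean: float
    skipped: list[str]


def motif_fidelity(ensemble: list[ChainStructure], design: ChainStructure,
                   motif_range: tuple[int, int],
                   native_motif: Motif | None = None,
                   mode: str = "local",
                   config: RunConfig = DEFAULT_CONFIG) -> MotifFidelity:
    """Backbone RMSD of the motif region across an ensemble of models.

    ``local`` mode superposes motif-on-motif (the reference motif backbone
    is the donor motif if ``native_motif`` is given, else the design's own
    motif window). ``global`` mode superposes each full model onto the
    design backbone and then measures the motif RMSD without refitting, so
    local ≤ global per model. Models missing motif residues are skipped and
    reported by source id.
    """
    if mode not in ("local", "global"):
        raise ValueError("mode must be 'local' or 'global'")
    start, end = motif_range
    atom_set = config.backbone_atoms
    design_motif = backbone_coords(design, start, end, atom_set)
    if native_motif is not None and mode == "local":
        reference = native_motif.backbone(atom_set)
    else:
        reference = design_motif
    design_full = None
    if mode == "global":
        design_full = backbone_coords(design, design.residues[0].seq_number,
                                      design.residues[-1].seq_number, atom_set)

    per_model, skipped = [], []
    for model in ensemble:
        try:
            model_motif = backbone_coords(model, start, end, atom_set)
        except ValueError:
            skipped.append(model.source_id)
            continue
        if mode == "local":
            _, rmsd = superpose(model_motif, reference)
        else:
            model_full = backbone_coords(model,
                                         model.residues[0].seq_number,
                                         model.residues[-1].seq_number,
                                         atom_set)
            if model_full.shape != design_full.shape:
                skipped.append(model.source_id)
                continue
            transform, _ = superpose(model_full, design_full)
            placed = transform.apply(model_motif)
            rmsd = float(np.sqrt(np.mean(np.sum((placed - reference) ** 2,
                                                axis=1))))
        per_model.append(rmsd)
    mean = float(np.mean(per_model)) if per_model else float("nan")
    return MotifFidelity(per_model, mean, skipped)


# ---------------------------------------------------------------------------
# Trajectory metrics
# ---------------------------------------------------------------------------


def _select_atoms(chain: ChainStructure, selection) -> list[tuple[int, str]]:
    keys = []
    for i, res in enumerate(chain.residues):
        for atom in res.heavy_atoms():
            if selection is None or (callable(selection)
                                     and selection(res, atom)) \
                    or (isinstance(selection, (set, frozenset, tuple, list))
                        and atom.name in selection):
                keys.append((i, atom.name))
    return keys


def _frame_coords(chain: ChainStructure, keys: list[tuple[int, str]]
                  ) -> np.ndarray:
    rows = []
    for i, name in keys:
        if i >= chain.length():
            raise ValueError(f"frame lacks residue index {i}")
        atom = chain.residues[i].get_atom(name)
        if atom is None:
            raise ValueError(
                f"atom mismatch: frame residue "
                f"{chain.residues[i].label} lacks atom {name}")
        rows.append(atom.position)
    return np.asarray(rows, dtype=float)


def trajectory_metrics(frames: list[ChainStructure] | np.ndarray,
                       reference: ChainStructure,
                       selection=None) -> TrajectoryMetrics:
    """Per-frame superposed RMSD to a reference and radius of gyration.

    ``frames`` is either a list of chains (e.g. from a multi-MODEL PDB) or
    an (F, N, 3) coordinate array matching the reference selection.
    ``selection`` is None (all heavy atoms), a set of atom names, or a
    predicate ``f(residue, atom) -> bool``. Rigid motion is removed before
    the RMSD, so a rigidly transformed copy of the reference scores 0.
    """
    keys = _select_atoms(reference, selection)
    if not keys:
        raise ValueError("selection matches no atoms in the reference")
    ref_coords = _frame_coords(reference, keys)
    masses = np.array([
        ATOMIC_MASS.get(reference.residues[i].get_atom(name).element.upper(),
                        12.011)
        for i, name in keys])

    if isinstance(frames, np.ndarray):
        frame_coords = np.asarray(frames, dtype=float)
        if frame_coords.ndim != 3 or frame_coords.shape[1:] != ref_coords.shape:
            raise ValueError(
                f"coordinate array shape {frame_coords.shape} does not match "
                f"reference selection {ref_coords.shape}")
    else:
        frame_coords = np.stack([_frame_coords(f, keys) for f in frames])

    rmsds, rgs = [], []
    for coords in frame_coords:
        _, rmsd = superpose(coords, ref_coords)
        rmsds.append(rmsd)
        rgs.append(radius_of_gyration(coords, masses))
    rmsds = np.array(rmsds)
    rgs = np.array(rgs)
    return TrajectoryMetrics(rmsds, rgs,
                             float(rmsds.mean()), float(rmsds.std()),
                             float(rgs.mean()), float(rgs.std()))
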