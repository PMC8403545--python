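"""Seeded toy-structure generators with known ground truth.

Every stage of the grafting pipeline is testable without downloading any
real structure: ideal backbones are built by internal-coordinate chain
extension from canonical φ/ψ per secondary-structure letter, scaffolds can
carry a planted graft site whose backbone deviates from a motif by a
calibrated RMSD, and rigid dummy binding-partner chains can be positioned
to produce an exact, pre-verified clash count.

Ground truths are computed with geometry that is independent of the rest of
the package: optimal RMSD inside this module uses the Horn quaternion
method (closed-form eigenvalue solution), and clash counts are verified by
brute-force all-pairs distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structure_core import Atom, ChainStructure, ONE_TO_THREE, Residue

__all__ = [
    "FixtureSpec",
    "PlantedScaffold",
    "GraftScenario",
    "build_ideal_chain",
    "plant_motif",
    "make_context_decoy",
    "build_graft_scenario",
    "horn_rmsd",
]

# Ideal backbone internal coordinates (Å, degrees) — standard values.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
ANGLE_C_CA_CB = 110.6
OMEGA = 180.0

CANONICAL_TORSIONS = {"H": (-57.0, -47.0), "E": (-139.0, 135.0)}
# Coil torsions are drawn from a region outside both the helix and strand
# windows of the torsion-based assigner (phi > -80 excludes strand, psi > 20
# excludes helix); the wide psi range makes coil stretches geometrically
# diverse, so seeded coil segments are effectively unique.
COIL_PHI_RANGE = (-78.0, -45.0)
COIL_PSI_RANGE = (20.0, 160.0)


@dataclass
class FixtureSpec:
    seed: int
    ss_string: str
    sequence: str

    def __post_init__(self):
        if len(self.ss_string) != len(self.sequence):
            raise ValueError("ss_string and sequence lengths differ")
        bad = set(self.ss_string) - set("HEC")
        if bad:
            raise ValueError(f"invalid secondary-structure letters {sorted(bad)}")
        if any(aa not in ONE_TO_THREE for aa in self.sequence):
            raise ValueError("sequence contains a non-standard letter")


@dataclass
class PlantedScaffold:
    chain: ChainStructure
    site: int              # author number of the first planted residue
    achieved_rmsd: float   # optimal-superposition RMSD, independent check
    rotation: np.ndarray | None = None     # motif frame -> scaffold frame
    translation: np.ndarray | None = None


@dataclass
class GraftScenario:
    """A self-contained donor/scaffold pair with known ground truth."""

    donor: ChainStructure          # chain D, carries the motif
    context: ChainStructure        # chain X, binding-partner decoy (donor frame)
    scaffold: ChainStructure       # carries the planted site
    motif_start: int
    motif_end: int
    site: int                      # planted window start (author number)
    achieved_rmsd: float
    n_clash_atoms: int


# ---------------------------------------------------------------------------
# Internal-coordinate chain extension (NeRF)
# ---------------------------------------------------------------------------


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float
                ) -> np.ndarray:
    """Position a fourth atom from three reference atoms and internal
    coordinates (bond to c, angle b-c-new, torsion a-b-c-new)."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(angle),
                  bond * np.sin(angle) * np.cos(torsion),
                  bond * np.sin(angle) * np.sin(torsion)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def generate_torsions(spec: FixtureSpec) -> list[tuple[float, float]]:
    """Per-residue (φ, ψ) for a fixture spec: canonical helix/strand values,
    coil drawn uniformly from the seeded coil region."""
    rng = np.random.default_rng(spec.seed)
    torsions = []
    for letter in spec.ss_string:
        if letter in CANONICAL_TORSIONS:
            torsions.append(CANONICAL_TORSIONS[letter])
        else:
            torsions.append((rng.uniform(*COIL_PHI_RANGE),
                             rng.uniform(*COIL_PSI_RANGE)))
    return torsions


def build_ideal_chain(spec: FixtureSpec,
                      torsions: list[tuple[float, float]] | None = None
                      ) -> ChainStructure:
    """Build a backbone (N, CA, C, O + CB except glycine) from canonical
    torsions: helix −57/−47, strand −139/+135, coil drawn uniformly from a
    seeded region outside both windows. Bit-deterministic per seed.
    An explicit per-residue (φ, ψ) list overrides the spec-derived torsions."""
    n_res = len(spec.sequence)
    if torsions is None:
        torsions = generate_torsions(spec)
    if len(torsions) != n_res:
        raise ValueError("need one (phi, psi) pair per residue")

    n_pos = [np.array([0.0, 0.0, 0.0])]
    ca_pos = [np.array([BOND_N_CA, 0.0, 0.0])]
    angle0 = np.radians(ANGLE_N_CA_C)
    c_pos = [ca_pos[0] + BOND_CA_C * np.array([-np.cos(angle0),
                                               np.sin(angle0), 0.0])]
    for i in range(n_res - 1):
        psi = torsions[i][1]
        n_next = _place_atom(n_pos[i], ca_pos[i], c_pos[i],
                             BOND_C_N, ANGLE_CA_C_N, psi)
        ca_next = _place_atom(ca_pos[i], c_pos[i], n_next,
                              BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        phi_next = torsions[i + 1][0]
        c_next = _place_atom(c_pos[i], n_next, ca_next,
                             BOND_CA_C, ANGLE_N_CA_C, phi_next)
        n_pos.append(n_next)
        ca_pos.append(ca_next)
        c_pos.append(c_next)

    residues = []
    serial = 0
    for i, aa in enumerate(spec.sequence):
        psi = torsions[i][1]
        o = _place_atom(n_pos[i], ca_pos[i], c_pos[i],
                        BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        atoms = []
        for name, pos in (("N", n_pos[i]), ("CA", ca_pos[i]),
                          ("C", c_pos[i]), ("O", o)):
            serial += 1
            atoms.append(Atom(serial, name, name[0], pos))
        if aa != "G":
            cb = _place_atom(c_pos[i], n_pos[i], ca_pos[i],
                             BOND_CA_CB, ANGLE_C_CA_CB, 122.7)
            serial += 1
            atoms.append(Atom(serial, "CB", "C", cb))
        residues.append(Residue(ONE_TO_THREE[aa], i + 1, "", atoms))
    return ChainStructure(f"SYN{spec.seed}_A", "A", residues)


# ---------------------------------------------------------------------------
# Independent optimal-RMSD oracle (Horn quaternion method)
# ---------------------------------------------------------------------------


def horn_rmsd(coords_a: np.ndarray, coords_b: np.ndarray,
              return_transform: bool = False):
    """Optimal-superposition RMSD of two point sets by the closed-form
    quaternion eigenvalue method (proper rotations only). Independent of
    the SVD-based superposition used elsewhere in the package."""
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("expected equal-shape (N, 3) arrays")
    n = a.shape[0]
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    m = ac.T @ bc
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    eigvals, eigvecs = np.linalg.eigh(k)
    lam = eigvals[-1]
    sq = (np.sum(ac ** 2) + np.sum(bc ** 2) - 2.0 * lam) / n
    rmsd = float(np.sqrt(max(sq, 0.0)))
    if not return_transform:
        return rmsd
    w, x, y, z = eigvecs[:, -1]
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    # rot maps centered a onto centered b
    trans = b.mean(axis=0) - rot @ a.mean(axis=0)
    return rmsd, rot, trans


# ---------------------------------------------------------------------------
# Planted graft sites
# ---------------------------------------------------------------------------

_BACKBONE = ("N", "CA", "C", "O")

_MAX_CA_CA = 4.4  # planted windows must stay clear of the chain-break cutoff


def _calibrated_twist(placed: np.ndarray, motif_bb: np.ndarray,
                      target_rmsd: float, tol: float, seed: int,
                      before_ca: np.ndarray | None,
                      after_ca: np.ndarray | None
                      ) -> tuple[np.ndarray, float]:
    """Deform ``placed`` to a calibrated optimal-superposition RMSD.

    The deformation is a twist about a near end-to-end axis whose angle
    varies smoothly along the window and vanishes exactly at both ends, so
    it is locally near-isometric and the junctions stay put, yet a single
    rigid superposition cannot undo it. The twist amplitude is bisected
    against the independent quaternion RMSD until the target is met; the
    result is accepted only if every window-internal and junction Cα–Cα
    distance stays below the chain-break cutoff, retrying with a re-seeded
    axis otherwise.
    """
    n_pts = placed.shape[0]
    profile = np.sin(np.pi * np.arange(n_pts) / (n_pts - 1))
    center = placed.mean(axis=0)
    rel = placed - center

    fallback = None
    for attempt in range(30):
        rng = np.random.default_rng([seed, attempt])
        axis = placed[-1] - placed[0]
        axis = axis / np.linalg.norm(axis)
        tilt = rng.normal(size=3) * 0.4
        axis = axis + tilt - np.dot(tilt, axis) * axis
        axis /= np.linalg.norm(axis)
        par = np.outer(rel @ axis, axis)
        perp = rel - par

        def twist(s):
            theta = s * profile
            cos_t = np.cos(theta)[:, None]
            sin_t = np.sin(theta)[:, None]
            return center + par + perp * cos_t + np.cross(axis, perp) * sin_t

        def f(s):
            return horn_rmsd(motif_bb, twist(s))

        lo, hi = 0.0, 0.5
        reachable = False
        for _ in range(20):
            if f(hi) >= target_rmsd:
                reachable = True
                break
            hi *= 1.5
        if not reachable:
            continue
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            val = f(mid)
            if abs(val - target_rmsd) <= 0.25 * tol:
                lo = hi = mid
                break
            if val < target_rmsd:
                lo = mid
            else:
                hi = mid
        s = 0.5 * (lo + hi)
        noised = twist(s)
        achieved = f(s)
        if abs(achieved - target_rmsd) > tol:
            continue
        ca = noised[1::4]  # atom order N, CA, C, O
        chain_ca = [before_ca] if before_ca is not None else []
        chain_ca += list(ca)
        chain_ca += [after_ca] if after_ca is not None else []
        gaps = [np.linalg.norm(b - a)
                for a, b in zip(chain_ca, chain_ca[1:])]
        if max(gaps) < _MAX_CA_CA:
            return noised, achieved
        if fallback is None:
            fallback = (noised, achieved)
    if fallback is not None:
        warnings.warn(
            f"planted window at {target_rmsd} Å RMSD could not stay "
            "continuous; the chain contains a break at or near the window",
            stacklevel=2)
        return fallback
    raise RuntimeError(
        f"could not calibrate a planted window to {target_rmsd} Å; "
        "try a different seed")


def plant_motif(scaffold: ChainStructure, motif_residues: list[Residue],
                site: int, target_rmsd: float, seed: int = 0,
                tol: float = 0.02) -> PlantedScaffold:
    """Replace a scaffold window with a motif copy at a calibrated RMSD.

    The motif backbone is rigidly placed onto the window (Horn transform),
    then perturbed by seeded noise whose amplitude is bisected until the
    optimal-superposition RMSD between the planted window and the original
    motif is within ``tol`` of ``target_rmsd``. The achieved value — from
    the independent quaternion oracle — is recorded as ground truth.
    """
    if target_rmsd < 0:
        raise ValueError("target_rmsd must be >= 0")
    m = len(motif_residues)
    start_idx = scaffold.index_of(site)
    if start_idx + m > scaffold.length():
        raise ValueError(f"window of {m} residues at {site} does not fit")
    window = scaffold.residues[start_idx:start_idx + m]

    def bb(residues):
        rows = []
        for res in residues:
            for name in _BACKBONE:
                atom = res.get_atom(name)
                if atom is None:
                    raise ValueError(f"{res.label} lacks backbone atom {name}")
                rows.append(atom.position)
        return np.asarray(rows)

    motif_bb = bb(motif_residues)
    window_bb = bb(window)
    _, rot, trans = horn_rmsd(motif_bb, window_bb, return_transform=True)
    placed = motif_bb @ rot.T + trans

    achieved = 0.0
    noised = placed
    if target_rmsd > 0:
        prev_res = scaffold.residues[start_idx - 1] if start_idx > 0 else None
        next_res = (scaffold.residues[start_idx + m]
                    if start_idx + m < scaffold.length() else None)
        before_ca = prev_res.get_atom("CA").position if prev_res else None
        after_ca = next_res.get_atom("CA").position if next_res else None
        noised, achieved = _calibrated_twist(placed, motif_bb, target_rmsd,
                                             tol, seed, before_ca, after_ca)

    chain = scaffold.copy()
    for j, src in enumerate(motif_residues):
        res = src.copy()
        res.seq_number = window[j].seq_number
        res.insertion_code = window[j].insertion_code
        for atom in res.atoms:
            atom.position = rot @ atom.position + trans
        for k, name in enumerate(_BACKBONE):
            atom = res.get_atom(name)
            atom.position = noised[4 * j + k]
        chain.residues[start_idx + j] = res
    chain.source_id = f"{scaffold.source_id}-plant{site}"
    return PlantedScaffold(chain, site, achieved, rot, trans)


# ---------------------------------------------------------------------------
# Context (binding partner) decoys with exact clash counts
# ---------------------------------------------------------------------------


def make_context_decoy(scaffold: ChainStructure, window: tuple[int, int],
                       n_clash_atoms: int, clash_distance: float,
                       seed: int = 0, n_far_atoms: int = 5
                       ) -> ChainStructure:
    """Build a rigid dummy chain with an exact number of scaffold clashes.

    Exactly ``n_clash_atoms`` atoms are placed so each is strictly within
    ``clash_distance`` of exactly one scaffold heavy atom outside the window
    (author-number range, inclusive); every other decoy atom sits at least
    2 × ``clash_distance`` from all scaffold atoms. The construction is
    verified internally by brute-force all-pairs distances and raises after
    bounded retries if the geometry cannot be realized.
    """
    if n_clash_atoms < 0:
        raise ValueError("n_clash_atoms must be >= 0")
    rng = np.random.default_rng(seed)
    w_lo, w_hi = window
    outside = []
    for res in scaffold.residues:
        in_window = w_lo <= res.seq_number <= w_hi and not res.insertion_code
        if not in_window:
            outside.extend(a.position for a in res.heavy_atoms())
    all_pts = np.array([a.position for r in scaffold.residues
                        for a in r.heavy_atoms()])
    outside = np.asarray(outside).reshape(-1, 3)
    if n_clash_atoms > 0 and outside.shape[0] == 0:
        raise ValueError("no scaffold atoms outside the window")
    centroid = all_pts.mean(axis=0)

    positions = []
    # Clashing atoms: approach surface atoms radially from outside, backing
    # off until exactly one scaffold pair is under the cutoff.
    order = np.argsort(-np.linalg.norm(outside - centroid, axis=1))
    used = set()
    for _ in range(n_clash_atoms):
        placed = False
        for idx in order:
            if int(idx) in used:
                continue
            anchor = outside[idx]
            direction = anchor - centroid
            norm = np.linalg.norm(direction)
            direction = (direction / norm if norm > 1e-9
                         else rng.normal(size=3))
            for frac in (0.95, 0.8, 0.6, 0.4):
                p = anchor + direction * (frac * clash_distance)
                d = np.linalg.norm(outside - p, axis=1)
                if int(np.sum(d < clash_distance)) == 1 and all(
                        np.linalg.norm(np.asarray(q) - p) >= clash_distance
                        for q in positions):
                    positions.append(p)
                    used.add(int(idx))
                    placed = True
                    break
            if placed:
                break
        if not placed:
            raise RuntimeError(
                "could not place a clash atom with a unique partner; "
                "try another seed or a smaller n_clash_atoms")

    # Far atoms: strung out well beyond the scaffold.
    max_radius = float(np.max(np.linalg.norm(all_pts - centroid, axis=1)))
    far_dir = rng.normal(size=3)
    far_dir /= np.linalg.norm(far_dir)
    for k in range(n_far_atoms):
        p = centroid + far_dir * (max_radius + 4.0 * clash_distance + 2.0 * k)
        positions.append(p)

    # Brute-force verification of the advertised ground truth.
    pos_arr = np.asarray(positions)
    pair_count = int(np.sum(
        np.linalg.norm(pos_arr[:, None, :] - outside[None, :, :], axis=2)
        < clash_distance)) if outside.size else 0
    if pair_count != n_clash_atoms:
        raise RuntimeError(
            f"decoy construction produced {pair_count} clash pairs, "
            f"wanted {n_clash_atoms}")
    far_ok = np.all(
        np.linalg.norm(pos_arr[n_clash_atoms:, None, :] - all_pts[None, :, :],
                       axis=2) >= 2.0 * clash_distance)
    if not far_ok:
        raise RuntimeError("far decoy atoms intrude within 2x clash distance")

    residues = [Residue("ALA", i + 1, "",
                        [Atom(i + 1, "CA", "C", p)])
                for i, p in enumerate(positions)]
    return ChainStructure(f"DECOY{seed}_X", "X", residues)


# ---------------------------------------------------------------------------
# Full graftable scenario
# ---------------------------------------------------------------------------

# The motif window (indices 8-17) is seeded coil, so its geometry is
# effectively unique and cannot be matched by the scaffold's ideal helix or
# strand windows or by another coil stretch by chance.
_DONOR_SS = "CC" + "E" * 4 + "CC" + "C" * 10 + "E" * 4 + "CCCC"  # 26
_DONOR_SEQ = "GAVLKSTDNEQFYWHKRAVLITSGAE"
_SCAFFOLD_SS = ("CC" + "H" * 10 + "CC" + "E" * 5 + "C" * 6 + "H" * 10
                + "C" * 3 + "E" * 5 + "C" * 6 + "H" * 7 + "C" * 4)      # 60
_SCAFFOLD_SEQ = _DONOR_SEQ * 2 + "GAVLKSTD"


def build_graft_scenario(seed: int, target_rmsd: float = 0.0,
                         n_clash_atoms: int = 0,
                         clash_distance: float = 3.0) -> GraftScenario:
    """A donor chain, binding-partner decoy and scaffold with one planted
    graft site at a calibrated backbone RMSD.

    The donor motif (authors 9–18 of chain D, a loop/helix junction with
    seeded coil torsions, hence effectively unique) is planted into a
    60-residue scaffold at author number 26. The context decoy is built in
    the scaffold frame with an exact verified clash count, then moved to
    the donor frame by the inverse of the planting transform, so grafting
    the motif back onto the planted site reproduces that clash count
    (exactly so for ``target_rmsd`` 0).
    """
    donor_spec = FixtureSpec(seed + 1, _DONOR_SS, _DONOR_SEQ)
    donor_torsions = generate_torsions(donor_spec)
    donor = build_ideal_chain(donor_spec, donor_torsions)
    donor.chain_id = "D"
    donor.source_id = f"SYND{seed}_D"
    motif_residues = [r.copy() for r in donor.residues[8:18]]

    # The scaffold is built with the motif's torsions at the planted window,
    # so the window geometry matches the motif by construction and the chain
    # stays continuous; plant_motif then only applies the calibrated noise.
    scaffold_spec = FixtureSpec(seed, _SCAFFOLD_SS, _SCAFFOLD_SEQ)
    scaffold_torsions = generate_torsions(scaffold_spec)
    scaffold_torsions[25:35] = donor_torsions[8:18]
    scaffold0 = build_ideal_chain(scaffold_spec, scaffold_torsions)
    planted = plant_motif(scaffold0, motif_residues, site=26,
                          target_rmsd=target_rmsd, seed=seed + 2)
    scaffold = planted.chain
    scaffold.source_id = f"SYNS{seed}_A"

    decoy = make_context_decoy(scaffold, (26, 35), n_clash_atoms,
                               clash_distance, seed=seed + 3)
    # Move to the donor frame: x_donor = R^T (x_scaffold - t).
    for res in decoy.residues:
        for atom in res.atoms:
            atom.position = planted.rotation.T @ (atom.position
                                                  - planted.translation)
    decoy.chain_id = "X"
    decoy.source_id = f"SYND{seed}_X"
    return GraftScenario(donor, decoy, scaffold, 9, 18, 26,
                         planted.achieved_rmsd, n_clash_atoms)
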