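import numpy as np
import pytest

from epigraft.synthetic_fixtures import (FixtureSpec, build_graft_scenario,
                                         build_ideal_chain)


@pytest.fixture(scope="session")
def helix_chain():
    return build_ideal_chain(FixtureSpec(11, "C" + "H" * 10 + "C", "A" * 12))


@pytest.fixture(scope="session")
def strand_chain():
    return build_ideal_chain(FixtureSpec(11, "C" + "E" * 10 + "C", "A" * 12))


@pytest.fixture(scope="session")
def coil_chain():
    return build_ideal_chain(FixtureSpec(12, "C" * 15, "A" * 15))


@pytest.fixture(scope="session")
def scenario_exact():
    """Scaffold with an exact (0 Å) planted copy of the donor motif."""
    return build_graft_scenario(5, target_rmsd=0.0, n_clash_atoms=0)


@pytest.fixture(scope="session")
def scenario_clashing():
    """Exact planted site whose context decoy makes 3 clashes."""
    return build_graft_scenario(5, target_rmsd=0.0, n_clash_atoms=3)


def brute_force_clash_count(context_points: np.ndarray,
                            scaffold_points: np.ndarray,
                            cutoff: float) -> int:
    """O(n^2) all-pairs distance count, independent of the implementation."""
    if len(context_points) == 0 or len(scaffold_points) == 0:
        return 0
    d = np.linalg.norm(context_points[:, None, :] - scaffold_points[None, :, :],
                       axis=2)
    return int(np.sum(d < cutoff))


def grid_min_rmsd(mobile: np.ndarray, target: np.ndarray,
                  final_step_deg: float = 0.1) -> float:
    """Brute-force minimum RMSD over rotation space.

    Dense z-y-z Euler sampling, refined hierarchically down to
    ``final_step_deg`` resolution. Centroids are aligned analytically (the
    optimal translation for any fixed rotation).
    """
    from scipy.spatial.transform import Rotation

    a = mobile - mobile.mean(axis=0)
    b = target - target.mean(axis=0)

    def rmsd_for(angles):
        rot = Rotation.from_euler("zyz", angles, degrees=True).as_matrix()
        return float(np.sqrt(np.mean(np.sum((a @ rot.T - b) ** 2, axis=1))))

    best = (np.inf, (0.0, 0.0, 0.0))
    spans = (360.0, 180.0, 360.0)
    centers = (0.0, 90.0, 0.0)
    grid = 9
    for alpha in np.linspace(centers[0] - spans[0] / 2,
                             centers[0] + spans[0] / 2, grid):
        for beta in np.linspace(centers[1] - spans[1] / 2,
                                centers[1] + spans[1] / 2, grid):
            for gamma in np.linspace(centers[2] - spans[2] / 2,
                                     centers[2] + spans[2] / 2, grid):
                r = rmsd_for((alpha, beta, gamma))
                if r < best[0]:
                    best = (r, (alpha, beta, gamma))
    spans = [s / (grid - 1) * 2 for s in spans]
    while max(spans) / (grid - 1) > final_step_deg / 2:
        center = best[1]
        for alpha in np.linspace(center[0] - spans[0], center[0] + spans[0], grid):
            for beta in np.linspace(center[1] - spans[1], center[1] + spans[1], grid):
                for gamma in np.linspace(center[2] - spans[2], center[2] + spans[2], grid):
                    r = rmsd_for((alpha, beta, gamma))
                    if r < best[0]:
                        best = (r, (alpha, beta, gamma))
        spans = [2 * 2 * s / (grid - 1) for s in spans]
    return best[0]
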