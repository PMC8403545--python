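import dataclasses
import warnings

import numpy as np
import pytest

from epigraft.grafting import (
    clash_screen,
    excise_motif,
    graft,
    parse_motif_spec,
    scan_scaffold,
    search_database,
)
from epigraft.scaffold_db import build_catalog, validate_chain
from epigraft.structure_core import (residues_backbone_coords, superpose,
                                     write_pdb)
from epigraft.synthetic_fixtures import build_graft_scenario

from conftest import brute_force_clash_count


def _motif_of(scenario):
    return excise_motif([scenario.donor, scenario.context], "D",
                        scenario.motif_start, scenario.motif_end, "X")


class TestMotifSpec:
    def test_parse_full_spec(self):
        spec = parse_motif_spec("2Y7Q:B:420-429+A")
        assert (spec.entry, spec.chain_id, spec.start, spec.end,
                spec.context_chain_id) == ("2Y7Q", "B", 420, 429, "A")

    def test_context_optional(self):
        assert parse_motif_spec("1YN3:A:164-173").context_chain_id is None

    def test_garbage_rejected(self):
        with pytest.raises(ValueError):
            parse_motif_spec("2Y7Q 420 429")


class TestExcise:
    def test_motif_fields(self, scenario_exact):
        motif = _motif_of(scenario_exact)
        assert len(motif) == 10
        assert motif.sequence == scenario_exact.donor.sequence[8:18]
        assert motif.start == 9 and motif.end == 18
        assert motif.context is not None
        assert motif.context.chain_id == "X"

    def test_inverted_range_rejected(self, scenario_exact):
        with pytest.raises(ValueError, match="start"):
            excise_motif([scenario_exact.donor], "D", 10, 5)

    def test_missing_residue_rejected(self, scenario_exact):
        with pytest.raises(ValueError, match="missing"):
            excise_motif([scenario_exact.donor], "D", 20, 40)

    def test_unknown_chain_rejected(self, scenario_exact):
        with pytest.raises(ValueError, match="chain"):
            excise_motif([scenario_exact.donor], "Q", 9, 18)


class TestScan:
    def test_planted_identity_ranked_first_with_zero_rmsd(self, scenario_exact):
        motif = _motif_of(scenario_exact)
        matches = scan_scaffold(motif, scenario_exact.scaffold)
        assert matches[0].window_start == scenario_exact.site
        assert matches[0].rmsd < 1e-6
        assert matches[0].window_length == 10

    @pytest.mark.parametrize("target", [0.2, 0.5, 0.9])
    def test_calibrated_sites_recovered_within_tolerance(self, target):
        scenario = build_graft_scenario(7, target_rmsd=target)
        motif = _motif_of(scenario)
        matches = scan_scaffold(motif, scenario.scaffold)
        assert matches[0].window_start == scenario.site
        assert matches[0].rmsd == pytest.approx(target, abs=0.05)
        # the generator's independent quaternion oracle agrees
        assert matches[0].rmsd == pytest.approx(scenario.achieved_rmsd,
                                                abs=1e-6)

    def test_threshold_monotonicity(self, scenario_exact):
        motif = _motif_of(scenario_exact)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            loose = scan_scaffold(motif, scenario_exact.scaffold,
                                  rmsd_threshold=2.0)
            tight = scan_scaffold(motif, scenario_exact.scaffold,
                                  rmsd_threshold=0.5)
        tight_keys = {(m.window_start, m.rmsd) for m in tight}
        loose_keys = {(m.window_start, m.rmsd) for m in loose}
        assert tight_keys <= loose_keys

    def test_short_scaffold_warns_and_returns_empty(self, scenario_exact,
                                                    helix_chain):
        motif = _motif_of(scenario_exact)
        with pytest.warns(UserWarning, match="shorter"):
            # helix chain (12 residues) works; truncate below motif length
            short = helix_chain.copy()
            short.residues = short.residues[:5]
            assert scan_scaffold(motif, short) == []

    def test_transform_places_motif_on_window(self, scenario_exact):
        motif = _motif_of(scenario_exact)
        match = scan_scaffold(motif, scenario_exact.scaffold)[0]
        placed = match.transform.apply(motif.backbone(("N", "CA", "C", "O")))
        idx = scenario_exact.scaffold.index_of(match.window_start)
        window = scenario_exact.scaffold.residues[idx:idx + 10]
        target = residues_backbone_coords(window)
        assert np.allclose(placed, target, atol=1e-5)


class TestClashScreen:
    def test_distant_context_accepted(self, scenario_exact):
        motif = _motif_of(scenario_exact)
        match = scan_scaffold(motif, scenario_exact.scaffold)[0]
        screened = clash_screen(match, motif, scenario_exact.scaffold)
        assert screened.clash_count == 0
        assert screened.accepted

    def test_exact_counts_match_brute_force(self, scenario_clashing):
        motif = _motif_of(scenario_clashing)
        scaffold = scenario_clashing.scaffold
        match = scan_scaffold(motif, scaffold)[0]
        screened = clash_screen(match, motif, scaffold)
        assert screened.clash_count == scenario_clashing.n_clash_atoms
        assert not screened.accepted
        # independent O(n^2) oracle on the transformed context
        ctx = np.array([a.position for r in motif.context.residues
                        for a in r.heavy_atoms()])
        ctx = match.transform.apply(ctx)
        idx = scaffold.index_of(match.window_start)
        outside = np.array([a.position
                            for i, r in enumerate(scaffold.residues)
                            if not idx <= i < idx + 10
                            for a in r.heavy_atoms()])
        assert screened.clash_count == brute_force_clash_count(ctx, outside, 3.0)

    def test_coincident_atom_rejected(self, scenario_exact):
        motif = _motif_of(scenario_exact)
        scaffold = scenario_exact.scaffold
        match = scan_scaffold(motif, scaffold)[0]
        bad_context = motif.context.copy()
        bad_context.residues[0].atoms[0].position = (
            match.transform.inverse().apply(
                scaffold.residues[0].get_atom("CA").position))
        bad_motif = dataclasses.replace(motif, context=bad_context)
        screened = clash_screen(match, bad_motif, scaffold)
        assert screened.clash_count >= 1
        assert not screened.accepted

    def test_pair_at_exact_cutoff_does_not_clash(self, scenario_exact):
        # minimal scaffold: the motif window itself plus one isolated
        # outside atom; the context atom sits at exactly the cutoff from it
        from epigraft.grafting import GraftMatch
        from epigraft.structure_core import (Atom, ChainStructure, Residue,
                                             RigidTransform)
        motif = _motif_of(scenario_exact)
        window = [r.copy() for r in motif.residues]
        for i, res in enumerate(window, start=1):
            res.seq_number = i
        anchor = np.array([500.0, 0.0, 0.0])
        outside = Residue("ALA", 11, "", [Atom(1, "CA", "C", anchor)])
        scaffold = ChainStructure("MINI_A", "A", window + [outside])
        context = ChainStructure("MINI_X", "X", [Residue("ALA", 1, "", [
            Atom(1, "CA", "C", anchor + np.array([3.0, 0.0, 0.0]))])])
        match = GraftMatch("MINI_A", 1, 10, 0.0, RigidTransform.identity())
        near = clash_screen(match, dataclasses.replace(motif, context=context),
                            scaffold, clash_distance=3.0)
        assert near.clash_count == 0
        inside = clash_screen(
            match, dataclasses.replace(motif, context=context), scaffold,
            clash_distance=3.0 + 1e-6)
        assert inside.clash_count == 1

    def test_missing_context_is_instructive_error(self, scenario_exact):
        motif = dataclasses.replace(_motif_of(scenario_exact), context=None)
        match = scan_scaffold(motif, scenario_exact.scaffold)[0]
        with pytest.raises(ValueError, match="skip_clash_screen"):
            clash_screen(match, motif, scenario_exact.scaffold)

    def test_raising_cutoff_never_decreases_count(self, scenario_clashing):
        motif = _motif_of(scenario_clashing)
        match = scan_scaffold(motif, scenario_clashing.scaffold)[0]
        counts = [clash_screen(match, motif, scenario_clashing.scaffold,
                               clash_distance=c).clash_count
                  for c in (2.0, 3.0, 4.0, 6.0)]
        assert counts == sorted(counts)


class TestGraft:
    def _grafted(self, scenario):
        motif = _motif_of(scenario)
        match = clash_screen(scan_scaffold(motif, scenario.scaffold)[0],
                             motif, scenario.scaffold)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return motif, graft(match, motif, scenario.scaffold, force=True)

    def test_equal_length_replacement_with_provenance(self, scenario_exact):
        motif, grafted = self._grafted(scenario_exact)
        chimera = grafted.chimera
        assert chimera.length() == scenario_exact.scaffold.length()
        assert grafted.provenance.count("motif") == len(motif)
        motif_seq = "".join(chimera.residues[i].one_letter
                            for i in grafted.motif_indices())
        assert motif_seq == motif.sequence
        assert [r.seq_number for r in chimera.residues] == list(
            range(1, chimera.length() + 1))

    def test_replaced_sequence_is_original_window(self, scenario_exact):
        _, grafted = self._grafted(scenario_exact)
        scaffold = scenario_exact.scaffold
        idx = scaffold.index_of(scenario_exact.site)
        assert grafted.replaced_sequence == "".join(
            r.one_letter for r in scaffold.residues[idx:idx + 10])

    def test_planted_identity_graft_preserves_backbone(self, scenario_exact):
        _, grafted = self._grafted(scenario_exact)
        chim = residues_backbone_coords(grafted.chimera.residues)
        scaf = residues_backbone_coords(scenario_exact.scaffold.residues)
        assert np.allclose(chim, scaf, atol=1e-6)

    def test_motif_internal_geometry_preserved(self, scenario_exact):
        motif, grafted = self._grafted(scenario_exact)
        idx = grafted.motif_indices()
        chim_motif = residues_backbone_coords(
            [grafted.chimera.residues[i] for i in idx])
        _, rmsd = superpose(chim_motif, motif.backbone(("N", "CA", "C", "O")))
        assert rmsd < 1e-6

    def test_chimera_passes_validation(self, scenario_exact):
        _, grafted = self._grafted(scenario_exact)
        assert validate_chain(grafted.chimera).ok

    def test_unaccepted_match_needs_force(self, scenario_clashing):
        motif = _motif_of(scenario_clashing)
        match = clash_screen(scan_scaffold(motif, scenario_clashing.scaffold)[0],
                             motif, scenario_clashing.scaffold)
        assert not match.accepted
        with pytest.raises(ValueError, match="force"):
            graft(match, motif, scenario_clashing.scaffold)

    def test_missing_transform_rejected(self, scenario_exact):
        motif = _motif_of(scenario_exact)
        match = scan_scaffold(motif, scenario_exact.scaffold)[0]
        bare = dataclasses.replace(match, transform=None)
        with pytest.raises(ValueError, match="transform"):
            graft(bare, motif, scenario_exact.scaffold, force=True)


class TestSearchDatabase:
    @pytest.fixture()
    def catalog(self, tmp_path, scenario_exact, helix_chain):
        src = tmp_path / "src"
        src.mkdir()
        (src / "syns.pdb").write_text(write_pdb(scenario_exact.scaffold))
        decoy = build_graft_scenario(9, target_rmsd=0.0).scaffold
        decoy.source_id = "OTHR_A"
        (src / "othr.pdb").write_text(write_pdb(decoy))
        build_catalog(src, tmp_path / "db")
        return tmp_path / "db"

    def test_report_sorted_and_deterministic(self, catalog, scenario_exact):
        motif = _motif_of(scenario_exact)
        r1 = search_database(motif, catalog)
        r2 = search_database(motif, catalog)
        assert r1.table.equals(r2.table)
        accepted = r1.table[r1.table.accepted]
        assert not accepted.empty
        assert list(accepted.rmsd) == sorted(accepted.rmsd)
        top = r1.table.iloc[0]
        assert top.window_start == scenario_exact.site
        assert bool(top.accepted)

    def test_duplicate_entries_give_duplicate_rows(self, tmp_path,
                                                   scenario_exact):
        src = tmp_path / "dup"
        src.mkdir()
        text = write_pdb(scenario_exact.scaffold)
        (src / "syns.pdb").write_text(text)
        (src / "synt.pdb").write_text(text.replace("SYNS", "SYNT"))
        build_catalog(src, tmp_path / "dupdb")
        motif = _motif_of(scenario_exact)
        table = search_database(motif, tmp_path / "dupdb").table
        accepted = table[table.accepted]
        assert len(accepted) == 2
        assert set(accepted.window_start) == {scenario_exact.site}

    def test_no_context_requires_explicit_skip(self, catalog, scenario_exact):
        motif = dataclasses.replace(_motif_of(scenario_exact), context=None)
        with pytest.raises(ValueError):
            search_database(motif, catalog)
        result = search_database(motif, catalog, skip_clash_screen=True)
        assert result.table.accepted.any()
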