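"""Unit and property tests for the coarse-grained model."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from p20kit import prime20_model as pm
from p20kit import samc_sampler as ss


# -- independent brute-force oracle -------------------------------------------


def image_distance(a, b, box):
    """Minimum distance over all 27 periodic images (independent oracle)."""
    best = np.inf
    for sx, sy, sz in itertools.product((-1, 0, 1), repeat=3):
        shift = np.array([sx, sy, sz], dtype=float) * box
        best = min(best, float(np.linalg.norm(np.asarray(b) + shift - np.asarray(a))))
    return best


def oracle_counts(system: pm.CGSystem, params: pm.InteractionParams):
    """From-scratch greedy matching over all-pairs image distances."""
    kinds = [pm.BEAD_KINDS[k] for k in system.kind_index]
    n = system.n_beads

    def excluded(i, j):
        return (system.chain_index[i] == system.chain_index[j]
                and abs(system.residue_index[i] - system.residue_index[j])
                < params.min_residue_separation)

    def match(candidates):
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        used, total = set(), 0
        for _, i, j in candidates:
            if i not in used and j not in used:
                used.update((i, j))
                total += 1
        return total

    hb = []
    if params.hb_well is not None:
        lo, hi = params.hb_well
        for i in range(n):
            for j in range(i + 1, n):
                if {kinds[i], kinds[j]} == {"NH", "CO"} and not excluded(i, j):
                    d = image_distance(system.coords[i], system.coords[j],
                                      system.box_length)
                    if lo <= d <= hi:
                        hb.append((d, i, j))
    sc = []
    wells = {tuple(sorted(k)): v for k, v in params.sc_wells.items()}
    for i in range(n):
        for j in range(i + 1, n):
            key = tuple(sorted((kinds[i], kinds[j])))
            if key in wells and not excluded(i, j):
                lo, hi = wells[key]
                d = image_distance(system.coords[i], system.coords[j],
                                  system.box_length)
                if lo <= d <= hi:
                    sc.append((d, i, j))
    return match(hb), match(sc)


def single_residue_system(positions_by_chain, box):
    """Hand-placed system of single-residue chains; positions are dicts
    NH/CA/CO/SC -> coordinates."""
    chains = []
    for k, pos in enumerate(positions_by_chain):
        res = pm.CGResidue(0, "Q", {kind: np.asarray(p, dtype=float)
                                    for kind, p in pos.items()})
        chains.append(pm.CGChain(chr(ord("A") + k), [res]))
    return pm.CGSystem.from_chains(chains, box)


# -- build_system -------------------------------------------------------------


class TestBuildSystem:
    def test_dimer_26_residues(self):
        system = pm.build_system("Q" * 26, 2, 150.0, seed=11)
        assert system.n_beads == 2 * 26 * 4 == 208
        assert pm.validate_constraints(system) == []

    def test_minimal_single_residue(self):
        system = pm.build_system("Q", 1, 150.0, seed=11)
        assert system.n_beads == 4
        assert pm.validate_constraints(system) == []

    def test_seed_determinism(self):
        a = pm.build_system("QQQ", 2, 50.0, seed=3)
        b = pm.build_system("QQQ", 2, 50.0, seed=3)
        c = pm.build_system("QQQ", 2, 50.0, seed=4)
        assert np.array_equal(a.coords, b.coords)
        assert not np.array_equal(a.coords, c.coords)

    def test_wrapped_coordinates(self):
        system = pm.build_system("QQ", 2, 14.0, seed=2)
        assert np.all(system.coords >= 0.0)
        assert np.all(system.coords < 14.0)

    def test_placement_failure_names_constraint(self):
        with pytest.raises(pm.PlacementError, match="constraint"):
            # box far too small to hold two chains
            pm.build_system("Q" * 8, 2, 9.0, seed=1, max_retries=5)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pm.build_system("", 1, 50.0, seed=1)


# -- minimum image ------------------------------------------------------------


class TestMinimumImage:
    def test_zero(self):
        assert np.array_equal(
            pm.minimum_image_displacement((1, 2, 3), (1, 2, 3), 10.0),
            np.zeros(3))

    def test_wrap_across_boundary(self):
        d = pm.minimum_image_displacement((0, 0, 0), (149, 0, 0), 150.0)
        assert np.allclose(d, (-1, 0, 0))

    def test_within_half_box(self):
        d = pm.minimum_image_displacement((10, 10, 10), (20, 10, 10), 150.0)
        assert np.allclose(d, (10, 0, 0))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            pm.minimum_image_displacement((np.nan, 0, 0), (0, 0, 0), 10.0)

    @given(st.lists(st.floats(-500, 500), min_size=6, max_size=6),
           st.floats(1.0, 200.0))
    @settings(max_examples=200, deadline=None)
    def test_components_in_half_open_box(self, values, box):
        a, b = np.array(values[:3]), np.array(values[3:])
        d = pm.minimum_image_displacement(a, b, box)
        assert np.all(d >= -box / 2)
        assert np.all(d < box / 2)


# -- energy -------------------------------------------------------------------


class TestEnergy:
    def test_zero_counts(self):
        assert pm.p20_energy(pm.InteractionCount(0, 0)) == 0.0

    def test_one_each(self):
        assert pm.p20_energy(pm.InteractionCount(1, 1)) == pytest.approx(-1.08)

    def test_backbone_only_22(self):
        assert pm.p20_energy(pm.InteractionCount(22, 0)) == -22.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            pm.InteractionCount(-1, 0)


# -- count_interactions -------------------------------------------------------


class TestCountInteractions:
    def test_extended_single_chain_no_contacts(self):
        coords = pm.build_chain_coords("Q" * 8) + 30.0
        system = pm.CGSystem(["A"], ["Q" * 8], coords, 150.0)
        counts = pm.count_interactions(system)
        assert counts.as_tuple() == (0, 0)
        assert counts.as_tuple() == oracle_counts(system, pm.default_params())

    def test_single_pair_at_well_center(self):
        params = pm.default_params()
        lo, hi = params.hb_well
        target = 0.5 * (lo + hi)
        a = {"NH": (10.0, 10.0, 10.0), "CA": (11.46, 10.0, 10.0),
             "CO": (12.97, 10.0, 10.0), "SC": (11.46, 12.56, 10.0)}
        b = {"CO": (10.0, 10.0 - target, 10.0), "NH": (20.0, 10.0 - target, 10.0),
             "CA": (18.5, 10.0 - target, 10.0), "SC": (18.5, 2.0, 10.0)}
        system = single_residue_system([a, b], 150.0)
        assert oracle_counts(system, params) == (1, 0)
        assert pm.count_interactions(system, params).as_tuple() == (1, 0)

    def test_single_pair_across_periodic_boundary(self):
        params = pm.default_params()
        lo, hi = params.hb_well
        target = 0.5 * (lo + hi)
        box = 150.0
        a = {"NH": (1.0, 10.0, 10.0), "CA": (2.46, 10.0, 10.0),
             "CO": (3.97, 10.0, 10.0), "SC": (2.46, 12.56, 10.0)}
        # CO of chain B sits across the x boundary: true image distance = target
        b = {"CO": (box - (target - 1.0), 10.0, 10.0),
             "NH": (box - (target + 2.0), 10.0, 10.0),
             "CA": (box - (target + 0.5), 10.0, 10.0),
             "SC": (box - (target + 0.5), 18.0, 10.0)}
        system = single_residue_system([a, b], box)
        assert oracle_counts(system, params) == (1, 0)
        assert pm.count_interactions(system, params).as_tuple() == (1, 0)

    def test_matches_oracle_on_random_toys(self):
        params = pm.default_params()
        for seed in range(6):
            system = pm.build_system("QQ", 2, 13.0, seed=seed, params=params)
            assert (pm.count_interactions(system, params).as_tuple()
                    == oracle_counts(system, params)), f"seed {seed}"

    def test_donor_acceptor_saturation(self):
        # One NH equidistant-ish from two CO beads: only one bond may form.
        params = pm.default_params()
        lo, hi = params.hb_well
        target = 0.5 * (lo + hi)
        a = {"NH": (20.0, 20.0, 20.0), "CA": (21.46, 20.0, 20.0),
             "CO": (60.0, 60.0, 60.0), "SC": (21.46, 22.56, 20.0)}
        b = {"CO": (20.0 + target, 20.0, 20.0), "NH": (80.0, 20.0, 20.0),
             "CA": (82.0, 20.0, 20.0), "SC": (82.0, 28.0, 20.0)}
        c = {"CO": (20.0 - target, 20.0, 20.0), "NH": (100.0, 20.0, 20.0),
             "CA": (102.0, 20.0, 20.0), "SC": (102.0, 28.0, 20.0)}
        system = single_residue_system([a, b, c], 150.0)
        assert pm.count_interactions(system, params).as_tuple() == (1, 0)
        assert oracle_counts(system, params) == (1, 0)


# -- validate_constraints -----------------------------------------------------


class TestValidateConstraints:
    def test_fresh_system_valid(self):
        system = pm.build_system("QQQQ", 2, 60.0, seed=9)
        assert pm.validate_constraints(system) == []

    def test_coincident_beads_single_violation(self):
        # Spread every other bead far apart so the coincident NH pair is the
        # only excluded-volume contact (bond violations are filtered out).
        a = {"NH": (10.0, 10.0, 10.0), "CA": (30.0, 10.0, 10.0),
             "CO": (50.0, 10.0, 10.0), "SC": (70.0, 10.0, 10.0)}
        b = {"NH": (10.0, 10.0, 10.0), "CA": (30.0, 40.0, 10.0),
             "CO": (50.0, 40.0, 10.0), "SC": (70.0, 40.0, 10.0)}
        system = single_residue_system([a, b], 150.0)
        violations = [v for v in pm.validate_constraints(system)
                      if v.kind == "excluded_volume"]
        assert len(violations) == 1
        (v,) = violations
        assert v.distance == 0.0
        assert "A/0/NH" in str(v) and "B/0/NH" in str(v)

    def test_stretched_bond_single_violation(self):
        params = pm.default_params()
        system = pm.build_system("Q", 1, 150.0, seed=1, params=params)
        i = system.bead_index(0, 0, "SC")
        ca = system.coords[system.bead_index(0, 0, "CA")]
        ref = params.bond_lengths["CA-SC"]
        direction = (system.coords[i] - ca) / np.linalg.norm(system.coords[i] - ca)
        system.coords[i] = ca + ref * (1 + 2 * params.bond_tolerance) * direction
        violations = pm.validate_constraints(system, params)
        assert len(violations) == 1
        assert violations[0].kind == "bond"
        assert "SC" in str(violations[0])

    def test_bond_at_tolerance_edge_valid(self):
        params = pm.default_params()
        system = pm.build_system("Q", 1, 150.0, seed=1, params=params)
        i = system.bead_index(0, 0, "SC")
        ca = system.coords[system.bead_index(0, 0, "CA")]
        ref = params.bond_lengths["CA-SC"]
        direction = (system.coords[i] - ca) / np.linalg.norm(system.coords[i] - ca)
        system.coords[i] = ca + ref * (1 + 0.99 * params.bond_tolerance) * direction
        assert pm.validate_constraints(system, params) == []


# -- interaction_delta --------------------------------------------------------


def displacement_proposal(system, bead, new_position):
    return ss.MoveProposal("displacement", [bead],
                           system.coords[[bead]].copy(),
                           np.asarray([new_position], dtype=float), True)


class TestInteractionDelta:
    def test_identity_proposal(self):
        system = pm.build_system("QQ", 2, 14.0, seed=2)
        prop = displacement_proposal(system, 0, system.coords[0])
        assert pm.interaction_delta(system, prop) == (0, 0)

    def test_isolated_bead_displacement(self):
        system = pm.build_system("QQ", 2, 150.0, seed=2)
        prop = displacement_proposal(system, 0, system.coords[0] + 0.01)
        assert pm.interaction_delta(system, prop) == (0, 0)

    def test_breaking_a_counted_pair(self):
        params = pm.default_params()
        lo, hi = params.hb_well
        target = 0.5 * (lo + hi)
        a = {"NH": (10.0, 10.0, 10.0), "CA": (11.46, 10.0, 10.0),
             "CO": (12.97, 10.0, 10.0), "SC": (11.46, 12.56, 10.0)}
        b = {"CO": (10.0, 10.0 - target, 10.0), "NH": (20.0, 10.0 - target, 10.0),
             "CA": (18.5, 10.0 - target, 10.0), "SC": (18.5, 2.0, 10.0)}
        system = single_residue_system([a, b], 150.0)
        assert pm.count_interactions(system, params).as_tuple() == (1, 0)
        bead = system.bead_index(1, 0, "CO")
        prop = displacement_proposal(system, bead,
                                     (10.0, 10.0 - (hi + 3.0), 10.0))
        delta = pm.interaction_delta(system, prop, params)
        # full-recount oracle
        before = oracle_counts(system, params)
        pm.apply_proposal(system, prop)
        after = oracle_counts(system, params)
        assert delta == (after[0] - before[0], after[1] - before[1]) == (-1, 0)


# -- invariants ---------------------------------------------------------------


class TestInvariants:
    def test_incremental_matches_full_recount_over_10000_moves(self):
        params = pm.default_params()
        system = pm.build_system("QQ", 2, 13.0, seed=4, params=params)
        config = ss.SamcConfig(max_displacement=0.05, max_chain_translation=2.0)
        rng = np.random.default_rng(8)
        counts = np.array(pm.count_interactions(system, params).as_tuple())
        n_accepted = 0
        for step in range(10_000):
            prop = ss.propose_move(system, config, rng, params)
            if not prop.valid:
                continue
            delta = pm.interaction_delta(system, prop, params)
            pm.apply_proposal(system, prop)
            counts += delta
            n_accepted += 1
            if step % 1000 == 0:
                assert tuple(counts) == pm.count_interactions(
                    system, params).as_tuple()
        assert tuple(counts) == pm.count_interactions(system, params).as_tuple()
        assert n_accepted > 1000  # the walk actually moved

    def test_translation_invariance(self):
        params = pm.default_params()
        for seed in range(3):
            system = pm.build_system("QQ", 2, 13.0, seed=seed, params=params)
            before = pm.count_interactions(system, params)
            shifted = system.copy()
            shifted.coords = pm.wrap_positions(
                shifted.coords + np.array([37.2, -11.9, 5.4]), 13.0)
            after = pm.count_interactions(shifted, params)
            assert before == after
            assert pm.p20_energy(before, params) == pm.p20_energy(after, params)

    def test_energy_lattice(self):
        params = pm.default_params()
        rng = np.random.default_rng(1)
        config = ss.SamcConfig(max_displacement=0.05)
        system = pm.build_system("QQ", 2, 13.0, seed=1, params=params)
        for _ in range(300):
            prop = ss.propose_move(system, config, rng, params)
            if prop.valid:
                pm.apply_proposal(system, prop)
            counts = pm.count_interactions(system, params)
            energy = pm.p20_energy(counts, params)
            assert energy == -(params.w_bb * counts.n_backbone
                               + params.w_sc * counts.n_sidechain)

    def test_chain_relabel_symmetry(self):
        params = pm.default_params()
        system = pm.build_system("QQ", 2, 13.0, seed=6, params=params)
        chains = system.chains
        swapped = pm.CGSystem.from_chains(
            [pm.CGChain("A", chains[1].residues),
             pm.CGChain("B", chains[0].residues)], system.box_length)
        assert (pm.count_interactions(system, params)
                == pm.count_interactions(swapped, params))


# -- params file --------------------------------------------------------------


class TestParamsFile:
    def test_round_trip(self, tmp_path):
        params = pm.InteractionParams(w_sc=1.0 / 12.0, min_residue_separation=2)
        path = tmp_path / "params.yaml"
        params.to_file(path)
        loaded = pm.InteractionParams.from_file(path)
        assert loaded.w_sc == params.w_sc
        assert loaded.min_residue_separation == 2
        assert loaded.hb_well == params.hb_well
        assert loaded.sc_wells == params.sc_wells

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            pm.InteractionParams.from_dict({"bogus": 1})

    def test_invalid_well_rejected(self):
        with pytest.raises(ValueError):
            pm.InteractionParams(hb_well=(4.5, 3.4))

    def test_invalid_tolerance_rejected(self):
        with pytest.raises(ValueError):
            pm.InteractionParams(bond_tolerance=0.5)
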