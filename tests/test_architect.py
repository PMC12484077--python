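"""Placement, closure scoring, DOF scanning, clash counting, junction export."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.spatial import cKDTree

from bondforge.architect import (
    ArchitectureSpec,
    ComponentSlot,
    clash_count,
    closure_error,
    junction_gaps,
    place_components,
    scan_dofs,
)
from bondforge.blocks import BondSite
from bondforge.fixtures import (
    FixtureSpec,
    attach_site,
    make_heterotrimer,
    make_ideal_oligomer,
    make_mated_pair,
)
from bondforge.geometry import RigidTransform, random_rotation, rotation_about_axis
from bondforge.symgroups import generate_point_group


def g_invariance_rmsd(model) -> float:
    """Worst-case RMSD of the assembly onto itself under every group op."""
    coords = model.ca_coords()
    tree = cKDTree(coords)
    worst = 0.0
    for op in model.spec.group.ops:
        moved = coords @ op.rotation.T + op.translation
        d, _ = tree.query(moved)
        worst = max(worst, float(np.sqrt(np.mean(d**2))))
    return worst


class TestPlacement:
    @pytest.mark.parametrize(
        "design,g",
        [("D22", 4), ("D32", 6), ("D42", 8), ("D52", 10), ("D62", 12),
         ("D72", 14), ("D82", 16), ("T33", 12), ("O42", 24), ("I32", 60)],
    )
    def test_instance_counts(self, design, g):
        """Each slot contributes |G| / n instances (duplicate copies related
        by the block's own Cn merged)."""
        spec, dofs = make_mated_pair(design)
        model = place_components(spec, dofs)
        assert model.instance_count(0) == g // int(design[1])
        assert model.instance_count(1) == g // int(design[2])

    def test_c3_slot_on_d3(self):
        block = make_ideal_oligomer(FixtureSpec(n=3))
        spec = ArchitectureSpec(
            name="d3", group=generate_point_group("D3"),
            slots=(ComponentSlot(block, target_axis_order=3),),
        )
        model = place_components(spec, {"psi0": 10.0, "r0": 20.0})
        assert model.instance_count(0) == 2

    @pytest.mark.parametrize("design", ["O42", "T33", "I32"])
    def test_g_invariance(self, design):
        """The assembly superposes on itself under every group operator."""
        spec, dofs = make_mated_pair(design)
        model = place_components(spec, dofs)
        assert g_invariance_rmsd(model) < 1e-6

    def test_missing_axis_order_errors(self):
        block = make_ideal_oligomer(FixtureSpec(n=5))
        spec = ArchitectureSpec(
            name="bad", group=generate_point_group("O"),
            slots=(ComponentSlot(block, target_axis_order=5),),
        )
        with pytest.raises(ValueError):
            place_components(spec, {})

    def test_general_position_full_orbit(self):
        """A docked heterotrimer at a general position gets |G| instances --
        the D4 route to eight displayed bonding modules."""
        het = make_heterotrimer()
        het = attach_site(het, RigidTransform.from_translation([30.0, 4.0, 6.0]),
                          "LHD206", "A", replicate=False)
        spec = ArchitectureSpec(
            name="D4het", group=generate_point_group("D4"),
            slots=(ComponentSlot(het, target_axis_order="general",
                                 base_transform=RigidTransform.from_translation([22.0, 3.0, 5.0])),),
        )
        model = place_components(spec, {})
        assert model.instance_count(0) == 8
        assert len(model.site_instances(0)) == 8


class TestClosure:
    def test_translated_site_gives_exact_dt(self, o42_pair):
        """Shifting the partner's site frame 1 A along global z produces a
        translational deviation of exactly 1.0 A."""
        spec, dofs = o42_pair
        block_b = spec.slots[1].block
        model0 = place_components(spec, dofs)
        p_b = model0.placements[1]
        shift = p_b.inverse() @ RigidTransform.from_translation([0, 0, 1.0]) @ p_b
        moved = block_b.with_sites(
            [replace(s, frame=shift @ s.frame) for s in block_b.bond_sites]
        )
        spec2 = ArchitectureSpec(
            name=spec.name, group=spec.group,
            slots=(spec.slots[0], ComponentSlot(moved, spec.slots[1].target_axis_order)),
            bond_pairings=spec.bond_pairings, tolerance=spec.tolerance,
            lever_arm=spec.lever_arm,
        )
        report = closure_error(place_components(spec2, dofs))
        assert report.pairings[0].dt == pytest.approx(1.0, abs=1e-9)
        assert report.pairings[0].dtheta == pytest.approx(0.0, abs=1e-7)

    def test_rotated_site_combined_score(self, o42_pair):
        """A 5-degree in-place rotation with a 20 A lever arm scores
        20 * 5 * pi / 180 ~ 1.745."""
        spec, dofs = o42_pair
        block_b = spec.slots[1].block
        twist = RigidTransform.from_rotation(rotation_about_axis([0, 0, 1], 5.0))
        moved = block_b.with_sites(
            [replace(s, frame=s.frame @ twist) for s in block_b.bond_sites]
        )
        spec2 = ArchitectureSpec(
            name=spec.name, group=spec.group,
            slots=(spec.slots[0], ComponentSlot(moved, spec.slots[1].target_axis_order)),
            bond_pairings=spec.bond_pairings, tolerance=spec.tolerance, lever_arm=20.0,
        )
        report = closure_error(place_components(spec2, dofs))
        assert report.pairings[0].dt == pytest.approx(0.0, abs=1e-9)
        assert report.pairings[0].dtheta == pytest.approx(5.0, abs=1e-6)
        assert report.pairings[0].combined == pytest.approx(20 * np.deg2rad(5.0), rel=1e-6)

    def test_invariant_under_global_rigid_motion(self, o42_pair, rng):
        spec, dofs = o42_pair
        model = place_components(spec, dofs)
        bumped = dict(dofs, r0=dofs["r0"] + 0.7)
        off = place_components(spec, bumped)
        ref = closure_error(off).worst
        g = RigidTransform(random_rotation(rng), rng.normal(size=3) * 30)
        moved = replace(
            off,
            placements=tuple(g @ p for p in off.placements),
            instances=tuple((s, oi, g @ tf) for s, oi, tf in off.instances),
        )
        assert closure_error(moved).worst == pytest.approx(ref, abs=1e-8)

    def test_non_complementary_pairing_rejected(self):
        block = make_ideal_oligomer(FixtureSpec(n=2))
        block = attach_site(block, RigidTransform.identity(), "LHD101", "A")
        with pytest.raises(ValueError):
            ArchitectureSpec(
                name="bad", group=generate_point_group("D2"),
                slots=(ComponentSlot(block, 2), ComponentSlot(block, 2)),
                bond_pairings=((0, 0, 1, 0),),  # A against A
            )


class TestScanDofs:
    def test_recovers_planted_cage_dofs(self, o42_pair):
        """The planted DOFs are the grid argmin with exactly zero closure."""
        spec, dofs = o42_pair
        grid = {
            "psi0": dofs["psi0"] + np.array([-4.0, 0.0, 4.0]),
            "r0": dofs["r0"] + np.array([-3.0, 0.0, 3.0]),
            "psi1": dofs["psi1"] + np.array([-4.0, 0.0, 4.0]),
            "r1": dofs["r1"] + np.array([-3.0, 0.0, 3.0]),
        }
        df, best = scan_dofs(spec, grid, compute_clash=False)
        assert len(df) == 81
        row = df.loc[best]
        for name, val in dofs.items():
            assert row[name] == pytest.approx(val)
        assert row["closure"] == pytest.approx(0.0, abs=1e-9)

    def test_grid_without_solution_has_positive_minimum(self, o42_pair):
        spec, dofs = o42_pair
        grid = {k: np.array([v + 1.5]) for k, v in dofs.items()}
        df, best = scan_dofs(spec, grid, compute_clash=False)
        assert df.loc[best, "closure"] > 1e-3

    def test_recovers_coaxial_offsets(self, coaxial_pair):
        """Stacked-ring two-DOF scan recovers the planted (dz, dphi)."""
        spec, dofs = coaxial_pair
        grid = {
            "psi1": dofs["psi1"] + np.array([-10.0, 0.0, 10.0]),
            "r1": dofs["r1"] + np.array([-4.0, 0.0, 4.0]),
        }
        df, best = scan_dofs(spec, grid, compute_clash=False)
        assert df.loc[best, "psi1"] == pytest.approx(dofs["psi1"])
        assert df.loc[best, "r1"] == pytest.approx(dofs["r1"])
        assert df.loc[best, "closure"] == pytest.approx(0.0, abs=1e-9)

    def test_empty_grid_rejected(self, o42_pair):
        spec, _ = o42_pair
        with pytest.raises(ValueError):
            scan_dofs(spec, {})


def brute_force_clashes(model, cutoff=2.4, shell=5.0, mate_tol=1.0) -> int:
    """O(N^2) oracle replicating the clash definition independently."""
    coords, inst, _ = model.atoms()
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    close = (d < cutoff) & (inst[:, None] != inst[None, :])
    sites = model.site_instances()
    engaged = []
    for a in range(len(sites)):
        for b in range(len(sites)):
            if a == b or not sites[a][4].complements(sites[b][4]):
                continue
            if np.linalg.norm(sites[a][3].origin - sites[b][3].origin) <= mate_tol:
                engaged.append(sites[a][3].origin)
                break
    if engaged:
        near = np.zeros(len(coords), dtype=bool)
        for e in engaged:
            near |= np.linalg.norm(coords - e, axis=1) <= shell
        close &= ~(near[:, None] & near[None, :])
    return int(np.triu(close, k=1).sum())


class TestClashCount:
    def test_separated_instances_zero(self, o42_model):
        assert clash_count(o42_model) == 0

    def test_superposed_copies_count_self_pairs(self):
        block = make_ideal_oligomer(FixtureSpec(n=2, monomer_atoms=30))
        spec = ArchitectureSpec(
            name="dup", group=generate_point_group("C1"),
            slots=(
                ComponentSlot(block, "general", base_transform=RigidTransform.identity()),
                ComponentSlot(block, "general", base_transform=RigidTransform.identity()),
            ),
        )
        model = place_components(spec, {})
        assert clash_count(model) == block.n_atoms

    @pytest.mark.parametrize("shrink", [0.55, 0.7])
    def test_matches_all_pairs_oracle(self, o42_pair, shrink):
        """k-d-tree counting equals the brute-force all-pairs oracle on a
        deliberately compressed (clashing) assembly."""
        spec, dofs = o42_pair
        tight = {k: v * shrink if k.startswith("r") else v for k, v in dofs.items()}
        model = place_components(spec, tight)
        expected = brute_force_clashes(model)
        assert expected > 0
        assert clash_count(model) == expected


class TestJunctionGaps:
    def test_two_slot_cage_has_two_unique_gaps(self, o42_model):
        gaps = junction_gaps(o42_model)
        assert len(gaps) == 2
        assert {g.slot_index for g in gaps} == {0, 1}

    def test_bispecific_slot_has_two_gaps(self, o42_pair):
        spec, _ = o42_pair
        block_a = attach_site(
            spec.slots[0].block,
            RigidTransform.from_translation([25.0, 2.0, 3.0]),
            "LHD206", "A", replicate=False,
        )
        spec2 = ArchitectureSpec(
            name="bis", group=spec.group,
            slots=(ComponentSlot(block_a, spec.slots[0].target_axis_order),
                   spec.slots[1]),
            bond_pairings=(),
        )
        model = place_components(spec2, {"psi0": 0, "r0": 30, "psi1": 0, "r1": 26})
        gaps = junction_gaps(model)
        assert sum(1 for g in gaps if g.slot_index == 0) == 2

    def test_gap_distance_matches_hand_computation(self):
        block = make_ideal_oligomer(FixtureSpec(n=3, monomer_atoms=10))
        target = np.array([30.0, 0.0, 5.0])
        block = attach_site(block, RigidTransform.from_translation(target),
                            "LHD101", "A")
        anchor_ca = next(
            a for a in block.chains[0]
            if a.residue_index == block.bond_sites[0].anchor[1] and a.is_ca
        )
        expected = float(np.linalg.norm(target - anchor_ca.coords))
        spec = ArchitectureSpec(
            name="one", group=generate_point_group("C3"),
            slots=(ComponentSlot(block, 3),),
        )
        gaps = junction_gaps(place_components(spec, {}))
        assert len(gaps) == 1
        assert gaps[0].gap_distance == pytest.approx(expected, abs=1e-9)
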