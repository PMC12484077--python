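"""P3 layer and F432 crystal construction, clusters, free-DOF accounting."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from bondforge.fixtures import FixtureSpec, make_ideal_oligomer
from bondforge.lattice import (
    build_f432_crystal,
    build_p3_layer,
    constraint_nullity,
    count_bonded_partners,
    f432_crystal_dofs,
    free_dof_count,
    lattice_closure,
    local_cluster,
    p3_layer_dofs,
    two_component_cage_dofs,
)


class TestP3Layer:
    def test_planted_parameters_close_all_bonds(self, p3_fixture):
        block_a, block_b, planted = p3_fixture
        layer = build_p3_layer(block_a, block_b, planted["a"], planted["z_off"],
                               planted["phi"], n_cells=3)
        bonds = lattice_closure(layer)
        assert len(bonds) == 6  # three sites on each of A and B
        assert max(b.combined for b in bonds) == pytest.approx(0.0, abs=1e-9)

    def test_closure_independent_of_slab_size(self, p3_fixture):
        block_a, block_b, planted = p3_fixture
        args = (block_a, block_b, planted["a"], planted["z_off"], planted["phi"])
        small = lattice_closure(build_p3_layer(*args, n_cells=1))
        large = lattice_closure(build_p3_layer(*args, n_cells=2))
        for b1, b2 in zip(small, large):
            assert b1.combined == pytest.approx(b2.combined, abs=1e-12)
        n1 = len(build_p3_layer(*args, n_cells=1).instances())
        n2 = len(build_p3_layer(*args, n_cells=2).instances())
        assert n2 == 4 * n1

    def test_each_trimer_contacts_three_partners(self, p3_fixture):
        """On the P3 net each bonded trimer touches three partner trimers."""
        block_a, block_b, planted = p3_fixture
        layer = build_p3_layer(block_a, block_b, planted["a"], planted["z_off"],
                               planted["phi"], n_cells=2)
        assert count_bonded_partners(layer, "A") == 3
        assert count_bonded_partners(layer, "B") == 3

    def test_off_planted_spacing_breaks_closure(self, p3_fixture):
        block_a, block_b, planted = p3_fixture
        layer = build_p3_layer(block_a, block_b, planted["a"] + 4.0,
                               planted["z_off"], planted["phi"])
        assert max(b.combined for b in lattice_closure(layer)) > 1.0

    def test_parameter_recovery_by_grid(self, p3_fixture):
        """Scanning (a, z_off, phi) recovers the planted values as the
        closure minimum, exactly zero at the plant."""
        block_a, block_b, planted = p3_fixture
        best = None
        for a in planted["a"] + np.array([-4.0, 0.0, 4.0]):
            for z in planted["z_off"] + np.array([-3.0, 0.0, 3.0]):
                for phi in planted["phi"] + np.array([-8.0, 0.0, 8.0]):
                    layer = build_p3_layer(block_a, block_b, a, z, phi)
                    worst = max(b.combined for b in lattice_closure(layer, reach=1))
                    if best is None or worst < best[0]:
                        best = (worst, a, z, phi)
        assert best[0] == pytest.approx(0.0, abs=1e-9)
        assert (best[1], best[2], best[3]) == (
            pytest.approx(planted["a"]),
            pytest.approx(planted["z_off"]),
            pytest.approx(planted["phi"]),
        )

    def test_alternate_b_site_setting(self, p3_fixture):
        block_a, block_b, planted = p3_fixture
        layer = build_p3_layer(block_a, block_b, planted["a"], planted["z_off"],
                               planted["phi"], site_b=(2 / 3, 1 / 3))
        assert len(layer.units) == 2

    def test_non_trimer_rejected(self, p3_fixture):
        block_a, _, planted = p3_fixture
        dimer = make_ideal_oligomer(FixtureSpec(n=2))
        with pytest.raises(ValueError):
            build_p3_layer(block_a, dimer, planted["a"], 0.0, 0.0)

    def test_lattice_translation_invariance(self, p3_fixture):
        """Translating by one lattice vector maps cell (i,j) content exactly
        onto cell (i+1,j) content."""
        block_a, block_b, planted = p3_fixture
        layer = build_p3_layer(block_a, block_b, planted["a"], planted["z_off"],
                               planted["phi"], n_cells=2)
        a1 = layer.lattice_vectors[0]
        insts = layer.instances()
        by_cell = {(lab, shift): tf for lab, _, tf, shift in insts}
        for (lab, shift), tf in by_cell.items():
            target = (lab, (shift[0] + 1, shift[1]))
            if target in by_cell:
                moved = np.concatenate([tf.rotation.ravel(), tf.translation + a1])
                ref = np.concatenate([by_cell[target].rotation.ravel(),
                                      by_cell[target].translation])
                np.testing.assert_allclose(moved, ref, atol=1e-9)


class TestF432Crystal:
    def test_unit_cell_census(self, f432_fixture):
        cage, linker, planted = f432_fixture
        crystal = build_f432_crystal(cage, linker, planted["a"])
        labels = [lab for lab, _, _ in crystal.units]
        assert labels.count("cage") == 4  # FCC nodes
        assert labels.count("linker") == 8  # tetrahedral holes

    def test_planted_constant_closes_all_linker_bonds(self, f432_fixture):
        cage, linker, planted = f432_fixture
        crystal = build_f432_crystal(cage, linker, planted["a"])
        linker_bonds = [b for b in lattice_closure(crystal) if b.unit_label == "linker"]
        assert len(linker_bonds) == 24  # 8 linkers x 3 arms
        assert max(b.combined for b in linker_bonds) == pytest.approx(0.0, abs=1e-9)

    def test_wrong_constant_breaks_closure(self, f432_fixture):
        cage, linker, planted = f432_fixture
        crystal = build_f432_crystal(cage, linker, planted["a"] * 1.05)
        linker_bonds = [b for b in lattice_closure(crystal) if b.unit_label == "linker"]
        assert min(b.combined for b in linker_bonds) > 0.5

    def test_local_cluster_is_tetrahedron_of_four_cages_four_linkers(self, f432_fixture):
        """Around a tetrahedral hole: four cages in a regular tetrahedron
        (edge a/sqrt 2) interconnected by four C3 linkers."""
        cage, linker, planted = f432_fixture
        crystal = build_f432_crystal(cage, linker, planted["a"], n_cells=2)
        cluster = local_cluster(crystal, (0.25, 0.25, 0.25))
        assert len(cluster.cage_instances) == 4
        assert len(cluster.linker_instances) == 4
        d = pdist(cluster.cage_centers)
        expected = planted["a"] / np.sqrt(2.0)
        np.testing.assert_allclose(d, expected, atol=1e-6 * planted["a"])

    def test_cluster_without_linker_bonds(self, f432_fixture):
        cage, _, planted = f432_fixture
        bare_linker = make_ideal_oligomer(FixtureSpec(n=3, radius=10.0))
        crystal = build_f432_crystal(cage, bare_linker, planted["a"], n_cells=2)
        cluster = local_cluster(crystal, (0.25, 0.25, 0.25))
        assert len(cluster.cage_instances) == 4
        assert len(cluster.linker_instances) == 0

    def test_non_interstitial_site_rejected(self, f432_fixture):
        cage, linker, planted = f432_fixture
        crystal = build_f432_crystal(cage, linker, planted["a"])
        with pytest.raises(ValueError):
            local_cluster(crystal, (0.5, 0.5, 0.5))

    def test_asymmetric_cage_rejected(self, f432_fixture):
        _, linker, planted = f432_fixture
        lump = make_ideal_oligomer(FixtureSpec(n=1, monomer_atoms=40))
        with pytest.raises(ValueError):
            build_f432_crystal(lump, linker, planted["a"])


class TestFreeDofCount:
    @pytest.mark.parametrize(
        "spec_factory,expected,labels",
        [
            (lambda: two_component_cage_dofs(4, 2), 4,
             ["C4:psi", "C4:r", "C2:psi", "C2:r"]),
            (p3_layer_dofs, 3, ["cell:a", "B:psi", "B:r"]),
            (f432_crystal_dofs, 1, ["cell:a"]),
        ],
    )
    def test_analytic_counts(self, spec_factory, expected, labels):
        n, got = free_dof_count(spec_factory())
        assert n == expected
        assert got == labels

    @pytest.mark.parametrize(
        "spec_factory",
        [lambda: two_component_cage_dofs(4, 2),
         lambda: two_component_cage_dofs(3, 3),
         p3_layer_dofs, f432_crystal_dofs],
    )
    def test_numeric_jacobian_agrees(self, spec_factory):
        """The analytic count equals the nullity of the numeric
        constraint Jacobian at a feasible configuration."""
        spec = spec_factory()
        assert constraint_nullity(spec) == free_dof_count(spec)[0]
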