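import math

import numpy as np
import pytest

from axomech.builder import (
    BuildError,
    SolvationSpec,
    achieved_protein_density,
    build_bilayer,
    place_proteins,
    solvate_and_ionize,
    stack_multilayer,
    tile_bilayer,
)
from axomech.composition import leaflet_counts
from axomech.composition import MembraneComposition, LeafletComposition
from axomech.frames import CYTOPLASMIC, EXTRACELLULAR


@pytest.fixture(scope="module")
def single_species():
    leaf = LeafletComposition({"POPC": 1.0})
    return MembraneComposition(leaf, leaf, label="pure-PC")


class TestBuildBilayer:
    def test_published_patch_geometry(self, myelin):
        frame = build_bilayer(myelin, 2000)
        assert len(frame.lipid_molecule_ids()) == 2000
        assert frame.box[0] == pytest.approx(24.0)
        assert frame.box[1] == pytest.approx(24.0)
        upper = [m for m, l in frame.leaflet_label.items() if l == EXTRACELLULAR]
        assert len(upper) == 1000

    def test_minimal_bilayer_head_planes(self, single_species):
        frame = build_bilayer(
            single_species, 4, thickness=4.0, box_lz=10.0, lateral_jitter=0.0
        )
        z = np.sort(frame.positions[frame.head_mask, 2])
        assert z == pytest.approx([3.0, 3.0, 7.0, 7.0])

    def test_deterministic_per_seed(self, myelin):
        a = build_bilayer(myelin, 128, seed=9)
        b = build_bilayer(myelin, 128, seed=9)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.species, b.species)

    def test_composition_conservation(self, myelin):
        frame = build_bilayer(myelin, 500, seed=3)
        for leaflet, comp in (
            (EXTRACELLULAR, myelin.extracellular),
            (CYTOPLASMIC, myelin.cytoplasmic),
        ):
            hist = frame.species_histogram(leaflet)
            assert hist == leaflet_counts(comp, 250, seed=3)

    def test_odd_count_rejected(self, myelin):
        with pytest.raises(BuildError):
            build_bilayer(myelin, 201)

    def test_extracellular_on_top(self, myelin):
        frame = build_bilayer(myelin, 100)
        heads = np.flatnonzero(frame.head_mask)
        for i in heads:
            mol = int(frame.molecule_id[i])
            above = frame.positions[i, 2] > frame.box[2] / 2
            expected = EXTRACELLULAR if above else CYTOPLASMIC
            assert frame.leaflet_label[mol] == expected


class TestTile:
    def test_published_tiling_makes_8000(self, myelin):
        patch = build_bilayer(myelin, 2000)
        big = tile_bilayer(patch, 2, 2)
        assert len(big.lipid_molecule_ids()) == 8000
        assert big.box[:2] == pytest.approx([48.0, 48.0])

    def test_identity(self, small_frame):
        same = tile_bilayer(small_frame, 1, 1)
        assert np.array_equal(same.positions, small_frame.positions)

    def test_counts_and_box_arithmetic(self, myelin):
        toy = build_bilayer(myelin, 10)
        tiled = tile_bilayer(toy, 3, 2)
        assert len(tiled.lipid_molecule_ids()) == 60
        assert tiled.box == pytest.approx(
            [3 * toy.box[0], 2 * toy.box[1], toy.box[2]]
        )

    def test_molecule_ids_unique(self, small_frame):
        tiled = tile_bilayer(small_frame, 2, 3)
        per_mol = tiled.species_histogram()
        assert sum(per_mol.values()) == 6 * 200

    def test_composition_preserved_exactly(self, small_frame):
        tiled = tile_bilayer(small_frame, 2, 2)
        base = small_frame.species_histogram()
        assert tiled.species_histogram() == {k: 4 * v for k, v in base.items()}

    def test_tiling_composes(self, myelin):
        f = build_bilayer(myelin, 50)
        once = tile_bilayer(tile_bilayer(f, 2, 1), 1, 3)
        direct = tile_bilayer(f, 2, 3)
        assert once.species_histogram() == direct.species_histogram()
        assert once.box == pytest.approx(direct.box)

    def test_bad_factors(self, small_frame):
        with pytest.raises(BuildError):
            tile_bilayer(small_frame, 0, 1)


class TestStack:
    def test_two_units_have_one_extracellular_gap(self, single_species):
        frame = build_bilayer(
            single_species, 64, thickness=4.0, box_lz=10.0, lateral_jitter=0.0
        )
        stack = stack_multilayer(frame, 2, 1.7, 1.6)
        z = np.unique(np.round(stack.positions[stack.head_mask, 2], 6))
        # gap between the two adjacent extracellular head planes
        gaps = np.diff(z)
        assert 1.7 in np.round(gaps, 6)

    def test_three_unit_stack_height(self, single_species):
        frame = build_bilayer(single_species, 64, thickness=4.5, box_lz=12.0)
        stack = stack_multilayer(frame, 3, 1.7, 1.6)
        z = stack.positions[stack.lipid_mask, 2]
        assert z.max() - z.min() == pytest.approx(3 * 4.5 + 1.7 + 1.6)

    def test_zero_gap_rejected(self, small_frame):
        with pytest.raises(BuildError):
            stack_multilayer(small_frame, 2, 0.0, 1.6)

    def test_alternating_orientation_swaps_labels(self, myelin):
        frame = build_bilayer(myelin, 64)
        stack = stack_multilayer(frame, 2)
        labels = set(stack.leaflet_label.values())
        assert labels == {EXTRACELLULAR, CYTOPLASMIC}
        stride = int(frame.molecule_id.max()) + 1
        for mol, lab in frame.leaflet_label.items():
            flipped = stack.leaflet_label[mol + stride]
            assert flipped != lab

    def test_max_height_guard(self, small_frame):
        with pytest.raises(BuildError, match="max_lz"):
            stack_multilayer(small_frame, 8, max_lz=20.0)


class TestProteins:
    def test_published_nodal_density_gives_16(self, node):
        apl = 2 * 72.0**2 / 15000
        frame = build_bilayer(node, 15000, area_per_lipid=apl)
        embedded = place_proteins(frame, target_density=3086.0, seed=0)
        n_prot = len(np.unique(embedded.molecule_id[embedded.protein_mask]))
        assert n_prot == 16
        assert achieved_protein_density(embedded) == pytest.approx(
            16 / (72.0**2 * 1e-6)
        )

    def test_single_protein_centered(self, small_frame):
        embedded = place_proteins(small_frame, count=1)
        prot = embedded.positions[embedded.protein_mask]
        lx, ly, _ = embedded.box
        assert prot[:, 0].mean() == pytest.approx(lx / 2, abs=1e-6)
        assert prot[:, 1].mean() == pytest.approx(ly / 2, abs=1e-6)

    def test_zero_density_is_identity(self, small_frame):
        same = place_proteins(small_frame, target_density=0.0)
        assert np.array_equal(same.positions, small_frame.positions)

    def test_lipids_in_footprint_removed(self, small_frame):
        embedded = place_proteins(small_frame, count=1, footprint_radius=2.0)
        heads = np.flatnonzero(embedded.head_mask)
        center = embedded.box[:2] / 2
        d = embedded.positions[heads, :2] - center
        d -= np.round(d / embedded.box[:2]) * embedded.box[:2]
        assert np.hypot(d[:, 0], d[:, 1]).min() > 2.0

    def test_infeasible_packing_reports_maximum(self, small_frame):
        with pytest.raises(BuildError, match="at most"):
            place_proteins(small_frame, count=100, min_separation=5.0)


class TestSolvation:
    def test_no_salt_no_ions(self, small_frame):
        spec = SolvationSpec(salt_concentration=0.0, neutralize=False)
        wet = solvate_and_ionize(small_frame, spec)
        assert int(wet.ion_mask.sum()) == 0
        assert int(wet.water_mask.sum()) > 0

    def test_physiological_pair_count(self, myelin):
        # 0.15 mol/L in the filled volume: n = round(c * N_A * V)
        frame = build_bilayer(
            myelin, 2000, thickness=4.5, box_lz=14.0
        )
        spec = SolvationSpec(salt_concentration=0.15, neutralize=False)
        wet = solvate_and_ionize(frame, spec)
        v_water = int(wet.water_mask.sum() + wet.ion_mask.sum()) / 8.3
        expected_pairs = round(0.15 * 6.02214076e23 * v_water * 1e-24)
        assert int((wet.species == "NA").sum()) == expected_pairs
        assert int((wet.species == "CL").sum()) == expected_pairs

    def test_published_solvation_count(self, myelin):
        apl = 2 * 41.0**2 / 8000
        frame = build_bilayer(
            myelin, 8000, area_per_lipid=apl, thickness=4.5, box_lz=14.0
        )
        wet = solvate_and_ionize(frame)
        n_solvent = int(wet.water_mask.sum() + wet.ion_mask.sum())
        assert abs(n_solvent - 138_000) / 138_000 < 0.10

    def test_neutralization_balances_lipid_charge(self, myelin, registry):
        frame = build_bilayer(myelin, 400, box_lz=12.0)
        wet = solvate_and_ionize(frame, SolvationSpec(salt_concentration=0.0))
        lipid_charge = sum(
            registry[n].charge for n in frame.molecule_species().values()
        )
        n_na = int((wet.species == "NA").sum())
        n_cl = int((wet.species == "CL").sum())
        assert n_na - n_cl == -lipid_charge

    def test_no_water_in_hydrophobic_core(self, myelin):
        frame = build_bilayer(myelin, 200, thickness=4.5, box_lz=12.0)
        wet = solvate_and_ionize(frame)
        mid = wet.box[2] / 2
        wz = wet.positions[wet.water_mask, 2]
        assert np.all(np.abs(wz - mid) > 0.4 * 4.5)

    def test_no_solvent_volume(self, myelin):
        frame = build_bilayer(myelin, 200, thickness=4.5, box_lz=4.6)
        with pytest.raises(BuildError):
            solvate_and_ionize(frame)
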