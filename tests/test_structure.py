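import math

import numpy as np
import pytest

from axomech.builder import build_bilayer
from axomech.composition import LeafletComposition, MembraneComposition
from axomech.frames import BilayerFrame
from axomech.structure import (
    AnalysisError,
    assign_leaflets,
    block_error,
    count_contacts,
    enrichment_factor,
    thickness_voronoi,
    water_partition,
)
from axomech.synthetic import SynthFrameSpec, synth_frame

from oracles import brute_shell_ratio, brute_thickness

AVOGADRO = 6.02214076e23


def two_bead_frame(pairs, box=(24.0, 24.0, 12.0), species="POPC"):
    """Frame of minimal 2-bead lipids at given (x, y, z_head) tuples.

    ``pairs`` alternates leaflets by the sign of z_head relative to lz/2.
    """
    pos, mol, spec, role = [], [], [], []
    for i, (x, y, zh) in enumerate(pairs, start=1):
        ztail = zh - 0.5 if zh > box[2] / 2 else zh + 0.5
        pos += [(x, y, zh), (x, y, ztail)]
        mol += [i, i]
        spec += [species, species]
        role += ["head", "first_tail"]
    return BilayerFrame(
        positions=np.array(pos),
        molecule_id=np.array(mol),
        species=np.array(spec),
        role=np.array(role),
        box=np.array(box),
    )


class TestAssignLeaflets:
    def test_matches_builder_labels(self, small_frame):
        got = assign_leaflets(small_frame)
        for mol, lab in small_frame.leaflet_label.items():
            expected = "upper" if lab == "extracellular" else "lower"
            assert got[mol] == expected

    def test_invariant_under_z_translation(self, small_frame):
        shifted = small_frame.translated((0.0, 0.0, 5.0))
        assert assign_leaflets(shifted) == assign_leaflets(small_frame)

    def test_even_split_on_symmetric_frame(self, myelin):
        frame = build_bilayer(myelin, 100, seed=2)
        got = assign_leaflets(frame)
        assert sum(1 for v in got.values() if v == "upper") == 50

    def test_unbalanced_coplanar_leaflets_still_split(self, myelin):
        frame = synth_frame(
            SynthFrameSpec(
                composition=myelin, n_lipids=200, pore=((3.0, 3.0), 1.5), seed=0
            )
        )
        got = assign_leaflets(frame)
        assert {"upper", "lower"} == set(got.values())


class TestThickness:
    def test_lattice_frame_exact(self, myelin):
        frame = build_bilayer(
            myelin, 500, thickness=4.506, box_lz=12.0, seed=1
        )
        res = thickness_voronoi(frame)
        assert res.mean_thickness == pytest.approx(4.506, abs=1e-9)

    def test_jitter_does_not_change_z_separation(self, myelin):
        a = build_bilayer(myelin, 200, thickness=4.5, lateral_jitter=0.0)
        b = build_bilayer(myelin, 200, thickness=4.5, lateral_jitter=0.1)
        ta = thickness_voronoi(a).mean_thickness
        tb = thickness_voronoi(b).mean_thickness
        assert ta == pytest.approx(tb, abs=1e-9)

    def test_translation_invariance(self, small_frame):
        t0 = thickness_voronoi(small_frame).mean_thickness
        t1 = thickness_voronoi(
            small_frame.translated((1.3, -0.7, 2.9))
        ).mean_thickness
        assert t1 == pytest.approx(t0, abs=1e-12)

    def test_matches_brute_force_on_random_frames(self, myelin, registry, rng):
        for _ in range(5):
            n = int(rng.integers(60, 250)) * 2
            frame = build_bilayer(
                myelin,
                n,
                thickness=float(rng.uniform(3.5, 5.0)),
                seed=int(rng.integers(0, 2**16)),
            )
            # perturb all coordinates so the lattice is not degenerate
            frame.positions += rng.normal(0, 0.15, frame.positions.shape)
            got = thickness_voronoi(frame, registry).mean_thickness
            want = brute_thickness(frame, registry)
            assert got == pytest.approx(want, abs=1e-12)

    def test_mean_is_average_of_per_lipid(self, small_frame):
        res = thickness_voronoi(small_frame)
        assert res.mean_thickness == pytest.approx(
            np.mean(list(res.per_lipid.values()))
        )

    def test_cholesterol_excluded_without_phosphate(self, small_frame, registry):
        res = thickness_voronoi(small_frame, registry)
        chol_mols = {
            m
            for m, s in small_frame.molecule_species().items()
            if s == "CHOL"
        }
        assert chol_mols.isdisjoint(res.per_lipid)


class TestContacts:
    def test_pair_within_cutoff(self):
        frame = two_bead_frame([(1.0, 1.0, 8.0), (2.0, 1.0, 8.0),
                                (1.0, 1.0, 4.0), (5.0, 5.0, 4.0)])
        df = count_contacts(frame, per_leaflet=True)["upper"]
        assert df.loc["POPC", "POPC"] == pytest.approx(1.0)

    def test_pair_beyond_cutoff(self):
        frame = two_bead_frame([(1.0, 1.0, 8.0), (2.6, 1.0, 8.0),
                                (1.0, 1.0, 4.0), (5.0, 5.0, 4.0)])
        df = count_contacts(frame, per_leaflet=True)["upper"]
        assert df.loc["POPC", "POPC"] == 0.0

    def test_minimum_image_contact(self):
        # 0.2 and 23.8 in a 24 nm box are 0.4 nm apart periodically
        frame = two_bead_frame([(0.2, 1.0, 8.0), (23.8, 1.0, 8.0),
                                (1.0, 1.0, 4.0), (5.0, 5.0, 4.0)])
        df = count_contacts(frame, per_leaflet=True)["upper"]
        assert df.loc["POPC", "POPC"] == pytest.approx(1.0)

    def test_unordered_totals_symmetric(self, myelin):
        frame = build_bilayer(myelin, 300, seed=7)
        res = count_contacts(frame, per_leaflet=True)
        hist_up = frame.species_histogram("extracellular")
        df = res["upper"]
        for a in df.index:
            for b in df.columns:
                total_ab = df.loc[a, b] * hist_up.get(a, 0)
                total_ba = df.loc[b, a] * hist_up.get(b, 0)
                assert total_ab == pytest.approx(total_ba)


class TestEnrichment:
    def test_single_class_membrane_is_unity(self):
        leaf = LeafletComposition({"POPC": 1.0})
        frame = build_bilayer(
            MembraneComposition(leaf, leaf), 200, seed=1
        )
        res = enrichment_factor(frame, "PC", 1.5, per_leaflet=False)
        assert res.enrichment["PC"] == pytest.approx(1.0)

    def test_whole_box_shell_is_unity(self, myelin):
        # a shell covering the whole box recovers the bulk composition;
        # only the reference's own class sees a small self-exclusion dip
        frame = build_bilayer(myelin, 1000, seed=5)
        big = float(np.max(frame.box)) * 2
        res = enrichment_factor(frame, "PC", big, per_leaflet=False)
        for cls, val in res.enrichment.items():
            assert val == pytest.approx(1.0, abs=0.02), cls

    def test_cluster_matches_brute_force_exactly(self, myelin, registry):
        frame = synth_frame(
            SynthFrameSpec(
                composition=myelin,
                n_lipids=600,
                cluster=("GCER", 3.0, 2.0),
                seed=9,
            )
        )
        res = enrichment_factor(frame, "GLYCO", 1.5, per_leaflet=True)["upper"]
        ratio_x, ratio_bulk = brute_shell_ratio(
            frame, registry, "GLYCO", 1.5, "upper"
        )
        for cls in ratio_bulk:
            assert res.ratio_x[cls] == pytest.approx(ratio_x[cls], abs=1e-12)
            assert res.ratio_bulk[cls] == pytest.approx(ratio_bulk[cls])
        assert res.enrichment["GLYCO"] > 1.0

    def test_homogeneous_frames_near_unity(self, node):
        # averaged over independently seeded frames, as the method averages
        # over trajectory frames
        acc = {}
        n_frames = 6
        for seed in range(n_frames):
            frame = build_bilayer(node, 5000, seed=seed)
            for leaflet, res in enrichment_factor(
                frame, "PC", 1.5, per_leaflet=True
            ).items():
                for cls, val in res.enrichment.items():
                    acc.setdefault((leaflet, cls), []).append(val)
        for key, vals in acc.items():
            assert 0.9 <= np.mean(vals) <= 1.1, key

    def test_empty_shell_flagged(self, small_frame):
        res = enrichment_factor(small_frame, "PC", 1e-4, per_leaflet=False)
        assert res.empty_shell
        assert all(math.isnan(v) for v in res.enrichment.values())

    def test_absent_reference_raises(self, small_frame):
        with pytest.raises(AnalysisError, match="not present"):
            enrichment_factor(small_frame, "DOPG", 1.5, per_leaflet=False)


class TestWaterPartition:
    def _frame_with_slab_water(self, myelin, n_water_beads, seed=0):
        frame = build_bilayer(myelin, 200, thickness=4.5, box_lz=12.0, seed=seed)
        rng = np.random.default_rng(seed)
        mid = frame.box[2] / 2
        pts = np.column_stack(
            [
                rng.uniform(0, frame.box[0], n_water_beads),
                rng.uniform(0, frame.box[1], n_water_beads),
                rng.uniform(mid - 2.0, mid + 2.0, n_water_beads),
            ]
        )
        start = int(frame.molecule_id.max()) + 1
        return BilayerFrame(
            positions=np.concatenate([frame.positions, pts]),
            molecule_id=np.concatenate(
                [frame.molecule_id, np.arange(start, start + n_water_beads)]
            ),
            species=np.concatenate(
                [frame.species, np.full(n_water_beads, "W", dtype="U8")]
            ),
            role=np.concatenate(
                [frame.role, np.full(n_water_beads, "water", dtype="U12")]
            ),
            box=frame.box,
            leaflet_label=frame.leaflet_label,
        )

    def test_unit_conversion_against_hand_result(self, myelin):
        frame = self._frame_with_slab_water(myelin, 100)
        res = water_partition([frame], waters_per_bead=4)
        slab_volume = res.membrane_volume
        want = math.log10(
            (400 / (AVOGADRO * slab_volume * 1e-24)) / 55.5
        )
        assert res.log_k == pytest.approx(want, abs=1e-12)

    def test_bulk_concentration_gives_log_zero(self, myelin):
        frame = self._frame_with_slab_water(myelin, 10)
        res = water_partition([frame], waters_per_bead=4)
        # rescale: choose bead count that reproduces 55.5 mol/L exactly
        n_for_bulk = 55.5 * AVOGADRO * res.membrane_volume * 1e-24 / 4
        frame2 = self._frame_with_slab_water(myelin, int(round(n_for_bulk)))
        res2 = water_partition([frame2], waters_per_bead=4)
        assert res2.log_k == pytest.approx(0.0, abs=5e-3)

    def test_dry_slab_flagged(self, small_frame):
        res = water_partition([small_frame])
        assert res.below_detection
        assert res.log_k == float("-inf")

    def test_protein_correction_shrinks_volume(self, myelin):
        frame = self._frame_with_slab_water(myelin, 100)
        base = water_partition([frame])
        corrected = water_partition([frame], protein_volume=50.0)
        assert corrected.membrane_volume == pytest.approx(
            base.membrane_volume - 50.0
        )
        with pytest.raises(AnalysisError):
            water_partition([frame], protein_volume=1e6)


class TestBlockError:
    def test_constant_series(self):
        mean, se = block_error([3.3] * 20, 5)
        assert mean == pytest.approx(3.3)
        assert se == pytest.approx(0.0)

    def test_one_to_ten_hand_values(self):
        mean, se = block_error(list(range(1, 11)), 5)
        assert mean == pytest.approx(5.5)
        assert se == pytest.approx(math.sqrt(10) / math.sqrt(5))

    def test_uneven_partition_drops_nothing(self):
        series = list(range(9))
        mean, _ = block_error(series, 5)
        # blocks of sizes 2,2,2,2,1: mean of block means
        assert mean == pytest.approx(np.mean([0.5, 2.5, 4.5, 6.5, 8.0]))

    @pytest.mark.parametrize("n_blocks", [0, 1])
    def test_too_few_blocks(self, n_blocks):
        with pytest.raises(AnalysisError):
            block_error([1.0, 2.0, 3.0], n_blocks)
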