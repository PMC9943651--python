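"""Rp/Sp assignment, anomalous map peaks and the four-way stereo call."""

import dataclasses

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from psbind import stereo, synthetic_data
from psbind.structio import DensityGrid


def rdkit_cip_label(p, s_pos, o3, o5, o_nb):
    """Independent CIP oracle: embed the center as C(Br)(Cl)(F)H with the
    halogen priorities standing in for S > O3' > O5' > O(non-bridging), and
    read RDKit's R/S assignment from the 3-D coordinates."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    mol = Chem.RWMol()
    idxs = [mol.AddAtom(Chem.Atom(z)) for z in (6, 35, 17, 9, 1)]
    for i in idxs[1:]:
        mol.AddBond(idxs[0], i, Chem.BondType.SINGLE)
    conf = Chem.Conformer(5)
    for i, v in zip(idxs, (p, s_pos, o3, o5, o_nb)):
        conf.SetAtomPosition(i, Point3D(*map(float, v)))
    m = mol.GetMol()
    m.AddConformer(conf)
    Chem.SanitizeMol(m)
    Chem.AssignStereochemistryFrom3D(m)
    code = m.GetAtomWithIdx(idxs[0]).GetPropsAsDict().get("_CIPCode")
    return {"R": "Rp", "S": "Sp"}[code]


def blob_map(centers_heights, lo=(-5, -5, -5), hi=(5, 5, 5), spacing=0.25, width=0.5):
    """Map with Gaussian blobs of given σ-heights; values on the σ scale."""
    lo, hi = np.asarray(lo, float), np.asarray(hi, float)
    dims = np.ceil((hi - lo) / spacing).astype(int) + 1
    axes = [lo[k] + spacing * np.arange(dims[k]) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    vals = np.zeros(tuple(dims))
    for center, h in centers_heights:
        c = np.asarray(center, float)
        vals += h * np.exp(
            -((gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2) / (2 * width**2)
        )
    return DensityGrid(origin=lo, spacing=np.full(3, spacing), values=vals, sigma=1.0)


def test_stereoisomer_count_doubles_per_linkage():
    assert stereo.stereoisomer_count(2) == 2
    assert stereo.stereoisomer_count(15) == 16384
    with pytest.raises(ValueError):
        stereo.stereoisomer_count(0)


class TestExtractLinkages:
    def test_strand_has_n_minus_one_linkages(self, strand_model):
        links = stereo.extract_linkages(strand_model, ["A"])
        assert len(links) == 14
        assert [lk.linkage_id for lk in links] == list(range(1, 15))

    def test_dinucleotide_single_linkage(self):
        spec = synthetic_data.FixtureSpec(n_nucleotides=2, stereo_pattern=["Rp"])
        model = synthetic_data.build_ps_strand(spec)
        assert len(stereo.extract_linkages(model, ["A"])) == 1

    def test_missing_backbone_atom_skips_with_warning(self, strand_spec):
        model = synthetic_data.build_ps_strand(strand_spec)
        atoms = [
            a
            for a in model.atoms
            if not (a.residue_number == 7 and a.name == "O3'")
        ]
        model = dataclasses.replace(model, atoms=atoms)
        with pytest.warns(UserWarning, match="linkage 7"):
            links = stereo.extract_linkages(model, ["A"])
        assert len(links) == 13
        assert 7 not in [lk.linkage_id for lk in links]

    def test_geometry_invariants_enforced(self, strand_model):
        lk = stereo.extract_linkages(strand_model, ["A"])[0]
        # moving O5' far from P violates the bond-length invariant
        with pytest.raises(ValueError, match="P-O5"):
            dataclasses.replace(lk, o5_pos=lk.o5_pos + 5.0)


class TestAssignChirality:
    def test_matches_independent_cip_oracle_on_strand(self, strand_model):
        for lk in stereo.extract_linkages(strand_model, ["A"]):
            for site in (0, 1):
                want = rdkit_cip_label(
                    lk.p_pos,
                    lk.nonbridge[site].position,
                    lk.o3_pos,
                    lk.o5_pos,
                    lk.nonbridge[1 - site].position,
                )
                assert stereo.assign_chirality(lk, site) == want

    def test_two_sites_have_opposite_labels(self, strand_model):
        for lk in stereo.extract_linkages(strand_model, ["A"]):
            assert stereo.assign_chirality(lk, 0) != stereo.assign_chirality(lk, 1)

    def test_invariant_under_rigid_motion(self, strand_model):
        lk = stereo.extract_linkages(strand_model, ["A"])[3]
        rot = Rotation.from_euler("xyz", [0.4, -1.1, 2.2]).as_matrix()
        shift = np.array([5.0, -3.0, 8.0])

        def move(v):
            return rot @ v + shift

        moved = dataclasses.replace(
            lk,
            p_pos=move(lk.p_pos),
            o5_pos=move(lk.o5_pos),
            o3_pos=move(lk.o3_pos),
            nonbridge=[
                dataclasses.replace(s, position=move(s.position)) for s in lk.nonbridge
            ],
        )
        for site in (0, 1):
            assert stereo.assign_chirality(moved, site) == stereo.assign_chirality(lk, site)

    def test_flips_under_reflection(self, strand_model):
        for lk in stereo.extract_linkages(strand_model, ["A"])[:4]:
            mirror = dataclasses.replace(
                lk,
                p_pos=lk.p_pos * [-1, 1, 1],
                o5_pos=lk.o5_pos * [-1, 1, 1],
                o3_pos=lk.o3_pos * [-1, 1, 1],
                nonbridge=[
                    dataclasses.replace(s, position=s.position * [-1, 1, 1])
                    for s in lk.nonbridge
                ],
            )
            for site in (0, 1):
                assert stereo.assign_chirality(mirror, site) != stereo.assign_chirality(
                    lk, site
                )


class TestPeakHeight:
    def test_flat_map_with_unit_noise_region_near_zero(self):
        rng = np.random.default_rng(0)
        vals = np.zeros((20, 20, 20))
        vals[:, :, :4] = rng.normal(size=(20, 20, 4))  # σ-calibration region
        g = DensityGrid(origin=[0, 0, 0], spacing=[0.5, 0.5, 0.5], values=vals, sigma=1.0)
        assert abs(stereo.peak_height(g, [5.0, 5.0, 7.0], radius=1.0)) < 0.5

    def test_blob_at_query_returns_its_height(self):
        g = blob_map([((0.0, 0.0, 0.0), 5.0)])
        assert stereo.peak_height(g, [0, 0, 0], radius=1.0) == pytest.approx(5.0, rel=0.02)

    def test_offset_blob_matches_gaussian_tail(self):
        width = 0.5
        g = blob_map([((2.0, 0.0, 0.0), 5.0)], width=width)
        # nearest approach of the search sphere (radius 1) to the blob center
        # is 1 Å; the max lies there, at the analytic Gaussian tail value
        expect = 5.0 * np.exp(-1.0**2 / (2 * width**2))
        got = stereo.peak_height(g, [0, 0, 0], radius=1.0)
        assert got == pytest.approx(expect, rel=0.15)

    def test_out_of_bounds_rejected(self):
        g = blob_map([((0.0, 0.0, 0.0), 5.0)])
        with pytest.raises(ValueError, match="outside"):
            stereo.peak_height(g, [50, 0, 0])


class TestClassifyLinkage:
    def _linkage_and_sites(self, strand_model):
        lk = stereo.extract_linkages(strand_model, ["A"])[0]
        rp = lk.nonbridge[stereo.rp_site_index(lk)].position
        sp = lk.nonbridge[1 - stereo.rp_site_index(lk)].position
        return lk, rp, sp

    def _grid_around(self, lk, centers_heights):
        lo = lk.p_pos - 6
        hi = lk.p_pos + 6
        return blob_map(centers_heights, lo=lo, hi=hi)

    def test_single_rp_blob_called_rp(self, strand_model):
        lk, rp, _sp = self._linkage_and_sites(strand_model)
        call = stereo.classify_linkage(self._grid_around(lk, [(rp, 6.0)]), lk)
        assert call.call == "Rp" and call.reliable

    def test_equal_blobs_called_mixed(self, strand_model):
        lk, rp, sp = self._linkage_and_sites(strand_model)
        call = stereo.classify_linkage(
            self._grid_around(lk, [(rp, 5.0), (sp, 5.0)]), lk
        )
        assert call.call == "mixed"

    def test_no_density_called_indeterminate(self, strand_model):
        lk, rp, _sp = self._linkage_and_sites(strand_model)
        call = stereo.classify_linkage(self._grid_around(lk, [(rp, 1.0)]), lk)
        assert call.call == "indeterminate" and call.reliable

    def test_high_b_forces_unreliable_indeterminate(self, strand_model):
        lk, rp, _sp = self._linkage_and_sites(strand_model)
        hot = dataclasses.replace(lk, mean_b=70.0)
        call = stereo.classify_linkage(self._grid_around(lk, [(rp, 6.0)]), hot)
        assert call.call == "indeterminate" and not call.reliable

    def test_monotone_in_rp_amplitude(self, strand_model):
        # raising the Rp-site amplitude can never change a call to Sp
        lk, rp, sp = self._linkage_and_sites(strand_model)
        order = {"Sp": 0, "indeterminate": 1, "mixed": 1, "Rp": 2}
        ranks = []
        for h in (0.0, 2.0, 4.0, 6.0, 9.0, 15.0):
            call = stereo.classify_linkage(
                self._grid_around(lk, [(rp, h), (sp, 4.0)]), lk
            )
            ranks.append(order[call.call])
        assert ranks == sorted(ranks)
        assert ranks[0] == 0 and ranks[-1] == 2

    def test_sites_outside_map_raise_frame_error(self, strand_model):
        lk, _rp, _sp = self._linkage_and_sites(strand_model)
        far = blob_map([((0, 0, 0), 5.0)], lo=(100, 100, 100), hi=(110, 110, 110))
        with pytest.raises(ValueError, match="frame"):
            stereo.classify_linkage(far, lk)


class TestCallStrand:
    def test_programmed_pattern_recovered(self, strand_model, strand_map, strand_spec):
        calls = stereo.call_strand(strand_map, strand_model, chains=["A"])
        assert [c.call for c in calls] == strand_spec.stereo_pattern

    def test_sulfur_swap_flips_every_single_conformer_call(self, strand_spec):
        flipped = dataclasses.replace(
            strand_spec,
            stereo_pattern=[
                {"Rp": "Sp", "Sp": "Rp", "mixed": "mixed"}[s]
                for s in strand_spec.stereo_pattern
            ],
        )
        model = synthetic_data.build_ps_strand(flipped)
        grid = synthetic_data.render_anomalous_map(model, noise=0.0, seed=0)
        calls = stereo.call_strand(grid, model, chains=["A"])
        assert [c.call for c in calls] == flipped.stereo_pattern

    def test_all_high_b_all_indeterminate(self, strand_spec):
        hot = dataclasses.replace(strand_spec, b_profile=[80.0] * 14)
        model = synthetic_data.build_ps_strand(hot)
        grid = synthetic_data.render_anomalous_map(model, noise=0.0, seed=0)
        calls = stereo.call_strand(grid, model, chains=["A"])
        assert all(c.call == "indeterminate" and not c.reliable for c in calls)
        assert stereo.summarize_calls(calls)["indeterminate"] == 14


def test_unreliable_call_cannot_carry_a_label():
    with pytest.raises(ValueError):
        stereo.StereoCall(
            linkage_id=1, call="Rp", peak_rp_sigma=6.0, peak_sp_sigma=0.0, reliable=False
        )
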