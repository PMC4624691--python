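"""Fragment construction, copy expansion, anchoring, greedy grouping."""

import numpy as np
import pytest

from molfrag import (
    FixtureRecipe,
    FragmentKind,
    FragmentSpec,
    GroupingError,
    anchor_restraints,
    build_bridge_fragment,
    build_label_fragment,
    group_fragments,
    make_helix_bundle,
    make_label_host,
    minimize,
)
from molfrag.engine import RestraintProvider


class TestBridgeBuilder:
    def test_cd_bridge_composition_and_neutrality(self, bundle_copy):
        system, catalog = bundle_copy
        frag = build_bridge_fragment(
            system, FragmentSpec(kind="cd_bridge", host_sites=catalog[0].sites)
        )
        names = [system.name[i] for i in frag.atoms]
        assert names.count("SG") == 2
        assert names.count("CD") == 1
        assert float(system.charge[frag.atoms].sum()) == pytest.approx(0.0, abs=1e-12)
        assert len(frag.anchor_pairs) == 8  # 4 backbone atoms x 2 residues
        system.validate()

    def test_mg_bridge_coordinates_via_od2(self, bundle_copy):
        system, catalog = bundle_copy
        frag = build_bridge_fragment(
            system, FragmentSpec(kind="mg_bridge", host_sites=catalog[2].sites)
        )
        ion = frag.bridging_ion
        od2 = [i for i in frag.atoms if system.name[i] == "OD2"]
        assert len(od2) == 2
        # ion placed at the midpoint of the two coordinating O-delta2
        mid = 0.5 * (system.positions[od2[0]] + system.positions[od2[1]])
        np.testing.assert_allclose(system.positions[ion], mid, atol=1e-12)

    def test_every_bridge_kind_is_neutral(self, bundle_copy):
        system, catalog = bundle_copy
        for entry in catalog:
            frag = build_bridge_fragment(
                system, FragmentSpec(kind=entry.kind, host_sites=entry.sites)
            )
            assert float(system.charge[frag.atoms].sum()) == pytest.approx(0.0, abs=1e-12)

    def test_label_kind_rejected_by_bridge_builder(self, bundle_copy):
        system, catalog = bundle_copy
        with pytest.raises(ValueError, match="not a bridge"):
            build_bridge_fragment(
                system, FragmentSpec(kind="mtssl_label", host_sites=(catalog[0].sites[0],))
            )

    def test_missing_backbone_site_rejected(self, bundle_copy):
        system, _ = bundle_copy
        with pytest.raises(ValueError, match="backbone"):
            build_bridge_fragment(system, FragmentSpec(kind="cd_bridge", host_sites=(9000, 9001)))

    def test_anchor_backbone_overlays_host(self, bundle_copy):
        system, catalog = bundle_copy
        frag = build_bridge_fragment(
            system, FragmentSpec(kind="cd_bridge", host_sites=catalog[0].sites)
        )
        for a, b in frag.anchor_pairs:
            assert np.linalg.norm(system.positions[a] - system.positions[b]) < 1e-12


class TestLabelBuilder:
    def test_copy_count_and_scale(self, bundle_copy):
        system, catalog = bundle_copy
        site = catalog[0].sites[0]
        ens = build_label_fragment(
            system, FragmentSpec(kind="mtssl_label", host_sites=(site,), n_copies=25)
        )
        assert ens.n_copies == 25
        assert all(c.scale == pytest.approx(1 / 25) for c in ens.copies)
        assert len({c.exclusion_group for c in ens.copies}) == 25

    def test_single_copy_identity(self, bundle_copy):
        system, catalog = bundle_copy
        ens = build_label_fragment(
            system, FragmentSpec(kind="dummy_label", host_sites=(catalog[0].sites[0],), n_copies=1)
        )
        assert ens.n_copies == 1
        assert ens.copies[0].scale == 1.0

    def test_copies_share_composition(self, bundle_copy):
        system, catalog = bundle_copy
        ens = build_label_fragment(
            system, FragmentSpec(kind="mtssl_label", host_sites=(catalog[1].sites[0],), n_copies=5)
        )
        ref = [system.name[i] for i in ens.copies[0].atoms]
        ref_q = sorted(system.charge[ens.copies[0].atoms])
        for c in ens.copies[1:]:
            assert [system.name[i] for i in c.atoms] == ref
            assert sorted(system.charge[c.atoms]) == ref_q

    def test_seeds_change_dihedrals_not_composition(self, bundle_copy):
        system, catalog = bundle_copy
        site = catalog[0].sites[0]
        sys_a = system.copy()
        sys_b = system.copy()
        ens_a = build_label_fragment(
            sys_a, FragmentSpec(kind="mtssl_label", host_sites=(site,), n_copies=3), seed=1
        )
        ens_b = build_label_fragment(
            sys_b, FragmentSpec(kind="mtssl_label", host_sites=(site,), n_copies=3), seed=2
        )
        for ca, cb in zip(ens_a.copies, ens_b.copies):
            assert [sys_a.name[i] for i in ca.atoms] == [sys_b.name[i] for i in cb.atoms]
        # probe positions must differ between seeds (different chi draws)
        pa = sys_a.positions[[c.probe_atom for c in ens_a.copies]]
        pb = sys_b.positions[[c.probe_atom for c in ens_b.copies]]
        assert np.abs(pa - pb).max() > 0.1

    def test_probe_atom_is_nitroxide_oxygen(self, bundle_copy):
        system, catalog = bundle_copy
        ens = build_label_fragment(
            system, FragmentSpec(kind="mtssl_label", host_sites=(catalog[0].sites[0],), n_copies=2)
        )
        assert all(system.name[c.probe_atom] == "ON" for c in ens.copies)


class TestAnchors:
    def test_coincident_anchor_zero_energy(self, bundle_copy):
        system, catalog = bundle_copy
        frag = build_bridge_fragment(
            system, FragmentSpec(kind="cd_bridge", host_sites=catalog[0].sites)
        )
        terms = anchor_restraints(frag, k=50.0)
        from molfrag import restraint_energy_forces

        e, f = restraint_energy_forces(terms, system.positions)
        assert e == pytest.approx(0.0, abs=1e-20)
        assert np.abs(f).max() == 0.0

    def test_unit_displacement_energy_matches_convention(self, bundle_copy):
        """k (d - b0)^2 with k = 50, d = 1 A, b0 = 0 gives 50 kcal/mol."""
        system, catalog = bundle_copy
        frag = build_bridge_fragment(
            system, FragmentSpec(kind="cd_bridge", host_sites=catalog[0].sites)
        )
        a, b = frag.anchor_pairs[0]
        terms = anchor_restraints(frag, k=50.0)[:1]
        pos = system.positions.copy()
        pos[a] = pos[b] + np.array([1.0, 0.0, 0.0])
        from molfrag import restraint_energy_forces

        e, _ = restraint_energy_forces(terms, pos)
        assert e == pytest.approx(50.0, abs=1e-10)

    def test_nonpositive_k_rejected(self, bundle_copy):
        system, catalog = bundle_copy
        frag = build_bridge_fragment(
            system, FragmentSpec(kind="cd_bridge", host_sites=catalog[0].sites)
        )
        with pytest.raises(ValueError):
            anchor_restraints(frag, k=0.0)

    def test_minimization_under_anchors_restores_backbone(self, bundle_copy):
        system, catalog = bundle_copy
        frag = build_bridge_fragment(
            system, FragmentSpec(kind="cd_bridge", host_sites=catalog[0].sites)
        )
        rng = np.random.default_rng(4)
        pos = system.positions.copy()
        pos[frag.atoms] += rng.normal(scale=0.5, size=(len(frag.atoms), 3))
        terms = anchor_restraints(frag, k=50.0)
        res = minimize(pos, [RestraintProvider(terms)], max_steps=2000, tol=1e-10)
        for a, b in frag.anchor_pairs:
            assert np.linalg.norm(res.positions[a] - res.positions[b]) < 1e-3


class TestGrouping:
    def _host_with_labels(self, n_sites, n_copies, separation=30.0):
        system, sites = make_label_host(
            FixtureRecipe(kind="globular_label_host", n_sites=n_sites,
                          site_min_separation=separation, n_residues=10)
        )
        ensembles = [
            build_label_fragment(
                system, FragmentSpec(kind="dummy_label", host_sites=(s,), n_copies=n_copies),
                seed=s,
            )
            for s in sites
        ]
        return system, ensembles

    def test_two_remote_sites_give_n_copies_groups(self):
        system, ensembles = self._host_with_labels(2, 4, separation=40.0)
        asg = group_fragments(system, ensembles, cutoff=12.0)
        assert asg.n_groups == 4
        for members in asg.groups.values():
            assert len({m.site for m in members}) == len(members)

    def test_within_group_pairs_beyond_cutoff_brute_force(self):
        system, ensembles = self._host_with_labels(3, 5, separation=30.0)
        asg = group_fragments(system, ensembles, cutoff=12.0)
        for members in asg.groups.values():
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    pa = system.positions[members[a].atoms]
                    pb = system.positions[members[b].atoms]
                    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
                    assert d.min() > 12.0

    def test_same_site_copies_split_remote_sites_share(self):
        """Copies s and s' of one site always land in different groups,
        while copies of two beyond-cutoff sites can share one group."""
        system, ensembles = self._host_with_labels(2, 6, separation=40.0)
        asg = group_fragments(system, ensembles, cutoff=12.0)
        shared = [m for m in asg.groups.values() if len({c.site for c in m}) == 2]
        assert shared, "remote sites should share exclusion groups"
        for members in asg.groups.values():
            sites = [m.site for m in members]
            assert len(sites) == len(set(sites))

    def test_group_cap_error_reports_needed(self):
        system, ensembles = self._host_with_labels(2, 6, separation=40.0)
        with pytest.raises(GroupingError, match="cap"):
            group_fragments(system, ensembles, cutoff=12.0, max_groups=3)

    def test_fragment_ids_rewritten_consistently(self):
        system, ensembles = self._host_with_labels(2, 3, separation=40.0)
        asg = group_fragments(system, ensembles, cutoff=12.0)
        for g, members in asg.groups.items():
            for m in members:
                assert m.exclusion_group == g
                assert set(system.fragment_id[m.atoms].tolist()) == {g}
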