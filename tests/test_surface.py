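import numpy as np
import pytest

from elevator import errors, surface
from elevator.structures import AtomModel, DomainDefinition


def _atoms(records):
    """records: (chain, resnum, resname, atomname, element, xyz)"""
    return AtomModel(
        chain=np.array([r[0] for r in records], dtype=object),
        resnum=np.array([r[1] for r in records], dtype=int),
        icode=np.array([""] * len(records), dtype=object),
        resname=np.array([r[2] for r in records], dtype=object),
        atomname=np.array([r[3] for r in records], dtype=object),
        element=np.array([r[4] for r in records], dtype=object),
        coords=np.array([r[5] for r in records], dtype=float),
    )


def _mc_sphere_area(centers, radii, probe, n_points=100_000, seed=0):
    """Dense Monte-Carlo SASA oracle for a small set of spheres."""
    rng = np.random.default_rng(seed)
    total = 0.0
    for i, (c, r) in enumerate(zip(centers, radii)):
        R = r + probe
        pts = rng.normal(size=(n_points, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts = c + R * pts
        exposed = np.ones(n_points, dtype=bool)
        for j, (c2, r2) in enumerate(zip(centers, radii)):
            if i == j:
                continue
            exposed &= np.linalg.norm(pts - c2, axis=1) >= (r2 + probe)
        total += 4 * np.pi * R**2 * exposed.mean()
    return total


class TestSasa:
    def test_isolated_atom_analytic_sphere(self):
        model = _atoms([("A", 1, "ALA", "CA", "C", (0, 0, 0))])
        res = surface.sasa(model, probe_radius=1.4, point_number=960)
        expected = 4 * np.pi * (1.70 + 1.4) ** 2
        assert res.total == pytest.approx(expected, rel=0.01)

    def test_far_atoms_additive(self):
        pair = _atoms([
            ("A", 1, "ALA", "CA", "C", (0, 0, 0)),
            ("A", 2, "ALA", "O", "O", (100, 0, 0)),
        ])
        singles = [
            surface.sasa(_atoms([("A", 1, "ALA", "CA", "C", (0, 0, 0))])).total,
            surface.sasa(_atoms([("A", 2, "ALA", "O", "O", (100, 0, 0))])).total,
        ]
        assert surface.sasa(pair).total == pytest.approx(sum(singles), rel=1e-6)

    def test_overlapping_spheres_match_monte_carlo(self):
        # two carbons 2.5 Å apart, checked against a 1e5-point MC oracle
        coords = [(0.0, 0.0, 0.0), (2.5, 0.0, 0.0)]
        model = _atoms([
            ("A", 1, "ALA", "CA", "C", coords[0]),
            ("A", 2, "ALA", "CA", "C", coords[1]),
        ])
        res = surface.sasa(model, probe_radius=1.4, point_number=960)
        oracle = _mc_sphere_area(np.array(coords), [1.70, 1.70], probe=1.4, seed=3)
        assert res.total == pytest.approx(oracle, rel=0.02)

    def test_per_residue_sums_per_atom(self):
        model = _atoms([
            ("A", 1, "ALA", "CA", "C", (0, 0, 0)),
            ("A", 1, "ALA", "CB", "C", (1.5, 0, 0)),
            ("A", 2, "GLY", "CA", "C", (8, 0, 0)),
        ])
        res = surface.sasa(model)
        assert res.per_residue["sasa"].sum() == pytest.approx(res.total, rel=1e-9)
        assert len(res.per_residue) == 2

    def test_unknown_element_rejected(self):
        model = _atoms([("A", 1, "HEM", "FE", "FE", (0, 0, 0))])
        with pytest.raises(errors.ValidationError, match="FE"):
            surface.sasa(model)
        res = surface.sasa(model, radii_overrides={"FE": 1.4})
        assert res.total > 0

    def test_monotone_decrease_on_approach(self):
        areas = []
        for d in (10.0, 6.0, 4.0, 3.0, 2.0):
            model = _atoms([
                ("A", 1, "ALA", "CA", "C", (0, 0, 0)),
                ("A", 2, "ALA", "CA", "C", (d, 0, 0)),
            ])
            areas.append(surface.sasa(model).total)
        assert all(a >= b for a, b in zip(areas, areas[1:]))


class TestBuriedArea:
    def _two_group_model(self, gap):
        return _atoms([
            ("A", 1, "ALA", "CA", "C", (0, 0, 0)),
            ("A", 2, "ALA", "CA", "C", (3.0, 0, 0)),
            ("B", 1, "ALA", "CA", "C", (3.0 + gap, 0, 0)),
            ("B", 2, "ALA", "CA", "C", (6.0 + gap, 0, 0)),
        ])

    def test_distant_groups_zero(self):
        model = self._two_group_model(gap=100.0)
        bsa = surface.buried_area(model, {"A": {1, 2}}, {"B": {1, 2}})
        assert bsa == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self):
        model = self._two_group_model(gap=2.0)
        ab = surface.buried_area(model, {"A": {1, 2}}, {"B": {1, 2}})
        ba = surface.buried_area(model, {"B": {1, 2}}, {"A": {1, 2}})
        assert ab == pytest.approx(ba, rel=1e-12)
        assert ab > 0

    def test_total_convention_doubles_interface(self):
        model = self._two_group_model(gap=2.0)
        half = surface.buried_area(model, {"A": {1, 2}}, {"B": {1, 2}})
        full = surface.buried_area(
            model, {"A": {1, 2}}, {"B": {1, 2}}, convention="total"
        )
        assert full == pytest.approx(2 * half, rel=1e-12)

    def test_zero_iff_beyond_contact_range(self):
        # contact range for two carbons: 2 * (r + probe) = 6.2 Å
        for gap, expect_zero in ((3.5, False), (6.5, True)):
            model = _atoms([
                ("A", 1, "ALA", "CA", "C", (0, 0, 0)),
                ("B", 1, "ALA", "CA", "C", (gap, 0, 0)),
            ])
            bsa = surface.buried_area(model, {"A": {1}}, {"B": {1}})
            assert (bsa < 1e-9) == expect_zero

    def test_overlapping_groups_rejected(self):
        model = self._two_group_model(gap=2.0)
        with pytest.raises(errors.ValidationError):
            surface.buried_area(model, {"A": {1, 2}}, {"A": {2}, "B": {1}})


class TestContacts:
    def _model_and_domains(self):
        model = _atoms([
            ("A", 1, "VAL", "CB", "C", (0.0, 0.0, 5.0)),
            ("A", 2, "SER", "OG", "O", (0.0, 0.0, -5.0)),
            ("B", 1, "ILE", "CB", "C", (3.0, 0.0, 5.0)),
            ("B", 2, "LEU", "CB", "C", (3.0, 0.0, -5.0)),
            ("B", 3, "ALA", "HB1", "H", (3.2, 0.0, 5.0)),
        ])
        domains = DomainDefinition(domains={
            "dimer_domain": {"A": {1, 2}},
            "core_domain": {"B": {1, 2, 3}},
            "binding_site": {"B": {2}},
        })
        return model, domains

    def test_conserved_close_pair_is_edge(self):
        model, domains = self._model_and_domains()
        grades = {("A", 1): 9, ("B", 1): 9}
        net = surface.interdomain_contacts(model, domains, grades, cutoff=4.5)
        assert len(net) == 1
        edge = net.edges[0]
        assert {edge.residue_a[2], edge.residue_b[2]} == {"VAL", "ILE"}
        assert edge.min_distance == pytest.approx(3.0)

    def test_low_grade_filtered(self):
        model, domains = self._model_and_domains()
        grades = {("A", 1): 9, ("B", 1): 5}
        net = surface.interdomain_contacts(model, domains, grades, cutoff=4.5)
        assert len(net) == 0

    def test_unscored_residue_excluded(self):
        model, domains = self._model_and_domains()
        net = surface.interdomain_contacts(model, domains, {("A", 1): 9}, cutoff=4.5)
        assert len(net) == 0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(23)
        records = []
        for i in range(20):
            chain = "A" if i < 10 else "B"
            records.append(
                (chain, i % 10 + 1, "VAL", f"C{i}", "C", tuple(rng.uniform(0, 15, 3)))
            )
        model = _atoms(records)
        domains = DomainDefinition(domains={
            "dimer_domain": {"A": set(range(1, 11))},
            "core_domain": {"B": set(range(1, 11))},
        })
        grades = {(c, r): 9 for c, r in zip(model.chain, model.resnum)}
        cutoff = 6.0
        net = surface.interdomain_contacts(model, domains, grades, cutoff=cutoff)
        brute = {}
        for i in range(20):
            for j in range(20):
                if model.chain[i] != "A" or model.chain[j] != "B":
                    continue
                d = np.linalg.norm(model.coords[i] - model.coords[j])
                key = (("A", int(model.resnum[i])), ("B", int(model.resnum[j])))
                if d <= cutoff:
                    brute[key] = min(d, brute.get(key, np.inf))
        got = {
            ((e.residue_b[0], e.residue_b[1]), (e.residue_a[0], e.residue_a[1]))
            if e.residue_a[0] == "B"
            else ((e.residue_a[0], e.residue_a[1]), (e.residue_b[0], e.residue_b[1])): e.min_distance
            for e in net.edges
        }
        assert set(got) == set(brute)
        for k in brute:
            assert got[k] == pytest.approx(brute[k], rel=1e-9)

    def test_stable_under_atom_reordering(self):
        model, domains = self._model_and_domains()
        grades = {("A", 1): 9, ("B", 1): 9}
        perm = np.array([4, 2, 0, 3, 1])
        shuffled = model.select(np.ones(5, dtype=bool))
        shuffled = AtomModel(
            chain=model.chain[perm], resnum=model.resnum[perm],
            icode=model.icode[perm], resname=model.resname[perm],
            atomname=model.atomname[perm], element=model.element[perm],
            coords=model.coords[perm],
        )
        n1 = surface.interdomain_contacts(model, domains, grades)
        n2 = surface.interdomain_contacts(shuffled, domains, grades)
        e1 = {(e.residue_a, e.residue_b, round(e.min_distance, 9)) for e in n1.edges}
        e2 = {(e.residue_a, e.residue_b, round(e.min_distance, 9)) for e in n2.edges}
        assert e1 == e2


class TestGates:
    def test_empty_network(self):
        net = surface.ContactNetwork(edges=[], grades={})
        assert surface.gate_residues(net, np.zeros(3)) == []

    def test_hydrophobic_pair_above_site(self):
        # a single VAL–ILE inter-domain contact above the binding site must
        # come out as one extracellular-side gate pair
        model_records = [
            ("A", 1, "VAL", "CB", "C", (0.0, 0.0, 5.0)),
            ("B", 1, "ILE", "CB", "C", (3.0, 0.0, 5.0)),
        ]
        model = _atoms(model_records)
        domains = DomainDefinition(domains={
            "dimer_domain": {"A": {1}}, "core_domain": {"B": {1}},
        })
        grades = {("A", 1): 9, ("B", 1): 9}
        net = surface.interdomain_contacts(model, domains, grades)
        gates = surface.gate_residues(net, binding_site_centroid=np.zeros(3))
        assert len(gates) == 2
        assert all(g.side == "above" for g in gates)
        assert {g.resname for g in gates} == {"VAL", "ILE"}

    def test_equivalence_with_set_intersection(self):
        model, domains = (
            TestContacts()._model_and_domains()
        )
        grades = {("A", 1): 9, ("A", 2): 9, ("B", 1): 9, ("B", 2): 9}
        net = surface.interdomain_contacts(model, domains, grades)
        gates = surface.gate_residues(net, binding_site_centroid=np.zeros(3))
        expected = {
            (r[0], r[1]) for r in net.participants()
            if r[2] in surface.HYDROPHOBIC_RESIDUES
        }
        assert {(g.chain, g.resnum) for g in gates} == expected
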