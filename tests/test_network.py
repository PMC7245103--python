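import numpy as np
import pytest

from moblue.engine import RateParams, run
from moblue.network import (
    CORNER,
    EDGE,
    NetworkError,
    TemplateRule,
    annotate_templates,
    assign_base_constants,
    default_network,
    enumerate_reactions,
    enumerate_species,
    extend_with_inhibitor,
    ReactionNetwork,
)


@pytest.fixture(scope="module")
def default_net():
    return default_network(RateParams())


class TestSpeciesEnumeration:
    def test_smallest_network_without_targets(self):
        ids = {sp.id for sp in enumerate_species(3)}
        assert ids == {"Mo1", "Mo2c", "Mo2e", "Mo3"}

    def test_single_monomer(self):
        species = enumerate_species(1)
        assert [sp.id for sp in species] == ["Mo1"]

    def test_targets_flagged(self):
        species = enumerate_species(154, targets=(36, 132, 154))
        targets = {sp.nuclearity for sp in species if sp.is_target}
        assert targets == {36, 132, 154}
        templates = [sp for sp in species if sp.is_template]
        assert [t.nuclearity for t in templates] == [36]

    def test_exactly_two_dimers(self):
        species = enumerate_species(154, targets=(36, 132, 154))
        dimers = [sp for sp in species if sp.nuclearity == 2]
        assert {sp.id for sp in dimers} == {"Mo2c", "Mo2e"}

    def test_zero_free_sites_only_for_targets(self):
        for sp in enumerate_species(154, targets=(36, 132, 154)):
            assert (sp.free_sites == 0) == sp.is_target

    def test_cap_below_target_is_error(self):
        with pytest.raises(NetworkError):
            enumerate_species(100, targets=(36, 132, 154))

    def test_path_free_sites_count_down_to_target(self):
        species = enumerate_species(154, targets=(36, 132, 154))
        for sp in species:
            if sp.lineage == EDGE and sp.nuclearity > 2 and not sp.is_target:
                assert sp.free_sites == 132 - sp.nuclearity


class TestReactionEnumeration:
    def test_single_dimer_channel(self):
        species = [sp for sp in enumerate_species(2) if sp.id != "Mo2e"]
        net = enumerate_reactions(species, 2)
        assert len(net.reactions) == 2
        kinds = {(rx.kind, rx.products) for rx in net.reactions}
        assert ("synthesis", ("Mo2c",)) in kinds

    def test_both_dimer_channels(self):
        net = enumerate_reactions(enumerate_species(2), 2)
        assert len(net.reactions) == 4

    def test_monomer_only_has_no_reactions(self):
        net = enumerate_reactions(enumerate_species(1), 1)
        assert net.reactions == []

    def test_default_network_passes_invariants(self, default_net):
        # conservation, arity, reversibility bijection, no duplicates
        assert default_net.validate() == []

    def test_nuclearity_conserved_exhaustively(self, default_net):
        idx = default_net.species_by_id
        for rx in default_net.reactions:
            assert sum(idx[s].nuclearity for s in rx.reactants) == sum(
                idx[s].nuclearity for s in rx.products
            )

    def test_giants_form_only_via_their_paths(self, default_net):
        for giant, lineage in (("Mo132", EDGE), ("Mo154", CORNER)):
            producers = [
                rx for rx in default_net.reactions
                if rx.kind == "synthesis" and rx.products == (giant,)
            ]
            assert producers
            for rx in producers:
                lineages = {default_net.species_by_id[r].lineage for r in rx.reactants}
                assert lineage in lineages

    def test_roundtrip_through_json(self, tmp_path, default_net):
        path = tmp_path / "net.json"
        default_net.save(path)
        loaded = ReactionNetwork.load(path)
        assert loaded.species == default_net.species
        assert loaded.reactions == default_net.reactions

    def test_edge_list_export(self, default_net):
        df = default_net.to_edge_dataframe()
        assert {"source", "target", "kind"} <= set(df.columns)
        assert len(df) >= len(default_net.reactions)


class TestRateAssignment:
    def test_dimerization_ratio_is_d(self):
        topo = enumerate_reactions(enumerate_species(2), 2)
        for d in (1.0, 2.0, 0.25):
            net = assign_base_constants(topo, RateParams(D=d))
            ks = {
                rx.products[0]: rx.base_k
                for rx in net.reactions
                if rx.kind == "synthesis"
            }
            assert ks["Mo2c"] / ks["Mo2e"] == pytest.approx(d)

    def test_giants_degrade_slowly_paths_do_not(self, default_net):
        by_reactant = {}
        for rx in default_net.reactions:
            if rx.kind == "degradation":
                by_reactant.setdefault(rx.reactants[0], rx.base_k)
        assert by_reactant["Mo154"] == pytest.approx(RateParams().k_d)
        assert by_reactant["Mo132"] == pytest.approx(RateParams().k_d)
        # a wheel-path intermediate keeps the default unimolecular constant
        assert by_reactant["Mo48w"] == pytest.approx(1.0)
        # amorphous aggregates shed fragments at a size-proportional rate
        assert by_reactant["Mo77"] == pytest.approx(77 / 2)
        # the hexamer chain is structured, not amorphous
        assert by_reactant["Mo12"] == pytest.approx(1.0)

    def test_nonpositive_d_rejected(self):
        with pytest.raises(ValueError):
            RateParams(D=0.0)


class TestTemplating:
    def test_default_rules_cover_mo6_production(self, default_net):
        mo6_producers = [
            rx for rx in default_net.reactions
            if rx.kind == "synthesis" and rx.products == ("Mo6",)
        ]
        assert mo6_producers
        assert all(rx.template_id == "Mo36" for rx in mo6_producers)

    def test_wheel_path_is_templated(self, default_net):
        wheel_steps = [
            rx for rx in default_net.reactions
            if rx.kind == "synthesis"
            and default_net.species_by_id[rx.products[0]].lineage == CORNER
        ]
        assert wheel_steps
        assert all(rx.template_id == "Mo36" for rx in wheel_steps)

    def test_ablation_clears_all_annotations(self, default_net):
        ablated = annotate_templates(default_net, [])
        assert all(rx.template_id is None for rx in ablated.reactions)

    def test_unknown_template_species_rejected(self, default_net):
        with pytest.raises(NetworkError):
            annotate_templates(default_net, [TemplateRule("Mo999", product_nuclearity=6)])


class TestInhibitorExtension:
    def test_null_inhibitor_leaves_dynamics_unchanged(self):
        p = RateParams()
        base = default_network(p, max_nuclearity=40, targets=(36,))
        ext = extend_with_inhibitor(base, binding_k=0.0, release_k=0.0)
        t1 = run(base, p, {"Mo1": 300}, horizon=3.0, seed=5)
        t2 = run(ext, p, {"Mo1": 300}, horizon=3.0, seed=5)
        assert np.array_equal(t1.series("Mo36"), t2.series("Mo36"))

    def test_binding_suppresses_template_and_orders_by_strength(self):
        p = RateParams()
        base = default_network(p, max_nuclearity=40, targets=(36,))
        means = {}
        for kb in (0.0, 2.0, 10.0):
            net = extend_with_inhibitor(base, binding_k=kb, release_k=0.0)
            vals = []
            for r in range(12):
                traj = run(net, p, {"Mo1": 300, "I": 100}, horizon=6.0, seed=40 + r)
                half = traj.counts.shape[1] // 2
                vals.append(traj.series("Mo36")[half:].mean())
            means[kb] = np.mean(vals)
        assert means[2.0] < means[0.0]
        assert means[10.0] <= means[2.0]

    def test_negative_constants_rejected(self):
        net = default_network(RateParams(), max_nuclearity=40, targets=(36,))
        with pytest.raises(NetworkError):
            extend_with_inhibitor(net, binding_k=-1.0, release_k=0.0)

    def test_mass_conservation_with_inhibitor(self):
        p = RateParams()
        net = extend_with_inhibitor(
            default_network(p, max_nuclearity=40, targets=(36,)), 2.0, 1.0
        )
        traj = run(net, p, {"Mo1": 200, "I": 50}, horizon=2.0, seed=1)
        nuc = np.array([sp.nuclearity for sp in net.species])
        masses = traj.mass(nuc)
        assert (masses == masses[0]).all()
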