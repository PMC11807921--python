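"""Registry, dependency ordering and dynamically limited ranges."""

import networkx as nx
import numpy as np
import pytest

from tavrgen.errors import CycleError, EmptyRangeError, RangeError
from tavrgen.features import FeatureName as F
from tavrgen.parameter_space import (
    AnatomicalParameter,
    ConstraintRule,
    ParameterRegistry,
    default_registry,
    effective_range,
    validate_patient,
)


def neutral_values(registry):
    """All features at the lower end of their implemented ranges."""
    return {f: registry[f].implemented_range[0] for f in registry.features}


class TestDependencyOrder:
    def test_agrees_with_networkx_topological_oracle(self, registry):
        order = registry.dependency_order()
        pos = {f: i for i, f in enumerate(order)}
        g = nx.DiGraph()
        g.add_nodes_from(registry.features)
        for p in registry:
            for dep in p.depends_on:
                g.add_edge(dep, p.feature)
        assert set(order) == set(registry.features)
        # oracle: every edge respected (any valid topological order does)
        assert all(pos[a] < pos[b] for a, b in g.edges)
        assert nx.is_directed_acyclic_graph(g)

    def test_independent_parameters_occupy_a_prefix(self, registry):
        order = registry.dependency_order()
        independent = {f for f in registry.features if not registry[f].depends_on}
        prefix = set(order[: len(independent)])
        assert prefix == independent
        assert {F.AORTA_DIAMETER, F.ST_HEIGHT, F.VALVE_DIAMETER} <= prefix

    def test_valve_diameter_precedes_effective_height(self, registry):
        order = registry.dependency_order()
        assert order.index(F.VALVE_DIAMETER) < order.index(
            F.LEAFLET_EFFECTIVE_HEIGHT_LEFT
        )

    def test_cycle_rejected_with_cycle_listed(self):
        params = [
            AnatomicalParameter(F.AORTA_DIAMETER, "mm", (18.0, 32.0),
                                depends_on=(F.VALVE_DIAMETER,)),
            AnatomicalParameter(F.VALVE_DIAMETER, "mm", (18.1, 28.2),
                                depends_on=(F.AORTA_DIAMETER,)),
        ]
        with pytest.raises(CycleError, match="aorta_diameter"):
            ParameterRegistry(params)


class TestEffectiveRange:
    def test_independent_feature_with_any_context_keeps_full_range(self, registry):
        assert effective_range(F.ST_HEIGHT, {}) == (17.3, 23.3)
        assert effective_range(
            F.ST_HEIGHT, {F.VALVE_DIAMETER: 28.2}
        ) == (17.3, 23.3)

    def test_st_junction_rule_caps_valve_by_aorta(self, registry):
        # a narrower ST junction (continuous with the aortic base) than the
        # valve is prevented: valve upper bound == aorta diameter
        lo, hi = effective_range(F.VALVE_DIAMETER, {F.AORTA_DIAMETER: 25.0})
        assert hi == pytest.approx(25.0)
        assert lo == pytest.approx(18.1)

    def test_va_height_lower_bound_is_largest_effective_height(self, registry):
        ctx = {
            F.VALVE_DIAMETER: 28.2,
            F.LEAFLET_EFFECTIVE_HEIGHT_LEFT: 9.0,
            F.LEAFLET_EFFECTIVE_HEIGHT_RIGHT: 10.0,
            F.LEAFLET_EFFECTIVE_HEIGHT_NON: 12.0,
        }
        lo, hi = effective_range(F.VA_HEIGHT, ctx)
        # oracle: the bound is max(implemented lo, max effective height)
        assert lo == pytest.approx(max(7.6, max(9.0, 10.0, 12.0)))
        assert hi <= 18.9

    def test_missing_dependency_context_rejected_by_name(self, registry):
        with pytest.raises(RangeError, match="valve_diameter"):
            effective_range(F.RCA_DISTANCE, {F.ST_HEIGHT: 20.0})

    def test_always_subset_of_implemented_range(self, registry):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            ctx = {}
            for f in registry.dependency_order():
                lo, hi = registry[f].implemented_range
                ctx[f] = float(rng.uniform(lo, hi))
            for f in registry.features:
                lo, hi = registry.effective_range(f, ctx)
                impl_lo, impl_hi = registry[f].implemented_range
                assert impl_lo <= lo <= hi <= impl_hi

    def test_increasing_valve_never_lowers_st_junction_bound(self, registry):
        # monotonicity of the ST rule, stated on the implementation's form:
        # growing the aorta (= ST junction) never lowers the valve cap
        caps = [
            effective_range(F.VALVE_DIAMETER, {F.AORTA_DIAMETER: a})[1]
            for a in np.linspace(18.0, 32.0, 15)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(caps, caps[1:]))

    def test_infeasible_combination_collapses_to_degenerate_point(self, registry):
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = effective_range(F.VALVE_DIAMETER, {F.AORTA_DIAMETER: 18.0})
        assert lo == hi == pytest.approx(18.1)
        with pytest.raises(EmptyRangeError):
            effective_range(
                F.VALVE_DIAMETER, {F.AORTA_DIAMETER: 18.0}, strict=True
            )


class TestValidatePatient:
    def test_neutral_configuration_is_valid(self, registry):
        assert validate_patient(neutral_values(registry)) == []

    def test_generated_patients_always_validate(self, registry):
        from tavrgen.patient_generator import generate_patient

        for seed in range(300):
            record = generate_patient(seed)
            assert validate_patient(record.anatomy_values()) == []

    def test_st_narrower_than_valve_yields_exactly_one_named_violation(
        self, registry
    ):
        # hand-built anatomy that is admissible everywhere except for a
        # valve wider than the ST junction (= the aortic base)
        values = {
            F.AORTA_DIAMETER: 20.0,
            F.VALVE_DIAMETER: 26.0,
            F.ST_HEIGHT: 23.3,
            F.RCA_DISTANCE: 14.0,
            F.LCA_DISTANCE: 4.0,
            F.LEAFLET_EFFECTIVE_HEIGHT_LEFT: 10.0,
            F.LEAFLET_EFFECTIVE_HEIGHT_RIGHT: 10.0,
            F.LEAFLET_EFFECTIVE_HEIGHT_NON: 10.0,
            F.VA_HEIGHT: 14.0,
            F.BASAL_RING_DIAMETER: 15.0,
            F.LEAFLET_CALCIFICATION_LEFT: 0.0,
            F.LEAFLET_CALCIFICATION_RIGHT: 0.0,
            F.LEAFLET_CALCIFICATION_NON: 0.0,
            F.LEAFLET_OPENING_LEFT: 50.0,
            F.LEAFLET_OPENING_RIGHT: 50.0,
            F.LEAFLET_OPENING_NON: 50.0,
        }
        violations = validate_patient(values)
        assert len(violations) == 1
        assert violations[0].feature == F.VALVE_DIAMETER
        assert "st_junction_wider_than_valve" in violations[0].rules

    def test_missing_feature_rejected(self, registry):
        values = neutral_values(registry)
        del values[F.VA_HEIGHT]
        with pytest.raises(RangeError, match="va_height"):
            validate_patient(values)


class TestSerialisation:
    def test_registry_round_trips_through_yaml(self, registry, tmp_path):
        path = tmp_path / "registry.yaml"
        registry.to_yaml(path)
        back = ParameterRegistry.from_yaml(path)
        assert back.features == registry.features
        for f in registry.features:
            assert back[f].implemented_range == registry[f].implemented_range
            assert back[f].depends_on == registry[f].depends_on
        assert len(back.rules) == len(registry.rules)
        ctx = {F.AORTA_DIAMETER: 25.0}
        assert back.effective_range(
            F.VALVE_DIAMETER, ctx
        ) == registry.effective_range(F.VALVE_DIAMETER, ctx)

    def test_modified_ranges_take_effect_after_reload(self, registry, tmp_path):
        import yaml

        path = tmp_path / "registry.yaml"
        registry.to_yaml(path)
        data = yaml.safe_load(path.read_text())
        for p in data["parameters"]:
            if p["feature"] == "aorta_diameter":
                p["implemented_range"] = [20.0, 30.0]
        path.write_text(yaml.safe_dump(data))
        back = ParameterRegistry.from_yaml(path)
        assert back[F.AORTA_DIAMETER].implemented_range == (20.0, 30.0)
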