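import numpy as np
import pytest

from oglcnet.core import incidence_matrix, p_invariants, validate_net
from oglcnet.dynamics import SimulationSettings, readout, simulate
from oglcnet.errors import InterventionError
from oglcnet.interventions import (
    Intervention,
    InterventionPlan,
    apply_intervention,
    apply_plan,
    dose_sweep,
)
from oglcnet.models import build_model

FAST = SimulationSettings(t_end=100.0, n_points=101)


@pytest.fixture(scope="module")
def cancer_net():
    return build_model("cancer_hyperglycemia")


@pytest.fixture(scope="module")
def cancer_traj(cancer_net):
    return simulate(cancer_net, FAST)


class TestApplyIntervention:
    @pytest.mark.parametrize("kind", ["shrna", "bzx", "metformin"])
    def test_returns_new_validating_net(self, cancer_net, kind):
        before = cancer_net.structural_key()
        out = apply_intervention(cancer_net, Intervention(kind))
        assert validate_net(out) == []
        assert cancer_net.structural_key() == before  # input untouched
        assert out.structural_key() != before

    def test_metformin_adds_exactly_one_inhibitory_arc_on_proliferation(
        self, cancer_net
    ):
        out = apply_intervention(cancer_net, Intervention("metformin"))
        inhibitory = [a for a in out.arcs if a.arc_type == "inhibitory"]
        assert len(inhibitory) == 1
        (arc,) = inhibitory
        assert arc.source == "metformin" and arc.target == "proliferate"

    def test_bzx_complex_is_a_dead_end(self, cancer_net):
        out = apply_intervention(cancer_net, Intervention("bzx"))
        assert "ogt_bzx_complex" in out.place_ids
        # nothing consumes the complex: it only ever receives tokens
        assert not any(a.source == "ogt_bzx_complex" for a in out.arcs)

    def test_bzx_stoichiometry_conserves_ogt_plus_complex_flow(self, cancer_net):
        """The sequestration column moves ogt+bzx into the complex 1:1."""
        out = apply_intervention(cancer_net, Intervention("bzx"))
        C = incidence_matrix(out)
        col = C[:, out.transition_ids.index("sequester_ogt")]
        contributions = {
            out.place_ids[i]: col[i] for i in np.flatnonzero(col)
        }
        assert contributions == {
            "ogt": -1.0, "bzx": -1.0, "ogt_bzx_complex": 1.0
        }

    def test_missing_target_place_is_structured_error(self, two_place_cycle):
        with pytest.raises(InterventionError, match="ogt_mrna"):
            apply_intervention(two_place_cycle, Intervention("shrna"))

    def test_unknown_kind_rejected(self):
        with pytest.raises(InterventionError, match="unknown intervention kind"):
            Intervention("aspirin")

    @pytest.mark.parametrize("kind", ["shrna", "bzx", "metformin"])
    def test_null_dose_reproduces_baseline(self, cancer_net, cancer_traj, kind):
        out = apply_intervention(cancer_net, Intervention(kind, dose_tokens=0.0))
        traj = simulate(out, FAST)
        for place in ("ogt", "cell_survival", "akt_active"):
            assert readout(traj, place) == pytest.approx(
                readout(cancer_traj, place), abs=1e-6
            )


class TestApplyPlan:
    def test_empty_plan_is_identity(self, cancer_net):
        out = apply_plan(InterventionPlan("cancer_hyperglycemia"))
        assert out.structural_key() == cancer_net.structural_key()

    def test_combination_contains_both_mechanisms(self):
        out = apply_plan(
            InterventionPlan(
                "cancer_hyperglycemia",
                (Intervention("bzx"), Intervention("metformin")),
            )
        )
        assert "ogt_bzx_complex" in out.place_ids
        assert any(a.arc_type == "inhibitory" for a in out.arcs)

    def test_order_independent_up_to_element_order(self):
        ab = apply_plan(
            InterventionPlan(
                "cancer_hyperglycemia",
                (Intervention("shrna"), Intervention("bzx")),
            )
        )
        ba = apply_plan(
            InterventionPlan(
                "cancer_hyperglycemia",
                (Intervention("bzx"), Intervention("shrna")),
            )
        )
        assert ab.structural_key() == ba.structural_key()

    def test_duplicate_kinds_rejected(self):
        with pytest.raises(InterventionError, match="duplicate"):
            InterventionPlan(
                "cancer_hyperglycemia",
                (Intervention("bzx"), Intervention("bzx")),
            )


class TestMetforminSpecificity:
    def test_ogt_trajectory_unchanged(self, cancer_net, cancer_traj):
        out = apply_intervention(cancer_net, Intervention("metformin"))
        traj = simulate(out, FAST)
        assert np.allclose(traj.column("ogt"), cancer_traj.column("ogt"), atol=1e-7)

    def test_only_survival_changes(self, cancer_net, cancer_traj):
        out = apply_intervention(cancer_net, Intervention("metformin"))
        traj = simulate(out, FAST)
        for place in cancer_net.place_ids:
            if place == "cell_survival":
                assert readout(traj, place) < 0.5 * readout(cancer_traj, place)
            else:
                assert np.allclose(
                    traj.column(place), cancer_traj.column(place), atol=1e-6
                )


class TestDoseSweep:
    def test_bzx_terminal_ogt_strictly_decreasing(self):
        pairs = dose_sweep(
            InterventionPlan("cancer_hyperglycemia"),
            "bzx", [10, 20, 30], "ogt", FAST,
        )
        values = [v for _, v in pairs]
        assert values[0] > values[1] > values[2]

    def test_single_dose_single_pair(self):
        pairs = dose_sweep(
            InterventionPlan("cancer_hyperglycemia"), "bzx", [10], "ogt", FAST
        )
        assert len(pairs) == 1 and pairs[0][0] == 10.0

    def test_inhibitor_gated_source_monotone_in_dose(self):
        """On a minimal net (inhibitor gating a source) the readout is
        non-increasing in dose, the property the drug sweeps rely on."""
        from oglcnet.core import Arc, PetriNet, Place, Transition
        from oglcnet.dynamics import transition_rate
        from oglcnet.core import Marking

        net = PetriNet(
            places=[Place("drug", initial_tokens=0.0), Place("x")],
            transitions=[Transition("src", kind="source"),
                         Transition("dec", kind="sink")],
            arcs=[Arc("src", "x"), Arc("x", "dec"),
                  Arc("drug", "src", weight=5.0, arc_type="inhibitory")],
        )
        rates = [
            transition_rate(net, Marking({"drug": d, "x": 0.0}), "src")
            for d in (0.0, 2.0, 5.0, 10.0, 30.0)
        ]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_rejects_bad_dose_lists(self):
        plan = InterventionPlan("cancer_hyperglycemia")
        with pytest.raises(ValueError):
            dose_sweep(plan, "bzx", [], "ogt", FAST)
        with pytest.raises(ValueError):
            dose_sweep(plan, "bzx", [-1.0], "ogt", FAST)
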