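"""Pathway model: schema validation, closed-form kinetics, conservation,
homogeneity, seeding rules and shipped-model calibration."""

import json
import math

import numpy as np
import pandas as pd
import pytest

from il17sys.data import cscc_model_path, load_table5, psoriasis_model_path
from il17sys.pathway import (
    Edge,
    ModelSchemaError,
    PathwayModel,
    Species,
    apply_initial_values,
    build_odes,
    load_model,
    peak,
    simulate,
    total_mass,
)


def toy(species, edges, disease="toy"):
    return PathwayModel(disease, species, edges)


class TestSchema:
    def test_unknown_species_in_edge(self):
        with pytest.raises(ModelSchemaError, match="unknown species"):
            toy([Species("A", "gene")], [Edge("A", "B", "activation")])

    def test_negative_initial(self):
        with pytest.raises(ModelSchemaError, match="negative"):
            Species("A", "gene", initial=-1.0)

    def test_process_nonzero_initial(self):
        with pytest.raises(ModelSchemaError, match="must start at 0"):
            Species("P", "process", initial=0.5)

    def test_self_loop(self):
        with pytest.raises(ModelSchemaError, match="self-loop"):
            Edge("A", "A", "activation")

    def test_nonpositive_rate(self):
        with pytest.raises(ModelSchemaError, match="k must be"):
            Edge("A", "B", "activation", k=0.0)

    def test_unreachable_process(self):
        with pytest.raises(ModelSchemaError, match="unreachable"):
            toy([Species("A", "gene"), Species("P", "process", initial=0.0)], [])


class TestShippedModels:
    @pytest.mark.parametrize("path", [psoriasis_model_path(), cscc_model_path()])
    def test_loads_with_three_zero_processes(self, path):
        model = load_model(path)
        assert sorted(model.processes) == [
            "autoimmune_pathology",
            "immunity_extracellular_pathogens",
            "neutrophil_recruitment",
        ]
        assert all(model.get(p).initial == 0.0 for p in model.processes)

    def test_caption_groups_enforced(self):
        model = load_model(psoriasis_model_path())
        model.get("MAPKs").members = ["MAPK1"]
        with pytest.raises(ModelSchemaError, match="figure caption"):
            model.validate()

    @pytest.mark.parametrize("path", [psoriasis_model_path(), cscc_model_path()])
    def test_roundtrip_identity(self, tmp_path, path):
        model = load_model(path)
        model.save(tmp_path / "m.json")
        again = load_model(tmp_path / "m.json")
        assert again.to_dict() == model.to_dict()

    def test_rate_constants_within_band(self):
        for path in (psoriasis_model_path(), cscc_model_path()):
            model = load_model(path)
            assert all(0.25 <= e.k <= 4.0 for e in model.edges)


class TestSeeding:
    def test_grouped_species_take_member_mean(self):
        model = apply_initial_values(load_model(psoriasis_model_path()), load_table5())
        # AP-1 = mean(FOSL1 6.836052, FOS 8.704977)
        assert model.get("AP1").initial == pytest.approx(7.7705145)
        # members absent from the table contribute the 0.5 default
        assert model.get("C2").initial == pytest.approx((0.5 + 5.693991 + 0.5) / 3)

    def test_unmatched_species_get_default(self):
        model = apply_initial_values(load_model(psoriasis_model_path()), load_table5())
        assert model.get("NFKB").initial == 0.5
        assert model.get("TRAF6").initial == 0.5

    def test_empty_table_defaults_everything(self):
        empty = pd.DataFrame(columns=["gene", "disease", "avg_expr"])
        model = apply_initial_values(load_model(psoriasis_model_path()), empty)
        for sp in model.species:
            assert sp.initial == (0.0 if sp.role == "process" else 0.5)

    def test_disease_rows_filtered(self):
        model = apply_initial_values(load_model(cscc_model_path()), load_table5())
        assert model.get("TNF").initial == pytest.approx(3.775442)
        assert model.get("MAPKs").initial == pytest.approx(
            (7.049278 + 4.239504 + 4.192857 + 4.413777 + 5.104123) / 5)


class TestKinetics:
    def test_single_conversion_closed_form(self):
        m = toy([Species("X", "gene", initial=2.0), Species("Y", "process", initial=0.0)],
                [Edge("X", "Y", "activation", 1.0)])
        tr = simulate(m, t_end=5.0)
        expected = 2.0 * (1.0 - np.exp(-tr.times))
        assert np.allclose(tr["Y"], expected, atol=1e-6)
        assert np.allclose(total_mass(tr), 2.0, atol=1e-6)

    def test_pure_inhibition_closed_form(self):
        m = toy([Species("I", "inhibitor", initial=1.0), Species("Y", "gene", initial=3.0),
                 Species("P", "process", initial=0.0)],
                [Edge("I", "Y", "inhibition", 1.0), Edge("Y", "P", "activation", 1e-9)])
        # the (negligible-rate) activation edge keeps P reachable
        tr = simulate(m, t_end=5.0)
        assert np.allclose(tr["Y"], 3.0 * np.exp(-tr.times), atol=1e-5)
        assert np.allclose(tr["I"], 1.0, atol=1e-8)

    def test_no_edges_is_constant(self):
        m = toy([Species("A", "gene", initial=1.5)], [])
        tr = simulate(m, t_end=2.0)
        assert np.allclose(tr["A"], 1.5)

    def test_flux_split_preserves_total_outflow(self):
        # two outbound edges with k=1 each still drain X at rate k*[X]
        m = toy([Species("X", "gene", initial=1.0),
                 Species("Y", "process", initial=0.0), Species("Z", "process", initial=0.0)],
                [Edge("X", "Y", "activation", 1.0), Edge("X", "Z", "activation", 1.0)])
        tr = simulate(m, t_end=4.0)
        assert np.allclose(tr["X"], np.exp(-tr.times), atol=1e-6)
        assert np.allclose(tr["Y"], tr["Z"], atol=1e-8)

    def test_zero_initials_stay_zero(self):
        model = load_model(psoriasis_model_path())
        for sp in model.species:
            sp.initial = 0.0
        tr = simulate(model, t_end=3.0)
        assert np.allclose(tr.values, 0.0, atol=1e-12)


class TestInvariants:
    def activation_only(self):
        model = load_model(psoriasis_model_path())
        model.edges = [e for e in model.edges if e.kind == "activation"]
        return apply_initial_values(model, load_table5())

    def test_activation_only_conserves_mass(self):
        tr = simulate(self.activation_only(), rtol=1e-8)
        m = total_mass(tr)
        assert np.allclose(m, m[0], rtol=1e-7)  # within 10*rtol

    def test_homogeneity_in_initial_conditions(self):
        model = self.activation_only()
        doubled = model.copy()
        for sp in doubled.species:
            sp.initial *= 2.0
        tr1, tr2 = simulate(model), simulate(doubled)
        assert np.allclose(2.0 * tr1.values, tr2.values, atol=1e-6)

    @pytest.mark.parametrize("path", [psoriasis_model_path(), cscc_model_path()])
    def test_nonnegative_and_monotone_processes(self, path):
        model = apply_initial_values(load_model(path), load_table5())
        tr = simulate(model)
        assert tr.values.min() >= -1e-10
        for p in model.processes:
            y = tr[p]
            assert np.all(np.diff(y) >= -1e-9)

    def test_inhibition_makes_total_mass_nonincreasing(self):
        model = apply_initial_values(load_model(psoriasis_model_path()), load_table5())
        m = total_mass(simulate(model))
        assert np.all(np.diff(m) <= 1e-9)


class TestPeak:
    def test_plateau_onset_of_monotone_curve(self):
        m = toy([Species("X", "gene", initial=2.0), Species("Y", "process", initial=0.0)],
                [Edge("X", "Y", "activation", 1.0)])
        tr = simulate(m, t_end=10.0)
        t_peak, value = peak(tr, "Y")
        assert value == pytest.approx(2.0, rel=1e-3)
        # earliest grid time within 0.5% of the plateau: 2(1-e^-t)=0.995*2
        assert t_peak == pytest.approx(-math.log(0.005), abs=0.05)

    def test_psoriasis_calibration(self):
        model = apply_initial_values(load_model(psoriasis_model_path()), load_table5())
        tr = simulate(model)
        t_peak, value = peak(tr, "autoimmune_pathology")
        assert value == pytest.approx(28.0, rel=0.10)
        assert abs(t_peak - 9.5) <= 1.0

    def test_cscc_calibration(self):
        model = apply_initial_values(load_model(cscc_model_path()), load_table5())
        tr = simulate(model)
        best = max(peak(tr, p)[1] for p in model.processes)
        assert best == pytest.approx(21.0, rel=0.10)
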