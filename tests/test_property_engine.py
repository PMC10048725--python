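"""Replacement-model algebra and influence statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dinucouple.counts import DIMERS, DIMER_INDEX, compose
from dinucouple.null_models import dimer_probs
from dinucouple.property_engine import (
    PropertyModel,
    chromosome_property_value,
    influence_significance,
    influences_frame,
    large_influence_table,
    load_property_table,
    property_influences,
    replacement_delta,
    replacement_value,
    write_property_table,
)
from dinucouple.synthetic_data import SyntheticGenomeSpec, generate_genomes, generate_property_fixture


def indicator(dimer):
    values = np.zeros(16)
    values[DIMER_INDEX[dimer]] = 1.0
    return PropertyModel(id=99, name=f"{dimer}_indicator", values=values)


finite_models = st.lists(
    st.floats(-100, 100, allow_nan=False), min_size=16, max_size=16
).map(lambda v: PropertyModel(id=1, name="h", values=np.array(v)))


class TestLoadPropertyTable:
    def test_round_trip(self, tmp_path):
        models = generate_property_fixture(4, seed=0)
        path = tmp_path / "props.tsv"
        write_property_table(models, path)
        loaded = load_property_table(path)
        assert len(loaded) == 4
        for a, b in zip(models, loaded):
            assert a.id == b.id and a.name == b.name
            np.testing.assert_allclose(a.values, b.values)

    def test_missing_dimer_column_named(self, tmp_path):
        frame = pd.DataFrame({"id": [1], "name": ["x"], **{d: [0.0] for d in DIMERS}})
        frame = frame.drop(columns=["CG"])
        path = tmp_path / "bad.tsv"
        frame.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="CG"):
            load_property_table(path)

    def test_duplicated_id_errors(self, tmp_path):
        frame = pd.DataFrame(
            {"id": [1, 1], "name": ["x", "y"], **{d: [0.0, 1.0] for d in DIMERS}}
        )
        path = tmp_path / "dup.tsv"
        frame.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="duplicated"):
            load_property_table(path)

    def test_non_numeric_errors(self, tmp_path):
        frame = pd.DataFrame({"id": [1], "name": ["x"], **{d: ["?"] for d in DIMERS}})
        path = tmp_path / "nan.tsv"
        frame.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="non-numeric"):
            load_property_table(path)


class TestChromosomePropertyValue:
    def test_zero_model(self, acacaca):
        model = PropertyModel(id=1, name="zero", values=np.zeros(16))
        assert chromosome_property_value(model, acacaca.dimer_fractions) == 0.0

    def test_indicator_on_homopolymer(self, record_factory):
        comp = compose(record_factory("A" * 20))
        assert chromosome_property_value(indicator("AA"), comp.dimer_fractions) == 1.0

    def test_indicator_fraction(self, acacaca):
        assert chromosome_property_value(indicator("AC"), acacaca.dimer_fractions) == pytest.approx(0.5)


class TestReplacementValue:
    def test_homopolymer_replacement_changes_nothing(self, record_factory):
        comp = compose(record_factory("A" * 20))
        p = dimer_probs(comp.mono_counts)
        table = replacement_value(indicator("AA"), comp.dimer_fractions, p)
        row = table[table["dimer"] == "AA"].iloc[0]
        assert row["v_xy"] == pytest.approx(1.0)
        assert row["v_random"] == pytest.approx(1.0)
        assert row["delta"] == pytest.approx(0.0)

    def test_acacaca_hand_value(self, acacaca):
        # c_AC = 0.5, p_AC = (4/7)(3/7): delta = 0.5 (1 - 12/49) ~ 0.3776
        p = dimer_probs(acacaca.mono_counts)
        table = replacement_value(indicator("AC"), acacaca.dimer_fractions, p)
        delta = table.set_index("dimer").loc["AC", "delta"]
        assert delta == pytest.approx(0.5 * (1 - 12 / 49))
        assert delta == pytest.approx(0.37755102)

    @settings(derandomize=True, max_examples=30)
    @given(finite_models, st.floats(-50, 50, allow_nan=False))
    def test_shift_invariance(self, model, k):
        fractions = np.full(16, 1 / 16)
        p = np.full(16, 1 / 16)
        shifted = PropertyModel(id=2, name="s", values=model.values + k)
        np.testing.assert_allclose(
            replacement_delta(model, fractions, p),
            replacement_delta(shifted, fractions, p),
            atol=1e-9,
        )

    @settings(derandomize=True, max_examples=30)
    @given(finite_models, st.floats(-10, 10, allow_nan=False))
    def test_scale_equivariance(self, model, a):
        fractions = np.linspace(0, 1, 16)
        fractions /= fractions.sum()
        p = np.full(16, 1 / 16)
        scaled = PropertyModel(id=3, name="a", values=a * model.values)
        np.testing.assert_allclose(
            replacement_delta(scaled, fractions, p),
            a * replacement_delta(model, fractions, p),
            atol=1e-9,
        )

    def test_four_term_equals_closed_form(self, acacaca):
        rng = np.random.default_rng(20)
        model = PropertyModel(id=4, name="r", values=rng.normal(size=16))
        for kind in ("binomial", "chargaff"):
            p = dimer_probs(acacaca.mono_counts, kind)
            table = replacement_value(model, acacaca.dimer_fractions, p)
            np.testing.assert_allclose(
                table["delta"].to_numpy(),
                replacement_delta(model, acacaca.dimer_fractions, p),
                rtol=0, atol=1e-14,
            )

    def test_model_fractions_give_zero_delta(self):
        rng = np.random.default_rng(21)
        model = PropertyModel(id=5, name="r", values=rng.normal(size=16))
        p = rng.dirichlet(np.ones(16))
        # replacing model-random content with model-random content: only
        # the dimer's own mismatch term remains; at c = p the aggregate
        # V_E equals sum M p, so the total delta across dimers vanishes
        deltas = replacement_delta(model, p, p)
        assert deltas.sum() == pytest.approx(0.0, abs=1e-12)


class TestInfluenceSignificance:
    def _aggregate(self, deltas, values):
        model = PropertyModel(id=7, name="m", values=np.zeros(16))
        return influence_significance(model, deltas, values)

    def test_identical_nonzero_deltas_unbounded(self):
        deltas = np.tile(np.linspace(-1, 1, 16), (5, 1))
        out = self._aggregate(deltas, np.ones(5))
        nonzero = [i for i in out if i.mean_delta != 0]
        assert all(math.isinf(i.significance) for i in nonzero)
        assert all(i.significant for i in nonzero)

    def test_symmetric_deltas_insignificant(self):
        deltas = np.zeros((4, 16))
        deltas[0] = 1.0
        deltas[1] = -1.0
        deltas[2] = 0.5
        deltas[3] = -0.5
        out = self._aggregate(deltas, np.ones(4))
        assert all(i.significance == pytest.approx(0.0) for i in out)
        assert not any(i.significant for i in out)

    def test_requires_three_chromosomes(self):
        with pytest.raises(ValueError):
            self._aggregate(np.zeros((2, 16)), np.ones(2))

    def test_planted_excess_flagged_significant_and_large(self):
        spec = SyntheticGenomeSpec(
            chromosomes_per_genome=10, length=20_000,
            dimer_excess={"AA": 0.02}, seed=22,
        )
        comps = [compose(r) for r in generate_genomes(spec)]
        influences = property_influences(comps, [indicator("AA")])
        inf = next(i for i in influences if i.dimer == "AA")
        assert inf.significant and inf.large and inf.sign > 0


class TestLargeInfluenceTable:
    def test_empty_when_nothing_passes(self):
        comps_spec = SyntheticGenomeSpec(chromosomes_per_genome=5, length=20_000, seed=23)
        comps = [compose(r) for r in generate_genomes(comps_spec)]
        constant = PropertyModel(id=1, name="constant", values=np.ones(16))
        table = large_influence_table(property_influences(comps, [constant]))
        assert table.empty

    def test_boundary_relative_change_retained(self):
        from dinucouple.property_engine import PropertyInfluence

        inf = PropertyInfluence(
            property_id=1, property_name="m", dimer="AA",
            mean_delta=0.1, std_delta=0.01, significance=10.0,
            mean_value=1.0, relative_change=0.10,
        )
        table = large_influence_table([inf])
        assert list(table["positive"]) == ["AA"]

    def test_planted_scenario_single_row(self):
        spec = SyntheticGenomeSpec(
            chromosomes_per_genome=10, length=20_000,
            dimer_excess={"AA": 0.02}, seed=24,
        )
        comps = [compose(r) for r in generate_genomes(spec)]
        roll_like = indicator("AA")
        table = large_influence_table(property_influences(comps, [roll_like]))
        assert len(table) == 1
        assert "AA" in table.iloc[0]["positive"].split()


def test_influences_frame_has_flags():
    spec = SyntheticGenomeSpec(chromosomes_per_genome=5, length=15_000, seed=25)
    comps = [compose(r) for r in generate_genomes(spec)]
    frame = influences_frame(property_influences(comps, generate_property_fixture(3)))
    assert {"significant", "large", "mean_delta", "relative_change"} <= set(frame.columns)
    # constant model: all deltas vanish (to float precision)
    const = frame[frame["property_id"] == 1]
    assert np.allclose(const["mean_delta"], 0, atol=1e-12)
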