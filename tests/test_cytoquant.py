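"""Quantity formulas, binning, normalization, Strahler stratification, SYN calls."""

import numpy as np
import pandas as pd
import pytest

from dendroquant import errors
from dendroquant.cytoquant import (
    QuantityProfile,
    bin_by_path_distance,
    classify_syn_positive,
    compartment_quantities,
    compartment_quantity,
    denmark_quantity,
    normalize_cohort,
    peak_intensity_distance,
    quantity_by_strahler,
    syn_intensity,
    total_quantity,
)

from conftest import make_arbor, random_tree, uniform_signals
from oracles import quantity_bruteforce


class TestFormulas:
    def test_direct_product(self):
        assert compartment_quantity(I=2, F=0.5, D=1, L=10) == pytest.approx(10.0)

    def test_zero_fraction_annihilates(self):
        assert compartment_quantity(I=9, F=0.0, D=3, L=100) == 0.0

    def test_denmark_equals_qc_for_identical_inputs(self):
        assert denmark_quantity(1, 1, 2, 5) == pytest.approx(10.0)
        assert denmark_quantity(1.3, 0.4, 2.0, 7.0) == compartment_quantity(
            1.3, 0.4, 2.0, 7.0
        )

    def test_syn_intensity_is_length_independent(self):
        assert syn_intensity(I=2, F=0.5, D=1) == pytest.approx(1.0)
        # doubling L changes Q_c but not SYN_i
        assert compartment_quantity(2, 0.5, 1, 20) == 2 * compartment_quantity(
            2, 0.5, 1, 10
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(errors.ParameterError):
            compartment_quantity(-1, 0.5, 1, 1)
        with pytest.raises(errors.ParameterError):
            syn_intensity(1, 1.5, 1)


class TestPerArborQuantities:
    def test_uniform_signal_reduces_to_half_DL(self, bifurcation_arbor):
        arbor = uniform_signals(bifurcation_arbor, I=1.0, F=0.5)
        df = compartment_quantities(arbor, "MT")
        assert np.allclose(df["Q"], 0.5 * df["diameter_um"] * df["length_um"])

    def test_total_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        arbor = random_tree(rng, 40)
        sig = [
            (int(n), "MT", float(rng.uniform(0, 2)), float(rng.uniform(0, 1)))
            for n in arbor.nodes["node_id"]
        ]
        arbor = make_arbor(
            list(arbor.nodes.itertuples(index=False, name=None)), signals=sig
        )
        assert total_quantity(arbor, "MT") == pytest.approx(
            quantity_bruteforce(arbor, "MT"), rel=1e-9
        )

    def test_compartments_without_signal_are_excluded(self, chain_arbor):
        # signal only at node 2: the edge 2-1 and 2-3 both see one endpoint
        arbor = make_arbor(
            list(chain_arbor.nodes.itertuples(index=False, name=None)),
            signals=[(2, "MT", 1.0, 0.5)],
        )
        df = compartment_quantities(arbor, "MT")
        assert set(df.index) == {2, 3}
        arbor = make_arbor(
            list(chain_arbor.nodes.itertuples(index=False, name=None)),
            signals=[(1, "MT", 1.0, 0.5)],
        )
        df = compartment_quantities(arbor, "MT")
        assert set(df.index) == {2}  # edge 3-2 has no signal at either endpoint

    def test_intensity_scale_equivariance(self):
        rng = np.random.default_rng(5)
        base = random_tree(rng, 30)
        sig1 = [
            (int(n), "MT", float(rng.uniform(0.1, 2)), float(rng.uniform(0.1, 1)))
            for n in base.nodes["node_id"]
        ]
        c = 3.7
        sig2 = [(n, ch, c * I, F) for n, ch, I, F in sig1]
        rows = list(base.nodes.itertuples(index=False, name=None))
        t1 = total_quantity(make_arbor(rows, signals=sig1), "MT")
        t2 = total_quantity(make_arbor(rows, signals=sig2), "MT")
        assert t2 == pytest.approx(c * t1, rel=1e-12)


class TestBinning:
    def _line_arbor(self, xs):
        rows = [(1, 1, 0.0, 0.0, 0.0, 1.0, -1)]
        for k, x in enumerate(xs, start=2):
            rows.append((k, 3, float(x), 0.0, 0.0, 0.5, k - 1))
        return uniform_signals(make_arbor(rows), I=1.0, F=0.5)

    def test_midpoint_35_goes_to_bin_zero(self):
        arbor = self._line_arbor([70.0])  # single edge, midpoint 35
        prof = bin_by_path_distance(arbor, "MT", 40.0)
        assert len(prof.values) == 1 and prof.values[0] > 0

    def test_midpoint_exactly_40_goes_to_bin_one(self):
        arbor = self._line_arbor([80.0])  # midpoint exactly 40
        prof = bin_by_path_distance(arbor, "MT", 40.0)
        assert len(prof.values) == 2
        assert prof.values[0] == 0.0 and prof.values[1] > 0

    def test_bin_sums_conserve_total(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            arbor = random_tree(rng, int(rng.integers(10, 60)))
            sig = [
                (int(n), "MT", float(rng.uniform(0, 2)), float(rng.uniform(0, 1)))
                for n in arbor.nodes["node_id"]
            ]
            arbor = make_arbor(
                list(arbor.nodes.itertuples(index=False, name=None)), signals=sig
            )
            prof = bin_by_path_distance(arbor, "MT", 15.0)
            assert prof.total == pytest.approx(total_quantity(arbor, "MT"), rel=1e-9)

    def test_negative_bin_width_rejected(self, chain_arbor):
        with pytest.raises(errors.ParameterError):
            bin_by_path_distance(uniform_signals(chain_arbor), "MT", -1.0)


class TestNormalization:
    def _profile(self, total, group):
        return QuantityProfile(
            channel="MT", bin_width=40.0, values=np.array([total]), group=group
        )

    def test_factor_is_inverse_control_mean(self):
        profiles = [self._profile(2, "ctl"), self._profile(4, "ctl"), self._profile(1.5, "mut")]
        normed, factor = normalize_cohort(profiles, "ctl")
        assert factor == pytest.approx(1 / 3)
        assert normed[2].total == pytest.approx(0.5)
        ctl_mean = np.mean([p.total for p in normed if p.group == "ctl"])
        assert ctl_mean == pytest.approx(1.0, abs=1e-12)

    def test_double_normalization_refused(self):
        normed, _ = normalize_cohort([self._profile(2, "ctl")], "ctl")
        with pytest.raises(errors.NormalizationError, match="already"):
            normalize_cohort(normed, "ctl")

    def test_zero_control_mean_is_error(self):
        with pytest.raises(errors.NormalizationError, match="zero"):
            normalize_cohort([self._profile(0.0, "ctl")], "ctl")

    def test_missing_control_group_is_error(self):
        with pytest.raises(errors.NormalizationError):
            normalize_cohort([self._profile(1.0, "mut")], "ctl")

    def test_normalization_removes_intensity_scale(self):
        # multiplying all intensities by c leaves normalized outputs unchanged
        for c in (1.0, 5.0):
            profiles = [
                self._profile(2 * c, "ctl"),
                self._profile(4 * c, "ctl"),
                self._profile(1.5 * c, "mut"),
            ]
            normed, _ = normalize_cohort(profiles, "ctl")
            assert normed[2].total == pytest.approx(0.5)


class TestStrahlerStratification:
    def test_bifurcation_split(self, bifurcation_arbor):
        arbor = uniform_signals(bifurcation_arbor, I=1.0, F=0.5)
        table = quantity_by_strahler(arbor, "MT")
        df = compartment_quantities(arbor, "MT")
        assert table.loc[1, "quantity"] == pytest.approx(
            float(df.loc[[3, 4], "Q"].sum())
        )
        assert table.loc[2, "quantity"] == pytest.approx(float(df.loc[2, "Q"]))

    def test_uniform_signal_constant_per_order_length(self, bifurcation_arbor):
        # uniform I*F and uniform D make quantity/length identical across orders
        rows = [(i, c, x, y, z, 0.5, p) for i, c, x, y, z, _r, p in
                bifurcation_arbor.nodes.itertuples(index=False, name=None)]
        arbor = uniform_signals(make_arbor(rows), I=2.0, F=0.5)
        table = quantity_by_strahler(arbor, "MT", mode="per_order_length")
        assert np.allclose(table["per_length"], 2.0 * 0.5 * 1.0)  # I*F*D

    def test_order_sums_conserve_total(self):
        rng = np.random.default_rng(31)
        arbor = random_tree(rng, 50)
        sig = [
            (int(n), "MT", float(rng.uniform(0, 2)), float(rng.uniform(0, 1)))
            for n in arbor.nodes["node_id"]
        ]
        arbor = make_arbor(
            list(arbor.nodes.itertuples(index=False, name=None)), signals=sig
        )
        table = quantity_by_strahler(arbor, "MT")
        assert float(table["quantity"].sum()) == pytest.approx(
            total_quantity(arbor, "MT"), rel=1e-9
        )

    def test_unknown_mode_rejected(self, chain_arbor):
        with pytest.raises(errors.ParameterError):
            quantity_by_strahler(uniform_signals(chain_arbor), "MT", mode="per_branch")


class TestPeak:
    def _profile(self, values):
        return QuantityProfile(channel="F-actin", bin_width=40.0, values=np.array(values))

    def test_peak_bin_midpoint(self):
        assert peak_intensity_distance(self._profile([1, 5, 2])) == pytest.approx(60.0)

    def test_tie_breaks_toward_soma(self):
        assert peak_intensity_distance(self._profile([5, 5])) == pytest.approx(20.0)

    def test_all_zero_profile_is_error(self):
        with pytest.raises(errors.ParameterError):
            peak_intensity_distance(self._profile([0.0, 0.0]))


class TestSynClassification:
    def _table(self, syn, structure, diameter=None, ids=None):
        n = len(syn)
        return pd.DataFrame(
            {
                "syn_i": syn,
                "structure": structure,
                "diameter_um": diameter if diameter is not None else np.ones(n),
            },
            index=ids if ids is not None else range(1, n + 1),
        )

    def test_ten_distinct_gives_one_positive(self):
        syn = list(range(1, 11))
        structure = ["dendrite"] * 9 + ["axon"]  # the max (10) sits on the axon
        cls = classify_syn_positive(self._table(syn, structure))
        assert len(cls.positive_ids) == 1
        assert cls.p_axon == pytest.approx(1.0)  # 1 positive / 1 axonal compartment
        assert cls.p_dendrite == 0.0

    def test_twenty_all_dendritic(self):
        syn = list(range(20))
        cls = classify_syn_positive(self._table(syn, ["dendrite"] * 20))
        assert len(cls.positive_ids) == 2
        assert cls.p_dendrite == pytest.approx(0.1)

    @pytest.mark.parametrize("n,expected", [(10, 1), (20, 2), (95, 10), (100, 10)])
    def test_count_is_ceiling_of_ten_percent(self, n, expected):
        rng = np.random.default_rng(n)
        cls = classify_syn_positive(
            self._table(rng.uniform(0.1, 1, n), ["dendrite"] * n)
        )
        assert len(cls.positive_ids) == expected

    def test_ties_broken_by_diameter_then_id(self):
        syn = [5.0] * 10
        diam = [1, 1, 1, 1, 1, 1, 1, 1, 2, 1]
        cls = classify_syn_positive(self._table(syn, ["dendrite"] * 10, diam))
        assert cls.positive_ids == [9]  # the largest diameter wins
        cls = classify_syn_positive(self._table(syn, ["dendrite"] * 10))
        assert cls.positive_ids == [1]  # then the lowest id

    def test_all_zero_intensities_warns(self):
        with pytest.warns(UserWarning, match="zero"):
            cls = classify_syn_positive(self._table([0.0] * 12, ["dendrite"] * 12))
        assert cls.positive_ids == [] and cls.p_dendrite == 0.0

    def test_too_few_compartments_rejected(self):
        with pytest.raises(errors.ParameterError):
            classify_syn_positive(self._table([1.0] * 5, ["dendrite"] * 5))
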