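"""Scaling, module aggregation and proxy selection from OTU tables."""

import numpy as np
import pandas as pd
import pytest

from rumen_observer import tables
from rumen_observer.proxy_inference import (
    ModuleAbundances,
    ScalingError,
    aggregate_modules,
    compute_size_factors,
    scale_counts,
    select_vfa_proxies,
    sum_phases,
)
from rumen_observer.types import GeneContentProfile, ModuleCatalog, OTUTable


def make_table(counts, times=None):
    counts = pd.DataFrame(
        counts,
        index=[f"otu{i}" for i in range(len(counts))],
        columns=[f"s{j}" for j in range(len(counts[0]))],
    )
    times = times if times is not None else list(range(len(counts.columns)))
    return OTUTable(counts=counts, sample_times=pd.Series(times, index=counts.columns, dtype=float))


class TestSizeFactors:
    def test_identical_columns_are_identity(self):
        factors = compute_size_factors(make_table([[10, 10], [3, 3]]))
        assert factors.values == pytest.approx([1.0, 1.0])

    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([[10, 20], [30, 60]], [1 / np.sqrt(2), np.sqrt(2)]),
            ([[5, 10, 20]], [0.5, 1.0, 2.0]),  # geometric mean 10
        ],
    )
    def test_median_of_ratios_hand_computed(self, counts, expected):
        assert compute_size_factors(make_table(counts)).values == pytest.approx(expected)

    def test_zero_containing_otus_excluded_from_reference(self):
        # otu1 has a zero; factors must come from otu0 alone
        factors = compute_size_factors(make_table([[10, 20], [0, 100]]))
        assert factors.values == pytest.approx([1 / np.sqrt(2), np.sqrt(2)])

    def test_no_all_positive_otu_is_an_error(self):
        with pytest.raises(ScalingError):
            compute_size_factors(make_table([[0, 5], [7, 0]]))

    def test_matches_deseq2_reference_implementation(self):
        """Cross-check against pydeseq2's median-of-ratios size factors."""
        anndata = pytest.importorskip("anndata")
        from pydeseq2.dds import DeseqDataSet

        rng = np.random.default_rng(42)
        counts = rng.poisson(rng.uniform(5, 200, size=(30, 1)) * rng.uniform(0.5, 2, size=(1, 8))) + 1
        table = make_table(counts.tolist())
        ours = compute_size_factors(table)

        adata = anndata.AnnData(X=counts.T.astype(np.float64))
        adata.obs["condition"] = "a"
        dds = DeseqDataSet(adata=adata, design="~1")
        dds.fit_size_factors()
        # pydeseq2 computes the reference log-means in single precision
        assert ours.values == pytest.approx(dds.obs["size_factors"].values, rel=1e-4)


class TestScaleCounts:
    def test_unit_factors_are_identity(self):
        table = make_table([[10, 20], [30, 60]])
        ones = pd.Series(1.0, index=table.sample_ids)
        pd.testing.assert_frame_equal(scale_counts(table, ones), table.counts.astype(float))

    def test_division_and_zero_preservation(self):
        table = make_table([[60, 0]])
        factors = pd.Series([np.sqrt(2), 1.0], index=table.sample_ids)
        scaled = scale_counts(table, factors)
        assert scaled.iloc[0, 0] == pytest.approx(60 / np.sqrt(2))  # 42.43
        assert scaled.iloc[0, 1] == 0.0

    def test_missing_factor_rejected(self):
        table = make_table([[1, 2], [3, 4]])
        with pytest.raises(ValueError, match="no size factor"):
            scale_counts(table, pd.Series([1.0], index=["s0"]))


def profile(rows: dict) -> GeneContentProfile:
    return GeneContentProfile(pd.DataFrame(rows).T.fillna(0.0))


class TestAggregateModules:
    times = pd.Series([0.0, 1.0], index=["s0", "s1"])

    def test_single_product(self):
        scaled = pd.DataFrame([[10.0, 10.0]], index=["otu0"], columns=["s0", "s1"])
        genes = profile({"otu0": {"k1": 2.0}})
        out = aggregate_modules(scaled, genes, ModuleCatalog({"M1": frozenset({"k1"})}), self.times)
        assert out.abundances.loc["M1"].values == pytest.approx([20.0, 20.0])

    def test_weighted_sum_over_otus(self):
        scaled = pd.DataFrame([[10.0], [5.0]], index=["otu0", "otu1"], columns=["s0"])
        genes = profile({"otu0": {"k1": 1.0}, "otu1": {"k1": 3.0}})
        out = aggregate_modules(
            scaled, genes, ModuleCatalog({"M1": frozenset({"k1"})}), self.times.iloc[:1]
        )
        assert out.abundances.loc["M1", "s0"] == pytest.approx(25.0)

    def test_module_without_present_kos_is_zero(self):
        scaled = pd.DataFrame([[10.0, 3.0]], index=["otu0"], columns=["s0", "s1"])
        genes = profile({"otu0": {"k1": 2.0}})
        out = aggregate_modules(scaled, genes, ModuleCatalog({"M9": frozenset({"kX"})}), self.times)
        assert (out.abundances.loc["M9"] == 0).all()

    def test_empty_overlap_is_an_error(self):
        scaled = pd.DataFrame([[1.0]], index=["otuA"], columns=["s0"])
        genes = profile({"otuB": {"k1": 1.0}})
        with pytest.raises(ValueError, match="no overlap"):
            aggregate_modules(scaled, genes, ModuleCatalog({"M1": frozenset({"k1"})}), self.times)

    def test_unmapped_otus_reported(self):
        scaled = pd.DataFrame([[3.0], [1.0]], index=["otu0", "ghost"], columns=["s0"])
        genes = profile({"otu0": {"k1": 1.0}})
        with pytest.warns(UserWarning, match="absent from the gene-content"):
            out = aggregate_modules(
                scaled, genes, ModuleCatalog({"M1": frozenset({"k1"})}), self.times.iloc[:1]
            )
        assert out.unmapped_otus == ("ghost",)
        assert out.unmapped_fraction == pytest.approx(0.25)

    def test_linear_in_scaled_abundance(self):
        rng = np.random.default_rng(5)
        scaled = pd.DataFrame(rng.uniform(0, 50, (4, 3)),
                              index=[f"otu{i}" for i in range(4)],
                              columns=["s0", "s1", "s2"])
        genes = profile({f"otu{i}": {"k1": rng.uniform(0, 3), "k2": rng.uniform(0, 3)} for i in range(4)})
        cat = ModuleCatalog({"M1": frozenset({"k1", "k2"})})
        t = pd.Series([0.0, 1.0, 2.0], index=scaled.columns)
        once = aggregate_modules(scaled, genes, cat, t).abundances
        twice = aggregate_modules(2 * scaled, genes, cat, t).abundances
        pd.testing.assert_frame_equal(twice, 2 * once)

    def test_additive_over_disjoint_ko_sets(self):
        rng = np.random.default_rng(6)
        scaled = pd.DataFrame(rng.uniform(0, 50, (3, 2)),
                              index=["otu0", "otu1", "otu2"], columns=["s0", "s1"])
        genes = profile({o: {k: rng.uniform(0, 2) for k in ("k1", "k2", "k3")} for o in scaled.index})
        t = pd.Series([0.0, 1.0], index=scaled.columns)
        cat = ModuleCatalog({
            "A": frozenset({"k1"}), "B": frozenset({"k2", "k3"}),
            "AB": frozenset({"k1", "k2", "k3"}),
        })
        out = aggregate_modules(scaled, genes, cat, t).abundances
        assert out.loc["AB"].values == pytest.approx((out.loc["A"] + out.loc["B"]).values)


def modules_from(values, times, module_ids=("M00579", "M99999", "M00013")):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    cols = [f"s{j}" for j in range(values.shape[1])]
    return ModuleAbundances(
        abundances=pd.DataFrame(values, index=list(module_ids), columns=cols),
        sample_times=pd.Series(times, index=cols, dtype=float),
        unmapped_otus=(),
        unmapped_fraction=0.0,
    )


class TestSumPhases:
    def test_zero_solid_is_identity(self):
        liq = modules_from(np.arange(6).reshape(3, 2), [0, 1])
        sol = modules_from(np.zeros((3, 2)), [0, 1])
        combined = sum_phases(liq, sol)
        pd.testing.assert_frame_equal(combined.abundances, liq.abundances)

    def test_elementwise_addition(self):
        liq = modules_from([[20000.0]], [2.0], ["M00579"])
        sol = modules_from([[13139.0]], [2.0], ["M00579"])
        assert sum_phases(liq, sol).abundances.iloc[0, 0] == pytest.approx(33139.0)

    def test_mismatched_grids_rejected(self):
        liq = modules_from(np.ones((3, 2)), [0, 1])
        sol = modules_from(np.ones((3, 2)), [0, 2])
        with pytest.raises(ValueError, match="time grids differ"):
            sum_phases(liq, sol)

    def test_commutes_with_proxy_selection(self):
        rng = np.random.default_rng(8)
        liq = modules_from(rng.uniform(0, 1e4, (3, 4)), [2, 4, 8, 24])
        sol = modules_from(rng.uniform(0, 1e4, (3, 4)), [2, 4, 8, 24])
        summed_first = select_vfa_proxies(sum_phases(liq, sol))
        selected_first = {
            v: select_vfa_proxies(liq)[v].values + select_vfa_proxies(sol)[v].values
            for v in summed_first
        }
        for v, series in summed_first.items():
            assert series.values == pytest.approx(selected_first[v])


class TestSelectVfaProxies:
    def test_reference_invitro_series(self):
        proxies = tables.invitro_proxies("inoculum1_grass")
        assert proxies["acetate"].times.tolist() == [2, 4, 8, 24]
        assert proxies["acetate"].values.tolist() == [33139, 37601, 60680, 70338]

    def test_reference_invivo_value(self):
        proxies = tables.invivo_proxies("cow1")
        assert proxies["propionate"].values[proxies["propionate"].times == 7][0] == 7229

    def test_missing_module_rejected(self):
        mods = modules_from([[1.0]], [0.0], ["M00579"])
        with pytest.raises(KeyError, match="M99999"):
            select_vfa_proxies(mods, {"M00579": "acetate", "M99999": "butyrate"})
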