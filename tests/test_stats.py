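"""Areal metrics, printed-arithmetic identities, ANOVA, post hoc tests."""

import numpy as np
import pandas as pd
import pytest

from myelosurf.geometry import MetricMap, SurfacePair, TriangleMesh, vertex_areas
from myelosurf.parcellation import ParcelLabelMap
from myelosurf.stats import (
    parcel_metrics,
    posthoc_bonferroni,
    relative_fraction,
    summary_report,
    two_way_anova,
)

from conftest import make_icosphere


# Printed per-species relative-area identities: (parcel mean area mm²,
# total cortical area mm², printed percentage).
PRINTED_FRACTIONS = [
    ("MT+", "night_monkey", 47.9, 2030.0, 2.4),
    ("MT+", "macaque", 89.8, 9894.0, 0.9),
    ("MT+", "marmoset", 12.5, 1053.0, 1.2),
    ("AC", "night_monkey", 51.2, 2030.0, 2.5),
    ("AC", "macaque", 57.7, 9894.0, 0.6),
    ("AC", "marmoset", 16.1, 1053.0, 1.5),
    ("BA7", "night_monkey", 45.8, 2030.0, 2.3),
    ("BA7", "macaque", 320.0, 9894.0, 3.2),
    ("BA7", "marmoset", 20.6, 1053.0, 2.0),
    ("V1", "night_monkey", 381.0, 2030.0, 18.8),
    ("V1", "macaque", 1160.0, 9894.0, 11.7),
    ("V1", "marmoset", 215.0, 1053.0, 20.4),
]


def synthetic_table(n_hemis=(64, 18, 40), parcels=("MT+", "AC", "BA7", "V1"), seed=0):
    """A metrics table with the comparative-study hemisphere counts."""
    rng = np.random.default_rng(seed)
    rows = []
    for species, n in zip(("macaque", "night_monkey", "marmoset"), n_hemis):
        for h in range(n):
            for parcel in parcels:
                rows.append(
                    dict(
                        subject_id=f"{species}-{h // 2}",
                        hemisphere="LR"[h % 2],
                        species=species,
                        parcel=parcel,
                        rel_area=rng.normal(0.02, 0.002),
                        mean_thickness_mm=rng.normal(2.0, 0.1),
                        rel_volume=rng.normal(0.02, 0.002),
                    )
                )
    return pd.DataFrame(rows)


class TestRelativeFraction:
    @pytest.mark.parametrize("parcel,species,area,total,printed", PRINTED_FRACTIONS)
    def test_printed_arithmetic_reproduced_exactly(self, parcel, species, area, total, printed):
        assert relative_fraction(area, total) == printed

    def test_full_coverage_is_hundred_percent(self):
        assert relative_fraction(123.4, 123.4) == 100.0

    def test_nonpositive_total_rejected(self):
        with pytest.raises(ValueError):
            relative_fraction(1.0, 0.0)


class TestParcelMetrics:
    def _pair(self):
        base = make_icosphere(3, 10.0)
        outer = TriangleMesh(base.vertices * 1.2, base.faces)
        return SurfacePair(base, outer)

    def test_whole_mesh_parcel_equals_total_area(self):
        pair = self._pair()
        labels = ParcelLabelMap(np.ones(pair.n_vertices, dtype=int), {1: "all"})
        t = parcel_metrics(pair, labels)
        assert t.loc[0, "area_mm2"] == pytest.approx(t.loc[0, "total_area_mm2"], rel=1e-12)
        assert t.loc[0, "rel_area"] == pytest.approx(1.0, abs=1e-12)

    def test_spherical_cap_relative_area_matches_solid_angle(self):
        # cap of colatitude theta has area fraction (1 - cos theta) / 2
        base = make_icosphere(5, 10.0)
        pair = SurfacePair(base, TriangleMesh(base.vertices * 1.01, base.faces))
        cos_theta = 0.8
        labels = ParcelLabelMap(
            (base.vertices[:, 2] / 10.0 > cos_theta).astype(int), {1: "cap"}
        )
        t = parcel_metrics(pair, labels)
        q = (1 - cos_theta) / 2
        assert t.loc[0, "rel_area"] == pytest.approx(q, rel=0.01)

    def test_uniform_thickness_mean_is_exact(self):
        pair = self._pair()
        labels = ParcelLabelMap(
            (pair.white.vertices[:, 0] > 0).astype(int), {1: "half"}
        )
        th = MetricMap(np.full(pair.n_vertices, 1.75))
        t = parcel_metrics(pair, labels, thickness=th)
        assert t.loc[0, "mean_thickness_mm"] == 1.75

    def test_empty_parcel_warns_and_zeroes(self):
        pair = self._pair()
        labels = ParcelLabelMap(np.zeros(pair.n_vertices, dtype=int), {})
        labels.names[1] = "ghost"  # declared but unoccupied
        with pytest.warns(UserWarning, match="ghost"):
            t = parcel_metrics(pair, labels)
        assert t.loc[0, "area_mm2"] == 0.0

    def test_native_space_scaling_leaves_relative_metrics_unchanged(self):
        pair = self._pair()
        labels = ParcelLabelMap(
            (pair.white.vertices[:, 2] > 0).astype(int), {1: "top"}
        )
        s = 1.7
        scaled = SurfacePair(
            TriangleMesh(pair.white.vertices * s, pair.white.faces),
            TriangleMesh(pair.pial.vertices * s, pair.pial.faces),
        )
        t1 = parcel_metrics(pair, labels)
        t2 = parcel_metrics(scaled, labels)
        assert t2.loc[0, "area_mm2"] == pytest.approx(s**2 * t1.loc[0, "area_mm2"], rel=1e-12)
        assert t2.loc[0, "volume_mm3"] == pytest.approx(s**3 * t1.loc[0, "volume_mm3"], rel=1e-12)
        assert t2.loc[0, "rel_area"] == pytest.approx(t1.loc[0, "rel_area"], abs=1e-12)
        assert t2.loc[0, "rel_volume"] == pytest.approx(t1.loc[0, "rel_volume"], abs=1e-12)

    def test_rel_area_sums_below_one(self, night_hemisphere):
        pair, truth = night_hemisphere
        t = parcel_metrics(pair, truth.labels)
        assert t["rel_area"].sum() <= 1.0 + 1e-12


class TestTwoWayAnova:
    def test_comparative_design_interaction_df(self):
        table = synthetic_table()
        res = two_way_anova(table, "rel_area")
        inter = res.anova.set_index("effect").loc["species:parcel"]
        assert (inter.df1, inter.df2) == (6, 476)

    def test_df_identity_holds_for_random_designs(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            ns = tuple(int(n) for n in rng.integers(4, 30, size=3))
            parcels = tuple(f"p{i}" for i in range(rng.integers(2, 5)))
            table = synthetic_table(ns, parcels, seed=int(rng.integers(2**31)))
            res = two_way_anova(table, "rel_area")
            a, b = 3, len(parcels)
            n = len(table)
            assert (res.anova["df2"] == n - a * b).all()
            assert res.anova.set_index("effect").loc["species:parcel", "df1"] == (a - 1) * (b - 1)

    def test_matches_statsmodels_type_iii_oracle(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        table = synthetic_table((10, 7, 5), seed=3)
        res = two_way_anova(table, "rel_area").anova.set_index("effect")
        fit = smf.ols(
            "rel_area ~ C(species, Sum) * C(parcel, Sum)", data=table
        ).fit()
        oracle = anova_lm(fit, typ=3)
        pairs = {
            "species": "C(species, Sum)",
            "parcel": "C(parcel, Sum)",
            "species:parcel": "C(species, Sum):C(parcel, Sum)",
        }
        for mine, theirs in pairs.items():
            assert res.loc[mine, "F"] == pytest.approx(oracle.loc[theirs, "F"], rel=1e-8)
            assert res.loc[mine, "p"] == pytest.approx(oracle.loc[theirs, "PR(>F)"], abs=1e-12)

    def test_constant_response_flagged_with_zero_f(self):
        table = synthetic_table((4, 4, 4))
        table["rel_area"] = 0.5
        res = two_way_anova(table, "rel_area")
        assert res.zero_residual_variance
        assert (res.anova["F"] == 0.0).all()

    def test_species_f_equals_pooled_t_squared_on_single_factor_reduction(self):
        """Reduced to one balanced 2-level factor, the species F statistic
        equals the squared pooled two-sample t statistic."""
        from scipy import stats as sps

        rng = np.random.default_rng(8)
        g1 = rng.normal(0.0, 1.0, 12)
        g2 = rng.normal(0.6, 1.0, 12)
        rows = []
        for species, g in (("s1", g1), ("s2", g2)):
            for i, v in enumerate(g):
                rows.append(dict(species=species, parcel="pooled", rel_area=v,
                                 subject_id=f"{species}-{i}", hemisphere="L",
                                 mean_thickness_mm=0.0, rel_volume=0.0))
        res = two_way_anova(pd.DataFrame(rows), "rel_area").anova.set_index("effect")
        t_stat = sps.ttest_ind(g1, g2, equal_var=True).statistic
        assert res.loc["species", "F"] == pytest.approx(t_stat**2, rel=1e-9)

    def test_empty_cell_named_in_error(self):
        table = synthetic_table((4, 4, 4))
        table = table[~((table.species == "macaque") & (table.parcel == "V1"))]
        with pytest.raises(ValueError, match="macaque.*V1"):
            two_way_anova(table, "rel_area")

    def test_two_species_levels_required(self):
        table = synthetic_table((4, 0, 0))
        with pytest.raises(ValueError):
            two_way_anova(table, "rel_area")


class TestPosthoc:
    def test_single_pair_single_parcel_uncorrected(self):
        table = synthetic_table((6, 6, 0), parcels=("MT+",))
        table = table[table.species != "marmoset"]
        out = posthoc_bonferroni(table, "rel_area")
        assert len(out) == 1
        assert out.loc[0, "m"] == 1
        assert out.loc[0, "p_bonferroni"] == out.loc[0, "p_raw"]

    def test_identical_groups_give_t_zero_p_one(self):
        rows = []
        for species in ("a", "b"):
            for i in range(5):
                rows.append(dict(species=species, parcel="p", rel_area=float(i),
                                 subject_id=str(i), hemisphere="L",
                                 mean_thickness_mm=0.0, rel_volume=0.0))
        out = posthoc_bonferroni(pd.DataFrame(rows), "rel_area")
        assert out.loc[0, "t"] == 0.0
        assert out.loc[0, "p_raw"] == 1.0

    def test_correction_count_spans_species_pairs_times_parcels(self):
        table = synthetic_table((6, 6, 6))
        out = posthoc_bonferroni(table, "rel_area")
        assert (out["m"] == 12).all()
        assert len(out) == 12
        assert np.allclose(
            out["p_bonferroni"], np.minimum(1.0, 12 * out["p_raw"]), atol=1e-15
        )

    def test_small_group_flagged_not_tested(self):
        table = synthetic_table((6, 1, 6), parcels=("MT+",))
        out = posthoc_bonferroni(table, "rel_area")
        flagged = out[out["flag"] == "n<2"]
        assert len(flagged) == 2  # both pairs involving the n=1 species
        assert flagged["p_raw"].isna().all()

    def test_power_for_night_vs_macaque_like_shift(self):
        """A 1.5-percentage-point relative-area shift (sd 0.15 pp,
        n = 18 vs 64) yields corrected p < 0.001 in >= 99/100 replicates."""
        rng = np.random.default_rng(123)
        hits = 0
        for _ in range(100):
            rows = []
            for species, n, mu in (("night", 18, 2.4), ("macaque", 64, 0.9)):
                for i in range(n):
                    rows.append(dict(
                        species=species, parcel="MT+",
                        rel_area=rng.normal(mu, 0.15),
                        subject_id=f"{species}-{i}", hemisphere="L",
                        mean_thickness_mm=0.0, rel_volume=0.0,
                    ))
            out = posthoc_bonferroni(pd.DataFrame(rows), "rel_area")
            # single pair/parcel here; apply the full study's m = 12
            if min(1.0, 12 * out.loc[0, "p_raw"]) < 0.001:
                hits += 1
        assert hits >= 99


class TestSummaryReport:
    def test_single_observation_flagged_sd_zero(self):
        table = synthetic_table((2, 2, 2), parcels=("p",)).iloc[:1]
        out = summary_report(table)
        assert out.loc[0, "flag"] == "n=1"
        assert out.loc[0, "rel_area_sd"] == 0.0

    def test_two_value_hand_arithmetic(self):
        rows = [
            dict(species="s", parcel="p", rel_area=v, subject_id=str(i),
                 hemisphere="L", mean_thickness_mm=v, rel_volume=v)
            for i, v in enumerate((1.0, 3.0))
        ]
        out = summary_report(pd.DataFrame(rows))
        assert out.loc[0, "rel_area_mean"] == 2.0
        assert out.loc[0, "rel_area_sd"] == pytest.approx(np.sqrt(2.0))

    def test_deterministic_ordering(self):
        table = synthetic_table((2, 2, 2))
        out = summary_report(table)
        keys = list(zip(out.species, out.parcel))
        assert keys == sorted(keys)
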