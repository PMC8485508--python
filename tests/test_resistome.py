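import numpy as np
import pandas as pd
import pytest

from gutshift.resistome import (ResistomeTable, abr_relative_abundance,
                                cross_sectional_summary, family_proportions,
                                longitudinal_summary)


def make_table(counts: dict[str, list[int]], families: dict[str, str],
               totals: dict[str, int]) -> ResistomeTable:
    frame = pd.DataFrame(counts).T
    frame.columns = list(totals)
    return ResistomeTable(counts=frame, family=pd.Series(families),
                          totals=pd.Series(totals))


class TestFamilyProportions:
    def test_single_family_is_one(self):
        t = make_table({"g1": [10], "g2": [5]},
                       {"g1": "Tetracycline", "g2": "Tetracycline"}, {"s1": 100})
        assert family_proportions(t).loc["s1", "Tetracycline"] == 1.0

    def test_two_family_split(self):
        t = make_table({"g1": [30], "g2": [70]},
                       {"g1": "Beta-lactam", "g2": "Tetracycline"}, {"s1": 1_000})
        props = family_proportions(t)
        assert props.loc["s1", "Beta-lactam"] == pytest.approx(0.3)
        assert props.loc["s1", "Tetracycline"] == pytest.approx(0.7)

    def test_rows_close_to_one(self):
        rng = np.random.default_rng(0)
        counts = {f"g{i}": rng.integers(0, 50, 6).tolist() for i in range(8)}
        fams = {f"g{i}": ["Tetracycline", "Beta-lactam", "Macrolide", "MDR"][i % 4]
                for i in range(8)}
        totals = {f"s{j}": 10_000 for j in range(6)}
        props = family_proportions(make_table(counts, fams, totals))
        assert np.allclose(props.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_abr_sample_warns_all_zero(self):
        t = make_table({"g1": [0, 10]}, {"g1": "MDR"}, {"s1": 100, "s2": 100})
        with pytest.warns(UserWarning, match="zero ABR"):
            props = family_proportions(t)
        assert (props.loc["s1"] == 0).all()

    def test_unknown_family_maps_to_other(self):
        t = make_table({"g1": [5]}, {"g1": "Colistin"}, {"s1": 100})
        assert family_proportions(t).loc["s1", "Other"] == 1.0


class TestRelativeAbundance:
    def test_simple_ratio_and_scaling_invariance(self):
        t = make_table({"g1": [1_000]}, {"g1": "MDR"}, {"s1": 1_000_000})
        assert abr_relative_abundance(t).loc["s1"] == pytest.approx(1e-3)
        t2 = make_table({"g1": [2_000]}, {"g1": "MDR"}, {"s1": 2_000_000})
        assert abr_relative_abundance(t2).loc["s1"] == pytest.approx(1e-3)

    def test_totals_below_gene_sums_rejected(self):
        with pytest.raises(ValueError, match="below summed"):
            make_table({"g1": [200]}, {"g1": "MDR"}, {"s1": 100})

    def test_gene_splitting_preserves_summaries(self):
        """Splitting one gene into two of the same family changes nothing."""
        t1 = make_table({"g1": [40]}, {"g1": "MDR"}, {"s1": 1_000})
        t2 = make_table({"g1a": [15], "g1b": [25]},
                        {"g1a": "MDR", "g1b": "MDR"}, {"s1": 1_000})
        assert abr_relative_abundance(t1).equals(abr_relative_abundance(t2))
        assert family_proportions(t1).equals(family_proportions(t2))


class TestLongitudinalSummary:
    def _metadata(self):
        rows = []
        for a, g in [("a1", "ABX"), ("a2", "ABX"), ("a3", "ABX")]:
            for day, phase in [(-4, "pretreatment"), (6, "treatment"),
                               (13, "recovery")]:
                rows.append({"sample_id": f"{a}_d{day}", "animal_id": a,
                             "group": g, "day": day, "phase": phase})
        return pd.DataFrame(rows)

    def _table(self, values_by_day):
        md = self._metadata()
        counts, totals = {}, {}
        for _, r in md.iterrows():
            v = values_by_day[r["day"]][int(r["animal_id"][1]) - 1]
            counts[r["sample_id"]] = v
            totals[r["sample_id"]] = 1_000
        frame = pd.DataFrame({sid: [c] for sid, c in counts.items()},
                             index=["g1"])
        return ResistomeTable(counts=frame, family=pd.Series({"g1": "Beta-lactam"}),
                              totals=pd.Series(totals)), md

    def test_sem_closed_form(self):
        table, md = self._table({-4: [1, 2, 3], 6: [5, 5, 5], 13: [2, 2, 2]})
        summary, _ = longitudinal_summary(table, md)
        cell = summary.loc[("ABX", -4)]
        assert cell[("mean", "abr_relabund")] == pytest.approx(0.002)
        assert cell[("sem", "abr_relabund")] == pytest.approx(0.001 / np.sqrt(3))
        assert summary.loc[("ABX", 6)][("sem", "abr_relabund")] == 0.0

    def test_up_then_down_trend(self):
        table, md = self._table({-4: [1, 1, 1], 6: [50, 60, 40], 13: [5, 6, 4]})
        _, trends = longitudinal_summary(table, md)
        assert trends.loc[trends["group"] == "ABX", "trend"].iloc[0] == "up-then-down"

    def test_treatment_enriched_design_classified_up_then_down(self):
        """A treatment-enriched ABR design is classified "up-then-down" for
        the treated group in >= 90% of seeds."""
        from gutshift.simulate import SimulationDesign, make_truth, simulate_resistome
        hits, n_seeds = 0, 50
        for s in range(n_seeds):
            design = SimulationDesign(n_animals_per_group={"ABX": 2}, seed=s)
            table, md = simulate_resistome(design, make_truth(design))
            _, trends = longitudinal_summary(table, md)
            if trends.loc[trends["group"] == "ABX", "trend"].iloc[0] == "up-then-down":
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_single_animal_cell_has_missing_sem(self):
        md = self._metadata().iloc[:1]
        frame = pd.DataFrame({md["sample_id"].iloc[0]: [5]}, index=["g1"])
        table = ResistomeTable(counts=frame, family=pd.Series({"g1": "MDR"}),
                               totals=pd.Series({md["sample_id"].iloc[0]: 100}))
        summary, _ = longitudinal_summary(table, md)
        assert np.isnan(summary[("sem", "abr_relabund")].iloc[0])


class TestCrossSectional:
    def _table_for_animals(self, rel_abund: dict[str, float]):
        frame = pd.DataFrame({a: [int(v * 1_000)] for a, v in rel_abund.items()},
                             index=["g1"])
        return ResistomeTable(counts=frame, family=pd.Series({"g1": "MDR"}),
                              totals=pd.Series({a: 1_000 for a in rel_abund}))

    def test_monotone_exposure_gives_rho_one(self):
        exposure = pd.Series({f"a{i}": e for i, e in enumerate((0, 1, 3, 9, 16, 27))})
        rel = {f"a{i}": 0.1 + 0.1 * i for i in range(6)}
        out = cross_sectional_summary(self._table_for_animals(rel), exposure)
        assert out.attrs["spearman_rho"] == pytest.approx(1.0)
        assert out.attrs["permutation_p"] <= 0.01

    def test_constant_exposure_gives_na(self):
        exposure = pd.Series({f"a{i}": 5 for i in range(4)})
        rel = {f"a{i}": 0.1 * (i + 1) for i in range(4)}
        out = cross_sectional_summary(self._table_for_animals(rel), exposure)
        assert np.isnan(out.attrs["spearman_rho"])

    def test_independent_abr_rarely_looks_perfect(self):
        """Null simulation: |rho| < 0.9 in >= 95% of seeds at n=6."""
        exposure = pd.Series({f"a{i}": e for i, e in enumerate((0, 0, 3, 9, 16, 27))})
        extreme = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            rel = {f"a{i}": float(rng.uniform(0.05, 0.5)) for i in range(6)}
            out = cross_sectional_summary(self._table_for_animals(rel), exposure,
                                          n_perm=0 + 1, seed=s)
            if abs(out.attrs["spearman_rho"]) >= 0.9:
                extreme += 1
        assert extreme <= 5

    def test_permutation_p_calibrated_under_null(self):
        exposure = pd.Series({f"a{i}": e for i, e in enumerate((0, 1, 3, 9, 16, 27))})
        ps = []
        for s in range(200):
            rng = np.random.default_rng(1_000 + s)
            rel = {f"a{i}": float(rng.uniform(0.05, 0.5)) for i in range(6)}
            out = cross_sectional_summary(self._table_for_animals(rel), exposure,
                                          n_perm=99, seed=s)
            ps.append(out.attrs["permutation_p"])
        assert np.mean(np.array(ps) <= 0.05) <= 0.1
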