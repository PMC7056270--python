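"""Mass-dominance ranking, gene-set mass fractions, heatmap construction."""

import numpy as np
import pandas as pd
import pytest

import proteoruler as pr
from proteoruler.io_tables import condition_labels
from tests.conftest import make_groups


def brute_force_profile(masses: dict[str, float]):
    """Independent oracle: explicit sort + prefix enumeration."""
    order = sorted(masses, key=lambda g: (-masses[g], g))
    total = sum(masses.values())
    cum, acc = [], 0.0
    for g in order:
        acc += masses[g]
        cum.append(acc / total)
    counts = []
    for q in (0.25, 0.50, 0.75, 1.00):
        k = next(i + 1 for i, c in enumerate(cum) if c >= q - 1e-12)
        counts.append(k)
    return order, cum, tuple(counts), frozenset(order[: counts[2]])


def result_from_masses(masses: dict[str, float], design) -> pr.CopyNumberResult:
    """Single-sample CopyNumberResult with prescribed per-protein masses."""
    cfg = pr.RulerConfig(histone_mass_override_g=1.0)
    intens = {g: [m] for g, m in masses.items()}
    intens["HISTONE"] = [1.0]
    genes = list(masses) + ["H4c1"]
    groups = make_groups(intens, design, gene_name=genes,
                         mol_weight_da=[50000.0] * len(genes))
    res = pr.estimate_copy_numbers(groups, design, cfg)
    return res


class TestMassRank:
    def test_worked_example(self, single_sample_design):
        masses = {"a": 0.40, "b": 0.30, "c": 0.20, "d": 0.10}
        res = result_from_masses(masses, single_sample_design)
        prof = pr.mass_rank_profile(res, "WT.CD4.naive")
        # the histone anchor adds a fifth protein; restrict to the planted four
        sub = {g: masses[g] for g in masses}
        order, cum, counts, top75 = brute_force_profile(
            dict(sub, HISTONE=res.mass.loc["HISTONE", "s1"])
        )
        assert prof.ranked_ids == order
        assert np.allclose(prof.cumulative_mass_fraction, cum)
        assert prof.quartile_counts == counts
        assert prof.top75_set == top75

    def test_single_protein(self, single_sample_design):
        cfg = pr.RulerConfig(histone_mass_override_g=1e-12)
        groups = make_groups({"H4c1": [100.0]}, single_sample_design)
        res = pr.estimate_copy_numbers(groups, single_sample_design, cfg)
        prof = pr.mass_rank_profile(res, "WT.CD4.naive")
        assert prof.quartile_counts == (1, 1, 1, 1)
        assert np.allclose(prof.cumulative_mass_fraction, [1.0])
        assert prof.top75_set == {"H4c1"}

    def test_matches_brute_force_on_random_instances(self, single_sample_design):
        rng = np.random.default_rng(20)
        for trial in range(100):
            n = int(rng.integers(1, 50))
            masses = {f"g{i:02d}": float(rng.lognormal(0, 2)) for i in range(n)}
            res = result_from_masses(masses, single_sample_design)
            prof = pr.mass_rank_profile(res, "WT.CD4.naive")
            all_masses = {g: float(res.mass.loc[g, "s1"]) for g in res.group_ids}
            order, cum, counts, top75 = brute_force_profile(all_masses)
            assert prof.ranked_ids == order
            assert np.allclose(prof.cumulative_mass_fraction, cum, atol=1e-12)
            assert prof.quartile_counts == counts
            assert prof.top75_set == top75

    def test_profile_invariants_and_permutation_stability(self, noise_free_result):
        res, design, _ = noise_free_result
        prof = pr.mass_rank_profile(res, "WT.CD8.TCR")
        cum = prof.cumulative_mass_fraction
        assert (np.diff(cum) >= -1e-15).all()
        assert cum[-1] == pytest.approx(1.0, abs=1e-12)
        assert prof.quartile_counts == tuple(sorted(prof.quartile_counts))
        assert len(prof.top75_set) == prof.quartile_counts[2]
        # permuting input rows leaves the profile unchanged
        shuffled = pr.CopyNumberResult(
            copies=res.copies.sample(frac=1, random_state=0),
            mass=res.mass.sample(frac=1, random_state=0),
            detected=res.detected.sample(frac=1, random_state=0),
            mean_copies=res.mean_copies.sample(frac=1, random_state=0),
            quality=res.quality,
            mol_weight_da=res.mol_weight_da,
            gene_name=res.gene_name,
            design=design,
        )
        prof2 = pr.mass_rank_profile(shuffled, "WT.CD8.TCR")
        assert prof2.ranked_ids == prof.ranked_ids


class TestPathwayMass:
    def test_full_and_empty_sets(self, noise_free_result):
        res, _, _ = noise_free_result
        summary, unmatched = pr.pathway_mass_summary(res, list(res.gene_name))
        assert np.allclose(summary["percent_of_total_mass"], 100.0)
        assert unmatched == []
        with pytest.warns(UserWarning, match="no proteins matched"):
            summary, unmatched = pr.pathway_mass_summary(res, ["NotAGene"])
        assert np.allclose(summary["percent_of_total_mass"], 0.0)
        assert unmatched == ["notagene"]

    def test_planted_mass_fraction_recovered_exactly(self, noise_free_result):
        res, design, truth = noise_free_result
        t = truth.table.set_index("protein_id")
        genes = t.loc[t.effect_class == "unchanged", "gene_name"].tolist()
        summary, _ = pr.pathway_mass_summary(res, genes)
        mw = t["mol_weight_da"]
        for cond in res.mean_copies.columns:
            planted = t[f"copies.{cond}"] * mw
            expected = 100.0 * planted[t.effect_class == "unchanged"].sum() / planted.sum()
            assert summary.loc[cond, "percent_of_total_mass"] == pytest.approx(
                expected, rel=1e-9
            )

    def test_matching_is_case_insensitive(self, noise_free_result):
        res, _, _ = noise_free_result
        gene = str(res.gene_name.iloc[0])
        s1, _ = pr.pathway_mass_summary(res, [gene.upper()])
        s2, _ = pr.pathway_mass_summary(res, [gene.lower()])
        pd.testing.assert_frame_equal(s1, s2)


@pytest.fixture(scope="module")
def boundary_result():
    """Proteins straddling the 500-copy and 2-replicate boundaries."""
    design = pr.make_design()
    cfg = pr.RulerConfig(histone_mass_override_g=1e-12)
    n_samples = len(design)

    def with_copies(copies_cd8, detected_reps=3):
        """Intensity rows giving ~copies in CD8 conditions, more in CD4."""
        row = []
        for _, s in design.iterrows():
            if s["cell_type"] == "CD8" and s["replicate"] <= detected_reps:
                row.append(copies_cd8)
            elif s["cell_type"] == "CD8":
                row.append(np.nan)
            else:
                row.append(copies_cd8 * 2)
        return row

    intens = {
        "HIST": [1000.0] * n_samples,
        "PASS": with_copies(900.0),
        "JUST_UNDER": with_copies(499.0),
        "ONE_REP": with_copies(900.0, detected_reps=1),
        "CONST": [500.0] * n_samples,
    }
    groups = make_groups(
        intens, design, gene_name=["H4c1", "Pass", "Junder", "Onerep", "Const"]
    )
    res = pr.estimate_copy_numbers(groups, design, cfg)
    return res, design


class TestHeatmap:
    def test_threshold_boundaries(self, boundary_result):
        res, design = boundary_result
        # scale thresholds onto this fixture's copy scale
        copies_of = res.mean_copies["WT.CD8.TCR"]
        min_copies = float(copies_of["PASS"]) * 500.0 / 900.0
        heat = pr.build_heatmap_matrix(
            res, min_mean_copies=min_copies, min_reps=2, reference_celltype="CD8"
        )
        ids = set(heat.values.index)
        assert "PASS" in ids
        assert "JUST_UNDER" not in ids      # 499 < 500 in every CD8 condition
        assert "ONE_REP" not in ids         # detected in only 1 replicate
        assert "HIST" in ids and "CONST" in ids

    def test_row_scaling_bounds_and_constant_rows(self, boundary_result):
        res, design = boundary_result
        heat = pr.build_heatmap_matrix(res, min_mean_copies=0.0, min_reps=0)
        vals = heat.values
        var_rows = vals.index[vals.std(axis=1) > 0]
        assert np.allclose(vals.loc[var_rows].min(axis=1), 0.0)
        assert np.allclose(vals.loc[var_rows].max(axis=1), 1.0)
        # constant rows (CONST, and HIST which anchors itself to a constant
        # value) map to 0.5 and are appended after the clustered rows
        assert (vals.loc["CONST"] == 0.5).all()
        assert (vals.loc["HIST"] == 0.5).all()
        assert set(heat.row_order[-2:]) == {"CONST", "HIST"}

    def test_row_example_scaling(self):
        # [100, 200, 300] -> [0, 0.5, 1]
        lo, rng_ = 100.0, 200.0
        assert np.allclose((np.array([100, 200, 300]) - lo) / rng_, [0, 0.5, 1])

    def test_identical_rows_cluster_adjacently_and_order_is_deterministic(self):
        params = pr.SimulationParams(missing_rate=0.0, n_decoys=0, n_contaminants=0)
        groups, design, _ = pr.simulate_dataset(80, seed=17, params=params)
        res = pr.estimate_copy_numbers(groups, design)
        # plant an identical twin of one variable protein
        twin_src = res.mean_copies.index[0]
        for df in (res.copies, res.mass, res.mean_copies):
            df.loc["ZZ_TWIN"] = df.loc[twin_src]
        res.detected.loc["ZZ_TWIN"] = res.detected.loc[twin_src]
        res.quality.loc["ZZ_TWIN"] = res.quality.loc[twin_src]
        res.mol_weight_da.loc["ZZ_TWIN"] = res.mol_weight_da.loc[twin_src]
        res.gene_name.loc["ZZ_TWIN"] = "Twin"
        h1 = pr.build_heatmap_matrix(res, min_mean_copies=0.0, min_reps=0)
        h2 = pr.build_heatmap_matrix(res, min_mean_copies=0.0, min_reps=0)
        assert h1.row_order == h2.row_order
        i, j = h1.row_order.index(twin_src), h1.row_order.index("ZZ_TWIN")
        assert abs(i - j) == 1

    def test_no_survivors_names_thresholds(self, boundary_result):
        res, design = boundary_result
        with pytest.raises(ValueError, match="threshold"):
            pr.build_heatmap_matrix(res, min_mean_copies=1e18, min_reps=2)

    def test_reference_celltype_must_exist(self, boundary_result):
        res, design = boundary_result
        with pytest.raises(KeyError, match="cell type"):
            pr.build_heatmap_matrix(res, reference_celltype="NK")
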