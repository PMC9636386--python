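"""Differential sets, similarity rule, intersections, and the full screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mitotype.screen import (
    AbundanceMatrix,
    ComparisonSpec,
    PhenotypeTable,
    ScreenConfig,
    apply_external_filter,
    benchmark_design,
    differential_set,
    load_abundance,
    muscle_profile,
    paper_design,
    phenotype_association,
    run_screen,
    similar_set,
)
from mitotype.synthetic import ProteomeSimParams, make_proteome, phenotype_table, write_proteome


def toy_profiles(values: dict[str, list[float]], ids=None) -> pd.DataFrame:
    n = len(next(iter(values.values())))
    ids = ids or [f"p{i}" for i in range(n)]
    return pd.DataFrame(values, index=ids)


class TestLoadAbundance:
    def _write(self, tmp_path, rows, samples=("s1", "s2"), muscles=("A", "B")):
        table = tmp_path / "abund.tsv"
        lines = ["protein_id\t" + "\t".join(samples)]
        lines += [f"{pid}\t" + "\t".join(str(v) for v in vals) for pid, vals in rows]
        table.write_text("\n".join(lines) + "\n")
        meta = tmp_path / "samples.tsv"
        meta.write_text("sample_id\tmuscle_type\n" +
                        "".join(f"{s}\t{m}\n" for s, m in zip(samples, muscles)))
        return table, meta

    def test_complete_table_fully_retained(self, tmp_path):
        table, meta = self._write(tmp_path, [("a", [1, 2]), ("b", [3, 4]), ("c", [5, 6])])
        matrix = load_abundance(table, meta)
        assert matrix.values.shape == (3, 2)

    def test_protein_with_missing_value_dropped(self, tmp_path):
        table, meta = self._write(tmp_path, [("a", [1, 2]), ("b", ["", 4]), ("c", [5, 6])])
        matrix = load_abundance(table, meta)
        assert list(matrix.values.index) == ["a", "c"]

    def test_nonpositive_abundance_dropped(self, tmp_path):
        table, meta = self._write(tmp_path, [("a", [1, 2]), ("b", [0, 4])])
        assert list(load_abundance(table, meta).values.index) == ["a"]

    def test_unmapped_sample_is_an_error(self, tmp_path):
        table, meta = self._write(tmp_path, [("a", [1, 2])])
        meta.write_text("sample_id\tmuscle_type\ns1\tA\n")
        with pytest.raises(ValueError, match="s2"):
            load_abundance(table, meta)

    def test_duplicate_protein_id_is_an_error(self, tmp_path):
        table, meta = self._write(tmp_path, [("a", [1, 2]), ("a", [3, 4])])
        with pytest.raises(ValueError, match="duplicate"):
            load_abundance(table, meta)


class TestMuscleProfile:
    def _matrix(self):
        frame = pd.DataFrame(
            {"A_r1": [2.0, 1.0], "A_r2": [4.0, 2.0], "B_r1": [1.0, 9.0]},
            index=pd.Index(["p0", "p1"], name="protein_id"),
        )
        return AbundanceMatrix(frame, {"A_r1": "A", "A_r2": "A", "B_r1": "B"})

    def test_mean_of_replicates(self):
        prof = muscle_profile(self._matrix(), "mean")
        assert prof.loc["p0", "A"] == 3.0
        assert prof.loc["p0", "B"] == 1.0        # single replicate passes through

    def test_median_vs_mean(self):
        frame = pd.DataFrame({"A_r1": [1.0], "A_r2": [2.0], "A_r3": [9.0]},
                             index=pd.Index(["p"], name="protein_id"))
        matrix = AbundanceMatrix(frame, {c: "A" for c in frame.columns})
        assert muscle_profile(matrix, "median").loc["p", "A"] == 2.0
        assert muscle_profile(matrix, "mean").loc["p", "A"] == 4.0


class TestDifferentialAndSimilar:
    def test_inclusive_thresholds(self):
        prof = toy_profiles({"A": [4.0, 2.0, 1.0, 1.2], "B": [1.0, 1.0, 3.0, 1.0]})
        res = differential_set(prof, "A", "B")
        assert res["up"] == {"p0", "p1"}          # fc 4 and fc exactly 2.0
        assert res["down"] == {"p2"}              # fc 1/3 <= 0.5
        assert res["fc"]["p3"] == pytest.approx(1.2)

    def test_similarity_boundary_at_25_percent(self):
        prof = toy_profiles({"A": [1.0, 1.25, 0.8, 2.0], "B": [1.0, 1.0, 1.0, 1.0]})
        sim = similar_set(prof, "A", "B", tolerance=0.25)
        assert sim == {"p0", "p1", "p2"}          # 1.25 and 1/0.8 both on boundary

    def test_duality_down_equals_reversed_up_at_default_thresholds(self):
        rng = np.random.default_rng(4)
        prof = toy_profiles({"A": rng.lognormal(11, 1, 60).tolist(),
                             "B": rng.lognormal(11, 1, 60).tolist()})
        cfg = ScreenConfig()                      # 2.0 and 0.5 = 1/2.0
        assert differential_set(prof, "A", "B", cfg)["down"] == \
               differential_set(prof, "B", "A", cfg)["up"]

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(2.0, 6.0), st.floats(2.0, 6.0))
    def test_threshold_monotonicity(self, seed, t1, t2):
        rng = np.random.default_rng(seed)
        prof = toy_profiles({"A": rng.lognormal(0, 1.2, 40).tolist(),
                             "B": rng.lognormal(0, 1.2, 40).tolist()})
        lo, hi = sorted([t1, t2])
        up_lo = differential_set(prof, "A", "B", ScreenConfig(up_threshold=lo))["up"]
        up_hi = differential_set(prof, "A", "B", ScreenConfig(up_threshold=hi))["up"]
        assert up_hi <= up_lo
        dn_lo = differential_set(prof, "A", "B", ScreenConfig(down_threshold=1 / lo))["down"]
        dn_hi = differential_set(prof, "A", "B", ScreenConfig(down_threshold=1 / hi))["down"]
        assert dn_hi <= dn_lo


class TestPhenotypeAssociation:
    def test_single_pair_equals_differential_set(self):
        prof = toy_profiles({"A": [4.0, 1.0], "B": [1.0, 1.0]})
        spec = ComparisonSpec("fibrillar", "+", [("A", "B")])
        assert phenotype_association(prof, spec) == \
               differential_set(prof, "A", "B")["up"]

    def test_adding_a_pair_never_grows_the_set(self):
        rng = np.random.default_rng(8)
        prof = toy_profiles({m: rng.lognormal(0, 1, 50).tolist() for m in "ABC"})
        one = phenotype_association(prof, ComparisonSpec("x", "+", [("A", "B")]))
        two = phenotype_association(prof, ComparisonSpec("x", "+", [("A", "B"), ("A", "C")]))
        assert two <= one

    def test_empty_pair_list_rejected(self):
        with pytest.raises(ValueError):
            ComparisonSpec("x", "+", [])


class TestExternalFilter:
    def test_plain_intersection(self):
        assert apply_external_filter({"a", "b", "c"}, ["b", "c", "d"]) == {"b", "c"}

    def test_empty_external_list(self):
        assert apply_external_filter({"a"}, []) == set()

    def test_superset_leaves_unchanged(self):
        assert apply_external_filter({"a", "b"}, ["a", "b", "z"]) == {"a", "b"}


class TestRunScreen:
    def test_zero_noise_ten_class_recovery_exact(self, zero_noise_ten_class_proteome):
        params, matrix, truth = zero_noise_ten_class_proteome
        result = run_screen(matrix, phenotype_table(params.muscle_types),
                            benchmark_design())
        for key, ids in truth.items():
            assert result.filtered[key] == set(ids), key
        assert result.union_count == sum(len(v) for v in truth.values())

    def test_no_effect_matrix_yields_empty_screen(self):
        matrix, _ = make_proteome(ProteomeSimParams(n_proteins=100, noise_cv=0.0))
        result = run_screen(matrix, None, benchmark_design())
        assert result.union == set()
        assert all(len(v) == 0 for v in result.filtered.values())

    def test_empty_comparison_config(self):
        matrix, _ = make_proteome(ProteomeSimParams(n_proteins=10, noise_cv=0.0))
        result = run_screen(matrix, None, ScreenConfig(comparison_sets=[]))
        assert result.union == set()
        assert result.per_comparison == []

    def test_unknown_muscle_type_rejected(self):
        matrix, _ = make_proteome(ProteomeSimParams(n_proteins=10, noise_cv=0.0))
        cfg = ScreenConfig(comparison_sets=[
            ComparisonSpec("fibrillar", "+", [("flight_wt", "heart")])
        ])
        with pytest.raises(ValueError, match="heart"):
            run_screen(matrix, None, cfg)

    def test_external_filter_applied_to_named_design(self):
        matrix, truth = make_proteome(ProteomeSimParams(
            n_proteins=50, planted=[("grid", "+", 6, 4.0)], noise_cv=0.0))
        keep = truth["grid+"][:2]
        cfg = benchmark_design()
        cfg.external_filters = {"grid+": keep}
        result = run_screen(matrix, None, cfg)
        assert result.associations["grid+"] == set(truth["grid+"])
        assert result.filtered["grid+"] == set(keep)
        assert result.union >= set(keep)

    def test_plus_minus_sets_disjoint_and_contained(self):
        planted = [("parallel", "+", 5, 4.0), ("parallel", "-", 5, 4.0)]
        matrix, truth = make_proteome(ProteomeSimParams(
            n_proteins=100, planted=planted, noise_cv=0.1, seed=6))
        result = run_screen(matrix, None, benchmark_design())
        assert not (result.associations["parallel+"] & result.associations["parallel-"])

    def test_permutation_null_matches_no_effect_run(self):
        """Label shuffling on a no-effect matrix changes nothing systematic."""
        matrix, _ = make_proteome(ProteomeSimParams(n_proteins=200, noise_cv=0.1, seed=9))
        base = run_screen(matrix, None, benchmark_design()).union_count
        rng = np.random.default_rng(9)
        shuffled_counts = []
        for _ in range(5):
            samples = list(matrix.sample_muscle)
            muscles = list(matrix.sample_muscle.values())
            rng.shuffle(muscles)
            shuffled = AbundanceMatrix(matrix.values, dict(zip(samples, muscles)))
            shuffled_counts.append(run_screen(shuffled, None, benchmark_design()).union_count)
        assert abs(np.mean(shuffled_counts) - base) <= 2.0

    def test_paper_design_fibrillar_pairs_are_the_stated_four(self):
        cfg = paper_design()
        fib = next(s for s in cfg.comparison_sets if s.key == "fibrillar+")
        assert fib.pairs == [
            ("flight_wt", "leg_wt"), ("flight_wt", "jump_wt"),
            ("flight_wt", "flight_salm_kd"), ("leg_salm_oe", "leg_wt"),
        ]
        grid = next(s for s in cfg.comparison_sets if s.key == "grid+")
        assert len(grid.pairs) == 3              # grid has one fewer comparison

    def test_config_json_roundtrip(self, tmp_path):
        cfg = benchmark_design()
        cfg.external_filters = {"grid+": ["a", "b"]}
        path = tmp_path / "cfg.json"
        cfg.to_json(path)
        back = ScreenConfig.from_json(path)
        assert back == cfg


class TestPhenotypeTable:
    def test_vocabulary_enforced(self):
        with pytest.raises(ValueError):
            PhenotypeTable({"m": {"contractile": "smooth", "network": "grid", "salm": "high"}})

    def test_matrix_validation(self):
        matrix, _ = make_proteome(ProteomeSimParams(n_proteins=5, noise_cv=0.0))
        table = PhenotypeTable({"flight_wt": {
            "contractile": "fibrillar", "network": "parallel", "salm": "high"}})
        with pytest.raises(ValueError, match="jump_wt"):
            table.validate_matrix(matrix)


def test_screen_runs_from_files_written_by_generator(tmp_path):
    params = ProteomeSimParams(n_proteins=40, planted=[("tubular", "-", 3, 4.0)],
                               noise_cv=0.0)
    matrix, truth = make_proteome(params)
    paths = write_proteome(tmp_path, matrix, truth=truth, params=params)
    reloaded = load_abundance(paths["abundance"], paths["samples"])
    result = run_screen(reloaded, None, benchmark_design())
    assert result.filtered["tubular-"] == set(truth["tubular-"])
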