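"""Tests of parental centering, expression-marker calling, QC, imputation
and informative-marker pruning."""

import itertools

import numpy as np
import pandas as pd
import pytest

import mirileqtl as mq
from mirileqtl.containers import P1, P2
from mirileqtl.genetic_map import CALL_COLUMNS
from mirileqtl.simulate import truth_genotype_at


def make_expression(values, parents=(4.0, 6.0)):
    """Single-spot expression matrix with one replicate per parent."""
    strains = [f"s{i}" for i in range(len(values))]
    features = pd.DataFrame(
        {"spot_id": ["sp1"], "gene_id": ["g1"], "chrom": ["1"], "pos_bp": [100]}
    )
    return mq.ExpressionMatrix(
        features=features,
        values=pd.DataFrame([values], index=["sp1"], columns=strains),
        parental_values=pd.DataFrame(
            {"P1_rep1": [parents[0]], "P2_rep1": [parents[1]]}, index=["sp1"]
        ),
        parental_genotype={"P1_rep1": "P1", "P2_rep1": "P2"},
    )


class TestCentering:
    def test_parental_midpoint_maps_to_zero(self):
        centered = mq.center_on_parents(make_expression([5.0]))
        assert centered.values.iloc[0, 0] == pytest.approx(0.0)

    def test_value_at_parent_level(self):
        centered = mq.center_on_parents(make_expression([4.0]))
        assert centered.values.iloc[0, 0] == pytest.approx(-1.0)

    def test_swapping_parents_leaves_r_unchanged(self):
        a = mq.center_on_parents(make_expression([4.7], parents=(4.0, 6.0)))
        b = mq.center_on_parents(make_expression([4.7], parents=(6.0, 4.0)))
        assert a.values.iloc[0, 0] == pytest.approx(b.values.iloc[0, 0])

    def test_missing_parental_columns_rejected(self):
        expr = make_expression([5.0])
        expr.parental_values = None
        expr.parental_genotype = {}
        with pytest.raises(ValueError, match="parental"):
            mq.center_on_parents(expr)


def panel_and_expression(n_genes=100, n_strains=6, window=20, noise=0.0, seed=0):
    """Expression whose centred profiles equal +-effect/2 by construction."""
    rng = np.random.default_rng(seed)
    effects = rng.uniform(1.0, 3.0, n_genes) * rng.choice([-1, 1], n_genes)
    panel = mq.ReferenceCisPanel(
        table=pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n_genes)],
                "chrom": "1",
                "pos_bp": np.arange(1, n_genes + 1) * 10_000,
                "effect": effects,
            }
        )
    )
    # strain genotypes per window: alternate P1/P2 blocks
    strain_sign = rng.choice([1.0, -1.0], size=(n_genes, n_strains))
    for s in range(n_strains):
        for w in range(n_genes // window):
            strain_sign[w * window : (w + 1) * window, s] = 1.0 if (s + w) % 2 == 0 else -1.0
    ordered = panel.table["effect"].to_numpy()  # already position-sorted
    values = 8.0 + 0.5 * ordered[:, None] * strain_sign
    values += rng.normal(0, noise, values.shape)
    features = pd.DataFrame(
        {
            "spot_id": [f"sp{i}" for i in range(n_genes)],
            "gene_id": panel.table["gene_id"],
            "chrom": "1",
            "pos_bp": panel.table["pos_bp"],
        }
    )
    par = pd.DataFrame(
        {
            "P1_rep1": 8.0 + 0.5 * ordered,
            "P1_rep2": 8.0 + 0.5 * ordered,
            "P2_rep1": 8.0 - 0.5 * ordered,
            "P2_rep2": 8.0 - 0.5 * ordered,
        },
        index=features["spot_id"],
    )
    expr = mq.ExpressionMatrix(
        features=features,
        values=pd.DataFrame(
            values, index=features["spot_id"], columns=[f"s{i}" for i in range(n_strains)]
        ),
        parental_values=par,
        parental_genotype={"P1_rep1": "P1", "P1_rep2": "P1", "P2_rep1": "P2", "P2_rep2": "P2"},
    )
    return panel, expr, strain_sign


class TestMarkerCalling:
    def test_perfect_profile_gives_all_p1(self):
        panel, expr, _ = panel_and_expression(n_strains=1, seed=1)
        # strain 0 has sign +1 in even windows, -1 in odd windows
        centered = mq.center_on_parents(expr)
        calls = mq.call_expression_markers(centered, panel, include_parents=False)
        s0 = calls[calls["strain"] == "s0"].sort_values("window_id")
        expected = [P1 if w % 2 == 0 else P2 for w in range(5)]
        assert list(s0["call"]) == expected
        assert (s0["r"].abs() > 0.999).all()

    def test_marker_count_is_floor_of_matched_over_window(self):
        panel, expr, _ = panel_and_expression(n_genes=100, seed=2)
        centered = mq.center_on_parents(expr)
        calls = mq.call_expression_markers(centered, panel, window=20)
        assert calls["window_id"].nunique() == 5
        calls30 = mq.call_expression_markers(centered, panel, window=30)
        assert calls30["window_id"].nunique() == 3

    def test_negating_reference_effects_flips_calls(self):
        panel, expr, _ = panel_and_expression(noise=0.4, seed=3)
        centered = mq.center_on_parents(expr)
        flipped = mq.ReferenceCisPanel(table=panel.table.assign(effect=-panel.table["effect"]))
        a = mq.call_expression_markers(centered, panel, include_parents=False)
        b = mq.call_expression_markers(centered, flipped, include_parents=False)
        assert np.allclose(a["r"], -b["r"], atol=1e-12)
        swapped = b["call"].map({P1: P2, P2: P1})
        pd.testing.assert_series_equal(
            a["call"], swapped, check_names=False, check_dtype=False
        )

    def test_too_few_matched_genes_rejected(self):
        panel, expr, _ = panel_and_expression(seed=4)
        centered = mq.center_on_parents(expr)
        with pytest.raises(ValueError, match="window"):
            mq.call_expression_markers(centered, panel, window=101)

    def test_call_error_rate_below_one_percent(self, default_genotypes, default_panel,
                                               default_expression):
        """Windowed calling misassigns < 1% of calls per strain vs truth."""
        centered = mq.center_on_parents(default_expression)
        calls = mq.call_expression_markers(centered, default_panel, include_parents=False)
        wrong = total = 0
        for (chrom, pos), sub in calls.groupby(["chrom", "pos_bp"]):
            truth = truth_genotype_at(default_genotypes, chrom, int(pos))
            merged = sub.set_index("strain").join(truth.rename("truth"))
            known = merged["call"].notna() & merged["truth"].notna()
            total += int(known.sum())
            wrong += int((merged.loc[known, "call"] != merged.loc[known, "truth"]).sum())
        assert total > 5000
        assert wrong / total < 0.01


class TestQcFilter:
    def _calls(self, rows):
        return pd.DataFrame(rows, columns=CALL_COLUMNS)

    def test_window_misassigning_parent_dropped(self):
        rows = [
            ("P1_rep1", 0, "1", 100, 0.9, P2, "correlated"),  # wrong parent call
            ("P2_rep1", 0, "1", 100, -0.9, P2, "correlated"),
            ("s0", 0, "1", 100, 0.8, P1, "correlated"),
            ("s1", 0, "1", 100, 0.8, P1, "correlated"),
        ]
        out = mq.qc_filter_markers(
            self._calls(rows), {"P1_rep1": "P1", "P2_rep1": "P2"}
        )
        assert out.empty

    def test_low_called_fraction_dropped(self):
        rows = [("P1_rep1", 0, "1", 100, 0.9, P1, "correlated"),
                ("P2_rep1", 0, "1", 100, -0.9, P2, "correlated")]
        rows += [(f"s{i}", 0, "1", 100, 0.4, np.nan, "correlated") for i in range(6)]
        rows += [(f"s{i}", 0, "1", 100, 0.8, P1, "correlated") for i in range(6, 10)]
        out = mq.qc_filter_markers(
            self._calls(rows), {"P1_rep1": "P1", "P2_rep1": "P2"}
        )
        assert out.empty  # only 40% of samples with |r| > 0.5

    def test_clean_window_retained(self):
        rows = [("P1_rep1", 0, "1", 100, 0.9, P1, "correlated"),
                ("P2_rep1", 0, "1", 100, -0.9, P2, "correlated")]
        rows += [(f"s{i}", 0, "1", 100, 0.8, P1, "correlated") for i in range(4)]
        out = mq.qc_filter_markers(
            self._calls(rows), {"P1_rep1": "P1", "P2_rep1": "P2"}
        )
        assert set(out["strain"]) == {"s0", "s1", "s2", "s3"}


class TestImputation:
    def _calls_from_pattern(self, pattern):
        rows = [
            ("s0", w, "1", (w + 1) * 1000, 0.9 if not np.isnan(c) else 0.1, c, "correlated")
            for w, c in enumerate(pattern)
        ]
        return pd.DataFrame(rows, columns=CALL_COLUMNS)

    @pytest.mark.parametrize(
        "pattern,expected",
        # exhaustive 3-marker truth table of the decision rule
        [
            ([P1, np.nan, P1], [P1, P1, P1]),
            ([P2, np.nan, P2], [P2, P2, P2]),
            ([P1, np.nan, P2], [P1, np.nan, P2]),
            ([P2, np.nan, P1], [P2, np.nan, P1]),
            ([np.nan, P1, np.nan], [P1, P1, P1]),
            ([np.nan, np.nan, P2], [P2, P2, P2]),
            ([P1, P2, P1], [P1, P2, P1]),
            ([P1, P1, P1], [P1, P1, P1]),
        ],
    )
    def test_three_marker_patterns(self, pattern, expected):
        geno, prov = mq.impute_and_extend(self._calls_from_pattern(pattern))
        got = geno.calls.iloc[0].to_list()
        assert got == pytest.approx(expected, nan_ok=True)

    def test_crossover_interval_flagged(self):
        geno, prov = mq.impute_and_extend(self._calls_from_pattern([P1, np.nan, P2]))
        assert prov.iloc[0].to_list() == ["correlated", "crossover", "correlated"]

    def test_end_extension_provenance(self):
        geno, prov = mq.impute_and_extend(self._calls_from_pattern([np.nan, P1, np.nan]))
        assert prov.iloc[0].to_list() == ["end-extended", "correlated", "end-extended"]

    def test_no_missing_is_identity(self):
        geno, prov = mq.impute_and_extend(self._calls_from_pattern([P1, P2, P1]))
        assert (prov == "correlated").all().all()

    def test_uncalled_chromosome_names_strain(self):
        calls = self._calls_from_pattern([np.nan, np.nan, np.nan])
        with pytest.raises(ValueError, match="s0.*chromosome 1"):
            mq.impute_and_extend(calls)


class TestPruning:
    def _genotypes(self, columns):
        calls = pd.DataFrame(
            np.array(columns, dtype=float).T,
            index=[f"s{i}" for i in range(len(columns[0]))],
            columns=[f"1:{(j + 1) * 1000}" for j in range(len(columns))],
        )
        markers = pd.DataFrame(
            {
                "marker_id": calls.columns,
                "chrom": "1",
                "pos_bp": [(j + 1) * 1000 for j in range(len(columns))],
            }
        )
        return mq.GenotypeMatrix(calls=calls, markers=markers)

    def test_rare_minor_genotype_dropped(self):
        # 4/33 = 0.121 <= 0.15 -> dropped
        rare = [P1] * 29 + [P2] * 4
        common = [P1] * 17 + [P2] * 16
        g = self._genotypes([rare, common])
        pruned, _ = mq.prune_informative_markers(g)
        assert pruned.n_markers == 1

    def test_adjacent_identical_columns_deduplicated(self):
        col = [P1] * 5 + [P2] * 5
        other = [P2] * 5 + [P1] * 5
        g = self._genotypes([col, col, other])
        pruned, _ = mq.prune_informative_markers(g)
        assert list(pruned.markers["pos_bp"]) == [1000, 3000]

    def test_pruning_is_idempotent(self, default_map):
        again, _ = mq.prune_informative_markers(default_map)
        pd.testing.assert_frame_equal(again.calls, default_map.calls)

    def test_all_markers_pruned_is_error(self):
        g = self._genotypes([[P1] * 10])
        with pytest.raises(ValueError, match="pruned"):
            mq.prune_informative_markers(g)

    def test_selected_region_pruned_from_default_map(self, default_genotypes, default_map):
        sel_chrom, sel_pos = default_genotypes.selected_locus
        near = default_map.markers[
            (default_map.markers["chrom"] == sel_chrom)
            & ((default_map.markers["pos_bp"] - sel_pos).abs() < 1_000_000)
        ]
        assert near.empty


class TestGenotypeRecovery:
    def test_post_imputation_accuracy_at_least_99_percent(
        self, default_genotypes, default_map
    ):
        """Expression-marker genotypes match simulation truth >= 99%."""
        n_tot = n_ok = 0
        for _, m in default_map.markers.iterrows():
            truth = truth_genotype_at(default_genotypes, m["chrom"], int(m["pos_bp"]))
            est = default_map.calls[m["marker_id"]]
            mask = est.notna() & truth.notna()
            n_tot += int(mask.sum())
            n_ok += int((est[mask] == truth[mask]).sum())
        assert n_tot > 4000
        assert n_ok / n_tot >= 0.99
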