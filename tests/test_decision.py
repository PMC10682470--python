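import warnings

import numpy as np
import pandas as pd
import pytest

from interactdeg.decision import (
    DecisionError,
    Thresholds,
    method_one,
    method_two,
    run_method_one,
    run_method_two,
)
from interactdeg.design import DesignSpec
from interactdeg.glm import NBGLM
from interactdeg.simulate import NBScenario, seven_cases, simulate_counts

T = Thresholds()


def _table(rows: dict) -> pd.DataFrame:
    """Build a minimal Wald-results table: {gene: (padj, lfc)}."""
    genes = list(rows)
    padj = [rows[g][0] for g in genes]
    lfc = [rows[g][1] for g in genes]
    return pd.DataFrame(
        {
            "contrast": "diet[WD]",
            "log2fc_raw": lfc,
            "log2fc_shrunk": lfc,
            "se": 0.1,
            "stat": np.asarray(lfc) / 0.1,
            "pvalue": padj,
            "padj": padj,
            "flag": "",
        },
        index=pd.Index(genes, name="gene_id"),
    )


class TestMethodOne:
    def test_rule_application(self):
        """Week-6-only effects are DEG; effects already present at week 3 are
        not; a non-significant week 6 is never DEG."""
        wk3 = _table({"a": (0.50, 0.10), "b": (0.01, 0.90), "c": (0.049, 0.60)})
        wk6 = _table({"a": (0.01, 1.00), "b": (0.001, 2.50), "c": (0.051, 0.90)})
        out = method_one(wk3, wk6, T)
        assert out.loc["a", "status"] == "deg_up"
        assert out.loc["b", "status"] == "not_deg"  # already DEG at reference
        assert out.loc["c", "status"] == "not_deg"  # week 6 not significant

    def test_direction_from_target_week(self):
        wk3 = _table({"g": (0.9, 0.0)})
        wk6 = _table({"g": (0.001, -1.2)})
        assert method_one(wk3, wk6, T).loc["g", "status"] == "deg_down"

    def test_same_direction_rule_keeps_opposite_reference_deg(self):
        """A gene down-regulated at week 3 but up at week 6 is excluded by
        the direction-agnostic rule yet kept by the per-direction variant."""
        wk3 = _table({"g": (0.001, -2.0)})
        wk6 = _table({"g": (0.001, +2.0)})
        assert method_one(wk3, wk6, T, ref_rule="any").loc["g", "status"] == "not_deg"
        assert (
            method_one(wk3, wk6, T, ref_rule="same_direction").loc["g", "status"]
            == "deg_up"
        )

    def test_missing_gene_excluded_with_warning(self):
        wk3 = _table({"a": (0.5, 0.0), "b": (0.5, 0.0)})
        wk6 = _table({"a": (0.5, 0.0)})
        with pytest.warns(RuntimeWarning, match="missing"):
            out = method_one(wk3, wk6, T)
        assert list(out.index) == ["a"]


class TestMethodTwo:
    @pytest.mark.parametrize(
        "padj, lfc, expected",
        [
            (0.001, 1.2, "deg_up"),
            (0.001, 0.30, "not_deg"),  # significant but not relevant
            (0.20, 2.0, "not_deg"),  # relevant but not significant
            (0.001, -1.2, "deg_down"),
        ],
    )
    def test_rule_application(self, padj, lfc, expected):
        out = method_two(_table({"g": (padj, lfc)}), T)
        assert out.loc["g", "status"] == expected

    def test_flagged_gene_is_not_deg(self):
        tab = _table({"g": (0.001, 3.0)})
        tab["flag"] = "degenerate_cell"
        out = method_two(tab, T)
        assert out.loc["g", "status"] == "not_deg"
        assert out.loc["g", "flag"] == "degenerate_cell"


class TestThresholdMonotonicity:
    def test_stricter_thresholds_never_add_degs(self):
        rng = np.random.default_rng(12)
        genes = {f"g{i}": (rng.uniform(0, 0.2), rng.normal(0, 1.5)) for i in range(60)}
        tab = _table(genes)
        base = method_two(tab, Thresholds(0.05, np.log2(1.5)))
        stricter_lfc = method_two(tab, Thresholds(0.05, 1.2))
        stricter_alpha = method_two(tab, Thresholds(0.01, np.log2(1.5)))
        base_deg = set(base.index[base.status != "not_deg"])
        for stricter in (stricter_lfc, stricter_alpha):
            deg = set(stricter.index[stricter.status != "not_deg"])
            assert deg <= base_deg

    def test_decisions_are_pure(self):
        tab = _table({"g": (0.01, 1.0)})
        a = method_two(tab, T)
        b = method_two(tab.copy(), T)
        pd.testing.assert_frame_equal(a, b)


class TestFullRuns:
    def test_case1_and_case6_end_to_end(self):
        datasets = {d.spec.case_id: d for d in seven_cases(seed=7)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d1 = run_method_one(datasets[1].counts, datasets[1].metadata)
            d6 = run_method_one(datasets[6].counts, datasets[6].metadata)
        assert d1.decisions.loc[datasets[1].signal_gene, "status"] == "not_deg"
        # case 6 flips sign; direction follows the (negative) week-6 effect
        assert d6.decisions.loc[datasets[6].signal_gene, "status"] == "deg_down"

    def test_case4_method_two_end_to_end(self):
        ds = [d for d in seven_cases(seed=7) if d.spec.case_id == 4][0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run = run_method_two(ds.counts, ds.metadata, target_week=6)
        assert run.decisions.loc[ds.signal_gene, "status"] == "deg_down"

    def test_week_relabel_negates_interaction(self):
        """Swapping which week is the reference negates the interaction
        estimate but leaves its magnitude (and the DEG call) unchanged."""
        ds = [d for d in seven_cases(seed=3) if d.spec.case_id == 2][0]
        counts, meta = ds.counts, ds.metadata
        res = NBGLM(counts, meta, DesignSpec.with_interaction()).fit()
        meta_swapped = meta.assign(weeks=meta.weeks.map({3: 6, 6: 3}))
        res_swapped = NBGLM(counts, meta_swapped, DesignSpec.with_interaction()).fit()
        a = res.params["diet[WD]:weeks[6]"]
        b = res_swapped.params["diet[WD]:weeks[6]"]
        assert np.allclose(a, -b, atol=1e-8)

    def test_null_data_deg_rate_near_zero(self):
        rng = np.random.default_rng(55)
        G = 300
        scenario = NBScenario.two_by_two(
            baseline_log2=rng.uniform(6, 10, G),
            dispersion=0.05,
            n_per_cell=6,
            seed=808,
        )
        counts, metadata = simulate_counts(scenario)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run = run_method_two(counts, metadata, target_week=6)
        assert (run.decisions.status != "not_deg").mean() <= 0.02

    def test_missing_diet_group_raises(self):
        ds = seven_cases(seed=0, n_per_cell=3)[0]
        sd_only = ds.metadata.index[
            (ds.metadata.weeks == 6) & (ds.metadata.diet == "SD")
        ]
        drop = ds.metadata.index.difference(sd_only, sort=False)
        keep = [s for s in ds.metadata.index if s in drop]
        counts = ds.counts[keep]
        meta = ds.metadata.loc[keep]
        with pytest.raises(DecisionError, match="diet group"):
            run_method_one(counts, meta)

    def test_invalid_thresholds(self):
        with pytest.raises(DecisionError):
            Thresholds(alpha_fdr=0.0)
        with pytest.raises(DecisionError):
            Thresholds(lfc_threshold=-1.0)
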