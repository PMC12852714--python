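import numpy as np
import pytest

from sigratio.datatypes import ClassificationThresholds, ExpressionMatrix, GeneSignature
from sigratio.errors import ComputationError, ValidationError
from sigratio.scoring import (
    classify_correlation,
    m1_m2_profile,
    ratio_score,
    score_panel,
    tier_table,
)
from sigratio.signatures import HIGH_RISK, M1, M2
from sigratio.simulate import ExpressionSimSpec, simulate_expression

RHO_GRID = [0.1, 0.26, 0.29, 0.30, 0.49, 0.50, 0.9]
P_GRID = [1e-4, 1e-3, 0.01, 0.049, 0.05, 0.5]


def hand_tier(rho: float, p: float) -> str:
    """Decision table transcribed by hand from the printed rules:
    weak |r| >= 0.26 & p < 0.001; moderate |r| >= 0.30 & p < 0.05;
    strong |r| >= 0.50 & p < 0.05; strongest satisfied tier wins."""
    mag, sign = abs(rho), ("pos" if rho > 0 else "neg")
    if mag >= 0.50 and p < 0.05:
        return f"strong_{sign}"
    if mag >= 0.30 and p < 0.05:
        return f"moderate_{sign}"
    if mag >= 0.26 and p < 0.001:
        return f"weak_{sign}"
    return "none"


class TestClassifyCorrelation:
    @pytest.mark.parametrize(
        "rho,p,expected",
        [
            (0.55, 0.001, "strong_pos"),
            (0.28, 0.0005, "weak_pos"),
            (0.28, 0.01, "none"),       # the printed rules' gap region
            (-0.31, 0.02, "moderate_neg"),
            (0.10, 0.9, "none"),
        ],
    )
    def test_published_examples(self, rho, p, expected):
        assert classify_correlation(rho, p) == expected

    @pytest.mark.parametrize("rho", [r for g in RHO_GRID for r in (g, -g)])
    @pytest.mark.parametrize("p", P_GRID)
    def test_full_truth_table(self, rho, p):
        assert classify_correlation(rho, p) == hand_tier(rho, p)

    @pytest.mark.parametrize("rho", [0.1, 0.27, 0.35, 0.6, 0.99])
    @pytest.mark.parametrize("p", P_GRID)
    def test_odd_in_rho(self, rho, p):
        pos = classify_correlation(rho, p)
        neg = classify_correlation(-rho, p)
        assert neg == pos.replace("_pos", "_neg") if pos != "none" else neg == "none"

    def test_relaxed_weak_closes_gap(self):
        thr = ClassificationThresholds().relaxed_weak()
        assert classify_correlation(0.28, 0.01, thr) == "weak_pos"

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            classify_correlation(1.5, 0.01)
        with pytest.raises(ValidationError):
            classify_correlation(0.5, -0.1)


def _matrix_with(genes: dict, n: int, rng) -> ExpressionMatrix:
    values = np.array([genes[g] for g in genes], dtype=float)
    return ExpressionMatrix(list(genes), [f"s{i}" for i in range(n)], values)


class TestRatioScore:
    def test_saturates_at_one_for_comonotone_plant(self, rng):
        n = 100
        base = rng.normal(size=n)
        data = {"CD24": base}
        for g in HIGH_RISK.genes:
            data[g] = base + rng.normal(scale=1e-3, size=n)
        expr = _matrix_with(data, n, rng)
        score = ratio_score(expr, "CD24", HIGH_RISK, "positive")
        assert score.ratio == 1.0 and score.denominator == 10

    def test_two_missing_genes_divide_by_eight(self, rng):
        n = 50
        data = {"CD24": rng.normal(size=n)}
        for g in HIGH_RISK.genes:
            if g not in ("ITGB", "UMPS"):
                data[g] = rng.normal(size=n)
        expr = _matrix_with(data, n, rng)
        score = ratio_score(expr, "CD24", HIGH_RISK, "positive")
        assert score.denominator == 8
        assert set(score.missing_genes) == {"ITGB", "UMPS"}

    def test_self_membership_divides_by_eleven(self, rng):
        n = 50
        data = {g: rng.normal(size=n) for g in (*M1.genes, *M2.genes)}
        expr = _matrix_with(data, n, rng)
        score = ratio_score(expr, "TREM2", M2, "positive")
        assert score.denominator == 11 and score.self_excluded

    def test_missing_ido1_divides_by_eleven(self, rng):
        n = 50
        data = {g: rng.normal(size=n) for g in M1.genes if g != "IDO1"}
        data["SIGLEC10"] = rng.normal(size=n)
        expr = _matrix_with(data, n, rng)
        score = ratio_score(expr, "SIGLEC10", M1, "positive")
        assert score.denominator == 11 and score.missing_genes == ("IDO1",)

    def test_null_data_scores_zero(self, rng):
        spec = ExpressionSimSpec("CD24", HIGH_RISK, 200, 0.0, 0, seed=7)
        expr, _ = simulate_expression(spec)
        assert ratio_score(expr, "CD24", HIGH_RISK, "positive").ratio == 0.0

    def test_invariant_under_increasing_per_gene_transform(self, rng):
        spec = ExpressionSimSpec("CD24", HIGH_RISK, 80, 0.6, 5, seed=3)
        expr, _ = simulate_expression(spec)
        base = ratio_score(expr, "CD24", HIGH_RISK, "positive")
        scales = rng.uniform(0.5, 2.0, size=expr.n_genes)[:, None]
        warped = ExpressionMatrix(
            expr.gene_ids, expr.sample_ids, np.exp(expr.values * scales)
        )
        assert ratio_score(warped, "CD24", HIGH_RISK, "positive").ratio == base.ratio

    def test_negative_tier_never_counts_positive(self, rng):
        n = 100
        base = rng.normal(size=n)
        data = {"CD24": base}
        for g in HIGH_RISK.genes:
            data[g] = -base + rng.normal(scale=1e-3, size=n)
        expr = _matrix_with(data, n, rng)
        assert ratio_score(expr, "CD24", HIGH_RISK, "positive").ratio == 0.0
        assert ratio_score(expr, "CD24", HIGH_RISK, "negative").ratio == 1.0

    def test_errors(self, rng):
        expr = _matrix_with({"A": rng.normal(size=10)}, 10, rng)
        with pytest.raises(ValidationError):
            ratio_score(expr, "CD24", HIGH_RISK)
        sig = GeneSignature("only_self", ("CD24",), "marker")
        expr2 = _matrix_with({"CD24": rng.normal(size=10)}, 10, rng)
        with pytest.raises(ComputationError):
            ratio_score(expr2, "CD24", sig)


class TestScorePanel:
    @pytest.fixture
    def grouped_expr(self, rng):
        n_per = {"SHH": 30, "Group3": 30, "Group4": 3}
        genes = {"CD24": None, "MKI67": None, **{g: None for g in HIGH_RISK.genes},
                 **{g: None for g in M1.genes}}
        samples, groups, cols = [], {}, []
        for lab, n in n_per.items():
            for i in range(n):
                sid = f"{lab}_{i}"
                samples.append(sid)
                groups[sid] = lab
                cols.append(rng.normal(size=len(genes)))
        return ExpressionMatrix(
            list(genes), samples, np.array(cols).T, sample_groups=groups
        )

    def test_cardinality_and_ordering(self, grouped_expr):
        table = score_panel(
            grouped_expr, ["CD24", "MKI67"], [HIGH_RISK, M1], per_subgroup=True
        )
        assert len(table) == 2 * 2 * 3
        assert list(table["gene"]) == sorted(table["gene"])

    def test_small_subgroup_flagged_not_dropped(self, grouped_expr):
        table = score_panel(grouped_expr, ["CD24"], [HIGH_RISK], per_subgroup=True)
        flagged = table[table["subgroup"] == "Group4"]
        assert len(flagged) == 1
        assert flagged["flag"].iloc[0] == "insufficient_samples"
        assert np.isnan(flagged["ratio"].iloc[0])

    def test_low_risk_defaults_to_negative_direction(self, grouped_expr):
        from sigratio.signatures import LOW_RISK

        # low_risk genes absent from this matrix -> just check direction column
        n = 30
        rng = np.random.default_rng(0)
        data = {"CD24": rng.normal(size=n)}
        data.update({g: rng.normal(size=n) for g in LOW_RISK.genes})
        expr = ExpressionMatrix(list(data), [f"s{i}" for i in range(n)],
                                np.array([data[g] for g in data]))
        table = score_panel(expr, ["CD24"], [LOW_RISK])
        assert table["direction"].iloc[0] == "negative"


class TestTierTable:
    def test_planted_strong_and_absent_cells(self, rng):
        n = 120
        base = rng.normal(size=n)
        expr = _matrix_with(
            {"SIGLEC10": base, "TREM2": base + rng.normal(scale=0.1, size=n),
             "P2RY12": rng.normal(size=n)},
            n, rng,
        )
        table = tier_table(expr, "SIGLEC10", ["TREM2", "P2RY12", "ITGA4", "SIGLEC10"])
        row = table.loc["all"]
        assert row["TREM2"] == "strong_pos"
        assert row["ITGA4"] == "absent"
        assert row["SIGLEC10"] == "self"
        assert row["P2RY12"] in ("none", "weak_pos", "weak_neg")


class TestM1M2Profile:
    def test_planted_m2_skew(self, rng):
        n = 150
        base = rng.normal(size=n)
        data = {"SIGLEC10": base}
        for g in M2.genes:
            data[g] = base + rng.normal(scale=0.3, size=n)
        for g in M1.genes:
            data[g] = rng.normal(size=n)
        expr = _matrix_with(data, n, rng)
        m1, m2 = m1_m2_profile(expr, "SIGLEC10")
        assert m2.ratio == 1.0 and m1.ratio <= 0.1
        assert m1.denominator == 12 and m2.denominator == 12
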