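"""Monte-Carlo power for main-effect vs interaction tests, and Method I vs II.

In a balanced 2x2 design the dummy-coded interaction estimate is a
difference of differences of cell means with variance ``4 sigma^2 / n`` per
cell, four times the variance of the main-effect estimate in the additive
model (``sigma^2 / n``).  Since power depends on effect/SE and the SE scales
as ``1/sqrt(n)``, detecting an interaction of a given size at equal power
requires four times the total sample size needed for a main effect of the
same size.  :func:`power_curve` measures this empirically for normal and NB
responses; :func:`interaction_sample_size_factor` estimates the 4x factor
directly as a variance ratio; :func:`compare_methods` tabulates the two DEG
calling procedures on the canonical case scenarios.

Tests default to the Wald z reference used throughout the package;
``use_t=True`` switches the normal-response mode to exact t references,
which the closed-form check :func:`analytic_power_normal` reproduces from
the noncentral t distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decision import Thresholds, run_method_one, run_method_two
from .simulate import NBScenario, seven_cases, simulate_counts
from .design import DesignSpec
from .glm import NBGLM


class PowerError(ValueError):
    pass


@dataclass(frozen=True)
class PowerGrid:
    """Monte-Carlo grid: one effect size, several per-cell sample sizes."""

    effect_size: float
    sample_sizes: tuple[int, ...]
    n_reps: int = 1000
    alpha: float = 0.05
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise PowerError("alpha must be in (0, 1)")
        if self.n_reps < 100:
            raise PowerError("n_reps must be at least 100 for reported estimates")
        if any(n < 2 for n in self.sample_sizes):
            raise PowerError("each cell needs at least 2 samples")


def _mc_se(p: float, n_reps: int) -> float:
    return float(np.sqrt(p * (1.0 - p) / n_reps))


def _normal_2x2_pvalues(
    rng, target: str, effect: float, sigma: float, n: int, n_reps: int, use_t: bool
) -> np.ndarray:
    """Vectorised 2x2 normal simulation via sufficient statistics.

    Cell means and the within-cell sum of squares are sufficient for the
    OLS contrasts; the main effect is tested in the additive model (whose
    residual sum of squares adds the unexplained interaction component),
    the interaction in the full model.
    """
    means = np.zeros(4)  # cells ordered (g0c0, g0c1, g1c0, g1c1)
    if target == "interaction":
        means[3] = effect
    elif target == "main_effect":
        means[2] += effect
        means[3] += effect
    else:
        raise PowerError("target must be 'main_effect' or 'interaction'")
    ybar = rng.normal(means, sigma / np.sqrt(n), size=(n_reps, 4))
    rss_within = sigma**2 * rng.chisquare(4 * (n - 1), size=n_reps)
    inter_hat = ybar[:, 3] - ybar[:, 2] - ybar[:, 1] + ybar[:, 0]
    if target == "interaction":
        est = inter_hat
        c_var = 4.0 / n
        rss, df = rss_within, 4 * n - 4
    else:
        est = ybar[:, [2, 3]].mean(axis=1) - ybar[:, [0, 1]].mean(axis=1)
        c_var = 1.0 / n
        rss = rss_within + n * inter_hat**2 / 4.0
        df = 4 * n - 3
    se = np.sqrt(rss / df * c_var)
    stat = est / se
    if use_t:
        return 2.0 * stats.t.sf(np.abs(stat), df)
    return 2.0 * stats.norm.sf(np.abs(stat))


def _nb_2x2_pvalues(
    seed: int, target: str, effect: float, n: int, n_reps: int, dispersion: float,
    baseline_log2: float,
) -> np.ndarray:
    """NB-response power: replicates are simulated as independent genes."""
    e3 = effect if target == "main_effect" else 0.0
    e6 = effect
    scenario = NBScenario.two_by_two(
        baseline_log2=np.full(n_reps, baseline_log2),
        diet_effect_wk3=e3,
        diet_effect_wk6=e6,
        dispersion=dispersion,
        n_per_cell=n,
        seed=seed,
    )
    counts, metadata = simulate_counts(scenario)
    if target == "main_effect":
        res = NBGLM(counts, metadata, DesignSpec.additive(), size_factors=1.0).fit()
        contrast = "diet[WD]"
    else:
        res = NBGLM(
            counts, metadata, DesignSpec.with_interaction(), size_factors=1.0
        ).fit()
        contrast = [c for c in res.params.columns if ":" in c][0]
    return res.wald_test(contrast, shrink=False)["pvalue"].to_numpy()


def power_curve(
    grid: PowerGrid,
    target: str = "interaction",
    response: str = "normal",
    use_t: bool = False,
    dispersion: float = 0.05,
    baseline_log2: float = float(np.log2(500.0)),
) -> pd.DataFrame:
    """Empirical power of the target coefficient's test across sample sizes.

    Returns one row per per-cell sample size with the rejection fraction and
    its Monte-Carlo standard error ``sqrt(p(1-p)/n_reps)``.
    """
    rows = []
    ss = np.random.SeedSequence(grid.seed)
    for n, child in zip(grid.sample_sizes, ss.spawn(len(grid.sample_sizes))):
        if response == "normal":
            rng = np.random.default_rng(child)
            p = _normal_2x2_pvalues(
                rng, target, grid.effect_size, grid.sigma, n, grid.n_reps, use_t
            )
        elif response == "nb":
            seed = int(child.generate_state(1)[0] % (2**31))
            p = _nb_2x2_pvalues(
                seed, target, grid.effect_size, n, grid.n_reps, dispersion, baseline_log2
            )
        else:
            raise PowerError("response must be 'normal' or 'nb'")
        power = float(np.mean(p < grid.alpha))
        rows.append(
            {
                "n_per_cell": n,
                "n_total": 4 * n,
                "power": power,
                "mc_se": _mc_se(power, grid.n_reps),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs.update(target=target, response=response, effect_size=grid.effect_size)
    return out


def analytic_power_normal(
    n_per_cell: int,
    effect: float,
    sigma: float = 1.0,
    target: str = "interaction",
    alpha: float = 0.05,
) -> float:
    """Closed-form power of the two-sided t-test from the noncentral t."""
    n = n_per_cell
    if target == "interaction":
        c_var, df = 4.0 / n, 4 * n - 4
    elif target == "main_effect":
        c_var, df = 1.0 / n, 4 * n - 3
    else:
        raise PowerError("target must be 'main_effect' or 'interaction'")
    ncp = effect / (sigma * np.sqrt(c_var))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def interaction_sample_size_factor(
    n_per_cell: int = 16, n_reps: int = 20000, sigma: float = 1.0, seed: int = 0
) -> float:
    """Empirical sample-size multiplier for equal interaction vs main power.

    Simulates the null balanced 2x2 normal model and returns the ratio of the
    Monte-Carlo variances of the interaction and main-effect OLS contrasts at
    the same total sample size.  Because power depends on effect/SE and the
    contrast variance scales as 1/n, this ratio is the factor by which the
    sample size must grow to detect an interaction with the power of an
    equally sized main effect; the theoretical value is exactly 4.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ybar = rng.normal(0.0, sigma / np.sqrt(n_per_cell), size=(n_reps, 4))
    inter = ybar[:, 3] - ybar[:, 2] - ybar[:, 1] + ybar[:, 0]
    main = ybar[:, [2, 3]].mean(axis=1) - ybar[:, [0, 1]].mean(axis=1)
    return float(np.var(inter) / np.var(main))


def compare_methods(
    cases=(1, 2, 3, 4, 5, 6, 7),
    n_reps: int = 50,
    thresholds: Thresholds = Thresholds(),
    seed: int = 0,
    **case_kwargs,
) -> pd.DataFrame:
    """Per-method empirical DEG rates on the canonical case scenarios.

    Each replicate regenerates the selected case datasets with a fresh seed
    and runs both full pipelines on them; the returned table reports, per
    case, each method's DEG rate for the signal gene with its Monte-Carlo
    standard error, alongside the true interaction effect (zero or not) and
    the expected decisions.
    """
    cases = tuple(cases)
    hits = {c: {"I": 0, "II": 0} for c in cases}
    spec_info = {}
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_reps):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        for ds in seven_cases(seed=rep_seed, **case_kwargs):
            if ds.spec.case_id not in hits:
                continue
            run_i = run_method_one(ds.counts, ds.metadata, thresholds=thresholds)
            run_ii = run_method_two(
                ds.counts, ds.metadata, target_week=6, thresholds=thresholds
            )
            if run_i.decisions.loc[ds.signal_gene, "status"] != "not_deg":
                hits[ds.spec.case_id]["I"] += 1
            if run_ii.decisions.loc[ds.signal_gene, "status"] != "not_deg":
                hits[ds.spec.case_id]["II"] += 1
            spec_info[ds.spec.case_id] = ds.spec
    rows = []
    for c in cases:
        spec = spec_info[c]
        rate_i = hits[c]["I"] / n_reps
        rate_ii = hits[c]["II"] / n_reps
        rows.append(
            {
                "case_id": c,
                "true_interaction": spec.true_interaction,
                "has_true_ie": abs(spec.true_interaction) > 1e-12,
                "expected_I": spec.expected_decision_I,
                "expected_II": spec.expected_decision_II,
                "deg_rate_I": rate_i,
                "mc_se_I": _mc_se(rate_i, n_reps),
                "deg_rate_II": rate_ii,
                "mc_se_II": _mc_se(rate_ii, n_reps),
            }
        )
    return pd.DataFrame(rows).set_index("case_id")
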