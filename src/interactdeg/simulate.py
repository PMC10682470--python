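"""Synthetic data with the exact statistical structure the analysis assumes.

Three generators are provided:

* :func:`simulate_linear` — the normal-response two-factor model
  ``y = mu + alpha*g + beta*c + gamma*g*c + eps`` behind interaction plots;
* :func:`simulate_counts` — NB-distributed count matrices for a factorial
  diet x week design with per-gene log2 cell means, gene-specific dispersion
  (variance ``mu + tau*mu^2``) and sample-specific size factors;
* :func:`seven_cases` — the seven canonical decision scenarios that separate
  the per-week method (Method I) from the interaction method (Method II).

A single integer seed expands deterministically into independent per-gene
substreams, so the same seed always yields bit-identical data and adding
genes never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

LOG2_1P5 = float(np.log2(1.5))

#: (week-3 multiplier, week-6 multiplier, expected Method I, expected Method II)
#: Diet effects are in units of the relevance threshold log2(1.5); entries with
#: magnitude >= 3 are "large" effects rescaled by ``effect_scale``.
CASE_TABLE: dict[int, tuple[float, float, str, str]] = {
    1: (0.3, 0.3, "not_deg", "not_deg"),   # neither week relevant, no IE
    2: (0.0, 3.0, "deg", "deg"),           # effect only at week 6
    3: (3.0, 9.0, "not_deg", "deg"),       # relevant both weeks, much larger at 6
    4: (3.0, -3.0, "not_deg", "deg"),      # sign change, both relevant
    5: (0.8, 1.2, "deg", "not_deg"),       # both near threshold, similar size
    6: (0.3, -3.0, "deg", "deg"),          # sign change, week 3 negligible
    7: (0.7, -0.7, "not_deg", "deg"),      # opposite sub-threshold effects, large IE
}


class ScenarioError(ValueError):
    pass


# ---------------------------------------------------------------------------
# normal-response model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearScenario:
    """Two-factor normal-response scenario.

    ``mu`` baseline mean, ``alpha`` group main effect, ``beta`` treatment
    main effect, ``gamma`` interaction, ``sigma`` residual SD, ``n_per_cell``
    samples per factor combination.  The cell mean at (g=1, c=1) is
    ``mu + alpha + beta + gamma``.
    """

    mu: float = 0.0
    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    sigma: float = 1.0
    n_per_cell: int = 5

    def __post_init__(self):
        if self.sigma <= 0:
            raise ScenarioError("sigma must be positive")
        if self.n_per_cell < 1:
            raise ScenarioError("n_per_cell must be at least 1")

    def cell_mean(self, g: int, c: int) -> float:
        return self.mu + self.alpha * g + self.beta * c + self.gamma * g * c


def simulate_linear(scenario: LinearScenario, seed: int) -> pd.DataFrame:
    """Simulate the balanced 2x2 normal model; columns group, treatment, response."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for g in (0, 1):
        for c in (0, 1):
            y = rng.normal(scenario.cell_mean(g, c), scenario.sigma, scenario.n_per_cell)
            rows.append(pd.DataFrame({"group": g, "treatment": c, "response": y}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# NB count model
# ---------------------------------------------------------------------------

@dataclass
class NBScenario:
    """Factorial NB count scenario.

    ``cell_log2_means`` is genes x cells with the log2 expected concentration
    of each gene in each (diet, week) cell (the linear-predictor value, i.e.
    intercept plus the active main and interaction effects).  ``cells`` names
    the columns as (diet, week) pairs.  Counts are drawn as
    ``K ~ NB(mean = s_j * 2^m, var = mean + tau * mean^2)``.
    """

    cell_log2_means: np.ndarray
    dispersion: np.ndarray | float = 0.05
    cells: tuple[tuple[str, int], ...] = (("SD", 3), ("WD", 3), ("SD", 6), ("WD", 6))
    n_per_cell: np.ndarray | int = 5
    size_factors: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        self.cell_log2_means = np.atleast_2d(np.asarray(self.cell_log2_means, float))
        n_genes, n_cells = self.cell_log2_means.shape
        if n_cells != len(self.cells):
            raise ScenarioError(
                f"cell_log2_means has {n_cells} columns but {len(self.cells)} cells declared"
            )
        if not np.isfinite(self.cell_log2_means).all():
            raise ScenarioError("cell means must be finite")
        self.dispersion = np.broadcast_to(
            np.asarray(self.dispersion, float), (n_genes,)
        ).copy()
        if (self.dispersion <= 0).any():
            raise ScenarioError("all dispersions must be positive")
        self.n_per_cell = np.broadcast_to(
            np.asarray(self.n_per_cell, int), (n_cells,)
        ).copy()
        if (self.n_per_cell < 1).any():
            raise ScenarioError("n_per_cell must be at least 1 in every cell")
        n_samples = int(self.n_per_cell.sum())
        if self.size_factors is None:
            self.size_factors = np.ones(n_samples)
        else:
            self.size_factors = np.asarray(self.size_factors, float)
            if self.size_factors.shape != (n_samples,):
                raise ScenarioError(
                    f"size_factors must have length {n_samples} (total samples)"
                )
            if (self.size_factors <= 0).any():
                raise ScenarioError("all size factors must be positive")

    @property
    def n_genes(self) -> int:
        return self.cell_log2_means.shape[0]

    @classmethod
    def two_by_two(
        cls,
        baseline_log2,
        diet_effect_wk3=0.0,
        diet_effect_wk6=0.0,
        week_effect=0.0,
        dispersion=0.05,
        n_per_cell=5,
        size_factors=None,
        seed: int = 0,
        weeks: tuple[int, int] = (3, 6),
    ) -> "NBScenario":
        """Build a 2x2 (diet x week) scenario from per-gene effects.

        ``diet_effect_wk6 - diet_effect_wk3`` is the true interaction effect
        gamma_2 on the log2 scale.
        """
        b = np.atleast_1d(np.asarray(baseline_log2, float))
        e3 = np.broadcast_to(np.asarray(diet_effect_wk3, float), b.shape)
        e6 = np.broadcast_to(np.asarray(diet_effect_wk6, float), b.shape)
        w = np.broadcast_to(np.asarray(week_effect, float), b.shape)
        means = np.column_stack([b, b + e3, b + w, b + w + e6])
        cells = (("SD", weeks[0]), ("WD", weeks[0]), ("SD", weeks[1]), ("WD", weeks[1]))
        return cls(
            means,
            dispersion=dispersion,
            cells=cells,
            n_per_cell=n_per_cell,
            size_factors=size_factors,
            seed=seed,
        )


def _sample_ids(cells, n_per_cell) -> list[str]:
    ids = []
    for (diet, week), n in zip(cells, n_per_cell):
        ids.extend(f"{diet}_wk{week}_{k + 1}" for k in range(n))
    return ids


def simulate_counts(scenario: NBScenario) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a count matrix and matching sample metadata from an NB scenario.

    Returns ``(counts, metadata)`` with counts genes x samples and metadata
    indexed by sample with ``diet`` and ``weeks`` columns.  Identical seeds
    give bit-identical output.
    """
    means_per_sample = np.repeat(scenario.cell_log2_means, scenario.n_per_cell, axis=1)
    mu = scenario.size_factors[None, :] * np.exp2(means_per_sample)
    if (mu > 1e12).any():
        raise ScenarioError(
            "expected counts exceed 1e12; cell means are at overflow scale"
        )
    tau = scenario.dispersion
    ss = np.random.SeedSequence(scenario.seed)
    children = ss.spawn(scenario.n_genes)
    K = np.empty(mu.shape, dtype=np.int64)
    for g in range(scenario.n_genes):
        rng = np.random.default_rng(children[g])
        if tau[g] < 1e-8:
            K[g] = rng.poisson(mu[g])
        else:
            r = 1.0 / tau[g]
            K[g] = rng.negative_binomial(r, r / (r + mu[g]))
    samples = _sample_ids(scenario.cells, scenario.n_per_cell)
    genes = [f"gene{g + 1:05d}" for g in range(scenario.n_genes)]
    counts = pd.DataFrame(K, index=pd.Index(genes, name="gene_id"), columns=samples)
    diet = np.repeat([c[0] for c in scenario.cells], scenario.n_per_cell)
    weeks = np.repeat([c[1] for c in scenario.cells], scenario.n_per_cell)
    metadata = pd.DataFrame(
        {"diet": diet, "weeks": weeks.astype(int)},
        index=pd.Index(samples, name="sample"),
    )
    return counts, metadata


# ---------------------------------------------------------------------------
# the seven decision cases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CaseSpec:
    """One of the seven canonical scenarios with its expected decisions."""

    case_id: int
    week3_sd: float
    week3_wd: float
    week6_sd: float
    week6_wd: float
    expected_decision_I: str
    expected_decision_II: str

    def __post_init__(self):
        if self.case_id not in CASE_TABLE:
            raise ScenarioError("case_id must be in 1..7")

    @property
    def true_interaction(self) -> float:
        """True gamma_2 on the log2 scale implied by the cell means."""
        return (self.week6_wd - self.week6_sd) - (self.week3_wd - self.week3_sd)


class CaseDataset(NamedTuple):
    counts: pd.DataFrame
    metadata: pd.DataFrame
    spec: CaseSpec
    signal_gene: str


def seven_cases(
    effect_scale: float = 3.0 * LOG2_1P5,
    n_per_cell: int = 20,
    dispersion: float = 0.01,
    seed: int = 0,
    n_background: int = 200,
    baseline_log2: float = float(np.log2(1000.0)),
    relevance_threshold: float = LOG2_1P5,
    week_effect: float = 0.5,
) -> list[CaseDataset]:
    """Generate the seven canonical (Method I, Method II) decision scenarios.

    Each dataset holds one signal gene realising the case's diet effects at
    weeks 3 and 6 plus ``n_background`` background genes with heterogeneous
    baselines and diet effects (a quarter of them with their own interaction
    effects), mimicking a real experiment so that size factors, the BH
    family and the shrinkage prior behave as they would on full data.  All
    genes share one constant dispersion, the count-model analogue of
    constant residual variance, so decisions are driven by effect sizes
    alone.

    ``effect_scale`` sets the size of "clearly relevant" effects (default
    three times the relevance threshold); near-threshold effects in cases 5
    and 7 are fixed multiples of the threshold itself.  Expected decisions
    per case: (-,-), (D,D), (-,D), (-,D), (D,-), (D,D), (-,D).
    """
    if effect_scale <= relevance_threshold:
        raise ScenarioError("effect_scale must exceed the relevance threshold")
    t = relevance_threshold
    root = np.random.SeedSequence(seed)
    case_seeds = root.spawn(len(CASE_TABLE) + 1)
    bg_rng = np.random.default_rng(case_seeds[-1])
    bg_base = bg_rng.uniform(5.0, 11.0, n_background)
    # most background genes are null so median-of-ratios normalisation stays
    # anchored on them, as it is on real data; a minority carry diet effects
    # (and some of those an interaction) to keep the shrinkage prior wide
    bg_diet = np.where(
        bg_rng.random(n_background) < 0.30, bg_rng.normal(0.0, 0.8, n_background), 0.0
    )
    bg_ie = np.where(
        bg_rng.random(n_background) < 0.15, bg_rng.normal(0.0, 0.8, n_background), 0.0
    )
    sf = np.exp(bg_rng.normal(0.0, 0.15, 4 * n_per_cell))
    sf /= np.exp(np.mean(np.log(sf)))

    datasets = []
    for case_id, (m3, m6, exp_i, exp_ii) in CASE_TABLE.items():
        def scale(m):
            return m * t if abs(m) < 3 else np.sign(m) * (abs(m) / 3.0) * effect_scale

        e3, e6 = scale(m3), scale(m6)
        spec = CaseSpec(
            case_id=case_id,
            week3_sd=baseline_log2,
            week3_wd=baseline_log2 + e3,
            week6_sd=baseline_log2 + week_effect,
            week6_wd=baseline_log2 + week_effect + e6,
            expected_decision_I=exp_i,
            expected_decision_II=exp_ii,
        )
        means = np.empty((1 + n_background, 4))
        means[0] = [spec.week3_sd, spec.week3_wd, spec.week6_sd, spec.week6_wd]
        means[1:, 0] = bg_base
        means[1:, 1] = bg_base + bg_diet
        means[1:, 2] = bg_base + week_effect
        means[1:, 3] = bg_base + week_effect + bg_diet + bg_ie
        scenario = NBScenario(
            means,
            dispersion=dispersion,
            n_per_cell=n_per_cell,
            size_factors=sf,
            seed=int(case_seeds[case_id - 1].generate_state(1)[0] % (2**31)),
        )
        counts, metadata = simulate_counts(scenario)
        signal = f"case{case_id}_signal"
        counts.index = pd.Index(
            [signal] + [f"bg{k + 1:04d}" for k in range(n_background)], name="gene_id"
        )
        datasets.append(CaseDataset(counts, metadata, spec, signal))
    return datasets
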