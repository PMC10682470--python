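"""Comparing and characterising the DEG sets of the two methods.

* :func:`classify_region` — the effect-plane map: with x the estimated
  diet main effect at the reference week and y = x + IE the overall diet
  effect at the target week (both from the interaction model, unshrunken),
  the relevance-only decision rules carve the plane into four regions:
  DEG for neither method, Method I only, both, or Method II only.
* :func:`crosstab` — per-direction overlap tables of two decision sets.
* :func:`effect_arrows` — the fitted log2 cell means of one gene decomposed
  into intercept, main-effect and interaction contributions (the arrows of
  an interaction plot).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .decision import STATUS_DOWN, STATUS_UP
from .glm import NBGLMResults

REGION_NEITHER = "orange_neither"
REGION_I_ONLY = "green_I_only"
REGION_BOTH = "purple_both"
REGION_II_ONLY = "blue_II_only"


class ComparisonError(ValueError):
    pass


def classify_region(x, y, lfc_threshold: float):
    """Label points of the (main effect, main effect + IE) plane.

    Method I is relevance-DEG iff ``|x| <= t`` (no relevant effect at the
    reference week) and ``|y| > t`` (relevant overall effect at the target
    week); Method II iff ``|y - x| > t`` (relevant interaction).  Points on
    the diagonal have IE 0.  Scalar inputs give a scalar label, arrays an
    object array of labels.
    """
    if lfc_threshold <= 0:
        raise ComparisonError("lfc_threshold must be positive")
    x_arr = np.asarray(x, float)
    y_arr = np.asarray(y, float)
    if not (np.isfinite(x_arr).all() and np.isfinite(y_arr).all()):
        raise ComparisonError("region classification requires finite effects")
    t = float(lfc_threshold)
    deg_i = (np.abs(x_arr) <= t) & (np.abs(y_arr) > t)
    deg_ii = np.abs(y_arr - x_arr) > t
    labels = np.where(
        deg_i & deg_ii,
        REGION_BOTH,
        np.where(deg_i, REGION_I_ONLY, np.where(deg_ii, REGION_II_ONLY, REGION_NEITHER)),
    )
    if np.isscalar(x) and np.isscalar(y):
        return str(labels)
    return labels.astype(object)


def region_table(
    results: NBGLMResults,
    main_contrast: str,
    interaction_contrast: str,
    lfc_threshold: float,
    tests: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Per-gene region labels from an interaction-model fit.

    Uses unshrunken estimates and the relevance rule only; when per-contrast
    Wald tables are supplied their significance booleans are carried along so
    the full (p-value-aware) variant can be plotted.
    """
    x = results.params[main_contrast]
    y = x + results.params[interaction_contrast]
    ok = (results.flags == "") & np.isfinite(x) & np.isfinite(y)
    out = pd.DataFrame({"main_effect": x, "overall_effect": y}, index=results.params.index)
    out["region"] = pd.NA
    out.loc[ok, "region"] = classify_region(x[ok].to_numpy(), y[ok].to_numpy(), lfc_threshold)
    if tests is not None:
        for name, tab in tests.items():
            out[f"significant[{name}]"] = tab["padj"] < 0.05
    out.index.name = "gene_id"
    return out


def crosstab(decisions_a: pd.DataFrame, decisions_b: pd.DataFrame) -> pd.DataFrame:
    """Per-direction overlap counts of two DEG decision tables.

    Rows ``up``/``down``; columns ``a_only``, ``overlap``, ``b_only``.  Both
    tables must cover the same gene universe.
    """
    if not decisions_a.index.sort_values().equals(decisions_b.index.sort_values()):
        raise ComparisonError("decision tables cover different gene universes")
    rows = {}
    for direction, status in (("up", STATUS_UP), ("down", STATUS_DOWN)):
        a = set(decisions_a.index[decisions_a["status"] == status])
        b = set(decisions_b.index[decisions_b["status"] == status])
        rows[direction] = [len(a - b), len(a & b), len(b - a)]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["a_only", "overlap", "b_only"]
    )


def effect_arrows(results: NBGLMResults, gene_id) -> pd.DataFrame:
    """Arrow decomposition of one gene's fitted log2 cell means.

    One row per (diet, week) cell with the fitted log2 mean (q scale) and
    the additive contribution of every coefficient; the contributions sum
    exactly to the fitted mean.  Without an interaction term the diet arrow
    is identical in every week; with a saturated interaction design the
    fitted cell means reproduce the observed normalised cell means.
    """
    if gene_id not in results.params.index:
        raise ComparisonError(f"unknown gene {gene_id!r}")
    if results.flags.loc[gene_id] != "":
        raise ComparisonError(
            f"gene {gene_id!r} is flagged ({results.flags.loc[gene_id]}); "
            "arrows require a clean converged fit"
        )
    X = results.model.exog
    meta = results.model.metadata
    factors = [f.name for f in results.model.design.factors]
    cell_key = meta[factors].astype(str).agg("/".join, axis=1)
    coef = results.params.loc[gene_id]
    rows = []
    for key in pd.unique(cell_key):
        sample = cell_key.index[cell_key == key][0]
        xrow = X.loc[sample]
        contrib = xrow * coef
        rows.append(
            {"cell": key, **contrib.to_dict(), "fitted_log2_mean": float(contrib.sum())}
        )
    return pd.DataFrame(rows).set_index("cell")
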