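"""DEG calling by the per-week method (I) and the interaction method (II).

A gene is *significant* when its FDR-adjusted p-value is below
``alpha_fdr`` and *relevant* when its absolute log2 fold change exceeds
``lfc_threshold`` (strictly; default log2(1.5)).

Method I (separate): fit a one-factor ``~ diet`` model per week.  A gene is
DEG when its diet effect is both significant and relevant at the target
week (6) but not both at the reference week (3); the direction follows the
sign of the target-week diet effect.

Method II (interaction): fit one two-factor model with interaction.  A gene
is DEG when the interaction coefficient itself is both significant and
relevant; the direction follows the sign of the interaction effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .design import DesignSpec
from .filtering import subset_weeks
from .glm import NBGLM, NBGLMResults

LOG2_1P5 = float(np.log2(1.5))

STATUS_NOT_DEG = "not_deg"
STATUS_UP = "deg_up"
STATUS_DOWN = "deg_down"


class DecisionError(ValueError):
    pass


@dataclass(frozen=True)
class Thresholds:
    """Significance and relevance bounds for DEG calling."""

    alpha_fdr: float = 0.05
    lfc_threshold: float = LOG2_1P5

    def __post_init__(self):
        if not 0 < self.alpha_fdr < 1:
            raise DecisionError("alpha_fdr must be in (0, 1)")
        if self.lfc_threshold <= 0:
            raise DecisionError("lfc_threshold must be positive")


def _basis_lfc(table: pd.DataFrame, basis: str) -> pd.Series:
    if basis not in {"shrunk", "raw"}:
        raise DecisionError("lfc basis must be 'shrunk' or 'raw'")
    col = "log2fc_shrunk" if basis == "shrunk" else "log2fc_raw"
    return table[col]


def _sig_rel(table: pd.DataFrame, thresholds: Thresholds, basis: str):
    sig = table["padj"] < thresholds.alpha_fdr
    rel = _basis_lfc(table, basis).abs() > thresholds.lfc_threshold
    flagged = table["flag"].fillna("") != ""
    return sig.fillna(False) & ~flagged, rel.fillna(False) & ~flagged


def _status(deg: pd.Series, direction_lfc: pd.Series) -> pd.Series:
    status = pd.Series(STATUS_NOT_DEG, index=deg.index, dtype=object)
    status[deg & (direction_lfc > 0)] = STATUS_UP
    status[deg & (direction_lfc < 0)] = STATUS_DOWN
    return status


def method_one(
    results_ref_week: pd.DataFrame,
    results_target_week: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    basis: str = "shrunk",
    ref_rule: str = "any",
) -> pd.DataFrame:
    """Combine per-week Wald tables into Method I decisions.

    ``ref_rule`` controls how a DEG call at the reference week disqualifies
    a gene: ``"any"`` (default, matching the definition "not DEG for week 3")
    disqualifies on a reference-week DEG in either direction;
    ``"same_direction"`` disqualifies only when the reference effect points
    the same way as the target effect, the bookkeeping used for per-direction
    overlap tables.
    """
    if ref_rule not in {"any", "same_direction"}:
        raise DecisionError("ref_rule must be 'any' or 'same_direction'")
    common = results_ref_week.index.intersection(results_target_week.index)
    dropped = results_ref_week.index.symmetric_difference(results_target_week.index)
    if len(dropped):
        warnings.warn(
            f"{len(dropped)} gene(s) missing from one week's results were excluded",
            RuntimeWarning,
            stacklevel=2,
        )
    ref = results_ref_week.loc[common]
    tgt = results_target_week.loc[common]
    sig_ref, rel_ref = _sig_rel(ref, thresholds, basis)
    sig_tgt, rel_tgt = _sig_rel(tgt, thresholds, basis)
    deg_ref = sig_ref & rel_ref
    deg_tgt = sig_tgt & rel_tgt
    lfc_ref = _basis_lfc(ref, basis)
    lfc_tgt = _basis_lfc(tgt, basis)
    if ref_rule == "any":
        disqualified = deg_ref
    else:
        disqualified = deg_ref & (np.sign(lfc_ref) == np.sign(lfc_tgt))
    deg = deg_tgt & ~disqualified
    out = pd.DataFrame(
        {
            "method": "I",
            "status": _status(deg, lfc_tgt),
            "significant_ref": sig_ref,
            "relevant_ref": rel_ref,
            "significant_target": sig_tgt,
            "relevant_target": rel_tgt,
            "lfc_ref": lfc_ref,
            "lfc_target": lfc_tgt,
        },
        index=common,
    )
    out.index.name = "gene_id"
    return out


def method_two(
    interaction_results: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    basis: str = "shrunk",
) -> pd.DataFrame:
    """Method II decisions from the interaction-contrast Wald table."""
    sig, rel = _sig_rel(interaction_results, thresholds, basis)
    lfc = _basis_lfc(interaction_results, basis)
    deg = sig & rel
    out = pd.DataFrame(
        {
            "method": "II",
            "status": _status(deg, lfc),
            "significant": sig,
            "relevant": rel,
            "lfc_interaction": lfc,
            "flag": interaction_results["flag"],
        },
        index=interaction_results.index,
    )
    out.index.name = "gene_id"
    return out


class MethodRun(NamedTuple):
    """Decisions plus the underlying per-contrast Wald tables and fits."""

    decisions: pd.DataFrame
    tests: dict[str, pd.DataFrame]
    fits: dict[str, NBGLMResults]


def run_method_one(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    ref_week: int = 3,
    target_week: int = 6,
    thresholds: Thresholds = Thresholds(),
    basis: str = "shrunk",
    ref_rule: str = "any",
) -> MethodRun:
    """Full Method I: per-week one-factor fits, per-week BH, decision rule.

    The two weeks are treated as separate datasets: size factors and
    dispersions are re-estimated within each week's samples and the BH
    adjustment runs within each week's family of genes.
    """
    tests: dict[str, pd.DataFrame] = {}
    fits: dict[str, NBGLMResults] = {}
    for week in (ref_week, target_week):
        wk_counts, wk_meta = subset_weeks(counts, metadata, [week])
        diets = wk_meta["diet"].value_counts()
        if len(diets) < 2 or (diets < 2).any():
            raise DecisionError(
                f"week {week} needs at least two samples per diet group; got "
                f"{diets.to_dict()}"
            )
        res = NBGLM(wk_counts, wk_meta, DesignSpec.one_factor("diet")).fit()
        contrast = [c for c in res.params.columns if c.startswith("diet[")][0]
        tests[f"week{week}"] = res.wald_test(contrast)
        fits[f"week{week}"] = res
    decisions = method_one(
        tests[f"week{ref_week}"],
        tests[f"week{target_week}"],
        thresholds,
        basis=basis,
        ref_rule=ref_rule,
    )
    decisions.attrs.update(ref_week=ref_week, target_week=target_week)
    return MethodRun(decisions, tests, fits)


def run_method_two(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    weeks=None,
    target_week: int | None = None,
    thresholds: Thresholds = Thresholds(),
    basis: str = "shrunk",
) -> MethodRun:
    """Full Method II: one interaction fit, BH per interaction contrast.

    ``weeks`` restricts the samples (default: all weeks present); with
    ``target_week`` given, the returned decisions are for the interaction
    contrast of that week against the reference (smallest) week, otherwise
    for the first interaction contrast.  Tables for every interaction
    contrast are returned in ``tests``.
    """
    if weeks is not None:
        counts, metadata = subset_weeks(counts, metadata, weeks)
    if metadata["weeks"].nunique() < 2:
        raise DecisionError("Method II requires at least two weeks")
    res = NBGLM(counts, metadata, DesignSpec.with_interaction("diet", "weeks")).fit()
    inter_cols = [c for c in res.params.columns if ":" in c]
    tests = {c: res.wald_test(c) for c in inter_cols}
    if target_week is not None:
        wanted = [c for c in inter_cols if c.endswith(f"[{target_week}]")]
        if not wanted:
            raise DecisionError(
                f"no interaction contrast for week {target_week}; have {inter_cols}"
            )
        chosen = wanted[0]
    else:
        chosen = inter_cols[0]
    decisions = method_two(tests[chosen], thresholds, basis=basis)
    decisions.attrs.update(contrast=chosen)
    return MethodRun(decisions, tests, {"interaction": res})
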