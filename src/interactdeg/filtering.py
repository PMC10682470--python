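"""Gene filtering applied between data loading and model fitting.

Two rules are supported:

* ``max_zero_fraction`` (default threshold 0.5): remove genes whose fraction
  of zero-count samples exceeds the threshold.  "More than 50% zeros" is a
  strict inequality: a gene with zeros in exactly half the samples is kept.
* ``min_total_count`` (default threshold 10): remove genes whose total count
  over all samples is strictly below the threshold.

The zero-fraction rule is the recommended default; filtering only on a small
total count leaves genes whose effect estimates pile up at artifactual values.
Filtering is applied after any week subsetting so the rule sees exactly the
samples that enter the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

FILTER_KINDS = ("max_zero_fraction", "min_total_count")


class FilterError(ValueError):
    pass


@dataclass(frozen=True)
class FilterRule:
    kind: str = "max_zero_fraction"
    threshold: float = 0.5

    def __post_init__(self):
        if self.kind not in FILTER_KINDS:
            raise FilterError(f"unknown filter kind {self.kind!r}; choose from {FILTER_KINDS}")
        if self.threshold < 0:
            raise FilterError("filter threshold must be nonnegative")
        if self.kind == "max_zero_fraction" and not 0 <= self.threshold <= 1:
            raise FilterError("max_zero_fraction threshold must be in [0, 1]")


def filter_genes(
    counts: pd.DataFrame, rule: FilterRule = FilterRule()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply a filter rule; returns (kept counts, removal report).

    The report has one row per removed gene with columns ``gene_id`` and
    ``reason``.  Kept and removed genes partition the input.
    """
    if rule.kind == "max_zero_fraction":
        zero_frac = (counts == 0).mean(axis=1)
        keep = zero_frac <= rule.threshold
        reason = zero_frac.map(lambda f: f"zero fraction {f:.3f} > {rule.threshold}")
    else:
        totals = counts.sum(axis=1)
        keep = totals >= rule.threshold
        reason = totals.map(lambda t: f"total count {t} < {rule.threshold:g}")
    report = pd.DataFrame(
        {"gene_id": counts.index[~keep], "reason": reason[~keep].to_numpy()}
    ).reset_index(drop=True)
    kept = counts.loc[keep]
    if kept.empty:
        raise FilterError(
            f"filter {rule.kind}={rule.threshold} removed every gene; relax the threshold"
        )
    return kept, report


def subset_weeks(
    counts: pd.DataFrame, metadata: pd.DataFrame, weeks
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict counts and metadata to samples from the given weeks."""
    weeks = [int(w) for w in weeks]
    known = set(metadata["weeks"])
    unknown = [w for w in weeks if w not in known]
    if unknown:
        raise FilterError(f"week(s) {unknown} not present in metadata (have {sorted(known)})")
    keep = metadata["weeks"].isin(weeks)
    samples = metadata.index[keep]
    return counts[list(samples)], metadata.loc[samples]
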