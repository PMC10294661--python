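"""Volcano-style differential-expression classification and qPCR
standard-curve quantification.

Differential-expression tables (gene, log2 fold change, P value) are consumed
as input — the upstream count model fit is out of scope — and classified with
the conventional volcano thresholds: up means log2FC strictly above the cutoff
(default 1) with P at or below the cutoff (default 0.01); down mirrors it.

qPCR quantities are calibrated absolutely: a genomic-DNA dilution series gives
a per-primer-pair standard curve Cq = slope * log10(quantity) + intercept,
whose slope encodes the amplification efficiency E = 10^(-1/slope) - 1
(slope -3.3219 means perfect doubling).  Sample Cq values are inverted through
the curve to starting quantities (SQ), divided by the reference gene's SQ, and
normalized so the baseline group's mean relative expression is exactly 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "log2fc_to_fc",
    "volcano_classify",
    "fit_standard_curve",
    "cq_to_sq",
    "sq_to_cq",
    "relative_expression",
    "classification_counts",
    "qpcr_quantify",
    "naive_de_table",
]


def log2fc_to_fc(x: float) -> float:
    """Convert a log2 fold change to a linear fold change (2**x)."""
    if not math.isfinite(x):
        raise ValueError("log2 fold change must be finite")
    return 2.0**x


def volcano_classify(
    table: pd.DataFrame, lfc_gt: float = 1.0, p_le: float = 0.01
) -> pd.DataFrame:
    """Classify genes as up / down / ns by volcano thresholds.

    Strict inequality on |log2fc| ("above 1"), inclusive on the P value
    ("P <= 0.01").  Expects columns ``gene``, ``log2fc`` and ``p_value``;
    returns a copy with a ``class`` column.
    """
    required = {"gene", "log2fc", "p_value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    p = table["p_value"].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p_value entries must lie in [0, 1]")
    lfc = table["log2fc"].to_numpy(dtype=float)
    sig = p <= p_le
    out = table.copy()
    out["class"] = np.where(
        sig & (lfc > lfc_gt), "up", np.where(sig & (lfc < -lfc_gt), "down", "ns")
    )
    return out


def classification_counts(classified: pd.DataFrame) -> dict[str, int]:
    counts = classified["class"].value_counts().to_dict()
    return {k: int(counts.get(k, 0)) for k in ("up", "down", "ns")}


@dataclass
class StandardCurve:
    """Fitted qPCR standard curve: Cq = slope * log10(quantity) + intercept."""

    slope: float
    intercept: float
    efficiency: float
    r_squared: float


def fit_standard_curve(points: list[tuple[float, float]]) -> StandardCurve:
    """Ordinary least squares on (log10 quantity, Cq) dilution points."""
    if len(points) < 3:
        raise ValueError("standard curve needs at least 3 points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("standard curve needs at least 3 distinct quantities")
    fit = stats.linregress(x, y)
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency=float(efficiency),
        r_squared=float(fit.rvalue**2),
    )


def cq_to_sq(cq: float, curve: StandardCurve) -> float:
    """Starting quantity from a quantification cycle: 10^((Cq - b) / m)."""
    if curve.slope >= 0:
        raise ValueError("a valid standard curve has negative slope")
    return 10.0 ** ((cq - curve.intercept) / curve.slope)


def sq_to_cq(sq: float, curve: StandardCurve) -> float:
    """Inverse of :func:`cq_to_sq`."""
    if curve.slope >= 0:
        raise ValueError("a valid standard curve has negative slope")
    if sq <= 0:
        raise ValueError("starting quantity must be positive")
    return curve.slope * math.log10(sq) + curve.intercept


def relative_expression(
    target_sq: dict[str, float],
    ref_sq: dict[str, float],
    groups: dict[str, str],
    baseline_group: str,
    per_sample: bool = False,
) -> dict[str, float]:
    """Reference-normalized relative expression per group, baseline set to 1.

    Each sample's target SQ is divided by the mean reference SQ of that
    sample's group (or by its own reference SQ with ``per_sample=True``); group
    mean ratios are then normalized to the baseline group's mean ratio.
    """
    samples = list(target_sq)
    missing = [s for s in samples if s not in ref_sq or s not in groups]
    if missing:
        raise ValueError(f"samples missing reference SQ or group: {missing}")
    group_names = {}
    for s in samples:
        group_names.setdefault(groups[s], []).append(s)
    if baseline_group not in group_names:
        raise ValueError(f"baseline group {baseline_group!r} has no samples")

    ref_mean = {
        g: float(np.mean([ref_sq[s] for s in members])) for g, members in group_names.items()
    }
    for g, m in ref_mean.items():
        if m <= 0 and not per_sample:
            raise ValueError(f"reference SQ mean for group {g!r} is not positive")

    ratios = {}
    for s in samples:
        denom = ref_sq[s] if per_sample else ref_mean[groups[s]]
        if denom <= 0:
            raise ValueError(f"reference SQ for sample {s!r} is not positive")
        ratios[s] = target_sq[s] / denom

    group_mean = {
        g: float(np.mean([ratios[s] for s in members])) for g, members in group_names.items()
    }
    baseline = group_mean[baseline_group]
    if baseline == 0:
        raise ValueError("baseline group mean relative expression is zero")
    return {g: m / baseline for g, m in group_mean.items()}


def qpcr_quantify(
    cq_table: pd.DataFrame,
    standards: pd.DataFrame,
    target: str,
    reference: str,
    baseline_group: str,
    per_sample: bool = False,
) -> tuple[pd.DataFrame, dict[str, StandardCurve]]:
    """Full qPCR quantification: curves, SQ conversion, reference normalization.

    ``cq_table`` has columns sample, group, gene, cq (technical replicates as
    repeated rows; they are averaged to one Cq per sample and gene before SQ
    conversion).  ``standards`` has columns gene, log10_quantity, cq.  Returns
    a per-group relative-expression table (baseline group exactly 1) and the
    fitted per-gene standard curves.
    """
    for col in ("sample", "group", "gene", "cq"):
        if col not in cq_table.columns:
            raise ValueError(f"Cq table missing column {col!r}")
    for col in ("gene", "log10_quantity", "cq"):
        if col not in standards.columns:
            raise ValueError(f"standards table missing column {col!r}")

    curves: dict[str, StandardCurve] = {}
    for gene in (target, reference):
        pts = standards[standards["gene"] == gene]
        if pts.empty:
            raise ValueError(f"no standard-curve points for gene {gene!r}")
        curves[gene] = fit_standard_curve(list(zip(pts["log10_quantity"], pts["cq"])))

    mean_cq = cq_table.groupby(["sample", "gene"])["cq"].mean()
    groups = cq_table.drop_duplicates("sample").set_index("sample")["group"].to_dict()

    def sq_of(gene: str) -> dict[str, float]:
        out = {}
        for sample in groups:
            if (sample, gene) not in mean_cq.index:
                raise ValueError(f"sample {sample!r} lacks Cq values for gene {gene!r}")
            out[sample] = cq_to_sq(float(mean_cq[(sample, gene)]), curves[gene])
        return out

    rel = relative_expression(
        sq_of(target), sq_of(reference), groups, baseline_group, per_sample=per_sample
    )
    table = pd.DataFrame(
        {"group": list(rel), "relative_expression": [rel[g] for g in rel]}
    )
    return table, curves


def naive_de_table(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Simple per-gene DE table from a count matrix, for synthetic data only.

    Computes log2 of the ratio of group-mean CPM (with a pseudocount) and a
    pooled-variance two-sample t-test on log2 CPM.  This is a deliberately naive
    exercising path for volcano classification; it is not equivalent to a
    negative-binomial GLM fit and should not be used for real experiments.
    """
    for col in group_a + group_b:
        if col not in counts.columns:
            raise ValueError(f"sample {col!r} not in count matrix")
    lib = counts.sum(axis=0)
    cpm = counts / lib * 1e6
    log_cpm = np.log2(cpm + pseudocount)
    mean_a = cpm[group_a].mean(axis=1)
    mean_b = cpm[group_b].mean(axis=1)
    lfc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    t = stats.ttest_ind(log_cpm[group_b], log_cpm[group_a], axis=1)
    p = np.nan_to_num(t.pvalue, nan=1.0)
    return pd.DataFrame(
        {"gene": counts.index, "log2fc": lfc.to_numpy(), "p_value": p}
    ).reset_index(drop=True)
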