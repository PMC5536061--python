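"""Mixture-expectation and signed fold-change statistics for co-culture qPCR.

A 9/1 Caco-2 / HT29-MTX co-culture that behaved as a passive mixture would
express each gene at the seeding-weighted average of the monoculture means:

    expected = 0.9 * mean_Caco2 + 0.1 * mean_HT29MTX

Deviations of the observed co-culture mean from this expectation are
"emergent" regulation induced by the co-culture itself.  Fold changes are
signed with magnitude >= 1: positive ``observed/reference`` when the
observed mean is above the reference, negative ``-reference/observed``
otherwise, so swapping the two arguments flips the sign and keeps the
magnitude.  Integer rounding (half away from zero) is applied only at
reporting; raw folds stay in the data model.

Expression values are housekeeping-normalized ratios (target/HPRT1), so
"nd" (not detected) propagates as not-evaluable rather than zero.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .util import round_half_away_int

CACO2 = "Caco2"
HT29MTX = "HT29MTX"
COCULTURE = "CoCulture"


@dataclass(frozen=True)
class ExpressionMeasure:
    """Mean +/- SD of a gene's normalized expression in one condition."""

    gene: str
    condition: str
    mean: float | None
    sd: float | None
    n_reps: int
    detected: bool = True

    def __post_init__(self) -> None:
        if self.detected:
            if self.mean is None or self.mean < 0:
                raise ValidationError(f"{self.gene}/{self.condition}: mean must be >= 0")
            if self.sd is not None and self.sd < 0:
                raise ValidationError(f"{self.gene}/{self.condition}: sd must be >= 0")
        if self.n_reps < 0:
            raise ValidationError("n_reps must be >= 0")


def condition_means(table: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Aggregate a tidy replicate table (gene, condition, replicate, value)
    into per-(gene, condition) mean, sd, n and a detected flag.

    A gene/condition with all replicate values missing (NA) is marked not
    detected; its mean and sd are left missing.
    """
    required = {"gene", "condition", value_col}
    if not required.issubset(table.columns):
        raise ValidationError(f"replicate table needs columns {sorted(required)}")
    grouped = table.groupby(["gene", "condition"])[value_col]
    out = grouped.agg(mean="mean", sd="std", n="count").reset_index()
    out["detected"] = out["n"] > 0
    # single-replicate conditions have undefined sd; report 0 spread
    out.loc[out["n"] == 1, "sd"] = 0.0
    return out


def mixture_expectation(mean_a: float, mean_b: float, prop_a: float = 0.9) -> float:
    """Seeding-weighted mixture of two monoculture means."""
    if mean_a < 0 or mean_b < 0:
        raise ValidationError("expression means must be >= 0")
    if not 0.0 <= prop_a <= 1.0:
        raise ValidationError(f"mixture proportion must be in [0, 1], got {prop_a}")
    return prop_a * mean_a + (1.0 - prop_a) * mean_b


def signed_fold(observed: float, reference: float) -> float:
    """Signed fold change with magnitude >= 1.

    ``observed/reference`` when observed >= reference, else
    ``-reference/observed``.  Zero values are an error here: undetected
    genes must be filtered upstream via the ``detected`` flag.
    """
    if observed <= 0 or reference <= 0:
        raise ValidationError(
            "signed fold change requires strictly positive values "
            f"(got observed={observed}, reference={reference})"
        )
    if observed >= reference:
        return observed / reference
    return -reference / observed


def classify_regulation(fold: float, significant: bool, threshold: float = 2.0) -> str:
    """Direction call: ``up`` / ``down`` when the fold passes the threshold
    and the test is significant, else ``unchanged``."""
    if threshold < 1.0:
        raise ValidationError("fold threshold must be >= 1")
    if abs(fold) < 1.0:
        raise ValidationError("signed folds have magnitude >= 1 by construction")
    if significant and fold >= threshold:
        return "up"
    if significant and fold <= -threshold:
        return "down"
    return "unchanged"


@dataclass(frozen=True)
class MixtureFoldChange:
    """Observed co-culture expression versus the mixture expectation."""

    gene: str
    expected: float | None
    observed: float | None
    signed_fold: float | None
    rounded_fold: int | None
    direction: str
    evaluable: bool


def fc_vs_theoretical(
    means: pd.DataFrame,
    prop: float = 0.9,
    conditions: tuple[str, str, str] = (CACO2, HT29MTX, COCULTURE),
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Fold change of observed co-culture means versus the mixture
    expectation, per gene.

    ``means`` must carry columns gene, condition, mean, detected (as
    produced by :func:`condition_means`).  Genes with any required
    condition not detected are reported as not evaluable rather than
    failing the pipeline.  ``rounded_fold`` is the reporting integer
    (half away from zero); the raw fold is kept alongside.
    """
    cond_a, cond_b, cond_obs = conditions
    required = {"gene", "condition", "mean", "detected"}
    if not required.issubset(means.columns):
        raise ValidationError(f"means table needs columns {sorted(required)}")
    wide_mean = means.pivot(index="gene", columns="condition", values="mean")
    wide_det = means.pivot(index="gene", columns="condition", values="detected")
    rows = []
    def _has(gene: str, cond: str) -> bool:
        if cond not in wide_mean.columns or cond not in wide_det.columns:
            return False
        det = wide_det.loc[gene, cond]
        return pd.notna(det) and bool(det) and pd.notna(wide_mean.loc[gene, cond])

    for gene in wide_mean.index:
        if not all(_has(gene, c) for c in conditions):
            rows.append(MixtureFoldChange(gene, None, None, None, None, "not_evaluable", False))
            continue
        a, b, obs = (float(wide_mean.loc[gene, c]) for c in conditions)
        expected = mixture_expectation(a, b, prop)
        if expected <= 0 or obs <= 0:
            rows.append(MixtureFoldChange(gene, expected, obs, None, None, "not_evaluable", False))
            continue
        fold = signed_fold(obs, expected)
        rounded = round_half_away_int(fold)
        direction = classify_regulation(fold, significant=True, threshold=threshold)
        rows.append(MixtureFoldChange(gene, expected, obs, fold, rounded, direction, True))
    return pd.DataFrame(
        {
            "gene": [r.gene for r in rows],
            "expected": [r.expected for r in rows],
            "observed": [r.observed for r in rows],
            "signed_fold": [r.signed_fold for r in rows],
            "rounded_fold": pd.array([r.rounded_fold for r in rows], dtype="Int64"),
            "direction": [r.direction for r in rows],
            "evaluable": [r.evaluable for r in rows],
        }
    )


@dataclass(frozen=True)
class TreatmentFoldChange:
    """Signed fold of a treated condition versus its vehicle control."""

    gene: str
    dose: float
    signed_fold: float
    sd: float
    p_value: float
    significant: bool


def treatment_fold(
    treated: ExpressionMeasure,
    control: ExpressionMeasure,
    dose: float = 0.0,
    alpha: float = 0.05,
) -> TreatmentFoldChange:
    """Fold change of treated vs control means with delta-method spread and
    a two-sample Student t-test (Welch not assumed; classic pooled test,
    matching triplicate qPCR practice)."""
    for m in (treated, control):
        if not m.detected or m.mean is None:
            raise ValidationError(f"{m.gene}/{m.condition}: not detected, fold undefined")
        if m.n_reps < 1:
            raise ValidationError("treatment fold needs n_reps >= 1")
    if control.mean <= 0 or treated.mean <= 0:
        raise ValidationError("treatment fold requires positive means")
    fold = signed_fold(treated.mean, control.mean)
    sd_t = treated.sd or 0.0
    sd_c = control.sd or 0.0
    # first-order (delta-method) propagation of the two condition SDs
    rel = np.sqrt((sd_t / treated.mean) ** 2 + (sd_c / control.mean) ** 2)
    sd_fold = abs(fold) * rel
    if sd_t == 0.0 and sd_c == 0.0:
        p = 0.0 if treated.mean != control.mean else 1.0
    else:
        _, p = stats.ttest_ind_from_stats(
            treated.mean, sd_t, treated.n_reps,
            control.mean, sd_c, control.n_reps,
            equal_var=True,
        )
        p = float(p)
    return TreatmentFoldChange(
        gene=treated.gene,
        dose=dose,
        signed_fold=fold,
        sd=sd_fold,
        p_value=p,
        significant=bool(p < alpha),
    )


def treatment_folds_from_means(
    means: pd.DataFrame,
    treated_condition: str,
    control_condition: str,
    dose: float = 0.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene treatment folds from an aggregated condition-means table.

    Genes not detected in either condition are reported not evaluable.
    """
    rows = []
    for gene, sub in means.groupby("gene"):
        sub = sub.set_index("condition")
        try:
            t = sub.loc[treated_condition]
            c = sub.loc[control_condition]
        except KeyError:
            rows.append({"gene": gene, "dose": dose, "signed_fold": None, "sd": None,
                         "p_value": None, "significant": False, "evaluable": False})
            continue
        if not (bool(t["detected"]) and bool(c["detected"])) or pd.isna(t["mean"]) or pd.isna(c["mean"]):
            rows.append({"gene": gene, "dose": dose, "signed_fold": None, "sd": None,
                         "p_value": None, "significant": False, "evaluable": False})
            continue
        tm = ExpressionMeasure(gene, treated_condition, float(t["mean"]),
                               float(t["sd"]) if pd.notna(t["sd"]) else 0.0, int(t["n"]))
        cm = ExpressionMeasure(gene, control_condition, float(c["mean"]),
                               float(c["sd"]) if pd.notna(c["sd"]) else 0.0, int(c["n"]))
        fc = treatment_fold(tm, cm, dose=dose, alpha=alpha)
        rows.append({"gene": gene, "dose": dose, "signed_fold": fc.signed_fold, "sd": fc.sd,
                     "p_value": fc.p_value, "significant": fc.significant, "evaluable": True})
    return pd.DataFrame(rows)
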