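"""Monte-Carlo validation studies for the analysis stages.

These studies quantify, on synthetic data with known ground truth, how the
analysis modules behave: type-I calibration of the over-representation
screen under the null, recovery of a planted always-enriched pathway,
recovery of planted emergent-repression folds from noisy triplicates, and
the error of the proliferation-slope estimator.  They are the package's
own evidence for its statistical claims and double as its test surface.

All studies use the without-replacement (hypergeometric) variance for the
z statistic because the synthetic generator draws datasets without
replacement from the universe; see the methods note for why the
with-replacement default is a poor null model at dataset sizes comparable
to the universe.

The planted-pathway recovery study uses three datasets of size 579 (the
smaller phenotype-dataset scale): planting an overlap at 3x its expected
value is only feasible when the dataset is at most a third of the
universe (3 * n * K / N <= K requires n <= N/3), which excludes the
6038-gene dataset by arithmetic, and equal moderate sizes give the
screen uniform power across columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import coculture_expression as ccx
from .enrichment import _screen_core
from .rtca import RtcaTrace, linear_phase_slope
from .synthetic_data import SyntheticSpec, _study_indices, gen_qpcr_experiment, gen_rtca_traces


def _child_seeds(seed: int, n: int) -> list[int]:
    """Independent per-replicate seeds derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


@dataclass(frozen=True)
class CalibrationResult:
    flag_rate: float
    n_cells: int
    n_reps: int


def null_screen_calibration(
    seed: int,
    reps: int = 2000,
    dataset_sizes: tuple[int, ...] = (579, 1371, 6038),
    universe_size: int = 7000,
    pathway_count: int = 49,
    pathway_size: int = 133,
    confidence: float = 0.90,
    variance: str = "hypergeometric",
) -> CalibrationResult:
    """Fraction of screen cells flagged under the null generator
    (no planted enrichment); should match 1 - confidence."""
    spec = SyntheticSpec(
        seed=seed,
        universe_size=universe_size,
        dataset_sizes=dataset_sizes,
        pathway_count=pathway_count,
        pathway_size=pathway_size,
    )
    rng = np.random.default_rng(seed)
    flagged = 0
    cells = 0
    for _ in range(reps):
        pathways, datasets, _ = _study_indices(spec, rng)
        *_, flags = _screen_core(pathways, datasets, universe_size, confidence, variance)
        flagged += int(flags.sum())
        cells += flags.size
    return CalibrationResult(flag_rate=flagged / cells, n_cells=cells, n_reps=reps)


@dataclass(frozen=True)
class RecoveryResult:
    success_rate: float
    n_seeds: int
    n_planted_flagged: int


def planted_screen_recovery(
    seed: int,
    n_seeds: int = 100,
    multiplier: float = 3.0,
    dataset_sizes: tuple[int, ...] = (579, 579, 579),
    universe_size: int = 7000,
    pathway_count: int = 49,
    pathway_size: int = 133,
    confidence: float = 0.90,
    variance: str = "hypergeometric",
) -> RecoveryResult:
    """How often a pathway planted at ``multiplier`` x expected overlap in
    every dataset is the *unique* pathway significant in all datasets."""
    planted = {(0, di): multiplier for di in range(len(dataset_sizes))}
    successes = 0
    planted_flagged = 0
    for s in _child_seeds(seed, n_seeds):
        spec = SyntheticSpec(
            seed=s,
            universe_size=universe_size,
            dataset_sizes=dataset_sizes,
            pathway_count=pathway_count,
            pathway_size=pathway_size,
            planted_enrichment=planted,
        )
        rng = np.random.default_rng(s)
        pathways, datasets, _ = _study_indices(spec, rng)
        *_, flags = _screen_core(pathways, datasets, universe_size, confidence, variance)
        hits = np.flatnonzero(flags.all(axis=1))
        if flags[0].all():
            planted_flagged += 1
        if hits.size == 1 and hits[0] == 0:
            successes += 1
    return RecoveryResult(
        success_rate=successes / n_seeds, n_seeds=n_seeds,
        n_planted_flagged=planted_flagged,
    )


@dataclass(frozen=True)
class EmergenceRecoveryResult:
    per_gene_rate: dict[str, float]
    joint_rate: float
    n_seeds: int


def emergence_recovery(
    seed: int,
    n_seeds: int = 200,
    factors: dict[str, float] | None = None,
    cv: float = 0.05,
    reps: int = 3,
    mixture_prop: float = 0.9,
) -> EmergenceRecoveryResult:
    """How often planted emergent-repression divisors come back as the
    matching rounded fold (divisor f -> rounded fold -round(f); f = 1 ->
    rounded fold ±1).

    Defaults plant {1, 6, 8} on the goblet-marker-like genes (SOX9, TFF3,
    MUC2) whose co-culture repression the mixture analysis is built for.
    """
    if factors is None:
        factors = {"SOX9": 1.0, "TFF3": 6.0, "MUC2": 8.0}
    genes = list(factors)
    correct = {g: 0 for g in genes}
    joint = 0
    for s in _child_seeds(seed, n_seeds):
        spec = SyntheticSpec(
            seed=s, emergence_factors=factors, qpcr_cv=cv, reps=reps,
            mixture_prop=mixture_prop,
        )
        table, _ = gen_qpcr_experiment(spec)
        means = ccx.condition_means(table)
        fc = ccx.fc_vs_theoretical(means, prop=mixture_prop).set_index("gene")
        all_ok = True
        for g in genes:
            rounded = fc.loc[g, "rounded_fold"]
            f = factors[g]
            ok = (abs(int(rounded)) == 1) if f == 1.0 else (int(rounded) == -round(f))
            correct[g] += int(ok)
            all_ok &= ok
        joint += int(all_ok)
    return EmergenceRecoveryResult(
        per_gene_rate={g: c / n_seeds for g, c in correct.items()},
        joint_rate=joint / n_seeds,
        n_seeds=n_seeds,
    )


@dataclass(frozen=True)
class SlopeErrorResult:
    mean_abs_error: float
    mean_error: float
    n_reps: int


def slope_error_study(
    seed: int,
    n_reps: int = 100,
    sigma: float = 0.01,
    slope: float = 0.023,
    n_wells: int = 8,
) -> SlopeErrorResult:
    """Mean absolute / signed error of the linear-phase slope estimator on
    noisy synthetic traces, fit over the true linear window."""
    errors = []
    for s in _child_seeds(seed, n_reps):
        spec = SyntheticSpec(seed=s, growth_slope=slope, well_sigma=sigma,
                             n_wells=n_wells)
        table, truth = gen_rtca_traces(spec)
        trace = RtcaTrace.from_long(table)
        fit = linear_phase_slope(trace, window=truth.growth_window)
        errors.append(fit.slope - slope)
    errors = np.asarray(errors)
    return SlopeErrorResult(
        mean_abs_error=float(np.abs(errors).mean()),
        mean_error=float(errors.mean()),
        n_reps=n_reps,
    )
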