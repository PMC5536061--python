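"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the structure of the study inputs so all analyses
run offline:

* gene-set studies: phenotype datasets of the published sizes (579, 1371,
  6038, 103, 142) drawn from a 7000-gene universe, screened against 49
  pathway target-gene sets.  Default pathway size (133) is chosen so the
  expected pathway-union coverage of a random dataset is
  1 - (1 - 133/7000)^49 ~= 0.61, the coverage reported for the phenotype
  datasets.  Enrichment can be planted per (pathway, dataset) pair as a
  multiplier on the expected overlap; planted counts are exact (the
  overlap count is fixed first, then the remaining genes are filled in),
  so recovery can be scored without re-deriving anything.
* qPCR experiments: per-gene monoculture means (defaulting to the packaged
  reference panel), a 90/10 mixture expectation for the co-culture, an
  optional per-gene "emergent repression" divisor applied to that
  expectation, optional treated arms with planted signed folds, and
  triplicate replicates with multiplicative lognormal noise (SDs of qPCR
  ratios scale with the mean).
* RTCA traces: lag / linear / plateau growth per well with Gaussian
  noise and optional planted post-treatment dose effects on the delta
  cell index.

Identical seeds give identical outputs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import coculture_expression as ccx
from .exceptions import ValidationError
from .genesets import GeneSet, GeneUniverse
from .util import round_half_away_int

DEFAULT_DATASET_SIZES = (579, 1371, 6038, 103, 142)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters controlling all three generators.

    Only the fields relevant to the generator being called matter; the
    rest keep their defaults.
    """

    seed: int = 0

    # gene-set study
    universe_size: int = 7000
    dataset_sizes: tuple[int, ...] = DEFAULT_DATASET_SIZES
    pathway_count: int = 49
    pathway_size: int = 133
    planted_enrichment: Mapping[tuple[int, int], float] = field(default_factory=dict)
    coverage_target: float | None = 0.61

    # qPCR experiment
    mixture_prop: float = 0.9
    emergence_factors: Mapping[str, float] = field(default_factory=dict)
    treatment_folds: Mapping[str, float] = field(default_factory=dict)
    treatment_dose_uM: float = 60.0
    qpcr_cv: float = 0.10
    reps: int = 3
    qpcr_noise: str = "lognormal"

    # RTCA traces
    n_wells: int = 8
    well_sigma: float = 0.01
    baseline_ci: float = 0.3
    lag_h: float = 24.0
    growth_slope: float = 0.023
    plateau_ci: float = 4.5
    sample_interval_h: float = 0.25
    duration_h: float = 240.0
    doses_uM: tuple[float, ...] = (0.0,)
    dose_effects: Mapping[float, float] = field(default_factory=dict)
    t_treat_h: float | None = None
    t_eval_h: float | None = None

    def __post_init__(self) -> None:
        if self.universe_size <= 0 or self.pathway_count <= 0 or self.pathway_size <= 0:
            raise ValidationError("universe, pathway count and pathway size must be positive")
        if any(n <= 0 for n in self.dataset_sizes):
            raise ValidationError("dataset sizes must be positive")
        if any(n > self.universe_size for n in self.dataset_sizes):
            raise ValidationError("dataset sizes cannot exceed the universe size")
        if self.pathway_size >= self.universe_size:
            raise ValidationError("pathway size must be below the universe size")
        if any(m < 1.0 for m in self.planted_enrichment.values()):
            raise ValidationError("planted enrichment multipliers must be >= 1")
        if self.coverage_target is not None and not 0.0 < self.coverage_target < 1.0:
            raise ValidationError("coverage target must be in (0, 1)")
        if not 0.0 < self.mixture_prop < 1.0:
            raise ValidationError("mixture proportion must be in (0, 1)")
        if any(f <= 0 for f in self.emergence_factors.values()):
            raise ValidationError("emergence factors are positive divisors")
        if self.qpcr_cv < 0 or self.well_sigma < 0:
            raise ValidationError("noise levels must be >= 0")
        if self.reps < 1:
            raise ValidationError("replicate count must be >= 1")
        if self.qpcr_noise not in ("lognormal", "normal"):
            raise ValidationError("qpcr_noise must be 'lognormal' or 'normal'")


@dataclass
class GroundTruth:
    """Planted parameters, kept so recovery can be scored directly."""

    planted_overlaps: dict[tuple[int, int], int] = field(default_factory=dict)
    pathway_indices: list[np.ndarray] = field(default_factory=list)
    dataset_indices: list[np.ndarray] = field(default_factory=list)
    union_size: int | None = None
    coverage: list[float] = field(default_factory=list)
    true_means: pd.DataFrame | None = None
    emergence_factors: dict[str, float] = field(default_factory=dict)
    treatment_folds: dict[str, float] = field(default_factory=dict)
    growth_slope: float | None = None
    growth_window: tuple[float, float] | None = None
    dose_effects: dict[float, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Gene-set study


def _study_indices(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray], GroundTruth]:
    """Index-space core of the gene-set study generator.

    Shared with the Monte-Carlo study helpers so simulations sample
    exactly as :func:`gen_geneset_study` does.
    """
    N = spec.universe_size
    pathways = [
        np.sort(rng.choice(N, spec.pathway_size, replace=False))
        for _ in range(spec.pathway_count)
    ]
    union_mask = np.zeros(N, dtype=bool)
    for p in pathways:
        union_mask[p] = True
    U = np.flatnonzero(union_mask)
    comp = np.flatnonzero(~union_mask)

    # validate all planted pairs before any sampling
    planted_counts: dict[tuple[int, int], int] = {}
    for (pi, di), mult in spec.planted_enrichment.items():
        if not (0 <= pi < spec.pathway_count and 0 <= di < len(spec.dataset_sizes)):
            raise ValidationError(f"planted pair {(pi, di)} out of range")
        n = spec.dataset_sizes[di]
        K = len(pathways[pi])
        kstar = round_half_away_int(mult * n * K / N)
        if kstar > min(n, K):
            raise ValidationError(
                f"infeasible planting: multiplier {mult} on pathway {pi} / dataset {di} "
                f"needs overlap {kstar} > min(n={n}, K={K})"
            )
        planted_counts[(pi, di)] = kstar

    datasets: list[np.ndarray] = []
    coverage: list[float] = []
    for di, n in enumerate(spec.dataset_sizes):
        pairs = [(pi, planted_counts[(pi, di)])
                 for (pi, dj) in spec.planted_enrichment if dj == di]
        used = np.zeros(N, dtype=bool)
        blocked = np.zeros(N, dtype=bool)
        chosen_parts: list[np.ndarray] = []
        for pi, kstar in pairs:
            avail = pathways[pi][~used[pathways[pi]]]
            if avail.size < kstar:
                raise ValidationError(
                    f"infeasible planting: pathway {pi} overlaps earlier planted "
                    f"pathways too much to place {kstar} genes in dataset {di}"
                )
            sel = rng.choice(avail, kstar, replace=False)
            used[sel] = True
            blocked[pathways[pi]] = True
            chosen_parts.append(sel)
        chosen = (np.concatenate(chosen_parts) if chosen_parts
                  else np.empty(0, dtype=np.int64))

        if spec.coverage_target is not None:
            m = max(round_half_away_int(spec.coverage_target * n), chosen.size)
            pool_u = U[~blocked[U]]
            need_u = m - chosen.size
            need_out = n - m
            if need_u > pool_u.size or need_out > comp.size:
                raise ValidationError(
                    f"infeasible coverage target {spec.coverage_target} for dataset "
                    f"size {n} over a union of {U.size} genes"
                )
            fill_u = rng.choice(pool_u, need_u, replace=False)
            fill_out = rng.choice(comp, need_out, replace=False)
            idx = np.concatenate([chosen, fill_u, fill_out])
        else:
            pool = np.flatnonzero(~blocked & ~used)
            need = n - chosen.size
            if need > pool.size:
                raise ValidationError(f"dataset size {n} infeasible after planting")
            idx = np.concatenate([chosen, rng.choice(pool, need, replace=False)])
        idx = np.sort(idx)
        datasets.append(idx)
        coverage.append(float(union_mask[idx].mean()))

    truth = GroundTruth(
        planted_overlaps=planted_counts,
        pathway_indices=pathways,
        dataset_indices=datasets,
        union_size=int(U.size),
        coverage=coverage,
    )
    return pathways, datasets, truth


def universe_symbols(universe_size: int) -> list[str]:
    """Fixed-width symbols whose lexicographic order matches index order."""
    return [f"G{i:05d}" for i in range(universe_size)]


def gen_geneset_study(
    spec: SyntheticSpec,
) -> tuple[GeneUniverse, list[GeneSet], list[GeneSet], GroundTruth]:
    """Generate (universe, phenotype datasets, pathway sets, ground truth)."""
    rng = np.random.default_rng(spec.seed)
    pathways_idx, datasets_idx, truth = _study_indices(spec, rng)
    symbols = universe_symbols(spec.universe_size)
    universe = GeneUniverse(frozenset(symbols))
    datasets = [
        GeneSet(
            name=f"DATASET_{di + 1}",
            genes=frozenset(symbols[i] for i in idx),
            source=f"synthetic phenotype dataset, size {idx.size}, seed {spec.seed}",
        )
        for di, idx in enumerate(datasets_idx)
    ]
    pathways = [
        GeneSet(
            name=f"PATHWAY_{pi + 1:02d}",
            genes=frozenset(symbols[i] for i in idx),
            source=f"synthetic pathway target set, seed {spec.seed}",
        )
        for pi, idx in enumerate(pathways_idx)
    ]
    return universe, datasets, pathways, truth


# ---------------------------------------------------------------------------
# qPCR experiment


def _default_qpcr_panel() -> pd.DataFrame:
    """Reference gene panel: genes of the packaged expression fixture with
    both monoculture means detected."""
    t2 = reference_tables().expression
    panel = t2.dropna(subset=["caco2_mean", "ht29mtx_mean"])
    return panel[["gene", "caco2_mean", "ht29mtx_mean"]].reset_index(drop=True)


def gen_qpcr_experiment(
    spec: SyntheticSpec, panel: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a tidy replicate table (gene, condition, dose_uM,
    replicate, value) plus ground truth.

    The co-culture true mean is the mixture expectation divided by the
    gene's emergence factor (1 = passive mixture).  Treated arms (condition
    ``CoCulture_OA``) apply the planted signed fold to the co-culture true
    mean.  Replicates are perturbed multiplicatively (mean-preserving
    lognormal at the configured CV) or additively (``qpcr_noise="normal"``).
    """
    rng = np.random.default_rng(spec.seed)
    if panel is None:
        panel = _default_qpcr_panel()
    truth_rows = []
    data_rows = []

    def draw(mean: float) -> np.ndarray:
        if spec.qpcr_cv == 0.0:
            return np.full(spec.reps, mean)
        if spec.qpcr_noise == "lognormal":
            sigma = float(np.sqrt(np.log1p(spec.qpcr_cv ** 2)))
            return mean * np.exp(rng.normal(0.0, sigma, spec.reps) - sigma ** 2 / 2.0)
        return mean * (1.0 + rng.normal(0.0, spec.qpcr_cv, spec.reps))

    for _, row in panel.iterrows():
        gene = row["gene"]
        a, b = float(row["caco2_mean"]), float(row["ht29mtx_mean"])
        factor = float(spec.emergence_factors.get(gene, 1.0))
        co = ccx.mixture_expectation(a, b, spec.mixture_prop) / factor
        cond_means = {ccx.CACO2: a, ccx.HT29MTX: b, ccx.COCULTURE: co}
        doses = {ccx.CACO2: 0.0, ccx.HT29MTX: 0.0, ccx.COCULTURE: 0.0}
        if gene in spec.treatment_folds:
            fold = float(spec.treatment_folds[gene])
            if abs(fold) < 1.0:
                raise ValidationError("planted treatment folds have magnitude >= 1")
            treated = co * fold if fold > 0 else co / abs(fold)
            cond_means["CoCulture_OA"] = treated
            doses["CoCulture_OA"] = spec.treatment_dose_uM
        for cond, mean in cond_means.items():
            for r, v in enumerate(draw(mean), start=1):
                data_rows.append(
                    {"gene": gene, "condition": cond, "dose_uM": doses[cond],
                     "replicate": r, "value": float(v)}
                )
        truth_rows.append(
            {"gene": gene, "caco2": a, "ht29mtx": b, "coculture": co,
             "mixture_expectation": ccx.mixture_expectation(a, b, spec.mixture_prop),
             "emergence_factor": factor,
             "treatment_fold": spec.treatment_folds.get(gene, float("nan"))}
        )
    truth = GroundTruth(
        true_means=pd.DataFrame(truth_rows),
        emergence_factors=dict(spec.emergence_factors),
        treatment_folds=dict(spec.treatment_folds),
    )
    return pd.DataFrame(data_rows), truth


# ---------------------------------------------------------------------------
# RTCA traces


def _growth_curve(spec: SyntheticSpec, times: np.ndarray) -> np.ndarray:
    """Noise-free lag / linear / plateau cell-index curve."""
    t_plateau = spec.lag_h + (spec.plateau_ci - spec.baseline_ci) / spec.growth_slope
    ci = np.where(
        times < spec.lag_h,
        spec.baseline_ci,
        np.minimum(spec.baseline_ci + spec.growth_slope * (times - spec.lag_h),
                   spec.plateau_ci),
    )
    return ci


def gen_rtca_traces(spec: SyntheticSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate long-format cell-index traces (time_h, well, condition,
    dose_uM, cell_index) plus ground truth.

    Each dose group gets ``n_wells`` wells of the same lag/linear/plateau
    curve with i.i.d. Gaussian noise.  If treatment and evaluation times
    are set, a planted per-dose effect ramps the delta cell index linearly
    from the treatment time so that delta at the evaluation time is offset
    by exactly the planted amount (before noise).
    """
    if spec.growth_slope <= 0:
        raise ValidationError("growth slope must be positive")
    rng = np.random.default_rng(spec.seed)
    times = np.round(np.arange(0.0, spec.duration_h + 1e-9, spec.sample_interval_h), 6)
    base = _growth_curve(spec, times)
    rows = []
    for dose in spec.doses_uM:
        curve = base.copy()
        effect = float(spec.dose_effects.get(dose, 0.0))
        if effect != 0.0:
            if spec.t_treat_h is None or spec.t_eval_h is None:
                raise ValidationError("dose effects need t_treat_h and t_eval_h")
            i0 = int(np.searchsorted(times, spec.t_treat_h, side="right")) - 1
            ci0 = base[i0]
            ramp = np.clip((times - times[i0]) / (spec.t_eval_h - times[i0]), 0.0, None)
            curve = base + effect * ci0 * ramp
        noise = rng.normal(0.0, spec.well_sigma, size=(spec.n_wells, times.size)) \
            if spec.well_sigma > 0 else np.zeros((spec.n_wells, times.size))
        for w in range(spec.n_wells):
            ci = curve + noise[w]
            for t, v in zip(times, ci):
                rows.append(
                    {"time_h": float(t), "well": f"d{dose:g}_w{w + 1}",
                     "condition": "synthetic", "dose_uM": dose, "cell_index": float(v)}
                )
    t_plateau = spec.lag_h + (spec.plateau_ci - spec.baseline_ci) / spec.growth_slope
    truth = GroundTruth(
        growth_slope=spec.growth_slope,
        growth_window=(spec.lag_h, min(t_plateau, spec.duration_h)),
        dose_effects=dict(spec.dose_effects),
    )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Packaged reference fixtures


@dataclass(frozen=True)
class ReferenceTables:
    """Structured records of the packaged reference tables.

    ``datasets_info``: dataset names, sizes and provenance of the phenotype
    gene datasets.  ``overlaps``: pairwise common-gene counts with
    the printed reciprocal frequencies (``printed_discrepancy`` marks the
    one cell whose printed value is not reproducible from its count).
    ``expression``: per-gene qPCR condition means/SDs (``NaN`` = not detected)
    with the printed mixture fold-changes and treated-arm folds.
    """

    datasets_info: pd.DataFrame
    overlaps: pd.DataFrame
    expression: pd.DataFrame

    def expression_condition_means(self) -> pd.DataFrame:
        """Table 2 condition means in the aggregated-means layout consumed
        by the fold-change pipeline (n = 3 replicates per condition)."""
        cols = {
            ccx.CACO2: ("caco2_mean", "caco2_sd"),
            ccx.HT29MTX: ("ht29mtx_mean", "ht29mtx_sd"),
            ccx.COCULTURE: ("coculture_mean", "coculture_sd"),
        }
        rows = []
        for _, r in self.expression.iterrows():
            for cond, (mc, sc) in cols.items():
                detected = pd.notna(r[mc])
                rows.append(
                    {"gene": r["gene"], "condition": cond,
                     "mean": float(r[mc]) if detected else float("nan"),
                     "sd": float(r[sc]) if detected and pd.notna(r[sc]) else float("nan"),
                     "n": 3 if detected else 0, "detected": bool(detected)}
                )
        return pd.DataFrame(rows)


def reference_tables() -> ReferenceTables:
    """Load the packaged reference tables (no network access needed)."""
    data = importlib.resources.files("cocultrx.data")
    with importlib.resources.as_file(data / "reference_datasets.csv") as p:
        t1s = pd.read_csv(p)
    with importlib.resources.as_file(data / "reference_overlaps.csv") as p:
        t1o = pd.read_csv(p)
    with importlib.resources.as_file(data / "reference_expression.csv") as p:
        t2 = pd.read_csv(p)
    return ReferenceTables(datasets_info=t1s, overlaps=t1o, expression=t2)


def reference_overlap_sets() -> tuple[GeneUniverse, list[GeneSet]]:
    """Deterministic gene-level realization of the reference overlap matrix.

    Builds five gene sets over a 7000-symbol universe whose sizes and
    pairwise common-gene counts match the packaged fixture exactly.  Only
    pairwise counts are constrained (the printed matrix reports nothing
    deeper), so overlap regions are laid out pairwise-disjoint; this is
    feasible because the sizes minus all pairwise overlaps sum to 6864
    <= 7000.  The sets are synthetic stand-ins: real member identities
    were never published.
    """
    fx = reference_tables()
    sizes = dict(zip(fx.datasets_info["name"], fx.datasets_info["size"]))
    names = list(sizes)
    members: dict[str, list[str]] = {n: [] for n in names}
    symbols = universe_symbols(7000)
    cursor = 0

    def take(count: int) -> list[str]:
        nonlocal cursor
        block = symbols[cursor:cursor + count]
        if len(block) < count:
            raise ValidationError("universe too small for the fixture layout")
        cursor += count
        return block

    for _, row in fx.overlaps.iterrows():
        block = take(int(row["common"]))
        members[row["name_a"]].extend(block)
        members[row["name_b"]].extend(block)
    sets = []
    for name in names:
        remaining = sizes[name] - len(members[name])
        if remaining < 0:
            raise ValidationError(f"fixture set {name} overfilled")
        members[name].extend(take(remaining))
        sets.append(GeneSet(name=name, genes=frozenset(members[name]),
                            source="synthetic realization of the reference overlap matrix"))
    return GeneUniverse(frozenset(symbols)), sets
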