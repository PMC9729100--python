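"""Variant:WT' selection measurements, internal controls and depth guidance.

The assay's readout is the change in the variant:WT' read ratio between a
baseline point and one or more later points (time, compartment, or FACS
state — the arithmetic is identical).  Because every sample carries its
own internal normalization allele, the normalized fold change
(later ratio / baseline ratio) is invariant to the initial knock-in
stoichiometry; the frameshift-InDel:WT' ratio provides a built-in negative
selection control that guards against calling a variant neutral when no
selection pressure was present at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .quant import AlleleCategory, EditingProfile

__all__ = [
    "SampleRatio",
    "PointSummary",
    "SelectionResult",
    "PairedTestResult",
    "DepthRecommendation",
    "compute_ratios",
    "normalize_to_baseline",
    "paired_test",
    "frameshift_control",
    "recommend_depth",
    "simulate_power",
]


@dataclass(frozen=True)
class SampleRatio:
    """Variant:WT' and frameshift:WT' ratios for one sample.

    Ratios are undefined (None, ``undefined`` flag set) when the WT' count
    is zero; the 95% CI comes from a log-ratio normal approximation with a
    half-count correction for zero numerators.
    """

    sample_id: str
    point: str
    replicate: str
    variant_reads: int
    wtprime_reads: int
    frameshift_reads: int
    ratio_variant_wtprime: float | None
    ratio_frameshift_wtprime: float | None
    ratio_ci: tuple[float, float] | None
    undefined: bool = False


def _log_ratio_ci(a: int, b: int, z: float = 1.959964) -> tuple[float, float]:
    """95% CI for a count ratio a/b on the log scale (half-count corrected)."""
    a_, b_ = a + 0.5, b + 0.5
    log_r = math.log(a_ / b_)
    se = math.sqrt(1.0 / a_ + 1.0 / b_)
    return (math.exp(log_r - z * se), math.exp(log_r + z * se))


def compute_ratios(
    profile: EditingProfile, point: str = "", replicate: str = ""
) -> SampleRatio:
    """Read-count ratios of one editing profile."""
    v = profile.counts.get(AlleleCategory.VARIANT_KI, 0)
    w = profile.counts.get(AlleleCategory.WTPRIME_KI, 0)
    f = profile.counts.get(AlleleCategory.FRAMESHIFT_INDEL, 0)
    if w == 0:
        return SampleRatio(
            profile.sample_id, point, replicate, v, w, f, None, None, None, True
        )
    return SampleRatio(
        sample_id=profile.sample_id,
        point=point,
        replicate=replicate,
        variant_reads=v,
        wtprime_reads=w,
        frameshift_reads=f,
        ratio_variant_wtprime=v / w,
        ratio_frameshift_wtprime=f / w,
        ratio_ci=_log_ratio_ci(v, w),
    )


@dataclass
class PointSummary:
    """Normalized fold changes at one assay point, across replicates."""

    point: str
    folds: dict[str, float]          # replicate -> variant fold change
    control_folds: dict[str, float]  # replicate -> frameshift fold change
    mean: float
    sd: float
    control_mean: float | None
    control_sd: float | None


@dataclass
class SelectionResult:
    """Baseline-normalized selection measurement for one variant."""

    baseline_point: str
    points: list[PointSummary]
    excluded_replicates: list[str] = field(default_factory=list)
    verdicts: dict[str, str] = field(default_factory=dict)

    def point(self, name: str) -> PointSummary:
        for p in self.points:
            if p.point == name:
                return p
        raise KeyError(name)


def normalize_to_baseline(
    ratios: list[SampleRatio], baseline_point: str
) -> SelectionResult:
    """Per-replicate normalized fold changes relative to the baseline point.

    Each replicate's later-point ratio is divided by that replicate's
    baseline ratio, so the baseline maps to exactly 1 and the result is
    invariant to the initial variant:WT' stoichiometry.  Replicates lacking
    a defined baseline ratio are excluded with a warning entry.
    """
    by_rep: dict[str, dict[str, SampleRatio]] = {}
    for r in ratios:
        by_rep.setdefault(r.replicate, {})[r.point] = r

    excluded = []
    usable: dict[str, dict[str, SampleRatio]] = {}
    for rep, pts in by_rep.items():
        base = pts.get(baseline_point)
        if base is None or base.undefined or base.ratio_variant_wtprime == 0:
            excluded.append(rep)
            continue
        usable[rep] = pts

    point_names: list[str] = []
    for r in ratios:
        if r.point != baseline_point and r.point not in point_names:
            point_names.append(r.point)

    points = []
    for name in point_names:
        folds: dict[str, float] = {}
        control: dict[str, float] = {}
        for rep, pts in usable.items():
            later = pts.get(name)
            if later is None or later.undefined:
                continue
            base = pts[baseline_point]
            folds[rep] = later.ratio_variant_wtprime / base.ratio_variant_wtprime
            if base.ratio_frameshift_wtprime:
                control[rep] = (
                    later.ratio_frameshift_wtprime / base.ratio_frameshift_wtprime
                )
        vals = np.array(list(folds.values()), dtype=float)
        cvals = np.array(list(control.values()), dtype=float)
        points.append(
            PointSummary(
                point=name,
                folds=folds,
                control_folds=control,
                mean=float(vals.mean()) if vals.size else float("nan"),
                sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                control_mean=float(cvals.mean()) if cvals.size else None,
                control_sd=float(cvals.std(ddof=1)) if cvals.size > 1 else None,
            )
        )
    return SelectionResult(
        baseline_point=baseline_point, points=points, excluded_replicates=excluded
    )


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p_value: float
    significant: bool
    n: int
    zero_variance: bool = False
    alpha: float = 0.05


def paired_test(
    values_a: list[float],
    values_b: list[float],
    alpha: float = 0.05,
    log_scale: bool = False,
) -> PairedTestResult:
    """Two-tailed paired t-test on per-replicate values.

    Operates on the linear scale by default (matching the plotted
    quantities); ``log_scale=True`` tests log-transformed values, which is
    preferable for strongly skewed ratios.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 2:
        raise ValueError("paired t-test needs at least 2 replicates")
    if log_scale:
        a, b = np.log(a), np.log(b)
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0):
        return PairedTestResult(
            statistic=0.0 if np.allclose(diffs, 0) else math.inf,
            p_value=float("nan"),
            significant=False,
            n=a.size,
            zero_variance=True,
            alpha=alpha,
        )
    t, p = stats.ttest_rel(a, b)
    return PairedTestResult(
        statistic=float(t),
        p_value=float(p),
        significant=bool(p <= alpha),
        n=a.size,
        alpha=alpha,
    )


def frameshift_control(
    result: SelectionResult,
    neutral_band: tuple[float, float] = (0.7, 1.4),
    control_threshold: float = 0.67,
) -> SelectionResult:
    """Attach per-point verdicts using the frameshift-InDel internal control.

    A variant fold outside the neutral band is called enriched/depleted on
    its own.  Inside the band, "validated neutral" additionally requires
    the frameshift:WT' fold to drop below ``control_threshold`` — evidence
    that negative selection pressure was present and detectable.  When the
    control also stays near 1 the assay is inconclusive (no selection
    pressure), the guard against false-negative calls.
    """
    lo, hi = neutral_band
    for p in result.points:
        if math.isnan(p.mean):
            verdict = "inconclusive"
        elif p.mean > hi:
            verdict = "enriched"
        elif p.mean < lo:
            verdict = "depleted"
        elif p.control_mean is not None and p.control_mean < control_threshold:
            verdict = "validated_neutral"
        else:
            verdict = "inconclusive"
        result.verdicts[p.point] = verdict
    return result


def normalize_to_condition(
    point: PointSummary, reference: PointSummary, scale: float = 100.0
) -> dict[str, float]:
    """Express per-replicate folds relative to a reference condition.

    With the default scale the reference (e.g. vehicle) maps to 100%.
    """
    out = {}
    for rep, v in point.folds.items():
        if rep in reference.folds and reference.folds[rep] != 0:
            out[rep] = scale * v / reference.folds[rep]
    return out


# ---------------------------------------------------------------------------
# Sequencing-depth guidance


@dataclass(frozen=True)
class DepthRecommendation:
    """Reads per sample needed to resolve a fold change at given power.

    Guideline-grade normal approximation on the log fold change of two
    pairs of binomial counts; ``clones`` is the number of knock-in cells
    tracked at the stated template mass (genome equivalents x frequency).
    """

    ki_frequency: float
    effect_size: float
    alpha: float
    power: float
    n_replicates: int
    recommended_reads: int
    clones: float
    feasible: bool


def _required_reads(
    ki_frequency: float, effect_size: float, alpha: float, power: float, n_replicates: int
) -> float:
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    # Var(log fold) = 1/v1 + 1/w1 + 1/v2 + 1/w2 with v1=w1=w2=N*f, v2=N*f*phi
    var_unit = (3.0 + 1.0 / effect_size) / ki_frequency
    return z**2 * var_unit / (n_replicates * math.log(effect_size) ** 2)


def recommend_depth(
    ki_frequency: float,
    effect_size: float,
    alpha: float = 0.05,
    power: float = 0.9,
    n_replicates: int = 1,
    gdna_ng: float = 100.0,
    pg_per_diploid_genome: float = 6.0,
    max_reads: int = 10_000_000,
) -> DepthRecommendation:
    """Recommend a per-sample read depth for a selection experiment.

    ``effect_size`` is the true normalized fold change to be distinguished
    from 1 with a two-sided test at level ``alpha``.  Recommended reads
    increase as the knock-in frequency decreases or the effect size
    approaches 1; unattainable settings return ``feasible=False``.
    """
    if not 0.0 < ki_frequency < 1.0:
        raise ValueError("ki_frequency must be in (0, 1)")
    if effect_size <= 0 or effect_size == 1.0:
        raise ValueError("effect_size must be positive and different from 1")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    n = _required_reads(ki_frequency, effect_size, alpha, power, n_replicates)
    n_rounded = int(math.ceil(n / 100.0) * 100)
    feasible = n_rounded <= max_reads
    ge = gdna_ng * 1000.0 / pg_per_diploid_genome
    return DepthRecommendation(
        ki_frequency=ki_frequency,
        effect_size=effect_size,
        alpha=alpha,
        power=power,
        n_replicates=n_replicates,
        recommended_reads=n_rounded if feasible else max_reads,
        clones=ge * ki_frequency,
        feasible=feasible,
    )


def simulate_power(
    reads: int,
    ki_frequency: float,
    effect_size: float,
    alpha: float = 0.05,
    n_sim: int = 10_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the log-ratio z-test at a given depth.

    Independent cross-check of :func:`recommend_depth`: draws baseline and
    later-point variant/WT' counts from binomials, tests
    |log fold| / SE > z(1 - alpha/2), and returns the rejection rate.
    """
    rng = np.random.default_rng(seed)
    f = ki_frequency
    v1 = rng.binomial(reads, f, n_sim).astype(float)
    w1 = rng.binomial(reads, f, n_sim).astype(float)
    v2 = rng.binomial(reads, min(f * effect_size, 1.0), n_sim).astype(float)
    w2 = rng.binomial(reads, f, n_sim).astype(float)
    v1 += 0.5
    w1 += 0.5
    v2 += 0.5
    w2 += 0.5
    log_fold = np.log(v2 / w2) - np.log(v1 / w1)
    se = np.sqrt(1 / v1 + 1 / w1 + 1 / v2 + 1 / w2)
    z_crit = stats.norm.ppf(1 - alpha / 2)
    return float(np.mean(np.abs(log_fold) / se > z_crit))
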