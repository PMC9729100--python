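"""Forward simulation of a variant:WT' knock-in selection experiment.

The generator emulates the study conditions of the assay end to end:

1. *editing* — each cell's two alleles independently receive a Cas9 cut
   with probability ``cut_probability``; a cut allele resolves into a
   categorical editing outcome.  The default outcome distribution makes
   frameshift InDels ~5-fold more frequent than variant knock-in and gives
   day-2 knock-in allele frequencies of ~8.5%, the regime reported for
   efficiently edited diploid lines;
2. *selection* — genotype classes grow exponentially with configurable
   per-day fitness multipliers, deterministically in expectation, with
   multinomial resampling at passaging days;
3. *sampling* — alleles are drawn into the genome-equivalent pool implied
   by the template mass, then into reads at the configured depth, with
   uniform per-base substitution errors and matching constant Phred
   qualities, written as standard FASTQ.

Every realization is paired with a truth table (genotype counts, true cell
ratios, emitted read counts) so recovery can be tested quantitatively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import Cassette
from .quant import AmpliconContext

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_editing",
    "simulate_selection",
    "emit_reads",
    "simulate_experiment",
    "fitness_for_fold",
]

CATEGORIES = ("unedited", "VARIANT_KI", "WTPRIME_KI", "FRAMESHIFT_INDEL", "INFRAME_INDEL")

DEFAULT_OUTCOMES = {
    "unedited": 0.25,
    "VARIANT_KI": 0.094,
    "WTPRIME_KI": 0.094,
    "FRAMESHIFT_INDEL": 0.470,
    "INFRAME_INDEL": 0.092,
}

DEFAULT_FRAMESHIFT_LENGTHS = {-1: 0.40, -2: 0.20, 1: 0.20, -4: 0.10, 2: 0.05, -7: 0.05}
DEFAULT_INFRAME_LENGTHS = {-3: 0.60, 3: 0.25, -6: 0.15}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated experiment.  The seed is mandatory."""

    seed: int
    n_cells: int = 50_000
    cut_probability: float = 0.9
    outcome_distribution: dict = field(default_factory=lambda: dict(DEFAULT_OUTCOMES))
    frameshift_lengths: dict = field(
        default_factory=lambda: dict(DEFAULT_FRAMESHIFT_LENGTHS)
    )
    inframe_lengths: dict = field(default_factory=lambda: dict(DEFAULT_INFRAME_LENGTHS))
    fitness: dict = field(
        default_factory=lambda: {c: 1.0 for c in ("variant", "wtprime", "frameshift", "inframe", "unedited")}
    )
    timepoints: tuple = (2, 12)
    passaging: dict = field(default_factory=lambda: {7: 50_000})
    gdna_ng: float = 100.0
    pg_per_diploid_genome: float = 6.0
    read_depth: int = 30_000
    error_rate: float = 0.003
    n_replicates: int = 3
    condition: str = ""
    # Optional explicit joint distribution over unordered category pairs;
    # overrides the per-allele independence model.
    joint_table: dict | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a random seed is required")
        for name, dist in (
            ("outcome_distribution", self.outcome_distribution),
            ("frameshift_lengths", self.frameshift_lengths),
            ("inframe_lengths", self.inframe_lengths),
        ):
            if any(p < 0 for p in dist.values()):
                raise ValueError(f"{name} has negative probabilities")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if not 0.0 <= self.cut_probability <= 1.0:
            raise ValueError("cut_probability must be in [0, 1]")
        if set(self.outcome_distribution) != set(CATEGORIES):
            raise ValueError(f"outcome_distribution must cover {CATEGORIES}")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        """Load a simulation config from YAML, coercing key/value types.

        InDel-length and passaging keys arrive as strings or ints depending
        on the YAML writer; both are accepted.
        """
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("frameshift_lengths", "inframe_lengths"):
            if key in raw:
                raw[key] = {int(k): float(v) for k, v in raw[key].items()}
        if "passaging" in raw:
            raw["passaging"] = {float(k): int(v) for k, v in raw["passaging"].items()}
        if "timepoints" in raw:
            raw["timepoints"] = tuple(raw["timepoints"])
        if "joint_table" in raw and raw["joint_table"] is not None:
            raw["joint_table"] = {
                tuple(k.split("|")): float(v) for k, v in raw["joint_table"].items()
            }
        return cls(**raw)

    def allele_types(self) -> list[tuple[str, int, float]]:
        """Marginal per-allele distribution as (category, indel_len, prob).

        Uncut alleles and cut-but-unedited alleles both read as WT.
        """
        p = self.cut_probability
        out = [("WT", 0, (1 - p) + p * self.outcome_distribution["unedited"])]
        out.append(("VARIANT_KI", 0, p * self.outcome_distribution["VARIANT_KI"]))
        out.append(("WTPRIME_KI", 0, p * self.outcome_distribution["WTPRIME_KI"]))
        for length, q in sorted(self.frameshift_lengths.items()):
            out.append(
                ("FRAMESHIFT_INDEL", length, p * self.outcome_distribution["FRAMESHIFT_INDEL"] * q)
            )
        for length, q in sorted(self.inframe_lengths.items()):
            out.append(
                ("INFRAME_INDEL", length, p * self.outcome_distribution["INFRAME_INDEL"] * q)
            )
        return out


@dataclass
class SimTruth:
    """Ground truth of one simulated sample."""

    day: float
    genotype_counts: pd.DataFrame  # columns a1, l1, a2, l2, count
    variant_wtprime_cell_ratio: float | None
    read_counts: dict | None = None

    @property
    def n_cells(self) -> float:
        return float(self.genotype_counts["count"].sum())


def _cell_ratio(pop: pd.DataFrame) -> float | None:
    has_v = (pop["a1"] == "VARIANT_KI") | (pop["a2"] == "VARIANT_KI")
    has_w = (pop["a1"] == "WTPRIME_KI") | (pop["a2"] == "WTPRIME_KI")
    v = pop.loc[has_v, "count"].sum()
    w = pop.loc[has_w, "count"].sum()
    return float(v / w) if w > 0 else None


def simulate_editing(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, SimTruth]:
    """Draw the biallelic genotype composition of the edited population.

    Under the default independence model each allele is cut and resolved
    independently; genotype counts follow a multinomial over ordered allele
    pairs.  With ``joint_table`` set, category pairs are drawn from the
    explicit joint distribution instead (InDel lengths still from the
    length distributions).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.joint_table is not None:
        pairs = []
        probs = []
        for (c1, c2), q in sorted(config.joint_table.items()):
            if q < 0:
                raise ValueError("joint_table has negative probabilities")
            pairs.append((c1, c2))
            probs.append(q)
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("joint_table must sum to 1")

        def expand(cat):
            if cat == "FRAMESHIFT_INDEL":
                items = sorted(config.frameshift_lengths.items())
            elif cat == "INFRAME_INDEL":
                items = sorted(config.inframe_lengths.items())
            else:
                return [(cat, 0, 1.0)]
            return [(cat, l, q) for l, q in items]

        types = []
        tprobs = []
        for (c1, c2), q in zip(pairs, probs):
            for a1, l1, q1 in expand(c1):
                for a2, l2, q2 in expand(c2):
                    types.append((a1, l1, a2, l2))
                    tprobs.append(q * q1 * q2)
    else:
        alleles = config.allele_types()
        types = []
        tprobs = []
        for a1, l1, p1 in alleles:
            for a2, l2, p2 in alleles:
                types.append((a1, l1, a2, l2))
                tprobs.append(p1 * p2)
    counts = rng.multinomial(config.n_cells, np.asarray(tprobs) / sum(tprobs))
    pop = pd.DataFrame(types, columns=["a1", "l1", "a2", "l2"])
    pop["count"] = counts.astype(float)
    pop = pop[pop["count"] > 0].reset_index(drop=True)
    truth = SimTruth(day=0.0, genotype_counts=pop.copy(), variant_wtprime_cell_ratio=_cell_ratio(pop))
    return pop, truth


_PRECEDENCE = ("variant", "wtprime", "frameshift", "inframe", "unedited")
_CAT_TO_CLASS = {
    "VARIANT_KI": "variant",
    "WTPRIME_KI": "wtprime",
    "FRAMESHIFT_INDEL": "frameshift",
    "INFRAME_INDEL": "inframe",
    "WT": "unedited",
}


def _cell_class(a1: str, a2: str) -> str:
    classes = {_CAT_TO_CLASS[a1], _CAT_TO_CLASS[a2]}
    for c in _PRECEDENCE:
        if c in classes:
            return c
    return "unedited"


def fitness_for_fold(fold: float, delta_days: float) -> float:
    """Per-day growth multiplier giving a target ratio fold over an interval."""
    return fold ** (1.0 / delta_days)


def simulate_selection(
    population: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> dict[float, SimTruth]:
    """Propagate the population and snapshot it at each timepoint.

    Growth is exponential in expectation: a genotype whose cell class has
    per-day fitness w is scaled by w**dt over an interval of dt days.
    At each passaging day the population is multinomially resampled down to
    the passaged cell number.  Neutral genotypes therefore keep their
    expected frequencies, and the expected variant:WT' ratio fold between
    days t1 and t2 is (w_variant / w_wtprime)**(t2 - t1).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    fitness = config.fitness
    if any(w < 0 for w in fitness.values()):
        raise ValueError("fitness multipliers must be non-negative")
    pop = population.copy()
    w = pop.apply(lambda r: fitness[_cell_class(r["a1"], r["a2"])], axis=1).to_numpy()

    events = sorted(
        [(float(d), "passage", n) for d, n in config.passaging.items()]
        + [(float(t), "snapshot", None) for t in config.timepoints]
    )
    truths: dict[float, SimTruth] = {}
    day = 0.0
    counts = pop["count"].to_numpy(dtype=float)
    for t, kind, arg in events:
        dt = t - day
        if dt < 0:
            raise ValueError("timepoints and passaging days must be non-negative")
        counts = counts * np.power(w, dt)
        day = t
        if kind == "passage":
            total = counts.sum()
            if total <= 0:
                raise ValueError("population extinct before passaging")
            counts = rng.multinomial(int(arg), counts / total).astype(float)
        else:
            snap = pop.copy()
            snap["count"] = counts
            snap = snap[snap["count"] > 0].reset_index(drop=True)
            truths[t] = SimTruth(
                day=t,
                genotype_counts=snap,
                variant_wtprime_cell_ratio=_cell_ratio(snap),
            )
    return truths


# ---------------------------------------------------------------------------
# Read emission

_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {65: 0, 67: 1, 71: 2, 84: 3}


def _allele_sequence(
    ctx: AmpliconContext, cut: int, category: str, indel_len: int, rng: np.random.Generator
) -> str:
    ref = ctx.reference
    if category == "WT":
        return ref
    if category == "VARIANT_KI":
        out = list(ref)
        for pos, _r, alt in ctx.variant_sites:
            if alt:
                out[pos] = alt
        return "".join(out)
    if category == "WTPRIME_KI":
        out = list(ref)
        for pos, _r, alt in ctx.wtprime_sites:
            if alt:
                out[pos] = alt
        return "".join(out)
    # InDel alleles, centered at the cut
    if indel_len < 0:
        k = -indel_len
        start = max(0, cut - k // 2)
        return ref[:start] + ref[start + k :]
    ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=indel_len))
    return ref[:cut] + ins + ref[cut:]


def _reads_with_errors(
    seq: str, n: int, error_rate: float, rng: np.random.Generator
) -> list[str]:
    if n == 0:
        return []
    idx = np.array([_BASE_INDEX[b] for b in seq.encode()], dtype=np.uint8)
    arr = np.tile(idx, (n, 1))
    if error_rate > 0:
        mask = rng.random(arr.shape) < error_rate
        shifts = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
        arr[mask] = (arr[mask] + shifts) % 4
    chars = _BASE_LUT[arr]
    return [row.tobytes().decode("ascii") for row in chars]


def emit_reads(
    population: pd.DataFrame,
    cassette: Cassette,
    config: SimConfig,
    out_fastq: str | Path,
    rng: np.random.Generator | None = None,
    read_depth: int | None = None,
) -> SimTruth:
    """Sample gDNA and sequencing reads from a population snapshot.

    Two-stage sampling: the allele pool implied by the genomic-DNA mass
    (2 x genome equivalents molecules) is drawn multinomially from the
    population allele frequencies, then reads are drawn from that finite
    pool.  Substitution errors are applied per base; qualities are constant
    at the Phred value matching the configured error rate.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    depth = config.read_depth if read_depth is None else read_depth
    ctx = AmpliconContext.from_cassette(cassette)
    cut = cassette.guide.cut_position - ctx.amplicon_start

    weights: dict[tuple[str, int], float] = {}
    for _, row in population.iterrows():
        for a, l in ((row["a1"], row["l1"]), (row["a2"], row["l2"])):
            weights[(a, int(l))] = weights.get((a, int(l)), 0.0) + row["count"]
    types = sorted(weights)
    probs = np.array([weights[t] for t in types], dtype=float)
    probs /= probs.sum()

    n_molecules = int(round(2 * config.gdna_ng * 1000.0 / config.pg_per_diploid_genome))
    pool = rng.multinomial(n_molecules, probs)
    out_fastq = Path(out_fastq)
    truth_counts: dict[str, int] = {}
    if depth == 0:
        out_fastq.write_text("")
        return SimTruth(
            day=math.nan,
            genotype_counts=population,
            variant_wtprime_cell_ratio=_cell_ratio(population),
            read_counts={},
        )
    reads_per_type = rng.multinomial(depth, pool / pool.sum())

    e = config.error_rate
    q = 40 if e <= 0 else min(40, int(round(-10.0 * math.log10(e))))
    qchar = chr(q + 33)
    i = 0
    with open(out_fastq, "w") as fh:
        for (cat, length), n in zip(types, reads_per_type):
            if n == 0:
                continue
            truth_counts[cat] = truth_counts.get(cat, 0) + int(n)
            seq = _allele_sequence(ctx, cut, cat, length, rng)
            for read in _reads_with_errors(seq, int(n), e, rng):
                fh.write(f"@sim_{i}_{cat}\n{read}\n+\n{qchar * len(read)}\n")
                i += 1
    return SimTruth(
        day=math.nan,
        genotype_counts=population,
        variant_wtprime_cell_ratio=_cell_ratio(population),
        read_counts=truth_counts,
    )


def simulate_experiment(
    config: SimConfig,
    cassette: Cassette,
    out_dir: str | Path,
) -> tuple[pd.DataFrame, dict]:
    """Run a full multi-replicate experiment and write FASTQs plus metadata.

    Returns the sample sheet (sample_id, replicate, point, condition,
    fastq_path, gdna_ng) and a {(replicate, day): SimTruth} map.  A truth
    TSV and the sample sheet are written alongside the FASTQs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    children = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    rows = []
    truths: dict[tuple[str, float], SimTruth] = {}
    for r, ss in enumerate(children, start=1):
        rng = np.random.default_rng(ss)
        rep = f"rep{r}"
        pop, _ = simulate_editing(config, rng)
        snaps = simulate_selection(pop, config, rng)
        for day, truth in snaps.items():
            point = f"day{day:g}"
            sample_id = f"{rep}_{point}"
            fastq = out_dir / f"{sample_id}.fastq"
            emitted = emit_reads(truth.genotype_counts, cassette, config, fastq, rng)
            truth.read_counts = emitted.read_counts
            truths[(rep, day)] = truth
            rows.append(
                {
                    "sample_id": sample_id,
                    "replicate": rep,
                    "point": point,
                    "condition": config.condition,
                    "fastq_path": str(fastq),
                    "gdna_ng": config.gdna_ng,
                }
            )
    sheet = pd.DataFrame(rows)
    sheet.to_csv(out_dir / "sample_sheet.tsv", sep="\t", index=False)
    truth_rows = []
    for (rep, day), t in truths.items():
        truth_rows.append(
            {
                "replicate": rep,
                "day": day,
                "n_cells": t.n_cells,
                "variant_wtprime_cell_ratio": t.variant_wtprime_cell_ratio,
                **{f"reads_{k}": v for k, v in (t.read_counts or {}).items()},
            }
        )
    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return sheet, truths
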