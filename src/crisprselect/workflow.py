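"""Sample-sheet driven analysis: single-variant and arrayed batch runs.

An arrayed (96-well style) experiment screens many variants in parallel,
one cassette per well group; the per-variant arithmetic is exactly the
single-variant pipeline, so a batch run over a combined sample sheet must
produce the same numbers as independent single runs.
"""

from __future__ import annotations

import pandas as pd

from .design import Cassette
from .quant import ClassifierConfig, quantify_sample
from .selection import SelectionResult, compute_ratios, frameshift_control, normalize_to_baseline

__all__ = ["select_samples", "batch_select"]


def select_samples(
    sheet: pd.DataFrame,
    cassette: Cassette,
    baseline_point: str,
    config: ClassifierConfig = ClassifierConfig(),
) -> SelectionResult:
    """Quantify every sample of a sheet and compute the selection result.

    The sheet needs columns sample_id, replicate, point, fastq_path and
    optionally gdna_ng.
    """
    ratios = []
    for _, row in sheet.iterrows():
        profile = quantify_sample(
            row["fastq_path"],
            cassette,
            config=config,
            gdna_ng=row.get("gdna_ng", 100.0),
            sample_id=row["sample_id"],
        )
        ratios.append(
            compute_ratios(profile, point=row["point"], replicate=row["replicate"])
        )
    return frameshift_control(normalize_to_baseline(ratios, baseline_point))


def batch_select(
    sheet: pd.DataFrame,
    cassettes: dict[str, Cassette],
    baseline_point: str,
    config: ClassifierConfig = ClassifierConfig(),
) -> dict[str, SelectionResult]:
    """Arrayed mode: one independent SelectionResult per variant.

    The sheet carries a ``variant`` column naming the cassette for each
    sample; results are independent of row order and of which other
    variants share the plate.
    """
    if "variant" not in sheet.columns:
        raise ValueError("arrayed sample sheet needs a 'variant' column")
    unknown = set(sheet["variant"]) - set(cassettes)
    if unknown:
        raise ValueError(f"no cassette supplied for variant(s): {sorted(unknown)}")
    out: dict[str, SelectionResult] = {}
    for variant_label in sorted(set(sheet["variant"])):
        sub = sheet[sheet["variant"] == variant_label]
        out[variant_label] = select_samples(
            sub, cassettes[variant_label], baseline_point, config
        )
    return out
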