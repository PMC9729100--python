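"""File formats: locus FASTA, annotation TSV, cassette bundles, sample sheets.

The annotation format is a 4-column TSV (locus_id, start, end,
frame_offset; 0-based half-open) preceded by a header line of the form
``#locus_id=<id>	strand=<+/->``.  A minimal GFF3 convenience importer maps
CDS features onto the same structure.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import Cassette
from .sequence import ReferenceLocus, VariantSpec

__all__ = [
    "read_locus",
    "write_locus",
    "read_annotation",
    "write_annotation",
    "annotation_from_gff",
    "cassette_to_dict",
    "write_cassette_bundle",
    "read_sample_sheet",
    "format_design_report",
]


def read_fasta_sequences(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_locus(fasta_path, annotation_path=None) -> ReferenceLocus:
    """Load a locus from FASTA (first record) plus optional annotation TSV."""
    rec = next(SeqIO.parse(str(fasta_path), "fasta"))
    segments, strand = (), "+"
    if annotation_path is not None:
        segments, strand = read_annotation(annotation_path)
    return ReferenceLocus(
        locus_id=rec.id,
        sequence=str(rec.seq).upper(),
        coding_segments=segments,
        strand_of_gene=strand,
    )


def write_locus(locus: ReferenceLocus, fasta_path, annotation_path=None) -> None:
    SeqIO.write(
        [SeqRecord(Seq(locus.sequence), id=locus.locus_id, description="")],
        str(fasta_path),
        "fasta",
    )
    if annotation_path is not None:
        write_annotation(locus, annotation_path)


def read_annotation(path) -> tuple[tuple[tuple[int, int, int], ...], str]:
    strand = "+"
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split("\t"):
                    if tok.startswith("strand="):
                        strand = tok.split("=", 1)[1]
                continue
            _locus_id, start, end, frame = line.split("\t")
            rows.append((int(start), int(end), int(frame)))
    return tuple(rows), strand


def write_annotation(locus: ReferenceLocus, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#locus_id={locus.locus_id}\tstrand={locus.strand_of_gene}\n")
        for s, e, f in locus.coding_segments:
            fh.write(f"{locus.locus_id}\t{s}\t{e}\t{f}\n")


def annotation_from_gff(path, locus_id: str | None = None):
    """CDS features of a GFF3 file as (coding_segments, strand).

    GFF coordinates (1-based inclusive) are converted to 0-based half-open;
    the GFF phase column maps directly onto the frame offset.
    """
    rows = []
    strand = "+"
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8 or fields[2] != "CDS":
                continue
            if locus_id is not None and fields[0] != locus_id:
                continue
            start, end = int(fields[3]) - 1, int(fields[4])
            strand = fields[6] if fields[6] in "+-" else "+"
            phase = int(fields[7]) if fields[7] in "012" else 0
            rows.append((start, end, phase))
    rows.sort()
    return tuple(rows), strand


# ---------------------------------------------------------------------------
# Cassette bundles


def cassette_to_dict(cassette: Cassette) -> dict:
    """YAML-serializable description of a designed cassette.

    Coordinates are reported 1-based inclusive.
    """

    def coords(interval):
        return {"start": interval[0] + 1, "end": interval[1]}

    def edit(spec: VariantSpec):
        return {
            "label": spec.label,
            "position": spec.position + 1,
            "ref": spec.ref_bases,
            "alt": spec.alt_bases,
            "class": spec.variant_class,
        }

    g = cassette.guide
    return {
        "locus_id": cassette.locus.locus_id,
        "variant": edit(cassette.variant),
        "wtprime": edit(cassette.wtprime_spec),
        "guide": {
            "protospacer": g.protospacer,
            "pam": g.pam,
            "strand": g.strand,
            "cut_position": g.cut_position + 1,
            "variant_distance_to_cut": g.variant_distance_to_cut,
            "disruption_positions": {
                str(k + 1): v for k, v in g.disruption_positions.items()
            },
        },
        "variant_ssodn": {
            "sequence": cassette.variant_ssodn.sequence,
            "polarity": cassette.variant_ssodn.polarity,
            "arm_lengths": [
                cassette.variant_ssodn.arm_5_len,
                cassette.variant_ssodn.arm_3_len,
            ],
            "region": coords(cassette.variant_ssodn.region),
        },
        "wtprime_ssodn": {
            "sequence": cassette.wtprime_ssodn.sequence,
            "polarity": cassette.wtprime_ssodn.polarity,
            "arm_lengths": [
                cassette.wtprime_ssodn.arm_5_len,
                cassette.wtprime_ssodn.arm_3_len,
            ],
            "region": coords(cassette.wtprime_ssodn.region),
        },
        "primers": {
            "forward": cassette.primers.forward,
            "reverse": cassette.primers.reverse,
            "forward_region": coords(cassette.primers.forward_region),
            "reverse_region": coords(cassette.primers.reverse_region),
            "product_length": cassette.primers.product_length,
            "offsets": [
                cassette.primers.forward_offset,
                cassette.primers.reverse_offset,
            ],
        },
        "design_report": [
            {"rule": r, "pass": bool(p), "detail": d} for r, p, d in cassette.design_report
        ],
    }


def format_design_report(cassette: Cassette) -> str:
    lines = [f"Design report: {cassette.variant.label or cassette.locus.locus_id}"]
    for rule, ok, detail in cassette.design_report:
        mark = "PASS" if ok else "FAIL"
        lines.append(f"  [{mark}] {rule}: {detail}")
    return "\n".join(lines)


def write_cassette_bundle(cassette: Cassette, out_dir) -> Path:
    """Write the cassette as YAML + oligo FASTA + plain-text report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "cassette.yaml", "w") as fh:
        yaml.safe_dump(cassette_to_dict(cassette), fh, sort_keys=False)
    records = [
        SeqRecord(Seq(cassette.guide.protospacer), id="protospacer", description=""),
        SeqRecord(
            Seq(cassette.variant_ssodn.sequence), id="variant_ssodn", description=""
        ),
        SeqRecord(
            Seq(cassette.wtprime_ssodn.sequence), id="wtprime_ssodn", description=""
        ),
        SeqRecord(Seq(cassette.primers.forward), id="primer_fwd", description=""),
        SeqRecord(Seq(cassette.primers.reverse), id="primer_rev", description=""),
    ]
    SeqIO.write(records, str(out_dir / "oligos.fasta"), "fasta")
    (out_dir / "design_report.txt").write_text(format_design_report(cassette) + "\n")
    return out_dir / "cassette.yaml"


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet TSV: sample_id, replicate, point, condition, fastq_path, gdna_ng."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "replicate": str})
    required = {"sample_id", "replicate", "point", "fastq_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if "condition" not in df.columns:
        df["condition"] = ""
    if "gdna_ng" not in df.columns:
        df["gdna_ng"] = 100.0
    return df
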