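"""Mutation-catalog and reference-sequence I/O, plus pyrimidine-oriented contexts.

Input coordinates are 1-based inclusive (VCF/MAF convention); all internal
interval arithmetic is 0-based half-open.  Every single base substitution
(SBS) is re-expressed with the mutated base as a pyrimidine: records whose
reference base is G or A are reverse-complemented, which is the standard
convention for mutation-signature channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MutationRecord:
    """One somatic single-base substitution with sample and condition labels."""

    sample_id: str
    condition: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(f"non-SBS alleles {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt are identical")
        if self.pos < 1:
            raise ValueError(f"position {self.pos} < 1")


class ReferenceSequence:
    """Uppercased contig sequences over {A,C,G,T,N} with derived lengths."""

    def __init__(self, contigs: Mapping[str, str]):
        if not contigs:
            raise ValueError("reference has no contigs")
        self.contigs: dict[str, str] = {
            name: seq.upper() for name, seq in contigs.items()
        }
        self.lengths: dict[str, int] = {
            name: len(seq) for name, seq in self.contigs.items()
        }

    @property
    def total_bp(self) -> int:
        return sum(self.lengths.values())

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self.contigs[chrom][pos - 1]

    def window(self, chrom: str, pos: int, flank: int) -> str | None:
        """(2*flank+1)-mer centred on a 1-based position, or None at a contig edge."""
        start = pos - 1 - flank
        end = pos + flank
        if start < 0 or end > self.lengths[chrom]:
            return None
        return self.contigs[chrom][start:end]

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class OrientedContext:
    """Pyrimidine-normalized k-mer context around a mutated base.

    ``kmer`` is the (2*flank+1)-mer with the mutated pyrimidine at the centre.
    ``strand`` is '+' when the reference base was already C/T and '-' when the
    record was reverse-complemented; in the latter case ``alt_oriented`` is the
    complement of the recorded alt allele.  ``flagged`` marks windows that
    overlap a contig edge or contain N; such contexts are excluded from motif
    statistics but keep their position for clustering-style analyses.
    """

    mutation: MutationRecord
    kmer: str
    strand: str
    alt_oriented: str
    flagged: bool = False

    @property
    def flank(self) -> int:
        return len(self.kmer) // 2

    @property
    def center(self) -> str:
        return self.kmer[self.flank]

    def base_at(self, offset: int) -> str:
        """Base at a signed offset from the mutated pyrimidine (-2..+2 etc.)."""
        return self.kmer[self.flank + offset]

    @property
    def substitution(self) -> str:
        """Pyrimidine-normalized substitution, e.g. 'C>T'."""
        return f"{self.center}>{self.alt_oriented}"

    @property
    def is_tc(self) -> bool:
        return not self.flagged and self.center == "C" and self.base_at(-1) == "T"

    @property
    def is_tcw(self) -> bool:
        return self.is_tc and self.base_at(+1) in "AT"

    @property
    def is_apobec_signature(self) -> bool:
        """C>T or C>G at a TCW motif (SBS2/SBS13 definition)."""
        return self.is_tcw and self.alt_oriented in "TG"


# --- default MAF column synonym map; configurable via parse_mutations ---
MAF_COLUMN_SYNONYMS: dict[str, tuple[str, ...]] = {
    "sample_id": ("sample_id", "sample", "tumor_sample_barcode"),
    "chrom": ("chrom", "chromosome", "chr"),
    "pos": ("pos", "position", "start_position", "start"),
    "ref": ("ref", "reference_allele", "ref_allele"),
    "alt": ("alt", "tumor_seq_allele2", "alt_allele", "variant_allele"),
    "condition": ("condition", "group", "label"),
}


def _resolve_columns(
    columns: Sequence[str], column_map: Mapping[str, str] | None
) -> dict[str, str]:
    lower = {c.lower(): c for c in columns}
    resolved: dict[str, str] = {}
    for field_name, synonyms in MAF_COLUMN_SYNONYMS.items():
        if column_map and field_name in column_map:
            if column_map[field_name] not in columns:
                raise ValueError(
                    f"mapped column {column_map[field_name]!r} not in file"
                )
            resolved[field_name] = column_map[field_name]
            continue
        for syn in synonyms:
            if syn in lower:
                resolved[field_name] = lower[syn]
                break
    required = ("sample_id", "chrom", "pos", "ref", "alt")
    missing = [f for f in required if f not in resolved]
    if missing:
        raise ValueError(f"MAF is missing required columns for: {missing}")
    return resolved


def parse_mutations(
    path: str | Path,
    format: str = "MAF",
    sample: str | None = None,
    condition: str = "",
    column_map: Mapping[str, str] | None = None,
) -> list[MutationRecord]:
    """Parse a MAF-style TSV or a VCF into SBS ``MutationRecord``s.

    Non-SBS rows (indels, MNVs, non-ACGT alleles) are skipped and counted in a
    logged summary.  For VCF input the sample label comes from ``sample`` or,
    failing that, the first sample in the header / the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.upper()
    if fmt == "MAF":
        records, skipped = _parse_maf(path, condition, column_map)
    elif fmt == "VCF":
        records, skipped = _parse_vcf(path, sample, condition)
    else:
        raise ValueError(f"unknown format {format!r}")
    if skipped:
        log.warning("%s: skipped %d non-SBS records", path.name, skipped)
    return records


def _parse_maf(
    path: Path, condition: str, column_map: Mapping[str, str] | None
) -> tuple[list[MutationRecord], int]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = _resolve_columns(list(df.columns), column_map)
    records: list[MutationRecord] = []
    skipped = 0
    for row in df.itertuples(index=False):
        row_d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        ref = str(row_d[cols["ref"]]).upper()
        alt = str(row_d[cols["alt"]]).upper()
        if ref not in VALID_BASES or alt not in VALID_BASES or ref == alt:
            skipped += 1
            continue
        cond = condition
        if "condition" in cols:
            cond = str(row_d[cols["condition"]])
        records.append(
            MutationRecord(
                sample_id=str(row_d[cols["sample_id"]]),
                condition=cond,
                chrom=str(row_d[cols["chrom"]]),
                pos=int(row_d[cols["pos"]]),
                ref=ref,
                alt=alt,
            )
        )
    return records, skipped


def _parse_vcf(
    path: Path, sample: str | None, condition: str
) -> tuple[list[MutationRecord], int]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if sample is None:
        sample = vcf.samples[0] if vcf.samples else path.stem
    records: list[MutationRecord] = []
    skipped = 0
    for var in vcf:
        ref = var.REF.upper()
        for alt in var.ALT:
            alt = alt.upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in VALID_BASES or alt not in VALID_BASES:
                skipped += 1
                continue
            records.append(
                MutationRecord(
                    sample_id=sample,
                    condition=condition,
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=ref,
                    alt=alt,
                )
            )
    return records, skipped


def load_reference(path: str | Path) -> ReferenceSequence:
    """Load a FASTA into memory; contig names are taken up to the first whitespace."""
    from pyfaidx import Fasta

    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"empty or missing FASTA: {path}")
    fa = Fasta(str(path), read_ahead=10_000_000, duplicate_action="stop")
    contigs = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return ReferenceSequence(contigs)


def annotate_contexts(
    muts: Iterable[MutationRecord],
    genome: ReferenceSequence,
    flank: int = 2,
) -> list[OrientedContext]:
    """Attach pyrimidine-oriented (2*flank+1)-mer contexts to SBS records.

    Records whose ref disagrees with the genome are dropped with a warning.
    Windows that overlap a contig edge or contain N are flagged (kept for
    position-only analyses, excluded from motif statistics).
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    out: list[OrientedContext] = []
    mismatches = 0
    for m in muts:
        if m.chrom not in genome.contigs:
            raise KeyError(f"contig {m.chrom!r} not in reference")
        if genome.base(m.chrom, m.pos) != m.ref:
            mismatches += 1
            continue
        window = genome.window(m.chrom, m.pos, flank)
        flagged = window is None or "N" in window
        if window is None:
            # degenerate edge window: center the available sequence is not
            # possible, keep a minimal placeholder k-mer of the ref base
            kmer_src = m.ref
            pad = "N" * flank
            kmer_src = pad + m.ref + pad
        else:
            kmer_src = window
        if m.ref in "CT":
            out.append(OrientedContext(m, kmer_src, "+", m.alt, flagged))
        else:
            out.append(
                OrientedContext(
                    m, revcomp(kmer_src), "-", revcomp(m.alt), flagged
                )
            )
    if mismatches:
        log.warning("dropped %d records whose ref mismatched the genome", mismatches)
    return out


def contexts_to_frame(contexts: Iterable[OrientedContext]) -> pd.DataFrame:
    """Tabular export of oriented contexts (round-trips through write_maf)."""
    rows = [
        {
            "sample_id": c.mutation.sample_id,
            "condition": c.mutation.condition,
            "chrom": c.mutation.chrom,
            "pos": c.mutation.pos,
            "ref": c.mutation.ref,
            "alt": c.mutation.alt,
            "kmer": c.kmer,
            "strand": c.strand,
            "alt_oriented": c.alt_oriented,
            "flagged": c.flagged,
        }
        for c in contexts
    ]
    return pd.DataFrame(rows)


def write_maf(records: Iterable[MutationRecord], path: str | Path) -> None:
    """Write records as a MAF-style TSV readable by :func:`parse_mutations`."""
    df = pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "condition": m.condition,
                "chromosome": m.chrom,
                "position": m.pos,
                "ref": m.ref,
                "alt": m.alt,
            }
            for m in records
        ]
    )
    df.to_csv(path, sep="\t", index=False)
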