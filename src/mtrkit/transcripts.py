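"""Protein-coding transcript models and exhaustive single-nucleotide mutagenesis.

A :class:`TranscriptModel` couples a coding sequence (always stored on the
coding strand, 5'→3') with the exon structure that places it on the genome.
From it we enumerate every possible single-nucleotide change in the coding
region and classify each as missense, synonymous, or nonsense under the
standard genetic code.  These "possible SNV" tallies form the denominator of
the missense tolerance ratio: the expected missense proportion assuming every
single-base change is equally likely.

Coordinate conventions: genomic positions are 1-based inclusive; CDS positions
are 1-based along the coding strand; codon indices are 1-based protein
positions.  The stop codon, when present in the CDS, is recorded but excluded
from analysis — windows and possible-SNV enumeration run over codons 1..L.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd
from Bio.Seq import Seq
from Bio import SeqIO

BASES = ("A", "C", "G", "T")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

Consequence = Literal["missense", "synonymous", "nonsense"]


class TranscriptValidationError(ValueError):
    """Base class for transcript validation failures."""


class CdsLengthError(TranscriptValidationError):
    """CDS length not divisible by 3, or exon blocks do not sum to it."""


class InternalStopError(TranscriptValidationError):
    """A stop codon occurs before the final codon of the CDS."""


class InvalidBaseError(TranscriptValidationError):
    """The CDS contains a character outside A, C, G, T."""


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon; '*' for stop (standard code)."""
    return str(Seq(codon).translate())


@dataclass(frozen=True)
class TranscriptModel:
    """A single protein-coding transcript with genomic placement.

    ``exon_blocks`` are (start, end) genomic intervals, 1-based inclusive and
    ascending on the chromosome regardless of strand.  ``cds_sequence`` is on
    the coding strand; for minus-strand transcripts the genomic map runs in
    descending order.  ``protein_length`` (L) counts codons excluding the stop
    codon; ``includes_stop`` records whether the CDS carries one.
    """

    transcript_id: str
    gene_symbol: str
    chromosome: str
    strand: str
    exon_blocks: tuple[tuple[int, int], ...]
    cds_sequence: str
    includes_stop: bool = field(init=False)
    protein_length: int = field(init=False)

    def __post_init__(self) -> None:
        tid = self.transcript_id
        cds = self.cds_sequence
        if set(cds) - set(BASES):
            bad = sorted(set(cds) - set(BASES))
            raise InvalidBaseError(f"{tid}: CDS contains non-ACGT characters {bad}")
        if len(cds) == 0 or len(cds) % 3 != 0:
            raise CdsLengthError(f"{tid}: CDS length {len(cds)} not a positive multiple of 3")
        exon_len = sum(e - s + 1 for s, e in self.exon_blocks)
        if exon_len != len(cds):
            raise CdsLengthError(
                f"{tid}: exon blocks sum to {exon_len} bp but CDS is {len(cds)} bp"
            )
        if self.strand not in {"+", "-"}:
            raise TranscriptValidationError(f"{tid}: strand must be '+' or '-'")
        prev_end = 0
        for s, e in self.exon_blocks:
            if s > e or s <= prev_end:
                raise TranscriptValidationError(
                    f"{tid}: exon blocks must be ascending, non-overlapping intervals"
                )
            prev_end = e

        n_codons = len(cds) // 3
        codons = [cds[3 * i : 3 * i + 3] for i in range(n_codons)]
        includes_stop = codons[-1] in STOP_CODONS
        L = n_codons - 1 if includes_stop else n_codons
        for i, codon in enumerate(codons[:L], start=1):
            if codon in STOP_CODONS:
                raise InternalStopError(f"{tid}: internal stop codon at codon {i}")
        object.__setattr__(self, "includes_stop", includes_stop)
        object.__setattr__(self, "protein_length", L)

    # ---- coordinate maps -------------------------------------------------

    def _genomic_positions(self) -> list[int]:
        """Genomic position of each CDS base, index 0 = CDS position 1."""
        pos: list[int] = []
        for s, e in self.exon_blocks:
            pos.extend(range(s, e + 1))
        if self.strand == "-":
            pos.reverse()
        return pos

    def cds_to_genomic(self, cds_pos: int) -> int:
        """Genomic coordinate of 1-based CDS position."""
        if not 1 <= cds_pos <= len(self.cds_sequence):
            raise IndexError(f"CDS position {cds_pos} outside 1..{len(self.cds_sequence)}")
        return self._genomic_positions()[cds_pos - 1]

    def genomic_to_cds(self, genomic_pos: int) -> int | None:
        """1-based CDS position of a genomic coordinate, or None if non-coding."""
        try:
            return self._genomic_positions().index(genomic_pos) + 1
        except ValueError:
            return None

    # ---- codon access ----------------------------------------------------

    def codon(self, codon_index: int) -> str:
        if not 1 <= codon_index <= self.protein_length:
            raise IndexError(
                f"codon {codon_index} outside 1..{self.protein_length} for {self.transcript_id}"
            )
        return self.cds_sequence[3 * (codon_index - 1) : 3 * codon_index]

    def codon_genomic_positions(self, codon_index: int) -> tuple[int, int, int]:
        base = 3 * (codon_index - 1)
        g = self._genomic_positions()
        return (g[base], g[base + 1], g[base + 2])


def classify_consequence(
    model: TranscriptModel, codon_index: int, position_in_codon: int, alt_base: str
) -> Consequence:
    """Consequence of substituting ``alt_base`` at a codon position.

    Alleles are on the coding strand.  Raises if the codon is out of range,
    the position is not 1..3, or alt equals the reference base.
    """
    if position_in_codon not in (1, 2, 3):
        raise ValueError(f"position_in_codon must be 1..3, got {position_in_codon}")
    if alt_base not in BASES:
        raise ValueError(f"alt_base must be one of {BASES}, got {alt_base!r}")
    ref_codon = model.codon(codon_index)
    ref_base = ref_codon[position_in_codon - 1]
    if alt_base == ref_base:
        raise ValueError(f"alt base {alt_base} equals reference at codon {codon_index}")
    alt_codon = ref_codon[: position_in_codon - 1] + alt_base + ref_codon[position_in_codon:]
    if alt_codon in STOP_CODONS:
        return "nonsense"
    if translate_codon(alt_codon) == translate_codon(ref_codon):
        return "synonymous"
    return "missense"


@dataclass(frozen=True)
class PossibleSnv:
    """One of the nine possible single-base changes at a codon position."""

    codon_index: int
    position_in_codon: int
    ref_base: str
    alt_base: str
    consequence: Consequence

    @property
    def cds_pos(self) -> int:
        return 3 * (self.codon_index - 1) + self.position_in_codon


def enumerate_possible_snvs(model: TranscriptModel) -> list[PossibleSnv]:
    """All 9·L possible SNVs over codons 1..L, classified by the standard code.

    Deterministic order: by codon index, position in codon, then alt base.
    """
    out: list[PossibleSnv] = []
    for ci in range(1, model.protein_length + 1):
        ref_codon = model.codon(ci)
        for pos in (1, 2, 3):
            ref = ref_codon[pos - 1]
            for alt in BASES:
                if alt == ref:
                    continue
                out.append(
                    PossibleSnv(ci, pos, ref, alt, classify_consequence(model, ci, pos, alt))
                )
    return out


# ---- input/output --------------------------------------------------------


def read_exon_spec(path: str | Path) -> dict[str, dict]:
    """Exon structure from TSV (transcript_id, chrom, strand, exon_start,
    exon_end; one row per exon) or an equivalent JSON document."""
    path = Path(path)
    specs: dict[str, dict] = {}
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        records = doc if isinstance(doc, list) else [doc]
        for rec in records:
            specs[rec["transcript_id"]] = {
                "gene_symbol": rec.get("gene_symbol", rec["transcript_id"]),
                "chrom": str(rec["chrom"]),
                "strand": rec["strand"],
                "exons": [tuple(map(int, e)) for e in rec["exons"]],
            }
        return specs
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"transcript_id", "chrom", "strand", "exon_start", "exon_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"exon spec {path} missing columns: {sorted(missing)}")
    for tid, grp in df.groupby("transcript_id", sort=False):
        exons = sorted(zip(grp["exon_start"].astype(int), grp["exon_end"].astype(int)))
        specs[str(tid)] = {
            "gene_symbol": str(grp["gene_symbol"].iloc[0]) if "gene_symbol" in grp else str(tid),
            "chrom": str(grp["chrom"].iloc[0]),
            "strand": str(grp["strand"].iloc[0]),
            "exons": exons,
        }
    return specs


def build_transcript_model(
    cds_record, exon_spec: dict, gene_symbol: str | None = None
) -> TranscriptModel:
    """Assemble and validate a TranscriptModel.

    ``cds_record`` is a Bio.SeqRecord (or any object with .id and .seq) whose
    ID is the transcript ID; ``exon_spec`` is one entry of
    :func:`read_exon_spec`.  Minus-strand transcripts supply the CDS already
    on the coding strand; only the genomic map is reversed.
    """
    return TranscriptModel(
        transcript_id=str(cds_record.id),
        gene_symbol=gene_symbol or exon_spec.get("gene_symbol", str(cds_record.id)),
        chromosome=exon_spec["chrom"],
        strand=exon_spec["strand"],
        exon_blocks=tuple((int(s), int(e)) for s, e in exon_spec["exons"]),
        cds_sequence=str(cds_record.seq).upper(),
    )


def load_transcripts(cds_fasta: str | Path, exon_path: str | Path) -> list[TranscriptModel]:
    """Read all transcripts from a CDS FASTA plus exon sidecar."""
    specs = read_exon_spec(exon_path)
    models = []
    for rec in SeqIO.parse(str(cds_fasta), "fasta"):
        if rec.id not in specs:
            raise TranscriptValidationError(f"{rec.id}: no exon specification found")
        models.append(build_transcript_model(rec, specs[rec.id]))
    return models


def possible_snv_table(model: TranscriptModel) -> pd.DataFrame:
    """Possible-SNV export: one row per SNV with CDS and genomic coordinates."""
    rows = []
    for snv in enumerate_possible_snvs(model):
        rows.append(
            {
                "transcript_id": model.transcript_id,
                "codon_index": snv.codon_index,
                "cds_pos": snv.cds_pos,
                "genomic_pos": model.cds_to_genomic(snv.cds_pos),
                "ref": snv.ref_base,
                "alt": snv.alt_base,
                "consequence": snv.consequence,
            }
        )
    return pd.DataFrame(rows)
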