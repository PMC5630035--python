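"""Standing-variation ingest, control stratification, and pathogenic qualification.

Population reference sites (VCF or TSV) are mapped onto a transcript's coding
sequence and classified by consequence.  Quality-passing missense variants are
then stratified into three mutually exclusive presumed-benign control groups
modelled on the ExAC v1 / ExAC v2+gnomAD releases:

* Group 1 — singletons (global allele count exactly 1) in the v1 release;
* Group 2 — v2 singletons absent at any frequency from v1;
* Group 3 — v2 non-singletons rare in every ancestry group (MAF < 0.05% in
  each of the seven populations), excluding Groups 1 and 2.

Pathogenic-candidate records carry segregation evidence and database
classification strings; :func:`qualify_pathogenic` applies the two-tier screen
(pathogenic classification consensus, then de novo or pedigree segregation
support) that separates qualified from unqualified case variants.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd
from Bio.Seq import Seq

from mtrkit.transcripts import TranscriptModel, classify_consequence

logger = logging.getLogger(__name__)

# The seven ancestry groups reported by the reference cohorts.
POPULATIONS = ("AFR", "AMR", "EAS", "FIN", "NFE", "OTH", "SAS")

#: Rare-variant MAF ceiling for Control Group 3 (per population).
GROUP3_MAF_MAX = 0.0005

#: Phenotype keywords marking epilepsy association.  "glucose" applies only
#: to SLC2A1 (GLUT1 deficiency presents as a metabolic epilepsy).
PHENOTYPE_KEYWORDS = (
    "seizure",
    "epilepsy",
    "convulsion",
    "gastaut",
    "spasm",
    "ohtahara",
    "west syndrome",
    "encephalopathy",
    "dravet",
)

CLINVAR_PATHOGENIC = {
    "pathogenic",
    "likely pathogenic",
    "likely pathogenic; pathogenic",
    "pathogenic; likely pathogenic",
}


@dataclass(frozen=True)
class VariantSite:
    """One observed alternate allele at a coding site.

    Alleles are stored on the coding strand (forward-strand VCF alleles are
    reverse-complemented on ingest for minus-strand transcripts).
    """

    transcript_id: str
    codon_index: int
    genomic_pos: int
    ref: str
    alt: str
    allele_count: int
    allele_number: int
    per_population_af: dict[str, float]
    qc_pass: bool
    consequence: str
    cohort_tag: str = "v2"

    def __post_init__(self) -> None:
        if self.allele_count < 0 or self.allele_number <= 0:
            raise ValueError("AC must be >= 0 and AN > 0")
        if self.allele_count > self.allele_number:
            raise ValueError(f"AC {self.allele_count} exceeds AN {self.allele_number}")
        for pop, af in self.per_population_af.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"population AF for {pop} outside [0,1]: {af}")


@dataclass(frozen=True)
class ControlAssignment:
    group: int | None  # 1, 2, 3 or None
    reason: str


@dataclass(frozen=True)
class EvidenceRecord:
    """A pathogenic-candidate variant with its supporting evidence."""

    transcript_id: str
    codon_index: int
    ref: str
    alt: str
    classification_clinvar: str | None = None
    classification_hgmd: str | None = None
    phenotype_terms: tuple[str, ...] = ()
    de_novo: bool = False
    n_affected_genotyped_carriers: int = 0
    n_affected_genotyped_noncarriers: int = 0
    n_unaffected_genotyped_carriers: int = 0

    def __post_init__(self) -> None:
        for f in (
            self.n_affected_genotyped_carriers,
            self.n_affected_genotyped_noncarriers,
            self.n_unaffected_genotyped_carriers,
        ):
            if f < 0:
                raise ValueError("pedigree genotype counts must be non-negative")


@dataclass
class CoverageTrack:
    """Per-site fraction of cohort samples with >= 10x depth."""

    fraction_ge_10x: dict[int, float]

    def __post_init__(self) -> None:
        for pos, frac in self.fraction_ge_10x.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"coverage fraction at {pos} outside [0,1]: {frac}")


@dataclass
class IngestSummary:
    n_kept: int = 0
    n_fail_qc: int = 0
    n_outside_cds: int = 0
    n_non_snv: int = 0


# ---- reading -------------------------------------------------------------

_VARIANT_TSV_COLUMNS = ["chrom", "pos", "ref", "alt", "filter", "ac", "an"]


def _site_from_alleles(
    model: TranscriptModel,
    pos: int,
    ref: str,
    alt: str,
    ac: int,
    an: int,
    pop_af: dict[str, float],
    qc_pass: bool,
    cohort_tag: str,
    summary: IngestSummary,
) -> VariantSite | None:
    if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
        summary.n_non_snv += 1
        return None
    cds_pos = model.genomic_to_cds(pos)
    if cds_pos is None:
        summary.n_outside_cds += 1
        return None
    codon_index = (cds_pos - 1) // 3 + 1
    if codon_index > model.protein_length:  # stop codon positions excluded
        summary.n_outside_cds += 1
        return None
    if model.strand == "-":
        ref = str(Seq(ref).reverse_complement())
        alt = str(Seq(alt).reverse_complement())
    expected_ref = model.cds_sequence[cds_pos - 1]
    if ref != expected_ref:
        raise ValueError(
            f"{model.transcript_id}: ref allele {ref} at genomic {pos} does not match "
            f"CDS base {expected_ref}"
        )
    if not qc_pass:
        summary.n_fail_qc += 1
        return None
    pos_in_codon = (cds_pos - 1) % 3 + 1
    consequence = classify_consequence(model, codon_index, pos_in_codon, alt)
    summary.n_kept += 1
    return VariantSite(
        transcript_id=model.transcript_id,
        codon_index=codon_index,
        genomic_pos=pos,
        ref=ref,
        alt=alt,
        allele_count=ac,
        allele_number=an,
        per_population_af=pop_af,
        qc_pass=True,
        consequence=consequence,
        cohort_tag=cohort_tag,
    )


def read_variant_table(
    path: str | Path, model: TranscriptModel, cohort_tag: str = "v2"
) -> list[VariantSite]:
    """Read quality-passing coding SNVs from a VCF or TSV site table.

    Multi-allelic VCF records are split into one :class:`VariantSite` per
    alternate allele.  Sites outside the CDS, non-SNVs, and FILTER failures
    are dropped and tallied in a logged summary.  Per-population allele
    frequencies are taken from ``AF_<pop>`` INFO fields when present, else
    computed as ``AC_<pop>/AN_<pop>``.
    """
    path = Path(path)
    summary = IngestSummary()
    sites: list[VariantSite] = []
    if path.suffix.lower() in {".tsv", ".txt", ".csv"}:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, dtype={"chrom": str})
        missing = set(_VARIANT_TSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"variant table {path} missing columns: {sorted(missing)}")
        for row in df.itertuples(index=False):
            pop_af = {
                p: float(getattr(row, f"af_{p.lower()}"))
                for p in POPULATIONS
                if hasattr(row, f"af_{p.lower()}") and pd.notna(getattr(row, f"af_{p.lower()}"))
            }
            site = _site_from_alleles(
                model,
                int(row.pos),
                str(row.ref),
                str(row.alt),
                int(row.ac),
                int(row.an),
                pop_af,
                str(row.filter).upper() in {"PASS", "."},
                cohort_tag,
                summary,
            )
            if site is not None:
                sites.append(site)
    else:
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        for rec in vcf:
            if str(rec.CHROM) != model.chromosome:
                raise ValueError(
                    f"contig {rec.CHROM} does not match transcript chromosome "
                    f"{model.chromosome}"
                )
            ac = rec.INFO.get("AC")
            an = rec.INFO.get("AN")
            if ac is None or an is None:
                raise ValueError(f"{path}: record at {rec.POS} missing AC/AN INFO fields")
            acs = ac if isinstance(ac, tuple) else (ac,)
            qc = rec.FILTER is None  # cyvcf2 reports PASS/'.' as None
            for i, alt in enumerate(rec.ALT):
                pop_af: dict[str, float] = {}
                for pop in POPULATIONS:
                    af = rec.INFO.get(f"AF_{pop}")
                    if af is not None:
                        af = af[i] if isinstance(af, tuple) else af
                        pop_af[pop] = float(af)
                    else:
                        pac = rec.INFO.get(f"AC_{pop}")
                        pan = rec.INFO.get(f"AN_{pop}")
                        if pac is not None and pan is not None:
                            pac = pac[i] if isinstance(pac, tuple) else pac
                            if pan > 0:
                                pop_af[pop] = float(pac) / float(pan)
                site = _site_from_alleles(
                    model,
                    rec.POS,
                    rec.REF,
                    alt,
                    int(acs[i] if i < len(acs) else acs[0]),
                    int(an),
                    pop_af,
                    qc,
                    cohort_tag,
                    summary,
                )
                if site is not None:
                    sites.append(site)
    logger.info(
        "%s: kept %d sites (%d QC-fail, %d outside CDS, %d non-SNV dropped)",
        path.name,
        summary.n_kept,
        summary.n_fail_qc,
        summary.n_outside_cds,
        summary.n_non_snv,
    )
    return sites


def read_coverage_table(path: str | Path, chromosome: str | None = None) -> CoverageTrack:
    """Coverage TSV with columns chrom, pos, frac_ge_10x."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "pos", "frac_ge_10x"} - set(df.columns)
    if missing:
        raise ValueError(f"coverage table {path} missing columns: {sorted(missing)}")
    if chromosome is not None:
        df = df[df["chrom"] == chromosome]
    return CoverageTrack({int(r.pos): float(r.frac_ge_10x) for r in df.itertuples(index=False)})


def read_evidence_records(path: str | Path) -> list[EvidenceRecord]:
    """Pathogenic-candidate records from TSV or JSON."""
    path = Path(path)
    records: list[EvidenceRecord] = []
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        df = pd.read_csv(path, sep="\t")
        rows = df.to_dict(orient="records")
    for row in rows:
        terms = row.get("phenotype_terms", "") or ""
        if isinstance(terms, str):
            terms = tuple(t.strip() for t in terms.split(";") if t.strip())
        else:
            terms = tuple(terms)

        def _opt(key: str) -> str | None:
            v = row.get(key)
            if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
                return None
            return str(v)

        records.append(
            EvidenceRecord(
                transcript_id=str(row["transcript_id"]),
                codon_index=int(row["codon_index"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                classification_clinvar=_opt("classification_clinvar"),
                classification_hgmd=_opt("classification_hgmd"),
                phenotype_terms=terms,
                de_novo=bool(row.get("de_novo", False) in (True, "True", "true", 1, "1")),
                n_affected_genotyped_carriers=int(row.get("n_affected_genotyped_carriers", 0)),
                n_affected_genotyped_noncarriers=int(
                    row.get("n_affected_genotyped_noncarriers", 0)
                ),
                n_unaffected_genotyped_carriers=int(
                    row.get("n_unaffected_genotyped_carriers", 0)
                ),
            )
        )
    return records


# ---- control stratification ---------------------------------------------


def assign_control_group(
    site: VariantSite, in_v1: bool, v1_ac: int | None = None
) -> ControlAssignment:
    """Assign a quality-passing missense site to control group 1, 2, 3 or none.

    ``in_v1`` states whether the same allele was reported at any frequency in
    the v1 release; ``v1_ac`` gives its v1 allele count when known.
    """
    if site.consequence != "missense" or not site.qc_pass:
        return ControlAssignment(None, "not a quality-passing missense variant")
    if site.cohort_tag == "v1":
        if site.allele_count == 1:
            return ControlAssignment(1, "v1 singleton")
        return ControlAssignment(None, "v1 non-singleton")
    # v2 cohort
    if site.allele_count == 1:
        if not in_v1:
            return ControlAssignment(2, "v2 singleton absent from v1")
        return ControlAssignment(None, "v2 singleton already present in v1")
    if in_v1 and v1_ac == 1:
        return ControlAssignment(None, "group 1 member from the v1 release")
    missing = [p for p in POPULATIONS if p not in site.per_population_af]
    if missing:
        raise ValueError(
            f"cannot evaluate group 3 for {site.genomic_pos}{site.ref}>{site.alt}: "
            f"missing population AFs {missing}"
        )
    if all(site.per_population_af[p] < GROUP3_MAF_MAX for p in POPULATIONS):
        return ControlAssignment(3, "rare (MAF < 0.05% in all populations)")
    return ControlAssignment(None, "population MAF above the rare-variant ceiling")


# ---- pathogenic qualification ---------------------------------------------


def match_phenotype_keywords(terms: Sequence[str], gene_symbol: str) -> bool:
    """Case-insensitive substring match against the epilepsy keyword list.

    "glucose" matches only for SLC2A1.
    """
    keywords = PHENOTYPE_KEYWORDS + (("glucose",) if gene_symbol.upper() == "SLC2A1" else ())
    for term in terms:
        low = term.lower()
        if any(kw in low for kw in keywords):
            return True
    return False


def _passes_classification_screen(record: EvidenceRecord) -> bool:
    cv = record.classification_clinvar
    hg = record.classification_hgmd
    cv_path = cv is not None and cv.strip().lower() in CLINVAR_PATHOGENIC
    hg_path = hg is not None and hg.strip().upper() == "DM"
    if cv is not None and hg is not None:
        # both databases report: consensus required
        return cv_path and hg_path
    return cv_path or hg_path


QualificationStatus = Literal["qualified", "unqualified", "not_pathogenic_reported"]


def qualify_pathogenic(record: EvidenceRecord) -> QualificationStatus:
    """Two-tier screen for pathogenic-candidate variants.

    Tier 1: the variant must carry a pathogenic classification (ClinVar
    Pathogenic/Likely Pathogenic and/or HGMD DM, with consensus required when
    both databases report it); otherwise ``not_pathogenic_reported``.

    Tier 2 (segregation support): ``qualified`` iff the variant arose de novo,
    or it segregated among all (and more than three) genotyped affected
    carriers with at most one genotyped unaffected carrier.
    """
    if not _passes_classification_screen(record):
        return "not_pathogenic_reported"
    if record.de_novo:
        return "qualified"
    segregates = (
        record.n_affected_genotyped_carriers > 3
        and record.n_affected_genotyped_noncarriers == 0
        and record.n_unaffected_genotyped_carriers <= 1
    )
    return "qualified" if segregates else "unqualified"


# ---- coverage --------------------------------------------------------------


def codon_coverage(
    track: CoverageTrack, model: TranscriptModel, codon_index: int
) -> tuple[float, bool]:
    """Mean >=10x coverage fraction over a codon's three genomic positions.

    Positions absent from the track contribute 0 and set the ``flagged``
    member of the returned (coverage, flagged) pair.
    """
    positions = model.codon_genomic_positions(codon_index)
    fracs = []
    flagged = False
    for pos in positions:
        if pos in track.fraction_ge_10x:
            fracs.append(track.fraction_ge_10x[pos])
        else:
            fracs.append(0.0)
            flagged = True
    return sum(fracs) / 3.0, flagged
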