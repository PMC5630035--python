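"""Synthetic transcripts, standing variation, pathogenic variants and features.

The generator emulates the inputs of the analysis at desk scale: a random
protein-coding transcript; a standing-variation site table in which every
possible coding SNV is independently observed with a small probability,
thinned for missense changes inside configurable depletion regions (the
signature of regional purifying selection); pathogenic-candidate variants
concentrated in those depleted regions with segregation evidence fields; a
per-site coverage track; and variant-by-feature rank-score matrices with
planted class separation.

Every generator is a pure function of its config and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from mtrkit.transcripts import (
    BASES,
    STOP_CODONS,
    TranscriptModel,
    enumerate_possible_snvs,
)
from mtrkit.variants import (
    POPULATIONS,
    CoverageTrack,
    EvidenceRecord,
    VariantSite,
)

#: Chromosome count of the v2-scale reference cohort (138,632 individuals).
DEFAULT_ALLELE_NUMBER = 277_264


@dataclass(frozen=True)
class FeatureSpec:
    """One synthetic feature: class separation d (in SD units) and noise scale."""

    name: str
    effect_size: float = 0.0
    noise: float = 1.0


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic test bed.

    Defaults mirror the data regime of the large reference cohorts: a
    per-possible-SNV observation probability of 0.06 reproduces the ~15
    distinct variants a 31-codon window captures in a cohort of ~280k
    chromosomes; the allele-count spectrum is heavily singleton-weighted
    (P(AC=1)=0.7 with a geometric tail); pathogenic qualification succeeds
    for 58% of candidates, matching the fraction of database-reported
    pathogenic variants that survive segregation screening (606/1043).
    """

    seed: int = 0
    transcript_length_codons: int = 400
    #: None -> one region retaining 20% of missense across the middle quarter
    #: of the transcript (resolved against the length at construction).
    depletion_regions: tuple[tuple[int, int, float], ...] | None = None
    site_variation_prob: float = 0.06
    pathogenic_concentration: float = 0.8
    qualification_share: float = 0.58
    singleton_prob: float = 0.7
    geometric_tail_p: float = 0.5
    allele_number: int = DEFAULT_ALLELE_NUMBER
    gc_bias: float = 0.0  # -1..1; >0 favours G/C
    strand: str = "+"
    n_exons: int = 3
    genomic_offset: int = 10_000
    intron_length: int = 500
    transcript_id: str = "SIM0001"
    gene_symbol: str = "SIMGENE"
    chromosome: str = "1"
    feature_spec: tuple[FeatureSpec, ...] = (
        FeatureSpec("planted_1", effect_size=2.0),
        FeatureSpec("noise_1"),
        FeatureSpec("noise_2"),
        FeatureSpec("noise_3"),
        FeatureSpec("noise_4"),
    )

    def __post_init__(self) -> None:
        if self.depletion_regions is None:
            L = self.transcript_length_codons
            self.depletion_regions = ((max(1, int(0.375 * L)), max(1, int(0.625 * L)), 0.2),)
        for lo, hi, r in self.depletion_regions:
            if not (1 <= lo <= hi <= self.transcript_length_codons):
                raise ValueError(f"depletion region ({lo},{hi}) outside transcript")
            if not 0.0 <= r <= 1.0:
                raise ValueError("missense retention must lie in [0,1]")
        if not 0.0 <= self.site_variation_prob <= 1.0:
            raise ValueError("site_variation_prob must lie in [0,1]")
        if not 0.0 <= self.pathogenic_concentration <= 1.0:
            raise ValueError("pathogenic_concentration must lie in [0,1]")


def _base_probs(gc_bias: float) -> np.ndarray:
    w = np.array([1 - gc_bias, 1 + gc_bias, 1 + gc_bias, 1 - gc_bias], dtype=float)  # A C G T
    w = np.clip(w, 0.05, None)
    return w / w.sum()


def simulate_transcript(config: SimulationConfig) -> TranscriptModel:
    """Random CDS with no internal stop codon, placed on a synthetic genome.

    Codons are drawn base-by-base (optionally GC-biased) with stop codons
    rejected; the CDS opens with ATG and carries a trailing stop.  The exon
    structure splits the CDS into ``n_exons`` blocks separated by fixed-size
    introns.
    """
    rng = np.random.default_rng(config.seed)
    probs = _base_probs(config.gc_bias)
    codons = ["ATG"]
    while len(codons) < config.transcript_length_codons:
        codon = "".join(np.array(BASES)[rng.choice(4, size=3, p=probs)])
        if codon not in STOP_CODONS:
            codons.append(codon)
    codons.append("TAA")
    cds = "".join(codons)

    n_exons = max(1, min(config.n_exons, len(cds)))
    cuts = np.linspace(0, len(cds), n_exons + 1).astype(int)
    blocks = []
    start = config.genomic_offset
    for i in range(n_exons):
        length = int(cuts[i + 1] - cuts[i])
        blocks.append((start, start + length - 1))
        start += length + config.intron_length
    return TranscriptModel(
        transcript_id=config.transcript_id,
        gene_symbol=config.gene_symbol,
        chromosome=config.chromosome,
        strand=config.strand,
        exon_blocks=tuple(blocks),
        cds_sequence=cds,
    )


def _retention_at(config: SimulationConfig, codon_index: int) -> float:
    for lo, hi, r in config.depletion_regions:
        if lo <= codon_index <= hi:
            return r
    return 1.0


def _draw_allele_count(rng: np.random.Generator, config: SimulationConfig) -> int:
    if rng.random() < config.singleton_prob:
        return 1
    return 2 + int(rng.geometric(config.geometric_tail_p) - 1)


def simulate_standing_variation(
    model: TranscriptModel, config: SimulationConfig, cohort_tag: str = "v2"
) -> list[VariantSite]:
    """Independent observation of each possible missense/synonymous SNV.

    Missense SNVs inside a depletion region are observed with probability
    ``site_variation_prob * retention``; synonymous SNVs are unaffected by
    depletion.  Allele counts follow the singleton-weighted spectrum, and
    per-population frequencies are the global AF split evenly (every
    population sees the same rarity class).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sites: list[VariantSite] = []
    an = config.allele_number
    for snv in enumerate_possible_snvs(model):
        if snv.consequence == "nonsense":
            continue
        prob = config.site_variation_prob
        if snv.consequence == "missense":
            prob *= _retention_at(config, snv.codon_index)
        if rng.random() >= prob:
            continue
        ac = _draw_allele_count(rng, config)
        af = ac / an
        sites.append(
            VariantSite(
                transcript_id=model.transcript_id,
                codon_index=snv.codon_index,
                genomic_pos=model.cds_to_genomic(snv.cds_pos),
                ref=snv.ref_base,
                alt=snv.alt_base,
                allele_count=ac,
                allele_number=an,
                per_population_af={p: af for p in POPULATIONS},
                qc_pass=True,
                consequence=snv.consequence,
                cohort_tag=cohort_tag,
            )
        )
    return sites


def simulate_pathogenic_variants(
    model: TranscriptModel, config: SimulationConfig, n: int
) -> list[EvidenceRecord]:
    """Pathogenic-candidate records concentrated in the depleted regions.

    A fraction ``pathogenic_concentration`` of the n variants is sampled
    uniformly from missense SNVs inside depletion regions, the remainder
    uniformly from missense SNVs elsewhere.  A ``qualification_share``
    fraction carries qualifying evidence (de novo, or >3 segregating affected
    carriers with <=1 unaffected carrier); the rest carries insufficient
    support.  All records pass the pathogenic-classification screen.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    missense = [s for s in enumerate_possible_snvs(model) if s.consequence == "missense"]
    inside = [s for s in missense if _retention_at(config, s.codon_index) < 1.0]
    outside = [s for s in missense if _retention_at(config, s.codon_index) >= 1.0]
    if not inside:
        inside = missense
    if not outside:
        outside = missense

    records: list[EvidenceRecord] = []
    for _ in range(n):
        pool = inside if rng.random() < config.pathogenic_concentration else outside
        snv = pool[rng.integers(len(pool))]
        qualifies = rng.random() < config.qualification_share
        if qualifies and rng.random() < 0.5:
            evidence = dict(de_novo=True)
        elif qualifies:
            evidence = dict(
                de_novo=False,
                n_affected_genotyped_carriers=int(rng.integers(4, 9)),
                n_affected_genotyped_noncarriers=0,
                n_unaffected_genotyped_carriers=int(rng.integers(0, 2)),
            )
        else:
            evidence = dict(
                de_novo=False,
                n_affected_genotyped_carriers=int(rng.integers(0, 4)),
                n_affected_genotyped_noncarriers=0,
                n_unaffected_genotyped_carriers=int(rng.integers(0, 2)),
            )
        records.append(
            EvidenceRecord(
                transcript_id=model.transcript_id,
                codon_index=snv.codon_index,
                ref=snv.ref_base,
                alt=snv.alt_base,
                classification_clinvar="Pathogenic",
                classification_hgmd="DM",
                phenotype_terms=("early infantile epileptic encephalopathy",),
                **evidence,
            )
        )
    return records


def simulate_coverage(
    model: TranscriptModel, config: SimulationConfig, alpha: float = 20.0, beta: float = 1.0
) -> CoverageTrack:
    """Beta-distributed per-site fractions of samples at >=10x depth."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    fractions = {}
    for cds_pos in range(1, len(model.cds_sequence) + 1):
        fractions[model.cds_to_genomic(cds_pos)] = float(rng.beta(alpha, beta))
    return CoverageTrack(fractions)


def simulate_feature_matrix(
    n_case: int,
    n_control: int,
    feature_spec: Sequence[FeatureSpec],
    seed: int = 0,
    gene_symbol: str = "SIMGENE",
):
    """Variant-by-feature rank-score matrix with planted class separation.

    Informative features draw raw values from N(d·y, noise²) and are mapped
    to rank scores in [0,1]; zero-effect features are uniform noise.  The
    expected single-feature AUC of a planted feature at separation d is
    Phi(d / (noise·sqrt(2))).
    """
    from mtrkit.gpp import FeatureMatrix

    if n_case < 1 or n_control < 1:
        raise ValueError("need at least one case and one control")
    rng = np.random.default_rng(seed)
    y = np.concatenate([np.ones(n_case, dtype=int), np.zeros(n_control, dtype=int)])
    n = n_case + n_control
    cols = {}
    for spec in feature_spec:
        if spec.effect_size == 0.0:
            cols[spec.name] = rng.uniform(0.0, 1.0, size=n)
        else:
            raw = rng.normal(spec.effect_size * y, spec.noise)
            ranks = pd.Series(raw).rank(method="average").to_numpy()
            cols[spec.name] = (ranks - 0.5) / n
    scores = pd.DataFrame(cols, index=[f"var{i:05d}" for i in range(n)])
    return FeatureMatrix(
        scores=scores,
        labels=pd.Series(y, index=scores.index),
        genes=pd.Series([gene_symbol] * n, index=scores.index),
    )


# ---- fixture export --------------------------------------------------------


def _forward_allele(model: TranscriptModel, base: str) -> str:
    return str(Seq(base).reverse_complement()) if model.strand == "-" else base


def write_fixture_set(config: SimulationConfig, out_dir: str | Path, n_pathogenic: int = 60) -> dict:
    """Write a complete text fixture set consumable by the CLI commands.

    Produces cds.fasta, exons.tsv, variants.vcf, coverage.tsv, evidence.tsv,
    features.tsv plus a manifest; returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = simulate_transcript(config)
    sites = simulate_standing_variation(model, config)
    coverage = simulate_coverage(model, config)
    records = simulate_pathogenic_variants(model, config, n_pathogenic)

    fasta = out / "cds.fasta"
    fasta.write_text(f">{model.transcript_id}\n{model.cds_sequence}\n")

    exon_rows = [
        {
            "transcript_id": model.transcript_id,
            "gene_symbol": model.gene_symbol,
            "chrom": model.chromosome,
            "strand": model.strand,
            "exon_start": s,
            "exon_end": e,
        }
        for s, e in model.exon_blocks
    ]
    pd.DataFrame(exon_rows).to_csv(out / "exons.tsv", sep="\t", index=False)

    vcf = out / "variants.vcf"
    with vcf.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count">\n')
        fh.write('##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">\n')
        for pop in POPULATIONS:
            fh.write(
                f'##INFO=<ID=AF_{pop},Number=A,Type=Float,Description="{pop} allele frequency">\n'
            )
        fh.write(f"##contig=<ID={model.chromosome}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for site in sorted(sites, key=lambda s: (s.genomic_pos, s.alt)):
            info = f"AC={site.allele_count};AN={site.allele_number};" + ";".join(
                f"AF_{p}={site.per_population_af[p]:.3e}" for p in POPULATIONS
            )
            fh.write(
                f"{model.chromosome}\t{site.genomic_pos}\t.\t"
                f"{_forward_allele(model, site.ref)}\t{_forward_allele(model, site.alt)}\t"
                f".\tPASS\t{info}\n"
            )

    cov_rows = [
        {"chrom": model.chromosome, "pos": pos, "frac_ge_10x": round(frac, 6)}
        for pos, frac in sorted(coverage.fraction_ge_10x.items())
    ]
    pd.DataFrame(cov_rows).to_csv(out / "coverage.tsv", sep="\t", index=False)

    ev_rows = [
        {
            "transcript_id": r.transcript_id,
            "codon_index": r.codon_index,
            "ref": r.ref,
            "alt": r.alt,
            "classification_clinvar": r.classification_clinvar or "",
            "classification_hgmd": r.classification_hgmd or "",
            "phenotype_terms": ";".join(r.phenotype_terms),
            "de_novo": r.de_novo,
            "n_affected_genotyped_carriers": r.n_affected_genotyped_carriers,
            "n_affected_genotyped_noncarriers": r.n_affected_genotyped_noncarriers,
            "n_unaffected_genotyped_carriers": r.n_unaffected_genotyped_carriers,
        }
        for r in records
    ]
    pd.DataFrame(ev_rows).to_csv(out / "evidence.tsv", sep="\t", index=False)

    fm = simulate_feature_matrix(
        n_case=n_pathogenic,
        n_control=2 * n_pathogenic,
        feature_spec=config.feature_spec,
        seed=config.seed,
        gene_symbol=model.gene_symbol,
    )
    feat = fm.scores.copy()
    feat.insert(0, "label", fm.labels)
    feat.insert(0, "gene", fm.genes)
    feat.index.name = "variant_id"
    feat.to_csv(out / "features.tsv", sep="\t")

    manifest = {
        "seed": config.seed,
        "transcript_id": model.transcript_id,
        "n_codons": model.protein_length,
        "n_standing_sites": len(sites),
        "n_pathogenic_records": len(records),
        "files": [
            "cds.fasta",
            "exons.tsv",
            "variants.vcf",
            "coverage.tsv",
            "evidence.tsv",
            "features.tsv",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
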