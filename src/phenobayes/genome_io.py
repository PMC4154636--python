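"""Per-individual variant calls, genotype dosing and rare-variant selection.

A personal genome is reduced to the minimum the model needs: variant
position, reference and alternative allele, and the count of alternative
alleles carried (1 = heterozygous, 2 = homozygous), plus age, gender and
self-reported ancestry. Sites without a call are assumed homozygous for
the genomic reference — genomes here list only differences from the
reference, and no-call regions are not distinguishable in that input.

Coordinates are 1-based, fully closed, forward strand (VCF convention) in
every supported format. Indels are compared as given, without
left-alignment; knowledge base and genomes must share coordinate
provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .annotation_kb import AnnotationKB, GwasHit, HighPenetranceVariant
from .exceptions import MalformedInput

logger = logging.getLogger(__name__)

PRESENT = "PRESENT"
ABSENT = "ABSENT"
UNKNOWN = "UNKNOWN"

#: consequence labels counted as non-silent for rare-variant selection
DEFAULT_NONSILENT = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift",
        "splice-site",
        "in-frame-indel",
        "stop-loss",
    }
)

#: variants at or above this minor allele frequency are "common"
RARE_MAF = 0.01


@dataclass(frozen=True)
class GenotypeCall:
    """One alternative allele observed in one individual at one site."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    allele_count: int  # 1 = heterozygous, 2 = homozygous alternative

    def __post_init__(self) -> None:
        if self.alt_allele == self.ref_allele:
            raise ValueError(f"call at {self.chrom}:{self.pos}: alt == ref")
        if self.allele_count not in (1, 2):
            raise ValueError(
                f"call at {self.chrom}:{self.pos}: allele_count must be 1 "
                f"or 2, got {self.allele_count}"
            )


@dataclass
class PersonalGenome:
    participant_id: str
    calls: list[GenotypeCall] = field(default_factory=list)
    age: float = 0.0
    gender: str = ""
    ancestry: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        unique = []
        for c in self.calls:
            key = (c.chrom, c.pos, c.alt_allele)
            if key not in seen:
                seen.add(key)
                unique.append(c)
        self.calls = unique
        self._by_site: dict[tuple[str, int], list[GenotypeCall]] = {}
        for c in self.calls:
            self._by_site.setdefault((c.chrom, c.pos), []).append(c)

    def calls_at(self, chrom: str, pos: int) -> list[GenotypeCall]:
        return self._by_site.get((chrom, pos), [])

    def has_call(self, chrom: str, pos: int, ref: str, alt: str) -> int:
        """Allele count of an exact (chrom,pos,ref,alt) match, else 0."""
        for c in self.calls_at(chrom, pos):
            if c.ref_allele == ref and c.alt_allele == alt:
                return c.allele_count
        return 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PersonalGenome):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and sorted(self.calls, key=repr) == sorted(other.calls, key=repr)
            and self.age == other.age
            and self.gender == other.gender
            and self.ancestry == other.ancestry
        )


class CohortPhenotypes:
    """Participant × phenotype status matrix (PRESENT / ABSENT / UNKNOWN)."""

    def __init__(self, frame: pd.DataFrame | None = None) -> None:
        # frame: index participants, columns phenotypes, values status labels
        self.frame = frame if frame is not None else pd.DataFrame()
        bad = set(self.frame.values.ravel()) - {PRESENT, ABSENT, UNKNOWN}
        if bad:
            raise ValueError(f"invalid phenotype statuses: {sorted(bad)}")

    @property
    def participants(self) -> list[str]:
        return list(self.frame.index)

    @property
    def phenotypes(self) -> list[str]:
        return list(self.frame.columns)

    def status(self, participant: str, phenotype: str) -> str:
        return self.frame.loc[participant, phenotype]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_genome(
    path: str | Path,
    format: str = "vcf",
    metadata: Mapping[str, object] | None = None,
) -> PersonalGenome:
    """Read one individual's variant calls.

    ``metadata`` must supply ``participant_id``, ``age``, ``gender`` and
    ``ancestry``; a participant with missing metadata is rejected, mirroring
    cohort-inclusion practice. Multi-allelic records are split into one
    call per alternative allele.
    """
    meta = dict(metadata or {})
    for key in ("participant_id", "age", "gender", "ancestry"):
        if key not in meta or meta[key] in ("", None):
            raise MalformedInput(
                f"{path}: participant rejected: missing metadata field {key!r}"
            )
    if format == "vcf":
        calls = _read_vcf_calls(Path(path))
    elif format == "tsv":
        genomes = read_genomes_tsv(path, {meta["participant_id"]: meta})
        return genomes[str(meta["participant_id"])]
    else:
        raise MalformedInput(f"unknown genome format {format!r}")
    return PersonalGenome(
        participant_id=str(meta["participant_id"]),
        calls=calls,
        age=float(meta["age"]),
        gender=str(meta["gender"]),
        ancestry=str(meta["ancestry"]),
    )


def _read_vcf_calls(path: Path) -> list[GenotypeCall]:
    from cyvcf2 import VCF

    calls: list[GenotypeCall] = []
    vcf = VCF(str(path))
    try:
        for rec in vcf:
            gt = rec.genotypes[0] if rec.genotypes else None
            if gt is None:
                continue
            alleles = [a for a in gt[:-1] if a is not None and a >= 0]
            for alt_index, alt in enumerate(rec.ALT, start=1):
                count = sum(1 for a in alleles if a == alt_index)
                if count in (1, 2):
                    calls.append(
                        GenotypeCall(
                            chrom=rec.CHROM,
                            pos=rec.POS,
                            ref_allele=rec.REF,
                            alt_allele=alt,
                            allele_count=count,
                        )
                    )
    finally:
        vcf.close()
    return calls


def read_genomes_tsv(
    path: str | Path, metadata: Mapping[str, Mapping[str, object]]
) -> dict[str, PersonalGenome]:
    """Read the TSV genome dialect (may hold a whole cohort).

    Columns: participant_id, chrom, pos, ref, alt, allele_count.
    ``metadata`` maps participant id to its age/gender/ancestry record;
    participants lacking metadata are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["participant_id", "chrom", "pos", "ref", "alt", "allele_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MalformedInput(f"{path}: missing columns {missing}")
    calls_by_pid: dict[str, list[GenotypeCall]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            call = GenotypeCall(
                chrom=row.chrom,
                pos=int(row.pos),
                ref_allele=row.ref,
                alt_allele=row.alt,
                allele_count=int(row.allele_count),
            )
        except ValueError as exc:
            raise MalformedInput(f"{path}: line {i}: {exc}") from exc
        calls_by_pid.setdefault(row.participant_id, []).append(call)
    genomes = {}
    for pid in sorted(set(calls_by_pid) | set(metadata)):
        meta = metadata.get(pid)
        if meta is None or any(
            meta.get(k) in ("", None) for k in ("age", "gender", "ancestry")
        ):
            raise MalformedInput(
                f"{path}: participant {pid!r} rejected: missing metadata"
            )
        genomes[pid] = PersonalGenome(
            participant_id=pid,
            calls=calls_by_pid.get(pid, []),
            age=float(meta["age"]),
            gender=str(meta["gender"]),
            ancestry=str(meta["ancestry"]),
        )
    return genomes


def write_genomes_tsv(genomes: Iterable[PersonalGenome], path: str | Path) -> None:
    rows = [
        {
            "participant_id": g.participant_id,
            "chrom": c.chrom,
            "pos": c.pos,
            "ref": c.ref_allele,
            "alt": c.alt_allele,
            "allele_count": c.allele_count,
        }
        for g in genomes
        for c in g.calls
    ]
    pd.DataFrame(
        rows,
        columns=["participant_id", "chrom", "pos", "ref", "alt", "allele_count"],
    ).to_csv(Path(path), sep="\t", index=False)


def read_participants_tsv(path: str | Path) -> dict[str, dict[str, object]]:
    """Read participant metadata: participant_id, age, gender, ancestry."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    return {
        row.participant_id: {
            "participant_id": row.participant_id,
            "age": float(row.age),
            "gender": row.gender,
            "ancestry": row.ancestry,
        }
        for row in df.itertuples(index=False)
    }


def write_participants_tsv(
    genomes: Iterable[PersonalGenome], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "participant_id": g.participant_id,
                "age": g.age,
                "gender": g.gender,
                "ancestry": g.ancestry,
            }
            for g in genomes
        ],
        columns=["participant_id", "age", "gender", "ancestry"],
    ).to_csv(Path(path), sep="\t", index=False)


_STATUS_TO_TSV = {PRESENT: "1", ABSENT: "0", UNKNOWN: "NA"}
_TSV_TO_STATUS = {v: k for k, v in _STATUS_TO_TSV.items()}


def read_phenotypes_tsv(path: str | Path) -> CohortPhenotypes:
    """Read the long-format status table: participant_id, phenotype, status."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.status not in _TSV_TO_STATUS:
            raise MalformedInput(
                f"{path}: line {i}: column 'status': expected 1/0/NA, "
                f"got {row.status!r}"
            )
    wide = (
        df.assign(status=df["status"].map(_TSV_TO_STATUS))
        .pivot(index="participant_id", columns="phenotype", values="status")
        .fillna(UNKNOWN)
    )
    wide.index.name = None
    wide.columns.name = None
    return CohortPhenotypes(wide)


def write_phenotypes_tsv(cohort: CohortPhenotypes, path: str | Path) -> None:
    rows = [
        {
            "participant_id": pid,
            "phenotype": pheno,
            "status": _STATUS_TO_TSV[cohort.frame.loc[pid, pheno]],
        }
        for pid in cohort.participants
        for pheno in cohort.phenotypes
    ]
    pd.DataFrame(rows, columns=["participant_id", "phenotype", "status"]).to_csv(
        Path(path), sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# genotype resolution against the knowledge base
# ---------------------------------------------------------------------------

def risk_allele_dose(genome: PersonalGenome, hit: GwasHit) -> int | None:
    """Number of risk alleles carried at a GWAS hit, in {0, 1, 2}.

    Absence of a call at the site means homozygous genomic reference: the
    dose is then 2 when the risk allele is the recorded reference allele
    and 0 otherwise. A call whose alleles cannot be reconciled with the
    hit's allele pair makes the site unresolvable (returns None); such
    sites are excluded from the likelihood product rather than imputed.
    """
    calls = genome.calls_at(hit.chrom, hit.pos)
    if not calls:
        if hit.ref_allele is not None and hit.risk_allele == hit.ref_allele:
            return 2
        return 0
    for call in calls:
        if call.alt_allele == hit.risk_allele:
            return call.allele_count
        if call.alt_allele == hit.other_allele and call.ref_allele == hit.risk_allele:
            return 2 - call.allele_count
    logger.warning(
        "unresolvable site %s:%s for %s: call alleles inconsistent with "
        "GWAS hit %s", hit.chrom, hit.pos, genome.participant_id, hit.rsid,
    )
    return None


def select_rare_nonsilent(
    genome: PersonalGenome,
    gene: str,
    kb: AnnotationKB,
    nonsilent: frozenset[str] = DEFAULT_NONSILENT,
    rare_in_all_populations: bool = True,
) -> list[GenotypeCall]:
    """The individual's rare, non-silent calls within a gene.

    Rarity requires MAF < 0.01; with ``rare_in_all_populations`` (default)
    every population recorded in the KB must satisfy the bound, otherwise
    one suffices. Variants absent from the frequency map count as rare
    (an unobserved allele is presumed rarer than the catalogued ones).
    Calls without a consequence label are excluded: they cannot be
    certified non-silent.
    """
    region = kb.gene_regions.get(gene)
    if region is None:
        logger.warning("gene %s has no coordinates in the KB", gene)
        return []
    chrom, start, end = region
    selected = []
    for call in genome.calls:
        if call.chrom != chrom or not start <= call.pos <= end:
            continue
        freqs = kb.allele_freqs.get((call.chrom, call.pos, call.alt_allele))
        if freqs:
            values = list(freqs.values())
            if rare_in_all_populations:
                rare = all(v < RARE_MAF for v in values)
            else:
                rare = any(v < RARE_MAF for v in values)
        else:
            rare = True  # unobserved allele treated as rare
            logger.debug(
                "no recorded MAF for %s:%s %s; treated as rare",
                call.chrom, call.pos, call.alt_allele,
            )
        if not rare:
            continue
        consequence = kb.consequences.get(
            (call.chrom, call.pos, call.ref_allele, call.alt_allele)
        )
        if consequence in nonsilent:
            selected.append(call)
    return selected


def match_hp_variant(
    genome: PersonalGenome, kb: AnnotationKB, phenotype: str
) -> list[tuple[HighPenetranceVariant, int]]:
    """Curated disease variants present in the genome, with zygosity.

    Matching is exact on (chrom, pos, ref, alt); the returned allele count
    carries zygosity through. Any match — heterozygous or homozygous —
    counts: curated disease variants are treated as dominant-acting.
    """
    matches = []
    for v in kb.hp_variants_for(phenotype):
        count = genome.has_call(v.chrom, v.pos, v.ref_allele, v.alt_allele)
        if count:
            if count == 1:
                logger.debug(
                    "heterozygous curated variant %s:%s in %s treated as "
                    "dominant-acting", v.chrom, v.pos, genome.participant_id,
                )
            matches.append((v, count))
    return matches
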