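"""Knowledge base of phenotype-associated variants, genes and prevalences.

The knowledge layer collects, per phenotype:

* GWAS hits — common variants with a reported odds ratio and risk-allele
  frequency, treated as *low-penetrance variants*;
* high-penetrance variants — curated disease mutations (the most confident
  "DM" class of a mutation database);
* gene associations — phenotype-associated genes labelled HIGH (curated) or
  LOW (literature-mined) penetrance;
* a prevalence table stratified by ancestry, gender and age band, which
  supplies the model's prior.

Inclusion filters applied on load:

* GWAS hits are kept only when ``1 < OR <= 20`` (effect sizes reported as
  beta regression coefficients are treated as log-odds and exponentiated
  first);
* mined gene associations are kept only when Z > 4.0 or they rank in the
  top five for their phenotype by Z-score;
* curated disease variants are admitted only from the most confident
  disease-mutation class ("DM").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import MalformedInput, NoPrevalence

logger = logging.getLogger(__name__)

#: label of the curated disease-mutation class admitted as high penetrance
DM_CLASS = "DM"

#: wildcard used in prevalence tables for "any ancestry" / "any gender"
ALL = "ALL"

HIGH = "HIGH"
LOW = "LOW"


@dataclass(frozen=True)
class GwasHit:
    """A GWAS association: one risk allele at one site for one phenotype.

    ``ref_allele`` optionally records the genomic reference base at the
    site; it is needed to dose individuals whose genome has no call there
    when the risk allele is itself the reference allele.
    """

    rsid: str
    chrom: str
    pos: int
    risk_allele: str
    other_allele: str
    effect_size: float
    risk_allele_freq: float
    phenotype: str
    ref_allele: str | None = None
    from_beta: bool = False  # effect was reported as a beta coefficient

    def __post_init__(self) -> None:
        if not self.effect_size > 0:
            raise ValueError(
                f"GWAS hit {self.rsid}: effect size must be positive, "
                f"got {self.effect_size}"
            )
        if not 0.0 < self.risk_allele_freq < 1.0:
            raise ValueError(
                f"GWAS hit {self.rsid}: risk allele frequency must lie in "
                f"(0,1), got {self.risk_allele_freq}"
            )
        if self.risk_allele == self.other_allele:
            raise ValueError(
                f"GWAS hit {self.rsid}: risk and other allele are identical"
            )


@dataclass(frozen=True)
class HighPenetranceVariant:
    """A curated disease mutation (highest-confidence class only)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene: str
    phenotype: str
    source_class: str = DM_CLASS


@dataclass(frozen=True)
class GeneAssociation:
    """A phenotype-associated gene.

    Curated associations carry ``zscore=None``; literature-mined ones carry
    the mining Z-score.
    """

    gene: str
    phenotype: str
    penetrance_class: str
    zscore: float | None = None

    def __post_init__(self) -> None:
        if self.penetrance_class not in (HIGH, LOW):
            raise ValueError(
                f"gene {self.gene}: penetrance class must be HIGH or LOW, "
                f"got {self.penetrance_class!r}"
            )

    @property
    def curated(self) -> bool:
        return self.zscore is None


@dataclass(frozen=True)
class PrevalenceEntry:
    phenotype: str
    ancestry: str  # ALL = any
    gender: str  # ALL = any
    age_lo: float | None  # None = unbounded below; band is [lo, hi)
    age_hi: float | None  # None = unbounded above
    prevalence: float
    source: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(
                f"prevalence for {self.phenotype} must lie in (0,1), "
                f"got {self.prevalence}"
            )

    def matches(self, ancestry: str, gender: str, age: float) -> bool:
        if self.ancestry != ALL and self.ancestry != ancestry:
            return False
        if self.gender != ALL and self.gender != gender:
            return False
        if self.age_lo is not None and age < self.age_lo:
            return False
        if self.age_hi is not None and age >= self.age_hi:
            return False
        return True

    def _specificity(self) -> tuple[int, int, int]:
        # lower sorts first: specific keys beat wildcards, and the drop
        # order on fallback is age band first, then ancestry, then gender
        return (
            int(self.gender == ALL),
            int(self.ancestry == ALL),
            int(self.age_lo is None and self.age_hi is None),
        )


class PrevalenceTable:
    """Phenotype prevalences stratified by ancestry / gender / age band."""

    def __init__(self, entries: Iterable[PrevalenceEntry] = ()) -> None:
        self.entries: list[PrevalenceEntry] = list(entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PrevalenceTable) and sorted(
            self.entries, key=repr
        ) == sorted(other.entries, key=repr)

    def __len__(self) -> int:
        return len(self.entries)

    def phenotypes(self) -> set[str]:
        return {e.phenotype for e in self.entries}

    def add(self, entry: PrevalenceEntry) -> None:
        self.entries.append(entry)

    def lookup(
        self, phenotype: str, ancestry: str, gender: str, age: float
    ) -> float:
        """Most specific matching prevalence for the individual.

        Falls back from the full (ancestry, gender, age-band) key by
        relaxing, in order of preference, the age band, then ancestry,
        then gender, down to the phenotype-global row. Raises
        :class:`NoPrevalence` when the phenotype has no matching entry at
        all (such phenotypes are excluded from prediction).
        """
        candidates = [
            e
            for e in self.entries
            if e.phenotype == phenotype and e.matches(ancestry, gender, age)
        ]
        if not candidates:
            raise NoPrevalence(
                f"no prevalence for phenotype {phenotype!r} "
                f"(ancestry={ancestry}, gender={gender}, age={age})"
            )
        best = min(candidates, key=lambda e: e._specificity())
        return best.prevalence


def lookup_prevalence(
    table: PrevalenceTable, phenotype: str, ancestry: str, gender: str, age: float
) -> float:
    """Functional alias for :meth:`PrevalenceTable.lookup`."""
    return table.lookup(phenotype, ancestry, gender, age)


def average_prevalence(table: PrevalenceTable) -> float:
    """Mean of each phenotype's most-global prevalence row.

    Used as the uniform baseline prior in genome-only evaluation, where
    every phenotype and individual is assigned the same prevalence.
    """
    per_pheno = []
    for pheno in sorted(table.phenotypes()):
        rows = [e for e in table.entries if e.phenotype == pheno]
        best = min(rows, key=lambda e: tuple(-x for x in e._specificity()))
        per_pheno.append(best.prevalence)
    if not per_pheno:
        raise NoPrevalence("prevalence table is empty")
    return float(sum(per_pheno) / len(per_pheno))


# ---------------------------------------------------------------------------
# inclusion filters
# ---------------------------------------------------------------------------

def effective_odds_ratio(hit: GwasHit) -> GwasHit:
    """Normalise a beta-coefficient effect size to an odds ratio.

    Effect sizes flagged ``from_beta`` are treated as log-odds and
    exponentiated; the returned record is flagged so downstream code can
    tell which convention applied.
    """
    if hit.from_beta:
        return replace(hit, effect_size=math.exp(hit.effect_size), from_beta=True)
    return hit


def filter_gwas_hits(raw_hits: Sequence[GwasHit]) -> list[GwasHit]:
    """Keep exactly the hits with odds ratio in (1, 20]; order preserved.

    Records with a non-positive effect size are rejected outright (they
    are malformed, not merely out of range) — but GwasHit construction
    already refuses those, so the check here guards records built through
    other paths.
    """
    kept = []
    for hit in raw_hits:
        if not hit.effect_size > 0:
            raise ValueError(
                f"GWAS hit {hit.rsid}: non-positive effect size "
                f"{hit.effect_size}"
            )
        if 1.0 < hit.effect_size <= 20.0:
            kept.append(hit)
    return kept


def filter_gene_associations(
    raw: Sequence[GeneAssociation],
    per_phenotype_rank: Mapping[tuple[str, str], int] | None = None,
) -> list[GeneAssociation]:
    """Apply the mined-association filter: Z > 4.0 or top-5 by Z-score.

    Curated associations (no Z-score) are always kept. Ranks are computed
    within each phenotype by descending Z-score, ties broken by stable
    input order; a precomputed ``(phenotype, gene) -> rank`` map may be
    supplied instead.
    """
    mined = [a for a in raw if not a.curated]
    for a in mined:
        if a.zscore is None or math.isnan(a.zscore):
            raise ValueError(
                f"mined association {a.gene}/{a.phenotype} lacks a Z-score"
            )
    if per_phenotype_rank is None:
        per_phenotype_rank = {}
        by_pheno: dict[str, list[GeneAssociation]] = {}
        for a in mined:
            by_pheno.setdefault(a.phenotype, []).append(a)
        for pheno, assocs in by_pheno.items():
            # stable sort: ties at the rank-5 boundary keep input order
            ordered = sorted(assocs, key=lambda a: -a.zscore)
            for rank, a in enumerate(ordered, start=1):
                per_phenotype_rank[(a.phenotype, a.gene)] = rank
    kept = []
    for a in raw:
        if a.curated:
            kept.append(a)
            continue
        rank = per_phenotype_rank.get((a.phenotype, a.gene))
        if a.zscore > 4.0 or (rank is not None and rank <= 5):
            kept.append(a)
    return kept


def admit_high_penetrance_variant(record: HighPenetranceVariant) -> bool:
    """True iff the record is in the most confident disease-mutation class."""
    return record.source_class == DM_CLASS


# ---------------------------------------------------------------------------
# the assembled knowledge base
# ---------------------------------------------------------------------------

@dataclass
class AnnotationKB:
    """All phenotype annotations plus allele frequencies and consequences.

    ``allele_freqs`` maps ``(chrom, pos, alt) -> {population: MAF}``;
    ``consequences`` maps ``(chrom, pos, ref, alt) -> label``;
    ``gene_regions`` maps gene symbol -> ``(chrom, start, end)`` with
    1-based fully-closed coordinates.
    """

    gwas_hits: list[GwasHit] = field(default_factory=list)
    hp_variants: list[HighPenetranceVariant] = field(default_factory=list)
    gene_assocs: list[GeneAssociation] = field(default_factory=list)
    allele_freqs: dict[tuple[str, int, str], dict[str, float]] = field(
        default_factory=dict
    )
    consequences: dict[tuple[str, int, str, str], str] = field(
        default_factory=dict
    )
    gene_regions: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    prevalence: PrevalenceTable = field(default_factory=PrevalenceTable)

    def __post_init__(self) -> None:
        self._dedupe()
        self._ensure_hp_genes()

    def _dedupe(self) -> None:
        seen: set[tuple] = set()
        unique_hits = []
        for h in self.gwas_hits:
            key = (h.phenotype, h.chrom, h.pos, h.risk_allele)
            if key not in seen:
                seen.add(key)
                unique_hits.append(h)
        self.gwas_hits = unique_hits
        seen = set()
        unique_hp = []
        for v in self.hp_variants:
            key = (v.phenotype, v.chrom, v.pos, v.alt_allele)
            if key not in seen:
                seen.add(key)
                unique_hp.append(v)
        self.hp_variants = unique_hp

    def _ensure_hp_genes(self) -> None:
        """Every curated disease variant's gene is a HIGH association."""
        have = {(a.gene, a.phenotype, a.penetrance_class) for a in self.gene_assocs}
        for v in self.hp_variants:
            if (v.gene, v.phenotype, HIGH) not in have:
                self.gene_assocs.append(
                    GeneAssociation(v.gene, v.phenotype, HIGH)
                )
                have.add((v.gene, v.phenotype, HIGH))

    # --- per-phenotype views -------------------------------------------

    def phenotypes(self) -> set[str]:
        return (
            {h.phenotype for h in self.gwas_hits}
            | {v.phenotype for v in self.hp_variants}
            | {a.phenotype for a in self.gene_assocs}
        )

    def gwas_for(self, phenotype: str) -> list[GwasHit]:
        return [h for h in self.gwas_hits if h.phenotype == phenotype]

    def hp_variants_for(self, phenotype: str) -> list[HighPenetranceVariant]:
        return [v for v in self.hp_variants if v.phenotype == phenotype]

    def genes_for(self, phenotype: str, penetrance_class: str) -> list[str]:
        """Gene symbols in the given class, HIGH taking precedence.

        A gene annotated both HIGH (curated) and LOW (mined) for the same
        phenotype contributes only to the HIGH category.
        """
        high = {
            a.gene
            for a in self.gene_assocs
            if a.phenotype == phenotype and a.penetrance_class == HIGH
        }
        if penetrance_class == HIGH:
            return sorted(high)
        low = {
            a.gene
            for a in self.gene_assocs
            if a.phenotype == phenotype and a.penetrance_class == LOW
        }
        return sorted(low - high)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationKB):
            return NotImplemented
        return (
            sorted(self.gwas_hits, key=repr) == sorted(other.gwas_hits, key=repr)
            and sorted(self.hp_variants, key=repr)
            == sorted(other.hp_variants, key=repr)
            and sorted(self.gene_assocs, key=repr)
            == sorted(other.gene_assocs, key=repr)
            and self.allele_freqs == other.allele_freqs
            and self.consequences == other.consequences
            and self.gene_regions == other.gene_regions
            and self.prevalence == other.prevalence
        )


# ---------------------------------------------------------------------------
# TSV persistence
# ---------------------------------------------------------------------------

_FILES = {
    "gwas": "kb_gwas.tsv",
    "hp": "kb_hpvariants.tsv",
    "genes": "kb_genes.tsv",
    "prevalence": "prevalence.tsv",
    "freqs": "kb_freqs.tsv",
    "consequences": "kb_consequences.tsv",
    "regions": "kb_gene_regions.tsv",
}


def _read_tsv(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        return pd.DataFrame(columns=required)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MalformedInput(f"{path}: cannot parse: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MalformedInput(f"{path}: missing columns {missing}")
    return df


def _num(path: Path, line: int, col: str, raw: str) -> float:
    try:
        return float(raw)
    except ValueError as exc:
        raise MalformedInput(
            f"{path}: line {line}: column '{col}': not a number: {raw!r}"
        ) from exc


def load_kb(directory: str | Path, apply_filters: bool = True) -> AnnotationKB:
    """Load a knowledge base from a directory of TSV files.

    Missing files yield empty collections. With ``apply_filters`` (the
    default) the GWAS odds-ratio window, the mined-gene Z/top-5 rule and
    the DM-only admission of curated variants are enforced on load.
    """
    directory = Path(directory)
    kb = AnnotationKB()

    path = directory / _FILES["gwas"]
    df = _read_tsv(
        path,
        [
            "phenotype", "rsid", "chrom", "pos", "risk_allele",
            "other_allele", "odds_ratio", "risk_allele_freq",
        ],
    )
    hits = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            hit = GwasHit(
                rsid=row.rsid,
                chrom=row.chrom,
                pos=int(_num(path, i, "pos", row.pos)),
                risk_allele=row.risk_allele,
                other_allele=row.other_allele,
                effect_size=_num(path, i, "odds_ratio", row.odds_ratio),
                risk_allele_freq=_num(
                    path, i, "risk_allele_freq", row.risk_allele_freq
                ),
                phenotype=row.phenotype,
                ref_allele=(getattr(row, "ref_allele", "") or None),
                from_beta=(getattr(row, "is_beta", "") in ("1", "true", "True")),
            )
        except ValueError as exc:
            raise MalformedInput(f"{path}: line {i}: {exc}") from exc
        hits.append(effective_odds_ratio(hit))
    kb.gwas_hits = filter_gwas_hits(hits) if apply_filters else hits

    path = directory / _FILES["hp"]
    df = _read_tsv(path, ["phenotype", "chrom", "pos", "ref", "alt", "gene", "class"])
    variants = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        v = HighPenetranceVariant(
            chrom=row.chrom,
            pos=int(_num(path, i, "pos", row.pos)),
            ref_allele=row.ref,
            alt_allele=row.alt,
            gene=row.gene,
            phenotype=row.phenotype,
            source_class=row[6],  # "class" is a keyword; itertuples renames it
        )
        variants.append(v)
    if apply_filters:
        variants = [v for v in variants if admit_high_penetrance_variant(v)]
    kb.hp_variants = variants

    path = directory / _FILES["genes"]
    df = _read_tsv(path, ["phenotype", "gene", "penetrance_class", "zscore"])
    assocs = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        z = None if row.zscore == "" else _num(path, i, "zscore", row.zscore)
        try:
            assocs.append(
                GeneAssociation(row.gene, row.phenotype, row.penetrance_class, z)
            )
        except ValueError as exc:
            raise MalformedInput(f"{path}: line {i}: {exc}") from exc
    kb.gene_assocs = (
        filter_gene_associations(assocs) if apply_filters else assocs
    )

    path = directory / _FILES["prevalence"]
    df = _read_tsv(
        path,
        ["phenotype", "ancestry", "gender", "age_lo", "age_hi", "prevalence"],
    )
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            kb.prevalence.add(
                PrevalenceEntry(
                    phenotype=row.phenotype,
                    ancestry=row.ancestry or ALL,
                    gender=row.gender or ALL,
                    age_lo=None if row.age_lo == "" else _num(path, i, "age_lo", row.age_lo),
                    age_hi=None if row.age_hi == "" else _num(path, i, "age_hi", row.age_hi),
                    prevalence=_num(path, i, "prevalence", row.prevalence),
                    source=getattr(row, "source", ""),
                )
            )
        except ValueError as exc:
            raise MalformedInput(f"{path}: line {i}: {exc}") from exc

    path = directory / _FILES["freqs"]
    df = _read_tsv(path, ["chrom", "pos", "alt", "population", "maf"])
    for i, row in enumerate(df.itertuples(index=False), start=2):
        key = (row.chrom, int(_num(path, i, "pos", row.pos)), row.alt)
        kb.allele_freqs.setdefault(key, {})[row.population] = _num(
            path, i, "maf", row.maf
        )

    path = directory / _FILES["consequences"]
    df = _read_tsv(path, ["chrom", "pos", "ref", "alt", "consequence"])
    for i, row in enumerate(df.itertuples(index=False), start=2):
        kb.consequences[
            (row.chrom, int(_num(path, i, "pos", row.pos)), row.ref, row.alt)
        ] = row.consequence

    path = directory / _FILES["regions"]
    df = _read_tsv(path, ["gene", "chrom", "start", "end"])
    for i, row in enumerate(df.itertuples(index=False), start=2):
        kb.gene_regions[row.gene] = (
            row.chrom,
            int(_num(path, i, "start", row.start)),
            int(_num(path, i, "end", row.end)),
        )

    kb.__post_init__()  # re-run consistency normalisation after load
    return kb


def write_kb(kb: AnnotationKB, directory: str | Path) -> None:
    """Write a KB to a directory of TSV files; ``load_kb`` inverts this."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {
                "phenotype": h.phenotype,
                "rsid": h.rsid,
                "chrom": h.chrom,
                "pos": h.pos,
                "risk_allele": h.risk_allele,
                "other_allele": h.other_allele,
                "odds_ratio": repr(h.effect_size),
                "risk_allele_freq": repr(h.risk_allele_freq),
                "ref_allele": h.ref_allele or "",
            }
            for h in kb.gwas_hits
        ],
        columns=[
            "phenotype", "rsid", "chrom", "pos", "risk_allele",
            "other_allele", "odds_ratio", "risk_allele_freq", "ref_allele",
        ],
    ).to_csv(directory / _FILES["gwas"], sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "phenotype": v.phenotype,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref_allele,
                "alt": v.alt_allele,
                "gene": v.gene,
                "class": v.source_class,
            }
            for v in kb.hp_variants
        ],
        columns=["phenotype", "chrom", "pos", "ref", "alt", "gene", "class"],
    ).to_csv(directory / _FILES["hp"], sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "phenotype": a.phenotype,
                "gene": a.gene,
                "penetrance_class": a.penetrance_class,
                "zscore": "" if a.zscore is None else repr(a.zscore),
            }
            for a in kb.gene_assocs
        ],
        columns=["phenotype", "gene", "penetrance_class", "zscore"],
    ).to_csv(directory / _FILES["genes"], sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "phenotype": e.phenotype,
                "ancestry": e.ancestry,
                "gender": e.gender,
                "age_lo": "" if e.age_lo is None else repr(e.age_lo),
                "age_hi": "" if e.age_hi is None else repr(e.age_hi),
                "prevalence": repr(e.prevalence),
                "source": e.source,
            }
            for e in kb.prevalence.entries
        ],
        columns=[
            "phenotype", "ancestry", "gender", "age_lo", "age_hi",
            "prevalence", "source",
        ],
    ).to_csv(directory / _FILES["prevalence"], sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "chrom": chrom,
                "pos": pos,
                "alt": alt,
                "population": popn,
                "maf": repr(maf),
            }
            for (chrom, pos, alt), pops in kb.allele_freqs.items()
            for popn, maf in pops.items()
        ],
        columns=["chrom", "pos", "alt", "population", "maf"],
    ).to_csv(directory / _FILES["freqs"], sep="\t", index=False)

    pd.DataFrame(
        [
            {"chrom": c, "pos": p, "ref": r, "alt": a, "consequence": label}
            for (c, p, r, a), label in kb.consequences.items()
        ],
        columns=["chrom", "pos", "ref", "alt", "consequence"],
    ).to_csv(directory / _FILES["consequences"], sep="\t", index=False)

    pd.DataFrame(
        [
            {"gene": g, "chrom": c, "start": s, "end": e}
            for g, (c, s, e) in kb.gene_regions.items()
        ],
        columns=["gene", "chrom", "start", "end"],
    ).to_csv(directory / _FILES["regions"], sep="\t", index=False)
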