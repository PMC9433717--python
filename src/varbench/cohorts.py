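"""Labeled benchmark-cohort construction.

Cohorts of pathogenic and benign missense variants are assembled through
explicit, auditable filter chains:

* a ClinVar-style chain (disease-ontology match, review-star floor,
  significance exclusions, P/LP vs B/LB labeling),
* a population-database chain for benign controls (allele-frequency floor,
  gene-panel restriction, missense selection, gene exclusions, overlap
  exclusion against other cohorts, then a seeded random split),
* import of externally curated clinical lists,
* circularity control (removal of variants present in tool training sets)
  and recency filtering (variants first reported after a cutoff date).

Every operation returns a :class:`CohortDataset` whose ``audit_trail``
records (filter_name, n_in, n_kept) for each step, telescoping so that each
step's output count is the next step's input count.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .registry import VariantRecord

logger = logging.getLogger("varbench")

#: ClinVar significance strings that label a record pathogenic / benign.
PATHOGENIC_SIGNIFICANCES = frozenset(
    {"Pathogenic", "Likely_pathogenic", "Pathogenic/Likely_pathogenic"}
)
BENIGN_SIGNIFICANCES = frozenset({"Benign", "Likely_benign", "Benign/Likely_benign"})

DEFAULT_EXCLUDED_SIGNIFICANCES = frozenset(
    {"Uncertain_significance", "Conflicting_interpretations_of_pathogenicity"}
)


class CohortError(ValueError):
    """Raised for invalid cohort-construction inputs."""


@dataclass
class FilterRuleSet:
    """Parameters of a cohort filter chain; empty sets disable a rule."""

    ontology_ids: frozenset = frozenset()
    min_review_stars: int = 1
    excluded_significances: frozenset = DEFAULT_EXCLUDED_SIGNIFICANCES
    require_consequence: frozenset = frozenset({"missense_variant"})
    maf_threshold: float = 0.001
    gene_panel: frozenset = frozenset()
    excluded_genes: frozenset = frozenset()
    exclusion_variant_sets: tuple = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_threshold <= 1.0:
            raise CohortError("maf_threshold must lie in [0, 1]")


@dataclass
class CohortDataset:
    """A named, labeled set of variants plus the audit trail that built it."""

    name: str
    records: list = field(default_factory=list)
    audit_trail: list = field(default_factory=list)  # (filter_name, n_in, n_kept)

    @property
    def n_pathogenic(self) -> int:
        return sum(1 for r in self.records if r.label == "pathogenic")

    @property
    def n_benign(self) -> int:
        return sum(1 for r in self.records if r.label == "benign")

    @property
    def n_vus(self) -> int:
        return sum(1 for r in self.records if r.label == "vus")

    @property
    def keys(self) -> set:
        return {r.key for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def audit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.audit_trail, columns=["filter", "n_in", "n_kept"]
        )


def _step(trail: list, name: str, before: Sequence, after: Sequence) -> None:
    trail.append((name, len(before), len(after)))


def _require_unique_keys(records: Sequence[VariantRecord], context: str) -> None:
    keys = [r.key for r in records]
    if len(set(keys)) != len(keys):
        raise CohortError(f"{context}: duplicate variant keys in input")


# ---------------------------------------------------------------------------
# ClinVar-style chain
# ---------------------------------------------------------------------------

def significance_label(significance: str | None) -> str | None:
    """P/LP -> 'pathogenic', B/LB -> 'benign', anything else -> None."""
    if significance in PATHOGENIC_SIGNIFICANCES:
        return "pathogenic"
    if significance in BENIGN_SIGNIFICANCES:
        return "benign"
    return None


def filter_clinvar(
    records: Sequence[VariantRecord],
    rules: FilterRuleSet,
    name: str = "clinvar",
) -> CohortDataset:
    """ClinVar-style benchmark chain: ontology, review stars, significance.

    Keeps records matching at least one configured disease-ontology id (rule
    disabled when the set is empty), with ``review_stars >=
    min_review_stars``, whose significance is not excluded, and that carry a
    P/LP or B/LB significance (which becomes the benchmark label).
    """
    for fld in ("review_stars", "significance"):
        missing = [r.key_str for r in records if getattr(r, fld) is None]
        if missing:
            raise CohortError(
                f"filter_clinvar: records lacking required field {fld!r}: "
                + ", ".join(missing[:5])
            )
    _require_unique_keys(records, "filter_clinvar")
    trail: list = []
    cur = list(records)

    if rules.ontology_ids:
        nxt = [r for r in cur if r.ontology_ids & rules.ontology_ids]
        _step(trail, "ontology_match", cur, nxt)
        cur = nxt
    nxt = [r for r in cur if r.review_stars >= rules.min_review_stars]
    _step(trail, f"review_stars>={rules.min_review_stars}", cur, nxt)
    cur = nxt
    nxt = [r for r in cur if r.significance not in rules.excluded_significances]
    _step(trail, "significance_exclusions", cur, nxt)
    cur = nxt
    labeled = []
    for r in cur:
        lab = significance_label(r.significance)
        if lab is not None:
            rr = VariantRecord(**{**r.__dict__, "label": lab, "source": "clinvar"})
            labeled.append(rr)
    _step(trail, "assign_labels_plp_blb", cur, labeled)
    return CohortDataset(name=name, records=labeled, audit_trail=trail)


def select_missense(records: Sequence[VariantRecord]) -> list:
    """Keep records whose picked consequence contains 'missense_variant'."""
    return [r for r in records if "missense_variant" in (r.consequence or "")]


# ---------------------------------------------------------------------------
# Population-database benign chain
# ---------------------------------------------------------------------------

def build_gnomad_benign(
    records: Sequence[VariantRecord],
    rules: FilterRuleSet,
    split_sizes: Sequence[int] = (),
    seed: int = 0,
    name: str = "gnomad_benign",
) -> tuple[CohortDataset, list]:
    """Benign-control chain with a seeded disjoint split.

    Filter order: AF strictly above ``maf_threshold`` -> gene in panel ->
    missense -> gene not excluded -> key absent from every exclusion set.
    Survivors are labeled benign.  ``split_sizes`` then draws disjoint
    subsets without replacement (seeded); leftover survivors stay in the
    parent cohort but are logged as unassigned.
    """
    missing = [r.key_str for r in records if r.allele_frequency is None]
    if missing:
        raise CohortError(
            "build_gnomad_benign: records lacking required field "
            "'allele_frequency': " + ", ".join(missing[:5])
        )
    _require_unique_keys(records, "build_gnomad_benign")
    trail: list = []
    cur = list(records)

    nxt = [r for r in cur if r.allele_frequency > rules.maf_threshold]
    _step(trail, f"af>{rules.maf_threshold:g}", cur, nxt)
    cur = nxt
    if rules.gene_panel:
        nxt = [r for r in cur if r.gene in rules.gene_panel]
        _step(trail, "gene_panel", cur, nxt)
        cur = nxt
    nxt = select_missense(cur)
    _step(trail, "missense", cur, nxt)
    cur = nxt
    if rules.excluded_genes:
        nxt = [r for r in cur if r.gene not in rules.excluded_genes]
        _step(trail, "excluded_genes", cur, nxt)
        cur = nxt
    for i, excl in enumerate(rules.exclusion_variant_sets):
        nxt = [r for r in cur if r.key not in excl]
        _step(trail, f"exclusion_set_{i + 1}", cur, nxt)
        cur = nxt
    survivors = [
        VariantRecord(**{**r.__dict__, "label": "benign", "source": "gnomad"})
        for r in cur
    ]
    cohort = CohortDataset(name=name, records=survivors, audit_trail=trail)

    splits: list = []
    if split_sizes:
        total = sum(split_sizes)
        if total > len(survivors):
            raise CohortError(
                f"split sizes sum to {total} but only {len(survivors)} "
                "survivors are available"
            )
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(survivors))
        offset = 0
        for i, size in enumerate(split_sizes):
            idx = sorted(order[offset : offset + size])
            splits.append(
                CohortDataset(
                    name=f"{name}_set{i + 1}",
                    records=[survivors[j] for j in idx],
                    audit_trail=[(f"random_split_{i + 1}", len(survivors), size)],
                )
            )
            offset += size
        if total < len(survivors):
            logger.info(
                "build_gnomad_benign: %d survivors left unassigned by the split",
                len(survivors) - total,
            )
    return cohort, splits


# ---------------------------------------------------------------------------
# External clinical lists
# ---------------------------------------------------------------------------

def import_external_list(
    rows: pd.DataFrame,
    exclusion_keys: Iterable = (),
    significance_whitelist: Iterable = ("Pathogenic", "Likely_pathogenic"),
    name: str = "external",
    source: str = "share",
) -> CohortDataset:
    """Import a curated clinical list (TSV-style table) as a pathogenic cohort.

    Required columns: chrom, pos, ref, alt, assignment.  Optional columns:
    gene, consequence, allele_mismatch (truthy rows are dropped — the list's
    alleles disagreed with the reference-checked annotation).  Chain:
    whitelist assignment -> not in ``exclusion_keys`` -> no allele mismatch
    -> missense.  Survivors are labeled pathogenic.
    """
    required = {"chrom", "pos", "ref", "alt", "assignment"}
    missing = required - set(rows.columns)
    if missing:
        raise CohortError(
            "import_external_list: missing columns " + ", ".join(sorted(missing))
        )
    whitelist = set(significance_whitelist)
    exclusion = set(exclusion_keys)
    trail: list = []

    recs = [
        VariantRecord(
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=str(row.ref),
            alt=str(row.alt),
            gene=str(getattr(row, "gene", "") or ""),
            consequence=str(getattr(row, "consequence", "") or ""),
            significance=str(row.assignment),
            source=source,
        )
        for row in rows.itertuples(index=False)
    ]
    mismatch_flags = (
        rows["allele_mismatch"].astype(bool).tolist()
        if "allele_mismatch" in rows.columns
        else [False] * len(rows)
    )

    cur = list(zip(recs, mismatch_flags))
    nxt = [(r, m) for r, m in cur if r.significance in whitelist]
    _step(trail, "assignment_whitelist", cur, nxt)
    cur = nxt
    nxt = [(r, m) for r, m in cur if r.key not in exclusion]
    _step(trail, "exclude_known_keys", cur, nxt)
    cur = nxt
    nxt = [(r, m) for r, m in cur if not m]
    _step(trail, "allele_mismatch", cur, nxt)
    cur = nxt
    kept = select_missense([r for r, _ in cur])
    _step(trail, "missense", cur, kept)
    labeled = [
        VariantRecord(**{**r.__dict__, "label": "pathogenic"}) for r in kept
    ]
    return CohortDataset(name=name, records=labeled, audit_trail=trail)


# ---------------------------------------------------------------------------
# Merging, summaries, circularity, recency
# ---------------------------------------------------------------------------

def merge_cohorts(
    cohorts: Sequence[CohortDataset], dedupe: bool = True, name: str = "merged"
) -> CohortDataset:
    """Union of labeled cohorts keyed by variant.

    On key collision the first-listed cohort's record (and metadata) wins and
    the collision is logged; with ``dedupe=False`` a collision with
    conflicting labels is an error instead.
    """
    seen: dict = {}
    conflicts: list = []
    for c in cohorts:
        for r in c.records:
            if r.key in seen:
                if seen[r.key].label != r.label:
                    conflicts.append(r.key)
                logger.info(
                    "merge_cohorts: duplicate key %s kept from earlier cohort",
                    r.key,
                )
                continue
            seen[r.key] = r
    if conflicts and not dedupe:
        raise CohortError(
            "conflicting labels for keys: "
            + ", ".join(str(k) for k in conflicts[:10])
        )
    records = list(seen.values())
    trail = [("merge", sum(len(c) for c in cohorts), len(records))]
    return CohortDataset(name=name, records=records, audit_trail=trail)


def _generalize_category(category: str) -> str:
    c = (category or "").strip()
    if c in ("inframe_deletion", "inframe_insertion"):
        return "Inframe indel"
    low = c.lower()
    if "splice" in low or low == "intron_variant":
        return "Splice site/Intron"
    return c or "unknown"


def summarize_distribution(
    records: Sequence[VariantRecord], min_gene_count: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Gene and variant-category composition tables.

    Genes with fewer than ``min_gene_count`` variants pool into "Other".  The
    category is the molecular-consequence field, falling back to the picked
    consequence when empty; inframe insertions/deletions generalize to
    "Inframe indel" and splice/intron terms to "Splice site/Intron".
    Proportions sum to 1.
    """
    genes = pd.Series([r.gene or "unknown" for r in records])
    gene_counts = genes.value_counts()
    pooled = genes.where(genes.map(gene_counts) >= min_gene_count, "Other")
    gene_table = pooled.value_counts().rename_axis("gene").reset_index(name="count")
    gene_table["proportion"] = gene_table["count"] / gene_table["count"].sum()

    cats = pd.Series(
        [
            _generalize_category(r.molecular_consequence or r.consequence)
            for r in records
        ]
    )
    category_table = cats.value_counts().rename_axis("category").reset_index(
        name="count"
    )
    category_table["proportion"] = (
        category_table["count"] / category_table["count"].sum()
    )

    per_gene: dict = {}
    frame = pd.DataFrame({"gene": pooled, "category": cats})
    for gene, sub in frame.groupby("gene"):
        t = sub["category"].value_counts().rename_axis("category").reset_index(
            name="count"
        )
        t["proportion"] = t["count"] / t["count"].sum()
        per_gene[gene] = t
    return gene_table, category_table, per_gene


def exclude_training_overlap(
    cohort: CohortDataset, training_sets: Mapping[str, Iterable]
) -> CohortDataset:
    """Type-I circularity control: drop variants seen in tool training sets.

    Removes every record whose key appears in the union of the provided
    per-tool key sets; the audit trail records one step per tool set (applied
    sequentially) plus a closing union step.
    """
    trail = list(cohort.audit_trail)
    cur = list(cohort.records)
    n_start = len(cur)
    for tool, keys in training_sets.items():
        keyset = set(keys)
        nxt = [r for r in cur if r.key not in keyset]
        _step(trail, f"training_overlap:{tool}", cur, nxt)
        cur = nxt
    trail.append(("training_overlap:union", len(cur), len(cur)))
    return CohortDataset(
        name=f"{cohort.name}_excluded_training", records=cur, audit_trail=trail
    )


def filter_recent(
    records: Sequence[VariantRecord],
    cutoff: datetime.date,
    name: str = "recent",
) -> CohortDataset:
    """Keep records first reported strictly after ``cutoff``.

    Records lacking a first-reported date cannot prove recency and are
    dropped (with a logged count) before the date comparison.
    """
    trail: list = []
    cur = list(records)
    dated = [r for r in cur if r.first_reported is not None]
    if len(dated) < len(cur):
        logger.info(
            "filter_recent: dropped %d records lacking a first_reported date",
            len(cur) - len(dated),
        )
    _step(trail, "has_first_reported", cur, dated)
    kept = [r for r in dated if r.first_reported > cutoff]
    _step(trail, f"first_reported>{cutoff.isoformat()}", dated, kept)
    return CohortDataset(name=name, records=kept, audit_trail=trail)
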