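"""Predictor registry and annotated-VCF ingestion.

A *tool registry* declares, for each pathogenicity predictor, where its score
lives in an annotated VCF (an INFO key or a VEP-style CSQ sub-field), the
direction of its scale, and its published decision threshold.  Ingestion
normalizes VCF records (decomposing multi-allelic sites) into
:class:`VariantRecord` rows and collects one score per variant per tool into a
:class:`ScoreMatrix` with explicit missingness.

Comparators are strict throughout: a tool calls a variant pathogenic when its
score is strictly greater than (``strict_greater``) or strictly less than
(``strict_less``) the threshold; a score exactly equal to the threshold is
classified benign.
"""

from __future__ import annotations

import datetime
import logging
import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

logger = logging.getLogger("varbench")

HIGHER = "higher_is_pathogenic"
LOWER = "lower_is_pathogenic"
STRICT_GREATER = "strict_greater"
STRICT_LESS = "strict_less"

#: Valid tool scopes.
SCOPES = ("protein", "conservation", "consequence_agnostic", "disease_specific")

#: Keys accepted in a per-tool registry entry.
_TOOL_KEYS = {
    "field",
    "direction",
    "comparator",
    "reference_threshold",
    "scope",
    "range",
    "categorical_map",
    "excluded_from_multithreshold",
}

_MANDATORY_KEYS = ("field", "reference_threshold")


class RegistryError(ValueError):
    """Raised for invalid tool-registry configurations."""


class VcfParseError(ValueError):
    """Raised when an annotated VCF cannot be interpreted against a registry."""


@dataclass(frozen=True)
class ToolSpec:
    """One predictor: annotation locator, scale direction and threshold.

    ``direction`` and ``comparator`` are redundant by construction
    (``higher_is_pathogenic`` <=> ``strict_greater``); both are kept because
    configs may declare either.
    """

    name: str
    field_path: str
    direction: str
    reference_threshold: float
    scope: str = "protein"
    score_range: tuple[float, float] | None = None
    categorical_map: Mapping[str, float] | None = None
    excluded_from_multithreshold: bool = False

    def __post_init__(self) -> None:
        if self.direction not in (HIGHER, LOWER):
            raise RegistryError(f"tool {self.name!r}: bad direction {self.direction!r}")
        if not math.isfinite(self.reference_threshold):
            raise RegistryError(f"tool {self.name!r}: non-finite reference threshold")
        if self.scope not in SCOPES:
            raise RegistryError(f"tool {self.name!r}: bad scope {self.scope!r}")
        if self.categorical_map is not None:
            vals = list(self.categorical_map.values())
            if len(set(vals)) != len(vals):
                raise RegistryError(
                    f"tool {self.name!r}: categorical_map is not injective"
                )
            if not all(0.0 <= v <= 1.0 for v in vals):
                raise RegistryError(
                    f"tool {self.name!r}: categorical_map values must lie in [0, 1]"
                )

    @property
    def comparator(self) -> str:
        return STRICT_GREATER if self.direction == HIGHER else STRICT_LESS

    def is_pathogenic_call(self, score: float, threshold: float | None = None) -> bool:
        """Classify one score under this tool's strict comparator."""
        thr = self.reference_threshold if threshold is None else threshold
        if self.direction == HIGHER:
            return score > thr
        return score < thr

    def flipped(self) -> "ToolSpec":
        """Spec for the sign-negated score scale (direction inverted)."""
        return replace(
            self,
            direction=LOWER if self.direction == HIGHER else HIGHER,
            reference_threshold=-self.reference_threshold,
            score_range=None
            if self.score_range is None
            else (-self.score_range[1], -self.score_range[0]),
            categorical_map=None
            if self.categorical_map is None
            else {k: -v for k, v in self.categorical_map.items()},
        )


@dataclass
class VariantRecord:
    """One normalized (bi-allelic) variant with clinical metadata.

    ``(chrom, pos, ref, alt)`` is the unique key; ``pos`` follows the 1-based
    VCF convention on the configured genome build (metadata only).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    consequence: str = ""
    label: str = "unlabeled"  # pathogenic | benign | vus | unlabeled
    source: str = "user"  # clinvar | share | walsh | gnomad | user
    review_stars: int | None = None
    significance: str | None = None
    ontology_ids: frozenset = field(default_factory=frozenset)
    first_reported: datetime.date | None = None
    allele_frequency: float | None = None
    molecular_consequence: str | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def key_str(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


def variant_key_str(key: tuple[str, int, str, str]) -> str:
    return f"{key[0]}:{key[1]}:{key[2]}:{key[3]}"


@dataclass
class ScoreMatrix:
    """Variants x tools score table with NaN as the explicit missing marker.

    Consumers must mask missing entries; no NaN enters metric arithmetic.
    Rows are keyed by ``chrom:pos:ref:alt`` strings in variant order.
    """

    data: pd.DataFrame

    @property
    def variants(self) -> list[str]:
        return list(self.data.index)

    @property
    def tools(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def column(self, tool: str) -> np.ndarray:
        return self.data[tool].to_numpy(dtype=float)

    def coverage(self, tool: str) -> float:
        n = len(self.data)
        if n == 0:
            return 0.0
        return float(self.data[tool].notna().sum()) / n

    def subset(self, keys: Sequence[str]) -> "ScoreMatrix":
        return ScoreMatrix(self.data.loc[list(keys)])

    def equals(self, other: "ScoreMatrix") -> bool:
        """Cell-for-cell equality including missingness pattern."""
        return self.data.equals(other.data)


# ---------------------------------------------------------------------------
# Registry loading
# ---------------------------------------------------------------------------

def _spec_from_entry(name: str, entry: Mapping) -> ToolSpec:
    if not isinstance(entry, Mapping):
        raise RegistryError(f"tool {name!r}: entry must be a mapping")
    unknown = set(entry) - _TOOL_KEYS
    if unknown:
        raise RegistryError(f"tool {name!r}: unknown keys {sorted(unknown)}")
    for k in _MANDATORY_KEYS:
        if k not in entry:
            raise RegistryError(f"tool {name!r}: missing mandatory key {k!r}")
    direction = entry.get("direction")
    comparator = entry.get("comparator")
    if direction is None and comparator is None:
        raise RegistryError(f"tool {name!r}: missing mandatory key 'direction'")
    if comparator is not None:
        if comparator not in (STRICT_GREATER, STRICT_LESS):
            raise RegistryError(f"tool {name!r}: bad comparator {comparator!r}")
        implied = HIGHER if comparator == STRICT_GREATER else LOWER
        if direction is not None and direction != implied:
            raise RegistryError(
                f"tool {name!r}: direction {direction!r} inconsistent with "
                f"comparator {comparator!r}"
            )
        direction = implied
    rng = entry.get("range")
    if rng is not None:
        rng = (float(rng[0]), float(rng[1]))
        if not rng[0] < rng[1]:
            raise RegistryError(f"tool {name!r}: empty score range")
    cmap = entry.get("categorical_map")
    if cmap is not None:
        cmap = {str(k): float(v) for k, v in cmap.items()}
    return ToolSpec(
        name=name,
        field_path=str(entry["field"]),
        direction=direction,
        reference_threshold=float(entry["reference_threshold"]),
        scope=entry.get("scope", "protein"),
        score_range=rng,
        categorical_map=cmap,
        excluded_from_multithreshold=bool(
            entry.get("excluded_from_multithreshold", False)
        ),
    )


def load_tool_registry(config_source) -> list[ToolSpec]:
    """Load predictor specs from a YAML registry file, path, or mapping.

    The config maps tool names to entries with at least ``field``,
    ``reference_threshold`` and one of ``direction``/``comparator``.
    Unknown keys and duplicate tool names are rejected.  An empty config
    yields an empty list.
    """
    if isinstance(config_source, (str, Path)):
        with open(config_source) as fh:
            cfg = yaml.safe_load(fh)
    elif isinstance(config_source, Mapping):
        cfg = dict(config_source)
    else:  # file-like
        cfg = yaml.safe_load(config_source)
    if cfg is None:
        return []
    tools = cfg.get("tools", cfg) if isinstance(cfg, Mapping) else cfg
    if tools is None or tools == {}:
        return []
    specs: list[ToolSpec] = []
    seen: set[str] = set()
    for name, entry in tools.items():
        if name in ("version", "genome_build"):
            continue
        if name in seen:
            raise RegistryError(f"duplicate tool name {name!r}")
        seen.add(name)
        specs.append(_spec_from_entry(str(name), entry))
    return specs


def default_registry() -> list[ToolSpec]:
    """The built-in registry of 39 predictors with published thresholds."""
    ref = resources.files("varbench").joinpath("data/default_registry.yaml")
    with ref.open() as fh:
        return load_tool_registry(fh)


def registry_version(config_source=None) -> str:
    if config_source is None:
        ref = resources.files("varbench").joinpath("data/default_registry.yaml")
        with ref.open() as fh:
            cfg = yaml.safe_load(fh)
    else:
        with open(config_source) as fh:
            cfg = yaml.safe_load(fh)
    return str(cfg.get("version", "unversioned")) if isinstance(cfg, dict) else "unversioned"


# ---------------------------------------------------------------------------
# Score extraction
# ---------------------------------------------------------------------------

def map_categorical_score(label: str, spec: ToolSpec) -> float:
    """Map a categorical prediction label to its numeric surrogate.

    Labels outside the tool's map (including VUS-style labels) degrade to
    missing (NaN), never to an error.
    """
    if spec.categorical_map is None:
        raise RegistryError(f"tool {spec.name!r} has no categorical_map")
    if label in spec.categorical_map:
        return float(spec.categorical_map[label])
    logger.debug("tool %s: unmapped categorical label %r -> missing", spec.name, label)
    return math.nan


_MULTIVALUE_SPLIT = re.compile(r"[&,]")


def _parse_score_field(raw: str | None, spec: ToolSpec) -> float:
    """One raw annotation value -> float score or NaN.

    Multi-value annotations (``&`` or ``,`` separated per-transcript values)
    collapse to the most deleterious value under the tool's direction.
    Unparseable values become missing with a logged warning.
    """
    if raw is None:
        return math.nan
    raw = raw.strip()
    if raw in ("", ".", "NA", "nan", "NaN"):
        return math.nan
    parts = [p for p in _MULTIVALUE_SPLIT.split(raw) if p not in ("", ".")]
    if not parts:
        return math.nan
    vals: list[float] = []
    for p in parts:
        if spec.categorical_map is not None and p in spec.categorical_map:
            vals.append(float(spec.categorical_map[p]))
            continue
        try:
            v = float(p)
        except ValueError:
            if spec.categorical_map is not None:
                # categorical tool with an unmapped label: missing by design
                continue
            logger.warning(
                "tool %s: malformed score %r treated as missing", spec.name, p
            )
            continue
        if not math.isfinite(v):
            continue
        vals.append(v)
    if not vals:
        return math.nan
    best = max(vals) if spec.direction == HIGHER else min(vals)
    if spec.score_range is not None:
        lo, hi = spec.score_range
        if not (lo <= best <= hi):
            logger.warning(
                "tool %s: score %s outside declared range [%s, %s]; treated as missing",
                spec.name, best, lo, hi,
            )
            return math.nan
    return best


# ---------------------------------------------------------------------------
# VCF parsing
# ---------------------------------------------------------------------------

#: default transcript pick order (most preferred criterion first):
#: has a CCDS id -> canonical flag -> protein-coding biotype -> low rank.
DEFAULT_PICK_ORDER = ("ccds", "canonical", "biotype", "rank")

_REVSTAT_STARS = {
    "no_assertion_provided": 0,
    "no_assertion_criteria_provided": 0,
    "no_interpretation_for_the_single_variant": 0,
    "criteria_provided,_single_submitter": 1,
    "criteria_provided,_conflicting_interpretations": 1,
    "criteria_provided,_multiple_submitters,_no_conflicts": 2,
    "reviewed_by_expert_panel": 3,
    "practice_guideline": 4,
}


def _stars_from_revstat(revstat: str | None) -> int | None:
    if revstat is None:
        return None
    return _REVSTAT_STARS.get(revstat.strip())


def _pick_sort_key(entry: Mapping[str, str], order: Sequence[str]):
    key = []
    for crit in order:
        if crit == "ccds":
            key.append(0 if entry.get("CCDS") else 1)
        elif crit == "canonical":
            key.append(0 if entry.get("CANONICAL") == "YES" else 1)
        elif crit == "biotype":
            key.append(0 if entry.get("BIOTYPE", "") in ("protein_coding", "") else 1)
        elif crit == "rank":
            try:
                key.append(int(str(entry.get("RANK", "")).split("/")[0]))
            except ValueError:
                key.append(10**9)
        else:
            raise VcfParseError(f"unknown pick criterion {crit!r}")
    return tuple(key)


def _parse_date(text: str | None) -> datetime.date | None:
    if not text:
        return None
    try:
        return datetime.date.fromisoformat(str(text))
    except ValueError:
        logger.warning("unparseable date %r ignored", text)
        return None


def parse_annotated_vcf(
    vcf_source,
    registry: Sequence[ToolSpec],
    pick_order: Sequence[str] = DEFAULT_PICK_ORDER,
) -> tuple[list[VariantRecord], ScoreMatrix]:
    """Ingest a VEP/vcfanno-annotated VCF into records plus a score matrix.

    Multi-allelic records are decomposed into one row per alternate allele.
    Per variant, exactly one CSQ transcript block is chosen by ``pick_order``
    and per-tool scores are read either from that block (CSQ sub-fields) or
    from INFO keys.  Absent or unparseable scores become missing.

    Raises :class:`VcfParseError` if a registry tool references a CSQ
    sub-field that the header does not declare.
    """
    vcf = VCF(str(vcf_source))
    csq_fields: list[str] = []
    info_keys: set[str] = set()
    for h in vcf.header_iter():
        try:
            info = h.info()
        except Exception:  # pragma: no cover - defensive
            continue
        if h["HeaderType"] == "INFO":
            info_keys.add(info["ID"])
            if info["ID"] == "CSQ":
                desc = info.get("Description", "")
                m = re.search(r"Format:\s*([^\"]+)", desc)
                if m:
                    csq_fields = m.group(1).strip().strip("'\"").split("|")

    tool_in_csq: dict[str, bool] = {}
    missing_fields = []
    for spec in registry:
        if spec.field_path in csq_fields:
            tool_in_csq[spec.name] = True
        elif spec.field_path in info_keys:
            tool_in_csq[spec.name] = False
        else:
            missing_fields.append(spec.field_path)
    if missing_fields:
        raise VcfParseError(
            "annotation field(s) not declared in VCF header: "
            + ", ".join(sorted(missing_fields))
        )

    records: list[VariantRecord] = []
    rows: list[list[float]] = []
    for v in vcf:
        raw_csq = v.INFO.get("CSQ") if csq_fields else None
        csq_entries = []
        if raw_csq:
            for block in str(raw_csq).split(","):
                parts = block.split("|")
                entry = {f: (parts[i] if i < len(parts) else "") for i, f in enumerate(csq_fields)}
                csq_entries.append(entry)
        revstat = v.INFO.get("CLNREVSTAT")
        stars = v.INFO.get("STARS")
        stars = int(stars) if stars is not None else _stars_from_revstat(revstat)
        sig = v.INFO.get("CLNSIG")
        disdb = v.INFO.get("CLNDISDB")
        ontology = frozenset(
            x for x in re.split(r"[|,]", str(disdb)) if x
        ) if disdb else frozenset()
        label = v.INFO.get("LABEL") or "unlabeled"
        source = v.INFO.get("SOURCE") or "user"
        mc_field = v.INFO.get("MC")
        mc = str(mc_field).split("|")[-1].split(",")[0] if mc_field else None
        first = _parse_date(v.INFO.get("FIRST_REPORTED"))
        af = v.INFO.get("AF")
        geneinfo = v.INFO.get("GENEINFO")

        alts = list(v.ALT)
        for ai, alt in enumerate(alts):
            picked: Mapping[str, str] = {}
            candidates = csq_entries
            if csq_entries and "Allele" in csq_fields:
                matching = [e for e in csq_entries if e.get("Allele") == alt]
                if matching:
                    candidates = matching
            if candidates:
                picked = min(candidates, key=lambda e: _pick_sort_key(e, pick_order))
            gene = picked.get("SYMBOL", "") or (
                str(geneinfo).split(":")[0] if geneinfo else ""
            )
            if isinstance(af, (tuple, list)):
                af_val = float(af[ai]) if af[ai] is not None else None
            else:
                af_val = float(af) if af is not None else None
            rec = VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=alt,
                gene=gene,
                consequence=picked.get("Consequence", ""),
                label=str(label),
                source=str(source),
                review_stars=stars,
                significance=str(sig) if sig is not None else None,
                ontology_ids=ontology,
                first_reported=first,
                allele_frequency=af_val,
                molecular_consequence=mc,
            )
            records.append(rec)
            row = []
            for spec in registry:
                if tool_in_csq[spec.name]:
                    raw = picked.get(spec.field_path) if picked else None
                else:
                    raw = v.INFO.get(spec.field_path)
                    if raw is not None:
                        raw = str(raw)
                row.append(_parse_score_field(raw, spec))
            rows.append(row)
    vcf.close()

    index = [r.key_str for r in records]
    data = pd.DataFrame(
        np.array(rows, dtype=float).reshape(len(records), len(registry)),
        index=index,
        columns=[s.name for s in registry],
    )
    return records, ScoreMatrix(data)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def records_to_frame(
    records: Sequence[VariantRecord], matrix: ScoreMatrix | None = None
) -> pd.DataFrame:
    """Normalized variant table (optionally joined with per-tool scores)."""
    base = pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "ref": [r.ref for r in records],
            "alt": [r.alt for r in records],
            "gene": [r.gene for r in records],
            "consequence": [r.consequence for r in records],
            "label": [r.label for r in records],
            "source": [r.source for r in records],
        },
        index=[r.key_str for r in records],
    )
    if matrix is not None:
        base = base.join(matrix.data)
    return base


def _fmt_float(x: float) -> str:
    return repr(float(x))


def write_scored_vcf(
    path,
    records: Sequence[VariantRecord],
    matrix: ScoreMatrix,
    registry: Sequence[ToolSpec],
    genome_build: str = "GRCh37",
) -> None:
    """Write normalized records plus scores back to a plain-text VCF.

    Scores are placed in a CSQ block whose sub-fields are the registry field
    names; floats are serialized with ``repr`` so a re-parse reproduces the
    score matrix cell-for-cell (the round-trip invariant).
    """
    csq_fields = ["Allele", "Consequence", "SYMBOL"] + [s.field_path for s in registry]
    contigs = list(dict.fromkeys(r.chrom for r in records))
    lines = [
        "##fileformat=VCFv4.2",
        f"##reference={genome_build}",
        *[f"##contig=<ID={c}>" for c in contigs],
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. Format: '
        + "|".join(csq_fields) + '">',
        '##INFO=<ID=LABEL,Number=1,Type=String,Description="Benchmark label">',
        '##INFO=<ID=SOURCE,Number=1,Type=String,Description="Cohort source">',
        '##INFO=<ID=STARS,Number=1,Type=Integer,Description="Review stars">',
        '##INFO=<ID=CLNSIG,Number=1,Type=String,Description="Clinical significance">',
        '##INFO=<ID=CLNDISDB,Number=1,Type=String,Description="Disease ontology ids">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">',
        '##INFO=<ID=MC,Number=1,Type=String,Description="Molecular consequence">',
        '##INFO=<ID=FIRST_REPORTED,Number=1,Type=String,Description="First report date">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for rec in records:
        scores = matrix.data.loc[rec.key_str]
        csq_vals = [rec.alt, rec.consequence or "missense_variant", rec.gene]
        for spec in registry:
            val = scores[spec.name]
            if pd.isna(val):
                csq_vals.append("")
            elif spec.categorical_map is not None:
                inv = {v: k for k, v in spec.categorical_map.items()}
                csq_vals.append(inv.get(float(val), _fmt_float(val)))
            else:
                csq_vals.append(_fmt_float(val))
        info = [f"CSQ={'|'.join(csq_vals)}", f"LABEL={rec.label}", f"SOURCE={rec.source}"]
        if rec.review_stars is not None:
            info.append(f"STARS={rec.review_stars}")
        if rec.significance:
            info.append(f"CLNSIG={rec.significance}")
        if rec.ontology_ids:
            info.append("CLNDISDB=" + "|".join(sorted(rec.ontology_ids)))
        if rec.allele_frequency is not None:
            info.append(f"AF={_fmt_float(rec.allele_frequency)}")
        if rec.molecular_consequence:
            info.append(f"MC={rec.molecular_consequence}")
        if rec.first_reported is not None:
            info.append(f"FIRST_REPORTED={rec.first_reported.isoformat()}")
        lines.append(
            f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\t.\t{';'.join(info)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
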