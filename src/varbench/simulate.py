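"""Ground-truthed synthetic cohorts for end-to-end testing and calibration
recovery.

A simulated tool is a pair of class-conditional score distributions
(pathogenic vs benign) plus per-class missingness and a scale direction; a
simulated cohort is a set of variants on a fictional contig with labels,
genes drawn from a weighted pool (emulating the over-representation of
pathogenic variants in a single disease gene, against more uniformly spread
benign variants), and one score per tool per variant.  Cohorts are emitted
as plain-text annotated VCFs plus a truth TSV, byte-reproducible under a
seed.

``analytic_optimum`` returns the score where the prevalence-weighted class
densities cross — the population-optimal decision point that grid
calibration at beta = 1 should recover on large samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .registry import (
    HIGHER,
    LOWER,
    ScoreMatrix,
    ToolSpec,
    VariantRecord,
    write_scored_vcf,
)
import pandas as pd


@dataclass(frozen=True)
class ScoreDistribution:
    """Parametric score distribution: normal, beta, or a two-component
    mixture of those."""

    family: str  # normal | beta | mixture
    params: tuple = ()
    components: tuple = ()  # ((weight, ScoreDistribution), ...) for mixture

    def _frozen(self):
        if self.family == "normal":
            loc, scale = self.params
            return stats.norm(loc=loc, scale=scale)
        if self.family == "beta":
            a, b = self.params
            return stats.beta(a, b)
        raise ValueError(f"unknown family {self.family!r}")

    def pdf(self, x):
        if self.family == "mixture":
            x = np.asarray(x, dtype=float)
            return sum(w * d.pdf(x) for w, d in self.components)
        return self._frozen().pdf(x)

    def rvs(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "mixture":
            weights = np.array([w for w, _ in self.components], dtype=float)
            weights = weights / weights.sum()
            choice = rng.choice(len(self.components), size=size, p=weights)
            out = np.empty(size)
            for i, (_, d) in enumerate(self.components):
                m = choice == i
                out[m] = d.rvs(rng, int(m.sum()))
            return out
        if self.family == "normal":
            loc, scale = self.params
            return rng.normal(loc, scale, size)
        if self.family == "beta":
            a, b = self.params
            return rng.beta(a, b, size)
        raise ValueError(f"unknown family {self.family!r}")

    def support(self) -> tuple[float, float]:
        if self.family == "mixture":
            los, his = zip(*(d.support() for _, d in self.components))
            return min(los), max(his)
        if self.family == "beta":
            return 0.0, 1.0
        loc, scale = self.params
        return loc - 8 * scale, loc + 8 * scale

    def mean(self) -> float:
        if self.family == "mixture":
            weights = np.array([w for w, _ in self.components], dtype=float)
            weights = weights / weights.sum()
            return float(sum(w * d.mean() for w, (_, d) in zip(weights, self.components)))
        return float(self._frozen().mean())


@dataclass(frozen=True)
class SimToolProfile:
    """One simulated predictor: class-conditional scores plus missingness."""

    name: str
    direction: str = HIGHER
    pathogenic_distribution: ScoreDistribution = ScoreDistribution("beta", (8, 2))
    benign_distribution: ScoreDistribution = ScoreDistribution("beta", (2, 8))
    missingness_pathogenic: float = 0.0
    missingness_benign: float = 0.0
    analytic_crossing: float | None = None
    reference_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.missingness_pathogenic >= 1 and self.missingness_benign >= 1:
            raise ValueError("at least one class must have missingness < 1")
        for m in (self.missingness_pathogenic, self.missingness_benign):
            if not 0.0 <= m <= 1.0:
                raise ValueError("missingness must lie in [0, 1]")

    def to_spec(self) -> ToolSpec:
        return ToolSpec(
            name=self.name,
            field_path=self.name,
            direction=self.direction,
            reference_threshold=self.reference_threshold,
        )


#: Default gene pool: one heavily weighted disease gene over a flatter tail,
#: mimicking the skew of pathogenic variants toward a single sarcomeric gene.
DEFAULT_GENE_POOL = (
    ("MYH7", 0.45),
    ("MYBPC3", 0.15),
    ("TNNT2", 0.08),
    ("TNNI3", 0.08),
    ("TPM1", 0.06),
    ("MYL2", 0.06),
    ("MYL3", 0.06),
    ("ACTC1", 0.06),
)


@dataclass(frozen=True)
class SimCohortSpec:
    """Composition of a simulated cohort."""

    n_pathogenic: int = 100
    n_benign: int = 100
    n_vus: int = 0
    gene_pool: tuple = DEFAULT_GENE_POOL
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pathogenic, self.n_benign, self.n_vus) < 0:
            raise ValueError("cohort counts must be non-negative")
        if self.n_pathogenic + self.n_benign + self.n_vus == 0:
            raise ValueError("cohort must contain at least one variant")


_BASES = ("A", "C", "G", "T")


def generate_cohort(
    spec: SimCohortSpec, profiles: Sequence[SimToolProfile]
) -> tuple[list[VariantRecord], ScoreMatrix]:
    """Draw a labeled cohort and its score matrix in memory.

    Variants live on the fictional contig ``chrS`` with sequential positions
    and random ref != alt bases.  Scores are class-conditional draws per
    profile; VUS scores are drawn from an equal mixture of the two class
    distributions (their truth is unknown by construction).  Fully
    reproducible under ``spec.seed``.
    """
    if not profiles:
        raise ValueError("at least one tool profile is required")
    rng = np.random.default_rng(spec.seed)
    labels = (
        ["pathogenic"] * spec.n_pathogenic
        + ["benign"] * spec.n_benign
        + ["vus"] * spec.n_vus
    )
    n = len(labels)
    genes, weights = zip(*spec.gene_pool)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    gene_draw = rng.choice(len(genes), size=n, p=weights)
    records = []
    for i, label in enumerate(labels):
        ref_i = int(rng.integers(0, 4))
        alt_i = (ref_i + int(rng.integers(1, 4))) % 4
        records.append(
            VariantRecord(
                chrom="chrS",
                pos=1000 + i,
                ref=_BASES[ref_i],
                alt=_BASES[alt_i],
                gene=genes[gene_draw[i]],
                consequence="missense_variant",
                label=label,
                source="user",
            )
        )
    cols = {}
    is_path = np.array([l == "pathogenic" for l in labels])
    is_benign = np.array([l == "benign" for l in labels])
    is_vus = np.array([l == "vus" for l in labels])
    for prof in profiles:
        col = np.empty(n)
        col[is_path] = prof.pathogenic_distribution.rvs(rng, int(is_path.sum()))
        col[is_benign] = prof.benign_distribution.rvs(rng, int(is_benign.sum()))
        if is_vus.any():
            half = rng.random(int(is_vus.sum())) < 0.5
            vus_scores = np.empty(int(is_vus.sum()))
            vus_scores[half] = prof.pathogenic_distribution.rvs(rng, int(half.sum()))
            vus_scores[~half] = prof.benign_distribution.rvs(rng, int((~half).sum()))
            col[is_vus] = vus_scores
        drop = np.zeros(n, dtype=bool)
        drop[is_path] = rng.random(int(is_path.sum())) < prof.missingness_pathogenic
        drop[is_benign | is_vus] = (
            rng.random(int((is_benign | is_vus).sum())) < prof.missingness_benign
        )
        col[drop] = np.nan
        cols[prof.name] = col
    data = pd.DataFrame(cols, index=[r.key_str for r in records])
    return records, ScoreMatrix(data)


def simulate_cohort(
    spec: SimCohortSpec,
    profiles: Sequence[SimToolProfile],
    out_vcf,
    out_truth,
) -> tuple[Path, Path]:
    """Generate a cohort and write the annotated VCF plus a truth TSV."""
    records, matrix = generate_cohort(spec, profiles)
    registry = [p.to_spec() for p in profiles]
    write_scored_vcf(out_vcf, records, matrix, registry)
    truth = pd.DataFrame(
        {
            "variant": [r.key_str for r in records],
            "gene": [r.gene for r in records],
            "label": [r.label for r in records],
        }
    )
    truth.to_csv(out_truth, sep="\t", index=False)
    return Path(out_vcf), Path(out_truth)


def write_provenance(path, spec: SimCohortSpec, profiles: Sequence[SimToolProfile]) -> None:
    """Record the seed and profile parameters alongside generated fixtures."""
    doc = {
        "seed": spec.seed,
        "n_pathogenic": spec.n_pathogenic,
        "n_benign": spec.n_benign,
        "n_vus": spec.n_vus,
        "gene_pool": list(spec.gene_pool),
        "profiles": [
            {
                "name": p.name,
                "direction": p.direction,
                "pathogenic": [p.pathogenic_distribution.family,
                               list(p.pathogenic_distribution.params)],
                "benign": [p.benign_distribution.family,
                           list(p.benign_distribution.params)],
                "missingness": [p.missingness_pathogenic, p.missingness_benign],
            }
            for p in profiles
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def analytic_optimum(profile: SimToolProfile, prevalence: float = 0.5) -> float:
    """Score where prevalence-weighted class densities cross.

    Solves ``prevalence * f_path(t) = (1 - prevalence) * f_benign(t)`` by
    root finding on a dense bracket between the class means.  Raises if the
    densities never cross in the common support (e.g. identical
    distributions).
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly between 0 and 1")
    fp = profile.pathogenic_distribution
    fb = profile.benign_distribution
    if fp == fb:
        raise ValueError("identical class distributions have no unique crossing")

    def g(x):
        return prevalence * fp.pdf(x) - (1.0 - prevalence) * fb.pdf(x)

    lo = max(fp.support()[0], fb.support()[0])
    hi = min(fp.support()[1], fb.support()[1])
    if not lo < hi:
        raise ValueError("class distributions have no common support")
    xs = np.linspace(lo, hi, 4001)
    vals = g(xs)
    signs = np.sign(vals)
    crossings = []
    for i in range(len(xs) - 1):
        if signs[i] != 0 and signs[i + 1] != 0 and signs[i] != signs[i + 1]:
            root = optimize.brentq(g, xs[i], xs[i + 1])
            crossings.append(root)
        elif signs[i] == 0 and (i == 0 or signs[i - 1] != 0):
            crossings.append(float(xs[i]))
    if not crossings:
        raise ValueError("class densities do not cross in the common support")
    mid = 0.5 * (fp.mean() + fb.mean())
    return float(min(crossings, key=lambda c: abs(c - mid)))
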