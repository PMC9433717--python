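import datetime

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from varbench import (
    ScoreDistribution,
    SimCohortSpec,
    SimToolProfile,
    ToolSpec,
    VariantRecord,
    generate_cohort,
)

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. Format: Allele|Consequence|SYMBOL|HiTool|LoTool">
##INFO=<ID=LABEL,Number=1,Type=String,Description="Benchmark label">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


@pytest.fixture
def two_tool_registry():
    return [
        ToolSpec("HiTool", "HiTool", "higher_is_pathogenic", 0.5),
        ToolSpec("LoTool", "LoTool", "lower_is_pathogenic", 0.0),
    ]


@pytest.fixture
def hand_vcf(tmp_path):
    """3 variants, 2 tools, exactly one blank score (HiTool at pos 200)."""
    body = (
        "chr1\t100\t.\tA\tC\t.\t.\tCSQ=C|missense_variant|GENE1|0.9|-3.0;LABEL=pathogenic\n"
        "chr1\t200\t.\tG\tT\t.\t.\tCSQ=T|missense_variant|GENE2||-1.0;LABEL=benign\n"
        "chr1\t300\t.\tC\tA\t.\t.\tCSQ=A|synonymous_variant|GENE3|0.2|2.5;LABEL=benign\n"
    )
    path = tmp_path / "hand.vcf"
    path.write_text(VCF_HEADER + body)
    return path


@pytest.fixture
def multiallelic_vcf(tmp_path):
    body = (
        "chr1\t400\t.\tA\tC,T\t.\t.\t"
        "CSQ=C|missense_variant|G1|0.8|1.0,T|missense_variant|G1|0.1|2.0;LABEL=vus\n"
    )
    path = tmp_path / "multi.vcf"
    path.write_text(VCF_HEADER + body)
    return path


@pytest.fixture
def empty_vcf(tmp_path):
    path = tmp_path / "empty.vcf"
    path.write_text(VCF_HEADER)
    return path


def make_record(i, **kw):
    defaults = dict(
        chrom="chr1",
        pos=1000 + i,
        ref="A",
        alt="C" if i % 2 else "G",
        gene=f"GENE{i}",
        consequence="missense_variant",
    )
    defaults.update(kw)
    return VariantRecord(**defaults)


@pytest.fixture
def clinvar_six_records():
    """2 ontology+stars P/LP, 1 B/LB, 1 zero-star, 1 conflicting, 1 wrong
    phenotype -> expected kept = 3 (2 pathogenic, 1 benign)."""
    hcm = frozenset({"MedGen:C3495498"})
    other = frozenset({"MedGen:C0000001"})
    return [
        make_record(0, significance="Pathogenic", review_stars=2, ontology_ids=hcm),
        make_record(1, significance="Likely_pathogenic", review_stars=1, ontology_ids=hcm),
        make_record(2, significance="Benign", review_stars=2, ontology_ids=hcm),
        make_record(3, significance="Pathogenic", review_stars=0, ontology_ids=hcm),
        make_record(
            4,
            significance="Conflicting_interpretations_of_pathogenicity",
            review_stars=1,
            ontology_ids=hcm,
        ),
        make_record(5, significance="Pathogenic", review_stars=2, ontology_ids=other),
    ]


@pytest.fixture
def separable_profile():
    return SimToolProfile(
        name="sharp_tool",
        pathogenic_distribution=ScoreDistribution("beta", (20, 2)),
        benign_distribution=ScoreDistribution("beta", (2, 20)),
    )


@pytest.fixture
def normal_profile():
    """Equal-variance normals: density crossing at the midpoint 1.0."""
    return SimToolProfile(
        name="normal_tool",
        pathogenic_distribution=ScoreDistribution("normal", (2.0, 1.0)),
        benign_distribution=ScoreDistribution("normal", (0.0, 1.0)),
        reference_threshold=1.0,
    )


@pytest.fixture
def small_cohort(separable_profile):
    spec = SimCohortSpec(n_pathogenic=30, n_benign=30, n_vus=10, seed=7)
    return generate_cohort(spec, [separable_profile])
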