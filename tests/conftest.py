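"""Shared fixtures: a hand-derived filtering micro-cohort and a toy catalogue."""

from __future__ import annotations

import pytest

from ctlong.core_io import AnnotationRecord, IntervalSet, VariantRecord
from ctlong.simdata import toy_signature_matrix


def make_variant(chrom, pos, ref, alt, sample_id, alt_fwd, alt_rev,
                 ref_fwd=50, ref_rev=50, bq=35.0, **ann) -> VariantRecord:
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, sample_id=sample_id,
        ref_fwd=ref_fwd, ref_rev=ref_rev, alt_fwd=alt_fwd, alt_rev=alt_rev,
        mean_alt_bq=bq, annotations=AnnotationRecord(**ann))


@pytest.fixture(scope="session")
def toy_matrix():
    return toy_signature_matrix(10)


@pytest.fixture()
def filter_fixture():
    """Twelve-locus micro-cohort: 4 true somatics + one exemplar per artifact class.

    Thirteen plasma rows over twelve loci (the multi-allelic locus carries two
    alternate alleles). The expected survivor set and each artifact's designed
    drop stage are hand-derived from the cascade rules.
    """
    V = make_variant
    cos = dict(exonic_function="nonsynonymous")

    true_somatics = [
        V("chr1", 10000, "C", "T", "TOY_P1", 10, 10, cosmic_id="COSV1", **cos),
        # rescue-eligible: one plasma read, >=3 alt reads in matched tumour
        V("chr2", 20000, "A", "G", "TOY_P1", 1, 0, ref_fwd=20, ref_rev=20,
          cosmic_id="COSV2", **cos),
        V("chr3", 30000, "G", "C", "TOY_P2", 8, 9, cosmic_id="COSV3", **cos),
        V("chr4", 40000, "T", "A", "TOY_P3", 5, 6, cosmic_id="COSV4",
          af_gnomad=0.001, **cos),  # survives but must carry the pop_af flag
    ]
    artifacts = {
        "dbsnp_only": [V("chr5", 50000, "C", "A", "TOY_P1", 6, 7,
                         dbsnp_id="rs123", **cos)],
        "exonic": [V("chr6", 60000, "C", "T", "TOY_P1", 6, 7,
                     exonic_function="synonymous")],
        "base_quality": [V("chr7", 70000, "A", "T", "TOY_P1", 6, 7, bq=24.9, **cos)],
        "germline": [V("chr8", 80000, "G", "A", "TOY_P1", 6, 7, **cos)],
        "cp_control": [V("chr10", 100000, "C", "G", "TOY_P1", 6, 7, **cos)],
        "blacklist": [V("chr9", 1500, "T", "C", "TOY_P1", 6, 7, **cos)],
        "strand_bias": [V("chr11", 110000, "C", "T", "TOY_P1", 30, 0,
                          ref_fwd=100, ref_rev=100, **cos)],
        "multiallelic": [
            V("chr12", 120000, "A", "T", "TOY_P1", 10, 10, **cos),
            V("chr12", 120000, "A", "G", "TOY_P2", 9, 9, **cos),
        ],
    }
    plasma = true_somatics + [r for rows in artifacts.values() for r in rows]

    tumour = [
        # rescues chr2:20000 at the call stage
        V("chr2", 20000, "A", "G", "TOY_T", 3, 2, cosmic_id="COSV2", **cos),
        # rescues the strand-biased artifact so it reaches the Fisher stage
        V("chr11", 110000, "C", "T", "TOY_T", 15, 15, **cos),
    ]

    germline = []
    for rec in plasma:
        alt = 1 if rec.pos == 80000 else 0  # the germline-leak exemplar
        germline.append(V(rec.chrom, rec.pos, rec.ref, rec.alt, "TOY_GL",
                          alt, 0, ref_fwd=15, ref_rev=15 - alt))

    cp = [V("chr10", 100000, "C", "G", "CPX_P1", 2, 0, ref_fwd=250, ref_rev=250)]

    blacklist = IntervalSet([("chr9", 1000, 2000)])

    expected_survivors = {r.key for r in true_somatics}
    designed_stage = {}
    for stage, rows in artifacts.items():
        for r in rows:
            designed_stage[(r.chrom, r.pos, r.ref, r.alt, r.sample_id)] = stage

    return dict(plasma=plasma, tumour=tumour, germline=germline, cp=cp,
                blacklist=blacklist, expected_survivors=expected_survivors,
                designed_stage=designed_stage)
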