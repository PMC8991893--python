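"""Patient-specific plasma variant calling and the artifact-filtering cascade.

Stages, in fixed order:

1. call        — >=3 alt-supporting plasma reads with one on each strand, or
                 >=1 plasma read rescued by a matched tumour with >=3 alt reads
2. dbsnp_only  — drop variants absent from COSMIC but carrying a dbSNP id
3. exonic      — drop synonymous / unknown exonic function
4. base_quality— drop mean alt base quality < 25
5. germline    — keep only loci covered >=20x in the matched germline with
                 zero alt reads there
6. cp_control  — drop loci with any alt read in chronic-pancreatitis plasma
7. multiallelic— drop every alt at loci with more than one alternate allele
                 across the patient's serial plasma
8. blacklist   — drop positions inside problematic-region intervals
9. strand_bias — FPfilter-style: two-sided Fisher exact on strand counts,
                 drop when p < 0.01 and the minor alt strand carries < 10%
10. pop_af     — flag (not drop) variants with any population allele frequency

Stages 2-9 are pure per-variant predicates evaluated against fixed context
(annotations, the germline and control tables, the called universe, the
blacklist), so their order does not change the surviving set. In particular,
the multi-allelic rule is evaluated against the patient's *called* plasma
universe rather than the current survivor set; otherwise removing one allele
of a multi-allelic pair at an earlier stage would rescue the other allele and
the cascade would become order-dependent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from scipy.stats import fisher_exact

from .config import FilterConfig
from .core_io import IntervalSet, VariantRecord

log = logging.getLogger("ctlong")

STAGE_ORDER = ("call", "dbsnp_only", "exonic", "base_quality", "germline",
               "cp_control", "multiallelic", "blacklist", "strand_bias", "pop_af")


@dataclass(slots=True)
class StageResult:
    name: str
    n_in: int
    n_out: int
    dropped: dict = field(default_factory=dict)  # variant key -> reason


@dataclass(slots=True)
class FilterReport:
    """Auditable per-stage record of the cascade."""

    patient_id: str
    stages: list = field(default_factory=list)
    survivors: list = field(default_factory=list)

    def stage(self, name: str) -> StageResult:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)

    def dropped_at(self, key) -> str | None:
        """Stage name at which a sample-level variant key was dropped."""
        for s in self.stages:
            if key in s.dropped:
                return s.name
        return None

    def summary(self) -> list:
        return [dict(stage=s.name, n_in=s.n_in, n_out=s.n_out,
                     n_dropped=len(s.dropped)) for s in self.stages]


def record_key(rec: VariantRecord) -> tuple:
    """Per-sample variant identity used in reports."""
    return (rec.chrom, rec.pos, rec.ref, rec.alt, rec.sample_id)


def _sorted(records):
    return sorted(records, key=lambda r: (r.chrom, r.pos, r.alt, r.sample_id))


# ---------------------------------------------------------------------------
# stage predicates

def call_plasma_candidates(plasma_records, tumour_records=None,
                           config: FilterConfig | None = None):
    """Apply the plasma calling rule, with matched-tumour rescue.

    A plasma variant is called when it has >=3 alt-supporting reads with at
    least one on each strand, or >=1 alt read when the same variant carries
    >=3 alt reads in the matched tumour. Absent tumour disables the rescue.
    """
    cfg = config or FilterConfig()
    tumour_support: dict[tuple, int] = {}
    for rec in tumour_records or []:
        k = rec.key
        tumour_support[k] = max(tumour_support.get(k, 0), rec.alt_count)
    called, dropped = [], {}
    for rec in _sorted(plasma_records):
        n = rec.alt_count
        direct = n >= cfg.min_alt_reads and (
            not cfg.require_both_strands or (rec.alt_fwd >= 1 and rec.alt_rev >= 1))
        rescued = (n >= cfg.rescue_min_plasma_reads and
                   tumour_support.get(rec.key, 0) >= cfg.rescue_min_tumour_reads)
        if direct or rescued:
            called.append(rec)
        else:
            dropped[record_key(rec)] = "call: insufficient read support"
    return called, dropped


def filter_dbsnp_only(candidates, config=None):
    """Drop variants absent from COSMIC but with a dbSNP identifier."""
    kept, dropped = [], {}
    for rec in candidates:
        a = rec.annotations
        if a.cosmic_id is None and a.dbsnp_id is not None:
            dropped[record_key(rec)] = f"dbsnp_only: {a.dbsnp_id} without COSMIC id"
        else:
            kept.append(rec)
    return kept, dropped


def filter_exonic_function(candidates, config: FilterConfig | None = None):
    """Drop synonymous/unknown classifications; missing counts as unknown."""
    cfg = config or FilterConfig()
    kept, dropped = [], {}
    for rec in candidates:
        fn = rec.annotations.exonic_function
        if fn is None:
            dropped[record_key(rec)] = "exonic: missing annotation (treated as unknown)"
        elif fn in cfg.drop_exonic_functions:
            dropped[record_key(rec)] = f"exonic: {fn}"
        else:
            kept.append(rec)
    return kept, dropped


def filter_base_quality(candidates, config: FilterConfig | None = None):
    cfg = config or FilterConfig()
    kept, dropped = [], {}
    for rec in candidates:
        if rec.mean_alt_bq < cfg.min_mean_alt_bq:
            dropped[record_key(rec)] = f"base_quality: {rec.mean_alt_bq} < {cfg.min_mean_alt_bq}"
        else:
            kept.append(rec)
    return kept, dropped


def filter_germline(candidates, germline_records, config: FilterConfig | None = None):
    """Keep loci covered >=20x in the matched germline with no alt reads.

    Loci absent from the germline table count as depth 0; under-covered loci
    are dropped as unverifiable (config ``germline_undercovered`` can keep
    them instead).
    """
    cfg = config or FilterConfig()
    germ: dict[tuple, tuple[int, int]] = {}
    for rec in germline_records or []:
        depth, alt = germ.get(rec.locus, (0, 0))
        germ[rec.locus] = (max(depth, rec.depth), max(alt, rec.alt_count))
    kept, dropped = [], {}
    for rec in candidates:
        depth, alt = germ.get(rec.locus, (0, 0))
        if alt > 0:
            dropped[record_key(rec)] = f"germline: {alt} alt read(s) in germline"
        elif depth < cfg.germline_min_depth:
            if cfg.germline_undercovered == "keep":
                kept.append(rec)
            else:
                dropped[record_key(rec)] = \
                    f"germline_undercovered: depth {depth} < {cfg.germline_min_depth}"
        else:
            kept.append(rec)
    return kept, dropped


def filter_cp_controls(candidates, cp_records, config=None):
    """Drop loci with any alt read in chronic-pancreatitis control plasma."""
    if not cp_records:
        log.warning("cp_control filter: no CP samples supplied; all variants kept")
    cp_hit = {rec.key for rec in cp_records or [] if rec.alt_count >= 1}
    kept, dropped = [], {}
    for rec in candidates:
        if rec.key in cp_hit:
            dropped[record_key(rec)] = "cp_control: alt reads in CP plasma"
        else:
            kept.append(rec)
    return kept, dropped


def filter_multiallelic(candidates, universe=None, config=None):
    """Drop every alt at loci showing more than one alternate allele.

    ``universe`` is the patient's called plasma variant set against which
    multi-allelism is judged (defaults to ``candidates``); judging against a
    fixed universe keeps the cascade order-independent.
    """
    alts_at: dict[tuple, set] = {}
    for rec in (universe if universe is not None else candidates):
        alts_at.setdefault(rec.locus, set()).add(rec.alt)
    kept, dropped = [], {}
    for rec in candidates:
        alts = alts_at.get(rec.locus, {rec.alt})
        if len(alts) > 1:
            dropped[record_key(rec)] = \
                f"multiallelic: {len(alts)} alt alleles across serial plasma"
        else:
            kept.append(rec)
    return kept, dropped


def filter_blacklist(candidates, blacklist: IntervalSet, config=None):
    kept, dropped = [], {}
    for rec in candidates:
        if blacklist.contains(rec.chrom, rec.pos):
            dropped[record_key(rec)] = "blacklist: position in problematic region"
        else:
            kept.append(rec)
    return kept, dropped


def strand_bias_test(rec: VariantRecord) -> float:
    """Two-sided Fisher exact p on the per-strand ref/alt contingency table."""
    table = [[rec.ref_fwd, rec.ref_rev], [rec.alt_fwd, rec.alt_rev]]
    return float(fisher_exact(table, alternative="two-sided")[1])


def filter_strand_bias(candidates, config: FilterConfig | None = None):
    """FPfilter-style strand-bias exclusion.

    Drop when the Fisher exact p is below 0.01 *and* the minor alt strand
    carries under 10% of alt reads; the joint rule spares genuinely
    low-depth variants.
    """
    cfg = config or FilterConfig()
    kept, dropped = [], {}
    for rec in candidates:
        n = rec.alt_count
        minor_frac = min(rec.alt_fwd, rec.alt_rev) / max(1, n)
        if minor_frac < cfg.strand_bias_min_fraction:
            p = strand_bias_test(rec)
            if p < cfg.strand_bias_p:
                dropped[record_key(rec)] = \
                    f"strand_bias: Fisher p={p:.2e}, minor strand {minor_frac:.2f}"
                continue
        kept.append(rec)
    return kept, dropped


def flag_population_af(candidates, config: FilterConfig | None = None):
    """Flag (and optionally drop) variants with any population AF > 0."""
    cfg = config or FilterConfig()
    kept, dropped = [], {}
    for rec in candidates:
        afs = rec.annotations.population_afs
        if any(af is not None and af > 0 for af in afs):
            rec.flags.add("pop_af")
            if cfg.drop_population_af:
                dropped[record_key(rec)] = "pop_af: population allele frequency > 0"
                continue
        kept.append(rec)
    return kept, dropped


# ---------------------------------------------------------------------------
# cascade

def run_cascade(plasma_records, germline_records=None, tumour_records=None,
                cp_records=None, blacklist: IntervalSet | None = None,
                config: FilterConfig | None = None,
                patient_id: str = "unknown") -> FilterReport:
    """Run the full cascade for one patient and return the per-stage report."""
    cfg = config or FilterConfig()
    blacklist = blacklist or IntervalSet()
    report = FilterReport(patient_id=patient_id)

    def record_stage(name, before, after, dropped):
        report.stages.append(StageResult(name, len(before), len(after), dropped))
        log.info("filter[%s] %s: %d -> %d", patient_id, name, len(before), len(after))

    snvs = [r for r in plasma_records if r.is_snv]
    current, dropped = call_plasma_candidates(snvs, tumour_records, cfg)
    record_stage("call", snvs, current, dropped)
    universe = list(current)

    stages = [
        ("dbsnp_only", lambda recs: filter_dbsnp_only(recs, cfg)),
        ("exonic", lambda recs: filter_exonic_function(recs, cfg)),
        ("base_quality", lambda recs: filter_base_quality(recs, cfg)),
        ("germline", lambda recs: filter_germline(recs, germline_records, cfg)),
        ("cp_control", lambda recs: filter_cp_controls(recs, cp_records, cfg)),
        ("multiallelic", lambda recs: filter_multiallelic(recs, universe, cfg)),
        ("blacklist", lambda recs: filter_blacklist(recs, blacklist, cfg)),
        ("strand_bias", lambda recs: filter_strand_bias(recs, cfg)),
        ("pop_af", lambda recs: flag_population_af(recs, cfg)),
    ]
    for name, fn in stages:
        nxt, dropped = fn(current)
        record_stage(name, current, nxt, dropped)
        current = nxt

    report.survivors = current
    return report
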