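"""Synthetic serial-plasma cohorts with known ground truth.

The generator emulates the data structure the downstream analysis assumes:
a clonal tumour shedding DNA into serial plasma draws. Each patient carries a
random rooted clone tree whose per-timepoint cellular prevalences satisfy the
phylogenetic sum condition (a parent's prevalence is at least the sum of its
children's). A heterozygous, copy-neutral somatic variant private to clone c
is expected at allele fraction

    v = 0.5 * t_j * P_{c,j}

in the plasma drawn at timepoint j, where t_j is the tumour fraction of the
cfDNA and P_{c,j} the clone's cellular prevalence. Read counts are binomial at
the configured depth with a fair strand split; germline draws show no alt
reads at somatic loci. On top of the clean signal the generator injects each
artifact class the filtering cascade is designed to remove, kataegis clusters
(with an optional T>G substitution bias), signature-driven trinucleotide
spectra, copy-number bin profiles, and cfDNA fragment sizes with the
characteristic 167 bp mononucleosome mode. Every injected object is recorded
in machine-readable truth tables so downstream modules can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._genome import AUTOSOME_MB, AUTOSOMES, BASES, CHANNELS, COMPLEMENT, revcomp
from .core_io import AnnotationRecord, IntervalSet, SampleMeta, VariantRecord

DRIVER_GENES = ("KRAS", "TP53", "SMAD4", "CDKN2A", "NRAS", "HRAS", "BRCA1",
                "BRCA2", "PALB2", "MTOR", "ERBB2", "EGFR", "PBRM1", "KMT2D",
                "RNF43", "IDH1", "IDH2")
DDR_BIOMARKER_GENES = ("BRCA1", "BRCA2", "PALB2")

ARTIFACT_CLASSES = ("germline_leak", "cp_shared", "strand_bias", "blacklist",
                    "multiallelic", "dbsnp_only", "low_bq", "nonexonic")


@dataclass(slots=True)
class SimClone:
    """One tumour clone: its private mutations and prevalence trajectory."""

    clone_id: int
    parent_id: int | None
    mutations: list = field(default_factory=list)  # list of mutation dicts
    prevalence: np.ndarray = field(default_factory=lambda: np.zeros(0))


@dataclass
class SimConfig:
    """Study conditions for one synthetic patient.

    Defaults mirror the serial-plasma design the analysis targets: five plasma
    draws around a treatment course, deep targeted coverage (1000x plasma),
    a matched tumour and germline, and artifact classes injected at modest
    rates relative to the somatic burden.
    """

    seed: int = 0
    n_clones: int = 5
    muts_per_clone: int = 20
    n_timepoints: int = 5
    tumour_fraction_per_timepoint: tuple = (0.25, 0.05, 0.08, 0.12, 0.10)
    plasma_days: tuple = (55, 84, 280, 460, 742)
    depth_plasma: int = 1000
    depth_tumour: int = 200
    depth_germline: int = 50
    depth_cp: int = 500
    tumour_cellularity: float = 0.7
    # minimum pairwise max-over-timepoints prevalence gap between clones;
    # coincident trajectories are unresolvable at any depth
    min_clone_separation: float = 0.25
    include_tumour: bool = True
    driver_rate: float = 0.15
    # artifact rates, as fractions of the somatic mutation count
    germline_leak_rate: float = 0.1
    cp_shared_rate: float = 0.1
    strand_bias_rate: float = 0.1
    blacklist_rate: float = 0.1
    multiallelic_rate: float = 0.1
    dbsnp_only_rate: float = 0.1
    low_bq_rate: float = 0.1
    nonexonic_rate: float = 0.1
    # kataegis injection
    kataegis_clusters: int = 1
    kataegis_cluster_size: int = 8
    kataegis_spacing_max: int = 800
    kataegis_tg_bias: bool = True
    # mutational-signature exposures over the toy catalogue
    n_signatures: int = 10
    signature_exposures: tuple = (0.6, 0.3, 0.1)
    # cfDNA fragment model
    fragment_mode: int = 167
    fragment_sd: float = 10.0
    dinucleosome_weight: float = 0.15
    n_fragments: int = 20000

    def __post_init__(self) -> None:
        nt = self.n_timepoints
        self.tumour_fraction_per_timepoint = tuple(
            self.tumour_fraction_per_timepoint)[:nt]
        self.plasma_days = tuple(self.plasma_days)[:nt]
        if len(self.tumour_fraction_per_timepoint) != nt or len(self.plasma_days) != nt:
            raise ValueError("need a tumour fraction and day per timepoint")
        for t in self.tumour_fraction_per_timepoint:
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"tumour fraction {t} outside [0,1]")
        for name in ("germline_leak_rate", "cp_shared_rate", "strand_bias_rate",
                     "blacklist_rate", "multiallelic_rate", "dbsnp_only_rate",
                     "low_bq_rate", "nonexonic_rate", "driver_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name}={r} outside [0,1]")
        if self.muts_per_clone < 1:
            raise ValueError("muts_per_clone must be >= 1")
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        w = np.asarray(self.signature_exposures, float)
        if w.size > self.n_signatures or w.min(initial=0.0) < 0 or \
                abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("signature exposures must be >=0 and sum to 1")


# ---------------------------------------------------------------------------
# signature catalogue and spectra

def toy_signature_matrix(n_signatures: int = 10, seed: int = 7,
                         concentration: float = 0.08) -> pd.DataFrame:
    """A random, well-separated 96-channel signature catalogue.

    Columns are sparse Dirichlet draws, so distinct signatures concentrate on
    nearly disjoint channel subsets. Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    for s in range(n_signatures):
        w = rng.dirichlet(np.full(96, concentration))
        cols[f"Signature.{s + 1}"] = w
    return pd.DataFrame(cols, index=list(CHANNELS))


def simulate_spectrum(signature_matrix: pd.DataFrame, exposures,
                      n_mutations: int, rng) -> np.ndarray:
    """Draw a 96-channel mutation count vector from a signature mixture.

    Counts are multinomial with channel probabilities ``M @ w``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    w = np.asarray(exposures, float)
    if w.shape[0] != signature_matrix.shape[1]:
        raise ValueError(
            f"exposure vector length {w.shape[0]} != {signature_matrix.shape[1]} signatures")
    if w.min(initial=0.0) < 0:
        raise ValueError("exposures must be non-negative")
    p = signature_matrix.to_numpy() @ (w / w.sum())
    if n_mutations == 0:
        return np.zeros(96, dtype=int)
    return rng.multinomial(n_mutations, p)


def _channel_to_snv(channel: str, rng) -> tuple[str, str, str]:
    """(ref, alt, reference-orientation trinucleotide) for a channel label.

    The pyrimidine-referenced channel is placed on either genomic strand with
    equal probability.
    """
    five, mid, three = channel[0], channel[2:5], channel[6]
    ref, alt = mid[0], mid[2]
    context = five + ref + three
    if rng.random() < 0.5:
        return ref, alt, context
    return COMPLEMENT[ref], COMPLEMENT[alt], revcomp(context)


# ---------------------------------------------------------------------------
# clone trees and read counts

def _draw_positions(n: int, rng, taken: set, chrom: str | None = None) -> list:
    """Unique (chrom, pos) pairs, chromosome chosen length-weighted."""
    lengths = np.array([AUTOSOME_MB[c] for c in AUTOSOMES], float)
    probs = lengths / lengths.sum()
    out = []
    while len(out) < n:
        c = chrom or AUTOSOMES[rng.choice(len(AUTOSOMES), p=probs)]
        pos = int(rng.integers(2, AUTOSOME_MB[c] * 1_000_000 - 1))
        if (c, pos) not in taken:
            taken.add((c, pos))
            out.append((c, pos))
    return out


def simulate_clone_tree(config: SimConfig, rng=None,
                        signature_matrix: pd.DataFrame | None = None):
    """Random rooted clone tree with sum-condition prevalences and truth tables.

    Returns ``(clones, truth)`` where truth holds the mutation->clone map and
    the clone x timepoint prevalence matrix. Prevalences are generated
    top-down: each node's children split a Dirichlet share of the parent's
    prevalence, so the sum condition holds exactly by construction.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if signature_matrix is None:
        signature_matrix = toy_signature_matrix(config.n_signatures)
    k, nt = config.n_clones, config.n_timepoints

    parents = [None] + [int(rng.integers(0, i)) for i in range(1, k)]
    children: dict[int, list[int]] = {i: [] for i in range(k)}
    for i in range(1, k):
        children[parents[i]].append(i)

    # top-down prevalence: root gets U(0.6, 0.95); children of a node split a
    # Dirichlet fraction of the parent's mass, the remainder stays clonal to
    # the parent. Draws are rejected until every clone pair is separated in
    # trajectory space: coincident trajectories are unresolvable at any
    # sequencing depth and would make the simulated truth unidentifiable
    # rather than the inference wrong.
    def draw_prevalence():
        prev = np.zeros((k, nt))
        for j in range(nt):
            prev[0, j] = rng.uniform(0.6, 0.95)
            order = [0]
            while order:
                node = order.pop()
                kids = children[node]
                if not kids:
                    continue
                shares = rng.dirichlet(np.ones(len(kids) + 1))
                for kid, s in zip(kids, shares[:-1]):
                    prev[kid, j] = prev[node, j] * s
                    order.append(kid)
        return prev

    def separation(prev):
        if k == 1:
            return np.inf
        gaps = [np.abs(prev[a] - prev[b]).max()
                for a in range(k) for b in range(a + 1, k)]
        return min(gaps)

    best_prev, best_sep = None, -1.0
    for _ in range(500):
        prev = draw_prevalence()
        sep = separation(prev)
        if sep > best_sep:
            best_prev, best_sep = prev, sep
        if sep >= config.min_clone_separation:
            break
    prev = best_prev

    # per-mutation channel draws give each variant a trinucleotide context
    w = np.zeros(signature_matrix.shape[1])
    w[:len(config.signature_exposures)] = config.signature_exposures
    p_chan = signature_matrix.to_numpy() @ w
    taken: set = set()
    clones, mut_rows = [], []
    n_drivers = 0
    for c in range(k):
        clone = SimClone(clone_id=c, parent_id=parents[c], prevalence=prev[c].copy())
        positions = _draw_positions(config.muts_per_clone, rng, taken)
        for chrom, pos in positions:
            chan = CHANNELS[rng.choice(96, p=p_chan)]
            ref, alt, context = _channel_to_snv(chan, rng)
            if rng.random() < config.driver_rate and n_drivers < len(DRIVER_GENES):
                gene = DRIVER_GENES[n_drivers]
                n_drivers += 1
                driver_class = "tier1"
            else:
                gene = f"GENE{len(mut_rows):04d}"
                driver_class = None
            mut = dict(chrom=chrom, pos=pos, ref=ref, alt=alt, context=context,
                       gene=gene, clone_id=c, driver_class=driver_class)
            clone.mutations.append(mut)
            mut_rows.append(mut)
        clones.append(clone)

    truth = {
        "mutations": pd.DataFrame(mut_rows),
        "prevalence": pd.DataFrame(
            prev, index=[f"clone{c}" for c in range(k)],
            columns=[f"P{j + 1}" for j in range(nt)]),
        "parents": parents,
    }
    return clones, truth


def _truncnorm_bq(rng, n: int) -> np.ndarray:
    bq = rng.normal(35.0, 3.0, size=n)
    return np.clip(bq, 2.0, 60.0)


def _count_row(rng, depth: int, v: float) -> tuple[int, int, int, int]:
    """Binomial alt draw with fair strand split; ref reads fill to depth."""
    alt = rng.binomial(depth, min(max(v, 0.0), 1.0)) if depth > 0 else 0
    alt_fwd = rng.binomial(alt, 0.5) if alt else 0
    ref = depth - alt
    ref_fwd = rng.binomial(ref, 0.5) if ref else 0
    return ref_fwd, ref - ref_fwd, alt_fwd, alt - alt_fwd


def _make_record(sample_id, mut, counts, bq, **ann) -> VariantRecord:
    annotations = AnnotationRecord(
        gene=mut.get("gene"), driver_class=mut.get("driver_class"), **ann)
    rf, rr, af, ar = counts
    return VariantRecord(
        chrom=mut["chrom"], pos=mut["pos"], ref=mut["ref"], alt=mut["alt"],
        sample_id=sample_id, ref_fwd=rf, ref_rev=rr, alt_fwd=af, alt_rev=ar,
        mean_alt_bq=round(float(bq), 2), annotations=annotations,
        extra={"context": mut["context"]} if mut.get("context") else {},
    )


def simulate_reads(clones: list[SimClone], config: SimConfig, rng,
                   patient_id: str = "PT01"):
    """Per-sample variant tables for one patient's clone tree.

    Returns ``(manifest, tables)`` where tables maps sample_id to a list of
    :class:`VariantRecord`. Plasma VAF follows the heterozygous copy-neutral
    model 0.5*t_j*P_{c,j}; the tumour sample replaces t_j with the pathology
    cellularity; the germline shows zero alt reads at every somatic locus.
    """
    nt = config.n_timepoints
    manifest = [SampleMeta(patient_id, f"{patient_id}_GL", "germline")]
    if config.include_tumour:
        manifest.append(SampleMeta(patient_id, f"{patient_id}_T", "tumour",
                                   target_depth=config.depth_tumour))
    for j in range(nt):
        manifest.append(SampleMeta(
            patient_id, f"{patient_id}_P{j + 1}", "plasma", f"P{j + 1}",
            day=config.plasma_days[j], target_depth=config.depth_plasma))

    tables: dict[str, list[VariantRecord]] = {m.sample_id: [] for m in manifest}
    t = np.asarray(config.tumour_fraction_per_timepoint, float)
    for clone in clones:
        for i_m, mut in enumerate(clone.mutations):
            exonic = "nonsynonymous" if rng.random() < 0.85 else "stopgain"
            cosmic = f"COSV{mut['chrom'][3:]}{mut['pos']}"
            for j in range(nt):
                sid = f"{patient_id}_P{j + 1}"
                v = 0.5 * t[j] * clone.prevalence[j]
                depth = max(int(rng.poisson(config.depth_plasma)), 1)
                counts = _count_row(rng, depth, v)
                tables[sid].append(_make_record(
                    sid, mut, counts, _truncnorm_bq(rng, 1)[0],
                    cosmic_id=cosmic, exonic_function=exonic))
            if config.include_tumour:
                sid = f"{patient_id}_T"
                v = 0.5 * config.tumour_cellularity * clone.prevalence[0]
                depth = max(int(rng.poisson(config.depth_tumour)), 1)
                counts = _count_row(rng, depth, v)
                tables[sid].append(_make_record(
                    sid, mut, counts, _truncnorm_bq(rng, 1)[0],
                    cosmic_id=cosmic, exonic_function=exonic))
            sid = f"{patient_id}_GL"
            depth = max(int(rng.poisson(config.depth_germline)), 1)
            ref_fwd = rng.binomial(depth, 0.5)
            tables[sid].append(_make_record(
                sid, mut, (ref_fwd, depth - ref_fwd, 0, 0),
                _truncnorm_bq(rng, 1)[0],
                cosmic_id=cosmic, exonic_function=exonic))
    return manifest, tables


def simulate_blacklist(rng, n_intervals: int = 25,
                       min_len: int = 10_000, max_len: int = 100_000) -> IntervalSet:
    """Random problematic-region intervals in BED convention."""
    intervals = []
    for _ in range(n_intervals):
        chrom = AUTOSOMES[int(rng.integers(0, len(AUTOSOMES)))]
        length = int(rng.integers(min_len, max_len))
        start = int(rng.integers(0, AUTOSOME_MB[chrom] * 1_000_000 - length))
        intervals.append((chrom, start, start + length))
    return IntervalSet(intervals)


# ---------------------------------------------------------------------------
# artifact injection

def _force_called_counts(rng, depth: int, v: float) -> tuple[int, int, int, int]:
    """Counts guaranteed to pass the plasma call rule (>=3 alt, both strands)."""
    alt = max(int(rng.binomial(depth, v)), 3)
    alt = min(alt, depth)
    alt_fwd = int(np.clip(rng.binomial(alt, 0.5), 1, alt - 1))
    ref = depth - alt
    ref_fwd = rng.binomial(ref, 0.5) if ref else 0
    return ref_fwd, ref - ref_fwd, alt_fwd, alt - alt_fwd


def _germline_clean_row(rng, config, mut, patient_id) -> VariantRecord:
    depth = max(int(rng.poisson(config.depth_germline)), 21)
    rf = rng.binomial(depth, 0.5)
    return _make_record(f"{patient_id}_GL", mut, (rf, depth - rf, 0, 0),
                        _truncnorm_bq(rng, 1)[0])


def _rand_snv(rng, taken, chrom=None, pos=None) -> dict:
    if pos is None:
        chrom, pos = _draw_positions(1, rng, taken, chrom)[0]
    ref = BASES[int(rng.integers(0, 4))]
    alt = rng.choice([b for b in BASES if b != ref])
    flank = [BASES[int(rng.integers(0, 4))] for _ in range(2)]
    return dict(chrom=chrom, pos=pos, ref=ref, alt=str(alt),
                context=flank[0] + ref + flank[1], gene=None, driver_class=None)


def inject_artifacts(tables: dict, manifest: list, config: SimConfig, rng,
                     blacklist: IntervalSet, cp_loci: list | None = None,
                     patient_id: str = "PT01") -> pd.DataFrame:
    """Add one cohort of each artifact class the filtering cascade removes.

    Modifies ``tables`` in place and returns a truth table labelling every
    injected variant key with its artifact class. ``cp_loci`` are the
    run-level loci shared by all chronic-pancreatitis control samples; the
    patient's cp_shared artifacts are drawn from them.
    """
    plasma_ids = [m.sample_id for m in manifest
                  if m.sample_class == "plasma" and m.patient_id == patient_id]
    n_somatic = config.n_clones * config.muts_per_clone
    taken = {(r.chrom, r.pos) for recs in tables.values() for r in recs}
    truth_rows = []

    def n_of(rate):
        return int(round(rate * n_somatic))

    def add_plasma_rows(mut, vaf, samples=None, bq=None, counts_fn=None, **ann):
        for sid in (samples or plasma_ids):
            depth = max(int(rng.poisson(config.depth_plasma)), 1)
            counts = (counts_fn or _force_called_counts)(rng, depth, vaf)
            q = bq if bq is not None else _truncnorm_bq(rng, 1)[0]
            tables[sid].append(_make_record(sid, mut, counts, q, **ann))

    def label(mut, cls):
        truth_rows.append(dict(chrom=mut["chrom"], pos=mut["pos"],
                               ref=mut["ref"], alt=mut["alt"], artifact_class=cls))

    # (a) germline leak: real alt reads in the matched germline
    for _ in range(n_of(config.germline_leak_rate)):
        mut = _rand_snv(rng, taken)
        add_plasma_rows(mut, 0.5, exonic_function="nonsynonymous")
        depth = max(int(rng.poisson(config.depth_germline)), 21)
        alt = max(int(rng.binomial(depth, 0.5)), 1)
        af = rng.binomial(alt, 0.5)
        rf = rng.binomial(depth - alt, 0.5)
        tables[f"{patient_id}_GL"].append(_make_record(
            f"{patient_id}_GL", mut, (rf, depth - alt - rf, af, alt - af),
            _truncnorm_bq(rng, 1)[0], exonic_function="nonsynonymous"))
        label(mut, "germline_leak")

    # (b) shared with chronic-pancreatitis control plasma
    cp_pool = list(cp_loci or [])
    rng.shuffle(cp_pool)
    for mut in cp_pool[:n_of(config.cp_shared_rate)]:
        add_plasma_rows(mut, 0.05, exonic_function="nonsynonymous")
        tables[f"{patient_id}_GL"].append(_germline_clean_row(rng, config, mut, patient_id))
        label(mut, "cp_shared")

    # (c) strand-biased: every alt read on one strand; half get matched-tumour
    # support so they are rescued into the cascade and must fall to the
    # Fisher test rather than the call rule
    tumour_sid = f"{patient_id}_T" if config.include_tumour else None
    for i in range(n_of(config.strand_bias_rate)):
        mut = _rand_snv(rng, taken)
        fwd = rng.random() < 0.5
        for sid in plasma_ids:
            depth = max(int(rng.poisson(config.depth_plasma)), 1)
            alt = int(rng.integers(10, 26))
            ref = depth - alt
            rf = rng.binomial(ref, 0.5)
            counts = (rf, ref - rf, alt, 0) if fwd else (rf, ref - rf, 0, alt)
            tables[sid].append(_make_record(
                sid, mut, counts, _truncnorm_bq(rng, 1)[0],
                exonic_function="nonsynonymous"))
        tables[f"{patient_id}_GL"].append(_germline_clean_row(rng, config, mut, patient_id))
        if tumour_sid and i % 2 == 0:
            depth = max(int(rng.poisson(config.depth_tumour)), 1)
            counts = _force_called_counts(rng, depth, 0.05)
            tables[tumour_sid].append(_make_record(
                tumour_sid, mut, counts, _truncnorm_bq(rng, 1)[0],
                exonic_function="nonsynonymous"))
        label(mut, "strand_bias")

    # (d) inside blacklist regions
    bl = list(blacklist)
    for _ in range(n_of(config.blacklist_rate) if bl else 0):
        chrom, start, end = bl[int(rng.integers(0, len(bl)))]
        pos = int(rng.integers(start + 1, end + 1))  # 1-based inside interval
        if (chrom, pos) in taken:
            continue
        taken.add((chrom, pos))
        mut = _rand_snv(rng, taken, chrom=chrom, pos=pos)
        add_plasma_rows(mut, 0.05, exonic_function="nonsynonymous")
        tables[f"{patient_id}_GL"].append(_germline_clean_row(rng, config, mut, patient_id))
        label(mut, "blacklist")

    # (e) multi-allelic: two alternate alleles at one locus across serial plasma
    for _ in range(n_of(config.multiallelic_rate)):
        chrom, pos = _draw_positions(1, rng, taken)[0]
        ref = BASES[int(rng.integers(0, 4))]
        alts = rng.choice([b for b in BASES if b != ref], size=2, replace=False)
        flank = [BASES[int(rng.integers(0, 4))] for _ in range(2)]
        for i_alt, alt in enumerate(alts):
            mut = dict(chrom=chrom, pos=pos, ref=ref, alt=str(alt),
                       context=flank[0] + ref + flank[1], gene=None, driver_class=None)
            sample = plasma_ids[i_alt % len(plasma_ids)]
            add_plasma_rows(mut, 0.05, samples=[sample],
                            exonic_function="nonsynonymous")
            label(mut, "multiallelic")
        mut_gl = dict(chrom=chrom, pos=pos, ref=ref, alt=str(alts[0]),
                      context=flank[0] + ref + flank[1], gene=None, driver_class=None)
        tables[f"{patient_id}_GL"].append(_germline_clean_row(rng, config, mut_gl, patient_id))

    # (f) dbSNP identifier without a COSMIC identifier
    for _ in range(n_of(config.dbsnp_only_rate)):
        mut = _rand_snv(rng, taken)
        add_plasma_rows(mut, 0.05, exonic_function="nonsynonymous",
                        dbsnp_id=f"rs{int(rng.integers(10**6, 10**8))}")
        tables[f"{patient_id}_GL"].append(_germline_clean_row(rng, config, mut, patient_id))
        label(mut, "dbsnp_only")

    # (g) low mean alt base quality
    for _ in range(n_of(config.low_bq_rate)):
        mut = _rand_snv(rng, taken)
        add_plasma_rows(mut, 0.05, bq=round(float(rng.uniform(10, 24.5)), 2),
                        exonic_function="nonsynonymous")
        tables[f"{patient_id}_GL"].append(_germline_clean_row(rng, config, mut, patient_id))
        label(mut, "low_bq")

    # (h) synonymous / unknown exonic function
    for _ in range(n_of(config.nonexonic_rate)):
        mut = _rand_snv(rng, taken)
        fn = "synonymous" if rng.random() < 0.5 else "unknown"
        add_plasma_rows(mut, 0.05, exonic_function=fn)
        tables[f"{patient_id}_GL"].append(_germline_clean_row(rng, config, mut, patient_id))
        label(mut, "nonexonic")

    cols = ["chrom", "pos", "ref", "alt", "artifact_class"]
    return pd.DataFrame(truth_rows, columns=cols)


def inject_kataegis(tables: dict, manifest: list, config: SimConfig, rng,
                    patient_id: str = "PT01") -> pd.DataFrame:
    """Place clustered SNV runs and return their truth intervals.

    Each cluster holds ``kataegis_cluster_size`` SNVs with consecutive spacing
    uniform on [100, spacing_max]; clusters below six members or with mean
    spacing above 1 kb are labelled sub-threshold in the truth table. With
    ``kataegis_tg_bias`` every member is a T>G substitution (on the pyrimidine
    strand), emulating a polymerase-eta-like local process.
    """
    plasma_ids = [m.sample_id for m in manifest
                  if m.sample_class == "plasma" and m.patient_id == patient_id]
    t = np.asarray(config.tumour_fraction_per_timepoint, float)
    taken = {(r.chrom, r.pos) for recs in tables.values() for r in recs}
    rows = []
    for ev in range(config.kataegis_clusters):
        size = config.kataegis_cluster_size
        span_max = size * config.kataegis_spacing_max + 1000
        chrom = AUTOSOMES[int(rng.integers(0, len(AUTOSOMES)))]
        start = int(rng.integers(1000, AUTOSOME_MB[chrom] * 1_000_000 - span_max))
        spacings = rng.integers(100, max(config.kataegis_spacing_max, 101),
                                size=max(size - 1, 0))
        positions = start + np.concatenate([[0], np.cumsum(spacings)])
        # reposition on collision with existing loci
        while any((chrom, int(p)) in taken for p in positions):
            start += span_max
            positions = start + np.concatenate([[0], np.cumsum(spacings)])
        for p in positions:
            taken.add((chrom, int(p)))
            if config.kataegis_tg_bias:
                on_pyr = rng.random() < 0.5
                ref, alt = ("T", "G") if on_pyr else ("A", "C")
                flank = [BASES[int(rng.integers(0, 4))] for _ in range(2)]
                mut = dict(chrom=chrom, pos=int(p), ref=ref, alt=alt,
                           context=flank[0] + ref + flank[1],
                           gene=None, driver_class=None)
            else:
                mut = _rand_snv(rng, taken, chrom=chrom, pos=int(p))
            cosmic = f"COSV{chrom[3:]}{int(p)}"
            for j, sid in enumerate(plasma_ids):
                depth = max(int(rng.poisson(config.depth_plasma)), 1)
                counts = _force_called_counts(rng, depth, 0.5 * t[j] * 0.9)
                tables[sid].append(_make_record(
                    sid, mut, counts, _truncnorm_bq(rng, 1)[0],
                    cosmic_id=cosmic, exonic_function="nonsynonymous"))
            tables[f"{patient_id}_GL"].append(
                _germline_clean_row(rng, config, mut, patient_id))
        imds = np.diff(np.sort(positions))
        meets = size >= 6 and (imds.mean() <= 1000.0 if len(imds) else False)
        rows.append(dict(event_id=ev, chrom=chrom, start=int(positions.min()),
                         end=int(positions.max()), n_mutations=size,
                         mean_imd=float(imds.mean()) if len(imds) else np.nan,
                         meets_definition=bool(meets)))
    cols = ["event_id", "chrom", "start", "end", "n_mutations", "mean_imd",
            "meets_definition"]
    return pd.DataFrame(rows, columns=cols)


def simulate_background_snvs(rate_per_mb: float, genome_mb: int, rng,
                             chrom: str = "chr1") -> np.ndarray:
    """Poisson background of unclustered SNV positions on one synthetic contig."""
    n = rng.poisson(rate_per_mb * genome_mb)
    return np.sort(rng.integers(1, genome_mb * 1_000_000, size=n))


def simulate_fragments(config: SimConfig, rng, n: int | None = None) -> np.ndarray:
    """cfDNA fragment lengths: mono- plus di-nucleosome Gaussian mixture.

    Weight ``1 - d`` on Normal(mode, sd) and ``d`` on Normal(2*mode, 2*sd),
    rounded to integer bp and truncated at >= 50.
    """
    d = config.dinucleosome_weight
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"dinucleosome weight {d} outside [0,1]")
    if config.fragment_mode <= 0:
        raise ValueError("fragment mode must be positive")
    n = config.n_fragments if n is None else n
    comp = rng.random(n) < d
    n_di = int(comp.sum())
    lengths = np.empty(n)
    lengths[~comp] = rng.normal(config.fragment_mode, config.fragment_sd, n - n_di)
    lengths[comp] = rng.normal(2 * config.fragment_mode, 2 * config.fragment_sd, n_di)
    return np.maximum(np.rint(lengths).astype(np.int32), 50)


# ---------------------------------------------------------------------------
# copy-number bin profiles

def simulate_bin_profiles(tumour_fraction: float, aberrant: dict, rng,
                          mean_reads_per_bin: int = 1665,
                          gc_bias: float = 0.0, low_map_fraction: float = 0.02):
    """Paired (sample, normal) 1 Mb bin profiles with known copy states.

    ``aberrant`` maps chromosome name to an integer copy state applied to the
    whole chromosome, or to ``(start_mb, end_mb, state)`` for a focal event;
    everything else is diploid. Counts are Poisson around a GC-biased rate;
    the default depth puts the per-bin log-ratio noise near sigma = 0.05.
    Returns ``(sample_df, normal_df, truth_states)``.
    """
    rows = []
    states = []
    for chrom in AUTOSOMES:
        n_bins = AUTOSOME_MB[chrom]
        spec = aberrant.get(chrom)
        for b in range(n_bins):
            c = 2
            if spec is not None:
                if isinstance(spec, tuple):
                    s_mb, e_mb, st = spec
                    c = st if s_mb <= b < e_mb else 2
                else:
                    c = int(spec)
            gc = rng.uniform(0.35, 0.55)
            mappability = rng.uniform(0.5, 0.89) if rng.random() < low_map_fraction \
                else rng.uniform(0.95, 1.0)
            bias = np.exp(-gc_bias * (gc - 0.45) ** 2)
            lam_n = mean_reads_per_bin * bias
            lam_s = lam_n * (c * tumour_fraction + 2 * (1 - tumour_fraction)) / 2.0
            rows.append(dict(chrom=chrom, start=b * 1_000_000,
                             count_sample=int(rng.poisson(lam_s)),
                             count_normal=int(rng.poisson(lam_n)),
                             gc=gc, mappability=mappability))
            states.append(c)
    df = pd.DataFrame(rows)
    sample = df[["chrom", "start", "count_sample", "gc", "mappability"]].rename(
        columns={"count_sample": "count"})
    normal = df[["chrom", "start", "count_normal", "gc", "mappability"]].rename(
        columns={"count_normal": "count"})
    return sample, normal, np.array(states)


# ---------------------------------------------------------------------------
# cohort assembly

@dataclass(slots=True)
class PatientSim:
    patient_id: str
    config: SimConfig
    manifest: list
    tables: dict                      # sample_id -> list[VariantRecord]
    truth: dict                       # mutations/prevalence/parents/artifacts/kataegis
    fragments: np.ndarray


@dataclass(slots=True)
class CohortSim:
    patients: list                    # list[PatientSim]
    cp_manifest: list
    cp_tables: dict
    blacklist: IntervalSet
    signature_matrix: pd.DataFrame

    @property
    def manifest(self) -> list:
        out = []
        for p in self.patients:
            out.extend(p.manifest)
        out.extend(self.cp_manifest)
        return out

    @property
    def tables(self) -> dict:
        out = {}
        for p in self.patients:
            out.update(p.tables)
        out.update(self.cp_tables)
        return out


def simulate_patient(config: SimConfig, patient_id: str, rng,
                     blacklist: IntervalSet, cp_loci: list,
                     signature_matrix: pd.DataFrame | None = None) -> PatientSim:
    """One synthetic patient: tree, reads, artifacts, kataegis, fragments."""
    if signature_matrix is None:
        signature_matrix = toy_signature_matrix(config.n_signatures)
    clones, truth = simulate_clone_tree(config, rng, signature_matrix)
    manifest, tables = simulate_reads(clones, config, rng, patient_id)
    truth["artifacts"] = inject_artifacts(
        tables, manifest, config, rng, blacklist, cp_loci, patient_id)
    truth["kataegis"] = inject_kataegis(tables, manifest, config, rng, patient_id)
    fragments = simulate_fragments(config, rng)
    return PatientSim(patient_id=patient_id, config=config, manifest=manifest,
                      tables=tables, truth=truth, fragments=fragments)


def simulate_cohort(configs: dict, seed: int = 0, n_cp_samples: int = 2,
                    n_cp_loci: int = 20) -> CohortSim:
    """A cohort of patients plus shared chronic-pancreatitis control plasma.

    ``configs`` maps patient_id to a :class:`SimConfig`. CP-control artifact
    loci are drawn once per run and shared by every CP sample, emulating the
    recurrent technical artifacts the CP filter is designed to catch.
    """
    rng = np.random.default_rng(seed)
    blacklist = simulate_blacklist(rng)
    taken: set = set()
    cp_loci = [_rand_snv(rng, taken) for _ in range(n_cp_loci)]

    sig = toy_signature_matrix()
    cp_manifest, cp_tables = [], {}
    for i in range(n_cp_samples):
        pid = f"CP{i + 1:02d}"
        sid = f"{pid}_P1"
        cp_manifest.append(SampleMeta(pid, sid, "cp_control"))
        recs = []
        for mut in cp_loci:
            depth = max(int(rng.poisson(500)), 1)
            alt = max(int(rng.binomial(depth, 0.03)), 1)
            af = rng.binomial(alt, 0.5)
            ref = depth - alt
            rf = rng.binomial(ref, 0.5)
            recs.append(_make_record(sid, mut, (rf, ref - rf, af, alt - af),
                                     _truncnorm_bq(rng, 1)[0]))
        cp_tables[sid] = recs

    patients = []
    for pid, cfg in configs.items():
        patients.append(simulate_patient(cfg, pid, rng, blacklist, cp_loci, sig))
    return CohortSim(patients=patients, cp_manifest=cp_manifest,
                     cp_tables=cp_tables, blacklist=blacklist,
                     signature_matrix=sig)


def write_cohort(cohort: CohortSim, outdir) -> None:
    """Write the cohort as the pipeline's on-disk inputs plus truth tables."""
    from pathlib import Path

    from .core_io import write_blacklist, write_manifest, write_variant_table

    out = Path(outdir)
    (out / "variants").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    write_manifest(cohort.manifest, out / "manifest.tsv")
    write_blacklist(cohort.blacklist, out / "blacklist.bed")
    cohort.signature_matrix.to_csv(out / "signatures.tsv", sep="\t",
                                   index_label="channel", float_format="%.8g")
    for sid, recs in sorted(cohort.tables.items()):
        write_variant_table(recs, out / "variants" / f"{sid}.tsv")
    for p in cohort.patients:
        prefix = out / "truth" / p.patient_id
        p.truth["mutations"].to_csv(f"{prefix}_mutations.tsv", sep="\t", index=False)
        p.truth["prevalence"].to_csv(f"{prefix}_prevalence.tsv", sep="\t",
                                     float_format="%.6g")
        p.truth["artifacts"].to_csv(f"{prefix}_artifacts.tsv", sep="\t", index=False)
        p.truth["kataegis"].to_csv(f"{prefix}_kataegis.tsv", sep="\t", index=False)
        np.savetxt(f"{prefix}_fragments.txt", p.fragments, fmt="%d")
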