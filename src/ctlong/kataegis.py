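"""Localized-hypermutation (kataegis) detection.

A kataegis event is a run of six or more SNVs whose mean inter-mutational
distance (IMD) is at most 1000 bp. Consecutive SNVs on a chromosome are
grouped greedily while the gap stays within 10^4 bp (log10 IMD <= 4); a
closed group is emitted when it meets the size and mean-IMD thresholds.
A sliding-window binomial hypermutation score (observed/expected mutation
rate, significant when the score is >= 5 and the binomial upper tail is
below 0.05) is provided for window-level scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from ._genome import SUB_CLASSES, pyrimidine_class
from .config import KataegisConfig
from .core_io import VariantRecord


@dataclass(slots=True)
class KataegisEvent:
    chrom: str
    start: int              # 1-based, min member position
    end: int                # 1-based, max member position
    members: list = field(default_factory=list)  # (chrom,pos,ref,alt) keys
    n_mutations: int = 0
    mean_imd: float = 0.0
    score: float | None = None
    spectrum: dict = field(default_factory=dict)
    dominant_class: tuple = ()


def intermutation_distances(positions) -> np.ndarray:
    """IMDs between consecutive sorted unique positions on one chromosome."""
    pos = np.asarray(sorted(positions), dtype=np.int64)
    if len(pos) != len(np.unique(pos)):
        dup = pos[np.where(np.diff(pos) == 0)[0][0]]
        raise ValueError(f"duplicate position {dup}; multi-allelic sites must be "
                         "removed before kataegis analysis")
    return np.diff(pos)


def substitution_spectrum(variants) -> tuple[dict, tuple]:
    """Six-class pyrimidine-referenced substitution counts and dominant class.

    Accepts VariantRecords or (ref, alt) pairs. Ties for the dominant class
    are reported as a tuple of all tied classes; an empty input yields an
    all-zero spectrum and no dominant class.
    """
    counts = {c: 0 for c in SUB_CLASSES}
    for v in variants:
        ref, alt = (v.ref, v.alt) if isinstance(v, VariantRecord) else (v[0], v[1])
        counts[pyrimidine_class(ref, alt)] += 1
    top = max(counts.values(), default=0)
    dominant = tuple(c for c in SUB_CLASSES if counts[c] == top and top > 0)
    return counts, dominant


def detect_kataegis(variants, config: KataegisConfig | None = None):
    """Greedy per-chromosome clustering of SNVs into kataegis events.

    Variants may come from one sample or a patient's combined plasma set;
    duplicate variant keys (the same mutation seen at several timepoints)
    are collapsed before clustering.
    """
    cfg = config or KataegisConfig()
    max_gap = 10 ** cfg.max_log10_imd
    by_chrom: dict[str, dict[int, tuple]] = {}
    for rec in variants:
        if isinstance(rec, VariantRecord):
            if not rec.is_snv:
                continue
            by_chrom.setdefault(rec.chrom, {})[rec.pos] = rec.key
        else:  # (chrom, pos, ref, alt)
            chrom, pos, ref, alt = rec
            by_chrom.setdefault(chrom, {})[pos] = (chrom, pos, ref, alt)

    events = []
    for chrom in sorted(by_chrom):
        keys = [by_chrom[chrom][p] for p in sorted(by_chrom[chrom])]
        positions = [k[1] for k in keys]
        cluster: list = []

        def close(cluster):
            if len(cluster) < cfg.min_cluster_size:
                return
            pos = [k[1] for k in cluster]
            imds = np.diff(pos)
            if imds.mean() > cfg.max_mean_imd:
                return
            spectrum, dominant = substitution_spectrum(
                [(k[2], k[3]) for k in cluster])
            events.append(KataegisEvent(
                chrom=chrom, start=pos[0], end=pos[-1], members=list(cluster),
                n_mutations=len(cluster), mean_imd=float(imds.mean()),
                spectrum=spectrum, dominant_class=dominant))

        for i, key in enumerate(keys):
            if cluster and positions[i] - cluster[-1][1] > max_gap:
                close(cluster)
                cluster = []
            cluster.append(key)
        close(cluster)
    return events


def hypermutation_score(window_mutation_count: int, window_bp: int,
                        background_rate: float,
                        config: KataegisConfig | None = None):
    """Window rate ratio H and its binomial upper-tail p.

    ``background_rate`` is the sample-wide SNV rate per bp (total SNVs over
    total covered bp). H = (count / window_bp) / background_rate; the window
    is flagged when H >= 5 and the Binomial(window_bp, background_rate)
    upper tail at the observed count is < 0.05.
    """
    cfg = config or KataegisConfig()
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if background_rate <= 0:
        raise ValueError("background rate is zero: hypermutation score undefined")
    h = (window_mutation_count / window_bp) / background_rate
    # P(X >= k) under the null
    p = float(binom.sf(window_mutation_count - 1, window_bp, background_rate)) \
        if window_mutation_count > 0 else 1.0
    flagged = h >= cfg.min_score and p < cfg.score_p
    return h, p, flagged


def score_events(events, total_snvs: int, covered_bp: int,
                 config: KataegisConfig | None = None):
    """Attach hypermutation scores to detected events in place."""
    cfg = config or KataegisConfig()
    rate = total_snvs / covered_bp if covered_bp else 0.0
    for ev in events:
        window = max(ev.end - ev.start + 1, 1)
        ev.score, _, _ = hypermutation_score(ev.n_mutations, window, rate, cfg)
    return events


def rainfall_table(variants):
    """Per-variant (chrom, pos, IMD to previous, substitution class) rows.

    The first variant on each chromosome has no IMD (None); ready for
    rainfall-style plotting.
    """
    by_chrom: dict[str, list] = {}
    for rec in variants:
        if isinstance(rec, VariantRecord):
            if not rec.is_snv:
                continue
            by_chrom.setdefault(rec.chrom, []).append((rec.pos, rec.ref, rec.alt))
        else:
            chrom, pos, ref, alt = rec
            by_chrom.setdefault(chrom, []).append((pos, ref, alt))
    rows = []
    for chrom in sorted(by_chrom):
        prev = None
        for pos, ref, alt in sorted(set(by_chrom[chrom])):
            rows.append(dict(chrom=chrom, pos=pos,
                             imd=None if prev is None else pos - prev,
                             sub_class=pyrimidine_class(ref, alt)))
            prev = pos
    return rows
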