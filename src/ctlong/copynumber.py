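"""Binned read-depth normalization, copy-state segmentation and tumour fraction.

Read counts in non-overlapping 1 Mb bins are corrected for GC and mappability
bias with LOESS fits on autosomes, converted to log2 ratios against a matched
normal, and segmented with a 6-state Viterbi pass (HOMD through HLAMP) whose
state means follow the purity model

    E[log2 r | c, t] = log2((t*c + 2*(1 - t)) / 2)

for integer copy state c and tumour fraction t. The tumour fraction is chosen
to maximize the Viterbi path likelihood over the published normal-contamination
grid, refined by golden-section search around the best grid point; a mild
diploid-favouring per-bin state prior breaks the aliasing degeneracy between
(state c at fraction t) and (a more extreme state at a smaller fraction).
The model is clonal-only: one aberrant cell population, no subclonal fraction
parameter. Pathology cellularity, when provided for a tumour sample, fixes t
instead of estimating it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .config import CopyNumberConfig

STATE_NAMES = ("HOMD", "HETD", "NEUT", "GAIN", "AMP", "HLAMP")


@dataclass(slots=True)
class CNSegment:
    chrom: str
    start: int          # 0-based bin-grid start
    end: int            # exclusive
    state: int          # integer copy number, capped at the HLAMP state
    state_name: str
    mean_logr: float
    n_bins: int


@dataclass(slots=True)
class CNResult:
    segments: list
    tumour_fraction: float
    log_likelihood: float
    no_evidence: bool
    sigma: float


def expected_logr(state: int, tumour_fraction: float,
                  floor: float = -8.0) -> float:
    """Expected log2 ratio of copy state ``state`` at the given tumour fraction."""
    if not 0.0 <= tumour_fraction <= 1.0:
        raise ValueError(f"tumour fraction {tumour_fraction} outside [0,1]")
    if state < 0:
        raise ValueError("copy state must be a non-negative integer")
    ratio = (tumour_fraction * state + 2.0 * (1.0 - tumour_fraction)) / 2.0
    if ratio <= 0:
        return floor
    return max(float(np.log2(ratio)), floor)


def _loess_correct(counts: np.ndarray, covariate: np.ndarray,
                   usable: np.ndarray) -> np.ndarray:
    """Divide counts by the LOESS-predicted count given a covariate."""
    x = covariate[usable]
    y = counts[usable].astype(float)
    fit = lowess(y, x, frac=0.3, return_sorted=True)
    pred = np.interp(covariate, fit[:, 0], fit[:, 1])
    pred = np.where(pred <= 0, np.nan, pred)
    return counts / pred


def normalize_bins(sample: pd.DataFrame, normal: pd.DataFrame,
                   config: CopyNumberConfig | None = None) -> pd.DataFrame:
    """GC/mappability LOESS correction and log2 ratio against a matched normal.

    Both frames need columns chrom, start, count and per-bin gc and
    mappability on an identical bin grid. Bins with mappability below the
    threshold or zero normal count are masked (column ``usable``).
    """
    cfg = config or CopyNumberConfig()
    for col in ("chrom", "start", "count", "gc", "mappability"):
        for name, df in (("sample", sample), ("normal", normal)):
            if col not in df.columns:
                raise ValueError(f"{name} profile missing column {col!r}")
    if len(sample) != len(normal) or \
            not (sample["chrom"].values == normal["chrom"].values).all() or \
            not (sample["start"].values == normal["start"].values).all():
        raise ValueError("sample and normal bin grids do not match")

    out = sample[["chrom", "start", "gc", "mappability"]].copy()
    usable = (sample["mappability"].values >= cfg.min_mappability) & \
             (normal["count"].values > 0) & (sample["count"].values > 0)
    corr_s = _loess_correct(sample["count"].values.astype(float),
                            sample["gc"].values, usable)
    corr_n = _loess_correct(normal["count"].values.astype(float),
                            normal["gc"].values, usable)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = corr_s / corr_n
        ratio = ratio / np.nanmedian(ratio[usable])
        logr = np.log2(ratio)
    usable &= np.isfinite(logr)
    out["logr"] = logr
    out["usable"] = usable
    return out


def _viterbi(logr: np.ndarray, chrom_index: np.ndarray, t: float,
             sigma: float, cfg: CopyNumberConfig):
    """Viterbi path and log-likelihood over the 6 copy states.

    The chain restarts at each chromosome boundary with the state prior.
    """
    n_states = cfg.max_copy_state + 1
    means = np.array([expected_logr(c, t, cfg.logr_floor) for c in range(n_states)])
    prior = np.log(np.asarray(cfg.state_prior, float) /
                   np.sum(cfg.state_prior))
    stay = np.log(cfg.self_transition)
    move = np.log((1.0 - cfg.self_transition) / (n_states - 1))
    trans = np.full((n_states, n_states), move)
    np.fill_diagonal(trans, stay)

    # Gaussian emission + per-bin state prior (the prior regularizes the
    # purity likelihood against state/purity aliasing)
    emit = (-0.5 * ((logr[:, None] - means[None, :]) / sigma) ** 2
            - np.log(sigma * np.sqrt(2 * np.pi))) + prior[None, :]

    n = len(logr)
    path = np.zeros(n, dtype=int)
    total_ll = 0.0
    start = 0
    while start < n:
        end = start
        while end < n and chrom_index[end] == chrom_index[start]:
            end += 1
        seg = emit[start:end]
        m = end - start
        delta = seg[0] + prior
        back = np.zeros((m, n_states), dtype=int)
        for i in range(1, m):
            cand = delta[:, None] + trans
            back[i] = np.argmax(cand, axis=0)
            delta = cand[back[i], np.arange(n_states)] + seg[i]
        best = int(np.argmax(delta))
        total_ll += float(delta[best])
        states = np.zeros(m, dtype=int)
        states[-1] = best
        for i in range(m - 1, 0, -1):
            states[i - 1] = back[i, states[i]]
        path[start:end] = states
        start = end
    return path, total_ll


def _segments_from_path(profile: pd.DataFrame, path: np.ndarray) -> list:
    segs = []
    chroms = profile["chrom"].values
    starts = profile["start"].values
    i = 0
    n = len(path)
    while i < n:
        j = i
        while j < n and chroms[j] == chroms[i] and path[j] == path[i]:
            j += 1
        logr = profile["logr"].values[i:j]
        segs.append(CNSegment(
            chrom=str(chroms[i]), start=int(starts[i]),
            end=int(starts[j - 1]) + 1_000_000, state=int(path[i]),
            state_name=STATE_NAMES[int(path[i])],
            mean_logr=float(np.mean(logr)), n_bins=j - i))
        i = j
    return segs


def segment_and_estimate(profile: pd.DataFrame,
                         t_grid=None,
                         fixed_tumour_fraction: float | None = None,
                         config: CopyNumberConfig | None = None) -> CNResult:
    """Copy-state segmentation with maximum-likelihood tumour fraction.

    ``profile`` is the output of :func:`normalize_bins`. The candidate grid
    defaults to one minus the published contamination grid; the best grid
    point is refined by golden-section search between its neighbours. With
    ``fixed_tumour_fraction`` (pathology cellularity for tumour samples) the
    search is skipped.
    """
    cfg = config or CopyNumberConfig()
    usable = profile[profile["usable"]].reset_index(drop=True)
    if len(usable) < cfg.min_usable_bins:
        raise ValueError(
            f"insufficient bins: {len(usable)} usable < {cfg.min_usable_bins}")
    logr = usable["logr"].values
    chrom_index = pd.factorize(usable["chrom"])[0]
    mad = float(np.median(np.abs(logr - np.median(logr))))
    sigma = max(1.4826 * mad, 1e-3)

    def loglik(t):
        return _viterbi(logr, chrom_index, t, sigma, cfg)[1]

    if fixed_tumour_fraction is not None:
        t_hat = float(fixed_tumour_fraction)
    else:
        grid = sorted(1.0 - np.asarray(
            cfg.normal_contamination_grid if t_grid is None else
            [1.0 - t for t in t_grid], float))
        lls = [loglik(t) for t in grid]
        best = int(np.argmax(lls))
        lo = grid[best - 1] if best > 0 else max(grid[best] / 2, 1e-4)
        hi = grid[best + 1] if best < len(grid) - 1 else min(
            grid[best] + (grid[best] - grid[best - 1]), 1.0)
        t_hat = _golden_section(loglik, lo, hi)

    path, ll = _viterbi(logr, chrom_index, t_hat, sigma, cfg)
    segments = _segments_from_path(usable, path)
    no_evidence = bool(np.all(path == 2))
    return CNResult(segments=segments, tumour_fraction=float(t_hat),
                    log_likelihood=ll, no_evidence=no_evidence, sigma=sigma)


def _golden_section(f, lo: float, hi: float, tol: float = 1e-3,
                    max_iter: int = 40) -> float:
    """Maximize a unimodal function on [lo, hi]."""
    inv_phi = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c = b - inv_phi * (b - a)
    d = a + inv_phi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        if b - a < tol:
            break
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - inv_phi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + inv_phi * (b - a)
            fd = f(d)
    return (a + b) / 2


def compare_sample_states(results: dict, gene_map: dict | None = None) -> pd.DataFrame:
    """Per-chromosome (and per named locus) copy-state concordance table.

    ``results`` maps sample_id to :class:`CNResult`. For each chromosome the
    dominant (most-bins) state per sample is reported with a shared/discordant
    call: "concordant" when all samples agree, "shared gain/loss,
    amplitude-discordant" when all deviate in the same direction but by
    different amounts, otherwise "discordant"; loci aberrant in a single
    sample are labelled "<sample>-specific". ``gene_map`` may supply
    gene -> (chrom, pos) entries scored on the containing segment.
    """
    def dominant_state(segs, chrom):
        counts: dict[int, int] = {}
        for s in segs:
            if s.chrom == chrom:
                counts[s.state] = counts.get(s.state, 0) + s.n_bins
        return max(counts, key=counts.get) if counts else None

    def state_at(segs, chrom, pos):
        for s in segs:
            if s.chrom == chrom and s.start <= pos < s.end:
                return s.state
        return None

    def verdict(states: dict):
        vals = [v for v in states.values() if v is not None]
        if not vals:
            return "no data"
        if len(set(vals)) == 1:
            return "concordant neutral" if vals[0] == 2 else "concordant aberrant"
        signs = {np.sign(v - 2) for v in vals}
        aberrant = [sid for sid, v in states.items() if v is not None and v != 2]
        if len(aberrant) == 1:
            return f"{aberrant[0]}-specific"
        if signs == {1}:
            return "shared gain, amplitude-discordant"
        if signs == {-1}:
            return "shared loss, amplitude-discordant"
        return "discordant"

    sample_ids = list(results)
    chroms = sorted({s.chrom for r in results.values() for s in r.segments})
    rows = []
    for chrom in chroms:
        states = {sid: dominant_state(results[sid].segments, chrom)
                  for sid in sample_ids}
        row = {"locus": chrom, **{sid: None if st is None else STATE_NAMES[st]
                                  for sid, st in states.items()},
               "call": verdict(states)}
        rows.append(row)
    for gene, (chrom, pos) in (gene_map or {}).items():
        states = {sid: state_at(results[sid].segments, chrom, pos)
                  for sid in sample_ids}
        rows.append({"locus": gene,
                     **{sid: None if st is None else STATE_NAMES[st]
                        for sid, st in states.items()},
                     "call": verdict(states)})
    return pd.DataFrame(rows)


def segments_table(result: CNResult, path=None) -> pd.DataFrame:
    df = pd.DataFrame([{
        "chrom": s.chrom, "start": s.start, "end": s.end, "state": s.state,
        "state_name": s.state_name, "mean_logr": round(s.mean_logr, 4),
        "n_bins": s.n_bins} for s in result.segments])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
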