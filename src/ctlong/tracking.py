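"""Longitudinal summaries: mean MAF series, tumour-plasma concordance,
mutation loads, fragment-size profiles, pathway enrichment and
driver/actionability annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .config import TrackingConfig
from .core_io import VariantRecord


@dataclass(slots=True)
class TimepointSummary:
    patient_id: str
    timepoint_label: str
    n_candidates: int
    mean_maf: float | None
    n_covered_loci: int
    ca199: float | None = None


@dataclass(slots=True)
class EnrichmentResult:
    pathway_id: str
    universe_size: int
    pathway_size: int
    n_selected: int
    n_overlap: int
    p_value: float
    q_value: float | None = None


def mean_maf_series(candidates_by_timepoint: dict, patient_id: str = "unknown",
                    ca199: pd.DataFrame | None = None,
                    timepoint_days: dict | None = None,
                    config: TrackingConfig | None = None) -> list:
    """Mean mutant allele fraction over the patient's candidate locus set.

    ``candidates_by_timepoint`` maps timepoint label to that draw's records.
    The locus set is the union of candidate variant keys across timepoints;
    at each timepoint a locus covered but undetected counts as MAF 0 (the
    ``undetected_maf_policy`` config drops such loci instead). Duplicate rows
    for one variant key are collapsed to the deepest observation. A CA19-9
    series (columns day, value) is joined by nearest day within the allowed
    gap when timepoint days are supplied.
    """
    cfg = config or TrackingConfig()
    locus_set: set = set()
    per_tp: dict[str, dict] = {}
    for tp, records in candidates_by_timepoint.items():
        best: dict = {}
        for rec in records:
            k = rec.key
            if k not in best or rec.depth > best[k].depth:
                best[k] = rec
        per_tp[tp] = best
        locus_set |= {k for k, r in best.items() if r.alt_count > 0}

    out = []
    for tp in candidates_by_timepoint:
        best = per_tp[tp]
        mafs = []
        for k in sorted(locus_set):
            rec = best.get(k)
            if rec is None or rec.depth == 0:
                continue  # not covered at this draw
            if rec.alt_count == 0 and cfg.undetected_maf_policy == "drop":
                continue
            mafs.append(rec.vaf)
        value = float(np.mean(mafs)) if mafs else None
        ca = None
        if ca199 is not None and timepoint_days and tp in timepoint_days:
            day = timepoint_days[tp]
            gaps = (ca199["day"] - day).abs()
            i = gaps.idxmin()
            if gaps[i] <= cfg.ca199_max_day_gap:
                ca = float(ca199.loc[i, "value"])
        out.append(TimepointSummary(
            patient_id=patient_id, timepoint_label=tp,
            n_candidates=sum(1 for r in best.values() if r.alt_count > 0),
            mean_maf=value, n_covered_loci=len(mafs), ca199=ca))
    return out


def concordance(tumour_keys, plasma_keys_by_timepoint: dict) -> dict:
    """Tumour-plasma variant overlap at baseline and over combined plasma.

    Baseline is the first timepoint in the mapping's order; fractions are of
    the tumour call set. Empty tumour sets yield None fractions, flagged.
    """
    tumour = set(tumour_keys)
    tps = list(plasma_keys_by_timepoint)
    baseline = set(plasma_keys_by_timepoint[tps[0]]) if tps else set()
    combined: set = set()
    for tp in tps:
        combined |= set(plasma_keys_by_timepoint[tp])
    result = {
        "n_tumour": len(tumour),
        "n_baseline_plasma": len(baseline),
        "n_combined_plasma": len(combined),
        "n_overlap_baseline": len(tumour & baseline),
        "n_overlap_combined": len(tumour & combined),
        "plasma_specific": len(combined - tumour),
    }
    if tumour:
        result["baseline_fraction"] = len(tumour & baseline) / len(tumour)
        result["combined_fraction"] = len(tumour & combined) / len(tumour)
    else:
        result["baseline_fraction"] = result["combined_fraction"] = None
        result["undefined"] = True
    return result


def mutation_load_table(loads: dict, groups: dict | None = None) -> dict:
    """Per-sample mutation loads with optional two-group comparison.

    ``loads`` maps sample_id to candidate count; ``groups`` maps sample_id to
    a group label (e.g. resectable / unresectable). The Mann-Whitney rank
    test p is reported descriptively when both groups have members.
    """
    table = pd.DataFrame(
        [{"sample_id": sid, "n_mutations": n,
          "group": (groups or {}).get(sid)} for sid, n in loads.items()])
    out = {"table": table}
    if groups:
        by_group = table.dropna(subset=["group"]).groupby("group")["n_mutations"]
        medians = by_group.median().to_dict()
        out["group_medians"] = medians
        vals = [g.values for _, g in by_group]
        if len(vals) == 2 and all(len(v) for v in vals):
            out["mannwhitney_p"] = float(mannwhitneyu(vals[0], vals[1]).pvalue)
    return out


def modal_fragment_size(lengths, labels=None) -> dict:
    """Histogram mode of fragment lengths at 1 bp resolution.

    Ties resolve to the smallest length and are flagged. With per-fragment
    allele-class ``labels`` (e.g. mutant / wild-type) a per-class mode is
    also reported.
    """
    lengths = np.asarray(lengths, dtype=int)
    if lengths.size == 0:
        raise ValueError("no fragment lengths supplied")
    if lengths.min() < 50:
        raise ValueError("fragment lengths below 50 bp are not expected")

    def mode_of(arr):
        values, counts = np.unique(arr, return_counts=True)
        top = counts.max()
        winners = values[counts == top]
        return int(winners.min()), len(winners) > 1

    mode, tie = mode_of(lengths)
    out = {"mode": mode, "tie": tie, "n": int(lengths.size)}
    if labels is not None:
        labels = np.asarray(labels)
        out["per_class"] = {}
        for cls in np.unique(labels):
            m, t = mode_of(lengths[labels == cls])
            out["per_class"][str(cls)] = {"mode": m, "tie": t}
    return out


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def pathway_enrichment(selected_genes, pathway_db: dict,
                       universe=None) -> tuple[list, int]:
    """Hypergeometric over-representation of selected genes per pathway.

    ``pathway_db`` maps pathway id to a gene set; the universe defaults to
    the union of all pathway genes. Selected genes outside the universe are
    excluded and counted. P-values are Benjamini-Hochberg adjusted across
    pathways.
    """
    universe = set(universe) if universe is not None else \
        set().union(*pathway_db.values()) if pathway_db else set()
    selected = set(selected_genes)
    excluded = len(selected - universe)
    selected &= universe
    N, n = len(universe), len(selected)
    results = []
    for pid in sorted(pathway_db):
        genes = set(pathway_db[pid]) & universe
        K = len(genes)
        k = len(genes & selected)
        results.append(EnrichmentResult(
            pathway_id=pid, universe_size=N, pathway_size=K,
            n_selected=n, n_overlap=k, p_value=hypergeom_pvalue(N, K, n, k)))
    if results:
        qs = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qs):
            r.q_value = float(q)
    return results, excluded


def load_gene_catalogue(path=None) -> pd.DataFrame:
    """Gene -> class/therapy catalogue (bundled toy catalogue by default)."""
    if path is None:
        path = resources.files("ctlong.data") / "gene_catalogue.tsv"
    return pd.read_csv(path, sep="\t")


def load_pathway_db(path=None) -> dict:
    """Pathway gene sets from a two-column TSV (pathway_id, gene)."""
    if path is None:
        path = resources.files("ctlong.data") / "pathways.tsv"
    df = pd.read_csv(path, sep="\t")
    return {pid: set(g["gene"]) for pid, g in df.groupby("pathway")}


def annotate_actionability(candidates_by_sample: dict,
                           catalogue: pd.DataFrame | None = None,
                           config: TrackingConfig | None = None) -> pd.DataFrame:
    """Oncoprint-ready gene x annotation table for one patient.

    ``candidates_by_sample`` maps plasma sample ids (serial order) to
    filtered records. Each mutated catalogued gene is reported with its
    class and therapy hint; a variant detected in at least two serial plasma
    samples is flagged trackable.
    """
    cfg = config or TrackingConfig()
    if catalogue is None:
        catalogue = load_gene_catalogue()
    classes = dict(zip(catalogue["gene"], catalogue["gene_class"]))
    therapy_col = catalogue["therapy"] if "therapy" in catalogue.columns \
        else pd.Series(["."] * len(catalogue))
    therapy = dict(zip(catalogue["gene"], therapy_col))

    seen_in: dict[tuple, set] = {}
    gene_of: dict[tuple, str] = {}
    for sid, records in candidates_by_sample.items():
        for rec in records:
            if isinstance(rec, VariantRecord) and rec.alt_count > 0:
                seen_in.setdefault(rec.key, set()).add(sid)
                if rec.annotations.gene:
                    gene_of[rec.key] = rec.annotations.gene
    rows = []
    for key in sorted(seen_in):
        gene = gene_of.get(key)
        if gene is None:
            continue
        rows.append({
            "chrom": key[0], "pos": key[1], "ref": key[2], "alt": key[3],
            "gene": gene,
            "gene_class": classes.get(gene, "none"),
            "therapy": therapy.get(gene, "."),
            "n_plasma_detected": len(seen_in[key]),
            "trackable": len(seen_in[key]) >= cfg.trackable_min_timepoints,
        })
    cols = ["chrom", "pos", "ref", "alt", "gene", "gene_class", "therapy",
            "n_plasma_detected", "trackable"]
    return pd.DataFrame(rows, columns=cols)
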