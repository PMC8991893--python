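"""End-to-end orchestration: simulate -> filter -> kataegis -> signatures ->
copy number -> clones -> tracking, with deterministic on-disk outputs.

Every stage writes plain TSV/JSON under the output directory; given the same
seed two runs produce bitwise-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import clonal, copynumber, filtering, kataegis, signatures, simdata, tracking
from .config import PipelineConfig, default_config


def default_cohort_configs(seed: int = 0) -> dict:
    """Three patients spanning the study's sampling designs."""
    return {
        "PT01": simdata.SimConfig(seed=seed, n_timepoints=5),
        "PT02": simdata.SimConfig(seed=seed, n_timepoints=4, n_clones=4,
                                  tumour_fraction_per_timepoint=(0.30, 0.10, 0.15, 0.08),
                                  plasma_days=(40, 120, 250, 400)),
        "PT03": simdata.SimConfig(seed=seed, n_timepoints=3, n_clones=3,
                                  include_tumour=False,
                                  tumour_fraction_per_timepoint=(0.20, 0.12, 0.05),
                                  plasma_days=(30, 150, 300)),
    }


def _filter_patient(patient: simdata.PatientSim, cohort: simdata.CohortSim,
                    config: PipelineConfig):
    plasma = [r for m in patient.manifest if m.sample_class == "plasma"
              for r in patient.tables[m.sample_id]]
    tumour = [r for m in patient.manifest if m.sample_class == "tumour"
              for r in patient.tables[m.sample_id]]
    germline = [r for m in patient.manifest if m.sample_class == "germline"
                for r in patient.tables[m.sample_id]]
    cp = [r for recs in cohort.cp_tables.values() for r in recs]
    return filtering.run_cascade(
        plasma, germline_records=germline, tumour_records=tumour or None,
        cp_records=cp, blacklist=cohort.blacklist, config=config.filtering,
        patient_id=patient.patient_id)


def run_pipeline(outdir, seed: int = 0, config: PipelineConfig | None = None,
                 cohort_configs: dict | None = None) -> dict:
    """Run the whole analysis on a simulated cohort; returns a result summary."""
    cfg = config or default_config()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = simdata.simulate_cohort(cohort_configs or default_cohort_configs(seed),
                                     seed=seed)
    simdata.write_cohort(cohort, out / "sim")

    summary: dict = {"seed": seed, "patients": {}}
    for patient in cohort.patients:
        pid = patient.patient_id
        pdir = out / pid
        pdir.mkdir(exist_ok=True)
        psum: dict = {}

        # filtering cascade
        report = _filter_patient(patient, cohort, cfg)
        pd.DataFrame(report.summary()).to_csv(pdir / "filter_report.tsv",
                                              sep="\t", index=False)
        from .core_io import write_variant_table
        write_variant_table(report.survivors, pdir / "candidates.tsv")
        psum["filter"] = report.summary()

        plasma_ids = [m.sample_id for m in patient.manifest
                      if m.sample_class == "plasma"]
        by_tp = {m.timepoint_label: [r for r in report.survivors
                                     if r.sample_id == m.sample_id]
                 for m in patient.manifest if m.sample_class == "plasma"}

        # kataegis on the combined plasma candidate set
        events = kataegis.detect_kataegis(report.survivors, cfg.kataegis)
        total = len({r.key for r in report.survivors})
        covered = sum(simdata.AUTOSOME_MB.values()) * 1_000_000
        kataegis.score_events(events, total, covered, cfg.kataegis)
        pd.DataFrame([{
            "chrom": e.chrom, "start": e.start, "end": e.end,
            "n_mutations": e.n_mutations, "mean_imd": round(e.mean_imd, 1),
            "score": round(e.score, 2) if e.score is not None else ".",
            "dominant_class": "/".join(e.dominant_class)} for e in events]
        ).to_csv(pdir / "kataegis.tsv", sep="\t", index=False)
        psum["kataegis_events"] = len(events)

        # signature refitting on the combined candidate spectrum
        uniq = {r.key: r for r in report.survivors}
        spectrum, skipped = signatures.trinucleotide_spectrum(uniq.values())
        if spectrum.sum() > 0:
            exposure = signatures.fit_exposures(spectrum, cohort.signature_matrix,
                                                cfg.signatures)
            exposure.weights.to_csv(pdir / "exposures.tsv", sep="\t",
                                    header=["weight"], float_format="%.6g")
            psum["signature_labels"] = signatures.classify_instability(
                exposure, cfg.signatures)

        # copy number / tumour fraction on a baseline-plasma bin profile
        rng_cn = np.random.default_rng(seed + 17)
        t0 = patient.config.tumour_fraction_per_timepoint[0]
        aberrant = {"chr18": 1, "chr8": 3, "chr17": (35, 45, 4)}
        sample_bins, normal_bins, _ = simdata.simulate_bin_profiles(
            t0, aberrant, rng_cn)
        profile = copynumber.normalize_bins(sample_bins, normal_bins, cfg.copynumber)
        cn = copynumber.segment_and_estimate(profile, config=cfg.copynumber)
        copynumber.segments_table(cn, pdir / "segments.tsv")
        psum["tumour_fraction"] = {"true": t0,
                                   "estimated": round(cn.tumour_fraction, 4)}

        # clonal inference (patients with >=3 plasma draws)
        if len(plasma_ids) >= 3:
            keys = sorted({r.key for r in report.survivors})
            idx = {k: i for i, k in enumerate(keys)}
            alt = np.zeros((len(keys), len(plasma_ids)))
            depth = np.zeros_like(alt)
            for j, sid in enumerate(plasma_ids):
                for r in patient.tables[sid]:
                    i = idx.get(r.key)
                    if i is not None:
                        alt[i, j] = r.alt_count
                        depth[i, j] = r.depth
            if len(keys) >= 2:
                assign = clonal.cluster_vafs(alt, depth, seed=seed,
                                             config=cfg.clonal)
                tree = clonal.infer_longitudinal_tree(assign, cfg.clonal)
                stem, stem_tie = clonal.identify_stem_clone(tree)
                dyn = clonal.call_dynamics(tree, config=cfg.clonal)
                pd.DataFrame(tree.prevalence,
                             index=[f"clone{i}" for i in range(assign.k)],
                             columns=[m.timepoint_label for m in patient.manifest
                                      if m.sample_class == "plasma"]
                             ).to_csv(pdir / "prevalence.tsv", sep="\t",
                                      float_format="%.4f")
                (pdir / "clone_tree.nwk").write_text(
                    clonal.tree_newick(tree) + "\n")
                psum["clonal"] = {"k": assign.k, "violation": tree.violation,
                                  "stem_clone": stem, "dynamics": dyn}

        # tracking summaries
        series = tracking.mean_maf_series(by_tp, patient_id=pid,
                                          config=cfg.tracking)
        pd.DataFrame([{
            "timepoint": s.timepoint_label, "n_candidates": s.n_candidates,
            "mean_maf": "." if s.mean_maf is None else round(s.mean_maf, 5)}
            for s in series]).to_csv(pdir / "maf_series.tsv", sep="\t", index=False)
        psum["mean_maf"] = {s.timepoint_label: s.mean_maf for s in series}

        tumour_keys = {r.key for m in patient.manifest
                       if m.sample_class == "tumour"
                       for r in patient.tables[m.sample_id] if r.alt_count >= 3}
        if tumour_keys:
            plasma_keys = {tp: {r.key for r in recs if r.alt_count > 0}
                           for tp, recs in by_tp.items()}
            psum["concordance"] = tracking.concordance(tumour_keys, plasma_keys)

        onco = tracking.annotate_actionability(
            {sid: [r for r in report.survivors if r.sample_id == sid]
             for sid in plasma_ids}, config=cfg.tracking)
        onco.to_csv(pdir / "actionability.tsv", sep="\t", index=False)

        frag = tracking.modal_fragment_size(patient.fragments)
        psum["fragment_mode"] = frag["mode"]

        driver_genes = sorted({g for g in onco["gene"]})
        enrich, _ = tracking.pathway_enrichment(driver_genes,
                                                tracking.load_pathway_db())
        pd.DataFrame([{
            "pathway": e.pathway_id, "K": e.pathway_size, "k": e.n_overlap,
            "p": f"{e.p_value:.4g}", "q": f"{e.q_value:.4g}"} for e in enrich]
        ).to_csv(pdir / "pathway_enrichment.tsv", sep="\t", index=False)

        summary["patients"][pid] = psum

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")
    return summary


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
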