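"""96-channel trinucleotide spectra and mutational-signature refitting.

Exposures are refit against a provided signature catalogue by iterative
forward selection: starting from an empty set, the signature whose inclusion
most reduces the sum of squared errors (weights re-solved by non-negative
least squares at each step) is added until the relative SSE improvement falls
below a stopping tolerance; weights below a discard threshold are then zeroed
and the remaining set re-solved. This mirrors the refitting strategy of
widely used exposure-fitting tools while staying a pure least-squares
procedure with no sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from ._genome import CHANNELS, channel_of
from .config import SignatureConfig
from .core_io import VariantRecord


@dataclass(slots=True)
class ExposureVector:
    """Fitted signature weights for one sample's spectrum."""

    weights: pd.Series          # indexed by signature name, >= 0, sum <= 1
    sse: float
    n_mutations: int
    skipped_variants: int = 0

    def active(self) -> pd.Series:
        return self.weights[self.weights > 0]


def trinucleotide_spectrum(variants, contexts=None):
    """Count SNVs into the 96 pyrimidine-referenced channels.

    The trinucleotide context comes either from each record's ``extra
    ["context"]`` column or from a ``contexts`` mapping of (chrom, pos) to
    3-mers. Purine-reference sites are reverse-complemented including flanks.
    Variants with missing or ambiguous context are skipped and counted.

    Returns ``(spectrum, n_skipped)`` with the spectrum as a length-96 int
    array in canonical channel order.
    """
    spectrum = np.zeros(96, dtype=int)
    skipped = 0
    index = {c: i for i, c in enumerate(CHANNELS)}
    for rec in variants:
        if isinstance(rec, VariantRecord):
            if not rec.is_snv:
                skipped += 1
                continue
            ctx = rec.extra.get("context")
            if ctx is None and contexts is not None:
                ctx = contexts.get((rec.chrom, rec.pos))
            ref, alt = rec.ref, rec.alt
        else:
            ref, alt, ctx = rec
        try:
            chan = channel_of(ref, alt, ctx or "")
        except ValueError:
            skipped += 1
            continue
        spectrum[index[chan]] += 1
    return spectrum, skipped


def _solve_subset(M: np.ndarray, s: np.ndarray, subset: list) -> tuple[np.ndarray, float]:
    """Non-negative least squares on a signature subset; weights capped at sum 1."""
    w_sub, _ = nnls(M[:, subset], s)
    total = w_sub.sum()
    if total > 1.0:
        w_sub = w_sub / total
    resid = s - M[:, subset] @ w_sub
    return w_sub, float(resid @ resid)


def fit_exposures(spectrum, signature_matrix: pd.DataFrame,
                  config: SignatureConfig | None = None) -> ExposureVector:
    """Forward-selection signature refit of one 96-channel spectrum.

    ``spectrum`` may be raw channel counts or proportions; it is normalized
    to proportions, so exposures are invariant to the mutation count scale.
    """
    cfg = config or SignatureConfig()
    s = np.asarray(spectrum, dtype=float)
    if s.shape[0] != 96:
        raise ValueError(f"spectrum has {s.shape[0]} channels, expected 96")
    n_mut = int(round(s.sum()))
    if s.sum() <= 0:
        raise ValueError("empty spectrum: no mutations to fit")
    s = s / s.sum()
    M = signature_matrix.to_numpy(dtype=float)
    names = list(signature_matrix.columns)

    chosen: list[int] = []
    sse = float(s @ s)  # SSE of the empty model
    while len(chosen) < len(names):
        best = None
        for j in range(len(names)):
            if j in chosen:
                continue
            _, trial_sse = _solve_subset(M, s, chosen + [j])
            if best is None or trial_sse < best[1]:
                best = (j, trial_sse)
        j, new_sse = best
        if sse > 0 and (sse - new_sse) / sse < cfg.stop_rel_improvement:
            break
        chosen.append(j)
        sse = new_sse
        if sse <= 1e-15:
            break

    w = np.zeros(len(names))
    if chosen:
        w_sub, sse = _solve_subset(M, s, chosen)
        w[chosen] = w_sub
        # discard trace exposures and re-solve on the surviving set
        keep = [j for j in chosen if w[j] >= cfg.discard_threshold]
        if keep != chosen:
            w = np.zeros(len(names))
            if keep:
                w_sub, sse = _solve_subset(M, s, keep)
                w[keep] = w_sub
            else:
                sse = float(s @ s)
    return ExposureVector(weights=pd.Series(w, index=names), sse=sse,
                          n_mutations=n_mut)


def classify_instability(exposure: ExposureVector,
                         config: SignatureConfig | None = None) -> list:
    """Genomic-instability labels implied by post-discard signature weights.

    DSBR (double-strand break repair deficiency) when the BRCA-associated
    signature carries weight; MMR (mismatch repair deficiency) when any of
    its associated signatures do; POLN for the polymerase-nu hypermutation
    signature. Signature ids missing from the catalogue leave that label
    undetermined.
    """
    cfg = config or SignatureConfig()
    labels = []
    mapping = (("DSBR", cfg.dsbr_signatures), ("MMR", cfg.mmr_signatures),
               ("POLN", cfg.poln_signatures))
    for label, sigs in mapping:
        present = [sg for sg in sigs if sg in exposure.weights.index]
        if not present:
            labels.append(f"{label}?")  # undetermined: signature absent from matrix
            continue
        if any(exposure.weights[sg] > 0 for sg in present):
            labels.append(label)
    return labels


def exposures_table(exposures: dict, path=None) -> pd.DataFrame:
    """Samples x signatures exposure table (one ExposureVector per sample)."""
    df = pd.DataFrame({sid: ev.weights for sid, ev in exposures.items()}).T
    df.index.name = "sample_id"
    if path is not None:
        df.to_csv(path, sep="\t", float_format="%.6g")
    return df
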