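"""Longitudinal clonal inference from serial plasma allele fractions.

Variants are clustered across the joint timepoint space with an
absence-aware binomial mixture: a variant contributes a
Binomial(depth, phi_{k,j}) likelihood at every timepoint, so zero alt reads
at a timepoint is evidence about the cluster trajectory rather than missing
data. The number of clusters is chosen by BIC; each EM run uses seeded
k-means++ initialization with multiple restarts.

Cluster mean VAFs are converted to cellular prevalences U = clip(2*phi, 0, 1)
under the heterozygous copy-neutral model, and a rooted tree over clusters is
found by exhaustive enumeration of all rooted spanning forests under a
virtual germline root whose capacity at each timepoint is the total
tumour-derived fraction (estimated by the largest clone prevalence). The tree
minimizing the total sum-condition violation

    sum_{k,j} max(0, sum_{children c of k} U_{c,j} - U_{k,j})

is returned, with violations bucketed at the prevalence-estimation noise
scale; trees tied at that resolution are ranked by the likelihood of their
parent-child prevalence splits under a neutral Dirichlet model, then by
summed parent-child trajectory correlation, then lexicographically.
Per-timepoint clonal proportions are the child-subtracted prevalences.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .config import ClonalConfig


from math import lgamma


@dataclass(slots=True)
class ClusterAssignment:
    labels: np.ndarray          # per-variant cluster index
    phi: np.ndarray             # k x T cluster mean VAFs
    sizes: np.ndarray
    log_likelihood: float
    bic: float
    k: int
    excluded: list = field(default_factory=list)  # all-zero variant indices
    mean_depth: float = 1000.0  # mean per-variant depth, for noise scaling


@dataclass(slots=True)
class CloneTreeResult:
    parents: tuple              # parents[k] = parent cluster index or -1 (germline)
    prevalence: np.ndarray      # U, k x T
    proportions: np.ndarray     # child-subtracted, k x T, floored at 0
    violation: float
    tie: bool = False


# ---------------------------------------------------------------------------
# absence-aware binomial mixture EM

def _binom_loglik_matrix(alt, depth, phi):
    """(n x k) log-likelihood of each variant's trajectory under each cluster."""
    const = (gammaln(depth + 1) - gammaln(alt + 1)
             - gammaln(depth - alt + 1)).sum(axis=1)
    lp = alt @ np.log(phi).T + (depth - alt) @ np.log1p(-phi).T
    return lp + const[:, None]


def _em_fit(alt, depth, k, rng, cfg: ClonalConfig):
    n, T = alt.shape
    vaf = alt / np.maximum(depth, 1)
    # k-means++ style seeding on VAF trajectories
    centers = [vaf[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min([((vaf - c) ** 2).sum(axis=1) for c in centers], axis=0)
        total = d2.sum()
        probs = d2 / total if total > 0 else np.full(n, 1.0 / n)
        centers.append(vaf[rng.choice(n, p=probs)])
    phi = np.clip(np.array(centers), 1e-4, 1 - 1e-4)
    pi = np.full(k, 1.0 / k)

    prev_ll = -np.inf
    for _ in range(cfg.max_em_iter):
        logr = _binom_loglik_matrix(alt, depth, phi) + np.log(pi)[None, :]
        norm = logsumexp(logr, axis=1)
        ll = float(norm.sum())
        resp = np.exp(logr - norm[:, None])
        # EM monotonicity: the observed-data likelihood must not decrease
        assert ll >= prev_ll - 1e-6 * max(abs(prev_ll), 1.0), \
            "EM likelihood decreased"
        if ll - prev_ll < cfg.em_tol * max(abs(ll), 1.0):
            prev_ll = ll
            break
        prev_ll = ll
        pi = np.clip(resp.mean(axis=0), 1e-12, None)
        pi = pi / pi.sum()
        wsum = resp.T @ depth
        phi = np.clip((resp.T @ alt) / np.maximum(wsum, 1e-12), 1e-6, 1 - 1e-6)
    labels = np.argmax(resp, axis=1)
    return prev_ll, phi, pi, labels


def cluster_vafs(alt, depth, k_range=None, seed: int = 0,
                 config: ClonalConfig | None = None) -> ClusterAssignment:
    """Cluster variant trajectories with an absence-aware binomial mixture.

    ``alt`` and ``depth`` are (variants x timepoints) count matrices over
    a patient's serial plasma samples. Variants never detected at any
    timepoint are excluded and reported. k is selected by BIC over
    ``k_range``; each candidate k runs multiple seeded restarts and keeps the
    best likelihood.
    """
    cfg = config or ClonalConfig()
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if alt.shape != depth.shape:
        raise ValueError("alt and depth shapes differ")
    n_all = alt.shape[0]
    detected = alt.sum(axis=1) > 0
    excluded = list(np.flatnonzero(~detected))
    alt_d, depth_d = alt[detected], depth[detected]
    n, T = alt_d.shape
    if n == 0:
        raise ValueError("no variant detected at any timepoint")

    rng = np.random.default_rng(seed)
    k_range = tuple(k for k in (k_range or cfg.k_range) if k <= n)
    best = None
    for k in k_range:
        best_k = None
        for _ in range(cfg.n_restarts):
            ll, phi, pi, labels = _em_fit(alt_d, depth_d, k, rng, cfg)
            if best_k is None or ll > best_k[0]:
                best_k = (ll, phi, pi, labels)
        ll, phi, pi, labels = best_k
        n_params = k * T + (k - 1)
        bic = -2.0 * ll + n_params * np.log(n)
        if best is None or bic < best[0]:
            best = (bic, ll, phi, labels, k)

    bic, ll, phi, labels_d, k = best
    # deterministic cluster order: by descending mean phi
    order = np.argsort(-phi.mean(axis=1), kind="stable")
    phi = phi[order]
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels_d = remap[labels_d]

    labels = np.full(n_all, -1, dtype=int)
    labels[detected] = labels_d
    sizes = np.bincount(labels_d, minlength=k)
    return ClusterAssignment(labels=labels, phi=phi, sizes=sizes,
                             log_likelihood=ll, bic=bic, k=k, excluded=excluded,
                             mean_depth=float(depth_d.mean()))


# ---------------------------------------------------------------------------
# sum-condition tree search

def _enumerate_parent_vectors(k: int):
    """All rooted spanning forests over k clusters under a germline root.

    Yields parent vectors p with p[i] in {-1 (germline), 0..k-1}\\{i}. Trees on
    the k+1 node set (germline = node 0) are enumerated via Pruefer sequences;
    for small k a direct product with an acyclicity check is faster.
    """
    if k == 1:
        yield (-1,)
        return
    for parents in itertools.product(range(-1, k), repeat=k):
        ok = True
        for i in range(k):
            if parents[i] == i:
                ok = False
                break
            # walk to the root; a cycle revisits i
            seen = 0
            j = parents[i]
            while j != -1:
                j = parents[j]
                seen += 1
                if seen > k:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            yield parents


def _violation(parents, U: np.ndarray) -> float:
    """Total sum-condition violation of a parent vector.

    The germline root has no somatic mutations, so its capacity in the
    ctDNA compartment is the total tumour-derived fraction at each timepoint,
    estimated by the largest observed clone prevalence; without this the
    germline capacity of 1 never binds at low tumour fraction and star-like
    trees are always feasible.
    """
    k, T = U.shape
    child_sum = np.zeros((k + 1, T))  # index k = germline
    for i, p in enumerate(parents):
        child_sum[p if p >= 0 else k] += U[i]
    germline_capacity = U.max(axis=0, keepdims=True)
    parent_prev = np.vstack([U, germline_capacity])
    return float(np.maximum(child_sum - parent_prev, 0.0).sum())


def _tie_score(parents, U: np.ndarray) -> float:
    """Sum of parent-child Pearson correlations (constant series score 0)."""
    total = 0.0
    for i, p in enumerate(parents):
        if p < 0:
            continue
        a, b = U[i], U[p]
        sa, sb = a.std(), b.std()
        if sa > 0 and sb > 0:
            total += float(np.corrcoef(a, b)[0, 1])
    return total


def _tree_loglik(parents, U: np.ndarray, floor: float = 1e-3) -> float:
    """Log-likelihood of a tree under a neutral Dirichlet-split model.

    If the children of each clone split a uniform-Dirichlet share of the
    parent's prevalence at every timepoint, the density of the observed child
    prevalences under parent p with m children is m!/U_p^m per timepoint.
    Maximizing this prefers attaching clones to the smallest feasible parent,
    which is the maximum-likelihood placement when the violation alone does
    not discriminate.
    """
    k, T = U.shape
    cap = np.maximum(U.max(axis=0), floor)
    ll = 0.0
    children: dict[int, list[int]] = {}
    for i, p in enumerate(parents):
        children.setdefault(p, []).append(i)
    for p, kids in children.items():
        m = len(kids)
        up = cap if p < 0 else np.maximum(U[p], floor)
        ll += T * lgamma(m + 1) - m * float(np.log(up).sum())
    return ll


def infer_longitudinal_tree(assignment: ClusterAssignment,
                            config: ClonalConfig | None = None) -> CloneTreeResult:
    """Exhaustive sum-condition tree search over VAF clusters.

    Prevalences are U = clip(2*phi, 0, 1); every rooted spanning forest under
    a virtual germline root (prevalence 1) is scored by its total
    sum-condition violation and the minimizer returned. When a zero-violation
    tree exists it is found by construction of the exhaustive search.
    """
    cfg = config or ClonalConfig()
    k = assignment.k
    if k > cfg.max_exhaustive_clones:
        raise ValueError(
            f"{k} clusters exceeds the exhaustive-search cap "
            f"({cfg.max_exhaustive_clones}); raise max_exhaustive_clones "
            "only if you can afford (k+1)^(k-1) trees")
    U = np.clip(2.0 * assignment.phi, 0.0, 1.0)

    # violations smaller than the prevalence-estimation noise cannot be
    # distinguished from zero: bucket them at ~3 standard errors of a cluster
    # prevalence so noise-scale differences fall through to the likelihood
    # and correlation tie-breaks
    phi = assignment.phi
    sizes = np.maximum(assignment.sizes, 1)
    se = 2.0 * np.sqrt(phi * (1 - phi) /
                       np.maximum(sizes[:, None] * assignment.mean_depth, 1.0))
    tol = max(3.0 * float(np.median(se)), 1e-6)

    best = None
    tie = False
    for parents in _enumerate_parent_vectors(k):
        v = _violation(parents, U)
        # violations are compared at the noise resolution: a tree whose
        # violation is within the prevalence standard error of zero is as
        # feasible as an exactly-feasible tree, and the likelihood decides
        key = (round(v / tol), -_tree_loglik(parents, U),
               -_tie_score(parents, U), parents)
        if best is None or key < best[0]:
            best = (key, parents, v)
            tie = False
        elif key[:3] == best[0][:3]:
            tie = True

    _, parents, violation = best
    child_sum = np.zeros_like(U)
    for i, p in enumerate(parents):
        if p >= 0:
            child_sum[p] += U[i]
    proportions = np.maximum(U - child_sum, 0.0)
    return CloneTreeResult(parents=tuple(parents), prevalence=U,
                           proportions=proportions, violation=violation, tie=tie)


def identify_stem_clone(result: CloneTreeResult) -> tuple[int, bool]:
    """Cluster with the highest mean prevalence across timepoints.

    Returns ``(clone_index, tie)``; ties resolve to the smallest index.
    """
    means = result.prevalence.mean(axis=1)
    best = float(means.max())
    winners = np.flatnonzero(np.isclose(means, best))
    return int(winners[0]), len(winners) > 1


def call_dynamics(result: CloneTreeResult, timepoint_days=None,
                  treatment_days=None,
                  config: ClonalConfig | None = None) -> list:
    """Per-clone emergence/decline/stability labels.

    A clone is *emergent* when undetectable (below the detection floor) at
    baseline but detected later; *declining* when its prevalence halves
    between consecutive timepoints (restricted to intervals spanning a
    treatment day when ``treatment_days`` is supplied); otherwise *stable*.
    """
    cfg = config or ClonalConfig()
    eps = cfg.detection_floor
    U = result.prevalence
    k, T = U.shape
    labels = []
    for i in range(k):
        u = U[i]
        if u[0] <= eps and (u[1:] > eps).any():
            labels.append("emergent")
            continue
        declining = False
        for j in range(T - 1):
            if treatment_days is not None and timepoint_days is not None:
                spans = any(timepoint_days[j] <= d <= timepoint_days[j + 1]
                            for d in treatment_days)
                if not spans:
                    continue
            if u[j] > eps and (u[j] - u[j + 1]) >= cfg.decline_fraction * u[j]:
                declining = True
                break
        labels.append("declining" if declining else "stable")
    return labels


def tree_newick(result: CloneTreeResult, names=None) -> str:
    """Newick string of the clone tree under the germline root."""
    k = len(result.parents)
    names = names or [f"clone{i}" for i in range(k)]
    children: dict[int, list[int]] = {i: [] for i in range(-1, k)}
    for i, p in enumerate(result.parents):
        children[p].append(i)

    def render(node: int) -> str:
        kids = children[node]
        label = "germline" if node == -1 else names[node]
        if not kids:
            return label
        return "(" + ",".join(render(c) for c in kids) + ")" + label

    return render(-1) + ";"
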