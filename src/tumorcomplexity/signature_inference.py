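"""De-novo mutational-signature inference and exposure refitting.

Signatures are extracted from a nonnegative categories x samples count
matrix by nonnegative matrix factorization (NMF) under the generalized
Kullback-Leibler objective with multiplicative updates — the convention of
the mutational-signature literature.  The factorization rank is selected by
consensus clustering over random restarts (cophenetic coefficient and mean
silhouette width), compared against the same diagnostics on a row-permuted
("randomized") version of the matrix to guard against overfitting.

Per-sample exposures are refit by nonnegative least squares with a minimum
contribution threshold: signatures below the threshold are not assigned and
their weight, together with the fit residual, is reported as
unassigned/other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.optimize import nnls
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .genome_io import ValidationError
from .feature_catalogs import FeatureMatrix

__all__ = [
    "SignatureModel",
    "ExposureVector",
    "extract_signatures",
    "match_to_reference",
    "refit_exposures",
    "cosine_similarity",
]

_EPS = 1e-12

EXPOSURE_THRESHOLD = 0.15
MIN_MUTATIONS = 50
NOVELTY_COSINE = 0.85


@dataclass
class SignatureModel:
    """Extracted signatures plus the rank-selection diagnostics."""

    scheme: str
    W: pd.DataFrame  # categories x K, columns sum to 1
    chosen_rank: int
    rank_diagnostics: pd.DataFrame  # per rank: cophenetic, silhouette, baselines

    def __post_init__(self):
        w = self.W.to_numpy()
        if (w < 0).any():
            raise ValidationError("signature matrix must be nonnegative")
        if not np.allclose(w.sum(axis=0), 1.0, atol=1e-9):
            raise ValidationError("signature columns must sum to 1")


@dataclass
class ExposureVector:
    """Per-sample signature proportions plus an unassigned remainder."""

    sample_id: str
    exposures: dict  # signature name -> proportion, each >= threshold
    unassigned: float

    def __post_init__(self):
        total = sum(self.exposures.values()) + self.unassigned
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValidationError(f"exposures + unassigned = {total}, expected 1")


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    mask = V > 0
    out = WH.sum() - V.sum()
    out += float((V[mask] * np.log(V[mask] / np.maximum(WH[mask], _EPS))).sum())
    return out


def _nmf_kl(
    V: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> tuple:
    """One NMF run (generalized KL, multiplicative updates).

    Returns ``(W, H, objective)``.  The multiplicative updates are monotone;
    a numerically significant increase in the objective raises, as a guard
    against implementation error.
    """
    n, m = V.shape
    scale = np.sqrt(V.mean() / k)
    W = rng.uniform(_EPS, 1.0, size=(n, k)) * scale
    H = rng.uniform(_EPS, 1.0, size=(k, m)) * scale
    prev = _kl_divergence(V, W @ H)
    obj = prev
    for it in range(max_iter):
        WH = np.maximum(W @ H, _EPS)
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = np.maximum(W @ H, _EPS)
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        if (it + 1) % 10 == 0 or it == max_iter - 1:
            obj = _kl_divergence(V, W @ H)
            if obj > prev + 1e-6 * (abs(prev) + 1.0):
                raise AssertionError("KL objective increased during updates")
            if prev - obj < tol * (abs(prev) + 1.0):
                prev = obj
                break
            prev = obj
    return W, H, prev


def _consensus_diagnostics(assignments: np.ndarray, k: int) -> tuple:
    """Cophenetic coefficient and mean silhouette of the consensus matrix.

    ``assignments`` is runs x samples cluster labels (dominant signature per
    sample per run).
    """
    n_runs, m = assignments.shape
    consensus = np.zeros((m, m))
    for r in range(n_runs):
        a = assignments[r]
        consensus += (a[:, None] == a[None, :]).astype(float)
    consensus /= n_runs
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    cond = squareform(dist, checks=False)
    Z = linkage(cond, method="average")
    with np.errstate(invalid="ignore", divide="ignore"):
        coph = cophenet(Z, cond)[0]
    if not np.isfinite(coph):
        coph = 1.0  # all pairwise distances identical (perfectly stable)
    labels = fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(labels)) < 2 or len(np.unique(labels)) >= m:
        sil = float("nan")
    else:
        sil = float(silhouette_score(dist, labels, metric="precomputed"))
    return float(coph), sil


def _randomize_rows(V: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each row's entries across samples."""
    R = V.copy()
    for i in range(R.shape[0]):
        rng.shuffle(R[i])
    return R


def extract_signatures(
    matrix: FeatureMatrix,
    ranks=range(2, 13),
    n_runs: int = 100,
    n_randomized_runs: int = 100,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-8,
    cophenetic_min: float = 0.95,
    silhouette_min: float = 0.8,
) -> SignatureModel:
    """De-novo NMF signature extraction with randomization-based rank selection.

    For each rank, ``n_runs`` random restarts are clustered into a consensus
    matrix; the cophenetic coefficient and mean silhouette width measure the
    stability of that rank.  The same diagnostics on a row-permuted matrix
    (``n_randomized_runs`` restarts) form the overfitting baseline.  The
    chosen rank is the largest one whose cophenetic >= ``cophenetic_min``,
    silhouette >= ``silhouette_min`` and both exceed the randomized baseline;
    if no rank qualifies, the rank with the highest cophenetic coefficient is
    used.  Signatures are taken from the best-objective restart at the chosen
    rank, columns normalized to sum 1.
    """
    V = matrix.to_array()
    if V.sum() == 0:
        raise ValidationError("all-zero feature matrix")
    m = V.shape[1]
    if m < 2:
        raise ValidationError("need at least 2 samples")
    root = np.random.default_rng(seed)
    Vrand = _randomize_rows(V, root)

    rows = []
    best_runs = {}  # rank -> (objective, W)
    for k in ranks:
        if k >= m:
            warnings.warn(f"rank {k} >= number of samples {m}; skipped")
            continue
        assign = np.empty((n_runs, m), dtype=int)
        best = (np.inf, None)
        for r in range(n_runs):
            rng = np.random.default_rng(root.integers(2**31))
            W, H, obj = _nmf_kl(V, k, rng, max_iter=max_iter, tol=tol)
            assign[r] = H.argmax(axis=0)
            if obj < best[0]:
                best = (obj, W)
        coph, sil = _consensus_diagnostics(assign, k)

        rassign = np.empty((n_randomized_runs, m), dtype=int)
        for r in range(n_randomized_runs):
            rng = np.random.default_rng(root.integers(2**31))
            _, Hr, _ = _nmf_kl(Vrand, k, rng, max_iter=max_iter, tol=tol)
            rassign[r] = Hr.argmax(axis=0)
        rcoph, rsil = _consensus_diagnostics(rassign, k)

        best_runs[k] = best
        rows.append((k, coph, sil, rcoph, rsil))

    if not rows:
        raise ValidationError("no usable ranks (all >= number of samples)")
    diag = pd.DataFrame(
        rows,
        columns=[
            "rank", "cophenetic", "silhouette",
            "randomized_cophenetic", "randomized_silhouette",
        ],
    ).set_index("rank")

    eligible = diag[
        (diag["cophenetic"] >= cophenetic_min)
        & (diag["silhouette"] >= silhouette_min)
        & (diag["cophenetic"] > diag["randomized_cophenetic"])
        & (diag["silhouette"] > diag["randomized_silhouette"])
    ]
    if len(eligible):
        chosen = int(eligible.index.max())
    else:
        chosen = int(diag["cophenetic"].idxmax())

    Wbest = best_runs[chosen][1]
    Wbest = Wbest / np.maximum(Wbest.sum(axis=0), _EPS)
    Wdf = pd.DataFrame(
        Wbest,
        index=list(matrix.labels),
        columns=[f"S{i + 1}" for i in range(chosen)],
    )
    return SignatureModel(matrix.scheme, Wdf, chosen, diag)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def match_to_reference(model: SignatureModel, reference: pd.DataFrame) -> pd.DataFrame:
    """Match each extracted signature to its closest reference signature.

    ``reference`` is a categories x signatures table with the same category
    labels (and order) as the model.  Matches with cosine similarity below
    0.85 are flagged novel.  Returns a table indexed by extracted-signature
    name with columns best_match, cosine, novel.
    """
    if list(reference.index) != list(model.W.index):
        raise ValidationError("reference categories do not match model scheme")
    rows = []
    for sig in model.W.columns:
        w = model.W[sig].to_numpy()
        sims = {ref: cosine_similarity(w, reference[ref].to_numpy()) for ref in reference.columns}
        best = max(sims, key=sims.get)
        rows.append((sig, best, sims[best], sims[best] < NOVELTY_COSINE))
    return pd.DataFrame(
        rows, columns=["signature", "best_match", "cosine", "novel"]
    ).set_index("signature")


def refit_exposures(
    catalog_column: np.ndarray,
    W: pd.DataFrame,
    threshold: float = EXPOSURE_THRESHOLD,
    min_mutations: int = MIN_MUTATIONS,
    max_signatures: int | None = None,
    sample_id: str = "sample",
) -> ExposureVector:
    """Refit one sample's catalog on fixed signatures by NNLS.

    The catalog is normalized to proportions, so the fit is scale invariant.
    Samples with ``min_mutations`` mutations or fewer are entirely
    unassigned.  Fitted signature weights below ``threshold`` (and, when
    ``max_signatures`` is set, any beyond the top contributors) are not
    assigned; their weight plus the fit residual forms the unassigned
    remainder.  Retained weights are reported as fitted, not re-inflated.
    """
    if W.shape[1] == 0:
        raise ValidationError("empty signature matrix")
    v = np.asarray(catalog_column, dtype=float)
    total = v.sum()
    if total <= min_mutations:
        return ExposureVector(sample_id, {}, 1.0)
    p = v / total
    A = W.to_numpy(dtype=float)
    x, _ = nnls(A, p)
    # weights are proportions: signature columns sum to 1 and p sums to 1
    x = np.minimum(x, 1.0)
    order = np.argsort(x)[::-1]
    keep = np.zeros_like(x, dtype=bool)
    for rank_i, j in enumerate(order):
        if x[j] >= threshold and (max_signatures is None or rank_i < max_signatures):
            keep[j] = True
    retained = {W.columns[j]: float(x[j]) for j in np.flatnonzero(keep)}
    if sum(retained.values()) > 1.0:  # numerical guard
        s = sum(retained.values())
        retained = {k: val / s for k, val in retained.items()}
    unassigned = 1.0 - sum(retained.values())
    return ExposureVector(sample_id, retained, float(unassigned))
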