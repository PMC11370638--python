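"""Temporal classification of viral genes by nonsmooth NMF.

Pipeline: median-of-ratios size factors -> gene-length standardization ->
replicate averaging per timepoint -> per-gene centering/scaling -> shift to
non-negativity -> nonsmooth nonnegative matrix factorization (nsNMF) ->
kinetic-class assignment (early ... late, ordered by the peak time of each
class's mean profile).  Also provides the replicate-concordance check that
justifies averaging replicates, and the threshold rule for calling
differentially expressed genes from a (log2 fold change, adjusted p) table.

nsNMF inserts a smoothing matrix S = (1 - theta) I + (theta / k) J between
the factors, V ~ W S H, which drives W and H toward sparser, more localized
structure as theta grows; theta = 0 recovers plain NMF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "NmfFactorization",
    "ClassAssignment",
    "size_factors",
    "length_standardize",
    "timepoint_profiles",
    "min_shift",
    "nsnmf_factorize",
    "assign_classes",
    "classify_genes",
    "replicate_concordance",
    "log2_fold_change",
    "de_threshold",
]

_EPS = 1e-12

CLASS_NAMES = {
    3: ["early", "mid", "late"],
    4: ["early", "early-mid", "mid", "late"],
}


@dataclass
class ExpressionMatrix:
    """Gene x sample counts with gene lengths and per-sample metadata.

    ``sample_meta`` is indexed by sample id with columns ``timepoint_h``,
    ``condition`` and ``replicate``.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.index) - set(self.gene_lengths.index)
        if missing:
            raise ValueError(f"genes without length: {sorted(missing)[:5]} ...")
        if not (self.gene_lengths.loc[self.counts.index] > 0).all():
            raise ValueError("all gene lengths must be > 0")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample scaling factors.

    For genes expressed in every sample, each sample's factor is the median of
    that sample's counts divided by the gene-wise geometric mean across
    samples.
    """
    mat = counts.to_numpy(float)
    expressed = (mat > 0).all(axis=1)
    if not expressed.any():
        raise ValueError("no gene expressed in all samples")
    log_sub = np.log(mat[expressed])
    log_ratios = log_sub - log_sub.mean(axis=1, keepdims=True)
    # median taken on the log scale (geometric interpolation between the two
    # middle genes when the count is even), matching the DESeq2 convention
    return pd.Series(
        np.exp(np.median(log_ratios, axis=0)), index=counts.columns,
        name="size_factor",
    )


def length_standardize(
    normalized: pd.DataFrame, gene_lengths: pd.Series
) -> pd.DataFrame:
    """Divide each gene's normalized counts by its length (bp)."""
    lengths = gene_lengths.reindex(normalized.index)
    if lengths.isna().any():
        missing = normalized.index[lengths.isna()].tolist()
        raise ValueError(f"missing length for gene(s): {missing[:5]}")
    if not (lengths > 0).all():
        raise ValueError("gene lengths must be > 0")
    return normalized.div(lengths, axis=0)


def timepoint_profiles(
    standardized: pd.DataFrame,
    sample_meta: pd.DataFrame,
    condition: str | None = None,
    ddof: int = 1,
) -> tuple[pd.DataFrame, pd.Index]:
    """Per-timepoint replicate means, then per-gene centering and scaling.

    Scaling uses the sample standard deviation (ddof=1) by default.  Genes
    with zero variance across timepoints get an all-zero profile and are
    returned in the flagged index.
    """
    meta = sample_meta
    if condition is not None:
        meta = meta[meta["condition"] == condition]
    cols = [c for c in standardized.columns if c in meta.index]
    if not cols:
        raise ValueError("no samples left after condition filtering")
    tps = meta.loc[cols, "timepoint_h"]
    means = standardized[cols].T.groupby(tps.values).mean().T
    means = means[sorted(means.columns)]
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=ddof)
    flat = means.index[sd == 0]
    sd_safe = sd.replace(0, 1.0)
    profiles = means.sub(mu, axis=0).div(sd_safe, axis=0)
    profiles.loc[flat] = 0.0
    return profiles, flat


def min_shift(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-gene shift to non-negativity: subtract each row's minimum."""
    return profiles.sub(profiles.min(axis=1), axis=0)


@dataclass
class NmfFactorization:
    """Result of one nsNMF run: V ~ W S H with S = (1-theta) I + (theta/k) J."""

    basis: np.ndarray  # W, genes x k
    coeff: np.ndarray  # H, k x samples
    theta: float
    rank: int
    seed: int
    reconstruction_error: float  # Frobenius residual ||V - W S H||_F
    objective_history: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))
    n_iter: int = 0
    converged: bool = False

    def smoothing_matrix(self) -> np.ndarray:
        k, th = self.rank, self.theta
        return (1.0 - th) * np.eye(k) + (th / k) * np.ones((k, k))

    def reconstruct(self) -> np.ndarray:
        if self.theta == 0:
            return self.basis @ self.coeff
        return self.basis @ self.smoothing_matrix() @ self.coeff


def _nsnmf_once(
    v: np.ndarray,
    k: int,
    theta: float,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    n, m = v.shape
    scale = np.sqrt(max(v.mean(), _EPS) / k)
    w = rng.uniform(_EPS, 1.0, size=(n, k)) * scale
    h = rng.uniform(_EPS, 1.0, size=(k, m)) * scale
    if theta == 0:
        s = None
    else:
        s = (1.0 - theta) * np.eye(k) + (theta / k) * np.ones((k, k))
    history = np.empty(max_iter)
    prev = np.inf
    converged = False
    it = 0
    for it in range(max_iter):
        # multiplicative Frobenius updates on the effective factors W S and S H
        ws = w if s is None else w @ s
        h *= (ws.T @ v) / (ws.T @ ws @ h + _EPS)
        sh = h if s is None else s @ h
        w *= (v @ sh.T) / (w @ (sh @ sh.T) + _EPS)
        obj = float(np.linalg.norm(v - (w @ sh if s is None else w @ s @ h), "fro"))
        history[it] = obj
        if np.isfinite(prev) and prev - obj <= tol * max(prev, _EPS):
            converged = True
            break
        prev = obj
    return w, h, history[: it + 1], converged


def nsnmf_factorize(
    matrix: np.ndarray | pd.DataFrame,
    rank: int,
    theta: float = 0.5,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    n_restarts: int = 30,
) -> NmfFactorization:
    """Nonsmooth NMF by multiplicative updates, best of ``n_restarts`` seeds.

    The Frobenius objective ||V - W S H||_F is non-increasing at every
    iteration (alternating Lee-Seung updates with fixed effective factors);
    iteration stops when the relative objective decrease falls below ``tol``.
    Fully reproducible given ``seed``.
    """
    v = np.asarray(matrix, float)
    if v.ndim != 2:
        raise ValueError("matrix must be 2-D")
    if (v < 0).any():
        raise ValueError("nsNMF input must be non-negative")
    if not 1 <= rank < min(v.shape) + 1:
        raise ValueError(f"rank {rank} out of range for shape {v.shape}")
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must be in [0, 1]")
    root = np.random.default_rng(seed)
    best: NmfFactorization | None = None
    for _ in range(max(1, n_restarts)):
        rng = np.random.default_rng(root.integers(2**31))
        w, h, history, converged = _nsnmf_once(v, rank, theta, rng, max_iter, tol)
        if best is None or history[-1] < best.reconstruction_error:
            best = NmfFactorization(
                basis=w,
                coeff=h,
                theta=theta,
                rank=rank,
                seed=seed,
                reconstruction_error=float(history[-1]),
                objective_history=history,
                n_iter=len(history),
                converged=converged,
            )
    assert best is not None
    return best


@dataclass
class ClassAssignment:
    """Gene -> kinetic class labels plus membership scores and tie flags."""

    labels: pd.Series
    membership: pd.Series
    class_order: list[str]
    class_peak_time: dict[str, float]
    tied_genes: list[str] = field(default_factory=list)


def assign_classes(
    factorization: NmfFactorization,
    profiles: pd.DataFrame,
) -> ClassAssignment:
    """Assign each gene to the basis component with its largest loading.

    Components are labelled early ... late by the peak timepoint of each
    component's mean member profile (the coefficient row's peak breaks ties
    and covers empty components).  Argmax ties between components are broken
    toward the temporally earlier class and flagged.
    """
    w = factorization.basis
    k = factorization.rank
    if w.shape[0] != len(profiles.index):
        raise ValueError("factorization and profiles disagree on gene count")
    timepoints = np.asarray(profiles.columns, float)
    raw_comp = np.argmax(w, axis=1)

    peak_time = np.empty(k)
    for c in range(k):
        members = raw_comp == c
        if members.any():
            mean_profile = profiles.to_numpy()[members].mean(axis=0)
        else:
            mean_profile = factorization.coeff[c]
        peak_time[c] = timepoints[int(np.argmax(mean_profile))]
    temporal_order = np.argsort(peak_time, kind="stable")

    names = CLASS_NAMES.get(k, [f"class_{i + 1}" for i in range(k)])
    # reorder columns so that argmax's first-index tie-break favours the
    # temporally earlier class
    w_ordered = w[:, temporal_order]
    comp_ordered = np.argmax(w_ordered, axis=1)
    row_max = w_ordered.max(axis=1)
    ties = (w_ordered == row_max[:, None]).sum(axis=1) > 1
    row_sum = w_ordered.sum(axis=1)
    membership = np.divide(
        row_max, row_sum, out=np.zeros_like(row_max), where=row_sum > 0
    )
    labels = pd.Series(
        [names[c] for c in comp_ordered], index=profiles.index, name="kinetic_class"
    )
    peaks = {names[i]: float(peak_time[temporal_order[i]]) for i in range(k)}
    return ClassAssignment(
        labels=labels,
        membership=pd.Series(membership, index=profiles.index, name="membership"),
        class_order=names,
        class_peak_time=peaks,
        tied_genes=list(profiles.index[ties]),
    )


def classify_genes(
    em: ExpressionMatrix,
    rank: int = 3,
    theta: float = 0.5,
    seed: int = 0,
    condition: str | None = None,
    n_restarts: int = 30,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> tuple[ClassAssignment, NmfFactorization, pd.DataFrame]:
    """Full kinetic-class pipeline on an ExpressionMatrix.

    Returns (assignment, factorization, centered/scaled profiles).
    """
    sf = size_factors(em.counts)
    normalized = em.counts / sf
    standardized = length_standardize(normalized, em.gene_lengths)
    profiles, _ = timepoint_profiles(standardized, em.sample_meta, condition=condition)
    fact = nsnmf_factorize(
        min_shift(profiles).to_numpy(),
        rank=rank,
        theta=theta,
        seed=seed,
        n_restarts=n_restarts,
        max_iter=max_iter,
        tol=tol,
    )
    return assign_classes(fact, profiles), fact, profiles


def replicate_concordance(
    em: ExpressionMatrix,
    rank: int | None = None,
    theta: float = 0.5,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[bool, pd.DataFrame]:
    """Check that timepoint replicates co-cluster before averaging them.

    Samples are clustered by the argmax of their nsNMF coefficient column on
    size-factor-normalized, length-standardized counts scaled per gene by the
    gene's mean (so components capture relative temporal profiles, not gene
    magnitudes; rank defaults to the number of distinct timepoints).  Returns
    ``(verdict, table)`` where the table lists each sample's cluster and
    whether its replicate group is concordant; the verdict is True when every
    replicate group shares one cluster.
    """
    sf = size_factors(em.counts)
    standardized = length_standardize(em.counts / sf, em.gene_lengths)
    row_means = standardized.mean(axis=1).replace(0, 1.0)
    standardized = standardized.div(row_means, axis=0)
    meta = em.sample_meta.loc[standardized.columns]
    if rank is None:
        rank = int(meta["timepoint_h"].nunique())
    fact = nsnmf_factorize(
        standardized.to_numpy(), rank=rank, theta=theta, seed=seed,
        n_restarts=n_restarts,
    )
    cluster = pd.Series(
        np.argmax(fact.coeff, axis=0), index=standardized.columns, name="cluster"
    )
    key_cols = ["timepoint_h"] + (
        ["condition"] if "condition" in meta.columns else []
    )
    table = meta[key_cols].copy()
    table["cluster"] = cluster
    concordant = table.groupby(key_cols)["cluster"].transform("nunique") == 1
    table["concordant"] = concordant
    return bool(concordant.all()), table


def log2_fold_change(
    normalized: pd.DataFrame,
    sample_meta: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Convenience log2 fold change (b over a) of mean normalized counts."""
    meta = sample_meta.loc[normalized.columns]
    a = normalized[meta.index[meta["condition"] == condition_a]].mean(axis=1)
    b = normalized[meta.index[meta["condition"] == condition_b]].mean(axis=1)
    return np.log2(b + pseudocount) - np.log2(a + pseudocount)


def de_threshold(
    table: pd.DataFrame,
    lfc_column: str = "log2fc",
    padj_column: str = "padj",
    lfc_threshold: float = 2.0,
    padj_threshold: float = 0.001,
) -> pd.DataFrame:
    """Differential-expression call: |log2FC| > 2 and adjusted p < 0.001.

    Both inequalities are strict.  Returns the significant rows with a
    ``direction`` column ("up"/"down" by the sign of the fold change).
    """
    for col in (lfc_column, padj_column):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    lfc = table[lfc_column].astype(float)
    padj = table[padj_column].astype(float)
    sig = (lfc.abs() > lfc_threshold) & (padj < padj_threshold)
    out = table.loc[sig].copy()
    out["direction"] = np.where(out[lfc_column] > 0, "up", "down")
    return out
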