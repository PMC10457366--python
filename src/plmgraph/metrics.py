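"""Evaluation statistics for the four downstream benchmark tasks.

Model quality assessment (MQA) ranks candidate structural models per
target by predicted quality (e.g. GDT-TS, consumed here as the true
score, never computed): per-target ("mean") and pooled ("global")
Spearman, Pearson and Kendall correlations, plus First Rank Loss — the
average over targets of the gap between the best model's true score and
the true score of the model ranked first by predictions.

Protein-protein rigid-body docking is scored by complex, ligand and
interface RMSD.  The default convention keeps the receptor fixed —
predicted and true coordinates are compared in the frame where the two
receptors coincide, with no Kabsch superposition of the compared point
sets; the superposed variant is available for cross-checking against
protocols that do align first.  Interface residues are all residues
participating in a cross-molecule CA pair strictly closer than 8
angstroms in the ground-truth complex.

Protein interface prediction uses AUROC (Mann-Whitney pair counting,
ties worth one half), and ligand binding affinity uses RMSE on
pK = -log10 K with K in molar units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import kendalltau, pearsonr, rankdata, spearmanr

from .errors import ShapeError, UndefinedMetricError, ValidationError

__all__ = [
    "RankingTable",
    "ComplexPair",
    "rank_correlations",
    "first_rank_loss",
    "auroc",
    "pk_from_affinity",
    "kabsch",
    "interface_residues",
    "docking_rmsds",
    "rmse",
]


@dataclass
class RankingTable:
    """(target_id, model_id, pred_score, true_score) rows for MQA metrics."""

    df: pd.DataFrame

    COLUMNS = ("target_id", "model_id", "pred", "true")

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise ValidationError(f"ranking table missing columns {missing}")
        if self.df.duplicated(["target_id", "model_id"]).any():
            raise ValidationError("duplicate (target_id, model_id) rows")
        if len(self.df) == 0:
            raise ValidationError("empty ranking table")

    @classmethod
    def from_rows(cls, rows) -> "RankingTable":
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    @classmethod
    def from_tsv(cls, path) -> "RankingTable":
        return cls(pd.read_csv(path, sep="\t",
                               names=list(cls.COLUMNS), header=0))


@dataclass
class ComplexPair:
    """A docked complex: the receptor is shared between truth and
    prediction (fixed during evaluation); ligand coordinates come in a
    true and a predicted copy with identical residue ordering."""

    receptor: np.ndarray       # (n_r, 3)
    ligand_true: np.ndarray    # (n_l, 3)
    ligand_pred: np.ndarray    # (n_l, 3)

    def __post_init__(self):
        self.receptor = np.asarray(self.receptor, dtype=float)
        self.ligand_true = np.asarray(self.ligand_true, dtype=float)
        self.ligand_pred = np.asarray(self.ligand_pred, dtype=float)
        for name in ("receptor", "ligand_true", "ligand_pred"):
            arr = getattr(self, name)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ShapeError(f"{name} must be (N, 3)")
        if self.ligand_true.shape != self.ligand_pred.shape:
            raise ShapeError("true and predicted ligand node counts differ")


def _safe_corr(fn, x, y) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero-variance scores; correlation reported as 0")
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = fn(x, y)[0]
    return float(r) if np.isfinite(r) else 0.0


def rank_correlations(t: RankingTable) -> dict[str, float]:
    """Mean (per-target average) and global (pooled) R_S, R_P, K_R.

    Kendall is the tie-corrected tau-b; Spearman uses average ranks.
    Targets with fewer than two models are excluded from the mean
    statistics with a warning; zero-variance targets contribute 0.
    """
    df = t.df
    if len(df) < 2:
        raise ValidationError("global correlations need >= 2 rows")
    pred, true = df["pred"].to_numpy(float), df["true"].to_numpy(float)
    out = {
        "global_RS": _safe_corr(spearmanr, pred, true),
        "global_RP": _safe_corr(pearsonr, pred, true),
        "global_KR": _safe_corr(kendalltau, pred, true),
    }
    per = {"RS": [], "RP": [], "KR": []}
    for tid, grp in df.groupby("target_id", sort=True):
        if len(grp) < 2:
            warnings.warn(f"target {tid!r} has a single model; excluded from"
                          " per-target correlations")
            continue
        p = grp["pred"].to_numpy(float)
        y = grp["true"].to_numpy(float)
        per["RS"].append(_safe_corr(spearmanr, p, y))
        per["RP"].append(_safe_corr(pearsonr, p, y))
        per["KR"].append(_safe_corr(kendalltau, p, y))
    if not per["RS"]:
        raise ValidationError("no target has >= 2 models")
    out.update({
        "mean_RS": float(np.mean(per["RS"])),
        "mean_RP": float(np.mean(per["RP"])),
        "mean_KR": float(np.mean(per["KR"])),
    })
    return out


def first_rank_loss(t: RankingTable) -> float:
    """Average over targets of max(true) - true(argmax pred).

    Prediction ties are broken toward the smaller model_id, making the
    statistic deterministic.
    """
    losses = []
    for _, grp in t.df.groupby("target_id", sort=True):
        grp = grp.sort_values(["pred", "model_id"],
                              ascending=[False, True], kind="mergesort")
        top_true = float(grp["true"].iloc[0])
        losses.append(float(grp["true"].max()) - top_true)
    return float(np.mean(losses))


def auroc(labels, scores) -> float:
    """Probability a random positive outscores a random negative, ties
    counted one half (Mann-Whitney U / pair-counting definition)."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ShapeError("labels and scores must have equal length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC requires both classes present")
    ranks = rankdata(s, method="average")
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def pk_from_affinity(K: float) -> float:
    """pK = -log10 K for a binding affinity K in molar units."""
    if K <= 0:
        raise ValidationError("binding affinity must be positive")
    return float(-np.log10(K))


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares optimal proper rigid superposition of P onto Q.

    Returns (R, t, rmsd) with q_i ~ R p_i + t and det(R) = +1 (a
    reflection is never returned).  Collinear or rank-deficient point
    sets still yield a solution, with a warning.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ShapeError("P and Q must both be (N, 3)")
    if P.shape[0] < 3:
        raise ValidationError("superposition needs at least 3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-9 * max(S[0], 1.0):
        warnings.warn("degenerate (collinear) point set in superposition")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = (P @ R.T) + t
    return R, t, rmse_coords(moved, Q)


def rmse_coords(A: np.ndarray, B: np.ndarray) -> float:
    """Root mean squared deviation between paired coordinate sets."""
    A, B = np.asarray(A, float), np.asarray(B, float)
    if A.shape != B.shape:
        raise ShapeError("coordinate sets must have equal shape")
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))


def interface_residues(rec: np.ndarray, lig: np.ndarray,
                       cutoff: float = 8.0) -> tuple[np.ndarray, np.ndarray]:
    """Indices of receptor/ligand residues in any cross-molecule CA pair
    strictly closer than ``cutoff`` (computed on the true complex).
    Empty index sets are legitimate (no contact)."""
    rec = np.asarray(rec, float)
    lig = np.asarray(lig, float)
    if rec.size == 0 or lig.size == 0:
        raise ValidationError("both molecules must be non-empty")
    close = cdist(rec, lig) < cutoff
    return np.nonzero(close.any(axis=1))[0], np.nonzero(close.any(axis=0))[0]


def docking_rmsds(c: ComplexPair, convention: str = "fixed_receptor",
                  cutoff: float = 8.0) -> dict[str, float]:
    """Complex, ligand and interface RMSD for one docked pair.

    ``fixed_receptor`` (default): the receptor frame is shared, so the
    deviation is measured directly — no superposition of the compared
    sets.  ``kabsch``: each compared point set is optimally superposed
    first.  Interface membership always comes from the ground-truth
    complex at the given cutoff.
    """
    if convention not in ("fixed_receptor", "kabsch"):
        raise ValidationError(f"unknown convention {convention!r}")
    rec_i, lig_i = interface_residues(c.receptor, c.ligand_true, cutoff)

    true_complex = np.vstack([c.receptor, c.ligand_true])
    pred_complex = np.vstack([c.receptor, c.ligand_pred])
    iface_true = np.vstack([c.receptor[rec_i], c.ligand_true[lig_i]])
    iface_pred = np.vstack([c.receptor[rec_i], c.ligand_pred[lig_i]])

    if convention == "fixed_receptor":
        return {
            "complex_rmsd": rmse_coords(pred_complex, true_complex),
            "ligand_rmsd": rmse_coords(c.ligand_pred, c.ligand_true),
            "interface_rmsd": rmse_coords(iface_pred, iface_true)
            if len(iface_true) else 0.0,
        }
    out = {}
    out["complex_rmsd"] = kabsch(pred_complex, true_complex)[2]
    out["ligand_rmsd"] = kabsch(c.ligand_pred, c.ligand_true)[2]
    out["interface_rmsd"] = (kabsch(iface_pred, iface_true)[2]
                             if len(iface_true) >= 3 else
                             rmse_coords(iface_pred, iface_true)
                             if len(iface_true) else 0.0)
    return out


def rmse(pred, true) -> float:
    """Root mean squared error between paired scalar lists."""
    p = np.asarray(pred, dtype=float).ravel()
    y = np.asarray(true, dtype=float).ravel()
    if p.shape != y.shape or p.size == 0:
        raise ShapeError("pred and true must be non-empty and equal length")
    return float(np.sqrt(np.mean((p - y) ** 2)))
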